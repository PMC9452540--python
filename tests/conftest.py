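"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from isotail.reference import LocusContext, MatureMiRNA, ReferenceCatalog
from isotail.simulate import simulate_reference


@pytest.fixture
def tiny_catalog() -> ReferenceCatalog:
    """Two hand-built miRNAs; mirX has two loci with different contexts."""
    mirx = MatureMiRNA(
        name="mirX-5p",
        sequence="UGAGGUAGUAGGUUGUAUAGUU",  # 22 nt, let-7a-like
        loci=(
            LocusContext("L1", "AGGAAGGAAGGAAGGAAGGA"),
            LocusContext("L2", "UGGUUGGUUGGUUGGUUGGU"),
        ),
        arm="5p",
    )
    miry = MatureMiRNA(
        name="mirY-3p",
        sequence="UAGCUUAUCAGACUGAUGUUGA",  # 22 nt, miR-21-like
        loci=(LocusContext("L1", "CCAACCAACCAACCAACCAA"),),
        arm="3p",
    )
    return ReferenceCatalog(mirnas={m.name: m for m in (mirx, miry)})


@pytest.fixture(scope="session")
def catalog10() -> ReferenceCatalog:
    return simulate_reference(10, seed=7)


@pytest.fixture(scope="session")
def catalog50() -> ReferenceCatalog:
    return simulate_reference(50, seed=7)


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_assign(read_seq: str, catalog: ReferenceCatalog):
    """Try every (miRNA, offset) pair by direct string comparison; return the
    set of (mismatches, offset, name) candidates with exact motif match."""
    candidates = []
    for name in catalog.names():
        mir = catalog[name]
        motif = mir.sequence[
            catalog.motif_start[name] : catalog.motif_start[name] + catalog.motif_len
        ]
        for off in range(len(read_seq) - catalog.motif_len + 1):
            if read_seq[off : off + catalog.motif_len] != motif:
                continue
            shift = off - catalog.motif_start[name]
            mm = sum(
                1
                for j, base in enumerate(mir.sequence)
                if 0 <= shift + j < len(read_seq) and read_seq[shift + j] != base
            )
            candidates.append((mm, off, name))
    return candidates


def brute_force_classify(read_seq: str, mirna_name: str, catalog: ReferenceCatalog, anchor: int):
    """Enumerate every (locus, split point) decomposition of the post-motif
    read suffix and derive (end_status, tail, origin) from the stated rules.

    Completely independent of the walking implementation: templated
    prefixes are found by trying all split lengths against the
    mature+downstream template of every locus.
    """
    mir = catalog[mirna_name]
    k = catalog.motif_len
    m_start = catalog.motif_start[mirna_name]
    mature_after = mir.sequence[m_start + k :]
    rest = read_seq[anchor + k :]

    # matched mature length: largest split s <= len(mature_after) such that
    # rest[:s] == mature_after[:s], found by exhaustive trial
    matched_mature = max(
        s
        for s in range(0, min(len(rest), len(mature_after)) + 1)
        if rest[:s] == mature_after[:s]
    )

    if matched_mature == len(mature_after):
        ext = rest[len(mature_after) :]
        if ext == "":
            return "canonical", "", "none"
        templated_any = any(
            len(loc.downstream) >= len(ext) and loc.downstream[: len(ext)] == ext
            for loc in mir.loci
        )
        if templated_any:
            return "tailed", ext, "ambiguous"
        return "tailed", ext, "NT"

    if matched_mature == len(rest):
        return "trimmed", "", "none"
    return "trimmed_tailed", rest[matched_mature:], "NT"


def random_isomir_reads(catalog: ReferenceCatalog, n: int, seed: int) -> list[str]:
    """Randomized isomiR-like reads: mature bodies with random 5' trims,
    3' trims/templated extensions, random appended tails, and occasional
    internal substitutions."""
    rng = np.random.default_rng(seed)
    names = catalog.names()
    nts = "ACGU"
    reads = []
    for _ in range(n):
        mir = catalog[names[rng.integers(len(names))]]
        seq = mir.sequence
        t5 = int(rng.integers(0, 3))
        o3 = int(rng.integers(-3, 3))
        locus = mir.loci[rng.integers(len(mir.loci))]
        body = seq[t5 : len(seq) + o3] if o3 <= 0 else seq[t5:] + locus.downstream[:o3]
        tail_len = int(rng.integers(0, 4))
        tail = "".join(nts[rng.integers(4)] for _ in range(tail_len))
        read = body + tail
        if rng.random() < 0.1:  # occasional internal substitution
            pos = int(rng.integers(len(read)))
            read = read[:pos] + nts[rng.integers(4)] + read[pos + 1 :]
        reads.append(read)
    return reads
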