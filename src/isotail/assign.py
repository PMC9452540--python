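"""Read collapsing and motif-anchored miRNA assignment.

Each distinct read is scanned for an exact occurrence of any catalog motif;
variability is allowed only outside the motif, at the 5' and 3' ends. A read
whose motif region carries a substitution is left unassigned — mismatches in
the middle of a read are never tolerated. When motifs of several distinct
miRNAs occur in one read, the read goes to the miRNA whose anchored mature
sequence disagrees with the read at the fewest positions; a residual tie is
ambiguous and excluded from profiles.
"""

from __future__ import annotations

import gzip
import os
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from ._seq import to_rna
from .reference import ReferenceCatalog

UNASSIGNED = "UNASSIGNED"
UNASSIGNED_AMBIGUOUS = "UNASSIGNED_AMBIGUOUS"

DEFAULT_MIN_READ_LEN = 16
DEFAULT_MAX_READ_LEN = 35

_COLLAPSED_HEADER = re.compile(r"_x(\d+)$")


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int


@dataclass(frozen=True)
class Assignment:
    read: CollapsedRead
    mirna: str  # miRNA name, UNASSIGNED, or UNASSIGNED_AMBIGUOUS
    motif_start_in_read: int = -1

    @property
    def assigned(self) -> bool:
        return self.mirna not in (UNASSIGNED, UNASSIGNED_AMBIGUOUS)


def collapse_reads(reads: Iterable[str]) -> list[CollapsedRead]:
    """Collapse identical sequences to (sequence, count), ordered by
    descending count then lexicographically."""
    counts = Counter(to_rna(r) for r in reads)
    return [
        CollapsedRead(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def _anchored_mismatches(read: str, mature: str, motif_start_in_read: int, motif_start: int) -> int:
    """Mismatches between read and mature over their overlap after anchoring
    the motif (the motif itself contributes zero)."""
    offset = motif_start_in_read - motif_start  # read index of mature position 0
    mismatches = 0
    for j, base in enumerate(mature):
        i = offset + j
        if 0 <= i < len(read) and read[i] != base:
            mismatches += 1
    return mismatches


def assign_read(read: CollapsedRead, catalog: ReferenceCatalog) -> Assignment:
    """Assign one collapsed read by exact central-motif scan."""
    seq = read.sequence
    k = catalog.motif_len
    candidates: list[tuple[int, int, str]] = []  # (mismatches, motif_pos, name)
    seen: set[tuple[str, int]] = set()
    for i in range(len(seq) - k + 1):
        names = catalog.motif_index.get(seq[i : i + k])
        if not names:
            continue
        for name in names:
            if (name, i) in seen:
                continue
            seen.add((name, i))
            mm = _anchored_mismatches(seq, catalog[name].sequence, i, catalog.motif_start[name])
            candidates.append((mm, i, name))
    if not candidates:
        return Assignment(read, UNASSIGNED)
    candidates.sort()
    best_mm, best_pos, best_name = candidates[0]
    distinct_best = {name for mm, _pos, name in candidates if mm == best_mm}
    if len(distinct_best) > 1:
        return Assignment(read, UNASSIGNED_AMBIGUOUS)
    return Assignment(read, best_name, best_pos)


def _open_maybe_gzip(path: str | os.PathLike):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_sequences(path: str | os.PathLike) -> Iterator[str]:
    """Yield read sequences from FASTQ or FASTA (optionally gzipped).

    Collapsed-FASTA headers in the ``name_xCOUNT`` dialect repeat the
    sequence COUNT times.
    """
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
        if not first:
            return
        fh.seek(0)
        if first == "@":  # FASTQ
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()  # +
                fh.readline()  # qualities
                yield seq
        elif first == ">":  # FASTA, possibly pre-collapsed ("name_xCOUNT")
            for rec in SeqIO.parse(fh, "fasta"):
                m = _COLLAPSED_HEADER.search(rec.id)
                n = int(m.group(1)) if m else 1
                for _ in range(n):
                    yield str(rec.seq)
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ")


@dataclass
class LibraryAssignment:
    """Per-(miRNA, sequence) counts plus conservation bookkeeping."""

    table: pd.DataFrame  # columns: mirna, sequence, count, motif_start
    unassigned: int
    ambiguous: int
    filtered: int  # outside the length window
    total_reads: int

    @property
    def assigned(self) -> int:
        return int(self.table["count"].sum())


def assign_library(
    reads: str | os.PathLike | Iterable[str],
    catalog: ReferenceCatalog,
    *,
    min_read_len: int = DEFAULT_MIN_READ_LEN,
    max_read_len: int = DEFAULT_MAX_READ_LEN,
) -> LibraryAssignment:
    """Collapse a library and assign every distinct sequence.

    Count conservation holds by construction:
    assigned + unassigned + ambiguous + filtered == total input reads.
    """
    if isinstance(reads, (str, os.PathLike)):
        reads = iter_sequences(reads)
    collapsed = collapse_reads(reads)

    rows = []
    unassigned = ambiguous = filtered = total = 0
    for cr in collapsed:
        total += cr.count
        if not (min_read_len <= len(cr.sequence) <= max_read_len):
            filtered += cr.count
            continue
        a = assign_read(cr, catalog)
        if a.mirna == UNASSIGNED:
            unassigned += cr.count
        elif a.mirna == UNASSIGNED_AMBIGUOUS:
            ambiguous += cr.count
        else:
            rows.append((a.mirna, cr.sequence, cr.count, a.motif_start_in_read))

    table = pd.DataFrame(rows, columns=["mirna", "sequence", "count", "motif_start"])
    return LibraryAssignment(
        table=table,
        unassigned=unassigned,
        ambiguous=ambiguous,
        filtered=filtered,
        total_reads=total,
    )
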