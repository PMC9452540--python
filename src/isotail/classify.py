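"""3' isomiR decomposition and templated/non-templated tail classification.

An assigned read, anchored by its central motif, is walked 3'-ward along the
mature sequence. Relative to the annotated mature 3' end each read is:

* ``canonical`` — matches the mature body and stops exactly at the end;
* ``trimmed`` — stops short of the annotated end with nothing appended;
* ``tailed`` — reaches the annotated end and carries an extension;
* ``trimmed_tailed`` — diverges from the mature body before the annotated
  end and continues with other nucleotides.

An extension beyond the annotated end that fully matches the downstream
genomic context at ANY locus of the miRNA is *ambiguous* (templated): it may
arise from alternative Drosha/Dicer cleavage rather than enzymatic tailing.
Any other extension is a non-templated (NT) tail — the direct product of a
terminal nucleotidyltransferase. Partially templated extensions (first base
genomic, later bases not) count as NT with the full extension as the tail;
set ``nt_suffix_only`` to restrict the tail to the post-mismatch suffix.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .reference import LocusContext, MatureMiRNA, ReferenceCatalog

END_STATUSES = ("canonical", "trimmed", "tailed", "trimmed_tailed")
ORIGINS = ("none", "ambiguous", "NT")

_DI_CATEGORIES = {"AA": "di_AA", "UU": "di_UU", "AU": "di_AU", "UA": "di_UA"}


@dataclass(frozen=True)
class TailClass:
    """Classification of one isomiR's 3' end."""

    end_status: str
    tail_seq: str  # extension beyond the templated body ("" if none)
    origin: str  # none | ambiguous | NT
    category: str  # fine tail category (mono_A, di_AU, mixed, ... or none)
    coarse: str  # A_tail | U_tail | Mixed | none (Fig.-1c-style 3-way label)
    templated_len: int  # matched nt beyond the motif anchor
    three_prime_offset: int  # templated 3' end minus annotated 3' end
    flagged: bool = False  # tail longer than max_tail_len; excluded from category stats


def tail_category(tail_seq: str) -> str:
    """Fine-grained tail category: mono_X, the four A/U dinucleotides, or mixed."""
    if not tail_seq:
        raise ValueError("empty tail has no category")
    if len(tail_seq) == 1:
        return f"mono_{tail_seq}"
    if len(tail_seq) == 2:
        return _DI_CATEGORIES.get(tail_seq, "mixed")
    return "mixed"


def coarse_tail_label(tail_seq: str) -> str:
    """3-way tail label: homogeneous U tail, homogeneous A tail, or Mixed."""
    if not tail_seq:
        raise ValueError("empty tail has no label")
    letters = set(tail_seq)
    if letters == {"U"}:
        return "U_tail"
    if letters == {"A"}:
        return "A_tail"
    return "Mixed"


def split_templated(
    read_seq: str, mirna: MatureMiRNA, locus: LocusContext, anchor: int, motif_start: int, motif_len: int
) -> tuple[int, str]:
    """Maximal templated walk beyond the motif at one locus.

    Starting at the motif's 3' edge the read is matched against the mature
    sequence and then, past the annotated end, against the locus' downstream
    context. Returns (templated_len, tail_seq): the matched length and the
    read suffix from the first mismatch (or read end) onward.
    """
    k = motif_len
    if read_seq[anchor : anchor + k] != mirna.sequence[motif_start : motif_start + k]:
        raise ValueError("anchor inconsistent with read: motif does not match")
    template = mirna.sequence[motif_start + k :] + locus.downstream
    i = anchor + k
    matched = 0
    while i < len(read_seq) and matched < len(template) and read_seq[i] == template[matched]:
        i += 1
        matched += 1
    return matched, read_seq[i:]


def classify_isomir(
    read_seq: str,
    mirna_name: str,
    catalog: ReferenceCatalog,
    anchor: int,
    *,
    nt_suffix_only: bool = False,
) -> TailClass:
    """Classify one assigned read's 3' end against every locus of its miRNA."""
    mir = catalog[mirna_name]
    m_start = catalog.motif_start[mirna_name]
    k = catalog.motif_len
    mature = mir.sequence
    L = len(mature)
    offset = anchor - m_start  # read index of mature position 0
    annotated_end = offset + L  # read index just past the last mature base

    # walk the mature body 3' of the motif
    j = m_start + k
    while j < L:
        i = offset + j
        if i >= len(read_seq) or read_seq[i] != mature[j]:
            break
        j += 1

    if j == L:
        # read matches through the annotated 3' end
        extension = read_seq[annotated_end:]
        templated_len = L - (m_start + k)
        if not extension:
            return TailClass("canonical", "", "none", "none", "none", templated_len, 0)
        return _classify_extension(extension, mir, catalog, templated_len, nt_suffix_only)

    i = offset + j
    if i >= len(read_seq):
        # read ends before the annotated end, matching all the way: trimmed
        templated_len = j - (m_start + k)
        return TailClass("trimmed", "", "none", "none", "none", templated_len, j - L)

    # mismatch before the annotated end with read continuing: trimmed + retailed
    tail = read_seq[i:]
    templated_len = j - (m_start + k)
    flagged = len(tail) > catalog.max_tail_len
    category = "none" if flagged else tail_category(tail)
    coarse = "none" if flagged else coarse_tail_label(tail)
    return TailClass("trimmed_tailed", tail, "NT", category, coarse, templated_len, j - L, flagged)


def _classify_extension(
    extension: str,
    mir: MatureMiRNA,
    catalog: ReferenceCatalog,
    mature_templated: int,
    nt_suffix_only: bool,
) -> TailClass:
    """Classify a non-empty extension beyond the annotated end."""
    checkable = [loc for loc in mir.loci if len(loc.downstream) >= len(extension)]
    if not checkable and len(extension) <= catalog.max_tail_len:
        raise ValueError(
            f"{mir.name}: extension {extension!r} longer than stored downstream context"
        )
    ambiguous = any(loc.downstream[: len(extension)] == extension for loc in checkable)
    flagged = len(extension) > catalog.max_tail_len

    if ambiguous:
        category = "none" if flagged else tail_category(extension)
        coarse = "none" if flagged else coarse_tail_label(extension)
        return TailClass(
            "tailed", extension, "ambiguous", category, coarse,
            mature_templated + len(extension), len(extension), flagged,
        )

    tail = extension
    if nt_suffix_only:
        # longest prefix templated at some locus is credited to the genome
        best = 0
        for loc in checkable or mir.loci:
            p = 0
            while p < min(len(extension), len(loc.downstream)) and extension[p] == loc.downstream[p]:
                p += 1
            best = max(best, p)
        tail = extension[best:]
    flagged = len(tail) > catalog.max_tail_len
    category = "none" if flagged else tail_category(tail)
    coarse = "none" if flagged else coarse_tail_label(tail)
    return TailClass(
        "tailed", tail, "NT", category, coarse,
        mature_templated + (len(extension) - len(tail)), len(extension) - len(tail), flagged,
    )


def classify_table(
    assignment_table: pd.DataFrame,
    catalog: ReferenceCatalog,
    *,
    nt_suffix_only: bool = False,
) -> pd.DataFrame:
    """Classify every row of an assignment table (mirna, sequence, count, motif_start).

    Returns the table with end_status, three_prime_offset, tail_seq, origin,
    category, coarse, templated_len and flagged columns appended.
    """
    records = []
    for row in assignment_table.itertuples(index=False):
        tc = classify_isomir(
            row.sequence, row.mirna, catalog, row.motif_start, nt_suffix_only=nt_suffix_only
        )
        records.append(
            (
                row.mirna, row.sequence, row.count, row.motif_start,
                tc.end_status, tc.three_prime_offset, tc.tail_seq, tc.origin,
                tc.category, tc.coarse, tc.templated_len, tc.flagged,
            )
        )
    return pd.DataFrame(
        records,
        columns=[
            "mirna", "sequence", "count", "motif_start",
            "end_status", "three_prime_offset", "tail_seq", "origin",
            "category", "coarse", "templated_len", "flagged",
        ],
    )
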