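"""miRNA reference catalog: mature sequences, genomic downstream context, motif index.

A mature miRNA is identified by name (miRBase-style, e.g. ``hsa-miR-345-5p``)
and carries one or more genomic loci. Each locus stores at least
``max_tail_len`` nucleotides of genomic sequence immediately 3' of the
annotated mature end — the context against which 3' extensions are tested
for templated origin. Paralogous loci producing the same mature sequence are
one catalog entry with multiple loci; counting never splits across paralogs,
but the templated-tail check considers every locus.

Assignment anchors reads by an exact central motif of each mature sequence
(default 13 nt taken from the centre), so end variability never interferes
with miRNA identification.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from pyfaidx import Fasta

from ._seq import revcomp_dna, to_rna, validate_rna

DEFAULT_MOTIF_LEN = 13
DEFAULT_MAX_TAIL_LEN = 8
DEFAULT_CONTEXT_LEN = 20


@dataclass(frozen=True)
class LocusContext:
    """Genomic context of one locus producing a mature miRNA."""

    locus_id: str
    downstream: str  # RNA, immediately 3' of the annotated mature end

    def __post_init__(self) -> None:
        object.__setattr__(self, "downstream", validate_rna(self.downstream, what="downstream"))


@dataclass(frozen=True)
class MatureMiRNA:
    name: str
    sequence: str  # RNA, 5'->3'
    loci: tuple[LocusContext, ...]
    arm: str = "unknown"  # {"5p", "3p", "unknown"}

    def __post_init__(self) -> None:
        seq = validate_rna(self.sequence, what=f"{self.name} sequence")
        if not seq:
            raise ValueError(f"{self.name}: empty sequence")
        object.__setattr__(self, "sequence", seq)
        if not self.loci:
            raise ValueError(f"{self.name}: at least one locus is required")
        if self.arm not in ("5p", "3p", "unknown"):
            raise ValueError(f"{self.name}: invalid arm {self.arm!r}")

    @property
    def last_nt(self) -> str:
        """Last templated (annotated 3'-terminal) nucleotide."""
        return self.sequence[-1]


def arm_of(name: str) -> str:
    """Parse the 5p/3p arm from a miRBase-style name suffix."""
    lowered = name.lower()
    if lowered.endswith("-5p"):
        return "5p"
    if lowered.endswith("-3p"):
        return "3p"
    return "unknown"


def motif_of(sequence: str, motif_len: int) -> tuple[str, int]:
    """Central motif of a mature sequence and its 0-based start.

    start = floor((L - motif_len) / 2); deterministic for every length.
    """
    length = len(sequence)
    if motif_len > length:
        raise ValueError(f"motif_len {motif_len} exceeds sequence length {length}")
    if motif_len < 1:
        raise ValueError("motif_len must be >= 1")
    start = (length - motif_len) // 2
    return sequence[start : start + motif_len], start


@dataclass
class ReferenceCatalog:
    """Indexed miRNA reference used by assignment and tail classification."""

    mirnas: dict[str, MatureMiRNA]
    motif_len: int = DEFAULT_MOTIF_LEN
    max_tail_len: int = DEFAULT_MAX_TAIL_LEN
    motif_index: dict[str, set[str]] = field(default_factory=dict)
    motif_start: dict[str, int] = field(default_factory=dict)  # name -> motif start in mature

    def __post_init__(self) -> None:
        if not self.motif_index:
            self._build_index()
        self._validate()

    def _build_index(self) -> None:
        self.motif_index = {}
        self.motif_start = {}
        for name, mir in self.mirnas.items():
            motif, start = motif_of(mir.sequence, self.motif_len)
            self.motif_index.setdefault(motif, set()).add(name)
            self.motif_start[name] = start

    def _validate(self) -> None:
        for name, mir in self.mirnas.items():
            if len(mir.sequence) < self.motif_len:
                raise ValueError(f"{name}: sequence shorter than motif length {self.motif_len}")
            for locus in mir.loci:
                if len(locus.downstream) < self.max_tail_len:
                    raise ValueError(
                        f"{name}/{locus.locus_id}: downstream context "
                        f"({len(locus.downstream)} nt) shorter than max tail length "
                        f"{self.max_tail_len}"
                    )

    def __len__(self) -> int:
        return len(self.mirnas)

    def __contains__(self, name: str) -> bool:
        return name in self.mirnas

    def __getitem__(self, name: str) -> MatureMiRNA:
        return self.mirnas[name]

    def names(self) -> list[str]:
        return sorted(self.mirnas)

    def context_frame(self) -> pd.DataFrame:
        """The catalog's context table as a DataFrame (name, locus_id, downstream)."""
        rows = [
            (name, locus.locus_id, locus.downstream)
            for name, mir in sorted(self.mirnas.items())
            for locus in mir.loci
        ]
        return pd.DataFrame(rows, columns=["name", "locus_id", "downstream"])

    def write_context_table(self, path: str | os.PathLike) -> None:
        self.context_frame().to_csv(path, sep="\t", index=False)

    def write_mature_fasta(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for name, mir in sorted(self.mirnas.items()):
                fh.write(f">{name}\n{mir.sequence}\n")


def load_reference(
    mature_fasta: str | os.PathLike,
    context_table: str | os.PathLike,
    *,
    motif_len: int = DEFAULT_MOTIF_LEN,
    max_tail_len: int = DEFAULT_MAX_TAIL_LEN,
) -> ReferenceCatalog:
    """Load mature miRNA FASTA plus per-locus downstream context TSV.

    The context table needs columns (name, locus_id, downstream); T is
    accepted and converted to U everywhere. Every FASTA entry must have at
    least one context row; duplicate (name, locus_id) rows are an error.
    """
    if not os.path.exists(mature_fasta):
        raise FileNotFoundError(mature_fasta)
    if not os.path.exists(context_table):
        raise FileNotFoundError(context_table)

    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(mature_fasta), "fasta"):
        name = rec.id
        if name in sequences:
            raise ValueError(f"duplicate FASTA entry {name!r}")
        sequences[name] = validate_rna(str(rec.seq), what=f"{name} sequence")

    ctx = pd.read_csv(context_table, sep="\t", dtype=str)
    missing_cols = {"name", "locus_id", "downstream"} - set(ctx.columns)
    if missing_cols:
        raise ValueError(f"context table lacks columns {sorted(missing_cols)}")
    dup = ctx.duplicated(subset=["name", "locus_id"])
    if dup.any():
        bad = ctx.loc[dup, ["name", "locus_id"]].iloc[0].tolist()
        raise ValueError(f"duplicate context row for {tuple(bad)}")

    loci_by_name: dict[str, list[LocusContext]] = {}
    for row in ctx.itertuples(index=False):
        loci_by_name.setdefault(row.name, []).append(
            LocusContext(locus_id=row.locus_id, downstream=to_rna(row.downstream))
        )

    mirnas: dict[str, MatureMiRNA] = {}
    for name, seq in sequences.items():
        loci = loci_by_name.get(name)
        if not loci:
            raise ValueError(f"{name}: no context rows in {context_table}")
        mirnas[name] = MatureMiRNA(name=name, sequence=seq, loci=tuple(loci), arm=arm_of(name))

    return ReferenceCatalog(mirnas=mirnas, motif_len=motif_len, max_tail_len=max_tail_len)


def build_context_table(
    genome_fasta: str | os.PathLike,
    gff3: str | os.PathLike,
    k: int = DEFAULT_CONTEXT_LEN,
    *,
    feature_type: str = "miRNA",
) -> pd.DataFrame:
    """Build the (name, locus_id, downstream) context table from genome + GFF3.

    For each miRNA feature the k genomic nucleotides 3' of the feature end
    are extracted, reverse-complemented on the minus strand. GFF3 coordinates
    are 1-based inclusive. The miRNA name is taken from the attributes'
    ``Name=`` (falling back to ``ID=``); locus_id is ``seqid:start-end(strand)``.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    genome = Fasta(str(genome_fasta))

    rows: list[tuple[str, str, str]] = []
    with open(gff3) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype != feature_type:
                continue
            start, end = int(start_s), int(end_s)
            attr_map = dict(
                item.split("=", 1) for item in attrs.strip(";").split(";") if "=" in item
            )
            name = attr_map.get("Name") or attr_map.get("ID")
            if name is None:
                raise ValueError(f"GFF3 feature without Name/ID: {line!r}")
            contig = genome[seqid]
            if strand == "+":
                if end + k > len(contig):
                    raise ValueError(f"{name}: downstream window beyond end of {seqid}")
                downstream = str(contig[end : end + k])  # 0-based slice == bases end+1..end+k
            elif strand == "-":
                if start - 1 - k < 0:
                    raise ValueError(f"{name}: downstream window beyond start of {seqid}")
                downstream = revcomp_dna(str(contig[start - 1 - k : start - 1]))
            else:
                raise ValueError(f"{name}: unknown strand {strand!r}")
            locus_id = f"{seqid}:{start}-{end}({strand})"
            rows.append((name, locus_id, to_rna(downstream)))

    return pd.DataFrame(rows, columns=["name", "locus_id", "downstream"])
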