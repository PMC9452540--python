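"""Per-condition tailing metrics.

All abundances are RPM — reads per million assigned miRNA reads. Per-miRNA
percentages (NT tailing, nucleotide identity, mono-tail rates) are computed
within each miRNA and then averaged UNWEIGHTED across miRNAs for top-N
summaries, so highly expressed miRNAs do not dominate the average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import ReferenceCatalog

NUCLEOTIDES = ("A", "C", "G", "U")

#: per-miRNA metric columns produced by :func:`profile_condition`
METRIC_COLUMNS = [
    "count", "rpm",
    "frac_canonical", "frac_trimmed", "frac_tailed", "frac_trimmed_tailed",
    "pct_NT",
    "nt_A", "nt_C", "nt_G", "nt_U",
    "mono_A", "mono_C", "mono_G", "mono_U",
    "pct_NT_A", "pct_NT_C", "pct_NT_G", "pct_NT_U",
    "weighted_len", "last_templated_nt", "arm",
]


@dataclass
class ConditionProfile:
    """Per-miRNA tailing metrics for one library (condition x replicate)."""

    condition: str
    replicate: str
    per_mirna: pd.DataFrame  # indexed by miRNA name, columns METRIC_COLUMNS
    total_assigned: int

    def rpm(self) -> pd.Series:
        return self.per_mirna["rpm"]


def profile_condition(
    classified: pd.DataFrame,
    catalog: ReferenceCatalog,
    *,
    condition: str = "",
    replicate: str = "",
) -> ConditionProfile:
    """Summarize a classified isomiR table into per-miRNA tailing metrics.

    Reads flagged for overlong tails count toward NT prevalence but are
    excluded from nucleotide-identity and category statistics.
    """
    if classified.empty:
        raise ValueError("empty classified table")
    total_assigned = int(classified["count"].sum())

    rows = {}
    for name, grp in classified.groupby("mirna", sort=True):
        n = int(grp["count"].sum())
        status = grp.groupby("end_status")["count"].sum()
        nt_reads = grp.loc[grp["origin"] == "NT", ["count", "tail_seq", "category", "flagged"]]
        n_nt = int(nt_reads["count"].sum())

        # nucleotide identity within NT tails (nucleotide-weighted, not read-weighted)
        letter_counts = dict.fromkeys(NUCLEOTIDES, 0)
        for r in nt_reads.loc[~nt_reads["flagged"]].itertuples(index=False):
            for base in r.tail_seq:
                letter_counts[base] += r.count
        total_letters = sum(letter_counts.values())

        mono = dict.fromkeys(NUCLEOTIDES, 0)
        for r in nt_reads.loc[~nt_reads["flagged"]].itertuples(index=False):
            if len(r.tail_seq) == 1:
                mono[r.tail_seq] += r.count

        lengths = grp["sequence"].str.len().to_numpy()
        weighted_len = float(np.average(lengths, weights=grp["count"].to_numpy()))

        pct_nt = 100.0 * n_nt / n
        rec = {
            "count": n,
            "frac_canonical": status.get("canonical", 0) / n,
            "frac_trimmed": status.get("trimmed", 0) / n,
            "frac_tailed": status.get("tailed", 0) / n,
            "frac_trimmed_tailed": status.get("trimmed_tailed", 0) / n,
            "pct_NT": pct_nt,
            "weighted_len": weighted_len,
            "last_templated_nt": catalog[name].last_nt if name in catalog else "",
            "arm": catalog[name].arm if name in catalog else "unknown",
        }
        for base in NUCLEOTIDES:
            identity = 100.0 * letter_counts[base] / total_letters if total_letters else 0.0
            rec[f"nt_{base}"] = identity
            rec[f"mono_{base}"] = 100.0 * mono[base] / n
            # prevalence x identity: percentage of tailing attributable to each letter
            rec[f"pct_NT_{base}"] = pct_nt * identity / 100.0
        rows[name] = rec

    per_mirna = pd.DataFrame.from_dict(rows, orient="index")
    per_mirna["rpm"] = 1e6 * per_mirna["count"] / total_assigned
    per_mirna = per_mirna[METRIC_COLUMNS]
    per_mirna.index.name = "mirna"
    return ConditionProfile(condition, replicate, per_mirna, total_assigned)


def top_n_mirnas(
    profiles: Sequence[ConditionProfile], n: int, *, split_arm: bool = False
) -> list[str]:
    """Top-n miRNA set by mean RPM across all given profiles.

    The set is shared across the profiles being compared so that every
    comparison is made over the same miRNAs. With ``split_arm`` the set is
    the top n/2 of each arm (top-100-per-arm layout).
    """
    rpm = pd.concat([p.rpm() for p in profiles], axis=1).fillna(0.0).mean(axis=1)
    if n >= len(rpm):
        return sorted(rpm.index)
    if not split_arm:
        return list(rpm.sort_values(ascending=False, kind="stable").index[:n])
    arms = profiles[0].per_mirna["arm"].reindex(rpm.index).fillna("unknown")
    out: list[str] = []
    for arm in ("5p", "3p"):
        members = rpm[arms == arm].sort_values(ascending=False, kind="stable")
        out.extend(members.index[: n // 2])
    return out


def topn_summary(
    profiles: Sequence[ConditionProfile],
    n: int,
    columns: Iterable[str] = ("pct_NT", "pct_NT_A", "pct_NT_U", "pct_NT_G", "pct_NT_C"),
    *,
    split_arm: bool = False,
) -> pd.DataFrame:
    """Mean +/- standard error of per-miRNA percentages over the top-n set.

    Averaging is unweighted across miRNAs; each profile contributes one row
    per metric (condition, replicate, metric, mean, se, n_mirnas).
    """
    top = top_n_mirnas(profiles, n, split_arm=split_arm)
    rows = []
    for p in profiles:
        sub = p.per_mirna.reindex(top)
        for col in columns:
            vals = sub[col].dropna()
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "condition": p.condition,
                    "replicate": p.replicate,
                    "metric": col,
                    "mean": float(vals.mean()),
                    "se": se,
                    "n_mirnas": len(vals),
                }
            )
    return pd.DataFrame(rows)


def tail_length_identity(classified: pd.DataFrame, max_len: int = 8) -> pd.DataFrame:
    """Per-miRNA NT-tail percentage decomposed by tail length and coarse identity.

    Rows: (length 1..max_len, label in {A_tail, U_tail, Mixed}) with the mean
    across miRNAs of the percentage of that miRNA's reads carrying such a
    tail — the tail-length-by-identity column decomposition.
    """
    per = []
    for name, grp in classified.groupby("mirna"):
        n = grp["count"].sum()
        nt = grp[(grp["origin"] == "NT") & (~grp["flagged"])]
        cell = (
            nt.assign(length=nt["tail_seq"].str.len())
            .groupby(["length", "coarse"])["count"]
            .sum()
            / n
            * 100.0
        )
        cell.name = name
        per.append(cell)
    wide = pd.DataFrame(per).fillna(0.0)
    full_index = pd.MultiIndex.from_product(
        [range(1, max_len + 1), ["A_tail", "U_tail", "Mixed"]], names=["length", "label"]
    )
    mean = wide.mean(axis=0)
    mean.index.names = ["length", "label"]
    return mean.reindex(full_index, fill_value=0.0).rename("pct").reset_index()


def weighted_mean_length(lengths: Sequence[int], counts: Sequence[int]) -> float:
    """Mean read length weighted by isomiR abundance."""
    return float(np.average(np.asarray(lengths, dtype=float), weights=np.asarray(counts, dtype=float)))


def delta_length(
    prof_a: ConditionProfile, prof_b: ConditionProfile, top: Sequence[str]
) -> pd.Series:
    """Per-miRNA weighted-length change (B minus A) over a shared top set.

    miRNAs absent from either profile are excluded.
    """
    a = prof_a.per_mirna["weighted_len"].reindex(top)
    b = prof_b.per_mirna["weighted_len"].reindex(top)
    return (b - a).dropna()


def boxplot_summary(values: pd.Series) -> dict[str, float]:
    """Median, quartiles, and Tukey whiskers (1.5 IQR, clipped to data)."""
    v = values.dropna().to_numpy()
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = float(v[v >= q1 - 1.5 * iqr].min())
    hi = float(v[v <= q3 + 1.5 * iqr].max())
    return {"median": float(med), "q1": float(q1), "q3": float(q3), "whisker_lo": lo, "whisker_hi": hi}


def estimate_conversion_rate(
    sequences: Iterable[str],
    spikeins: dict[str, str],
    known_a_positions: dict[str, Sequence[int]],
    *,
    anchor_len: int = 12,
) -> pd.DataFrame:
    """Estimate the apparent A-to-G misread rate from spike-in reads.

    Spike-ins are synthetic RNAs of known sequence; ``known_a_positions``
    gives 0-based positions whose true identity is A. Reads are matched to a
    spike-in by an exact anchor of the first ``anchor_len`` reference
    positions that are NOT themselves queried — a read carrying a conversion
    at a queried position must still match its spike-in, or the estimate
    would be biased low. Returns one row per (spikein, position): coverage,
    G count, and the conversion rate as a percentage of covering reads.
    """
    anchors: dict[str, list[int]] = {}
    for name, ref in spikeins.items():
        queried = set(known_a_positions.get(name, ()))
        positions = [i for i in range(len(ref)) if i not in queried][:anchor_len]
        if len(positions) < anchor_len:
            raise ValueError(f"{name}: spike-in too short for a {anchor_len}-nt anchor")
        anchors[name] = positions

    counts = {
        (name, pos): [0, 0]  # coverage, G observations
        for name, positions in known_a_positions.items()
        for pos in positions
    }
    for seq in sequences:
        for name, anchor_pos in anchors.items():
            ref = spikeins[name]
            if len(seq) > anchor_pos[-1] and all(seq[i] == ref[i] for i in anchor_pos):
                for pos in known_a_positions.get(name, ()):
                    if pos < len(seq):
                        counts[(name, pos)][0] += 1
                        if seq[pos] == "G":
                            counts[(name, pos)][1] += 1
                break

    rows = []
    for (name, pos), (cov, g) in sorted(counts.items()):
        position_class = "terminal" if pos == len(spikeins[name]) - 1 else "internal"
        rate = 100.0 * g / cov if cov else float("nan")
        rows.append(
            {
                "spikein": name,
                "position": pos,
                "position_class": position_class,
                "coverage": cov,
                "g_count": g,
                "rate_pct": rate,
            }
        )
    return pd.DataFrame(rows)
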