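"""Differential tailing between conditions.

Fold-changes are formed on replicate-pooled RPM with a 0.5-read pseudocount;
isomiRs (or miRNAs) below an RPM floor in every condition are excluded so
ratios stay stable. Cumulative curves follow the binned-CDF construction:
for each fold-change threshold, the fraction of isomiRs of a class whose
fold-change is less than or equal to that threshold.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import ReferenceCatalog

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_FLOOR_RPM = 1.0
DEFAULT_HEATMAP_CAP = 100.0

#: isomiR classes tracked by the cumulative curves
CURVE_CLASSES = ("canonical", "ambiguous", "NT")


def isomir_class(row) -> str:
    """Curve class of one classified isomiR row: canonical, ambiguous, NT, or other."""
    if row.end_status == "canonical":
        return "canonical"
    if row.origin in ("ambiguous", "NT"):
        return row.origin
    return "other"


def _pool(tables: Sequence[pd.DataFrame]) -> tuple[pd.DataFrame, int]:
    """Sum isomiR counts across replicate tables; keep class columns."""
    pooled = pd.concat(tables, ignore_index=True)
    keys = ["mirna", "sequence"]
    keep_first = ["end_status", "origin", "category", "coarse", "tail_seq"]
    agg = {c: "first" for c in keep_first}
    agg["count"] = "sum"
    out = pooled.groupby(keys, as_index=False).agg(agg)
    return out, int(out["count"].sum())


def isomir_fold_change(
    tables_a: Sequence[pd.DataFrame],
    tables_b: Sequence[pd.DataFrame],
    *,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    floor_rpm: float = DEFAULT_FLOOR_RPM,
) -> pd.DataFrame:
    """Per-isomiR fold-change of abundance (B over A) from classified tables.

    Returns one row per isomiR present in either condition with columns
    rpm_a, rpm_b, fc, and the curve class. isomiRs below ``floor_rpm`` in
    both conditions are dropped.
    """
    a, total_a = _pool(tables_a)
    b, total_b = _pool(tables_b)
    merged = a.merge(
        b[["mirna", "sequence", "count"]],
        on=["mirna", "sequence"],
        how="outer",
        suffixes=("_a", "_b"),
    )
    # class columns may be missing for isomiRs seen only in B
    only_b = merged["end_status"].isna()
    if only_b.any():
        b_classes = b.set_index(["mirna", "sequence"])
        idx = pd.MultiIndex.from_frame(merged.loc[only_b, ["mirna", "sequence"]])
        for col in ["end_status", "origin", "category", "coarse", "tail_seq"]:
            merged.loc[only_b, col] = b_classes[col].reindex(idx).to_numpy()
    merged[["count_a", "count_b"]] = merged[["count_a", "count_b"]].fillna(0.0)

    merged["rpm_a"] = 1e6 * merged["count_a"] / total_a
    merged["rpm_b"] = 1e6 * merged["count_b"] / total_b
    merged["fc"] = ((merged["count_b"] + pseudocount) / total_b) / (
        (merged["count_a"] + pseudocount) / total_a
    )
    merged["class"] = [isomir_class(r) for r in merged.itertuples(index=False)]
    keep = (merged["rpm_a"] >= floor_rpm) | (merged["rpm_b"] >= floor_rpm)
    return merged.loc[keep].reset_index(drop=True)


def default_bin_edges(n: int = 25, lo: float = 1 / 8, hi: float = 8.0) -> np.ndarray:
    """log2-spaced fold-change thresholds, by default 25 between 1/8 and 8."""
    return np.logspace(np.log2(lo), np.log2(hi), n, base=2.0)


def cumulative_curve(
    fold_changes: Sequence[float],
    class_labels: Sequence[str],
    bin_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binned cumulative fold-change curves per isomiR class.

    For every threshold edge, the fraction of the class' isomiRs with
    fold-change <= edge. Empty classes are omitted.
    """
    if bin_edges is None:
        bin_edges = default_bin_edges()
    fc = np.asarray(fold_changes, dtype=float)
    if not np.all(np.isfinite(fc)) or np.any(fc <= 0):
        raise ValueError("fold-changes must be finite and positive (pseudocounted)")
    labels = np.asarray(class_labels)
    rows = []
    for cls in pd.unique(labels):
        vals = np.sort(fc[labels == cls])
        if vals.size == 0:
            continue
        fracs = np.searchsorted(vals, bin_edges, side="right") / vals.size
        rows.extend(
            {"class": cls, "edge": float(e), "fraction": float(f)}
            for e, f in zip(bin_edges, fracs)
        )
    return pd.DataFrame(rows)


def heatmap_values(fold_changes: pd.Series, cap: float = DEFAULT_HEATMAP_CAP) -> pd.Series:
    """Relative abundance of B vs A as a percentage, capped (rendered '>=cap')."""
    return (100.0 * fold_changes).clip(upper=cap)


def _mean_metric(profiles, column: str) -> pd.Series:
    return (
        pd.concat([p.per_mirna[column] for p in profiles], axis=1)
        .mean(axis=1)
    )


def pct_fold_change(
    profiles_a,
    profiles_b,
    column: str = "pct_NT_U",
    *,
    eps: float = 0.05,
    floor_rpm: float = 10.0,
) -> pd.Series:
    """Per-miRNA fold-change of an NT-tail percentage (B over A).

    ``eps`` (percentage points) regularizes ratios of small percentages;
    miRNAs below ``floor_rpm`` mean RPM in both conditions are excluded.
    """
    a = _mean_metric(profiles_a, column)
    b = _mean_metric(profiles_b, column)
    rpm_a = _mean_metric(profiles_a, "rpm")
    rpm_b = _mean_metric(profiles_b, "rpm")
    shared = a.index.intersection(b.index)
    keep = shared[(rpm_a.reindex(shared).fillna(0) >= floor_rpm) | (rpm_b.reindex(shared).fillna(0) >= floor_rpm)]
    return ((b.reindex(keep) + eps) / (a.reindex(keep) + eps)).rename(f"fc_{column}")


def sensitivity_ranking(
    fc_1: pd.Series, fc_2: pd.Series, top_n: int = 100
) -> pd.DataFrame:
    """Consensus enzyme-sensitive miRNA set from two knockout comparisons.

    miRNAs are ranked in each comparison by the DECREASE of the tailing
    percentage upon knockout (ascending fold-change); the sensitive set is
    the intersection of the two top-n lists, reported with both
    fold-changes.
    """
    shared = fc_1.index.intersection(fc_2.index)
    if top_n > len(shared):
        raise ValueError(f"top_n {top_n} exceeds the shared miRNA universe ({len(shared)})")
    top1 = set(fc_1.reindex(shared).sort_values(kind="stable").index[:top_n])
    top2 = set(fc_2.reindex(shared).sort_values(kind="stable").index[:top_n])
    members = sorted(top1 & top2)
    return pd.DataFrame(
        {"mirna": members, "fc_1": fc_1.reindex(members).to_numpy(), "fc_2": fc_2.reindex(members).to_numpy()}
    )


def terminal_nt_composition(
    mirna_set: Sequence[str],
    catalog: ReferenceCatalog,
    background_set: Sequence[str],
) -> pd.DataFrame:
    """Last templated nucleotide composition of a miRNA set vs a background.

    The last templated nucleotide is the annotated mature 3'-terminal base.
    Enrichment per letter is tested two-sided against the background
    frequency with a binomial test.
    """
    if not len(mirna_set) or not len(background_set):
        raise ValueError("miRNA sets must be non-empty")

    def freqs(names):
        last = pd.Series([catalog[n].last_nt for n in names])
        return last.value_counts().reindex(list("ACGU"), fill_value=0)

    obs = freqs(mirna_set)
    bg = freqs(background_set)
    n = obs.sum()
    rows = []
    for base in "ACGU":
        p_bg = bg[base] / bg.sum()
        frac = obs[base] / n
        if 0.0 < p_bg < 1.0:
            pval = stats.binomtest(int(obs[base]), int(n), p_bg).pvalue
        else:
            pval = 1.0 if frac == p_bg else 0.0
        rows.append(
            {
                "nt": base,
                "freq": float(frac),
                "bg_freq": float(p_bg),
                "enrichment": float(frac / p_bg) if p_bg > 0 else float("inf"),
                "p_value": float(pval),
            }
        )
    return pd.DataFrame(rows)


def correlate_profiles(a: pd.Series, b: pd.Series, *, log: bool = True) -> tuple[float, float]:
    """Pearson correlation of paired per-isomiR/per-miRNA values.

    Values are log10-transformed by default (abundances span orders of
    magnitude); non-finite pairs are dropped.
    """
    df = pd.concat([a, b], axis=1, join="inner").astype(float)
    if log:
        df = np.log10(df.where(df > 0))
    df = df.replace([np.inf, -np.inf], np.nan).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 paired finite values")
    x, y = df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the profiles")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def wilcoxon_compare(
    x: Sequence[float], y: Sequence[float], *, paired: bool = False
) -> float:
    """Two-sided Wilcoxon p-value: signed-rank if paired, rank-sum otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per group")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        diffs = x - y
        if np.all(diffs == 0):
            raise ValueError("all paired differences are zero")
        return float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
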