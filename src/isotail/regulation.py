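"""miRNA-level abundance comparison and consensus regulation calls.

A miRNA is called regulated by the tailing enzymes when its abundance
responds consistently across knockouts AND the response reverts on rescue:
up in every knockout comparison and down upon rescue means the enzymes
normally suppress it (consensus "up" = negatively regulated by the
enzymes); the mirror pattern means positive regulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_LOG2FC_THRESHOLD = 0.2
DEFAULT_RPM_FLOOR = 10.0


def mirna_abundance(classified: pd.DataFrame) -> pd.Series:
    """RPM per miRNA: summed isomiR counts normalized to a million assigned reads."""
    counts = classified.groupby("mirna")["count"].sum()
    return (1e6 * counts / counts.sum()).rename("rpm")


def abundance_log2fc(
    tables_a: Sequence[pd.DataFrame],
    tables_b: Sequence[pd.DataFrame],
    *,
    pseudocount: float = 0.5,
    floor_rpm: float = DEFAULT_RPM_FLOOR,
) -> pd.Series:
    """Per-miRNA log2 fold-change of abundance (B over A), replicate-pooled.

    miRNAs whose mean RPM is below ``floor_rpm`` in both conditions are
    excluded (lowly expressed calls are unreliable).
    """

    def pooled(tables):
        counts = (
            pd.concat(tables, ignore_index=True).groupby("mirna")["count"].sum()
        )
        return counts, counts.sum()

    ca, ta = pooled(tables_a)
    cb, tb = pooled(tables_b)
    union = ca.index.union(cb.index)
    ca = ca.reindex(union, fill_value=0)
    cb = cb.reindex(union, fill_value=0)
    rpm_a = 1e6 * ca / ta
    rpm_b = 1e6 * cb / tb
    keep = (rpm_a >= floor_rpm) | (rpm_b >= floor_rpm)
    fc = ((cb + pseudocount) / tb) / ((ca + pseudocount) / ta)
    return np.log2(fc[keep]).rename("log2fc")


def _direction(log2fc: float, threshold: float) -> str:
    if log2fc >= threshold:
        return "up"
    if log2fc <= -threshold:
        return "down"
    return "none"


@dataclass(frozen=True)
class RegulationCall:
    mirna: str
    per_comparison: dict[str, str]
    consensus: str  # up | down | none


def regulation_calls(
    ko_comparisons: Mapping[str, pd.Series],
    rescue_comparisons: Mapping[str, pd.Series],
    *,
    threshold: float = DEFAULT_LOG2FC_THRESHOLD,
    require_all_rescues: bool = True,
) -> pd.DataFrame:
    """Consensus regulation calls across knockout and rescue comparisons.

    Each comparison maps miRNA to log2FC (KO over control, or rescue over
    KO). A miRNA is consensus "up" (negatively regulated by the enzymes)
    when log2FC >= +threshold in EVERY knockout comparison and <= -threshold
    in the rescue comparison(s); "down" is the mirror. The threshold is
    inclusive and symmetric. A miRNA missing from any comparison is "none".
    """
    all_comps = {**{f"ko:{k}": v for k, v in ko_comparisons.items()},
                 **{f"rescue:{k}": v for k, v in rescue_comparisons.items()}}
    universe = sorted(set().union(*[set(v.index) for v in all_comps.values()]))

    rescue_agg = all if require_all_rescues else any
    rows = []
    for name in universe:
        dirs = {}
        missing = False
        for comp, fcs in all_comps.items():
            if name in fcs.index and np.isfinite(fcs[name]):
                dirs[comp] = _direction(float(fcs[name]), threshold)
            else:
                dirs[comp] = "missing"
                missing = True
        ko_dirs = [dirs[c] for c in dirs if c.startswith("ko:")]
        rescue_dirs = [dirs[c] for c in dirs if c.startswith("rescue:")]
        consensus = "none"
        if not missing and ko_dirs and rescue_dirs:
            if all(d == "up" for d in ko_dirs) and rescue_agg(d == "down" for d in rescue_dirs):
                consensus = "up"
            elif all(d == "down" for d in ko_dirs) and rescue_agg(d == "up" for d in rescue_dirs):
                consensus = "down"
        rows.append({"mirna": name, **dirs, "consensus": consensus})
    return pd.DataFrame(rows)


def venn_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Count miRNAs per consensus response pattern across comparisons."""
    comp_cols = [c for c in calls.columns if c not in ("mirna", "consensus")]
    return (
        calls.groupby(comp_cols + ["consensus"])
        .size()
        .rename("n_mirnas")
        .reset_index()
        .sort_values("n_mirnas", ascending=False)
        .reset_index(drop=True)
    )
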