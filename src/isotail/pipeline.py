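"""End-to-end pipeline: assign -> classify -> profile -> compare -> regulate.

A single validated config drives every stage; all thresholds the analysis
leaves open (motif length, RPM floors, fold-change threshold, top-N) live
here with documented defaults. Unknown config keys are rejected.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .assign import assign_library
from .classify import classify_table
from .compare import (
    cumulative_curve,
    heatmap_values,
    isomir_fold_change,
    pct_fold_change,
)
from .metrics import ConditionProfile, profile_condition, top_n_mirnas, topn_summary
from .reference import load_reference
from .regulation import abundance_log2fc, regulation_calls, venn_summary


class ReferenceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mature_fasta: str
    context_table: str
    motif_len: int = 13
    max_tail_len: int = 8


class LibraryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    condition: str
    replicate: str
    path: str


class ParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    top_n: int = 200
    min_read_len: int = 16
    max_read_len: int = 35
    pseudocount: float = 0.5
    floor_rpm: float = 1.0
    pct_floor_rpm: float = 10.0
    log2fc_threshold: float = 0.2
    nt_suffix_only: bool = False


class ComparisonConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    a: str  # baseline condition
    b: str  # perturbed condition


class RegulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ko: list[str] = []
    rescue: list[str] = []


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reference: ReferenceConfig
    libraries: list[LibraryConfig]
    comparisons: list[ComparisonConfig] = []
    regulation: Optional[RegulationConfig] = None
    params: ParamsConfig = ParamsConfig()
    output: str = "isotail_out"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def validate_inputs(self) -> None:
        for path in (self.reference.mature_fasta, self.reference.context_table):
            if not os.path.exists(path):
                raise FileNotFoundError(path)
        for lib in self.libraries:
            if not os.path.exists(lib.path):
                raise FileNotFoundError(f"{lib.condition}/{lib.replicate}: {lib.path}")
        conditions = {lib.condition for lib in self.libraries}
        for comp in self.comparisons:
            missing = {comp.a, comp.b} - conditions
            if missing:
                raise ValueError(f"comparison {comp.name}: unknown conditions {sorted(missing)}")
        comp_names = {c.name for c in self.comparisons}
        if self.regulation:
            bad = (set(self.regulation.ko) | set(self.regulation.rescue)) - comp_names
            if bad:
                raise ValueError(f"regulation refers to unknown comparisons {sorted(bad)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write per-stage TSVs under config.output.

    Returns the in-memory bundle: classified tables, profiles, comparison
    results, and regulation calls.
    """
    config.validate_inputs()
    out = config.output
    os.makedirs(out, exist_ok=True)
    p = config.params

    catalog = load_reference(
        config.reference.mature_fasta,
        config.reference.context_table,
        motif_len=config.reference.motif_len,
        max_tail_len=config.reference.max_tail_len,
    )

    classified: dict[str, dict[str, pd.DataFrame]] = {}
    profiles: dict[str, list[ConditionProfile]] = {}
    log_rows = []
    for lib in config.libraries:
        la = assign_library(
            lib.path, catalog, min_read_len=p.min_read_len, max_read_len=p.max_read_len
        )
        table = classify_table(la.table, catalog, nt_suffix_only=p.nt_suffix_only)
        classified.setdefault(lib.condition, {})[lib.replicate] = table
        prof = profile_condition(
            table, catalog, condition=lib.condition, replicate=lib.replicate
        )
        profiles.setdefault(lib.condition, []).append(prof)
        stem = f"{lib.condition}_{lib.replicate}"
        table.to_csv(os.path.join(out, f"classified_{stem}.tsv"), sep="\t", index=False)
        prof.per_mirna.to_csv(os.path.join(out, f"profile_{stem}.tsv"), sep="\t")
        log_rows.append(
            {
                "condition": lib.condition,
                "replicate": lib.replicate,
                "total_reads": la.total_reads,
                "assigned": la.assigned,
                "unassigned": la.unassigned,
                "ambiguous": la.ambiguous,
                "filtered": la.filtered,
            }
        )

    log = pd.DataFrame(log_rows)
    log.to_csv(os.path.join(out, "assignment_log.tsv"), sep="\t", index=False)

    all_profiles = [prof for plist in profiles.values() for prof in plist]
    summary = topn_summary(all_profiles, p.top_n)
    summary.to_csv(os.path.join(out, "topn_summary.tsv"), sep="\t", index=False)

    comparisons: dict[str, dict] = {}
    for comp in config.comparisons:
        tables_a = list(classified[comp.a].values())
        tables_b = list(classified[comp.b].values())
        fc = isomir_fold_change(
            tables_a, tables_b, pseudocount=p.pseudocount, floor_rpm=p.floor_rpm
        )
        curves = cumulative_curve(fc["fc"], fc["class"])
        heat = fc.assign(heatmap=heatmap_values(fc["fc"]))
        u_fc = pct_fold_change(
            profiles[comp.a], profiles[comp.b], "pct_NT_U", floor_rpm=p.pct_floor_rpm
        )
        a_fc = pct_fold_change(
            profiles[comp.a], profiles[comp.b], "pct_NT_A", floor_rpm=p.pct_floor_rpm
        )
        ab_fc = abundance_log2fc(tables_a, tables_b, floor_rpm=p.pct_floor_rpm)
        comparisons[comp.name] = {
            "isomir_fc": fc,
            "curves": curves,
            "uridylation_fc": u_fc,
            "adenylation_fc": a_fc,
            "abundance_log2fc": ab_fc,
        }
        fc.to_csv(os.path.join(out, f"comparison_{comp.name}_isomir_fc.tsv"), sep="\t", index=False)
        curves.to_csv(os.path.join(out, f"comparison_{comp.name}_curves.tsv"), sep="\t", index=False)
        heat[["mirna", "sequence", "class", "heatmap"]].to_csv(
            os.path.join(out, f"comparison_{comp.name}_heatmap.tsv"), sep="\t", index=False
        )
        pd.DataFrame({"uridylation_fc": u_fc, "adenylation_fc": a_fc, "abundance_log2fc": ab_fc}).to_csv(
            os.path.join(out, f"comparison_{comp.name}_mirna.tsv"), sep="\t"
        )

    calls = None
    if config.regulation and (config.regulation.ko or config.regulation.rescue):
        ko = {n: comparisons[n]["abundance_log2fc"] for n in config.regulation.ko}
        rescue = {n: comparisons[n]["abundance_log2fc"] for n in config.regulation.rescue}
        calls = regulation_calls(ko, rescue, threshold=p.log2fc_threshold)
        calls.to_csv(os.path.join(out, "regulation_calls.tsv"), sep="\t", index=False)
        venn_summary(calls).to_csv(os.path.join(out, "regulation_venn.tsv"), sep="\t", index=False)

    with open(os.path.join(out, "run_info.json"), "w") as fh:
        json.dump(
            {
                "isotail_version": __version__,
                "params": p.model_dump(),
                "reference": config.reference.model_dump(),
                "n_libraries": len(config.libraries),
            },
            fh,
            indent=2,
        )

    return {
        "catalog": catalog,
        "classified": classified,
        "profiles": profiles,
        "log": log,
        "summary": summary,
        "comparisons": comparisons,
        "regulation": calls,
    }
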