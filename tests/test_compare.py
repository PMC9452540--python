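"""Differential tailing: fold-changes, curves, rankings, statistics."""

import numpy as np
import pandas as pd
import pytest

from isotail.assign import assign_library
from isotail.classify import classify_table
from isotail.compare import (
    correlate_profiles,
    cumulative_curve,
    default_bin_edges,
    heatmap_values,
    isomir_fold_change,
    pct_fold_change,
    sensitivity_ranking,
    terminal_nt_composition,
    wilcoxon_compare,
)
from isotail.metrics import profile_condition
from isotail.simulate import knockout_panel_design, simulate_library


@pytest.fixture(scope="module")
def wt_tables(catalog10):
    design = knockout_panel_design(depth=5000, seed=21)
    tabs = []
    for rep in (1, 2):
        sim = simulate_library(catalog10, design, "WT", rep)
        tabs.append(classify_table(assign_library(sim.reads, catalog10).table, catalog10))
    return tabs


class TestCumulativeCurve:
    def test_hand_counted_fraction(self):
        curves = cumulative_curve([0.5, 1.0, 2.0], ["x"] * 3, np.array([1.0]))
        assert curves.iloc[0]["fraction"] == pytest.approx(2 / 3)

    def test_degenerate_step_function(self):
        edges = np.array([0.5, 0.99, 1.0, 2.0])
        curves = cumulative_curve([1.0] * 5, ["x"] * 5, edges)
        assert list(curves["fraction"]) == [0.0, 0.0, 1.0, 1.0]

    def test_monotone_and_matches_empirical_cdf(self):
        rng = np.random.default_rng(17)
        fc = rng.lognormal(0, 1, size=500)
        labels = rng.choice(["canonical", "NT"], size=500)
        edges = default_bin_edges()
        curves = cumulative_curve(fc, labels, edges)
        for cls, grp in curves.groupby("class"):
            fr = grp.sort_values("edge")["fraction"].to_numpy()
            assert (np.diff(fr) >= 0).all()
            vals = fc[labels == cls]
            # brute-force empirical CDF at every edge
            expected = [(vals <= e).sum() / len(vals) for e in edges]
            assert np.allclose(grp.sort_values("edge")["fraction"], expected)

    def test_rejects_nonpositive_fold_changes(self):
        with pytest.raises(ValueError):
            cumulative_curve([0.0, 1.0], ["x", "x"])


class TestFoldChange:
    def test_identical_conditions_give_unit_fc_and_capped_100(self, catalog10, wt_tables):
        fc = isomir_fold_change(wt_tables, wt_tables)
        assert np.allclose(fc["fc"], 1.0)
        assert np.allclose(heatmap_values(fc["fc"]), 100.0)

    def test_heatmap_never_exceeds_cap(self, catalog10, wt_tables):
        design = knockout_panel_design(depth=5000, seed=21)
        sim = simulate_library(catalog10, design, "TKO", 1)
        tko = [classify_table(assign_library(sim.reads, catalog10).table, catalog10)]
        fc = isomir_fold_change(tko, wt_tables)
        heat = heatmap_values(fc["fc"])
        assert (heat <= 100.0).all() and (heat >= 0.0).all()
        assert (heat > 0).any()

    def test_count_floor_excludes_rare_isomirs(self, catalog10, wt_tables):
        fc_all = isomir_fold_change(wt_tables, wt_tables, floor_rpm=0.0)
        fc_floored = isomir_fold_change(wt_tables, wt_tables, floor_rpm=500.0)
        assert len(fc_floored) < len(fc_all)
        assert (fc_floored[["rpm_a", "rpm_b"]].max(axis=1) >= 500.0).all()


class TestSensitivityRanking:
    def test_rank_intersection_by_hand(self):
        fc1 = pd.Series({"m1": 0.1, "m2": 0.5, "m3": 0.9})
        fc2 = pd.Series({"m1": 0.1, "m2": 0.9, "m3": 0.5})
        sens = sensitivity_ranking(fc1, fc2, top_n=1)
        assert list(sens["mirna"]) == ["m1"]

    def test_identical_comparisons_give_topn_set(self):
        fc = pd.Series({f"m{i}": i / 10 for i in range(1, 11)})
        sens = sensitivity_ranking(fc, fc, top_n=4)
        assert set(sens["mirna"]) == {"m1", "m2", "m3", "m4"}

    def test_permutation_invariant_and_idempotent(self):
        rng = np.random.default_rng(2)
        fc1 = pd.Series(rng.lognormal(0, 1, 50), index=[f"m{i}" for i in range(50)])
        fc2 = pd.Series(rng.lognormal(0, 1, 50), index=[f"m{i}" for i in range(50)])
        a = sensitivity_ranking(fc1, fc2, 10)
        perm = rng.permutation(50)
        b = sensitivity_ranking(fc1.iloc[perm], fc2.iloc[perm], 10)
        assert list(a["mirna"]) == list(b["mirna"])
        assert list(sensitivity_ranking(fc1, fc2, 10)["mirna"]) == list(a["mirna"])

    def test_topn_beyond_universe_is_error(self):
        fc = pd.Series({"m1": 0.5})
        with pytest.raises(ValueError):
            sensitivity_ranking(fc, fc, top_n=2)


class TestTerminalComposition:
    def test_hand_frequency(self, catalog10):
        # pick miRNAs by their actual terminal nucleotides
        by_last = {}
        for name in catalog10.names():
            by_last.setdefault(catalog10[name].last_nt, []).append(name)
        some_letter = max(by_last, key=lambda k: len(by_last[k]))
        mirna_set = by_last[some_letter][:3]
        comp = terminal_nt_composition(mirna_set, catalog10, catalog10.names())
        row = comp[comp["nt"] == some_letter].iloc[0]
        assert row["freq"] == 1.0

    def test_set_equal_background_means_no_enrichment(self, catalog10):
        comp = terminal_nt_composition(catalog10.names(), catalog10, catalog10.names())
        present = comp[comp["bg_freq"] > 0]
        assert np.allclose(present["enrichment"], 1.0)

    def test_empty_set_is_error(self, catalog10):
        with pytest.raises(ValueError):
            terminal_nt_composition([], catalog10, catalog10.names())


class TestCorrelation:
    def test_perfect_correlation(self):
        a = pd.Series([1.0, 10.0, 100.0, 1000.0])
        r, _ = correlate_profiles(a, a)
        assert r == pytest.approx(1.0)

    def test_anticorrelation_linear_scale(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0])
        r, _ = correlate_profiles(a, -a, log=False)
        assert r == pytest.approx(-1.0)

    def test_recovers_known_rho(self):
        rng = np.random.default_rng(0)
        cov = [[1, 0.8], [0.8, 1]]
        x, y = rng.multivariate_normal([0, 0], cov, size=1000).T
        r, p = correlate_profiles(pd.Series(x), pd.Series(y), log=False)
        assert 0.75 <= r <= 0.85 and p < 1e-10

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError):
            correlate_profiles(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]))

    def test_zero_variance_is_error(self):
        a = pd.Series([1.0, 1.0, 1.0, 1.0])
        b = pd.Series([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            correlate_profiles(a, b, log=False)


class TestWilcoxon:
    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        assert wilcoxon_compare(x, y) == pytest.approx(wilcoxon_compare(y, x))

    def test_power_at_one_sd_shift(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(50):
            x = rng.normal(0, 1, 100)
            y = rng.normal(1, 1, 100)
            if wilcoxon_compare(x, y) < 0.05:
                hits += 1
        assert hits >= 48  # a 1 SD shift at n=100 is detected almost always

    def test_paired_requires_equal_length(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([1, 2, 3], [1, 2, 3, 4], paired=True)

    def test_all_tied_pairs_degenerate(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)


def test_pct_fold_change_direction_on_knockout(catalog10, wt_tables):
    """Removing the uridylases lowers per-miRNA NT-U percentages, so the
    DKO/WT uridylation fold-changes sit mostly below 1."""
    design = knockout_panel_design(depth=5000, seed=21)
    profs_wt = [profile_condition(t, catalog10, condition="WT") for t in wt_tables]
    dko_tabs = []
    for rep in (1, 2):
        sim = simulate_library(catalog10, design, "DKO", rep)
        dko_tabs.append(classify_table(assign_library(sim.reads, catalog10).table, catalog10))
    profs_dko = [profile_condition(t, catalog10, condition="DKO") for t in dko_tabs]
    fc = pct_fold_change(profs_wt, profs_dko, "pct_NT_U", floor_rpm=1.0)
    assert (fc < 1).mean() > 0.7
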