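"""The hierarchical testing procedure: gate, descent, rescue, union."""

import numpy as np
import pandas as pd
import pytest

from cladiff import (
    DifferentialAbundanceModel,
    AnalysisConfig,
    TaxaTable,
    apriori_scan,
    build_cladogram,
    leaf_test,
    sister_correct,
    trajectory_test,
)
from cladiff.simulate import RegimeConfig, simulate_regime

from conftest import make_labels, rp


class TestSisterCorrect:
    def test_bh_removes_weak_sisters(self):
        # BH over (0.04, 0.2) -> (0.08, 0.2): both >= 0.05, only best kept
        surv = sister_correct({"a": 0.01, "b": 0.04, "c": 0.2}, alpha=0.05)
        assert surv == {"a"}

    def test_two_strong_sisters_both_survive(self):
        # BH over the single remaining p: 0.002 < 0.05
        surv = sister_correct({"a": 0.001, "b": 0.002}, alpha=0.05)
        assert surv == {"a", "b"}

    def test_raw_threshold_applies_first(self):
        surv = sister_correct({"a": 0.01, "b": 0.3}, alpha=0.05)
        assert surv == {"a"}

    def test_best_sister_needs_raw_significance(self):
        assert sister_correct({"a": 0.2, "b": 0.4}, alpha=0.05) == set()

    def test_tie_broken_lexicographically(self):
        surv = sister_correct({"b": 0.01, "a": 0.01, "c": 0.9}, alpha=0.05)
        assert "a" in surv  # "a" is the designated most-significant sister


def _shifted_dataset(seed=0, n=100, shift=2.0):
    """1 kingdom, 2 phyla of 2 leaves; phylum A shifted in positives."""
    rng = np.random.default_rng(seed)
    paths = [rp("K", "A", "a1"), rp("K", "A", "a2"),
             rp("K", "B", "b1"), rp("K", "B", "b2")]
    vals = rng.normal(size=(2 * n, 4))
    vals[:n, 0] += shift
    vals[:n, 1] += shift
    df = pd.DataFrame(vals, index=[f"s{i}" for i in range(2 * n)], columns=paths)
    table = TaxaTable(df, value_kind="log_processed")
    labels = make_labels([1] * n + [0] * n, ids=table.sample_ids)
    return table, labels


class TestTrajectory:
    def test_shifted_phylum_found_other_absent(self):
        table, labels = _shifted_dataset()
        clad = build_cladogram(table)
        taxa = trajectory_test(clad, labels, AnalysisConfig(), start_level=1)
        paths = {str(t.path) for t in taxa}
        assert "k__K" in paths and "k__K;p__A" in paths
        assert "k__K;p__B" not in paths
        assert all(t.direction == 1 for t in taxa if "p__A" in str(t.path))

    def test_descent_stops_at_nonsignificant_child(self):
        # kingdom strongly shifted via phylum A, but phylum B pure noise:
        # B's children must never appear even if one would be raw-significant
        table, labels = _shifted_dataset(seed=1)
        clad = build_cladogram(table)
        taxa = trajectory_test(clad, labels, AnalysisConfig(), start_level=1)
        traj_paths = {str(t.path) for t in taxa}
        for t in taxa:
            if t.depth > 1:
                assert str(t.path.prefix(t.depth - 1)) in traj_paths

    def test_null_labels_mostly_empty(self):
        hits = 0
        for seed in range(40):
            ds = simulate_regime(RegimeConfig(regime="zzz", n_per_class=30,
                                              n_triplets=2, seed=seed))
            clad = build_cladogram(ds.table)
            taxa = trajectory_test(clad, ds.labels, AnalysisConfig(), start_level=1)
            hits += bool(taxa)
        assert hits <= 5  # >= 95%-ish of null runs come back empty


class TestLeafTest:
    def test_bonferroni_arithmetic(self):
        # one strong leaf among 100: 1e-5 * 100 = 1e-3 < 0.05 survives;
        # a 0.03 leaf would not (0.03 * 100 = 3)
        rng = np.random.default_rng(2)
        n = 60
        paths = [rp("K", "P", f"leaf{i:03d}") for i in range(100)]
        vals = rng.normal(size=(n, 100))
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        vals[:, 0] += 2.5 * y  # strong shift in positives
        df = pd.DataFrame(vals, index=[f"s{i}" for i in range(n)], columns=paths)
        clad = build_cladogram(TaxaTable(df, value_kind="log_processed"))
        labels = make_labels(y.astype(int), ids=list(df.index))
        found = leaf_test(clad, labels, AnalysisConfig())
        assert rp("K", "P", "leaf000") in {t.path for t in found}
        assert all(t.p_value * 100 < 0.05 for t in found)
        assert all(t.source == "leaf" for t in found)


class TestAprioriScan:
    def test_strong_signal_stops_at_depth1(self):
        table, labels = _shifted_dataset()
        clad = build_cladogram(table)
        res = apriori_scan(clad, labels)
        assert res.first_significant_depth == 1
        assert list(res.per_depth_p) == [1]
        assert res.explainable

    def test_no_signal_scans_all_depths(self):
        ds = simulate_regime(RegimeConfig(regime="zzz", n_per_class=25, seed=12))
        clad = build_cladogram(ds.table)
        res = apriori_scan(clad, ds.labels)
        if not res.explainable:
            assert sorted(res.per_depth_p) == [1, 2, 3]


class TestFullModel:
    def test_not_explainable_returns_no_taxa(self):
        # labels independent of values; pick a seed where the gate fails
        for seed in range(10):
            ds = simulate_regime(RegimeConfig(regime="zzz", n_per_class=25, seed=seed))
            res = DifferentialAbundanceModel(ds.table, ds.labels).fit()
            if not res.explainable:
                assert res.taxa == []
                assert "NOT microbially explainable" in res.summary()
                return
        pytest.fail("no null seed produced a non-explainable gate")

    def test_union_sources(self):
        ds = simulate_regime(RegimeConfig(regime="zzm", mu=1.5, n_per_class=80, seed=4))
        res = DifferentialAbundanceModel(ds.table, ds.labels).fit()
        by_key = {t.key: t for t in res.taxa}
        planted = rp("SimKingdom", "mother000", "z1")
        assert (planted, True) in by_key
        assert by_key[(planted, True)].source == "both"  # trajectory + rescue

    def test_determinism(self):
        ds = simulate_regime(RegimeConfig(regime="zzm", mu=0.8, n_per_class=50, seed=5))
        a = DifferentialAbundanceModel(ds.table, ds.labels).fit()
        b = DifferentialAbundanceModel(ds.table, ds.labels).fit()
        assert a.to_frame().equals(b.to_frame())
        assert a.used_start_level == b.used_start_level

    def test_trajectory_ancestor_chain_significant(self):
        for seed in range(5):
            ds = simulate_regime(RegimeConfig(regime="zzm", mu=1.0,
                                              n_per_class=60, seed=seed))
            res = DifferentialAbundanceModel(ds.table, ds.labels).fit()
            traj = {str(t.path) for t in res.taxa if t.source in ("trajectory", "both")}
            for t in res.taxa:
                if t.source not in ("trajectory", "both"):
                    continue
                for lvl in range(res.used_start_level, t.depth):
                    assert str(t.path.prefix(lvl)) in traj

    def test_escalation_reaches_finer_level(self):
        # opposite-sign sisters cancel in the mother: level 1/2 empty,
        # daughters found only when the start level escalates
        ds = simulate_regime(RegimeConfig(regime="zma", mu=1.0, alpha_coef=-1.0,
                                          n_per_class=640, seed=6))
        res = DifferentialAbundanceModel(ds.table, ds.labels).fit()
        assert res.explainable
        assert res.used_start_level >= 2
        found = {str(t.path) for t in res.taxa}
        assert "k__SimKingdom;p__mother000;c__z1" in found

    def test_pinned_start_level_disables_escalation(self):
        ds = simulate_regime(RegimeConfig(regime="zzm", mu=1.0, n_per_class=80, seed=7))
        cfg = AnalysisConfig(start_level=2)
        res = DifferentialAbundanceModel(ds.table, ds.labels, config=cfg).fit()
        assert res.used_start_level == 2

    def test_invalid_start_level_rejected(self):
        with pytest.raises(ValueError):
            AnalysisConfig(start_level=4)

    def test_monotone_safety_under_added_noise(self):
        """Adding pure-noise features under a new phylum never removes the
        shifted phylum's trajectory chain (level-1 node count fixed: the
        kingdom is the only level-1 node either way)."""
        table, labels = _shifted_dataset(seed=8)
        clad = build_cladogram(table)
        base = {str(t.path) for t in trajectory_test(clad, labels, AnalysisConfig(), 1)}

        rng = np.random.default_rng(8)
        noisy = table.data.copy()
        for i in range(3):
            noisy[rp("K", "Cnoise", f"n{i}")] = rng.normal(size=len(noisy))
        clad2 = build_cladogram(TaxaTable(noisy, value_kind="log_processed"))
        aug = {str(t.path) for t in trajectory_test(clad2, labels, AnalysisConfig(), 1)}
        assert {"k__K", "k__K;p__A"} <= base
        assert {"k__K", "k__K;p__A"} <= aug

    def test_write_outputs(self, tmp_path):
        ds = simulate_regime(RegimeConfig(regime="zzm", mu=1.2, n_per_class=60, seed=9))
        res = DifferentialAbundanceModel(ds.table, ds.labels).fit()
        res.write(tmp_path)
        assert (tmp_path / "significant_taxa.tsv").exists()
        assert (tmp_path / "run_summary.json").exists()
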