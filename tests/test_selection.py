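import numpy as np
import pandas as pd
import pytest

from anchorprobe import (
    SelectionConfig,
    aggregate_by_compartment,
    anchor_table_stats,
    apply_filters,
    exclude_cross_expressed,
    generate_expression_fixture,
    rank_candidates,
    select_candidates,
)


def _stats_row(pid, comp, raw, median, q=0.001):
    fc = raw / median if median > 0 else np.inf
    return {
        "probeset_id": pid, "compartment": comp, "raw": raw,
        "median_other": median, "fold_change": fc,
        "log2_fold_change": np.log2(fc), "p_anova": q, "q_bh": q,
    }


class TestApplyFilters:
    def test_published_anchor_table_survives_base_filters(self):
        stats = anchor_table_stats()
        cfg = SelectionConfig(per_compartment_fold_min={})
        assert len(apply_filters(stats, cfg)) == 37

    def test_proximal_tubule_tenfold_override_keeps_all_25(self):
        stats = anchor_table_stats()
        kept = apply_filters(stats, SelectionConfig())  # default EPT >= 10
        ept = kept.loc[kept["compartment"] == "EPT"]
        assert len(ept) == 25
        assert len(kept) == 37

    def test_raw_signal_boundary_is_exclusive(self):
        stats = pd.DataFrame([_stats_row("p", "A", 100.0, 10.0)])
        assert apply_filters(stats, SelectionConfig()).empty

    def test_fold_threshold_reads_minimum_as_inclusive(self):
        stats = pd.DataFrame([_stats_row("p", "A", 200.0, 100.0)])  # fold 2.0
        assert len(apply_filters(stats, SelectionConfig())) == 1

    def test_insignificant_q_removed(self):
        stats = pd.DataFrame([_stats_row("p", "A", 500.0, 10.0, q=0.02)])
        assert apply_filters(stats, SelectionConfig()).empty

    def test_tightening_thresholds_never_grows_the_list(self):
        stats = anchor_table_stats()
        base = len(apply_filters(stats, SelectionConfig(per_compartment_fold_min={})))
        for cfg in (
            SelectionConfig(fold_min=5, per_compartment_fold_min={}),
            SelectionConfig(raw_min=400, per_compartment_fold_min={}),
            SelectionConfig(fold_min=5, raw_min=400, per_compartment_fold_min={}),
        ):
            assert len(apply_filters(stats, cfg)) <= base


class TestExcludeCrossExpressed:
    @staticmethod
    def _profile_with_dual_gene():
        comps = [f"c{i}" for i in range(6)]
        data = {c: [50.0, 50.0] for c in comps}
        profile = pd.DataFrame(data, index=["clean", "dual"])
        profile.loc["clean", "c0"] = 1000.0
        profile.loc["dual", "c0"] = 150.0
        profile.loc["dual", "c1"] = 150.0  # 3-fold in a second compartment
        return profile

    def test_clean_anchor_retained_dual_gene_dropped_everywhere(self):
        profile = self._profile_with_dual_gene()
        candidates = pd.DataFrame(
            [
                _stats_row("clean", "c0", 1000.0, 50.0),
                _stats_row("dual", "c0", 150.0, 50.0),
                _stats_row("dual", "c1", 150.0, 50.0),
            ]
        )
        kept = exclude_cross_expressed(candidates, profile, SelectionConfig())
        assert list(kept["probeset_id"]) == ["clean"]


class TestRankCandidates:
    def test_lower_median_ranks_first_then_higher_raw(self):
        cands = pd.DataFrame(
            [
                _stats_row("a", "A", 300.0, 100.0),
                _stats_row("b", "A", 500.0, 10.0),
                _stats_row("c", "A", 300.0, 10.0),
            ]
        )
        ranked = rank_candidates(cands, SelectionConfig())
        assert list(ranked["probeset_id"]) == ["b", "c", "a"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_high_median_candidates_sink_and_are_flagged(self):
        cands = pd.DataFrame(
            [
                _stats_row("noisy", "A", 5000.0, 1000.0),  # above median_max
                _stats_row("quiet", "A", 300.0, 20.0),
            ]
        )
        ranked = rank_candidates(cands, SelectionConfig())
        assert list(ranked["probeset_id"]) == ["quiet", "noisy"]
        assert list(ranked["high_median"]) == [False, True]

    def test_ranking_is_permutation_invariant(self):
        rows = [
            _stats_row(f"p{i}", "A", raw, med)
            for i, (raw, med) in enumerate([(300, 40), (300, 30), (900, 30), (120, 55)])
        ]
        base = rank_candidates(pd.DataFrame(rows), SelectionConfig())
        shuffled = rank_candidates(
            pd.DataFrame([rows[i] for i in (2, 0, 3, 1)]), SelectionConfig()
        )
        assert list(base["probeset_id"]) == list(shuffled["probeset_id"])

    def test_mixed_compartments_rejected(self):
        cands = pd.DataFrame(
            [_stats_row("a", "A", 300.0, 10.0), _stats_row("b", "B", 300.0, 10.0)]
        )
        with pytest.raises(ValueError):
            rank_candidates(cands)


class TestSelectCandidates:
    def test_noiseless_fixture_recovered_exactly(self, noiseless_expr_fixture):
        matrix, table, truth = noiseless_expr_fixture
        result = select_candidates(matrix, table)
        found = {
            (pid, comp)
            for comp, df in result.items()
            for pid in df["probeset_id"]
        }
        assert found == {(p, c) for p, c, _ in truth.planted}

    def test_subthreshold_fold_yields_empty_lists(self):
        matrix, table, _ = generate_expression_fixture(
            planted=[("weak_EPT", "EPT", 1.5)], noise_sd=0.0, seed=2
        )
        result = select_candidates(matrix, table)
        assert all(df.empty for df in result.values())

    def test_selection_is_deterministic(self, expr_fixture):
        matrix, table, _ = expr_fixture
        r1 = select_candidates(matrix, table)
        r2 = select_candidates(matrix, table)
        assert list(r1) == list(r2)
        for comp in r1:
            pd.testing.assert_frame_equal(r1[comp], r2[comp])

    def test_each_probeset_in_at_most_one_list(self, expr_fixture):
        matrix, table, _ = expr_fixture
        result = select_candidates(matrix, table)
        ids = [pid for df in result.values() for pid in df["probeset_id"]]
        assert len(ids) == len(set(ids))

    def test_exclusion_order_independent_of_raw_filter(self, expr_fixture):
        # running exclusion before or after the filters gives the same set
        from anchorprobe.stats import compute_stats

        matrix, table, _ = expr_fixture
        cfg = SelectionConfig()
        stats = compute_stats(matrix, table)
        profile = aggregate_by_compartment(matrix, table)
        after = exclude_cross_expressed(apply_filters(stats, cfg), profile, cfg)
        before = apply_filters(exclude_cross_expressed(stats, profile, cfg), cfg)
        key = lambda df: sorted(zip(df["probeset_id"], df["compartment"]))
        assert key(after) == key(before)


class TestSelectionConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = SelectionConfig(fold_min=3.0, per_compartment_fold_min={"EPT": 12.0})
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SelectionConfig.from_yaml(path) == cfg

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fold_min": 0.5},
            {"p_threshold": 0.0},
            {"per_compartment_fold_min": {"EPT": 1.0}},
        ],
    )
    def test_invalid_thresholds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SelectionConfig(**kwargs)
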