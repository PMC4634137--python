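import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch

from hcregulon import (AnalysisConfig, anova_de, bh_fdr, call_markers,
                       cluster_patterns, detection_filter, hc_enriched_set,
                       normalize_counts, quantile_normalize,
                       sample_dendrogram, standardize_rows, validate_markers)

from conftest import make_design, make_matrix
from oracles import anova2_projection


@pytest.fixture
def design_1organ_2ct():
    return make_design(organs=("cochlea",), cell_types=("HC", "ENHC"),
                       reps=1)


class TestDetectionFilter:
    def test_threshold_on_sample_count(self, design18):
        values = np.full((3, 18), 100.0)
        dp = np.full((3, 18), 0.5)
        dp[0, :2] = 0.001      # detected in exactly 2 samples -> kept
        dp[1, 0] = 0.001       # 1 sample only -> dropped
        dp[2, :] = 0.001       # everywhere -> kept
        m = make_matrix(values, design18, detection_p=dp)
        kept = detection_filter(m)
        assert list(kept.values.index) == ["g0", "g2"]

    def test_all_detected_is_identity(self, design18):
        values = np.random.default_rng(0).uniform(50, 500, (4, 18))
        m = make_matrix(values, design18,
                        detection_p=np.full((4, 18), 0.001))
        assert detection_filter(m).values.equals(m.values)

    def test_missing_detection_table_instructs_fallback(self, design18):
        m = make_matrix(np.ones((2, 18)), design18)
        with pytest.raises(ValueError, match="fallback"):
            detection_filter(m)


class TestQuantileNormalize:
    def test_hand_example(self, design_1organ_2ct):
        m = make_matrix(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 8.0]]),
                        design_1organ_2ct)
        out = quantile_normalize(m).values.to_numpy()
        expected = np.array([[1.5, 1.5], [3.5, 3.5], [6.5, 6.5]])
        np.testing.assert_allclose(out, expected)

    def test_identical_columns_unchanged(self, design_1organ_2ct):
        col = np.array([4.0, 1.0, 9.0])
        m = make_matrix(np.column_stack([col, col]), design_1organ_2ct)
        np.testing.assert_allclose(quantile_normalize(m).values.to_numpy(),
                                   np.column_stack([col, col]))

    def test_columns_share_distribution_and_ranks(self, design18):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.lognormal(5, 1, size=(60, 18)), design18)
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)
            orig = m.values.to_numpy()[:, j]
            assert (np.argsort(orig) == np.argsort(out[:, j])).all()

    def test_idempotent(self, design18):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.uniform(1, 100, size=(30, 18)), design18)
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values.to_numpy(),
                                   once.values.to_numpy())

    def test_ties_get_mean_of_rank_range(self, design_1organ_2ct):
        m = make_matrix(np.array([[2.0, 1.0], [2.0, 5.0], [7.0, 9.0]]),
                        design_1organ_2ct)
        out = quantile_normalize(m).values.to_numpy()
        ref = np.array([1.5, 3.5, 8.0])
        # tied values in column 1 share the mean of reference ranks 1-2
        np.testing.assert_allclose(out[:, 0], [2.5, 2.5, 8.0])
        np.testing.assert_allclose(np.sort(out[:, 1]), ref)


class TestNormalizeCounts:
    def test_floor_applied_after_quantile(self, design_1organ_2ct):
        m = make_matrix(np.array([[5.0, 5.0], [30.0, 30.0], [100.0, 100.0]]),
                        design_1organ_2ct)
        out = normalize_counts(m, AnalysisConfig(floor_value=20.0))
        np.testing.assert_allclose(out.values.to_numpy(),
                                   [[20, 20], [30, 30], [100, 100]])
        assert out.values.to_numpy().min() >= 20.0

    def test_zero_floor_is_pure_quantile(self, design_1organ_2ct):
        m = make_matrix(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 8.0]]),
                        design_1organ_2ct)
        out = normalize_counts(m, AnalysisConfig(floor_value=0.0))
        np.testing.assert_allclose(
            out.values.to_numpy(),
            quantile_normalize(m).values.to_numpy())


class TestBHFDR:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
        ([0.3], [0.3]),
    ])
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all() and (q <= 1).all()


class TestAnovaDE:
    def test_constant_feature_not_selected(self, design18):
        m = make_matrix(np.full((1, 18), 7.0), design18)
        res = anova_de(m)
        row = res.table.iloc[0]
        assert row["F_organ"] == 0 and row["p_cell_type"] == 1.0
        assert not row["selected"]

    def test_pure_additive_structure_has_zero_interaction(self, design18):
        organ_shift = design18["organ"].map({"cochlea": 0.0,
                                             "vestibule": 1.0})
        ct_shift = design18["cell_type"].map({"HC": 2.0, "ENHC": 0.0,
                                              "NEC": 1.0})
        log2x = 5.0 + organ_shift + ct_shift
        m = make_matrix((2.0 ** log2x.to_numpy())[None, :] - 1.0, design18)
        res = anova_de(m, AnalysisConfig(log_offset=1.0))
        assert res.table.iloc[0]["F_interaction"] == 0.0

    def test_matches_projection_oracle(self, design18):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.lognormal(4, 1, size=(5, 18)), design18)
        res = anova_de(m)
        organ_idx = design18["organ"].map(
            {"cochlea": 0, "vestibule": 1}).to_numpy()
        ct_idx = design18["cell_type"].map(
            {"ENHC": 0, "HC": 1, "NEC": 2}).to_numpy()
        y_all = np.log2(m.values.to_numpy() + 1.0)
        for i in range(5):
            oracle = anova2_projection(y_all[i], organ_idx, ct_idx)
            for effect in ("organ", "cell_type", "interaction"):
                assert res.table.iloc[i][f"F_{effect}"] == pytest.approx(
                    oracle[f"F_{effect}"], rel=1e-9, abs=1e-9)

    def test_unbalanced_design_rejected(self):
        design = make_design(reps=2).iloc[:-1].reset_index(drop=True)
        m = make_matrix(np.ones((1, len(design))), design)
        with pytest.raises(ValueError, match="[Uu]nbalanced|observations"):
            anova_de(m)


class TestStandardize:
    def test_hand_example(self):
        frame = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                             columns=list("abc"))
        out, flagged = standardize_rows(frame)
        np.testing.assert_allclose(out.to_numpy(), [[-1.0, 0.0, 1.0]])
        assert len(flagged) == 0

    def test_constant_row_flagged_zeroed(self):
        frame = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"],
                             columns=list("abc"))
        out, flagged = standardize_rows(frame)
        assert (out.to_numpy() == 0).all()
        assert list(flagged) == ["g"]

    def test_idempotent_on_standardized_rows(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.normal(size=(10, 6)))
        once, _ = standardize_rows(frame)
        twice, _ = standardize_rows(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(),
                                   atol=1e-12)


class TestClusterPatterns:
    def test_recovers_separated_groups(self):
        rng = np.random.default_rng(4)
        up = np.tile([1.0, 1.0, -1.0, -1.0], (20, 1))
        down = -up
        data = np.vstack([up, down]) + rng.normal(0, 0.05, (40, 4))
        frame = pd.DataFrame(data, index=[f"g{i}" for i in range(40)])
        assign, means, sds = cluster_patterns(
            frame, AnalysisConfig(n_pattern_clusters=2))
        assert assign.iloc[:20].nunique() == 1
        assert assign.iloc[20:].nunique() == 1
        assert assign.iloc[0] != assign.iloc[-1]

    def test_k1_mean_profile_is_column_mean(self):
        frame = pd.DataFrame(np.arange(12.0).reshape(3, 4))
        assign, means, _ = cluster_patterns(
            frame, AnalysisConfig(n_pattern_clusters=1))
        np.testing.assert_allclose(means.to_numpy()[0],
                                   frame.mean(axis=0).to_numpy())

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(rng.normal(size=(50, 6)))
        cfg = AnalysisConfig(n_pattern_clusters=4, cluster_seed=2)
        a1, _, _ = cluster_patterns(frame, cfg)
        a2, _, _ = cluster_patterns(frame, cfg)
        assert a1.equals(a2)

    def test_k_exceeding_features_rejected(self):
        frame = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_patterns(frame, AnalysisConfig(n_pattern_clusters=5))


class TestSampleDendrogram:
    def test_average_linkage_heights(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=40)
        b = a + rng.normal(0, 0.2, size=40)       # close to a
        c = -a + rng.normal(0, 0.5, size=40)      # far from both
        design = make_design(organs=("cochlea",), cell_types=("HC",), reps=3)
        m = make_matrix(np.column_stack([a - a.min() + 1, b - b.min() + 1,
                                         c - c.min() + 1]), design)
        linkage, labels = sample_dendrogram(m)
        vals = m.values.to_numpy()
        corr = np.corrcoef(vals.T)
        d = 1 - corr
        assert linkage[0, 2] == pytest.approx(d[0, 1], abs=1e-12)
        assert linkage[1, 2] == pytest.approx((d[0, 2] + d[1, 2]) / 2,
                                              abs=1e-12)

    def test_duplicate_samples_merge_at_zero(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(1, 10, size=30)
        c = rng.uniform(1, 10, size=30)
        design = make_design(organs=("cochlea",), cell_types=("HC",), reps=3)
        m = make_matrix(np.column_stack([a, a, c]), design)
        linkage, _ = sample_dendrogram(m)
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert (np.diff(linkage[:, 2]) >= -1e-12).all()

    def test_constant_sample_rejected_by_name(self):
        design = make_design(organs=("cochlea",), cell_types=("HC",), reps=3)
        vals = np.column_stack([np.arange(5.0), np.ones(5),
                                np.arange(5.0) ** 2])
        m = make_matrix(vals, design)
        with pytest.raises(ValueError, match="cochlea_HC_r2"):
            sample_dendrogram(m)


class TestHCEnrichedSet:
    def _matrix(self, hc_coch, enhc_coch, hc_vest, enhc_vest):
        design = make_design(cell_types=("HC", "ENHC"), reps=1)
        return make_matrix(
            np.array([[hc_coch, enhc_coch, hc_vest, enhc_vest]]), design)

    def test_threefold_included(self):
        gs = hc_enriched_set(self._matrix(60, 20, 30, 30))
        assert "g0" in gs.members

    def test_boundary_inclusive(self):
        gs = hc_enriched_set(self._matrix(60.0, 20.0, 20.0, 20.0))
        assert "g0" in gs.members      # exactly 3.0 in cochlea

    def test_or_rule_over_organs(self):
        gs = hc_enriched_set(self._matrix(20, 20, 90, 20))
        assert "g0" in gs.members      # vestibule only
        gs2 = hc_enriched_set(self._matrix(40, 20, 40, 20))
        assert "g0" not in gs2.members

    def test_missing_cell_type_rejected(self):
        design = make_design(cell_types=("HC",), reps=2)
        m = make_matrix(np.ones((1, 4)), design)
        with pytest.raises(ValueError, match="ENHC"):
            hc_enriched_set(m)


class TestCallMarkers:
    def _matrix(self, target, others, design=None):
        design = design if design is not None else make_design()
        vals = np.full((1, len(design)), others, dtype=float)
        idx = [i for i, ct in enumerate(design["cell_type"]) if ct == "HC"]
        vals[0, idx] = target
        return make_matrix(vals, design), design

    def test_clear_marker_called_both_organs(self):
        m, _ = self._matrix(310.0, 100.0)
        calls = call_markers(m)
        assert len(calls) == 1
        call = calls[0]
        assert (call.cell_type, call.organ_scope) == ("HC", "both")

    def test_single_high_nontarget_sample_disqualifies(self):
        m, design = self._matrix(310.0, 100.0)
        vals = m.values.to_numpy().copy()
        nec_col = list(design["sample_id"]).index("vestibule_NEC_r2")
        vals[0, nec_col] = 130.0
        assert call_markers(make_matrix(vals, design)) == []

    def test_target_mean_below_threshold_disqualifies(self):
        m, _ = self._matrix(240.0, 50.0)
        assert call_markers(m) == []

    def test_organ_restricted_scope(self):
        design = make_design()
        vals = np.full((1, len(design)), 60.0)
        for i, (o, ct) in enumerate(zip(design["organ"],
                                        design["cell_type"])):
            if o == "cochlea" and ct == "HC":
                vals[0, i] = 400.0
        calls = call_markers(make_matrix(vals, design))
        assert len(calls) == 1
        assert calls[0].organ_scope == "cochlea_only"

    def test_invariant_to_column_order(self):
        design = make_design()
        rng = np.random.default_rng(12)
        vals = rng.uniform(20, 500, size=(30, len(design)))
        m = make_matrix(vals, design)
        perm = rng.permutation(len(design))
        design_p = design.iloc[perm].reset_index(drop=True)
        m_p = make_matrix(vals[:, perm], design_p)
        as_tuples = lambda calls: sorted(
            (c.gene, c.cell_type, c.organ_scope) for c in calls)
        assert as_tuples(call_markers(m)) == as_tuples(call_markers(m_p))


class TestValidateMarkers:
    def _rnaseq(self, hc, enhc):
        design = make_design(cell_types=("HC", "ENHC"), reps=1)
        return make_matrix(np.array([[hc, enhc, hc, enhc]]), design,
                           feature_ids=["m1"])

    def _call(self, gene="m1"):
        from hcregulon import MarkerCall
        return MarkerCall(gene=gene, cell_type="HC", organ_scope="both",
                          target_mean=300.0, max_other=50.0)

    def test_tenfold_marker_passes(self):
        out = validate_markers([self._call()], self._rnaseq(200.0, 20.0))
        assert out["summary"]["fraction_passing"] == 1.0
        assert out["summary"]["mean_fold_cochlea"] == pytest.approx(10.0)

    def test_absent_marker_counted(self):
        out = validate_markers([self._call("nope")],
                               self._rnaseq(200.0, 20.0))
        assert out["summary"]["n_excluded"] == 1
        assert out["summary"]["n_validated"] == 0

    def test_planted_fold_recovered_exactly(self):
        calls = [self._call()]
        out = validate_markers(calls, self._rnaseq(80.0, 10.0))
        assert out["summary"]["mean_fold_vestibule"] == pytest.approx(8.0)
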