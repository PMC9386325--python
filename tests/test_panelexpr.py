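"""Panel expression processing: QC, down-sampling, normalization, fences,
outlier print, differential expression and the TERT negativity rule."""

import numpy as np
import pandas as pd
import pytest

from telohallmark import panelexpr
from telohallmark.panelexpr import (
    ExpressionStudy,
    compute_fences,
    differential_expression,
    downsample_counts,
    flag_ffpe_extremes,
    log2cpm,
    outlier_flags,
    outlier_print,
    qc_filter_samples,
    remove_batch_effect,
    tert_status,
)

from conftest import make_log2cpm


def make_study(counts: np.ndarray, cohort=None, preservation=None) -> ExpressionStudy:
    n_probes, n_samples = counts.shape
    probes = [f"p{i}" for i in range(n_probes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return ExpressionStudy(
        counts=pd.DataFrame(counts, index=probes, columns=samples),
        probe_to_gene=pd.Series({p: f"g{i}" for i, p in enumerate(probes)}),
        samples=pd.DataFrame(
            {
                "cohort": cohort or ["disease_free"] * n_samples,
                "preservation": preservation or ["frozen"] * n_samples,
            },
            index=samples,
        ),
    )


class TestQcAndDownsampling:
    def test_threshold_is_strict(self):
        study = make_study(np.array([[169_999, 170_000]]))
        kept, discarded = qc_filter_samples(study)
        assert list(kept.counts.columns) == ["s1"]
        assert list(discarded.index) == ["s0"]

    def test_zero_threshold_keeps_all(self):
        study = make_study(np.array([[5, 10]]))
        kept, discarded = qc_filter_samples(study, min_total=0)
        assert kept.counts.shape[1] == 2 and discarded.empty

    def test_all_below_threshold_raises(self):
        with pytest.raises(ValueError, match="empty study"):
            qc_filter_samples(make_study(np.array([[5, 10]])), min_total=100)

    def test_downsample_conserves_total_exactly(self):
        counts = np.array([[500, 800], [300, 100], [0, 700]])
        study = downsample_counts(make_study(counts), target_total=400, seed=3)
        assert (study.counts.sum(axis=0) == 400).all()
        assert (study.counts.loc["p2", "s0"]) == 0  # zero probe stays zero

    def test_downsample_identity_at_full_total(self):
        counts = np.array([[10], [10]])
        study = downsample_counts(make_study(counts), target_total=20, seed=0)
        np.testing.assert_array_equal(study.counts.values, counts)

    def test_downsample_requires_qc_first(self):
        with pytest.raises(ValueError, match="below target"):
            downsample_counts(make_study(np.array([[10]])), target_total=50)

    def test_downsample_hypergeometric_mean(self):
        # two probes of 10 reads each, drawing 10: symmetric mean 5 per probe
        counts = np.array([[10], [10]])
        draws = [
            downsample_counts(make_study(counts), target_total=10, seed=s)
            .counts.iloc[0, 0]
            for s in range(1000)
        ]
        # hypergeometric SE of the mean of 1000 draws
        var = 10 * 0.5 * 0.5 * (20 - 10) / (20 - 1)
        assert abs(np.mean(draws) - 5) < 3 * np.sqrt(var / 1000)


class TestNormalization:
    def test_log2cpm_closed_form(self):
        study = make_study(np.array([[170_000]]))
        m = log2cpm(study, pseudocount=0)
        assert m.values.iloc[0, 0] == pytest.approx(np.log2(1e6))

    def test_pseudocount_keeps_zero_counts_finite(self):
        m = log2cpm(make_study(np.array([[0], [100]])))
        assert np.isfinite(m.values.values).all()

    def test_depth_invariance_in_small_pseudocount_limit(self):
        base = np.array([[100], [300], [600]])
        m1 = log2cpm(make_study(base), pseudocount=1e-9)
        m2 = log2cpm(make_study(2 * base), pseudocount=1e-9)
        np.testing.assert_allclose(m1.values.values, m2.values.values, atol=1e-7)

    def test_batch_means_equalized(self):
        m = make_log2cpm([[5.0, 5.0, 7.0, 7.0]])
        adj = remove_batch_effect(m, ["frozen", "frozen", "FFPE", "FFPE"])
        np.testing.assert_allclose(adj.values.values, [[6.0, 6.0, 6.0, 6.0]])

    def test_already_balanced_is_identity(self):
        m = make_log2cpm([[1.0, 3.0, 1.0, 3.0]])
        adj = remove_batch_effect(m, ["a", "a", "b", "b"])
        np.testing.assert_allclose(adj.values.values, m.values.values)

    def test_shift_invariance_up_to_gene_constant(self):
        # a constant added to one batch is fully absorbed: the adjusted
        # matrices agree up to a per-gene constant (the preserved grand
        # mean moves with the shift)
        vals = np.array([[1.0, 2.0, 5.0, 4.0], [0.0, 1.0, 2.0, 3.0]])
        batch = ["a", "a", "b", "b"]
        shifted = vals.copy()
        shifted[:, 2:] += 3.0
        a1 = remove_batch_effect(make_log2cpm(vals), batch).values.values
        a2 = remove_batch_effect(make_log2cpm(shifted), batch).values.values
        diff = a2 - a1
        np.testing.assert_allclose(diff, diff[:, :1] * np.ones_like(diff), atol=1e-12)


class TestFfpeExtremes:
    def test_planted_shifted_ffpe_sample_excluded(self, rng):
        vals = rng.normal(size=(187, 20))
        vals[:150, 0] += 5.0  # FFPE sample extreme on 150 genes
        meta = pd.DataFrame(
            {"preservation": ["FFPE"] * 2 + ["frozen"] * 18},
            index=[f"s{j}" for j in range(20)],
        )
        m = make_log2cpm(vals)
        assert flag_ffpe_extremes(m, meta) == ["s0"]

    def test_frozen_sample_never_excluded(self, rng):
        vals = rng.normal(size=(187, 20))
        vals[:150, 0] += 5.0
        meta = pd.DataFrame(
            {"preservation": ["frozen"] * 20}, index=[f"s{j}" for j in range(20)]
        )
        assert flag_ffpe_extremes(make_log2cpm(vals), meta) == []

    def test_identical_values_nobody_extreme(self):
        vals = np.ones((30, 12))
        meta = pd.DataFrame(
            {"preservation": ["FFPE"] * 12}, index=[f"s{j}" for j in range(12)]
        )
        assert flag_ffpe_extremes(make_log2cpm(vals), meta, max_extreme_genes=0) == []


class TestFences:
    def test_tukey_on_one_to_five(self):
        m = make_log2cpm([[1.0, 2.0, 3.0, 4.0, 5.0]])
        f = compute_fences(m, m.values.columns, "tukey")
        assert f.table.loc["g0", "lower"] == pytest.approx(-1.0)
        assert f.table.loc["g0", "upper"] == pytest.approx(7.0)

    def test_median_iqr_on_one_to_five(self):
        m = make_log2cpm([[1.0, 2.0, 3.0, 4.0, 5.0]])
        f = compute_fences(m, m.values.columns, "median_iqr")
        assert f.table.loc["g0", "lower"] == pytest.approx(1.0)
        assert f.table.loc["g0", "upper"] == pytest.approx(5.0)

    def test_constant_reference_zero_width(self):
        m = make_log2cpm([[2.0] * 6])
        f = compute_fences(m, m.values.columns, "tukey")
        assert f.table.loc["g0", "lower"] == f.table.loc["g0", "upper"] == 2.0

    def test_small_reference_rejected(self):
        m = make_log2cpm([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            compute_fences(m, m.values.columns)

    def test_matches_brute_force_quantile_oracle(self, rng):
        for _ in range(200):
            vals = rng.normal(size=(1, int(rng.integers(4, 15))))
            m = make_log2cpm(vals)
            f = compute_fences(m, m.values.columns, "tukey").table.iloc[0]
            q1, q3 = np.quantile(np.sort(vals[0]), [0.25, 0.75])
            assert f["lower"] == pytest.approx(q1 - 1.5 * (q3 - q1), rel=1e-9, abs=1e-12)
            assert f["upper"] == pytest.approx(q3 + 1.5 * (q3 - q1), rel=1e-9, abs=1e-12)

    def test_flags_invariant_under_common_shift(self, rng):
        vals = rng.normal(size=(5, 12))
        m1 = make_log2cpm(vals)
        m2 = make_log2cpm(vals + 7.5)
        ref = list(m1.values.columns[:6])
        f1 = compute_fences(m1, ref)
        f2 = compute_fences(m2, ref)
        pd.testing.assert_frame_equal(outlier_flags(m1, f1), outlier_flags(m2, f2))


class TestOutlierPrint:
    def test_boundary_value_not_flagged(self):
        m = make_log2cpm([[1.0, 2.0, 3.0, 4.0, 5.0, 7.0]])
        f = compute_fences(m, m.values.columns[:5], "tukey")  # upper fence 7.0
        op = outlier_print(m, {"g0": f}, {"g0": "high"})
        assert not op.flags.loc["g0", "s5"]  # exactly on the fence

    def test_event_count_over_candidate_set(self, rng):
        vals = rng.normal(size=(7, 10))
        vals[:6, 9] += 50.0
        vals[6, 9] -= 50.0
        m = make_log2cpm(vals)
        ref = list(m.values.columns[:8])
        f = compute_fences(m, ref, "tukey")
        directions = {f"g{i}": "high" for i in range(6)} | {"g6": "low"}
        op = outlier_print(m, {g: f for g in directions}, directions)
        assert op.event_count["s9"] == 7

    def test_missing_fence_raises(self):
        m = make_log2cpm([[1.0, 2.0, 3.0, 4.0, 5.0]])
        with pytest.raises(ValueError, match="fence"):
            outlier_print(m, {}, {"g0": "high"})


class TestDifferentialExpression:
    @staticmethod
    def _matrix(rng, n_genes=30, n_ref=12, n_agg=10):
        vals = rng.normal(size=(n_genes, n_ref + n_agg))
        cohort = ["disease_free"] * n_ref + ["aggressive"] * n_agg
        m = make_log2cpm(vals)
        return m, pd.Series(cohort, index=m.values.columns)

    def test_planted_shift_found_by_rank_route(self, rng):
        m, cohort = self._matrix(rng)
        m.values.loc["g0", cohort == "aggressive"] += 3.5
        res = differential_expression(m, cohort).table
        assert res.loc["g0", "candidate"] and res.loc["g0", "reason"] == "mw_significant"

    def test_partial_penetrance_found_by_outlier_route(self, rng):
        m, cohort = self._matrix(rng)
        agg = list(cohort.index[cohort == "aggressive"])
        m.values.loc["g1", agg[:3]] += 6.0  # 30% of aggressive only
        res = differential_expression(m, cohort).table
        assert res.loc["g1", "candidate"]
        assert res.loc["g1", "reason"] == "outlier_ratio"
        assert res.loc["g1", "p"] > 0.05 or res.loc["g1", "q"] > 0.15

    def test_small_cohort_rejected(self, rng):
        m, _ = self._matrix(rng, n_ref=2, n_agg=2)
        cohort = pd.Series(
            ["disease_free", "disease_free", "aggressive", "aggressive"],
            index=m.values.columns,
        )
        with pytest.raises(ValueError):
            differential_expression(m, cohort)

    def test_null_type_one_error_controlled(self):
        # exchangeable cohorts: fraction with p < .05 close to 0.05
        rng = np.random.default_rng(99)
        vals = rng.normal(size=(2000, 40))
        m = make_log2cpm(vals)
        cohort = pd.Series(
            ["disease_free"] * 20 + ["aggressive"] * 20, index=m.values.columns
        )
        res = differential_expression(m, cohort).table
        assert np.mean(res["p"] < 0.05) == pytest.approx(0.05, abs=0.02)


class TestTertStatus:
    @staticmethod
    def _tert_study(tert_counts):
        counts = pd.DataFrame(
            {"s0": list(tert_counts) + [100]},
            index=["TERT_p1", "TERT_p2", "TERT_p3", "TERT_p4", "other"],
        )
        p2g = pd.Series(
            {"TERT_p1": "TERT", "TERT_p2": "TERT", "TERT_p3": "TERT",
             "TERT_p4": "TERT", "other": "G1"}
        )
        meta = pd.DataFrame(
            {"cohort": ["aggressive"], "preservation": ["frozen"]}, index=["s0"]
        )
        return ExpressionStudy(counts=counts, probe_to_gene=p2g, samples=meta)

    @pytest.mark.parametrize(
        "tert_counts,expected",
        [((2, 2, 2, 2), "negative"), ((3, 0, 0, 0), "positive"), ((0, 0, 0, 0), "negative")],
    )
    def test_per_probe_rule(self, tert_counts, expected):
        assert tert_status(self._tert_study(tert_counts))["s0"] == expected

    def test_sum_rule_variant(self):
        study = self._tert_study((1, 1, 1, 0))
        assert tert_status(study, rule="per_probe")["s0"] == "negative"
        assert tert_status(study, rule="sum")["s0"] == "positive"

    def test_missing_tert_probes_raise(self):
        study = make_study(np.array([[10]]))
        with pytest.raises(ValueError, match="TERT"):
            tert_status(study)
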