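"""Preprocessing algebra: depth filter boundary, CLR identities, core
selection against a brute-force criterion, interpolation exactness, and
Box-Cox lambda recovery."""

import numpy as np
import pytest
from scipy import stats

from wavecluster.preprocessing import (PreprocessConfig, boxcox_rescale,
                                       clr_transform, filter_low_depth,
                                       interpolate_equidistant,
                                       preprocess_table, relative_abundance,
                                       select_core_taxa,
                                       union_across_subjects)
from wavecluster.series import CountTable, SampledSeries
from wavecluster.synthetic import make_synthetic_community


def _table(counts, times=None):
    counts = np.asarray(counts)
    times = np.arange(counts.shape[1], dtype=float) if times is None else times
    taxa = tuple(f"t{i}" for i in range(counts.shape[0]))
    return CountTable(taxa, times, counts)


class TestDepthFilter:
    def test_strict_less_than_boundary_keeps_exact_threshold(self):
        t = _table([[400, 600, 500]])
        out = filter_low_depth(t, 500)
        assert out.n_samples == 2
        np.testing.assert_array_equal(out.reads_per_sample, [600, 500])

    def test_zero_threshold_is_identity(self):
        t = _table([[5, 0, 7], [1, 2, 3]])
        out = filter_low_depth(t, 0)
        np.testing.assert_array_equal(out.counts, t.counts)

    def test_synthetic_community_passes_untouched(self):
        t = make_synthetic_community(depth=10_000, seed=0)
        assert filter_low_depth(t, 500).n_samples == t.n_samples

    def test_all_samples_removed_is_explicit_failure(self):
        with pytest.raises(ValueError, match="fewer than"):
            filter_low_depth(_table([[10, 20]]), 500)


class TestCoreSelection:
    def test_direct_criterion(self):
        # taxon 0: fraction 0.006 in 30% of samples; taxon 1: 0.004 always
        n = 100
        fr = np.full((3, n), 0.004)
        fr[0, :30] = 0.006
        fr[2] = 1.0 - fr[:2].sum(axis=0)
        rel = relative_abundance(_table(np.round(fr * 1e6).astype(int)))
        kept = select_core_taxa(rel, detection=0.005, prevalence=0.25, n_boot=0)
        assert "t0" in kept and "t1" not in kept

    def test_bootstrap_matches_brute_force_on_clear_community(self):
        t = make_synthetic_community(19, [(30, 5), (64, 5)], seed=5)
        rel = relative_abundance(t)
        direct = set(select_core_taxa(rel, n_boot=0))
        boot = set(select_core_taxa(rel, n_boot=100, seed=1))
        # brute-force evaluation of the criterion per taxon
        manual = {
            tax for tax, row in zip(rel.taxa, rel.fractions)
            if (row > 0.005).sum() >= 0.25 * rel.n_samples
        }
        assert direct == manual
        # abundant group taxa are never in doubt under the bootstrap
        group = {x for x in rel.taxa if not x.startswith("filler")}
        assert group <= boot

    def test_bootstrap_deterministic_given_seed(self):
        rel = relative_abundance(make_synthetic_community(seed=6))
        a = select_core_taxa(rel, n_boot=50, seed=9)
        b = select_core_taxa(rel, n_boot=50, seed=9)
        assert a == b

    def test_empty_selection_warns_not_raises(self):
        rel = relative_abundance(_table(np.ones((3, 30), dtype=int)))
        with pytest.warns(UserWarning, match="no taxa"):
            out = select_core_taxa(rel, detection=0.9, prevalence=1.0, n_boot=0)
        assert out == []


class TestUnion:
    def test_stable_ordered_union(self):
        assert union_across_subjects([["A", "B"], ["B", "C"]]) == ["A", "B", "C"]
        assert union_across_subjects([["A"], []]) == ["A"]


class TestCLR:
    def test_columns_sum_to_zero_and_monotone(self):
        rel = relative_abundance(_table([[2, 1], [1, 1], [1, 2]]))
        out = clr_transform(rel)
        np.testing.assert_allclose(out.sum(axis=0), 0.0, atol=1e-9)
        assert np.argmax(out[:, 0]) == 0  # largest fraction -> largest CLR

    def test_uniform_column_maps_to_zero(self):
        rel = relative_abundance(_table([[3, 1], [3, 1], [3, 1], [3, 1]]))
        out = clr_transform(rel)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_half_min_policy_matches_manual_computation(self):
        rel = relative_abundance(_table([[4, 1], [0, 1], [4, 2]]))
        out = clr_transform(rel, "half-min")
        # manual: fractions (0.5, 0, 0.5); zero -> (min nonzero)/2 = 0.25,
        # renormalize to (0.4, 0.2, 0.4), then CLR
        col = np.array([0.5, 0.25, 0.5])
        col = col / col.sum()
        expected = np.log(col) - np.log(col).mean()
        np.testing.assert_allclose(out[:, 0], expected, atol=1e-12)

    def test_all_zero_sample_rejected_upstream(self):
        t = CountTable(("a", "b"), np.array([0.0, 1.0]),
                       np.array([[1, 0], [1, 0]]))
        with pytest.raises(ValueError, match="zero"):
            relative_abundance(t)


class TestInterpolation:
    def test_reproduces_nodes_exactly(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 50, 40))
        s = SampledSeries("x", times, rng.normal(size=40))
        out = interpolate_equidistant(s, 1.6)
        # original t0 is on the grid; values at shared points match exactly
        assert out.values[0] == pytest.approx(s.values[0], abs=1e-12)
        from scipy.interpolate import PchipInterpolator
        interp = PchipInterpolator(s.times, s.values)
        np.testing.assert_allclose(interp(s.times), s.values, atol=1e-12)

    def test_exact_on_linear_data(self):
        s = SampledSeries("lin", np.array([0.0, 1.0, 3.0, 7.0, 10.0]),
                          np.array([0.0, 2.0, 6.0, 14.0, 20.0]))
        out = interpolate_equidistant(s, 0.7)
        np.testing.assert_allclose(out.values, 2.0 * out.times, atol=1e-10)

    def test_grid_point_count_formula(self):
        # span of 536 days at dt = 1.6 -> floor(536/1.6) + 1 = 336 points
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(0, 536, 300))
        times[0], times[-1] = 0.0, 536.0
        s = SampledSeries("m", times, rng.normal(size=300))
        out = interpolate_equidistant(s, 1.6)
        assert out.n == 336
        # female-subject-like span: floor(208/1.6) + 1 = 131
        times2 = np.sort(rng.uniform(0, 208, 120))
        times2[0], times2[-1] = 0.0, 208.0
        s2 = SampledSeries("f", times2, rng.normal(size=120))
        assert interpolate_equidistant(s2, 1.6).n == 131

    def test_no_extrapolation_beyond_span(self):
        s = SampledSeries("x", np.array([0.0, 1.0, 2.0, 3.0, 4.1]),
                          np.zeros(5))
        out = interpolate_equidistant(s, 1.0)
        assert out.times[-1] <= 4.1 + 1e-9

    def test_duplicate_timestamps_fail(self):
        with pytest.raises(ValueError):
            SampledSeries("d", np.array([0.0, 1.0, 1.0, 2.0]), np.zeros(4))


class TestBoxCox:
    def test_normal_input_transform_near_affine(self):
        # on already-normal data the PPCC surface is flat in lambda (every
        # power is near-affine on a narrow positive range): lambda = 1 must
        # be within 0.005 of the optimum and the chosen transform affine
        rng = np.random.default_rng(2)
        x = rng.normal(10, 1, 500)
        s = SampledSeries("n", np.arange(500.0), x)
        out, lam, shift = boxcox_rescale(s)
        lams, ppcc = stats.boxcox_normplot(x + shift, -2.0, 2.0, N=401)
        at_one = ppcc[np.argmin(np.abs(lams - 1.0))]
        assert ppcc.max() - at_one < 0.005
        assert abs(np.corrcoef(out.values, x)[0, 1]) > 0.999  # affine
        assert out.values.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.values.std() == pytest.approx(1.0, abs=1e-9)

    def test_lognormal_input_lambda_near_zero(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(0, 1, 500))
        s = SampledSeries("ln", np.arange(500.0), x)
        _, lam, shift = boxcox_rescale(s)
        assert shift == 0.0  # positive data are not shifted
        assert -0.2 < lam < 0.2

    def test_agrees_with_scipy_ppcc_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(2.0, 1.0, 400) + 1.0
        s = SampledSeries("g", np.arange(400.0), x)
        _, lam, shift = boxcox_rescale(s)
        # independent oracle: scipy's Box-Cox normality plot on a lambda
        # grid (Filliben plotting positions; argmax should agree closely)
        lams, ppcc = stats.boxcox_normplot(x + shift, -2.0, 2.0, N=401)
        assert lam == pytest.approx(lams[np.argmax(ppcc)], abs=0.1)

    def test_constant_series_fails(self):
        s = SampledSeries("c", np.arange(20.0), np.ones(20))
        with pytest.raises(ValueError, match="constant"):
            boxcox_rescale(s)


class TestPipelineAssembly:
    def test_full_preprocess_on_synthetic_community(self):
        table = make_synthetic_community(19, [(30, 5), (64, 5)], seed=1)
        rs, prov = preprocess_table(table, PreprocessConfig(seed=1))
        assert rs.dt == pytest.approx(1.6)
        assert rs.grid_times.size == int(np.floor(table.sample_times[-1] / 1.6)) + 1
        # group taxa are abundant by construction and must be retained
        assert all(any(l.startswith(p) for l in rs.labels) for p in ("p30", "p64"))
        # every retained series is standardized after Box-Cox
        np.testing.assert_allclose(rs.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(rs.values.std(axis=1), 1.0, atol=1e-9)
        assert set(prov["boxcox"]) == set(rs.labels)
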