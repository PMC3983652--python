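"""Turnover index estimation: OLS, truncation search, scaling, classification."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from h3turnover.genomic import GenomicInterval, TagLibrary
from h3turnover.turnover import (PeakTimeCourse, TurnoverFit, classify_bimodal,
                                 enrichment_series, fit_turnover, ols_fit,
                                 replicate_concordance, scale_indices)

HOURS12 = np.array([0, 1, 2, 3, 4, 5, 6, 12, 18, 24, 48, 72], dtype=float)


def closed_form_ols(x, y):
    """Normal equations evaluated independently (the test oracle)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def exhaustive_fit(tc, time_axis="ordinal"):
    """Independent implementation of the truncated best-fit search."""
    n = len(tc.E)
    x = np.arange(n, dtype=float) if time_axis == "ordinal" else tc.hours
    m = int(np.argmax(tc.E))
    ends = [n - 1] if m == n - 1 else list(range(max(m, 2), n))
    fits = [(ols_fit(x[:e + 1], tc.E[:e + 1]), e) for e in ends]
    (slope, intercept, p), e = min(fits, key=lambda t: t[0][2])
    return slope, intercept, p, e


def _tc(E, hours=None):
    E = np.asarray(E, float)
    hours = HOURS12[:len(E)] if hours is None else np.asarray(hours, float)
    return PeakTimeCourse(GenomicInterval("chr1", 0, 1000), hours, E)


class TestOlsFit:
    def test_exact_line(self):
        slope, intercept, p = ols_fit([0, 1, 2], [1, 3, 5])
        assert (slope, intercept) == (2.0, 1.0)
        assert 0 < p <= 1e-300 or p == np.finfo(float).tiny

    def test_constant_response_convention(self):
        slope, intercept, p = ols_fit([0, 1, 2, 3], [4, 4, 4, 4])
        assert (slope, intercept, p) == (0.0, 4.0, 1.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ols_fit([0, 1], [0, 1])

    def test_constant_predictor(self):
        with pytest.raises(ValueError):
            ols_fit([2, 2, 2], [0, 1, 2])

    def test_matches_normal_equations(self, rng):
        """30 random instances at 1e-10 against the closed form."""
        for _ in range(30):
            n = int(rng.integers(3, 15))
            x = rng.normal(0, 3, n)
            while np.allclose(x, x[0]):
                x = rng.normal(0, 3, n)
            y = rng.normal(0, 5, n)
            slope, intercept, _ = ols_fit(x, y)
            s2, i2 = closed_form_ols(x, y)
            assert slope == pytest.approx(s2, abs=1e-10)
            assert intercept == pytest.approx(i2, abs=1e-10)

    def test_p_matches_scipy_linregress(self, rng):
        from scipy.stats import linregress
        x = rng.normal(0, 1, 10)
        y = 0.5 * x + rng.normal(0, 1, 10)
        _, _, p = ols_fit(x, y)
        assert p == pytest.approx(linregress(x, y).pvalue, rel=1e-9)


class TestFitTurnover:
    def test_monotone_rise_uses_full_series(self):
        E = np.linspace(0, 3, 12)
        fit = fit_turnover(_tc(E))
        assert fit.end_index == 11
        slope, _ = closed_form_ols(np.arange(12), E)
        assert fit.ti_raw == pytest.approx(slope)

    def test_rise_then_plateau_matches_enumeration(self):
        E = np.array([0, 2, 4, 4, 4, 4, 4, 4, 4, 4, 4, 4], float)
        fit = fit_turnover(_tc(E))
        s, i, p, e = exhaustive_fit(_tc(E))
        assert (fit.ti_raw, fit.e0, fit.end_index) == (s, i, e)

    def test_truncation_removes_decline_bias(self):
        """Rise to a max then decline: truncated TI beats the full fit."""
        E = np.array([0, 1, 2, 3, 3.2, 3.1, 3.0, 2.5, 2.2, 2.0, 1.5, 1.2])
        fit = fit_turnover(_tc(E))
        full_slope, _ = closed_form_ols(np.arange(12), E)
        assert fit.end_index >= int(np.argmax(E))
        assert fit.ti_raw > full_slope

    def test_end_index_at_least_argmax(self, rng):
        for _ in range(50):
            E = np.abs(rng.normal(1, 0.5, 12))
            fit = fit_turnover(_tc(E))
            assert fit.end_index >= int(np.argmax(E)) or int(np.argmax(E)) < 2

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_turnover(_tc([0, 1], hours=[0, 1]))

    def test_oracle_equivalence_500_instances(self, rng):
        """The spec's core invariant: output equals exhaustive end search."""
        for _ in range(500):
            n = int(rng.integers(4, 13))
            E = np.abs(rng.normal(1.0, 0.8, n))
            tc = _tc(E, hours=np.sort(rng.choice(np.arange(1, 100), n, replace=False)) - 1)
            tc.hours[0] = 0 if tc.hours[0] != 0 else tc.hours[0]
            fit = fit_turnover(tc)
            s, i, p, e = exhaustive_fit(tc)
            assert fit.ti_raw == s and fit.e0 == i and fit.end_index == e

    def test_ordinal_axis_ignores_hour_spacing(self):
        E = np.array([0, 1, 1.5, 2, 2.6, 3.1, 3.3, 3.8, 4.0, 4.4, 4.6, 5.0])
        a = fit_turnover(_tc(E, hours=HOURS12), time_axis="ordinal")
        b = fit_turnover(_tc(E, hours=np.arange(12) * 7.0), time_axis="ordinal")
        assert a.ti_raw == b.ti_raw

    def test_hours_axis_depends_on_spacing(self):
        E = np.array([0, 1, 1.5, 2, 2.6, 3.1, 3.3, 3.8, 4.0, 4.4, 4.6, 5.0])
        a = fit_turnover(_tc(E, hours=HOURS12), time_axis="hours")
        b = fit_turnover(_tc(E, hours=np.arange(12) * 7.0), time_axis="hours")
        assert a.ti_raw != b.ti_raw

    def test_constant_offset_changes_only_intercept(self):
        E = np.array([0, 1, 2, 2.5, 3, 3.2, 3.4, 4, 4.5, 5, 6, 7])
        a = fit_turnover(_tc(E))
        b = fit_turnover(_tc(E + 5.0))
        assert b.ti_raw == pytest.approx(a.ti_raw)
        assert b.e0 == pytest.approx(a.e0 + 5.0)


class TestEnrichmentSeries:
    def _libs(self, tags_by_hour, input_tags):
        libs = [TagLibrary.from_tags(t, hours=h) for h, t in tags_by_hour]
        return libs, TagLibrary.from_tags(input_tags)

    def test_identical_densities_give_unit_enrichment(self):
        peak = GenomicInterval("chr1", 0, 10_000)
        tags = [("chr1", i, "+") for i in range(0, 10_000, 100)]
        libs, inp = self._libs([(0, tags), (6, tags)], tags)
        (tc,) = enrichment_series([peak], libs, inp, shift=0, input_pseudocount=0)
        assert np.allclose(tc.E, 1.0)

    def test_zero_chip_gives_zero(self):
        peak = GenomicInterval("chr1", 50_000, 60_000)
        tags = [("chr1", i, "+") for i in range(0, 10_000, 100)]
        libs, inp = self._libs([(0, tags), (6, tags)],
                               [("chr1", 55_000, "+")] * 10)
        (tc,) = enrichment_series([peak], libs, inp, shift=0)
        assert np.all(tc.E == 0)

    def test_rational_arithmetic_oracle(self, rng):
        """E_t recomputed with exact fractions for random peaks and libraries."""
        peaks = []
        for _ in range(20):
            s = int(rng.integers(0, 90_000))
            peaks.append(GenomicInterval("chr1", s, s + int(rng.integers(500, 5_000))))
        libs = []
        for h in (0.0, 6.0, 24.0):
            tags = [("chr1", int(p), "+") for p in rng.integers(0, 100_000, 3_000)]
            libs.append(TagLibrary.from_tags(tags, hours=h))
        inp = TagLibrary.from_tags(
            [("chr1", int(p), "+") for p in rng.integers(0, 100_000, 2_500)])
        series = enrichment_series(peaks, libs, inp, shift=75)
        from h3turnover.genomic import count_tags
        for tc, peak in zip(series, peaks):
            for lib, e in zip(libs, tc.E):
                c = count_tags(lib, peak, 75)
                i = count_tags(inp, peak, 75)
                exact = (Fraction(c, lib.total_mapped)
                         / (Fraction(i + 1, inp.total_mapped)))
                assert e == pytest.approx(float(exact), rel=1e-12)

    def test_duplicate_hours_rejected(self):
        tags = [("chr1", 10, "+")]
        libs = [TagLibrary.from_tags(tags, hours=3), TagLibrary.from_tags(tags, hours=3)]
        with pytest.raises(ValueError):
            enrichment_series([GenomicInterval("chr1", 0, 100)], libs,
                              TagLibrary.from_tags(tags))


class TestScaleIndices:
    def _fits(self, tis):
        return [TurnoverFit(GenomicInterval("chr1", i * 100 + 1, i * 100 + 50),
                            ti, 0.0, 0.5, 11, 12) for i, ti in enumerate(tis)]

    def test_linear_example(self):
        fits = scale_indices(self._fits([0, 5, 10]), "linear")
        assert [f.ti_scaled for f in fits] == [0.0, 0.5, 1.0]

    def test_endpoints_map_to_zero_and_one(self, rng):
        tis = rng.normal(0, 2, 50)
        for mode, attr in (("linear", "ti_scaled"), ("log", "ti_log")):
            fits = scale_indices(self._fits(tis), mode)
            vals = [getattr(f, attr) for f in fits]
            assert min(vals) == 0.0 and max(vals) == 1.0

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(-10**6, 10**6), min_size=2, max_size=60, unique=True))
    def test_rank_preservation(self, tis_int):
        tis = [t / 1000 for t in tis_int]
        fits = scale_indices(self._fits(tis), "linear")
        order_raw = np.argsort([f.ti_raw for f in fits], kind="stable")
        order_scaled = np.argsort([f.ti_scaled for f in fits], kind="stable")
        assert np.array_equal(order_raw, order_scaled)

    def test_log_clamps_non_positive(self):
        fits = scale_indices(self._fits([-1.0, 0.5, 5.0]), "log")
        assert fits[0].ti_log == 0.0
        assert fits[2].ti_log == 1.0

    def test_degenerate_scaling_rejected(self):
        with pytest.raises(ValueError):
            scale_indices(self._fits([2.0, 2.0, 2.0]), "linear")


class TestClassifyBimodal:
    def _fits_from(self, vals):
        fits = [TurnoverFit(GenomicInterval("chr1", i * 10 + 1, i * 10 + 5),
                            v, 0.0, 0.5, 11, 12) for i, v in enumerate(vals)]
        scale_indices(fits, "linear")
        scale_indices(fits, "log")
        return fits

    def test_separated_classes_detected(self, rng):
        vals = np.concatenate([rng.normal(0.02, 0.003, 100).clip(1e-4),
                               rng.normal(0.5, 0.05, 100)])
        res = classify_bimodal(self._fits_from(vals))
        assert res.two_populations and res.delta_bic > 0
        assert (res.labels[:100] == "slow").mean() >= 0.95
        assert (res.labels[100:] == "fast").mean() >= 0.95

    def test_all_identical_falls_back(self):
        fits = [TurnoverFit(GenomicInterval("chr1", i * 10 + 1, i * 10 + 5),
                            1.0, 0.0, 0.5, 11, 12, ti_scaled=0.5, ti_log=0.5)
                for i in range(60)]
        with pytest.warns(UserWarning):
            res = classify_bimodal(fits)
        assert res.fallback and not res.two_populations

    def test_outlier_component_treated_as_degenerate(self, rng):
        vals = np.concatenate([rng.normal(0.5, 0.05, 98), [5.0, 5.1]])
        with pytest.warns(UserWarning):
            res = classify_bimodal(self._fits_from(vals), use="linear")
        assert res.fallback

    def test_too_few_fits_rejected(self, rng):
        with pytest.raises(ValueError):
            classify_bimodal(self._fits_from(rng.normal(0.5, 0.1, 10)))


class TestReplicateConcordance:
    def _fits(self, tis, start0=0):
        fits = [TurnoverFit(GenomicInterval("chr1", start0 + i * 100 + 1,
                                            start0 + i * 100 + 50),
                            ti, 0.0, 0.5, 11, 12) for i, ti in enumerate(tis)]
        return scale_indices(fits, "linear")

    def test_self_correlation(self, rng):
        fits = self._fits(rng.normal(1, 0.3, 40))
        res = replicate_concordance(fits, fits)
        assert res.r == pytest.approx(1.0)
        assert res.n_shared == 40 and res.n_only_a == 0

    def test_affine_invariance(self, rng):
        tis = rng.normal(1, 0.3, 40)
        a = self._fits(tis)
        b = self._fits(3.0 * tis + 2.0)
        assert replicate_concordance(a, b).r == pytest.approx(1.0)

    def test_disjoint_peaks_rejected(self, rng):
        a = self._fits(rng.normal(1, 0.3, 20))
        b = self._fits(rng.normal(1, 0.3, 20), start0=500_000)
        with pytest.raises(ValueError):
            replicate_concordance(a, b)
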