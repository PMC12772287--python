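"""Titer estimation, inverse-relative-error weighting, and the jackknife screen.

The jackknife tests compare the module against a deliberately independent
brute-force implementation (plain-Python loops re-deriving the weighted
statistics from scratch).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phagekinetics import (ExperimentConfig, estimate_concentration,
                           jackknife_outliers, summarize_timepoint)
from phagekinetics.enumeration import (ConcentrationEstimate, QUANTITATIVE,
                                       TNTC, ZERO, weighted_mean_sd)
from phagekinetics.exceptions import (InsufficientDataError,
                                      NoQuantitativeDataError)

from conftest import obs


# --------------------------------------------------------------------------
# independent brute-force oracle for the weighted stats + jackknife screen
# --------------------------------------------------------------------------

def oracle_weighted(values, sigmas):
    """Weighted mean/SD re-derived from scratch (normalized convention)."""
    n = len(values)
    weights = [v / s for v, s in zip(values, sigmas)]
    total = sum(weights)
    mean = sum(w * v for w, v in zip(weights, values)) / total
    if n == 1:
        return mean, sigmas[0]
    acc = 0.0
    for w, v in zip(weights, values):
        acc += (w * n / total) * (v - mean) ** 2
    return mean, math.sqrt(acc / (n - 1))


def oracle_flags(values, sigmas, cv_thr=0.8, jk_thr=0.5, min_q=4):
    """Brute-force leave-one-out dual-criterion screen."""
    n = len(values)
    mean, sd = oracle_weighted(values, sigmas)
    if not (sd / mean > cv_thr and n >= min_q):
        return None  # screen does not run
    flags = []
    for i in range(n):
        rest_v = values[:i] + values[i + 1:]
        rest_s = sigmas[:i] + sigmas[i + 1:]
        m_jack, s_jack = oracle_weighted(rest_v, rest_s)
        a = abs((mean - m_jack) / m_jack)
        b = abs((sd - s_jack) / sd)
        flags.append(a > jk_thr and b > jk_thr)
    return flags


def quant(value, sigma):
    return ConcentrationEstimate(value, sigma, QUANTITATIVE, None)


# --------------------------------------------------------------------------
# titer estimation
# --------------------------------------------------------------------------

class TestEstimateConcentration:
    def test_direct_arithmetic_above_floor(self, cfg):
        # 100 plaques at 1e4-fold dilution, 10 uL plated -> 1e8 PFU/mL ± 10%
        est = estimate_concentration(obs(0, "free", 1e4, 100), cfg)
        assert est.status == QUANTITATIVE
        assert est.value == pytest.approx(1.0e8)
        assert est.sigma == pytest.approx(1.0e7)
        assert est.sigma / est.value == pytest.approx(0.10)

    def test_single_plaque_uses_sigma_floor(self, cfg):
        # sqrt(1) = 1 < 1.2, so the count-scale uncertainty is floored
        est = estimate_concentration(obs(0, "free", 1e6, 1), cfg)
        assert est.value == pytest.approx(1.0e8)
        assert est.sigma == pytest.approx(1.2e8)

    def test_zero_count_censored(self, cfg):
        est = estimate_concentration(obs(0, "free", 1e6, 0), cfg)
        assert est.status == ZERO
        assert est.value is None and est.sigma is None

    def test_tntc_censored(self, cfg):
        est = estimate_concentration(obs(0, "free", 10, None, tntc=True), cfg)
        assert est.status == TNTC
        assert est.value is None

    def test_relative_error_formula(self, cfg):
        # relative error = max(sqrt(c), floor)/c for any count
        for c in (1, 2, 5, 50, 400):
            est = estimate_concentration(obs(0, "free", 1e3, c), cfg)
            assert est.sigma / est.value == pytest.approx(
                max(math.sqrt(c), 1.2) / c)


# --------------------------------------------------------------------------
# per-timepoint aggregation
# --------------------------------------------------------------------------

class TestSummarizeTimepoint:
    def test_equal_values_give_zero_sd(self, cfg):
        ests = [estimate_concentration(obs(0, "free", 10, 100, rep=r), cfg)
                for r in ("R1", "R2", "R3")]
        s = summarize_timepoint(ests, cfg)
        assert s.weighted_mean == pytest.approx(1e5)
        assert s.weighted_sd == 0.0
        assert s.n_quantitative == s.n_attempted == 3

    def test_hand_computed_weighted_mean(self, cfg):
        # counts 100 and 400 -> weights 10 and 20; mean = 5e9/30
        a = estimate_concentration(obs(0, "free", 1e4, 100, rep="R1"), cfg)
        b = estimate_concentration(obs(0, "free", 5e3, 400, rep="R2"), cfg)
        assert (a.value, b.value) == (pytest.approx(1e8), pytest.approx(2e8))
        s = summarize_timepoint([a, b], cfg)
        assert s.weighted_mean == pytest.approx(5e9 / 30)
        om, osd = oracle_weighted([a.value, b.value], [a.sigma, b.sigma])
        assert s.weighted_mean == pytest.approx(om)
        assert s.weighted_sd == pytest.approx(osd)

    def test_single_estimate_keeps_its_sigma(self, cfg):
        est = estimate_concentration(obs(0, "free", 1e4, 100), cfg)
        s = summarize_timepoint([est], cfg)
        assert s.weighted_mean == est.value
        assert s.weighted_sd == est.sigma

    def test_censored_estimates_never_contribute(self, cfg):
        ests = [estimate_concentration(obs(0, "free", 10, 100, rep="R1"), cfg),
                estimate_concentration(obs(0, "free", 10, 0, rep="R2"), cfg),
                estimate_concentration(obs(0, "free", 10, None, rep="R3",
                                           tntc=True), cfg)]
        s = summarize_timepoint(ests, cfg)
        assert s.n_quantitative == 1 and s.n_attempted == 3
        assert s.weighted_mean == ests[0].value

    def test_all_censored_raises(self, cfg):
        ests = [estimate_concentration(obs(0, "free", 10, 0), cfg)]
        with pytest.raises(NoQuantitativeDataError):
            summarize_timepoint(ests, cfg)

    def test_frequency_convention_differs_but_same_mean(self):
        cfg_n = ExperimentConfig(sd_convention="normalized")
        cfg_f = ExperimentConfig(sd_convention="frequency")
        values = np.array([1e8, 2e8, 1.5e8])
        sigmas = np.array([1e7, 3e7, 2e7])
        mn, sn = weighted_mean_sd(values, sigmas, cfg_n.sd_convention)
        mf, sf = weighted_mean_sd(values, sigmas, cfg_f.sd_convention)
        assert mn == pytest.approx(mf)
        assert sn != pytest.approx(sf)


# --------------------------------------------------------------------------
# jackknife outlier screen
# --------------------------------------------------------------------------

class TestJackknife:
    def _screen(self, values, sigmas, cfg):
        ests = [quant(v, s) for v, s in zip(values, sigmas)]
        summary = summarize_timepoint(ests, cfg)
        return jackknife_outliers(summary, ests, cfg), summary

    def test_low_cv_not_screened(self, cfg):
        values = [1e8, 1.05e8, 0.95e8, 1e8]
        screened, before = self._screen(values, [v * 0.1 for v in values], cfg)
        assert before.weighted_cv <= 0.8
        assert not screened.screened
        assert screened == before  # summary unchanged

    def test_three_quantitative_not_screened(self, cfg):
        # huge CV but only 3 quantitative measurements: screen must not run
        values = [1e8, 1e8, 5e9]
        screened, before = self._screen(values, [v * 0.1 for v in values], cfg)
        assert before.weighted_cv > 0.8
        assert not screened.screened

    def test_extreme_value_flagged_and_excluded(self, cfg):
        # five concordant values plus one 50-fold larger with comparable weight
        values = [1e8] * 5 + [5e9]
        sigmas = [v * 0.1 for v in values]
        screened, before = self._screen(values, sigmas, cfg)
        assert screened.screened
        assert screened.outlier_flags == (False,) * 5 + (True,)
        assert screened.outlier_flags == tuple(oracle_flags(values, sigmas))
        # flagged estimate excluded: recomputed mean is the concordant value
        assert screened.weighted_mean == pytest.approx(1e8)
        assert screened.weighted_mean < before.weighted_mean

    def test_influence_statistics_recorded(self, cfg):
        values = [1e8] * 5 + [5e9]
        sigmas = [v * 0.1 for v in values]
        screened, before = self._screen(values, sigmas, cfg)
        a, b = screened.influence[5]
        # dropping the outlier collapses the jackknife mean to 1e8 and SD to 0
        assert a == pytest.approx(abs(before.weighted_mean - 1e8) / 1e8)
        assert b == pytest.approx(1.0)

    def test_threshold_ties_not_flagged(self):
        # strict comparison: A_i exactly at threshold must not flag
        cfg = ExperimentConfig(jackknife_threshold=0.5)
        values = [1e8] * 5 + [5e9]
        sigmas = [v * 0.1 for v in values]
        ests = [quant(v, s) for v, s in zip(values, sigmas)]
        summary = summarize_timepoint(ests, cfg)
        # raise the threshold to the exact computed A of the outlier: no flag
        probe = jackknife_outliers(summary, ests, cfg)
        a_out, b_out = probe.influence[5]
        cfg_tie = ExperimentConfig(jackknife_threshold=min(a_out, b_out))
        tied = jackknife_outliers(summary, ests, cfg_tie)
        assert not any(tied.outlier_flags)

    def test_refuses_below_two_quantitative(self):
        cfg = ExperimentConfig(min_quantitative=1)
        est = quant(1e8, 1e8 * 0.9)  # CV of a single point is its rel. error
        summary = summarize_timepoint([est], cfg)
        with pytest.raises(InsufficientDataError):
            jackknife_outliers(summary, [est], cfg)

    def test_matches_brute_force_on_random_tables(self, cfg):
        """Exhaustive agreement with the leave-one-out oracle, random tables."""
        rng = np.random.default_rng(2024)
        screened_seen = flagged_seen = 0
        for _ in range(400):
            n = int(rng.integers(4, 7))
            counts = rng.integers(1, 300, size=n)
            scales = 10.0 ** rng.integers(0, 4, size=n)
            values = [float(c * s * 1e4) for c, s in zip(counts, scales)]
            sigmas = [float(max(math.sqrt(c), 1.2) * s * 1e4)
                      for c, s in zip(counts, scales)]
            ests = [quant(v, s) for v, s in zip(values, sigmas)]
            summary = summarize_timepoint(ests, cfg)
            result = jackknife_outliers(summary, ests, cfg)
            expected = oracle_flags(values, sigmas)
            if expected is None:
                assert not result.screened
            else:
                screened_seen += 1
                flagged_seen += sum(expected)
                assert result.screened
                assert list(result.outlier_flags) == expected
        assert screened_seen > 50       # both branches genuinely exercised
        assert flagged_seen > 10


# --------------------------------------------------------------------------
# invariants
# --------------------------------------------------------------------------

@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(1, 500), min_size=2, max_size=6))
def test_equal_count_reduction(counts):
    """Equal counts at one dilution -> weighted mean equals arithmetic mean."""
    cfg = ExperimentConfig()
    c = counts[0]
    ests = [quant(float(c * 1e4), max(math.sqrt(c), 1.2) * 1e4)
            for _ in counts]
    s = summarize_timepoint(ests, cfg)
    assert s.weighted_mean == pytest.approx(c * 1e4)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(1, 400), st.integers(0, 4)),
                min_size=2, max_size=6),
       st.floats(0.01, 1e6))
def test_scale_equivariance(table, c):
    """Scaling all values and sigmas by c scales mean/SD by c; CV and flags
    are invariant."""
    cfg = ExperimentConfig()
    values = [float(cnt * 10.0 ** d * 1e3) for cnt, d in table]
    sigmas = [max(math.sqrt(cnt), 1.2) * 10.0 ** d * 1e3 for cnt, d in table]
    base = jackknife_outliers(
        summarize_timepoint([quant(v, s) for v, s in zip(values, sigmas)], cfg),
        [quant(v, s) for v, s in zip(values, sigmas)], cfg)
    ests_c = [quant(v * c, s * c) for v, s in zip(values, sigmas)]
    scaled = jackknife_outliers(summarize_timepoint(ests_c, cfg), ests_c, cfg)
    assert scaled.weighted_mean == pytest.approx(base.weighted_mean * c)
    assert scaled.weighted_sd == pytest.approx(base.weighted_sd * c,
                                               rel=1e-9, abs=1e-12)
    assert scaled.weighted_cv == pytest.approx(base.weighted_cv, abs=1e-12)
    assert scaled.outlier_flags == base.outlier_flags
    assert scaled.screened == base.screened
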