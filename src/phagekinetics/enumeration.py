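"""Titer estimation with Poisson counting error and weighted aggregation.

Each plate count ``c`` becomes a concentration estimate

    value = c * dilution_factor / plated_volume_ml          [PFU/mL]
    sigma = max(sqrt(c), sigma_floor) * dilution / volume   [PFU/mL]

so the relative error of a plate is ``max(sqrt(c), floor) / c`` — pure
Poisson counting statistics with a small-count floor (default 1.2 counts).
Zero-count and TNTC plates are censored: they carry a status but no value
usable downstream.

Per timepoint, the quantitative estimates (typically six: three biological
replicates at two sequential dilutions, each treated as an independent
measurement) are combined with weights equal to the *inverse relative
error* of each measurement, ``w_i = value_i / sigma_i``.  When the weighted
coefficient of variation exceeds ``cv_threshold`` (default 0.8) and at
least ``min_quantitative`` (default 4) measurements are quantitative, a
single-pass jackknife screen flags influential outliers: measurement *i*
is an outlier iff *both*

    A_i = |(m_full - m_jack(i)) / m_jack(i)| > threshold     (influence on mean)
    B_i = |(s_full - s_jack(i)) / s_full|   > threshold      (contribution to SD)

strictly exceed the dual threshold (default 0.5).  Flagged measurements
are removed and the summary recomputed once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .config import ExperimentConfig
from .exceptions import InsufficientDataError, NoQuantitativeDataError
from .observations import PlateObservation

__all__ = [
    "ConcentrationEstimate",
    "TimepointSummary",
    "estimate_concentration",
    "summarize_timepoint",
    "jackknife_outliers",
    "summarize_series",
    "weighted_mean_sd",
]

QUANTITATIVE = "quantitative"
ZERO = "zero"
TNTC = "tntc"


@dataclass(frozen=True)
class ConcentrationEstimate:
    """A titer (PFU/mL) with Poisson-derived uncertainty, or a censored status."""

    value: Optional[float]
    sigma: Optional[float]
    status: str  # quantitative | zero | tntc
    source: Optional[PlateObservation] = None

    @property
    def is_quantitative(self) -> bool:
        return self.status == QUANTITATIVE


@dataclass(frozen=True)
class TimepointSummary:
    """Weighted mean ± weighted SD of titer at one sampling time.

    ``outlier_flags`` and ``influence`` align with the estimate sequence the
    summary was computed from (False / None for censored estimates).  When
    outliers were flagged, ``weighted_mean`` / ``weighted_sd`` / ``weighted_cv``
    are the post-exclusion values.
    """

    time_min: float
    phage_fraction: str
    weighted_mean: float
    weighted_sd: float
    weighted_cv: float
    n_quantitative: int
    n_attempted: int
    screened: bool = False
    outlier_flags: Tuple[bool, ...] = ()
    influence: Tuple[Optional[Tuple[float, float]], ...] = ()

    @property
    def n_flagged(self) -> int:
        return sum(self.outlier_flags)


def estimate_concentration(obs: PlateObservation,
                           cfg: ExperimentConfig) -> ConcentrationEstimate:
    """Convert one plate observation to a titer with Poisson uncertainty.

    Status is ``quantitative`` iff the count is >= 1 and not TNTC; zero
    counts and TNTC plates are censored with no numeric value.
    """
    if obs.tntc:
        return ConcentrationEstimate(None, None, TNTC, obs)
    if obs.plaque_count == 0:
        return ConcentrationEstimate(None, None, ZERO, obs)
    scale = obs.dilution_factor / obs.plated_volume_ml
    c = obs.plaque_count
    sigma_count = max(np.sqrt(c), cfg.sigma_floor)
    return ConcentrationEstimate(c * scale, sigma_count * scale, QUANTITATIVE, obs)


def weighted_mean_sd(values: np.ndarray, sigmas: np.ndarray,
                     convention: str = "normalized") -> Tuple[float, float]:
    """Inverse-relative-error-weighted mean and SD.

    Weights are w_i = value_i / sigma_i.  For a single value the SD is that
    value's own sigma (preserving a usable uncertainty for propagation).
    "normalized" rescales weights to sum to n and divides by n-1, so the
    result is invariant to the overall weight scale; "frequency" treats
    weights as effective frequencies and divides by (sum w) - 1.
    """
    values = np.asarray(values, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    n = values.size
    if n == 0:
        raise NoQuantitativeDataError("no quantitative values to aggregate")
    if np.any(sigmas == 0):
        # exact measurements dominate: aggregate only those, with zero spread
        exact = values[sigmas == 0]
        return float(np.mean(exact)), 0.0
    w = values / sigmas
    mean = float(np.sum(w * values) / np.sum(w))
    if n == 1:
        return mean, float(sigmas[0])
    if convention == "normalized":
        wn = w * (n / np.sum(w))
        var = float(np.sum(wn * (values - mean) ** 2) / (n - 1))
    elif convention == "frequency":
        denom = np.sum(w) - 1.0
        if denom <= 0:
            raise InsufficientDataError(
                "frequency-convention weighted SD undefined: sum of weights <= 1")
        var = float(np.sum(w * (values - mean) ** 2) / denom)
    else:
        raise ValueError(f"unknown sd convention {convention!r}")
    return mean, float(np.sqrt(max(var, 0.0)))


def _quantitative(estimates: Sequence[ConcentrationEstimate]):
    idx = [i for i, e in enumerate(estimates) if e.is_quantitative]
    values = np.array([estimates[i].value for i in idx], dtype=float)
    sigmas = np.array([estimates[i].sigma for i in idx], dtype=float)
    return idx, values, sigmas


def summarize_timepoint(estimates: Sequence[ConcentrationEstimate],
                        cfg: ExperimentConfig) -> TimepointSummary:
    """Aggregate one timepoint's estimates into a weighted summary.

    All estimates must share ``time_min`` and ``phage_fraction``.  Censored
    (zero/TNTC) estimates never contribute to the mean, SD, or CV.

    Raises
    ------
    NoQuantitativeDataError
        If no estimate is quantitative.
    """
    if not estimates:
        raise NoQuantitativeDataError("empty timepoint")
    sources = [e.source for e in estimates if e.source is not None]
    times = {s.time_min for s in sources}
    fracs = {s.phage_fraction for s in sources}
    if len(times) > 1 or len(fracs) > 1:
        raise ValueError("estimates mix timepoints or phage fractions")
    time_min = times.pop() if times else float("nan")
    fraction = fracs.pop() if fracs else ""

    idx, values, sigmas = _quantitative(estimates)
    if not idx:
        raise NoQuantitativeDataError(
            f"no quantitative data at t={time_min:g} ({fraction})")
    mean, sd = weighted_mean_sd(values, sigmas, cfg.sd_convention)
    return TimepointSummary(
        time_min=time_min,
        phage_fraction=fraction,
        weighted_mean=mean,
        weighted_sd=sd,
        weighted_cv=sd / mean,
        n_quantitative=len(idx),
        n_attempted=len(estimates),
        screened=False,
        outlier_flags=tuple(False for _ in estimates),
        influence=tuple(None for _ in estimates),
    )


def jackknife_outliers(summary: TimepointSummary,
                       estimates: Sequence[ConcentrationEstimate],
                       cfg: ExperimentConfig) -> TimepointSummary:
    """Screen a timepoint for influential outliers by leave-one-out resampling.

    Screening runs iff ``weighted_cv > cv_threshold`` and at least
    ``min_quantitative`` estimates are quantitative; otherwise the summary is
    returned unchanged (``screened`` False).  Flagging is strict (> on both
    thresholds) and single-pass: flagged measurements are removed and the
    summary recomputed once, with no re-screening.
    """
    if not (summary.weighted_cv > cfg.cv_threshold
            and summary.n_quantitative >= cfg.min_quantitative):
        return summary
    idx, values, sigmas = _quantitative(estimates)
    n = len(idx)
    if n < 2:
        raise InsufficientDataError(
            "jackknife undefined with fewer than 2 quantitative estimates")

    m_full, s_full = summary.weighted_mean, summary.weighted_sd
    flags = list(summary.outlier_flags) or [False] * len(estimates)
    influence: List[Optional[Tuple[float, float]]] = [None] * len(estimates)
    mask = np.ones(n, dtype=bool)
    for j in range(n):
        mask[j] = False
        m_jack, s_jack = weighted_mean_sd(values[mask], sigmas[mask],
                                          cfg.sd_convention)
        mask[j] = True
        a = abs((m_full - m_jack) / m_jack)
        b = abs((s_full - s_jack) / s_full)
        influence[idx[j]] = (a, b)
        flags[idx[j]] = bool(a > cfg.jackknife_threshold
                             and b > cfg.jackknife_threshold)

    if any(flags):
        kept = [j for j in range(n) if not flags[idx[j]]]
        if not kept:
            raise InsufficientDataError(
                "jackknife flagged every quantitative measurement")
        mean, sd = weighted_mean_sd(values[kept], sigmas[kept], cfg.sd_convention)
    else:
        mean, sd = m_full, s_full
    return replace(
        summary,
        weighted_mean=mean,
        weighted_sd=sd,
        weighted_cv=sd / mean,
        screened=True,
        outlier_flags=tuple(flags),
        influence=tuple(influence),
    )


def summarize_series(observations: Iterable[PlateObservation],
                     cfg: ExperimentConfig,
                     screen: bool = True):
    """Estimate, aggregate, and (optionally) screen a whole table.

    Returns
    -------
    dict mapping ``(experiment_id, medium, phage_fraction)`` to a
    time-ordered list of ``(TimepointSummary | None, [ConcentrationEstimate])``
    pairs; the summary is ``None`` for timepoints with no quantitative data
    (the pipeline continues past them).
    """
    grouped: Dict[tuple, Dict[float, List[ConcentrationEstimate]]] = {}
    for obs in observations:
        est = estimate_concentration(obs, cfg)
        key = (obs.experiment_id, obs.medium, obs.phage_fraction)
        grouped.setdefault(key, {}).setdefault(obs.time_min, []).append(est)

    out: Dict[tuple, list] = {}
    for key, by_time in grouped.items():
        series = []
        for t in sorted(by_time):
            ests = by_time[t]
            try:
                summ = summarize_timepoint(ests, cfg)
            except NoQuantitativeDataError:
                series.append((None, ests))
                continue
            if screen:
                summ = jackknife_outliers(summ, ests, cfg)
            series.append((summ, ests))
        out[key] = series
    return out
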