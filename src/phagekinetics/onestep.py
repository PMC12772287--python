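"""One-step growth analysis: latent period and burst size.

A one-step growth assay synchronizes a single infection cycle: phage adsorb
briefly at MOI ~0.1, then the culture is diluted a hundredfold so progeny
cannot start new infections.  Two series are followed over time:

* free phage (0.22-µm filtrate) — residual unadsorbed phage, then progeny;
* total phage (unfiltered) — free phage plus one plaque per infected cell.

From the first post-transfer sampling time, the initial infected-cell
concentration is

    I0 = T0 - F0        (total minus free, both as value ± sigma)

and the burst size is the plateau free-phage concentration after one
infective cycle divided by I0:

    B = plateau_mean / I0

with first-order error propagation throughout.  The latent period onset is
operationalized as the earliest sampled time whose free-phage mean exceeds
the pre-burst baseline by ``onset_z`` combined standard deviations (the
"first clear evidence of burst" judgement made explicit and configurable).

Plaque counting, Poisson uncertainties, inverse-relative-error weighting,
and the jackknife outlier screen are identical to the adsorption analysis
(the same :mod:`phagekinetics.enumeration` machinery runs on both series).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import pandas as pd

from .config import ExperimentConfig
from .enumeration import TimepointSummary, summarize_series, weighted_mean_sd
from .exceptions import AssayError, ConfigurationError, InsufficientDataError
from .observations import PlateObservation, observations_from_dataframe, \
    read_counts_table, split_conditions
from .uncertainty import Uncertain
from .welch import WelchResult, welch_tsum

__all__ = [
    "OneStepResults",
    "OneStepModel",
    "infected_cells",
    "aggregate_summaries",
    "detect_latent_onset",
    "burst_size",
    "compare_burst",
]

import numpy as np


@dataclass(frozen=True)
class OneStepResults:
    """One-step growth estimates for a single condition."""

    T0: Uncertain
    F0: Uncertain
    I0: Uncertain
    latent_onset_min: Optional[float]
    baseline: Uncertain
    plateau_mean: Uncertain
    burst_size: Uncertain
    n_plateau: int
    plateau_window: Tuple[float, float]
    experiment_id: Optional[str] = None
    medium: Optional[str] = None
    free_summaries: Tuple[TimepointSummary, ...] = ()
    total_summaries: Tuple[TimepointSummary, ...] = ()

    def to_dict(self) -> dict:
        def u(x: Uncertain):
            return {"value": x.value, "sigma": x.sigma}
        return {
            "experiment_id": self.experiment_id,
            "medium": self.medium,
            "T0": u(self.T0),
            "F0": u(self.F0),
            "I0": u(self.I0),
            "latent_onset_min": self.latent_onset_min,
            "baseline": u(self.baseline),
            "plateau_mean": u(self.plateau_mean),
            "burst_size": u(self.burst_size),
            "n_plateau": self.n_plateau,
            "plateau_window": list(self.plateau_window),
        }

    def summary(self) -> str:
        cond = " / ".join(x for x in (self.experiment_id, self.medium) if x)
        onset = (f"{self.latent_onset_min:g} min" if self.latent_onset_min
                 is not None else "no burst detected")
        lines = [
            "One-step growth analysis" + (f" [{cond}]" if cond else ""),
            "=" * 46,
            f"  T0 (total, t0)   {self.T0.value:.4e} ± {self.T0.sigma:.2e} PFU/mL",
            f"  F0 (free, t0)    {self.F0.value:.4e} ± {self.F0.sigma:.2e} PFU/mL",
            f"  I0 = T0 - F0     {self.I0.value:.4e} ± {self.I0.sigma:.2e} /mL",
            f"  latent onset     {onset}",
            f"  plateau mean     {self.plateau_mean.value:.4e} ± "
            f"{self.plateau_mean.sigma:.2e} PFU/mL"
            f"  ({self.n_plateau} timepoints in "
            f"{self.plateau_window[0]:g}-{self.plateau_window[1]:g} min)",
            f"  burst size B     {self.burst_size.value:.1f} ± "
            f"{self.burst_size.sigma:.1f} phage/cell",
        ]
        return "\n".join(lines)


def infected_cells(T0: Uncertain, F0: Uncertain) -> Uncertain:
    """Initial infected cells I0 = T0 - F0 (per mL), sigma in quadrature.

    Raises :class:`AssayError` if F0 >= T0 (the assay produced no inferable
    infected cells; this signals failure rather than warning).
    """
    if F0.value >= T0.value:
        raise AssayError(
            f"non-positive infected cells: initial free phage ({F0.value:.3e})"
            f" >= initial total phage ({T0.value:.3e})")
    return T0 - F0


def aggregate_summaries(summaries: Sequence[TimepointSummary],
                        cfg: ExperimentConfig) -> Uncertain:
    """Inverse-relative-error-weighted aggregate of whole-timepoint summaries.

    Weights each timepoint by mean/SD (mirroring the per-plate weighting one
    level up); a single timepoint passes through as mean ± SD.
    """
    if not summaries:
        raise InsufficientDataError("no summaries to aggregate")
    values = np.array([s.weighted_mean for s in summaries], dtype=float)
    sigmas = np.array([s.weighted_sd for s in summaries], dtype=float)
    mean, sd = weighted_mean_sd(values, sigmas, cfg.sd_convention)
    return Uncertain(mean, sd)


def detect_latent_onset(free_series: Sequence[TimepointSummary],
                        cfg: ExperimentConfig,
                        ) -> Tuple[Optional[float], Uncertain]:
    """Detect the onset of progeny release against a pre-burst baseline.

    The baseline is the weighted aggregate over ``cfg.baseline_window``;
    the onset is the earliest sampled time t with

        mean(t) > baseline + onset_z * sqrt(baseline_sd² + sd(t)²).

    Returns ``(onset_time, baseline)``; onset is ``None`` when no sampled
    time qualifies ("no burst detected").
    """
    series = sorted(free_series, key=lambda s: s.time_min)
    lo, hi = cfg.baseline_window
    base = [s for s in series if lo <= s.time_min <= hi]
    if not base:
        raise ConfigurationError(
            f"baseline window [{lo:g}, {hi:g}] contains no sampled timepoints")
    if len(base) < 2:
        raise InsufficientDataError(
            "need >= 2 timepoints in the baseline window")
    baseline = aggregate_summaries(base, cfg)
    for s in series:
        threshold = baseline.value + cfg.onset_z * np.hypot(
            baseline.sigma, s.weighted_sd)
        if s.weighted_mean > threshold:
            return s.time_min, baseline
    return None, baseline


def burst_size(plateau_summaries: Sequence[TimepointSummary],
               I0: Uncertain, cfg: ExperimentConfig) -> Uncertain:
    """Burst size B = plateau free-phage mean / I0, with propagated sigma.

    ``plateau_summaries`` must already be restricted to the plateau window
    (>= 1 summary).
    """
    if not plateau_summaries:
        raise InsufficientDataError("empty plateau window: no summaries")
    plateau = aggregate_summaries(plateau_summaries, cfg)
    return plateau / I0


def compare_burst(b_a: Uncertain, b_b: Uncertain,
                  n_a: int, n_b: int) -> WelchResult:
    """Welch comparison of two burst sizes (value, sigma) as (mean, SD)."""
    return welch_tsum(b_a.value, b_a.sigma, n_a, b_b.value, b_b.sigma, n_b)


class OneStepModel:
    """One-step growth analysis for a single experimental condition.

    Consumes a plaque-count table with both ``free`` and ``total`` fraction
    rows for one (experiment_id, medium) condition; ``fit()`` runs
    estimation, weighting, outlier screening, infected-cell inference,
    onset detection, plateau aggregation, and burst-size calculation.
    """

    def __init__(self, observations: Sequence[PlateObservation],
                 config: ExperimentConfig):
        conditions = split_conditions(observations)
        if len(conditions) != 1:
            raise ValueError(
                f"OneStepModel handles one condition; got {len(conditions)}."
                " Split the table with observations.split_conditions first.")
        (self.experiment_id, self.medium), = conditions.keys()
        self.observations = list(observations)
        self.config = config

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: ExperimentConfig):
        return cls(observations_from_dataframe(df), config)

    @classmethod
    def from_csv(cls, path, config: ExperimentConfig, sep: Optional[str] = None):
        return cls(read_counts_table(path, sep=sep), config)

    def summarize(self, screen: bool = True):
        """Screened per-timepoint summaries, keyed 'free' / 'total'."""
        series = summarize_series(self.observations, self.config, screen=screen)
        out = {}
        for fraction in ("free", "total"):
            key = (self.experiment_id, self.medium, fraction)
            out[fraction] = series.get(key, [])
        return out

    def fit(self, plateau_window: Optional[Tuple[float, float]] = None,
            baseline_window: Optional[Tuple[float, float]] = None,
            screen: bool = True) -> OneStepResults:
        cfg = self.config
        if plateau_window is not None or baseline_window is not None:
            from dataclasses import replace as _replace
            cfg = _replace(
                cfg,
                plateau_window=tuple(plateau_window) if plateau_window
                else cfg.plateau_window,
                baseline_window=tuple(baseline_window) if baseline_window
                else cfg.baseline_window)

        pairs = self.summarize(screen=screen)
        free = [s for s, _ in pairs["free"] if s is not None]
        total = [s for s, _ in pairs["total"] if s is not None]
        if not free or not total:
            raise InsufficientDataError(
                "one-step analysis needs quantitative free and total series")

        t0 = min(min(s.time_min for s in free), min(s.time_min for s in total))
        f0s = next((s for s in sorted(free, key=lambda s: s.time_min)
                    if s.time_min == t0), None)
        t0s = next((s for s in sorted(total, key=lambda s: s.time_min)
                    if s.time_min == t0), None)
        if f0s is None or t0s is None:
            raise InsufficientDataError(
                f"free and total series must both be quantitative at t0={t0:g}")
        T0 = Uncertain(t0s.weighted_mean, t0s.weighted_sd)
        F0 = Uncertain(f0s.weighted_mean, f0s.weighted_sd)
        I0 = infected_cells(T0, F0)

        onset, baseline = detect_latent_onset(free, cfg)

        lo, hi = cfg.plateau_window
        plateau_summaries = [s for s in free if lo <= s.time_min <= hi]
        plateau = aggregate_summaries(plateau_summaries, cfg) \
            if plateau_summaries else None
        if plateau is None:
            raise InsufficientDataError(
                f"plateau window [{lo:g}, {hi:g}] contains no quantitative"
                " free-phage timepoints")
        B = plateau / I0

        return OneStepResults(
            T0=T0, F0=F0, I0=I0,
            latent_onset_min=onset, baseline=baseline,
            plateau_mean=plateau, burst_size=B,
            n_plateau=len(plateau_summaries),
            plateau_window=(float(lo), float(hi)),
            experiment_id=self.experiment_id, medium=self.medium,
            free_summaries=tuple(free), total_summaries=tuple(total),
        )
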