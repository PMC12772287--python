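"""Adsorption kinetics: first-order rate-constant estimation.

Free phage adsorbing to excess host cells decay as

    P(t) = P0 * exp(-k * N * t)

with N the host concentration (CFU/mL) and k the adsorption rate constant
(mL/min).  The estimator plots the fraction of free phage remaining,
Pt/P0, against time, fits the natural-log-transformed fractions by ordinary
least squares over a configured time window, and reports

    k    = -slope / N        k_se = slope_se / N

(optionally adding a relative uncertainty on N in quadrature).  The
pointwise closed form k = -ln(Pt/P0) / (N t) is also provided for
single-timepoint checks.

The :class:`AdsorptionModel` composes the whole chain — plate counts ->
Poisson-weighted timepoint summaries (with the jackknife screen) ->
free-fraction series -> ln-linear fit — in the model/results idiom:
``AdsorptionModel.from_csv(...).fit()`` returns an
:class:`AdsorptionResults` with estimates, standard errors and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import ExperimentConfig
from .enumeration import TimepointSummary, summarize_series
from .exceptions import DomainError, InsufficientDataError
from .observations import PlateObservation, observations_from_dataframe, \
    read_counts_table, split_conditions
from .uncertainty import Uncertain
from .welch import WelchResult, welch_tsum

__all__ = [
    "AdsorptionResults",
    "AdsorptionModel",
    "free_fraction_series",
    "fit_adsorption_constant",
    "pointwise_k",
    "compare_k",
]


@dataclass(frozen=True)
class AdsorptionResults:
    """Fitted adsorption rate constant with fit provenance.

    k and k_se are in mL/min; slope and slope_se are the ln(Pt/P0)-vs-t
    regression coefficients in 1/min.
    """

    k: float
    k_se: float
    slope: float
    slope_se: float
    intercept: float
    n_points: int
    fit_window: Tuple[float, float]
    host_N: float
    weighted_fit: bool = False
    experiment_id: Optional[str] = None
    medium: Optional[str] = None
    series: Tuple[Tuple[float, Uncertain], ...] = ()
    summaries: Tuple[TimepointSummary, ...] = ()

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "medium": self.medium,
            "k": self.k,
            "k_se": self.k_se,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "n_points": self.n_points,
            "fit_window": list(self.fit_window),
            "host_N": self.host_N,
            "weighted_fit": self.weighted_fit,
        }

    def summary(self) -> str:
        cond = " / ".join(x for x in (self.experiment_id, self.medium) if x)
        lines = [
            "Adsorption kinetics fit" + (f" [{cond}]" if cond else ""),
            "=" * 46,
            f"  model            ln(Pt/P0) = a + slope * t",
            f"  fit window       {self.fit_window[0]:g}-{self.fit_window[1]:g} min"
            f"  ({self.n_points} timepoints)",
            f"  slope            {self.slope:.4e} ± {self.slope_se:.2e} 1/min",
            f"  intercept        {self.intercept:.4f}",
            f"  host N           {self.host_N:.3e} CFU/mL",
            f"  k = -slope/N     {self.k:.4e} ± {self.k_se:.2e} mL/min",
            f"  weighted fit     {self.weighted_fit}",
        ]
        return "\n".join(lines)


def free_fraction_series(free_summaries: Sequence[TimepointSummary],
                         cfg: ExperimentConfig,
                         t0: Optional[float] = None,
                         ) -> List[Tuple[float, Uncertain]]:
    """Build the free-phage fraction series Pt/P0 from timepoint summaries.

    P0 is the weighted mean at the earliest summarized time.  Each element
    carries a first-order-propagated sigma (P0 and Pt treated as
    independent, so the t0 element is 1 with a nonzero propagated sigma).

    Parameters
    ----------
    t0 : optional expected initial time; if given and the earliest summary
        is not at t0, raise (no P0 available).
    """
    summaries = sorted(free_summaries, key=lambda s: s.time_min)
    if not summaries:
        raise InsufficientDataError("no free-phage summaries: no P0")
    if t0 is not None and summaries[0].time_min != t0:
        raise InsufficientDataError(
            f"no P0: earliest quantitative summary is at t={summaries[0].time_min:g},"
            f" expected t0={t0:g}")
    p0 = Uncertain(summaries[0].weighted_mean, summaries[0].weighted_sd)
    series = []
    for s in summaries:
        pt = Uncertain(s.weighted_mean, s.weighted_sd)
        series.append((s.time_min, pt / p0))
    return series


def fit_adsorption_constant(series: Sequence[Tuple[float, Uncertain]],
                            cfg: ExperimentConfig,
                            window: Optional[Tuple[float, float]] = None,
                            weighted: bool = False) -> AdsorptionResults:
    """Fit k from a free-fraction series by ln-linear least squares.

    Points with time inside ``window`` (default ``cfg.adsorption_fit_window``,
    inclusive) enter the fit.  ``weighted=True`` uses WLS with weights
    1/sigma_ln^2 instead of the default unweighted OLS.
    """
    window = tuple(window) if window is not None else cfg.adsorption_fit_window
    lo, hi = window
    in_window = [(t, u) for t, u in series if lo <= t <= hi]
    if len(in_window) < 2:
        raise InsufficientDataError(
            f"need >= 2 points in fit window [{lo:g}, {hi:g}], got {len(in_window)}")
    for t, u in in_window:
        if u.value <= 0:
            raise DomainError(f"non-positive free fraction {u.value!r} at t={t:g}")

    times = np.array([t for t, _ in in_window], dtype=float)
    logs = np.array([math.log(u.value) for _, u in in_window], dtype=float)
    X = sm.add_constant(times)
    with np.errstate(divide="ignore", invalid="ignore"):  # 2-point fits have no residual df
        if weighted:
            sig_ln = np.array([max(u.sigma / u.value, 1e-300) for _, u in in_window])
            res = sm.WLS(logs, X, weights=1.0 / sig_ln**2).fit()
        else:
            res = sm.OLS(logs, X).fit()
        intercept, slope = res.params
        slope_se = float(res.bse[1])
    if not math.isfinite(slope_se):  # two-point fit: no residual df
        slope_se = 0.0

    N = cfg.host_concentration_N
    k = -slope / N
    k_se = slope_se / N
    if cfg.host_N_sigma > 0 and k != 0:
        # optional uncertainty on N, in quadrature on the relative scale
        rel = math.hypot(slope_se / abs(slope) if slope != 0 else 0.0,
                         cfg.host_N_sigma / N)
        k_se = abs(k) * rel
    return AdsorptionResults(
        k=float(k), k_se=float(k_se),
        slope=float(slope), slope_se=slope_se,
        intercept=float(intercept),
        n_points=len(in_window), fit_window=(float(lo), float(hi)),
        host_N=N, weighted_fit=weighted,
        series=tuple(series),
    )


def pointwise_k(Pt: Uncertain, P0: Uncertain, N: float, t: float) -> Uncertain:
    """Closed-form k = -ln(Pt/P0) / (N t) with propagated sigma."""
    if t == 0:
        raise DomainError("pointwise k undefined at t = 0")
    if N <= 0:
        raise DomainError("host concentration N must be > 0")
    return -(Pt / P0).log() / (N * t)


def compare_k(fit_a: AdsorptionResults, fit_b: AdsorptionResults,
              n_a: int, n_b: int) -> WelchResult:
    """Welch comparison of two fitted rate constants, (k, k_se) as (mean, SD).

    The n values are caller-supplied (the fit itself has no natural sample
    size for the summary t-test) and are recorded in the result.
    """
    return welch_tsum(fit_a.k, fit_a.k_se, n_a, fit_b.k, fit_b.k_se, n_b)


class AdsorptionModel:
    """Adsorption-assay analysis for a single experimental condition.

    Parameters
    ----------
    observations : plate counts for one (experiment_id, medium) condition,
        free fraction; total-fraction rows are ignored by the fit.
    config : :class:`ExperimentConfig`.

    Examples
    --------
    >>> model = AdsorptionModel.from_csv("counts.csv", ExperimentConfig())
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, observations: Sequence[PlateObservation],
                 config: ExperimentConfig):
        conditions = split_conditions(observations)
        if len(conditions) != 1:
            raise ValueError(
                f"AdsorptionModel handles one condition; got {len(conditions)}."
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
        """Per-timepoint weighted summaries for the free fraction."""
        series = summarize_series(self.observations, self.config, screen=screen)
        key = (self.experiment_id, self.medium, "free")
        return series.get(key, [])

    def fit(self, window: Optional[Tuple[float, float]] = None,
            weighted: bool = False, screen: bool = True) -> AdsorptionResults:
        """Run the full chain and return fitted results."""
        pairs = self.summarize(screen=screen)
        summaries = [s for s, _ in pairs if s is not None]
        attempted_times = sorted({o.time_min for o in self.observations
                                  if o.phage_fraction == "free"})
        t0 = attempted_times[0] if attempted_times else None
        series = free_fraction_series(summaries, self.config, t0=t0)
        res = fit_adsorption_constant(series, self.config, window=window,
                                      weighted=weighted)
        return AdsorptionResults(
            **{**res.to_dict(),
               "experiment_id": self.experiment_id, "medium": self.medium,
               "fit_window": tuple(res.fit_window)},
            series=res.series,
            summaries=tuple(summaries),
        )
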