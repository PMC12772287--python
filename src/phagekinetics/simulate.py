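"""Generative twin of the plaque assays: synthetic plaque-count tables.

The simulators produce tables in the canonical schema with exactly the
statistical structure the analysis assumes, so every pipeline stage can be
verified by parameter recovery without external data:

* **Adsorption**: expected free titer C(t) = P0 * exp(-k_true * N * t);
  each (time, replicate, dilution) plate draws a Poisson count with mean
  lambda = C(t) * plated_volume / dilution.
* **One-step growth**: a deterministic lysed-fraction ramp
  r(t) = 0 before the latent period, rising linearly to 1 over
  ``rise_min`` minutes (a step when rise_min = 0), with

      free(t)  = F0 + B_true * I0 * r(t)
      total(t) = free(t) + I0 * (1 - r(t))

  so that pre-burst E[total] - E[free] = I0 exactly and both curves
  converge to F0 + B_true * I0 at the plateau.

Counts at or above ``tntc_cutoff`` are emitted as TNTC; zero draws are
emitted as zero counts — the two censoring modes the enumeration stage must
handle.  Default study conditions: N = 1e8 CFU/mL hosts at MOI 0.1,
triplicate cultures, two sequential tenfold dilutions per sample, 10 µL
plated.  ``dilution_factors="auto"`` picks, per timepoint, the smallest
power-of-ten dilution with expected count <= 300 plus the next tenfold
dilution — the bench serial-dilution choice that lands the better plate in
the countable 30-300 range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .exceptions import ConfigurationError, SchemaError
from .observations import PlateObservation

__all__ = [
    "AdsorptionSimConfig",
    "OneStepSimConfig",
    "simulate_adsorption",
    "simulate_onestep",
    "expected_free_titer",
    "expected_onestep_titers",
    "auto_dilutions",
    "recovery_report",
]

Dilutions = Union[str, Tuple[float, ...]]

_MAX_LAMBDA = 1e9


def auto_dilutions(expected_titer: float, plated_volume_ml: float,
                   target_max: float = 300.0) -> Tuple[float, float]:
    """Two sequential tenfold dilutions for an expected titer.

    The first is the smallest power of ten >= 1 that brings the expected
    plate count to <= ``target_max``; the second is tenfold deeper.
    """
    expected_count = expected_titer * plated_volume_ml
    if expected_count <= target_max:
        d1 = 1.0
    else:
        d1 = 10.0 ** math.ceil(math.log10(expected_count / target_max))
    return d1, 10.0 * d1


@dataclass(frozen=True)
class AdsorptionSimConfig:
    """Study conditions for a simulated adsorption assay.

    Defaults mirror a rich-medium assay: hosts at N = 1e8 CFU/mL, phage at
    MOI 0.1 (P0 = 1e7 PFU/mL), sampling every minute over 0-10 min,
    triplicates, two sequential dilutions chosen automatically, 10 µL
    plated, TNTC above 400 plaques/plate.
    """

    k_true: float = 2e-9
    N: float = 1e8
    P0: float = 1e7
    sample_times: Tuple[float, ...] = tuple(float(t) for t in range(0, 11))
    dilution_factors: Dilutions = "auto"
    plated_volume_ml: float = 0.01
    n_replicates: int = 3
    tntc_cutoff: int = 400
    seed: int = 0
    experiment_id: str = "sim_adsorption"
    medium: str = "PYCa"

    def __post_init__(self):
        if self.k_true < 0:
            raise ConfigurationError("k_true must be >= 0")
        if self.N <= 0 or self.P0 <= 0:
            raise ConfigurationError("N and P0 must be > 0")
        if any(t < 0 for t in self.sample_times):
            raise ConfigurationError("sample times must be >= 0")
        _validate_common(self)


@dataclass(frozen=True)
class OneStepSimConfig:
    """Study conditions for a simulated one-step growth assay.

    Defaults mirror a rich-medium one-step curve post hundredfold transfer:
    residual free phage F0 = 1e5 PFU/mL, infected cells I0 = 1e6 /mL,
    latent period 28 min, 20-min rise to plateau, burst size 117.
    """

    F0: float = 1e5
    I0: float = 1e6
    latent_min: float = 28.0
    rise_min: float = 20.0
    B_true: float = 117.0
    sample_times: Tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0,
                                       35.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)
    dilution_factors: Dilutions = "auto"
    plated_volume_ml: float = 0.01
    n_replicates: int = 3
    tntc_cutoff: int = 400
    seed: int = 0
    experiment_id: str = "sim_onestep"
    medium: str = "PYCa"

    def __post_init__(self):
        if self.B_true < 0:
            raise ConfigurationError("B_true must be >= 0")
        if self.latent_min < 0 or self.rise_min < 0:
            raise ConfigurationError("latent_min and rise_min must be >= 0")
        if self.F0 < 0 or self.I0 <= 0:
            raise ConfigurationError("F0 must be >= 0 and I0 > 0")
        if any(t < 0 for t in self.sample_times):
            raise ConfigurationError("sample times must be >= 0")
        _validate_common(self)


def _validate_common(cfg):
    if cfg.plated_volume_ml <= 0:
        raise ConfigurationError("plated_volume_ml must be > 0")
    if cfg.n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if cfg.tntc_cutoff < 1:
        raise ConfigurationError("tntc_cutoff must be >= 1")
    if isinstance(cfg.dilution_factors, str):
        if cfg.dilution_factors != "auto":
            raise ConfigurationError(
                'dilution_factors must be "auto" or a sequence of fold-dilutions')
    else:
        if any(d < 1 for d in cfg.dilution_factors):
            raise ConfigurationError("dilution factors must be >= 1")


def expected_free_titer(cfg: AdsorptionSimConfig, t: float) -> float:
    """Noise-free expected free-phage titer C(t) = P0 exp(-k N t)."""
    return cfg.P0 * math.exp(-cfg.k_true * cfg.N * t)


def lysed_fraction(cfg: OneStepSimConfig, t: float) -> float:
    """Deterministic lysed fraction r(t): 0 before the latent period, a
    linear ramp over ``rise_min`` minutes after (a step when rise_min = 0)."""
    if t < cfg.latent_min:
        return 0.0
    if cfg.rise_min == 0:
        return 1.0
    return min(1.0, (t - cfg.latent_min) / cfg.rise_min)


def expected_onestep_titers(cfg: OneStepSimConfig, t: float) -> Tuple[float, float]:
    """Noise-free expected (free, total) titers at time t.

    Pre-burst: free = F0 and total = F0 + I0 exactly; at the plateau both
    converge to F0 + B_true * I0.
    """
    r = lysed_fraction(cfg, t)
    free = cfg.F0 + cfg.B_true * cfg.I0 * r
    total = free + cfg.I0 * (1.0 - r)
    return free, total


def _dilutions_for(cfg, titer: float) -> Sequence[float]:
    if isinstance(cfg.dilution_factors, str):
        return auto_dilutions(titer, cfg.plated_volume_ml)
    return tuple(cfg.dilution_factors)


def _plate(rng: np.random.Generator, cfg, titer: float, *, experiment_id,
           medium, replicate_id, time_min, fraction) -> List[PlateObservation]:
    """Plate one sample at its two sequential dilutions with Poisson noise."""
    out = []
    for d in _dilutions_for(cfg, titer):
        lam = titer * cfg.plated_volume_ml / d
        if lam > _MAX_LAMBDA:
            raise ConfigurationError(
                f"expected plate count {lam:.3g} overflows; use a larger dilution")
        count = int(rng.poisson(lam))
        tntc = count >= cfg.tntc_cutoff
        out.append(PlateObservation(
            experiment_id=experiment_id, medium=medium,
            replicate_id=replicate_id, time_min=float(time_min),
            phage_fraction=fraction, dilution_factor=float(d),
            plated_volume_ml=cfg.plated_volume_ml,
            plaque_count=None if tntc else count, tntc=tntc))
    return out


def simulate_adsorption(cfg: AdsorptionSimConfig,
                        rng: Optional[np.random.Generator] = None,
                        ) -> List[PlateObservation]:
    """Simulate a free-phage adsorption assay as plate observations.

    Deterministic under a fixed ``cfg.seed`` (unless an explicit ``rng``
    is supplied, e.g. by a recovery harness driving many runs).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    obs: List[PlateObservation] = []
    for t in cfg.sample_times:
        titer = expected_free_titer(cfg, t)
        for rep in range(1, cfg.n_replicates + 1):
            obs.extend(_plate(rng, cfg, titer,
                              experiment_id=cfg.experiment_id, medium=cfg.medium,
                              replicate_id=f"R{rep}", time_min=t,
                              fraction="free"))
    return obs


def simulate_onestep(cfg: OneStepSimConfig,
                     rng: Optional[np.random.Generator] = None,
                     ) -> List[PlateObservation]:
    """Simulate a one-step growth assay (free and total series)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    obs: List[PlateObservation] = []
    for t in cfg.sample_times:
        free, total = expected_onestep_titers(cfg, t)
        for rep in range(1, cfg.n_replicates + 1):
            for fraction, titer in (("free", free), ("total", total)):
                obs.extend(_plate(rng, cfg, titer,
                                  experiment_id=cfg.experiment_id,
                                  medium=cfg.medium,
                                  replicate_id=f"R{rep}", time_min=t,
                                  fraction=fraction))
    return obs


def recovery_report(truth: dict, estimates: Sequence[dict],
                    z: float = 1.96) -> dict:
    """Parameter-recovery summary over repeated simulated analyses.

    Parameters
    ----------
    truth : mapping of parameter name -> true value.
    estimates : one mapping per seed, parameter name -> (estimate, se);
        a bare number is accepted as (estimate, nan) and excluded from
        coverage.
    z : half-width multiplier for the coverage interval (est ± z·se).

    Returns
    -------
    dict per parameter with ``bias`` (mean estimate minus truth),
    ``median_relative_error`` (median |est - true| / |true|), ``coverage``
    (fraction of intervals containing the truth), and ``n``.
    """
    if len(estimates) < 2:
        raise SchemaError("recovery_report needs >= 2 estimate sets")
    report = {}
    for name, true_value in truth.items():
        vals, ses = [], []
        for i, est in enumerate(estimates):
            if set(est) != set(truth):
                raise SchemaError(
                    f"estimate set {i} parameters {sorted(est)} != truth"
                    f" parameters {sorted(truth)}")
            entry = est[name]
            if isinstance(entry, (tuple, list)):
                v, s = entry
            else:
                v, s = entry, float("nan")
            vals.append(float(v))
            ses.append(float(s))
        vals_a = np.asarray(vals)
        ses_a = np.asarray(ses)
        rel = np.abs(vals_a - true_value) / abs(true_value) if true_value != 0 \
            else np.abs(vals_a)
        with_se = ~np.isnan(ses_a)
        coverage = (float(np.mean(
            np.abs(vals_a[with_se] - true_value) <= z * ses_a[with_se]))
            if with_se.any() else None)
        report[name] = {
            "true": float(true_value),
            "n": len(vals),
            "bias": float(np.mean(vals_a) - true_value),
            "median_relative_error": float(np.median(rel)),
            "coverage": coverage,
        }
    return report
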