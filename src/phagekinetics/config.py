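"""Experiment configuration: the constants of a plaque-count analysis.

The configuration collects everything the analysis needs beyond the raw
plate counts: the host cell concentration N (CFU/mL) that converts a fitted
decay slope into an adsorption rate constant, the target multiplicity of
infection, the time windows used for fitting / baseline / plateau
aggregation, and the counting-statistics thresholds (Poisson sigma floor,
CV trigger, jackknife thresholds).

Defaults encode the analysis conventions this package implements: a sigma
floor of 1.2 counts, a weighted-CV screen trigger of 0.8 with at least 4 of
6 quantitative measurements, dual jackknife thresholds of 0.5, and a
hundredfold transfer dilution for one-step growth assays.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Tuple

import yaml

from .exceptions import ConfigurationError

__all__ = ["ExperimentConfig", "load_config"]

_SD_CONVENTIONS = ("normalized", "frequency")


@dataclass(frozen=True)
class ExperimentConfig:
    """Experimental constants and statistical thresholds.

    Attributes
    ----------
    host_concentration_N : float
        Host cell density N in CFU/mL during adsorption (typically ~1e8).
    moi : float
        Target multiplicity of infection (phage per cell), dimensionless.
    adsorption_fit_window : (float, float)
        [t_lo, t_hi] in minutes over which ln(Pt/P0) is fitted.
    baseline_window : (float, float)
        Minutes defining the pre-burst baseline of a one-step curve.
    plateau_window : (float, float)
        Minutes defining the post-burst plateau of a one-step curve.
    transfer_dilution : float
        Fold-dilution applied after adsorption in one-step assays (100).
    tntc_cutoff : int
        Plaques/plate above which the simulator censors a plate as TNTC.
        Real tables mark TNTC explicitly; this only drives simulation.
    sigma_floor : float
        Minimum count-scale uncertainty (counts); the Poisson sqrt(c)
        uncertainty is floored at this value before scaling to PFU/mL.
    cv_threshold : float
        Weighted CV above which the jackknife outlier screen is triggered.
    jackknife_threshold : float
        Dual threshold on both relative jackknife shifts (mean and SD);
        a measurement is an outlier only if it strictly exceeds both.
    min_quantitative : int
        Minimum quantitative measurements required to run the screen.
    onset_z : float
        z multiplier for latent-period onset detection (baseline + z·SD).
    sd_convention : str
        Weighted-SD convention: "normalized" rescales weights to sum to n
        and divides by n-1 (weight-scale invariant); "frequency" treats
        weights as frequencies and divides by (sum of weights) - 1.
    host_N_sigma : float
        Optional standard uncertainty on N, propagated into k_se in
        quadrature; 0 treats N as exact.
    """

    host_concentration_N: float = 1e8
    moi: float = 0.1
    adsorption_fit_window: Tuple[float, float] = (0.0, 10.0)
    baseline_window: Tuple[float, float] = (0.0, 10.0)
    plateau_window: Tuple[float, float] = (60.0, 90.0)
    transfer_dilution: float = 100.0
    tntc_cutoff: int = 400
    sigma_floor: float = 1.2
    cv_threshold: float = 0.8
    jackknife_threshold: float = 0.5
    min_quantitative: int = 4
    onset_z: float = 2.0
    sd_convention: str = "normalized"
    host_N_sigma: float = 0.0

    def __post_init__(self):
        if self.host_concentration_N <= 0:
            raise ConfigurationError("host_concentration_N must be > 0")
        if self.moi <= 0:
            raise ConfigurationError("moi must be > 0")
        for name in ("adsorption_fit_window", "baseline_window", "plateau_window"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name}: t_lo {lo} > t_hi {hi}")
            object.__setattr__(self, name, (float(lo), float(hi)))
        for name in ("transfer_dilution", "sigma_floor", "cv_threshold",
                     "jackknife_threshold", "onset_z"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.tntc_cutoff < 1:
            raise ConfigurationError("tntc_cutoff must be >= 1")
        if self.min_quantitative < 1:
            raise ConfigurationError("min_quantitative must be >= 1")
        if self.sd_convention not in _SD_CONVENTIONS:
            raise ConfigurationError(
                f"sd_convention must be one of {_SD_CONVENTIONS}")
        if self.host_N_sigma < 0:
            raise ConfigurationError("host_N_sigma must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("adsorption_fit_window", "baseline_window", "plateau_window"):
            d[name] = list(d[name])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        # YAML 1.1 leaves exponent notation without a signed exponent (1.0e8)
        # as a string; coerce scalars to their field types explicitly
        for name, value in list(kwargs.items()):
            try:
                if name in ("adsorption_fit_window", "baseline_window",
                            "plateau_window"):
                    kwargs[name] = tuple(float(x) for x in value)
                elif name in ("tntc_cutoff", "min_quantitative"):
                    kwargs[name] = int(value)
                elif name != "sd_convention":
                    kwargs[name] = float(value)
            except (TypeError, ValueError) as err:
                raise ConfigurationError(f"config key {name}: {err}") from err
        return cls(**kwargs)


def load_config(path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML file.

    Missing keys take the package defaults; unknown keys are an error.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return ExperimentConfig.from_dict(raw)
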