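"""Shared fixtures: configs and hand-built deterministic plaque tables."""

import pytest

from phagekinetics import ExperimentConfig, PlateObservation


@pytest.fixture
def cfg():
    """Default analysis configuration (N = 1e8 CFU/mL)."""
    return ExperimentConfig()


def obs(time, fraction, dilution, count, *, rep="R1", tntc=False,
        exp="E1", medium="PYCa", volume=0.01):
    """Terse PlateObservation builder for hand-built tables."""
    return PlateObservation(
        experiment_id=exp, medium=medium, replicate_id=rep,
        time_min=float(time), phage_fraction=fraction,
        dilution_factor=float(dilution), plated_volume_ml=volume,
        plaque_count=None if tntc else count, tntc=tntc)


def _six(time, fraction, spec_list):
    """Six measurements at one timepoint: [(rep, dilution, count), ...]."""
    return [obs(time, fraction, d, c, rep=r) for r, d, c in spec_list]


@pytest.fixture
def onestep_table():
    """Deterministic one-step growth table with known truth.

    Free phage: flat at 1e5 PFU/mL through 10 min, burst onset at 28 min,
    plateau 1.17e8 PFU/mL from 60 min.  Total phage: 1.1e6 at t0 (so
    I0 = 1e6 /mL and B = 117 exactly).  Three total-phage timepoints
    (28, 60, 90 min) each carry one engineered influential outlier (a
    single plate ~50x the concordant value with comparable Poisson weight)
    that the dual-criterion jackknife screen must flag — and nothing else.
    """
    rows = []
    # free series: counts chosen so every plate at a timepoint implies the
    # same titer (zero weighted SD -> exact downstream arithmetic)
    for t in (0.0, 10.0):
        rows += _six(t, "free", [("R1", 10, 100), ("R1", 100, 10),
                                 ("R2", 10, 100), ("R2", 100, 10),
                                 ("R3", 10, 100), ("R3", 100, 10)])  # 1e5
    rows += _six(28.0, "free", [("R1", 1e3, 50), ("R1", 1e4, 5),
                                ("R2", 1e3, 50), ("R2", 1e4, 5),
                                ("R3", 1e3, 50), ("R3", 1e4, 5)])  # 5e6
    rows += _six(45.0, "free", [("R1", 1e4, 50), ("R1", 1e5, 5),
                                ("R2", 1e4, 50), ("R2", 1e5, 5),
                                ("R3", 1e4, 50), ("R3", 1e5, 5)])  # 5e7
    for t in (60.0, 90.0):
        rows += _six(t, "free", [("R1", 1e4, 117), ("R1", 5e3, 234),
                                 ("R2", 1e4, 117), ("R2", 5e3, 234),
                                 ("R3", 1e4, 117), ("R3", 5e3, 234)])  # 1.17e8

    # total series: 1.1e6 at t0/t10; outlier plates at 28, 60, 90 min
    for t in (0.0, 10.0):
        rows += _six(t, "total", [("R1", 100, 110), ("R1", 50, 220),
                                  ("R2", 100, 110), ("R2", 50, 220),
                                  ("R3", 100, 110), ("R3", 50, 220)])  # 1.1e6
    rows += _six(28.0, "total", [("R1", 1e3, 50), ("R1", 2e3, 25),
                                 ("R2", 1e3, 50), ("R2", 2e3, 25),
                                 ("R3", 1e3, 50), ("R3", 1e5, 25)])  # 5e6 + outlier 2.5e8
    rows += _six(45.0, "total", [("R1", 1e4, 60), ("R1", 5e3, 120),
                                 ("R2", 1e4, 60), ("R2", 5e3, 120),
                                 ("R3", 1e4, 60), ("R3", 5e3, 120)])  # 6e7
    for t in (60.0, 90.0):
        rows += _six(t, "total", [("R1", 1e4, 117), ("R1", 9e3, 130),
                                  ("R2", 1e4, 117), ("R2", 9e3, 130),
                                  ("R3", 1e4, 117), ("R3", 5e5, 117)])  # 1.17e8 + outlier 5.85e9
    return rows


@pytest.fixture
def onestep_cfg():
    """Analysis windows matching the hand-built one-step table."""
    return ExperimentConfig(baseline_window=(0.0, 10.0),
                            plateau_window=(60.0, 90.0))
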