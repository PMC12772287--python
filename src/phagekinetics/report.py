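"""Full-analysis assembly: pipelines and the machine-readable report.

One report schema serves both assays; sections that do not apply are null,
never omitted.  The report echoes the configuration actually used (so it is
self-describing), carries every per-timepoint summary, and ledgers every
jackknifed measurement with both influence statistics, so each reported
number is traceable to raw rows by plate identifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .adsorption import AdsorptionModel, AdsorptionResults, compare_k
from .config import ExperimentConfig, load_config
from .enumeration import ConcentrationEstimate, TimepointSummary
from .observations import read_counts_table, split_conditions
from .onestep import OneStepModel, OneStepResults, compare_burst

__all__ = ["AnalysisReport", "run_adsorption", "run_onestep"]


@dataclass
class AnalysisReport:
    """Assembled analysis outputs for one counts table."""

    assay: str  # "adsorption" | "one_step"
    config: dict
    timepoints: List[dict]
    adsorption_fits: Optional[List[dict]]
    onestep_results: Optional[List[dict]]
    welch_tests: List[dict]
    outlier_ledger: List[dict]
    skipped_timepoints: List[dict]
    version: str = __version__
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "assay": self.assay,
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "timepoints": self.timepoints,
            "adsorption_fits": self.adsorption_fits,
            "onestep_results": self.onestep_results,
            "welch_tests": self.welch_tests,
            "outlier_ledger": self.outlier_ledger,
            "skipped_timepoints": self.skipped_timepoints,
        }

    def write(self, out_dir) -> Tuple[Path, Path]:
        """Write report.json and timepoints.tsv; returns both paths.

        Re-reading the JSON reproduces every value bit-for-bit (floats are
        serialized at full repr precision).
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        json_path = out_dir / "report.json"
        json_path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        tsv_path = out_dir / "timepoints.tsv"
        pd.DataFrame(self.timepoints).to_csv(tsv_path, sep="\t", index=False)
        return json_path, tsv_path

    @classmethod
    def from_json(cls, path) -> "AnalysisReport":
        d = json.loads(Path(path).read_text())
        return cls(
            assay=d["assay"], config=d["config"], timepoints=d["timepoints"],
            adsorption_fits=d["adsorption_fits"],
            onestep_results=d["onestep_results"],
            welch_tests=d["welch_tests"], outlier_ledger=d["outlier_ledger"],
            skipped_timepoints=d["skipped_timepoints"],
            version=d["version"], seed=d["seed"])


def _timepoint_record(condition, fraction, summary: TimepointSummary) -> dict:
    experiment_id, medium = condition
    return {
        "experiment_id": experiment_id,
        "medium": medium,
        "phage_fraction": fraction,
        "time_min": summary.time_min,
        "weighted_mean": summary.weighted_mean,
        "weighted_sd": summary.weighted_sd,
        "weighted_cv": summary.weighted_cv,
        "n_quantitative": summary.n_quantitative,
        "n_attempted": summary.n_attempted,
        "screened": summary.screened,
        "n_flagged": summary.n_flagged,
    }


def _ledger_records(summary: TimepointSummary,
                    estimates: Sequence[ConcentrationEstimate]) -> List[dict]:
    records = []
    if not summary.screened:
        return records
    for est, flag, infl in zip(estimates, summary.outlier_flags,
                               summary.influence):
        if infl is None:
            continue
        records.append({
            "measurement_id": est.source.plate_id if est.source else None,
            "value": est.value,
            "sigma": est.sigma,
            "mean_shift_A": infl[0],
            "sd_shift_B": infl[1],
            "flagged": flag,
        })
    return records


def _collect(model_pairs, condition, fraction, timepoints, ledger, skipped):
    for summary, estimates in model_pairs:
        if summary is None:
            src = next((e.source for e in estimates if e.source is not None), None)
            skipped.append({
                "experiment_id": condition[0], "medium": condition[1],
                "phage_fraction": fraction,
                "time_min": src.time_min if src else None,
                "reason": "no quantitative data",
            })
            continue
        timepoints.append(_timepoint_record(condition, fraction, summary))
        ledger.extend(_ledger_records(summary, estimates))


def _resolve_config(config) -> ExperimentConfig:
    if config is None:
        return ExperimentConfig()
    if isinstance(config, ExperimentConfig):
        return config
    return load_config(config)


def run_adsorption(counts_path, config=None, out_dir=None,
                   window: Optional[Tuple[float, float]] = None,
                   weighted: bool = False,
                   welch_n: Optional[int] = None) -> AnalysisReport:
    """Run the adsorption pipeline on a counts table.

    Executes read -> estimate -> summarize -> jackknife screen ->
    free-fraction -> ln-linear fit per condition, then (when ``welch_n`` is
    given and >= 2 conditions were fitted) pairwise Welch comparisons of the
    fitted k values using the caller-supplied n.

    Parameters
    ----------
    counts_path : canonical-schema CSV/TSV.
    config : ExperimentConfig, path to a YAML config, or None for defaults.
    out_dir : if given, report.json + timepoints.tsv are written there.
    """
    cfg = _resolve_config(config)
    observations = read_counts_table(counts_path)
    timepoints: List[dict] = []
    ledger: List[dict] = []
    skipped: List[dict] = []
    fits: List[AdsorptionResults] = []
    for condition, obs in split_conditions(observations).items():
        model = AdsorptionModel(obs, cfg)
        _collect(model.summarize(), condition, "free", timepoints, ledger, skipped)
        fits.append(model.fit(window=window, weighted=weighted))

    tests = []
    if welch_n is not None and len(fits) >= 2:
        for i in range(len(fits)):
            for j in range(i + 1, len(fits)):
                res = compare_k(fits[i], fits[j], welch_n, welch_n)
                tests.append({
                    "comparison": "k",
                    "group_a": f"{fits[i].experiment_id}/{fits[i].medium}",
                    "group_b": f"{fits[j].experiment_id}/{fits[j].medium}",
                    **res.to_dict()})

    report = AnalysisReport(
        assay="adsorption", config=cfg.to_dict(), timepoints=timepoints,
        adsorption_fits=[f.to_dict() for f in fits], onestep_results=None,
        welch_tests=tests, outlier_ledger=ledger, skipped_timepoints=skipped)
    if out_dir is not None:
        report.write(out_dir)
    return report


def run_onestep(counts_path, config=None, out_dir=None,
                plateau_window: Optional[Tuple[float, float]] = None,
                baseline_window: Optional[Tuple[float, float]] = None,
                welch_n: Optional[int] = None) -> AnalysisReport:
    """Run the one-step growth pipeline on a counts table.

    As :func:`run_adsorption`, with one-step stages: infected-cell
    inference, latent-onset detection, plateau aggregation, burst size,
    and (optionally) pairwise Welch comparisons of burst sizes.
    """
    cfg = _resolve_config(config)
    observations = read_counts_table(counts_path)
    timepoints: List[dict] = []
    ledger: List[dict] = []
    skipped: List[dict] = []
    results: List[OneStepResults] = []
    for condition, obs in split_conditions(observations).items():
        model = OneStepModel(obs, cfg)
        pairs = model.summarize()
        _collect(pairs["free"], condition, "free", timepoints, ledger, skipped)
        _collect(pairs["total"], condition, "total", timepoints, ledger, skipped)
        results.append(model.fit(plateau_window=plateau_window,
                                 baseline_window=baseline_window))

    tests = []
    if welch_n is not None and len(results) >= 2:
        for i in range(len(results)):
            for j in range(i + 1, len(results)):
                res = compare_burst(results[i].burst_size,
                                    results[j].burst_size, welch_n, welch_n)
                tests.append({
                    "comparison": "burst_size",
                    "group_a": f"{results[i].experiment_id}/{results[i].medium}",
                    "group_b": f"{results[j].experiment_id}/{results[j].medium}",
                    **res.to_dict()})

    report = AnalysisReport(
        assay="one_step", config=cfg.to_dict(), timepoints=timepoints,
        adsorption_fits=None,
        onestep_results=[r.to_dict() for r in results],
        welch_tests=tests, outlier_ledger=ledger, skipped_timepoints=skipped)
    if out_dir is not None:
        report.write(out_dir)
    return report
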