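"""Raw plaque-count records and their tabular I/O.

One :class:`PlateObservation` is one plate: a sample from one replicate
culture at one timepoint, of one phage fraction (free = 0.22-µm filtrate;
total = unfiltered, where each infected cell also yields one plaque), at
one fold-dilution, with either an integer plaque count or the TNTC ("too
numerous to count") censoring marker.

Canonical table schema (CSV or TSV, header required)::

    experiment_id, medium, replicate_id, time_min, phage_fraction,
    dilution_factor, plated_volume_ml, plaque_count

``phage_fraction`` is ``free`` or ``total``; ``plaque_count`` is a
non-negative integer or the string ``TNTC`` (case-insensitive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .exceptions import RowValidationError, SchemaError

__all__ = [
    "PlateObservation",
    "REQUIRED_COLUMNS",
    "read_counts_table",
    "observations_to_dataframe",
    "write_counts_table",
    "split_conditions",
]

REQUIRED_COLUMNS = (
    "experiment_id",
    "medium",
    "replicate_id",
    "time_min",
    "phage_fraction",
    "dilution_factor",
    "plated_volume_ml",
    "plaque_count",
)

_FRACTIONS = ("free", "total")


@dataclass(frozen=True)
class PlateObservation:
    """A single raw plaque count on one plate.

    ``plaque_count`` is ``None`` exactly when ``tntc`` is True; the two are
    mutually exclusive representations of the count field.
    """

    experiment_id: str
    medium: str
    replicate_id: str
    time_min: float
    phage_fraction: str
    dilution_factor: float
    plated_volume_ml: float
    plaque_count: Optional[int]
    tntc: bool = False

    def __post_init__(self):
        if self.time_min < 0 or not math.isfinite(self.time_min):
            raise ValueError(f"time_min must be finite and >= 0, got {self.time_min}")
        if self.phage_fraction not in _FRACTIONS:
            raise ValueError(
                f"phage_fraction must be one of {_FRACTIONS}, got {self.phage_fraction!r}")
        if self.dilution_factor < 1:
            raise ValueError(f"dilution_factor must be >= 1, got {self.dilution_factor}")
        if self.plated_volume_ml <= 0:
            raise ValueError(f"plated_volume_ml must be > 0, got {self.plated_volume_ml}")
        if self.tntc:
            if self.plaque_count is not None:
                raise ValueError("TNTC observations carry no numeric count")
        else:
            if self.plaque_count is None:
                raise ValueError("non-TNTC observations need an integer count")
            if not isinstance(self.plaque_count, int) or isinstance(self.plaque_count, bool):
                raise ValueError(f"plaque_count must be an integer, got {self.plaque_count!r}")
            if self.plaque_count < 0:
                raise ValueError(f"plaque_count must be >= 0, got {self.plaque_count}")

    @property
    def plate_id(self) -> str:
        """Human-readable identifier for provenance ledgers."""
        return (f"{self.experiment_id}|{self.medium}|{self.replicate_id}"
                f"|t{self.time_min:g}|{self.phage_fraction}|d{self.dilution_factor:g}")

    @property
    def key(self):
        """Tuple uniquely identifying the plate within a table."""
        return (self.experiment_id, self.medium, self.replicate_id,
                self.time_min, self.phage_fraction, self.dilution_factor)


def _parse_count(raw, row_index: int):
    """Return (count, tntc) from a raw cell value."""
    if isinstance(raw, str):
        text = raw.strip()
        if text.lower() == "tntc":
            return None, True
        try:
            value = float(text)
        except ValueError:
            raise RowValidationError(row_index, f"unparseable plaque_count {raw!r}")
    elif raw is None or (isinstance(raw, float) and math.isnan(raw)):
        raise RowValidationError(row_index, "missing plaque_count")
    else:
        value = float(raw)
    if not value.is_integer():
        raise RowValidationError(row_index, f"non-integer plaque_count {raw!r}")
    if value < 0:
        raise RowValidationError(row_index, f"negative plaque_count {raw!r}")
    return int(value), False


def read_counts_table(path, sep: Optional[str] = None) -> List[PlateObservation]:
    """Read a plaque-count table (CSV/TSV) into validated observations.

    Parameters
    ----------
    path : path to a delimited text file with the canonical header.
    sep : field delimiter; ``None`` sniffs comma vs tab from the extension
        and content.

    Raises
    ------
    SchemaError
        A required column is missing (named in the message).
    RowValidationError
        A row failed validation; the 0-based data-row index is reported.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=[""])
    return observations_from_dataframe(df)


def observations_from_dataframe(df: pd.DataFrame) -> List[PlateObservation]:
    """Validate a DataFrame in the canonical schema into observations.

    Row order is preserved; every row either becomes an observation or
    raises a :class:`RowValidationError` naming the row.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out: List[PlateObservation] = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        count, tntc = _parse_count(rec["plaque_count"], i)
        try:
            obs = PlateObservation(
                experiment_id=str(rec["experiment_id"]),
                medium=str(rec["medium"]),
                replicate_id=str(rec["replicate_id"]),
                time_min=float(rec["time_min"]),
                phage_fraction=str(rec["phage_fraction"]).strip().lower(),
                dilution_factor=float(rec["dilution_factor"]),
                plated_volume_ml=float(rec["plated_volume_ml"]),
                plaque_count=count,
                tntc=tntc,
            )
        except (ValueError, TypeError) as err:
            raise RowValidationError(i, str(err)) from err
        if obs.key in seen:
            raise RowValidationError(i, f"duplicate plate {obs.plate_id}")
        seen.add(obs.key)
        out.append(obs)
    return out


def observations_to_dataframe(observations: Iterable[PlateObservation]) -> pd.DataFrame:
    """Render observations back into the canonical schema."""
    rows = []
    for o in observations:
        rows.append({
            "experiment_id": o.experiment_id,
            "medium": o.medium,
            "replicate_id": o.replicate_id,
            "time_min": o.time_min,
            "phage_fraction": o.phage_fraction,
            "dilution_factor": o.dilution_factor,
            "plated_volume_ml": o.plated_volume_ml,
            "plaque_count": "TNTC" if o.tntc else o.plaque_count,
        })
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_counts_table(observations: Sequence[PlateObservation], path,
                       sep: Optional[str] = None) -> None:
    """Write observations to CSV/TSV in the canonical schema.

    ``read_counts_table(write_counts_table(x)) == x`` for every valid table.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    observations_to_dataframe(observations).to_csv(path, sep=sep, index=False)


def split_conditions(observations: Iterable[PlateObservation]):
    """Group observations by experimental condition (experiment_id, medium).

    Returns an insertion-ordered dict of condition -> list of observations.
    """
    groups: dict = {}
    for o in observations:
        groups.setdefault((o.experiment_id, o.medium), []).append(o)
    return groups
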