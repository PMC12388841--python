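"""Experimental factors, coded/natural transforms and the full-factorial design.

The extraction experiment varies three factors — bath temperature (°C),
sonication time (min) and ethanol fraction of the solvent (%) — each at
three levels, giving a 3x3x3 full factorial of 27 runs.  Response-surface
models are fitted on the *coded* scale, where each factor's low/center/high
levels map to -1/0/+1:

    x = (value - center) / half_range,   half_range = (high - low) / 2

The packaged dataset holds the run-level Total Antioxidant Status (TAS)
response of Paralepista flaccida extracts: per run a triplicate mean
(mmol Trolox equiv./L), its standard deviation and the replicate count.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "Factor",
    "DesignPoint",
    "FactorialDataset",
    "DEFAULT_FACTORS",
    "code_point",
    "decode_point",
    "full_factorial",
    "load_dataset",
    "load_fixture",
    "fixture_path",
]


class DesignError(ValueError):
    """Invalid factor definition, design point or dataset file."""


@dataclass(frozen=True)
class Factor:
    """One controllable extraction variable with its three design levels."""

    name: str
    unit: str
    low: float
    center: float
    high: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.low) and np.isfinite(self.center) and np.isfinite(self.high)):
            raise DesignError(f"factor {self.name!r}: levels must be finite")
        if not (self.low < self.center < self.high):
            raise DesignError(
                f"factor {self.name!r}: levels must satisfy low < center < high, "
                f"got ({self.low}, {self.center}, {self.high})"
            )

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0

    @property
    def levels(self) -> tuple[float, float, float]:
        return (self.low, self.center, self.high)

    def code(self, value: float) -> float:
        if not np.isfinite(value):
            raise DesignError(f"factor {self.name!r}: non-finite value {value!r}")
        return (value - self.center) / self.half_range

    def decode(self, coded: float) -> float:
        if not np.isfinite(coded):
            raise DesignError(f"factor {self.name!r}: non-finite coded value {coded!r}")
        return self.center + coded * self.half_range


#: Factors of the P. flaccida ultrasonic-extraction experiment.
DEFAULT_FACTORS: tuple[Factor, Factor, Factor] = (
    Factor("temperature", "°C", 30.0, 45.0, 60.0),
    Factor("time", "min", 30.0, 45.0, 60.0),
    Factor("ethanol", "%", 0.0, 50.0, 100.0),
)


@dataclass(frozen=True)
class DesignPoint:
    """A single condition in both natural units and coded units."""

    natural: tuple[float, ...]
    coded: tuple[float, ...]


def code_point(factors: Sequence[Factor], natural: Sequence[float]) -> tuple[float, ...]:
    """Map natural-unit values to coded units, one per factor."""
    if len(natural) != len(factors):
        raise DesignError(f"expected {len(factors)} values, got {len(natural)}")
    return tuple(f.code(v) for f, v in zip(factors, natural))


def decode_point(factors: Sequence[Factor], coded: Sequence[float]) -> tuple[float, ...]:
    """Inverse of :func:`code_point`."""
    if len(coded) != len(factors):
        raise DesignError(f"expected {len(factors)} values, got {len(coded)}")
    return tuple(f.decode(v) for f, v in zip(factors, coded))


def make_point(factors: Sequence[Factor], natural: Sequence[float]) -> DesignPoint:
    return DesignPoint(tuple(float(v) for v in natural), code_point(factors, natural))


def full_factorial(factors: Sequence[Factor], levels: int = 3) -> list[DesignPoint]:
    """All level combinations of the given factors.

    Rows are in standard product order: the first factor varies slowest and
    the last factor fastest.  Only three-level factors are supported, since
    the levels are the factors' (low, center, high).
    """
    if levels != 3:
        raise DesignError("only 3-level factors are supported")
    for f in factors:
        if len(set(f.levels)) != 3:
            raise DesignError(f"factor {f.name!r} has duplicate levels {f.levels}")
    points = []
    for combo in itertools.product(*(f.levels for f in factors)):
        points.append(make_point(factors, combo))
    return points


@dataclass
class FactorialDataset:
    """Run-level factorial data: condition, response mean, SD and n per run.

    ``table`` columns: one natural-unit column per factor (factor name), then
    ``response_mean``, ``response_sd``, ``n_rep`` and optionally ``letters``
    (post hoc annotation only, never used in fitting).
    """

    factors: tuple[Factor, ...]
    table: pd.DataFrame
    response_name: str = "tas"
    response_unit: str = "mmol/L"

    def __post_init__(self) -> None:
        for f in self.factors:
            if f.name not in self.table.columns:
                raise DesignError(f"dataset table lacks factor column {f.name!r}")
        for col in ("response_mean", "response_sd", "n_rep"):
            if col not in self.table.columns:
                raise DesignError(f"dataset table lacks column {col!r}")
        if (self.table["response_sd"] < 0).any():
            raise DesignError("negative response_sd")
        if (self.table["n_rep"] < 1).any():
            raise DesignError("n_rep must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def points(self) -> list[DesignPoint]:
        nat = self.natural_matrix()
        return [make_point(self.factors, row) for row in nat]

    @property
    def runs(self) -> list[tuple[DesignPoint, float, float, int]]:
        return [
            (p, float(m), float(s), int(n))
            for p, m, s, n in zip(
                self.points,
                self.table["response_mean"],
                self.table["response_sd"],
                self.table["n_rep"],
            )
        ]

    def natural_matrix(self) -> np.ndarray:
        return self.table[[f.name for f in self.factors]].to_numpy(dtype=float)

    def coded_matrix(self) -> np.ndarray:
        nat = self.natural_matrix()
        centers = np.array([f.center for f in self.factors])
        halves = np.array([f.half_range for f in self.factors])
        return (nat - centers) / halves

    @property
    def response(self) -> np.ndarray:
        return self.table["response_mean"].to_numpy(dtype=float)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "factors": [
                {"name": f.name, "unit": f.unit, "low": f.low, "center": f.center, "high": f.high}
                for f in self.factors
            ],
            "response_name": self.response_name,
            "response_unit": self.response_unit,
            "runs": self.table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


_CSV_COLUMNS = ["temperature_C", "time_min", "ethanol_pct", "tas_mean", "tas_sd", "n"]


def load_dataset(
    path: str | Path,
    factors: Sequence[Factor] = DEFAULT_FACTORS,
) -> FactorialDataset:
    """Read a run-level dataset CSV.

    Expected header: ``temperature_C,time_min,ethanol_pct,tas_mean,tas_sd,n``;
    an optional trailing ``letters`` column is kept as annotation.  Rows with
    duplicate conditions, missing columns or non-numeric cells are rejected
    with the offending row named.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise DesignError(f"{path}: empty dataset file") from exc
    missing = [c for c in _CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise DesignError(f"{path}: missing column(s) {missing}")
    if len(raw) == 0:
        raise DesignError(f"{path}: no data rows")

    numeric = {}
    for col in _CSV_COLUMNS:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna() | raw[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DesignError(f"{path}: non-numeric or missing {col!r} in data row {row + 1}")
        numeric[col] = vals
    frame = pd.DataFrame(
        {
            factors[0].name: numeric["temperature_C"],
            factors[1].name: numeric["time_min"],
            factors[2].name: numeric["ethanol_pct"],
            "response_mean": numeric["tas_mean"],
            "response_sd": numeric["tas_sd"],
            "n_rep": numeric["n"].astype(int),
        }
    )
    if "letters" in raw.columns:
        frame["letters"] = raw["letters"]
    key = frame[[f.name for f in factors]]
    dup = key.duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise DesignError(f"{path}: duplicate condition at data row {row + 1}")
    return FactorialDataset(tuple(factors), frame)


def fixture_path() -> Path:
    """Path of the packaged 27-run P. flaccida TAS dataset."""
    return Path(resources.files("surfopt").joinpath("data/pflaccida_tas.csv"))  # type: ignore[arg-type]


def load_fixture() -> FactorialDataset:
    """The published 27-run TAS table (triplicate means ± SD, n=3 per run)."""
    return load_dataset(fixture_path())
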