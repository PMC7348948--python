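"""Reading and writing trial tables and run configuration.

One table dialect: comma-delimited UTF-8 with a header row and columns
(density, killed, distribution, enemy, replicate), validated strictly with
row numbers preserved in error messages.  Run configuration is YAML.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .core import FRParams
from .errors import InvalidDesignError, TableParseError
from .study import (
    DISTRIBUTIONS,
    ENEMIES,
    REFERENCE_ESTIMATES,
    STUDY_DENSITIES,
    STUDY_DURATION,
    STUDY_REPLICATES,
)
from .tables import COLUMNS, ExperimentTable

__all__ = ["read_trials", "write_trials", "RunConfig", "config_hash"]


def read_trials(path: str | Path, duration: float = STUDY_DURATION) -> ExperimentTable:
    """Read a validated trial table from a CSV file.

    Row numbers in error messages refer to data rows (the first row below
    the header is row 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise TableParseError(f"{path}: could not parse CSV ({exc})") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df.loc[:, list(COLUMNS)]
    for col in ("density", "killed"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 1
            raise TableParseError(f"{path}: row {row}, column '{col}': not a number")
        df[col] = vals.astype(int)
    if (df["density"] < 1).any():
        row = int(df.index[df["density"] < 1][0]) + 1
        raise TableParseError(f"{path}: row {row}, column 'density': must be positive")
    bad = (df["killed"] < 0) | (df["killed"] > df["density"])
    if bad.any():
        row = int(df.index[bad][0]) + 1
        raise TableParseError(f"{path}: row {row}, column 'killed': outside [0, density]")
    for col, allowed in (("distribution", DISTRIBUTIONS), ("enemy", ENEMIES)):
        known = df[col].isin(allowed)
        if not known.all():
            row = int(df.index[~known][0]) + 1
            raise TableParseError(
                f"{path}: row {row}, column '{col}': unknown label {df.loc[row - 1, col]!r}"
            )
    return ExperimentTable(df, duration)


def write_trials(table: ExperimentTable, path: str | Path) -> None:
    """Write a trial table as comma-delimited UTF-8 with header."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.trials.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``cells`` maps (distribution, enemy) to generating/initial FRParams and
    defaults to the published estimates of the emulated cage study.
    """

    duration: float = STUDY_DURATION
    densities: tuple[int, ...] = STUDY_DENSITIES
    replicates: int = STUDY_REPLICATES
    n_boot: int = 2000
    seed: int = 1
    grid_step: float = 1.0
    alpha: float = 0.05
    polynomial_degree: int = 2
    quadrature_nodes: int = 15
    cells: dict[tuple[str, str], FRParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cells:
            self.cells = {
                (dist, enemy): FRParams(ref.attack_rate, ref.handling_time, self.duration)
                for (enemy, dist), ref in REFERENCE_ESTIMATES.items()
            }
        if self.duration <= 0:
            raise InvalidDesignError("duration must be > 0")
        if self.replicates < 1 or self.n_boot < 1:
            raise InvalidDesignError("replicates and n_boot must be >= 1")
        if not 0 < self.alpha < 1:
            raise InvalidDesignError("alpha must be in (0, 1)")
        if self.polynomial_degree not in (1, 2, 3):
            raise InvalidDesignError("polynomial_degree must be 1, 2 or 3")

    def to_dict(self) -> dict[str, Any]:
        return {
            "duration": self.duration,
            "densities": list(self.densities),
            "replicates": self.replicates,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "grid_step": self.grid_step,
            "alpha": self.alpha,
            "polynomial_degree": self.polynomial_degree,
            "quadrature_nodes": self.quadrature_nodes,
            "cells": [
                {
                    "distribution": dist,
                    "enemy": enemy,
                    "attack_rate": p.attack_rate,
                    "handling_time": p.handling_time,
                }
                for (dist, enemy), p in self.cells.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        cells_raw = d.pop("cells", [])
        duration = float(d.get("duration", STUDY_DURATION))
        cells = {
            (c["distribution"], c["enemy"]): FRParams(float(c["attack_rate"]), float(c["handling_time"]), duration)
            for c in cells_raw
        }
        known = {f for f in cls.__dataclass_fields__ if f != "cells"}
        unknown = set(d) - known
        if unknown:
            raise InvalidDesignError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        if "densities" in d:
            d["densities"] = tuple(int(x) for x in d["densities"])
        return cls(cells=cells, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Stable short hash identifying a configuration."""
    payload = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
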