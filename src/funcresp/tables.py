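"""Trial-level containers for functional-response experiments.

A trial is one cage-level observation: an initial prey density, the number
of prey killed (eaten or mummified) after the exposure period, and the
treatment labels.  An :class:`ExperimentTable` wraps a pandas DataFrame of
trials together with the exposure duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidDesignError
from .study import DISTRIBUTIONS, ENEMIES

__all__ = ["Trial", "ExperimentTable", "COLUMNS"]

COLUMNS = ("density", "killed", "distribution", "enemy", "replicate")


@dataclass(frozen=True)
class Trial:
    """One cage-level observation."""

    density: int
    killed: int
    distribution: str
    enemy: str
    replicate: int

    def __post_init__(self) -> None:
        if self.density < 1:
            raise InvalidDesignError(f"density must be positive, got {self.density}")
        if not 0 <= self.killed <= self.density:
            raise InvalidDesignError(f"killed must be in [0, density], got {self.killed} of {self.density}")
        if self.distribution not in DISTRIBUTIONS:
            raise InvalidDesignError(f"unknown distribution label {self.distribution!r}")
        if self.enemy not in ENEMIES:
            raise InvalidDesignError(f"unknown enemy label {self.enemy!r}")


@dataclass
class ExperimentTable:
    """Ordered collection of trials plus the exposure duration.

    ``trials`` is a DataFrame with columns
    (density, killed, distribution, enemy, replicate).
    """

    trials: pd.DataFrame
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidDesignError(f"duration must be > 0, got {self.duration}")
        df = self.trials
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise InvalidDesignError(f"missing column(s): {', '.join(missing)}")
        if len(df) == 0:
            raise InvalidDesignError("experiment table has no trials")
        df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
        df["density"] = df["density"].astype(np.int64)
        df["killed"] = df["killed"].astype(np.int64)
        if (df["density"] < 1).any():
            row = int(df.index[df["density"] < 1][0])
            raise InvalidDesignError(f"row {row}: density must be positive")
        bad = (df["killed"] < 0) | (df["killed"] > df["density"])
        if bad.any():
            row = int(df.index[bad][0])
            raise InvalidDesignError(f"row {row}: killed outside [0, density]")
        for col, allowed in (("distribution", DISTRIBUTIONS), ("enemy", ENEMIES)):
            known = df[col].isin(allowed)
            if not known.all():
                row = int(df.index[~known][0])
                raise InvalidDesignError(f"row {row}: unknown {col} label {df.loc[row, col]!r}")
        self.trials = df

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def densities(self) -> np.ndarray:
        return self.trials["density"].to_numpy()

    @property
    def killed(self) -> np.ndarray:
        return self.trials["killed"].to_numpy()

    def subset(self, distribution: str | None = None, enemy: str | None = None) -> "ExperimentTable":
        """Trials for one treatment cell (either label may be left unrestricted)."""
        df = self.trials
        if distribution is not None:
            df = df[df["distribution"] == distribution]
        if enemy is not None:
            df = df[df["enemy"] == enemy]
        if len(df) == 0:
            raise InvalidDesignError(f"no trials for distribution={distribution!r}, enemy={enemy!r}")
        return ExperimentTable(df.reset_index(drop=True), self.duration)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExperimentTable):
            return NotImplemented
        return self.duration == other.duration and self.trials.equals(other.trials)
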