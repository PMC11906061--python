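"""Right-censored survival data container and delimited-table I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "read_survival_table", "write_survival_table"]


@dataclass
class SurvivalDataset:
    """Observed triplets (t_i, delta_i, x_i) for right-censored survival data.

    Attributes
    ----------
    time : ndarray, shape (n,)
        Observed times (event or censoring), all >= 0.
    event : ndarray, shape (n,)
        Event indicator: 1 = event observed, 0 = right-censored.
    covariates : ndarray, shape (n, J)
        Covariate matrix; J may be 0 for a covariate-free analysis.
    covariate_names : list of str
        Column labels for the covariates.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray = None
    covariate_names: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.covariates is None:
            self.covariates = np.empty((self.time.size, 0))
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.time.size and self.covariates.shape[1] == self.time.size:
            self.covariates = self.covariates.T
        if not self.covariate_names:
            self.covariate_names = [f"x{j+1}" for j in range(self.covariates.shape[1])]
        self._validate()

    def _validate(self):
        n = self.time.size
        if self.event.size != n or self.covariates.shape[0] != n:
            raise ValueError(
                f"component lengths differ: time={n}, event={self.event.size}, "
                f"covariates={self.covariates.shape[0]}"
            )
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise ValueError("covariate_names length does not match covariate columns")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            bad = np.where(~np.isfinite(self.time) | (self.time < 0))[0]
            raise ValueError(f"times must be finite and >= 0; offending rows: {bad.tolist()}")
        ev = np.asarray(self.event, dtype=float)
        if np.any(~np.isin(ev, (0.0, 1.0))):
            bad = np.where(~np.isin(ev, (0.0, 1.0)))[0]
            raise ValueError(
                f"event indicator must be 0 (censored) or 1 (event); offending rows: {bad.tolist()}"
            )
        self.event = ev.astype(int)
        if np.any(~np.isfinite(self.covariates)):
            bad = np.where(~np.isfinite(self.covariates).all(axis=1))[0]
            raise ValueError(f"covariates must be finite; offending rows: {bad.tolist()}")

    # -- conveniences --------------------------------------------------
    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def censoring_fraction(self) -> float:
        return 1.0 - self.event.mean()

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        time: str = "time",
        event: str = "event",
        covariates: Optional[Sequence[str]] = None,
    ) -> "SurvivalDataset":
        missing = [c for c in (time, event) if c not in df.columns]
        if covariates is None:
            covariates = [c for c in df.columns if c not in (time, event)]
        missing += [c for c in covariates if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns in table: {missing}")
        sub = df[[time, event, *covariates]]
        if sub.isna().any().any():
            bad = sub.index[sub.isna().any(axis=1)].tolist()
            raise ValueError(f"rows with missing values: {bad}")
        return cls(
            time=sub[time].to_numpy(dtype=float),
            event=sub[event].to_numpy(),
            covariates=sub[list(covariates)].to_numpy(dtype=float),
            covariate_names=list(covariates),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.time, "event": self.event}
        for j, name in enumerate(self.covariate_names):
            data[name] = self.covariates[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def read_survival_table(
    path,
    time: str = "time",
    event: str = "event",
    covariates: Optional[Sequence[str]] = None,
    sep: Optional[str] = None,
) -> SurvivalDataset:
    """Read a delimited survival table (comma default, tab accepted).

    The header must contain the mapped time and event columns; remaining
    columns are treated as covariates unless an explicit list is given.
    Rows with missing values, non-binary event codes or negative times are
    rejected with the offending row indices in the error message.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    return SurvivalDataset.from_frame(df, time=time, event=event, covariates=covariates)


def write_survival_table(dataset: SurvivalDataset, path, sep: str = ",") -> None:
    dataset.to_csv(path, sep=sep)
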