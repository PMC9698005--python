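"""Longitudinal dataset container and tidy-CSV round-tripping.

The estimation engine consumes group-aggregated longitudinal data: per
observable a set of measurement times (days), group means, SDs and group
sizes.  Two constraint classes are distinguished, mirroring the study design:

* ``longitudinal`` — measured repeatedly per group (plasma lipids, glucose,
  body weight, 24-h fecal outputs);
* ``cross_sectional_group_average`` — terminal flux measurements (VLDL-TG
  production, hepatic de novo lipogenesis, biliary secretion, liver lipids)
  pooled over the whole cohort and therefore identical for both groups.

Tidy CSV schema: group, observable, time_days, mean, sd, n, constraint_class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .model import Model

__all__ = [
    "CONSTRAINT_CLASSES",
    "TIDY_COLUMNS",
    "ObservableSeries",
    "LongitudinalDataset",
    "read_datasets",
    "write_datasets",
]

CONSTRAINT_CLASSES = ("longitudinal", "cross_sectional_group_average")
TIDY_COLUMNS = ("group", "observable", "time_days", "mean", "sd", "n", "constraint_class")

GROUPS = ("responder", "non_responder")


@dataclass
class ObservableSeries:
    """Measurements of one observable for one group."""

    observable: str
    constraint_class: str
    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)

    def validate(self) -> None:
        if self.constraint_class not in CONSTRAINT_CLASSES:
            raise ValidationError(
                f"{self.observable}: unknown constraint class {self.constraint_class!r}"
            )
        if self.observable not in Model.observable_names():
            raise ValidationError(f"unknown observable {self.observable!r}")
        m = len(self.times)
        if not (len(self.mean) == len(self.sd) == len(self.n) == m) or m == 0:
            raise ValidationError(f"{self.observable}: ragged or empty series")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"{self.observable}: time points not strictly increasing")
        if np.any(self.sd < 0):
            raise ValidationError(f"{self.observable}: negative SD")
        if np.any(~np.isfinite(self.mean)) or np.any(~np.isfinite(self.sd)):
            raise ValidationError(f"{self.observable}: non-finite values")


@dataclass
class LongitudinalDataset:
    """All observable series for one phenotype group."""

    group: str
    series: dict[str, ObservableSeries] = field(default_factory=dict)

    def validate(self) -> "LongitudinalDataset":
        if not self.series:
            raise ValidationError("dataset has no observable series")
        for name, s in self.series.items():
            if name != s.observable:
                raise ValidationError(f"series key {name!r} != observable {s.observable!r}")
            s.validate()
        return self

    @property
    def observables(self) -> tuple[str, ...]:
        return tuple(self.series)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.series.values():
            for t, m, sd, n in zip(s.times, s.mean, s.sd, s.n):
                rows.append((self.group, s.observable, t, m, sd, n, s.constraint_class))
        return pd.DataFrame(rows, columns=list(TIDY_COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group: str) -> "LongitudinalDataset":
        missing = [c for c in TIDY_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing column(s): {missing}")
        sub = df[df["group"] == group]
        if sub.empty:
            raise ValidationError(f"no rows for group {group!r}")
        series: dict[str, ObservableSeries] = {}
        for obs, block in sub.groupby("observable", sort=False):
            block = block.sort_values("time_days")
            cls_vals = block["constraint_class"].unique()
            if len(cls_vals) != 1:
                raise ValidationError(f"{obs}: inconsistent constraint_class")
            series[str(obs)] = ObservableSeries(
                observable=str(obs),
                constraint_class=str(cls_vals[0]),
                times=block["time_days"].to_numpy(),
                mean=block["mean"].to_numpy(),
                sd=block["sd"].to_numpy(),
                n=block["n"].to_numpy(),
            )
        return cls(group=group, series=series).validate()


def read_datasets(path) -> dict[str, LongitudinalDataset]:
    """Read a tidy CSV into one dataset per group."""
    df = pd.read_csv(path)
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s): {missing}")
    return {
        str(g): LongitudinalDataset.from_frame(df, str(g))
        for g in df["group"].unique()
    }


def write_datasets(datasets, path) -> None:
    """Write datasets (iterable or dict of LongitudinalDataset) to tidy CSV."""
    if isinstance(datasets, dict):
        datasets = datasets.values()
    pd.concat([d.to_frame() for d in datasets], ignore_index=True).to_csv(
        path, index=False
    )
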