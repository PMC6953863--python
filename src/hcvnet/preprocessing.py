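"""Per-basis input scaling and the train/generalisation holdout split.

Each basis-function family needs its own input range: product units are
scaled to [1, 2] (positive inputs, bounded so large exponents do not blow
up), sigmoid units to [0.1, 0.9] (avoids saturation), and radial basis
functions to [-1, 1] (symmetric about the origin).  The transform is the
usual affine min-max map

    x* = (x - min) / (max - min) * (high - low) + low,

with column minima/maxima captured on the training data only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "TARGET_RANGES",
    "ScalingSpec",
    "SplitResult",
    "fit_scaler",
    "apply_scaler",
    "holdout_split",
    "default_train_size",
]

#: Target scaling range per basis family.
TARGET_RANGES: dict[str, tuple[float, float]] = {
    "PU": (1.0, 2.0),
    "SU": (0.1, 0.9),
    "RBF": (-1.0, 1.0),
}


@dataclass(frozen=True)
class ScalingSpec:
    """Fitted per-column min/max plus the basis-specific target range."""

    columns: tuple[str, ...]
    mins: tuple[float, ...]
    maxs: tuple[float, ...]
    low: float
    high: float
    basis: str

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("target range must satisfy low < high")

    def to_json(self) -> str:
        return json.dumps(
            {
                "basis": self.basis,
                "columns": list(self.columns),
                "mins": list(self.mins),
                "maxs": list(self.maxs),
                "low": self.low,
                "high": self.high,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalingSpec":
        d = json.loads(text)
        return cls(
            columns=tuple(d["columns"]),
            mins=tuple(d["mins"]),
            maxs=tuple(d["maxs"]),
            low=d["low"],
            high=d["high"],
            basis=d["basis"],
        )


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, CohortTable):
        return table.features
    return table


def fit_scaler(table, basis: str) -> ScalingSpec:
    """Capture per-column min/max from training data for the given basis."""
    if basis not in TARGET_RANGES:
        raise ValueError(f"unknown basis {basis!r}; expected one of {sorted(TARGET_RANGES)}")
    df = _as_frame(table)
    if len(df) == 0:
        raise ValueError("cannot fit a scaler on an empty table")
    low, high = TARGET_RANGES[basis]
    return ScalingSpec(
        columns=tuple(df.columns),
        mins=tuple(float(v) for v in df.min()),
        maxs=tuple(float(v) for v in df.max()),
        low=low,
        high=high,
        basis=basis,
    )


def apply_scaler(spec: ScalingSpec, table) -> np.ndarray:
    """Affine per-column transform into [low, high].

    Columns that were constant at fit time map to the range midpoint.
    Values outside the fitted min/max extrapolate linearly (no clipping), so
    a generalisation-set value can fall outside the target range.
    """
    df = _as_frame(table)
    if list(df.columns) != list(spec.columns):
        raise ValueError("column mismatch between scaler and table")
    X = df.to_numpy(dtype=float)
    mins = np.asarray(spec.mins)
    maxs = np.asarray(spec.maxs)
    span = maxs - mins
    out = np.empty_like(X)
    const = span == 0
    mid = 0.5 * (spec.low + spec.high)
    if const.any():
        out[:, const] = mid
    nc = ~const
    out[:, nc] = (X[:, nc] - mins[nc]) / span[nc] * (spec.high - spec.low) + spec.low
    return out


def default_train_size(n: int) -> int:
    """Training-set size for a cohort of ``n`` patients.

    The reference experiment used 2193 of 2940 (74.6%); that literal split
    is reproduced at n = 2940 and its proportion applied elsewhere.
    """
    return 2193 if n == 2940 else int(round(0.746 * n))


@dataclass
class SplitResult:
    """Disjoint train/generalisation partition of a cohort."""

    train: CohortTable
    generalisation: CohortTable
    seed: int
    stratified: bool

    @property
    def train_ids(self) -> np.ndarray:
        return self.train.data.index.to_numpy()

    @property
    def generalisation_ids(self) -> np.ndarray:
        return self.generalisation.data.index.to_numpy()


def holdout_split(
    table: CohortTable, n_train: int, seed: int, stratified: bool = True
) -> SplitResult:
    """Random holdout split, reproducible per seed.

    With ``stratified`` (the default) the class proportions of the training
    partition match the full table to within one patient per class, which
    protects the minimum-sensitivity metric on imbalanced cohorts.
    """
    n = table.n
    if not 0 < n_train < n:
        raise ValueError(f"n_train must lie strictly between 0 and {n}, got {n_train}")
    rng = np.random.default_rng(seed)
    y = table.outcome
    idx = np.arange(n)
    if stratified:
        train_pos: list[np.ndarray] = []
        classes = np.unique(y)
        # largest-remainder allocation so per-class counts sum to n_train
        quotas = np.array([n_train * (y == c).sum() / n for c in classes])
        base = np.floor(quotas).astype(int)
        rem = n_train - base.sum()
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:rem]] += 1
        for c, k in zip(classes, base):
            members = idx[y == c]
            members = members[rng.permutation(len(members))]
            train_pos.append(members[:k])
        train_idx = np.sort(np.concatenate(train_pos))
    else:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    train_df = table.data.iloc[mask]
    gen_df = table.data.iloc[~mask]
    return SplitResult(
        train=CohortTable(train_df, table.schema, table.provenance),
        generalisation=CohortTable(gen_df, table.schema, table.provenance),
        seed=seed,
        stratified=stratified,
    )
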