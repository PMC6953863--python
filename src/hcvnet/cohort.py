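"""Cohort variable schema and synthetic patient generator.

The classification task operates on tabular cohorts of HIV/HCV co-infected
patients described by 17 indicator/ordinal/continuous variables (X1..X17)
plus a binary outcome y (1 = received HCV therapy).  The real cohort
(clinicaltrials.gov NCT02511496) is not public, so this module encodes its
published marginal structure as a :class:`VariableSchema` and samples
synthetic cohorts from it, with a configurable logistic outcome model that
plants a known dependence of treatment uptake on a chosen variable subset.

Variable layout
---------------
==== ================================== ===========================
id   meaning                            encoding
==== ================================== ===========================
X1   met national prioritisation plan   binary (1 = yes)
X2   lifetime PWID                      one-hot group ``pwid``
X3   OST PWID                           one-hot group ``pwid``
X4   recent PWID                        one-hot group ``pwid``
X5   never PWID                         one-hot group ``pwid``
X6   major psychiatric disorder         binary
X7   been in jail                       binary
X8   naive to HCV therapy               one-hot group ``prev_treatment``
X9   prior Peg-IFN/RBV                  one-hot group ``prev_treatment``
X10  prior DAAs/Peg-IFN/RBV             one-hot group ``prev_treatment``
X11  liver fibrosis stage               ordinal 1..4 (F0-F1 .. F4)
X12  gender                             binary (1 = male)
X13  age (years)                        continuous
X14  HCV genotype 1                     one-hot group ``genotype``
X15  HCV genotype 2                     one-hot group ``genotype``
X16  HCV genotype 3                     one-hot group ``genotype``
X17  HCV genotype 4                     one-hot group ``genotype``
==== ================================== ===========================
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

__all__ = [
    "Variable",
    "VariableSchema",
    "CohortTable",
    "OutcomeModel",
    "build_default_schema",
    "default_outcome_model",
    "null_outcome_model",
    "stage_fibrosis",
    "calibrate_intercept",
    "sample_cohort",
    "unit_scale_features",
    "COHORT_SIZE",
]

#: Size of the reference cohort from which the marginal frequencies come.
COHORT_SIZE = 2940


@dataclass(frozen=True)
class Variable:
    """Descriptor of one feature column.

    ``kind`` is one of ``binary``, ``onehot`` (member of a mutually exclusive
    indicator group named by ``group``), ``ordinal`` (integer levels with
    per-level probabilities) or ``continuous`` (truncated-normal law).
    """

    id: str
    name: str
    kind: str
    group: str | None = None
    p: float | None = None
    levels: tuple[int, ...] | None = None
    level_probs: tuple[float, ...] | None = None
    minimum: float | None = None
    maximum: float | None = None
    mean: float | None = None
    sd: float | None = None

    def to_dict(self) -> dict:
        d = {"id": self.id, "name": self.name, "kind": self.kind}
        for k in ("group", "p", "levels", "level_probs", "minimum", "maximum", "mean", "sd"):
            v = getattr(self, k)
            if v is not None:
                d[k] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Variable":
        d = dict(d)
        for k in ("levels", "level_probs"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class VariableSchema:
    """The full 17-feature + outcome layout, with marginal probabilities.

    Invariants are enforced at construction: probabilities lie in [0, 1],
    each one-hot group closes to 1, there are exactly 17 features, and the
    continuous age variable satisfies min < mean < max.
    """

    variables: tuple[Variable, ...]
    outcome_name: str = "y"
    prevalence: float = 0.5

    def __post_init__(self):
        if len(self.variables) != 17:
            raise ValueError(f"expected 17 feature variables, got {len(self.variables)}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("outcome prevalence must lie strictly in (0, 1)")
        for v in self.variables:
            if v.p is not None and not 0.0 <= v.p <= 1.0:
                raise ValueError(f"{v.id}: marginal probability {v.p} outside [0, 1]")
            if v.kind == "ordinal":
                if abs(sum(v.level_probs) - 1.0) > 1e-12:
                    raise ValueError(f"{v.id}: ordinal level probabilities must sum to 1")
            if v.kind == "continuous":
                if not (v.minimum < v.mean < v.maximum):
                    raise ValueError(f"{v.id}: requires min < mean < max")
        for gname, members in self.groups.items():
            s = sum(m.p for m in members)
            if abs(s - 1.0) > 1e-12:
                raise ValueError(f"one-hot group {gname!r} probabilities sum to {s}, not 1")

    @property
    def feature_ids(self) -> list[str]:
        return [v.id for v in self.variables]

    @property
    def groups(self) -> dict[str, list[Variable]]:
        g: dict[str, list[Variable]] = {}
        for v in self.variables:
            if v.kind == "onehot":
                g.setdefault(v.group, []).append(v)
        return g

    def variable(self, var_id: str) -> Variable:
        for v in self.variables:
            if v.id == var_id:
                return v
        raise KeyError(var_id)

    def to_dict(self) -> dict:
        return {
            "variables": [v.to_dict() for v in self.variables],
            "outcome": {"name": self.outcome_name, "prevalence": self.prevalence},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        return cls(
            variables=tuple(Variable.from_dict(v) for v in d["variables"]),
            outcome_name=d["outcome"]["name"],
            prevalence=d["outcome"]["prevalence"],
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "VariableSchema":
        return cls.from_dict(yaml.safe_load(text))


def build_default_schema(age_sd: float = 8.0) -> VariableSchema:
    """Schema with the published cohort marginals (N = 2940).

    Marginal probabilities are the printed occurrence counts over 2940.
    The age dispersion is not published; ``age_sd`` (years) parameterises
    the truncated normal used by the generator.
    """
    N = COHORT_SIZE
    V = Variable
    variables = (
        V("X1", "met prioritisation criteria", "binary", p=1653 / N),
        V("X2", "lifetime PWID", "onehot", group="pwid", p=2169 / N),
        V("X3", "OST PWID", "onehot", group="pwid", p=339 / N),
        V("X4", "recent PWID", "onehot", group="pwid", p=47 / N),
        V("X5", "never PWID", "onehot", group="pwid", p=385 / N),
        V("X6", "major psychiatric disorder", "binary", p=54 / N),
        V("X7", "been in jail", "binary", p=117 / N),
        V("X8", "naive to therapy", "onehot", group="prev_treatment", p=2053 / N),
        V("X9", "prior Peg-IFN/RBV", "onehot", group="prev_treatment", p=725 / N),
        V("X10", "prior DAAs/Peg-IFN/RBV", "onehot", group="prev_treatment", p=162 / N),
        V(
            "X11",
            "liver fibrosis stage",
            "ordinal",
            levels=(1, 2, 3, 4),
            level_probs=(898 / N, 475 / N, 787 / N, 780 / N),
        ),
        V("X12", "male gender", "binary", p=2449 / N),
        V("X13", "age", "continuous", minimum=18.0, maximum=76.0, mean=48.95, sd=age_sd),
        V("X14", "HCV genotype 1", "onehot", group="genotype", p=1741 / N),
        V("X15", "HCV genotype 2", "onehot", group="genotype", p=27 / N),
        V("X16", "HCV genotype 3", "onehot", group="genotype", p=484 / N),
        V("X17", "HCV genotype 4", "onehot", group="genotype", p=688 / N),
    )
    return VariableSchema(variables=variables, prevalence=1952 / N)


# Liver-stiffness (kPa) bands for fibrosis staging.  The published bands
# leave the intervals [8.9, 9.0) and [14.5, 14.6) uncovered; they are closed
# downward (the lower stage wins), which is the conservative choice.
_FIBROSIS_BANDS = ((7.2, "F0-F1"), (9.0, "F2"), (14.6, "F3"))


def stage_fibrosis(lsm_kpa: float) -> str:
    """Map a liver stiffness measurement in kPa to a fibrosis stage label.

    F0-F1 below 7.2 kPa, F2 in [7.2, 9.0), F3 in [9.0, 14.6), F4 from
    14.6 kPa upward.  Together the four stages partition (0, inf).
    """
    if not math.isfinite(lsm_kpa) or lsm_kpa <= 0:
        raise ValueError(f"liver stiffness must be a positive finite kPa value, got {lsm_kpa}")
    for upper, label in _FIBROSIS_BANDS:
        if lsm_kpa < upper:
            return label
    return "F4"


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic outcome model over unit-scaled features.

    ``coef`` maps variable ids to log-odds coefficients (ids absent from the
    map contribute 0); ``intercept`` is on the same log-odds scale.  All
    features are min-max scaled to [0, 1] before entering the linear
    predictor, so coefficients are comparable across binary, ordinal and
    continuous variables.
    """

    coef: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0

    def __post_init__(self):
        for k, v in self.coef.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite coefficient for {k}")
        if not math.isfinite(self.intercept):
            raise ValueError("non-finite intercept")

    def linear_predictor(self, schema: VariableSchema, features: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(features), self.intercept, dtype=float)
        scaled = unit_scale_features(schema, features)
        for var_id, c in self.coef.items():
            if c != 0.0:
                eta += c * scaled[var_id].to_numpy(dtype=float)
        return eta

    def probabilities(self, schema: VariableSchema, features: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(schema, features))

    def to_dict(self) -> dict:
        return {"coef": dict(self.coef), "intercept": self.intercept}

    @classmethod
    def from_dict(cls, d: dict) -> "OutcomeModel":
        return cls(coef=dict(d.get("coef", {})), intercept=float(d.get("intercept", 0.0)))


def unit_scale_features(schema: VariableSchema, features: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each feature column to [0, 1] using schema-implied ranges.

    Binary/one-hot columns are already 0/1; ordinal levels map linearly from
    their first to last level; continuous columns use the schema min/max.
    """
    out = features.copy()
    for v in schema.variables:
        if v.kind == "ordinal":
            lo, hi = v.levels[0], v.levels[-1]
            out[v.id] = (features[v.id] - lo) / (hi - lo)
        elif v.kind == "continuous":
            out[v.id] = (features[v.id] - v.minimum) / (v.maximum - v.minimum)
    return out


@dataclass
class CohortTable:
    """N patients x (17 features + outcome), synthetic or user-supplied.

    ``data`` holds the features in schema order plus the outcome column;
    row identifiers live in the index.
    """

    data: pd.DataFrame
    schema: VariableSchema
    provenance: str = "synthetic"

    def __post_init__(self):
        expected = self.schema.feature_ids + [self.schema.outcome_name]
        if list(self.data.columns) != expected:
            raise ValueError(f"cohort columns {list(self.data.columns)} != schema layout {expected}")
        self.validate()

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.schema.feature_ids]

    @property
    def outcome(self) -> np.ndarray:
        return self.data[self.schema.outcome_name].to_numpy(dtype=int)

    def validate(self) -> None:
        if self.n == 0:
            return
        y = self.data[self.schema.outcome_name]
        if not y.isin([0, 1]).all():
            raise ValueError("outcome values must be 0 or 1")
        for gname, members in self.schema.groups.items():
            ones = self.data[[m.id for m in members]].to_numpy().sum(axis=1)
            if not np.all(ones == 1):
                raise ValueError(f"one-hot group {gname!r} violated: rows without exactly one 1")
        for v in self.schema.variables:
            col = self.data[v.id]
            if v.kind in ("binary", "onehot") and not col.isin([0, 1]).all():
                raise ValueError(f"{v.id}: indicator values must be 0/1")
            if v.kind == "ordinal" and not col.isin(v.levels).all():
                raise ValueError(f"{v.id}: values outside ordinal levels {v.levels}")
            if v.kind == "continuous" and ((col < v.minimum) | (col > v.maximum)).any():
                raise ValueError(f"{v.id}: values outside [{v.minimum}, {v.maximum}]")

    def subset_features(self, feature_ids: list[str]) -> pd.DataFrame:
        return self.data[feature_ids]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="patient_id")

    @classmethod
    def from_csv(cls, path, schema: VariableSchema, provenance: str = "external") -> "CohortTable":
        df = pd.read_csv(path, index_col=0)
        return cls(data=df, schema=schema, provenance=provenance)


def null_outcome_model(schema: VariableSchema) -> OutcomeModel:
    """Outcome independent of all features, at the schema prevalence."""
    return OutcomeModel(coef={}, intercept=float(logit(schema.prevalence)))


def default_outcome_model(
    schema: VariableSchema, seed: int = 0, calibrate: bool = True
) -> OutcomeModel:
    """Planted outcome model with a dominant negative effect of recent PWID.

    Nonzero log-odds coefficients are placed on the six variables that the
    sparse classifiers are expected to discover: OST PWID and therapy-naive
    status raise treatment odds, advanced fibrosis raises them strongly,
    while age, genotype 3 and - dominantly - recent injecting drug use lower
    them.  The intercept is calibrated so the expected prevalence matches
    the schema's treated fraction.
    """
    model = OutcomeModel(
        coef={
            "X3": 1.0,
            "X4": -8.0,
            "X8": 1.0,
            "X11": 1.5,
            "X13": -1.0,
            "X16": -1.0,
        },
        intercept=0.0,
    )
    if calibrate:
        model = calibrate_intercept(model, schema, schema.prevalence, seed=seed)
    return model


def _sample_features(schema: VariableSchema, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    done_groups: set[str] = set()
    for v in schema.variables:
        if v.kind == "binary":
            cols[v.id] = (rng.random(n) < v.p).astype(int)
        elif v.kind == "onehot":
            if v.group in done_groups:
                continue
            members = schema.groups[v.group]
            probs = np.array([m.p for m in members])
            picks = rng.choice(len(members), size=n, p=probs / probs.sum())
            for j, m in enumerate(members):
                cols[m.id] = (picks == j).astype(int)
            done_groups.add(v.group)
        elif v.kind == "ordinal":
            probs = np.array(v.level_probs)
            idx = rng.choice(len(v.levels), size=n, p=probs / probs.sum())
            cols[v.id] = np.array(v.levels)[idx]
        elif v.kind == "continuous":
            a = (v.minimum - v.mean) / v.sd
            b = (v.maximum - v.mean) / v.sd
            cols[v.id] = truncnorm.rvs(a, b, loc=v.mean, scale=v.sd, size=n, random_state=rng)
        else:  # pragma: no cover - schema construction forbids this
            raise ValueError(f"unknown variable kind {v.kind!r}")
    return pd.DataFrame({v.id: cols[v.id] for v in schema.variables})


def sample_cohort(
    schema: VariableSchema, model: OutcomeModel, n: int, seed: int
) -> CohortTable:
    """Draw a synthetic cohort of ``n`` patients.

    One-hot groups come from their multinomial marginals, independent
    binaries from Bernoulli marginals, fibrosis stage from its level
    probabilities, age from the truncated normal, and the outcome from the
    logistic model applied to unit-scaled features.  Identical
    ``(schema, model, n, seed)`` yields a bit-identical table.
    """
    if n < 0:
        raise ValueError("cohort size must be non-negative")
    rng = np.random.default_rng(seed)
    if n == 0:
        empty = pd.DataFrame(
            {c: pd.Series(dtype=float) for c in schema.feature_ids + [schema.outcome_name]}
        )
        return CohortTable(data=empty, schema=schema, provenance="synthetic")
    features = _sample_features(schema, n, rng)
    p = model.probabilities(schema, features)
    y = (rng.random(n) < p).astype(int)
    data = features.copy()
    data[schema.outcome_name] = y
    return CohortTable(data=data, schema=schema, provenance="synthetic")


def calibrate_intercept(
    model: OutcomeModel,
    schema: VariableSchema,
    target_prevalence: float,
    tol: float = 1e-3,
    seed: int = 0,
    n_mc: int = 100_000,
) -> OutcomeModel:
    """Find the intercept whose expected outcome prevalence hits the target.

    The expectation over the feature distribution is estimated once by Monte
    Carlo (``n_mc`` draws, deterministic per ``seed``); the intercept is then
    solved by root finding, which is exact because the expectation is
    strictly increasing in the intercept.  Raises if the achieved prevalence
    misses the target by more than ``tol``.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must lie strictly in (0, 1)")
    if not model.coef:
        return replace(model, intercept=float(logit(target_prevalence)))
    rng = np.random.default_rng(seed)
    features = _sample_features(schema, n_mc, rng)
    base = replace(model, intercept=0.0)
    eta0 = base.linear_predictor(schema, features)

    def gap(b0: float) -> float:
        return float(expit(eta0 + b0).mean()) - target_prevalence

    lo, hi = -5.0, 5.0
    while gap(lo) > 0:
        lo *= 2
        if lo < -1e6:
            raise RuntimeError("intercept calibration failed: target prevalence unattainable")
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise RuntimeError("intercept calibration failed: target prevalence unattainable")
    b0 = brentq(gap, lo, hi, xtol=1e-10)
    achieved = target_prevalence + gap(b0)
    if abs(achieved - target_prevalence) > tol:
        raise RuntimeError(
            f"intercept calibration failed: achieved {achieved:.4f} vs target {target_prevalence:.4f}"
        )
    return replace(model, intercept=float(b0))
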