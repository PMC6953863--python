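"""Experimental protocol: repeated seeded runs, statistics, and ablation.

The protocol mirrors the reference study design: a single stratified
holdout split of the cohort (74.6% training), per-basis input scaling
fitted on the training partition only, then ``n_runs`` (default 30)
independent evolutionary runs differing only in the EA seed.  Each run's
best network is evaluated on the generalisation partition; run samples of
CCR, MS, AUC and connection count feed the statistical comparison
(Kolmogorov-Smirnov normality per method, one-way ANOVA, Levene, Tukey HSD)
and the variable-ablation study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .cohort import CohortTable
from .evolution import EAConfig, EvolutionTrace, evolve, fitness
from .metrics import MetricsReport, compute_report
from .networks import NetworkGenome, active_inputs, count_connections, forward
from .preprocessing import apply_scaler, default_train_size, fit_scaler, holdout_split

__all__ = [
    "RunResult",
    "RunSummary",
    "ComparisonReport",
    "AblationReport",
    "run_protocol",
    "compare_methods",
    "ablation_study",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("ccr", "ms", "auc", "n_conn")


def derive_run_seed(master_seed: int, run_index: int) -> int:
    """Stable per-run seed from the master seed (below 2**31)."""
    ss = np.random.SeedSequence([master_seed, run_index])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunResult:
    """One evolutionary run: its seed, generalisation metrics and best genome."""

    seed: int
    train_fitness: float
    report: MetricsReport
    genome: NetworkGenome
    active: set[int] = field(default_factory=set)

    @property
    def row(self) -> dict:
        return {
            "seed": self.seed,
            "train_fitness": self.train_fitness,
            "ccr": self.report.ccr,
            "ms": self.report.ms,
            "auc": self.report.auc,
            "pr_auc": self.report.pr_auc,
            "n_conn": self.report.n_connections,
        }


@dataclass
class RunSummary:
    """Per-method sample of run metrics with mean +/- sd and the selected best run."""

    basis: str
    runs: list[RunResult]
    feature_columns: list[str]
    split_train_ids: np.ndarray
    split_seed: int
    master_seed: int

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([r.row for r in self.runs])

    @property
    def mean(self) -> dict:
        t = self.table
        return {m: float(t[m].mean()) for m in METRIC_COLUMNS}

    @property
    def sd(self) -> dict:
        t = self.table
        if len(t) == 1:
            return {m: 0.0 for m in METRIC_COLUMNS}
        return {m: float(t[m].std(ddof=1)) for m in METRIC_COLUMNS}

    @property
    def best_index(self) -> int:
        """Highest training fitness; ties broken by fewer connections.

        Generalisation data never influence selection.
        """
        keys = [(-r.train_fitness, r.report.n_connections, i) for i, r in enumerate(self.runs)]
        return min(keys)[2]

    @property
    def best_run(self) -> RunResult:
        return self.runs[self.best_index]

    def describe(self) -> str:
        m, s = self.mean, self.sd
        return (
            f"{self.basis}: "
            + ", ".join(f"{k}={m[k]:.3f}+/-{s[k]:.3f}" for k in METRIC_COLUMNS)
            + f" over {len(self.runs)} runs"
        )


def run_protocol(
    cohort: CohortTable,
    basis: str,
    config: EAConfig,
    n_runs: int = 30,
    n_train: int | None = None,
    split_seed: int = 0,
    stratified: bool = True,
    feature_columns: list[str] | None = None,
    master_seed: int | None = None,
) -> RunSummary:
    """Split once, scale, then run ``n_runs`` independent evolutionary fits.

    The split is shared across runs (and, via ``split_seed``, across
    methods); only the EA seed varies.  ``feature_columns`` restricts the
    input space, which is how the ablation study removes a variable.
    """
    if master_seed is None:
        master_seed = config.seed
    features = feature_columns or cohort.schema.feature_ids
    nt = n_train if n_train is not None else default_train_size(cohort.n)
    split = holdout_split(cohort, nt, split_seed, stratified)
    train_df = split.train.subset_features(features)
    gen_df = split.generalisation.subset_features(features)
    spec = fit_scaler(train_df, basis)
    X_train = apply_scaler(spec, train_df)
    X_gen = apply_scaler(spec, gen_df)
    y_train = split.train.outcome
    y_gen = split.generalisation.outcome
    runs: list[RunResult] = []
    for i in range(n_runs):
        seed_i = derive_run_seed(master_seed, i)
        cfg_i = replace(config, basis=basis, seed=seed_i)
        trace = evolve(X_train, y_train, cfg_i)
        genome = trace.best_genome
        scores = forward(genome, X_gen)
        report = compute_report(y_gen, scores, n_connections=count_connections(genome))
        runs.append(
            RunResult(
                seed=seed_i,
                train_fitness=trace.final_fitness,
                report=report,
                genome=genome,
                active=active_inputs(genome),
            )
        )
    return RunSummary(
        basis=basis,
        runs=runs,
        feature_columns=list(features),
        split_train_ids=split.train_ids,
        split_seed=split_seed,
        master_seed=master_seed,
    )


def grid_search_config(
    X: np.ndarray,
    y: np.ndarray,
    base_config: EAConfig,
    param_grid: Mapping[str, list],
    k: int = 5,
    seed: int = 0,
) -> tuple[EAConfig, pd.DataFrame]:
    """Optional k-fold cross-validated grid search over EA hyperparameters.

    Each candidate configuration is scored by the mean validation fitness of
    its evolved best genome across ``k`` folds of the training data; the
    highest-scoring candidate wins (ties go to the earlier grid point).
    Returns the winning :class:`EAConfig` and the per-candidate score table.
    """
    from itertools import product as _product

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    n = len(X)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    keys = list(param_grid)
    rows = []
    best: tuple[float, int] | None = None
    best_cfg = base_config
    for gi, combo in enumerate(_product(*(param_grid[k_] for k_ in keys))):
        cfg = replace(base_config, **dict(zip(keys, combo)))
        scores = []
        for fi, val_idx in enumerate(folds):
            mask = np.ones(n, dtype=bool)
            mask[val_idx] = False
            trace = evolve(X[mask], y[mask], replace(cfg, seed=derive_run_seed(seed, gi * k + fi)))
            scores.append(fitness(trace.best_genome, X[val_idx], y[val_idx]))
        mean_score = float(np.mean(scores))
        rows.append({**dict(zip(keys, combo)), "mean_val_fitness": mean_score})
        if best is None or mean_score > best[0]:
            best = (mean_score, gi)
            best_cfg = cfg
    return best_cfg, pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Normality / ANOVA / Levene / Tukey results per metric across methods."""

    alpha: float
    metrics: tuple[str, ...]
    ks_pvalues: dict[str, dict[str, float]]
    anova_f: dict[str, float]
    anova_p: dict[str, float]
    levene_p: dict[str, float]
    tukey: dict[str, pd.DataFrame]
    ranking: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "metrics": list(self.metrics),
            "ks_pvalues": self.ks_pvalues,
            "anova_f": self.anova_f,
            "anova_p": self.anova_p,
            "levene_p": self.levene_p,
            "tukey": {m: t.to_dict(orient="records") for m, t in self.tukey.items()},
            "ranking": self.ranking,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _metric_samples(summaries: Mapping[str, "RunSummary | pd.DataFrame"]) -> dict[str, pd.DataFrame]:
    out = {}
    for name, s in summaries.items():
        out[name] = s.table if isinstance(s, RunSummary) else s
    return out


def compare_methods(
    summaries: Mapping[str, "RunSummary | pd.DataFrame"],
    alpha: float = 0.05,
    metrics: tuple[str, ...] = METRIC_COLUMNS,
) -> ComparisonReport:
    """Statistical comparison of >= 2 methods over matched run counts.

    Per metric: a Kolmogorov-Smirnov test of each method's run sample
    against a normal with the sample mean/sd (parameters are estimated, so
    the test is of the Lilliefors kind and its p-values are conservative),
    one-way ANOVA across methods, Levene's test of equal variances, and
    Tukey honest-significant-difference pairwise comparisons, from which the
    ranking of method means is read.  No multiple-testing correction is
    applied across metrics; each metric is presented on its own.
    """
    tables = _metric_samples(summaries)
    if len(tables) < 2:
        raise ValueError("need at least two methods to compare")
    counts = {name: len(t) for name, t in tables.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"methods must have equal run counts, got {counts}")
    ks_p: dict[str, dict[str, float]] = {}
    anova_f: dict[str, float] = {}
    anova_p: dict[str, float] = {}
    levene_p: dict[str, float] = {}
    tukey: dict[str, pd.DataFrame] = {}
    ranking: dict[str, list[str]] = {}
    for m in metrics:
        samples = {name: t[m].to_numpy(dtype=float) for name, t in tables.items()}
        ks_p[m] = {}
        for name, x in samples.items():
            sd = x.std(ddof=1)
            if sd == 0:
                ks_p[m][name] = float("nan")
            else:
                ks_p[m][name] = float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)
        groups = list(samples.values())
        f, p = stats.f_oneway(*groups)
        if np.isfinite(f) and f < 0:  # cancellation in the between-group SS
            f, p = 0.0, 1.0
        anova_f[m] = float(f)
        anova_p[m] = float(p)
        levene_p[m] = float(stats.levene(*groups).pvalue)
        values = np.concatenate(groups)
        labels = np.concatenate([[name] * len(x) for name, x in samples.items()])
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
        tukey[m] = pd.DataFrame(
            res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
        )
        ranking[m] = sorted(samples, key=lambda name: -samples[name].mean())
    return ComparisonReport(
        alpha=alpha,
        metrics=tuple(metrics),
        ks_pvalues=ks_p,
        anova_f=anova_f,
        anova_p=anova_p,
        levene_p=levene_p,
        tukey=tukey,
        ranking=ranking,
    )


@dataclass
class AblationReport:
    """Matched-design comparison of the protocol with and without one variable."""

    variable_id: str
    with_variable: RunSummary
    without_variable: RunSummary
    deltas: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "variable_id": self.variable_id,
            "mean_with": self.with_variable.mean,
            "mean_without": self.without_variable.mean,
            "sd_with": self.with_variable.sd,
            "sd_without": self.without_variable.sd,
            "deltas": self.deltas,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def ablation_study(
    cohort: CohortTable,
    basis: str,
    config: EAConfig,
    variable_id: str,
    n_runs: int = 10,
    n_train: int | None = None,
    split_seed: int = 0,
    stratified: bool = True,
    master_seed: int | None = None,
) -> AblationReport:
    """Run the protocol with the full feature set and with one column removed.

    Both arms share the same split membership and the same per-run EA seeds
    (matched design); ``deltas`` holds mean(without) - mean(with) per metric.
    Removing a one-hot group member keeps the remaining indicators intact.
    """
    all_features = cohort.schema.feature_ids
    if variable_id not in all_features:
        raise KeyError(f"variable {variable_id!r} not in schema")
    reduced = [f for f in all_features if f != variable_id]
    common = dict(
        n_runs=n_runs,
        n_train=n_train,
        split_seed=split_seed,
        stratified=stratified,
        master_seed=master_seed if master_seed is not None else config.seed,
    )
    full = run_protocol(cohort, basis, config, feature_columns=all_features, **common)
    without = run_protocol(cohort, basis, config, feature_columns=reduced, **common)
    assert np.array_equal(full.split_train_ids, without.split_train_ids)
    deltas = {m: without.mean[m] - full.mean[m] for m in METRIC_COLUMNS}
    return AblationReport(
        variable_id=variable_id,
        with_variable=full,
        without_variable=without,
        deltas=deltas,
    )
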