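"""Evolutionary programming trainer for sparse basis-function networks.

Architecture and weights are learned jointly by a mutation-only evolutionary
algorithm: there is no crossover, selection is by truncation with elitism,
and two mutation operators act on the genotype.  Structural mutation adds or
deletes hidden nodes or individual connections (counts drawn uniformly from
{1, 2}), with repairs that keep every genome inside the architecture bounds
(1-4 hidden nodes, at least one connection per node).  Parametric mutation
applies Gaussian perturbations to every numeric parameter, with a standard
deviation that decays linearly from its initial scale to 10% of it across
the generation budget.

Fitness is ``1 / (1 + E)`` where ``E`` is the mean binary cross-entropy of
the network's probabilities against the 0/1 outcomes - bounded in (0, 1],
monotone in the error, and maximal for a perfectly confident correct model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .networks import MAX_HIDDEN_NODES, HiddenNode, NetworkGenome, forward

__all__ = [
    "EAConfig",
    "EvolutionTrace",
    "init_population",
    "fitness",
    "structural_mutation",
    "parametric_mutation",
    "evolve",
]

_PROB_CLAMP = 1e-12


@dataclass(frozen=True)
class EAConfig:
    """Evolutionary-algorithm settings.

    Input-layer parameters initialise uniformly in [-1, 1] for product units
    and [-5, 5] for sigmoid and RBF nodes; output-layer weights in [-5, 5]
    for every family.  Populations start with 1-2 hidden nodes and may grow
    to 4 during evolution.
    """

    basis: str
    population_size: int = 500
    generations: int = 600
    min_hidden: int = 1
    init_max_hidden: int = 2
    max_hidden: int = MAX_HIDDEN_NODES
    structural_counts: tuple[int, int] = (1, 2)
    elite_fraction: float = 0.1
    mutation_scale: float = 1.0
    mutation_scale_floor: float = 0.1
    min_radius: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.basis not in ("PU", "SU", "RBF"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population size must be >= 2 and generations >= 1")
        if not (1 <= self.min_hidden <= self.init_max_hidden <= self.max_hidden):
            raise ValueError("hidden-node bounds must satisfy min <= init-max <= overall-max")
        lo, hi = self.structural_counts
        if not (1 <= lo <= hi):
            raise ValueError("structural mutation counts must be positive and ordered")
        if not 0.0 <= self.elite_fraction < 1.0:
            raise ValueError("elite fraction must lie in [0, 1)")

    @property
    def input_init_range(self) -> tuple[float, float]:
        return (-1.0, 1.0) if self.basis == "PU" else (-5.0, 5.0)

    @property
    def output_init_range(self) -> tuple[float, float]:
        return (-5.0, 5.0)


@dataclass
class EvolutionTrace:
    """Per-generation record of an evolutionary run."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    max_nodes: list[int] = field(default_factory=list)
    best_genomes: list[NetworkGenome] = field(default_factory=list)
    warning: str | None = None

    @property
    def best_genome(self) -> NetworkGenome:
        return self.best_genomes[-1]

    @property
    def final_fitness(self) -> float:
        return self.best_fitness[-1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": np.arange(len(self.best_fitness)),
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
                "max_nodes": self.max_nodes,
            }
        )


def _random_node(cfg: EAConfig, n_inputs: int, rng: np.random.Generator) -> HiddenNode:
    k = int(rng.integers(1, n_inputs + 1))
    idx = rng.choice(n_inputs, size=k, replace=False)
    lo, hi = cfg.input_init_range
    params = rng.uniform(lo, hi, size=k)
    node = HiddenNode(inputs={int(i): float(w) for i, w in zip(idx, params)})
    if cfg.basis == "SU":
        node.bias = float(rng.uniform(lo, hi))
    elif cfg.basis == "RBF":
        node.radius = max(abs(float(rng.uniform(lo, hi))), cfg.min_radius)
    return node


def _random_genome(cfg: EAConfig, n_inputs: int, rng: np.random.Generator) -> NetworkGenome:
    n_nodes = int(rng.integers(cfg.min_hidden, cfg.init_max_hidden + 1))
    nodes = [_random_node(cfg, n_inputs, rng) for _ in range(n_nodes)]
    olo, ohi = cfg.output_init_range
    return NetworkGenome(
        basis=cfg.basis,
        n_inputs=n_inputs,
        nodes=nodes,
        output_weights=[float(rng.uniform(olo, ohi)) for _ in nodes],
        output_bias=float(rng.uniform(olo, ohi)),
    )


def init_population(cfg: EAConfig, n_inputs: int, rng=None) -> list[NetworkGenome]:
    """Random initial population: 1-2 hidden nodes, random input subsets."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return [_random_genome(cfg, n_inputs, rng) for _ in range(cfg.population_size)]


def fitness(genome: NetworkGenome, X: np.ndarray, y: np.ndarray) -> float:
    """``1 / (1 + mean binary cross-entropy)`` - in (0, 1], higher is better."""
    with np.errstate(over="ignore", under="ignore"):
        p = forward(genome, X)
    p = np.clip(p, _PROB_CLAMP, 1.0 - _PROB_CLAMP)
    y = np.asarray(y, dtype=float)
    E = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    return 1.0 / (1.0 + E)


def structural_mutation(
    genome: NetworkGenome, cfg: EAConfig, rng: np.random.Generator
) -> NetworkGenome:
    """Add/delete hidden nodes or connections; counts uniform in {1, 2}.

    Infeasible operations are truncated: node additions stop at the overall
    maximum, deletions stop at the minimum, connection deletions only touch
    nodes with two or more connections (so no node is ever left dangling).
    """
    g = genome.copy()
    op = int(rng.integers(4))
    lo, hi = cfg.structural_counts
    count = int(rng.integers(lo, hi + 1))
    olo, ohi = cfg.output_init_range
    ilo, ihi = cfg.input_init_range
    if op == 0:  # add nodes
        for _ in range(count):
            if len(g.nodes) >= cfg.max_hidden:
                break
            g.nodes.append(_random_node(cfg, g.n_inputs, rng))
            g.output_weights.append(float(rng.uniform(olo, ohi)))
    elif op == 1:  # delete nodes
        for _ in range(count):
            if len(g.nodes) <= cfg.min_hidden:
                break
            j = int(rng.integers(len(g.nodes)))
            g.nodes.pop(j)
            g.output_weights.pop(j)
    elif op == 2:  # add connections
        for _ in range(count):
            candidates = [
                j for j, nd in enumerate(g.nodes) if len(nd.inputs) < g.n_inputs
            ]
            if not candidates:
                break
            j = candidates[int(rng.integers(len(candidates)))]
            absent = [i for i in range(g.n_inputs) if i not in g.nodes[j].inputs]
            i = absent[int(rng.integers(len(absent)))]
            g.nodes[j].inputs[i] = float(rng.uniform(ilo, ihi))
    else:  # delete connections
        for _ in range(count):
            candidates = [j for j, nd in enumerate(g.nodes) if len(nd.inputs) >= 2]
            if not candidates:
                break
            j = candidates[int(rng.integers(len(candidates)))]
            keys = sorted(g.nodes[j].inputs)
            i = keys[int(rng.integers(len(keys)))]
            del g.nodes[j].inputs[i]
    g.validate(max_hidden=cfg.max_hidden)
    return g


def parametric_mutation(
    genome: NetworkGenome, cfg: EAConfig, rng: np.random.Generator, generation: int
) -> NetworkGenome:
    """Gaussian perturbation of every numeric parameter.

    The standard deviation decays linearly from ``mutation_scale`` at
    generation 0 to ``mutation_scale_floor`` of it at the final generation.
    RBF radii stay positive by reflecting perturbed values about zero (with
    a small floor against degenerate collapse).
    """
    g = genome.copy()
    G = max(cfg.generations, 1)
    frac = min(generation / max(G - 1, 1), 1.0)
    sd = cfg.mutation_scale * (1.0 - (1.0 - cfg.mutation_scale_floor) * frac)
    for nd in g.nodes:
        for i in sorted(nd.inputs):
            nd.inputs[i] += float(rng.normal(0.0, sd))
        if nd.bias is not None:
            nd.bias += float(rng.normal(0.0, sd))
        if nd.radius is not None:
            r = nd.radius + float(rng.normal(0.0, sd))
            nd.radius = max(abs(r), cfg.min_radius)
    g.output_weights = [w + float(rng.normal(0.0, sd)) for w in g.output_weights]
    g.output_bias += float(rng.normal(0.0, sd))
    return g


def evolve(X: np.ndarray, y: np.ndarray, cfg: EAConfig) -> EvolutionTrace:
    """Run the generational loop and return the full trace.

    Each generation: evaluate fitness; copy the elite fraction unchanged
    (displacing the worst); fill the remaining slots with mutated copies of
    the better-ranked genomes - parametric mutation for the better half,
    structural mutation for the rest.  Elitism makes the best fitness
    non-decreasing across generations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("training set is empty")
    trace = EvolutionTrace()
    if len(np.unique(y)) < 2:
        trace.warning = "training outcomes contain a single class"
        warnings.warn(trace.warning, stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    n_inputs = X.shape[1]
    pop = init_population(cfg, n_inputs, rng)
    P = cfg.population_size
    n_elite = max(int(round(cfg.elite_fraction * P)), 1)
    for gen in range(cfg.generations):
        fits = np.array([fitness(g, X, y) for g in pop])
        order = np.argsort(-fits, kind="stable")
        best = int(order[0])
        trace.best_fitness.append(float(fits[best]))
        trace.mean_fitness.append(float(fits.mean()))
        trace.max_nodes.append(max(len(g.nodes) for g in pop))
        trace.best_genomes.append(pop[best].copy())
        if gen == cfg.generations - 1:
            break
        elites = [pop[i].copy() for i in order[:n_elite]]
        parents = [pop[i] for i in order[: P - n_elite]]
        half = len(parents) // 2
        children = [parametric_mutation(p, cfg, rng, gen) for p in parents[:half]]
        children += [structural_mutation(p, cfg, rng) for p in parents[half:]]
        pop = elites + children
    return trace
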