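"""Sparse evolvable single-hidden-layer networks of three basis families.

A :class:`NetworkGenome` holds between 1 and 4 hidden nodes; each node keeps
a sparse map from input index to parameter, so the architecture itself (which
inputs survive, how many nodes exist) is part of the genotype and evolves.
The three families differ only in the hidden-node transfer function:

* ``PU`` - product units: ``prod_i x_i ** w_ji`` over connected inputs
  (multiplicative, real exponents; inputs must be strictly positive).
* ``SU`` - sigmoid units: ``logistic(w_j0 + sum_i w_ji x_i)``.
* ``RBF`` - Gaussian radial basis functions:
  ``exp(-sum_i (x_i - c_ji)^2 / (2 r_j^2))`` with one shared radius per node.

The output layer is a single logistic unit, ``p = logistic(b0 + sum_j bj Bj(x))``,
read as the probability of the positive (treated) class; hard labels use the
0.5 threshold.  The connection count - the parsimony measure - counts every
input->hidden link, every hidden->output weight and the output bias; node
biases and radii are node parameters, not connections.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "BASES",
    "HiddenNode",
    "NetworkGenome",
    "basis_output",
    "forward",
    "predict_labels",
    "count_connections",
    "active_inputs",
    "MAX_HIDDEN_NODES",
]

BASES = ("PU", "SU", "RBF")

#: Default cap on hidden nodes over the whole evolutionary process.
MAX_HIDDEN_NODES = 4


@dataclass
class HiddenNode:
    """One hidden node: sparse input connections plus family-specific extras.

    ``inputs`` maps input index -> parameter (exponent for PU, weight for SU,
    center coordinate for RBF).  ``bias`` is used by SU nodes only; ``radius``
    (strictly positive) by RBF nodes only.
    """

    inputs: dict[int, float]
    bias: float | None = None
    radius: float | None = None

    def copy(self) -> "HiddenNode":
        return HiddenNode(inputs=dict(self.inputs), bias=self.bias, radius=self.radius)


@dataclass
class NetworkGenome:
    basis: str
    n_inputs: int
    nodes: list[HiddenNode]
    output_weights: list[float]
    output_bias: float = 0.0

    def __post_init__(self):
        self.validate()

    def validate(self, max_hidden: int = MAX_HIDDEN_NODES) -> None:
        if self.basis not in BASES:
            raise ValueError(f"unknown basis {self.basis!r}")
        if not 1 <= len(self.nodes) <= max_hidden:
            raise ValueError(
                f"hidden-node count {len(self.nodes)} outside [1, {max_hidden}]"
            )
        if len(self.output_weights) != len(self.nodes):
            raise ValueError("one output weight required per hidden node")
        for node in self.nodes:
            if len(node.inputs) == 0:
                raise ValueError("every hidden node needs at least one input connection")
            if any(not 0 <= i < self.n_inputs for i in node.inputs):
                raise ValueError("connection index outside the input space")
            if self.basis == "RBF" and not (node.radius is not None and node.radius > 0):
                raise ValueError("RBF nodes require a strictly positive radius")
            if self.basis == "SU" and node.bias is None:
                raise ValueError("SU nodes require a bias parameter")

    def copy(self) -> "NetworkGenome":
        return NetworkGenome(
            basis=self.basis,
            n_inputs=self.n_inputs,
            nodes=[nd.copy() for nd in self.nodes],
            output_weights=list(self.output_weights),
            output_bias=self.output_bias,
        )

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "basis": self.basis,
            "n_inputs": self.n_inputs,
            "output_bias": self.output_bias,
            "nodes": [
                {
                    "inputs": {str(i): w for i, w in sorted(nd.inputs.items())},
                    "bias": nd.bias,
                    "radius": nd.radius,
                    "output_weight": ow,
                }
                for nd, ow in zip(self.nodes, self.output_weights)
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkGenome":
        nodes = [
            HiddenNode(
                inputs={int(i): float(w) for i, w in nd["inputs"].items()},
                bias=nd.get("bias"),
                radius=nd.get("radius"),
            )
            for nd in d["nodes"]
        ]
        return cls(
            basis=d["basis"],
            n_inputs=d["n_inputs"],
            nodes=nodes,
            output_weights=[float(nd["output_weight"]) for nd in d["nodes"]],
            output_bias=float(d["output_bias"]),
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkGenome":
        return cls.from_dict(json.loads(text))


def basis_output(node: HiddenNode, x, basis: str) -> float:
    """Evaluate one hidden node on a single (already scaled) feature row."""
    x = np.asarray(x, dtype=float)
    idx = np.fromiter(node.inputs.keys(), dtype=np.intp, count=len(node.inputs))
    w = np.fromiter(node.inputs.values(), dtype=float, count=len(node.inputs))
    z = x[idx]
    if basis == "PU":
        if np.any(z <= 0):
            raise ValueError("product units require strictly positive inputs (scale to [1, 2])")
        return float(np.prod(z**w))
    if basis == "SU":
        return float(expit(node.bias + z @ w))
    if basis == "RBF":
        if node.radius is None or node.radius <= 0:
            raise ValueError("RBF radius must be strictly positive")
        return float(np.exp(-np.sum((z - w) ** 2) / (2.0 * node.radius**2)))
    raise ValueError(f"unknown basis {basis!r}")


def hidden_layer(genome: NetworkGenome, X: np.ndarray) -> np.ndarray:
    """Basis outputs for every row: shape (n_rows, n_nodes)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != genome.n_inputs:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match genome input space {genome.n_inputs}"
        )
    B = np.empty((X.shape[0], len(genome.nodes)))
    for j, node in enumerate(genome.nodes):
        idx = np.fromiter(node.inputs.keys(), dtype=np.intp, count=len(node.inputs))
        w = np.fromiter(node.inputs.values(), dtype=float, count=len(node.inputs))
        Z = X[:, idx]
        if genome.basis == "PU":
            if np.any(Z <= 0):
                raise ValueError(
                    "product units require strictly positive inputs (scale to [1, 2])"
                )
            B[:, j] = np.prod(Z**w, axis=1)
        elif genome.basis == "SU":
            B[:, j] = expit(node.bias + Z @ w)
        else:
            B[:, j] = np.exp(-np.sum((Z - w) ** 2, axis=1) / (2.0 * node.radius**2))
    return B


def forward(genome: NetworkGenome, X) -> np.ndarray:
    """Probability of the positive class for each row.

    ``p = logistic(b0 + sum_j bj * Bj(x))``; accepts a single row or a 2-D
    matrix and returns a 1-D probability vector.
    """
    B = hidden_layer(genome, X)
    eta = genome.output_bias + B @ np.asarray(genome.output_weights)
    return expit(eta)


def predict_labels(genome: NetworkGenome, X, threshold: float = 0.5) -> np.ndarray:
    """Hard 0/1 labels at the given probability threshold (default 0.5)."""
    return (forward(genome, X) >= threshold).astype(int)


def count_connections(genome: NetworkGenome) -> int:
    """Input->hidden links + hidden->output weights + the output bias.

    SU node biases and RBF radii are node parameters and are not counted;
    a one-node RBF model touching six inputs therefore has 6 + 1 + 1 = 8
    connections.
    """
    genome.validate()
    return sum(len(nd.inputs) for nd in genome.nodes) + len(genome.nodes) + 1


def active_inputs(genome: NetworkGenome) -> set[int]:
    """Input indices with at least one surviving connection.

    Because connections are added and deleted during evolution, this set is
    the model's implicit variable selection.
    """
    genome.validate()
    out: set[int] = set()
    for nd in genome.nodes:
        out |= set(nd.inputs)
    return out
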