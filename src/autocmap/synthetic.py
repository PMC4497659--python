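"""Synthetic dataset generators with known planted structure.

Two families are provided:

* :func:`synth_two_class` — a two-class tabular dataset with class-shifted
  variable means and blocks of mutually correlated variables, for exercising
  classification baselines and prototype queries against a known truth.
* :func:`synth_tree_gaussian` — a Gaussian Markov process on a tree, whose
  pairwise correlation decays multiplicatively along tree paths, so that at
  large sample size the strongest-association spanning structure of the data
  is the planted tree.  Used to validate spanning-tree recovery end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dataset import Dataset
from .exceptions import SpecError

__all__ = ["SyntheticSpec", "synth_two_class", "synth_tree_gaussian"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a two-class synthetic dataset.

    Parameters
    ----------
    n_per_class : (int, int)
        Record counts for class "A" and class "B"; each must be ≥ 2.
    variables : sequence of str
        Variable names.
    class_effects : mapping var → float
        Mean shift added to class "B" for that variable, in units of
        ``noise_sd`` (so an effect of 2.0 is a two-standard-deviation
        separation).  Variables not listed get no shift.
    blocks : sequence of (variables, correlation)
        Groups of variables given the stated pairwise correlation; the
        implied correlation matrix must be positive semi-definite.
    noise_sd : float
        Common within-class standard deviation.
    seed : int
        Seed for the generator; identical seeds give identical datasets.
    """

    n_per_class: tuple[int, int]
    variables: Sequence[str]
    class_effects: Mapping[str, float] = field(default_factory=dict)
    blocks: Sequence[tuple[Sequence[str], float]] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_class) < 2:
            raise SpecError("n_per_class must be at least 2 per class")
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be positive")
        for group, rho in self.blocks:
            if not -1 < rho < 1:
                raise SpecError(f"block correlation {rho} outside (-1, 1)")
            unknown = set(group) - set(self.variables)
            if unknown:
                raise SpecError(f"block names unknown variables: {sorted(unknown)}")
        unknown = set(self.class_effects) - set(self.variables)
        if unknown:
            raise SpecError(f"effects name unknown variables: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        raw = json.loads(Path(path).read_text())
        raw["n_per_class"] = tuple(raw["n_per_class"])
        raw["blocks"] = [tuple(b) for b in raw.get("blocks", [])]
        return cls(**raw)


def _correlation_matrix(spec: SyntheticSpec) -> np.ndarray:
    k = len(spec.variables)
    idx = {v: i for i, v in enumerate(spec.variables)}
    rho = np.eye(k)
    for group, r in spec.blocks:
        for a in group:
            for b in group:
                if a != b:
                    rho[idx[a], idx[b]] = r
    if np.linalg.eigvalsh(rho).min() < -1e-10:
        raise SpecError("requested block correlations are not positive semi-definite")
    return rho


def synth_two_class(spec: SyntheticSpec) -> Dataset:
    """Draw the two-class dataset described by ``spec``.

    Class indicator columns ``ClassA``/``ClassB`` (complementary 0/1) are
    appended and matching categorical labels attached, mirroring how
    clinical tables carry diagnostic membership alongside measurements.
    """
    rng = np.random.default_rng(spec.seed)
    rho = _correlation_matrix(spec)
    chol = np.linalg.cholesky(rho + 1e-12 * np.eye(len(rho)))
    nA, nB = spec.n_per_class
    shift = np.array([spec.class_effects.get(v, 0.0) for v in spec.variables])
    z = rng.standard_normal((nA + nB, len(spec.variables))) @ chol.T
    x = z * spec.noise_sd
    x[nA:] += shift * spec.noise_sd
    ids = [f"A{i+1:03d}" for i in range(nA)] + [f"B{i+1:03d}" for i in range(nB)]
    frame = pd.DataFrame(x, index=ids, columns=list(spec.variables))
    frame["ClassA"] = [1.0] * nA + [0.0] * nB
    frame["ClassB"] = 1.0 - frame["ClassA"]
    labels = pd.Series(["A"] * nA + ["B"] * nB, index=ids, name="class")
    return Dataset(values=frame, class_labels=labels)


def synth_tree_gaussian(
    tree: Sequence[tuple[str, str, float]],
    n: int,
    seed: int = 0,
) -> Dataset:
    """Sample ``n`` records from a Gaussian Markov process on a tree.

    ``tree`` lists edges ``(parent, child, r)`` with edge correlations
    ``0 < r < 1``.  Each node is a unit-variance Gaussian; along any path the
    correlation is the product of the edge correlations, so the planted tree
    is the unique maximum-|r| spanning tree of the population correlation
    matrix.

    Raises
    ------
    SpecError
        Cyclic/disconnected edge list, out-of-range edge correlation, or
        ``n < 1``.
    """
    if n < 1:
        raise SpecError("n must be at least 1")
    g = nx.Graph()
    for a, b, r in tree:
        if not 0 < r < 1:
            raise SpecError(f"edge correlation {r} outside (0, 1)")
        g.add_edge(a, b, r=r)
    if g.number_of_nodes() == 0:
        raise SpecError("empty tree")
    if not nx.is_tree(g):
        raise SpecError("edge list is not a tree (cycle or disconnection)")
    rng = np.random.default_rng(seed)
    root = next(iter(g.nodes))
    cols: dict[str, np.ndarray] = {root: rng.standard_normal(n)}
    for parent, child in nx.bfs_edges(g, root):
        r = g.edges[parent, child]["r"]
        cols[child] = r * cols[parent] + np.sqrt(1 - r * r) * rng.standard_normal(n)
    order = list(g.nodes)
    frame = pd.DataFrame({v: cols[v] for v in order},
                         index=[f"s{i+1:05d}" for i in range(n)])
    return Dataset(values=frame)
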