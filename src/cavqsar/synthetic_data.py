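"""Synthetic descriptor/activity datasets and random molecule-like graphs.

The generator emulates the statistical shape of a small QSAR study: a few
dozen compounds described by intercorrelated descriptor columns, a linear
response with Gaussian noise, and a lopsided train/test split.  Defaults
mirror a 24-compound campaign (20 train / 4 test, six descriptors of which
half carry signal) with mild noise.  Correlation between descriptors is
compound-symmetric — a single rho — which is the cleanest way to stress
the collinearity that principal-components regression exists to absorb.

Graphs from :func:`gen_molecule_graph` are chemically plausible (connected,
degree-capped, C/O elements) but make no attempt at exact valence rules;
the descriptor layer needs graphs, not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .chem_graph import Atom, MolecularGraph

__all__ = [
    "SyntheticSpec",
    "gen_descriptor_matrix",
    "gen_activity",
    "gen_molecule_graph",
    "make_split",
    "gen_qsar_dataset",
]


@dataclass
class SyntheticSpec:
    """Parameters of a planted linear descriptor-activity dataset.

    Defaults emulate the study conditions this package targets: 24
    compounds, 6 descriptors with moderate intercorrelation, 3 of them
    active, noise SD 0.05 on a pIC50-scale response, 20/24 training
    fraction.
    """

    n_compounds: int = 24
    n_descriptors: int = 6
    rho: float = 0.5
    beta: Optional[np.ndarray] = None
    intercept: float = 0.5
    sigma: float = 0.05
    train_fraction: float = 20 / 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta is None:
            b = np.zeros(self.n_descriptors)
            b[: max(1, self.n_descriptors // 2)] = np.linspace(
                1.0, 0.5, max(1, self.n_descriptors // 2)
            )
            self.beta = b
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.n_descriptors,):
            raise ValueError("beta length must equal n_descriptors")
        if not 0 <= self.rho < 1:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_compounds <= self.n_descriptors + 2:
            raise ValueError("need n_compounds > n_descriptors + 2 for fitable data")


def gen_descriptor_matrix(spec: SyntheticSpec) -> np.ndarray:
    """Gaussian descriptor matrix with compound-symmetric correlation rho.

    Each row is z*sqrt(rho) + e*sqrt(1-rho) with a shared standard-normal
    z per compound, so every pair of columns has population correlation
    rho.  Deterministic for a given spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    shared = rng.standard_normal((spec.n_compounds, 1))
    own = rng.standard_normal((spec.n_compounds, spec.n_descriptors))
    return np.sqrt(spec.rho) * shared + np.sqrt(1.0 - spec.rho) * own


def gen_activity(
    X: np.ndarray,
    beta: np.ndarray,
    intercept: float,
    sigma: float,
    seed: int,
) -> np.ndarray:
    """Linear response Y = intercept + X beta + N(0, sigma^2) noise."""
    x = np.asarray(X, dtype=float)
    b = np.asarray(beta, dtype=float)
    if x.shape[1] != b.shape[0]:
        raise ValueError("beta length must match descriptor count")
    rng = np.random.default_rng(seed)
    return intercept + x @ b + sigma * rng.standard_normal(x.shape[0])


def gen_molecule_graph(
    n_atoms: int, extra_ring_prob: float = 0.15, seed: int = 0
) -> MolecularGraph:
    """Random connected molecule-like graph.

    A random spanning tree (each new atom bonds to a uniformly chosen
    earlier atom with spare valence), then each non-adjacent pair with
    spare valence closes a ring with probability ``extra_ring_prob``.
    Degree is capped at 4; elements are C (80%) or O (20%) with sp3/sp2
    tags.
    """
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    rng = np.random.default_rng(seed)
    degree = np.zeros(n_atoms, dtype=int)
    bonds: list[tuple[int, int, float]] = []
    for new in range(1, n_atoms):
        candidates = [i for i in range(new) if degree[i] < 4]
        parent = int(rng.choice(candidates))
        bonds.append((parent, new, 1.0))
        degree[parent] += 1
        degree[new] += 1
    if extra_ring_prob > 0:
        bonded = {(min(i, j), max(i, j)) for i, j, _ in bonds}
        for i in range(n_atoms):
            for j in range(i + 1, n_atoms):
                if (i, j) in bonded or degree[i] >= 4 or degree[j] >= 4:
                    continue
                if rng.random() < extra_ring_prob:
                    bonds.append((i, j, 1.0))
                    degree[i] += 1
                    degree[j] += 1
    elements = rng.choice(["C", "O"], size=n_atoms, p=[0.8, 0.2])
    hybrid = rng.choice(["sp3", "sp2"], size=n_atoms, p=[0.7, 0.3])
    atoms = [Atom(e, h) for e, h in zip(elements, hybrid)]
    return MolecularGraph(atoms=atoms, bonds=bonds)


def make_split(n: int, train_fraction: float, seed: int = 0) -> np.ndarray:
    """Seeded random train/test tags; train count = round(n * fraction)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train fraction must lie strictly between 0 and 1")
    n_train = int(round(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"degenerate split: {n_train} train of {n} rows at fraction {train_fraction}"
        )
    rng = np.random.default_rng(seed)
    tags = np.array(["test"] * n, dtype=object)
    tags[rng.choice(n, size=n_train, replace=False)] = "train"
    return tags


def gen_qsar_dataset(spec: SyntheticSpec) -> pd.DataFrame:
    """Full synthetic dataset in the CSV layout the pipeline consumes.

    Columns: compound_id index, descriptor columns d1..dp, ``activity``
    and ``split``.  Derived seeds keep the three random stages (X, noise,
    split) independent but jointly reproducible.
    """
    x = gen_descriptor_matrix(spec)
    y = gen_activity(x, spec.beta, spec.intercept, spec.sigma, seed=spec.seed + 1)
    tags = make_split(spec.n_compounds, spec.train_fraction, seed=spec.seed + 2)
    df = pd.DataFrame(
        x,
        columns=[f"d{i+1}" for i in range(spec.n_descriptors)],
        index=[f"cmpd_{i+1:03d}" for i in range(spec.n_compounds)],
    )
    df.index.name = "compound_id"
    df["activity"] = y
    df["split"] = tags
    return df
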