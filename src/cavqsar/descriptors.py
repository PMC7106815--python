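"""Molecular descriptors for the CaV-channel QSAR models.

Four descriptors are computed from structure:

* ``k2alpha`` — second-order kappa alpha-modified shape index, a function of
  the heavy-atom count A, the count P of two-bond paths, and the atom-type
  correction alpha.
* ``Id`` / ``IdwAverage`` — total and mean information content on the
  equality of pairwise graph distances: partition the K = A(A-1)/2 upper-
  triangle distances into equality classes with counts f_g, then
  ``Id = K log2 K - sum f_g log2 f_g`` and
  ``IdwAverage = -sum (f_g/K) log2 (f_g/K)``.  The identity
  ``Id = K * IdwAverage`` holds exactly.
* ``MomInertiaY`` — moment of inertia about the y-axis through the center
  of mass, in amu * A**2.

The two electronic descriptors of the inhibition model,
``Most+vePotential`` and ``DeltaEpsilonC``, come from quantum-chemical
calculations outside this package and are accepted as supplied table
columns only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem_graph import (
    DistanceMatrix,
    MolecularGraph,
    alpha_sum,
    path_count,
    reciprocal_square_distance_matrix,
    topological_distance_matrix,
)

__all__ = [
    "COMPUTED_DESCRIPTORS",
    "SUPPLIED_DESCRIPTORS",
    "DescriptorTable",
    "kappa2_alpha",
    "total_info_distance",
    "mean_info_distance",
    "distance_equality_classes",
    "moment_of_inertia_y",
    "compute_descriptors",
    "build_descriptor_table",
]

COMPUTED_DESCRIPTORS = ("k2alpha", "Id", "IdwAverage", "MomInertiaY")
SUPPLIED_DESCRIPTORS = ("Most+vePotential", "DeltaEpsilonC")


def kappa2_alpha(g: MolecularGraph, variant: str = "kier_standard") -> float:
    """Second-order kappa alpha shape index.

    ``kier_standard`` evaluates (A+a-1)(A+a-2)^2 / (P+a)^2, Kier's form of
    the second-order index.  ``literal_printed`` evaluates
    (A+a-1)(A+a-1)^2 / (P+a)^2, i.e. with the first factor repeated; this
    variant exists so published tables typeset that way can be audited
    without silently correcting them.  Here A is the heavy-atom count,
    P the number of two-bond paths and a the Kier alpha sum.
    """
    if variant not in ("kier_standard", "literal_printed"):
        raise ValueError(f"unknown kappa variant {variant!r}")
    a_count = g.n_atoms
    if a_count < 3:
        raise ValueError("kappa2_alpha needs at least 3 atoms")
    alpha = alpha_sum(g)
    p = path_count(g, 2)
    denom = (p + alpha) ** 2
    if denom <= 0 or not math.isfinite(denom):
        raise ZeroDivisionError("degenerate kappa denominator (P + alpha)^2")
    if variant == "kier_standard":
        return (a_count + alpha - 1) * (a_count + alpha - 2) ** 2 / denom
    return (a_count + alpha - 1) ** 3 / denom


def distance_equality_classes(
    dm: DistanceMatrix, tolerance: Optional[float] = None
) -> np.ndarray:
    """Counts f_g of the equality classes of the strict upper triangle.

    Topological distances are grouped exactly; float-valued modes group
    values whose gap after sorting is within a relative ``tolerance``
    (default 1e-9), which keeps the grouping deterministic.
    """
    tri = np.sort(dm.upper_triangle())
    if tri.size == 0:
        raise ValueError("distance matrix has an empty upper triangle")
    if tolerance is None:
        tolerance = 0.0 if dm.mode == "topological" else 1e-9
    counts = []
    run = 1
    for prev, cur in zip(tri[:-1], tri[1:]):
        if abs(cur - prev) <= tolerance * max(abs(cur), abs(prev), 1e-300):
            run += 1
        else:
            counts.append(run)
            run = 1
    counts.append(run)
    return np.asarray(counts)


def total_info_distance(dm: DistanceMatrix, tolerance: Optional[float] = None) -> float:
    """Total information content on the distance equality (Id), in bits."""
    f = distance_equality_classes(dm, tolerance)
    k = int(f.sum())
    return float(k * math.log2(k) - np.sum(f * np.log2(f)))


def mean_info_distance(dm: DistanceMatrix, tolerance: Optional[float] = None) -> float:
    """Mean information content on the distance equality (IdwAverage), bits."""
    f = distance_equality_classes(dm, tolerance)
    p = f / f.sum()
    return float(-np.sum(p * np.log2(p)))


def moment_of_inertia_y(
    coords: np.ndarray, masses: np.ndarray
) -> float:
    """Moment of inertia about the y-axis through the center of mass.

    I_y = sum_i m_i (x_i^2 + z_i^2) after translating to the center of
    mass.  Units amu * A**2 when coordinates are in angstroms.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("coords must be a non-empty (n, 3) array")
    if masses.shape != (coords.shape[0],):
        raise ValueError("one mass per atom required")
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    rel = coords - com
    return float(np.sum(masses * (rel[:, 0] ** 2 + rel[:, 2] ** 2)))


def compute_descriptors(
    g: MolecularGraph,
    distance_mode: str = "topological",
    kappa_variant: str = "kier_standard",
) -> dict[str, float]:
    """All structure-derived descriptors for one molecule.

    ``distance_mode`` selects the D matrix the information indices are
    computed from: plain shortest-path counts (``topological``) or the
    1/d**2 weighted form (``reciprocal_square``).  MomInertiaY is NaN when
    the graph carries no coordinates; coordinates from 2D records give a
    planar, 2D-derived value.
    """
    if distance_mode == "topological":
        dm = topological_distance_matrix(g)
    elif distance_mode == "reciprocal_square":
        dm = reciprocal_square_distance_matrix(g)
    else:
        raise ValueError(f"unknown distance mode {distance_mode!r}")
    out = {
        "k2alpha": kappa2_alpha(g, variant=kappa_variant),
        "Id": total_info_distance(dm),
        "IdwAverage": mean_info_distance(dm),
    }
    if g.coords is not None and g.masses is not None:
        out["MomInertiaY"] = moment_of_inertia_y(g.coords, g.masses)
    else:
        out["MomInertiaY"] = float("nan")
    return out


@dataclass
class DescriptorTable:
    """Compounds x descriptors table with per-cell provenance.

    ``values`` holds the numbers; ``provenance`` mirrors it with one of
    ``"computed"``, ``"supplied"`` or ``"missing"`` per cell.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate compound IDs: {dups}")
        if not self.values.index.equals(self.provenance.index) or list(
            self.values.columns
        ) != list(self.provenance.columns):
            raise ValueError("values and provenance must be aligned")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "compound_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DescriptorTable":
        df = pd.read_csv(path, index_col="compound_id")
        prov = df.where(df.isna(), "supplied").where(~df.isna(), "missing")
        return cls(values=df, provenance=prov)


def build_descriptor_table(
    structures: Mapping[str, MolecularGraph] | Sequence[tuple[str, MolecularGraph]],
    supplied: Optional[pd.DataFrame] = None,
    distance_mode: str = "topological",
    kappa_variant: str = "kier_standard",
) -> DescriptorTable:
    """Assemble the QSAR descriptor table.

    Structure-derived columns are computed here; quantum-chemical columns
    (``Most+vePotential``, ``DeltaEpsilonC``) are merged from ``supplied``
    (indexed by compound ID) when given.  Compound IDs in ``supplied`` must
    be a subset of the structure IDs.
    """
    items = list(structures.items()) if isinstance(structures, Mapping) else list(structures)
    ids = [ident for ident, _ in items]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate compound IDs: {dups}")
    rows = {
        ident: compute_descriptors(g, distance_mode=distance_mode, kappa_variant=kappa_variant)
        for ident, g in items
    }
    values = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(COMPUTED_DESCRIPTORS)
    )
    values.index.name = "compound_id"
    prov = pd.DataFrame("computed", index=values.index, columns=values.columns)
    prov[values.isna()] = "missing"
    for col in SUPPLIED_DESCRIPTORS:
        values[col] = np.nan
        prov[col] = "missing"
    if supplied is not None:
        unmatched = [i for i in supplied.index if i not in set(ids)]
        if unmatched:
            raise ValueError(f"supplied table has unmatched compound IDs: {unmatched}")
        for col in supplied.columns:
            values.loc[supplied.index, col] = supplied[col].astype(float).values
            prov.loc[supplied.index, col] = "supplied"
    return DescriptorTable(values=values, provenance=prov)
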