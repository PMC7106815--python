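"""Principal-components regression with adjusted-r2 component selection and
genetic-algorithm descriptor-subset search.

The response is regressed on the leading principal components of the
standardized descriptor matrix (X = T P^T); the fitted component-space
coefficients are then folded back through the loadings and scaling into an
ordinary linear equation in descriptor space, so a fitted model can always
be applied as intercept + sum(beta_j * x_j).  Retaining fewer components
than the rank guards against the collinearity that makes plain
least-squares unstable on small, intercorrelated descriptor sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "LinearModel",
    "PcrModel",
    "GaParams",
    "GaResult",
    "principal_components",
    "fit_pcr",
    "ga_select_descriptors",
    "predict",
]


@dataclass
class LinearModel:
    """Intercept plus named coefficients in descriptor space."""

    intercept: float
    coefficients: dict[str, float]
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.coefficients)
        if len(set(names)) != len(names):
            raise ValueError("coefficient names must be unique")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "metadata": dict(self.metadata),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, record: dict) -> "LinearModel":
        return cls(
            intercept=float(record["intercept"]),
            coefficients={k: float(v) for k, v in record["coefficients"].items()},
            name=record.get("name", ""),
            metadata=record.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, path) -> "LinearModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def principal_components(
    X, standardize: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores T, loadings P and explained-variance shares of X.

    Columns are centered (and scaled to unit variance when ``standardize``)
    before the decomposition; loadings columns are unit-norm eigendirections
    ordered by decreasing variance, with the sign fixed so the
    largest-magnitude loading in each column is positive.
    """
    arr, names = _as_matrix(X)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 1:
        raise ValueError("X must be a matrix with >= 2 rows and >= 1 column")
    if np.isnan(arr).any():
        raise ValueError("X contains missing values")
    mean = arr.mean(axis=0)
    centered = arr - mean
    if standardize:
        scale = centered.std(axis=0, ddof=1)
        dead = np.where(scale == 0)[0]
        if dead.size:
            raise ValueError(
                f"zero-variance column(s) cannot be standardized: "
                f"{[names[i] for i in dead]}"
            )
        centered = centered / scale
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    p = vt.T
    # deterministic sign: largest-|loading| entry of each PC positive
    for j in range(p.shape[1]):
        pivot = np.argmax(np.abs(p[:, j]))
        if p[pivot, j] < 0:
            p[:, j] = -p[:, j]
            u[:, j] = -u[:, j]
    t = u * s
    var = s**2
    shares = var / var.sum() if var.sum() > 0 else var
    return t, p, shares


@dataclass
class PcrModel:
    """A fitted principal-components regression.

    Stores the standardization constants, the full loadings/scores, the
    retained component count p_prime and the component-space coefficients,
    plus the equivalent back-transformed :class:`LinearModel`.
    """

    descriptor_names: list[str]
    column_means: np.ndarray
    column_scales: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_shares: np.ndarray
    p_prime: int
    intercept_pc: float
    beta_pc: np.ndarray
    linear_model: LinearModel
    r2: float
    r2_adj: float

    def predict(self, rows) -> np.ndarray:
        return predict(self.linear_model, rows)


def _rank(matrix: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(matrix))


def fit_pcr(
    X,
    Y,
    p_prime: Union[int, str] = "auto",
    standardize: bool = True,
) -> PcrModel:
    """Fit Y on the first ``p_prime`` principal components of X.

    ``p_prime="auto"`` picks the component count maximizing the adjusted
    r2, breaking ties toward the smaller count.  The back-transformed
    descriptor-space equation is exposed as ``model.linear_model`` and
    reproduces ordinary least squares when ``p_prime`` equals the rank.
    """
    arr, names = _as_matrix(X)
    y = np.asarray(Y, dtype=float).ravel()
    n = arr.shape[0]
    if y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    mean = arr.mean(axis=0)
    centered = arr - mean
    if standardize:
        scale = centered.std(axis=0, ddof=1)
        if np.any(scale == 0):
            dead = [names[i] for i in np.where(scale == 0)[0]]
            raise ValueError(f"zero-variance column(s): {dead}")
    else:
        scale = np.ones(arr.shape[1])
    t, p, shares = principal_components(arr, standardize=standardize)
    rank = _rank(centered / scale)
    if isinstance(p_prime, str):
        if p_prime != "auto":
            raise ValueError(f"p_prime must be an integer or 'auto', got {p_prime!r}")
        best: Optional[tuple[float, int]] = None
        for k in range(1, rank + 1):
            if n < k + 2:
                break
            r2_k, _ = _score_regression(t[:, :k], y)
            adj = _adjusted(r2_k, n, k)
            if best is None or adj > best[0] + 1e-12:
                best = (adj, k)
        if best is None:
            raise ValueError("not enough rows to fit any component count")
        chosen = best[1]
    else:
        chosen = int(p_prime)
        if not 1 <= chosen <= rank:
            raise ValueError(f"p_prime={chosen} outside 1..rank({rank})")
        if n < chosen + 2:
            raise ValueError("need at least p_prime + 2 rows")
    r2, coef = _score_regression(t[:, :chosen], y)
    b0_pc, beta_pc = coef[0], coef[1:]
    # back-transform: x_std = (x - mean)/scale, t = x_std . P
    beta_x = (p[:, :chosen] @ beta_pc) / scale
    intercept = b0_pc - float(mean @ beta_x)
    lm = LinearModel(
        intercept=intercept,
        coefficients={nm: float(b) for nm, b in zip(names, beta_x)},
        name="pcr_fit",
        metadata={"source": "fitted", "p_prime": chosen},
    )
    return PcrModel(
        descriptor_names=names,
        column_means=mean,
        column_scales=scale,
        loadings=p,
        scores=t,
        explained_variance_shares=shares,
        p_prime=chosen,
        intercept_pc=b0_pc,
        beta_pc=beta_pc,
        linear_model=lm,
        r2=r2,
        r2_adj=_adjusted(r2, n, chosen),
    )


def _score_regression(t: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    design = np.column_stack([np.ones(len(y)), t])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
    return r2, coef


def _adjusted(r2: float, n: int, p: int) -> float:
    return ((n - 1) * r2 - p) / (n - 1 - p)


@dataclass
class GaParams:
    """Knobs of the descriptor-subset genetic algorithm.

    Defaults are chosen for reproducible desk-scale runs on tens of
    candidate descriptors, not taken from any published configuration.
    """

    population: int = 50
    generations: int = 100
    tournament_size: int = 3
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    elitism: int = 1


@dataclass
class GaResult:
    selected: tuple[str, ...]
    model: PcrModel
    fitness: float
    history: list[float]


def _loo_q2(fit: Callable[[np.ndarray, np.ndarray], PcrModel], x: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        m = fit(x[keep], y[keep])
        press += float((y[i] - m.predict(pd.DataFrame(x[i : i + 1], columns=m.descriptor_names))[0]) ** 2)
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def ga_select_descriptors(
    X,
    Y,
    fitness: str = "adjusted_r2",
    ga_params: Optional[GaParams] = None,
    seed: int = 0,
) -> GaResult:
    """Evolve a descriptor-subset bitmask maximizing model fitness.

    Fitness of a mask is the adjusted r2 (or LOO q2) of a PCR model fitted
    on the masked columns with auto component selection.  Tournament
    selection, uniform crossover, per-bit mutation and elitism; all-zero
    masks are repaired by switching one random bit on.  Deterministic for
    a given seed.
    """
    arr, names = _as_matrix(X)
    y = np.asarray(Y, dtype=float).ravel()
    n_desc = arr.shape[1]
    if n_desc < 2:
        raise ValueError("need at least 2 candidate descriptors")
    if fitness not in ("adjusted_r2", "loo_q2"):
        raise ValueError(f"unknown fitness {fitness!r}")
    params = ga_params or GaParams()
    rng = np.random.default_rng(seed)
    cache: dict[tuple[int, ...], float] = {}

    def evaluate(mask: np.ndarray) -> float:
        key = tuple(int(b) for b in mask)
        if key in cache:
            return cache[key]
        cols = np.where(mask)[0]
        sub = pd.DataFrame(arr[:, cols], columns=[names[c] for c in cols])
        try:
            if fitness == "adjusted_r2":
                val = fit_pcr(sub, y, p_prime="auto").r2_adj
            else:
                val = _loo_q2(lambda a, b: fit_pcr(
                    pd.DataFrame(a, columns=list(sub.columns)), b, p_prime="auto"
                ), sub.to_numpy(), y)
        except (ValueError, np.linalg.LinAlgError):
            val = -np.inf
        cache[key] = val
        return val

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask[rng.integers(n_desc)] = True
        return mask

    pop = [repair(rng.random(n_desc) < 0.5) for _ in range(params.population)]
    fits = np.array([evaluate(m) for m in pop])
    history: list[float] = [float(fits.max())]
    for _gen in range(params.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i].copy() for i in order[: params.elitism]]
        while len(new_pop) < params.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, params.population, params.tournament_size)
                parents.append(pop[max(contenders, key=lambda i: fits[i])])
            if rng.random() < params.crossover_rate:
                take_first = rng.random(n_desc) < 0.5
                child = np.where(take_first, parents[0], parents[1])
            else:
                child = parents[0].copy()
            flip = rng.random(n_desc) < params.mutation_rate
            child = np.logical_xor(child, flip)
            new_pop.append(repair(child))
        pop = new_pop
        fits = np.array([evaluate(m) for m in pop])
        history.append(float(fits.max()))  # monotone by elitism, not by fiat
    best_mask = pop[int(np.argmax(fits))]
    # elitism guarantees the best-ever mask survives to the final population
    cols = np.where(best_mask)[0]
    sub = pd.DataFrame(arr[:, cols], columns=[names[c] for c in cols])
    model = fit_pcr(sub, y, p_prime="auto")
    return GaResult(
        selected=tuple(names[c] for c in cols),
        model=model,
        fitness=float(fits.max()),
        history=history,
    )


def predict(model: LinearModel, rows) -> np.ndarray:
    """Apply a linear QSAR equation to descriptor rows (pIC50 units)."""
    if isinstance(rows, pd.DataFrame):
        missing = [c for c in model.descriptor_names if c not in rows.columns]
        if missing:
            raise KeyError(f"missing descriptor column(s): {missing}")
        x = rows[model.descriptor_names].to_numpy(dtype=float)
    else:
        x = np.asarray(rows, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != len(model.descriptor_names):
            raise ValueError(
                f"expected {len(model.descriptor_names)} descriptor values per row"
            )
    beta = np.array([model.coefficients[c] for c in model.descriptor_names])
    return model.intercept + x @ beta
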