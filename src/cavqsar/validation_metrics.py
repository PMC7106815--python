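"""QSAR validation statistics.

Quality-of-fit metrics (r2, adjusted r2, F, standard error), internal
validation by leave-one-out cross-validation (PRESS, SDEP, q2) and Roy's
r_m2 family, and external validation (r2_pred against the training mean,
RMSEP).  Everything is a pure function of observed/predicted vectors, or
of a refit callback for the cross-validation routines.

Conventions that the literature leaves loose are explicit arguments here:

* ``std_error`` exposes both degrees-of-freedom conventions (N-p-1 and
  N-p), because published tables are not consistent about which one they
  used.
* r0**2 and r0'**2 inside the r_m2 metrics follow Roy's definition: the
  determination coefficient of the least-squares regression through the
  origin (observed on predicted, and predicted on observed respectively).
* q2's denominator uses the full training-set mean, not fold-local means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ValidationReport",
    "Rm2Result",
    "r_squared",
    "adjusted_r2",
    "f_statistic",
    "std_error",
    "loo_cv",
    "rm2_metrics",
    "r2_pred",
    "rmsep",
    "kfold_external",
]


def _pair(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(obs, dtype=float).ravel()
    p = np.asarray(pred, dtype=float).ravel()
    if o.shape != p.shape:
        raise ValueError("observed and predicted lengths differ")
    return o, p


def r_squared(obs, pred) -> float:
    """Determination coefficient 1 - RSS/TSS."""
    o, p = _pair(obs, pred)
    if o.size < 2:
        raise ValueError("need at least two observations")
    tss = float(np.sum((o - o.mean()) ** 2))
    if tss == 0:
        raise ValueError("constant observed values: r2 undefined")
    return 1.0 - float(np.sum((o - p) ** 2)) / tss


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted r2 = ((N-1) r2 - p) / (N - 1 - p)."""
    if n - 1 - p <= 0:
        raise ValueError(f"non-positive degrees of freedom (N={n}, p={p})")
    return ((n - 1) * r2 - p) / (n - 1 - p)


def f_statistic(obs, pred, p: int) -> float:
    """Variance ratio: explained mean square over residual mean square.

    Returns ``inf`` for a noise-free fit (zero residual sum of squares).
    """
    o, pr = _pair(obs, pred)
    n = o.size
    if n - p - 1 <= 0:
        raise ValueError(f"non-positive residual degrees of freedom (N={n}, p={p})")
    explained = float(np.sum((pr - o.mean()) ** 2)) / p
    rss = float(np.sum((o - pr) ** 2))
    if rss == 0:
        return math.inf
    return explained / (rss / (n - p - 1))


def std_error(
    obs, pred, p: int, df_convention: str = "n_minus_p_minus_1"
) -> float:
    """Standard error of estimate sqrt(RSS/df).

    ``df_convention`` is ``"n_minus_p_minus_1"`` (regression default) or
    ``"n_minus_p"`` (the convention some published tables reproduce).
    """
    o, pr = _pair(obs, pred)
    n = o.size
    if df_convention == "n_minus_p_minus_1":
        df = n - p - 1
    elif df_convention == "n_minus_p":
        df = n - p
    else:
        raise ValueError(f"unknown df convention {df_convention!r}")
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    return math.sqrt(float(np.sum((o - pr) ** 2)) / df)


FitFn = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


def loo_cv(fit_fn: FitFn, X, Y) -> tuple[float, float, float, np.ndarray]:
    """Leave-one-out cross-validation.

    ``fit_fn(X_train, Y_train)`` must return a predictor callable.  Returns
    ``(press, sdep, q2, loo_predictions)`` with
    PRESS = sum (y_i - yhat_(-i))^2, SDEP = sqrt(PRESS/n) and
    q2 = 1 - PRESS / sum (y - mean(y))^2 over the full training response.
    """
    x = np.asarray(X, dtype=float)
    y = np.asarray(Y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 rows")
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            predictor = fit_fn(x[keep], y[keep])
            preds[i] = float(np.asarray(predictor(x[i : i + 1])).ravel()[0])
        except Exception as exc:  # noqa: BLE001 - annotate the failing fold
            raise RuntimeError(f"model refit failed on LOO fold {i}") from exc
    press = float(np.sum((y - preds) ** 2))
    sdep = math.sqrt(press / n)
    tss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / tss
    return press, sdep, q2, preds


def _r0_squared(y: np.ndarray, x: np.ndarray) -> float:
    """Determination coefficient of the through-origin regression of y on x."""
    sxx = float(np.sum(x * x))
    if sxx == 0:
        return 0.0
    k = float(np.sum(x * y)) / sxx
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    return 1.0 - float(np.sum((y - k * x) ** 2)) / tss


@dataclass
class Rm2Result:
    rm2: float
    rm2_prime: float
    rm2_avg: float
    delta_rm2: float
    radicand_clamped: bool = False


def rm2_metrics(obs, pred, scale: bool = False) -> Rm2Result:
    """Roy's r_m2 metric family.

    rm2 = r2 (1 - sqrt(r2 - r0^2)) with r0^2 from the through-origin
    regression of observed on predicted; rm2' swaps the roles.  With
    ``scale`` both vectors are first min-max scaled by the observed range.
    A negative radicand (anticorrelated predictions) is clamped to zero
    and flagged rather than raised.
    """
    o, p = _pair(obs, pred)
    if o.size < 3:
        raise ValueError("r_m2 metrics need at least 3 points")
    if scale:
        lo, hi = o.min(), o.max()
        if hi == lo:
            raise ValueError("constant observed values: scaling undefined")
        # both vectors scaled by the observed range
        o = (o - lo) / (hi - lo)
        p = (p - lo) / (hi - lo)
    r2 = _pearson_r2(o, p)
    r0_sq = _r0_squared(o, p)
    r0p_sq = _r0_squared(p, o)
    clamped = False

    def _rm(r0: float) -> float:
        nonlocal clamped
        rad = r2 - r0
        if rad < 0:
            clamped = True
            rad = 0.0
        return r2 * (1.0 - math.sqrt(rad))

    rm2 = _rm(r0_sq)
    rm2p = _rm(r0p_sq)
    return Rm2Result(
        rm2=rm2,
        rm2_prime=rm2p,
        rm2_avg=(rm2 + rm2p) / 2.0,
        delta_rm2=abs(rm2 - rm2p),
        radicand_clamped=clamped,
    )


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = math.sqrt(float(np.sum(ac**2)) * float(np.sum(bc**2)))
    if denom == 0:
        return 0.0
    return (float(np.sum(ac * bc)) / denom) ** 2


def r2_pred(obs_test, pred_test, train_mean: float) -> float:
    """External predictive r2 relative to the training-set observed mean."""
    o, p = _pair(obs_test, pred_test)
    if o.size < 1:
        raise ValueError("empty test set")
    denom = float(np.sum((o - train_mean) ** 2))
    if denom == 0:
        raise ValueError("zero denominator: test observations equal the training mean")
    return 1.0 - float(np.sum((o - p) ** 2)) / denom


def rmsep(obs_test, pred_test) -> float:
    """Root mean square error of external prediction."""
    o, p = _pair(obs_test, pred_test)
    if o.size == 0:
        raise ValueError("empty test set")
    return math.sqrt(float(np.mean((o - p) ** 2)))


@dataclass
class FoldReport:
    fold: int
    test_indices: np.ndarray
    r2_pred: float
    rmsep: float


def kfold_external(
    fit_fn: FitFn,
    X,
    Y,
    k_subsets: Union[int, str, Sequence[Sequence[int]]],
    seed: int = 0,
) -> list[FoldReport]:
    """External validation over a partition into k subsets.

    ``k_subsets`` is an integer k, a spec string like ``"6x4"`` (6 subsets
    of exactly 4 rows), or an explicit list of index groups covering every
    row exactly once.  Each fold trains on the complement and reports
    r2_pred (against that fold's training mean) and RMSEP on the held-out
    rows.  Partitioning is a seeded shuffle, deterministic for a seed.
    """
    x = np.asarray(X, dtype=float)
    y = np.asarray(Y, dtype=float).ravel()
    n = y.size
    if isinstance(k_subsets, str):
        k_str, size_str = k_subsets.lower().split("x")
        k, size = int(k_str), int(size_str)
        if k * size != n:
            raise ValueError(
                f"partition {k_subsets!r} does not cover {n} rows exactly"
            )
        order = np.random.default_rng(seed).permutation(n)
        groups = [order[i * size : (i + 1) * size] for i in range(k)]
    elif isinstance(k_subsets, int):
        k = k_subsets
        if not 2 <= k <= n:
            raise ValueError(f"k={k} outside 2..{n}")
        order = np.random.default_rng(seed).permutation(n)
        groups = [order[i::k] for i in range(k)]
    else:
        groups = [np.asarray(g, dtype=int) for g in k_subsets]
        flat = np.concatenate(groups) if groups else np.array([], dtype=int)
        if sorted(flat.tolist()) != list(range(n)):
            raise ValueError("explicit partition must cover every row exactly once")
    reports: list[FoldReport] = []
    for fold, test_idx in enumerate(groups):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        predictor = fit_fn(x[mask], y[mask])
        pred_test = np.asarray(predictor(x[test_idx])).ravel()
        reports.append(
            FoldReport(
                fold=fold,
                test_indices=np.asarray(test_idx),
                r2_pred=r2_pred(y[test_idx], pred_test, float(y[mask].mean()))
                if np.sum((y[test_idx] - y[mask].mean()) ** 2) > 0
                else float("nan"),
                rmsep=rmsep(y[test_idx], pred_test),
            )
        )
    return reports


@dataclass
class ValidationReport:
    """Bundle of quality/validation statistics for one model.

    Absent metrics stay ``None``; ``reference`` carries published values
    that this package's own recomputation does not reproduce (kept as
    metadata, never asserted).
    """

    n: Optional[int] = None
    p: Optional[int] = None
    df_convention: str = "n_minus_p_minus_1"
    r2: Optional[float] = None
    r2_adj: Optional[float] = None
    f_stat: Optional[float] = None
    std_error: Optional[float] = None
    press: Optional[float] = None
    sdep: Optional[float] = None
    q2: Optional[float] = None
    rm2: Optional[float] = None
    rm2_prime: Optional[float] = None
    rm2_avg: Optional[float] = None
    delta_rm2: Optional[float] = None
    r2_pred: Optional[float] = None
    rmsep: Optional[float] = None
    reference: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("r2", "r2_pred", "q2"):
            v = getattr(self, name)
            if v is not None and v > 1 + 1e-12:
                raise ValueError(f"{name} cannot exceed 1 (got {v})")
        for name in ("press", "sdep", "rmsep", "std_error"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative (got {v})")
        if self.rm2 is not None and self.rm2_prime is not None:
            expected = abs(self.rm2 - self.rm2_prime)
            if self.delta_rm2 is None:
                self.delta_rm2 = expected
            elif abs(self.delta_rm2 - expected) > 1e-12:
                raise ValueError("delta_rm2 must equal |rm2 - rm2_prime|")

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "n", "p", "df_convention", "r2", "r2_adj", "f_stat", "std_error",
                "press", "sdep", "q2", "rm2", "rm2_prime", "rm2_avg", "delta_rm2",
                "r2_pred", "rmsep",
            )
            if getattr(self, k) is not None
        }
        if self.reference:
            out["reference"] = dict(self.reference)
        return out
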