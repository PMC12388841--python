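"""Polynomial response-surface models in coded factors.

Four nested model families are supported for a three-factor experiment:

* ``linear``      — intercept + x1 + x2 + x3
* ``2fi``         — linear + the three two-factor interactions
* ``quadratic``   — 2fi + the three pure quadratic terms
* ``cubic``       — quadratic + x1*x2*x3 + the six xi^2*xj (i != j) terms

On a three-level design the pure cubes xi^3 are aliased with xi
(xi in {-1,0,1} implies xi^3 = xi), so they are excluded from the cubic
family; the full cubic is therefore a 20-term model, still estimable on
27 runs.

Fitting is ordinary least squares on the run means.  For a balanced design
with equal replication this gives the same coefficients as fitting the
replicate-level data, and R^2 is defined on the means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import DesignError, Factor, FactorialDataset, decode_point

__all__ = [
    "FAMILIES",
    "PolynomialModel",
    "StationaryPointResult",
    "SurfaceGrid",
    "term_names",
    "build_design_matrix",
    "fit_ols",
    "anova_table",
    "compare_models",
    "select_model",
    "stationary_point",
    "maximize_in_box",
    "surface_grid",
]

FAMILIES = ("linear", "2fi", "quadratic", "cubic")

_LINEAR = ["1", "x1", "x2", "x3"]
_2FI = _LINEAR + ["x1*x2", "x1*x3", "x2*x3"]
_QUAD = _2FI + ["x1^2", "x2^2", "x3^2"]
_CUBIC = _QUAD + ["x1*x2*x3", "x1^2*x2", "x1^2*x3", "x2^2*x1", "x2^2*x3", "x3^2*x1", "x3^2*x2"]

_TERMS: dict[str, list[str]] = {"linear": _LINEAR, "2fi": _2FI, "quadratic": _QUAD, "cubic": _CUBIC}

_TERM_FUNCS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "1": lambda X: np.ones(len(X)),
    "x1": lambda X: X[:, 0],
    "x2": lambda X: X[:, 1],
    "x3": lambda X: X[:, 2],
    "x1*x2": lambda X: X[:, 0] * X[:, 1],
    "x1*x3": lambda X: X[:, 0] * X[:, 2],
    "x2*x3": lambda X: X[:, 1] * X[:, 2],
    "x1^2": lambda X: X[:, 0] ** 2,
    "x2^2": lambda X: X[:, 1] ** 2,
    "x3^2": lambda X: X[:, 2] ** 2,
    "x1*x2*x3": lambda X: X[:, 0] * X[:, 1] * X[:, 2],
    "x1^2*x2": lambda X: X[:, 0] ** 2 * X[:, 1],
    "x1^2*x3": lambda X: X[:, 0] ** 2 * X[:, 2],
    "x2^2*x1": lambda X: X[:, 1] ** 2 * X[:, 0],
    "x2^2*x3": lambda X: X[:, 1] ** 2 * X[:, 2],
    "x3^2*x1": lambda X: X[:, 2] ** 2 * X[:, 0],
    "x3^2*x2": lambda X: X[:, 2] ** 2 * X[:, 1],
}


def term_names(family: str) -> list[str]:
    """Ordered monomial basis of a model family (coded factors)."""
    try:
        return list(_TERMS[family])
    except KeyError:
        raise DesignError(f"unknown model family {family!r}; expected one of {FAMILIES}") from None


def build_design_matrix(coded: np.ndarray, family: str) -> np.ndarray:
    """Evaluate the family's monomials at coded points (rows)."""
    coded = np.asarray(coded, dtype=float)
    if coded.ndim == 1:
        coded = coded[None, :]
    if coded.shape[0] < 1 or coded.shape[1] != 3:
        raise DesignError("coded points must be an (n, 3) array with n >= 1")
    return np.column_stack([_TERM_FUNCS[t](coded) for t in term_names(family)])


@dataclass
class PolynomialModel:
    """A fitted polynomial response surface on the coded scale."""

    family: str
    terms: list[str]
    beta: np.ndarray
    sse: float
    sst: float
    r2: float
    adj_r2: float
    df_resid: int
    factors: tuple[Factor, ...]

    def predict_coded(self, coded: np.ndarray) -> np.ndarray:
        X = build_design_matrix(np.atleast_2d(np.asarray(coded, dtype=float)), self.family)
        return X @ self.beta

    def predict_natural(self, natural: np.ndarray) -> np.ndarray:
        natural = np.atleast_2d(np.asarray(natural, dtype=float))
        centers = np.array([f.center for f in self.factors])
        halves = np.array([f.half_range for f in self.factors])
        return self.predict_coded((natural - centers) / halves)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "terms": self.terms,
            "beta": [float(b) for b in self.beta],
            "sse": self.sse,
            "sst": self.sst,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "df_resid": self.df_resid,
        }


def fit_ols(dataset: FactorialDataset, family: str) -> PolynomialModel:
    """Least-squares fit of one model family to the run means.

    Solved by SVD (``numpy.linalg.lstsq``); the design matrix must have full
    column rank, otherwise the aliased columns are named in the error.
    """
    X = build_design_matrix(dataset.coded_matrix(), family)
    y = dataset.response
    n, k = X.shape
    if n < k:
        raise DesignError(f"{family}: {k} terms but only {n} runs")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name columns whose removal restores full rank
        aliased = []
        for j in range(k):
            keep = [c for c in range(k) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                aliased.append(term_names(family)[j])
        raise DesignError(f"{family}: design matrix rank deficient; aliased terms {aliased}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    df_resid = n - k
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid if df_resid > 0 else float("nan")
    return PolynomialModel(
        family=family,
        terms=term_names(family),
        beta=beta,
        sse=sse,
        sst=sst,
        r2=r2,
        adj_r2=adj_r2,
        df_resid=df_resid,
        factors=dataset.factors,
    )


def anova_table(model: PolynomialModel, dataset: FactorialDataset) -> pd.DataFrame:
    """Regression / residual / total decomposition on the run means.

    The F statistic tests the whole regression (all non-intercept terms)
    against the residual; its p-value uses F(k, n - k - 1).
    """
    y = dataset.response
    n = len(y)
    k = len(model.terms) - 1  # non-intercept terms
    ss_total = model.sst
    ss_resid = model.sse
    ss_reg = ss_total - ss_resid
    df_reg, df_resid = k, model.df_resid
    ms_reg = ss_reg / df_reg if df_reg > 0 else float("nan")
    if df_resid >= 1:
        ms_resid = ss_resid / df_resid
        if ms_resid > 0:
            F = ms_reg / ms_resid
            p = float(stats.f.sf(F, df_reg, df_resid))
        else:  # perfect fit: F unbounded
            F, p = float("inf"), 0.0
    else:
        ms_resid, F, p = float("nan"), float("nan"), float("nan")
    return pd.DataFrame(
        {
            "source": ["regression", "residual", "total"],
            "SS": [ss_reg, ss_resid, ss_total],
            "df": [df_reg, df_resid, n - 1],
            "MS": [ms_reg, ms_resid, float("nan")],
            "F": [F, float("nan"), float("nan")],
            "p": [p, float("nan"), float("nan")],
        }
    )


def compare_models(
    dataset: FactorialDataset, families: Sequence[str] = FAMILIES
) -> list[PolynomialModel]:
    """Fit every family and rank by adjusted R^2 (descending).

    Ties break toward the smaller model.  The leading entry is the selected
    model.
    """
    fits = [fit_ols(dataset, fam) for fam in families]
    fits.sort(key=lambda m: (-m.adj_r2, len(m.terms)))
    return fits


def select_model(
    dataset: FactorialDataset,
    families: Sequence[str] = FAMILIES,
    alpha: float = 0.05,
) -> PolynomialModel:
    """Sequential model selection over the nested family ladder.

    Walks linear -> 2fi -> quadratic -> cubic and accepts a richer family
    only when its additional terms are jointly significant (partial F-test
    at ``alpha``).  This is the conventional sequential-sum-of-squares
    choice for factorial response surfaces; on near-quadratic data it picks
    the quadratic even when the cubic's adjusted R^2 is marginally higher.
    """
    ladder = [f for f in FAMILIES if f in families]
    if not ladder:
        raise DesignError("no known families given")
    current = fit_ols(dataset, ladder[0])
    for fam in ladder[1:]:
        if current.sse <= 1e-12 * max(current.sst, 1.0):  # already interpolates
            break
        candidate = fit_ols(dataset, fam)
        if candidate.df_resid < 1:
            break
        d_df = len(candidate.terms) - len(current.terms)
        ms_resid = candidate.sse / candidate.df_resid
        if ms_resid == 0:  # richer family interpolates: accept it
            current = candidate
            continue
        F = (current.sse - candidate.sse) / d_df / ms_resid
        if float(stats.f.sf(F, d_df, candidate.df_resid)) < alpha:
            current = candidate
    return current


@dataclass
class StationaryPointResult:
    coded: tuple[float, float, float]
    natural: tuple[float, float, float]
    predicted_response: float
    nature: str  # maximum | minimum | saddle
    inside_box: bool


def _quad_grad_hess(model: PolynomialModel) -> tuple[np.ndarray, np.ndarray]:
    b = {t: model.coef(t) for t in model.terms}
    g = np.array([b["x1"], b["x2"], b["x3"]])
    H = np.array(
        [
            [2 * b["x1^2"], b["x1*x2"], b["x1*x3"]],
            [b["x1*x2"], 2 * b["x2^2"], b["x2*x3"]],
            [b["x1*x3"], b["x2*x3"], 2 * b["x3^2"]],
        ]
    )
    return g, H


def stationary_point(model: PolynomialModel) -> StationaryPointResult:
    """Solve grad = 0 of a fitted quadratic and classify it by the Hessian."""
    if model.family != "quadratic":
        raise DesignError("stationary_point requires a quadratic model")
    g, H = _quad_grad_hess(model)
    if abs(np.linalg.det(H)) < 1e-12:
        raise DesignError("singular Hessian: no isolated stationary point; use maximize_in_box")
    xs = np.linalg.solve(H, -g)
    eig = np.linalg.eigvalsh(H)
    if np.all(eig < 0):
        nature = "maximum"
    elif np.all(eig > 0):
        nature = "minimum"
    else:
        nature = "saddle"
    pred = float(model.predict_coded(xs)[0])
    natural = decode_point(model.factors, xs)
    return StationaryPointResult(
        coded=tuple(float(v) for v in xs),
        natural=tuple(float(v) for v in natural),
        predicted_response=pred,
        nature=nature,
        inside_box=bool(np.all(np.abs(xs) <= 1.0)),
    )


def maximize_in_box(
    model: PolynomialModel,
    bounds: tuple[float, float] = (-1.0, 1.0),
    coarse: int = 101,
) -> StationaryPointResult:
    """Maximize the fitted surface over the coded box.

    Deterministic coarse grid search (``coarse`` points per axis, first
    maximum in lexicographic order on ties) followed by an L-BFGS-B polish
    within the bounds.
    """
    lo, hi = bounds
    axis = np.linspace(lo, hi, coarse)
    G1, G2, G3 = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([G1.ravel(), G2.ravel(), G3.ravel()])
    vals = model.predict_coded(pts)
    x0 = pts[int(np.argmax(vals))]  # argmax takes the first = lexicographic tie-break

    res = optimize.minimize(
        lambda x: -model.predict_coded(x)[0],
        x0,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * 3,
        options={"ftol": 1e-15, "gtol": 1e-12},
    )
    x = np.clip(res.x, lo, hi)
    pred = float(model.predict_coded(x)[0])
    # keep the grid point if the polish somehow lost ground
    if pred < float(vals.max()):
        x, pred = x0, float(vals.max())
    natural = decode_point(model.factors, x)
    inside = bool(np.all((x > lo + 1e-9) & (x < hi - 1e-9)))
    nature = "maximum" if inside else "boundary-maximum"
    return StationaryPointResult(
        coded=tuple(float(v) for v in x),
        natural=tuple(float(v) for v in natural),
        predicted_response=pred,
        nature=nature,
        inside_box=inside,
    )


@dataclass
class SurfaceGrid:
    """Predictions over two free coded axes with the third factor fixed."""

    fixed_factor: str
    fixed_value: float
    axis_names: tuple[str, str]
    axis1: np.ndarray
    axis2: np.ndarray
    predicted: np.ndarray  # shape (len(axis1), len(axis2))

    def to_frame(self) -> pd.DataFrame:
        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame(
            {"axis1": a1.ravel(), "axis2": a2.ravel(), "predicted": self.predicted.ravel()}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def surface_grid(
    model: PolynomialModel,
    fixed_factor: str,
    fixed_value: float = 0.0,
    resolution: int = 41,
    bounds: tuple[float, float] = (-1.0, 1.0),
) -> SurfaceGrid:
    """Response grid over the two factors not held fixed (coded scale)."""
    if resolution < 2:
        raise DesignError("resolution must be >= 2")
    names = [f.name for f in model.factors]
    if fixed_factor not in names:
        raise DesignError(f"unknown factor {fixed_factor!r}; have {names}")
    i_fixed = names.index(fixed_factor)
    free = [i for i in range(3) if i != i_fixed]
    axis = np.linspace(bounds[0], bounds[1], resolution)
    A1, A2 = np.meshgrid(axis, axis, indexing="ij")
    pts = np.empty((resolution * resolution, 3))
    pts[:, i_fixed] = fixed_value
    pts[:, free[0]] = A1.ravel()
    pts[:, free[1]] = A2.ravel()
    pred = model.predict_coded(pts).reshape(resolution, resolution)
    return SurfaceGrid(
        fixed_factor=fixed_factor,
        fixed_value=float(fixed_value),
        axis_names=(names[free[0]], names[free[1]]),
        axis1=axis.copy(),
        axis2=axis.copy(),
        predicted=pred,
    )
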