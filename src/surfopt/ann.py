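"""Small feed-forward surrogates trained with Levenberg-Marquardt.

The network is a 3-h-1 multilayer perceptron: three inputs (temperature,
time, ethanol fraction), one tanh hidden layer of ``h`` neurons, one linear
output (TAS).  Inputs are scaled to [-1, 1] by the design box, the output by
the data range.  Training minimizes the sum of squared residuals on the
training split with damped Gauss-Newton (LM) steps:

    (J'J + lambda I) delta = -J' r

where J is the analytic Jacobian of the residuals.  An accepted step divides
the damping ``lambda`` by a fixed factor, a rejected step multiplies it; the
accepted-step training SSE is therefore non-increasing.  Training stops at
``max_iter`` iterations, when the training SSE improves by less than
``tol``, or when the validation SSE has not improved for ``patience``
consecutive accepted steps; the returned weights are always the
validation-best ones.

The topology search repeats training from many random initializations
(re-drawing the 80/10/10 split each restart) for each hidden-layer size and
keeps, per size, the restart with the lowest all-data MSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .design import DesignError, Factor, FactorialDataset

__all__ = [
    "AffineScaler",
    "TrainConfig",
    "ANNModel",
    "MetricsReport",
    "SearchResult",
    "split_dataset",
    "lm_train",
    "train_on_dataset",
    "metrics",
    "topology_search",
]


@dataclass(frozen=True)
class AffineScaler:
    """Per-variable affine map onto [-1, 1] given (lo, hi) ranges."""

    lo: tuple[float, ...]
    hi: tuple[float, ...]

    def transform(self, x: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return 2.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo) - 1.0

    def inverse(self, z: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return lo + (np.asarray(z, dtype=float) + 1.0) * (hi - lo) / 2.0

    @staticmethod
    def from_box(factors: Sequence[Factor]) -> "AffineScaler":
        return AffineScaler(tuple(f.low for f in factors), tuple(f.high for f in factors))

    @staticmethod
    def from_data(y: np.ndarray) -> "AffineScaler":
        y = np.asarray(y, dtype=float)
        lo, hi = float(y.min()), float(y.max())
        if hi == lo:  # degenerate range: identity-width window around the value
            lo, hi = lo - 0.5, hi + 0.5
        return AffineScaler((lo,), (hi,))


@dataclass(frozen=True)
class TrainConfig:
    """LM training settings.

    ``learning_rate`` and ``momentum`` are recorded for provenance with the
    conventional value 0.5 but are not used: plain Levenberg-Marquardt has
    neither; its step size is governed by the damping schedule
    (``lambda0``, ``lambda_factor``).
    """

    max_iter: int = 500
    patience: int = 50
    tol: float = 1e-5
    lambda0: float = 1e-3
    lambda_factor: float = 10.0
    lambda_max: float = 1e10
    init_scale: float = 0.5
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    learning_rate: float = 0.5  # recorded, unused by LM
    momentum: float = 0.5  # recorded, unused by LM

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.patience < 1 or self.patience >= self.max_iter:
            raise ValueError("need 1 <= patience < max_iter")
        if min(self.tol, self.lambda0, self.lambda_factor, self.init_scale) <= 0:
            raise ValueError("tol, lambda0, lambda_factor, init_scale must be positive")


def split_dataset(
    n: int,
    fractions: tuple[float, float, float],
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint train/validation/test index split.

    Subset sizes are the largest-remainder rounding of ``n * fractions``
    (27 with (0.8, 0.1, 0.1) gives 21/3/3); membership is a deterministic
    function of the RNG state.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if n < 5:
        raise ValueError("need at least 5 runs to split")
    rng = np.random.default_rng(rng)
    quotas = np.array([n * f for f in fractions])
    sizes = np.floor(quotas).astype(int)
    rem = n - sizes.sum()
    order = np.argsort(-(quotas - sizes), kind="stable")
    for i in range(rem):
        sizes[order[i]] += 1
    perm = rng.permutation(n)
    i1, i2 = sizes[0], sizes[0] + sizes[1]
    return np.sort(perm[:i1]), np.sort(perm[i1:i2]), np.sort(perm[i2:])


def _unpack(p: np.ndarray, h: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    W1 = p[: 3 * h].reshape(h, 3)
    b1 = p[3 * h : 4 * h]
    w2 = p[4 * h : 5 * h]
    b2 = p[5 * h]
    return W1, b1, w2, b2


def _forward(p: np.ndarray, h: int, X: np.ndarray) -> np.ndarray:
    W1, b1, w2, b2 = _unpack(p, h)
    return np.tanh(X @ W1.T + b1) @ w2 + b2


def _jacobian(p: np.ndarray, h: int, X: np.ndarray) -> np.ndarray:
    """d(prediction)/d(params), one row per sample."""
    W1, b1, w2, b2 = _unpack(p, h)
    A = np.tanh(X @ W1.T + b1)  # (n, h)
    D = (1.0 - A * A) * w2  # (n, h): w2_j * tanh'
    n = len(X)
    J = np.empty((n, 5 * h + 1))
    J[:, : 3 * h] = (D[:, :, None] * X[:, None, :]).reshape(n, 3 * h)
    J[:, 3 * h : 4 * h] = D
    J[:, 4 * h : 5 * h] = A
    J[:, 5 * h] = 1.0
    return J


@dataclass
class ANNModel:
    """A trained 3-h-1 network with its scalers and split bookkeeping."""

    n_hidden: int
    params: np.ndarray  # packed (W1, b1, w2, b2)
    input_scaler: AffineScaler
    output_scaler: AffineScaler
    split: dict[str, np.ndarray]
    history: list[float]
    converged: bool
    seed: int | None = None
    val_history: list[float] = field(default_factory=list)

    def predict(self, natural: np.ndarray) -> np.ndarray:
        """Predicted response in original units at natural-unit inputs."""
        Xs = self.input_scaler.transform(np.atleast_2d(np.asarray(natural, dtype=float)))
        ys = _forward(self.params, self.n_hidden, Xs)
        return self.output_scaler.inverse(ys[:, None])[:, 0]

    def to_dict(self) -> dict:
        W1, b1, w2, b2 = _unpack(self.params, self.n_hidden)
        return {
            "format_version": 1,
            "n_hidden": self.n_hidden,
            "W1": W1.tolist(),
            "b1": b1.tolist(),
            "w2": w2.tolist(),
            "b2": float(b2),
            "input_scaler": {"lo": self.input_scaler.lo, "hi": self.input_scaler.hi},
            "output_scaler": {"lo": self.output_scaler.lo, "hi": self.output_scaler.hi},
            "split": {k: v.tolist() for k, v in self.split.items()},
            "converged": self.converged,
            "seed": self.seed,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @staticmethod
    def from_dict(d: dict) -> "ANNModel":
        h = int(d["n_hidden"])
        p = np.concatenate(
            [
                np.asarray(d["W1"], dtype=float).ravel(),
                np.asarray(d["b1"], dtype=float),
                np.asarray(d["w2"], dtype=float),
                [float(d["b2"])],
            ]
        )
        return ANNModel(
            n_hidden=h,
            params=p,
            input_scaler=AffineScaler(tuple(d["input_scaler"]["lo"]), tuple(d["input_scaler"]["hi"])),
            output_scaler=AffineScaler(tuple(d["output_scaler"]["lo"]), tuple(d["output_scaler"]["hi"])),
            split={k: np.asarray(v, dtype=int) for k, v in d["split"].items()},
            history=[],
            converged=bool(d.get("converged", True)),
            seed=d.get("seed"),
        )

    @staticmethod
    def load(path: str | Path) -> "ANNModel":
        return ANNModel.from_dict(json.loads(Path(path).read_text()))


def lm_train(
    Xs: np.ndarray,
    ys: np.ndarray,
    n_hidden: int,
    config: TrainConfig,
    rng: np.random.Generator | int,
    split: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    input_scaler: AffineScaler | None = None,
    output_scaler: AffineScaler | None = None,
) -> ANNModel:
    """Train one network on pre-scaled data.

    ``Xs``/``ys`` are already on the [-1, 1] scale; ``split`` holds
    (train, validation, test) index arrays into them (default: all rows
    train, no early stopping).
    """
    if not 1 <= n_hidden:
        raise ValueError("n_hidden must be >= 1")
    rng = np.random.default_rng(rng)
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if split is None:
        tr = np.arange(len(Xs))
        va = te = np.empty(0, dtype=int)
    else:
        tr, va, te = split
    Xtr, ytr = Xs[tr], ys[tr]
    Xva, yva = Xs[va], ys[va]

    h = n_hidden
    n_par = 5 * h + 1
    p = rng.uniform(-config.init_scale, config.init_scale, size=n_par)

    def sse_of(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
        r = _forward(params, h, X) - y
        return float(r @ r)

    lam = config.lambda0
    sse = sse_of(p, Xtr, ytr)
    history = [sse]
    converged = False
    best_val = sse_of(p, Xva, yva) if len(va) else np.inf
    val_history = [best_val] if len(va) else []
    best_p = p.copy()
    stall = 0

    for _ in range(config.max_iter):
        r = _forward(p, h, Xtr) - ytr
        J = _jacobian(p, h, Xtr)
        JtJ = J.T @ J
        Jtr_ = J.T @ r
        accepted = False
        while lam <= config.lambda_max:
            try:
                delta = np.linalg.solve(JtJ + lam * np.eye(n_par), -Jtr_)
            except np.linalg.LinAlgError:
                lam *= config.lambda_factor
                continue
            p_new = p + delta
            sse_new = sse_of(p_new, Xtr, ytr)
            if np.isfinite(sse_new) and sse_new < sse:
                accepted = True
                break
            lam *= config.lambda_factor
        if not accepted:  # damping exhausted: cannot descend further
            break
        p = p_new
        improvement = sse - sse_new
        sse = sse_new
        history.append(sse)
        lam = max(lam / config.lambda_factor, 1e-15)
        if len(va):
            val = sse_of(p, Xva, yva)
            val_history.append(val)
            if val < best_val:
                best_val = val
                best_p = p.copy()
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
        if improvement < config.tol:
            converged = True
            break

    final_p = best_p if len(va) else p
    return ANNModel(
        n_hidden=h,
        params=final_p,
        input_scaler=input_scaler or AffineScaler((-1.0,) * Xs.shape[1], (1.0,) * Xs.shape[1]),
        output_scaler=output_scaler or AffineScaler((-1.0,), (1.0,)),
        split={"train": tr, "validation": va, "test": te},
        history=history,
        converged=converged,
        val_history=val_history,
    )


def train_on_dataset(
    dataset: FactorialDataset,
    n_hidden: int,
    config: TrainConfig,
    rng: np.random.Generator | int,
) -> ANNModel:
    """Scale a factorial dataset, draw a fresh split, and train one network."""
    rng = np.random.default_rng(rng)
    in_sc = AffineScaler.from_box(dataset.factors)
    out_sc = AffineScaler.from_data(dataset.response)
    Xs = in_sc.transform(dataset.natural_matrix())
    ys = out_sc.transform(dataset.response[:, None])[:, 0]
    split = split_dataset(len(dataset), config.fractions, rng)
    return lm_train(Xs, ys, n_hidden, config, rng, split, in_sc, out_sc)


@dataclass(frozen=True)
class MetricsReport:
    """MSE, MAPE (%) and Pearson R on original-unit values."""

    mse: float
    mape: float
    r: float
    scope: str
    n: int


def metrics(model: ANNModel, dataset: FactorialDataset, scope: str = "all") -> MetricsReport:
    """Prediction-error metrics on one data scope.

    MSE = mean (e_i - p_i)^2 and MAPE = mean |e_i - p_i| / e_i * 100 with
    e_i observed and p_i predicted, both in original units.  R is the
    Pearson correlation of observed vs predicted (NaN when the observations
    are constant).
    """
    if scope == "all":
        idx = np.arange(len(dataset))
    else:
        try:
            idx = model.split[scope]
        except KeyError:
            raise ValueError(f"unknown scope {scope!r}") from None
    if len(idx) == 0:
        raise ValueError(f"scope {scope!r} is empty")
    e = dataset.response[idx]
    p = model.predict(dataset.natural_matrix()[idx])
    mse = float(np.mean((e - p) ** 2))
    if np.any(e == 0):
        raise ZeroDivisionError("MAPE undefined: observed value equal to zero")
    mape = float(np.mean(np.abs(e - p) / np.abs(e)) * 100.0)
    if len(e) < 2 or np.std(e) == 0 or np.std(p) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(e, p).statistic)
    return MetricsReport(mse=mse, mape=mape, r=r, scope=scope, n=len(idx))


@dataclass
class SearchResult:
    n_hidden: int
    report: MetricsReport
    model: ANNModel
    n_failures: int = 0


def topology_search(
    dataset: FactorialDataset,
    h_range: Iterable[int] = range(1, 21),
    restarts: int = 50,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> list[SearchResult]:
    """Multi-restart hidden-layer-size sweep.

    For each hidden size, training restarts from ``restarts`` independent
    seeded initializations (each with a freshly drawn 80/10/10 split); the
    restart with the lowest all-data MSE represents that size.  Results are
    ranked by that MSE, ties toward fewer neurons.  The whole sweep is a
    deterministic function of ``seed``.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    in_sc = AffineScaler.from_box(dataset.factors)
    out_sc = AffineScaler.from_data(dataset.response)
    Xs = in_sc.transform(dataset.natural_matrix())
    ys = out_sc.transform(dataset.response[:, None])[:, 0]
    n = len(dataset)

    results: list[SearchResult] = []
    for h in h_range:
        best: tuple[float, ANNModel] | None = None
        failures = 0
        for rep in range(restarts):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(h, rep)))
            split = split_dataset(n, config.fractions, rng)
            try:
                model = lm_train(Xs, ys, h, config, rng, split, in_sc, out_sc)
            except (np.linalg.LinAlgError, FloatingPointError):
                failures += 1
                continue
            model.seed = seed
            mse = metrics(model, dataset, "all").mse
            if best is None or mse < best[0]:
                best = (mse, model)
        if best is None:
            failures = restarts
            continue
        results.append(
            SearchResult(
                n_hidden=h,
                report=metrics(best[1], dataset, "all"),
                model=best[1],
                n_failures=failures,
            )
        )
    results.sort(key=lambda r: (r.report.mse, r.n_hidden))
    return results
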