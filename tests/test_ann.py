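"""Levenberg-Marquardt MLP training, metrics and the topology search."""

import numpy as np
import pytest

import surfopt as so
from surfopt.ann import (
    AffineScaler,
    MetricsReport,
    TrainConfig,
    _forward,
    _jacobian,
    lm_train,
    metrics,
    split_dataset,
    topology_search,
    train_on_dataset,
)
from surfopt.synthetic import GeneratorSpec, generate


# --- Jacobian ---------------------------------------------------------------


@pytest.mark.parametrize("h", [1, 2, 4, 7])
@pytest.mark.parametrize("seed", [0, 1])
def test_jacobian_matches_central_differences(h, seed):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, size=(9, 3))
    p = rng.uniform(-0.8, 0.8, size=5 * h + 1)
    J = _jacobian(p, h, X)
    eps = 1e-6
    J_fd = np.empty_like(J)
    for k in range(len(p)):
        dp = np.zeros_like(p)
        dp[k] = eps
        J_fd[:, k] = (_forward(p + dp, h, X) - _forward(p - dp, h, X)) / (2 * eps)
    assert np.allclose(J, J_fd, rtol=1e-5, atol=1e-7)


# --- splitting and scaling --------------------------------------------------


@pytest.mark.parametrize(
    "n, sizes",
    [(27, (21, 3, 3)), (10, (8, 1, 1)), (5, (4, 1, 0)), (100, (80, 10, 10))],
)
def test_split_sizes_largest_remainder(n, sizes):
    tr, va, te = split_dataset(n, (0.8, 0.1, 0.1), np.random.default_rng(0))
    assert (len(tr), len(va), len(te)) == sizes
    allidx = np.concatenate([tr, va, te])
    assert sorted(allidx) == list(range(n))


def test_split_deterministic_in_seed():
    a = split_dataset(27, (0.8, 0.1, 0.1), 42)
    b = split_dataset(27, (0.8, 0.1, 0.1), 42)
    for x, y in zip(a, b):
        assert np.array_equal(x, y)


def test_split_bad_fractions():
    with pytest.raises(ValueError):
        split_dataset(27, (0.8, 0.1, 0.2), 0)


def test_scaler_round_trip():
    sc = AffineScaler((30.0, 30.0, 0.0), (60.0, 60.0, 100.0))
    rng = np.random.default_rng(0)
    x = rng.uniform([30, 30, 0], [60, 60, 100], size=(50, 3))
    assert np.allclose(sc.inverse(sc.transform(x)), x, atol=1e-12)
    z = sc.transform(x)
    assert z.min() >= -1 - 1e-12 and z.max() <= 1 + 1e-12


# --- metrics ----------------------------------------------------------------


def _model_with_predictions(dataset, preds):
    """A stub model whose predict() returns fixed values (for metric math)."""

    class Stub:
        split = {"all": np.arange(len(dataset))}

        def predict(self, X):
            return np.asarray(preds, dtype=float)

    return Stub()


def test_metric_formulas():
    ds = generate(GeneratorSpec(noise_sd=0.0))
    sub = ds.table.iloc[:2].copy()
    sub["response_mean"] = [2.0, 4.0]
    ds2 = so.FactorialDataset(ds.factors, sub)
    rep = metrics(_model_with_predictions(ds2, [1.0, 2.0]), ds2, "all")
    assert rep.mse == pytest.approx(2.5)
    assert rep.mape == pytest.approx(50.0)


def test_metrics_perfect_prediction():
    ds = generate(GeneratorSpec(noise_sd=0.0, seed=3))
    rep = metrics(_model_with_predictions(ds, ds.response), ds, "all")
    assert rep.mse == 0.0
    assert rep.mape == 0.0
    assert rep.r == pytest.approx(1.0)


def test_metrics_zero_observation_flagged():
    ds = generate(GeneratorSpec(noise_sd=0.0))
    sub = ds.table.iloc[:2].copy()
    sub["response_mean"] = [0.0, 4.0]
    ds2 = so.FactorialDataset(ds.factors, sub)
    with pytest.raises(ZeroDivisionError):
        metrics(_model_with_predictions(ds2, [1.0, 2.0]), ds2, "all")


# --- training ---------------------------------------------------------------


def test_accepted_sse_history_non_increasing(fixture_dataset):
    model = train_on_dataset(fixture_dataset, 4, TrainConfig(), np.random.default_rng(0))
    hist = np.array(model.history)
    assert np.all(np.diff(hist) <= 1e-12)


def test_training_deterministic_in_seed(fixture_dataset):
    m1 = train_on_dataset(fixture_dataset, 3, TrainConfig(), np.random.default_rng(7))
    m2 = train_on_dataset(fixture_dataset, 3, TrainConfig(), np.random.default_rng(7))
    assert np.array_equal(m1.params, m2.params)
    for k in m1.split:
        assert np.array_equal(m1.split[k], m2.split[k])


def test_constant_response_reaches_zero_error():
    rng = np.random.default_rng(0)
    X = rng.uniform(-1, 1, size=(20, 3))
    y = np.zeros(20)
    model = lm_train(X, y, 2, TrainConfig(tol=1e-16), rng)
    mse = float(np.mean((_forward(model.params, 2, X) - y) ** 2))
    assert mse < 1e-10


def test_recovers_teacher_network():
    """Data generated by a 3-2-1 net is matched to near machine precision
    by at least one of 20 restarts."""
    rng = np.random.default_rng(11)
    teacher = rng.uniform(-1, 1, size=5 * 2 + 1)
    X = rng.uniform(-1, 1, size=(30, 3))
    y = _forward(teacher, 2, X)
    best = np.inf
    for rep in range(20):
        child = np.random.default_rng(np.random.SeedSequence(11, spawn_key=(rep,)))
        m = lm_train(X, y, 2, TrainConfig(), child)
        mse = float(np.mean((_forward(m.params, 2, X) - y) ** 2))
        best = min(best, mse)
    assert best < 1e-6


@pytest.mark.parametrize("seed", [0, 5, 9])
def test_validation_best_weights_returned(fixture_dataset, seed):
    """The returned weights score exactly the best validation SSE ever seen."""
    in_sc = AffineScaler.from_box(fixture_dataset.factors)
    out_sc = AffineScaler.from_data(fixture_dataset.response)
    Xs = in_sc.transform(fixture_dataset.natural_matrix())
    ys = out_sc.transform(fixture_dataset.response[:, None])[:, 0]
    rng = np.random.default_rng(seed)
    split = split_dataset(27, (0.8, 0.1, 0.1), rng)
    model = lm_train(Xs, ys, 6, TrainConfig(), rng, split, in_sc, out_sc)
    va = split[1]
    val_sse = float(np.sum((_forward(model.params, 6, Xs[va]) - ys[va]) ** 2))
    assert val_sse == pytest.approx(min(model.val_history), rel=1e-12)


# --- topology search --------------------------------------------------------


def test_more_restarts_never_worse(fixture_dataset):
    one = topology_search(fixture_dataset, [4], restarts=1, seed=9)[0].report.mse
    many = topology_search(fixture_dataset, [4], restarts=10, seed=9)[0].report.mse
    assert many <= one


def test_search_reproducible(fixture_dataset):
    a = topology_search(fixture_dataset, [3, 4], restarts=5, seed=2)
    b = topology_search(fixture_dataset, [3, 4], restarts=5, seed=2)
    assert [r.n_hidden for r in a] == [r.n_hidden for r in b]
    assert [r.report.mse for r in a] == [r.report.mse for r in b]


def test_linear_data_needs_one_neuron():
    beta = (3.0, 0.2, -0.2, 0.1, 0, 0, 0, 0, 0, 0)
    ds = generate(GeneratorSpec(true_beta=beta, noise_sd=0.0, seed=1))
    res = topology_search(ds, [1], restarts=30, config=TrainConfig(tol=1e-10), seed=4)
    assert res[0].report.mse < 1e-6


def test_model_json_round_trip(tmp_path, fixture_dataset):
    model = train_on_dataset(fixture_dataset, 3, TrainConfig(), np.random.default_rng(1))
    path = tmp_path / "ann.json"
    model.save(path)
    loaded = so.ANNModel.load(path)
    X = fixture_dataset.natural_matrix()
    assert np.allclose(loaded.predict(X), model.predict(X), atol=1e-12)
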