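import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from staplr.data import MultiViewDataset, ViewHierarchy
from staplr.glm import PenalizedLogisticModel, PenaltySpec
from staplr.stacking import StackedClassifier, StaplrConfig

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def random_instance(rng, n=None, p=None, correlated=True, signal=True):
    """A small random logistic-regression instance (no separation at these sizes)."""
    n = n or int(rng.integers(30, 60))
    p = p or int(rng.integers(2, 10))
    X = rng.standard_normal((n, p))
    if correlated:
        X = X @ (np.eye(p) + 0.4 * rng.random((p, p)))
    if signal:
        beta = rng.normal(scale=0.7, size=p)
        eta = X @ beta - np.median(X @ beta)
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    else:
        y = (rng.random(n) < 0.5).astype(float)
    if y.min() == y.max():
        y[: n // 3] = 1 - y[: n // 3]
    return X, y


def make_model(penalty, intercept, coefficients, names):
    return PenalizedLogisticModel(
        intercept=float(intercept),
        coefficients=np.asarray(coefficients, dtype=float),
        penalty=penalty,
        lambda_selected=0.1,
        feature_names=list(names),
    )


def build_stacked(hierarchy, base_coefs, node_coefs, ybar=0.4, cv_predictions=None):
    """Assemble a StackedClassifier from explicit coefficient settings.

    ``base_coefs``: leaf -> (intercept, coefficient vector);
    ``node_coefs``: internal node -> (intercept, child coefficient vector).
    """
    ridge = PenaltySpec(alpha=0.0)
    nnl = PenaltySpec(alpha=1.0, nonnegative=True, standardize=False)
    base_models = {}
    for leaf, (b0, coefs) in base_coefs.items():
        names = [f"{leaf}_f{j + 1}" for j in range(len(coefs))]
        base_models[leaf] = make_model(ridge, b0, coefs, names)
    node_models = {}
    for node, (b0, coefs) in node_coefs.items():
        node_models[node] = make_model(nnl, b0, coefs, hierarchy.children[node])
    return StackedClassifier(
        hierarchy=hierarchy,
        base_models=base_models,
        node_models=node_models,
        ybar=ybar,
        config=StaplrConfig(prediction_folds=2, lambda_folds=2),
        cv_predictions=cv_predictions or {},
    )


@pytest.fixture
def toy_depth3_model():
    """S = 2 branches with (2, 1) leaves; ω̂0 = −1, ω̂ = (2, 1);
    β̂0 = (−1, −0.5), β̂[1] = (3, 1), β̂[2] = (2,)."""
    hier = ViewHierarchy.from_nested({"root": {"s1": ["v11", "v12"], "s2": ["v21"]}})
    base = {leaf: (0.0, [1.0, -0.5]) for leaf in ["v11", "v12", "v21"]}
    nodes = {
        "root": (-1.0, [2.0, 1.0]),
        "s1": (-1.0, [3.0, 1.0]),
        "s2": (-0.5, [2.0]),
    }
    return build_stacked(hier, base, nodes, ybar=0.4)


@pytest.fixture
def tiny_dataset():
    """60 subjects, 3 leaf views under 2 branches, signal in one view."""
    from staplr.synthetic import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(
        n_subjects=60,
        views={"a": {"v1": 4, "v2": 3}, "b": {"v3": 5}},
        signal_views=("v1",),
        effect_size=2.5,
        rho=0.2,
        seed=7,
    )
    dataset, hierarchy, truth = generate_dataset(cfg)
    return dataset, hierarchy, truth


@pytest.fixture
def fast_staplr_config():
    return StaplrConfig(prediction_folds=3, lambda_folds=3, n_lambda=20, seed=0)
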