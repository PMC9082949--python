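"""Synthetic hierarchical multi-view binary-classification data with known
ground truth.

The generator emulates the structure of a multimodal neuroimaging study:
a small number of top-level branches (scan types), each holding several
leaf views (derived measures) of wildly unequal width, features correlated
within a view, a class-imbalanced binary outcome, and predictive signal
concentrated in a minority of leaf views.

Features of each leaf view follow an exchangeable-correlation Gaussian
factor model: x_ij = √ρ·u_v + √(1−ρ)·ε_ij with a shared per-view factor
u_v, giving within-view correlation exactly ρ. The outcome is drawn from a
latent logistic (optionally probit) model whose nonzero coefficients live
only in the designated signal views; each signal view's contribution to the
linear predictor is scaled to unit variance times ``effect_size``, so views
of very different widths carry comparable signal. The intercept is solved
numerically so the expected prevalence matches the configured class
balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .data import MultiViewDataset, ViewHierarchy
from .stacking import StackedClassifier, StaplrConfig, fit_staplr

logger = logging.getLogger("staplr")

__all__ = [
    "SyntheticConfig",
    "generate_dataset",
    "recovery_experiment",
    "three_scan_type_preset",
    "flat_eight_view_preset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth generating process for a hierarchical multi-view dataset.

    ``views`` maps either leaf view → width (a flat, depth-2 hierarchy) or
    branch → {leaf view → width} (depth 3). ``signal_views`` name the leaves
    that carry outcome signal; ``effect_size`` scales each signal view's
    (unit-variance) contribution to the latent linear predictor.
    ``class_balance`` is the expected class-1 proportion; the default 0.305
    mirrors a case–control imbalance of roughly 76:173. ``rho`` is the
    exchangeable within-view feature correlation.
    """

    n_subjects: int = 249
    views: Mapping = field(
        default_factory=lambda: {
            "branch_1": {"v1": 50, "v2": 15, "v3": 70},
            "branch_2": {"v4": 20, "v5": 20},
            "branch_3": {"v6": 5, "v7": 190, "v8": 12},
        }
    )
    signal_views: tuple = ("v1", "v3")
    effect_size: float = 2.0
    rho: float = 0.3
    class_balance: float = 0.305
    seed: int = 0
    link: str = "logit"
    feature_noise: str = "gaussian"  # or "t" for heavy tails (misspecified variant)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class balance must lie in (0, 1)")
        if self.link not in {"logit", "probit"}:
            raise ValueError(f"unknown link '{self.link}'")
        if self.feature_noise not in {"gaussian", "t"}:
            raise ValueError(f"unknown feature noise '{self.feature_noise}'")
        leaves = self.leaf_widths()
        if not leaves:
            raise ValueError("config defines no leaf views")
        if any(w < 1 for w in leaves.values()):
            raise ValueError("every view needs at least one feature")
        unknown = set(self.signal_views) - set(leaves)
        if unknown:
            raise ValueError(f"signal views not among the leaves: {sorted(unknown)}")
        if self.effect_size > 0 and not self.signal_views:
            raise ValueError("effect_size > 0 requires at least one signal view")

    def is_nested(self) -> bool:
        return any(isinstance(v, Mapping) for v in self.views.values())

    def leaf_widths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for k, v in self.views.items():
            if isinstance(v, Mapping):
                for leaf, w in v.items():
                    out[str(leaf)] = int(w)
            else:
                out[str(k)] = int(v)
        return out

    def hierarchy(self) -> ViewHierarchy:
        if self.is_nested():
            # mapping values may mix branches (nested mappings) and bare leaves
            spec: dict = {}
            for k, v in self.views.items():
                spec[str(k)] = [str(leaf) for leaf in v] if isinstance(v, Mapping) else None
            nested = {"root": spec}
        else:
            nested = {"root": [str(k) for k in self.views]}
        return ViewHierarchy.from_nested(nested)


def three_scan_type_preset(
    n_subjects: int = 150,
    effect_size: float = 2.0,
    seed: int = 0,
) -> SyntheticConfig:
    """A 3-branch, 5/4/31-leaf hierarchy with widths spanning 5 to 191,
    shaped like a multimodal MRI study (structural / diffusion / functional
    scan types) with the enormous voxel-wise views scaled down to desk size.
    Signal sits in three structural leaves."""
    functional = {}
    for i, w in enumerate(
        [19, 48, 19, 48, 19, 48, 19, 48, 5, 5, 5, 5, 12, 42, 12, 42]
        + [191] * 15
    ):
        functional[f"func_{i + 1:02d}"] = w
    views = {
        "structural": {
            "gray_matter_density": 48,
            "subcortical_volumes": 14,
            "cortical_thickness": 68,
            "cortical_area": 68,
            "cortical_curvature": 68,
        },
        "diffusion": {
            "fractional_anisotropy": 20,
            "mean_diffusivity": 20,
            "axial_diffusivity": 20,
            "radial_diffusivity": 20,
        },
        "functional": functional,
    }
    return SyntheticConfig(
        n_subjects=n_subjects,
        views=views,
        signal_views=("gray_matter_density", "subcortical_volumes", "cortical_thickness"),
        effect_size=effect_size,
        seed=seed,
    )


def flat_eight_view_preset(
    n_subjects: int = 300,
    effect_size: float = 3.0,
    seed: int = 0,
    signal_views: tuple = ("v1", "v3"),
) -> SyntheticConfig:
    """Eight leaf views directly under the root (the original two-level
    stacked shape), widths wildly unequal (5 to 80), signal in two views."""
    return SyntheticConfig(
        n_subjects=n_subjects,
        views={"v1": 80, "v2": 10, "v3": 50, "v4": 5, "v5": 20, "v6": 10, "v7": 40, "v8": 15},
        signal_views=signal_views,
        effect_size=effect_size,
        seed=seed,
    )


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[MultiViewDataset, ViewHierarchy, dict]:
    """Draw one dataset; fully reproducible from ``config.seed``.

    Returns the dataset, its hierarchy, and a ground-truth record holding
    the signal views, the true per-feature coefficients, the intercept and
    the latent linear predictor.
    """
    rng = np.random.default_rng(config.seed)
    widths = config.leaf_widths()
    n = config.n_subjects
    hierarchy = config.hierarchy()

    blocks, feature_ids, view_of_feature = [], [], []
    eta = np.zeros(n)
    true_coef: dict[str, float] = {}
    for view in hierarchy.leaves:
        w = widths[view]
        u = rng.standard_normal(n)
        if config.feature_noise == "t":
            eps = rng.standard_t(df=3, size=(n, w)) / np.sqrt(3.0)  # unit variance
        else:
            eps = rng.standard_normal((n, w))
        Xv = np.sqrt(config.rho) * u[:, None] + np.sqrt(1.0 - config.rho) * eps
        names = [f"{view}_f{j + 1}" for j in range(w)]
        if view in config.signal_views and config.effect_size > 0:
            # equal weights on all features; scaled so the view's contribution
            # to eta has variance effect_size**2 regardless of width
            mean_var = config.rho + (1.0 - config.rho) / w
            b = config.effect_size / (w * np.sqrt(mean_var))
            eta += Xv.sum(axis=1) * b
            for nm in names:
                true_coef[nm] = float(b)
        else:
            for nm in names:
                true_coef[nm] = 0.0
        blocks.append(Xv)
        feature_ids.extend(names)
        view_of_feature.extend([view] * w)

    link = expit if config.link == "logit" else norm.cdf

    def prevalence(b0: float) -> float:
        return float(np.mean(link(b0 + eta))) - config.class_balance

    intercept = brentq(prevalence, -40.0, 40.0)
    probs = link(intercept + eta)
    y = (rng.random(n) < probs).astype(int)
    # a one-class draw (vanishingly rare at realistic n) cannot form a dataset:
    # flip the subject with the most extreme probability
    if y.min() == y.max():
        flip = int(np.argmin(probs) if y[0] == 1 else np.argmax(probs))
        y[flip] = 1 - y[flip]
        logger.warning("single-class outcome draw; flipped subject %d", flip)

    dataset = MultiViewDataset(
        X=np.column_stack(blocks), y=y, feature_ids=feature_ids, view_of_feature=view_of_feature
    )
    ground_truth = {
        "signal_views": list(config.signal_views),
        "coefficients": true_coef,
        "intercept": float(intercept),
        "linear_predictor": eta,
        "probabilities": probs,
    }
    return dataset, hierarchy, ground_truth


def _leaf_selected(model: StackedClassifier, leaf: str) -> bool:
    """A leaf counts as selected when its immediate combiner coefficient is
    nonzero."""
    parent = model.hierarchy.parent[leaf]
    m = model.node_models[parent]
    return bool(m.coefficients[m.feature_names.index(leaf)] != 0.0)


def recovery_experiment(
    config: SyntheticConfig,
    n_seeds: int = 25,
    staplr_config: StaplrConfig | None = None,
    mrm_config=None,
    include_elastic_net: bool = False,
    elastic_net_config=None,
) -> dict:
    """Repeatedly generate data and fit the stacked model; report per-view
    selection frequencies, view-selection true/false positive rates, the
    per-view coefficient distribution and mean MRM of signal vs noise views.

    Optionally fits the flat elastic net on the same draws and reports its
    view-level inclusion rate (fraction of (fit, noise view) pairs with at
    least one nonzero coefficient) for comparison.
    """
    from .evaluation import EvaluationConfig, elastic_net_benchmark
    from .importance import MRMConfig, mrm_all

    staplr_config = staplr_config or StaplrConfig()
    mrm_config = mrm_config or MRMConfig()
    widths = config.leaf_widths()
    signal = set(config.signal_views)
    noise = [v for v in widths if v not in signal]
    sel_counts = {v: 0 for v in widths}
    coef_records: dict[str, list[float]] = {v: [] for v in widths}
    mrm_signal, mrm_noise = [], []
    enet_noise_inclusions = 0
    enet_noise_total = 0
    for k in range(n_seeds):
        cfg = replace(config, seed=_spawn_seed(config.seed, k))
        dataset, hierarchy, _ = generate_dataset(cfg)
        model = fit_staplr(dataset, hierarchy, replace(staplr_config, seed=cfg.seed))
        for v in hierarchy.leaves:
            parent = model.hierarchy.parent[v]
            m = model.node_models[parent]
            c = float(m.coefficients[m.feature_names.index(v)])
            coef_records[v].append(c)
            if c != 0.0:
                sel_counts[v] += 1
        mrm = mrm_all(model, dataset, mrm_config).table.set_index("view")["mrm"]
        mrm_signal.extend(mrm[v] for v in widths if v in signal)
        mrm_noise.extend(mrm[v] for v in noise)
        if include_elastic_net:
            ecfg = elastic_net_config or EvaluationConfig(
                learner="elastic_net", outer_folds=3, inner_folds=3, repeats=1,
                n_lambda=30, seed=cfg.seed,
            )
            eres = elastic_net_benchmark(dataset, ecfg)
            vs = eres.view_summary
            noise_rows = vs[vs["view"].isin(noise)]
            enet_noise_inclusions += int((noise_rows["n_nonzero"] > 0).sum())
            enet_noise_total += len(noise_rows)
    selection_frequency = {v: sel_counts[v] / n_seeds for v in widths}
    tpr = float(np.mean([selection_frequency[v] for v in signal])) if signal else float("nan")
    fpr = float(np.mean([selection_frequency[v] for v in noise])) if noise else float("nan")
    report = {
        "n_seeds": n_seeds,
        "selection_frequency": selection_frequency,
        "signal_selection_tpr": tpr,
        "noise_selection_fpr": fpr,
        "median_coefficient": {v: float(np.median(coef_records[v])) for v in widths},
        "mean_mrm_signal": float(np.mean(mrm_signal)) if mrm_signal else float("nan"),
        "mean_mrm_noise": float(np.mean(mrm_noise)) if mrm_noise else float("nan"),
    }
    if include_elastic_net:
        report["elastic_net_noise_view_inclusion_rate"] = (
            enet_noise_inclusions / enet_noise_total if enet_noise_total else float("nan")
        )
    return report


def _spawn_seed(base: int, k: int) -> int:
    return int(np.random.SeedSequence([int(base) % (2**31), k]).generate_state(1)[0] % (2**31))
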