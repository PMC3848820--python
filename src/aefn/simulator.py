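"""Synthetic multi-annotator data with full ground truth.

The generator mirrors the statistical structure the consensus model assumes:
instances are drawn from a K-component Gaussian mixture, hidden true labels
follow a logistic link on the features, and each annotator emits independent
Bernoulli labels governed by a per-component sensitivity/specificity pair.
Panels mixing a few experts with many novices (the regime where naive
aggregation breaks down, e.g. 90% novices / 10% experts) are first-class:
:func:`make_panel` draws expert accuracies from U(0.8, 0.95) per component and
pins novice ranking scores |α+β−1| at exactly 0, and
:func:`make_specialist_panel` builds panels whose members are expert-grade in
one component only — the regime where component-conditioned estimation pays.

Defaults (two well-separated components along the first feature axis, the
label signal carried by the second feature so classes stay balanced within
each component) are the reference study conditions used by the package's
recovery and comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .annotations_io import MISSING, AnnotationMatrix, FeatureMatrix
from .errors import ConfigError


@dataclass(frozen=True)
class AnnotatorSpec:
    """One annotator's role and true per-component accuracy.

    ``alpha[k]``/``beta[k]`` are the true sensitivity/specificity in
    component k. Experts satisfy |α+β−1| ≥ 0.5 in every component, novices
    |α+β−1| ≤ 0.1.
    """

    role: str
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.alpha, float))
        b = np.atleast_1d(np.asarray(self.beta, float))
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)
        if a.shape != b.shape:
            raise ConfigError("alpha and beta must have one entry per component")
        if ((a < 0) | (a > 1) | (b < 0) | (b > 1)).any():
            raise ConfigError("alpha and beta must lie in [0, 1]")
        s = np.abs(a + b - 1.0)
        if self.role == "expert" and (s < 0.5).any():
            raise ConfigError("expert specs need |alpha+beta-1| >= 0.5 per component")
        if self.role == "novice" and (s > 0.1 + 1e-12).any():
            raise ConfigError("novice specs need |alpha+beta-1| <= 0.1 per component")
        if self.role == "specialist":
            # expert-grade somewhere, novice-grade everywhere else
            if not (s >= 0.5).any() or not ((s >= 0.5) | (s <= 0.1 + 1e-12)).all():
                raise ConfigError("specialist specs need |alpha+beta-1| >= 0.5 in at "
                                  "least one component and <= 0.1 in the others")

    @property
    def score(self) -> np.ndarray:
        return np.abs(self.alpha + self.beta - 1.0)


def _default_means(k: int, d: int) -> np.ndarray:
    """Components spaced 6 units apart on the first feature axis (±3 for K=2)."""
    means = np.zeros((k, d))
    if k > 1:
        means[:, 0] = 6.0 * (np.arange(k) - (k - 1) / 2.0)
    return means


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``true_prior_weights`` is the d+1 logistic link (intercept last) that
    generates the hidden labels: P[y_i = 1] = σ(wᵀ[x_i, 1]). The default
    (0, 1.5, 0) puts the label signal on the second feature while components
    separate on the first, so each component holds a roughly balanced mix of
    classes. ``label_mode="component_rate"`` instead draws labels at a fixed
    per-component positive rate — a deliberate misspecification stress test.
    """

    n_instances: int = 2000
    n_features: int = 2
    n_components: int = 2
    component_means: np.ndarray | None = None
    component_covariances: np.ndarray | None = None
    component_weights: np.ndarray | None = None
    true_prior_weights: np.ndarray | None = None
    annotator_specs: tuple[AnnotatorSpec, ...] = ()
    missing_rate: float = 0.0
    label_mode: str = "logistic"
    component_positive_rates: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n, d, k = self.n_instances, self.n_features, self.n_components
        if n < 1 or d < 1 or k < 1:
            raise ConfigError("n_instances, n_features and n_components must be >= 1")
        means = (np.asarray(self.component_means, float)
                 if self.component_means is not None else _default_means(k, d))
        covs = (np.asarray(self.component_covariances, float)
                if self.component_covariances is not None
                else np.repeat(np.eye(d)[None], k, axis=0))
        weights = (np.asarray(self.component_weights, float)
                   if self.component_weights is not None else np.full(k, 1.0 / k))
        if self.true_prior_weights is not None:
            w = np.asarray(self.true_prior_weights, float)
        else:  # signal on the last feature, zero intercept
            w = np.zeros(d + 1)
            w[d - 1] = 1.5
        object.__setattr__(self, "component_means", means)
        object.__setattr__(self, "component_covariances", covs)
        object.__setattr__(self, "component_weights", weights)
        object.__setattr__(self, "true_prior_weights", w)
        object.__setattr__(self, "annotator_specs", tuple(self.annotator_specs))

        if means.shape != (k, d):
            raise ConfigError(f"component_means must have shape {(k, d)}")
        if covs.shape != (k, d, d):
            raise ConfigError(f"component_covariances must have shape {(k, d, d)}")
        if weights.shape != (k,) or abs(weights.sum() - 1.0) > 1e-10 or (weights < 0).any():
            raise ConfigError("component_weights must form a K-simplex")
        for kk in range(k):
            try:
                np.linalg.cholesky(covs[kk])
            except np.linalg.LinAlgError as exc:
                raise ConfigError(f"covariance {kk} is not positive-definite") from exc
        if w.shape != (d + 1,):
            raise ConfigError("true_prior_weights must have d+1 entries (intercept last)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.label_mode not in ("logistic", "component_rate"):
            raise ConfigError("label_mode must be 'logistic' or 'component_rate'")
        if self.label_mode == "component_rate":
            rates = np.asarray(self.component_positive_rates, float)
            if rates.shape != (k,) or ((rates < 0) | (rates > 1)).any():
                raise ConfigError("component_positive_rates must be K probabilities")
            object.__setattr__(self, "component_positive_rates", rates)
        for spec in self.annotator_specs:
            if spec.alpha.shape != (k,):
                raise ConfigError("each annotator spec needs one alpha/beta per component")


@dataclass(frozen=True)
class SimulationTruth:
    """A generated dataset plus everything needed for recovery tests."""

    features: FeatureMatrix
    components: np.ndarray
    y_true: np.ndarray
    annotations: AnnotationMatrix
    config: SimulationConfig

    @property
    def n(self) -> int:
        return len(self.y_true)

    def true_alpha_beta(self) -> tuple[np.ndarray, np.ndarray]:
        """True (K×R) sensitivity and specificity grids from the panel specs."""
        alpha = np.stack([s.alpha for s in self.config.annotator_specs], axis=1)
        beta = np.stack([s.beta for s in self.config.annotator_specs], axis=1)
        return alpha, beta


def make_panel(n_experts: int, n_novices: int, k: int, seed: int = 0
               ) -> tuple[AnnotatorSpec, ...]:
    """Draw an annotator panel of experts and novices.

    Experts draw α, β ~ U(0.8, 0.95) independently per component; novices draw
    α ~ U(0.45, 0.55) and take β = 1 − α, pinning the ranking score
    |α+β−1| at exactly 0 — a novice's labels carry no information about the
    truth, which makes the filter's target population unambiguous.
    """
    if n_experts < 1:
        raise ConfigError("need at least one expert")
    if n_novices < 0:
        raise ConfigError("n_novices must be non-negative")
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_experts):
        specs.append(AnnotatorSpec("expert", rng.uniform(0.8, 0.95, size=k),
                                   rng.uniform(0.8, 0.95, size=k)))
    for _ in range(n_novices):
        alpha = rng.uniform(0.45, 0.55, size=k)
        specs.append(AnnotatorSpec("novice", alpha, 1.0 - alpha))
    return tuple(specs)


def make_specialist_panel(n_annotators: int, k: int, seed: int = 0
                          ) -> tuple[AnnotatorSpec, ...]:
    """Panel where annotator quality is component-dependent.

    The first *k* annotators are specialists: annotator j is expert-grade
    (α, β ~ U(0.8, 0.95)) in component j and novice-grade (S = 0) in every
    other component; the rest are pure novices everywhere. Each component
    therefore contains exactly one expert-grade annotator and
    ``n_annotators − 1`` novice-grade ones — the regime in which
    component-conditioned accuracy estimation pays off, mirroring real
    predictor panels whose members are reliable only on parts of the data.
    """
    if n_annotators < k:
        raise ConfigError("need at least one specialist per component")
    rng = np.random.default_rng(seed)
    specs = []
    for j in range(k):
        alpha = rng.uniform(0.45, 0.55, size=k)
        beta = 1.0 - alpha
        alpha[j] = rng.uniform(0.8, 0.95)
        beta[j] = rng.uniform(0.8, 0.95)
        specs.append(AnnotatorSpec("specialist", alpha, beta))
    for _ in range(n_annotators - k):
        alpha = rng.uniform(0.45, 0.55, size=k)
        specs.append(AnnotatorSpec("novice", alpha, 1.0 - alpha))
    return tuple(specs)


def simulate_instances(config: SimulationConfig, rng: np.random.Generator | None = None
                       ) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Draw features from the mixture and hidden labels from the logistic link.

    Returns (features, component indices, y_true); deterministic under the
    config seed when no generator is passed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, d, k = config.n_instances, config.n_features, config.n_components
    comps = rng.choice(k, size=n, p=config.component_weights)
    x = np.empty((n, d))
    for kk in range(k):
        idx = np.flatnonzero(comps == kk)
        if idx.size:
            x[idx] = rng.multivariate_normal(config.component_means[kk],
                                             config.component_covariances[kk],
                                             size=idx.size)
    if config.label_mode == "logistic":
        p = expit(x @ config.true_prior_weights[:-1] + config.true_prior_weights[-1])
    else:
        p = config.component_positive_rates[comps]
    y_true = rng.random(n) < p
    features = FeatureMatrix(x, tuple(f"f{j + 1}" for j in range(d)),
                             tuple(f"i{i + 1:05d}" for i in range(n)))
    return features, comps, y_true


def simulate_annotations(y_true: np.ndarray, components: np.ndarray,
                         config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> AnnotationMatrix:
    """Draw each annotator's labels from its per-component confusion rates.

    y_i^j ~ Bernoulli(α_k^j) when y_i = 1 and Bernoulli(1 − β_k^j) when
    y_i = 0, with k the instance's true component. Cells are then masked at
    ``missing_rate``; if masking would leave an instance with no label at
    all, one randomly chosen cell is restored.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    specs = config.annotator_specs
    if not specs:
        raise ConfigError("config has no annotator specs")
    n = len(y_true)
    r = len(specs)
    labels = np.empty((n, r), dtype=np.int64)
    y = np.asarray(y_true, bool)
    for j, spec in enumerate(specs):
        p_one = np.where(y, spec.alpha[components], 1.0 - spec.beta[components])
        labels[:, j] = rng.random(n) < p_one
    if config.missing_rate > 0:
        mask = rng.random((n, r)) < config.missing_rate
        dead = mask.all(axis=1)
        if dead.any():  # keep the >=1-observed-label invariant
            restore = rng.integers(0, r, size=int(dead.sum()))
            mask[np.flatnonzero(dead), restore] = False
        labels[mask] = MISSING
    counts: dict[str, int] = {}
    ids = []
    for spec in specs:
        counts[spec.role] = counts.get(spec.role, 0) + 1
        ids.append(f"{spec.role}{counts[spec.role]}")
    return AnnotationMatrix(labels, tuple(f"i{i + 1:05d}" for i in range(n)), tuple(ids))


def simulate(config: SimulationConfig) -> SimulationTruth:
    """Generate a complete dataset (features, truth, annotations) from one seed."""
    rng = np.random.default_rng(config.seed)
    features, comps, y_true = simulate_instances(config, rng)
    ann = simulate_annotations(y_true, comps, config, rng)
    return SimulationTruth(features, comps, y_true, ann, config)
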