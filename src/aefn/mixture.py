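"""Gaussian-mixture fitting over instance features with BIC model selection.

The consensus algorithms condition annotator accuracy on the mixture component
that most plausibly generated each instance, so the first step of every
component-aware run is to find the best (K, covariance family) pair on the
feature table. Model order and family are selected jointly by BIC over a grid;
each candidate is fitted with several EM restarts driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

from .annotations_io import FeatureMatrix
from .config import FAMILIES
from .errors import DegenerateDataError, InputError

_SKLEARN_TYPE = {"spherical": "spherical", "diagonal": "diag",
                 "tied": "tied", "full": "full"}
_REG_COVAR = 1e-6  # diagonal jitter guarding small-N fits


@dataclass(frozen=True)
class MixtureModel:
    """A fitted K-component Gaussian mixture.

    Covariances are stored as full K×d×d matrices regardless of the family
    they were fitted under; ``family`` records the parameterization so runs
    remain auditable. ``bic_table`` keeps the score of every candidate tried.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    family: str
    bic: float
    seed: int
    bic_table: tuple = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        m = np.atleast_2d(np.asarray(self.means, float))
        c = np.asarray(self.covariances, float)
        if c.ndim == 2:
            c = c[None, :, :]
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "covariances", c)
        if abs(w.sum() - 1.0) > 1e-10 or (w < 0).any():
            raise InputError("mixture weights must form a simplex")
        if m.shape[0] != w.size or c.shape[0] != w.size:
            raise InputError("weights, means and covariances disagree on K")
        for k in range(w.size):
            ck = c[k]
            if not np.allclose(ck, ck.T, atol=1e-10):
                raise InputError(f"covariance {k} is not symmetric")
            try:
                np.linalg.cholesky(ck)
            except np.linalg.LinAlgError as exc:
                raise DegenerateDataError(
                    f"covariance {k} is not positive-definite") from exc

    @property
    def k(self) -> int:
        return int(self.weights.size)

    @property
    def d(self) -> int:
        return self.means.shape[1]


@dataclass(frozen=True)
class Responsibilities:
    """N×K posterior component-membership probabilities τ_ik."""

    tau: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, float)
        object.__setattr__(self, "tau", tau)
        if tau.ndim != 2 or (tau < 0).any():
            raise InputError("tau must be a non-negative 2-D grid")
        if np.abs(tau.sum(axis=1) - 1.0).max() > 1e-10:
            raise InputError("each tau row must sum to 1")


def _expand_covariances(gm: GaussianMixture, d: int) -> np.ndarray:
    cov = gm.covariances_
    k = gm.n_components
    if gm.covariance_type == "full":
        return cov
    if gm.covariance_type == "tied":
        return np.repeat(cov[None, :, :], k, axis=0)
    if gm.covariance_type == "diag":
        return np.stack([np.diag(cov[i]) for i in range(k)])
    # spherical: one variance per component
    return np.stack([np.eye(d) * cov[i] for i in range(k)])


def fit_mixture(features: FeatureMatrix | np.ndarray,
                k_range: tuple[int, int] = (1, 6),
                families: tuple[str, ...] = FAMILIES,
                restarts: int = 5,
                seed: int = 0) -> MixtureModel:
    """Select and fit the best Gaussian mixture by BIC over (K, family).

    Ties keep the smallest K and the earliest family in *families*; all EM
    restarts are driven deterministically from *seed*.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    n, d = x.shape
    lo, hi = int(k_range[0]), int(k_range[1])
    if lo < 1 or hi < lo:
        raise InputError("k_range must satisfy 1 <= low <= high")
    if n <= hi:
        raise InputError(f"need more instances ({n}) than the largest K ({hi})")
    if np.allclose(x, x[0], atol=0.0):
        raise DegenerateDataError("all feature rows identical; no mixture is identifiable")
    for fam in families:
        if fam not in _SKLEARN_TYPE:
            raise InputError(f"unknown covariance family {fam!r}")

    best = None
    table = []
    for k in range(lo, hi + 1):
        for fam in families:
            gm = GaussianMixture(
                n_components=k,
                covariance_type=_SKLEARN_TYPE[fam],
                n_init=restarts,
                reg_covar=_REG_COVAR,
                random_state=seed % (2 ** 31),
                max_iter=200,
            )
            try:
                gm.fit(x)
            except (ValueError, np.linalg.LinAlgError) as exc:
                raise DegenerateDataError(
                    f"mixture fit failed for K={k}, family={fam}: {exc}") from exc
            bic = float(gm.bic(x))
            table.append({"k": k, "family": fam, "bic": bic})
            if best is None or bic < best[0]:
                best = (bic, k, fam, gm)

    bic, k, fam, gm = best
    return MixtureModel(
        weights=gm.weights_,
        means=gm.means_,
        covariances=_expand_covariances(gm, d),
        family=fam,
        bic=bic,
        seed=seed,
        bic_table=tuple(tuple(row.items()) for row in table),
    )


def responsibilities(model: MixtureModel,
                     features: FeatureMatrix | np.ndarray) -> Responsibilities:
    """Posterior τ_ik ∝ weight_k · N(x_i | μ_k, Σ_k), rows normalized."""
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    x = np.atleast_2d(x)
    if x.shape[1] != model.d:
        raise InputError(f"feature dimension {x.shape[1]} != model dimension {model.d}")
    logp = np.empty((x.shape[0], model.k))
    for k in range(model.k):
        logp[:, k] = np.log(model.weights[k]) + multivariate_normal.logpdf(
            x, mean=model.means[k], cov=model.covariances[k])
    tau = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    tau /= tau.sum(axis=1, keepdims=True)
    return Responsibilities(tau)


def hard_component(tau: Responsibilities | np.ndarray) -> np.ndarray:
    """Per-instance component q_i = argmax_k τ_ik (ties → lowest index, 0-based)."""
    t = tau.tau if isinstance(tau, Responsibilities) else np.asarray(tau, float)
    return np.argmax(t, axis=1)
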