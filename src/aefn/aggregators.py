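"""Consensus-labelling algorithms for multi-annotator binary data.

Four estimators of the hidden true label share one iterative engine:

* **Majority voting (MV)** — the per-instance mean of observed labels; no
  model of annotator quality.
* **MAP-ML** — joint EM over a single global sensitivity α^j and specificity
  β^j per annotator and a logistic prior p_i = σ(wᵀx_i) on the features.
* **GMM-MAPML** — the same EM with annotator accuracy conditioned on the
  Gaussian-mixture component of each instance (α_k^j, β_k^j).
* **AEFN** — GMM-MAPML extended with per-component novice filtering: once
  the estimates have stabilized, any annotator whose ranking score
  S_k^j = |α_k^j + β_k^j − 1| falls below the pruning threshold ξ is removed
  permanently from that component's active set Λ_k, and the posterior is
  re-estimated from the surviving (expert) annotations only, repeating until
  no further annotator is removed.

Every iteration performs, in order: the ML update of (α, β), the logistic
prior refit, and the MAP update of the posterior z_i, stopping when
max_i |Δz_i| drops below the convergence tolerance; the filtering check runs
between convergence passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .annotations_io import AnnotationMatrix, FeatureMatrix
from .config import RunConfig
from .errors import AlignmentError, InputError
from .mixture import MixtureModel, Responsibilities, fit_mixture, hard_component, responsibilities

_CLAMP = 1e-6  # keeps α, β, p away from {0,1} so likelihood factors never vanish
_TINY = 1e-12


@dataclass(frozen=True)
class AnnotatorProfile:
    """Per-component annotator quality estimates.

    ``alpha[k, j]`` and ``beta[k, j]`` are the estimated sensitivity and
    specificity of annotator j within mixture component k, ``score`` the
    ranking score S_k^j = |α+β−1|, and ``active`` the membership of j in the
    component's good-annotator set Λ_k. ``alpha_flagged``/``beta_flagged``
    mark cells whose EM update had zero mass and fell back to 0.5.
    """

    alpha: np.ndarray
    beta: np.ndarray
    score: np.ndarray
    active: np.ndarray
    alpha_flagged: np.ndarray | None = None
    beta_flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, float)
        b = np.asarray(self.beta, float)
        act = np.asarray(self.active, bool)
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "score", np.asarray(self.score, float))
        object.__setattr__(self, "active", act)
        if not (a.shape == b.shape == act.shape == self.score.shape):
            raise InputError("alpha, beta, score and active must share a K×R shape")
        if ((a < 0) | (a > 1) | (b < 0) | (b > 1)).any():
            raise InputError("alpha and beta must lie in [0, 1]")
        if not act.any(axis=1).all():
            raise InputError("every component needs at least one active annotator")

    @property
    def k(self) -> int:
        return self.alpha.shape[0]

    @property
    def r(self) -> int:
        return self.alpha.shape[1]


@dataclass(frozen=True)
class ConsensusResult:
    """Output of a consensus run.

    ``z`` is the posterior P[y_i = 1], ``y_hat`` the thresholded hard label
    (z > γ), ``p`` the logistic prior σ(wᵀx_i), ``prior_weights`` the fitted
    w with the intercept last, and ``delta_trace`` the per-iteration
    max_i |Δz_i| values.
    """

    z: np.ndarray
    y_hat: np.ndarray
    p: np.ndarray
    prior_weights: np.ndarray | None
    iterations: int
    delta_trace: tuple
    gamma: float
    xi_prune: float
    epsilon_conv: float
    converged: bool
    prior_only: np.ndarray | None = None  # instances estimated from the prior alone


@dataclass(frozen=True)
class LikelihoodFactors:
    """Per-instance likelihood products a_i (positive branch) and b_i (negative)."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, float)
        b = np.asarray(self.b, float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if ((a <= 0) | (a > 1) | (b <= 0) | (b > 1)).any():
            raise InputError("likelihood factors must lie in (0, 1]")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def majority_vote_soft(ann: AnnotationMatrix) -> np.ndarray:
    """Soft majority vote: z_i = mean of the observed labels of instance i."""
    obs = ann.observed
    y = np.where(obs, ann.labels, 0)
    return y.sum(axis=1) / obs.sum(axis=1)


def majority_vote_hard(ann: AnnotationMatrix) -> np.ndarray:
    """Hard majority vote; an exact tie resolves to 0."""
    return majority_vote_soft(ann) > 0.5


def ranking_score(alpha, beta):
    """Ranking score S = |α + β − 1|.

    0 for a random annotator (α + β = 1), 1 for a perfect one. Accepts
    scalars or arrays.
    """
    a = np.asarray(alpha, float)
    b = np.asarray(beta, float)
    if ((a < 0) | (a > 1) | (b < 0) | (b > 1)).any():
        raise InputError("alpha and beta must lie in [0, 1]")
    s = np.abs(a + b - 1.0)
    return float(s) if np.isscalar(alpha) and np.isscalar(beta) else s


def update_alpha_beta(ann: AnnotationMatrix, z: np.ndarray, tau: Responsibilities,
                      active: np.ndarray) -> AnnotatorProfile:
    """ML update of per-component sensitivity and specificity.

    With z_ik = τ_ik · z_i (the joint responsibility of component k and a
    positive label),

        α_k^j = Σ_i z_ik y_i^j / Σ_i z_ik
        β_k^j = Σ_i (τ_ik − z_ik)(1 − y_i^j) / Σ_i (τ_ik − z_ik)

    where the sums run over instances whose label from annotator j is
    observed. A zero denominator (no positive or no negative mass in a
    component for that annotator) falls back to 0.5 and is flagged rather
    than raising. Estimates are clamped to [1e-6, 1−1e-6].
    """
    z = np.asarray(z, float)
    if ((z < 0) | (z > 1)).any():
        raise InputError("z must lie in [0, 1]")
    t = tau.tau if isinstance(tau, Responsibilities) else np.asarray(tau, float)
    active = np.asarray(active, bool)
    obs = ann.observed
    y = np.where(obs, ann.labels, 0).astype(float)

    zik = t * z[:, None]                       # N×K, joint responsibility
    wik = t - zik                              # τ_ik (1 − z_i)
    num_a = zik.T @ (obs * y)                  # K×R
    den_a = zik.T @ obs
    num_b = wik.T @ (obs * (1.0 - y))
    den_b = wik.T @ obs

    alpha_flagged = den_a <= _TINY
    beta_flagged = den_b <= _TINY
    alpha = np.where(alpha_flagged, 0.5, num_a / np.where(alpha_flagged, 1.0, den_a))
    beta = np.where(beta_flagged, 0.5, num_b / np.where(beta_flagged, 1.0, den_b))
    alpha = np.clip(alpha, _CLAMP, 1.0 - _CLAMP)
    beta = np.clip(beta, _CLAMP, 1.0 - _CLAMP)
    return AnnotatorProfile(alpha, beta, np.abs(alpha + beta - 1.0), active,
                            alpha_flagged, beta_flagged)


def filter_annotators(profile: AnnotatorProfile, xi_prune: float) -> AnnotatorProfile:
    """Deactivate active cells with S_k^j < ξ; never empties a component.

    If every active annotator of a component scores below ξ, the single
    highest-scoring one is retained so the posterior product stays defined.
    Deactivation is permanent: already-inactive cells are never revisited.
    """
    if not (0.0 <= xi_prune < 1.0):
        raise InputError("xi_prune must lie in [0, 1)")
    active = profile.active.copy()
    for k in range(profile.k):
        row = active[k]
        keep = row & (profile.score[k] >= xi_prune)
        if not keep.any():
            scores = np.where(row, profile.score[k], -np.inf)
            keep = np.zeros_like(row)
            keep[int(np.argmax(scores))] = True
        active[k] = keep
    return replace(profile, active=active)


def map_posterior(ann: AnnotationMatrix, profile: AnnotatorProfile, p: np.ndarray,
                  q: np.ndarray) -> tuple[np.ndarray, LikelihoodFactors]:
    """MAP update of the posterior z_i from the active annotators.

    For each instance, with k = q_i its hard component,

        a_i = Π_j α_k^j^{y_i^j} (1−α_k^j)^{1−y_i^j}
        b_i = Π_j (1−β_k^j)^{y_i^j} β_k^j^{1−y_i^j}
        z_i = a_i p_i / (a_i p_i + b_i (1−p_i))

    with the products over annotators that are active in component k and
    observed for instance i. An instance with no usable annotator falls back
    to its prior (z_i = p_i) and is flagged in the returned mask.
    """
    p = np.asarray(p, float)
    if ((p <= 0) | (p >= 1)).any():
        raise InputError("prior probabilities must lie strictly inside (0, 1)")
    q = np.asarray(q, int)
    obs = ann.observed
    y = np.where(obs, ann.labels, 0).astype(float)

    a_q = np.clip(profile.alpha[q], _CLAMP, 1.0 - _CLAMP)   # N×R
    b_q = np.clip(profile.beta[q], _CLAMP, 1.0 - _CLAMP)
    use = obs & profile.active[q]

    log_a = np.where(use, y * np.log(a_q) + (1.0 - y) * np.log1p(-a_q), 0.0).sum(axis=1)
    log_b = np.where(use, y * np.log1p(-b_q) + (1.0 - y) * np.log(b_q), 0.0).sum(axis=1)
    a = np.exp(log_a)
    b = np.exp(log_b)
    z = expit(log_a - log_b + logit(p))
    prior_only = ~use.any(axis=1)
    z = np.where(prior_only, p, z)
    return z, LikelihoodFactors(np.maximum(a, _TINY), np.maximum(b, _TINY))


def fit_prior(features: FeatureMatrix | np.ndarray, z: np.ndarray,
              l2: float = 1e-4, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Fit the logistic prior p_i = σ(wᵀx_i) to soft targets z.

    Maximizes the soft-label Bernoulli log-likelihood
    Σ_i [z_i log σ(wᵀx_i) + (1−z_i) log(1−σ(wᵀx_i))] − (l2/2)‖w‖², starting
    from w = 0 (a deterministic refit each call). An intercept column is
    appended last. Returns (w, p) with p clamped to [1e-6, 1−1e-6].
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    x = np.atleast_2d(x)
    z = np.asarray(z, float)
    if ((z < 0) | (z > 1)).any():
        raise InputError("z must lie in [0, 1]")
    xa = np.column_stack([x, np.ones(x.shape[0])])

    def objective(w):
        s = xa @ w
        # log(1 + e^s) − z s, computed stably
        nll = np.logaddexp(0.0, s).sum() - z @ s + 0.5 * l2 * (w @ w)
        grad = xa.T @ (expit(s) - z) + l2 * w
        return nll, grad

    res = minimize(objective, np.zeros(xa.shape[1]), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    if not res.success and "MAXITER" in str(res.message).upper():
        warnings.warn("prior fit did not converge; returning best iterate",
                      RuntimeWarning, stacklevel=2)
    w = res.x
    p = np.clip(expit(xa @ w), _CLAMP, 1.0 - _CLAMP)
    return w, p


# ---------------------------------------------------------------------------
# the shared iterative engine
# ---------------------------------------------------------------------------

def _check_aligned(ann: AnnotationMatrix, features: FeatureMatrix) -> None:
    if ann.n != features.n:
        raise AlignmentError(f"annotations have {ann.n} rows but features {features.n}")


def _engine(ann: AnnotationMatrix, features: FeatureMatrix, config: RunConfig,
            *, fit_gmm: bool, filtering: bool, log_fn=None):
    """Run the EM/MAP loop shared by MAP-ML, GMM-MAPML and AEFN.

    The loop alternates the ML update of (α, β), the logistic prior refit and
    the MAP posterior update until z stabilizes. When filtering is enabled,
    annotator quality is measured at the *fixed point* of the current active
    sets: once the inner loop converges, every component's active annotators
    with S below ξ are removed (permanently) and the loop resumes from the
    current z, repeating until a pass removes nobody. Filtering on converged
    scores rather than after a single refinement pass matters in
    novice-dominant panels, where one pass after the majority-vote
    initialization leaves the scores dominated by initialization noise.
    """
    _check_aligned(ann, features)
    n, r = ann.n, ann.r

    if fit_gmm:
        model = fit_mixture(features, k_range=config.k_range, families=config.families,
                            restarts=config.restarts, seed=config.seed)
        tau = responsibilities(model, features)
    else:  # MAP-ML: one global component, τ_i1 = 1
        model = None
        tau = Responsibilities(np.ones((n, 1)))
    k = tau.tau.shape[1]
    q = hard_component(tau)

    active = np.ones((k, r), dtype=bool)
    z = majority_vote_soft(ann)
    profile = AnnotatorProfile(np.full((k, r), 0.5), np.full((k, r), 0.5),
                               np.zeros((k, r)), active)
    w = None
    p = np.full(n, 0.5)
    prior_only = np.zeros(n, dtype=bool)
    delta_trace: list[float] = []
    converged = False
    iterations = 0

    for outer in range(k * r + 1):  # each pass after the first removes >=1 cell
        converged = False
        for it in range(config.max_iter):
            new = update_alpha_beta(ann, z, tau, active)
            # frozen estimates persist for filtered cells (reported, never updated)
            alpha = np.where(active, new.alpha, profile.alpha)
            beta = np.where(active, new.beta, profile.beta)
            profile = AnnotatorProfile(alpha, beta, np.abs(alpha + beta - 1.0), active,
                                       new.alpha_flagged, new.beta_flagged)
            w, p = fit_prior(features, z, l2=config.l2_prior)
            z_new, _ = map_posterior(ann, profile, p, q)
            prior_only = ~(ann.observed & profile.active[q]).any(axis=1)
            delta = float(np.max(np.abs(z_new - z)))
            delta_trace.append(delta)
            z = z_new
            iterations += 1
            if log_fn is not None:
                counts = " ".join(str(int(c)) for c in active.sum(axis=1))
                log_fn(f"iter={iterations} delta={delta:.3e} "
                       f"active_per_component=[{counts}]")
            if delta < config.epsilon_conv:
                converged = True
                break
        if not filtering or config.max_iter == 0:
            break
        pruned = filter_annotators(profile, config.xi_prune)
        if (pruned.active == active).all():
            break
        profile = pruned
        active = pruned.active
        if log_fn is not None:
            counts = " ".join(str(int(c)) for c in active.sum(axis=1))
            log_fn(f"filtered: active_per_component=[{counts}]")

    # Orientation convention: the likelihood is invariant under the global
    # label flip (z → 1−z, α ↔ 1−β, w → −w), so EM can converge to either
    # member of the mirror pair. Report the representative in which the
    # active annotators are informative (mean α+β−1 > 0) rather than
    # systematic inverters — the generative assumption of the model.
    info = np.mean(profile.alpha[active] + profile.beta[active] - 1.0)
    if info < 0:
        z = 1.0 - z
        p = 1.0 - p
        w = None if w is None else -w
        alpha, beta = 1.0 - profile.beta, 1.0 - profile.alpha
        profile = AnnotatorProfile(alpha, beta, np.abs(alpha + beta - 1.0), active,
                                   profile.beta_flagged, profile.alpha_flagged)
        if log_fn is not None:
            log_fn("orientation: mirrored (panel estimated anti-informative)")

    result = ConsensusResult(
        z=z, y_hat=z > config.gamma, p=p, prior_weights=w,
        iterations=iterations, delta_trace=tuple(delta_trace),
        gamma=config.gamma, xi_prune=config.xi_prune if filtering else 0.0,
        epsilon_conv=config.epsilon_conv, converged=converged,
        prior_only=prior_only,
    )
    return result, profile, model


def run_aefn(ann: AnnotationMatrix, features: FeatureMatrix,
             config: RunConfig | None = None, log_fn=None
             ) -> tuple[ConsensusResult, AnnotatorProfile, MixtureModel]:
    """Full consensus run with per-component novice filtering.

    Alternates converged sensitivity/specificity estimation with permanent
    removal of annotators scoring below ``config.xi_prune``, until no
    annotator is removed. Returns the consensus result, the final annotator
    profile (with the filtered cells deactivated) and the fitted mixture
    model. With ``xi_prune = 0`` the filter never fires and the run
    coincides exactly with :func:`run_gmm_mapml`.
    """
    config = config or RunConfig()
    return _engine(ann, features, config, fit_gmm=True, filtering=True, log_fn=log_fn)


def run_gmm_mapml(ann: AnnotationMatrix, features: FeatureMatrix,
                  config: RunConfig | None = None, log_fn=None) -> ConsensusResult:
    """Component-conditioned consensus without annotator filtering."""
    config = config or RunConfig()
    result, _, _ = _engine(ann, features, config, fit_gmm=True, filtering=False,
                           log_fn=log_fn)
    return result

def run_map_ml(ann: AnnotationMatrix, features: FeatureMatrix,
               config: RunConfig | None = None, log_fn=None) -> ConsensusResult:
    """Global (single-component) consensus: τ_i1 = 1 for every instance."""
    config = config or RunConfig()
    result, _, _ = _engine(ann, features, config, fit_gmm=False, filtering=False,
                           log_fn=log_fn)
    return result


def run_majority_vote(ann: AnnotationMatrix, gamma: float = 0.5) -> ConsensusResult:
    """Majority-vote baseline wrapped in the common result container."""
    z = majority_vote_soft(ann)
    return ConsensusResult(
        z=z, y_hat=z > gamma, p=np.full(ann.n, 0.5), prior_weights=None,
        iterations=0, delta_trace=(), gamma=gamma, xi_prune=0.0,
        epsilon_conv=0.0, converged=True,
    )
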