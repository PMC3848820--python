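"""Replicated simulation studies quantifying the consensus algorithms.

Each study runs the full pipeline (simulate → fit → measure) over seeded
replicates at the reference conditions: N=2000 instances, K=2 components,
10 annotators, 20 replicates. The mixture is fitted at the known order with
the full-covariance family and 3 restarts, which keeps a whole study within
a few minutes on one core without changing what is being measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .aggregators import (majority_vote_soft, run_aefn, run_gmm_mapml, run_map_ml)
from .config import RunConfig
from .evaluation import compare_label_sources, roc_auc
from .mixture import hard_component, responsibilities
from .simulator import (SimulationConfig, SimulationTruth, make_panel,
                        make_specialist_panel, simulate)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def _run_config(k: int, xi_prune: float, seed: int) -> RunConfig:
    return RunConfig(xi_prune=xi_prune, k_range=(k, k), families=("full",),
                     restarts=3, seed=seed)


def match_components(true_components: np.ndarray, hard_assignments: np.ndarray,
                     k: int) -> np.ndarray:
    """Map fitted component indices onto the generating ones.

    Solves the assignment problem maximizing the overlap of hard assignments
    with the true component ids; returns ``perm`` with
    ``perm[fitted_index] = true_index``.
    """
    overlap = np.zeros((k, k))
    for fitted in range(k):
        for true in range(k):
            overlap[fitted, true] = np.sum(
                (hard_assignments == fitted) & (true_components == true))
    rows, cols = linear_sum_assignment(-overlap)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm


def _simulate_panel(n_instances: int, n_experts: int, n_novices: int, k: int,
                    seed: int) -> SimulationTruth:
    panel = make_panel(n_experts, n_novices, k, seed=seed)
    cfg = SimulationConfig(n_instances=n_instances, n_components=k,
                           annotator_specs=panel, seed=seed)
    return simulate(cfg)


def _simulate_specialists(n_instances: int, n_annotators: int, k: int,
                          seed: int) -> SimulationTruth:
    panel = make_specialist_panel(n_annotators, k, seed=seed)
    cfg = SimulationConfig(n_instances=n_instances, n_components=k,
                           annotator_specs=panel, seed=seed)
    return simulate(cfg)


@dataclass(frozen=True)
class RecoveryResult:
    """Per-replicate and summary errors of the retained-annotator estimates."""

    mae_per_replicate: tuple
    mean_mae: float
    n_replicates: int
    n_instances: int


def parameter_recovery_study(n_replicates: int = 20, n_instances: int = 2000,
                             n_experts: int = 2, n_novices: int = 8, k: int = 2,
                             xi_prune: float = 0.3, seed: int = 0) -> RecoveryResult:
    """Mean absolute error of estimated α_k^j, β_k^j for retained annotators.

    Fitted components are matched to the generating ones by maximal-overlap
    assignment before comparing the K×R grids.
    """
    seeds = _child_seeds(seed, n_replicates)
    maes = []
    for s in seeds:
        truth = _simulate_panel(n_instances, n_experts, n_novices, k, s)
        result, profile, model = run_aefn(
            truth.annotations, truth.features, _run_config(k, xi_prune, s))
        q = hard_component(responsibilities(model, truth.features))
        perm = match_components(truth.components, q, k)
        alpha_true, beta_true = truth.true_alpha_beta()
        errs = []
        for fitted_k in range(k):
            true_k = perm[fitted_k]
            for j in range(profile.r):
                if profile.active[fitted_k, j]:
                    errs.append(abs(profile.alpha[fitted_k, j] - alpha_true[true_k, j]))
                    errs.append(abs(profile.beta[fitted_k, j] - beta_true[true_k, j]))
        maes.append(float(np.mean(errs)))
    return RecoveryResult(tuple(maes), float(np.mean(maes)), n_replicates, n_instances)


@dataclass(frozen=True)
class FilteringOutcome:
    """Filter behaviour of one replicate: expert retention and novice removal."""

    experts_retained: bool          # every expert active in every component
    novices_removed_min: int        # worst-case component's removed-novice count
    n_novices: int


@dataclass(frozen=True)
class OrderingResult:
    """AUC comparison of the four consensus strategies across replicates."""

    auc: dict                        # method -> per-replicate tuple
    mean_auc: dict                   # method -> float
    filtering: tuple                 # FilteringOutcome per replicate
    n_replicates: int
    n_instances: int

    @property
    def filtering_success_count(self) -> int:
        """Replicates whose every component kept all experts and shed >=8/9 novices."""
        return sum(1 for f in self.filtering
                   if f.experts_retained and f.novices_removed_min >= f.n_novices - 1)


def method_ordering_study(n_replicates: int = 20, n_instances: int = 2000,
                          n_annotators: int = 10, k: int = 2,
                          xi_prune: float = 0.3, seed: int = 0) -> OrderingResult:
    """Dominant-novice comparison of MV, MAP-ML, GMM-MAPML and the filtering run.

    Each replicate draws a specialist panel (every component holds exactly
    one expert-grade annotator and ``n_annotators − 1`` novice-grade ones,
    with annotator quality varying across components); the four methods then
    produce posterior scores for the same data and are scored by exact AUC
    against the simulated truth. The filtering run's final active sets are
    also recorded, so the same replicates measure per-component expert
    retention and novice removal.
    """
    seeds = _child_seeds(seed, n_replicates)
    auc: dict[str, list] = {m: [] for m in ("mv", "mapml", "gmm_mapml", "aefn")}
    filtering = []
    for s in seeds:
        truth = _simulate_specialists(n_instances, n_annotators, k, s)
        y = truth.y_true
        cfg = _run_config(k, xi_prune, s)

        auc["mv"].append(roc_auc(y, majority_vote_soft(truth.annotations)).auc)
        auc["mapml"].append(
            roc_auc(y, run_map_ml(truth.annotations, truth.features, cfg).z).auc)
        auc["gmm_mapml"].append(
            roc_auc(y, run_gmm_mapml(truth.annotations, truth.features, cfg).z).auc)
        result, profile, model = run_aefn(truth.annotations, truth.features, cfg)
        auc["aefn"].append(roc_auc(y, result.z).auc)

        # map fitted components onto generating ones, then check who survived
        q = hard_component(responsibilities(model, truth.features))
        perm = match_components(truth.components, q, k)
        alpha_true, beta_true = truth.true_alpha_beta()
        s_true = np.abs(alpha_true + beta_true - 1.0)       # K×R, generating scores
        experts_ok = True
        removed_min = None
        n_nov = 0
        for fitted_k in range(k):
            true_k = perm[fitted_k]
            expert_cols = np.flatnonzero(s_true[true_k] >= 0.5)
            novice_cols = np.flatnonzero(s_true[true_k] < 0.5)
            n_nov = len(novice_cols)
            if not profile.active[fitted_k, expert_cols].all():
                experts_ok = False
            removed = int((~profile.active[fitted_k, novice_cols]).sum())
            removed_min = removed if removed_min is None else min(removed_min, removed)
        filtering.append(FilteringOutcome(experts_ok, removed_min or 0, n_nov))
    return OrderingResult(
        auc={m: tuple(v) for m, v in auc.items()},
        mean_auc={m: float(np.mean(v)) for m, v in auc.items()},
        filtering=tuple(filtering),
        n_replicates=n_replicates, n_instances=n_instances,
    )


@dataclass(frozen=True)
class SourceComparisonResult:
    """Downstream-classifier AUCs for the three annotation strategies."""

    auc: dict                        # strategy -> per-replicate tuple
    mean_auc: dict
    n_replicates: int
    n_instances: int


def annotation_source_study(n_replicates: int = 20, n_instances: int = 2000,
                            n_annotators: int = 10, k: int = 2,
                            xi_prune: float = 0.3, seed: int = 0
                            ) -> SourceComparisonResult:
    """Replicated random / indicated / truth label-source comparison.

    Uses the specialist panels of :func:`method_ordering_study`, so the
    recommended annotator genuinely switches with the component.
    """
    seeds = _child_seeds(seed, n_replicates)
    auc: dict[str, list] = {s: [] for s in ("random", "indicated", "truth")}
    for s in seeds:
        truth = _simulate_specialists(n_instances, n_annotators, k, s)
        reports = compare_label_sources(truth, _run_config(k, xi_prune, s))
        for strategy, report in reports.items():
            auc[strategy].append(report.auc)
    return SourceComparisonResult(
        auc={m: tuple(v) for m, v in auc.items()},
        mean_auc={m: float(np.mean(v)) for m, v in auc.items()},
        n_replicates=n_replicates, n_instances=n_instances,
    )
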