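"""Run configuration shared by the consensus algorithms and the CLI."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import yaml

from .errors import ConfigError

ALGORITHMS = ("mv", "mapml", "gmm-mapml", "aefn")
FAMILIES = ("spherical", "diagonal", "tied", "full")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds, mixture settings and the single seed driving a run.

    Attributes
    ----------
    xi_prune
        Pruning threshold ξ on the ranking score S=|α+β−1|; annotators whose
        score drops below it are removed from a component's active set. 0
        disables filtering.
    gamma
        Decision threshold γ on the posterior z for the hard label.
    epsilon_conv
        Convergence tolerance on max_i |Δz_i| between successive iterations.
    k_range
        Inclusive (low, high) range of mixture orders searched by BIC.
    families
        Covariance parameterizations tried during model selection.
    """

    algorithm: str = "aefn"
    xi_prune: float = 0.3
    gamma: float = 0.5
    epsilon_conv: float = 1e-4
    max_iter: int = 100
    k_range: tuple[int, int] = (1, 6)
    families: tuple[str, ...] = FAMILIES
    restarts: int = 5
    l2_prior: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigError(f"unknown algorithm {self.algorithm!r}")
        if not (0.0 <= self.xi_prune < 1.0):
            raise ConfigError("xi_prune must lie in [0, 1)")
        if not (0.0 <= self.gamma <= 1.0):
            raise ConfigError("gamma must lie in [0, 1]")
        if self.epsilon_conv <= 0:
            raise ConfigError("epsilon_conv must be positive")
        if self.max_iter < 0:
            raise ConfigError("max_iter must be non-negative")
        lo, hi = self.k_range
        if lo < 1 or hi < lo:
            raise ConfigError("k_range must satisfy 1 <= low <= high")
        for fam in self.families:
            if fam not in FAMILIES:
                raise ConfigError(f"unknown covariance family {fam!r}")
        if self.restarts < 1:
            raise ConfigError("restarts must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        d["families"] = list(self.families)
        return d

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        if "families" in d:
            d["families"] = tuple(d["families"])
        known = cls.__dataclass_fields__.keys()
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = open(path).read()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))
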