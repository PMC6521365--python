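"""Run configuration for the data-quality evaluation pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable parameters of one evaluation run.

    Defaults follow the values used for the reference cohort analyses:
    alpha=0.8 and eps_mcd=0.99 for the MCD, eps_rpca=0.90 and tau=0.05 for
    the RPCA, lambda0 = 1/sqrt(max(n, p)) (``lam0=None``), and listing on
    two or more of the four multivariate approaches.
    """

    # MCD
    alpha: float = 0.8
    eps_mcd: float = 0.99
    n_sims: int = 100
    n_starts: int = 500
    max_subsets: int = 100_000
    pooling: str = "pooled"  # "pooled" | "per_sample" threshold percentile
    # RPCA
    eps_rpca: float = 0.90
    tau: float = 0.05
    lam0: float | None = None
    decay: float = 0.9
    ratio_orientation: str = "ls_over_xs"  # or "xs_over_ls"
    # aggregation
    min_flags: int = 2
    # randomness
    seed: int = 0
    seed_policy: str = "fixed"  # "fixed" | "per_iteration"

    def __post_init__(self) -> None:
        if not 0.5 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0.5, 1]")
        for name in ("eps_mcd", "eps_rpca", "tau"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.seed_policy not in ("fixed", "per_iteration"):
            raise ValueError("seed_policy must be 'fixed' or 'per_iteration'")
        if self.min_flags < 1:
            raise ValueError("min_flags must be at least 1")

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
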