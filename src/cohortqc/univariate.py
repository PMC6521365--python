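"""Per-variable outlier detectors: univariate MCD and boxplot fences.

These are the comparators used to show which errors only become visible when
variables are considered jointly.  The univariate MCD (uMCD) is the exact
one-dimensional specialization of the MCD: the h-point subset of minimal
variance is always contiguous in sort order, so a window scan over the sorted
values finds the global optimum.  Thresholding mirrors the multivariate
pipeline with normal (rather than multivariate normal) simulations.  Boxplot
fences are the classic 1.5*IQR whisker rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import PreparedDataset
from .mcd import (RobustLocationScatter, compute_h, consistency_factor,
                  outlyingness, simulate_threshold)

__all__ = ["UnivariateResult", "umcd_detect", "boxplot_detect",
           "univariate_screen"]

_ZERO_VAR_RTOL = 1e-12


@dataclass
class UnivariateResult:
    """One variable's univariate screening outcome."""

    variable: str
    method: str  # "umcd" | "boxplot"
    robust_center: float
    robust_spread: float
    lower_bound: float
    upper_bound: float
    flags: np.ndarray
    excluded: bool = False
    exclusion_reason: str | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def to_record(self) -> dict:
        return {
            "variable": self.variable,
            "method": self.method,
            "robust_center": self.robust_center,
            "robust_spread": self.robust_spread,
            "lower_bound": self.lower_bound,
            "upper_bound": self.upper_bound,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
            "n_flagged": 0 if self.excluded else self.n_flagged,
        }


def _min_variance_window(x: np.ndarray, h: int):
    """Start index and ML variance of the minimum-variance length-h window."""
    xs = np.sort(x, kind="stable")
    c1 = np.concatenate([[0.0], np.cumsum(xs)])
    c2 = np.concatenate([[0.0], np.cumsum(xs**2)])
    sums = c1[h:] - c1[:-h]
    sqsums = c2[h:] - c2[:-h]
    variances = np.maximum(sqsums / h - (sums / h) ** 2, 0.0)
    start = int(np.argmin(variances))  # first minimum on ties
    return xs, start, float(variances[start]), float(sums[start] / h)


def umcd_detect(x, alpha: float = 0.8, eps: float = 0.99, n_sims: int = 100,
                seed=None, variable: str = "x") -> UnivariateResult:
    """Exact 1-D MCD with normal-simulation threshold.

    Scans contiguous windows of length h over the sorted values for the
    minimum (ML) variance, applies the consistency factor, converts
    standardized distances |x - mu| / sigma to outlyingness and flags values
    beyond the simulated ``eps`` percentile.  A zero robust variance excludes
    the variable (the distance is undefined), mirroring how ties in the
    concentrated subset are handled in practice.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= 1:
        raise ValueError("need more than one observation")
    h = compute_h(n, 1, alpha)
    _, _, raw_var, mu = _min_variance_window(x, h)
    scale_ref = max(1.0, float(np.sqrt(np.mean(x**2))))
    if raw_var <= (_ZERO_VAR_RTOL * scale_ref) ** 2:
        return UnivariateResult(
            variable=variable, method="umcd", robust_center=mu,
            robust_spread=0.0, lower_bound=mu, upper_bound=mu,
            flags=np.zeros(n, dtype=bool), excluded=True,
            exclusion_reason=("robust variance of 0 within the concentrated "
                              "subset; Mahalanobis distance undefined"))
    c0 = consistency_factor(n, 1, h)
    sigma2 = c0 * raw_var
    sigma = float(np.sqrt(sigma2))
    est = RobustLocationScatter(
        location=np.array([mu]), scatter=np.array([[sigma2]]), h=h,
        alpha=alpha, c0=c0, subset_indices=np.arange(h), determinant=raw_var)
    # Same seed-spawning layout as detect_mcd so that p=1 multivariate runs
    # and uMCD runs share the threshold stream.
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    _, seed_thr = ss.spawn(2)
    thr = simulate_threshold(est, n, eps, n_sims=n_sims,
                             seed=np.random.default_rng(seed_thr))
    m = np.abs(x - mu) / sigma
    r = outlyingness(m)
    m_star = thr / (1.0 - thr)  # invert r = 1 - 1/(1+m) at the threshold
    return UnivariateResult(
        variable=variable, method="umcd", robust_center=mu,
        robust_spread=sigma, lower_bound=mu - m_star * sigma,
        upper_bound=mu + m_star * sigma, flags=r > thr,
        extras={"threshold": thr, "eps": eps, "h": h, "c0": c0,
                "outlyingness": r, "distances": m})


def boxplot_detect(x, variable: str = "x") -> UnivariateResult:
    """1.5*IQR fence rule with linear-interpolation (type 7) quartiles.

    Values strictly beyond Q1 - 1.5*IQR or Q3 + 1.5*IQR are flagged; a
    constant vector has IQR 0 and flags nothing.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 observations for quartiles")
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lower = q1 - 1.5 * iqr
    upper = q3 + 1.5 * iqr
    return UnivariateResult(
        variable=variable, method="boxplot", robust_center=float(q2),
        robust_spread=float(iqr), lower_bound=float(lower),
        upper_bound=float(upper), flags=(x < lower) | (x > upper),
        extras={"q1": float(q1), "q3": float(q3),
                "quartile_convention": "linear interpolation (type 7)"})


def univariate_screen(prepared: PreparedDataset, method: str = "umcd",
                      alpha: float = 0.8, eps: float = 0.99,
                      n_sims: int = 100, seed=None) -> list[UnivariateResult]:
    """Run a univariate detector over every column of a prepared dataset.

    With ``method="umcd"``, per-column seeds are spawned from ``seed`` so the
    whole screen is reproducible.
    """
    results = []
    if method == "umcd":
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        children = ss.spawn(prepared.p)
        for j, name in enumerate(prepared.variable_names):
            results.append(umcd_detect(prepared.values[:, j], alpha=alpha,
                                       eps=eps, n_sims=n_sims,
                                       seed=children[j], variable=name))
    elif method == "boxplot":
        for j, name in enumerate(prepared.variable_names):
            results.append(boxplot_detect(prepared.values[:, j], variable=name))
    else:
        raise ValueError(f"unknown univariate method {method!r}")
    return results
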