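"""Fast-MCD robust location/scatter estimation and Mahalanobis outlyingness.

The minimum covariance determinant (MCD) estimator is the mean and covariance
of the h-observation subset whose covariance matrix has minimal determinant,
with (n+p+1)/2 <= h <= n.  The fast-MCD algorithm approximates it by drawing
random (p+1)-point starting subsets and concentrating each with C-steps —
recompute robust distances from the current subset's mean/covariance, keep
the h closest observations — until the subset is a fixed point.  The C-step
never increases the determinant, so each start converges; the best fixed
point over all starts is kept.

Robust Mahalanobis distances m_i are mapped to the outlyingness statistic
r = 1 - 1/(1+m) in [0, 1), and the flagging threshold is the eps_mcd
percentile of outlyingness values simulated from multivariate normal draws
with the robust parameters.  The corr-max transformation partitions each
squared distance into p per-variable terms (sum w_ij^2 = m_i^2) that name
the variables driving each flagged participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .datasets import PreparedDataset

__all__ = [
    "DegenerateSubsetError",
    "RobustLocationScatter",
    "MCDResult",
    "compute_h",
    "mahalanobis_distances",
    "c_step",
    "fast_mcd",
    "consistency_factor",
    "outlyingness",
    "simulate_threshold",
    "corr_max_contributions",
    "detect_mcd",
]


class DegenerateSubsetError(ValueError):
    """A candidate subset has a singular covariance; the caller should redraw."""


def compute_h(n: int, p: int, alpha: float) -> int:
    """Subset size h for robustness parameter alpha in [0.5, 1].

    h = floor(2*m - n + 2*alpha*(n - m)) with m = floor((n+p+1)/2); alpha=1
    gives h=n (no trimming), alpha=0.5 gives the maximally robust h=m.
    """
    if not 0.5 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0.5, 1], got {alpha}")
    if n <= p:
        raise ValueError(
            f"MCD needs more observations than variables (n={n}, p={p}); "
            "the Mahalanobis distance is undefined otherwise")
    m = (n + p + 1) // 2
    h = int(np.floor(2 * m - n + 2 * alpha * (n - m)))
    return h


def _nameless(p: int) -> list[str]:
    return [f"var{j}" for j in range(p)]


def _singularity_message(sigma: np.ndarray, variable_names=None) -> str:
    names = variable_names or _nameless(sigma.shape[0])
    w, v = np.linalg.eigh(sigma)
    loadings = np.abs(v[:, 0])
    top = np.argsort(loadings)[::-1][:3]
    involved = [names[j] for j in top if loadings[j] > 0.1 * loadings.max()]
    return (f"covariance matrix is singular or not positive definite "
            f"(smallest eigenvalue {w[0]:.3g}); near-collinear variables: "
            f"{involved}")


def mahalanobis_distances(X, location, scatter, variable_names=None) -> np.ndarray:
    """Robust distances sqrt((x-mu)' Sigma^-1 (x-mu)) via Cholesky solve."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    location = np.asarray(location, dtype=float)
    scatter = np.asarray(scatter, dtype=float)
    diff = X - location
    try:
        factor = sla.cho_factor(scatter, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise np.linalg.LinAlgError(
            _singularity_message(scatter, variable_names)) from exc
    except sla.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            _singularity_message(scatter, variable_names)) from exc
    solved = sla.cho_solve(factor, diff.T)
    d2 = np.einsum("ij,ji->i", diff, solved)
    return np.sqrt(np.maximum(d2, 0.0))


def _subset_stats(X: np.ndarray, subset: np.ndarray):
    """Mean, ML covariance and its Cholesky factor for a row subset."""
    sub = X[subset]
    mu = sub.mean(axis=0)
    centered = sub - mu
    cov = centered.T @ centered / len(subset)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise DegenerateSubsetError("subset covariance is singular") from None
    # rounding can let an exactly singular matrix through: check the smallest
    # conditional variance (squared Cholesky diagonal) against the scale
    scale = np.diag(cov).max()
    if scale <= 0 or np.diag(chol).min() ** 2 <= 1e-12 * scale:
        raise DegenerateSubsetError("subset covariance is singular")
    return mu, cov, chol


def _chol_distances(X: np.ndarray, mu: np.ndarray, chol: np.ndarray) -> np.ndarray:
    z = sla.solve_triangular(chol, (X - mu).T, lower=True)
    return np.sqrt(np.einsum("ji,ji->i", z, z))


def c_step(X: np.ndarray, subset, h: int | None = None) -> np.ndarray:
    """One concentration step: keep the h rows closest to the subset estimate.

    Ties in the distance ranking are broken by row order so the algorithm is
    deterministic.  The determinant of the new subset's covariance never
    exceeds the old one's.
    """
    X = np.asarray(X, dtype=float)
    subset = np.asarray(subset, dtype=int)
    if h is None:
        h = len(subset)
    mu, _, chol = _subset_stats(X, subset)
    d = _chol_distances(X, mu, chol)
    keep = np.argsort(d, kind="stable")[:h]
    return np.sort(keep)


def consistency_factor(n: int, p: int, h: int) -> float:
    """Multiplier making the trimmed covariance consistent under normality.

    c0 = (h/n) / F_{chi2(p+2)}(chi2(p) quantile of h/n); equals 1 at h=n and
    exceeds 1 whenever observations are trimmed.
    """
    if not (n + p + 1) / 2 - 1 <= h <= n:
        raise ValueError(f"h={h} outside the admissible range for n={n}, p={p}")
    if h == n:
        return 1.0
    q = h / n
    return float(q / stats.chi2.cdf(stats.chi2.ppf(q, p), p + 2))


@dataclass
class RobustLocationScatter:
    """MCD-robust mean and covariance with the concentration bookkeeping.

    ``scatter`` already includes the consistency factor ``c0``;
    ``determinant`` is the determinant of the pre-c0 subset covariance.
    """

    location: np.ndarray
    scatter: np.ndarray
    h: int
    alpha: float
    c0: float
    subset_indices: np.ndarray
    determinant: float

    @property
    def p(self) -> int:
        return self.location.shape[0]


def fast_mcd(X, alpha: float = 0.8, n_starts: int = 500,
             max_subsets: int = 100_000, seed=None,
             max_csteps: int = 100) -> RobustLocationScatter:
    """Approximate the MCD by concentrating random (p+1)-point starts.

    Each start grows until its covariance is nonsingular, then C-steps run to
    a fixed point; the fixed point with the globally minimal determinant wins
    (first found kept on ties).  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    h = compute_h(n, p, alpha)
    rng = np.random.default_rng(seed)

    if h == n:
        subset = np.arange(n)
        mu, cov, chol = _subset_stats(X, subset)
        det = float(np.prod(np.diag(chol)) ** 2)
        return RobustLocationScatter(mu, cov, h, alpha, 1.0, subset, det)

    n_starts = min(n_starts, max_subsets)
    best_det = np.inf
    best_subset = None
    n_degenerate = 0
    for _ in range(n_starts):
        order = rng.permutation(n)
        size = p + 1
        try:
            # grow the start until its covariance supports a distance ranking
            while True:
                try:
                    subset = np.sort(order[:size])
                    current = c_step(X, subset, h)
                    break
                except DegenerateSubsetError:
                    size += 1
                    if size > n:
                        raise
            for _ in range(max_csteps):
                nxt = c_step(X, current, h)
                if np.array_equal(nxt, current):
                    break
                current = nxt
            _, _, chol = _subset_stats(X, current)
        except DegenerateSubsetError:
            n_degenerate += 1
            continue
        det = float(np.prod(np.diag(chol)) ** 2)
        if det < best_det:
            best_det = det
            best_subset = current
    if best_subset is None:
        raise ValueError(
            f"all {n_starts} starts were degenerate: data rank-deficient")

    mu, cov, _ = _subset_stats(X, best_subset)
    c0 = consistency_factor(n, p, h)
    return RobustLocationScatter(mu, c0 * cov, h, alpha, c0, best_subset,
                                 best_det)


def outlyingness(m) -> np.ndarray:
    """Map distances to r = 1 - 1/(1+m), a strictly increasing [0,1) score."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("distances must be nonnegative")
    return 1.0 - 1.0 / (1.0 + m)


def simulate_threshold(est: RobustLocationScatter, n: int, eps_mcd: float,
                       n_sims: int = 100, seed=None,
                       pooling: str = "pooled") -> float:
    """Monte-Carlo outlyingness threshold under the robust normal model.

    Draws ``n_sims`` multivariate normal samples of size ``n`` with the
    robust mean and covariance, scores every simulated observation's
    outlyingness against the same parameters, and returns the ``eps_mcd``
    empirical percentile — of the pooled values by default, or the mean of
    per-sample percentiles with ``pooling="per_sample"``.
    """
    if not 0 < eps_mcd <= 1:
        raise ValueError(f"eps_mcd must be in (0, 1], got {eps_mcd}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chol = np.linalg.cholesky(est.scatter)
    z = rng.standard_normal((n_sims * n, est.p))
    sims = z @ chol.T + est.location
    r = outlyingness(mahalanobis_distances(sims, est.location, est.scatter))
    if pooling == "pooled":
        return float(np.quantile(r, eps_mcd))
    if pooling == "per_sample":
        per = np.quantile(r.reshape(n_sims, n), eps_mcd, axis=1)
        return float(per.mean())
    raise ValueError(f"unknown pooling {pooling!r}")


def corr_max_contributions(X, est: RobustLocationScatter,
                           variable_names=None) -> np.ndarray:
    """Partition each squared robust distance into p per-variable terms.

    With D = diag(1/sqrt(diag(Sigma))), the transformation C =
    (D Sigma D)^(-1/2) D (symmetric matrix square root) maps deviations
    x_i - mu to contribution vectors w_i whose squared entries sum to m_i^2.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sigma = est.scatter
    d = 1.0 / np.sqrt(np.diag(sigma))
    corr = sigma * np.outer(d, d)
    w, v = np.linalg.eigh(corr)
    if w[0] <= 0:
        raise np.linalg.LinAlgError(_singularity_message(sigma, variable_names))
    inv_sqrt = (v / np.sqrt(w)) @ v.T
    transform = inv_sqrt * d[np.newaxis, :]  # C = (D Sigma D)^(-1/2) D
    return (X - est.location) @ transform.T


@dataclass
class MCDResult:
    """Per-participant MCD outlyingness, flags and ranked contributions."""

    ids: list[str]
    variable_names: list[str]
    distances: np.ndarray
    outlyingness: np.ndarray
    threshold: float
    eps_mcd: float
    flags: np.ndarray
    contributions: np.ndarray
    estimator: RobustLocationScatter
    dropped_variables: list[str]

    method = "mcd"

    @property
    def flagged_ids(self) -> list[str]:
        return [pid for pid, f in zip(self.ids, self.flags) if f]

    def ranked_contributions(self, participant, top: int | None = None):
        """Variables ranked by absolute corr-max contribution, descending."""
        i = participant if isinstance(participant, int) else self.ids.index(participant)
        w = self.contributions[i]
        order = np.argsort(-np.abs(w), kind="stable")
        if top is not None:
            order = order[:top]
        return [(self.variable_names[j], float(w[j])) for j in order]

    def to_records(self, top: int = 5) -> list[dict]:
        return [
            {
                "id": pid,
                "distance": float(self.distances[i]),
                "outlyingness": float(self.outlyingness[i]),
                "flag": bool(self.flags[i]),
                "top_contributions": self.ranked_contributions(i, top=top),
            }
            for i, pid in enumerate(self.ids)
        ]


def _active_columns(prepared: PreparedDataset) -> list[int]:
    keep = [j for j, name in enumerate(prepared.variable_names)
            if name not in prepared.constant_columns]
    if len(keep) < prepared.p:
        dropped = [n for n in prepared.variable_names
                   if n in prepared.constant_columns]
        warnings.warn(
            f"dropping constant columns from multivariate detection "
            f"(covariance would be singular): {dropped}", stacklevel=3)
    return keep


def detect_mcd(prepared: PreparedDataset, alpha: float = 0.8,
               eps_mcd: float = 0.99, n_sims: int = 100, n_starts: int = 500,
               max_subsets: int = 100_000, seed=None,
               pooling: str = "pooled") -> MCDResult:
    """Full MCD pipeline: fast-MCD, distances, threshold, flags, contributions.

    ``seed`` drives both the subset search and the threshold simulation via
    independent spawned streams, so results are reproducible from
    (data, parameters, seed).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_search, seed_thr = ss.spawn(2)
    keep = _active_columns(prepared)
    names = [prepared.variable_names[j] for j in keep]
    X = prepared.values[:, keep]
    est = fast_mcd(X, alpha=alpha, n_starts=n_starts, max_subsets=max_subsets,
                   seed=seed_search)
    m = mahalanobis_distances(X, est.location, est.scatter, names)
    r = outlyingness(m)
    thr = simulate_threshold(est, prepared.n, eps_mcd, n_sims=n_sims,
                             seed=np.random.default_rng(seed_thr),
                             pooling=pooling)
    contributions = corr_max_contributions(X, est, names)
    return MCDResult(
        ids=list(prepared.ids),
        variable_names=names,
        distances=m,
        outlyingness=r,
        threshold=thr,
        eps_mcd=eps_mcd,
        flags=r > thr,
        contributions=contributions,
        estimator=est,
        dropped_variables=[n for n in prepared.variable_names if n not in names],
    )
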