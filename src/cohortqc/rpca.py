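"""Robust PCA: low-rank + sparse decomposition with a sparsity target.

Principal component pursuit splits a data matrix X into a low-rank part L
(nuclear-norm penalty) and a sparse part S (elementwise l1 penalty with
weight lambda): min ||L||_* + lambda * ||S||_1 subject to X = L + S.  The
solver alternates singular-value soft-thresholding (towards L) with
elementwise soft-thresholding of the residual (towards S) inside an inexact
augmented-Lagrangian loop, which drives the reconstruction gap X - L - S to
zero while keeping S genuinely sparse.

On top of the plain decomposition sits a sparsity target tau: the fraction
of nonzero entries of S must fall below tau.  Starting from the customary
lambda0 = 1/sqrt(max(n, p)), the l1 weight is strengthened geometrically
(lambda <- lambda/decay, decay in (0,1)) and the decomposition re-run until
the target is met; under this objective a larger lambda always produces a
sparser S, so the loop terminates.

Outlyingness per participant is measured with orthogonal distances: o_xs is
the squared row distance between X and S, o_ls between L and S, and the
ratio o_ls/o_xs deviates from 1 exactly where the sparse part absorbed
structure the low-rank model could not explain.  Rows whose |ratio - 1|
reaches the eps_rpca empirical percentile are flagged, and their nonzero S
entries, ranked by magnitude, name the contributing variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import PreparedDataset

__all__ = [
    "RPCADecomposition",
    "RPCAResult",
    "singular_value_soft_threshold",
    "rpca_decompose",
    "rpca_with_sparsity_target",
    "orthogonal_distances",
    "detect_rpca",
]


def singular_value_soft_threshold(M, t: float) -> np.ndarray:
    """Shrink the singular values of M by t (soft threshold) and reconstruct."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    M = np.asarray(M, dtype=float)
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - t, 0.0)
    keep = s > 0
    return (u[:, keep] * s[keep]) @ vt[keep]


def _soft(M: np.ndarray, t: float) -> np.ndarray:
    return np.sign(M) * np.maximum(np.abs(M) - t, 0.0)


@dataclass
class RPCADecomposition:
    """X = L + S split with solver provenance."""

    L: np.ndarray
    S: np.ndarray
    lambda_final: float
    tau: float | None
    n_outer_iterations: int
    reconstruction_gap: float  # max |X - L - S| entry
    converged: bool

    @property
    def sparsity(self) -> float:
        """Fraction of nonzero entries in S."""
        return float(np.count_nonzero(self.S)) / self.S.size

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.L))


def rpca_decompose(X, lam: float, tol: float = 1e-7,
                   max_iter: int = 500) -> RPCADecomposition:
    """Principal component pursuit at a fixed l1 weight ``lam``.

    Inexact augmented-Lagrangian alternation: L-updates soft-threshold the
    singular values at 1/mu, S-updates soft-threshold the residual at
    lam/mu, and a running multiplier enforces X = L + S.  Stops when
    ||X - L - S||_F <= tol * ||X||_F; non-convergence within ``max_iter``
    returns the current iterate with ``converged=False``.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    norm_f = np.linalg.norm(X)
    if norm_f == 0:
        Z = np.zeros_like(X)
        return RPCADecomposition(Z, Z.copy(), lam, None, 0, 0.0, True)

    norm_two = np.linalg.norm(X, 2)
    Y = X / max(norm_two, np.abs(X).max() / lam)
    mu = 1.25 / norm_two
    mu_bar = mu * 1e7
    rho = 1.5
    S = np.zeros_like(X)
    L = np.zeros_like(X)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        L = singular_value_soft_threshold(X - S + Y / mu, 1.0 / mu)
        S = _soft(X - L + Y / mu, lam / mu)
        Z = X - L - S
        if np.linalg.norm(Z) <= tol * norm_f:
            converged = True
            break
        Y = Y + mu * Z
        mu = min(mu * rho, mu_bar)
    gap = float(np.abs(X - L - S).max())
    return RPCADecomposition(L, S, lam, None, it, gap, converged)


def rpca_with_sparsity_target(X, tau: float = 0.05, lam0: float | None = None,
                              decay: float = 0.9, tol: float = 1e-7,
                              max_iter: int = 500,
                              max_outer: int = 200) -> RPCADecomposition:
    """Re-run the decomposition until nnz(S)/(n*p) < tau.

    Starts at ``lam0`` (default 1/sqrt(max(n, p))).  If the sparse part is
    already below the target it is returned immediately; otherwise the l1
    weight is strengthened by 1/decay per outer pass until the target holds.
    """
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    if not 0 < decay < 1:
        raise ValueError("decay must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    lam = lam0 if lam0 is not None else 1.0 / np.sqrt(max(n, p))
    history = []
    for outer in range(1, max_outer + 1):
        dec = rpca_decompose(X, lam, tol=tol, max_iter=max_iter)
        history.append((lam, dec.sparsity))
        if dec.sparsity < tau:
            return RPCADecomposition(dec.L, dec.S, lam, tau, outer,
                                     dec.reconstruction_gap, dec.converged)
        lam = lam / decay
    raise RuntimeError(
        f"sparsity target tau={tau} not reached after {max_outer} passes; "
        f"(lambda, sparsity) trail: {history[-5:]}")


def orthogonal_distances(X, L, S, orientation: str = "ls_over_xs"):
    """Row-wise squared distances o_xs, o_ls and their ratio.

    o_xs_i = sum_j (x_ij - s_ij)^2 and o_ls_i = sum_j (l_ij - s_ij)^2; the
    ratio is o_ls/o_xs (or o_xs/o_ls with ``orientation="xs_over_ls"``) with
    the convention ratio = 1 when both distances vanish.
    """
    X, L, S = (np.asarray(a, dtype=float) for a in (X, L, S))
    if not X.shape == L.shape == S.shape:
        raise ValueError("X, L, S must have equal shapes")
    o_xs = ((X - S) ** 2).sum(axis=1)
    o_ls = ((L - S) ** 2).sum(axis=1)
    if orientation == "ls_over_xs":
        num, den = o_ls, o_xs
    elif orientation == "xs_over_ls":
        num, den = o_xs, o_ls
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = num / den
    ratios[(num == 0) & (den == 0)] = 1.0
    return o_xs, o_ls, ratios


@dataclass
class RPCAResult:
    """Per-participant RPCA outlyingness, flags and S-based contributions."""

    ids: list[str]
    variable_names: list[str]
    o_xs: np.ndarray
    o_ls: np.ndarray
    ratios: np.ndarray
    threshold: float
    eps_rpca: float
    flags: np.ndarray
    decomposition: RPCADecomposition

    method = "rpca"

    @property
    def flagged_ids(self) -> list[str]:
        return [pid for pid, f in zip(self.ids, self.flags) if f]

    def ranked_contributions(self, participant, top: int | None = None):
        """Nonzero S entries of the row, ranked by absolute value."""
        i = participant if isinstance(participant, int) else self.ids.index(participant)
        s = self.decomposition.S[i]
        nz = np.nonzero(s)[0]
        order = nz[np.argsort(-np.abs(s[nz]), kind="stable")]
        if top is not None:
            order = order[:top]
        return [(self.variable_names[j], float(s[j])) for j in order]

    def to_records(self, top: int = 5) -> list[dict]:
        return [
            {
                "id": pid,
                "o_xs": float(self.o_xs[i]),
                "o_ls": float(self.o_ls[i]),
                "ratio": float(self.ratios[i]),
                "flag": bool(self.flags[i]),
                "top_contributions": self.ranked_contributions(i, top=top),
            }
            for i, pid in enumerate(self.ids)
        ]


def detect_rpca(prepared: PreparedDataset, tau: float = 0.05,
                eps_rpca: float = 0.90, lam0: float | None = None,
                decay: float = 0.9, tol: float = 1e-7,
                orientation: str = "ls_over_xs",
                decomposition: RPCADecomposition | None = None) -> RPCAResult:
    """Full RPCA pipeline: sparsity-targeted decomposition, ODs, flags.

    Rows whose |ratio - 1| is at or beyond the ``eps_rpca`` empirical
    percentile of the ordered deviations are flagged (inclusive at the
    threshold, for determinism).  A precomputed ``decomposition`` may be
    passed to re-threshold without re-solving.
    """
    if decomposition is None:
        decomposition = rpca_with_sparsity_target(
            prepared.values, tau=tau, lam0=lam0, decay=decay, tol=tol)
    o_xs, o_ls, ratios = orthogonal_distances(
        prepared.values, decomposition.L, decomposition.S,
        orientation=orientation)
    deviation = np.abs(ratios - 1.0)
    thr = float(np.quantile(deviation, eps_rpca))
    return RPCAResult(
        ids=list(prepared.ids),
        variable_names=list(prepared.variable_names),
        o_xs=o_xs,
        o_ls=o_ls,
        ratios=ratios,
        threshold=thr,
        eps_rpca=eps_rpca,
        flags=deviation >= thr,
        decomposition=decomposition,
    )
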