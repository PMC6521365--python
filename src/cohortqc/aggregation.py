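"""Cross-method compilation, the iterate-until-static loop, and sweeps.

Each dataset is evaluated up to four times — MCD and RPCA, with and without
covariate adjustment — and participants flagged by at least ``min_flags`` of
the approaches form the verification list handed to the data platform.  The
platform verifies listed values against source documents and supplies
corrections; detection is then re-run on the corrected table.  The process
converges when an iteration applies no corrections and produces the same
list as the one before, i.e. the dataset remains static.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .datasets import CovariateTable, RawDataset
from .mcd import detect_mcd
from .preprocessing import prepare_variants
from .rpca import detect_rpca, rpca_with_sparsity_target

__all__ = [
    "METHOD_ORDER",
    "ParticipantEntry",
    "OutlierReport",
    "IterationState",
    "compile_outlier_list",
    "run_iteration",
    "run_until_static",
    "parameter_sweep",
]

#: Canonical method order; compilation output never depends on input order.
METHOD_ORDER = ("mcd_adj", "mcd_unadj", "rpca_adj", "rpca_unadj")


@dataclass
class ParticipantEntry:
    """One participant's compiled outcome across the multivariate methods."""

    id: str
    flagged_by: tuple[str, ...]
    listed: bool
    #: merged ranking: (variable, {method: (rank, value)}) in merged order
    contributions: list[tuple[str, dict[str, tuple[int, float]]]]

    @property
    def n_methods(self) -> int:
        return len(self.flagged_by)

    def top_variables(self, k: int = 5) -> list[str]:
        return [var for var, _ in self.contributions[:k]]


@dataclass
class OutlierReport:
    """The cross-method verification list with per-method provenance."""

    entries: list[ParticipantEntry]
    methods: tuple[str, ...]
    min_flags: int
    iteration: int = 0

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    @property
    def listed_ids(self) -> list[str]:
        return [e.id for e in self.entries if e.listed]

    @property
    def flagged_ids(self) -> list[str]:
        return [e.id for e in self.entries if e.n_methods > 0]

    def entry(self, participant_id: str) -> ParticipantEntry:
        for e in self.entries:
            if e.id == participant_id:
                return e
        raise KeyError(participant_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [e.id for e in self.entries],
                "n_methods": [e.n_methods for e in self.entries],
                "flagged_by": ["|".join(e.flagged_by) for e in self.entries],
                "listed": [e.listed for e in self.entries],
                "top_contributions": [
                    ";".join(e.top_variables(5)) for e in self.entries
                ],
            }
        )

    def to_csv(self, path) -> None:
        """Human-readable list: one row per listed participant."""
        df = self.to_dataframe()
        df[df["listed"]].to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "iteration": self.iteration,
            "min_flags": self.min_flags,
            "methods": list(self.methods),
            "participants": [
                {
                    "id": e.id,
                    "flagged_by": list(e.flagged_by),
                    "n_methods": e.n_methods,
                    "listed": e.listed,
                    "contributions": [
                        {
                            "variable": var,
                            "methods": {
                                m: {"rank": r, "value": v}
                                for m, (r, v) in prov.items()
                            },
                        }
                        for var, prov in e.contributions
                    ],
                }
                for e in self.entries
            ],
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload


def compile_outlier_list(results: dict, min_flags: int = 2) -> OutlierReport:
    """Merge detector outputs into the ≥ min_flags-of-k verification list.

    ``results`` maps method labels (subset of METHOD_ORDER) to MCD/RPCA
    results over an identical participant set.  Contribution rankings are
    interleaved across methods by per-method rank, ties broken by absolute
    value; a variable keeps the provenance of every method that ranked it.
    """
    if not results:
        raise ValueError("no detector results to compile")
    methods = tuple(m for m in METHOD_ORDER if m in results)
    if set(results) - set(methods):
        raise ValueError(
            f"unknown method labels: {sorted(set(results) - set(methods))}")
    ids = results[methods[0]].ids
    for m in methods[1:]:
        if results[m].ids != ids:
            raise ValueError(
                f"participant sets differ between {methods[0]!r} and {m!r}")

    entries = []
    for i, pid in enumerate(ids):
        flagged = tuple(m for m in methods if results[m].flags[i])
        per_var: dict[str, dict[str, tuple[int, float]]] = {}
        for m in flagged:
            for rank, (var, val) in enumerate(
                    results[m].ranked_contributions(i), start=1):
                per_var.setdefault(var, {})[m] = (rank, val)
        ordered = sorted(
            per_var.items(),
            key=lambda item: (
                min(r for r, _ in item[1].values()),
                -max(abs(v) for _, v in item[1].values()),
                item[0],
            ),
        )
        entries.append(ParticipantEntry(
            id=pid,
            flagged_by=flagged,
            listed=len(flagged) >= min_flags,
            contributions=ordered,
        ))
    return OutlierReport(entries=entries, methods=methods, min_flags=min_flags)


@dataclass
class IterationState:
    """One pass of the evaluation loop: report, provenance, convergence."""

    iteration: int
    fingerprint: str
    report: OutlierReport
    corrections_applied: list[tuple[str, str, float, float]]  # id, var, old, new
    converged: bool
    results: dict = field(default_factory=dict)
    data: RawDataset | None = None


def _fingerprint(data: RawDataset) -> str:
    digest = hashlib.sha256()
    digest.update(np.ascontiguousarray(data.values).tobytes())
    digest.update("|".join(data.ids).encode())
    digest.update("|".join(data.variable_names).encode())
    return digest.hexdigest()


def _apply_corrections(data: RawDataset, corrections):
    """Apply (id, variable, corrected_value) records; returns changes made."""
    applied = []
    if corrections is None:
        return data, applied
    if isinstance(corrections, pd.DataFrame):
        corrections = list(
            corrections[["participant_id", "variable", "corrected_value"]]
            .itertuples(index=False, name=None))
    data = data.copy()
    for pid, var, value in corrections:
        i = data.row_index(pid)
        j = data.variable_names.index(var)
        old = float(data.values[i, j])
        data.values[i, j] = float(value)
        applied.append((str(pid), str(var), old, float(value)))
    return data, applied


def _iteration_seed(config: RunConfig, iteration: int) -> int:
    if config.seed_policy == "per_iteration":
        return (config.seed + 1_000_003 * iteration) % (2**31)
    return config.seed % (2**31)


def _detect_all(variants, config: RunConfig, base_seed: int) -> dict:
    results = {}
    for k, label in enumerate(METHOD_ORDER):
        kind, variant = label.split("_")
        variant = {"adj": "adjusted", "unadj": "unadjusted"}[variant]
        if variant not in variants:
            continue
        prepared = variants[variant]
        seed = np.random.SeedSequence([base_seed, k])
        if kind == "mcd":
            results[label] = detect_mcd(
                prepared, alpha=config.alpha, eps_mcd=config.eps_mcd,
                n_sims=config.n_sims, n_starts=config.n_starts,
                max_subsets=config.max_subsets, seed=seed,
                pooling=config.pooling)
        else:
            results[label] = detect_rpca(
                prepared, tau=config.tau, eps_rpca=config.eps_rpca,
                lam0=config.lam0, decay=config.decay,
                orientation=config.ratio_orientation)
    return results


def run_iteration(data: RawDataset, cov: CovariateTable | None,
                  config: RunConfig, prior: IterationState | None = None,
                  corrections=None) -> IterationState:
    """One pass: apply corrections, re-detect with all methods, compile.

    Convergence is declared when the pass applied no corrections and its
    listed set matches the previous iteration's.
    """
    iteration = 1 if prior is None else prior.iteration + 1
    data, applied = _apply_corrections(data, corrections)
    variants = prepare_variants(data, cov)
    results = _detect_all(variants, config, _iteration_seed(config, iteration))
    report = compile_outlier_list(results, min_flags=config.min_flags)
    report.iteration = iteration
    fingerprint = _fingerprint(data)
    converged = (
        prior is not None
        and not applied
        and fingerprint == prior.fingerprint
        and set(report.listed_ids) == set(prior.report.listed_ids)
    )
    return IterationState(
        iteration=iteration,
        fingerprint=fingerprint,
        report=report,
        corrections_applied=applied,
        converged=converged,
        results=results,
        data=data,
    )


def run_until_static(data: RawDataset, cov: CovariateTable | None,
                     config: RunConfig, corrections_provider=None,
                     max_iterations: int = 10) -> list[IterationState]:
    """Drive the loop until the dataset and verification list are static.

    ``corrections_provider(state)`` stands in for the human verification
    step: it inspects the report and returns (id, variable, corrected_value)
    records for confirmed errors, or an empty list when nothing needs fixing.
    """
    states: list[IterationState] = []
    prior = None
    corrections = None
    current = data
    for _ in range(max_iterations):
        state = run_iteration(current, cov, config, prior=prior,
                              corrections=corrections)
        states.append(state)
        current = state.data
        if state.converged:
            break
        corrections = (corrections_provider(state)
                       if corrections_provider is not None else None)
        prior = state
    return states


def parameter_sweep(data: RawDataset, cov: CovariateTable | None,
                    alphas, eps_rpca_values,
                    config: RunConfig | None = None) -> pd.DataFrame:
    """Grid the MCD robustness alpha against the RPCA percentile eps_rpca.

    For every grid point the four detectors are run (the RPCA decomposition
    is solved once per variant and re-thresholded across the eps grid) and
    flag counts, the listed count and the MCD/RPCA overlap are tabulated.
    """
    alphas = list(alphas)
    eps_values = list(eps_rpca_values)
    if not alphas or not eps_values:
        raise ValueError("parameter grids must be nonempty")
    config = config or RunConfig()
    variants = prepare_variants(data, cov)
    base_seed = _iteration_seed(config, 1)

    decomps = {
        variant: rpca_with_sparsity_target(
            prep.values, tau=config.tau, lam0=config.lam0, decay=config.decay)
        for variant, prep in variants.items()
    }
    rows = []
    for alpha in alphas:
        cfg_a = config.replace(alpha=alpha)
        from .mcd import compute_h  # local import to avoid cycle noise

        mcd_results = {}
        for k, label in enumerate(("mcd_adj", "mcd_unadj")):
            variant = "adjusted" if label.endswith("_adj") else "unadjusted"
            if variant not in variants:
                continue
            mcd_results[label] = detect_mcd(
                variants[variant], alpha=alpha, eps_mcd=config.eps_mcd,
                n_sims=config.n_sims, n_starts=config.n_starts,
                max_subsets=config.max_subsets,
                seed=np.random.SeedSequence([base_seed, k]),
                pooling=config.pooling)
        for eps in eps_values:
            results = dict(mcd_results)
            for label in ("rpca_adj", "rpca_unadj"):
                variant = "adjusted" if label.endswith("_adj") else "unadjusted"
                if variant not in variants:
                    continue
                results[label] = detect_rpca(
                    variants[variant], tau=config.tau, eps_rpca=eps,
                    orientation=config.ratio_orientation,
                    decomposition=decomps[variant])
            report = compile_outlier_list(results, min_flags=config.min_flags)
            mcd_any = {pid for lab in results for pid in results[lab].flagged_ids
                       if lab.startswith("mcd")}
            rpca_any = {pid for lab in results for pid in results[lab].flagged_ids
                        if lab.startswith("rpca")}
            row = {
                "alpha": alpha,
                "eps_rpca": eps,
                "h": compute_h(data.n, variants["unadjusted"].p
                               - len(variants["unadjusted"].constant_columns),
                               alpha),
                "n_listed": len(report.listed_ids),
                "n_flagged_any": len(report.flagged_ids),
                "n_overlap_mcd_rpca": len(mcd_any & rpca_any),
            }
            for label in METHOD_ORDER:
                if label in results:
                    row[f"n_flagged_{label}"] = int(results[label].flags.sum())
            rows.append(row)
    return pd.DataFrame(rows)
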