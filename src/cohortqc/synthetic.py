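"""Synthetic cohorts with ground-truth error injection.

Real study tables of the kind this package targets have two structural
signatures: (1) raw-score / transformed-score variable pairs that are very
strongly correlated, because the transformed member is a normed version of
the raw one; and (2) blocks of task variables (e.g. gait measures across
walking conditions) that share within-block correlation.  The generator
emulates both on a Gaussian-copula backbone, adds covariate-dependent means
(age, sex, years of education drawn to match a stroke-cohort demographic
profile), and injects errors of the three mechanisms observed in practice:

* ``transcription`` — a cell is replaced by another participant's value;
* ``transform_miscalc`` — the transformed member of a pair is shifted so it
  stays inside its own boxplot fences yet breaks the pair relationship
  (invisible univariately, glaring bivariately);
* ``block_miscount`` — every variable of one task block is rescaled by
  (s±1)/s for a plausible step count s, the signature of a step-detection
  miscount propagating through derived measures.

Every draw is deterministic given the seed, and the error log records enough
to score detection sensitivity against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CovariateTable, RawDataset
from .univariate import boxplot_detect

__all__ = ["CohortSpec", "ErrorRecord", "ErrorLog", "variable_layout",
           "generate_cohort", "inject_errors", "score_detection"]

MECHANISMS = ("transcription", "transform_miscalc", "block_miscount")


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort.

    ``p = 2*n_pairs + n_blocks*block_size`` variables: raw/transformed pairs
    first (within-pair correlation ``pair_correlation``), then task blocks
    with within-block correlation ``block_correlation``.  Demographics
    default to a vascular-impairment stroke cohort: age ~ N(68.72, 7.42²)
    truncated to [55, 85] years, education ~ N(14.61, 2.92²) truncated at 6
    years, and a male fraction of 110/161.
    """

    n: int = 161
    n_pairs: int = 8
    pair_correlation: float = 0.9
    n_blocks: int = 2
    block_size: int = 6
    block_correlation: float = 0.7
    covariate_effects: np.ndarray | None = None  # (n_source_vars, 3): age, sex, edu
    noise_sd: float = 1.0
    seed: int = 0
    age_mean: float = 68.72
    age_sd: float = 7.42
    age_range: tuple[float, float] = (55.0, 85.0)
    education_mean: float = 14.61
    education_sd: float = 2.92
    education_min: float = 6.0
    male_fraction: float = 110 / 161

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not 0 <= self.pair_correlation < 1:
            raise ValueError("pair_correlation must be in [0, 1)")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.p < 1:
            raise ValueError("spec implies zero variables")

    @property
    def n_source_vars(self) -> int:
        return self.n_pairs + self.n_blocks * self.block_size

    @property
    def p(self) -> int:
        return 2 * self.n_pairs + self.n_blocks * self.block_size


@dataclass
class ErrorRecord:
    participant_id: str
    variables: list[str]
    mechanism: str
    original: list[float]
    corrupted: list[float]
    note: str = ""


@dataclass
class ErrorLog:
    """Ground truth of injected errors, scorable against detector reports."""

    entries: list[ErrorRecord] = field(default_factory=list)

    @property
    def participant_ids(self) -> list[str]:
        seen = []
        for e in self.entries:
            if e.participant_id not in seen:
                seen.append(e.participant_id)
        return seen

    def variables_for(self, participant_id: str) -> list[str]:
        out = []
        for e in self.entries:
            if e.participant_id == participant_id:
                out.extend(v for v in e.variables if v not in out)
        return out

    def corrections(self) -> list[tuple[str, str, float]]:
        """(id, variable, original_value) records that undo every error."""
        return [
            (e.participant_id, var, orig)
            for e in self.entries
            for var, orig in zip(e.variables, e.original)
        ]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            for var, orig, corr in zip(e.variables, e.original, e.corrupted):
                rows.append({"participant_id": e.participant_id,
                             "variable": var, "mechanism": e.mechanism,
                             "original": orig, "corrupted": corr,
                             "note": e.note})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def variable_layout(variable_names) -> tuple[list[tuple[int, int]], list[list[int]]]:
    """Recover (raw, transformed) pair indices and task blocks from names.

    Pairs are columns named ``<stem>_raw`` / ``<stem>_std``; blocks are
    columns sharing a ``walk<k>_`` prefix.  This matches the names written
    by :func:`generate_cohort`.
    """
    names = list(variable_names)
    index = {n: j for j, n in enumerate(names)}
    pairs = []
    for n in names:
        if n.endswith("_raw") and n[:-4] + "_std" in index:
            pairs.append((index[n], index[n[:-4] + "_std"]))
    blocks: dict[str, list[int]] = {}
    for j, n in enumerate(names):
        if n.startswith("walk") and "_" in n:
            blocks.setdefault(n.split("_")[0], []).append(j)
    return pairs, [sorted(v) for _, v in sorted(blocks.items())]


def _truncnorm(rng, mean, sd, lower, upper, size):
    """Truncated-normal draws whose post-truncation moments hit (mean, sd).

    Truncation shrinks the spread, so the parent parameters are calibrated
    (by a small root solve) such that the truncated distribution itself has
    the requested mean and standard deviation — these are observed cohort
    summaries, not parent parameters.
    """
    from scipy import optimize

    def moments(params):
        loc, scale = params
        a, b = (lower - loc) / scale, (upper - loc) / scale
        dist = stats.truncnorm(a, b, loc=loc, scale=scale)
        return dist.mean() - mean, dist.std() - sd

    (loc, scale), info, ok, _ = optimize.fsolve(
        moments, x0=(mean, sd), full_output=True)
    if ok != 1 or scale <= 0:  # infeasible target (e.g. sd too wide): fall back
        loc, scale = mean, sd
    a, b = (lower - loc) / scale, (upper - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size,
                               random_state=rng)


def generate_cohort(spec: CohortSpec) -> tuple[RawDataset, CovariateTable]:
    """Draw a cohort matching the spec; bit-identical per seed.

    The transformed member of each pair is a monotone (linear) function of
    its raw member plus noise calibrated so the empirical within-pair
    correlation matches ``pair_correlation``; block variables load on a
    shared latent factor with loading sqrt(block_correlation).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    ids = [f"SUB{i + 1:04d}" for i in range(n)]

    age = _truncnorm(rng, spec.age_mean, spec.age_sd, *spec.age_range, size=n)
    education = _truncnorm(rng, spec.education_mean, spec.education_sd,
                           spec.education_min, np.inf, size=n)
    sex = (rng.random(n) < spec.male_fraction).astype(float)
    cov = CovariateTable(ids, age, sex, education)

    effects = spec.covariate_effects
    if effects is None:
        effects = np.column_stack([
            rng.uniform(-0.05, -0.02, spec.n_source_vars),   # per year of age
            rng.uniform(-0.4, 0.4, spec.n_source_vars),      # sex shift
            rng.uniform(0.02, 0.08, spec.n_source_vars),     # per year of education
        ])
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (spec.n_source_vars, 3):
        raise ValueError(
            f"covariate_effects must have shape ({spec.n_source_vars}, 3)")
    cov_design = np.column_stack([
        age - spec.age_mean, sex - spec.male_fraction,
        education - spec.education_mean,
    ])
    shift = cov_design @ effects.T  # (n, n_source_vars)

    columns, names = [], []
    source = 0
    for k in range(spec.n_pairs):
        loc = rng.uniform(20.0, 60.0)
        raw = loc + shift[:, source] + spec.noise_sd * rng.standard_normal(n)
        source += 1
        raw_sd = raw.std(ddof=1)
        rho = spec.pair_correlation
        if rho > 0 and raw_sd > 0:
            noise_sd = raw_sd * np.sqrt(1.0 / rho**2 - 1.0)
        else:
            noise_sd = 1.0 if spec.noise_sd == 0 else spec.noise_sd
        offset = rng.uniform(-30.0, 0.0)
        transformed = offset + raw + noise_sd * rng.standard_normal(n)
        columns += [raw, transformed]
        names += [f"test{k + 1:02d}_raw", f"test{k + 1:02d}_std"]

    gamma = np.sqrt(spec.block_correlation)
    for b in range(spec.n_blocks):
        factor = rng.standard_normal(n)
        for j in range(spec.block_size):
            loc = rng.uniform(10.0, 30.0)
            noise = rng.standard_normal(n)
            col = (loc + shift[:, source]
                   + spec.noise_sd * (gamma * factor
                                      + np.sqrt(1 - gamma**2) * noise))
            columns.append(col)
            names.append(f"walk{b + 1}_m{j + 1}")
            source += 1

    data = RawDataset(ids, np.column_stack(columns), names)
    return data, cov


def _fit_pair_line(raw: np.ndarray, trans: np.ndarray):
    """OLS line trans ~ raw; returns (intercept, slope, residual sd)."""
    design = np.column_stack([np.ones_like(raw), raw])
    beta, *_ = np.linalg.lstsq(design, trans, rcond=None)
    resid = trans - design @ beta
    return beta[0], beta[1], resid.std(ddof=1)


def _inject_transform_miscalc(values, i, pair, rng, break_sd, names):
    """Shift a transformed score inside its fences but off the pair line."""
    raw_j, trans_j = pair
    raw, trans = values[:, raw_j], values[:, trans_j]
    b0, b1, sd_r = _fit_pair_line(raw, trans)
    fences = boxplot_detect(trans, variable=names[trans_j])
    fitted = b0 + b1 * raw[i]
    old = trans[i]
    signs = [1.0, -1.0] if rng.random() < 0.5 else [-1.0, 1.0]
    for mag in (break_sd, break_sd * 0.9, break_sd * 0.8):
        for sign in signs:
            candidate = fitted + sign * mag * sd_r
            if (fences.lower_bound < candidate < fences.upper_bound
                    and candidate != old):
                return candidate, ""
    # cannot satisfy the inside-fences constraint: place just outside
    iqr = max(fences.robust_spread, 1e-12)
    candidate = (fences.upper_bound + 0.05 * iqr if rng.random() < 0.5
                 else fences.lower_bound - 0.05 * iqr)
    return candidate, "gross"


def inject_errors(data: RawDataset, k: int, mechanisms=None,
                  break_sd: float = 5.0, seed=None,
                  layout=None) -> tuple[RawDataset, ErrorLog]:
    """Corrupt k distinct participants and log the ground truth.

    ``mechanisms`` maps mechanism names to sampling weights (default: equal
    weight on every mechanism the variable layout supports).  ``break_sd``
    is the pair-residual displacement of a miscomputed transformed score, in
    residual-sd units.  ``layout`` overrides the (pairs, blocks) structure
    otherwise recovered from the variable names.
    """
    if k > data.n:
        raise ValueError(f"cannot corrupt {k} of {data.n} participants")
    rng = np.random.default_rng(seed)
    pairs, blocks = layout if layout is not None else variable_layout(
        data.variable_names)
    if mechanisms is None:
        mechanisms = {m: 1.0 for m in MECHANISMS
                      if (m != "transform_miscalc" or pairs)
                      and (m != "block_miscount" or blocks)}
    mechanisms = {m: w for m, w in mechanisms.items() if w > 0}
    if not mechanisms:
        raise ValueError("no applicable error mechanism")
    for m in mechanisms:
        if m not in MECHANISMS:
            raise ValueError(f"unknown mechanism {m!r}")
    if "transform_miscalc" in mechanisms and not pairs:
        raise ValueError("transform_miscalc requires raw/transformed pairs")
    if "block_miscount" in mechanisms and not blocks:
        raise ValueError("block_miscount requires task blocks")

    corrupted = data.copy()
    log = ErrorLog()
    if k == 0:
        return corrupted, log
    values = corrupted.values
    names = corrupted.variable_names
    targets = rng.choice(data.n, size=k, replace=False)
    mech_names = sorted(mechanisms)
    weights = np.array([mechanisms[m] for m in mech_names], dtype=float)
    weights /= weights.sum()
    for i in targets:
        mech = rng.choice(mech_names, p=weights)
        pid = corrupted.ids[i]
        if mech == "transcription":
            j = int(rng.integers(data.p))
            donors = [d for d in range(data.n)
                      if d != i and values[d, j] != values[i, j]]
            donor = int(rng.choice(donors))
            old = float(values[i, j])
            values[i, j] = values[donor, j]
            log.entries.append(ErrorRecord(pid, [names[j]], "transcription",
                                           [old], [float(values[i, j])],
                                           note=f"copied from row {donor}"))
        elif mech == "transform_miscalc":
            pair = pairs[int(rng.integers(len(pairs)))]
            old = float(values[i, pair[1]])
            new, note = _inject_transform_miscalc(values, i, pair, rng,
                                                  break_sd, names)
            values[i, pair[1]] = new
            log.entries.append(ErrorRecord(pid, [names[pair[1]]],
                                           "transform_miscalc", [old],
                                           [float(new)], note=note))
        else:  # block_miscount
            block = blocks[int(rng.integers(len(blocks)))]
            s = int(rng.integers(8, 16))
            factor = (s + int(rng.choice([-1, 1]))) / s
            old = [float(values[i, j]) for j in block]
            for j in block:
                values[i, j] *= factor
            log.entries.append(ErrorRecord(
                pid, [names[j] for j in block], "block_miscount", old,
                [float(values[i, j]) for j in block],
                note=f"step count {s} miscounted, factor {factor:.4f}"))
    return corrupted, log


def score_detection(report, log: ErrorLog, top: int = 3) -> dict:
    """Sensitivity, verification burden and contribution hit-rate vs truth.

    Per method and overall: sensitivity is the fraction of erroneous
    participants flagged (listed, for "overall"), burden the fraction of the
    cohort on the verification list, and the hit-rate the fraction of
    detections whose erroneous variable appears among the top ``top``
    contributing variables.
    """
    erroneous = log.participant_ids
    n = len(report.ids)
    listed = set(report.listed_ids)

    def _hit(entry, pid) -> bool:
        top_vars = entry.top_variables(top)
        return any(v in top_vars for v in log.variables_for(pid))

    overall_detected = [pid for pid in erroneous if pid in listed]
    out = {
        "overall": {
            "sensitivity": (len(overall_detected) / len(erroneous)
                            if erroneous else float("nan")),
            "burden": len(listed) / n,
            "contribution_hit_rate": (
                sum(_hit(report.entry(pid), pid) for pid in overall_detected)
                / len(overall_detected) if overall_detected else float("nan")),
        }
    }
    for method in report.methods:
        flagged = [e.id for e in report.entries if method in e.flagged_by]
        detected = [pid for pid in erroneous if pid in flagged]
        hits = 0
        for pid in detected:
            entry = report.entry(pid)
            ranked = [var for var, prov in entry.contributions
                      if method in prov]
            ranked.sort(key=lambda v: entry_rank(entry, v, method))
            hits += any(v in ranked[:top] for v in log.variables_for(pid))
        out[method] = {
            "sensitivity": (len(detected) / len(erroneous)
                            if erroneous else float("nan")),
            "burden": len(flagged) / n,
            "contribution_hit_rate": (hits / len(detected)
                                      if detected else float("nan")),
        }
    return out


def entry_rank(entry, variable: str, method: str) -> int:
    for var, prov in entry.contributions:
        if var == variable and method in prov:
            return prov[method][0]
    return 10**9
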