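"""Cross-method compilation, the evaluation loop, and parameter sweeps."""

import numpy as np
import pytest

from cohortqc.aggregation import (compile_outlier_list, parameter_sweep,
                                  run_iteration, run_until_static)
from cohortqc.config import RunConfig
from cohortqc.mcd import compute_h
from cohortqc.synthetic import _inject_transform_miscalc, variable_layout


class FakeResult:
    """Minimal detector-result stand-in for compilation unit tests."""

    def __init__(self, ids, flagged, contribs):
        self.ids = list(ids)
        self.flags = np.array([i in flagged for i in range(len(ids))])
        self._contribs = contribs

    def ranked_contributions(self, i, top=None):
        ranked = self._contribs.get(i, [])
        return ranked if top is None else ranked[:top]


IDS = ["A", "B", "C", "D"]


def fake(flagged, contribs=None):
    return FakeResult(IDS, flagged, contribs or
                      {i: [("v1", 2.0), ("v2", 1.0)] for i in flagged})


class TestCompile:
    def test_two_of_four_rule(self):
        report = compile_outlier_list({
            "mcd_adj": fake({0}),
            "mcd_unadj": fake(set()),
            "rpca_adj": fake({1}),
            "rpca_unadj": fake({0}),
        })
        assert report.listed_ids == ["A"]          # mcd_adj + rpca_unadj
        assert report.entry("B").flagged_by == ("rpca_adj",)
        assert not report.entry("B").listed        # one method only

    def test_all_four_carry_provenance(self):
        report = compile_outlier_list({m: fake({2}) for m in
                                       ("mcd_adj", "mcd_unadj", "rpca_adj",
                                        "rpca_unadj")})
        entry = report.entry("C")
        assert entry.n_methods == 4
        assert all(len(prov) == 4 for _, prov in entry.contributions)

    def test_order_independent_and_idempotent(self):
        results = {
            "rpca_unadj": fake({0, 3}),
            "mcd_adj": fake({3}),
            "mcd_unadj": fake(set()),
            "rpca_adj": fake({3}),
        }
        a = compile_outlier_list(results)
        b = compile_outlier_list(dict(reversed(list(results.items()))))
        assert a.listed_ids == b.listed_ids == ["D"]
        assert [e.flagged_by for e in a.entries] == [e.flagged_by for e in b.entries]

    def test_contribution_merge_interleaves_by_rank(self):
        report = compile_outlier_list({
            "mcd_adj": fake({0}, {0: [("x", 5.0), ("y", 1.0)]}),
            "mcd_unadj": fake({0}, {0: [("y", 9.0), ("z", 0.5)]}),
            "rpca_adj": fake(set()),
            "rpca_unadj": fake(set()),
        })
        merged = [var for var, _ in report.entry("A").contributions]
        # both rank-1 variables first, tie broken by |value|
        assert merged == ["y", "x", "z"]

    def test_mismatched_participants_error(self):
        bad = FakeResult(["A", "B", "X", "D"], set(), {})
        with pytest.raises(ValueError, match="participant sets differ"):
            compile_outlier_list({"mcd_adj": fake(set()), "mcd_unadj": bad})

    def test_min_flags_configurable(self):
        results = {"mcd_adj": fake({1}), "rpca_adj": fake({1}),
                   "rpca_unadj": fake({1})}
        assert compile_outlier_list(results, min_flags=3).listed_ids == ["B"]
        assert compile_outlier_list(results, min_flags=4).listed_ids == []


class TestIteration:
    def test_clean_data_converges_without_corrections(self, small_cohort):
        data, cov = small_cohort
        cfg = RunConfig(seed=11)
        states = run_until_static(data, cov, cfg, max_iterations=4)
        assert states[-1].converged
        assert sum(1 for s in states if s.corrections_applied) == 0
        assert len(states) == 2  # one pass plus the static confirmation

    def test_correction_changes_fingerprint(self, small_cohort):
        data, cov = small_cohort
        cfg = RunConfig(seed=11)
        first = run_iteration(data, cov, cfg)
        second = run_iteration(first.data, cov, cfg, prior=first,
                               corrections=[(data.ids[0],
                                             data.variable_names[0], 999.0)])
        assert second.fingerprint != first.fingerprint
        assert not second.converged

    def test_masked_error_needs_second_pass(self, small_cohort):
        # two in-fence pair-breaking errors in one row; verification uncovers
        # only the most apparent one per pass, so the row must be re-listed
        # by the second error after the first is corrected
        data, cov = small_cohort
        data = data.copy()
        pairs, _ = variable_layout(data.variable_names)
        row = 17
        rng = np.random.default_rng(5)
        known = {}
        for pair in (pairs[0], pairs[3]):
            old = float(data.values[row, pair[1]])
            new, _ = _inject_transform_miscalc(data.values, row, pair, rng,
                                               6.5, data.variable_names)
            data.values[row, pair[1]] = new
            known[(data.ids[row], data.variable_names[pair[1]])] = old

        corrected = set()

        def verify_top_error(state):
            for pid in state.report.listed_ids:
                for var in state.report.entry(pid).top_variables(10):
                    key = (pid, var)
                    if key in known and key not in corrected:
                        corrected.add(key)
                        return [(pid, var, known[key])]
            return []

        cfg = RunConfig(seed=11)
        states = run_until_static(data, cov, cfg,
                                  corrections_provider=verify_top_error,
                                  max_iterations=8)
        listed_row = [data.ids[row] in s.report.listed_ids for s in states]
        assert listed_row[0]                       # listed with both errors
        assert listed_row[1]                       # re-listed via the masked one
        assert states[-1].converged
        assert sum(1 for s in states if s.corrections_applied) == 2
        assert len(corrected) == 2


class TestParameterSweep:
    def test_grid_counts_and_h(self, small_cohort):
        data, cov = small_cohort
        cfg = RunConfig(seed=11, n_starts=150)
        table = parameter_sweep(data, cov, alphas=[0.8],
                                eps_rpca_values=[0.85, 0.90, 0.95],
                                config=cfg)
        assert len(table) == 3
        # percentile tail shrinks as eps grows
        counts = table.sort_values("eps_rpca")["n_flagged_rpca_unadj"].tolist()
        assert counts == sorted(counts, reverse=True)
        assert (table["h"] == compute_h(data.n, data.p, 0.8)).all()

    def test_single_point_matches_run_iteration(self, small_cohort):
        data, cov = small_cohort
        cfg = RunConfig(seed=11)
        table = parameter_sweep(data, cov, [cfg.alpha], [cfg.eps_rpca],
                                config=cfg)
        state = run_iteration(data, cov, cfg)
        assert int(table["n_listed"].iloc[0]) == len(state.report.listed_ids)

    def test_empty_grid_rejected(self, small_cohort):
        data, cov = small_cohort
        with pytest.raises(ValueError, match="nonempty"):
            parameter_sweep(data, cov, [], [0.9])
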