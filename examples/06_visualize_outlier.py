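"""Diagnostic figures for a flagged participant.

Writes (1) a scatterplot of the cohort on the outlier's two primary
contributing variables — the off-the-regression-band geometry that makes a
relationship-breaking error obvious — and (2) a boxplot of the erroneous
variable with the uMCD typical range overlaid, showing the same value
sitting innocuously inside all univariate fences.
"""

from pathlib import Path

from cohortqc import (CohortSpec, boxplot_with_ranges, contribution_scatter,
                      detect_mcd, generate_cohort, inject_errors,
                      prepare_variants, umcd_detect)

out_dir = Path("example_output")
out_dir.mkdir(exist_ok=True)

data, cov = generate_cohort(CohortSpec(n=161, seed=5))
corrupted, log = inject_errors(data, 1,
                               mechanisms={"transform_miscalc": 1.0}, seed=26)
entry = log.entries[0]

prepared = prepare_variants(corrupted, cov)["adjusted"]
result = detect_mcd(prepared, seed=6)
print(f"{entry.participant_id} flagged: "
      f"{entry.participant_id in result.flagged_ids}")

scatter = contribution_scatter(prepared, result, entry.participant_id,
                               path=out_dir / "scatter.png")
print(f"scatter of top-2 contributing variables -> {scatter}")

j = prepared.variable_names.index(entry.variables[0])
umcd = umcd_detect(prepared.values[:, j], seed=7, variable=entry.variables[0])
box = boxplot_with_ranges(prepared.values[:, j], variable=entry.variables[0],
                          umcd_result=umcd,
                          highlight_indices=[prepared.ids.index(entry.participant_id)],
                          path=out_dir / "boxplot.png")
print(f"boxplot with uMCD range and the erroneous cell -> {box}")
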