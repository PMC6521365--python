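"""Why univariate screening misses relationship-breaking errors.

A miscomputed transformed score is injected so that it stays inside its own
variable's boxplot fences (and the uMCD typical range) yet sits far off the
raw/transformed regression line.  Boxplots and the univariate MCD see
nothing; the multivariate MCD flags the participant and names the variable.
"""

import numpy as np

from cohortqc import (CohortSpec, boxplot_detect, detect_mcd, generate_cohort,
                      inject_errors, prepare_variants, umcd_detect)

data, cov = generate_cohort(CohortSpec(n=200, seed=3))
corrupted, log = inject_errors(data, 1,
                               mechanisms={"transform_miscalc": 1.0}, seed=9)
entry = log.entries[0]
print(f"injected {entry.mechanism} for {entry.participant_id} "
      f"on {entry.variables[0]}: {entry.original[0]:.2f} -> "
      f"{entry.corrupted[0]:.2f}")

prepared = prepare_variants(corrupted, cov)["unadjusted"]
i = prepared.ids.index(entry.participant_id)
j = prepared.variable_names.index(entry.variables[0])
col = prepared.values[:, j]

box = boxplot_detect(col, variable=entry.variables[0])
umcd = umcd_detect(col, seed=4, variable=entry.variables[0])
print(f"boxplot fences [{box.lower_bound:.2f}, {box.upper_bound:.2f}]: "
      f"flagged = {bool(box.flags[i])}")
print(f"uMCD range    [{umcd.lower_bound:.2f}, {umcd.upper_bound:.2f}]: "
      f"flagged = {bool(umcd.flags[i])}")

mcd = detect_mcd(prepared, seed=5)
print(f"multivariate MCD: flagged = {bool(mcd.flags[i])}")
top = [v for v, _ in mcd.ranked_contributions(i, top=3)]
print(f"top-3 contributing variables: {top}")
print(f"erroneous variable in top 3: {entry.variables[0] in top}")
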