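"""Group-level summaries on a synthetic cohort.

Cell means/SDs per group x condition x timepoint, the 30-min-vs-baseline
marginal-mean contrast per group with its 95% CI and Hedges' g, and a Welch
comparison of the groups' baseline central pressures.
"""

import numpy as np

from pehresponse import (
    Timepoint,
    cell_summaries,
    cells_to_frame,
    generate_cohort,
    marginal_contrast,
    welch_test,
)

data, _ = generate_cohort(seed=21)

cells = cells_to_frame(cell_summaries(data, "csbp"))
print(cells[cells.timepoint == "PRE"].to_string(index=False))
print()

for group in ("CAD", "CON"):
    c = marginal_contrast(data, "csbp", group, "PRE", "P30")
    print(
        f"{group} cSBP {c.label}: {c.estimate:+.1f} mmHg "
        f"(95% CI {c.ci_lower:+.1f} to {c.ci_upper:+.1f}), g = {c.hedges_g:.2f}, n = {c.n_pairs}"
    )

pre = {g: [] for g in ("CAD", "CON")}
groups = {p.id: p.group.value for p in data.participants}
for m in data.measurements:
    if m.timepoint is Timepoint.PRE:
        pre[groups[m.participant_id]].append(m.csbp)
w = welch_test(np.array(pre["CAD"]), np.array(pre["CON"]))
print(
    f"baseline cSBP CAD - CON: {w.difference:+.1f} mmHg "
    f"(95% CI {w.ci_lower:+.1f} to {w.ci_upper:+.1f}), t = {w.t:.2f}, p = {w.p:.3g}"
)
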