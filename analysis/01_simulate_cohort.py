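#!/usr/bin/env python
"""Generate the synthetic study cohort used by the downstream analyses.

Emulates the study design: five CNV subgroups (de novo, familial,
common-from-cases, common-from-controls, curated pathogenic) with
group-specific size distributions, a miRNA-hotspot bias of 5x for the de
novo and pathogenic groups, a multi-study known-variant database anchoring
the common CNVs, and a planted target-gene pathway.  Counts are scaled to
a quarter of the study's cohort so the full analysis runs in seconds.

Writes every pipeline input plus the ground-truth side-car under
results/cohort/.
"""

import json
from pathlib import Path

from cnvmir.simulate import GroupSpec, SimulationSpec, generate_cohort

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 1
SCALE = 0.25

groups = {
    "de_novo": GroupSpec(max(1, int(24 * SCALE)), 2.5e6, 0.6, 5.0, 0.55),
    "familial": GroupSpec(max(1, int(46 * SCALE)), 0.55e6, 0.6, 1.0, 0.50),
    "common_case": GroupSpec(max(1, int(216 * SCALE)), 0.45e6, 0.5, 1.0, 0.25),
    "common_control": GroupSpec(max(1, int(67 * SCALE)), 0.50e6, 0.5, 1.0, 0.0),
    "decipher": GroupSpec(max(1, int(35 * SCALE)), 2.5e6, 0.6, 5.0, 0.46),
}
spec = SimulationSpec(
    seed=SEED,
    n_mirnas=int(2042 * SCALE),
    n_genes=int(19905 * SCALE),
    groups=groups,
)

paths, truth = generate_cohort(spec, OUTDIR)
n_by_class = {}
for label in truth.true_class.values():
    n_by_class[label] = n_by_class.get(label, 0) + 1
print(f"cohort written to {OUTDIR} (seed {SEED}, scale {SCALE})")
print("CNVs per subgroup:", json.dumps(n_by_class, sort_keys=True))
print(f"planted pathway: {truth.planted_pathway} "
      f"({len(truth.planted_genes)} genes)")
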