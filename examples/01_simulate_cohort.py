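"""Generate a synthetic two-group connectome cohort and write it to disk.

Builds a 60-node, six-subnetwork atlas, plants a 40% reduction of edge
weights around four cerebellum nodes and a 40% increase around three
sensorimotor and two occipital nodes in the patient group, draws node time
series for 20 + 20 subjects, and writes everything as plain-text files.
"""

from pathlib import Path

import connectoml as cm
from connectoml.io import write_cohort

atlas = cm.default_atlas(60)
plan = cm.default_effect_plan(atlas, delta=0.4)
cohort = cm.sample_cohort(atlas, plan, n_group1=20, n_group0=20,
                          n_timepoints=230, seed=42)

outdir = Path("cohort_out")
write_cohort(cohort, outdir)

print(f"atlas: {atlas.n_nodes} nodes in {atlas.n_subnetworks} subnetworks")
print(f"planted down (cerebellum): {plan.affected_down}")
print(f"planted up (sensorimotor/occipital): {plan.affected_up}")
print(f"subjects: {len(cohort.covariates)}, "
      f"timepoints: {cohort.timeseries.shape[2]}")
print(f"wrote {len(list(outdir.iterdir()))} files to {outdir}/")
# The planted node indices are ground truth: downstream feature selection
# should keep rediscovering features at exactly these nodes.
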