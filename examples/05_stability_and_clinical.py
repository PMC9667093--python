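"""Stable discriminative features, clinical correlation, demographics table.

After the outer loops, features selected in more than 80% of loops (the
full-scale rule: more than 80 of 100) are the stable discriminators;
family-level stability asks how often *any* feature of a planted node set
is selected.  Stable features are then correlated with the simulated
tremor-severity score by partial Pearson correlation controlling age, sex,
education, head motion and psychometric scores, Bonferroni-corrected.
"""

import connectoml as cm

atlas = cm.default_atlas(60)
plan = cm.default_effect_plan(atlas, delta=0.4)
cohort = cm.sample_cohort(atlas, plan, 25, 25, 230, seed=31)
table = cm.compute_feature_table(cohort, n_random=6, swaps_per_edge=5, seed=37)
y = cohort.labels

specs = cm.default_model_specs(("lr",))
results, _ = cm.run_loops(table, y, specs, n_loops=15, master_seed=41)

report = cm.feature_stability(results, threshold=int(0.8 * len(results)),
                              table=table, labels=y)
print("most frequently selected features (count / loops, direction):")
for name, c in sorted(report.counts.items(), key=lambda kv: -kv[1])[:8]:
    print(f"  {name:24s} {c:2d}/{len(results)}  "
          f"{'+' if report.direction[name] > 0 else '-'}")

fam = cm.family_stability(results, {
    "cerebellum-down": set(plan.affected_down),
    "sensorimotor/occipital-up": set(plan.affected_up),
})
print("\nfamily-level selection frequency:")
for k, v in fam.items():
    print(f"  {k}: {v:.0%} of loops")

top = [n for n, _ in sorted(report.counts.items(), key=lambda kv: -kv[1])[:10]]
corr = cm.correlate_clinical(table, cohort.covariates, top,
                             scores=("trs_ab", "trs_c", "tetras"))
print("\npartial correlations with tremor scores (patients only):")
for c in corr:
    if c.significant:
        print(f"  {c.feature} ~ {c.score}: r = {c.r:+.3f}, p = {c.p:.2e}  *")
print("(the planted coupling makes the affected hub's degree features "
      "track trs_ab negatively)")

print("\ndemographics comparison (matched by construction):")
print(cm.demographic_table(cohort.covariates)[["test", "statistic", "p"]]
      .round(3))
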