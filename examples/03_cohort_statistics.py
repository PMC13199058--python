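"""Two-group cohort comparison on a synthetic burden table.

Samples a cohort from the default template (94 proton-like vs 50
photon-like cases, out-of-CTV burden elevated in the proton-like group),
then runs the normality-gated two-group tests per region and the survival
summary."""

from recurmap import CohortSpec, compare_region, make_cohort, survival_summary

result = make_cohort(CohortSpec(seed=42), rasterize=False)
table = result.ground_truth

for region in ("inside_ctv", "outside_ctv", "transition_zone", "outside_ptv"):
    c = compare_region(table, region)
    print(f"{region:16s} {c.test_used:12s} "
          f"proton median={c.group_a_median:9.1f} "
          f"photon median={c.group_b_median:9.1f} p={c.p_value:.2e}")

summaries, logrank_p = survival_summary(table)
for s in summaries:
    print(f"{s.group}: {s.events}/{s.n} progressed "
          f"({s.progression_proportion_pct}%), "
          f"KM median PFS = {s.median_pfs_months:.2f} months")
print(f"log-rank p = {logrank_p:.4f}")
print("Low p-values outside the CTV reflect the template's built-in group "
      "effect; medians are burdens in mm^3 (1 mm^3 nominal voxels).")
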