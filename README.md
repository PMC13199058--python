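# recurmap

Spatial analysis of where glioblastoma progresses relative to the
radiotherapy target volumes, for neuro-oncology imaging groups comparing
treatment modalities (e.g. a sequential proton boost vs conventional photon
radiotherapy).

Given a post-operative resection-cavity mask and a tumor segmentation at the
progression time point (plus, optionally, a co-registered relative-CBV map
from perfusion MRI), the package:

1. reconstructs an analysis **CTV** (clinical target volume) as the convex
   hull of the resection cavity, rasterized by voxel-center containment,
   and an analysis **PTV** (planning target volume) as the CTV expanded
   concentrically by a physical margin (default 5 mm) with an
   anisotropic-spacing Euclidean distance transform;
2. partitions the contrast-enhancing voxels at progression into six regions
   — inside the CTV, outside the CTV, inside the perfusion **inclusion zone
   (IZ)** inside/outside the CTV, in the CTV–PTV transition zone, and
   beyond the PTV — and bins them by distance from the CTV (≤ 2 cm,
   2–3 cm, > 3 cm);
3. compares the two treatment groups per region with normality-gated tests
   (Shapiro–Wilk, then Student's t or two-sided Mann–Whitney U — exact for
   small tie-free samples), chi-squared tests for categorical covariates,
   subgroup analyses by MGMT/TERT/methylation subtype, and Kaplan–Meier
   progression-free-survival summaries with a log-rank test.

The IZ is the subset of enhancing voxels whose relative CBV reaches a
threshold ratio (default 1.75) of the mean CBV over a normal-appearing
reference region — a stand-in for "metabolically active tumor".

Because patient MRI cannot ship with the package, a first-class synthetic
module generates phantom cases (cavity ball + recurrence spheres at
controlled offsets from the CTV surface + CBV channel) and whole two-group
cohorts with known ground truth, against which every geometric and
statistical claim is tested.

## Worked example

```bash
python examples/02_phantom_case.py
```

```
inside_ctv       pipeline=  281 ground_truth=  281
outside_ctv      pipeline=   80 ground_truth=   80
transition_zone  pipeline=   11 ground_truth=   11
outside_ptv      pipeline=   69 ground_truth=   69
iz_inside_ctv    pipeline=  112 ground_truth=  112
iz_outside_ctv   pipeline=   27 ground_truth=   27
```

The phantom has three recurrence spheres: one deep inside the CTV (281
voxels inside), one straddling the 5 mm CTV–PTV shell (the 11
transition-zone voxels), and one well beyond the PTV (69 voxels). The
pipeline's counts match the generator's brute-force ground truth exactly.

Cohort level (`python examples/03_cohort_statistics.py`, default template of
94 proton-like vs 50 photon-like cases):

```
inside_ctv       mann_whitney proton median=  13092.5 photon median=  13358.0 p=5.06e-01
outside_ctv      mann_whitney proton median=   5752.5 photon median=    623.5 p=6.92e-20
transition_zone  mann_whitney proton median=   1357.5 photon median=    178.0 p=5.04e-15
proton: 79/94 progressed (84.0%), KM median PFS = 10.46 months
photon: 40/50 progressed (80.0%), KM median PFS = 7.41 months
```

The template builds in a proton-like excess of out-of-CTV burden
(concentrated in the transition zone) with no inside-CTV effect — the
comparison detects exactly that pattern.

Shell interface for study directories of NIfTI masks:

```bash
recurmap simulate --out study --seed 7
recurmap run --in study --out results --ptv-margin-mm 5 --iz-threshold 1.75
```

`run` writes `region_counts.csv`, `comparisons.csv`,
`subgroup_comparisons.csv`, `survival.csv`, `report.md` and the resolved
configuration.

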