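# Methods

## Coordinate conventions

All per-case volumes must share one voxel grid; the pipeline never
resamples, because resampling changes absolute voxel counts, the unit of
measure throughout. Alongside counts, every output carries the voxel volume
(mm³) so users can convert to physical volumes when grids differ across
scanners. Geometry uses 0-based voxel indices with voxel-center semantics: a
voxel belongs to a region iff its center does, and the center of voxel *i*
sits at *i* · spacing (mm). The NIfTI affine is preserved through I/O but
plays no role in distances, which are only meaningful within one grid.

## Target-volume reconstruction

The analysis CTV is the convex hull of the resection-cavity voxel centers.
Rasterization rule: a voxel is in the CTV iff its center lies inside or on
the hull (facet half-space test with a relative tolerance of 1e-9 of the
coordinate scale, so centers exactly on a facet are included). Cavities
whose centers are collinear or coplanar have no full-rank 3-D hull; they are
rasterized by distance-to-hull ≤ half the smallest voxel edge, which on any
lattice admits exactly the centers lying on the degenerate hull itself.

The analysis PTV is the CTV expanded concentrically by a physical margin
(default 5 mm): all voxels whose center lies within the margin of the
nearest CTV voxel center, computed with an anisotropic-spacing Euclidean
distance transform. The expansion ball is closed (≤ margin), so a 0 mm
margin is the identity, and the operation is monotone in the margin. An
absolute tie-break tolerance of 1e-9 mm absorbs floating-point noise in the
transform at distance thresholds without admitting off-boundary lattice
points.

Neither volume is cropped to anatomical boundaries by default — the hull may
extend beyond the brain. An optional brain-mask crop exists for users who
want anatomically constrained volumes; cropped volumes are always subsets of
the uncropped ones. Both treatment groups use the same hull + margin
construction: this is a post-hoc analysis geometry, not the clinically
planned target volume of either modality.

## Region classification

Enhancing voxels at progression are tallied as: inside CTV, outside CTV,
IZ ∩ inside CTV, IZ ∩ outside CTV, transition zone (PTV \ CTV), and beyond
PTV. By construction inside + outside = total, transition + beyond =
outside, and IZ counts are sub-counts of their regions; these identities are
validated on every emitted row.

Distance bands bin enhancing voxels by Euclidean distance to the CTV voxel
set (0 on or inside the CTV; unsigned, so the bands partition the counted
voxels): ≤ 2 cm, 2–3 cm, > 3 cm by default, closed on the left band.
Inside-CTV voxels count in the first band by default; `include_inside=False`
drops them from the denominator. Both cut points and the
inside-voxel policy are configurable.

The inclusion zone is derived as enhancing voxels with CBV ≥ ratio × mean
CBV over a user-supplied normal-appearing reference region. The default
ratio of 1.75 is a conventional relative-CBV cutoff for distinguishing
active tumor; how a perfusion map becomes a binary zone is genuinely open
(fixed cutoff, visual reading, and vendor outputs all occur in practice), so
the ratio is configurable and a pre-made IZ mask can be supplied instead,
bypassing derivation entirely. Restricting the IZ to enhancing voxels makes
its tallies sub-counts of the inside/outside regions.

## Cohort statistics

Per region, the two groups are compared after a Shapiro–Wilk normality gate
(Student's t-test only if both groups have Shapiro–Wilk p ≥ α, else
two-sided Mann–Whitney U; constant samples, where Shapiro–Wilk is undefined,
route to Mann–Whitney). The Mann–Whitney p-value is exact when both n ≤ 8
and the pooled sample is tie-free, otherwise the tie-corrected normal
approximation with continuity correction. Medians and IQRs use linear
interpolation. A `method` argument can force either test when the automatic
gate is not wanted.

Categorical covariates use Pearson's chi-squared without Yates correction on
the group × level table, with unknown levels dropped by default. PFS is
summarized by Kaplan–Meier medians per group with a log-rank test;
progression proportions are 100 · events / n rounded to one decimal, and
cases without a recorded time contribute to the proportion but not the
curve. All p-values are two-sided and reported raw — no multiple-testing
correction is applied by default, though a Benjamini–Hochberg helper is
provided.

## Synthetic data

Phantoms: the cavity is a rasterized ball; recurrence components are balls
placed at controlled signed offsets from the CTV surface along random
directions (offset found by marching the signed distance map outward from
the cavity center), which gives direct analytic control over region
membership. The CBV channel is background level 1.0 with Gaussian noise
(σ = 0.05) and an elevated level of 3.0 on a per-component random fraction
of voxels; the reference region is a small ball in a fixed
lesion-distant location. Ground truth is measured, not assumed: CTV
membership by per-voxel half-space tests against the cavity hull, distances
by exact nearest-neighbour queries (KD-tree) rather than a distance
transform, so a pipeline/ground-truth match is a genuine two-route check of
the distance machinery.

Cohorts: per-region recurrence burdens (mm³) are log-normal; the photon-like
baseline medians (inside ≈ 19 000 mm³, transition ≈ 156 mm³, beyond ≈
270 mm³, log-scale spreads 0.8/1.3/1.3) give the same order of magnitude and
dynamic range as the emulated study (out-of-CTV burdens of order 10³ vs 10²)
without claiming to reproduce it; the proton-like group multiplies each
region's median by a per-region effect (defaults 0.76 inside, 9.5
transition, 8.9 beyond). Covariates are i.i.d. categorical with frequencies
of the same character as the emulated cohort. Progression follows an
exponential event time with independent exponential censoring whose rate is
chosen so the probability of observing progression equals the target
(84 % proton-like, 80 % photon-like); Kaplan–Meier on the result therefore
recovers the stated PFS medians (9.56 / 6.77 months). Group sizes default to
94 vs 50.

`rasterize=False` returns the sampled burden table directly (at a nominal
1 mm³ voxel) without building volumes — the fast path used for calibration
and power experiments, whose statistical content does not depend on
rasterization. `rasterize=True` converts burdens into sphere components
(one inside ball sized to the inside burden, 3 mm spheres mid-shell for the
transition burden, 4 mm spheres at 10–40 mm beyond the surface) on the
default 96³ grid at 2 mm; realized counts then track, but do not exactly
equal, the sampled burdens (sphere overlap and shell leakage make the
mapping proportional rather than exact), and the ground-truth table records
the measured counts. One seeded generator drives each cohort, with per-case
streams keyed by (seed, case index) so cases are reproducible independently
of cohort size.

What the phantoms do *not* emulate: realistic MRI intensities and lesion
texture, mass effect, anatomically constrained growth, non-spherical
recurrence shapes, and registration error between time points. Passing tests
therefore establish the correctness of the geometry and statistics on
idealized inputs, not robustness to segmentation or registration noise in
real data.

## Numerical choices and degenerate inputs

- Distance-threshold ties break inclusively (≤) with a 1e-9 mm tolerance,
  identical in the pipeline and the ground-truth builder.
- Hull facet tests use a 1e-9 relative tolerance; rank-deficient cavities
  use the half-voxel distance rule described above.
- Empty enhancing masks yield all-zero rows (legal, logged as a warning at
  pipeline level for empty IZ or out-of-CTV sets); empty cavities are
  errors, since no target volume can be built.
- CSV/NIfTI round trips preserve voxel counts exactly and spacings to
  1e-4 mm (NIfTI headers store float32 zooms).
- Test problem sizes: geometry oracles run on grids ≤ 25³ where exhaustive
  per-voxel checking is exact and cheap; phantom invariants use 48³ grids at
  2 mm; calibration (1000 replicates) and power (200 replicates) use the
  tabular cohort path.

## Known limitations

- Absolute voxel counts are grid-dependent; cross-scanner cohorts should
  compare the mm³ columns instead (both are emitted).
- The IZ definition is a configurable stand-in; results involving IZ regions
  depend on the chosen reference region and ratio.
- The Mann–Whitney exact path is limited to n ≤ 8 per group; beyond that the
  tie-corrected asymptotic p is used (the two agree within 0.05 already at
  n = 8, checked by property test).
- The survival layer deliberately stops at Kaplan–Meier + log-rank; no Cox
  modeling or covariate adjustment.
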