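"""Synthetic phantom cases and cohorts with known ground-truth structure.

No patient imaging ships with this package, so every geometric and
statistical claim is exercised on phantoms: a resection cavity is a
rasterized ball, the recurrence at progression is a union of balls placed at
controlled signed offsets from the CTV surface, and the CBV channel marks a
random "metabolically active" subset of each recurrence component. The
generator returns, alongside each case, the analytic region counts computed
by brute-force per-voxel tests (exact point-in-hull membership and exact
nearest-neighbour distances), which the analysis pipeline must reproduce.

Cohorts follow a two-group template: per-region recurrence burdens (mm^3)
are log-normal with group-dependent multiplicative effects on the
out-of-CTV compartments, covariates are i.i.d. categorical, progression is
Bernoulli per group and PFS is exponential per group. Default medians are of
the same order as the study cohort this emulates (out-of-CTV burdens of
order 10^3 vs 10^2) without claiming to reproduce it. ``rasterize=False``
samples the burden table directly without building volumes, which is what
the statistical calibration experiments consume; ``rasterize=True``
additionally realizes each case as voxel masks whose measured counts stand
in for the sampled burdens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .spatial_classification import AnalysisConfig, RegionCounts
from .target_volumes import EPS_MM, convex_hull_mask
from .volumes_io import (
    ClinicalRecord,
    GridSpec,
    Group,
    LabelVolume,
    MGMTStatus,
    MethylationSubtype,
    PatientCase,
    ScalarVolume,
    TERTStatus,
    TTFUse,
    records_to_frame,
    write_label_volume,
    write_scalar_volume,
)

__all__ = [
    "RecurrenceComponent",
    "PhantomSpec",
    "CohortSpec",
    "CohortResult",
    "make_phantom_case",
    "ground_truth_counts",
    "make_cohort",
    "iter_cohort_cases",
    "write_study",
]


class PlacementError(RuntimeError):
    """A recurrence component could not be placed inside the grid."""


@dataclass(frozen=True)
class RecurrenceComponent:
    """One spherical recurrence component.

    ``offset_mm`` is the signed distance from the CTV surface to the sphere
    center (negative = inside the CTV, clamped at the cavity center);
    ``active_fraction`` of its voxels receive the elevated CBV level.
    """

    offset_mm: float
    radius_mm: float
    active_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in [0, 1]")


def _default_grid() -> GridSpec:
    return GridSpec((96, 96, 96), (2.0, 2.0, 2.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one phantom case."""

    grid: GridSpec = field(default_factory=_default_grid)
    cavity_center_mm: Optional[tuple[float, float, float]] = None
    cavity_radius_mm: float = 16.0
    recurrence_components: tuple[RecurrenceComponent, ...] = (
        RecurrenceComponent(offset_mm=-30.0, radius_mm=10.0, active_fraction=0.4),
        RecurrenceComponent(offset_mm=2.5, radius_mm=3.0, active_fraction=0.5),
        RecurrenceComponent(offset_mm=15.0, radius_mm=6.0, active_fraction=0.3),
    )
    cbv_active_level: float = 3.0
    cbv_background_level: float = 1.0
    cbv_noise_sd: float = 0.05
    reference_radius_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cavity_radius_mm <= 0:
            raise ValueError("cavity_radius_mm must be positive")

    @property
    def center_mm(self) -> np.ndarray:
        if self.cavity_center_mm is not None:
            return np.asarray(self.cavity_center_mm, dtype=float)
        return np.asarray(self.grid.extent_mm) / 2.0


def _ball_mask(grid: GridSpec, center_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    """Voxels whose centers lie within radius of the center point."""
    spacing = np.asarray(grid.spacing_mm)
    lo = np.maximum(np.floor((center_mm - radius_mm) / spacing), 0).astype(int)
    hi = np.minimum(
        np.ceil((center_mm + radius_mm) / spacing), np.asarray(grid.shape) - 1
    ).astype(int)
    out = np.zeros(grid.shape, dtype=bool)
    if np.any(lo > hi):
        return out
    axes = [np.arange(lo[a], hi[a] + 1) * spacing[a] - center_mm[a] for a in range(3)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij", sparse=True)
    box = dx * dx + dy * dy + dz * dz <= radius_mm * radius_mm
    out[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = box
    return out


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _place_component(
    comp: RecurrenceComponent,
    center_mm: np.ndarray,
    signed_dist: np.ndarray,
    grid: GridSpec,
    rng: np.random.Generator,
    attempts: int = 100,
) -> np.ndarray:
    """Find a component center at the requested signed offset from the CTV.

    Marches outward from the cavity center along a random direction until
    the signed distance map reaches the offset; retries new directions until
    the sphere fits inside the grid.
    """
    spacing = np.asarray(grid.spacing_mm)
    extent = np.asarray(grid.extent_mm)
    step = min(grid.spacing_mm) / 2.0
    t_max = float(np.linalg.norm(extent))
    ts = np.arange(0.0, t_max, step)
    for _ in range(attempts):
        u = _random_unit_vector(rng)
        pts = center_mm + ts[:, None] * u
        idx = np.rint(pts / spacing).astype(int)
        valid = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
        if not valid.any():
            continue
        idx = idx[valid]
        sd = signed_dist[idx[:, 0], idx[:, 1], idx[:, 2]]
        hit = np.nonzero(sd >= comp.offset_mm)[0]
        if len(hit) == 0:
            continue
        pos = pts[valid][hit[0]]
        if np.all(pos - comp.radius_mm >= 0) and np.all(pos + comp.radius_mm <= extent):
            return pos
    raise PlacementError(
        f"could not place component (offset {comp.offset_mm} mm, "
        f"radius {comp.radius_mm} mm) inside the grid after {attempts} attempts"
    )


def make_phantom_case(
    spec: PhantomSpec,
    case_id: str = "phantom",
    record: Optional[ClinicalRecord] = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[PatientCase, RegionCounts]:
    """Build one phantom case and its brute-force ground-truth counts.

    Deterministic for a fixed spec (including its seed). The returned
    :class:`RegionCounts` is computed by :func:`ground_truth_counts`, i.e.
    independently of the analysis pipeline's distance transforms.
    """
    grid = spec.grid
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    center = spec.center_mm
    extent = np.asarray(grid.extent_mm)
    if np.any(center - spec.cavity_radius_mm < 0) or np.any(
        center + spec.cavity_radius_mm > extent
    ):
        raise PlacementError("cavity does not fit inside the grid")

    cavity = _ball_mask(grid, center, spec.cavity_radius_mm)
    cavity_vol = LabelVolume.from_mask(cavity, grid, name="cavity")

    # Signed distance to the CTV surface (negative inside), used only to
    # steer placement; ground truth is measured afterwards.
    ctv = convex_hull_mask(cavity_vol).foreground
    spacing = grid.spacing_mm
    d_out = ndimage.distance_transform_edt(~ctv, sampling=spacing)
    d_in = ndimage.distance_transform_edt(ctv, sampling=spacing)
    signed = d_out - d_in

    enhancing = np.zeros(grid.shape, dtype=bool)
    comp_masks = []
    for comp in spec.recurrence_components:
        pos = _place_component(comp, center, signed, grid, rng)
        m = _ball_mask(grid, pos, comp.radius_mm)
        comp_masks.append((comp, m))
        enhancing |= m

    cbv = rng.normal(spec.cbv_background_level, spec.cbv_noise_sd, size=grid.shape)
    for comp, m in comp_masks:
        vox = np.argwhere(m & enhancing)
        n_active = int(round(comp.active_fraction * len(vox)))
        if n_active > 0:
            chosen = vox[rng.choice(len(vox), size=n_active, replace=False)]
            cbv[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = rng.normal(
                spec.cbv_active_level, spec.cbv_noise_sd, size=n_active
            )
    cbv = np.clip(cbv, 0.01, None)

    ref_center = np.asarray(extent) * np.array([0.15, 0.15, 0.5])
    reference = _ball_mask(grid, ref_center, spec.reference_radius_mm)
    reference &= ~(enhancing | cavity)
    if not reference.any():
        raise PlacementError("reference region overlaps the lesion entirely")

    case = PatientCase(
        case_id=case_id,
        cavity=cavity_vol,
        enhancing=LabelVolume.from_mask(enhancing, grid, name="enhancing"),
        cbv=ScalarVolume(grid=grid, data=cbv),
        reference=LabelVolume.from_mask(reference, grid, name="reference"),
        record=record,
    )
    truth = ground_truth_counts(case, config=config)
    return case, truth


def _in_hull(centers: np.ndarray, hull: ConvexHull, tol: float) -> np.ndarray:
    normals = hull.equations[:, :3]
    offsets = hull.equations[:, 3]
    return np.all(centers @ normals.T + offsets <= tol, axis=1)


def ground_truth_counts(
    case: PatientCase, config: AnalysisConfig = AnalysisConfig()
) -> RegionCounts:
    """Analytic region counts by brute-force per-voxel tests.

    CTV membership is decided voxel center by voxel center against the hull
    half-spaces of the cavity voxel centers; distances from the CTV are exact
    nearest-neighbour distances between voxel centers (KD-tree), not a
    distance transform. Requires a full-rank (non-coplanar) cavity.
    """
    grid = case.grid
    spacing = np.asarray(grid.spacing_mm)
    cav = case.cavity.foreground
    cav_pts = np.argwhere(cav) * spacing
    if len(cav_pts) == 0:
        raise ValueError("ground truth requires a non-empty cavity")
    try:
        hull = ConvexHull(cav_pts)
    except QhullError as exc:
        raise ValueError("ground truth requires a full-rank cavity") from exc
    tol = 1e-9 * (1.0 + float(np.max(np.abs(cav_pts))))

    # CTV voxel set: test every voxel center in the hull's bounding box.
    lo = np.maximum(np.floor(cav_pts.min(axis=0) / spacing), 0).astype(int)
    hi = np.minimum(
        np.ceil(cav_pts.max(axis=0) / spacing), np.asarray(grid.shape) - 1
    ).astype(int)
    axes = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    box_idx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    inside_box = _in_hull(box_idx * spacing, hull, tol)
    ctv = np.zeros(grid.shape, dtype=bool)
    sel = box_idx[inside_box]
    ctv[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    ctv |= cav

    enh = case.enhancing.foreground
    enh_idx = np.argwhere(enh)
    enh_in = ctv[enh_idx[:, 0], enh_idx[:, 1], enh_idx[:, 2]]
    inside_ctv = int(np.count_nonzero(enh_in))
    outside_ctv = int(len(enh_idx) - inside_ctv)

    tree = cKDTree(np.argwhere(ctv) * spacing)
    d_outside = (
        tree.query(enh_idx[~enh_in] * spacing)[0]
        if outside_ctv
        else np.empty(0)
    )
    margin = config.ptv_margin_mm
    transition = int(np.count_nonzero(d_outside <= margin + EPS_MM))
    outside_ptv = outside_ctv - transition

    c1, c2 = config.distance_cuts_mm
    b1 = int(np.count_nonzero(d_outside <= c1 + EPS_MM))
    b2 = int(np.count_nonzero((d_outside > c1 + EPS_MM) & (d_outside <= c2 + EPS_MM)))
    b3 = int(np.count_nonzero(d_outside > c2 + EPS_MM))
    if config.include_inside_in_bands:
        b1 += inside_ctv

    iz_inside = iz_outside = 0
    if case.cbv is not None and case.reference is not None:
        ref = case.reference.foreground
        ref_mean = float(case.cbv.data[ref].mean())
        cutoff = config.iz_threshold_ratio * ref_mean
        iz = enh & (case.cbv.data >= cutoff)
        iz_inside = int(np.count_nonzero(iz & ctv))
        iz_outside = int(np.count_nonzero(iz & ~ctv))

    counts = RegionCounts(
        case_id=case.case_id,
        inside_ctv=inside_ctv,
        outside_ctv=outside_ctv,
        iz_inside_ctv=iz_inside,
        iz_outside_ctv=iz_outside,
        transition_zone=transition,
        outside_ptv=outside_ptv,
        band_le_2cm=b1,
        band_2_3cm=b2,
        band_gt_3cm=b3,
        voxel_volume_mm3=grid.voxel_volume_mm3,
    )
    counts.validate(bands_include_inside=config.include_inside_in_bands)
    return counts


# --------------------------------------------------------------------------
# Cohort generation


def _default_covariate_frequencies() -> dict[str, dict[str, float]]:
    return {
        "mgmt": {"methylated": 0.42, "unmethylated": 0.46, "unknown": 0.12},
        "tert": {"mutant": 0.60, "nonmutant": 0.25, "unknown": 0.15},
        "subtype": {"RTK_II": 0.28, "MES": 0.20, "RTK_I": 0.15,
                    "none": 0.10, "unknown": 0.27},
        "ttf": {"used": 0.15, "not_used": 0.44, "unknown": 0.41},
    }


def _default_medians() -> dict[str, float]:
    # Photon-like baseline burdens in mm^3; same order of magnitude as the
    # emulated cohort (inside-CTV ~2x10^4, out-of-CTV compartments ~10^2).
    return {"inside": 19000.0, "transition": 156.0, "beyond": 270.0}


def _default_effects() -> dict[str, float]:
    # Proton-like multiplicative effects: slightly smaller inside burden,
    # roughly an order of magnitude more mass in the transition zone and
    # beyond the PTV.
    return {"inside": 0.76, "transition": 9.5, "beyond": 8.9}


def _default_sigmas() -> dict[str, float]:
    return {"inside": 0.8, "transition": 1.3, "beyond": 1.3}


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort template.

    ``volume_medians_mm3`` are the photon-like per-region burden medians;
    the proton-like group multiplies each region's median by
    ``group_effect[region]``. Burdens are log-normal with log-scale spread
    ``volume_sigmas``. PFS is exponential with the stated per-group median;
    non-progressed cases carry an exponential last-follow-up time and are
    censored there.
    """

    n_per_group: tuple[int, int] = (94, 50)  # (proton, photon)
    group_effect: dict = field(default_factory=_default_effects)
    volume_medians_mm3: dict = field(default_factory=_default_medians)
    volume_sigmas: dict = field(default_factory=_default_sigmas)
    covariate_frequencies: dict = field(default_factory=_default_covariate_frequencies)
    progression_probability: dict = field(
        default_factory=lambda: {"proton": 0.84, "photon": 0.80}
    )
    pfs_median_months: dict = field(
        default_factory=lambda: {"proton": 9.56, "photon": 6.77}
    )
    iz_fraction_range: tuple[float, float] = (0.1, 0.5)
    grid: GridSpec = field(default_factory=_default_grid)
    min_cavity_radius_mm: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 3:
            raise ValueError("need at least 3 cases per group")
        for region, sigma in self.volume_sigmas.items():
            if sigma <= 0:
                raise ValueError(f"sigma for {region} must be positive")
        for cov, freqs in self.covariate_frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{cov} frequencies sum to {total}, expected 1")


_ENUMS = {"mgmt": MGMTStatus, "tert": TERTStatus, "subtype": MethylationSubtype,
          "ttf": TTFUse}


def _case_rng(seed: int, index: int) -> np.random.Generator:
    # Per-case streams keyed by (cohort seed, case index) so each case is
    # reproducible independently of cohort size.
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _sample_case(spec: CohortSpec, group: str, index: int) -> dict:
    rng = _case_rng(spec.seed, index)
    burdens = {}
    for region in ("inside", "transition", "beyond"):
        median = spec.volume_medians_mm3[region]
        if group == "proton":
            median *= spec.group_effect.get(region, 1.0)
        burdens[region] = float(
            rng.lognormal(mean=math.log(median), sigma=spec.volume_sigmas[region])
        )
    covs = {}
    for cov, freqs in spec.covariate_frequencies.items():
        levels = list(freqs)
        covs[cov] = str(rng.choice(levels, p=[freqs[k] for k in levels]))
    # Exponential event times with independent exponential censoring whose
    # rate is set so P(event before censoring) equals the target progression
    # probability; Kaplan-Meier on the result recovers the stated median.
    p_prog = spec.progression_probability[group]
    rate = math.log(2) / spec.pfs_median_months[group]
    t_event = float(rng.exponential(1.0 / rate))
    if p_prog >= 1.0:
        t_censor = math.inf
    else:
        censor_rate = rate * (1.0 - p_prog) / p_prog
        t_censor = float(rng.exponential(1.0 / censor_rate))
    progressed = t_event <= t_censor
    pfs = min(t_event, t_censor)
    f_lo, f_hi = spec.iz_fraction_range
    iz_in = float(rng.uniform(f_lo, f_hi))
    iz_out = float(rng.uniform(f_lo, f_hi))
    band_split = rng.multinomial(1000, [0.35, 0.35, 0.30]) / 1000.0
    return {
        "burdens": burdens, "covariates": covs, "progressed": progressed,
        "pfs_months": pfs, "iz_in": iz_in, "iz_out": iz_out,
        "band_split": band_split, "rng": rng,
    }


def _record_from_sample(case_id: str, group: str, sample: dict) -> ClinicalRecord:
    covs = sample["covariates"]
    return ClinicalRecord(
        case_id=case_id,
        group=Group(group),
        mgmt=MGMTStatus(covs["mgmt"]),
        tert=TERTStatus(covs["tert"]),
        subtype=MethylationSubtype(covs["subtype"]),
        ttf=TTFUse(covs["ttf"]),
        progressed=sample["progressed"],
        pfs_months=sample["pfs_months"],
    )


def _tabular_counts(case_id: str, sample: dict) -> RegionCounts:
    """Burden table row at a nominal 1 mm^3 voxel, without rasterization."""
    inside = int(round(sample["burdens"]["inside"]))
    transition = int(round(sample["burdens"]["transition"]))
    beyond = int(round(sample["burdens"]["beyond"]))
    outside = transition + beyond
    # Beyond-PTV mass is spread over the distance bands (5-20, 20-30,
    # > 30 mm); transition mass is always within the first band.
    shares = sample["band_split"]
    b1_extra = int(round(shares[0] * beyond))
    b2 = int(round(shares[1] * beyond))
    b2 = min(b2, beyond - b1_extra)
    b3 = beyond - b1_extra - b2
    return RegionCounts(
        case_id=case_id,
        inside_ctv=inside,
        outside_ctv=outside,
        iz_inside_ctv=int(round(sample["iz_in"] * inside)),
        iz_outside_ctv=int(round(sample["iz_out"] * outside)),
        transition_zone=transition,
        outside_ptv=beyond,
        band_le_2cm=inside + transition + b1_extra,
        band_2_3cm=b2,
        band_gt_3cm=b3,
        voxel_volume_mm3=1.0,
    )


# Unit recurrence spheres used to deposit burden in each compartment. The
# per-sphere transition-zone yield is approximate (a 3 mm sphere centered in
# the 5 mm shell leaks a little both ways); realized counts are measured by
# the ground-truth builder, so only proportionality matters.
_TRANSITION_SPHERE_R = 3.0
_TRANSITION_SPHERE_YIELD = 80.0  # mm^3 in-shell per sphere, rough
_BEYOND_SPHERE_R = 4.0
_MAX_SPHERES = 150


def _phantom_spec_from_sample(spec: CohortSpec, sample: dict, index: int) -> PhantomSpec:
    burdens = sample["burdens"]
    r_in = (3.0 * burdens["inside"] / (4.0 * math.pi)) ** (1.0 / 3.0)
    r_cav = max(spec.min_cavity_radius_mm, 1.1 * r_in)
    max_r = 0.35 * min(spec.grid.extent_mm)
    r_cav = min(r_cav, max_r)
    r_in = min(r_in, 0.9 * r_cav)
    rng = sample["rng"]
    comps = [RecurrenceComponent(offset_mm=-2.0 * r_cav, radius_mm=r_in,
                                 active_fraction=sample["iz_in"])]
    v_sphere = 4.0 / 3.0 * math.pi * _BEYOND_SPHERE_R ** 3
    k_tr = min(_MAX_SPHERES, int(round(burdens["transition"] / _TRANSITION_SPHERE_YIELD)))
    k_bey = min(_MAX_SPHERES, int(round(burdens["beyond"] / v_sphere)))
    # Keep beyond-PTV sphere centers reachable inside the grid for any
    # cavity size (cavity sits at the grid center).
    o_hi = min(40.0, 0.5 * min(spec.grid.extent_mm) - r_cav - _BEYOND_SPHERE_R - 2.0)
    o_hi = max(o_hi, 12.0)
    for _ in range(k_tr):
        comps.append(
            RecurrenceComponent(
                offset_mm=float(rng.uniform(1.5, 3.5)),
                radius_mm=_TRANSITION_SPHERE_R,
                active_fraction=sample["iz_out"],
            )
        )
    for _ in range(k_bey):
        comps.append(
            RecurrenceComponent(
                offset_mm=float(rng.uniform(10.0, o_hi)),
                radius_mm=_BEYOND_SPHERE_R,
                active_fraction=sample["iz_out"],
            )
        )
    return PhantomSpec(
        grid=spec.grid,
        cavity_radius_mm=r_cav,
        recurrence_components=tuple(comps),
        seed=int(np.random.SeedSequence([spec.seed, index, 1]).generate_state(1)[0]
                 % (2**31 - 1)),
    )


def _case_ids_and_groups(spec: CohortSpec) -> list[tuple[str, str]]:
    n_proton, n_photon = spec.n_per_group
    out = [(f"P{i + 1:03d}", "proton") for i in range(n_proton)]
    out += [(f"X{i + 1:03d}", "photon") for i in range(n_photon)]
    return out


def iter_cohort_cases(
    spec: CohortSpec, config: AnalysisConfig = AnalysisConfig()
) -> Iterator[tuple[PatientCase, ClinicalRecord, RegionCounts]]:
    """Yield rasterized cases one at a time (memory-friendly).

    Ground truth counts are computed with the given analysis configuration.
    """
    for index, (case_id, group) in enumerate(_case_ids_and_groups(spec)):
        sample = _sample_case(spec, group, index)
        record = _record_from_sample(case_id, group, sample)
        pspec = _phantom_spec_from_sample(spec, sample, index)
        case, truth = make_phantom_case(pspec, case_id=case_id, record=record,
                                        config=config)
        yield case, record, truth


@dataclass
class CohortResult:
    """Everything the pipeline entry point consumes."""

    cases: list  # list[PatientCase]; empty in tabular mode
    records: list  # list[ClinicalRecord]
    cohort: pd.DataFrame  # clinical covariates
    ground_truth: pd.DataFrame  # RegionCounts rows joined with covariates


def _truth_frame(truths: list[RegionCounts], cohort: pd.DataFrame) -> pd.DataFrame:
    rows = pd.DataFrame([t.as_dict() for t in truths])
    return rows.merge(cohort, on="case_id", validate="one_to_one")


def make_cohort(
    spec: CohortSpec,
    rasterize: bool = True,
    config: AnalysisConfig = AnalysisConfig(),
) -> CohortResult:
    """Generate a synthetic two-group cohort.

    With ``rasterize=True`` every case is realized as voxel volumes and the
    ground-truth table holds the measured brute-force counts. With
    ``rasterize=False`` the sampled burden table itself (at a nominal
    1 mm^3 voxel) is returned and no volumes are built — the fast path for
    statistical calibration experiments.
    """
    records: list[ClinicalRecord] = []
    truths: list[RegionCounts] = []
    cases: list[PatientCase] = []
    if rasterize:
        for case, record, truth in iter_cohort_cases(spec, config=config):
            cases.append(case)
            records.append(record)
            truths.append(truth)
    else:
        for index, (case_id, group) in enumerate(_case_ids_and_groups(spec)):
            sample = _sample_case(spec, group, index)
            records.append(_record_from_sample(case_id, group, sample))
            truths.append(_tabular_counts(case_id, sample))
    cohort = records_to_frame(records)
    return CohortResult(
        cases=cases, records=records, cohort=cohort,
        ground_truth=_truth_frame(truths, cohort),
    )


def write_study(
    spec: CohortSpec,
    out_dir: Path,
    config: AnalysisConfig = AnalysisConfig(),
) -> Path:
    """Write a complete synthetic study directory consumable by the pipeline.

    Layout: one subdirectory per case with cavity/enhancing/cbv/reference
    NIfTI volumes, plus ``cohort.csv`` and ``ground_truth.csv`` at the root.
    Cases are generated and written one at a time.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: list[ClinicalRecord] = []
    truths: list[RegionCounts] = []
    for case, record, truth in iter_cohort_cases(spec, config=config):
        case_dir = out_dir / case.case_id
        case_dir.mkdir(exist_ok=True)
        write_label_volume(case.cavity, case_dir / "cavity.nii.gz")
        write_label_volume(case.enhancing, case_dir / "enhancing.nii.gz")
        if case.cbv is not None:
            write_scalar_volume(case.cbv, case_dir / "cbv.nii.gz")
        if case.reference is not None:
            write_label_volume(case.reference, case_dir / "reference.nii.gz")
        records.append(record)
        truths.append(truth)
    cohort = records_to_frame(records)
    cohort.to_csv(out_dir / "cohort.csv", index=False)
    _truth_frame(truths, cohort).to_csv(out_dir / "ground_truth.csv", index=False)
    return out_dir
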