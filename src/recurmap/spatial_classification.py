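"""Six-region classification of contrast-enhancing voxels at progression.

Enhancing voxels are partitioned relative to the analysis target volumes:

1. inside the CTV,
2. outside the CTV,
3. inside the perfusion inclusion zone (IZ) and inside the CTV,
4. inside the IZ and outside the CTV,
5. in the CTV-PTV transition zone (PTV minus CTV),
6. outside the PTV,

and additionally binned by Euclidean distance (mm) from the CTV voxel set
(distance 0 on or inside the CTV): <= 2 cm, 2-3 cm, > 3 cm by default. Band
edges are closed on the left band (<= cut). The IZ is the subset of
enhancing voxels whose relative CBV reaches a threshold ratio of the mean
CBV over a normal-appearing reference region; the default ratio of 1.75 is a
conventional rCBV cutoff and is configurable, as is supplying a pre-made IZ
mask instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .target_volumes import EPS_MM, TargetVolumes, build_target_volumes
from .volumes_io import (
    GridMismatchError,
    LabelVolume,
    PatientCase,
    ScalarVolume,
    assert_same_grid,
)

__all__ = [
    "AnalysisConfig",
    "InclusionZone",
    "RegionCounts",
    "REGION_FIELDS",
    "derive_inclusion_zone",
    "classify_regions",
    "distance_bands",
    "summarize_case",
]

REGION_FIELDS = (
    "inside_ctv",
    "outside_ctv",
    "iz_inside_ctv",
    "iz_outside_ctv",
    "transition_zone",
    "outside_ptv",
)

BAND_FIELDS = ("band_le_2cm", "band_2_3cm", "band_gt_3cm")


@dataclass(frozen=True)
class AnalysisConfig:
    """Per-case analysis parameters.

    ptv_margin_mm
        Concentric CTV -> PTV expansion (mm).
    iz_threshold_ratio
        rCBV cutoff relative to the reference-region mean.
    distance_cuts_mm
        Strictly increasing pair of band edges from the CTV (mm).
    include_inside_in_bands
        Whether inside-CTV voxels (distance 0) count in the first band.
    """

    ptv_margin_mm: float = 5.0
    iz_threshold_ratio: float = 1.75
    distance_cuts_mm: tuple[float, float] = (20.0, 30.0)
    include_inside_in_bands: bool = True
    crop_to_brain_mask: bool = False

    def __post_init__(self) -> None:
        if self.ptv_margin_mm < 0:
            raise ValueError("ptv_margin_mm must be >= 0")
        if self.iz_threshold_ratio <= 0:
            raise ValueError("iz_threshold_ratio must be > 0")
        c1, c2 = self.distance_cuts_mm
        if not (0 < c1 < c2):
            raise ValueError("distance_cuts_mm must be strictly increasing and positive")


@dataclass
class InclusionZone:
    """Perfusion-defined metabolically active subset of enhancing tumor."""

    mask: LabelVolume
    threshold_ratio: float
    reference_stat: float

    def __post_init__(self) -> None:
        if self.threshold_ratio <= 0:
            raise ValueError("threshold_ratio must be positive")


@dataclass
class RegionCounts:
    """Voxel tallies for one case.

    Counts are on the native grid; ``voxel_volume_mm3`` converts them to
    physical volumes (count * voxel volume) for cross-grid comparability.
    """

    case_id: str
    inside_ctv: int = 0
    outside_ctv: int = 0
    iz_inside_ctv: int = 0
    iz_outside_ctv: int = 0
    transition_zone: int = 0
    outside_ptv: int = 0
    band_le_2cm: int = 0
    band_2_3cm: int = 0
    band_gt_3cm: int = 0
    voxel_volume_mm3: float = 1.0
    extras: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.inside_ctv + self.outside_ctv

    def validate(self, bands_include_inside: bool = True) -> None:
        """Check the partition identities; raise ``ValueError`` on violation."""
        for name in REGION_FIELDS + BAND_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{self.case_id}: negative count {name}")
        if self.transition_zone + self.outside_ptv != self.outside_ctv:
            raise ValueError(
                f"{self.case_id}: transition_zone + outside_ptv != outside_ctv"
            )
        if self.iz_inside_ctv > self.inside_ctv or self.iz_outside_ctv > self.outside_ctv:
            raise ValueError(f"{self.case_id}: IZ counts exceed region counts")
        band_total = self.band_le_2cm + self.band_2_3cm + self.band_gt_3cm
        expected = self.total if bands_include_inside else self.outside_ctv
        if band_total != expected:
            raise ValueError(
                f"{self.case_id}: bands sum to {band_total}, expected {expected}"
            )
        if self.voxel_volume_mm3 <= 0:
            raise ValueError(f"{self.case_id}: voxel_volume_mm3 must be positive")

    def as_dict(self) -> dict:
        d = {"case_id": self.case_id}
        for name in REGION_FIELDS + BAND_FIELDS:
            d[name] = int(getattr(self, name))
        d["voxel_volume_mm3"] = self.voxel_volume_mm3
        for name in REGION_FIELDS:
            d[name + "_mm3"] = getattr(self, name) * self.voxel_volume_mm3
        return d


def derive_inclusion_zone(
    enhancing: LabelVolume,
    cbv: ScalarVolume,
    reference: LabelVolume,
    threshold_ratio: float = 1.75,
) -> InclusionZone:
    """Threshold CBV against a reference region to get the inclusion zone.

    IZ = enhancing voxels whose CBV >= threshold_ratio * mean CBV over the
    reference mask (contralateral normal-appearing white matter in practice).
    The IZ is restricted to enhancing voxels so its region tallies are
    sub-counts of the inside/outside-CTV regions.
    """
    assert_same_grid([enhancing, cbv, reference], names=["enhancing", "cbv", "reference"])
    ref = reference.foreground
    if not ref.any():
        raise ValueError("reference region is empty")
    ref_mean = float(cbv.data[ref].mean())
    if ref_mean <= 0:
        raise ValueError(f"reference mean CBV must be positive, got {ref_mean}")
    cutoff = threshold_ratio * ref_mean
    mask = enhancing.foreground & (cbv.data >= cutoff)
    return InclusionZone(
        mask=LabelVolume.from_mask(mask, enhancing.grid, name="iz"),
        threshold_ratio=threshold_ratio,
        reference_stat=ref_mean,
    )


def _distance_to_set(mask: np.ndarray, spacing) -> np.ndarray:
    """Per-voxel Euclidean distance (mm) to the nearest mask voxel center."""
    if not mask.any():
        raise ValueError("distance to an empty set is undefined")
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def distance_bands(
    enhancing: LabelVolume,
    ctv: LabelVolume,
    cut_mm: tuple[float, float] = (20.0, 30.0),
    include_inside: bool = True,
) -> tuple[int, int, int]:
    """Bin enhancing voxels by distance from the CTV voxel set.

    Distance is 0 for voxels inside the CTV; bands are ``d <= cut1``,
    ``cut1 < d <= cut2`` and ``d > cut2`` (closed on the left band). With
    ``include_inside`` false, inside-CTV voxels are dropped entirely.
    """
    c1, c2 = cut_mm
    if not c1 < c2:
        raise ValueError("distance cuts must be strictly increasing")
    assert_same_grid([enhancing, ctv], names=["enhancing", "ctv"])
    dist = _distance_to_set(ctv.foreground, ctv.grid.spacing_mm)
    sel = enhancing.foreground
    if not include_inside:
        sel = sel & ~ctv.foreground
    d = dist[sel]
    b1 = int(np.count_nonzero(d <= c1 + EPS_MM))
    b2 = int(np.count_nonzero((d > c1 + EPS_MM) & (d <= c2 + EPS_MM)))
    b3 = int(np.count_nonzero(d > c2 + EPS_MM))
    return b1, b2, b3


def classify_regions(
    enhancing: LabelVolume,
    targets: TargetVolumes,
    iz: Optional[InclusionZone] = None,
    case_id: str = "",
    distance_cuts_mm: tuple[float, float] = (20.0, 30.0),
    include_inside_in_bands: bool = True,
) -> RegionCounts:
    """Tally enhancing voxels in the six regions plus distance bands."""
    assert_same_grid([enhancing, targets.ctv], names=["enhancing", "ctv"])
    enh = enhancing.foreground
    ctv = targets.ctv.foreground
    ptv = targets.ptv.foreground

    if iz is not None:
        assert_same_grid([enhancing, iz.mask], names=["enhancing", "iz"])
        izm = iz.mask.foreground
        if np.any(izm & ~enh):
            raise ValueError("inclusion zone must be a subset of the enhancing mask")
    else:
        izm = np.zeros_like(enh)

    bands = distance_bands(
        enhancing, targets.ctv, cut_mm=distance_cuts_mm,
        include_inside=include_inside_in_bands,
    )
    counts = RegionCounts(
        case_id=case_id,
        inside_ctv=int(np.count_nonzero(enh & ctv)),
        outside_ctv=int(np.count_nonzero(enh & ~ctv)),
        iz_inside_ctv=int(np.count_nonzero(izm & ctv)),
        iz_outside_ctv=int(np.count_nonzero(izm & ~ctv)),
        transition_zone=int(np.count_nonzero(enh & ptv & ~ctv)),
        outside_ptv=int(np.count_nonzero(enh & ~ptv)),
        band_le_2cm=bands[0],
        band_2_3cm=bands[1],
        band_gt_3cm=bands[2],
        voxel_volume_mm3=enhancing.grid.voxel_volume_mm3,
    )
    counts.validate(bands_include_inside=include_inside_in_bands)
    return counts


def summarize_case(
    case: PatientCase,
    config: AnalysisConfig = AnalysisConfig(),
    brain_mask: Optional[LabelVolume] = None,
) -> RegionCounts:
    """Run the full per-case analysis: targets, inclusion zone, regions.

    The inclusion zone is taken from ``case.iz_mask`` when supplied,
    otherwise derived from CBV when both CBV and a reference region are
    present; without either, IZ counts are zero. Deterministic for fixed
    inputs and configuration.
    """
    targets = build_target_volumes(
        case.cavity,
        ptv_margin_mm=config.ptv_margin_mm,
        brain_mask=brain_mask,
        crop_to_brain_mask=config.crop_to_brain_mask,
    )
    iz: Optional[InclusionZone] = None
    if case.iz_mask is not None:
        mask = case.iz_mask.foreground & case.enhancing.foreground
        iz = InclusionZone(
            mask=LabelVolume.from_mask(mask, case.grid, name="iz"),
            threshold_ratio=config.iz_threshold_ratio,
            reference_stat=float("nan"),
        )
    elif case.cbv is not None and case.reference is not None:
        iz = derive_inclusion_zone(
            case.enhancing, case.cbv, case.reference,
            threshold_ratio=config.iz_threshold_ratio,
        )
    return classify_regions(
        case.enhancing,
        targets,
        iz=iz,
        case_id=case.case_id,
        distance_cuts_mm=config.distance_cuts_mm,
        include_inside_in_bands=config.include_inside_in_bands,
    )


def region_label_volume(
    enhancing: LabelVolume, targets: TargetVolumes, iz: Optional[InclusionZone] = None
) -> LabelVolume:
    """Six-region label map (labels 1-6) of enhancing voxels for visual QC."""
    enh = enhancing.foreground
    ctv = targets.ctv.foreground
    ptv = targets.ptv.foreground
    izm = iz.mask.foreground if iz is not None else np.zeros_like(enh)
    data = np.zeros(enhancing.grid.shape, dtype=np.int16)
    data[enh & ctv] = 1
    data[enh & ~ctv] = 2
    data[izm & ctv] = 3
    data[izm & ~ctv] = 4
    data[enh & ptv & ~ctv & ~izm] = 5
    data[enh & ~ptv & ~izm] = 6
    return LabelVolume(
        grid=enhancing.grid,
        data=data,
        label_map={1: "inside_ctv", 2: "outside_ctv", 3: "iz_inside_ctv",
                   4: "iz_outside_ctv", 5: "transition_zone", 6: "outside_ptv"},
    )
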