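"""Reading, writing and validating label volumes, CBV maps and cohort tables.

All per-case volumes of a patient must live on one voxel grid; the pipeline
never resamples, because resampling changes absolute voxel counts, which are
the unit of measure throughout. Geometry is computed in millimetres in the
spacing-scaled index frame (voxel ``i`` has its center at ``i * spacing_mm``);
the affine is carried through for serialization but plays no role in
distances, which are only meaningful within one grid anyway.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "LabelVolume",
    "ScalarVolume",
    "PatientCase",
    "ClinicalRecord",
    "Group",
    "MGMTStatus",
    "TERTStatus",
    "MethylationSubtype",
    "TTFUse",
    "VolumeFormatError",
    "GridMismatchError",
    "CohortTableError",
    "read_label_volume",
    "write_label_volume",
    "read_scalar_volume",
    "write_scalar_volume",
    "assert_same_grid",
    "read_cohort_table",
    "records_to_frame",
]

# Non-integer voxel values are rounded when within this tolerance of an
# integer, rejected otherwise.
INTEGER_TOL = 1e-3
# Grids "agree" when spacings match within 1e-4 mm per axis and affines
# within 1e-3 elementwise.
SPACING_TOL_MM = 1e-4
AFFINE_TOL = 1e-3


class VolumeFormatError(ValueError):
    """The file or array content violates the label-volume contract."""


class GridMismatchError(ValueError):
    """Volumes that must share a grid do not."""


class CohortTableError(ValueError):
    """The cohort CSV violates its schema."""


@dataclass(frozen=True, eq=False)
class GridSpec:
    """A 3D voxel grid bound to physical space.

    Parameters
    ----------
    shape
        Voxels per axis.
    spacing_mm
        Physical edge length of a voxel along each axis, in millimetres.
    affine
        4x4 voxel-index -> scanner-space matrix. Defaults to a diagonal
        affine built from the spacing.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(shape) != 3 or len(spacing) != 3:
            raise VolumeFormatError("GridSpec is strictly three-dimensional")
        if any(s < 1 for s in shape):
            raise VolumeFormatError(f"shape components must be >= 1, got {shape}")
        if any(not (s > 0) for s in spacing):
            raise VolumeFormatError(f"spacing must be positive, got {spacing}")
        affine = self.affine
        if affine is None:
            affine = np.diag([*spacing, 1.0])
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise VolumeFormatError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise VolumeFormatError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(cls, n: int, spacing_mm: float = 1.0) -> "GridSpec":
        return cls((n, n, n), (spacing_mm,) * 3)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical coordinate of the last voxel center along each axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing_mm))

    def matches(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and all(
                abs(a - b) <= SPACING_TOL_MM
                for a, b in zip(self.spacing_mm, other.spacing_mm)
            )
            and bool(np.all(np.abs(self.affine - other.affine) <= AFFINE_TOL))
        )


def _check_shape(grid: GridSpec, data: np.ndarray, what: str) -> None:
    if data.ndim != 3:
        raise VolumeFormatError(f"{what} must be 3D, got {data.ndim}D")
    if tuple(data.shape) != grid.shape:
        raise VolumeFormatError(
            f"{what} shape {tuple(data.shape)} != grid shape {grid.shape}"
        )


@dataclass
class LabelVolume:
    """Integer label array on a grid; 0 is background.

    ``label_map`` associates every non-zero label value with a compartment
    name (cavity, enhancing, non_enhancing, edema, ctv, ptv, iz, ...).
    """

    grid: GridSpec
    data: np.ndarray
    label_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            data = np.asarray(data, dtype=np.int32)
        _check_shape(self.grid, data, "label data")
        if data.min() < 0:
            raise VolumeFormatError("labels must be non-negative")
        present = set(np.unique(data)) - {0}
        missing = sorted(int(v) for v in present if int(v) not in self.label_map)
        if missing:
            raise VolumeFormatError(
                f"labels {missing} present in data but absent from label_map"
            )
        self.data = data

    @classmethod
    def from_mask(
        cls, mask: np.ndarray, grid: GridSpec, name: str = "mask", label: int = 1
    ) -> "LabelVolume":
        mask = np.asarray(mask, dtype=bool)
        return cls(grid=grid, data=mask.astype(np.int16) * label, label_map={label: name})

    @property
    def foreground(self) -> np.ndarray:
        """Boolean array of non-background voxels."""
        return self.data > 0

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.data))

    def with_data(self, data: np.ndarray) -> "LabelVolume":
        return replace(self, data=data)


@dataclass
class ScalarVolume:
    """A real-valued map (e.g. relative CBV, a unitless ratio) on a grid."""

    grid: GridSpec
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        _check_shape(self.grid, data, "scalar data")
        if not np.all(np.isfinite(data)):
            raise VolumeFormatError("scalar volume contains non-finite values")
        self.data = data


class Group(str, enum.Enum):
    proton = "proton"
    photon = "photon"


class MGMTStatus(str, enum.Enum):
    methylated = "methylated"
    unmethylated = "unmethylated"
    unknown = "unknown"


class TERTStatus(str, enum.Enum):
    mutant = "mutant"
    nonmutant = "nonmutant"
    unknown = "unknown"


class MethylationSubtype(str, enum.Enum):
    RTK_I = "RTK_I"
    RTK_II = "RTK_II"
    MES = "MES"
    none = "none"
    unknown = "unknown"


class TTFUse(str, enum.Enum):
    used = "used"
    not_used = "not_used"
    unknown = "unknown"


@dataclass
class ClinicalRecord:
    """One row of the cohort table."""

    case_id: str
    group: Group
    mgmt: MGMTStatus = MGMTStatus.unknown
    tert: TERTStatus = TERTStatus.unknown
    subtype: MethylationSubtype = MethylationSubtype.unknown
    ttf: TTFUse = TTFUse.unknown
    progressed: bool = False
    pfs_months: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pfs_months is not None:
            if not math.isfinite(self.pfs_months) or self.pfs_months < 0:
                raise CohortTableError(
                    f"{self.case_id}: pfs_months must be non-negative, "
                    f"got {self.pfs_months}"
                )


@dataclass
class PatientCase:
    """One patient's volumes plus clinical covariates.

    All volumes must share one grid. ``reference`` is the normal-appearing
    region used to normalize CBV; ``iz_mask`` optionally supplies a pre-made
    inclusion zone, bypassing CBV thresholding.
    """

    case_id: str
    cavity: LabelVolume
    enhancing: LabelVolume
    cbv: Optional[ScalarVolume] = None
    reference: Optional[LabelVolume] = None
    iz_mask: Optional[LabelVolume] = None
    record: Optional[ClinicalRecord] = None

    def __post_init__(self) -> None:
        vols = [v for v in (self.cavity, self.enhancing, self.cbv,
                            self.reference, self.iz_mask) if v is not None]
        assert_same_grid(vols, names=self._volume_names())

    def _volume_names(self) -> list[str]:
        names = ["cavity", "enhancing"]
        for name in ("cbv", "reference", "iz_mask"):
            if getattr(self, name) is not None:
                names.append(name)
        return names

    @property
    def grid(self) -> GridSpec:
        return self.cavity.grid


Volume = Union[LabelVolume, ScalarVolume]


def assert_same_grid(volumes: Sequence[Volume], names: Optional[Sequence[str]] = None) -> None:
    """Raise :class:`GridMismatchError` unless all volumes share one grid.

    Shapes must be identical; spacings may differ by at most 1e-4 mm per
    axis and affines by 1e-3 elementwise.
    """
    if not volumes:
        raise ValueError("assert_same_grid requires a non-empty list")
    if names is None:
        names = [f"volume[{i}]" for i in range(len(volumes))]
    ref = volumes[0].grid
    for name, vol in zip(names[1:], volumes[1:]):
        g = vol.grid
        if g.shape != ref.shape:
            raise GridMismatchError(
                f"{name}: shape {g.shape} != {ref.shape} of {names[0]}"
            )
        for ax in range(3):
            if abs(g.spacing_mm[ax] - ref.spacing_mm[ax]) > SPACING_TOL_MM:
                raise GridMismatchError(
                    f"{name}: spacing mismatch on axis {ax + 1} "
                    f"({g.spacing_mm[ax]} vs {ref.spacing_mm[ax]} mm)"
                )
        if np.any(np.abs(g.affine - ref.affine) > AFFINE_TOL):
            raise GridMismatchError(f"{name}: affine differs from {names[0]}")


def _grid_from_nifti(img: nib.Nifti1Image) -> GridSpec:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return GridSpec(shape=tuple(img.shape[:3]), spacing_mm=zooms, affine=img.affine)


def read_label_volume(path: Union[str, Path], label_map: dict[int, str]) -> LabelVolume:
    """Read a 3D NIfTI label volume.

    Voxel values are rounded to integers when within 1e-3 of one; anything
    else is rejected, as is any label missing from ``label_map``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got shape {img.shape}")
    raw = np.asarray(img.dataobj, dtype=float)
    rounded = np.rint(raw)
    if np.max(np.abs(raw - rounded)) > INTEGER_TOL:
        raise VolumeFormatError(f"{path}: non-integer voxel values beyond tolerance")
    return LabelVolume(grid=_grid_from_nifti(img), data=rounded.astype(np.int32),
                       label_map=dict(label_map))


def write_label_volume(volume: LabelVolume, path: Union[str, Path]) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.int16), volume.grid.affine)
    img.header.set_zooms(volume.grid.spacing_mm)
    nib.save(img, str(path))


def read_scalar_volume(path: Union[str, Path]) -> ScalarVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got shape {img.shape}")
    return ScalarVolume(grid=_grid_from_nifti(img), data=img.get_fdata())


def write_scalar_volume(volume: ScalarVolume, path: Union[str, Path]) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.grid.affine)
    img.header.set_zooms(volume.grid.spacing_mm)
    nib.save(img, str(path))


_COHORT_COLUMNS = ["case_id", "group", "mgmt", "tert", "subtype", "ttf",
                   "progressed", "pfs_months"]

# Categorical columns where out-of-vocabulary values collapse to "unknown".
_LENIENT = {
    "mgmt": MGMTStatus,
    "tert": TERTStatus,
    "subtype": MethylationSubtype,
    "ttf": TTFUse,
}


def _parse_bool(value: object, case_id: str) -> bool:
    s = str(value).strip().lower()
    if s in {"1", "true", "yes"}:
        return True
    if s in {"0", "false", "no"}:
        return False
    raise CohortTableError(f"{case_id}: cannot parse progressed flag {value!r}")


def read_cohort_table(path: Union[str, Path]) -> list[ClinicalRecord]:
    """Read and validate the cohort CSV.

    The treatment group is strict (must be proton or photon); molecular
    covariates fall back to the ``unknown`` level for unrecognized values.
    Missing PFS is allowed only for non-progressed cases.
    """
    frame = pd.read_csv(path, dtype={"case_id": str})
    missing_cols = [c for c in _COHORT_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise CohortTableError(f"cohort table missing columns {missing_cols}")
    dupes = frame["case_id"][frame["case_id"].duplicated()].tolist()
    if dupes:
        raise CohortTableError(f"duplicate case_id values: {sorted(set(dupes))}")

    records: list[ClinicalRecord] = []
    for _, row in frame.iterrows():
        cid = str(row["case_id"])
        group_raw = str(row["group"]).strip()
        try:
            group = Group(group_raw)
        except ValueError:
            allowed = [g.value for g in Group]
            raise CohortTableError(
                f"{cid}: unknown group {group_raw!r}; allowed values: {allowed}"
            ) from None
        cats = {}
        for col, enum_cls in _LENIENT.items():
            raw = str(row[col]).strip()
            try:
                cats[col] = enum_cls(raw)
            except ValueError:
                cats[col] = enum_cls("unknown")
        progressed = _parse_bool(row["progressed"], cid)
        pfs = row["pfs_months"]
        pfs_months = None if pd.isna(pfs) else float(pfs)
        if pfs_months is None and progressed:
            raise CohortTableError(
                f"{cid}: pfs_months missing for a progressed case"
            )
        records.append(
            ClinicalRecord(case_id=cid, group=group, progressed=progressed,
                           pfs_months=pfs_months, **cats)
        )
    return records


def records_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Flatten clinical records to a DataFrame with enum values as strings."""
    return pd.DataFrame(
        {
            "case_id": [r.case_id for r in records],
            "group": [r.group.value for r in records],
            "mgmt": [r.mgmt.value for r in records],
            "tert": [r.tert.value for r in records],
            "subtype": [r.subtype.value for r in records],
            "ttf": [r.ttf.value for r in records],
            "progressed": [r.progressed for r in records],
            "pfs_months": [r.pfs_months for r in records],
        }
    )
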