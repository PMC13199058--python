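"""End-to-end study orchestration.

``run_pipeline`` consumes a study directory (one subdirectory per case with
``cavity.nii.gz`` and ``enhancing.nii.gz``, optionally ``cbv.nii.gz``,
``reference.nii.gz`` and ``iz.nii.gz``, plus ``cohort.csv`` at the root) and
writes region counts, two-group comparisons, subgroup comparisons, survival
summaries and a markdown report. ``simulate`` writes a synthetic study
directory that ``run_pipeline`` can consume directly.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import cohort_stats as cs
from .spatial_classification import AnalysisConfig, REGION_FIELDS, summarize_case
from .synthetic_data import CohortSpec, write_study
from .volumes_io import (
    ClinicalRecord,
    LabelVolume,
    PatientCase,
    read_cohort_table,
    read_label_volume,
    read_scalar_volume,
    records_to_frame,
)

__all__ = ["PipelineConfig", "run_pipeline", "simulate", "write_report"]

logger = logging.getLogger("recurmap")

SUBGROUP_FIELDS = {
    "mgmt": ["methylated", "unmethylated"],
    "tert": ["mutant", "nonmutant"],
    "subtype": ["RTK_I", "RTK_II", "MES"],
}
SUBGROUP_REGIONS = ("inside_ctv", "outside_ctv")


@dataclass
class PipelineConfig:
    """Pipeline parameters; defaults mirror the analysis conventions."""

    input_dir: Path = Path(".")
    output_dir: Path = Path("results")
    ptv_margin_mm: float = 5.0
    iz_threshold_ratio: float = 1.75
    distance_cuts_mm: tuple[float, float] = (20.0, 30.0)
    include_inside_in_bands: bool = True
    alpha: float = 0.05
    crop_to_brain_mask: bool = False
    brain_mask_path: Optional[Path] = None
    skip_bad: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        self.distance_cuts_mm = tuple(float(c) for c in self.distance_cuts_mm)

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            ptv_margin_mm=self.ptv_margin_mm,
            iz_threshold_ratio=self.iz_threshold_ratio,
            distance_cuts_mm=self.distance_cuts_mm,
            include_inside_in_bands=self.include_inside_in_bands,
            crop_to_brain_mask=self.crop_to_brain_mask,
        )

    def to_yaml(self, path: Path) -> None:
        data = dataclasses.asdict(self)
        data["input_dir"] = str(self.input_dir)
        data["output_dir"] = str(self.output_dir)
        data["brain_mask_path"] = (
            str(self.brain_mask_path) if self.brain_mask_path else None
        )
        data["distance_cuts_mm"] = list(self.distance_cuts_mm)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("brain_mask_path"):
            data["brain_mask_path"] = Path(data["brain_mask_path"])
        return cls(**data)


_LABEL_MAPS = {
    "cavity": {1: "cavity"},
    "enhancing": {1: "enhancing"},
    "reference": {1: "reference"},
    "iz": {1: "iz"},
}


def load_case(case_dir: Path, record: ClinicalRecord) -> PatientCase:
    """Load one case directory; cavity and enhancing masks are mandatory."""

    def _opt(name: str):
        for suffix in (".nii.gz", ".nii"):
            p = case_dir / f"{name}{suffix}"
            if p.exists():
                return p
        return None

    cavity_path = _opt("cavity")
    enhancing_path = _opt("enhancing")
    if cavity_path is None or enhancing_path is None:
        raise FileNotFoundError(
            f"{case_dir}: needs cavity and enhancing NIfTI volumes"
        )
    cbv_path = _opt("cbv")
    ref_path = _opt("reference")
    iz_path = _opt("iz")
    return PatientCase(
        case_id=record.case_id,
        cavity=read_label_volume(cavity_path, _LABEL_MAPS["cavity"]),
        enhancing=read_label_volume(enhancing_path, _LABEL_MAPS["enhancing"]),
        cbv=read_scalar_volume(cbv_path) if cbv_path else None,
        reference=read_label_volume(ref_path, _LABEL_MAPS["reference"]) if ref_path else None,
        iz_mask=read_label_volume(iz_path, _LABEL_MAPS["iz"]) if iz_path else None,
        record=record,
    )


def _comparison_row(c: cs.CohortComparison) -> dict:
    return {
        "region": c.region,
        "stratum_field": c.stratum_field or "",
        "stratum_level": c.stratum_level or "",
        "group_a": c.group_a,
        "group_b": c.group_b,
        "n_a": c.n_a,
        "n_b": c.n_b,
        "group_a_median": c.group_a_median,
        "group_a_q1": c.group_a_iqr[0],
        "group_a_q3": c.group_a_iqr[1],
        "group_b_median": c.group_b_median,
        "group_b_q1": c.group_b_iqr[0],
        "group_b_q3": c.group_b_iqr[1],
        "test_used": c.test_used,
        "statistic": c.statistic,
        "p_value": c.p_value,
    }


def analyze_cohort(
    region_counts: pd.DataFrame, alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Cohort statistics on a region-counts table joined with covariates."""
    comparisons = []
    for region in REGION_FIELDS:
        try:
            comparisons.append(_comparison_row(
                cs.compare_region(region_counts, region, alpha=alpha)
            ))
        except ValueError as exc:
            logger.warning("comparison skipped for %s: %s", region, exc)
    subgroup = []
    for stratum_field, levels in SUBGROUP_FIELDS.items():
        for level in levels:
            for region in SUBGROUP_REGIONS:
                try:
                    subgroup.append(_comparison_row(
                        cs.subgroup_compare(
                            region_counts, region, stratum_field, level, alpha=alpha
                        )
                    ))
                except ValueError as exc:
                    logger.warning(
                        "subgroup %s=%s %s skipped: %s",
                        stratum_field, level, region, exc,
                    )
    summaries, logrank_p = cs.survival_summary(region_counts)
    survival = pd.DataFrame(
        [
            {
                "group": s.group,
                "n": s.n,
                "events": s.events,
                "progression_proportion_pct": s.progression_proportion_pct,
                "median_pfs_months": s.median_pfs_months,
                "logrank_p": logrank_p,
            }
            for s in summaries
        ]
    )
    return {
        "comparisons": pd.DataFrame(comparisons),
        "subgroup_comparisons": pd.DataFrame(subgroup),
        "survival": survival,
    }


def write_report(tables: dict[str, pd.DataFrame], path: Path) -> None:
    """Human-readable markdown report mirroring the cohort tables."""
    lines = ["# Progression pattern analysis report", ""]
    lines += ["## Survival", "", tables["survival"].to_markdown(index=False), ""]
    comp = tables["comparisons"]
    if not comp.empty:
        lines += ["## Region comparisons", "", comp.to_markdown(index=False), ""]
    sub = tables["subgroup_comparisons"]
    if not sub.empty:
        lines += ["## Subgroup comparisons", "", sub.to_markdown(index=False), ""]
    Path(path).write_text("\n".join(lines))


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Process every case, assemble the cohort table, run the statistics.

    Returns the paths of the written outputs. Cases failing validation abort
    the run unless ``skip_bad`` is set, in which case they are logged and
    skipped.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_cohort_table(in_dir / "cohort.csv")
    analysis = config.analysis_config()

    brain_mask = None
    if config.crop_to_brain_mask:
        if config.brain_mask_path is None:
            raise ValueError("crop_to_brain_mask requires brain_mask_path")
        brain_mask = read_label_volume(config.brain_mask_path, {1: "brain"})

    rows = []
    kept_records = []
    for record in records:
        started = time.perf_counter()
        try:
            case = load_case(in_dir / record.case_id, record)
            counts = summarize_case(case, analysis, brain_mask=brain_mask)
            counts.validate(bands_include_inside=config.include_inside_in_bands)
        except Exception as exc:
            if config.skip_bad:
                logger.warning("case %s skipped: %s", record.case_id, exc)
                continue
            raise
        elapsed = time.perf_counter() - started
        logger.info("case %s stage=summarize duration=%.2fs outcome=ok",
                    record.case_id, elapsed)
        if counts.iz_inside_ctv + counts.iz_outside_ctv == 0:
            logger.warning("case %s: empty inclusion zone", record.case_id)
        if counts.outside_ctv == 0:
            logger.warning("case %s: no enhancing voxels outside the CTV",
                           record.case_id)
        rows.append(counts.as_dict())
        kept_records.append(record)

    if not rows:
        raise RuntimeError("no cases could be processed")
    region_counts = pd.DataFrame(rows).merge(
        records_to_frame(kept_records), on="case_id", validate="one_to_one"
    )
    tables = analyze_cohort(region_counts, alpha=config.alpha)

    paths = {}
    outputs = {"region_counts": region_counts, **tables}
    for name, frame in outputs.items():
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p
    report_path = out_dir / "report.md"
    write_report(tables, report_path)
    paths["report"] = report_path
    resolved = out_dir / "config.resolved.yaml"
    config.to_yaml(resolved)
    paths["config"] = resolved
    return paths


def simulate(spec: CohortSpec, out_dir: Path,
             config: Optional[AnalysisConfig] = None) -> Path:
    """Write a synthetic study directory consumable by :func:`run_pipeline`."""
    return write_study(spec, Path(out_dir), config=config or AnalysisConfig())


def cohort_spec_from_yaml(path: Path) -> CohortSpec:
    """Build a :class:`CohortSpec` from a YAML mapping of its fields."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "n_per_group" in data:
        data["n_per_group"] = tuple(int(n) for n in data["n_per_group"])
    if "grid" in data:
        g = data["grid"]
        from .volumes_io import GridSpec

        data["grid"] = GridSpec(tuple(g["shape"]), tuple(g["spacing_mm"]))
    return CohortSpec(**data)
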