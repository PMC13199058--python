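import numpy as np
import pytest

from recurmap.spatial_classification import (
    AnalysisConfig,
    classify_regions,
    derive_inclusion_zone,
    distance_bands,
    region_label_volume,
    summarize_case,
)
from recurmap.synthetic_data import PhantomSpec, make_phantom_case
from recurmap.target_volumes import build_target_volumes
from recurmap.volumes_io import (
    GridMismatchError,
    GridSpec,
    LabelVolume,
    PatientCase,
    ScalarVolume,
)

from conftest import make_mask, random_blob
from oracles import min_distance_mm


def small_phantom_spec(seed=0):
    return PhantomSpec(
        grid=GridSpec((48, 48, 48), (2.0, 2.0, 2.0)),
        cavity_radius_mm=10.0,
        seed=seed,
    )


class TestInclusionZone:
    def grid(self):
        return GridSpec.isotropic(12)

    def _setup(self, cbv_values):
        grid = self.grid()
        enh = np.zeros(grid.shape, bool)
        enh[3:7, 3:7, 3:7] = True
        ref = np.zeros(grid.shape, bool)
        ref[9:, 9:, 9:] = True
        return (
            LabelVolume.from_mask(enh, grid, name="enhancing"),
            ScalarVolume(grid=grid, data=cbv_values),
            LabelVolume.from_mask(ref, grid, name="reference"),
        )

    def test_all_below_cutoff_gives_empty_iz(self):
        enh, cbv, ref = self._setup(np.ones(self.grid().shape))
        iz = derive_inclusion_zone(enh, cbv, ref, threshold_ratio=1.75)
        assert iz.mask.count == 0
        assert iz.reference_stat == pytest.approx(1.0)

    def test_all_above_cutoff_gives_full_enhancing(self):
        grid = self.grid()
        data = np.ones(grid.shape)
        data[3:7, 3:7, 3:7] = 2.0
        enh, cbv, ref = self._setup(data)
        iz = derive_inclusion_zone(enh, cbv, ref, threshold_ratio=1.75)
        assert np.array_equal(iz.mask.foreground, enh.foreground)

    def test_mixed_values_match_per_voxel_threshold(self, rng):
        grid = self.grid()
        data = rng.uniform(0.5, 3.0, size=grid.shape)
        enh, cbv, ref = self._setup(data)
        iz = derive_inclusion_zone(enh, cbv, ref, threshold_ratio=1.75)
        cutoff = 1.75 * data[ref.foreground].mean()
        expected = enh.foreground & (data >= cutoff)
        assert np.array_equal(iz.mask.foreground, expected)

    def test_nonpositive_reference_rejected(self):
        enh, cbv, ref = self._setup(np.full(self.grid().shape, -1.0) + 0.0)
        with pytest.raises(ValueError, match="positive"):
            derive_inclusion_zone(enh, cbv, ref)

    def test_grid_mismatch_rejected(self):
        enh, cbv, ref = self._setup(np.ones(self.grid().shape))
        other = GridSpec((12, 12, 12), (1.0, 1.0, 2.0))
        bad = ScalarVolume(grid=other, data=np.ones(other.shape))
        with pytest.raises(GridMismatchError):
            derive_inclusion_zone(enh, bad, ref)


class TestClassifyRegions:
    def test_empty_enhancing_all_zero(self, small_grid, rng):
        cavity = random_blob(small_grid, rng)
        targets = build_target_volumes(cavity, 3.0)
        enh = LabelVolume.from_mask(np.zeros(small_grid.shape, bool), small_grid)
        counts = classify_regions(enh, targets)
        assert counts.total == 0
        assert counts.band_le_2cm == counts.band_2_3cm == counts.band_gt_3cm == 0

    def test_enhancing_equal_to_ctv(self, small_grid, rng):
        cavity = random_blob(small_grid, rng)
        targets = build_target_volumes(cavity, 3.0)
        enh = LabelVolume.from_mask(targets.ctv.foreground.copy(), small_grid)
        counts = classify_regions(enh, targets)
        assert counts.inside_ctv == targets.ctv.count
        assert counts.outside_ctv == 0
        assert counts.transition_zone == 0
        assert counts.outside_ptv == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_brute_force_membership(self, seed):
        rng = np.random.default_rng(400 + seed)
        grid = GridSpec.isotropic(20)
        cavity = random_blob(grid, rng, n_seeds=2, radius_vox=2.5)
        targets = build_target_volumes(cavity, 4.0)
        enh = random_blob(grid, rng, n_seeds=3, radius_vox=3.0)
        counts = classify_regions(enh, targets)
        # brute force: per-voxel membership tallies
        spacing = np.asarray(grid.spacing_mm)
        ctv_pts = np.argwhere(targets.ctv.foreground) * spacing
        inside = outside = trans = beyond = 0
        for v in np.argwhere(enh.foreground):
            in_ctv = targets.ctv.foreground[tuple(v)]
            in_ptv = targets.ptv.foreground[tuple(v)]
            if in_ctv:
                inside += 1
            else:
                outside += 1
                if in_ptv:
                    trans += 1
                else:
                    beyond += 1
        assert (counts.inside_ctv, counts.outside_ctv) == (inside, outside)
        assert (counts.transition_zone, counts.outside_ptv) == (trans, beyond)
        # bands against exact nearest-neighbour distances
        out_pts = np.argwhere(enh.foreground & ~targets.ctv.foreground) * spacing
        d = min_distance_mm(out_pts, ctv_pts) if len(out_pts) else np.empty(0)
        assert counts.band_le_2cm == inside + int(np.count_nonzero(d <= 20.0))
        assert counts.band_2_3cm == int(np.count_nonzero((d > 20.0) & (d <= 30.0)))
        assert counts.band_gt_3cm == int(np.count_nonzero(d > 30.0))

    def test_iz_must_be_subset(self, small_grid, rng):
        from recurmap.spatial_classification import InclusionZone

        cavity = random_blob(small_grid, rng)
        targets = build_target_volumes(cavity, 3.0)
        enh = make_mask(small_grid, [(2, 2, 2)])
        iz_mask = make_mask(small_grid, [(3, 3, 3)])
        iz = InclusionZone(mask=iz_mask, threshold_ratio=1.75, reference_stat=1.0)
        with pytest.raises(ValueError, match="subset"):
            classify_regions(enh, targets, iz=iz)


class TestDistanceBands:
    def test_enhancing_inside_ctv_all_first_band(self, small_grid, rng):
        cavity = random_blob(small_grid, rng)
        targets = build_target_volumes(cavity, 3.0)
        enh = LabelVolume.from_mask(targets.ctv.foreground.copy(), small_grid)
        b1, b2, b3 = distance_bands(enh, targets.ctv)
        assert (b1, b2, b3) == (targets.ctv.count, 0, 0)

    def test_voxel_at_25mm_lands_in_middle_band(self):
        grid = GridSpec.isotropic(40)
        ctv = make_mask(grid, [(5, 5, 5)])
        enh = make_mask(grid, [(30, 5, 5)])  # 25 mm along one axis
        assert distance_bands(enh, ctv) == (0, 1, 0)

    def test_exclude_inside_empties_contained_mask(self, small_grid, rng):
        cavity = random_blob(small_grid, rng)
        targets = build_target_volumes(cavity, 3.0)
        enh = LabelVolume.from_mask(targets.ctv.foreground.copy(), small_grid)
        assert distance_bands(enh, targets.ctv, include_inside=False) == (0, 0, 0)

    def test_bad_cuts_rejected(self, small_grid):
        ctv = make_mask(small_grid, [(5, 5, 5)])
        enh = make_mask(small_grid, [(6, 6, 6)])
        with pytest.raises(ValueError):
            distance_bands(enh, ctv, cut_mm=(30.0, 20.0))

    def test_empty_ctv_rejected(self, small_grid):
        ctv = LabelVolume.from_mask(np.zeros(small_grid.shape, bool), small_grid)
        enh = make_mask(small_grid, [(6, 6, 6)])
        with pytest.raises(ValueError):
            distance_bands(enh, ctv)


class TestInvariantsAndEquivariance:
    def test_translation_equivariance(self):
        grid = GridSpec.isotropic(26)
        rng = np.random.default_rng(7)
        cavity = random_blob(grid, rng, n_seeds=2, radius_vox=2.0)
        enh = random_blob(grid, rng, n_seeds=2, radius_vox=2.5)

        def counts_of(cav, en):
            targets = build_target_volumes(cav, 4.0)
            return classify_regions(en, targets).as_dict()

        base = counts_of(cavity, enh)
        shift = (2, -1, 3)
        cav_t = LabelVolume.from_mask(np.roll(cavity.foreground, shift, (0, 1, 2)), grid)
        enh_t = LabelVolume.from_mask(np.roll(enh.foreground, shift, (0, 1, 2)), grid)
        # ensure nothing wrapped around the grid edge
        assert cav_t.count == cavity.count and enh_t.count == enh.count
        moved = counts_of(cav_t, enh_t)
        base.pop("case_id"), moved.pop("case_id")
        assert moved == base

    def test_outside_ptv_nonincreasing_in_margin(self, rng):
        grid = GridSpec.isotropic(24)
        cavity = random_blob(grid, rng, n_seeds=2)
        enh = random_blob(grid, rng, n_seeds=3)
        prev = None
        for margin in (0.0, 2.0, 5.0, 9.0):
            targets = build_target_volumes(cavity, margin)
            c = classify_regions(enh, targets)
            if prev is not None:
                assert c.outside_ptv <= prev
            prev = c.outside_ptv


class TestSummarizeCase:
    def test_matches_phantom_ground_truth(self):
        case, truth = make_phantom_case(small_phantom_spec(seed=11), case_id="ph")
        counts = summarize_case(case)
        assert counts.as_dict() == truth.as_dict()

    def test_without_cbv_iz_counts_zero(self):
        case, _ = make_phantom_case(small_phantom_spec(seed=12))
        case = PatientCase(case_id=case.case_id, cavity=case.cavity,
                           enhancing=case.enhancing)
        counts = summarize_case(case)
        assert counts.iz_inside_ctv == 0 and counts.iz_outside_ctv == 0
        assert counts.total > 0

    def test_deterministic(self):
        case, _ = make_phantom_case(small_phantom_spec(seed=13))
        a = summarize_case(case).as_dict()
        b = summarize_case(case).as_dict()
        assert a == b

    def test_premade_iz_mask_is_used(self):
        case, _ = make_phantom_case(small_phantom_spec(seed=14))
        iz_full = LabelVolume.from_mask(case.enhancing.foreground.copy(),
                                        case.grid, name="iz")
        with_iz = PatientCase(case_id="x", cavity=case.cavity,
                              enhancing=case.enhancing, iz_mask=iz_full)
        counts = summarize_case(with_iz)
        assert counts.iz_inside_ctv == counts.inside_ctv
        assert counts.iz_outside_ctv == counts.outside_ctv

    def test_region_label_volume_covers_enhancing(self):
        case, _ = make_phantom_case(small_phantom_spec(seed=15))
        targets = build_target_volumes(case.cavity, 5.0)
        labels = region_label_volume(case.enhancing, targets)
        assert np.array_equal(labels.foreground, case.enhancing.foreground)


def test_analysis_config_validation():
    with pytest.raises(ValueError):
        AnalysisConfig(distance_cuts_mm=(30.0, 20.0))
    with pytest.raises(ValueError):
        AnalysisConfig(iz_threshold_ratio=0.0)
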