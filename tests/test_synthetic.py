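import dataclasses

import numpy as np
import pytest

from neuroskin import (
    CohortSpec,
    SectionSpec,
    VesselPlacement,
    count_crossings,
    derive_rois,
    generate_section,
    threshold_segment,
)
from neuroskin.synthetic import generate_cohort, iter_cohort


class TestGenerateSection:
    def test_identical_seeds_bitwise_identical(self):
        spec = SectionSpec(shape=(320, 320), n_crossing_fibers=4, seed=9)
        s1, t1 = generate_section(spec)
        s2, t2 = generate_section(dataclasses.replace(spec))
        for m in s1.masks:
            assert np.array_equal(s1.masks[m].grid, s2.masks[m].grid)
        for c in s1.channels:
            assert np.array_equal(s1.channels[c].grid, s2.channels[c].grid)
        assert t1 == t2

    def test_different_seeds_differ(self):
        spec = SectionSpec(shape=(320, 320), seed=1)
        s1, _ = generate_section(spec)
        s2, _ = generate_section(dataclasses.replace(spec, seed=2))
        assert not np.array_equal(s1.masks["nerve"].grid, s2.masks["nerve"].grid)

    def test_zero_crossing_plant_counts_zero(self):
        spec = SectionSpec(shape=(320, 320), n_crossing_fibers=0, n_dermal_fibers=4, seed=5)
        section, truth = generate_section(spec)
        rois = derive_rois(section.masks["epidermis"], section.masks["dermis"])
        assert truth.crossing_count == 0
        assert count_crossings(section.masks["nerve"], rois).count == 0

    def test_planted_crossings_recovered_exactly(self):
        spec = SectionSpec(shape=(512, 512), n_crossing_fibers=6, n_dermal_fibers=3, seed=21)
        section, truth = generate_section(spec)
        rois = derive_rois(section.masks["epidermis"], section.masks["dermis"])
        assert count_crossings(section.masks["nerve"], rois).count == 6 == truth.crossing_count

    def test_infeasible_fiber_packing_rejected(self):
        spec = SectionSpec(shape=(320, 320), n_crossing_fibers=30, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            generate_section(spec)

    def test_infeasible_undulation_rejected(self):
        spec = SectionSpec(undulation_amplitude_px=80, undulation_wavelength_px=100, seed=0)
        with pytest.raises(ValueError, match="undulation"):
            generate_section(spec)

    def test_vessel_on_fiber_rejected(self):
        spec = SectionSpec(
            shape=(320, 320), seed=0,
            vessels=(VesselPlacement(radius_um=6.0, distance_um=2.0),),
        )
        with pytest.raises(ValueError, match="infeasible vessel"):
            generate_section(spec)

    def test_planted_vessel_distances_hit_target(self):
        spec = SectionSpec(
            shape=(512, 512), n_crossing_fibers=4, seed=13,
            vessels=tuple(VesselPlacement(radius_um=4.0, distance_um=d) for d in (8.0, 12.0, 20.0)),
        )
        section, truth = generate_section(spec)
        for planted, target in zip(truth.vessel_distances_um, (8.0, 12.0, 20.0)):
            assert abs(planted - target) <= spec.pixel_size_um  # within one pixel

    def test_masks_are_consistent(self, small_section):
        section, truth = small_section
        assert not (section.masks["epidermis"].grid & section.masks["dermis"].grid).any()
        # cgrp fibers are a subset of the nerve mask
        assert not (section.masks["cgrp"].grid & ~section.masks["nerve"].grid).any()
        assert section.masks["vessels"].area_um2 >= truth.vessel_area_um2

    def test_membrane_length_truth_close_to_measured(self, small_section):
        section, truth = small_section
        rois = derive_rois(section.masks["epidermis"], section.masks["dermis"])
        assert rois.membrane.length_mm == pytest.approx(truth.membrane_length_mm, rel=0.05)


class TestThresholdSegment:
    def test_threshold_zero_selects_everything(self, small_section):
        section, _ = small_section
        ch = section.channels["PGP9.5"]
        assert threshold_segment(ch, 0).n_foreground == ch.grid.size

    def test_threshold_above_max_selects_nothing(self, small_section):
        section, _ = small_section
        ch = section.channels["PGP9.5"]
        with pytest.raises(ValueError):
            threshold_segment(ch, 2**17)
        top = threshold_segment(ch, int(ch.grid.max()) + 1 if ch.grid.max() < 65535 else 65535)
        assert top.n_foreground <= (ch.grid == 65535).sum()

    def test_high_contrast_segmentation_matches_truth_mask(self, small_section):
        # fiber mean 2000, background 200, sd 50: threshold 1000 separates
        section, _ = small_section
        seg = threshold_segment(section.channels["PGP9.5"], 1000)
        truth_mask = section.masks["nerve"].grid
        jaccard = (seg.grid & truth_mask).sum() / (seg.grid | truth_mask).sum()
        assert jaccard >= 0.9


@pytest.fixture(scope="module")
def tiny_spec():
    return CohortSpec(
        n_control=3, n_painless=3, n_painful=3, images_per_subject=1,
        base_crossings=5, master_seed=11,
        section=SectionSpec(shape=(448, 448), n_dermal_fibers=2),
    )


class TestCohort:
    def test_groups_and_reproducibility(self, tiny_spec):
        subjects1 = list(iter_cohort(tiny_spec))
        subjects2 = list(iter_cohort(tiny_spec))
        assert [s.group for s in subjects1] == ["control"] * 3 + ["painless"] * 3 + ["painful"] * 3
        for a, b in zip(subjects1, subjects2):
            assert a.planted == b.planted
            assert np.array_equal(
                a.sections[0].masks["nerve"].grid, b.sections[0].masks["nerve"].grid
            )

    def test_painless_only_interaction_plant(self, tiny_spec):
        for rec in iter_cohort(tiny_spec):
            if rec.group == "painless":
                assert rec.planted["n_near_vessels"] > tiny_spec.base_near_vessels
            else:
                assert rec.planted["n_near_vessels"] == tiny_spec.base_near_vessels

    def test_group_minimum_enforced(self):
        with pytest.raises(ValueError, match="n >= 3"):
            CohortSpec(n_control=2)

    def test_cohort_file_tree(self, tiny_spec, tmp_path):
        manifest = generate_cohort(tiny_spec, tmp_path / "cohort")
        root = tmp_path / "cohort"
        assert (root / "truth_manifest.json").exists()
        assert (root / "qst_raw.csv").exists()
        assert (root / "ct_values.csv").exists()
        assert (root / "norms.yaml").exists()
        first = manifest["subjects"][0]
        stem = root / first["subject"] / first["images"][0]["stem"]
        from neuroskin.io import read_section

        section = read_section(stem)
        assert section.pixel_size_um == pytest.approx(0.61)
        assert "nerve" in section.masks and "PGP9.5" in section.channels
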