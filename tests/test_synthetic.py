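"""Ground-truth generator: determinism, geometry and truth consistency."""

from __future__ import annotations

import math

import numpy as np
import pytest

from nucleopunct.puncta import estimate_background, detect_puncta
from nucleopunct.config import RunConfig
from nucleopunct.synthetic import (
    FlowSimParams,
    SceneParams,
    ScenePlacementError,
    disk_mask,
    disk_overlap_fraction,
    ellipse_mask,
    generate_flow_table,
    generate_negative_control,
    generate_scene,
    lens_area,
    offset_for_overlap,
)

from conftest import small_scene_params


class TestGenerateScene:
    def test_deterministic_given_seed(self):
        params = small_scene_params(seed=5)
        s1, t1 = generate_scene(params)
        s2, t2 = generate_scene(small_scene_params(seed=5))
        for p1, p2 in zip(s1.planes, s2.planes):
            np.testing.assert_array_equal(p1, p2)
        assert [n.center for n in t1.nuclei] == [n.center for n in t2.nuclei]
        assert [p.center for p in t1.puncta] == [p.center for p in t2.puncta]

    def test_truth_lists_requested_nuclei(self, small_scene):
        params, _, truth = small_scene
        assert len(truth.nuclei) == params.n_nuclei
        assert [n.label for n in truth.nuclei] == list(
            range(1, params.n_nuclei + 1))

    def test_zero_coloc_fraction_plants_no_pairs(self):
        params = small_scene_params(seed=3, coloc_fraction_gal9_pdna=0.0)
        _, truth = generate_scene(params)
        assert not any(p.partner_channel == "pdna" for p in truth.coloc_pairs)

    def test_overcrowded_scene_fails_loudly(self):
        params = small_scene_params(
            seed=0, image_shape=(400, 400), n_nuclei=10)
        with pytest.raises(ScenePlacementError):
            generate_scene(params)

    def test_nucleus_raster_area_matches_analytic(self, small_scene):
        # pi*a*b within 2 % for diameters >= 100 px
        params, _, truth = small_scene
        for nuc in truth.nuclei:
            a, b = nuc.axes
            mask = ellipse_mask(params.image_shape, nuc.center, nuc.axes,
                                nuc.orientation)
            assert mask.sum() == pytest.approx(math.pi * a * b, rel=0.02)

    def test_planted_overlap_holds_pixelwise(self, small_scene):
        # every planted pair overlaps by at least the recorded fraction
        # on the pre-blur disk masks
        params, _, truth = small_scene
        assert truth.coloc_pairs, "scene should plant some pairs"
        by_index = {p.index: p for p in truth.puncta}
        for pair in truth.coloc_pairs:
            g = by_index[pair.gal9_index]
            partner = by_index[pair.partner_index]
            gm = disk_mask(params.image_shape, g.center, g.diameter_px / 2)
            pm = disk_mask(params.image_shape, partner.center,
                           partner.diameter_px / 2)
            frac = (gm & pm).sum() / gm.sum()
            assert frac >= pair.planted_overlap - 1e-9

    def test_inner_puncta_lie_inside_inner_partition(self, small_scene):
        # region labels in the truth agree with a centroid test against
        # the nucleus's own edge/inner partition
        from nucleopunct.segmentation import NucleusRecord, partition_rings
        params, _, truth = small_scene
        for nuc in truth.nuclei:
            mask = ellipse_mask(params.image_shape, nuc.center, nuc.axes,
                                nuc.orientation)
            rr, cc = np.nonzero(mask)
            r0, c0 = int(rr.min()), int(cc.min())
            rec = NucleusRecord(
                label=nuc.label, bbox=(r0, c0, int(rr.max()) + 1,
                                       int(cc.max()) + 1),
                mask=mask[r0:rr.max() + 1, c0:cc.max() + 1],
                area_px=int(mask.sum()), equiv_diameter_px=0.0,
                form_factor=1.0, centroid=nuc.center, touches_border=False,
                passed_filters=True)
            partition_rings(rec, params.ring_edge_fraction)
            for p in truth.puncta:
                if p.nucleus_label != nuc.label:
                    continue
                r = int(round(p.center[0])) - r0
                c = int(round(p.center[1])) - c0
                if p.region == "inner":
                    assert rec.inner_mask[r, c]
                elif p.region == "edge":
                    assert rec.edge_mask[r, c]


class TestNegativeControl:
    def test_noiseless_background_is_exact(self):
        params = small_scene_params(seed=2, noise_sd=0.0,
                                    background_level=100.0)
        control = generate_negative_control(params)
        assert np.all(control.plane("gal9") == 100.0)
        assert np.all(control.plane("pdna") == 100.0)

    def test_deterministic(self):
        params = small_scene_params(seed=9)
        c1 = generate_negative_control(params)
        c2 = generate_negative_control(small_scene_params(seed=9))
        for p1, p2 in zip(c1.planes, c2.planes):
            np.testing.assert_array_equal(p1, p2)

    def test_detection_on_control_finds_nothing(self):
        params = small_scene_params(seed=4)
        control = generate_negative_control(params)
        config = RunConfig()
        model = estimate_background([control], "pdna", k=3.0)
        puncta = detect_puncta(control.plane("pdna"), "pdna",
                               config.channels["pdna"], model,
                               pixel_size_um=params.pixel_size_um)
        assert puncta == []


class TestDiskGeometry:
    @pytest.mark.parametrize("r1,r2,d,expected", [
        (10.0, 10.0, 0.0, 1.0),            # coincident
        (10.0, 10.0, 25.0, 0.0),           # disjoint
        (10.0, 5.0, 0.0, 0.25),            # contained smaller disk
    ])
    def test_disk_overlap_fraction(self, r1, r2, d, expected):
        assert disk_overlap_fraction(r1, r2, d) == pytest.approx(expected)

    def test_offset_for_overlap_inverts_the_overlap(self):
        for target in (0.3, 0.5):
            d = offset_for_overlap(12.0, 9.0, target)
            assert disk_overlap_fraction(12.0, 9.0, d) == pytest.approx(
                target, abs=1e-9)
        d = offset_for_overlap(12.0, 12.0, 0.8)
        assert disk_overlap_fraction(12.0, 12.0, d) == pytest.approx(
            0.8, abs=1e-9)

    def test_offset_rejects_unreachable_target(self):
        # a small partner cannot cover 80 % of a large reference
        with pytest.raises(ValueError):
            offset_for_overlap(20.0, 5.0, 0.8)

    def test_lens_area_symmetry(self):
        assert lens_area(7.0, 11.0, 9.0) == pytest.approx(
            lens_area(11.0, 7.0, 9.0))


class TestFlowTable:
    def test_zero_positive_fraction(self):
        table = generate_flow_table(FlowSimParams(
            n_events=2000, positive_fraction=0.0, seed=1))
        assert table["is_positive"].sum() == 0
        # all intensities from the negative component stay well below
        # the positive population's location
        assert table["green"].max() < math.exp(
            FlowSimParams().pos_logmean - 2 * FlowSimParams().pos_logsd)

    def test_row_count_and_determinism(self):
        p = FlowSimParams(n_events=1000, seed=7)
        t1 = generate_flow_table(p)
        t2 = generate_flow_table(FlowSimParams(n_events=1000, seed=7))
        assert len(t1) == 1000
        assert t1.equals(t2)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            FlowSimParams(positive_fraction=1.5)
        with pytest.raises(ValueError):
            FlowSimParams(neg_logsd=0.0)
        with pytest.raises(ValueError):
            SceneParams(coloc_fraction_gal9_pdna=-0.1, seed=0)
        with pytest.raises(ValueError):
            SceneParams(nucleus_diameter_um_range=(12.0, 8.0), seed=0)
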