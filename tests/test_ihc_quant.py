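"""Stain unmixing, multiplex overlay, angular ROI morphometry tests."""

import numpy as np
import pandas as pd
import pytest

import flimplaque as fp
from flimplaque.ihc import (
    DEFAULT_STAINS,
    StainSpec,
    color_deconvolve,
    compare_rfc_vs_ihc,
    generate_quad_rois,
    multiplex_overlay,
    roi_component_densities,
)
from flimplaque.synthetic import (
    IhcImageConfig,
    atheroma_config,
    build_vessel_phantom,
    make_ihc_fixture,
    section_from_labels,
)


def _circle_contour(radius=600.0, n=360):
    th = np.linspace(0, 2 * np.pi, n + 1)
    return np.c_[radius * np.sin(th), -radius * np.cos(th)]


def _mix(weights: dict[str, float]) -> np.ndarray:
    """Forward Beer-Lambert mixing of the default stains at unit pixel."""
    od = np.zeros(3)
    for s in DEFAULT_STAINS:
        od += weights.get(s.name, 0.0) * np.asarray(s.od_vector)
    return np.exp(-od)[None, None, :]


class TestColorDeconvolution:
    def test_white_pixel_zero_density(self):
        dens = color_deconvolve(np.ones((1, 1, 3)))
        assert all(v[0, 0] == 0.0 for v in dens.values())

    @pytest.mark.parametrize("stain", [s.name for s in DEFAULT_STAINS])
    def test_unit_basis_case(self, stain):
        dens = color_deconvolve(_mix({stain: 1.0}))
        for name, v in dens.items():
            assert v[0, 0] == pytest.approx(1.0 if name == stain else 0.0, abs=1e-9)

    def test_mixture_recovered_to_1e6(self):
        dens = color_deconvolve(_mix({"ORO": 0.6, "PM-2K": 0.4}))
        assert dens["ORO"][0, 0] == pytest.approx(0.6, abs=1e-6)
        assert dens["PM-2K"][0, 0] == pytest.approx(0.4, abs=1e-6)
        assert dens["SMA"][0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_agrees_with_skimage_unmixing(self):
        """Cross-check against scikit-image's stain separation routine."""
        from skimage.color import separate_stains

        rgb = np.clip(_mix({"ORO": 0.5, "PM-2K": 0.3, "SMA": 0.2}), 1e-6, 1.0)
        mine = color_deconvolve(rgb)
        m = np.array([s.od_vector for s in DEFAULT_STAINS])
        # skimage works in OD normalized by -log(1e-6); undo that scale
        theirs = separate_stains(rgb, np.linalg.inv(m)) * -np.log(1e-6)
        for i, s in enumerate(DEFAULT_STAINS):
            assert mine[s.name][0, 0] == pytest.approx(theirs[0, 0, i], abs=1e-4)

    def test_remix_reconstructs_image(self):
        rgb = _mix({"ORO": 0.3, "PM-2K": 0.5, "SMA": 0.1})
        dens = color_deconvolve(rgb)
        m = np.array([s.od_vector for s in DEFAULT_STAINS])
        stack = np.stack([dens[s.name] for s in DEFAULT_STAINS], axis=-1)
        remixed = np.exp(-(stack @ m))
        assert np.allclose(remixed, rgb, atol=1e-9)

    def test_collinear_vectors_rejected(self):
        bad = (
            StainSpec("A", "lipid", (0.5, 0.5, 0.5), (1, 0, 0)),
            StainSpec("B", "macrophage", (0.5, 0.5, 0.5), (0, 1, 0)),
        )
        with pytest.raises(ValueError, match="collinear"):
            color_deconvolve(np.ones((1, 1, 3)), bad)


class TestMultiplexOverlay:
    def test_zero_density_blank(self):
        mux = multiplex_overlay({"ORO": np.zeros((4, 4))})
        assert np.allclose(mux.overlay, 0.0)

    def test_single_stain_display_color_only(self):
        mux = multiplex_overlay({"PM-2K": np.full((2, 2), 0.8)})
        expect = 0.8 * np.asarray(DEFAULT_STAINS[1].display_color)
        assert np.allclose(mux.overlay[0, 0], expect)

    def test_regenerated_overlay_pixel_identical(self):
        rng = np.random.default_rng(0)
        dens = {s.name: rng.random((8, 8)) for s in DEFAULT_STAINS}
        a = multiplex_overlay(dens)
        b = multiplex_overlay(a.densities)
        assert np.array_equal(a.overlay, b.overlay)

    def test_unknown_stain_rejected(self):
        with pytest.raises(ValueError, match="unknown stain"):
            multiplex_overlay({"HE": np.zeros((2, 2))})


class TestQuadRois:
    def test_360_rois_per_section(self):
        rois = generate_quad_rois(_circle_contour())
        assert len(rois) == 360
        assert [r.angle_deg for r in rois] == list(range(360))

    def test_open_contour_rejected(self):
        open_contour = _circle_contour()[:-1]
        with pytest.raises(ValueError, match="open"):
            generate_quad_rois(open_contour)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            generate_quad_rois(_circle_contour(), depth_um=0.0)

    def test_circular_lumen_congruent_sectors(self):
        rois = generate_quad_rois(_circle_contour())

        def area(v):
            x, y = np.array(v).T
            return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

        areas = np.array([area(r.vertices_um) for r in rois])
        assert np.allclose(areas, areas[0], rtol=1e-6)

    def test_union_covers_subluminal_band(self):
        """ROI union covers the 200-um band with <1% gap/overlap by area."""
        rois = generate_quad_rois(_circle_contour())

        def area(v):
            x, y = np.array(v).T
            return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

        total = sum(area(r.vertices_um) for r in rois)
        band = np.pi * (800.0**2 - 600.0**2)
        assert abs(total - band) / band < 0.01


class TestRepresentativeComponent:
    def _mux(self, lipid, mph, smc, n=40):
        dens = {
            "ORO": np.full((n, n), lipid),
            "PM-2K": np.full((n, n), mph),
            "SMA": np.full((n, n), smc),
        }
        return multiplex_overlay(dens, DEFAULT_STAINS, pixel_size_um=20.0)

    def _single_roi(self):
        return generate_quad_rois(_circle_contour(radius=150.0), depth_um=100.0, step_deg=120)[:1]

    def test_argmax_rule(self):
        df = roi_component_densities(self._mux(0.3, 0.5, 0.2), self._single_roi(),
                                     dominance_ratio=1.2)
        assert df.representative.iloc[0] == "macrophage"

    def test_all_below_threshold_is_none(self):
        df = roi_component_densities(self._mux(0.01, 0.02, 0.03), self._single_roi())
        assert df.representative.iloc[0] == "none"

    def test_copresence_dual_threshold_rule(self):
        df = roi_component_densities(self._mux(0.5, 0.4, 0.0), self._single_roi())
        assert df.representative.iloc[0] == "lipid_macrophage"

    def test_dominance_breaks_copresence(self):
        df = roi_component_densities(self._mux(0.8, 0.2, 0.0), self._single_roi())
        assert df.representative.iloc[0] == "lipid"

    def test_stain_relabeling_permutes_output(self):
        """Swapping which stain marks which component permutes representatives."""
        swapped = (
            StainSpec("ORO", "macrophage", DEFAULT_STAINS[0].od_vector, (1, 0, 0)),
            StainSpec("PM-2K", "lipid", DEFAULT_STAINS[1].od_vector, (1, 1, 0)),
            StainSpec("SMA", "smc", DEFAULT_STAINS[2].od_vector, (0, 0, 1)),
        )
        dens = {"ORO": np.full((40, 40), 0.6), "PM-2K": np.full((40, 40), 0.2),
                "SMA": np.zeros((40, 40))}
        base = roi_component_densities(
            multiplex_overlay(dens, DEFAULT_STAINS, 20.0), self._single_roi()
        )
        perm = roi_component_densities(
            multiplex_overlay(dens, swapped, 20.0), self._single_roi()
        )
        assert base.representative.iloc[0] == "lipid"
        assert perm.representative.iloc[0] == "macrophage"


class TestRfcVsIhcComparison:
    @pytest.fixture(scope="class")
    def section_quant(self):
        ph = build_vessel_phantom(atheroma_config(3), seed=9)
        frame = ph.labels[0]
        images, _ = make_ihc_fixture(section_from_labels(frame))
        dmaps = {s.name: color_deconvolve(images[s.name], (s,))[s.name]
                 for s in DEFAULT_STAINS}
        mux = multiplex_overlay(dmaps, DEFAULT_STAINS, pixel_size_um=4.0)
        dens = roi_component_densities(mux, generate_quad_rois(_circle_contour()))
        return frame, dens

    def test_fixture_representatives_match_ground_truth(self, section_quant):
        frame, dens = section_quant
        expect = {"normal": "smc", "fibrotic": "smc", "lipid": "lipid",
                  "macrophage": "macrophage", "lipid_macrophage": "lipid_macrophage"}
        loc = np.round(np.arange(360) / 360 * len(frame)).astype(int) % len(frame)
        truth = [expect[fp.CLASS_ORDER[i].value] for i in frame[loc]]
        rep = dens.sort_values("angle_deg").representative.to_numpy()
        assert np.mean([t == r for t, r in zip(truth, rep)]) >= 0.95

    def test_identical_sequences_full_agreement(self, section_quant):
        frame, dens = section_quant
        assert compare_rfc_vs_ihc(frame, dens, 0)["percent_agreement"] == 100.0

    def test_declared_rotation_consistency(self, section_quant):
        frame, dens = section_quant
        rotated = dens.copy()
        rotated["angle_deg"] = (rotated["angle_deg"] - 90) % 360
        r0 = compare_rfc_vs_ihc(frame, dens, 0)
        r90 = compare_rfc_vs_ihc(frame, rotated, 90)
        assert r90["percent_agreement"] == r0["percent_agreement"]

    def test_random_labels_near_chance(self, section_quant):
        frame, dens = section_quant
        rng = np.random.default_rng(15)
        random_frame = rng.integers(0, 5, size=len(frame)).astype(np.int8)
        res = compare_rfc_vs_ihc(random_frame, dens, 0)
        assert res["percent_agreement"] < 75.0  # far below the matched 100%
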