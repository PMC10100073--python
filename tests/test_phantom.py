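"""Phantom rasterization and forward-model physics."""

import numpy as np
import pytest

import coce
from coce.phantom import (CLASS_MEAN_KPA, SILICONE_LABEL, _MUCIN,
                          template_phantom)


def _tissue_cls(label=1, name="tissue", E0=58.0, **kw):
    return coce.MechanicalClass(label, name, E0, **kw)


class TestBuildPhantom:
    def test_background_only_fills_tissue_under_silicone(self):
        spec = coce.PhantomSpec(background=_tissue_cls(), depth_px=100,
                                lateral_px=50, silicone_thickness_um=100.0)
        ph = coce.build_phantom(spec)
        ir = spec.interface_row
        assert ir == 25
        assert (ph.label_map[:ir] == SILICONE_LABEL).all()
        assert (ph.label_map[ir:] == 1).all()
        assert np.allclose(ph.E0[:ir], spec.E_sil)
        assert np.allclose(ph.E0[ir:], 58.0)

    def test_centered_rectangle_matches_brute_force_rasterizer(self):
        # 200x200 um rectangle centered in a 1000x1000 um tissue grid at
        # 5 um pixels must occupy exactly a 40x40 px block
        gland = _tissue_cls(2, "gland", 724.0)
        rect = coce.Rectangle(400.0, 400.0, 200.0, 200.0)
        spec = coce.PhantomSpec(
            background=_tissue_cls(), shapes=[(rect, gland)],
            depth_px=220, lateral_px=200, axial_pixel_um=5.0,
            lateral_pixel_um=5.0, silicone_thickness_um=100.0)
        ph = coce.build_phantom(spec)
        ir = spec.interface_row

        # oracle: test every pixel center independently
        expected = np.full((220, 200), 1, dtype=int)
        expected[:ir] = SILICONE_LABEL
        for i in range(ir, 220):
            for j in range(200):
                x = (j + 0.5) * 5.0
                z = (i - ir + 0.5) * 5.0
                if 400.0 <= x < 600.0 and 400.0 <= z < 600.0:
                    expected[i, j] = 2
        assert (ph.label_map == expected).all()
        assert (ph.label_map == 2).sum() == 40 * 40

    def test_two_class_gland_in_stroma_phantom(self):
        stroma = _tissue_cls(1, "stroma", CLASS_MEAN_KPA["stroma"])
        gland = _tissue_cls(2, "gland", CLASS_MEAN_KPA["gland"])
        shapes = [(coce.Ellipse(500.0, 500.0, 150.0, 120.0), gland)]
        spec = coce.PhantomSpec(background=stroma, shapes=shapes,
                                depth_px=300, lateral_px=256)
        ph = coce.build_phantom(spec)
        labels = set(np.unique(ph.label_map))
        assert labels == {SILICONE_LABEL, 1, 2}
        assert ph.classes[2].E0 == 724.0

    def test_later_shapes_overwrite_earlier(self):
        a = _tissue_cls(2, "a", 100.0)
        b = _tissue_cls(3, "b", 200.0)
        sq = coce.Rectangle(100.0, 100.0, 200.0, 200.0)
        spec = coce.PhantomSpec(background=_tissue_cls(),
                                shapes=[(sq, a), (sq, b)],
                                depth_px=200, lateral_px=128)
        ph = coce.build_phantom(spec)
        assert (ph.label_map == 3).sum() > 0
        assert (ph.label_map == 2).sum() == 0

    def test_shape_outside_grid_raises_naming_the_shape(self):
        far = coce.Rectangle(10_000.0, 10_000.0, 50.0, 50.0)
        spec = coce.PhantomSpec(background=_tissue_cls(),
                                shapes=[(far, _tissue_cls(2, "far", 1.0))],
                                depth_px=200, lateral_px=128)
        with pytest.raises(ValueError, match="far"):
            coce.build_phantom(spec)

    def test_zero_area_shape_raises(self):
        flat = coce.Rectangle(100.0, 100.0, 0.0, 50.0)
        spec = coce.PhantomSpec(background=_tissue_cls(),
                                shapes=[(flat, _tissue_cls(2, "flat", 1.0))],
                                depth_px=200, lateral_px=128)
        with pytest.raises(ValueError, match="zero area"):
            coce.build_phantom(spec)

    def test_depth_beyond_scanning_range_rejected(self):
        with pytest.raises(ValueError, match="scanning depth"):
            coce.PhantomSpec(background=_tissue_cls(), depth_px=600,
                             lateral_px=64)


class TestSimulator:
    def test_no_compression_gives_identical_noiseless_frames(self):
        ph = coce.homogeneous_phantom(100.0, depth_px=150, lateral_px=32)
        acq = coce.AcquisitionSpec(n_frames=3, max_stress_kPa=0.0,
                                   snr_db=None, seed=0)
        series, truth = coce.simulate_compression_series(ph, acq)
        assert np.array_equal(series.data[0], series.data[1])
        assert np.array_equal(series.data[0], series.data[2])
        assert truth.stress_per_frame.max() == 0.0

    def test_linear_tissue_strain_closed_form(self):
        # sigma = 1 kPa on E = 100 kPa gives exactly 1% strain
        ph = coce.homogeneous_phantom(100.0, depth_px=150, lateral_px=32,
                                      E_sil=100.0)
        acq = coce.AcquisitionSpec(n_frames=5, max_stress_kPa=1.0,
                                   snr_db=None, seed=0)
        _, truth = coce.simulate_compression_series(ph, acq)
        assert np.allclose(truth.true_cumulative_strain[-1], 0.01)

    def test_default_protocol_uses_about_hundred_frames(self):
        assert coce.AcquisitionSpec().n_frames == 100

    def test_phase_self_consistency_noiseless(self):
        """Unwrapped interframe phase equals (4 pi n / lambda) * delta-u."""
        ph = coce.homogeneous_phantom(100.0, depth_px=200, lateral_px=16)
        acq = coce.AcquisitionSpec(n_frames=4, max_stress_kPa=1.5,
                                   snr_db=None, seed=3)
        series, truth = coce.simulate_compression_series(ph, acq)
        d_eps = (truth.true_cumulative_strain[2]
                 - truth.true_cumulative_strain[1])
        du = np.cumsum(d_eps, axis=0) * series.axial_pixel_um
        k = 4 * np.pi * series.refractive_index / series.wavelength_um
        phase = np.unwrap(
            np.angle(coce.interframe_field(series.data[1], series.data[2])),
            axis=0)
        assert np.allclose(phase, k * du, atol=1e-9)

    def test_stress_schedule_strictly_increasing(self):
        ph = coce.homogeneous_phantom(300.0, depth_px=150, lateral_px=16)
        acq = coce.AcquisitionSpec(n_frames=10, max_stress_kPa=5.5, seed=0)
        _, truth = coce.simulate_compression_series(ph, acq)
        assert truth.stress_per_frame[0] == 0.0
        assert (np.diff(truth.stress_per_frame) > 0).all()

    def test_nonlinear_truth_modulus_is_E0_plus_4beta(self):
        ph = coce.homogeneous_phantom(300.0, beta=25.0, depth_px=150,
                                      lateral_px=16)
        acq = coce.AcquisitionSpec(n_frames=10, max_stress_kPa=5.5, seed=0)
        _, truth = coce.simulate_compression_series(ph, acq)
        ir = ph.interface_row
        assert np.allclose(truth.true_stiffness_map[ir:], 300.0 + 4 * 25.0)

    def test_interframe_strain_limit_enforced(self):
        ph = coce.homogeneous_phantom(58.0, depth_px=150, lateral_px=16)
        acq = coce.AcquisitionSpec(n_frames=2, max_stress_kPa=6.0, seed=0)
        with pytest.raises(coce.StrainLimitError, match="n_frames"):
            coce.simulate_compression_series(ph, acq)

    def test_bit_identical_for_same_seed(self):
        ph = coce.homogeneous_phantom(200.0, depth_px=150, lateral_px=32)
        acq = coce.AcquisitionSpec(n_frames=5, max_stress_kPa=3.0,
                                   snr_db=20.0, seed=42)
        s1, _ = coce.simulate_compression_series(ph, acq)
        s2, _ = coce.simulate_compression_series(ph, acq)
        assert np.array_equal(s1.data, s2.data)

    def test_nonsignal_pixels_carry_noise_only(self):
        mucin_rect = coce.Rectangle(40.0, 100.0, 300.0, 200.0)
        spec = coce.PhantomSpec(
            background=_tissue_cls(1, "stroma", 295.0),
            shapes=[(mucin_rect, _MUCIN)], depth_px=200, lateral_px=128)
        ph = coce.build_phantom(spec)
        acq = coce.AcquisitionSpec(n_frames=3, max_stress_kPa=1.0,
                                   snr_db=None, seed=1)
        series, _ = coce.simulate_compression_series(ph, acq)
        # mucin occupies rows 100..150, cols 10..85; stay 10+ px away from
        # the PSF-blurred boundary
        core = ph.label_map == _MUCIN.label
        interior = np.zeros(ph.label_map.shape, dtype=bool)
        interior[112:140, 25:70] = True
        assert (interior <= core).all()
        assert np.abs(series.data[0][interior]).max() < 1e-6


class TestCohort:
    def test_single_normal_sample_has_no_cancer_range_tissue(self):
        samples = coce.make_cohort(1, {"normal": 1.0}, seed=5, n_frames=4,
                                   max_stress_kPa=0.2)
        sample = samples[0]
        assert sample.subtype == "normal"
        assert sample.truth.cancer_area_percent == 0.0
        ph_E0 = sample.truth.true_stiffness_map[sample.truth.interface_row:]
        assert (ph_E0 < 520.0).all()

    def test_truth_fractions_match_label_map_recount(self):
        samples = coce.make_cohort(6, seed=9, n_frames=4, max_stress_kPa=0.2)
        for s in samples:
            truth = s.truth
            tissue = truth.tissue_mask()
            cancer = (tissue & ~truth.is_nonsignal
                      & (truth.true_stiffness_map >= 520.0))
            recount = 100.0 * cancer.sum() / tissue.sum()
            assert recount == pytest.approx(truth.cancer_area_percent)

    def test_mac_template_mucin_dominates_shallow_band(self):
        samples = coce.make_cohort(1, {"mac": 1.0}, seed=2, n_frames=4,
                                   max_stress_kPa=0.2)
        truth = samples[0].truth
        ir = truth.interface_row
        band = truth.is_nonsignal[ir:ir + 125]  # 500 um at 4 um pixels
        assert band.mean() > 0.5

    def test_empty_class_mix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            coce.make_cohort(3, {}, seed=0)

    def test_cohort_reproducible(self):
        a = coce.make_cohort(2, seed=77, n_frames=3, max_stress_kPa=0.2)
        b = coce.make_cohort(2, seed=77, n_frames=3, max_stress_kPa=0.2)
        for sa, sb in zip(a, b):
            assert sa.subtype == sb.subtype
            assert np.array_equal(sa.series.data, sb.series.data)
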