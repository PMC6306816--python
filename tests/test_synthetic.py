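"""Synthetic scene generator: angular law, determinism, wound contract."""

import numpy as np
import pytest
from scipy import stats as sps

import fibralign as fa
from fibralign.synthetic import ParameterError, sample_axial_angles


def small_spec(**kw):
    defaults = dict(
        image_size_px=(128, 128), n_fibrils=30, noise_sd=0.0, seed=7
    )
    defaults.update(kw)
    return fa.FibrilFieldSpec(**defaults)


class TestAxialSampling:
    def test_kappa_zero_is_uniform(self):
        """kappa = 0 must give uniform orientations on [-90, 90)."""
        rng = np.random.default_rng(0)
        ang = sample_axial_angles(10_000, 25.0, 0.0, rng)
        counts, _ = np.histogram(ang, bins=18, range=(-90, 90))
        chi2 = sps.chisquare(counts)
        assert chi2.pvalue > 0.01

    def test_large_kappa_concentrates_at_mean(self):
        """Dispersion shrinks as 1/sqrt(kappa); huge kappa pins every sample.

        The axial deviation has sd ~ 1/(2*sqrt(kappa)) rad, so kappa = 100
        keeps the spread near 2.9 deg while kappa = 1e4 confines all of
        5000 samples within +-3 deg of the mean.
        """
        rng = np.random.default_rng(1)
        for mean in (-40.0, 0.0, 60.0):
            ang = sample_axial_angles(5_000, mean, 1e4, rng)
            dev = (ang - mean + 90.0) % 180.0 - 90.0
            assert np.max(np.abs(dev)) < 3.0
        dev100 = (sample_axial_angles(5_000, 0.0, 100.0, rng) + 90.0) % 180.0 - 90.0
        assert np.std(dev100) == pytest.approx(np.degrees(0.05), rel=0.15)

    @pytest.mark.parametrize("mean", [-60.0, -10.0, 45.0])
    def test_circular_mean_recovery(self, mean):
        """Circular mean of sampled axial angles within 2 deg for kappa >= 10."""
        rng = np.random.default_rng(2)
        ang = sample_axial_angles(500, mean, 10.0, rng)
        doubled = np.radians(2.0 * ang)
        est = np.degrees(np.arctan2(np.sin(doubled).mean(), np.cos(doubled).mean())) / 2.0
        dev = (est - mean + 90.0) % 180.0 - 90.0
        assert abs(dev) < 2.0


class TestFibrilField:
    def test_empty_scene_is_constant_background(self):
        ras = fa.generate_fibril_field(small_spec(n_fibrils=0, background_level=0.25))
        assert np.all(ras.pixels == 0.25)

    def test_seed_determinism_bit_identical(self):
        spec = small_spec(noise_sd=0.05)
        a = fa.generate_fibril_field(spec)
        b = fa.generate_fibril_field(spec)
        assert np.array_equal(a.pixels, b.pixels)

    def test_different_seeds_differ(self):
        a = fa.generate_fibril_field(small_spec(seed=1))
        b = fa.generate_fibril_field(small_spec(seed=2))
        assert not np.array_equal(a.pixels, b.pixels)

    def test_ground_truth_angles_in_provenance(self):
        ras = fa.generate_fibril_field(small_spec())
        assert len(ras.provenance["fibril_angles_deg"]) == 30

    def test_output_in_unit_range_with_noise(self):
        ras = fa.generate_fibril_field(small_spec(noise_sd=0.2))
        assert ras.pixels.min() >= 0.0 and ras.pixels.max() <= 1.0

    @pytest.mark.parametrize(
        "bad",
        [
            dict(image_size_px=(0, 128)),
            dict(waviness_wavelength_px=0.0),
            dict(dispersion_kappa=-1.0),
            dict(fibril_intensity=0.0),
            dict(background_level=1.0),
        ],
    )
    def test_invalid_spec_raises(self, bad):
        with pytest.raises(ParameterError):
            small_spec(**bad)

    def test_aligned_field_recovered_by_structure_tensor(self):
        """Generated mean orientation is visible to an independent estimator."""
        spec = small_spec(
            image_size_px=(256, 256), n_fibrils=80, mean_angle_deg=0.0,
            dispersion_kappa=50.0, waviness_amplitude_px=0.0,
        )
        ras = fa.generate_fibril_field(spec)
        peak = fa.peak_orientation(fa.structure_tensor_distribution(ras))
        assert abs(peak) <= 5.0


class TestCells:
    def test_zero_cells_leaves_background_unchanged(self):
        base = fa.generate_fibril_field(small_spec())
        out, mask = fa.generate_cells(fa.CellFieldSpec(n_cells=0, seed=0), base)
        assert np.array_equal(out.pixels, base.pixels)
        assert not mask.any()

    def test_elongation_ratio_one_degenerates_to_circular(self):
        base = fa.ImageRaster(np.zeros((128, 128)))
        spec_e = fa.CellFieldSpec(
            n_cells=5, morphology="elongated", elongation_ratio=1.0,
            n_processes=0, seed=3,
        )
        spec_c = fa.CellFieldSpec(
            n_cells=5, morphology="circular", n_processes=0, seed=3
        )
        _, mask_e = fa.generate_cells(spec_e, base)
        _, mask_c = fa.generate_cells(spec_c, base)
        assert np.array_equal(mask_e, mask_c)

    def test_circular_with_processes_rejected(self):
        with pytest.raises(ParameterError):
            fa.CellFieldSpec(morphology="circular", n_processes=3)

    def test_dendritic_component_count(self):
        from scipy import ndimage

        base = fa.ImageRaster(np.zeros((512, 512)))
        spec = fa.CellFieldSpec(
            n_cells=3, morphology="dendritic", n_processes=6,
            body_radius_px=6, process_length_px=20, seed=11,
        )
        _, mask = fa.generate_cells(spec, base)
        _, n = ndimage.label(mask, structure=np.ones((3, 3)))  # 8-connectivity
        assert n == 3  # this seed places cells without overlap

    def test_elongated_cells_along_axis_have_positive_oi(self):
        """Cells elongated at 45 deg carry positive OI(45) in the mask image."""
        base = fa.ImageRaster(np.zeros((256, 256)) + 0.05)
        spec = fa.CellFieldSpec(
            n_cells=25, morphology="elongated", body_axis_angle_deg=45.0,
            elongation_ratio=4.0, n_processes=0, seed=5,
        )
        out, _ = fa.generate_cells(spec, base)
        dist = fa.orientation_distribution(out)
        assert fa.orientation_index(dist, 45.0).oi_percent > 20.0


class TestWound:
    @pytest.fixture
    def scene(self):
        base = fa.generate_fibril_field(
            small_spec(image_size_px=(256, 256), n_fibrils=60, seed=1)
        )
        ras, mask = fa.generate_cells(
            fa.CellFieldSpec(n_cells=15, morphology="dendritic", seed=2), base
        )
        return base, ras, mask

    def test_zero_radius_is_identity(self, scene):
        _, ras, mask = scene
        out = fa.apply_wound(ras, mask, fa.WoundSpec(center_px=(128, 128), radius_um=0.0))
        assert np.array_equal(out.pixels, ras.pixels)

    def test_cells_removed_inside_disc_only(self, scene):
        _, ras, mask = scene
        spec = fa.WoundSpec(center_px=(128, 128), radius_um=30.0)
        out = fa.apply_wound(ras, mask, spec)
        rr, cc = np.ogrid[:256, :256]
        disc = (rr - 128) ** 2 + (cc - 128) ** 2 < (30.0 / ras.pixel_size_um) ** 2
        assert np.any(out.pixels[disc & mask] != ras.pixels[disc & mask])
        assert np.array_equal(out.pixels[~disc], ras.pixels[~disc])
        assert np.array_equal(out.pixels[disc & ~mask], ras.pixels[disc & ~mask])

    def test_fibril_only_image_unchanged(self, scene):
        """Freezing leaves the collagen architecture exactly intact."""
        base, _, _ = scene
        out = fa.apply_wound(
            base, np.zeros(base.shape, bool),
            fa.WoundSpec(center_px=(128, 128), radius_um=60.0),
        )
        assert np.array_equal(out.pixels, base.pixels)

    def test_disc_covering_image_removes_all_cells(self, scene):
        _, ras, mask = scene
        spec = fa.WoundSpec(center_px=(128, 128), radius_um=1000.0)
        out = fa.apply_wound(ras, mask, spec)
        # composited cell pixels (strictly brightened) drop back toward substrate
        brightened = mask & (ras.pixels > 0.85)
        assert np.all(out.pixels[brightened] < ras.pixels[brightened])

    def test_disc_outside_image_rejected(self, scene):
        _, ras, mask = scene
        with pytest.raises(ParameterError):
            fa.apply_wound(
                ras, mask, fa.WoundSpec(center_px=(5000, 5000), radius_um=10.0)
            )


class TestWallShearRate:
    def test_stated_channel_geometry(self):
        # 7.5 uL/min in a 60 x 1500 um channel: 6Q/(w h^2) = 138.9 1/s
        assert fa.wall_shear_rate(7.5, 1500.0, 60.0) == pytest.approx(138.888, abs=0.01)

    def test_linearity_in_flow(self):
        one = fa.wall_shear_rate(3.0, 1000.0, 80.0)
        two = fa.wall_shear_rate(6.0, 1000.0, 80.0)
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_millimetre_channel(self):
        assert fa.wall_shear_rate(1.0, 1000.0, 1000.0) == pytest.approx(0.1, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            fa.wall_shear_rate(-1.0, 1000.0, 60.0)
        with pytest.raises(ParameterError):
            fa.wall_shear_rate(1.0, 60.0, 1500.0)  # height > width
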