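import numpy as np
import pytest

from cartiq import fiber3d as f3
from cartiq import metabolism as met
from cartiq import phasor_flim as pf
from cartiq import synthetic as syn
from cartiq.segmentation import ZONE_CODES

from oracles import mono_exponential_phasor


class TestAxialOrientationSampling:
    def test_fixed_axis_has_zero_variance(self):
        axes = syn.sample_axial_orientations(500, (0.0, 1.0, 0.0), np.inf)
        assert f3.variance_from_axes(axes) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_mean_dyadic_is_third_identity(self):
        # closed form: E[u u^T] = I/3 for uniform axes on the sphere
        rng = np.random.default_rng(11)
        u = syn.sample_axial_orientations(100_000, kappa=0.0, rng=rng)
        T = np.einsum("ni,nj->ij", u, u) / len(u)
        assert np.max(np.abs(T - np.eye(3) / 3.0)) < 0.01

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            syn.sample_axial_orientations(10, kappa=-1.0)

    def test_concentration_shrinks_spread(self):
        rng = np.random.default_rng(0)
        tight = syn.sample_axial_orientations(2000, (1, 0, 0), 100.0, rng)
        loose = syn.sample_axial_orientations(2000, (1, 0, 0), 2.0, rng)
        assert f3.variance_from_axes(tight) < f3.variance_from_axes(loose)


class TestFiberStack:
    def test_seeded_determinism(self):
        spec = syn.FiberSpec(seed=7)
        img1, t1 = syn.generate_fiber_stack(spec)
        img2, t2 = syn.generate_fiber_stack(syn.FiberSpec(seed=7))
        np.testing.assert_array_equal(img1.intensities, img2.intensities)
        np.testing.assert_array_equal(t1.theta, t2.theta)

    def test_subresolution_radius_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            syn.generate_fiber_stack(syn.FiberSpec(fiber_radius=0.2))

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            syn.FiberSpec(kappa=-2.0)

    def test_truth_valid_only_on_fibers(self):
        img, truth = syn.generate_fiber_stack(syn.FiberSpec(seed=3))
        assert truth.valid.any()
        # background voxels carry no truth orientation
        assert not truth.valid[img.intensities == 0].any()

    def test_poisson_stack_is_integer_counts(self):
        img, _ = syn.generate_fiber_stack(syn.FiberSpec(photon_scale=50.0, seed=2))
        assert np.all(img.intensities == np.round(img.intensities))
        assert img.intensities.max() > 0


class TestCartilagePhantom:
    def test_superficial_axes_near_surface_direction(self, cartilage_phantom):
        axes = cartilage_phantom["truth"].meta["zone_axes"]["superficial"]
        dev = np.degrees(np.arccos(np.clip(np.abs(axes[:, 0]), 0, 1)))
        assert np.all(dev <= 10.0)

    def test_endplate_is_dark(self, cartilage_phantom):
        img, truth = cartilage_phantom["img"], cartilage_phantom["truth"]
        spec = cartilage_phantom["spec"]
        calc_rows = np.nonzero(
            (truth.labels == ZONE_CODES["calcified"]).any(axis=(0, 2))
        )[0]
        endplate = img.intensities[:, calc_rows[: spec.endplate_rows], :]
        cartilage = img.intensities[:, truth.labels[0, :, 0] != 0, :]
        assert endplate.mean() / cartilage.mean() < 0.1

    def test_zone_fractions_respected(self, cartilage_phantom):
        truth = cartilage_phantom["truth"]
        spec = cartilage_phantom["spec"]
        total = (truth.labels != ZONE_CODES["background"]).sum()
        for frac, zone in zip(
            spec.zone_fractions, ("superficial", "transitional", "radial", "calcified")
        ):
            got = (truth.labels == ZONE_CODES[zone]).sum() / total
            assert got == pytest.approx(frac, abs=0.02)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            syn.CartilageSpec(zone_fractions=(0.5, 0.2, 0.2, 0.2))

    def test_thin_zone_flagged(self):
        spec = syn.CartilageSpec(
            volume_shape=(4, 40, 32),
            zone_fractions=(0.1, 0.3, 0.4, 0.2),
            seed=0,
        )
        _, truth = syn.generate_cartilage_phantom(spec)
        assert any("thinner" in f for f in truth.flags)


class TestDecayCube:
    def test_pure_long_component_decay_shape(self):
        spec = syn.DecaySpec(
            image_shape=(4, 4), f_long_map=1.0, sample_poisson=False, seed=0
        )
        cube, _ = syn.generate_decay_cube(spec)
        decay = cube.counts[:, 0, 0]
        t = cube.bin_centers
        # log-linear with slope -1/tau_long (mid-bin integration is exact
        # up to a constant factor for exponentials)
        slope = np.polyfit(t, np.log(decay), 1)[0]
        assert -1.0 / slope == pytest.approx(spec.tau_long, rel=1e-3)

    def test_midpoint_phasor_of_even_mixture(self):
        # phasor linearity: intensity-weighted combination of components
        f = np.array([[0.0, 0.5, 1.0]])
        cube, _ = syn.generate_decay_cube(
            syn.DecaySpec(image_shape=(1, 3), f_long_map=f, sample_poisson=False)
        )
        ph = pf.phasor_transform(cube, min_photons=1)
        mid = np.array([ph.G[0, 1], ph.S[0, 1]])
        short = np.array([ph.G[0, 0], ph.S[0, 0]])
        long_ = np.array([ph.G[0, 2], ph.S[0, 2]])
        np.testing.assert_allclose(mid, (short + long_) / 2.0, atol=1e-12)

    def test_photon_conservation(self):
        spec = syn.DecaySpec(image_shape=(64, 64), total_counts=5000.0, seed=9)
        cube, _ = syn.generate_decay_cube(spec)
        expected = spec.total_counts * 64 * 64
        assert abs(cube.counts.sum() - expected) < 3 * np.sqrt(expected)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="ill-conditioned"):
            syn.DecaySpec(n_bins=4)

    def test_bad_lifetime_ordering_rejected(self):
        with pytest.raises(ValueError):
            syn.DecaySpec(tau_short=3.0, tau_long=0.4)

    def test_f_long_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            syn.DecaySpec(image_shape=(2, 2), f_long_map=np.full((2, 2), 1.5))

    def test_noise_free_matches_closed_form_phasor(self):
        cube, _ = syn.generate_decay_cube(
            syn.DecaySpec(image_shape=(2, 2), f_long_map=1.0, sample_poisson=False)
        )
        ph = pf.phasor_transform(cube)
        g, s = mono_exponential_phasor(3.0, 12.5)
        assert ph.G[0, 0] == pytest.approx(g, abs=1e-3)
        assert ph.S[0, 0] == pytest.approx(s, abs=1e-3)


class TestMetabolicField:
    def test_white_texture_psd_flat(self):
        rng = np.random.default_rng(4)
        tex = syn.power_law_texture((256, 256), 0.0, 0.5, rng)
        fit = met.psd_power_law(tex, 0.5)
        assert fit.beta == pytest.approx(0.0, abs=0.1)

    def test_noise_free_redox_identity(self, metabolic_field):
        nadh = metabolic_field["nadh"].intensities
        fad = metabolic_field["fad"].intensities
        cyto = metabolic_field["masks"]["cytoplasm"]
        rr = fad[cyto] / (nadh[cyto] + fad[cyto])
        np.testing.assert_allclose(rr, 0.4, atol=1e-12)

    def test_lipofuscin_is_bright(self, metabolic_field):
        nadh = metabolic_field["nadh"].intensities
        masks = metabolic_field["masks"]
        plain = masks["cytoplasm"] & ~masks["lipofuscin"]
        assert nadh[masks["lipofuscin"]].min() >= 10 * np.median(nadh[plain])

    def test_nuclei_dark(self, metabolic_field):
        nadh = metabolic_field["nadh"].intensities
        assert nadh[metabolic_field["masks"]["nucleus"]].max() == 0.0

    def test_rr_of_one_rejected(self):
        with pytest.raises(ValueError, match="rr"):
            syn.CellFieldSpec(rr_per_cell=1.0)

    def test_nucleus_larger_than_cell_rejected(self):
        with pytest.raises(ValueError):
            syn.CellFieldSpec(cell_radius=3.0, nucleus_radius=5.0)

    def test_seeded_determinism(self):
        a = syn.generate_metabolic_field(syn.CellFieldSpec(seed=3))
        b = syn.generate_metabolic_field(syn.CellFieldSpec(seed=3))
        np.testing.assert_array_equal(a[0].intensities, b[0].intensities)
        np.testing.assert_array_equal(a[1].intensities, b[1].intensities)
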