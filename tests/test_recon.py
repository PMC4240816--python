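"""Zero-filled baseline, coil combination, patch thresholding, data consistency."""

import numpy as np
import pytest

from pvmra import (
    ReconConfig,
    combine_coils,
    cs_reconstruct,
    data_consistency,
    generate_pattern,
    make_coil_maps,
    patch_threshold,
    simulate_acquisition,
    zero_filled_recon,
)
from pvmra._fft import dc_index, fftc


def _full_pattern(n_y, n_z):
    p = generate_pattern(n_y, n_z, 1.0, (1, 1), seed=0)
    p.mask[:] = True
    return p


class TestZeroFilled:
    def test_full_sampling_recovers_volume(self, slab_phantom):
        vol, _ = slab_phantom
        coils = make_coil_maps(vol.shape, 1)
        k = simulate_acquisition(vol, coils, _full_pattern(*vol.shape[1:]))
        img = zero_filled_recon(k)[0]
        assert np.abs(img - vol.data).max() / np.abs(vol.data).max() < 1e-10

    def test_undersampling_cannot_gain_energy(self, slab_acquisition):
        vol, _, coils, pattern, k = slab_acquisition
        k_full = simulate_acquisition(vol, coils, _full_pattern(*vol.shape[1:]))
        e_sub = (np.abs(zero_filled_recon(k)) ** 2).sum()
        e_full = (np.abs(zero_filled_recon(k_full)) ** 2).sum()
        assert e_sub <= e_full

    def test_dc_only_mask_gives_constant_image(self, slab_phantom):
        vol, _ = slab_phantom
        coils = make_coil_maps(vol.shape, 1)
        p = _full_pattern(*vol.shape[1:])
        p.mask[:] = False
        p.mask[dc_index(vol.shape[1]), dc_index(vol.shape[2])] = True
        k = simulate_acquisition(vol, coils, p)
        img = zero_filled_recon(k)[0]
        # constant over the phase-encoded plane at every readout position
        spread = np.abs(img - img[:, :1, :1]).max()
        assert spread < 1e-8 * np.abs(img).max()


class TestCombineCoils:
    def test_single_unit_coil_b1_is_identity(self):
        coils = make_coil_maps((8, 16, 16), 1)
        x = np.random.default_rng(0).standard_normal((1, 8, 16, 16)) + 0j
        np.testing.assert_allclose(combine_coils(x, coils, "b1"), x[0], atol=1e-12)

    def test_b1_recovers_modulated_image_and_rss_its_magnitude(self):
        coils = make_coil_maps((8, 16, 16), 6, seed=4)
        rng = np.random.default_rng(1)
        m = rng.standard_normal((8, 16, 16)) + 1j * rng.standard_normal((8, 16, 16))
        x = coils.maps * m[None]
        np.testing.assert_allclose(combine_coils(x, coils, "b1"), m, atol=1e-10)
        np.testing.assert_allclose(combine_coils(x, coils, "rss"), np.abs(m), atol=1e-10)

    def test_shape_mismatch_rejected(self):
        coils = make_coil_maps((8, 16, 16), 2, seed=0)
        with pytest.raises(ValueError):
            combine_coils(np.zeros((2, 8, 16, 8)), coils)


class TestPatchThreshold:
    def test_vanishing_threshold_is_identity(self):
        img = np.random.default_rng(0).standard_normal((8, 24, 24))
        out = patch_threshold(img, ReconConfig(patch_mode="slice"), tau=1e-12)
        assert np.abs(out - img).max() < 1e-8

    def test_constant_image_unchanged(self):
        img = np.full((24, 24), 3.0)
        out = patch_threshold(img, ReconConfig(), tau=0.2)
        assert np.abs(out - 3.0).max() < 1e-8

    def test_denoises_piecewise_constant_image(self):
        rng = np.random.default_rng(7)
        clean = np.zeros((48, 48))
        clean[12:36, 12:36] = 1.0
        noisy = clean + 0.08 * rng.standard_normal(clean.shape)
        out = patch_threshold(noisy, ReconConfig(), tau=0.2)
        rmse_in = np.sqrt(((noisy - clean) ** 2).mean())
        rmse_out = np.sqrt((np.abs(out - clean) ** 2).mean())
        assert rmse_out < rmse_in

    def test_3d_patch_mode_also_denoises(self):
        rng = np.random.default_rng(8)
        clean = np.zeros((12, 20, 20))
        clean[3:9, 5:15, 5:15] = 1.0
        noisy = clean + 0.08 * rng.standard_normal(clean.shape)
        out = patch_threshold(noisy, ReconConfig(patch_mode="3d"), tau=0.2)
        assert np.sqrt((np.abs(out - clean) ** 2).mean()) < np.sqrt(
            ((noisy - clean) ** 2).mean()
        )

    def test_patch_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="patch larger"):
            patch_threshold(np.zeros((3, 3)), ReconConfig(), tau=0.1)

    def test_threshold_schedule_is_geometric(self):
        cfg = ReconConfig(n_iterations=10, threshold_initial=0.1, threshold_final=0.01)
        sched = cfg.threshold_schedule()
        assert sched[0] == pytest.approx(0.1) and sched[-1] == pytest.approx(0.01)
        ratios = sched[1:] / sched[:-1]
        np.testing.assert_allclose(ratios, ratios[0])


class TestDataConsistency:
    @pytest.fixture()
    def single_coil_problem(self, slab_phantom):
        vol, _ = slab_phantom
        coils = make_coil_maps(vol.shape, 1)
        pattern = generate_pattern(vol.shape[1], vol.shape[2], 5.0, (32, 19), seed=7)
        k = simulate_acquisition(vol, coils, pattern, noise_sigma=1.0, seed=9)
        return vol, coils, pattern, k

    def test_exact_at_sampled_lines(self, single_coil_problem):
        vol, coils, pattern, k = single_coil_problem
        x = np.random.default_rng(0).standard_normal(vol.shape) + 0j
        out = data_consistency(x, k, coils)
        kk = fftc(out)
        err = np.abs(kk[:, pattern.mask] - k.data[0][:, pattern.mask]).max()
        assert err / np.abs(k.data).max() < 1e-8

    def test_idempotent(self, single_coil_problem):
        vol, coils, pattern, k = single_coil_problem
        x = np.random.default_rng(1).standard_normal(vol.shape) + 0j
        once = data_consistency(x, k, coils)
        twice = data_consistency(once, k, coils)
        assert np.abs(twice - once).max() < 1e-8 * np.abs(once).max()

    def test_zero_image_fully_sampled_gives_zero_filled(self, slab_phantom):
        vol, _ = slab_phantom
        coils = make_coil_maps(vol.shape, 1)
        k = simulate_acquisition(vol, coils, _full_pattern(*vol.shape[1:]))
        out = data_consistency(np.zeros(vol.shape, complex), k, coils)
        zf = combine_coils(zero_filled_recon(k), coils, "b1")
        assert np.abs(out - zf).max() < 1e-10


class TestCsReconstruct:
    def test_zero_iterations_equals_zero_filled(self, slab_acquisition):
        vol, _, coils, pattern, k = slab_acquisition
        cs = cs_reconstruct(k, coils, ReconConfig(n_iterations=0))
        zf = np.abs(combine_coils(zero_filled_recon(k), coils, "b1"))
        np.testing.assert_allclose(cs.data, zf, atol=1e-12)

    def test_fully_sampled_final_kspace_matches_measurement(self, slab_phantom):
        vol, _ = slab_phantom
        coils = make_coil_maps(vol.shape, 1)
        k = simulate_acquisition(vol, coils, _full_pattern(*vol.shape[1:]))
        cs = cs_reconstruct(
            k, coils, ReconConfig(n_iterations=3, patch_mode="slice"), magnitude=False
        )
        err = np.abs(fftc(cs.data) - k.data[0]).max()
        assert err / np.abs(k.data).max() < 1e-8

    def test_deterministic(self, slab_acquisition):
        vol, _, coils, pattern, k = slab_acquisition
        cfg = ReconConfig(n_iterations=2, patch_mode="slice")
        a = cs_reconstruct(k, coils, cfg)
        b = cs_reconstruct(k, coils, cfg)
        assert np.array_equal(a.data, b.data)
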