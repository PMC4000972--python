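"""3D Gabor kernels: rotation geometry, sampling, normalization, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_correlate

from gaborgist import (
    GaborParams,
    VideoVolume,
    build_default_bank,
    build_kernel,
    filter_volume,
    filter_volume_bank,
    gabor_value,
    rotate_coords,
)


class TestRotateCoords:
    def test_zero_angles_identity(self):
        assert rotate_coords(1.5, -2.0, 3.0, 0.0, 0.0) == (1.5, -2.0, 3.0)

    def test_quarter_turn_spatial(self):
        X, Y, T = rotate_coords(2.0, 3.0, 5.0, np.pi / 2, 0.0)
        np.testing.assert_allclose((X, Y, T), (2.0, -5.0, 3.0), atol=1e-12)

    def test_quarter_turn_temporal(self):
        X, Y, T = rotate_coords(2.0, 3.0, 5.0, 0.0, np.pi / 2)
        np.testing.assert_allclose((X, Y, T), (5.0, 3.0, -2.0), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=st.floats(-10, 10), y=st.floats(-10, 10), t=st.floats(-10, 10),
        theta=st.floats(-np.pi, np.pi), omega=st.floats(-np.pi, np.pi),
    )
    def test_norm_preserved(self, x, y, t, theta, omega):
        X, Y, T = rotate_coords(x, y, t, theta, omega)
        np.testing.assert_allclose(
            X * X + Y * Y + T * T, x * x + y * y + t * t, atol=1e-9
        )


class TestGaborValue:
    def test_origin_is_one(self):
        p = GaborParams(theta=0.7, omega=-0.3)
        assert gabor_value(p, 0.0, 0.0, 0.0) == pytest.approx(1.0)

    def test_even_symmetry(self, rng):
        p = GaborParams(theta=0.5, omega=1.1)
        pts = rng.uniform(-5, 5, size=(20, 3))
        for x, y, t in pts:
            assert gabor_value(p, x, y, t) == pytest.approx(
                gabor_value(p, -x, -y, -t), rel=1e-12
            )

    def test_half_wavelength_value(self):
        # at (lambda_x/2, 0, 0) with theta=omega=0: envelope * cos(pi) * cos(0)
        p = GaborParams()
        expected = -np.exp(-p.lambda_x**2 / (8 * p.sigma_x**2))
        assert gabor_value(p, p.lambda_x / 2, 0.0, 0.0) == pytest.approx(expected)

    def test_literal_sigma_convention(self):
        # with sigma_as_variance the envelope denominators are 2*sigma directly
        p = GaborParams(sigma_as_variance=True)
        expected = -np.exp(-p.lambda_x**2 / (8 * p.sigma_x))
        assert gabor_value(p, p.lambda_x / 2, 0.0, 0.0) == pytest.approx(expected)


class TestBuildKernel:
    def test_normalization_invariants(self):
        k = build_kernel(GaborParams(theta=np.pi / 2, omega=np.pi / 2))
        assert abs(k.taps.sum()) < 1e-10 * k.taps.size
        assert np.linalg.norm(k.taps) == pytest.approx(1.0, abs=1e-10)

    def test_axis_negation_symmetry_at_zero_orientation(self):
        k = build_kernel(GaborParams())
        np.testing.assert_allclose(k.taps, k.taps[::-1, :, :], atol=1e-12)
        np.testing.assert_allclose(k.taps, k.taps[:, ::-1, :], atol=1e-12)
        np.testing.assert_allclose(k.taps, k.taps[:, :, ::-1], atol=1e-12)

    def test_unnormalized_tap_matches_direct_evaluation(self):
        p = GaborParams()
        k = build_kernel(p, normalize=False)
        hx, hy, ht = p.support
        # taps are laid out (row=y, col=x, frame=t)
        assert k.taps[hy, hx + 1, ht] == pytest.approx(gabor_value(p, 1.0, 0.0, 0.0))
        assert k.taps[hy + 2, hx, ht + 1] == pytest.approx(gabor_value(p, 0.0, 2.0, 1.0))

    def test_rotation_consistency_quarter_turn(self):
        """theta=pi/2 kernel equals the theta=0 kernel on permuted coordinates.

        Under (X,Y,T) = (x,-t,y), evaluating the unrotated function at the
        rotated coordinates reproduces the rotated kernel tap-for-tap.
        """
        base = GaborParams(support=(5, 5, 5))
        rot = build_kernel(
            GaborParams(theta=np.pi / 2, support=(5, 5, 5)), normalize=False
        )
        h = 5
        grid = np.arange(-h, h + 1, dtype=float)
        Y, X, T = np.meshgrid(grid, grid, grid, indexing="ij")
        expected = gabor_value(base, X, -T, Y)
        np.testing.assert_allclose(rot.taps, expected, atol=1e-12)


class TestDefaultBank:
    def test_bank_has_four_kernels(self, default_bank):
        assert len(default_bank) == 4

    def test_single_shared_scale(self, default_bank):
        scales = {
            (k.params.sigma_x, k.params.sigma_y, k.params.sigma_t,
             k.params.lambda_x, k.params.lambda_y)
            for k in default_bank
        }
        assert len(scales) == 1

    def test_orientations_are_distinct(self, default_bank):
        pairs = [(k.params.theta, k.params.omega) for k in default_bank]
        assert len(set(pairs)) == 4

    def test_bank_construction_is_deterministic(self):
        b1, b2 = build_default_bank(), build_default_bank()
        for k1, k2 in zip(b1, b2):
            np.testing.assert_array_equal(k1.taps, k2.taps)

    def test_empty_orientation_list_rejected(self):
        with pytest.raises(ValueError, match="orientation"):
            build_default_bank(orientations=[])


class TestFilterVolume:
    def test_constant_volume_gives_zero_response(self, default_bank):
        vol = np.full((36, 36, 14), 0.6)
        for kernel in default_bank:
            assert np.abs(filter_volume(vol, kernel)).max() < 1e-8

    def test_offset_invariance(self, default_bank, rng):
        vol = rng.uniform(0.1, 0.7, size=(36, 36, 14))
        k = default_bank.kernels[1]
        delta = filter_volume(vol + 0.25, k) - filter_volume(vol, k)
        assert np.abs(delta).max() < 1e-8

    def test_impulse_reproduces_taps(self):
        kernel = build_kernel(GaborParams(support=(3, 3, 2)))
        vol = np.zeros((15, 15, 11))
        vol[7, 7, 5] = 1.0
        response = filter_volume(vol, kernel)
        # correlation flips the kernel around the impulse
        np.testing.assert_allclose(
            response[4:11, 4:11, 3:8], kernel.taps[::-1, ::-1, ::-1], atol=1e-10
        )

    def test_linearity(self, rng):
        kernel = build_kernel(GaborParams(support=(2, 2, 2)))
        v1 = rng.uniform(size=(9, 9, 9))
        v2 = rng.uniform(size=(9, 9, 9))
        lhs = filter_volume(0.3 * v1 + 0.6 * v2, kernel)
        rhs = 0.3 * filter_volume(v1, kernel) + 0.6 * filter_volume(v2, kernel)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        kernel = build_kernel(GaborParams(support=(2, 2, 2)))
        for _ in range(3):
            vol = rng.uniform(size=(9, 9, 9))
            fast = filter_volume(vol, kernel)
            slow = brute_force_correlate(vol, kernel.taps)
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_zero_boundary_mode_matches_oracle(self, rng):
        kernel = build_kernel(GaborParams(support=(2, 2, 2)))
        vol = rng.uniform(size=(9, 9, 9))
        fast = filter_volume(vol, kernel, boundary="zero")
        slow = brute_force_correlate(vol, kernel.taps, boundary="zero")
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_chunked_equals_unchunked(self, rng):
        kernel = build_kernel(GaborParams(support=(3, 3, 2)))
        vol = rng.uniform(size=(12, 12, 40))
        full = filter_volume(vol, kernel)
        chunked = filter_volume(vol, kernel, chunk_frames=7)
        np.testing.assert_allclose(chunked, full, atol=1e-12)

    def test_kernel_larger_than_volume_rejected(self, default_bank):
        with pytest.raises(ValueError, match="support"):
            filter_volume(np.zeros((5, 5, 3)), default_bank.kernels[0])

    def test_bank_filtering_matches_per_kernel(self, default_bank, rng):
        vol = rng.uniform(size=(36, 40, 16))
        shared = filter_volume_bank(vol, default_bank)
        for r, kernel in zip(shared, default_bank):
            np.testing.assert_allclose(r, filter_volume(vol, kernel), atol=1e-12)

    def test_accepts_video_volume(self, random_volume, default_bank):
        r = filter_volume(random_volume, default_bank.kernels[0])
        assert r.shape == random_volume.shape
        assert np.all(np.isfinite(r))


class TestBankConfigAndDump:
    def test_bank_from_yaml_config(self, tmp_path):
        cfg = tmp_path / "bank.yaml"
        cfg.write_text(
            "sigma: [4, 4, 2]\n"
            "lambdas: [16, 16]\n"
            "support: [8, 8, 4]\n"
            "angles_in: degrees\n"
            "orientations:\n  - [0, 0]\n  - [90, 0]\n"
        )
        from gaborgist import bank_from_config

        bank = bank_from_config(cfg)
        assert len(bank) == 2
        k = bank.kernels[1]
        assert k.taps.shape == (17, 17, 9)
        assert k.params.lambda_x == 16.0
        assert k.params.theta == pytest.approx(np.pi / 2)

    def test_kernel_dump_roundtrip_text_and_npy(self, tmp_path):
        from gaborgist import dump_kernel

        kernel = build_kernel(GaborParams(support=(2, 2, 2)))
        txt = tmp_path / "kernel.txt"
        dump_kernel(kernel, txt)
        flat = np.loadtxt(txt)
        np.testing.assert_allclose(flat.reshape(kernel.taps.shape), kernel.taps)

        npy = tmp_path / "kernel.npy"
        dump_kernel(kernel, npy)
        np.testing.assert_array_equal(np.load(npy), kernel.taps)
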