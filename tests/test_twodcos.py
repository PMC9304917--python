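"""Generalized 2D correlation spectroscopy: formulas, invariants, rendering."""

import numpy as np
import pytest

from poriascreen import twodcos as tdc
from poriascreen.synth import SynthConfig, generate_spectra


class TestDynamicSpectra:
    def test_mean_subtraction(self):
        d = tdc.dynamic_spectra(np.array([[0.0, 0.0], [2.0, 4.0]]))
        assert np.array_equal(d.W, [[-1.0, -2.0], [1.0, 2.0]])

    def test_mean_reference_zero_column_sums(self):
        rng = np.random.default_rng(0)
        d = tdc.dynamic_spectra(rng.standard_normal((5, 8)))
        assert np.allclose(d.W.sum(axis=0), 0, atol=1e-12)

    def test_explicit_zero_reference_identity(self):
        traces = np.random.default_rng(1).standard_normal((3, 6))
        d = tdc.dynamic_spectra(traces, np.zeros(6))
        assert np.array_equal(d.W, traces)

    def test_single_trace_error(self):
        with pytest.raises(ValueError):
            tdc.dynamic_spectra(np.ones((1, 4)))


class TestSynchronous:
    def test_hand_computed_two_trace(self):
        d = tdc.DynamicSpectra(W=np.array([[-1.0, -2.0], [1.0, 2.0]]), reference=np.zeros(2))
        assert np.array_equal(tdc.synchronous(d), [[2.0, 4.0], [4.0, 8.0]])

    def test_constant_traces_zero_map(self):
        d = tdc.dynamic_spectra(np.ones((4, 5)))
        assert np.allclose(tdc.synchronous(d), 0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            d = tdc.dynamic_spectra(rng.standard_normal((5, 8)))
            phi = tdc.synchronous(d)
            assert np.max(np.abs(phi - tdc.synchronous_bruteforce(d))) < 1e-10
            assert np.allclose(phi, phi.T)
            assert np.all(np.diag(phi) >= 0)
            assert np.min(np.linalg.eigvalsh(phi)) >= -1e-10  # PSD


class TestHilbertNoda:
    def test_m1(self):
        assert np.array_equal(tdc.hilbert_noda(1), [[0.0]])

    def test_m3_closed_form(self):
        expected = np.array(
            [
                [0.0, 1 / np.pi, 1 / (2 * np.pi)],
                [-1 / np.pi, 0.0, 1 / np.pi],
                [-1 / (2 * np.pi), -1 / np.pi, 0.0],
            ]
        )
        assert np.allclose(tdc.hilbert_noda(3), expected, atol=1e-15)

    @pytest.mark.parametrize("m", [2, 4, 9])
    def test_antisymmetric(self, m):
        N = tdc.hilbert_noda(m)
        assert np.allclose(N + N.T, 0, atol=1e-15)
        assert np.all(np.diag(N) == 0)

    def test_m0_error(self):
        with pytest.raises(ValueError):
            tdc.hilbert_noda(0)


class TestAsynchronous:
    def test_two_traces_always_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            d = tdc.dynamic_spectra(rng.standard_normal((2, 6)))
            assert np.allclose(tdc.asynchronous(d), 0, atol=1e-12)

    def test_hand_computed_three_trace(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])
        d = tdc.DynamicSpectra(W=W, reference=np.zeros(2))
        psi = tdc.asynchronous(d)
        assert psi[0, 1] == pytest.approx(3 / (4 * np.pi), abs=1e-12)
        assert psi[1, 0] == pytest.approx(-3 / (4 * np.pi), abs=1e-12)
        assert psi[0, 0] == psi[1, 1] == 0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            d = tdc.dynamic_spectra(rng.standard_normal((5, 8)))
            psi = tdc.asynchronous(d)
            assert np.max(np.abs(psi - tdc.asynchronous_bruteforce(d))) < 1e-10
            assert np.allclose(psi + psi.T, 0, atol=1e-12)
            assert np.allclose(np.diag(psi), 0, atol=1e-12)


class TestIntegrated:
    def test_zero_async_gives_zero(self):
        phi = np.ones((3, 3))
        assert np.allclose(tdc.integrated(phi, np.zeros((3, 3))), 0)

    def test_hand_computed_product(self):
        phi = np.array([[1.0, 2.0], [2.0, 1.0]])
        psi = np.array([[0.0, 3.0], [-3.0, 0.0]])
        assert np.array_equal(tdc.integrated(phi, psi), [[0.0, 6.0], [-6.0, 0.0]])

    def test_antisymmetry_of_product(self):
        rng = np.random.default_rng(5)
        d = tdc.dynamic_spectra(rng.standard_normal((4, 6)))
        prod = tdc.integrated(tdc.synchronous(d), tdc.asynchronous(d))
        assert np.allclose(prod + prod.T, 0, atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            tdc.integrated(np.ones((2, 2)), np.ones((3, 3)))


class TestRenderMap:
    def test_zero_map_mid_scale(self):
        img = tdc.render_map(np.zeros((8, 8)), size=16)
        assert img.pixels.shape == (16, 16, 1)
        assert np.all(img.pixels == 0.5)

    def test_shared_scale_saturation(self):
        rng = np.random.default_rng(6)
        m = rng.standard_normal((8, 8))
        scale = np.abs(m).max()
        a = tdc.render_map(m, 8, color_scale=scale)
        b = tdc.render_map(2 * m, 8, color_scale=scale)
        assert np.abs(b.pixels - 0.5).max() >= np.abs(a.pixels - 0.5).max()
        assert b.pixels.min() == 0.0 or b.pixels.max() == 1.0

    def test_deterministic(self):
        m = np.random.default_rng(7).standard_normal((10, 10))
        a = tdc.render_map(m, 32)
        b = tdc.render_map(m, 32)
        assert np.array_equal(a.pixels, b.pixels)

    def test_png_write(self, tmp_path):
        img = tdc.render_map(np.eye(6), 16, kind="sync")
        tdc.save_map_png(img, tmp_path / "map.png")
        assert (tmp_path / "map.png").stat().st_size > 0


class TestPerSampleMaps:
    def test_counts(self, small_spectra):
        maps = tdc.per_sample_maps(small_spectra, max_grid=16)
        assert len(maps) == 24  # one triple per sample
        assert maps[0].sync.shape == (16, 16)

    def test_600_maps_from_200_samples(self):
        s = generate_spectra(SynthConfig(n_per_part=100, grid_step=100, seed=1))
        maps = tdc.per_sample_maps(s, max_grid=8)
        assert 3 * len(maps) == 600

    def test_identical_replicates_zero_maps(self):
        cfg = SynthConfig(
            n_per_part=2, n_regions=2, grid_step=200, noise_sd=0,
            baseline_drift_sd=0, scatter_sd=0, part_effect=0, region_effect=0,
            seed=0,
        )
        maps = tdc.per_sample_maps(generate_spectra(cfg), max_grid=8)
        for m in maps:
            assert np.allclose(m.sync, 0, atol=1e-20)
            assert np.allclose(m.async_, 0, atol=1e-20)
            assert np.allclose(m.integrated, 0, atol=1e-30)

    def test_replicate_order_reversal_negates_async(self, small_spectra):
        s = small_spectra
        flipped = s.select(np.arange(s.n_records))
        # reverse replicate order within every sample
        flipped.replicate_id = (
            s.replicate_id.max() + 1 - s.replicate_id
        )
        a = tdc.per_sample_maps(s, max_grid=8)
        b = tdc.per_sample_maps(flipped, max_grid=8)
        for ma, mb in zip(a, b):
            assert np.allclose(ma.sync, mb.sync, atol=1e-12)
            assert np.allclose(ma.async_, -mb.async_, atol=1e-12)
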