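"""Pretreatment math: replicate means, SG second derivative, SNV, MSC."""

import numpy as np
import pytest

from conftest import toy_set
from poriascreen import preprocess
from poriascreen.preprocess import PreprocessSpec
from poriascreen.synth import SynthConfig, generate_spectra


def sg2_bruteforce(y: np.ndarray, window: int, order: int, delta: float) -> np.ndarray:
    """Local least-squares polynomial fit, evaluated as the 2nd derivative.

    Independent oracle for the interior points of a Savitzky-Golay filter.
    """
    half = window // 2
    out = np.full(y.size, np.nan)
    for i in range(half, y.size - half):
        x = (np.arange(-half, half + 1)) * delta
        coeffs = np.polyfit(x, y[i - half : i + half + 1], order)
        # second derivative of the fitted polynomial at x = 0
        der = np.polyder(np.poly1d(coeffs), 2)
        out[i] = der(0.0)
    return out


class TestAverageReplicates:
    def test_arithmetic_mean(self):
        s = toy_set(
            [[1, 1, 1, 1], [3, 3, 3, 3]],
            sample_id=np.array(["a", "a"], dtype=object),
            replicate_id=np.array([1, 2]),
        )
        out = preprocess.average_replicates(s)
        assert out.n_records == 1
        assert np.array_equal(out.absorbance[0], [2, 2, 2, 2])

    def test_single_replicate_identity(self):
        s = toy_set([[1.0, 2.0, 3.0]])
        out = preprocess.average_replicates(s)
        assert np.array_equal(out.absorbance, s.absorbance)

    def test_noise_free_average_equals_any_replicate(self, clean_spectra):
        out = preprocess.average_replicates(clean_spectra)
        sid = out.sample_id[0]
        assert np.allclose(
            out.absorbance[0], clean_spectra.sample_traces(str(sid))[0]
        )

    def test_missing_replicate_names_sample(self):
        # container-level invariant: unequal counts are rejected on construction
        with pytest.raises(ValueError, match="replicate"):
            toy_set(
                np.ones((3, 4)),
                sample_id=np.array(["a", "a", "b"], dtype=object),
                replicate_id=np.array([1, 2, 1]),
            )


class TestSecondDerivative:
    def test_quadratic_gives_constant(self):
        x = np.arange(50, dtype=float)
        a = 0.7
        s = toy_set((a * x**2)[None, :], wavenumbers=50.0 - x)  # step 1 grid
        out = preprocess.second_derivative(s, PreprocessSpec("SD", 17, 3))
        assert np.allclose(out.absorbance[0, 8:-8], 2 * a, atol=1e-8)

    def test_linear_ramp_annihilated(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(60)
        s1 = toy_set(y[None, :], wavenumbers=np.arange(60.0, 0, -1))
        s2 = toy_set(
            (y + 3.0 * np.arange(60) + 5.0)[None, :],
            wavenumbers=np.arange(60.0, 0, -1),
        )
        o1 = preprocess.second_derivative(s1)
        o2 = preprocess.second_derivative(s2)
        assert np.allclose(o1.absorbance[0, 8:-8], o2.absorbance[0, 8:-8], atol=1e-9)

    def test_matches_local_polyfit_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(80)
        delta = 4.0
        s = toy_set(y[None, :], wavenumbers=10_000 - delta * np.arange(80))
        out = preprocess.second_derivative(s, PreprocessSpec("SD", 17, 3))
        oracle = sg2_bruteforce(y, 17, 3, delta)
        interior = slice(8, -8)
        assert np.nanmax(np.abs(out.absorbance[0, interior] - oracle[interior])) < 1e-10

    def test_errors(self):
        s = toy_set(np.ones((1, 30)), wavenumbers=np.sort(np.random.default_rng(0).uniform(0, 1, 30))[::-1])
        with pytest.raises(ValueError, match="uniform"):
            preprocess.second_derivative(s)
        s2 = toy_set(np.ones((1, 10)))
        with pytest.raises(ValueError, match="window"):
            preprocess.second_derivative(s2, PreprocessSpec("SD", 17, 3))


class TestSNV:
    def test_unit_moments(self):
        s = toy_set([[1.0, 2.0, 3.0]])
        out = preprocess.snv(s)
        assert out.absorbance[0].mean() == pytest.approx(0, abs=1e-12)
        assert out.absorbance[0].std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(40)
        a = preprocess.snv(toy_set(y[None, :]))
        b = preprocess.snv(toy_set((5 * y + 2)[None, :]))
        assert np.allclose(a.absorbance, b.absorbance, atol=1e-12)

    def test_moments_invariant_property(self, small_spectra):
        out = preprocess.snv(small_spectra)
        assert np.all(np.abs(out.absorbance.mean(axis=1)) < 1e-12)
        assert np.allclose(out.absorbance.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_scatter_reduced_between_replicates(self):
        s = generate_spectra(
            SynthConfig(n_per_part=10, grid_step=40, scatter_sd=0.08, seed=3)
        )
        raw_d, snv_d = [], []
        out = preprocess.snv(s)
        for sid in s.unique_samples():
            tr_raw = s.sample_traces(sid)
            tr_snv = out.sample_traces(sid)
            raw_n = tr_raw / np.linalg.norm(tr_raw)  # comparable scales
            snv_n = tr_snv / np.linalg.norm(tr_snv)
            raw_d.append(np.linalg.norm(raw_n[0] - raw_n[1]))
            snv_d.append(np.linalg.norm(snv_n[0] - snv_n[1]))
        assert np.mean(snv_d) < np.mean(raw_d)

    def test_constant_record_error(self):
        with pytest.raises(ValueError, match="s0"):
            preprocess.snv(toy_set(np.ones((1, 5))))


class TestMSC:
    def test_reference_record_unchanged(self):
        rng = np.random.default_rng(3)
        ref = rng.standard_normal(30)
        s = toy_set(ref[None, :])
        out = preprocess.msc(s, PreprocessSpec("MSC", msc_reference=ref))
        assert np.allclose(out.absorbance[0], ref, atol=1e-10)

    def test_exact_affine_removal(self):
        rng = np.random.default_rng(4)
        ref = rng.standard_normal(30)
        s = toy_set((2 * ref + 3)[None, :])
        out = preprocess.msc(s, PreprocessSpec("MSC", msc_reference=ref))
        assert np.allclose(out.absorbance[0], ref, atol=1e-10)

    def test_matches_regression_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((6, 25))
        s = toy_set(X)
        out = preprocess.msc(s)
        ref = X.mean(axis=0)
        for i in range(6):
            a, b = np.polyfit(ref, X[i], 1)
            assert np.max(np.abs(out.absorbance[i] - (X[i] - b) / a)) < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((4, 20))
        ref = X.mean(axis=0)
        spec = PreprocessSpec("MSC", msc_reference=ref)
        once = preprocess.msc(toy_set(X), spec)
        twice = preprocess.msc(once, spec)
        assert np.allclose(once.absorbance, twice.absorbance, atol=1e-10)

    def test_constant_reference_error(self):
        with pytest.raises(ValueError, match="constant"):
            preprocess.msc(
                toy_set(np.random.default_rng(7).standard_normal((2, 10))),
                PreprocessSpec("MSC", msc_reference=np.ones(10)),
            )
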