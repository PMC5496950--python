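"""Frequency transform and the 14 interaction measures."""

import numpy as np
import pytest

from eegretest import (
    DEFAULT_FREQS,
    MVARModel,
    band_average,
    coherence_family,
    compute_all_measures,
    direct_causality,
    dtf_family,
    granger_family,
    partial_family,
    spectral_decompose,
)
from eegretest.connectivity import BANDS, MEASURES, SpectralDecomposition
from eegretest.synth import simulate_var

FS = 500.0


def random_stable_model(m, p, rng, scale=0.15):
    while True:
        A = rng.standard_normal((p, m, m)) * scale
        model = MVARModel(A=A, V=np.eye(m), fs=FS)
        if model.spectral_radius() < 0.9:
            return model


class TestSpectralDecompose:
    def test_white_noise_identity(self):
        model = MVARModel(A=np.zeros((1, 3, 3)), V=np.eye(3), fs=FS)
        dec = spectral_decompose(model)
        eye = np.broadcast_to(np.eye(3), dec.Abar.shape)
        np.testing.assert_allclose(dec.Abar, eye, atol=1e-14)
        np.testing.assert_allclose(dec.H, eye, atol=1e-14)
        np.testing.assert_allclose(dec.S, eye / FS, atol=1e-16)

    def test_ar1_closed_form_spectrum(self):
        model = MVARModel(A=np.array([[[0.5]]]), V=np.eye(1), fs=FS)
        dec = spectral_decompose(model)
        expected = 1.0 / (FS * np.abs(1 - 0.5 * np.exp(-2j * np.pi * dec.freqs / FS)) ** 2)
        rel = np.abs(np.real(dec.S[:, 0, 0]) - expected) / expected
        assert rel.max() < 1e-10

    def test_h_inverts_abar_everywhere(self, rng):
        model = random_stable_model(4, 3, rng)
        dec = spectral_decompose(model)
        prod = dec.H @ dec.Abar
        np.testing.assert_allclose(prod, np.broadcast_to(np.eye(4), prod.shape), atol=1e-10)

    def test_s_hermitian_nonnegative_diagonal(self, rng):
        model = random_stable_model(3, 2, rng)
        dec = spectral_decompose(model)
        np.testing.assert_allclose(dec.S, np.conj(dec.S).transpose(0, 2, 1), atol=1e-14)
        assert (np.real(np.diagonal(dec.S, axis1=1, axis2=2)) > 0).all()

    def test_triangular_coupling_gives_triangular_h(self):
        A = np.array([[[0.5, 0.0], [0.4, 0.3]]])  # coupling only 0 -> 1
        dec = spectral_decompose(MVARModel(A=A, V=np.eye(2), fs=FS))
        assert np.abs(dec.H[:, 0, 1]).max() < 1e-14

    def test_nyquist_and_above_rejected(self):
        model = MVARModel(A=np.zeros((1, 1, 1)), V=np.eye(1), fs=FS)
        with pytest.raises(ValueError, match="Nyquist"):
            spectral_decompose(model, np.array([250.0]))

    def test_spectrum_integrates_to_process_variance(self):
        # univariate AR(1): var = sigma^2 / (1 - a^2)
        model = MVARModel(A=np.array([[[0.5]]]), V=np.eye(1), fs=FS)
        mids = np.arange(0.5, FS / 2, 1.0)
        dec = spectral_decompose(model, mids)
        integral = 2 * np.real(dec.S[:, 0, 0]).sum() * 1.0  # two-sided
        assert integral == pytest.approx(1 / (1 - 0.25), rel=1e-3)


class TestCoherenceFamily:
    def test_diagonal_is_unit_coherence(self, rng):
        dec = spectral_decompose(random_stable_model(3, 2, rng))
        fam = coherence_family(dec)
        idx = np.arange(3)
        np.testing.assert_allclose(fam["COH"][:, idx, idx], 1.0, atol=1e-12)
        np.testing.assert_allclose(fam["iCOH"][:, idx, idx], 0.0, atol=1e-12)

    def test_independent_channels_zero_off_diagonal(self):
        dec = spectral_decompose(MVARModel(A=np.zeros((1, 2, 2)), V=np.eye(2), fs=FS))
        fam = coherence_family(dec)
        assert np.abs(fam["COH"][:, 0, 1]).max() < 1e-14
        assert np.abs(fam["iCOH"][:, 0, 1]).max() < 1e-14

    def test_duplicated_channel_fully_coherent_at_zero_lag(self):
        # S for x2 == x1: rank-one outer product of the common spectrum
        freqs = DEFAULT_FREQS[:10]
        s = np.linspace(1.0, 2.0, len(freqs))
        S = s[:, None, None] * np.ones((2, 2))
        dec = SpectralDecomposition(
            freqs=freqs, Abar=np.zeros_like(S, dtype=complex),
            H=np.zeros_like(S, dtype=complex), S=S.astype(complex),
            fs=FS, V=np.eye(2),
        )
        fam = coherence_family(dec)
        np.testing.assert_allclose(np.abs(fam["COH"][:, 0, 1]), 1.0, atol=1e-12)
        np.testing.assert_allclose(fam["iCOH"][:, 0, 1], 0.0, atol=1e-12)

    def test_coherency_bounded(self, rng):
        dec = spectral_decompose(random_stable_model(4, 3, rng))
        fam = coherence_family(dec)
        assert (np.abs(fam["COH"]) <= 1 + 1e-10).all()
        assert (np.abs(fam["iCOH"]) <= 1 + 1e-10).all()


class TestPartialFamily:
    def test_white_noise_identity_patterns(self):
        dec = spectral_decompose(MVARModel(A=np.zeros((2, 3, 3)), V=np.eye(3), fs=FS))
        fam = partial_family(dec)
        eye = np.broadcast_to(np.eye(3), fam["PDC"].shape)
        np.testing.assert_allclose(fam["PDC"], eye, atol=1e-12)
        np.testing.assert_allclose(fam["GPDC"], eye, atol=1e-12)
        off = fam["pCOH"] * (1 - np.eye(3))
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_pdc_column_normalization(self, rng):
        for _ in range(10):
            dec = spectral_decompose(random_stable_model(5, 3, rng))
            pdc = partial_family(dec)["PDC"]
            np.testing.assert_allclose((pdc**2).sum(axis=1), 1.0, atol=1e-10)

    def test_gpdc_scale_invariant_pdc_not(self, rng):
        model = random_stable_model(2, 2, rng)
        # rescale channel 1 by 10: A' = D A D^-1, V' = D V D
        D = np.diag([1.0, 10.0])
        Di = np.diag([1.0, 0.1])
        A2 = np.stack([D @ Ak @ Di for Ak in model.A])
        scaled = MVARModel(A=A2, V=D @ model.V @ D, fs=FS)
        fam1 = partial_family(spectral_decompose(model))
        fam2 = partial_family(spectral_decompose(scaled))
        np.testing.assert_allclose(fam2["GPDC"], fam1["GPDC"], atol=1e-10)
        assert np.abs(fam2["PDC"] - fam1["PDC"]).max() > 1e-3

    def test_bounds(self, rng):
        dec = spectral_decompose(random_stable_model(4, 2, rng))
        fam = partial_family(dec)
        for key in ("PDC", "GPDC"):
            assert (fam[key] >= -1e-12).all() and (fam[key] <= 1 + 1e-10).all()
        assert (np.abs(fam["pCOH"]) <= 1 + 1e-10).all()


class TestDTFFamily:
    def test_white_noise_patterns(self):
        freqs = DEFAULT_FREQS
        dec = spectral_decompose(MVARModel(A=np.zeros((1, 2, 2)), V=np.eye(2), fs=FS))
        fam = dtf_family(dec)
        eye = np.broadcast_to(np.eye(2), fam["DTF"].shape)
        np.testing.assert_allclose(fam["DTF"], eye, atol=1e-12)
        idx = np.arange(2)
        np.testing.assert_allclose(
            fam["ffDTF"][:, idx, idx], 1 / np.sqrt(len(freqs)), atol=1e-12
        )

    def test_row_normalizations(self, rng):
        for _ in range(10):
            dec = spectral_decompose(random_stable_model(5, 3, rng))
            fam = dtf_family(dec)
            np.testing.assert_allclose((fam["DTF"] ** 2).sum(axis=2), 1.0, atol=1e-10)
            np.testing.assert_allclose(
                (fam["ffDTF"] ** 2).sum(axis=(0, 2)), 1.0, atol=1e-10
            )

    def test_unidirectional_coupling(self):
        A = np.array([[[0.5, 0.0], [0.4, 0.3]]])  # flow 0 -> 1 only
        dec = spectral_decompose(MVARModel(A=A, V=np.eye(2), fs=FS))
        fam = dtf_family(dec)
        assert np.abs(fam["DTF"][:, 0, 1]).max() < 1e-12  # no 1 -> 0
        assert fam["DTF"][:, 1, 0].min() > 0

    def test_ddtf_bounded_by_ffdtf(self, rng):
        dec = spectral_decompose(random_stable_model(4, 2, rng))
        fam = dtf_family(dec)
        assert (fam["dDTF"] <= fam["ffDTF"] + 1e-12).all()


class TestGrangerFamily:
    def test_independent_channels_near_zero(self, rng):
        data = rng.standard_normal((2, 20_000))
        ggc = granger_family(data, 2, FS)
        assert np.abs(ggc[:, 0, 1]).max() < 0.05
        assert np.abs(ggc[:, 1, 0]).max() < 0.05

    def test_directed_flow_detected(self, bivariate_var1_data):
        _, data = bivariate_var1_data
        ggc = granger_family(data, 4, FS)
        assert ggc[:, 1, 0].mean() > 0.1  # true flow 0 -> 1
        assert ggc[:, 0, 1].mean() < 0.02  # no reverse flow

    def test_direct_causality(self):
        assert not direct_causality(
            MVARModel(A=np.zeros((2, 3, 3)), V=np.eye(3), fs=FS)
        ).any()
        A = np.zeros((2, 2, 2))
        A[0, 1, 0], A[1, 1, 0] = 0.4, -0.3
        dc = direct_causality(MVARModel(A=A, V=np.eye(2), fs=FS))
        assert dc[1, 0] == pytest.approx(0.4**2 + 0.3**2)
        assert dc[0, 1] == 0


class TestBandAverage:
    def test_constant_measure(self):
        vals = np.full((len(DEFAULT_FREQS), 2, 2), 0.7)
        out = band_average(vals)
        np.testing.assert_allclose(out, 0.7)
        assert out.shape == (6, 2, 2)

    def test_hand_mean_delta(self):
        freqs = DEFAULT_FREQS
        vals = np.zeros((len(freqs), 1, 1))
        vals[freqs == 2] = 0.1
        vals[freqs == 3] = 0.2
        vals[freqs == 4] = 0.6
        out = band_average(vals)
        assert out[0, 0, 0] == pytest.approx(0.3)

    def test_band_frequency_counts(self):
        freqs = DEFAULT_FREQS
        for name, lo, hi in BANDS:
            count = ((freqs >= lo) & (freqs <= hi)).sum()
            if name == "theta":
                assert count == 3
            if name == "high_gamma":
                assert count == 45

    def test_direct_causality_passes_through(self):
        dc = np.arange(4.0).reshape(2, 2)
        np.testing.assert_array_equal(band_average(dc), dc)

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            band_average(np.zeros((3, 1, 1)), np.array([2.0, 3.0, 4.0]),
                         bands=[("x", 10, 20)])


class TestComputeAllMeasures:
    def test_all_measures_present_finite(self):
        A = np.array([[[0.5, 0.0], [0.4, 0.3]]])
        data = simulate_var(A, np.eye(2), 6000, np.random.default_rng(5))
        out = compute_all_measures(data, 3, FS)
        assert sorted(out) == sorted(MEASURES)
        for key, tensor in out.items():
            assert np.isfinite(tensor).all(), key
            assert tensor.shape[-2:] == (2, 2)
        assert out["DC"].ndim == 2

    def test_joint_channel_permutation_invariance(self):
        A = np.zeros((2, 3, 3))
        A[0] = [[0.4, 0.0, 0.2], [0.3, 0.3, 0.0], [0.0, 0.0, 0.25]]
        data = simulate_var(A, np.eye(3), 8000, np.random.default_rng(8))
        perm = [1, 2, 0]
        out = compute_all_measures(data, 2, FS)
        out_p = compute_all_measures(data[perm], 2, FS)
        for key in MEASURES:
            expected = out[key][..., perm, :][..., :, perm]
            np.testing.assert_allclose(out_p[key], expected, atol=1e-8, err_msg=key)

    def test_unknown_measure_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown measure"):
            compute_all_measures(rng.standard_normal((2, 1000)), 2, FS,
                                 measures=["COH", "XXX"])
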