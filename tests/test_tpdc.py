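"""Time-varying MVAR estimation and TPDC: oracles, identities, invariants."""

import numpy as np
import pytest

from tpdcflow import (
    EKFConfig,
    TimeSeriesSet,
    TimeVaryingVAR,
    TPDCTransformer,
    TVARModel,
    band_average,
    compute_tpdc,
    dual_ekf_tvar,
    estimate_tpdc,
    estimate_tpdc_batch,
    fit_stationary_var,
    frequency_grid,
    make_template,
    simulate_subject,
    spectral_transfer,
    static_pdc,
)
from tpdcflow.datatypes import YEO7_CHANNELS
from tpdcflow.tpdc import _dual_ekf_batch


def _model_from_coeffs(coeffs, tr=2.0, channels=None):
    coeffs = np.asarray(coeffs, float)
    if coeffs.ndim == 2:
        coeffs = coeffs[None, None]  # one time point, p=1
    n = coeffs.shape[-1]
    return TVARModel(
        order=coeffs.shape[1],
        coeffs=coeffs,
        innovation_cov=np.eye(n),
        channels=channels or tuple(f"ch{i}" for i in range(n)),
        tr=tr,
    )


class TestStationaryFit:
    def test_recovers_known_var1_coefficients(self, coupled_template):
        ts = simulate_subject(coupled_template, 4000, seed=11)
        coeffs, sigma = fit_stationary_var(ts, 1)
        np.testing.assert_allclose(coeffs[0], coupled_template.coupling, atol=0.05)
        assert np.allclose(sigma, sigma.T)

    def test_white_noise_gives_zero_coefficients(self):
        coeffs, _ = fit_stationary_var(
            TimeSeriesSet(
                "w4000",
                np.random.default_rng(0).normal(size=(4000, 7)),
                YEO7_CHANNELS,
                2.0,
            ),
            1,
        )
        assert np.abs(coeffs).max() < 0.05

    def test_short_series_precondition(self):
        ts = TimeSeriesSet(
            "short", np.random.default_rng(0).normal(size=(16, 7)), YEO7_CHANNELS, 2.0
        )
        with pytest.raises(ValueError, match="too short"):
            fit_stationary_var(ts, 1)


class TestDualEKF:
    def test_stationary_limit_matches_ols(self, coupled_template):
        ts = simulate_subject(coupled_template, 1000, seed=13)
        ols, _ = fit_stationary_var(ts, 1)
        model = dual_ekf_tvar(ts, 1)
        np.testing.assert_allclose(model.time_average(), ols, atol=0.05)

    def test_tracks_coupling_switch(self):
        """Coupling 0 -> 0.5 at T/2: second-half estimate exceeds first half."""

        def switch_series(seed, t=1000):
            r = np.random.default_rng(seed)
            x = np.zeros((t + 50, 7))
            e = r.normal(size=(t + 50, 7))
            a0 = np.eye(7) * 0.5
            a1 = a0.copy()
            a1[1, 0] = 0.5
            for i in range(1, t + 50):
                x[i] = (a0 if i < 50 + t // 2 else a1) @ x[i - 1] + e[i]
            return x[50:]

        data = np.stack([switch_series(100 + s) for s in range(20)])
        data -= data.mean(axis=1, keepdims=True)
        coeffs, _, _ = _dual_ekf_batch(data, 1, EKFConfig())
        half = coeffs.shape[1] // 2
        hits = np.mean(
            coeffs[:, half:, 1, 0].mean(axis=1) > coeffs[:, :half, 1, 0].mean(axis=1)
        )
        assert hits >= 0.9

    def test_deterministic(self, short_series):
        a = dual_ekf_tvar(short_series, 1)
        b = dual_ekf_tvar(short_series, 1)
        np.testing.assert_array_equal(a.coeffs, b.coeffs)

    def test_sklearn_estimator_surface(self, short_series):
        est = TimeVaryingVAR(order=1, tr=2.0).fit(short_series.data)
        assert est.coeffs_.shape == (short_series.n_times - 1, 1, 7, 7)
        assert est.get_params()["order"] == 1


class TestSpectralTransfer:
    def test_zero_coefficients_give_identity(self):
        model = _model_from_coeffs(np.zeros((7, 7)))
        transfer = spectral_transfer(model, 16)
        np.testing.assert_allclose(
            transfer.values, np.broadcast_to(np.eye(7), transfer.values.shape)
        )

    def test_diagonal_low_frequency_closed_form(self):
        model = _model_from_coeffs(np.eye(2) * 0.5, tr=2.0)
        transfer = spectral_transfer(model, 512)
        # lowest grid frequency ~ 0: Abar_ii -> 1 - 0.5 e^{-i theta} ~ 0.5
        theta = 2 * np.pi * transfer.freqs[0] * 2.0
        low = transfer.values[0, 0]
        assert low[0, 0] == pytest.approx(1 - 0.5 * np.exp(-1j * theta), abs=1e-12)
        assert abs(low[0, 0] - 0.5) < 5e-3
        assert abs(low[0, 1]) == 0

    @pytest.mark.parametrize("p,seed", [(1, 0), (2, 1), (3, 2)])
    def test_matches_brute_force_loop_oracle(self, p, seed):
        """Vectorized transfer equals a literal per-(f,t,i,j) evaluation."""
        rng = np.random.default_rng(seed)
        coeffs = rng.normal(scale=0.2, size=(4, p, 3, 3))
        model = _model_from_coeffs(coeffs, tr=1.5)
        transfer = spectral_transfer(model, 16)
        for fi, f in enumerate(transfer.freqs):
            for t in range(4):
                expected = np.eye(3, dtype=complex)
                for k in range(1, p + 1):
                    expected -= coeffs[t, k - 1] * np.exp(-2j * np.pi * f * k * 1.5)
                np.testing.assert_allclose(
                    transfer.values[fi, t], expected, atol=1e-12
                )


class TestComputeTPDC:
    def test_zero_coupling_is_identity_pattern(self):
        transfer = spectral_transfer(_model_from_coeffs(np.zeros((7, 7))), 16)
        pi = compute_tpdc(transfer)
        off = ~np.eye(7, dtype=bool)
        assert np.all(pi[..., off] == 0)
        np.testing.assert_allclose(pi[..., np.eye(7, dtype=bool)], 1.0)

    def test_unidirectional_two_channel_example(self):
        # channel 0 drives channel 1; no reverse influence at any frequency
        a = np.array([[0.5, 0.0], [0.4, 0.5]])
        pi = compute_tpdc(spectral_transfer(_model_from_coeffs(a), 64))
        assert np.all(pi[:, :, 0, 1] == 0)
        assert np.all(pi[:, :, 1, 0] > 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_column_normalization_identity(self, seed):
        rng = np.random.default_rng(seed)
        coeffs = rng.normal(scale=0.25, size=(6, 1, 5, 5))
        pi = compute_tpdc(spectral_transfer(_model_from_coeffs(coeffs), 32))
        colnorm = (pi**2).sum(axis=2)
        np.testing.assert_allclose(colnorm, 1.0, atol=1e-10)


class TestBandAverage:
    def test_constant_tensor_averages_to_itself(self):
        freqs = frequency_grid(2.0, 32)
        pi = np.full((32, 10, 3, 3), 0.25)
        out = band_average(pi, freqs, band=(0.009, 0.08))
        np.testing.assert_allclose(out.values, 0.25)

    def test_two_bin_arithmetic_mean(self):
        freqs = np.array([0.01, 0.02])
        pi = np.zeros((2, 4, 2, 2))
        pi[0] = 0.2
        pi[1] = 0.4
        out = band_average(pi, freqs, band=(0.005, 0.03))
        np.testing.assert_allclose(out.values, 0.3)

    def test_empty_band_rejected(self):
        freqs = frequency_grid(2.0, 16)
        with pytest.raises(ValueError, match="no grid frequency"):
            band_average(np.zeros((16, 4, 2, 2)), freqs, band=(1e-5, 1e-4))

    def test_default_band_has_bins_at_tr2(self):
        freqs = frequency_grid(2.0, 128)
        assert ((freqs >= 0.009) & (freqs <= 0.08)).sum() >= 9

    def test_burn_fraction_drops_initial_points(self):
        freqs = np.array([0.02])
        pi = np.zeros((1, 10, 1, 1))
        pi[0, :5] = 1.0  # early transient
        out = band_average(pi, freqs, band=(0.01, 0.03), burn_fraction=0.5)
        np.testing.assert_allclose(out.values, 0.0)


class TestPipelineConsistency:
    def test_fast_band_path_equals_explicit_path(self, short_series):
        cfg = EKFConfig()
        model = dual_ekf_tvar(short_series, 1, cfg)
        transfer = spectral_transfer(model, cfg.n_freqs)
        explicit = band_average(
            compute_tpdc(transfer),
            transfer.freqs,
            burn_fraction=cfg.burn_fraction,
            channels=short_series.channels,
        )
        fast = estimate_tpdc(short_series, cfg=cfg)
        np.testing.assert_allclose(fast.values, explicit.values, atol=1e-12)

    def test_batch_matches_single_subject(self, coupled_template):
        subjects = [
            simulate_subject(coupled_template, 200, seed=s, subject_id=f"s{s}")
            for s in range(3)
        ]
        batch = estimate_tpdc_batch(
            np.stack([s.data for s in subjects]), tr=2.0, channels=YEO7_CHANNELS
        )
        for s, m in zip(subjects, batch):
            np.testing.assert_allclose(
                m.values, estimate_tpdc(s).values, atol=1e-12
            )

    def test_monotone_in_true_coupling(self):
        """Mean estimated TPDC grows with the generating coupling strength."""
        means = []
        for coupling in (0.0, 0.2, 0.4):
            edges = (("VIS", "SMN"),) if coupling else ()
            tmpl = make_template("custom", coupling, 0.5, edges=edges)
            data = np.stack(
                [simulate_subject(tmpl, 300, seed=s).data for s in range(20)]
            )
            mats = estimate_tpdc_batch(data, tr=2.0, channels=YEO7_CHANNELS)
            means.append(np.mean([m.values[1, 0] for m in mats]))
        assert means[0] < means[1] < means[2]

    def test_transformer_flattens_row_major(self, coupled_template):
        subjects = [simulate_subject(coupled_template, 200, seed=s) for s in range(2)]
        tf = TPDCTransformer(tr=2.0).fit(subjects)
        feats = tf.transform(subjects)
        assert feats.shape == (2, 49)
        ref = estimate_tpdc(subjects[0]).values.ravel()
        np.testing.assert_allclose(feats[0], ref, atol=1e-12)
        names = tf.get_feature_names_out()
        assert names[1] == "SMN->VIS"  # row 0 = target VIS, col 1 = source SMN
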