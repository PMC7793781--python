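import numpy as np
import pytest

from gpdcpipe import connectivity as conn
from gpdcpipe import preprocess as pp
from gpdcpipe import synth


@pytest.fixture(scope="module")
def bivariate_model():
    # x2 driven by x1; used for the closed-form worked example
    return synth.make_var_model([(0, 1, 0.4)], base_diag=0.5, n_channels=2,
                                channel_names=("x1", "x2"))


class TestFitMvar:
    def test_recovers_known_var1(self, bivariate_model):
        x = synth.simulate_var(bivariate_model, 50000, seed=0)
        fit = conn.fit_mvar(x, 1)
        assert np.abs(fit.coeffs[0] - bivariate_model.coeffs[0]).max() < 0.02
        assert np.abs(fit.resid_cov - np.eye(2)).max() < 0.05

    def test_white_noise_coefficients_near_zero(self):
        m = synth.make_var_model([], base_diag=0.0)
        x = synth.simulate_var(m, 50000, seed=1)
        fit = conn.fit_mvar(x, 1)
        assert np.abs(fit.coeffs).max() < 0.05

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            conn.fit_mvar(np.zeros((4, 100)), 12)

    def test_matches_statsmodels_var(self):
        from statsmodels.tsa.api import VAR

        m = synth.make_var_model([(0, 1, 0.3), (2, 3, 0.25)], base_diag=0.4,
                                 order=2)
        x = synth.simulate_var(m, 5000, seed=5)
        fit = conn.fit_mvar(x, 2)
        sm = VAR((x - x.mean(axis=1, keepdims=True)).T).fit(2, trend="n")
        assert np.allclose(np.stack(sm.coefs), fit.coeffs, atol=1e-10)


class TestSbc:
    def test_identity_covariance_closed_form(self):
        fit = conn.MvarFit(order=12, coeffs=np.zeros((12, 4, 4)),
                           resid_cov=np.eye(4), n_obs=1308, sbc=np.nan)
        expected = np.log(1308) / 1308 * 12 * 16  # logdet(I)=0
        assert conn.sbc(fit) == pytest.approx(expected, abs=1e-12)

    def test_doubling_covariance_adds_c_log2(self):
        f1 = conn.MvarFit(12, np.zeros((12, 4, 4)), np.eye(4), 1308, np.nan)
        f2 = conn.MvarFit(12, np.zeros((12, 4, 4)), 2 * np.eye(4), 1308, np.nan)
        assert conn.sbc(f2) - conn.sbc(f1) == pytest.approx(4 * np.log(2))

    def test_known_order_recovered_var3(self):
        m = synth.make_var_model(
            [(0, 1, 0.3, 3), (2, 3, -0.3, 3), (1, 2, 0.25, 2)],
            base_diag=0.4, order=3,
        )
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            x = synth.simulate_var(m, 1320, seed=1000 + seed)
            sbcs = [conn.fit_mvar(x, p).sbc for p in range(1, 13)]
            hits += (int(np.argmin(sbcs)) + 1) == 3
        assert hits >= 0.90 * n_seeds


class TestSelectOrder:
    def test_var2_epochs_give_2(self):
        m = synth.make_var_model([(0, 1, 0.35, 2), (2, 3, 0.3, 2)],
                                 base_diag=0.4, order=2)
        epochs = [synth.simulate_var(m, 1320, seed=k) for k in range(5)]
        assert conn.select_order(epochs, p_max=8) == 2

    def test_white_noise_prefers_smallest_order(self):
        m = synth.make_var_model([], base_diag=0.0)
        epochs = [synth.simulate_var(m, 1320, seed=k) for k in range(5)]
        assert conn.select_order(epochs, p_max=6) == 1

    def test_boundary_hit_warns(self):
        m = synth.make_var_model([(0, 1, 0.35, 2)], base_diag=0.4, order=2)
        epochs = [synth.simulate_var(m, 1320, seed=k) for k in range(3)]
        with pytest.warns(UserWarning, match="boundary"):
            assert conn.select_order(epochs, p_max=1) == 1


class TestTransferMatrix:
    def test_zero_coefficients_give_identity(self):
        fit = conn.MvarFit(2, np.zeros((2, 3, 3)), np.eye(3), 100, np.nan)
        for f in (0.0, 10.0, 50.0):
            assert np.allclose(conn.transfer_matrix(fit, f), np.eye(3))

    def test_worked_example_at_dc(self):
        coeffs = np.array([[[0.5, 0.0], [0.4, 0.3]]])
        fit = conn.MvarFit(1, coeffs, np.eye(2), 100, np.nan)
        expected = np.array([[0.5, 0.0], [-0.4, 0.7]])
        assert np.allclose(conn.transfer_matrix(fit, 0.0), expected)

    def test_continuity_in_frequency(self):
        coeffs = np.array([[[0.5, 0.0], [0.4, 0.3]]])
        fit = conn.MvarFit(1, coeffs, np.eye(2), 100, np.nan)
        a = conn.transfer_matrix(fit, 20.0)
        b = conn.transfer_matrix(fit, 20.0 + 1e-6)
        assert np.abs(a - b).max() < 1e-4


class TestGpdc:
    def test_uncoupled_white_noise_is_diagonal(self):
        fit = conn.MvarFit(1, np.zeros((1, 4, 4)), np.eye(4), 100, np.nan)
        res = conn.gpdc(fit)
        eye = np.eye(4)[:, :, None]
        assert np.allclose(res.values, np.broadcast_to(eye, res.values.shape))

    def test_bivariate_closed_form(self):
        coeffs = np.array([[[0.5, 0.0], [0.4, 0.3]]])
        g = conn.gpdc_from_model(coeffs, np.eye(2), freqs=np.array([0.0]))
        assert g[1, 0, 0] == pytest.approx(0.4 / np.hypot(0.5, 0.4), abs=1e-9)
        assert g[0, 1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_column_normalization_invariant(self, bivariate_model):
        x = synth.simulate_var(bivariate_model, 1320, seed=3)
        res = conn.gpdc(conn.fit_mvar(x, 12))
        colnorm = (res.values**2).sum(axis=0)
        assert np.abs(colnorm - 1.0).max() < 1e-8

    def test_scale_invariance_through_full_fit(self, bivariate_model):
        x = synth.simulate_var(bivariate_model, 1320, seed=4)
        g1 = conn.gpdc(conn.fit_mvar(x, 12)).values
        x2 = x.copy()
        x2[0] *= 10.0
        g2 = conn.gpdc(conn.fit_mvar(x2, 12)).values
        assert np.abs(g1 - g2).max() < 1e-6

    def test_estimated_converges_to_closed_form(self, bivariate_model):
        x = synth.simulate_var(bivariate_model, 50000, seed=6)
        fit = conn.fit_mvar(x, 1)
        est = conn.gpdc(fit).values
        truth = conn.gpdc_from_model(bivariate_model.coeffs,
                                     bivariate_model.noise_cov)
        assert np.abs(est - truth).max() < 0.05


class TestSessionGpdc:
    def test_directionality_recovered(self, clean_epochs):
        res = conn.session_gpdc(clean_epochs)
        names = list(res.channel_names)
        i, j = names.index("TP10"), names.index("AF07")
        assert (res.band_means[i, j] > res.band_means[j, i]).all()

    def test_duplicated_epochs_average_is_idempotent(self, clean_epochs):
        one = pp.CleanEpochSet(
            epochs=clean_epochs.epochs[:1] * 3,
            epoch_start_samples=[0, 0, 0],
            rejection_mask=clean_epochs.rejection_mask,
            kept_fraction=1.0,
            channel_names=clean_epochs.channel_names,
        )
        single = pp.CleanEpochSet(
            epochs=clean_epochs.epochs[:1],
            epoch_start_samples=[0],
            rejection_mask=clean_epochs.rejection_mask,
            kept_fraction=1.0,
            channel_names=clean_epochs.channel_names,
        )
        assert np.allclose(conn.session_gpdc(one).values,
                           conn.session_gpdc(single).values)

    def test_band_means_in_unit_interval(self, clean_epochs):
        res = conn.session_gpdc(clean_epochs)
        assert ((res.band_means >= 0) & (res.band_means <= 1)).all()

    def test_empty_epoch_set_rejected(self, clean_epochs):
        empty = pp.CleanEpochSet(
            epochs=[], epoch_start_samples=[],
            rejection_mask=clean_epochs.rejection_mask, kept_fraction=0.0,
        )
        with pytest.raises(ValueError, match="empty"):
            conn.session_gpdc(empty)
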