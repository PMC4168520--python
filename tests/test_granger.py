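"""VAR fitting, time-domain and spectral Granger causality."""

import numpy as np
import pytest

from conftest import simulate_var1, var1_causality_oracle
from neuromkl.containers import EpochedEEG
from neuromkl.granger import (
    REGION_MAP,
    REGION_ORDER,
    VARModel,
    fit_ar_restricted,
    fit_var_pair,
    gc_features,
    gc_time,
    group_difference_ttest,
    region_average,
    select_order_bic,
    spectral_gc,
)


class TestRegionAverage:
    def _epochs(self, rng):
        channels = ["EOG1", "EOG2"] + [c for r in REGION_ORDER for c in REGION_MAP[r]]
        data = rng.standard_normal((2, len(channels), 200))
        return EpochedEEG(data, 256.0, channels, np.array([0, 1]))

    def test_eighteen_channels_to_five_regions(self, rng):
        out = region_average(self._epochs(rng))
        assert out.channels == list(REGION_ORDER)
        assert out.data.shape == (2, 5, 200)

    def test_mean_of_members(self, rng):
        ep = self._epochs(rng)
        out = region_average(ep)
        idx = [ep.channel_index(c) for c in REGION_MAP["CENTRAL"]]
        np.testing.assert_allclose(out.data[:, 2], ep.data[:, idx].mean(axis=1))

    def test_identical_members_passthrough(self, rng):
        ep = self._epochs(rng)
        cz, pz = ep.channel_index("CZ"), ep.channel_index("PZ")
        ep.data[:, pz] = ep.data[:, cz]
        out = region_average(ep)
        np.testing.assert_allclose(out.data[:, 2], ep.data[:, cz])

    def test_channel_order_irrelevant(self, rng):
        ep = self._epochs(rng)
        perm = np.random.default_rng(1).permutation(ep.n_channels)
        ep_perm = EpochedEEG(ep.data[:, perm], ep.fs,
                             [ep.channels[i] for i in perm], ep.labels)
        np.testing.assert_allclose(
            region_average(ep).data, region_average(ep_perm).data
        )

    def test_missing_channel_named_in_error(self, rng):
        ep = self._epochs(rng)
        ep.channels[ep.channel_index("PZ")] = "XX"
        with pytest.raises(KeyError, match="PZ"):
            region_average(ep)


class TestVARFit:
    def test_known_var1_coefficients_recovered(self):
        x = simulate_var1(0.5, 0.4, 0.5, 5000, seed=12)
        model = fit_var_pair(x[:, 0], x[:, 1], 1)
        truth = np.array([[0.5, 0.4], [0.0, 0.5]])
        assert np.abs(model.coefs[0] - truth).max() < 0.05

    def test_residuals_orthogonal_to_regressors(self):
        x = simulate_var1(0.5, 0.4, 0.5, 2000, seed=13)
        model = fit_var_pair(x[:, 0], x[:, 1], 3)
        X = np.column_stack([x[:, 0] - x[:, 0].mean(), x[:, 1] - x[:, 1].mean()])
        Z = np.column_stack([X[3 - j : len(X) - j] for j in range(1, 4)])
        assert np.abs(Z.T @ model.residuals).max() / len(Z) < 1e-8

    def test_independent_noise_gives_equal_variances(self):
        g = np.random.default_rng(14)
        x1, x2 = g.standard_normal(8000), g.standard_normal(8000)
        full = fit_var_pair(x1, x2, 3)
        restricted = fit_ar_restricted(x1, 3)
        assert full.sigma[0, 0] == pytest.approx(restricted.sigma[0, 0], rel=0.01)

    def test_short_signal_raises(self):
        with pytest.raises(ValueError, match="too short"):
            fit_var_pair(np.ones(50), np.ones(50), 10)

    def test_statsmodels_cross_check(self):
        # independent reference fit of the same lag regression
        from statsmodels.tsa.api import VAR as smVAR

        x = simulate_var1(0.5, 0.4, 0.5, 3000, seed=15)
        mine = fit_var_pair(x[:, 0], x[:, 1], 2)
        ref = smVAR(x - x.mean(axis=0)).fit(2, trend="n")
        np.testing.assert_allclose(mine.coefs, ref.coefs, atol=1e-8)


class TestTimeDomainGC:
    def test_independent_pair_near_zero(self):
        g = np.random.default_rng(16)
        F = gc_time(g.standard_normal(10000), g.standard_normal(10000), 5)
        assert F < 0.01

    def test_coupled_var1_matches_population_oracle(self):
        x = simulate_var1(0.5, 0.4, 0.5, 20000, seed=17)
        F21 = gc_time(x[:, 0], x[:, 1], 10)
        F12 = gc_time(x[:, 1], x[:, 0], 10)
        oracle = var1_causality_oracle(0.5, 0.4, 0.5, 10)
        assert abs(F21 - oracle) < 0.02
        assert F12 < 0.01

    def test_asymmetry_of_directions(self):
        x = simulate_var1(0.5, 0.4, 0.5, 20000, seed=17)
        assert gc_time(x[:, 0], x[:, 1], 10) > 10 * gc_time(x[:, 1], x[:, 0], 10)


class TestSpectralGC:
    def test_uncoupled_identically_zero(self):
        model = VARModel(
            order=1,
            coefs=np.array([[[0.5, 0.0], [0.0, 0.3]]]),
            sigma=np.eye(2),
            residuals=np.zeros((10, 2)),
        )
        I = spectral_gc(model, np.arange(0, 128.5, 0.5), 256.0)
        assert np.abs(I).max() <= 1e-10

    def test_theta_coupled_peak_in_band(self):
        from neuromkl.synthdata import theta_coupled_spec

        spec = theta_coupled_spec(0.4)
        A = spec.var_coefs()
        pair = np.ix_([2, 0], [2, 0])  # target CENTRAL, source FCENTRAL
        model = VARModel(
            order=2,
            coefs=np.stack([A[0][pair], A[1][pair]]),
            sigma=np.eye(2),
            residuals=np.zeros((10, 2)),
        )
        freqs = np.arange(0.0, 128.25, 0.5)
        I = spectral_gc(model, freqs, 256.0)
        assert 4.0 <= freqs[np.argmax(I)] <= 8.0
        assert I.min() >= -1e-10

    def test_frequency_mean_matches_time_domain(self):
        x = simulate_var1(0.5, 0.4, 0.5, 20000, seed=18)
        p = 10
        model = fit_var_pair(x[:, 0], x[:, 1], p)
        freqs = np.arange(0.0, 0.5, 0.001)
        I = spectral_gc(model, freqs, 1.0)
        F = gc_time(x[:, 0], x[:, 1], p)
        assert abs(I.mean() - F) / F < 0.15

    def test_unstable_var_raises(self):
        model = VARModel(
            order=1,
            coefs=np.array([[[1.05, 0.0], [0.0, 0.5]]]),
            sigma=np.eye(2),
            residuals=np.zeros((10, 2)),
        )
        with pytest.raises(ValueError, match="unstable"):
            spectral_gc(model, np.array([1.0]), 256.0)


class TestOrderSelection:
    def test_bic_finds_low_order_for_var1(self):
        x = simulate_var1(0.5, 0.4, 0.5, 4000, seed=19)
        assert select_order_bic(x[:, 0], x[:, 1], 10) <= 3


class TestGCFeatures:
    def test_twenty_ordered_pairs(self):
        from neuromkl.synthdata import default_control_spec, gen_coupled_var

        eeg = gen_coupled_var(default_control_spec(), 2, n_samples=600, seed=20)
        feats = gc_features(eeg, p=3)
        assert feats.values.shape == (2, 20)
        assert feats.columns[0] == "FCENTRAL->LSM"

    def test_identical_trials_identical_rows(self):
        from neuromkl.synthdata import default_control_spec, gen_coupled_var

        eeg = gen_coupled_var(default_control_spec(), 1, n_samples=600, seed=21)
        eeg2 = EpochedEEG(
            np.repeat(eeg.data, 2, axis=0), eeg.fs, eeg.channels, np.array([0, 1])
        )
        feats = gc_features(eeg2, p=3)
        np.testing.assert_array_equal(feats.values[0], feats.values[1])

    def test_patient_coupling_reduction_detected(self):
        from neuromkl.synthdata import (
            default_control_spec,
            default_patient_spec,
            gen_coupled_var,
        )

        ctrl = gc_features(
            gen_coupled_var(default_control_spec(), 8, n_samples=1024, seed=22), p=5
        )
        pat = gc_features(
            gen_coupled_var(default_patient_spec(), 8, n_samples=1024, seed=23), p=5
        )
        i = ctrl.columns.index("FCENTRAL->CENTRAL")
        ratio = pat.values[:, i].mean() / ctrl.values[:, i].mean()
        assert ratio < 0.5

    def test_group_ttest_reports_direction(self):
        from neuromkl.containers import FeatureMatrix

        g = np.random.default_rng(24)
        vals = np.vstack([g.normal(1.0, 0.1, (10, 4)), g.normal(0.3, 0.1, (10, 4))])
        feats = FeatureMatrix(vals, list("abcd"), np.array(["c"] * 10 + ["p"] * 10))
        t, pval = group_difference_ttest(feats, "c", "p")
        assert t > 0 and pval < 1e-6
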