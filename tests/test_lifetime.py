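"""Reconvolution forward model and multi-exponential decay fitting."""

import numpy as np
import pytest

from flimcoloc import (
    DecayHistogram,
    DecayModel,
    IRF,
    SyntheticDecaySpec,
    bin_photons,
    fit_decay,
    fit_field,
    mean_lifetime,
    model_decay,
    sample_arrival_times,
    simulate_decay,
)
from flimcoloc.errors import (
    ConfigError,
    IdentifiabilityWarning,
    InsufficientPhotonsError,
    RegridRequiredError,
    UndefinedMeanError,
)


class TestModelDecay:
    def test_delta_irf_proportional_to_exponential(self, mono_model, delta_irf,
                                                   edges_256):
        expected = model_decay(mono_model, delta_irf, edges_256, wrap=False)
        centers = 0.5 * (edges_256[:-1] + edges_256[1:])
        ratio = expected / np.exp(-centers / 2.0)
        assert np.ptp(ratio) / ratio.mean() < 1e-6

    def test_baseline_only_model_is_constant(self, delta_irf, edges_256):
        model = DecayModel(components=[(0.0, 1.0)], baseline=3.5)
        expected = model_decay(model, delta_irf, edges_256)
        assert np.allclose(expected, 3.5)

    def test_matches_oversampled_brute_force_convolution(self, edges_256):
        """Two-component reconvolution vs direct convolution at x64."""
        model = DecayModel(components=[(0.7, 0.8), (0.3, 3.2)])
        irf = IRF(kind="gaussian", center_ns=2.0, fwhm_ns=0.4)
        got = model_decay(model, irf, edges_256, oversample=16)

        # independent oracle: direct (non-FFT) circular convolution, x64 grid,
        # decay density integrated exactly over each fine cell
        window, n_bins, m = 25.0, 256, 64
        n = n_bins * m
        dt = window / n
        t = np.arange(n) * dt  # kernel at grid points: center-to-center lags
        lefts = np.arange(n) * dt
        dens = np.zeros(n)
        for a, tau in model.components:
            wfac = 1.0 / (1.0 - np.exp(-window / tau))
            dens += a * wfac * tau / dt * (
                np.exp(-lefts / tau) - np.exp(-(lefts + dt) / tau)
            )
        sig = irf.fwhm_ns / (2 * np.sqrt(2 * np.log(2)))
        kern = np.zeros(n)
        for k in (-1, 0, 1):
            kern += np.exp(-0.5 * ((t - 2.0 + k * window) / sig) ** 2)
        kern /= kern.sum()
        conv = np.array(
            [np.sum(dens * np.roll(kern[::-1], i + 1)) for i in range(n)]
        )
        oracle = conv.reshape(n_bins, m).sum(axis=1) * dt

        rel = np.abs(got - oracle) / oracle.max()
        assert rel.max() < 1e-3

    def test_wrap_term_adds_pre_rise_signal(self, mono_model, edges_256):
        irf = IRF(kind="gaussian", center_ns=3.0, fwhm_ns=0.3)
        wrapped = model_decay(mono_model, irf, edges_256, wrap=True)
        unwrapped = model_decay(mono_model, irf, edges_256, wrap=False)
        # before the pulse, only the previous-pulse tail contributes
        assert wrapped[5] > unwrapped[5]
        assert np.all(wrapped >= unwrapped - 1e-12)

    def test_measured_irf_window_mismatch_raises(self, mono_model):
        irf_hist = bin_photons([1.0, 1.1, 1.2], n_bins=64, window_ns=12.5)
        irf = IRF(kind="measured", histogram=irf_hist)
        with pytest.raises(RegridRequiredError):
            model_decay(mono_model, irf, np.linspace(0, 25, 65))

    def test_measured_irf_regrids_by_interpolation(self, mono_model):
        # a narrow measured pulse behaves like its parametric counterpart
        rng = np.random.default_rng(5)
        pulse = rng.normal(1.0, 0.1274, size=200_000) % 25.0
        irf_m = IRF(kind="measured", histogram=bin_photons(pulse, 512, 25.0))
        irf_g = IRF(kind="gaussian", center_ns=1.0, fwhm_ns=0.3)
        edges = np.linspace(0, 25, 129)
        a = model_decay(mono_model, irf_m, edges)
        b = model_decay(mono_model, irf_g, edges)
        assert np.abs(a - b).max() / b.max() < 0.02


class TestMeanLifetime:
    def test_single_component_identity(self):
        model = DecayModel(components=[(0.8, 2.45)])
        assert mean_lifetime(model, "amplitude") == pytest.approx(2.45)
        assert mean_lifetime(model, "intensity") == pytest.approx(2.45)

    def test_amplitude_weighting_is_arithmetic_mean(self):
        model = DecayModel(components=[(1.0, 1.0), (1.0, 3.0)])
        assert mean_lifetime(model, "amplitude") == pytest.approx(2.0)

    def test_intensity_weighting_hand_evaluated(self):
        model = DecayModel(components=[(1.0, 1.0), (1.0, 3.0)])
        assert mean_lifetime(model, "intensity") == pytest.approx(2.5)

    def test_all_zero_amplitudes_undefined(self):
        model = DecayModel(components=[(0.0, 2.0)], baseline=1.0)
        with pytest.raises(UndefinedMeanError):
            mean_lifetime(model)


class TestFitDecay:
    def test_noiseless_self_consistency(self, delta_irf, edges_256):
        truth = DecayModel(components=[(100.0, 2.0)])
        counts = model_decay(truth, delta_irf, edges_256)
        hist = DecayHistogram(edges_256, counts)
        fit = fit_decay(hist, delta_irf, min_photons=None, fit_baseline=False)
        assert fit.tau_mean_ns == pytest.approx(2.0, abs=1e-3)

    def test_noisy_mono_exponential_recovery(self, gaussian_irf):
        """25 Poisson replicates at the donor lifetime recover the truth
        within 0.05 ns in the mean."""
        truth = 2.45
        spec = SyntheticDecaySpec(
            model=DecayModel(components=[(1.0, truth)]),
            irf=gaussian_irf,
            n_photons=10_000,
            n_replicates=25,
            seed=20,
        )
        taus = [fit_decay(h, gaussian_irf).tau_mean_ns for h in simulate_decay(spec)]
        assert np.mean(taus) == pytest.approx(truth, abs=0.05)

    def test_two_component_recovery_at_high_counts(self, gaussian_irf):
        spec = SyntheticDecaySpec(
            model=DecayModel(components=[(0.5, 1.0), (0.5, 3.0)]),
            irf=gaussian_irf,
            n_photons=100_000,
            seed=13,
        )
        fit = fit_decay(simulate_decay(spec)[0], gaussian_irf, n_components=2)
        taus = fit.model.taus
        assert abs(taus[0] - 1.0) / 1.0 < 0.05
        assert abs(taus[1] - 3.0) / 3.0 < 0.05

    def test_below_photon_threshold_raises(self, delta_irf):
        hist = bin_photons(np.linspace(0.1, 10, 100), n_bins=64)
        with pytest.raises(InsufficientPhotonsError):
            fit_decay(hist, delta_irf, min_photons=500)

    def test_non_finite_counts_rejected(self, delta_irf, edges_256):
        counts = np.full(256, 10.0)
        counts[3] = np.nan
        with pytest.raises(Exception):
            fit_decay(DecayHistogram(edges_256, counts), delta_irf)

    def test_scale_equivariance_weighted_ls(self, delta_irf, edges_256):
        rng = np.random.default_rng(4)
        truth = DecayModel(components=[(50.0, 2.2)])
        lam = model_decay(truth, delta_irf, edges_256)
        counts = rng.poisson(lam) + 1  # keep counts >= 1 so weights scale
        h1 = DecayHistogram(edges_256, counts)
        h2 = DecayHistogram(edges_256, counts * 7)
        f1 = fit_decay(h1, delta_irf, objective="weighted-ls", min_photons=None)
        f2 = fit_decay(h2, delta_irf, objective="weighted-ls", min_photons=None)
        assert f1.model.taus[0] == pytest.approx(f2.model.taus[0], rel=1e-4)

    def test_close_lifetimes_flag_identifiability(self, gaussian_irf, edges_256):
        # noiseless close-pair data: the optimum itself has tau2/tau1 < 1.5
        truth = DecayModel(components=[(300.0, 2.0), (300.0, 2.4)])
        counts = model_decay(truth, gaussian_irf, edges_256)
        hist = DecayHistogram(edges_256, counts)
        with pytest.warns(IdentifiabilityWarning):
            fit = fit_decay(hist, gaussian_irf, n_components=2, min_photons=None)
        assert fit.identifiability_flag

    def test_parameter_recovery_unbiased_with_coverage(self, gaussian_irf):
        """Over 100 seeded Poisson simulations at 10k photons the
        mono-exponential estimate is unbiased within 1% and its empirical
        95% interval covers the truth in >= 90 runs."""
        truth = 2.45
        spec = SyntheticDecaySpec(
            model=DecayModel(components=[(1.0, truth)]),
            irf=gaussian_irf,
            n_photons=10_000,
            n_replicates=100,
            seed=77,
        )
        taus = np.array(
            [fit_decay(h, gaussian_irf).tau_mean_ns for h in simulate_decay(spec)]
        )
        assert abs(taus.mean() - truth) / truth < 0.01
        half_width = 1.96 * taus.std(ddof=1)
        covered = np.sum(np.abs(taus - truth) <= half_width)
        assert covered >= 90


class TestFitField:
    def test_uniform_field_is_flat(self, delta_irf):
        rng = np.random.default_rng(3)
        model = DecayModel(components=[(1.0, 2.0)])
        field = {}
        for y in range(3):
            for x in range(3):
                field[(y, x)] = sample_arrival_times(
                    model, delta_irf, 5_000, 25.0, rng
                )
        img = fit_field(field, delta_irf, n_bins=64, min_photons=500)
        taus = img.tau_mean_ns[img.fitted]
        assert taus.std() / taus.mean() < 0.03

    def test_subthreshold_stripe_flagged_absent(self, delta_irf):
        rng = np.random.default_rng(6)
        model = DecayModel(components=[(1.0, 2.0)])
        field = {}
        budgets = {}
        for y in range(2):
            for x in range(4):
                n = 100 if x == 1 else 2_000  # stripe below threshold
                budgets[(y, x)] = n
                field[(y, x)] = sample_arrival_times(model, delta_irf, n, 25.0, rng)
        img = fit_field(field, delta_irf, n_bins=64, min_photons=500)
        expected_absent = sum(1 for n in budgets.values() if n < 500)
        assert np.sum(~img.fitted) == expected_absent
        assert np.all(np.isnan(img.tau_mean_ns[~img.fitted]))

    def test_empty_field(self, delta_irf):
        img = fit_field({}, delta_irf)
        assert img.tau_mean_ns.size == 0
        assert img.fits == {}


class TestDecayModelValidation:
    def test_components_sorted_ascending(self):
        model = DecayModel(components=[(0.3, 3.0), (0.7, 1.0)])
        assert model.taus.tolist() == [1.0, 3.0]

    def test_too_many_components(self):
        with pytest.raises(ConfigError):
            DecayModel(components=[(1, 1), (1, 2), (1, 3), (1, 4)])

    def test_non_positive_lifetime(self):
        with pytest.raises(ConfigError):
            DecayModel(components=[(1.0, 0.0)])
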