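"""Noise estimation, Rician-likelihood fitting, amplitude-modulation
correction."""

import numpy as np
import pytest

from megre import estimation as E
from megre.experiments import mc_voxel_curves
from megre.phantom_sim import build_default_phantom, simulate_series
from megre.protocol import train_from_params
from megre.signal_model import (
    AcquisitionParams,
    ParityModulation,
    TissueParams,
    apply_parity_modulation,
    noiseless_signal,
)


class TestNoiseEstimation:
    def test_recovers_sigma_from_rayleigh_background(self, rng):
        data = np.abs(
            rng.normal(0, 1.0, (1200, 10)) + 1j * rng.normal(0, 1.0, (1200, 10))
        )
        est = E.estimate_noise_background(data[:, None, :], np.ones((1200, 1), bool))
        assert 0.95 <= est.sigma <= 1.05
        assert est.n_voxels == 1200

    def test_zero_background(self):
        est = E.estimate_noise_background(
            np.zeros((10, 10, 4)), np.ones((10, 10), bool)
        )
        assert est.sigma == 0.0

    def test_methods_agree(self, rng):
        data = np.abs(
            rng.normal(0, 0.7, (1200, 1, 8)) + 1j * rng.normal(0, 0.7, (1200, 1, 8))
        )
        mask = np.ones((1200, 1), bool)
        a = E.estimate_noise_background(data, mask, method="rayleigh_second_moment")
        b = E.estimate_noise_background(data, mask, method="rayleigh_mean")
        assert a.sigma == pytest.approx(b.sigma, rel=0.03)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            E.estimate_noise_background(
                np.ones((4, 4, 2)), np.zeros((4, 4), bool)
            )


class TestFitSingle:
    def test_exact_recovery_on_noiseless_data(self, mono_train, roi3_tissue):
        acq = AcquisitionParams(75.0, 1200.0)
        mags = np.abs(noiseless_signal(roi3_tissue, acq, mono_train))
        fit = E.fit_t2star_rician(mono_train, mags, sigma=0.0)
        assert fit.t2_star == pytest.approx(69.0, abs=1e-5)
        assert fit.converged

    def test_scale_equivariance(self, mono_train, roi3_tissue):
        acq = AcquisitionParams(75.0, 1200.0, sigma=0.01)
        mags = mc_voxel_curves(roi3_tissue, acq, mono_train, 1, seed=3)[0]
        f1 = E.fit_t2star_rician(mono_train, mags, 0.01)
        f2 = E.fit_t2star_rician(mono_train, 10.0 * mags, 0.1)
        assert f2.t2_star == pytest.approx(f1.t2_star, rel=1e-5)
        assert f2.amplitude == pytest.approx(10.0 * f1.amplitude, rel=1e-5)

    def test_rician_matches_gaussian_at_high_snr(self, roi3_tissue):
        """Above per-echo SNR 20 the Rician likelihood degenerates to least
        squares within 0.1% in T2*."""
        train = train_from_params(3.84, 2.92, "monopolar", te_max=30.0)
        sigma = 0.729 / 50.0  # min per-echo SNR ~ 34
        acq = AcquisitionParams(75.0, 1200.0, sigma=sigma)
        mags = mc_voxel_curves(roi3_tissue, acq, train, 1, seed=9)[0]
        fr = E.fit_t2star_rician(train, mags, sigma)
        fg = E.fit_t2star_rician(
            train, mags, sigma, E.FitOptions(likelihood="gaussian")
        )
        assert fr.t2_star == pytest.approx(fg.t2_star, rel=1e-3)

    def test_noise_floor_bias_removed_at_moderate_snr(self, mono_train, roi3_tissue):
        """At first-echo SNR 5 the magnitude noise floor makes least squares
        overestimate T2*; the Rician likelihood removes most of that bias."""
        acq = AcquisitionParams(75.0, 1200.0, sigma=0.729 / 5.0)
        curves = mc_voxel_curves(roi3_tissue, acq, mono_train, 1200, seed=21)
        t2r, _, _ = E.fit_t2star_batch(mono_train, curves, acq.sigma)
        t2g, _, _ = E.fit_t2star_batch(
            mono_train, curves, acq.sigma, E.FitOptions(likelihood="gaussian")
        )
        assert abs(t2r.mean() - 69.0) < abs(t2g.mean() - 69.0)
        assert t2g.mean() > 69.0  # the classic overestimation direction

    def test_too_few_echoes_rejected(self, roi3_tissue):
        train = train_from_params(3.84, 2.92, "monopolar", n_e=2)
        with pytest.raises(ValueError):
            E.fit_t2star_rician(train, np.ones(2), 0.1)

    def test_negative_sigma_rejected(self, mono_train):
        with pytest.raises(ValueError):
            E.fit_t2star_rician(mono_train, np.ones(32), -1.0)


class TestFitMap:
    def test_noiseless_phantom_recovers_ground_truth(self, bip_train):
        phantom = build_default_phantom((96, 96))
        acq = AcquisitionParams(75.0, 1200.0, sigma=0.0)
        series = simulate_series(phantom, acq, bip_train, seed=0)
        t2_map, amp_map, diag = E.fit_t2star_map(series)
        for rid, tissue in phantom.regions.items():
            vals = t2_map[phantom.region_mask(rid)]
            np.testing.assert_allclose(vals, tissue.t2_star, atol=1e-5)
        assert np.all(np.isnan(t2_map[phantom.label_map == 0]))
        assert diag["n_converged"] == diag["n_fit"]


@pytest.fixture(scope="module")
def bip14():
    return train_from_params(3.84, 1.47, "bipolar", n_e=14)


class TestAMCorrection:
    def test_unmodulated_noiseless_is_fixed_point(self, bip14, roi3_tissue):
        acq = AcquisitionParams(75.0, 1200.0)
        mags = np.abs(noiseless_signal(roi3_tissue, acq, bip14))
        res = E.correct_amplitude_modulation(mags, bip14, sigma=0.0)
        assert res.modulation.g_odd == pytest.approx(1.0, abs=1e-6)
        assert res.modulation.g_even == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(res.corrected, mags, rtol=1e-6)
        assert res.converged

    def test_monopolar_refused(self, roi3_tissue):
        mono = train_from_params(3.84, 2.92, "monopolar", n_e=14)
        with pytest.raises(E.AMNotApplicableError):
            E.correct_amplitude_modulation(np.ones(14), mono, sigma=0.1)

    def test_even_strided_bipolar_refused(self, bip_train, roi3_tissue):
        """An even stride on a bipolar train leaves constant parity, so the
        modulation becomes an unidentifiable uniform scale."""
        strided = bip_train.subset(np.arange(0, 64, 2))
        with pytest.raises(E.AMNotApplicableError):
            E.correct_amplitude_modulation(np.ones(32), strided, sigma=0.1)

    def test_injected_modulation_recovered(self, bip_train, roi3_tissue):
        ratio = 1.05 / 0.95
        mod = ParityModulation.from_ratio(ratio)
        acq = AcquisitionParams(75.0, 1200.0, sigma=0.729 / 50.0)
        curves = mc_voxel_curves(roi3_tissue, acq, bip_train, 300, seed=17, mod=mod)
        res = E.correct_amplitude_modulation(
            curves[:, None, :], bip_train, acq.sigma, mode="pooled"
        )
        recovered = float(np.atleast_1d(res.modulation.ratio)[0])
        assert recovered == pytest.approx(ratio, abs=1e-2)
        # correction shrinks the T2* bias left by the modulation
        t2_pre, _, _ = E.fit_t2star_batch(bip_train, curves, acq.sigma)
        t2_post = res.fit["t2_star"][np.isfinite(res.fit["t2_star"])]
        assert abs(t2_post.mean() - 69.0) < abs(t2_pre.mean() - 69.0)

    def test_voxel_mode_factor_maps(self, bip14, roi3_tissue):
        mod = ParityModulation.from_ratio(1.08)
        acq = AcquisitionParams(75.0, 1200.0, sigma=0.729 / 100.0)
        curves = mc_voxel_curves(roi3_tissue, acq, bip14, 50, seed=23, mod=mod)
        res = E.correct_amplitude_modulation(
            curves[:, None, :], bip14, acq.sigma, mode="voxel"
        )
        ratios = np.asarray(res.modulation.ratio)
        assert ratios.shape == (50,)
        assert np.median(ratios) == pytest.approx(1.08, abs=0.02)
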