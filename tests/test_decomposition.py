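"""Five-band decomposition: seeding, recovery, pinning and replicates."""

import numpy as np
import pytest

from carbscreen import (Band, BandShape, FitConfig, FiveBandModel, RamanSpectrum,
                        fit_five_bands, initial_guess, maturity_point,
                        maturity_series, params_from_fit, replicate_params,
                        spectrum_from_bands)

FREE = FitConfig(pin_d1=False)


def _noiseless(m):
    pt = maturity_point(m)
    return spectrum_from_bands(pt.true_bands, noise_sd=0.0), pt


class TestInitialGuess:
    def test_centers_near_generating_truth(self):
        s, pt = _noiseless(0.7)
        guess = {b.name: b for b in initial_guess(s)}
        truth = {b.name: b for b in pt.true_bands}
        for name in ("G", "D1"):
            assert abs(guess[name].center - truth[name].center) <= 20.0

    def test_flat_spectrum_rejected(self, grid):
        with pytest.raises(ValueError, match="discernible"):
            initial_guess(RamanSpectrum(grid, np.zeros_like(grid)))

    def test_minor_bands_seeded_small(self):
        s, _ = _noiseless(0.5)
        guess = {b.name: b for b in initial_guess(s)}
        assert guess["D3"].height <= 0.11 * guess["D1"].height + 1e-12


class TestFreeFitRecovery:
    def test_noiseless_exact_recovery(self):
        """Every center within 0.5 cm^-1, heights and widths within 1%."""
        s, pt = _noiseless(0.5)
        res = fit_five_bands(s, FREE)
        assert res.converged
        truth = {b.name: b for b in pt.true_bands}
        for name, b in res.bands.items():
            t = truth[name]
            assert abs(b.center - t.center) <= 0.5
            assert b.height == pytest.approx(t.height, rel=0.01)
            assert b.fwhm == pytest.approx(t.fwhm, rel=0.01)

    def test_noisy_r1_within_5_percent(self):
        pt = maturity_point(0.6)
        s = spectrum_from_bands(pt.true_bands, noise_sd=0.02, seed=42)
        p = params_from_fit(fit_five_bands(s, FREE))
        assert p.r1 == pytest.approx(pt.true_params.r1, rel=0.05)

    def test_recovery_batch_median_errors(self):
        """Median |dR1|/R1 <= 3% and |dFWHM-D1|/FWHM-D1 <= 5% at 2% noise."""
        series = maturity_series(30, seed=123, noise_sd=0.02)
        r1_err, fw_err = [], []
        for s, pt in series:
            p = params_from_fit(fit_five_bands(s, FREE))
            t = pt.true_params
            r1_err.append(abs(p.r1 - t.r1) / t.r1)
            fw_err.append(abs(p.fwhm_d1 - t.fwhm_d1) / t.fwhm_d1)
        assert np.median(r1_err) <= 0.03
        assert np.median(fw_err) <= 0.05


class TestPinnedFit:
    def test_pinned_r1_within_5pct_when_d3d4_small(self):
        """When D3+D4 contribute < 5% of the D1 height under the D1 peak,
        the pinned fit reproduces the generating height ratio within 5%."""
        from carbscreen.bands import evaluate_bands
        checked = 0
        for m in (0.25, 0.5, 0.75, 1.0):
            pt = maturity_point(m)
            by = {b.name: b for b in pt.true_bands}
            under = float(evaluate_bands([by["D3"], by["D4"]],
                                         np.array([by["D1"].center]))[0])
            if under / by["D1"].height >= 0.05:
                continue
            s = spectrum_from_bands(pt.true_bands, noise_sd=0.0)
            p = params_from_fit(fit_five_bands(s, FitConfig(pin_d1=True)))
            assert p.r1 == pytest.approx(pt.true_params.r1, rel=0.05)
            checked += 1
        assert checked >= 3

    def test_g_only_spectrum_gives_tiny_d_heights(self):
        g = Band("G", BandShape.LORENTZIAN, 1580.0, 1.0, 60.0)
        s = spectrum_from_bands([g], noise_sd=0.0)
        res = fit_five_bands(s)  # pinned default
        assert res.converged
        assert res.bands["D1"].height <= 0.05 * res.bands["G"].height

    def test_results_record_pinning(self):
        s, _ = _noiseless(0.5)
        assert fit_five_bands(s).d1_pinned
        assert not fit_five_bands(s, FREE).d1_pinned


class TestFitDiagnostics:
    def test_residual_never_worse_than_initial_guess(self):
        for s, _ in maturity_series(6, seed=5, noise_sd=0.05):
            res = fit_five_bands(s)
            assert res.residual_rms <= res.initial_rms + 1e-12

    def test_eval_cap_reported_not_raised(self):
        s, _ = _noiseless(0.3)
        res = fit_five_bands(s, FitConfig(max_eval=2))
        assert not res.converged

    def test_summary_mentions_all_bands(self):
        s, _ = _noiseless(0.5)
        text = fit_five_bands(s).summary()
        for name in ("G", "D1", "D2", "D3", "D4", "R1"):
            assert name in text

    def test_unvalidated_laser_refused(self):
        s, _ = _noiseless(0.5)
        odd = RamanSpectrum(s.wavenumber, s.intensity, laser_nm=785.0)
        with pytest.raises(ValueError, match="laser"):
            FiveBandModel(odd)
        FiveBandModel(odd, FitConfig(allow_any_laser=True))  # override ok


class TestParamsFromFit:
    def test_ratio_and_widths_pass_through(self):
        s, _ = _noiseless(0.5)
        res = fit_five_bands(s, FREE)
        bands = dict(res.bands)
        bands["D1"] = bands["D1"].with_(height=1.4, fwhm=59.0)
        bands["G"] = bands["G"].with_(height=1.0)
        import dataclasses
        res2 = dataclasses.replace(res, bands=bands)
        p = params_from_fit(res2)
        assert p.r1 == pytest.approx(1.4)
        assert p.fwhm_d1 == pytest.approx(59.0)

    def test_non_converged_fit_rejected(self):
        s, _ = _noiseless(0.5)
        res = fit_five_bands(s, FitConfig(max_eval=2))
        with pytest.raises(ValueError, match="converged"):
            params_from_fit(res)


class TestReplicates:
    def test_seeded_replicates_bracket_truth(self):
        pt = maturity_point(0.5)
        spectra = [spectrum_from_bands(pt.true_bands, noise_sd=0.02, seed=s)
                   for s in range(5)]
        p = replicate_params(spectra, FREE)
        assert p.r1_sd is not None and p.r1_sd >= 0
        assert abs(p.r1 - pt.true_params.r1) <= max(2 * p.r1_sd, 0.02 * pt.true_params.r1)

    def test_identical_replicates_zero_sd(self):
        s, _ = _noiseless(0.5)
        p = replicate_params([s, s], FREE)
        assert p.r1_sd == pytest.approx(0.0, abs=1e-9)

    def test_single_replicate_rejected(self):
        s, _ = _noiseless(0.5)
        with pytest.raises(ValueError, match=">= 2"):
            replicate_params([s])
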