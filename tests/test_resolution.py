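import numpy as np
import pandas as pd
import pytest

from petqc import listmode
from petqc.errors import DomainError, InsufficientDataError
from petqc.listmode import C_MM_PER_PS, sample_coincidences, trues_only_preset
from petqc.presets import tof_fwhm_at
from petqc.resolution import (estimate_energy_resolution,
                              estimate_tof_resolution, histogram_fwhm,
                              tof_error)

GAUSS_FWHM = 2 * np.sqrt(2 * np.log(2))


def _event(ax, ay, az, bx, by, bz, dt):
    return pd.DataFrame({
        "ax_mm": [ax], "ay_mm": [ay], "az_mm": [az],
        "bx_mm": [bx], "by_mm": [by], "bz_mm": [bz],
        "delta_t_ps": [dt], "energy_a_kev": [511.0], "energy_b_kev": [511.0],
        "event_class": np.zeros(1, dtype=np.uint8),
    })


class TestTofError:
    def test_source_on_midpoint_gives_zero(self):
        # LOR along y through (45, 0): midpoint is the nearest point
        ev = _event(45.0, 447.7, 0.0, 45.0, -447.7, 0.0, dt=0.0)
        assert tof_error(ev, 45.0)[0] == pytest.approx(0.0, abs=1e-9)

    def test_offset_annihilation_oracle(self):
        """Nearest point 45 mm from the midpoint along the LOR, measured
        delta_t = 0: the TOF error is the full 2*45/c ~ 300 ps."""
        # LOR along x through y=0; source at (45, 0) -> nearest point (45, 0)
        ev = _event(450.0, 0.0, 0.0, -450.0, 0.0, 0.0, dt=0.0)
        # expected dt = (|P-A| - |P-B|)/c = (405 - 495)/c = -300.2 ps
        err = tof_error(ev, 45.0)[0]
        assert err == pytest.approx(2 * 45.0 / C_MM_PER_PS, abs=0.1)
        assert err == pytest.approx(300.2, abs=0.2)

    def test_additivity(self):
        base = _event(450.0, 0.0, 0.0, -450.0, 0.0, 0.0, dt=0.0)
        expected_dt = -2 * 45.0 / C_MM_PER_PS
        shifted = _event(450.0, 0.0, 0.0, -450.0, 0.0, 0.0,
                         dt=expected_dt + 100.0)
        assert tof_error(shifted, 45.0)[0] == pytest.approx(100.0, abs=1e-6)

    def test_degenerate_lor_rejected(self):
        ev = _event(450.0, 0.0, 0.0, 450.0, 0.0, 0.0, dt=0.0)
        with pytest.raises(DomainError):
            tof_error(ev, 45.0)


class TestHistogramFwhm:
    def test_gaussian_oracle(self):
        rng = np.random.default_rng(1)
        sigma = 100.0
        x = rng.normal(0.0, sigma, 1_000_000)
        edges = np.arange(-600, 601, 10.0)
        counts, edges = np.histogram(x, bins=edges)
        assert histogram_fwhm(counts, edges) == pytest.approx(
            GAUSS_FWHM * sigma, abs=2.0)

    def test_shift_invariance_and_linear_scaling(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 50.0, 400_000)
        def fwhm(samples, width):
            lo, hi = samples.min() - width, samples.max() + width
            counts, edges = np.histogram(
                samples, bins=np.arange(lo, hi, width))
            return histogram_fwhm(counts, edges)
        f0 = fwhm(x, 5.0)
        assert fwhm(x + 1234.5, 5.0) == pytest.approx(f0, rel=0.01)
        assert fwhm(3.0 * x, 15.0) == pytest.approx(3 * f0, rel=0.01)

    def test_delta_distribution_bounded_by_bin_width(self):
        counts = np.array([0, 0, 500, 0, 0])
        edges = np.arange(6) * 10.0
        assert histogram_fwhm(counts, edges) <= 10.0


class TestTofResolution:
    def test_recovers_preset_timing_blur(self, lm_trues, vereos):
        res = estimate_tof_resolution(lm_trues)
        assert res.fwhm == pytest.approx(326.0, rel=0.015)
        assert res.n_events_used == lm_trues.n_events
        assert res.gate_pass_fraction == 1.0
        assert res.counts.sum() == res.n_events_used

    def test_out_of_gate_events_do_not_narrow_estimate(self, lm_mixed):
        gated = estimate_tof_resolution(lm_mixed, distance_gate_mm=20.0)
        everything = estimate_tof_resolution(lm_mixed, distance_gate_mm=1e9)
        assert everything.fwhm >= gated.fwhm - 2.0

    def test_insufficient_events(self, vereos, scatter_phantom):
        pure = trues_only_preset(vereos)
        lm = sample_coincidences(pure, scatter_phantom, 2.0, 500, seed=4)
        with pytest.raises(InsufficientDataError, match="500"):
            estimate_tof_resolution(lm)

    def test_rate_dependent_degradation_recovered(self, ingenuity,
                                                  scatter_phantom):
        """Across the analog camera's routine range the estimator must
        track the preset's rate-dependent anchors within 1.5 % and be
        non-decreasing (generator-estimator consistency loop)."""
        pure = trues_only_preset(ingenuity)
        inv = ingenuity.inverse_rate_model
        from petqc.ratemodel import predict

        fwhms = []
        for s_target in (5.8, 21.7, 33.2, 39.5):
            activity = float(predict(inv, s_target))
            lm = sample_coincidences(pure, scatter_phantom, activity,
                                     500_000, seed=int(s_target * 10))
            singles = float(predict(ingenuity.forward_rate_model, activity))
            expected = tof_fwhm_at(ingenuity, singles)
            # wide histograms at these counts warrant the smoothing flag
            res = estimate_tof_resolution(lm, smooth=True)
            assert res.fwhm == pytest.approx(expected, rel=0.015)
            fwhms.append(res.fwhm)
        assert np.all(np.diff(fwhms) > 0)


class TestEnergyResolution:
    def test_gaussian_energy_oracle(self):
        """sigma = 23.93 keV about the photopeak is 11.0 % FWHM of 511."""
        rng = np.random.default_rng(3)
        e = rng.normal(511.0, 23.93, 1_000_000)
        edges = np.arange(np.floor(e.min()), np.ceil(e.max()) + 1, 1.0)
        counts, edges = np.histogram(e, bins=edges)
        fwhm_pct = histogram_fwhm(counts, edges) / 511.0 * 100.0
        assert fwhm_pct == pytest.approx(11.0, abs=0.1)

    def test_full_path_recovers_preset_energy_resolution(self, lm_trues):
        res = estimate_energy_resolution(lm_trues)
        assert res.fwhm == pytest.approx(11.0, abs=0.15)
        assert res.counts.sum() == res.n_events_used  # pooled photons

    def test_degenerate_energies_below_bin_width(self, lm_trues):
        lm = listmode.ListModeSet(
            preset_name=lm_trues.preset_name, phantom=lm_trues.phantom,
            activity_kbq_ml=lm_trues.activity_kbq_ml,
            events=lm_trues.events.assign(
                energy_a_kev=511.0, energy_b_kev=511.0),
            frames=lm_trues.frames, seed=0, duration_s=lm_trues.duration_s)
        res = estimate_energy_resolution(lm)
        assert res.fwhm < 0.4          # one 1-keV bin -> < 0.4 % of 511
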