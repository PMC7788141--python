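import numpy as np
import pandas as pd
import pytest

from petqc import listmode
from petqc.countrate import (RatePoint, classify_events, compute_rate_point,
                             find_peaks, lor_source_distance, necr_from_rates)
from petqc.errors import DomainError, NoPeakError, UnsupportedPhantomError
from petqc.listmode import PhantomSpec, sample_coincidences, trues_only_preset
from petqc.ratemodel import predict


def _event_frame(ax, ay, bx, by):
    n = len(ax)
    return pd.DataFrame({
        "ax_mm": ax, "ay_mm": ay, "az_mm": np.zeros(n),
        "bx_mm": bx, "by_mm": by, "bz_mm": np.zeros(n),
        "delta_t_ps": np.zeros(n), "energy_a_kev": np.full(n, 511.0),
        "energy_b_kev": np.full(n, 511.0),
        "event_class": np.zeros(n, dtype=np.uint8),
    })


def test_lor_distance_point_line_oracle():
    # LOR along x through (45, 0): distance 0; parallel LOR at y = 25: distance 25
    ev = _event_frame(ax=[450.0, 450.0], ay=[0.0, 25.0],
                      bx=[-450.0, -450.0], by=[0.0, 25.0])
    d = lor_source_distance(ev, 45.0)
    assert d[0] == pytest.approx(0.0, abs=1e-9)
    assert d[1] == pytest.approx(25.0)


def test_classification_gate(lm_trues, lm_mixed):
    n_in, n_out, mask = classify_events(lm_trues)
    assert n_out == 0 and n_in == lm_trues.n_events        # pure trues
    n_in, n_out, mask = classify_events(lm_mixed)
    cls = lm_mixed.events["event_class"].to_numpy()
    # every scatter fails the gate by construction
    assert not mask[cls == listmode.CLASS_SCATTER].any()
    # every true passes
    assert mask[cls == listmode.CLASS_TRUE].all()


def test_classification_rejects_iec_phantom(lm_mixed):
    bad = listmode.ListModeSet(
        preset_name="vereos", phantom=PhantomSpec(kind="iec_spheres"),
        activity_kbq_ml=1.0, events=lm_mixed.events, frames=lm_mixed.frames,
        seed=0, duration_s=1.0)
    with pytest.raises(UnsupportedPhantomError):
        classify_events(bad)


@pytest.mark.parametrize("t,s,r,expected", [
    (1.0, 0.0, 0.0, 1.0),
    (0.100, 0.050, 0.050, 0.050),   # 100^2/200 kcps
    (0.0, 1.0, 1.0, 0.0),
])
def test_necr_identity(t, s, r, expected):
    assert necr_from_rates(t, s, r) == pytest.approx(expected)


def test_necr_scales_linearly():
    rng = np.random.default_rng(0)
    for _ in range(20):
        t, s, r = rng.uniform(0.1, 5.0, 3)
        k = rng.uniform(0.1, 10.0)
        assert necr_from_rates(k * t, k * s, k * r) == pytest.approx(
            k * necr_from_rates(t, s, r))


def test_rate_point_invariants_and_sf_recovery(vereos, scatter_phantom):
    """NECR never exceeds T, and as activity -> 0 (randoms vanish) the
    estimated scatter fraction recovers the generator's 0.30."""
    lm = sample_coincidences(vereos, scatter_phantom, 1.0, 150_000, seed=21,
                             duration_s=300.0)
    rp = compute_rate_point(lm, preset=vereos)
    assert rp.necr_mcps <= rp.trues_mcps + 1e-12
    assert rp.scatter_fraction_est == pytest.approx(0.30, abs=0.01)
    assert rp.scatter_fraction_est == pytest.approx(
        rp.scatter_mcps / (rp.trues_mcps + rp.scatter_mcps))


def test_rate_point_necr_equals_t_without_scatter_randoms(lm_trues, vereos):
    pure = trues_only_preset(vereos)
    rp = compute_rate_point(lm_trues, preset=pure)
    assert rp.randoms_mcps == 0.0
    assert rp.scatter_mcps == pytest.approx(0.0, abs=1e-9)
    assert rp.necr_mcps == pytest.approx(rp.trues_mcps)


def test_rate_point_requires_frames(lm_mixed):
    broken = listmode.ListModeSet(
        preset_name="vereos", phantom=lm_mixed.phantom, activity_kbq_ml=1.0,
        events=lm_mixed.events, frames=lm_mixed.frames.iloc[0:0],
        seed=0, duration_s=0.0)
    with pytest.raises(DomainError):
        compute_rate_point(broken)


def _rate_series(activities, necr_fn, singles_fn):
    return [RatePoint(activity_kbq_ml=a, trues_mcps=necr_fn(a),
                      scatter_mcps=0.0, randoms_mcps=0.0,
                      necr_mcps=necr_fn(a), scatter_fraction_est=0.0,
                      singles_mcps=singles_fn(a))
            for a in activities]


def test_peak_of_exact_parabola_in_log_activity():
    acts = np.exp(np.linspace(0, 4, 9))
    necr = lambda a: 10.0 - (np.log(a) - 2.1) ** 2
    singles = lambda a: 5.0 - 0.5 * (np.log(a) - 1.7) ** 2
    res = find_peaks(_rate_series(acts, necr, singles))
    assert res.necr_peak.activity_kbq_ml == pytest.approx(np.exp(2.1))
    assert res.necr_peak.rate_mcps == pytest.approx(10.0)
    assert res.singles_peak.activity_kbq_ml == pytest.approx(np.exp(1.7))


def test_monotone_series_reports_direction():
    acts = np.linspace(1, 10, 6)
    with pytest.raises(NoPeakError) as exc:
        find_peaks(_rate_series(acts, lambda a: a, lambda a: a))
    assert exc.value.direction == "increasing"


def test_peak_against_analytic_count_rate_model(vereos):
    """NECR built from closed-form T, S, R curves with a dead-time rollover:
    the interpolated peak must sit within 2 % of a dense-grid oracle.

    The fitted singles curves themselves never turn over (they are only
    valid below the singles peak), so the rollover factor exp(-A/A0) that
    produces the peak is injected analytically here.
    """
    sf, k, pps = 0.30, vereos.randoms_coeff, vereos.prompts_per_single

    def S(a):
        return predict(vereos.forward_rate_model, a) * np.exp(-a / 120.0)

    def necr(a):
        s_rate = S(a)
        t = (1 - sf) * pps * s_rate * np.exp(-a / 80.0)
        sc = sf * pps * s_rate
        r = k * s_rate ** 2
        return t ** 2 / (t + sc + r)

    fine = np.linspace(5.0, 200.0, 20000)
    oracle_peak = fine[np.argmax([necr(a) for a in fine])]

    acts = np.geomspace(5.0, 200.0, 15)
    series = _rate_series(acts, necr, S)
    res = find_peaks(series)
    assert res.necr_peak.activity_kbq_ml == pytest.approx(oracle_peak, rel=0.02)
    # recordings above the singles-peak activity are flagged for exclusion
    expected_excluded = acts > res.singles_peak.activity_kbq_ml
    assert np.array_equal(res.excluded, expected_excluded)
    assert 0 < res.excluded.sum() < len(series)


def test_class_probability_recovery_on_generator_output(vereos, lm_mixed):
    """T/(T+S+R) from the analysis chain matches the generator's configured
    class probabilities within a few binomial standard errors."""
    rp = compute_rate_point(lm_mixed, preset=vereos)
    total = rp.trues_mcps + rp.scatter_mcps + rp.randoms_mcps
    p_t, p_s, p_r = listmode.event_class_probabilities(
        vereos, lm_mixed.mean_singles_mcps())
    n = lm_mixed.n_events
    se = 3 * np.sqrt(p_t * (1 - p_t) / n) + 0.01
    assert rp.trues_mcps / total == pytest.approx(p_t, abs=se)
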