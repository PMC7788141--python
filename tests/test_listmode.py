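import h5py
import numpy as np
import pandas as pd
import pytest

from petqc import listmode
from petqc.errors import DomainError, SchemaError
from petqc.listmode import (C_MM_PER_PS, DETECTOR_RADIUS_MM, PhantomSpec,
                            read_listmode, sample_coincidences,
                            simulate_decay_series, trues_only_preset,
                            write_listmode)
from petqc.ratemodel import predict


def test_phantom_spec_validation():
    with pytest.raises(DomainError):
        PhantomSpec(line_offset_mm=150.0)          # outside the cylinder
    with pytest.raises(DomainError):
        PhantomSpec(kind="iec_spheres", sphere_to_background_ratio=1.0)
    with pytest.raises(DomainError):
        PhantomSpec(kind="donut")


def test_trues_annihilate_on_source_and_endpoints_on_ring(lm_trues):
    ev = lm_trues.events
    assert set(ev["event_class"]) == {listmode.CLASS_TRUE}
    r_a = np.hypot(ev["ax_mm"], ev["ay_mm"])
    r_b = np.hypot(ev["bx_mm"], ev["by_mm"])
    assert np.allclose(r_a, DETECTOR_RADIUS_MM, atol=1e-6)
    assert np.allclose(r_b, DETECTOR_RADIUS_MM, atol=1e-6)
    half = 164.0 / 2
    assert np.all(np.abs(ev["az_mm"]) <= half + 1e-9)
    assert np.all(np.abs(ev["bz_mm"]) <= half + 1e-9)


def test_tof_difference_matches_point_line_geometry(lm_trues):
    """With the blur removed, the stored delta_t must equal the geometric
    (|P-A| - |P-B|)/c for the annihilation point on the source line."""
    ev = lm_trues.events.head(2000)
    a = ev[["ax_mm", "ay_mm", "az_mm"]].to_numpy()
    b = ev[["bx_mm", "by_mm", "bz_mm"]].to_numpy()
    # the true annihilation point: LOR point nearest (transaxially) to the line
    d = b - a
    t = ((45.0 - a[:, 0]) * d[:, 0] + (0.0 - a[:, 1]) * d[:, 1]) / (
        d[:, 0] ** 2 + d[:, 1] ** 2)
    p = a + t[:, None] * d
    expected = (np.linalg.norm(p - a, axis=1)
                - np.linalg.norm(p - b, axis=1)) / C_MM_PER_PS
    resid = ev["delta_t_ps"].to_numpy() - expected
    # residual is pure timing blur: zero-mean Gaussian, FWHM 326 ps
    assert abs(np.mean(resid)) < 3 * 326 / 2.355 / np.sqrt(len(resid))
    # a 45-mm displacement from the LOR midpoint corresponds to ~300 ps
    assert 2 * 45.0 / C_MM_PER_PS == pytest.approx(300.2, abs=0.2)


def test_singles_frames_converge_to_forward_model(vereos, scatter_phantom):
    """Mean frame singles matches the saturation model within 1 % once many
    500-ms frames accumulate."""
    for activity in (1.0, 10.0, 30.0):
        lm = sample_coincidences(vereos, scatter_phantom, activity, 1000,
                                 seed=3, duration_s=300.0)   # 600 frames
        assert len(lm.frames) == 600
        assert np.all(lm.frames["duration_s"] == 0.5)
        expected = predict(vereos.forward_rate_model, activity)
        assert lm.mean_singles_mcps() == pytest.approx(expected, rel=0.01)


def test_event_class_mix_matches_probabilities(vereos, lm_mixed):
    p = listmode.event_class_probabilities(
        vereos, lm_mixed.mean_singles_mcps())
    counts = np.bincount(lm_mixed.events["event_class"], minlength=3)
    n = counts.sum()
    for k in range(3):
        se = np.sqrt(n * p[k] * (1 - p[k]))
        assert abs(counts[k] - n * p[k]) < 5 * se


def test_trues_only_when_no_scatter_or_randoms(lm_trues):
    assert (lm_trues.events["event_class"] == listmode.CLASS_TRUE).all()


def test_seed_reproducibility(vereos, scatter_phantom):
    a = sample_coincidences(vereos, scatter_phantom, 5.0, 5000, seed=42)
    b = sample_coincidences(vereos, scatter_phantom, 5.0, 5000, seed=42)
    pd.testing.assert_frame_equal(a.events, b.events)
    pd.testing.assert_frame_equal(a.frames, b.frames)
    c = sample_coincidences(vereos, scatter_phantom, 5.0, 5000, seed=43)
    assert not a.events["delta_t_ps"].equals(c.events["delta_t_ps"])


def test_energies_inside_window(vereos, lm_mixed):
    lo, hi = vereos.energy_window_bounds()
    for col in ("energy_a_kev", "energy_b_kev"):
        e = lm_mixed.events[col]
        assert e.between(lo, hi).all()
        assert (e > 0).all()


# ------------------------------------------------------------ decay series

def test_decay_series_halves_activity_after_one_half_life(vereos, scatter_phantom):
    series = simulate_decay_series(vereos, scatter_phantom, 10.0, 6586.2,
                                   n_recordings=2, seed=1,
                                   events_per_recording=1000,
                                   total_time_s=6586.2)
    assert series[0].activity_kbq_ml == pytest.approx(10.0)
    assert series[1].activity_kbq_ml == pytest.approx(5.0)
    # durations grow to compensate decay
    assert series[1].duration_s > series[0].duration_s


def test_decay_series_single_recording(vereos, scatter_phantom):
    series = simulate_decay_series(vereos, scatter_phantom, 7.2, 6586.2,
                                   n_recordings=1, seed=1,
                                   events_per_recording=500)
    assert len(series) == 1
    assert series[0].activity_kbq_ml == pytest.approx(7.2)


def test_decay_series_matches_published_rate_activity_pair(vereos, scatter_phantom):
    """7.2 kBq/mL on the digital camera corresponds to ~10.5 Mcps."""
    series = simulate_decay_series(vereos, scatter_phantom, 7.2, 6586.2,
                                   n_recordings=1, seed=5,
                                   events_per_recording=1000,
                                   base_duration_s=300.0)
    assert series[0].mean_singles_mcps() == pytest.approx(10.5, rel=0.02)


def test_decay_series_rejects_bad_half_life(vereos, scatter_phantom):
    with pytest.raises(DomainError):
        simulate_decay_series(vereos, scatter_phantom, 10.0, -1.0, 3, seed=1)


# ------------------------------------------------------------- container

def test_round_trip_is_lossless(tmp_path, lm_mixed):
    path = tmp_path / "rec.h5"
    write_listmode(lm_mixed, path)
    back = read_listmode(path)
    pd.testing.assert_frame_equal(back.events, lm_mixed.events)
    pd.testing.assert_frame_equal(back.frames, lm_mixed.frames)
    assert back.preset_name == lm_mixed.preset_name
    assert back.seed == lm_mixed.seed
    assert back.activity_kbq_ml == lm_mixed.activity_kbq_ml
    assert back.phantom == lm_mixed.phantom


def test_empty_event_list_round_trips(tmp_path, lm_mixed):
    empty = listmode.ListModeSet(
        preset_name="vereos", phantom=PhantomSpec(), activity_kbq_ml=1.0,
        events=lm_mixed.events.iloc[0:0], frames=lm_mixed.frames.head(3),
        seed=0, duration_s=1.5)
    path = tmp_path / "empty.h5"
    write_listmode(empty, path)
    back = read_listmode(path)
    assert back.n_events == 0


def test_unknown_column_is_reported(tmp_path, lm_trues):
    path = tmp_path / "extra.h5"
    write_listmode(lm_trues, path)
    with h5py.File(path, "a") as f:
        f["events"].create_dataset("mystery_col", data=np.zeros(3))
    with pytest.raises(SchemaError, match="mystery_col"):
        read_listmode(path)


def test_schema_version_mismatch_names_versions(tmp_path, lm_trues):
    path = tmp_path / "old.h5"
    write_listmode(lm_trues, path)
    with h5py.File(path, "a") as f:
        f.attrs["schema_version"] = "petqc-listmode-0"
    with pytest.raises(SchemaError, match="petqc-listmode-1.*petqc-listmode-0"):
        read_listmode(path)


def test_routine_frames_emulate_published_fdg_regime(ingenuity):
    """1853 analog-camera frames around the FDG median concentration must
    land their median inside the published routine interval."""
    med_act = predict(ingenuity.inverse_rate_model, 8.1)
    frames = listmode.simulate_routine_frames(ingenuity, med_act, 0.15,
                                              1853, seed=9)
    med = frames["singles_mcps"].median()
    assert 5.8 <= med <= 10.0
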