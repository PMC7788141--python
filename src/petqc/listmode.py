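"""Synthetic list-mode generation and the list-mode container.

Emulates the statistical structure of scanner list-mode recordings of the
NEMA scatter phantom: a line source parallel to the axis at a 45-mm radial
offset inside a polyethylene cylinder, coincidence events of three classes
(true / scatter / random), Gaussian timing blur whose FWHM may depend on the
singles rate, Gaussian energy blur around 511 keV truncated to the camera's
acceptance window, and 500-ms singles/prompts/delayeds frames whose mean
follows the preset's saturating rate-activity model.

The detector is a single cylindrical surface (radius 450 mm, axial extent =
the preset's axial FOV) with no crystal discretisation: every analysis in
this package works on LOR geometry and event times/energies only.

Events are held columnar (one pandas DataFrame row per coincidence) and
persisted, together with the frames table and recording metadata, in a
self-describing versioned HDF5 container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, UnsupportedPhantomError
from .presets import CameraPreset, energy_res_at, tof_fwhm_at
from .ratemodel import predict

#: speed of light, mm per picosecond
C_MM_PER_PS = 0.29979
#: detector ring radius, mm
DETECTOR_RADIUS_MM = 450.0
#: Gaussian FWHM / sigma
FWHM_OVER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))
#: singles frame length, s
FRAME_DURATION_S = 0.5
#: coincidence window half-width for uniformly timed randoms, ps
RANDOM_DT_HALF_WINDOW_PS = 3000.0

SCHEMA_VERSION = "petqc-listmode-1"

EVENT_COLUMNS = {
    "ax_mm": "mm", "ay_mm": "mm", "az_mm": "mm",
    "bx_mm": "mm", "by_mm": "mm", "bz_mm": "mm",
    "delta_t_ps": "ps (time(a) - time(b))",
    "energy_a_kev": "keV", "energy_b_kev": "keV",
    "event_class": "0=true 1=scatter 2=random",
}
FRAME_COLUMNS = {
    "t_start_s": "s", "duration_s": "s",
    "singles_mcps": "Mcps", "prompts_mcps": "Mcps", "delayeds_mcps": "Mcps",
}

CLASS_TRUE, CLASS_SCATTER, CLASS_RANDOM = 0, 1, 2


@dataclass
class PhantomSpec:
    """Geometry and fill of a phantom.

    ``scatter_line``: NEMA count-rate phantom, a 101.5-mm-radius cylinder
    with an axial line source offset ``line_offset_mm`` from the axis.
    ``iec_spheres``: IEC body phantom with six hot spheres at
    ``sphere_to_background_ratio`` times the background concentration.
    """

    kind: str = "scatter_line"
    cylinder_radius_mm: float = 101.5
    line_offset_mm: float = 45.0
    axial_length_mm: float = 700.0
    sphere_diameters_mm: tuple = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    sphere_to_background_ratio: float = 4.0
    background_concentration_kbq_ml: float | None = None

    def __post_init__(self):
        if self.kind not in ("scatter_line", "iec_spheres"):
            raise DomainError(f"unknown phantom kind {self.kind!r}")
        if self.line_offset_mm >= self.cylinder_radius_mm:
            raise DomainError("line_offset_mm must be < cylinder_radius_mm")
        if self.kind == "iec_spheres" and self.sphere_to_background_ratio <= 1:
            raise DomainError("sphere_to_background_ratio must be > 1")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "cylinder_radius_mm": self.cylinder_radius_mm,
            "line_offset_mm": self.line_offset_mm,
            "axial_length_mm": self.axial_length_mm,
            "sphere_diameters_mm": list(self.sphere_diameters_mm),
            "sphere_to_background_ratio": self.sphere_to_background_ratio,
            "background_concentration_kbq_ml": self.background_concentration_kbq_ml,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["sphere_diameters_mm"] = tuple(d.get("sphere_diameters_mm", ()))
        return cls(**d)


@dataclass
class ListModeSet:
    """One synthetic recording: coincidences + 500-ms frames + metadata."""

    preset_name: str
    phantom: PhantomSpec
    activity_kbq_ml: float
    events: pd.DataFrame
    frames: pd.DataFrame
    seed: int
    duration_s: float

    @property
    def n_events(self) -> int:
        return len(self.events)

    def mean_singles_mcps(self) -> float:
        return float(self.frames["singles_mcps"].mean())


# ---------------------------------------------------------------- geometry

def _sample_lors_through(rng, points_xy, n, z_half_det, azimuth=None,
                         tilt_max=0.10):
    """LORs through given transaxial annihilation positions, endpoints on the
    detector ring.

    Directions have uniform azimuth (or the supplied one) and a small uniform
    axial tilt; axial positions are uniform over the FOV, and draws whose
    endpoints fall outside the axial FOV are resampled together with their
    axial position (axial acceptance weighting).  Returns endpoint arrays
    a, b (n, 3) and the exact signed TOF difference time(a) - time(b) in ps.
    """
    a = np.empty((n, 3))
    b = np.empty((n, 3))
    dt = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        m = todo.size
        phi = rng.uniform(0.0, 2.0 * np.pi, m) if azimuth is None else azimuth[todo]
        psi = rng.uniform(-tilt_max, tilt_max, m)
        z = rng.uniform(-z_half_det, z_half_det, m)
        cpsi = np.cos(psi)
        d = np.column_stack([cpsi * np.cos(phi), cpsi * np.sin(phi), np.sin(psi)])
        p = np.column_stack([points_xy[todo, 0], points_xy[todo, 1], z])
        # intersect the transaxial projection with the ring circle
        dxy2 = d[:, 0] ** 2 + d[:, 1] ** 2
        pd_ = p[:, 0] * d[:, 0] + p[:, 1] * d[:, 1]
        pp = p[:, 0] ** 2 + p[:, 1] ** 2
        disc = pd_ ** 2 - dxy2 * (pp - DETECTOR_RADIUS_MM ** 2)
        sq = np.sqrt(np.maximum(disc, 0.0))
        t2 = (-pd_ + sq) / dxy2          # forward root, > 0
        t1 = (-pd_ - sq) / dxy2          # backward root, < 0
        aa = p + t2[:, None] * d
        bb = p + t1[:, None] * d
        ok = (np.abs(aa[:, 2]) <= z_half_det) & (np.abs(bb[:, 2]) <= z_half_det)
        idx = todo[ok]
        a[idx] = aa[ok]
        b[idx] = bb[ok]
        # |P-A| = t2, |P-B| = -t1 (unit direction), so dt = (t2 + t1) / c
        dt[idx] = (t2[ok] + t1[ok]) / C_MM_PER_PS
        todo = todo[~ok]
    return a, b, dt


def _truncated_normal(rng, mean, sigma, lo, hi, n):
    out = rng.normal(mean, sigma, n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sigma, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _make_frames(rng, singles_mcps, prompts_mcps, delayeds_mcps, duration_s):
    n_frames = max(1, int(round(duration_s / FRAME_DURATION_S)))
    counts_per_mcps = 1e6 * FRAME_DURATION_S
    starts = np.arange(n_frames) * FRAME_DURATION_S
    s = rng.poisson(singles_mcps * counts_per_mcps, n_frames) / counts_per_mcps
    p = rng.poisson(prompts_mcps * counts_per_mcps, n_frames) / counts_per_mcps
    d = rng.poisson(delayeds_mcps * counts_per_mcps, n_frames) / counts_per_mcps
    return pd.DataFrame({
        "t_start_s": starts,
        "duration_s": np.full(n_frames, FRAME_DURATION_S),
        "singles_mcps": s, "prompts_mcps": p, "delayeds_mcps": d,
    })


# ---------------------------------------------------------------- sampling

def event_class_probabilities(preset: CameraPreset, singles_mcps: float):
    """(p_true, p_scatter, p_random) implied by the preset at a singles rate."""
    sf = preset.scatter_fraction
    c_rate = preset.prompts_per_single * singles_mcps
    r_rate = preset.randoms_coeff * singles_mcps ** 2
    rf = r_rate / (c_rate + r_rate) if (c_rate + r_rate) > 0 else 0.0
    return (1.0 - sf) * (1.0 - rf), sf * (1.0 - rf), rf


def sample_coincidences(
    preset: CameraPreset,
    phantom: PhantomSpec,
    activity_kbq_ml: float,
    n_events: int,
    seed: int,
    duration_s: float | None = None,
    scatter_kick_sigma_mm: float = 40.0,
    scatter_min_distance_mm: float = 20.0,
) -> ListModeSet:
    """Draw one scatter-phantom recording at a fixed activity concentration.

    Event classes are multinomial with probabilities
    ((1-SF)(1-RF), SF(1-RF), RF) where SF is the preset scatter fraction and
    RF the randoms fraction implied by the rate-squared randoms model at the
    singles rate the preset predicts for this activity.

    True events annihilate on the line source; the measured time difference
    is the exact geometric TOF difference plus Gaussian noise with FWHM
    ``tof_fwhm_at(preset, singles)``.  Scatter events annihilate at a
    transaxially kicked point (Gaussian kick, resampled until at least
    ``scatter_min_distance_mm`` from the source) with the LOR oriented
    perpendicular to the displacement so the event fails the true gate by
    construction.  Random events join two independent uniform detector hits
    with a uniformly distributed time difference.  Photon energies are
    Gaussian around 511 keV (FWHM from the preset's energy-resolution curve)
    truncated to the acceptance window.
    """
    if phantom.kind != "scatter_line":
        raise UnsupportedPhantomError(
            f"sample_coincidences requires a scatter_line phantom, got {phantom.kind!r}"
        )
    if n_events < 1:
        raise DomainError("n_events must be >= 1")

    rng = np.random.default_rng(seed)
    singles = float(predict(preset.forward_rate_model, activity_kbq_ml))
    fwhm_ps = tof_fwhm_at(preset, singles)
    eres_pct = energy_res_at(preset, singles)

    p_t, p_s, p_r = event_class_probabilities(preset, singles)
    n_t, n_s, n_r = rng.multinomial(n_events, [p_t, p_s, p_r])

    z_half = preset.axial_fov_mm / 2.0
    src = np.array([phantom.line_offset_mm, 0.0])
    parts = []

    if n_t:
        pts = np.tile(src, (n_t, 1))
        a, b, dt = _sample_lors_through(rng, pts, n_t, z_half)
        parts.append((a, b, dt, CLASS_TRUE))
    if n_s:
        kick = rng.normal(0.0, scatter_kick_sigma_mm, (n_s, 2))
        r = np.hypot(kick[:, 0], kick[:, 1])
        bad = r < scatter_min_distance_mm
        while bad.any():
            kick[bad] = rng.normal(0.0, scatter_kick_sigma_mm, (bad.sum(), 2))
            r = np.hypot(kick[:, 0], kick[:, 1])
            bad = r < scatter_min_distance_mm
        pts = src + kick
        # LOR azimuth perpendicular to the displacement: the transaxial
        # LOR-to-source distance then equals the kick length (>= the gate)
        perp = np.arctan2(kick[:, 1], kick[:, 0]) + np.pi / 2.0
        perp += np.pi * rng.integers(0, 2, n_s)
        a, b, dt = _sample_lors_through(rng, pts, n_s, z_half, azimuth=perp)
        parts.append((a, b, dt, CLASS_SCATTER))
    if n_r:
        th = rng.uniform(0.0, 2.0 * np.pi, (n_r, 2))
        zz = rng.uniform(-z_half, z_half, (n_r, 2))
        a = np.column_stack([DETECTOR_RADIUS_MM * np.cos(th[:, 0]),
                             DETECTOR_RADIUS_MM * np.sin(th[:, 0]), zz[:, 0]])
        b = np.column_stack([DETECTOR_RADIUS_MM * np.cos(th[:, 1]),
                             DETECTOR_RADIUS_MM * np.sin(th[:, 1]), zz[:, 1]])
        dt = rng.uniform(-RANDOM_DT_HALF_WINDOW_PS, RANDOM_DT_HALF_WINDOW_PS, n_r)
        parts.append((a, b, dt, CLASS_RANDOM))

    n_tot = n_t + n_s + n_r
    A = np.vstack([p[0] for p in parts])
    B = np.vstack([p[1] for p in parts])
    dt_exact = np.concatenate([p[2] for p in parts])
    cls = np.concatenate([np.full(len(p[2]), p[3], dtype=np.uint8) for p in parts])

    sigma_t = fwhm_ps / FWHM_OVER_SIGMA
    blur = rng.normal(0.0, sigma_t, n_tot)
    delta_t = np.where(cls == CLASS_RANDOM, dt_exact, dt_exact + blur)

    sigma_e = eres_pct / 100.0 * 511.0 / FWHM_OVER_SIGMA
    lo, hi = preset.energy_window_bounds()
    ea = _truncated_normal(rng, 511.0, sigma_e, lo, hi, n_tot)
    eb = _truncated_normal(rng, 511.0, sigma_e, lo, hi, n_tot)

    order = rng.permutation(n_tot)
    events = pd.DataFrame({
        "ax_mm": A[order, 0], "ay_mm": A[order, 1], "az_mm": A[order, 2],
        "bx_mm": B[order, 0], "by_mm": B[order, 1], "bz_mm": B[order, 2],
        "delta_t_ps": delta_t[order],
        "energy_a_kev": ea[order], "energy_b_kev": eb[order],
        "event_class": cls[order],
    })

    c_rate = preset.prompts_per_single * singles
    r_rate = preset.randoms_coeff * singles ** 2
    if duration_s is None:
        duration_s = max(FRAME_DURATION_S, n_events / max(c_rate + r_rate, 1e-9) / 1e6)
    frames = _make_frames(rng, singles, c_rate + r_rate, r_rate, duration_s)

    return ListModeSet(
        preset_name=preset.name, phantom=phantom,
        activity_kbq_ml=float(activity_kbq_ml),
        events=events, frames=frames, seed=int(seed),
        duration_s=float(duration_s),
    )


def simulate_decay_series(
    preset: CameraPreset,
    phantom: PhantomSpec,
    initial_kbq_ml: float,
    half_life_s: float,
    n_recordings: int,
    seed: int,
    events_per_recording: int = 20000,
    total_time_s: float = 57600.0,
    base_duration_s: float = 30.0,
) -> list[ListModeSet]:
    """Consecutive recordings of a decaying phantom.

    Recordings are spread uniformly over ``total_time_s`` (default 16 h, the
    span of a full count-rate test); the nominal concentration decays
    exponentially and recording durations grow as the reciprocal of the
    expected coincidence rate, so each recording targets a constant expected
    number of trues.
    """
    if half_life_s <= 0:
        raise DomainError("half_life_s must be > 0")
    if n_recordings < 1:
        raise DomainError("n_recordings must be >= 1")
    if initial_kbq_ml <= 0:
        raise DomainError("initial_kbq_ml must be > 0")

    times = (np.linspace(0.0, total_time_s, n_recordings)
             if n_recordings > 1 else np.array([0.0]))
    activities = initial_kbq_ml * 0.5 ** (times / half_life_s)
    c0 = preset.prompts_per_single * float(
        predict(preset.forward_rate_model, activities[0]))
    children = np.random.SeedSequence(seed).spawn(n_recordings)
    out = []
    for act, child in zip(activities, children):
        c = preset.prompts_per_single * float(predict(preset.forward_rate_model, act))
        dur = base_duration_s * c0 / max(c, 1e-9)
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(sample_coincidences(
            preset, phantom, act, events_per_recording, sub_seed, duration_s=dur))
    return out


def simulate_routine_frames(
    preset: CameraPreset,
    median_activity_kbq_ml: float,
    sigma_log: float,
    n_frames: int,
    seed: int,
) -> pd.DataFrame:
    """500-ms singles frames emulating a routine patient exam.

    The recorded activity seen by the camera fluctuates over bed positions
    and patients; it is modelled log-normally around a median concentration.
    Each frame's singles rate is the preset forward model at the drawn
    concentration plus Poisson counting noise.
    """
    rng = np.random.default_rng(seed)
    acts = np.exp(rng.normal(np.log(median_activity_kbq_ml), sigma_log, n_frames))
    singles = np.asarray(predict(preset.forward_rate_model, acts))
    counts_per_mcps = 1e6 * FRAME_DURATION_S
    s = rng.poisson(singles * counts_per_mcps) / counts_per_mcps
    c = preset.prompts_per_single * s
    r = preset.randoms_coeff * s ** 2
    return pd.DataFrame({
        "t_start_s": np.arange(n_frames) * FRAME_DURATION_S,
        "duration_s": np.full(n_frames, FRAME_DURATION_S),
        "singles_mcps": s, "prompts_mcps": c + r, "delayeds_mcps": r,
    })


# ---------------------------------------------------------------- container

def write_listmode(lmset: ListModeSet, path: str | Path) -> None:
    """Persist a recording to the versioned HDF5 list-mode container."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["preset_name"] = lmset.preset_name
        f.attrs["activity_kbq_ml"] = lmset.activity_kbq_ml
        f.attrs["seed"] = lmset.seed
        f.attrs["duration_s"] = lmset.duration_s
        f.attrs["phantom_json"] = json.dumps(lmset.phantom.to_dict())
        ev = f.create_group("events")
        for col, unit in EVENT_COLUMNS.items():
            ds = ev.create_dataset(col, data=lmset.events[col].to_numpy())
            ds.attrs["units"] = unit
        fr = f.create_group("frames")
        for col, unit in FRAME_COLUMNS.items():
            ds = fr.create_dataset(col, data=lmset.frames[col].to_numpy())
            ds.attrs["units"] = unit


def read_listmode(path: str | Path) -> ListModeSet:
    """Read a recording back; schema version and column sets are enforced."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version mismatch: expected {SCHEMA_VERSION!r}, found {version!r}"
            )
        for group, expected in (("events", EVENT_COLUMNS), ("frames", FRAME_COLUMNS)):
            found = set(f[group].keys())
            extra = sorted(found - set(expected))
            missing = sorted(set(expected) - found)
            if extra:
                raise SchemaError(f"unknown {group} column(s): {', '.join(extra)}")
            if missing:
                raise SchemaError(f"missing {group} column(s): {', '.join(missing)}")
        events = pd.DataFrame({c: f["events"][c][()] for c in EVENT_COLUMNS})
        frames = pd.DataFrame({c: f["frames"][c][()] for c in FRAME_COLUMNS})
        return ListModeSet(
            preset_name=str(f.attrs["preset_name"]),
            phantom=PhantomSpec.from_dict(json.loads(f.attrs["phantom_json"])),
            activity_kbq_ml=float(f.attrs["activity_kbq_ml"]),
            events=events, frames=frames,
            seed=int(f.attrs["seed"]),
            duration_s=float(f.attrs["duration_s"]),
        )


def trues_only_preset(preset: CameraPreset) -> CameraPreset:
    """Copy of a preset that emits only true coincidences (SF = 0, no randoms)."""
    return replace(preset, scatter_fraction=0.0, randoms_coeff=0.0)
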