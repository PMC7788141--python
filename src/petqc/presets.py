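"""Camera presets.

A :class:`CameraPreset` bundles everything the simulations and conversions
need to know about one scanner model: the fitted singles-rate/activity
regressions in both directions, the rate dependence of the timing and energy
resolutions, and a handful of physics constants.  Two presets ship with the
package: ``"vereos"`` (digital, dSiPM) and ``"ingenuity"`` (analog, PMT).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import DomainError, PresetNotFoundError, PresetValidationError
from .ratemodel import ExpFitParams, predict

SHIPPED_PRESETS = ("vereos", "ingenuity")


@dataclass
class CameraPreset:
    name: str
    forward_rate_model: ExpFitParams       # activity kBq/mL -> singles Mcps
    inverse_rate_model: ExpFitParams       # singles Mcps -> activity kBq/mL
    tof_fwhm_anchors: np.ndarray           # (n, 2): singles Mcps -> FWHM ps
    energy_res_anchors: np.ndarray         # (n, 2): singles Mcps -> % FWHM at 511 keV
    scatter_fraction: float = 0.30
    randoms_coeff: float = 1e-3            # Mcps^-1, R = k * S^2
    prompts_per_single: float = 0.10       # true+scatter coincidence rate / singles
    axial_fov_mm: float = 164.0
    energy_window_kev: float = 164.0       # full window width, symmetric about 511
    metadata: dict = field(default_factory=dict)

    def energy_window_bounds(self) -> tuple[float, float]:
        half = self.energy_window_kev / 2.0
        return 511.0 - half, 511.0 + half


def _piecewise(anchors: np.ndarray, x: float) -> float:
    """Piecewise-linear in the anchor range, constant below the first anchor,
    linear continuation of the last segment above the last anchor."""
    xs, ys = anchors[:, 0], anchors[:, 1]
    if len(xs) == 1:
        return float(ys[0])
    if x <= xs[0]:
        return float(ys[0])
    if x >= xs[-1]:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return float(ys[-1] + slope * (x - xs[-1]))
    return float(np.interp(x, xs, ys))


def tof_fwhm_at(preset: CameraPreset, singles_mcps: float) -> float:
    """Timing FWHM (ps) at a given singles rate (Mcps)."""
    if singles_mcps < 0:
        raise DomainError("singles rate must be >= 0")
    return _piecewise(preset.tof_fwhm_anchors, singles_mcps)


def energy_res_at(preset: CameraPreset, singles_mcps: float) -> float:
    """Energy resolution (% FWHM at 511 keV) at a given singles rate (Mcps)."""
    if singles_mcps < 0:
        raise DomainError("singles rate must be >= 0")
    return _piecewise(preset.energy_res_anchors, singles_mcps)


def _load_params(obj: dict, name: str, bad: list[str]) -> ExpFitParams | None:
    if not isinstance(obj, dict) or any(k not in obj for k in ("a", "b", "c", "d")):
        bad.append(name)
        return None
    try:
        return ExpFitParams(
            a=float(obj["a"]), b=float(obj["b"]),
            c=float(obj["c"]), d=float(obj["d"]),
            r_squared=float(obj.get("r_squared", float("nan"))),
            rmse=float(obj.get("rmse", float("nan"))),
            direction=obj.get("direction"),
        )
    except (TypeError, ValueError):
        bad.append(name)
        return None


def _anchors(obj, name: str, bad: list[str]) -> np.ndarray | None:
    try:
        arr = np.asarray(obj, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
            raise ValueError
        if np.any(np.diff(arr[:, 0]) <= 0) and arr.shape[0] > 1:
            raise ValueError
        if np.any(np.diff(arr[:, 1]) < 0):
            raise ValueError("resolution curves must be non-decreasing in rate")
        return arr
    except (TypeError, ValueError):
        bad.append(name)
        return None


def preset_from_dict(cfg: dict) -> CameraPreset:
    """Build and validate a preset from a parsed config mapping."""
    bad: list[str] = []
    fwd = _load_params(cfg.get("forward_rate_model"), "forward_rate_model", bad)
    inv = _load_params(cfg.get("inverse_rate_model"), "inverse_rate_model", bad)
    tof = _anchors(cfg.get("tof_fwhm_ps_vs_mcps"), "tof_fwhm_ps_vs_mcps", bad)
    ene = _anchors(cfg.get("energy_res_pct_vs_mcps"), "energy_res_pct_vs_mcps", bad)

    sf = cfg.get("scatter_fraction", 0.30)
    if not isinstance(sf, (int, float)) or not 0 <= sf < 1:
        bad.append("scatter_fraction")
    for key in ("axial_fov_mm", "energy_window_kev", "randoms_coeff_per_mcps",
                "prompts_per_single"):
        v = cfg.get(key)
        if v is not None and (not isinstance(v, (int, float)) or v <= 0):
            bad.append(key)
    if "name" not in cfg:
        bad.append("name")
    if bad:
        raise PresetValidationError(bad)

    # forward model must be increasing and concave-saturating over the
    # activity range the analysis uses
    grid = np.linspace(0.0, 60.0, 121)
    s = predict(fwd, grid)
    if np.any(np.diff(s) <= 0):
        raise PresetValidationError(["forward_rate_model (not strictly increasing)"])
    if np.any(np.diff(s, 2) > 1e-9):
        raise PresetValidationError(["forward_rate_model (not concave-saturating)"])

    return CameraPreset(
        name=str(cfg["name"]),
        forward_rate_model=fwd,
        inverse_rate_model=inv,
        tof_fwhm_anchors=tof,
        energy_res_anchors=ene,
        scatter_fraction=float(sf),
        randoms_coeff=float(cfg.get("randoms_coeff_per_mcps", 1e-3)),
        prompts_per_single=float(cfg.get("prompts_per_single", 0.10)),
        axial_fov_mm=float(cfg.get("axial_fov_mm", 164.0)),
        energy_window_kev=float(cfg.get("energy_window_kev", 164.0)),
        metadata=dict(cfg.get("metadata") or {}),
    )


def load_preset(name: str | Path) -> CameraPreset:
    """Load a shipped preset by name ("vereos", "ingenuity") or a YAML file by path."""
    name_s = str(name)
    if name_s in SHIPPED_PRESETS:
        text = (
            importlib.resources.files("petqc")
            .joinpath("data", f"{name_s}.yaml")
            .read_text()
        )
    else:
        p = Path(name_s)
        if not p.is_file():
            raise PresetNotFoundError(
                f"unknown preset {name_s!r}; shipped presets are {SHIPPED_PRESETS} "
                "and anything else must be a path to a preset YAML file"
            )
        text = p.read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise PresetValidationError(["<document root>"])
    return preset_from_dict(cfg)


def export_preset(preset: CameraPreset, path: str | Path) -> None:
    """Write a preset back out as a YAML config (round-trips through load_preset)."""
    cfg = {
        "name": preset.name,
        "axial_fov_mm": preset.axial_fov_mm,
        "energy_window_kev": preset.energy_window_kev,
        "scatter_fraction": preset.scatter_fraction,
        "prompts_per_single": preset.prompts_per_single,
        "randoms_coeff_per_mcps": preset.randoms_coeff,
        "forward_rate_model": _params_dict(preset.forward_rate_model),
        "inverse_rate_model": _params_dict(preset.inverse_rate_model),
        "tof_fwhm_ps_vs_mcps": preset.tof_fwhm_anchors.tolist(),
        "energy_res_pct_vs_mcps": preset.energy_res_anchors.tolist(),
        "metadata": preset.metadata,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def _params_dict(p: ExpFitParams) -> dict:
    return {"a": p.a, "b": p.b, "c": p.c, "d": p.d,
            "r_squared": p.r_squared, "rmse": p.rmse, "direction": p.direction}
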