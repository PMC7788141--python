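"""End-to-end pipeline runs and figure rendering.

A single YAML config drives the stages (simulate → countrate → fit-rates →
tofres → routine → recon-demo); every stage's outputs land under the
config's ``out_dir`` and are recorded in a :class:`RunManifest` written as
``manifest.json`` — also on failure, with the error attached.  All
randomness derives from the config's ``seed``, so re-running a config
reproduces every numeric output bit for bit.
"""

from __future__ import annotations

import importlib.metadata
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import countrate, listmode, ratemodel, resolution, routine, tofrecon
from .errors import PetqcError
from .presets import load_preset

log = logging.getLogger("petqc")


@dataclass
class RunManifest:
    config: dict
    preset_names: list[str]
    seeds: dict
    package_version: str
    outputs: list[str] = field(default_factory=list)
    stage_seconds: dict = field(default_factory=dict)
    error: dict | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _load_config(config_path) -> dict:
    cfg = yaml.safe_load(Path(config_path).read_text())
    if not isinstance(cfg, dict):
        raise PetqcError("config must be a YAML mapping")
    for key in ("seed", "preset", "out_dir"):
        if key not in cfg:
            raise PetqcError(f"config missing required key {key!r}")
    return cfg


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute the configured stages; returns the manifest (also written to
    ``out_dir/manifest.json``)."""
    cfg = _load_config(config_path)
    preset = load_preset(cfg["preset"])  # validates before any stage runs
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    log.info("run: preset=%s seed=%d", preset.name, seed)
    log.info("forward model coefficients: %s", vars(preset.forward_rate_model))
    log.info("inverse model coefficients: %s", vars(preset.inverse_rate_model))

    manifest = RunManifest(
        config=cfg, preset_names=[preset.name], seeds={"root": seed},
        package_version=importlib.metadata.version("petqc"),
    )
    mpath = out / "manifest.json"
    try:
        _run_stages(cfg, preset, out, seed, manifest)
    except Exception as exc:  # manifest is written even on stage failure
        manifest.error = {"stage": getattr(exc, "_stage", "unknown"),
                          "message": str(exc)}
        manifest.write(mpath)
        raise
    manifest.outputs.append(str(mpath))
    manifest.write(mpath)
    return manifest


@contextmanager
def _stage(manifest: RunManifest, name: str):
    t0 = time.perf_counter()
    try:
        yield
    except Exception as exc:
        exc._stage = name
        raise
    finally:
        manifest.stage_seconds[name] = time.perf_counter() - t0


def _run_stages(cfg, preset, out, seed, manifest):
    phantom = listmode.PhantomSpec()

    sim = cfg.get("simulate", {})
    with _stage(manifest, "simulate"):
        series = listmode.simulate_decay_series(
            preset, phantom,
            initial_kbq_ml=float(sim.get("initial_kbq_ml", 45.0)),
            half_life_s=float(sim.get("half_life_s", 6586.2)),
            n_recordings=int(sim.get("n_recordings", 10)),
            seed=seed,
            events_per_recording=int(sim.get("events_per_recording", 40000)),
        )
        for i, lm in enumerate(series):
            path = out / f"recording_{i:02d}.h5"
            listmode.write_listmode(lm, path)
            manifest.outputs.append(str(path))
            manifest.seeds[f"recording_{i:02d}"] = lm.seed

    gate = float(cfg.get("countrate", {}).get("gate_mm", 20.0))
    with _stage(manifest, "countrate"):
        points = [countrate.compute_rate_point(lm, gate, preset) for lm in series]
        rates = countrate.rate_points_to_frame(points)
        rates_csv = out / "rates.csv"
        rates.to_csv(rates_csv, index=False)
        manifest.outputs.append(str(rates_csv))

    with _stage(manifest, "fit_rates"):
        act = rates["activity_kbq_ml"].to_numpy()[::-1]
        sng = rates["singles_mcps"].to_numpy()[::-1]
        fwd = ratemodel.fit_double_exponential(act, sng, direction="A_to_S")
        inv = ratemodel.fit_double_exponential(sng, act, direction="S_to_A")
        params_json = out / "params.json"
        params_json.write_text(json.dumps(
            {"A_to_S": vars(fwd), "S_to_A": vars(inv)}, indent=2))
        manifest.outputs.append(str(params_json))

    with _stage(manifest, "tofres"):
        bin_ps = float(cfg.get("tofres", {}).get("bin_ps", 10.0))
        res_rows = []
        first_hist = None
        for lm in series:
            try:
                tr = resolution.estimate_tof_resolution(lm, gate, bin_ps)
                er = resolution.estimate_energy_resolution(lm, gate)
            except PetqcError as exc:
                log.warning("resolution skipped at %.2f kBq/mL: %s",
                            lm.activity_kbq_ml, exc)
                continue
            if first_hist is None:
                first_hist = {"bin_edges_ps": tr.bin_edges.tolist(),
                              "counts": tr.counts.tolist()}
            res_rows.append({
                "activity_kbq_ml": lm.activity_kbq_ml,
                "singles_mcps": lm.mean_singles_mcps(),
                "tof_fwhm_ps": tr.fwhm, "energy_res_pct": er.fwhm,
                "n_events_used": tr.n_events_used,
            })
        res_json = out / "res.json"
        res_json.write_text(json.dumps(
            {"per_recording": res_rows, "example_histogram": first_hist},
            indent=2))
        manifest.outputs.append(str(res_json))

    with _stage(manifest, "routine"):
        rt = cfg.get("routine", {})
        frames = listmode.simulate_routine_frames(
            preset,
            median_activity_kbq_ml=float(rt.get("median_activity_kbq_ml", 2.9)),
            sigma_log=float(rt.get("sigma_log", 0.15)),
            n_frames=int(rt.get("n_frames", 1853)),
            seed=seed + 1,
        )
        manifest.seeds["routine"] = seed + 1
        dist = routine.summarize_rates(frames["singles_mcps"],
                                       labels={"camera": preset.name})
        lo, hi = routine.limits_to_activity(dist, preset)
        dist_json = out / "dist.json"
        dist_json.write_text(json.dumps({
            "labels": dist.labels, "median_mcps": dist.median,
            "q1_mcps": dist.q1, "q3_mcps": dist.q3,
            "lower_limit_mcps": dist.lower_limit,
            "upper_limit_mcps": dist.upper_limit,
            "n_samples": dist.n_samples, "n_outliers": dist.n_outliers,
            "lower_limit_kbq_ml": lo, "upper_limit_kbq_ml": hi,
        }, indent=2))
        manifest.outputs.append(str(dist_json))

    rd = cfg.get("recon_demo", {})
    if rd.get("enabled", False):
        with _stage(manifest, "recon_demo"):
            rcfg = tofrecon.ReconConfig(
                n_pixels=int(rd.get("n_pixels", 128)),
                pixel_mm=float(rd.get("pixel_mm", 2.5)),
                n_angles=int(rd.get("n_angles", 96)),
                n_subsets=int(rd.get("n_subsets", 10)),
                n_iterations=int(rd.get("n_iterations", 2)),
            )
            table = tofrecon.kernel_mismatch_experiment(
                rd.get("true_fwhm_ps", [300.0, 600.0]),
                float(rd.get("recon_kernel_ps", 300.0)),
                rcfg, seed=seed + 2,
                total_counts=float(rd.get("counts", 3e5)),
            )
            manifest.seeds["recon_demo"] = seed + 2
            recon_csv = out / "recon_metrics.csv"
            table.to_csv(recon_csv, index=False)
            manifest.outputs.append(str(recon_csv))


def render_report(manifest: RunManifest) -> list[Path]:
    """Render figure analogues from a completed run: NECR vs activity, the
    two rate-activity regressions, resolutions vs rate, and (when the demo
    ran) the kernel-mismatch metric panel."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outputs = {Path(p).name: Path(p) for p in manifest.outputs}
    missing = [n for n in ("rates.csv", "params.json", "res.json")
               if n not in outputs]
    if missing:
        raise PetqcError("missing pipeline outputs: " + ", ".join(missing))
    out_dir = Path(manifest.config["out_dir"])
    figures: list[Path] = []

    rates = pd.read_csv(outputs["rates.csv"])
    fig, ax = plt.subplots()
    if len(rates):
        ax.plot(rates["activity_kbq_ml"], rates["necr_mcps"], "o-", label="NECR")
        ax.plot(rates["activity_kbq_ml"], rates["trues_mcps"], "s--", label="T")
        ax.plot(rates["activity_kbq_ml"], rates["randoms_mcps"], "^--", label="R")
        ax.set_xlabel("activity concentration (kBq/mL)")
        ax.set_ylabel("rate (Mcps)")
        ax.legend()
        f = out_dir / "fig_necr.png"
        fig.savefig(f, dpi=110)
        figures.append(f)
    else:
        log.warning("empty rate series; NECR figure skipped")
    plt.close(fig)

    if len(rates):
        params = json.loads(outputs["params.json"].read_text())
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        a_grid = np.linspace(0.1, max(rates["activity_kbq_ml"].max(), 1.0), 100)
        fwd = ratemodel.ExpFitParams(**{k: params["A_to_S"][k] for k in "abcd"})
        axes[0].plot(rates["activity_kbq_ml"], rates["singles_mcps"], "o")
        axes[0].plot(a_grid, ratemodel.predict(fwd, a_grid), "-")
        axes[0].set_xlabel("activity (kBq/mL)")
        axes[0].set_ylabel("singles (Mcps)")
        inv = ratemodel.ExpFitParams(**{k: params["S_to_A"][k] for k in "abcd"})
        s_grid = np.linspace(0.1, max(rates["singles_mcps"].max(), 1.0), 100)
        axes[1].plot(rates["singles_mcps"], rates["activity_kbq_ml"], "o")
        axes[1].plot(s_grid, ratemodel.predict(inv, s_grid), "-")
        axes[1].set_xlabel("singles (Mcps)")
        axes[1].set_ylabel("activity (kBq/mL)")
        f = out_dir / "fig_rate_activity.png"
        fig.tight_layout(); fig.savefig(f, dpi=110); plt.close(fig)
        figures.append(f)
    else:
        log.warning("empty rate series; rate-activity figure skipped")

    res = json.loads(outputs["res.json"].read_text())
    rows = pd.DataFrame(res["per_recording"])
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    if len(rows):
        axes[0].plot(rows["singles_mcps"], rows["tof_fwhm_ps"], "o-")
        axes[1].plot(rows["singles_mcps"], rows["energy_res_pct"], "o-")
    axes[0].set_xlabel("singles (Mcps)"); axes[0].set_ylabel("TOF FWHM (ps)")
    axes[1].set_xlabel("singles (Mcps)"); axes[1].set_ylabel("energy res (%)")
    f = out_dir / "fig_resolution.png"
    fig.tight_layout(); fig.savefig(f, dpi=110); plt.close(fig)
    figures.append(f)

    if "dist.json" in outputs:
        dist = json.loads(outputs["dist.json"].read_text())
        fig, ax = plt.subplots()
        ax.bar(["lower", "median", "upper"],
               [dist["lower_limit_mcps"], dist["median_mcps"],
                dist["upper_limit_mcps"]])
        ax.set_ylabel("singles (Mcps)")
        ax.set_title("routine count-rate summary")
        f = out_dir / "fig_routine.png"
        fig.savefig(f, dpi=110); plt.close(fig)
        figures.append(f)

    if "recon_metrics.csv" in outputs:
        tab = pd.read_csv(outputs["recon_metrics.csv"])
        agg = tab.groupby(["true_fwhm_ps", "arm"])["snr"].mean().unstack()
        fig, ax = plt.subplots()
        agg.plot(ax=ax, marker="o")
        ax.set_xlabel("true timing FWHM (ps)"); ax.set_ylabel("mean sphere SNR")
        f = out_dir / "fig_kernel_mismatch.png"
        fig.savefig(f, dpi=110); plt.close(fig)
        figures.append(f)

    return figures
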