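"""Toy 2-D TOF-OSEM reconstructor.

A desk-scale parallel-beam reconstructor whose only purpose is to exhibit
the TOF effects of interest: the SNR advantage of TOF-weighted
reconstruction over non-TOF at equal iterations, and the contrast/SNR
degradation caused by reconstructing with a TOF kernel narrower than the
true timing spread of the data (kernel mismatch).

The TOF axis discretises the position of emission along each ray: the
measured time difference places the emission with a Gaussian uncertainty of
sigma = FWHM_ps * c / 2 / 2.355 millimetres, binned at ``tof_bin_ps``
picoseconds (3.75 mm at the 25-ps default).  Forward and back projections
rotate the image (bilinear), sum along rays, and spread/collect counts along
the TOF axis with a column-normalised Gaussian matrix truncated at 3 sigma.
No attenuation, scatter, randoms or detector blur is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DomainError
from .imagequality import (ImageVolume, default_iec_layout, measure_all_spheres,
                           synthetic_iec_image)
from .listmode import C_MM_PER_PS, FWHM_OVER_SIGMA

_EPS = 1e-12


@dataclass
class ReconConfig:
    n_pixels: int = 128
    pixel_mm: float = 2.5
    n_angles: int = 96
    n_subsets: int = 10
    n_iterations: int = 1          # 1 for TOF, 4 for noTOF by convention
    relaxation: float = 1.0
    tof_kernel_fwhm_ps: float | None = None   # None -> classic (noTOF) OSEM
    tof_bin_ps: float = 25.0
    true_timing_fwhm_ps: float | None = None  # timing spread of the data

    def __post_init__(self):
        if self.n_subsets < 1:
            raise DomainError("n_subsets must be >= 1")
        if not 0 < self.relaxation <= 2:
            raise DomainError("relaxation must be in (0, 2]")


@dataclass
class SinogramTOF:
    """Projection data: (n_angles, n_radial, n_tof) counts."""

    data: np.ndarray
    angles_deg: np.ndarray
    pixel_mm: float
    tof_bin_ps: float
    true_timing_fwhm_ps: float | None


def tof_bin_mm(tof_bin_ps: float) -> float:
    # a time difference dt localises the emission at dt*c/2 from midpoint
    return tof_bin_ps * C_MM_PER_PS / 2.0


def _n_tof_bins(n_pixels: int, pixel_mm: float, tof_bin_ps: float) -> int:
    n = int(np.ceil(n_pixels * pixel_mm / tof_bin_mm(tof_bin_ps)))
    return n + 1 - n % 2           # odd, so a bin is centred on the axis


def tof_kernel_matrix(
    fwhm_ps: float | None,
    n_pixels: int,
    pixel_mm: float,
    tof_bin_ps: float,
) -> np.ndarray:
    """K[tof_bin, along-ray pixel]: probability of a count from that pixel
    landing in that TOF bin.  Columns sum to 1; ``None`` FWHM collapses the
    TOF axis to a single bin (non-TOF)."""
    if fwhm_ps is None:
        return np.ones((1, n_pixels))
    n_tof = _n_tof_bins(n_pixels, pixel_mm, tof_bin_ps)
    bm = tof_bin_mm(tof_bin_ps)
    s_centers = (np.arange(n_tof) - (n_tof - 1) / 2.0) * bm
    y_centers = (np.arange(n_pixels) - (n_pixels - 1) / 2.0) * pixel_mm
    sigma = fwhm_ps * C_MM_PER_PS / 2.0 / FWHM_OVER_SIGMA
    diff = s_centers[:, None] - y_centers[None, :]
    K = np.exp(-0.5 * (diff / sigma) ** 2)
    K[np.abs(diff) > 3.0 * sigma] = 0.0
    colsum = K.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return K / colsum


def _angles(n_angles: int) -> np.ndarray:
    return np.arange(n_angles) * 180.0 / n_angles


def _rotate(img: np.ndarray, angle_deg: float) -> np.ndarray:
    return ndimage.rotate(img, angle_deg, reshape=False, order=1,
                          mode="constant", cval=0.0, prefilter=False)


def forward_project(
    image: np.ndarray,
    cfg: ReconConfig,
    timing_fwhm_ps: float | None,
    seed: int | None = None,
    total_counts: float | None = None,
) -> SinogramTOF:
    """TOF line integrals of a non-negative 2-D image.

    The emission position along each ray is smeared into TOF bins by a
    Gaussian of ``timing_fwhm_ps``; with ``total_counts`` set, the sinogram
    is scaled to that expectation and Poisson sampled (seeded).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape != (cfg.n_pixels, cfg.n_pixels):
        raise DomainError(f"image must be ({cfg.n_pixels}, {cfg.n_pixels})")
    if np.any(image < 0):
        raise DomainError("image must be non-negative")
    K = tof_kernel_matrix(timing_fwhm_ps, cfg.n_pixels, cfg.pixel_mm, cfg.tof_bin_ps)
    angles = _angles(cfg.n_angles)
    data = np.empty((cfg.n_angles, cfg.n_pixels, K.shape[0]))
    for i, ang in enumerate(angles):
        rot = _rotate(image, ang)
        data[i] = (K @ rot).T      # (n_radial, n_tof)
    if total_counts is not None:
        s = data.sum()
        if s > 0:
            data *= total_counts / s
        rng = np.random.default_rng(seed)
        data = rng.poisson(data).astype(float)
    return SinogramTOF(data=data, angles_deg=angles, pixel_mm=cfg.pixel_mm,
                       tof_bin_ps=cfg.tof_bin_ps,
                       true_timing_fwhm_ps=timing_fwhm_ps)


def reconstruct(sino: SinogramTOF, cfg: ReconConfig) -> ImageVolume:
    """TOF-weighted (or classic, if no kernel) OSEM reconstruction.

    Multiplicative updates with ``cfg.n_subsets`` angle-interleaved subsets;
    the relaxation parameter exponentiates the update factor (1.0 = plain
    OSEM).  Deterministic given inputs; non-negativity is preserved by
    construction.
    """
    n_ang, n_rad, n_tof = sino.data.shape
    if n_ang != cfg.n_angles or n_rad != cfg.n_pixels:
        raise DomainError("sinogram geometry does not match the recon config")
    K = tof_kernel_matrix(cfg.tof_kernel_fwhm_ps, cfg.n_pixels, cfg.pixel_mm,
                          cfg.tof_bin_ps)
    if cfg.tof_kernel_fwhm_ps is None:
        data = sino.data.sum(axis=2, keepdims=True)
    else:
        if K.shape[0] != n_tof:
            raise DomainError(
                f"TOF binning mismatch: sinogram has {n_tof} bins, "
                f"kernel expects {K.shape[0]}")
        data = sino.data

    n = cfg.n_pixels
    yy, xx = np.mgrid[0:n, 0:n]
    support = (xx - (n - 1) / 2) ** 2 + (yy - (n - 1) / 2) ** 2 <= (n / 2 - 1) ** 2

    subsets = [np.arange(s, cfg.n_angles, cfg.n_subsets)
               for s in range(cfg.n_subsets)]
    # per-subset sensitivity (backprojection of ones)
    sens = []
    for sub in subsets:
        acc = np.zeros((n, n))
        ones = np.ones((data.shape[2], n))
        for i in sub:
            acc += _rotate(K.T @ ones, -sino.angles_deg[i])
        sens.append(acc)

    img = np.where(support, 1.0, 0.0)
    for _ in range(cfg.n_iterations):
        for sub, sv in zip(subsets, sens):
            back = np.zeros((n, n))
            for i in sub:
                rot = _rotate(img, sino.angles_deg[i])
                fp = K @ rot                       # (n_tof, n_rad)
                ratio = data[i].T / np.maximum(fp, _EPS)
                back += _rotate(K.T @ ratio, -sino.angles_deg[i])
            factor = back / np.maximum(sv, _EPS)
            if cfg.relaxation != 1.0:
                factor = np.power(factor, cfg.relaxation, where=factor > 0,
                                  out=np.zeros_like(factor))
            img = np.where(support, img * factor, 0.0)
    return ImageVolume.centered(img, (1.0, cfg.pixel_mm, cfg.pixel_mm))


def tof_vs_notof_experiment(
    cfg: ReconConfig,
    timing_fwhm_ps: float,
    seeds,
    total_counts: float = 3e5,
    true_ratio: float = 4.0,
) -> pd.DataFrame:
    """Per-sphere SNR of matched-kernel TOF vs noTOF reconstructions of the
    same Poisson sinograms, at equal iterations.

    The TOF advantage is informational (the TOF axis of the data constrains
    emission positions), so it expresses itself near convergence; with very
    few iterations the under-converged noTOF image is smoother and the ratio
    can dip below 1.  Use a near-converged ``cfg.n_iterations`` (≈ 12 at the
    default geometry) when measuring the gain.
    """
    phantom = synthetic_iec_image(
        shape=(1, cfg.n_pixels, cfg.n_pixels),
        voxel_size_mm=(1.0, cfg.pixel_mm, cfg.pixel_mm),
        sphere_ratio=true_ratio,
    )
    layout = default_iec_layout(z_offsets_mm=(0.0,))
    rows = []
    for seed in seeds:
        sino = forward_project(phantom.values[0], cfg, timing_fwhm_ps,
                               seed=int(seed), total_counts=total_counts)
        rec_tof = reconstruct(sino, replace(cfg, tof_kernel_fwhm_ps=timing_fwhm_ps))
        rec_ntf = reconstruct(sino, replace(cfg, tof_kernel_fwhm_ps=None))
        mt = measure_all_spheres(rec_tof, layout, true_ratio)
        mn = measure_all_spheres(rec_ntf, layout, true_ratio)
        for t, n in zip(mt, mn):
            rows.append({
                "seed": int(seed), "diameter_mm": t.diameter_mm,
                "snr_tof": t.snr, "snr_notof": n.snr,
                "crc_tof_pct": t.crc_pct, "crc_notof_pct": n.crc_pct,
            })
    return pd.DataFrame(rows)


def kernel_mismatch_experiment(
    true_fwhm_list_ps,
    recon_kernel_ps: float,
    cfg: ReconConfig,
    seed: int,
    total_counts: float = 3e6,
    true_ratio: float = 4.0,
) -> pd.DataFrame:
    """CRC/SNR of matched-kernel vs fixed misfit-kernel TOF reconstructions.

    For each true timing FWHM, one Poisson sinogram of the 2-D IEC-like
    phantom is reconstructed twice: with a kernel matching the data's true
    FWHM and with the fixed ``recon_kernel_ps`` kernel.  Returns one row per
    (true FWHM, arm, sphere) with CRC (%) and SNR, tagged with the seed.
    """
    phantom = synthetic_iec_image(
        shape=(1, cfg.n_pixels, cfg.n_pixels),
        voxel_size_mm=(1.0, cfg.pixel_mm, cfg.pixel_mm),
        sphere_ratio=true_ratio,
    )
    layout = default_iec_layout(z_offsets_mm=(0.0,))
    rows = []
    for j, true_fwhm in enumerate(true_fwhm_list_ps):
        sino = forward_project(phantom.values[0], cfg, float(true_fwhm),
                               seed=seed * 1009 + j, total_counts=total_counts)
        for arm, kernel in (("matched", float(true_fwhm)),
                            ("misfit", float(recon_kernel_ps))):
            recon = reconstruct(sino, replace(cfg, tof_kernel_fwhm_ps=kernel))
            for m in measure_all_spheres(recon, layout, true_ratio):
                rows.append({
                    "true_fwhm_ps": float(true_fwhm), "arm": arm,
                    "recon_kernel_ps": kernel,
                    "diameter_mm": m.diameter_mm,
                    "crc_pct": m.crc_pct, "snr": m.snr, "seed": seed,
                })
    return pd.DataFrame(rows)
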