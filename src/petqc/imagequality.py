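"""IEC sphere-phantom image-quality metrics.

Contrast recovery coefficient, sphere signal-to-noise ratio and background
relative noise on volumetric (or single-slice) images of the IEC body
phantom:

    CRC_i = ((S_i/B_i - 1) / (a_H/a_c - 1)) * 100       [%]
    SNR_i = (S_i - B_i) / sigma_i
    RN    = sigma_37mm / B_37mm * 100                    [%]

where S_i is the mean over a circular 2-D ROI matching sphere i on the slice
through its centre, and B_i / sigma_i are the mean and standard deviation of
all voxels inside the background ROIs of the same diameter (12 transaxial
positions replicated on 5 slices = 60 ROIs for a volume; the 12 central-slice
positions for a single-slice image).  a_H/a_c is the true sphere-to-background
concentration ratio.  Voxels count as inside an ROI when their centre is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import DomainError

#: IEC sphere diameters (mm) and the radius of the circle they sit on
IEC_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
IEC_SPHERE_RING_RADIUS_MM = 57.2
#: synthetic body cross-section, ellipse semi-axes (x, y) mm
IEC_BODY_SEMI_AXES_MM = (145.0, 105.0)
IEC_LUNG_RADIUS_MM = 25.0


@dataclass
class ImageVolume:
    """Axis-aligned image volume; values are activity-proportional.

    ``values`` is (nz, ny, nx); ``voxel_size_mm`` and ``origin_mm`` are
    (z, y, x).  ``origin_mm`` is the world position of the centre of voxel
    (0, 0, 0).
    """

    values: np.ndarray
    voxel_size_mm: tuple
    origin_mm: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None]
        if any(v <= 0 for v in self.voxel_size_mm):
            raise DomainError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("image contains non-finite values")

    @classmethod
    def centered(cls, values, voxel_size_mm) -> "ImageVolume":
        """Volume whose world origin is at the grid centre."""
        values = np.asarray(values, dtype=float)
        if values.ndim == 2:
            values = values[None]
        vz, vy, vx = voxel_size_mm
        nz, ny, nx = values.shape
        origin = (-(nz - 1) / 2 * vz, -(ny - 1) / 2 * vy, -(nx - 1) / 2 * vx)
        return cls(values, tuple(voxel_size_mm), origin)

    def world_axes(self):
        nz, ny, nx = self.values.shape
        vz, vy, vx = self.voxel_size_mm
        oz, oy, ox = self.origin_mm
        return (oz + vz * np.arange(nz),
                oy + vy * np.arange(ny),
                ox + vx * np.arange(nx))

    def slice_index(self, z_mm: float) -> int:
        z = self.world_axes()[0]
        return int(np.argmin(np.abs(z - z_mm)))

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        vz, vy, vx = self.voxel_size_mm
        oz, oy, ox = self.origin_mm
        affine = np.diag([vx, vy, vz, 1.0])
        affine[:3, 3] = [ox, oy, oz]
        # NIfTI stores (x, y, z)
        nib.save(nib.Nifti1Image(self.values.T, affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ImageVolume":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).T
        aff = img.affine
        voxel = (float(aff[2, 2]), float(aff[1, 1]), float(aff[0, 0]))
        origin = (float(aff[2, 3]), float(aff[1, 3]), float(aff[0, 3]))
        return cls(data, voxel, origin)


@dataclass
class RoiLayout:
    """Sphere and background ROI placement, world mm.

    ``sphere_centers`` is (6, 3) as (x, y, z); ``background_centers`` is
    (n, 3) — the same centres serve every sphere diameter, with the ROI size
    matching the diameter being measured (NEMA convention).
    """

    sphere_centers: np.ndarray
    sphere_diameters: tuple = IEC_SPHERE_DIAMETERS_MM
    background_centers: np.ndarray = field(default=None)
    central_slice_z_mm: float = 0.0


@dataclass
class SphereMetrics:
    diameter_mm: float
    sphere_mean: float             # S_i
    background_mean: float         # B_i
    background_sd: float           # sigma_i
    crc_pct: float
    snr: float


def _sphere_centers(ring_radius: float = IEC_SPHERE_RING_RADIUS_MM,
                    z_mm: float = 0.0) -> np.ndarray:
    ang = np.deg2rad(np.arange(6) * 60.0)
    return np.column_stack([ring_radius * np.cos(ang),
                            ring_radius * np.sin(ang),
                            np.full(6, z_mm)])


def default_iec_layout(
    n_background: int = 12,
    z_offsets_mm: tuple = (-20.0, -10.0, 0.0, 10.0, 20.0),
    body_semi_axes_mm: tuple = IEC_BODY_SEMI_AXES_MM,
    max_roi_diameter_mm: float = 37.0,
    edge_margin_mm: float = 2.5,
    sphere_margin_mm: float = 2.0,
) -> RoiLayout:
    """NEMA-convention layout: spheres on the 57.2-mm ring, background ROI
    centres chosen deterministically on the central slice (well inside the
    body, clear of every sphere and of the lung insert) and replicated on the
    slices at the given z offsets.

    Pass ``z_offsets_mm=(0.0,)`` for a single-slice image (12 ROIs).
    """
    spheres = _sphere_centers()
    r_roi = max_roi_diameter_mm / 2.0
    ax, ay = body_semi_axes_mm
    candidates = []
    for radius in (65.0, 70.0, 75.0, 80.0, 85.0, 90.0, 95.0,
                   100.0, 105.0, 110.0, 115.0, 120.0):
        for ang_deg in range(0, 360, 10):
            a = np.deg2rad(ang_deg)
            x, y = radius * np.cos(a), radius * np.sin(a)
            inside = ((x / (ax - r_roi - edge_margin_mm)) ** 2
                      + (y / (ay - r_roi - edge_margin_mm)) ** 2) <= 1.0
            if not inside:
                continue
            d_sph = np.hypot(spheres[:, 0] - x, spheres[:, 1] - y).min()
            if d_sph < max_roi_diameter_mm + sphere_margin_mm:
                continue
            if np.hypot(x, y) < IEC_LUNG_RADIUS_MM + r_roi + sphere_margin_mm:
                continue
            candidates.append((ang_deg, radius, x, y))
    candidates.sort()
    chosen: list[tuple[float, float]] = []
    for _, _, x, y in candidates:
        if all(np.hypot(x - cx, y - cy) >= 1.5 * r_roi for cx, cy in chosen):
            chosen.append((x, y))
        if len(chosen) == n_background:
            break
    if len(chosen) < min(6, n_background):
        raise DomainError("could not place background ROIs inside the body")
    bg = np.array([(x, y, z) for z in z_offsets_mm for x, y in chosen])
    return RoiLayout(sphere_centers=spheres,
                     background_centers=bg, central_slice_z_mm=0.0)


def _circular_roi_values(image: ImageVolume, cx, cy, cz, diameter) -> np.ndarray:
    k = image.slice_index(cz)
    _, yw, xw = image.world_axes()
    if not (xw.min() - 1 <= cx <= xw.max() + 1 and yw.min() - 1 <= cy <= yw.max() + 1):
        raise DomainError(f"ROI at ({cx:.1f}, {cy:.1f}, {cz:.1f}) mm outside volume")
    yy, xx = np.meshgrid(yw, xw, indexing="ij")
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= (diameter / 2.0) ** 2
    if not mask.any():
        raise DomainError(
            f"ROI at ({cx:.1f}, {cy:.1f}, {cz:.1f}) mm contains no voxel centres")
    return image.values[k][mask]


def background_voxels(image: ImageVolume, layout: RoiLayout,
                      diameter_mm: float) -> np.ndarray:
    """Pooled voxel values of every background ROI of one diameter."""
    vals = [
        _circular_roi_values(image, cx, cy, cz, diameter_mm)
        for cx, cy, cz in np.atleast_2d(layout.background_centers)
    ]
    return np.concatenate(vals)


def measure_sphere(
    image: ImageVolume,
    layout: RoiLayout,
    diameter_mm: float,
    true_ratio: float = 4.0,
) -> SphereMetrics:
    """CRC and SNR of the sphere of the given diameter."""
    idx = list(layout.sphere_diameters).index(diameter_mm)
    cx, cy, cz = layout.sphere_centers[idx]
    s_i = float(np.mean(_circular_roi_values(image, cx, cy, cz, diameter_mm)))
    bg = background_voxels(image, layout, diameter_mm)
    b_i = float(np.mean(bg))
    sigma_i = float(np.std(bg, ddof=1))
    crc = (s_i / b_i - 1.0) / (true_ratio - 1.0) * 100.0 if b_i != 0 else float("nan")
    snr = (s_i - b_i) / sigma_i if sigma_i > 0 else 0.0
    return SphereMetrics(diameter_mm=diameter_mm, sphere_mean=s_i,
                         background_mean=b_i, background_sd=sigma_i,
                         crc_pct=crc, snr=snr)


def measure_all_spheres(image, layout, true_ratio: float = 4.0):
    return [measure_sphere(image, layout, d, true_ratio)
            for d in layout.sphere_diameters]


def background_noise(image: ImageVolume, layout: RoiLayout) -> float:
    """Background relative noise RN (%) from the 37-mm background ROIs."""
    bg = background_voxels(image, layout, 37.0)
    b = float(np.mean(bg))
    if b == 0:
        raise DomainError("zero background mean")
    return float(np.std(bg, ddof=1) / b * 100.0)


def tof_gain(metrics_tof, metrics_notof):
    """Per-sphere and averaged SNR gain of TOF over noTOF images.

    Returns ``(gains, mean_gain)``; a sphere with zero noTOF SNR gets NaN and
    is excluded from the average.
    """
    tof = {m.diameter_mm: m for m in metrics_tof}
    ntf = {m.diameter_mm: m for m in metrics_notof}
    if set(tof) != set(ntf):
        raise DomainError("TOF and noTOF metric sets cover different spheres")
    gains = {}
    for d in sorted(tof):
        denom = ntf[d].snr
        gains[d] = tof[d].snr / denom if denom != 0 else float("nan")
    vals = [g for g in gains.values() if np.isfinite(g)]
    mean = float(np.mean(vals)) if vals else float("nan")
    return gains, mean


def synthetic_iec_image(
    shape=(5, 128, 128),
    voxel_size_mm=(10.0, 2.5, 2.5),
    sphere_ratio: float = 4.0,
    background_level: float = 1.0,
    blur_fwhm_mm: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ImageVolume:
    """Synthetic IEC-like volume: elliptical warm body, cold lung insert, six
    hot spheres at ``sphere_ratio`` times the background, optional Gaussian
    partial-volume blur and additive Gaussian noise.

    With ``shape=(1, ny, nx)`` this doubles as the 2-D phantom for the toy
    reconstructor.
    """
    nz, ny, nx = shape
    vol = ImageVolume.centered(np.zeros(shape), voxel_size_mm)
    zw, yw, xw = vol.world_axes()
    zz, yy, xx = np.meshgrid(zw, yw, xw, indexing="ij")
    ax, ay = IEC_BODY_SEMI_AXES_MM
    body = (xx / ax) ** 2 + (yy / ay) ** 2 <= 1.0
    img = np.where(body, background_level, 0.0)
    img[np.hypot(xx, yy) <= IEC_LUNG_RADIUS_MM] = 0.0
    for (cx, cy, cz), d in zip(_sphere_centers(), IEC_SPHERE_DIAMETERS_MM):
        inside = ((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2) <= (d / 2) ** 2
        img[inside] = sphere_ratio * background_level
    if blur_fwhm_mm > 0:
        sig = blur_fwhm_mm / (2 * np.sqrt(2 * np.log(2)))
        img = ndimage.gaussian_filter(
            img, sigma=[sig / v for v in voxel_size_mm])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return ImageVolume.centered(img, voxel_size_mm)
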