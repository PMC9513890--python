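"""Synthetic angiography-like phantoms: bright tubular vessels with attached
saccular aneurysm bulges on a dark background.

A phantom emulates a vessel-extracted TOF-MRA volume: a handful of smooth
tubes along random spline centerlines, each optionally carrying an
ellipsoidal bulge that intersects the vessel wall.  Bulge diameters follow a
truncated lognormal law calibrated to a clinical aneurysm cohort (mean
5.468 mm, SD 3.283 mm, truncated to [2, 20] mm).  The label marks the bulge
voxels that do not belong to the parent tube lumen — ground truth covers the
aneurysm only, never the carrying vessel.

Intensity defaults are free parameters (clinical intensity statistics are
scanner-dependent): bright foreground with mild texture, near-zero
background, additive Gaussian noise, and an optional smooth multiplicative
bias field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage

from .imaging import BinaryMask, VolumeBundle, VolumeImage
from .voi import CONNECTIVITY_26

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "PlacementError",
    "sample_diameters",
    "generate_phantom",
    "generate_cohort",
    "desk_spec",
]


class PlacementError(RuntimeError):
    """An aneurysm could not be placed inside the volume."""


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom volume.

    Diameters are drawn from a lognormal whose underlying parameters are set
    so the *untruncated* law has the requested mean and SD; draws outside
    the truncation bounds are rejected and redrawn.
    """

    shape: tuple = (96, 96, 96)
    spacing: tuple = (0.5, 0.5, 0.5)
    n_vessels: int = 2
    vessel_radius_mm: tuple = (1.0, 2.5)
    n_aneurysms: int = 1
    aneurysm_diameter_mean_mm: float = 5.468
    aneurysm_diameter_sd_mm: float = 3.283
    aneurysm_diameter_bounds_mm: tuple = (2.0, 20.0)
    fixed_diameter_mm: float | None = None
    vessel_intensity: tuple = (1.0, 0.05)
    background_intensity: tuple = (0.05, 0.02)
    noise_sd: float = 0.03
    bias_field: bool = False
    bias_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or min(self.shape) < 32:
            raise ValueError(f"shape must be 3 components, each >= 32; got {self.shape}")
        if self.n_vessels < 1:
            raise ValueError("need at least one vessel")
        if self.n_aneurysms < 0:
            raise ValueError("n_aneurysms must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.aneurysm_diameter_bounds_mm
        if not (0 < lo < hi):
            raise ValueError("bad diameter truncation bounds")


@dataclass
class PhantomSample:
    """One generated phantom: image bundle, spec, and aneurysm records.

    ``aneurysm_records`` holds ``(center_mm, diameter_mm)`` per aneurysm in
    physical coordinates of the generated volume.
    """

    bundle: VolumeBundle
    spec: PhantomSpec
    aneurysm_records: list = field(default_factory=list)


def sample_diameters(n: int, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` aneurysm diameters (mm) from the truncated lognormal rule."""
    if spec.fixed_diameter_mm is not None:
        return np.full(n, float(spec.fixed_diameter_mm))
    m, s = spec.aneurysm_diameter_mean_mm, spec.aneurysm_diameter_sd_mm
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    sigma = np.sqrt(sigma2)
    lo, hi = spec.aneurysm_diameter_bounds_mm
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mean=mu, sigma=sigma, size=max(16, 2 * (n - filled)))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def _spline_centerline(shape_mm: np.ndarray, rng: np.random.Generator, n_pts: int) -> np.ndarray:
    """Smooth random curve crossing the volume, sampled densely (mm coords)."""
    axis = rng.integers(0, 3)
    margin = 0.08 * shape_mm
    ctrl = np.empty((5, 3))
    for i in range(5):
        ctrl[i] = rng.uniform(0.25 * shape_mm, 0.75 * shape_mm)
    # entry/exit pinned near opposite faces of one axis so the tube crosses
    ctrl[:, axis] = np.linspace(margin[axis], shape_mm[axis] - margin[axis], 5)
    jitter = rng.uniform(-0.08, 0.08, size=(5, 3)) * shape_mm
    jitter[0] = jitter[-1] = 0
    ctrl = np.clip(ctrl + jitter, margin, shape_mm - margin)
    tck, _ = interpolate.splprep(ctrl.T, k=3, s=0)
    u = np.linspace(0, 1, n_pts)
    return np.asarray(interpolate.splev(u, tck)).T


def _rasterize_points(points_mm: np.ndarray, shape, spacing) -> np.ndarray:
    """Binary volume marking the voxels nearest to the given mm points."""
    idx = np.floor(points_mm / spacing + 0.5).astype(int)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    vol = np.zeros(shape, dtype=bool)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return vol


def _tube_from_centerline(center_vol: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    dist = ndimage.distance_transform_edt(~center_vol, sampling=spacing)
    return dist <= radius_mm


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom volume deterministically from ``spec.seed``.

    Raises :class:`PlacementError` if an aneurysm cannot be placed without
    leaving the volume after 100 attempts.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    shape_mm = np.asarray(shape) * spacing

    # --- vessels -----------------------------------------------------------
    n_pts = int(np.ceil(shape_mm.max() / (0.4 * spacing.min()))) + 50
    centerlines, radii, tubes = [], [], []
    lumen = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_vessels):
        cl = _spline_centerline(shape_mm, rng, n_pts)
        r = float(rng.uniform(*spec.vessel_radius_mm))
        tube = _tube_from_centerline(_rasterize_points(cl, shape, spacing), r, spacing)
        centerlines.append(cl)
        radii.append(r)
        tubes.append(tube)
        lumen |= tube

    # --- aneurysms ---------------------------------------------------------
    diameters = sample_diameters(spec.n_aneurysms, spec, rng)
    coords_mm = [np.arange(shape[a]) * spacing[a] for a in range(3)]
    grid = np.meshgrid(*coords_mm, indexing="ij")
    label = np.zeros(shape, dtype=bool)
    records = []
    for d in diameters:
        placed = False
        for _ in range(100):
            v = int(rng.integers(0, spec.n_vessels))
            cl, r_v = centerlines[v], radii[v]
            k = int(rng.integers(int(0.2 * len(cl)), int(0.8 * len(cl))))
            point = cl[k]
            tangent = cl[min(k + 1, len(cl) - 1)] - cl[max(k - 1, 0)]
            tangent /= np.linalg.norm(tangent) + 1e-12
            raw = rng.normal(size=3)
            normal = raw - np.dot(raw, tangent) * tangent
            nn = np.linalg.norm(normal)
            if nn < 1e-6:
                continue
            normal /= nn
            radius = d / 2.0
            center = point + (r_v + 0.6 * radius) * normal
            # mild axis jitter, volume-preserving, keeps d_eq at the target
            ax = radius * rng.uniform(0.85, 1.15, size=3)
            ax *= radius / np.prod(ax) ** (1.0 / 3.0)
            if np.any(center - ax.max() < spacing) or np.any(center + ax.max() > shape_mm - spacing):
                continue
            q = sum(((grid[a] - center[a]) / ax[a]) ** 2 for a in range(3))
            bulge = q <= 1.0
            new_label = bulge & ~lumen
            if not new_label.any() or (new_label & label).any():
                continue
            comp_n = ndimage.label(new_label, structure=CONNECTIVITY_26)[1]
            if comp_n != 1:
                continue
            label |= new_label
            lumen |= bulge
            records.append((tuple(float(c) for c in center), float(d)))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place a {d:.1f} mm aneurysm in a "
                f"{tuple(np.round(shape_mm, 1))} mm volume after 100 attempts"
            )

    # --- intensities -------------------------------------------------------
    foreground = lumen  # tubes plus bulges
    ind = ndimage.gaussian_filter(foreground.astype(np.float64), sigma=0.6)
    fg_mean, fg_sd = spec.vessel_intensity
    bg_mean, bg_sd = spec.background_intensity
    img = (
        rng.normal(bg_mean, bg_sd, size=shape) * (1.0 - ind)
        + rng.normal(fg_mean, fg_sd, size=shape) * ind
    )
    if spec.bias_field:
        rough = rng.normal(size=tuple(max(2, s // 16) for s in shape))
        bias = ndimage.zoom(rough, np.asarray(shape) / np.asarray(rough.shape), order=1)
        bias = ndimage.gaussian_filter(bias, sigma=4.0)
        bias = bias / (np.abs(bias).max() + 1e-12)
        img *= 1.0 + spec.bias_amplitude * bias
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=shape)

    vessel = VolumeImage(data=img.astype(np.float32), spacing=spacing)
    mask = BinaryMask(data=label.astype(np.uint8), spacing=spacing)
    return PhantomSample(
        bundle=VolumeBundle(vessel=vessel, label=mask, contour=None),
        spec=spec,
        aneurysm_records=records,
    )


def generate_cohort(n: int, spec_template: PhantomSpec, seed: int) -> list:
    """Generate ``n`` phantoms with per-sample seeds derived from ``seed``.

    Per-sample seeds come from a :class:`numpy.random.SeedSequence` spawned
    from ``(seed, index)``, so cohorts are reproducible at any size and
    samples are pairwise distinct.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    out = []
    for i in range(n):
        sub = int(np.random.SeedSequence(entropy=(seed, i)).generate_state(1)[0] % (2 ** 31))
        spec_i = dataclasses.replace(spec_template, seed=sub)
        try:
            out.append(generate_phantom(spec_i))
        except PlacementError as err:
            raise PlacementError(f"sample {i}: {err}") from err
    return out


def desk_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Small-volume preset for CPU-scale runs: 64 voxels at 0.75 mm.

    The coarser spacing keeps the 48 mm physical extent of the default
    phantom while quartering the voxel count, so whole cohorts fit in
    minutes on one CPU.
    """
    kw = dict(shape=(64, 64, 64), spacing=(0.75, 0.75, 0.75), seed=seed)
    kw.update(overrides)
    return PhantomSpec(**kw)
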