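"""Synthetic rCBF-SPECT brain phantoms with known ground truth.

The phantom emulates the gross appearance of a perfusion SPECT brain volume:
a high-uptake cortical shell over lower-uptake white matter, a cold ventricle,
a posterior-inferior cerebellum, Gaussian PSF blur and Poisson counting noise.
Geometry is analytic (a cerebral ellipsoid unioned with a cerebellar
ellipsoid) so that the true outer surface, lobe masks, and corresponding
landmark sets are available exactly.

Landmarks are laid out as closed rings in sagittal (constant-``x``) planes,
the way brain outlines are traced slice by slice, with 14 rings of 39 points
(546 total) by default.  The outer surface is star-shaped about the cerebral
cross-section centre in every sagittal slice, so each ring is a single closed
curve and a radius function ``r(x, theta)`` describes the whole surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .regions import (
    CEREBELLUM_DX,
    CEREBELLUM_SIN,
    REGIONS,
)
from .shape_model import LandmarkSet
from .volume import Volume

DEFAULT_N_RINGS = 14
DEFAULT_N_THETA = 39  # 14 * 39 = 546 landmarks


class GeometryError(ValueError):
    """Phantom compartment falls outside the voxel grid or is degenerate."""


@dataclass
class Uptake:
    """Relative tracer uptake per tissue compartment (arbitrary count units)."""

    cortex: float = 100.0
    white: float = 40.0
    ventricle: float = 0.0
    cerebellum: float = 100.0
    background: float = 0.0

    def validate(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"uptake.{name} must be >= 0")


@dataclass
class PhantomSpec:
    """Geometry + acquisition parameters of a synthetic brain volume.

    Distances are mm in the world frame of :class:`~asmbrain.volume.Volume`
    (origin at the volume centre; +x left, +y anterior, +z superior).
    """

    grid_size: int = 128
    voxel_mm: float = 2.0
    brain_center: tuple[float, float, float] = (0.0, 8.0, 10.0)
    brain_axes_mm: tuple[float, float, float] = (62.0, 80.0, 52.0)
    cortex_thickness_mm: float = 10.0
    cerebellum_center: tuple[float, float, float] = (0.0, -52.0, -28.0)
    cerebellum_axes_mm: tuple[float, float, float] = (38.0, 32.0, 26.0)
    ventricle_center: tuple[float, float, float] = (0.0, 10.0, 8.0)
    ventricle_axes_mm: tuple[float, float, float] = (14.0, 22.0, 12.0)
    uptake: Uptake = field(default_factory=Uptake)
    psf_fwhm_mm: float = 10.0   # camera resolution, FWHM of the Gaussian PSF
    counts_scale: float = 1.0   # expected counts per uptake unit; 0 = noiseless
    rotation_deg: float = 0.0   # applied in-sagittal-plane tilt (ground truth)
    seed: int = 0
    n_rings: int = DEFAULT_N_RINGS
    n_theta: int = DEFAULT_N_THETA
    # lobe-boundary fractions of the cerebral semi-axes (see regions module)
    frontal_y_frac: float = 0.34
    occipital_y_frac: float = -0.60
    parietal_z_frac: float = 0.15
    medial_x_frac: float = 0.22

    def __post_init__(self) -> None:
        self.uptake.validate()
        half = self.grid_size * self.voxel_mm / 2.0
        for name, centre, axes in [
            ("brain", self.brain_center, self.brain_axes_mm),
            ("cerebellum", self.cerebellum_center, self.cerebellum_axes_mm),
            ("ventricle", self.ventricle_center, self.ventricle_axes_mm),
        ]:
            if any(a <= 0 for a in axes):
                raise GeometryError(f"{name} semi-axes must be positive")
            if any(abs(c) + a > half for c, a in zip(centre, axes)):
                raise GeometryError(f"{name} compartment does not fit inside the grid")
        if self.cortex_thickness_mm <= 0:
            raise GeometryError("cortex thickness must be positive")

    @property
    def n_landmarks(self) -> int:
        return self.n_rings * self.n_theta


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom volume."""

    surface_landmarks: LandmarkSet
    brain_mask: np.ndarray          # bool, outer-surface interior
    lobe_masks: dict[str, np.ndarray]  # bool masks over the cortical shell
    true_rotation_deg: float
    ventricle_fraction: float       # ventricle voxels / brain voxels
    n_theta: int


# ---------------------------------------------------------------------------
# analytic surface geometry


def _ellipse_ray_far_root(dy, dz, uy, uz, p, q):
    """Largest non-negative ray parameter where origin+rho*u meets the ellipse
    centred at -d with semi-axes (p, q); NaN where the ray misses it."""
    A = (uy / p) ** 2 + (uz / q) ** 2
    B = 2.0 * (dy * uy / p**2 + dz * uz / q**2)
    C = (dy / p) ** 2 + (dz / q) ** 2 - 1.0
    disc = B**2 - 4.0 * A * C
    with np.errstate(invalid="ignore"):
        root = (-B + np.sqrt(disc)) / (2.0 * A)
    root = np.where((disc >= 0) & (root >= 0), root, np.nan)
    return root


def _analytic_slice(spec: PhantomSpec, x: float):
    """Return (yc, zc, r(uy, uz)) for the sagittal slice at ``x``; None if the
    slice misses the brain entirely.  ``r`` takes unit direction components and
    returns the outer union radius from the cerebral cross-section centre."""
    bc, ba = spec.brain_center, spec.brain_axes_mm
    cc, ca = spec.cerebellum_center, spec.cerebellum_axes_mm
    f2 = 1.0 - ((x - bc[0]) / ba[0]) ** 2
    if f2 <= 0:
        return None
    f = np.sqrt(f2)
    yc, zc = bc[1], bc[2]
    p_b, q_b = ba[1] * f, ba[2] * f
    g2 = 1.0 - ((x - cc[0]) / ca[0]) ** 2
    has_cb = g2 > 0
    if has_cb:
        g = np.sqrt(g2)
        p_c, q_c = ca[1] * g, ca[2] * g
        d_cy, d_cz = yc - cc[1], zc - cc[2]

    def radius(uy, uz):
        r = _ellipse_ray_far_root(0.0, 0.0, uy, uz, p_b, q_b)
        if has_cb:
            r_cb = _ellipse_ray_far_root(d_cy, d_cz, uy, uz, p_c, q_c)
            r = np.fmax(r, r_cb)
        return np.nan_to_num(r, nan=0.0)

    return yc, zc, radius


def base_landmarks(spec: PhantomSpec) -> LandmarkSet:
    """Landmarks on the analytic outer surface: ``n_rings`` sagittal rings of
    ``n_theta`` points, ring stations at ``x = cx + ax * cos(phi_i)`` with
    ``phi_i = pi (i + 1/2) / n_rings``."""
    bc, ba = spec.brain_center, spec.brain_axes_mm
    phi = np.pi * (np.arange(spec.n_rings) + 0.5) / spec.n_rings
    stations = bc[0] + ba[0] * np.cos(phi)
    theta = 2.0 * np.pi * np.arange(spec.n_theta) / spec.n_theta
    uy, uz = np.cos(theta), np.sin(theta)
    pts = np.empty((spec.n_rings, spec.n_theta, 3))
    for i, x in enumerate(stations):
        sl = _analytic_slice(spec, float(x))
        if sl is None:  # pragma: no cover - stations are strictly interior
            raise GeometryError("ring station outside brain extent")
        yc, zc, radius = sl
        r = radius(uy, uz)
        pts[i, :, 0] = x
        pts[i, :, 1] = yc + r * uy
        pts[i, :, 2] = zc + r * uz
    return LandmarkSet(pts.reshape(-1, 3))


# ---------------------------------------------------------------------------
# landmark-interpolated surface (for volumes synthesized from a shape model)


class _RingSurface:
    """Radius interpolator built from a ring-structured landmark set."""

    def __init__(self, landmarks: LandmarkSet, n_theta: int):
        pts = landmarks.points
        n_rings = len(pts) // n_theta
        pts = pts.reshape(n_rings, n_theta, 3)
        order = np.argsort(pts[:, :, 0].mean(axis=1))
        pts = pts[order]
        self.stations = pts[:, :, 0].mean(axis=1)
        self.centers = pts[:, :, 1:].mean(axis=1)
        rel = pts[:, :, 1:] - self.centers[:, None, :]
        self.theta = np.arctan2(rel[:, :, 1], rel[:, :, 0])
        self.r = np.hypot(rel[:, :, 0], rel[:, :, 1])
        # estimated pole positions assuming an elliptical x-profile
        n = len(self.stations)
        cosphi = np.cos(np.pi / (2.0 * n))
        cx = 0.5 * (self.stations[0] + self.stations[-1])
        self.ax_est = max(
            (self.stations[-1] - cx) / cosphi, (cx - self.stations[0]) / cosphi
        )
        self.cx = cx

    def _ring_radius(self, i: int, t: np.ndarray) -> np.ndarray:
        order = np.argsort(self.theta[i])
        th = self.theta[i][order]
        rr = self.r[i][order]
        th_ext = np.concatenate([th - 2 * np.pi, th, th + 2 * np.pi])
        rr_ext = np.concatenate([rr, rr, rr])
        return np.interp(t, th_ext, rr_ext)

    def slice(self, x: float):
        """(yc, zc, r(t)) at sagittal position x, or None outside the poles."""
        s = self.stations
        rel2 = 1.0 - ((x - self.cx) / self.ax_est) ** 2
        if rel2 <= 0:
            return None
        if x <= s[0] or x >= s[-1]:
            i = 0 if x <= s[0] else len(s) - 1
            end2 = 1.0 - ((s[i] - self.cx) / self.ax_est) ** 2
            fac = np.sqrt(max(rel2, 0.0) / end2)
            yc, zc = self.centers[i]
            return yc, zc, lambda t, i=i, fac=fac: fac * self._ring_radius(i, t)
        j = int(np.searchsorted(s, x)) - 1
        w = (x - s[j]) / (s[j + 1] - s[j])
        yc, zc = (1 - w) * self.centers[j] + w * self.centers[j + 1]

        def radius(t, j=j, w=w):
            return (1 - w) * self._ring_radius(j, t) + w * self._ring_radius(j + 1, t)

        return yc, zc, radius


# ---------------------------------------------------------------------------
# voxel composition


def _grid_coords(spec: PhantomSpec):
    n = spec.grid_size
    c = (np.arange(n) - (n - 1) / 2.0) * spec.voxel_mm
    return c


def _rotation_yz(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def _ellipsoid_mask(points, centre, axes) -> np.ndarray:
    q = ((points - np.asarray(centre)) / np.asarray(axes)) ** 2
    return q.sum(axis=-1) <= 1.0


def _compose(spec: PhantomSpec, slice_fn):
    """Paint compartments slice by slice from a star-shaped radius function.

    ``slice_fn(x)`` returns ``(yc, zc, radius_callable)`` or None.  Geometry is
    evaluated in the *unrotated* frame; the phantom tilt ``rotation_deg`` is
    applied by rotating the query coordinates, so no resampling is involved.
    """
    n = spec.grid_size
    coords = _grid_coords(spec)
    Y, Z = np.meshgrid(coords, coords, indexing="ij")
    Rinv = _rotation_yz(-spec.rotation_deg)
    img = np.full((n, n, n), spec.uptake.background, dtype=np.float64)
    brain = np.zeros((n, n, n), dtype=bool)
    shell = np.zeros((n, n, n), dtype=bool)
    cb = np.zeros((n, n, n), dtype=bool)
    vent = np.zeros((n, n, n), dtype=bool)
    for ix, x in enumerate(coords):
        Yu = Rinv[0, 0] * Y + Rinv[0, 1] * Z
        Zu = Rinv[1, 0] * Y + Rinv[1, 1] * Z
        sl = slice_fn(float(x))
        if sl is None:
            continue
        yc, zc, radius = sl
        dy, dz = Yu - yc, Zu - zc
        rho = np.hypot(dy, dz)
        with np.errstate(invalid="ignore", divide="ignore"):
            uy = np.where(rho > 0, dy / rho, 1.0)
            uz = np.where(rho > 0, dz / rho, 0.0)
        if getattr(radius, "takes_uv", False):
            r = radius(uy, uz)
        else:
            r = radius(np.arctan2(dz, dy))
        inside = rho <= r
        inner = rho <= np.maximum(r - spec.cortex_thickness_mm, 0.0)
        pts = np.stack([np.full_like(Yu, x), Yu, Zu], axis=-1)
        in_cb = _ellipsoid_mask(pts, spec.cerebellum_center, spec.cerebellum_axes_mm)
        in_vent = _ellipsoid_mask(pts, spec.ventricle_center, spec.ventricle_axes_mm)
        sh = inside & ~inner
        sl_img = img[ix]
        sl_img[inner] = spec.uptake.white
        sl_img[sh & ~in_cb] = spec.uptake.cortex
        sl_img[sh & in_cb] = spec.uptake.cerebellum
        sl_img[inner & in_vent] = spec.uptake.ventricle
        brain[ix] = inside
        shell[ix] = sh
        cb[ix] = inside & in_cb
        vent[ix] = inside & in_vent
    return img, brain, shell, cb, vent


def _analytic_slice_fn(spec: PhantomSpec):
    def slice_fn(x: float):
        sl = _analytic_slice(spec, x)
        if sl is None:
            return None
        yc, zc, radius = sl

        def rad(uy, uz):
            return radius(uy, uz)

        rad.takes_uv = True
        return yc, zc, rad

    return slice_fn


def _apply_blur_noise(spec: PhantomSpec, img: np.ndarray, seed: int | None = None) -> np.ndarray:
    if spec.psf_fwhm_mm > 0:
        sigma = spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spec.voxel_mm
        img = gaussian_filter(img, sigma=sigma, mode="constant")
    if spec.counts_scale > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        img = rng.poisson(np.maximum(img, 0.0) * spec.counts_scale) / spec.counts_scale
    return img


def _lobe_masks(spec: PhantomSpec, shell: np.ndarray, cb: np.ndarray) -> dict[str, np.ndarray]:
    from .regions import label_points_geometric

    coords = _grid_coords(spec)
    idx = np.argwhere(shell)
    pts = coords[idx]  # (M, 3) world mm; rotate back to the anatomical frame
    Rinv = _rotation_yz(-spec.rotation_deg)
    yz = pts[:, 1:] @ Rinv.T
    pts_u = np.column_stack([pts[:, 0], yz])
    labels = label_points_geometric(pts_u, spec, in_cerebellum=cb[shell])
    masks = {}
    for r, region in enumerate(REGIONS):
        m = np.zeros(shell.shape, dtype=bool)
        sel = idx[labels == r]
        m[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        masks[region] = m
    return masks


def generate_brain_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Full phantom: compartment image -> PSF blur -> Poisson noise, plus truth."""
    img, brain, shell, cb, vent = _compose(spec, _analytic_slice_fn(spec))
    lm = base_landmarks(spec)
    if spec.rotation_deg != 0.0:
        R = _rotation_yz(spec.rotation_deg)
        pts = lm.points.copy()
        pts[:, 1:] = pts[:, 1:] @ R.T
        lm = LandmarkSet(pts)
    vol = Volume(_apply_blur_noise(spec, img), (spec.voxel_mm,) * 3)
    truth = PhantomTruth(
        surface_landmarks=lm,
        brain_mask=brain,
        lobe_masks=_lobe_masks(spec, shell, cb),
        true_rotation_deg=spec.rotation_deg,
        ventricle_fraction=float(vent.sum()) / max(int(brain.sum()), 1),
        n_theta=spec.n_theta,
    )
    return vol, truth


def generate_lobe_phantom(spec: PhantomSpec, region: str) -> Volume:
    """Noiseless, unblurred volume with uptake only in one atlas region's part
    of the cortical shell (zero elsewhere); used to assign landmarks to lobes."""
    if region not in REGIONS:
        raise KeyError(f"unknown region {region!r}; expected one of {REGIONS}")
    img, brain, shell, cb, vent = _compose(spec, _analytic_slice_fn(spec))
    masks = _lobe_masks(spec, shell, cb)
    out = np.zeros_like(img)
    m = masks[region]
    value = (
        spec.uptake.cerebellum
        if region in (CEREBELLUM_DX, CEREBELLUM_SIN)
        else spec.uptake.cortex
    )
    out[m] = value
    return Volume(out, (spec.voxel_mm,) * 3)


def generate_phantom_from_landmarks(
    landmarks: LandmarkSet, spec: PhantomSpec, seed: int | None = None
) -> tuple[Volume, np.ndarray]:
    """Voxelize an arbitrary ring-structured landmark surface into a phantom.

    The outer surface follows the landmark rings (bilinear radius
    interpolation across stations and angles); compartment shading, blur and
    noise follow ``spec``.  Returns the volume and its brain mask.
    """
    surf = _RingSurface(landmarks, spec.n_theta)
    img, brain, shell, cb, vent = _compose(spec, surf.slice)
    vol = Volume(_apply_blur_noise(spec, img, seed=seed), (spec.voxel_mm,) * 3)
    return vol, brain


def interior_mask(
    landmarks: LandmarkSet, n_theta: int, grid_size: int, voxel_mm: float
) -> np.ndarray:
    """Boolean mask of the voxels enclosed by a ring-structured surface."""
    surf = _RingSurface(landmarks, n_theta)
    coords = (np.arange(grid_size) - (grid_size - 1) / 2.0) * voxel_mm
    Y, Z = np.meshgrid(coords, coords, indexing="ij")
    mask = np.zeros((grid_size,) * 3, dtype=bool)
    for ix, x in enumerate(coords):
        sl = surf.slice(float(x))
        if sl is None:
            continue
        yc, zc, radius = sl
        dy, dz = Y - yc, Z - zc
        rho = np.hypot(dy, dz)
        mask[ix] = rho <= radius(np.arctan2(dz, dy))
    return mask


@dataclass
class ShapeVariation:
    """Generative degrees of freedom for synthetic training surfaces.

    Six independent draws per subject: three per-axis size factors, a
    superior-inferior bend, an anterior-posterior slant, and a cerebellar
    size factor.  All deformations are mirror-symmetric in x and preserve the
    sagittal ring structure of the landmarks.
    """

    axis_scale_sd: float = 0.05       # relative SD of each semi-axis
    bend_sd_mm: float = 4.0           # z-shift amplitude ~ (y/ay)^2
    slant_sd_mm: float = 4.0          # y-shift amplitude ~ (z/az)^2
    cerebellum_scale_sd: float = 0.08

    def n_dof(self) -> int:
        return sum(
            int(v > 0)
            for v in (
                self.axis_scale_sd,
                self.axis_scale_sd,
                self.axis_scale_sd,
                self.bend_sd_mm,
                self.slant_sd_mm,
                self.cerebellum_scale_sd,
            )
        )


def generate_training_set(
    n: int,
    base_spec: PhantomSpec | None = None,
    variation: ShapeVariation | None = None,
    seed: int = 0,
) -> list[LandmarkSet]:
    """Sample ``n`` corresponding landmark sets with realistic shape spread.

    Correspondence is preserved by construction (every set uses the same ring
    parameterization of its deformed surface).  Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("need n >= 2 training shapes")
    spec = base_spec or PhantomSpec()
    var = variation or ShapeVariation()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        sx, sy, sz = 1.0 + var.axis_scale_sd * rng.standard_normal(3)
        bend = var.bend_sd_mm * rng.standard_normal()
        slant = var.slant_sd_mm * rng.standard_normal()
        scb = 1.0 + var.cerebellum_scale_sd * rng.standard_normal()
        axes = tuple(a * s for a, s in zip(spec.brain_axes_mm, (sx, sy, sz)))
        cb_axes = tuple(a * scb for a in spec.cerebellum_axes_mm)
        sub = replace(spec, brain_axes_mm=axes, cerebellum_axes_mm=cb_axes)
        pts = base_landmarks(sub).points.copy()
        cy, cz = spec.brain_center[1], spec.brain_center[2]
        ay, az = axes[1], axes[2]
        pts[:, 2] += bend * ((pts[:, 1] - cy) / ay) ** 2
        pts[:, 1] += slant * ((pts[:, 2] - cz) / az) ** 2
        out.append(LandmarkSet(pts))
    return out
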