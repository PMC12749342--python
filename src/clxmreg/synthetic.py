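"""Synthetic correlative FM/SXT scene generator.

Emulates the study conditions of a correlative cryo-imaging experiment on a
desk scale: fields of circular lipid droplets (radii from a few hundred
nanometres up to a micron) that appear as bright PSF-blurred blobs in
epifluorescence (~120 nm/px sampling) and as dark, optionally ring-like
absorption features in soft X-ray projections (~29 nm/px).  A ground-truth
moving→reference transform (affine plus a capped thin-plate-spline local
distortion) links the two modalities, so every downstream estimate —
segmentation centroids, registration parameters, leave-one-out errors — can
be checked against known truth.

Conventions
-----------
* The droplet scene lives in the *reference* (SXT) physical frame.
* ``GroundTruthTransform`` maps FM (moving) physical coordinates to SXT
  (reference) coordinates — the same direction the registration estimates.
  FM droplet positions are therefore obtained by the inverse map, and a
  ground-truth translation of +x shifts the rendered FM content by −x.
* All rendering is anti-aliased by 4× supersampling followed by box
  averaging, so noise-free centroids are accurate to well under a pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InputError, PackingError
from .image import AxisMeaning, ImagePlane, ImageStack, Modality
from .transforms import AffineTransform2D, WarpModel


# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------

@dataclass
class DropletScene:
    """Ground-truth droplet field in the reference physical frame (nm)."""

    field_size_nm: Tuple[float, float]  # (width, height)
    droplets: List[Tuple[float, float, float]]  # (cx_nm, cy_nm, radius_nm)
    seed: int = 0

    @property
    def positions_nm(self) -> np.ndarray:
        return np.array([(d[0], d[1]) for d in self.droplets], dtype=float)

    @property
    def radii_nm(self) -> np.ndarray:
        return np.array([d[2] for d in self.droplets], dtype=float)

    def to_dict(self) -> dict:
        return {
            "field_size_nm": list(self.field_size_nm),
            "droplets": [list(d) for d in self.droplets],
            "seed": self.seed,
        }


def sample_scene(n_droplets: int,
                 field_size_nm: Tuple[float, float],
                 radius_range_nm: Tuple[float, float],
                 min_sep_nm: float = 0.0,
                 seed: int = 0,
                 margin_nm: float = 0.0,
                 max_attempts_per_droplet: int = 2000) -> DropletScene:
    """Rejection-sample non-overlapping droplets fully inside the field.

    ``margin_nm`` keeps droplet centres at least ``radius + margin`` from the
    field edge — useful when the moving modality will be displaced by a
    ground-truth transform and every droplet must remain visible in both
    renders.  Raises :class:`PackingError` if the geometry is infeasible
    within the attempt budget.
    """
    if n_droplets < 1:
        raise InputError("n_droplets must be >= 1")
    rmin, rmax = radius_range_nm
    if not (0 < rmin <= rmax):
        raise InputError(f"bad radius range {radius_range_nm}")
    w, h = field_size_nm
    rng = np.random.default_rng(seed)
    placed: List[Tuple[float, float, float]] = []
    attempts = 0
    budget = n_droplets * max_attempts_per_droplet
    while len(placed) < n_droplets:
        if attempts >= budget:
            raise PackingError(
                f"could not place {n_droplets} droplets of radii {radius_range_nm} nm "
                f"with min separation {min_sep_nm} nm in a {w}x{h} nm field "
                f"after {attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(rmin, rmax)
        lo = r + margin_nm
        if w - 2 * lo <= 0 or h - 2 * lo <= 0:
            continue
        cx = rng.uniform(lo, w - lo)
        cy = rng.uniform(lo, h - lo)
        ok = all(math.hypot(cx - px, cy - py) >= min_sep_nm for px, py, _ in placed)
        if ok:
            placed.append((cx, cy, r))
    return DropletScene(field_size_nm=tuple(field_size_nm), droplets=placed, seed=seed)


# ---------------------------------------------------------------------------
# ground-truth transform
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthTransform:
    """True moving→reference (FM→SXT) map: affine plus capped local warp."""

    affine: AffineTransform2D
    local_warp: Optional[WarpModel] = None
    warp_cap_nm: float = 0.0
    seed: int = 0

    def apply(self, pts) -> np.ndarray:
        """Map moving-frame points to the reference frame."""
        out = self.affine.apply(pts)
        if self.local_warp is not None:
            out = self.local_warp.apply(out)
        return out

    def inverse_map(self, pts) -> np.ndarray:
        """Map reference-frame points back to the moving frame."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if self.local_warp is not None:
            pts = self.local_warp.apply_inverse(pts)
        return self.affine.inverse().apply(pts)

    def to_dict(self) -> dict:
        return {
            "affine": self.affine.to_dict(),
            "local_warp": self.local_warp.to_dict() if self.local_warp else None,
            "warp_cap_nm": self.warp_cap_nm,
            "seed": self.seed,
        }


def identity_transform() -> GroundTruthTransform:
    return GroundTruthTransform(affine=AffineTransform2D())


def sample_ground_truth(field_size_nm: Tuple[float, float],
                        seed: int = 0,
                        max_translation_nm: float = 2000.0,
                        max_rotation_deg: float = 3.0,
                        scale_range: Tuple[float, float] = (0.97, 1.03),
                        warp_cap_nm: float = 150.0,
                        n_warp_points: Tuple[int, int] = (5, 10)) -> GroundTruthTransform:
    """Draw a random ground-truth transform within the stated bounds.

    The affine part has |translation| ≤ ``max_translation_nm``, rotation in
    ±``max_rotation_deg`` and anisotropic scales in ``scale_range``, pivoted
    at the field centre.  The local distortion is a thin-plate spline through
    5–10 random control displacements, rescaled so its maximum magnitude over
    the field never exceeds ``warp_cap_nm`` (0 disables it).
    """
    rng = np.random.default_rng(seed)
    w, h = field_size_nm
    t_mag = rng.uniform(0.0, max_translation_nm)
    t_ang = rng.uniform(0.0, 2 * np.pi)
    affine = AffineTransform2D(
        tx_nm=t_mag * np.cos(t_ang),
        ty_nm=t_mag * np.sin(t_ang),
        theta_deg=rng.uniform(-max_rotation_deg, max_rotation_deg),
        sx=rng.uniform(*scale_range),
        sy=rng.uniform(*scale_range),
        centre_nm=(w / 2.0, h / 2.0),
    )
    warp = None
    if warp_cap_nm > 0:
        n_cp = int(rng.integers(n_warp_points[0], n_warp_points[1] + 1))
        cp = np.column_stack([rng.uniform(0, w, n_cp), rng.uniform(0, h, n_cp)])
        ang = rng.uniform(0, 2 * np.pi, n_cp)
        mag = rng.uniform(0, warp_cap_nm, n_cp)
        disp = np.column_stack([mag * np.cos(ang), mag * np.sin(ang)])
        warp = WarpModel(cp, disp, smoothing=0.0)
        # enforce the cap over the whole field, not just at control points
        gx, gy = np.meshgrid(np.linspace(0, w, 25), np.linspace(0, h, 25))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        peak = float(np.linalg.norm(warp.displacement(grid), axis=1).max())
        if peak > warp_cap_nm:
            warp = WarpModel(cp, disp * (warp_cap_nm / peak), smoothing=0.0)
    return GroundTruthTransform(affine=affine, local_warp=warp,
                                warp_cap_nm=warp_cap_nm, seed=seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderParams:
    """Rendering and noise parameters for both modalities.

    Pixel pitches default to the instrument values (FM ~120 nm/px, SXT
    ~29 nm/px).  The FM point-spread function is a Gaussian of σ 250 nm — a
    wide-field PSF comfortably wider than the smallest droplets.  Noise is
    additive Gaussian applied last (optional Poisson shot-noise scaling
    before it); defaults put the faintest droplet at a contrast-to-noise
    ratio of about 5, the regime in which global Otsu segmentation is
    reliable but not trivial.
    """

    fm_pixel_nm: float = 120.0
    sxt_pixel_nm: float = 29.0
    fm_psf_sigma_nm: float = 250.0
    sxt_ring: bool = True
    fm_background: float = 0.05
    fm_amplitude: float = 1.0
    sxt_background: float = 0.85
    sxt_rim_level: float = 0.25
    sxt_core_level: float = 0.55
    sxt_rim_frac: float = 0.3
    noise_sigma_fm: float = 0.05
    noise_sigma_sxt: float = 0.05
    poisson_scale: float = 0.0  # photons per unit intensity; 0 disables
    supersample: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.fm_pixel_nm <= 0 or self.sxt_pixel_nm <= 0:
            raise InputError("pixel sizes must be positive")
        for name in ("noise_sigma_fm", "noise_sigma_sxt", "poisson_scale", "fm_psf_sigma_nm"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.supersample < 1:
            raise InputError("supersample must be >= 1")


def _grid_n(extent_nm: float, pixel_nm: float) -> int:
    return max(1, int(round(extent_nm / pixel_nm)))


def _sub_coords(n_px: int, pixel_nm: float, ss: int) -> np.ndarray:
    """Physical coordinates of supersampled sub-pixel centres (pixel-centre origin)."""
    k = np.arange(n_px * ss)
    return (k + 0.5) * (pixel_nm / ss) - pixel_nm / 2.0


def _downsample(arr: np.ndarray, ss: int) -> np.ndarray:
    if ss == 1:
        return arr
    h, w = arr.shape
    return arr.reshape(h // ss, ss, w // ss, ss).mean(axis=(1, 3))


def _apply_noise(img: np.ndarray, sigma: float, poisson_scale: float,
                 rng: np.random.Generator) -> np.ndarray:
    out = img
    if poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * poisson_scale) / poisson_scale
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, size=out.shape)
    return out


def render_fm(scene: DropletScene,
              gt: Optional[GroundTruthTransform] = None,
              params: Optional[RenderParams] = None) -> ImagePlane:
    """Render the fluorescence view: bright PSF-blurred blobs on a dark field.

    Droplet positions are pulled back through the inverse of the ground-truth
    moving→reference map (FM is the distorted modality); pass ``gt=None`` for
    an undistorted render.
    """
    p = params or RenderParams()
    ss = p.supersample
    w_nm, h_nm = scene.field_size_nm
    nx, ny = _grid_n(w_nm, p.fm_pixel_nm), _grid_n(h_nm, p.fm_pixel_nm)
    xs = _sub_coords(nx, p.fm_pixel_nm, ss)
    ys = _sub_coords(ny, p.fm_pixel_nm, ss)
    canvas = np.zeros((ny * ss, nx * ss), dtype=np.float32)

    pos = scene.positions_nm
    if gt is not None:
        pos = gt.inverse_map(pos)
    for (cx, cy), r in zip(pos, scene.radii_nm):
        _draw_disc(canvas, xs, ys, cx, cy, r, inside=1.0, mode="max")
    if p.fm_psf_sigma_nm > 0:
        canvas = gaussian_filter(canvas, sigma=p.fm_psf_sigma_nm / (p.fm_pixel_nm / ss))
    img = p.fm_background + p.fm_amplitude * _downsample(canvas, ss)
    rng = np.random.default_rng(p.seed)
    img = _apply_noise(img, p.noise_sigma_fm, p.poisson_scale, rng)
    return ImagePlane(pixels=img.astype(np.float64), pixel_size_nm=p.fm_pixel_nm,
                      modality=Modality.FM)


def _draw_disc(canvas: np.ndarray, xs: np.ndarray, ys: np.ndarray,
               cx: float, cy: float, r: float, inside, mode: str,
               ring: Optional[Tuple[float, float, float]] = None) -> None:
    """Draw one droplet into the supersampled canvas, bounded-box only.

    ``ring=(rim_level, core_level, rim_frac)`` renders an absorption ring;
    otherwise a filled disc of value ``inside``.  ``mode`` is 'max' (bright
    blobs) or 'min' (dark absorption against a bright background).
    """
    j = np.searchsorted(xs, [cx - r - 1, cx + r + 1])
    i = np.searchsorted(ys, [cy - r - 1, cy + r + 1])
    j0, j1 = int(j[0]), int(j[1])
    i0, i1 = int(i[0]), int(i[1])
    if j0 >= j1 or i0 >= i1:
        return
    X = xs[j0:j1][None, :]
    Y = ys[i0:i1][:, None]
    d = np.hypot(X - cx, Y - cy)
    region = canvas[i0:i1, j0:j1]
    if ring is None:
        patch = np.where(d <= r, inside, region)
    else:
        rim_level, core_level, rim_frac = ring
        patch = np.where(d <= r, np.where(d >= r * (1.0 - rim_frac), rim_level, core_level), region)
    if mode == "max":
        np.maximum(region, patch, out=region)
    else:
        np.minimum(region, patch, out=region)


def _render_sxt_canvas(scene: DropletScene, p: RenderParams,
                       droplet_idx: Optional[Sequence[int]] = None) -> np.ndarray:
    ss = p.supersample
    w_nm, h_nm = scene.field_size_nm
    nx, ny = _grid_n(w_nm, p.sxt_pixel_nm), _grid_n(h_nm, p.sxt_pixel_nm)
    xs = _sub_coords(nx, p.sxt_pixel_nm, ss)
    ys = _sub_coords(ny, p.sxt_pixel_nm, ss)
    canvas = np.full((ny * ss, nx * ss), p.sxt_background, dtype=np.float32)
    idx = range(len(scene.droplets)) if droplet_idx is None else droplet_idx
    for k in idx:
        cx, cy, r = scene.droplets[k]
        if p.sxt_ring:
            _draw_disc(canvas, xs, ys, cx, cy, r, inside=None, mode="min",
                       ring=(p.sxt_rim_level, p.sxt_core_level, p.sxt_rim_frac))
        else:
            _draw_disc(canvas, xs, ys, cx, cy, r, inside=p.sxt_rim_level, mode="min")
    return _downsample(canvas, ss)


def render_sxt(scene: DropletScene, params: Optional[RenderParams] = None) -> ImagePlane:
    """Render the soft X-ray view: dark absorbing droplets (rings by default)
    against a bright transmission background, undistorted (reference frame)."""
    p = params or RenderParams()
    img = _render_sxt_canvas(scene, p).astype(np.float64)
    rng = np.random.default_rng(p.seed + 1)
    img = _apply_noise(img, p.noise_sigma_sxt, p.poisson_scale, rng)
    return ImagePlane(pixels=img, pixel_size_nm=p.sxt_pixel_nm, modality=Modality.SXT)


def render_sxt_stack(scene: DropletScene, params: Optional[RenderParams] = None,
                     n_slices: int = 5) -> ImageStack:
    """Render an SXT slice stack whose minimum-intensity projection equals the
    2D render: each droplet's full (equatorial) cross-section is assigned to
    one slice, round-robin, so no droplet is lost in projection."""
    p = params or RenderParams()
    if n_slices < 1:
        raise InputError("n_slices must be >= 1")
    rng = np.random.default_rng(p.seed + 1)
    planes = []
    for z in range(n_slices):
        idx = [k for k in range(len(scene.droplets)) if k % n_slices == z]
        img = _render_sxt_canvas(scene, p, droplet_idx=idx).astype(np.float64)
        img = _apply_noise(img, p.noise_sigma_sxt, p.poisson_scale, rng)
        planes.append(ImagePlane(pixels=img, pixel_size_nm=p.sxt_pixel_nm,
                                 modality=Modality.SXT))
    return ImageStack(slices=planes, axis_meaning=AxisMeaning.Z_SLICES)


# ---------------------------------------------------------------------------
# FRC pairs and tilt planning
# ---------------------------------------------------------------------------

def make_frc_pair(base: ImagePlane, noise_sigma: float, seed: int = 0
                  ) -> Tuple[ImagePlane, ImagePlane]:
    """Two noise-independent realizations of the same underlying image, the
    input expected by Fourier ring correlation."""
    if noise_sigma < 0:
        raise InputError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    a = base.pixels + rng.normal(0.0, noise_sigma, base.shape) if noise_sigma > 0 else base.pixels.copy()
    b = base.pixels + rng.normal(0.0, noise_sigma, base.shape) if noise_sigma > 0 else base.pixels.copy()
    return base.with_pixels(a), base.with_pixels(b)


def plan_tilt_series(min_deg: float, max_deg: float, step_deg: float) -> np.ndarray:
    """Inclusive arithmetic progression of tilt angles.

    A 1° step over a ±60° (flat grids) or ±90° (cylindrical specimens) range
    yields 121 or 181 projections respectively.
    """
    if step_deg <= 0:
        raise InputError("step_deg must be > 0")
    if max_deg <= min_deg:
        raise InputError("max_deg must exceed min_deg")
    span = max_deg - min_deg
    n = span / step_deg
    if abs(n - round(n)) > 1e-9:
        raise InputError(f"range {span} deg is not divisible by step {step_deg} deg")
    n = int(round(n))
    return min_deg + step_deg * np.arange(n + 1)


# ---------------------------------------------------------------------------
# the default study conditions
# ---------------------------------------------------------------------------

#: Default correlative-scene conditions: 15 droplets with radii 200–1000 nm in
#: a 30×30 µm field (≥2 µm separation), ground-truth affine with |t| ≤ 2 µm,
#: |θ| ≤ 3°, scales 0.97–1.03, plus a ≤150 nm thin-plate local distortion.
DEFAULT_SCENE = dict(n_droplets=15, field_size_nm=(30000.0, 30000.0),
                     radius_range_nm=(200.0, 1000.0), min_sep_nm=2000.0,
                     margin_nm=2500.0)
DEFAULT_GT = dict(max_translation_nm=2000.0, max_rotation_deg=3.0,
                  scale_range=(0.97, 1.03), warp_cap_nm=150.0)


def default_correlative_pair(seed: int, noise: bool = True,
                             with_warp: bool = True):
    """Generate the default synthetic study pair for a given seed.

    Returns ``(fm_plane, sxt_plane, scene, gt)``.  Child seeds for the
    ground truth and the two renders are derived deterministically from
    ``seed`` so the pair is fully reproducible.
    """
    def child(k: int) -> int:
        return int(np.random.SeedSequence((seed, k)).generate_state(1)[0] % (2 ** 31))

    scene = sample_scene(seed=seed, **DEFAULT_SCENE)
    gt_kw = dict(DEFAULT_GT)
    if not with_warp:
        gt_kw["warp_cap_nm"] = 0.0
    gt = sample_ground_truth(scene.field_size_nm, seed=child(1), **gt_kw)
    params = RenderParams(seed=child(2))
    if not noise:
        params = replace(params, noise_sigma_fm=0.0, noise_sigma_sxt=0.0, poisson_scale=0.0)
    fm = render_fm(scene, gt, params)
    sxt = render_sxt(scene, params)
    return fm, sxt, scene, gt
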