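"""Three-stage landmark registration of fluorescence onto soft X-ray images.

Stages, in pipeline order:

1. **Rescale** — the moving FM image (~120 nm/px) is interpolated onto the
   reference SXT pixel pitch (~29 nm/px) so both modalities share a grid.
2. **Coarse translation** — phase cross-correlation of the binary droplet
   masks (masks, not intensities: the modalities have unrelated contrast),
   with subpixel peak refinement.
3. **Affine refinement** — ICP-style minimisation of the mean squared
   distance between mutually-nearest matched centroids over translation,
   rotation and anisotropic scale, with a shrinking match gate.
4. **Non-rigid correction** — a thin-plate-spline warp fitted to the
   residual displacements of the matched landmarks.

All geometry is in physical nm coordinates (xy = column,row at pixel
centres); transforms map the moving frame into the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from skimage.registration import phase_cross_correlation

from .errors import ConvergenceError, DegenerateGeometryError, InputError
from .image import ImagePlane, Modality
from .segment import (CentroidSet, PreprocessParams, SegmentationMask,
                      centroids, segment_droplets)
from .transforms import AffineTransform2D, WarpModel, _collinear


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------

def rescale_to_reference(mov: ImagePlane, ref_pixel_nm: float) -> ImagePlane:
    """Resample an image onto the reference pixel pitch by bilinear
    interpolation, preserving the physical field of view and the origin
    (pixel-centre) convention.  Intensities are not renormalized."""
    if ref_pixel_nm <= 0:
        raise InputError("ref_pixel_nm must be > 0")
    if mov.pixel_size_nm == ref_pixel_nm:
        return mov
    factor = mov.pixel_size_nm / ref_pixel_nm
    ny, nx = mov.shape
    out_ny, out_nx = max(1, round(ny * factor)), max(1, round(nx * factor))
    # output index j sits at physical j*ref_px  ->  input index j*ref/mov
    rows = np.arange(out_ny) * (ref_pixel_nm / mov.pixel_size_nm)
    cols = np.arange(out_nx) * (ref_pixel_nm / mov.pixel_size_nm)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(np.asarray(mov.pixels, dtype=float),
                                  [rr, cc], order=1, mode="nearest")
    return mov.with_pixels(out, pixel_size_nm=ref_pixel_nm)


# ---------------------------------------------------------------------------
# coarse alignment
# ---------------------------------------------------------------------------

def _pad_to_common(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ny = max(a.shape[0], b.shape[0])
    nx = max(a.shape[1], b.shape[1])
    pa = np.zeros((ny, nx), dtype=float)
    pb = np.zeros((ny, nx), dtype=float)
    pa[: a.shape[0], : a.shape[1]] = a
    pb[: b.shape[0], : b.shape[1]] = b
    return pa, pb


def _translation_cost(ref_pts: np.ndarray, mov_pts: np.ndarray,
                      shift_nm: Tuple[float, float]) -> float:
    """Mean nearest-neighbour distance of shifted moving centroids to the
    reference centroids — used to score candidate coarse shifts."""
    moved = mov_pts + np.asarray(shift_nm, dtype=float)
    d, _ = cKDTree(ref_pts).query(moved)
    return float(np.mean(d))


def coarse_align_pcc(ref_mask: SegmentationMask, mov_mask: SegmentationMask,
                     upsample_factor: int = 10) -> Tuple[float, float]:
    """Subpixel translation (dx_nm, dy_nm) aligning the moving mask to the
    reference mask: a point p in the moving frame maps to p + (dx, dy).

    Computed by cross-correlation of the binary masks with subpixel
    (upsampled-DFT) peak refinement; top-left-aligned zero padding
    reconciles unequal shapes without moving the origin.  Two correlation
    peaks are considered — the phase-normalized and the plain cross-power
    peak (phase whitening is brittle on sparse binary masks when the
    modalities also differ by rotation/scale) — and the candidate whose
    translation gives the lower mean matched-centroid distance wins.
    """
    if ref_mask.pixel_size_nm != mov_mask.pixel_size_nm:
        raise InputError("masks must share a pixel size; rescale first")
    a = ref_mask.binary().astype(float)
    b = mov_mask.binary().astype(float)
    if a.sum() == 0 or b.sum() == 0:
        raise InputError("empty segmentation mask: nothing to align")
    a, b = _pad_to_common(a, b)
    px = ref_mask.pixel_size_nm
    candidates = []
    for normalization in ("phase", None):
        shift, _, _ = phase_cross_correlation(a, b, upsample_factor=upsample_factor,
                                              normalization=normalization)
        candidates.append((float(shift[1]) * px, float(shift[0]) * px))
    ref_pts = ref_mask.table[["x_nm", "y_nm"]].to_numpy(dtype=float)
    mov_pts = mov_mask.table[["x_nm", "y_nm"]].to_numpy(dtype=float)
    if len(ref_pts) == 0 or len(mov_pts) == 0 or candidates[0] == candidates[1]:
        return candidates[0]
    costs = [_translation_cost(ref_pts, mov_pts, c) for c in candidates]
    return candidates[int(np.argmin(costs))]


# ---------------------------------------------------------------------------
# landmark matching
# ---------------------------------------------------------------------------

@dataclass
class MatchedPairs:
    """One-to-one mutual-nearest-neighbour landmark pairing."""

    ref_idx: np.ndarray
    mov_idx: np.ndarray
    distances_nm: np.ndarray
    gate_nm: float

    def __len__(self) -> int:
        return len(self.ref_idx)

    @property
    def rms_nm(self) -> float:
        return float(np.sqrt(np.mean(self.distances_nm ** 2))) if len(self) else np.nan


def match_pairs(ref: CentroidSet, mov: CentroidSet, transform=None,
                gate_nm: float = 2000.0) -> MatchedPairs:
    """Mutual nearest neighbours between reference points and transformed
    moving points, keeping pairs within ``gate_nm``."""
    if gate_nm <= 0:
        raise InputError("gate_nm must be > 0")
    rp = ref.points_nm
    mp = mov.points_nm
    if transform is not None:
        mp = transform.apply(mp) if hasattr(transform, "apply") else mp + np.asarray(transform, dtype=float)
    if len(rp) == 0 or len(mp) == 0:
        return MatchedPairs(np.array([], int), np.array([], int), np.array([]), gate_nm)
    tree_r, tree_m = cKDTree(rp), cKDTree(mp)
    d_m2r, i_m2r = tree_r.query(mp)  # nearest ref for each mov
    _, i_r2m = tree_m.query(rp)      # nearest mov for each ref
    ref_sel, mov_sel, dist = [], [], []
    for m, (r, d) in enumerate(zip(i_m2r, d_m2r)):
        if i_r2m[r] == m and d <= gate_nm:
            ref_sel.append(r)
            mov_sel.append(m)
            dist.append(d)
    return MatchedPairs(np.asarray(ref_sel, int), np.asarray(mov_sel, int),
                        np.asarray(dist, float), gate_nm)


# ---------------------------------------------------------------------------
# affine refinement
# ---------------------------------------------------------------------------

@dataclass
class RefineOptions:
    """Knobs of the cost-driven affine refinement.

    The cost is the mean squared matched-centroid distance, re-matched each
    outer (ICP) iteration; the inner solver is a derivative-free simplex over
    (tx, ty, θ, sx, sy), restarted from the best of a 3×3 translation jitter
    grid.  Scale and rotation bounds keep the search inside the physically
    plausible regime for an instrument pair on a shared stage.
    """

    gate_start_nm: float = 2000.0
    gate_floor_nm: float = 300.0
    scale_bounds: Tuple[float, float] = (0.8, 1.25)
    rotation_bound_deg: float = 15.0
    max_icp_iter: int = 30
    simplex_maxiter: int = 500
    rel_tol: float = 1e-4
    jitter_nm: float = 150.0


def _bounded_cost(params, centre, ref_pts, mov_pts, pairs, opts: RefineOptions) -> float:
    tx, ty, th, sx, sy = params
    lo, hi = opts.scale_bounds
    penalty = 0.0
    if not (lo <= sx <= hi and lo <= sy <= hi) or abs(th) > opts.rotation_bound_deg:
        penalty = 1e12 * (max(0, lo - sx) + max(0, sx - hi) + max(0, lo - sy)
                          + max(0, sy - hi) + max(0, abs(th) - opts.rotation_bound_deg) + 1e-6)
        sx = np.clip(sx, lo, hi)
        sy = np.clip(sy, lo, hi)
        th = np.clip(th, -opts.rotation_bound_deg, opts.rotation_bound_deg)
    t = AffineTransform2D(tx, ty, th, sx, sy, centre)
    moved = t.apply(mov_pts[pairs.mov_idx])
    return float(np.mean(np.sum((ref_pts[pairs.ref_idx] - moved) ** 2, axis=1))) + penalty


def refine_affine(ref: CentroidSet, mov: CentroidSet,
                  init: Tuple[float, float] = (0.0, 0.0),
                  opts: Optional[RefineOptions] = None) -> AffineTransform2D:
    """ICP-style refinement of translation, rotation and anisotropic scale.

    Starting from the coarse translation ``init``, alternates
    mutual-nearest-neighbour matching (gate shrinking towards 3× the current
    RMS residual, floored) with simplex minimisation of the mean squared
    pair distance.  The pivot is the reference landmark centroid.  Raises
    :class:`DegenerateGeometryError` when fewer than 3 usable pairs remain
    and :class:`ConvergenceError` (carrying the best estimate) if the outer
    loop exhausts its budget without stabilising.
    """
    opts = opts or RefineOptions()
    ref_pts, mov_pts = ref.points_nm, mov.points_nm
    if len(ref_pts) < 3 or len(mov_pts) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 landmarks on each side, got {len(ref_pts)} ref / {len(mov_pts)} mov")
    centre = tuple(ref_pts.mean(axis=0))

    # one restart from the best of a 3x3 translation jitter grid
    best_init, best_c = None, np.inf
    for jx in (-opts.jitter_nm, 0.0, opts.jitter_nm):
        for jy in (-opts.jitter_nm, 0.0, opts.jitter_nm):
            cand = (init[0] + jx, init[1] + jy)
            pr = match_pairs(ref, mov, np.asarray(cand), opts.gate_start_nm)
            if len(pr) < 3:
                continue
            c = _bounded_cost((cand[0], cand[1], 0, 1, 1), centre, ref_pts, mov_pts, pr, opts)
            if c < best_c:
                best_c, best_init = c, cand
    if best_init is None:
        raise DegenerateGeometryError("fewer than 3 gated landmark pairs at initialisation")

    params = np.array([best_init[0], best_init[1], 0.0, 1.0, 1.0])
    gate = opts.gate_start_nm
    prev_cost = np.inf
    cost = best_c
    n_outer = 0
    converged = False
    for n_outer in range(1, opts.max_icp_iter + 1):
        t = AffineTransform2D(*params[:3], params[3], params[4], centre)
        pairs = match_pairs(ref, mov, t, gate)
        if len(pairs) < 3:
            raise DegenerateGeometryError(
                f"fewer than 3 gated landmark pairs at ICP iteration {n_outer}")
        res = minimize(_bounded_cost, params,
                       args=(centre, ref_pts, mov_pts, pairs, opts),
                       method="Nelder-Mead",
                       options={"maxiter": opts.simplex_maxiter,
                                "xatol": 1e-3, "fatol": 1e-10})
        new_params, new_cost = res.x, float(res.fun)
        if new_cost <= cost or not np.isfinite(cost):
            params, cost = new_params, new_cost
        rms = max(np.sqrt(max(cost, 0.0)), 1.0)
        gate = min(gate, max(3.0 * rms, opts.gate_floor_nm))
        if prev_cost < np.inf and abs(prev_cost - cost) <= opts.rel_tol * max(cost, 1e-9):
            converged = True
            break
        prev_cost = cost

    lo, hi = opts.scale_bounds
    out = AffineTransform2D(
        tx_nm=params[0], ty_nm=params[1],
        theta_deg=float(np.clip(params[2], -opts.rotation_bound_deg, opts.rotation_bound_deg)),
        sx=float(np.clip(params[3], lo, hi)), sy=float(np.clip(params[4], lo, hi)),
        centre_nm=centre)
    out.fit_info = {"final_cost_nm2": cost, "n_icp_iter": n_outer,
                    "gate_nm": gate, "converged": converged}
    if not converged:
        raise ConvergenceError(
            f"affine refinement did not stabilise in {opts.max_icp_iter} ICP iterations",
            best=out)
    return out


# ---------------------------------------------------------------------------
# non-rigid correction
# ---------------------------------------------------------------------------

def fit_warp(pairs: MatchedPairs, ref: CentroidSet, mov_transformed: CentroidSet,
             smoothing: float = 0.0) -> WarpModel:
    """Thin-plate-spline warp carrying affine-transformed moving landmarks
    onto their matched reference landmarks (λ=0 → exact interpolation)."""
    if len(pairs) < 3:
        raise DegenerateGeometryError("need >= 3 matched pairs to fit a warp")
    cp = mov_transformed.points_nm[pairs.mov_idx]
    disp = ref.points_nm[pairs.ref_idx] - cp
    return WarpModel(cp, disp, smoothing=smoothing)


def apply_to_points(pts, affine: AffineTransform2D,
                    warp: Optional[WarpModel] = None) -> np.ndarray:
    """Forward-map points: affine, then optional warp."""
    out = affine.apply(pts)
    if warp is not None:
        out = warp.apply(out)
    return out


def apply_to_image(img: ImagePlane, affine: AffineTransform2D,
                   warp: Optional[WarpModel] = None,
                   out_shape: Optional[Tuple[int, int]] = None,
                   out_pixel_nm: Optional[float] = None,
                   cval: float = 0.0) -> ImagePlane:
    """Resample the moving image onto the reference grid by inverse mapping
    with bilinear interpolation."""
    out_pixel_nm = out_pixel_nm or img.pixel_size_nm
    out_shape = out_shape or img.shape
    ny, nx = out_shape
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    q = np.column_stack([jj.ravel() * out_pixel_nm, ii.ravel() * out_pixel_nm])
    if warp is not None:
        q = warp.apply_inverse(q)
    p = affine.inverse().apply(q)
    cols = p[:, 0] / img.pixel_size_nm
    rows = p[:, 1] / img.pixel_size_nm
    out = ndimage.map_coordinates(np.asarray(img.pixels, dtype=float),
                                  [rows.reshape(ny, nx), cols.reshape(ny, nx)],
                                  order=1, mode="constant", cval=cval)
    return ImagePlane(pixels=out, pixel_size_nm=out_pixel_nm, modality=img.modality)


# ---------------------------------------------------------------------------
# overlay
# ---------------------------------------------------------------------------

@dataclass
class RGBOverlay:
    """8-bit RGB composite of the two registered modalities."""

    pixels: np.ndarray  # (rows, cols, 3) uint8
    pixel_size_nm: float


def compose_overlay(ref: ImagePlane, warped_mov: ImagePlane) -> RGBOverlay:
    """Red = reference X-ray channel (contrast-inverted so absorbing droplets
    are bright), blue = fluorescence, green = min(red, blue) so coincident
    signal renders white-ish."""
    if ref.shape != warped_mov.shape:
        raise InputError(f"overlay grids differ: {ref.shape} vs {warped_mov.shape}")

    def norm(x):
        x = np.asarray(x, dtype=float)
        lo, hi = x.min(), x.max()
        return np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)

    red = norm(ref.pixels)
    if ref.modality == Modality.SXT:
        red = 1.0 - red
    blue = norm(warped_mov.pixels)
    green = np.minimum(red, blue)
    rgb = np.stack([red, green, blue], axis=-1)
    return RGBOverlay(pixels=(rgb * 255).round().astype(np.uint8),
                      pixel_size_nm=ref.pixel_size_nm)


# ---------------------------------------------------------------------------
# end-to-end pair registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationParams:
    """Everything the end-to-end pipeline needs, with study defaults."""

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    min_radius_nm: float = 150.0
    max_radius_nm: float = 1500.0
    refine: RefineOptions = field(default_factory=RefineOptions)
    warp_smoothing: float = 0.0
    do_warp: bool = True
    match_gate_nm: float = 2000.0


@dataclass
class RegistrationResult:
    """All intermediates of a pair registration, in pipeline-stage order."""

    coarse_shift_nm: Tuple[float, float]
    affine: AffineTransform2D
    warp: Optional[WarpModel]
    pairs: MatchedPairs
    residuals_before_nm: np.ndarray
    residuals_after_nm: np.ndarray
    ref_mask: SegmentationMask
    mov_mask: SegmentationMask
    ref_centroids: CentroidSet
    mov_centroids: CentroidSet
    overlay: Optional[RGBOverlay]
    stages: List[str]


def register_masks(ref_mask: SegmentationMask, mov_mask: SegmentationMask,
                   params: Optional[RegistrationParams] = None
                   ) -> Tuple[Tuple[float, float], AffineTransform2D, MatchedPairs]:
    """PCC coarse translation + affine refinement from segmentation masks.

    The landmark-level core shared by :func:`register_pair` and the
    leave-one-out protocol (which re-runs exactly these stages per fold).
    """
    params = params or RegistrationParams()
    coarse = coarse_align_pcc(ref_mask, mov_mask)
    ref_c, mov_c = centroids(ref_mask), centroids(mov_mask)
    affine = refine_affine(ref_c, mov_c, init=coarse, opts=params.refine)
    pairs = match_pairs(ref_c, mov_c, affine, gate_nm=params.match_gate_nm)
    return coarse, affine, pairs


def register_pair(ref_img: ImagePlane, mov_img: ImagePlane,
                  params: Optional[RegistrationParams] = None,
                  make_overlay: bool = True) -> RegistrationResult:
    """Run the full pipeline: rescale → segment both → PCC → affine → TPS.

    ``ref_img`` is typically the (projected) SXT plane, ``mov_img`` the FM
    plane; stage names are attached to propagated errors.
    """
    params = params or RegistrationParams()
    stages: List[str] = []

    def stage(name):
        stages.append(name)
        return name

    try:
        stage("rescale")
        mov_r = rescale_to_reference(mov_img, ref_img.pixel_size_nm)
        stage("segment")
        ref_mask = segment_droplets(ref_img, params=params.preprocess,
                                    min_radius_nm=params.min_radius_nm,
                                    max_radius_nm=params.max_radius_nm)
        mov_mask = segment_droplets(mov_r, params=params.preprocess,
                                    min_radius_nm=params.min_radius_nm,
                                    max_radius_nm=params.max_radius_nm)
        stage("coarse_pcc+affine")
        coarse, affine, pairs = register_masks(ref_mask, mov_mask, params)
        ref_c, mov_c = centroids(ref_mask), centroids(mov_mask)
        mov_t = CentroidSet(affine.apply(mov_c.points_nm), mov_c.modality, mov_c.ids)
        res_before = pairs.distances_nm.copy()
        warp = None
        res_after = res_before.copy()
        if params.do_warp and len(pairs) >= 3 and not _collinear(mov_t.points_nm[pairs.mov_idx]):
            stage("tps_warp")
            warp = fit_warp(pairs, ref_c, mov_t, smoothing=params.warp_smoothing)
            warped_pts = warp.apply(mov_t.points_nm[pairs.mov_idx])
            res_after = np.linalg.norm(ref_c.points_nm[pairs.ref_idx] - warped_pts, axis=1)
        overlay = None
        if make_overlay:
            stage("overlay")
            warped_img = apply_to_image(mov_r, affine, warp, out_shape=ref_img.shape,
                                        out_pixel_nm=ref_img.pixel_size_nm)
            overlay = compose_overlay(ref_img, warped_img)
        return RegistrationResult(
            coarse_shift_nm=coarse, affine=affine, warp=warp, pairs=pairs,
            residuals_before_nm=res_before, residuals_after_nm=res_after,
            ref_mask=ref_mask, mov_mask=mov_mask,
            ref_centroids=ref_c, mov_centroids=mov_c,
            overlay=overlay, stages=stages)
    except Exception as exc:
        if stages and not getattr(exc, "_stage_tagged", False):
            exc.args = (f"[stage: {stages[-1]}] {exc.args[0] if exc.args else exc}",) + exc.args[1:]
            exc._stage_tagged = True
        raise
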