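"""Image-resolution metrics: Fourier ring correlation and FWHM line profiles.

FRC correlates two noise-independent realizations of the same scene over
concentric spatial-frequency rings,

.. math::

    \\mathrm{FRC}(r) = \\frac{\\Re\\sum_{k \\in r} F_1(k)\\,\\overline{F_2(k)}}
        {\\sqrt{\\sum_{k \\in r} |F_1(k)|^2 \\; \\sum_{k \\in r} |F_2(k)|^2}}

and the resolution is read where the curve first drops through a fixed
threshold (0.25 by default, the convention matching published synchrotron
soft X-ray characterisation), reported as *full pitch* — one full period,
1 / crossing frequency.  The noise-independent halves come from splitting
the per-tilt frames into even/odd sets (:func:`split_frames`).

Both images have their mean removed before the (default Hann) window, which
makes the curve exactly invariant to a common affine intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import InputError
from .image import ImagePlane, ImageStack


# ---------------------------------------------------------------------------
# frame splitting
# ---------------------------------------------------------------------------

def split_frames(frames: ImageStack, frames_per_tilt: Optional[int] = None
                 ) -> Tuple[ImageStack, ImageStack]:
    """Split per-tilt frames into two noise-independent summed half-sets.

    Even-indexed frames within each tilt group are summed into half A,
    odd-indexed into half B, so A + B conserves the total signal.  With the
    default ``frames_per_tilt=None`` the whole stack is one tilt group.
    """
    n = len(frames)
    fpt = n if frames_per_tilt is None else int(frames_per_tilt)
    if fpt < 2 or fpt % 2 != 0:
        raise InputError(f"frames per tilt must be even and >= 2, got {fpt}")
    if n % fpt != 0:
        raise InputError(f"{n} frames do not divide into tilt groups of {fpt}")
    data = frames.as_array().astype(float)
    groups = data.reshape(n // fpt, fpt, *data.shape[1:])
    a = groups[:, 0::2].sum(axis=1)
    b = groups[:, 1::2].sum(axis=1)
    px = frames.pixel_size_nm
    mk = lambda arr: ImageStack(
        [frames.slices[0].with_pixels(sl, pixel_size_nm=px) for sl in arr],
        axis_meaning=frames.axis_meaning)
    return mk(a), mk(b)


# ---------------------------------------------------------------------------
# FRC
# ---------------------------------------------------------------------------

@dataclass
class FRCCurve:
    """Per-ring correlation of two half-datasets."""

    spatial_frequency: np.ndarray  # cycles/nm, strictly increasing
    frc: np.ndarray
    ring_counts: np.ndarray
    pixel_size_nm: float
    threshold: Optional[float] = None


@dataclass
class ResolutionEstimate:
    """Threshold crossing of an FRC curve, reported as full pitch (nm)."""

    full_pitch_nm: float
    crossing_frequency: float  # cycles/nm
    threshold: float
    interpolated: bool
    status: str = "ok"  # ok | nyquist | degenerate


def _square_pad(x: np.ndarray) -> np.ndarray:
    ny, nx = x.shape
    n = max(ny, nx)
    if ny == nx:
        return x
    out = np.zeros((n, n), dtype=float)
    out[:ny, :nx] = x
    return out


def frc(a: ImagePlane, b: ImagePlane, ring_width_bins: int = 1,
        window: str = "hann") -> FRCCurve:
    """Fourier ring correlation of two images of the same scene.

    Symmetric in its arguments; images are mean-subtracted, optionally Hann
    windowed (default, to suppress edge leakage), zero-padded to square if
    needed, and correlated ring by ring up to the Nyquist frequency
    1/(2·pixel size).
    """
    if a.shape != b.shape:
        raise InputError(f"FRC inputs differ in shape: {a.shape} vs {b.shape}")
    if a.pixel_size_nm != b.pixel_size_nm:
        raise InputError("FRC inputs differ in pixel size")
    if ring_width_bins < 1:
        raise InputError("ring_width_bins must be >= 1")
    if window not in ("hann", "none"):
        raise InputError(f"unknown window '{window}'")
    xa = np.asarray(a.pixels, dtype=float)
    xb = np.asarray(b.pixels, dtype=float)
    xa = xa - xa.mean()
    xb = xb - xb.mean()
    if window == "hann":
        wy = np.hanning(xa.shape[0])[:, None]
        wx = np.hanning(xa.shape[1])[None, :]
        xa = xa * wy * wx
        xb = xb * wy * wx
    xa, xb = _square_pad(xa), _square_pad(xb)
    n = xa.shape[0]
    fa = np.fft.fftshift(np.fft.fft2(xa))
    fb = np.fft.fftshift(np.fft.fft2(xb))
    cy = cx = n // 2
    yy, xx = np.indices((n, n))
    r = np.hypot(yy - cy, xx - cx)
    rmax = n // 2
    ring = (r / ring_width_bins).astype(int)
    valid = r <= rmax
    idx = ring[valid]
    nrings = idx.max() + 1
    num = np.bincount(idx, weights=(fa * np.conj(fb)).real[valid], minlength=nrings)
    d1 = np.bincount(idx, weights=(np.abs(fa) ** 2)[valid], minlength=nrings)
    d2 = np.bincount(idx, weights=(np.abs(fb) ** 2)[valid], minlength=nrings)
    counts = np.bincount(idx, minlength=nrings)
    denom = np.sqrt(d1 * d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    # mean radius (in bins) of each ring -> cycles/nm
    rsum = np.bincount(idx, weights=r[valid], minlength=nrings)
    mean_r = np.where(counts > 0, rsum / np.maximum(counts, 1), 0.0)
    freq = mean_r / (n * a.pixel_size_nm)
    keep = counts > 0
    return FRCCurve(spatial_frequency=freq[keep], frc=np.clip(corr[keep], -1.0, 1.0),
                    ring_counts=counts[keep], pixel_size_nm=a.pixel_size_nm)


def resolution_at_threshold(curve: FRCCurve, threshold: float = 0.25
                            ) -> ResolutionEstimate:
    """Locate the first downward crossing of ``threshold`` (DC ring excluded)
    by linear interpolation between adjacent rings.

    No crossing → Nyquist-limited estimate (full pitch = 2·pixel size) with
    status 'nyquist'; a curve already below threshold at the first non-DC
    ring → status 'degenerate' (resolution undefined)."""
    if not (0 < threshold < 1):
        raise InputError("threshold must be in (0, 1)")
    f, c = curve.spatial_frequency, curve.frc
    if len(f) < 2:
        raise InputError("FRC curve too short")
    if c[1] < threshold:
        return ResolutionEstimate(full_pitch_nm=np.nan, crossing_frequency=np.nan,
                                  threshold=threshold, interpolated=False,
                                  status="degenerate")
    for i in range(1, len(f) - 1):
        if c[i] >= threshold and c[i + 1] < threshold:
            t = (c[i] - threshold) / (c[i] - c[i + 1])
            fc = f[i] + t * (f[i + 1] - f[i])
            return ResolutionEstimate(full_pitch_nm=1.0 / fc, crossing_frequency=fc,
                                      threshold=threshold, interpolated=True)
    nyq = 1.0 / (2.0 * curve.pixel_size_nm)
    return ResolutionEstimate(full_pitch_nm=2.0 * curve.pixel_size_nm,
                              crossing_frequency=nyq, threshold=threshold,
                              interpolated=False, status="nyquist")


def depth_profile(recon_a: ImageStack, recon_b: ImageStack,
                  threshold: float = 0.25,
                  z_step_nm: Optional[float] = None,
                  **frc_kwargs) -> List[Tuple[float, float]]:
    """FRC resolution slice by slice through paired half-dataset
    reconstructions, as (signed z offset from the focal slice, full pitch).

    The focal slice is the one with the finest (minimal) full-pitch value;
    ``z_step_nm`` defaults to the in-plane pixel size (isotropic voxels).
    """
    if len(recon_a) != len(recon_b):
        raise InputError(f"slice counts differ: {len(recon_a)} vs {len(recon_b)}")
    z_step = z_step_nm if z_step_nm is not None else recon_a.pixel_size_nm
    pitches = []
    for sa, sb in zip(recon_a.slices, recon_b.slices):
        est = resolution_at_threshold(frc(sa, sb, **frc_kwargs), threshold)
        pitches.append(est.full_pitch_nm)
    pitches = np.asarray(pitches)
    finite = np.where(np.isfinite(pitches), pitches, np.inf)
    focal = int(np.argmin(finite))
    return [((i - focal) * z_step, float(pitches[i])) for i in range(len(pitches))]


# ---------------------------------------------------------------------------
# line profiles and FWHM
# ---------------------------------------------------------------------------

@dataclass
class LineProfile:
    """Bilinear intensity samples along a segment, uniform step in nm."""

    positions_nm: np.ndarray
    intensities: np.ndarray
    step_nm: float


def line_profile(img: ImagePlane, p0_nm: Tuple[float, float],
                 p1_nm: Tuple[float, float], step_nm: float) -> LineProfile:
    """Sample the image along the segment p0→p1 every ``step_nm``."""
    if step_nm <= 0:
        raise InputError("step_nm must be > 0")
    p0 = np.asarray(p0_nm, dtype=float)
    p1 = np.asarray(p1_nm, dtype=float)
    px = img.pixel_size_nm
    ny, nx = img.shape
    for pt in (p0, p1):
        if not (0 <= pt[0] <= (nx - 1) * px and 0 <= pt[1] <= (ny - 1) * px):
            raise InputError(f"profile endpoint {pt} nm outside the image")
    length = float(np.linalg.norm(p1 - p0))
    n = max(2, int(np.floor(length / step_nm)) + 1)
    pos = np.arange(n) * step_nm
    pos = pos[pos <= length + 1e-9]
    u = (p1 - p0) / length if length > 0 else np.array([1.0, 0.0])
    pts = p0[None, :] + pos[:, None] * u[None, :]
    vals = ndimage.map_coordinates(np.asarray(img.pixels, dtype=float),
                                   [pts[:, 1] / px, pts[:, 0] / px],
                                   order=1, mode="nearest")
    return LineProfile(positions_nm=pos, intensities=vals, step_nm=step_nm)


def fwhm(profile: LineProfile, polarity: str = "auto") -> float:
    """Full width at half maximum (or half minimum, for a dip) in nm.

    Baseline = median of the two profile end regions (10% of samples each);
    the extremum is the peak, the dip, or whichever lies farther from
    baseline for ``polarity='auto'``; the two half-level crossings flanking
    the extremum are located by linear interpolation.
    """
    y = np.asarray(profile.intensities, dtype=float)
    x = np.asarray(profile.positions_nm, dtype=float)
    if len(y) < 5:
        raise InputError("profile too short for a FWHM estimate")
    k = max(1, len(y) // 10)
    baseline = float(np.median(np.concatenate([y[:k], y[-k:]])))
    if polarity == "peak":
        ext = int(np.argmax(y))
    elif polarity == "dip":
        ext = int(np.argmin(y))
    elif polarity == "auto":
        ext = int(np.argmax(np.abs(y - baseline)))
    else:
        raise InputError(f"unknown polarity '{polarity}'")
    half = 0.5 * (baseline + y[ext])
    sign = 1.0 if y[ext] >= baseline else -1.0
    z = sign * (y - half)  # extremum side is positive

    def crossing(idx_range):
        prev = None
        for i in idx_range:
            if z[i] <= 0:
                j = prev if prev is not None else i
                # interpolate between i (<=0) and its neighbour towards the extremum (>0)
                i2 = i + (1 if idx_range.step < 0 else -1)
                t = z[i2] / (z[i2] - z[i])
                return x[i2] + t * (x[i] - x[i2])
            prev = i
        return None

    left = crossing(range(ext, -1, -1))
    right = crossing(range(ext, len(z)))
    if left is None or right is None:
        raise InputError("profile does not cross the half level on both sides; FWHM undefined")
    return float(right - left)
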