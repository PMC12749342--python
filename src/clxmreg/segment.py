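"""Preprocessing and lipid-droplet segmentation for both modalities.

The landmark-extraction half of the registration workflow: Gaussian
denoising and CLAHE local-contrast enhancement, global Otsu thresholding,
light morphological cleanup (opening + hole filling, so ring-like SXT
droplets become solid), a size gate on equivalent radius, and unweighted
centre-of-mass centroids in physical (nm) coordinates.

Dark absorption features (SXT) are inverted before thresholding; polarity
defaults per modality (FM bright, SXT dark) and can be inferred for unknown
images by taking the minority pixel class as foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.exposure import equalize_adapthist
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import disk

from .errors import DegenerateInputError, InputError
from .image import ImagePlane, ImageStack, Modality


@dataclass
class PreprocessParams:
    """Gaussian + CLAHE preprocessing parameters.

    ``gaussian_sigma_px`` is in pixels of the image being processed (the
    pipeline preprocesses on the common reference grid); CLAHE clip limit is
    the normalized skimage convention.  Defaults were chosen so that a flat
    field stays flat and droplet rims are enhanced without amplifying
    background noise into spurious blobs.
    """

    gaussian_sigma_px: float = 2.0
    clahe_clip_limit: float = 0.01
    clahe_tile_px: int = 64
    gaussian_enabled: bool = True
    clahe_enabled: bool = True

    def __post_init__(self):
        if self.gaussian_sigma_px < 0:
            raise InputError("gaussian_sigma_px must be >= 0")
        if self.clahe_clip_limit <= 0:
            raise InputError("clahe_clip_limit must be > 0")
        if self.clahe_tile_px < 8:
            raise InputError("clahe_tile_px must be >= 8")


@dataclass
class SegmentationMask:
    """Labelled droplet segments plus per-component statistics.

    ``labels`` uses 0 for background and 1..n for components; ``table`` has
    one row per component: id, area_px, x_nm, y_nm (unweighted centroid, xy
    convention), eq_radius_nm.
    """

    labels: np.ndarray
    pixel_size_nm: float
    table: pd.DataFrame
    modality: Modality = Modality.OTHER
    connectivity: int = 2  # skimage convention: 2 = 8-connected

    @property
    def n_components(self) -> int:
        return len(self.table)

    def binary(self) -> np.ndarray:
        return self.labels > 0

    def without(self, component_id: int) -> "SegmentationMask":
        """Copy of the mask with one component erased (used by leave-one-out)."""
        labels = self.labels.copy()
        labels[labels == component_id] = 0
        table = self.table[self.table["id"] != component_id].reset_index(drop=True)
        return SegmentationMask(labels=labels, pixel_size_nm=self.pixel_size_nm,
                                table=table, modality=self.modality,
                                connectivity=self.connectivity)


@dataclass
class CentroidSet:
    """Landmark centres of mass in physical nm coordinates (xy convention)."""

    points_nm: np.ndarray  # (n, 2)
    modality: Modality = Modality.OTHER
    ids: Optional[np.ndarray] = None

    def __post_init__(self):
        self.points_nm = np.atleast_2d(np.asarray(self.points_nm, dtype=float))
        if self.points_nm.size == 0:
            self.points_nm = np.empty((0, 2))
        if self.points_nm.shape[1] != 2:
            raise InputError("centroids must be (n, 2) [x_nm, y_nm]")
        if not np.all(np.isfinite(self.points_nm)):
            raise InputError("centroid coordinates must be finite")
        if self.ids is None:
            self.ids = np.arange(1, len(self.points_nm) + 1)
        self.ids = np.asarray(self.ids)

    def __len__(self) -> int:
        return len(self.points_nm)


def _normalize01(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def preprocess(img: ImagePlane, params: Optional[PreprocessParams] = None) -> ImagePlane:
    """Gaussian smoothing followed by CLAHE, output min-max scaled to [0, 1]."""
    p = params or PreprocessParams()
    x = _normalize01(img.pixels)
    if p.gaussian_enabled and p.gaussian_sigma_px > 0:
        x = ndimage.gaussian_filter(x, p.gaussian_sigma_px)
    if p.clahe_enabled and x.max() > x.min():
        tile = min(p.clahe_tile_px, min(x.shape))
        x = equalize_adapthist(_normalize01(x), kernel_size=tile,
                               clip_limit=p.clahe_clip_limit)
    return img.with_pixels(_normalize01(x))


def project_stack(stack: ImageStack, mode: str = "min") -> ImagePlane:
    """Collapse a stack to 2D by a pixelwise reduction.

    Minimum-intensity projection is the default: absorption-dark droplets
    survive the collapse regardless of which slice they sit in.
    """
    if len(stack) == 0:
        raise InputError("cannot project an empty stack")
    data = stack.as_array()
    reducers = {"min": np.min, "mean": np.mean, "max": np.max}
    if mode not in reducers:
        raise InputError(f"unknown projection mode '{mode}'")
    out = reducers[mode](data, axis=0)
    s0 = stack.slices[0]
    return ImagePlane(pixels=out, pixel_size_nm=s0.pixel_size_nm, modality=s0.modality)


def _resolve_polarity(polarity: str, modality: Optional[Modality],
                      pre: np.ndarray) -> str:
    if polarity in ("bright", "dark"):
        return polarity
    if polarity != "auto":
        raise InputError(f"unknown polarity '{polarity}'")
    if modality == Modality.FM:
        return "bright"
    if modality == Modality.SXT:
        return "dark"
    # minority class above the Otsu threshold => bright foreground
    thr = threshold_otsu(pre)
    frac_above = float(np.mean(pre > thr))
    return "bright" if frac_above <= 0.5 else "dark"


def segment_droplets(img: ImagePlane,
                     modality: Optional[Modality] = None,
                     params: Optional[PreprocessParams] = None,
                     min_radius_nm: float = 150.0,
                     max_radius_nm: float = 1500.0,
                     polarity: str = "auto") -> SegmentationMask:
    """Segment lipid droplets: preprocess → global Otsu → opening → hole fill
    → size gate on equivalent radius.

    The default radius gate (150–1500 nm) brackets the droplet population
    (a few hundred nanometres up to a micron) with margin on both sides.
    """
    if not (0 < min_radius_nm < max_radius_nm):
        raise InputError("need 0 < min_radius_nm < max_radius_nm")
    if modality is None:
        modality = img.modality
    pre_plane = preprocess(img, params)
    pre = pre_plane.pixels
    if pre.max() == pre.min():
        raise DegenerateInputError("all-equal image: Otsu threshold undefined")
    pol = _resolve_polarity(polarity, modality, pre)
    work = pre if pol == "bright" else 1.0 - pre
    thr = threshold_otsu(work)
    binary = work > thr
    binary = ndimage.binary_opening(binary, structure=disk(1))
    binary = ndimage.binary_fill_holes(binary)
    labels = sk_label(binary, connectivity=2)
    px = img.pixel_size_nm
    rows: List[dict] = []
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for comp in range(1, labels.max() + 1):
        mask = labels == comp
        area = int(mask.sum())
        eq_r_nm = np.sqrt(area / np.pi) * px
        if min_radius_nm <= eq_r_nm <= max_radius_nm:
            keep[comp] = True
            ys, xs = np.nonzero(mask)
            rows.append({"area_px": area, "x_nm": xs.mean() * px,
                         "y_nm": ys.mean() * px, "eq_radius_nm": eq_r_nm})
    # relabel survivors 1..n in original label order
    out_labels = np.zeros_like(labels)
    new_id = 0
    for comp in range(1, labels.max() + 1):
        if keep[comp]:
            new_id += 1
            out_labels[labels == comp] = new_id
            rows[new_id - 1]["id"] = new_id
    table = pd.DataFrame(rows, columns=["id", "area_px", "x_nm", "y_nm", "eq_radius_nm"]
                         ) if rows else pd.DataFrame(
        columns=["id", "area_px", "x_nm", "y_nm", "eq_radius_nm"])
    return SegmentationMask(labels=out_labels, pixel_size_nm=px, table=table,
                            modality=modality)


def mask_from_labels(labels: np.ndarray, pixel_size_nm: float,
                     modality: Modality = Modality.OTHER) -> SegmentationMask:
    """Build a :class:`SegmentationMask` (with per-component stats) from an
    existing label image, e.g. one loaded from disk or built synthetically."""
    labels = np.asarray(labels)
    if labels.ndim != 2 or np.any(labels < 0):
        raise InputError("labels must be a 2D non-negative integer grid")
    rows = []
    for comp in np.unique(labels):
        if comp == 0:
            continue
        ys, xs = np.nonzero(labels == comp)
        area = len(xs)
        rows.append({"id": int(comp), "area_px": area,
                     "x_nm": xs.mean() * pixel_size_nm,
                     "y_nm": ys.mean() * pixel_size_nm,
                     "eq_radius_nm": np.sqrt(area / np.pi) * pixel_size_nm})
    table = pd.DataFrame(rows, columns=["id", "area_px", "x_nm", "y_nm", "eq_radius_nm"]
                         ) if rows else pd.DataFrame(
        columns=["id", "area_px", "x_nm", "y_nm", "eq_radius_nm"])
    return SegmentationMask(labels=labels, pixel_size_nm=pixel_size_nm,
                            table=table, modality=modality)


def centroids(mask: SegmentationMask) -> CentroidSet:
    """Unweighted centre of mass of each component, in nm, ids ascending."""
    t = mask.table.sort_values("id")
    pts = t[["x_nm", "y_nm"]].to_numpy(dtype=float) if len(t) else np.empty((0, 2))
    return CentroidSet(points_nm=pts, modality=mask.modality,
                       ids=t["id"].to_numpy() if len(t) else np.array([], dtype=int))


def transmission_to_od(img: ImagePlane, i0: float, eps: float = 1e-6) -> ImagePlane:
    """Convert transmitted intensity to optical density, −ln(I/I₀).

    Absorption contrast is quantitative (Beer–Lambert), so OD maps are
    proportional to the projected linear absorption coefficient.
    Intensities are clipped at ``eps·I₀`` to keep zeros finite.
    """
    if i0 <= 0:
        raise InputError("i0 must be > 0")
    if np.any(img.pixels < 0):
        raise InputError("transmission image must be non-negative")
    od = -np.log(np.clip(img.pixels / i0, eps, None))
    out = img.with_pixels(od)
    out.units = "optical_density"
    return out
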