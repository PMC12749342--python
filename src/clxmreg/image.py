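"""In-memory image containers with physical-scale metadata.

Every stage of the pipeline passes :class:`ImagePlane` / :class:`ImageStack`
around rather than bare arrays, so the physical pixel pitch (nm/px) can never
be silently dropped — unit mix-ups between the ~120 nm/px fluorescence grid
and the ~29 nm/px soft X-ray grid are the canonical failure mode of
correlative workflows.

Coordinate convention (used package-wide): 0-based indices, position
``(x, y)`` with ``x`` = column index and ``y`` = row index; physical
coordinate in nm = index × pixel_size_nm, measured at pixel centres, origin
at the centre of pixel (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .errors import InputError

COORD_CONVENTION = (
    "xy=(col,row); nm = index * pixel_size_nm at pixel centres; origin at pixel (0,0); "
    "affine: p' = R(theta) @ diag(sx,sy) @ (p - centre) + centre + t"
)


class Modality(str, Enum):
    """Imaging modality of a plane; SYNTH marks generator output."""

    FM = "FM"
    SXT = "SXT"
    SYNTH = "SYNTH"
    OTHER = "OTHER"


class AxisMeaning(str, Enum):
    Z_SLICES = "Z_SLICES"
    TILT_FRAMES = "TILT_FRAMES"


@dataclass
class ImagePlane:
    """A single 2D intensity image with its physical pixel pitch.

    Parameters
    ----------
    pixels
        2D array (rows × cols), any real dtype, finite everywhere.
    pixel_size_nm
        Isotropic physical pixel pitch in nanometres; must be > 0.
    modality
        Which channel the image comes from; drives segmentation polarity
        defaults (FM droplets are bright, SXT droplets dark).
    """

    pixels: np.ndarray
    pixel_size_nm: float
    modality: Modality = Modality.OTHER
    units: str = "intensity"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise InputError(f"ImagePlane needs a 2D array, got shape {self.pixels.shape}")
        if not np.isfinite(self.pixel_size_nm) or self.pixel_size_nm <= 0:
            raise InputError(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("ImagePlane pixels must be finite everywhere")
        if isinstance(self.modality, str) and not isinstance(self.modality, Modality):
            self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, pixel_size_nm: Optional[float] = None) -> "ImagePlane":
        """New plane with replaced pixel data, keeping metadata."""
        return ImagePlane(
            pixels=pixels,
            pixel_size_nm=self.pixel_size_nm if pixel_size_nm is None else pixel_size_nm,
            modality=self.modality,
            units=self.units,
        )

    def astype(self, dtype) -> "ImagePlane":
        return self.with_pixels(self.pixels.astype(dtype))


@dataclass
class ImageStack:
    """Ordered stack of identically-shaped :class:`ImagePlane` slices.

    ``axis_meaning`` distinguishes reconstruction z-slices from raw tilt
    frames; ``tilt_angles_deg``, when given, must have one angle per slice.
    """

    slices: Sequence[ImagePlane]
    axis_meaning: AxisMeaning = AxisMeaning.Z_SLICES
    tilt_angles_deg: Optional[Sequence[float]] = None

    def __post_init__(self):
        self.slices = list(self.slices)
        if not self.slices:
            raise InputError("ImageStack needs at least one slice")
        s0 = self.slices[0]
        for s in self.slices[1:]:
            if s.shape != s0.shape:
                raise InputError(f"ragged stack: {s.shape} vs {s0.shape}")
            if s.pixel_size_nm != s0.pixel_size_nm:
                raise InputError("stack slices disagree on pixel_size_nm")
        if isinstance(self.axis_meaning, str) and not isinstance(self.axis_meaning, AxisMeaning):
            self.axis_meaning = AxisMeaning(self.axis_meaning)
        if self.tilt_angles_deg is not None and len(self.tilt_angles_deg) != len(self.slices):
            raise InputError("tilt_angles_deg length must equal slice count")

    def __len__(self) -> int:
        return len(self.slices)

    def __getitem__(self, i) -> ImagePlane:
        return self.slices[i]

    @property
    def pixel_size_nm(self) -> float:
        return self.slices[0].pixel_size_nm

    def as_array(self) -> np.ndarray:
        """(n_slices, rows, cols) view of the stack data."""
        return np.stack([s.pixels for s in self.slices])
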