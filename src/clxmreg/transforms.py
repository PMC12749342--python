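"""2D geometric transforms used by the registration stages.

Two models:

* :class:`AffineTransform2D` — the parametric moving→reference map estimated
  by the cost-driven refinement: translation, rotation and anisotropic scale
  about a pivot,

  .. math:: p' = R(\\theta)\\,S(s_x, s_y)\\,(p - c) + c + t

  in physical (nm) coordinates.  Note the family ``R·S`` is not closed under
  composition or inversion when rotation and anisotropic scale are both
  present, so :meth:`AffineTransform2D.inverse` returns an exact
  matrix-backed :class:`MatrixTransform2D` rather than forcing the result
  back into the parameter family.

* :class:`WarpModel` — thin-plate-spline (kernel ``U(r) = r² log r``)
  interpolation of residual landmark displacements, the non-rigid correction
  applied after the affine stage.  With regularisation λ=0 the spline
  interpolates the control displacements exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import RBFInterpolator

from .errors import DegenerateGeometryError, InputError
from .image import COORD_CONVENTION


def _as_points(pts) -> np.ndarray:
    a = np.atleast_2d(np.asarray(pts, dtype=float))
    if a.shape[1] != 2:
        raise InputError(f"points must be (n, 2) [x_nm, y_nm], got {a.shape}")
    return a


@dataclass
class MatrixTransform2D:
    """General 2D affine map ``p' = M p + b`` (physical nm coordinates)."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)

    def apply(self, pts) -> np.ndarray:
        pts = _as_points(pts)
        return pts @ np.asarray(self.matrix, dtype=float).T + np.asarray(self.offset, dtype=float)

    def inverse(self) -> "MatrixTransform2D":
        Minv = np.linalg.inv(self.matrix)
        return MatrixTransform2D(Minv, -Minv @ self.offset)


@dataclass
class AffineTransform2D:
    """Translation + rotation + anisotropic scale about a pivot, in nm.

    Parameters follow the convention string stored with every serialised
    transform: ``p' = R(theta) @ diag(sx, sy) @ (p - centre) + centre + t``.
    """

    tx_nm: float = 0.0
    ty_nm: float = 0.0
    theta_deg: float = 0.0
    sx: float = 1.0
    sy: float = 1.0
    centre_nm: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not (self.sx > 0 and self.sy > 0):
            raise InputError(f"scale factors must be positive, got sx={self.sx}, sy={self.sy}")

    # -- linear algebra ----------------------------------------------------
    @property
    def linear(self) -> np.ndarray:
        """The 2×2 linear part R(θ)·S — pivot independent."""
        th = np.deg2rad(self.theta_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return R @ np.diag([self.sx, self.sy])

    def as_matrix(self) -> MatrixTransform2D:
        c = np.asarray(self.centre_nm, dtype=float)
        t = np.array([self.tx_nm, self.ty_nm], dtype=float)
        M = self.linear
        return MatrixTransform2D(M, c + t - M @ c)

    def apply(self, pts) -> np.ndarray:
        return self.as_matrix().apply(pts)

    def inverse(self) -> MatrixTransform2D:
        return self.as_matrix().inverse()

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "tx_nm": float(self.tx_nm),
            "ty_nm": float(self.ty_nm),
            "theta_deg": float(self.theta_deg),
            "sx": float(self.sx),
            "sy": float(self.sy),
            "centre_nm": [float(self.centre_nm[0]), float(self.centre_nm[1])],
            "convention": COORD_CONVENTION,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform2D":
        return cls(
            tx_nm=d["tx_nm"], ty_nm=d["ty_nm"], theta_deg=d["theta_deg"],
            sx=d["sx"], sy=d["sy"], centre_nm=tuple(d["centre_nm"]),
        )


class WarpModel:
    """Thin-plate-spline displacement field fitted to landmark residuals.

    Maps a point ``p`` (reference-frame nm, i.e. after the affine stage) to
    ``p + d(p)`` where ``d`` interpolates the control-point displacements.
    With fewer than 3 non-collinear controls the spline degenerates to its
    affine part — here a pure translation by the mean displacement.

    Parameters
    ----------
    control_points_nm : (n, 2) array
        Landmark positions in the reference frame.
    displacements_nm : (n, 2) array
        Residual displacement each control should be moved by.
    smoothing : float
        TPS regularisation λ ≥ 0; 0 means exact interpolation.
    """

    def __init__(self, control_points_nm, displacements_nm, smoothing: float = 0.0):
        cp = _as_points(control_points_nm)
        dp = _as_points(displacements_nm)
        if cp.shape != dp.shape:
            raise InputError("control points and displacements must have equal shapes")
        if smoothing < 0:
            raise InputError("smoothing must be >= 0")
        self.control_points_nm = cp
        self.displacements_nm = dp
        self.smoothing = float(smoothing)
        self._rbf = None
        self._fallback_shift = None
        if len(cp) >= 3 and not _collinear(cp):
            self._rbf = RBFInterpolator(
                cp, dp, kernel="thin_plate_spline", smoothing=self.smoothing, degree=1
            )
        elif self.smoothing == 0.0 and len(cp) >= 3:
            raise DegenerateGeometryError(
                "collinear control points with smoothing=0; increase smoothing or add landmarks"
            )
        else:
            # affine-only fallback: rigid translation by the mean displacement
            self._fallback_shift = dp.mean(axis=0)

    def displacement(self, pts) -> np.ndarray:
        pts = _as_points(pts)
        if self._rbf is not None:
            return self._rbf(pts)
        return np.broadcast_to(self._fallback_shift, pts.shape).copy()

    def apply(self, pts) -> np.ndarray:
        pts = _as_points(pts)
        return pts + self.displacement(pts)

    def apply_inverse(self, pts, n_iter: int = 4) -> np.ndarray:
        """Approximate inverse by fixed-point iteration p ← q − d(p).

        Converges rapidly for the smooth, small-magnitude (≪ field size)
        distortions this model corrects.
        """
        q = _as_points(pts)
        p = q.copy()
        for _ in range(n_iter):
            p = q - self.displacement(p)
        return p

    def to_dict(self) -> dict:
        return {
            "kernel": "thin_plate_spline",
            "smoothing": self.smoothing,
            "control_points_nm": self.control_points_nm.tolist(),
            "displacements_nm": self.displacements_nm.tolist(),
            "convention": COORD_CONVENTION,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WarpModel":
        return cls(d["control_points_nm"], d["displacements_nm"], d.get("smoothing", 0.0))


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    if len(pts) < 3:
        return True
    centred = pts - pts.mean(axis=0)
    # rank < 2 within tolerance relative to the point-cloud extent
    s = np.linalg.svd(centred, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)
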