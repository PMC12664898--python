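"""Mapping raw sample-space nuclear coordinates into atlas space.

The registration convention mirrors the common ANTs-style point workflow:
the *forward* affine (tagged ``atlas->sample``) is applied **inversely** to
move sample points toward the atlas, and the stored *inverse* deformation
field (displacements on the atlas grid, in micrometres) is then applied
**directly** by trilinear sampling and addition.  Estimating the nonlinear
field itself is delegated to external registration tools; this module only
estimates the affine part and applies supplied fields.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from .core import NucleusSet, Volume

logger = logging.getLogger(__name__)

__all__ = [
    "AffineTransform",
    "DeformationField",
    "TransformChain",
    "invert_affine",
    "apply_chain_to_points",
    "resample_to_atlas",
    "estimate_affine",
    "point_to_voxel",
]

_DIRECTIONS = ("sample->atlas", "atlas->sample")


@dataclass(frozen=True)
class AffineTransform:
    """y = linear @ x + translation, with an explicit direction tag."""

    linear: np.ndarray
    translation: np.ndarray
    direction: str

    def __post_init__(self):
        lin = np.asarray(self.linear, dtype=float).reshape(3, 3)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}, got {self.direction!r}")
        cond = np.linalg.cond(lin)
        if not np.isfinite(cond):
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls, direction: str = "atlas->sample") -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3), direction)

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        return pts @ self.linear.T + self.translation


def invert_affine(a: AffineTransform) -> AffineTransform:
    """Inverse map with the direction tag flipped."""
    inv = np.linalg.inv(a.linear)
    flipped = "atlas->sample" if a.direction == "sample->atlas" else "sample->atlas"
    return AffineTransform(inv, -inv @ a.translation, flipped)


@dataclass(frozen=True)
class DeformationField:
    """Grid of 3-component displacement vectors (um) on atlas-grid geometry."""

    displacements_um: np.ndarray  # (nx, ny, nz, 3)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        disp = np.asarray(self.displacements_um, dtype=float)
        if disp.ndim != 4 or disp.shape[-1] != 3:
            raise ValueError(f"displacement grid must be (nx,ny,nz,3), got {disp.shape}")
        if not np.all(np.isfinite(disp)):
            raise ValueError("non-finite displacements")
        object.__setattr__(self, "displacements_um", disp)
        object.__setattr__(self, "spacing", tuple(float(s) for s in np.broadcast_to(self.spacing, (3,))))
        object.__setattr__(self, "origin", tuple(float(s) for s in np.broadcast_to(self.origin, (3,))))

    def sample(self, points_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Trilinearly interpolated displacement at each point.

        Points outside the field support are clamped to the nearest edge
        displacement; the second return value flags them.
        """
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        # displacement samples live at voxel centres of the atlas grid
        coords = (pts - np.asarray(self.origin)) / np.asarray(self.spacing) - 0.5
        shape = np.asarray(self.displacements_um.shape[:3])
        outside = np.any((coords < -0.5) | (coords > shape - 0.5), axis=1)
        clamped = np.clip(coords, 0, shape - 1).T
        out = np.empty_like(pts)
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.displacements_um[..., c], clamped, order=1, mode="nearest")
        return out, outside


@dataclass(frozen=True)
class TransformChain:
    """Affine (used inversely) + optional deformation field (applied directly).

    ``sample_to_atlas`` is the map the pipeline consumes.  The opposite
    direction (used by the synthetic generator to place "acquired" data)
    inverts the displacement part by fixed-point iteration, which converges
    quickly for the smooth, few-voxel-amplitude fields in scope.
    """

    affine: AffineTransform = dc_field(default_factory=AffineTransform.identity)
    field: DeformationField | None = None

    def __post_init__(self):
        if self.affine.direction != "atlas->sample":
            raise ValueError(
                "TransformChain stores the forward affine tagged 'atlas->sample' "
                f"(used inversely); got {self.affine.direction!r}")

    def sample_to_atlas(self, points_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map sample-space points to atlas space; also returns outside flags."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        out = invert_affine(self.affine).apply(pts)
        outside = np.zeros(len(out), dtype=bool)
        if self.field is not None:
            disp, outside = self.field.sample(out)
            out = out + disp
        return out, outside

    def atlas_to_sample(self, points_um: np.ndarray, tol_um: float = 1e-3,
                        max_iter: int = 100) -> np.ndarray:
        """Numerically exact inverse of :meth:`sample_to_atlas`."""
        q = np.atleast_2d(np.asarray(points_um, dtype=float))
        u = q.copy()
        if self.field is not None:
            for _ in range(max_iter):
                disp, _ = self.field.sample(u)
                nxt = q - disp
                if np.max(np.abs(nxt - u)) < tol_um:
                    u = nxt
                    break
                u = nxt
        return self.affine.apply(u)


def apply_chain_to_points(points: NucleusSet, chain: TransformChain) -> NucleusSet:
    """Normalize a sample-space NucleusSet into atlas space.

    Points landing outside the deformation-field support are clamped to the
    edge displacement and flagged in an ``outside`` column — never dropped.
    """
    if points.space != "sample":
        raise ValueError(f"points must be tagged 'sample', got {points.space!r}")
    coords, outside = chain.sample_to_atlas(points.coords())
    out = points.with_coords(coords, space="atlas")
    out.points["outside"] = outside
    if outside.any():
        logger.warning("%d/%d points landed outside the deformation-field support",
                       int(outside.sum()), len(out))
    return out


def resample_to_atlas(volume: Volume, atlas_spacing_um: float | tuple,
                      mode: str = "auto") -> Volume:
    """Resample a volume to the atlas voxel size.

    Downsampling by an integer factor uses block means (mass-conserving);
    anything else falls back to spline interpolation with Gaussian
    anti-aliasing when shrinking.
    """
    target = np.broadcast_to(np.asarray(atlas_spacing_um, dtype=float), (3,))
    if np.any(target <= 0):
        raise ValueError("atlas spacing must be positive")
    src = np.asarray(volume.spacing)
    if np.allclose(target, src):
        return volume
    ratio = target / src
    int_ratio = np.round(ratio).astype(int)
    if mode in ("auto", "block") and np.allclose(ratio, int_ratio) and np.all(int_ratio >= 1):
        f = int_ratio
        trimmed = volume.data[: volume.shape[0] // f[0] * f[0],
                              : volume.shape[1] // f[1] * f[1],
                              : volume.shape[2] // f[2] * f[2]]
        new_shape = np.asarray(trimmed.shape) // f
        data = trimmed.reshape(new_shape[0], f[0], new_shape[1], f[1],
                               new_shape[2], f[2]).mean(axis=(1, 3, 5))
    else:
        logger.info("non-integer resampling ratio %s; using interpolation", ratio)
        blur = np.where(ratio > 1, 0.4 * np.sqrt(ratio**2 - 1), 0.0)
        smoothed = ndimage.gaussian_filter(np.asarray(volume.data, dtype=float), blur)
        new_shape = np.maximum(1, np.floor(np.asarray(volume.shape) * src / target)).astype(int)
        idx = np.indices(new_shape, dtype=float)
        # sample at centres of the target voxels, expressed in source voxel units
        coords = [(idx[d] + 0.5) * ratio[d] - 0.5 for d in range(3)]
        data = ndimage.map_coordinates(smoothed, coords, order=1, mode="nearest")
    return Volume(data, tuple(target), volume.origin)


def _params_to_affine(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """12-vector -> (3x3 linear, translation): rotations (rad), log-scales, shears, t."""
    rx, ry, rz = p[0:3]
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    S = np.diag(np.exp(p[3:6]))
    Sh = np.array([[1, p[6], p[7]], [0, 1, p[8]], [0, 0, 1]])
    return Rx @ Ry @ Rz @ S @ Sh, p[9:12].copy()


def _moments(vol: Volume) -> tuple[np.ndarray, float]:
    w = np.clip(np.asarray(vol.data, dtype=float), 0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate intensity distribution (non-positive mass)")
    idx = np.indices(vol.shape, dtype=float)
    com_vox = np.array([(idx[d] * w).sum() / total for d in range(3)])
    com = (com_vox + 0.5) * np.asarray(vol.spacing) + np.asarray(vol.origin)
    return com, total


def _warp_cost(p: np.ndarray, moving: Volume, fixed: Volume) -> float:
    lin, tr = _params_to_affine(p)
    # map fixed voxel centres through the atlas->sample affine, sample moving there
    inv_lin = np.linalg.inv(lin)
    sp_f = np.asarray(fixed.spacing); sp_m = np.asarray(moving.spacing)
    # voxel-centre coordinate maps composed into ndimage's pull-back form
    A = np.diag(1 / sp_m) @ lin @ np.diag(sp_f)
    b = (np.diag(1 / sp_m) @ (lin @ (np.asarray(fixed.origin) + 0.5 * sp_f)
                              + tr - np.asarray(moving.origin))) - 0.5
    warped = ndimage.affine_transform(np.asarray(moving.data, dtype=float), A, offset=b,
                                      output_shape=fixed.shape, order=1, mode="constant")
    diff = warped - np.asarray(fixed.data, dtype=float)
    return float(np.mean(diff * diff))


def estimate_affine(moving: Volume, fixed: Volume, init: str = "moments",
                    seed: int = 0) -> AffineTransform:
    """Estimate the forward (atlas->sample) affine aligning *moving* to *fixed*.

    *fixed* is the atlas-side reference (e.g. the average template) and
    *moving* the sample autofluorescence volume.  Initialization places the
    centres of mass on top of each other; refinement minimizes mean-squared
    intensity error with a derivative-free simplex search.  Deterministic for
    a given seed.
    """
    if init not in ("moments", "identity"):
        raise ValueError(f"init must be 'moments' or 'identity', got {init!r}")
    p0 = np.zeros(12)
    if init == "moments":
        com_m, _ = _moments(moving)
        com_f, _ = _moments(fixed)
        p0[9:12] = com_m - com_f  # atlas->sample translation
    rng = np.random.default_rng(seed)
    cost0 = _warp_cost(p0, moving, fixed)
    scale = np.concatenate([np.full(3, 0.05), np.full(3, 0.05), np.full(3, 0.02),
                            np.full(3, 2.0 * np.max(fixed.spacing))])
    best_p, best_cost = p0, cost0
    res = optimize.minimize(
        _warp_cost, p0, args=(moving, fixed), method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-4, "fatol": 1e-10,
                 "initial_simplex": p0 + np.vstack([np.zeros(12), np.diag(scale)])
                 + rng.normal(0, 1e-9, (13, 12))})
    if res.fun < best_cost:
        best_p, best_cost = res.x, float(res.fun)
    else:
        warnings.warn("affine refinement failed to improve over initialization")
    lin, tr = _params_to_affine(best_p)
    logger.info("estimate_affine: cost %.4g -> %.4g", cost0, best_cost)
    return AffineTransform(lin, tr, "atlas->sample")


def point_to_voxel(point_um: np.ndarray, spacing, shape,
                   origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Half-open voxel binning: index = floor((point - origin) / spacing).

    Out-of-grid points get the sentinel index (-1, -1, -1).
    """
    vol = Volume(np.zeros((1, 1, 1)), spacing, origin)
    pts = np.atleast_2d(np.asarray(point_um, dtype=float))
    idx = np.floor((pts - np.asarray(vol.origin)) / np.asarray(vol.spacing)).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    idx[~inside] = -1
    return idx
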