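"""Homography estimation, warping and mosaicking of the thermal views.

Two low-resolution thermal cameras view the scene from slightly tilted
positions; both are registered into the RGB camera's point of view with
3×3 projective transforms (homographies).  Correspondences are supplied
as point pairs (in the original setup ten points were clicked once, the
cameras being rigidly mounted).  Estimation runs normalized DLT inside a
seeded RANSAC loop, then refits on the consensus set.

Warped frames carry NaN outside the source footprint so that invalid
pixels are distinguishable from cold ones; the mosaic gives camera 1
precedence in the overlap (it views the upper body).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.measure import ransac as _sk_ransac
from skimage.transform import ProjectiveTransform, warp as _sk_warp

__all__ = [
    "Homography",
    "CorrespondenceSet",
    "estimate_homography",
    "warp_frame",
    "mosaic",
    "upscale_nearest",
]


@dataclass(frozen=True)
class Homography:
    """3×3 projective map, normalized so the bottom-right element is 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if m[2, 2] == 0 or not np.isfinite(m).all():
            raise ValueError("invalid homography matrix")
        m = m / m[2, 2]
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("homography is singular")
        object.__setattr__(self, "matrix", m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` pixel coordinates (x, y) through the homography."""
        pts = np.asarray(points, dtype=float)
        ones = np.ones((pts.shape[0], 1))
        h = (self.matrix @ np.hstack([pts, ones]).T).T
        return h[:, :2] / h[:, 2:3]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def compose(self, other: "Homography") -> "Homography":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return Homography(self.matrix @ other.matrix)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.matrix.tolist(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Homography":
        return cls(np.array(json.loads(Path(path).read_text())))

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "Homography":
        m = np.eye(3)
        m[0, 2], m[1, 2] = dx, dy
        return cls(m)

    @classmethod
    def scale_translate(cls, sx: float, sy: float, dx: float = 0.0, dy: float = 0.0) -> "Homography":
        m = np.diag([sx, sy, 1.0])
        m[0, 2], m[1, 2] = dx, dy
        return cls(m)


@dataclass(frozen=True)
class CorrespondenceSet:
    """Paired source/destination pixel coordinates, ``(n, 2)`` each, n >= 4."""

    src: np.ndarray
    dst: np.ndarray

    def __post_init__(self) -> None:
        src = np.atleast_2d(np.asarray(self.src, dtype=float))
        dst = np.atleast_2d(np.asarray(self.dst, dtype=float))
        if src.shape != dst.shape or src.shape[1] != 2:
            raise ValueError("src and dst must both be (n, 2)")
        if src.shape[0] < 4:
            raise ValueError("need at least 4 correspondences")
        if len(np.unique(src, axis=0)) != src.shape[0]:
            raise ValueError("duplicated source points")
        object.__setattr__(self, "src", src)
        object.__setattr__(self, "dst", dst)

    def __len__(self) -> int:
        return self.src.shape[0]

    def to_csv(self, path: str | Path) -> None:
        arr = np.hstack([self.src, self.dst])
        header = "x_src,y_src,x_dst,y_dst"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrespondenceSet":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(src=arr[:, :2], dst=arr[:, 2:4])


def estimate_homography(
    corr: CorrespondenceSet,
    ransac_threshold: float = 2.0,
    max_iter: int = 1000,
    seed: int = 0,
) -> tuple[Homography, np.ndarray]:
    """Estimate the source→destination homography with RANSAC + DLT refit.

    Returns the homography and a boolean inlier mask.  Deterministic for
    a fixed seed.  Raises if fewer than 4 correspondences end up in the
    consensus set.
    """
    model, inliers = _sk_ransac(
        (corr.src, corr.dst),
        ProjectiveTransform,
        min_samples=4,
        residual_threshold=ransac_threshold,
        max_trials=max_iter,
        rng=np.random.default_rng(seed),
    )
    if model is None or inliers is None or inliers.sum() < 4:
        raise ValueError(
            f"homography estimation failed: {0 if inliers is None else int(inliers.sum())}"
            " inliers (need >= 4)"
        )
    # refit on the full consensus set (normalized DLT)
    refit = ProjectiveTransform.from_estimate(corr.src[inliers], corr.dst[inliers])
    if not refit:
        raise ValueError("degenerate consensus set; homography unidentifiable")
    return Homography(refit.params), np.asarray(inliers, dtype=bool)


def upscale_nearest(frame: np.ndarray, factor: int = 4) -> np.ndarray:
    """Nearest-neighbour upscaling (no invented sub-sensor temperatures)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return np.repeat(np.repeat(frame, factor, axis=0), factor, axis=1)


def upscale_transform(factor: int) -> Homography:
    """Homography mapping original pixel centers to upscaled pixel centers.

    Pixel ``i`` maps to the center of its ``factor``-wide block:
    ``x_up = factor * x + (factor - 1) / 2``.
    """
    off = (factor - 1) / 2.0
    return Homography.scale_translate(factor, factor, off, off)


def warp_frame(
    frame: np.ndarray,
    h: Homography,
    output_size: tuple[int, int],
) -> np.ndarray:
    """Warp a temperature grid by ``h`` (source→output coordinates).

    Inverse-mapping warp with bilinear interpolation; output pixels whose
    preimage falls outside the source are NaN (invalid), never zero.
    ``output_size`` is ``(height, width)``.
    """
    warped = _sk_warp(
        np.asarray(frame, dtype=float),
        inverse_map=ProjectiveTransform(matrix=h.inverse().matrix),
        output_shape=output_size,
        order=1,
        cval=np.nan,
        preserve_range=True,
    )
    return warped


def mosaic(warped1: np.ndarray, warped2: np.ndarray) -> np.ndarray:
    """Combine two warped thermal frames; camera 1 wins in the overlap.

    A pixel valid in only one frame takes that frame's value; valid in
    both → camera 1; valid in neither → NaN.
    """
    if warped1.shape != warped2.shape:
        raise ValueError(f"shape mismatch: {warped1.shape} vs {warped2.shape}")
    out = np.where(np.isnan(warped1), warped2, warped1)
    return out
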