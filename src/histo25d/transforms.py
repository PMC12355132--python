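"""2-D similarity transforms and image resampling.

One geometric convention is used throughout the package: coordinates are
0-based with ``x`` the column index (rightward) and ``y`` the row index
(downward); point sets are ``(M, 2)`` arrays of ``(x, y)`` pairs.  A
similarity transform maps ``p' = s * R(theta) @ p + (tx, ty)`` — rotation,
isotropic scale and translation only, so shapes are preserved (this is the
"morphology-preserving" constraint of the rigid alignment stage: shear and
anisotropic stretching would distort gland outlines).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import skimage.transform


@dataclass(frozen=True)
class SimilarityTransform2D:
    """Rotation + isotropic scale + translation in pixel units.

    Parameters
    ----------
    theta : float
        Rotation angle in radians (counter-clockwise in the x-right /
        y-down pixel frame, i.e. visually clockwise).
    scale : float
        Isotropic scale factor, strictly positive.
    tx, ty : float
        Translation in pixels.
    level_mpp : float
        Microns-per-pixel of the resolution level the transform was
        estimated at.  ``rescale_transform`` keeps it consistent when the
        transform is propagated across pyramid levels.
    """

    theta: float = 0.0
    scale: float = 1.0
    tx: float = 0.0
    ty: float = 0.0
    level_mpp: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.theta, self.scale, self.tx, self.ty]).all():
            raise ValueError("similarity parameters must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    # -- matrix forms ------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) column vectors."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        a = self.scale
        return np.array(
            [[a * c, -a * s, self.tx],
             [a * s, a * c, self.ty],
             [0.0, 0.0, 1.0]]
        )

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:2, :2]

    @classmethod
    def from_matrix(cls, m: np.ndarray, level_mpp: float = 1.0) -> "SimilarityTransform2D":
        """Build from a homogeneous matrix; rejects reflections and shear."""
        m = np.asarray(m, dtype=float)
        lin = m[:2, :2]
        det = float(np.linalg.det(lin))
        if det <= 0:
            raise ValueError("matrix has non-positive determinant (reflection)")
        scale = float(np.sqrt(det))
        rot = lin / scale
        # rot must be a pure rotation for a valid similarity
        if not np.allclose(rot @ rot.T, np.eye(2), atol=1e-6):
            raise ValueError("matrix contains shear; not a similarity")
        theta = float(np.arctan2(rot[1, 0], rot[0, 0]))
        return cls(theta=theta, scale=scale, tx=float(m[0, 2]), ty=float(m[1, 2]),
                   level_mpp=level_mpp)

    # -- algebra -----------------------------------------------------------
    def inverse(self) -> "SimilarityTransform2D":
        c, s = np.cos(self.theta), np.sin(self.theta)
        inv_scale = 1.0 / self.scale
        # p = (1/s) R(-theta) (p' - t)
        tx = -inv_scale * (c * self.tx + s * self.ty)
        ty = -inv_scale * (-s * self.tx + c * self.ty)
        return SimilarityTransform2D(theta=-self.theta, scale=inv_scale,
                                     tx=tx, ty=ty, level_mpp=self.level_mpp)

    def compose(self, other: "SimilarityTransform2D") -> "SimilarityTransform2D":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        m = self.matrix @ other.matrix
        out = SimilarityTransform2D.from_matrix(m, level_mpp=other.level_mpp)
        return out

    def __matmul__(self, other: "SimilarityTransform2D") -> "SimilarityTransform2D":
        return self.compose(other)

    @classmethod
    def identity(cls, level_mpp: float = 1.0) -> "SimilarityTransform2D":
        return cls(level_mpp=level_mpp)

    @classmethod
    def about_center(cls, theta: float, scale: float, tx: float, ty: float,
                     center: tuple[float, float],
                     level_mpp: float = 1.0) -> "SimilarityTransform2D":
        """Similarity rotating/scaling about ``center`` then translating.

        ``p' = s R (p - c) + c + t`` expressed in the canonical
        origin-anchored form.
        """
        c = np.asarray(center, dtype=float)
        base = cls(theta=theta, scale=scale, tx=0.0, ty=0.0, level_mpp=level_mpp)
        shift = c + np.array([tx, ty]) - base.linear @ c
        return replace(base, tx=float(shift[0]), ty=float(shift[1]))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "theta_deg": float(np.degrees(self.theta)),
            "scale": float(self.scale),
            "tx": float(self.tx),
            "ty": float(self.ty),
            "level_mpp": float(self.level_mpp),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform2D":
        return cls(theta=float(np.radians(d["theta_deg"])), scale=float(d["scale"]),
                   tx=float(d["tx"]), ty=float(d["ty"]),
                   level_mpp=float(d.get("level_mpp", 1.0)))


def transform_points(points: np.ndarray, t: SimilarityTransform2D) -> np.ndarray:
    """Apply a similarity transform to an ``(M, 2)`` array of (x, y) points."""
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 2:
        raise ValueError("points must have shape (M, 2)")
    if not np.isfinite(pts).all():
        raise ValueError("points contain non-finite coordinates")
    out = pts @ t.linear.T + np.array([t.tx, t.ty])
    return out[0] if squeeze else out


def rescale_transform(t: SimilarityTransform2D, factor: float) -> SimilarityTransform2D:
    """Propagate a transform to a resolution level ``factor`` times finer.

    Translations scale linearly with the pyramid level; rotation angle and
    scale factor are resolution-independent.
    """
    if factor <= 0:
        raise ValueError(f"factor must be positive, got {factor}")
    return replace(t, tx=t.tx * factor, ty=t.ty * factor,
                   level_mpp=t.level_mpp / factor)


def warp_similarity(img: np.ndarray, t: SimilarityTransform2D,
                    out_shape: tuple[int, int] | None = None,
                    *, is_mask: bool = False) -> np.ndarray:
    """Render ``img`` transformed by ``t`` (backward resampling).

    Every output pixel ``q`` is sampled at the inverse-mapped source
    location ``t⁻¹(q)``; bilinear interpolation for intensity images,
    nearest-neighbour for masks.  Out-of-bounds regions are filled with
    white (255) for intensity images and 0 for masks, matching the white
    slide background.
    """
    img = np.asarray(img)
    if out_shape is None:
        out_shape = img.shape[:2]
    inv = t.inverse()
    sk_t = skimage.transform.SimilarityTransform(matrix=inv.matrix)
    order = 0 if is_mask else 1
    cval = 0.0 if is_mask else 255.0
    out = skimage.transform.warp(
        img.astype(float), sk_t, output_shape=out_shape, order=order,
        mode="constant", cval=cval, preserve_range=True,
    )
    return out.astype(img.dtype) if np.issubdtype(img.dtype, np.integer) or img.dtype == bool else out


def save_transform_chain(path, transforms, extra=None) -> None:
    """Serialize a transform chain as JSON (one record per section)."""
    records = []
    for i, t in enumerate(transforms):
        rec = {"section": i, **t.to_dict()}
        if extra is not None and i < len(extra):
            rec.update(extra[i])
        records.append(rec)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2, sort_keys=True)


def load_transform_chain(path) -> list[SimilarityTransform2D]:
    with open(path) as fh:
        records = json.load(fh)
    return [SimilarityTransform2D.from_dict(r) for r in records]
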