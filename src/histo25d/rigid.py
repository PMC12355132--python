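"""Serial rigid (similarity) registration of a section stack.

Keypoints and descriptors come from the scale-invariant feature
transform (SIFT); candidate assignments are one-to-one mutual-nearest
matches filtered by Lowe's ratio test, and the per-pair transform is a
robust consensus (RANSAC) similarity fit — rotation, isotropic scale and
translation only, so the fitted map cannot shear or reflect tissue.

Registration is serial: the first section is the reference, each later
section is registered against the already-registered *rendering* of its
predecessor, so every returned transform maps that section's native
coordinates directly into the reference frame.  The matcher sits behind
a small functional interface so a learned matcher (e.g. an
optimal-transport assignment model) can be substituted without touching
the consensus fit or the chaining logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import skimage.color
import skimage.feature
import skimage.measure
import skimage.transform

from histo25d.image import SectionImage, as_section
from histo25d.segmentation import TissueMask
from histo25d.transforms import (
    SimilarityTransform2D,
    rescale_transform,
    transform_points,
    warp_similarity,
)

__all__ = [
    "KeypointSet", "MatchSet", "PairDiagnostics",
    "detect_keypoints", "match_keypoints", "estimate_similarity",
    "register_stack_serial", "rescale_transform", "warp_similarity",
    "InsufficientMatchesError", "DegenerateFitError",
]


class InsufficientMatchesError(RuntimeError):
    """Fewer candidate pairs than a similarity fit requires."""


class DegenerateFitError(RuntimeError):
    """Matched points are collinear/coincident; no unique similarity."""


@dataclass
class KeypointSet:
    """SIFT keypoints of one image: (x, y) positions plus descriptors."""

    positions: np.ndarray     # (M, 2) float, (x, y)
    descriptors: np.ndarray   # (M, d) float
    scales: np.ndarray = field(default_factory=lambda: np.empty(0))
    orientations: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def empty(cls, d: int = 128) -> "KeypointSet":
        return cls(positions=np.empty((0, 2)), descriptors=np.empty((0, d)))


@dataclass
class MatchSet:
    """One-to-one keypoint correspondences between two sets."""

    pairs: np.ndarray         # (P, 2) int: (index_in_A, index_in_B)
    distances: np.ndarray     # (P,) descriptor distances
    inlier_flags: np.ndarray  # (P,) bool, set by the robust fit

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def empty(cls) -> "MatchSet":
        return cls(pairs=np.empty((0, 2), dtype=int), distances=np.empty(0),
                   inlier_flags=np.empty(0, dtype=bool))


@dataclass
class PairDiagnostics:
    """Inlier correspondences of one adjacent pair, in native frames."""

    pair_index: int                  # registers section pair_index -> pair_index - 1
    n_matches: int
    n_inliers: int
    points_moving: np.ndarray        # native coords in section pair_index
    points_fixed: np.ndarray         # native coords in section pair_index - 1


def detect_keypoints(img: SectionImage | np.ndarray,
                     max_keypoints: int = 2000,
                     mask: TissueMask | np.ndarray | None = None,
                     upsampling: int = 2) -> KeypointSet:
    """SIFT keypoints, optionally restricted to a tissue mask.

    Deterministic for a fixed image.  A blank image yields an empty set.
    ``upsampling=1`` skips the initial 2x image upsampling — about an
    order of magnitude faster but with fewer, coarser keypoints and
    poorer sub-pixel localization.
    """
    sec = as_section(img)
    gray = sec.to_gray()
    if np.ptp(gray) == 0:
        return KeypointSet.empty()
    det = skimage.feature.SIFT(upsampling=upsampling)
    try:
        det.detect_and_extract(gray)
    except RuntimeError:  # SIFT raises when no extrema survive
        return KeypointSet.empty()
    pos = det.keypoints[:, ::-1].astype(float)  # (row, col) -> (x, y)
    desc = det.descriptors.astype(float)
    scales = det.scales.astype(float)
    orients = det.orientations.astype(float)
    if mask is not None:
        m = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask).astype(bool)
        keep = m[pos[:, 1].astype(int), pos[:, 0].astype(int)]
        pos, desc, scales, orients = pos[keep], desc[keep], scales[keep], orients[keep]
    if len(pos) > max_keypoints:
        pos, desc = pos[:max_keypoints], desc[:max_keypoints]
        scales, orients = scales[:max_keypoints], orients[:max_keypoints]
    return KeypointSet(positions=pos, descriptors=desc,
                       scales=scales, orientations=orients)


def match_keypoints(a: KeypointSet, b: KeypointSet,
                    ratio: float = 0.75, mutual: bool = True) -> MatchSet:
    """One-to-one descriptor matches with Lowe-ratio and mutual-NN filters.

    A keypoint whose nearest/second-nearest descriptor distance ratio
    exceeds ``ratio`` is dropped (ambiguous); with ``mutual`` each pair
    must be nearest in both directions.
    """
    if len(a) == 0 or len(b) == 0:
        return MatchSet.empty()
    pairs = skimage.feature.match_descriptors(
        a.descriptors, b.descriptors, metric="euclidean",
        max_ratio=ratio, cross_check=mutual)
    if not mutual:
        # enforce one-to-one on the b side: keep the closest a per b
        d_all = np.linalg.norm(a.descriptors[pairs[:, 0]] - b.descriptors[pairs[:, 1]], axis=1)
        order = np.argsort(d_all)
        seen: set[int] = set()
        keep = []
        for i in order:
            if pairs[i, 1] not in seen:
                seen.add(int(pairs[i, 1]))
                keep.append(i)
        pairs = pairs[np.sort(keep)]
    d = np.linalg.norm(a.descriptors[pairs[:, 0]] - b.descriptors[pairs[:, 1]], axis=1)
    return MatchSet(pairs=pairs, distances=d,
                    inlier_flags=np.ones(len(pairs), dtype=bool))


def estimate_similarity(matches: MatchSet, a: KeypointSet, b: KeypointSet,
                        inlier_tol_px: float = 3.0, seed: int = 0,
                        max_trials: int = 500) -> SimilarityTransform2D:
    """Robust similarity fit mapping A-coordinates onto B-coordinates.

    RANSAC consensus with a fixed seed over closed-form similarity fits,
    followed by a least-squares refit on all inliers; ``inlier_flags`` on
    ``matches`` are updated in place.  Reflections cannot be produced.
    """
    if len(matches) < 3:
        raise InsufficientMatchesError(
            f"need at least 3 candidate pairs, got {len(matches)}")
    src = a.positions[matches.pairs[:, 0]]
    dst = b.positions[matches.pairs[:, 1]]
    if np.linalg.matrix_rank(src - src.mean(axis=0)) < 1:
        raise DegenerateFitError("matched points are coincident")
    model, inliers = skimage.measure.ransac(
        (src, dst), skimage.transform.SimilarityTransform,
        min_samples=3, residual_threshold=inlier_tol_px,
        max_trials=max_trials, rng=seed)
    if model is None or inliers is None or inliers.sum() < 3:
        raise DegenerateFitError("robust similarity fit failed")
    # least-squares refit on the consensus set, then one tightening pass:
    # re-select at half the tolerance and refit, which suppresses the
    # localization noise of borderline inliers without losing robustness
    inl = np.asarray(inliers, dtype=bool)
    refit = None
    for tol in (inlier_tol_px, max(1.0, inlier_tol_px / 2.0)):
        cand = skimage.transform.SimilarityTransform.from_estimate(src[inl], dst[inl])
        if not cand:
            raise DegenerateFitError("inlier refit failed (degenerate geometry)")
        refit = cand
        resid = np.linalg.norm(refit(src) - dst, axis=1)
        new_inl = resid <= tol
        if new_inl.sum() >= max(3, 0.25 * inl.sum()):
            inl = new_inl
    final = skimage.transform.SimilarityTransform.from_estimate(src[inl], dst[inl])
    if final:
        refit = final
    matches.inlier_flags = inl
    return SimilarityTransform2D.from_matrix(refit.params)


def register_stack_serial(stack: list[SectionImage],
                          masks: list[TissueMask] | None = None,
                          *,
                          max_keypoints: int = 2000,
                          ratio: float = 0.75,
                          inlier_tol_px: float = 3.0,
                          seed: int = 0,
                          upsampling: int = 2,
                          fall_through: bool = False,
                          return_details: bool = False):
    """Serial chained registration of a z-ordered section stack.

    The first section is the reference; section ``k`` is registered
    against the rendered (already-registered) version of section
    ``k - 1``, so only features present in both neighbours drive each
    link and every returned transform maps section-``k`` native
    coordinates into the reference frame.

    Returns the transform list, plus per-pair :class:`PairDiagnostics`
    when ``return_details`` is set.  A failing pair raises an error
    naming the pair unless ``fall_through`` is enabled, in which case the
    link is treated as identity.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 sections")
    sections = [as_section(s) for s in stack]
    mpp = sections[0].mpp
    shape = sections[0].data.shape[:2]
    mask_arrays = None
    if masks is not None:
        mask_arrays = [m.mask if isinstance(m, TissueMask) else np.asarray(m).astype(bool)
                       for m in masks]

    transforms = [SimilarityTransform2D.identity(level_mpp=mpp)]
    details: list[PairDiagnostics] = []
    rendered_prev = sections[0].data
    rendered_prev_mask = mask_arrays[0] if mask_arrays is not None else None

    for k in range(1, len(sections)):
        kp_prev = detect_keypoints(SectionImage(rendered_prev, mpp=mpp),
                                   max_keypoints, rendered_prev_mask, upsampling)
        kp_k = detect_keypoints(sections[k], max_keypoints,
                                mask_arrays[k] if mask_arrays is not None else None,
                                upsampling)
        try:
            matches = match_keypoints(kp_k, kp_prev, ratio=ratio)
            t_k = estimate_similarity(matches, kp_k, kp_prev,
                                      inlier_tol_px=inlier_tol_px, seed=seed)
        except (InsufficientMatchesError, DegenerateFitError) as exc:
            if not fall_through:
                raise type(exc)(f"registration of pair ({k} -> {k - 1}) failed: {exc}")
            transforms.append(transforms[k - 1])
            details.append(PairDiagnostics(k, 0, 0, np.empty((0, 2)), np.empty((0, 2))))
            rendered_prev = warp_similarity(sections[k].data, transforms[k], shape)
            if mask_arrays is not None:
                rendered_prev_mask = warp_similarity(mask_arrays[k], transforms[k],
                                                     shape, is_mask=True)
            continue
        t_k = SimilarityTransform2D(theta=t_k.theta, scale=t_k.scale,
                                    tx=t_k.tx, ty=t_k.ty, level_mpp=mpp)
        transforms.append(t_k)
        # Diagnostics keep every match that is plausibly correct (within a
        # loose multiple of the fit tolerance), not only the tight fit
        # inliers: non-rigid tissue distortion displaces true matches well
        # beyond the similarity-fit tolerance, and censoring them would
        # bias the registration-error statistic toward zero.
        src_all = kp_k.positions[matches.pairs[:, 0]]
        dst_all = kp_prev.positions[matches.pairs[:, 1]]
        resid = np.linalg.norm(transform_points(src_all, t_k) - dst_all, axis=1)
        keep = resid <= 5.0 * inlier_tol_px
        pts_moving = src_all[keep]
        # rendered-prev coordinates are already reference coordinates;
        # map back through the accumulated chain to section k-1's frame
        pts_fixed = transform_points(dst_all[keep], transforms[k - 1].inverse())
        details.append(PairDiagnostics(k, len(matches), int(keep.sum()),
                                       pts_moving, pts_fixed))
        rendered_prev = warp_similarity(sections[k].data, t_k, shape)
        if mask_arrays is not None:
            rendered_prev_mask = warp_similarity(mask_arrays[k], t_k, shape, is_mask=True)

    if return_details:
        return transforms, details
    return transforms
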