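"""2.5D core assembly, patch tiling and the registration-error statistic.

A co-registered stack of Z sections approximates the biopsy volume
("2.5D core").  For model input the core is tiled into non-overlapping
256x256xZ patches, keeping only tiles with more than 60% tissue — the
threshold is strict, a tile at exactly 0.60 is discarded.  Alignment
quality is summarized per adjacent section pair as the median distance
(in microns) between matched keypoints, and per core as the mean of the
pair medians weighted by each pair's match count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from histo25d.segmentation import TissueMask


@dataclass
class Core25D:
    """Ordered co-registered z-stack of one biopsy core."""

    volume: np.ndarray                  # (Z, H, W, 3) uint8
    masks: list[TissueMask]
    mpp: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume)
        if self.volume.ndim != 4:
            raise ValueError("volume must be (Z, H, W, C)")
        if self.volume.shape[0] < 2:
            raise ValueError("a core needs at least 2 sections")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if len(self.masks) != self.volume.shape[0]:
            raise ValueError("one mask per section required")

    @property
    def n_sections(self) -> int:
        return self.volume.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.volume.shape[1:3]

    def mask_stack(self) -> np.ndarray:
        return np.stack([m.mask for m in self.masks])

    def tissue_bbox(self) -> tuple[int, int, int, int]:
        """Tight half-open bbox of the union of section masks."""
        union = np.logical_or.reduce(self.mask_stack())
        if not union.any():
            raise ValueError("core has no tissue")
        ys, xs = np.nonzero(union)
        return (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


@dataclass
class Patch25D:
    """One 256x256xZ tile of a core."""

    origin: tuple[int, int]             # (x, y) in core coordinates
    data: np.ndarray                    # (Z, patch, patch, 3)
    tissue_fraction: float


@dataclass
class RegistrationReport:
    """Per-pair medians and the match-count-weighted core error."""

    per_pair: list[tuple[int, float, int]]   # (pair index, median um, n matches)
    core_error_um: float

    def to_records(self) -> list[dict]:
        return [{"pair": p, "median_um": m, "n_matches": n} for p, m, n in self.per_pair]


def assemble_core(aligned_sections: list[np.ndarray], masks: list[TissueMask],
                  mpp: float, provenance: dict | None = None) -> Core25D:
    """Stack aligned sections into a core; fails loudly on shape mismatch."""
    if len(aligned_sections) < 2:
        raise ValueError("need at least 2 sections")
    shape0 = np.asarray(aligned_sections[0]).shape
    for i, s in enumerate(aligned_sections):
        if np.asarray(s).shape != shape0:
            raise ValueError(f"section {i} shape {np.asarray(s).shape} != {shape0}")
        if masks[i].mask.shape != shape0[:2]:
            raise ValueError(f"mask {i} shape mismatch")
    volume = np.stack([np.asarray(s) for s in aligned_sections])
    return Core25D(volume=volume, masks=list(masks), mpp=mpp,
                   provenance=provenance or {})


def patch_tissue_fraction(core: Core25D, origin: tuple[int, int],
                          patch_px: int = 256) -> float:
    """Mean over sections of the in-window tissue-pixel fraction."""
    x, y = origin
    h, w = core.shape
    if x < 0 or y < 0 or x + patch_px > w or y + patch_px > h:
        raise ValueError(f"window at {origin} exceeds core bounds {w}x{h}")
    ms = core.mask_stack()[:, y:y + patch_px, x:x + patch_px]
    return float(ms.mean())


def extract_patches(core: Core25D, patch_px: int = 256,
                    min_fraction: float = 0.6) -> list[Patch25D]:
    """Non-overlapping tiles with tissue fraction strictly above threshold.

    The grid is anchored at the top-left of the core's tissue bbox with
    stride ``patch_px``; partial edge tiles are discarded.  Returns an
    empty list when no tile fits.
    """
    h, w = core.shape
    try:
        x0, y0, _, _ = core.tissue_bbox()
    except ValueError:
        return []
    patches = []
    for y in range(y0, h - patch_px + 1, patch_px):
        for x in range(x0, w - patch_px + 1, patch_px):
            frac = patch_tissue_fraction(core, (x, y), patch_px)
            if frac > min_fraction:
                patches.append(Patch25D(
                    origin=(x, y),
                    data=core.volume[:, y:y + patch_px, x:x + patch_px],
                    tissue_fraction=frac))
    return patches


def pair_registration_error(matched_points_a: np.ndarray,
                            matched_points_b: np.ndarray,
                            mpp: float) -> tuple[float, int]:
    """Median keypoint distance in microns for one adjacent pair."""
    pa = np.atleast_2d(np.asarray(matched_points_a, dtype=float))
    pb = np.atleast_2d(np.asarray(matched_points_b, dtype=float))
    if len(pa) == 0 or len(pa) != len(pb):
        raise ValueError("need equal-length non-empty point lists")
    d = np.linalg.norm(pa - pb, axis=1) * mpp
    return float(np.median(d)), int(len(d))


def core_registration_error(report_pairs: list[tuple[float, int]]) -> float:
    """Match-count-weighted mean of the per-pair median errors."""
    if len(report_pairs) == 0:
        raise ValueError("no pair entries")
    medians = np.array([m for m, _ in report_pairs], dtype=float)
    counts = np.array([n for _, n in report_pairs], dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero total matches")
    return float(np.sum(medians * counts) / total)
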