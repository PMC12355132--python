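"""Synthetic serial-section phantoms with known ground truth.

A phantom emulates one needle-core biopsy serially sectioned into 6-16
ribbons: an H&E-like stained ribbon (pink stroma, purple nuclear
speckle, white glandular lumina) on a white slide background.  Each
section is the same base tissue, slightly morphed with depth the way
adjacent serial sections differ, then corrupted by a known similarity
misalignment (placement on the glass) and a smooth low-frequency
non-rigid warp (sectioning distortion).  The corruptions, per-section
tissue masks and cross-section landmark correspondences are all stored,
so every registration stage can be scored against exact ground truth.

Direction convention: ``true_transforms[t]`` maps section-``t``
coordinates INTO reference (section 0) coordinates — the map the rigid
stage must recover.  ``true_warps[t]`` is the backward resampling field
used to render section ``t`` (applied after the similarity corruption).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import skimage.transform

from histo25d.bspline import random_smooth_field
from histo25d.image import SectionImage
from histo25d.nonrigid import DisplacementField, push_points_through_field, warp_dense
from histo25d.transforms import SimilarityTransform2D, transform_points, warp_similarity

# H&E-like palette (RGB)
_STROMA = np.array([226.0, 143.0, 187.0])    # eosin pink
_NUCLEUS = np.array([108.0, 48.0, 138.0])    # hematoxylin purple
_LUMEN = np.array([249.0, 243.0, 247.0])     # near-white gland lumen
_WHITE = 255.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic core.

    Defaults reflect serially sectioned biopsy ribbons: 8 sections (cores
    yield 6-16), placement misalignments of up to 10 degrees rotation,
    3% scale and 20 px translation at the working resolution, and smooth
    sectioning warps of 6 px peak amplitude on a 64 px control grid.
    """

    n_sections: int = 8
    canvas_size: int = 320
    n_glands: int = 6
    rotation_max_deg: float = 10.0
    scale_range: tuple[float, float] = (0.97, 1.03)
    translation_max_px: float = 20.0
    warp_amplitude: float = 6.0
    warp_grid_px: float = 64.0
    noise_sd: float = 4.0
    depth_drift: float = 0.3
    gland_size_frac: tuple[float, float] = (0.025, 0.05)
    mpp: float = 0.5
    n_landmarks: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 2:
            raise ValueError("n_sections must be at least 2")
        if self.canvas_size <= 0:
            raise ValueError("canvas_size must be positive")
        if not (self.scale_range[0] <= 1.0 <= self.scale_range[1]):
            raise ValueError("scale_range must contain 1.0")
        for name in ("rotation_max_deg", "translation_max_px", "warp_amplitude",
                     "noise_sd", "depth_drift"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_glands < 0:
            raise ValueError("n_glands must be non-negative")


@dataclass
class PhantomStack:
    """A generated stack with its complete ground truth."""

    spec: PhantomSpec
    sections: list[SectionImage]
    true_transforms: list[SimilarityTransform2D]
    true_warps: list[DisplacementField]
    landmarks: list[np.ndarray]           # per section, (M, 2) (x, y)
    tissue_truth: list[np.ndarray]        # per section, bool masks
    analytic_tissue_fraction: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.sections)
        for name in ("true_transforms", "true_warps", "landmarks", "tissue_truth"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must equal number of sections")
        cards = {len(lm) for lm in self.landmarks}
        if len(cards) > 1:
            raise ValueError("landmark cardinality differs across sections")


def _ellipse_mask(shape, center, axes, angle) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - center[0], yy - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    xr = dx * ca + dy * sa
    yr = -dx * sa + dy * ca
    return (xr / axes[0]) ** 2 + (yr / axes[1]) ** 2 <= 1.0


def _place_glands(rng, spec, center, tissue_axes, tissue_angle):
    """Rejection-sample disjoint gland ellipses fully inside the tissue."""
    glands = []
    c = spec.canvas_size
    tries = 0
    while len(glands) < spec.n_glands and tries < 400:
        tries += 1
        ax = rng.uniform(*spec.gland_size_frac, size=2) * c
        ang = rng.uniform(0, np.pi)
        # position in tissue-ellipse normalized coordinates, kept well inside
        r = np.sqrt(rng.uniform(0, 1)) * 0.72
        phi = rng.uniform(0, 2 * np.pi)
        ca, sa = np.cos(tissue_angle), np.sin(tissue_angle)
        ex = r * np.cos(phi) * tissue_axes[0]
        ey = r * np.sin(phi) * tissue_axes[1]
        gc = np.array([center[0] + ex * ca - ey * sa, center[1] + ex * sa + ey * ca])
        rmax = ax.max()
        ok = True
        for (oc, oax, _) in glands:
            if np.linalg.norm(gc - oc) < rmax + max(oax) + 5:
                ok = False
                break
        if ok:
            glands.append((gc, ax, ang))
    return glands


def _base_geometry(rng, spec):
    c = spec.canvas_size
    center = np.array([c / 2.0, c / 2.0]) + rng.uniform(-0.02, 0.02, size=2) * c
    axes = np.array([0.33, 0.24]) * c * rng.uniform(0.9, 1.1, size=2)
    angle = rng.uniform(0, np.pi)
    glands = _place_glands(rng, spec, center, axes, angle)
    return center, axes, angle, glands


def _render_reference(rng, spec, tissue, glands_mask, depth_frac, tex0, tex1, lowfreq):
    """H&E-like texture for one depth in reference coordinates."""
    phi = depth_frac * spec.depth_drift
    pattern = np.cos(phi) * tex0 + np.sin(phi) * tex1
    z = (pattern - pattern.mean()) / (pattern.std() + 1e-12)
    nuc_w = np.clip((z - 1.0) / 0.6, 0.0, 1.0)

    img = np.full((*tissue.shape, 3), _WHITE)
    stroma = _STROMA[None, None, :] + lowfreq[..., None] * 18.0
    img[tissue] = stroma[tissue]
    blend = nuc_w[..., None]
    img = np.where(tissue[..., None], img * (1 - blend) + _NUCLEUS[None, None, :] * blend, img)
    img[glands_mask] = _LUMEN
    return img


def generate_phantom_core(spec: PhantomSpec) -> PhantomStack:
    """Generate one synthetic core stack; bit-identical for equal seeds."""
    rng = np.random.default_rng(spec.seed)
    c = spec.canvas_size
    center, axes, angle, glands = _base_geometry(rng, spec)

    tissue_full = _ellipse_mask((c, c), center, axes, angle)
    glands_mask = np.zeros((c, c), dtype=bool)
    for gc, gax, gang in glands:
        glands_mask |= _ellipse_mask((c, c), gc, gax, gang)
    truth_ref = tissue_full & ~glands_mask
    gland_area = sum(np.pi * gax[0] * gax[1] for _, gax, _ in glands)
    analytic_fraction = (np.pi * axes[0] * axes[1] - gland_area) / (c * c)

    # depth-drifting nuclear speckle and a fixed low-frequency eosin modulation
    tex0 = ndi.gaussian_filter(rng.normal(size=(c, c)), 1.4)
    tex1 = ndi.gaussian_filter(rng.normal(size=(c, c)), 1.4)
    lowfreq = ndi.gaussian_filter(rng.normal(size=(c, c)), 12.0)
    lowfreq /= (np.abs(lowfreq).max() + 1e-12)

    # landmarks: fixed anatomical points, well inside the tissue
    eroded = ndi.binary_erosion(truth_ref, iterations=8)
    ys, xs = np.nonzero(eroded)
    idx = rng.choice(len(xs), size=min(spec.n_landmarks, len(xs)), replace=False)
    base_landmarks = np.stack([xs[idx], ys[idx]], axis=1).astype(float)

    sections, transforms, warps, landmarks, truths = [], [], [], [], []
    nz = max(spec.n_sections - 1, 1)
    for t in range(spec.n_sections):
        if t == 0:
            T = SimilarityTransform2D.identity(level_mpp=spec.mpp)
            w = DisplacementField.zero((c, c), spec.warp_grid_px)
        else:
            T = SimilarityTransform2D.about_center(
                theta=np.radians(rng.uniform(-spec.rotation_max_deg, spec.rotation_max_deg)),
                scale=rng.uniform(*spec.scale_range),
                tx=rng.uniform(-spec.translation_max_px, spec.translation_max_px),
                ty=rng.uniform(-spec.translation_max_px, spec.translation_max_px),
                center=(c / 2.0, c / 2.0), level_mpp=spec.mpp)
            u, v = random_smooth_field((c, c), spec.warp_grid_px,
                                       spec.warp_amplitude, rng)
            w = DisplacementField(u, v, spec.warp_grid_px)

        ref_img = _render_reference(rng, spec, truth_ref, glands_mask,
                                    t / nz, tex0, tex1, lowfreq)
        sim_img = warp_similarity(ref_img, T.inverse())
        sim_truth = warp_similarity(truth_ref, T.inverse(), is_mask=True)
        img = warp_dense(sim_img, w)
        truth = warp_dense(sim_truth, w, is_mask=True)
        if spec.noise_sd > 0:
            img = img + rng.normal(scale=spec.noise_sd, size=img.shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

        lm = transform_points(base_landmarks, T.inverse())
        if spec.warp_amplitude > 0 and t > 0:
            lm = push_points_through_field(w, lm)

        sections.append(SectionImage(data=img, mpp=spec.mpp))
        transforms.append(T)
        warps.append(w)
        landmarks.append(lm)
        truths.append(truth.astype(bool))

    return PhantomStack(spec=spec, sections=sections, true_transforms=transforms,
                        true_warps=warps, landmarks=landmarks, tissue_truth=truths,
                        analytic_tissue_fraction=float(analytic_fraction))


def downsample_pyramid(img: SectionImage, factors: list[int]) -> list[SectionImage]:
    """Resolution pyramid: level k has dims floor(original/factor_k).

    Factors must be >= 1 and ascending; microns-per-pixel scales with the
    factor (e.g. 0.25 um/px at 40x becomes 0.5 um/px at 20x for factor 2).
    """
    factors = list(factors)
    if any(f < 1 for f in factors):
        raise ValueError("factors must be >= 1")
    if factors != sorted(factors):
        raise ValueError("factors must be ascending")
    h, w = img.data.shape[:2]
    levels = []
    for f in factors:
        nh, nw = h // f, w // f
        if nh < 1 or nw < 1:
            raise ValueError(f"factor {f} larger than image ({h}x{w})")
        if f == 1:
            data = img.data.copy()
        else:
            out_shape = (nh, nw) if img.data.ndim == 2 else (nh, nw, img.data.shape[2])
            data = skimage.transform.resize(
                img.data.astype(float), out_shape, order=1,
                anti_aliasing=f > 1, preserve_range=True)
            if np.issubdtype(img.data.dtype, np.integer):
                data = np.clip(np.rint(data), 0, 255).astype(img.data.dtype)
        levels.append(SectionImage(data=data, mpp=img.mpp * f, origin=img.origin))
    return levels
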