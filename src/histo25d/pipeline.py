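"""End-to-end alignment: segmentation -> rigid -> non-rigid -> core.

Also computes the registration-error statistic under three conditions —
unregistered, rigid only, and rigid + non-rigid — on the *same* match
population per adjacent pair: the inlier keypoint correspondences found
by the rigid stage, mapped through each condition's transform chain.
Scoring all conditions on one population makes the error ordering a
property of the alignment, not of which keypoints happened to be
detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from histo25d.corestack import (
    Core25D,
    RegistrationReport,
    assemble_core,
    core_registration_error,
    pair_registration_error,
)
from histo25d.image import SectionImage, as_section
from histo25d.nonrigid import (
    DisplacementField,
    build_registration_mask,
    estimate_displacement,
    extract_boundary,
    push_points_through_field,
    warp_dense,
)
from histo25d.rigid import PairDiagnostics, register_stack_serial, warp_similarity
from histo25d.segmentation import TissueMask, compute_tissue_mask
from histo25d.transforms import SimilarityTransform2D, transform_points


@dataclass
class AlignmentResult:
    """Everything the alignment produced, plus per-condition error reports."""

    transforms: list[SimilarityTransform2D]
    fields: list[DisplacementField]
    masks: list[TissueMask]                   # native-frame tissue masks
    aligned_rigid: list[np.ndarray]
    aligned: list[np.ndarray]                 # final (rigid + non-rigid) images
    aligned_masks: list[TissueMask]
    core: Core25D
    registration_bbox: tuple[int, int, int, int]
    pair_diagnostics: list[PairDiagnostics]
    reports: dict[str, RegistrationReport] = field(default_factory=dict)


def _error_report(diags: list[PairDiagnostics], mpp: float,
                  map_moving, map_fixed) -> RegistrationReport:
    pairs = []
    entries = []
    for d in diags:
        if d.n_inliers == 0:
            continue
        pa = map_moving(d.pair_index, d.points_moving)
        pb = map_fixed(d.pair_index - 1, d.points_fixed)
        med, n = pair_registration_error(pa, pb, mpp)
        pairs.append((med, n))
        entries.append((d.pair_index, med, n))
    if not pairs:
        raise ValueError("no usable pairs for the error report")
    return RegistrationReport(per_pair=entries,
                              core_error_um=core_registration_error(pairs))


def evaluate_registration_error(diags: list[PairDiagnostics],
                                transforms: list[SimilarityTransform2D],
                                fields: list[DisplacementField] | None,
                                mpp: float) -> dict[str, RegistrationReport]:
    """Per-condition core registration errors on one match population."""
    identity = lambda k, pts: pts
    rigid_map = lambda k, pts: transform_points(pts, transforms[k])
    reports = {
        "unregistered": _error_report(diags, mpp, identity, identity),
        "rigid": _error_report(diags, mpp, rigid_map, rigid_map),
    }
    if fields is not None:
        def nonrigid_map(k, pts):
            return push_points_through_field(fields[k], transform_points(pts, transforms[k]))
        reports["nonrigid"] = _error_report(diags, mpp, nonrigid_map, nonrigid_map)
    return reports


def align_stack(sections: list[SectionImage | np.ndarray],
                *,
                mpp: float | None = None,
                hue_window="auto",
                closing_radius_px: int = 5,
                max_keypoints: int = 2000,
                ratio: float = 0.75,
                inlier_tol_px: float = 3.0,
                upsampling: int = 2,
                grid_spacing_px: int = 32,
                n_iterations: int = 150,
                bending_weight: float = 0.03,
                seed: int = 0,
                rigid_only: bool = False,
                fall_through: bool = False) -> AlignmentResult:
    """Run the full morphology-preserving alignment on a z-ordered stack."""
    secs = [as_section(s, mpp=mpp or 1.0) for s in sections]
    if mpp is not None:
        for s in secs:
            s.mpp = mpp
    work_mpp = secs[0].mpp
    shape = secs[0].data.shape[:2]

    masks = [compute_tissue_mask(s, hue_window, closing_radius_px) for s in secs]
    transforms, diags = register_stack_serial(
        secs, masks, max_keypoints=max_keypoints, ratio=ratio,
        inlier_tol_px=inlier_tol_px, seed=seed, upsampling=upsampling,
        fall_through=fall_through, return_details=True)

    aligned_rigid = [warp_similarity(s.data, t, shape)
                     for s, t in zip(secs, transforms)]
    rigid_masks = [warp_similarity(m.mask, t, shape, is_mask=True)
                   for m, t in zip(masks, transforms)]
    _, bbox = build_registration_mask(rigid_masks)

    if rigid_only:
        fields = [DisplacementField.zero(shape, grid_spacing_px)
                  for _ in secs]
        aligned = aligned_rigid
        final_masks = rigid_masks
    else:
        fixed_b = extract_boundary(rigid_masks[0])
        fields = [DisplacementField.zero(shape, grid_spacing_px)]
        aligned = [aligned_rigid[0]]
        final_masks = [rigid_masks[0]]
        for k in range(1, len(secs)):
            moving_b = extract_boundary(rigid_masks[k])
            fld = estimate_displacement(fixed_b, moving_b,
                                        grid_spacing_px=grid_spacing_px,
                                        n_iterations=n_iterations,
                                        bending_weight=bending_weight)
            fields.append(fld)
            aligned.append(warp_dense(aligned_rigid[k], fld))
            final_masks.append(warp_dense(rigid_masks[k], fld, is_mask=True))

    aligned_mask_objs = [TissueMask(m, work_mpp) for m in final_masks]
    core = assemble_core(aligned, aligned_mask_objs, work_mpp,
                         provenance={"n_sections": len(secs), "seed": seed,
                                     "rigid_only": rigid_only})
    reports = evaluate_registration_error(
        diags, transforms, None if rigid_only else fields, work_mpp)

    return AlignmentResult(transforms=transforms, fields=fields, masks=masks,
                           aligned_rigid=aligned_rigid, aligned=aligned,
                           aligned_masks=aligned_mask_objs, core=core,
                           registration_bbox=bbox, pair_diagnostics=diags,
                           reports=reports)
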