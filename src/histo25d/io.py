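"""Readers and writers binding the pipeline stages together.

Section images travel as PNG/TIFF; transform chains as JSON; landmark
tables, ribbon tables, patch manifests and registration reports as CSV;
displacement fields as 2-channel 32-bit TIFF; core volumes and patch
stacks as Zarr arrays (Z x Y x X x C, chunked per 256 px tile).  All
non-image outputs are written deterministically (sorted keys, fixed
float formatting) so reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
import zarr
from imageio.v3 import imread, imwrite

from histo25d.corestack import Core25D, Patch25D, RegistrationReport
from histo25d.image import SectionImage
from histo25d.nonrigid import DisplacementField
from histo25d.phantom import PhantomStack
from histo25d.segmentation import TissueMask
from histo25d.transforms import save_transform_chain


@dataclass
class RunConfig:
    """Fully resolved run configuration, echoed next to every output."""

    working_mpp: float = 0.5
    hue_window: str | tuple[float, float] = "auto"
    closing_radius_px: int = 5
    max_keypoints: int = 2000
    ratio: float = 0.75
    inlier_tol_px: float = 3.0
    upsampling: int = 2
    grid_spacing_px: int = 32
    n_iterations: int = 150
    bending_weight: float = 0.03
    patch_px: int = 256
    min_fraction: float = 0.6
    seed: int = 0

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        c = cls(**d)
        if isinstance(c.hue_window, list):
            c.hue_window = tuple(c.hue_window)
        return c


# ---------------------------------------------------------------------------
# sections


def load_section(path, mpp: float = 1.0) -> SectionImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = imread(path)
    return SectionImage(data=np.asarray(data), mpp=mpp)


def load_stack(directory, mpp: float = 1.0, pattern: str = "*.png") -> list[SectionImage]:
    """Z-ordered stack from numbered image files in one directory."""
    files = sorted(Path(directory).glob(pattern))
    if not files:
        raise FileNotFoundError(f"no {pattern} files in {directory}")
    return [load_section(f, mpp) for f in files]


def save_section(path, img: SectionImage | np.ndarray) -> None:
    data = img.data if isinstance(img, SectionImage) else np.asarray(img)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        imwrite(path, data.astype(np.uint8))


# ---------------------------------------------------------------------------
# phantom ground truth


def save_phantom(stack: PhantomStack, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for i, sec in enumerate(stack.sections):
        save_section(out / f"section_{i:03d}.png", sec)
        imwrite(out / f"mask_{i:03d}.png",
                (stack.tissue_truth[i] * 255).astype(np.uint8))
    truth = {
        "n_sections": stack.spec.n_sections,
        "mpp": stack.spec.mpp,
        "analytic_tissue_fraction": stack.analytic_tissue_fraction,
        "transforms": [t.to_dict() for t in stack.true_transforms],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    rows = []
    for i, lm in enumerate(stack.landmarks):
        for j, (x, y) in enumerate(lm):
            rows.append({"section": i, "landmark": j, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(out / "landmarks.csv", index=False,
                              float_format="%.6f")


# ---------------------------------------------------------------------------
# alignment outputs


def save_displacement_field(path, fld: DisplacementField) -> None:
    """2-channel (u, v) 32-bit TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.stack([fld.u, fld.v]).astype(np.float32))
    meta = {"grid_spacing_px": fld.grid_spacing_px,
            "converged": bool(fld.converged),
            "final_objective": (fld.objective_trace[-1]
                                if fld.objective_trace else None)}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_displacement_field(path, grid_spacing_px: float | None = None
                            ) -> DisplacementField:
    path = Path(path)
    uv = tifffile.imread(path).astype(float)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return DisplacementField(
        uv[0], uv[1],
        grid_spacing_px=grid_spacing_px or meta.get("grid_spacing_px", 0) or 0,
        converged=meta.get("converged", True))


def save_report(report: RegistrationReport, path_base) -> None:
    base = Path(path_base)
    pd.DataFrame(report.to_records()).to_csv(base.with_suffix(".csv"),
                                             index=False, float_format="%.6f")
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump({"core_error_um": report.core_error_um,
                   "per_pair": report.to_records()}, fh, indent=2, sort_keys=True)


def save_alignment(result, outdir, config: RunConfig | None = None) -> None:
    """Aligned sections, transform chain, fields and error reports."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(result.aligned):
        save_section(out / f"aligned_{i:03d}.png", img)
    extras = [{}] + [{"n_matches": d.n_matches, "n_inliers": d.n_inliers}
                     for d in result.pair_diagnostics]
    save_transform_chain(out / "transforms.json", result.transforms, extras)
    pd.DataFrame([{"pair": d.pair_index, "n_matches": d.n_matches,
                   "n_inliers": d.n_inliers}
                  for d in result.pair_diagnostics]).to_csv(
        out / "match_diagnostics.csv", index=False)
    for i, fld in enumerate(result.fields):
        save_displacement_field(out / f"field_{i:03d}.tiff", fld)
    for name, rep in result.reports.items():
        save_report(rep, out / f"report_{name}")
    if config is not None:
        config.save(out / "config.yaml")


# ---------------------------------------------------------------------------
# encoder weights


def save_encoder_params(path, params: dict) -> None:
    """Weights (or attention maps) in a portable array container (.npz)."""
    np.savez_compressed(path, **params)


def load_encoder_params(path) -> dict:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


# ---------------------------------------------------------------------------
# cores and patches


def save_core_zarr(core: Core25D, path) -> None:
    z = zarr.open_array(str(path), mode="w", shape=core.volume.shape,
                        chunks=(1, 256, 256, core.volume.shape[3]),
                        dtype=core.volume.dtype)
    z[:] = core.volume
    z.attrs["mpp"] = core.mpp
    z.attrs["provenance"] = json.dumps(core.provenance, sort_keys=True)


def load_core_zarr(path, masks: list[TissueMask] | None = None) -> Core25D:
    z = zarr.open_array(str(path), mode="r")
    vol = np.asarray(z)
    if masks is None:
        masks = [TissueMask(np.ones(vol.shape[1:3], dtype=bool), z.attrs.get("mpp", 1.0))
                 for _ in range(vol.shape[0])]
    return Core25D(volume=vol, masks=masks, mpp=float(z.attrs.get("mpp", 1.0)),
                   provenance=json.loads(z.attrs.get("provenance", "{}")))


def save_patches(patches: list[Patch25D], outdir) -> None:
    """One chunked array (n, Z, p, p, 3) plus a CSV manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.DataFrame([{"index": i, "origin_x": p.origin[0],
                              "origin_y": p.origin[1],
                              "tissue_fraction": p.tissue_fraction}
                             for i, p in enumerate(patches)])
    manifest.to_csv(out / "manifest.csv", index=False, float_format="%.6f")
    if patches:
        arr = np.stack([p.data for p in patches])
        z = zarr.open_array(str(out / "patches.zarr"), mode="w",
                            shape=arr.shape, chunks=(1, *arr.shape[1:]),
                            dtype=arr.dtype)
        z[:] = arr
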