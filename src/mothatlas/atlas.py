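"""Standard-brain construction: align hemispheres, average, binarize, surface.

The scheme treats the two hemispheres of each individual as independent
samples under a bilateral-symmetry assumption (12 hemisphere stacks from six
brains in the original study).  Left hemispheres are mirrored about the
sagittal midplane, every stack is rigidly aligned — translation and
rotation only, size and shape unchanged — to a designated reference using
five named landmarks (canonically CCB, RMC, LMC and the two antennal-lobe
centers), the aligned stacks are averaged voxelwise, the average is
binarized into the outline mask, and a triangle surface is extracted.

The brain coordinate origin is anchored at the center of the esophageal
foramen in the middle slice (the slice with the largest brain outline),
because that point is unambiguous in every sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .formats import (ImageStack, LandmarkSet, SurfaceMesh, read_landmarks,
                      read_stack, write_landmarks, write_obj, write_stack)
from .transforms import fit_rigid, mirror, resample_image, swap_lr_names

__all__ = [
    "AtlasBundle",
    "AtlasConfig",
    "set_brain_origin",
    "align_to_reference",
    "average_stacks",
    "binarize_outline",
    "extract_surface",
    "build_standard_brain",
]


class AtlasError(RuntimeError):
    """A stage of atlas construction failed; the message names the stage."""


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def set_brain_origin(stack: ImageStack, esophagus_center: tuple[float, float],
                     middle_slice_index: int) -> ImageStack:
    """Re-anchor the physical origin at a named point in the middle slice.

    ``esophagus_center`` is the (x, y) physical position (um, in the stack's
    current frame) of the esophageal foramen center in slice
    ``middle_slice_index``; that point becomes (0, 0, 0).  Idempotent when
    re-applied with the re-expressed point.
    """
    nz = stack.shape[0]
    if not 0 <= middle_slice_index < nz:
        raise ValueError(f"slice index {middle_slice_index} outside stack of {nz}")
    ext = stack.physical_extent()
    x, y = (float(v) for v in esophagus_center)
    if not (ext[0, 0] <= x <= ext[0, 1] and ext[1, 0] <= y <= ext[1, 1]):
        raise ValueError(f"esophagus center ({x}, {y}) outside the field of view")
    z = stack.origin[0] + middle_slice_index * stack.spacing[0]
    new_origin = (stack.origin[0] - z, stack.origin[1] - y, stack.origin[2] - x)
    return ImageStack(stack.voxels, stack.spacing, new_origin)


def align_to_reference(stack: ImageStack, its_landmarks: LandmarkSet,
                       ref_landmarks: LandmarkSet,
                       reference: ImageStack | None = None) -> ImageStack:
    """Rigidly resample a stack into the reference frame via named landmarks.

    No scaling or shearing: a least-squares rotation + translation fitted
    from >= 3 shared landmark names, applied by inverse-mapped trilinear
    resampling into the reference geometry (default: the stack's own).
    """
    transform = fit_rigid(its_landmarks, ref_landmarks)
    return resample_image(transform, stack, out_geometry=reference)


def average_stacks(stacks: list[ImageStack]) -> ImageStack:
    """Voxelwise arithmetic mean of >= 2 geometry-identical stacks (float64)."""
    if len(stacks) < 2:
        raise ValueError("averaging needs at least two stacks")
    first = stacks[0]
    for k, s in enumerate(stacks[1:], start=1):
        if not first.same_geometry(s):
            raise ValueError(f"stack {k} geometry differs from stack 0")
    acc = np.zeros(first.shape, dtype=np.float64)
    for s in stacks:
        acc += s.voxels
    return ImageStack(acc / len(stacks), first.spacing, first.origin)


def binarize_outline(stack: ImageStack, method: str = "otsu",
                     threshold: float | None = None) -> ImageStack:
    """Extract the brain outline mask by separating light from dark.

    Global Otsu threshold by default (``method="fixed"`` with ``threshold``
    for a manual cut), then keep the largest 26-connected component and fill
    interior holes so the outline is one solid region.
    """
    from skimage.filters import threshold_otsu

    vol = stack.voxels.astype(np.float64)
    if method == "otsu":
        if np.ptp(vol) == 0:
            raise AtlasError("binarize: constant image, no outline separable")
        th = threshold_otsu(vol)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarization needs a threshold value")
        th = float(threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    mask = vol > th
    if not mask.any():
        raise AtlasError("binarize: empty mask (threshold above all intensities)")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    return ImageStack(mask.astype(np.uint8), stack.spacing, stack.origin)


def extract_surface(mask: ImageStack,
                    spacing: tuple[float, float, float] | None = None
                    ) -> SurfaceMesh:
    """Marching-cubes isosurface (level 0.5) of a binary mask, in physical um.

    The mesh is checked for watertightness (warning only — a mask touching
    the volume faces yields an open surface).
    """
    from skimage.measure import marching_cubes

    vol = mask.voxels.astype(np.float64)
    if not np.any(vol > 0):
        raise AtlasError("extract_surface: empty mask")
    sp = spacing if spacing is not None else mask.spacing
    # pad so surfaces close even when the mask touches the volume boundary
    padded = np.pad(vol, 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=sp)
    verts -= np.asarray(sp)  # undo the pad shift
    verts_xyz = verts[:, ::-1] + np.asarray(mask.origin)[::-1]
    mesh = SurfaceMesh(verts_xyz, faces)
    if not mesh.is_watertight():
        warnings.warn("extracted surface is not watertight", stacklevel=2)
    return mesh


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class AtlasConfig:
    """Inputs of a standard-brain build.

    ``stacks`` and ``landmarks`` are parallel lists of TIFF / CSV paths (or
    in-memory objects); ``hemispheres`` labels each input ``"L"`` or ``"R"``
    (left hemispheres are mirrored about the sagittal x-midplane, with
    left/right landmark names swapped).  ``reference`` is the index of the
    base stack defining the output geometry and landmark frame.
    """

    stacks: list
    landmarks: list
    hemispheres: list[str]
    reference: int = 0
    spacing: tuple[float, float, float] | None = None
    binarize_method: str = "otsu"
    threshold: float | None = None

    def validate(self) -> None:
        n = len(self.stacks)
        if n < 1:
            raise AtlasError("config: no input stacks")
        if len(self.landmarks) != n or len(self.hemispheres) != n:
            raise AtlasError("config: stacks, landmarks and hemispheres "
                             "must have equal length")
        for h in self.hemispheres:
            if h not in ("L", "R"):
                raise AtlasError(f"config: hemisphere label {h!r} not L/R")
        if not 0 <= self.reference < n:
            raise AtlasError(f"config: reference index {self.reference} out of range")
        for p in list(self.stacks) + list(self.landmarks):
            if isinstance(p, (str, Path)) and not Path(p).exists():
                raise AtlasError(f"config: input file {p} does not exist")


@dataclass
class AtlasBundle:
    """The constructed standard brain and its provenance."""

    average_stack: ImageStack
    outline_mask: ImageStack
    surface: SurfaceMesh
    reference_landmarks: LandmarkSet
    provenance: list[dict] = field(default_factory=list)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        avg = self.average_stack
        write_stack(ImageStack(np.clip(np.rint(avg.voxels), 0, 255).astype(np.uint8),
                               avg.spacing, avg.origin), out / "average.tif")
        write_stack(self.outline_mask, out / "outline_mask.tif")
        write_obj(self.surface, out / "surface.obj")
        write_landmarks(self.reference_landmarks, out / "landmarks.csv")
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


def _load_stack(obj, spacing) -> ImageStack:
    if isinstance(obj, ImageStack):
        return obj
    return read_stack(obj, spacing=spacing)


def _load_landmarks(obj) -> LandmarkSet:
    if isinstance(obj, LandmarkSet):
        return obj
    return read_landmarks(obj)


def build_standard_brain(config: AtlasConfig) -> AtlasBundle:
    """Run the full scheme: mirror left hemispheres, align, average,
    binarize, surface.

    Validation happens before any computation; any stage error is re-raised
    with the stage name.  A single input degenerates to that input (no
    averaging)."""
    config.validate()
    try:
        stacks = [_load_stack(s, config.spacing) for s in config.stacks]
        landmark_sets = [_load_landmarks(l) for l in config.landmarks]
    except Exception as exc:
        raise AtlasError(f"loading inputs: {exc}") from exc

    provenance: list[dict] = []
    prepared: list[tuple[ImageStack, LandmarkSet]] = []
    for k, (stack, lms, hemi) in enumerate(
            zip(stacks, landmark_sets, config.hemispheres)):
        steps = []
        if hemi == "L":
            ext = stack.physical_extent()
            stack = mirror(stack, axis="x")
            lms = swap_lr_names(mirror(lms, axis="x", extent=tuple(ext[0])))
            steps.append("mirror_x")
        prepared.append((stack, lms))
        provenance.append({"input": k, "hemisphere": hemi, "steps": steps})

    ref_stack, ref_landmarks = prepared[config.reference]
    aligned = []
    for k, (stack, lms) in enumerate(prepared):
        try:
            if k == config.reference:
                aligned.append(stack)
            else:
                aligned.append(align_to_reference(stack, lms, ref_landmarks,
                                                  reference=ref_stack))
                provenance[k]["steps"].append("rigid_align")
        except Exception as exc:
            raise AtlasError(f"aligning input {k}: {exc}") from exc

    try:
        average = (average_stacks(aligned) if len(aligned) > 1
                   else ImageStack(aligned[0].voxels.astype(np.float64),
                                   aligned[0].spacing, aligned[0].origin))
    except Exception as exc:
        raise AtlasError(f"averaging: {exc}") from exc
    try:
        outline = binarize_outline(average, method=config.binarize_method,
                                   threshold=config.threshold)
    except Exception as exc:
        raise AtlasError(f"binarizing: {exc}") from exc
    try:
        surface = extract_surface(outline)
    except Exception as exc:
        raise AtlasError(f"surfacing: {exc}") from exc

    return AtlasBundle(average, outline, surface, ref_landmarks, provenance)
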