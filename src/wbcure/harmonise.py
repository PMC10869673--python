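"""Resampling onto a common axial target grid and NIfTI export.

The target grid defaults to the DWI geometry (the transverse protocol was
designed to match the DWI in-plane resolution) with a field of view covering
the union of every series' extent.  World coordinates are LPS internally;
NIfTI affines are emitted in RAS+ with voxel (0,0,0) at the first-slice
first-voxel centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import ImagingSession, SliceStack, ValidationError

__all__ = [
    "TargetGrid",
    "define_target_grid",
    "resample_to_grid",
    "export_nifti",
    "harmonise_session",
]

AXIAL_ORIENTATION = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


@dataclass(frozen=True)
class TargetGrid:
    """Axial grid: LPS origin (first voxel centre), spacing and dims per axis."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]  # (dx, dy, dz) mm
    shape: tuple[int, int, int]  # (nx, ny, nz)

    def __post_init__(self) -> None:
        if min(self.spacing) <= 0 or min(self.shape) <= 0:
            raise ValidationError("grid spacing and shape must be positive")

    def slice_positions(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.shape[2]) * self.spacing[2]

    def to_dict(self) -> dict:
        return {
            "origin_mm": list(self.origin),
            "spacing_mm": list(self.spacing),
            "shape": list(self.shape),
        }


def _stack_bounds(stack: SliceStack) -> tuple[np.ndarray, np.ndarray]:
    """World-space (LPS) bounding box over all voxel centres."""
    n_sl, n_rows, n_cols = stack.shape
    row_dir, col_dir = stack.orientation
    normal = stack.slice_normal
    corners = []
    for k in (0, n_sl - 1):
        base = stack.origin + (stack.slice_positions[k] - stack.slice_positions[0]) * normal
        for i in (0, n_rows - 1):
            for j in (0, n_cols - 1):
                corners.append(
                    base
                    + j * stack.pixel_spacing[1] * row_dir
                    + i * stack.pixel_spacing[0] * col_dir
                )
    corners = np.array(corners)
    return corners.min(axis=0), corners.max(axis=0)


def define_target_grid(
    session: ImagingSession,
    explicit: TargetGrid | None = None,
    max_fov_mm: tuple[float, float, float] | None = None,
) -> TargetGrid:
    """DWI-donor grid covering the union of all series extents.

    An ``explicit`` grid wins verbatim.  Otherwise the in-plane and slice
    spacing come from the first DWI series present (b50, then b900, then adc).
    """
    if explicit is not None:
        return explicit
    donor = next(
        (session.series[k] for k in ("b50", "b900", "adc") if k in session.series), None
    )
    if donor is None:
        raise ValidationError("no DWI donor series and no explicit grid supplied")
    spacing = (
        float(donor.pixel_spacing[1]),
        float(donor.pixel_spacing[0]),
        float(donor.nominal_slice_spacing),
    )
    lows, highs = [], []
    for stack in session.series.values():
        lo, hi = _stack_bounds(stack)
        lows.append(lo)
        highs.append(hi)
    lo = np.min(lows, axis=0)
    hi = np.max(highs, axis=0)
    if max_fov_mm is not None:
        centre = (lo + hi) / 2
        half = np.asarray(max_fov_mm) / 2
        lo = np.maximum(lo, centre - half)
        hi = np.minimum(hi, centre + half)
    shape = tuple(int(np.floor((hi[a] - lo[a]) / spacing[a])) + 1 for a in range(3))
    return TargetGrid(origin=tuple(float(v) for v in lo), spacing=spacing, shape=shape)


def resample_to_grid(
    stack: SliceStack, grid: TargetGrid, interp: str = "linear"
) -> SliceStack:
    """Resample one series onto the target grid (trilinear or nearest).

    Voxels outside the source extent are zero and marked True in the returned
    stack's ``out_of_field_mask`` attribute.
    """
    if interp not in ("linear", "nearest"):
        raise ValidationError("interp must be 'linear' or 'nearest'")
    positions = np.asarray(stack.slice_positions, float)
    if len(positions) > 1:
        steps = np.diff(positions)
        if np.any(steps <= 0) or np.ptp(steps) > 0.01:
            raise ValidationError("source stack must be on a uniform slice grid")
        dz_src = float(steps.mean())
    else:
        dz_src = stack.nominal_slice_spacing

    nx, ny, nz = grid.shape
    dx, dy, dz = grid.spacing
    ox, oy, oz = grid.origin
    # world coordinates of target voxel centres, array layout (slice, row, col)
    zs = oz + np.arange(nz) * dz
    ys = oy + np.arange(ny) * dy
    xs = ox + np.arange(nx) * dx
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    world = np.stack([X, Y, Z], axis=-1)

    rel = world - stack.origin
    row_dir, col_dir = stack.orientation
    normal = stack.slice_normal
    j = rel @ row_dir / stack.pixel_spacing[1]  # column index
    i = rel @ col_dir / stack.pixel_spacing[0]  # row index
    k = rel @ normal / dz_src  # slice index

    n_sl, n_rows, n_cols = stack.shape
    eps = 1e-6
    oof = (
        (k < -eps) | (k > n_sl - 1 + eps)
        | (i < -eps) | (i > n_rows - 1 + eps)
        | (j < -eps) | (j > n_cols - 1 + eps)
    )
    if oof.all():
        raise ValidationError("target grid does not intersect the source extent")
    order = 1 if interp == "linear" else 0
    values = ndimage.map_coordinates(
        stack.voxels.astype(float), [k, i, j], order=order, mode="constant", cval=0.0
    )
    values[oof] = 0.0

    out = SliceStack(
        voxels=values,
        slice_positions=zs.astype(float),
        orientation=AXIAL_ORIENTATION.copy(),
        origin=np.array([ox, oy, oz], float),
        pixel_spacing=(dy, dx),
        nominal_slice_spacing=dz,
        contrast_label=stack.contrast_label,
    )
    out.out_of_field_mask = oof
    return out


def _lps_affine(stack: SliceStack) -> np.ndarray:
    """4x4 mapping (col, row, slice) voxel indices to LPS world mm."""
    row_dir, col_dir = stack.orientation
    normal = stack.slice_normal
    steps = np.diff(stack.slice_positions)
    dz = float(steps.mean()) if steps.size else stack.nominal_slice_spacing
    aff = np.eye(4)
    aff[:3, 0] = row_dir * stack.pixel_spacing[1]
    aff[:3, 1] = col_dir * stack.pixel_spacing[0]
    aff[:3, 2] = normal * dz
    aff[:3, 3] = stack.origin
    return aff


def export_nifti(stack: SliceStack, path, missing_mask: np.ndarray | None = None) -> str:
    """Write a NIfTI-1 file (RAS+ affine); optional paired ``_mask`` sidecar."""
    positions = np.asarray(stack.slice_positions, float)
    if len(positions) > 1:
        steps = np.diff(positions)
        if np.any(steps <= 0) or np.ptp(steps) > 0.01:
            raise ValidationError("non-uniform slice spacing: regrid before export")
    affine = np.diag([-1.0, -1.0, 1.0, 1.0]) @ _lps_affine(stack)
    data = np.ascontiguousarray(stack.voxels.transpose(2, 1, 0))
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_qform(affine, code=1)
    img.header.set_sform(affine, code=1)
    nib.save(img, str(path))
    if missing_mask is not None:
        mpath = _mask_path(path)
        mimg = nib.Nifti1Image(
            np.ascontiguousarray(missing_mask.transpose(2, 1, 0)).astype(np.uint8), affine
        )
        nib.save(mimg, str(mpath))
    return str(path)


def _mask_path(path) -> str:
    s = str(path)
    for suffix in (".nii.gz", ".nii"):
        if s.endswith(suffix):
            return s[: -len(suffix)] + "_mask" + suffix
    return s + "_mask.nii.gz"


def harmonise_session(
    session: ImagingSession, grid: TargetGrid | None = None
) -> tuple[ImagingSession, TargetGrid]:
    """Resample every series of a session onto one grid (shared affine)."""
    grid = define_target_grid(session) if grid is None else grid
    out = ImagingSession(
        subject_id=session.subject_id,
        session_id=session.session_id,
        series={},
        cohort=session.cohort,
        protocol=session.protocol,
    )
    for label, stack in session.series.items():
        out.series[label] = resample_to_grid(stack, grid, interp="linear")
    return out, grid
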