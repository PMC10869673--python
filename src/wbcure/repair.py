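"""Repair of composition defects: regridding, offset correction, reordering.

Overlaps are resolved by averaging duplicate-position slices and linearly
interpolating onto a uniform grid (no information loss); underlap intervals
are interpolated too but flagged in a ``missing_mask`` sidecar so downstream
consumers can exclude fabricated voxels.  Per-station in-plane offsets are
estimated at integer-pixel resolution by phase correlation of
gradient-magnitude images and undone by translation with zero padding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .audit import GapClassification, classify_gaps
from .core import SliceStack, StationBlock, ValidationError, validate_blocks

__all__ = [
    "RepairedStack",
    "OffsetBoundError",
    "regrid_overlaps",
    "estimate_inplane_offset",
    "apply_offset_correction",
    "reorder_stations",
]


class OffsetBoundError(ValidationError):
    """Estimated shift lies outside the configured search bound."""


@dataclass
class RepairedStack:
    stack: SliceStack
    missing_mask: np.ndarray  # bool, same shape as stack.voxels
    repair_log: list[dict] = field(default_factory=list)


def _is_uniform(positions: np.ndarray, spacing: float, tol: float = 0.01) -> bool:
    gaps = np.diff(positions)
    return bool(gaps.size == 0 or (np.all(gaps > 0) and np.all(np.abs(gaps - spacing) <= tol)))


def regrid_overlaps(
    stack: SliceStack,
    gaps: GapClassification | None = None,
    rel_tol: float = 0.05,
    fill_underlaps: bool = True,
    dup_tol_mm: float = 0.01,
) -> RepairedStack:
    """Resample a composed stack onto a uniform slice grid.

    Duplicate-position slices are averaged first; remaining voxels are
    linearly interpolated along the slice normal.  Output grid spans
    [first, last] source position at the nominal spacing.  Underlap intervals
    are filled by interpolation (or NaN if ``fill_underlaps=False``) and
    flagged True in ``missing_mask``.
    """
    if gaps is None:
        gaps = classify_gaps(stack.slice_positions, stack.nominal_slice_spacing, rel_tol)
    s = gaps.nominal_spacing
    positions = np.asarray(stack.slice_positions, float)

    if _is_uniform(positions, s):
        out = stack.copy()
        return RepairedStack(out, np.zeros(out.shape, dtype=bool), [])

    order = np.argsort(positions, kind="stable")
    pos_sorted = positions[order]
    vox_sorted = stack.voxels[order]

    # average duplicates (full overlaps)
    src_pos: list[float] = []
    src_vox: list[np.ndarray] = []
    i = 0
    n_averaged = 0
    while i < len(pos_sorted):
        j = i + 1
        while j < len(pos_sorted) and pos_sorted[j] - pos_sorted[i] <= dup_tol_mm:
            j += 1
        if j - i > 1:
            n_averaged += j - i
            src_vox.append(vox_sorted[i:j].mean(axis=0))
        else:
            src_vox.append(vox_sorted[i])
        src_pos.append(float(pos_sorted[i:j].mean()))
        i = j
    if len(src_pos) < 2:
        raise ValidationError("degenerate stack: fewer than 2 distinct slice positions")
    src_pos_arr = np.asarray(src_pos)
    src_arr = np.stack(src_vox)

    first, last = src_pos_arr[0], src_pos_arr[-1]
    n_out = int(round((last - first) / s)) + 1
    out_pos = first + np.arange(n_out) * s

    # linear interpolation along the slice axis
    idx = np.clip(np.searchsorted(src_pos_arr, out_pos) - 1, 0, len(src_pos_arr) - 2)
    p0, p1 = src_pos_arr[idx], src_pos_arr[idx + 1]
    w = np.clip((out_pos - p0) / np.where(p1 - p0 == 0, 1.0, p1 - p0), 0.0, 1.0)
    out_vox = (1 - w)[:, None, None] * src_arr[idx] + w[:, None, None] * src_arr[idx + 1]

    # voxels too far from any acquired slice are fabrications
    dist = np.min(np.abs(out_pos[:, None] - src_pos_arr[None, :]), axis=1)
    missing_slices = dist > 0.5 * s * (1 + rel_tol)
    missing_mask = np.zeros(out_vox.shape, dtype=bool)
    missing_mask[missing_slices] = True
    if not fill_underlaps:
        out_vox[missing_slices] = np.nan

    log = []
    if n_averaged:
        log.append({"action": "average_duplicates", "n_slices": int(n_averaged)})
    log.append(
        {
            "action": "regrid",
            "n_in": int(stack.n_slices),
            "n_out": int(n_out),
            "spacing_mm": float(s),
        }
    )
    if missing_slices.any():
        log.append(
            {
                "action": "mask_underlap",
                "slice_positions_mm": [float(p) for p in out_pos[missing_slices]],
                "filled": bool(fill_underlaps),
            }
        )

    out = SliceStack(
        voxels=out_vox,
        slice_positions=out_pos,
        orientation=stack.orientation.copy(),
        origin=stack.origin + (out_pos[0] - positions[0]) * stack.slice_normal,
        pixel_spacing=tuple(stack.pixel_spacing),
        nominal_slice_spacing=float(s),
        contrast_label=stack.contrast_label,
        station_blocks=None,
    )
    return RepairedStack(out, missing_mask, log)


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gy = ndimage.sobel(img, axis=0, mode="constant")
    gx = ndimage.sobel(img, axis=1, mode="constant")
    return np.hypot(gx, gy)


def estimate_inplane_offset(
    moving: SliceStack,
    reference: SliceStack,
    block: StationBlock,
    bound: int = 16,
    on_exceed: str = "error",
) -> tuple[int, int]:
    """Integer-pixel (dx, dy) translation of ``moving`` relative to ``reference``.

    Phase correlation of gradient-magnitude images averaged over the block's
    slices.  Returns the shift that was applied to the moving image, so
    correcting means translating by the negative.  ``on_exceed`` controls what
    happens when the correlation peak lies outside ``±bound``: ``"error"``
    raises :class:`OffsetBoundError`, ``"bounded"`` returns the best peak
    within the search window.
    """
    idx = block.indices()
    mov = np.mean([_gradient_magnitude(sl) for sl in moving.voxels[idx]], axis=0)
    ref = np.mean([_gradient_magnitude(sl) for sl in reference.voxels[idx]], axis=0)
    if mov.shape != ref.shape:
        raise ValidationError("moving and reference blocks differ in shape")
    if float(mov.std()) == 0.0 or float(ref.std()) == 0.0:
        raise ValidationError("uninformative block: zero variance")

    fr = np.fft.fft2(ref - ref.mean())
    fm = np.fft.fft2(mov - mov.mean())
    cross = fr * np.conj(fm)
    cross /= np.abs(cross) + 1e-12  # phase correlation
    surface = np.real(np.fft.ifft2(cross))

    h, wdt = surface.shape

    def peak_to_shift(py: int, px: int) -> tuple[int, int]:
        dy = -(py if py <= h // 2 else py - h)
        dx = -(px if px <= wdt // 2 else px - wdt)
        return dx, dy

    py, px = np.unravel_index(np.argmax(surface), surface.shape)
    dx, dy = peak_to_shift(int(py), int(px))
    if abs(dx) > bound or abs(dy) > bound:
        if on_exceed == "error":
            raise OffsetBoundError(
                f"estimated shift ({dx}, {dy}) exceeds search bound ±{bound}"
            )
        # restrict search to the ±bound window around zero shift
        masked = np.full_like(surface, -np.inf)
        for yy in range(-bound, bound + 1):
            for xx in range(-bound, bound + 1):
                masked[(-yy) % h, (-xx) % wdt] = surface[(-yy) % h, (-xx) % wdt]
        py, px = np.unravel_index(np.argmax(masked), masked.shape)
        dx, dy = peak_to_shift(int(py), int(px))
    return int(dx), int(dy)


def _translate2d(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    out = np.zeros_like(img)
    h, w = img.shape[-2], img.shape[-1]
    ys = slice(max(dy, 0), min(h + dy, h))
    yd = slice(max(-dy, 0), min(h - dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    xd = slice(max(-dx, 0), min(w - dx, w))
    out[..., ys, xs] = img[..., yd, xd]
    return out


def apply_offset_correction(
    stack: SliceStack,
    shifts: Mapping[int, tuple[int, int]],
    bound: int = 16,
) -> SliceStack:
    """Translate each station block by the negative of its estimated shift."""
    for dx, dy in shifts.values():
        if abs(dx) > bound or abs(dy) > bound:
            raise OffsetBoundError(f"shift ({dx}, {dy}) exceeds bound ±{bound}")
    out = stack.copy()
    if out.station_blocks is None:
        raise ValidationError("stack has no station blocks")
    for block in out.station_blocks:
        shift = shifts.get(block.station_index)
        if not shift or shift == (0, 0):
            continue
        dx, dy = shift
        idx = block.indices()
        out.voxels[idx] = _translate2d(out.voxels[idx], -dx, -dy)
        block.source_offset_mm = (0.0, 0.0)
    return out


def reorder_stations(
    stack: SliceStack,
    blocks: Sequence[StationBlock] | None,
    permutation: Sequence[int],
) -> SliceStack:
    """Re-sort station blocks per ``permutation`` and reassign positions
    monotonically.

    ``permutation[slot] = i`` places the i-th block (in composed order) at
    ``slot`` — i.e. the permutation returned by
    :func:`wbcure.audit.check_station_order`.
    """
    if blocks is None:
        blocks = stack.station_blocks
    if blocks is None:
        raise ValidationError("stack has no station blocks")
    perm = [int(p) for p in permutation]
    if sorted(perm) != list(range(len(blocks))):
        raise ValidationError(f"permutation {permutation!r} is not a bijection")
    validate_blocks(blocks, stack.n_slices)
    blocks = sorted(blocks, key=lambda b: b.slice_range[0])
    vox = [stack.voxels[blocks[i].indices()] for i in perm]
    pos = [stack.slice_positions[blocks[i].indices()] for i in perm]
    new_vox = np.concatenate(vox, axis=0)
    new_pos = np.concatenate(pos)
    new_blocks, start = [], 0
    for slot, i in enumerate(perm):
        b = blocks[i]
        new_blocks.append(
            StationBlock(b.station_index, (start, start + b.n_slices), b.source_offset_mm)
        )
        start += b.n_slices
    out = stack.copy()
    out.voxels = new_vox
    out.slice_positions = new_pos
    out.origin = stack.origin + (new_pos[0] - stack.slice_positions[0]) * stack.slice_normal
    out.station_blocks = new_blocks
    return out
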