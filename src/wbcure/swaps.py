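"""Fat-water mislabelling detection and correction.

Global and station scopes use a subcutaneous-rim statistic: the rim of the
body (body mask minus its erosion) is fat-bright on correctly labelled
anatomy, so ``(mean(fat) - mean(water)) / mean(fat + water)`` over the rim is
positive when labels are right and exactly negated when they are exchanged.

Local swaps are flagged, never auto-corrected: they are detected as connected
components where Dixon fat-dominance disagrees with b50 brightness (DWI is
reconstructed independently of the Dixon fat-water separation, so it is
immune to the swap).  Without a DWI series local detection is skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import ImagingSession, SliceStack, StationBlock, ValidationError

__all__ = [
    "SwapFinding",
    "body_mask",
    "rim_mask",
    "rim_statistic",
    "detect_swaps",
    "apply_swap_fix",
]

DEFAULT_THETA = 0.2
DEFAULT_MIN_VOLUME = 30  # voxels


@dataclass
class SwapFinding:
    scope: str  # global | station | local
    station_index: int | None = None
    region_mask: np.ndarray | None = None  # bool array on the fat grid
    evidence: dict = field(default_factory=dict)
    action: str = "relabel"  # local findings are always flag_only

    def __post_init__(self) -> None:
        if self.scope == "local" and self.action != "flag_only":
            raise ValidationError("local swap findings must be flag_only")


def body_mask(fat: SliceStack, water: SliceStack, erosion: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """(body, eroded) boolean masks from Otsu on fat+water, largest component."""
    combined = fat.voxels + water.voxels
    if combined.max() <= 0:
        raise ValidationError("uninformative volume: no signal")
    thresh = threshold_otsu(combined)
    mask = combined > thresh
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValidationError("uninformative volume: empty body mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    # in-plane erosion: the subcutaneous rim is an annulus on each slice, so
    # axial end faces must not leak core voxels into the rim
    structure = np.zeros((1, 3, 3), dtype=bool)
    structure[0] = True
    eroded = ndimage.binary_erosion(mask, structure=structure, iterations=erosion)
    return mask, eroded


def rim_mask(fat: SliceStack, water: SliceStack, erosion: int = 2) -> np.ndarray:
    mask, eroded = body_mask(fat, water, erosion)
    return mask & ~eroded


def rim_statistic(
    fat: SliceStack,
    water: SliceStack,
    slice_range: tuple[int, int] | None = None,
    valid_mask: np.ndarray | None = None,
) -> float:
    """Normalised fat-minus-water contrast over the subcutaneous rim.

    Positive on correctly labelled anatomy; exactly negated when fat and water
    are exchanged (the denominator is label-symmetric).
    """
    rim = rim_mask(fat, water)
    if slice_range is not None:
        sel = np.zeros_like(rim)
        sel[slice_range[0] : slice_range[1]] = True
        rim = rim & sel
    if valid_mask is not None:
        rim = rim & valid_mask
    if rim.any():
        # drop voxels lost to zero padding (offset repair); a label swap
        # preserves fat+water, so this cannot hide a real swap
        combined = fat.voxels + water.voxels
        rim = rim & (combined > 0.25 * np.median(combined[rim]))
    if not rim.any():
        raise ValidationError("uninformative slice range: empty rim")
    mf = float(fat.voxels[rim].mean())
    mw = float(water.voxels[rim].mean())
    denom = float((fat.voxels[rim] + water.voxels[rim]).mean())
    if denom == 0:
        return 0.0
    return (mf - mw) / denom


def _local_findings(
    session: ImagingSession,
    blocks: Sequence[StationBlock],
    consistent_stations: list[int],
    theta: float,
    min_volume: int,
    valid_mask: np.ndarray | None = None,
) -> list[SwapFinding]:
    fat, water = session.series["fat"], session.series["water"]
    b50 = session.series.get("b50")
    if b50 is None or b50.voxels.shape != fat.voxels.shape:
        return []
    body, _ = body_mask(fat, water)
    interior = ndimage.binary_erosion(body, iterations=2)
    if not interior.any():
        return []
    # DWI-derived water-dominance reference, immune to the Dixon swap
    water_like = b50.voxels > threshold_otsu(b50.voxels[body])
    fat_dominant = fat.voxels > water.voxels
    mismatch = interior & (fat_dominant == water_like)
    if valid_mask is not None:
        mismatch &= valid_mask
    allowed = np.zeros_like(mismatch)
    for b in blocks:
        if b.station_index in consistent_stations:
            allowed[b.indices()] = True
    mismatch &= allowed
    labels, n = ndimage.label(mismatch)
    findings = []
    for comp in range(1, n + 1):
        comp_mask = labels == comp
        size = int(comp_mask.sum())
        if size < min_volume:
            continue
        stations = [
            b.station_index for b in blocks if comp_mask[b.indices()].any()
        ]
        findings.append(
            SwapFinding(
                scope="local",
                station_index=stations[0] if len(stations) == 1 else None,
                region_mask=comp_mask,
                evidence={"component_voxels": size, "stations": stations},
                action="flag_only",
            )
        )
    return findings


def detect_swaps(
    session: ImagingSession,
    blocks: Sequence[StationBlock] | None = None,
    theta: float = DEFAULT_THETA,
    min_volume: int = DEFAULT_MIN_VOLUME,
    valid_mask: np.ndarray | None = None,
) -> list[SwapFinding]:
    """Detect global, station and local fat-water swaps in one session.

    ``valid_mask`` excludes voxels known to be unreliable (e.g. zero-filled
    borders left by offset correction) from every statistic.
    """
    fat = session.series.get("fat")
    water = session.series.get("water")
    if fat is None or water is None:
        raise ValidationError("swap detection requires fat and water series")
    if blocks is None:
        blocks = fat.station_blocks or [StationBlock(0, (0, fat.n_slices))]

    stat_global = rim_statistic(fat, water, valid_mask=valid_mask)
    if stat_global < -theta:
        return [
            SwapFinding(
                scope="global",
                evidence={"rim_statistic": stat_global, "theta": theta},
                action="relabel",
            )
        ]

    findings: list[SwapFinding] = []
    consistent: list[int] = []
    for b in sorted(blocks, key=lambda b: b.station_index):
        try:
            stat = rim_statistic(fat, water, b.slice_range, valid_mask=valid_mask)
        except ValidationError:
            consistent.append(b.station_index)
            continue
        if stat < -theta:
            findings.append(
                SwapFinding(
                    scope="station",
                    station_index=b.station_index,
                    evidence={"rim_statistic": stat, "theta": theta},
                    action="relabel",
                )
            )
        else:
            consistent.append(b.station_index)

    findings.extend(
        _local_findings(session, blocks, consistent, theta, min_volume, valid_mask)
    )
    return findings


def apply_swap_fix(
    session: ImagingSession, findings: Sequence[SwapFinding]
) -> ImagingSession:
    """Exchange labels for global/station findings; leave local ones untouched."""
    scopes = {f.scope for f in findings}
    if "global" in scopes and "station" in scopes:
        raise ValidationError(
            "conflicting global and station swap findings: manual resolution required"
        )
    out = session.copy()
    fat, water = out.series.get("fat"), out.series.get("water")
    for f in findings:
        if f.scope == "global":
            fat.voxels, water.voxels = water.voxels, fat.voxels
        elif f.scope == "station":
            fb = next(
                b for b in (fat.station_blocks or []) if b.station_index == f.station_index
            )
            wb = next(
                b for b in (water.station_blocks or []) if b.station_index == f.station_index
            )
            fi, wi = fb.indices(), wb.indices()
            fat.voxels[fi], water.voxels[wi] = (
                water.voxels[wi].copy(),
                fat.voxels[fi].copy(),
            )
        # local: flag only — persisted by the caller's RunRecord
    return out
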