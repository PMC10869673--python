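"""End-to-end curation of one session: audit -> reorder -> swap fix ->
offset correction -> regrid, with every action logged to a RunRecord."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import audit as audit_mod
from . import repair as repair_mod
from . import swaps as swaps_mod
from .core import ImagingSession, StationBlock, ValidationError
from .qa import RunRecord, check_inventory

__all__ = ["CurationConfig", "CurationResult", "curate_session", "finding_station_boundary"]


@dataclass
class CurationConfig:
    rel_tol: float = 0.05
    swap_theta: float = 0.2
    swap_min_volume: int = 30
    offset_bound_px: int = 16
    offset_reference: str = "water"  # reference series for offset estimation
    offset_moving: str = "fat"
    fill_underlaps: bool = True

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CurationResult:
    session: ImagingSession  # repaired series on uniform grids
    missing_masks: dict[str, np.ndarray]
    record: RunRecord
    swap_findings: list = field(default_factory=list)
    severities: dict[str, str] = field(default_factory=dict)


def finding_station_boundary(
    blocks: Sequence[StationBlock], boundary_index: int
) -> int | None:
    """Map a slice-boundary index to the station boundary it sits on.

    Returns the composed-order index of the station left of the boundary, or
    None if the boundary is interior to a single station.
    """
    blocks = sorted(blocks, key=lambda b: b.slice_range[0])
    for pos, b in enumerate(blocks):
        lo, hi = b.slice_range
        if lo <= boundary_index < hi:
            return pos if boundary_index == hi - 1 and pos < len(blocks) - 1 else None
    return None


def curate_session(
    session: ImagingSession, config: CurationConfig | None = None
) -> CurationResult:
    config = config or CurationConfig()
    record = RunRecord(session_id=session.session_id, config=config.to_dict())

    inv = check_inventory(session)
    record.add_step(
        "check_inventory",
        {"expected": list(inv.expected)},
        {"verdict": inv.verdict, "missing": list(inv.missing), "extraneous": list(inv.extraneous)},
    )
    record.add_step("identify_protocol", {"protocol": session.protocol})

    work = session.copy()

    # 1. station ordering
    for label, stack in work.series.items():
        if not stack.station_blocks:
            continue
        verdict, perm = audit_mod.check_station_order(stack)
        if verdict == "misordered":
            work.series[label] = repair_mod.reorder_stations(stack, None, perm)
        record.add_step(
            "check_station_order",
            {"series": label},
            {"verdict": verdict, "permutation": list(perm)},
        )

    # 2. slice-contiguity audit
    severities: dict[str, str] = {}
    gap_results = {}
    for label, stack in work.series.items():
        gaps, severity, lines = audit_mod.audit_series(stack, rel_tol=config.rel_tol)
        severities[label] = severity
        gap_results[label] = gaps
        record.add_step(
            "audit_series",
            {"series": label, "rel_tol": config.rel_tol},
            {
                "severity": severity,
                "counts": gaps.counts,
                "map": gaps.ascii_map(),
                "summary": lines,
            },
        )

    # 3. per-station in-plane offsets (before swap detection: a misaligned rim
    # depresses the rim statistic and can mimic a station swap).  Offset
    # estimation itself is label-agnostic — it correlates gradient magnitudes.
    mov_label, ref_label = config.offset_moving, config.offset_reference
    mov = work.series.get(mov_label)
    ref = work.series.get(ref_label)
    if (
        mov is not None
        and ref is not None
        and mov.station_blocks
        and mov.voxels.shape == ref.voxels.shape
    ):
        shifts = {}
        for block in mov.station_blocks:
            try:
                dx, dy = repair_mod.estimate_inplane_offset(
                    mov, ref, block, bound=config.offset_bound_px
                )
            except ValidationError:
                continue
            if (dx, dy) != (0, 0):
                shifts[block.station_index] = (dx, dy)
        record.add_step(
            "estimate_inplane_offsets",
            {"moving": mov_label, "reference": ref_label, "bound": config.offset_bound_px},
            {str(k): list(v) for k, v in shifts.items()},
        )
        if shifts:
            work.series[mov_label] = repair_mod.apply_offset_correction(
                mov, shifts, bound=config.offset_bound_px
            )
            record.add_step(
                "apply_offset_correction",
                {"series": mov_label},
                {str(k): list(v) for k, v in shifts.items()},
            )
            # borders zero-filled by translation are unreliable for detectors
            valid_mask = np.ones(mov.voxels.shape, dtype=bool)
            h, wdt = mov.voxels.shape[1:]
            for block in mov.station_blocks:
                shift = shifts.get(block.station_index)
                if not shift:
                    continue
                # pad by the rim erosion width: the zero band also distorts
                # the body boundary for a few voxels beyond it
                dx, dy = abs(shift[0]) + 3, abs(shift[1]) + 3
                idx = block.indices()
                if dy:
                    valid_mask[idx, :dy, :] = False
                    valid_mask[idx, h - dy :, :] = False
                if dx:
                    valid_mask[idx, :, :dx] = False
                    valid_mask[idx, :, wdt - dx :] = False
        else:
            valid_mask = None
    else:
        valid_mask = None

    # 4. fat-water swaps
    swap_findings = []
    if "fat" in work.series and "water" in work.series:
        swap_findings = swaps_mod.detect_swaps(
            work,
            theta=config.swap_theta,
            min_volume=config.swap_min_volume,
            valid_mask=valid_mask,
        )
        record.add_step(
            "detect_swaps",
            {"theta": config.swap_theta, "min_volume": config.swap_min_volume},
            [
                {
                    "scope": f.scope,
                    "station_index": f.station_index,
                    "action": f.action,
                    "evidence": {
                        k: v for k, v in f.evidence.items() if not isinstance(v, np.ndarray)
                    },
                }
                for f in swap_findings
            ],
        )
        fixable = [f for f in swap_findings if f.action == "relabel"]
        if fixable:
            work = swaps_mod.apply_swap_fix(work, fixable)
            record.add_step("apply_swap_fix", {}, {"n_fixed": len(fixable)})

    # 5. regrid every series onto a uniform slice grid
    missing_masks: dict[str, np.ndarray] = {}
    for label in list(work.series):
        stack = work.series[label]
        repaired = repair_mod.regrid_overlaps(
            stack,
            rel_tol=config.rel_tol,
            fill_underlaps=config.fill_underlaps,
        )
        work.series[label] = repaired.stack
        missing_masks[label] = repaired.missing_mask
        if repaired.repair_log:
            record.add_step("regrid", {"series": label}, repaired.repair_log)

    return CurationResult(
        session=work,
        missing_masks=missing_masks,
        record=record,
        swap_findings=swap_findings,
        severities=severities,
    )
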