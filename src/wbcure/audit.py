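"""Slice-contiguity audit of composed series.

Each successive gap between slice positions is classified against the nominal
spacing ``s``: contiguous if ``|g - s| <= rel_tol*s``, underlap if
``g > s*(1 + rel_tol)`` and overlap otherwise (this includes duplicate
positions, ``g == 0``, and the negative steps a vendor composition produces
when a station re-images already-covered anatomy).  Severity of a series is
red if any boundary underlaps (missing data), amber if overlaps only
(repairable by interpolation), ok otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import SliceStack, StationBlock, ValidationError, validate_blocks

__all__ = [
    "Boundary",
    "GapClassification",
    "GridMismatch",
    "classify_gaps",
    "infer_nominal_spacing",
    "audit_series",
    "compare_grids",
    "check_station_order",
    "render_gapmap_png",
]

CONTIGUOUS, UNDERLAP, OVERLAP = "contiguous", "underlap", "overlap"


@dataclass(frozen=True)
class Boundary:
    index: int  # between slice index and index+1
    klass: str
    gap_mm: float
    n_slices_equivalent: int


@dataclass
class GapClassification:
    boundaries: list[Boundary]
    nominal_spacing: float
    rel_tol: float

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(b.klass for b in self.boundaries)
        return {k: c.get(k, 0) for k in (CONTIGUOUS, UNDERLAP, OVERLAP)}

    @property
    def findings(self) -> list[Boundary]:
        return [b for b in self.boundaries if b.klass != CONTIGUOUS]

    def ascii_map(self) -> str:
        """One character per boundary: c / u / o (diff-able in tests)."""
        return "".join(b.klass[0] for b in self.boundaries)


def infer_nominal_spacing(positions: Sequence[float]) -> float:
    """Mode of the gaps rounded to 0.1 mm — robust to a minority of bad gaps."""
    gaps = np.diff(np.asarray(positions, float))
    if gaps.size == 0:
        raise ValidationError("need at least 2 slices to infer spacing")
    rounded = np.round(np.abs(gaps), 1)
    rounded = rounded[rounded > 0]
    if rounded.size == 0:
        raise ValidationError("all gaps are zero; cannot infer nominal spacing")
    values, counts = np.unique(rounded, return_counts=True)
    return float(values[np.argmax(counts)])


def classify_gaps(
    slice_positions: Sequence[float],
    nominal_spacing: float | None = None,
    rel_tol: float = 0.05,
) -> GapClassification:
    """Classify every slice-to-slice gap of a composed stack."""
    positions = np.asarray(slice_positions, float)
    if positions.size < 2:
        raise ValidationError("need at least 2 slices to classify gaps")
    if not 0 < rel_tol < 0.5:
        raise ValidationError("rel_tol must be in (0, 0.5)")
    s = nominal_spacing if nominal_spacing is not None else infer_nominal_spacing(positions)
    if s <= 0:
        raise ValidationError("nominal_spacing must be positive")
    boundaries = []
    for i, g in enumerate(np.diff(positions)):
        if abs(g - s) <= rel_tol * s:
            klass = CONTIGUOUS
        elif g > s * (1 + rel_tol):
            klass = UNDERLAP
        else:
            klass = OVERLAP
        boundaries.append(
            Boundary(
                index=i,
                klass=klass,
                gap_mm=float(g),
                n_slices_equivalent=int(round(abs(g - s) / s)),
            )
        )
    return GapClassification(boundaries=boundaries, nominal_spacing=float(s), rel_tol=rel_tol)


def severity_of(gaps: GapClassification) -> str:
    counts = gaps.counts
    if counts[UNDERLAP]:
        return "red"
    if counts[OVERLAP]:
        return "amber"
    return "ok"


def audit_series(
    stack: SliceStack,
    nominal_spacing: float | None = None,
    rel_tol: float = 0.05,
) -> tuple[GapClassification, str, list[str]]:
    """Audit one series: gap classes, severity, human-readable summary lines."""
    s = nominal_spacing if nominal_spacing is not None else stack.nominal_slice_spacing
    gaps = classify_gaps(stack.slice_positions, s, rel_tol)
    severity = severity_of(gaps)
    lines = [
        f"series {stack.contrast_label}: {stack.n_slices} slices, "
        f"nominal spacing {gaps.nominal_spacing:.2f} mm, severity {severity.upper()}"
    ]
    for b in gaps.findings:
        lines.append(
            f"  boundary {b.index} ({stack.slice_positions[b.index]:.2f} -> "
            f"{stack.slice_positions[b.index + 1]:.2f} mm): {b.klass}, "
            f"gap {b.gap_mm:.2f} mm (~{b.n_slices_equivalent} slice(s))"
        )
    return gaps, severity, lines


@dataclass
class GridMismatch:
    origin_delta_mm: np.ndarray
    pixel_spacing_delta_mm: tuple[float, float]
    slice_spacing_delta_mm: float
    slices_only_in_a: list[float] = field(default_factory=list)
    slices_only_in_b: list[float] = field(default_factory=list)

    def is_empty(self, tol: float = 0.01) -> bool:
        return (
            bool(np.all(np.abs(self.origin_delta_mm) <= tol))
            and all(abs(d) <= tol for d in self.pixel_spacing_delta_mm)
            and abs(self.slice_spacing_delta_mm) <= tol
            and not self.slices_only_in_a
            and not self.slices_only_in_b
        )


def compare_grids(a: SliceStack, b: SliceStack, tol: float = 0.01) -> GridMismatch:
    """Report origin / spacing / slice-position disagreement of two stacks."""
    origin_delta = a.origin - b.origin
    ps_delta = (
        a.pixel_spacing[0] - b.pixel_spacing[0],
        a.pixel_spacing[1] - b.pixel_spacing[1],
    )
    ss_delta = a.nominal_slice_spacing - b.nominal_slice_spacing

    def set_diff(xs, ys):
        # multiset difference: duplicate positions (overlaps) consume matches
        out = []
        remaining = sorted(float(y) for y in ys)
        for x in sorted(float(v) for v in xs):
            hit = next((i for i, y in enumerate(remaining) if abs(y - x) <= tol), None)
            if hit is None:
                out.append(x)
            else:
                remaining.pop(hit)
        return out

    return GridMismatch(
        origin_delta_mm=origin_delta,
        pixel_spacing_delta_mm=ps_delta,
        slice_spacing_delta_mm=float(ss_delta),
        slices_only_in_a=set_diff(a.slice_positions, b.slice_positions),
        slices_only_in_b=set_diff(b.slice_positions, a.slice_positions),
    )


def check_station_order(
    stack: SliceStack, blocks: Sequence[StationBlock] | None = None
) -> tuple[str, tuple[int, ...]]:
    """Verdict ('ordered'|'misordered') plus the permutation sorting blocks.

    The returned permutation lists, for each target slot, the index (within the
    given block list) of the block that belongs there — i.e. applying it to the
    composed block order restores monotonically increasing mean positions.
    """
    if blocks is None:
        blocks = stack.station_blocks
    if not blocks:
        raise ValidationError("no station blocks supplied")
    validate_blocks(blocks, stack.n_slices)
    order = sorted(range(len(blocks)), key=lambda i: blocks[i].slice_range[0])
    means = [float(np.mean(stack.slice_positions[blocks[i].indices()])) for i in order]
    perm_sorted = tuple(int(i) for i in np.argsort(means, kind="stable"))
    verdict = "ordered" if perm_sorted == tuple(range(len(blocks))) else "misordered"
    return verdict, perm_sorted


def render_gapmap_png(gaps: GapClassification, path) -> None:
    """Colour strip, one cell per boundary: light blue contiguous, white
    underlap, dark blue overlap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    code = {"contiguous": 0, "underlap": 1, "overlap": 2}
    row = np.array([[code[b.klass] for b in gaps.boundaries]])
    cmap = ListedColormap(["#9ecae1", "#ffffff", "#08519c"])
    fig, ax = plt.subplots(figsize=(max(2, row.shape[1] / 8), 0.8))
    ax.imshow(row, aspect="auto", cmap=cmap, vmin=0, vmax=2, interpolation="nearest")
    ax.set_yticks([])
    ax.set_xlabel("slice boundary")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
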