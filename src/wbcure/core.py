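"""Shared domain types: slice stacks, sessions, disease-pattern coding and counts.

Geometry conventions
--------------------
Patient coordinates are LPS.  A :class:`SliceStack` stores voxels as
``(n_slices, n_rows, n_cols)``; ``orientation`` holds the DICOM direction
cosines ``(row_dir, col_dir)`` where ``row_dir`` is the patient-space direction
of increasing *column* index and ``col_dir`` of increasing *row* index.  The
slice normal is ``cross(row_dir, col_dir)`` and ``slice_positions`` are mm
offsets of each slice along that normal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTRAST_LABELS",
    "DISEASE_CODES",
    "CANONICAL_CODE_ORDER",
    "SliceStack",
    "StationBlock",
    "ImagingSession",
    "DiseasePattern",
    "AnnotationRecord",
    "ValidationError",
    "UncategorisableError",
    "parse_pattern_code",
    "render_pattern",
    "coalesce_category",
    "subject_category",
    "aggregate_pattern_counts",
    "DEFAULT_REGIONS",
]

CONTRAST_LABELS = ("in_phase", "out_of_phase", "fat", "water", "b50", "b900", "adc")

DISEASE_CODES = frozenset({"D", "EM", "PM", "F", "MN", "I", "N", "H"})

#: Order in which pattern codes are rendered, e.g. "F D PM".
CANONICAL_CODE_ORDER = ("F", "D", "PM", "EM", "MN", "I", "N", "H")

#: Default 18 skeletal region names for annotation records (configurable).
DEFAULT_REGIONS = (
    "skull",
    "cervical_spine",
    "thoracic_spine",
    "lumbar_spine",
    "sacrum",
    "left_clavicle",
    "right_clavicle",
    "sternum",
    "left_ribs",
    "right_ribs",
    "left_scapula",
    "right_scapula",
    "left_humerus",
    "right_humerus",
    "left_pelvis",
    "right_pelvis",
    "left_femur",
    "right_femur",
)


class ValidationError(ValueError):
    """Raised when a domain invariant or input contract is violated."""


class UncategorisableError(ValidationError):
    """Raised when a disease pattern cannot be coalesced into a category."""


# ---------------------------------------------------------------------------
# Imaging types
# ---------------------------------------------------------------------------


@dataclass
class StationBlock:
    """Contiguous run of slices contributed by one couch position."""

    station_index: int
    slice_range: tuple[int, int]  # half-open [start, stop)
    source_offset_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        start, stop = self.slice_range
        if stop < start:
            raise ValidationError(f"invalid slice_range {self.slice_range}")

    @property
    def n_slices(self) -> int:
        return self.slice_range[1] - self.slice_range[0]

    def indices(self) -> slice:
        return slice(self.slice_range[0], self.slice_range[1])


def validate_blocks(blocks: Sequence[StationBlock], n_slices: int) -> None:
    """Check that blocks partition ``range(n_slices)`` with unique ordinals."""
    if not blocks:
        raise ValidationError("no station blocks given")
    ordinals = [b.station_index for b in blocks]
    if len(set(ordinals)) != len(ordinals):
        raise ValidationError("duplicate station ordinals")
    spans = sorted(b.slice_range for b in blocks)
    cursor = 0
    for start, stop in spans:
        if start != cursor:
            raise ValidationError(
                f"station blocks do not partition the stack (gap/overlap at slice {start})"
            )
        cursor = stop
    if cursor != n_slices:
        raise ValidationError(
            f"station blocks cover {cursor} slices but the stack has {n_slices}"
        )


@dataclass
class SliceStack:
    """3-D volume plus per-slice geometry for one composed series."""

    voxels: np.ndarray
    slice_positions: np.ndarray
    orientation: np.ndarray  # (2, 3): row_dir, col_dir
    origin: np.ndarray  # (3,) mm, first-slice first-voxel centre
    pixel_spacing: tuple[float, float]  # (row, col) mm
    nominal_slice_spacing: float
    contrast_label: str
    station_blocks: list[StationBlock] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError("voxels must be 3-D (slices, rows, cols)")
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if self.slice_positions.shape != (self.voxels.shape[0],):
            raise ValidationError("slice_positions length must equal slice count")
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(2, 3)
        for v in self.orientation:
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValidationError("orientation vectors must be unit norm")
        if abs(float(np.dot(self.orientation[0], self.orientation[1]))) > 1e-6:
            raise ValidationError("orientation vectors must be orthogonal")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if min(self.pixel_spacing) <= 0:
            raise ValidationError("pixel_spacing must be positive")
        if self.nominal_slice_spacing <= 0:
            raise ValidationError("nominal_slice_spacing must be positive")
        if self.contrast_label not in CONTRAST_LABELS:
            raise ValidationError(f"unknown contrast_label {self.contrast_label!r}")

    # -- geometry helpers ---------------------------------------------------

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def slice_normal(self) -> np.ndarray:
        return np.cross(self.orientation[0], self.orientation[1])

    def world_coords(self, slice_idx: int) -> np.ndarray:
        """World (LPS, mm) coordinates of every voxel centre of one slice.

        Returns an array of shape (rows, cols, 3).
        """
        n_sl, n_rows, n_cols = self.voxels.shape
        row_dir, col_dir = self.orientation
        normal = self.slice_normal
        base = self.origin + (self.slice_positions[slice_idx] - self.slice_positions[0]) * normal
        jj, ii = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
        return (
            base
            + jj[..., None] * self.pixel_spacing[1] * row_dir
            + ii[..., None] * self.pixel_spacing[0] * col_dir
        )

    def copy(self) -> "SliceStack":
        blocks = None
        if self.station_blocks is not None:
            blocks = [dataclasses.replace(b) for b in self.station_blocks]
        return SliceStack(
            voxels=self.voxels.copy(),
            slice_positions=self.slice_positions.copy(),
            orientation=self.orientation.copy(),
            origin=self.origin.copy(),
            pixel_spacing=tuple(self.pixel_spacing),
            nominal_slice_spacing=self.nominal_slice_spacing,
            contrast_label=self.contrast_label,
            station_blocks=blocks,
        )


COHORTS = ("a_retro_RM", "b_iTIMM", "c_healthy", "d_retro_ICHT")
PROTOCOLS = ("transverse_dixon", "coronal_dixon")


@dataclass
class ImagingSession:
    """One subject visit: a bundle of co-acquired composed series."""

    subject_id: str
    session_id: str
    series: dict[str, SliceStack] = field(default_factory=dict)
    cohort: str = "a_retro_RM"
    protocol: str = "transverse_dixon"
    #: descriptions of series present on disk but not one of the 7 contrasts
    extra_series: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(f"unknown cohort {self.cohort!r}")
        if self.protocol not in PROTOCOLS:
            raise ValidationError(f"unknown protocol {self.protocol!r}")
        for label, stack in self.series.items():
            if label != stack.contrast_label:
                raise ValidationError(
                    f"series key {label!r} != stack contrast {stack.contrast_label!r}"
                )

    def copy(self) -> "ImagingSession":
        return ImagingSession(
            subject_id=self.subject_id,
            session_id=self.session_id,
            series={k: v.copy() for k, v in self.series.items()},
            cohort=self.cohort,
            protocol=self.protocol,
            extra_series=list(self.extra_series),
        )


# ---------------------------------------------------------------------------
# Disease patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiseasePattern:
    codes: frozenset[str]

    def __post_init__(self) -> None:
        codes = frozenset(self.codes)
        object.__setattr__(self, "codes", codes)
        if not codes:
            raise ValidationError("disease pattern must be non-empty")
        unknown = codes - DISEASE_CODES
        if unknown:
            raise ValidationError(f"unknown code {sorted(unknown)[0]!r}")
        if "H" in codes and len(codes) > 1:
            raise ValidationError("'H' (healthy) cannot combine with disease codes")

    def render(self) -> str:
        return render_pattern(self)

    def __iter__(self):
        return iter(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.codes


def parse_pattern_code(code: str) -> DiseasePattern:
    """Parse a whitespace-separated pattern code string such as ``"F D PM"``.

    Case-insensitive; duplicate tokens collapse; order is irrelevant.
    """
    if not isinstance(code, str) or not code.strip():
        raise ValidationError("pattern code must be a non-empty string")
    tokens = {t.upper() for t in code.split()}
    for t in sorted(tokens):
        if t not in DISEASE_CODES:
            raise ValidationError(f"unknown code {t!r}")
    return DiseasePattern(frozenset(tokens))


def render_pattern(pattern: DiseasePattern) -> str:
    """Render codes in canonical order (``F D PM``, not ``PM D F``)."""
    return " ".join(c for c in CANONICAL_CODE_ORDER if c in pattern.codes)


DEFAULT_PRECEDENCE = ("F", "D", "I")
DEFAULT_CODE_ALIASES = {"MN": "F"}  # micronodular counts as focal by default


def coalesce_category(
    pattern: DiseasePattern,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    code_aliases: Mapping[str, str] = DEFAULT_CODE_ALIASES,
) -> str:
    """Coalesce a pattern into one of the categories F, D, I, H.

    H wins outright; otherwise the first category in ``precedence`` present in
    the (alias-mapped) code set wins.  EM/PM/N never determine a category on
    their own.
    """
    if "H" in pattern:
        return "H"
    mapped = {code_aliases.get(c, c) for c in pattern.codes}
    for cat in precedence:
        if cat in mapped:
            return cat
    raise UncategorisableError(
        f"pattern {render_pattern(pattern)!r} has no category-determining code"
    )


def subject_category(
    patterns: Iterable[DiseasePattern],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    code_aliases: Mapping[str, str] = DEFAULT_CODE_ALIASES,
) -> str:
    """Subject-level category: coalesce the union of all session patterns.

    Default reduction rule for subjects whose sessions carry mixed patterns.
    """
    union: set[str] = set()
    for p in patterns:
        union |= p.codes
    if "H" in union and len(union) > 1:
        # A subject cannot be healthy at one visit and diseased at another in
        # this model; drop H and categorise by disease codes.
        union.discard("H")
    return coalesce_category(DiseasePattern(frozenset(union)), precedence, code_aliases)


def aggregate_pattern_counts(
    records: Sequence[tuple[str, int, DiseasePattern]],
) -> pd.DataFrame:
    """Aggregate (session_id, phase, pattern) records into a count table.

    Returns a DataFrame with pattern rows (canonical rendering), one column per
    phase, plus a ``Total`` row and column.  Duplicate session ids are an
    error; phases must be 1, 2 or 3.
    """
    seen: set[str] = set()
    rows = []
    for session_id, phase, pattern in records:
        if session_id in seen:
            raise ValidationError(f"duplicate session_id {session_id!r}")
        seen.add(session_id)
        if phase not in (1, 2, 3):
            raise ValidationError(f"phase must be 1, 2 or 3 (got {phase!r})")
        rows.append({"pattern": render_pattern(pattern), "phase": phase})
    if not rows:
        return pd.DataFrame(
            [[0]], index=pd.Index(["Total"], name="pattern"), columns=["Total"]
        )
    df = pd.DataFrame(rows)
    table = df.pivot_table(index="pattern", columns="phase", aggfunc="size", fill_value=0)
    table.columns = [int(c) for c in table.columns]
    # Sort rows by descending combined count then canonical string (Table-1 style).
    totals = table.sum(axis=1)
    table = table.loc[totals.sort_values(ascending=False, kind="stable").index]
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    table.index.name = "pattern"
    return table


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass
class AnnotationRecord:
    """Per-region semantic labelling entry of an eCRF."""

    region_name: str
    focal_lesion_count: int = 0
    max_lesion_size_mm: float = 0.0
    diffuse_present: bool = False
    inactive_present: bool = False
    region_normal: bool = False
    artefact_present: bool = False
    regions: Sequence[str] = DEFAULT_REGIONS

    def __post_init__(self) -> None:
        if self.region_name not in self.regions:
            raise ValidationError(f"unknown region {self.region_name!r}")
        if self.focal_lesion_count < 0:
            raise ValidationError("focal_lesion_count must be non-negative")
        if self.max_lesion_size_mm < 0:
            raise ValidationError("max_lesion_size_mm must be non-negative")
        if self.region_normal and (self.focal_lesion_count > 0 or self.diffuse_present):
            raise ValidationError("a normal region cannot carry lesions or diffuse disease")
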