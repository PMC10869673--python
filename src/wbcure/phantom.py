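"""Synthetic multi-station whole-body Dixon+DWI session generator.

The phantom is an analytic soft-edged cylinder (subcutaneous fat rim, water
core, optional fat-bright marrow ellipsoids and low-ADC lesions) sampled on a
composed multi-station slice grid.  Channel model:

* ``in_phase  = fat + water`` voxelwise (exactly, including noise),
* ``out_of_phase = |water - fat|``,
* ``b50`` is a water-dominated baseline, clipped positive,
* ``b900 = b50 * exp(-(900 - 50) * ADC)`` with ADC in mm^2/s, so
  ``ln(b50/b900)/850`` recovers the ADC channel identically,
* the ``adc`` channel itself is noise-free.

Defects (slice overlap/underlap at station boundaries, per-station in-plane
offsets, global/station/local fat-water swaps, station misordering) are
injected by :func:`inject_defects` from a :class:`DefectLedger`, which doubles
as the ground truth for detector tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import (
    ImagingSession,
    SliceStack,
    StationBlock,
    ValidationError,
    validate_blocks,
)

__all__ = [
    "PhantomSpec",
    "GapEvent",
    "OffsetEvent",
    "SwapEvent",
    "DefectLedger",
    "build_phantom",
    "inject_defects",
]

B_LOW, B_HIGH = 50.0, 900.0
_DB = B_HIGH - B_LOW  # 850 s/mm^2

ADC_SOFT = 1.2e-3  # mm^2/s, water core
ADC_FAT = 4.5e-4  # mm^2/s, rim and marrow
B50_FLOOR = 1e-2


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic whole-body session."""

    body_length_mm: float = 144.0
    body_radius_mm: float = 80.0
    n_stations: int = 3
    station_overlap_slices: int = 0
    slice_spacing_mm: float = 6.0
    in_plane_spacing_mm: float = 6.0
    fat_rim_thickness_mm: float = 18.0
    bone_sites: tuple = ()  # ((cx, cy, cz), (rx, ry, rz)) mm
    lesion_sites: tuple = ()  # ((cx, cy, cz), (rx, ry, rz), adc_mm2_s)
    seed: int = 0
    matrix_size: int | None = None
    noise_sigma_frac: float = 0.02
    rim_intensity: float = 200.0
    edge_width_mm: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "body_length_mm",
            "body_radius_mm",
            "slice_spacing_mm",
            "in_plane_spacing_mm",
            "fat_rim_thickness_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_stations < 2:
            raise ValidationError("n_stations must be >= 2")
        if self.station_overlap_slices < 0:
            raise ValidationError("station_overlap_slices must be >= 0")
        if self.n_slices < self.n_stations:
            raise ValidationError("stations cannot cover the body length")

    @property
    def n_slices(self) -> int:
        return int(round(self.body_length_mm / self.slice_spacing_mm))

    @property
    def matrix(self) -> int:
        if self.matrix_size is not None:
            return int(self.matrix_size)
        return int(round(2.4 * self.body_radius_mm / self.in_plane_spacing_mm))

    @property
    def noise_sigma(self) -> float:
        return self.noise_sigma_frac * self.rim_intensity

    def station_sizes(self) -> list[int]:
        """Near-equal split of the composed slice count over stations."""
        n, k = self.n_slices, self.n_stations
        base, extra = divmod(n, k)
        return [base + (1 if i < extra else 0) for i in range(k)]

    def station_blocks(self) -> list[StationBlock]:
        blocks, start = [], 0
        for i, size in enumerate(self.station_sizes()):
            blocks.append(StationBlock(station_index=i, slice_range=(start, start + size)))
            start += size
        return blocks


# ---------------------------------------------------------------------------
# Analytic anatomy
# ---------------------------------------------------------------------------


def _soft(d: np.ndarray, w: float) -> np.ndarray:
    """Smooth 0..1 step, ~1 where d >> w (logistic edge of width w)."""
    return 1.0 / (1.0 + np.exp(np.clip(-d / w, -60, 60)))


def _ellipsoid(coords: np.ndarray, centre, radii, w: float) -> np.ndarray:
    c = np.asarray(centre, float)
    r = np.asarray(radii, float)
    d = np.sqrt(np.sum(((coords - c) / r) ** 2, axis=-1))
    return _soft((1.0 - d) * float(r.min()), w)


def _compartments(spec: PhantomSpec, coords: np.ndarray) -> dict[str, np.ndarray]:
    x, y, z = coords[..., 0], coords[..., 1], coords[..., 2]
    w = spec.edge_width_mm
    r_xy = np.hypot(x, y)
    body = (
        _soft(spec.body_radius_mm - r_xy, w)
        * _soft(z, w)
        * _soft(spec.body_length_mm - z, w)
    )
    rim = body * _soft(r_xy - (spec.body_radius_mm - spec.fat_rim_thickness_mm), w)
    core = body - rim
    marrow_ind = np.zeros_like(body)
    for centre, radii in spec.bone_sites:
        marrow_ind = np.maximum(marrow_ind, _ellipsoid(coords, centre, radii, w))
    marrow = core * marrow_ind
    water_core = core * (1.0 - marrow_ind)
    return {"body": body, "rim": rim, "marrow": marrow, "water_core": water_core, "coords": coords}


def _channels(spec: PhantomSpec, comp: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Noise-free fat / water / adc fields from compartment indicators."""
    I = spec.rim_intensity
    fatty = comp["rim"] + comp["marrow"]
    fat = I * fatty + 0.1 * I * comp["water_core"]
    water = I * comp["water_core"] + 0.1 * I * fatty
    adc = ADC_SOFT * comp["water_core"] + ADC_FAT * fatty
    for centre, radii, adc_value in spec.lesion_sites:
        les = _ellipsoid(comp["coords"], centre, radii, spec.edge_width_mm) * comp["body"]
        adc = adc * (1.0 - les) + les * adc_value
        water = water * (1.0 - les) + les * I  # lesions water/DWI-bright
    adc = np.where(adc < 1e-9, 0.0, adc)  # flush logistic tails: air has ADC 0
    return {"fat": fat, "water": water, "adc": adc}


_GEOM = {
    # orientation (row_dir, col_dir); slice normal = row_dir x col_dir
    "transverse": np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
    "coronal": np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0]]),
}


def _grid_coords(origin, orientation, positions, shape, pixel_spacing):
    """World (LPS) voxel-centre coordinates for a whole stack: (ns, nr, nc, 3)."""
    n_sl, n_rows, n_cols = shape
    row_dir, col_dir = orientation
    normal = np.cross(row_dir, col_dir)
    jj = np.arange(n_cols)[None, None, :, None]
    ii = np.arange(n_rows)[None, :, None, None]
    kk = (np.asarray(positions) - positions[0])[:, None, None, None]
    return (
        np.asarray(origin)
        + jj * pixel_spacing[1] * row_dir
        + ii * pixel_spacing[0] * col_dir
        + kk * normal
    )


def _dixon_geometry(spec: PhantomSpec, protocol: str):
    p = spec.in_plane_spacing_mm
    if protocol == "transverse_dixon":
        n_rows = n_cols = spec.matrix
        positions = (np.arange(spec.n_slices) + 0.5) * spec.slice_spacing_mm
        origin = np.array([-(n_cols - 1) / 2 * p, -(n_rows - 1) / 2 * p, positions[0]])
        return _GEOM["transverse"], positions, origin, (len(positions), n_rows, n_cols)
    # coronal: rows run superior->inferior, slices anterior->posterior
    n_cols = spec.matrix
    n_rows = int(round(spec.body_length_mm / p))
    half = 1.2 * spec.body_radius_mm
    n_sl = int(round(2 * half / spec.slice_spacing_mm))
    positions = -half + (np.arange(n_sl) + 0.5) * spec.slice_spacing_mm
    origin = np.array([-(n_cols - 1) / 2 * p, positions[0], spec.body_length_mm - p / 2])
    return _GEOM["coronal"], positions, origin, (n_sl, n_rows, n_cols)


def render_analytic(spec: PhantomSpec, channel: str, coords: np.ndarray) -> np.ndarray:
    """Noise-free analytic value of one of fat/water/adc at world coordinates."""
    return _channels(spec, _compartments(spec, coords))[channel]


def build_phantom(spec: PhantomSpec, protocol: str = "transverse_dixon") -> ImagingSession:
    """Render a defect-free 7-contrast session from a :class:`PhantomSpec`.

    With ``protocol="coronal_dixon"`` the four Dixon series are rendered on a
    coronal grid while DWI/ADC stay transverse (as acquired clinically).
    """
    ss = np.random.SeedSequence(spec.seed)
    rngs = {name: np.random.default_rng(s) for name, s in
            zip(("fat", "water", "b50"), ss.spawn(3))}

    def make_stack(label, voxels, orientation, positions, origin, blocks):
        return SliceStack(
            voxels=voxels,
            slice_positions=np.asarray(positions, float),
            orientation=orientation,
            origin=origin,
            pixel_spacing=(spec.in_plane_spacing_mm, spec.in_plane_spacing_mm),
            nominal_slice_spacing=spec.slice_spacing_mm,
            contrast_label=label,
            station_blocks=blocks,
        )

    def render_group(orientation, positions, origin, shape, with_blocks):
        coords = _grid_coords(origin, orientation, positions, shape, (spec.in_plane_spacing_mm,) * 2)
        ch = _channels(spec, _compartments(spec, coords))
        sigma = spec.noise_sigma
        fat = np.clip(ch["fat"] + sigma * rngs["fat"].standard_normal(shape), 0, None)
        water = np.clip(ch["water"] + sigma * rngs["water"].standard_normal(shape), 0, None)
        return fat, water, ch["adc"]

    series: dict[str, SliceStack] = {}

    # Dixon group (transverse or coronal depending on protocol)
    orientation, positions, origin, shape = _dixon_geometry(spec, protocol)
    dixon_blocks = spec.station_blocks() if protocol == "transverse_dixon" else None
    fat, water, _ = render_group(orientation, positions, origin, shape, dixon_blocks)

    def blocks_copy():
        return None if dixon_blocks is None else [dataclasses.replace(b) for b in dixon_blocks]

    series["fat"] = make_stack("fat", fat, orientation, positions, origin, blocks_copy())
    series["water"] = make_stack("water", water, orientation, positions, origin, blocks_copy())
    series["in_phase"] = make_stack(
        "in_phase", fat + water, orientation, positions, origin, blocks_copy()
    )
    series["out_of_phase"] = make_stack(
        "out_of_phase", np.abs(water - fat), orientation, positions, origin, blocks_copy()
    )

    # DWI/ADC group: always transverse
    t_orient, t_pos, t_origin, t_shape = _dixon_geometry(spec, "transverse_dixon")
    t_blocks = spec.station_blocks()
    coords = _grid_coords(t_origin, t_orient, t_pos, t_shape, (spec.in_plane_spacing_mm,) * 2)
    ch = _channels(spec, _compartments(spec, coords))
    sigma = spec.noise_sigma
    fat_t = np.clip(ch["fat"] + sigma * rngs["fat"].standard_normal(t_shape), 0, None) \
        if protocol != "transverse_dixon" else fat
    water_t = np.clip(ch["water"] + sigma * rngs["water"].standard_normal(t_shape), 0, None) \
        if protocol != "transverse_dixon" else water
    adc = ch["adc"]
    b50 = np.clip(
        0.9 * water_t + 0.1 * fat_t + sigma * rngs["b50"].standard_normal(t_shape),
        B50_FLOOR,
        None,
    )
    b900 = b50 * np.exp(-_DB * adc)

    def t_blocks_copy():
        return [dataclasses.replace(b) for b in t_blocks]

    series["b50"] = make_stack("b50", b50, t_orient, t_pos, t_origin, t_blocks_copy())
    series["b900"] = make_stack("b900", b900, t_orient, t_pos, t_origin, t_blocks_copy())
    series["adc"] = make_stack("adc", adc, t_orient, t_pos, t_origin, t_blocks_copy())

    return ImagingSession(
        subject_id=f"PH{spec.seed:05d}",
        session_id=f"PH{spec.seed:05d}_S1",
        series=series,
        cohort="c_healthy",
        protocol="transverse_dixon" if protocol == "transverse_dixon" else "coronal_dixon",
    )


# ---------------------------------------------------------------------------
# Defect ledger and injection
# ---------------------------------------------------------------------------

GAP_KINDS = ("underlap", "overlap")
SWAP_SCOPES = ("global", "station", "local")
DEFAULT_GAP_CONTRASTS = ("fat", "water", "in_phase", "out_of_phase", "b50", "b900", "adc")


@dataclass(frozen=True)
class GapEvent:
    """Slice-contiguity defect at the boundary after station ``boundary`` (0-based)."""

    boundary: int
    kind: str
    n_slices: int
    contrasts: tuple[str, ...] = DEFAULT_GAP_CONTRASTS

    def __post_init__(self) -> None:
        if self.kind not in GAP_KINDS:
            raise ValidationError(f"gap kind must be one of {GAP_KINDS}")
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")


@dataclass(frozen=True)
class OffsetEvent:
    """In-plane translation of one station's block in one contrast.

    ``dx_px`` shifts along the column-index (x) axis, ``dy_px`` along the
    row-index (y) axis.
    """

    station_index: int
    dx_px: int
    dy_px: int
    contrast: str = "fat"


@dataclass(frozen=True)
class SwapEvent:
    """Fat-water mislabelling: global, per-station, or a local ellipsoid region."""

    scope: str
    station_index: int | None = None
    region: tuple | None = None  # ((cx, cy, cz), (rx, ry, rz)) mm, scope="local"

    def __post_init__(self) -> None:
        if self.scope not in SWAP_SCOPES:
            raise ValidationError(f"swap scope must be one of {SWAP_SCOPES}")
        if self.scope == "station" and self.station_index is None:
            raise ValidationError("station swap needs station_index")
        if self.scope == "local" and self.region is None:
            raise ValidationError("local swap needs a region ellipsoid")


@dataclass
class DefectLedger:
    """Ground-truth record of every defect injected into a phantom session."""

    slice_gap_events: list[GapEvent] = field(default_factory=list)
    offset_events: list[OffsetEvent] = field(default_factory=list)
    swap_events: list[SwapEvent] = field(default_factory=list)
    station_permutation: tuple[int, ...] | None = None

    def is_empty(self) -> bool:
        return not (
            self.slice_gap_events
            or self.offset_events
            or self.swap_events
            or (self.station_permutation is not None
                and tuple(self.station_permutation) != tuple(range(len(self.station_permutation))))
        )

    def validate(self, n_stations: int) -> None:
        boundaries = [e.boundary for e in self.slice_gap_events]
        if len(set(boundaries)) != len(boundaries):
            raise ValidationError("contradictory gap events on the same boundary")
        for e in self.slice_gap_events:
            if not 0 <= e.boundary < n_stations - 1:
                raise ValidationError(f"gap boundary {e.boundary} out of range")
        off_keys = [(e.station_index, e.contrast) for e in self.offset_events]
        if len(set(off_keys)) != len(off_keys):
            raise ValidationError("contradictory offset events on the same station")
        for e in self.offset_events:
            if not 0 <= e.station_index < n_stations:
                raise ValidationError(f"offset station {e.station_index} out of range")
        scopes = [e.scope for e in self.swap_events]
        if scopes.count("global") > 1:
            raise ValidationError("multiple global swap events")
        st = [e.station_index for e in self.swap_events if e.scope == "station"]
        if len(set(st)) != len(st):
            raise ValidationError("contradictory swap events on the same station")
        for e in self.swap_events:
            if e.scope == "station" and not 0 <= e.station_index < n_stations:
                raise ValidationError(f"swap station {e.station_index} out of range")
        if self.station_permutation is not None:
            perm = tuple(self.station_permutation)
            if sorted(perm) != list(range(n_stations)):
                raise ValidationError("station_permutation is not a bijection")

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "slice_gap_events": [dataclasses.asdict(e) | {"contrasts": list(e.contrasts)}
                                 for e in self.slice_gap_events],
            "offset_events": [dataclasses.asdict(e) for e in self.offset_events],
            "swap_events": [dataclasses.asdict(e) for e in self.swap_events],
            "station_permutation": (
                list(self.station_permutation) if self.station_permutation is not None else None
            ),
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DefectLedger":
        doc = yaml.safe_load(text) or {}
        gaps = [
            GapEvent(
                boundary=int(e["boundary"]),
                kind=e["kind"],
                n_slices=int(e["n_slices"]),
                contrasts=tuple(e.get("contrasts") or DEFAULT_GAP_CONTRASTS),
            )
            for e in doc.get("slice_gap_events") or []
        ]
        offs = [
            OffsetEvent(
                station_index=int(e["station_index"]),
                dx_px=int(e["dx_px"]),
                dy_px=int(e["dy_px"]),
                contrast=e.get("contrast", "fat"),
            )
            for e in doc.get("offset_events") or []
        ]
        swaps = [
            SwapEvent(
                scope=e["scope"],
                station_index=e.get("station_index"),
                region=(
                    (tuple(e["region"][0]), tuple(e["region"][1]))
                    if e.get("region") is not None
                    else None
                ),
            )
            for e in doc.get("swap_events") or []
        ]
        perm = doc.get("station_permutation")
        return cls(
            slice_gap_events=gaps,
            offset_events=offs,
            swap_events=swaps,
            station_permutation=tuple(perm) if perm is not None else None,
        )


def _translate2d(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Integer-pixel translation with zero fill; dx along axis 1 (cols)."""
    out = np.zeros_like(img)
    h, w = img.shape[-2], img.shape[-1]
    ys = slice(max(dy, 0), min(h + dy, h))
    yd = slice(max(-dy, 0), min(h - dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    xd = slice(max(-dx, 0), min(w - dx, w))
    # shift content by (+dy, +dx): out[y+dy, x+dx] = img[y, x]
    out[..., ys, xs] = img[..., yd, xd]
    return out


def _stack_voxel_mask(stack: SliceStack, centre, radii) -> np.ndarray:
    """Boolean mask of voxels inside a world-space ellipsoid."""
    coords = _grid_coords(
        stack.origin, stack.orientation, stack.slice_positions, stack.shape, stack.pixel_spacing
    )
    c = np.asarray(centre, float)
    r = np.asarray(radii, float)
    return np.sum(((coords - c) / r) ** 2, axis=-1) <= 1.0


def inject_defects(session: ImagingSession, ledger: DefectLedger) -> ImagingSession:
    """Apply every ledger event to a copy of ``session`` (input untouched)."""
    out = session.copy()
    blocked = {k: s for k, s in out.series.items() if s.station_blocks}
    if not blocked:
        raise ValidationError("session carries no station blocks; cannot inject defects")
    n_stations = max(len(s.station_blocks) for s in blocked.values())
    ledger.validate(n_stations)

    # 1. station misordering (applied to every station-blocked series)
    perm = ledger.station_permutation
    if perm is not None and tuple(perm) != tuple(range(n_stations)):
        for stack in blocked.values():
            blocks = stack.station_blocks
            vox = [stack.voxels[b.indices()] for b in blocks]
            pos = [stack.slice_positions[b.indices()] for b in blocks]
            new_blocks, start = [], 0
            new_vox, new_pos = [], []
            for slot, src in enumerate(perm):
                new_vox.append(vox[src])
                new_pos.append(pos[src])
                size = blocks[src].n_slices
                new_blocks.append(
                    StationBlock(
                        station_index=blocks[src].station_index,
                        slice_range=(start, start + size),
                        source_offset_mm=blocks[src].source_offset_mm,
                    )
                )
                start += size
            stack.voxels = np.concatenate(new_vox, axis=0)
            stack.slice_positions = np.concatenate(new_pos)
            stack.station_blocks = new_blocks

    # 2. slice-gap events, highest boundary first so indices stay valid
    for ev in sorted(ledger.slice_gap_events, key=lambda e: -e.boundary):
        for label in ev.contrasts:
            stack = out.series.get(label)
            if stack is None or not stack.station_blocks:
                continue
            blocks = sorted(stack.station_blocks, key=lambda b: b.slice_range[0])
            left, right = blocks[ev.boundary], blocks[ev.boundary + 1]
            n = ev.n_slices
            if ev.kind == "underlap":
                if n >= right.n_slices:
                    raise ValidationError("underlap would consume a whole station")
                lo = right.slice_range[0]
                stack.voxels = np.delete(stack.voxels, slice(lo, lo + n), axis=0)
                stack.slice_positions = np.delete(stack.slice_positions, slice(lo, lo + n))
                delta = -n
            else:  # overlap: re-imaged copies of the previous station's tail
                hi = left.slice_range[1]
                dup_v = stack.voxels[hi - n : hi]
                dup_p = stack.slice_positions[hi - n : hi]
                stack.voxels = np.concatenate(
                    [stack.voxels[:hi], dup_v, stack.voxels[hi:]], axis=0
                )
                stack.slice_positions = np.concatenate(
                    [stack.slice_positions[:hi], dup_p, stack.slice_positions[hi:]]
                )
                delta = n
            new_blocks = []
            for b in blocks:
                lo, hi2 = b.slice_range
                if b is right:
                    hi2 += delta  # gains (overlap) or loses (underlap) n slices
                elif lo >= right.slice_range[0]:
                    lo += delta
                    hi2 += delta
                new_blocks.append(
                    StationBlock(b.station_index, (lo, hi2), b.source_offset_mm)
                )
            stack.station_blocks = new_blocks
            validate_blocks(stack.station_blocks, stack.n_slices)

    # 3. in-plane offsets
    for ev in ledger.offset_events:
        stack = out.series.get(ev.contrast)
        if stack is None or not stack.station_blocks:
            raise ValidationError(f"offset event targets missing series {ev.contrast!r}")
        block = next(
            b for b in stack.station_blocks if b.station_index == ev.station_index
        )
        idx = block.indices()
        stack.voxels[idx] = _translate2d(stack.voxels[idx], ev.dx_px, ev.dy_px)
        block.source_offset_mm = (
            ev.dx_px * stack.pixel_spacing[1],
            ev.dy_px * stack.pixel_spacing[0],
        )

    # 4. fat-water swaps
    for ev in ledger.swap_events:
        fat, water = out.series.get("fat"), out.series.get("water")
        if fat is None or water is None:
            raise ValidationError("swap event needs fat and water series")
        if ev.scope == "global":
            fat.voxels, water.voxels = water.voxels, fat.voxels
        elif ev.scope == "station":
            fb = next(b for b in fat.station_blocks if b.station_index == ev.station_index)
            wb = next(b for b in water.station_blocks if b.station_index == ev.station_index)
            fi, wi = fb.indices(), wb.indices()
            fat.voxels[fi], water.voxels[wi] = (
                water.voxels[wi].copy(),
                fat.voxels[fi].copy(),
            )
        else:  # local
            centre, radii = ev.region
            mask = _stack_voxel_mask(fat, centre, radii)
            f = fat.voxels[mask].copy()
            fat.voxels[mask] = water.voxels[mask]
            water.voxels[mask] = f

    return out
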