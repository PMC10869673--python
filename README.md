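# wbcure

Curation toolkit for composed ("stitched") whole-body MRI sessions: audit and
repair the geometric defects that vendor multi-station composition introduces,
detect fat–water label swaps, harmonise every series onto a common grid,
allocate subjects to study phases stratified by disease category, and record
every action in a self-documenting QA trail. A synthetic multi-station
Dixon+DWI phantom generator with ground-truth defect injection serves as the
test fixture in place of clinical data.

## Modules

| Module | Purpose |
| --- | --- |
| `wbcure.core` | Domain types (`SliceStack`, `StationBlock`, `ImagingSession`), disease-pattern coding (`parse_pattern_code`, `coalesce_category`) and count aggregation |
| `wbcure.phantom` | `PhantomSpec` → 7-contrast synthetic session (`build_phantom`); `DefectLedger` + `inject_defects` for slice overlap/underlap, per-station in-plane offsets, global/station/local fat–water swaps and station misordering |
| `wbcure.dicomio` | Bounded DICOM codec (uncompressed Explicit-VR-LE MR); `write_session_dicom` / `read_session_dicom` |
| `wbcure.audit` | Slice-contiguity classification (`classify_gaps`), per-series severity (`audit_series`), cross-series grid comparison, station-order check, colour-strip gap maps |
| `wbcure.repair` | `regrid_overlaps` (average duplicates, interpolate, mask underlaps), integer-pixel offset estimation by phase correlation, offset correction, station reordering |
| `wbcure.swaps` | Rim-statistic swap detection (global/station) and b50-referenced local-swap flagging; `apply_swap_fix` |
| `wbcure.harmonise` | DWI-donor target grid, trilinear/nearest resampling, NIfTI export (RAS+ affine) |
| `wbcure.allocate` | Deterministic seeded phase allocation stratified by category; summary tables |
| `wbcure.qa` | Inventory checks, DICOM pseudonymisation, repository layout, `RunRecord` (JSON + HTML), project metrics |
| `wbcure.pipeline` | `curate_session`: inventory → reorder → offsets → swaps → regrid, fully logged |
| `wbcure.evaluation` | Seeded single-defect recovery suite scored against the injection ledger |

## CLI

```bash
# synthetic session with an injected 2-slice overlap, written as DICOM
wbcure phantom --spec spec.yaml --defects ledger.yaml --out session/

# slice-contiguity audit: report.json, report.html, gapmap_<series>.png
wbcure audit session/ --report report/

# full repair pipeline: repaired DICOM, missing-mask NIfTI, repair_log.json,
# crystallised HTML run record
wbcure clean session/ --out cleaned/ --stations 3

# resample all series to a common grid, export NIfTI + grid.json
wbcure harmonise session/ --out nifti/

# deterministic phase allocation from subjects.csv (subject_id, cohort, pattern_code)
wbcure allocate subjects.csv --seed 1 --out alloc/

# project-level metrics recomputed from stored run records
wbcure qa project_dir/ --report qa.html
```

A defect ledger is plain YAML, e.g.

```yaml
slice_gap_events:
  - {boundary: 1, kind: overlap, n_slices: 2}
offset_events:
  - {station_index: 2, dx_px: 3, dy_px: -2}
swap_events:
  - {scope: station, station_index: 1}
```

## Conventions

- Patient coordinates are LPS; NIfTI is exported RAS+ with an explicit
  LPS→RAS conversion; voxel (0,0,0) is the first-slice first-voxel centre.
- Slice stacks are `(slices, rows, cols)`; `orientation` holds DICOM-style
  row/column direction cosines; the slice normal is their cross product.
- Offsets `(dx_px, dy_px)` are shifts along the column- and row-index axes;
  estimation is integer-pixel only (sub-pixel resampling would blur data).
- Underlap voxels are interpolated *and* flagged in a `missing_mask` sidecar
  so downstream consumers can exclude fabricated data.
- Local fat–water swaps are never auto-corrected, only flagged.
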