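import numpy as np
import pytest

from wbcure.audit import audit_series, check_station_order
from wbcure.core import ValidationError
from wbcure.phantom import (
    DefectLedger,
    GapEvent,
    OffsetEvent,
    PhantomSpec,
    build_phantom,
    inject_defects,
)
from wbcure.repair import (
    OffsetBoundError,
    apply_offset_correction,
    estimate_inplane_offset,
    regrid_overlaps,
    reorder_stations,
)


class TestRegridOverlaps:
    def test_uniform_stack_identity(self, clean_session):
        rep = regrid_overlaps(clean_session.series["fat"])
        assert rep.repair_log == []
        assert not rep.missing_mask.any()
        assert np.array_equal(rep.stack.voxels, clean_session.series["fat"].voxels)

    def test_overlap_repair_matches_ground_truth(self, clean_session, default_spec):
        d = inject_defects(
            clean_session, DefectLedger(slice_gap_events=[GapEvent(1, "overlap", 2)])
        )
        rep = regrid_overlaps(d.series["fat"])
        gaps = np.diff(rep.stack.slice_positions)
        assert np.ptp(gaps) < 0.01 and np.all(gaps > 0)
        rms = np.sqrt(
            np.mean((rep.stack.voxels - clean_session.series["fat"].voxels) ** 2)
        )
        assert rms < default_spec.noise_sigma
        assert rep.repair_log  # non-trivial repair is logged

    def test_underlap_mask_marks_missing_slices(self, clean_session):
        d = inject_defects(
            clean_session, DefectLedger(slice_gap_events=[GapEvent(1, "underlap", 2)])
        )
        rep = regrid_overlaps(d.series["fat"])
        masked = np.where(rep.missing_mask.any(axis=(1, 2)))[0]
        assert len(masked) == 2
        # the masked output slices sit exactly at the deleted positions
        clean_pos = set(np.round(clean_session.series["fat"].slice_positions, 6))
        defect_pos = set(np.round(d.series["fat"].slice_positions, 6))
        missing = sorted(clean_pos - defect_pos)
        assert np.allclose(rep.stack.slice_positions[masked], missing)
        # all masked slices fully flagged, no others
        assert rep.missing_mask[masked].all()
        assert not np.delete(rep.missing_mask, masked, axis=0).any()

    def test_underlap_void_mode(self, clean_session):
        d = inject_defects(
            clean_session, DefectLedger(slice_gap_events=[GapEvent(1, "underlap", 1)])
        )
        rep = regrid_overlaps(d.series["fat"], fill_underlaps=False)
        assert np.isnan(rep.stack.voxels[rep.missing_mask]).all()

    def test_degenerate_stack_rejected(self, clean_session):
        stack = clean_session.series["fat"].copy()
        stack.slice_positions = np.full(stack.n_slices, 3.0)
        stack.station_blocks = None
        with pytest.raises(ValidationError):
            regrid_overlaps(stack)

    def test_post_regrid_audit_never_amber(self, clean_session):
        for ev in [GapEvent(0, "overlap", 2), GapEvent(1, "underlap", 2)]:
            d = inject_defects(clean_session, DefectLedger(slice_gap_events=[ev]))
            rep = regrid_overlaps(d.series["fat"])
            _, severity, _ = audit_series(rep.stack)
            assert severity == "ok"  # uniform grid: overlaps always repaired

    def test_mean_intensity_conserved_noise_free(self, noisefree_session):
        d = inject_defects(
            noisefree_session, DefectLedger(slice_gap_events=[GapEvent(1, "overlap", 2)])
        )
        rep = regrid_overlaps(d.series["water"])
        body = noisefree_session.series["water"].voxels > 10
        before = noisefree_session.series["water"].voxels[body].mean()
        after = rep.stack.voxels[body].mean()
        assert abs(after - before) / before < 0.01


class TestEstimateInplaneOffset:
    def test_self_is_zero(self, clean_session):
        fat = clean_session.series["fat"]
        blk = fat.station_blocks[0]
        assert estimate_inplane_offset(fat, fat, blk) == (0, 0)

    def test_recovers_injected_shift(self, clean_session):
        d = inject_defects(
            clean_session, DefectLedger(offset_events=[OffsetEvent(2, 3, -2)])
        )
        blk = next(b for b in d.series["fat"].station_blocks if b.station_index == 2)
        assert estimate_inplane_offset(d.series["fat"], d.series["water"], blk) == (3, -2)

    def test_exact_recovery_noise_free_sweep(self, noisefree_session):
        for dx in range(-10, 11, 5):
            for dy in (-10, -3, 0, 7):
                d = inject_defects(
                    noisefree_session,
                    DefectLedger(offset_events=[OffsetEvent(1, dx, dy)]),
                )
                blk = next(
                    b for b in d.series["fat"].station_blocks if b.station_index == 1
                )
                est = estimate_inplane_offset(d.series["fat"], d.series["water"], blk)
                assert est == (dx, dy)

    def test_within_one_px_at_5pc_noise(self):
        session = build_phantom(PhantomSpec(seed=21, noise_sigma_frac=0.05))
        for dx, dy in [(-10, 4), (6, -6), (10, 10), (2, 0)]:
            d = inject_defects(
                session, DefectLedger(offset_events=[OffsetEvent(1, dx, dy)])
            )
            blk = next(b for b in d.series["fat"].station_blocks if b.station_index == 1)
            ex, ey = estimate_inplane_offset(d.series["fat"], d.series["water"], blk)
            assert abs(ex - dx) <= 1 and abs(ey - dy) <= 1

    def test_zero_variance_block_rejected(self, clean_session):
        fat = clean_session.series["fat"]
        flat = fat.copy()
        flat.voxels[:] = 0.0
        with pytest.raises(ValidationError, match="uninformative"):
            estimate_inplane_offset(flat, flat, fat.station_blocks[0])

    def test_shift_beyond_bound_raises(self, noisefree_session):
        d = inject_defects(
            noisefree_session, DefectLedger(offset_events=[OffsetEvent(1, 10, 0)])
        )
        blk = next(b for b in d.series["fat"].station_blocks if b.station_index == 1)
        with pytest.raises(OffsetBoundError):
            estimate_inplane_offset(d.series["fat"], d.series["water"], blk, bound=5)
        # bounded mode returns something inside the window instead
        ex, ey = estimate_inplane_offset(
            d.series["fat"], d.series["water"], blk, bound=5, on_exceed="bounded"
        )
        assert abs(ex) <= 5 and abs(ey) <= 5


class TestApplyOffsetCorrection:
    def test_zero_shift_identity(self, clean_session):
        fat = clean_session.series["fat"]
        out = apply_offset_correction(fat, {0: (0, 0)})
        assert np.array_equal(out.voxels, fat.voxels)

    def test_apply_then_reestimate_zero(self, clean_session):
        d = inject_defects(
            clean_session, DefectLedger(offset_events=[OffsetEvent(1, 4, -3)])
        )
        corrected = apply_offset_correction(d.series["fat"], {1: (4, -3)})
        for blk in corrected.station_blocks:
            est = estimate_inplane_offset(corrected, d.series["water"], blk)
            assert est == (0, 0)

    def test_roundtrip_voxel_identical_away_from_border(self, clean_session):
        d = inject_defects(
            clean_session, DefectLedger(offset_events=[OffsetEvent(1, 5, 5)])
        )
        corrected = apply_offset_correction(d.series["fat"], {1: (5, 5)})
        dev = np.abs(corrected.voxels - clean_session.series["fat"].voxels)
        b = 5
        assert dev[:, b:-b, b:-b].max() == 0.0

    def test_shift_beyond_bound_rejected(self, clean_session):
        with pytest.raises(OffsetBoundError):
            apply_offset_correction(clean_session.series["fat"], {0: (20, 0)})


class TestReorderStations:
    def test_identity(self, clean_session):
        fat = clean_session.series["fat"]
        out = reorder_stations(fat, None, (0, 1, 2))
        assert np.array_equal(out.voxels, fat.voxels)

    def test_inverse_recovers_clean(self, clean_session):
        d = inject_defects(clean_session, DefectLedger(station_permutation=(2, 0, 1)))
        verdict, perm = check_station_order(d.series["fat"])
        assert verdict == "misordered"
        out = reorder_stations(d.series["fat"], None, perm)
        assert np.array_equal(out.voxels, clean_session.series["fat"].voxels)
        assert np.array_equal(
            out.slice_positions, clean_session.series["fat"].slice_positions
        )

    def test_invalid_permutation(self, clean_session):
        with pytest.raises(ValidationError, match="bijection"):
            reorder_stations(clean_session.series["fat"], None, (0, 0, 1))
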