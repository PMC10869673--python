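import numpy as np
import pytest

from wbcure.core import ValidationError
from wbcure.phantom import (
    DefectLedger,
    GapEvent,
    OffsetEvent,
    PhantomSpec,
    SwapEvent,
    build_phantom,
    inject_defects,
)


class TestBuildPhantom:
    def test_all_seven_contrasts(self, clean_session):
        assert sorted(clean_session.series) == sorted(
            ["in_phase", "out_of_phase", "fat", "water", "b50", "b900", "adc"]
        )

    def test_in_phase_identity(self, clean_session):
        s = clean_session.series
        assert np.array_equal(
            s["in_phase"].voxels, s["fat"].voxels + s["water"].voxels
        )

    def test_out_of_phase_identity(self, clean_session):
        s = clean_session.series
        assert np.array_equal(
            s["out_of_phase"].voxels, np.abs(s["water"].voxels - s["fat"].voxels)
        )

    def test_adc_closed_form_recovery(self, clean_session):
        # ln(b50/b900)/850 inverts the mono-exponential decay exactly
        s = clean_session.series
        recovered = np.log(s["b50"].voxels / s["b900"].voxels) / 850.0
        assert np.abs(recovered - s["adc"].voxels).max() < 1e-6

    def test_zero_adc_means_equal_dwi(self, clean_session):
        s = clean_session.series
        zero_adc = s["adc"].voxels == 0
        assert zero_adc.any()
        assert np.array_equal(s["b50"].voxels[zero_adc], s["b900"].voxels[zero_adc])

    def test_determinism(self, default_spec, clean_session):
        again = build_phantom(PhantomSpec(seed=default_spec.seed))
        for label, stack in clean_session.series.items():
            assert np.array_equal(stack.voxels, again.series[label].voxels)

    def test_different_seed_differs(self, default_spec, clean_session):
        other = build_phantom(PhantomSpec(seed=default_spec.seed + 1))
        assert not np.array_equal(
            other.series["fat"].voxels, clean_session.series["fat"].voxels
        )

    def test_geometry_consistent_across_contrasts(self, clean_session):
        stacks = list(clean_session.series.values())
        ref = stacks[0]
        for stack in stacks[1:]:
            assert np.allclose(stack.slice_positions, ref.slice_positions)
            assert np.allclose(stack.origin, ref.origin)
            assert np.allclose(stack.orientation, ref.orientation)

    def test_station_blocks_partition(self, clean_session):
        blocks = clean_session.series["fat"].station_blocks
        assert [b.slice_range for b in blocks] == [(0, 8), (8, 16), (16, 24)]

    def test_invalid_spec(self):
        with pytest.raises(ValidationError):
            PhantomSpec(body_length_mm=-1)
        with pytest.raises(ValidationError):
            PhantomSpec(n_stations=1)

    def test_coronal_protocol_geometry(self):
        session = build_phantom(PhantomSpec(seed=3), protocol="coronal_dixon")
        fat = session.series["fat"]
        assert np.allclose(fat.slice_normal, [0, 1, 0])  # slices stack along A-P
        assert np.allclose(session.series["b50"].slice_normal, [0, 0, 1])
        assert session.protocol == "coronal_dixon"


class TestInjectDefects:
    def test_empty_ledger_identity(self, clean_session):
        out = inject_defects(clean_session, DefectLedger())
        for label, stack in out.series.items():
            assert np.array_equal(stack.voxels, clean_session.series[label].voxels)
            assert np.array_equal(
                stack.slice_positions, clean_session.series[label].slice_positions
            )

    def test_input_unmodified(self, clean_session):
        before = clean_session.series["fat"].voxels.copy()
        inject_defects(
            clean_session, DefectLedger(swap_events=[SwapEvent("global")])
        )
        assert np.array_equal(clean_session.series["fat"].voxels, before)

    def test_overlap_creates_duplicate_positions(self, clean_session):
        out = inject_defects(
            clean_session,
            DefectLedger(slice_gap_events=[GapEvent(boundary=1, kind="overlap", n_slices=2)]),
        )
        pos = out.series["fat"].slice_positions
        assert len(pos) == 26
        values, counts = np.unique(pos, return_counts=True)
        assert (counts == 2).sum() == 2  # two pairs of duplicate-position slices

    def test_underlap_removes_positions(self, clean_session):
        out = inject_defects(
            clean_session,
            DefectLedger(slice_gap_events=[GapEvent(boundary=1, kind="underlap", n_slices=2)]),
        )
        pos = out.series["fat"].slice_positions
        clean_pos = clean_session.series["fat"].slice_positions
        assert len(pos) == 22
        missing = sorted(set(clean_pos) - set(pos))
        assert len(missing) == 2
        assert np.isclose(missing[1] - missing[0], 6.0)

    def test_offset_translates_fat_block(self, clean_session):
        out = inject_defects(
            clean_session,
            DefectLedger(offset_events=[OffsetEvent(station_index=2, dx_px=3, dy_px=-2)]),
        )
        fat, clean_fat = out.series["fat"], clean_session.series["fat"]
        blk = next(b for b in fat.station_blocks if b.station_index == 2)
        idx = blk.indices()
        # (dx=3, dy=-2): out[y-2, x+3] = in[y, x]
        assert np.array_equal(
            fat.voxels[idx][:, 0:30, 3:32], clean_fat.voxels[idx][:, 2:32, 0:29]
        )
        # water untouched
        assert np.array_equal(out.series["water"].voxels, clean_session.series["water"].voxels)
        assert blk.source_offset_mm == (18.0, -12.0)

    def test_global_swap_exchanges_labels(self, clean_session):
        out = inject_defects(clean_session, DefectLedger(swap_events=[SwapEvent("global")]))
        assert np.array_equal(out.series["fat"].voxels, clean_session.series["water"].voxels)
        assert np.array_equal(out.series["water"].voxels, clean_session.series["fat"].voxels)

    def test_station_swap(self, clean_session):
        out = inject_defects(
            clean_session, DefectLedger(swap_events=[SwapEvent("station", station_index=1)])
        )
        sl = slice(8, 16)
        assert np.array_equal(out.series["fat"].voxels[sl], clean_session.series["water"].voxels[sl])
        assert np.array_equal(out.series["fat"].voxels[0:8], clean_session.series["fat"].voxels[0:8])

    def test_local_swap_region_only(self, clean_session):
        region = ((0.0, 0.0, 72.0), (25.0, 25.0, 15.0))
        out = inject_defects(
            clean_session, DefectLedger(swap_events=[SwapEvent("local", region=region)])
        )
        changed = out.series["fat"].voxels != clean_session.series["fat"].voxels
        assert changed.any()
        assert changed.sum() < clean_session.series["fat"].voxels.size // 4

    def test_station_permutation_moves_blocks(self, clean_session):
        out = inject_defects(clean_session, DefectLedger(station_permutation=(2, 0, 1)))
        fat, cf = out.series["fat"], clean_session.series["fat"]
        assert np.array_equal(fat.voxels[0:8], cf.voxels[16:24])
        assert np.array_equal(fat.slice_positions[0:8], cf.slice_positions[16:24])

    def test_contradictory_gap_events_rejected(self, clean_session):
        ledger = DefectLedger(
            slice_gap_events=[GapEvent(0, "overlap", 1), GapEvent(0, "underlap", 1)]
        )
        with pytest.raises(ValidationError, match="contradictory"):
            inject_defects(clean_session, ledger)

    def test_out_of_range_station_rejected(self, clean_session):
        with pytest.raises(ValidationError):
            inject_defects(
                clean_session, DefectLedger(offset_events=[OffsetEvent(7, 2, 2)])
            )

    def test_bad_permutation_rejected(self, clean_session):
        with pytest.raises(ValidationError, match="bijection"):
            inject_defects(clean_session, DefectLedger(station_permutation=(0, 0, 1)))


class TestLedgerYaml:
    def test_roundtrip(self):
        ledger = DefectLedger(
            slice_gap_events=[GapEvent(1, "overlap", 2)],
            offset_events=[OffsetEvent(0, 3, -2)],
            swap_events=[SwapEvent("local", region=((0, 0, 70), (20, 20, 10)))],
            station_permutation=(1, 0, 2),
        )
        again = DefectLedger.from_yaml(ledger.to_yaml())
        assert again.slice_gap_events == ledger.slice_gap_events
        assert again.offset_events == ledger.offset_events
        assert again.swap_events[0].scope == "local"
        assert again.station_permutation == (1, 0, 2)

    def test_empty_is_empty(self):
        assert DefectLedger().is_empty()
        assert not DefectLedger(swap_events=[SwapEvent("global")]).is_empty()
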