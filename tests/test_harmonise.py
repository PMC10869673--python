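import nibabel as nib
import numpy as np
import pytest
from skimage.filters import threshold_otsu

from wbcure.core import ValidationError
from wbcure.harmonise import (
    TargetGrid,
    define_target_grid,
    export_nifti,
    harmonise_session,
    resample_to_grid,
)
from wbcure.phantom import PhantomSpec, build_phantom


class TestDefineTargetGrid:
    def test_explicit_grid_verbatim(self, clean_session):
        explicit = TargetGrid(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(10, 10, 10))
        assert define_target_grid(clean_session, explicit=explicit) is explicit

    def test_dwi_donor_spacing(self, clean_session, default_spec):
        grid = define_target_grid(clean_session)
        p = default_spec.in_plane_spacing_mm
        assert grid.spacing == (p, p, default_spec.slice_spacing_mm)

    def test_no_donor_rejected(self, clean_session):
        from wbcure.core import ImagingSession

        session = ImagingSession(
            subject_id="x",
            session_id="x_s1",
            series={"fat": clean_session.series["fat"].copy()},
        )
        with pytest.raises(ValidationError):
            define_target_grid(session)

    def test_union_extent(self, clean_session):
        """Grid extent covers the union of all series' bounding boxes."""
        session = clean_session.copy()
        shifted = session.series["fat"]
        shifted.origin = shifted.origin + np.array([24.0, 0.0, 0.0])
        grid = define_target_grid(session)
        # oracle: interval union per axis over all stacks
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        from wbcure.harmonise import _stack_bounds

        for stack in session.series.values():
            a, b = _stack_bounds(stack)
            lo = np.minimum(lo, a)
            hi = np.maximum(hi, b)
        assert np.allclose(grid.origin, lo)
        for axis in range(3):
            top = grid.origin[axis] + (grid.shape[axis] - 1) * grid.spacing[axis]
            assert top >= hi[axis] - 1e-9
            assert top < hi[axis] + grid.spacing[axis]


class TestResampleToGrid:
    def test_identity_on_own_grid(self, clean_session):
        fat = clean_session.series["fat"]
        grid = TargetGrid(
            origin=tuple(fat.origin),
            spacing=(fat.pixel_spacing[1], fat.pixel_spacing[0], fat.nominal_slice_spacing),
            shape=(fat.shape[2], fat.shape[1], fat.shape[0]),
        )
        out = resample_to_grid(fat, grid)
        assert np.allclose(out.voxels, fat.voxels, atol=1e-9)
        assert not out.out_of_field_mask.any()

    def test_constant_field_preserved(self, clean_session):
        fat = clean_session.series["fat"].copy()
        fat.voxels = np.full_like(fat.voxels, 7.5)
        grid = define_target_grid(clean_session)
        out = resample_to_grid(fat, grid)
        inside = ~out.out_of_field_mask
        assert np.allclose(out.voxels[inside], 7.5)
        assert np.all(out.voxels[out.out_of_field_mask] == 0.0)

    def test_linear_field_exact(self, clean_session):
        # trilinear interpolation reproduces degree-1 polynomials exactly
        fat = clean_session.series["fat"].copy()
        nz, ny, nx = fat.shape
        k, i, j = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
        fat.voxels = 1.0 + 2.0 * k + 0.5 * i - 0.25 * j
        half = (fat.pixel_spacing[0] / 2, fat.nominal_slice_spacing / 2)
        grid = TargetGrid(
            origin=(
                fat.origin[0] + half[0],
                fat.origin[1] + half[0],
                fat.slice_positions[0] + half[1],
            ),
            spacing=(6.0, 6.0, 6.0),
            shape=(nx - 1, ny - 1, nz - 1),
        )
        out = resample_to_grid(fat, grid)
        kk, ii, jj = np.meshgrid(
            np.arange(nz - 1) + 0.5,
            np.arange(ny - 1) + 0.5,
            np.arange(nx - 1) + 0.5,
            indexing="ij",
        )
        expected = 1.0 + 2.0 * kk + 0.5 * ii - 0.25 * jj
        assert np.allclose(out.voxels, expected, atol=1e-9)

    def test_nearest_mode(self, clean_session):
        fat = clean_session.series["fat"]
        grid = TargetGrid(
            origin=tuple(fat.origin),
            spacing=(fat.pixel_spacing[1], fat.pixel_spacing[0], fat.nominal_slice_spacing),
            shape=(fat.shape[2], fat.shape[1], fat.shape[0]),
        )
        out = resample_to_grid(fat, grid, interp="nearest")
        assert np.allclose(out.voxels, fat.voxels)

    def test_disjoint_grid_rejected(self, clean_session):
        grid = TargetGrid(origin=(5000, 5000, 5000), spacing=(2, 2, 2), shape=(4, 4, 4))
        with pytest.raises(ValidationError):
            resample_to_grid(clean_session.series["fat"], grid)

    def test_nonuniform_source_rejected(self, clean_session):
        fat = clean_session.series["fat"].copy()
        fat.slice_positions = fat.slice_positions.copy()
        fat.slice_positions[3] += 2.0
        grid = define_target_grid(clean_session)
        with pytest.raises(ValidationError):
            resample_to_grid(fat, grid)

    def test_coronal_to_transverse_dice(self):
        spec = PhantomSpec(seed=5)
        coronal = build_phantom(spec, protocol="coronal_dixon")
        transverse = build_phantom(spec, protocol="transverse_dixon")
        grid = define_target_grid(coronal)

        def mask(session):
            f = resample_to_grid(session.series["fat"], grid).voxels
            w = resample_to_grid(session.series["water"], grid).voxels
            c = f + w
            return c > threshold_otsu(c)

        mc, mt = mask(coronal), mask(transverse)
        dice = 2 * (mc & mt).sum() / (mc.sum() + mt.sum())
        assert dice >= 0.98


class TestExportNifti:
    def test_roundtrip_affine_and_voxels(self, clean_session, tmp_path):
        fat = clean_session.series["fat"]
        path = tmp_path / "fat.nii.gz"
        export_nifti(fat, path)
        img = nib.load(path)
        # RAS+ affine: x/y negated LPS, z kept
        assert np.allclose(img.affine[:3, 3], [-fat.origin[0], -fat.origin[1], fat.origin[2]], atol=1e-5)
        assert np.allclose(np.abs(np.diag(img.affine)[:3]), [6, 6, 6], atol=1e-5)
        data = np.asarray(img.dataobj).transpose(2, 1, 0)
        assert np.allclose(data, fat.voxels, atol=1e-2)

    def test_mask_sidecar(self, clean_session, tmp_path):
        fat = clean_session.series["fat"]
        mask = np.zeros(fat.shape, dtype=bool)
        mask[3] = True
        export_nifti(fat, tmp_path / "fat.nii.gz", missing_mask=mask)
        mimg = nib.load(tmp_path / "fat_mask.nii.gz")
        got = np.asarray(mimg.dataobj).transpose(2, 1, 0).astype(bool)
        assert np.array_equal(got, mask)

    def test_nonuniform_rejected(self, clean_session, tmp_path):
        fat = clean_session.series["fat"].copy()
        fat.slice_positions = fat.slice_positions.copy()
        fat.slice_positions[5] += 3.0
        with pytest.raises(ValidationError):
            export_nifti(fat, tmp_path / "x.nii.gz")

    def test_voxel_centre_world_roundtrip(self, rng):
        """LPS->RAS affine maps voxel indices to the stack's world coords."""
        from wbcure.harmonise import _lps_affine
        from wbcure.core import SliceStack

        for _ in range(20):
            origin = rng.uniform(-100, 100, 3)
            sp = rng.uniform(0.5, 5.0, 2)
            dz = float(rng.uniform(0.5, 8.0))
            stack = SliceStack(
                voxels=np.zeros((4, 5, 6)),
                slice_positions=np.arange(4) * dz,
                orientation=[[1, 0, 0], [0, 1, 0]],
                origin=origin,
                pixel_spacing=(float(sp[0]), float(sp[1])),
                nominal_slice_spacing=dz,
                contrast_label="fat",
            )
            aff = _lps_affine(stack)
            j, i, k = 2, 3, 1  # col, row, slice
            world = aff @ np.array([j, i, k, 1.0])
            expected = stack.world_coords(k)[i, j]
            assert np.allclose(world[:3], expected, atol=1e-9)


def test_harmonised_session_shares_grid(clean_session):
    harmonised, grid = harmonise_session(clean_session)
    first = harmonised.series["fat"]
    for stack in harmonised.series.values():
        assert np.array_equal(stack.slice_positions, first.slice_positions)
        assert np.array_equal(stack.origin, first.origin)
        assert stack.pixel_spacing == first.pixel_spacing
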