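"""Containers, resampling, rigid transforms, morphology, components, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ztebone.core import (BinaryMask, GeometryError, Grid, ImageVolume,
                          RigidTransform, dice, largest_component,
                          mean_abs_surface_distance, morphology,
                          precision_recall, register_rigid,
                          remove_small_components, resample, resample_mask)


def make_volume(arr, spacing=(1.0, 1.0, 1.0), origin=None, modality="DERIVED"):
    arr = np.asarray(arr, dtype=np.float32)
    if origin is None:
        origin = tuple(-(np.asarray(arr.shape) - 1) * np.asarray(spacing) / 2)
    return ImageVolume(arr, Grid(arr.shape, spacing, origin), modality)


def make_mask(arr, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(arr, dtype=bool)
    origin = tuple(-(np.asarray(arr.shape) - 1) * np.asarray(spacing) / 2)
    return BinaryMask(arr, Grid(arr.shape, spacing, origin))


# --------------------------------------------------------------------------- #
# grids and containers
# --------------------------------------------------------------------------- #

class TestContainers:
    def test_spacing_must_be_positive(self):
        with pytest.raises(GeometryError):
            Grid((4, 4, 4), (1.0, 0.0, 1.0))

    def test_direction_must_be_orthonormal(self):
        with pytest.raises(GeometryError):
            Grid((4, 4, 4), (1, 1, 1), direction=np.eye(3) * 2)

    def test_voxels_must_be_finite(self):
        arr = np.zeros((3, 3, 3), dtype=np.float32)
        arr[1, 1, 1] = np.nan
        with pytest.raises(ValueError):
            make_volume(arr)

    def test_mask_shape_must_match_grid(self):
        with pytest.raises(GeometryError):
            BinaryMask(np.zeros((3, 3, 3), bool), Grid((4, 4, 4), (1, 1, 1)))


# --------------------------------------------------------------------------- #
# rigid transforms
# --------------------------------------------------------------------------- #

class TestRigidTransform:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=6))
    def test_inverse_composes_to_identity(self, params):
        t = RigidTransform(rotation_deg=tuple(params[:3]),
                           translation_mm=tuple(params[3:]),
                           center_mm=(5.0, -3.0, 2.0))
        comp = t.compose(t.inverse())
        pts = np.array([[0, 0, 0], [80, 90, 75], [-80, -90, -75], [40, -40, 10]],
                       dtype=float)
        assert np.allclose(comp.apply(pts), pts, atol=1e-6)

    def test_apply_matches_matrix_form(self):
        t = RigidTransform(rotation_deg=(10, -5, 3), translation_mm=(1, 2, 3),
                           center_mm=(4, 5, 6))
        r, b = t.matrix_offset()
        p = np.array([7.0, -2.0, 1.0])
        assert np.allclose(t.apply(p), r @ p + b)

    def test_compose_order(self):
        a = RigidTransform(translation_mm=(1, 0, 0))
        b = RigidTransform(rotation_deg=(0, 0, 90))
        p = np.array([1.0, 0.0, 0.0])
        # a(b(p)): rotate then translate
        assert np.allclose(a.compose(b).apply(p), b.apply(p) + [1, 0, 0], atol=1e-9)


# --------------------------------------------------------------------------- #
# resampling
# --------------------------------------------------------------------------- #

def brute_force_resample_nearest(source, target_grid, transform, fill=0.0):
    """Independent oracle: map every output index through the transform and
    pick the nearest source voxel."""
    out = np.full(target_grid.shape, fill, dtype=np.float32)
    sg = source.grid
    inv_dir = np.linalg.inv(sg.direction)
    for idx in np.ndindex(*target_grid.shape):
        p = target_grid.index_to_physical(idx)
        q = transform.apply(p)
        cont = (inv_dir @ (q - np.asarray(sg.origin))) / np.asarray(sg.spacing)
        j = np.rint(cont).astype(int)
        if np.all(j >= 0) and np.all(j < sg.shape):
            out[idx] = source.voxels[tuple(j)]
    return out


class TestResample:
    def test_identity_is_exact(self):
        rng = np.random.default_rng(0)
        v = make_volume(rng.normal(size=(6, 7, 8)))
        out = resample(v, v.grid, interpolation="linear")
        assert np.allclose(out.voxels, v.voxels, atol=1e-5)

    def test_constant_field_invariant(self):
        v = make_volume(np.full((4, 4, 4), 3.25))
        t = RigidTransform(rotation_deg=(3, -2, 5), translation_mm=(0.3, -0.2, 0.1))
        out = resample(v, v.grid, t, interpolation="linear", fill=3.25)
        assert np.allclose(out.voxels, 3.25, atol=1e-5)

    def test_translated_bright_voxel_matches_brute_force(self):
        arr = np.zeros((20, 20, 20), dtype=np.float32)
        arr[10, 10, 10] = 100.0
        v = make_volume(arr)
        t = RigidTransform(translation_mm=(1.0, 0.0, 0.0))  # exactly one voxel
        with pytest.warns(UserWarning):
            out = resample(v, v.grid, t, interpolation="nearest")
        oracle = brute_force_resample_nearest(v, v.grid, t)
        assert np.array_equal(out.voxels, oracle)
        # output(x) = source(x + 1 voxel): the bright voxel shifts to index 9
        assert out.voxels[9, 10, 10] == 100.0

    def test_composition_equivariance_on_smooth_field(self):
        xs = np.linspace(-1, 1, 48)
        x, y, z = np.meshgrid(xs, xs, xs, indexing="ij")
        smooth = np.exp(-(x ** 2 + y ** 2 + z ** 2) * 0.25).astype(np.float32)
        v = make_volume(smooth, spacing=(2, 2, 2))
        t1 = RigidTransform(rotation_deg=(2, 0, -1), translation_mm=(0.5, -0.3, 0.2))
        t2 = RigidTransform(rotation_deg=(-1, 1, 0), translation_mm=(-0.2, 0.4, 0.1))
        twice = resample(resample(v, v.grid, t1), v.grid, t2)
        once = resample(v, v.grid, t1.compose(t2))
        interior = np.s_[6:-6, 6:-6, 6:-6]
        rng_ = float(np.ptp(smooth))
        assert np.max(np.abs(twice.voxels - once.voxels)[interior]) <= 1e-3 * rng_

    def test_mask_transfer_is_binary(self):
        m = make_mask(np.zeros((6, 6, 6), bool))
        m.voxels[2:4, 2:4, 2:4] = True
        target = Grid((12, 12, 12), (0.5, 0.5, 0.5),
                      origin=tuple(np.asarray(m.grid.origin) - 0.25))
        out = resample_mask(m, target)
        assert out.voxels.dtype == bool and out.count > 0


class TestRegistration:
    def test_self_registration_recovers_identity(self, tiny_set):
        t = register_rigid(moving=tiny_set.bb, fixed=tiny_set.bb, seed=3)
        assert np.all(np.abs(t.translation_mm) < 0.1)
        assert np.all(np.abs(t.rotation_deg) < 0.1)

    def test_noisy_self_registration(self):
        import dataclasses
        from conftest import tiny_spec
        from ztebone import generate_phantom
        a = generate_phantom(tiny_spec(noise_sigma=50.0, seed=11))
        b = generate_phantom(tiny_spec(noise_sigma=50.0, seed=12))
        t = register_rigid(moving=a.bb, fixed=b.bb, seed=5)
        assert np.all(np.abs(t.translation_mm) < 0.5)
        assert np.all(np.abs(t.rotation_deg) < 0.5)


# --------------------------------------------------------------------------- #
# metrics
# --------------------------------------------------------------------------- #

class TestDice:
    def test_identity_and_disjoint(self):
        a = make_mask(np.zeros((4, 4, 4), bool)); a.voxels[:2] = True
        b = make_mask(np.zeros((4, 4, 4), bool)); b.voxels[2:] = True
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0

    def test_hand_counted_overlap(self):
        # 2x2x1 blocks overlapping in 2 voxels: 2*2/(4+4) = 0.5
        a = make_mask(np.zeros((4, 4, 1), bool)); a.voxels[0:2, 0:2, 0] = True
        b = make_mask(np.zeros((4, 4, 1), bool)); b.voxels[1:3, 0:2, 0] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        a = make_mask(np.zeros((3, 3, 3), bool))
        assert dice(a, a) == 1.0

    def test_grid_mismatch_raises(self):
        a = make_mask(np.ones((3, 3, 3), bool))
        b = make_mask(np.ones((3, 3, 3), bool), spacing=(2, 1, 1))
        with pytest.raises(GeometryError):
            dice(a, b)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 27 - 1), st.integers(0, 2 ** 27 - 1))
    def test_symmetric_bounded_and_one_iff_identical(self, s1, s2):
        rng1, rng2 = np.random.default_rng(s1), np.random.default_rng(s2)
        a = make_mask(rng1.random((5, 5, 5)) > 0.5)
        b = make_mask(rng2.random((5, 5, 5)) > 0.5)
        d = dice(a, b)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0
        assert (d == 1.0) == np.array_equal(a.voxels, b.voxels)


class TestSurfaceDistance:
    def test_identical_masks_zero(self):
        m = make_mask(np.zeros((8, 8, 8), bool)); m.voxels[2:6, 2:6, 2:6] = True
        assert mean_abs_surface_distance(m, m) == 0.0

    def test_dilated_mask_within_one_voxel(self):
        from scipy import ndimage
        m = make_mask(np.zeros((12, 12, 12), bool), spacing=(0.5, 0.5, 1.2))
        m.voxels[4:8, 4:8, 4:8] = True
        d = BinaryMask(ndimage.binary_dilation(m.voxels), m.grid)
        assert mean_abs_surface_distance(d, m) <= max(m.grid.spacing)


# --------------------------------------------------------------------------- #
# connected components
# --------------------------------------------------------------------------- #

def flood_fill_components(mask, connectivity=26):
    """Independent BFS flood-fill oracle returning component voxel sets."""
    if connectivity == 6:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp, stack = [], [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for o in offs:
                n = tuple(np.add(v, o))
                if all(0 <= n[d] < mask.shape[d] for d in range(3)) \
                        and mask[n] and not seen[n]:
                    seen[n] = True
                    stack.append(n)
        comps.append(set(comp))
    return comps


class TestComponents:
    def test_single_blob_unchanged(self):
        m = make_mask(np.zeros((6, 6, 6), bool)); m.voxels[1:4, 1:4, 1:4] = True
        out = largest_component(m)
        assert np.array_equal(out.voxels, m.voxels)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(7)
        arr = rng.random((15, 15, 15)) > 0.75
        arr[0] = arr[-1] = False
        m = make_mask(arr)
        out = largest_component(m, connectivity)
        comps = flood_fill_components(arr, connectivity)
        biggest = max(len(c) for c in comps)
        # out must be exactly one of the maximal components
        out_set = set(zip(*np.nonzero(out.voxels)))
        assert len(out_set) == biggest
        assert out_set in [c for c in comps if len(c) == biggest]

    def test_two_blobs_keeps_larger(self):
        arr = np.zeros((10, 10, 10), bool)
        arr[0:2, 0:5, 0] = True          # 10 voxels
        arr[7:8, 7:10, 7] = True         # 3 voxels
        out = largest_component(make_mask(arr))
        assert out.count == 10 and out.voxels[0, 0, 0]

    def test_tie_broken_by_lowest_linear_index(self):
        arr = np.zeros((10, 10, 10), bool)
        arr[8, 0:5, 0] = True            # 5 voxels, later in raster order
        arr[1, 0:5, 0] = True            # 5 voxels, earlier in raster order
        out = largest_component(make_mask(arr))
        assert out.voxels[1, 0, 0] and not out.voxels[8, 0, 0]

    def test_empty_mask_warns(self):
        m = make_mask(np.zeros((4, 4, 4), bool))
        with pytest.warns(UserWarning):
            out = largest_component(m)
        assert out.count == 0

    def test_remove_small_components(self):
        arr = np.zeros((10, 10, 10), bool)
        arr[0:3, 0:3, 0:3] = True        # 27 voxels
        arr[8, 8, 8] = True              # 1 voxel
        out = remove_small_components(make_mask(arr), min_voxels=5)
        assert out.count == 27


# --------------------------------------------------------------------------- #
# morphology
# --------------------------------------------------------------------------- #

def ball_offsets(radius_mm, spacing):
    r = [int(np.floor(radius_mm / s)) for s in spacing]
    offs = []
    for i in range(-r[0], r[0] + 1):
        for j in range(-r[1], r[1] + 1):
            for k in range(-r[2], r[2] + 1):
                if (i * spacing[0]) ** 2 + (j * spacing[1]) ** 2 \
                        + (k * spacing[2]) ** 2 <= radius_mm ** 2:
                    offs.append((i, j, k))
    return offs


def brute_force_morph(mask, op, radius_mm, spacing):
    """Independent structuring-element sweep with a physical-space ball."""
    offs = ball_offsets(radius_mm, spacing)
    out = np.zeros_like(mask)
    idxs = np.array(offs)
    if op == "dilate":
        for v in zip(*np.nonzero(mask)):
            for o in offs:
                n = tuple(np.add(v, o))
                if all(0 <= n[d] < mask.shape[d] for d in range(3)):
                    out[n] = True
        return out
    # erode: keep v iff every in-bounds ball neighbour is foreground and no
    # background voxel of the array lies inside the ball
    for v in zip(*np.nonzero(mask)):
        keep = True
        for o in offs:
            n = tuple(np.add(v, o))
            if all(0 <= n[d] < mask.shape[d] for d in range(3)) and not mask[n]:
                keep = False
                break
        out[v] = keep
    return out


class TestMorphology:
    def test_radius_zero_is_identity(self):
        m = make_mask(np.zeros((6, 6, 6), bool)); m.voxels[2:4, 2:4, 2:4] = True
        for op in ("erode", "dilate"):
            assert np.array_equal(morphology(m, op, 0.0).voxels, m.voxels)

    def test_subvoxel_radius_warns_and_is_identity(self):
        m = make_mask(np.zeros((6, 6, 6), bool), spacing=(2, 2, 2))
        m.voxels[2:4, 2:4, 2:4] = True
        with pytest.warns(UserWarning):
            out = morphology(m, "erode", 0.5)
        assert np.array_equal(out.voxels, m.voxels)

    def test_cube_erosion_analytic(self):
        # 10x10x10 mm cube on a 1 mm grid, erode 2 mm -> 6x6x6 mm cube
        arr = np.zeros((14, 14, 14), bool)
        arr[2:12, 2:12, 2:12] = True
        out = morphology(make_mask(arr), "erode", 2.0)
        assert out.count == 6 ** 3
        assert out.voxels[4:10, 4:10, 4:10].all()

    @pytest.mark.parametrize("op,radius,spacing", [
        ("erode", 1.5, (1.0, 1.0, 1.0)),
        ("dilate", 1.5, (1.0, 1.0, 1.0)),
        ("erode", 2.0, (0.5, 0.5, 1.2)),
        ("dilate", 2.0, (0.5, 0.5, 1.2)),
    ])
    def test_matches_structuring_element_sweep(self, op, radius, spacing):
        rng = np.random.default_rng(11)
        arr = rng.random((12, 12, 12)) > 0.6
        pad = 4
        arr[:pad] = arr[-pad:] = False
        arr[:, :pad] = arr[:, -pad:] = False
        arr[:, :, :pad] = arr[:, :, -pad:] = False
        m = make_mask(arr, spacing=spacing)
        out = morphology(m, op, radius)
        oracle = brute_force_morph(arr, op, radius, spacing)
        assert np.array_equal(out.voxels, oracle)

    def test_fill_holes_seals_hollow_sphere(self):
        xs = np.arange(-10, 11)
        x, y, z = np.meshgrid(xs, xs, xs, indexing="ij")
        r = np.sqrt(x ** 2 + y ** 2 + z ** 2)
        shell = (r >= 5) & (r <= 8)
        out = morphology(make_mask(shell), "fill_holes", 0.0)
        assert out.voxels[10, 10, 10]          # centre filled
        assert not out.voxels[0, 0, 0]          # outside untouched
        assert out.count == ((r <= 8).sum())

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 27 - 1), st.floats(1.0, 3.0))
    def test_erode_shrinks_dilate_grows(self, seed, radius):
        rng = np.random.default_rng(seed)
        arr = rng.random((10, 10, 10)) > 0.5
        m = make_mask(arr)
        er = morphology(m, "erode", radius)
        di = morphology(m, "dilate", radius)
        assert not np.any(er.voxels & ~m.voxels)
        assert np.all(di.voxels[m.voxels])

    def test_close_covers_original_on_border_free_mask(self):
        arr = np.zeros((12, 12, 12), bool)
        arr[4:8, 4:8, 4:8] = True
        arr[5, 5, 9] = True
        m = make_mask(arr)
        cl = morphology(m, "close", 1.5)
        assert np.all(cl.voxels[m.voxels])
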