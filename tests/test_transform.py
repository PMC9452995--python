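"""Patch frame, direction ordering/selection, and the 1-D wavelet."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbdw import (
    DEFAULT_DIRECTIONS,
    DirectionSet,
    DirectionalPatchTransform,
    PatchGeometry,
    PhantomSpec,
    assemble_patches,
    direction_order,
    extract_patches,
    inverse_transform_1d,
    make_directional_phantom,
    scatter_patches,
    select_direction,
    transform_1d,
    wavelet_matrix,
)


class TestPatchGeometry:
    def test_counts(self):
        g = PatchGeometry((64, 64), patch_size=8, stride=4)
        assert g.n_patches == 256
        assert g.overlap_count == 4
        assert len(g.patch_origins) == 256

    def test_non_overlapping_partition(self, rng):
        g = PatchGeometry((64, 64), patch_size=8, stride=8)
        X = rng.normal(size=(64, 64))
        patches = extract_patches(X, g)
        assert patches.shape == (64, 64)
        assert g.overlap_count == 1
        np.testing.assert_allclose(assemble_patches(patches, g), X, atol=1e-12)

    def test_constant_image_constant_patches(self):
        g = PatchGeometry((32, 32), patch_size=8, stride=4)
        patches = extract_patches(np.full((32, 32), 3.5), g)
        assert np.ptp(patches) == 0.0

    @pytest.mark.parametrize(
        "shape,b,s", [((64, 64), 8, 3), ((30, 30), 8, 4), ((64, 64), 7, 4)]
    )
    def test_invalid_geometry_rejected(self, shape, b, s):
        with pytest.raises(ValueError):
            PatchGeometry(shape, patch_size=b, stride=s)


class TestExtractAssemble:
    def test_roundtrip_overlapping(self, rng):
        g = PatchGeometry((32, 32), patch_size=8, stride=4)
        X = rng.normal(size=(32, 32))
        np.testing.assert_allclose(
            assemble_patches(extract_patches(X, g), g), X, atol=1e-12
        )

    def test_overlap_identity_on_ones(self):
        # sum_i Qi^T Qi (all-ones) == p everywhere, exactly
        g = PatchGeometry((64, 64), patch_size=8, stride=4)
        ones = np.ones((64, 64))
        cover = scatter_patches(extract_patches(ones, g), g)
        np.testing.assert_array_equal(cover, np.full((64, 64), 4.0))

    def test_adjoint_identity(self, rng):
        g = PatchGeometry((32, 32), patch_size=8, stride=4)
        X = rng.normal(size=(32, 32))
        Y = rng.normal(size=(g.n_patches, 64))
        lhs = np.vdot(extract_patches(X, g), Y)
        rhs = np.vdot(X, scatter_patches(Y, g))
        assert abs(lhs - rhs) < 1e-10 * abs(rhs)


class TestDirectionOrder:
    def test_horizontal_is_row_major(self):
        np.testing.assert_array_equal(direction_order((0, 1), 2), [0, 1, 2, 3])

    def test_vertical_is_column_major(self):
        np.testing.assert_array_equal(direction_order((1, 0), 2), [0, 2, 1, 3])

    @pytest.mark.parametrize("direction", DEFAULT_DIRECTIONS)
    def test_every_candidate_is_permutation(self, direction):
        perm = direction_order(direction, 8)
        assert sorted(perm.tolist()) == list(range(64))

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            DirectionSet(candidates=((0, 0),))

    def test_duplicate_directions_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            DirectionSet(candidates=((0, 1), (0, 1)))


class TestTransform1D:
    @pytest.mark.parametrize("wavelet", ["haar", "db4"])
    def test_orthonormal(self, rng, wavelet):
        v = rng.normal(size=64)
        w = transform_1d(v, wavelet)
        assert np.linalg.norm(w) == pytest.approx(np.linalg.norm(v), rel=1e-10)
        np.testing.assert_allclose(inverse_transform_1d(w, wavelet), v, atol=1e-12)

    @pytest.mark.parametrize("wavelet", ["haar", "db4"])
    def test_constant_energy_in_approximation_band(self, wavelet):
        # a constant vector has zero detail coefficients; all energy sits in
        # the coarsest approximation band
        W = wavelet_matrix(64, wavelet)
        w = transform_1d(np.ones(64), wavelet)
        n_approx = 1 if wavelet == "haar" else 8  # 2-adic depth vs db4 level cap
        assert np.linalg.norm(w[n_approx:]) < 1e-10
        assert np.linalg.norm(w) == pytest.approx(8.0, rel=1e-10)
        assert W.shape == (64, 64)

    def test_wrong_length_rejected(self):
        with pytest.raises(Exception):
            transform_1d(np.ones((8, 8)))


def _brute_force_select(patch, dirs, E, wavelet="db4"):
    """Independent exhaustive re-implementation of direction scoring."""
    v = np.abs(patch).reshape(-1)
    b = patch.shape[0]
    best = None
    for c, d in enumerate(dirs.candidates):
        perm = direction_order(d, b)
        w = transform_1d(v[perm], wavelet)
        # energy outside the E largest magnitudes, smallest terms first
        resid = float(np.sort(w * w)[: len(w) - E].sum())
        if best is None or resid < best[1]:
            best = (c, resid)
    return best


class TestSelectDirection:
    def test_constant_patch_ties_to_first(self):
        idx, score = select_direction(np.full((8, 8), 2.0), DirectionSet(), E=16)
        assert idx == 0
        assert score == pytest.approx(0.0, abs=1e-20)

    def test_keep_everything_zero_score(self, rng):
        patch = rng.normal(size=(8, 8))
        idx, score = select_direction(patch, DirectionSet(), E=64)
        assert idx == 0
        assert score == pytest.approx(0.0, abs=1e-20)

    def test_matches_brute_force_on_random_patches(self, rng):
        dirs = DirectionSet()
        for _ in range(50):
            patch = rng.normal(size=(8, 8))
            assert select_direction(patch, dirs, E=16) == pytest.approx(
                _brute_force_select(patch, dirs, 16)
            )

    def test_stripe_patch_prefers_aligned_direction(self):
        dirs = DirectionSet()
        # varies only across rows -> traversal along rows (0,1) groups equal
        # pixels into constant runs, minimal residual
        patch = np.outer(np.arange(8, dtype=float) ** 2, np.ones(8))
        idx, score = select_direction(patch, dirs, E=8)
        assert (idx, score) == pytest.approx(_brute_force_select(patch, dirs, 8))
        scores = []
        for c, d in enumerate(dirs.candidates):
            perm = direction_order(d, 8)
            w = transform_1d(patch.reshape(-1)[perm])
            scores.append(float(np.sort(w * w)[:-8].sum()))
        assert score <= min(scores) + 1e-12

    def test_argmin_never_beaten_by_any_fixed_direction(self, rng):
        dirs = DirectionSet()
        for _ in range(10):
            patch = rng.normal(size=(8, 8))
            _, score = select_direction(patch, dirs, E=16)
            for c, d in enumerate(dirs.candidates):
                perm = direction_order(d, 8)
                w = transform_1d(np.abs(patch).reshape(-1)[perm])
                assert score <= np.sort(w * w)[:-16].sum() + 1e-12

    def test_bad_retain_count_rejected(self):
        with pytest.raises(ValueError, match="E"):
            select_direction(np.zeros((8, 8)), DirectionSet(), E=0)


class TestDirectionalPatchTransform:
    @pytest.mark.parametrize("wavelet", ["haar", "db4"])
    def test_tight_frame_roundtrip(self, rng, wavelet):
        T = DirectionalPatchTransform((32, 32), wavelet=wavelet)
        X = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        a = T.select_directions(X)
        c = T.analyze(X, a)
        assert np.linalg.norm(T.synthesize(c) - X) <= 1e-10 * np.linalg.norm(X)

    def test_frame_energy_identity(self, rng):
        # ||B X||^2 = p ||X||^2 (each per-patch operator is an isometry)
        T = DirectionalPatchTransform((32, 32))
        X = rng.normal(size=(32, 32))
        c = T.analyze(X, T.select_directions(X))
        assert np.sum(np.abs(c.coeffs) ** 2) == pytest.approx(
            4 * np.sum(X**2), rel=1e-10
        )

    def test_zero_image_zero_coefficients(self):
        T = DirectionalPatchTransform((32, 32))
        X = np.zeros((32, 32))
        c = T.analyze(X, T.select_directions(X))
        assert not np.any(c.coeffs)

    def test_batch_selection_matches_single_patch_op(self, rng):
        T = DirectionalPatchTransform((32, 32))
        X = rng.normal(size=(32, 32))
        a = T.select_directions(X)
        patches = extract_patches(X, T.geometry)
        for i in [0, 17, 63]:
            idx, score = select_direction(
                patches[i].reshape(8, 8), T.directions, T.retain_count
            )
            assert a.selected[i] == idx
            assert a.residuals[i] == pytest.approx(score, abs=1e-9)

    def test_selection_beats_fixed_horizontal_on_aligned_stripes(self):
        # the point of per-patch directions: better E-term approximation than
        # an axis-aligned ordering on oblique structure
        spec = PhantomSpec(size=32, kind="directional_stripes",
                           stripe_angles=[45.0], n_features=4)
        X = make_directional_phantom(spec)
        T = DirectionalPatchTransform((32, 32))
        a = T.select_directions(X)
        fixed = type(a)(selected=np.zeros(len(a), dtype=int),
                        residuals=np.zeros(len(a)))

        def e_term_error(assignment):
            c = T.analyze(X, assignment)
            kept = np.zeros_like(c.coeffs)
            for i, row in enumerate(c.coeffs):
                order = np.argsort(-np.abs(row), kind="stable")
                kept[i, order[: T.retain_count]] = row[order[: T.retain_count]]
            trunc = type(c)(coeffs=kept, geometry=c.geometry, directions=assignment)
            return np.linalg.norm(T.synthesize(trunc) - X)

        assert e_term_error(a) <= e_term_error(fixed)

    def test_direction_map_export(self, rng, tmp_path):
        import csv

        from pbdw.transform import export_direction_map

        T = DirectionalPatchTransform((32, 32))
        a = T.select_directions(rng.normal(size=(32, 32)))
        p = tmp_path / "dirs.csv"
        export_direction_map(a, T.geometry, p)
        with open(p) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == T.geometry.n_patches
        assert int(rows[5]["direction_index"]) == a.selected[5]
        assert float(rows[5]["residual"]) == pytest.approx(a.residuals[5])

    def test_assignment_length_checked(self, rng):
        T = DirectionalPatchTransform((32, 32))
        X = rng.normal(size=(32, 32))
        a = DirectionalPatchTransform((64, 64)).select_directions(
            rng.normal(size=(64, 64))
        )
        with pytest.raises(ValueError, match="length"):
            T.analyze(X, a)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_tight_frame_property_random_images(seed):
    """Frame identity holds for arbitrary random images (property test)."""
    X = np.random.default_rng(seed).normal(size=(16, 16))
    T = DirectionalPatchTransform((16, 16), patch_size=4, stride=2, wavelet="haar")
    c = T.analyze(X, T.select_directions(X))
    assert np.linalg.norm(T.synthesize(c) - X) <= 1e-10 * (np.linalg.norm(X) + 1e-30)
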