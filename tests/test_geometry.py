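"""Superimposition: centroid size, Procrustes fits, GPA, shape distance."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from paleoshape import (
    LandmarkConfiguration,
    centroid_size,
    gpa,
    ordinary_procrustes,
    procrustes_distance,
)
from paleoshape.geometry import (
    DegenerateConfigurationError,
    GeneralizedProcrustes,
    MissingLandmarkError,
    _center_and_scale,
)

from conftest import random_similarity

CUBE = np.array([[x, y, z] for x in (-0.5, 0.5) for y in (-0.5, 0.5) for z in (-0.5, 0.5)])


class TestCentroidSize:
    def test_cube_closed_form(self):
        assert centroid_size(CUBE) == pytest.approx(np.sqrt(6.0), abs=1e-12)

    @pytest.mark.parametrize("s", [0.1, 1.0, 7.3])
    def test_homogeneous_in_scale(self, s):
        assert centroid_size(CUBE * s) == pytest.approx(s * np.sqrt(6.0), rel=1e-12)

    def test_degenerate_point_is_zero(self):
        assert centroid_size(np.tile([1.0, 2.0, 3.0], (5, 1))) == 0.0

    def test_missing_landmarks_rejected(self):
        c = LandmarkConfiguration("x", np.vstack([CUBE, [np.nan] * 3]),
                                  missing=[False] * 8 + [True])
        with pytest.raises(MissingLandmarkError):
            centroid_size(c)


class TestOrdinaryProcrustes:
    def test_pure_rotation_gives_zero_distance(self, rng):
        a = rng.normal(size=(9, 3))
        r = Rotation.random(random_state=7).as_matrix()
        _, d = ordinary_procrustes(a, a @ r)
        assert d == pytest.approx(0.0, abs=1e-10)

    def test_mirror_of_chiral_config_has_positive_distance(self, rng):
        """Reflections are disallowed, so a mirrored chiral shape stays distant.

        An orthogonal (reflection-allowed) fit would recover it exactly.
        """
        a = rng.normal(size=(10, 3))
        b = a.copy()
        b[:, 0] = -b[:, 0]
        _, d = ordinary_procrustes(a, b)
        assert d > 0.05
        # reflection-allowed oracle: plain orthogonal Procrustes
        za, zb = _center_and_scale(a), _center_and_scale(b)
        u, _, vt = np.linalg.svd(zb.T @ za)
        d_orth = np.linalg.norm(za - zb @ (u @ vt))
        assert d_orth == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_rotation_search(self):
        """Planar quadrilaterals: distance equals a brute-force minimum over rotations."""
        a = np.array([[0.0, 0, 0], [2, 0, 0], [2, 1, 0], [0, 1.5, 0]])
        b = np.array([[0.1, 0, 0], [1.9, 0.3, 0], [2.2, 1.2, 0], [-0.2, 1.4, 0]])
        _, d = ordinary_procrustes(a, b)
        za, zb = _center_and_scale(a), _center_and_scale(b)

        def objective(rotvec):
            return np.linalg.norm(za - zb @ Rotation.from_rotvec(rotvec).as_matrix())

        best = np.inf
        g = np.linspace(-np.pi, np.pi, 7)
        for x in g:
            for y in g:
                for z in g:
                    res = minimize(objective, [x, y, z], method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12})
                    best = min(best, res.fun)
        assert d == pytest.approx(best, abs=1e-6)

    def test_too_few_or_degenerate_landmarks_rejected(self, rng):
        tri = rng.normal(size=(3, 3))
        with pytest.raises(DegenerateConfigurationError):
            ordinary_procrustes(tri, tri)
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateConfigurationError):
            ordinary_procrustes(line, line)


class TestGPA:
    def test_identical_shapes_under_similarity_transforms(self, rng):
        base = rng.normal(size=(12, 3)) * 10
        sample = np.stack([random_similarity(base, rng) for _ in range(6)])
        al = gpa(sample)
        arr = al.coords_array()
        assert np.allclose(arr - al.consensus, 0.0, atol=1e-8)
        assert np.allclose(arr[0], arr[1:], atol=1e-8)

    def test_unit_size_and_centered_output(self, rng):
        sample = np.stack([rng.normal(size=(10, 3)) * 5 for _ in range(4)])
        al = gpa(sample)
        for c in al.configs:
            assert np.abs(c.coords.mean(axis=0)).max() < 1e-9
            assert centroid_size(c.coords) == pytest.approx(1.0, abs=1e-9)
        cons = al.consensus
        assert centroid_size(cons) == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_specimen_permutation(self, rng):
        base = rng.normal(size=(15, 3)) * 10
        sample = np.stack([base + rng.normal(scale=0.5, size=base.shape) for _ in range(7)])
        c1 = gpa(sample).consensus
        c2 = gpa(sample[::-1]).consensus
        assert np.allclose(c1, c2, atol=1e-8)

    def test_invariant_under_input_similarity_transforms(self, rng):
        sample = [rng.normal(size=(10, 3)) for _ in range(5)]
        moved = [random_similarity(s, rng) for s in sample]
        c1 = gpa(np.stack(sample)).consensus
        c2 = gpa(np.stack(moved)).consensus
        assert np.allclose(c1, c2, atol=1e-8)

    def test_two_specimens_equidistant_from_consensus(self, rng):
        a, b = rng.normal(size=(2, 8, 3))
        al = gpa(np.stack([a, b]))
        d1 = procrustes_distance(al.configs[0].coords, al.consensus)
        d2 = procrustes_distance(al.configs[1].coords, al.consensus)
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_transformer_interface_roundtrip(self, rng):
        sample = np.stack([rng.normal(size=(9, 3)) for _ in range(5)])
        est = GeneralizedProcrustes().fit(sample)
        back = est.transform(sample)
        assert np.allclose(back, est.aligned_, atol=1e-8)
        params = est.get_params()
        assert params["max_iter"] == 100

    def test_missing_landmarks_rejected(self):
        c = LandmarkConfiguration("x", np.vstack([CUBE, [np.nan] * 3]),
                                  missing=[False] * 8 + [True])
        ok = LandmarkConfiguration("y", np.vstack([CUBE, [0.0, 0, 1]]))
        with pytest.raises(MissingLandmarkError):
            gpa([c, ok])


class TestProcrustesDistance:
    def test_identity_and_symmetry(self, rng):
        sample = np.stack([rng.normal(size=(7, 3)) for _ in range(2)])
        al = gpa(sample)
        a, b = al.configs
        assert procrustes_distance(a, a) == 0.0
        assert procrustes_distance(a, b) == procrustes_distance(b, a)

    def test_metric_triangle_inequality(self, rng):
        """Triangle inequality over 1000 random aligned triples."""
        sample = np.stack([rng.normal(size=(6, 3)) for _ in range(30)])
        al = gpa(sample)
        arr = al.coords_array()
        n = arr.shape[0]
        idx = np.random.default_rng(0).integers(0, n, size=(1000, 3))
        for i, j, k in idx:
            dij = procrustes_distance(arr[i], arr[j])
            djk = procrustes_distance(arr[j], arr[k])
            dik = procrustes_distance(arr[i], arr[k])
            assert dik <= dij + djk + 1e-12

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            procrustes_distance(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestSimilarityInvarianceProperties:
    """Property checks over generated scales and translations."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(scale=st.floats(0.01, 100.0), shift=st.floats(-1e3, 1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_centroid_size_homogeneity_and_translation_invariance(self, scale, shift):
        x = CUBE * scale + shift
        assert centroid_size(x) == pytest.approx(scale * np.sqrt(6.0), rel=1e-9)

    @given(scale=st.floats(0.1, 10.0), shift=st.floats(-100.0, 100.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_procrustes_fit_removes_scale_and_translation(self, scale, shift):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 3))
        b = a * scale + shift
        _, d = ordinary_procrustes(a, b)
        assert d == pytest.approx(0.0, abs=1e-9)
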