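"""Group operations, log-norm distance, symmetries, and ball stencils."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm, logm

import se2cc as s
from conftest import element_of, mat_of, random_cloud

angles = st.floats(-6.0, 6.0)
coords = st.floats(-10.0, 10.0)
elements = st.builds(s.GroupElement, coords, coords, angles)


class TestGroupOps:
    def test_identity_neutral(self):
        g = s.GroupElement(1.3, -0.4, 2.1)
        e = s.GroupElement.identity()
        for prod in (s.group_product(e, g), s.group_product(g, e)):
            assert np.allclose(prod.as_array(), g.as_array(), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(elements, elements)
    def test_product_matches_matrix_oracle(self, g1, g2):
        got = s.group_product(g1, g2)
        want = element_of(mat_of(g1) @ mat_of(g2))
        assert np.allclose(got.as_array(), want.as_array(), atol=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(elements, elements, elements)
    def test_associativity(self, a, b, c):
        lhs = s.group_product(s.group_product(a, b), c)
        rhs = s.group_product(a, s.group_product(b, c))
        assert np.allclose(lhs.as_array(), rhs.as_array(), atol=1e-8)

    def test_product_example(self):
        got = s.group_product(s.GroupElement(1, 0, math.pi / 2),
                              s.GroupElement(1, 0, 0))
        assert np.allclose(got.as_array(), [1, 1, math.pi / 2], atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(elements)
    def test_inverse(self, g):
        gi = s.group_inverse(g)
        assert np.allclose(mat_of(gi), np.linalg.inv(mat_of(g)), atol=1e-9)
        back = s.group_inverse(gi)
        assert np.allclose(back.as_array(), g.as_array(), atol=1e-9)
        prod = s.group_product(g, gi)
        assert np.allclose([prod.x, prod.y], 0, atol=1e-9)
        assert min(prod.theta, 2 * math.pi - prod.theta) < 1e-9

    def test_inverse_examples(self):
        assert s.group_inverse(s.GroupElement(0, 0, 0)) == s.GroupElement(0, 0, 0)
        gi = s.group_inverse(s.GroupElement(1, 0, 0))
        assert np.allclose(gi.as_array(), [-1, 0, 0], atol=1e-15)
        gi = s.group_inverse(s.GroupElement(1, 0, math.pi / 2))
        assert np.allclose(gi.as_array(), [0, 1, 3 * math.pi / 2], atol=1e-12)

    def test_theta_wrapped(self):
        assert 0 <= s.GroupElement(0, 0, -1.0).theta < 2 * math.pi
        assert 0 <= s.GroupElement(0, 0, 7.0).theta < 2 * math.pi


class TestLogExp:
    def test_log_examples(self):
        assert np.allclose(s.log_map(s.GroupElement(0, 0, 0)).as_array(), 0)
        c = s.log_map(s.GroupElement(1.5, -2.0, 0))
        assert np.allclose(c.as_array(), [1.5, -2.0, 0])
        c = s.log_map(s.GroupElement(1, 0, math.pi / 2))
        assert np.allclose(c.as_array(),
                           [math.pi / 4, -math.pi / 4, math.pi / 2],
                           atol=1e-12)

    def test_log_matches_matrix_logarithm(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = s.GroupElement(*rng.uniform(-3, 3, 2),
                               rng.uniform(-math.pi + 1e-2, math.pi - 1e-2))
            L = logm(mat_of(g))
            # generator decomposition: L = c1*A1 + c2*A2 + c3*A3 at identity
            c3 = L[1, 0]
            c1, c2 = L[0, 2], L[1, 2]
            got = s.log_map(g).as_array()
            assert np.allclose(got, [c1, c2, c3], atol=1e-8)

    def test_exp_log_roundtrip(self):
        rng = np.random.default_rng(7)
        thetas = rng.uniform(-math.pi + 1e-3, math.pi - 1e-3, 200)
        for th in thetas:
            g = s.GroupElement(rng.uniform(-5, 5), rng.uniform(-5, 5), th)
            back = s.exp_map(s.log_map(g))
            assert np.allclose(back.as_array(), g.as_array(), atol=1e-9)

    def test_exp_matches_matrix_exponential(self):
        c = s.AlgebraCoords(0.7, -0.3, 1.1)
        A = np.array([[0, -c.c3, c.c1], [c.c3, 0, c.c2], [0, 0, 0]])
        want = element_of(expm(A))
        got = s.exp_map(c)
        assert np.allclose(got.as_array(), want.as_array(), atol=1e-10)

    def test_theta_pi_uses_same_formula(self):
        g = s.GroupElement(1.0, 0.5, math.pi)
        c = s.log_map(g)
        assert abs(c.c3 - math.pi) < 1e-12
        # cot(pi/2) = 0: (c1, c2) = (pi/2) * (y, -x)
        assert np.allclose([c.c1, c.c2],
                           [math.pi / 2 * 0.5, -math.pi / 2 * 1.0], atol=1e-9)


class TestDistance:
    def test_zero_iff_equal(self, w111):
        g = s.GroupElement(1, 2, 0.5)
        assert s.approx_distance(g, g, w111) == 0.0
        h = s.GroupElement(1, 2, 0.6)
        assert s.approx_distance(g, h, w111) > 0

    def test_pure_translation(self, w111):
        d = s.approx_distance(s.GroupElement.identity(),
                              s.GroupElement(1, 0, 0), w111)
        assert abs(d - 1.0) < 1e-12

    def test_pure_rotation_weighted(self):
        w = s.MetricWeights(1, 1, 4)
        d = s.approx_distance(s.GroupElement.identity(),
                              s.GroupElement(0, 0, math.pi / 2), w)
        assert abs(d - math.pi) < 1e-12

    def test_symmetry(self, rng, w_aniso):
        pts = random_cloud(rng, 40)
        D = s.pairwise_distances(pts, w_aniso)
        assert np.allclose(D, D.T, atol=1e-12)
        assert np.allclose(np.diag(D), 0.0)

    def test_left_invariance(self, rng, w_aniso):
        for _ in range(1000):
            p, g, h = (s.GroupElement(*rng.uniform(-4, 4, 2),
                                      rng.uniform(0, 2 * math.pi))
                       for _ in range(3))
            d0 = s.approx_distance(g, h, w_aniso)
            d1 = s.approx_distance(s.group_product(p, g),
                                   s.group_product(p, h), w_aniso)
            assert abs(d0 - d1) < 1e-9

    def test_triangle_inequality_mostly_holds_locally(self, rng, w111):
        # the log-norm is only a local approximation; report-style check
        bad = total = 0
        while total < 2000:
            pts = random_cloud(rng, 3, extent=1.2)
            d01, d02, d12 = (s.approx_distance(
                s.GroupElement(*pts[a]), s.GroupElement(*pts[b]), w111)
                for a, b in ((0, 1), (0, 2), (1, 2)))
            if max(d01, d02, d12) > 2.0:
                continue
            total += 1
            if d01 > d02 + d12 + 1e-12:
                bad += 1
        assert bad / total < 0.05


class TestReflectionSymmetries:
    def test_eight_for_diagonal_weights(self, rng):
        w = s.MetricWeights(0.3, 1.7, 2.2)
        assert s.reflection_invariance_count(w, random_cloud(rng, 50)) == 8

    def test_origin_sample(self, w111):
        assert s.reflection_invariance_count(w111, np.zeros((1, 3))) == 8

    def test_norm_even_under_full_flip(self, w_aniso, rng):
        pts = random_cloud(rng, 10, extent=2.0)
        for p in pts:
            g = s.GroupElement(*p)
            c = s.log_map(g)
            h = s.exp_map(s.AlgebraCoords(-c.c1, -c.c2, -c.c3))
            d1 = s.approx_distance(s.GroupElement.identity(), g, w_aniso)
            d2 = s.approx_distance(s.GroupElement.identity(), h, w_aniso)
            assert abs(d1 - d2) < 1e-9


class TestBallStencil:
    def test_tiny_radius_single_offset(self, w111):
        grid = s.LiftedGrid(8, 8, 8)
        st_ = s.build_ball_stencil(grid, w111, radius=0.2)
        for offsets, dist in st_.layers:
            assert offsets.shape == (1, 3)
            assert tuple(offsets[0]) == (0, 0, 0)
            assert dist[0] == 0.0

    def test_center_offset_always_present(self, w_aniso):
        grid = s.LiftedGrid(10, 10, 6)
        st_ = s.build_ball_stencil(grid, w_aniso, radius=1.5)
        for offsets, dist in st_.layers:
            row = np.flatnonzero((offsets == 0).all(axis=1))
            assert len(row) == 1
            assert dist[row[0]] == 0.0

    def test_membership_matches_brute_force(self):
        w = s.MetricWeights(0.5, 2.0, 1.5)
        grid = s.LiftedGrid(12, 12, 6)
        radius = 2.0
        st_ = s.build_ball_stencil(grid, w, radius)
        for k in [0, 2, 5]:
            offsets, dist = st_.layers[k]
            got = {tuple(o) for o in offsets}
            want = set()
            gk = s.GroupElement(0, 0, k * grid.dtheta)
            for di in range(-6, 7):
                for dj in range(-6, 7):
                    for dm in range(-3, 3):
                        h = s.GroupElement(di * grid.dx, dj * grid.dy,
                                           (k + dm) * grid.dtheta)
                        if s.approx_distance(gk, h, w) <= radius:
                            want.add((di, dj, dm))
            assert got == want

    def test_huge_angular_weight_planar_ellipse(self):
        w = s.MetricWeights(1.0, 4.0, 1e6)
        grid = s.LiftedGrid(16, 16, 8)
        radius = 3.0
        st_ = s.build_ball_stencil(grid, w, radius)
        offsets, dist = st_.layers[0]
        assert set(offsets[:, 2].tolist()) == {0}
        got = {tuple(o[:2]) for o in offsets}
        want = {(di, dj) for di in range(-8, 9) for dj in range(-8, 9)
                if di ** 2 + 4.0 * dj ** 2 <= radius ** 2}
        assert got == want

    def test_layer_rotation_consistency(self):
        # layer k offsets, continuously rotated back by theta_k, satisfy the
        # layer-0 distance inequality
        w = s.MetricWeights(0.4, 1.0, 2.0)
        grid = s.LiftedGrid(14, 14, 8)
        radius = 1.8
        st_ = s.build_ball_stencil(grid, w, radius)
        e = s.GroupElement.identity()
        for k, (offsets, dist) in enumerate(st_.layers):
            th = k * grid.dtheta
            for (di, dj, dm), d in zip(offsets, dist):
                rx = math.cos(th) * di + math.sin(th) * dj
                ry = -math.sin(th) * di + math.cos(th) * dj
                h = s.GroupElement(rx, ry, dm * grid.dtheta)
                assert abs(s.approx_distance(e, h, w) - d) < 1e-9
                assert d <= radius

    def test_reflected_offsets_stay_in_ball(self):
        # continuous check of the 8 sign-flip symmetries on stencil members
        w = s.MetricWeights(0.7, 1.3, 2.0)
        grid = s.LiftedGrid(12, 12, 8)
        st_ = s.build_ball_stencil(grid, w, 1.6)
        offsets, dist = st_.layers[2]
        th = 2 * grid.dtheta
        for (di, dj, dm), d in zip(offsets[:40], dist[:40]):
            rx = math.cos(th) * di + math.sin(th) * dj
            ry = -math.sin(th) * di + math.cos(th) * dj
            c = s.log_map(s.GroupElement(rx, ry, dm * grid.dtheta))
            for s1 in (1, -1):
                for s2 in (1, -1):
                    for s3 in (1, -1):
                        flipped = math.sqrt(w.w1 * (s1 * c.c1) ** 2
                                            + w.w2 * (s2 * c.c2) ** 2
                                            + w.w3 * (s3 * c.c3) ** 2)
                        assert flipped <= st_.radius + 1e-9

    def test_oversized_radius_warns_and_clips(self, w111, caplog):
        grid = s.LiftedGrid(6, 6, 4)
        with caplog.at_level("WARNING", logger="se2cc"):
            st_ = s.build_ball_stencil(grid, w111, radius=50.0)
        assert any("clipped" in r.message for r in caplog.records)
        for offsets, _ in st_.layers:
            assert np.abs(offsets[:, 0]).max() <= grid.Nx - 1
            assert np.abs(offsets[:, 1]).max() <= grid.Ny - 1

    def test_invalid_inputs(self, w111):
        grid = s.LiftedGrid(4, 4, 4)
        with pytest.raises(ValueError):
            s.build_ball_stencil(grid, w111, radius=0.0)
        with pytest.raises(ValueError):
            s.MetricWeights(1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            s.LiftedGrid(0, 4, 4)

    def test_grid_dtheta_closes_circle(self):
        grid = s.LiftedGrid(4, 4, 12)
        assert abs(grid.dtheta * grid.No - 2 * math.pi) < 1e-12
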