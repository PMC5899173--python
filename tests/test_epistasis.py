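"""Square classification, domain maps, pleiotropy and panel combinatorics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import episcade as ep
from episcade.cascade import FULL_WINDOW, default_cascade, r_landscape
from episcade.epistasis import (CLASSES, EpistasisMap, Square, classify_effects,
                                classify_square, count_pairwise_interactions,
                                double_mutant_reach, epistasis_map, panel_size,
                                pleiotropic_slice)
from episcade.landscapes import Landscape, PhenotypeAxis


def _oracle_classify(f, s: Square, tol_abs: float) -> str:
    """Independent four-corner evaluation of the sign-flip definition."""
    (x0, y0), (x1, y1) = s.start, s.end
    F = {(x, y): float(f(x, y)) for x in (x0, x1) for y in (y0, y1)}
    dX = [F[(x1, y0)] - F[(x0, y0)], F[(x1, y1)] - F[(x0, y1)]]
    dY = [F[(x0, y1)] - F[(x0, y0)], F[(x1, y1)] - F[(x1, y0)]]
    sgn = lambda v: 0 if abs(v) < tol_abs else (1 if v > 0 else -1)
    xs, ys = [sgn(v) for v in dX], [sgn(v) for v in dY]
    x_flip = xs[0] * xs[1] == -1
    y_flip = ys[0] * ys[1] == -1
    if not any(xs + ys):
        return "neutral"
    if x_flip and y_flip:
        return "reciprocal"
    if x_flip:
        return "x_sign"
    if y_flip:
        return "y_sign"
    return "magnitude"


class TestClassifySquare:
    def test_unrotated_gaussian_squares_to_origin_are_magnitude(self, gauss0):
        rng = np.random.default_rng(0)
        for _ in range(25):
            start = tuple(rng.uniform(-2.5, 2.5, 2))
            if abs(start[0]) < 1e-3 or abs(start[1]) < 1e-3:
                continue
            call = classify_square(gauss0, Square(start=start, end=(0.0, 0.0)))
            assert call.klass == "magnitude"

    def test_degenerate_square_rejected(self):
        with pytest.raises(ValueError):
            Square(start=(1.0, 2.0), end=(1.0, 3.0))

    def test_corner_outside_bounds_rejected(self, gauss0):
        with pytest.raises(ValueError):
            classify_square(gauss0, Square(start=(-5.0, 0.5), end=(0.1, 0.2)))

    def test_quarter_rotation_has_reciprocal_squares(self, gauss4):
        """At a = π/4 the map contains a reciprocal domain; from such a
        start, both single-mutant intermediates lose performance."""
        m = epistasis_map(gauss4, grid=101)
        names = np.array(m.class_names)
        ii, jj = np.nonzero(m.codes == list(names).index("reciprocal"))
        assert ii.size > 0
        # pick the reciprocal start furthest from the end point
        k = np.argmax((m.x[jj] - m.end[0]) ** 2 + (m.y[ii] - m.end[1]) ** 2)
        start = (float(m.x[jj[k]]), float(m.y[ii[k]]))
        call = classify_square(gauss4, Square(start=start, end=m.end))
        assert call.klass == "reciprocal"
        f0 = float(gauss4(*start))
        assert float(gauss4(m.end[0], start[1])) < f0
        assert float(gauss4(start[0], m.end[1])) < f0

    def test_separable_oracle_equivalence(self):
        """1000 random squares on a separable landscape match an
        independently coded four-corner oracle (and are never sign-type)."""
        f = lambda x, y: np.sin(np.asarray(x, float)) - (np.asarray(y, float) - 0.4) ** 2
        L = Landscape(f=f, axis_x=PhenotypeAxis(name="x", bounds=(-1.2, 1.2)),
                      axis_y=PhenotypeAxis(name="y", bounds=(-2, 2)))
        scale = float(np.ptp(L.grid(51)[2]))
        rng = np.random.default_rng(42)
        for _ in range(1000):
            x0, x1 = rng.uniform(-1.2, 1.2, 2)
            y0, y1 = rng.uniform(-2, 2, 2)
            if x0 == x1 or y0 == y1:
                continue
            s = Square(start=(x0, y0), end=(x1, y1))
            got = classify_square(L, s, scale=scale).klass
            want = _oracle_classify(f, s, 1e-9 * scale)
            assert got == want
            assert got in ("magnitude", "neutral")

    @given(seed=st.integers(0, 500))
    @settings(max_examples=60, deadline=None)
    def test_random_smooth_landscape_oracle_equivalence(self, seed):
        """classify_square equals the brute-force definition on random
        smooth (quadratic + cross-term) landscapes."""
        rng = np.random.default_rng(seed)
        a, b, c, d, e = rng.normal(size=5)
        f = lambda x, y: (a * np.asarray(x, float) ** 2 + b * np.asarray(y, float) ** 2
                          + c * np.asarray(x, float) * np.asarray(y, float)
                          + d * np.asarray(x, float) + e * np.asarray(y, float))
        L = Landscape(f=f, axis_x=PhenotypeAxis(name="x", bounds=(-2, 2)),
                      axis_y=PhenotypeAxis(name="y", bounds=(-2, 2)))
        scale = float(np.ptp(L.grid(31)[2])) or 1.0
        for _ in range(20):
            x0, x1, y0, y1 = rng.uniform(-2, 2, 4)
            if x0 == x1 or y0 == y1:
                continue
            s = Square(start=(x0, y0), end=(x1, y1))
            assert classify_square(L, s, scale=scale).klass == \
                _oracle_classify(f, s, 1e-9 * scale)

    def test_start_end_exchange_invariance(self, gauss12):
        scale = float(np.ptp(gauss12.grid(51)[2]))
        rng = np.random.default_rng(3)
        for _ in range(50):
            x0, x1, y0, y1 = rng.uniform(-2, 2, 4)
            if x0 == x1 or y0 == y1:
                continue
            k1 = classify_square(gauss12, Square((x0, y0), (x1, y1)), scale=scale).klass
            k2 = classify_square(gauss12, Square((x1, y1), (x0, y0)), scale=scale).klass
            assert k1 == k2

    def test_axis_swap_exchanges_sign_labels(self, gauss12):
        swapped = Landscape(f=lambda x, y: gauss12.f(y, x),
                            axis_x=gauss12.axis_y, axis_y=gauss12.axis_x)
        scale = float(np.ptp(gauss12.grid(51)[2]))
        rng = np.random.default_rng(4)
        exchange = {"x_sign": "y_sign", "y_sign": "x_sign"}
        for _ in range(50):
            x0, x1, y0, y1 = rng.uniform(-2, 2, 4)
            if x0 == x1 or y0 == y1:
                continue
            k1 = classify_square(gauss12, Square((x0, y0), (x1, y1)), scale=scale).klass
            k2 = classify_square(swapped, Square((y0, x0), (y1, x1)), scale=scale).klass
            assert k2 == exchange.get(k1, k1)


class TestEpistasisMap:
    def test_unrotated_gaussian_all_magnitude(self, gauss0):
        m = epistasis_map(gauss0, grid=101)
        fr = m.class_fractions()
        assert fr["magnitude"] > 0.999
        assert fr["x_sign"] == 0 and fr["y_sign"] == 0 and fr["reciprocal"] == 0

    def test_fractions_sum_to_one(self, map_full, map_restricted, gauss4):
        for m in (map_full, map_restricted, epistasis_map(gauss4, grid=61)):
            assert sum(m.class_fractions().values()) == pytest.approx(1.0)

    def test_cascade_full_window_domains(self, map_full):
        assert map_full.domain_present("downstream_sign")
        assert not map_full.domain_present("upstream_sign")
        assert not map_full.domain_present("reciprocal")

    def test_cascade_restricted_window_domains(self, map_restricted):
        for k in ("downstream_sign", "upstream_sign", "reciprocal"):
            assert map_restricted.domain_present(k)

    def test_criterion_consistency(self, plane_full, map_full, gauss0, gauss12):
        """A sign domain can only exist where the matching optimum line
        actually shifts."""
        crit = ep.sign_epistasis_criterion(plane_full)
        if map_full.domain_present("downstream_sign"):
            assert crit["x_effect_sign_epistasis"]
        for g, expect in ((gauss0, False), (gauss12, True)):
            m = epistasis_map(g, grid=61)
            c = ep.sign_epistasis_criterion(g)
            assert (m.class_fractions()["x_sign"] > 0) == expect
            assert c["x_effect_sign_epistasis"] == expect

    def test_arbitrary_end_point(self, gauss12):
        m = epistasis_map(gauss12, grid=41, end=(0.5, -0.5))
        assert m.end == (0.5, -0.5)
        assert sum(m.class_fractions().values()) == pytest.approx(1.0)

    def test_end_outside_bounds_rejected(self, gauss0):
        with pytest.raises(ValueError):
            epistasis_map(gauss0, grid=21, end=(10.0, 0.0))

    def test_map_export(self, gauss12, tmp_path):
        m = epistasis_map(gauss12, grid=21)
        m.to_csv(tmp_path / "m.csv")
        m.summary_json(tmp_path / "m.json")
        lines = (tmp_path / "m.csv").read_text().strip().splitlines()
        assert lines[0] == "x,y,class"
        valid = int((m.codes >= 0).sum())
        assert len(lines) == 1 + valid


class TestPleiotropy:
    def _build(self, **kw):
        return r_landscape(default_cascade(), FULL_WINDOW,
                           ("lacI", "K"), ("tetR", "K"),
                           (1.0, 4.0), (-1.5, 1.5), **kw)

    def test_identity_coupling_matches_uncoupled(self):
        base = self._build()
        coupled = pleiotropic_slice(self._build, coupling=lambda v: {},
                                    coupling_axis="x")
        rng = np.random.default_rng(0)
        xs, ys = rng.uniform(1, 4, 8), rng.uniform(-1.5, 1.5, 8)
        for x, y in zip(xs, ys):
            assert float(coupled(x, y)) == pytest.approx(float(base(x, y)), rel=1e-12)

    def test_constant_coupling_equals_pinned_parameter(self):
        pinned = r_landscape(default_cascade().with_stage_params("lacI", n=2.2),
                             FULL_WINDOW, ("lacI", "K"), ("tetR", "K"),
                             (1.0, 4.0), (-1.5, 1.5))
        coupled = pleiotropic_slice(self._build, coupling=lambda v: {"n": 2.2},
                                    coupling_axis="x")
        for x, y in ((1.5, 0.0), (2.5, 1.0), (3.5, -1.0)):
            assert float(coupled(x, y)) == pytest.approx(float(pinned(x, y)), rel=1e-12)

    def test_linear_coupling_keeps_downstream_domain(self):
        """Tying the downstream Hill coefficient to log10 K still leaves a
        downstream sign-epistasis domain."""
        coupled = pleiotropic_slice(
            self._build, coupling=lambda v: {"n": 1.7 + 0.15 * (v - 2.5)},
            coupling_axis="x")
        m = epistasis_map(coupled, grid=61)
        assert m.domain_present("downstream_sign")

    def test_cross_gene_coupling_rejected(self):
        with pytest.raises(ValueError):
            self._build(coupling=lambda v: {"bogus": v}, coupling_axis="x")


class TestCombinatorics:
    def test_reference_panel_counts(self):
        assert count_pairwise_interactions(5, 7) == 210
        assert panel_size(5, 7) == 35
        assert double_mutant_reach(5, 7) == 24

    def test_minimal_square(self):
        assert count_pairwise_interactions(2, 2) == 1

    @given(nu=st.integers(2, 7), nd=st.integers(2, 7))
    @settings(max_examples=36, deadline=None)
    def test_count_matches_exhaustive_enumeration(self, nu, nd):
        squares = {
            frozenset({(u0, d0), (u0, d1), (u1, d0), (u1, d1)})
            for u0, u1 in itertools.combinations(range(nu), 2)
            for d0, d1 in itertools.combinations(range(nd), 2)
        }
        assert count_pairwise_interactions(nu, nd) == len(squares)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            count_pairwise_interactions(1, 7)
        with pytest.raises(ValueError):
            double_mutant_reach(5, 1)
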