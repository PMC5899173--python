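"""Hill stages, cascade composition, response range and fitness proxy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import episcade as ep
from episcade.cascade import (Cascade, EnvFitnessParams, FULL_WINDOW,
                              HillStage, InputRange, RESTRICTED_WINDOW,
                              activator_substituted, cascade_output,
                              default_cascade, fitness_proxy,
                              inverted_cascade, load_cascade_config,
                              r_landscape, response_range_R,
                              save_cascade_config, stage_response)


def _stage(role="repressor", M=100.0, m=1.0, K=10.0, n=2.0, name="s"):
    return HillStage(name=name, role=role, M_max=M, m_min=m, K=K, n=n)


class TestStageResponse:
    def test_repressor_limits(self):
        s = _stage()
        assert float(stage_response(s, 0.0)) == pytest.approx(100.0)
        assert float(stage_response(s, s.K)) == pytest.approx((100 + 1) / 2)
        # saturation: within 1e-6 relative at u = 1e6 K
        assert float(stage_response(s, 1e6 * s.K)) == pytest.approx(1.0, rel=1e-6)

    def test_activator_printed_example(self):
        s = _stage(role="activator", M=10.0, m=1.0, K=5.0, n=2.0)
        # (10-1)*1/(1+1) + 1 = 5.5 at half-saturation
        assert float(stage_response(s, 5.0)) == pytest.approx(5.5)
        assert float(stage_response(s, 0.0)) == pytest.approx(1.0)
        assert float(stage_response(s, 1e6 * s.K)) == pytest.approx(10.0, rel=1e-6)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            stage_response(_stage(), -1.0)

    @given(u=st.floats(0, 1e4), K=st.floats(0.1, 1e3), n=st.floats(0.5, 6),
           m=st.floats(0, 5), span=st.floats(1, 200))
    @settings(max_examples=100, deadline=None)
    def test_output_always_within_expression_bounds(self, u, K, n, m, span):
        for role in ("repressor", "activator"):
            s = _stage(role=role, M=m + span, m=m, K=K, n=n)
            v = float(stage_response(s, u))
            assert s.m_min - 1e-9 <= v <= s.M_max + 1e-9

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            _stage(M=1.0, m=2.0)
        with pytest.raises(ValueError):
            _stage(K=0.0)
        with pytest.raises(ValueError):
            _stage(n=-1.0)


class TestCascadeComposition:
    def test_single_stage_equals_stage_response(self):
        s = _stage()
        C = Cascade(stages=(s,))
        u = np.array([0.0, 1.0, 10.0, 100.0])
        assert np.allclose(cascade_output(C, u), stage_response(s, u))

    def test_three_stage_hand_chained_oracle(self):
        """Output at 0 and 100 µM must equal the explicit stage-by-stage
        arithmetic of the three Hill equations."""
        C = default_cascade()
        for ara in (0.0, 100.0):
            t = (100.0 - 0.2) / (1.0 + (ara / 22.0) ** 1.0) + 0.2
            l = (100.0 - 4.0) / (1.0 + (t / 25.0) ** 5.0) + 4.0
            out = (100.0 - 1.0) / (1.0 + (l / 20.0) ** 1.7) + 1.0
            assert float(cascade_output(C, ara)) == pytest.approx(out, rel=1e-12)

    def test_two_repressors_at_zero_input(self):
        s1, s2 = _stage(name="a"), _stage(name="b", K=30.0)
        C = Cascade(stages=(s1, s2))
        assert float(cascade_output(C, 0.0)) == pytest.approx(
            float(stage_response(s2, s1.M_max)))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_composition_is_monotone_in_input(self, seed):
        """Each stage is monotone, so the composed response is monotone and
        R over a sub-window never exceeds R over a containing window."""
        rng = np.random.default_rng(seed)
        stages = []
        for i in range(rng.integers(1, 4)):
            role = rng.choice(["repressor", "activator"])
            m = rng.uniform(0, 5)
            stages.append(_stage(role=role, M=m + rng.uniform(1, 100), m=m,
                                 K=10 ** rng.uniform(-1, 2),
                                 n=rng.uniform(0.5, 5), name=f"s{i}"))
        C = Cascade(stages=tuple(stages))
        u = np.linspace(0, 100, 41)
        out = np.asarray(cascade_output(C, u))
        d = np.diff(out)
        assert np.all(d >= -1e-9) or np.all(d <= 1e-9)
        R_full = response_range_R(C, InputRange(0, 100)).value
        R_sub = response_range_R(C, InputRange(30, 70)).value
        assert R_sub <= R_full + 1e-9


class TestResponseRange:
    def test_nearly_constant_stage_kills_transmission(self):
        C = default_cascade().with_stage_params("tetR", M_max=4.0 + 1e-9)
        assert response_range_R(C, FULL_WINDOW).value < 1e-8

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            InputRange(50.0, 50.0)
        with pytest.raises(ValueError):
            InputRange(-1.0, 50.0)

    def test_window_nesting(self):
        C = default_cascade()
        assert (response_range_R(C, FULL_WINDOW).value
                >= response_range_R(C, RESTRICTED_WINDOW).value)

    def test_orientation_metadata(self):
        rr = response_range_R(default_cascade(), FULL_WINDOW)
        # the printed three-repressor composition falls with arabinose
        assert rr.orientation == "in_min"
        assert rr.value == pytest.approx(abs(rr.signed))

    def test_relabelling_invariance(self):
        C = default_cascade()
        relabelled = Cascade(stages=tuple(
            HillStage(name=f"gene{i}", role=s.role, M_max=s.M_max,
                      m_min=s.m_min, K=s.K, n=s.n)
            for i, s in enumerate(C.stages)))
        assert (response_range_R(relabelled, FULL_WINDOW).value
                == pytest.approx(response_range_R(C, FULL_WINDOW).value))


class TestFitnessProxy:
    def test_zero_range_gives_mean_benefit(self):
        F, R = fitness_proxy(EnvFitnessParams(a=3.0, b=5.0, c=1.0), 2.0, 2.0)
        assert F == pytest.approx(4.0)
        assert R == 0.0

    def test_printed_substitution(self):
        F, R = fitness_proxy(EnvFitnessParams(a=0.0, b=0.0, c=2.0), 1.0, 3.0)
        assert F == pytest.approx(-2.0)
        assert R == pytest.approx(2.0)

    @given(y1=st.floats(-10, 10), y2=st.floats(-10, 10),
           z1=st.floats(-10, 10), z2=st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_fitness_difference_is_linear_in_range(self, y1, y2, z1, z2):
        p = EnvFitnessParams(a=1.0, b=2.0, c=0.8)
        F1, R1 = fitness_proxy(p, y1, y2)
        F2, R2 = fitness_proxy(p, z1, z2)
        assert F1 - F2 == pytest.approx(-(p.c / 2) * (R1 - R2), abs=1e-9)


class TestRLandscape:
    def test_plane_axis_metadata(self, plane_full):
        assert plane_full.axis_x.gene == "lacI"
        assert plane_full.axis_x.cascade_position == "downstream"
        assert plane_full.axis_y.gene == "tetR"
        assert plane_full.axis_y.cascade_position == "upstream"
        assert plane_full.axis_x.scale == "log10"

    def test_fast_path_matches_generic_path(self, plane_full):
        C = default_cascade()
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(*plane_full.axis_x.bounds)
            y = rng.uniform(*plane_full.axis_y.bounds)
            cc = (C.with_stage_params("lacI", K=10 ** x)
                   .with_stage_params("tetR", K=10 ** y))
            assert float(plane_full(x, y)) == pytest.approx(
                response_range_R(cc, FULL_WINDOW).value, rel=1e-12)

    def test_hill_plane_is_valid(self):
        L = r_landscape(default_cascade(), FULL_WINDOW,
                        ("lacI", "n"), ("tetR", "n"), (0.5, 4.0), (0.5, 6.0))
        _, _, Z = L.grid(21)
        assert np.all(np.isfinite(Z)) and Z.max() > 0
        assert L.axis_x.scale == "linear"

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            r_landscape(default_cascade(), FULL_WINDOW,
                        ("lacI", "K"), ("tetR", "K"), (1.0, 1.0), (0.0, 1.0))

    def test_same_stage_without_coupling_rejected(self):
        with pytest.raises(ValueError):
            r_landscape(default_cascade(), FULL_WINDOW,
                        ("lacI", "K"), ("lacI", "n"), (1.0, 4.0), (0.5, 4.0))

    def test_inverted_order_uses_same_code_path(self):
        L = ep.default_plane(inverted_cascade())
        assert L.axis_x.gene == "tetR"
        assert L.axis_x.cascade_position == "downstream"
        _, _, Z = L.grid(31)
        assert Z.max() > 1.0

    def test_activator_final_stage_preserves_R(self):
        """act(ρ) + rep(ρ) = M + m, so swapping the last stage's role leaves
        |R| pointwise unchanged."""
        C = default_cascade()
        A = activator_substituted(C, "lacI")
        La = ep.default_plane(A)
        Lr = ep.default_plane(C)
        rng = np.random.default_rng(1)
        xs = rng.uniform(*Lr.axis_x.bounds, 25)
        ys = rng.uniform(*Lr.axis_y.bounds, 25)
        assert np.allclose(La(xs, ys), Lr(xs, ys), rtol=1e-12)


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path):
        C = default_cascade()
        p = tmp_path / "cascade.yaml"
        save_cascade_config(C, p)
        C2 = load_cascade_config(p)
        assert C2 == C

    def test_landscape_families_from_config(self, tmp_path, gauss12):
        from episcade.cascade import load_landscape_config

        pg = tmp_path / "g.yaml"
        pg.write_text(f"family: gaussian\nangle: {np.pi / 12}\n")
        Lg = load_landscape_config(pg)
        assert float(Lg(0.3, -0.7)) == pytest.approx(float(gauss12(0.3, -0.7)))

        pc = tmp_path / "c.yaml"
        pc.write_text("family: cascade_R\nwindow: [0.0, 100.0]\n")
        Lc = load_landscape_config(pc)
        assert float(Lc(2.0, 0.5)) == pytest.approx(
            float(ep.default_plane()(2.0, 0.5)))

        bad = tmp_path / "bad.yaml"
        bad.write_text("family: nope\n")
        with pytest.raises(ValueError):
            load_landscape_config(bad)
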