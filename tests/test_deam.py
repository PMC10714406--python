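"""The statistical reconstructor: objective, normalizer, penalty, loop."""

import numpy as np
import pytest

from dectunroll import (
    BasisImage,
    DEAMConfig,
    EnergyGrid,
    PenaltyConfig,
    SinogramSet,
    SpectrumPair,
    build_material_basis,
    build_system_operator,
    deam_step,
    desk_fan_geometry,
    i_divergence,
    penalty_value_grad,
    polychromatic_forward,
    run_deam,
    step_normalizer,
)
from dectunroll.deam import _psi, bit_reversed_order
from dectunroll.dc import dc_forward
from dectunroll.geometry import SystemOperator
from dectunroll.spectral import MaterialBasis


class TestIDivergence:
    def test_identity_zero(self):
        d = np.random.default_rng(0).random((2, 10)) + 0.1
        assert i_divergence(d, d) == pytest.approx(0.0, abs=1e-12)

    def test_zero_count_convention(self):
        assert i_divergence(np.array([[0.0], [0.0]]),
                            np.array([[2.0], [0.0]])) == pytest.approx(2.0)

    def test_hand_value(self):
        d = np.array([[1.0, 3.0]])
        g = np.array([[2.0, 2.0]])
        expected = np.log(0.5) + 1.0 + 3 * np.log(1.5) - 1.0
        assert i_divergence(d, g) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.5233, abs=1e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            i_divergence(np.array([[1.0]]), np.array([[0.0]]))


class TestStepNormalizer:
    def test_positive_on_desk_geometry(self, fan_op, Z_fan):
        finite = np.isfinite(Z_fan)
        assert finite.all()
        assert np.all(Z_fan > 0)

    def test_scales_with_voxel_spacing(self, ectx):
        _, basis, spec = ectx
        Z1 = step_normalizer(
            build_system_operator(desk_fan_geometry(n=16, n_channels=15,
                                                    n_views=12, pixel_mm=1.0)),
            basis, spec)
        Z2 = step_normalizer(
            build_system_operator(desk_fan_geometry(n=16, n_channels=15,
                                                    n_views=12, pixel_mm=2.0)),
            basis, spec)
        assert np.nanmax(Z2) > np.nanmax(Z1)

    def test_untouched_voxel_frozen(self, ectx):
        _, basis, spec = ectx
        H = np.array([[1.0, 0.0], [2.0, 0.0]])  # voxel 1 sees no ray
        op = SystemOperator.from_matrix(H, (2, 1, 1))
        with pytest.warns(RuntimeWarning):
            Z = step_normalizer(op, basis, spec)
        assert np.isinf(Z[:, 1, 0, 0]).all()
        assert np.isfinite(Z[:, 0, 0, 0]).all()

    def test_unknown_mode_rejected(self, fan_op, ectx):
        _, basis, spec = ectx
        with pytest.raises(ValueError):
            step_normalizer(fan_op, basis, spec, Z_mode="bogus")


class TestPenalty:
    def test_closed_form_values(self):
        assert _psi(1.0, 1.0) == pytest.approx(1.0 - np.log(2.0), rel=1e-12)

    def test_constant_image(self):
        v, g = penalty_value_grad(np.full((2, 5, 5, 1), 0.7), PenaltyConfig())
        assert v == 0.0 and np.all(g == 0.0)

    def test_small_t_quadratic_limit(self):
        delta = 1.0
        t = 1e-4
        assert _psi(t, delta) == pytest.approx(t**2 / 2, rel=1e-3)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        c = 0.1 * rng.standard_normal((2, 6, 6, 1))
        cfg = PenaltyConfig(delta=0.05, strength=2.0)
        _, g = penalty_value_grad(c, cfg)
        eps = 1e-6
        for idx in [(0, 2, 3, 0), (1, 5, 0, 0)]:
            cp, cm = c.copy(), c.copy()
            cp[idx] += eps
            cm[idx] -= eps
            fd = (penalty_value_grad(cp, cfg)[0]
                  - penalty_value_grad(cm, cfg)[0]) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-6)

    def test_neighborhood_weights_normalized(self):
        cfg = PenaltyConfig()
        offs, w = cfg.offsets_weights((8, 8, 1))
        assert len(offs) == 8  # thin z: in-plane 8-neighborhood
        assert w.sum() == pytest.approx(1.0)
        offs3, w3 = cfg.offsets_weights((8, 8, 8))
        assert len(offs3) == 26

    def test_bad_delta_rejected(self):
        with pytest.raises(ValueError):
            PenaltyConfig(delta=0.0)


class TestDeamStep:
    def test_fixed_point_at_consistency(self, fan_op, ectx, insert_phantom,
                                        noiseless_sino, Z_fan):
        _, basis, spec = ectx
        ct, _, _ = insert_phantom
        out = deam_step(ct, noiseless_sino, fan_op, spec, basis, Z_fan)
        assert np.max(np.abs(out.c - ct.c)) < 1e-12

    def test_single_step_decreases_objective(self, fan_op, ectx,
                                             noiseless_sino, Z_fan):
        _, basis, spec = ectx
        rng = np.random.default_rng(8)
        c0 = BasisImage(0.2 * rng.random((2, 64, 64, 1)))
        before = i_divergence(noiseless_sino,
                              polychromatic_forward(fan_op, spec, basis, c0))
        c1 = deam_step(c0, noiseless_sino, fan_op, spec, basis, Z_fan)
        after = i_divergence(noiseless_sino,
                             polychromatic_forward(fan_op, spec, basis, c1))
        assert after < before

    def test_scalar_sign(self):
        """One voxel, one ray, one energy: d < g must increase c."""
        grid = EnergyGrid(np.array([60.0, 61.0]))
        basis = MaterialBasis(grid=grid,
                              mu=np.array([[0.02, 0.02], [1e-4, 1e-4]]),
                              names=("a", "b"))
        spec = SpectrumPair(grid=grid, I0=np.array([[100.0, 0.0],
                                                    [100.0, 0.0]]))
        op = SystemOperator.from_matrix(np.array([[10.0]]), (1, 1, 1))
        c = BasisImage(np.full((2, 1, 1, 1), 0.5))
        g = polychromatic_forward(op, spec, basis, c)
        d = SinogramSet(0.5 * g.d)  # measured more attenuated than modeled
        Z = step_normalizer(op, basis, spec)
        out = deam_step(c, d, op, spec, basis, Z)
        assert np.all(out.c > c.c)

    def test_matches_dc_forward(self, fan_op, ectx, noiseless_sino, Z_fan):
        _, basis, spec = ectx
        rng = np.random.default_rng(9)
        c0 = BasisImage(0.3 * rng.random((2, 64, 64, 1)))
        ud = dc_forward(c0, noiseless_sino, fan_op, spec, basis, Z_fan)
        out = deam_step(c0, noiseless_sino, fan_op, spec, basis, Z_fan)
        assert np.array_equal(out.c, c0.c + ud.delta_c)


class TestRunDeam:
    def test_truth_init_stationary(self, fan_op, ectx, insert_phantom,
                                   noiseless_sino):
        _, basis, spec = ectx
        ct, _, _ = insert_phantom
        st = run_deam(noiseless_sino, ct, DEAMConfig(n_iterations=3),
                      None, fan_op, spec, basis)
        assert np.max(np.abs(st.c.c - ct.c)) < 1e-8

    def test_single_subset_reproduces_plain_algorithm(self, fan_op, ectx,
                                                      noiseless_sino, Z_fan):
        _, basis, spec = ectx
        init = BasisImage(np.zeros((2, 64, 64, 1)))
        st = run_deam(noiseless_sino, init, DEAMConfig(n_iterations=4),
                      None, fan_op, spec, basis)
        c = init.copy()
        for _ in range(4):
            c = deam_step(c, noiseless_sino, fan_op, spec, basis, Z_fan)
        assert np.array_equal(st.c.c, c.c)

    def test_subset_sweeps_nearly_monotone(self, fan_op, ectx,
                                           noiseless_sino):
        _, basis, spec = ectx
        init = BasisImage(np.zeros((2, 64, 64, 1)))
        st = run_deam(noiseless_sino, init,
                      DEAMConfig(n_iterations=20, n_subsets=30),
                      None, fan_op, spec, basis)
        tr = np.array(st.objective_trace)
        assert np.all(np.diff(tr) <= 1e-3 * np.abs(tr[:-1]))

    def test_penalized_objective_monotone(self, fan_op, ectx, noiseless_sino):
        _, basis, spec = ectx
        pen = PenaltyConfig(delta=0.01, strength=2e4)
        init = BasisImage(np.zeros((2, 64, 64, 1)))
        st = run_deam(noiseless_sino, init, DEAMConfig(n_iterations=10),
                      pen, fan_op, spec, basis)
        tr = np.array(st.objective_trace)
        assert np.all(np.diff(tr) <= 1e-9 * np.abs(tr[:-1]))

    def test_penalty_zero_strength_matches_unpenalized(self, fan_op, ectx,
                                                       noiseless_sino):
        _, basis, spec = ectx
        init = BasisImage(np.zeros((2, 64, 64, 1)))
        a = run_deam(noiseless_sino, init, DEAMConfig(n_iterations=3),
                     PenaltyConfig(strength=0.0), fan_op, spec, basis)
        b = run_deam(noiseless_sino, init, DEAMConfig(n_iterations=3),
                     None, fan_op, spec, basis)
        assert np.array_equal(a.c.c, b.c.c)

    def test_better_init_keeps_lower_trace(self, fan_op, ectx, insert_phantom,
                                           noiseless_sino):
        _, basis, spec = ectx
        ct, _, _ = insert_phantom
        cfg = DEAMConfig(n_iterations=10, n_subsets=12)
        # a mildly perturbed truth starts lower than the zero image
        good = BasisImage(0.9 * ct.c)
        bad = BasisImage(np.zeros_like(ct.c))
        tr_g = np.array(run_deam(noiseless_sino, good, cfg, None, fan_op,
                                 spec, basis).objective_trace)
        tr_b = np.array(run_deam(noiseless_sino, bad, cfg, None, fan_op,
                                 spec, basis).objective_trace)
        assert tr_g[0] < tr_b[0]
        assert np.all(tr_g <= tr_b * (1 + 1e-9))

    def test_deterministic(self, fan_op, ectx, noiseless_sino):
        _, basis, spec = ectx
        init = BasisImage(np.zeros((2, 64, 64, 1)))
        cfg = DEAMConfig(n_iterations=3, n_subsets=12, momentum=True)
        a = run_deam(noiseless_sino, init, cfg, None, fan_op, spec, basis)
        b = run_deam(noiseless_sino, init, cfg, None, fan_op, spec, basis)
        assert np.array_equal(a.c.c, b.c.c)
        assert a.objective_trace == b.objective_trace

    def test_safeguard_accepts_descending_steps(self, fan_op, ectx,
                                                noiseless_sino):
        _, basis, spec = ectx
        init = BasisImage(np.zeros((2, 64, 64, 1)))
        st = run_deam(noiseless_sino, init,
                      DEAMConfig(n_iterations=3, step_safeguard=True),
                      None, fan_op, spec, basis)
        tr = np.array(st.objective_trace)
        assert np.all(np.diff(tr) <= 0.0)


def test_bit_reversed_order_is_permutation():
    for k in (1, 2, 7, 12, 16, 30):
        assert sorted(bit_reversed_order(k)) == list(range(k))
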