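"""Transplantation initial conditions, integration, perturbations."""

import numpy as np
import pytest

from tniche import (
    IntegrationSettings,
    KillEvent,
    ModelConfig,
    TransplantSpec,
    apply_cell_kill,
    integrate,
    make_initial_state,
    model_rhs,
    run_physiological,
)
from tniche.model import build_affinity_matrix
from tniche.simulate import clone_initial_counts


class TestInitialState:
    def test_p100_monoclonal(self, default_config):
        spec = TransplantSpec(n_preleukemic=100, clonality="monoclonal")
        c0 = make_initial_state(spec, default_config)
        assert c0[0] == 400 and c0[100] == 100
        assert c0.sum() == 500 and np.count_nonzero(c0) == 2

    def test_p10_polyclonal_even(self, default_config):
        spec = TransplantSpec(n_preleukemic=10, clonality="polyclonal")
        c0 = make_initial_state(spec, default_config)
        assert np.all(c0[100:110] == 1) and np.all(c0[110:] == 0)
        healthy = c0[:100]
        # 490 cells spread as equally as possible: 90 clones with 5, 10 with 4,
        # remainder assigned to the lowest indices
        assert np.all(healthy[:90] == 5) and np.all(healthy[90:] == 4)
        assert c0.sum() == 500

    def test_healthy_only_monoclonal(self, default_config):
        spec = TransplantSpec(n_preleukemic=0, clonality="monoclonal")
        c0 = make_initial_state(spec, default_config)
        assert c0[0] == 500 and np.count_nonzero(c0) == 1

    def test_multinomial_allocation_is_seeded_and_exact(self, default_config):
        spec = TransplantSpec(n_preleukemic=10, clonality="polyclonal",
                              allocation_mode="multinomial", seed=7)
        c0 = make_initial_state(spec, default_config)
        c0b = make_initial_state(spec, default_config)
        np.testing.assert_array_equal(c0, c0b)
        assert c0.sum() == 500 and c0[100:110].sum() == 10

    def test_multinomial_without_seed_rejected(self, default_config):
        spec = TransplantSpec(n_preleukemic=0, clonality="polyclonal",
                              allocation_mode="multinomial")
        with pytest.raises(ValueError, match="seed"):
            make_initial_state(spec, default_config)

    def test_too_many_preleukemic_clones_rejected(self):
        spec = TransplantSpec(n_preleukemic=10, clonality="polyclonal")
        with pytest.raises(ValueError, match="n_preleukemic <= q"):
            clone_initial_counts(spec, q=5)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TransplantSpec(total_cells=500, n_preleukemic=501)


class TestCellKill:
    def test_99_percent_kill(self):
        np.testing.assert_allclose(
            apply_cell_kill(np.full(3, 100.0), 0.99), np.ones(3)
        )

    def test_identity_and_total_kill(self):
        c = np.array([5.0, 0.0, 3.0])
        np.testing.assert_array_equal(apply_cell_kill(c, 0.0), c)
        assert np.all(apply_cell_kill(c, 1.0) == 0.0)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_cell_kill(np.ones(2), 1.5)


class TestIntegrate:
    def test_empty_system_is_fixed_point(self, default_config):
        traj = integrate(default_config, np.zeros(200))
        assert traj.converged and traj.t_converged == 1.0
        assert np.all(traj.final_state == 0.0)

    def test_scalar_logistic_closed_form(self):
        """A single species on a single niche follows the textbook logistic
        c(t) = K / (1 + (K - c0)/c0 * exp(-t/tau)) with K = v*p."""
        cfg = ModelConfig(n=1, q=1, p=100.0, u_h=0.0, v_h=1.0)
        traj = integrate(cfg, np.array([1.0, 0.0]), IntegrationSettings(t_max=3000))
        assert traj.converged
        K = 100.0
        expected = K / (1 + (K - 1) / 1 * np.exp(-traj.times / 8.0))
        np.testing.assert_allclose(traj.states[:, 0], expected, rtol=1e-6)

    def test_healthy_polyclonal_reaches_100_per_clone(self, default_config):
        spec = TransplantSpec(n_preleukemic=0, clonality="polyclonal")
        traj = integrate(default_config, make_initial_state(spec, default_config))
        assert traj.converged
        np.testing.assert_allclose(traj.final_state[:100], 100.0, rtol=1e-4)
        np.testing.assert_allclose(traj.final_state.sum(), 1e4, rtol=1e-4)

    def test_steady_state_independent_of_initial_allocation(self, default_config):
        """Any healthy-only polyclonal start with all clones present ends at
        the same equal-abundance steady state."""
        even = TransplantSpec(n_preleukemic=0, clonality="polyclonal")
        multi = TransplantSpec(n_preleukemic=0, clonality="polyclonal",
                               allocation_mode="multinomial", seed=2)
        c0 = make_initial_state(multi, default_config)
        assert c0[:100].min() > 0  # seed chosen so every clone is seeded
        t_even = integrate(default_config, make_initial_state(even, default_config))
        t_multi = integrate(default_config, c0)
        np.testing.assert_allclose(
            t_even.final_state, t_multi.final_state, rtol=1e-4
        )

    def test_states_never_negative(self, default_config):
        spec = TransplantSpec(n_preleukemic=100, clonality="monoclonal")
        cfg = default_config.with_folds(0.2, 0.5, 3.0)
        traj = integrate(cfg, make_initial_state(spec, cfg))
        assert np.all(traj.states >= 0.0)

    def test_rhs_residual_small_at_convergence(self, default_config):
        spec = TransplantSpec(n_preleukemic=0, clonality="polyclonal")
        traj = integrate(default_config, make_initial_state(spec, default_config))
        a = build_affinity_matrix(default_config)
        dc = model_rhs(traj.final_state, a, default_config.p_vector,
                       default_config.v_vector, default_config.tau)
        # per checkpoint interval the motion is below the declared tolerance
        assert np.max(np.abs(dc)) < 1e-6 * np.max(traj.final_state)

    def test_no_store_keeps_endpoints_only(self, default_config):
        spec = TransplantSpec(n_preleukemic=0, clonality="polyclonal")
        full = integrate(default_config, make_initial_state(spec, default_config))
        slim = integrate(default_config, make_initial_state(spec, default_config),
                         store_trajectory=False)
        assert slim.states.shape[0] == 2
        np.testing.assert_allclose(slim.final_state, full.final_state, rtol=1e-12)

    def test_event_outside_horizon_rejected(self, default_config):
        with pytest.raises(ValueError, match="event time"):
            integrate(default_config, np.zeros(200),
                      events=[KillEvent(500.0, 0.5)], t_end=400.0)


@pytest.fixture(scope="module", params=["polyclonal", "monoclonal"])
def physio(request):
    return request.param, run_physiological(request.param)


class TestPhysiological:
    def test_steady_total_is_1e4_before_kill_and_at_end(self, physio):
        _, traj = physio
        np.testing.assert_allclose(traj.state_at(199.0).sum(), 1e4, rtol=1e-3)
        np.testing.assert_allclose(traj.final_state.sum(), 1e4, rtol=1e-3)

    def test_kill_recovery_to_previous_state(self, physio):
        _, traj = physio
        pre = traj.state_at(199.0)
        post_kill = traj.state_at(201.0)
        assert post_kill.sum() < 0.05 * pre.sum()
        np.testing.assert_allclose(
            traj.final_state, pre, rtol=1e-3, atol=1e-9
        )

    def test_monoclonal_single_clone_at_1e4(self):
        traj = run_physiological("monoclonal")
        pre = traj.state_at(199.0)
        assert pre[0] == pytest.approx(1e4, rel=1e-3)
        assert np.count_nonzero(pre) == 1

    def test_complete_kill_is_absorbing(self):
        traj = run_physiological("polyclonal", kill_fraction=1.0)
        assert np.all(traj.final_state == 0.0)
        assert traj.state_at(199.0).sum() == pytest.approx(1e4, rel=1e-3)
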