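"""Constraint solver, integrator conservation laws, thermostats, protocols."""

import numpy as np
import pytest

from dyndist.constants import KB
from dyndist.cv import (
    DynamicDistanceSpec,
    dynamic_distance,
    dynamic_distance_gradient,
)
from dyndist.md import (
    ConstraintState,
    Langevin,
    NoseHooverChain,
    anneal,
    initialize_velocities,
    run_nvt,
    step_constrained,
    zip_schedule,
    zip_up,
)
from dyndist.toymodel import make_harmonic_dimer, make_random_cluster


def _dimer_spec(conf):
    return DynamicDistanceSpec.from_masses([(0, 1)], conf.masses)


class TestConstraintSolver:
    def test_lambda_vanishes_at_stationary_point(self, dimer):
        """Constrained at the bond minimum with zero velocity the
        constraint force has nothing to balance."""
        topo, conf = dimer
        spec = _dimer_spec(conf)
        cstate = ConstraintState(spec, target_D=1.0)
        forces = None
        for _ in range(50):
            _, forces, lam = step_constrained(
                topo, conf, spec, cstate, None, 0.5, forces
            )
        assert np.abs(cstate.lambda_trace).max() < 1e-10

    def test_static_force_balance_at_stretched_target(self, dimer):
        """At T→0 and D = r0+0.2 the mean multiplier balances k·ΔD."""
        topo, conf = dimer
        spec = _dimer_spec(conf)
        initialize_velocities(conf, 1e-4, np.random.default_rng(0), spec)
        res = run_nvt(topo, conf, 2000, 0.5, None, spec, target_D=1.2,
                      record_frames=False)
        assert np.mean(np.abs(res.lambdas[500:])) == pytest.approx(100.0, rel=1e-3)

    def test_constraint_satisfied_every_step(self, rng):
        topo, conf = make_random_cluster(10, seed=4)
        spec = DynamicDistanceSpec.from_masses([(0, 9), (2, 5)], conf.masses)
        d0 = dynamic_distance(spec, conf.positions)
        initialize_velocities(conf, 300, rng, spec)
        res = run_nvt(topo, conf, 500, 0.5, None, spec, target_D=d0,
                      record_frames=False)
        assert np.abs(res.d_measured - d0).max() <= 1e-8

    def test_rattle_velocity_condition(self, rng):
        topo, conf = make_random_cluster(10, seed=4)
        spec = DynamicDistanceSpec.from_masses([(0, 9), (2, 5)], conf.masses)
        initialize_velocities(conf, 300, rng, spec)
        cstate = ConstraintState(spec, dynamic_distance(spec, conf.positions))
        forces = None
        for _ in range(200):
            _, forces, _ = step_constrained(topo, conf, spec, cstate, None, 0.5, forces)
            dDdt = abs(
                np.sum(dynamic_distance_gradient(spec, conf.positions) * conf.velocities)
            )
            assert dDdt <= 1e-10


class TestConservation:
    def test_nve_energy_drift_constrained_dimer(self, dimer):
        """Rotating constrained dimer: symplectic integrator, tiny drift."""
        topo, conf = dimer
        spec = _dimer_spec(conf)
        initialize_velocities(conf, 300, np.random.default_rng(5), spec)
        res = run_nvt(topo, conf, 20000, 0.5, None, spec, target_D=1.2,
                      record_frames=False)
        t_ps = res.steps * 0.5 / 1000.0
        drift = abs(np.polyfit(t_ps, res.e_total, 1)[0])
        assert drift < 1e-4

    def test_nve_energy_drift_free_cluster(self):
        topo, conf = make_random_cluster(6, seed=8)
        initialize_velocities(conf, 50, np.random.default_rng(2))
        res = run_nvt(topo, conf, 20000, 0.5, record_frames=False)
        t_ps = res.steps * 0.5 / 1000.0
        drift = abs(np.polyfit(t_ps, res.e_total, 1)[0])
        assert drift < 1e-3

    def test_nhc_conserved_quantity_drift(self, dimer):
        topo, conf = dimer
        spec = _dimer_spec(conf)
        initialize_velocities(conf, 300, np.random.default_rng(6), spec)
        ts = NoseHooverChain(300.0, chain_length=3, tau=1000.0)
        res = run_nvt(topo, conf, 20000, 0.5, ts, spec, target_D=1.2,
                      record_frames=False)
        t_ps = res.steps * 0.5 / 1000.0
        drift = abs(np.polyfit(t_ps, res.conserved, 1)[0])
        assert drift < 1e-3

    def test_seeded_runs_bit_reproducible(self, dimer):
        results = []
        for _ in range(2):
            topo, conf = make_harmonic_dimer()
            spec = _dimer_spec(conf)
            initialize_velocities(conf, 300, np.random.default_rng(7), spec)
            ts = Langevin(300.0, seed=7)
            res = run_nvt(topo, conf, 500, 0.5, ts, spec, target_D=1.1,
                          record_frames=False)
            results.append((conf.positions.copy(), res.lambdas.copy()))
        np.testing.assert_array_equal(results[0][0], results[1][0])
        np.testing.assert_array_equal(results[0][1], results[1][1])


class TestThermostats:
    def test_langevin_dimer_temperature(self, dimer):
        """25 ps constrained dimer at 300 K: equipartition within 3σ."""
        topo, conf = dimer
        spec = _dimer_spec(conf)
        initialize_velocities(conf, 300, np.random.default_rng(11), spec,
                              remove_com=False)
        ts = Langevin(300.0, gamma=0.01, seed=11)
        res = run_nvt(topo, conf, 50000, 0.5, ts, spec, target_D=1.2,
                      record_frames=False)
        temps = res.temperature[5000:]
        blocks = np.array_split(temps, 10)
        means = np.array([b.mean() for b in blocks])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(temps.mean() - 300.0) < 3 * se

    def test_nhc_controls_duplex_temperature(self, duplex_system, equi_spec):
        # start at 2x the target so equipartition into the potential
        # modes does not bias the early average low
        topo, conf, _ = duplex_system
        initialize_velocities(conf, 600, np.random.default_rng(3), equi_spec)
        ts = NoseHooverChain(300.0)
        res = run_nvt(topo, conf, 8000, 0.5, ts, equi_spec, record_frames=False)
        assert res.temperature[4000:].mean() == pytest.approx(300.0, rel=0.1)

    def test_zero_steps_rejected(self, dimer):
        topo, conf = dimer
        with pytest.raises(ValueError):
            run_nvt(topo, conf, 0)


class TestAnneal:
    def test_final_target_closed_form(self, dimer):
        topo, conf = dimer
        initialize_velocities(conf, 300, np.random.default_rng(1))
        ts = NoseHooverChain(300.0)
        _, schedule = anneal(topo, conf, 300.0, 0.99, 3000, 100,
                             thermostat=ts)
        assert schedule[-1] == pytest.approx(300.0 * 0.99**29)
        assert ts.target_T == pytest.approx(300.0 * 0.99**29)

    def test_thirty_thousand_step_schedule_endpoint(self):
        """Full-length annealing schedule: 300 K × 0.99^300."""
        n_rescale = 30000 // 100
        final = 300.0 * 0.99 ** np.arange(30000 // 100)[-1]
        assert final == pytest.approx(300.0 * 0.99 ** (n_rescale - 1))
        assert 300.0 * 0.99**300 == pytest.approx(14.7, abs=0.1)

    def test_factor_one_keeps_temperature(self, dimer):
        topo, conf = dimer
        initialize_velocities(conf, 300, np.random.default_rng(1))
        _, schedule = anneal(topo, conf, 300.0, 1.0, 500, 100)
        assert np.all(schedule == 300.0)

    def test_zero_steps_is_identity(self, dimer):
        topo, conf = dimer
        pos0 = conf.positions.copy()
        out, schedule = anneal(topo, conf, 300.0, 0.99, 0)
        np.testing.assert_array_equal(out.positions, pos0)
        assert len(schedule) == 0

    def test_factor_above_one_rejected(self, dimer):
        topo, conf = dimer
        with pytest.raises(ValueError):
            anneal(topo, conf, 300.0, 1.01, 100)


class TestZipUp:
    def test_schedule_endpoints_and_midpoint(self):
        assert zip_schedule(1.88, 1.56, 10000, 0) == pytest.approx(1.88)
        assert zip_schedule(1.88, 1.56, 10000, 5000) == pytest.approx(1.72)
        assert zip_schedule(1.88, 1.56, 10000, 10000) == pytest.approx(1.56)

    def test_constant_target_thermalizes(self, duplex_system, equi_spec):
        topo, conf, _ = duplex_system
        res = zip_up(topo, conf, equi_spec, 1.88, 1.88, steps=300, seed=2)
        assert np.abs(res.d_measured - 1.88).max() <= 1e-8
        assert res.temperature[150:].mean() > 100.0  # thermal, not frozen

    def test_short_ramp_reaches_endpoint(self, duplex_system, equi_spec):
        topo, conf, _ = duplex_system
        res = zip_up(topo, conf, equi_spec, 1.88, 1.80, steps=800, seed=3)
        assert dynamic_distance(equi_spec, conf.positions) == pytest.approx(
            1.80, abs=1e-8
        )

    def test_individual_bonds_free_to_differ(self, duplex_system, equi_spec):
        from dyndist.cv import pair_distances

        topo, conf, _ = duplex_system
        zip_up(topo, conf, equi_spec, 1.88, 1.82, steps=500, seed=4)
        d = pair_distances(equi_spec, conf.positions)
        assert d.std() > 1e-3  # not rigidly uniform

    def test_mismatched_start_rejected(self, duplex_system, equi_spec):
        topo, conf, _ = duplex_system
        with pytest.raises(ValueError, match="0.5"):
            zip_up(topo, conf, equi_spec, 3.0, 1.56, steps=100)

    def test_upward_ramp_rejected(self, duplex_system, equi_spec):
        topo, conf, _ = duplex_system
        with pytest.raises(ValueError):
            zip_up(topo, conf, equi_spec, 1.56, 1.88, steps=100)
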