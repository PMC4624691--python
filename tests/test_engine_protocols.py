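"""Minimizer, Langevin integrator, and the staged protocols."""

import numpy as np
import pytest

from molfrag import (
    EngineError,
    EnsembleRestraintProvider,
    FragmentSpec,
    HistogramRestraint,
    InternalForceField,
    Langevin,
    NonbondedProvider,
    PositionalRestraintProvider,
    Protocol,
    RestraintProvider,
    SimulationState,
    SoftCoreParams,
    Stage,
    anchor_restraints,
    build_bridge_fragment,
    build_label_fragment,
    group_fragments,
    make_target_histogram,
    metal_bridge_restraints,
    minimize,
    run_refinement,
    run_restrained_ensemble,
    secondary_structure_restraints,
)
from molfrag.engine import ACC_CONV, KB, ForceProvider, evaluate_all, masses_for
from molfrag.fixtures import FixtureRecipe, make_free_probes, make_label_host
from molfrag.nonbonded import ExclusionModel
from molfrag.restraints import RampSchedule


class Quadratic(ForceProvider):
    """E = k sum x^2 about the origin."""

    name = "quadratic"

    def __init__(self, k=3.0):
        self.k = k

    def evaluate(self, p, step=0):
        return self.k * float(np.sum(p * p)), -2.0 * self.k * p


class TestMinimize:
    def test_already_at_minimum_returns_immediately(self):
        res = minimize(np.zeros((2, 3)), [Quadratic()], max_steps=100, tol=1e-8)
        assert res.converged
        assert res.energy == pytest.approx(0.0, abs=1e-20)

    def test_1d_quadratic_converges(self):
        x0 = np.array([[1.0, 0.0, 0.0]])
        res = minimize(x0, [Quadratic(k=2.0)], max_steps=500, tol=1e-8)
        assert np.abs(res.positions).max() < 1e-6

    def test_energy_monotone_nonincreasing(self, bridged_bundle):
        system, frag_cd, _, model = bridged_bundle
        from molfrag import FragmentKind

        terms = metal_bridge_restraints(FragmentKind.CD_BRIDGE, system, frag_cd)
        res = minimize(system.positions,
                       [RestraintProvider(terms), InternalForceField(system)],
                       max_steps=2000, tol=1e-8)
        for a, b in zip(res.energies, res.energies[1:]):
            assert b <= a + 1e-9

    def test_nan_energy_names_provider(self):
        class Bad(ForceProvider):
            name = "bad_provider"

            def evaluate(self, p, step=0):
                return float("nan"), np.zeros_like(p)

        with pytest.raises(EngineError, match="bad_provider"):
            minimize(np.ones((1, 3)), [Bad()], max_steps=10)


class TestLangevin:
    def test_velocity_decay_closed_form(self):
        st = SimulationState(positions=np.zeros((1, 3)),
                             velocities=np.array([[0.2, 0.0, 0.0]]))
        gamma, dt = 0.03, 1.0
        L = Langevin(np.array([12.0]), dt=dt, T=0.0, friction=gamma)
        L.step(st, [])
        assert st.velocities[0, 0] == pytest.approx(0.2 * np.exp(-gamma * dt), rel=1e-12)

    def test_same_seed_bitwise_identical(self):
        def traj(seed):
            st = SimulationState(positions=np.array([[0.5, 0.1, -0.2]]))
            L = Langevin(np.array([12.0]), dt=1.0, T=300.0, friction=0.05,
                         rng=np.random.default_rng(seed))
            out = []
            forces = None
            for _ in range(100):
                forces = L.step(st, [Quadratic()], forces)
                out.append(st.positions.copy())
            return np.array(out)

        np.testing.assert_array_equal(traj(11), traj(11))
        assert np.abs(traj(11) - traj(12)).max() > 0.0

    def test_energy_conservation_frictionless(self):
        """T=0, friction=0 reduces BAOAB to velocity Verlet: harmonic
        oscillator total energy drifts < 1e-4 relative over 1e5 steps."""
        k = 5.0
        prov = [Quadratic(k=k)]
        st = SimulationState(positions=np.array([[0.5, 0.0, 0.0]]))
        L = Langevin(np.array([12.0]), dt=1.0, T=0.0, friction=0.0)
        forces = None
        e0 = None
        drift = 0.0
        for _ in range(100_000):
            forces = L.step(st, prov, forces)
            ke = 0.5 * 12.0 * float(np.sum(st.velocities**2)) / ACC_CONV
            pe = k * float(np.sum(st.positions**2))
            e = ke + pe
            if e0 is None:
                e0 = e
            drift = max(drift, abs(e - e0) / e0)
        assert drift < 1e-4

    def test_equipartition_of_harmonic_oscillator(self):
        """Under E = k x^2, <x^2> = kB T / (2 k) within 5%."""
        k, T = 5.0, 300.0
        prov = [Quadratic(k=k)]
        st = SimulationState(positions=np.zeros((1, 3)))
        L = Langevin(np.array([12.0]), dt=1.0, T=T, friction=0.05,
                     rng=np.random.default_rng(11))
        forces = None
        acc, n = 0.0, 0
        for i in range(200_000):
            forces = L.step(st, prov, forces)
            if i > 20_000:
                acc += float(np.sum(st.positions**2))
                n += 3
        assert acc / n == pytest.approx(KB * T / (2 * k), rel=0.05)


class TestRefinementProtocol:
    def test_zero_stage_protocol_is_identity(self, bundle_copy):
        system, _ = bundle_copy
        pos0 = system.positions.copy()
        rep = run_refinement(system, [], {"internal": InternalForceField(system)},
                             Protocol(stages=[]))
        np.testing.assert_array_equal(rep.final_state.positions, pos0)

    def test_ramp_to_zero_reproduces_plain_dynamics(self, bundle_copy):
        """With restraints ramped to zero the trajectory is identical to
        running without the restraint provider (same seeds)."""
        system, catalog = bundle_copy
        frag = build_bridge_fragment(
            system, FragmentSpec(kind="cd_bridge", host_sites=catalog[0].sites))
        from molfrag import FragmentKind

        terms = metal_bridge_restraints(FragmentKind.CD_BRIDGE, system, frag,
                                        ramp_id="off")
        ramps = {"off": RampSchedule([(0, 10**9, 0.0, 0.0)])}
        stages = [Stage(mode="dynamics", n_steps=50, temperature=100.0)]

        sys_a = system.copy()
        rep_a = run_refinement(
            sys_a, [frag],
            {"internal": InternalForceField(sys_a),
             "restraints": RestraintProvider(terms, ramps)},
            Protocol(stages=stages, seed=7))
        sys_b = system.copy()
        rep_b = run_refinement(
            sys_b, [frag], {"internal": InternalForceField(sys_b)},
            Protocol(stages=stages, seed=7))
        np.testing.assert_array_equal(rep_a.final_state.positions,
                                      rep_b.final_state.positions)

    def test_bridge_refinement_closes_bridges(self, bundle):
        """Scaled bundle protocol: minimization, ramped restrained
        dynamics, final minimization; every active bridge ends with
        C-beta--C-beta <= 9 A and small anchor deviations."""
        system, catalog = bundle
        system = system.copy()
        frags, terms = [], []
        for entry in catalog[:2]:  # two Cd bridges
            frag = build_bridge_fragment(
                system, FragmentSpec(kind=entry.kind, host_sites=entry.sites))
            frags.append(frag)
            terms += metal_bridge_restraints(entry.kind, system, frag, ramp_id="on")
            terms += anchor_restraints(frag, 50.0)
        terms += secondary_structure_restraints(
            system, [(102, 111), (202, 211), (302, 311), (402, 411)], k=5.0)
        model = ExclusionModel.from_system(system, frags)
        providers = {
            "internal": InternalForceField(system),
            "nonbonded": NonbondedProvider(system, model, SoftCoreParams(delta=1.0)),
            "restraints": RestraintProvider(terms, {"on": RampSchedule([(0, 2000, 0.0, 1.0)])}),
        }
        proto = Protocol(stages=[
            Stage(mode="minimize", n_steps=500, tol=1e-4),
            Stage(mode="dynamics", n_steps=12000, temperature=300.0, friction=0.01),
            Stage(mode="minimize", n_steps=500, tol=1e-4),
        ], seed=3)
        rep = run_refinement(system, frags, providers, proto)
        pos = rep.final_state.positions
        for f in frags:
            cbs = [i for i in f.atoms if system.name[i] == "CB"]
            assert np.linalg.norm(pos[cbs[0]] - pos[cbs[1]]) <= 9.0
        assert rep.anchor_max < 0.5
        assert set(rep.bridge_stats.columns.get_level_values(0)) >= {"ligand_ion", "cb_cb"}


class TestEnsembleProtocol:
    def test_self_consistent_targets_keep_u_re_near_zero(self):
        """Targets equal to the ensemble's own histograms: U_RE stays
        near zero during production."""
        system, ii, jj = make_free_probes(
            FixtureRecipe(kind="free_probes", n_probes_per_site=10, box=35.0, seed=9))
        from molfrag.histogram import smoothed_histogram

        d = np.linalg.norm(
            system.positions[ii][:, None, :] - system.positions[jj][None, :, :], axis=-1)
        self_target = smoothed_histogram(d.ravel(), 1.1, 1.0, 60)
        hr = HistogramRestraint((1, 2), ii, jj, self_target)
        e0, _ = hr.energy_forces(system.positions)
        assert e0 == pytest.approx(0.0, abs=1e-18)
        prov = {"ensemble": EnsembleRestraintProvider([hr])}
        rep = run_restrained_ensemble(
            system, [], [hr], prov, prov,
            n_equil=0, n_prod=2000, temperature=20.0, friction=0.05, seed=2)
        e1, _ = hr.energy_forces(rep.final_state.positions)
        assert e1 < 0.5  # thermal fluctuation scale, far below a mismatch

    def test_unlabeled_site_in_target_rejected(self):
        system, sites = make_label_host(
            FixtureRecipe(kind="globular_label_host", n_sites=2,
                          site_min_separation=20.0, n_residues=10))
        ensembles = [
            build_label_fragment(
                system, FragmentSpec(kind="dummy_label", host_sites=(s,), n_copies=2),
                seed=s)
            for s in sites
        ]
        tgt = make_target_histogram([(20.0, 1.0)], 2.0, 1.0, 60)
        hr = HistogramRestraint((sites[0], 9999), ensembles[0].probe_atoms,
                                ensembles[1].probe_atoms, tgt)
        with pytest.raises(ValueError, match="unlabeled site"):
            run_restrained_ensemble(system, ensembles, [hr], {}, {},
                                    n_equil=0, n_prod=0)

    def test_dummy_label_remd_converges_to_bimodal_target(self):
        """Dummy spin-labels on the scaffold host: cold production drives
        the time-averaged histogram onto an achievable bimodal target
        (RMS bin deviation < 0.01 1/A)."""
        system, sites = make_label_host(
            FixtureRecipe(kind="globular_label_host", n_sites=2,
                          site_min_separation=30.0, n_residues=12))
        ensembles = [
            build_label_fragment(
                system, FragmentSpec(kind="dummy_label", host_sites=(s,), n_copies=10),
                seed=s)
            for s in sites
        ]
        group_fragments(system, ensembles, cutoff=12.0)
        frags = [c for e in ensembles for c in e.copies]
        model = ExclusionModel.from_system(system, frags)
        terms = []
        for e in ensembles:
            for c in e.copies:
                terms += anchor_restraints(c, 10.0)
        tgt = make_target_histogram([(27.0, 0.5), (33.0, 0.5)], 2.5, 1.0, 60,
                                    site_distance=30.0, reach=4.6)
        hr = HistogramRestraint((sites[0], sites[1]), ensembles[0].probe_atoms,
                                ensembles[1].probe_atoms, tgt)
        host = np.nonzero(system.fragment_id == 0)[0]
        base = {
            "internal": InternalForceField(system),
            "nonbonded": NonbondedProvider(system, model, SoftCoreParams(delta=1.0)),
            "restraints": RestraintProvider(terms),
            "positional": PositionalRestraintProvider(host, 100.0, system.positions),
        }
        prod = dict(base)
        prod["ensemble"] = EnsembleRestraintProvider([hr])
        rep = run_restrained_ensemble(
            system, ensembles, [hr], base, prod,
            n_equil=1000, n_prod=30000, temperature=50.0, friction=0.01, seed=5)
        assert rep.rms_deviation[(sites[0], sites[1])] < 0.01
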