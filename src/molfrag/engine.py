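"""Minimizer, Langevin integrator and staged refinement protocols.

Units: positions in A, energies in kcal/mol, forces in kcal/mol/A,
masses in amu, time in fs, temperatures in K. The acceleration
conversion constant turns kcal/mol/A/amu into A/fs^2.

The integrator is the BAOAB splitting of Langevin dynamics: accurate
configurational sampling at the 1 fs timestep the toy force field uses
(no constraint solver, so no 2 fs + SHAKE). With zero friction and
temperature it reduces to velocity Verlet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize as _scipy_minimize

from . import geometry
from .fragments import CopyEnsemble, MolecularFragment
from .histogram import HistogramRestraint
from .nonbonded import ExclusionModel, SoftCoreParams, neighbor_pairs, total_nonbonded
from .restraints import RampSchedule, RestraintTerm, restraint_energy_forces
from .system import AtomicSystem, write_pdb

KB = 0.0019872041  # kcal/mol/K
ACC_CONV = 4.184e-4  # (kcal/mol/A)/amu -> A/fs^2

ELEMENT_MASS = {
    "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008,
    "CD": 112.41, "MG": 24.305, "ZN": 65.38, "P": 30.974,
}


class EngineError(RuntimeError):
    pass


def masses_for(system: AtomicSystem) -> np.ndarray:
    return np.array([ELEMENT_MASS.get(e.upper(), 12.011) for e in system.element])


# ------------------------------------------------------------- providers

class ForceProvider:
    """Interface: evaluate(positions, step) -> (energy, forces)."""

    name = "provider"

    def evaluate(self, positions: np.ndarray, step: int = 0):  # pragma: no cover
        raise NotImplementedError


class InternalForceField(ForceProvider):
    """Harmonic bonds/angles and cosine dihedrals of the AtomicSystem."""

    name = "internal"

    def __init__(self, system: AtomicSystem):
        self.system = system

    def evaluate(self, positions, step=0):
        s = self.system
        energy = 0.0
        forces = np.zeros_like(positions)
        if len(s.bonds):
            d = positions[s.bonds[:, 0]] - positions[s.bonds[:, 1]]
            r = np.linalg.norm(d, axis=1)
            k, b0 = s.bond_params[:, 0], s.bond_params[:, 1]
            dev = r - b0
            energy += float(np.sum(k * dev * dev))
            with np.errstate(divide="ignore", invalid="ignore"):
                g = np.where(r > 1e-12, 2.0 * k * dev / r, 0.0)
            fv = -g[:, None] * d
            np.add.at(forces, s.bonds[:, 0], fv)
            np.add.at(forces, s.bonds[:, 1], -fv)
        if len(s.angles):
            idx = s.angles
            th, g1, g2, g3 = geometry.angle_grad_batch(
                positions[idx[:, 0]], positions[idx[:, 1]], positions[idx[:, 2]]
            )
            k, th0 = s.angle_params[:, 0], s.angle_params[:, 1]
            dev = th - th0
            energy += float(np.sum(k * dev * dev))
            dE = (2.0 * k * dev)[:, None]
            np.add.at(forces, idx[:, 0], -dE * g1)
            np.add.at(forces, idx[:, 1], -dE * g2)
            np.add.at(forces, idx[:, 2], -dE * g3)
        if len(s.dihedrals):
            idx = s.dihedrals
            phi, g1, g2, g3, g4 = geometry.dihedral_grad_batch(
                positions[idx[:, 0]], positions[idx[:, 1]],
                positions[idx[:, 2]], positions[idx[:, 3]]
            )
            k, n, delta = (s.dihedral_params[:, 0], s.dihedral_params[:, 1],
                           s.dihedral_params[:, 2])
            energy += float(np.sum(k * (1.0 + np.cos(n * phi - delta))))
            dE = (-k * n * np.sin(n * phi - delta))[:, None]
            np.add.at(forces, idx[:, 0], -dE * g1)
            np.add.at(forces, idx[:, 1], -dE * g2)
            np.add.at(forces, idx[:, 2], -dE * g3)
            np.add.at(forces, idx[:, 3], -dE * g4)
        return float(energy), forces


class NonbondedProvider(ForceProvider):
    """Switched LJ + Coulomb with exclusions and a skin-buffered
    neighbor list rebuilt on large displacements."""

    name = "nonbonded"

    def __init__(self, system: AtomicSystem, model: ExclusionModel,
                 params: SoftCoreParams, skin: float = 2.0):
        self.system = system
        self.model = model
        self.params = params
        self.skin = skin
        self._pairs = None
        self._ref_positions = None

    def _refresh(self, positions):
        if self._pairs is not None and self._ref_positions is not None:
            disp = np.linalg.norm(positions - self._ref_positions, axis=1).max()
            if disp < 0.5 * self.skin:
                return
        saved = self.system.positions
        self.system.positions = positions
        self._pairs = neighbor_pairs(self.system, self.params.cutoff + self.skin)
        self.system.positions = saved
        self._ref_positions = positions.copy()

    def evaluate(self, positions, step=0):
        self._refresh(positions)
        saved = self.system.positions
        self.system.positions = positions
        try:
            e, f = total_nonbonded(self.system, self.model, self.params, pairs=self._pairs)
        finally:
            self.system.positions = saved
        return e, f


class RestraintProvider(ForceProvider):
    name = "restraints"

    def __init__(self, terms: list[RestraintTerm],
                 schedules: dict[str, RampSchedule] | None = None,
                 name: str = "restraints"):
        self.terms = terms
        self.schedules = schedules or {}
        self.name = name

    def evaluate(self, positions, step=0):
        return restraint_energy_forces(self.terms, positions, step, self.schedules)


class PositionalRestraintProvider(ForceProvider):
    """E = k sum |x - x_ref|^2 over selected atoms."""

    name = "positional"

    def __init__(self, atom_indices, k: float, ref_positions: np.ndarray):
        self.idx = np.asarray(atom_indices, dtype=np.int64)
        self.k = k
        self.ref = ref_positions[self.idx].copy()

    def evaluate(self, positions, step=0):
        d = positions[self.idx] - self.ref
        energy = self.k * float(np.sum(d * d))
        forces = np.zeros_like(positions)
        forces[self.idx] = -2.0 * self.k * d
        return energy, forces


class EnsembleRestraintProvider(ForceProvider):
    """Sum of histogram restraints over all configured site pairs."""

    name = "ensemble_histogram"

    def __init__(self, restraints: list[HistogramRestraint]):
        self.restraints = restraints

    def evaluate(self, positions, step=0):
        energy = 0.0
        forces = np.zeros_like(positions)
        for r in self.restraints:
            e, f = r.energy_forces(positions)
            energy += e
            forces += f
        return energy, forces


def evaluate_all(providers, positions, step=0):
    energy = 0.0
    forces = np.zeros_like(positions)
    for p in providers:
        e, f = p.evaluate(positions, step)
        if not np.isfinite(e) or not np.all(np.isfinite(f)):
            raise EngineError(f"non-finite energy/forces from provider {p.name!r}")
        energy += e
        forces += f
    return energy, forces


# ------------------------------------------------------------ state

@dataclass
class SimulationState:
    positions: np.ndarray
    velocities: np.ndarray | None = None
    step: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)


def maxwell_boltzmann_velocities(masses, T, rng) -> np.ndarray:
    sigma = np.sqrt(KB * max(T, 0.0) * ACC_CONV / masses)
    return rng.standard_normal((len(masses), 3)) * sigma[:, None]


# --------------------------------------------------------- minimizer

@dataclass
class MinimizationResult:
    positions: np.ndarray
    energy: float
    max_force: float
    n_iter: int
    energies: list[float]
    converged: bool


def minimize(
    positions: np.ndarray,
    providers,
    max_steps: int = 5000,
    tol: float = 1e-6,
    step: int = 0,
) -> MinimizationResult:
    """L-BFGS minimization to max-|force| tolerance.

    The line search guarantees a monotone non-increasing energy over
    accepted iterates; NaN energies abort with the offending provider's
    name.
    """
    shape = positions.shape
    energies: list[float] = []
    last = {"e": np.inf}

    def objective(x):
        e, f = evaluate_all(providers, x.reshape(shape), step)
        last["e"] = float(e)
        return e, -f.ravel()

    def callback(xk):
        # energy of the accepted iterate: the line search's final
        # evaluation is at xk, so the cached value matches
        energies.append(last["e"])

    res = _scipy_minimize(
        objective,
        positions.ravel(),
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": max_steps, "gtol": tol, "ftol": 1e-16, "maxcor": 20},
    )
    final = res.x.reshape(shape)
    e, f = evaluate_all(providers, final, step)
    return MinimizationResult(
        positions=final,
        energy=float(e),
        max_force=float(np.abs(f).max()) if f.size else 0.0,
        n_iter=int(res.nit),
        energies=energies,
        converged=bool(np.abs(f).max() <= tol) if f.size else True,
    )


# --------------------------------------------------------- integrator

class Langevin:
    """BAOAB Langevin integrator.

    friction is in 1/fs; with T=0 and zero forces a full step maps
    v -> v * exp(-friction * dt).
    """

    def __init__(self, masses: np.ndarray, dt: float = 1.0, T: float = 300.0,
                 friction: float = 0.01, rng: np.random.Generator | None = None):
        if dt <= 0:
            raise ValueError("dt must be positive")
        if T < 0:
            raise ValueError("temperature must be >= 0")
        self.m = masses[:, None]
        self.dt = dt
        self.T = T
        self.friction = friction
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.c1 = np.exp(-friction * dt)
        self.c2 = np.sqrt(max(0.0, 1.0 - self.c1 * self.c1) * KB * T * ACC_CONV) / np.sqrt(
            masses
        )[:, None]

    def step(self, state: SimulationState, providers, forces: np.ndarray | None = None):
        """Advance one step in place; returns the forces at the new
        positions (reusable as the next call's ``forces``)."""
        if forces is None:
            _, forces = evaluate_all(providers, state.positions, state.step)
        half = 0.5 * self.dt
        state.velocities += half * ACC_CONV * forces / self.m
        state.positions += half * state.velocities
        state.velocities = self.c1 * state.velocities + self.c2 * self.rng.standard_normal(
            state.positions.shape
        )
        state.positions += half * state.velocities
        _, forces = evaluate_all(providers, state.positions, state.step + 1)
        state.velocities += half * ACC_CONV * forces / self.m
        state.step += 1
        return forces


def langevin_step(state: SimulationState, providers, dt: float, T: float,
                  friction: float, rng: np.random.Generator, masses: np.ndarray):
    """One BAOAB update of ``state`` (convenience wrapper)."""
    return Langevin(masses, dt=dt, T=T, friction=friction, rng=rng).step(state, providers)


def run_dynamics(state, providers, masses, n_steps, dt=1.0, T=300.0, friction=0.01,
                 rng=None, observer=None, observe_every=10):
    integ = Langevin(masses, dt=dt, T=T, friction=friction, rng=rng)
    forces = None
    for _ in range(n_steps):
        forces = integ.step(state, providers, forces)
        if observer is not None and state.step % observe_every == 0:
            observer(state)
    return state


# --------------------------------------------------------- protocols

@dataclass
class Stage:
    mode: str  # "minimize" | "dynamics"
    n_steps: int
    temperature: float = 300.0
    dt: float = 1.0
    friction: float = 0.01
    tol: float = 1e-4
    providers: list[str] = field(default_factory=list)  # names; empty = all

    def __post_init__(self):
        if self.mode not in ("minimize", "dynamics"):
            raise ValueError(f"unknown stage mode {self.mode!r}")
        if self.n_steps < 0:
            raise ValueError("stage step count must be >= 0")
        if self.temperature < 0:
            raise ValueError("stage temperature must be >= 0")


@dataclass
class Protocol:
    stages: list[Stage]
    seed: int = 0


def _select(providers: dict[str, ForceProvider], names: list[str]):
    if not names:
        return list(providers.values())
    missing = [n for n in names if n not in providers]
    if missing:
        raise KeyError(f"stage references unknown providers {missing}")
    return [providers[n] for n in names]


@dataclass
class RefinementReport:
    bridge_stats: pd.DataFrame
    anchor_max: float
    energy_log: pd.DataFrame
    final_state: SimulationState


def _bridge_measurements(system, fragments, positions):
    """Instantaneous bridge geometry: ligand-ion distances and
    C-beta--C-beta separation per bridge fragment."""
    from .fragments import COORDINATING_ATOM

    rows = []
    for f in fragments:
        if f.bridging_ion is None and f.kind.value != "salt_bridge":
            continue
        entry = {"group": f.exclusion_group, "kind": f.kind.value}
        if f.kind.value == "salt_bridge":
            nz = [i for i in f.atoms if system.name[i] == "NZ"][0]
            oe2 = [i for i in f.atoms if system.name[i] == "OE2"][0]
            entry["ligand_ion"] = float(np.linalg.norm(positions[nz] - positions[oe2]))
        else:
            coord = COORDINATING_ATOM[f.kind]
            ligs = [i for i in f.atoms if system.name[i] == coord]
            ion = f.bridging_ion
            entry["ligand_ion"] = float(
                np.mean([np.linalg.norm(positions[i] - positions[ion]) for i in ligs])
            )
        cbs = [i for i in f.atoms if system.name[i] == "CB"]
        if len(cbs) == 2:
            entry["cb_cb"] = float(np.linalg.norm(positions[cbs[0]] - positions[cbs[1]]))
        rows.append(entry)
    return rows


def run_refinement(
    system: AtomicSystem,
    fragments: list[MolecularFragment],
    providers: dict[str, ForceProvider],
    protocol: Protocol,
    *,
    masses: np.ndarray | None = None,
    report_fraction: float = 0.25,
    out_pdb: str | Path | None = None,
    energy_log_path: str | Path | None = None,
) -> RefinementReport:
    """Run the staged bridge-refinement protocol.

    Stages execute in order; dynamics stages sample bridge geometry over
    their last ``report_fraction`` so the report carries mean +/- SD of
    the ligand-ion and C-beta--C-beta distances, plus the worst anchor
    deviation at the end.
    """
    masses = masses if masses is not None else masses_for(system)
    rng = np.random.default_rng(protocol.seed)
    state = SimulationState(positions=system.positions.copy(), seed=protocol.seed)
    log_rows: list[dict] = []
    samples: list[dict] = []
    for si, stage in enumerate(protocol.stages):
        active = _select(providers, stage.providers)
        if stage.mode == "minimize":
            res = minimize(state.positions, active, max_steps=stage.n_steps, tol=stage.tol,
                           step=state.step)
            state.positions = res.positions
            state.velocities = np.zeros_like(state.positions)
            log_rows.append({"stage": si, "step": state.step, "energy": res.energy,
                             "mode": "minimize"})
        else:
            state.velocities = maxwell_boltzmann_velocities(masses, stage.temperature, rng)
            integ = Langevin(masses, dt=stage.dt, T=stage.temperature,
                             friction=stage.friction, rng=rng)
            sample_from = stage.n_steps - max(1, int(report_fraction * stage.n_steps))
            forces = None
            for it in range(stage.n_steps):
                forces = integ.step(state, active, forces)
                if it % 500 == 0:
                    e, _ = evaluate_all(active, state.positions, state.step)
                    log_rows.append({"stage": si, "step": state.step, "energy": e,
                                     "mode": "dynamics"})
                if si == len(protocol.stages) - 1 and it >= sample_from and it % 10 == 0:
                    for row in _bridge_measurements(system, fragments, state.positions):
                        samples.append(row)
    system.positions = state.positions.copy()
    if not samples:
        samples = _bridge_measurements(system, fragments, state.positions)
    stats = pd.DataFrame(samples)
    if len(stats):
        stats = stats.groupby(["group", "kind"]).agg(["mean", "std"]).reset_index()
    anchor_max = 0.0
    for f in fragments:
        for a, b in f.anchor_pairs:
            anchor_max = max(anchor_max,
                             float(np.linalg.norm(state.positions[a] - state.positions[b])))
    log = pd.DataFrame(log_rows)
    if out_pdb is not None:
        write_pdb(system, out_pdb)
    if energy_log_path is not None:
        log.to_csv(energy_log_path, sep="\t", index=False)
    return RefinementReport(bridge_stats=stats, anchor_max=anchor_max,
                            energy_log=log, final_state=state)


@dataclass
class EnsembleReport:
    histograms: dict[tuple[int, int], np.ndarray]  # time-averaged h per pair
    rms_deviation: dict[tuple[int, int], float]
    energy_log: pd.DataFrame
    final_state: SimulationState


def run_restrained_ensemble(
    system: AtomicSystem,
    ensembles: list[CopyEnsemble],
    hist_restraints: list[HistogramRestraint],
    providers_equil: dict[str, ForceProvider],
    providers_prod: dict[str, ForceProvider],
    *,
    n_equil: int = 2000,
    n_prod: int = 1000,
    dt: float = 1.0,
    temperature: float = 300.0,
    friction: float = 0.01,
    seed: int = 0,
    masses: np.ndarray | None = None,
    sample_every: int = 10,
) -> EnsembleReport:
    """Equilibrate without the histogram energy, then run production
    with it, accumulating the time-averaged simulated histogram and its
    RMS bin deviation from the target for every restrained pair."""
    if ensembles:
        sites = {e.site for e in ensembles}
        for r in hist_restraints:
            for s in r.site_pair:
                if s not in sites:
                    raise ValueError(f"histogram restraint references unlabeled site {s}")
    masses = masses if masses is not None else masses_for(system)
    rng = np.random.default_rng(seed)
    state = SimulationState(positions=system.positions.copy(), seed=seed)
    state.velocities = maxwell_boltzmann_velocities(masses, temperature, rng)
    log_rows = []
    integ = Langevin(masses, dt=dt, T=temperature, friction=friction, rng=rng)
    eq = list(providers_equil.values())
    forces = None
    for it in range(n_equil):
        forces = integ.step(state, eq, forces)
        if it % 100 == 0:
            e, _ = evaluate_all(eq, state.positions, state.step)
            log_rows.append({"phase": "equil", "step": state.step, "energy": e})
    prod = list(providers_prod.values())
    acc = {r.site_pair: np.zeros(r.n_bins) for r in hist_restraints}
    n_acc = 0
    forces = None
    burn_in = n_prod // 4  # histogram averages discard the onset transient
    for it in range(n_prod):
        forces = integ.step(state, prod, forces)
        if it >= burn_in and it % sample_every == 0:
            for r in hist_restraints:
                acc[r.site_pair] += r.histogram(state.positions).values
            n_acc += 1
        if it % 100 == 0:
            e, _ = evaluate_all(prod, state.positions, state.step)
            log_rows.append({"phase": "prod", "step": state.step, "energy": e})
    system.positions = state.positions.copy()
    histograms = {}
    rms = {}
    for r in hist_restraints:
        avg = acc[r.site_pair] / max(n_acc, 1)
        histograms[r.site_pair] = avg
        rms[r.site_pair] = float(np.sqrt(np.mean((avg - r.target.values) ** 2)))
    return EnsembleReport(
        histograms=histograms,
        rms_deviation=rms,
        energy_log=pd.DataFrame(log_rows),
        final_state=state,
    )
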