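"""Harmonic restraints for bridges, anchors and secondary structure.

Convention: every harmonic term is E = k (x - x0)^2 with no factor of
one half, so a distance term with k = 50 kcal/mol/A^2 at 1 A deviation
costs 50 kcal/mol. Angular force constants are kcal/mol/rad^2;
equilibrium angles are accepted in degrees at the construction surface
and stored in radians. Dihedral and improper deviations are taken as
the minimal periodic difference in (-pi, pi].
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from . import geometry
from .fragments import COORDINATING_ATOM, MolecularFragment
from .system import AtomicSystem, FragmentKind

DEG = math.pi / 180.0


class RestraintKind(str, enum.Enum):
    BOND = "bond"
    ANGLE = "angle"
    DIHEDRAL = "dihedral"
    IMPROPER = "improper"
    ANCHOR = "anchor"


_ARITY = {
    RestraintKind.BOND: 2,
    RestraintKind.ANCHOR: 2,
    RestraintKind.ANGLE: 3,
    RestraintKind.DIHEDRAL: 4,
    RestraintKind.IMPROPER: 4,
}


@dataclass
class RestraintTerm:
    kind: RestraintKind
    atoms: tuple[int, ...]
    k: float
    x0: float  # A for bond/anchor, radians for angular kinds
    ramp_id: str | None = None

    def __post_init__(self) -> None:
        self.kind = RestraintKind(self.kind)
        if len(self.atoms) != _ARITY[self.kind]:
            raise ValueError(
                f"{self.kind.value} term needs {_ARITY[self.kind]} atoms, got {len(self.atoms)}"
            )
        if self.k <= 0:
            raise ValueError("force constant must be positive")

    @property
    def is_angular(self) -> bool:
        return self.kind in (RestraintKind.ANGLE, RestraintKind.DIHEDRAL, RestraintKind.IMPROPER)


@dataclass
class RampSchedule:
    """Piecewise-linear force-constant scaling over dynamics steps."""

    stages: list[tuple[int, int, float, float]]  # (start, end, scale_start, scale_end)

    def __post_init__(self) -> None:
        prev_end = None
        for s0, s1, a, b in self.stages:
            if s1 < s0 or a < 0 or b < 0:
                raise ValueError(f"invalid ramp stage {(s0, s1, a, b)}")
            if prev_end is not None and s0 < prev_end:
                raise ValueError("ramp stages must be ordered and non-overlapping")
            prev_end = s1

    def __call__(self, step: int) -> float:
        return ramp(self, step)


def ramp(schedule: RampSchedule, step: int) -> float:
    """Scale at ``step``: linear within stages, clamped outside them."""
    if not schedule.stages:
        return 1.0
    first = schedule.stages[0]
    if step <= first[0]:
        return first[2]
    for s0, s1, a, b in schedule.stages:
        if step <= s1:
            if step < s0:  # gap between stages: hold previous end value
                return last_b
            if s1 == s0:
                return b
            t = (step - s0) / (s1 - s0)
            return a + t * (b - a)
        last_b = b
    return schedule.stages[-1][3]


def _one(fragment: MolecularFragment, system: AtomicSystem, name: str,
         residue: int | None = None) -> int:
    hits = [
        int(i)
        for i in fragment.atoms
        if system.name[i] == name and (residue is None or system.residue_index[i] == residue)
    ]
    if not hits:
        raise KeyError(f"atom {name!r} not found in fragment (residue {residue})")
    if len(hits) > 1:
        raise KeyError(f"atom {name!r} ambiguous in fragment (residue {residue}): {hits}")
    return hits[0]


def metal_bridge_restraints(
    kind: FragmentKind,
    system: AtomicSystem,
    fragment: MolecularFragment,
    *,
    salt_k: float = 10.0,
    ramp_id: str | None = None,
) -> list[RestraintTerm]:
    """Bridge restraint terms for one fragment.

    Cd: two S-gamma--Cd bonds (k=10, 2.6 A) and the S-gamma--Cd--S-gamma
    angle (k=10, 180 deg). Mg: two O-delta2--Mg bonds (k=10, 2.1 A) and
    the 180 deg angle. Zn: two N-epsilon--Zn bonds (k=10, 2.1 A) plus,
    per histidine, the two ring angles (127.0 and 125.5 deg), the ring
    dihedral (180 deg) and two impropers (0 deg) that keep the ion in
    the imidazole plane, all with k=10. Salt bridge: one N-zeta--O-eps2
    distance restraint at 3.5 A with a configurable force constant.
    """
    kind = FragmentKind(kind)
    if fragment.kind != kind:
        raise ValueError(f"fragment was built as {fragment.kind.value}, not {kind.value}")
    terms: list[RestraintTerm] = []
    K = 10.0
    if kind == FragmentKind.SALT_BRIDGE:
        nz = _one(fragment, system, "NZ")
        oe2 = _one(fragment, system, "OE2")
        return [RestraintTerm(RestraintKind.BOND, (nz, oe2), salt_k, 3.5, ramp_id)]
    if fragment.bridging_ion is None:
        raise ValueError("bridge fragment has no bridging ion")
    ion = int(fragment.bridging_ion)
    res_a, res_b = fragment.target_residues
    coord = COORDINATING_ATOM[kind]
    ca_ = _one(fragment, system, coord, res_a)
    cb_ = _one(fragment, system, coord, res_b)
    if kind == FragmentKind.CD_BRIDGE:
        b0, theta0 = 2.6, 180.0
    else:
        b0, theta0 = 2.1, 180.0
    terms.append(RestraintTerm(RestraintKind.BOND, (ca_, ion), K, b0, ramp_id))
    terms.append(RestraintTerm(RestraintKind.BOND, (cb_, ion), K, b0, ramp_id))
    if kind in (FragmentKind.CD_BRIDGE, FragmentKind.MG_BRIDGE):
        terms.append(
            RestraintTerm(RestraintKind.ANGLE, (ca_, ion, cb_), K, theta0 * DEG, ramp_id)
        )
        return terms
    # Zn: ring-orientation terms per histidine
    for res, ne in ((res_a, ca_), (res_b, cb_)):
        ce1 = _one(fragment, system, "CE1", res)
        cd2 = _one(fragment, system, "CD2", res)
        cg = _one(fragment, system, "CG", res)
        terms.append(RestraintTerm(RestraintKind.ANGLE, (ce1, ne, ion), K, 127.0 * DEG, ramp_id))
        terms.append(RestraintTerm(RestraintKind.ANGLE, (cd2, ne, ion), K, 125.5 * DEG, ramp_id))
        terms.append(
            RestraintTerm(RestraintKind.DIHEDRAL, (cg, cd2, ne, ion), K, 180.0 * DEG, ramp_id)
        )
        terms.append(RestraintTerm(RestraintKind.IMPROPER, (ne, cd2, ce1, ion), K, 0.0, ramp_id))
        terms.append(RestraintTerm(RestraintKind.IMPROPER, (ne, ce1, cd2, ion), K, 0.0, ramp_id))
    return terms


def restraint_energy_forces(
    terms: list[RestraintTerm],
    positions: np.ndarray,
    step: int = 0,
    schedules: dict[str, RampSchedule] | None = None,
) -> tuple[float, np.ndarray]:
    """Total restraint energy and exact-gradient forces.

    Each term contributes k_eff (x - x0)^2 with k_eff = k * ramp(step)
    when the term carries a ramp_id (scale 1 otherwise).
    """
    schedules = schedules or {}
    energy = 0.0
    forces = np.zeros_like(positions)

    def k_eff(t: RestraintTerm) -> float:
        if t.ramp_id is None:
            return t.k
        sched = schedules.get(t.ramp_id)
        if sched is None:
            raise KeyError(f"restraint references undefined ramp {t.ramp_id!r}")
        return t.k * ramp(sched, step)

    pairs = [t for t in terms if t.kind in (RestraintKind.BOND, RestraintKind.ANCHOR)]
    angs = [t for t in terms if t.kind == RestraintKind.ANGLE]
    dihs = [t for t in terms
            if t.kind in (RestraintKind.DIHEDRAL, RestraintKind.IMPROPER)]

    if pairs:
        idx = np.array([t.atoms for t in pairs])
        k = np.array([k_eff(t) for t in pairs])
        x0 = np.array([t.x0 for t in pairs])
        d = positions[idx[:, 0]] - positions[idx[:, 1]]
        r = np.linalg.norm(d, axis=1)
        dev = r - x0
        energy += float(np.sum(k * dev * dev))
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(r > 1e-12, 2.0 * k * dev / r, 0.0)
        fv = -g[:, None] * d
        np.add.at(forces, idx[:, 0], fv)
        np.add.at(forces, idx[:, 1], -fv)
    if angs:
        idx = np.array([t.atoms for t in angs])
        k = np.array([k_eff(t) for t in angs])
        x0 = np.array([t.x0 for t in angs])
        th, g1, g2, g3 = geometry.angle_grad_batch(
            positions[idx[:, 0]], positions[idx[:, 1]], positions[idx[:, 2]]
        )
        dev = th - x0
        energy += float(np.sum(k * dev * dev))
        dE = (2.0 * k * dev)[:, None]
        np.add.at(forces, idx[:, 0], -dE * g1)
        np.add.at(forces, idx[:, 1], -dE * g2)
        np.add.at(forces, idx[:, 2], -dE * g3)
    if dihs:
        idx = np.array([t.atoms for t in dihs])
        k = np.array([k_eff(t) for t in dihs])
        x0 = np.array([t.x0 for t in dihs])
        phi, g1, g2, g3, g4 = geometry.dihedral_grad_batch(
            positions[idx[:, 0]], positions[idx[:, 1]],
            positions[idx[:, 2]], positions[idx[:, 3]]
        )
        dev = geometry.wrap_angles(phi - x0)
        energy += float(np.sum(k * dev * dev))
        dE = (2.0 * k * dev)[:, None]
        np.add.at(forces, idx[:, 0], -dE * g1)
        np.add.at(forces, idx[:, 1], -dE * g2)
        np.add.at(forces, idx[:, 2], -dE * g3)
        np.add.at(forces, idx[:, 3], -dE * g4)
    return float(energy), forces


def secondary_structure_restraints(
    system: AtomicSystem,
    helix_ranges: list[tuple[int, int]],
    k: float,
    *,
    phi0: float = -57.0,
    psi0: float = -47.0,
    ramp_id: str | None = None,
) -> list[RestraintTerm]:
    """Backbone phi/psi dihedral restraints at canonical alpha-helix
    targets over each residue span (inclusive). Spans must have full
    backbone including flanking C(i-1) and N(i+1)."""
    terms: list[RestraintTerm] = []
    for lo, hi in helix_ranges:
        if hi - lo + 1 < 4:
            raise ValueError(f"helix span ({lo},{hi}) shorter than 4 residues")
        for res in range(lo, hi + 1):
            try:
                c_prev = system.find_atom(res - 1, "C", fragment_id=0)
                n = system.find_atom(res, "N", fragment_id=0)
                ca = system.find_atom(res, "CA", fragment_id=0)
                c = system.find_atom(res, "C", fragment_id=0)
                n_next = system.find_atom(res + 1, "N", fragment_id=0)
            except KeyError as exc:
                raise ValueError(f"residue {res}: missing backbone atom for phi/psi: {exc}") from exc
            terms.append(
                RestraintTerm(RestraintKind.DIHEDRAL, (c_prev, n, ca, c), k, phi0 * DEG, ramp_id)
            )
            terms.append(
                RestraintTerm(RestraintKind.DIHEDRAL, (n, ca, c, n_next), k, psi0 * DEG, ramp_id)
            )
    return terms
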