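"""Ideal-geometry templates for fragment residues and labels.

Side chains are generated from a small internal z-matrix table with
ideal bond lengths and angles, anchored on the residue's own backbone
(N, CA, C). The table covers only the residue types that appear in
engineered bridge and label fragments; it is a synthetic, heavy-atom
reduction, not a transferable force field.

Charge states follow the bridge chemistry: residues coordinating a
metal ion are deprotonated and carry net charge -1 so that a
two-residue fragment plus a divalent ion is electrically neutral.
Lysine carries +1 and glutamate -1, making the salt-bridge fragment
neutral as well. Backbone partial charges sum to zero per residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry

DEG = math.pi / 180.0

# Backbone ideal internal geometry (lengths A, angles deg)
BB_N_CA = 1.458
BB_CA_C = 1.525
BB_C_O = 1.231
BB_C_N = 1.329
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8

# Backbone partial charges (sum to zero; no hydrogens in this model)
BACKBONE_CHARGES = {"N": -0.30, "CA": 0.30, "C": 0.50, "O": -0.50}

# Force constants of the internal force field
K_BOND = 250.0  # kcal/mol/A^2
K_ANGLE = 50.0  # kcal/mol/rad^2


@dataclass
class ZEntry:
    """One z-matrix row: place ``name`` using three previously placed atoms.

    dihedral(a, b, c, name) = phi, angle(b, c, name) = theta,
    |name - c| = bond. ``chi`` > 0 marks phi as the chi_n torsion of the
    side chain (perturbed when copies are spread).
    """

    name: str
    refs: tuple[str, str, str]  # (a, b, c)
    bond: float
    theta: float  # degrees
    phi: float  # degrees
    chi: int = 0


@dataclass
class ResidueTemplate:
    resname: str
    entries: list[ZEntry]
    charges: dict[str, float]
    bonds: list[tuple[str, str, float]]  # (i, j, b0); k = K_BOND
    angles: list[tuple[str, str, str, float]]  # (i, j, k, theta0 deg); k = K_ANGLE
    probe: str | None = None  # distance-probe atom (labels only)
    elements: dict[str, str] = field(default_factory=dict)

    @property
    def atom_names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def net_charge(self) -> float:
        return float(sum(self.charges.values()))


def _chain_entries(names, bonds, thetas, chis_from=1, first_refs=("C", "N", "CA")):
    """Helper for unbranched side chains CB-...: standard chi staircase."""
    entries = [ZEntry(names[0], first_refs, bonds[0], 110.5, 122.5)]
    prev = ["N", "CA", names[0]]
    for i, nm in enumerate(names[1:], start=1):
        entries.append(
            ZEntry(nm, tuple(prev), bonds[i], thetas[i - 1], -65.0, chi=chis_from + i - 1)
        )
        prev = [prev[1], prev[2], nm]
    return entries


def _mk_cys() -> ResidueTemplate:
    entries = _chain_entries(["CB", "SG"], [1.53, 1.82], [114.0])
    return ResidueTemplate(
        resname="CYS",
        entries=entries,
        charges={**BACKBONE_CHARGES, "CB": 0.0, "SG": -1.0},
        bonds=[("CA", "CB", 1.53), ("CB", "SG", 1.82)],
        angles=[
            ("N", "CA", "CB", 110.5),
            ("C", "CA", "CB", 110.1),
            ("CA", "CB", "SG", 114.0),
        ],
    )


def _mk_asp() -> ResidueTemplate:
    entries = _chain_entries(["CB", "CG"], [1.53, 1.52], [113.0])
    entries += [
        ZEntry("OD1", ("CA", "CB", "CG"), 1.26, 118.3, -30.0, chi=2),
        ZEntry("OD2", ("CA", "CB", "CG"), 1.26, 118.3, 150.0),
    ]
    return ResidueTemplate(
        resname="ASP",
        entries=entries,
        charges={**BACKBONE_CHARGES, "CB": 0.0, "CG": 0.20, "OD1": -0.60, "OD2": -0.60},
        bonds=[("CA", "CB", 1.53), ("CB", "CG", 1.52), ("CG", "OD1", 1.26), ("CG", "OD2", 1.26)],
        angles=[
            ("N", "CA", "CB", 110.5),
            ("C", "CA", "CB", 110.1),
            ("CA", "CB", "CG", 113.0),
            ("CB", "CG", "OD1", 118.3),
            ("CB", "CG", "OD2", 118.3),
            ("OD1", "CG", "OD2", 123.4),
        ],
    )


def _mk_his() -> ResidueTemplate:
    # Imidazolate ring as a regular pentagon (bond 1.355 A, interior 108 deg):
    # closes exactly under the harmonic ring terms.
    entries = _chain_entries(["CB", "CG"], [1.53, 1.50], [113.0])
    entries += [
        ZEntry("ND1", ("CA", "CB", "CG"), 1.355, 126.0, -90.0, chi=2),
        ZEntry("CE1", ("CB", "CG", "ND1"), 1.355, 108.0, 180.0),
        ZEntry("NE2", ("CG", "ND1", "CE1"), 1.355, 108.0, 0.0),
        ZEntry("CD2", ("ND1", "CE1", "NE2"), 1.355, 108.0, 0.0),
    ]
    ring = ["CG", "ND1", "CE1", "NE2", "CD2"]
    ring_bonds = [(ring[i], ring[(i + 1) % 5], 1.355) for i in range(5)]
    ring_angles = [(ring[i - 1], ring[i], ring[(i + 1) % 5], 108.0) for i in range(5)]
    return ResidueTemplate(
        resname="HIS",
        entries=entries,
        charges={
            **BACKBONE_CHARGES,
            "CB": 0.0,
            "CG": 0.0,
            "ND1": -0.50,
            "CE1": 0.0,
            "NE2": -0.50,
            "CD2": 0.0,
        },
        bonds=[("CA", "CB", 1.53), ("CB", "CG", 1.50)] + ring_bonds,
        angles=[
            ("N", "CA", "CB", 110.5),
            ("C", "CA", "CB", 110.1),
            ("CA", "CB", "CG", 113.0),
            ("CB", "CG", "ND1", 126.0),
            ("CB", "CG", "CD2", 126.0),
        ]
        + ring_angles,
    )


def _mk_lys() -> ResidueTemplate:
    names = ["CB", "CG", "CD", "CE", "NZ"]
    entries = _chain_entries(names, [1.53, 1.53, 1.53, 1.53, 1.49], [111.0, 111.0, 111.0, 111.0])
    bonds = [("CA", "CB", 1.53)] + [
        (names[i], names[i + 1], 1.53 if i < 3 else 1.49) for i in range(4)
    ]
    chain = ["CA"] + names
    angles = [("N", "CA", "CB", 110.5), ("C", "CA", "CB", 110.1)] + [
        (chain[i], chain[i + 1], chain[i + 2], 111.0) for i in range(4)
    ]
    return ResidueTemplate(
        resname="LYS",
        entries=entries,
        charges={**BACKBONE_CHARGES, "CB": 0.0, "CG": 0.0, "CD": 0.0, "CE": 0.25, "NZ": 0.75},
        bonds=bonds,
        angles=angles,
    )


def _mk_glu() -> ResidueTemplate:
    entries = _chain_entries(["CB", "CG", "CD"], [1.53, 1.53, 1.52], [111.0, 113.0])
    entries += [
        ZEntry("OE1", ("CB", "CG", "CD"), 1.26, 118.3, -30.0, chi=3),
        ZEntry("OE2", ("CB", "CG", "CD"), 1.26, 118.3, 150.0),
    ]
    return ResidueTemplate(
        resname="GLU",
        entries=entries,
        charges={
            **BACKBONE_CHARGES,
            "CB": 0.0,
            "CG": 0.0,
            "CD": 0.20,
            "OE1": -0.60,
            "OE2": -0.60,
        },
        bonds=[
            ("CA", "CB", 1.53),
            ("CB", "CG", 1.53),
            ("CG", "CD", 1.52),
            ("CD", "OE1", 1.26),
            ("CD", "OE2", 1.26),
        ],
        angles=[
            ("N", "CA", "CB", 110.5),
            ("C", "CA", "CB", 110.1),
            ("CA", "CB", "CG", 111.0),
            ("CB", "CG", "CD", 113.0),
            ("CG", "CD", "OE1", 118.3),
            ("CG", "CD", "OE2", 118.3),
            ("OE1", "CD", "OE2", 123.4),
        ],
    )


def _mk_trp() -> ResidueTemplate:
    # Crude planar indole: pentagon fused to a hexagon. Closure strain is
    # tolerated by the harmonic terms; the tryptophan of the salt-bridge
    # double mutant plays no restrained role.
    entries = _chain_entries(["CB", "CG"], [1.53, 1.50], [114.0])
    entries += [
        ZEntry("CD1", ("CA", "CB", "CG"), 1.37, 127.0, -90.0, chi=2),
        ZEntry("NE1", ("CB", "CG", "CD1"), 1.37, 110.0, 180.0),
        ZEntry("CE2", ("CG", "CD1", "NE1"), 1.37, 109.0, 0.0),
        ZEntry("CD2", ("CD1", "NE1", "CE2"), 1.41, 107.0, 0.0),
        ZEntry("CE3", ("NE1", "CE2", "CD2"), 1.40, 134.0, 180.0),
        ZEntry("CZ2", ("NE1", "CD2", "CE2"), 1.40, 122.0, 180.0),
        ZEntry("CZ3", ("CE2", "CD2", "CE3"), 1.40, 118.0, 180.0),
        ZEntry("CH2", ("CD2", "CE2", "CZ2"), 1.40, 117.0, 180.0),
    ]
    bonds = [
        ("CA", "CB", 1.53),
        ("CB", "CG", 1.50),
        ("CG", "CD1", 1.37),
        ("CD1", "NE1", 1.37),
        ("NE1", "CE2", 1.37),
        ("CE2", "CD2", 1.41),
        ("CD2", "CG", 1.43),
        ("CD2", "CE3", 1.40),
        ("CE3", "CZ3", 1.40),
        ("CZ3", "CH2", 1.40),
        ("CH2", "CZ2", 1.40),
        ("CZ2", "CE2", 1.40),
    ]
    angles = [
        ("N", "CA", "CB", 110.5),
        ("C", "CA", "CB", 110.1),
        ("CA", "CB", "CG", 114.0),
        ("CB", "CG", "CD1", 127.0),
        ("CG", "CD1", "NE1", 110.0),
        ("CD1", "NE1", "CE2", 109.0),
        ("NE1", "CE2", "CD2", 107.0),
        ("CE2", "CD2", "CG", 107.0),
        ("CD2", "CG", "CD1", 107.0),
        ("CE2", "CD2", "CE3", 118.0),
        ("CD2", "CE3", "CZ3", 118.0),
        ("CE3", "CZ3", "CH2", 121.0),
        ("CZ3", "CH2", "CZ2", 121.0),
        ("CH2", "CZ2", "CE2", 117.0),
        ("CZ2", "CE2", "CD2", 122.0),
    ]
    charges = {**BACKBONE_CHARGES}
    for nm in ["CB", "CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"]:
        charges[nm] = 0.0
    return ResidueTemplate("TRP", entries, charges, bonds, angles)


def _mk_mtssl() -> ResidueTemplate:
    # Simplified heavy-atom MTSSL side chain: disulfide tether plus a
    # reduced nitroxide head. The probe is the nitroxide oxygen ON,
    # roughly 7 A from CB at extended chi angles.
    names = ["CB", "SG", "SD", "CE", "C3", "N1", "ON"]
    bonds_len = [1.53, 1.82, 2.03, 1.82, 1.51, 1.40, 1.28]
    thetas = [114.0, 103.8, 103.8, 112.0, 114.0, 120.0]
    entries = _chain_entries(names, bonds_len, thetas)
    # the terminal N-O is not rotatable
    entries[-1].chi = 0
    chain = ["CA"] + names
    bonds = [(chain[i], chain[i + 1], bonds_len[i]) for i in range(7)]
    angles = [("N", "CA", "CB", 110.5), ("C", "CA", "CB", 110.1)] + [
        (chain[i], chain[i + 1], chain[i + 2], thetas[i]) for i in range(6)
    ]
    charges = {**BACKBONE_CHARGES}
    for nm in names:
        charges[nm] = 0.0
    return ResidueTemplate("R1A", entries, charges, bonds, angles, probe="ON")


def _mk_dummy() -> ResidueTemplate:
    # Single pseudo-atom on a soft tether from CA, standing in for the
    # whole label at roughly the reach of three side-chain bonds.
    entries = [ZEntry("DP", ("C", "N", "CA"), 4.6, 110.0, 122.5, chi=1)]
    return ResidueTemplate(
        resname="DUM",
        entries=entries,
        charges={**BACKBONE_CHARGES, "DP": 0.0},
        bonds=[("CA", "DP", 4.6)],
        angles=[],
        probe="DP",
        elements={"DP": "P"},
    )


TEMPLATES: dict[str, ResidueTemplate] = {
    "CYS": _mk_cys(),
    "ASP": _mk_asp(),
    "HIS": _mk_his(),
    "LYS": _mk_lys(),
    "GLU": _mk_glu(),
    "TRP": _mk_trp(),
    "R1A": _mk_mtssl(),
    "DUM": _mk_dummy(),
}

# Override the internal-force-field bond constant for the dummy tether:
# a stiff 4.6 A pseudo-bond would be unphysical.
DUMMY_TETHER_K = 5.0


def build_sidechain(template: ResidueTemplate, n: np.ndarray, ca: np.ndarray,
                    c: np.ndarray, chi_offsets: dict[int, float] | None = None
                    ) -> dict[str, np.ndarray]:
    """Place the template's side-chain atoms given backbone N, CA, C.

    ``chi_offsets`` maps chi index -> additional rotation (radians)
    applied to that torsion, used to spread label copies.
    """
    placed: dict[str, np.ndarray] = {"N": np.asarray(n, float),
                                     "CA": np.asarray(ca, float),
                                     "C": np.asarray(c, float)}
    offsets = chi_offsets or {}
    for e in template.entries:
        a, b, cref = (placed[r] for r in e.refs)
        phi = e.phi * DEG
        if e.chi and e.chi in offsets:
            phi += offsets[e.chi]
        placed[e.name] = geometry.place_atom(a, b, cref, e.bond, e.theta * DEG, phi)
    return {k: v for k, v in placed.items() if k not in ("N", "CA", "C")}


def n_chi(template: ResidueTemplate) -> int:
    return max((e.chi for e in template.entries), default=0)
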