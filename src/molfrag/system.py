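"""Core data model: atoms, bonded topology, PDB and histogram-table I/O.

The in-memory container is :class:`AtomicSystem`, a struct-of-arrays
record of atoms plus a deliberately small internal force field (harmonic
bonds and angles, cosine dihedrals, LJ + Coulomb handled elsewhere).
Every atom carries a ``fragment_id``: 0 for the host protein, a positive
integer naming the exclusion group of the molecular fragment it belongs
to.

PDB I/O is fixed-column (ATOM/HETATM records only). Exclusion-group
membership survives a round trip through the segment-identifier columns
(73-76, ``G<id>``), which also keeps files viewable when the number of
fragment copies exceeds the chain-identifier alphabet.
"""

from __future__ import annotations

import dataclasses
import enum
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class PDBFormatError(ValueError):
    """Malformed or unwritable PDB content."""


class HistogramError(ValueError):
    """Invalid distance-histogram table."""


# Minimal per-element nonbonded parameter table (epsilon kcal/mol,
# Rmin/2 Angstrom), CHARMM-like magnitudes. Used when parameters are not
# supplied explicitly, e.g. for atoms read back from a PDB file.
ELEMENT_LJ: dict[str, tuple[float, float]] = {
    "C": (0.070, 2.00),
    "N": (0.200, 1.85),
    "O": (0.120, 1.70),
    "S": (0.450, 2.00),
    "H": (0.046, 0.22),
    "CD": (0.120, 1.37),
    "MG": (0.015, 1.19),
    "ZN": (0.250, 1.09),
    "P": (0.100, 2.00),  # pseudo-atom (dummy spin-label probe)
}

_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


def element_from_name(name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Two-letter ion names (CD, MG, ZN) are recognized first; otherwise
    the first alphabetic character wins (standard PDB heavy-atom
    naming: CA, CB, SG, OD1, NE2, ...).
    """
    stripped = name.strip()
    up = stripped.upper()
    if up in ("CD", "MG", "ZN") and not up[-1].isdigit():
        return up
    for ch in up:
        if ch.isalpha():
            return ch
    raise PDBFormatError(f"cannot infer element from atom name {name!r}")


def lj_for_element(element: str) -> tuple[float, float]:
    try:
        return ELEMENT_LJ[element.upper()]
    except KeyError:
        return ELEMENT_LJ["C"]


class FragmentKind(str, enum.Enum):
    CD_BRIDGE = "cd_bridge"
    MG_BRIDGE = "mg_bridge"
    ZN_BRIDGE = "zn_bridge"
    SALT_BRIDGE = "salt_bridge"
    MTSSL_LABEL = "mtssl_label"
    DUMMY_LABEL = "dummy_label"

    @property
    def is_bridge(self) -> bool:
        return self in (
            FragmentKind.CD_BRIDGE,
            FragmentKind.MG_BRIDGE,
            FragmentKind.ZN_BRIDGE,
            FragmentKind.SALT_BRIDGE,
        )

    @property
    def is_label(self) -> bool:
        return self in (FragmentKind.MTSSL_LABEL, FragmentKind.DUMMY_LABEL)


@dataclass
class FragmentSpec:
    """Declarative description of one molecular fragment.

    Bridge kinds connect two host residues through a bridging ion (or a
    salt bridge); label kinds attach a spin-label at a single site and
    may be expanded into ``n_copies`` non-interacting copies.
    """

    kind: FragmentKind
    host_sites: tuple[int, ...]
    mutations: tuple[str, ...] = ()
    n_copies: int = 1
    chain: str = "A"

    def __post_init__(self) -> None:
        self.kind = FragmentKind(self.kind)
        self.host_sites = tuple(int(s) for s in self.host_sites)
        if self.kind.is_bridge and len(self.host_sites) != 2:
            raise ValueError(f"{self.kind.value} requires 2 host sites, got {len(self.host_sites)}")
        if self.kind.is_label and len(self.host_sites) != 1:
            raise ValueError(f"{self.kind.value} requires 1 host site, got {len(self.host_sites)}")
        if self.kind.is_bridge and self.host_sites[0] == self.host_sites[1]:
            raise ValueError("bridge sites must be distinct residues")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")


@dataclass
class AtomicSystem:
    """Atoms plus bonded terms of the internal force field.

    Bonded parameter conventions: bonds E = k (b - b0)^2 with k in
    kcal/mol/A^2; angles E = k (theta - theta0)^2 with k in
    kcal/mol/rad^2 and theta0 stored in radians; dihedrals
    E = k (1 + cos(n phi - delta)).
    """

    serial: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    name: list[str] = field(default_factory=list)
    element: list[str] = field(default_factory=list)
    residue_index: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    residue_name: list[str] = field(default_factory=list)
    chain: list[str] = field(default_factory=list)
    positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    charge: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lj_epsilon: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lj_rmin_half: np.ndarray = field(default_factory=lambda: np.zeros(0))
    fragment_id: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    bond_params: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))  # k, b0
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    angle_params: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))  # k, theta0
    dihedrals: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=np.int64))
    dihedral_params: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))  # k, n, delta

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def copy(self) -> "AtomicSystem":
        out = AtomicSystem()
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            setattr(out, f.name, v.copy() if isinstance(v, np.ndarray) else list(v))
        return out

    def add_atom(
        self,
        name: str,
        residue_index: int,
        residue_name: str,
        position: Sequence[float],
        *,
        chain: str = "A",
        element: str | None = None,
        charge: float = 0.0,
        lj_epsilon: float | None = None,
        lj_rmin_half: float | None = None,
        fragment_id: int = 0,
        serial: int | None = None,
    ) -> int:
        """Append one atom; returns its index."""
        el = element if element is not None else element_from_name(name)
        eps, rmh = lj_for_element(el)
        if lj_epsilon is not None:
            eps = lj_epsilon
        if lj_rmin_half is not None:
            rmh = lj_rmin_half
        idx = self.n_atoms
        ser = serial if serial is not None else (int(self.serial[-1]) + 1 if idx else 1)
        self.serial = np.append(self.serial, ser)
        self.name.append(name)
        self.element.append(el)
        self.residue_index = np.append(self.residue_index, int(residue_index))
        self.residue_name.append(residue_name)
        self.chain.append(chain)
        self.positions = np.vstack([self.positions, np.asarray(position, dtype=float)])
        self.charge = np.append(self.charge, charge)
        self.lj_epsilon = np.append(self.lj_epsilon, eps)
        self.lj_rmin_half = np.append(self.lj_rmin_half, rmh)
        self.fragment_id = np.append(self.fragment_id, int(fragment_id))
        return idx

    def add_bond(self, i: int, j: int, k: float, b0: float) -> None:
        self.bonds = np.vstack([self.bonds, [i, j]]).astype(np.int64)
        self.bond_params = np.vstack([self.bond_params, [k, b0]])

    def add_angle(self, i: int, j: int, k_idx: int, k: float, theta0: float) -> None:
        self.angles = np.vstack([self.angles, [i, j, k_idx]]).astype(np.int64)
        self.angle_params = np.vstack([self.angle_params, [k, theta0]])

    def add_dihedral(self, i: int, j: int, k_idx: int, l: int, k: float, n: int, delta: float) -> None:
        self.dihedrals = np.vstack([self.dihedrals, [i, j, k_idx, l]]).astype(np.int64)
        self.dihedral_params = np.vstack([self.dihedral_params, [k, n, delta]])

    def find_atom(self, residue_index: int, name: str, chain: str | None = None,
                  fragment_id: int | None = None) -> int:
        """Index of the unique atom matching the query; raises KeyError."""
        hits = [
            i
            for i in range(self.n_atoms)
            if self.residue_index[i] == residue_index
            and self.name[i] == name
            and (chain is None or self.chain[i] == chain)
            and (fragment_id is None or self.fragment_id[i] == fragment_id)
        ]
        if not hits:
            raise KeyError(f"no atom {name!r} in residue {residue_index} (chain={chain})")
        if len(hits) > 1:
            raise KeyError(f"ambiguous atom {name!r} in residue {residue_index}: {hits}")
        return hits[0]

    def validate(self) -> None:
        """Check structural invariants; raises ValueError on violation."""
        n = self.n_atoms
        if len(set(self.serial.tolist())) != n:
            raise ValueError("atom serials are not unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atomic positions")
        for arr, arity, label in (
            (self.bonds, 2, "bond"),
            (self.angles, 3, "angle"),
            (self.dihedrals, 4, "dihedral"),
        ):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise ValueError(f"{label} term references a missing atom")
            for row in arr:
                fids = {int(self.fragment_id[i]) for i in row}
                if len(fids) > 1:
                    raise ValueError(f"{label} term {row.tolist()} spans fragment groups {fids}")

    # ---------------------------------------------------------------- misc
    def merge(self, other: "AtomicSystem") -> "AtomicSystem":
        """Concatenate two systems; ``other``'s serials are renumbered."""
        out = self.copy()
        offset = out.n_atoms
        start_serial = int(out.serial.max()) + 1 if offset else 1
        out.serial = np.concatenate([out.serial, start_serial + np.arange(other.n_atoms)])
        out.name += list(other.name)
        out.element += list(other.element)
        out.residue_index = np.concatenate([out.residue_index, other.residue_index])
        out.residue_name += list(other.residue_name)
        out.chain += list(other.chain)
        out.positions = np.vstack([out.positions, other.positions])
        out.charge = np.concatenate([out.charge, other.charge])
        out.lj_epsilon = np.concatenate([out.lj_epsilon, other.lj_epsilon])
        out.lj_rmin_half = np.concatenate([out.lj_rmin_half, other.lj_rmin_half])
        out.fragment_id = np.concatenate([out.fragment_id, other.fragment_id])
        if other.bonds.size:
            out.bonds = np.vstack([out.bonds, other.bonds + offset])
            out.bond_params = np.vstack([out.bond_params, other.bond_params])
        if other.angles.size:
            out.angles = np.vstack([out.angles, other.angles + offset])
            out.angle_params = np.vstack([out.angle_params, other.angle_params])
        if other.dihedrals.size:
            out.dihedrals = np.vstack([out.dihedrals, other.dihedrals + offset])
            out.dihedral_params = np.vstack([out.dihedral_params, other.dihedral_params])
        return out


# ------------------------------------------------------------------ PDB I/O

def read_pdb(path: str | Path) -> AtomicSystem:
    """Read ATOM/HETATM records from a fixed-column PDB file.

    Residue indices are taken from the file (1-based), chains preserved,
    elements inferred from atom names when the element column is blank,
    and exclusion-group ids recovered from ``G<id>`` segment labels.
    Charges and LJ parameters are assigned from the element table.
    """
    path = Path(path)
    system = AtomicSystem()
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec not in ("ATOM  ", "HETATM"):
                continue
            n_records += 1
            try:
                serial = int(line[6:11])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PDBFormatError(f"{path.name}:{lineno}: malformed numeric field: {exc}") from exc
            name = line[12:16].strip()
            resname = line[17:21].strip() or "UNK"
            chain = line[21].strip() or "A"
            try:
                resi = int(line[22:26])
            except ValueError as exc:
                raise PDBFormatError(f"{path.name}:{lineno}: malformed residue number") from exc
            segid = line[72:76].strip() if len(line) >= 76 else ""
            elem_col = line[76:78].strip() if len(line) >= 78 else ""
            element = elem_col.upper() if elem_col else element_from_name(name)
            frag = 0
            if segid.startswith("G") and segid[1:].isdigit():
                frag = int(segid[1:])
            system.add_atom(
                name,
                resi,
                resname,
                (x, y, z),
                chain=chain,
                element=element,
                fragment_id=frag,
                serial=serial,
            )
    if n_records == 0:
        raise PDBFormatError(f"{path.name}: no ATOM/HETATM records")
    return system


def chain_label_for_group(group: int) -> str:
    """Deterministic single-character chain label for an exclusion group.

    Labels cycle through [A-Za-z0-9]; uniqueness beyond 62 groups is
    provided by the segment label, not the chain character.
    """
    if group <= 0:
        return ""
    return _CHAIN_ALPHABET[(group - 1) % len(_CHAIN_ALPHABET)]


def write_pdb(system: AtomicSystem, path: str | Path) -> None:
    """Write fixed-column ATOM records (%8.3f coordinates).

    Host atoms keep their chain; fragment atoms get a chain letter
    cycled per exclusion group plus a ``G<id>`` segment label so that
    any number of copies remains distinguishable on re-read.
    """
    path = Path(path)
    if system.n_atoms and float(np.abs(system.positions).max()) >= 1e4:
        raise PDBFormatError("coordinate magnitude >= 10^4 A does not fit fixed columns")
    with open(path, "w") as fh:
        fh.write("REMARK   generated by molfrag\n")
        for i in range(system.n_atoms):
            frag = int(system.fragment_id[i])
            chain = system.chain[i] if frag == 0 else chain_label_for_group(frag)
            segid = "" if frag == 0 else f"G{frag}"
            name = system.name[i]
            # PDB name column: right-pad 1-3 char names starting at col 14
            fname = f" {name:<3s}" if len(name) < 4 else name[:4]
            x, y, z = system.positions[i]
            fh.write(
                f"ATOM  {int(system.serial[i]) % 100000:5d} {fname}"
                f" {system.residue_name[i][:4]:<4s}{chain[:1]:1s}"
                f"{int(system.residue_index[i]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"      {segid:<4s}{system.element[i][:2]:>2s}\n"
            )
        fh.write("END\n")


# ------------------------------------------------------ histogram tables

@dataclass
class HistogramTable:
    """Distance histogram on the grid of bin centers n * delta_r, n=1..n_bins.

    ``values`` are densities (1/A); after :meth:`normalize`,
    sum(values) * delta_r == 1.
    """

    delta_r: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.delta_r <= 0:
            raise HistogramError("bin width must be positive")
        if np.any(self.values < 0):
            raise HistogramError("histogram values must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.delta_r * np.arange(1, self.n_bins + 1)

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.delta_r)

    def normalize(self) -> "HistogramTable":
        m = self.mass
        if m <= 0:
            raise HistogramError("histogram has zero mass, cannot normalize")
        return HistogramTable(self.delta_r, self.values / m)

    def same_grid(self, other: "HistogramTable", tol: float = 1e-9) -> bool:
        return self.n_bins == other.n_bins and abs(self.delta_r - other.delta_r) < tol


def read_histogram_table(path: str | Path, delta_r: float, n_bins: int) -> HistogramTable:
    """Load a two-column (bin_center, value) text table onto the n*delta_r grid.

    Lines starting with '#' are comments. Missing bins are zero-filled;
    the result is renormalized to unit mass.
    """
    path = Path(path)
    values = np.zeros(n_bins)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise HistogramError(f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}")
            center, value = float(parts[0]), float(parts[1])
            if value < 0:
                raise HistogramError(f"{path.name}:{lineno}: negative histogram value {value}")
            n = center / delta_r
            if abs(n - round(n)) > 1e-6:
                raise HistogramError(
                    f"{path.name}:{lineno}: bin center {center} not on the n*{delta_r} grid"
                )
            n = int(round(n))
            if not 1 <= n <= n_bins:
                raise HistogramError(f"{path.name}:{lineno}: bin index {n} outside 1..{n_bins}")
            values[n - 1] = value
    return HistogramTable(delta_r, values).normalize()


def write_histogram_table(table: HistogramTable, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for c, v in zip(table.bin_centers, table.values):
            fh.write(f"{c:10.4f} {v:14.8e}\n")
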