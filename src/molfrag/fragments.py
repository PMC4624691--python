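"""Construction of molecular fragments and copy ensembles.

A fragment is an atomically detailed sub-molecule — a pair of mutated
side chains with a bridging ion, or one spin-label copy — appended to
the host :class:`~molfrag.system.AtomicSystem` with its own positive
``fragment_id`` (exclusion group). Fragment backbone atoms (N, C, O,
C-alpha) duplicate the host residue's backbone and are tied to it by
anchor restraints; everything else about the fragment only talks to the
environment through the scaled, soft-core nonbonded interactions.

Label fragments are expanded into N copies, each scaled by 1/N, and the
greedy :func:`group_fragments` packs copies that can never see each
other (all pairwise atoms beyond the nonbonded cutoff) into shared
exclusion groups to respect an engine-level cap on group count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import templates
from .system import AtomicSystem, FragmentKind, FragmentSpec, lj_for_element

ION_INFO = {
    FragmentKind.CD_BRIDGE: ("CD", "CD", 2.0),
    FragmentKind.MG_BRIDGE: ("MG", "MG", 2.0),
    FragmentKind.ZN_BRIDGE: ("ZN", "ZN", 2.0),
}

# Atom of the mutated residue that coordinates the bridging ion
COORDINATING_ATOM = {
    FragmentKind.CD_BRIDGE: "SG",
    FragmentKind.MG_BRIDGE: "OD2",
    FragmentKind.ZN_BRIDGE: "NE2",
}

DEFAULT_MUTATIONS = {
    FragmentKind.CD_BRIDGE: ("CYS", "CYS"),
    FragmentKind.MG_BRIDGE: ("ASP", "ASP"),
    FragmentKind.ZN_BRIDGE: ("HIS", "HIS"),
    FragmentKind.SALT_BRIDGE: ("LYS", "GLU"),
    FragmentKind.MTSSL_LABEL: ("R1A",),
    FragmentKind.DUMMY_LABEL: ("DUM",),
}

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class MolecularFragment:
    """One fragment instance living inside a merged AtomicSystem."""

    kind: FragmentKind
    atoms: np.ndarray  # indices into the system
    anchor_pairs: list[tuple[int, int]]  # (fragment atom, host atom)
    exclusion_group: int
    scale: float = 1.0
    target_residues: list[int] = field(default_factory=list)
    bridging_ion: int | None = None
    probe_atom: int | None = None
    site: int | None = None
    copy_index: int = 0

    def atom_named(self, system: AtomicSystem, name: str) -> list[int]:
        return [int(i) for i in self.atoms if system.name[i] == name]

    def backbone_atoms(self, system: AtomicSystem) -> list[int]:
        return [int(i) for i in self.atoms if system.name[i] in BACKBONE_NAMES]


@dataclass
class CopyEnsemble:
    """All copies of one spin-label site."""

    site: int
    copies: list[MolecularFragment]

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    @property
    def probe_atoms(self) -> list[int]:
        return [c.probe_atom for c in self.copies]


def _host_backbone(system: AtomicSystem, site: int, chain: str | None):
    try:
        return {nm: system.find_atom(site, nm, chain=chain, fragment_id=0) for nm in BACKBONE_NAMES}
    except KeyError as exc:
        raise ValueError(f"host residue {site} lacks a full backbone: {exc}") from exc


def _next_group(system: AtomicSystem) -> int:
    return int(system.fragment_id.max()) + 1 if system.n_atoms else 1


def _append_patched_residue(
    system: AtomicSystem,
    site: int,
    chain: str | None,
    resname: str,
    group: int,
    chi_offsets: dict[int, float] | None = None,
    bb: dict[str, int] | None = None,
) -> tuple[dict[str, int], templates.ResidueTemplate]:
    """Duplicate the host backbone of ``site`` and graft a template side
    chain onto it, as atoms of exclusion group ``group``. Returns the
    name -> atom-index map of the new residue."""
    tpl = templates.TEMPLATES[resname]
    if bb is None:
        bb = _host_backbone(system, site, chain)
    pos = {nm: system.positions[i].copy() for nm, i in bb.items()}
    side = templates.build_sidechain(tpl, pos["N"], pos["CA"], pos["C"], chi_offsets)
    host_chain = system.chain[bb["CA"]]
    idx: dict[str, int] = {}
    for nm in BACKBONE_NAMES:
        idx[nm] = system.add_atom(
            nm, site, resname, pos[nm], chain=host_chain,
            charge=templates.BACKBONE_CHARGES[nm], fragment_id=group,
        )
    for nm, p in side.items():
        el = tpl.elements.get(nm)
        idx[nm] = system.add_atom(
            nm, site, resname, p, chain=host_chain,
            element=el, charge=tpl.charges[nm], fragment_id=group,
        )
    # internal force-field terms of the patched residue
    system.add_bond(idx["N"], idx["CA"], templates.K_BOND, templates.BB_N_CA)
    system.add_bond(idx["CA"], idx["C"], templates.K_BOND, templates.BB_CA_C)
    system.add_bond(idx["C"], idx["O"], templates.K_BOND, templates.BB_C_O)
    system.add_angle(idx["N"], idx["CA"], idx["C"], templates.K_ANGLE,
                     templates.ANG_N_CA_C * templates.DEG)
    system.add_angle(idx["CA"], idx["C"], idx["O"], templates.K_ANGLE,
                     templates.ANG_CA_C_O * templates.DEG)
    for a, b, b0 in tpl.bonds:
        k = templates.DUMMY_TETHER_K if resname == "DUM" else templates.K_BOND
        system.add_bond(idx[a], idx[b], k, b0)
    for a, b, c, th in tpl.angles:
        system.add_angle(idx[a], idx[b], idx[c], templates.K_ANGLE, th * templates.DEG)
    return idx, tpl


def build_bridge_fragment(
    system: AtomicSystem,
    spec: FragmentSpec,
    *,
    chains: tuple[str | None, str | None] = (None, None),
) -> MolecularFragment:
    """Build a bridge fragment (two mutated residues + bridging ion).

    The system is extended in place. The ion starts at the midpoint of
    the two coordinating atoms; the bridge restraints pull it into
    geometry later. Mutated residues carry the deprotonated charge
    state, so the whole fragment is electrically neutral.
    """
    if not spec.kind.is_bridge:
        raise ValueError(f"{spec.kind.value} is not a bridge kind; use build_label_fragment")
    group = _next_group(system)
    mutations = spec.mutations or DEFAULT_MUTATIONS[spec.kind]
    all_atoms: list[int] = []
    anchors: list[tuple[int, int]] = []
    res_maps = []
    for site, resname, chain in zip(spec.host_sites, mutations, chains):
        bb = _host_backbone(system, site, chain)
        idx, _tpl = _append_patched_residue(system, site, chain, resname, group)
        res_maps.append(idx)
        all_atoms.extend(idx.values())
        anchors.extend((idx[nm], bb[nm]) for nm in BACKBONE_NAMES)
    ion_idx = None
    if spec.kind in ION_INFO:
        ion_name, ion_el, ion_q = ION_INFO[spec.kind]
        coord = COORDINATING_ATOM[spec.kind]
        p1 = system.positions[res_maps[0][coord]]
        p2 = system.positions[res_maps[1][coord]]
        ion_idx = system.add_atom(
            ion_name, spec.host_sites[0], ion_name,
            0.5 * (p1 + p2), chain=system.chain[all_atoms[0]],
            element=ion_el, charge=ion_q, fragment_id=group,
        )
        all_atoms.append(ion_idx)
    return MolecularFragment(
        kind=spec.kind,
        atoms=np.asarray(all_atoms, dtype=np.int64),
        anchor_pairs=anchors,
        exclusion_group=group,
        scale=1.0,
        target_residues=list(spec.host_sites),
        bridging_ion=ion_idx,
    )


def build_label_fragment(
    system: AtomicSystem,
    spec: FragmentSpec,
    *,
    seed: int = 0,
    chain: str | None = None,
) -> CopyEnsemble:
    """Attach ``spec.n_copies`` spin-label copies at one host site.

    Each copy is its own fragment with interaction scale 1/n_copies.
    Copies share composition; their side-chain chi torsions are offset
    by uniform random angles from a generator seeded with ``seed`` so
    the ensemble starts spread out deterministically.
    """
    if not spec.kind.is_label:
        raise ValueError(f"{spec.kind.value} is not a label kind; use build_bridge_fragment")
    rng = np.random.default_rng(seed)
    site = spec.host_sites[0]
    resname = (spec.mutations or DEFAULT_MUTATIONS[spec.kind])[0]
    tpl = templates.TEMPLATES[resname]
    nchi = templates.n_chi(tpl)
    copies: list[MolecularFragment] = []
    scale = 1.0 / spec.n_copies
    bb = _host_backbone(system, site, chain)
    for c in range(spec.n_copies):
        offsets = {k: float(rng.uniform(-np.pi, np.pi)) for k in range(1, nchi + 1)}
        group = _next_group(system)
        idx, _ = _append_patched_residue(system, site, chain, resname, group, offsets, bb=bb)
        if tpl.probe is None:
            raise ValueError(f"template {resname} declares no probe atom")
        copies.append(
            MolecularFragment(
                kind=spec.kind,
                atoms=np.asarray(sorted(idx.values()), dtype=np.int64),
                anchor_pairs=[(idx[nm], bb[nm]) for nm in BACKBONE_NAMES],
                exclusion_group=group,
                scale=scale,
                target_residues=[site],
                probe_atom=idx[tpl.probe],
                site=site,
                copy_index=c,
            )
        )
    return CopyEnsemble(site=site, copies=copies)


def anchor_restraints(fragment: MolecularFragment, k: float, b0: float = 0.0):
    """Harmonic anchor terms E = k (d - b0)^2 tying fragment backbone
    atoms onto the host backbone. One term per anchor pair."""
    from .restraints import RestraintKind, RestraintTerm

    if k <= 0:
        raise ValueError("anchor force constant must be positive")
    if not fragment.anchor_pairs:
        raise ValueError("fragment has no anchor pairs")
    return [
        RestraintTerm(kind=RestraintKind.ANCHOR, atoms=(int(a), int(b)), k=k, x0=b0)
        for a, b in fragment.anchor_pairs
    ]


@dataclass
class GroupAssignment:
    """Result of packing label copies into shared exclusion groups."""

    groups: dict[int, list[MolecularFragment]]
    cutoff: float

    @property
    def n_groups(self) -> int:
        return len(self.groups)


class GroupingError(RuntimeError):
    def __init__(self, needed: int, max_groups: int):
        super().__init__(
            f"greedy grouping needs {needed} exclusion groups, cap is {max_groups}"
        )
        self.needed = needed
        self.max_groups = max_groups


def group_fragments(
    system: AtomicSystem,
    ensembles: list[CopyEnsemble],
    cutoff: float,
    max_groups: int = 255,
) -> GroupAssignment:
    """Greedy first-fit packing of label copies into exclusion groups.

    A copy may join a group only if its minimum interatomic distance to
    every copy already in the group exceeds ``cutoff`` — such copies can
    share an engine-level fragment identity because they can never
    interact. Copies are visited in site-major order (site, then copy
    index); ties go to the lowest group index, so the assignment is
    deterministic. ``system.fragment_id`` and each copy's
    ``exclusion_group`` are rewritten in place.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    copies = [c for ens in sorted(ensembles, key=lambda e: e.site) for c in ens.copies]
    copy_atoms = np.concatenate([c.atoms for c in copies]) if copies else np.zeros(0, np.int64)
    other = np.ones(system.n_atoms, dtype=bool)
    other[copy_atoms] = False
    # keep group ids disjoint from any non-label fragment already present
    base = int(system.fragment_id[other].max()) if other.any() else 0
    group_members: list[list[MolecularFragment]] = []
    group_coords: list[np.ndarray] = []
    cut2 = cutoff * cutoff
    for copy in copies:
        coords = system.positions[copy.atoms]
        placed = False
        for g, gc in enumerate(group_coords):
            d2 = np.sum((coords[:, None, :] - gc[None, :, :]) ** 2, axis=-1)
            if d2.min() > cut2:
                group_members[g].append(copy)
                group_coords[g] = np.vstack([gc, coords])
                copy.exclusion_group = base + g + 1
                placed = True
                break
        if not placed:
            if len(group_members) >= max_groups:
                raise GroupingError(len(group_members) + 1, max_groups)
            group_members.append([copy])
            group_coords.append(coords)
            copy.exclusion_group = base + len(group_members)
    for g, members in enumerate(group_members, start=1):
        for copy in members:
            system.fragment_id[copy.atoms] = base + g
    return GroupAssignment(
        groups={base + g + 1: m for g, m in enumerate(group_members)}, cutoff=cutoff
    )
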