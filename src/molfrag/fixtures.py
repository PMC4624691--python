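"""Deterministic synthetic fixtures.

Three recipes cover the mechanisms the package exercises:

* ``four_helix_bundle`` — four ideal alpha-helices on a square lattice
  with a catalog of bridgeable cross-helix residue pairs, emulating a
  voltage-sensor-like transmembrane bundle;
* ``globular_label_host`` — a single-chain backbone scaffold threaded
  along a serpentine space curve, giving any number of label sites with
  a declared minimum pairwise separation (the real benchmark protein is
  compact; the scaffold trades realism for a controllable site layout);
* ``free_probes`` — bare probe particles for histogram-restraint
  convergence experiments.

All fixtures are reduced to backbone + C-beta heavy atoms; side chains
appear only where fragments are built. Geometry is bit-for-bit
reproducible from (recipe, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry, templates
from .system import AtomicSystem, FragmentKind, HistogramTable

DEG = math.pi / 180.0

BACKBONE_CHARGES = templates.BACKBONE_CHARGES


@dataclass
class FixtureRecipe:
    kind: str = "four_helix_bundle"  # | globular_label_host | free_probes
    helix_length: int = 14
    lattice_spacing: float = 10.0
    n_residues: int = 160
    n_sites: int = 2
    site_min_separation: float = 10.0
    n_copies: int = 25
    n_probes_per_site: int = 25
    box: float = 40.0
    seed: int = 0


# ------------------------------------------------------------ helix bundle

def _ideal_helix(length: int, phi: float = -57.0, psi: float = -47.0) -> dict[str, np.ndarray]:
    """Backbone + CB coordinates of one ideal alpha-helix (NeRF chain)."""
    phi_r, psi_r, omega_r = phi * DEG, psi * DEG, math.pi
    n = [np.array([0.0, 0.0, 0.0])]
    ca = [np.array([templates.BB_N_CA, 0.0, 0.0])]
    th = templates.ANG_N_CA_C * DEG
    c = [ca[0] + templates.BB_CA_C * np.array([-math.cos(th), math.sin(th), 0.0])]
    for i in range(1, length):
        n.append(geometry.place_atom(n[i - 1], ca[i - 1], c[i - 1], templates.BB_C_N,
                                     templates.ANG_CA_C_N * DEG, psi_r))
        ca.append(geometry.place_atom(ca[i - 1], c[i - 1], n[i], templates.BB_N_CA,
                                      templates.ANG_C_N_CA * DEG, omega_r))
        c.append(geometry.place_atom(c[i - 1], n[i], ca[i], templates.BB_CA_C,
                                     templates.ANG_N_CA_C * DEG, phi_r))
    o, cb = [], []
    for i in range(length):
        # carbonyl O anti to the next amide N: dihedral(N, CA, C, O) = psi + pi
        o.append(geometry.place_atom(n[i], ca[i], c[i], templates.BB_C_O,
                                     templates.ANG_CA_C_O * DEG, psi_r + math.pi))
        cb.append(geometry.place_atom(c[i], n[i], ca[i], 1.53, 110.5 * DEG, 122.5 * DEG))
    return {"N": np.array(n), "CA": np.array(ca), "C": np.array(c),
            "O": np.array(o), "CB": np.array(cb)}


def _axis_align(coords: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Rotate so the helix axis (first principal component of CA) is +z,
    centered at the origin."""
    ca = coords["CA"]
    center = ca.mean(axis=0)
    u, s, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    if axis[0] + axis[1] + axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    sv = np.linalg.norm(v)
    cv = float(np.dot(axis, z))
    if sv < 1e-12:
        R = np.eye(3) if cv > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - cv) / (sv * sv))
    return {k: (p - center) @ R.T for k, p in coords.items()}


def _add_backbone_residue(system, resi, chain, pos, elementless=True):
    idx = {}
    for nm in ("N", "CA", "C", "O", "CB"):
        q = BACKBONE_CHARGES.get(nm, 0.0)
        idx[nm] = system.add_atom(nm, resi, "ALA", pos[nm], chain=chain, charge=q)
    return idx


def _wire_backbone(system, idx_prev, idx, *, measured=True):
    """Intra-residue terms plus the peptide link to the previous residue.

    With ``measured`` the equilibrium values are taken from the current
    coordinates, so a freshly built fixture starts strain-free.
    """
    pos = system.positions

    def b0(a, b):
        return float(np.linalg.norm(pos[a] - pos[b]))

    def t0(a, b, c):
        return geometry.angle(pos[a], pos[b], pos[c])

    K_B, K_A = templates.K_BOND, templates.K_ANGLE
    system.add_bond(idx["N"], idx["CA"], K_B, b0(idx["N"], idx["CA"]))
    system.add_bond(idx["CA"], idx["C"], K_B, b0(idx["CA"], idx["C"]))
    system.add_bond(idx["C"], idx["O"], K_B, b0(idx["C"], idx["O"]))
    system.add_bond(idx["CA"], idx["CB"], K_B, b0(idx["CA"], idx["CB"]))
    system.add_angle(idx["N"], idx["CA"], idx["C"], K_A, t0(idx["N"], idx["CA"], idx["C"]))
    system.add_angle(idx["CA"], idx["C"], idx["O"], K_A, t0(idx["CA"], idx["C"], idx["O"]))
    system.add_angle(idx["N"], idx["CA"], idx["CB"], K_A, t0(idx["N"], idx["CA"], idx["CB"]))
    system.add_angle(idx["C"], idx["CA"], idx["CB"], K_A, t0(idx["C"], idx["CA"], idx["CB"]))
    if idx_prev is not None:
        system.add_bond(idx_prev["C"], idx["N"], K_B, b0(idx_prev["C"], idx["N"]))
        system.add_angle(idx_prev["CA"], idx_prev["C"], idx["N"], K_A,
                         t0(idx_prev["CA"], idx_prev["C"], idx["N"]))
        system.add_angle(idx_prev["O"], idx_prev["C"], idx["N"], K_A,
                         t0(idx_prev["O"], idx_prev["C"], idx["N"]))
        system.add_angle(idx_prev["C"], idx["N"], idx["CA"], K_A,
                         t0(idx_prev["C"], idx["N"], idx["CA"]))


@dataclass
class BridgeCatalogEntry:
    label: str
    kind: FragmentKind
    sites: tuple[int, int]
    helices: tuple[int, int]
    cb_cb: float


def make_helix_bundle(recipe: FixtureRecipe) -> tuple[AtomicSystem, list[BridgeCatalogEntry]]:
    """Four ideal antiparallel helices on a square lattice, plus a
    catalog of bridgeable cross-helix residue pairs (C-beta separations
    in the 8-16 A window typical of engineered bridges).

    Residues are numbered 100*h + r (helix h = 1..4, r = 1..length) so
    residue indices are globally unique; chains are A-D.
    """
    if recipe.helix_length < 10:
        raise ValueError("helix length must be >= 10 residues")
    if recipe.lattice_spacing < 5.0:
        raise ValueError("lattice spacing < 5 A would clash the helices")
    base = _axis_align(_ideal_helix(recipe.helix_length))
    d = recipe.lattice_spacing
    placements = [  # (x, y, flip) — neighbors antiparallel around the square
        (0.0, 0.0, False),
        (d, 0.0, True),
        (d, d, False),
        (0.0, d, True),
    ]
    flip = np.diag([1.0, -1.0, -1.0])  # 180 deg about x
    system = AtomicSystem()
    chains = "ABCD"
    for h, (x, y, do_flip) in enumerate(placements):
        coords = {k: (p @ flip.T if do_flip else p) + np.array([x, y, 0.0])
                  for k, p in base.items()}
        prev = None
        for r in range(recipe.helix_length):
            resi = 100 * (h + 1) + r + 1
            pos = {k: coords[k][r] for k in coords}
            idx = _add_backbone_residue(system, resi, chains[h], pos)
            _wire_backbone(system, prev, idx)
            prev = idx
    # bridge-site catalog mirroring the S1/S4, S2/S4, S2/S3, S3/S4 pairings
    wanted = [
        ("MF-1", FragmentKind.CD_BRIDGE, (1, 4)),
        ("MF-2", FragmentKind.CD_BRIDGE, (2, 4)),
        ("MF-3", FragmentKind.MG_BRIDGE, (2, 3)),
        ("MF-4", FragmentKind.SALT_BRIDGE, (2, 4)),
        ("MF-5", FragmentKind.ZN_BRIDGE, (2, 4)),
        ("MF-6", FragmentKind.CD_BRIDGE, (3, 4)),
        ("MF-7", FragmentKind.CD_BRIDGE, (3, 4)),
    ]
    cb = {}
    for h in range(4):
        for r in range(recipe.helix_length):
            resi = 100 * (h + 1) + r + 1
            cb[resi] = system.positions[system.find_atom(resi, "CB")]
    catalog = []
    used_pairs: set[tuple[int, int]] = set()
    for label, kind, (ha, hb) in wanted:
        best = None
        for ra in range(2, recipe.helix_length):  # skip termini
            for rb in range(2, recipe.helix_length):
                sa = 100 * ha + ra
                sb = 100 * hb + rb
                if (sa, sb) in used_pairs:
                    continue
                dist = float(np.linalg.norm(cb[sa] - cb[sb]))
                if 8.0 <= dist <= 16.0:
                    score = abs(dist - 11.0)
                    if best is None or score < best[0]:
                        best = (score, sa, sb, dist)
        if best is None:
            raise ValueError(f"no bridgeable pair for {label} between helices {ha}/{hb}")
        _, sa, sb, dist = best
        used_pairs.add((sa, sb))
        catalog.append(BridgeCatalogEntry(label, kind, (sa, sb), (ha, hb), dist))
    return system, catalog


# --------------------------------------------------------- label host

def _serpentine_nodes(n_nodes: int, spacing: float) -> np.ndarray:
    """Boustrophedon path through a near-cubic grid; consecutive nodes
    are exactly ``spacing`` apart, distinct nodes never closer."""
    nx = max(1, math.ceil(n_nodes ** (1.0 / 3.0)))
    ny = max(1, math.ceil(math.sqrt(n_nodes / nx)))
    nz = max(1, math.ceil(n_nodes / (nx * ny)))
    nodes = []
    for iz in range(nz):
        ys = range(ny) if iz % 2 == 0 else range(ny - 1, -1, -1)
        for iy in ys:
            snake = iz * ny + (iy if iz % 2 == 0 else ny - 1 - iy)
            xs = range(nx) if snake % 2 == 0 else range(nx - 1, -1, -1)
            for ix in xs:
                nodes.append((ix, iy, iz))
                if len(nodes) == n_nodes:
                    return np.array(nodes, dtype=float) * spacing
    return np.array(nodes, dtype=float) * spacing


def make_label_host(recipe: FixtureRecipe) -> tuple[AtomicSystem, list[int]]:
    """Single-chain backbone scaffold with ``n_sites`` label sites whose
    pairwise C-alpha separations are at least ``site_min_separation``.

    The chain follows a serpentine space curve through a grid whose
    nodes are the label sites; intermediate residues are interpolated
    every ~3.8 A. Equilibrium bonded parameters are set to the built
    geometry, so the scaffold starts strain-free.
    """
    if recipe.n_sites < 1:
        raise ValueError("need at least one site")
    nodes = _serpentine_nodes(recipe.n_sites, recipe.site_min_separation)
    step = 3.8
    # curve points: walk node to node in straight segments
    points = [nodes[0]]
    site_point_index = [0]
    for a, b in zip(nodes[:-1], nodes[1:]):
        seg = b - a
        length = float(np.linalg.norm(seg))
        n_steps = max(1, round(length / step))
        for t in range(1, n_steps + 1):
            points.append(a + seg * (t / n_steps))
        site_point_index.append(len(points) - 1)
    # pad with a straight tail to reach the requested residue count
    direction = nodes[-1] - nodes[-2] if len(nodes) > 1 else np.array([1.0, 0.0, 0.0])
    direction = direction / np.linalg.norm(direction)
    while len(points) < recipe.n_residues:
        points.append(points[-1] + direction * step)
    points = np.asarray(points)
    n_res = len(points)
    if recipe.n_sites > n_res:
        raise ValueError("requested more sites than residues")

    ref = np.array([0.12, 0.37, 0.92])
    system = AtomicSystem()
    prev = None
    for i in range(n_res):
        if i == 0:
            t = points[1] - points[0]
        elif i == n_res - 1:
            t = points[-1] - points[-2]
        else:
            t = points[i + 1] - points[i - 1]
        t = t / np.linalg.norm(t)
        nvec = ref - np.dot(ref, t) * t
        nn = np.linalg.norm(nvec)
        if nn < 1e-6:
            alt = np.array([1.0, 0.0, 0.0])
            nvec = alt - np.dot(alt, t) * t
            nn = np.linalg.norm(nvec)
        nvec = nvec / nn
        bvec = np.cross(t, nvec)
        ca = points[i]
        pos = {
            "N": ca - 1.2 * t,
            "CA": ca,
            "C": ca + 1.2 * t,
            "O": ca + 1.2 * t + 1.23 * nvec,
            "CB": ca - 0.77 * nvec + 1.33 * bvec,
        }
        idx = _add_backbone_residue(system, i + 1, "A", pos)
        _wire_backbone(system, prev, idx)
        prev = idx
    sites = [int(p) + 1 for p in site_point_index[: recipe.n_sites]]
    return system, sites


def infer_backbone_topology(system: AtomicSystem, max_peptide_gap: float = 2.5) -> None:
    """Reconstruct backbone + C-beta bonded terms for a host read from a
    coordinate-only file (PDB carries no topology).

    Equilibrium values are taken from the current geometry, so a loaded
    fixture is strain-free, mirroring how the generators wire their
    residues. Consecutive residues of one chain are linked only when
    the C--N gap is below ``max_peptide_gap``.
    """
    if len(system.bonds):
        return  # topology already present
    host = [i for i in range(system.n_atoms) if system.fragment_id[i] == 0]
    by_res: dict[tuple[str, int], dict[str, int]] = {}
    for i in host:
        by_res.setdefault((system.chain[i], int(system.residue_index[i])), {})[
            system.name[i]] = i
    keys = sorted(by_res)
    prev_key = None
    for key in keys:
        idx = by_res[key]
        if not {"N", "CA", "C", "O", "CB"} <= set(idx):
            prev_key = None
            continue
        prev = None
        if (prev_key is not None and prev_key[0] == key[0]
                and key[1] == prev_key[1] + 1):
            cand = by_res[prev_key]
            gap = float(np.linalg.norm(
                system.positions[cand["C"]] - system.positions[idx["N"]]))
            if gap < max_peptide_gap:
                prev = cand
        _wire_backbone(system, prev, idx)
        prev_key = key


# --------------------------------------------------------- free probes

def make_free_probes(recipe: FixtureRecipe) -> tuple[AtomicSystem, list[int], list[int]]:
    """Two ensembles of free probe pseudo-atoms in a cubic box,
    positions seeded; used for histogram-restraint experiments."""
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_probes_per_site
    system = AtomicSystem()
    idx_i, idx_j = [], []
    for s, bucket in ((1, idx_i), (2, idx_j)):
        for c in range(n):
            p = rng.uniform(0.0, recipe.box, size=3)
            bucket.append(
                system.add_atom("DP", s, "DUM", p, chain="A", element="P", fragment_id=0)
            )
    return system, idx_i, idx_j


# ------------------------------------------------------ target histograms

class UnachievableTarget(ValueError):
    def __init__(self, msg: str):
        super().__init__(msg)


def make_target_histogram(
    modes: list[tuple[float, float]],
    sigma_gen: float,
    delta_r: float,
    n_bins: int,
    *,
    site_distance: float | None = None,
    reach: float = 8.0,
    override: bool = False,
) -> HistogramTable:
    """Gaussian-mixture target histogram on the n*delta_r grid.

    ``modes`` are (mean A, weight) pairs with weights summing to 1.
    When ``site_distance`` is given, each mode must lie inside the
    geometrically reachable band [site_distance - 2*reach,
    site_distance + 2*reach] (probe tether reach on both ends), unless
    ``override`` is set.
    """
    w = sum(wt for _, wt in modes)
    if abs(w - 1.0) > 1e-9:
        raise ValueError(f"mode weights sum to {w}, expected 1")
    window = (0.0, n_bins * delta_r)
    centers = delta_r * np.arange(1, n_bins + 1)
    values = np.zeros(n_bins)
    for mean, weight in modes:
        if not window[0] < mean < window[1]:
            raise UnachievableTarget(
                f"mode at {mean} A lies outside the histogram window {window}"
            )
        if site_distance is not None and not override:
            lo = max(0.0, site_distance - 2.0 * reach)
            hi = site_distance + 2.0 * reach
            if not lo <= mean <= hi:
                raise UnachievableTarget(
                    f"mode at {mean} A violates tether-reach bound [{lo:.1f}, {hi:.1f}] A"
                )
        values += weight * np.exp(-((centers - mean) ** 2) / (2.0 * sigma_gen ** 2))
    table = HistogramTable(delta_r, values)
    return table.normalize()


def make_target_histograms(
    pair_distances: dict[tuple[int, int], float],
    modes: dict[tuple[int, int], list[tuple[float, float]]],
    sigma_gen: float = 2.0,
    delta_r: float = 1.0,
    n_bins: int = 60,
    *,
    reach: float = 8.0,
    override: bool = False,
) -> dict[tuple[int, int], HistogramTable]:
    """Targets for a set of site pairs (see :func:`make_target_histogram`)."""
    return {
        pair: make_target_histogram(
            modes[pair], sigma_gen, delta_r, n_bins,
            site_distance=pair_distances.get(pair), reach=reach, override=override,
        )
        for pair in modes
    }
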