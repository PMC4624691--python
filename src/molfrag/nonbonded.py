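"""Nonbonded energies and forces under the fragment exclusion scheme.

Pair interactions are Lennard-Jones (epsilon/Rmin form, Lorentz-
Berthelot-style combination: geometric epsilon, additive Rmin/2) plus
Coulomb, both multiplied by a C1 switching function that turns the
interaction off smoothly between ``switch_on`` and ``cutoff``. Any pair
with at least one fragment atom is evaluated at the soft-core effective
distance r' = sqrt(r^2 + Delta), which keeps energies and forces finite
at atomic overlap; host-host pairs use the plain distance.

The exclusion model encodes who sees whom:

* atoms of two different exclusion groups never interact;
* a fragment atom never sees any atom of its target host residue;
* fragment backbone atoms never see the backbone of host residues
  i-1 and i+1 around each target residue i;
* standard 1-2/1-3 bonded exclusions apply everywhere;
* fragment-environment pairs are scaled by the fragment's 1/N scale;
* host-host and intra-fragment pairs have scale 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .fragments import BACKBONE_NAMES, MolecularFragment
from .system import AtomicSystem

COULOMB_CONST = 332.0636  # kcal/mol * A / e^2


class NonbondedError(ValueError):
    pass


@dataclass
class SoftCoreParams:
    """Soft-core and truncation parameters (A and A^2)."""

    delta: float = 1.0
    switch_on: float = 10.0
    cutoff: float = 12.0
    dielectric: float = 1.0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0 <= self.switch_on < self.cutoff:
            raise ValueError("require 0 <= switch_on < cutoff")


def softcore_distance(r, delta):
    """Effective distance r' = sqrt(r^2 + delta); accepts arrays."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    out = np.sqrt(r * r + delta)
    return float(out) if out.ndim == 0 else out


def _pair_code(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    lo = np.minimum(i, j).astype(np.int64)
    hi = np.maximum(i, j).astype(np.int64)
    return lo * n + hi


@dataclass
class ExclusionModel:
    """Pairwise interaction scales implied by the fragment scheme."""

    n_atoms: int
    group: np.ndarray  # per-atom exclusion group (0 = host)
    atom_scale: np.ndarray  # per-atom fragment scale (1 for host)
    excluded_codes: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))

    @classmethod
    def from_system(
        cls, system: AtomicSystem, fragments: list[MolecularFragment] | None = None
    ) -> "ExclusionModel":
        fragments = fragments or []
        n = system.n_atoms
        group = system.fragment_id.astype(np.int64).copy()
        atom_scale = np.ones(n)
        codes: list[np.ndarray] = []

        # 1-2 and 1-3 bonded exclusions
        if len(system.bonds):
            codes.append(_pair_code(system.bonds[:, 0], system.bonds[:, 1], n))
        if len(system.angles):
            codes.append(_pair_code(system.angles[:, 0], system.angles[:, 2], n))

        resi = system.residue_index
        is_host = group == 0
        host_backbone = np.array(
            [is_host[i] and system.name[i] in BACKBONE_NAMES for i in range(n)]
        )
        for frag in fragments:
            atom_scale[frag.atoms] = frag.scale
            fb = [i for i in frag.atoms if system.name[i] in BACKBONE_NAMES]
            for site in frag.target_residues:
                # (b) fragment atoms vs. all atoms of the target residue
                tgt = np.nonzero(is_host & (resi == site))[0]
                if len(tgt):
                    fi, ti = np.meshgrid(frag.atoms, tgt, indexing="ij")
                    codes.append(_pair_code(fi.ravel(), ti.ravel(), n))
                # (c) fragment backbone vs. host backbone of residues i-1, i+1
                nb = np.nonzero(host_backbone & np.isin(resi, [site - 1, site + 1]))[0]
                if len(nb) and fb:
                    fi, ti = np.meshgrid(np.asarray(fb), nb, indexing="ij")
                    codes.append(_pair_code(fi.ravel(), ti.ravel(), n))
        all_codes = (
            np.unique(np.concatenate(codes)) if codes else np.zeros(0, np.int64)
        )
        return cls(n_atoms=n, group=group, atom_scale=atom_scale, excluded_codes=all_codes)

    # ------------------------------------------------------------- queries
    def pair_scale_array(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Vectorized interaction scale for atom-index arrays."""
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        gi = self.group[i]
        gj = self.group[j]
        scale = np.ones(len(i))
        both = (gi > 0) & (gj > 0)
        # different exclusion groups never interact; same group (intra-
        # fragment, or grouped copies that are beyond cutoff) scale 1
        scale[both & (gi != gj)] = 0.0
        one = (gi > 0) ^ (gj > 0)
        frag_scale = np.where(gi > 0, self.atom_scale[i], self.atom_scale[j])
        scale[one] = frag_scale[one]
        if len(self.excluded_codes):
            code = _pair_code(i, j, self.n_atoms)
            pos = np.searchsorted(self.excluded_codes, code)
            pos = np.clip(pos, 0, len(self.excluded_codes) - 1)
            scale[self.excluded_codes[pos] == code] = 0.0
        return scale

    def pair_scale(self, i: int, j: int) -> float:
        return float(self.pair_scale_array(np.array([i]), np.array([j]))[0])

    def pair_softcore(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """True where the soft-core effective distance applies (any
        fragment atom in the pair)."""
        return (self.group[np.asarray(i)] > 0) | (self.group[np.asarray(j)] > 0)


def _switch(r2: np.ndarray, ron: float, rc: float) -> tuple[np.ndarray, np.ndarray]:
    """CHARMM-style switching function S(r) and dS/dr, vectorized on r^2."""
    ron2, rc2 = ron * ron, rc * rc
    denom = (rc2 - ron2) ** 3
    s = np.ones_like(r2)
    ds = np.zeros_like(r2)
    mid = (r2 > ron2) & (r2 < rc2)
    r2m = r2[mid]
    s[mid] = (rc2 - r2m) ** 2 * (rc2 + 2.0 * r2m - 3.0 * ron2) / denom
    r = np.sqrt(r2m)
    ds[mid] = 12.0 * r * (rc2 - r2m) * (ron2 - r2m) / denom
    s[r2 >= rc2] = 0.0
    return s, ds


def _pair_terms(system: AtomicSystem, i, j):
    eps = np.sqrt(system.lj_epsilon[i] * system.lj_epsilon[j])
    rmin = system.lj_rmin_half[i] + system.lj_rmin_half[j]
    qq = system.charge[i] * system.charge[j]
    return eps, rmin, qq


def _eval_pairs(system, model, params, i, j, scale=None):
    """Energy and dE/d(effective r) for pair arrays; returns
    (energy_per_pair, dEdr_per_pair, reff, softcore_mask)."""
    if scale is None:
        scale = model.pair_scale_array(i, j)
    dvec = system.positions[i] - system.positions[j]
    r2 = np.sum(dvec * dvec, axis=1)
    soft = model.pair_softcore(i, j)
    r2eff = np.where(soft, r2 + params.delta, r2)
    reff = np.sqrt(r2eff)
    eps, rmin, qq = _pair_terms(system, i, j)
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = (rmin * rmin / r2eff) ** 3
    lj = eps * (sr6 * sr6 - 2.0 * sr6)
    dlj = eps * 12.0 * (sr6 - sr6 * sr6) / reff
    coul = COULOMB_CONST * qq / (params.dielectric * reff)
    dcoul = -coul / reff
    sw, dsw = _switch(r2eff, params.switch_on, params.cutoff)
    v = lj + coul
    energy = scale * sw * v
    dEdr = scale * (sw * (dlj + dcoul) + dsw * v)
    return energy, dEdr, reff, dvec


def pair_energy(
    system: AtomicSystem,
    i: int,
    j: int,
    model: ExclusionModel,
    params: SoftCoreParams,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Energy and forces (on i, on j) of one nonbonded pair."""
    if i == j:
        raise ValueError("pair requires two distinct atoms")
    ii = np.array([i])
    jj = np.array([j])
    e, dEdr, reff, dvec = _eval_pairs(system, model, params, ii, jj)
    # f_i = -dE/dr * d r/d x_i; with r = sqrt(r_geo^2 + delta),
    # dr/dx_i = (x_i - x_j)/r, finite even at geometric overlap.
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(reff > 0, dEdr / reff, 0.0)
    fi = -g[0] * dvec[0]
    return float(e[0]), fi, -fi


def neighbor_pairs(system: AtomicSystem, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """All atom pairs with geometric distance below cutoff (KD-tree)."""
    tree = cKDTree(system.positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros(0, np.int64), np.zeros(0, np.int64)
    return pairs[:, 0].astype(np.int64), pairs[:, 1].astype(np.int64)


def total_nonbonded(
    system: AtomicSystem,
    model: ExclusionModel,
    params: SoftCoreParams,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Sum of switched pair energies over all pairs within cutoff."""
    i, j = pairs if pairs is not None else neighbor_pairs(system, params.cutoff)
    forces = np.zeros_like(system.positions)
    if len(i) == 0:
        return 0.0, forces
    scale = model.pair_scale_array(i, j)
    live = scale != 0.0
    i, j, scale = i[live], j[live], scale[live]
    if len(i) == 0:
        return 0.0, forces
    # canonical pair order: keeps per-atom force accumulation bitwise
    # reproducible regardless of how the neighbor list was produced
    order = np.lexsort((j, i))
    i, j, scale = i[order], j[order], scale[order]
    e, dEdr, reff, dvec = _eval_pairs(system, model, params, i, j, scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(reff > 0, dEdr / reff, 0.0)
    fvec = -g[:, None] * dvec
    np.add.at(forces, i, fvec)
    np.add.at(forces, j, -fvec)
    return float(e.sum()), forces


def nonbonded_components(
    system: AtomicSystem,
    model: ExclusionModel,
    params: SoftCoreParams,
    fragments: list[MolecularFragment],
) -> dict[str, float]:
    """Decompose the total into host-host, per-fragment intra, and
    per-fragment scaled cross terms (cross reported both raw and
    scaled). Satisfies E_total = host + sum intra + sum scale*cross_raw.
    """
    i, j = neighbor_pairs(system, params.cutoff)
    out: dict[str, float] = {}
    gi = model.group[i]
    gj = model.group[j]
    host_mask = (gi == 0) & (gj == 0)

    def esum(mask, override_scale=None):
        ii, jj = i[mask], j[mask]
        if len(ii) == 0:
            return 0.0
        scale = model.pair_scale_array(ii, jj)
        if override_scale is not None:
            scale = np.where(scale != 0.0, override_scale, 0.0)
        e, *_ = _eval_pairs(system, model, params, ii, jj, scale)
        return float(e.sum())

    out["host_host"] = esum(host_mask)
    for frag in fragments:
        g = frag.exclusion_group
        intra = (gi == g) & (gj == g)
        cross = ((gi == g) & (gj == 0)) | ((gi == 0) & (gj == g))
        out[f"intra_g{g}"] = esum(intra)
        e_cross_raw = esum(cross, override_scale=1.0)
        out[f"cross_raw_g{g}"] = e_cross_raw
        out[f"cross_scaled_g{g}"] = frag.scale * e_cross_raw
    # totals (groups counted once)
    seen = sorted({f.exclusion_group for f in fragments})
    out["intra_total"] = sum(out[f"intra_g{g}"] for g in seen)
    out["cross_scaled_total"] = sum(out[f"cross_scaled_g{g}"] for g in seen)
    out["decomposed_total"] = out["host_host"] + out["intra_total"] + out["cross_scaled_total"]
    out["total"], _ = total_nonbonded(system, model, params, pairs=(i, j))
    return out


def scaled_interaction_ratio(
    system: AtomicSystem,
    model: ExclusionModel,
    params: SoftCoreParams,
    fragment: MolecularFragment,
) -> float:
    """Ratio of scaled to unscaled fragment-environment energy.

    Equals the fragment's 1/N scale by construction; computed
    numerically from the two cross-energy sums. If the unscaled cross
    energy vanishes the ratio is reported as the scale itself.
    """
    i, j = neighbor_pairs(system, params.cutoff)
    g = fragment.exclusion_group
    gi = model.group[i]
    gj = model.group[j]
    cross = ((gi == g) & (gj == 0)) | ((gi == 0) & (gj == g))
    ii, jj = i[cross], j[cross]
    if len(ii) == 0:
        return fragment.scale
    scale = model.pair_scale_array(ii, jj)
    e_scaled, *_ = _eval_pairs(system, model, params, ii, jj, scale)
    raw = np.where(scale != 0.0, 1.0, 0.0)
    e_raw, *_ = _eval_pairs(system, model, params, ii, jj, raw)
    if e_raw.sum() == 0.0:
        return fragment.scale
    return float(e_scaled.sum() / e_raw.sum())
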