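"""Restrained-ensemble distance-histogram energy.

For a pair of label sites i, j with N copies each, the N^2 probe-probe
distances are smeared with a Gaussian of width sigma onto the grid of
bin centers n * delta_r (n = 1..n_bins):

    raw(n) = (1/N^2) sum_{s,s'} (2 pi sigma^2)^(-1/2)
             exp(-(n delta_r - d_ss')^2 / 2 sigma^2)

The simulated histogram h(n) is raw(n) renormalized to unit mass over
the bin window, and the restraint energy against the target H is

    U = (K/2) sum_n (h(n) - H(n))^2 .

Forces are the exact gradient of U with respect to the probe-atom
Cartesian coordinates, including the quotient-rule term from the
renormalization; no other atom feels this restraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragments import CopyEnsemble
from .system import HistogramError, HistogramTable


def _gauss_matrix(distances: np.ndarray, sigma: float, delta_r: float, n_bins: int):
    """G[p, n] = N(bin_center_n - d_p; sigma) for flattened distances."""
    centers = delta_r * np.arange(1, n_bins + 1)
    u = centers[None, :] - distances[:, None]
    pref = 1.0 / np.sqrt(2.0 * np.pi * sigma * sigma)
    return u, pref * np.exp(-(u * u) / (2.0 * sigma * sigma))


def smoothed_histogram(
    distances: np.ndarray, sigma: float, delta_r: float, n_bins: int
) -> HistogramTable:
    """Gaussian-smoothed, renormalized ensemble distance histogram."""
    d = np.asarray(distances, dtype=float).ravel()
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if sigma <= 0 or delta_r <= 0:
        raise ValueError("sigma and delta_r must be positive")
    _, G = _gauss_matrix(d, sigma, delta_r, n_bins)
    raw = G.mean(axis=0)
    mass = raw.sum() * delta_r
    if mass < 1e-12:
        raise HistogramError(
            "ensemble distances fall outside the histogram window; no mass to normalize"
        )
    return HistogramTable(delta_r, raw / mass)


def restraint_energy(hbar: HistogramTable, target: HistogramTable, K: float) -> float:
    """U = (K/2) sum_n (h(n) - H(n))^2 over a shared bin grid."""
    if not hbar.same_grid(target):
        raise HistogramError("simulated and target histograms are on different bin grids")
    diff = hbar.values - target.values
    return float(0.5 * K * np.dot(diff, diff))


@dataclass
class HistogramRestraint:
    """One site-pair ensemble restraint toward a target histogram."""

    site_pair: tuple[int, int]
    probe_atoms_i: list[int]
    probe_atoms_j: list[int]
    target: HistogramTable
    K: float = 500.0
    sigma: float = 1.1
    delta_r: float = 1.0
    n_bins: int = 60

    def __post_init__(self) -> None:
        if self.site_pair[0] == self.site_pair[1]:
            raise ValueError("self-pairs are undefined for histogram restraints")
        if self.K <= 0 or self.sigma <= 0 or self.delta_r <= 0:
            raise ValueError("K, sigma, delta_r must be positive")
        if self.target.n_bins != self.n_bins:
            raise HistogramError("target histogram grid does not match n_bins")
        m = self.target.mass
        if abs(m - 1.0) > 1e-8:
            raise HistogramError(f"target histogram mass {m} != 1; normalize it first")

    def distances(self, positions: np.ndarray) -> np.ndarray:
        pi = positions[self.probe_atoms_i]
        pj = positions[self.probe_atoms_j]
        diff = pi[:, None, :] - pj[None, :, :]
        return np.sqrt(np.sum(diff * diff, axis=-1))

    def histogram(self, positions: np.ndarray) -> HistogramTable:
        return smoothed_histogram(self.distances(positions), self.sigma, self.delta_r, self.n_bins)

    def energy_forces(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        """Energy and forces on the probe atoms (zeros elsewhere)."""
        ni, nj = len(self.probe_atoms_i), len(self.probe_atoms_j)
        pi = positions[self.probe_atoms_i]
        pj = positions[self.probe_atoms_j]
        diff = pi[:, None, :] - pj[None, :, :]
        dmat = np.sqrt(np.sum(diff * diff, axis=-1))
        d = dmat.ravel()
        npairs = ni * nj
        u, G = _gauss_matrix(d, self.sigma, self.delta_r, self.n_bins)
        raw = G.mean(axis=0)
        Z = raw.sum() * self.delta_r
        if Z < 1e-12:
            raise HistogramError("ensemble distances fall outside the histogram window")
        h = raw / Z
        dv = h - self.target.values
        energy = 0.5 * self.K * float(np.dot(dv, dv))
        # dU/dd_p = K [ (dv . A_p)/Z - (dv . raw)/Z^2 * delta_r * sum_n A_p(n) ]
        # with A_p(n) = d raw(n) / d d_p = (1/npairs) G[p,n] u[p,n] / sigma^2
        A = G * u / (self.sigma * self.sigma) / npairs
        dU_dd = self.K * (A @ dv / Z - (np.dot(dv, raw) / (Z * Z)) * self.delta_r * A.sum(axis=1))
        forces = np.zeros_like(positions)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_d = np.where(dmat > 1e-12, 1.0 / dmat, 0.0)
        w = (dU_dd.reshape(ni, nj) * inv_d)[:, :, None]
        fvec = -w * diff  # force on probe i_s from pair (s, s')
        np.add.at(forces, self.probe_atoms_i, fvec.sum(axis=1))
        np.add.at(forces, self.probe_atoms_j, -fvec.sum(axis=0))
        return energy, forces


def ensemble_distance_matrix(
    ensemble_i: CopyEnsemble, ensemble_j: CopyEnsemble, positions: np.ndarray
) -> np.ndarray:
    """All N_i x N_j probe-probe distances across two distinct sites."""
    if ensemble_i.site == ensemble_j.site:
        raise ValueError("self-pairs (same site) are undefined")
    pi = positions[ensemble_i.probe_atoms]
    pj = positions[ensemble_j.probe_atoms]
    diff = pi[:, None, :] - pj[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def restraint_forces(
    restraint: HistogramRestraint, positions: np.ndarray
) -> np.ndarray:
    """Forces only (see :meth:`HistogramRestraint.energy_forces`)."""
    return restraint.energy_forces(positions)[1]
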