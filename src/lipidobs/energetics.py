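"""Short-range peptide-lipid interaction energies and their decompositions.

Computes truncated Coulomb and Lennard-Jones pair energies between peptide
residues and lipid species, time-averaged with block errors, plus the
net / normalized / percentage contribution arithmetic used to compare
systems.  Electrostatics are plain truncated Coulomb (no mesh term): a
per-pair decomposition of mesh electrostatics is ill-defined, so group
energies here are short-range terms by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import COULOMB_CONSTANT
from .core_io import (LIPID_SPECIES, Topology, Trajectory,
                      block_average_matrix, select)


def pair_energy(q1: float, q2: float, sigma: float, epsilon: float,
                r: float, cutoff: float | None = None):
    """Coulomb and LJ energy (kJ/mol) of one atom pair at separation r (nm).

    coulomb = f*q1*q2/r with f = 138.935458 kJ mol^-1 nm e^-2;
    lj = 4*eps*((sigma/r)^12 - (sigma/r)^6).  Both are zero beyond the
    cutoff when one is given.
    """
    if r == 0:
        raise ValueError("overlapping atoms: r = 0")
    if cutoff is not None and r > cutoff:
        return 0.0, 0.0
    coul = COULOMB_CONSTANT * q1 * q2 / r
    if epsilon == 0.0:
        lj = 0.0
    else:
        sr6 = (sigma / r) ** 6
        lj = 4.0 * epsilon * (sr6 * sr6 - sr6)
    return coul, lj


def combine_lj(sig_i, eps_i, sig_j, eps_j, rule: str = "lorentz-berthelot"):
    """Combine per-atom LJ parameters; arrays broadcast."""
    if rule == "lorentz-berthelot":
        return (np.add(sig_i, sig_j) / 2.0, np.sqrt(np.multiply(eps_i, eps_j)))
    if rule == "geometric":
        return (np.sqrt(np.multiply(sig_i, sig_j)),
                np.sqrt(np.multiply(eps_i, eps_j)))
    raise ValueError(f"unknown combining rule {rule!r}")


@dataclass
class EnergyDecomposition:
    """Residue x lipid-species Coulomb/LJ matrices with block errors."""

    residues: list
    species: list
    elec: np.ndarray
    vdw: np.ndarray
    elec_err: np.ndarray
    vdw_err: np.ndarray
    species_counts: dict
    cutoff: float

    def __post_init__(self):
        shape = (len(self.residues), len(self.species))
        for m in (self.elec, self.vdw, self.elec_err, self.vdw_err):
            if np.asarray(m).shape != shape:
                raise ValueError("matrix shape inconsistent with labels")
        if (self.elec_err < 0).any() or (self.vdw_err < 0).any():
            raise ValueError("errors must be >= 0")
        for sp in self.species:
            if self.species_counts.get(sp, 0) <= 0:
                raise ValueError(f"species_counts must be > 0 for {sp}")

    def totals(self):
        return float(self.elec.sum()), float(self.vdw.sum())

    def to_frame(self, which: str = "elec") -> pd.DataFrame:
        mat = {"elec": self.elec, "vdw": self.vdw,
               "elec_err": self.elec_err, "vdw_err": self.vdw_err}[which]
        return pd.DataFrame(mat, index=self.residues, columns=self.species)


def residue_labels(topo: Topology, indices) -> np.ndarray:
    a = topo.atoms
    return np.array([f"{a['residue_name'].iloc[i]}_{a['residue_index'].iloc[i]}"
                     for i in indices])


def interaction_energy_matrix(traj: Trajectory, topo: Topology,
                              peptide_sel: str = "species == PEPTIDE",
                              cutoff: float = 1.2,
                              combining: str = "lorentz-berthelot",
                              n_blocks: int = 5,
                              method: str = "cell",
                              lipid_sel: str | None = None) -> EnergyDecomposition:
    """Time-averaged peptide-residue x lipid-species energy matrices.

    For every frame, pair energies over peptide-atom / lipid-atom pairs
    within the cutoff (minimum image) are accumulated into
    (residue, species) cells; block errors come from the per-frame series.
    ``method`` picks the periodic KD-tree neighbour search ('cell') or the
    all-pairs evaluation ('brute'); both must agree.
    """
    pep_idx = select(topo, peptide_sel)
    if len(pep_idx) == 0:
        raise ValueError("peptide selection is empty")
    a = topo.atoms
    if lipid_sel is not None:
        lip_mask = np.zeros(len(a), dtype=bool)
        lip_mask[select(topo, lipid_sel)] = True
    else:
        lip_mask = a["species"].isin(LIPID_SPECIES).to_numpy()
    lip_mask[pep_idx] = False          # reference group never pairs itself
    lip_idx = np.nonzero(lip_mask)[0]
    if len(lip_idx) == 0:
        raise ValueError("no lipid species present")
    if cutoff > traj.boxes.min() / 2:
        raise ValueError(
            f"cutoff {cutoff} nm exceeds half the smallest box edge "
            f"({traj.boxes.min() / 2:.3f} nm): minimum image is violated")

    res_lab = residue_labels(topo, pep_idx)
    residues = list(dict.fromkeys(res_lab))          # first-appearance order
    species = sorted(set(a["species"].iloc[lip_idx]))
    ri = {r: i for i, r in enumerate(residues)}
    si = {s: i for i, s in enumerate(species)}
    row_of_pep = np.array([ri[r] for r in res_lab])
    col_of_lip = np.array([si[s] for s in a["species"].iloc[lip_idx]])

    q = a["charge"].to_numpy(float)
    sg = a["lj_sigma"].to_numpy(float)
    ep = a["lj_epsilon"].to_numpy(float)

    n_frames = traj.n_frames
    elec_t = np.zeros((n_frames, len(residues), len(species)))
    vdw_t = np.zeros_like(elec_t)

    for f in range(n_frames):
        box = traj.boxes[f]
        pp = traj.coords[f][pep_idx] % box
        lp = traj.coords[f][lip_idx] % box
        if method == "brute":
            d = pp[:, None, :] - lp[None, :, :]
            d -= box * np.floor(d / box + 0.5)
            r = np.sqrt((d ** 2).sum(-1))
            ii, jj = np.nonzero(r <= cutoff)
            rr = r[ii, jj]
        elif method == "cell":
            tree_l = cKDTree(lp, boxsize=box)
            tree_p = cKDTree(pp, boxsize=box)
            pairs = tree_p.query_ball_tree(tree_l, r=cutoff)
            ii = np.concatenate([np.full(len(js), i, dtype=int)
                                 for i, js in enumerate(pairs)]) \
                if any(pairs) else np.empty(0, dtype=int)
            jj = np.concatenate([np.asarray(js, dtype=int) for js in pairs]) \
                if any(pairs) else np.empty(0, dtype=int)
            if len(ii):
                d = pp[ii] - lp[jj]
                d -= box * np.floor(d / box + 0.5)
                rr = np.sqrt((d ** 2).sum(-1))
                keep = rr <= cutoff
                ii, jj, rr = ii[keep], jj[keep], rr[keep]
            else:
                rr = np.empty(0)
        else:
            raise ValueError(f"unknown method {method!r}")
        if len(ii) == 0:
            continue
        if (rr == 0).any():
            raise ValueError("overlapping atoms: r = 0")
        gi, gj = pep_idx[ii], lip_idx[jj]
        coul = COULOMB_CONSTANT * q[gi] * q[gj] / rr
        sij, eij = combine_lj(sg[gi], ep[gi], sg[gj], ep[gj], combining)
        sr6 = np.where(eij > 0, (sij / rr) ** 6, 0.0)
        lj = 4.0 * eij * (sr6 * sr6 - sr6)
        np.add.at(elec_t[f], (row_of_pep[ii], col_of_lip[jj]), coul)
        np.add.at(vdw_t[f], (row_of_pep[ii], col_of_lip[jj]), lj)

    elec, elec_err = block_average_matrix(elec_t, n_blocks) \
        if n_frames >= n_blocks else (elec_t.mean(0), np.zeros_like(elec_t[0]))
    vdw, vdw_err = block_average_matrix(vdw_t, n_blocks) \
        if n_frames >= n_blocks else (vdw_t.mean(0), np.zeros_like(vdw_t[0]))

    counts = topo.species_molecule_counts()
    return EnergyDecomposition(residues, species, elec, vdw, elec_err,
                               vdw_err,
                               {s: counts[s] for s in species}, cutoff)


@dataclass
class ContributionReport:
    """Per-species net shares (%) and per-molecule normalized energies."""

    table: pd.DataFrame   # index species; columns elec_share_pct,
    # elec_normalized, vdw_share_pct, vdw_normalized, elec_net, vdw_net
    total_elec: float
    total_vdw: float


def contribution_report(decomp: EnergyDecomposition) -> ContributionReport:
    """Net percentage share and per-molecule normalized energy per species.

    share(species) = 100 * sum_residues E[., species] / sum_all E;
    normalized(species) = net(species) / molecule count of that species.
    """
    e_net = decomp.elec.sum(axis=0)
    v_net = decomp.vdw.sum(axis=0)
    te, tv = e_net.sum(), v_net.sum()
    if te == 0 or tv == 0:
        raise ValueError("zero total energy: percentage shares undefined")
    counts = np.array([decomp.species_counts[s] for s in decomp.species],
                      dtype=float)
    table = pd.DataFrame({
        "elec_net": e_net, "vdw_net": v_net,
        "elec_share_pct": 100.0 * e_net / te,
        "vdw_share_pct": 100.0 * v_net / tv,
        "elec_normalized": e_net / counts,
        "vdw_normalized": v_net / counts,
    }, index=decomp.species)
    return ContributionReport(table, float(te), float(tv))


def percentage_share(e_elec: float, e_vdw: float) -> float:
    """Electrostatic percentage of the total (elec + vdW) energy.

    Well-defined for same-sign components; an opposite-sign pair whose sum
    nearly cancels has no meaningful share and raises.
    """
    total = e_elec + e_vdw
    if e_elec * e_vdw < 0 and abs(total) < 1e-9 * max(abs(e_elec), abs(e_vdw)):
        raise ValueError("components cancel: share undefined")
    if total == 0:
        raise ValueError("zero total energy: share undefined")
    return 100.0 * e_elec / total


def fold_change(e_ref: float, e_new: float) -> float:
    """Ratio e_new / e_ref (e.g. tetramer vs monomer component energy)."""
    if e_ref == 0:
        raise ValueError("zero reference energy")
    return e_new / e_ref
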