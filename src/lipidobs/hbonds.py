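"""Geometric hydrogen-bond detection and residue x lipid-species tables.

A bond is a (donor, hydrogen, acceptor) triplet with donor-acceptor
distance <= d_DA_max and H-D-A angle <= angle_HDA_max under the minimum
image.  Defaults (0.35 nm, 30 deg) are the de-facto standard geometric
criteria; both are exposed because conventions differ between tools.
Donors are N/O heavy atoms carrying at least one bonded hydrogen; acceptors
are N/O atoms.  Hydrogen attachment comes from an explicit ``bonded_to``
topology field when present, else from proximity (< 0.12 nm, same molecule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (LIPID_SPECIES, Topology, Trajectory,
                      block_average_matrix, minimum_image_displacement,
                      select)
from .energetics import residue_labels

DEFAULT_D_MAX = 0.35      # nm, donor-acceptor distance
DEFAULT_ANGLE_MAX = 30.0  # degrees, H-D-A angle

_BOND_HX_MAX = 0.12  # nm: H belongs to the nearest N/O closer than this


def _hydrogen_parents(coords, box, topo: Topology):
    """Map hydrogen atom index -> parent heavy atom index."""
    a = topo.atoms
    names = a["name"].astype(str)
    is_h = (a["atomic_number"] == 1).to_numpy()
    heavy_no = names.str.startswith(("N", "O")).to_numpy() & ~is_h
    parents = {}
    has_bonds = "bonded_to" in a.columns
    id_to_idx = {int(aid): i for i, aid in enumerate(a["atom_id"])}
    for h in np.nonzero(is_h)[0]:
        if has_bonds and not pd.isna(a["bonded_to"].iloc[h]):
            parents[h] = id_to_idx[int(a["bonded_to"].iloc[h])]
            continue
        mol = a["molecule_id"].iloc[h]
        cand = np.nonzero(heavy_no & (a["molecule_id"] == mol).to_numpy())[0]
        if len(cand) == 0:
            continue
        d = minimum_image_displacement(coords[h], coords[cand], box)
        r = np.sqrt((d ** 2).sum(-1))
        j = int(np.argmin(r))
        if r[j] < _BOND_HX_MAX:
            parents[h] = int(cand[j])
    return parents


def detect_hbonds(coords, box, topo: Topology,
                  donors: str = "species == PEPTIDE",
                  acceptors: str | None = None,
                  d_DA_max: float = DEFAULT_D_MAX,
                  angle_HDA_max: float = DEFAULT_ANGLE_MAX):
    """All (donor, hydrogen, acceptor) triplets in one frame.

    ``donors``/``acceptors`` are selection expressions restricting the
    candidate heavy atoms; N*/O* typing and hydrogen attachment are applied
    within those selections.  Returns sorted triplets of atom indices.
    """
    coords = np.asarray(coords, dtype=float)
    a = topo.atoms
    names = a["name"].astype(str)
    is_no = names.str.startswith(("N", "O")).to_numpy() \
        & (a["atomic_number"] != 1).to_numpy()

    don_pool = select(topo, donors)
    acc_pool = select(topo, acceptors) if acceptors else np.arange(len(a))
    parents = _hydrogen_parents(coords, box, topo)
    children: dict[int, list[int]] = {}
    for h, p in parents.items():
        children.setdefault(p, []).append(h)

    don_idx = [i for i in don_pool if is_no[i]]
    for i in don_idx:
        if i not in children and str(names.iloc[i]).startswith("N"):
            # amide/amine nitrogen selected as a donor must carry a hydrogen
            raise ValueError(
                f"donor atom {int(a['atom_id'].iloc[i])} "
                f"({names.iloc[i]}) has no bonded hydrogen")
    don_idx = [i for i in don_idx if i in children]
    acc_idx = np.array([i for i in acc_pool if is_no[i]], dtype=int)

    out = []
    for d in don_idx:
        if len(acc_idx) == 0:
            break
        disp = minimum_image_displacement(coords[d], coords[acc_idx], box)
        r = np.sqrt((disp ** 2).sum(-1))
        near = np.nonzero((r <= d_DA_max) & (acc_idx != d))[0]
        for k in near:
            acc = int(acc_idx[k])
            if parents.get(acc) == d or acc in children.get(d, []):
                continue
            v_da = disp[k]
            for h in children[d]:
                v_dh = minimum_image_displacement(coords[d], coords[h], box)
                denom = np.linalg.norm(v_dh) * np.linalg.norm(v_da)
                if denom == 0:
                    continue
                cosang = np.clip(v_dh @ v_da / denom, -1.0, 1.0)
                if np.degrees(np.arccos(cosang)) <= angle_HDA_max:
                    out.append((d, h, acc))
    return sorted(set(out))


@dataclass
class HBondTable:
    """Mean bonds-per-frame by (peptide residue, lipid species)."""

    residues: list
    species: list
    mean_counts: np.ndarray
    errors: np.ndarray
    criteria: tuple  # (d_DA_max nm, angle_HDA_max deg)

    def __post_init__(self):
        if (self.mean_counts < 0).any() or (self.errors < 0).any():
            raise ValueError("counts and errors must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_counts, index=self.residues,
                            columns=self.species)


def hbond_table(traj: Trajectory, topo: Topology,
                peptide_sel: str = "species == PEPTIDE",
                d_DA_max: float = DEFAULT_D_MAX,
                angle_HDA_max: float = DEFAULT_ANGLE_MAX,
                n_blocks: int = 5) -> HBondTable:
    """Per-frame peptide-donor -> lipid-acceptor bond counts, averaged."""
    if traj.n_frames == 0:
        raise ValueError("empty analysis window")
    a = topo.atoms
    pep_idx = select(topo, peptide_sel)
    res_lab = residue_labels(topo, pep_idx)
    residues = list(dict.fromkeys(res_lab))
    species = sorted(set(a["species"]) & set(LIPID_SPECIES))
    ri = {r: i for i, r in enumerate(residues)}
    si = {s: i for i, s in enumerate(species)}
    res_of_atom = {int(i): r for i, r in zip(pep_idx, res_lab)}

    counts_t = np.zeros((traj.n_frames, len(residues), len(species)))
    for f in range(traj.n_frames):
        triplets = detect_hbonds(traj.coords[f], traj.boxes[f], topo,
                                 donors=peptide_sel,
                                 d_DA_max=d_DA_max,
                                 angle_HDA_max=angle_HDA_max)
        for d, h, acc in triplets:
            sp = a["species"].iloc[acc]
            if sp in si and d in res_of_atom:
                counts_t[f, ri[res_of_atom[d]], si[sp]] += 1
    if traj.n_frames >= n_blocks:
        mean, err = block_average_matrix(counts_t, n_blocks)
    else:
        mean, err = counts_t.mean(0), np.zeros_like(counts_t[0])
    return HBondTable(residues, species, mean, err,
                      (d_DA_max, angle_HDA_max))


def aggregate_table(table: HBondTable, axis: str) -> dict:
    """Marginal sums of the table: 'by_residue' sums over species for each
    residue; 'by_species' sums over residues for each species."""
    if len(table.residues) == 0 or len(table.species) == 0:
        raise ValueError("empty table")
    m = np.asarray(table.mean_counts, dtype=float)
    if axis == "by_residue":
        sums = m.sum(axis=1)
        return {r: float(s) for r, s in zip(table.residues, sums)}
    if axis == "by_species":
        sums = m.sum(axis=0)
        return {s: float(v) for s, v in zip(table.species, sums)}
    raise ValueError(f"unknown axis {axis!r}")
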