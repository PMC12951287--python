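"""Gyration tensor, radius of gyration and relative shape anisotropy.

The mass-weighted gyration tensor of a point set is the second-moment
tensor about the centre of mass; with its eigenvalues sorted
lambda1 >= lambda2 >= lambda3, Rg^2 = lambda1 + lambda2 + lambda3 and the
relative shape anisotropy is

    kappa^2 = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1 + l2 + l3)^2 ,

which is 0 for spherically symmetric spectra (three equal eigenvalues),
exactly 0.25 for a symmetric planar structure (two equal, one zero) and 1
for a linear chain (one nonzero eigenvalue).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Topology, Trajectory, select


@dataclass
class GyrationReport:
    """Sorted gyration eigenvalues (nm^2), Rg^2 and kappa^2."""

    lambda1: float
    lambda2: float
    lambda3: float
    Rg2: float
    kappa2: float

    def __post_init__(self):
        if not self.lambda1 >= self.lambda2 >= self.lambda3 >= -1e-12:
            raise ValueError("eigenvalues must be sorted descending, >= 0")
        if not -1e-9 <= self.kappa2 <= 1 + 1e-9:
            raise ValueError("kappa^2 must lie in [0, 1]")

    @property
    def eigenvalues(self):
        return np.array([self.lambda1, self.lambda2, self.lambda3])


def gyration_tensor(coords, masses=None) -> GyrationReport:
    """Mass-weighted gyration tensor report for one point set.

    ``masses=None`` means equal weights.  All-coincident points have
    Rg^2 = 0 and an undefined anisotropy, which raises.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or len(x) < 2:
        raise ValueError("need >= 2 points of shape (n, 3)")
    w = np.ones(len(x)) if masses is None else np.asarray(masses, float)
    if w.sum() <= 0:
        raise ValueError("total mass must be > 0")
    com = np.average(x, axis=0, weights=w)
    d = x - com
    S = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(0) / w.sum()
    lam = np.linalg.eigvalsh(S)[::-1]
    lam = np.clip(lam, 0.0, None)
    rg2 = float(lam.sum())
    if rg2 == 0.0:
        raise ValueError("all points coincident: Rg^2 = 0, "
                         "shape anisotropy undefined")
    kappa2 = 1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2]
                          + lam[2] * lam[0]) / rg2 ** 2
    return GyrationReport(float(lam[0]), float(lam[1]), float(lam[2]),
                          rg2, float(np.clip(kappa2, 0.0, 1.0)))


def _make_whole(coords, box):
    """Shift atoms to the periodic image nearest the first atom."""
    d = coords - coords[0]
    d -= box * np.floor(d / box + 0.5)
    return coords[0] + d


def rsa_density(traj: Trajectory, topo: Topology,
                selection: str = "species == PEPTIDE", n_bins: int = 50,
                mass_weighted: bool = True):
    """Probability density of kappa^2 over frames and molecules.

    The selection is split by molecule_id (several peptide copies give one
    sample per copy per frame); each molecule is made whole across the
    periodic boundary first.  Returns (bin centres in [0,1], density)
    normalised to integrate to 1.
    """
    if traj.n_frames == 0:
        raise ValueError("empty analysis window")
    idx = select(topo, selection)
    if len(idx) < 2:
        raise ValueError("selection must span at least 2 atoms")
    a = topo.atoms
    groups = [grp.index.to_numpy()
              for _, grp in a.iloc[idx].groupby("molecule_id")]
    masses = a["mass"].to_numpy(float)
    samples = []
    for f in range(traj.n_frames):
        for g in groups:
            if len(g) < 2:
                continue
            pts = _make_whole(traj.coords[f][g], traj.boxes[f])
            rep = gyration_tensor(pts, masses[g] if mass_weighted else None)
            samples.append(rep.kappa2)
    hist, edges = np.histogram(samples, bins=n_bins, range=(0.0, 1.0),
                               density=True)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, hist
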