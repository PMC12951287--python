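"""Desk-scale synthetic trajectories with analytic ground truth.

Each generator returns ``(Trajectory, Topology, GroundTruth)`` where the
GroundTruth carries every parameter needed to compute the analytic
expectation of the observable the fixture targets: true lateral diffusion
coefficients for Brownian bilayers, the true C-H tilt angle for ordered
chains, the planted cluster count, the capacitor potential drop for charge
slabs, and the exact relative shape anisotropy for rigid shape fixtures.

Lipids are single-site headgroup proxies except where the observable needs
chains (order parameters).  Every generator is a pure function of its
parameters and seed; random streams are per-molecule substreams of the
master seed so adding molecules never reshuffles existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import CM2_PER_S_TO_NM2_PER_PS, POTENTIAL_E_PER_NM_TO_VOLT
from .core_io import Topology, Trajectory

#: Gram-positive model-membrane composition: species -> (atoms per molecule,
#: formal charge in e, molecules per leaflet).
TABLE_COMPOSITION = {
    "AIPE": (115, 0, 11),
    "AIPG": (117, -1, 27),
    "DPPE": (121, 0, 3),
    "DPPG": (123, -1, 7),
    "MAIPE": (112, 0, 9),
    "MAIPG": (114, -1, 22),
    "PAIPE": (118, 0, 4),
    "PAIPG": (120, -1, 9),
    "PAICL": (226, -2, 8),
}

GENERATOR_KINDS = ("brownian", "ordered_chains", "planted_clusters",
                   "charge_slabs", "shape_fixture", "dimer", "hbond_fixture")


@dataclass
class GroundTruth:
    """Generator parameters sufficient for the matching analytic oracle."""

    kind: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in GENERATOR_KINDS:
            raise ValueError(f"unknown ground-truth kind {self.kind!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "parameters": self.parameters}, fh,
                      default=str)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(doc["kind"], doc["parameters"])


def _lipid_atom(atom_id, mol_id, species, leaflet, charge=0.0, name="P",
                atomic_number=15, mass=30.97, lj_sigma=0.35, lj_epsilon=0.5,
                residue_name=None, residue_index=None):
    return dict(atom_id=atom_id, name=name, atomic_number=atomic_number,
                residue_name=residue_name or species,
                residue_index=residue_index if residue_index is not None else mol_id,
                molecule_id=mol_id, species=species, charge=float(charge),
                lj_sigma=lj_sigma, lj_epsilon=lj_epsilon, mass=mass,
                leaflet=leaflet)


def _mol_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def make_brownian_bilayer(composition: Mapping[str, int],
                          D_map: Mapping[str, float],
                          n_frames: int, dt: float,
                          box=(10.0, 10.0, 8.0), seed: int = 0,
                          leaflet_offset: float = 1.83):
    """Two-leaflet bilayer of single-site lipids doing 2D Brownian motion.

    Each lipid takes independent Gaussian lateral steps with variance
    ``2*D*dt`` per axis at fixed z = box centre +/- ``leaflet_offset``;
    ``D_map`` is in cm^2/s, dt in ps.  Both leaflets carry ``composition``.
    """
    box = np.asarray(box, dtype=float)
    if n_frames < 1 or dt <= 0:
        raise ValueError("need n_frames >= 1 and dt > 0")
    for sp, D in D_map.items():
        if not np.isfinite(D) or D < 0:
            raise ValueError(f"non-finite or negative D for species {sp}")
    for sp, cnt in composition.items():
        if cnt <= 0:
            raise ValueError(f"non-positive count for species {sp}")

    atoms, walks = [], []
    idx = 0
    zc = box[2] / 2.0
    for leaflet, zsign in (("upper", +1), ("lower", -1)):
        for sp in sorted(composition):
            D_nm2_ps = D_map.get(sp, 0.0) * CM2_PER_S_TO_NM2_PER_PS
            step_sd = np.sqrt(2.0 * D_nm2_ps * dt)
            charge = TABLE_COMPOSITION.get(sp, (0, 0, 0))[1]
            for _ in range(composition[sp]):
                rng = _mol_rng(seed, idx)
                xy0 = rng.uniform(0, box[:2])
                steps = rng.normal(0.0, step_sd, size=(n_frames - 1, 2)) \
                    if n_frames > 1 else np.zeros((0, 2))
                xy = np.vstack([xy0, xy0 + np.cumsum(steps, axis=0)]) \
                    if n_frames > 1 else xy0[None, :]
                z = np.full((n_frames, 1), zc + zsign * leaflet_offset)
                walks.append(np.hstack([xy, z]))
                atoms.append(_lipid_atom(idx, idx + 1, sp, leaflet,
                                         charge=charge))
                idx += 1
    coords = np.stack(walks, axis=1)  # (frames, atoms, 3)
    coords[..., 0] %= box[0]
    coords[..., 1] %= box[1]
    times = np.arange(n_frames) * dt
    boxes = np.tile(box, (n_frames, 1))
    topo = Topology(pd.DataFrame(atoms))
    truth = GroundTruth("brownian", {
        "D_true": dict(D_map), "dt": dt, "n_frames": n_frames,
        "leaflet_offset": leaflet_offset, "seed": seed,
    })
    return Trajectory(times, boxes, coords), topo, truth


def make_ordered_chains(theta_deg: float, n_lipids: int, n_carbons: int,
                        box=(12.0, 12.0, 10.0), seed: int = 0,
                        species: str = "MAIPG", n_frames: int = 5):
    """Lipids with two acyl chains whose every C-H bond tilts ``theta_deg``
    from the +z bilayer normal (azimuth uniform random per bond)."""
    if not 0.0 <= theta_deg <= 180.0:
        raise ValueError("theta must be in [0, 180] degrees")
    if n_carbons < 2:
        raise ValueError("need n_carbons >= 2")
    box = np.asarray(box, dtype=float)
    theta = np.radians(theta_deg)
    bond = 0.109  # C-H bond length, nm
    n_side = int(np.ceil(np.sqrt(n_lipids)))
    pitch = box[0] / n_side

    atoms, pos = [], []
    chain_map = {"SN1": {"carbons": [], "hydrogens": {}},
                 "SN2": {"carbons": [], "hydrogens": {}}}
    for ci in range(1, n_carbons + 1):
        for chain, pref in (("SN1", "C1"), ("SN2", "C2")):
            cname = f"{pref}{ci}"
            chain_map[chain]["carbons"].append(cname)
            chain_map[chain]["hydrogens"][cname] = [f"H{pref[1]}{ci}A",
                                                    f"H{pref[1]}{ci}B"]
    aid = 0
    for li in range(n_lipids):
        rng = _mol_rng(seed, li)
        ox = (li % n_side + 0.5) * pitch
        oy = (li // n_side + 0.5) * pitch
        top_z = box[2] / 2 + 1.5
        for chain, pref, xoff in (("SN1", "C1", -0.25), ("SN2", "C2", 0.25)):
            for ci in range(1, n_carbons + 1):
                cpos = np.array([ox + xoff, oy, top_z - 0.127 * ci])
                atoms.append(_lipid_atom(aid, li + 1, species, "upper",
                                         name=f"{pref}{ci}", atomic_number=6,
                                         mass=12.011, lj_sigma=0.36,
                                         lj_epsilon=0.3))
                pos.append(cpos)
                aid += 1
                for hl in ("A", "B"):
                    phi = rng.uniform(0, 2 * np.pi)
                    u = np.array([np.sin(theta) * np.cos(phi),
                                  np.sin(theta) * np.sin(phi),
                                  np.cos(theta)])
                    atoms.append(_lipid_atom(aid, li + 1, species, "upper",
                                             name=f"H{pref[1]}{ci}{hl}",
                                             atomic_number=1, mass=1.008,
                                             lj_sigma=0.24, lj_epsilon=0.1))
                    pos.append(cpos + bond * u)
                    aid += 1
    coords = np.tile(np.asarray(pos), (n_frames, 1, 1))
    times = np.arange(n_frames, dtype=float)
    boxes = np.tile(box, (n_frames, 1))
    topo = Topology(pd.DataFrame(atoms), {species: chain_map})
    truth = GroundTruth("ordered_chains", {
        "theta_true": theta_deg, "n_carbons": n_carbons,
        "expected_scd": float(abs(3 * np.cos(theta) ** 2 - 1) / 2),
        "species": species, "seed": seed,
    })
    return Trajectory(times, boxes, coords), topo, truth


def make_planted_clusters(k_clusters: int, m_per_cluster: int,
                          intra_spacing: float, inter_spacing: float,
                          species: str = "MAIPG", box=(20.0, 20.0, 8.0),
                          n_frames: int = 5):
    """k well-separated groups of m single-site lipids in the upper leaflet.

    Consecutive members within a group sit ``intra_spacing`` apart; group
    envelopes are at least ``inter_spacing`` apart.
    """
    box = np.asarray(box, dtype=float)
    extent = (m_per_cluster - 1) * intra_spacing
    pitch = inter_spacing + extent
    n_side = int(np.ceil(np.sqrt(k_clusters)))
    if n_side * pitch > min(box[0], box[1]):
        raise ValueError(
            f"{k_clusters} clusters of extent {extent:.2f} nm with "
            f"{inter_spacing:.2f} nm gaps do not fit in the box")
    atoms, pos = [], []
    aid = 0
    z = box[2] / 2 + 1.8
    for c in range(k_clusters):
        cx = (c % n_side) * pitch + extent / 2 + inter_spacing / 2
        cy = (c // n_side) * pitch + inter_spacing / 2
        for m in range(m_per_cluster):
            pos.append([cx - extent / 2 + m * intra_spacing, cy, z])
            atoms.append(_lipid_atom(aid, aid + 1, species, "upper"))
            aid += 1
    coords = np.tile(np.asarray(pos, dtype=float), (n_frames, 1, 1))
    topo = Topology(pd.DataFrame(atoms))
    truth = GroundTruth("planted_clusters", {
        "k_clusters": k_clusters, "m_per_cluster": m_per_cluster,
        "intra_spacing": intra_spacing, "inter_spacing": inter_spacing,
        "species": species,
    })
    return (Trajectory(np.arange(n_frames, dtype=float),
                       np.tile(box, (n_frames, 1)), coords), topo, truth)


def make_charge_slabs(sigma_surface: float, gap: float, box=(6.0, 6.0, 12.0),
                      n_points_per_sheet: int = 400):
    """Parallel-plate capacitor: two grids of point charges at +/- gap/2
    about the box centre carrying uniform surface charge +/- sigma.

    The analytic potential is linear inside the gap and constant outside,
    with total drop sigma*gap/eps0 (stored in volts in the ground truth).
    """
    if not np.isfinite(sigma_surface):
        raise ValueError("sigma must be finite")
    box = np.asarray(box, dtype=float)
    if gap >= box[2]:
        raise ValueError("gap must be smaller than the box height")
    n = max(1, int(round(np.sqrt(n_points_per_sheet))))
    q_point = sigma_surface * box[0] * box[1] / n ** 2
    xs = (np.arange(n) + 0.5) * box[0] / n
    ys = (np.arange(n) + 0.5) * box[1] / n
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    zc = box[2] / 2
    atoms, pos = [], []
    aid = 0
    for zoff, sign in ((-gap / 2, +1), (+gap / 2, -1)):
        for x, y in zip(gx.ravel(), gy.ravel()):
            atoms.append(_lipid_atom(aid, aid + 1, "ION", "none",
                                     charge=sign * q_point, name="Q",
                                     atomic_number=11, mass=22.99))
            pos.append([x, y, zc + zoff])
            aid += 1
    coords = np.asarray(pos, dtype=float)[None, :, :]
    topo = Topology(pd.DataFrame(atoms))
    drop_V = sigma_surface * gap * POTENTIAL_E_PER_NM_TO_VOLT
    truth = GroundTruth("charge_slabs", {
        "sigma_surface": sigma_surface, "gap": gap,
        "drop_volts": drop_V, "z_center": zc,
        "n_points_per_sheet": n ** 2,
    })
    return (Trajectory(np.array([0.0]), box[None, :], coords), topo, truth)


_TETRA = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                   [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])


def make_shape_fixture(kind: str, n_points: int = 4, box_edge: float = 50.0,
                       n_frames: int = 1):
    """Rigid point clouds with known relative shape anisotropy.

    line -> kappa^2 = 1; square (planar, two equal eigenvalues) -> 0.25;
    regular tetrahedron -> 0; helix -> no analytic value (recorded as None).
    """
    if kind == "line":
        if n_points < 2:
            raise ValueError("a line needs at least 2 points")
        pts = np.zeros((n_points, 3))
        pts[:, 0] = np.arange(n_points, dtype=float)
        expected = 1.0
    elif kind == "square":
        if n_points < 4 or n_points % 4:
            raise ValueError("a square needs a positive multiple of 4 points")
        vert = np.array([[1.0, 1.0, 0.0], [1.0, -1.0, 0.0],
                         [-1.0, 1.0, 0.0], [-1.0, -1.0, 0.0]])
        pts = np.tile(vert, (n_points // 4, 1))
        expected = 0.25
    elif kind == "tetrahedron":
        if n_points < 4 or n_points % 4:
            raise ValueError("a tetrahedron needs a positive multiple of 4 points")
        pts = np.tile(_TETRA, (n_points // 4, 1))
        expected = 0.0
    elif kind == "helix":
        if n_points < 4:
            raise ValueError("a helix needs at least 4 points")
        t = np.linspace(0, 4 * np.pi, n_points)
        pts = np.column_stack([np.cos(t), np.sin(t), 0.3 * t])
        expected = None
    else:
        raise ValueError(f"unknown shape kind {kind!r}")
    box = np.full(3, box_edge)
    pts = pts + box / 2
    atoms = [_lipid_atom(i, 1, "PEPTIDE", "none", name=f"CA",
                         atomic_number=6, mass=12.011,
                         residue_name="GLY", residue_index=i + 1)
             for i in range(len(pts))]
    coords = np.tile(pts, (n_frames, 1, 1))
    topo = Topology(pd.DataFrame(atoms))
    truth = GroundTruth("shape_fixture", {
        "shape": kind, "expected_kappa2": expected, "n_points": len(pts),
    })
    return (Trajectory(np.arange(n_frames, dtype=float),
                       np.tile(box, (n_frames, 1)), coords), topo, truth)


def make_dimer_fixture(q1: float, q2: float, sigma: float, epsilon: float,
                       r: float, box_edge: float = 50.0,
                       residue=("R", 19), species2: str = "MAIPG",
                       n_frames: int = 1):
    """Two atoms separated by ``r`` along x in a large box (no periodic
    image within any sensible cutoff): closed-form Coulomb/LJ anchor."""
    if r <= 0:
        raise ValueError("separation must be > 0")
    box = np.full(3, box_edge)
    c = box / 2
    pos = np.array([c - [r / 2, 0, 0], c + [r / 2, 0, 0]])
    atoms = [
        dict(atom_id=0, name="NZ", atomic_number=7, residue_name=residue[0],
             residue_index=residue[1], molecule_id=1, species="PEPTIDE",
             charge=float(q1), lj_sigma=sigma, lj_epsilon=epsilon,
             mass=14.007, leaflet="none"),
        dict(atom_id=1, name="P", atomic_number=15, residue_name=species2,
             residue_index=1, molecule_id=2, species=species2,
             charge=float(q2), lj_sigma=sigma, lj_epsilon=epsilon,
             mass=30.97, leaflet="upper"),
    ]
    from .constants import COULOMB_CONSTANT
    lj = 0.0 if epsilon == 0 else 4 * epsilon * ((sigma / r) ** 12
                                                 - (sigma / r) ** 6)
    truth = GroundTruth("dimer", {
        "q1": q1, "q2": q2, "sigma_LJ": sigma, "eps_LJ": epsilon, "r": r,
        "expected_coulomb": COULOMB_CONSTANT * q1 * q2 / r,
        "expected_lj": lj,
    })
    coords = np.tile(pos, (n_frames, 1, 1))
    return (Trajectory(np.arange(n_frames, dtype=float),
                       np.tile(box, (n_frames, 1)), coords),
            Topology(pd.DataFrame(atoms)), truth)


def make_hbond_fixture(d_DA: float, angle_HDA: float, box_edge: float = 10.0,
                       d_max: float = 0.35, angle_max: float = 30.0,
                       n_frames: int = 1):
    """One donor-hydrogen-acceptor triplet with exact requested geometry.

    The donor nitrogen (peptide residue G_1) points its hydrogen at
    ``angle_HDA`` degrees off the donor->acceptor axis; the acceptor is a
    phosphate oxygen of a MAIPG lipid ``d_DA`` nm away.
    """
    box = np.full(3, box_edge)
    c = box / 2
    a = np.radians(angle_HDA)
    d_pos = c
    acc_pos = c + [0.0, 0.0, d_DA]
    h_pos = c + 0.1 * np.array([np.sin(a), 0.0, np.cos(a)])
    atoms = [
        dict(atom_id=0, name="N", atomic_number=7, residue_name="G",
             residue_index=1, molecule_id=1, species="PEPTIDE", charge=-0.3,
             lj_sigma=0.33, lj_epsilon=0.7, mass=14.007, leaflet="none"),
        dict(atom_id=1, name="HN", atomic_number=1, residue_name="G",
             residue_index=1, molecule_id=1, species="PEPTIDE", charge=0.3,
             lj_sigma=0.1, lj_epsilon=0.05, mass=1.008, leaflet="none",
             bonded_to=0),
        dict(atom_id=2, name="OP1", atomic_number=8, residue_name="MAIPG",
             residue_index=2, molecule_id=2, species="MAIPG", charge=-0.8,
             lj_sigma=0.3, lj_epsilon=0.6, mass=15.999, leaflet="upper"),
    ]
    coords = np.tile(np.array([d_pos, h_pos, acc_pos]), (n_frames, 1, 1))
    truth = GroundTruth("hbond_fixture", {
        "d_DA": d_DA, "angle_HDA": angle_HDA,
        "expected_detected": bool(d_DA <= d_max and angle_HDA <= angle_max),
    })
    return (Trajectory(np.arange(n_frames, dtype=float),
                       np.tile(box, (n_frames, 1)), coords),
            Topology(pd.DataFrame(atoms)), truth)


def membrane_composition_fixture() -> Topology:
    """Two symmetric leaflets of single-site lipids with the packaged
    Gram-positive composition and formal charges (100 lipids per leaflet)."""
    atoms = []
    aid = 0
    for leaflet in ("upper", "lower"):
        for sp in sorted(TABLE_COMPOSITION):
            _, charge, per_leaflet = TABLE_COMPOSITION[sp]
            for _ in range(per_leaflet):
                atoms.append(_lipid_atom(aid, aid + 1, sp, leaflet,
                                         charge=charge))
                aid += 1
    return Topology(pd.DataFrame(atoms))
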