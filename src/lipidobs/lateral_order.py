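"""Leaflet assignment, lipid clustering (NC/NNC), RDF/NRDF and CH order.

Clustering follows single-linkage semantics: two lipids of a species join
a cluster iff any interatomic distance is within the threshold (minimum
image); clusters are connected components of that contact graph.  NNC is
the time-averaged cluster count divided by the number of lipids of the
species in the analysed leaflet.

The CH order parameter per acyl carbon is

    S_CD = | < (3 cos^2 theta - 1) / 2 > |

with theta the angle between a C-H bond and the bilayer normal (+z),
averaged over bonded hydrogens, molecules and frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core_io import LIPID_SPECIES, Topology, Trajectory, block_average

DEFAULT_CLUSTER_THRESHOLD = 0.35  # nm, single-linkage contact distance


def assign_leaflets(frame0: np.ndarray, topo: Topology,
                    head_atom: str = "P") -> Topology:
    """Label each lipid upper/lower from the first frame.

    A lipid is 'upper' iff its headgroup reference atom (named
    ``head_atom``, else the lipid's first atom) sits above the centre of
    mass of all lipid atoms.  The assignment is frozen thereafter.
    """
    a = topo.atoms
    lip = a["species"].isin(LIPID_SPECIES).to_numpy()
    if not lip.any():
        raise ValueError("no lipids present")
    m = a["mass"].to_numpy(float)[lip]
    z_com = float(np.average(np.asarray(frame0)[lip, 2], weights=m))
    leaflet = list(a["leaflet"] if "leaflet" in a.columns
                   else ["none"] * len(a))
    for mol, grp in a[lip].groupby("molecule_id"):
        heads = grp.index[grp["name"] == head_atom]
        ref = heads[0] if len(heads) else grp.index[0]
        if ref is None:
            raise ValueError(f"molecule {mol} has no headgroup reference atom")
        side = "upper" if frame0[ref, 2] > z_com else "lower"
        for i in grp.index:
            leaflet[i] = side
    return topo.with_leaflets(leaflet)


def _species_molecules(topo: Topology, species: str, leaflet: str):
    a = topo.atoms
    if species not in set(a["species"]):
        raise ValueError(f"species {species!r} not present in topology")
    mask = (a["species"] == species).to_numpy()
    if leaflet != "any":
        mask &= (a["leaflet"] == leaflet).to_numpy()
    mols = []
    for _, grp in a[mask].groupby("molecule_id"):
        mols.append(grp.index.to_numpy())
    return mols


def cluster_lipids(coords: np.ndarray, box, topo: Topology, species: str,
                   threshold: float = DEFAULT_CLUSTER_THRESHOLD,
                   leaflet: str = "upper") -> list:
    """Connected components of the any-atom contact graph for one frame.

    Returns a list of clusters, each a sorted list of molecule_ids.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mols = _species_molecules(topo, species, leaflet)
    if not mols:
        return []
    box = np.asarray(box, dtype=float)
    atom_idx = np.concatenate(mols)
    owner = np.concatenate([np.full(len(m), k) for k, m in enumerate(mols)])
    pts = np.asarray(coords)[atom_idx] % box
    tree = cKDTree(pts, boxsize=box)
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    if len(pairs):
        ii = owner[pairs[:, 0]]
        jj = owner[pairs[:, 1]]
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
    else:
        ii = jj = np.empty(0, dtype=int)
    n = len(mols)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    mol_ids = [int(topo.atoms["molecule_id"].iloc[m[0]]) for m in mols]
    clusters = [[] for _ in range(n_comp)]
    for k, lab in enumerate(labels):
        clusters[lab].append(mol_ids[k])
    return [sorted(c) for c in clusters]


@dataclass
class ClusterReport:
    """Time-averaged cluster count NC and its normalized form NNC."""

    species: str
    NC: float
    NC_err: float
    NNC: float
    n_species: int
    threshold: float

    def __post_init__(self):
        if self.n_species >= 1 and not (
                1.0 / self.n_species - 1e-12 <= self.NNC <= 1.0 + 1e-12):
            raise ValueError("NNC out of [1/N, 1] bounds")


def nnc_report(traj: Trajectory, topo: Topology, species: str,
               threshold: float = DEFAULT_CLUSTER_THRESHOLD,
               leaflet: str = "upper", n_blocks: int = 5,
               whole_membrane_denominator: bool = False) -> ClusterReport:
    """NC (time-averaged cluster count) and NNC = NC / N_species.

    The denominator is the species count in the analysed leaflet by
    default; ``whole_membrane_denominator`` switches to both leaflets.
    """
    if traj.n_frames == 0:
        raise ValueError("empty analysis window")
    mols = _species_molecules(topo, species,
                              "any" if whole_membrane_denominator else leaflet)
    n_species = len(mols)
    if n_species < 1:
        raise ValueError(f"no {species} lipids in leaflet {leaflet!r}")
    nc_t = np.array([
        len(cluster_lipids(traj.coords[f], traj.boxes[f], topo, species,
                           threshold, leaflet))
        for f in range(traj.n_frames)], dtype=float)
    if traj.n_frames >= n_blocks:
        est = block_average(nc_t, n_blocks)
        nc, err = est.mean, est.error
    else:
        nc, err = float(nc_t.mean()), 0.0
    return ClusterReport(species, nc, err, nc / n_species, n_species,
                         threshold)


@dataclass
class RDFCurve:
    """g(r) with optional per-molecule normalized variant (NRDF)."""

    r: np.ndarray
    g: np.ndarray
    n_reference: int
    normalized: np.ndarray | None = None

    def __post_init__(self):
        if (np.asarray(self.g) < 0).any():
            raise ValueError("g(r) must be >= 0")


def rdf(traj: Trajectory, topo: Topology, sel_ref: np.ndarray,
        sel_target: np.ndarray, r_max: float = 2.0, bin: float = 0.02,
        mode: str = "3d", n_normalize: int | None = None) -> RDFCurve:
    """Radial distribution function between two atom-index selections.

    Normalization is against the ideal-gas expectation for the chosen
    geometry: spherical shells ('3d') or annuli x slab ('lateral2d', using
    x,y distances only).  Self-pairs are excluded.  ``n_normalize`` (e.g.
    the molecule count of the target species) adds the NRDF = g/n curve.
    """
    sel_ref = np.asarray(sel_ref, dtype=int)
    sel_target = np.asarray(sel_target, dtype=int)
    if len(sel_ref) == 0 or len(sel_target) == 0:
        raise ValueError("selections must be non-empty")
    if r_max > traj.boxes.min() / 2:
        raise ValueError("r_max exceeds half the smallest box edge")
    n_bins = int(np.floor(r_max / bin))
    edges = np.arange(n_bins + 1) * bin
    hist = np.zeros(n_bins)
    ideal_acc = np.zeros(n_bins)
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        ref = traj.coords[f][sel_ref]
        tgt = traj.coords[f][sel_target]
        d = ref[:, None, :] - tgt[None, :, :]
        d -= box * np.floor(d / box + 0.5)
        if mode == "lateral2d":
            r = np.sqrt((d[..., :2] ** 2).sum(-1))
        elif mode == "3d":
            r = np.sqrt((d ** 2).sum(-1))
        else:
            raise ValueError(f"unknown rdf mode {mode!r}")
        same = sel_ref[:, None] == sel_target[None, :]
        r = r[~same]
        h, _ = np.histogram(r, bins=edges)
        if mode == "3d":
            vol = box.prod()
            shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        else:
            vol = box[0] * box[1]
            shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        # ideal count per shell: n_ref * target density * shell volume,
        # excluding one self-partner when the selections overlap
        dens = (len(sel_target) - (1 if same.any() else 0)) / vol
        hist += h
        ideal_acc += len(sel_ref) * dens * shell
    g = np.divide(hist, ideal_acc, out=np.zeros_like(hist),
                  where=ideal_acc > 0)
    centers = (edges[:-1] + edges[1:]) / 2
    nrdf = g / n_normalize if n_normalize else None
    return RDFCurve(centers, g, len(sel_ref), nrdf)


@dataclass
class OrderProfile:
    """Per-carbon CH order parameters for one acyl chain."""

    chain: str                 # 'SN1' or 'SN2'
    carbon_index: np.ndarray   # 1-based, contiguous
    S_CD: np.ndarray
    errors: np.ndarray

    def __post_init__(self):
        if (np.abs(self.S_CD) > 1 + 1e-12).any():
            raise ValueError("|S_CD| must be <= 1")
        ci = np.asarray(self.carbon_index)
        if len(ci) and not np.array_equal(ci, np.arange(ci[0], ci[0] + len(ci))):
            raise ValueError("carbon indices must be contiguous")


def order_parameters(traj: Trajectory, topo: Topology, species: str,
                     chain: str = "SN1", n_blocks: int = 5) -> OrderProfile:
    """S_CD per carbon of one chain of one species.

    The per-frame mean of (3 cos^2 theta - 1)/2 over hydrogens and
    molecules is block-averaged over frames; the modulus is applied to the
    grand mean.
    """
    cmap = topo.chain_map.get(species)
    if not cmap or chain not in cmap:
        raise ValueError(f"chain_map lacks {chain} for species {species!r}")
    carbons = cmap[chain]["carbons"]
    hmap = cmap[chain]["hydrogens"]
    a = topo.atoms
    sp_mask = (a["species"] == species).to_numpy()
    # (molecule, name) -> row index
    lut = {}
    for i in np.nonzero(sp_mask)[0]:
        lut[(a["molecule_id"].iloc[i], a["name"].iloc[i])] = i
    mols = sorted(set(a["molecule_id"][sp_mask]))

    s_means, s_errs = [], []
    for cname in carbons:
        hs = hmap.get(cname, [])
        if not hs:
            raise ValueError(f"carbon {cname} has no bonded hydrogens")
        per_frame = np.empty(traj.n_frames)
        pairs = [(lut[(m, cname)], [lut[(m, h)] for h in hs])
                 for m in mols if (m, cname) in lut]
        if not pairs:
            raise ValueError(f"carbon {cname} not found in any molecule")
        for f in range(traj.n_frames):
            xyz = traj.coords[f]
            p2 = []
            for ci, his in pairs:
                for hi in his:
                    v = xyz[hi] - xyz[ci]
                    cos = v[2] / np.linalg.norm(v)
                    p2.append((3 * cos * cos - 1) / 2)
            per_frame[f] = np.mean(p2)
        if traj.n_frames >= n_blocks:
            est = block_average(per_frame, n_blocks)
            s_means.append(est.mean)
            s_errs.append(est.error)
        else:
            s_means.append(per_frame.mean())
            s_errs.append(0.0)
    return OrderProfile(chain, np.arange(1, len(carbons) + 1),
                        np.abs(np.asarray(s_means)), np.asarray(s_errs))


def order_change_summary(profile_a: OrderProfile,
                         profile_b: OrderProfile) -> float:
    """Sum over carbons of |S_CD,a - S_CD,b| (total absolute order change)."""
    if not np.array_equal(profile_a.carbon_index, profile_b.carbon_index):
        raise ValueError("carbon indices do not match")
    return float(np.abs(profile_a.S_CD - profile_b.S_CD).sum())
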