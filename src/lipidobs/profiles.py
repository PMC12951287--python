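"""z-binned density profiles, electrostatic potential, thickness, 2D maps.

Profiles are histograms along the bilayer normal (z), by default in a
membrane-centred frame (z measured from the per-frame centre of mass of all
lipid atoms).  The electrostatic potential follows from the 1D Poisson
equation by double cumulative integration of the charge density,

    psi(z) = -(1/eps0) * int_z0^z dz' int_z0^z' rho(z'') dz'' ,

with psi(z0) = 0 at a chosen reference (conventionally the centre of the
water slab).  Bilayer thickness is the distance between the two leaflet
phosphate peaks, each refined by 3-point parabolic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import POTENTIAL_E_PER_NM_TO_VOLT
from .core_io import LIPID_SPECIES, Topology, Trajectory, select

WEIGHT_KINDS = ("number", "charge", "electron", "mass")


@dataclass
class Profile:
    """Uniform z-binned density profile (per-bin values are densities)."""

    bin_centers: np.ndarray   # nm
    values: np.ndarray        # count/nm^3, e/nm^3, electrons/nm^3 or amu/nm^3
    weight_kind: str
    selection: str = ""

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        widths = np.diff(self.bin_centers)
        if len(widths) and not np.allclose(widths, widths[0]):
            raise ValueError("bins must be uniform")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


def _z_reference(traj: Trajectory, topo: Topology, center: str, f: int):
    if center == "membrane":
        lip = topo.atoms["species"].isin(LIPID_SPECIES).to_numpy()
        if lip.any():
            m = topo.atoms["mass"].to_numpy(float)[lip]
            return float(np.average(traj.coords[f][lip, 2], weights=m))
        center = "box"
    if center == "box":
        return traj.boxes[f][2] / 2.0
    if center == "none":
        return 0.0
    raise ValueError(f"unknown centering {center!r}")


def density_profile(traj: Trajectory, topo: Topology, selection: str,
                    weight_kind: str = "number", bin_width: float = 0.05,
                    center: str = "membrane",
                    subtract_partial_charge: bool = False) -> Profile:
    """Time-averaged z-density of the selected atoms.

    Weights: 1 (number), partial charge (charge), atomic number (electron;
    optionally minus the partial charge), or mass.  Values are divided by
    the per-frame bin volume Lx*Ly*bin_width.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if weight_kind not in WEIGHT_KINDS:
        raise ValueError(f"unknown weight_kind {weight_kind!r}")
    idx = select(topo, selection)
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    a = topo.atoms
    if weight_kind == "number":
        w = np.ones(len(idx))
    elif weight_kind == "charge":
        w = a["charge"].to_numpy(float)[idx]
    elif weight_kind == "mass":
        w = a["mass"].to_numpy(float)[idx]
    else:
        w = a["atomic_number"].to_numpy(float)[idx]
        if subtract_partial_charge:
            w = w - a["charge"].to_numpy(float)[idx]

    half = traj.boxes[:, 2].max() / 2.0
    n_bins = int(np.ceil(2 * half / bin_width))
    edges = -half + np.arange(n_bins + 1) * bin_width
    acc = np.zeros(n_bins)
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        if box[0] * box[1] == 0:
            raise ValueError("zero-area box cross-section")
        z0 = _z_reference(traj, topo, center, f)
        z = traj.coords[f][idx, 2] - z0
        z = z - box[2] * np.floor(z / box[2] + 0.5)   # wrap about the centre
        hist, _ = np.histogram(z, bins=edges, weights=w)
        acc += hist / (box[0] * box[1] * bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return Profile(centers, acc / traj.n_frames, weight_kind, selection)


@dataclass
class PotentialProfile:
    """Electrostatic potential psi(z) in volts, zero at z0_ref."""

    bin_centers: np.ndarray
    psi: np.ndarray
    z0_ref: float


def potential_profile(charge_profile: Profile, z0: float) -> PotentialProfile:
    """Double-integrate a charge-density profile into psi(z) (volts).

    ``z0`` (nm, on the profile axis) is the zero-potential reference.
    """
    if charge_profile.weight_kind != "charge":
        raise ValueError("potential needs a charge-weighted profile")
    z = charge_profile.bin_centers
    if not (z[0] <= z0 <= z[-1]):
        raise ValueError(f"z0={z0} nm outside profile range "
                         f"[{z[0]:.3f}, {z[-1]:.3f}]")
    rho = charge_profile.values                      # e/nm^3
    i1 = cumulative_trapezoid(rho, z, initial=0.0)   # e/nm^2
    i2 = cumulative_trapezoid(i1, z, initial=0.0)    # e/nm
    i1_0 = np.interp(z0, z, i1)
    i2_0 = np.interp(z0, z, i2)
    double_int = i2 - i2_0 - i1_0 * (z - z0)         # int_z0^z int_z0^z' rho
    psi = -POTENTIAL_E_PER_NM_TO_VOLT * double_int
    return PotentialProfile(z.copy(), psi, z0)


def bilayer_thickness(profile: Profile,
                      phosphate_profile: Profile | None = None) -> float:
    """P-P distance: separation of the two leaflet peaks of the phosphate
    density, each refined by 3-point parabolic interpolation.

    Peaks are read from ``phosphate_profile`` when given, else from
    ``profile`` itself (which must then show one dominant peak per side of
    the membrane centre).
    """
    p = phosphate_profile if phosphate_profile is not None else profile
    z, v = p.bin_centers, p.values
    lower = z < 0
    upper = ~lower
    # each side must carry a real peak, not just the other leaflet's tail
    vmax = v.max()
    if vmax <= 0 or v[lower].max(initial=0.0) < 0.05 * vmax \
            or v[upper].max(initial=0.0) < 0.05 * vmax:
        raise ValueError("fewer than two separated leaflet peaks")
    peaks = []
    for mask in (lower, upper):
        sub = np.nonzero(mask)[0]
        k = sub[np.argmax(v[sub])]
        peaks.append(_parabolic_peak(z, v, k))
    if abs(peaks[1] - peaks[0]) < 2 * p.bin_width:
        raise ValueError("leaflet peaks are not separated")
    return float(peaks[1] - peaks[0])


def _parabolic_peak(z, v, k):
    if k == 0 or k == len(v) - 1:
        return float(z[k])
    y0, y1, y2 = v[k - 1], v[k], v[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(z[k])
    delta = 0.5 * (y0 - y2) / denom
    return float(z[k] + delta * (z[1] - z[0]))


@dataclass
class Map2D:
    """Time-averaged 2D density map over a coordinate plane."""

    plane: str                # 'xy', 'xz' or 'yz'
    x_edges: np.ndarray       # nm
    y_edges: np.ndarray
    density: np.ndarray       # count/nm^3

    def __post_init__(self):
        if (np.asarray(self.density) < 0).any():
            raise ValueError("density cells must be non-negative")


_PLANE_AXES = {"xy": (0, 1, 2), "xz": (0, 2, 1), "yz": (1, 2, 0)}


def density_map_2d(traj: Trajectory, topo: Topology, selection: str,
                   plane: str = "xy", bins: int = 32) -> Map2D:
    """Time-averaged per-cell density of selected atoms over a plane.

    Counts per cell are divided by cell area x box depth along the
    remaining axis.
    """
    if plane not in _PLANE_AXES:
        raise ValueError(f"unknown plane {plane!r}")
    if bins < 2:
        raise ValueError("need at least 2 bins per axis")
    idx = select(topo, selection)
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    ax, ay, az = _PLANE_AXES[plane]
    bx = traj.boxes[:, ax].max()
    by = traj.boxes[:, ay].max()
    x_edges = np.linspace(0, bx, bins + 1)
    y_edges = np.linspace(0, by, bins + 1)
    acc = np.zeros((bins, bins))
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        c = traj.coords[f][idx] % box
        h, _, _ = np.histogram2d(c[:, ax], c[:, ay],
                                 bins=[x_edges, y_edges])
        cell_vol = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0]) \
            * box[az]
        acc += h / cell_vol
    return Map2D(plane, x_edges, y_edges, acc / traj.n_frames)
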