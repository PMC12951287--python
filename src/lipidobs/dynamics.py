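"""Mean-square displacement and Einstein-relation lateral diffusion.

MSD uses every frame as a time origin (FFT-accelerated), averaged over the
molecules of a species in one leaflet.  Coordinates are unwrapped across
periodic images frame-to-frame, and the centre-of-mass drift of the
analysed molecule set is removed before displacements are taken.  The
lateral diffusion coefficient follows from the Einstein relation
MSD(tau) = 2 * dims * D * tau fitted on an interior lag window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import NM2_PER_PS_TO_CM2_PER_S
from .core_io import Topology, Trajectory


@dataclass
class MSDCurve:
    """Multiple-origin MSD over lag time for one species/leaflet."""

    lags: np.ndarray       # ps
    msd: np.ndarray        # nm^2
    species: str
    n_molecules: int

    def __post_init__(self):
        if len(self.lags) and self.msd[0] != 0.0:
            raise ValueError("msd(0) must be 0")
        if len(self.lags) > 1 and not np.all(np.diff(self.lags) > 0):
            raise ValueError("lags must be strictly increasing")


def _reference_positions(traj: Trajectory, topo: Topology, species: str,
                         leaflet: str, head_atom: str = "P") -> np.ndarray:
    """(frames, molecules, 3) positions of each molecule's reference atom."""
    a = topo.atoms
    mask = (a["species"] == species).to_numpy()
    if leaflet != "any":
        mask &= (a["leaflet"] == leaflet).to_numpy()
    if not mask.any():
        raise ValueError(f"no {species} molecules in leaflet {leaflet!r}")
    refs = []
    for _, grp in a[mask].groupby("molecule_id"):
        heads = grp.index[grp["name"] == head_atom]
        refs.append(int(heads[0] if len(heads) else grp.index[0]))
    return traj.coords[:, refs, :]


def unwrap(positions: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping, assuming no jump exceeds half a box edge."""
    pos = np.asarray(positions, dtype=float)
    out = pos.copy()
    steps = np.diff(pos, axis=0)
    box = boxes[1:, None, :]
    wrapped_steps = steps - box * np.floor(steps / box + 0.5)
    # steps near half a box edge are ambiguous under the minimum image:
    # the true jump may have exceeded L/2, which cannot be undone
    if np.any(np.abs(wrapped_steps) > 0.45 * box):
        raise ValueError("unwrapping unreliable: a per-frame jump approaches "
                         "half the box edge; sample frames more finely")
    out[1:] = pos[0] + np.cumsum(wrapped_steps, axis=0)
    return out


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """Multiple-origin MSD of one scalar series via FFT autocorrelation."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[:n].real
    sq = x * x
    ssum = 2.0 * sq.sum()
    s1 = np.empty(n)
    left = 0.0
    right = 0.0
    for m in range(n):
        if m > 0:
            left += sq[m - 1]
            right += sq[n - m]
        s1[m] = ssum - left - right
    counts = n - np.arange(n)
    return s1 / counts - 2.0 * acf / counts


def msd(traj: Trajectory, topo: Topology, species: str,
        leaflet: str = "upper", lateral: bool = True,
        max_lag_fraction: float = 0.8, head_atom: str = "P",
        remove_drift: bool = True) -> MSDCurve:
    """Species-averaged multiple-origin MSD over lag time.

    Uses the per-molecule reference atom (``head_atom`` or the first atom),
    unwrapped coordinates and leaflet-set centre-of-mass drift removal;
    x,y components only when ``lateral``.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    pos = _reference_positions(traj, topo, species, leaflet, head_atom)
    pos = unwrap(pos, traj.boxes)
    if remove_drift and pos.shape[1] > 1:
        com = pos.mean(axis=1, keepdims=True)
        pos = pos - (com - com[0])       # remove collective drift
    dims = 2 if lateral else 3
    n = traj.n_frames
    max_lag = max(1, int(np.floor(max_lag_fraction * (n - 1))))
    acc = np.zeros(n)
    n_mol = pos.shape[1]
    for m in range(n_mol):
        for d in range(dims):
            acc += _msd_fft_1d(np.ascontiguousarray(pos[:, m, d]))
    acc /= n_mol
    lags = (traj.times - traj.times[0])[: max_lag + 1]
    curve = acc[: max_lag + 1]
    curve[0] = 0.0
    return MSDCurve(lags, curve, species, n_mol)


@dataclass
class DiffusionEstimate:
    """Lateral diffusion coefficient from an MSD linear fit."""

    D_L: float            # cm^2/s
    stderr: float         # cm^2/s
    fit_window: tuple     # (lag_lo, lag_hi) ps
    dims: int = 2
    r_squared: float = float("nan")


def diffusion_coefficient(curve: MSDCurve, fit_lo_frac: float = 0.1,
                          fit_hi_frac: float = 0.8,
                          dims: int = 2) -> DiffusionEstimate:
    """Einstein-relation D from the MSD slope: D = slope / (2*dims).

    The fit window is given as fractions of the maximum lag; the default
    10-80% band avoids short-time noise and poorly sampled long lags.
    """
    lags, m = np.asarray(curve.lags, float), np.asarray(curve.msd, float)
    lo = fit_lo_frac * lags[-1]
    hi = fit_hi_frac * lags[-1]
    sel = (lags >= lo) & (lags <= hi)
    if sel.sum() < 3:
        raise ValueError("fit window contains fewer than 3 lag points")
    x, y = lags[sel], m[sel]
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, _, _ = np.linalg.lstsq(A, y, rcond=None)
    slope = coef[0]
    dof = len(x) - 2
    if dof > 0 and len(res):
        sigma2 = res[0] / dof
        sxx = ((x - x.mean()) ** 2).sum()
        slope_err = np.sqrt(sigma2 / sxx)
    else:
        slope_err = 0.0
    yhat = A @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ((y - yhat) ** 2).sum() / ss_tot if ss_tot > 0 else 1.0
    conv = NM2_PER_PS_TO_CM2_PER_S / (2.0 * dims)
    return DiffusionEstimate(float(slope * conv), float(slope_err * conv),
                             (float(lo), float(hi)), dims, float(r2))
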