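"""Trajectory/topology containers, file IO, selections and shared statistics.

Units follow GROMACS conventions throughout: lengths in nm, times in ps,
charges in elementary charge units e, masses in amu, energies in kJ/mol.
Boxes are orthorhombic; triclinic inputs are rejected.

The topology lives in a JSON sidecar rather than an engine-specific
force-field file; the schema is documented in the README.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LIPID_SPECIES = (
    "AIPE", "AIPG", "DPPE", "DPPG", "MAIPE", "MAIPG", "PAIPE", "PAIPG", "PAICL",
)
SPECIES = LIPID_SPECIES + ("PEPTIDE", "WATER", "ION")
LEAFLETS = ("upper", "lower", "none")

TOPOLOGY_SCHEMA_VERSION = 1

_ATOM_REQUIRED = (
    "atom_id", "name", "atomic_number", "residue_name", "residue_index",
    "molecule_id", "species", "charge", "lj_sigma", "lj_epsilon", "mass",
)
_ATOM_OPTIONAL = ("leaflet", "bonded_to")


class TopologyError(ValueError):
    """Raised for schema or invariant violations in a topology."""


class TrajectoryError(ValueError):
    """Raised for malformed trajectory files or frames."""


class SelectionError(ValueError):
    """Raised for selection-grammar violations."""


@dataclass
class Topology:
    """Per-atom metadata table plus acyl-chain maps.

    ``atoms`` is a DataFrame with one row per atom and the columns listed in
    the JSON schema.  ``chain_map`` maps a lipid species to, per chain
    ("SN1"/"SN2"), an ordered list of carbon atom names and a dict of carbon
    name -> bonded hydrogen names.
    """

    atoms: pd.DataFrame
    chain_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = self.atoms
        if len(a) == 0:
            raise TopologyError("topology has an empty atom list")
        missing = [c for c in _ATOM_REQUIRED if c not in a.columns]
        if missing:
            raise TopologyError(f"atom table missing required field(s): {missing}")
        if "leaflet" not in a.columns:
            a = a.assign(leaflet="none")
        ids = np.asarray(a["atom_id"])
        if len(np.unique(ids)) != len(ids):
            raise TopologyError("atom_ids are not unique")
        if not np.array_equal(np.sort(ids), np.arange(ids.min(), ids.min() + len(ids))):
            raise TopologyError("atom_ids are not contiguous")
        bad = set(a["species"]) - set(SPECIES)
        if bad:
            raise TopologyError(f"unknown species label(s): {sorted(bad)}")
        bad = set(a["leaflet"]) - set(LEAFLETS)
        if bad:
            raise TopologyError(f"unknown leaflet label(s): {sorted(bad)}")
        if (np.asarray(a["lj_sigma"], float) < 0).any():
            raise TopologyError("lj_sigma must be >= 0")
        if (np.asarray(a["lj_epsilon"], float) < 0).any():
            raise TopologyError("lj_epsilon must be >= 0")
        if (np.asarray(a["mass"], float) <= 0).any():
            raise TopologyError("mass must be > 0")
        self.atoms = a.reset_index(drop=True)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def species_molecule_counts(self) -> dict:
        """Number of molecules per species (distinct molecule_ids)."""
        g = self.atoms.groupby("species")["molecule_id"].nunique()
        return g.to_dict()

    def with_leaflets(self, leaflet: Sequence[str]) -> "Topology":
        atoms = self.atoms.copy()
        atoms["leaflet"] = list(leaflet)
        return Topology(atoms, dict(self.chain_map))

    def to_dict(self) -> dict:
        recs = self.atoms.to_dict(orient="records")
        return {"version": TOPOLOGY_SCHEMA_VERSION, "atoms": recs,
                "chain_map": self.chain_map}


def read_topology(path) -> Topology:
    """Read a topology from its JSON sidecar, validating the schema."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if "atoms" not in doc:
        raise TopologyError("topology JSON missing required field: atoms")
    atoms = doc["atoms"]
    if not atoms:
        raise TopologyError("topology has an empty atom list")
    for i, rec in enumerate(atoms):
        missing = [k for k in _ATOM_REQUIRED if k not in rec]
        if missing:
            raise TopologyError(
                f"atom record {i} missing required field(s): {missing}")
        extra = set(rec) - set(_ATOM_REQUIRED) - set(_ATOM_OPTIONAL)
        if extra:
            raise TopologyError(
                f"atom record {i} has unknown field(s): {sorted(extra)}")
    df = pd.DataFrame(atoms)
    return Topology(df, doc.get("chain_map", {}))


def write_topology(topo: Topology, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))
    with open(path, "w") as fh:
        json.dump(topo.to_dict(), fh, default=_default)


@dataclass
class Trajectory:
    """Frames x atoms coordinates (nm) with per-frame orthorhombic boxes."""

    times: np.ndarray      # (n_frames,) ps, strictly increasing
    boxes: np.ndarray      # (n_frames, 3) nm
    coords: np.ndarray     # (n_frames, n_atoms, 3) nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (frames, atoms, 3)")
        n = len(self.times)
        if self.boxes.shape != (n, 3) or self.coords.shape[0] != n:
            raise TrajectoryError("times/boxes/coords frame counts differ")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("times must be strictly increasing")
        if not np.all(self.boxes > 0):
            raise TrajectoryError("all box lengths must be > 0")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


_GRO_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


def read_trajectory(path, topology: Topology, time_unit: str = "ps") -> Trajectory:
    """Read a multi-frame GRO or multi-MODEL PDB trajectory.

    Frame times are taken from ``t=`` headers (GRO) when present, else
    0, 1, 2, ... ps.  ``time_unit='ns'`` rescales header times to ps.
    """
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        times, boxes, coords = _read_pdb(path, topology.n_atoms)
    else:
        times, boxes, coords = _read_gro(path, topology.n_atoms)
    if times is None:
        times = np.arange(len(coords), dtype=float)
    else:
        times = np.asarray(times, dtype=float)
        if time_unit == "ns":
            times = times * 1000.0
    return Trajectory(times, np.asarray(boxes), np.asarray(coords))


def _read_gro(path, n_atoms_expected):
    frames, boxes, times = [], [], []
    have_times = True
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        m = _GRO_TIME_RE.search(title)
        if m:
            times.append(float(m.group(1)))
        else:
            have_times = False
        try:
            n_atoms = int(lines[i + 1])
        except (ValueError, IndexError):
            raise TrajectoryError(
                f"unparseable atom count at line {i + 2}") from None
        if n_atoms != n_atoms_expected:
            raise TrajectoryError(
                f"frame {frame_idx}: atom count {n_atoms} does not match "
                f"topology ({n_atoms_expected})")
        start = i + 2
        if start + n_atoms >= len(lines):
            raise TrajectoryError(f"frame {frame_idx}: file truncated")
        xyz = np.empty((n_atoms, 3))
        for j in range(n_atoms):
            ln = lines[start + j]
            try:
                xyz[j] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
            except (ValueError, IndexError):
                raise TrajectoryError(
                    f"unparseable coordinate at line {start + j + 1}") from None
        box_line = lines[start + n_atoms].split()
        try:
            vals = [float(v) for v in box_line]
        except ValueError:
            raise TrajectoryError(
                f"unparseable box at line {start + n_atoms + 1}") from None
        if len(vals) > 3 and any(abs(v) > 1e-9 for v in vals[3:]):
            raise TrajectoryError(
                f"frame {frame_idx}: triclinic box not supported")
        frames.append(xyz)
        boxes.append(vals[:3])
        i = start + n_atoms + 1
        frame_idx += 1
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    return (times if have_times and len(times) == len(frames) else None,
            boxes, frames)


def _read_pdb(path, n_atoms_expected):
    frames, boxes = [], []
    box = None
    cur: list = []
    frame_idx = 0
    in_model = False
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            rec = ln[:6]
            if rec == "CRYST1":
                try:
                    box = (float(ln[6:15]) / 10, float(ln[15:24]) / 10,
                           float(ln[24:33]) / 10)
                    angles = (float(ln[33:40]), float(ln[40:47]), float(ln[47:54]))
                except ValueError:
                    raise TrajectoryError(
                        f"unparseable CRYST1 at line {lineno}") from None
                if any(abs(a - 90.0) > 1e-6 for a in angles):
                    raise TrajectoryError("triclinic box not supported")
            elif rec == "MODEL ":
                in_model = True
                cur = []
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    cur.append((float(ln[30:38]) / 10, float(ln[38:46]) / 10,
                                float(ln[46:54]) / 10))
                except ValueError:
                    raise TrajectoryError(
                        f"unparseable coordinate at line {lineno}") from None
            elif rec == "ENDMDL":
                in_model = False
                if len(cur) != n_atoms_expected:
                    raise TrajectoryError(
                        f"frame {frame_idx}: atom count {len(cur)} does not "
                        f"match topology ({n_atoms_expected})")
                frames.append(np.asarray(cur))
                frame_idx += 1
                cur = []
    if cur and not in_model:  # single frame without MODEL records
        pass
    if not frames and cur:
        if len(cur) != n_atoms_expected:
            raise TrajectoryError(
                f"frame 0: atom count {len(cur)} does not match topology "
                f"({n_atoms_expected})")
        frames.append(np.asarray(cur))
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    if box is None:
        raise TrajectoryError(f"{path}: missing CRYST1 box record")
    boxes = [box] * len(frames)
    return None, boxes, frames


def write_trajectory(traj: Trajectory, topology: Topology, path) -> None:
    """Write a trajectory as multi-frame GRO or multi-MODEL PDB by suffix."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        _write_pdb(traj, topology, path)
    else:
        _write_gro(traj, topology, path)


def _write_gro(traj, topo, path):
    a = topo.atoms
    resid = np.asarray(a["residue_index"]) % 100000
    resnm = list(a["residue_name"])
    name = list(a["name"])
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"frame t= {traj.times[f]:.3f}\n{traj.n_atoms}\n")
            xyz = traj.coords[f]
            for j in range(traj.n_atoms):
                fh.write(f"{resid[j]:>5d}{resnm[j]:<5.5s}{name[j]:>5.5s}"
                         f"{(j + 1) % 100000:>5d}"
                         f"{xyz[j, 0]:8.3f}{xyz[j, 1]:8.3f}{xyz[j, 2]:8.3f}\n")
            bx = traj.boxes[f]
            fh.write(f"{bx[0]:10.5f}{bx[1]:10.5f}{bx[2]:10.5f}\n")


def _write_pdb(traj, topo, path):
    a = topo.atoms
    with open(path, "w") as fh:
        bx = traj.boxes[0] * 10
        fh.write(f"CRYST1{bx[0]:9.3f}{bx[1]:9.3f}{bx[2]:9.3f}"
                 f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            xyz = traj.coords[f] * 10
            for j in range(traj.n_atoms):
                nm = str(a["name"].iloc[j])[:4]
                fh.write(
                    f"ATOM  {(j + 1) % 100000:5d} {nm:<4.4s}"
                    f"{str(a['residue_name'].iloc[j]):<4.4s}A"
                    f"{int(a['residue_index'].iloc[j]) % 10000:4d}    "
                    f"{xyz[j, 0]:8.3f}{xyz[j, 1]:8.3f}{xyz[j, 2]:8.3f}"
                    f"  1.00  0.00\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_FIELDS = {"species", "residue_name", "residue_index", "name", "leaflet"}
_TOKEN_RE = re.compile(r"\s*(\(|\)|==|and\b|or\b|[A-Za-z_][\w\-]*|-?\d+)")


def select(topology: Topology, expression: str) -> np.ndarray:
    """Evaluate a selection expression, returning ascending atom indices.

    Grammar: ``field == VALUE`` terms combined with ``and`` / ``or`` and
    parentheses; ``and`` binds tighter than ``or``.  Fields: species,
    residue_name, residue_index, name, leaflet.
    """
    tokens = []
    pos = 0
    while pos < len(expression):
        if expression[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(expression, pos)
        if not m:
            raise SelectionError(
                f"selection parse error at position {pos}: "
                f"{expression[pos:pos + 10]!r}")
        tokens.append((m.group(1), pos))
        pos = m.end()
    parser = _SelParser(tokens, expression, topology)
    mask = parser.parse_or()
    if parser.i != len(tokens):
        tok, p = tokens[parser.i]
        raise SelectionError(f"unexpected token {tok!r} at position {p}")
    return np.nonzero(mask)[0]


class _SelParser:
    def __init__(self, tokens, text, topo):
        self.tokens = tokens
        self.text = text
        self.topo = topo
        self.i = 0

    def _peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def parse_or(self):
        left = self.parse_and()
        while self._peek() == "or":
            self.i += 1
            left = left | self.parse_and()
        return left

    def parse_and(self):
        left = self.parse_term()
        while self._peek() == "and":
            self.i += 1
            left = left & self.parse_term()
        return left

    def parse_term(self):
        if self._peek() == "(":
            self.i += 1
            inner = self.parse_or()
            if self._peek() != ")":
                raise SelectionError("missing closing parenthesis")
            self.i += 1
            return inner
        if self.i >= len(self.tokens):
            raise SelectionError("incomplete comparison at end of expression")
        field, fpos = self.tokens[self.i]
        op, opos = self.tokens[self.i + 1] if self.i + 1 < len(self.tokens) else (None, len(self.text))
        if field not in _FIELDS:
            raise SelectionError(
                f"unknown field {field!r} at position {fpos}")
        if op != "==":
            raise SelectionError(f"expected '==' at position {opos}")
        if self.i + 2 >= len(self.tokens):
            raise SelectionError("missing value after '=='")
        value, vpos = self.tokens[self.i + 2]
        self.i += 3
        col = self.topo.atoms[field]
        if field == "residue_index":
            try:
                return np.asarray(col) == int(value)
            except ValueError:
                raise SelectionError(
                    f"residue_index needs an integer, got {value!r} "
                    f"at position {vpos}") from None
        if field == "species" and value not in SPECIES:
            raise SelectionError(
                f"unknown species {value!r} at position {vpos}")
        if field == "leaflet" and value not in LEAFLETS:
            raise SelectionError(
                f"unknown leaflet {value!r} at position {vpos}")
        return np.asarray(col.astype(str)) == value


# ---------------------------------------------------------------------------
# periodic geometry, windows, statistics
# ---------------------------------------------------------------------------

def minimum_image_displacement(r1, r2, box) -> np.ndarray:
    """Minimum-image displacement r2 - r1, componentwise in [-L/2, L/2)."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be > 0")
    d = np.asarray(r2, dtype=float) - np.asarray(r1, dtype=float)
    return d - box * np.floor(d / box + 0.5)


def slice_time(traj: Trajectory, t_start: float, t_end: float) -> Trajectory:
    """Frames with t_start <= t <= t_end (ps), order preserved."""
    if not t_start < t_end:
        raise ValueError("t_start must be < t_end")
    mask = (traj.times >= t_start) & (traj.times <= t_end)
    if not mask.any():
        raise ValueError(
            f"time window [{t_start}, {t_end}] ps selects no frames")
    return Trajectory(traj.times[mask], traj.boxes[mask], traj.coords[mask])


@dataclass
class BlockEstimate:
    """Mean with a block-averaging standard error."""

    mean: float
    error: float
    n_blocks: int

    def __post_init__(self):
        if self.error < 0:
            raise ValueError("error must be >= 0")
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")


def block_average(series: Iterable[float], n_blocks: int = 5) -> BlockEstimate:
    """Block-averaged mean and standard error of a correlated series.

    The series is split into ``n_blocks`` contiguous blocks (trailing
    remainder frames go to the last block); the error is the standard error
    of the block means.
    """
    x = np.asarray(list(series) if not isinstance(series, np.ndarray) else series,
                   dtype=float)
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    n = len(x)
    if n < n_blocks:
        raise ValueError(f"series of length {n} is shorter than "
                         f"n_blocks={n_blocks}")
    size = n // n_blocks
    means = np.empty(n_blocks)
    for b in range(n_blocks):
        lo = b * size
        hi = (b + 1) * size if b < n_blocks - 1 else n
        means[b] = x[lo:hi].mean()
    err = means.std(ddof=1) / np.sqrt(n_blocks)
    return BlockEstimate(float(x.mean()), float(err), n_blocks)


def block_average_matrix(series: np.ndarray, n_blocks: int = 5):
    """Blockwise mean/error along axis 0 of a (frames, ...) array."""
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if n < n_blocks:
        raise ValueError(f"series of length {n} is shorter than "
                         f"n_blocks={n_blocks}")
    size = n // n_blocks
    means = []
    for b in range(n_blocks):
        lo = b * size
        hi = (b + 1) * size if b < n_blocks - 1 else n
        means.append(series[lo:hi].mean(axis=0))
    means = np.stack(means)
    err = means.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return series.mean(axis=0), err
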