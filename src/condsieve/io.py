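"""Trajectory formats, configuration files and synthetic fixtures.

Two plain-text trajectory dialects are supported: extended XYZ (with a
``Lattice=...`` comment line) and the LAMMPS-dump column format
(orthogonal boxes only).  Both round-trip positions, types and the box to
1e-6 nm.  Fixture generators produce small, statistically documented bead
configurations for estimator tests.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import yaml

from .simulator import TYPE_C, TYPE_D, TYPE_LABELS, SystemState, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "generate_fixture",
    "make_trajectory",
    "load_config",
    "config_hash",
    "UnsupportedFormatError",
]

DEFAULT_TYPE_RADII = np.array([0.3, 0.3, 1.0, 1.5])


class UnsupportedFormatError(ValueError):
    """Raised for malformed or unsupported (e.g. triclinic) trajectory files."""


def make_trajectory(
    frames: list[np.ndarray],
    box,
    types: np.ndarray,
    type_radii: np.ndarray = DEFAULT_TYPE_RADII,
    mol: np.ndarray | None = None,
    steps: list[int] | None = None,
    temperature: float = 300.0,
) -> Trajectory:
    """Assemble a :class:`Trajectory` from raw arrays."""
    types = np.asarray(types, np.int32)
    if mol is None:
        mol = np.arange(types.size, dtype=np.int32)
    return Trajectory(
        frames=[np.asarray(f, float) for f in frames],
        steps=steps if steps is not None else list(range(len(frames))),
        box=np.asarray(box, float),
        types=types,
        mol=np.asarray(mol, np.int32),
        type_radii=np.asarray(type_radii, float),
        temperature=temperature,
    )


# ---------------------------------------------------------------- extended XYZ

def _write_xyz(traj: Trajectory, fh, provenance: str | None) -> None:
    labels = np.array(TYPE_LABELS)[traj.types]
    L = traj.box
    radii = " ".join(f"{r:.6f}" for r in traj.type_radii)
    for frame, step in zip(traj.frames, traj.steps):
        fh.write(f"{frame.shape[0]}\n")
        comment = (
            f'Lattice="{L[0]:.6f} 0.0 0.0 0.0 {L[1]:.6f} 0.0 0.0 0.0 {L[2]:.6f}" '
            f'Properties=species:S:1:pos:R:3:mol:I:1 Time={step} '
            f'type_radii="{radii}"'
        )
        if provenance:
            comment += f' config_hash="{provenance}"'
        fh.write(comment + "\n")
        for lbl, (x, y, z), m in zip(labels, frame, traj.mol):
            fh.write(f"{lbl} {x:.6f} {y:.6f} {z:.6f} {m}\n")


def _parse_lattice(comment: str) -> np.ndarray:
    key = 'Lattice="'
    i = comment.find(key)
    if i < 0:
        raise UnsupportedFormatError("extended XYZ comment lacks Lattice")
    vals = [float(v) for v in comment[i + len(key):].split('"')[0].split()]
    if len(vals) != 9:
        raise UnsupportedFormatError("Lattice must have 9 components")
    m = np.array(vals).reshape(3, 3)
    if np.any(m - np.diag(np.diag(m)) != 0.0):
        raise UnsupportedFormatError("non-orthogonal lattice is not supported")
    return np.diag(m).copy()


def _read_xyz(fh) -> Trajectory:
    frames, steps = [], []
    types = mol = None
    box = None
    radii = DEFAULT_TYPE_RADII
    temperature = 300.0
    while True:
        line = fh.readline()
        if not line:
            break
        if not line.strip():
            continue
        try:
            n = int(line.strip())
        except ValueError as exc:
            raise UnsupportedFormatError(f"bad atom-count line: {line!r}") from exc
        comment = fh.readline()
        box = _parse_lattice(comment)
        if 'type_radii="' in comment:
            seg = comment.split('type_radii="')[1].split('"')[0]
            radii = np.array([float(v) for v in seg.split()])
        step = 0
        if "Time=" in comment:
            step = int(float(comment.split("Time=")[1].split()[0]))
        pos = np.empty((n, 3))
        t = np.empty(n, np.int32)
        m = np.zeros(n, np.int32)
        for i in range(n):
            parts = fh.readline().split()
            if len(parts) < 4:
                raise UnsupportedFormatError("truncated atom line")
            t[i] = TYPE_LABELS.index(parts[0])
            pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            if len(parts) >= 5:
                m[i] = int(parts[4])
        if types is not None and not np.array_equal(types, t):
            raise UnsupportedFormatError("inconsistent atom types across frames")
        types, mol = t, m
        frames.append(pos)
        steps.append(step)
    if not frames:
        raise UnsupportedFormatError("no frames found")
    return make_trajectory(frames, box, types, radii, mol, steps, temperature)


# ---------------------------------------------------------------- LAMMPS dump

def _write_dump(traj: Trajectory, fh) -> None:
    L = traj.box
    for frame, step in zip(traj.frames, traj.steps):
        fh.write("ITEM: TIMESTEP\n")
        fh.write(f"{step}\n")
        fh.write("ITEM: NUMBER OF ATOMS\n")
        fh.write(f"{frame.shape[0]}\n")
        fh.write("ITEM: BOX BOUNDS pp pp pp\n")
        for d in range(3):
            fh.write(f"{-L[d] / 2:.6f} {L[d] / 2:.6f}\n")
        fh.write("ITEM: ATOMS id type x y z mol\n")
        for i, ((x, y, z), t, m) in enumerate(zip(frame, traj.types, traj.mol)):
            fh.write(f"{i + 1} {t + 1} {x:.6f} {y:.6f} {z:.6f} {m}\n")


def _read_dump(fh, type_radii: np.ndarray) -> Trajectory:
    frames, steps = [], []
    types = mol = None
    box = None
    while True:
        line = fh.readline()
        if not line:
            break
        if not line.startswith("ITEM: TIMESTEP"):
            if not line.strip():
                continue
            raise UnsupportedFormatError(f"unexpected line: {line!r}")
        step = int(fh.readline())
        item = fh.readline()
        if not item.startswith("ITEM: NUMBER OF ATOMS"):
            raise UnsupportedFormatError("missing NUMBER OF ATOMS")
        n = int(fh.readline())
        bounds_hdr = fh.readline()
        if not bounds_hdr.startswith("ITEM: BOX BOUNDS"):
            raise UnsupportedFormatError("missing BOX BOUNDS")
        if any(t in bounds_hdr for t in ("xy", "xz", "yz")):
            raise UnsupportedFormatError("triclinic boxes are not supported")
        box = np.empty(3)
        for d in range(3):
            parts = fh.readline().split()
            if len(parts) != 2:
                raise UnsupportedFormatError("triclinic boxes are not supported")
            box[d] = float(parts[1]) - float(parts[0])
        atoms_hdr = fh.readline()
        if not atoms_hdr.startswith("ITEM: ATOMS"):
            raise UnsupportedFormatError("missing ATOMS header")
        cols = atoms_hdr.split()[2:]
        idx = {c: k for k, c in enumerate(cols)}
        for key in ("id", "type", "x", "y", "z"):
            if key not in idx:
                raise UnsupportedFormatError(f"dump lacks column {key}")
        pos = np.empty((n, 3))
        t = np.empty(n, np.int32)
        m = np.zeros(n, np.int32)
        for _ in range(n):
            parts = fh.readline().split()
            if len(parts) != len(cols):
                raise UnsupportedFormatError("inconsistent atom line width")
            i = int(parts[idx["id"]]) - 1
            t[i] = int(parts[idx["type"]]) - 1
            pos[i] = [float(parts[idx["x"]]), float(parts[idx["y"]]),
                      float(parts[idx["z"]])]
            if "mol" in idx:
                m[i] = int(parts[idx["mol"]])
        if types is not None and not np.array_equal(types, t):
            raise UnsupportedFormatError("inconsistent atom types across frames")
        types, mol = t, m
        frames.append(pos)
        steps.append(step)
    if not frames:
        raise UnsupportedFormatError("no frames found")
    return make_trajectory(frames, box, types, type_radii, mol, steps)


def write_trajectory(
    traj: Trajectory, path, dialect: str | None = None, provenance: str | None = None
) -> None:
    """Write frames as extended XYZ (.xyz) or LAMMPS dump (.dump/.lammpstrj)."""
    path = Path(path)
    dialect = dialect or ("dump" if path.suffix in (".dump", ".lammpstrj") else "xyz")
    with open(path, "w") as fh:
        if dialect == "xyz":
            _write_xyz(traj, fh, provenance)
        elif dialect == "dump":
            _write_dump(traj, fh)
        else:
            raise UnsupportedFormatError(f"unknown dialect {dialect!r}")


def read_trajectory(
    path, dialect: str | None = None, type_radii: np.ndarray = DEFAULT_TYPE_RADII
) -> Trajectory:
    """Read a trajectory; ``type_radii`` supplies bead radii for dump files.

    The XYZ dialect carries its own ``type_radii`` annotation when written
    by this package; the dump dialect cannot, so pass the radii of the
    system that produced it when they differ from the compact-spacer
    defaults.
    """
    path = Path(path)
    dialect = dialect or ("dump" if path.suffix in (".dump", ".lammpstrj") else "xyz")
    with open(path) as fh:
        if dialect == "xyz":
            return _read_xyz(fh)
        if dialect == "dump":
            return _read_dump(fh, np.asarray(type_radii, float))
        raise UnsupportedFormatError(f"unknown dialect {dialect!r}")


# ------------------------------------------------------------------- fixtures

def generate_fixture(kind: str, params: dict | None = None, seed: int = 0) -> Trajectory:
    """Deterministic synthetic configurations for estimator tests.

    Kinds: ``empty`` (no beads), ``single_sphere`` (one spacer at the box
    center), ``hard_sphere_gas`` (rejection-placed non-overlapping spheres
    at a target volume fraction), ``ideal_slab`` (ideal-gas beads confined
    to |x| < halfwidth), ``mini_polymer_box`` (self-avoiding random-walk
    chains relaxed by short capped-force descent).  All are single-frame
    trajectories, deterministic for a given seed.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    box = np.asarray(params.pop("box", (20.0, 20.0, 20.0)), float)
    radius = float(params.pop("radius", 1.0))

    def radii_with_c(rc):
        r = DEFAULT_TYPE_RADII.copy()
        r[TYPE_C] = rc
        return r

    if kind == "empty":
        pos = np.empty((0, 3))
        return make_trajectory([pos], box, np.empty(0, np.int32), radii_with_c(radius))
    if kind == "single_sphere":
        pos = np.zeros((1, 3))
        return make_trajectory([pos], box, np.array([TYPE_C]), radii_with_c(radius))
    if kind == "hard_sphere_gas":
        phi = float(params.pop("phi", 0.05))
        v_sphere = (4 / 3) * math.pi * radius**3
        n = int(round(phi * float(np.prod(box)) / v_sphere))
        if phi > 0.3:
            raise ValueError("rejection placement infeasible above phi ~ 0.3")
        pos = np.empty((n, 3))
        placed = 0
        attempts = 0
        max_attempts = 20000 * max(n, 1)
        while placed < n:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError("rejection placement failed; phi too high")
            cand = rng.uniform(-box / 2, box / 2)
            if placed:
                d = pos[:placed] - cand
                d -= box * np.round(d / box)
                if np.min(np.sum(d * d, axis=1)) < (2 * radius) ** 2:
                    continue
            pos[placed] = cand
            placed += 1
        return make_trajectory(
            [pos], box, np.full(n, TYPE_C, np.int32), radii_with_c(radius)
        )
    if kind == "ideal_slab":
        n = int(params.pop("n", 1000))
        halfwidth = float(params.pop("halfwidth", box[0] / 4))
        pos = rng.uniform(-box / 2, box / 2, size=(n, 3))
        pos[:, 0] = rng.uniform(-halfwidth, halfwidth, size=n)
        return make_trajectory(
            [pos], box, np.full(n, TYPE_C, np.int32), radii_with_c(radius)
        )
    if kind == "mini_polymer_box":
        from .simulator import (SimulationConfig, build_system, forcefield_spacers_only,
                                spacers_only_topology)

        n_chains = int(params.pop("n_chains", 4))
        chain_length = int(params.pop("chain_length", 30))
        ff = forcefield_spacers_only()
        topo = spacers_only_topology(n_chains, chain_length, ff)
        cfg = SimulationConfig(box=tuple(box), wall_x=None, dt=1e-4, tau=0.01)
        state = build_system(topo, cfg, ff, rng)
        return make_trajectory(
            [state.wrapped_positions()], box, topo.types,
            np.array([0.3, 0.3, 0.3, 1.5]), topo.mol,
        )
    raise ValueError(f"unknown fixture kind {kind!r}")


# -------------------------------------------------------------- configuration

def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable hash of a configuration for provenance records."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
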