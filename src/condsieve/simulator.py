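"""Coarse-grained Langevin dynamics of sticker-spacer condensates.

The model: linear bead-spring polymers of volume-excluding spacer beads
(type C) carry small sticker beads (types A and B) bonded to the backbone.
A-B stickers attract through a short-range soft cosine well, driving phase
separation; same-type stickers repel so that A:B binding is one-to-one.
Stickers are virtual patches: they have no volume interaction with spacers
or free particles.  Neutral/client particles (type D) repel spacers through
a WCA potential and, when client attraction is switched on, bind stickers
through a cosine shell well.

Dynamics are underdamped Langevin (BAOAB splitting) with per-type friction
gamma_i = m_i / tau, so each bead's long-time diffusivity is kBT/gamma_i.
Units: nm, ns, ag, energies in kBT at the configured temperature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from dataclasses import replace as replace_config
from typing import NamedTuple, Sequence

import numpy as np

from . import _kernels as K
from .units import T_REF, kbt_mech, pa_per_kbt_nm3

__all__ = [
    "BeadType",
    "ForceField",
    "Topology",
    "SimulationConfig",
    "SystemState",
    "Trajectory",
    "SimulationError",
    "forcefield_compact",
    "forcefield_idr",
    "forcefield_spacers_only",
    "compact_spacer_topology",
    "idr_spacer_topology",
    "spacers_only_topology",
    "particles_only_topology",
    "build_system",
    "potential_energy",
    "langevin_step",
    "Engine",
    "run_protocol",
    "osmotic_pressure",
    "frame_virial",
    "kinetic_temperature",
]

TYPE_LABELS = ("A", "B", "C", "D")
TYPE_A, TYPE_B, TYPE_C, TYPE_D = 0, 1, 2, 3


class SimulationError(RuntimeError):
    """Raised on numerical instability (FENE overextension, blow-up)."""


@dataclass(frozen=True)
class BeadType:
    """A bead species: its label, radius (nm), mass (ag) and patch flag."""

    label: str
    radius: float
    mass: float
    is_virtual_patch: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0.0 or self.mass <= 0.0:
            raise ValueError("bead radius and mass must be positive")


class PairTables(NamedTuple):
    kind_tab: np.ndarray
    p_tab: np.ndarray
    cut2_tab: np.ndarray
    rlist2_tab: np.ndarray
    bulk_rlist: float
    max_rlist: float
    sparse_mask: np.ndarray
    mass: np.ndarray
    radius: np.ndarray


@dataclass(frozen=True)
class ForceField:
    """Interaction parameters keyed by bead-type pair.

    WCA repulsion (strength ``wca_eps``, range sigma_ij = r_i + r_j) acts
    between the pairs AA, BB, CC, DD and CD.  The A-B soft attraction has
    depth ``u0`` and range ``r0``.  Client attraction (A-D and B-D) is a
    cosine shell of depth ``client_eps`` centred at distance ``client_R``
    with half-width ``client_ra``; zero depth disables it.  Bond classes
    ("backbone", "sticker") are (form, p1, p2) with form "fene" (k, rmax)
    or "harmonic" (kb, rb).
    """

    bead_types: tuple[BeadType, BeadType, BeadType, BeadType]
    backbone_bond: tuple[str, float, float]
    sticker_bond: tuple[str, float, float] | None = None
    u0: float = 0.0
    r0: float = 0.3
    wca_eps: float = 1.0
    client_eps: float = 0.0
    client_R: float = 1.5
    client_ra: float = 0.3

    def bead(self, label: str) -> BeadType:
        return self.bead_types[TYPE_LABELS.index(label)]

    def with_u0(self, u0: float) -> "ForceField":
        return replace(self, u0=u0)

    def with_client_eps(self, eps: float) -> "ForceField":
        return replace(self, client_eps=eps)

    def pair_tables(self, skin: float = 0.4) -> PairTables:
        nt = 4
        kind = np.zeros((nt, nt), np.int32)
        p = np.zeros((nt, nt, 3), np.float64)
        cut2 = np.zeros((nt, nt), np.float64)
        radius = np.array([bt.radius for bt in self.bead_types])
        mass = np.array([bt.mass for bt in self.bead_types])

        def set_pair(i, j, k_, params, cutoff):
            kind[i, j] = kind[j, i] = k_
            p[i, j, : len(params)] = params
            p[j, i, : len(params)] = params
            cut2[i, j] = cut2[j, i] = cutoff**2

        for i, j in [(0, 0), (1, 1), (2, 2), (3, 3), (2, 3)]:
            sigma = radius[i] + radius[j]
            set_pair(i, j, K.PAIR_WCA, (self.wca_eps, sigma), 2 ** (1 / 6) * sigma)
        if self.u0 != 0.0:
            set_pair(0, 1, K.PAIR_COS_WELL, (self.u0, self.r0), self.r0)
        if self.client_eps != 0.0:
            prm = (self.client_eps, self.client_R, self.client_ra)
            cutoff = self.client_R + self.client_ra
            set_pair(0, 3, K.PAIR_SHELL_WELL, prm, cutoff)
            set_pair(1, 3, K.PAIR_SHELL_WELL, prm, cutoff)

        sparse = np.zeros(nt, np.bool_)
        sparse[TYPE_D] = True
        cuts = np.sqrt(cut2)
        rlist = np.where(cuts > 0.0, cuts + skin, 0.0)
        rlist2 = rlist**2
        bulk = float(rlist[:3, :3].max())
        if bulk <= 0.0:
            bulk = float(rlist.max()) if rlist.max() > 0 else skin
        return PairTables(
            kind, p, cut2, rlist2, bulk, float(max(rlist.max(), bulk)), sparse, mass, radius
        )

    def bond_params(self, bond_class: str) -> tuple[int, float, float, float, float]:
        """Resolve a bond class to (kind, p1, p2, wca_eps, wca_sigma).

        FENE backbone bonds carry their own WCA core (sigma = spacer
        diameter), as in the standard bead-spring convention; harmonic
        bonds rely on the bond minimum alone and get no core.
        """
        spec = self.backbone_bond if bond_class == "backbone" else self.sticker_bond
        if spec is None:
            raise ValueError(f"force field defines no '{bond_class}' bond")
        form, p1, p2 = spec
        if form == "fene":
            return K.BOND_FENE, p1, p2, self.wca_eps, 2.0 * self.bead("C").radius
        return K.BOND_HARMONIC, p1, p2, 0.0, 0.0


def forcefield_compact(u0: float = 18.8, client_eps: float = 0.0) -> ForceField:
    """Compact-spacer system: 10 spacers of radius 1 nm per polymer."""
    return ForceField(
        bead_types=(
            BeadType("A", 0.3, 5.65, True),
            BeadType("B", 0.3, 5.65, True),
            BeadType("C", 1.0, 18.85),
            BeadType("D", 1.5, 28.27),
        ),
        backbone_bond=("fene", 0.129, 14.03),
        sticker_bond=("harmonic", 100.0, 1.0),
        u0=u0,
        client_eps=client_eps,
    )


def forcefield_idr(u0: float = 18.0, client_eps: float = 0.0) -> ForceField:
    """IDR-spacer system: amino-acid-sized spacers of radius 0.3 nm."""
    return ForceField(
        bead_types=(
            BeadType("A", 0.3, 5.65, True),
            BeadType("B", 0.3, 5.65, True),
            BeadType("C", 0.3, 5.65),
            BeadType("D", 1.5, 28.27),
        ),
        backbone_bond=("harmonic", 692.0, 0.38),
        sticker_bond=("harmonic", 1111.0, 0.3),
        u0=u0,
        client_eps=client_eps,
    )


def forcefield_spacers_only() -> ForceField:
    """Flexible self-avoiding bead-spring chains (no stickers), light beads."""
    return ForceField(
        bead_types=(
            BeadType("A", 0.3, 0.0565, True),
            BeadType("B", 0.3, 0.0565, True),
            BeadType("C", 0.3, 0.0565),
            BeadType("D", 1.5, 28.27),
        ),
        backbone_bond=("harmonic", 692.0, 0.38),
        u0=0.0,
    )


@dataclass(frozen=True)
class Topology:
    """Full-system architecture: bead types, molecule ids and bonds."""

    types: np.ndarray  # (n,) int32 type codes
    mol: np.ndarray  # (n,) int32 molecule indices
    bond_i: np.ndarray  # (nb,) int32
    bond_j: np.ndarray
    bond_kind: np.ndarray  # (nb,) int32
    bond_p: np.ndarray  # (nb, 4) float64: p1, p2, bond-WCA eps, sigma
    sticker_host: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))

    @property
    def n(self) -> int:
        return int(self.types.shape[0])

    @property
    def n_molecules(self) -> int:
        return int(self.mol.max()) + 1 if self.n else 0

    def excluded_pair_keys(self) -> np.ndarray:
        """Sorted i*n+j keys of bonded pairs, excluded from nonbonded forces."""
        if self.bond_i.size == 0:
            return np.empty(0, np.int64)
        lo = np.minimum(self.bond_i, self.bond_j).astype(np.int64)
        hi = np.maximum(self.bond_i, self.bond_j).astype(np.int64)
        return np.sort(lo * self.n + hi)


def _assemble(molecules: Sequence[tuple[list[int], list[tuple[int, int, str]], list[int]]],
              ff: ForceField) -> Topology:
    types, mol, bi, bj, bk, bp, hosts = [], [], [], [], [], [], []
    offset = 0
    for m, (tcodes, bonds, sticker_pairs) in enumerate(molecules):
        types.extend(tcodes)
        mol.extend([m] * len(tcodes))
        for i, j, cls in bonds:
            kind, p1, p2, beps, bsig = ff.bond_params(cls)
            bi.append(offset + i)
            bj.append(offset + j)
            bk.append(kind)
            bp.append((p1, p2, beps, bsig))
        for h in sticker_pairs:
            hosts.append(offset + h)
        offset += len(tcodes)
    return Topology(
        np.asarray(types, np.int32),
        np.asarray(mol, np.int32),
        np.asarray(bi, np.int32),
        np.asarray(bj, np.int32),
        np.asarray(bk, np.int32),
        np.asarray(bp, np.float64).reshape(-1, 4),
        np.asarray(hosts, np.int32),
    )


def compact_spacer_topology(
    n_polymers: int = 50, n_particles: int = 50, ff: ForceField | None = None
) -> Topology:
    """Chains of 10 compact spacers, one sticker per spacer (5 A then 5 B)."""
    ff = ff or forcefield_compact()
    mols = []
    for _ in range(n_polymers):
        tcodes = [TYPE_C] * 10 + [TYPE_A] * 5 + [TYPE_B] * 5
        bonds = [(s, s + 1, "backbone") for s in range(9)]
        bonds += [(10 + s, s, "sticker") for s in range(10)]
        mols.append((tcodes, bonds, [s for s in range(10)]))
    for _ in range(n_particles):
        mols.append(([TYPE_D], [], []))
    return _assemble(mols, ff)


def idr_spacer_topology(
    n_polymers: int = 50,
    n_particles: int = 50,
    n_spacers: int = 450,
    sticker_every: int = 8,
    ff: ForceField | None = None,
) -> Topology:
    """Chains of amino-acid-sized spacers with a sticker on every 8th spacer.

    Stickers sit on spacers ``sticker_every-1, 2*sticker_every-1, ...``; the
    first half carry type A, the second half type B.
    """
    ff = ff or forcefield_idr()
    mols = []
    sticker_sites = list(range(sticker_every - 1, n_spacers, sticker_every))
    for _ in range(n_polymers):
        tcodes = [TYPE_C] * n_spacers
        bonds = [(s, s + 1, "backbone") for s in range(n_spacers - 1)]
        hosts = []
        for s in sticker_sites:
            idx = len(tcodes)
            tcodes.append(TYPE_A if s < n_spacers // 2 else TYPE_B)
            bonds.append((idx, s, "sticker"))
            hosts.append(s)
        mols.append((tcodes, bonds, hosts))
    for _ in range(n_particles):
        mols.append(([TYPE_D], [], []))
    return _assemble(mols, ff)


def spacers_only_topology(
    n_chains: int = 60, chain_length: int = 450, ff: ForceField | None = None
) -> Topology:
    """Flexible self-avoiding bead-spring chains with all stickers removed."""
    ff = ff or forcefield_spacers_only()
    mols = []
    for _ in range(n_chains):
        tcodes = [TYPE_C] * chain_length
        bonds = [(s, s + 1, "backbone") for s in range(chain_length - 1)]
        mols.append((tcodes, bonds, []))
    return _assemble(mols, ff)


def particles_only_topology(n_particles: int) -> Topology:
    """Free D beads only (ideal-gas and diffusion checks)."""
    return _assemble([([TYPE_D], [], []) for _ in range(n_particles)], forcefield_compact())


@dataclass
class SimulationConfig:
    """Box geometry, thermostat and protocol schedule.

    Step counts follow the coexistence protocol: short force-capped
    relaxation happens inside :func:`build_system`; then ``steps_initial``
    with confinement walls and stickers off, a linear U0 ramp over
    ``steps_anneal``, ``steps_equilibrate`` at full U0 with walls,
    ``steps_release`` after wall removal, and ``steps_production`` with a
    frame recorded every ``record_every`` steps (plus the initial frame).
    """

    box: tuple[float, float, float]
    temperature: float = T_REF  # K
    tau: float = 1.0  # ns, damping m/gamma
    dt: float = 0.01  # ns
    seed: int = 0
    wall_x: float | None = 30.0  # nm; None disables confinement
    wall_k: float = 5.0  # kBT/nm^2
    steps_soft: int = 0  # run at dt/10 first, to relax residual overlaps
    steps_initial: int = 0
    steps_anneal: int = 0
    steps_equilibrate: int = 0
    steps_release: int = 0
    steps_production: int = 0
    record_every: int = 5000
    skin: float = 0.4  # nm, neighbor-list margin (displacement-triggered rebuild)
    chunk_steps: int = 250

    def __post_init__(self) -> None:
        if self.dt <= 0.0 or any(L <= 0.0 for L in self.box):
            raise ValueError("dt and box edges must be positive")
        if self.record_every <= 0:
            raise ValueError("record_every must be positive")


@dataclass
class SystemState:
    """Positions (unwrapped), velocities, types, molecules, box, step count."""

    pos: np.ndarray
    vel: np.ndarray
    types: np.ndarray
    mol: np.ndarray
    box: np.ndarray
    step: int = 0

    @property
    def n(self) -> int:
        return int(self.pos.shape[0])

    def wrapped_positions(self) -> np.ndarray:
        """Positions wrapped to [-L/2, L/2) per axis."""
        L = self.box
        return self.pos - L * np.round(self.pos / L)

    def copy(self) -> "SystemState":
        return SystemState(
            self.pos.copy(), self.vel.copy(), self.types.copy(),
            self.mol.copy(), self.box.copy(), self.step,
        )


@dataclass
class Trajectory:
    """Recorded frames plus the metadata needed for analysis."""

    frames: list[np.ndarray]
    steps: list[int]
    box: np.ndarray
    types: np.ndarray
    mol: np.ndarray
    type_radii: np.ndarray  # per type code, nm
    temperature: float = T_REF

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _pair_buffer(n: int, n_sparse: int) -> np.ndarray:
    cap = 96 * max(n, 1) + 512 * max(n_sparse, 1) + 4096
    return np.empty((cap, 2), np.int32)


def build_system(
    topology: Topology,
    config: SimulationConfig,
    ff: ForceField,
    rng: np.random.Generator | int | None = None,
) -> SystemState:
    """Place molecules, relax overlaps under capped forces, draw velocities.

    Polymers are grown as random walks at the backbone bond length, started
    inside the confinement region when walls are active; free particles are
    placed uniformly in the box.  A short force-capped steepest descent
    (stickers off) removes catastrophic overlaps before dynamics.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    box = np.asarray(config.box, np.float64)
    n = topology.n
    if n == 0:
        return SystemState(
            np.empty((0, 3)), np.empty((0, 3)), topology.types.copy(),
            topology.mol.copy(), box,
        )
    tables = ff.pair_tables(config.skin)
    vol_beads = float(np.sum((4 / 3) * math.pi * tables.radius[topology.types] ** 3
                             * ~np.array([ff.bead_types[t].is_virtual_patch
                                          for t in topology.types])))
    if vol_beads > 0.55 * float(np.prod(box)):
        raise ValueError("requested composition exceeds feasible packing density")

    pos = np.zeros((n, 3))
    xlim = config.wall_x - 1.0 if config.wall_x is not None else box[0] / 2
    # group beads by molecule; polymers are walked along their bond graph
    order = np.argsort(topology.mol, kind="stable")
    mol_ids = topology.mol[order]
    starts = np.searchsorted(mol_ids, np.arange(topology.n_molecules))
    ends = np.append(starts[1:], n)
    bond_by_bead: dict[int, list[tuple[int, float]]] = {}
    for b in range(topology.bond_i.shape[0]):
        i, j = int(topology.bond_i[b]), int(topology.bond_j[b])
        rb = topology.bond_p[b, 1] if topology.bond_kind[b] == K.BOND_HARMONIC \
            else 0.25 * topology.bond_p[b, 1]
        bond_by_bead.setdefault(i, []).append((j, rb))
        bond_by_bead.setdefault(j, []).append((i, rb))

    placed = np.zeros(n, np.bool_)
    for m in range(topology.n_molecules):
        beads = order[starts[m]:ends[m]]
        root = int(beads[0])
        start = np.array([
            rng.uniform(-xlim, xlim),
            rng.uniform(-box[1] / 2, box[1] / 2),
            rng.uniform(-box[2] / 2, box[2] / 2),
        ])
        pos[root] = start
        placed[root] = True
        mol_placed: list[int] = [root]
        stack = [root]
        while stack:
            i = stack.pop()
            for j, rb in bond_by_bead.get(i, []):
                if placed[j]:
                    continue
                # self-avoiding growth: retry directions that overlap beads
                # already placed in this molecule (inter-molecule overlaps
                # are left to the capped-force relaxation)
                sig = 2.0 * tables.radius[topology.types[j]]
                cand = pos[i]
                for _ in range(40):
                    step = rng.normal(size=3)
                    step *= max(rb, 0.3) / np.linalg.norm(step)
                    cand = pos[i] + step
                    if config.wall_x is not None:
                        if cand[0] > xlim:
                            cand[0] = 2 * xlim - cand[0]
                        elif cand[0] < -xlim:
                            cand[0] = -2 * xlim - cand[0]
                    others = [k for k in mol_placed if k != i]
                    if not others:
                        break
                    d = pos[others] - cand
                    if np.min(np.sum(d * d, axis=1)) > (0.85 * sig) ** 2:
                        break
                pos[j] = cand
                placed[j] = True
                mol_placed.append(j)
                stack.append(j)

    # free particles (molecules of a single D bead) roam the whole box
    for m in range(topology.n_molecules):
        beads = order[starts[m]:ends[m]]
        if beads.size == 1 and topology.types[beads[0]] == TYPE_D:
            pos[beads[0]] = rng.uniform(-box / 2, box / 2)

    _relax_overlaps(pos, topology, ff.with_u0(0.0).with_client_eps(0.0), config, rng)

    kbt = kbt_mech(config.temperature)
    sigma_v = np.sqrt(kbt / tables.mass[topology.types])
    vel = rng.normal(size=(n, 3)) * sigma_v[:, None]
    return SystemState(pos, vel, topology.types.copy(), topology.mol.copy(), box)


def _relax_overlaps(pos, topology, ff_repulsive, config, rng, iters: int = 300,
                    max_move: float = 0.05) -> None:
    """Capped-force steepest descent to remove initial overlaps in place."""
    tables = ff_repulsive.pair_tables(config.skin)
    box = np.asarray(config.box, np.float64)
    frc = np.zeros_like(pos)
    pairs = _pair_buffer(topology.n, int(np.sum(topology.types == TYPE_D)))
    excl = topology.excluded_pair_keys()
    for _ in range(iters):
        npairs = K.build_neighbors(
            pos, topology.types, box, tables.sparse_mask, tables.rlist2_tab,
            tables.bulk_rlist, tables.max_rlist, excl, pairs,
        )
        if npairs < 0:
            raise SimulationError("neighbor buffer overflow during relaxation")
        K.compute_forces(
            pos, topology.types, box, pairs, npairs, tables.kind_tab, tables.p_tab,
            tables.cut2_tab, topology.bond_i, topology.bond_j, topology.bond_kind,
            topology.bond_p, frc,
        )
        if config.wall_x is not None:
            wall_mask = topology.types != TYPE_D
            K.add_wall_forces(pos, frc, wall_mask, config.wall_x, config.wall_k)
        norm = np.linalg.norm(frc, axis=1, keepdims=True)
        scale = np.minimum(1.0, max_move / np.maximum(norm * 0.002, 1e-12))
        pos += 0.002 * frc * scale


def potential_energy(
    state: SystemState, ff: ForceField, topology: Topology, skin: float = 0.4
) -> tuple[float, np.ndarray, float]:
    """Total potential energy (kBT), forces (kBT/nm) and virial (kBT)."""
    tables = ff.pair_tables(skin)
    frc = np.zeros_like(state.pos)
    pairs = _pair_buffer(state.n, int(np.sum(state.types == TYPE_D)))
    npairs = K.build_neighbors(
        state.pos, state.types, state.box, tables.sparse_mask, tables.rlist2_tab,
        tables.bulk_rlist, tables.max_rlist, topology.excluded_pair_keys(), pairs,
    )
    if npairs < 0:
        raise SimulationError("neighbor buffer overflow")
    epot, vir, ok = K.compute_forces(
        state.pos, state.types, state.box, pairs, npairs, tables.kind_tab,
        tables.p_tab, tables.cut2_tab, topology.bond_i, topology.bond_j,
        topology.bond_kind, topology.bond_p, frc,
    )
    if not ok:
        raise SimulationError("FENE bond overextension (r >= rmax)")
    return float(epot), frc, float(vir)


def _thermostat_coeffs(config: SimulationConfig, tables: PairTables, thermostat: bool):
    kbt = kbt_mech(config.temperature)
    acc_scale = kbt / tables.mass  # forces are in kBT/nm
    if thermostat:
        c1 = np.exp(-config.dt / config.tau) * np.ones(4)
        c2 = np.sqrt((1.0 - c1**2) * kbt / tables.mass)
    else:
        c1 = np.ones(4)
        c2 = np.zeros(4)
    return acc_scale, c1, c2


_STATUS_MSG = {
    1: "FENE bond overextension (r >= rmax): unstable timestep or bad initial state",
    2: "neighbor-list buffer overflow",
    3: "per-step displacement exceeded a quarter box edge: numerical blow-up",
}


class Engine:
    """Binds a topology, force field and config into a runnable integrator.

    Holds the persistent force/neighbor buffers; ``run`` advances a state in
    place.  The force field may be swapped between runs (annealing ramps)
    without invalidating the state.
    """

    def __init__(self, topology: Topology, ff: ForceField, config: SimulationConfig):
        self.topology = topology
        self.config = config
        self.set_forcefield(ff)
        self.excl = topology.excluded_pair_keys()
        self.pairs = _pair_buffer(topology.n, int(np.sum(topology.types == TYPE_D)))
        self.frc = np.zeros((topology.n, 3))
        self.wall_mask = topology.types != TYPE_D

    def set_forcefield(self, ff: ForceField) -> None:
        self.ff = ff
        self.tables = ff.pair_tables(self.config.skin)

    def run(
        self,
        state: SystemState,
        n_steps: int,
        rng: np.random.Generator,
        walls: bool = False,
        thermostat: bool = True,
        record_every: int | None = None,
        collector: list | None = None,
    ) -> tuple[float, float]:
        """Advance ``n_steps`` in place; return final-step (epot, virial).

        With ``record_every``, appends (step, wrapped positions, epot,
        virial) to ``collector`` at every boundary (not the initial state).
        """
        if state.n == 0 or n_steps == 0:
            return 0.0, 0.0
        cfg = self.config
        t = self.tables
        acc_scale, c1, c2 = _thermostat_coeffs(cfg, t, thermostat)
        wall_x = cfg.wall_x if (walls and cfg.wall_x is not None) else 0.0
        wall_on = walls and cfg.wall_x is not None
        epot = vir = 0.0
        # forces consistent with entry positions
        _, self.frc, _ = _forces_into(self, state)
        done = 0
        while done < n_steps:
            chunk = min(cfg.chunk_steps, n_steps - done)
            if record_every is not None:
                until_rec = record_every - (done % record_every)
                chunk = min(chunk, until_rec)
            if thermostat:
                noise = rng.standard_normal((chunk, state.n, 3))
            else:
                noise = np.zeros((chunk, state.n, 3))
            epot, vir, status = K.baoab_chunk(
                state.pos, state.vel, self.frc, state.types, state.box, cfg.dt,
                acc_scale, c1, c2, noise,
                t.kind_tab, t.p_tab, t.cut2_tab,
                self.topology.bond_i, self.topology.bond_j,
                self.topology.bond_kind, self.topology.bond_p,
                wall_on, self.wall_mask, wall_x, cfg.wall_k,
                t.sparse_mask, t.rlist2_tab, t.bulk_rlist, t.max_rlist, self.excl,
                self.pairs, cfg.skin,
            )
            if status != 0:
                raise SimulationError(
                    f"step ~{state.step + done}: {_STATUS_MSG[status]}"
                )
            done += chunk
            if record_every is not None and done % record_every == 0 \
                    and collector is not None:
                collector.append(
                    (state.step + done, state.wrapped_positions(), epot, vir)
                )
        state.step += n_steps
        return float(epot), float(vir)


def _forces_into(engine: Engine, state: SystemState):
    t = engine.tables
    npairs = K.build_neighbors(
        state.pos, state.types, state.box, t.sparse_mask, t.rlist2_tab,
        t.bulk_rlist, t.max_rlist, engine.excl, engine.pairs,
    )
    if npairs < 0:
        raise SimulationError("neighbor-list buffer overflow")
    epot, vir, ok = K.compute_forces(
        state.pos, state.types, state.box, engine.pairs, npairs, t.kind_tab,
        t.p_tab, t.cut2_tab, engine.topology.bond_i, engine.topology.bond_j,
        engine.topology.bond_kind, engine.topology.bond_p, engine.frc,
    )
    if not ok:
        raise SimulationError("FENE bond overextension (r >= rmax)")
    return epot, engine.frc, vir


def langevin_step(
    state: SystemState,
    ff: ForceField,
    config: SimulationConfig,
    topology: Topology,
    rng: np.random.Generator,
    thermostat: bool = True,
) -> SystemState:
    """Advance one underdamped Langevin step (convenience over :class:`Engine`)."""
    engine = Engine(topology, ff, config)
    engine.run(state, 1, rng, thermostat=thermostat)
    return state


def run_protocol(
    topology: Topology,
    config: SimulationConfig,
    ff: ForceField,
    n_ramp_segments: int = 40,
) -> Trajectory:
    """Full coexistence protocol; deterministic for a given config seed.

    Phases: confined relaxation with stickers off, linear U0 ramp with
    walls, equilibration at full U0 with walls, wall removal and free
    equilibration, then production with frames recorded every
    ``config.record_every`` steps (the state at production start is frame 0).
    """
    rng = np.random.default_rng(config.seed)
    state = build_system(topology, config, ff, rng)
    engine = Engine(topology, ff.with_u0(0.0), config)

    if config.steps_soft:
        soft_cfg = replace_config(config, dt=config.dt / 10.0)
        soft_engine = Engine(topology, ff.with_u0(0.0), soft_cfg)
        soft_engine.run(state, config.steps_soft, rng, walls=True)
    if config.steps_initial:
        engine.run(state, config.steps_initial, rng, walls=True)
    if config.steps_anneal:
        seg = max(1, config.steps_anneal // n_ramp_segments)
        done = 0
        while done < config.steps_anneal:
            ns = min(seg, config.steps_anneal - done)
            frac = (done + 0.5 * ns) / config.steps_anneal
            engine.set_forcefield(ff.with_u0(ff.u0 * frac))
            engine.run(state, ns, rng, walls=True)
            done += ns
    engine.set_forcefield(ff)
    if config.steps_equilibrate:
        engine.run(state, config.steps_equilibrate, rng, walls=True)
    if config.steps_release:
        engine.run(state, config.steps_release, rng, walls=False)

    collector: list = []
    epot, _, vir = _forces_into(engine, state)
    collector.append((state.step, state.wrapped_positions(), epot, vir))
    if config.steps_production:
        engine.run(
            state, config.steps_production, rng, walls=False,
            record_every=config.record_every, collector=collector,
        )
    radii = np.array([bt.radius for bt in ff.bead_types])
    return Trajectory(
        frames=[c[1] for c in collector],
        steps=[c[0] for c in collector],
        box=state.box.copy(),
        types=state.types.copy(),
        mol=state.mol.copy(),
        type_radii=radii,
        temperature=config.temperature,
    )


def frame_virial(
    frame: np.ndarray, traj: Trajectory, ff: ForceField, topology: Topology,
    skin: float = 0.4,
) -> float:
    """Virial sum r_ij . f_ij (kBT) of a single stored frame."""
    state = SystemState(
        frame.astype(np.float64), np.zeros_like(frame), traj.types, traj.mol, traj.box
    )
    _, _, vir = potential_energy(state, ff, topology, skin)
    return vir


def osmotic_pressure(
    traj: Trajectory, ff: ForceField, topology: Topology, n_blocks: int = 5
) -> tuple[float, float]:
    """Time-averaged virial pressure in Pa, with block standard error.

    P = [N kBT + W/3] / V per frame, W the interaction virial including
    bonds; frames are assumed decorrelated at the recording interval.
    Warns when first- and second-half block means disagree beyond 3 sigma
    (non-stationary trajectory).
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    vol = float(np.prod(traj.box))
    n = traj.types.shape[0]
    p_inst = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        w = frame_virial(frame, traj, ff, topology)
        p_inst[f] = (n + w / 3.0) / vol  # kBT/nm^3
    p_pa = p_inst * pa_per_kbt_nm3(traj.temperature)
    blocks = np.array_split(p_pa, min(n_blocks, traj.n_frames))
    means = np.array([b.mean() for b in blocks])
    stderr = means.std(ddof=1) / math.sqrt(len(means)) if len(means) > 1 else 0.0
    if len(means) >= 4:
        half = len(means) // 2
        drift = abs(means[:half].mean() - means[half:].mean())
        if stderr > 0 and drift > 3.0 * stderr * math.sqrt(2.0):
            warnings.warn("osmotic pressure blocks look non-stationary", stacklevel=2)
    return float(p_pa.mean()), float(stderr)


def coexistence_preset(
    kind: str = "compact",
    scale: str = "mini",
    n_particles: int | None = None,
    seed: int = 0,
    client_eps: float = 0.0,
) -> tuple[Topology, ForceField, SimulationConfig]:
    """Ready-to-run coexistence systems.

    ``kind`` is "compact" (10 spacers of radius 1 nm per polymer) or "idr"
    (450 spacers of radius 0.3 nm).  ``scale`` "cluster" reproduces the
    full-scale study conditions (50 polymers, 100 x 25 x 25 nm box, 1e8-step
    schedules — cluster work); "mini" is the desk-scale profile used by the
    test suite: fewer polymers in a proportionally smaller box with
    1e5-step schedule segments, which still phase separates into a single
    dense slab plus dilute phase.
    """
    if kind == "compact":
        ff = forcefield_compact(client_eps=client_eps)
        if scale == "cluster":
            topo = compact_spacer_topology(50, 50 if n_particles is None else n_particles, ff)
            cfg = SimulationConfig(
                box=(100.0, 25.0, 25.0), wall_x=30.0, seed=seed,
                steps_soft=10**5, steps_initial=10**6, steps_anneal=4 * 10**7,
                steps_equilibrate=10**7, steps_release=5 * 10**7,
                steps_production=2 * 10**8, record_every=5 * 10**4,
            )
        else:
            topo = compact_spacer_topology(16, 50 if n_particles is None else n_particles, ff)
            cfg = SimulationConfig(
                box=(70.0, 18.0, 18.0), wall_x=15.0, seed=seed,
                steps_soft=5_000, steps_initial=20_000, steps_anneal=150_000,
                steps_equilibrate=50_000, steps_release=200_000,
                steps_production=600_000, record_every=10_000,
            )
    elif kind == "idr":
        ff = forcefield_idr(client_eps=client_eps)
        if scale == "cluster":
            topo = idr_spacer_topology(50, 50 if n_particles is None else n_particles, ff=ff)
            cfg = SimulationConfig(
                box=(100.0, 25.0, 25.0), wall_x=30.0, seed=seed,
                steps_soft=10**5, steps_initial=10**6, steps_anneal=4 * 10**7,
                steps_equilibrate=10**7, steps_release=5 * 10**7,
                steps_production=4 * 10**8, record_every=8 * 10**4,
            )
        else:
            topo = idr_spacer_topology(
                5, 0 if n_particles is None else n_particles, ff=ff
            )
            cfg = SimulationConfig(
                box=(55.0, 14.0, 14.0), wall_x=11.0, seed=seed,
                steps_soft=15_000, steps_initial=15_000, steps_anneal=100_000,
                steps_equilibrate=30_000, steps_release=50_000,
                steps_production=100_000, record_every=10_000,
            )
    else:
        raise ValueError(f"unknown coexistence kind {kind!r}")
    return topo, ff, cfg


def spacers_only_preset(
    scale: str = "mini",
    box_edge: float | None = None,
    seed: int = 0,
) -> tuple[Topology, ForceField, SimulationConfig]:
    """Homogeneous self-avoiding chain boxes for pressure/insertion studies.

    The cluster-scale profile is 60 chains of 450 monomers (box edges
    31.55-43.76 nm); the mini profile is 10 chains of 60 monomers in a
    proportionally chosen box, with the fast-bead parameters (m = 0.0565 ag,
    tau = 0.01 ns, dt = 1e-4 ns).
    """
    ff = forcefield_spacers_only()
    if scale == "cluster":
        topo = spacers_only_topology(60, 450, ff)
        edge = 31.55 if box_edge is None else box_edge
        cfg = SimulationConfig(
            box=(edge, edge, edge), wall_x=None, seed=seed,
            tau=0.01, dt=1e-4,
            steps_equilibrate=0, steps_release=10**7,
            steps_production=4 * 10**8, record_every=2 * 10**5,
        )
    else:
        topo = spacers_only_topology(10, 60, ff)
        edge = 12.0 if box_edge is None else box_edge
        cfg = SimulationConfig(
            box=(edge, edge, edge), wall_x=None, seed=seed,
            tau=0.01, dt=1e-4, skin=0.3,
            steps_release=40_000, steps_production=60_000,
            record_every=4_000,
        )
    return topo, ff, cfg


def kinetic_temperature(state: SystemState, ff: ForceField) -> float:
    """Instantaneous kinetic temperature in K from equipartition."""
    mass = np.array([bt.mass for bt in ff.bead_types])[state.types]
    ke = 0.5 * float(np.sum(mass[:, None] * state.vel**2))  # ag nm^2/ns^2
    kb_mech = 1.380649e-23 / 1e-21  # per K
    return 2.0 * ke / (3.0 * state.n * kb_mech)
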