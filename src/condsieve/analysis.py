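"""Coexistence-trajectory analysis: profiles, partitioning, KD extraction.

A phase-separated slab in a periodic box is recentered frame by frame to
the polymer center of mass (a circular mean, since the box is periodic),
volume-fraction profiles along x are histogrammed at 1/50 of the box
length, and dense/dilute-phase averages give measured partition
coefficients and, for attractive clients, the dissociation constant KD and
binding-site density entering the recruitment free energy -rho/KD + dF0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .simulator import TYPE_D, TYPE_LABELS, Topology, Trajectory

__all__ = [
    "ProfileTable",
    "PhaseRegions",
    "PartitionMeasurement",
    "KDMeasurement",
    "density_profile",
    "partition_coefficient_measured",
    "measure_KD",
    "largest_cluster_fraction",
    "chain_end_to_end",
    "recenter_trajectory",
]


@dataclass
class ProfileTable:
    """Binned per-species volume-fraction profiles along x."""

    bin_centers: np.ndarray
    phi: dict[str, np.ndarray]  # label -> volume fraction per bin
    n_frames: int
    n_excluded_frames: int
    symmetrized: bool
    box: np.ndarray
    bin_width: float


@dataclass(frozen=True)
class PhaseRegions:
    """Dense slab |x| < dense_halfwidth; dilute wings |x| > dilute_min (nm)."""

    dense_halfwidth: float = 10.0
    dilute_min: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.dense_halfwidth < self.dilute_min:
            raise ValueError("regions must satisfy 0 < dense_halfwidth < dilute_min")

    @classmethod
    def for_box(cls, box_length: float, dense_frac: float = 0.2,
                dilute_frac: float = 0.8) -> "PhaseRegions":
        """Scale the canonical |x|<10 / |x|>40 split of a 100 nm box."""
        return cls(dense_frac * box_length / 2, dilute_frac * box_length / 2)


@dataclass
class PartitionMeasurement:
    """Measured partition coefficient and paired free energy (kBT)."""

    partition: float
    delta_f: float
    phi_dense: float
    phi_dilute: float
    is_bound: bool = False  # True when dilute phase had zero counts


@dataclass
class KDMeasurement:
    """Dense-phase dissociation constant and binding-site density (nm^-3)."""

    kd: float
    rho_sites: float
    rho_clients: float
    n_bound: float
    n_free: float
    is_upper_bound: bool = False  # True when no bound stickers were seen


def _circular_com_x(x: np.ndarray, L: float) -> float:
    theta = 2.0 * math.pi * x / L
    return L / (2.0 * math.pi) * math.atan2(np.sin(theta).mean(), np.cos(theta).mean())


def _wrap(x: np.ndarray, L: float) -> np.ndarray:
    return x - L * np.round(x / L)


def recenter_trajectory(traj: Trajectory) -> Trajectory:
    """Copy of a trajectory with each frame shifted along x so the polymer
    center of mass (circular mean under periodicity) sits at x = 0.

    The dense slab can diffuse along the box after the confinement walls
    come off; slab-relative analyses (dense/dilute regions, Widom insertion
    slabs) should operate on recentered frames.
    """
    import copy

    out = copy.copy(traj)
    poly = traj.types != TYPE_D
    L = float(traj.box[0])
    frames = []
    for frame in traj.frames:
        shift = _circular_com_x(frame[poly, 0], L) if np.any(poly) else 0.0
        f = frame.copy()
        f[:, 0] -= shift
        f -= traj.box * np.round(f / traj.box)
        frames.append(f)
    out.frames = frames
    return out


def largest_cluster_fraction(
    pos: np.ndarray, types: np.ndarray, mol: np.ndarray, box: np.ndarray,
    radii: np.ndarray, cutoff_factor: float = 1.2,
) -> float:
    """Fraction of polymer molecules in the largest contact cluster.

    Two beads are in contact when closer than cutoff_factor*(r_i + r_j);
    molecules sharing a contact are merged.  Free particles are ignored.
    """
    poly = types != TYPE_D
    if not np.any(poly):
        return 1.0
    p = pos[poly]
    t = types[poly]
    m = mol[poly]
    mols = np.unique(m)
    if mols.size == 1:
        return 1.0
    r = radii[t]
    shifted = np.mod(p + box / 2.0, box)
    tree = cKDTree(shifted, boxsize=box)
    rmax = cutoff_factor * 2.0 * r.max()
    pairs = np.array(list(tree.query_pairs(rmax)), dtype=np.int64)
    mol_index = {mm: k for k, mm in enumerate(mols)}
    if pairs.size == 0:
        return 1.0 / mols.size
    d = np.linalg.norm(
        _wrap(p[pairs[:, 0]] - p[pairs[:, 1]], box), axis=1
    )
    ok = d < cutoff_factor * (r[pairs[:, 0]] + r[pairs[:, 1]])
    mi = np.array([mol_index[mm] for mm in m[pairs[ok, 0]]])
    mj = np.array([mol_index[mm] for mm in m[pairs[ok, 1]]])
    graph = coo_matrix(
        (np.ones(mi.size), (mi, mj)), shape=(mols.size, mols.size)
    )
    _, labels = connected_components(graph, directed=False)
    counts = np.bincount(labels)
    return counts.max() / mols.size


def density_profile(
    traj: Trajectory,
    species: tuple[str, ...] = ("C", "D"),
    bins: int = 50,
    recenter: bool = True,
    symmetrize: bool = True,
    min_cluster_fraction: float | None = 0.5,
    cluster_cutoff_factor: float = 1.2,
) -> ProfileTable:
    """Per-species volume-fraction profile along x, averaged over frames.

    Each frame is recentered to the polymer center of mass along x
    (circular mean under periodicity).  Frames whose largest polymer
    cluster holds less than ``min_cluster_fraction`` of the molecules are
    excluded and counted; pass None to skip the check.  Volume fractions
    are bead counts times single-bead volume per bin volume.
    """
    box = np.asarray(traj.box, float)
    L = box[0]
    edges = np.linspace(-L / 2, L / 2, bins + 1)
    bin_vol = (L / bins) * box[1] * box[2]
    codes = {lbl: TYPE_LABELS.index(lbl) for lbl in species}
    sums = {lbl: np.zeros(bins) for lbl in species}
    poly_mask = traj.types != TYPE_D
    used = 0
    excluded = 0
    for frame in traj.frames:
        if min_cluster_fraction is not None:
            frac = largest_cluster_fraction(
                frame, traj.types, traj.mol, box, traj.type_radii,
                cluster_cutoff_factor,
            )
            if frac < min_cluster_fraction:
                excluded += 1
                continue
        shift = _circular_com_x(frame[poly_mask, 0], L) if recenter and \
            np.any(poly_mask) else 0.0
        x = _wrap(frame[:, 0] - shift, L)
        for lbl, code in codes.items():
            sel = traj.types == code
            counts, _ = np.histogram(x[sel], bins=edges)
            sums[lbl] += counts
        used += 1
    if used == 0:
        raise ValueError("no usable frames (all excluded by cluster check)")
    phi = {}
    for lbl in species:
        v_bead = (4.0 / 3.0) * math.pi * traj.type_radii[codes[lbl]] ** 3
        prof = sums[lbl] / used * v_bead / bin_vol
        if symmetrize:
            prof = 0.5 * (prof + prof[::-1])
        phi[lbl] = prof
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ProfileTable(
        bin_centers=centers, phi=phi, n_frames=used, n_excluded_frames=excluded,
        symmetrized=symmetrize, box=box, bin_width=L / bins,
    )


def partition_coefficient_measured(
    profile: ProfileTable, regions: PhaseRegions, species: str = "D"
) -> PartitionMeasurement:
    """P = phi_dense / phi_dilute from region-averaged profile bins.

    The paired free energy is dF = -kBT ln P.  Zero dilute-phase density is
    reported as a bound (partition = inf, ``is_bound`` set) rather than a
    number.
    """
    x = profile.bin_centers
    prof = profile.phi[species]
    dense = np.abs(x) < regions.dense_halfwidth
    dilute = np.abs(x) > regions.dilute_min
    if not dense.any() or not dilute.any():
        raise ValueError("phase regions select no profile bins")
    phi_den = float(prof[dense].mean())
    phi_dil = float(prof[dilute].mean())
    if phi_dil == 0.0:
        return PartitionMeasurement(math.inf, -math.inf, phi_den, phi_dil, True)
    p = phi_den / phi_dil
    return PartitionMeasurement(p, -math.log(p) if p > 0 else math.inf,
                                phi_den, phi_dil, False)


def measure_KD(
    traj: Trajectory,
    regions: PhaseRegions,
    binding_range: float = 1.8,
    client_label: str = "D",
    sticker_labels: tuple[str, ...] = ("A", "B"),
) -> KDMeasurement:
    """Dense-phase dissociation constant KD = rho_client rho_S,free / rho_S,bound.

    A sticker counts as bound when its center lies within ``binding_range``
    (the attraction reach R + ra by default) of any client center.  The
    total client density stands in for the free-client density, since a
    client engaging several stickers at once is never saturated.  Also
    returns the total sticker (binding-site) density rho for the
    recruitment prediction -rho/KD + dF0.
    """
    box = np.asarray(traj.box, float)
    L = box[0]
    client_code = TYPE_LABELS.index(client_label)
    sticker_codes = [TYPE_LABELS.index(s) for s in sticker_labels]
    poly_mask = traj.types != TYPE_D
    v_dense = 2.0 * regions.dense_halfwidth * box[1] * box[2]
    n_clients = 0
    n_bound = 0
    n_free = 0
    for frame in traj.frames:
        shift = _circular_com_x(frame[poly_mask, 0], L)
        x = _wrap(frame[:, 0] - shift, L)
        in_dense = np.abs(x) < regions.dense_halfwidth
        clients = frame[(traj.types == client_code) & in_dense]
        stickers = frame[np.isin(traj.types, sticker_codes) & in_dense]
        n_clients += clients.shape[0]
        if clients.shape[0] == 0 or stickers.shape[0] == 0:
            n_free += stickers.shape[0]
            continue
        ctree = cKDTree(np.mod(clients + box / 2, box), boxsize=box)
        dist, _ = ctree.query(np.mod(stickers + box / 2, box), k=1)
        bound = dist < binding_range
        n_bound += int(bound.sum())
        n_free += int((~bound).sum())
    nf = traj.n_frames
    if n_clients == 0:
        raise ValueError("no clients found in the dense region")
    rho_c = n_clients / (nf * v_dense)
    rho_free = n_free / (nf * v_dense)
    rho_bound = n_bound / (nf * v_dense)
    rho_sites = (n_free + n_bound) / (nf * v_dense)
    if n_bound == 0:
        # KD is only bounded from below: report the bound with a flag
        kd = rho_c * rho_free * nf * v_dense  # one bound sticker would give this
        return KDMeasurement(kd, rho_sites, rho_c, 0.0, n_free / nf, True)
    return KDMeasurement(
        rho_c * rho_free / rho_bound, rho_sites, rho_c,
        n_bound / nf, n_free / nf, False,
    )


def chain_end_to_end(pos: np.ndarray, topology: Topology) -> np.ndarray:
    """End-to-end distances of each polymer backbone (unwrapped positions)."""
    out = []
    from .simulator import TYPE_C

    for m in range(topology.n_molecules):
        sel = np.where((topology.mol == m) & (topology.types == TYPE_C))[0]
        if sel.size >= 2:
            out.append(float(np.linalg.norm(pos[sel[-1]] - pos[sel[0]])))
    return np.asarray(out)
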