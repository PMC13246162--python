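"""Hard-sphere Widom insertion: free-energy cost of ghost-particle insertion.

A spherical test particle of radius R is inserted at many positions in each
stored configuration; the insertion energy is hard-sphere (infinite on
overlap with any volume-excluding bead, zero otherwise), so the Boltzmann
factor is an indicator and

    F(R) = -kBT ln <accepted fraction>.

Sticker beads are virtual patches and never exclude the probe.  For
homogeneous polymer boxes held at pressure Pi, comparison between phases at
equal pressure requires subtracting the pressure-volume work Pi*(4pi/3)R^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import widom_scan_points
from .simulator import TYPE_LABELS, Trajectory
from .units import T_REF, kbt_joules

__all__ = [
    "InsertionJob",
    "InsertionResult",
    "insert_hard_spheres",
    "pv_correction",
    "partition_from_widom",
]


@dataclass(frozen=True)
class InsertionJob:
    """Probe radii, sampling scheme and insertion region.

    Sampling is a deterministic uniform grid (``grid_shape``) by default; a
    seeded random mode (``n_random`` points per frame) is available for
    convergence checks.  ``slab`` restricts probe *centers* to
    xlo <= x <= xhi; excluded-volume interactions still reach outside the
    slab through the minimum-image metric.  ``exclude_types`` lists the
    bead labels that exclude the probe (spacers by default; stickers are
    virtual patches and never excluded against).
    """

    probe_radii: tuple[float, ...]
    grid_shape: tuple[int, int, int] = (140, 140, 140)
    n_random: int | None = None
    slab: tuple[float, float] | None = None
    exclude_types: tuple[str, ...] = ("C",)
    seed: int = 0

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.probe_radii)
        if any(r < 0 for r in radii):
            raise ValueError("probe radii must be non-negative")
        object.__setattr__(self, "probe_radii", radii)
        if self.slab is not None and self.slab[0] >= self.slab[1]:
            raise ValueError("slab bounds must satisfy xlo < xhi")


@dataclass
class InsertionResult:
    """Per-radius insertion free energies and their sampling errors.

    ``free_energy`` is F(R) in kBT (inf where no insertion was accepted, in
    which case ``lower_bound`` holds -ln(1/n_samples), a bound on F).
    ``delta_f`` is filled by :func:`pv_correction`.
    """

    radii: np.ndarray
    free_energy: np.ndarray
    acceptance: np.ndarray
    stderr: np.ndarray
    n_samples: int
    n_frames: int
    lower_bound: np.ndarray | None = None
    is_lower_bound: np.ndarray | None = None
    delta_f: np.ndarray | None = None


def _region_bounds(box: np.ndarray, slab):
    lo = -box / 2.0
    hi = box / 2.0
    if slab is not None:
        if slab[0] < lo[0] or slab[1] > hi[0]:
            raise ValueError("slab extends outside the box")
        lo = lo.copy()
        hi = hi.copy()
        lo[0], hi[0] = slab
    return lo, hi


def _grid_points(lo, hi, shape):
    axes = [lo[d] + (np.arange(shape[d]) + 0.5) * (hi[d] - lo[d]) / shape[d]
            for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def insert_hard_spheres(traj: Trajectory, job: InsertionJob) -> InsertionResult:
    """Widom hard-sphere insertion over all frames of a trajectory.

    Per-frame acceptance fractions are averaged; the standard error is the
    scatter of per-frame acceptances (frames treated as decorrelated),
    propagated to F as sigma_acc / acc.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    radii = np.sort(np.asarray(job.probe_radii, float))
    excl_codes = [TYPE_LABELS.index(lbl) for lbl in job.exclude_types]
    mask = np.isin(traj.types, excl_codes)
    r_excl = traj.type_radii[traj.types[mask]]
    box = np.asarray(traj.box, float)
    lo, hi = _region_bounds(box, job.slab)

    rng = np.random.default_rng(job.seed)
    if job.n_random is None:
        points = _grid_points(lo, hi, job.grid_shape)
    n_pts = job.n_random if job.n_random is not None else points.shape[0]

    acc_frames = np.empty((traj.n_frames, radii.size))
    for f, frame in enumerate(traj.frames):
        if job.n_random is not None:
            points = lo + rng.random((n_pts, 3)) * (hi - lo)
        hist = widom_scan_points(
            np.ascontiguousarray(points), np.ascontiguousarray(frame[mask]),
            r_excl, box, radii,
        )
        # acceptance count of radii[k] is the tail sum beyond bin k
        tail = np.cumsum(hist[::-1])[::-1]
        acc_frames[f] = tail[1:] / n_pts

    acc = acc_frames.mean(axis=0)
    if traj.n_frames > 1:
        stderr_acc = acc_frames.std(axis=0, ddof=1) / math.sqrt(traj.n_frames)
    else:
        stderr_acc = np.sqrt(np.maximum(acc * (1 - acc), 0.0) / n_pts)
    total = n_pts * traj.n_frames
    with np.errstate(divide="ignore"):
        free = -np.log(acc)
    is_bound = acc == 0.0
    lower = np.where(is_bound, math.log(total), free)
    stderr = np.where(acc > 0, stderr_acc / np.maximum(acc, 1e-300), np.nan)
    return InsertionResult(
        radii=radii, free_energy=free, acceptance=acc, stderr=stderr,
        n_samples=n_pts, n_frames=traj.n_frames,
        lower_bound=lower, is_lower_bound=is_bound,
    )


def pv_correction(
    result_or_f: InsertionResult | np.ndarray,
    pressure: float,
    temperature: float = T_REF,
    radii: np.ndarray | None = None,
) -> np.ndarray:
    """Subtract pressure-volume work: dF(R) = F(R) - Pi (4pi/3) R^3 / kBT.

    ``pressure`` in Pa.  Accepts an :class:`InsertionResult` (fills its
    ``delta_f`` and returns it) or a raw F array with explicit ``radii``.
    """
    if isinstance(result_or_f, InsertionResult):
        f = result_or_f.free_energy
        radii = result_or_f.radii
    else:
        f = np.asarray(result_or_f, float)
        if radii is None:
            raise ValueError("raw-array form requires radii")
    work = pressure * (4.0 / 3.0) * math.pi * (np.asarray(radii) * 1e-9) ** 3 \
        / kbt_joules(temperature)
    delta = f - work
    if isinstance(result_or_f, InsertionResult):
        result_or_f.delta_f = delta
    return delta


def partition_from_widom(f_dense: float | np.ndarray, f_dilute: float | np.ndarray):
    """Partition coefficient P = exp(-(F_dense - F_dilute)).

    Inputs that are only lower bounds on F_dense propagate as upper bounds
    on P (inf F gives P = 0, an exact statement of 'below detection').
    """
    return np.exp(-(np.asarray(f_dense, float) - np.asarray(f_dilute, float)))
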