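"""Parameter estimation tying simulation to theory.

Given PV-corrected insertion free energies dF(R) measured in several
polymer systems with known volume fractions phi and correlation lengths
xi, the polymer-entropy contribution y = dF/kBT + ln(1-phi) should collapse
onto the universal curve a1 x^(3-1/nu) + a2 x^2 in the rescaled radius
x = R/xi.  The global fit of (a1, a2) is linear least squares in the two
basis functions; the xi(phi) scaling prefactor c comes from a log-log
regression with theoretical slope -nu/(3nu-1) = -0.7696.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .theory import FLORY_NU, InsertionModel

__all__ = [
    "InsertionDataset",
    "InsertionFit",
    "ScalingFit",
    "fit_insertion_model",
    "collapse_check",
    "fit_scaling_prefactor",
    "default_radius_grid",
]


def default_radius_grid(n: int = 18, lo: float = 0.50, hi: float = 2.48) -> np.ndarray:
    """Probe radii in nm, log-spaced; the conventional 18-point grid."""
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class InsertionDataset:
    """One system's PV-corrected insertion free energies."""

    radii: np.ndarray  # nm
    delta_f: np.ndarray  # kBT
    phi: float
    xi: float  # nm
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, float)
        f = np.asarray(self.delta_f, float)
        if r.shape != f.shape:
            raise ValueError("radii and delta_f must have matching shapes")
        if not np.all(np.isfinite(f)):
            raise ValueError(
                "delta_f contains non-finite entries (drop flagged "
                "lower-bound radii before fitting)"
            )
        if not 0.0 <= self.phi < 1.0:
            raise ValueError("phi must be in [0, 1)")
        if self.xi <= 0.0:
            raise ValueError("xi must be positive")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "delta_f", f)

    def rescaled(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) with x = R/xi and y = dF/kBT + ln(1-phi)."""
        return self.radii / self.xi, self.delta_f + math.log1p(-self.phi)


@dataclass
class InsertionFit:
    model: InsertionModel
    stderr: tuple[float, float]  # on (a1, a2)
    covariance: np.ndarray
    residuals: np.ndarray
    n_points: int


@dataclass
class ScalingFit:
    c: float
    exponent: float
    c_stderr: float
    exponent_stderr: float
    expected_exponent: float


def _design(x: np.ndarray, nu: float) -> np.ndarray:
    return np.column_stack([x ** (3.0 - 1.0 / nu), x**2])


def fit_insertion_model(
    datasets: list[InsertionDataset], nu: float = FLORY_NU
) -> InsertionFit:
    """Global weighted least-squares fit of (a1, a2) across systems.

    nu is held fixed (it is a known exponent, not a fit parameter); pass a
    different value for sensitivity analysis.  Points are weighted by
    1/stderr^2 where per-point errors are available, unweighted otherwise.
    """
    if len(datasets) < 1:
        raise ValueError("at least one dataset required")
    xs, ys, ws = [], [], []
    for ds in datasets:
        x, y = ds.rescaled()
        xs.append(x)
        ys.append(y)
        if ds.stderr is not None:
            ws.append(np.asarray(ds.stderr, float))
        else:
            ws.append(np.ones_like(x))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    sig = np.concatenate(ws)
    if np.unique(np.round(x, 12)).size < 2:
        raise ValueError("fit is rank-deficient: need at least two distinct R/xi")
    A = _design(x, nu) / sig[:, None]
    b = y / sig
    coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 2:
        raise ValueError("fit is rank-deficient: basis functions indistinguishable")
    resid = y - _design(x, nu) @ coef
    dof = max(x.size - 2, 1)
    ata_inv = np.linalg.inv(A.T @ A)
    if np.allclose(sig, 1.0):
        cov = ata_inv * float(resid @ resid) / dof
    else:
        chi2 = float(((resid / sig) ** 2).sum())
        cov = ata_inv * max(chi2 / dof, 1.0)  # scale up when underdispersed errors
    return InsertionFit(
        model=InsertionModel(a1=float(coef[0]), a2=float(coef[1]), nu=nu),
        stderr=(math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])),
        covariance=cov,
        residuals=resid,
        n_points=int(x.size),
    )


def collapse_check(
    datasets: list[InsertionDataset], n_grid: int = 50, rescale: bool = True
) -> float:
    """Cross-system dispersion of y = dF + ln(1-phi) at matched radius.

    Each system's y is interpolated onto a common grid of the rescaled
    radius x = R/xi (or the bare radius R when ``rescale`` is False, for
    the control direction); the statistic is the median over the grid of
    std(y)/mean(|y|) across systems.  Zero means perfect collapse.
    """
    if len(datasets) < 2:
        raise ValueError("collapse needs at least two systems")
    curves = []
    for ds in datasets:
        x, y = ds.rescaled()
        if not rescale:
            x = ds.radii
        order = np.argsort(x)
        curves.append((x[order], y[order]))
    lo = max(c[0][0] for c in curves)
    hi = min(c[0][-1] for c in curves)
    if hi <= lo:
        raise ValueError("systems share no overlapping radius range")
    grid = np.linspace(lo, hi, n_grid)
    from scipy.interpolate import CubicSpline

    ys = np.array([CubicSpline(cx, cy)(grid) for cx, cy in curves])
    spread = ys.std(axis=0, ddof=1) / np.maximum(np.abs(ys.mean(axis=0)), 1e-12)
    return float(np.median(spread))


def fit_scaling_prefactor(
    phi: np.ndarray, xi: np.ndarray, d: float = 0.6, nu: float = FLORY_NU
) -> ScalingFit:
    """Log-log fit of xi = c d phi^(-nu/(3nu-1)): prefactor c and slope.

    Returns the fitted exponent (expected -nu/(3nu-1), -0.7696 for
    nu = 0.588) and c = exp(intercept)/d with propagated standard errors.
    """
    phi = np.asarray(phi, float)
    xi = np.asarray(xi, float)
    if phi.size < 3 or phi.size != xi.size:
        raise ValueError("need at least three (phi, xi) pairs")
    if np.any(phi <= 0) or np.any(xi <= 0):
        raise ValueError("phi and xi must be positive")
    res = stats.linregress(np.log(phi), np.log(xi))
    c = math.exp(res.intercept) / d
    return ScalingFit(
        c=c,
        exponent=float(res.slope),
        c_stderr=c * float(res.intercept_stderr),
        exponent_stderr=float(res.stderr),
        expected_exponent=-nu / (3.0 * nu - 1.0),
    )
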