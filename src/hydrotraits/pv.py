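"""Pressure-volume (P-V) curve analysis.

A leaf P-V curve records paired (fresh mass, water potential) observations
while a rehydrated leaf dries on the bench.  Plotting the inverse water
potential transform ``-1/psi`` against dehydration ``1 - RWC`` (RWC =
relative water content) separates the trajectory into two phases:

* a curved initial phase while the cells retain turgor, where
  ``psi = psi_s + psi_p`` (osmotic plus turgor pressure components), and
* a straight terminal phase after turgor is lost, where ``psi`` is purely
  osmotic and ``-1/psi`` is linear in ``1 - RWC``.

The junction between the two phases is the turgor loss point (TLP).  This
module locates it with a deterministic two-segment least-squares breakpoint
scan and reports ``psi_tlp``, the relative water content at turgor loss,
and the osmotic potential at full turgor ``pi0`` (the terminal line's value
extrapolated to full hydration).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PVCurve",
    "TLPResult",
    "PVFitError",
    "estimate_saturated_mass",
    "compute_rwc",
    "fit_tlp",
]

#: observations wetter than this (psi in MPa) are excluded from the
#: transformed-axis fit: -1/psi blows up as psi -> 0 and the pressure
#: chamber cannot resolve such small tensions anyway.
PSI_WET_CUTOFF = -0.05


class PVFitError(RuntimeError):
    """Raised when a P-V curve cannot be fit (too few points, bad geometry)."""


@dataclass
class PVCurve:
    """One sample's bench-drying trajectory.

    Parameters
    ----------
    observations
        Sequence of ``(fresh_mass_g, psi_mpa)`` pairs in measurement order
        (wet to dry).  Water potentials are tensions, so ``psi <= 0``.
    dry_mass
        Oven-dry mass of the same leaf material, g.
    leaf_area
        One-sided leaf area in cm^2 (optional; used downstream for LMA).
    sat_mass
        Saturated (full-turgor) mass, g.  If omitted it is estimated from
        the observations via :func:`estimate_saturated_mass`.
    """

    sample_id: str
    species: str
    microhabitat: str
    observations: list[tuple[float, float]]
    dry_mass: float
    leaf_area: float | None = None
    sat_mass: float | None = None

    def __post_init__(self) -> None:
        if len(self.observations) < 6:
            raise ValueError(
                f"observations: need >= 6 points, got {len(self.observations)}"
            )
        fresh, psi = self.arrays()
        if np.any(psi > 0):
            raise ValueError("observations: all psi must be <= 0 MPa")
        if not self.dry_mass > 0:
            raise ValueError(f"dry_mass: must be > 0, got {self.dry_mass}")
        if np.any(fresh <= self.dry_mass):
            raise ValueError("observations: fresh masses must exceed dry_mass")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (fresh_mass, psi) as float arrays."""
        a = np.asarray(self.observations, dtype=float)
        return a[:, 0], a[:, 1]


@dataclass
class TLPResult:
    """Turgor-loss-point fit for one curve.

    ``psi_tlp <= pi0 <= 0`` in signed MPa: the TLP water potential is the
    full-turgor osmotic potential divided by a relative water content < 1,
    so it is always at least as negative as ``pi0``.
    """

    psi_tlp: float
    rwc_tlp: float
    pi0: float
    n_linear_points: int
    r2_linear: float
    flags: list[str] = field(default_factory=list)


def estimate_saturated_mass(
    curve: PVCurve, mode: str = "max", k: int = 4
) -> float:
    """Estimate the saturated (full-turgor) mass of a P-V sample.

    mode="max" (default) returns the largest observed fresh mass.
    mode="extrapolate" regresses fresh mass on psi over the ``k`` wettest
    points and returns the intercept at psi = 0, correcting for samples
    that were already transpiring at the first weighing.  If the wet-region
    slope is not positive toward psi = 0 (i.e. the extrapolation would fall
    below the observed maximum) or fewer than ``k`` points are available,
    the default is returned with a warning.
    """
    fresh, psi = curve.arrays()
    fallback = float(np.max(fresh))
    if mode == "max":
        return fallback
    if mode != "extrapolate":
        raise ValueError(f"mode: expected 'max' or 'extrapolate', got {mode!r}")
    if len(fresh) < k:
        logger.warning(
            "%s: only %d points (< k=%d); falling back to max observed mass",
            curve.sample_id, len(fresh), k,
        )
        return fallback
    order = np.argsort(psi)[::-1]  # wettest (least negative) first
    idx = order[:k]
    slope, intercept = np.polyfit(psi[idx], fresh[idx], 1)
    if slope <= 0:
        logger.warning(
            "%s: wet-region mass does not increase toward psi=0; "
            "falling back to max observed mass", curve.sample_id,
        )
        return fallback
    return float(max(intercept, fallback))


def compute_rwc(
    curve: PVCurve, sat_mass: float
) -> tuple[np.ndarray, np.ndarray]:
    """Relative water content per observation.

    RWC = (fresh - dry) / (sat - dry).  Values are clipped to
    (0, 1.0001]; a boolean mask marks observations that were out of range
    before clipping (oversaturated rehydration artifacts, or mass below
    dry mass which indicates a data error).
    """
    if sat_mass <= curve.dry_mass:
        raise ValueError(
            f"sat_mass: must exceed dry_mass ({curve.dry_mass}), got {sat_mass}"
        )
    fresh, _ = curve.arrays()
    rwc = (fresh - curve.dry_mass) / (sat_mass - curve.dry_mass)
    out_of_range = (rwc <= 0) | (rwc > 1.0001)
    return np.clip(rwc, np.nextafter(0, 1), 1.0001), out_of_range


def _segment_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = c0 + c1*x; returns (c0, c1, rss)."""
    c1, c0 = np.polyfit(x, y, 1)
    resid = y - (c0 + c1 * x)
    return float(c0), float(c1), float(resid @ resid)


def _split_score(
    x: np.ndarray, y: np.ndarray, psi: np.ndarray, split: int
) -> float:
    """Residual sum of squares, in MPa^2, of a two-segment model split at
    ``split``.

    Measurement noise is additive on psi, not on the transform -1/psi
    (whose variance explodes as psi -> 0), so candidate breakpoints are
    scored on the psi scale: the terminal (osmotic) segment is the line
    fit on the transformed axes mapped back through psi = -1/(c0 + c1 x),
    and the initial (turgor) segment is a low-order polynomial in psi
    itself, which tracks the smooth curvature of the turgor phase.
    Returns +inf for splits whose terminal line is unphysical.
    """
    c0, c1, _ = _segment_fit(x[split:], y[split:])
    denom = c0 + c1 * x[split:]
    if c1 >= 0 or np.any(denom <= 0):
        return float("inf")
    rss_term = float(np.sum((psi[split:] + 1.0 / denom) ** 2))
    deg = min(2, split - 1)
    coef = np.polyfit(x[:split], psi[:split], deg)
    rss_init = float(np.sum((psi[:split] - np.polyval(coef, x[:split])) ** 2))
    return rss_init + rss_term


def fit_tlp(
    curve: PVCurve,
    sat_mode: str = "max",
    min_terminal_points: int = 4,
) -> TLPResult:
    """Locate the turgor loss point of a bench-drying series.

    The observations are transformed to ``x = 1 - RWC`` and ``y = -1/psi``
    and scanned over all candidate breakpoints that leave at least
    ``min_terminal_points`` of the most-dehydrated observations in the
    terminal (post-turgor-loss) segment and two in the initial segment.
    For each candidate, lines are fit to both segments; the breakpoint
    minimising the summed residual sum of squares is selected.

    The terminal line determines the osmotic relationship:
    ``pi0 = -1 / y(0)`` and ``psi_tlp = -1 / y(x_bp)``, where ``x_bp`` is
    the breakpoint abscissa -- the intersection of the terminal line with a
    local chord through the last initial-segment points, clamped to the
    data interval bracketing the split (this refines the grid-limited
    split location to sub-step accuracy on clean data).
    """
    sat = curve.sat_mass if curve.sat_mass is not None else estimate_saturated_mass(
        curve, mode=sat_mode
    )
    rwc, oor = compute_rwc(curve, sat)
    _, psi = curve.arrays()

    flags: list[str] = []
    keep = (~oor) & (psi < PSI_WET_CUTOFF)
    if np.any(oor):
        flags.append("oversaturated_points_excluded")
    psi_kept = psi[keep]
    x = 1.0 - rwc[keep]
    y = -1.0 / psi_kept
    order = np.argsort(x)
    x, y, psi_kept = x[order], y[order], psi_kept[order]
    n = len(x)
    if n < 8:
        raise PVFitError(
            f"{curve.sample_id}: {n} usable points after filtering; need >= 8"
        )

    best: tuple[float, int] | None = None  # (total rss, split index)
    for split in range(2, n - min_terminal_points + 1):
        total = _split_score(x, y, psi_kept, split)
        if np.isfinite(total) and (best is None or total < best[0]):
            best = (total, split)
    if best is None:
        raise PVFitError(
            f"{curve.sample_id}: no admissible breakpoint yields a physical "
            "osmotic line"
        )
    rss_two, split = best

    c0, c1, rss_term = _segment_fit(x[split:], y[split:])
    if c1 >= 0:
        raise PVFitError(
            f"{curve.sample_id}: terminal segment of -1/psi does not decline "
            "with dehydration; cannot identify an osmotic line"
        )
    if c0 <= 0:
        raise PVFitError(
            f"{curve.sample_id}: terminal line implies non-negative osmotic "
            "potential at full turgor"
        )

    # Degenerate geometry: data already linear over the whole range means
    # the sample never held turgor within the measured window.
    g0, g1, _ = _segment_fit(x, y)
    denom_all = g0 + g1 * x
    if g1 < 0 and np.all(denom_all > 0):
        rss_one = float(np.sum((psi_kept + 1.0 / denom_all) ** 2))
        # relative improvement of the two-segment model; the floor keeps
        # exactly-linear (RSS ~ 0) data in the "no curvature" branch
        improvement = (rss_one - rss_two) / max(rss_one, 1e-12)
        if improvement < 0.01:
            flags.append("no_curvature_detected")

    # Refine the breakpoint between the last initial and first terminal
    # observation: the turgor loss point is where the initial-segment
    # psi trajectory (quadratic in x) meets the extrapolated osmotic
    # curve psi = -1/(c0 + c1 x).
    x_lo, x_hi = float(x[split - 1]), float(x[split])
    deg = min(2, split - 1)
    coef = np.polyfit(x[:split], psi_kept[:split], deg)
    grid = np.linspace(x_lo, x_hi, 201)
    gap = np.polyval(coef, grid) - (-1.0 / (c0 + c1 * grid))
    sign_change = np.nonzero(np.diff(np.sign(gap)) != 0)[0]
    if sign_change.size:
        i = sign_change[0]
        # linear interpolation of the crossing within one grid cell
        g0_, g1_ = gap[i], gap[i + 1]
        x_bp = float(grid[i] + (grid[i + 1] - grid[i]) * g0_ / (g0_ - g1_))
    else:
        x_bp = x_lo if abs(gap[0]) < abs(gap[-1]) else x_hi

    y_bp = c0 + c1 * x_bp
    if y_bp <= 0:
        raise PVFitError(
            f"{curve.sample_id}: terminal line non-positive at breakpoint"
        )

    y_term = y[split:]
    ss_tot = float(np.sum((y_term - y_term.mean()) ** 2))
    r2 = 1.0 - rss_term / ss_tot if ss_tot > 0 else 1.0

    if flags:
        warnings.warn(
            f"{curve.sample_id}: " + "; ".join(flags), stacklevel=2
        )
    return TLPResult(
        psi_tlp=float(-1.0 / y_bp),
        rwc_tlp=float(1.0 - x_bp),
        pi0=float(-1.0 / c0),
        n_linear_points=int(n - split),
        r2_linear=float(r2),
        flags=flags,
    )
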