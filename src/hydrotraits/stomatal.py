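"""Stomatal regulation stringency and hydraulic safety margins.

During a soil drydown, predawn leaf water potential (psi_pd) tracks soil
water status while midday potential (psi_md) additionally reflects the
transpiration the stomata allow.  Regressing psi_md on psi_pd across a
drydown yields the isohydricity index sigma (the slope): sigma = 0 means
midday potential is held constant regardless of soil drought (strict
isohydry), sigma = 1 means midday potential falls one-for-one with soil
drought (strict anisohydry), and intermediate slopes grade between.

The *hydroscape* is the area in the (psi_pd, psi_md) plane over which
stomata actively regulate water status: the triangle bounded by the
regression line, the psi_md axis, and the 1:1 line.  With regression
intercept L (< 0) and slope sigma (< 1) the lines intersect at
psi_pd = L/(1 - sigma), giving the closed form

    area = L**2 / (2 * (1 - sigma))   [MPa^2]

Safety margins relate the seasonal minimum water potential psi_min to the
vulnerability thresholds: HSM12 = psi_min - psi12 and
HSM50 = psi_min - psi50; negative values mean the plant operates beyond
the corresponding embolism threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .vulnerability import VCFit, VCFitError

__all__ = [
    "DrydownSeries",
    "RegulationFit",
    "SafetyMargins",
    "fit_sigma",
    "classify_regulation",
    "hydroscape_closed_form",
    "hydroscape_numeric",
    "hydroscape_vertices",
    "safety_margins",
]

#: minimum predawn span (MPa) for a meaningful slope.
MIN_PD_SPAN = 0.3

#: half-width of the tolerance band used when mapping a fitted slope onto
#: the discrete regulation classes (exact equality never occurs on data).
CLASS_TOL = 0.05


@dataclass
class DrydownSeries:
    """Paired predawn/midday water potentials over a drydown.

    ``observations`` columns: individual_id, date, leaf_replicate,
    psi_pd, psi_md (MPa, <= 0).  Observations with psi_md > psi_pd
    (midday wetter than predawn) are physically suspicious; they are
    flagged by :meth:`suspect_mask` but never dropped.
    """

    species: str
    microhabitat: str
    observations: pd.DataFrame

    REQUIRED = ("individual_id", "date", "leaf_replicate", "psi_pd", "psi_md")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations: missing columns {sorted(missing)}")
        if (self.observations["psi_pd"] > 0).any() or (
            self.observations["psi_md"] > 0
        ).any():
            raise ValueError("observations: water potentials must be <= 0 MPa")

    def suspect_mask(self) -> pd.Series:
        """True where midday potential exceeds predawn (flag, don't drop)."""
        return self.observations["psi_md"] > self.observations["psi_pd"]


@dataclass
class RegulationFit:
    """Isohydricity regression for one species x microhabitat group."""

    sigma: float
    intercept: float
    r2: float
    n: int
    hydroscape_area: float
    regulation_class: str
    sigma_ci95: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class SafetyMargins:
    """Distance between the seasonal minimum potential and failure thresholds."""

    psi_min: float
    hsm12: float
    hsm50: float


def classify_regulation(sigma: float, tol: float = CLASS_TOL) -> str:
    """Map a fitted slope onto the isohydry continuum labels.

    A +/- ``tol`` band around the theoretical points 0 and 1 absorbs
    sampling noise; negative slopes (over-compensating regulation) fall in
    the strict-isohydric band or are labelled separately.
    """
    if abs(sigma) < tol:
        return "strict isohydric"
    if abs(sigma - 1.0) < tol:
        return "strict anisohydric"
    if sigma > 1.0:
        return "extreme anisohydric"
    if sigma < 0:
        return "negative slope"
    return "partial isohydric"


def fit_sigma(series: DrydownSeries) -> RegulationFit:
    """OLS regression of midday on predawn water potential.

    Technical replicate leaves are averaged per individual x date before
    regression (replicates measure the same organismal state and would
    otherwise pseudo-replicate); the regression then pools all individual
    x date means within the group.  Requires >= 5 pairs spanning >= 0.3
    MPa of predawn potential.
    """
    means = (
        series.observations
        .groupby(["individual_id", "date"], sort=True)[["psi_pd", "psi_md"]]
        .mean()
        .reset_index()
    )
    if len(means) < 5:
        raise ValueError(
            f"need >= 5 individual x date pairs, got {len(means)}"
        )
    span = means["psi_pd"].max() - means["psi_pd"].min()
    if span < MIN_PD_SPAN:
        raise ValueError(
            f"psi_pd span {span:.3f} MPa < {MIN_PD_SPAN} MPa; "
            "slope would be unconstrained"
        )
    X = sm.add_constant(means["psi_pd"].to_numpy())
    model = sm.OLS(means["psi_md"].to_numpy(), X).fit()
    intercept, sigma = float(model.params[0]), float(model.params[1])
    ci = model.conf_int(alpha=0.05)
    flags: list[str] = []
    if sigma < 0:
        flags.append("negative_sigma")
    area, hflag = hydroscape_closed_form(sigma, intercept, flag=True)
    if hflag:
        flags.append(hflag)
    n_suspect = int(series.suspect_mask().sum())
    if n_suspect:
        flags.append(f"psi_md_above_psi_pd:{n_suspect}")
    return RegulationFit(
        sigma=sigma,
        intercept=intercept,
        r2=float(model.rsquared),
        n=len(means),
        hydroscape_area=area,
        regulation_class=classify_regulation(sigma),
        sigma_ci95=(float(ci[1][0]), float(ci[1][1])),
        flags=flags,
    )


def hydroscape_closed_form(
    sigma: float, intercept: float, flag: bool = False
) -> float | tuple[float, str | None]:
    """Hydroscape area in MPa^2, L^2 / (2 (1 - sigma)).

    Defined for 0 <= sigma < 1 and intercept < 0, where the regression
    line and the 1:1 line bound a finite triangle.  For sigma >= 1 the
    lines never close a region (or the species is beyond anisohydric) and
    for intercept >= 0 the regression starts on or above the 1:1 line; in
    both cases the area is reported as 0 so multi-group pipelines do not
    abort, with a flag when ``flag=True``.
    """
    if sigma >= 1.0 or intercept >= 0.0:
        reason = "hydroscape_unbounded" if sigma >= 1.0 else "hydroscape_degenerate"
        # intercept == 0 with sigma < 1 is a zero-area triangle, not an error
        if intercept == 0.0 and sigma < 1.0:
            reason = None
        return (0.0, reason) if flag else 0.0
    area = intercept**2 / (2.0 * (1.0 - sigma))
    return (area, None) if flag else area


def hydroscape_vertices(
    sigma: float, intercept: float
) -> list[tuple[float, float]]:
    """Vertices of the hydroscape triangle in the (psi_pd, psi_md) plane."""
    if sigma >= 1.0 or intercept >= 0.0:
        return []
    x_star = intercept / (1.0 - sigma)
    return [(0.0, 0.0), (0.0, intercept), (x_star, x_star)]


def hydroscape_numeric(
    sigma: float, intercept: float, grid_step: float = 1e-3
) -> float:
    """Trapezoid-rule twin of :func:`hydroscape_closed_form`.

    Integrates the vertical gap between the 1:1 line and the regression
    line from psi_pd = 0 down to their intersection.  Exists as an
    independent cross-check of the closed form; agrees to <= 1e-6 MPa^2
    for grid_step <= 1e-3 over the valid domain.
    """
    if sigma >= 1.0 or intercept >= 0.0:
        return 0.0
    x_star = intercept / (1.0 - sigma)  # negative
    n = max(int(np.ceil(abs(x_star) / grid_step)), 2)
    x = np.linspace(x_star, 0.0, n + 1)
    gap = x - (intercept + sigma * x)  # (1:1) minus regression, >= 0 here
    return float(np.trapezoid(np.abs(gap), x))


def safety_margins(psi_min: float, vcfit: VCFit) -> SafetyMargins:
    """Hydraulic safety margins from psi_min and a fitted vulnerability curve.

    ``psi_min`` is the mean midday potential of foil-wrapped
    (non-transpiring) leaves at the end of the dry season.  Negative
    margins are legitimate results, not errors: they mean the plant's
    operating range crosses the embolism threshold.
    """
    if psi_min > 0:
        raise ValueError(f"psi_min: must be <= 0 MPa, got {psi_min}")
    if not vcfit.converged:
        raise VCFitError("safety margins require a converged vulnerability fit")
    return SafetyMargins(
        psi_min=psi_min,
        hsm12=psi_min - vcfit.psi12,
        hsm50=psi_min - vcfit.psi50,
    )
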