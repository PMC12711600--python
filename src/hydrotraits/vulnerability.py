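"""Xylem vulnerability-curve construction and fitting.

Bench-dehydrated branches are measured for initial hydraulic conductivity
(Ki), flushed to remove embolism, and re-measured for maximum conductivity
(Kmax).  The percentage loss of conductivity

    PLC = 100 * (Kmax - Ki) / Kmax

as a function of stem water potential (psi_stem) is fit with the classic
two-parameter sigmoid (Pammenter & Van der Willigen form)

    PLC(psi) = 100 / (1 + exp(a * (psi - psi50)))

where ``psi50`` is the water potential inducing 50% loss and ``a`` (MPa^-1,
> 0) sets the steepness.  ``psi12``, the conventional onset-of-embolism
threshold, follows in closed form.  Uncertainty is quantified by
nonparametric case resampling of branches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FlowMeasurement",
    "BranchRecord",
    "VulnerabilitySeries",
    "VCFit",
    "VCFitError",
    "initial_conductivity",
    "percent_loss_conductivity",
    "equilibration_qc",
    "fit_vulnerability",
    "psi_at_plc",
    "bootstrap_ci",
    "specific_conductivity",
    "sigmoid_plc",
]

#: two wrapped-leaf water potentials must agree within this (MPa) for a
#: branch to count as equilibrated.
EQUILIBRATION_TOL = 0.20

#: minimum psi_stem span (MPa) required for a constrained sigmoid fit.
MIN_PSI_SPAN = 1.5


class VCFitError(RuntimeError):
    """Raised when a vulnerability curve cannot be fit."""


@dataclass(frozen=True)
class FlowMeasurement:
    """A single gravimetric flow measurement on a stem segment.

    jv : mass flow rate, kg/s.
    dp_dl : axial pressure gradient driving the flow, MPa/m.
    """

    jv: float
    dp_dl: float

    def __post_init__(self) -> None:
        if self.jv < 0:
            raise ValueError(f"jv: must be >= 0, got {self.jv}")
        if not self.dp_dl > 0:
            raise ValueError(f"dp_dl: must be > 0, got {self.dp_dl}")


@dataclass
class BranchRecord:
    """One dehydration time point: a branch's water status and conductivities.

    ``psi_stem`` is the mean of the two wrapped-leaf measurements; if not
    supplied it is computed.  ``plc`` likewise defaults to the value implied
    by (k_i, k_max).  Negative implied PLC (k_i slightly above k_max, a
    flushing artifact) is clipped to 0 and flagged.
    """

    branch_id: str
    psi_leaf_a: float
    psi_leaf_b: float
    k_i: float
    k_max: float
    psi_stem: float | None = None
    plc: float | None = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if not self.k_max > 0:
            raise ValueError(f"k_max: must be > 0, got {self.k_max}")
        if self.psi_leaf_a > 0 or self.psi_leaf_b > 0:
            raise ValueError("psi_leaf_a/psi_leaf_b: must be <= 0 MPa")
        if self.psi_stem is None:
            self.psi_stem = 0.5 * (self.psi_leaf_a + self.psi_leaf_b)
        if self.plc is None:
            self.plc, self.clipped = percent_loss_conductivity(
                self.k_i, self.k_max
            )
        if not 0 <= self.plc <= 100:
            raise ValueError(f"plc: must be in [0, 100], got {self.plc}")


@dataclass
class VulnerabilitySeries:
    """Pooled branch records for one species x microhabitat group."""

    species: str
    microhabitat: str
    records: list[BranchRecord]
    poorly_constrained: bool = False

    def accepted(self) -> list[BranchRecord]:
        """Records passing the wrapped-leaf equilibration check."""
        return [
            r for r in self.records
            if equilibration_qc(r.psi_leaf_a, r.psi_leaf_b)
        ]


@dataclass
class VCFit:
    """Fitted sigmoid vulnerability curve."""

    psi50: float
    slope_a: float
    psi12: float
    n_branches: int
    converged: bool
    ci95_psi50: tuple[float, float] | None = None
    ci95_psi12: tuple[float, float] | None = None
    model: str = "sigmoid"
    flags: list[str] = field(default_factory=list)


def sigmoid_plc(psi: np.ndarray, a: float, psi50: float) -> np.ndarray:
    """PLC (%) predicted by the sigmoid model at stem water potential psi."""
    return 100.0 / (1.0 + np.exp(a * (np.asarray(psi, float) - psi50)))


def _weibull_plc(psi: np.ndarray, b: float, c: float) -> np.ndarray:
    # alternative vulnerability model, PLC = 100*(1 - exp(-(-psi/b)^c))
    psi = np.asarray(psi, float)
    return 100.0 * (1.0 - np.exp(-np.power(np.maximum(-psi, 0) / b, c)))


def initial_conductivity(m: FlowMeasurement) -> float:
    """Hydraulic conductivity Ki = Jv / (dP/dL), kg m s^-1 MPa^-1."""
    return m.jv / m.dp_dl


def percent_loss_conductivity(k_i: float, k_max: float) -> tuple[float, bool]:
    """PLC = 100 (Kmax - Ki)/Kmax, with negative values clipped to 0.

    Returns ``(plc, clipped)``; ``clipped`` is True when measurement noise
    put Ki above Kmax and the physical lower bound of 0 was applied.
    """
    if not k_max > 0:
        raise ValueError(f"k_max: must be > 0, got {k_max}")
    if k_i < 0:
        raise ValueError(f"k_i: must be >= 0, got {k_i}")
    plc = 100.0 * (k_max - k_i) / k_max
    if plc < 0:
        return 0.0, True
    return float(plc), False


def equilibration_qc(psi_leaf_a: float, psi_leaf_b: float) -> bool:
    """Accept a branch iff its two wrapped-leaf potentials differ by < 0.20 MPa.

    The strict inequality matters: a difference of exactly 0.20 MPa is
    rejected (the branch should be re-equilibrated).  A small epsilon
    guards the boundary against float representation (0.20 stored as
    0.1999...).
    """
    return EQUILIBRATION_TOL - abs(psi_leaf_a - psi_leaf_b) > 1e-9


def fit_vulnerability(
    records: list[BranchRecord],
    model: str = "sigmoid",
    n_boot: int | None = None,
    seed: int | None = None,
) -> VCFit:
    """Fit a vulnerability curve to pooled, QC-accepted branch records.

    Requires >= 6 records spanning >= 1.5 MPa of stem water potential.
    Initialisation: ``a = 1 MPa^-1`` and ``psi50`` at the record whose PLC
    is nearest 50%; a few perturbed restarts are attempted before the fit
    is declared non-converged.  If ``n_boot`` is given, bootstrap
    confidence intervals are attached (see :func:`bootstrap_ci`).
    """
    if len(records) < 6:
        raise VCFitError(f"need >= 6 records, got {len(records)}")
    psi = np.array([r.psi_stem for r in records], float)
    plc = np.array([r.plc for r in records], float)
    span = psi.max() - psi.min()
    if span < MIN_PSI_SPAN:
        raise VCFitError(
            f"psi_stem span {span:.2f} MPa < {MIN_PSI_SPAN} MPa; "
            "curve would be unconstrained"
        )

    if model == "sigmoid":
        func = sigmoid_plc
        psi50_init = psi[np.argmin(np.abs(plc - 50.0))]
        p0s = [(1.0, psi50_init), (2.0, psi50_init), (0.5, psi.mean()),
               (4.0, psi50_init)]
        bounds = ([1e-6, -20.0], [50.0, 0.0])
    elif model == "weibull":
        func = _weibull_plc
        b0 = max(-psi[np.argmin(np.abs(plc - 50.0))], 0.1)
        p0s = [(b0, 2.0), (b0, 1.0), (max(-psi.mean(), 0.1), 3.0)]
        bounds = ([1e-6, 0.05], [50.0, 50.0])
    else:
        raise ValueError(f"model: expected 'sigmoid' or 'weibull', got {model!r}")

    popt = None
    for p0 in p0s:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand, _ = curve_fit(
                    func, psi, plc, p0=p0, bounds=bounds, maxfev=5000
                )
            popt = cand
            break
        except (RuntimeError, ValueError):
            continue

    if popt is None:
        return VCFit(
            psi50=float("nan"), slope_a=float("nan"), psi12=float("nan"),
            n_branches=len(records), converged=False, model=model,
            flags=["non_convergence"],
        )

    if model == "sigmoid":
        a_hat, psi50_hat = float(popt[0]), float(popt[1])
        fit = VCFit(
            psi50=psi50_hat, slope_a=a_hat, psi12=float("nan"),
            n_branches=len(records), converged=True, model=model,
        )
        fit.psi12 = psi_at_plc(fit, 12.0)
    else:
        b_hat, c_hat = float(popt[0]), float(popt[1])
        psi50_hat = float(-b_hat * np.log(2.0) ** (1.0 / c_hat))
        # local log-odds slope at psi50, so steepness is comparable
        # across the two model families
        a_hat = float(c_hat * np.log(2.0) ** (1.0 - 1.0 / c_hat) / b_hat)
        fit = VCFit(
            psi50=psi50_hat, slope_a=a_hat,
            psi12=float(-b_hat * (-np.log(1 - 0.12)) ** (1.0 / c_hat)),
            n_branches=len(records), converged=True, model=model,
        )
    if n_boot is not None:
        bootstrap_ci(records, n_boot=n_boot, seed=seed, fit=fit, model=model)
    return fit


def psi_at_plc(fit: VCFit, p: float) -> float:
    """Water potential at which the fitted curve reaches ``p`` % loss.

    For the sigmoid model: psi_p = psi50 + ln((100 - p)/p) / a.
    """
    if not 0 < p < 100:
        raise ValueError(f"p: must be in (0, 100), got {p}")
    if not fit.converged:
        raise VCFitError("cannot evaluate a non-converged fit")
    return float(fit.psi50 + np.log((100.0 - p) / p) / fit.slope_a)


def bootstrap_ci(
    records: list[BranchRecord],
    n_boot: int = 1000,
    seed: int | None = None,
    fit: VCFit | None = None,
    model: str = "sigmoid",
    method: str = "basic",
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Case-resampling bootstrap intervals for psi50 and psi12.

    Branches are resampled with replacement ``n_boot`` times and the
    curve refit on each replicate.  ``method="basic"`` (default) returns
    the basic (reverse-percentile) interval ``2*theta_hat - q_{97.5/2.5}``,
    which is better calibrated than the raw percentile interval for this
    estimator at bench-scale sample sizes; ``method="percentile"`` returns
    the raw 2.5/97.5 percentiles.  Replicates whose refit fails, or whose
    resample collapses below the span requirement, are dropped; more than
    20% dropped sets a ``ci_widened`` flag on ``fit``.
    """
    if n_boot < 200:
        raise ValueError(f"n_boot: must be >= 200, got {n_boot}")
    if method not in ("basic", "percentile"):
        raise ValueError(
            f"method: expected 'basic' or 'percentile', got {method!r}"
        )
    point = fit if fit is not None else fit_vulnerability(records, model=model)
    rng = np.random.default_rng(seed)
    n = len(records)
    psi50s, psi12s = [], []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = [records[i] for i in idx]
        try:
            f = fit_vulnerability(sample, model=model)
        except VCFitError:
            failed += 1
            continue
        if not f.converged:
            failed += 1
            continue
        psi50s.append(f.psi50)
        psi12s.append(f.psi12)
    if not psi50s:
        raise VCFitError("all bootstrap replicates failed to converge")

    def _interval(values: list[float], center: float) -> tuple[float, float]:
        q_lo, q_hi = np.percentile(values, [2.5, 97.5])
        if method == "percentile":
            return float(q_lo), float(q_hi)
        return float(2 * center - q_hi), float(2 * center - q_lo)

    ci50 = _interval(psi50s, point.psi50)
    ci12 = _interval(psi12s, point.psi12)
    if fit is not None:
        fit.ci95_psi50 = ci50
        fit.ci95_psi12 = ci12
        if failed > 0.2 * n_boot:
            fit.flags.append("ci_widened")
    return ci50, ci12


def specific_conductivity(
    k_max: float, total_xs_area: float, pith_area: float = 0.0
) -> float:
    """Sapwood-specific conductivity Ks = Kmax / functional sapwood area.

    The functional area is the total stem cross-section (m^2) minus the
    non-conductive pith; units kg m^-1 s^-1 MPa^-1.
    """
    if pith_area < 0:
        raise ValueError(f"pith_area: must be >= 0, got {pith_area}")
    functional = total_xs_area - pith_area
    if not functional > 0:
        raise ValueError(
            f"functional sapwood area must be > 0, got {functional}"
        )
    return k_max / functional
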