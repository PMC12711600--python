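"""Synthetic raw-measurement generators with known ground truth.

Every downstream stage of the pipeline (turgor-loss-point extraction,
vulnerability-curve fitting, isohydricity regression, anatomy summaries)
can be validated by parameter recovery: generate raw tables from known
parameters, run the estimator, compare.  The generators are pure
functions of their parameter objects — the seed is a mandatory field, not
global state — so fixtures are bit-reproducible across platforms.

Generative models
-----------------
* P-V series: two-phase pressure-volume relationship.  With symplastic
  relative water content R, osmotic potential follows the hyperbola
  ``pi0 / R`` and turgor pressure declines linearly from ``-pi0`` at full
  hydration to 0 at ``R = rwc_tlp``:

      psi(R) = pi0/R + max(0, -pi0 * (R - rwc_tlp) / (1 - rwc_tlp))

  so psi(1) = 0 and the true turgor loss point is ``pi0 / rwc_tlp``.
  An apoplastic water fraction (default 0) maps R onto total RWC.
* Vulnerability observations: PLC drawn from the sigmoid
  ``100 / (1 + exp(a (psi - psi50)))`` plus truncated Gaussian noise,
  with internally consistent (Ki, Kmax) pairs.
* Drydown: psi_md = intercept + sigma * psi_pd + noise, two technical
  replicate leaves per individual per date, predawn potentials declining
  over the campaign.
* Vessels: lognormal diameter mixture; one component for the usual
  unimodal case, two well-separated components for dimorphic xylem.

Measurement noise is Gaussian and additive on the measured quantity,
truncated to the physical range — the simplest model that exercises the
fitters; nothing distributional is implied about real pressure-chamber
error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any
import warnings

import numpy as np
import pandas as pd

from .anatomy import VesselSet
from .pv import PVCurve
from .stomatal import DrydownSeries
from .vulnerability import BranchRecord, VulnerabilitySeries, sigmoid_plc

__all__ = [
    "PVGenParams",
    "VCGenParams",
    "DrydownGenParams",
    "VesselGenParams",
    "gen_pv_series",
    "gen_vc_observations",
    "gen_drydown",
    "gen_vessels",
    "gen_leaf_traits",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class PVGenParams:
    """Ground truth for a bench-drying series.

    pi0 : osmotic potential at full turgor, MPa (< 0).
    rwc_tlp : symplastic relative water content at turgor loss, in (0, 1).
    sat_mass, dry_mass : saturated and oven-dry sample masses, g.
    n_points : number of (mass, psi) observations, >= 8.
    noise_sd_psi : Gaussian noise SD added to psi, MPa.
    apoplastic_fraction : water fraction outside the symplast, in [0, 1).
    """

    pi0: float
    rwc_tlp: float
    sat_mass: float
    dry_mass: float
    n_points: int = 12
    noise_sd_psi: float = 0.0
    apoplastic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.pi0 < 0, f"pi0: must be < 0, got {self.pi0}")
        _require(0 < self.rwc_tlp < 1,
                 f"rwc_tlp: must be in (0, 1), got {self.rwc_tlp}")
        _require(self.dry_mass < self.sat_mass,
                 "dry_mass: must be less than sat_mass")
        _require(self.dry_mass > 0, f"dry_mass: must be > 0, got {self.dry_mass}")
        _require(self.n_points >= 8,
                 f"n_points: must be >= 8, got {self.n_points}")
        _require(self.noise_sd_psi >= 0, "noise_sd_psi: must be >= 0")
        _require(0 <= self.apoplastic_fraction < 1,
                 "apoplastic_fraction: must be in [0, 1)")

    @property
    def psi_tlp(self) -> float:
        """True turgor loss point implied by the two-phase model, MPa."""
        return self.pi0 / self.rwc_tlp


@dataclass(frozen=True)
class VCGenParams:
    """Ground truth for a set of vulnerability-curve observations.

    psi50_true : water potential at 50% loss, MPa (< 0).
    slope_a : sigmoid steepness, MPa^-1 (> 0).
    psi_range : (most negative, least negative) stem potentials sampled.
    noise_sd_plc : Gaussian noise SD on PLC, percentage points.
    kmax : the fixed maximum conductivity used to back out Ki.
    """

    psi50_true: float
    slope_a: float
    n_branches: int = 30
    psi_range: tuple[float, float] = (-6.0, -0.25)
    noise_sd_plc: float = 0.0
    kmax: float = 5.0e-4
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.psi50_true < 0,
                 f"psi50_true: must be < 0, got {self.psi50_true}")
        _require(self.slope_a > 0, f"slope_a: must be > 0, got {self.slope_a}")
        _require(self.n_branches >= 2, "n_branches: must be >= 2")
        lo, hi = self.psi_range
        _require(lo < hi, "psi_range: must be (low, high) with low < high")
        _require(-10 < lo and hi <= 0, "psi_range: must lie within (-10, 0]")
        _require(self.noise_sd_plc >= 0, "noise_sd_plc: must be >= 0")
        _require(self.kmax > 0, f"kmax: must be > 0, got {self.kmax}")


@dataclass(frozen=True)
class DrydownGenParams:
    """Ground truth for a paired predawn/midday drydown campaign.

    sigma_true : isohydricity slope (dimensionless).
    intercept_true : fitted psi_md at psi_pd = 0, MPa (<= 0).
    psi_pd_range : (most negative, least negative) predawn potentials
        spanned over the campaign; max must be <= 0.
    noise_sd : Gaussian noise SD on each midday leaf measurement, MPa.
    """

    sigma_true: float
    intercept_true: float
    n_individuals: int = 5
    n_dates: int = 12
    psi_pd_range: tuple[float, float] = (-2.5, -0.3)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.intercept_true <= 0,
                 f"intercept_true: must be <= 0, got {self.intercept_true}")
        _require(self.n_individuals >= 1, "n_individuals: must be >= 1")
        _require(self.n_dates >= 3, f"n_dates: must be >= 3, got {self.n_dates}")
        lo, hi = self.psi_pd_range
        _require(lo < hi, "psi_pd_range: must be (low, high) with low < high")
        _require(hi <= 0, f"psi_pd_range: max must be <= 0, got {hi}")
        _require(self.noise_sd >= 0, "noise_sd: must be >= 0")


@dataclass(frozen=True)
class VesselGenParams:
    """Lognormal (mixture) model for vessel diameters, um.

    Each component is parametrised by its arithmetic mean and SD;
    ``mix_weight`` is the probability of the first component.  Omitting
    the second component requires mix_weight = 1 (unimodal).
    """

    mode1_mean: float
    mode1_sd: float
    n_vessels: int
    mode2_mean: float | None = None
    mode2_sd: float | None = None
    mix_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.mode1_mean > 0, "mode1_mean: must be > 0")
        _require(self.mode1_sd > 0, "mode1_sd: must be > 0")
        _require(self.n_vessels >= 1,
                 f"n_vessels: must be >= 1 (empty set), got {self.n_vessels}")
        _require(0 <= self.mix_weight <= 1, "mix_weight: must be in [0, 1]")
        if self.mode2_mean is None:
            _require(self.mix_weight == 1.0,
                     "mix_weight: must be 1 when mode2 is absent")
        else:
            _require(self.mode2_mean > 0, "mode2_mean: must be > 0")
            _require(self.mode2_sd is not None and self.mode2_sd > 0,
                     "mode2_sd: must be > 0 when mode2_mean is given")


def gen_pv_series(
    params: PVGenParams,
    sample_id: str = "synthetic-pv",
    species: str = "synthetic",
    microhabitat: str = "synthetic",
) -> tuple[PVCurve, dict[str, Any]]:
    """Generate one bench-drying series plus its ground truth.

    The symplastic RWC grid runs from 1.0 (saturation, psi = 0) down past
    the turgor loss point, so both phases of the curve are represented;
    fresh masses decrease strictly from ``sat_mass``.  Returns
    ``(curve, truth)`` where truth holds psi_tlp, pi0 and rwc_tlp.
    """
    rng = np.random.default_rng(params.seed)
    r_min = max(params.rwc_tlp - 0.15, 0.05)
    r = np.linspace(1.0, r_min, params.n_points)
    turgor = np.where(
        r >= params.rwc_tlp,
        -params.pi0 * (r - params.rwc_tlp) / (1.0 - params.rwc_tlp),
        0.0,
    )
    psi = params.pi0 / r + turgor
    if params.noise_sd_psi > 0:
        psi = psi + rng.normal(0.0, params.noise_sd_psi, size=psi.shape)
    psi = np.minimum(psi, 0.0)  # tension cannot be positive

    af = params.apoplastic_fraction
    rwc_total = af + (1.0 - af) * r
    fresh = params.dry_mass + rwc_total * (params.sat_mass - params.dry_mass)
    curve = PVCurve(
        sample_id=sample_id,
        species=species,
        microhabitat=microhabitat,
        observations=list(zip(fresh.tolist(), psi.tolist())),
        dry_mass=params.dry_mass,
        sat_mass=params.sat_mass,
    )
    truth = {
        "psi_tlp": params.psi_tlp,
        "pi0": params.pi0,
        "rwc_tlp": params.rwc_tlp,
    }
    return curve, truth


def gen_vc_observations(
    params: VCGenParams,
    species: str = "synthetic",
    microhabitat: str = "synthetic",
) -> tuple[VulnerabilitySeries, dict[str, Any]]:
    """Generate pooled branch records following the sigmoid PLC model.

    Stem potentials are evenly spread over ``psi_range``; PLC is the
    sigmoid value plus truncated Gaussian noise; (Ki, Kmax) pairs are
    back-computed so Ki/Kmax = 1 - PLC/100 holds exactly.  If the sampled
    range does not bracket psi50 the series is flagged poorly constrained.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.psi_range
    psi = np.linspace(hi, lo, params.n_branches)
    plc = sigmoid_plc(psi, params.slope_a, params.psi50_true)
    if params.noise_sd_plc > 0:
        plc = plc + rng.normal(0.0, params.noise_sd_plc, size=plc.shape)
    plc = np.clip(plc, 0.0, 100.0)
    k_i = params.kmax * (1.0 - plc / 100.0)

    poorly = not (lo < params.psi50_true < hi)
    if poorly:
        warnings.warn(
            "psi_range does not bracket psi50_true; the fit will be "
            "poorly constrained", stacklevel=2,
        )
    records = [
        BranchRecord(
            branch_id=f"b{i:03d}",
            psi_leaf_a=float(p),
            psi_leaf_b=float(p),
            k_i=float(ki),
            k_max=params.kmax,
            plc=float(pl),
        )
        for i, (p, ki, pl) in enumerate(zip(psi, k_i, plc))
    ]
    series = VulnerabilitySeries(
        species=species, microhabitat=microhabitat, records=records,
        poorly_constrained=poorly,
    )
    truth = {"psi50": params.psi50_true, "slope_a": params.slope_a}
    return series, truth


def gen_drydown(
    params: DrydownGenParams,
    species: str = "synthetic",
    microhabitat: str = "synthetic",
) -> tuple[DrydownSeries, dict[str, Any]]:
    """Generate a drydown campaign of paired predawn/midday potentials.

    Each individual's predawn trajectory declines linearly over the
    campaign within ``psi_pd_range`` plus a small fixed individual offset;
    each (individual, date) yields two technical-replicate leaves whose
    midday potentials are ``intercept + sigma * psi_pd`` plus independent
    Gaussian noise.  With zero noise the downstream regression recovers
    sigma and the intercept to machine precision.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.psi_pd_range
    base = np.linspace(hi, lo, params.n_dates)
    offsets = rng.normal(0.0, 0.05, size=params.n_individuals)
    rows = []
    for i in range(params.n_individuals):
        pd_traj = np.minimum(base + offsets[i], 0.0)
        for d in range(params.n_dates):
            psi_pd = float(pd_traj[d])
            for leaf in (1, 2):
                eps = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
                psi_md = params.intercept_true + params.sigma_true * psi_pd + eps
                rows.append(
                    {
                        "individual_id": f"ind{i + 1:02d}",
                        "date": f"d{d + 1:02d}",
                        "leaf_replicate": leaf,
                        "psi_pd": psi_pd,
                        "psi_md": min(psi_md, 0.0),
                    }
                )
    series = DrydownSeries(
        species=species, microhabitat=microhabitat,
        observations=pd.DataFrame(rows),
    )
    truth = {"sigma": params.sigma_true, "intercept": params.intercept_true}
    return series, truth


def _lognormal_from_moments(
    mean: float, sd: float
) -> tuple[float, float]:
    """Underlying (mu, sigma) of a lognormal with given arithmetic moments."""
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


def gen_vessels(
    params: VesselGenParams,
    section_id: str = "synthetic-section",
    species: str = "synthetic",
    microhabitat: str = "synthetic",
) -> VesselSet:
    """Draw vessel diameters from a lognormal (mixture) distribution.

    With two well-separated components the sample is dimorphic (bimodal
    diameter histogram); with one component, unimodal.
    """
    rng = np.random.default_rng(params.seed)
    mu1, s1 = _lognormal_from_moments(params.mode1_mean, params.mode1_sd)
    if params.mode2_mean is None:
        d = rng.lognormal(mu1, s1, size=params.n_vessels)
    else:
        mu2, s2 = _lognormal_from_moments(params.mode2_mean, params.mode2_sd)
        pick1 = rng.random(params.n_vessels) < params.mix_weight
        d = np.where(
            pick1,
            rng.lognormal(mu1, s1, size=params.n_vessels),
            rng.lognormal(mu2, s2, size=params.n_vessels),
        )
    return VesselSet(
        section_id=section_id, species=species, microhabitat=microhabitat,
        diameters=d,
    )


def gen_leaf_traits(
    mean_area_cm2: float,
    sd_area_cm2: float,
    mean_lma_g_m2: float,
    sd_lma_g_m2: float,
    n: int = 5,
    seed: int = 0,
    species: str = "synthetic",
    microhabitat: str = "synthetic",
) -> pd.DataFrame:
    """Replicate leaf-trait table (area, dry mass) with known LMA moments.

    Leaf areas and LMA values are drawn independently (truncated at small
    positive floors); dry mass is back-computed as LMA x area so the
    derived LMA recovers the sampled value exactly.
    """
    if n < 1:
        raise ValueError(f"n: must be >= 1, got {n}")
    for name, val in [("mean_area_cm2", mean_area_cm2),
                      ("mean_lma_g_m2", mean_lma_g_m2)]:
        if val <= 0:
            raise ValueError(f"{name}: must be > 0, got {val}")
    rng = np.random.default_rng(seed)
    area = np.maximum(rng.normal(mean_area_cm2, sd_area_cm2, n), 0.1)
    lma = np.maximum(rng.normal(mean_lma_g_m2, sd_lma_g_m2, n), 1.0)
    dry = lma * (area * 1e-4)  # g = g/m^2 * m^2
    return pd.DataFrame(
        {
            "species": species,
            "microhabitat": microhabitat,
            "leaf_id": [f"leaf{i + 1:03d}" for i in range(n)],
            "leaf_area_cm2": area,
            "dry_mass_g": dry,
        }
    )
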