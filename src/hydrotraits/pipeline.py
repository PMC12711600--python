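"""Trait aggregation: LMA, variability index (PPI), microhabitat classes,
and the long-format species x microhabitat trait summary.

The variability index PPI for a trait is computed from its three
microhabitat means:

    PPI = (mean_max - mean_min) / mean_max

By default the means are replaced by their absolute values first
("magnitude" mode): water-potential traits are negative-valued, and only
the magnitude reading yields the positive indices the framework expects
(a literal application to means around -2 MPa produces negative,
uninterpretable ratios).  Raw mode applies the formula literally and is
kept for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TraitSummary",
    "PPIResult",
    "TRAIT_UNITS",
    "leaf_mass_per_area",
    "ppi",
    "classify_microhabitat",
    "summarize",
    "ppi_table",
]

#: controlled unit vocabulary for summary rows.
TRAIT_UNITS = {
    "psi_tlp": "MPa",
    "pi0": "MPa",
    "psi12": "MPa",
    "psi50": "MPa",
    "psi_min": "MPa",
    "hsm12": "MPa",
    "hsm50": "MPa",
    "hydroscape_area": "MPa^2",
    "sigma": "dimensionless",
    "dh": "um",
    "ks": "kg.m-1.s-1.MPa-1",
    "lma": "g/m^2",
    "leaf_area": "cm^2",
}

#: traits whose PPI is conventionally reported (magnitude mode).
PPI_TRAITS = ("psi_tlp", "psi50", "ks", "hsm50", "dh", "lma", "leaf_area")


@dataclass(frozen=True)
class TraitSummary:
    """One summary cell: a trait's mean +/- sd over n samples in a group."""

    species: str
    microhabitat: str
    trait: str
    mean: float
    sd: float
    n: int
    units: str

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n: must be >= 1, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd: must be >= 0, got {self.sd}")
        if self.units not in TRAIT_UNITS.values():
            raise ValueError(f"units: {self.units!r} not in controlled vocabulary")


@dataclass(frozen=True)
class PPIResult:
    """Variability index of one trait across a species' microhabitats."""

    species: str
    trait: str
    ppi: float
    habitat_of_max: str
    habitat_of_min: str


def leaf_mass_per_area(dry_mass: float, leaf_area: float) -> float:
    """LMA in g/m^2 from dry mass (g) and one-sided leaf area (cm^2)."""
    if dry_mass <= 0:
        raise ValueError(f"dry_mass: must be > 0, got {dry_mass}")
    if leaf_area <= 0:
        raise ValueError(f"leaf_area: must be > 0, got {leaf_area}")
    return dry_mass / (leaf_area * 1e-4)


def ppi(
    habitat_means: dict[str, float],
    mode: str = "magnitude",
    species: str = "",
    trait: str = "",
) -> PPIResult:
    """Variability index across exactly three microhabitat means.

    magnitude mode (default) takes absolute values before the
    (max - min)/max ratio, which is required for negative-valued traits;
    raw mode applies the formula to the signed means as given.
    """
    if len(habitat_means) != 3:
        raise ValueError(
            f"habitat_means: need exactly 3 microhabitats, got {len(habitat_means)}"
        )
    vals = {h: float(m) for h, m in habitat_means.items()}
    if any(not np.isfinite(v) for v in vals.values()):
        raise ValueError("habitat_means: all means must be finite")
    if mode == "magnitude":
        vals = {h: abs(v) for h, v in vals.items()}
    elif mode != "raw":
        raise ValueError(f"mode: expected 'magnitude' or 'raw', got {mode!r}")
    h_max = max(vals, key=vals.get)
    h_min = min(vals, key=vals.get)
    if vals[h_max] == 0:
        raise ValueError("habitat_means: maximum mean is zero (PPI undefined)")
    return PPIResult(
        species=species,
        trait=trait,
        ppi=(vals[h_max] - vals[h_min]) / vals[h_max],
        habitat_of_max=h_max,
        habitat_of_min=h_min,
    )


def classify_microhabitat(elevation: float) -> str:
    """Karst peak-cluster microhabitat class from elevation (m a.s.l.).

    Valleys lie below 300 m, slopes between 300 and 380 m inclusive,
    hilltops above 380 m.
    """
    if not 0 < elevation < 9000:
        raise ValueError(f"elevation: must be in (0, 9000) m, got {elevation}")
    if elevation < 300:
        return "valley"
    if elevation <= 380:
        return "slope"
    return "hilltop"


def _agg_samples(
    df: pd.DataFrame, value_col: str, trait: str
) -> pd.DataFrame:
    g = (
        df.groupby(["species", "microhabitat"], sort=True)[value_col]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    g["std"] = g["std"].fillna(0.0)
    return pd.DataFrame(
        {
            "species": g["species"],
            "microhabitat": g["microhabitat"],
            "trait": trait,
            "mean": g["mean"],
            "sd": g["std"],
            "n": g["count"].astype(int),
            "units": TRAIT_UNITS[trait],
        }
    )


def _rows_from_fits(df: pd.DataFrame, cols: dict[str, str]) -> pd.DataFrame:
    # one fitted value per group: mean = value, sd = 0, n = group n
    out = []
    for _, row in df.iterrows():
        for col, trait in cols.items():
            if col not in df.columns or pd.isna(row[col]):
                continue
            out.append(
                {
                    "species": row["species"],
                    "microhabitat": row["microhabitat"],
                    "trait": trait,
                    "mean": float(row[col]),
                    "sd": 0.0,
                    "n": int(row.get("n", 1)),
                    "units": TRAIT_UNITS[trait],
                }
            )
    return pd.DataFrame(out)


def summarize(
    pv: pd.DataFrame | None = None,
    vc: pd.DataFrame | None = None,
    anatomy: pd.DataFrame | None = None,
    stomatal: pd.DataFrame | None = None,
    leaf_traits: pd.DataFrame | None = None,
    ks: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join per-stage outputs into one long trait-summary table.

    Inputs are the tidy per-sample / per-group tables the stage runners
    emit (see :mod:`hydrotraits.io`); any subset may be supplied and
    missing stages simply contribute no rows — never silent zeros.
    Columns of the result: species, microhabitat, trait, mean, sd, n,
    units, one row per species x microhabitat x trait.  Duplicate keys in
    a per-group input are an error (they indicate conflicting fits).
    """
    parts: list[pd.DataFrame] = []
    if pv is not None and len(pv):
        parts.append(_agg_samples(pv, "psi_tlp", "psi_tlp"))
    if vc is not None and len(vc):
        _check_unique(vc, "vulnerability fits")
        parts.append(_rows_from_fits(vc, {"psi50": "psi50", "psi12": "psi12"}))
    if anatomy is not None and len(anatomy):
        parts.append(_agg_samples(anatomy, "dh", "dh"))
    if stomatal is not None and len(stomatal):
        _check_unique(stomatal, "regulation fits")
        parts.append(
            _rows_from_fits(
                stomatal,
                {
                    "sigma": "sigma",
                    "hydroscape_area": "hydroscape_area",
                    "hsm12": "hsm12",
                    "hsm50": "hsm50",
                    "psi_min": "psi_min",
                },
            )
        )
    if leaf_traits is not None and len(leaf_traits):
        lt = leaf_traits.copy()
        lt["lma"] = [
            leaf_mass_per_area(m, a)
            for m, a in zip(lt["dry_mass_g"], lt["leaf_area_cm2"])
        ]
        parts.append(_agg_samples(lt, "leaf_area_cm2", "leaf_area"))
        parts.append(_agg_samples(lt, "lma", "lma"))
    if ks is not None and len(ks):
        parts.append(_agg_samples(ks, "ks", "ks"))
    if not parts:
        raise ValueError("summarize: no stage outputs supplied")
    out = pd.concat(parts, ignore_index=True)
    dup = out.duplicated(["species", "microhabitat", "trait"], keep=False)
    if dup.any():
        offenders = out.loc[dup, ["species", "microhabitat", "trait"]]
        raise ValueError(
            "summarize: conflicting duplicate keys:\n"
            + offenders.drop_duplicates().to_string(index=False)
        )
    return out.sort_values(
        ["species", "trait", "microhabitat"], ignore_index=True
    )


def _check_unique(df: pd.DataFrame, what: str) -> None:
    dup = df.duplicated(["species", "microhabitat"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["species", "microhabitat"]].drop_duplicates()
        raise ValueError(
            f"{what}: duplicate species x microhabitat keys:\n"
            + offenders.to_string(index=False)
        )


def ppi_table(
    summary: pd.DataFrame,
    traits: tuple[str, ...] = PPI_TRAITS,
    mode: str = "magnitude",
) -> pd.DataFrame:
    """Compute PPI per species x trait from a long summary table.

    Species x trait combinations lacking all three microhabitat means are
    omitted (not imputed).  Recomputing this table from a written summary
    CSV reproduces it exactly — the index depends only on the means.
    """
    rows = []
    for (species, trait), grp in summary.groupby(["species", "trait"]):
        if trait not in traits:
            continue
        means = dict(zip(grp["microhabitat"], grp["mean"]))
        if len(means) != 3:
            continue
        res = ppi(means, mode=mode, species=species, trait=trait)
        rows.append(
            {
                "species": species,
                "trait": trait,
                "ppi": res.ppi,
                "habitat_of_max": res.habitat_of_max,
                "habitat_of_min": res.habitat_of_min,
            }
        )
    return pd.DataFrame(
        rows, columns=["species", "trait", "ppi", "habitat_of_max", "habitat_of_min"]
    )
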