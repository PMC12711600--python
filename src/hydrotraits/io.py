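"""Tidy CSV schemas for the raw-measurement tables and stage outputs.

All inputs are long-format CSVs keyed by species x microhabitat (plus a
sample/branch/section/individual identifier).  Water potentials are stored
as tensions (<= 0 MPa); ``psi_sign="auto"`` tolerates field sheets that
record positive pressure-chamber readings by negating a column whose
values are all positive.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .anatomy import VesselSet
from .pv import PVCurve
from .stomatal import DrydownSeries
from .vulnerability import BranchRecord, VulnerabilitySeries

__all__ = [
    "read_pv_csv",
    "write_pv_csv",
    "read_vc_csv",
    "write_vc_csv",
    "read_drydown_csv",
    "write_drydown_csv",
    "read_psimin_csv",
    "read_vessels_csv",
    "write_vessels_csv",
    "read_leaf_traits_csv",
    "write_truth_json",
    "read_truth_json",
]


def _apply_psi_sign(col: pd.Series, psi_sign: str, name: str) -> pd.Series:
    if psi_sign == "keep":
        return col
    if psi_sign == "negate":
        return -col
    if psi_sign == "auto":
        # field sheets sometimes record chamber balance pressures (> 0)
        return -col if (col.dropna() > 0).all() and len(col.dropna()) else col
    raise ValueError(
        f"psi_sign: expected 'auto', 'negate' or 'keep', got {psi_sign!r} ({name})"
    )


def read_pv_csv(path: str | Path, psi_sign: str = "auto") -> list[PVCurve]:
    """Read bench-drying observations, one curve per sample_id.

    Columns: sample_id, species, microhabitat, fresh_mass_g, psi_mpa,
    dry_mass_g, leaf_area_cm2 (optional).
    """
    df = pd.read_csv(path)
    df["psi_mpa"] = _apply_psi_sign(df["psi_mpa"], psi_sign, "psi_mpa")
    curves = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        curves.append(
            PVCurve(
                sample_id=str(sample_id),
                species=str(grp["species"].iloc[0]),
                microhabitat=str(grp["microhabitat"].iloc[0]),
                observations=list(
                    zip(grp["fresh_mass_g"].astype(float),
                        grp["psi_mpa"].astype(float))
                ),
                dry_mass=float(grp["dry_mass_g"].iloc[0]),
                leaf_area=(
                    float(grp["leaf_area_cm2"].iloc[0])
                    if "leaf_area_cm2" in grp and pd.notna(grp["leaf_area_cm2"].iloc[0])
                    else None
                ),
            )
        )
    return curves


def write_pv_csv(curves: Iterable[PVCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for fresh, psi in c.observations:
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "species": c.species,
                    "microhabitat": c.microhabitat,
                    "fresh_mass_g": fresh,
                    "psi_mpa": psi,
                    "dry_mass_g": c.dry_mass,
                    "leaf_area_cm2": c.leaf_area if c.leaf_area is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_vc_csv(path: str | Path, psi_sign: str = "auto") -> list[VulnerabilitySeries]:
    """Read branch records, one series per species x microhabitat.

    Columns: species, microhabitat, branch_id, psi_leaf_a_mpa,
    psi_leaf_b_mpa, and either (k_i, k_max) directly or the flow columns
    (jv_kg_s, dp_dl_mpa_m) plus k_max from which Ki is derived.
    """
    df = pd.read_csv(path)
    for col in ("psi_leaf_a_mpa", "psi_leaf_b_mpa"):
        df[col] = _apply_psi_sign(df[col], psi_sign, col)
    if "k_i" not in df.columns:
        if not {"jv_kg_s", "dp_dl_mpa_m"} <= set(df.columns):
            raise ValueError(
                "vc csv: need either k_i or (jv_kg_s, dp_dl_mpa_m) columns"
            )
        df["k_i"] = df["jv_kg_s"] / df["dp_dl_mpa_m"]
    out = []
    for (species, micro), grp in df.groupby(
        ["species", "microhabitat"], sort=True
    ):
        records = [
            BranchRecord(
                branch_id=str(r.branch_id),
                psi_leaf_a=float(r.psi_leaf_a_mpa),
                psi_leaf_b=float(r.psi_leaf_b_mpa),
                k_i=float(r.k_i),
                k_max=float(r.k_max),
            )
            for r in grp.itertuples()
        ]
        out.append(
            VulnerabilitySeries(
                species=str(species), microhabitat=str(micro), records=records
            )
        )
    return out


def write_vc_csv(series: Iterable[VulnerabilitySeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for r in s.records:
            rows.append(
                {
                    "species": s.species,
                    "microhabitat": s.microhabitat,
                    "branch_id": r.branch_id,
                    "psi_leaf_a_mpa": r.psi_leaf_a,
                    "psi_leaf_b_mpa": r.psi_leaf_b,
                    "k_i": r.k_i,
                    "k_max": r.k_max,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_drydown_csv(path: str | Path, psi_sign: str = "auto") -> list[DrydownSeries]:
    """Read paired predawn/midday potentials, one series per group.

    Columns: species, microhabitat, individual_id, date, leaf_replicate,
    psi_pd_mpa, psi_md_mpa.
    """
    df = pd.read_csv(path)
    for col in ("psi_pd_mpa", "psi_md_mpa"):
        df[col] = _apply_psi_sign(df[col], psi_sign, col)
    out = []
    for (species, micro), grp in df.groupby(
        ["species", "microhabitat"], sort=True
    ):
        obs = grp.rename(
            columns={"psi_pd_mpa": "psi_pd", "psi_md_mpa": "psi_md"}
        )[["individual_id", "date", "leaf_replicate", "psi_pd", "psi_md"]]
        out.append(
            DrydownSeries(
                species=str(species), microhabitat=str(micro),
                observations=obs.reset_index(drop=True),
            )
        )
    return out


def write_drydown_csv(series: Iterable[DrydownSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        df = s.observations.copy()
        df.insert(0, "species", s.species)
        df.insert(1, "microhabitat", s.microhabitat)
        frames.append(
            df.rename(columns={"psi_pd": "psi_pd_mpa", "psi_md": "psi_md_mpa"})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_psimin_csv(path: str | Path, psi_sign: str = "auto") -> pd.DataFrame:
    """Seasonal minimum water potentials per individual.

    Columns: species, microhabitat, individual_id, psi_min_mpa.
    Returns the per-individual table; group means are taken downstream.
    """
    df = pd.read_csv(path)
    df["psi_min_mpa"] = _apply_psi_sign(df["psi_min_mpa"], psi_sign, "psi_min_mpa")
    return df


def read_vessels_csv(path: str | Path) -> list[VesselSet]:
    """Read vessel diameters, one set per section.

    Columns: species, microhabitat, section_id, diameter_um.
    """
    df = pd.read_csv(path)
    out = []
    for (species, micro, section), grp in df.groupby(
        ["species", "microhabitat", "section_id"], sort=True
    ):
        out.append(
            VesselSet(
                section_id=str(section), species=str(species),
                microhabitat=str(micro),
                diameters=grp["diameter_um"].to_numpy(dtype=float),
            )
        )
    return out


def write_vessels_csv(sets: Iterable[VesselSet], path: str | Path) -> None:
    rows = []
    for v in sets:
        for d in np.asarray(v.diameters):
            rows.append(
                {
                    "species": v.species,
                    "microhabitat": v.microhabitat,
                    "section_id": v.section_id,
                    "diameter_um": float(d),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_leaf_traits_csv(path: str | Path) -> pd.DataFrame:
    """Leaf trait replicates: species, microhabitat, leaf_id,
    leaf_area_cm2, dry_mass_g."""
    df = pd.read_csv(path)
    required = {"species", "microhabitat", "leaf_area_cm2", "dry_mass_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"leaf traits csv: missing columns {sorted(missing)}")
    return df


def write_truth_json(truth: dict[str, Any], path: str | Path) -> None:
    """Sidecar recording a synthetic run's ground-truth parameters."""
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def read_truth_json(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
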