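"""Species-level aggregation and latitudinal classification of trait reports.

Literature reports arrive one row per report (a species may contribute
several).  Species are the replicates of every downstream analysis, so
reports are collapsed to per-species medians.  Each species is then placed
in one of four latitudinal classes from its median latitude and the span of
its report latitudes relative to the tropics of Cancer/Capricorn (+/-23.5
degrees), and the four classes coarsen to a binary temperate/tropical zone.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "TROPIC_LATITUDE",
    "REPORT_COLUMNS",
    "classify_latitude",
    "aggregate_species",
    "zone_summary",
    "zone_of_class",
]

TROPIC_LATITUDE = 23.5

#: canonical report-table column order
REPORT_COLUMNS = [
    "species",
    "family",
    "latitude",
    "longitude",
    "carapace_length_mm",
    "clutch_size",
    "clutch_frequency_per_yr",
    "age_maturity_yr",
    "adult_survival",
    "bio10_c",
    "bio17_mm",
]

_TRAIT_COLS = [
    "carapace_length_mm",
    "clutch_size",
    "clutch_frequency_per_yr",
    "age_maturity_yr",
    "adult_survival",
    "bio10_c",
    "bio17_mm",
]

LAT_CLASSES = ("Temperate", "Temp-trop", "Trop-temp", "Tropical")


def _tropical(x: float) -> bool:
    return abs(x) <= TROPIC_LATITUDE


def classify_latitude(median_lat: float, lat_min: float, lat_max: float) -> str:
    """Latitudinal class from a species' median latitude and range.

    Tropical if the whole range lies within the tropics, Temperate if wholly
    outside; otherwise the median decides the side: Temp-trop for a
    temperate median with tropical overlap, Trop-temp for a tropical median
    with temperate overlap.
    """
    if not lat_min <= median_lat <= lat_max:
        raise ValueError(
            f"median latitude {median_lat} outside range "
            f"[{lat_min}, {lat_max}]"
        )
    if _tropical(lat_min) and _tropical(lat_max):
        return "Tropical"
    if lat_min > TROPIC_LATITUDE or lat_max < -TROPIC_LATITUDE:
        return "Temperate"
    # Mixed range: the median decides the side.
    return "Trop-temp" if _tropical(median_lat) else "Temp-trop"


def zone_of_class(lat_class: str) -> str:
    """Coarsen the four classes to the binary zone: temperate-median classes
    (Temperate, Temp-trop) are temperate, the rest tropical."""
    if lat_class in ("Temperate", "Temp-trop"):
        return "temperate"
    if lat_class in ("Trop-temp", "Tropical"):
        return "tropical"
    raise ValueError(f"unknown latitudinal class {lat_class!r}")


def aggregate_species(reports: pd.DataFrame) -> pd.DataFrame:
    """Collapse a report table to one row per species.

    Each trait becomes the median over that species' non-missing reports;
    species fecundity is (median clutch size) x (median clutch frequency),
    defined only when both are present.  Latitude yields the median plus the
    min/max over reports, feeding the latitudinal classification.
    """
    if reports.empty:
        raise ValueError("report table is empty")
    bad = reports["species"].isna() | (reports["species"].astype(str) == "")
    bad |= reports["family"].isna() | (reports["family"].astype(str) == "")
    if bad.any():
        raise ValueError("blank species or family names in report table")

    fam_counts = reports.groupby("species")["family"].nunique()
    multi = fam_counts[fam_counts > 1]
    if len(multi):
        raise ValueError(
            "species mapped to more than one family: "
            + ", ".join(multi.index.tolist())
        )

    rows = []
    for sp, grp in reports.groupby("species", sort=True):
        row = {
            "species": sp,
            "family": grp["family"].iloc[0],
            "n_reports": len(grp),
            "median_latitude": grp["latitude"].median(),
            "lat_min": grp["latitude"].min(),
            "lat_max": grp["latitude"].max(),
        }
        for col in _TRAIT_COLS:
            vals = grp[col].dropna()
            row[col] = vals.median() if len(vals) else np.nan
        rows.append(row)
    species = pd.DataFrame(rows)
    species["abs_latitude"] = species["median_latitude"].abs()
    species["fecundity"] = (
        species["clutch_size"] * species["clutch_frequency_per_yr"]
    )
    species["lat_class"] = [
        classify_latitude(m, lo, hi)
        for m, lo, hi in zip(
            species["median_latitude"], species["lat_min"], species["lat_max"]
        )
    ]
    species["zone"] = species["lat_class"].map(zone_of_class)
    return species


_SUMMARY_TRAITS = [
    ("carapace_length_mm", "carapace_length"),
    ("clutch_size", "clutch_size"),
    ("clutch_frequency_per_yr", "clutch_frequency"),
    ("age_maturity_yr", "age_maturity"),
    ("adult_survival", "adult_survival"),
    ("fecundity", "fecundity"),
]


def zone_summary(species: pd.DataFrame) -> pd.DataFrame:
    """Per-class (plus overall) medians with explicit n per trait.

    One row per latitudinal class and an "Overall" row; columns give family
    and species counts, the median latitude of species medians, and for each
    trait its median and the number of species contributing.
    """
    def _summarize(grp: pd.DataFrame, label: str) -> dict:
        row = {
            "lat_class": label,
            "families": grp["family"].nunique(),
            "species": len(grp),
            "median_latitude": grp["median_latitude"].median(),
        }
        for col, name in _SUMMARY_TRAITS:
            vals = grp[col].dropna()
            row[name] = vals.median() if len(vals) else np.nan
            row[f"{name}_n"] = len(vals)
        return row

    rows = []
    for cls in LAT_CLASSES:
        grp = species[species["lat_class"] == cls]
        rows.append(_summarize(grp, cls))
    rows.append(_summarize(species, "Overall"))
    return pd.DataFrame(rows)
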