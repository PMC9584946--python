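"""Per-sample study metadata: harmonisation of heterogeneous raw fields.

Multi-study collections arrive with inconsistent metadata vocabularies.
This module maps raw per-sample fields onto a fixed set of harmonised
categories (study, geographic location, hypervariable region, sample type,
gender, age group, smoking, drinking) with the binning conventions of the
meta-analysis: numeric ages fall into 18-30 / 31-55 / 56+; any e-cigarette
or tobacco use makes a smoker; any alcohol use makes a drinker; locations
outside North America / Europe / China, regions outside V3-V4 / V4 and
swab-collected samples are pooled as "others"; anything missing is
"unknown".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "HOST_CATEGORIES",
    "harmonise_metadata",
    "read_metadata",
    "write_metadata",
    "analysis_samples",
]

CATEGORIES: dict[str, tuple[str, ...]] = {
    "location": ("NorthAmerica", "Europe", "China", "others"),
    "region": ("V3V4", "V4", "others"),
    "sample_type": ("spit", "mouthwash", "oral_rinse", "others"),
    "gender": ("male", "female", "unknown"),
    "age_group": ("18-30", "31-55", "56+", "unknown"),
    "smoking": ("smoker", "non_smoker", "unknown"),
    "drinking": ("drinker", "non_drinker", "unknown"),
}

#: categories describing the host rather than the protocol
HOST_CATEGORIES = ("gender", "age_group", "smoking", "drinking", "location")

_NA_COUNTRIES = {"usa", "united states", "united states of america", "canada", "mexico"}
_EU_COUNTRIES = {
    "uk", "united kingdom", "england", "scotland", "wales", "ireland",
    "germany", "france", "spain", "italy", "netherlands", "belgium",
    "sweden", "norway", "denmark", "finland", "poland", "austria",
    "switzerland", "portugal", "greece", "czech republic", "hungary",
}

_TRUE = {"true", "yes", "y", "1", "t"}
_FALSE = {"false", "no", "n", "0", "f"}


def _norm(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().lower()
    return s if s and s not in {"na", "nan", "none", ""} else None


def _bool(value) -> bool | None:
    s = _norm(value)
    if s is None:
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    return None


def _bin_age(value) -> str:
    s = _norm(value)
    if s is None:
        return "unknown"
    try:
        age = float(s)
    except ValueError:
        return s if s in CATEGORIES["age_group"] else "unknown"
    if age < 18:
        return "unknown"
    if age <= 30:
        return "18-30"
    if age <= 55:
        return "31-55"
    return "56+"


def _bin_location(value) -> str:
    s = _norm(value)
    if s is None:
        return "unknown"
    compact = s.replace(" ", "").replace("_", "")
    if compact in {"northamerica", "na"} or s in _NA_COUNTRIES:
        return "NorthAmerica"
    if compact == "europe" or s in _EU_COUNTRIES:
        return "Europe"
    if s == "china":
        return "China"
    return "others"


def _bin_region(value) -> str:
    s = _norm(value)
    if s is None:
        return "unknown"
    compact = s.replace("-", "").replace("_", "").upper()
    if compact == "V3V4":
        return "V3V4"
    if compact == "V4":
        return "V4"
    return "others"


def _bin_sample_type(value) -> str:
    s = _norm(value)
    if s is None:
        return "unknown"
    compact = s.replace(" ", "_")
    if compact in {"spit", "spitting", "saliva", "whole_saliva"}:
        return "spit"
    if compact in {"mouthwash", "mouth_washing"}:
        return "mouthwash"
    if compact in {"oral_rinse", "rinse", "oral_rinsing"}:
        return "oral_rinse"
    return "others"


def _bin_smoking(row: pd.Series) -> str:
    ecig = _bool(row.get("smokes_ecig"))
    tobacco = _bool(row.get("smokes_tobacco"))
    if ecig or tobacco:
        return "smoker"
    direct = _norm(row.get("smoking"))
    if direct in {"smoker", "yes", "true", "current"}:
        return "smoker"
    if direct in {"non_smoker", "non-smoker", "no", "false", "never"} or (
        ecig is False and tobacco is False
    ):
        return "non_smoker"
    return "unknown"


def _bin_drinking(row: pd.Series) -> str:
    drinks = _bool(row.get("drinks_alcohol"))
    if drinks:
        return "drinker"
    direct = _norm(row.get("drinking"))
    if direct in {"drinker", "yes", "true"}:
        return "drinker"
    if direct in {"non_drinker", "non-drinker", "no", "false", "never"} or drinks is False:
        return "non_drinker"
    return "unknown"


def harmonise_metadata(raw: pd.DataFrame) -> pd.DataFrame:
    """Harmonise a raw per-sample metadata table.

    ``raw`` must carry ``sample_id`` and ``study`` columns; any of
    ``location``/``country``, ``region``, ``sample_type``, ``gender``/``sex``,
    ``age``/``age_group``, ``smoking``/``smokes_ecig``/``smokes_tobacco`` and
    ``drinking``/``drinks_alcohol`` are consumed when present. Returns a
    DataFrame with one row per sample and the harmonised category columns.
    """
    for required in ("sample_id", "study"):
        if required not in raw.columns:
            raise ValueError(f"raw metadata lacks required column {required!r}")
    if raw["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in raw metadata")

    def col(name, alt=None):
        if name in raw.columns:
            return raw[name]
        if alt is not None and alt in raw.columns:
            return raw[alt]
        return pd.Series([None] * len(raw), index=raw.index)

    out = pd.DataFrame(
        {
            "sample_id": raw["sample_id"].astype(str),
            "study": raw["study"].astype(str),
            "location": col("location", "country").map(_bin_location),
            "region": col("region").map(_bin_region),
            "sample_type": col("sample_type", "collection").map(_bin_sample_type),
            "gender": col("gender", "sex").map(
                lambda v: {"m": "male", "male": "male", "f": "female", "female": "female"}.get(
                    _norm(v) or "", "unknown"
                )
            ),
            "age_group": col("age", "age_group").map(_bin_age),
            "smoking": raw.apply(_bin_smoking, axis=1),
            "drinking": raw.apply(_bin_drinking, axis=1),
        }
    )
    return out.reset_index(drop=True)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata TSV lacks sample_id column")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def analysis_samples(meta: pd.DataFrame, category: str) -> pd.DataFrame:
    """Rows usable for analyses of ``category``.

    Samples labelled "unknown" (or, for host categories, "others") in the
    category under analysis are excluded from that analysis only.
    """
    if category not in CATEGORIES and category != "study":
        raise ValueError(f"unknown category {category!r}")
    if category == "study":
        return meta
    drop = {"unknown"}
    if category in ("gender", "age_group", "smoking", "drinking", "location"):
        drop.add("others")
    return meta[~meta[category].isin(drop)]
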