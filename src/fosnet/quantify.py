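"""Marker densities from per-section counts, and percent change from baseline.

A section table is long-format with one row per counted section:
``subject_id, treatment, age, sex, marker, count, area`` where ``count``
is a non-negative integer and ``area`` is the traced area in mm^2.
Densities are the ratio of summed counts to summed area per subject and
marker (cells/mm^2), so unequal section areas are weighted naturally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import MissingBaselineError, SchemaError

SECTION_COLUMNS = ("subject_id", "treatment", "age", "sex", "marker", "count", "area")
_KEY_COLUMNS = ["subject_id", "treatment", "age", "sex", "marker"]


def validate_sections(sections: pd.DataFrame) -> None:
    """Schema checks for a section-count table; raises SchemaError."""
    missing = [c for c in SECTION_COLUMNS if c not in sections.columns]
    if missing:
        raise SchemaError(f"section table missing columns: {missing}")
    if len(sections) == 0:
        raise SchemaError("section table is empty")
    areas = sections["area"].to_numpy(dtype=float)
    if not np.all(np.isfinite(areas)) or np.any(areas <= 0):
        bad = sections.loc[~(np.isfinite(areas) & (areas > 0)), "subject_id"].unique()
        raise SchemaError(f"non-positive or missing section areas for subjects: {list(bad)}")
    counts = sections["count"].to_numpy(dtype=float)
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        bad = sections.loc[(counts < 0) | (counts != np.round(counts)), "subject_id"].unique()
        raise SchemaError(f"counts must be non-negative integers; offending subjects: {list(bad)}")


def compute_density(sections: pd.DataFrame) -> pd.DataFrame:
    """Per-subject marker density: pooled counts over pooled area.

    Returns one row per (subject, marker) with columns ``n_sections``,
    ``total_count``, ``total_area`` and ``density`` (cells/mm^2).

    Raises
    ------
    SchemaError
        On schema violations, including any subject whose total traced
        area is not strictly positive (named in the message).
    """
    validate_sections(sections)
    grouped = sections.groupby(_KEY_COLUMNS, sort=True, as_index=False).agg(
        n_sections=("count", "size"),
        total_count=("count", "sum"),
        total_area=("area", "sum"),
    )
    zero_area = grouped.loc[grouped["total_area"] <= 0, "subject_id"]
    if len(zero_area):
        raise SchemaError(f"zero total traced area for subjects: {list(zero_area.unique())}")
    grouped["density"] = grouped["total_count"] / grouped["total_area"]
    return grouped


def percent_change_from_baseline(densities: pd.DataFrame, baseline_age: int = 4) -> pd.DataFrame:
    """Express each subject's density relative to its stratum baseline.

    The baseline for subject *i* is the mean density of the same-sex,
    same-treatment, same-marker group at ``baseline_age``; the value is
    ``100 * (density_i - baseline_mean) / baseline_mean``.  By
    construction the baseline group itself averages to 0%.

    Raises
    ------
    MissingBaselineError
        If any (marker, treatment, sex) stratum lacks a baseline-age
        group, or a baseline mean is zero.
    """
    required = _KEY_COLUMNS + ["density"]
    missing = [c for c in required if c not in densities.columns]
    if missing:
        raise SchemaError(f"density table missing columns: {missing}")
    strata = ["marker", "treatment", "sex"]
    base = densities.loc[densities["age"] == baseline_age]
    base_means = base.groupby(strata)["density"].mean()

    all_strata = densities[strata].drop_duplicates()
    lacking = [
        tuple(row)
        for row in all_strata.itertuples(index=False)
        if tuple(row) not in base_means.index
    ]
    if lacking:
        raise MissingBaselineError(
            f"no age-{baseline_age} baseline group for strata (marker, treatment, sex): {lacking}"
        )
    zero = [idx for idx, val in base_means.items() if val == 0]
    if zero:
        raise MissingBaselineError(f"baseline mean density is zero for strata: {zero}")

    out = densities.copy()
    means = out[strata].apply(lambda row: base_means[tuple(row)], axis=1)
    out["percent_change"] = 100.0 * (out["density"] - means) / means
    return out
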