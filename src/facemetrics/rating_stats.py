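"""Rater filtering, rating aggregation, and interrater agreement.

The study design: raters aged 18-50, of one of the three target groups
(AVN = Asian Vietnamese, CZVN = Czech Vietnamese, CZE = Czech European),
self-reported heterosexual, each rating only opposite-sex faces on a
1-7 Likert scale with a known-person skip. Interrater agreement is
ICC(3,k): two-way mixed, consistency, average of k raters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from facemetrics.landmark_io import RATER_GROUPS, ValidationError


@dataclass(frozen=True)
class RaterFilter:
    min_age: int = 18
    max_age: int = 50
    allowed_groups: tuple[str, ...] = RATER_GROUPS
    require_heterosexual: bool = True
    opposite_sex_only: bool = True

    def __post_init__(self) -> None:
        if self.min_age > self.max_age:
            raise ValueError("min_age must not exceed max_age")


def filter_raters(
    ratings: pd.DataFrame,
    rater_filter: RaterFilter = RaterFilter(),
    face_sexes: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study's rater exclusion rules.

    Age bounds are inclusive (a 50-year-old is retained; "younger than
    18 and older than 50" are excluded). Orientation filtering applies
    when a ``rater_orientation`` column is present. Opposite-sex
    filtering drops same-sex (rater, face) rows and needs ``face_sexes``
    (specimen_id -> 'male'/'female') unless a ``face_sex`` column exists.

    Returns the filtered table and a per-reason exclusion report counting
    dropped rows.
    """
    df = ratings.copy()
    report: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        report[reason] = int(mask.sum())
        df = df.loc[~mask]

    drop(df["rater_age"] < rater_filter.min_age, "age_below_minimum")
    drop(df["rater_age"] > rater_filter.max_age, "age_above_maximum")
    drop(~df["rater_group"].isin(rater_filter.allowed_groups), "group_not_allowed")
    if rater_filter.require_heterosexual and "rater_orientation" in df.columns:
        drop(df["rater_orientation"] != "heterosexual", "non_heterosexual")
    if rater_filter.opposite_sex_only:
        if "face_sex" not in df.columns:
            if face_sexes is None:
                raise ValidationError(
                    "opposite-sex filtering needs face sexes (face_sex column or face_sexes)"
                )
            df = df.assign(face_sex=df["face_id"].map(pd.Series(face_sexes)))
        if df["face_sex"].isna().any():
            missing = df.loc[df["face_sex"].isna(), "face_id"].unique()[:5]
            raise ValidationError(f"face sex unknown for: {list(missing)}")
        drop(df["rater_sex"] == df["face_sex"], "same_sex_pairing")
    if df.empty:
        raise ValidationError(
            f"no ratings survive the filter {rater_filter}; exclusions: {report}"
        )
    return df.reset_index(drop=True), report


def aggregate(ratings: pd.DataFrame) -> pd.DataFrame:
    """Face-level mean attractiveness per (face_id, rater_group).

    Known-person skips (missing ratings) do not enter the mean. A face
    with no valid rating in a group yields no row for that cell (warned).
    """
    valid = ratings.dropna(subset=["rating"])
    grouped = valid.groupby(["face_id", "rater_group"], observed=True)["rating"]
    out = grouped.agg(mean_rating="mean", n_raters="count", sd_rating="std").reset_index()
    expected = ratings.groupby(["face_id", "rater_group"], observed=True).size()
    missing = set(expected.index) - set(zip(out["face_id"], out["rater_group"]))
    if missing:
        warnings.warn(f"cells with zero valid ratings: {sorted(missing)[:5]}", stacklevel=2)
    return out


def icc3k(matrix: np.ndarray | pd.DataFrame, missing: str = "listwise") -> float:
    """ICC(3,k): two-way mixed, consistency, average-of-raters agreement.

    ``matrix`` is faces x raters. With the two-way ANOVA mean squares
    (faces as rows, raters as columns), ICC(3,k) = (MS_faces - MS_error)
    / MS_faces. Faces with any missing cell are dropped (listwise).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings matrix must be 2-D (faces x raters)")
    if missing == "listwise":
        x = x[~np.isnan(x).any(axis=1)]
    elif np.isnan(x).any():
        raise ValueError("missing cells present; use missing='listwise'")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 complete faces and 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0:
        raise ValueError("no between-face variance; ICC undefined")
    return float((ms_rows - ms_err) / ms_rows)


def icc_by_dataset(ratings: pd.DataFrame, face_sexes: pd.Series | dict) -> pd.DataFrame:
    """ICC(3,k) per (rater_group, stimulus_sex) rater dataset.

    Mirrors reporting agreement separately for every rater sample; the
    faces-x-raters matrix for each dataset uses listwise face deletion.
    """
    df = ratings.copy()
    df["face_sex"] = df["face_id"].map(pd.Series(face_sexes))
    rows = []
    for (group, sex), sub in df.groupby(["rater_group", "face_sex"], observed=True):
        mat = sub.pivot(index="face_id", columns="rater_id", values="rating")
        rows.append(
            {
                "rater_group": group,
                "stimulus_sex": sex,
                "icc3k": icc3k(mat.to_numpy()),
                "n_faces": mat.shape[0],
                "n_raters": mat.shape[1],
            }
        )
    return pd.DataFrame(rows)
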