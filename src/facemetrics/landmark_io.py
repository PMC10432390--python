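"""Reading, writing, and validating landmark and tabular study inputs.

Landmark configurations travel in the TPS digitizing dialect (``LM=``
record headers followed by one ``x y`` coordinate line per point, with
optional ``IMAGE=``, ``ID=`` and ``SCALE=`` fields). Covariates and
ratings travel as delimited text tables.

Coordinates are kept in the digitizer convention (y increases upward).
Downstream Procrustes superimposition removes position, scale, and
orientation, so the image origin convention is immaterial.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RATER_GROUPS = ("AVN", "CZVN", "CZE")


class TPSParseError(ValueError):
    """Malformed TPS record; message names the record and line."""


class ValidationError(ValueError):
    """A table or configuration failed validation."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D landmark configuration.

    ``points`` is an (n_points, 2) float array in digitizing units.
    """

    specimen_id: str
    points: np.ndarray
    sex: str | None = None
    image: str | None = None
    scale_hint: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: points must be (n, 2), got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValidationError(f"specimen {self.specimen_id!r}: non-finite coordinates")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValidationError(f"specimen {self.specimen_id!r}: sex must be male/female")
        # Coincident points break nothing downstream by themselves but
        # usually indicate a digitizing slip: warn, don't fail.
        d = self.points[:, None, :] - self.points[None, :, :]
        same = (np.abs(d).sum(axis=2) == 0) & ~np.eye(len(self.points), dtype=bool)
        if same.any():
            i, j = np.argwhere(same)[0]
            warnings.warn(
                f"specimen {self.specimen_id!r}: points {i} and {j} exactly coincide",
                stacklevel=2,
            )

    @property
    def n_points(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# TPS dialect
# ---------------------------------------------------------------------------


def read_tps(
    path: str | Path, n_points: int | None = 72
) -> list[LandmarkConfiguration]:
    """Parse a TPS landmark file into configurations.

    Each record must declare ``LM=<n>``; when ``n_points`` is given every
    record must carry exactly that many landmarks. ``SCALE=`` is applied
    multiplicatively to the coordinates when present (and kept as
    ``scale_hint``); ``ID=`` and ``IMAGE=`` are captured.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"{path.name}, line {i + 1}: expected 'LM=', got {line!r}")
        record += 1
        try:
            n = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"{path.name}, record {record}, line {i + 1}: bad LM count") from exc
        if n_points is not None and n != n_points:
            raise TPSParseError(
                f"{path.name}, record {record}: LM={n}, expected {n_points}"
            )
        i += 1
        pts = np.empty((n, 2), dtype=float)
        for k in range(n):
            if i >= len(lines):
                raise TPSParseError(f"{path.name}, record {record}: truncated coordinates")
            parts = lines[i].split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"{path.name}, record {record}, line {i + 1}: expected 'x y', got {lines[i]!r}"
                )
            try:
                pts[k, 0] = float(parts[0])
                pts[k, 1] = float(parts[1])
            except ValueError as exc:
                raise TPSParseError(
                    f"{path.name}, record {record}, line {i + 1}: non-numeric coordinate"
                ) from exc
            i += 1
        image = None
        spec_id = None
        scale = None
        while i < len(lines):
            tail = lines[i].strip()
            upper = tail.upper()
            if upper.startswith("IMAGE="):
                image = tail.split("=", 1)[1]
            elif upper.startswith("ID="):
                spec_id = tail.split("=", 1)[1]
            elif upper.startswith("SCALE="):
                try:
                    scale = float(tail.split("=", 1)[1])
                except ValueError as exc:
                    raise TPSParseError(
                        f"{path.name}, record {record}, line {i + 1}: bad SCALE"
                    ) from exc
            else:
                break
            i += 1
        if scale is not None:
            pts = pts * scale
        configs.append(
            LandmarkConfiguration(
                specimen_id=spec_id if spec_id is not None else str(record - 1),
                points=pts,
                image=image,
                scale_hint=scale,
            )
        )
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations in the TPS dialect; round-trips with read_tps.

    SCALE is not re-emitted (coordinates were already rescaled on read).
    """
    out: list[str] = []
    for c in configs:
        out.append(f"LM={c.n_points}")
        for x, y in c.points:
            out.append(f"{x:.17g} {y:.17g}")  # full float64 round-trip precision
        if c.image is not None:
            out.append(f"IMAGE={c.image}")
        out.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

_COV_COLS = ["specimen_id", "sex", "age", "height", "weight"]
_RATING_COLS = [
    "rater_id",
    "rater_group",
    "rater_sex",
    "rater_age",
    "face_id",
    "rating",
]


def load_covariates(path: str | Path) -> pd.DataFrame:
    """Load and validate the per-stimulus covariate table.

    Columns: specimen_id, sex, age (years), height (m), weight (kg).
    """
    df = pd.read_csv(path)
    missing = [c for c in _COV_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"covariate table missing columns: {missing}")
    df = df.copy()
    df["specimen_id"] = df["specimen_id"].astype(str)
    if df["specimen_id"].duplicated().any():
        dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].iloc[0]
        raise ValidationError(f"duplicate specimen_id {dup!r} in covariates")
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise ValidationError(f"unknown sex token(s): {sorted(df.loc[bad_sex, 'sex'].unique())}")
    for col, cond in (("age", df["age"] < 0), ("height", df["height"] <= 0), ("weight", df["weight"] <= 0)):
        if cond.fillna(False).any():
            raise ValidationError(f"covariate {col!r} out of range")
    return df


def load_ratings(path: str | Path) -> pd.DataFrame:
    """Load and validate the long-format rating table.

    ``rating`` must be an integer 1-7 or empty/NA; an NA rating (or a
    truthy ``skip`` column) marks a known-person skip and the row is
    retained with a missing rating. Optional columns ``rater_ethnicity``
    and ``rater_orientation`` are passed through when present.
    """
    df = pd.read_csv(path)
    missing = [c for c in _RATING_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"rating table missing columns: {missing}")
    df = df.copy()
    df["rater_id"] = df["rater_id"].astype(str)
    df["face_id"] = df["face_id"].astype(str)
    bad_group = ~df["rater_group"].isin(RATER_GROUPS)
    if bad_group.any():
        raise ValidationError(
            f"unknown rater_group token(s): {sorted(df.loc[bad_group, 'rater_group'].unique())}"
        )
    if "skip" in df.columns:
        df.loc[df["skip"].astype(bool), "rating"] = np.nan
    df["rating"] = pd.to_numeric(df["rating"], errors="raise")
    present = df["rating"].notna()
    vals = df.loc[present, "rating"]
    if ((vals < 1) | (vals > 7) | (vals != vals.round())).any():
        bad = vals[(vals < 1) | (vals > 7) | (vals != vals.round())].iloc[0]
        raise ValidationError(f"rating {bad} outside the 1-7 Likert scale")
    dup = df.duplicated(subset=["rater_id", "face_id"])
    if dup.any():
        r, f = df.loc[dup, ["rater_id", "face_id"]].iloc[0]
        raise ValidationError(f"duplicate rating for rater {r!r}, face {f!r}")
    return df


def load_tables(
    covariate_path: str | Path, rating_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load both study tables: (covariates, ratings)."""
    return load_covariates(covariate_path), load_ratings(rating_path)
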