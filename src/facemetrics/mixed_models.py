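"""Rating-level linear mixed-effects models with rater-group interactions.

The model: attractiveness rating ~ standardized face predictors (age,
BMI, AVRG, SShD, FA) crossed with rater group (reference AVN), with
correlated random intercept + slopes per rater (nested in group) and a
random intercept per stimulus face. Separate models are fitted for male
and female stimuli. Restricted maximum likelihood, Satterthwaite
denominator df, and single-step (Tukey-style) post hoc contrasts between
rater groups are delegated to R's lmerTest and multcomp packages — the
standard machinery for this model class — through an Rscript subprocess;
this module owns the model specification, data marshalling, and parsing.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from facemetrics.path_analysis import standardize

DEFAULT_PREDICTORS = ("age", "bmi", "avrg", "sshd", "fa")
GROUP_LEVELS = ("AVN", "CZVN", "CZE")


@dataclass(frozen=True)
class LMMSpec:
    """Specification of the rating-level mixed model.

    ``random_slopes=False`` drops the per-rater slopes (random
    intercepts only) — useful for small simulated datasets where the
    full covariance is not estimable.
    """

    response: str = "rating"
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    group_col: str = "rater_group"
    rater_col: str = "rater_id"
    face_col: str = "face_id"
    group_levels: tuple[str, ...] = GROUP_LEVELS
    random_slopes: bool = True
    contrast_terms: tuple[str, ...] = ("group",) + DEFAULT_PREDICTORS

    def __post_init__(self) -> None:
        bad = [t for t in self.contrast_terms if t != "group" and t not in self.predictors]
        if bad:
            raise ValueError(f"contrast terms not in the model: {bad}")


@dataclass
class ContrastResult:
    """Pairwise group contrasts for one term family.

    ``table`` has one row per ordered pair 'A-B' with the estimated
    difference (delta), its SE, and single-step-adjusted / unadjusted p.
    """

    term: str
    table: pd.DataFrame

    def delta(self, a: str, b: str) -> float:
        """Estimate of the (a - b) contrast; antisymmetric in (a, b)."""
        hit = self.table[self.table["pair"] == f"{a}-{b}"]
        if not hit.empty:
            return float(hit["estimate"].iloc[0])
        hit = self.table[self.table["pair"] == f"{b}-{a}"]
        if not hit.empty:
            return -float(hit["estimate"].iloc[0])
        raise KeyError(f"no contrast between {a} and {b}")


@dataclass
class LMMFit:
    """A fitted mixed model: fixed effects, variance components, contrasts."""

    fixed: pd.DataFrame  # term, estimate, se, df, t, p
    random: pd.DataFrame  # grp, var1, var2, vcov, sdcor
    loglik: float
    converged: bool
    singular: bool
    messages: list[str]
    n_obs: int
    spec: LMMSpec
    contrasts: dict[str, ContrastResult] = field(default_factory=dict)

    def coef(self, term: str) -> pd.Series:
        hit = self.fixed[self.fixed["term"] == term]
        if hit.empty:
            raise KeyError(f"no fixed effect {term!r}; have {list(self.fixed['term'])}")
        return hit.iloc[0]


def build_long_table(
    ratings: pd.DataFrame,
    scores: pd.DataFrame,
    stimulus_sex: str | None = None,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
) -> pd.DataFrame:
    """One row per (rater, face) with standardized face-level predictors.

    Skip-flagged (missing) ratings are dropped. Predictors are
    standardized over the rows of the built table.
    """
    sc = scores.copy()
    sc["specimen_id"] = sc["specimen_id"].astype(str)
    if stimulus_sex is not None:
        sc = sc[sc["sex"] == stimulus_sex]
    valid = ratings.dropna(subset=["rating"]).copy()
    valid["face_id"] = valid["face_id"].astype(str)
    merged = valid.merge(
        sc[["specimen_id", *predictors]],
        left_on="face_id",
        right_on="specimen_id",
        how="inner",
        validate="many_to_one",
    ).drop(columns="specimen_id")
    unmatched = set(valid["face_id"]) - set(sc["specimen_id"])
    if stimulus_sex is None and unmatched:
        raise ValueError(f"ratings reference faces without scores: {sorted(unmatched)[:5]}")
    if merged.empty:
        raise ValueError("no (rater, face) rows after joining ratings and scores")
    return standardize(merged, columns=list(predictors))


def _rscript_path() -> str:
    exe = shutil.which("Rscript")
    if exe is None:
        raise RuntimeError("Rscript not found on PATH; mixed-model fitting needs R")
    return exe


def fit_lmm(table: pd.DataFrame, spec: LMMSpec = LMMSpec()) -> LMMFit:
    """Fit the mixed model by REML and compute the post hoc contrasts.

    Groups absent from ``spec.group_levels`` raise; the first level is
    the reference for the treatment-coded group terms (AVN by default,
    the study's standard measure).
    """
    for colname in (spec.response, spec.group_col, spec.rater_col, spec.face_col, *spec.predictors):
        if colname not in table.columns:
            raise ValueError(f"modeling table lacks column {colname!r}")
    seen = set(table[spec.group_col].unique())
    unknown = seen - set(spec.group_levels)
    if unknown:
        raise ValueError(f"groups not in spec.group_levels: {sorted(unknown)}")
    levels = [g for g in spec.group_levels if g in seen]
    if table.groupby(spec.group_col, observed=True)[spec.rater_col].nunique().min() < 2:
        raise ValueError("need at least 2 raters per group")
    if table[spec.face_col].nunique() < 2:
        raise ValueError("need at least 2 faces")

    with tempfile.TemporaryDirectory(prefix="facemetrics_lmm_") as tmp:
        tmpdir = Path(tmp)
        data_csv = tmpdir / "data.csv"
        out_json = tmpdir / "out.json"
        cfg_json = tmpdir / "config.json"
        table.to_csv(data_csv, index=False)
        multi_group = len(levels) > 1
        cfg = {
            "data_csv": str(data_csv),
            "out_json": str(out_json),
            "response": spec.response,
            "predictors": list(spec.predictors),
            "group_col": spec.group_col,
            "rater_col": spec.rater_col,
            "face_col": spec.face_col,
            "group_levels": levels,
            "random_slopes": spec.random_slopes,
            "contrast_terms": list(spec.contrast_terms) if multi_group else [],
        }
        cfg_json.write_text(json.dumps(cfg))
        with resources.as_file(
            resources.files("facemetrics").joinpath("lmm_fit.R")
        ) as rscript:
            proc = subprocess.run(
                [_rscript_path(), str(rscript), str(cfg_json)],
                capture_output=True,
                text=True,
            )
        if proc.returncode != 0 or not out_json.exists():
            raise RuntimeError(
                f"lmer fit failed (exit {proc.returncode}):\n{proc.stderr[-3000:]}"
            )
        out = json.loads(out_json.read_text())

    fixed = pd.DataFrame(out["fixed"])
    random = pd.DataFrame(out["random"])
    messages = out.get("messages", [])
    if isinstance(messages, str):  # jsonlite unboxes a single message
        messages = [messages]
    messages = list(messages)
    raw_contrasts = out.get("contrasts", {})
    if not isinstance(raw_contrasts, dict):  # jsonlite writes an empty list
        raw_contrasts = {}
    contrasts = {
        term: ContrastResult(term=term, table=pd.DataFrame(tab))
        for term, tab in raw_contrasts.items()
    }
    return LMMFit(
        fixed=fixed,
        random=random,
        loglik=float(out["loglik"]),
        converged=not any("failed to converge" in m for m in messages),
        singular=bool(out["singular"]),
        messages=messages,
        n_obs=int(out["n_obs"]),
        spec=spec,
        contrasts=contrasts,
    )


def tukey_contrasts(fit: LMMFit, terms: list[str] | None = None) -> dict[str, ContrastResult]:
    """Pairwise rater-group contrasts (single-step adjusted) per term.

    ``'group'`` compares the group main effects (mean rating shifts);
    a predictor name compares that predictor's slope between groups.
    Contrasts are computed alongside the fit; this accessor validates
    and returns the requested families.
    """
    if terms is None:
        terms = list(fit.spec.contrast_terms)
    out = {}
    for term in terms:
        if term not in fit.contrasts:
            raise KeyError(
                f"term {term!r} has no contrasts in this fit; available: {sorted(fit.contrasts)}"
            )
        out[term] = fit.contrasts[term]
    return out
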