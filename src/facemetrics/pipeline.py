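"""End-to-end study orchestration.

align (per-sex GPA for averageness, pooled GPA for SShD and FA) ->
score faces -> filter raters and aggregate ratings -> ICC per rater
dataset -> six permutation path fits (3 rater groups x 2 stimulus
sexes) -> two mixed models (per stimulus sex) with post hoc contrasts
-> SShD distribution summary. Deterministic given the seed; every
stage logs its n-in/n-out bookkeeping into the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from facemetrics.landmark_io import LandmarkConfiguration, load_tables, read_tps
from facemetrics.mixed_models import LMMFit, LMMSpec, build_long_table, fit_lmm
from facemetrics.path_analysis import (
    PathFit,
    default_path_model,
    fit_path_model,
    permutation_pvalues,
)
from facemetrics.rating_stats import RaterFilter, aggregate, filter_raters, icc_by_dataset
from facemetrics.scheme import LandmarkScheme, default_scheme
from facemetrics.shape_metrics import score_table
from facemetrics.procrustes import gpa
from facemetrics.synthetic_data import SyntheticConfig, generate_cohort, simulate_ratings

logger = logging.getLogger("facemetrics")

_version = "0.1.0"  # kept in sync with the package version


@dataclass
class StudyConfig:
    """Inputs and knobs of a full study run.

    Leave the three input paths as None to run on a synthetic cohort
    generated from ``synthetic`` (seeded by ``seed``).
    """

    tps_path: str | None = None
    covariate_path: str | None = None
    rating_path: str | None = None
    scheme: LandmarkScheme = field(default_factory=default_scheme)
    slide: bool = True
    n_perm: int = 10_000
    seed: int = 0
    fit_mixed_models: bool = True
    lmm_random_slopes: bool = True
    sshd_sign: str = "male"
    synthetic: SyntheticConfig | None = None
    output_dir: str | None = None


@dataclass
class StudyReport:
    scores: pd.DataFrame
    icc: pd.DataFrame
    path_fits: dict[tuple[str, str], PathFit]
    lmm_fits: dict[str, LMMFit]
    contrast_tables: dict[str, pd.DataFrame]
    sshd_summary: pd.DataFrame
    log: dict
    seed: int
    n_perm: int
    version: str = _version


def sshd_distribution_summary(scores: pd.DataFrame, by: str = "sex") -> pd.DataFrame:
    """Median, quartiles, and range of SShD per cohort group."""
    rows = []
    for group, sub in scores.groupby(by, observed=True):
        if sub.empty:
            raise ValueError(f"empty group {group!r}")
        v = sub["sshd"].to_numpy(dtype=float)
        rows.append(
            {
                by: group,
                "n": len(v),
                "median": float(np.median(v)),
                "q1": float(np.quantile(v, 0.25)),
                "q3": float(np.quantile(v, 0.75)),
                "min": float(v.min()),
                "max": float(v.max()),
            }
        )
    return pd.DataFrame(rows)


def _load_inputs(config: StudyConfig):
    if config.tps_path is not None:
        configs = read_tps(config.tps_path, n_points=config.scheme.n_points)
        covariates, ratings = load_tables(config.covariate_path, config.rating_path)
        sex_of = dict(zip(covariates["specimen_id"], covariates["sex"]))
        for c in configs:
            if c.specimen_id not in sex_of:
                raise ValueError(f"specimen {c.specimen_id!r} missing from covariates")
            c.sex = sex_of[c.specimen_id]
        return configs, covariates, ratings
    syn = config.synthetic if config.synthetic is not None else SyntheticConfig(seed=config.seed)
    ss = np.random.SeedSequence(config.seed)
    cohort_seed, rating_seed = (int(s) % (2**31) for s in ss.generate_state(2))
    syn = SyntheticConfig(**{**syn.__dict__, "seed": cohort_seed})
    configs, covariates, truth = generate_cohort(syn, config.scheme)
    return configs, covariates, (truth, rating_seed, syn)


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full analysis and (optionally) write report artifacts."""
    scheme = config.scheme
    log: dict = {"seed": config.seed, "n_perm": config.n_perm, "version": _version}
    configs, covariates, rating_source = _load_inputs(config)
    log["n_faces"] = len(configs)
    log["n_male"] = sum(c.sex == "male" for c in configs)
    log["n_female"] = sum(c.sex == "female" for c in configs)
    logger.info("aligning %d faces (%d male, %d female)", log["n_faces"], log["n_male"], log["n_female"])

    by_sex = {}
    for sex in ("male", "female"):
        subset = [c for c in configs if c.sex == sex]
        if len(subset) < 2:
            raise ValueError(f"fewer than 2 {sex} faces; cannot compute averageness")
        by_sex[sex] = gpa(subset, scheme=scheme, slide=config.slide)
    pooled = gpa(configs, scheme=scheme, slide=config.slide)
    scores = score_table(by_sex, pooled, covariates, scheme, sshd_sign=config.sshd_sign)

    if isinstance(rating_source, tuple):  # synthetic run
        truth, rating_seed, syn = rating_source
        ratings = simulate_ratings(scores, syn.rater_configs, seed=rating_seed, truth=truth)
        log["synthetic"] = True
    else:
        ratings = rating_source
        truth = None
        log["synthetic"] = False

    face_sexes = pd.Series(scores["sex"].values, index=scores["specimen_id"])
    filtered, exclusions = filter_raters(ratings, RaterFilter(), face_sexes=face_sexes)
    log["rating_exclusions"] = exclusions
    log["n_ratings_in"] = len(ratings)
    log["n_ratings_kept"] = len(filtered)

    icc = icc_by_dataset(filtered, face_sexes)
    agg = aggregate(filtered)

    model = default_path_model()
    ss = np.random.SeedSequence([config.seed, 1])
    path_fits: dict[tuple[str, str], PathFit] = {}
    groups = sorted(filtered["rater_group"].unique())
    perm_seeds = iter(int(s) % (2**31) for s in ss.generate_state(2 * len(groups)))
    for group in groups:
        for sex in ("male", "female"):
            face_attr = agg[agg["rater_group"] == group].set_index("face_id")["mean_rating"]
            sub = scores[scores["sex"] == sex].copy()
            sub["attractiveness"] = sub["specimen_id"].map(face_attr)
            sub = sub.dropna(subset=["attractiveness"])
            if len(sub) < 8:
                logger.warning("skipping path fit %s/%s: only %d faces", group, sex, len(sub))
                continue
            fit = fit_path_model(sub, model, rater_group=group, stimulus_sex=sex)
            fit = permutation_pvalues(
                sub, model, n_perm=config.n_perm, seed=next(perm_seeds), fit=fit
            )
            path_fits[(group, sex)] = fit

    lmm_fits: dict[str, LMMFit] = {}
    contrast_tables: dict[str, pd.DataFrame] = {}
    if config.fit_mixed_models:
        spec = LMMSpec(random_slopes=config.lmm_random_slopes)
        for sex in ("male", "female"):
            table = build_long_table(filtered, scores, stimulus_sex=sex)
            fit = fit_lmm(table, spec)
            lmm_fits[sex] = fit
            parts = []
            for term, cres in fit.contrasts.items():
                t = cres.table.copy()
                t.insert(0, "term", term)
                parts.append(t)
            if parts:
                contrast_tables[sex] = pd.concat(parts, ignore_index=True)

    summary = sshd_distribution_summary(scores)
    report = StudyReport(
        scores=scores,
        icc=icc,
        path_fits=path_fits,
        lmm_fits=lmm_fits,
        contrast_tables=contrast_tables,
        sshd_summary=summary,
        log=log,
        seed=config.seed,
        n_perm=config.n_perm,
    )
    if config.output_dir is not None:
        _write_report(report, Path(config.output_dir))
    return report


def _write_report(report: StudyReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": report.seed, "n_perm": report.n_perm, "version": report.version}
    report.scores.to_csv(outdir / "scores.csv", index=False)
    report.icc.assign(**meta).to_csv(outdir / "icc.csv", index=False)
    for (group, sex), fit in report.path_fits.items():
        fit.table.assign(rater_group=group, stimulus_sex=sex, **meta).to_csv(
            outdir / f"path_{group}_{sex}.csv", index=False
        )
    for sex, fit in report.lmm_fits.items():
        payload = {
            "fixed": fit.fixed.to_dict(orient="records"),
            "random": fit.random.to_dict(orient="records"),
            "loglik": fit.loglik,
            "converged": fit.converged,
            "singular": fit.singular,
            "n_obs": fit.n_obs,
            **meta,
        }
        (outdir / f"lmm_{sex}.json").write_text(json.dumps(payload, indent=2))
    for sex, table in report.contrast_tables.items():
        table.assign(**meta).to_csv(outdir / f"contrasts_{sex}.csv", index=False)
    report.sshd_summary.assign(**meta).to_csv(outdir / "sshd_summary.csv", index=False)
    (outdir / "study_log.json").write_text(json.dumps(report.log, indent=2, default=str))
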