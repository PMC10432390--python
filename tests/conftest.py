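import numpy as np
import pandas as pd
import pytest

import facemetrics as fm
from facemetrics.synthetic_data import RaterGroupConfig, SyntheticConfig


@pytest.fixture(scope="session")
def scheme():
    return fm.default_scheme()


@pytest.fixture(scope="session")
def template(scheme):
    return fm.make_template(scheme)


def small_rater_configs(n_male_raters=12, n_female_raters=10):
    return tuple(
        RaterGroupConfig(
            g,
            {"male": n_male_raters, "female": n_female_raters},
            {"male": {"avrg": -0.5}, "female": {"avrg": -0.6, "age": -0.5}},
        )
        for g in ("AVN", "CZVN", "CZE")
    )


@pytest.fixture(scope="session")
def small_cohort(scheme):
    """A small generated cohort with scores and simulated ratings."""
    cfg = SyntheticConfig(
        n_male=22, n_female=14, seed=42, rater_configs=small_rater_configs()
    )
    configs, covariates, truth = fm.generate_cohort(cfg, scheme)
    pooled = fm.gpa(configs, scheme=scheme, slide=False)
    by_sex = {
        sex: fm.gpa([c for c in configs if c.sex == sex], scheme=scheme, slide=False)
        for sex in ("male", "female")
    }
    scores = fm.score_table(by_sex, pooled, covariates, scheme)
    ratings = fm.simulate_ratings(scores, cfg.rater_configs, seed=43, truth=truth)
    return {
        "config": cfg,
        "configs": configs,
        "covariates": covariates,
        "truth": truth,
        "pooled": pooled,
        "by_sex": by_sex,
        "scores": scores,
        "ratings": ratings,
    }


def random_shape(rng, k=72, spread=1.0):
    return rng.normal(scale=spread, size=(k, 2))


def grid_search_distance(a, b, step_deg=0.001):
    """Independent oracle: best root-summed-square distance between unit-size
    centered shapes over a dense grid of rotations of b."""
    a = a - a.mean(axis=0)
    a = a / np.sqrt((a**2).sum())
    b = b - b.mean(axis=0)
    b = b / np.sqrt((b**2).sum())
    theta = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    # ||a - R b||^2 = 2 - 2 (cos t * dot + sin t * cross)
    dot = float((a * b).sum())
    cross = float((a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]).sum())
    d2 = 2.0 - 2.0 * (np.cos(theta) * dot - np.sin(theta) * cross)
    return float(np.sqrt(max(d2.min(), 0.0)))


def reference_gpa(shapes, tol=1e-12, max_iter=2000):
    """Independent alternating-least-squares GPA written from the closed-form
    2D rotation angle (atan2 of summed cross/dot products), not the SVD."""
    xs = []
    for s in shapes:
        s = np.asarray(s, float)
        s = s - s.mean(axis=0)
        xs.append(s / np.sqrt((s**2).sum()))
    cons = xs[0].copy()
    for _ in range(max_iter):
        rotated = []
        for s in xs:
            dot = (s * cons).sum()
            cross = (s[:, 0] * cons[:, 1] - s[:, 1] * cons[:, 0]).sum()
            th = np.arctan2(cross, dot)
            r = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
            rotated.append(s @ r)
        xs = rotated
        new = np.mean(xs, axis=0)
        new = new - new.mean(axis=0)
        new = new / np.sqrt((new**2).sum())
        if np.abs(new - cons).max() < tol:
            cons = new
            break
        cons = new
    return np.stack(xs), np.mean(xs, axis=0)


def align_consensus(a, b):
    """Rotate consensus b onto a (for comparisons modulo joint rotation)."""
    return fm.optimal_rotation(b - b.mean(axis=0), a - a.mean(axis=0))
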