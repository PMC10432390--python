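"""Synthetic landmark cohorts, covariates, and simulated raters.

The generator emulates the structure of the photographed study sample
with known ground truth, so every pipeline stage is testable without the
original images:

* a bilaterally symmetric 72-point facial template;
* low-rank symmetric individual shape variation (k basis deformations);
* a fixed symmetric sexual-dimorphism displacement of magnitude ``d``
  (males at +d/2, females at -d/2 along the axis);
* symmetric age- and BMI-linked deformations (age and BMI correlate);
* per-landmark fluctuating-asymmetry noise (the only symmetry breaker);
* along-curve semilandmark jitter (digitizing arbitrariness that
  sliding is meant to remove);
* random rigid motion and scale applied last (what GPA removes);
* three rater groups (AVN, CZVN, CZE) whose latent ratings are linear
  in the standardized shape cues plus rater random intercepts and
  noise, discretized to the 1-7 Likert scale at half-integer cuts,
  with the opposite-sex rating design enforced.

Default sizes match the study: 60 male and 33 female faces, rater
counts per group as published.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from facemetrics.landmark_io import LandmarkConfiguration
from facemetrics.scheme import LandmarkScheme, default_scheme

# ---------------------------------------------------------------------------
# Template geometry (right side + midline; left side mirrored exactly)
# ---------------------------------------------------------------------------

_MIDLINE_XY = {
    "glabella": (0.0, 0.62),
    "pronasale": (0.0, 0.05),
    "labiale_superius": (0.0, -0.28),
    "gnathion": (0.0, -0.85),
}

_PAIR_XY = {
    "endocanthion": (0.15, 0.32),
    "exocanthion": (0.45, 0.34),
    "brow_inner": (0.12, 0.48),
    "brow_outer": (0.50, 0.46),
    "supraorbital": (0.30, 0.62),
    "alare": (0.17, -0.02),
    "cheilion": (0.28, -0.33),
    "zygion": (0.62, 0.18),
    "gonion": (0.52, -0.45),
    "temporal": (0.60, 0.45),
    "forehead_lateral": (0.40, 0.72),
    "mid_mandible": (0.36, -0.66),
    "nostril_base": (0.08, -0.08),
    "upper_lip_lateral": (0.10, -0.24),
    "lower_lip_lateral": (0.14, -0.42),
    "infraorbital": (0.28, 0.20),
}

# Interior semilandmarks per curve, right side, ordered start -> end.
_CURVE_SEMI_XY = [
    [(0.635, 0.39), (0.650, 0.32), (0.645, 0.25)],  # temporal -> zygion
    [(0.630, 0.02), (0.610, -0.14), (0.570, -0.30)],  # zygion -> gonion
    [(0.440, -0.58), (0.300, -0.72), (0.150, -0.81)],  # gonion -> gnathion
    [(0.220, 0.37), (0.300, 0.385), (0.380, 0.37)],  # upper eyelid
    [(0.220, 0.29), (0.300, 0.28), (0.380, 0.295)],  # lower eyelid
    [(0.200, 0.52), (0.300, 0.545), (0.420, 0.51)],  # eyebrow
]


def make_template(scheme: LandmarkScheme | None = None) -> np.ndarray:
    """The symmetric 72x2 template: centered, unit centroid size.

    Bilateral pairs have exactly mirrored x-coordinates and midline
    points sit at x = 0, so the fluctuating-asymmetry score of the
    template is exactly zero. Only the package's default scheme layout
    has template geometry; other schemes must supply their own template.
    """
    scheme = scheme if scheme is not None else default_scheme()
    ref = default_scheme()
    if (
        scheme.bilateral_pairs != ref.bilateral_pairs
        or scheme.midline_indices != ref.midline_indices
    ):
        raise ValueError("make_template only knows the default scheme's geometry")
    pts = np.zeros((72, 2))
    name_of = ref.names
    for i in range(36):
        name = name_of[i]
        if name in _MIDLINE_XY:
            pts[i] = _MIDLINE_XY[name]
        else:
            base, side = name.rsplit("_", 1)
            x, y = _PAIR_XY[base]
            pts[i] = (x, y) if side == "R" else (-x, y)
    for c, semis in enumerate(_CURVE_SEMI_XY):
        for j, (x, y) in enumerate(semis):
            pts[36 + 6 * c + j] = (x, y)
            pts[36 + 6 * c + 3 + j] = (-x, y)
    pts[:, 1] -= pts[:, 1].mean()  # x-mean is 0 by symmetry
    pts /= np.sqrt((pts**2).sum())
    return pts


def _symmetrize(field_arr: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Project a displacement field onto the bilaterally symmetric subspace."""
    out = field_arr.copy()
    mirrored = field_arr.copy()
    mirrored[:, 0] = -mirrored[:, 0]
    relab = mirrored.copy()
    for left, right in scheme.bilateral_pairs:
        relab[left] = mirrored[right]
        relab[right] = mirrored[left]
    out = (field_arr + relab) / 2.0
    for i in scheme.midline_indices:
        out[i, 0] = 0.0
    return out


def _masculinity_field(template: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Deterministic symmetric dimorphism axis: wider jaw and brow ridge
    descent with increasing masculinity, unit Procrustes norm."""
    f = np.zeros_like(template)
    x, y = template[:, 0], template[:, 1]
    lower = y < -0.1
    f[lower, 0] = 0.6 * x[lower]  # widen the mandible region
    brow = (y > 0.35) & (y < 0.65)
    f[brow, 1] = -0.35  # lower the brow
    eyes = (np.abs(y - 0.33) < 0.08) & (np.abs(x) > 0.1)
    f[eyes, 1] -= 0.15 * np.sign(y[eyes] - 0.33 + 1e-9)  # narrow the eyes
    f = _symmetrize(f, scheme)
    return f / np.sqrt((f**2).sum())


@dataclass(frozen=True)
class RaterGroupConfig:
    """One rater group's sample sizes and preference structure.

    ``n_raters[stimulus_sex]`` raters (of the opposite sex) rate every
    face of that stimulus sex. ``weights[stimulus_sex]`` are linear
    preference weights on the standardized cues (age, bmi, avrg, sshd,
    fa); the latent rating is intercept + rater effect + weighted cues +
    Gaussian noise, discretized at half-integer cut points to 1-7.
    """

    name: str
    n_raters: dict[str, int]
    weights: dict[str, dict[str, float]]
    intercept: float = 4.0
    intercept_sd: float = 0.8
    residual_sd: float = 0.9


def _default_rater_configs() -> tuple[RaterGroupConfig, ...]:
    # Rater counts follow the study's samples (upper end of each range).
    male_stim = {"avrg": -0.45, "sshd": -0.35}
    female_stim = {"avrg": -0.60, "age": -0.50}
    return (
        RaterGroupConfig("AVN", {"male": 124, "female": 86}, {"male": dict(male_stim), "female": dict(female_stim)}),
        RaterGroupConfig("CZVN", {"male": 67, "female": 47}, {"male": dict(male_stim), "female": dict(female_stim)}),
        RaterGroupConfig(
            "CZE",
            {"male": 104, "female": 64},
            # Czech European raters weigh averageness more heavily.
            {"male": {"avrg": -0.55, "sshd": -0.30}, "female": {"avrg": -0.70, "age": -0.45}},
        ),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Shape units are Procrustes units (unit-centroid-size space).
    Defaults mirror the photographed sample: 60 men, 33 women, ages
    18-33 / 18-40, a dimorphism separation of 0.04 between sex means,
    and low-rank individual variation an order of magnitude above the
    per-landmark asymmetry noise.
    """

    n_male: int = 60
    n_female: int = 33
    n_basis: int = 8
    basis_sd: float = 0.012  # sd of the leading basis score, decaying by basis_decay
    basis_decay: float = 0.85
    dimorphism: float = 0.04  # ||male mean - female mean|| in shape units
    asymmetry_sd: float = 0.0025  # per-coordinate lateral noise
    semilandmark_jitter_sd: float = 0.004  # along-curve digitizing jitter
    age_effect: float = 0.008  # shape displacement per sd of age
    bmi_effect: float = 0.010  # shape displacement per sd of BMI
    age_bmi_rho: float = 0.35
    male_age: tuple[float, float, float, float] = (21.1, 1.85, 18.0, 33.0)  # mean, sd, lo, hi
    female_age: tuple[float, float, float, float] = (21.8, 4.21, 18.0, 40.0)
    rater_configs: tuple[RaterGroupConfig, ...] = field(default_factory=_default_rater_configs)
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the generating process."""

    template: np.ndarray
    dimorphism_vector: np.ndarray
    dimorphism: float
    basis: np.ndarray  # (k, 72, 2) symmetric fields, unit norm
    basis_scores: np.ndarray  # (n, k)
    asymmetry_noise: np.ndarray  # (n, 72, 2)
    shape_space_coords: np.ndarray  # (n, 72, 2) before rigid motion/scale
    age_bmi_rho: float
    age_z: np.ndarray
    bmi_z: np.ndarray
    rater_weights: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    rater_intercepts: dict[str, np.ndarray] = field(default_factory=dict)


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def generate_cohort(
    config: SyntheticConfig = SyntheticConfig(),
    scheme: LandmarkScheme | None = None,
) -> tuple[list[LandmarkConfiguration], pd.DataFrame, GroundTruth]:
    """Generate landmark configurations, covariates, and ground truth.

    Deterministic given ``config.seed``. Faces are built in shape space
    (template + sex displacement + basis variation + covariate-linked
    deformation + semilandmark jitter + asymmetry noise) and then pushed
    out through a random rigid motion and scale into digitizing units.
    """
    scheme = scheme if scheme is not None else default_scheme()
    rng = np.random.default_rng(config.seed)
    template = make_template(scheme)
    masc = _masculinity_field(template, scheme)

    n = config.n_male + config.n_female
    sexes = ["male"] * config.n_male + ["female"] * config.n_female
    ids = [f"M{i + 1:03d}" for i in range(config.n_male)] + [
        f"F{i + 1:03d}" for i in range(config.n_female)
    ]

    # Symmetric low-rank individual-variation basis, orthonormalized.
    basis = np.empty((config.n_basis, 72, 2))
    flat = np.empty((config.n_basis, 144))
    for k in range(config.n_basis):
        raw = _symmetrize(rng.normal(size=(72, 2)), scheme).reshape(-1)
        for prev in flat[:k]:
            raw -= (raw @ prev) * prev
        raw /= np.linalg.norm(raw)
        flat[k] = raw
        basis[k] = raw.reshape(72, 2)
    sds = config.basis_sd * config.basis_decay ** np.arange(config.n_basis)
    scores = rng.normal(size=(n, config.n_basis)) * sds

    age_dir = _symmetrize(rng.normal(size=(72, 2)), scheme)
    age_dir /= np.linalg.norm(age_dir)
    bmi_dir = _symmetrize(rng.normal(size=(72, 2)), scheme)
    bmi_dir /= np.linalg.norm(bmi_dir)

    # Covariates: age truncated-normal per sex; BMI correlated with age.
    age = np.empty(n)
    m = np.array([s == "male" for s in sexes])
    age[m] = _truncnorm(rng, *config.male_age, m.sum())
    age[~m] = _truncnorm(rng, *config.female_age, (~m).sum())
    age_z = (age - age.mean()) / age.std(ddof=1)
    eps = rng.normal(size=n)
    bmi_z = config.age_bmi_rho * age_z + np.sqrt(1 - config.age_bmi_rho**2) * eps
    bmi = 21.5 + 2.3 * bmi_z
    height = np.where(m, rng.normal(1.68, 0.055, n), rng.normal(1.555, 0.05, n))
    weight = bmi * height**2

    sex_shift = np.where(m, 0.5, -0.5)[:, None, None] * config.dimorphism * masc[None]
    shapes = (
        template[None]
        + sex_shift
        + np.einsum("nk,kij->nij", scores, basis)
        + config.age_effect * age_z[:, None, None] * age_dir[None]
        + config.bmi_effect * bmi_z[:, None, None] * bmi_dir[None]
    )

    # Along-curve semilandmark jitter (what sliding removes).
    if config.semilandmark_jitter_sd > 0:
        for idx in range(n):
            for curve in scheme.semilandmark_curves:
                path = curve.path
                for pos in range(1, len(path) - 1):
                    i = path[pos]
                    t = shapes[idx, path[pos + 1]] - shapes[idx, path[pos - 1]]
                    norm = np.linalg.norm(t)
                    if norm > 0:
                        shapes[idx, i] += rng.normal(0, config.semilandmark_jitter_sd) * t / norm

    asym = rng.normal(0, config.asymmetry_sd, size=(n, 72, 2)) if config.asymmetry_sd > 0 else np.zeros((n, 72, 2))
    shapes = shapes + asym

    # Random rigid motion + scale into digitizing units.
    configs: list[LandmarkConfiguration] = []
    for idx in range(n):
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        scale = rng.uniform(800, 1200)
        shift = rng.uniform(-200, 200, size=2)
        pts = shapes[idx] @ rot.T * scale + shift
        configs.append(LandmarkConfiguration(specimen_id=ids[idx], points=pts, sex=sexes[idx]))

    covariates = pd.DataFrame(
        {
            "specimen_id": ids,
            "sex": sexes,
            "age": np.round(age, 1),
            "height": np.round(height, 3),
            "weight": np.round(weight, 1),
        }
    )
    truth = GroundTruth(
        template=template,
        dimorphism_vector=masc,
        dimorphism=config.dimorphism,
        basis=basis,
        basis_scores=scores,
        asymmetry_noise=asym,
        shape_space_coords=shapes,
        age_bmi_rho=config.age_bmi_rho,
        age_z=age_z,
        bmi_z=bmi_z,
    )
    return configs, covariates, truth


# ---------------------------------------------------------------------------
# Simulated raters
# ---------------------------------------------------------------------------

CUES = ("age", "bmi", "avrg", "sshd", "fa")


def simulate_ratings(
    scores: pd.DataFrame,
    rater_configs: tuple[RaterGroupConfig, ...] | None = None,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Simulate the three rater groups' Likert ratings of the cohort.

    ``scores`` is the score_table output (specimen_id, sex, avrg, sshd,
    fa, age, bmi). Cues are standardized within each stimulus sex (the
    models are fitted separately per stimulus sex). Each rater of the
    opposite sex rates every face of a stimulus sex; the latent rating
    is discretized by rounding to the nearest scale point (half-integer
    cut points), clipped to 1-7.

    When ``truth`` is given, the generating weights and rater
    intercepts are recorded on it.
    """
    rater_configs = rater_configs if rater_configs is not None else _default_rater_configs()
    rng = np.random.default_rng(seed)
    rows = []
    opposite = {"male": "female", "female": "male"}
    for stim_sex in ("male", "female"):
        sub = scores[scores["sex"] == stim_sex]
        if sub.empty:
            continue
        z = {}
        for cue in CUES:
            v = sub[cue].to_numpy(dtype=float)
            sd = v.std(ddof=1)
            z[cue] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        face_ids = sub["specimen_id"].to_numpy()
        for gcfg in rater_configs:
            weights = gcfg.weights.get(stim_sex, {})
            signal = np.zeros(len(sub))
            for cue, w in weights.items():
                signal = signal + w * z[cue]
            n_raters = gcfg.n_raters.get(stim_sex, 0)
            intercepts = gcfg.intercept + rng.normal(0, gcfg.intercept_sd, n_raters)
            if truth is not None:
                truth.rater_weights[(gcfg.name, stim_sex)] = dict(weights)
                truth.rater_intercepts[f"{gcfg.name}_{stim_sex}"] = intercepts
            rater_sex = opposite[stim_sex]
            rater_ages = rng.integers(18, 51, n_raters)
            for r in range(n_raters):
                latent = (
                    intercepts[r]
                    + signal
                    + rng.normal(0, gcfg.residual_sd, len(sub))
                )
                rating = np.clip(np.rint(latent), 1, 7).astype(int)
                rows.append(
                    pd.DataFrame(
                        {
                            "rater_id": f"{gcfg.name}_{rater_sex[0]}{r + 1:04d}",
                            "rater_group": gcfg.name,
                            "rater_sex": rater_sex,
                            "rater_age": rater_ages[r],
                            "rater_ethnicity": gcfg.name,
                            "rater_orientation": "heterosexual",
                            "face_id": face_ids,
                            "rating": rating,
                        }
                    )
                )
    if not rows:
        raise ValueError("no ratings generated (empty scores or zero rater counts)")
    return pd.concat(rows, ignore_index=True)
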