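"""The three facial shape cues — averageness, sexual shape dimorphism,
fluctuating asymmetry — plus BMI, scored per face.

* Averageness (AVRG): Procrustes distance between a face and its
  sex-specific consensus; higher = more distinctive (less average).
* Sexual shape dimorphism (SShD): signed projection of a face, aligned in
  the pooled two-sex Procrustes space, onto the unit axis connecting the
  female and male mean shapes. By default higher = more male-like
  (``sign="male"``); pass ``sign="female"`` for the opposite labelling.
* Fluctuating asymmetry (FA): summed squared distance between a
  configuration and its mirrored, relabelled copy after re-superimposing
  the mirror by translation and rotation only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from facemetrics.procrustes import AlignedSample, optimal_rotation, procrustes_distance
from facemetrics.scheme import LandmarkScheme


def compute_averageness(aligned: AlignedSample) -> pd.Series:
    """Procrustes distance of each face to the sample consensus.

    Run this on a single-sex aligned sample: male and female faces get
    their distances to their own sex's consensus.
    """
    if len(aligned) < 2:
        raise ValueError("averageness needs at least two faces per sex")
    vals = [
        procrustes_distance(c, aligned.consensus) for c in aligned.aligned_coords
    ]
    return pd.Series(vals, index=aligned.specimen_ids, name="avrg")


def compute_sshd(
    pooled: AlignedSample,
    sex_labels: dict[str, str] | pd.Series | None = None,
    sign: str = "male",
) -> pd.Series:
    """Signed projection onto the axis connecting the sex mean shapes.

    ``pooled`` must be a GPA of both sexes together; ``sex_labels`` maps
    specimen_id -> 'male'/'female' (defaults to the sample's own labels).
    Scores are centered on the midpoint of the two means, so a face at
    the male mean scores +||m - f||/2 under ``sign='male'``.
    """
    if sex_labels is None:
        if pooled.sexes is None:
            raise ValueError("sex labels required (not carried by the aligned sample)")
        labels = pd.Series(pooled.sexes, index=pooled.specimen_ids)
    else:
        labels = pd.Series(sex_labels).reindex(pooled.specimen_ids)
    if labels.isna().any():
        raise ValueError("sex label missing for some specimens")
    if sign not in ("male", "female"):
        raise ValueError("sign must be 'male' or 'female'")
    flat = pooled.aligned_coords.reshape(len(pooled), -1)
    male = flat[(labels == "male").to_numpy()]
    female = flat[(labels == "female").to_numpy()]
    if len(male) == 0 or len(female) == 0:
        raise ValueError("both sexes must be present in the pooled sample")
    m = male.mean(axis=0)
    f = female.mean(axis=0)
    axis = m - f
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("male and female mean shapes coincide")
    v = axis / norm
    scores = (flat - (m + f) / 2.0) @ v
    if sign == "female":
        scores = -scores
    return pd.Series(scores, index=pooled.specimen_ids, name="sshd")


def _mirror_relabel(points: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Horizontally invert a configuration and swap bilateral labels."""
    mirrored = points.copy()
    mirrored[:, 0] = -mirrored[:, 0]
    out = mirrored.copy()
    for left, right in scheme.bilateral_pairs:
        out[left] = mirrored[right]
        out[right] = mirrored[left]
    return out


def compute_asymmetry(
    points: np.ndarray, scheme: LandmarkScheme, refit: bool = True
) -> float:
    """Fluctuating-asymmetry score of one configuration.

    The configuration is mirrored (x negated), bilateral labels are
    swapped, and the mirror is superimposed back onto the original by
    translation and rotation (no scaling — mirror and original share
    size by construction). The score is the sum over landmarks of squared
    original-vs-mirror distances; 0 for perfect bilateral symmetry.

    ``refit=False`` skips the rotational re-superimposition (translation
    only), scoring the literal mirrored difference.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) != scheme.n_points:
        raise ValueError(f"expected {scheme.n_points} points, got {len(pts)}")
    mirror = _mirror_relabel(pts, scheme)
    a = pts - pts.mean(axis=0)
    b = mirror - mirror.mean(axis=0)
    if refit:
        b = optimal_rotation(b, a)
    return float(((a - b) ** 2).sum())


def compute_bmi(weight_kg: float, height_m: float):
    """Body mass index: weight (kg) / height (m) squared."""
    weight = np.asarray(weight_kg, dtype=float)
    height = np.asarray(height_m, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be positive")
    out = weight / height**2
    return float(out) if out.ndim == 0 else out


def score_table(
    aligned_by_sex: dict[str, AlignedSample],
    pooled: AlignedSample,
    covariates: pd.DataFrame,
    scheme: LandmarkScheme,
    sshd_sign: str = "male",
) -> pd.DataFrame:
    """Join the three shape cues with age and BMI into one row per face.

    ``aligned_by_sex`` maps 'male'/'female' to that sex's own GPA (for
    averageness); ``pooled`` is the two-sex GPA (for SShD and FA).
    Missing covariates yield missing BMI with a warning rather than an
    error; the face row is retained.
    """
    frames = []
    for sex, sample in aligned_by_sex.items():
        avrg = compute_averageness(sample)
        frames.append(pd.DataFrame({"specimen_id": avrg.index, "sex": sex, "avrg": avrg.values}))
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        return pd.DataFrame(columns=["specimen_id", "sex", "avrg", "sshd", "fa", "age", "bmi"])
    sshd = compute_sshd(pooled, sign=sshd_sign)
    fa = pd.Series(
        [compute_asymmetry(c, scheme) for c in pooled.aligned_coords],
        index=pooled.specimen_ids,
        name="fa",
    )
    out["sshd"] = out["specimen_id"].map(sshd)
    out["fa"] = out["specimen_id"].map(fa)
    if out[["sshd", "fa"]].isna().any().any():
        missing = out.loc[out[["sshd", "fa"]].isna().any(axis=1), "specimen_id"].tolist()
        raise ValueError(f"faces absent from the pooled alignment: {missing}")
    cov = covariates.set_index("specimen_id")
    unknown = [i for i in out["specimen_id"] if i not in cov.index]
    if unknown:
        warnings.warn(f"faces lacking covariates: {unknown}", stacklevel=2)
    out["age"] = out["specimen_id"].map(cov["age"])
    with np.errstate(invalid="ignore", divide="ignore"):
        bmi = cov["weight"] / cov["height"] ** 2
    out["bmi"] = out["specimen_id"].map(bmi)
    if out["bmi"].isna().any():
        warnings.warn("BMI missing for some faces (absent weight or height)", stacklevel=2)
    return out
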