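"""Generalized Procrustes superimposition with sliding semilandmarks.

Shapes are (k, 2) landmark arrays. Superimposition removes translation
(centroid to origin), size (unit centroid size), and orientation (optimal
proper rotation). Semilandmarks may slide along their digitized curves to
minimize thin-plate-spline bending energy against the current consensus,
removing arbitrary along-curve positioning from the shape signal.

The consensus orientation of a GPA solution is defined only up to a joint
rotation of the whole sample; all quantities computed downstream
(Procrustes distances, projections onto inter-mean axes, asymmetry
scores) are invariant to that joint rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from facemetrics.landmark_io import LandmarkConfiguration
from facemetrics.scheme import LandmarkScheme


class DegenerateShapeError(ValueError):
    """Configuration has no usable shape (e.g. all points coincide)."""


@dataclass
class AlignedSample:
    """A Procrustes-superimposed sample.

    aligned_coords: (n, k, 2); each configuration is centered and of unit
    centroid size up to the final rotation. consensus is the coordinate-wise
    mean of aligned_coords.
    """

    specimen_ids: list[str]
    aligned_coords: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    iterations_used: int
    converged: bool
    sexes: list[str] | None = None

    def __len__(self) -> int:
        return len(self.aligned_coords)


def centroid_size(points: np.ndarray) -> float:
    """Root-sum-of-squared distances of the landmarks to their centroid."""
    pts = np.asarray(points, dtype=float)
    return float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum()))


def center_scale(points: np.ndarray) -> np.ndarray:
    """Translate the centroid to the origin and scale to unit centroid size."""
    pts = np.asarray(points, dtype=float)
    pts = pts - pts.mean(axis=0)
    size = np.sqrt((pts**2).sum())
    if size == 0.0 or not np.isfinite(size):
        raise DegenerateShapeError("configuration has zero centroid size")
    return pts / size


def optimal_rotation(points: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate ``points`` to minimize summed squared distance to ``target``.

    Both inputs should be centered (unit size is conventional but not
    required). Reflections are excluded: the returned configuration is
    ``points @ R`` for a proper rotation R.
    """
    a = np.asarray(points, dtype=float)
    b = np.asarray(target, dtype=float)
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, d]) @ vt
    return a @ r


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both are centered and scaled to unit centroid size, ``b`` is rotated
    optimally onto ``a``, and the root-summed-squared point distance is
    returned. Symmetric in its arguments.
    """
    a = center_scale(a)
    b = center_scale(b)
    b = optimal_rotation(b, a)
    return float(np.sqrt(((a - b) ** 2).sum()))


# ---------------------------------------------------------------------------
# Thin-plate spline bending energy
# ---------------------------------------------------------------------------


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy matrix of the thin-plate spline on ``reference``.

    With kernel U(r) = r^2 log r^2 and Q = [1 | x | y], the matrix is the
    upper-left k-by-k block of the inverse of L = [[K, Q], [Q', 0]]. It is
    symmetric, positive semi-definite, and annihilates affine displacement
    fields (its null space is spanned by 1, x, y).
    """
    ref = np.asarray(reference, dtype=float)
    k = len(ref)
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    if np.any((d2 == 0) & ~np.eye(k, dtype=bool)):
        raise DegenerateShapeError("duplicated reference points make the TPS kernel singular")
    with np.errstate(divide="ignore", invalid="ignore"):
        kmat = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    q = np.column_stack([np.ones(k), ref])
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = q
    lmat[k:, :k] = q.T
    try:
        linv = np.linalg.inv(lmat)
    except np.linalg.LinAlgError as exc:
        raise DegenerateShapeError("singular TPS system (collinear reference?)") from exc
    be = linv[:k, :k]
    return (be + be.T) / 2.0


def bending_energy(points: np.ndarray, be: np.ndarray) -> float:
    """Bending energy of the map from the BE matrix's reference to ``points``."""
    pts = np.asarray(points, dtype=float)
    return float(pts[:, 0] @ be @ pts[:, 0] + pts[:, 1] @ be @ pts[:, 1])


# ---------------------------------------------------------------------------
# Semilandmark sliding
# ---------------------------------------------------------------------------


def _curve_tangents(points: np.ndarray, scheme: LandmarkScheme) -> tuple[np.ndarray, list[int]]:
    """Unit tangent (central difference of curve neighbors) per semilandmark.

    Returns (tangents, indices); points with degenerate tangents are
    dropped from the slide with a warning.
    """
    tangents: list[np.ndarray] = []
    indices: list[int] = []
    for curve in scheme.semilandmark_curves:
        path = curve.path
        for pos in range(1, len(path) - 1):
            i = path[pos]
            t = points[path[pos + 1]] - points[path[pos - 1]]
            norm = np.linalg.norm(t)
            if norm < 1e-12:
                warnings.warn(
                    f"degenerate tangent at semilandmark {i}; holding it fixed",
                    stacklevel=3,
                )
                continue
            tangents.append(t / norm)
            indices.append(i)
    return np.array(tangents).reshape(-1, 2), indices


def slide_semilandmarks(
    points: np.ndarray,
    reference: np.ndarray,
    scheme: LandmarkScheme,
    be: np.ndarray | None = None,
) -> np.ndarray:
    """Slide semilandmarks along their curve tangents to minimize bending
    energy of the deformation from ``reference`` to the configuration.

    Each semilandmark moves only along its local tangent (central
    difference of its curve neighbors); fixed landmarks never move. The
    bending energy against the reference never increases (the unslid
    configuration is always a feasible solution).
    """
    pts = np.asarray(points, dtype=float).copy()
    ref = np.asarray(reference, dtype=float)
    if be is None:
        be = bending_energy_matrix(ref)
    tangents, idx = _curve_tangents(pts, scheme)
    if not idx:
        return pts
    s = len(idx)
    k = len(pts)
    tx = np.zeros((k, s))
    ty = np.zeros((k, s))
    for col, (i, t) in enumerate(zip(idx, tangents)):
        tx[i, col] = t[0]
        ty[i, col] = t[1]
    # Displacements relative to the reference; BE annihilates the
    # reference's own coordinates so using raw coordinates is equivalent,
    # but the explicit difference keeps the numbers small.
    dx = pts[:, 0] - ref[:, 0]
    dy = pts[:, 1] - ref[:, 1]
    a = tx.T @ be @ tx + ty.T @ be @ ty
    b = tx.T @ be @ dx + ty.T @ be @ dy
    alpha = np.linalg.lstsq(a, -b, rcond=None)[0]
    slid = pts.copy()
    slid[idx, 0] += tx[idx, :] @ alpha
    slid[idx, 1] += ty[idx, :] @ alpha
    # Exact minimizer can only lower the quadratic; guard against a
    # numerically ill-conditioned solve all the same.
    if bending_energy(slid - ref, be) > bending_energy(pts - ref, be) + 1e-12:
        return pts
    return slid


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------


def _as_arrays(configs) -> tuple[list[str], list[str] | None, np.ndarray]:
    if isinstance(configs[0], LandmarkConfiguration):
        ids = [c.specimen_id for c in configs]
        sexes = [c.sex for c in configs]
        if any(s is None for s in sexes):
            sexes = None
        coords = np.stack([c.points for c in configs])
    else:
        ids = [str(i) for i in range(len(configs))]
        sexes = None
        coords = np.stack([np.asarray(c, dtype=float) for c in configs])
    return ids, sexes, coords


def gpa(
    configs,
    scheme: LandmarkScheme | None = None,
    slide: bool = False,
    tol: float = 1e-10,
    max_iter: int = 100,
    slide_cycles: int = 3,
) -> AlignedSample:
    """Generalized Procrustes analysis of a set of configurations.

    Iteratively rotates every centered, unit-size configuration to the
    running consensus and re-estimates the consensus until it moves less
    than ``tol`` (or ``max_iter`` is hit, which flags ``converged=False``
    rather than raising). With ``slide=True`` (requires a scheme),
    bending-energy sliding against the consensus alternates with
    re-alignment for ``slide_cycles`` cycles.

    ``configs`` may be LandmarkConfiguration objects or (k, 2) arrays.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    ids, sexes, raw = _as_arrays(configs)
    n, k, _ = raw.shape
    if slide and scheme is None:
        raise ValueError("sliding requires a landmark scheme")
    sizes = np.array([centroid_size(c) for c in raw])
    x = np.stack([center_scale(c) for c in raw])

    total_iters = 0
    converged = True

    def _align_pass(x: np.ndarray, consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, bool]:
        nonlocal_iters = 0
        ok = False
        for _ in range(max_iter):
            nonlocal_iters += 1
            x = np.stack([optimal_rotation(c, consensus) for c in x])
            new = center_scale(x.mean(axis=0))
            if np.abs(new - consensus).max() < tol:
                consensus = new
                ok = True
                break
            consensus = new
        return x, consensus, nonlocal_iters, ok

    consensus = x[0].copy()
    x, consensus, iters, ok = _align_pass(x, consensus)
    total_iters += iters
    converged &= ok

    if slide:
        for _ in range(slide_cycles):
            be = bending_energy_matrix(consensus)
            x = np.stack(
                [center_scale(slide_semilandmarks(c, consensus, scheme, be)) for c in x]
            )
            x, consensus, iters, ok = _align_pass(x, consensus)
            total_iters += iters
            converged &= ok

    # Final consensus is the exact mean of the aligned coordinates.
    x = np.stack([optimal_rotation(c, consensus) for c in x])
    consensus = x.mean(axis=0)
    return AlignedSample(
        specimen_ids=ids,
        aligned_coords=x,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations_used=total_iters,
        converged=converged,
        sexes=sexes,
    )
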