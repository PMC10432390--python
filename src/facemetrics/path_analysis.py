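"""Recursive path analysis with Monte-Carlo permutation "robust" p-values.

The model is a directed acyclic system over the standardized face-level
variables age, BMI, FA (asymmetry), AVRG (averageness/distinctiveness),
SShD (sexual shape dimorphism), and attractiveness. For a recursive DAG
the maximum-likelihood coefficients factor into per-equation ordinary
least squares of each endogenous variable on its parents, so each edge
coefficient is a standardized partial regression coefficient.

Robust p-values: the whole fit is repeated on data whose variables have
each been independently row-shuffled (destroying every association), and
each observed |beta| is referred to its own permutation distribution,
two-sided, with the +1 finite-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_VARIABLES = ("age", "bmi", "fa", "avrg", "sshd", "attractiveness")

DEFAULT_EDGES = (
    ("age", "bmi"),
    ("age", "fa"),
    ("age", "avrg"),
    ("age", "sshd"),
    ("age", "attractiveness"),
    ("bmi", "fa"),
    ("bmi", "avrg"),
    ("bmi", "sshd"),
    ("bmi", "attractiveness"),
    ("fa", "avrg"),
    ("fa", "sshd"),
    ("fa", "attractiveness"),
    ("avrg", "attractiveness"),
    ("sshd", "attractiveness"),
)


@dataclass(frozen=True)
class PathModel:
    """A recursive (acyclic) path model given as a directed edge list."""

    variables: tuple[str, ...] = DEFAULT_VARIABLES
    edges: tuple[tuple[str, str], ...] = DEFAULT_EDGES

    def __post_init__(self) -> None:
        for src, dst in self.edges:
            if src not in self.variables or dst not in self.variables:
                raise ValueError(f"edge ({src}, {dst}) uses an unknown variable")
        order = {v: i for i, v in enumerate(self.variables)}
        for src, dst in self.edges:
            if order[src] >= order[dst]:
                raise ValueError(
                    f"edge ({src}, {dst}) violates the causal ordering given by `variables`"
                )

    @property
    def parents(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for src, dst in self.edges:
            out.setdefault(dst, []).append(src)
        return out


def default_path_model() -> PathModel:
    """The study's default DAG: age -> everything; BMI, FA, AVRG, SShD as
    mediators; attractiveness the sole sink."""
    return PathModel()


@dataclass
class PathFit:
    """Standardized edge coefficients with asymptotic and permutation p."""

    table: pd.DataFrame  # columns: source, target, beta, p_asymptotic, robust_p
    n: int
    n_permutations: int | None = None
    seed: int | None = None
    rater_group: str | None = None
    stimulus_sex: str | None = None

    def beta(self, src: str, dst: str) -> float:
        row = self.table[(self.table["source"] == src) & (self.table["target"] == dst)]
        if row.empty:
            raise KeyError(f"no edge {src} -> {dst} in the fit")
        return float(row["beta"].iloc[0])


def standardize(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Scale columns to zero mean and unit variance (n-1 denominator)."""
    out = table.copy()
    cols = columns if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    for c in cols:
        sd = out[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {c!r} has zero variance; cannot standardize")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


def _fit_equations(x: np.ndarray, model: PathModel, col: dict[str, int]) -> np.ndarray:
    """Per-equation OLS for every edge; returns betas in model.edges order."""
    betas = np.empty(len(model.edges))
    edge_pos = {e: i for i, e in enumerate(model.edges)}
    for target, parents in model.parents.items():
        design = x[:, [col[p] for p in parents]]
        y = x[:, col[target]]
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        for p, b in zip(parents, coef):
            betas[edge_pos[(p, target)]] = b
    return betas


def fit_path_model(
    data: pd.DataFrame,
    model: PathModel | None = None,
    rater_group: str | None = None,
    stimulus_sex: str | None = None,
) -> PathFit:
    """Fit the recursive path model on (already face-level) data.

    Variables are standardized internally; each endogenous variable is
    regressed on its parents (no intercept is needed after
    standardization). Asymptotic two-sided p-values come from the usual
    per-equation t statistics and are reported for reference — the
    permutation p-values are the primary inference.
    """
    model = model if model is not None else default_path_model()
    missing = [v for v in model.variables if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    z = standardize(data[list(model.variables)])
    x = z.to_numpy()
    n = len(x)
    col = {v: i for i, v in enumerate(model.variables)}
    rows = []
    for target, parents in model.parents.items():
        design = x[:, [col[p] for p in parents]]
        if n < design.shape[1] + 2:
            raise ValueError(f"too few faces ({n}) for equation of {target!r}")
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            cond = np.linalg.cond(design)
            raise ValueError(
                f"rank-deficient design for {target!r} (rank {rank} < {design.shape[1]}, cond {cond:.3g})"
            )
        y = x[:, col[target]]
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        dof = n - design.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = coef / se
        pvals = 2 * stats.t.sf(np.abs(tvals), dof)
        for p, b, pv in zip(parents, coef, pvals):
            rows.append({"source": p, "target": target, "beta": b, "p_asymptotic": pv})
    table = pd.DataFrame(rows)
    # Preserve the model's edge order.
    order = {e: i for i, e in enumerate(model.edges)}
    table["_o"] = [order[(s, t)] for s, t in zip(table["source"], table["target"])]
    table = table.sort_values("_o").drop(columns="_o").reset_index(drop=True)
    return PathFit(table=table, n=n, rater_group=rater_group, stimulus_sex=stimulus_sex)


def permutation_pvalues(
    data: pd.DataFrame,
    model: PathModel | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    scheme: str = "all-columns",
    fit: PathFit | None = None,
) -> PathFit:
    """Monte-Carlo permutation ("robust") p-values for every edge.

    Each permutation independently shuffles the rows of every variable
    (``scheme='all-columns'``, the default reading of "randomised data")
    or only each equation's response (``scheme='response-only'``), refits
    the whole system, and records all coefficients. For each edge,
    robust_p = (1 + #{|beta*| >= |beta_obs|}) / (n_perm + 1), two-sided.
    """
    import warnings

    model = model if model is not None else default_path_model()
    if scheme not in ("all-columns", "response-only"):
        raise ValueError("scheme must be 'all-columns' or 'response-only'")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value resolution", stacklevel=2)
    if fit is None:
        fit = fit_path_model(data, model)
    z = standardize(data[list(model.variables)])
    x = z.to_numpy()
    n, k = x.shape
    col = {v: i for i, v in enumerate(model.variables)}
    obs = np.array([fit.beta(s, t) for s, t in model.edges])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(model.edges), dtype=int)
    for _ in range(n_perm):
        if scheme == "all-columns":
            xp = np.empty_like(x)
            for j in range(k):
                xp[:, j] = x[rng.permutation(n), j]
            betas = _fit_equations(xp, model, col)
        else:
            xp = x
            betas = np.empty(len(model.edges))
            edge_pos = {e: i for i, e in enumerate(model.edges)}
            for target, parents in model.parents.items():
                design = xp[:, [col[p] for p in parents]]
                y = xp[rng.permutation(n), col[target]]
                coef, *_ = np.linalg.lstsq(design, y, rcond=None)
                for p, b in zip(parents, coef):
                    betas[edge_pos[(p, target)]] = b
        exceed += np.abs(betas) >= np.abs(obs)
    robust = (1 + exceed) / (n_perm + 1)
    table = fit.table.copy()
    table["robust_p"] = [
        robust[i] for i, _ in enumerate(model.edges)
    ]
    return PathFit(
        table=table,
        n=n,
        n_permutations=n_perm,
        seed=seed,
        rater_group=fit.rater_group,
        stimulus_sex=fit.stimulus_sex,
    )
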