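"""Statistical kernels: per-child summaries, Poisson/OLS/random-intercept
fits, and pinball-loss quantile regression with participant-clustered
bootstrap inference.

The quantile-regression contract here is deliberately simple and fully
specified: the coefficients are the exact minimiser of the convex pinball
loss sum rho_q(y - X beta) (solved as a linear program), and inference
comes from resampling whole participants with replacement — the natural
scheme when transitions are nested within children.  Point estimates from
other mixed-quantile estimators (e.g. lqmm-style shrinkage) may differ.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sparse
from scipy.optimize import linprog
from scipy.special import ndtr
from scipy.stats import t as t_dist

from .cohort import SearchPath, Task
from .distances import DistanceSeries, count_repetitions


class ConvergenceError(RuntimeError):
    """IRLS or LP failed to converge."""


class DesignError(ValueError):
    """Invalid design matrix (rank deficiency, shape mismatch)."""


@dataclasses.dataclass
class FitResult:
    """Named (coefficient, SE, statistic, p) quadruples for one model fit."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    statistic: dict[str, float]
    p_values: dict[str, float]
    n_obs: int
    model_tag: str
    extra: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = set(self.coefficients)
        for name, d in [
            ("standard_errors", self.standard_errors),
            ("statistic", self.statistic),
            ("p_values", self.p_values),
        ]:
            if set(d) != keys:
                raise ValueError(f"{name} keys do not match coefficients")
        for k, p in self.p_values.items():
            if not (np.isnan(p) or 0.0 <= p <= 1.0):
                raise ValueError(f"p-value for {k} outside [0, 1]: {p}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = [f"model: {self.model_tag}  (n_obs={self.n_obs})"]
        for k in self.coefficients:
            lines.append(
                f"  {k:>16s}  beta={self.coefficients[k]: .6g}  "
                f"se={self.standard_errors[k]:.6g}  "
                f"stat={self.statistic[k]: .4g}  p={self.p_values[k]:.4g}"
            )
        return "\n".join(lines)


@dataclasses.dataclass
class ChildSummary:
    participant_id: str
    task: Task
    n_items: int
    n_unique: int
    mean_distance: float
    sd_distance: float
    immediate_repetitions: int = 0
    distant_repetitions: int = 0

    @property
    def degenerate(self) -> bool:
        return np.isnan(self.mean_distance)


def summarize_child(series: DistanceSeries, path: SearchPath) -> ChildSummary:
    """Per-child production counts and distance moments (sample SD, n-1)."""
    if series.participant_id != path.participant_id or series.task != path.task:
        raise ValueError("series and path refer to different participant/task")
    n_items = len(path.events)
    if path.task is Task.SEMANTIC:
        from .embeddings import normalize_token

        n_unique = len({normalize_token(t) for t in path.tokens})
        immediate, distant = count_repetitions(path)
    else:
        n_unique = n_items
        immediate = distant = 0
    d = series.distances
    mean = float(np.mean(d)) if len(d) else float("nan")
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else float("nan")
    return ChildSummary(
        participant_id=series.participant_id,
        task=series.task,
        n_items=n_items,
        n_unique=n_unique,
        mean_distance=mean,
        sd_distance=sd,
        immediate_repetitions=immediate,
        distant_repetitions=distant,
    )


# ---------------------------------------------------------------------------
# design helpers


def _as_design(design) -> tuple[np.ndarray, list[str]]:
    """Accept a DataFrame or mapping name -> column; return (X, names)."""
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    if isinstance(design, Mapping):
        names = list(design)
        X = np.column_stack([np.asarray(design[k], dtype=float) for k in names])
        return X, names
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[i] for i in piv[rank:]]
        raise DesignError(f"rank-deficient design; collinear columns: {bad}")


def _named(names, beta, se, stat, p) -> tuple[dict, dict, dict, dict]:
    return (
        dict(zip(names, map(float, beta))),
        dict(zip(names, map(float, se))),
        dict(zip(names, map(float, stat))),
        dict(zip(names, map(float, p))),
    )


# ---------------------------------------------------------------------------
# Poisson


def fit_poisson(counts, design, offset=None, max_iter: int = 100, tol: float = 1e-12) -> FitResult:
    """Log-link Poisson MLE by iteratively reweighted least squares.

    Standard errors from the Fisher information at the optimum;
    ``z = beta/SE`` and two-sided normal p-values.  ``offset`` (optional)
    is a log-exposure term added to the linear predictor.
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    X, names = _as_design(design)
    if X.shape[0] != len(y):
        raise DesignError("design and counts have different lengths")
    _check_rank(X, names)
    off = np.zeros(len(y)) if offset is None else np.asarray(offset, dtype=float)

    mu = y + 0.5
    eta = np.log(mu) - off
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = np.exp(X @ beta + off) if np.any(beta) else np.exp(eta + off)
        w = np.sqrt(mu)
        z = (X @ beta if np.any(beta) else eta) + (y - mu) / mu
        new_beta, *_ = np.linalg.lstsq(X * w[:, None], z * w, rcond=None)
        step = np.max(np.abs(new_beta - beta))
        beta = new_beta
        eta = X @ beta
        if np.any(np.abs(eta + off) > 50):
            raise ConvergenceError("Poisson IRLS diverged (separation?)")
        if step < tol * (1.0 + np.max(np.abs(beta))):
            break
    else:
        raise ConvergenceError(f"Poisson IRLS did not converge in {max_iter} iterations")

    mu = np.exp(X @ beta + off)
    fisher = X.T @ (X * mu[:, None])
    cov = np.linalg.inv(fisher)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    p = 2.0 * ndtr(-np.abs(zstat))
    return FitResult(*_named(names, beta, se, zstat, p), n_obs=len(y), model_tag="poisson_irls")


def fit_two_group_poisson(counts, group01) -> FitResult:
    """Closed-form two-group Poisson regression (intercept + binary group).

    With one binary predictor the MLE is saturated: the slope is the log
    rate ratio ``ln(mean_high/mean_low)`` and the Fisher SE is
    ``sqrt(1/sum_low + 1/sum_high)``.  Identical to :func:`fit_poisson`
    on the same data, but O(n).
    """
    y = np.asarray(counts, dtype=float)
    g = np.asarray(group01, dtype=bool)
    s0, s1 = float(y[~g].sum()), float(y[g].sum())
    n0, n1 = int((~g).sum()), int(g.sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both groups must be non-empty")
    if s0 == 0 or s1 == 0:
        # degenerate: MLE on the boundary; flagged, p = 1 by convention
        return FitResult(
            {"intercept": float("nan"), "group": 0.0},
            {"intercept": float("nan"), "group": float("nan")},
            {"intercept": float("nan"), "group": 0.0},
            {"intercept": 1.0, "group": 1.0},
            n_obs=len(y),
            model_tag="poisson_two_group(degenerate)",
            extra={"degenerate": True},
        )
    b0 = np.log(s0 / n0)
    b1 = np.log(s1 / n1) - b0
    se0 = np.sqrt(1.0 / s0)
    se1 = np.sqrt(1.0 / s0 + 1.0 / s1)
    z = np.array([b0 / se0, b1 / se1])
    p = 2.0 * ndtr(-np.abs(z))
    return FitResult(
        *_named(["intercept", "group"], [b0, b1], [se0, se1], z, p),
        n_obs=len(y),
        model_tag="poisson_two_group",
    )


# ---------------------------------------------------------------------------
# OLS and random intercept


def fit_ols(y, design) -> FitResult:
    """Ordinary least squares with classical SEs and t statistics."""
    import statsmodels.api as sm

    yv = np.asarray(y, dtype=float)
    X, names = _as_design(design)
    if X.shape[0] <= X.shape[1]:
        raise DesignError("need n_obs > n_params")
    _check_rank(X, names)
    res = sm.OLS(yv, X).fit()
    return FitResult(
        *_named(names, res.params, res.bse, res.tvalues, res.pvalues),
        n_obs=len(yv),
        model_tag="ols",
        extra={"df_resid": float(res.df_resid), "r_squared": float(res.rsquared)},
    )


def fit_random_intercept(y, x, cluster) -> FitResult:
    """Gaussian random-intercept model fitted by REML (statsmodels MixedLM).

    Fixed effects reported with t statistics on containment degrees of
    freedom ``df = n_obs - n_fixed - n_clusters + 1``.  When the
    between-cluster variance estimate hits the 0 boundary (or no cluster
    has two observations) the fit degrades to OLS with a warning.
    """
    import statsmodels.api as sm

    yv = np.asarray(y, dtype=float)
    xv = np.asarray(x, dtype=float)
    ids = np.asarray(cluster)
    uniq, counts = np.unique(ids, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    design = {"intercept": np.ones_like(yv), "x": xv}
    if counts.max() < 2:
        warnings.warn(
            "all clusters are singletons; random intercept unidentifiable, using OLS",
            stacklevel=2,
        )
        res = fit_ols(yv, design)
        res.model_tag = "random_intercept_reml(degraded=ols)"
        return res

    X, names = _as_design(design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(yv, X, groups=ids)
        fit = model.fit(reml=True)
    var_u = float(np.asarray(fit.cov_re)[0, 0])
    scale = float(fit.scale)
    # variance ratios below 1e-4 are numerically a boundary solution
    if var_u < 1e-4 * max(scale, 1e-300):
        warnings.warn("between-cluster variance at the 0 boundary; using OLS", stacklevel=2)
        res = fit_ols(yv, design)
        res.model_tag = "random_intercept_reml(degraded=ols)"
        return res
    beta = np.asarray(fit.fe_params)
    se = np.asarray(fit.bse_fe)
    df = len(yv) - X.shape[1] - len(uniq) + 1
    tval = beta / se
    p = 2.0 * t_dist.sf(np.abs(tval), df)
    return FitResult(
        *_named(names, beta, se, tval, p),
        n_obs=len(yv),
        model_tag="random_intercept_reml(df=containment)",
        extra={"df": int(df), "var_between": var_u, "var_residual": scale},
    )


# ---------------------------------------------------------------------------
# quantile regression


def pinball_loss(y, X, beta, q: float) -> float:
    """Asymmetric check loss sum_i rho_q(y_i - x_i beta)."""
    r = np.asarray(y, dtype=float) - np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    return float(np.sum(np.where(r >= 0, q * r, (q - 1.0) * r)))


def _solve_pinball(y: np.ndarray, X: np.ndarray, q: float) -> np.ndarray:
    """Exact pinball minimiser via linear programming (HiGHS).

    Solves the dual LP — max y'a subject to X'a = 0, a_i in [q-1, q] —
    whose equality-constraint marginals are (minus) the primal
    coefficients.  Strong duality makes this exact, and the dual has only
    p equality rows, which is much faster than the 2n-variable primal.
    """
    n, p = X.shape
    res = linprog(
        -y,
        A_eq=sparse.csc_matrix(X.T),
        b_eq=np.zeros(p),
        bounds=[(q - 1.0, q)] * n,
        method="highs",
    )
    if not res.success:
        raise ConvergenceError(f"pinball LP failed: {res.message}")
    marginals = getattr(res.eqlin, "marginals", None)
    if marginals is None:  # pragma: no cover - solver corner case
        return _solve_pinball_primal(y, X, q)
    return -np.asarray(marginals, dtype=float)


def _solve_pinball_primal(y: np.ndarray, X: np.ndarray, q: float) -> np.ndarray:
    """Primal LP reformulation; reference implementation and fallback."""
    n, p = X.shape
    c = np.concatenate([np.zeros(p), np.full(n, q), np.full(n, 1.0 - q)])
    eye = sparse.eye(n, format="csc")
    A = sparse.hstack([sparse.csc_matrix(X), eye, -eye], format="csc")
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise ConvergenceError(f"pinball LP failed: {res.message}")
    return res.x[:p]


def fit_quantile(
    y,
    design,
    q: float,
    cluster,
    n_boot: int = 200,
    seed: int | None = None,
) -> FitResult:
    """Quantile regression: exact pinball LP + participant-clustered bootstrap.

    SEs are the bootstrap SD over ``n_boot`` refits on cohorts resampled
    at the cluster (participant) level; p-values from the normal
    approximation ``z = beta / SE``.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile level must be in (0, 1), got {q}")
    yv = np.asarray(y, dtype=float)
    X, names = _as_design(design)
    ids = np.asarray(cluster)
    uniq = np.unique(ids)
    if len(uniq) < 3:
        raise ValueError("need at least 3 clusters for clustered bootstrap inference")
    _check_rank(X, names)
    beta = _solve_pinball(yv, X, q)

    rows_of = {u: np.flatnonzero(ids == u) for u in uniq}
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        take = rng.choice(uniq, size=len(uniq), replace=True)
        rows = np.concatenate([rows_of[u] for u in take])
        boots[b] = _solve_pinball(yv[rows], X[rows], q)
    if n_boot >= 2:
        se = boots.std(axis=0, ddof=1)
    else:
        se = np.full(X.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p = np.where(np.isnan(se), 1.0, 2.0 * ndtr(-np.abs(z)))
    return FitResult(
        *_named(names, beta, se, z, p),
        n_obs=len(yv),
        model_tag=f"quantile_pinball_lp(q={q})",
        extra={"n_boot": int(n_boot), "seed": seed, "n_clusters": int(len(uniq))},
    )
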