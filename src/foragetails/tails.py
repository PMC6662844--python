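"""Distribution-tail group comparison over a quantile sweep.

The hypothesis under test is that one group's transition distances show
an *excess of long jumps* — an inflated upper tail with an unchanged
bulk.  Two complementary detectors are provided:

* **Exceedance-count sweep** (median-split groups): for each level of a
  quantile grid over the pooled distance distribution, count per child
  the distances strictly above the pooled threshold and fit a Poisson
  regression of the counts on group.  Contiguous runs of significant
  levels form clusters whose mass is compared against a resampling null
  of maximum cluster masses — the familywise-error control of
  cluster-based permutation testing.

* **Quantile-regression sweep** (continuous trait): pinball-loss
  quantile regression of raw distances on the trait score at each level,
  with participant-clustered bootstrap inference.

Plus the per-child exploration index (summing a child's own distance
quantiles at the levels the regression sweep flags) and the cross-task
index correlation controlled for the trait score.

Empirical quantiles use linear interpolation (type 7) throughout;
exceedance is strict (> threshold).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .distances import DistanceSeries
from .regression import FitResult, fit_ols, fit_poisson, fit_quantile

DEFAULT_POISSON_LEVELS = np.round(np.arange(50, 100) / 100.0, 2)  # 0.50 .. 0.99
DEFAULT_QUANTREG_LEVELS = np.round(np.arange(10, 20) / 20.0, 2)  # 0.50 .. 0.95


@dataclasses.dataclass
class QuantileSweepResult:
    task: str
    method: str  # quantile_regression | exceedance_poisson
    levels: np.ndarray
    thresholds: np.ndarray
    effects: np.ndarray
    statistics: np.ndarray
    p_values: np.ndarray
    degenerate: np.ndarray
    extra: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        for name in ("thresholds", "effects", "statistics", "p_values", "degenerate"):
            v = np.asarray(getattr(self, name))
            if v.shape != self.levels.shape:
                raise ValueError(f"{name} does not match levels in length")
            setattr(self, name, v)

    def significant_levels(self, alpha: float = 0.05) -> np.ndarray:
        return self.levels[self.p_values < alpha]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "level": self.levels,
                "threshold": self.thresholds,
                "effect": self.effects,
                "statistic": self.statistics,
                "p_value": self.p_values,
                "degenerate": self.degenerate,
            }
        )


@dataclasses.dataclass
class Cluster:
    start_level: float
    end_level: float
    start_idx: int
    end_idx: int
    mass: float


@dataclasses.dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_masses: np.ndarray
    significant: list[bool]
    alpha_cluster: float
    alpha_family: float
    n_resamples: int
    seed: int | None
    resample_scheme: str
    mass_kind: str
    sweep: QuantileSweepResult | None = None

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c, s in zip(self.clusters, self.significant) if s]

    def to_dict(self) -> dict:
        return {
            "clusters": [dataclasses.asdict(c) for c in self.clusters],
            "significant": list(map(bool, self.significant)),
            "alpha_cluster": self.alpha_cluster,
            "alpha_family": self.alpha_family,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "resample_scheme": self.resample_scheme,
            "mass_kind": self.mass_kind,
            "null_mass_quantile": float(
                np.quantile(self.null_masses, 1 - self.alpha_family)
            )
            if len(self.null_masses)
            else float("nan"),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


# ---------------------------------------------------------------------------
# exceedance machinery


def exceedance_counts(
    series: Sequence[DistanceSeries], level: float
) -> tuple[float, np.ndarray]:
    """Pooled type-7 quantile threshold and per-child strict exceedance counts."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    pooled = np.concatenate([s.distances for s in series])
    if len(pooled) == 0:
        raise ValueError("pooled distances are empty")
    threshold = float(np.quantile(pooled, level))
    counts = np.array([int(np.sum(s.distances > threshold)) for s in series])
    return threshold, counts


def _counts_matrix(
    series: Sequence[DistanceSeries], levels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(thresholds, counts) with counts of shape (n_children, n_levels)."""
    pooled = np.concatenate([s.distances for s in series])
    thresholds = np.quantile(pooled, levels)
    counts = np.stack(
        [np.sum(s.distances[:, None] > thresholds[None, :], axis=0) for s in series]
    )
    return thresholds, counts


def _two_group_stats(
    sum_low: np.ndarray, sum_high: np.ndarray, n_low: int, n_high: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised closed-form two-group Poisson slope/z/p (see fit_two_group_poisson)."""
    sum_low = np.asarray(sum_low, dtype=float)
    sum_high = np.asarray(sum_high, dtype=float)
    degenerate = (sum_low == 0) | (sum_high == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.log(sum_high / n_high) - np.log(sum_low / n_low)
        se = np.sqrt(1.0 / sum_low + 1.0 / sum_high)
        z = slope / se
    slope = np.where(degenerate, 0.0, slope)
    z = np.where(degenerate, 0.0, z)
    p = np.where(degenerate, 1.0, 2.0 * ndtr(-np.abs(z)))
    return slope, z, p, degenerate


def _labels01(groups: Sequence[str]) -> np.ndarray:
    lab = np.asarray([str(getattr(g, "value", g)) for g in groups])
    bad = set(lab) - {"low", "high"}
    if bad:
        raise ValueError(f"groups must be 'low' or 'high', got {sorted(bad)}")
    return lab == "high"


def poisson_sweep(
    series: Sequence[DistanceSeries],
    groups: Sequence[str],
    levels: np.ndarray | None = None,
    task: str = "",
) -> QuantileSweepResult:
    """Per-level Poisson regression of exceedance counts on group (high vs low).

    Levels where one group has all-zero counts are flagged degenerate and
    recorded with p = 1 so the cluster machinery keeps a full p-vector.
    """
    levels = DEFAULT_POISSON_LEVELS if levels is None else np.asarray(levels, dtype=float)
    high = _labels01(groups)
    if high.all() or not high.any():
        raise ValueError("both groups must be non-empty")
    thresholds, counts = _counts_matrix(series, levels)
    effects = np.zeros(len(levels))
    stats = np.zeros(len(levels))
    pvals = np.ones(len(levels))
    degen = np.zeros(len(levels), dtype=bool)
    design = {"intercept": np.ones(len(series)), "group": high.astype(float)}
    for j in range(len(levels)):
        c = counts[:, j]
        if c[high].sum() == 0 or c[~high].sum() == 0:
            degen[j] = True
            continue
        fit = fit_poisson(c, design)
        effects[j] = fit.coefficients["group"]
        stats[j] = fit.statistic["group"]
        pvals[j] = fit.p_values["group"]
    return QuantileSweepResult(
        task=task,
        method="exceedance_poisson",
        levels=levels,
        thresholds=thresholds,
        effects=effects,
        statistics=stats,
        p_values=pvals,
        degenerate=degen,
        extra={"n_children": len(series), "n_high": int(high.sum())},
    )


def quantile_regression_sweep(
    series: Sequence[DistanceSeries],
    scores: Sequence[float],
    levels: np.ndarray | None = None,
    n_boot: int = 200,
    seed: int | None = None,
    task: str = "",
) -> QuantileSweepResult:
    """Pinball quantile regression of raw distances on the trait score.

    Every transition carries its child's score; participants are the
    bootstrap clusters.
    """
    levels = DEFAULT_QUANTREG_LEVELS if levels is None else np.asarray(levels, dtype=float)
    y = np.concatenate([s.distances for s in series])
    score_vec = np.concatenate(
        [np.full(len(s), sc, dtype=float) for s, sc in zip(series, scores)]
    )
    ids = np.concatenate([np.full(len(s), i) for i, s in enumerate(series)])
    thresholds = np.quantile(y, levels)
    effects = np.zeros(len(levels))
    stats = np.zeros(len(levels))
    pvals = np.ones(len(levels))
    degen = np.zeros(len(levels), dtype=bool)
    if np.ptp(score_vec) == 0:
        import warnings

        warnings.warn("all trait scores equal; slope undefined at every level", stacklevel=2)
        degen[:] = True
    else:
        design = {"intercept": np.ones_like(y), "score": score_vec}
        child_seeds = np.random.SeedSequence(seed).generate_state(len(levels)) % (2**31)
        for j, q in enumerate(levels):
            fit = fit_quantile(y, design, float(q), ids, n_boot=n_boot, seed=int(child_seeds[j]))
            effects[j] = fit.coefficients["score"]
            stats[j] = fit.statistic["score"]
            pvals[j] = fit.p_values["score"]
    return QuantileSweepResult(
        task=task,
        method="quantile_regression",
        levels=levels,
        thresholds=thresholds,
        effects=effects,
        statistics=stats,
        p_values=pvals,
        degenerate=degen,
        extra={"n_children": len(series), "n_boot": n_boot, "seed": seed},
    )


# ---------------------------------------------------------------------------
# clusters


def form_clusters(
    p_values: np.ndarray,
    levels: np.ndarray,
    alpha_cluster: float = 0.05,
    statistics: np.ndarray | None = None,
    mass: str = "count",
) -> list[Cluster]:
    """Maximal runs of consecutive levels with p < alpha_cluster.

    ``mass='count'`` (default) is the run length; ``mass='sum_z'`` sums
    |z| over the run (requires ``statistics``).
    """
    p = np.asarray(p_values, dtype=float)
    lv = np.asarray(levels, dtype=float)
    if p.shape != lv.shape:
        raise ValueError("p_values and levels must align")
    sig = p < alpha_cluster
    clusters: list[Cluster] = []
    start = None
    for i in range(len(sig) + 1):
        if i < len(sig) and sig[i]:
            if start is None:
                start = i
        elif start is not None:
            end = i - 1
            if mass == "count":
                m = float(end - start + 1)
            elif mass == "sum_z":
                if statistics is None:
                    raise ValueError("mass='sum_z' requires statistics")
                m = float(np.sum(np.abs(statistics[start : end + 1])))
            else:
                raise ValueError(f"unknown mass kind {mass!r}")
            clusters.append(Cluster(float(lv[start]), float(lv[end]), start, end, m))
            start = None
    return clusters


def _max_masses(sig: np.ndarray, absz: np.ndarray | None, mass: str) -> np.ndarray:
    """Per-row maximum cluster mass over a (n_resamples, n_levels) boolean grid."""
    n, L = sig.shape
    best = np.zeros(n)
    cur = np.zeros(n)
    for j in range(L):
        inc = absz[:, j] if mass == "sum_z" else 1.0
        cur = (cur + inc) * sig[:, j]
        best = np.maximum(best, cur)
    return best


def cluster_null_test(
    series: Sequence[DistanceSeries],
    groups: Sequence[str],
    levels: np.ndarray | None = None,
    n_resamples: int = 1000,
    alpha_cluster: float = 0.05,
    alpha_family: float = 0.05,
    seed: int | None = None,
    resample: str = "permutation",
    mass: str = "count",
    task: str = "",
) -> ClusterResult:
    """Cluster-based familywise test of group differences over the sweep.

    Observed clusters come from the exceedance-count Poisson sweep; the
    null distribution of maximum cluster masses is built by resampling at
    the child level:

    * ``permutation`` (default): random reassignment of the low/high
      labels — the exact exchangeable null for a two-group contrast;
    * ``bootstrap``: children resampled with replacement within group and
      the per-level statistics recentred at the observed slopes.

    A cluster is significant iff its mass strictly exceeds the empirical
    ``1 - alpha_family`` quantile of the null maxima.

    Uses the closed-form two-group Poisson MLE per level (identical to
    ``fit_poisson``), vectorised over levels and resamples.
    """
    levels = DEFAULT_POISSON_LEVELS if levels is None else np.asarray(levels, dtype=float)
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    high = _labels01(groups)
    n_children = len(series)
    n_high = int(high.sum())
    n_low = n_children - n_high
    if n_high < 2 or n_low < 2:
        raise ValueError("need at least 2 children per group")

    thresholds, counts = _counts_matrix(series, levels)  # (n_children, n_levels)
    tot = counts.sum(axis=0)

    sum_high = counts[high].sum(axis=0)
    slope, z, p, degen = _two_group_stats(tot - sum_high, sum_high, n_low, n_high)
    sweep = QuantileSweepResult(
        task=task,
        method="exceedance_poisson",
        levels=levels,
        thresholds=thresholds,
        effects=slope,
        statistics=z,
        p_values=p,
        degenerate=degen,
        extra={"n_children": n_children, "n_high": n_high},
    )
    observed = form_clusters(p, levels, alpha_cluster, statistics=z, mass=mass)

    rng = np.random.default_rng(seed)
    if resample == "permutation":
        sum_high_b = np.empty((n_resamples, len(levels)))
        for b in range(n_resamples):
            perm = rng.permutation(n_children)[:n_high]
            sum_high_b[b] = counts[perm].sum(axis=0)
        _, zb, pb, _ = _two_group_stats(tot[None, :] - sum_high_b, sum_high_b, n_low, n_high)
    elif resample == "bootstrap":
        idx_low = np.flatnonzero(~high)
        idx_high = np.flatnonzero(high)
        slopes_b = np.empty((n_resamples, len(levels)))
        ses_b = np.empty((n_resamples, len(levels)))
        for b in range(n_resamples):
            lo = counts[rng.choice(idx_low, n_low, replace=True)].sum(axis=0)
            hi = counts[rng.choice(idx_high, n_high, replace=True)].sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                slopes_b[b] = np.log(hi / n_high) - np.log(lo / n_low)
                ses_b[b] = np.sqrt(1.0 / lo + 1.0 / hi)
        ok = np.isfinite(slopes_b) & np.isfinite(ses_b) & (ses_b > 0)
        zb = np.where(ok, (slopes_b - slope[None, :]) / ses_b, 0.0)  # recentred
        pb = np.where(ok, 2.0 * ndtr(-np.abs(zb)), 1.0)
    else:
        raise ValueError(f"unknown resample scheme {resample!r}")

    sig_b = pb < alpha_cluster
    null_masses = _max_masses(sig_b, np.abs(zb), mass)
    crit = float(np.quantile(null_masses, 1.0 - alpha_family))
    significant = [c.mass > crit for c in observed]
    return ClusterResult(
        clusters=observed,
        null_masses=null_masses,
        significant=significant,
        alpha_cluster=alpha_cluster,
        alpha_family=alpha_family,
        n_resamples=n_resamples,
        seed=seed,
        resample_scheme=resample,
        mass_kind=mass,
        sweep=sweep,
    )


# ---------------------------------------------------------------------------
# exploration index


def exploration_index(
    series: DistanceSeries,
    significant_levels: Sequence[float],
    interpretation: str = "child_quantile",
    thresholds: Sequence[float] | None = None,
) -> float:
    """Per-child exploration index over the regression-significant levels.

    Interpretations:
      * ``child_quantile`` (default): sum of the child's own empirical
        distance quantiles at the significant levels;
      * ``level_sum``: sum of the level values themselves;
      * ``exceedance_count``: sum of the child's counts above the pooled
        ``thresholds`` (one per significant level).
    """
    lv = np.asarray(significant_levels, dtype=float)
    if len(lv) == 0:
        return 0.0
    if len(series.distances) == 0:
        raise ValueError(f"{series.participant_id}: empty distance series")
    if interpretation == "child_quantile":
        return float(np.sum(np.quantile(series.distances, lv)))
    if interpretation == "level_sum":
        return float(np.sum(lv))
    if interpretation == "exceedance_count":
        if thresholds is None or len(thresholds) != len(lv):
            raise ValueError("exceedance_count interpretation needs one threshold per level")
        th = np.asarray(thresholds, dtype=float)
        return float(np.sum(series.distances[:, None] > th[None, :]))
    raise ValueError(f"unknown interpretation {interpretation!r}")


def index_correlation(visual_index, semantic_index, scores) -> FitResult:
    """OLS of the semantic index on the visual index, controlling for the trait."""
    vi = np.asarray(visual_index, dtype=float)
    si = np.asarray(semantic_index, dtype=float)
    sc = np.asarray(scores, dtype=float)
    design = {"intercept": np.ones_like(vi), "visual_index": vi, "score": sc}
    return fit_ols(si, design)
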