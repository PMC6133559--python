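"""ΔNoise / ΔFitness residual analysis.

Expression noise is correlated with median expression, and median
expression dominates fitness, so the effect of noise on fitness is
tested on residuals: ΔNoise is the residual of a LOESS regression of
noise on median expression, ΔFitness the residual of a LOESS regression
of fitness on median expression.  Genotypes are split by distance to
the expression optimum — the expression level at which the fitted
fitness falls a fixed amount (default 0.005) below its maximum — and
the ΔNoise–ΔFitness Pearson correlation is computed separately far from
and close to the optimum.  Group contrasts use permutation tests and
the whole analysis is repeated over a 100-combination grid of smoothing
spans and fitness-drop thresholds to check robustness.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._loess import LoessFit, loess_fit

__all__ = [
    "AnalysisConfig", "DeltaTable", "loess_fit", "delta_metrics",
    "optimum_split", "pearson_test", "permutation_median_test",
    "exhaustive_permutation_p", "classify_noise_groups", "robustness_grid",
    "group_tests",
]

GRID_SPANS = (2 / 6, 3 / 6, 4 / 6, 5 / 6, 1.0)
GRID_DROPS = (0.0025, 0.005, 0.0075, 0.01)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the residual analysis.

    ``span_noise`` / ``span_fitness`` are LOESS smoothing fractions
    (default 2/3), ``fitness_drop`` the drop below maximal predicted
    fitness defining the optimum threshold (default 0.005),
    ``expression_cap`` the upper bound (percent of wild type) above
    which genotypes are excluded (default 125), ``noise_cut`` the
    |ΔNoise| boundary (percentage points) for the low/high groups.
    """

    span_noise: float = 2 / 3
    span_fitness: float = 2 / 3
    fitness_drop: float = 0.005
    expression_cap: float = 125.0
    noise_cut: float = 1.0
    n_permutations: int = 100_000
    noise_metric: str = "strength"
    grid_points: int = 2001
    seed: int = 0


@dataclass
class DeltaTable:
    """Per-genotype residuals and classifications."""

    table: pd.DataFrame  # genotype, median_expression_pct, delta_noise,
    #                      delta_fitness, optimum_class, noise_class
    threshold: float
    noise_fit: LoessFit = field(repr=False, default=None)
    fitness_fit: LoessFit = field(repr=False, default=None)


def delta_metrics(panel: pd.DataFrame, cfg: AnalysisConfig | None = None,
                  ) -> DeltaTable:
    """Compute ΔNoise and ΔFitness for a genotype panel.

    ``panel`` must hold columns ``genotype``, ``median_expression_pct``,
    ``noise_pct`` and ``fitness``.  Genotypes above the expression cap
    are excluded before the LOESS fits (they carry no residuals).
    """
    cfg = cfg or AnalysisConfig()
    required = {"genotype", "median_expression_pct", "noise_pct", "fitness"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing column(s): {sorted(missing)}")
    kept = panel.loc[panel["median_expression_pct"] <= cfg.expression_cap]
    kept = kept.sort_values("median_expression_pct", kind="stable")
    x = kept["median_expression_pct"].to_numpy(dtype=float)
    nfit = loess_fit(x, kept["noise_pct"].to_numpy(dtype=float),
                     span=cfg.span_noise)
    ffit = loess_fit(x, kept["fitness"].to_numpy(dtype=float),
                     span=cfg.span_fitness)
    threshold, classes = optimum_split(ffit, cfg)
    out = pd.DataFrame({
        "genotype": kept["genotype"].to_numpy(),
        "median_expression_pct": x,
        "delta_noise": nfit.residuals,
        "delta_fitness": ffit.residuals,
        "optimum_class": classes,
        "noise_class": classify_noise_groups(nfit.residuals, cfg.noise_cut),
    })
    return DeltaTable(table=out, threshold=threshold,
                      noise_fit=nfit, fitness_fit=ffit)


def optimum_split(fitness_fit: LoessFit, cfg: AnalysisConfig | None = None):
    """Expression threshold for the far/close-to-optimum split.

    The fitted fitness curve is evaluated on a dense grid over the
    observed expression range; the threshold is the lowest expression
    below the curve's maximum at which the prediction first reaches
    (maximum - fitness_drop).  Genotypes below the threshold are
    classed ``far``, the rest ``close``.  If the prediction never drops
    by ``fitness_drop`` below the maximum on the low-expression side,
    all genotypes are ``close`` and a warning is issued.
    """
    cfg = cfg or AnalysisConfig()
    grid = np.linspace(fitness_fit.x.min(), fitness_fit.x.max(),
                       cfg.grid_points)
    pred = fitness_fit.predict(grid)
    imax = int(np.argmax(pred))
    target = pred[imax] - cfg.fitness_drop
    # lowest expression at/left of the optimum reaching the target
    icross = int(np.argmax(pred[:imax + 1] >= target))
    threshold = float(grid[icross])
    if cfg.fitness_drop > 0 and icross == 0 and pred[0] >= target:
        warnings.warn("fitness prediction never drops by fitness_drop "
                      "below the maximum; all genotypes classed close")
    classes = np.where(fitness_fit.x < threshold, "far", "close")
    return threshold, classes


def pearson_test(dx, dy, method: str = "t", n_perm: int = 100_000,
                 seed: int = 0):
    """Pearson correlation between ΔNoise and ΔFitness.

    Returns ``(r, p, r_squared)``.  ``method="t"`` uses the two-sided
    t-distribution with n-2 df; ``method="permutation"`` shuffles dy
    and reports the fraction of shuffles with |r| >= |observed r|.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if dx.size < 3:
        raise ValueError("need at least 3 pairs")
    r, p = stats.pearsonr(dx, dy)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        xc = (dx - dx.mean()) / (dx.std() * math.sqrt(dx.size))
        yc = (dy - dy.mean()) / (dy.std() * math.sqrt(dy.size))
        perms = rng.permuted(np.tile(yc, (n_perm, 1)), axis=1)
        rs = perms @ xc
        p = float(np.mean(np.abs(rs) >= abs(r) - 1e-12))
    return float(r), float(p), float(r * r)


def permutation_median_test(values, group_labels, statistic: str = "median",
                            n_perm: int = 100_000, seed: int = 0) -> float:
    """Two-group permutation test on a difference of medians (or mean/SD).

    Observations are shuffled between the two groups ``n_perm`` times;
    p is the proportion of shuffles whose absolute statistic difference
    is at least the observed absolute difference.  With no exceedances
    the caller should report p < 1/n_perm rather than 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    n1 = int(np.sum(labels == groups[0]))
    if n1 == 0 or n1 == values.size:
        raise ValueError("both groups must be nonempty")
    stat = _STATS[statistic]
    obs = abs(stat(values[labels == groups[0]])
              - stat(values[labels == groups[1]]))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(values, (n_perm, 1)), axis=1)
    diffs = np.abs(stat(perms[:, :n1], axis=1) - stat(perms[:, n1:], axis=1))
    return float(np.mean(diffs >= obs - 1e-12))


def exhaustive_permutation_p(values, group_labels,
                             statistic: str = "median") -> float:
    """Exact permutation p over all label assignments (small n only)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    n1 = int(np.sum(labels == groups[0]))
    n = values.size
    if math.comb(n, n1) > 200_000:
        raise ValueError("too many assignments to enumerate")
    stat = _STATS[statistic]
    obs = abs(stat(values[labels == groups[0]])
              - stat(values[labels == groups[1]]))
    count = total = 0
    idx = np.arange(n)
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        d = abs(stat(values[mask]) - stat(values[~mask]))
        count += d >= obs - 1e-12
        total += 1
    return count / total


_STATS = {
    "median": np.median,
    "mean": np.mean,
    "sd": lambda a, axis=None: np.std(a, ddof=1, axis=axis),
}


def classify_noise_groups(delta_noise, cut: float = 1.0) -> np.ndarray:
    """low (ΔNoise < -cut), high (ΔNoise > +cut), middle otherwise."""
    d = np.asarray(delta_noise, dtype=float)
    return np.select([d < -cut, d > cut], ["low", "high"], default="middle")


def group_tests(delta: DeltaTable, cfg: AnalysisConfig | None = None,
                ) -> pd.DataFrame:
    """Permutation comparisons of the low- vs high-ΔNoise groups.

    Compares median expression, ΔNoise and ΔFitness between genotypes
    with ΔNoise below -cut and above +cut (middle band excluded).
    """
    cfg = cfg or AnalysisConfig()
    t = delta.table
    sub = t.loc[t["noise_class"] != "middle"]
    rows = []
    for col in ("median_expression_pct", "delta_noise", "delta_fitness"):
        p = permutation_median_test(sub[col].to_numpy(),
                                    sub["noise_class"].to_numpy(),
                                    statistic="median",
                                    n_perm=cfg.n_permutations, seed=cfg.seed)
        rows.append({"variable": col, "p": p,
                     "p_report": f"<{1 / cfg.n_permutations:g}" if p == 0
                     else f"{p:g}"})
    return pd.DataFrame(rows)


def robustness_grid(panel: pd.DataFrame, cfg: AnalysisConfig | None = None,
                    spans=GRID_SPANS, drops=GRID_DROPS) -> pd.DataFrame:
    """ΔNoise–ΔFitness correlations over the full parameter grid.

    5 spans for the noise LOESS x 5 spans for the fitness LOESS x 4
    fitness drops = 100 combinations; each row reports the Pearson r
    and t-test p for the far- and close-to-optimum classes.
    """
    cfg = cfg or AnalysisConfig()
    rows = []
    for sn, sf, drop in itertools.product(spans, spans, drops):
        sub_cfg = AnalysisConfig(span_noise=sn, span_fitness=sf,
                                 fitness_drop=drop,
                                 expression_cap=cfg.expression_cap,
                                 noise_cut=cfg.noise_cut,
                                 grid_points=cfg.grid_points)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            delta = delta_metrics(panel, sub_cfg)
        row = {"span_noise": sn, "span_fitness": sf, "fitness_drop": drop,
               "threshold": delta.threshold}
        for cls in ("far", "close"):
            sub = delta.table.loc[delta.table["optimum_class"] == cls]
            if len(sub) >= 3:
                r, p, _ = pearson_test(sub["delta_noise"],
                                       sub["delta_fitness"])
            else:
                r = p = float("nan")
            row[f"r_{cls}"] = r
            row[f"p_{cls}"] = p
            row[f"n_{cls}"] = len(sub)
        rows.append(row)
    return pd.DataFrame(rows)
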