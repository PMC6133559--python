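"""Competitive-fitness estimation from co-culture assays.

Two assay families are covered.  In the *indirect* assays a strain
carrying a YFP reporter competes against a common GFP reference and the
two genotypes are counted by flow cytometry at four timepoints; mixed
YFP-GFP doublets are counted explicitly and singlet-color doublet
counts are inferred from a Hardy-Weinberg-style random-pairing argument
before the counts enter the regression.  In the *direct* assays the two
competitors are distinguished by pyrosequencing allele frequencies.  In
both cases competitive fitness is the exponential of the slope of the
log genotype ratio regressed on generations of growth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cytometry_expression import mad_filter

__all__ = [
    "DoubletCounts", "CellCounts", "CompetitionSeries", "FitnessEstimate",
    "classify_two_color", "doublet_correct", "generations_from_densities",
    "plate_generations", "fitness_from_series", "relative_fitness",
    "direct_fitness", "doubling_time",
]


@dataclass(frozen=True)
class DoubletCounts:
    """Raw event counts: YFP events, GFP events, mixed YFP-GFP doublets."""

    TY: int
    TG: int
    DYG: int

    def __post_init__(self):
        if min(self.TY, self.TG, self.DYG) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class CellCounts:
    """Doublet-corrected cell numbers.

    NY = TY + DY + DYG and NG = TG + DG + DYG, where the unobservable
    same-color doublet counts DY, DG solve DYG = 2*sqrt(DY*DG) (random
    pairing) together with DY/TY = DG/TG (equal doublet proportions).
    """

    NY: float
    NG: float
    DY: float
    DG: float


@dataclass
class CompetitionSeries:
    """Genotype counts (or a frequency trajectory) against generations."""

    generations: np.ndarray
    n_y: np.ndarray
    n_g: np.ndarray
    densities: np.ndarray | None = None
    dilution_factors: np.ndarray | None = None

    def __post_init__(self):
        self.generations = np.asarray(self.generations, dtype=float)
        self.n_y = np.asarray(self.n_y, dtype=float)
        self.n_g = np.asarray(self.n_g, dtype=float)
        if np.any(np.diff(self.generations) < 0):
            raise ValueError("generations must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"generations": self.generations,
                             "n_y": self.n_y, "n_g": self.n_g})


@dataclass
class FitnessEstimate:
    """Competitive fitness (per generation) with a 95% CI."""

    w: float
    ci95: tuple = (float("nan"), float("nan"))
    w_rel: float = float("nan")
    n_replicates: int = 1
    p_value: float = float("nan")
    per_replicate: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# two-color event classification

def classify_two_color(events: pd.DataFrame,
                       bounds: tuple[float, float] = (0.001, 0.999),
                       ) -> DoubletCounts:
    """Split two-color events into YFP, GFP and mixed-doublet counts.

    After removing extreme scatter/fluorescence values, a PCA on
    (log FL1, log FL2) is run; the first component tracks cell size and
    the second separates the fluorophores.  A Gaussian KDE (Silverman
    bandwidth) of the second-component scores shows three modes — GFP
    high, YFP low, mixed doublets intermediate — and events are split
    at the two deepest density minima between the three largest modes.
    If only two modes are found, DYG = 0 is returned with a warning.
    """
    if "fl2" not in events.columns:
        raise ValueError("two fluorescence channels required")
    df = events
    keep = (df["fl1"].to_numpy() > 0) & (df["fl2"].to_numpy() > 0)
    for c in ("fsc_a", "fsc_h"):
        if c in df.columns:
            keep &= df[c].to_numpy() > 0
    df = df.loc[keep]
    logs = np.column_stack([np.log10(df["fl1"]), np.log10(df["fl2"])])
    lo, hi = bounds
    inside = np.ones(len(df), dtype=bool)
    for j in range(2):
        ql, qh = np.quantile(logs[:, j], [lo, hi])
        inside &= (logs[:, j] >= ql) & (logs[:, j] <= qh)
    logs = logs[inside]
    centred = logs - logs.mean(axis=0)
    _, evecs = np.linalg.eigh(np.cov(centred, rowvar=False))
    pc2 = evecs[:, 0]  # smaller-eigenvalue direction separates colors
    scores = centred @ pc2
    # orient so GFP (relatively high FL1, the GFP-sensitive channel) scores high
    if np.corrcoef(scores, centred[:, 0] - centred[:, 1])[0, 1] < 0:
        scores = -scores
    color = logs[:, 0] - logs[:, 1]  # log(FL1/FL2): GFP positive, YFP negative
    cut_lo, cut_hi = _density_cuts(scores)
    if cut_lo is not None:
        ty = int(np.sum(scores < cut_lo))
        tg = int(np.sum(scores > cut_hi))
        return DoubletCounts(TY=ty, TG=tg, DYG=len(scores) - ty - tg)
    warnings.warn("fewer than three density modes; assuming no mixed doublets")
    single_cut = _single_cut(scores)
    if single_cut is None:  # one population: call it by its dominant color
        if float(np.median(color)) > 0:
            return DoubletCounts(TY=0, TG=len(scores), DYG=0)
        return DoubletCounts(TY=len(scores), TG=0, DYG=0)
    left = scores < single_cut
    n_left = int(left.sum())
    if float(np.mean(color[left])) < float(np.mean(color[~left])):
        return DoubletCounts(TY=n_left, TG=len(scores) - n_left, DYG=0)
    return DoubletCounts(TY=len(scores) - n_left, TG=n_left, DYG=0)


def _density_cuts(scores: np.ndarray, grid_size: int = 512):
    """Two deepest KDE minima between the three largest modes."""
    kde = stats.gaussian_kde(scores, bw_method="silverman")
    grid = np.linspace(scores.min(), scores.max(), grid_size)
    dens = kde(grid)
    d = np.diff(dens)
    maxima = np.where((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    minima = np.where((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
    if len(maxima) < 3 or len(minima) < 2:
        return None, None
    top3 = np.sort(maxima[np.argsort(dens[maxima])[-3:]])
    cuts = []
    for a, b in zip(top3[:-1], top3[1:]):
        between = minima[(minima > a) & (minima < b)]
        if len(between) == 0:
            return None, None
        cuts.append(grid[between[np.argmin(dens[between])]])
    return cuts[0], cuts[1]


def _single_cut(scores: np.ndarray, grid_size: int = 512):
    """Deepest KDE minimum between the two largest modes, if bimodal."""
    kde = stats.gaussian_kde(scores, bw_method="silverman")
    grid = np.linspace(scores.min(), scores.max(), grid_size)
    dens = kde(grid)
    d = np.diff(dens)
    maxima = np.where((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    minima = np.where((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
    if len(maxima) < 2 or len(minima) < 1:
        return None
    top2 = np.sort(maxima[np.argsort(dens[maxima])[-2:]])
    between = minima[(minima > top2[0]) & (minima < top2[1])]
    if len(between) == 0:
        return None
    valley = dens[between].min()
    # require a real valley, not a wiggle of a unimodal density
    if valley > 0.7 * dens[top2].min():
        return None
    return float(grid[between[np.argmin(dens[between])]])


def doublet_correct(c: DoubletCounts) -> CellCounts:
    """Infer cell numbers from event counts.

    The random-pairing (Hardy-Weinberg analogy) relation
    DYG = 2*sqrt(DY*DG) combined with equal doublet proportions
    DY/TY = DG/TG has the unique solution
    DY = (DYG/2)*sqrt(TY/TG), DG = (DYG/2)*sqrt(TG/TY).
    """
    if c.DYG > 0 and (c.TY == 0 or c.TG == 0):
        raise ValueError("mixed doublets with a zero singlet class violate "
                         "the random-pairing assumption")
    if c.DYG == 0:
        dy = dg = 0.0
    else:
        dy = c.DYG / 2.0 * math.sqrt(c.TY / c.TG)
        dg = c.DYG / 2.0 * math.sqrt(c.TG / c.TY)
    return CellCounts(NY=c.TY + dy + c.DYG, NG=c.TG + dg + c.DYG, DY=dy, DG=dg)


# ---------------------------------------------------------------------------
# generations and regressions

def generations_from_densities(densities, dilution_factors) -> np.ndarray:
    """Per-cycle generations from densities measured before each dilution.

    For cycle c the culture was diluted by factor f[c] from the density
    d[c-1] it had reached, then grew back to d[c]; generations are
    g[c] = log2(d[c] * f[c] / d[c-1]).
    """
    d = np.asarray(densities, dtype=float)
    f = np.asarray(dilution_factors, dtype=float)
    if np.any(d <= 0):
        raise ValueError("densities must be positive")
    if np.any(f < 1):
        raise ValueError("dilution factors must be at least 1")
    if f.size != d.size - 1:
        raise ValueError("need one dilution factor per growth cycle "
                         "(len(densities) - 1)")
    return np.log2(d[1:] * f / d[:-1])


def plate_generations(per_well_generations) -> np.ndarray:
    """Cumulative generations per timepoint for a 96-well plate.

    ``per_well_generations`` is a (wells x cycles) array of per-cycle
    generation counts; the plate-level value for each cycle is the
    median over wells, and the cumulative sum (prefixed with 0 for the
    first timepoint) is returned.
    """
    g = np.atleast_2d(np.asarray(per_well_generations, dtype=float))
    med = np.median(g, axis=0)
    return np.concatenate([[0.0], np.cumsum(med)])


def fitness_from_series(s: CompetitionSeries) -> FitnessEstimate:
    """OLS slope of ln(NY/NG) on generations; w = exp(slope).

    The 95% CI exponentiates the t-interval of the slope (df = n - 2);
    it is conditional on the observed trajectory and does not account
    for genetic drift between timepoints, so replicate-level intervals
    (see :func:`relative_fitness`) are the ones to report.
    """
    if len(s.generations) < 2:
        raise ValueError("need at least 2 timepoints")
    if np.any(s.n_y <= 0) or np.any(s.n_g <= 0):
        raise ValueError("zero counts at a timepoint")
    y = np.log(s.n_y / s.n_g)
    if len(s.generations) == 2:
        slope = (y[1] - y[0]) / (s.generations[1] - s.generations[0])
        return FitnessEstimate(w=float(np.exp(slope)))
    res = stats.linregress(s.generations, y)
    t = stats.t.ppf(0.975, len(y) - 2)
    ci = (float(np.exp(res.slope - t * res.stderr)),
          float(np.exp(res.slope + t * res.stderr)))
    return FitnessEstimate(w=float(np.exp(res.slope)), ci95=ci)


def relative_fitness(estimates, reference, mad_k: float = 5.0,
                     ) -> FitnessEstimate:
    """Fitness relative to the reference genotype across replicates.

    Replicates deviating from their genotype median by more than
    ``mad_k`` raw MADs are excluded (both sets); each surviving w is
    divided by the mean reference w; the mean, 95% t-CI and a
    one-sample t-test against 1 are reported.
    """
    ws = np.asarray([e.w if isinstance(e, FitnessEstimate) else e
                     for e in estimates], dtype=float)
    ref = np.asarray([e.w if isinstance(e, FitnessEstimate) else e
                      for e in reference], dtype=float)
    if ws.size >= 3:
        ws = ws[mad_filter(ws, mad_k)]
    if ref.size >= 3:
        ref = ref[mad_filter(ref, mad_k)]
    rel = ws / ref.mean()
    n = rel.size
    m = float(rel.mean())
    if n >= 2:
        se = float(rel.std(ddof=1)) / math.sqrt(n)
        t = stats.t.ppf(0.975, n - 1)
        ci = (m - t * se, m + t * se)
        p = float(stats.ttest_1samp(rel, 1.0).pvalue) if se > 0 else (
            0.0 if m != 1.0 else 1.0)
    else:
        ci, p = (float("nan"), float("nan")), float("nan")
    return FitnessEstimate(w=float(ws.mean()), w_rel=m, ci95=ci,
                           n_replicates=n, p_value=p, per_replicate=rel)


def direct_fitness(freqs, generations, peak_heights=None,
                   min_peak: float = 5.0) -> FitnessEstimate:
    """Fitness from allele-frequency trajectories (pairwise assays).

    ``freqs`` are the frequencies fH of the high-noise genotype
    (fH + fL = 1); w = exp(slope of ln(fH/fL) on generations), so
    w > 1 means the high-noise strain grew faster.  Samples whose mean
    pyrogram peak height is below ``min_peak`` are rejected.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("frequencies must lie strictly inside (0, 1)")
    if peak_heights is not None and float(np.mean(peak_heights)) < min_peak:
        raise ValueError(
            f"mean peak height below {min_peak}: sample excluded")
    series = CompetitionSeries(generations=np.asarray(generations, float),
                               n_y=f, n_g=1.0 - f)
    return fitness_from_series(series)


def doubling_time(densities, times) -> float:
    """Minutes per division from log-phase density measurements.

    The inverse of the slope of log2(density) regressed on time; the
    points supplied must belong to the exponential phase.
    """
    d = np.asarray(densities, dtype=float)
    t = np.asarray(times, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 log-phase points")
    slope = stats.linregress(t, np.log2(d)).slope
    if slope <= 0:
        raise ValueError("non-positive growth slope: not exponential growth")
    return 1.0 / slope
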