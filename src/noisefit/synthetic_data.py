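"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the raw data the pipeline consumes — flow
cytometry event tables, serial-dilution competition count trajectories,
and pyrosequencing peak heights — so that every estimator can be tested
round-trip against the truth that produced its input.

Single-cell expression is drawn log-normally (positive support; the
empirical distribution family is not constrained by the data the
pipeline sees) parameterized so that the *median* equals the requested
mean-expression value and the SD equals the requested noise value.
Flow events encode expression through the inverse of the pipeline's own
transformations: a log-normal cell size sets forward scatter, the
fluorescence channel is built so that the size-normalization ratio
recovers the inverse log-log mRNA calibration of the target expression,
and optional additive autofluorescence and doublet events (random
pairing of cells, so the Hardy-Weinberg doublet relations hold in
expectation) complete the picture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .competition_fitness import CompetitionSeries
from .cytometry_expression import MrnaCalibration, WT_CALIBRATION
from .pyroseq_quant import PeakHeights

__all__ = [
    "TRUTH_COLUMNS", "FlowSample", "StudyPanel",
    "gen_flow_events", "gen_two_color_events", "gen_competition_series",
    "gen_pyrogram", "gen_study_panel", "write_truth_tsv",
]

TRUTH_COLUMNS = ["genotype_id", "mu_true", "sigma_true", "w_true",
                 "copies_true", "expr_pct_true", "noise_pct_true",
                 "delta_noise_true"]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _lognormal_sigma_log(mu: float, sigma: float) -> float:
    """Log-scale SD of a log-normal with median mu and SD sigma.

    With ln E ~ N(ln mu, s^2): SD = mu * exp(s^2/2) * sqrt(exp(s^2)-1),
    which solves in closed form via t = exp(s^2) = (1+sqrt(1+4v^2))/2,
    v = sigma/mu.
    """
    if sigma == 0 or mu == 0:
        return 0.0
    v = sigma / mu
    t = (1.0 + math.sqrt(1.0 + 4.0 * v * v)) / 2.0
    return math.sqrt(math.log(t))


def draw_expression(rng: np.random.Generator, mu: float, sigma: float,
                    n: int) -> np.ndarray:
    """Log-normal single-cell expression: median mu, SD sigma."""
    if mu == 0:
        return np.zeros(n)
    s = _lognormal_sigma_log(mu, sigma)
    if s == 0:
        return np.full(n, mu)
    return np.exp(rng.normal(math.log(mu), s, n))


# ---------------------------------------------------------------------------
# flow cytometry events

def gen_flow_events(mu: float, sigma: float, n_events: int = 10_000,
                    seed=0, *, doublet_fraction: float = 0.0,
                    autofluorescence: float = 0.0,
                    cal: MrnaCalibration = WT_CALIBRATION,
                    log_fsc_mean: float = 5.0, log_fsc_sd: float = 0.3,
                    ) -> pd.DataFrame:
    """One sample of single-color flow events encoding expression mu±sigma.

    Per-event forward scatter is log-normal; the fluorescence channel
    is size-scaled so that the pipeline's PCA ratio normalization
    followed by the log-log calibration maps back to the cell's true
    expression (exactly so at sigma = 0, doublet_fraction = 0 and no
    autofluorescence).  A ``doublet_fraction`` of events is built by
    summing the raw signals of two random cells; ``autofluorescence``
    adds a fluorescence background with a 20% lognormal spread.
    """
    if mu < 0 or sigma < 0:
        raise ValueError("mu and sigma must be non-negative")
    if n_events < 1:
        raise ValueError("need at least one event")
    rng = _rng(seed)
    n_doublets = int(round(doublet_fraction * n_events))
    n_singlets = n_events - n_doublets
    n_cells = n_singlets + 2 * n_doublets

    expr = draw_expression(rng, mu, sigma, n_cells)
    log_fsc = rng.normal(log_fsc_mean, log_fsc_sd, n_cells)
    fsc_a = 10.0 ** log_fsc
    # singlet ridge: height tracks area tightly
    fsc_h = 10.0 ** (log_fsc - 0.10 + rng.normal(0, 0.008, n_cells))
    with np.errstate(divide="ignore"):
        # inverse calibration: the size-normalization ratio that maps to expr
        x = np.where(expr > 0,
                     10.0 ** ((np.log10(np.where(expr > 0, expr, 1.0))
                               - cal.b) / cal.a), 0.0)
    fl1 = np.where(x > 0, 10.0 ** (x * log_fsc), 0.0)
    if autofluorescence > 0:
        fl1 = fl1 + autofluorescence * np.exp(rng.normal(0, 0.2, n_cells))

    if n_doublets == 0:
        return pd.DataFrame({"fsc_a": fsc_a, "fsc_h": fsc_h, "fl1": fl1})
    s = slice(0, n_singlets)
    a, b = (slice(n_singlets, n_singlets + n_doublets),
            slice(n_singlets + n_doublets, None))
    d_fsc_a = fsc_a[a] + fsc_a[b]
    d_fsc_h = np.maximum(fsc_h[a], fsc_h[b]) * 1.1  # cells pass in series
    d_fl1 = fl1[a] + fl1[b]
    out = pd.DataFrame({
        "fsc_a": np.concatenate([fsc_a[s], d_fsc_a]),
        "fsc_h": np.concatenate([fsc_h[s], d_fsc_h]),
        "fl1": np.concatenate([fl1[s], d_fl1]),
    })
    return out.sample(frac=1.0, random_state=rng.integers(2 ** 31)
                      ).reset_index(drop=True)


def gen_two_color_events(freq_y: float, n_events: int = 50_000, seed=0, *,
                         doublet_fraction: float = 0.0,
                         separation: float = 0.6,
                         size_sd: float = 0.45,
                         ) -> pd.DataFrame:
    """Two-color (YFP vs GFP) events for the fitness-counting assays.

    YFP cells are bright in fl2 (585/40-like), GFP cells in fl1
    (510/10-like).  A ``doublet_fraction`` of events sums the raw
    signals of two cells paired at random, so mixed doublets arise at
    rate 2*f*(1-f)*doublet_fraction and same-color doublets fall into
    their singlet class, exactly the situation the Hardy-Weinberg
    correction assumes.
    """
    if not 0 <= freq_y <= 1:
        raise ValueError("freq_y must lie in [0, 1]")
    rng = _rng(seed)
    n_doublets = int(round(doublet_fraction * n_events))
    n_singlets = n_events - n_doublets
    n_cells = n_singlets + 2 * n_doublets
    is_y = rng.random(n_cells) < freq_y
    # shared cell-size factor dominates both channels, so the first
    # principal component tracks size and the second separates colors
    size = rng.normal(0.0, size_sd, n_cells)
    if n_doublets:
        # doublets are mostly clumped mother-daughter pairs: partners
        # share size closely, keeping the mixed population compact on
        # the color axis (color assignment itself stays random)
        a = slice(n_singlets, n_singlets + n_doublets)
        b = slice(n_singlets + n_doublets, None)
        size[b] = size[a] + rng.normal(0.0, 0.1, n_doublets)
    base_lo, base_hi = 3.6, 3.6 + separation
    fl1 = 10.0 ** (np.where(is_y, base_lo, base_hi) + size
                   + rng.normal(0, 0.05, n_cells))
    fl2 = 10.0 ** (np.where(is_y, base_hi, base_lo) + size
                   + rng.normal(0, 0.05, n_cells))
    log_fsc = rng.normal(5.0, 0.05, n_cells)
    fsc_a = 10.0 ** log_fsc
    fsc_h = 10.0 ** (log_fsc - 0.10 + rng.normal(0, 0.008, n_cells))
    if n_doublets == 0:
        return pd.DataFrame({"fsc_a": fsc_a, "fsc_h": fsc_h,
                             "fl1": fl1, "fl2": fl2})
    s = slice(0, n_singlets)
    a = slice(n_singlets, n_singlets + n_doublets)
    b = slice(n_singlets + n_doublets, None)
    out = pd.DataFrame({
        "fsc_a": np.concatenate([fsc_a[s], fsc_a[a] + fsc_a[b]]),
        "fsc_h": np.concatenate([fsc_h[s],
                                 np.maximum(fsc_h[a], fsc_h[b]) * 1.1]),
        "fl1": np.concatenate([fl1[s], fl1[a] + fl1[b]]),
        "fl2": np.concatenate([fl2[s], fl2[a] + fl2[b]]),
    })
    return out.sample(frac=1.0, random_state=rng.integers(2 ** 31)
                      ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# competition trajectories

def gen_competition_series(w: float, n_timepoints: int = 4,
                           gens_per_cycle: float = 7.0,
                           n_counted: int = 50_000,
                           bottleneck: int = 10_000,
                           start_freq: float = 0.5, seed=0, *,
                           drift: bool = True, counting_noise: bool = True,
                           final_density: float = 5e6) -> CompetitionSeries:
    """A serial-dilution competition trajectory against the reference.

    Enrichment is deterministic — ln(f/(1-f)) gains ln(w) per
    generation — with binomial drift of ``bottleneck`` cells at each
    dilution and binomial counting of ``n_counted`` events at each
    timepoint.  With both noise sources off, counts are exact expected
    values and the fitted slope recovers ln(w) exactly.
    """
    if w <= 0:
        raise ValueError("fitness must be positive")
    if not 0 < start_freq < 1:
        raise ValueError("start_freq must lie in (0, 1)")
    rng = _rng(seed)
    f = start_freq
    gens, n_y, n_g = [], [], []
    for t in range(n_timepoints):
        if counting_noise:
            k = int(rng.binomial(n_counted, f))
            k = min(max(k, 1), n_counted - 1)
        else:
            k = f * n_counted
        gens.append(t * gens_per_cycle)
        n_y.append(k)
        n_g.append(n_counted - k)
        if t < n_timepoints - 1:
            if drift:
                kb = int(rng.binomial(bottleneck, f))
                kb = min(max(kb, 1), bottleneck - 1)
                f = kb / bottleneck
            odds = f / (1.0 - f) * w ** gens_per_cycle
            f = odds / (1.0 + odds)
    densities = np.full(n_timepoints, final_density)
    factors = np.full(n_timepoints - 1, 2.0 ** gens_per_cycle)
    return CompetitionSeries(generations=np.array(gens), n_y=np.array(n_y),
                             n_g=np.array(n_g), densities=densities,
                             dilution_factors=factors)


# ---------------------------------------------------------------------------
# pyrograms

def gen_pyrogram(freq: float, depth: float = 30.0, bias: float = 1 / 0.86,
                 seed=0, *, cv: float = 0.0) -> PeakHeights:
    """Two pyrogram peak heights encoding a G-allele frequency.

    The A peak is inflated by ``bias`` (default 1/0.86, undone exactly
    by the conventional 0.86 correction); ``cv`` adds independent
    multiplicative log-normal noise to each peak.
    """
    if not 0 <= freq <= 1:
        raise ValueError("frequency must lie in [0, 1]")
    rng = _rng(seed)
    h_g = 2.0 * depth * freq
    h_a = 2.0 * depth * (1.0 - freq) * bias
    if cv > 0:
        h_g *= math.exp(rng.normal(0, cv))
        h_a *= math.exp(rng.normal(0, cv))
    return PeakHeights(h_g=h_g, h_a=h_a)


# ---------------------------------------------------------------------------
# the full study panel

@dataclass
class FlowSample:
    """One flow-cytometry sample with its batch labels."""

    genotype_id: str
    replicate: int
    flow_run: str
    row: str
    events: pd.DataFrame = field(repr=False)


@dataclass
class StudyPanel:
    """A synthetic allele panel with every derived dataset.

    ``truth`` carries per-genotype ground truth (columns
    :data:`TRUTH_COLUMNS`); the remaining fields hold the raw inputs
    the pipeline consumes, keyed by genotype.
    """

    truth: pd.DataFrame
    expression: dict = field(repr=False, default_factory=dict)
    reference_expression: list = field(repr=False, default_factory=list)
    blank_expression: list = field(repr=False, default_factory=list)
    competition: dict = field(repr=False, default_factory=dict)
    reference_competition: list = field(repr=False, default_factory=list)
    pyrograms: dict = field(repr=False, default_factory=dict)
    noise_effect: float = 0.0
    far_boundary_mu: float = float("nan")


def plateau_fitness(mu) -> np.ndarray:
    """Truth fitness-vs-expression shape: a rise to a plateau of maximal
    fitness around wild-type expression, with a mild decline above it.

    The total drop at null expression is 0.05 (the growth deficit of a
    deletion of the focal gene is about 5%)."""
    mu = np.asarray(mu, dtype=float)
    low = 1.0 - 0.05 * np.clip(1.0 - mu / 0.85, 0.0, None) ** 2
    high = 1.0 - 0.03 * np.clip((mu - 1.10) / 0.40, 0.0, None) ** 2
    return np.minimum(low, high)


def far_boundary(fitness_drop: float = 0.005) -> float:
    """Expression below which the plateau truth has lost ``fitness_drop``."""
    return 0.85 * (1.0 - math.sqrt(fitness_drop / 0.05))


def _cv_trend(mu):
    """Baseline noise-mean trend: CV declines with expression."""
    return 0.28 - 0.09 * np.asarray(mu, dtype=float)


def gen_study_panel(n_genotypes: int = 43, noise_effect: float = 0.001,
                    seed: int = 0, *,
                    n_expression_replicates: int = 6,
                    n_events: int = 10_000,
                    n_fitness_replicates: int = 8,
                    n_timepoints: int = 4, gens_per_cycle: float = 7.0,
                    n_counted: int = 50_000, bottleneck: int = 10_000,
                    n_pyro_replicates: int = 5,
                    doublet_fraction: float = 0.01,
                    autofluorescence: float = 50.0,
                    n_runs: int = 3,
                    generate_events: bool = True) -> StudyPanel:
    """A full synthetic allele panel with matched raw datasets.

    Genotypes span median expression 0.05–1.25 (relative to wild type)
    with a smooth declining CV–mean trend plus independent log-normal
    noise perturbations.  True fitness follows the plateau shape of
    :func:`plateau_fitness`; ``noise_effect`` (fitness units per
    percentage point of ΔNoise, noise-strength metric) is added for
    genotypes below the plateau's analytic 0.005-drop expression point
    and nowhere else, so far-from-optimum genotypes carry the planted
    noise–fitness signal and close-to-optimum genotypes are null.

    ``generate_events=False`` skips the (bulky) flow-event tables when
    only competition/pyrosequencing data are needed.
    """
    if n_genotypes < 10:
        raise ValueError("need at least 10 genotypes")
    root = np.random.SeedSequence((seed, 0xA11E1E))
    rng = np.random.default_rng(root.spawn(1)[0])

    mu = np.linspace(0.05, 1.25, n_genotypes)
    mu = np.clip(mu + rng.uniform(-0.01, 0.01, n_genotypes), 0.02, 1.25)
    pert = rng.normal(0.0, 0.08, n_genotypes)
    sigma = _cv_trend(mu) * mu * np.exp(pert)

    mu_ref, sigma_ref = 1.0, float(_cv_trend(1.0) * 1.0)
    ns_ref = sigma_ref ** 2 / mu_ref
    noise_pct = 100.0 * (sigma ** 2 / mu) / ns_ref
    trend_pct = 100.0 * (_cv_trend(mu) ** 2 * mu) / ns_ref
    delta_noise = noise_pct - trend_pct

    mu_far = far_boundary(0.005)
    w = plateau_fitness(mu) + noise_effect * delta_noise * (mu < mu_far)

    copies = np.ones(n_genotypes, dtype=int)
    high = np.where(mu > 0.9)[0]
    if high.size >= 3:
        extra = rng.choice(high, size=min(4, high.size), replace=False)
        copies[extra[:-1]] = 2
        copies[extra[-1]] = 3  # an over-inserted strain the t-test should flag

    ids = [f"var{i:02d}" for i in range(n_genotypes)]
    truth = pd.DataFrame({
        "genotype_id": ids, "mu_true": mu, "sigma_true": sigma,
        "w_true": w, "copies_true": copies,
        "expr_pct_true": 100.0 * mu / mu_ref,
        "noise_pct_true": noise_pct, "delta_noise_true": delta_noise,
    })
    panel = StudyPanel(truth=truth, noise_effect=noise_effect,
                       far_boundary_mu=mu_far)

    runs = [f"run{r}" for r in range(n_runs)]
    rows = "ABCDEFGH"

    def flow_samples(gid, m, sd, n_reps, stream):
        out = []
        for rep in range(n_reps):
            ev = gen_flow_events(
                m, sd, n_events, np.random.default_rng(stream.spawn(1)[0]),
                doublet_fraction=doublet_fraction,
                autofluorescence=autofluorescence)
            out.append(FlowSample(genotype_id=gid, replicate=rep,
                                  flow_run=runs[rep % n_runs],
                                  row=rows[rep % len(rows)], events=ev))
        return out

    expr_stream = np.random.SeedSequence((seed, 1))
    comp_stream = np.random.SeedSequence((seed, 2))
    pyro_stream = np.random.SeedSequence((seed, 3))

    if generate_events:
        for i, gid in enumerate(ids):
            panel.expression[gid] = flow_samples(
                gid, mu[i], sigma[i], n_expression_replicates, expr_stream)
        panel.reference_expression = flow_samples(
            "reference", mu_ref, sigma_ref, n_expression_replicates,
            expr_stream)
        panel.blank_expression = flow_samples(
            "blank", 0.0, 0.0, n_expression_replicates, expr_stream)

    for i, gid in enumerate(ids):
        panel.competition[gid] = [
            gen_competition_series(
                w[i], n_timepoints, gens_per_cycle, n_counted, bottleneck,
                seed=np.random.default_rng(comp_stream.spawn(1)[0]))
            for _ in range(n_fitness_replicates)]
    panel.reference_competition = [
        gen_competition_series(
            1.0, n_timepoints, gens_per_cycle, n_counted, bottleneck,
            seed=np.random.default_rng(comp_stream.spawn(1)[0]))
        for _ in range(n_fitness_replicates)]

    for i, gid in enumerate(ids):
        q = copies[i] / (copies[i] + 1.0)  # marked-allele expectation
        observed = (q + 0.111) * 0.9       # inverse of the linear PCR map
        panel.pyrograms[gid] = [
            gen_pyrogram(observed, depth=30.0, bias=1 / 0.86,
                         seed=np.random.default_rng(pyro_stream.spawn(1)[0]),
                         cv=0.01)
            for _ in range(n_pyro_replicates)]
    return panel


def write_truth_tsv(panel: StudyPanel, path) -> None:
    panel.truth.to_csv(path, sep="\t", index=False)
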