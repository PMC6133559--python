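"""Individual-based model linking single-cell expression to fitness.

Each cell of a clonal population draws an expression level E from a
normal distribution (mean mu_E, SD sigma_E, truncated at zero by
redrawing) at every division; a doubling-time function DT = f(E) maps
expression to the minutes until its next division.  Two shapes are
explored: a linear function DT = -40*E + 160 (more expression is always
better) and an inverted-Gaussian function
DT = -160*exp(-(E-1)^2/0.18) + 240, which puts a doubling-time optimum
at E = 1.  Populations grow for a fixed experiment duration T; fitness
of a genotype is exp(ln(N_i/N_ref)/T) against a reference genotype with
mu = 1, sigma = 0.1.

Each simulation is preceded by a seed run: founders are desynchronized
by scaling their first DT by a uniform(0,1) draw, grown for the full
duration, and the main run's founders are sampled from the seed run's
final population, inheriting its expression (and hence cell-cycle)
composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimGenotype", "SimConfig", "SimResult", "PopulationCapError",
    "dt_function", "sigma_from_noise", "simulate_population",
    "competitive_fitness_sim", "sweep",
]


class PopulationCapError(RuntimeError):
    """The simulated population exceeded the configured hard cap."""


@dataclass(frozen=True)
class SimGenotype:
    """A genotype of the model: mean expression, noise, DT function."""

    mu: float
    noise: float
    noise_metric: str = "sd"  # sd | cv | fano
    dt_kind: str = "gaussian"  # gaussian | linear

    def __post_init__(self):
        if not 0 <= self.mu:
            raise ValueError("mean expression must be non-negative")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")

    @property
    def sigma(self) -> float:
        return sigma_from_noise(self.noise_metric, self.noise, self.mu)


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings (defaults follow the modelled experiment)."""

    T: float = 1000.0  # experiment duration, minutes
    seed_cells: int = 1000  # founder count
    replicates: int = 100
    dt_floor: float = 1.0  # minutes; keeps DT positive at extreme E
    population_cap: int = 50_000_000
    reference: SimGenotype = field(
        default=SimGenotype(mu=1.0, noise=0.1, noise_metric="sd"))


@dataclass
class SimResult:
    """Aggregated fitness of one genotype over replicate simulations."""

    genotype: SimGenotype
    fitness_mean: float
    ci95: tuple
    per_replicate: np.ndarray = field(repr=False, default=None)
    final_counts: np.ndarray = field(repr=False, default=None)


def dt_function(E, kind: str = "gaussian", floor: float = 1.0):
    """Doubling time (minutes) as a function of expression level.

    linear:   DT = -40*E + 160
    gaussian: DT = -160*exp(-(E-1)^2/0.18) + 240
    Both are clamped below at ``floor`` minutes.
    """
    E = np.asarray(E, dtype=float)
    if kind == "linear":
        dt = -40.0 * E + 160.0
    elif kind == "gaussian":
        dt = -160.0 * np.exp(-((E - 1.0) ** 2) / 0.18) + 240.0
    else:
        raise ValueError(f"unknown DT function {kind!r}")
    return np.maximum(dt, floor)


def sigma_from_noise(metric: str, nu: float, mu: float) -> float:
    """Expression SD from a noise value in one of three parameterizations:
    sd -> sigma = nu; cv -> sigma = nu*mu; fano -> sigma = sqrt(nu*mu)."""
    if nu < 0 or mu < 0:
        raise ValueError("noise and mean must be non-negative")
    if metric == "sd":
        return nu
    if metric == "cv":
        return nu * mu
    if metric == "fano":
        return math.sqrt(nu * mu)
    raise ValueError(f"unknown noise metric {metric!r}")


def _draw_expression(rng: np.random.Generator, mu: float, sigma: float,
                     n: int) -> np.ndarray:
    """Normal draws truncated to E >= 0 by redrawing."""
    if sigma == 0:
        return np.full(n, mu)
    e = rng.normal(mu, sigma, n)
    bad = e < 0
    while bad.any():
        e[bad] = rng.normal(mu, sigma, int(bad.sum()))
        bad = e < 0
    return e


def _grow(rng: np.random.Generator, mu: float, sigma: float, kind: str,
          T: float, founders_E: np.ndarray, cfg: SimConfig,
          desynchronize: bool = True) -> np.ndarray:
    """Grow a population from founder expression levels for duration T.

    Returns the expression levels of the final population (one entry
    per cell alive at the end).  Every division replaces one cell by
    two, so the final count equals founders + division events.
    """
    dt = dt_function(founders_E, kind, cfg.dt_floor)
    if desynchronize:
        dt = dt * rng.uniform(0.0, 1.0, dt.size)
    rem = np.full(founders_E.size, T)
    E = founders_E.copy()
    final_E: list[np.ndarray] = []
    n_final = 0
    while E.size:
        divides = dt <= rem
        final_E.append(E[~divides])
        n_final += int((~divides).sum())
        rem = rem[divides] - dt[divides]
        k = rem.size
        if n_final + 2 * k > cfg.population_cap:
            raise PopulationCapError(
                f"population exceeded {cfg.population_cap} cells; "
                "use a shorter experiment duration T")
        rem = np.repeat(rem, 2)
        E = _draw_expression(rng, mu, sigma, 2 * k)
        dt = dt_function(E, kind, cfg.dt_floor)
    return np.concatenate(final_E) if final_E else np.empty(0)


def simulate_population(g: SimGenotype, cfg: SimConfig | None = None,
                        seed: int | np.random.Generator = 0) -> int:
    """Final cell count of one genotype after one seed + main run."""
    cfg = cfg or SimConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mu, sigma, kind = g.mu, g.sigma, g.dt_kind
    founders = _draw_expression(rng, mu, sigma, cfg.seed_cells)
    seed_pop = _grow(rng, mu, sigma, kind, cfg.T, founders, cfg)
    picks = rng.choice(seed_pop.size, size=cfg.seed_cells, replace=False) \
        if seed_pop.size >= cfg.seed_cells else \
        rng.integers(0, seed_pop.size, cfg.seed_cells)
    main = _grow(rng, mu, sigma, kind, cfg.T, seed_pop[picks], cfg)
    return int(main.size)


def competitive_fitness_sim(N_i: float, N_ref: float, T: float) -> float:
    """Fitness = exp(ln(N_i / N_ref) / T)."""
    if N_i <= 0 or N_ref <= 0 or T <= 0:
        raise ValueError("counts and duration must be positive")
    return math.exp(math.log(N_i / N_ref) / T)


def sweep(genotypes, cfg: SimConfig | None = None, seed: int = 0,
          paired: bool = True, reference_dt: str | None = None,
          ) -> list[SimResult]:
    """Mean fitness with 95% t-CIs over replicate simulations.

    For every replicate one reference population (mu = 1, sigma = 0.1)
    is simulated per DT function in use; with ``paired=True`` every
    genotype's replicate r shares its seed stream with reference
    replicate r, so genotype-versus-genotype contrasts are paired.  By
    default the reference uses the same DT function as the focal
    genotype; ``reference_dt`` overrides that.
    """
    cfg = cfg or SimConfig()
    genotypes = list(genotypes)
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(cfg.replicates)
    kinds = {reference_dt or g.dt_kind for g in genotypes}
    ref_counts: dict[str, np.ndarray] = {}
    for kind in kinds:
        ref_g = SimGenotype(mu=cfg.reference.mu, noise=cfg.reference.noise,
                            noise_metric=cfg.reference.noise_metric,
                            dt_kind=kind)
        counts = np.empty(cfg.replicates)
        for r, rs in enumerate(rep_seeds):
            child = rs.spawn(1)[0] if not paired else rs
            counts[r] = simulate_population(
                ref_g, cfg, np.random.default_rng(child))
        ref_counts[kind] = counts
    results = []
    for gi, g in enumerate(genotypes):
        counts = np.empty(cfg.replicates)
        for r, rs in enumerate(rep_seeds):
            # an independent stream per (genotype, replicate); pairing
            # comes from sharing the replicate's reference run
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, 1 + gi, r)))
            counts[r] = simulate_population(g, cfg, rng)
        refs = ref_counts[reference_dt or g.dt_kind]
        fit = np.array([competitive_fitness_sim(n, nr, cfg.T)
                        for n, nr in zip(counts, refs)])
        m = float(fit.mean())
        if cfg.replicates > 1:
            se = float(fit.std(ddof=1)) / math.sqrt(cfg.replicates)
            t = stats.t.ppf(0.975, cfg.replicates - 1)
            ci = (m - t * se, m + t * se)
        else:
            ci = (float("nan"), float("nan"))
        results.append(SimResult(genotype=g, fitness_mean=m, ci95=ci,
                                 per_replicate=fit, final_counts=counts))
    return results


def sweep_frame(results) -> pd.DataFrame:
    """Tidy table of sweep results (one aggregated row per genotype)."""
    rows = []
    for res in results:
        g = res.genotype
        rows.append({
            "mu": g.mu, "noise": g.noise, "noise_metric": g.noise_metric,
            "dt_kind": g.dt_kind, "fitness_mean": res.fitness_mean,
            "ci_low": res.ci95[0], "ci_high": res.ci95[1],
            "mean_final_count": float(np.mean(res.final_counts)),
        })
    return pd.DataFrame(rows)
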