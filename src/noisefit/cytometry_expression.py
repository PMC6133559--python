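"""Per-event cytometry data -> per-genotype expression and noise.

The chain implemented here turns raw flow-cytometry events (forward
scatter + fluorescence) into relative mRNA expression summaries:

1. ``filter_events``      — drop artifacts and non-singlet events.
2. ``size_normalize``     — PCA rotation of (log FSC.A, log FL1), then
                            the ratio of rotated values: fluorescence
                            per unit cell size.
3. ``fluor_to_mrna``      — log-log calibration to relative mRNA units.
4. ``summarize_sample``   — median, SD and four noise metrics per sample.
5. ``correct_batch``      — remove flow-run / plate-row effects fitted
                            on control samples.
6. ``subtract_autofluorescence`` — blank-strain correction.
7. ``mad_filter`` + ``aggregate_genotype`` — replicate outlier removal
                            and per-genotype summaries relative to the
                            wild-type reference (percent scale).

Event tables are plain :class:`pandas.DataFrame` objects with columns
``fsc_a``, ``fsc_h``, ``fl1`` (and optionally ``fl2`` plus batch labels
``sample_id``, ``plate``, ``row``, ``column``, ``flow_run``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "MrnaCalibration", "WT_CALIBRATION", "SampleExpression", "GenotypeSummary",
    "EmptySampleError", "InsufficientCellsError",
    "filter_events", "size_normalize", "fluor_to_mrna", "summarize_sample",
    "correct_batch", "subtract_autofluorescence", "mad_filter",
    "aggregate_genotype", "read_events_csv", "write_events_csv",
    "process_sample",
]

LN10 = math.log(10.0)


class EmptySampleError(ValueError):
    """All events of a sample were removed by filtering."""


class InsufficientCellsError(ValueError):
    """A sample has fewer cells than the summary floor (default 1000)."""


@dataclass(frozen=True)
class MrnaCalibration:
    """Log-log calibration between size-normalized fluorescence x and
    relative mRNA level y:  log10(y) = a * log10(x) + b."""

    a: float = 10.469
    b: float = -9.586

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("calibration slope a must be positive")


#: Least-squares calibration fitted in the source study (BD Accuri C6).
WT_CALIBRATION = MrnaCalibration()


@dataclass
class SampleExpression:
    """Expression summary of one sample.

    ``m`` is the median expression (relative mRNA units), ``s`` its SD
    among cells.  The four noise metrics all use the median in the
    denominator: noise strength s^2/m (Fano-factor analogue), cv s/m,
    and log10 cv.
    """

    m: float
    s: float
    n_cells: int
    sample_id: str = ""
    flow_run: str = ""
    row: str = ""

    @property
    def noise_strength(self) -> float:
        return self.s ** 2 / self.m if self.m > 0 else float("nan")

    @property
    def cv(self) -> float:
        return self.s / self.m if self.m > 0 else float("nan")

    @property
    def log_cv(self) -> float:
        cv = self.cv
        return math.log10(cv) if cv and cv > 0 else float("nan")

    def noise(self, metric: str) -> float:
        """One of the four noise metrics: strength, sd, cv, logcv."""
        return {"strength": self.noise_strength, "sd": self.s,
                "cv": self.cv, "logcv": self.log_cv}[metric]


@dataclass
class GenotypeSummary:
    """Per-genotype medians and noise relative to the reference (percent)."""

    genotype_id: str
    median_expression_pct: float
    noise_pct: dict  # metric name -> percent of reference
    n_replicates: int
    expression_ci95: tuple = (float("nan"), float("nan"))
    noise_ci95: dict | None = None


# ---------------------------------------------------------------------------
# event-level operations

def filter_events(raw: pd.DataFrame,
                  bounds: tuple[float, float] = (0.0005, 0.9995),
                  density_floor: float = 0.005,
                  channels: Sequence[str] = ("fsc_a", "fsc_h", "fl1"),
                  ) -> pd.DataFrame:
    """Remove artifact and non-single-cell events.

    Events with non-positive scatter/fluorescence are always dropped
    (they cannot be log-transformed).  Then events outside the
    ``bounds`` quantiles of each log channel are removed, and finally a
    singlet gate keeps events whose smoothed 2-D density on
    (log FSC.A, log FSC.H) is at least ``density_floor`` times the
    density maximum.  ``bounds=(0, 1)`` with ``density_floor=0``
    returns the input minus non-positive values.
    """
    if len(raw) == 0:
        raise EmptySampleError("empty event table")
    present = [c for c in channels if c in raw.columns]
    keep = np.ones(len(raw), dtype=bool)
    for c in present:
        keep &= raw[c].to_numpy() > 0
    df = raw.loc[keep]
    if len(df) == 0:
        raise EmptySampleError("all events non-positive")
    logs = {c: np.log10(df[c].to_numpy()) for c in present}
    keep = np.ones(len(df), dtype=bool)
    lo, hi = bounds
    if (lo, hi) != (0.0, 1.0):
        for c in present:
            v = logs[c]
            ql, qh = np.quantile(v, [lo, hi])
            keep &= (v >= ql) & (v <= qh)
    if density_floor > 0 and {"fsc_a", "fsc_h"} <= set(present):
        dens = _hist_density(logs["fsc_a"], logs["fsc_h"])
        keep &= dens >= density_floor * dens.max()
    out = df.loc[keep]
    if len(out) == 0:
        raise EmptySampleError("all events removed by filtering")
    return out


def _hist_density(x: np.ndarray, y: np.ndarray, bins: int = 64,
                  smooth: float = 1.5) -> np.ndarray:
    """Smoothed 2-D histogram density evaluated at each event."""
    hist, xe, ye = np.histogram2d(x, y, bins=bins)
    hist = ndimage.gaussian_filter(hist, smooth)
    ix = np.clip(np.searchsorted(xe, x, side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ye, y, side="right") - 1, 0, bins - 1)
    return hist[ix, iy]


def size_normalize(events: pd.DataFrame,
                   size_channel: str = "fsc_a",
                   fluor_channel: str = "fl1") -> np.ndarray:
    """Fluorescence per unit cell size via the PCA-rotation construction.

    A PCA is run on (log10 size, log10 fluorescence).  Both eigenvectors
    pass through the data centroid, so their intersection is the
    centroid; ``nu`` is the vector from the origin to it.  The cloud is
    rotated about the centroid by the angle between the first (larger
    eigenvalue) eigenvector and ``nu``, mapping the major axis onto the
    centroid ray, and the rotated fluorescence coordinate is divided by
    the rotated size coordinate.

    Sign conventions (the construction does not fix them): the first
    eigenvector is taken with positive dot product with ``nu`` and the
    rotation sense maps it exactly onto ``nu``.
    """
    if len(events) < 2:
        raise ValueError("need at least 2 events")
    L = np.log10(events[size_channel].to_numpy(dtype=float))
    F = np.log10(events[fluor_channel].to_numpy(dtype=float))
    pts = np.column_stack([L, F])
    centroid = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if not np.all(np.isfinite(cov)) or np.allclose(cov, 0):
        raise ValueError("degenerate covariance: all events identical")
    evals, evecs = np.linalg.eigh(cov)
    e1 = evecs[:, np.argmax(evals)]
    nu = centroid / np.hypot(*centroid)
    if e1 @ nu < 0:
        e1 = -e1
    theta = math.atan2(nu[1], nu[0]) - math.atan2(e1[1], e1[0])
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    rotated = (pts - centroid) @ rot.T + centroid
    return rotated[:, 1] / rotated[:, 0]


def fluor_to_mrna(x, cal: MrnaCalibration = WT_CALIBRATION):
    """Relative mRNA level from size-normalized fluorescence:
    y = 10**(a*log10(x) + b).  Strictly increasing in x."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("normalized fluorescence must be positive")
    return 10.0 ** (cal.a * np.log10(x) + cal.b)


def summarize_sample(expr, min_cells: int = 1000, **labels) -> SampleExpression:
    """Median/SD and noise metrics of per-cell mRNA values.

    Raises :class:`InsufficientCellsError` below the cell floor so the
    caller can flag (rather than silently summarize) a thin sample.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.size < min_cells:
        raise InsufficientCellsError(
            f"{expr.size} cells < floor of {min_cells}")
    s = float(np.std(expr, ddof=1)) if expr.size > 1 else 0.0
    return SampleExpression(m=float(np.median(expr)), s=s,
                            n_cells=int(expr.size), **labels)


# ---------------------------------------------------------------------------
# sample-level corrections

def correct_batch(samples: Sequence[SampleExpression],
                  controls: Sequence[SampleExpression],
                  factors: Sequence[str] = ("flow_run", "row"),
                  ) -> list[SampleExpression]:
    """Remove batch effects fitted on control samples.

    Fixed-effect linear models for median(log y) — via log10(m) — and
    for sigma(log y) — via the first-order delta-method relation
    sigma(log10 y) ~= s / (m ln 10) — are fitted on the controls with
    the given categorical factors, and the fitted effects (centred on
    the control mean) are subtracted from every sample on those scales
    before back-transforming to (m, s).
    """
    import statsmodels.formula.api as smf

    if not controls:
        raise ValueError("no control samples")
    for f in factors:
        have = {getattr(c, f) for c in controls}
        need = {getattr(s, f) for s in samples}
        missing = need - have
        if missing:
            raise ValueError(f"no controls for {f} level(s): {sorted(missing)}")

    def frame(group):
        return pd.DataFrame({
            "u": [math.log10(s.m) for s in group],
            "v": [s.s / (s.m * LN10) for s in group],
            **{f: [getattr(s, f) for s in group] for f in factors},
        })

    ctrl, samp = frame(controls), frame(samples)
    formula_rhs = " + ".join(f"C({f})" for f in factors)
    out = []
    effects = {}
    for col in ("u", "v"):
        fit = smf.ols(f"{col} ~ {formula_rhs}", data=ctrl).fit()
        pred_samp = fit.predict(samp)
        effects[col] = pred_samp.to_numpy() - fit.predict(ctrl).mean()
    for i, s0 in enumerate(samples):
        u = math.log10(s0.m) - effects["u"][i]
        v = s0.s / (s0.m * LN10) - effects["v"][i]
        m = 10.0 ** u
        out.append(replace(s0, m=m, s=v * m * LN10))
    return out


def subtract_autofluorescence(samples: Sequence[SampleExpression],
                              blank: Sequence[SampleExpression],
                              ) -> list[SampleExpression]:
    """Subtract the blank-strain mean (m, s) from every sample.

    Values may end up near zero for null promoters; downstream noise
    metrics become NaN when the corrected median is non-positive.
    """
    if not blank:
        raise ValueError("need at least one blank replicate")
    m0 = float(np.mean([b.m for b in blank]))
    s0 = float(np.mean([b.s for b in blank]))
    return [replace(s, m=s.m - m0, s=s.s - s0) for s in samples]


def mad_filter(values, k: float) -> np.ndarray:
    """Mask of replicate values within k raw-MAD of the replicate median.

    MAD is the raw median absolute deviation (no consistency constant).
    Only deviations strictly greater than k*MAD are dropped, so when
    MAD = 0 any value exactly at the median is retained.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 replicate values")
    med = np.median(values)
    dev = np.abs(values - med)
    return dev <= k * np.median(dev)


def aggregate_genotype(samples: Sequence[SampleExpression],
                       reference_samples: Sequence[SampleExpression],
                       genotype_id: str = "",
                       mad_k: float = 4.0,
                       metrics: Sequence[str] = ("strength", "sd", "cv", "logcv"),
                       ) -> GenotypeSummary:
    """Percent-of-reference expression and noise across replicates.

    Replicates whose median or SD deviates from the replicate median by
    more than ``mad_k`` times the MAD are discarded (in both the
    genotype and the reference sets); each surviving replicate is
    divided by the reference replicate mean and averaged, with a 95%
    Student-t CI when at least four replicates survive.
    """
    def surviving(group):
        if len(group) < 3:
            return list(group)
        keep = (mad_filter([s.m for s in group], mad_k)
                & mad_filter([s.s for s in group], mad_k))
        return [s for s, k in zip(group, keep) if k]

    gen = surviving(samples)
    ref = surviving(reference_samples)
    if not gen or not ref:
        raise ValueError("no replicates survive the MAD filter")
    ref_m = np.mean([s.m for s in ref])
    rel_m = np.array([s.m / ref_m for s in gen]) * 100.0
    noise_pct, noise_ci = {}, {}
    for met in metrics:
        ref_n = np.mean([s.noise(met) for s in ref])
        rel = np.array([s.noise(met) / ref_n for s in gen]) * 100.0
        noise_pct[met] = float(np.mean(rel))
        noise_ci[met] = _t_ci(rel)
    return GenotypeSummary(
        genotype_id=genotype_id,
        median_expression_pct=float(np.mean(rel_m)),
        noise_pct=noise_pct,
        n_replicates=len(gen),
        expression_ci95=_t_ci(rel_m),
        noise_ci95=noise_ci,
    )


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = len(values)
    if n < 4:  # CIs are reported from at least four replicates
        return (float("nan"), float("nan"))
    m = float(np.mean(values))
    se = float(np.std(values, ddof=1)) / math.sqrt(n)
    t = stats.t.ppf(0.5 + level / 2, n - 1)
    return (m - t * se, m + t * se)


# ---------------------------------------------------------------------------
# IO and convenience pipeline

EVENT_COLUMNS = {"fsc_a": "FSC.A", "fsc_h": "FSC.H", "fl1": "FL1", "fl2": "FL2"}


def write_events_csv(events: pd.DataFrame, path) -> None:
    """Write an event table with instrument-style column names."""
    events.rename(columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events_csv(path, channel_map: dict | None = None) -> pd.DataFrame:
    """Read a CSV event table; instrument-style names are mapped back."""
    df = pd.read_csv(path)
    inverse = {v: k for k, v in EVENT_COLUMNS.items()}
    if channel_map:
        inverse.update({v: k for k, v in channel_map.items()})
    return df.rename(columns={c: inverse.get(c, c) for c in df.columns})


def process_sample(events: pd.DataFrame,
                   cal: MrnaCalibration = WT_CALIBRATION,
                   min_cells: int = 1000,
                   bounds: tuple[float, float] = (0.0005, 0.9995),
                   density_floor: float = 0.005,
                   **labels) -> SampleExpression:
    """filter -> size-normalize -> calibrate -> summarize, one sample."""
    kept = filter_events(events, bounds=bounds, density_floor=density_floor)
    x = size_normalize(kept)
    y = fluor_to_mrna(x, cal)
    return summarize_sample(y, min_cells=min_cells, **labels)
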