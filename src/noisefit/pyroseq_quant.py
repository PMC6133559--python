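"""Pyrosequencing allele-frequency quantification.

Peak heights on a pyrogram are proportional to the abundance of each
allele in the template pool, up to a per-nucleotide incorporation bias
(A peaks run systematically high and carry the conventional 0.86
correction) and PCR amplification bias (corrected either by the printed
linear map calibrated on a known 50/50 control, or by a monotone
smoothing fit through control strains of known allele frequency).
Downstream, frequencies in gDNA and cDNA give the relative mRNA
abundance ratio, and gDNA frequencies alone give the promoter copy
number at the reporter locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

__all__ = [
    "PeakHeights", "PyroMeasurement", "freq_from_peaks",
    "linear_bias_correct", "spline_bias_correct", "expression_ratio",
    "cdna_freq_from_ratio", "expected_copy_freq", "infer_copies",
    "A_PEAK_CORRECTION",
]

#: Conventional multiplicative correction applied to A peaks.
A_PEAK_CORRECTION = 0.86


@dataclass(frozen=True)
class PeakHeights:
    """Signal heights of the two allele peaks on one pyrogram."""

    h_g: float
    h_a: float
    g_base: str = "G"
    a_base: str = "A"

    def __post_init__(self):
        if self.h_g < 0 or self.h_a < 0:
            raise ValueError("peak heights must be non-negative")

    @property
    def mean_height(self) -> float:
        return (self.h_g + self.h_a) / 2.0


@dataclass(frozen=True)
class PyroMeasurement:
    """Marked-allele frequencies in gDNA (G) and cDNA (C), and the
    relative mRNA abundance ratio A they imply."""

    G: float
    C: float

    @property
    def A(self) -> float:
        return expression_ratio(self.G, self.C)


def freq_from_peaks(p: PeakHeights,
                    a_correction: float = A_PEAK_CORRECTION) -> float:
    """G-allele frequency from peak heights.

    The A peak is multiplied by the correction factor before the ratio:
    freq = h_G / (h_G + a_correction * h_A).
    """
    if p.h_g == 0 and p.h_a == 0:
        raise ValueError("both peaks are zero")
    return p.h_g / (p.h_g + a_correction * p.h_a)


def linear_bias_correct(x: float) -> float:
    """PCR-bias correction calibrated on the single-copy control strain.

    y = x * (0.5/0.45) - 0.111, clipped to [0, 1]; it maps the observed
    control frequency 0.55 back to the true 0.5.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("frequency must lie in [0, 1]")
    y = np.clip(x * (0.5 / 0.45) - 0.111, 0.0, 1.0)
    return float(y) if y.ndim == 0 else y


def spline_bias_correct(known, observed):
    """Monotone correction map fitted on control strains of known frequency.

    ``known`` holds the true allele frequencies of the control strains
    (e.g. 0, 0.5, 1) and ``observed`` the matching replicate
    measurements (list of arrays, one per control).  Isotonic averaging
    of truth on the observed means, followed by a monotone (PCHIP)
    cubic through the averaged points, yields a smooth monotone
    corrector; outside the observed range the map extends linearly and
    output is clipped to [0, 1].  Unbiased observations give (numerically)
    the identity.
    """
    known = np.asarray(known, dtype=float)
    if len(set(known.tolist())) < 2:
        raise ValueError("need at least 2 distinct truth levels")
    xs = np.array([float(np.mean(np.atleast_1d(o))) for o in observed])
    order = np.argsort(xs)
    xs, ys = xs[order], known[order]
    # pool-adjacent-violators to enforce monotonicity of the knots
    ys = _isotonic(xs, ys)
    xs, idx = np.unique(xs, return_index=True)
    ys = ys[idx]
    if xs.size < 2:
        raise ValueError("observed control means are not distinct")
    interp = PchipInterpolator(xs, ys, extrapolate=False)
    lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])

    def correct(x):
        x = np.asarray(x, dtype=float)
        y = interp(x)
        y = np.where(x < xs[0], ys[0] + lo_slope * (x - xs[0]), y)
        y = np.where(x > xs[-1], ys[-1] + hi_slope * (x - xs[-1]), y)
        y = np.clip(y, 0.0, 1.0)
        return float(y) if y.ndim == 0 else y

    return correct


def _isotonic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators on already-x-sorted points."""
    y = y.astype(float).copy()
    w = np.ones_like(y)
    blocks = [[i] for i in range(len(y))]
    vals = list(y)
    wts = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-15:
            tot = wts[i] + wts[i + 1]
            vals[i] = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / tot
            wts[i] = tot
            blocks[i] += blocks.pop(i + 1)
            vals.pop(i + 1)
            wts.pop(i + 1)
            i = max(i - 1, 0)
        else:
            i += 1
    out = np.empty_like(y)
    for v, idxs in zip(vals, blocks):
        out[idxs] = v
    return out


def expression_ratio(G: float, C: float) -> float:
    """Relative mRNA abundance A from gDNA and cDNA allele frequencies.

    The forward relation is C = A*G / (A*G + (1-G)); inverting gives
    A = (1-G)*C / ((1-C)*G).
    """
    if not 0 < G < 1:
        raise ValueError("gDNA frequency must lie strictly inside (0, 1)")
    if not 0 <= C < 1:
        raise ValueError("cDNA frequency must lie in [0, 1)")
    return (1.0 - G) * C / ((1.0 - C) * G)


def cdna_freq_from_ratio(A: float, G: float) -> float:
    """Forward relation: cDNA frequency C = A*G / (A*G + (1-G))."""
    if not 0 < G < 1:
        raise ValueError("gDNA frequency must lie strictly inside (0, 1)")
    if A < 0:
        raise ValueError("abundance ratio must be non-negative")
    return A * G / (A * G + (1.0 - G))


def expected_copy_freq(n_marked: int, n_other: int = 1) -> float:
    """Expected marked-allele frequency for integer copy numbers.

    One marked copy against one native copy gives 0.5, two give 2/3,
    three give 0.75: n_marked / (n_marked + n_other).
    """
    if n_marked < 0 or n_other < 1:
        raise ValueError("need n_marked >= 0 and n_other >= 1")
    return n_marked / (n_marked + n_other)


def infer_copies(replicate_freqs, candidate_counts=(1, 2, 3),
                 claimed: int | None = 2, alpha: float = 0.05,
                 n_other: int = 1):
    """Copy-number call from replicate gDNA frequencies.

    The called copy number is the candidate whose expected frequency is
    nearest the replicate mean.  A one-sample t-test against the
    claimed candidate's expectation flags strains whose frequency is
    significantly *higher* than claimed (candidates for extra tandem
    insertions, excluded from downstream analyses).

    Returns ``(copies, flagged, p_value)``.
    """
    freqs = np.asarray(replicate_freqs, dtype=float)
    if freqs.size < 3:
        raise ValueError("need at least 3 replicates")
    expectations = {c: expected_copy_freq(c, n_other) for c in candidate_counts}
    mean = float(freqs.mean())
    copies = min(expectations, key=lambda c: abs(expectations[c] - mean))
    if claimed is None:
        claimed = copies
    target = expectations[claimed]
    if float(freqs.std(ddof=1)) == 0:
        p = 0.0 if not math.isclose(mean, target) else 1.0
    else:
        p = float(stats.ttest_1samp(freqs, target).pvalue)
    flagged = bool(p < alpha and mean > target)
    return copies, flagged, p
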