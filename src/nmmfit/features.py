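"""Feature spaces for model--data comparison.

Three representations of a single-channel time series are used to score how
well a simulated signal resembles data: a band-restricted normalised power
spectrum, its pre-whitened (1/f-detrended) log-power residual, and the
weighted horizontal visibility graph (wHVG), whose per-node strength
distribution captures waveform shape that the spectrum cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import signal as sp_signal

__all__ = [
    "PowerSpectrum",
    "WHVGraph",
    "compute_psd",
    "prewhiten_psd",
    "build_whvg",
    "node_strengths",
    "ks_statistic",
    "density_histogram",
    "amplitude_distribution",
    "hurst_exponent",
]


@dataclass
class PowerSpectrum:
    freqs: np.ndarray        # Hz, strictly increasing, uniform at the resolution
    power: np.ndarray        # normalised power per bin (unit sum over the band)
    band: tuple[float, float]
    normalised: bool = True


@dataclass
class WHVGraph:
    """Time series as a network with signed amplitude-difference edge weights.

    Nodes are time points; nodes i < j are linked when every intermediate
    sample lies strictly below both endpoints (a horizontal sight line
    clears all samples in between).  Each edge carries w = x_j - x_i.
    """

    n_nodes: int
    edges: list[tuple[int, int, float]]   # (i, j, w) with i < j
    node_strength: np.ndarray             # signed sum of incident weights

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def compute_psd(x, rate: float, band: tuple[float, float] = (2.0, 20.0),
                resolution: float = 0.125, method: str = "welch") -> PowerSpectrum:
    """Band-restricted, unit-sum power spectrum at a fixed bin width.

    Welch averaging with Hann-windowed segments of ``rate / resolution``
    samples and 50% overlap; the segment length is what fixes the frequency
    resolution.  ``method="periodogram"`` uses a single full-length FFT
    instead (resolution then equals rate/len(x)).
    """
    x = np.asarray(x, dtype=float)
    lo, hi = band
    if not (0.0 < lo < hi < rate / 2.0):
        raise ValueError("band must lie within (0, Nyquist)")
    if method == "welch":
        nperseg = int(round(rate / resolution))
        if len(x) < nperseg:
            raise ValueError(
                f"series of {len(x)} samples is shorter than one "
                f"{nperseg}-sample segment at {resolution} Hz resolution")
        freqs, power = sp_signal.welch(x, fs=rate, window="hann",
                                       nperseg=nperseg, noverlap=nperseg // 2)
    elif method == "periodogram":
        freqs, power = sp_signal.periodogram(x, fs=rate, window="hann")
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    eps = 1e-9
    sel = (freqs >= lo - eps) & (freqs <= hi + eps)
    freqs, power = freqs[sel], power[sel]
    total = power.sum()
    if total > 0:
        power = power / total
    return PowerSpectrum(freqs=freqs, power=power, band=(lo, hi))


def prewhiten_psd(spec: PowerSpectrum) -> np.ndarray:
    """Residual of a robust linear fit to the log-log spectrum.

    Removes the 1/f background: r(w) = ln P(w) - (a + b ln w), with (a, b)
    from iteratively reweighted least squares using bisquare weights.
    Invariant to multiplicative rescaling of the power (intercept absorbs
    it).
    """
    if len(spec.freqs) < 3:
        raise ValueError("need at least 3 frequency bins to detrend")
    power = np.maximum(np.asarray(spec.power, dtype=float), np.finfo(float).tiny)
    logp = np.log(power)
    logf = np.log(np.asarray(spec.freqs, dtype=float))
    X = sm.add_constant(logf)
    fit = sm.RLM(logp, X, M=sm.robust.norms.TukeyBiweight()).fit()
    return logp - fit.fittedvalues


def build_whvg(x) -> WHVGraph:
    """Weighted horizontal visibility graph, O(N) stack construction.

    Visibility is strict: an intermediate sample equal to an endpoint
    blocks the line of sight.  Edge weights are signed, latter minus
    former sample.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite samples")
    n = len(x)
    edges: list[tuple[int, int, float]] = []
    strength = np.zeros(n)

    def add_edge(i: int, j: int) -> None:
        w = x[j] - x[i]
        edges.append((i, j, w))
        strength[i] += w
        strength[j] += w

    stack: list[int] = [0]
    for j in range(1, n):
        # pop everything strictly below x[j]: visible, then blocked by j
        while stack and x[stack[-1]] < x[j]:
            add_edge(stack.pop(), j)
        if stack:
            add_edge(stack[-1], j)
            # an equal-valued predecessor is shadowed by j from now on
            if x[stack[-1]] == x[j]:
                stack.pop()
        stack.append(j)
    return WHVGraph(n_nodes=n, edges=edges, node_strength=strength)


def node_strengths(x) -> np.ndarray:
    """Per-node signed strength of the wHVG of ``x`` (the comparison statistic)."""
    return build_whvg(x).node_strength


def ks_statistic(a, b) -> float:
    """Two-sample Kolmogorov–Smirnov statistic D = sup_y |F_a(y) - F_b(y)|.

    Right-continuous empirical CDFs evaluated on the raw pooled values; no
    binning.  Symmetric, in [0, 1], invariant under any common strictly
    increasing transform of both samples.
    """
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    Fa = np.searchsorted(a, pooled, side="right") / len(a)
    Fb = np.searchsorted(b, pooled, side="right") / len(b)
    return float(np.max(np.abs(Fa - Fb)))


def density_histogram(sample, nbins: int = 100,
                      range: tuple[float, float] | None = None):
    """Equal-width histogram normalised to unit total mass.

    Bins are left-closed/right-open with the final bin right-closed.  A
    zero-width range degenerates to a single bin of density 1.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if len(sample) == 0:
        raise ValueError("sample must be non-empty")
    if not np.all(np.isfinite(sample)):
        raise ValueError("sample contains non-finite values")
    lo, hi = range if range is not None else (sample.min(), sample.max())
    if lo == hi:
        return np.array([lo, hi]), np.array([1.0])
    counts, edges = np.histogram(sample, bins=nbins, range=(lo, hi))
    total = counts.sum()
    density = counts / total if total > 0 else counts.astype(float)
    return edges, density


def amplitude_distribution(x, nbins: int = 100,
                           range: tuple[float, float] | None = None):
    """Density approximation of the raw sample-amplitude distribution."""
    return density_histogram(np.asarray(x, dtype=float), nbins=nbins, range=range)


def hurst_exponent(x, min_window: int = 8) -> float:
    """Rescaled-range (R/S) estimate of the Hurst exponent.

    Slope of log(R/S) against log(window) over dyadic window sizes from
    ``min_window`` to len(x)//2.  Around 0.5 for iid noise, near 1 for
    strongly persistent (integrated) signals.  Returns NaN for constant
    input, where the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 256:
        raise ValueError("need at least 256 samples")
    if np.ptp(x) == 0:
        return float("nan")
    sizes = []
    w = min_window
    while w <= len(x) // 2:
        sizes.append(w)
        w *= 2
    log_w, log_rs = [], []
    for w in sizes:
        n_blocks = len(x) // w
        rs_vals = []
        for b in range(n_blocks):
            seg = x[b * w:(b + 1) * w]
            sd = seg.std()
            if sd == 0:
                continue
            dev = np.cumsum(seg - seg.mean())
            rs_vals.append(np.ptp(dev) / sd)
        if rs_vals:
            log_w.append(np.log(w))
            log_rs.append(np.log(np.mean(rs_vals)))
    if len(log_w) < 2:
        return float("nan")
    slope = np.polyfit(log_w, log_rs, 1)[0]
    return float(slope)
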