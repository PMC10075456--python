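"""Post-fit analyses of recovered parameter distributions.

Practical identifiability is quantified as the Jensen–Shannon divergence
between a parameter's recovered marginal distribution and the uniform
distribution over its search range (which approximates the prior the
optimisation started from).  Cohort differences use the same JSD plus
Cohen's d effect sizes; parameter-space geometry is examined with
classical multidimensional scaling of bound-normalised Euclidean
distances and silhouette scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import silhouette_score as _sk_silhouette

from .model import (
    PARAM_NAMES,
    LileyParameters,
    ParameterBounds,
    SimulationConfig,
    NoiseMode,
    sigmoid_firing_rate,
    simulate,
)

__all__ = [
    "ParameterSample",
    "ComparisonReport",
    "jsd",
    "identifiability_jsd",
    "cohort_compare",
    "cohens_d",
    "mds_embed",
    "silhouette_score",
    "population_summaries",
    "mannwhitney_bonferroni",
]

LN2 = float(np.log(2.0))


@dataclass
class ParameterSample:
    """Pooled optimal decision vectors (rows) with their provenance labels."""

    matrix: np.ndarray                  # (n, g), canonical parameter order
    labels: np.ndarray                  # per-row algorithm/cohort/replicate tag
    bounds: ParameterBounds

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.matrix):
            raise ValueError("labels must align with rows")

    def normalised(self) -> np.ndarray:
        return (self.matrix - self.bounds.lower) / self.bounds.width


@dataclass
class ComparisonReport:
    param_names: tuple[str, ...]
    jsd_values: np.ndarray
    cohens_d: np.ndarray
    silhouette_2d: float | None = None
    silhouette_full: float | None = None
    mds_coords: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _entropy(p: np.ndarray) -> float:
    # Shannon entropy in nats with the 0 log 0 := 0 convention
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def jsd(p, q) -> float:
    """Jensen–Shannon divergence H((p+q)/2) - H(p)/2 - H(q)/2, in nats.

    Symmetric, bounded in [0, ln 2], zero iff p == q.  Inputs must be
    probability vectors of equal length.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("inputs must sum to 1")
    return _entropy((p + q) / 2.0) - 0.5 * _entropy(p) - 0.5 * _entropy(q)


def _binned(values: np.ndarray, lo: float, hi: float, nbins: int) -> np.ndarray:
    counts, _ = np.histogram(values, bins=nbins, range=(lo, hi))
    total = counts.sum()
    if total == 0:
        raise ValueError("no sample values fall inside the bounds")
    return counts / total


def identifiability_jsd(sample: ParameterSample, param_index: int,
                        nbins: int = 100) -> float:
    """Deviation of one parameter's marginal from the uniform prior.

    The marginal is histogrammed on ``nbins`` equal bins spanning the full
    search range; the reference is 1/nbins per bin.  Higher values mean the
    data (through the fit) constrain the parameter more — better practical
    identifiability.
    """
    if len(sample.matrix) < 2:
        raise ValueError("need at least 2 sample rows")
    lo = sample.bounds.lower[param_index]
    hi = sample.bounds.upper[param_index]
    emp = _binned(sample.matrix[:, param_index], lo, hi, nbins)
    uniform = np.full(nbins, 1.0 / nbins)
    return jsd(emp, uniform)


def cohens_d(a, b) -> float:
    """(mean_a - mean_b) / pooled sd, pooled variance weighted by (n - 1).

    NaN when the pooled standard deviation is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    denom = na + nb - 2
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / denom) if denom > 0 else 0.0
    if pooled == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def cohort_compare(sample_a: ParameterSample, sample_b: ParameterSample,
                   nbins: int = 100) -> ComparisonReport:
    """Per-parameter JSD and Cohen's d between two cohorts.

    Both marginals are histogrammed on the same grid spanning the shared
    optimisation bounds, so empty-bin handling is identical for both.
    Cohen's d is signed cohort_a minus cohort_b.
    """
    if not np.array_equal(sample_a.bounds.lower, sample_b.bounds.lower) or \
       not np.array_equal(sample_a.bounds.upper, sample_b.bounds.upper):
        raise ValueError("cohorts must share the optimisation bounds")
    g = sample_a.matrix.shape[1]
    jsd_vals = np.empty(g)
    d_vals = np.empty(g)
    for k in range(g):
        lo, hi = sample_a.bounds.lower[k], sample_a.bounds.upper[k]
        pa = _binned(sample_a.matrix[:, k], lo, hi, nbins)
        pb = _binned(sample_b.matrix[:, k], lo, hi, nbins)
        jsd_vals[k] = jsd(pa, pb)
        d_vals[k] = cohens_d(sample_a.matrix[:, k], sample_b.matrix[:, k])
    return ComparisonReport(param_names=PARAM_NAMES[:g], jsd_values=jsd_vals,
                            cohens_d=d_vals)


def mds_embed(sample: ParameterSample, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of bound-normalised Euclidean distances.

    Exact (up to rigid motion) when the normalised points are intrinsically
    ``n_components``-dimensional.  An all-identical sample maps to zeros.
    """
    X = sample.normalised()
    if len(X) < 3:
        raise ValueError("need at least 3 rows to embed")
    D2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    n = len(D2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    w_top = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w_top)


def silhouette_score(points, labels) -> float:
    """Mean silhouette (b - a)/max(a, b) over points, Euclidean distances.

    ``a`` is the mean within-cluster distance, ``b`` the smallest mean
    distance to another cluster; single-member clusters score 0.
    """
    labels = np.asarray(labels)
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points.reshape(-1, 1)
    if points.shape[0] != len(labels):
        raise ValueError("points and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 distinct labels")
    return float(_sk_silhouette(points, labels, metric="euclidean"))


def population_summaries(params: LileyParameters,
                         config: SimulationConfig) -> dict:
    """Time-averaged membrane potentials and firing rates of a simulation.

    Firing rates are the sigmoid applied pointwise along the trajectory,
    then averaged (not the sigmoid of the mean potential).  Divergent
    simulations are flagged with NaN summaries.
    """
    traj = simulate(params, config, record_hi=True)
    if traj.divergent:
        return {"divergent": True, "mean_he": float("nan"),
                "mean_hi": float("nan"), "mean_Se": float("nan"),
                "mean_Si": float("nan")}
    c = config.sigmoid_exponent
    Se = sigmoid_firing_rate(traj.samples, params.Se_max, params.mu_e,
                             params.sigma_e, c)
    Si = sigmoid_firing_rate(traj.hi_samples, params.Si_max, params.mu_i,
                             params.sigma_i, c)
    return {"divergent": False,
            "mean_he": float(np.mean(traj.samples)),
            "mean_hi": float(np.mean(traj.hi_samples)),
            "mean_Se": float(np.mean(Se)),
            "mean_Si": float(np.mean(Si))}


def mannwhitney_bonferroni(groups_a: list, groups_b: list) -> np.ndarray:
    """Mann–Whitney U p-values for paired comparisons, Bonferroni-corrected.

    Thin pass-through to scipy for the standard significance testing used
    alongside the effect sizes; nothing is re-derived.
    """
    m = len(groups_a)
    if m != len(groups_b):
        raise ValueError("need equally many comparison pairs")
    p = np.array([stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                  for a, b in zip(groups_a, groups_b)])
    return np.minimum(p * m, 1.0)
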