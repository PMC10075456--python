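"""Model–data discrepancy functions and the repeat-averaging protocol.

Three objectives, all to be minimised:

* ``psd20`` — sum of squared differences between the unit-sum power spectra
  of model and data over 2–20 Hz (linear power).
* ``psd45`` — the same over 2–45 Hz after pre-whitening, i.e. on the
  residuals of a robust 1/f fit in natural-log space.
* ``whvg`` — two-sample KS statistic between the node-strength
  distributions of the weighted horizontal visibility graphs.

Because the simulation is stochastic, each objective is averaged over
``n_repeats`` independently seeded simulations: the spectral objectives
average the model spectrum across repeats before differencing, the wHVG
objective averages the KS statistic.  Divergent simulations contribute a
large penalty rather than an error so an evolutionary search can discard
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import (
    PowerSpectrum,
    compute_psd,
    ks_statistic,
    node_strengths,
    prewhiten_psd,
)
from .model import LileyParameters, SimulationConfig, Trajectory, simulate

__all__ = [
    "PENALTY",
    "ALGORITHMS",
    "ObjectiveSpec",
    "DataFeatures",
    "objective_psd20",
    "objective_psd45",
    "objective_whvg",
    "evaluate_objectives",
    "algorithm_objectives",
]

#: Penalty per objective for a divergent simulation; orders of magnitude
#: above any achievable discrepancy.
PENALTY = 1.0e6

#: Algorithm menu: single-objective spectral fits and multi-objective
#: combinations with the wHVG objective.
ALGORITHMS = {
    "SOEA20": ("psd20",),
    "SOEA45": ("psd45",),
    "MOEA20": ("psd20", "whvg"),
    "MOEA45": ("psd45", "whvg"),
}

_BANDS = {"psd20": (2.0, 20.0), "psd45": (2.0, 45.0)}


@dataclass(frozen=True)
class ObjectiveSpec:
    """One objective: its kind, frequency band and spectral resolution."""

    kind: str                          # 'psd20' | 'psd45' | 'whvg'
    resolution: float = 0.125          # Hz; spectral objectives only

    def __post_init__(self) -> None:
        if self.kind not in ("psd20", "psd45", "whvg"):
            raise ValueError(f"unknown objective kind {self.kind!r}")

    @property
    def band(self) -> tuple[float, float] | None:
        return _BANDS.get(self.kind)


@dataclass
class DataFeatures:
    """Features of one data epoch, computed once and reused for every fit."""

    rate: float
    resolution: float
    psd20: PowerSpectrum
    psd45: PowerSpectrum
    psd45_residual: np.ndarray
    whvg_strengths: np.ndarray
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_series(cls, x, rate: float, resolution: float = 0.125,
                    meta: dict | None = None) -> "DataFeatures":
        x = np.asarray(x, dtype=float)
        p20 = compute_psd(x, rate, band=_BANDS["psd20"], resolution=resolution)
        p45 = compute_psd(x, rate, band=_BANDS["psd45"], resolution=resolution)
        return cls(rate=rate, resolution=resolution, psd20=p20, psd45=p45,
                   psd45_residual=prewhiten_psd(p45),
                   whvg_strengths=node_strengths(x), meta=meta or {})


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _model_series(traj: Trajectory) -> np.ndarray:
    # data epochs are z-scored; model output is compared on the same footing
    return traj.samples if traj.zscored else _zscore(traj.samples)


def objective_psd20(model: Trajectory, data: DataFeatures) -> float:
    """Spectral MSE over 2–20 Hz for one trajectory (no repeat averaging)."""
    if model.divergent:
        return PENALTY
    spec = compute_psd(_model_series(model), model.rate,
                       band=_BANDS["psd20"], resolution=data.resolution)
    return float(np.sum((data.psd20.power - spec.power) ** 2))


def objective_psd45(model: Trajectory, data: DataFeatures) -> float:
    """Pre-whitened log-spectral MSE over 2–45 Hz for one trajectory."""
    if model.divergent:
        return PENALTY
    spec = compute_psd(_model_series(model), model.rate,
                       band=_BANDS["psd45"], resolution=data.resolution)
    resid = prewhiten_psd(spec)
    return float(np.sum((data.psd45_residual - resid) ** 2))


def objective_whvg(model: Trajectory, data: DataFeatures) -> float:
    """KS distance between wHVG node-strength distributions, in [0, 1]."""
    if model.divergent:
        return PENALTY
    return ks_statistic(data.whvg_strengths, node_strengths(_model_series(model)))


def _repeat_seed(master_seed: int, individual_id: int, repeat: int) -> int:
    ss = np.random.SeedSequence((int(master_seed), int(individual_id), int(repeat)))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def evaluate_objectives(params: LileyParameters, data: DataFeatures,
                        specs: tuple[ObjectiveSpec, ...],
                        sim_config: SimulationConfig,
                        n_repeats: int = 5,
                        master_seed: int = 0,
                        individual_id: int = 0) -> np.ndarray:
    """Repeat-averaged objective vector for one parameter set.

    Runs ``n_repeats`` simulations with seeds derived deterministically
    from (master_seed, individual_id, repeat index).  Spectral objectives
    average the model PSD over the repeats before computing one MSE; the
    wHVG objective averages the per-repeat KS statistic.  Any divergent
    repeat contributes the penalty.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    trajs = []
    for r in range(n_repeats):
        cfg = sim_config.replace(seed=_repeat_seed(master_seed, individual_id, r))
        trajs.append(simulate(params, cfg))

    out = np.empty(len(specs))
    for k, spec in enumerate(specs):
        if spec.kind == "whvg":
            vals = [objective_whvg(t, data) for t in trajs]
            out[k] = float(np.mean(vals))
            continue
        band = spec.band
        powers, n_div = [], 0
        for t in trajs:
            if t.divergent:
                n_div += 1
                continue
            powers.append(compute_psd(_model_series(t), t.rate, band=band,
                                      resolution=data.resolution).power)
        if not powers:
            out[k] = PENALTY
            continue
        mean_power = np.mean(powers, axis=0)
        if spec.kind == "psd20":
            val = float(np.sum((data.psd20.power - mean_power) ** 2))
        else:
            resid = prewhiten_psd(PowerSpectrum(
                freqs=data.psd45.freqs, power=mean_power, band=band))
            val = float(np.sum((data.psd45_residual - resid) ** 2))
        # divergent repeats still penalise, pro-rated into the mean
        out[k] = (val * len(powers) + PENALTY * n_div) / n_repeats
    return out


def algorithm_objectives(algorithm: str,
                         resolution: float = 0.125) -> tuple[ObjectiveSpec, ...]:
    """Expand an algorithm name (SOEA20/SOEA45/MOEA20/MOEA45) to its objectives."""
    try:
        kinds = ALGORITHMS[algorithm]
    except KeyError:
        raise ValueError(f"unknown algorithm {algorithm!r}; "
                         f"choose from {sorted(ALGORITHMS)}") from None
    return tuple(ObjectiveSpec(kind=k, resolution=resolution) for k in kinds)
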