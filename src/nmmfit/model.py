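"""Liley neural mass model: parameters, stochastic simulation, fixed points.

The model describes a cortical macrocolumn as two interacting neuronal
populations (excitatory ``e``, inhibitory ``i``).  Mean soma membrane
potentials ``h_e, h_i`` evolve under four synaptic drives ``I_lk`` (synapses
of type ``l`` onto population ``k``) with second-order kinetics, and firing
rates are a sigmoid function of membrane potential.  Extrinsic input enters
the excitatory-to-excitatory drive as a Gaussian process with mean ``p_ee``
and noise amplitude ``xi``.  The excitatory membrane potential ``h_e(t)`` is
the model's EEG-like observable.

Internal units are millivolts and milliseconds throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from enum import Enum
from typing import Sequence

import numpy as np
from numba import njit
from scipy import optimize

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "LileyParameters",
    "ParameterBounds",
    "SimulationConfig",
    "Trajectory",
    "FixedPoint",
    "AttractorClass",
    "NoiseMode",
    "sigmoid_firing_rate",
    "drift",
    "simulate",
    "find_fixed_points",
    "jacobian",
    "jacobian_eigenvalues",
    "classify_attractor",
]

#: Canonical ordering of the decision vector (model parameters + noise amplitude).
PARAM_NAMES: tuple[str, ...] = (
    "he_rest", "hi_rest",
    "N_ee", "N_ei", "N_ie", "N_ii",
    "Gamma_e", "Gamma_i",
    "gamma_e", "gamma_i",
    "tau_e", "tau_i",
    "Se_max", "Si_max",
    "mu_e", "mu_i",
    "sigma_e", "sigma_i",
    "he_eq", "hi_eq",
    "p_ee", "p_ei",
    "xi",
)

#: Ordering of the ten first-order state variables.
STATE_NAMES: tuple[str, ...] = (
    "he", "hi",
    "I_ee", "I_ei", "I_ie", "I_ii",
    "J_ee", "J_ei", "J_ie", "J_ii",
)

N_PARAMS = len(PARAM_NAMES)
N_STATES = len(STATE_NAMES)

#: Divergence guard on |h_e| (mV): trajectories beyond this are flagged.
DIVERGENCE_LIMIT = 1.0e4


class NoiseMode(str, Enum):
    """How the extrinsic input fluctuation is discretised."""

    #: Euler–Maruyama white-noise increment on J_ee, dt-independent statistics.
    white_noise = "white_noise"
    #: Independent per-step draw p_k ~ N(p_ee, xi^2) in the drift.
    per_step_gaussian = "per_step_gaussian"
    #: Deterministic ODE path, p(t) = p_ee.
    off = "off"


class AttractorClass(str, Enum):
    noise_driven_fixed_point = "noise_driven_fixed_point"
    noise_driven_limit_cycle = "noise_driven_limit_cycle"
    unstable_or_divergent = "unstable_or_divergent"


@dataclass(frozen=True)
class LileyParameters:
    """The model's free parameters (Table-typical defaults where published).

    Units: potentials mV; rate constants 1/ms; time constants ms;
    connection counts and ``xi`` dimensionless amplitudes; input rates 1/ms.
    """

    he_rest: float = -70.0
    hi_rest: float = -70.0
    N_ee: float = 4000.0
    N_ei: float = 3034.0
    N_ie: float = 536.0
    N_ii: float = 536.0
    Gamma_e: float = 0.4
    Gamma_i: float = 0.8
    gamma_e: float = 0.3
    gamma_i: float = 0.065
    tau_e: float = 10.0
    tau_i: float = 10.0
    Se_max: float = 0.5
    Si_max: float = 0.5
    mu_e: float = -50.0
    mu_i: float = -50.0
    sigma_e: float = 5.0
    sigma_i: float = 5.0
    he_eq: float = -15.0
    hi_eq: float = -78.0
    p_ee: float = 1.0
    p_ei: float = 4.0
    xi: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_e <= 0 or self.sigma_i <= 0:
            raise ValueError("firing threshold spreads sigma_e, sigma_i must be > 0")
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("membrane time constants must be > 0")
        if self.gamma_e <= 0 or self.gamma_i <= 0:
            raise ValueError("postsynaptic rate constants must be > 0")
        for lhs, rhs in (
            (self.he_eq, self.he_rest), (self.hi_eq, self.hi_rest),
            (self.he_eq, self.hi_rest), (self.hi_eq, self.he_rest),
        ):
            if lhs == rhs:
                raise ValueError("reversal potentials must differ from resting potentials")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "LileyParameters":
        v = np.asarray(v, dtype=float)
        if v.shape != (N_PARAMS,):
            raise ValueError(f"expected a {N_PARAMS}-vector, got shape {v.shape}")
        return cls(**dict(zip(PARAM_NAMES, v.tolist())))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LileyParameters":
        return cls(**json.loads(text))

    def replace(self, **kw) -> "LileyParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class ParameterBounds:
    """Elementwise box bounds on the decision vector, canonical ordering."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)
        if lo.ndim != 1 or lo.shape != up.shape:
            raise ValueError("bounds must be equal-length 1-d vectors")
        if not np.all(lo < up):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, v: np.ndarray) -> bool:
        v = np.asarray(v, dtype=float)
        return bool(np.all(v >= self.lower) and np.all(v <= self.upper))

    def normalise(self, v: np.ndarray) -> np.ndarray:
        """Map decision vectors into the unit box (per-gene [0, 1])."""
        return (np.asarray(v, dtype=float) - self.lower) / self.width

    @classmethod
    def physiological(cls) -> "ParameterBounds":
        """The typically used physiological search ranges."""
        table = {
            "he_rest": (-80.0, -60.0), "hi_rest": (-80.0, -60.0),
            "N_ee": (2000.0, 5000.0), "N_ei": (2000.0, 5000.0),
            "N_ie": (100.0, 1000.0), "N_ii": (100.0, 1000.0),
            "Gamma_e": (0.1, 2.0), "Gamma_i": (0.1, 2.0),
            "gamma_e": (0.1, 1.0), "gamma_i": (0.01, 0.5),
            "tau_e": (5.0, 150.0), "tau_i": (5.0, 150.0),
            "Se_max": (0.05, 0.5), "Si_max": (0.05, 0.5),
            "mu_e": (-55.0, -40.0), "mu_i": (-55.0, -40.0),
            "sigma_e": (2.0, 7.0), "sigma_i": (2.0, 7.0),
            "he_eq": (-20.0, -10.0), "hi_eq": (-90.0, -65.0),
            "p_ee": (0.0, 10.0), "p_ei": (0.0, 10.0),
            "xi": (0.0, 10.0),
        }
        lo = np.array([table[k][0] for k in PARAM_NAMES])
        up = np.array([table[k][1] for k in PARAM_NAMES])
        return cls(lo, up)

    def to_json(self) -> str:
        return json.dumps(
            {k: [self.lower[i], self.upper[i]] for i, k in enumerate(PARAM_NAMES)},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ParameterBounds":
        d = json.loads(text)
        lo = np.array([d[k][0] for k in PARAM_NAMES])
        up = np.array([d[k][1] for k in PARAM_NAMES])
        return cls(lo, up)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    dt in ms; duration and transient in s; output_rate in samples/s.
    ``sigmoid_exponent`` is the constant c in exp(-c (h - mu)/sigma); the
    printed form of the firing function uses c=2 (the historical variant
    uses sqrt(2)), so c is configurable and recorded in all metadata.
    """

    dt: float = 0.0125
    duration: float = 20.0
    transient: float = 5.0
    output_rate: float = 256.0
    noise_mode: NoiseMode = NoiseMode.white_noise
    seed: int = 0
    sigmoid_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0 or self.transient < 0:
            raise ValueError("dt > 0, duration > 0, transient >= 0 required")
        if self.output_rate <= 0:
            raise ValueError("output_rate must be > 0")
        if 1000.0 / (self.dt * self.output_rate) < 1.0:
            raise ValueError("output_rate exceeds the integration rate")
        object.__setattr__(self, "noise_mode", NoiseMode(self.noise_mode))

    @property
    def n_steps(self) -> int:
        return int(round((self.transient + self.duration) * 1000.0 / self.dt))

    @property
    def n_output(self) -> int:
        return int(round(self.duration * self.output_rate))

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """Resampled excitatory membrane potential — the model's observable."""

    samples: np.ndarray          # h_e at output_rate, mV (or z-scored if flagged)
    rate: float
    divergent: bool = False
    zscored: bool = False
    hi_samples: np.ndarray | None = None   # h_i on the same grid, when recorded
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class FixedPoint:
    """A steady state of the deterministic model with its linearisation."""

    state: np.ndarray            # 10-vector in STATE_NAMES order
    eigenvalues: np.ndarray      # 10 complex eigenvalues, 1/ms
    dominant_real: float         # max real part, 1/ms
    stable: bool

    @property
    def he(self) -> float:
        return float(self.state[0])

    @property
    def hi(self) -> float:
        return float(self.state[1])


# ---------------------------------------------------------------------------
# firing rate and drift

def sigmoid_firing_rate(h, Smax: float, mu: float, sigma: float, c: float = 2.0):
    """Mean firing rate S(h) = Smax / (1 + exp(-c (h - mu) / sigma)).

    Monotone increasing in h, saturating at Smax, with S(mu) = Smax / 2.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if Smax <= 0:
        raise ValueError("Smax must be > 0")
    h = np.asarray(h, dtype=float)
    with np.errstate(over="ignore"):
        out = Smax / (1.0 + np.exp(-c * (h - mu) / sigma))
    return float(out) if out.ndim == 0 else out


def _sigmoid_deriv(h: float, Smax: float, mu: float, sigma: float, c: float) -> float:
    s = sigmoid_firing_rate(h, Smax, mu, sigma, c)
    return (c / sigma) * s * (1.0 - s / Smax)


def drift(state: Sequence[float], params: LileyParameters,
          p_input: float | None = None, c: float = 2.0) -> np.ndarray:
    """Time derivative of the ten-dimensional state.

    The four second-order synaptic equations are written as pairs
    (I' = J,  J' = RHS - 2 gamma J - gamma^2 I).  ``p_input`` is the
    instantaneous excitatory extrinsic input; defaults to ``p_ee``.
    May be any real number — stochastic forcing is not clipped.
    """
    s = np.asarray(state, dtype=float)
    if s.shape != (N_STATES,):
        raise ValueError(f"state must be a {N_STATES}-vector")
    p = params
    if p_input is None:
        p_input = p.p_ee
    he, hi, I_ee, I_ei, I_ie, I_ii, J_ee, J_ei, J_ie, J_ii = s

    Se = sigmoid_firing_rate(he, p.Se_max, p.mu_e, p.sigma_e, c)
    Si = sigmoid_firing_rate(hi, p.Si_max, p.mu_i, p.sigma_i, c)
    e = math.e

    # membrane-potential weighting terms (h_eq - h) / |h_eq - h_rest|
    w_ee = (p.he_eq - he) / abs(p.he_eq - p.he_rest)
    w_ie = (p.hi_eq - he) / abs(p.hi_eq - p.he_rest)
    w_ei = (p.he_eq - hi) / abs(p.he_eq - p.hi_rest)
    w_ii = (p.hi_eq - hi) / abs(p.hi_eq - p.hi_rest)

    dhe = (p.he_rest - he + w_ee * I_ee + w_ie * I_ie) / p.tau_e
    dhi = (p.hi_rest - hi + w_ei * I_ei + w_ii * I_ii) / p.tau_i

    dJ_ee = p.Gamma_e * p.gamma_e * e * (p.N_ee * Se + p_input) \
        - 2.0 * p.gamma_e * J_ee - p.gamma_e ** 2 * I_ee
    dJ_ei = p.Gamma_e * p.gamma_e * e * (p.N_ei * Se + p.p_ei) \
        - 2.0 * p.gamma_e * J_ei - p.gamma_e ** 2 * I_ei
    dJ_ie = p.Gamma_i * p.gamma_i * e * (p.N_ie * Si) \
        - 2.0 * p.gamma_i * J_ie - p.gamma_i ** 2 * I_ie
    dJ_ii = p.Gamma_i * p.gamma_i * e * (p.N_ii * Si) \
        - 2.0 * p.gamma_i * J_ii - p.gamma_i ** 2 * I_ii

    return np.array([dhe, dhi, J_ee, J_ei, J_ie, J_ii,
                     dJ_ee, dJ_ei, dJ_ie, dJ_ii])


# ---------------------------------------------------------------------------
# compiled Euler–Maruyama kernel

@njit(cache=True)
def _integrate(theta, c, dt, n_steps, noise, noise_mode):  # pragma: no cover
    """Fixed-step Euler–Maruyama from zero initial conditions.

    noise_mode: 0 = white noise increment on J_ee, 1 = per-step Gaussian
    input, 2 = deterministic.  Returns (he_path, hi_path, divergent_at)
    where divergent_at < 0 means the path stayed bounded and finite.
    """
    (he_rest, hi_rest, N_ee, N_ei, N_ie, N_ii, Gamma_e, Gamma_i,
     gamma_e, gamma_i, tau_e, tau_i, Se_max, Si_max, mu_e, mu_i,
     sigma_e, sigma_i, he_eq, hi_eq, p_ee, p_ei, xi) = theta

    e = math.e
    a_ee = 1.0 / abs(he_eq - he_rest)
    a_ie = 1.0 / abs(hi_eq - he_rest)
    a_ei = 1.0 / abs(he_eq - hi_rest)
    a_ii = 1.0 / abs(hi_eq - hi_rest)

    he = 0.0
    hi = 0.0
    I_ee = 0.0
    I_ei = 0.0
    I_ie = 0.0
    I_ii = 0.0
    J_ee = 0.0
    J_ei = 0.0
    J_ie = 0.0
    J_ii = 0.0

    he_path = np.empty(n_steps + 1)
    hi_path = np.empty(n_steps + 1)
    he_path[0] = he
    hi_path[0] = hi

    sqrt_dt = math.sqrt(dt)
    diverged = -1

    for k in range(n_steps):
        Se = Se_max / (1.0 + math.exp(-c * (he - mu_e) / sigma_e))
        Si = Si_max / (1.0 + math.exp(-c * (hi - mu_i) / sigma_i))

        p_in = p_ee
        if noise_mode == 1:
            p_in = p_ee + xi * noise[k]

        dhe = (he_rest - he + (he_eq - he) * a_ee * I_ee
               + (hi_eq - he) * a_ie * I_ie) / tau_e
        dhi = (hi_rest - hi + (he_eq - hi) * a_ei * I_ei
               + (hi_eq - hi) * a_ii * I_ii) / tau_i
        dJ_ee = Gamma_e * gamma_e * e * (N_ee * Se + p_in) \
            - 2.0 * gamma_e * J_ee - gamma_e * gamma_e * I_ee
        dJ_ei = Gamma_e * gamma_e * e * (N_ei * Se + p_ei) \
            - 2.0 * gamma_e * J_ei - gamma_e * gamma_e * I_ei
        dJ_ie = Gamma_i * gamma_i * e * (N_ie * Si) \
            - 2.0 * gamma_i * J_ie - gamma_i * gamma_i * I_ie
        dJ_ii = Gamma_i * gamma_i * e * (N_ii * Si) \
            - 2.0 * gamma_i * J_ii - gamma_i * gamma_i * I_ii

        he += dt * dhe
        hi += dt * dhi
        I_ee += dt * J_ee
        I_ei += dt * J_ei
        I_ie += dt * J_ie
        I_ii += dt * J_ii
        J_ee += dt * dJ_ee
        J_ei += dt * dJ_ei
        J_ie += dt * dJ_ie
        J_ii += dt * dJ_ii

        if noise_mode == 0:
            J_ee += Gamma_e * gamma_e * e * xi * sqrt_dt * noise[k]

        he_path[k + 1] = he
        hi_path[k + 1] = hi

        if not (math.isfinite(he) and math.isfinite(hi)) or abs(he) > 1.0e4:
            diverged = k + 1
            for j in range(k + 2, n_steps + 1):
                he_path[j] = he_path[k + 1]
                hi_path[j] = hi_path[k + 1]
            break

    return he_path, hi_path, diverged


_NOISE_CODE = {NoiseMode.white_noise: 0, NoiseMode.per_step_gaussian: 1,
               NoiseMode.off: 2}


def simulate(params: LileyParameters, config: SimulationConfig,
             record_hi: bool = False) -> Trajectory:
    """Integrate the model and return h_e resampled to the output rate.

    Euler–Maruyama at step ``config.dt`` from zero initial conditions; the
    first ``config.transient`` seconds are discarded and h_e is linearly
    interpolated onto the uniform grid at ``config.output_rate``.  A pure
    function of (params, config): the same seed gives bit-identical output.
    Divergent paths (|h_e| > 1e4 mV or non-finite) are returned flagged,
    never raised.
    """
    theta = params.to_vector()
    n_steps = config.n_steps
    mode = _NOISE_CODE[config.noise_mode]
    if mode == 2:
        noise = np.empty(0)
    else:
        noise = np.random.default_rng(config.seed).standard_normal(n_steps)

    he_path, hi_path, diverged = _integrate(
        theta, config.sigmoid_exponent, config.dt, n_steps, noise, mode)

    # output grid (ms), exact at sample instants
    t_grid = config.transient * 1000.0 + np.arange(config.n_output) * (1000.0 / config.output_rate)
    t_steps = np.arange(n_steps + 1) * config.dt
    samples = np.interp(t_grid, t_steps, he_path)
    hi_samples = np.interp(t_grid, t_steps, hi_path) if record_hi else None

    divergent = diverged >= 0 or not np.all(np.isfinite(samples))
    meta = {
        "params": asdict(params),
        "config": {
            "dt": config.dt, "duration": config.duration,
            "transient": config.transient, "output_rate": config.output_rate,
            "noise_mode": config.noise_mode.value, "seed": config.seed,
            "sigmoid_exponent": config.sigmoid_exponent,
        },
    }
    return Trajectory(samples=samples, rate=config.output_rate,
                      divergent=divergent, hi_samples=hi_samples, meta=meta)


# ---------------------------------------------------------------------------
# fixed points, Jacobian, attractor classification

def _steady_currents(he: float, hi: float, p: LileyParameters, c: float):
    """Steady-state synaptic drives I* = Gamma e (N S + input) / gamma."""
    Se = sigmoid_firing_rate(he, p.Se_max, p.mu_e, p.sigma_e, c)
    Si = sigmoid_firing_rate(hi, p.Si_max, p.mu_i, p.sigma_i, c)
    e = math.e
    I_ee = p.Gamma_e * e * (p.N_ee * Se + p.p_ee) / p.gamma_e
    I_ei = p.Gamma_e * e * (p.N_ei * Se + p.p_ei) / p.gamma_e
    I_ie = p.Gamma_i * e * (p.N_ie * Si) / p.gamma_i
    I_ii = p.Gamma_i * e * (p.N_ii * Si) / p.gamma_i
    return I_ee, I_ei, I_ie, I_ii


def _reduced_residual(hh: np.ndarray, p: LileyParameters, c: float) -> np.ndarray:
    he, hi = hh
    I_ee, I_ei, I_ie, I_ii = _steady_currents(he, hi, p, c)
    f1 = (p.he_rest - he
          + (p.he_eq - he) / abs(p.he_eq - p.he_rest) * I_ee
          + (p.hi_eq - he) / abs(p.hi_eq - p.he_rest) * I_ie)
    f2 = (p.hi_rest - hi
          + (p.he_eq - hi) / abs(p.he_eq - p.hi_rest) * I_ei
          + (p.hi_eq - hi) / abs(p.hi_eq - p.hi_rest) * I_ii)
    return np.array([f1, f2])


def find_fixed_points(params: LileyParameters, c: float = 2.0,
                      grid: int = 20, box=((-90.0, -10.0), (-90.0, -10.0)),
                      tol: float = 1e-10) -> list[FixedPoint]:
    """All steady states of the deterministic model with p(t) = p_ee.

    The ten-dimensional steady state reduces to two equations in
    (h_e, h_i) by eliminating the synaptic drives at their equilibria.
    Roots are sought from a ``grid`` x ``grid`` lattice of starts over the
    membrane-potential box, deduplicated at 1e-6 mV, sorted by h_e, and
    verified to have full drift norm below ``tol``.  Returns [] if no
    start converges.
    """
    (he_lo, he_hi), (hi_lo, hi_hi) = box
    starts_e = np.linspace(he_lo, he_hi, grid)
    starts_i = np.linspace(hi_lo, hi_hi, grid)
    roots: list[np.ndarray] = []
    for he0 in starts_e:
        for hi0 in starts_i:
            sol = optimize.root(_reduced_residual, np.array([he0, hi0]),
                                args=(params, c), method="hybr",
                                options={"xtol": 1e-13})
            if not sol.success or np.max(np.abs(sol.fun)) > 1e-9:
                continue
            r = sol.x
            if any(np.max(np.abs(r - q)) < 1e-6 for q in roots):
                continue
            roots.append(r)
    out = []
    for r in sorted(roots, key=lambda q: q[0]):
        he, hi = r
        I = _steady_currents(he, hi, params, c)
        state = np.array([he, hi, *I, 0.0, 0.0, 0.0, 0.0])
        if np.linalg.norm(drift(state, params, c=c)) > tol:
            continue
        ev = np.linalg.eigvals(jacobian(state, params, c=c))
        dom = float(np.max(ev.real))
        out.append(FixedPoint(state=state, eigenvalues=ev,
                              dominant_real=dom, stable=dom < 0.0))
    return out


def jacobian(state: Sequence[float], params: LileyParameters,
             c: float = 2.0) -> np.ndarray:
    """Analytic 10x10 Jacobian of the drift at ``state``."""
    s = np.asarray(state, dtype=float)
    p = params
    he, hi = s[0], s[1]
    I_ee, I_ei, I_ie, I_ii = s[2:6]
    e = math.e

    a_ee = 1.0 / abs(p.he_eq - p.he_rest)
    a_ie = 1.0 / abs(p.hi_eq - p.he_rest)
    a_ei = 1.0 / abs(p.he_eq - p.hi_rest)
    a_ii = 1.0 / abs(p.hi_eq - p.hi_rest)

    dSe = _sigmoid_deriv(he, p.Se_max, p.mu_e, p.sigma_e, c)
    dSi = _sigmoid_deriv(hi, p.Si_max, p.mu_i, p.sigma_i, c)

    J = np.zeros((N_STATES, N_STATES))
    # dhe/dt row
    J[0, 0] = (-1.0 - a_ee * I_ee - a_ie * I_ie) / p.tau_e
    J[0, 2] = (p.he_eq - he) * a_ee / p.tau_e
    J[0, 4] = (p.hi_eq - he) * a_ie / p.tau_e
    # dhi/dt row
    J[1, 1] = (-1.0 - a_ei * I_ei - a_ii * I_ii) / p.tau_i
    J[1, 3] = (p.he_eq - hi) * a_ei / p.tau_i
    J[1, 5] = (p.hi_eq - hi) * a_ii / p.tau_i
    # I' = J rows
    for i in range(4):
        J[2 + i, 6 + i] = 1.0
    # J' rows
    ge, gi = p.gamma_e, p.gamma_i
    J[6, 0] = p.Gamma_e * ge * e * p.N_ee * dSe
    J[6, 2] = -ge ** 2
    J[6, 6] = -2.0 * ge
    J[7, 0] = p.Gamma_e * ge * e * p.N_ei * dSe
    J[7, 3] = -ge ** 2
    J[7, 7] = -2.0 * ge
    J[8, 1] = p.Gamma_i * gi * e * p.N_ie * dSi
    J[8, 4] = -gi ** 2
    J[8, 8] = -2.0 * gi
    J[9, 1] = p.Gamma_i * gi * e * p.N_ii * dSi
    J[9, 5] = -gi ** 2
    J[9, 9] = -2.0 * gi
    return J


def jacobian_eigenvalues(params: LileyParameters, fp: Sequence[float],
                         c: float = 2.0, tol: float = 1e-8) -> np.ndarray:
    """Eigenvalues of the analytic Jacobian at a verified fixed point."""
    fp = np.asarray(fp, dtype=float)
    if np.linalg.norm(drift(fp, params, c=c)) > tol:
        raise ValueError("state is not a fixed point (drift norm above tolerance)")
    return np.linalg.eigvals(jacobian(fp, params, c=c))


def classify_attractor(params: LileyParameters,
                       config: SimulationConfig | None = None,
                       ptp_threshold: float = 0.1) -> AttractorClass:
    """Classify the deterministic attractor behind the stochastic dynamics.

    A long noise-free simulation decides: divergence -> unstable; sustained
    terminal oscillation (peak-to-peak h_e over the last 2 s above
    ``ptp_threshold`` mV) -> limit cycle; otherwise convergence to a
    (noise-driven) fixed point.
    """
    if config is None:
        config = SimulationConfig(duration=10.0, transient=5.0)
    cfg = config.replace(noise_mode=NoiseMode.off)
    traj = simulate(params, cfg)
    if traj.divergent:
        return AttractorClass.unstable_or_divergent
    n_tail = int(round(min(2.0, cfg.duration) * cfg.output_rate))
    tail = traj.samples[-n_tail:]
    if np.ptp(tail) > ptp_threshold:
        return AttractorClass.noise_driven_limit_cycle
    return AttractorClass.noise_driven_fixed_point
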