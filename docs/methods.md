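# Methods

## The model

`nmmfit` simulates the spatially homogeneous Liley mean-field model of a
cortical macrocolumn: two coupled neuronal populations (excitatory `e`,
inhibitory `i`) whose mean soma membrane potentials `h_e(t)`, `h_i(t)`
relax toward rest and are driven by four synaptic activities `I_lk(t)`
(synapses of type `l` on population `k`) with critically damped
second-order kinetics,

    tau_k dh_k/dt = h_k^rest - h_k
                    + sum_l (h_l^eq - h_k)/|h_l^eq - h_k^rest| * I_lk,

    d^2 I_lk/dt^2 + 2 gamma_l dI_lk/dt + gamma_l^2 I_lk
        = Gamma_l gamma_l e (N_lk S_l(h_l) + input_lk),

with `S_j(h) = Sj_max / (1 + exp(-c (h - mu_j)/sigma_j))` mapping membrane
potential to firing rate. The excitatory drive receives extrinsic input
`p(t)`, a Gaussian process with mean `p_ee` and amplitude `xi`; the
excitatory-to-inhibitory drive receives the constant rate `p_ei`. The
observable is `h_e(t)`, taken as linearly proportional to EEG. Rewriting
the four second-order equations as pairs gives a ten-dimensional SDE
system. Internal units are mV and ms.

Two conventions that vary across the modelling literature are exposed as
configuration rather than silently resolved:

* **Sigmoid exponent** — the firing function appears both with
  `exp(-2(h-mu)/sigma)` and with `sqrt(2)` in place of 2. The constant `c`
  defaults to 2 (`SimulationConfig.sigmoid_exponent`) and is recorded in
  all trajectory metadata.
* **Noise discretisation** — `xi` is described in different accounts as a
  variance or as a standard deviation. The default `white_noise` mode adds an
  Euler–Maruyama increment `Gamma_e * gamma_e * e * xi * sqrt(dt) * N(0,1)`
  to the `J_ee` equation, giving dt-independent output statistics with
  `xi` as an amplitude; the alternative `per_step_gaussian` mode draws
  `p_k ~ N(p_ee, xi^2)` independently each step. Noise is never clipped at
  zero: the synaptic equations accept any real forcing, and clipping would
  bias the noise mean.

## Integration and numerical choices

The SDE system is integrated by fixed-step Euler–Maruyama at `dt = 0.0125 ms`
from zero initial conditions; an initial transient (default 5 s) is
discarded, and `h_e` is linearly interpolated onto the uniform output grid
(default 256 samples/s). The 80 kHz-to-256 Hz resampling factor is
non-integer; linear interpolation is exact at sample instants, and no
anti-alias filter is applied because the comparison data receive only a
2 Hz high-pass. With noise off the scheme is plain Euler and is verified
first-order against an adaptive Runge–Kutta reference.

A trajectory with `|h_e| > 1e4 mV` or non-finite values is *flagged*
divergent, never raised: evolutionary populations routinely contain
pathological parameter sets, and the objectives convert the flag into a
large penalty (1e6 per objective, orders of magnitude above any achievable
discrepancy).

Default parameter values follow the published typical values where they
exist. Four quantities have only ranges (`he_eq`, `hi_eq`, `p_ee`,
`p_ei`); the package defaults (−15, −78, 1.0, 4.0) place the default
operating point in the model's canonical quiescent regime — a strongly
stable focus (dominant eigenvalue ≈ −0.039/ms) around which noise sustains
rhythmic fluctuations. This is the regime in which the vast majority of
resting-state fits land, and it is also the regime in which the
fixed-step integrator's ODE limit can meaningfully be compared with an
adaptive reference: on a limit cycle, phase drift makes the absolute
trajectory error of *any* first-order scheme large even when the
dynamics are faithful. Raising `p_ee` to ≈3/ms carries the default point
through an oscillatory instability and is used in tests to construct
limit-cycle examples.

Fixed points are found by reducing the ten-dimensional steady state to two
equations in `(h_e, h_i)` (the synaptic activities are eliminated at their
equilibria `I* = Gamma e (N S + input) / gamma`), multi-start root-finding
from a 20×20 grid of starts over [−90, −10]² mV, deduplicating roots at
1e-6 mV and verifying the full drift norm below 1e-10. The 10×10 Jacobian
is analytic and checked against central finite differences. Attractors are
classified from a long noise-free simulation: divergence → unstable;
terminal 2 s peak-to-peak `h_e` above 0.1 mV (configurable; separates
genuine cycles from numerical ringing) → noise-driven limit cycle;
otherwise noise-driven fixed point.

## Objectives

Data epochs and model trajectories are compared after z-scoring both, so
all objectives are invariant to the unknown EEG gain:

* **psd20** — sum of squared differences between unit-sum Welch power
  spectra over 2–20 Hz. The spectral resolution is set by the Welch
  segment length (`rate / resolution` samples, Hann window, 50% overlap);
  0.125 Hz (8 s segments) reproduces the published resolution on 20 s
  epochs, while desk-scale 2 s epochs use 0.5 Hz. Normalising to unit sum
  over the compared band means spectral *shape* is compared and amplitude
  cancels.
* **psd45** — the same over 2–45 Hz after pre-whitening: a robust
  (iteratively reweighted least squares, bisquare) linear fit in
  natural-log–log space is subtracted, removing the 1/f background. The
  objective is the sum of squared residual differences.
* **whvg** — the two-sample Kolmogorov–Smirnov statistic between the
  node-strength distributions of the weighted horizontal visibility
  graphs. The wHVG links time points `i < j` when all intermediate samples
  lie strictly below both endpoints (ties block visibility, as the strict
  inequality dictates); each edge carries the signed amplitude difference
  (latter minus former), and a node's strength is the sum of its incident
  weights. The KS statistic is computed on raw strengths, not on the
  100-bin density used for visualisation.

Because simulations are stochastic, objectives are averaged over
`n_repeats` simulations with seeds derived deterministically from
(master seed, individual id, repeat index). The spectral objectives
average the model spectrum across repeats *before* differencing (the
spectral MSE is defined on the mean model spectrum); the wHVG objective
averages the per-repeat KS statistic.

## The evolutionary search

Canonical NSGA-II over the box-bounded parameter vector (the 22 model
parameters plus the noise amplitude `xi`, all bounded by the published
physiological ranges): Latin hypercube initialisation (exactly one sample
per stratum per dimension), fast non-dominated sorting, crowding distance
with infinite boundary sentinels, binary tournament on (rank, crowding),
scattered crossover (per-gene uniform parent mask) on 80% of offspring,
and Gaussian mutation (sd 5% of bound width, reflected at the bounds) on
the rest, with elitist (mu+lambda) truncation. An optional geometric
annealing of the mutation scale is available (`mutation_sigma_final`) but
off by default. Parents keep cached objective values within a run;
offspring are always evaluated fresh. A single objective degenerates to an
elitist GA.

The algorithm menu mirrors the four fitting strategies: SOEA20/SOEA45
(single spectral objective) and MOEA20/MOEA45 (spectral + wHVG). From the
final non-dominated set one representative is selected: objectives are
divided by their front means and the member with the smallest Euclidean
norm is chosen (ties break to the lowest index, for determinism).
Convergence is tracked per generation by the hypervolume of the rank-0
front against a reference fixed at 1.1× the componentwise maximum of the
generation-0 objectives (exact sweep algorithm, up to three objectives)
and by the best mean-normalised distance to the objective-space origin.
With crowding-based truncation the hypervolume is exactly monotone only
while the front fits inside the population; on continuous fronts small
dips are expected and normal.

Desk-scale defaults are population 100, 20 generations, 3 repeats and 2 s
epochs — sized so a full fit completes in minutes on one CPU while still
demonstrating convergence; cohort-scale settings (population 500, 50
generations, 5 repeats, 20 s epochs) are one configuration switch away.

## Analyses

Practical identifiability of a parameter is the Jensen–Shannon divergence
(natural log, so values lie in [0, ln 2 ≈ 0.693]) between its marginal
distribution over pooled replicate optima — histogrammed on 100 equal bins
spanning the full search range — and the uniform distribution that
approximates the optimisation prior. Cohort comparisons use the same
100-bin JSD on the shared bound range (identical empty-bin handling for
both cohorts, `0·log 0 = 0`, no pseudo-counts) plus Cohen's d with
(n−1)-weighted pooled variance, signed first-cohort minus second.
Parameter-space geometry uses classical (Torgerson) multidimensional
scaling of Euclidean distances between bound-normalised decision vectors —
exact up to rigid motion whenever the points are intrinsically planar —
and silhouette scores in both the 2-d embedding and the full normalised
space (single-member clusters score 0, the scikit-learn convention).
Physiological summaries time-average the membrane potentials and the
*pointwise* sigmoid-transformed firing rates over the post-transient
trajectory; on oscillatory trajectories this differs from transforming the
mean potential, and the pointwise convention is asserted by test.
Mann–Whitney U tests with Bonferroni correction are thin pass-throughs to
scipy.

## Synthetic data

The package ships no recordings. `generate_synthetic_subject` simulates
the model at known ground-truth parameters, resamples to 256 Hz and
applies the same chain as real data (2 Hz high-pass Butterworth, 4th
order, zero-phase; z-score); the truth is stored in the provenance. The
committed "alpha subject" parameter set was found by scanning the
physiological box for a unique, weakly stable focus (dominant eigenvalue
≈ −0.005/ms) whose noise-driven output peaks at 9–10 Hz across seeds —
an EEG-like waxing-and-waning alpha rhythm. Toy generators provide
monotone ramps, white noise, (modulated) sinusoids and a ~3 Hz
spike-and-wave caricature (sharp transient riding an asymmetric slow
wave, 2.3 s epochs) for waveform-sensitivity tests.

What the synthetic subject does *not* emulate: volume conduction and
montage effects, artefacts, non-stationarity beyond the model's own
dynamics, or inter-subject variability. Passing the recovery tests
therefore demonstrates that the pipeline can invert its own forward model
at desk scale — the study-design question the synthetic-subject
experiment addresses — not that parameters recovered from real EEG are
correct.

The zero-phase (forward–backward) high-pass is chosen because phase
distortion would corrupt the waveform-shape information the wHVG
objective depends on; the occipital channel selection defaults to
{O1, O2} with user override. Repeated preprocessing is nearly idempotent,
but not exactly: each zero-phase pass costs 6 dB at the 2 Hz cutoff, so
an epoch with a few percent of sub-4 Hz power shifts by a few percent RMS
on a second pass.

## Known limitations

* The recovered "ground truth" in a 23-gene sloppy model is a region, not
  a point: many distant parameter sets produce statistically equivalent
  dynamics, so bound-normalised distance to the generating truth improves
  only modestly over a random initial population at desk scale, and the
  stochastic objectives have statistical floors (for 512-sample epochs the
  KS objective cannot fall much below ~0.03 even at the generating
  parameters).
* The search will not bit-match the original study's optimiser: mutation
  and selection details of that toolbox are unpublished, and the operator
  set here is the canonical one.
* The rescaled-range Hurst estimator is a convenience diagnostic; no
  specific published estimator is reproduced.
* Fixed-step Euler–Maruyama is first-order: limit-cycle trajectories are
  phase-accurate only to O(dt) per unit time, which is irrelevant for the
  distributional objectives used here but matters for trajectory-level
  comparisons.
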