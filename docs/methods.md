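# Methods

## Model

`divnorm` implements a normative account of early sensory processing under
signal-dependent noise.  The world is described by a linear generative
model: nonnegative stimulus features `x = (x_1 … x_n)` drive `m` sensory
inputs with mean activations

    <s_j | x> = Σ_k w_jk x_k + w_0,

and the observed inputs are independent Poisson counts over a T = 1 s
window (counts equal rates), so variance scales with the mean.  Perception
is cast as maximum-likelihood estimation of `x` from one noisy input vector
`s`.  Gradient ascent on the Poisson log-likelihood gives the **divisive**
update

    dx̂_i/dt = η Σ_j w_ji ( s_j / (Σ_k w_jk x̂_k + w_0) − 1 ),

a weighted sum of *fractional prediction errors*: each input is divided by
its current prediction before being combined.  Under constant-variance
Gaussian noise the same construction yields the **subtractive** update
driven by absolute errors `s_j − <s_j(x̂)>`, whose unconstrained fixed
point is the ordinary least-squares readout `(WᵀW)⁻¹Wᵀ(s − w_0)`.
Everything the package predicts — surround suppression that reshapes
receptive fields, tuning-curve repulsion by masks, an invariant linear
readout behind variable tuning, divisive normalization, gain control, and
contrast-dependent temporal dynamics — follows from the divisive form of
the error signal; the subtractive and LN models are the controls that lack
these signatures.

Features are nonnegative; the dynamics enforce this by projection (clamping
at zero after each Euler step).  Clamped fixed points therefore solve the
*constrained* problems: nonnegative Poisson ML for the divisive flow and
NNLS for the subtractive flow (computed directly with `scipy.optimize.nnls`
where only the fixed point is needed).

### Solvers

Two routes to the divisive fixed point are provided and tested against each
other:

* `run_to_convergence` — the Euler discretization of the gradient flow
  itself.  The default rate η = 10⁻³ / max-column-sum(W) is conservative
  (smooth trajectories for every basis in the package); on ill-conditioned
  bases the flow closes the final distance to the optimum slowly, so
  fixed-point studies use a larger rate with automatic backoff.
* `ml_estimate` — multiplicative updates
  `x ← x · Wᵀ(s/(Wx+w_0)) / colsum(W)` (the EM / Richardson–Lucy update
  with a known background).  Monotone in likelihood, robust to tiny
  backgrounds, vectorized over stimulus batches; this is what the
  large measurement protocols use.  Convergence is declared on the relative
  change of the predicted rates, which remains meaningful when features
  slide to the zero boundary.

Stationarity of a clamped fixed point is measured by the projected-gradient
(KKT) residual: `|g_i|` where `x̂_i > 0` and `max(g_i, 0)` on the boundary.
On severely ill-conditioned bases (the circular kernel's condition number
is ~e⁸) every first-order method closes the last stretch to the optimum
only slowly; `ml_estimate(..., polish=True)` finishes with damped
projected-Newton steps (the problem is convex) and reaches residuals near
machine precision.

## E/I network

The circuit realization uses two populations: excitatory units carrying the
fractional prediction error of one input each, inhibitory units carrying
the feature estimates:

    a dr_exc_j/dt = s_j − (w_0 + Σ_k w_jk r_inh_k) · r_exc_j
    b dr_inh_i/dt = Σ_j w_ji (r_exc_j − 1)

with a = 0.08, b = 40, w_0 = 1 and both populations clamped nonnegative.
Inhibition multiplies the excitatory leak, so the excitatory time constant
is `a / (w_0 + W r_inh)` — faster for stronger drive, which produces the
amplitude-dependent response latencies and the outward-traveling activity
wave in topographic networks.  At the fixed point `r_exc = s/(w_0 + W r_inh)`
(exactly 1 for perfectly predicted inputs) and `r_inh` equals the divisive
estimator's ML estimate.

The subtractive control network is classical linear predictive coding with
*signed* error units:

    a dr_exc_j/dt = (s_j − w_0) − w_0 r_exc_j − (W r_inh)_j
    b dr_inh_i/dt = Σ_j w_ji r_exc_j

No rectification: the system is linear, its excitatory time constant
`a/w_0` is input-independent (time-to-peak spread < 0.1% across amplitudes
50–200), error units carry the least-squares residual (zero for perfectly
predicted inputs), and the fixed point of `r_inh` is exactly the
subtractive closed form.  An alternative formulation with a `−1` offset in
the inhibitory integration and rectified rates was considered and rejected:
its offsets break linearity and give a ~4% amplitude-dependence of the
response timing, contradicting the defining input-invariance of the
subtractive model.

Integration is explicit Euler, default dt = 10⁻⁴·a with a runtime
instability guard (`leak · dt / a > 1` aborts); the studies use
dt = 10⁻³·a, still ≳50× below the stability bound for their inputs, after
checking that halving dt does not change any reported quantity at the
stated tolerances.  A numba-compiled kernel accelerates constant-input
simulations when numba is importable; a pure-numpy path implements the
identical scheme otherwise.

### Closed forms

For the minimal two-input network the steady state reduces to the canonical
divisive-normalization ratio `r_1 ∝ s_1 / max(s_1 + s_2, w_0)`; for
"simple" inputs (no co-activation of overlapping detectors) the general
form `r_j ∝ s_j / max(pool_j, w_0)` holds with `pool = (W Wᵀ / w_max²) s`,
the scaling chosen so the two-unit case is recovered exactly.  Constants of
proportionality are fixed to 1 and all simulation comparisons are
ratio-based.

## Measurement protocols

All probes treat a model as a deterministic map from inputs to steady-state
responses; stochasticity lives entirely in the stimulus samplers, which are
seeded.  Numbers below are the protocol sizes used by the presets and the
acceptance studies.

* **Surround suppression** (paired basis, 30 features, w_0 = 0.01): in-RF
  input at mean 50, context input at 20 adjacent ('adjoint') or across the
  RF ('disjoint'), 200 Poisson trials.  The subtractive model is evaluated
  in its linear regime (minimum-norm least squares; the even paired basis
  is rank-deficient), whose left/right symmetry makes the two contexts
  exactly equivalent.  Note a structural property of the divisive model
  here: contexts that touch only silent receptors (observed count 0) exert
  *no* influence, because a zero count fixes the fractional error at −1
  regardless of the prediction; disjoint suppression is therefore
  indistinguishable from no context at this background rate.
* **Tuning-curve repulsion** (circular basis, 30 directions, w_0 = 0.01):
  tuning from Poisson inputs with means `w_ji + w_0`; the mask is the
  encoded feature 3 steps left/right of the probed neuron at the amplitude
  that drives its central receptor at a mean of 200 (i.e. 200/w_max = 5).
  A mask of this form is representable by the generative model, evokes no
  response in the probed neuron alone, and repels its tuning peak by
  ~0.3 index units; an un-representable single-receptor spike of 200 would
  instead silence the neuron outright at the ML fixed point.  Shifts are
  measured by 3-point parabolic peak interpolation and averaged over three
  symmetry-equivalent probe neurons and both mask sides at 400 trials per
  direction, keeping the Monte-Carlo error of the peak estimate well below
  the effect size.
* **Receptive-field reshaping** (400 Gaussian-blob features, σ_w = 0.1, on
  a 30×30 sheet, w_0 = 0.01): reverse correlation `ŵ = Q_ss⁻¹ q_rs` with
  raw (uncentered) moments from 10⁴ random sparse stimuli (pixels 100 with
  probability 0.05), optionally plus a vertical square-wave grating (bars 8
  px, amplitude 20, uniform random phase).  RFs are L2-normalized before
  comparing across contexts (reshaping, not gain, is the claim).  An
  automatic diagonal ridge handles moment matrices with condition number
  above 10¹².
* **Readout invariance** (circular basis): three contexts, each a constant
  mask summing three random encoded features at coefficient 0.5, added to
  the varying single-feature stimulus before Poisson sampling; 100 trials
  per direction.  Readouts `U = <s̄ r̄ᵀ><r̄ r̄ᵀ>⁻¹` are fitted per context;
  reconstruction error is normalized rms (a zero decoder scores 1).  Two
  evaluations are reported: trial-level (includes the irreducible Poisson
  floor, identical for matched and mismatched decoders) and a
  decoder-transfer variant scoring direction-averaged reconstructions
  against the clean stimulus means.
* **Gain control / temporal dynamics** (two-unit network, w = 40, w_0 = 1):
  input–response curves from the closed form over Poisson trials; time
  courses from Euler simulation of step inputs using the Poisson *mean*
  drives, since the latency claims concern the deterministic network
  dynamics (counts over the 1 s window equal rates).  Time-to-peak uses
  parabolic refinement around the discrete maximum.
* **Traveling waves** (30-unit topographic ring, `w_ii = w_{i+1,i} = 40`,
  drive `150·e^{−|j−k|/2}`): the wave metric is the 70%-of-first-
  substantial-peak arrival time (first local maximum with prominence ≥5% of
  the trace maximum), evaluated at circular distances 1–8 from the peak
  unit — around, not at, the source, over units whose mean drive exceeds
  2·w_0.  For front-dominated responses this equals the plain 70%-of-max
  latency; for weakly driven units of the *linear* subtractive network the
  plain metric instead times late ringing or the slow relaxation to steady
  state, which is not a wavefront.  Both metrics are written to the output
  tables for distances 0–10.

## Synthetic data

All inputs are generated internally from the generative model and the
stimulus ensembles above; there is no external data.  The generator
reproduces the independence and variance-scaling structure the theory
assumes — independent Poisson inputs, exact basis knowledge, stationary
contexts.  It does not emulate correlated noise, temporal adaptation,
model mismatch between true and assumed bases, or spiking variability, so
passing tests demonstrate internal consistency of the normative model and
its circuit, not robustness of real neural data to those factors.  Letter
('V', 'I', 'A') rasters are fixed synthetic package fixtures (30×20 binary
grids) standing in for hand-drawn letter features.

## Numerical choices and edge cases

* η, tolerances: defaults above; convergence of the flows is on the largest
  per-step change (`tol`, default 1e-8), non-convergence is flagged on the
  returned state rather than raised.
* Boundary ties: a feature at 0 with exactly zero gradient stays at 0.
* Degenerate bases: even-sized paired bases have a one-dimensional kernel
  (alternating vector); gradients are orthogonal to it so zero-initialized
  flows remain well defined, the subtractive closed form raises and
  suggests a ridge, and the minimum-norm readout is used where linearity
  matters.
* LN fitting: ordinary ridge least squares (default ridge 10⁻⁶) with the
  rectifier applied at evaluation — target responses live predominantly in
  the supra-threshold regime; an optional active-set refit iterates the
  nonconvex rectified fit.
* Reverse correlation uses raw second moments as defined; a `centered`
  variant is not exposed because the sparse nonnegative ensembles used here
  make raw moments the meaningful choice.

## Known limitations

* Only Poisson and constant-Gaussian input noise; no correlated-noise or
  generalized variance-mean families, no multi-layer hierarchies, no
  spiking dynamics, no temporal adaptation.
* The LN baseline is fitted by (optionally refined) least squares, not by
  exhaustive nonconvex optimization; its contrast with the divisive model
  is qualitative.
* Acceptance-level claims are about fixed points and steady states;
  trajectory-level properties are checked only qualitatively (transient
  peaks, latency orderings).
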