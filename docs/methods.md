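# Methods

## The model

`popmem` implements a neural resource model of visual working memory for
one-dimensional stimulus features.  A memorized value θ is encoded in the
spike counts of M feature-selective neurons whose preferred values c_i
tile the stimulus space.  Neuron i fires a Poisson count with mean

    f_i(θ) = (γ / N) · g_i(θ) / Σ_j g_j(θ)

with tuning kernel g_i: on a circular space (grating orientation, period
180°, handled internally on the doubled circle), g_i(θ) =
exp[(cos(θ − c_i) − 1)/ω²], the von-Mises-shaped circular analogue of a
Gaussian with concentration κ = 1/ω²; on a bounded space (expression
intensity in [0, 100]%), g_i(θ) = exp[−(θ − c_i)²/(2ω²)].

The two free parameters are the **gain constant γ** — the expected total
spike count of the whole population — and the **tuning width ω** (in
doubled-angle radians for orientation, in % intensity for expression).
Divisive normalization is applied per stimulus value, so the summed
expected count is exactly γ/N for every θ, including next to the bounded
edges where the kernel sum shrinks.  Set size N enters the model only
through this γ/N division: the probed item's population is simulated in
isolation, and memory load is entirely a gain division.  Cross-item
interactions (swaps, misbinding) are out of scope.

Decoding reconstructs θ from a spike pattern on a dense grid (default
1° for orientation, 0.5% for intensity, configurable):

* **maximum likelihood** — the grid argmax of the Poisson log-likelihood
  Σ_i [n_i log f_i(θ) − f_i(θ)].  Ties, including the exactly flat
  surface left by a zero-spike pattern, resolve to the lowest grid index
  (within an absolute tolerance of 1e-9 to absorb floating-point noise in
  the θ-independent Σf term).
* **posterior sampling** — one draw from the posterior ∝ exp(log-lik) ×
  prior over the grid, computed with log-sum-exp stabilization.  The
  default prior is uniform.  This read-out is the natural choice on the
  bounded space, where the decoded value must stay inside the interval;
  on circular data both read-outs apply and can be compared.

Because total activity is fixed, a zero-spike pattern carries no
information: the ML decoder falls back to its tie rule and the sampling
decoder draws from the prior.  Guessing therefore emerges from the model
(probability e^{−γ/N}) without a separate guess parameter.

### Boundary bias

On the bounded space, responses to targets near 10% and 91% are biased
toward mid-range, and the bias grows with set size.  Nothing in the model
produces this explicitly: it follows from posterior mass truncated at the
interval ends once the posterior is wide relative to the distance to the
boundary (small γ/N).  At high precision the divisive-normalization term
−T·log S(θ) in the likelihood produces a small *edge-attracting*
counter-effect (S is smaller near the edges), so inward bias is a
coarse-memory phenomenon, which matches where it is observed
behaviourally.  A small bias toward the neutral (0%) end of the scale at
high load that is seen in behavioural data is *not* produced by this
symmetric model and is documented as expected behaviour, not a defect.

## Fitting

The fitting currency is a binned Monte-Carlo estimate of the response
distribution: for each candidate (γ, ω) on a log-spaced grid, simulated
encode–decode cycles are binned — per unique target over the response
interval for the bounded task (20 bins), as signed errors over (−90°,
90°] for orientation (40 bins, rotation invariance makes the error
distribution target-independent).  The data log-likelihood is the summed
log probability of each trial's bin; all set sizes are fit jointly with
one (γ, ω), since normalization alone must carry the load effect.
Default grouping for behavioural tables is per participant × emotion.

Defaults per task (n_sim = simulated decodes per condition):

| task                  | decoder            | gains                 | widths                    | n_sim | bins |
|-----------------------|--------------------|-----------------------|---------------------------|-------|------|
| `orientation_ml`      | ML                 | 60 log-spaced, 1–100  | 60 log-spaced κ, 1–100 (ω = κ^{−1/2}: 0.1–1) | 10⁴ | 40 |
| `orientation_sampling`| posterior sampling | 50 log-spaced, 0.1–10³| 20 log-spaced ω, 0.1–1    | 10⁴   | 40 |
| `expression_sampling` | posterior sampling | 50 log-spaced, 0.1–10³| 50 log-spaced ω, 0.01–10  | 10⁵   | 20 |

The ML-task width grid is specified in concentration units (κ from 10⁰
to 10²), the parameterization of the original circular-model grid
search; it is exposed in ω units so the two orientation tasks share one
width scale — necessary for their fits to be comparable parameter for
parameter.

Model comparison uses AIC = 2k − 2 ln L with k = 2 for both decoders, so
ΔAIC is a pure likelihood difference.  `compare_decoders` reports
ΔAIC = AIC(ML) − AIC(sampling); negative favours ML.

### Numerical design of the likelihood evaluation

* **Pseudo-count floor.**  Each predicted bin probability is floored by
  add-one smoothing, p ← (n_floor·p + 1)/(n_floor + n_bins), so no
  observed response has zero likelihood.  n_floor defaults to the task's
  nominal simulation count (10⁴/10⁵), *not* to a reduced Monte-Carlo
  budget: the floor is a model regularization, and strengthening it when
  simulations are cheapened visibly fattens predicted tails and biases
  fits toward higher gain.
* **Spike-count stratification** (default engine).  Conditional on the
  total count T, decode outcomes do not depend on γ or N — those enter
  only through T ~ Poisson(γ/N).  The fitter therefore builds, per
  tuning width (and per target on the bounded space), a table of
  decode-outcome histograms for T = 0…T_cap from coupled label chains
  (the first T labels of one i.i.d. sequence are an exact T-spike
  sample), then mixes rows with Poisson weights for every gain and set
  size, lumping the Poisson tail onto T_cap.  This Rao-Blackwellization
  evaluates the full 60×60 grid at the cost of 60 simulations.  A
  `direct` engine that literally recomputes the trial likelihood at
  every grid point is retained and tested for agreement.
* **Common random numbers.**  The table for each width reuses the same
  underlying uniform stream (inverse-CDF label sampling), so Monte-Carlo
  noise is strongly correlated across the width grid and the likelihood
  surface stays smooth; without this the argmax wanders along the
  gain-width ridge.
* **Analytic circular read-outs.**  On the circular space the ML decode
  is the resultant direction of the spiking neurons' preferred vectors
  (the score A·cosφ + B·sinφ is maximized there), and under a uniform
  prior the posterior is von Mises with concentration R/ω².  The fitter
  samples these continuous laws directly instead of building score
  matrices, which makes large table sizes cheap.
* **Dithered quantization.**  Orientation targets are continuous, so the
  decoding grid sits at a uniformly distributed offset from each target.
  Table outcomes simulated at the canonical target are therefore
  jittered by one uniform grid step before binning — exactly the error
  marginal over continuous targets for the ML read-out (discrete argmax
  = rounded continuous maximizer).  Zero-spike ML decodes (fixed
  tie-break point) are replaced by the exact uniform error marginal they
  induce when targets are uniform.  Omitting either correction produces
  a measurable systematic misfit (binning artifacts of integer-degree
  outcomes against 4.5° bins; a spurious point mass in one error bin).
* **Seeding.**  All child streams derive from a master seed via
  `numpy.random.SeedSequence` spawn keys (per condition, per width, per
  group), so every fit is reproducible and cache/no-cache evaluation is
  bit-identical.
* **Tie-breaks.**  Grid-search ties resolve to the lowest gain index,
  then the lowest width index.

## Synthetic experiments

`popmem.experiments` generates trial tables with the design structure of
three delayed-reproduction experiments and fills in responses with the
forward model:

* **1A** (faces): five 600-trial blocks at set sizes 1–5; per block each
  of 60 identities probed 10 times, twice per emotion, once below and
  once above 50% intensity; targets at 10 levels spanning 10–91%
  (optional final 300-trial set-size-1 block).  Balance constraints are
  exact and countable on the table.
* **1B** (gratings): 600 trials at each of set sizes 1, 3, 5, uniform
  random orientations.
* **1C** (mixed): one face plus one or three gratings; the probed item
  is chosen uniformly at random.  `design_mixed` builds custom
  fixed-composition arrays.

Responses follow a **dual-resource rule**: the expression resource is
divided among the faces (N_expr = number of faces) and the orientation
resource among gratings *plus* faces (N_orient = gratings + w·faces),
with w ∈ [0, 1] the orientation-resource cost of one face (default
w = 1).  Faces thus interfere with grating recall but gratings do not
touch expression recall — the asymmetry the rule exists to produce.

Default generating parameters (the package's study conditions, chosen
once to give realistic error magnitudes — expression SDs growing from
roughly 5–11% at one item to 16–24% at five, orientation SDs of a few
degrees growing several-fold, marked inward bias at extreme intensities
— and to sit in the interior of every fitting grid):
emotion gains γ = 9 / 7.5 / 6 / 4.5 / 3 (happy / disgusted / angry /
fearful / sad; happy:sad = 3), expression width ω = 8%, orientation
γ = 20, ω = 0.5, M = 1000 neurons, posterior sampling for expression and
ML for orientation.

What the generator does *not* emulate: stimulus rendering, eye
movements, practice/block-order effects, response-time dynamics, swap
errors, and the small toward-neutral bias at high load.  Passing tests
on this synthetic data show that the pipeline is self-consistent and
that the model's qualitative signatures are recoverable — not that real
data satisfy the model.

## Problem sizes in the test suite and acceptance script

Simulation-heavy checks run at reduced but statistically adequate sizes,
stated in each test: recovery uses 20 single-session replicates at
n_sim = 2×10³; the decoder comparison uses ten 600-trial subjects; the
emotion-gain analysis fits two emotions per replicate on reduced
(16×10-point) grids spanning the same decades as the defaults.  The
acceptance script mirrors these at smaller replicate counts.

## Known limitations

* Grid-search resolution bounds parameter precision to one grid step;
  the optional nonlinear refinement of the original model is not
  implemented (grids keep the two decoders directly comparable).
* The stratified engine assumes the prior is shared across trials of a
  fit (true of the uniform default).
* On the bounded space at high precision the per-θ divisive
  normalization induces a small edge-attraction in the likelihood (see
  Boundary bias); alternative normalization mechanisms are not explored.
* `compare_decoders` is defined for orientation data only; the ML
  read-out is not applied to the bounded task.
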