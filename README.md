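# popmem

Population-coding models of visual working memory, for researchers who
study continuous-reproduction (delayed-estimation) tasks — recall of
grating orientation, and of high-level features such as the intensity of
a facial expression — and want a generative, fittable account of how
recall error distributions arise and why they widen with memory load.

## The model

A memorized stimulus value θ is encoded in the Poisson spike counts of
M feature-tuned neurons (default M = 10³).  Neuron i with preferred
value c_i fires with mean

    f_i(θ) = (γ / N) · g_i(θ) / Σ_j g_j(θ)

where g_i is a von-Mises-shaped kernel on the (doubled) circle for
orientation, or a Gaussian on the bounded interval [0, 100]% for
expression intensity.  Divisive normalization fixes the total expected
spike count at γ/N for every θ: the **gain constant γ** is the
population's whole activity budget, and set size N simply divides it.
The **tuning width ω** is the second and last free parameter.

The stimulus is reconstructed from the spikes either by **maximum
likelihood** (grid argmax of Σᵢ nᵢ log fᵢ(θ) − fᵢ(θ)) or by **posterior
sampling** (one draw from the posterior under a uniform prior — the
natural read-out on a bounded space).  Rising error dispersion with
load, the specific error-distribution shapes, spontaneous guessing
(zero-spike trials), and the inward bias of near-boundary expression
targets all fall out of these ingredients; none is a separate
parameter.

Fitting is by grid search over log-spaced (γ, ω), with predicted
response histograms obtained by Monte-Carlo simulation and model
variants compared via AIC = 2k − 2 ln L.  A synthetic-experiment module
generates balanced trial designs (faces at set sizes 1–5; gratings at
1/3/5; mixed face+grating arrays with a dual-resource interference
rule) and model-generated responses for end-to-end testing.

## Worked example

`examples/fit_orientation_session.py` generates one synthetic grating
session (600 trials at each of set sizes 1, 3, 5) from known parameters
γ = 6, ω = 0.48 and refits it:

```
generated 1800 trials at gain=6.0, width=0.48
 set_size   n      bias        sd
        1 600 -0.063913  6.494367
        3 600  0.570280 19.570777
        5 600 -0.837884 27.031545
fitted gain = 6.02, width = 0.495 (log L = -4617.8, AIC = 9239.5)
```

Error SD (circular SD, degrees on the 180° orientation scale) roughly
quadruples from one to five items while the bias stays near zero; the
grid-search fit lands on the generating gain and one grid step from the
generating width, with a single (γ, ω) pair accounting for all three
set sizes.  `examples/boundary_bias.py` shows the bounded-space
signature — the mean response to a 10%-intensity target drifts inward
from 10.0% (N = 1) to 22.8% (N = 5) with no bias term in the model —
and `examples/face_grating_interference.py` the interference asymmetry:
adding a face raises grating-recall error SD from 3.6° to 5.2°, while
adding gratings leaves face recall at ~7.1%.

A thin CLI covers the pipeline for shell use:

```bash
popmem simulate --experiment 1A --participants 1 --seed 7 --out trials.csv
popmem stats --input trials.csv --groupby set_size --out summary.csv
popmem fit --input trials.csv --task expression_sampling --out fits.csv
popmem compare-decoders --input gratings.csv --out comparison.csv
```

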