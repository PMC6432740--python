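"""Inward bias at the edges of a bounded stimulus space.

Simulates expression-intensity recall with the posterior-sampling
decoder at a near-boundary target (10% intensity).  The mean response
pulls toward mid-range, and the pull grows with memory load — the model
produces this without any explicit bias term, purely because posterior
mass cannot extend past the boundary.
"""

import numpy as np

import popmem as pm

space = pm.BoundedSpace(0.0, 100.0)
params = pm.PopulationParams(gain=6.0, tuning_width=8.0)

print("target = 10% intensity, posterior-sampling decoder")
for set_size in (1, 2, 3, 4, 5):
    rng = np.random.default_rng(set_size)
    resp = pm.simulate_responses(
        params, space, 10.0, set_size, "posterior_sampling", 8000, rng
    )
    print(
        f"  set size {set_size}: mean response {resp.mean():5.1f}%  "
        f"(bias {resp.mean() - 10.0:+5.2f} points inward)"
    )
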