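"""The discrete edge-diffusion process, forward and (oracle) reverse.

Corrupts a clean network toward the sparsity prior step by step, then
runs the exact reverse chain using the true network as the denoiser's
prediction -- the noiseless skeleton the learned model plugs into.
"""

import numpy as np

import planet

cfg = planet.SimConfig(n_min=20, n_max=20, n_cells=10)
grn = planet.sample_grn_topology(cfg, seed=3)
mask = grn.candidate_mask()
schedule = planet.cosine_schedule(T=100, delta=0.9)

print("clean edges:", grn.n_edges, "of", int(mask.sum()), "candidate pairs")
for t in (0, 25, 50, 75, 100):
    e_t = planet.forward_sample(grn.adjacency, t, schedule, seed=7, mask=mask)
    agree = (e_t == grn.adjacency)[mask].mean()
    print(f"t={t:>3}: edges={int(e_t.sum()):>3}  agreement with clean state "
          f"{agree:.2f}")
# at t=100 the state is pure prior noise: edge frequency ~ 1-delta = 0.1

# reverse with a perfect denoiser: land exactly on the clean network
e = planet.sample_stationary(grn.adjacency.shape, schedule, seed=9, mask=mask)
tau = planet.make_subsequence(100, 10)  # accelerated: 10 reverse steps
for i in range(len(tau) - 1, 0, -1):
    e = planet.reverse_step(e, grn.adjacency.astype(float), int(tau[i]),
                            int(tau[i - 1]), schedule, seed=i, mask=mask)
print("recovered exactly:", bool(np.array_equal(e, grn.adjacency)))
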