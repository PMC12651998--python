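"""Train the denoiser on a tiny suite and generate a network.

Desk-scale demonstration: a handful of simulated networks, a short
diffusion schedule and a few epochs -- enough to watch the loss fall
and to produce a valid edge-probability matrix for a held-out
expression profile.  Scores are modest at this scale; the benchmark
protocol in the README uses larger settings.
"""

import numpy as np

import planet

sim = planet.SimConfig(n_min=12, n_max=16, n_cells=100)
train_pairs, test_pairs = planet.make_benchmark_suite(sim, n_train=4,
                                                      n_test=1, seed=2)

cfg = planet.TrainConfig(
    T=50, epochs=30, lr=1e-3, seed=0,
    model=planet.TriHATConfig(d_x=32, d_e=16, d_t=32, heads=2, gat_heads=2,
                              n_layers=2, edge_groups=2, p_profile=64))
model, schedule, log = planet.train(train_pairs, cfg)
print(f"loss: epoch 0 {log[0]['loss_mean']:.3f} -> "
      f"epoch {len(log)-1} {log[-1]['loss_mean']:.3f}")
print(f"schedule: T={schedule.T}, stationary no-edge prob "
      f"delta={schedule.delta:.3f} (from training edge density)")

grn, expr = test_pairs[0]
probs = planet.generate(expr, model, schedule, grn.tf_mask, k=25,
                        n_ensemble=8, seed=3)
scores = planet.score_network(probs, grn)
print(f"held-out network: AUROC {scores['auroc']:.3f}, "
      f"AUPRC {scores['auprc']:.3f}")
pcc = planet.score_network(planet.pcc_baseline(expr, grn.tf_mask), grn)
print(f"PCC baseline:     AUROC {pcc['auroc']:.3f}")

hard = planet.threshold_network(probs, 0.5, grn.genes, grn.tf_mask)
print(f"edges above probability 0.5: {hard.n_edges} "
      f"(truth has {grn.n_edges})")
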