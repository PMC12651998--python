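"""Benchmark simulator: random sparse TF->target networks and matched
steady-state stochastic expression.

The topology sampler enforces three constraints on every network: the
edge count lies in [n, 2n] for n genes, there are no self-loops, and
every edge originates at a transcription factor with at most one
direction present between any pair of genes.

Expression is produced by a simplified chemical-Langevin model run to
(approximate) steady state, with each cell an independent stochastic
realization:

    dx_j = (b_j + sum_i k_ij * H_ij(x_i) - lambda_j * x_j) dt
           + eta * sqrt(max(x_j, 0)) dW

where ``H_ij`` is an increasing (activation) or decreasing (repression)
Hill function of the regulator level.  A measurement layer then applies
logistic low-expression dropout, the dominant technical artifact of
scRNA-seq: the probability of observing a zero falls sigmoidally with
log expression.  This keeps the statistical structure GRN benchmarks
need -- sparse, nonlinear, directional TF->target dependence, per-cell
stochasticity and dropout -- in a fully self-contained simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import GRN, ConfigurationError, ExpressionMatrix

__all__ = ["SimConfig", "sample_grn_topology", "simulate_expression",
           "make_benchmark_suite"]


@dataclass
class SimConfig:
    """Settings for network topology and expression simulation.

    Gene counts are drawn uniformly from ``[n_min, n_max]``; set the two
    equal to pin the size.  Kinetic ranges are (low, high) bounds for
    uniform sampling per gene/edge.
    """

    n_min: int = 15
    n_max: int = 40
    tf_fraction: float = 0.3
    n_cells: int = 100
    basal_range: tuple[float, float] = (1.0, 3.0)
    regulated_basal_range: tuple[float, float] = (0.1, 0.3)
    interaction_range: tuple[float, float] = (2.0, 5.0)
    decay: float = 1.0
    noise_scale: float = 0.5
    hill_coef: float = 2.0
    activation_prob: float = 0.7
    dropout_shape: float = 2.0       # logistic steepness; 0 disables dropout
    dropout_percentile: float = 45.0  # log-expression percentile with 50% dropout
    sim_time: float = 10.0
    dt: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_min < 2 or self.n_max < self.n_min:
            raise ConfigurationError("need n_max >= n_min >= 2")
        if not 0.0 < self.tf_fraction < 1.0:
            raise ConfigurationError("tf_fraction must be in (0, 1)")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")


def _n_tfs(n: int, tf_fraction: float) -> int:
    return max(1, int(round(n * tf_fraction)))


def sample_grn_topology(config: SimConfig, seed: int) -> GRN:
    """Draw one random network satisfying the benchmark constraints.

    Edges are placed by shuffling all candidate (TF, target) ordered
    pairs and accepting greedily while skipping any pair whose reverse
    direction is already present.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(config.n_min, config.n_max + 1))
    n_tf = _n_tfs(n, config.tf_fraction)
    # max edges with no self-loops, TF sources, and one direction per pair
    feasible = n_tf * (n - n_tf) + n_tf * (n_tf - 1) // 2
    if feasible < n:
        raise ConfigurationError(
            f"{n_tf} TFs over {n} genes admit at most {feasible} edges "
            f"but at least {n} are required")
    m = int(rng.integers(n, min(2 * n, feasible) + 1))
    genes = [f"G{i:03d}" for i in range(n)]
    tf_idx = rng.choice(n, size=n_tf, replace=False)
    tf_mask = np.zeros(n, dtype=bool)
    tf_mask[tf_idx] = True

    pairs = [(int(i), int(j)) for i in tf_idx for j in range(n) if j != i]
    rng.shuffle(pairs)
    adj = np.zeros((n, n), dtype=np.int8)
    placed = 0
    for i, j in pairs:
        if placed == m:
            break
        if adj[j, i]:  # reverse direction already present
            continue
        adj[i, j] = 1
        placed += 1
    return GRN(genes=genes, tf_mask=tf_mask, adjacency=adj)


def _draw_kinetics(grn: GRN, config: SimConfig, rng: np.random.Generator):
    n = grn.n_genes
    regulated = grn.adjacency.sum(axis=0) > 0
    basal = np.where(
        regulated,
        rng.uniform(*config.regulated_basal_range, size=n),
        rng.uniform(*config.basal_range, size=n))
    strength = rng.uniform(*config.interaction_range, size=(n, n)) * grn.adjacency
    activating = rng.random((n, n)) < config.activation_prob
    # Half-saturation near the basal steady state of an unregulated gene so
    # that regulator variability propagates to targets.
    half_sat = np.full(n, float(np.mean(config.basal_range)) / config.decay)
    return basal, strength, activating, half_sat


def simulate_expression(grn: GRN, config: SimConfig, seed: int) -> ExpressionMatrix:
    """Simulate ``config.n_cells`` independent steady-state cells."""
    rng = np.random.default_rng(seed)
    n = grn.n_genes
    basal, strength, activating, half_sat = _draw_kinetics(grn, config, rng)
    h = config.hill_coef
    lam = config.decay
    n_steps = max(1, int(round(config.sim_time / config.dt)))
    dt = config.dt
    sqdt = np.sqrt(dt)

    x = np.tile(basal / lam, (config.n_cells, 1))  # start near basal fixed point
    adj = grn.adjacency.astype(bool)
    for _ in range(n_steps):
        xs = np.maximum(x, 0.0)
        ratio = (xs[:, :, None] / half_sat[None, :, None]) ** h  # cells x reg x 1
        hill_act = ratio / (1.0 + ratio)
        hill = np.where(activating[None, :, :], hill_act, 1.0 - hill_act)
        production = basal[None, :] + np.einsum(
            "cij,ij->cj", hill * adj[None, :, :], strength)
        drift = production - lam * x
        if config.noise_scale > 0:
            noise = config.noise_scale * np.sqrt(xs) * rng.standard_normal(x.shape)
            x = x + drift * dt + noise * sqdt
        else:
            x = x + drift * dt
        x = np.maximum(x, 0.0)
    if config.dropout_shape > 0:
        logx = np.log1p(x)
        mid = np.percentile(logx, config.dropout_percentile)
        p_keep = 1.0 / (1.0 + np.exp(-config.dropout_shape * (logx - mid)))
        x = x * (rng.random(x.shape) < p_keep)
    cells = [f"cell{i}" for i in range(config.n_cells)]
    return ExpressionMatrix(values=x, genes=list(grn.genes), cells=cells)


def make_benchmark_suite(config: SimConfig, n_train: int, n_test: int,
                         seed: int) -> tuple[list[tuple[GRN, ExpressionMatrix]],
                                             list[tuple[GRN, ExpressionMatrix]]]:
    """Generate independent (network, expression) pairs split train/test.

    Each pair gets its own deterministic substream spawned from ``seed``,
    so element ``i`` is reproducible regardless of how many pairs are
    drawn.
    """
    if n_train < 1 or n_test < 1:
        raise ConfigurationError("need n_train >= 1 and n_test >= 1")
    children = np.random.SeedSequence(seed).spawn(n_train + n_test)
    pairs = []
    for child in children:
        s_topo, s_expr = child.generate_state(2)
        grn = sample_grn_topology(config, int(s_topo % (2 ** 31)))
        expr = simulate_expression(grn, config, int(s_expr % (2 ** 31)))
        pairs.append((grn, expr))
    return pairs[:n_train], pairs[n_train:]
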