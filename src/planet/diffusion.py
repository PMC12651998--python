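"""Discrete two-state edge diffusion.

Forward corruption of a binary edge matrix toward a sparsity-encoding
stationary distribution, and the exact reverse machinery: per-step
transition matrices ``M_t = a_t*S + (1-a_t)*I``, closed-form cumulative
transitions, categorical forward sampling, skip-step ("DDIM-style")
bridge matrices, exact posteriors, and sampled reverse steps.

State convention: category 0 = no edge, 1 = edge.  The stationary
matrix ``S`` has both rows equal to ``(delta, 1-delta)`` where ``delta``
is the prior probability of edge absence, so it encodes the ratio of
true edges to candidate pairs.  Because both rows of ``S`` are equal and
sum to one, ``S @ S == S`` and the t-step product collapses to
``M_bar_t = (1-g_t)*I + g_t*S`` with ``1-g_t = prod_i (1-a_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .types import ConfigurationError

__all__ = ["NoiseSchedule", "cosine_schedule", "transition_matrix",
           "cumulative_transition", "bridge_matrix", "forward_sample",
           "make_subsequence", "posterior", "reverse_step",
           "sample_stationary", "delta_from_suite"]

_EPS = 1e-12  # numerical floor used when normalizing posteriors


@dataclass
class NoiseSchedule:
    """Cosine noise schedule for the two-state edge chain.

    ``alpha[t-1]`` holds the per-step mixing weight for step ``t`` in
    ``1..T``; ``gamma_bar[t]`` the cumulative mixing weight with
    ``gamma_bar[0] == 0`` and ``gamma_bar[T] ~= 1``.
    """

    T: int
    delta: float
    s: float = 0.008
    alpha: np.ndarray = field(repr=False, default=None)
    gamma_bar: np.ndarray = field(repr=False, default=None)

    @property
    def S(self) -> np.ndarray:
        return np.array([[self.delta, 1.0 - self.delta],
                         [self.delta, 1.0 - self.delta]])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"T": self.T, "delta": float(self.delta),
                            "s": float(self.s)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "NoiseSchedule":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cosine_schedule(int(cfg["T"]), float(cfg["delta"]),
                               s=float(cfg.get("s", 0.008)))

    def fingerprint(self) -> str:
        return f"T={self.T};delta={self.delta:.10g};s={self.s:.10g}"


def cosine_schedule(T: int, delta: float, s: float = 0.008) -> NoiseSchedule:
    """Build a schedule whose cumulative retention follows a squared cosine.

    Retention ``1 - gamma_bar_t = cos^2(((t/T + s)/(1 + s)) * pi/2)``
    (normalized to 1 at t=0), with the per-step ``alpha_t`` back-solved
    so the product of ``(1 - alpha_i)`` reproduces it exactly.
    """
    if T < 1:
        raise ConfigurationError("T must be >= 1")
    if not 0.0 < delta < 1.0:
        raise ConfigurationError("delta must be in (0, 1)")
    t = np.arange(T + 1) / T
    f = np.cos((t + s) / (1.0 + s) * np.pi / 2.0) ** 2
    retention = f / f[0]
    retention = np.clip(retention, 0.0, 1.0)
    retention[-1] = min(retention[-1], 1e-5)  # gamma_bar_T >= 1 - 1e-5
    alpha = 1.0 - retention[1:] / retention[:-1]
    gamma_bar = 1.0 - retention
    return NoiseSchedule(T=T, delta=float(delta), s=float(s),
                         alpha=alpha, gamma_bar=gamma_bar)


def _check_t(schedule: NoiseSchedule, t: int, lo: int = 0) -> None:
    if not lo <= t <= schedule.T:
        raise ValueError(f"t={t} outside [{lo}, {schedule.T}]")


def transition_matrix(schedule: NoiseSchedule, t: int) -> np.ndarray:
    """Single-step transition ``M_t = alpha_t * S + (1 - alpha_t) * I``."""
    _check_t(schedule, t, lo=1)
    a = schedule.alpha[t - 1]
    return a * schedule.S + (1.0 - a) * np.eye(2)


def cumulative_transition(schedule: NoiseSchedule, t: int) -> np.ndarray:
    """Closed-form t-step transition ``M_bar_t = (1-g_t) I + g_t S``."""
    _check_t(schedule, t)
    g = schedule.gamma_bar[t]
    return (1.0 - g) * np.eye(2) + g * schedule.S


def bridge_matrix(schedule: NoiseSchedule, t_prev: int, t: int) -> np.ndarray:
    """Transition from step ``t_prev`` to ``t`` (the skip-step bridge)."""
    if not 0 <= t_prev <= t <= schedule.T:
        raise ValueError(f"need 0 <= t_prev <= t <= T, got {t_prev}, {t}")
    g0, g1 = schedule.gamma_bar[t_prev], schedule.gamma_bar[t]
    gp = (g1 - g0) / (1.0 - g0)
    return (1.0 - gp) * np.eye(2) + gp * schedule.S


def forward_sample(e0: np.ndarray, t: int, schedule: NoiseSchedule,
                   seed: int, mask: np.ndarray | None = None) -> np.ndarray:
    """Corrupt the clean edge matrix to step ``t`` in one categorical draw.

    Each candidate pair's new state is Bernoulli with edge probability
    ``M_bar_t[e0_ij, 1]``; masked-out pairs stay 0.
    """
    _check_t(schedule, t)
    e0 = np.asarray(e0)
    rng = np.random.default_rng(seed)
    mbar = cumulative_transition(schedule, t)
    p_edge = mbar[e0.astype(int), 1]
    et = (rng.random(e0.shape) < p_edge).astype(np.int8)
    if mask is not None:
        et = np.where(mask, et, 0).astype(np.int8)
    return et


def sample_stationary(shape: tuple[int, ...], schedule: NoiseSchedule,
                      seed: int, mask: np.ndarray | None = None) -> np.ndarray:
    """Draw the reverse chain's starting state: each pair ~ Bernoulli(1-delta)."""
    rng = np.random.default_rng(seed)
    et = (rng.random(shape) < (1.0 - schedule.delta)).astype(np.int8)
    if mask is not None:
        et = np.where(mask, et, 0).astype(np.int8)
    return et


def make_subsequence(T: int, k: int) -> np.ndarray:
    """Evenly spaced inference ladder ``{0, tau_1, ..., T}`` with k steps."""
    if not 1 <= k <= T:
        raise ValueError(f"k must be in [1, T], got k={k}, T={T}")
    tau = np.unique(np.round(np.linspace(0, T, k + 1)).astype(int))
    return tau


def _posterior_table(schedule: NoiseSchedule, t_prev: int, t: int) -> np.ndarray:
    """q(e_prev | e_t=j, e0=i) for all (i, j): array [i, j, e_prev].

    q(e_prev=p | e_t=j, e0=i) proportional to  bridge[p, j] * M_bar_prev[i, p].
    """
    br = bridge_matrix(schedule, t_prev, t)
    mbar_prev = cumulative_transition(schedule, t_prev)
    # joint[i, p, j] = M_bar_prev[i, p] * bridge[p, j]
    joint = mbar_prev[:, :, None] * br[None, :, :]
    table = joint.transpose(0, 2, 1)  # [i, j, p]
    norm = table.sum(axis=-1, keepdims=True)
    bad = norm <= 0
    if np.any(bad):
        table = table + _EPS
        norm = table.sum(axis=-1, keepdims=True)
    return table / norm


def posterior(e_t: np.ndarray, e0_probs: np.ndarray, t: int, t_prev: int,
              schedule: NoiseSchedule,
              mask: np.ndarray | None = None) -> np.ndarray:
    """Exact reverse posterior over the previous step's edge states.

    ``e0_probs`` carries the denoiser's per-pair probability that the
    clean state is an edge.  Returns an array shaped like ``e_t`` plus a
    trailing axis of 2 (categories no-edge/edge), each pair normalized.
    """
    if not 0 <= t_prev < t <= schedule.T:
        raise ValueError(f"need 0 <= t_prev < t <= T, got {t_prev}, {t}")
    e_t = np.asarray(e_t).astype(int)
    p1 = np.asarray(e0_probs, dtype=np.float64)
    table = _posterior_table(schedule, t_prev, t)  # [i, j, p]
    # mixture over e0: (1-p1) * table[0, j] + p1 * table[1, j]
    post = (1.0 - p1)[..., None] * table[0, e_t] + p1[..., None] * table[1, e_t]
    norm = post.sum(axis=-1, keepdims=True)
    post = (post + _EPS * (norm <= 0)) / np.where(norm > 0, norm, 2 * _EPS)
    if mask is not None:
        absent = np.zeros(post.shape[-1])
        absent[0] = 1.0
        post = np.where(mask[..., None], post, absent)
    return post


def reverse_step(e_t: np.ndarray, e0_probs: np.ndarray, t: int, t_prev: int,
                 schedule: NoiseSchedule, seed: int,
                 mask: np.ndarray | None = None,
                 deterministic: bool = False) -> np.ndarray:
    """Sample (or argmax, if ``deterministic``) the previous edge state."""
    post = posterior(e_t, e0_probs, t, t_prev, schedule, mask=mask)
    if deterministic:
        prev = (post[..., 1] > post[..., 0]).astype(np.int8)
    else:
        rng = np.random.default_rng(seed)
        prev = (rng.random(np.asarray(e_t).shape) < post[..., 1]).astype(np.int8)
    if mask is not None:
        prev = np.where(mask, prev, 0).astype(np.int8)
    return prev


def delta_from_suite(grns, clamp: tuple[float, float] = (0.5, 0.999)) -> float:
    """Stationary no-edge probability from training networks.

    ``1 - mean(edge density over the candidate-pair universe)``, clamped.
    """
    densities = [g.n_edges / max(1, int(g.candidate_mask().sum())) for g in grns]
    return float(np.clip(1.0 - float(np.mean(densities)), *clamp))
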