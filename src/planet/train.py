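"""Training (forward-corrupt, predict E_0, cross-entropy) and generation
(reverse subsequence sampling with an ensemble edge-probability readout).

Each training step draws a network and a uniform diffusion step t,
corrupts the clean edge matrix to E_t with the closed-form forward
marginal, asks the denoiser for E_0 logits and descends the masked
two-class cross-entropy.  Class imbalance over the sparse candidate
universe is handled with a positive-class weight computed from the
training networks.

Generation runs ``n_ensemble`` independent reverse chains down an evenly
spaced step ladder; the returned edge probability is the ensemble mean
of the model's predicted clean-edge probabilities at the final step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import AdamW, Tensor, no_grad
from .denoiser import TriHAT, TriHATConfig
from .diffusion import (NoiseSchedule, cosine_schedule, delta_from_suite,
                        forward_sample, make_subsequence, reverse_step,
                        sample_stationary)
from .types import GRN, ExpressionMatrix, check_paired

__all__ = ["TrainConfig", "training_loss", "train", "generate",
           "threshold_network", "positive_class_weight"]


@dataclass
class TrainConfig:
    T: int = 100
    epochs: int = 100
    batch_size: int = 1
    lr: float = 3e-4
    optimizer: str = "adamw"
    clip_norm: float = 1.0
    weight_decay: float = 1e-4
    seed: int = 0
    k_val: int | None = None  # subsequence length for validation sampling (None = T)
    checkpoint_every: int = 0  # epochs; 0 disables periodic checkpoints
    pos_weight_cap: float = 20.0
    # cells are exchangeable, so each step sees a bootstrap resample of
    # them; this blocks the denoiser from keying on arbitrary cell
    # coordinates and forces it onto the between-gene dependence structure
    augment_cells: bool = True
    lr_decay: bool = True  # cosine decay of the learning rate to 10%
    model: TriHATConfig = field(default_factory=TriHATConfig)

    def __post_init__(self) -> None:
        if self.T < 1 or self.epochs < 1:
            raise ValueError("need T >= 1 and epochs >= 1")
        if self.k_val is not None and self.k_val > self.T:
            raise ValueError("k_val must be <= T")


def positive_class_weight(grns: list[GRN], cap: float = 20.0) -> float:
    """(candidate pairs - edges) / edges over the training set, capped."""
    cand = sum(int(g.candidate_mask().sum()) for g in grns)
    edges = sum(g.n_edges for g in grns)
    if edges == 0:
        return 1.0
    return float(min(cap, (cand - edges) / edges))


def training_loss(logits: Tensor, e0: np.ndarray, cand_mask: np.ndarray,
                  pos_weight: float = 1.0) -> Tensor:
    """Weighted mean two-class cross-entropy over candidate pairs."""
    mask = np.asarray(cand_mask, dtype=bool)
    sel = logits[mask]                      # (m, 2)
    logp = sel.log_softmax(axis=-1)
    y = np.asarray(e0)[mask].astype(int)
    onehot = np.eye(2)[y]
    w = np.where(y == 1, pos_weight, 1.0)
    nll = -(logp * Tensor(onehot)).sum(axis=-1)
    return (nll * Tensor(w)).sum() / float(w.sum())


def train(train_pairs: list[tuple[GRN, ExpressionMatrix]],
          config: TrainConfig,
          schedule: NoiseSchedule | None = None,
          callback=None,
          checkpoint_dir=None) -> tuple[TriHAT, NoiseSchedule, list[dict]]:
    """Fit a TriHAT denoiser on simulated (network, expression) pairs.

    Returns the trained model, the noise schedule (its stationary
    no-edge probability estimated from the training networks unless a
    schedule is supplied), and a per-epoch log of loss mean/sd.
    """
    if not train_pairs:
        raise ValueError("need at least one training pair")
    for grn, expr in train_pairs:
        check_paired(grn, expr)
    if schedule is None:
        delta = delta_from_suite([g for g, _ in train_pairs])
        schedule = cosine_schedule(config.T, delta)
    pos_w = positive_class_weight([g for g, _ in train_pairs],
                                  cap=config.pos_weight_cap)
    model = TriHAT(config.model, seed=config.seed)
    model.T_hint = schedule.T
    if config.optimizer.lower() != "adamw":
        raise ValueError(f"unsupported optimizer: {config.optimizer}")
    opt = AdamW(model.parameters(), lr=config.lr, clip_norm=config.clip_norm,
                weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    log: list[dict] = []
    n_pairs = len(train_pairs)
    for epoch in range(config.epochs):
        if config.lr_decay:
            frac = epoch / max(1, config.epochs - 1)
            opt.lr = config.lr * (0.1 + 0.45 * (1 + np.cos(np.pi * frac)))
        order = rng.permutation(n_pairs)
        losses = []
        for start in range(0, n_pairs, config.batch_size):
            batch = order[start:start + config.batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for idx in batch:
                grn, expr = train_pairs[idx]
                if config.augment_cells:
                    rows = rng.integers(0, expr.n_cells, expr.n_cells)
                    expr = ExpressionMatrix(expr.values[rows], expr.genes)
                t = int(rng.integers(1, schedule.T + 1))
                e_t = forward_sample(grn.adjacency, t, schedule,
                                     seed=int(rng.integers(2 ** 31)),
                                     mask=grn.candidate_mask())
                logits = model.forward(e_t, expr, t, grn.tf_mask,
                                       T=schedule.T)
                loss = training_loss(logits, grn.adjacency,
                                     grn.candidate_mask(), pos_weight=pos_w)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged: loss={loss.data} at epoch "
                        f"{epoch}, network {idx}, t={t}")
                (loss * (1.0 / len(batch))).backward()
                batch_loss += float(loss.data)
                losses.append(float(loss.data))
            opt.step()
        log.append({"epoch": epoch, "loss_mean": float(np.mean(losses)),
                    "loss_sd": float(np.std(losses))})
        if callback is not None:
            callback(epoch, log[-1])
        if checkpoint_dir is not None and config.checkpoint_every > 0 and \
                (epoch + 1) % config.checkpoint_every == 0:
            from pathlib import Path

            from .denoiser import save_checkpoint
            Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
            save_checkpoint(model,
                            Path(checkpoint_dir) / f"epoch{epoch + 1:05d}.ckpt",
                            meta={"epoch": epoch + 1,
                                  "fingerprint": schedule.fingerprint()})
    return model, schedule, log


def generate(expr: ExpressionMatrix, model: TriHAT, schedule: NoiseSchedule,
             tf_mask: np.ndarray, k: int | None = None, n_ensemble: int = 8,
             seed: int = 0, deterministic: bool = False,
             expected_fingerprint: str | None = None) -> np.ndarray:
    """Edge-probability matrix from ensemble reverse sampling.

    Runs ``n_ensemble`` reverse chains over the ``k``-step ladder
    starting from the stationary prior and averages the predicted
    clean-edge probabilities at the final step.
    """
    if expected_fingerprint is not None and \
            expected_fingerprint != schedule.fingerprint():
        raise ValueError(
            "schedule fingerprint mismatch: model was trained with "
            f"{expected_fingerprint!r}, got {schedule.fingerprint()!r}")
    k = schedule.T if k is None else int(k)
    if not 1 <= k <= schedule.T:
        raise ValueError(f"k must be in [1, T], got {k}")
    n = expr.n_genes
    tf_mask = np.asarray(tf_mask, dtype=bool)
    cand = np.repeat(tf_mask[:, None], n, axis=1)
    np.fill_diagonal(cand, False)
    tau = make_subsequence(schedule.T, k)
    root = np.random.SeedSequence(seed)
    member_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                    for s in root.spawn(n_ensemble)]
    acc = np.zeros((n, n))
    with no_grad():
        for m_seed in member_seeds:
            mrng = np.random.default_rng(m_seed)
            e = sample_stationary((n, n), schedule,
                                  seed=int(mrng.integers(2 ** 31)), mask=cand)
            p0 = None
            for i in range(len(tau) - 1, 0, -1):
                t, t_prev = int(tau[i]), int(tau[i - 1])
                p0 = model.predict_e0_probs(e, expr, t, tf_mask, T=schedule.T)
                e = reverse_step(e, p0, t, t_prev, schedule,
                                 seed=int(mrng.integers(2 ** 31)), mask=cand,
                                 deterministic=deterministic)
            acc += p0
    probs = acc / n_ensemble
    probs = np.where(cand, probs, 0.0)
    return np.clip(probs, 0.0, 1.0)


def threshold_network(probs: np.ndarray, cutoff: float, genes: list[str],
                      tf_mask: np.ndarray) -> GRN:
    """Binarize an edge-probability matrix at ``cutoff`` (edge iff p > cutoff)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    probs = np.asarray(probs)
    tf_mask = np.asarray(tf_mask, dtype=bool)
    adj = (probs > cutoff).astype(np.int8)
    np.fill_diagonal(adj, 0)
    adj[~tf_mask, :] = 0
    return GRN(genes=list(genes), tf_mask=tf_mask, adjacency=adj)
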