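"""TriHAT: the triple hybrid-attention denoiser.

Predicts the clean regulatory network ``E_0`` from a noisy edge state
``E_t``, the gene expression profile and the diffusion step.  The
pipeline is

1. expression-derived node initialization,
2. a two-layer multi-head GATv2 encoder over the noisy network with a
   sigmoid time gate blending aggregated and original features (so the
   original expression dominates at high noise),
3. ``L`` graph-transformer layers, each jointly updating node features
   (multi-head self-attention + FiLM time fusion), edge features
   (pairwise self-attention scores refined by cross-attention against
   the fed-back noisy network), and the time embedding (gated node
   pooling GPoX plus attention edge pooling AttE),
4. a per-ordered-pair two-way logit readout.

Non-candidate pairs (diagonal, non-TF sources) receive a -1e9 additive
logit mask so their edge probability is exactly 0 after softmax.

The three ablation switches (``use_gat``, ``use_cross``, ``use_pool``)
swap each attention block for its trivial counterpart: a linear node
projection, a pass-through of the pairwise scores, and plain mean
pooling respectively.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import LayerNorm, Linear, Module, Tensor, concatenate
from .types import AlignmentError, ExpressionMatrix

__all__ = ["TriHATConfig", "TriHAT", "film", "node_features",
           "sinusoidal_embedding", "save_checkpoint", "load_checkpoint"]

_MASK_LOGIT = -1e9
_PROFILE_PROJECTION_SEED = 0x5EED  # fixed: the projection is a featurizer, not a parameter


@dataclass
class TriHATConfig:
    d_x: int = 64
    d_e: int = 32
    d_t: int = 64
    heads: int = 4
    gat_heads: int = 4
    n_layers: int = 3
    edge_groups: int = 4
    p_profile: int = 32
    leaky_slope: float = 0.2
    use_gat: bool = True
    use_cross: bool = True
    use_pool: bool = True


def sinusoidal_embedding(t: int, d: int, T: int) -> np.ndarray:
    """Standard sinusoidal embedding of the integer diffusion step."""
    half = d // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(1, half - 1))
    ang = t * freqs  # integer-position convention; adjacent steps stay close
    emb = np.concatenate([np.sin(ang), np.cos(ang)])
    if emb.size < d:
        emb = np.concatenate([emb, np.zeros(d - emb.size)])
    return emb


def node_features(expr: ExpressionMatrix, tf_mask: np.ndarray,
                  p_profile: int) -> np.ndarray:
    """Per-gene input features from the expression matrix.

    Marginal summaries (mean, std, dropout fraction, quantiles) describe
    each gene alone; the standardized cross-cell profile, pushed through
    a fixed Gaussian random projection scaled by 1/sqrt(n_cells), keeps
    between-gene dependence visible to the attention layers (inner
    products of projected profiles approximate correlations) while
    remaining usable for any cell count.
    """
    v = expr.values
    n_cells = v.shape[0]
    mean = v.mean(axis=0)
    std = v.std(axis=0)
    dropout = (v == 0).mean(axis=0)
    q10, q50, q90 = np.quantile(v, [0.1, 0.5, 0.9], axis=0)
    prof = (v - mean) / np.where(std > 0, std, 1.0)
    proj_rng = np.random.default_rng(_PROFILE_PROJECTION_SEED)
    if p_profile >= n_cells:
        R = np.eye(n_cells, p_profile)
    else:
        # orthonormal columns: an exact isometry on the retained subspace
        R, _ = np.linalg.qr(proj_rng.standard_normal((n_cells, p_profile)))
    z = (prof.T @ R) / np.sqrt(n_cells)
    summaries = np.stack([mean, std, dropout, q10, q50, q90,
                          tf_mask.astype(float)], axis=1)
    # standardize summary columns so no single scale dominates
    s_mu = summaries.mean(axis=0)
    s_sd = summaries.std(axis=0)
    summaries = (summaries - s_mu) / np.where(s_sd > 0, s_sd, 1.0)
    return np.concatenate([summaries, z], axis=1)


def film(a: Tensor, b: Tensor, lin1: Linear, lin2: Linear) -> Tensor:
    """Feature-wise linear modulation: ``lin1(a) + lin2(a) * b + b``."""
    return lin1(a) + lin2(a) * b + b


class GATv2Layer(Module):
    """One multi-head GATv2 layer over the noisy network's neighborhoods."""

    def __init__(self, d_in: int, d_head: int, heads: int, slope: float,
                 rng: np.random.Generator, concat_heads: bool):
        self.heads, self.d_head, self.slope = heads, d_head, slope
        self.concat_heads = concat_heads
        self.lin_l = Linear(d_in, heads * d_head, rng)
        self.lin_r = Linear(d_in, heads * d_head, rng)
        self.att = Tensor(rng.normal(0, 0.3, size=(heads, d_head)),
                          requires_grad=True)

    def attention(self, X: Tensor, adjacency: np.ndarray
                  ) -> tuple[Tensor, Tensor]:
        n = X.shape[0]
        wl = self.lin_l(X).reshape(n, 1, self.heads, self.d_head)
        wr = self.lin_r(X).reshape(1, n, self.heads, self.d_head)
        scores = ((wl + wr).leaky_relu(self.slope) * self.att).sum(axis=-1)
        adj = np.asarray(adjacency, dtype=bool)
        neigh = adj | adj.T
        np.fill_diagonal(neigh, True)  # self-loop fallback: always attend to self
        bias = np.where(neigh, 0.0, _MASK_LOGIT)[:, :, None]
        alpha = (scores + Tensor(bias)).softmax(axis=1)
        return alpha, wr.reshape(n, self.heads, self.d_head)

    def __call__(self, X: Tensor, adjacency: np.ndarray) -> Tensor:
        n = X.shape[0]
        alpha, wr = self.attention(X, adjacency)
        # h'_i = sum_j alpha_ij W h_j, batched over heads
        a_h = alpha.transpose(2, 0, 1)           # heads x n x n
        v_h = wr.swapaxes(0, 1)                  # heads x n x d_head
        out = (a_h @ v_h).swapaxes(0, 1)         # n x heads x d_head
        if self.concat_heads:
            return out.reshape(n, self.heads * self.d_head)
        return out.mean(axis=1)


class TimeGate(Module):
    """Sigmoid time gate blending aggregated and original node features."""

    def __init__(self, d_t: int, d: int, slope: float, rng: np.random.Generator):
        self.lin_gate = Linear(d_t, d, rng)
        self.lin_fuse = Linear(2 * d, d, rng)
        self.slope = slope

    def blend(self, h_prime: Tensor, x_in: Tensor, t_vec: Tensor) -> Tensor:
        gate = self.lin_gate(t_vec).sigmoid()
        return (1.0 - gate) * h_prime + gate * x_in

    def __call__(self, h_prime: Tensor, x_in: Tensor, t_vec: Tensor) -> Tensor:
        h_tilde = self.blend(h_prime, x_in, t_vec)
        return self.lin_fuse(concatenate([h_tilde, x_in], axis=-1)
                             ).leaky_relu(self.slope)


class TransformerLayer(Module):
    """One graph-transformer layer updating (X, E, t) jointly."""

    def __init__(self, cfg: TriHATConfig, rng: np.random.Generator):
        self.cfg = cfg
        d_x, d_e, d_t = cfg.d_x, cfg.d_e, cfg.d_t
        # node self-attention
        self.lin_q = Linear(d_x, d_x, rng)
        self.lin_k = Linear(d_x, d_x, rng)
        self.lin_v = Linear(d_x, d_x, rng)
        self.lin_o = Linear(d_x, d_x, rng)
        self.film_x1 = Linear(d_t, d_x, rng, small_init=True)
        self.film_x2 = Linear(d_t, d_x, rng, small_init=True)
        self.ln_x = LayerNorm(d_x)
        self.ffn1 = Linear(d_x, 2 * d_x, rng)
        self.ffn2 = Linear(2 * d_x, d_x, rng)
        self.ln_ffn = LayerNorm(d_x)
        # edge update
        self.lin_qe = Linear(d_x, d_x, rng)
        self.lin_ke = Linear(d_x, d_x, rng)
        self.lin_expand = Linear(cfg.heads, d_e, rng)
        if cfg.use_cross:
            self.film_e1 = Linear(d_t, d_e, rng, small_init=True)
            self.film_e2 = Linear(d_t, d_e, rng, small_init=True)
            self.lin_qc = Linear(d_e, d_e, rng)
            self.lin_kc = Linear(d_e, d_e, rng)
            self.lin_vc = Linear(d_e, d_e, rng)
        self.ln_e = LayerNorm(d_e)
        # time update
        self.lin_t = Linear(d_t, d_t, rng)
        if cfg.use_pool:
            self.gpox_gate = Linear(d_x, d_x, rng)
            self.gpox_out = Linear(d_x, d_t, rng)
            self.atte_score = Linear(d_e + 2 * d_x, 1, rng)
            self.atte_val = Linear(d_e + 2 * d_x, d_t, rng)
        else:  # plain-mean fallback (ablation P)
            self.pool_x = Linear(d_x, d_t, rng)
            self.pool_e = Linear(d_e, d_t, rng)

    # --- node branch -------------------------------------------------------
    def node_attention(self, X: Tensor) -> Tensor:
        cfg = self.cfg
        n = X.shape[0]
        h, d_k = cfg.heads, cfg.d_x // cfg.heads
        q = self.lin_q(X).reshape(n, h, d_k).swapaxes(0, 1)
        k = self.lin_k(X).reshape(n, h, d_k).swapaxes(0, 1)
        v = self.lin_v(X).reshape(n, h, d_k).swapaxes(0, 1)
        att = ((q @ k.swapaxes(1, 2)) * (1.0 / np.sqrt(d_k))).softmax(axis=-1)
        out = (att @ v).swapaxes(0, 1).reshape(n, cfg.d_x)
        return self.lin_o(out)

    def update_nodes(self, X: Tensor, t_vec: Tensor) -> Tensor:
        attn = self.node_attention(X)
        x_hat = self.ln_x(X + film(t_vec, attn, self.film_x1, self.film_x2))
        ff = self.ffn2(self.ffn1(x_hat).leaky_relu(self.cfg.leaky_slope))
        return self.ln_ffn(x_hat + ff)

    # --- edge branch -------------------------------------------------------
    def edge_self(self, X: Tensor) -> Tensor:
        cfg = self.cfg
        n = X.shape[0]
        h, d_k = cfg.heads, cfg.d_x // cfg.heads
        q = self.lin_qe(X).reshape(n, h, d_k).swapaxes(0, 1)
        k = self.lin_ke(X).reshape(n, h, d_k).swapaxes(0, 1)
        scores = (q @ k.swapaxes(1, 2)) * (1.0 / np.sqrt(d_k))  # h x n x n
        return self.lin_expand(scores.transpose(1, 2, 0))       # n x n x d_e

    def cross_attention(self, e_self: Tensor, e_feed: Tensor
                        ) -> tuple[Tensor, Tensor]:
        """Pairwise-aligned cross-attention over channel groups.

        Each ordered pair is one token: its E_self representation
        queries its own E_feed representation split into channel
        groups, a tractable refinement instead of all-pairs x all-pairs
        attention.
        """
        cfg = self.cfg
        n = e_self.shape[0]
        G, gd = cfg.edge_groups, cfg.d_e // cfg.edge_groups
        q = self.lin_qc(e_self).reshape(n, n, G, gd)
        k = self.lin_kc(e_feed).reshape(n, n, G, gd)
        v = self.lin_vc(e_feed).reshape(n, n, G, gd)
        att = ((q @ k.swapaxes(2, 3)) * (1.0 / np.sqrt(gd))).softmax(axis=-1)
        out = (att @ v).reshape(n, n, cfg.d_e)
        return out, att

    def update_edges(self, X: Tensor, e_feed: Tensor | None,
                     t_vec: Tensor) -> Tensor:
        e_self = self.edge_self(X)
        if not self.cfg.use_cross:
            return self.ln_e(e_self)
        e_feed = film(t_vec, e_feed, self.film_e1, self.film_e2)
        out, _ = self.cross_attention(e_self, e_feed)
        return self.ln_e(e_self + out)

    # --- time branch -------------------------------------------------------
    def gpox(self, X: Tensor) -> Tensor:
        gate = self.gpox_gate(X).sigmoid()
        return self.gpox_out((gate * X).sum(axis=0))

    def atte(self, X: Tensor, E: Tensor, cand_mask: np.ndarray) -> Tensor:
        n = X.shape[0]
        xi = X.reshape(n, 1, -1) + Tensor(np.zeros((n, n, 1)))
        xj = X.reshape(1, n, -1) + Tensor(np.zeros((n, n, 1)))
        tokens = concatenate([E, xi, xj], axis=-1).reshape(n * n, -1)
        bias = np.where(cand_mask.reshape(-1), 0.0, _MASK_LOGIT)[:, None]
        w = (self.atte_score(tokens) + Tensor(bias)).softmax(axis=0)
        return (w * self.atte_val(tokens)).sum(axis=0)

    def update_time(self, X: Tensor, E: Tensor, t_vec: Tensor,
                    cand_mask: np.ndarray) -> Tensor:
        base = self.lin_t(t_vec)
        if not self.cfg.use_pool:
            return base + self.pool_x(X.mean(axis=0)) + self.pool_e(
                E.reshape(-1, self.cfg.d_e).mean(axis=0))
        return base + self.gpox(X) + self.atte(X, E, cand_mask)

    def __call__(self, X: Tensor, E: Tensor, t_vec: Tensor,
                 cand_mask: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        x_hat = self.update_nodes(X, t_vec)
        e_hat = self.update_edges(x_hat, E, t_vec)
        t_hat = self.update_time(x_hat, e_hat, t_vec, cand_mask)
        return x_hat, e_hat, t_hat


class TriHAT(Module):
    """Full denoiser: node init -> time-gated GATv2 -> graph transformer."""

    def __init__(self, config: TriHATConfig, n_cells_hint: int = 100,
                 seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        cfg = config
        d_in = cfg.p_profile + 7
        self.lin_node_in = Linear(d_in, cfg.d_x, rng)
        self.lin_time_in = Linear(cfg.d_t, cfg.d_t, rng)
        if cfg.use_cross:
            # the fed-back noisy network enters through the cross-attention
            # branch; without it the edge encoder has no consumer
            self.lin_edge_in = Linear(3, cfg.d_e, rng)
        if cfg.use_gat:
            # layer 1 concatenates heads (head dim d_x/heads); layer 2
            # averages heads (head dim d_x), so both blocks emit d_x.
            self.gat1 = GATv2Layer(cfg.d_x, cfg.d_x // cfg.gat_heads,
                                   cfg.gat_heads, cfg.leaky_slope, rng,
                                   concat_heads=True)
            self.gate1 = TimeGate(cfg.d_t, cfg.d_x, cfg.leaky_slope, rng)
            self.gat2 = GATv2Layer(cfg.d_x, cfg.d_x, cfg.gat_heads,
                                   cfg.leaky_slope, rng, concat_heads=False)
            self.gate2 = TimeGate(cfg.d_t, cfg.d_x, cfg.leaky_slope, rng)
        else:
            self.lin_node_plain = Linear(cfg.d_x, cfg.d_x, rng)
        self.layers = [TransformerLayer(cfg, rng) for _ in range(cfg.n_layers)]
        # final time embedding modulates the readout so the last layer's
        # time update participates in the prediction
        self.readout_film1 = Linear(cfg.d_t, cfg.d_e, rng, small_init=True)
        self.readout_film2 = Linear(cfg.d_t, cfg.d_e, rng, small_init=True)
        self.readout = Linear(cfg.d_e, 2, rng)
        self.T_hint = 100

    # -- featurization ------------------------------------------------------
    def _node_init(self, expr: ExpressionMatrix, tf_mask: np.ndarray) -> Tensor:
        return self.lin_node_in(Tensor(node_features(
            expr, tf_mask, self.config.p_profile)))

    def _time_init(self, t: int, T: int) -> Tensor:
        return self.lin_time_in(Tensor(sinusoidal_embedding(t, self.config.d_t, T)))

    def _edge_init(self, e_t: np.ndarray, cand_mask: np.ndarray) -> Tensor:
        onehot = np.zeros(e_t.shape + (3,))
        onehot[..., 0] = (e_t == 0) & cand_mask
        onehot[..., 1] = (e_t == 1) & cand_mask
        onehot[..., 2] = ~cand_mask  # dedicated "absent" encoding
        return self.lin_edge_in(Tensor(onehot))

    # -- forward ------------------------------------------------------------
    def forward(self, e_t: np.ndarray, expr: ExpressionMatrix, t: int,
                tf_mask: np.ndarray, genes: list[str] | None = None,
                T: int | None = None) -> Tensor:
        """Per-pair clean-edge logits, shape (n, n, 2)."""
        e_t = np.asarray(e_t)
        n = e_t.shape[0]
        if expr.n_genes != n:
            raise AlignmentError(
                f"expression has {expr.n_genes} genes but edge state has {n}")
        if genes is not None and expr.genes != list(genes):
            raise AlignmentError("gene order mismatch between expression and network")
        T = T or self.T_hint
        tf_mask = np.asarray(tf_mask, dtype=bool)
        cand_mask = np.repeat(tf_mask[:, None], n, axis=1)
        np.fill_diagonal(cand_mask, False)

        X = self._node_init(expr, tf_mask)
        t_vec = self._time_init(t, T)
        if self.config.use_gat:
            h1 = self.gat1(X, e_t)
            X = self.gate1(h1, X, t_vec)
            h2 = self.gat2(X, e_t)
            X = self.gate2(h2, X, t_vec)
        else:
            X = self.lin_node_plain(X).leaky_relu(self.config.leaky_slope)
        E = self._edge_init(e_t, cand_mask) if self.config.use_cross else None
        for layer in self.layers:
            X, E, t_vec = layer(X, E, t_vec, cand_mask)
        logits = self.readout(film(t_vec, E, self.readout_film1,
                                   self.readout_film2))
        bias = np.zeros(logits.shape)
        bias[..., 1][~cand_mask] = _MASK_LOGIT
        return logits + Tensor(bias)

    def predict_e0_probs(self, e_t: np.ndarray, expr: ExpressionMatrix, t: int,
                         tf_mask: np.ndarray, T: int | None = None) -> np.ndarray:
        """Probability that each candidate pair is an edge in E_0."""
        logits = self.forward(e_t, expr, t, tf_mask, T=T)
        return logits.softmax(axis=-1).data[..., 1]


# ---------------------------------------------------------------------------
# Checkpoints: single-file binary container with an embedded JSON header
# ---------------------------------------------------------------------------

def save_checkpoint(model: TriHAT, path, meta: dict | None = None) -> None:
    state = model.state_dict()
    index, blobs, offset = {}, [], 0
    for name, arr in state.items():
        raw = np.ascontiguousarray(arr, dtype=np.float64).tobytes()
        index[name] = {"shape": list(arr.shape), "offset": offset,
                       "nbytes": len(raw)}
        blobs.append(raw)
        offset += len(raw)
    header = {"format": "planet-ckpt-v1", "config": asdict(model.config),
              "meta": meta or {}, "index": index}
    hbytes = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(len(hbytes).to_bytes(8, "little"))
        fh.write(hbytes)
        for raw in blobs:
            fh.write(raw)


def load_checkpoint(path) -> tuple[TriHAT, dict]:
    with open(path, "rb") as fh:
        hlen = int.from_bytes(fh.read(8), "little")
        header = json.loads(fh.read(hlen).decode())
        body = fh.read()
    if header.get("format") != "planet-ckpt-v1":
        raise ValueError(f"{path} is not a planet checkpoint")
    model = TriHAT(TriHATConfig(**header["config"]))
    state = {}
    for name, entry in header["index"].items():
        arr = np.frombuffer(body[entry["offset"]:entry["offset"] + entry["nbytes"]],
                            dtype=np.float64).reshape(entry["shape"])
        state[name] = arr
    model.load_state_dict(state)
    return model, header["meta"]
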