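"""Divided depth/space attention encoder for 2.5D patches (NumPy reference).

A 2.5D patch is a z-stack of F co-registered section tiles.  Each tile
is cut into N non-overlapping P x P sub-patches; every sub-patch is
flattened to a length-3P^2 vector, linearly embedded into R^D and given
a learned spatio-depth positional embedding, with one classification
token prepended.  Each of L encoder blocks applies *divided* attention:
first depth ("time") attention, in which the token at spatial location p
and slice t attends only to the classification key and the tokens at
the same location p across all slices t' = 1..F; then spatial attention
within the same slice (classification key plus p' = 1..N at slice t);
then a two-layer GELU MLP.  All three sub-layers are residual with
pre-layer-normalization.

The classification token is passed through the depth-attention stage
unchanged and attends over all tokens in the spatial stage — the one
place the factorized key sets leave its path open to choice.

This is a desk-scale reference implementation (defaults D=64, L=2, A=4):
the factorized attention, the recorded per-layer attention maps, and the
parameter layout are the point, not throughput.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EncoderConfig", "AttentionMaps", "DepthEncoder",
           "tokenize", "layer_norm", "qkv_project", "time_attention",
           "space_attention", "encoder_block", "gelu",
           "init_encoder_params", "count_parameters"]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the 2.5D patch encoder.

    ``n_patches`` (N) is fixed by the input tile size: N = (H/P)(W/P).
    ``embed_dim`` must be divisible by ``n_heads``; the per-head width is
    Dh = D/A.
    """

    patch_px: int = 8            # P
    embed_dim: int = 64          # D
    n_heads: int = 4             # A
    n_layers: int = 2            # L
    mlp_ratio: float = 4.0
    input_px: int = 32           # H = W of one slice tile
    n_slices: int = 4            # F
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.input_px % self.patch_px != 0:
            raise ValueError("input_px must be divisible by patch_px")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    @property
    def n_patches(self) -> int:
        side = self.input_px // self.patch_px
        return side * side

    @property
    def n_tokens(self) -> int:
        return 1 + self.n_patches * self.n_slices


@dataclass
class AttentionMaps:
    """Per-layer attention weights recorded during a forward pass.

    ``time``  : list over layers of (A, N, F, F+1) arrays — query (p, t),
                keys [cls, t'=1..F at the same p].
    ``space`` : list over layers of (A, N, F, N+1) arrays — query (p, t),
                keys [cls, p'=1..N at the same t].
    ``cls_space`` : list over layers of (A, 1 + N*F) arrays — the
                classification token's spatial-stage attention over all
                tokens.
    """

    time: list = field(default_factory=list)
    space: list = field(default_factory=list)
    cls_space: list = field(default_factory=list)

    def head_averaged_time(self, layer: int) -> np.ndarray:
        return self.time[layer].mean(axis=0)

    def head_averaged_space(self, layer: int) -> np.ndarray:
        return self.space[layer].mean(axis=0)


# ---------------------------------------------------------------------------
# primitives


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian error linear unit."""
    from scipy.special import erf
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def layer_norm(x: np.ndarray, gain: np.ndarray, bias: np.ndarray,
               eps: float = 1e-6) -> np.ndarray:
    """Layer normalization over the last (embedding) axis."""
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gain + bias


def _split_heads(x: np.ndarray, n_heads: int) -> np.ndarray:
    """(M, D) -> (A, M, Dh)."""
    m, d = x.shape
    return x.reshape(m, n_heads, d // n_heads).transpose(1, 0, 2)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    """(A, M, Dh) -> (M, D)."""
    a, m, dh = x.shape
    return x.transpose(1, 0, 2).reshape(m, a * dh)


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# parameter initialization


def _linear_init(rng, d_out, d_in):
    return rng.normal(0.0, np.sqrt(2.0 / (d_in + d_out)), size=(d_out, d_in))


def init_encoder_params(cfg: EncoderConfig) -> dict:
    """Seeded deterministic initialization of all encoder weights."""
    rng = np.random.default_rng(cfg.seed)
    d, p = cfg.embed_dim, cfg.patch_px
    params: dict[str, np.ndarray] = {
        "embed_W": _linear_init(rng, d, 3 * p * p),
        "embed_b": np.zeros(d),
        "cls": rng.normal(0.0, 0.02, size=d),
        "pos": rng.normal(0.0, 0.02, size=(cfg.n_patches, cfg.n_slices, d)),
    }
    hidden = int(cfg.mlp_ratio * d)
    for l in range(cfg.n_layers):
        for stage in ("time", "space"):
            params[f"l{l}_{stage}_ln_g"] = np.ones(d)
            params[f"l{l}_{stage}_ln_b"] = np.zeros(d)
            for w in ("q", "k", "v"):
                params[f"l{l}_{stage}_W{w}"] = _linear_init(rng, d, d)
                params[f"l{l}_{stage}_b{w}"] = np.zeros(d)
            params[f"l{l}_{stage}_Wo"] = _linear_init(rng, d, d)
            params[f"l{l}_{stage}_bo"] = np.zeros(d)
        params[f"l{l}_mlp_ln_g"] = np.ones(d)
        params[f"l{l}_mlp_ln_b"] = np.zeros(d)
        params[f"l{l}_mlp_W1"] = _linear_init(rng, hidden, d)
        params[f"l{l}_mlp_b1"] = np.zeros(hidden)
        params[f"l{l}_mlp_W2"] = _linear_init(rng, d, hidden)
        params[f"l{l}_mlp_b2"] = np.zeros(d)
    params["final_ln_g"] = np.ones(d)
    params["final_ln_b"] = np.zeros(d)
    return params


def count_parameters(cfg: EncoderConfig) -> int:
    """Total parameter count — a pure function of the configuration."""
    return sum(v.size for v in init_encoder_params(cfg).values())


# ---------------------------------------------------------------------------
# forward operations


def tokenize(patch: np.ndarray, cfg: EncoderConfig, params: dict) -> np.ndarray:
    """Embed a (F, H, W, 3) 2.5D patch into the (1 + N*F, D) token grid.

    Token 0 is the classification token; patch token (p, t) sits at index
    ``1 + t*N + p`` with p row-major over the (H/P, W/P) tile grid.
    Pixel values are mapped to [-0.5, 0.5] before embedding.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 4 or patch.shape[3] != 3:
        raise ValueError("patch must be (F, H, W, 3)")
    f, h, w, _ = patch.shape
    p = cfg.patch_px
    if h % p or w % p:
        raise ValueError(f"tile size {h}x{w} not divisible by P={p}")
    if patch.max() > 1.5:
        patch = patch / 255.0
    patch = patch - 0.5
    n_side_y, n_side_x = h // p, w // p
    n = n_side_y * n_side_x
    # (F, ny, p, nx, p, 3) -> (F, ny*nx, p*p*3)
    tiles = patch.reshape(f, n_side_y, p, n_side_x, p, 3)
    tiles = tiles.transpose(0, 1, 3, 2, 4, 5).reshape(f, n, 3 * p * p)
    emb = tiles @ params["embed_W"].T + params["embed_b"]   # (F, N, D)
    emb = emb + params["pos"][:n, :f].transpose(1, 0, 2)    # pos is (N, F, D)
    tokens = np.concatenate([params["cls"][None, :],
                             emb.reshape(f * n, -1)], axis=0)
    return tokens


def qkv_project(tokens: np.ndarray, layer_weights: dict, head: int | None = None,
                n_heads: int | None = None):
    """Per-head q/k/v projections of layer-normalized tokens.

    ``layer_weights`` holds ``ln_g, ln_b, Wq, bq, Wk, bk, Wv, bv``.  With
    ``head`` given, returns that head's (M, Dh) triples; otherwise the
    stacked (A, M, Dh) triples.
    """
    h = layer_norm(tokens, layer_weights["ln_g"], layer_weights["ln_b"])
    q = h @ layer_weights["Wq"].T + layer_weights["bq"]
    k = h @ layer_weights["Wk"].T + layer_weights["bk"]
    v = h @ layer_weights["Wv"].T + layer_weights["bv"]
    if n_heads is None:
        n_heads = layer_weights.get("n_heads", 1)
    qh, kh, vh = (_split_heads(x, n_heads) for x in (q, k, v))
    if head is not None:
        return qh[head], kh[head], vh[head]
    return qh, kh, vh


def _stage_weights(params: dict, layer: int, stage: str, n_heads: int) -> dict:
    p = f"l{layer}_{stage}_"
    return {"ln_g": params[p + "ln_g"], "ln_b": params[p + "ln_b"],
            "Wq": params[p + "Wq"], "bq": params[p + "bq"],
            "Wk": params[p + "Wk"], "bk": params[p + "bk"],
            "Wv": params[p + "Wv"], "bv": params[p + "bv"],
            "Wo": params[p + "Wo"], "bo": params[p + "bo"],
            "n_heads": n_heads}


def time_attention(tokens: np.ndarray, cfg: EncoderConfig, layer_weights: dict,
                   maps: AttentionMaps | None = None) -> np.ndarray:
    """Depth attention: query (p, t) sees keys {cls} ∪ {(p, t'), t'=1..F}.

    Exactly F+1 logits per patch-token query, scaled by 1/sqrt(Dh).  The
    classification token is passed through unchanged.
    """
    a, dh = cfg.n_heads, cfg.head_dim
    n, f = cfg.n_patches, cfg.n_slices
    qh, kh, vh = qkv_project(tokens, layer_weights, n_heads=a)
    # patch tokens as (A, F, N, Dh) -> (A, N, F, Dh)
    q = qh[:, 1:].reshape(a, f, n, dh).transpose(0, 2, 1, 3)
    k = kh[:, 1:].reshape(a, f, n, dh).transpose(0, 2, 1, 3)
    v = vh[:, 1:].reshape(a, f, n, dh).transpose(0, 2, 1, 3)
    logits_t = np.einsum("anfd,angd->anfg", q, k) / np.sqrt(dh)
    logits_c = np.einsum("anfd,ad->anf", q, kh[:, 0]) / np.sqrt(dh)
    logits = np.concatenate([logits_c[..., None], logits_t], axis=-1)  # (A,N,F,F+1)
    w = _softmax(logits)
    if maps is not None:
        maps.time.append(w.copy())
    out = (np.einsum("anfg,angd->anfd", w[..., 1:], v)
           + w[..., :1] * vh[:, 0][:, None, None, :])          # (A, N, F, Dh)
    out = out.transpose(0, 2, 1, 3).reshape(a, f * n, dh)      # token order (t, p)
    merged = _merge_heads(out) @ layer_weights["Wo"].T + layer_weights["bo"]
    result = tokens.copy()
    result[1:] = tokens[1:] + merged
    return result


def space_attention(tokens_time: np.ndarray, cfg: EncoderConfig, layer_weights: dict,
                    maps: AttentionMaps | None = None) -> np.ndarray:
    """Spatial attention: query (p, t) sees keys {cls} ∪ {(p', t), p'=1..N}.

    The classification-token query attends over all tokens.
    """
    a, dh = cfg.n_heads, cfg.head_dim
    n, f = cfg.n_patches, cfg.n_slices
    qh, kh, vh = qkv_project(tokens_time, layer_weights, n_heads=a)
    q = qh[:, 1:].reshape(a, f, n, dh).transpose(0, 2, 1, 3)   # (A, N, F, Dh)
    k = kh[:, 1:].reshape(a, f, n, dh).transpose(0, 2, 1, 3)
    v = vh[:, 1:].reshape(a, f, n, dh).transpose(0, 2, 1, 3)
    logits_p = np.einsum("anfd,amfd->anfm", q, k) / np.sqrt(dh)
    logits_c = np.einsum("anfd,ad->anf", q, kh[:, 0]) / np.sqrt(dh)
    logits = np.concatenate([logits_c[..., None], logits_p], axis=-1)  # (A,N,F,N+1)
    w = _softmax(logits)
    if maps is not None:
        maps.space.append(w.copy())
    out = (np.einsum("anfm,amfd->anfd", w[..., 1:], v)
           + w[..., :1] * vh[:, 0][:, None, None, :])
    out = out.transpose(0, 2, 1, 3).reshape(a, f * n, dh)
    # classification query over all tokens
    logits_cls = np.einsum("ad,amd->am", qh[:, 0], kh) / np.sqrt(dh)
    w_cls = _softmax(logits_cls)
    if maps is not None:
        maps.cls_space.append(w_cls.copy())
    out_cls = np.einsum("am,amd->ad", w_cls, vh)               # (A, Dh)
    full = np.concatenate([out_cls[:, None, :], out], axis=1)  # (A, M, Dh)
    merged = _merge_heads(full) @ layer_weights["Wo"].T + layer_weights["bo"]
    return tokens_time + merged


def encoder_block(tokens: np.ndarray, cfg: EncoderConfig, params: dict,
                  layer: int, maps: AttentionMaps | None = None) -> np.ndarray:
    """One block: depth attention -> spatial attention -> residual MLP."""
    tw = _stage_weights(params, layer, "time", cfg.n_heads)
    sw = _stage_weights(params, layer, "space", cfg.n_heads)
    z = time_attention(tokens, cfg, tw, maps)
    z = space_attention(z, cfg, sw, maps)
    h = layer_norm(z, params[f"l{layer}_mlp_ln_g"], params[f"l{layer}_mlp_ln_b"])
    h = gelu(h @ params[f"l{layer}_mlp_W1"].T + params[f"l{layer}_mlp_b1"])
    h = h @ params[f"l{layer}_mlp_W2"].T + params[f"l{layer}_mlp_b2"]
    return z + h


class DepthEncoder:
    """The full tokenize -> L blocks -> final layer norm encoder."""

    def __init__(self, cfg: EncoderConfig, params: dict | None = None):
        self.cfg = cfg
        self.params = params if params is not None else init_encoder_params(cfg)

    def forward(self, patch: np.ndarray, record_attention: bool = False
                ) -> tuple[np.ndarray, AttentionMaps | None]:
        """Encode one 2.5D patch; returns (tokens, attention maps)."""
        maps = AttentionMaps() if record_attention else None
        tokens = tokenize(patch, self.cfg, self.params)
        for l in range(self.cfg.n_layers):
            tokens = encoder_block(tokens, self.cfg, self.params, l, maps)
        tokens = layer_norm(tokens, self.params["final_ln_g"], self.params["final_ln_b"])
        return tokens, maps

    def embed(self, patch: np.ndarray) -> np.ndarray:
        """Classification-token embedding of a 2.5D patch."""
        tokens, _ = self.forward(patch)
        return tokens[0]

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())
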