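"""Momentum self-distillation of the 2.5D patch encoder.

A student encoder is trained to match the output distribution of a
teacher with the same architecture.  Global views (large crops) of a
2.5D patch pass through the teacher; the student sees all views,
including small local crops, so it must learn local-to-global
correspondences.  The teacher is never trained by gradient: its weights
are an exponential moving average of the student's, and its output
distribution is centered (running mean subtracted) and sharpened with a
lower temperature than the student's, the standard collapse guards.

The student gradients come from a hand-written reverse pass through the
encoder; attention is evaluated in its masked dense form, which equals
the divided (gathered) form of :mod:`histo25d.encoder` exactly — one
implementation is the oracle of the other in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import skimage.transform
from scipy.special import erf

from histo25d.encoder import EncoderConfig, init_encoder_params

__all__ = ["DistillConfig", "SelfDistiller", "distill_step", "ema_update",
           "make_views", "forward_logits"]

_NEG = -1e30  # additive mask: exp underflows to exactly 0


# ---------------------------------------------------------------------------
# differentiable primitives (forward returns cache for the reverse pass)


def _ln_fwd(x, g, b, eps=1e-6):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _ln_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m = xhat.shape[-1]
    dx = inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))
    return dx, dg, db


def _gelu_fwd(x):
    phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
    return x * phi, (x, phi)


def _gelu_bwd(dy, cache):
    x, phi = cache
    pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return dy * (phi + x * pdf)


def _masks(cfg: EncoderConfig) -> tuple[np.ndarray, np.ndarray]:
    """Additive (M, M) attention masks for the time and space stages."""
    n, f = cfg.n_patches, cfg.n_slices
    m = 1 + n * f
    idx_p = np.concatenate([[-1], np.tile(np.arange(n), f)])
    idx_t = np.concatenate([[-1], np.repeat(np.arange(f), n)])
    time = np.full((m, m), _NEG)
    space = np.full((m, m), _NEG)
    same_p = idx_p[:, None] == idx_p[None, :]
    same_t = idx_t[:, None] == idx_t[None, :]
    time[same_p] = 0.0
    space[same_t] = 0.0
    time[:, 0] = 0.0   # classification key always visible
    space[:, 0] = 0.0
    time[0, :] = _NEG
    time[0, 0] = 0.0   # cls row irrelevant in time stage (query-gated out)
    space[0, :] = 0.0  # cls query attends over all tokens in space stage
    return time, space


def _attn_fwd(z, prefix, params, cfg, mask, gate):
    """Pre-norm masked multi-head attention with residual and query gate."""
    a, dh = cfg.n_heads, cfg.head_dim
    m = z.shape[0]
    h, ln_cache = _ln_fwd(z, params[prefix + "ln_g"], params[prefix + "ln_b"])
    q = h @ params[prefix + "Wq"].T + params[prefix + "bq"]
    k = h @ params[prefix + "Wk"].T + params[prefix + "bk"]
    v = h @ params[prefix + "Wv"].T + params[prefix + "bv"]
    qh = q.reshape(m, a, dh).transpose(1, 0, 2)
    kh = k.reshape(m, a, dh).transpose(1, 0, 2)
    vh = v.reshape(m, a, dh).transpose(1, 0, 2)
    logits = qh @ kh.transpose(0, 2, 1) / np.sqrt(dh) + mask
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    attn = e / e.sum(axis=-1, keepdims=True)      # (A, M, M)
    outh = attn @ vh                              # (A, M, Dh)
    out = outh.transpose(1, 0, 2).reshape(m, a * dh)
    o = out @ params[prefix + "Wo"].T + params[prefix + "bo"]
    znew = z + gate[:, None] * o
    cache = (z, h, ln_cache, qh, kh, vh, attn, out, gate)
    return znew, cache


def _attn_bwd(dznew, cache, prefix, params, cfg, grads):
    a, dh = cfg.n_heads, cfg.head_dim
    z, h, ln_cache, qh, kh, vh, attn, out, gate = cache
    m = z.shape[0]
    do = gate[:, None] * dznew
    grads[prefix + "Wo"] += do.T @ out
    grads[prefix + "bo"] += do.sum(axis=0)
    dout = do @ params[prefix + "Wo"]
    douth = dout.reshape(m, a, dh).transpose(1, 0, 2)
    dattn = douth @ vh.transpose(0, 2, 1)
    dvh = attn.transpose(0, 2, 1) @ douth
    dlogits = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
    dqh = dlogits @ kh / np.sqrt(dh)
    dkh = dlogits.transpose(0, 2, 1) @ qh / np.sqrt(dh)
    dq = dqh.transpose(1, 0, 2).reshape(m, a * dh)
    dk = dkh.transpose(1, 0, 2).reshape(m, a * dh)
    dv = dvh.transpose(1, 0, 2).reshape(m, a * dh)
    dh_total = dq @ params[prefix + "Wq"] + dk @ params[prefix + "Wk"] \
        + dv @ params[prefix + "Wv"]
    grads[prefix + "Wq"] += dq.T @ h
    grads[prefix + "bq"] += dq.sum(axis=0)
    grads[prefix + "Wk"] += dk.T @ h
    grads[prefix + "bk"] += dk.sum(axis=0)
    grads[prefix + "Wv"] += dv.T @ h
    grads[prefix + "bv"] += dv.sum(axis=0)
    dz_ln, dg, db = _ln_bwd(dh_total, ln_cache)
    grads[prefix + "ln_g"] += dg
    grads[prefix + "ln_b"] += db
    return dznew + dz_ln


def _tiles_of(patch, cfg):
    patch = np.asarray(patch, dtype=float)
    f, hh, ww, _ = patch.shape
    p = cfg.patch_px
    if patch.max() > 1.5:
        patch = patch / 255.0
    patch = patch - 0.5
    tiles = patch.reshape(f, hh // p, p, ww // p, p, 3)
    return tiles.transpose(0, 1, 3, 2, 4, 5).reshape(f, (hh // p) * (ww // p), 3 * p * p)


def forward_logits(params: dict, patch: np.ndarray, cfg: EncoderConfig,
                   with_cache: bool = False):
    """Encoder + projection head forward; masked-attention formulation."""
    tiles = _tiles_of(patch, cfg)                 # (F, N, 3P^2)
    f, n, _ = tiles.shape
    emb = tiles @ params["embed_W"].T + params["embed_b"]
    emb = emb + params["pos"][:n, :f].transpose(1, 0, 2)
    z = np.concatenate([params["cls"][None, :], emb.reshape(f * n, -1)], axis=0)
    mask_t, mask_s = _masks(cfg)
    gate_t = np.ones(z.shape[0])
    gate_t[0] = 0.0
    gate_s = np.ones(z.shape[0])
    caches = []
    for l in range(cfg.n_layers):
        z, c_t = _attn_fwd(z, f"l{l}_time_", params, cfg, mask_t, gate_t)
        z, c_s = _attn_fwd(z, f"l{l}_space_", params, cfg, mask_s, gate_s)
        h_in = z
        h1, ln_c = _ln_fwd(z, params[f"l{l}_mlp_ln_g"], params[f"l{l}_mlp_ln_b"])
        h2 = h1 @ params[f"l{l}_mlp_W1"].T + params[f"l{l}_mlp_b1"]
        h3, gelu_c = _gelu_fwd(h2)
        h4 = h3 @ params[f"l{l}_mlp_W2"].T + params[f"l{l}_mlp_b2"]
        z = h_in + h4
        caches.append((c_t, c_s, ln_c, h1, gelu_c, h3))
    zf, ln_f_c = _ln_fwd(z, params["final_ln_g"], params["final_ln_b"])
    cls = zf[0]
    g1 = cls @ params["head_W1"].T + params["head_b1"]
    g2, head_gelu_c = _gelu_fwd(g1)
    logits = g2 @ params["head_W2"].T + params["head_b2"]
    if not with_cache:
        return logits
    cache = (tiles, caches, ln_f_c, zf, cls, g2, head_gelu_c)
    return logits, cache


def backward_logits(dlogits: np.ndarray, cache, params: dict,
                    cfg: EncoderConfig) -> dict:
    """Gradients of all parameters for one view's logits gradient."""
    tiles, caches, ln_f_c, zf, cls, g2, head_gelu_c = cache
    f, n, _ = tiles.shape
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["head_W2"] += np.outer(dlogits, g2)
    grads["head_b2"] += dlogits
    dg2 = dlogits @ params["head_W2"]
    dg1 = _gelu_bwd(dg2, head_gelu_c)
    grads["head_W1"] += np.outer(dg1, cls)
    grads["head_b1"] += dg1
    dzf = np.zeros_like(zf)
    dzf[0] = dg1 @ params["head_W1"]
    dz, dg, db = _ln_bwd(dzf, ln_f_c)
    grads["final_ln_g"] += dg
    grads["final_ln_b"] += db
    for l in range(cfg.n_layers - 1, -1, -1):
        c_t, c_s, ln_c, h1, gelu_c, h3 = caches[l]
        dh4 = dz
        grads[f"l{l}_mlp_W2"] += dh4.T @ h3
        grads[f"l{l}_mlp_b2"] += dh4.sum(axis=0)
        dh3 = dh4 @ params[f"l{l}_mlp_W2"]
        dh2 = _gelu_bwd(dh3, gelu_c)
        grads[f"l{l}_mlp_W1"] += dh2.T @ h1
        grads[f"l{l}_mlp_b1"] += dh2.sum(axis=0)
        dh1 = dh2 @ params[f"l{l}_mlp_W1"]
        dz_ln, dg, db = _ln_bwd(dh1, ln_c)
        grads[f"l{l}_mlp_ln_g"] += dg
        grads[f"l{l}_mlp_ln_b"] += db
        dz = dz + dz_ln
        dz = _attn_bwd(dz, c_s, f"l{l}_space_", params, cfg, grads)
        dz = _attn_bwd(dz, c_t, f"l{l}_time_", params, cfg, grads)
    grads["cls"] += dz[0]
    demb = dz[1:].reshape(f, n, -1)
    grads["pos"][:n, :f] += demb.transpose(1, 0, 2)
    grads["embed_W"] += np.einsum("fnd,fnk->dk", demb, tiles)
    grads["embed_b"] += demb.sum(axis=(0, 1))
    return grads


# ---------------------------------------------------------------------------
# DINO-style loss, EMA and views


def _softmax(x):
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


def ema_update(teacher: dict, student: dict, m: float) -> dict:
    """teacher <- m * teacher + (1 - m) * student, elementwise."""
    if not (0.0 <= m <= 1.0):
        raise ValueError(f"momentum must lie in [0, 1], got {m}")
    return {k: m * teacher[k] + (1.0 - m) * student[k] for k in teacher}


def make_views(patch: np.ndarray, cfg: EncoderConfig, rng: np.random.Generator,
               n_global: int = 2, n_local: int = 4,
               global_scale=(0.6, 1.0), local_scale=(0.2, 0.5)) -> tuple[list, list]:
    """Random resized spatial crops of a 2.5D patch, full depth kept.

    Global views cover large regions, local views small ones; every view
    is resized back to ``cfg.input_px`` so the token geometry (and the
    positional table) is shared across views.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.max() > 1.5:
        patch = patch / 255.0
    f, h, w, _ = patch.shape
    out = cfg.input_px

    def crop(scale_range):
        s = np.sqrt(rng.uniform(*scale_range))
        ch, cw = max(4, int(s * h)), max(4, int(s * w))
        y0 = rng.integers(0, h - ch + 1)
        x0 = rng.integers(0, w - cw + 1)
        sub = patch[:, y0:y0 + ch, x0:x0 + cw]
        return np.stack([skimage.transform.resize(sub[i], (out, out, 3), order=1,
                                                  preserve_range=True,
                                                  anti_aliasing=False)
                         for i in range(f)])

    return ([crop(global_scale) for _ in range(n_global)],
            [crop(local_scale) for _ in range(n_local)])


def distill_loss(teacher_logits: list[np.ndarray], student_logits: list[np.ndarray],
                 center: np.ndarray, tau_s: float, tau_t: float
                 ) -> tuple[float, list[np.ndarray]]:
    """Cross-entropy of student distributions against centered teacher ones.

    Teacher logits correspond to the global views, which are also the
    first entries of ``student_logits``; same-view pairs are skipped.
    Returns the mean loss and the gradient wrt each student view's logits.
    """
    if tau_s <= 0 or tau_t <= 0:
        raise ValueError("temperatures must be positive")
    p_t = [_softmax((t - center) / tau_t) for t in teacher_logits]
    loss = 0.0
    dstudent = [np.zeros_like(s) for s in student_logits]
    count = 0
    for g, pt in enumerate(p_t):
        for v, s in enumerate(student_logits):
            if v == g:
                continue
            z = s / tau_s
            log_ps = z - (z.max() + np.log(np.exp(z - z.max()).sum()))
            loss += -np.sum(pt * log_ps)
            dstudent[v] += (np.exp(log_ps) - pt) / tau_s
            count += 1
    loss /= count
    dstudent = [d / count for d in dstudent]
    return float(loss), dstudent


@dataclass
class DistillConfig:
    """Self-distillation hyperparameters (momentum, temperatures, views)."""

    momentum: float = 0.996
    tau_s: float = 0.1
    tau_t: float = 0.04
    center_momentum: float = 0.9
    n_global: int = 2
    n_local: int = 4
    n_prototypes: int = 32
    head_hidden: int = 64
    lr: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.momentum <= 1.0):
            raise ValueError("momentum must lie in [0, 1]")
        if self.tau_s <= 0 or self.tau_t <= 0:
            raise ValueError("temperatures must be positive")


def _init_head(rng, cfg: EncoderConfig, dcfg: DistillConfig) -> dict:
    d = cfg.embed_dim
    h, k = dcfg.head_hidden, dcfg.n_prototypes
    return {
        "head_W1": rng.normal(0, np.sqrt(2.0 / (d + h)), size=(h, d)),
        "head_b1": np.zeros(h),
        "head_W2": rng.normal(0, np.sqrt(2.0 / (h + k)), size=(k, h)),
        "head_b2": np.zeros(k),
    }


def distill_step(student_params: dict, teacher_params: dict,
                 global_views: list[np.ndarray], local_views: list[np.ndarray],
                 cfg: EncoderConfig, *, momentum: float = 0.996,
                 tau_s: float = 0.1, tau_t: float = 0.04,
                 center_state: np.ndarray | None = None,
                 center_momentum: float = 0.9, lr: float = 5e-4
                 ) -> tuple[float, dict, dict, np.ndarray]:
    """One functional distillation step (plain SGD on the student).

    Returns ``(loss, new_student, new_teacher, new_center)``.  The
    teacher update is exactly ``m * teacher + (1 - m) * student`` using
    the *updated* student; the center is an exponential moving average of
    the teacher's mean logits over the global views.
    """
    k = student_params["head_W2"].shape[0]
    if center_state is None:
        center_state = np.zeros(k)
    t_logits = [forward_logits(teacher_params, v, cfg) for v in global_views]
    s_out = [forward_logits(student_params, v, cfg, with_cache=True)
             for v in list(global_views) + list(local_views)]
    s_logits = [o[0] for o in s_out]
    loss, dlogits = distill_loss(t_logits, s_logits, center_state, tau_s, tau_t)
    total = {kk: np.zeros_like(v) for kk, v in student_params.items()}
    for (logits, cache), dl in zip(s_out, dlogits):
        if np.all(dl == 0):
            continue
        g = backward_logits(dl, cache, student_params, cfg)
        for kk in total:
            total[kk] += g[kk]
    new_student = {kk: v - lr * total[kk] for kk, v in student_params.items()}
    new_teacher = ema_update(teacher_params, new_student, momentum)
    batch_mean = np.mean(t_logits, axis=0)
    new_center = center_momentum * center_state + (1 - center_momentum) * batch_mean
    return loss, new_student, new_teacher, new_center


class SelfDistiller:
    """Stateful trainer: student/teacher params, Adam moments, center."""

    def __init__(self, cfg: EncoderConfig, dcfg: DistillConfig | None = None):
        self.cfg = cfg
        self.dcfg = dcfg or DistillConfig()
        rng = np.random.default_rng(self.dcfg.seed)
        base = init_encoder_params(cfg)
        base.update(_init_head(rng, cfg, self.dcfg))
        self.student = base
        self.teacher = {k: v.copy() for k, v in base.items()}
        self.center = np.zeros(self.dcfg.n_prototypes)
        self._adam_m = {k: np.zeros_like(v) for k, v in base.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in base.items()}
        self._t = 0
        self.rng = rng
        self.loss_history: list[float] = []

    def step(self, patch: np.ndarray) -> float:
        """One distillation step on one 2.5D patch."""
        d = self.dcfg
        g_views, l_views = make_views(patch, self.cfg, self.rng,
                                      d.n_global, d.n_local)
        t_logits = [forward_logits(self.teacher, v, self.cfg) for v in g_views]
        if self._t == 0:
            # data-dependent center init: avoids the large transient the
            # centering term otherwise injects on the first steps
            self.center = np.mean(t_logits, axis=0)
        s_out = [forward_logits(self.student, v, self.cfg, with_cache=True)
                 for v in g_views + l_views]
        loss, dlogits = distill_loss(t_logits, [o[0] for o in s_out],
                                     self.center, d.tau_s, d.tau_t)
        total = {k: np.zeros_like(v) for k, v in self.student.items()}
        for (_, cache), dl in zip(s_out, dlogits):
            if np.all(dl == 0):
                continue
            g = backward_logits(dl, cache, self.student, self.cfg)
            for k in total:
                total[k] += g[k]
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in self.student:
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * total[k]
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * total[k] ** 2
            mhat = self._adam_m[k] / (1 - b1 ** self._t)
            vhat = self._adam_v[k] / (1 - b2 ** self._t)
            self.student[k] = self.student[k] - d.lr * mhat / (np.sqrt(vhat) + eps)
        self.teacher = ema_update(self.teacher, self.student, d.momentum)
        batch_mean = np.mean(t_logits, axis=0)
        self.center = d.center_momentum * self.center + (1 - d.center_momentum) * batch_mean
        self.loss_history.append(loss)
        return loss
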