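"""Attention rollout for the divided depth/space encoder.

Divided attention gives every patch token two per-layer weight arrays:
T[p, j, q], its depth attention at spatial site p from slice j to slice
q, and S[i, j, p], its spatial attention within slice j from site i to
site p.  Their composition

    W[(i, j), (p, q)] = S[i, j, p] * T[p, j, q]

is the probability mass flowing from token (i, j) to token (p, q)
through the unique two-hop path the factorization allows (spatial hop to
site p in the same slice, then depth hop at site p to slice q).  W is a
row-stochastic (N*F) x (N*F) matrix; multiplying the per-layer W
matrices from the input layer upward gives the rollout attribution of
every token to the input patches.
"""

from __future__ import annotations

import numpy as np

from histo25d.encoder import AttentionMaps

__all__ = ["patch_token_weights", "combine_space_time", "rollout",
           "rollout_from_maps", "attribution_volume"]


def _renormalize_rows(w: np.ndarray) -> np.ndarray:
    s = w.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("attention rows must have positive mass")
    return w / s


def patch_token_weights(maps: AttentionMaps, layer: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Head-averaged patch-token S and T for one layer.

    The recorded weights include the classification key; it is dropped
    and each row renormalized so the patch-token submatrices are
    row-stochastic, as the combination formula requires.

    Returns ``S`` of shape (N, F, N) — S[i, j, p] — and ``T`` of shape
    (N, F, F) — T[p, j, q].
    """
    t_full = maps.head_averaged_time(layer)     # (N, F, F+1): [cls, t'...]
    s_full = maps.head_averaged_space(layer)    # (N, F, N+1): [cls, p'...]
    T = _renormalize_rows(t_full[..., 1:])      # (N, F, F)
    S = _renormalize_rows(s_full[..., 1:])      # (N, F, N)
    return S, T


def combine_space_time(S: np.ndarray, T: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Combined space-time attention W[(i,j),(p,q)] = S[i,j,p] * T[p,j,q].

    ``S`` is (N, F, N) row-stochastic over its last axis, ``T`` is
    (N, F, F) row-stochastic over its last axis.  The result is an
    (N*F, N*F) row-stochastic matrix with token order index = t*N + p.
    """
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    n, f = S.shape[0], S.shape[1]
    if S.shape != (n, f, n) or T.shape != (n, f, f):
        raise ValueError(f"inconsistent shapes S{S.shape} T{T.shape}")
    for name, arr in (("S", S), ("T", T)):
        rows = arr.sum(axis=-1)
        if np.max(np.abs(rows - 1.0)) > atol:
            raise ValueError(f"{name} rows are not stochastic (max dev "
                             f"{np.max(np.abs(rows - 1.0)):.2e})")
    # W[i, j, p, q] = S[i, j, p] * T[p, j, q]
    w4 = np.einsum("ijp,pjq->ijpq", S, T)
    # token order (p, j) -> flat j*N + i rows, q*N + p cols
    w = w4.transpose(1, 0, 3, 2).reshape(f * n, f * n)
    return w


def rollout(per_layer_W: list[np.ndarray], residual_mixing: bool = False,
            atol: float = 1e-6) -> np.ndarray:
    """Recursive product of per-layer attention matrices, input layer first.

    ``residual_mixing`` averages each layer's matrix with the identity
    before multiplying, modelling the residual path; off by default since
    the combined space-time formulation carries no identity term.
    Row ``i`` of the result attributes token ``i`` to the input tokens.
    """
    if not per_layer_W:
        raise ValueError("no layers given")
    m = per_layer_W[0].shape[0]
    out = np.eye(m)
    for l, w in enumerate(per_layer_W):
        w = np.asarray(w, dtype=float)
        if w.shape != (m, m):
            raise ValueError(f"layer {l} matrix has shape {w.shape}, expected {(m, m)}")
        dev = np.max(np.abs(w.sum(axis=1) - 1.0))
        if dev > atol:
            raise ValueError(f"layer {l} rows not stochastic (max dev {dev:.2e})")
        if residual_mixing:
            w = 0.5 * (w + np.eye(m))
        out = w @ out
    return out


def rollout_from_maps(maps: AttentionMaps, residual_mixing: bool = False) -> np.ndarray:
    """Rollout attribution straight from recorded attention maps."""
    ws = []
    for layer in range(len(maps.time)):
        S, T = patch_token_weights(maps, layer)
        ws.append(combine_space_time(S, T))
    return rollout(ws, residual_mixing=residual_mixing)


def attribution_volume(maps: AttentionMaps, n_patches: int, n_slices: int,
                       tile_side: int | None = None) -> np.ndarray:
    """Mean input attribution reshaped to (F, side, side) heat maps.

    Rows of the rollout matrix are averaged over all query tokens to give
    one attribution score per input patch position and slice.
    """
    r = rollout_from_maps(maps)
    attr = r.mean(axis=0)                       # (N*F,), order t*N + p
    vol = attr.reshape(n_slices, n_patches)
    if tile_side is None:
        tile_side = int(round(np.sqrt(n_patches)))
    return vol.reshape(n_slices, tile_side, tile_side)
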