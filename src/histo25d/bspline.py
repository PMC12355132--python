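"""Tensor-product cubic B-spline fields on a regular control grid.

A dense 2-D displacement field is parameterized by a coarse grid of
control displacements with spacing ``grid_spacing_px``; the dense field is
the separable cubic B-spline interpolation of the grid,

    u(x, y) = sum_ij  c_ij  B_i(y) B_j(x),

the classic free-form deformation.  The explicit basis matrices make the
adjoint (gradient projection from pixel space onto the control grid) a
pair of small matrix products, which the non-rigid optimizer relies on.
"""

from __future__ import annotations

import numpy as np


def _cubic_bspline_weights(u: np.ndarray) -> np.ndarray:
    """The four cubic B-spline blending weights for fractional offsets u."""
    w0 = (1 - u) ** 3 / 6.0
    w1 = (3 * u**3 - 6 * u**2 + 4) / 6.0
    w2 = (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6.0
    w3 = u**3 / 6.0
    return np.stack([w0, w1, w2, w3], axis=-1)


def n_control_points(length: int, spacing: float) -> int:
    """Control points needed to cover ``length`` pixels (margin included)."""
    return int(np.floor((length - 1) / spacing)) + 4


def basis_matrix(length: int, spacing: float) -> np.ndarray:
    """Dense ``(length, n_ctrl)`` cubic B-spline basis along one axis.

    Rows sum to exactly 1, so a constant control grid yields a constant
    field — translations are representable without error.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    x = np.arange(length, dtype=float)
    t = x / spacing
    i = np.floor(t).astype(int)
    u = t - i
    w = _cubic_bspline_weights(u)  # (length, 4)
    nc = n_control_points(length, spacing)
    B = np.zeros((length, nc))
    rows = np.arange(length)
    for k in range(4):
        B[rows, i + k] += w[:, k]
    return B


class BSplineField2D:
    """A pair of scalar fields (u, v) on one control grid over an H x W image."""

    def __init__(self, shape: tuple[int, int], grid_spacing_px: float):
        self.shape = tuple(shape)
        self.grid_spacing_px = float(grid_spacing_px)
        h, w = shape
        self.By = basis_matrix(h, grid_spacing_px)   # (H, ncy)
        self.Bx = basis_matrix(w, grid_spacing_px)   # (W, ncx)
        self.ncy = self.By.shape[1]
        self.ncx = self.Bx.shape[1]

    @property
    def n_params(self) -> int:
        return 2 * self.ncy * self.ncx

    def zero_coefficients(self) -> np.ndarray:
        return np.zeros(self.n_params)

    def split(self, coeffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(coeffs).reshape(2, self.ncy, self.ncx)
        return c[0], c[1]

    def dense(self, coeffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate the dense (u, v) displacement images."""
        cu, cv = self.split(coeffs)
        u = self.By @ cu @ self.Bx.T
        v = self.By @ cv @ self.Bx.T
        return u, v

    def project_gradient(self, gu: np.ndarray, gv: np.ndarray) -> np.ndarray:
        """Adjoint of ``dense``: pixelwise gradients -> control-grid gradients."""
        grad_cu = self.By.T @ gu @ self.Bx
        grad_cv = self.By.T @ gv @ self.Bx
        return np.concatenate([grad_cu.ravel(), grad_cv.ravel()])

    def bending_energy(self, coeffs: np.ndarray) -> tuple[float, np.ndarray]:
        """Discrete thin-plate bending penalty on the control grid.

        Sum of squared second differences of the control displacements in
        both directions; returns (value, gradient wrt coeffs).
        """
        cu, cv = self.split(coeffs)
        val = 0.0
        grads = []
        for c in (cu, cv):
            dyy = c[2:, :] - 2 * c[1:-1, :] + c[:-2, :]
            dxx = c[:, 2:] - 2 * c[:, 1:-1] + c[:, :-2]
            val += float(np.sum(dyy**2) + np.sum(dxx**2))
            g = np.zeros_like(c)
            g[2:, :] += 2 * dyy
            g[1:-1, :] -= 4 * dyy
            g[:-2, :] += 2 * dyy
            g[:, 2:] += 2 * dxx
            g[:, 1:-1] -= 4 * dxx
            g[:, :-2] += 2 * dxx
            grads.append(g)
        return val, np.concatenate([grads[0].ravel(), grads[1].ravel()])


def random_smooth_field(shape: tuple[int, int], grid_spacing_px: float,
                        amplitude: float, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """A random smooth displacement field with peak magnitude ``amplitude``.

    Control displacements are drawn i.i.d. normal, interpolated, then
    rescaled so the maximum displacement magnitude equals ``amplitude``
    exactly (zero amplitude yields exact zero fields).  Deterministic
    given the generator state.
    """
    field = BSplineField2D(shape, grid_spacing_px)
    coeffs = rng.normal(size=field.n_params)
    u, v = field.dense(coeffs)
    mag = np.sqrt(u**2 + v**2)
    peak = mag.max()
    if amplitude == 0 or peak == 0:
        return np.zeros(shape), np.zeros(shape)
    s = amplitude / peak
    return u * s, v * s
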