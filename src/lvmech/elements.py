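"""Trilinear hexahedral shape functions and Gauss quadrature.

Shared by the mesher (quadrature volumes), the fiber assigner (Gauss-point
positions) and the FE engine (assembly). Node ordering follows the VTK
convention: nodes 0-3 on the bottom face (zeta = -1), 4-7 on the top face,
counter-clockwise seen from +zeta.
"""

from __future__ import annotations

import numpy as np

# corner coordinates (8, 3) in the parent element [-1, 1]^3
_XI = np.array(
    [
        [-1.0, -1.0, -1.0],
        [1.0, -1.0, -1.0],
        [1.0, 1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
        [1.0, -1.0, 1.0],
        [1.0, 1.0, 1.0],
        [-1.0, 1.0, 1.0],
    ]
)


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(xi) -> (..., 8)."""
    xi = np.asarray(xi, dtype=float)
    return 0.125 * np.prod(1.0 + xi[..., None, :] * _XI, axis=-1)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi_j -> (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    one = 1.0 + xi[..., None, :] * _XI  # (..., 8, 3)
    grad = np.empty(one.shape)
    for j in range(3):
        others = [k for k in range(3) if k != j]
        grad[..., j] = 0.125 * _XI[:, j] * one[..., others[0]] * one[..., others[1]]
    return grad


def gauss_points(order: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss rule on [-1,1]^3 -> (points (n,3), weights (n,))."""
    x1, w1 = np.polynomial.legendre.leggauss(order)
    pts = np.array([[a, b, c] for a in x1 for b in x1 for c in x1])
    wts = np.array([wa * wb * wc for wa in w1 for wb in w1 for wc in w1])
    return pts, wts


def gauss_points_2d(order: int = 2) -> tuple[np.ndarray, np.ndarray]:
    x1, w1 = np.polynomial.legendre.leggauss(order)
    pts = np.array([[a, b] for a in x1 for b in x1])
    wts = np.array([wa * wb for wa in w1 for wb in w1])
    return pts, wts


def quad_shape_functions(xi: np.ndarray) -> np.ndarray:
    """Bilinear quad shape functions -> (..., 4). Node order CCW."""
    corners = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
    xi = np.asarray(xi, dtype=float)
    return 0.25 * np.prod(1.0 + xi[..., None, :] * corners, axis=-1)


def quad_shape_gradients(xi: np.ndarray) -> np.ndarray:
    corners = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
    xi = np.asarray(xi, dtype=float)
    one = 1.0 + xi[..., None, :] * corners  # (..., 4, 2)
    grad = np.empty(one.shape)
    grad[..., 0] = 0.25 * corners[:, 0] * one[..., 1]
    grad[..., 1] = 0.25 * corners[:, 1] * one[..., 0]
    return grad


def jacobians(coords: np.ndarray, dN: np.ndarray) -> np.ndarray:
    """Element Jacobians dx/dxi.

    coords: (ne, 8, 3) nodal coordinates, dN: (ngp, 8, 3) parent gradients.
    Returns (ne, ngp, 3, 3).
    """
    return np.einsum("eai,gaj->egji", coords, dN)
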