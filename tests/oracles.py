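"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the element matrix is
integrated with a dense 3x3x3 Gauss rule built from scratch (scalar
loops, explicit strain assembly), global assembly scatters into a dense
matrix, and the constrained solve uses dense LAPACK.  They are only
viable on tiny meshes, which is the point — they provide ground truth
the sparse implementation must match.
"""

from __future__ import annotations

import itertools

import numpy as np

# 3-point Gauss rule on [-1, 1]
_GP3 = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GW3 = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])

# local corner signs, same geometric ordering as the package connectivity
_CORNERS = [(-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
            (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)]


def dense_elasticity_tensor(E: float, nu: float) -> np.ndarray:
    """Full 3x3x3x3 stiffness tensor C_ijkl for an isotropic solid."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    d = np.eye(3)
    C = np.zeros((3, 3, 3, 3))
    for i, j, k, l in itertools.product(range(3), repeat=4):
        C[i, j, k, l] = lam * d[i, j] * d[k, l] + mu * (d[i, k] * d[j, l] + d[i, l] * d[j, k])
    return C


def _shape_grad_local(a: int, xi: float, eta: float, zeta: float) -> np.ndarray:
    sx, sy, sz = _CORNERS[a]
    return 0.125 * np.array(
        [
            sx * (1 + sy * eta) * (1 + sz * zeta),
            (1 + sx * xi) * sy * (1 + sz * zeta),
            (1 + sx * xi) * (1 + sy * eta) * sz,
        ]
    )


def dense_element_stiffness(corners: np.ndarray, E: float, nu: float) -> np.ndarray:
    """24x24 element stiffness via tensor contraction at 3x3x3 Gauss points.

    K[3a+i, 3b+k] = integral dN_a/dx_j C_ijkl dN_b/dx_l.
    """
    X = np.asarray(corners, dtype=float)
    C = dense_elasticity_tensor(E, nu)
    K = np.zeros((24, 24))
    for (p, xi), (q, eta), (r, zeta) in itertools.product(enumerate(_GP3), repeat=3):
        w = _GW3[p] * _GW3[q] * _GW3[r]
        dN = np.array([_shape_grad_local(a, xi, eta, zeta) for a in range(8)])  # (8,3) local
        J = dN.T @ X
        dNdx = dN @ np.linalg.inv(J).T
        for a in range(8):
            for b in range(8):
                # block_ik = dN_a/dx_j C_ijkl dN_b/dx_l
                block = np.einsum("j,ijkl,l->ik", dNdx[a], C, dNdx[b])
                K[3 * a:3 * a + 3, 3 * b:3 * b + 3] += w * np.linalg.det(J) * block
    return K


def dense_assemble(node_coords: np.ndarray, connectivity: np.ndarray, E_per_element, nu_per_element) -> np.ndarray:
    """Dense global stiffness by direct scatter of per-element matrices."""
    n = node_coords.shape[0]
    K = np.zeros((3 * n, 3 * n))
    E_per_element = np.broadcast_to(E_per_element, (connectivity.shape[0],))
    nu_per_element = np.broadcast_to(nu_per_element, (connectivity.shape[0],))
    for e, conn in enumerate(connectivity):
        ke = dense_element_stiffness(node_coords[conn], E_per_element[e], nu_per_element[e])
        dofs = np.concatenate([[3 * c, 3 * c + 1, 3 * c + 2] for c in conn])
        K[np.ix_(dofs, dofs)] += ke
    return K


def dense_solve(K: np.ndarray, f: np.ndarray, constrained: np.ndarray) -> np.ndarray:
    """Dense constrained solve by elimination."""
    n = K.shape[0]
    free = np.setdiff1d(np.arange(n), constrained)
    u = np.zeros(n)
    u[free] = np.linalg.solve(K[np.ix_(free, free)], f[free])
    return u


def enumerate_square_grid_holes(defect: float, pitch: float) -> int:
    """Exhaustive packing count: the largest k x k grid of centres at the
    given pitch whose span fits the defect extent (centres may sit on the
    defect boundary), squared."""
    k = 0
    while k * pitch <= defect + 1e-9:
        k += 1
    return k * k
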