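"""Constitutive models for the myocardial wall.

The passive matrix is a two-term Ogden hyperelastic solid on the isochoric
principal stretches,

    W_dev = sum_p (mu_p / alpha_p) (lb1^a_p + lb2^a_p + lb3^a_p - 3),

with mu_1 = 220 kPa, mu_2 = 110 kPa, alpha_1 = 11.77, alpha_2 = 14.34, plus
a volumetric energy U(J) whose tangent bulk modulus at J = 1 is exactly the
bulk modulus K - the quantity the inverse loop identifies. Two convex forms
are provided: the default quadratic U = (K/2)(J-1)^2 and a log-barrier
variant U = K (J - 1 - ln J) for strongly compressive regimes.

Fiber constituents (myofiber and radial collagen) are uniaxial linear
reinforcements by volume fraction: with Green-Lagrange fiber strain
eps = f0 . E f0 the second Piola-Kirchhoff contribution is
S = v_f E_f eps (f0 x f0). The myofiber modulus is the time-varying active
elastance E_a(t); collagen keeps E = 50 kPa. The reinforcement is linear in
both tension and compression by default (``tension_only`` switches slack
behaviour under shortening).

All stresses are second Piola-Kirchhoff tensors in kPa; deformation is
measured from the stress-free reference configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OgdenParams",
    "BulkState",
    "FiberConstituents",
    "ogden_energy",
    "volumetric_energy",
    "volumetric_pressure",
    "volumetric_stiffness",
    "deviatoric_kirchhoff_principal",
    "matrix_stress",
    "fiber_stress",
]


class MaterialError(ValueError):
    pass


@dataclass(frozen=True)
class OgdenParams:
    """Two-term Ogden deviatoric parameters (kPa / dimensionless)."""

    mu: tuple = (220.0, 110.0)
    alpha: tuple = (11.77, 14.34)

    def __post_init__(self):
        if len(self.mu) != len(self.alpha):
            raise MaterialError("mu and alpha must pair up")
        if self.shear_modulus <= 0:
            raise MaterialError("ground-state shear modulus must be positive")

    @property
    def shear_modulus(self) -> float:
        """Small-strain shear modulus, sum(mu_p alpha_p)/2 [kPa]."""
        return 0.5 * sum(m * a for m, a in zip(self.mu, self.alpha))


@dataclass(frozen=True)
class BulkState:
    """Bulk modulus K [kPa] and its reciprocal compressibility [1/kPa]."""

    K: float

    def __post_init__(self):
        if self.K <= 0:
            raise MaterialError("bulk modulus must be positive")

    @property
    def compressibility(self) -> float:
        return 1.0 / self.K


@dataclass(frozen=True)
class FiberConstituents:
    """Fiber families: volume fractions and moduli.

    Collagen Poisson ratio and density are recorded for completeness but
    unused: a uniaxial reinforcement has no transverse response and
    quasi-statics carries no inertia.
    """

    vf_myo: float = 0.7
    vf_collagen: float = 0.015
    collagen_E: float = 50.0          # kPa
    collagen_nu: float = 0.49         # recorded, unused
    collagen_rho: float = 1000.0      # kg/m^3, recorded, unused

    def __post_init__(self):
        if not (0 < self.vf_myo < 1 and 0 < self.vf_collagen < 1):
            raise MaterialError("volume fractions must lie in (0, 1)")
        if self.vf_myo + self.vf_collagen >= 1:
            raise MaterialError("volume fractions must sum below 1")


# --------------------------------------------------------------------------
# energies


def ogden_energy(stretches, params: OgdenParams):
    """Isochoric Ogden energy density [kPa] from principal stretches.

    The stretches are reduced to their isochoric parts lb_i = J^(-1/3) l_i
    internally, so passing either total or isochoric stretches is valid.
    """
    lam = np.asarray(stretches, dtype=float)
    if np.any(lam <= 0):
        raise MaterialError("principal stretches must be positive")
    J = np.prod(lam, axis=-1, keepdims=True)
    lb = lam * J ** (-1.0 / 3.0)
    W = np.zeros(lb.shape[:-1])
    for m, a in zip(params.mu, params.alpha):
        W = W + (m / a) * (np.sum(lb**a, axis=-1) - 3.0)
    return W if W.ndim else float(W)


def volumetric_energy(J, K, form: str = "quadratic"):
    """Volumetric energy density U(J) [kPa]; d2U/dJ2 at J=1 equals K."""
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise MaterialError("volume ratio J must be positive")
    if K <= 0:
        raise MaterialError("bulk modulus must be positive")
    if form == "quadratic":
        U = 0.5 * K * (J - 1.0) ** 2
    elif form == "log":
        U = K * (J - 1.0 - np.log(J))
    else:
        raise MaterialError(f"unknown volumetric form {form!r}")
    return U if U.ndim else float(U)


def volumetric_pressure(J, K, form: str = "quadratic"):
    """dU/dJ [kPa]; the hydrostatic pressure is p_vol = -dU/dJ."""
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise MaterialError("volume ratio J must be positive")
    if form == "quadratic":
        out = K * (J - 1.0)
    elif form == "log":
        out = K * (1.0 - 1.0 / J)
    else:
        raise MaterialError(f"unknown volumetric form {form!r}")
    return out if out.ndim else float(out)


def volumetric_stiffness(J, K, form: str = "quadratic"):
    """d2U/dJ2 [kPa]."""
    J = np.asarray(J, dtype=float)
    if form == "quadratic":
        out = K * np.ones_like(J)
    elif form == "log":
        out = K / J**2
    else:
        raise MaterialError(f"unknown volumetric form {form!r}")
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# stresses


def deviatoric_kirchhoff_principal(lam_bar: np.ndarray, params: OgdenParams) -> np.ndarray:
    """Principal deviatoric Kirchhoff stresses tau_i [kPa], (..., 3)."""
    powers = [lam_bar**a for a in params.alpha]
    tau = np.zeros_like(lam_bar)
    for m, pw in zip(params.mu, powers):
        tau = tau + m * (pw - pw.mean(axis=-1, keepdims=True))
    return tau


def _spectral(C: np.ndarray):
    """Eigen-decomposition of right Cauchy-Green tensors (..., 3, 3)."""
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 1e-16, None)
    return np.sqrt(w), V  # principal stretches, material eigenvectors


def eigvalsh3(A: np.ndarray) -> np.ndarray:
    """Closed-form (Cardano) eigenvalues of symmetric 3x3 tensors, ascending.

    Vectorised over leading dimensions; much faster than LAPACK for large
    stacks of small matrices. Accuracy is ample for stress evaluation
    (relative error ~1e-12 away from degeneracy, graceful at degeneracy).
    """
    a00, a11, a22 = A[..., 0, 0], A[..., 1, 1], A[..., 2, 2]
    a01, a02, a12 = A[..., 0, 1], A[..., 0, 2], A[..., 1, 2]
    q = (a00 + a11 + a22) / 3.0
    b00, b11, b22 = a00 - q, a11 - q, a22 - q
    p2 = (b00**2 + b11**2 + b22**2) / 6.0 + (a01**2 + a02**2 + a12**2) / 3.0
    p = np.sqrt(np.clip(p2, 0.0, None))
    detB = (
        b00 * (b11 * b22 - a12**2)
        - a01 * (a01 * b22 - a12 * a02)
        + a02 * (a01 * a12 - b11 * a02)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(p > 0, detB / np.where(p > 0, 2.0 * p**3, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    e_hi = q + 2.0 * p * np.cos(phi)
    e_lo = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e_mid = 3.0 * q - e_hi - e_lo
    return np.stack([e_lo, e_mid, e_hi], axis=-1)


def sym_inv3(A: np.ndarray, det: np.ndarray) -> np.ndarray:
    """Inverse of symmetric 3x3 tensors via the adjugate, given det(A)."""
    a00, a11, a22 = A[..., 0, 0], A[..., 1, 1], A[..., 2, 2]
    a01, a02, a12 = A[..., 0, 1], A[..., 0, 2], A[..., 1, 2]
    inv = np.empty_like(A)
    inv[..., 0, 0] = a11 * a22 - a12 * a12
    inv[..., 1, 1] = a00 * a22 - a02 * a02
    inv[..., 2, 2] = a00 * a11 - a01 * a01
    inv[..., 0, 1] = inv[..., 1, 0] = a02 * a12 - a01 * a22
    inv[..., 0, 2] = inv[..., 2, 0] = a01 * a12 - a02 * a11
    inv[..., 1, 2] = inv[..., 2, 1] = a01 * a02 - a00 * a12
    return inv / det[..., None, None]


def ogden_dev_2pk(C: np.ndarray, J: np.ndarray, params: OgdenParams) -> np.ndarray:
    """Deviatoric Ogden second Piola-Kirchhoff stress as a tensor polynomial.

    Uses the spectral-projector (Lagrange) representation
    S = sum_i s_i prod_{j!=i} (C - x_j I)/(x_i - x_j) with x_i the
    eigenvalues of C and s_i = tau_i / x_i; eigenvalues are split by a tiny
    jitter so the formula stays well-conditioned through degeneracies
    (interpolation error O(jitter^2) of a smooth isotropic function).
    """
    x = eigvalsh3(C)
    scale = np.maximum(x[..., 2], 1e-30)
    jit = 1e-6 * scale
    x = x + jit[..., None] * np.array([-1.0, 0.0, 1.0])
    x = np.clip(x, 1e-20, None)
    lam = np.sqrt(x)
    lam_bar = lam * J[..., None] ** (-1.0 / 3.0)
    tau = deviatoric_kirchhoff_principal(lam_bar, params)
    s = tau / x

    eye = np.eye(3)
    x0, x1, x2 = x[..., 0], x[..., 1], x[..., 2]
    # unexpanded products: (C - x_j I)(C - x_k I) vanishes exactly on the
    # eigenspaces of the other eigenvalues, so no catastrophic cancellation
    # occurs at (near-)degenerate states
    Cm0 = C - x0[..., None, None] * eye
    Cm1 = C - x1[..., None, None] * eye
    Cm2 = C - x2[..., None, None] * eye
    c0 = s[..., 0] / ((x0 - x1) * (x0 - x2))
    c1 = s[..., 1] / ((x1 - x0) * (x1 - x2))
    c2 = s[..., 2] / ((x2 - x0) * (x2 - x1))
    return (
        c0[..., None, None] * np.matmul(Cm1, Cm2)
        + c1[..., None, None] * np.matmul(Cm0, Cm2)
        + c2[..., None, None] * np.matmul(Cm0, Cm1)
    )


def matrix_stress(F: np.ndarray, params: OgdenParams, K: float,
                  form: str = "quadratic", pbar: np.ndarray | None = None) -> np.ndarray:
    """Second Piola-Kirchhoff stress of the matrix, (..., 3, 3) [kPa].

    Deviatoric Ogden part via spectral decomposition plus the volumetric
    part p J C^-1 with p = dU/dJ. If ``pbar`` is given it replaces the
    locally evaluated dU/dJ (mean-dilatation elements pass the element
    average here).
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise MaterialError("deformation gradient must have positive determinant")
    C = np.einsum("...ki,...kj->...ij", F, F)
    lam, V = _spectral(C)
    lam_bar = lam * J[..., None] ** (-1.0 / 3.0)
    tau = deviatoric_kirchhoff_principal(lam_bar, params)
    # S_dev = sum_i tau_i / lam_i^2 N_i x N_i
    coeff = tau / lam**2
    S = np.einsum("...i,...ai,...bi->...ab", coeff, V, V)
    p = volumetric_pressure(J, K, form) if pbar is None else np.asarray(pbar)
    Cinv = np.linalg.inv(C)
    S = S + (p * J)[..., None, None] * Cinv
    return S


def apply_branch(eps, branch: str):
    """Restrict a fiber strain to the active branch of the reinforcement law.

    ``"linear"`` keeps both branches, ``"tension"`` keeps only stretch beyond
    the reference length, ``"compression"`` only shortening below it.
    """
    if branch == "linear":
        return eps
    if branch == "tension":
        return np.where(eps > 0, eps, 0.0)
    if branch == "compression":
        return np.where(eps < 0, eps, 0.0)
    raise MaterialError(f"unknown fiber branch {branch!r}")


def fiber_stress(F: np.ndarray, direction: np.ndarray, E_f: float, v_f: float,
                 tension_only: bool = False, branch: str | None = None) -> np.ndarray:
    """Uniaxial fiber reinforcement stress (2nd PK), (..., 3, 3) [kPa].

    S = v_f E_f eps (f0 x f0) with Green-Lagrange fiber strain
    eps = 0.5 (f0 . C f0 - 1). Zero transverse stiffness. ``branch``
    restricts the law to one strain branch (``tension_only`` is a shorthand
    for branch="tension").
    """
    if E_f < 0:
        raise MaterialError("fiber modulus must be non-negative")
    F = np.asarray(F, dtype=float)
    f0 = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(f0, axis=-1)
    if np.any(np.abs(norm - 1.0) > 1e-8):
        raise MaterialError("fiber directions must be unit vectors")
    Ff = np.einsum("...ij,...j->...i", F, f0)
    eps = 0.5 * (np.einsum("...i,...i->...", Ff, Ff) - 1.0)
    eps = apply_branch(eps, branch or ("tension" if tension_only else "linear"))
    return (v_f * E_f * eps)[..., None, None] * np.einsum("...i,...j->...ij", f0, f0)
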