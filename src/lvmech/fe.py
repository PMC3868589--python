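"""Quasi-static total-Lagrangian finite-element engine for the LV wall.

8-node hexahedra with 2x2x2 Gauss quadrature and a mean-dilatation
(B-bar family) volumetric treatment: the deviatoric Ogden response is
integrated pointwise on the isochoric stretches while the volumetric energy
acts on the element-averaged volume ratio J-bar, which suppresses volumetric
locking in the near-incompressible regime. Fiber reinforcement (active
myofiber + radial collagen) is superposed per Gauss point by volume
fraction.

Loads and boundary conditions follow the physiological model: follower
cavity pressure on the endocardial faces (always normal to the deforming
surface), a linear elastic foundation of stiffness K_f = 0.02 kPa/mm on the
epicardium standing in for the surrounding organs, zero longitudinal
displacement on the base plane, and suppression of the three in-plane rigid
modes at base-ring nodes (the structural counterpart of the paper-style
pressure-node lateral fixing).

Internal and external nodal forces are analytic; the consistent tangent is
obtained by vectorised central finite differencing of the exact element
force vectors (24 dofs per hexahedron, 12 per loaded face), which is
consistent with the mean-dilatation coupling and the non-symmetric follower
pressure stiffness by construction. Newton-Raphson iteration uses
backtracking line search and automatic bisection substepping of the load
path (pressure, active modulus, and log-K jointly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import elements
from .fibers import FiberField
from .geometry import Mesh, cavity_volume_of
from .materials import (
    FiberConstituents,
    OgdenParams,
    apply_branch,
    ogden_dev_2pk,
    sym_inv3,
    volumetric_pressure,
)

__all__ = [
    "BoundaryConditions",
    "SolverSettings",
    "SolveState",
    "FEModel",
    "FEError",
    "NonConvergence",
    "InvertedElement",
]


class FEError(RuntimeError):
    pass


def _det3(A: np.ndarray) -> np.ndarray:
    """Closed-form determinant of stacked 3x3 matrices."""
    return (
        A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
        - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
        + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
    )


class NonConvergence(FEError):
    pass


class InvertedElement(FEError):
    pass


@dataclass(frozen=True)
class BoundaryConditions:
    """Base constraint, rigid-mode suppression and epicardial foundation."""

    foundation_stiffness: float = 0.02   # kPa per mm normal displacement
    fix_base_longitudinal: bool = True   # Uz = 0 on all base-plane nodes
    fix_lateral_rigid_modes: bool = True

    def __post_init__(self):
        if self.foundation_stiffness < 0:
            raise ValueError("foundation stiffness must be non-negative")


@dataclass(frozen=True)
class SolverSettings:
    newton_tol: float = 1e-6        # relative residual
    newton_abs_tol: float = 1e-4    # kPa mm^2, absolute force floor
    max_newton: int = 30
    max_bisections: int = 4         # load-path halvings (up to 2**n substeps)
    n_linesearch: int = 6
    fd_step: float = 1e-6           # mm, tangent finite-difference half-step x2


@dataclass
class SolveState:
    """Converged equilibrium state of one load step."""

    u: np.ndarray            # (nn, 3) nodal displacements, mm
    p: float                 # cavity pressure, kPa
    e_active: float          # active myofiber modulus, kPa
    K: float | None          # bulk modulus, kPa (None for the virgin state)
    volume: float            # cavity volume, ml
    residuals: list = field(default_factory=list)
    n_newton: int = 0
    n_substeps: int = 1
    step_index: int = 0


class FEModel:
    """Assembled LV wall model: mesh + fibers + materials + BCs."""

    def __init__(
        self,
        mesh: Mesh,
        fiber_field: FiberField,
        ogden: OgdenParams | None = None,
        constituents: FiberConstituents | None = None,
        bcs: BoundaryConditions | None = None,
        vol_form: str = "quadratic",
        active_fiber_law: str = "compression",
        collagen_fiber_law: str = "compression",
        settings: SolverSettings | None = None,
    ):
        self.mesh = mesh
        self.fibers = fiber_field
        self.ogden = ogden or OgdenParams()
        self.constituents = constituents or FiberConstituents(
            vf_myo=fiber_field.vf_myo, vf_collagen=fiber_field.vf_collagen
        )
        self.bcs = bcs or BoundaryConditions()
        self.vol_form = vol_form
        for law in (active_fiber_law, collagen_fiber_law):
            if law not in ("linear", "tension", "compression"):
                raise FEError(f"unknown fiber law {law!r}")
        self.active_fiber_law = active_fiber_law
        self.collagen_fiber_law = collagen_fiber_law
        self.settings = settings or SolverSettings()
        self._precompute()

    # ------------------------------------------------------------------ setup
    def _precompute(self):
        mesh = self.mesh
        gp, w = elements.gauss_points(2)
        dN = elements.shape_gradients(gp)                 # (ngp, 8, 3)
        coords = mesh.nodes[mesh.elems]                    # (ne, 8, 3)
        J = elements.jacobians(coords, dN)                 # (ne, ngp, 3, 3) dx_i/dxi_j
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise FEError("reference mesh contains non-positive Jacobians")
        Jinv = np.linalg.inv(J)
        # with J[j,i] = dx_i/dxi_j, the inverse satisfies dxi_j/dx_i = Jinv[i,j]
        self._dNdX = np.einsum("gaj,egij->egai", dN, Jinv)
        self._wdet = detJ * w[None, :]                     # (ne, ngp)
        self._Ve = self._wdet.sum(axis=1)                  # (ne,)
        self._ngp = len(w)

        # sanity: gradients of linear field
        test = np.einsum("egai,eak->egik", self._dNdX, coords)
        if not np.allclose(test, np.eye(3), atol=1e-8):
            raise FEError("shape-gradient mapping failed self-check")

        ne = mesh.n_elems
        self._edofs = (3 * mesh.elems[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 24)
        self.ndof = 3 * mesh.n_nodes

        # face quadrature (pressure + foundation)
        gp2, w2 = elements.gauss_points_2d(2)
        self._Nq = elements.quad_shape_functions(gp2)      # (4gp, 4)
        self._dNq = elements.quad_shape_gradients(gp2)     # (4gp, 4, 2)
        self._wq = w2
        self._endoX = mesh.nodes[mesh.endo_faces]          # (nf, 4, 3)
        self._fdofs = (3 * mesh.endo_faces[:, :, None] + np.arange(3)[None, None, :]).reshape(
            len(mesh.endo_faces), 12
        )

        self._foundation = self._build_foundation()
        self._fixed = self._fixed_dofs()
        self._free = np.setdiff1d(np.arange(self.ndof), self._fixed)

        # assembly index cache
        rows = np.repeat(self._edofs[:, :, None], 24, axis=2)
        cols = np.repeat(self._edofs[:, None, :], 24, axis=1)
        self._Krows = rows.ravel()
        self._Kcols = cols.ravel()
        frows = np.repeat(self._fdofs[:, :, None], 12, axis=2)
        fcols = np.repeat(self._fdofs[:, None, :], 12, axis=1)
        self._Frows = frows.ravel()
        self._Fcols = fcols.ravel()

    def _build_foundation(self) -> sp.csr_matrix:
        """Sparse Winkler-foundation operator: f = -Kf_mat @ u."""
        kf = self.bcs.foundation_stiffness
        mesh = self.mesh
        if kf == 0 or len(mesh.epi_faces) == 0:
            return sp.csr_matrix((self.ndof, self.ndof))
        X = mesh.nodes[mesh.epi_faces]                     # (nf, 4, 3)
        xs = np.einsum("gad,fai->fgdi", self._dNq, X)      # (nf, 4gp, 2, 3)
        t0 = np.cross(xs[:, :, 0, :], xs[:, :, 1, :])      # outward area vectors
        area = np.linalg.norm(t0, axis=2)
        n0 = np.where(area[..., None] > 1e-14, t0 / np.maximum(area, 1e-300)[..., None], 0.0)
        # K_ab = kf * sum_g w |t0| N_a N_b n0 x n0
        blocks = kf * np.einsum(
            "g,fg,ga,gb,fgi,fgj->faibj", self._wq, area, self._Nq, self._Nq, n0, n0
        )
        fdofs = (3 * mesh.epi_faces[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
        rows = np.repeat(fdofs[:, :, None], 12, axis=2).ravel()
        cols = np.repeat(fdofs[:, None, :], 12, axis=1).ravel()
        mat = sp.coo_matrix(
            (blocks.reshape(-1, 12, 12).ravel(), (rows, cols)), shape=(self.ndof, self.ndof)
        )
        return mat.tocsr()

    def _fixed_dofs(self) -> np.ndarray:
        mesh = self.mesh
        fixed = set()
        # the virtual pressure node carries no stiffness
        fixed.update(3 * mesh.pressure_node + np.arange(3))
        if self.bcs.fix_base_longitudinal:
            fixed.update(3 * mesh.base_nodes + 2)
        if self.bcs.fix_lateral_rigid_modes:
            C = mesh.n_circ
            ring = mesh.base_ring
            a, b, c = ring[0], ring[C // 2], ring[(3 * C) // 4]
            # tangential components only: no reaction under symmetric loading
            fixed.update([3 * a + 1, 3 * b + 1, 3 * c + 0])
        return np.array(sorted(int(d) for d in fixed))

    def initial_state(self) -> SolveState:
        """Stress-free reference state (zero pressure, zero activation)."""
        u = np.zeros((self.mesh.n_nodes, 3))
        return SolveState(u=u, p=0.0, e_active=0.0, K=None,
                          volume=cavity_volume_of(self.mesh, u))

    # --------------------------------------------------------------- internal
    def _elem_internal(self, ue: np.ndarray, e_a: float, K: float, guard: bool,
                       tile: int = 1) -> np.ndarray:
        """Element internal force vectors (ne, 8, 3) for element displacements ue.

        ``tile`` > 1 evaluates a stacked batch of ``tile`` displacement sets
        for the whole mesh at once (used by the FD tangent)."""
        dNdX = self._dNdX if tile == 1 else np.tile(self._dNdX, (tile, 1, 1, 1))
        wdet = self._wdet if tile == 1 else np.tile(self._wdet, (tile, 1))
        Ve = self._Ve if tile == 1 else np.tile(self._Ve, tile)
        # F = I + du/dX via batched matmul (BLAS)
        F = np.eye(3) + np.swapaxes(
            np.matmul(np.swapaxes(dNdX, 2, 3), ue[:, None, :, :]), 2, 3
        )
        J = _det3(F)
        if guard and np.any(J <= 1e-10):
            raise InvertedElement("negative Jacobian during iteration")
        J = np.clip(J, 1e-10, None)
        C = np.matmul(np.swapaxes(F, 2, 3), F)
        S = ogden_dev_2pk(C, J, self.ogden)

        # mean dilatation: element-averaged J drives the volumetric pressure
        Jbar = np.einsum("eg,eg->e", wdet, J) / Ve
        pbar = volumetric_pressure(Jbar, K, self.vol_form)
        Cinv = sym_inv3(C, J**2)
        S = S + (pbar[:, None] * J)[..., None, None] * Cinv

        # fiber families (2nd PK uniaxial reinforcement), each coupled
        # through its configured strain branch
        con = self.constituents
        for f00, Ef, vf, branch in (
            (self.fibers.myofiber, e_a, con.vf_myo, self.active_fiber_law),
            (self.fibers.collagen, con.collagen_E, con.vf_collagen,
             self.collagen_fiber_law),
        ):
            if Ef == 0.0 or vf == 0.0:
                continue
            f0 = f00 if tile == 1 else np.tile(f00, (tile, 1, 1))
            Cf = np.matmul(C, f0[..., None])[..., 0]
            eps = apply_branch(0.5 * (np.einsum("egi,egi->eg", f0, Cf) - 1.0), branch)
            S = S + (vf * Ef * eps)[..., None, None] * np.einsum(
                "egi,egj->egij", f0, f0
            )

        P = np.matmul(F, S)
        return np.einsum("eg,egij,egaj->eai", wdet, P, dNdX)

    def internal_force(self, u: np.ndarray, e_a: float, K: float,
                       guard: bool = True) -> np.ndarray:
        """Assembled internal force vector (ndof,)."""
        ue = u.reshape(-1, 3)[self.mesh.elems]
        fe = self._elem_internal(ue, e_a, K, guard)
        f = np.zeros(self.ndof)
        np.add.at(f, self._edofs.ravel(), fe.reshape(-1, 24).ravel())
        return f

    # --------------------------------------------------------------- external
    def _face_pressure_forces(self, uf: np.ndarray, p: float) -> np.ndarray:
        """Follower-pressure nodal forces on endocardial faces (nf, 4, 3)."""
        x = self._endoX + uf
        xs = np.einsum("gad,fai->fgdi", self._dNq, x)
        t = np.cross(xs[:, :, 0, :], xs[:, :, 1, :])  # area vector, outward of cavity
        return p * np.einsum("g,ga,fgi->fai", self._wq, self._Nq, t)

    def external_force(self, u: np.ndarray, p: float) -> np.ndarray:
        """Pressure + foundation forces (ndof,)."""
        uflat = u.reshape(-1)
        uf = u.reshape(-1, 3)[self.mesh.endo_faces]
        f = np.zeros(self.ndof)
        ff = self._face_pressure_forces(uf, p)
        np.add.at(f, self._fdofs.ravel(), ff.reshape(-1, 12).ravel())
        f -= self._foundation @ uflat
        return f

    def residual(self, u: np.ndarray, p: float, e_a: float, K: float,
                 guard: bool = True) -> np.ndarray:
        return self.internal_force(u, e_a, K, guard) - self.external_force(u, p)

    # ---------------------------------------------------------------- tangent
    def tangent(self, u: np.ndarray, p: float, e_a: float, K: float) -> sp.csr_matrix:
        """Consistent tangent d(residual)/du by central differencing of the
        exact element/face force vectors."""
        h = self.settings.fd_step
        ue = u.reshape(-1, 3)[self.mesh.elems]
        ne = len(ue)
        Ke = np.empty((ne, 24, 24))
        up = ue.copy()
        for d in range(24):
            a, i = divmod(d, 3)
            up[:, a, i] += h
            fp = self._elem_internal(up, e_a, K, guard=False)
            up[:, a, i] -= 2 * h
            fm = self._elem_internal(up, e_a, K, guard=False)
            up[:, a, i] += h
            Ke[:, :, d] = (fp - fm).reshape(ne, 24) / (2 * h)
        Kt = sp.coo_matrix((Ke.ravel(), (self._Krows, self._Kcols)),
                           shape=(self.ndof, self.ndof)).tocsr()

        if p != 0.0:
            uf = u.reshape(-1, 3)[self.mesh.endo_faces]
            nf = len(uf)
            Kf = np.empty((nf, 12, 12))
            for d in range(12):
                a, i = divmod(d, 3)
                up = uf.copy()
                up[:, a, i] += h
                fp = self._face_pressure_forces(up, p)
                up[:, a, i] -= 2 * h
                fm = self._face_pressure_forces(up, p)
                Kf[:, :, d] = (fp - fm).reshape(nf, 12) / (2 * h)
            # external force enters the residual with a minus sign
            Kt = Kt - sp.coo_matrix(
                (Kf.ravel(), (self._Frows, self._Fcols)), shape=(self.ndof, self.ndof)
            ).tocsr()
        return Kt + self._foundation

    # ------------------------------------------------------------------ solve
    def _equilibrium(self, u0: np.ndarray, p: float, e_a: float, K: float):
        """Newton iteration at fixed loads; returns (u, residual_history, iters)."""
        st = self.settings
        free = self._free
        u = u0.copy()
        hist = []
        r = self.residual(u, p, e_a, K)
        scale = max(
            np.linalg.norm(self.external_force(u, p)[free]),
            np.linalg.norm(self.internal_force(u, e_a, K)[free]),
            1e-9,
        )
        rnorm = np.linalg.norm(r[free])
        lu, fresh = None, False
        for it in range(st.max_newton):
            hist.append(rnorm / scale)
            if rnorm <= max(st.newton_tol * scale, st.newton_abs_tol):
                return u, hist, it
            # quasi-Newton: reuse the factorised tangent while contraction is
            # fast; rebuild when progress stalls
            if lu is None:
                Kt = self.tangent(u, p, e_a, K)[free][:, free].tocsc()
                try:
                    lu = spla.splu(Kt)
                except RuntimeError as exc:  # singular factorisation
                    raise NonConvergence(f"linear solve failed: {exc}") from exc
                fresh = True
            du = lu.solve(-r[free])
            alpha, accepted = 1.0, False
            for _ in range(st.n_linesearch):
                utry = u.copy()
                utry.reshape(-1)[free] += alpha * du
                try:
                    rtry = self.residual(utry, p, e_a, K)
                    rtnorm = np.linalg.norm(rtry[free])
                except InvertedElement:
                    alpha *= 0.5
                    continue
                if (rtnorm < (1.0 - 1e-4 * alpha) * rnorm
                        or rtnorm <= max(st.newton_tol * scale, st.newton_abs_tol)):
                    contraction = rtnorm / rnorm
                    u, r, rnorm, accepted = utry, rtry, rtnorm, True
                    # stale tangent or slow step: refactorise next iteration
                    if alpha < 1.0 or contraction > 0.2:
                        lu = None
                    break
                alpha *= 0.5
            if not accepted:
                if not fresh:
                    lu = None       # retry the iteration with a fresh tangent
                    continue
                raise NonConvergence(
                    f"line search stalled at relative residual {rnorm / scale:.3e}"
                )
            fresh = False
            scale = max(
                np.linalg.norm(self.external_force(u, p)[free]),
                np.linalg.norm(self.internal_force(u, e_a, K)[free]),
                1e-9,
            )
        hist.append(rnorm / scale)
        if rnorm <= max(st.newton_tol * scale, st.newton_abs_tol):
            return u, hist, st.max_newton
        raise NonConvergence(
            f"Newton did not converge in {st.max_newton} iterations "
            f"(relative residual {rnorm / scale:.3e})"
        )

    def solve_step(self, state: SolveState, p: float, e_a: float, K: float) -> SolveState:
        """Advance to loads (p, E_a, K) from a converged state, with automatic
        bisection substepping along the joint load path (K interpolated in
        log space).

        Deep in the near-incompressible regime (K >> mu) Newton's quadratic
        convergence basin shrinks like mu/K; if the direct path fails there,
        the step is retried via continuation: advance the loads at a
        moderate bulk modulus first, then ramp K back up at fixed loads.
        """
        if K <= 0:
            raise FEError("bulk modulus must be positive")
        try:
            return self._solve_path(state, p, e_a, K)
        except NonConvergence:
            K_soft = 1e2 * self.ogden.shear_modulus
            if K <= 1.01 * K_soft:
                raise
            # three-leg continuation: soften K at the old loads, advance the
            # loads in the well-conditioned regime, then stiffen K back up
            cur = state
            n_newton = n_sub = 0
            if state.K is not None and state.K > K_soft:
                cur = self._solve_path(cur, state.p, state.e_active, K_soft)
                n_newton, n_sub = cur.n_newton, cur.n_substeps
            cur = self._solve_path(cur, p, e_a, K_soft)
            n_newton += cur.n_newton
            n_sub += cur.n_substeps
            out = self._solve_path(cur, p, e_a, K)
            out.n_newton += n_newton
            out.n_substeps += n_sub
            return out

    def _solve_path(self, state: SolveState, p: float, e_a: float, K: float) -> SolveState:
        st = self.settings
        p0, ea0 = state.p, state.e_active
        # from the virgin state, continue K up from the shear-modulus scale:
        # a direct jump deep into the near-incompressible regime overshoots
        K0 = state.K if state.K is not None else min(K, self.ogden.shear_modulus)

        def loads(lam):
            return (
                p0 + lam * (p - p0),
                ea0 + lam * (e_a - ea0),
                K0 * (K / K0) ** lam,
            )

        u = state.u.copy()
        lam0 = 0.0
        pending = [1.0]
        hist_all, n_newton, n_sub = [], 0, 0
        min_width = 0.5**st.max_bisections
        while pending:
            lam1 = pending[-1]
            pi, ei, Ki = loads(lam1)
            try:
                u_new, hist, its = self._equilibrium(u, pi, ei, Ki)
            except NonConvergence:
                if lam1 - lam0 <= min_width + 1e-12:
                    raise NonConvergence(
                        f"step to p={p:.4g}, E_a={e_a:.4g}, K={K:.4g} failed even "
                        f"with {2**st.max_bisections} substeps"
                    ) from None
                pending.append(0.5 * (lam0 + lam1))
                continue
            u, lam0 = u_new, lam1
            pending.pop()
            hist_all.extend(hist)
            n_newton += its
            n_sub += 1
        vol = cavity_volume_of(self.mesh, u)
        if vol <= 0:
            raise FEError("non-physical negative cavity volume")
        return SolveState(
            u=u, p=p, e_active=e_a, K=K, volume=vol,
            residuals=hist_all, n_newton=n_newton, n_substeps=n_sub,
            step_index=state.step_index,
        )

    def preload(self, state: SolveState, p_target: float, n_ramp: int = 10,
                K: float = 1.0, c_act: float = 500.0 / 16.93) -> SolveState:
        """Ramp cavity pressure 0 -> p_target from the stress-free state.

        The active modulus follows the elastance rule E_a = c_act * p along
        the ramp so the cycle starts from a physiologic inflated state.
        """
        if p_target < 0:
            raise FEError("preload pressure must be non-negative")
        if p_target == 0.0:
            return state
        cur = state
        for i in range(1, n_ramp + 1):
            pi = p_target * i / n_ramp
            cur = self.solve_step(cur, pi, c_act * pi, K)
        return cur

    # ------------------------------------------------------------- diagnostics
    def reaction_forces(self, state: SolveState) -> np.ndarray:
        """Residual at constrained dofs = support reactions (ndof,)."""
        r = self.residual(state.u, state.p, state.e_active,
                          state.K if state.K is not None else 1.0)
        out = np.zeros(self.ndof)
        out[self._fixed] = r[self._fixed]
        return out
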