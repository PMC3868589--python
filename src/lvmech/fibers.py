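"""Rule-based myofiber and collagen direction fields.

Myofiber orientation is described by two angles in a local orthonormal wall
frame (circumferential c, longitudinal l, radial r):

* helix angle beta: rotation of the fiber from c toward l within the tangent
  plane. It varies linearly across the wall thickness from a negative value
  at the epicardium to a positive value at the endocardium, with per-region
  endpoint pairs for the 8 anatomical regions.
* transverse angle eta: tilt of the fiber out of the tangent plane toward
  the radial direction, varying linearly from -15 deg at the apex through 0
  at the equator to +15 deg at the base.

The fiber unit vector is f = cos(eta)(cos(beta) c + sin(beta) l) + sin(eta) r.
Collagen fibers are purely radial. Both are sampled at the Gauss points of
every element, together with their volume fractions (0.7 myofiber, 0.015
collagen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import elements
from .geometry import Mesh

__all__ = [
    "DEFAULT_REGION_ANGLES",
    "RegionAngleTable",
    "FiberField",
    "helix_angle",
    "transverse_angle",
    "local_frame",
    "assign_fibers",
]

#: (beta_epi, beta_endo) in degrees for the 8 regions, ids as in
#: :data:`lvmech.geometry.REGION_NAMES`.
DEFAULT_REGION_ANGLES = {
    1: (-60.0, 40.0),   # septum-basal
    2: (-40.0, 60.0),   # anterior-basal
    3: (-20.0, 50.0),   # lateral-basal
    4: (-20.0, 60.0),   # posterior-basal
    5: (-50.0, 40.0),   # septum-apical
    6: (-20.0, 60.0),   # anterior-apical
    7: (-20.0, 50.0),   # lateral-apical
    8: (-20.0, 60.0),   # posterior-apical
}


class FiberError(ValueError):
    pass


@dataclass(frozen=True)
class RegionAngleTable:
    angles: dict = field(default_factory=lambda: dict(DEFAULT_REGION_ANGLES))

    def endpoints(self, region: int) -> tuple[float, float]:
        try:
            return self.angles[int(region)]
        except KeyError:
            raise FiberError(f"unknown region id {region}") from None


def helix_angle(region: int, s, table: RegionAngleTable | None = None):
    """Helix angle [deg] at transmural coordinate s (0 = epi -> 1 = endo)."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise FiberError("transmural coordinate must lie in [0, 1]")
    table = table or RegionAngleTable()
    b_epi, b_endo = table.endpoints(region)
    return b_epi + s * (b_endo - b_epi)


def transverse_angle(ell):
    """Transverse angle [deg] at longitudinal coordinate ell (0 = apex -> 1 = base)."""
    ell = np.asarray(ell, dtype=float)
    if np.any(ell < 0) or np.any(ell > 1):
        raise FiberError("longitudinal coordinate must lie in [0, 1]")
    return -15.0 + 30.0 * ell


def local_frame(points: np.ndarray, a: float, b: float):
    """Orthonormal (circumferential, longitudinal, radial) triads at points.

    ``a``/``b`` are the semi-axes of the (interpolated) ellipsoidal surface
    through the points; the radial vector is the outward surface normal, the
    circumferential vector the horizontal tangent, and l = r x c completes a
    right-handed triad. Points on the long axis have no circumferential
    direction and are rejected (the caller substitutes a neighbouring
    quadrature point's frame there).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rho = np.hypot(pts[:, 0], pts[:, 1])
    if np.any(rho < 1e-12):
        raise FiberError("local frame undefined on the long axis (apex singularity)")
    c = np.stack([-pts[:, 1], pts[:, 0], np.zeros(len(pts))], axis=1)
    c /= np.linalg.norm(c, axis=1, keepdims=True)
    n = np.stack([pts[:, 0] / b**2, pts[:, 1] / b**2, pts[:, 2] / a**2], axis=1)
    # n is orthogonal to c by construction; normalise
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    l = np.cross(n, c)
    return c, l, n


@dataclass
class FiberField:
    """Per-Gauss-point fiber data: (ne, ngp, 3) unit vectors and angles."""

    myofiber: np.ndarray
    collagen: np.ndarray
    beta: np.ndarray        # deg
    eta: np.ndarray         # deg
    circumferential: np.ndarray
    longitudinal: np.ndarray
    radial: np.ndarray
    vf_myo: float = 0.7
    vf_collagen: float = 0.015

    def recovered_angles(self):
        """Recompute (beta, eta) from the stored unit vectors [deg]."""
        f = self.myofiber
        eta = np.degrees(np.arcsin(np.clip(np.einsum("egi,egi->eg", f, self.radial), -1, 1)))
        beta = np.degrees(
            np.arctan2(
                np.einsum("egi,egi->eg", f, self.longitudinal),
                np.einsum("egi,egi->eg", f, self.circumferential),
            )
        )
        return beta, eta


def assign_fibers(
    mesh: Mesh,
    table: RegionAngleTable | None = None,
    vf_myo: float = 0.7,
    vf_collagen: float = 0.015,
    gauss_order: int = 2,
) -> FiberField:
    """Evaluate the fiber rule at every Gauss point of the mesh.

    The helix angle uses the element's layer-midpoint transmural coordinate
    (n_layers layers -> s in {1/2n, 3/2n, ...}); the transverse angle uses
    the element's longitudinal coordinate.
    """
    table = table or RegionAngleTable()
    gp, _ = elements.gauss_points(gauss_order)
    N = elements.shape_functions(gp)                       # (ngp, 8)
    x = np.einsum("ga,eai->egi", N, mesh.nodes[mesh.elems])  # (ne, ngp, 3)
    ne, ngp = x.shape[:2]

    # transmural coordinate: layer midpoint, 0 = epi -> 1 = endo (layer 1 is
    # endocardial, layer n_layers epicardial)
    K = mesh.n_layers
    s_mid = 1.0 - (mesh.layer - 0.5) / K                  # (ne,)
    beta = np.empty((ne, ngp))
    for rid in np.unique(mesh.region):
        m = mesh.region == rid
        beta[m] = helix_angle(rid, s_mid[m], table)[:, None]
    eta = np.broadcast_to(transverse_angle(mesh.elem_ell)[:, None], (ne, ngp)).copy()

    # frames; interpolate surface semi-axes at the element's transmural level
    g = mesh.geometry
    a_s = g.a_epi + (g.a_endo - g.a_epi) * s_mid
    b_s = g.b_epi + (g.b_endo - g.b_epi) * s_mid
    flat = x.reshape(-1, 3)
    rho = np.hypot(flat[:, 0], flat[:, 1])
    safe = rho >= 1e-12
    c = np.zeros_like(flat)
    l = np.zeros_like(flat)
    r = np.zeros_like(flat)
    ab = np.repeat(np.stack([a_s, b_s], axis=1), ngp, axis=0)
    cc, ll, rr = _frames_bulk(flat[safe], ab[safe])
    c[safe], l[safe], r[safe] = cc, ll, rr
    if not np.all(safe):
        # apex-axis points inherit the nearest safe Gauss-point frame of the
        # same element
        for idx in np.where(~safe)[0]:
            e = idx // ngp
            cand = np.where(safe[e * ngp:(e + 1) * ngp])[0]
            if cand.size == 0:
                raise FiberError(f"element {e} has no off-axis quadrature point")
            src = e * ngp + cand[0]
            c[idx], l[idx], r[idx] = c[src], l[src], r[src]
    c = c.reshape(ne, ngp, 3)
    l = l.reshape(ne, ngp, 3)
    r = r.reshape(ne, ngp, 3)

    br = np.radians(beta)
    er = np.radians(eta)
    f = (np.cos(er) * (np.cos(br) * c.transpose(2, 0, 1) + np.sin(br) * l.transpose(2, 0, 1))
         + np.sin(er) * r.transpose(2, 0, 1)).transpose(1, 2, 0)
    return FiberField(
        myofiber=f, collagen=r.copy(), beta=beta, eta=eta,
        circumferential=c, longitudinal=l, radial=r,
        vf_myo=vf_myo, vf_collagen=vf_collagen,
    )


def _frames_bulk(pts: np.ndarray, ab: np.ndarray):
    c = np.stack([-pts[:, 1], pts[:, 0], np.zeros(len(pts))], axis=1)
    c /= np.linalg.norm(c, axis=1, keepdims=True)
    n = np.stack(
        [pts[:, 0] / ab[:, 1] ** 2, pts[:, 1] / ab[:, 1] ** 2, pts[:, 2] / ab[:, 0] ** 2],
        axis=1,
    )
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    l = np.cross(n, c)
    return c, l, n
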