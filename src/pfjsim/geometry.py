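"""Parametric surface geometry of the patellofemoral joint.

Bones are rigid; each articular region carries a uniform-thickness cartilage
layer (3 mm by default).  The construction is a frozen recipe controlled only
by the 12 :class:`~pfjsim.params.KneeParams` scalars:

Femur
    The articular contact region is a surface of revolution about the
    epicondylar axis (the x-axis; +x medial, +y anterior, +z proximal).  Its
    transverse profile is a smoothed V-groove: floor at the posterior radius,
    walls inclined at the trochlear facet angle (half of the complement of a
    138 deg sulcus angle), blended by an arc whose smoothing length is
    0.3 x posterior_radius.  The cartilage outer surface places the groove
    floor at posterior_radius + thickness; the subchondral bone surface is its
    exact inward normal offset.  The condyles and epicondyle taper (medial /
    lateral radii, widths 2 and 3, epicondylar breadth = width) extend the
    exported bone surface outside the contact region.

Patella
    A concave revolution solid: the articular face revolves about an axis
    parallel to the epicondylar axis so it is sagittally concave with radius
    patella_curvature_radius (hugging the trochlea through flexion), while
    its mediolateral profile copies the trochlear groove profile — the
    median ridge and both facets seat congruently in the sulcus, as the
    patella is aligned with the groove.  Revolution cuts trim the solid to
    width 2 x patella_radius and the printed height.

The femoral AP length parameters validate, sample and scale with the knee but
do not shape the articular revolution surface; the contact region is governed
by the posterior radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .params import KneeParams

__all__ = [
    "SurfacePatch",
    "KneeGeometry",
    "TrochlearSurface",
    "PatellarDish",
    "MeshError",
    "build_patella",
    "build_femur",
    "build_knee",
    "through_thickness_layers",
    "SULCUS_ANGLE_DEG",
]

# Frozen construction constants (dimensionless / angular, so the recipe is
# scale-equivariant in the 12 printed lengths).
SULCUS_ANGLE_DEG = 138.0
FACET_ANGLE_RAD = math.radians((180.0 - SULCUS_ANGLE_DEG) / 2.0)  # 21 deg
GROOVE_SMOOTHING_FRACTION = 0.3        # smoothing length / posterior_radius
TROCHLEA_HALF_ARC_RAD = math.radians(60.0)   # meshed arc of the revolution


class MeshError(ValueError):
    """Raised when a surface cannot be discretized at the requested size."""


@dataclass
class SurfacePatch:
    """Discretized articular surface: nodes (mm), outward unit normals,
    triangular facets, per-node area weights, optional uniform cartilage
    thickness and a medial/lateral facet label per node."""

    nodes: np.ndarray            # (N, 3)
    normals: np.ndarray          # (N, 3), unit, outward
    faces: np.ndarray            # (M, 3) int
    node_area: np.ndarray        # (N,) mm^2
    medial: np.ndarray           # (N,) bool; lateral = ~medial
    thickness: np.ndarray | None = None   # (N,) mm, cartilage patches only

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def mediolateral_extent(self) -> float:
        return float(self.nodes[:, 0].max() - self.nodes[:, 0].min())

    def translated(self, t: np.ndarray) -> "SurfacePatch":
        return replace(self, nodes=self.nodes + np.asarray(t, float))

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.nodes, faces=self.faces, process=False)


def _faces_from_grid(index: np.ndarray) -> np.ndarray:
    """Triangulate a structured grid with -1 marking removed nodes."""
    tris = []
    ni, nj = index.shape
    for i in range(ni - 1):
        for j in range(nj - 1):
            a, b, c, d = index[i, j], index[i + 1, j], index[i + 1, j + 1], index[i, j + 1]
            if min(a, b, c, d) < 0:
                continue
            tris.append((a, b, c))
            tris.append((a, c, d))
    return np.asarray(tris, dtype=int).reshape(-1, 3)


def _node_areas(nodes: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0, v1, v2 = nodes[faces[:, 0]], nodes[faces[:, 1]], nodes[faces[:, 2]]
    tri_area = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    area = np.zeros(len(nodes))
    for k in range(3):
        np.add.at(area, faces[:, k], tri_area / 3.0)
    return area


def point_surface_distance(points: np.ndarray, nodes: np.ndarray,
                           faces: np.ndarray, chunk: int = 200) -> np.ndarray:
    """Exact unsigned distance from each point to a triangulated surface.

    Vectorized point-to-triangle projection (clamped barycentric solve),
    evaluated in chunks so memory stays bounded.
    """
    points = np.asarray(points, float)
    a = nodes[faces[:, 0]]
    e0 = nodes[faces[:, 1]] - a          # (M, 3)
    e1 = nodes[faces[:, 2]] - a
    a00 = np.einsum("ij,ij->i", e0, e0)
    a01 = np.einsum("ij,ij->i", e0, e1)
    a11 = np.einsum("ij,ij->i", e1, e1)
    det = np.maximum(a00 * a11 - a01**2, 1e-18)
    out = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        p = points[lo:lo + chunk]
        d = a[None, :, :] - p[:, None, :]          # (n, M, 3)
        b0 = -np.einsum("nmj,mj->nm", d, e0)
        b1 = -np.einsum("nmj,mj->nm", d, e1)
        s = (a11 * b0 - a01 * b1) / det
        t = (a00 * b1 - a01 * b0) / det
        interior = (s >= 0) & (t >= 0) & (s + t <= 1)

        def dist2_at(ss, tt):
            v = d + ss[:, :, None] * e0[None] + tt[:, :, None] * e1[None]
            return np.einsum("nmj,nmj->nm", v, v)

        # candidate 1: the unconstrained minimiser, valid only inside
        dist2 = np.where(interior, dist2_at(s, t), np.inf)
        # candidates 2-4: projections onto the three edges
        s0 = np.clip(b0 / np.maximum(a00, 1e-18), 0.0, 1.0)          # t = 0
        dist2 = np.minimum(dist2, dist2_at(s0, np.zeros_like(s0)))
        t0 = np.clip(b1 / np.maximum(a11, 1e-18), 0.0, 1.0)          # s = 0
        dist2 = np.minimum(dist2, dist2_at(np.zeros_like(t0), t0))
        sd = np.clip((a11 - a01 + b0 - b1) /
                     np.maximum(a00 - 2 * a01 + a11, 1e-18), 0.0, 1.0)  # s + t = 1
        dist2 = np.minimum(dist2, dist2_at(sd, 1.0 - sd))
        out[lo:lo + chunk] = np.sqrt(dist2.min(axis=1))
    return out


def _symmetric_stations(half_extent: float, step: float) -> np.ndarray:
    n = max(2, round(half_extent / step))
    return np.linspace(-half_extent, half_extent, 2 * n + 1)


class TrochlearSurface:
    """Analytic femoral cartilage contact surface (outer face).

    Revolution about the epicondylar axis; cylindrical radius at
    mediolateral station x is ``rho(x) = floor + tan(gamma) * (sqrt(x^2+s^2)-s)``
    with ``floor = posterior_radius + cartilage thickness``.
    """

    def __init__(self, params: KneeParams, thickness: float = 3.0):
        self.params = params
        self.thickness = float(thickness)
        self.floor_radius = params.posterior_radius + self.thickness
        self.smoothing = GROOVE_SMOOTHING_FRACTION * params.posterior_radius
        self.tan_gamma = math.tan(FACET_ANGLE_RAD)

    def rho(self, x: np.ndarray) -> np.ndarray:
        s = self.smoothing
        return self.floor_radius + self.tan_gamma * (np.sqrt(x**2 + s**2) - s)

    def drho(self, x: np.ndarray) -> np.ndarray:
        s = self.smoothing
        return self.tan_gamma * x / np.sqrt(x**2 + s**2)

    def penetration(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Signed penetration depth of points into the surface (positive =
        inside), with the outward surface normal at the closest point.

        The revolution symmetry reduces the projection to the (x, r) profile
        plane: the foot point of each query is found by Newton projection
        onto the profile curve r = rho(x), so the returned depth is the true
        normal distance and the normal is exact at the foot point (this
        makes the integrated contact force the exact gradient of the
        foundation energy).
        """
        points = np.asarray(points, float)
        x, y, z = points[:, 0], points[:, 1], points[:, 2]
        r = np.maximum(np.hypot(y, z), 1e-9)
        # Newton projection in the profile plane: foot abscissa u minimises
        # (u - x)^2 + (rho(u) - r)^2
        u = x.copy()
        for _ in range(12):
            du = self.drho(u)
            g = (u - x) + (self.rho(u) - r) * du
            s = self.smoothing
            ddu = self.tan_gamma * s**2 / (u**2 + s**2) ** 1.5
            h = 1.0 + du**2 + (self.rho(u) - r) * ddu
            step = g / np.where(np.abs(h) < 1e-12, 1e-12, h)
            step = np.clip(step, -2.0, 2.0)
            u = u - step
            if np.abs(step).max() < 1e-12:
                break
        rho_u = self.rho(u)
        dist = np.hypot(u - x, rho_u - r)
        pen = np.where(r < rho_u, dist, -dist)
        du = self.drho(u)
        norm = np.sqrt(1.0 + du**2)
        # outward normal at the foot point, rotated out of the profile plane
        normals = np.stack([-du / norm, (y / r) / norm, (z / r) / norm], axis=1)
        return pen, normals


class PatellarFacet:
    """Analytic patellar cartilage contact surface (outer face), in the
    patella-local frame (origin at the median-ridge contact point, -y toward
    the femur).

    A concave revolution surface: the generating axis runs parallel to the
    epicondylar axis at local (y, z) = (-curvature_radius, 0), so the face is
    sagittally concave with the printed curvature radius (it hugs the
    trochlea in flexion-extension), while the revolution radius profile
    copies the trochlear groove profile (median ridge and facets congruent
    with the sulcus):

        r_p(x) = curvature_radius + tan(gamma) * (sqrt(x^2 + s^2) - s)
        y(x, z) = sqrt(r_p(x)^2 - z^2) - curvature_radius

    The disc trim |x| <= patella_radius sets the mediolateral extent
    (2 x patella_radius) and |z| <= height/2 the proximodistal extent.
    """

    def __init__(self, params: KneeParams):
        self.radius = params.patella_radius
        self.half_height = params.patella_height / 2.0
        self.curvature_radius = params.patella_curvature_radius
        self.smoothing = GROOVE_SMOOTHING_FRACTION * params.posterior_radius
        self.tan_gamma = math.tan(FACET_ANGLE_RAD)

    def radius_profile(self, x: np.ndarray) -> np.ndarray:
        s = self.smoothing
        return self.curvature_radius + self.tan_gamma * (np.sqrt(x**2 + s**2) - s)

    def dradius_profile(self, x: np.ndarray) -> np.ndarray:
        s = self.smoothing
        return self.tan_gamma * x / np.sqrt(x**2 + s**2)

    def surface_y(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        rp = self.radius_profile(np.asarray(x, float))
        return np.sqrt(np.maximum(rp**2 - np.asarray(z, float) ** 2, 0.0)) - \
            self.curvature_radius

    def normals(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Outward (femur-facing) unit normals at surface points (x, z)."""
        x = np.asarray(x, float)
        z = np.asarray(z, float)
        rp = self.radius_profile(x)
        drp = self.dradius_profile(x)
        y_ax = np.sqrt(np.maximum(rp**2 - z**2, 1e-9))  # y + curvature_radius
        norm = np.sqrt(1.0 + drp**2)
        return np.stack([drp / norm, -(y_ax / rp) / norm, -(z / rp) / norm], axis=1)

    def offset_point(self, points: np.ndarray, t: float) -> np.ndarray:
        """Exact normal offset away from the femur (the subchondral side)."""
        points = np.asarray(points, float)
        n = self.normals(points[:, 0], points[:, 2])
        return points - t * n


# backwards-friendly alias used in a few call sites
PatellarDish = PatellarFacet


def _grid_patch(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    normals: np.ndarray,
    mask: np.ndarray,
    thickness: float | None,
) -> SurfacePatch:
    index = -np.ones(mask.shape, dtype=int)
    index[mask] = np.arange(mask.sum())
    nodes = np.stack([X[mask], Y[mask], Z[mask]], axis=1)
    faces = _faces_from_grid(index)
    patch = SurfacePatch(
        nodes=nodes,
        normals=normals[mask],
        faces=faces,
        node_area=_node_areas(nodes, faces),
        medial=nodes[:, 0] >= 0.0,
        thickness=None if thickness is None else np.full(mask.sum(), float(thickness)),
    )
    return patch


def _facet_grid(params: KneeParams, element_size: float, half_width: float,
                half_height: float):
    facet = PatellarFacet(params)
    xs = _symmetric_stations(half_width, element_size)
    zs = _symmetric_stations(half_height, element_size)
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    mask = np.ones(X.shape, bool)
    Y = facet.surface_y(X, Z)
    normals = facet.normals(X.ravel(), Z.ravel()).reshape(*X.shape, 3)
    return X, Y, Z, normals, mask


def patellar_subchondral_plate(params: KneeParams, element_size: float = 1.0,
                               thickness: float = 3.0) -> SurfacePatch:
    """Subchondral bone plate: the exact inward normal offset of the
    articular facet surface, extended slightly beyond the cartilage rim so
    every cartilage node projects onto its interior."""
    ext = 2.0 * element_size
    rp, hh = params.patella_radius, params.patella_height / 2.0
    X, Y, Z, normals, mask = _facet_grid(params, element_size, rp + ext, hh + ext)
    patch = _grid_patch(X, Y, Z, normals, mask, None)
    return replace(patch, nodes=patch.nodes - thickness * patch.normals,
                   normals=patch.normals, medial=patch.nodes[:, 0] >= 0)


def build_patella(
    params: KneeParams, element_size: float = 1.0, thickness: float = 3.0
) -> tuple[SurfacePatch, SurfacePatch]:
    """Build the patellar bone and cartilage surface patches.

    The cartilage patch is the articular facet surface trimmed to the
    patellar width and height; the bone patch is its exact inward (anterior)
    normal offset by ``thickness`` plus a rim wall up to a flat anterior
    face closing the solid.  Mediolateral extent of the solid equals
    2 x patella_radius.
    """
    if element_size <= 0:
        raise MeshError("element_size must be positive")
    if element_size > params.patella_radius:
        raise MeshError(
            f"element_size {element_size} exceeds patella_radius {params.patella_radius}"
        )
    facet = PatellarFacet(params)
    rp, hh = params.patella_radius, params.patella_height / 2.0
    X, Y, Z, normals, mask = _facet_grid(params, element_size, rp, hh)
    cart = _grid_patch(X, Y, Z, normals, mask, thickness)

    # bone articular face: exact normal offset away from the femur
    off = np.stack([X, Y, Z], axis=-1) - thickness * normals
    bone_plate = _grid_patch(off[..., 0], off[..., 1], off[..., 2],
                             -normals, mask, None)
    bone_art_nodes = bone_plate.nodes
    # close the solid: perimeter wall up to a flat anterior face
    y_ant = float(bone_art_nodes[:, 1].max()) + 0.25 * params.patella_height
    per_x, per_z = [], []
    for t in _symmetric_stations(rp, element_size)[:-1]:
        per_x += [t, -t]
        per_z += [hh, -hh]
    for t in _symmetric_stations(hh, element_size)[:-1]:
        per_x += [rp, -rp]
        per_z += [t, -t]
    ring = np.stack([per_x, per_z], axis=1)
    ang = np.arctan2(ring[:, 1] / hh, ring[:, 0] / rp)
    ring = ring[np.argsort(ang)]
    ring_x, ring_z = ring[:, 0], ring[:, 1]
    rim_surface = np.stack(
        [ring_x, facet.surface_y(ring_x, ring_z), ring_z], axis=1)
    rim_lo = facet.offset_point(rim_surface, thickness)
    rim_hi = np.stack([ring_x, np.full_like(ring_x, y_ant), ring_z], axis=1)
    wall_nodes = np.vstack([rim_lo, rim_hi])
    nw = len(ring_x)
    wall_faces = []
    for i in range(nw):
        j = (i + 1) % nw
        wall_faces.append((i, j, nw + j))
        wall_faces.append((i, nw + j, nw + i))
    wall_faces = np.asarray(wall_faces, int)

    bone_nodes = np.vstack([bone_art_nodes, wall_nodes])
    bone_faces = np.vstack([bone_plate.faces, wall_faces + len(bone_art_nodes)])
    bone_normals = np.vstack([bone_plate.normals, np.zeros_like(wall_nodes)])
    radial = np.hypot(wall_nodes[:, 0], wall_nodes[:, 2])
    bone_normals[len(bone_art_nodes):, 0] = wall_nodes[:, 0] / np.maximum(radial, 1e-9)
    bone_normals[len(bone_art_nodes):, 2] = wall_nodes[:, 2] / np.maximum(radial, 1e-9)
    bone = SurfacePatch(
        nodes=bone_nodes,
        normals=bone_normals,
        faces=bone_faces,
        node_area=_node_areas(bone_nodes, bone_faces),
        medial=bone_nodes[:, 0] >= 0.0,
    )
    return bone, cart


def build_femur(
    params: KneeParams, element_size: float = 1.0, thickness: float = 3.0
) -> tuple[SurfacePatch, SurfacePatch]:
    """Build the femoral bone surface (contact region + condyles, epicondylar
    breadth = femur_width) and the trochlear cartilage patch."""
    if element_size <= 0:
        raise MeshError("element_size must be positive")
    surf = TrochlearSurface(params, thickness)
    w3h = params.femur_width3 / 2.0
    xs = _symmetric_stations(w3h, element_size)
    mean_rho = float(np.mean(surf.rho(xs)))
    nphi = max(4, round(mean_rho * TROCHLEA_HALF_ARC_RAD / element_size))
    phis = np.linspace(-TROCHLEA_HALF_ARC_RAD, TROCHLEA_HALF_ARC_RAD, 2 * nphi + 1)
    X, PHI = np.meshgrid(xs, phis, indexing="ij")
    RHO = surf.rho(X)
    Y, Z = RHO * np.cos(PHI), RHO * np.sin(PHI)
    dr = surf.drho(X)
    nrm = np.sqrt(1.0 + dr**2)
    normals = np.stack(
        [-dr / nrm, np.cos(PHI) / nrm, np.sin(PHI) / nrm], axis=-1
    )
    mask = np.ones(X.shape, bool)
    cart = _grid_patch(X, Y, Z, normals, mask, thickness)

    # bone: exact inward normal offset of the contact region ...
    contact_bone_nodes = cart.nodes - thickness * cart.normals
    # ... extended by condylar blend and epicondyle taper (export geometry)
    bone_sections = [contact_bone_nodes.reshape(len(xs), len(phis), 3)]
    x_order = [xs]
    for side, r_side in ((1.0, params.medial_radius), (-1.0, params.lateral_radius)):
        w2h, wh = params.femur_width2 / 2.0, params.femur_width / 2.0
        edge_rho = float(surf.rho(np.array([side * w3h]))[0]) - thickness
        na = max(1, round((w2h - w3h) / element_size))
        xa = np.linspace(w3h, w2h, na + 1)[1:]
        nb = max(1, round((wh - w2h) / element_size))
        xb = np.linspace(w2h, wh, nb + 1)[1:]
        u = (xa - w3h) / (w2h - w3h)
        rho_a = edge_rho + (r_side - edge_rho) * (3 * u**2 - 2 * u**3)
        v = (xb - w2h) / (wh - w2h)
        rho_b = np.maximum(r_side * np.cos(0.5 * math.pi * v),
                           0.005 * params.femur_width)
        x_ext = side * np.concatenate([xa, xb])
        rho_ext = np.concatenate([rho_a, rho_b])
        sec = np.empty((len(x_ext), len(phis), 3))
        sec[:, :, 0] = x_ext[:, None]
        sec[:, :, 1] = rho_ext[:, None] * np.cos(phis)[None, :]
        sec[:, :, 2] = rho_ext[:, None] * np.sin(phis)[None, :]
        bone_sections.append(sec)
        x_order.append(x_ext)

    all_x = np.concatenate(x_order)
    order = np.argsort(all_x, kind="stable")
    grid = np.concatenate(bone_sections, axis=0)[order]
    ni, nj, _ = grid.shape
    index = np.arange(ni * nj).reshape(ni, nj)
    bone_nodes = grid.reshape(-1, 3)
    bone_faces = _faces_from_grid(index)
    radial = np.hypot(bone_nodes[:, 1], bone_nodes[:, 2])
    bone_normals = np.zeros_like(bone_nodes)
    bone_normals[:, 1] = bone_nodes[:, 1] / np.maximum(radial, 1e-9)
    bone_normals[:, 2] = bone_nodes[:, 2] / np.maximum(radial, 1e-9)
    bone = SurfacePatch(
        nodes=bone_nodes,
        normals=bone_normals,
        faces=bone_faces,
        node_area=_node_areas(bone_nodes, bone_faces),
        medial=bone_nodes[:, 0] >= 0.0,
    )
    return bone, cart


@dataclass
class KneeGeometry:
    """All surfaces of one knee plus the analytic contact surfaces.

    ``femur_bone_contact`` / ``patella_bone_contact`` are the exact normal
    offsets of the cartilage patches (the subchondral plates); the cartilage
    offset invariant is measured against these.  ``femur_bone`` is the full
    exported bone including condyles.
    """

    params: KneeParams
    element_size: float
    patellar_thickness: float
    femoral_thickness: float
    femur_bone: SurfacePatch
    femoral_cartilage: SurfacePatch
    femur_bone_contact: SurfacePatch
    patella_bone: SurfacePatch
    patellar_cartilage: SurfacePatch
    patella_bone_contact: SurfacePatch
    trochlea: TrochlearSurface
    facet: PatellarFacet
    epicondylar_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    groove_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def cartilage_offset_errors(self) -> dict[str, float]:
        """Max |distance(cartilage node, bone contact surface) - thickness|."""
        out = {}
        for name, cart, bone, t in (
            ("patella", self.patellar_cartilage, self.patella_bone_contact,
             self.patellar_thickness),
            ("femur", self.femoral_cartilage, self.femur_bone_contact,
             self.femoral_thickness),
        ):
            dist = point_surface_distance(cart.nodes, bone.nodes, bone.faces)
            out[name] = float(np.abs(dist - t).max())
        return out


def build_knee(
    params: KneeParams,
    element_size: float = 1.0,
    patellar_thickness: float = 3.0,
    femoral_thickness: float = 3.0,
) -> KneeGeometry:
    """Assemble the full knee geometry used by the contact solver."""
    fem_bone, fem_cart = build_femur(params, element_size, femoral_thickness)
    pat_bone, pat_cart = build_patella(params, element_size, patellar_thickness)

    fem_contact_nodes = fem_cart.nodes - femoral_thickness * fem_cart.normals
    fem_contact = replace(fem_cart, nodes=fem_contact_nodes, thickness=None,
                          normals=fem_cart.normals.copy())
    pat_contact = patellar_subchondral_plate(params, element_size, patellar_thickness)
    return KneeGeometry(
        params=params,
        element_size=element_size,
        patellar_thickness=patellar_thickness,
        femoral_thickness=femoral_thickness,
        femur_bone=fem_bone,
        femoral_cartilage=fem_cart,
        femur_bone_contact=fem_contact,
        patella_bone=pat_bone,
        patellar_cartilage=pat_cart,
        patella_bone_contact=pat_contact,
        trochlea=TrochlearSurface(params, femoral_thickness),
        facet=PatellarFacet(params),
    )


def through_thickness_layers(thickness: float = 3.0, element_size: float = 1.0) -> int:
    """Equivalent through-thickness resolution of the cartilage response.

    The foundation closure integrates the layer constitutive response in
    closed form; its resolution is equivalent to at least
    ``thickness / element_size`` uniform layers (3 at the defaults).
    """
    return int(thickness // element_size)
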