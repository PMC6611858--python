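"""Elastic-foundation cartilage contact and quasi-static patellar equilibrium.

The two rigid bones carry thin linear-elastic cartilage layers; contact
pressure follows the confined-compression (Winkler) foundation closure

    p = (1-nu) E / ((1+nu)(1-2nu) t) * max(d, 0)

where d is the mutual surface overlap and the two layers act in series
(summed compliance).  The patella is a rigid body: it is seated in the
trochlear groove, pressed on by a perpendicular approach displacement to
create the stored baseline field, and then loaded by ligament forces.  The
quadriceps/patellar-tendon tie fixes the superior-inferior and
anteroposterior coordinates at the approached pose, so equilibrium resolves
the mediolateral glide by minimising total potential energy (foundation
contact energy + element strain energy - work of constant pretension
forces).  Friction (mu = 0.02) enters as a dissipative bound on the
reported tangential load; it does not alter the quasi-static normal
solution, consistent with the observed insensitivity of peak pressure to mu.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .geometry import KneeGeometry
from .materials import CartilageMaterial, ContactSettings
from .tissue import LigamentElement

__all__ = [
    "foundation_pressure",
    "combined_foundation_stiffness",
    "ContactField",
    "PatellaPose",
    "ContactModel",
    "relative_field",
    "IndeterminateEquilibriumError",
    "SolverError",
]

FREE_DOF_DEFAULT = ("x",)
_DOF_INDEX = {"x": 0, "y": 1, "z": 2}


class IndeterminateEquilibriumError(RuntimeError):
    """No contact and no tense element: the patellar pose is not determined."""


class SolverError(RuntimeError):
    pass


def foundation_pressure(penetration, mat: CartilageMaterial):
    """Foundation pressure (MPa) for a penetration depth (mm) into a layer.

    For two stacked layers of the same material, pass a layer with the summed
    thickness (series compliance).
    """
    k = mat.confined_modulus / mat.thickness
    return k * np.maximum(np.asarray(penetration, float), 0.0)


def combined_foundation_stiffness(*layers: CartilageMaterial) -> float:
    """Foundation stiffness (MPa/mm) of layers in series: 1 / sum(t_i/C_i)."""
    return 1.0 / sum(layer.thickness / layer.confined_modulus for layer in layers)


@dataclass
class ContactField:
    """Nodal contact state on the patellar cartilage surface."""

    nodes: np.ndarray          # (N, 3) node positions at this pose (mm)
    penetration: np.ndarray    # (N,) mm (may be negative = gap, clipped in p)
    pressure: np.ndarray       # (N,) MPa (>= 0, or signed for relative fields)
    normals: np.ndarray        # (N, 3) femoral outward normals at the nodes
    node_area: np.ndarray      # (N,) mm^2
    medial: np.ndarray         # (N,) bool
    friction: float = 0.0
    mesh_token: str = ""
    is_relative: bool = False

    @property
    def total_force(self) -> float:
        """Total normal force (N): integral of pressure over area."""
        return float(np.sum(self.pressure * self.node_area))

    def resultant(self) -> np.ndarray:
        """Resultant contact force vector on the patella (N)."""
        return np.sum((self.pressure * self.node_area)[:, None] * self.normals, axis=0)

    @property
    def contact_area(self) -> float:
        return float(np.sum(self.node_area[self.pressure > 0]))

    @property
    def friction_bound(self) -> float:
        """Upper bound on the tangential (friction) load: mu * normal force."""
        return self.friction * abs(self.total_force)

    def peak(self, facet: str | None = None) -> float:
        if facet is None:
            sel = slice(None)
        elif facet == "medial":
            sel = self.medial
        elif facet == "lateral":
            sel = ~self.medial
        else:
            raise ValueError(f"facet must be 'medial' or 'lateral', got {facet!r}")
        vals = self.pressure[sel]
        return float(vals.max()) if len(vals) else 0.0


@dataclass
class PatellaPose:
    """Rigid patella translation (mm, femur frame) and the equilibrium
    residual on the free DOFs (N)."""

    translation: np.ndarray
    residual_n: float = 0.0
    free_dofs: tuple[str, ...] = FREE_DOF_DEFAULT


def relative_field(loaded: ContactField, baseline: ContactField) -> ContactField:
    """Nodewise signed difference loaded - baseline on the same mesh."""
    if loaded.mesh_token != baseline.mesh_token or len(loaded.pressure) != len(baseline.pressure):
        raise ValueError("relative field requires fields on the same mesh")
    return replace(
        loaded,
        pressure=loaded.pressure - baseline.pressure,
        penetration=loaded.penetration - baseline.penetration,
        is_relative=True,
    )


class ContactModel:
    """Foundation contact between one knee's patellar and femoral cartilage."""

    def __init__(
        self,
        geometry: KneeGeometry,
        patellar_mat: CartilageMaterial | None = None,
        femoral_mat: CartilageMaterial | None = None,
        settings: ContactSettings | None = None,
    ):
        self.geometry = geometry
        self.patellar_mat = patellar_mat or CartilageMaterial(
            thickness=geometry.patellar_thickness)
        self.femoral_mat = femoral_mat or CartilageMaterial(
            thickness=geometry.femoral_thickness)
        self.settings = settings or ContactSettings()
        self.stiffness = combined_foundation_stiffness(self.patellar_mat, self.femoral_mat)
        patch = geometry.patellar_cartilage
        self._local_nodes = patch.nodes
        self._areas = patch.node_area
        self._medial = patch.medial
        self.mesh_token = hashlib.sha256(
            np.ascontiguousarray(self._local_nodes).tobytes()
        ).hexdigest()[:16]
        self._baseline_pose: PatellaPose | None = None

    # -- kinematics -------------------------------------------------------
    def penetration(self, translation: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = self._local_nodes + np.asarray(translation, float)
        return self.geometry.trochlea.penetration(pts)

    def field(self, translation: np.ndarray) -> ContactField:
        pen, normals = self.penetration(translation)
        p = self.stiffness * np.maximum(pen, 0.0)
        return ContactField(
            nodes=self._local_nodes + np.asarray(translation, float),
            penetration=pen,
            pressure=p,
            normals=normals,
            node_area=self._areas,
            medial=self._medial,
            friction=self.settings.friction,
            mesh_token=self.mesh_token,
        )

    # -- baseline ---------------------------------------------------------
    def seat_patella(self) -> np.ndarray:
        """Anteroposterior translation seating the patella in the groove:
        advanced until the closest point is within the contact-adjustment
        distance of the femoral surface (counted as just-touching)."""
        adj = self.settings.adjustment

        def max_pen(ty: float) -> float:
            pen, _ = self.penetration(np.array([0.0, ty, 0.0]))
            return float(pen.max())

        hi = self.geometry.trochlea.rho(np.array([0.0]))[0] + \
            self.geometry.params.patella_curvature_radius + 20.0
        lo = self.geometry.trochlea.floor_radius * 0.2
        ty = optimize.brentq(lambda t: max_pen(t) + adj, lo, hi, xtol=1e-10)
        return np.array([0.0, float(ty), 0.0])

    def baseline(self) -> tuple[PatellaPose, ContactField]:
        """Seat the patella, impose the perpendicular approach displacement,
        and store the resulting baseline field."""
        t0 = self.seat_patella()
        t = t0 - np.array([0.0, self.settings.approach, 0.0])
        pose = PatellaPose(translation=t, residual_n=0.0, free_dofs=())
        self._baseline_pose = pose
        return pose, self.field(t)

    # -- equilibrium ------------------------------------------------------
    def solve_equilibrium(
        self,
        applied_force: np.ndarray | None = None,
        springs: list[tuple[LigamentElement, float]] | None = None,
        free_dofs: tuple[str, ...] = FREE_DOF_DEFAULT,
        start: PatellaPose | None = None,
    ) -> tuple[PatellaPose, ContactField]:
        """Quasi-static equilibrium of the patella under constant applied
        forces and only-tension springs.

        ``springs`` are (element, rest_length) pairs contributing strain
        energy 0.5 K max(L - l0, 0)^2.  The locked DOFs stay at the baseline
        (approached) pose; the free DOFs are solved by energy minimisation
        followed by a Newton polish until the residual force is below the
        configured tolerance.
        """
        if self._baseline_pose is None:
            self.baseline()
        base = start.translation if start is not None else self._baseline_pose.translation
        f_app = np.zeros(3) if applied_force is None else np.asarray(applied_force, float)
        springs = springs or []
        idx = [_DOF_INDEX[d] for d in free_dofs]

        base_field = self.field(base)
        if base_field.total_force == 0 and not springs and np.linalg.norm(f_app) == 0:
            raise IndeterminateEquilibriumError(
                "no contact and no tense element: patellar pose indeterminate"
            )

        def translation(u: np.ndarray) -> np.ndarray:
            t = base.copy()
            t[idx] += u
            return t

        def energy_grad(u: np.ndarray) -> tuple[float, np.ndarray]:
            t = translation(u)
            pen, normals = self.penetration(t)
            active = pen > 0
            e = 0.5 * self.stiffness * np.sum(self._areas[active] * pen[active] ** 2)
            # dE/dt = -(contact force); pen decreases along the femoral normal
            f_contact = np.sum(
                (self.stiffness * pen[active] * self._areas[active])[:, None]
                * normals[active], axis=0,
            ) if active.any() else np.zeros(3)
            g = -f_contact - f_app
            e -= float(f_app @ t)
            for element, l0 in springs:
                length = element.length(t)
                stretch = length - l0
                if stretch > 0:
                    e += 0.5 * element.stiffness * stretch**2
                    g -= element.stiffness * stretch * element.direction(t)
            return e, g[idx]

        if idx:
            res = optimize.minimize(
                lambda u: energy_grad(u)[0],
                x0=np.zeros(len(idx)),
                jac=lambda u: energy_grad(u)[1],
                method="L-BFGS-B",
                options={"gtol": 1e-9, "ftol": 1e-15, "maxiter": 500},
            )
            u = res.x
            # Newton polish on the residual force
            tol = self.settings.residual_tol_n
            for _ in range(60):
                g = energy_grad(u)[1]
                if np.linalg.norm(g) < 1e-2 * tol:
                    break
                h = np.zeros((len(idx), len(idx)))
                eps = 1e-5
                for k in range(len(idx)):
                    du = np.zeros(len(idx))
                    du[k] = eps
                    h[:, k] = (energy_grad(u + du)[1] - energy_grad(u - du)[1]) / (2 * eps)
                try:
                    step = np.linalg.solve(h, -g)
                except np.linalg.LinAlgError:
                    break
                step = np.clip(step, -0.5, 0.5)
                u = u + step
            residual = float(np.linalg.norm(energy_grad(u)[1]))
            if residual > self.settings.residual_tol_n:
                raise SolverError(
                    f"equilibrium residual {residual:.3e} N exceeds tolerance "
                    f"{self.settings.residual_tol_n} N"
                )
        else:
            u = np.zeros(0)
            residual = 0.0

        t = translation(u)
        pose = PatellaPose(translation=t, residual_n=residual, free_dofs=tuple(free_dofs))
        return pose, self.field(t)
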