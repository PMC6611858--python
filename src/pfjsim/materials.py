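"""Tissue material properties and contact settings.

Ligament/tendon stiffnesses (N/mm) come from the packaged reference table:
quadriceps tendon 1350, patellar tendon 2000, lateral retinaculum 2, native
MPFL 12, and the three graft options (semitendinosus 100, gracilis 80,
quadriceps-tendon graft 33.6), all with Poisson ratio 0.3.  Cartilage is a
linear elastic layer (E = 10 MPa, nu = 0.45, 3 mm thick by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "MaterialTable",
    "CartilageMaterial",
    "ContactSettings",
    "UnknownTissueError",
]

MM = float  # lengths in mm package-wide; forces N; pressures/stresses MPa

BEAM_RADIUS_MM = 1.0  # ligament/tendon line elements carry a 1 mm circular cross-section
REFERENCE_ANGLE_DEG = 40.0  # strain-free reference flexion angle for graft length tables
MPFL_THERMAL_ALPHA = 0.0005  # 1/degC, fictitious dilatation coefficient for thermal shortening


class UnknownTissueError(KeyError):
    """Requested tissue is not in the material table (the table is closed)."""


class MaterialTable:
    """Closed lookup table of tissue stiffness (N/mm) and Poisson ratio."""

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            with resources.files("pfjsim.data").joinpath("material_properties.csv").open("r") as fh:
                frame = pd.read_csv(fh)
        frame = frame.set_index("tissue")
        if (frame["stiffness_n_per_mm"] <= 0).any():
            raise ValueError("all stiffnesses must be positive")
        self._frame = frame

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(self._frame.index)

    def stiffness(self, tissue: str) -> float:
        try:
            return float(self._frame.loc[tissue, "stiffness_n_per_mm"])
        except KeyError:
            raise UnknownTissueError(tissue) from None

    def poisson(self, tissue: str) -> float:
        try:
            return float(self._frame.loc[tissue, "poisson_ratio"])
        except KeyError:
            raise UnknownTissueError(tissue) from None


@dataclass(frozen=True)
class CartilageMaterial:
    """Linear-elastic cartilage layer: modulus (MPa), Poisson ratio, thickness (mm)."""

    elastic_modulus: float = 10.0
    poisson_ratio: float = 0.45
    thickness: MM = 3.0

    def __post_init__(self) -> None:
        if self.elastic_modulus <= 0 or self.thickness <= 0:
            raise ValueError("modulus and thickness must be positive")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5); 0.5 is incompressible/singular")

    @property
    def confined_modulus(self) -> float:
        """Constrained (oedometric) modulus (1-nu)E/((1+nu)(1-2nu)), MPa."""
        nu = self.poisson_ratio
        return (1.0 - nu) * self.elastic_modulus / ((1.0 + nu) * (1.0 - 2.0 * nu))


@dataclass(frozen=True)
class ContactSettings:
    """Contact model settings.

    ``friction`` is the (penalty) friction coefficient; in the foundation
    closure it only bounds the reported tangential load, it does not alter the
    quasi-static normal solution.  ``adjustment`` is the initial-gap snap
    threshold: when seating the patella, surface points within this distance
    of the counter-surface count as touching.  ``approach`` is the initial
    perpendicular displacement imposed on the patella to generate baseline
    contact before any soft tissue acts.
    """

    friction: float = 0.02
    adjustment: MM = 0.1
    approach: MM = 0.5
    residual_tol_n: float = 0.01
    thermal_tol_mm: float = 0.01

    def __post_init__(self) -> None:
        if self.friction < 0:
            raise ValueError("friction coefficient must be >= 0")
        if self.approach < 0:
            raise ValueError("approach displacement must be >= 0")
        if self.adjustment < 0:
            raise ValueError("contact adjustment must be >= 0")
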