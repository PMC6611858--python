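"""Tendon and ligament line elements and graft tensioning protocols.

Ligaments (MPFL, lateral retinaculum) and tendons (quadriceps, patellar) are
axial-only line elements with a 1 mm circular cross-section that carry load
in tension only.  Bending of a 1 mm ligament beam is negligible at joint
loads, so the beam formulation reduces to springs/applied forces along the
insertion line — a deliberate simplification.

A graft length table gives the patella-to-femur insertion distance at each
flexion angle; the 40 deg position is the strain-free reference.  At a given
angle the element is

``slack``
    target distance below the reference: no load, no analysis needed;
``pretension`` (tension type 1)
    target distance above the reference by Δl: loaded by a constant
    pretension force Δl·K along the insertion line;
``thermal`` (tension type 2)
    target distance shorter than the joint would allow without compressing
    the cartilage: the element rest length is contracted via a fictitious
    temperature drop ΔT with dilatation coefficient α, iterated until the
    achieved length matches the target.

The zero-elongation boundary (target equal to the reference) is classified
as pretension with zero force.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable

import numpy as np

from .materials import BEAM_RADIUS_MM, MPFL_THERMAL_ALPHA

logger = logging.getLogger(__name__)

__all__ = [
    "TensionState",
    "TensionProtocol",
    "LigamentElement",
    "ConvergenceError",
    "ligament_force",
    "ligament_stress",
    "classify_tension",
    "thermal_deltaT",
    "iterate_thermal",
    "lr_alpha",
]


class ConvergenceError(RuntimeError):
    """Thermal-shortening iteration failed to reach the target length."""


class TensionState(str, Enum):
    SLACK = "slack"
    PRETENSION = "pretension"
    THERMAL = "thermal"


_NOTE_TO_STATE = {"a": TensionState.SLACK, "b": TensionState.PRETENSION,
                  "c": TensionState.THERMAL}


def ligament_force(elongation: float, stiffness: float) -> float:
    """Tension (N) of an only-tension element: K·Δl for Δl > 0, else 0."""
    if stiffness <= 0:
        raise ValueError("stiffness must be positive")
    return stiffness * elongation if elongation > 0 else 0.0


def ligament_stress(force: float, radius: float = BEAM_RADIUS_MM) -> float:
    """Axial stress (MPa) = force / (pi r^2) for the circular cross-section."""
    if force < 0:
        raise ValueError("only-tension elements cannot carry negative force")
    if radius <= 0:
        raise ValueError("radius must be positive")
    return force / (math.pi * radius**2)


def classify_tension(
    target_length: float,
    reference_length: float,
    footnote_hint: str | None = None,
) -> TensionState:
    """Classify the tension state of a graft at one flexion angle.

    The geometric rule compares the target insertion distance with the
    strain-free 40 deg reference: Δl >= 0 means the element must be loaded
    (pretension; zero force exactly at the boundary), Δl < 0 means it goes
    slack.  The thermal state cannot be detected geometrically — it requires
    knowing that the target is reachable only by compressing the cartilage —
    so a table footnote hint ('a'/'b'/'c') overrides the rule; a disagreement
    between hint and rule is logged, not raised.
    """
    if target_length <= 0 or reference_length <= 0:
        raise ValueError("lengths must be positive")
    dl = target_length - reference_length
    geometric = TensionState.PRETENSION if dl >= 0 else TensionState.SLACK
    if footnote_hint is None or footnote_hint == "":
        return geometric
    try:
        hinted = _NOTE_TO_STATE[footnote_hint]
    except KeyError:
        raise ValueError(f"unknown footnote hint {footnote_hint!r}") from None
    if hinted is not geometric:
        logger.warning(
            "tension hint %r (%s) overrides geometric rule (%s) at target=%.2f "
            "reference=%.2f", footnote_hint, hinted.value, geometric.value,
            target_length, reference_length,
        )
    return hinted


def thermal_deltaT(dl: float, l0: float, alpha: float = MPFL_THERMAL_ALPHA) -> float:
    """Temperature drop (degC) whose thermal strain equals the required
    shortening strain |Δl|/l0; the initial guess of the iterative scheme."""
    if l0 <= 0 or alpha <= 0:
        raise ValueError("l0 and alpha must be positive")
    return (abs(dl) / l0) / alpha


def iterate_thermal(
    achieved_length: Callable[[float], float],
    target_length: float,
    l0: float,
    alpha: float = MPFL_THERMAL_ALPHA,
    tol: float = 0.01,
    max_iter: int = 50,
) -> float:
    """Iterate the fictitious temperature drop until the element length
    reaches the target.

    ``achieved_length(deltaT)`` must re-solve equilibrium with the rest
    length contracted to l0·(1 - α·ΔT) and return the resulting insertion
    distance; it is monotone non-increasing in ΔT.  Returns the converged ΔT
    (0 if the unshortened length is already within tolerance).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    f0 = achieved_length(0.0) - target_length
    if abs(f0) < tol:
        return 0.0
    if f0 < 0:
        raise ConvergenceError(
            f"unshortened length is already {-f0:.3f} mm below target; "
            "thermal shortening cannot lengthen an element"
        )
    # bracket by doubling from the strain-matched initial guess
    dt_hi = thermal_deltaT(f0, l0, alpha)
    n = 0
    while achieved_length(dt_hi) - target_length > 0:
        dt_hi *= 2.0
        n += 1
        if n > max_iter:
            raise ConvergenceError(
                f"could not bracket target length {target_length} "
                f"(residual {achieved_length(dt_hi) - target_length:.4f} mm)"
            )
    from scipy.optimize import brentq

    dt = brentq(lambda t: achieved_length(t) - target_length, 0.0, dt_hi,
                xtol=1e-6, maxiter=max_iter * 4)
    residual = achieved_length(dt) - target_length
    if abs(residual) > tol:
        raise ConvergenceError(
            f"thermal iteration stalled: residual {residual:.4f} mm > tol {tol}"
        )
    return float(dt)


def lr_alpha(dl: float, deltaT: float, l0_lr: float) -> float:
    """Dilatation coefficient for the lateral retinaculum so the same model
    temperature drop reproduces the same absolute length change Δl on the LR:
    α_LR = Δl / (ΔT · l0_LR)."""
    if l0_lr <= 0:
        raise ValueError("l0_lr must be positive")
    if deltaT == 0:
        if dl == 0:
            return 0.0
        raise ValueError("alpha_LR undefined: ΔT = 0 with Δl != 0")
    return dl / (deltaT * l0_lr)


@dataclass(frozen=True)
class LigamentElement:
    """Axial line element between a patella-fixed and a femur-fixed point.

    ``patellar_point`` is in the patella-local frame (moves with the patella
    rigid body); ``femoral_point`` is in the fixed femur frame.
    """

    name: str
    patellar_point: np.ndarray
    femoral_point: np.ndarray
    stiffness: float
    tissue: str = ""
    radius: float = BEAM_RADIUS_MM
    bundle: str = "single"

    def length(self, patella_translation: np.ndarray) -> float:
        p = np.asarray(self.patellar_point, float) + np.asarray(patella_translation, float)
        return float(np.linalg.norm(p - np.asarray(self.femoral_point, float)))

    def direction(self, patella_translation: np.ndarray) -> np.ndarray:
        """Unit vector of the pull on the patella (toward the femoral point)."""
        p = np.asarray(self.patellar_point, float) + np.asarray(patella_translation, float)
        d = np.asarray(self.femoral_point, float) - p
        return d / np.linalg.norm(d)


@dataclass
class TensionProtocol:
    """Per-angle tensioning record for one graft bundle."""

    angle_deg: float
    target_length: float
    reference_length: float
    state: TensionState
    note: str | None = None
    thermal_deltaT_c: float | None = None
    alpha_lr: float | None = None

    @property
    def dl(self) -> float:
        return self.target_length - self.reference_length

    @property
    def pretension_force(self) -> float:
        """Constant applied force Δl·K is formed by the caller; here Δl only."""
        return max(self.dl, 0.0)


def extensor_elements(femur_width: float, patella_height: float,
                      dish_center_y: float = 0.0) -> list[LigamentElement]:
    """Quadriceps (VM/VL/VI/RF) and patellar-tendon line elements.

    Orientations follow standard coronal lines of action (vastus medialis
    ~45 deg medial, vastus lateralis ~30 deg lateral, intermedius and rectus
    near-vertical; patellar tendon to the tibial tubercle).  During
    equilibrium these act as the fixed tie that locks the superior-inferior
    and anteroposterior patellar position — no force passes through them —
    so they are carried for geometry export and reporting.
    """
    from .materials import MaterialTable

    table = MaterialTable()
    kq = table.stiffness("quadriceps_tendon")
    kp = table.stiffness("patellar_tendon")
    top = np.array([0.0, dish_center_y, patella_height / 2.0])
    bot = np.array([0.0, dish_center_y, -patella_height / 2.0])
    reach = 80.0
    lines = [
        ("VM", top, np.array([math.sin(math.radians(45)), 0.1, math.cos(math.radians(45))]), kq),
        ("VL", top, np.array([-math.sin(math.radians(30)), 0.1, math.cos(math.radians(30))]), kq),
        ("VI", top, np.array([0.0, 0.15, 1.0]), kq),
        ("RF", top, np.array([0.0, 0.3, 1.0]), kq),
        ("PT_med", bot, np.array([0.08, 0.3, -1.0]), kp),
        ("PT_lat", bot, np.array([-0.08, 0.3, -1.0]), kp),
    ]
    out = []
    for name, anchor, d, k in lines:
        d = d / np.linalg.norm(d)
        tissue = "quadriceps_tendon" if name in ("VM", "VL", "VI", "RF") else "patellar_tendon"
        out.append(LigamentElement(name=name, patellar_point=anchor,
                                   femoral_point=anchor + reach * d,
                                   stiffness=k, tissue=tissue))
    return out
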