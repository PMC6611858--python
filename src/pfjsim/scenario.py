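"""Full simulations: native knee, MPFL reconstructions, clinical cases.

Flexion is driven kinematically: each technique/case supplies a measured
patella-to-femur insertion distance per flexion angle (0/30/60/90/120 deg,
with the strain-free reference at 40 deg), and the solver imposes the
corresponding tension protocol at each angle on a fixed contact
configuration (the articular contact region is a surface of revolution about
the epicondylar axis, so the seated contact geometry is the same at every
groove station).  The native knee uses the anatomic insertion-length column
with the native MPFL stiffness — the anatomic femoral point is by definition
the native footprint.

Reported per angle: patella pose, the relative contact-pressure field
(loaded minus stored baseline), peak relative pressure per facet, maximum
MPFL/graft and lateral-retinaculum stress, and the tension classification.
The lateral retinaculum is assumed to undergo the same length change as the
MPFL (equilibrium of the medial and lateral restraints), so its tension is
K_LR times the MPFL elongation.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contact import ContactField, ContactModel, PatellaPose, relative_field
from .geometry import KneeGeometry, build_knee
from .materials import (
    CartilageMaterial,
    ContactSettings,
    MaterialTable,
    REFERENCE_ANGLE_DEG,
    MPFL_THERMAL_ALPHA,
)
from .params import KneeParams, load_case
from .tissue import (
    LigamentElement,
    TensionProtocol,
    TensionState,
    classify_tension,
    iterate_thermal,
    ligament_stress,
    lr_alpha,
)

__all__ = [
    "ANGLES_DEG",
    "ReconstructionSpec",
    "AngleResult",
    "SimulationResult",
    "ClinicalReport",
    "run_case",
    "physiometric_check",
    "isometric_check",
    "sweep",
    "clinical_report",
    "OA_PRESSURE_THRESHOLD_MPA",
]

ANGLES_DEG = (0.0, 30.0, 60.0, 90.0, 120.0)

# Conservative symptomatic-osteoarthritis contact-stress threshold,
# extrapolated from tibiofemoral data; a reporting flag only, never a
# pass/fail gate (patellar cartilage is thicker, so the true threshold is
# plausibly higher).
OA_PRESSURE_THRESHOLD_MPA = 3.42

TECHNIQUES = (
    "native",
    "anatomic",
    "non_anatomic_physiometric",
    "non_anatomic_non_physiometric",
)

_DB_BUNDLE_HALF_SEPARATION_MM = 5.0


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("pfjsim.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, keep_default_na=False)


@dataclass
class ReconstructionSpec:
    """One reconstruction (or the native ligament) to simulate.

    ``lengths`` maps bundle name -> {angle: (length_mm, footnote)} and must
    cover the five analysis angles plus the 40 deg reference.  ``graft``
    names a tissue in the material table.
    """

    technique: str
    graft: str
    bundle_config: str  # "SB" or "DB"
    lengths: Mapping[str, Mapping[float, tuple[float, str]]]
    reference_angle: float = REFERENCE_ANGLE_DEG

    def __post_init__(self) -> None:
        needed = set(ANGLES_DEG) | {self.reference_angle}
        for bundle, table in self.lengths.items():
            missing = needed - set(table)
            if missing:
                raise ValueError(
                    f"bundle {bundle!r} length table missing angles {sorted(missing)}"
                )

    @property
    def bundles(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    def reference_length(self, bundle: str) -> float:
        return self.lengths[bundle][self.reference_angle][0]

    def protocols(self, bundle: str) -> list[TensionProtocol]:
        ref = self.reference_length(bundle)
        out = []
        for angle in ANGLES_DEG:
            length, note = self.lengths[bundle][angle]
            state = classify_tension(length, ref, note or None)
            out.append(TensionProtocol(angle_deg=angle, target_length=length,
                                       reference_length=ref, state=state,
                                       note=note or None))
        return out

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_technique(cls, technique: str, graft: str | None = None) -> "ReconstructionSpec":
        """Standard techniques driven by the packaged mean length tables."""
        if technique not in TECHNIQUES:
            raise KeyError(f"unknown technique {technique!r}; expected one of {TECHNIQUES}")
        column = "anatomic" if technique == "native" else technique
        if graft is None:
            graft = "native_mpfl" if technique == "native" else "semitendinosus_graft"
        df = _load_csv("technique_lengths.csv")
        sub = df[df.technique == column]
        table = {float(r.angle_deg): (float(r.length_mm), str(r.note))
                 for r in sub.itertuples()}
        return cls(technique=technique, graft=graft, bundle_config="SB",
                   lengths={"single": table})

    @classmethod
    def from_clinical_case(cls, case_id: int) -> "ReconstructionSpec":
        df = _load_csv("clinical_lengths.csv")
        sub = df[df.case == case_id]
        if sub.empty:
            raise KeyError(f"unknown clinical case {case_id!r}; expected 1..5")
        graft = sub.graft.iloc[0]
        config = sub.bundle_config.iloc[0]
        lengths = {}
        for bundle, rows in sub.groupby("bundle"):
            lengths[str(bundle)] = {float(r.angle_deg): (float(r.length_mm), str(r.note))
                                    for r in rows.itertuples()}
        return cls(technique=str(sub.attachment.iloc[0]), graft=graft,
                   bundle_config=config, lengths=lengths)


def _norm_table(length_table) -> dict[str, dict[float, tuple[float, str | None]]]:
    """Accept a ReconstructionSpec, {angle: length} or {angle: (length, note)}."""
    if isinstance(length_table, ReconstructionSpec):
        return {b: {a: (v[0], v[1] or None) for a, v in t.items()}
                for b, t in length_table.lengths.items()}
    table = {}
    for angle, value in dict(length_table).items():
        if isinstance(value, (tuple, list)):
            table[float(angle)] = (float(value[0]), value[1] or None)
        else:
            table[float(angle)] = (float(value), None)
    return {"single": table}


def physiometric_check(length_table, reference_angle: float = REFERENCE_ANGLE_DEG) -> bool:
    """True iff the graft mimics the native MPFL: under tension at 0 and
    30 deg of flexion and slack at 60, 90 and 120 deg (every bundle)."""
    tables = _norm_table(length_table)
    for table in tables.values():
        ref = table[reference_angle][0]
        for angle in ANGLES_DEG:
            state = classify_tension(table[angle][0], ref, table[angle][1])
            tense = state is TensionState.PRETENSION and table[angle][0] > ref
            if angle <= 30.0 and not tense:
                return False
            if angle >= 60.0 and state is not TensionState.SLACK:
                return False
    return True


def isometric_check(length_table) -> bool:
    """True iff the insertion distance changes by less than 5 mm over the
    tabulated range of motion (every bundle)."""
    tables = _norm_table(length_table)
    for table in tables.values():
        values = [v[0] for v in table.values()]
        if max(values) - min(values) >= 5.0:
            return False
    return True


# -- attachment layout ----------------------------------------------------

def mpfl_elements(geometry: KneeGeometry, spec: ReconstructionSpec,
                  materials: MaterialTable) -> dict[str, LigamentElement]:
    """Place the graft bundles on the medial patellar rim and the medial
    epicondyle.  The printed per-angle insertion distances are the loading
    input; the placed points only set the direction of pull."""
    k = materials.stiffness(spec.graft)
    rp = geometry.params.patella_radius
    z_offsets = {"single": 0.0}
    if spec.bundle_config == "DB":
        dz = min(_DB_BUNDLE_HALF_SEPARATION_MM, 0.4 * geometry.params.patella_height)
        z_offsets = {"proximal": dz, "distal": -dz}
    femoral = np.array([geometry.params.femur_width / 2.0, 0.0, 0.0])
    out = {}
    for bundle in spec.bundles:
        z = z_offsets.get(bundle, 0.0)
        x = math.sqrt(max(rp**2 - z**2, 0.25 * rp**2))
        local = np.array([x, float(geometry.facet.surface_y(np.array([x]),
                                                            np.array([z]))[0]), z])
        out[bundle] = LigamentElement(
            name=f"mpfl_{bundle}", patellar_point=local, femoral_point=femoral,
            stiffness=k, tissue=spec.graft, bundle=bundle,
        )
    return out


def lr_element(geometry: KneeGeometry, materials: MaterialTable) -> LigamentElement:
    rp = geometry.params.patella_radius
    local = np.array([-rp, float(geometry.facet.surface_y(np.array([-rp]),
                                                          np.array([0.0]))[0]), 0.0])
    femoral = np.array([-geometry.params.femur_width / 2.0, 0.0, 0.0])
    return LigamentElement(name="lateral_retinaculum", patellar_point=local,
                           femoral_point=femoral,
                           stiffness=materials.stiffness("lateral_retinaculum"),
                           tissue="lateral_retinaculum")


# -- results --------------------------------------------------------------

@dataclass
class AngleResult:
    angle_deg: float
    pose: PatellaPose
    protocols: dict[str, TensionProtocol]
    relative: ContactField
    loaded: ContactField
    mpfl_stress_mpa: float
    lr_stress_mpa: float
    mpfl_force_n: float
    lr_force_n: float
    thermal_deltaT_c: float | None = None
    thermal_length_residual_mm: float | None = None

    @property
    def state(self) -> str:
        states = {p.state.value for p in self.protocols.values()}
        return "/".join(sorted(states))

    @property
    def peak_relative_mpa(self) -> float:
        return self.relative.peak()

    @property
    def peak_relative_medial_mpa(self) -> float:
        return self.relative.peak("medial")

    @property
    def peak_relative_lateral_mpa(self) -> float:
        return self.relative.peak("lateral")


@dataclass
class SimulationResult:
    knee: KneeParams
    spec: ReconstructionSpec
    settings: ContactSettings
    patellar_mat: CartilageMaterial
    femoral_mat: CartilageMaterial
    element_size: float
    baseline_pose: PatellaPose
    baseline: ContactField
    angles: list[AngleResult]
    config_hash: str

    def summary(self) -> pd.DataFrame:
        rows = []
        for a in self.angles:
            rows.append({
                "angle_deg": a.angle_deg,
                "state": a.state,
                "mpfl_stress_mpa": a.mpfl_stress_mpa,
                "lr_stress_mpa": a.lr_stress_mpa,
                "peak_relative_mpa": a.peak_relative_mpa,
                "peak_relative_medial_mpa": a.peak_relative_medial_mpa,
                "peak_relative_lateral_mpa": a.peak_relative_lateral_mpa,
                "mpfl_force_n": a.mpfl_force_n,
                "thermal_deltaT_c": a.thermal_deltaT_c,
                "residual_n": a.pose.residual_n,
            })
        return pd.DataFrame(rows)

    def angle(self, angle_deg: float) -> AngleResult:
        for a in self.angles:
            if a.angle_deg == angle_deg:
                return a
        raise KeyError(f"angle {angle_deg} not simulated")


@dataclass
class ClinicalReport:
    case_id: int
    result: SimulationResult
    physiometric: bool
    isometric: bool
    pressure_risk: bool
    risk_threshold_mpa: float = OA_PRESSURE_THRESHOLD_MPA


def _config_hash(knee: KneeParams, spec: ReconstructionSpec,
                 settings: ContactSettings, pmat: CartilageMaterial,
                 fmat: CartilageMaterial, element_size: float) -> str:
    payload = {
        "knee": knee.as_dict(),
        "technique": spec.technique,
        "graft": spec.graft,
        "bundle_config": spec.bundle_config,
        "lengths": {b: {str(a): v for a, v in t.items()} for b, t in spec.lengths.items()},
        "settings": asdict(settings),
        "patellar_mat": asdict(pmat),
        "femoral_mat": asdict(fmat),
        "element_size": element_size,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def run_case(
    knee: KneeParams,
    spec: ReconstructionSpec,
    settings: ContactSettings | None = None,
    patellar_mat: CartilageMaterial | None = None,
    femoral_mat: CartilageMaterial | None = None,
    element_size: float = 1.0,
    materials: MaterialTable | None = None,
    angles: Sequence[float] = ANGLES_DEG,
) -> SimulationResult:
    """Simulate one knee under one reconstruction across the flexion angles.

    Per angle: classify the tension state from the length table, apply the
    pretension force or the iterative thermal-shortening protocol, solve
    quasi-static equilibrium, subtract the stored baseline field and record
    facet pressure peaks and element stresses.
    """
    settings = settings or ContactSettings()
    materials = materials or MaterialTable()
    geometry = build_knee(knee, element_size=element_size,
                          patellar_thickness=(patellar_mat.thickness if patellar_mat else 3.0),
                          femoral_thickness=(femoral_mat.thickness if femoral_mat else 3.0))
    patellar_mat = patellar_mat or CartilageMaterial()
    femoral_mat = femoral_mat or CartilageMaterial()
    model = ContactModel(geometry, patellar_mat, femoral_mat, settings)
    base_pose, base_field = model.baseline()

    elements = mpfl_elements(geometry, spec, materials)
    lr = lr_element(geometry, materials)
    k_graft = materials.stiffness(spec.graft)
    k_lr = lr.stiffness

    results = []
    for angle in angles:
        prots = {b: next(p for p in spec.protocols(b) if p.angle_deg == angle)
                 for b in spec.bundles}
        states = {p.state for p in prots.values()}
        try:
            if states <= {TensionState.SLACK}:
                res = _slack_angle(angle, prots, base_pose, base_field)
            elif TensionState.THERMAL in states:
                res = _thermal_angle(angle, prots, spec, model, elements, lr,
                                     k_graft, k_lr, base_field, settings)
            else:
                res = _pretension_angle(angle, prots, model, elements, lr,
                                        k_graft, k_lr, base_field)
        except Exception as exc:
            raise type(exc)(f"at flexion angle {angle:g} deg: {exc}") from exc
        results.append(res)

    return SimulationResult(
        knee=knee, spec=spec, settings=settings, patellar_mat=patellar_mat,
        femoral_mat=femoral_mat, element_size=element_size,
        baseline_pose=base_pose, baseline=base_field, angles=results,
        config_hash=_config_hash(knee, spec, settings, patellar_mat,
                                 femoral_mat, element_size),
    )


def _slack_angle(angle, prots, base_pose, base_field) -> AngleResult:
    zero = relative_field(base_field, base_field)
    return AngleResult(angle_deg=angle, pose=base_pose, protocols=prots,
                       relative=zero, loaded=base_field,
                       mpfl_stress_mpa=0.0, lr_stress_mpa=0.0,
                       mpfl_force_n=0.0, lr_force_n=0.0)


def _pretension_angle(angle, prots, model, elements, lr, k_graft, k_lr,
                      base_field) -> AngleResult:
    base_t = model._baseline_pose.translation
    force = np.zeros(3)
    forces_n = []
    for bundle, prot in prots.items():
        if prot.state is not TensionState.PRETENSION:
            forces_n.append(0.0)
            continue
        f = k_graft * prot.pretension_force
        forces_n.append(f)
        force = force + f * elements[bundle].direction(base_t)
    # LR elongation follows the MPFL elongation (medial/lateral equilibrium)
    e_lr = float(np.mean([max(p.dl, 0.0) for p in prots.values()]))
    f_lr = k_lr * e_lr
    force = force + f_lr * lr.direction(base_t)
    pose, loaded = model.solve_equilibrium(applied_force=force)
    return AngleResult(
        angle_deg=angle, pose=pose, protocols=prots,
        relative=relative_field(loaded, base_field), loaded=loaded,
        mpfl_stress_mpa=max(ligament_stress(f) for f in forces_n),
        lr_stress_mpa=ligament_stress(f_lr),
        mpfl_force_n=max(forces_n), lr_force_n=f_lr,
    )


def _thermal_angle(angle, prots, spec, model, elements, lr, k_graft, k_lr,
                   base_field, settings) -> AngleResult:
    thermal = [b for b, p in prots.items() if p.state is TensionState.THERMAL]
    others = [b for b, p in prots.items()
              if p.state not in (TensionState.THERMAL, TensionState.SLACK)]
    if len(thermal) != 1 or others:
        raise NotImplementedError(
            "thermal shortening is supported for a single tense bundle "
            "(remaining bundles slack)"
        )
    bundle = thermal[0]
    prot = prots[bundle]
    element = elements[bundle]
    l0 = prot.reference_length
    alpha = MPFL_THERMAL_ALPHA
    state = {}

    # The measured lengths live on the CT scale while the element's geometric
    # length is set by the placed insertion points, so the protocol is mapped
    # onto the element by increments: the unloaded geometric length at the
    # baseline pose stands in for the 40 deg reference distance, the target
    # differs from it by dl, and a temperature drop contracts the rest length
    # by the absolute amount alpha*deltaT*l0 (the same millimetres either way).
    geo_ref = element.length(model._baseline_pose.translation)
    target = geo_ref + prot.dl

    def solve_at(deltaT: float):
        rest_geo = geo_ref - alpha * deltaT * l0
        tension = state.get("tension", 0.0)
        geo_len = geo_ref
        for _ in range(4):  # couple the small LR follow-up force
            e_mpfl = tension / k_graft
            f_lr = k_lr * e_mpfl
            pose, loaded = model.solve_equilibrium(
                applied_force=f_lr * lr.direction(model._baseline_pose.translation),
                springs=[(element, rest_geo)],
            )
            geo_len = element.length(pose.translation)
            new_tension = max(geo_len - rest_geo, 0.0) * k_graft
            if abs(new_tension - tension) < 1e-6:
                tension = new_tension
                break
            tension = new_tension
        state.update(tension=tension, pose=pose, loaded=loaded)
        return geo_len

    deltaT = iterate_thermal(solve_at, target, l0, alpha,
                             tol=settings.thermal_tol_mm)
    tension = state["tension"]
    pose, loaded = state["pose"], state["loaded"]
    prot.thermal_deltaT_c = deltaT
    realized_dl = alpha * deltaT * l0
    prot.alpha_lr = lr_alpha(realized_dl, deltaT, l0) if deltaT else 0.0
    f_lr = k_lr * tension / k_graft
    return AngleResult(
        angle_deg=angle, pose=pose, protocols=prots,
        relative=relative_field(loaded, base_field), loaded=loaded,
        mpfl_stress_mpa=ligament_stress(tension),
        lr_stress_mpa=ligament_stress(f_lr),
        mpfl_force_n=tension, lr_force_n=f_lr,
        thermal_deltaT_c=deltaT,
        thermal_length_residual_mm=abs(element.length(pose.translation) - target),
    )


SWEEPABLE = ("friction", "patellar_thickness", "femoral_thickness")


def sweep(parameter: str, values: Sequence[float], knee: KneeParams,
          spec: ReconstructionSpec, settings: ContactSettings | None = None,
          angles: Sequence[float] = ANGLES_DEG,
          element_size: float = 1.0) -> tuple[list[SimulationResult], pd.DataFrame]:
    """One simulation per parameter value, all else fixed; returns the
    results and a tidy comparison table."""
    from .params import PARAM_NAMES

    if parameter not in SWEEPABLE and parameter not in PARAM_NAMES:
        raise KeyError(f"cannot sweep {parameter!r}")
    settings = settings or ContactSettings()
    results, rows = [], []
    for v in values:
        knee_v, settings_v = knee, settings
        pmat = fmat = None
        if parameter == "friction":
            settings_v = ContactSettings(friction=float(v),
                                         adjustment=settings.adjustment,
                                         approach=settings.approach,
                                         residual_tol_n=settings.residual_tol_n,
                                         thermal_tol_mm=settings.thermal_tol_mm)
        elif parameter == "patellar_thickness":
            pmat = CartilageMaterial(thickness=float(v))
        elif parameter == "femoral_thickness":
            fmat = CartilageMaterial(thickness=float(v))
        else:
            knee_v = KneeParams(**{**knee.as_dict(), parameter: float(v)})
        res = run_case(knee_v, spec, settings_v, patellar_mat=pmat,
                       femoral_mat=fmat, angles=angles, element_size=element_size)
        results.append(res)
        for a in res.angles:
            rows.append({"parameter": parameter, "value": v,
                         "angle_deg": a.angle_deg,
                         "peak_pressure_mpa": a.loaded.peak(),
                         "peak_relative_mpa": a.peak_relative_mpa,
                         "mpfl_stress_mpa": a.mpfl_stress_mpa})
    return results, pd.DataFrame(rows)


def clinical_report(case_id: int, settings: ContactSettings | None = None,
                    element_size: float = 1.0,
                    angles: Sequence[float] = ANGLES_DEG) -> ClinicalReport:
    """Simulate one clinical case: patient geometry + measured graft lengths."""
    knee = load_case(case_id)
    spec = ReconstructionSpec.from_clinical_case(case_id)
    result = run_case(knee, spec, settings, angles=angles, element_size=element_size)
    peak = max(a.peak_relative_mpa for a in result.angles)
    return ClinicalReport(
        case_id=case_id, result=result,
        physiometric=physiometric_check(spec),
        isometric=isometric_check(spec),
        pressure_risk=bool(peak > OA_PRESSURE_THRESHOLD_MPA),
    )
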