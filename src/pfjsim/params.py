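"""Knee geometry parameters: the 12 scalars that define one parametric knee.

The patellofemoral joint is described by nine femoral measurements (epicondylar
widths/lengths at three proximodistal levels, the medial/lateral condylar radii
and the posterior radius that governs the articular contact region) and three
patellar measurements (radius, articular curvature radius, height).  All values
are millimetres.  The module also ships the population statistics (mean +/- SD
measured on a 24-knee instability cohort) and five patient-specific parameter
sets, and can sample synthetic knees from the population statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "KneeParams",
    "ParameterError",
    "PARAM_NAMES",
    "population_stats",
    "load_case",
    "sample_knee",
]


class ParameterError(ValueError):
    """Raised when a knee parameter set violates its invariants."""


PARAM_NAMES = (
    "femur_width",
    "femur_width2",
    "femur_width3",
    "femur_length",
    "femur_length2",
    "femur_length3",
    "medial_radius",
    "lateral_radius",
    "posterior_radius",
    "patella_radius",
    "patella_curvature_radius",
    "patella_height",
)


@dataclass(frozen=True)
class KneeParams:
    """The 12 geometric scalars (mm) defining one knee.

    Invariants: all strictly positive; the femoral widths and lengths are
    strictly ordered (level 1 > level 2 > level 3, distal to proximal); the
    patellar articular curvature radius exceeds the patellar radius so the
    articular face is a shallow concave dish.
    """

    femur_width: float
    femur_width2: float
    femur_width3: float
    femur_length: float
    femur_length2: float
    femur_length3: float
    medial_radius: float
    lateral_radius: float
    posterior_radius: float
    patella_radius: float
    patella_curvature_radius: float
    patella_height: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{f.name} must be strictly positive, got {v!r}")
        if not (self.femur_width > self.femur_width2 > self.femur_width3):
            raise ParameterError("femoral widths must satisfy width > width2 > width3")
        if not (self.femur_length > self.femur_length2 > self.femur_length3):
            raise ParameterError("femoral lengths must satisfy length > length2 > length3")
        if not (self.patella_curvature_radius > self.patella_radius):
            raise ParameterError("patella_curvature_radius must exceed patella_radius")

    def scaled(self, s: float) -> "KneeParams":
        """Return a copy with every length multiplied by ``s``."""
        if s <= 0:
            raise ParameterError("scale factor must be positive")
        return KneeParams(**{k: v * s for k, v in asdict(self).items()})

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("pfjsim.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def population_stats() -> pd.DataFrame:
    """Cohort mean and SD (mm) per parameter, indexed by parameter name."""
    df = _read_csv("geometry_population.csv").set_index("parameter")
    return df


def load_case(case_id: int | str) -> KneeParams:
    """Return a printed parameter set: ``"mean"`` or patient case ``1..5``."""
    if case_id == "mean":
        stats_df = population_stats()
        return KneeParams(**{p: float(stats_df.loc[p, "mean_mm"]) for p in PARAM_NAMES})
    try:
        idx = int(case_id)
    except (TypeError, ValueError):
        raise KeyError(f"unknown case id {case_id!r}; expected 'mean' or 1..5") from None
    col = f"case{idx}"
    cases = _read_csv("geometry_cases.csv").set_index("parameter")
    if col not in cases.columns:
        raise KeyError(f"unknown case id {case_id!r}; expected 'mean' or 1..5")
    return KneeParams(**{p: float(cases.loc[p, col]) for p in PARAM_NAMES})


def sample_knee(
    stats_table: Mapping[str, tuple[float, float]] | pd.DataFrame | None = None,
    seed: int | np.random.Generator | None = None,
    max_tries: int = 1000,
) -> KneeParams:
    """Draw one synthetic knee from per-parameter mean +/- SD statistics.

    Each parameter is a normal draw truncated at mean +/- 3 SD and at zero.
    Ordering invariants are enforced hierarchically: the leading parameter
    of each ordered chain (femur_width, femur_length, patella_radius) keeps
    its exact truncated-normal marginal, and each subordinate parameter is
    additionally truncated by its predecessor (width2 < width, width3 <
    width2, curvature_radius > radius, ...).  The rare draw for which a
    subordinate truncation interval is empty is rejected and retried, so
    the returned set is always a valid :class:`KneeParams`.
    ``stats_table`` defaults to the packaged cohort statistics.
    """
    if stats_table is None:
        stats_table = population_stats()
    if isinstance(stats_table, pd.DataFrame):
        table = {p: (float(stats_table.loc[p, "mean_mm"]), float(stats_table.loc[p, "sd_mm"]))
                 for p in PARAM_NAMES}
    else:
        table = {p: (float(stats_table[p][0]), float(stats_table[p][1])) for p in PARAM_NAMES}
    for mu, sd in table.values():
        if sd < 0:
            raise ParameterError("standard deviations must be >= 0")

    # (parameter, upper-bounded by, lower-bounded by)
    plan = [
        ("femur_width", None, None),
        ("femur_width2", "femur_width", None),
        ("femur_width3", "femur_width2", None),
        ("femur_length", None, None),
        ("femur_length2", "femur_length", None),
        ("femur_length3", "femur_length2", None),
        ("medial_radius", None, None),
        ("lateral_radius", None, None),
        ("posterior_radius", None, None),
        ("patella_radius", None, None),
        ("patella_curvature_radius", None, "patella_radius"),
        ("patella_height", None, None),
    ]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = 1e-6
    for _ in range(max_tries):
        draw: dict[str, float] = {}
        ok = True
        for name, upper, lower in plan:
            mu, sd = table[name]
            lo = max(mu - 3 * sd, 0.0)
            hi = mu + 3 * sd
            if upper is not None:
                hi = min(hi, draw[upper] - eps)
            if lower is not None:
                lo = max(lo, draw[lower] + eps)
            if sd == 0:
                value = mu
                if not (lo - eps <= value <= hi + eps):
                    ok = False
                    break
            else:
                if lo >= hi:
                    ok = False
                    break
                # inverse-CDF truncated-normal draw
                ca = ndtr((lo - mu) / sd)
                cb = ndtr((hi - mu) / sd)
                u = rng.uniform(ca, cb)
                value = float(mu + sd * ndtri(u))
                value = min(max(value, lo), hi)
            draw[name] = value
        if not ok:
            continue
        try:
            return KneeParams(**draw)
        except ParameterError:
            continue
    raise ParameterError(f"could not draw an ordered parameter set in {max_tries} tries")
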