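# Methods

This note documents the model behind `pfjsim`: what is computed, which
choices were genuinely open, what the defaults mean, and what the model does
*not* capture.

## Coordinate convention and units

Femur-fixed right-handed frame: **x** lateral→medial along the epicondylar
axis, **y** posterior→anterior, **z** distal→proximal. Units are fixed
package-wide: mm, N, MPa, °C. Knee flexion is not a geometric rotation in
the solver — it enters exclusively through the per-angle graft length tables
(see *Flexion handling*).

## Parametric geometry

Twelve scalars define a knee (`KneeParams`). The femoral articular contact
region is a surface of revolution about the epicondylar axis with transverse
profile

    ρ(x) = ρ₀ + tan γ · (√(x² + s²) − s),

a V-groove with a rounded floor: ρ₀ is the groove-floor radius (posterior
radius + cartilage thickness for the cartilage surface), γ = 21° is the
facet inclination corresponding to a 138° sulcus angle (the standard
textbook trochlear value), and s = 0.3 · posterior_radius smooths the floor.
Because the contact region is a revolution, the seated contact configuration
is identical at every station along the groove — the geometric fact the
flexion handling relies on. Condyles and the epicondyle taper (medial and
lateral radii, widths 2/3, breadth = femur width) extend the exported bone
surface but do not participate in contact. The anteroposterior length
parameters validate, sample and scale with the knee; the printed
construction gives no loft sections for them, so they do not shape the
articular revolution, whose geometry is governed by the posterior radius.

The patellar articular face is a concave revolution surface about an axis
parallel to the epicondylar axis: sagittally concave with the printed
curvature radius (so the face hugs the trochlea through flexion), and
transversely **congruent with the groove profile** — the median ridge and
both facets seat in the sulcus. Congruence is the deliberate closure of an
under-determined construction: the patella is aligned with the trochlear
groove by definition of the model, and a congruent fit is what gives the
broad two-facet contact patch and the firm mediolateral seating that any
wedge-type patellofemoral model needs. (A non-congruent concave face in a
V-groove necessarily contacts at its rim — a meshing artifact, not
mechanics.) Revolution cuts trim the solid to width 2·patella_radius and
the printed height.

Cartilage layers are uniform 3 mm by default (CT cannot resolve cartilage;
the observed joint gap supports ≈3 mm per side). Subchondral bone surfaces
are exact normal offsets of the cartilage surfaces; the offset invariant
(|distance − thickness| < 0.05 mm at every node) is enforced by test using
an exact point-to-triangle distance oracle. Surfaces are meshed at 1 mm
nominal edge length. The foundation closure integrates the through-thickness
response in closed form, which at 1 mm elements is equivalent to at least
three uniform layers across the 3 mm thickness
(`geometry.through_thickness_layers`).

## Synthetic knees

`sample_knee` draws each parameter from a normal truncated at mean ± 3 SD
and at zero, using the cohort statistics shipped with the package. The
ordering invariants (width > width2 > width3, length chain, curvature radius
> patellar radius) are enforced **hierarchically**: the leading parameter of
each chain keeps its exact truncated-normal marginal and each subordinate
parameter is additionally truncated by its predecessor. Plain joint
rejection would bias the leading marginals (≈ +1 mm on femur width);
hierarchical truncation keeps them unbiased, which is what the
law-of-large-numbers test checks. The generator emulates anatomical
variability only — it does not model measurement error, left/right
asymmetry, or correlations between parameters beyond the ordering
constraints, so passing tests say nothing about those aspects of real data.

## Cartilage contact

Contact uses the linear elastic-foundation (confined-compression/Winkler)
closure: nodal pressure

    p = (1−ν) E / [(1+ν)(1−2ν) t] · max(d, 0)

with E = 10 MPa, ν = 0.45, and the two 3 mm layers acting in series (summed
compliance, i.e. t = 6 mm at the defaults). Penetration d of each patellar
cartilage node into the femoral cartilage surface is the **true normal
distance**, obtained by Newton projection onto the revolution profile; this
matters because it makes the integrated contact force the exact gradient of
the foundation energy (the energy-stationarity property is tested by finite
differences). The foundation model replaces the deformable hexahedral
cartilage of a full finite-element treatment: identical constitutive inputs,
deterministic and fast, but **local** — it has no shear coupling between
neighbouring nodes, and therefore concentrates pressure more than an FE
continuum does. This is the main reason relative pressure peaks are checked
against reference values only within a factor-2 band, while element
stresses (which do not depend on the contact closure under the pretension
protocol) are checked at ±20%.

"Contact adjustment" (0.1 mm) is implemented as an initial-gap snap: the
patella is seated until its closest point is within 0.1 mm of the
counter-surface, which counts as just-touching. The baseline field is then
produced by a 0.5 mm perpendicular approach displacement, stored, and
subtracted nodewise from every loaded field ("relative pressure"). Relative
fields are signed; peaks are maxima of the signed difference, reported per
facet (medial/lateral, split at the groove plane).

Friction (μ = 0.02, penalty formulation in the reference treatment) enters
the quasi-static foundation closure only as a dissipative bound on the
reported tangential load, μ·∫p dA; it cannot alter the normal solution.
This single-step quasi-static reading is consistent with the observed
insensitivity of peak pressure to μ ∈ {0.01…0.03}, and the sweep reproduces
that insensitivity trivially (spread 0).

## Patellar degrees of freedom

After the approach, the quadriceps and patellar tendons are fixed and carry
no applied force; they act as the tie that holds the patella. Mechanically
a tie of six splayed inextensible struts locks all translations; the model
resolves this as: superior–inferior **and** anteroposterior translation
locked at the approached pose, mediolateral glide free. Freeing the
anteroposterior component instead would let the patella float anteriorly
until the contact force equalled the small posterior component of the
ligament pull, destroying the stored baseline that the relative-pressure
subtraction is defined against — so the lock is the only reading consistent
with baseline subtraction. Rotations are held at the groove-aligned
alignment. The force-balance tolerance (< 0.01 N) applies to the free
degrees of freedom; locked components are constraint reactions. Equilibrium
is found by L-BFGS energy minimisation with an analytic gradient, polished
by damped Newton steps on the residual.

## Tension protocols

The strain-free reference is the 40° insertion distance. Per angle and per
bundle:

* **Slack** (Δl < 0): no load, no solve needed; stresses are exactly zero.
* **Pretension** (Δl ≥ 0): a constant force Δl·K applied along the
  insertion line (the protocol of the reference treatment). The reported
  graft stress is then Δl·K/(πr²) — identical to the fixed-geometry oracle
  to machine precision, which is the designed behaviour, and independent of
  the contact closure. Δl = 0 is classified as pretension with zero force;
  this boundary convention follows the one published length table that
  marks its reference cell as tensioned.
* **Thermal shortening** (hint-marked cells): the element rest length is
  contracted by α·ΔT·l₀ (α = 5·10⁻⁴ °C⁻¹) and ΔT is iterated (bracketing +
  Brent) until the achieved insertion distance matches the target within
  0.01 mm. The measured lengths live on the CT scale while the element's
  geometric length is set by the placed insertion points, so the protocol
  maps onto the element by increments: the unloaded geometric length at the
  baseline pose stands in for the reference distance and the target differs
  from it by Δl. The LR dilatation coefficient α_LR = Δl/(ΔT·l₀_LR) is
  reported so the single model temperature drop reproduces the same length
  change on the LR.

The slack/pretension footnote classification is purely geometric (sign of
Δl); thermal cells cannot be detected geometrically (they require knowing
the target is reachable only by compressing cartilage), so table footnotes
override the rule, and any disagreement is logged rather than raised. One
published contradiction (thermal footnotes on cells *shorter* than the
reference, where the prose says "further") is resolved in favour of the
footnotes.

The lateral retinaculum is assumed to undergo the same length change as the
MPFL (medial/lateral equilibrium assumption), so its tension is always
K_LR · (MPFL elongation); for double-bundle grafts the mean positive bundle
elongation is used. Each bundle of a double-bundle graft carries the full
tabulated graft stiffness and its own length column; the two patellar
points are separated proximodistally by 10 mm. (Bundle stiffness was a
genuinely open choice; the full-K reading is the one that reproduces the
published double-bundle clinical stresses, e.g. 64.6 vs 60.02 MPa at full
extension for the anatomic double-bundle case, where a K/2 split would give
half that.)

## Flexion handling

Flexion is driven kinematically by the measured per-angle insertion
distances (dynamic-CT data printed with the study), not by a muscle-driven
knee model. Because the femoral contact region is a revolution about the
epicondylar axis, the seated contact configuration is the same at every
groove station; the solver therefore uses one seated configuration for all
angles, and angles differ only in their tension protocol. The native knee
uses the anatomic insertion-length column with the native MPFL stiffness
(12 N/mm): the anatomic femoral point is by definition the native footprint.
The malposition of a non-anatomic femoral point is expressed entirely
through its length table, which is the quantity the mechanics consumes; the
placed insertion points only set the direction of pull.

## Numerical choices

| Quantity | Default | Note |
|---|---|---|
| element size | 1 mm | mesh convergence convention of the reference model |
| cartilage E, ν, t | 10 MPa, 0.45, 3 mm | per side; layers act in series |
| equilibrium residual | 0.01 N | on free DOFs; typically converges to ≪10⁻⁶ N |
| thermal length tolerance | 0.01 mm | Brent on ΔT, bracketed by doubling |
| contact adjustment | 0.1 mm | just-touch snap distance |
| approach | 0.5 mm | perpendicular, along −y |
| beam radius | 1 mm | stress = force/(πr²) |
| sulcus angle / smoothing | 138° / 0.3·posterior radius | frozen recipe constants |
| OA pressure flag | 3.42 MPa | reporting flag only, extrapolated from tibiofemoral data |

Degenerate inputs: zero approach with no tense element raises an
indeterminate-equilibrium error; ν = 0.5 is rejected as singular; unknown
tissues, cases, techniques and config keys raise immediately. Ties at the
medial/lateral split assign x = 0 nodes to the medial facet. All
simulations are deterministic: identical configuration gives bit-identical
summaries (hashes included in reports).

## Scope and limitations

* The contact closure is a local foundation; absolute pressure levels
  inherit its peak-concentration bias (hence the factor-2 acceptance band).
* Rotational patellar DOFs (tilt, spin) are frozen; patellar tilt under
  asymmetric load is not predicted.
* Tendons are load paths only; no muscle forces, no dynamic effects, no
  viscoelasticity, toe-region nonlinearity, graft remodelling or
  bone-tunnel mechanics.
* Trochlear dysplasia is representable only through the printed scalars
  (e.g. a large posterior radius flattens the groove); there is no separate
  dysplasia shape parameter.
* The 3.42 MPa risk threshold is extrapolated from tibiofemoral
  osteoarthritis data and is deliberately a reporting flag, never a
  pass/fail criterion; patellar cartilage is thicker and its true threshold
  is plausibly higher.
* Simulation sizes: the default 1 mm meshes give ≈860 patellar and ≈1700
  femoral cartilage nodes; a full five-angle technique run, including the
  thermal iterations, solves in under a second, and the whole test suite in
  well under a minute.
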