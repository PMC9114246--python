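# Methods

## Scope and model

The package performs desk-scale design of ungassed, baffled, stirred-tank
fermenters. Its physical core is the turbulent power-draw law
P = n·Po·ρ·N³·D⁵, with the power number Po constant above Re = ρND²/μ = 10⁴
and Po = K_L/Re in creeping flow (Re < 10). Everything else is bookkeeping
layered on that law: specific power with an explicit working/total volume
basis, the mean dissipation rate ε = P/(ρV_w), the Kolmogorov microscale
λ_k = (ν³/ε)^¼ used as a shear screen, shaft torque, and two empirical
scale-up exponents. No gassed-power correction, non-Newtonian rheology,
mass transfer or thermal design is modelled — the target processes are
anaerobic and essentially Newtonian at the measured viscosities.

Multi-stage agitators are assumed to dissipate the sum of single-impeller
powers, which holds for adequately spaced stages; closely spaced stages
would draw less, so reported powers are conservative.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| turbulent Po (RTB/CBT/PBT/LA310/LA315/MP) | 5 / 4.4 / 1.64 / 0.3 / 0.75 / 0.34 | — | standard chart plateaus for baffled tanks |
| laminar K_L | 64 (radial), 40–45 (axial) | — | textbook creeping-flow constants; configurable, rarely exercised here |
| regime thresholds | Re 10 and 10⁴ | — | conventional bounds for agitated vessels |
| scale-up exponents α, β, γ | 0.37, 0.21, 5/3 | — | α from cross-plant practice; β and γ follow from holding P/V and the power law simultaneously |
| stage-count tolerance τ | 0.1 | — | opens the (Z−D)/D upper bound; admits fits a few % over the strict limit, which matches built vessels |
| P/V selection band | 2–4 | kW m⁻³ (total volume) | industrial rule of thumb; relative window tolerance 0.1 keeps near-misses (e.g. 4.3) on the table |
| motor correction | 1.5 | — | motor + bearing + gearbox losses |
| motor ladder | 75…1400 | kW | IEC-like frame steps; user-overridable |
| batch hours | 20 | h | one operating day charged per batch |
| functional unit volume | working volume | m³ | substrate processed per batch |

Torque is exposed in two modes. `physical` is P/(2πN). `hp_kw` reproduces
the horsepower-formula variant found in vendor sizing sheets,
(P[kW]·63025/rpm)·0.112985, which is exactly 0.74570× the physical value —
the 745.7 W-per-hp factor surviving a kW-fed imperial unit chain. The
physical mode is the default; the vendor mode exists so that design tables
quoted in that convention can be reproduced bit-for-bit.

## The bundled case study

The packaged config encodes a whey-permeate lactic acid fermentation at
three scales (0.003 / 0.1 / 207 m³ working volume; the industrial vessel
holds 300 m³ total). Impeller diameters are nowhere reported for these
vessels; they are anchored by inverting Re = ρND²/μ at the reported
Reynolds numbers and the nominal 3.333 s⁻¹ speed, which lands all three on
D/T ≈ 0.45, consistent with the reported diameter ratio. The inversion
happens at config load — no diameter is hard-coded — and each derived field
carries a provenance note.

Two conventions in the case study deserve flagging:

* **Laboratory power number.** The lab vessel runs at Re ≈ 1.8×10³,
  in the transition regime where Po sits below the turbulent plateau. The
  fixture stores a chart-read effective Po of 4.55, the midpoint of the
  narrow interval (4.53–4.57) consistent with both the reported power draw
  (0.257 W) and dissipation rate (0.080 W kg⁻¹), which round differently.
* **Industrial working height.** Strict similarity to the bench scale gives
  Z ≈ 6 m — only 52% occupancy of the 11.47 m column, below the customary
  80%. The study therefore also carries a tall variant using the pilot's
  similarity ratio at reporting precision (0.81 × 11.47 = 9.29 m); the
  package exposes both (`industrial` and `industrial_tall`), and the stage
  count rule yields two and three stages respectively. The unrounded pilot
  ratio is 0.820; the 0.81 convention is stored explicitly in the config as
  `alt_similarity_ratio` rather than recomputed, because the tall variant
  is defined by that reported ratio.

One reference figure is knowingly reinterpreted: the industrial dissipation
rate is tabulated in the source data as 0.042 W kg⁻¹, but the same sheet's
power (9425 W into 1060 kg m⁻³ × 207 m³) and microscale (245.1 µm) both
imply 0.0429. The replication anchors 0.0429, treating 0.042 as a truncated
print. Similarly, design-table cells at 0.29 s⁻¹/17 rpm mix two speed
roundings and are internally inconsistent by 1–5%; they are computed but
not anchored. The reported 1.2 MW installed motor for the tall variant is
not reproducible from 1.5× any tabulated power under a consistent rounding
and is asserted nowhere; the 0.9 MW case follows from the
(P/V_t)·V_w sizing convention, which the package adopts.

## Scenario sweep geometry

The working-height/slenderness sweep holds the vessel's total height H
fixed; each H/T point rescales the tank diameter as T = H/(H/T) and the
impeller diameter proportionally (constant D/T) *relative to the anchored
baseline*, so the case's own H/T reproduces the Reynolds-anchored diameter
exactly. At each point the feasible stage counts are enumerated and the
specific power aggregated across them (arithmetic mean by default — both
counts are equally buildable — with min/max selectable). The aggregate is
therefore piecewise constant in Z, stepping only where the feasible set
changes, and decreases monotonically in H/T.

## LCA assumptions

The LCA is gate-to-gate and single-flow: agitation electricity only, per
1 m³ of substrate processed, at 20 h of operation per batch and a substrate
volume equal to the working volume (both configurable and both assumptions,
not measurements). Characterization factors (kg category-equivalent per
kWh, CML 2001 midpoints) are user configuration — they depend on the grid
mix and database vintage and ship with no defaults. Consequently only
proportionality statements are meaningful package-wide: impacts are exactly
linear in energy, and rankings are factor-independent. No absolute impact
value is asserted anywhere in the test suite.

## Synthetic scenarios

The random-case generator samples near-water broths (ρ 950–1200 kg m⁻³,
μ 1–20 mPa·s), log-uniform working volumes over 10⁻³–10³ m³, conventional
ratios (D/T 0.3–0.5, Z/T 1–3, H/T 1.5–3.5) and speeds 0.2–5 s⁻¹, building
each vessel as a cylinder at the sampled aspect ratio. It emulates the
*parameter ranges* of real designs, not real data: broths are Newtonian,
vessels ideal cylinders, and no fermentation kinetics exist. Passing
property tests on these cases demonstrates algebraic correctness
(homogeneity, transitivity, invariance), not predictive accuracy for any
particular broth. The generator feeds property tests only; the case-study
replication never uses it.

## Numerical notes

* All replication checks are relative-error comparisons; the default
  per-cell tolerance is 1%, which absorbs the reference sheet's own
  rounding (independent cells there disagree with each other by up to
  ~0.8%). Pure-ratio cells (3-stage/2-stage = 1.5) are checked to float
  precision.
* Exponentiation uses plain floating point; the quantities span ~10 orders
  of magnitude without conditioning issues.
* Degenerate inputs fail loudly: non-positive physical quantities raise
  `ValueError` before any arithmetic; a liquid column shorter than one
  impeller diameter is an error in the count rule and a recorded gap in the
  sweep; an empty feasible count set with zero tolerance is an error with
  the offending bounds in the message.
* Everything is deterministic given inputs and seeds; CLI outputs are
  byte-identical across runs.

## Problem sizes

The whole analysis is closed-form arithmetic on a handful of cases: the
full replication (three scales, a 6×4×2 design matrix, selection, sweep)
runs in well under a second, and the property suite draws a few hundred
random cases. These sizes are the method's natural scale, not a truncation
of anything larger.
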