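# Methods

## Model

Blood flow in each arterial segment is described by the 1D cross-section
averaged mass and momentum balance for a Newtonian fluid,

    ∂A/∂t + ∂Q/∂z = 0
    ∂Q/∂t + ∂/∂z(α Q²/A) + (A/ρ) ∂P/∂z = −2(γᵥ+2)π μ Q/(ρA)

with lumen area A, volumetric flow Q, blood density ρ and viscosity μ,
Coriolis coefficient α and velocity-profile exponent γᵥ (γᵥ = 2 recovers
Poiseuille friction, −8πμQ/(ρA)). The wall is elastic with the algebraic
tube law

    P(A) = Pext + β(√(A/A₀) − 1),   β = √(π/A₀) · E h₀ / (1 − ν²)

(reference area A₀ = πr₀², wall thickness h₀, Young's modulus E, Poisson
ratio ν), giving the pulse wave speed c(A) = √(β/(2ρ√A₀)) · A^¼.

A note on the friction term: the literal source "−2μ(γᵥ+2)Q/A" that
sometimes appears in print is dimensionally inconsistent with the rest of
the momentum equation; the implementation uses the standard form
−2(γᵥ+2)πμQ/(ρA), which reduces exactly to Poiseuille for γᵥ = 2 and is
verified against the closed-form series-resistance oracle in the tests.

Terminal vessels couple to three-element Windkessel beds (R1–C–R2 with
outflow pressure Pout): `dPc/dt = (Q − (Pc − Pout)/R2)/C`, interface
pressure `P = Pc + R1·Q`. By default R1 matches the terminal vessel's
characteristic impedance ρc₀/A₀ to suppress artificial reflections
(falling back to 0.05·PVR if the impedance exceeds the total); the renal
beds instead use a fixed R1 fraction (see *Baseline reconstruction*).

## Numerics

Explicit MUSCL–Hancock finite volumes: minmod-limited reconstruction of
(P, u), a half-step predictor, HLL fluxes, semi-implicit friction, and
Newton solves for every boundary coupling (prescribed inflow; junctions
enforcing mass conservation, total-pressure continuity and outgoing
Riemann-invariant invariance, residuals < 1e-10; Windkessel outlets).
The pressure-gradient flux is written conservatively with a geometric
source discretised from the same face-geometry antiderivative, which makes
the rest state (A = A₀(z), Q = 0) an exact fixed point for tapered vessels
— the zero-inflow test asserts bit-exact zeros.

Defaults: target cell 7.5 mm with ≥ 3 cells/vessel (grid convergence:
halving the cell size moves brachial SBP by < 1%), CFL 0.9 under a global
time step re-planned each cycle with a safety margin, 200 probe samples
per cycle, convergence when consecutive-cycle probe pressure waveforms
agree to 1% in max-norm (≤ 50 cycles; typically 5 from the warm start:
uniform pressure at the estimated mean arterial pressure with matched
Windkessel charge). ρ = 1060 kg/m³, μ = 4 mPa·s, γᵥ = 2, α = 1 (α = 1
keeps the symmetric-junction total-pressure coupling exact), ν = 0.5,
heart rate fixed at 70 min⁻¹ (cardiac-output variation acts through the
waveform amplitude). One 113-vessel simulation takes ≈ 1–2 s
(numba-compiled kernels; first call pays ~30 s of compilation).

## Baseline network reconstruction

The full per-vessel parameterization of the original 113-vessel model is
unpublished (supplementary material); the packaged fixture reconstructs
it. Everything that is printed is honoured exactly: the counts (113
vessels, 38 renal vessels per side, 5 segmental per side), the named
radii/thicknesses/moduli (ascending aorta 15.95 mm, abdominal aorta
7.49 mm, carotid 3.17 mm / 0.70 mm, radial 1.38 mm, main renal 2.71 mm /
0.54 mm, descending aorta 2.12 mm, E ∈ [400, 500] kPa), the bed parameter
ranges (PVR ∈ [0.11, 17.20]·10¹⁰ Pa·s/m³, PVC ∈ [0.02, 2.60]·10⁻¹⁰ m³/Pa),
cardiac output 5.74 l/min. The systemic tree follows the classic
37-artery benchmark topology; the renal trees branch 1 main → 5 segmental
(pentafurcation) → interlobar bifurcations with Murray-law radii
(r_p³ = Σ r_c³) and h = 0.2 r. The printed outlet count (49) cannot
coexist with the printed vessel counts in a strict tree; the fixture has
60 outlets, recorded in its metadata.

The remaining free parameters were calibrated once against the printed
*healthy* outputs only, then frozen:

- bed resistances from target resting bed flows at MAP 93 mmHg (minus the
  upstream Poiseuille path resistance), summing to CO = 5.74 l/min with
  533 ml/min per kidney;
- systemic bed compliances from a 1.6 s bed time constant, capped at the
  printed PVC maximum; unprinted aortic wall thicknesses and the
  inlet-template systolic fraction (0.38) adjusted toward brachial
  120/74 mmHg (achieved 124/66 — the pulse pressure stays somewhat wide,
  a known consequence of purely elastic walls);
- the renal beds' (R1 fraction, time constant) = (0.30, 0.30 s), pinned
  jointly on the two published healthy RI anchors (segmental RI 0.63 at
  20–29 and 0.67 at 70–79). With R1 at the characteristic impedance no
  time constant satisfies both anchors simultaneously.

Disease-stage targets were never used in this calibration; the stage
populations follow from the published calibrated multipliers as printed.

## Virtual populations

Healthy subjects scale the baseline by normalised Gaussian factors per
age group: one cardiac-output draw per subject; independent draws per
vessel for length, radius, E and h; independent draws per outlet for PVR
and PVC; truncated to (0, mean + 4 SD] by rejection (negligible mass at
the published coefficients of variation). Each subject is reproducible
from (population seed, subject index) via `numpy` `SeedSequence`.

Disease stages multiply a *healthy* subject's factors by fixed calibrated
point values (severe stages start from healthy, not from the early
stage); all aortic segments share the printed aortic trend, and the
literature mean (SD) columns are carried as metadata only. The
physiology filter keeps a subject iff simulated brachial SBP and DBP both
lie within 2.575 SD of the age-group reference means; it is idempotent
and order-independent. Subjects whose simulation fails or does not reach
periodicity are excluded and counted separately from the filter.

What the generator does *not* emulate: sex-specific or anthropometric
covariates, parameter correlations (independence is the published
assumption), combined diabetes + hypertension, and the unpublished
per-vessel geometry variation of the original supplementary material. A
green population test therefore establishes correct sampling of the
published distributions and correct plumbing — not that the reconstructed
network is the original one.

## Biomarkers

RI per segmental probe uses V_PSV = cycle peak velocity and V_EDV = the
minimum over the final third of the cycle (robust to the early-diastolic
reverse-flow notch; the naive cycle minimum is available as an option);
the subject's RI is the arithmetic mean over the ten segmental sites, and
per-side values are reported as well. Mean RBF is the cycle-averaged flow
at the main renal artery midpoint, per kidney, in ml/min; brachial
SBP/DBP are cycle extrema at the brachial midpoint in mmHg.

## Analysis layer

Sobol indices use the Saltelli design on scrambled Sobol' sequences with
the Saltelli-2010 first-order and Jansen total-order estimators and
bootstrap percentile CIs; they are validated on the additive-linear and
Ishigami benchmarks. Screening of the hemodynamic model runs on a reduced
single-kidney network (aorta stub + one renal tree + lumped body bed,
~6× cheaper per run). The ROC scan uses every observed score as a
threshold, auto-orients so AUC ≥ 0.5 (the orientation is reported; RBF
classifies DN below, RI above the cut-off), computes AUC by trapezoid
(verified exactly equal to the pairwise-concordance estimator) and takes
the cut-off at maximal Youden J with ties broken toward higher
sensitivity. Summaries use population SD, linear-interpolation (type-7)
quartiles and the 1.5·IQR outlier rule. Stage calibration is a cyclic
golden-section search over the three renal tunables (radius, bed PVR, bed
PVC — the most RI-sensitive factors) within ±20% of their table values,
stopping when the population mean RI is within 5% of target or the
evaluation budget is exhausted (flagged, best found returned).

## Known limitations

- Purely elastic walls (no viscoelasticity): pulse pressure runs wide and
  waveform-derived indices inherit a small bias, consistent with the
  original study's own discussion.
- The reconstructed fixture reproduces the published healthy anchors but
  not the unpublished age-dependence of the renal parameterization: the
  simulated healthy 50–59 renal flow sits higher than the level implied
  by the published diseased-flow values, so diseased absolute RBF levels
  run ~25% high while the DN/HN flow ratio and both ROC AUCs match.
- RI responds non-monotonically through middle age (bed-compliance
  decline initially outweighs wall stiffening); the published endpoint
  rise is reproduced.
- The physiology filter keeps ~50% of subjects at desk scale versus the
  published 35%, reflecting the lower parameter dimensionality of the
  reconstruction.
- Desk-scale populations (tens per group versus 2,000) leave Monte-Carlo
  noise of roughly ±0.01 on group RI means and a few percent on group
  flow means.
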