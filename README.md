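# renalpulse

Coupled 1D–0D hemodynamic modelling of the systemic and renal arterial
circulation, for studying how ageing, diabetic nephropathy (DN) and
hypertensive nephropathy (HN) reshape renal hemodynamic biomarkers in
virtual patient populations.

Kidney disease caused by diabetes and by hypertension can currently only be
distinguished by invasive biopsy. Two non-invasive imaging biomarkers are
candidates for earlier differential diagnosis: the Doppler **resistive
index** at the segmental renal arteries,

    RI = (V_PSV − V_EDV) / V_PSV,

(peak-systolic minus end-diastolic over peak-systolic blood velocity) and the
**mean renal blood flow rate** (RBF, ml/min) through the main renal artery.
This package implements an in-silico pipeline to evaluate them:

- **1D pulse-wave solver** — mass and momentum balance per elastic vessel,
  `∂A/∂t + ∂Q/∂z = 0` and
  `∂Q/∂t + ∂z(αQ²/A) + (A/ρ)∂P/∂z = −2(γᵥ+2)πμQ/(ρA)`, closed by the tube
  law `P = Pext + β(√(A/A₀) − 1)`, `β = √(π/A₀)·Eh₀/(1−ν²)`; solved by a
  well-balanced MUSCL–Hancock finite-volume scheme (numba-compiled) with
  Riemann-invariant junction coupling and R-C-R (Windkessel) outlet beds.
- **Baseline network** — a packaged 113-vessel arterial tree: 37 systemic
  vessels plus two intrarenal trees of 38 vessels each (main renal →
  five segmental → interlobar generations, Murray-law radii).
- **Virtual populations** — per-vessel Gaussian scaling factors per age
  group (20–29 … 70–79) for cardiac output, geometry, stiffness and
  peripheral beds; a 2.575-SD brachial-pressure physiology filter; fixed
  calibrated multipliers for four disease stages (Early.D, Severe.D,
  Early.H, Severe.H).
- **Analysis layer** — biomarker extraction, Sobol sensitivity
  (Saltelli design), RI-target calibration, and ROC/Youden discrimination
  of DN vs HN.

## Worked example

```python
from renalpulse import build_baseline_network, generate_inlet_waveform, run_simulation
from renalpulse.biomarkers import extract_biomarkers
from renalpulse.units import lmin_to_m3s

net = build_baseline_network()                       # 113 vessels, 60 beds
inlet = generate_inlet_waveform(lmin_to_m3s(5.74))   # 5.74 l/min at 70 bpm
result = run_simulation(net, inlet)                  # periodic in 5 cycles, ~1 s
rec = extract_biomarkers(result, "baseline", "20-29")
print(rec.sbp_mmhg, rec.dbp_mmhg, rec.ri_mean, rec.rbf_total_mlmin)
```

prints (young healthy baseline subject):

```
124.5 66.0 0.641 1064.5
```

i.e. brachial pressure 124.5/66.0 mmHg, mean segmental resistive index
0.641, and 1064.5 ml/min of total renal blood flow — a young healthy adult
at rest (reference: ~120/74 mmHg, RI ≈ 0.63, RBF ≈ 1066 ml/min).

The study itself is organised as numbered drivers:

```
python analysis/01_baseline_hemodynamics.py     # resting baseline subject
python analysis/02_ageing_study.py              # ageing cohort + filter
python analysis/03_sensitivity.py               # Sobol: what drives RI?
python analysis/04_calibration.py               # tune renal factors to an RI target
python analysis/05_disease_roc.py               # DN vs HN discrimination (ROC)
```

Each writes its tables under `results/`. A `renalpulse` console script
exposes the same recipes (`renalpulse ageing-study`, `renalpulse
disease-study`, `renalpulse sobol`, …).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch at desk scale — samples healthy
subjects for all six age groups, simulates them on the packaged baseline
network, applies the physiology filter, generates the Early.D / Severe.D /
Early.H populations from the calibrated stage multipliers, and recomputes
the headline quantities (stage RI and single-kidney RBF means, healthy
ageing RI and total RBF, early-stage ROC AUCs for both biomarkers, and
the Youden-optimal RBF cut-off), writing them as JSON (~15 min on one CPU).

## Layout

```
src/renalpulse/      library: network, solver, populations, biomarkers, analysis
  data/              packaged baseline network + published distribution tables
analysis/            numbered study drivers (thin wrappers over the library)
scripts/acceptance.py
tests/               pytest suite (solver oracles, statistics oracles,
                     population recovery, scaled-down study reproduction)
docs/methods.md      model description, assumptions, numerical choices
```
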