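# exfrac

Expression-fraction estimation for whole-cell biosensors from plate-reader
time series.

## The problem

Transcription-factor biosensors and other regulatory circuits are usually
characterised by reporter fluorescence, but there is no consensus on *when*
to read the signal: end points, the time of maximum growth rate and fixed
induction times all give different — and unfairly compared — numbers across
strains. `exfrac` frames the question in terms of bacterial physiology. The
cell is treated as a small set of proteome fractions φ_i (ribosomal,
nutrient-fixing, structural, heterologous), each receiving a share f_i of
the total biosynthesis flux ρ(t) — its **expression fraction**. The fractions
then obey

    dφ_i/dt = ρ(t) · [f_i(t) − φ_i(t)],

which has two practical consequences for the heterologous (reporter)
fraction φ_H, proxied by fluorescence/OD600:

* **Maximum method** — at any interior maximum of φ_H, dφ_H/dt = 0 forces
  φ_H = f_H: the peak of the fluorescence/OD trace *is* the expression
  fraction, whatever the culture did to get there.
* **Slope method** — while f_H is constant and protein tracks biomass
  (ρ ≈ µ), the specific production rate ρ_H = Δflu/(Δt·OD) is proportional
  to the specific growth rate µ = ΔOD/(Δt·OD):
  ρ_H(t) = f_H·µ(t), or ρ_H(t) = f_H·[µ(t) − b] when production shuts down
  before growth does. The slope of ρ_H vs µ over the growth phase is f_H,
  with a defined window of validity.

Titrating the inducer I and fitting the f_H estimates with a Hill law
f_H(I) = H·Iⁿ/(Iⁿ + k_Iⁿ) condenses a biosensor into three parameters:
maximum expression H, apparent affinity k_I and cooperativity n.

The package implements both estimators with the published window-selection
rules (per-replicate maxima within the first 10 h; t-test growth-phase
detection at α = 0.05 plus early-point trimming to maximal R²), bounded
inverse-variance-weighted Hill fitting (H, k_I ≥ 0, n ≥ 1), and a
batch-culture proteome-allocation simulator that generates ground-truthed
synthetic plate-reader datasets for validating every stage.

## Worked example

```python
from exfrac import SimConfig, simulate_titration, fit_hill
from exfrac.slope import slope_fit_group, slope_dose_response

cfg = SimConfig(seed=7)                       # ground truth: H_flu/OD = 9600, k_I = 30, n = 2.5
tit = simulate_titration(cfg, [0, 10, 20, 40, 80, 160])
fits = [slope_fit_group(g, "gfp") for g in tit.groups]
for f in fits:
    print(f"I={f.concentration:6.1f}  f_H={f.slope:8.1f} ± {f.slope_se:6.1f}  R2={f.r_squared:.3f}")
p = fit_hill(slope_dose_response(fits))
print(f"H = {p.H:.0f} ± {p.se_H:.0f}   k_I = {p.k_I:.1f} ± {p.se_kI:.1f}   n = {p.n:.2f} ± {p.se_n:.2f}")
```

prints (seed 7):

```
I=   0.0  f_H=     0.0 ±    0.0  R2=1.000
I=  10.0  f_H=   553.6 ±   21.4  R2=0.859
I=  20.0  f_H=  2442.6 ±  111.8  R2=0.807
I=  40.0  f_H=  6294.3 ±  248.7  R2=0.836
I=  80.0  f_H=  7903.6 ±  490.5  R2=0.673
I= 160.0  f_H=  9157.8 ±  361.4  R2=0.823
H = 9122 ± 235   k_I = 29.7 ± 0.9   n = 2.52 ± 0.06
```

Each slope is the expression fraction (in fluorescence/OD units) at that
inducer concentration; the Hill fit recovers the generating affinity
k_I = 30 and cooperativity n = 2.5 to a few percent, with the plateau H a
few percent below truth (OD noise attenuates an ordinary-least-squares
slope; see `docs/methods.md`).

The same analysis runs from the shell on real or simulated tidy CSVs:

```bash
exfrac simulate --out run/ --concentrations 0,10,20,40,80,160 --seed 7
exfrac fit-slope --data run/data.csv --layout run/layout.csv \
    --out run/slopes.csv --dose-response-out run/dr.csv
exfrac fit-hill --dose-response run/dr.csv --out run/hill.json
```

or end to end from one YAML config with `exfrac run config.yaml`, which also
writes rates tables, both methods' estimates, method-comparison z-scores,
diagnostic plots and a reproducibility manifest.

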