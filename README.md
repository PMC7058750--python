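# petkin

Full quantification chain for dynamic PET tracer kinetics, built around the
case of a ⁶⁸Ga-labelled PSMA ligand in primary prostate cancer: arterial
input-function construction from an automatic blood sampler merged with
manual draws, an image-derived input function (IDIF) with partial-volume and
spill-over correction, serial compartment-model fitting with AIC model
selection, Patlak graphical analysis, SUV quantification over static
time-windows, and the validation statistics (Spearman, ICC(3,1), Friedman,
Wilcoxon signed-rank) that tie the simplified measures back to the kinetic
macro-parameter. A synthetic-study generator with recorded ground truth
stands in for patient data, so the entire chain is testable end to end.

The package is aimed at researchers in PET pharmacokinetics who want a
tested, reusable reference implementation of this analysis chain — or a
sandbox for studying how its pieces (dispersion correction, plasma-to-blood
conversion, PVC calibration, model selection) propagate into Ki and SUV.

## The model

Tracer exchange between arterial plasma Cp and tissue is described by serial
compartment models with rate constants (min⁻¹, K1 in mL·min⁻¹·mL⁻¹):

    dC1/dt = K1·Cp − (k2 + k3)·C1 + k4·C2
    dC2/dt = k3·C1 − k4·C2

with terms dropped for the smaller configurations: 1T1k (K1 only), 1T2k
(K1, k2), 2T3k (K1, k2, k3 — irreversible trapping), 2T4k (all four). Each
model is fitted with and without the fractional blood volume V_B, which
mixes the whole-blood curve into the model TAC as
(1−V_B)·(C1+C2) + V_B·C_wb. The preferred model is the lowest-AIC fit,
AIC = n·ln(RSS/n) + 2(p+1). The net influx rate

    Ki = K1·k3 / (k2 + k3)

is the irreversible-trapping macro-parameter; it also equals the slope of
the Patlak plot y = C_T/Cp vs x = ∫₀ᵗCp dτ / Cp for t ≥ t* (default
t* = 15 min). Plasma and whole blood are related by the hematocrit through
R_P/B = 1/(1−HCT) for a tracer excluded from red cells, and
SUV = C(kBq/mL)/(dose(MBq)/weight(kg)).

## Worked example

```python
from petkin import (FrameSchedule, ModelSpec, fit_model, hct_from_ratio,
                    net_influx, patlak, simulate_tissue)
from petkin.kinetics import KineticParams
from petkin.synthetic import SyntheticTruth, make_aif

truth = SyntheticTruth(seed=0)                     # HCT 0.38 -> R_P/B = 1.613
plasma, whole_blood, sampler, samples = make_aif(truth)

sched = FrameSchedule.default_60min()              # 28 frames, 60 min
p = KineticParams(K1=0.136, k2=0.277, k3=0.108)    # lesion-like kinetics
tac = simulate_tissue(ModelSpec("2T3k"), p, plasma, whole_blood, sched)

fit = fit_model(tac, ModelSpec("2T3k"), plasma, whole_blood)
pk = patlak(tac, plasma, t_star=15.0)
print(f"Ki (compartmental) = {fit.ki:.5f} mL/min/mL")
print(f"Ki (Patlak)        = {pk.ki:.5f} mL/min/mL")
print(f"HCT from R_P/B 1.62 = {100*hct_from_ratio(1.62):.0f}%")
```

prints

```
Ki (compartmental) = 0.03815 mL/min/mL
Ki (Patlak)        = 0.03809 mL/min/mL
HCT from R_P/B 1.62 = 38%
```

i.e. the fit recovers the generating parameters (Ki = K1·k3/(k2+k3) =
0.03815), the Patlak slope agrees with the compartmental macro-parameter to
0.2%, and a plasma-to-blood ratio of 1.62 corresponds to a hematocrit of
38%.

The numbered drivers under `analysis/` run the full study on the default
synthetic cohort (14 subjects, 18 lesions) and print their findings:

```bash
python analysis/01_simulate_study.py    # raw inputs -> results/study/
python analysis/02_input_functions.py   # AIF + IDIF, AUCr, hematocrit
python analysis/03_kinetic_fits.py      # AIC selection + rate-constant table
python analysis/04_suv_windows.py       # SUV 15-30/30-45/45-60 min + Friedman
python analysis/05_validation_stats.py  # SUV-Ki-PSA correlations, AIF-IDIF ICC
```

On the seed-0 cohort these report, e.g., the 2T3k model AIC-preferred in
17/18 lesions, rho(SUV 30–45 min, Ki) = 0.95, Ki ICC(3,1) between the
arterial and image-derived input functions of 1.00 (plasma) and 0.90
(whole blood), and a corrected IDIF AUCr of 1.004 (uncorrected: 0.76).

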