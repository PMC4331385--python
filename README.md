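# cmrperf

Quantitative myocardial blood flow (MBF) from first-pass contrast-enhanced
CMR perfusion: saturation-recovery FLASH signal-to-concentration
conversion, Fermi and distributed-parameter (DP) model-constrained
deconvolution, dual-bolus arterial-input handling, coronary-territory
classification of reduced hyperaemic flow, and a synthetic cohort
generator with known ground truth.

It is written for perfusion-imaging researchers who want to study how
arterial input function (AIF) saturation propagates into flow estimates —
in particular, why a dilute pre-bolus (dual-bolus protocol) changes Fermi
flow estimates much more than DP estimates — without needing patient data.

## The models

Tissue concentration is the convolution of the AIF with a scaled impulse
response, c_t(t) = (MBF/60) · (R ∗ c_a)(t):

* **Fermi** (empirical, fitted in the time domain over the first pass):

      R(t) = 1 / (exp[(t − τ₀)·k] + 1)

  τ₀ sets the shoulder width, k the washout rate. Reported MBF is the
  impulse-response initial height A·R(0) — by the indicator-dilution
  identity the tissue impulse response at t = 0⁺ equals flow — because the
  raw amplitude A trades against τ₀ and k and is not identifiable at
  realistic noise.

* **Distributed parameter** (two-region, one-barrier, fitted spectrally
  over the full curve):

      R(s) = (1 − exp[−s(T + s·T_c·T_e)/(1 + s·T_e)]) / s,  s = i2πf

  with overall / capillary / interstitial mean transit times T, T_c, T_e.
  Fitted parameters map onto microvascular characteristics: v_b = MBF·T_c,
  v_e = MPF·(T−T_c), v_d = MPF·T, PS = MPF·(T−T_c)/T_e,
  E = 1 − exp(−PS/MPF), with plasma flow MPF = MBF·(1 − hct), hct = 0.45.

Signal conversion uses the saturation-recovery FLASH closed form
SI = Ψ·[(1−e^(−PD·R1))·a^(n−1) + b·(1−a^(n−1))/(1−a)] with
a = cos α·e^(−TR·R1), b = 1−e^(−TR·R1); Ψ is calibrated per region from
pre-contrast frames and native T1, and c(t) = (R1(t) − 1/T1₀)/r1.
Territories with mean hyperaemic MBF < 2.5 mL/min/mL of tissue (strict)
are classified as having reduced flow.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and limitations.

## Worked example

Simulate eight stress volunteers whose main-bolus blood-pool signal
carries T2\* saturation, analyse each segment with both models using the
saturated AIF (single bolus) and the scaled dilute pre-bolus (dual bolus),
and compare:

```python
from cmrperf.experiments import saturation_asymmetry_experiment

res = saturation_asymmetry_experiment(n_subjects=8, n_segments=8, seed=0)
print(f"Fermi: single {res.mean('fermi','single'):.2f} vs dual "
      f"{res.mean('fermi','dual'):.2f} mL/min/mL, p={res.fermi_paired.p_value:.1e}")
print(f"DP:    single {res.mean('dp','single'):.2f} vs dual "
      f"{res.mean('dp','dual'):.2f} mL/min/mL, p={res.dp_paired.p_value:.2f}")
```

prints

```
Fermi: single 3.28 vs dual 2.62 mL/min/mL, p=1.3e-05
DP:    single 3.82 vs dual 3.38 mL/min/mL, p=0.15
```

i.e. the saturated input inflates Fermi flow by ~25% (highly significant
in a paired test across subjects) while the DP single/dual difference is
not significant; the DP Bland–Altman bias confidence interval
(−1.08, 0.20) spans zero. Classifying the packaged per-vessel patient
table (`cmrperf classify --out counts.json`, or
`analysis/04_patient_classification.py`):

```
dp:    flagged 12/12 stenotic vessels (group 3: 7/7, group 2: 5/5)
fermi: flagged  9/12 stenotic vessels (group 3: 6/7, group 2: 3/5)
```

The numbered scripts under `analysis/` run the full narrative —
`01_simulate_cohort.py` (cohort generation; large curve CSVs go to
`scratch/`), `02_saturation_comparison.py`, `03_parameter_recovery.py`
(median flow recovery error at 5% noise: DP 6.8%, Fermi 3.9%),
`04_patient_classification.py` — writing their tables to `results/`.

A `cmrperf` CLI chains the same stages
(`simulate`, `convert`, `fit`, `classify`, `stats`, `run`); see
`cmrperf --help`.

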