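# batquant

Multi-modal quantification of brown adipose tissue (BAT) metabolic activity,
for imaging scientists evaluating cheap and radiation-free surrogates of the
PET-measured glucose uptake rate.

BAT burns glucose and fatty acids to produce heat. The reference measurement
of its activity is the glucose uptake rate (GUR) from dynamic
¹⁸F-FDG PET during cold exposure — accurate but expensive and ionising.
Candidate surrogates are the skin temperature over the supraclavicular
depot measured by infrared thermography (IRT), and the fat fraction (FF) and
effective transverse relaxation rate (R2\*) of the depot from water-fat MRI.
`batquant` implements the full quantification chain for all three
modalities, plus the synthetic phantoms needed to validate every stage
against known ground truth:

- **kinetics** — image-derived arterial input function (aortic ROI, plasma =
  1.1 × whole blood), basis-function fit of the irreversible two-tissue
  compartment model (Ki = K1·k3/(k2+k3); 50 log-spaced clearance rates
  θ ∈ [0.02, 1.0] min⁻¹ plus one irreversible basis), GUR maps
  (Ki × serum glucose, lumped constant 1) in µmol/100 ml/min.
- **fatwater** — multi-echo magnitude fit of
  |S(TE)| = M·|(1−FF) + FF·c(TE)|·e^(−R2\*·TE) with a six-peak fat
  spectrum; two-point dual-echo water/fat separation; FF = F/(W+F).
- **batseg** — threshold segmentation (GUR > 10 µmol/100 ml/min), the
  FF < 40% / 6-neighbourhood-erosion / R2\* > 120 s⁻¹ refinement, fat
  masks (FF ≥ 40% + erosion), slice exclusions, total depot GUR in µmol/min.
- **thermo** — raw radiometric signal → temperature via emissivity (0.98),
  reflected-temperature and atmospheric-transmission compensation with
  Planck inversion; supraclavicular (SCF) and paranasal (PNR) window means.
- **stats** — the pre-specified 7 simple + 4 multiple OLS regressions of
  total BAT GUR on the IRT/MRI measurements, with adjusted R² and
  significance (p < 0.05) / trend (p < 0.10) flags.
- **synthio** — seeded generators for input functions, 4-D PET phantoms,
  multi-/dual-echo MR phantoms, raw IRT sequences and regression cohorts,
  all with known ground truth.

## Worked example

Run one fully synthetic subject through the whole pipeline:

```python
from batquant import pipeline as pl

subject, truth = pl.make_synthetic_subject(seed=1)
row = pl.run_subject(subject)
```

`row` (printed values, against a phantom truth of 0.68 µmol/min total GUR,
FF 80%, R2\* 44 s⁻¹):

```
total_bat_gur_umol_min: 0.6786     # 0.2% from the phantom truth
bat_ff2e_pct:  81.1                # dual-echo FF; +1.1 pp R2*-neglect bias
bat_ff15e_pct: 80.0                # multi-echo FF, exact at zero noise
bat_r2s_s1:    44.0
scf_neutral_c: 34.28   scf_cold_c: 34.10
pnr_neutral_c: 31.43   pnr_cold_c: 31.74
```

Cohort analysis on a simulated 12-subject table (GUR driven by the cold SCF
temperature, slope 48.07 µmol/min/°C, intercept −1591 µmol/min):

```python
from batquant import synthio

table = synthio.make_cohort(synthio.CohortSpec(n=12, seed=0))
res = pl.run_cohort(table)
print(res["models"].head(4))
```

```
        model     predictor       beta    intercept    adj_r2  p_value  significant
scf_neutral_c scf_neutral_c  17.129529  -538.909035 -0.053947 0.523533        False
   scf_cold_c    scf_cold_c  58.553935 -1936.324626  0.639877 0.001087         True
pnr_neutral_c pnr_neutral_c -27.535568   921.991782 -0.056246 0.534306        False
   pnr_cold_c    pnr_cold_c  26.434883  -807.896002  0.228664 0.065920        False
```

Only the true driver (SCF_cold) is significant at this n; its fitted slope
(58.6 ± sampling error at n = 12) scatters around the generative 48.07.

The same steps are available from the shell:

```sh
batquant synth --out subj1 --seed 1
batquant run-subject --subject-dir subj1 --out row.csv
batquant run-cohort --cohort cohort.csv --out-models models.csv
```

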