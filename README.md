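# mobiquant

Quantification of a small-molecule drug (osimertinib) in human plasma from
MALDI ion-mobility MS/MS spot acquisitions, with a full FDA/EMA
bioanalytical validation engine and cross-validation against a reference
method.

## Who this is for

Bioanalytical and clinical-pharmacology groups exploring MALDI-IM-MS/MS as
a fast alternative to LC-MS/MS for therapeutic drug monitoring. A spot
analysis takes about one minute; because there is no chromatography, the
drift time (DT) of the ion-mobility separation plays the role of a
retention time, and the *extracted ion mobilogram* plays the role of an
extracted ion chromatogram. The package covers the complete computational
side of such an assay:

- **study design** — spike/dilution arithmetic (virtual concentration in
  plasma), calibration standard (CAL5–CAL1000) and quality-control (LLOQ,
  LQC, MQC, HQC) batch layouts, including the dilution-compensated
  recovery (QC DIL / QC REC) and matrix-effect (QC MAT / QC EL) series;
- **mobilogram** — MobA (mobility-peak areas via an apex-tracking
  integrator) and MassI (combined-spectrum intensities) data extraction,
  plus 2D m/z × DT maps for interference diagnosis;
- **calibration** — internal-standard-normalized responses and a
  1/x²-weighted linear model with EMA/FDA acceptance rules;
- **validation** — precision/accuracy, specificity, carry-over, recovery,
  IS-normalized matrix factors, freeze/thaw bookkeeping, and a structured
  validation report;
- **crossval** — incurred-sample conformity (±20% of the pair mean, ≥67%
  rule) and Pearson correlation against a reference method;
- **simulate** — a synthetic acquisition generator reproducing the assay's
  signal structure (analyte fragment at m/z ≈185.11, IS fragment at
  ≈189.13, an endogenous interferent at Δm/z 0.03 / ΔDT 0.04 ms, V/W TOF
  resolution modes, spot-crystallization TIC heterogeneity), so the whole
  pipeline runs end to end without instrument data.

## The model at the core

The response of a sample is `y = A_analyte / A_IS`, the ratio of the MobA
peak areas of the analyte and its stable-isotope-labelled internal
standard, which cancels preparation and MALDI ionization variability.
Calibration fits

```
y = a + b·x  minimizing  Σ wᵢ (yᵢ − a − b·xᵢ)²,   wᵢ = 1/xᵢ²
```

on the replicate responses of the non-zero calibration standards
(x = nominal concentration in ng/mL), and concentrations are read back by
inverse prediction `x̂ = (y − a)/b`. A level is accepted at |bias| ≤ 15 %
(20 % at the LLOQ); a curve needs ≥ 75 % of its standards and ≥ 6 levels
accepted. Precision is `%CV = 100·sd/mean`, accuracy
`%bias = 100·(mean − nominal)/nominal`, gated at 15 %/±15 %
(LLOQ: 20 %/±20 %).

## Worked example

```python
from mobiquant import (CalibrationModel, InstrumentModel, PipelineConfig,
                       SignalModel, build_batch_layout, simulate_batch)
from mobiquant.campaign import extract_features
from mobiquant.design import SampleRole

instrument = InstrumentModel(resolution_mode="W")   # resolution mode
signal = SignalModel()                              # assay-like defaults
layout = build_batch_layout("validation", batch_id="B1")   # 72 spots
acqs = simulate_batch(layout, instrument, signal, seed=7)
features = extract_features(acqs, layout, PipelineConfig())

cal = features[features.role == SampleRole.CAL.value]
fit = CalibrationModel.from_dataframe(cal, y_col="response").fit()
print(fit.summary())
```

prints

```
Weighted linear calibration
---------------------------
n points                32   (weighting 1/x^2)
slope b           0.00677856 +/- 0.000149 per ng/mL
intercept a       0.00144125 +/- 0.00182
weighted r^2        0.985799
levels accepted      8/8   verdict: accepted
level (ng/mL)    n   back-calc    bias%   ok
           5    4       4.854    -2.92   y
          10    4       10.92     9.25   y
          ...
        1000    4        1037     3.72   y
```

Every calibration level back-calculates within the ±15 % (±20 % at the
LLOQ) bias limits, so the curve is accepted; the slope is the assay's
response per ng/mL and the small intercept absorbs the
concentration-independent endogenous interferent. Back-calculating the
eight LLOQ QC replicates of the same batch returns values like
`[5.72, 4.79, 4.45, 4.58, ...]` ng/mL — a ~10 % CV around the 5 ng/mL
nominal, the sensitivity level the assay validates.

A complete validation campaign (4 batches, blank panel, recovery and
matrix series) runs with

```sh
mobiquant run-campaign --seed 7 --out campaign/
```

and writes layouts, features, per-batch fits, back-calculated
concentrations and a `report.json`/`report.md` validation summary whose
rows mirror the usual validation-table layout (sensitivity, calibration
range, QC precision/accuracy, specificity, carry-over, freeze/thaw,
recovery, matrix effect). Other subcommands: `simulate`, `extract`,
`calibrate`, `validate`, `crossval`.

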