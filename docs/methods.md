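# Methods

This note documents the models, defaults and numerical choices behind
mobiquant: what the synthetic acquisition generator emulates, how the
mobilogram integrator and the calibration model work, which conventions
the validation statistics follow, and what the test suite does and does
not demonstrate about real instrument data.

## The assay being modelled

A 1 µL aliquot of the organic layer of a TBME liquid–liquid extraction of
spiked plasma is deposited on pre-spotted 2,5-DHB matrix and analyzed for
60 s on a MALDI Q–IMS–TOF instrument in MS/MS mode. The quadrupole
isolates the precursor (~m/z 500), fragments are separated by ion
mobility, and quantification uses the analyte's major fragment near
m/z 185.11 against the co-spiked stable-isotope-labelled internal
standard's fragment near 189.13. Concentrations are expressed as
*virtual concentrations in plasma*: a 50 µL spike into 100 µL plasma
makes the virtual concentration half the solution concentration
(CAL1000 = 2000 ng/mL in solution). The calibration range is
5–1000 ng/mL; QC levels are 5 (LLOQ), 15 (LQC), 400 (MQC) and
800 (HQC) ng/mL.

## Synthetic acquisition generator

One acquisition is a set of centroided scans, each tagged with a drift
bin, covering `scans_per_spot` IMS cycles. Three 2D Gaussian components
are rendered on the (m/z, DT) grid by exact bin integrals of the Gaussian
(so peak volumes are conserved and scale exactly linearly):

| component | m/z center | DT center | volume |
|---|---|---|---|
| analyte | 185.1075 | 1.85 ms | `response_slope · conc · prep · MF_a · spot · rep` |
| internal standard | 189.1325 | 1.86 ms | `is_slope · 200 · prep_IS · MF_IS · spot · rep` |
| interferent | +0.03 | +0.04 ms | `interferent_area · spot · rep` (concentration-independent, present whenever plasma extract is present) |

**Preparation routes.** `prep` encodes the sample's preparation:
ordinary samples co-extract analyte and IS (both multiplied by the
extraction recovery, default 0.536 — the assay's reported mean recovery);
QC DIL adds a 1:1 post-extraction dilution to both; QC REC spikes the
analyte *after* extracting a CAL0, so only the IS carries the recovery
loss; QC MAT and QC EL are post-extraction spikes at matched dilution
into matrix extract and neat eluent respectively (matrix factors apply
only to MAT; the MAT series' double plasma volume is what makes the
dilutions match). With these routes the paper-style estimators recover
the generator's parameters identically: the IS-normalized DIL/REC ratio
equals the extraction recovery, and the MAT/EL area ratio equals the
matrix factor, while MALDI spot variability cancels through the IS in
both. Carry-over blanks carry a residual analyte signal of 5 % of the
LLOQ-level signal and 0.2 % of the IS signal — chosen so the *measured*
carry-over ratio (raw-area integration keeps the baseline pedestal)
reproduces the below-17 %-of-LLOQ regime the assay reports.

**Noise structure.** Replicate noise is multiplicative mean-1 log-normal,
applied per compound with CV `replicate_cv/√2` so the analyte/IS response
has CV ≈ `replicate_cv` (default 0.08, inside the assay's reported
within-batch 5–10 % CV range). The spot factor — crystallization quality —
is a shared multiplier for all components of a spot (log-normal,
CV = `spot_heterogeneity`, default 0.25) times the mean of the per-cycle
TIC profile; because it is shared, IS normalization cancels it exactly.
The TIC profile itself distinguishes deposition orders: pre-spotted
matrix gives a stable profile (CV = `spot_heterogeneity`), matrix
deposited after the extract gives sparse Bernoulli bursts (hit
probability 0.25) with a far lower mean and higher variance. Baseline
noise is additive zero-truncated Gaussian (σ = 1 a.u.) rendered on the
m/z combs around both fragment windows across the whole DT axis.

**Resolution modes.** The TOF m/z FWHM at m/z 185 is 0.060 in sensitivity
(V) mode and 0.018 in resolution (W) mode. These resolving powers are not
published for the assay; they were chosen once so that the Δm/z 0.03
interferent merges with the analyte peak in V mode (FWHM = 2Δ) and is
mass-resolved in W mode (FWHM < Δ), reproducing the qualitative
resolution argument: with the default interferent volume (250 a.u.,
about half the LLOQ analyte signal) the analyte-window signal at the
LLOQ is inflated ≈25–30 % in V mode and <1 % in W mode. The mobility
separation alone (ΔDT 0.04 ms against a 0.10 ms FWHM mobility peak)
cannot separate the two — which is why the W mode exists.

**Other fixed choices.** DT axis 0–4 ms in 200 bins (the displayed range
of the assay's 2D maps; the bin count is free and documented here),
30 IMS cycles per 60 s spot, IS virtual concentration 200 ng/mL
(400 ng/mL solution, 50 µL into 100 µL plasma), response slope
200 a.u. per ng/mL. The absolute intensity scale of the instrument is
arbitrary; every validation statistic is a ratio, so the slope value is
irrelevant to all results. Per-spot seeds are derived from
(batch seed, CRC32(sample id)), making batches bit-reproducible and
order-independent.

## Mobilogram extraction and peak integration

`extract_mobilogram` sums centroid intensities inside the m/z window
(inclusive bounds; defaults are the assay's printed windows
185.094–185.121 and 189.125–189.140) per drift bin. `massi` takes the
maximum of the TIC-combined spectrum binned on a 0.005 m/z comb (≥5 bins
across the narrowest window). The mobility-peak integrator is a
deterministic reimplementation of a vendor-style apex-tracking algorithm
— a functional stand-in, not a clone, since the vendor's parameters are
proprietary:

1. smooth with a local quadratic (Savitzky–Golay) filter, window 5 bins;
2. baseline = median of the mobilogram more than 3×`dt_tolerance` from
   the expected DT; noise = 1.4826×MAD of that region;
3. apex = highest smoothed local maximum within `dt_tolerance`
   (default 0.2 ms) of the expected DT, provided it exceeds
   baseline + 2×noise; ties resolve to the apex closer to the expected
   DT, then to the earlier DT;
4. boundaries walk downhill from the apex on the smoothed trace and stop
   at the first bin at/below the threshold or at a strict valley — exact
   ties (plateaus) continue the walk, which matters when a peak is
   centered exactly on a bin edge and its two apex bins are equal;
5. area = trapezoidal integral of the **raw** trace between the
   boundaries; no baseline subtraction. When no qualifying maximum
   exists the integrator returns a zero-area peak at the expected DT.

Keeping the raw (unsubtracted) trapezoid makes blank and carry-over
statistics honest but means small peaks include the baseline pedestal;
this is accounted for where it matters (see carry-over above).

## Calibration

`CalibrationModel` fits the replicate responses of the non-zero
standards by weighted least squares (statsmodels WLS) with w = 1/x²;
zero-concentration samples never enter (their weight is undefined), and
fitting on per-level means is available but off by default (regression
on replicates is standard EMA practice). r² is computed on the weighted
model — whether vendor software uses weighted or unweighted residuals is
unstated, so the weighted convention is used and declared. The r² floor
(default 0.988, the assay's observed minimum) is reported, not gating:
guidelines gate on bias. Back-calculation is inverse prediction;
negative values are reported as-is and flagged, never clamped. The
concentration-independent interferent adds a constant to every response
and is therefore absorbed exactly by the fitted intercept — one reason
the noiseless end-to-end pipeline recovers every level essentially
exactly (residual ~10⁻⁵ relative, from peak boundaries shifting by one
bin between levels as the analyte/interferent height ratio changes).

## Validation statistics

CV uses the sample (n−1) standard deviation; bias uses the replicate
mean. Batch-to-batch statistics pool all replicates across batches
(grand mean/SD), matching the single pooled values of the usual summary
table. The CV limit is strict (`CV = 15.0 %` fails, `14.99 %` passes,
matching the "<20 %" guideline phrasing) and the bias limit inclusive;
both are configurable per criterion. "Signal" in the specificity and
carry-over ratios means the MobA area in the compound's window — MobA is
the validated extraction method — compared against the *lowest* LLOQ
analyte area (20 % limit) and the mean IS area of calibrators and QCs
(5 % limit). Freeze/thaw QCs (three cycles, quadruplicates at
LQC/MQC/HQC in batch 3) pool into that batch's precision/accuracy and
are additionally reported as their own stability row. The campaign's
overall verdict is *validated* only when every section is assessed and
passes; a missing section (e.g. no carry-over blanks when fewer than
four batches are run) yields *incomplete*.

## Cross-validation

The conformity of a pair is `100·(a−b)/((a+b)/2)` — the two-method mean
as denominator, the incurred-sample-reanalysis convention — with a ±20 %
limit and a ≥67 % pass rule (warning below 20 samples). Technical
duplicates are averaged per method before pairing (whether the assay's
reported figure was computed on averaged or per-replicate values is
unstated; averaged is adopted); raw duplicates are retained in the
output. Pearson r and its two-sided p come from the t transform with
n−2 degrees of freedom (scipy).

## Problem sizes

The test suite runs everything at the assay's own design sizes: 72-spot
validation batches, 24-spot recovery and matrix series, six-source blank
panels. The guideline-gate direction check runs 26 full campaigns at the
default replicate CV and 26 at 30 % CV; the cross-validation trend check
uses 200 seeds of 25-sample panels at the concentration level. These
sizes were chosen so the whole suite completes in about two minutes on
one CPU while keeping every estimator at its designed replicate count.

## What passing tests do and do not show

The generator reproduces the assay's *structure* — linear
concentration-response, IS cancellation of spot variability, the
resolution-mode interference geometry, the preparation-route arithmetic
of the recovery and matrix designs, and realistic replicate CVs. It does
not model crystallization physics, isotope envelopes, detector
saturation, ion suppression that varies across a spot, the six minor
fragments of the compound, or drift-time calibration drift; matrix
factors and recoveries are constants, not distributions over donors.
Passing the synthetic campaign therefore demonstrates that the
*computational pipeline* implements the validation logic correctly and
recovers known generator parameters — not that any particular instrument
would validate. The mzML reader covers the subset of the format this
pipeline consumes (centroided spectra with a drift-time scan attribute,
32/64-bit floats, none/zlib compression) and maps drift times onto the
acquisition contract by sorted unique values.
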