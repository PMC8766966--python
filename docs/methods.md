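# Methods

## The measurement model

Each analyte is quantified against a through-origin quadratic calibration

    y(c) = a·c + b·c²,   a > 0,   a + 2·b·ULOQ > 0,

where `y` is the instrument response (analyte/internal-standard area ratio by
default, raw analyte area via `response_mode="area"`) and `c` the
concentration in ng/ml.  The zero intercept encodes the physical constraint
that a blank produces no analyte signal; the quadratic term absorbs mild
detector saturation (`b < 0`) or enhancement (`b > 0`).  Coefficients
minimise the weighted residual sum `Σ wᵢ(yᵢ − a·cᵢ − b·cᵢ²)²` and are
computed in closed form from the 2×2 weighted normal equations

    [Σw c²  Σw c³] [a]   [Σw c y ]
    [Σw c³  Σw c⁴] [b] = [Σw c² y].

The default weighting is `w = 1/c`.  Over a calibration range spanning 256×
(nine 1:1 dilutions), unweighted least squares would be dominated by the top
standards; `1/x` restores relative accuracy at the low end, where adherence
decisions are made.

**Weighted r².**  `r² = 1 − SSres_w/SStot_w` with the total sum of squares
taken about the *weighted mean* response (the standard WLS definition).  The
uncentred alternative (`SStot` about zero) was rejected: for a through-origin
model it inflates r² to the point where values near 0.996 could not occur.
r² is not clipped; a negative value is reported as-is with a warning flag,
because it diagnoses a pathological fit.

**Monotonicity and inversion.**  A fitted curve is rejected unless monotone
increasing on `[0, ULOQ]`, which makes the inverse (quantification) root of
`b·c² + a·c − y = 0` unique on `[0, 2·ULOQ]`.  The quadratic is solved with
the numerically stable ±-form; for `|b| < 10⁻¹²·a` the linear inverse `y/a`
is used.  Back-calculated values carry qualifiers relative to the analyte's
limits: `below_lod`, `below_lloq` (reportable but with >20% error risk),
`quantified`, `above_uloq`.

## Assay design

The panel's top standard (STD9 = ULOQ) is analyte-specific (10–8000 ng/ml);
STD1 (= LLOQ) is STD9/2⁸.  QC levels are fixed fractions of STD9 — H = 0.8,
M = 0.1, L = 0.01.  Reported concentrations round half-away-from-zero to
2 decimals (0.0390625 → 0.04); all computation keeps full precision.  The
limit of detection is stored as an empirical per-analyte datum rather than
derived from the LLOQ: determined LOD/LLOQ ratios in practice vary between
1/2 and 1/16 depending on each analyte's noise floor.  Ionisation polarity
is carried as metadata only.

## Validation metrics

* **Accuracy** = 100·mean(back-calculated)/nominal, per QC level.
* **Imprecision** = RSD (sample sd, n−1 denominator).  Intra-day: the five
  replicates of the designated session.  Inter-day: all back-calculated
  values pooled across the six sessions (maximal degrees of freedom); an
  `inter_mode="session_means"` switch computes the RSD of session means
  instead, since either convention is defensible.
* **Recovery** REC_s = 100·mean(pre-spiked areas)/mean(neat areas) per
  session; **extraction efficiency** EE_s analogously against post-spiked
  areas; both summarised as mean and RSD across sessions.
* **Matrix effect** ME_l = 100·(mean(post-spiked in lot l)/mean(neat) − 1)
  per blank-matrix lot (post-extraction addition); suppression negative.
  The **IS-normalised ME** applies the same formula to the analyte/IS area
  ratio, so co-suppression of analyte and internal standard cancels.  For
  these signed metrics centred near zero, the dispersion column is the
  standard deviation of per-lot values in percentage points — a
  sd/mean-style RSD is ill-defined around 0.
* **Identity.**  When REC, EE and ME are computed from one (pre, post, neat)
  signal triplet, REC = EE·(1 + ME/100) holds algebraically; computed from
  session means (REC, EE) and lot means (ME) it holds approximately, to
  within the sampling error of the lot population.
* **Limits.**  From a descending dilution series with replicate
  back-calculation and peak heights: LLOQ is the lowest level satisfying the
  conjunction |bias| < 20%, RSD < 20%, S/N > 5; LOD the lowest with S/N ≥ 3.
  S/N is the mean peak height divided by the standard deviation of blank
  heights from the same matrix — the simplest estimator consistent with
  ratio thresholds of 5 and 3; the noise estimator is a function argument
  and therefore pluggable.  LOD ≤ LLOQ holds because the LLOQ level itself
  exceeds S/N 5.
* **Selectivity** (per lot, EMA convention): the blank analyte response must
  stay strictly below 20% of the mean LLOQ response and the blank IS
  response below 5% of the mean IS response.
* **Compliance** uses strict inequalities — bias and RSDs strictly below 15%
  at QC levels and 20% at the LLOQ.  Failures are flagged, never fatal:
  exceptions at very low QC levels are part of a method's characterisation,
  not grounds for discarding the batch report.
* **Device retention**: loss % = 100·(post − pre)/pre per medium (solvent,
  saliva); tiers: severe ≤ −50, moderate (−50, −20], negligible (−20, +20),
  increase ≥ +20.

## Adherence

Positivity for a prescribed drug uses the **LOD**, not the LLOQ: a
sub-LLOQ, supra-LOD salivary signal is evidence of intake, flagged with its
elevated error risk.  Concordance cross-tabulates matched (patient, drug)
positivity between a test matrix and a reference matrix; sensitivity =
100·TP/(TP+FN), specificity = 100·TN/(TN+FP), accuracy over all matches.
When a reference margin is empty the corresponding statistic is *not
applicable* rather than 100%, so all-adherent cohorts cannot inflate
specificity.  Three-matrix agreement counts matches where all three, or at
least two of three, matrices agree with the majority call.  Saliva/plasma
ratio summaries use inclusive (linear-interpolation) quartiles and Pearson
correlation on raw concentrations (Spearman available), reported only with
≥3 pairs.  Because determined instrument limits can sit below the nominal
panel limits, the limit set used for calling is an explicit input — no
reconciliation between the two is guessed.

## Synthetic generator

One injection's analyte area is

    area = (a·c + b·c²) · attenuation(role, lot) · e^(ε_sess) · e^(ε_inj) · e^(ε_det)

with `ε_sess ~ N(0, inter_day_cv)` per session, `ε_inj ~ N(0, intra_day_cv)`
per injection (shared with the IS channel — it models injected volume and
source drift) and `ε_det ~ N(0, intra_day_cv)` analyte-specific.  The IS
area omits `ε_det`, so the area ratio cancels the shared factors and carries
an effective CV of `intra_day_cv`; raw areas carry √2× that.  Noise is
multiplicative (lognormal) because reported RSDs are proportional across a
256-fold range.  Attenuation encodes the preparation chemistry: neat = 1,
post-spiked = 1 + ME_lot, pre-spiked/standards/dilution = EE·(1 + ME); lot
effects ME_lot ~ N(ME, lot_sd).  Blanks draw folded-normal baseline areas;
heights are 0.25× areas.

Defaults are the study conditions: 6 sessions × 5 intra-day replicates,
6 blank lots, intra- and inter-day CV 5%, EE 0.90, ME −0.10 (lot sd 0.03),
slope scaled to ~10⁶ counts at ULOQ with a 5% saturation sag, blank noise
placing S/N ≈ 10 at the nominal LLOQ.  Pre-spiked QCs rotate through the six
blank lots, as the donor lots serve both the extraction and matrix-effect
experiments; standards use pooled blank matrix.  Neat mixes are injected in
replicate (sessions × replicates) — with a single neat injection per session
its sampling error would dominate the ME estimate.

The cohort model draws, per adherent (patient, drug): plasma ~ lognormal
around a drug-typical median (population values where known, otherwise the
geometric mid-range of the calibration interval, STD9/16); saliva = plasma ×
salivary partition ratio × device retention × lognormal noise; urine =
plasma × 10 × noise.  Non-taken drugs are zero in every matrix.  Typical
plasma levels are floored (`ensure_detectable`) so that an adherent intake is
detectable *at the median signal* in every matrix, mirroring a cohort whose
prescribed drugs were overwhelmingly detectable; individual noisy draws can
still fall below the LOD, so saliva false negatives arise for
strong-retention, low-partition drugs exactly as in practice.  The
`noiseless()` configuration (optionally with full device transmission) is a
correctness harness: any discordance under it signals a pipeline defect, not
a detectability artifact.

### What the generator does not emulate

No pharmacokinetics (absorption/elimination, time since dose), no salivary
pH or protein-binding mechanisms, no chromatographic artifacts (carry-over,
retention-time drift, interfering peaks beyond white blank noise), and no
correlation between a drug's physicochemical properties and its device
retention (none was observed empirically).  Passing tests therefore
demonstrate that the *computational* pipeline is correct and well-calibrated
under the stated statistical structure — not that the physical assay meets
its specifications on real samples.

## Numerical choices and degenerate inputs

* Fitting needs ≥3 distinct nominal levels (two coefficients + 1 d.o.f.).
* r² with zero weighted response variance raises an error rather than
  returning a conventional value.
* RSD needs ≥2 values and a non-zero mean; inter-day imprecision needs ≥2
  sessions.
* Zero-plasma pairs are excluded from ratio statistics with a warning.
* Quadratic root selection: the stable ±-form plus range membership
  `[0, 2·ULOQ]`; a discriminant below zero (response beyond the model
  maximum) raises an out-of-model error.
* All threshold comparisons are strict, matching "lower than 15%/20%"
  guideline wording; boundary cases are tested on both sides.

## Problem sizes

The test suite and the acceptance script run the full 16-analyte batch
(≈5800 injections), 500-seed calibration ensembles, 100-series limit
monotonicity sweeps and a 200-patient cohort; together they complete in a
few seconds on one CPU, so no scaled-down variants are needed.

## Known limitations

* REC/EE/ME estimates from a single batch carry ~1-point sampling error per
  analyte at the default layout; recovery of the generator truth is
  therefore asserted at the level of the estimator's expectation.
* The inter-day RSD convention (pooled vs session means) changes values by
  up to a few tenths of a point at these CVs; both are provided.
* Determined LLOQ/LOD depend on the blank-noise estimator (6 lots → ~30%
  relative error in the sd); they satisfy the decision rules but are not
  sharp estimates of the instrument's true limits.
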