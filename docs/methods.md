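# Methods

## The measurement model

`snogel` quantifies three per-protein-spot quantities from multiplexed
two-dimensional-electrophoresis (2DE) fluorescence data:

* **abundance** — BODIPY FL-maleimide (BD) labels reduced cysteine thiols.
  On an ascorbate-treated aliquot (Asc+) every S-nitrosylated cysteine is
  reduced back to a free thiol first, so the BD spot volume reports total
  cysteine content and hence protein abundance.
* **S-nitrosylation (SNO)** — on a neocuproine-stabilised aliquot (Asc−)
  nitrosylated cysteines stay blocked and escape labelling, so the BD
  volume is suppressed by the factor `1 − s`, where `s` is the spot's SNO
  fraction.
* **phosphorylation** — Pro-Q Diamond (PQD) stains phosphoproteins in the
  same gels after the BD scans. A fraction of BD fluorescence (~13%) bleeds
  into the PQD excitation/emission window; a pre-stain scan in that window
  measures the bleed-through per spot so it can be subtracted.

Every biological sample therefore produces one cognate gel pair (Asc+ and
Asc−), and the default design is 3 groups (control M0 plus treatments M1,
M2) × 4 biological replicates × 2 aliquots = 24 gels with ~995 spots.

## Normalisation

Loading differences are corrected by a total-volume bias factor
`b_gel = T_ref / T_gel`, where `T` is the summed raw spot volume of an
ascorbate-plus BD gel and `T_ref` that of a designated control-group
reference gel. Because loading is a property of the biological sample, the
Asc− gel and the spillover/PQD scans of a sample are normalised with the
factor of its *cognate Asc+ BD gel*, never their own totals (an own-total
variant exists behind `normalization: own_total` for sensitivity analysis).

Two consequences worth knowing:

* After normalisation all Asc+ totals equal `T_ref` exactly, and a pure
  loading change (scaling all of one sample's gels by any `c > 0`) leaves
  every downstream ratio unchanged.
* Total-volume normalisation assumes equal total protein per group. When
  treatment effects shift a group's true total, Δabundance and Δphospho
  acquire a small common multiplicative bias `S_ctl/S_exp`. The ratio of
  ratios is immune — the factors cancel. This is a property of the method
  itself, not of this implementation; the noiseless-identifiability tests
  use abundance-balanced ground truths (multiplier pairs `m` and `2 − m`
  on equal base abundance) so the expected values are exact.

## Ratiometrics

With group summaries taken as the arithmetic mean of per-replicate
normalised volumes (median available via config):

* `Δabundance = Asc+_exp / Asc+_ctl`
* `ΔSNO = Asc−_exp / Asc−_ctl`
* `RoR = ΔSNO / Δabundance` — abundance-corrected SNO change. Because SNO
  *blocks* BD labelling, a negative signed RoR means SNO increased.
* `Δphospho = PQDcorr_exp / PQDcorr_ctl`, where
  `PQDcorr = max(PQD_post − spill_scan, 0)` per spot (clamped values are
  counted and reported).

Ratios are reported with the signed-reciprocal convention `r ↦ r` if
`r ≥ 1` else `−1/r`, so no signed value falls in (−1, 1). When one group's
summary lies below the detection floor ε (default 1.0 raw volume unit) and
the other does not, the fold change is capped at +100 or −100; when both
are below ε the spot is flagged `both_low` and reported as +1. Capping is
keyed to the floor rather than literal zero because caps arise from
extremely low fluorescence, not exact zeros.

The spillover coefficient is also *estimated* (per-gel least-squares slope
through the origin of spill vs BD, pooled by volume-weighted mean, with
R²) purely as a QC diagnostic; the correction always subtracts the
measured scan.

## Statistics

Welch's unequal-variance t-test is applied to log2-transformed
replicate-level values per spot, measure and comparison (M1 vs M0,
M2 vs M0, M2 vs M1). The replicate-level value for SNO is the per-sample
ratio `Asc− / cognate Asc+`, the analogue of RoR at the replicate level;
volumes are floored at ε before the log, while the SNO ratios — which live
near 1, far below any volume floor — are floored only at the smallest
positive float. Degenerate inputs follow fixed conventions: zero variance
in both groups with equal means gives p = 1; with unequal means, a
denormal p sentinel plus a flag.

Benjamini–Hochberg step-up adjustment is applied per measure and per
comparison (one global family available via config), and a spot is called
significant when `|signed FC| ≥ 1.5` and `q ≤ 0.05` (gating on raw p
available via config, since "significance accepted at p ≤ 0.05" after an
FDR correction is ambiguous). Both `welch_t` and `benjamini_hochberg` are
implemented from their definitions and are verified against scipy and
statsmodels as independent references in the test suite.

Summary counts mirror the per-comparison tally of increased/decreased
spots per measure with the extreme signed fold changes; for SNO,
"increased" counts negative signed RoR.

## PCA

Gel-level PCA runs on log2 normalised volumes (mean-centred, covariance
PCA; unit-variance scaling optional) with observations = gels and
variables = spots. For the SNO channel the default input is the per-sample
Asc−/Asc+ ratio matrix (raw Asc− volumes via config). The package reports
percent variance per component and a quantitative grouping diagnostic: the
fraction of gels whose nearest neighbour in PC1–PC2 space belongs to the
same group (baseline for random labels with 3 groups of 4 is 3/11).

## The synthetic generator

`generate_ground_truth` plants per-spot, per-group true values: base
abundances (lognormal, median 2×10⁴ volume units, log-sd 1), baseline SNO
fractions (uniform 0.05–0.30), phospho levels (lognormal, median 5×10³),
and exactly `round(frac_differential × n_spots)` differential spots, each
perturbed in each requested measure in one random treatment group —
multiplicative fold effects (uniform in `effect_range`, random direction)
for abundance and phospho, additive shifts (uniform in `sno_range`) on the
SNO fraction. `simulate_experiment` then draws per-sample lognormal
loading factors (log-sd 0.10 by default), optional per-gel jitter,
per-observation lognormal noise with mean 1 (CV 0.10 by default — typical
replicate-level variation for fluorescent 2DE volumes), and a 13% BD
spillover signal. The spillover component appears identically in the
pre-stain scan and the post-stain PQD scan, because it is physically the
same fluorophore population imaged twice; scan-to-scan detector noise on
that shared component is not modelled.

Note an asymmetry of the additive SNO encoding: with baseline fractions of
0.05–0.30, a *decrease* in SNO moves the RoR ratio only modestly above 1
(e.g. 0.30 → 0.10 gives 0.90/0.70 ≈ 1.29, below the 1.5 selection
threshold), while an increase of the same size easily crosses it. Default
simulations therefore detect far more SNO increases than decreases in
treatment-vs-control comparisons; raise the baseline range if both
directions need comparable power.

What the simulation deliberately omits: electrophoretic artifacts
(streaking, spot trains, co-migration), gel-warping/alignment error (spot
correspondence is given by construction, mirroring the known-correspondence
contract of spot-matching software), saturation, and any coupling between
SNO and phosphorylation. Passing tests therefore demonstrate correctness
of the quantification arithmetic and calibration of the statistics under
the stated noise model — not robustness to misaligned or saturated gels.

## Gel images

The optional render/quantify stage writes spots as isotropic 2-D Gaussians
on a pI × log10(MW) grid (pH 3–11 left→right, high MW on top), with
per-pixel masses computed from CDF differences so each spot's integral
equals its volume to machine precision inside the frame. Quantification
integrates a disc of given radius (axis units) around supplied
coordinates after subtracting a constant background (median of pixels
outside all discs) and flags overlapping discs. Round-trip accuracy is
within 2% for separations ≥ 6σ and radius ≥ 4σ; a radius of 1σ recovers
only `1 − e^{−1/2}` ≈ 39% of a spot, so radii ≥ 3σ are recommended.
Images are written as 16-bit grayscale TIFF with the gain (counts per
volume unit, scaled so the brightest pixel reads ~60 000) and axis ranges
stored in the TIFF description.

## Problem sizes and numerics

The test suite and the acceptance script run the full design at its study
scale (24 gels, up to 1000 spots) and use 10–50 repeated simulations for
the error-rate properties — enough for the Monte-Carlo error on the
reported rates to sit well inside the asserted bands. Determinism: all
randomness flows through `numpy.random.default_rng` seeds carried in
`NoiseModel` and the generator arguments; identical seeds give
byte-identical TSV outputs. Tolerances: exactness claims are asserted at
1e−9 (they hold to ~1e−15); reference-implementation agreement at 1e−8;
image round-trips at the discretisation-limited 1–2%.

## Known limitations

* Total-volume normalisation bias under unbalanced composition (above).
* No moderated variance estimation; with n = 4 per group the Welch test is
  slightly conservative (null p ≤ 0.05 rate ≈ 0.04).
* The ±100 capping makes capped fold changes unusable as magnitudes; they
  are counted and flagged so analysts can see their prevalence.
* Spot correspondence is assumed known; no de-novo detection or
  registration is attempted.
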