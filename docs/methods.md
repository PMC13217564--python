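# Methods

This note documents the models, defaults and design choices behind
`edascreen`, and what the synthetic test bed does and does not establish.

## Concentration–response evaluation

Reporter-gene output is expressed as % of the positive control's maximal
effect. The default potency model is a straight line through the origin
fitted to the low-effect region (points with effect ≤ 30%), with
EC10 = 10 / slope. This low-effect linear derivation is standard for
reporter assays where only the onset of the curve is sampled: it needs no
plateau estimate, is robust at 4–11 concentration levels, and is linear in
the quantities the downstream equivalence arithmetic divides. A
log-logistic (Hill) fit is available via `fit_potency(..., model="loglogistic")`
for full curves. Goodness of fit is the uncentered R² of the through-origin
fit (centered R² for the log-logistic option).

IC10 mirrors EC10 on the cytotoxicity trace at absolute 10%, fitted the
same way on the sub-30% region. If cytotoxicity never reaches 10% within
the tested range, IC10 and SR = IC10/EC10 are reported *missing* — never 0
or infinite — with a "no cytotoxicity observed" annotation. An inactive
series (non-positive slope) carries an explicit flag rather than a
sentinel EC10.

Units are explicit tags checked at every call: extracts in sediment
equivalents (g/L, g/mL), single chemicals in molar (uM, nM, M) or mass
concentration (ug/L, mg/L). Any mixed-family call raises `UnitError`;
conversions happen only at function boundaries.

## Equivalence arithmetic and trigger values

* REF = EF × DF (g sediment dry weight per mL bioassay medium).
* BEQ_bio = EC10(B[a]P) / EC10(extract); TOC normalization divides by the
  organic-carbon fraction.
* TCDD-EQ converts to B[a]P-EQ by the ratio of the two reference EC10s.
* REP = EC10(B[a]P)/EC10(chemical); BEQ_chem = Σ REP_i·C_i is additive
  over any partition of the ledger.
* EBT_sediment = 10^logKoc × EBT_water / 1000 (L/kg_OC × ug/L → ug/g_OC).
* Concentration addition uses 1/EC10_mix = Σ p_i/EC10_i; the mixture of a
  compound with itself returns that compound's EC10 and the formula is
  permutation-invariant.

The reference potency of benzo[a]pyrene is carried in two published forms,
108 uM (molar, used for REP ratios) and 2.67 ug/L (mass concentration,
used for extract BEQ). The two printed values are dimensionally
inconsistent with each other (252.3 g/mol would give ~27 mg/L for 108 uM);
they are therefore treated as two independent reference inputs for their
respective unit families and never interconverted.

Censored (<MDL) concentrations contribute 0 to BEQ_chem by default — a
conservative lower bound on the explained effect — with an MDL/2
substitution option. Blank BEQ is reported as % of the sample BEQ and
subtracted only above 10%.

## Spectral matching and retention indexing

Match factors are 1000 × the cosine of weighted intensity vectors, weights
intensity^0.6 · m/z^3 — the classical optimum for EI library search;
exponents are configurable arguments. Peaks are paired greedily by nearest
m/z within 0.01 Th; unpaired peaks enter with zero on the other side, so
the score is symmetric, bounded by [0, 1000], and reaches 1000 exactly for
parallel vectors. The reverse match factor discards query peaks with no
partner in the reference before scoring, hence RMF ≥ MF always. The exact
scoring used by commercial library software is not public; the
700/700 screening thresholds are retained but absolute comparability with
vendor scores is not claimed. Tests pin the implementation to a
brute-force union-grid cosine and to matchms's `CosineGreedy` as
independent oracles.

Retention indices use the van den Dool–Kratz (temperature-programmed)
form, RI = 100·(n + Δn·(rt − rt_n)/(rt_{n+Δn} − rt_n)), because the
underlying GC methods are temperature-programmed; the logarithmic
isothermal form would be wrong there. No extrapolation outside the alkane
ladder; ladder gaps are flagged.

Candidate filtering is strict at the boundary (MF > 700, RMF > 700,
|ΔRI| < 200), matching the screening workflow's wording; ranking is by
descending (MF+RMF)/2, ties by smaller ΔRI, then lexicographic structure
id — fully deterministic. Feature prefiltering defaults (max area ≥ 1e5
counts, sample/blank ratio ≥ 10) are exposed in configuration since the
upstream protocol does not fix them.

Isomer groups are connected components of the "shares a top candidate"
graph; grouping is order-independent and conserves the feature count
(unique + grouped = input).

## QSAR models and applicability domain

Descriptor curation retains one representative per correlated group
(components of the |Pearson r| > 0.95 graph); the representative is the
column with the fewest missing values, ties broken by column index, so the
choice is deterministic and row-order invariant. Constant columns have no
defined correlation and are dropped with a warning.

Each surviving descriptor is min–max normalized on the training set; the
resulting unit box is the applicability domain. A prediction row is *in
domain* iff every normalized value lies in [0, 1]. Out-of-domain rows are
predicted but flagged — predictions are never withheld, mirroring how the
screening workflow treats its ~5% out-of-domain candidates. Missing
descriptor values are imputed with training medians before normalization.

Both models are XGBoost ensembles behind a scikit-learn estimator surface
(`fit`/`predict`/`get_params`, fitted attributes with trailing
underscores), so they compose with sklearn pipelines and model selection.
Defaults: 500 trees, depth 6, learning rate 0.05, single thread,
`scale_pos_weight` = negatives/positives for the classifier. The engine's
published description names versions but no hyperparameters; these
defaults are ordinary gradient-boosting practice at this data size. The
regressor trains on log10(EC10/uM) of actives only and back-transforms to
uM. Given (data, hyperparameters, seed), predictions are bit-for-bit
reproducible; persistence stores the raw booster, the normalization
bounds, the seed and a schema hash.

Activity re-calling from screening curves labels a molecule active iff its
maximal efficacy exceeds 10% of the reference compound *and* the
low-effect linear fit reaches R² ≥ 0.8 (configurable; the upstream
protocol says "good linear fit" without a number). Records with fewer
than four concentrations are excluded with a reason, not silently labeled.

Reported percentages (accuracy/precision/recall) are rounded half-up to
one decimal, with raw fractions retained; precision is missing, not zero,
when no positive call was made. ROC AUC is trapezoidal; PR AUC uses step
interpolation (average precision).

## Virtual fractionation and confidence levels

A unique feature is retained iff ≥ 1 of its surviving candidates (top 5
after thresholds) is predicted active; an isomer group is retained iff any
shared candidate is — the members cannot be distinguished by EI spectra
alone, so they are kept or dropped together. The operation is idempotent
and its funnel summary conserves counts. Identification confidence: CL1
needs a spectral match (MF ≥ 800) *and* RT match (|ΔRT| ≤ 0.1 min) against
an authentic standard; CL2 a library match within the RI tolerance; CL3
only externally supplied characteristic-ion evidence. The CL1 tolerances
are this package's choices; the source workflow states "matching" without
numbers.

## Quantification

The RT axis is partitioned into half-open, lower-inclusive
internal-standard windows ([0,12), [12,19), [19,∞) min by default, served
by acenaphthene-D10, PCB118-13C12 and benzo[a]pyrene-D12); the prose
"below 12 / between 12 and 19 / above 19" is ambiguous exactly at the
integers, and lower-inclusive is the convention here. Analyte areas are
divided by the window's IS area, which cancels any common multiplicative
drift (property-tested).

Calibration is ordinary least squares on (concentration, normalized area),
unweighted by default with a 1/x-weighted option for wide geometric level
ranges where relative noise dominates. Vial concentration =
(area − intercept)/slope; per-gram concentration scales by extract volume
over sample mass. The MDL defaults to the lowest calibration level, or
3 × SD of blank responses through the curve when blanks are supplied;
below-MDL results are censored records rendering as "<MDL", never bare
numbers. Surrogate semiquantification picks, within the feature's
structure-similarity group, the authentic standard with the closest RI
(minimizing response-factor error); authentic curves always take
precedence, and the surrogate path coincides exactly with the authentic
one when the group curve is the analyte's own. Coeluting isomers split
the shared peak equally, each share carrying the coeluter list as
provenance.

## Iceberg ledgers

Ledger entries are (REP, concentration) with beq = REP·C; measured REPs
take precedence over predicted ones, the source is recorded on every
entry, and `measured_only=True` drops predicted-REP entries for
confirmed-chemicals-only sums. Explained fraction = BEQ_chem/BEQ_bio in
percent, not capped at 100% (over-explanation is informative). Rankings
are descending beq with lexicographic tie-break and a cumulative-share
column.

## Synthetic test bed

`fixtures.gen_world(seed)` builds a complete, byte-reproducible study:
~60 structures with synthetic 6–10-peak EI spectra (random m/z 50–450),
retention indices on a C8–C32 alkane ladder, 10 uniform descriptors with
the planted rule *active iff d1 + d2 > 1* and planted potency
log10 EC10 = 2.5 − 1.5·d1 − 1.0·d2 + N(0, 0.2) (uM), triplicate
concentration–response series (1% absolute effect noise, 11-level 1:2
dilution series topping out at 25% effect), per-analyte calibration series
and feature areas with 2% relative noise and lognormal IS drift, and
per-sample planted concentrations scaled so BEQ_chem = 10 ug/g with
BEQ_bio = BEQ_chem / explained_target. Replicate EC10s are combined by
geometric mean; the desk-scale pipeline uses 1/x-weighted calibration
because the level range spans four orders of magnitude with relative
noise.

What passing proves: the matching, quantification, potency and ledger
arithmetic compose without bias at realistic noise levels — a planted 30%
explained fraction is recovered within ±3 points end to end. What it does
not prove: anything about real EI fragmentation, real descriptor-activity
relationships, matrix effects, or chromatographic coelution; spectra are
abstract peak sets and descriptors are abstract coordinates. Real-data
performance must be established on real data.

Problem sizes in the default suite and acceptance script (2000 molecules
for the classifier, 400 for the regressor, 200 simulated curves, 3-sample
worlds with 60 structures) are the package's chosen desk scale; all runs
are seeded and complete in seconds.

## Known limitations

* The linear EC10 model is only valid when the sampled effects actually
  lie in the near-linear onset region; strongly supralinear curves need
  the log-logistic option.
* MF/RMF values are internally consistent but not numerically identical
  to commercial library scores.
* The applicability domain is an axis-aligned bounding box; it flags
  extrapolation per descriptor, not density holes inside the box.
* Semiquantification inherits the surrogate's response factor; errors of
  severalfold are possible and the `method` field keeps them visible.
* CL3 evidence is accepted from the caller, not derived; manual
  characteristic-ion workflows are out of scope.
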