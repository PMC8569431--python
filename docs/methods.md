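# Methods

`fluctevo` implements a complete, testable version of the analysis chain
used in batch-culture laboratory evolution of *E. coli* under fluctuating
temperatures: a serial-passage simulator with density- and time-triggered
temperature switching, growth-rate phenotyping with generalist/specialist
classification, gene-level mutation parallelism statistics, and a
phenotype-microarray "restoration" analysis that asks whether evolved
strains move back toward the ancestor's unstressed physiological state.
This note records the models, the parameter choices, and the places where
the procedure was genuinely open and a concrete rule had to be fixed.

## 1. Growth law and the serial-passage simulator

Within a constant-temperature segment a culture follows the Zwietering
parameterisation of the modified Gompertz law in log-OD,

    log OD(t) / OD_ref  =  A · exp( − exp( μ·e/A · (λ − t) + 1 ) ),

where `A` is the asymptotic log fold-increase (nat log of
capacity/inoculum), `μ` (min⁻¹) the maximum slope of log-OD — the maximum
specific growth rate — and `λ` (min) the lag.  This form is used because
its `μ` *is* the quantity the growth module estimates, so simulator truth
and estimator target coincide by construction.

Switching regimes between 15 °C and 43 °C:

* **slow** — switch once per cycle when the noiseless culture density
  crosses OD₈₃₀ = 0.25;
* **fast** — switch at OD₈₃₀ = 0.15, 0.30 and 0.45 (three switches per
  cycle);
* **random** — switch after a residence time drawn uniformly from 3–5 h at
  43 °C and 5–15 h at 15 °C, independent of density (the longer cold
  residence roughly balances generations across temperatures).

At a switch the curve is **re-anchored**: the culture continues along the
new temperature's Gompertz curve from its current density (the time offset
on the new curve is found by the closed-form inverse), so OD is continuous
and the subsequent maximum log-slope is the new temperature's `μ`.  A
configurable secondary lag (default 0 min) can hold the culture flat after
a shift; the default is no post-shift lag, consistent with transitions
that take well under one generation.  Temperature transitions are modelled
as instantaneous.

A cycle ends "just before stationary phase", operationalised as the
noiseless OD reaching **95 % of the active temperature's capacity**; the
culture is then diluted 100 µL into 20 mL (factor 201) and the next cycle
begins at the temperature the previous one ended at (start-temperature
alternation).  In the random regime the stationary trigger ends the cycle
regardless of the residence-time schedule.  Samples are taken on a 4-min
grid with additive Gaussian OD noise (truncated at 10⁻⁴ to keep OD
positive); switch/transfer events are recorded at the exact continuous
trigger times of the noiseless curve.

An optional per-strain **carry-over modifier** rescales `μ` at a
temperature conditional on the previous segment's temperature.  A modifier
below 1 at (15 °C | previous 15 °C) reproduces the "internalised
fluctuation" phenotype: such a strain grows faster at 15 °C only when the
preceding segment was hot.

**Generation accounting.**  How generations were counted in the original
experiment is not derivable from the record, so the ledger carries both
accountings and reports them separately: *OD-based* (per-segment
`g = log₂(OD_end/OD_start)`, clipped at 0, additive over segments) and
*dilution-based* (`log₂ 201 ≈ 7.65` per completed transfer).  At steady
state the two agree up to the capacity difference between the two
temperatures.

**Default strain parameters** (glucose minimal medium):
`μ = 0.0019 / 0.0140 / 0.0100 min⁻¹`, `λ = 300 / 90 / 120 min`,
capacity `0.52 / 0.58 / 0.55` OD₈₃₀ at 15/37/43 °C, OD noise SD 0.002.
These give doubling times of roughly 6 h in the cold, 50 min at the
optimum and 70 min at the hot edge — the ordering and scale a
microbiologist would expect for *E. coli* B at these temperatures — and a
slow-regime cycle of ~3.5 days starting cold.  Inoculum OD defaults to
0.0025 (capacity/201, the self-consistent serial-passage value).

## 2. Growth-rate estimation

`estimate_growth_rate` fits a cubic smoothing spline S(t) to the OD series
over a ~2,500-min analysis window and reports

    μ̂ = max_t  S′(t) / S(t)   =  max_t  d log S / dt ,

the maximum derivative of log-OD, evaluated only where the fitted curve
clears a noise floor (max of 0.005 OD and five robust residual SDs).  Two
numerical choices matter and were made deliberately:

* **Fit on the OD scale, not log-OD.**  Plate-reader noise is additive in
  OD, hence wildly heteroscedastic in log-OD at low density; splines
  fitted to log-OD (weighted or not) were unstable exactly in the region
  where the log-slope peaks.  Fitting S(t) to OD (homoscedastic) and
  differentiating log S gives the same target quantity with far better
  conditioning.
* **Smoothing by cross-validation with the 1-SE rule.**  The penalty is
  chosen on a fixed log-spaced grid (10⁰–10¹⁰) by interleaved 3-fold CV,
  taking the *largest* penalty within one standard error of the CV
  minimum.  Prediction error is nearly flat over a wide penalty range
  while the derivative is not; the 1-SE rule acts as the floor that
  prevents the spline from interpolating noise.  The grid's lower end
  bounds the penalty from below.

Measured on the generator itself (200 curves, μ ∈ [0.001, 0.02] min⁻¹,
noise SD ∈ [0, 0.005], the problem size also used by the acceptance
script): median relative error ≈ 3 %, 90th percentile ≈ 9 %.  A raw-OD
derivative mode (`log_scale=False`) exists for comparison only.
Degenerate inputs: a perfectly flat series returns μ̂ = 0; a declining
series returns μ̂ ≤ 0 with a warning flag rather than an error.

`fit_gompertz` cross-checks the spline by nonlinear least squares on the
same log-OD model (deterministic initialisation: λ from the first doubling
of the inoculum, μ from the spline, A from the observed range).  On
noiseless self-generated curves it recovers parameters to machine
precision; on noisy curves the two estimators agree to within ~10 %
median.  Non-convergence raises an error carrying the initial values.

## 3. Relative growth and strategy classification

For each evolved strain and temperature the relative growth rate is
`mean(evolved μ̂ replicates) / mean(ancestor μ̂ replicates)`, tested with a
two-sample t whose variance is pooled across **all** replicate groups
measured at that temperature:

    t = (x̄₁ − x̄₀) / ( s_p · √(1/n₁ + 1/n₀) ),
    s_p² = Σᵢ Σⱼ (xᵢⱼ − x̄ᵢ)² / Σᵢ (nᵢ − 1),    df = Σᵢ (nᵢ − 1).

Pooling everything measured at the temperature (the default; a switch
restricts the pool to the compared pair) buys degrees of freedom that
triplicate designs sorely need; with only the two compared groups in the
pool the statistic reduces exactly to the classical equal-variance
two-sample t.  Tests are two-sided; direction enters only in
classification:

* **generalist** — significant increase (p < α and ratio > 1) at both
  15 °C and 43 °C;
* **specialist_15 / specialist_43** — significant increase at exactly that
  temperature.  A significant *decrease* at the other temperature neither
  creates a specialist call nor vetoes this one;
* **not_significant** — otherwise.

The "at least 15 % / 30 % increase" phrasing sometimes attached to these
definitions is treated as a descriptive consequence of the significance
rule at realistic replicate numbers, not as an extra threshold; a strict
mode applies ratio ≥ 1.15 (15 °C) and ≥ 1.30 (43 °C) as additional gates.
Under a null with 26 groups of 3 replicates the per-temperature rejection
rate is the nominal 5 % and P(generalist) factorises into the product of
the one-sided per-temperature rates (both verified at 10⁴ simulations).

Group-level contrasts: generalist enrichment between regime classes by
two-sided Fisher exact (p from summing hypergeometric outcomes no more
probable than the observed table) and relative-growth variance between
regime classes by the two-sided F test.

## 4. Mutation statistics

Population calls below **5 % frequency** are dropped (boundary kept; clone
calls pass untouched).  Calls collapse to a binary gene × strain incidence
matrix: multi-gene deletions/amplifications count once and are attributed
to their declared **anchor gene** — anchoring must be supplied in the
table, never inferred, to avoid silent misattribution — and repeated hits
to one gene in one strain give incidence 1 while the multiplicity is kept
in a parallel count table.  Population and clone tables are analysed
separately, never mixed.

Enrichment between two strain groups uses the pooled two-proportion
z-test per gene, restricted to genes mutated in ≥ 3 strains, two-sided by
default, with Benjamini–Hochberg FDR across the tested genes (the FDR
procedure had to be fixed; BH is the standard choice and reproduces the
expected p→q inflation at these gene counts).  Per-class and per-category
count comparisons use the one-sided Mann–Whitney U, **exact by
enumeration up to combined n = 24** — implemented as a counting DP over
doubled mid-ranks, so ties are handled exactly and two groups of 12 (the
design's size) are still exact — with a tie- and continuity-corrected
normal approximation beyond.  All-tied inputs return p = 1 with a
degeneracy flag.  Mutation counts per strain are normalised by the
ledger's generation totals before group comparison (pooled t by default,
Welch behind a flag).

A GenomeDiff reader maps SNP/INS/DEL/MOB/AMP lines onto the call schema
(deletions ≥ 50 bp become `large_deletion`, MOB → `IS_insertion`,
AMP → `amplification`); functional categories (heat shock, cold shock,
both, regulatory, membrane/cell wall, metabolic, transporter, other) are
user-supplied, multi-label, defaulting to `other`.

## 5. Phenotype-array restoration analysis

A GEN III plate yields 96 endpoint OD₅₉₀ values.  The default layout puts
the negative control at well 1, 70 metabolic wells at 2–71, the positive
control at 72, and 22 chemical-sensitivity wells at 73–96 minus the two
tetrazolium-dye wells 86 and 94; only the dye-well numbers are pinned by
the instrument report, so the layout is explicit and overridable.
Normalisation: metabolic feature = well − NC, chemical feature =
PC − well; controls and dye wells are dropped, leaving **92 features**.
Both normalisations are differences, so plate-wide offsets cancel.

**Replicate QC.**  "Inconsistent" wells needed a concrete rule.  A
within-replicate-set rule of the form |x − mean| > k·SD can never fire:
the studentised residual from the replicate mean is bounded by
(n−1)/√n ≈ 1.15 at n = 3.  The implemented rule is leave-one-out: flag
well w of replicate r when it deviates from the mean of the remaining
replicates by more than 4× their SD, floored at 0.05 OD so two
near-identical remaining replicates do not trigger on noise.  Flagged
wells are imputed from the unflagged replicates' mean.  With exactly two
replicates a disagreement flags both; the tie breaks against the
replicate in which the well is also an outlier within its own plate
(robust row z-score).  Three or more replicates all flagging a well is
unresolvable and raises.

**Embedding.**  Features are column-centred (not scaled — the features
share units) and embedded by PCA.  Components are retained by the
broken-stick rule, `b_k = (1/p)·Σ_{i=k..p} 1/i`, keeping the leading run
of components whose variance share exceeds `b_k`; the "talus" drop (the
largest gap between consecutive log-eigenvalues) is computed as a
diagnostic, and when the two disagree the retained count defaults to 3.
Ancestor reference states are the k-means (k = 1) centroids — identically
the arithmetic means — of the ancestor replicate scores per lineage and
temperature (a pooled mode exists), with replicate dispersions kept.

**Classification.**  For each evolved strain, stress temperature
T ∈ {15, 43} and retained component, three t-tests are formed on component
scores: ancestral plasticity D_a (ancestor-at-T vs ancestor-at-37
replicates), evolved movement D_s (evolved vs ancestor-at-T), and distance
from optimum D_o (evolved vs ancestor-at-37).  Tests are pooled-variance
by default (technical replicates share measurement noise; Welch behind a
flag).  FWER is controlled by Holm (Bonferroni optional) per
strain × temperature family across the components' D_s and D_o tests, and
per temperature across components for D_a; whether the family should also
span strains is undecidable from the record — components-only is the
default.  The seven mutually exclusive categories then follow the
significance pattern and the position of the evolved mean E relative to
the ancestor's stressed state A_s and optimum state A_o:
uninformative (¬D_a, ¬D_s), novel (¬D_a, D_s), unrestored (D_a, ¬D_s),
restored (D_a, D_s, ¬D_o), and with all three significant:
partially restored (E strictly between), over-restored (beyond A_o, away
from A_s), reinforced (beyond A_s, away from A_o).  The first three
collapse to "restorative".  The rule is exhaustive and exclusive over all
patterns (verified by enumeration) and equivariant under component sign
flips.  The decision boundaries themselves are this package's
operationalisation of a verbally described scheme; alternative boundary
conventions (e.g. distance-ratio thresholds for partial restoration) would
slot in behind `classify_component`.

A strain × temperature **headline** call is the collapsed category of the
majority of informative components, ties broken toward the less
restorative side (order: restorative > reinforced > novel > unrestored),
a deliberately conservative aggregation.  Group comparisons reuse the
shared kernels: Fisher exact on category presence between the two stress
temperatures, one-sided Mann–Whitney on per-strain category counts
between strain groups.  Sample clustering is Ward linkage on Euclidean
distances of the centred 92-feature matrix, serialised to Newick with
branch lengths from the merge heights.

## 6. What the synthetic data emulates — and what it does not

The generators define the study conditions the tests run under:

* **Trajectories** reproduce the switching rules, 4-min sampling, transfer
  and dilution arithmetic, and measurement noise.  They do not model
  evolution within the run: growth parameters are fixed per strain, there
  are no lineage dynamics, no death phase, and mutation tables are drawn
  independently of growth parameters (no mutation–phenotype coupling).
* **Mutation tables** draw per-gene Bernoulli hits with group-specific
  probabilities (lineage, regime, lineage × regime), a class distribution
  over the eight mutation classes, uniform population frequencies on
  [0.1, 1], and an optional Poisson multi-hit rate (used for the
  protease-gene plant).  Linkage, clonal interference and shared-ancestry
  correlation between strains are absent — so passing enrichment tests
  shows calibration and power on independent draws, not robustness to
  phylogenetic confounding.
* **Plates** plant ground truth geometrically.  Two orthonormal
  directions in feature space are drawn with zero sum within the
  metabolic and chemical blocks, so control-well noise does not project
  onto them and the replicate score noise equals the per-well SD exactly;
  `u1` carries ancestral plasticity (ancestor at stress T sits at
  ±2·effect·σ along u1), `u2` carries "novel" movement (sign alternating
  across strains so the two directions stay uncorrelated in the sample and
  PCA does not rotate the basis).  Category positions are spaced so every
  distance the classifier must resolve is at least `effect` replicate-noise
  SDs — one knob governs recovery.  Control and dye wells are generated
  noiseless by default (`control_noise_sd = 0`): a shared control-well
  error is a plate-level nuisance offset, and at equal noise it creates a
  rank-one common-mode component comparable in variance to the planted
  signal, which is an artefact of the difference normalisation rather
  than a phenotype.  Real plates will sit between these extremes; the
  recovery rates measured here are therefore upper bounds for data with
  correlated well noise.

Default design: 24 evolved strains × 3 temperatures × 3 technical
replicates + 2 ancestors × 3 temperatures × 6 replicates = 252 plates;
effect size 5 σ; well noise SD 0.02 OD.  At these conditions ≈ 98–99 % of
planted categories are recovered on their carrying component (200 seeds);
recovery degrades smoothly as the effect shrinks and collapses to the
uninformative/unrestored null pattern at effect 0.

## 7. Problem sizes and determinism

All randomness flows from explicit integer seeds; the experiment simulator
spawns one child stream per population, and the pipeline derives per-stage
seeds from the top-level seed by folding in a CRC of the stage name, so
stages are independently reproducible and the consolidated report is
hash-stable under a fixed config + seed.  The shipped analyses use
problem sizes chosen to keep a full run in minutes on one core: 2–3 cycles
per population for the simulation tables, 200 curves for spline recovery,
10⁴ simulations for null calibration, 100–200 seeds for restoration
recovery.  All are parameters, not constants.

## 8. Known limitations

* The Gompertz re-anchoring assumes the culture's state is summarised by
  its density; physiological memory of the previous temperature is only
  captured through the explicit carry-over modifier.
* The spline estimator's μ̂ has a small upward bias (max of a noisy
  ratio); it largely cancels in relative growth rates, which is the
  quantity the classification consumes.
* The restoration rule tests component means; strains with bimodal
  replicate behaviour would need a different test family.
* Enrichment statistics treat strains as independent; replicate
  populations from one founder violate this mildly, as in the original
  design.
* The Mann–Whitney normal approximation (combined n > 24) with heavy ties
  is conservative rather than exact.
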