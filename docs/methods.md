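# Methods

This note records the statistical procedures implemented in `sextme`,
the choices made where the design was genuinely open, and what the
synthetic-cohort tests do and do not establish about real data.

## Cohort assembly

Samples enter a cohort when they are 18–85 years old inclusive, have a
known sex, appear in the expression matrix, and carry a true
`immune_infiltrated` flag.  That flag stands in for an upstream
deconvolution-based inclusion call (empirical P < 0.05 for the presence
of immune infiltrate); the package does not recompute it, and defaults it
to true (with a warning) when the column is absent.  Genes whose
zero-expression fraction strictly exceeds 0.9 are removed *after* sample
filtering — the ordering is a package choice; the boundary (exactly 90%
zeros) is kept, by a literal reading of "> 90%".  Surviving FPKM values
are log2(x+1)-transformed.  Sample identifiers are matched by exact
string equality after whitespace trimming; barcode vial/portion suffixes
are not parsed.  Sex-bias tests warn (rather than fail) below 10 samples
per sex.

## TME feature scores

**TMB.**  Count of records in the nine non-silent classes
(nonsense, missense, splice-site, stop-codon read-through, start-codon
change, frame-shift ins/del, in-frame ins/del) divided by 38 Mb, the
usual whole-exome coding-length estimate.  The denominator is fixed by
default and overridable per call (`length_mb`).

**Single-sample enrichment (ssGSEA).**  Per sample, genes are ranked by
expression descending, ties broken by gene token ascending (this makes
scores bit-reproducible; expression ties are rare in FPKM data).  The
gene at list position *p* of *N* carries rank *N − p + 1*.  In-set
positions step up by rank^α normalized to the in-set total (α = 0.25, the
standard single-sample weighting); out-of-set positions step down
uniformly by 1/(N − |G|).  The enrichment score is the *sum* of the
running difference over all positions (the integrated form), not the
maximal deviation.  No cross-sample rescaling is applied, so absolute
magnitudes are comparable only within a matrix; every downstream use is
either rank-based or within-cohort, which is unaffected by monotone
per-feature rescaling.  A set covering the whole matrix, or none of it,
is an error; per-signature overlap counts are logged.

**Compartment scores and purity.**  Immune and stromal scores are the
same statistic applied to two compartment signatures supplied by the
user; their sum feeds the published non-linear purity calibration
`cos(0.6049872018 + 0.0001467884 · score)`.  Values outside [0, 1] are
clamped (and logged); the original calibration leaves them undefined.

## Sex-bias tests and the strong/weak call

Summary scores (TMB, immune, stromal, purity) use the two-sided Wilcoxon
rank-sum test — exact enumeration when both groups are below 8 and
tie-free, otherwise the tie- and continuity-corrected normal
approximation.  Cells and checkpoint genes use Welch's unequal-variance
*t* with the female-minus-male sign convention (positive t = female
biased); Welch rather than pooled-variance because it is the safer
default when group spreads differ.  P-values are Benjamini–Hochberg
adjusted *within* each family (cells; checkpoint genes; pathways),
matching the per-analysis FDR < 0.25 thresholds.

A cancer is classified **strong sex-biased** when at least 4 of 7 flags
hold: the four summary-score tests at P < 0.05, plus one flag per family
(cells, checkpoint genes, pathways) that is true when at least one
member passes FDR < 0.25.  The threshold "at least one member" is a
package choice — the classification rule reports family fractions but no
published cutoff converts a fraction into a flag; any positive fraction
is the most permissive coherent reading, and the fractions themselves
are always reported alongside the call.

## Differential correlation (Fisher transformation)

Within each sex, TMB is correlated with each feature by Spearman's ρ
(average ranks for ties — TMB ties are common at low mutation counts).
Significance of a single ρ uses the t approximation
t = r·√((n−2)/(1−r²)) on n−2 df; an exact enumeration mode exists for
n ≤ 8.  The two coefficients are compared with
z = (atanh r_m − atanh r_f)/√(1/(n₁−3) + 1/(n₂−3)) referred to the
standard normal.  **Sidedness:** the reported `p_diff` is the upper-tail
probability of |z| — a one-sided convention.  This is deliberate: the
reference worked example this module reproduces (r 0.04 vs −0.36 at
n 83/29, printed P = 0.03) is consistent only with the one-sided reading
(|z| ≈ 1.85; two-sided would give 0.065).  The two-sided alternative is
one flag away (`two_sided=True`, CLI `--two-sided`).  A testable
consequence, asserted in the suite: under equal-correlation nulls the
rate of `p_diff < α` is ≈ 2α.  No multiplicity adjustment is applied
across features here; the workflow reports raw P < 0.05.

## Permutation GSEA

Genes are ranked by the vectorized Welch t (female − male);
zero-variance genes get t = 0 and a flag.  The enrichment score is the
classic signed maximal deviation of the weighted KS running sum (hit
steps |t|^w normalized, w = 1; miss steps uniform).  The null is
**sex-label permutation** with the full ranking recomputed per
permutation, preserving gene–gene correlation (a gene-permutation null
would ignore it).  With B permutations, for each pathway the same-sign
null pool gives `p = (1 + #{|ES₀| ≥ |ES|}) / (1 + #same-sign)` (the
pseudocount avoids zero P at finite B) and `NES = ES / mean|ES₀|`;
FDR is the sign-pooled ratio of null-NES to observed-NES tail fractions,
capped at 1.  Results are bit-reproducible given the seed.

## Mutation analyses

The binary mutation matrix marks (gene, sample) pairs with ≥ 1
non-silent record; genes are kept at mutation frequency strictly above
5%.  Sex bias per gene is a 2×2 Pearson chi-square; "continuity
correction if needed" is operationalized as Yates whenever any expected
cell count is below 5 (the common convention; logged per gene), with BH
adjustment and FDR < 0.25 calls.  The mutation→cell association fits,
per flagged gene, a logistic regression with **mutation status as the
outcome** and all standardized cell scores as joint predictors — a
binary variable can only be the outcome in a logistic model, so this is
the coherent direction for "the effect of mutations on cells"; the
reported up/down in mutated patients comes from the coefficient sign.
Standardizing predictors makes coefficients comparable across cells.
Non-converged fits (perfect separation, singular Hessians) are excluded
with warnings rather than reported.

## Survival models

Cox fits maximize the Efron-tie partial likelihood by Newton iteration
(the lifelines defaults; tie handling is not otherwise specified by the
workflow, and Efron is the accurate common default).  The per-sex screen
runs one univariate fit per cell; cells at Wald P < 0.05 form the
signature with their **univariate** coefficients — the risk score
Σ β_k·a_k deliberately does not refit jointly.  The median split sends
ties to the low-risk group (deterministic; logged).  Log-rank uses the
1-df hypergeometric-variance chi-square; an exact complete-relabeling
mode (own O/E/V statistic, total n ≤ 12) exists because the chi-square
tail is off the exact permutation distribution by up to ~0.08 at n = 8.
The multivariable adjustment fits risk score + age + ordinal stage
(I→1 … IV→4, trailing A/B/C substage letters dropped; missing stage
drops the patient from that fit only), with an explicit rank check that
names collinear columns.  Validation cohorts can reuse trained betas via
the CLI `--betas` option instead of refitting.

## ICB response

AUC per sex stratum is the Mann–Whitney probability that a responder's
TMB exceeds a non-responder's, ties at half credit; response labels are
consumed pre-dichotomized.  Strata missing a class are skipped.

## Synthetic cohorts: what they emulate, and what they don't

Each patient carries a latent Gaussian log-abundance per cell
(SD 1; log-normal abundance), with configurable female mean shifts.
Signature genes respond linearly in log2-expression (1.0 log2 units per
latent SD by default — a realistic marker-gene response), on a
log-normal baseline (mean 3, SD 1.5 in log2 FPKM) with noise SD 0.5;
values are exponentiated to FPKM scale, and the lowest 5% are zeroed to
exercise the zero filter.  Non-silent mutations are per-gene Bernoulli
(background rate 0.08 over 300 genes → TMB ≈ 0.7/Mb) with a log-normal
per-patient rate factor (σ = 0.8) coupled to the latent immune mean
through a Gaussian copula, so the within-sex TMB–immune correlation is a
direct dial; independent silent records (rate 0.01) exercise the
non-silent filters.  Survival is exponential with log-hazard
Σ γ_k·latent_k over a 1/1500-per-day baseline and uniform censoring
tuned by bisection to the target fraction (0.3).  Response is Bernoulli
logistic in TMB with per-sex slopes (0.3 male / 0.8 female, intercept
−1), reproducing a female-favored AUC by construction.

Deliberate simplifications: signatures are mutually disjoint (real
marker sets overlap — disjointness makes recovery attribution
unambiguous); expression margins are log-normal rather than
TCGA-realistic; mutations are independent across genes; no batch
effects, copy number, or sample-purity confounding.  Passing
planted-effect tests therefore demonstrates that the statistics recover
the effects they target under their own assumptions — not that those
assumptions hold in any particular tumor cohort.

## Problem sizes and runtime choices in the test suite

The calibration and recovery tests run at the sizes the package
documents as its study conditions: 24 cells × 30-gene signatures ×
1000 genes; n = 100/100 per sex (20 seeds for power, 100 cohorts for
null calibration); n = 300 per stratum × 50 seeds for the survival
recovery; 2000 replicates for the differential-correlation null;
1000 sex-label permutations for the planted-pathway GSEA check and 200
for the 100-set uniformity check.  All randomness flows from single
integer seeds through `numpy.random.SeedSequence` spawning, so every
table in the pipeline is reproducible byte-for-byte.

## Known limitations

* ssGSEA scores are not min–max normalized across samples, so absolute
  magnitudes are not comparable across matrices or to other
  implementations; within-cohort inference is unaffected.
* The one-sided `p_diff` convention doubles the nominal flag rate
  relative to a two-sided test; users wanting strict two-sided inference
  must pass the flag.
* The chi-square log-rank P is anti-conservative at very small n; use
  `exact=True` below a dozen patients.
* The purity calibration is a fixed published curve; it is not refit to
  the data at hand.
* Upstream deconvolution (the infiltration filter) and the content of
  marker/pathway/checkpoint gene lists are inputs, not outputs, of this
  package.
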