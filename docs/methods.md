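# Methods

`crcgerm` implements a two-track triage-and-classification analysis for
germline variants found by panel or exome sequencing in colorectal-cancer
(CRC) cohorts, together with the population-genetic and clinical
association statistics such a study reports, and a transcript-arithmetic
calculator for aberrant splice events. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
cohort generator does and does not emulate.

## Track A: rarity triage and ACMG/AMP classification

Track A retains candidate disease variants by a conjunction of gates and
hands them to the evidence-combining engine.

**Gates** (`crcgerm.triage`):

* *Rarity*: global minor allele frequency (MAF) ≤ `maf_threshold`
  (default 0.01, inclusive). A variant with no database frequency passes
  by default (`maf_missing_passes=True`): truly novel variants have no
  recorded MAF and must survive.
* *Routing by effect class*: nonsense, frameshift and canonical
  splice-site changes are loss-of-function; in-frame indels are retained
  on rarity alone; synonymous and unclassified effects are excluded from
  this track (they can still be flagged by track B).
* *Splice gate*: splice-site variants additionally need support from the
  ADA/RF ensemble splice scores, cut-off 0.6 inclusive. The published
  wording of such filters rarely states AND vs OR; the default passes on
  the best available score (OR), favouring sensitivity at triage, and
  `splice_require_both=True` switches to the conjunction. Both scores
  missing never passes — absence of evidence is not evidence of impact.
* *Missense vote*: at least `min_votes` (default 3) of the six fixed
  in-silico predictors (SIFT, Polyphen2, MutationTaster,
  MutationAssessor, FATHMM, FATHMM-MKL) must call the variant
  deleterious. Missing calls count against the variant: the denominator
  stays six, matching the "3 of 6" formulation of the rule.

**Evidence combining** (`crcgerm.acmg`): evidence codes follow the
standard ACMG/AMP grammar (PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4, BP1–7),
with strength fixed by prefix (no code-level up/down-grading). The
combining rules are the standard ones: e.g. Pathogenic requires PVS1 plus
one strong / two moderate / one moderate and one supporting / two
supporting, or two strong, or one strong with enough moderate+supporting
evidence; Likely pathogenic, Benign and Likely benign analogously;
anything else is a variant of uncertain significance (VUS).

Mixed evidence is policy-controlled. The guideline default demotes any
set containing both pathogenic-side and benign-side codes to VUS
(`strict_vus`). Clinical call sets, however, frequently report a
pathogenic verdict despite an isolated benign-supporting (BP) code;
`override_bp` — the package default — keeps the pathogenic-side verdict
and sets `conflict=True`. The packaged 13-variant reference call set
contains two such rows (a BP1 and a BP4 co-occurrence) printed as
Pathogenic / Likely pathogenic, which is why `override_bp` is the
default; both behaviours are first-class and tested. Under `override_bp`
a *benign* combination co-occurring with insufficient pathogenic-side
evidence is still demoted to VUS — the override is asymmetric by design,
so adding pathogenic-side evidence can never move a verdict toward
benign (a tested monotonicity invariant).

## Track B: driver-score flagging

Track B takes variants with global MAF strictly below 0.05 (missing MAF
passes) that carry at least one per-tumour-type driver score, and flags a
variant as an oncodriver when its score reaches the decision threshold.
The threshold defaults to 0.5 — the natural boundary of a calibrated
probability-like classifier output; the upstream score release prints no
cut-off — and is configurable and echoed in every report. The colorectal
model ("COREAD") is preferred when a variant is scored in several tumour
types; otherwise the best-scoring tumour type is used deterministically
(ties broken alphabetically). A variant counts once per gene in the
summaries regardless of how many tumour types scored it.

## Concordance benchmarking

`crcgerm.concordance` measures how well a continuous driver score ranks
variants against an external three-class missense-pathogenicity label
(likely benign / ambiguous / likely pathogenic):

1. *Binarisation*: the default policy is benign vs non-benign
   (`nonbenign_positive`: ambiguous is positive), which matches the
   benign/non-benign dichotomy such benchmarks describe;
   `pathogenic_only` and `exclude_ambiguous` are available because the
   treatment of the ambiguous class is rarely stated.
2. *Curve and area*: per (gene, tumour type) stratum, a precision-recall
   curve over all score thresholds with ties grouped. The default area
   estimator is step-wise average precision, AP = Σ_k (R_k − R_{k−1})
   P_k; trapezoidal interpolation is available but linear interpolation
   of precision is optimistically biased, so it is not the default. For
   an uninformative ranker AP converges to the positive-class prevalence
   (a tested property). Strata with a single class have no defined curve
   and are dropped with a warning.
3. *Aggregation*: per gene, the unweighted mean over tumour types
   (variant-count weighting available); overall and panel-restricted
   means, min and max over genes.

External score tables are joined on (chrom, pos, REF, ALT) with
upper-cased alleles; the two public releases this is designed for are
built on *different* genome assemblies, so coordinate liftover is the
caller's responsibility and is deliberately out of scope. Reproducing
the published external-data AUCs requires those multi-GB downloads and
is provided as the opt-in `scripts/validate_external.py`, not as part of
the desk-scale test suite.

## Population-genetic and clinical statistics

* `popgen.hwe_chi2`: chi-square goodness of fit to Hardy-Weinberg
  proportions with 1 df (three genotype classes, one estimated allele
  frequency). Zero-expectation cells (monomorphic sites) contribute
  nothing and set a degeneracy flag rather than raising. Under exact HWE
  sampling at n=500 the empirical type-I error at α=0.05 is 0.051
  (10,000 replicates, seeded) — the calibration is asserted in the test
  suite at 0.05 ± 0.01.
* `popgen.freq_compare`: 2×2 allele-count table (case vs reference
  population), Pearson chi-square with optional Yates continuity
  correction. Reference allele counts are reconstructed from frequency ×
  allele number when only frequencies are published.
* `cohort`: the clinical bivariate analysis tests each categorical
  variable against the age-at-diagnosis split (< 50 vs ≥ 50 years,
  configurable). Binary variables give one 2×2 table; multi-level
  variables are expanded one-vs-rest per level; `unknown` values are
  excluded before testing by default (this choice reproduces the
  published family-history row at n=92). Both the uncorrected and the
  Yates-corrected p-value are reported; the correction can only increase
  p (tested invariant). A pooled R×2 chi-square is available for
  multi-level blocks but no inference is built on it, because the table
  construction behind a single pooled p-value over sparse levels is
  ambiguous.

All chi-square machinery delegates to `scipy.stats`; the test suite
cross-checks every statistic against independently written textbook
formulas to 1e−9 over 1,000 random inputs.

## Splice-consequence arithmetic

`crcgerm.splicing` computes the coding consequence of an exon skip or an
intron retention purely from length arithmetic: Δbp = −(exon length) for
a skip, +retained length for a retention; the consequence is an in-frame
deletion (Δbp < 0, Δbp ≡ 0 mod 3, removing |Δbp|/3 residues), a
frameshift (Δbp ≢ 0 mod 3), or the identity. A 5′-UTR portion of the
translation-start exon is subtracted from a skip's coding loss. No
sequence-level stop-codon scanning is performed — frameshift outputs
report "fs" without a termination position, since predicted ter
positions depend on downstream sequence the model does not carry.
Consequences of disjoint events are additive in Δbp.

## Synthetic cohort generator

`crcgerm.simulate.gen_cohort` emulates the study conditions the pipeline
targets: 100 unselected CRC patients, 248 annotated variants over a
206-gene panel, 12% of patients planted as P/LP carriers and 65% as
oncodriver carriers. Planting is exact — carriers are drawn without
replacement and each receives one planted variant — so the planted P/LP
detection rate is recovered exactly by construction, and randomness
enters only through decoy annotations and score draws. Planted P/LP
variants carry evidence-code sets sampled from the 13-row reference call
set (so the 5:8 P:LP ratio holds in expectation) and annotations
guaranteed to survive track A; planted driver variants draw their
COREAD score from Beta(8, 2) and decoy scores come from Beta(2, 8), so
driver-rate recovery is stochastic and is asserted within the binomial
95% interval. Decoys are constructed to fail specific gates (common
alleles, failed predictor votes, synonymous effects) or to classify as
VUS / likely benign, populating the non-P/LP report classes.

What the generator does **not** emulate: linkage and haplotype
structure, realistic genomic coordinates and transcript accessions,
correlated predictor errors, sequencing artefacts, or any correlation
between clinical covariates and carrier status. Passing the end-to-end
recovery tests therefore demonstrates that the pipeline's gates,
combining rules and statistics are implemented correctly — not that the
annotations of real cohorts satisfy the gates' assumptions.

`gen_hwe_genotypes` draws genotypes as two independent allele draws per
individual (the exact HWE model); `gen_score_pairs` draws
class-conditional Beta scores for the concordance tests, whose expected
AP for the default (8,2)/(2,8) separation was pinned once by Monte Carlo
at 0.998.

## Problem sizes and tolerances

The test suite runs the heavier checks at sizes chosen to make the
statistical assertions sharp while staying fast: the engine-vs-oracle
sweep covers all ~24k evidence subsets of size ≤ 4; chi-square oracles
are checked on 1,000 random inputs at 1e−9; HWE calibration uses 10,000
replicates of n=500; AP convergence uses n=10⁵; label-assignment
exhaustion uses all 2⁸ assignments at n=8. Published p-values are
asserted to the three decimals at which they are printed; computed
shares are asserted against printed one-decimal percentages at ±0.1
(the printed precision). One published share (56/68 printed as 82.3%) is
a truncation of 82.35% and is checked at printed precision rather than
re-rounded.

## Known limitations

* Evidence codes are consumed, not derived: assigning ACMG/AMP codes
  from raw annotations is expert work the package does not automate.
* The effect-class vocabulary is flat; compound annotations (e.g. a
  missense change that is also splice-region) must be pre-resolved to
  one class upstream.
* HWE testing uses the chi-square approximation, not an exact test; at
  very rare alleles the approximation is poor and the degeneracy flag
  only covers the fully monomorphic case.
* The transcript model is length-only; consequences involving cryptic
  splice sites or partial exon loss are out of scope.
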