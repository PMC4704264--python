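# Methods

## Model and assumptions

`sccomp` treats a label-free LC-MS/MS run as a vector of spectral counts
SpC over identified proteins. Protein abundance within a run is summarized
either as the raw count or as the normalized spectral abundance factor

    NSAF_k = (SpC_k / L_k) / Σ_j (SpC_j / L_j),

with L the protein length in amino acids; a length-free variant (L ≡ 1,
i.e. plain spectral fractions) is used when lengths are unavailable. The
method's key quantities are ratios of within-sample ratios, in which both
the per-run normalizer and the per-protein length cancel, so none of the
headline results depend on the NSAF variant chosen.

**The SRA scale.** Relative amounts are expressed as the scalar relative
amount, SRA[α|β] = α/β − 1 for α ≥ β and 1 − β/α otherwise. This signed
linear scale makes opposite fold changes cancel under averaging (the
arithmetic mean of the ratios 2.0 and 0.5 is 1.25, a systematic upward
bias; the mean of their SRAs, +1 and −1, is 0). All averaging in the
toolkit — over internal standards, over replicate pairs — happens on the
SRA scale; fold magnitudes (|SRA| + 1) are rendered only for display. At
α = β both branches give 0, so the tie assignment is immaterial.

**Internal standards.** A panel of constitutively expressed proteins
(default: the nine glycolytic enzymes of *Lactococcus lactis*) serves as
pseudo-replicates shared between biological conditions. The adjusted SRA
of protein k between datasets A and B is the mean over standards j of
SRA[(SpC_Ak/SpC_Aj) | (SpC_Bk/SpC_Bj)]; its SD over the panel is reported
as the uncertainty. Because each term is a ratio of within-sample ratios,
multiplying all counts of one run by a constant leaves every term
unchanged — this exact invariance is the depth correction the standards
provide, and it holds identically on the count and NSAF bases (verified
to 1e−9 in the test suite).

**Comparability.** Before quantifying, a run pair is screened by the
conjunction of two gates, both evaluated at full precision (the 2-decimal
rendering in reports is presentation only):

* R_TS = max/min of the two SpC totals, gate ≤ 1.35 by default;
* SD over the internal-standard SRAs (sample SD, n−1 denominator),
  gate ≤ 0.46-fold by default.

R_TS is presumptive — it detects depth imbalance cheaply from totals
alone — while the standard-SD gate detects quality differences directly.
When no internal-standard SD can be computed (fewer than two shared
standards) the SD gate fails closed with an explanatory note.

`derive_thresholds` re-derives the R_TS gate for new data: it regresses
the internal-standard SD on R_TS over user-supplied replicate pairs
(ordinary least squares) and inverts the fitted line at the configured SD
threshold. It also reports twice the minimum whole-proteome replicate SD
as the analogous gate for SD over all proteins — with replicate data
whose minimum SD is 0.38-fold this doubling rule gives 0.76-fold, and the
corresponding standard-panel threshold of 0.46-fold inverts to an R_TS
near 1.35.

**Identification support.** Per-replicate identifications are scored 3
(≥2 unique peptides AND −log(e) ≥ 10), 2 (≥2 peptides OR −log(e) ≥ 10),
1 (exactly 1 peptide with 2 ≤ −log(e) < 10) or 0, evaluated as an
if/elif cascade in that order (otherwise every high-confidence row would
also match the OR row). A protein is present in a sample when its summed
score reaches the number of replicates n — with triplicates, one
high-confidence hit or three low-confidence hits suffice. Target-decoy
FDR is R/(F+R); `fdr_threshold` returns the smallest (most permissive)
score cutoff whose accepted set, ties included (closed threshold), holds
FDR ≤ the requested level, matching an exhaustive scan over all distinct
cutoffs. When no cutoff achieves the level the strictest one is returned
flagged. The level can be applied at PSM or protein-row granularity by
the caller; the toolkit does not take a position on which the benchmark
used. Decoy rows are dropped before count matrices are built.

## Statistical comparisons

Agreement between the MS-derived fold and an external measurement is
tested with Welch's two-sample, two-tailed t-test (unequal variances,
Welch–Satterthwaite degrees of freedom), available from raw values or
from (mean, SD, n) summaries. p-values are reported raw; the package
performs single planned comparisons, and users screening many proteins
should correct externally (statsmodels' `multipletests` composes
directly with the per-protein output).

Pooling over replicate pairs excludes pairs that failed the
comparability screen, recording each exclusion with the failing gate;
the pooled mean is the mean of the per-pair SRA values, rendered as a
signed fold, and the pooled SD is the SD of those SRA values (invariant
to the +1 fold shift).

## Synthetic data generator

The generator produces two-sample count matrices with known truth.
Expected count of protein k in a replicate = base_k × fold_k(sample) ×
exp(N(0, σ_k)) × depth, realized as a Poisson draw. Only the reporter
protein (`gfp`) changes between samples; standards use a smaller σ and
fold 1. Depth is a pure multiplicative factor — exactly the nuisance the
adjusted estimator cancels. Defaults (chosen once, as a realistic small
bacterial whole-cell experiment):

| parameter | default | rationale |
|---|---|---|
| n_proteins | 300 | typical per-run identification count for a small bacterium on an ion trap |
| protein_mean_count | 8 | puts run totals in the few-thousand range |
| abundance_log_sigma | 1.0 | order-of-magnitude spread of base abundances; yields realistic ragged detection (~10–20 % of proteins missing per run) |
| biological_cv (σ) | 0.2 | gives between-replicate SD_SRA over all proteins of ~0.4–0.6-fold at these counts, the few-tenths-fold regime of real biological replicates |
| standard_cv (σ) | 0.1 | standards vary less than the bulk proteome; gives panel SDs of ~0.2–0.3-fold between good replicates |
| standard_mean_count | 60 | glycolytic enzymes are among the most abundant proteins in a fermentative bacterium |
| reporter_base_count | 50 | an induced fluorescent reporter is highly expressed even in the low-copy strain |
| reporter_fold | 3.0 | a moderate, realistic induction difference |

`simulate_benchmark_like` fixes depth factors (1.00, 1.18, 1.70 / 1.32,
1.04, 1.72) and a slightly lower mean count so the six run totals span
roughly 2500–4400 and pairwise R_TS spans ~1.0–1.7 — the regime in which
the screen visibly separates good from bad pairs.

The generator emulates depth imbalance, constitutive standards,
lognormal biology and Poisson counting noise. It does **not** emulate
peptide-level phenomena (shared peptides, missed cleavages, saturation
of high-abundance proteins, run-to-run retention drift) or
non-multiplicative batch effects; passing tests therefore demonstrate
the estimator's behaviour under the model's assumptions, not its
robustness to every artifact of real MS data.

## Numerical choices and edge cases

* Undetected proteins (count 0) are excluded from SRA computations, never
  imputed; standards with a zero in either run are dropped with a warning
  and N reduced. A pseudocount option exists for exploration but is off
  by default and used nowhere in the shipped analyses.
* All SDs are sample SDs (n−1): panel and pair counts are small.
* The SRA-basis default for between-run comparisons is NSAF for single
  proteins (`sra_between_datasets`) and counts for the adjusted estimator
  (where the basis provably does not matter). SRA of NSAF equals SRA of
  raw counts only when the two runs share their total (and lengths
  cancel); the `basis` option makes the choice explicit.
* Monte-Carlo test sizes (100 seeds for estimator recovery, 50 pairs for
  the R_TS–SD correlation, 1000 instances for the basis-equivalence
  check) keep the default suite under a few seconds while leaving
  comfortable margins on the assertions.
* Report TSVs print reals with 4 decimals and round-trip through the
  bundled reader; integers survive bit-exactly.

## Known limitations

* Spectral counting itself saturates for very abundant proteins and is
  insensitive below ~a few spectra; the toolkit inherits these limits.
* The adjusted estimator is a mean of ratio-of-ratio transforms and
  carries the usual small positive Jensen bias at low counts (visible as
  a few-percent overestimate at panel counts of ~50 spectra); averaging
  over standards reduces variance but not this bias.
* The default thresholds (1.35, 0.46-fold) were derived on one instrument
  and organism; re-derive them from your own replicates for other
  platforms.
* Peptide-to-protein inference is out of scope: search-engine protein
  rows are taken as given.
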