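# Methods

## Model and procedure

The package builds case/control PRS models from three inputs: base GWAS
summary statistics (per SNP: effect allele, log-odds beta, p-value), one or
more target cohorts as PLINK bed/bim/fam filesets, and a genotype reference
panel for LD. The score of individual *i* under a score file *S* is

    PRS_i = Σ_{j∈S} d_ij β_j            (sum mode)

with `d_ij` the effect-allele dosage. Average mode divides by `2·|S|`
(PLINK 1.9 `--score` parity); missing dosages are mean-imputed at twice the
effect-allele frequency among observed samples (the PLINK default), or
skipped. All model construction and the centile machinery use sum mode:
average mode's per-sample denominator varies with missingness and would
break the fixed-range guarantee of the absolutes.

### Clumping and tagging

Greedy clumping sorts base SNPs by ascending p, repeatedly pops the best
remaining SNP as a clump index and absorbs as members all remaining SNPs on
the same chromosome within ±250 kb (inclusive, 1-based positions) with
dosage r² ≥ 0.8 against the index. r² is the squared Pearson correlation of
dosage vectors over pairwise-complete samples (composite LD); PLINK's
EM-phased haplotype r² can differ slightly, a documented dialect
difference that rarely changes decisions at r² ≥ 0.8. Ties in p are broken
by (chromosome, position, SNP id) for determinism. Base SNPs absent from
the reference become singleton clumps, keeping the partition property
(every clumped SNP in exactly one clump). A configurable keep-region
(chromosome, start, end) exempts its SNPs from member absorption — each
stays its own clump — for loci like the *APOE* region where independent
contributions within an LD block should not be collapsed; no coordinates
are hard-coded. Every SNP then carries its clump id (the tag map).

### Harmonization and beta QC

Per cohort, each clump is represented by its index SNP when genotyped,
otherwise by the genotyped member with the smallest base p (flagged as an
alternative); matching is by SNP id only. Clumps covered in every
development cohort form the common set. A clump is then removed when its
representatives across cohorts (a) carry different effect alleles — no
allele flipping is attempted, fidelity over power — (b) have betas of
opposing sign (a beta of exactly 0 counts as neither sign), or (c) spread
with sample SD (n−1 denominator; n = 5 cohorts is small) above `sd_max`.
`sd_max` defaults to 0.5 and is configurable; the sources motivating this
filter quote inconsistent figures, so the cutoff is exposed rather than
reconciled.

### SNP quality control

Removal uses strict inequalities exactly as conventionally printed: MAF
< 0.01 (computed from non-missing dosages), call rate < 0.95, or
Hardy–Weinberg exact p < 1e-4 in controls only. The HWE test is the
conditional exact test on the heterozygote count given the allele counts
(two-sided: summing probabilities of all configurations no more likely
than observed), computed in log space; it is validated against a
rational-arithmetic enumeration oracle to 1e-12 for totals up to 200
alleles. Filters are order-independent since each is evaluated on the
unfiltered cohort.

### Threshold models (the traditional baseline)

Score files are formed from panel SNPs with base p ≤ t for every t in a
grid from 5e-8 to 1 in steps of 1e-6. Distinct thresholds that select
identical SNP sets are evaluated once — the grid implies ~1e6 thresholds
but at most panel-size distinct sets, which is exact and tractable. Each
set is scored; logistic regression (phenotype ~ score) and the AUC are
reported; the best model maximizes AUC, ties broken by smaller logistic p
then fewer SNPs.

### Perfect-discrimination forward selection

Pass one orders the cohort's panel SNPs by ascending allelic-association
p *in that cohort* (1-df chi-square on the 2×2 allele × status table, no
continuity correction; ties again by chromosome, position, id), adds them
one at a time, and labels each addition `increase`/`decrease`/`none` by
comparing the AUC after the addition with the previous step, starting from
the empty-model baseline of 0.5. Scores are carried incrementally, which
is exactly equal to rescoring from scratch at every step (tested). Pass
two replays only the increase-labelled SNPs, in the same order, and stops
at the first step where every case score strictly exceeds every control
score. AUC = 1 is tested as this strict separation, never floating-point
equality. The contributing set is every clump added through that step; if
separation is never reached the trace is flagged and the contributing set
is the prefix achieving the maximum AUC. Decrease-labelled SNPs are
excluded from the replay (an option appends them after the increases,
for sensitivity analysis).

The AUC is the Mann–Whitney statistic (probability a random case outscores
a random control, ties ½), computed by ranks; the logistic fit is
maximum-likelihood IRLS with a Wald slope test. Perfect separation makes
the logistic MLE diverge; this is expected by construction here, so the
fit is flagged (`separated`) with a NaN p sentinel rather than treated as
an error — models are compared primarily by AUC.

### Commonality models and application

Clumps contributing in ≥ k of the development traces form the k-model
(lenient k=2, stringent k=3; stringent ⊆ lenient by construction). A model
is applied to any cohort through that cohort's own panel: its
representative SNP per model clump, with missing clumps dropped and
counted, and alternative representatives counted. Evaluation returns the
SNP count, logistic slope/p, AUC, and those counts.

### Absolutes and centiles

For a score file, the artificial minimum individual carries effect-allele
dosage 2 at every β < 0 SNP and 0 elsewhere; the maximum individual the
opposite; β = 0 SNPs contribute to neither. Their sum-mode scores bound
every achievable score (also under mean imputation, since imputed dosages
stay in [0, 2]). The range is cut into 100 equal bins, half-open with a
closed top bin so every in-range score maps to exactly one bin; a score
outside the range raises, certifying a scoring/range inconsistency.
Per-bin case/control counts, an upper-tail case proportion (the operating
point is always computed from data, never hard-coded), and a bar-chart
rendering are provided.

## The synthetic-data generator

`simulate_family` emulates the structure the method assumes. Each of
`n_clumps` LD clumps carries a latent biallelic indicator at ancestral
frequency Uniform(0.05, 0.5); member SNPs (1–3 per clump) copy each latent
haplotype allele with probability 1−ε and redraw from the class frequency
otherwise, giving expected member–member r² of (1−ε)⁴; ε is set from the
r² target (default 0.9). Causal clumps shift the latent frequency by
±0.1 in cases (direction constrained to keep frequencies in (0,1)), so all
members inherit the full shift. Genotypes are Hardy–Weinberg draws given
the latent indicator — block LD only, no recombination map, no ancestry
structure. Cohorts get independent platform masks (each SNP kept with
probability 0.9), 1% missing genotypes, and a random 20% of SNPs with the
bim a1/a2 orientation flipped to exercise allele reconciliation. Base
statistics report β = ln(implied OR) + Normal(0, 0.05²) — the noise SD is
small enough that the beta-SD filter rarely triggers under the null, so QC
behaviour is observable but not dominant — and p-values from a
two-proportion z-test at a virtual GWAS size of 17,000 cases / 37,000
controls, making null p-values uniform. A "degraded" cohort preset (small
n, no frequency shift at causal clumps) reproduces the known failure mode
of a cohort in which the flagship loci carry no signal. Everything is
deterministic under the seed.

What the generator does *not* emulate: realistic human LD maps and
recombination, ancestry admixture, genotyping batch effects, covariates
(age/sex), and real effect-size architectures. Passing tests therefore
show the selection machinery behaves as designed under its own
assumptions, not that the resulting models are clinically meaningful.

### Default study conditions

Defaults were chosen once to represent the regime the method operates in:
5 development cohorts of 100 cases / 100 controls, 6,000 clumps of 1–3
SNPs, 30 shared causal clumps plus 5 cohort-private ones, frequency shift
0.1. The clump panel is deliberately much larger than the cohorts
(ratio ~30), because the perfect-discrimination construction relies on
massive over-parameterization: replaying increase-labelled additions
separates cases from controls exactly only when the candidate pool dwarfs
the sample count. Empirically the separation property appears at
panel/sample ratios around 30× and above; at small ratios (a few ×) the
replayed path plateaus at AUC ≈ 0.92–0.96 and the trace reports the
max-AUC prefix instead. This is a property of the procedure itself, not
of any implementation choice — it holds across orderings and greedy
variants — and it is why the fixed 500-SNP / 200-sample benchmark reports
an AUC below 1 while the 2,500-SNP / 50-sample example separates exactly.

Problem sizes in the test suite (cohorts of 25–100 cases/controls, panels
of 500–6,000 clumps, 20 seeds for stochastic properties) were chosen as
desk-scale analogues of these conditions.

## Numerical choices and edge cases

- Dosages are int8 with −1 as the missing sentinel; bed decoding is
  bit-exact against the published 2-bit SNP-major layout and round-trips
  through the package's own writer.
- `pairwise_r2` returns a flagged not-computable (None) for monomorphic
  SNPs or fewer than two complete pairs, rather than NaN arithmetic.
- The HWE exact test normalizes in log space (max-subtraction) and treats
  probability ties with a 1e-12 relative slack.
- The threshold grid "snap-up" maps each base p to the smallest grid point
  ≥ p with a 1e-12 relative guard against floating-point ratio error.
- Degenerate absolutes (all β = 0) are flagged and refuse binning.
- Zero-margin association tables return chi² = 0, p = 1, direction 0.

## Known limitations

- Composite-LD r² instead of EM-phased haplotype r² (dialect difference
  from PLINK's clumper).
- No strand-ambiguity (A/T, C/G) resolution and no positional liftover;
  matching is by SNP id, and clumps with conflicting effect alleles are
  dropped rather than flipped.
- Sample-level QC (relatedness, ancestry) is out of scope; a keep-list is
  the supported mechanism.
- The logistic Wald p is unavailable (by design) under perfect separation.
- Exact AUC = 1 separation requires the over-parameterized regime
  discussed above.
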