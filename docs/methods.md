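# Methods

This note documents the models and conventions implemented in `plkevol`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not establish.

## Expression breadth (τ)

Input is a genes × samples table of normalized read counts (NRC), samples
labelled (sex, tissue, replicate).  Per sex-by-tissue group the replicate
median (NRC_TS) is taken — the ordinary sample median, midpoint of the two
central order statistics for even group sizes — then transformed to
S = log₁₀(NRC_TS + 1) so zero counts stay finite and map to 0.  For each
gene and sex, τ = Σ(1 − Sᵢ/Sₘₐₓ)/(N − 1) over the N analysis tissues.

Conventions:

* Whole-body samples are excluded from τ by default (they overlap every
  other sample); the tissue set is configuration, not hard-coded.  The
  default design has six nonoverlapping tissues (digestive, gonad,
  reproductive, thorax, abdomen, head) and four replicates.
* An all-zero profile (Sₘₐₓ = 0) leaves τ undefined: the formula divides
  by Sₘₐₓ, and silently returning 0 or 1 would misclassify unexpressed
  genes.  τ is returned as NaN with a warning.
* Ties for Sₘₐₓ need no tie-break — only the maximum value enters.
* Genome-wide percentile placement of a focal gene uses the mid-rank
  convention, 100·(#below + ½·#equal)/n, deterministic under ties.  This
  is a stated convention of this package, not a property of the source
  data.

## Lineage divergence and the relative-rate test

A three-taxon amino-acid alignment (two ingroup paralog lineages A and B,
one outgroup O) is classified per column: any gap → `gapped`; all equal →
`identical`; A differs while B = O → `subst_A` (one change on the A
branch); symmetrically `subst_B` and `subst_O`; all three distinct →
`ambiguous`.  These rules coincide with exhaustive small parsimony over
all 20 ancestral states at the internal node (a tested invariant); the
all-distinct case has two equally parsimonious placements and is counted
in neither lineage (reported separately for audit).  Only single changes
per column are inferred — counts are per-site, not per-event.

"Alignable" positions are columns with no gap in any sequence.  The test
statistic is χ²₁ = (m₁ − m₂)²/(m₁ + m₂) with an upper-tail χ² p-value
(m₁ = m₂ = 0 gives χ² = 0, p = 1).  Domain-restricted counts use a
user-supplied map of named column ranges (1-based inclusive in files,
0-based half-open internally); the packaged Polo map is an approximate
literature-derived default and must be replaced when the alignment frame
differs.

In-frame deletions: maximal gap runs private to one ingroup (outgroup has
residues) are terminal-lineage deletions; runs shared by both ingroups are
placed on the internal branch ("shared").  Outgroup-only gaps are not
reported.

## McDonald–Kreitman test

Both species' alignments must be in frame and aligned to each other.
Codon columns with a gap or ambiguous base in any strain are excluded
entirely (conservative and auditable); columns containing a stop codon in
any strain are excluded with a warning.  Per nucleotide position within a
codon: segregation within a species yields a polymorphism record for that
species; positions monomorphic in both species with disjoint alleles
yield fixed-difference records.  A position polymorphic in either species
is never counted as fixed.

Effects are scored in codon context.  Codons carrying several changes are
scored Nei–Gojobori style: synonymous/nonsynonymous steps are averaged
over all minimal mutational pathways (pathways through stop codons are
skipped), giving fractional per-position counts.  Within-species codons
with more than two haplotypes are scored per segregating position on the
majority-consensus background, averaging over alternate alleles.
Singleton polymorphisms are included — no frequency filter.

The 2×2 table restricts polymorphism to a configurable focal species
(both species' tables are computed).  Fractional counts are resolved by a
rounding policy before the exact test: `round` (half-up, default),
`floor`, or `keep`, which retains fractions and tests with a
likelihood-ratio G-test instead.  The two-sided Fisher exact p-value sums
hypergeometric probabilities of tables at most as probable as the
observed one, with the customary 1e-7 relative tie tolerance; the
implementation is an in-package vectorized hypergeometric sum,
cross-checked in the test suite against an independent pure-enumeration
oracle (all tables with total ≤ 60, agreement to 1e-12) and against
`scipy.stats.fisher_exact` on sampled tables.  NI and α are undefined
(NaN) when a required denominator is zero.  No outgroup polarization and
no asymptotic-MK extensions.

## Meiosis-II transmission model

Equal numbers of X- and Y-bearing secondary spermatocytes enter meiosis
II.  A normal division yields two single-chromosome sperm; a nondisjoined
division (rates ndj_X, ndj_Y per spermatocyte class) yields one disomic
(XX or YY) plus one nullo-XY sperm.  Sperm classes are weighted by a
viability map and renormalized; euploid X-bearing eggs map sperm to
zygotes (X→XX, Y→XY, XX→XXX, YY→XYY, nullo→XO), weighted by zygote
viability and renormalized.  Sex follows X dose; XO males are viable but
sterile and are counted as progeny.

Defaults are conventions, clearly labelled in output: every viability 1
except XXX = 0.05 (dramatically reduced but nonzero), all configurable.
Meiosis-I nondisjunction and female-side errors are out of scope
(documented limitation); autosomal aneuploidy enters only as whatever the
user folds into viabilities.  With ndj_X = ndj_Y = 0 the model collapses
exactly to the Mendelian 1:1 expectation regardless of disomic/nullo
viabilities.  The inverse problem (estimating the two rates from an
observed female fraction and XO fraction under fixed viabilities) is
solved by a 41×41 grid search plus Nelder–Mead refinement; a flat
objective flags non-identifiability, and a residual above 1e-4 flags
observations inconsistent with the model.

## Brood statistics

One record per mated male: transgene, strain, batch, n_female, n_male.

* **Count models** (total/female/male progeny): linear mixed model with
  transgene fixed and crossed random intercepts for batch and strain,
  fitted by REML (statsmodels MixedLM, variance components on a trivial
  group).  Contrast tests use containment denominator degrees of freedom:
  when strains are nested in transgenes the transgene contrast is tested
  against F(1, n_strains − n_levels), which is markedly better calibrated
  than the asymptotic normal reference when grouping levels are few.
* **Siring model** (brood > 0): logistic mixed model with the same
  random structure, fitted by a Laplace approximation of the marginal
  likelihood (joint optimization of fixed effects and log-variances;
  penalized Newton for the random-effect modes; Wald z conditioning on
  the estimated variances — the glmer criterion).  A variational-Bayes
  fit was rejected during development because its posterior sds were
  anticonservative under the null.  Complete separation is flagged;
  estimates then sit near the boundary with unreliable standard errors.
* **Sex-ratio model** (per transgene): reshape to two rows per vial, model
  count ~ progeny_sex + vial with batch/strain variance components.
  Vial fixed effects absorb the grouping factors, so the random-effect
  fit is usually degenerate and the model degrades to OLS with a logged
  warning — the fixed-effect estimates coincide.  The progeny-sex F uses
  containment df (1, n_vials − 1).  All-zero broods are excluded (ratio
  undefined); zero broods are retained in count and siring models.
* Fixed effects use treatment coding (named in every output).  A per-male
  exact binomial test against 1:1 serves as the model-free cross-check.

## Synthetic data

Count-planting generators (three-taxon proteins; two-species codon
alignments) place each change at its own site with no homoplasy and at
most one mutation per codon (unless multi-hit codons are requested), so
the analysis stages recover the planted m₁/m₂ and Pn/Ps/Dn/Ds exactly.
They are the fixtures for exact tests.  Distribution generators
(expression tables; brood tables) draw from the stated stochastic model
and are recovered within stochastic tolerance only.

Expression profiles are planted in closed form: one peak tissue at
log-level h and the rest at h(1 − τ*), whose analytic τ equals the target
exactly before replicate noise; replicates multiply NRC by lognormal
noise (sd 0.1 by default, 4 replicates, 6 tissues — the source design).
Brood tables use negative-binomial brood sizes (default mean 60,
dispersion 5 — a realistic single-pair *Drosophila* vial over a 3–5 day
lay), lognormal batch/strain intercepts (sd 0.3/0.2), a zero-inflation
component for non-siring males (default 0.2, matching the observed 20–25%
non-siring rate), and binomial sex allocation with p_female fixed or
derived from the transmission model.  Default 24 males per transgene, 3
batches, 2 strains mirror the experimental scale.

Calibration simulations (type-I error of the three brood tests under the
null) deliberately use more grouping levels (6 batches, 6 strains, 120
males per transgene): Wald-type mixed-model tests are asymptotic in the
number of random-effect levels, and no estimator is calibrated with two
strains per transgene.  This was fixed a priori as a property of the
calibration design, not tuned.  A green calibration test therefore
establishes that the procedures are calibrated at moderate design sizes —
not that p-values from very small designs (1–3 strains) are exact.

What green tests do *not* establish: the generators contain no selection,
no linkage, no codon substitution process and no real read-count
normalization, so passing recovery tests verifies bookkeeping and
inference machinery, not robustness to real-data pathologies (alignment
error, segmental duplications, expression batch structure).

## Numerical choices

* Fisher tie tolerance 1e-7 (relative), matching common practice.
* Rounding of fractional MK counts: half-up, not banker's rounding, so
  x.5 always moves away from zero consistently.
* Mixed-model degeneracies degrade stepwise (drop single-level random
  terms → OLS/plain logistic) with warnings recorded in the result
  object, never silently.
* τ of an all-zero profile is NaN, never 0 or 1.
* All generator randomness flows through `numpy.random.default_rng(seed)`
  with per-call independent streams; identical (config, seed) give
  byte-identical outputs.
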