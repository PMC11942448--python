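# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the design decisions behind `cspic`, in the spirit
of a statistical-software methods appendix.

## The connected design

The object of study is a *connected* set of biparental populations: five
inbred founders drawn from four heterotic groups (X: C783; Improved Reid:
C229; SiPingTou: C116A; early-maturity: UH306, EH) are crossed to give
five DH populations — C783×C229, C783×UH306, C783×EH, C229×UH306,
C783×C116A (POP1–POP5). Each DH population is test-crossed to three inbred
testers chosen from a third heterotic group distinct from both founders
(the *triangular heterotic pattern*), giving fifteen hybrid populations.
Twelve of the fifteen DH-by-tester pairings are fixed from the published
description of this design (POP1–4 × C116A; POP1, POP4 × J2416; POP5 ×
C229, C2404, Z58; POP2 × Z58; POP3 × Z58; POP1 × EH); the remaining three
slots (POP2/C2404, POP3/J2416, POP4/C783) are filled by the triangular
rule and are editable through the design JSON — the design file, not the
code, is the source of truth. Default DH population sizes are
124/97/134/91/89 lines.

## Synthetic-data generator

The generator produces data with the statistical structure the analysis
assumes; it is first-class, tested code.

**Founders.** Genomes are fully homozygous. Allele frequencies follow a
hierarchical drift (Balding–Nichols) model: per locus an ancestral
frequency p ~ U(0.05, 0.95); each heterotic group draws its frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F) with drift parameter F = `group_divergence`
(default 0.3, chosen so that between-group Fst lands in the 0.2–0.4 range
typical of divergent maize pools); each founder is fixed for an allele
sampled from its group frequency. The default genome is 10 chromosomes ×
150 cM with 2,000 SNPs placed uniformly at random (≈ desk-scale; the real
analysis would use 10⁵ markers, but accuracy plateaus far below that and
every algorithm here is O(n²m) or better, so marker count only scales
runtime).

**Meiosis.** Haldane model, i.e. no crossover interference: per
chromosome the crossover count is Poisson(length in Morgans) with uniform
positions. Nothing downstream needs interference — the 1:1 segregation
filter only requires Mendelian segregation — so the simplest defensible
model is used. A DH line is a single F1 gamete, doubled.

**Hybrids.** A test-cross hybrid genotype is deterministic given two
inbred parents: dosage = (DH + tester)/2 per locus, heterozygous exactly
where the parents are fixed for opposite alleles. This is the only
Mendelian-consistent rule for inbred parents; heterozygous parental calls
are an error.

**Traits.** Each trait has `qtl_per_trait` (default 50) QTL sampled among
the simulated loci, additive effects ~ N(0, 1) and heterozygote
(dominance) deviations of magnitude `dominance_ratio` × |N(0, 1)|
(default 0.5). DH per-se traits (DTA, DTS, PH, EH analogues) are additive
automatically — homozygous material never expresses the dominance terms.
Hybrid panels additionally carry a yield analogue (GY). Dominance is the
only non-additive component; no epistasis.

**Phenotypes.** Plot records follow
y_ijk = μ + g_i + e_j + b_k(e_j) + ε with environments e_j ~ N(0, Venv),
blocks within environments b ~ N(0, Vblock), residual ε ~ N(0, Ve). Given
a plot-mean heritability target H², the residual variance is solved from
the *realized* genetic variance, Ve = l·Vg(1−H²)/H², so the plug-in
H² = Vg/(Vg + Ve/l) hits the target exactly. Defaults: Venv = 2·Vg,
Vblock = 0.25·Vg (field trials typically show environment variance
exceeding genetic variance), three environments × two blocks, balanced.
Per-trait targets (DTA 0.85, DTS 0.82, PH 0.92, EH 0.90, GY 0.72) sit in
the 0.64–0.96 band typical of multi-environment maize trials, with yield
lowest. The generator can also mask genotype calls at a configurable rate
to exercise the missing-data filters; this is off by default.

**What the generator does not emulate.** Real augmented alpha designs are
unbalanced (the BLUE stage accepts unbalanced data, but the generator
emits balanced records by default); there is no genotype-by-environment
interaction, no spatial field trend, no genotyping error, and founder
genomes are exchangeable draws rather than real pedigree mosaics. Passing
tests therefore demonstrate that the *pipeline* recovers the structure it
assumes, not that real data satisfy those assumptions.

## Marker quality control

Filters run in a documented, deterministic order. `filter_missing_and_het`
removes loci with ≥ 40% missing calls first, then individuals with ≥ 30%
missing or ≥ 10% heterozygous calls (locus-first is the conservative
PLINK-like convention; the thresholds are the standard ones for
low-coverage DH panels). The segregation filter keeps a locus iff the
1-df statistic (n0 − n2)²/(n0 + n2) has p ≥ 0.001, without continuity
correction; heterozygous and missing calls are excluded from the counts
and flagged. Monomorphic loci fall under the same statistic, so a locus
fixed in a large panel is removed by the same rule. By construction the
type-I removal rate of truly 1:1 loci is at most α, so ≥ 99% of such loci
survive at any n; this is verified at n = 90.

The merge rule keeps loci genotyped in *all* populations plus loci
polymorphic in *at least one*; merged individuals get missing calls at
loci absent from their panel. Locus identity is keyed by
(chromosome, position, alleles), 1-based as in VCF. Before any model fit,
the training∪test extraction drops loci with a single observed dosage
value. LD-aware imputation is not reimplemented; a documented
major-dosage fill exists only for masked-data exercises, and the pipeline
applies the segregation filter after the missing-data filter and before
any imputation.

## BLUE and heritability

The plot model declares genotype fixed, environment and
block-within-environment random. REML profiles the residual variance
analytically and optimizes the remaining variance *ratios* on the log
scale with Nelder–Mead (derivative-free; tolerance 1e−6 on the criterion;
deterministic start at equal ratios); the covariance inverse uses the
Woodbury identity so each evaluation is small-matrix algebra. BLUEs are
the GLS genotype estimates reported as μ̂ + ĝ_i; with balanced data they
reduce to genotype means, and environments with a single level are
dropped from the random part.

Heritability is computed on a plot-mean basis as H² = Vg/(Vg + Ve/l).
Since the BLUE model has no genotypic variance component, Vg comes from a
companion fit of the same model with genotype random — the documented
source of Vg. The denominator deliberately omits Venv and Vblock (the
convention followed throughout); a flag adds the design variances for
users who want the conservative variant.

Recovery note: with only three environments, any estimator's error
against the *nominal* Venv is dominated by the χ²₂ sampling of the three
realized environment effects (median relative deviation ≈ 64% — an
identifiability floor, not an estimation defect). Recovery is therefore
assessed against the realized, identifiable components: the
within-environment block variance, the variance of e_j + b̄_j minus the
expected block-mean share, and the realized residual variance. Against
these, median REML error is a few percent.

## Prediction models

All three models fit y = 1μ + Zα + ε on per-marker mean-centered dosages
(centering, not standardization, is the default; the centering vector is
stored and applied to prediction candidates).

**RRBLUP.** α ~ N(0, Iσα²). The variance ratio λ = σε²/σα² is estimated
by REML on the equivalent random-effect model: after absorbing the
intercept, the criterion is a one-dimensional function of λ through the
eigenvalues of the projected Gram matrix ZZᵀ, optimized by bounded scalar
search on log λ. Effects are α̂ = Zᵀ(ZZᵀ + λI)⁻¹(y − 1μ̂) with μ̂ the GLS
intercept — algebraically identical to ridge regression at fixed λ and to
GBLUP with G ∝ ZZᵀ (both identities are enforced by oracle tests at
1e−8/1e−6).

**BayesB.** Marker effects are a mixture of a point mass at zero
(probability π, default 0.95) and, when included, a normal with
marker-specific variance σ_j² ~ scaled-inv-χ²(ν, S²) (marginally
scaled-t). The Gibbs sampler (numba-compiled; per marker: integrate the
effect out to get the inclusion Bayes factor, then draw effect and
variance) runs 10,000 iterations with 2,000 burn-in and thinning 5 by
default. ν = 4; S² is solved so the prior genetic variance matches a
share r² = 0.5 of the phenotypic variance given π. π = 1 short-circuits
to the exact null model (α = 0, μ̂ = ȳ). Chains are reproducible from the
stored seed.

**RKHS.** Gaussian kernel K_ij = exp(−h·D_ij) with D the mean squared
dosage difference; unit diagonal, PSD. The Bayesian model y = 1μ + u + ε,
u ~ N(0, Kσu²) is sampled by Gibbs on the kernel eigenbasis (the
conditional of the transformed coefficients is diagonal Gaussian);
variances carry scaled-inv-χ² updates. With a fixed ratio λ = σε²/σu² the
posterior mean is computed in closed form, u = K(K + λI)⁻¹(y − 1μ̂) —
exactly kernel ridge, which the oracle test checks at 1e−6. Default
bandwidth h = 1 with kernel averaging over a grid {0.1, 0.5, 1, 2.5, 5}
supported. Prediction for new individuals uses the cross-kernel and the
stored kernel-space coefficients.

SVM and random-forest learners are deliberately not reimplemented; the
evaluation protocols operate on any GEBV vector, so external predictions
can be compared without entering the models module.

## Evaluation protocols

Within-population accuracy: sample 77 accessions, five-fold CV, 10
repeats; one Pearson r per repeat from the pooled out-of-fold GEBVs (the
pooled variant is stabler than averaging per-fold correlations at this
size). Cross-population: 55 training, 12 test accessions, 50 repeats;
disjoint samples when the two populations coincide. The summary statistic
is always the **median** Pearson correlation over repeats. Phenotypes
entering the protocols are the per-population BLUEs. All sampling is
without replacement, with per-repeat RNG substreams spawned from the task
seed; MCMC fits derive their chain seeds the same way, so every protocol
is byte-reproducible.

Same_DH subtype tasks constrain sampling: `same_DH` forces every test
hybrid's DH line to appear among training hybrids (feasibility checked),
`diff_DH` forces disjoint DH-line sets, `rand_DH` leaves sampling free.

The accuracy–relatedness analysis correlates median cross-population
accuracy with PSP (expected positive) and with the Nei/IBS/Fst distances
(expected negative), per trait, with two-sided p-values. PSP is defined
as the count of loci polymorphic in *both* panels divided by the merged
reference panel's locus count ("shared polymorphism" read as *same locus
polymorphic in both sets*; the alternative same-segregating-alleles
reading is noted but not adopted). The DH↔hybrid analysis averages the
accuracies of all hybrid-population pairs that map to a given ordered DH
population pair (via the source DH population of training and test), then
correlates those means with the DH-pair accuracies; DH pairs with no
mapped hybrid pair are excluded with a warning.

## Replication scale

The multi-seed study (`cspic.study.run_study`) replicates the whole
analysis over independently simulated designs. The shipped configuration
uses the default generator conditions, RRBLUP (the three models rank
tasks near-identically and RRBLUP is closed-form), the PH analogue, all
25 ordered DH tasks, all Same_DH and Same_Tester hybrid tasks, and one
Same_DH subtype triple per DH population — 20 seeds in the test suite and
5 in the acceptance script, sizes chosen to keep a replicated run at
desk scale. The qualitative results (category ordering, subtype ordering,
positive PSP and DH↔hybrid correlations) are stable from a handful of
seeds onward.

## Known limitations

* No genotype-by-environment interaction, spatial adjustment, or
  multi-trait REML; no training-set optimization.
* The BayesB sampler uses the standard single-site Gibbs scheme; for
  panels with strong LD its mixing is the usual limitation.
* Relatedness indices are computed from dosages with missing calls
  excluded pairwise; no haplotype-based IBD.
* The hybrid taxonomy follows a fixed cascade precedence (In_Group >
  Same_DH > Same_Tester > Tri_Group > M2 > M1 > M0); pairs matching an
  earlier rule never reach a later one, which resolves the ambiguity of
  pairs that share all three inbred components without sharing a DH
  population or tester.
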