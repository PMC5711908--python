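# Methods

This note documents the models implemented in `hapdemog`, the parameter
conventions that matter for interpreting its output, the numerical choices
made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Haplotype definition and homopolymer masking

Plastid haplotypes are defined on a trimmed multiple-sequence alignment
over {A, C, G, T, -, N}. Mononucleotide-run (homopolymer) length variation
is a notorious source of non-phylogenetic signal in plastid markers, so
alignment columns are excluded when (a) they lie inside a run of the same
base of length ≥ `min_run` (default 3) in at least one sequence, and (b)
the states observed in that column are only the run base and the gap —
i.e. the variation is purely indel stutter. A substitution inside a run
(a different base) is retained. The rule is idempotent, and masked columns
are excluded from haplotype collapsing, diversity statistics and network
distances alike. `min_run = 3` is the smallest run for which polymerase
slippage is commonly reported; it is configurable.

Sequences containing N are assigned under an explicit policy: with
`treat_N_as="missing"` (default) a sequence joins an existing haplotype
only when it is compatible at all mutually scored sites with exactly one
haplotype; multi-way compatibility is ambiguous and the sequence keeps its
own haplotype with a warning. Haplotype ids are assigned H1, H2, … in
order of first appearance, so output is stable across reruns.

## Diversity statistics

For each group: segregating sites *S* (unmasked columns with ≥ 2
non-missing states), haplotype count *h*, Nei's unbiased haplotype
diversity *Hd = n/(n−1)(1 − Σ pᵢ²)*, nucleotide diversity π and mean
pairwise differences *k̄*. Missing data are handled by pairwise deletion:
each sequence pair is compared over the sites both have scored, π averages
the per-pair ratio (differences / comparable sites), and *k̄* averages raw
per-pair counts; for complete alignments *k̄ = π·L* exactly.

π is stored as a per-site fraction. Tabular output prints π × 100:
per-group diversity values of this magnitude are conventionally printed as
percent per site, and only that convention makes a printed π of e.g. 0.211
consistent with *k̄* ≈ 3.2 on a 1512-bp alignment.

Tajima's *D* uses the standard coefficients (a₁ = Σ1/i, a₂ = Σ1/i², b₁,
b₂, c₁, c₂, e₁, e₂ as functions of n) and is reported as undefined
(serialized "—") when *S* = 0 rather than as zero.

## Statistical-parsimony network

Haplotypes are joined in increasing order of pairwise Hamming distance
(computed over unmasked, mutually scored sites). Ties are ordered by
higher combined haplotype frequency, then lexicographic id, which makes
the network invariant to input order. Links longer than the connection
limit are refused, so distant clusters form separate subnetworks. A
k-step link is materialized with k−1 inferred (unsampled) intermediate
nodes. A link between already-connected haplotypes is kept as a
reticulation only when it is strictly shorter than the existing path;
equal-length alternatives are redundant under the distance metric and are
dropped. No frequency- or topology-based loop resolution is attempted:
the network is a descriptive summary, not a nested-clade inference.

The connection limit is the largest step count j whose probability of
parsimony is at least α (default 0.95). That probability is computed from
a Jukes–Cantor superimposition model with the plug-in per-site divergence
q = j/L: the per-site mutation count is Poisson with mean
λ = −¾ log(1 − 4q/3), a difference is parsimonious when it arose from a
single mutation, an identity when the site experienced none, giving

P(j, L) = [λe^(−λ) / (¾(1−e^(−4λ/3)))]^j · [e^(−λ) / (¼+¾e^(−4λ/3))]^(L−j).

For a 1512-site alignment the 95 % limit is 12 steps; the value is pinned
by a regression test. The limit grows with alignment length and reaches
`max_steps` as α → 0.

## Sudden-expansion mismatch model

The mismatch distribution is the histogram of pairwise difference counts
over all unordered pairs. Under the sudden (stepwise) expansion model a
population of mutation-scaled size θ₀ grows instantaneously to θ₁ at
τ/2 mutational time units in the past (τ = 2ut, u = per-haplotype
per-generation mutation rate, t in generations). Following a pair of
lineages in pair-mutational time (coalescence hazard 1/θ, Poisson(t)
differences given coalescence at t), the expected frequency of j
differences has the closed form

F_j = F̂_j(θ₁) · P[Gamma(j+1) ≤ τ(1+θ₁)/θ₁]
    + e^(−τ/θ₁) · Σ_{i≤j} Pois(i; τ) · F̂_{j−i}(θ₀),

where F̂_j(θ) = θ^j/(1+θ)^{j+1} is the constant-size geometric
equilibrium. The first term covers pairs coalescing after the expansion,
the second pairs that predate it. The implementation is verified in the
test suite against direct numerical integration of the two-epoch mixture,
against the geometric equilibrium at θ₀ = θ₁, and against the Poisson(τ)
limit at θ₀ → 0, θ₁ → ∞. The distribution has infinite support; by
default the mass beyond the last observed class is folded into that class
(the folded class is computed as the exact complement), with renormalized
truncation available by flag.

**Fitting.** (τ, θ₀, θ₁) minimize the sum of squared deviations
SSD = Σ_j (x_j − F_j)² subject to non-negativity and θ₁ ≤ 99 999 (the
conventional bound for an effectively infinite post-expansion size).
The optimizer is bounded trust-region least squares started from a
deterministic 3×3×3 grid scaled to the histogram mean; ties are broken by
lowest SSD, then lowest τ. Refitting frequencies generated by the model
itself recovers the parameters to machine precision (SSD ≤ 1e−8).

**Goodness of fit and uncertainty.** Harpending's raggedness index
r = Σ (x_i − x_{i−1})² (with a trailing zero class) measures the
smoothness expected of expansion-type distributions. A parametric
bootstrap simulates B coalescent datasets (default 1000) at the fitted
parameters, refits each, and reports p_SSD and p_HRag as the proportion of
simulated statistics at least as large as the observed ones, plus the
2.5/97.5 percentile interval of the refitted τ values. All randomness is
driven by explicit seeds; a fixed seed gives bit-identical results.

**Coalescent engine.** Genealogies under the two-epoch model are sampled
by the package's own Kingman-coalescent routine (pairwise coalescence rate
1/θ per pair-mutational time unit, epoch switch at τ; Poisson mutations on
branches under infinite sites). msprime implements the identical model and
is used two ways: as an independent cross-check of the internal sampler's
mean diversity in the test suite, and as the engine behind full alignment
simulation (mutations mapped to distinct columns of an L-site alignment,
collisions redrawn — negligible bias at L = 1512 ≫ S). The internal
sampler exists because the bootstrap needs tens of thousands of very small
genealogies, where per-call overhead dominates. Constant-size samples
reproduce E[k̄] = θ and E[S] = θ·a₁ within 5 % over 2000 replicates.

**Time conversion.** T = τ/(2u) with u = μkg (substitution rate ×
sequence length × generation time; defaults μ = 2.004×10⁻⁹/site/year,
k = 1512, g = 2). The default convention treats u as a per-year haplotype
rate, so T = τ/(2μkg) is in years; this is the convention that reproduces
the published expansion times this toolkit was validated against (τ =
11.34 → 0.936 My; τ = 2.84 → 0.234 My). It is not dimensionally strict: if
u is read literally as a per-generation rate, T = τ/(2u) is in generations
and calendar time is g times larger (τ/(2μk)). Both conventions are
implemented (`convention="per-year"` / `"per-generation"`) and the choice
is echoed in the run log, because published work in this area is
inconsistent on exactly this point. A generic d/2t calibration
(`rate_from_calibration`) derives μ from a dated split.

## AFLP quality control and ordination

Replicate error rate is total mismatches over total mutually scored loci
across all replicate pairs — an unbiased estimate of the per-locus flip
probability (verified on binomial-flip simulations). Degradation screening
compares per-sample fragment counts of pre- vs post-cutoff collections
with the Brown–Forsythe test (ANOVA on |x − group median|; scipy's
median-centered Levene statistic behind the module surface, with df
computed locally) and plain one-way ANOVA.

The fragment-count filter estimates μ and σ from samples collected in the
reference year (default 2003) or later and removes samples outside
[μ − kσ, μ + kσ] (k = 2). The band is two-sided because degradation loses
fragments but artifacts can add them. Because removing a recent outlier
shrinks the reference spread, the band is re-estimated after each removal
pass until stable (a trimmed estimate); this makes the filter idempotent.
The boundary is implemented as collection year ≥ 2003 ("after 2002" and
"2003 onwards" describe the same cohort).

Distances are Euclidean over mutually scored loci (a Jaccard-derived
√(1−J) alternative is available). PCoA applies Gower double-centering to
−½d² and an eigendecomposition; negative eigenvalues (possible for
non-Euclidean input) are reported but excluded from coordinates and from
the explained-variance denominator, with a strict-positivity threshold of
1e−8 × the largest eigenvalue. On Euclidean input the coordinates
reproduce the distances exactly, and a generic full-rank binary dataset of
n samples yields exactly n−1 positive eigenvalues. Axis significance is
assessed against the broken-stick expectation b_k = (1/p)Σ_{i=k..p} 1/i.

Band statistics count per-region fragments, private ("unique") fragments,
% polymorphic loci and Nei gene diversity under the dominant-marker
convention (null-allele frequency q = √(1−f) from band frequency f,
H = 2pq; labeled as such since dominant markers do not identify
heterozygotes). One-level AMOVA computes among/within sums of squares from
squared distances, variance components via the standard n₀ correction,
Φ_ST = σ²_a/(σ²_a+σ²_w), and a label-permutation p-value. Evanno's ΔK is
the absolute second difference of the mean log-probability across K,
divided by the replicate standard deviation at K; it is undefined at the
boundary K values and reported NaN (with a warning) where replicate
variance is zero. The clustering runs themselves are external; only their
log-probability table is consumed.

## Partial redundancy analysis

Responses (typically the significant PCoA axes) are centered; response
and predictors are residualized on [intercept, condition]; the constrained
component is the variance of the fitted values of the residualized
regression, and conditional + constrained + residual = total holds to
machine precision. Spatial predictors are the nine degree-≤3 monomials
{x, y, x², xy, y², x³, x²y, xy², y³} of Z-standardized longitude/latitude,
orthogonalized sequentially (Gram–Schmidt against the intercept and prior
terms, in that fixed order) and unit-scaled; degenerate columns are
dropped with a warning. Climate covariates are treated as opaque
Z-standardized columns — no semantics are asserted about specific
bioclimatic variable numbers. The correlation screen reports pairs with
|r| above threshold but drops nothing; retention is the analyst's call.

Significance uses permutation of residuals under the reduced model (the
standard scheme for partial ordination; simple row permutation available
by flag), with p = (#{F′ > F} + 1)/(n_perm + 1) so p is never zero.
Forward selection over spatial + climate main terms and all spatial ×
climate interactions is protected: a global permutation test of the full
candidate set must clear α before any term is considered. Without this
gate, testing ~49 candidates marginally at α = 0.01 would admit a spurious
term in roughly 40 % of pure-noise datasets; with it the family error is
held at α (verified by null calibration). Each subsequent step admits the
candidate with the largest marginal pseudo-F conditional on the selected
terms and the condition, if its permutation p ≤ α. VIF_j = 1/(1−R²_j)
regresses each retained term on the others plus the condition; axis tests
permute each canonical axis with prior axes as covariates. The partial-RDA
variance partition is cross-checked in the test suite against vegan's
`rda()` on the same data (agreement to 1e−4 %).

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (spec, seed) and produce the exact
file formats the analysis stages consume.

*Sequences* — per-group coalescent samples on a shared random ancestral
backbone; two gene pools separated by a configurable number of fixed
differences (default 10); group demographies default to the two-pool study
conditions the toolkit targets: a diverse native pool (n = 25, τ = 11.34)
and a younger expanding pool (n = 52, τ = 2.84), both with θ₀ = 0.5,
θ₁ = 1000 on a 1512-site alignment. Within-group mutations avoid the fixed
sites, so pool purity of haplotypes is a generator-level truth.

*AFLP* — two pools of null-allele frequencies drawn Beta(0.4, 1.6) per
locus with pool-private bands; band presence probability 1 − (1−p)² under
the recessive-allele (Hardy–Weinberg) convention; defaults 134 genotypes ×
404 loci with 25 replicate pairs at a 1.1 % per-locus flip error.
Collections before 2003 lose each present band with probability
0.006 × (2003 − year) — band loss only, matching the herbarium-DNA
mechanism — plus three planted extreme-degradation samples. The slope was
calibrated once so that the old-vs-new fragment screen shows an effect of
the strength reported for real herbarium surveys of this design (ANOVA
F ≈ 20–40, p ≪ 0.001), rather than a marginal one.

*Landscape* — response axes built per axis from condition, degree-2
spatial surface, climate, and noise components, orthogonalized
sequentially and scaled so the planted variance fractions (default
0.25/0.25/0/0.50 over n = 400) are exact sums of squares. The degree-2
surface leaves degree-3 forward-selection candidates as true negatives.

What the generators do **not** emulate: recombination and selection
(plastid loci are assumed one non-recombining neutral locus),
spatially-explicit coalescence and isolation by distance within pools,
AFLP homoplasy (co-migrating non-homologous fragments), peak-calling
noise beyond symmetric flips, and raster-derived climate fields. Passing
tests therefore validate the statistical machinery under the stated
models, not robustness to these real-data complications.

## Problem sizes and numerical conventions

Stochastic validations run at desk scale, chosen as the package's own
test conditions: τ-recovery over 100 simulated datasets; bootstrap CI
coverage over 30 datasets at B = 150 (threshold: the nominal ≥ 90 %
coverage); bootstrap type-I calibration over 60 datasets at B = 99 against
the exact binomial band at that count; forward-selection null calibration
over 60 datasets at 199 permutations; coalescent-oracle checks over 2000
replicates. Alignment coordinates are 1-based and inclusive in all
reports. All permutation and bootstrap seeds are explicit; pipeline stages
derive their seeds from the global seed and the stage name by stable
hashing, so stage order never perturbs another stage's randomness.

## Known limitations

The connection-limit estimator is one defensible reading of the
probability-of-parsimony criterion; published implementations differ in
detail, so the value is regression-pinned rather than treated as an
external constant. SSD bootstrap p-values depend on the fitted θ bounds
and the optimizer; they are calibrated under the model (type-I within the
binomial band) but, as with all parametric bootstraps, inherit the model's
assumptions. AMOVA is one-level only (no region/population hierarchy).
RDA assumes linear responses to predictors; unimodal methods (CCA) are out
of scope.
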