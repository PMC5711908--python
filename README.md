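# hapdemog

Analysis toolkit for continental-scale plant phylogeography surveys that
combine maternally inherited plastid sequence markers with nuclear AFLP
fingerprints — the classic design for reconstructing where an invasive
species came from and when its gene pools expanded.

The package covers the full chain for this design:

* **Haplotypes** — read an aligned set of concatenated plastid loci, mask
  homopolymer (polyA/T/G/C) length variation so indel stutter is never
  scored as a character, collapse sequences to haplotypes, and tabulate
  haplotype frequencies per region or status group.
* **Diversity** — per-group segregating sites *S*, haplotype count *h*,
  Nei's haplotype diversity *Hd = n/(n−1)(1 − Σpᵢ²)*, nucleotide diversity
  π (per site, printed as percent), mean pairwise differences *k̄*, and
  Tajima's *D = (k̄ − S/a₁)/√(e₁S + e₂S(S−1))*.
* **Networks** — statistical-parsimony (TCS-style) haplotype networks with
  a 95 % probability-of-parsimony connection limit and inferred
  intermediate nodes.
* **Demography** — mismatch-distribution analysis under the sudden
  (stepwise) expansion model: least-squares fit of (τ, θ₀, θ₁) to the
  pairwise-difference histogram, SSD goodness of fit, Harpending's
  raggedness index, a coalescent parametric bootstrap for p-values and τ
  confidence intervals, and conversion of τ to calendar time via
  *T = τ/(2u)* with *u = μkg*.
* **AFLP** — replicate genotyping-error rate, herbarium degradation
  screening (Brown–Forsythe homogeneity-of-variance test, ANOVA), the
  μ ± 2σ fragment-count filter, Euclidean distances, principal coordinates
  (PCoA) with broken-stick axis assessment, band statistics, one-level
  AMOVA (Φ_ST) and Evanno ΔK post-processing of external clustering runs.
* **RDA** — partial redundancy analysis of genotype ordination axes on
  third-degree orthogonal trend-surface polynomials and bioclimatic
  covariates, with a gene-pool conditioning term, permutation pseudo-F
  tests, protected forward selection and variance-inflation factors.
* **Synthetic data** — generators for coalescent sequence sets (constant
  size or sudden expansion, two gene pools fixed apart), two-pool
  dominant-marker matrices with replicate error and year-dependent
  fragment loss, and spatial landscapes with exactly planted variance
  partitions, so every stage is testable without any external download.

## Worked example

```python
from hapdemog import demography as dm, popgen, seqio, synthetic

# a synthetic survey with the package's default study conditions:
# a diverse native pool (tau = 11.34) and a younger invasive pool (tau = 2.84)
aln, truth = synthetic.make_sequence_dataset(synthetic.SequenceSpec(), seed=7)
aln = seqio.mask_homopolymer_variation(aln)
hset = seqio.collapse_haplotypes(aln)
print(popgen.summary_frame(
    popgen.group_summary(aln, hset, grouping="region")).to_string(index=False))

rate = dm.RateModel(mu=2.004e-9, k=1512, g=2.0)
sub = aln.subset([s.sample_id for s in aln.samples
                  if s.region == "Caucasus-Irano-Turanian"])
fit = dm.fit_sudden_expansion(dm.mismatch_histogram(sub))
print(f"tau = {fit.tau:.2f}  ->  T = {dm.expansion_time(fit.tau, rate)/1e6:.2f} My")
```

Output:

```
                  group  n   S  h    Hd  pi_percent       D
Caucasus-Irano-Turanian 25 111 25 1.000       0.725 -2.7359
                 Europe 52  80 40 0.941       0.261 -2.8668
tau = 8.97  ->  T = 0.74 My
```

Both groups show the classic expansion signature (strongly negative
Tajima's *D*, every sequence its own haplotype at θ₁ = 1000), and the
fitted expansion parameter of this one simulated native-like sample
(generating τ = 11.34) converts to an expansion time of roughly three
quarters of a million years under the calibrated plastid rate
μ = 2.004 × 10⁻⁹ substitutions/site/year, k = 1512 sites, g = 2 years.

The same stages are available from the shell:

```bash
hapdemog simulate sequences --seed 7 --out demo/
hapdemog diversity --alignment demo/alignment.fasta --metadata demo/metadata.tsv \
    --out demo/diversity.tsv
hapdemog mismatch  --alignment demo/alignment.fasta --metadata demo/metadata.tsv \
    --bootstrap 1000 --seed 42 --out demo/
hapdemog run --config run.yaml   # full pipeline with manifest + log
```

## Documentation

`docs/methods.md` describes the models, parameter conventions, numerical
choices and the limits of what the synthetic generators emulate.
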