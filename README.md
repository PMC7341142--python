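# dhdrift

Drift or selection? Quantifying the loss of genetic diversity when
doubled-haploid (DH) line libraries are produced from heterozygous,
open-pollinated landrace populations.

DH induction creates fully homozygous lines in a single generation — an
extreme form of inbreeding that genebanks and breeders have proposed as a
way to conserve landrace diversity in an immediately usable form. But
instantaneous homozygosity exposes recessive deleterious alleles: lines
carrying them die or fail during production, so the surviving library can
lose alleles and haplotypes far beyond neutral drift. `dhdrift` provides
the statistical machinery to measure that loss from paired SNP panels of
a landrace sample (LR) and its derived DH lines, plus a simulator that
generates such panel pairs with known ground truth.

## The model

The genotyped LR individuals are *not* the parents of the DH lines; both
are independent samples from a common ancestral population. Observed
allele counts at a site therefore arise from **three binomial sampling
events**: with `l` alternative alleles among `n_L` genotyped LR
chromosomes, `d` among `n_D` DH chromosomes, an unobserved surviving pool
of `n_H` DH lines of which `i` carry the allele, and `P(k, n, p)` the
binomial pmf,

```
I_ji = P(d, n_D, i/n_H) · P(i, n_H, p_j) · P(l, n_L, p_j)
```

over a grid of candidate ancestral frequencies `p_j` (100 points,
0.01–0.99). Two outlier statistics are built on this model:

- **aSFS test** — maximize `I_ji` to get the ML ancestral frequency
  `p̂_anc`, form the DH-count distribution
  `P_anc(s) = Σ_i P(s, n_D, i/n_H) · P(i, n_H, p̂_anc)`, and take its
  central 95% interval; a site whose observed `d` falls outside is an
  allele-frequency outlier (classified `above` / `below`).
- **Joint probability test** — integrate the unknown ancestral frequency
  out against a Beta(½, ½) prior:

  ```
  P = C(n_L, l) C(n_D, d) Σ_i C(n_H, i) · B(k+½, n−k+½)/B(½, ½) · (i/n_H)^d (1−i/n_H)^(n_D−d)
  ```

  with `k = i + l`, `n = n_L + n_H`. Sites in the top 5% of `−log10(P)`
  within an accession are outliers.

Around these sit the standard pipeline stages: VCF I/O and QC filters
(pooled-minor allele harmonization, monomorphic removal, exact
mid-p Hardy-Weinberg filtering, DH heterozygote masking, missingness),
per-site nucleotide diversity `π = 2c(n−c)/(n(n−1))` and the joint SFS,
haplotype windows (50 kb physical or 0.2 cM genetic) with Nei's
`H = N/(N−1)(1 − Σ xᵢ²)` and major-haplotype fate tracking
(lost / fixed / segregating), and enrichment analyses: LR heterozygosity
of outliers against LD-pruned, frequency-matched controls, and
GERP-weighted genetic load in 1 cM windows under additive and recessive
genotype models with frequency- and recombination-stratified controls.

## Worked example

The `examples/` scripts each demonstrate one capability end to end.
Running `python examples/03_outlier_tests.py` simulates one accession
(4,000 sites at ancestral frequency 0.3, half under recessive viability
selection with s = 0.5, 23 LR diploids, 58 DH lines genotyped from a pool
of 100) and prints:

```
flag rate           selected   neutral
aSFS test              0.027     0.003
joint probability      0.087     0.013
joint-test outliers also aSFS outliers: 29.5%
aSFS outlier fates: {'segregating': 59}
```

Selected sites are flagged at ~9× (aSFS) and ~7× (joint test) the
neutral false-positive rate. After `python examples/01_simulate_accession.py`,
`python examples/05_genetic_load.py` continues with the enrichment step:

```
joint-probability outliers: 99 of 2000 sites
mean LR heterozygosity  outliers 0.441  controls 0.388  bootstrap p = 0.006
```

Outlier SNPs are more heterozygous in the landrace than frequency-matched
controls — the signature of recessive deleterious alleles that selection
kept heterozygous in the outbred population and exposed during DH
production.

## Layout

- `src/dhdrift/genotype_io.py` — panels, VCF I/O, QC filters, HWE mid-p,
  imputation error rate
- `src/dhdrift/synthetic.py` — three-stage sampling simulator and fixtures
- `src/dhdrift/diversity.py` — per-site π, LR/DH comparison, jSFS
- `src/dhdrift/outliers.py` — aSFS and joint probability tests, overlap,
  fates
- `src/dhdrift/haplotypes.py` — windows, Nei's H, major-haplotype fates
- `src/dhdrift/enrichment.py` — LD pruning, matched controls,
  heterozygosity and GERP-load comparisons
- `src/dhdrift/pipeline.py` — single-accession orchestration to TSVs
- `docs/methods.md` — the model, parameter choices and limitations
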