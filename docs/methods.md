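# Methods

## The sampling model

All inference in `dhdrift` rests on one observation about how paired
landrace (LR) / doubled-haploid (DH) panels are produced: the genotyped
LR individuals and the DH lines descend independently from the same
ancestral accession, so a direct binomial comparison of the two panels
understates the sampling variance. The model chains three binomial
events per site:

1. **LR genotyping** — `n_L` chromosomes drawn at the ancestral frequency
   `p` (Hardy-Weinberg diploids);
2. **DH pool survival** — `n_H` haploid-induction survivors, each line a
   single allele draw at `p` (a DH line is homozygous, so its one gamete
   determines its genotype);
3. **DH genotyping** — `n_D` chromosomes observed among lines sampled
   from that pool.

Sites are treated independently; `n_L` and `n_D` are counted per site
over non-missing genotypes.

### aSFS test

The likelihood surface `I_ji` is the product of the three binomial masses
over a grid of 100 candidate frequencies (0.01–0.99) and pool counts
`i ∈ {0..n_H}`. The ML ancestral frequency is the grid value at the joint
argmax over `(j, i)`; a configuration switch (`ml_mode="marginal"`)
marginalizes the pool count instead. The two modes agree except on
near-flat surfaces; joint maximization is the default as the direct
reading of "maximizing the surface". Ties break to the smaller grid
frequency, then the smaller pool count, so results are deterministic.

The DH-count distribution `P_anc(s) = Σ_i P(s, n_D, i/n_H) P(i, n_H, p̂)`
is a mixture of binomials. Its confidence region is the **equal-tail
central interval**: the largest `s_lo` with `P(S < s_lo) < 0.025` and the
smallest `s_hi` with `P(S > s_hi) < 0.025`. In a discrete distribution
this overshoots, so contained mass is always ≥ 95% — coverage errs
conservative by construction. An equal-tail region was chosen over a
highest-density region because "central" is unambiguous in a discrete,
potentially multimodal mixture; the HPD alternative is not offered since
the equal-tail interval already covers at ≥ nominal rate.

### Joint probability test

The probability of the observed `(l, d)` pair under neutrality,
integrating the unknown ancestral frequency against a Beta(½, ½)
(Jeffreys) prior, has a closed form: the shared frequency couples the LR
count and the pool count through a beta-binomial over `k = i + l`
successes in `n = n_L + n_H` draws, and the genotyped DH counts are
binomial at the pool frequency `i/n_H`. All terms are computed with
log-gamma and combined by log-sum-exp; `0^0 = 1` at the pool boundaries
is handled by `xlogy`. Exhaustive summation over all `(l, d)` cells at
small panel sizes confirms unit total mass (tested to 1e-8).

Outliers are sites whose `−log10(P)` strictly exceeds the nearest-rank
95th percentile within the accession; the strict inequality means tied
values can only deflate, never inflate, the flagged fraction.

### Choice of `n_H`

The surviving-pool size between induction and genotyping is not observed;
it enters both tests as the mixing dimension. The default is 100 and the
same value is used in the surface, the interval construction and the
joint probability. Sensitivity is mild: larger pools shrink the
pool-sampling variance toward a pure two-binomial model.

## QC conventions

- **Alternative allele** = pooled minor allele across all panels; an
  exact 0.5 pooled frequency keeps the input coding (deterministic tie).
- **HWE filter**: exact conditional test on the heterozygote count given
  allele counts, two-sided with extremeness ranked by conditional
  probability, mid-p convention (half the probability of configurations
  exactly as likely as the observed one). A site is removed only when
  mid-p < 0.05 in *every* LR accession with data — the filter targets
  genotyping artifacts visible everywhere, not population-specific
  departures such as the heterozygote excess of selected sites.
- **DH heterozygote masking**: residual heterozygous DH calls are
  genotyping errors by construction and become missing.
- **Missingness**: sites with missing fraction strictly above 0.99
  (i.e. typed in no one) are dropped; the threshold is exposed.
- Chip-specific exclusion criteria are represented as a generic site
  exclusion list since array annotations are not reproducible here.
- Panel intersection matches on (chromosome, position), accepts ref/alt
  swaps with dosage recoding, and drops — with a warning, not an error —
  positions with incompatible allele pairs.
- Imputation quality is summarized per masked site as
  `E = 1 − z/(k − m)` (matches `z` among `k` individuals, `m` missing);
  imputation itself is out of scope.

## Diversity statistics

Per-site nucleotide diversity uses the unbiased pairwise estimator
`π = 2c(n−c)/(n(n−1))`. The LR–DH comparison removes sites monomorphic
across the pooled pair, then applies a two-sided unpaired
Mann-Whitney-Wilcoxon test (scipy: exact enumeration for small untied
samples, midrank normal approximation otherwise).

One analytic caveat, verified by simulation and asserted in the test
suite: even under pure neutrality `E[π_DH]` sits slightly below
`E[π_LR]`, by roughly `π · (1/(2L−1) + 1/n_H)` for `L` genotyped lines,
because DH chromosomes come in identical pairs and the finite surviving
pool adds drift variance that the `n/(n−1)` correction does not remove.
At realistic panel sizes this is a ~2–4% relative effect, far smaller
than the selection signals of interest, but it means small LR>DH π
differences should not be over-interpreted.

## Haplotype windows

Windows are half-open tiles anchored at coordinate 0, either 50 kb
physical or 0.2 cM genetic (positions interpolated on a piecewise-linear
map with constant extrapolation beyond the anchors). The sparse-window
filter (< 6 SNPs) applies in dense-array mode and is disabled for genetic
windows on sparse panels. Each phased LR individual contributes two
haplotype strings, each DH line one (its chromosomes are identical;
counting them twice would only rescale `N` and hence the `N/(N−1)`
factor). Strings containing a missing allele are dropped whole rather
than pattern-matched. Nei's `H = N/(N−1)(1 − Σxᵢ²)` is reported for
windows with ≥ 2 distinct LR haplotypes. The most abundant LR haplotype
(ties: lexicographically smallest) is `lost` if absent from DH, `fixed`
if it is the only retained DH string, else `segregating`.

## Enrichment analyses

- **LD pruning**: greedy sliding window (50 SNPs, step 5 — conventional
  defaults, exposed as parameters) removing one SNP of any pair with
  r² > 0.2 over pairwise-complete dosages; the lower-call-rate SNP loses,
  then the later position.
- **Matched controls**: outliers and controls are equalized per 0.1-wide
  allele-frequency bin, and for load comparisons additionally per
  recombination-rate quantile (quintiles by default) computed from 1 Mbp
  genetic-map windows. Deficient cells contribute what they have and the
  deficit is logged.
- **Heterozygosity enrichment**: group means compared by a 1000-replicate
  bootstrap; two-sided p = twice the fraction of resampled differences on
  the opposite side of zero, capped at 1.
- **Genetic load**: positive GERP scores at genotyped SNPs within
  ±0.5 cM of the focal SNP, weighted by genotype — `dosage/2` (additive)
  or the homozygous-alt indicator (recessive), so additive ≥ recessive
  per individual. Missing genotypes contribute zero and leave that site's
  per-individual denominator. Group comparison is a Welch two-sided
  t-test. Scores are attached only at genotyped positions because load is
  defined over observed genotypes.

## The simulator

`synthetic.simulate_accession` draws each stage explicitly: HWE LR
diploids (phased), an iid pool of `n_H` surviving lines, and a
without-replacement line subsample. Viability selection of strength `s`
removes a line carrying the (homozygous) alternative allele with
probability `s`; because a dead line is replaced by an independent fresh
induction, the surviving-line allele law is exactly Bernoulli
`p(1−s)/(1−ps)`, which the simulator samples directly (a unit test checks
the equivalence against an explicit rejection-sampling oracle). With
`lr_viability_selection` (default on, active only at selected sites) the
same recessive cost culls homozygous-alt LR individuals and redraws them,
leaving the heterozygote excess expected of recessive deleterious alleles
in an outbred standing population — without it, LR genotypes carry no
signal distinguishing selected from neutral sites.

Default study conditions mirror a typical conservation panel: 23 LR
diploids (46 chromosomes), a pool of `n_H = 100` lines, 58 genotyped
lines (116 chromosomes), ancestral frequencies uniform on (0.05, 0.95).
The haplotype-window generator composes windows from `K` founder
haplotypes with Dirichlet frequencies — a block model with no
recombination inside windows and no LD between them. Consequently,
passing tests demonstrate the statistics and their calibration under the
stated sampling scheme; they do not certify behavior under realistic LD,
genotyping error or demographic structure, which real panels have and the
generator deliberately omits. Fixture output (VCF, sample sheet, linear
genetic map, GERP mixture track with a point mass at zero and an
exponential positive tail, truth table) is plain text and byte-stable
under a fixed seed.

## Numerical choices

- All probability computations in log space (log-gamma, log-sum-exp);
  surfaces that underflow everywhere raise instead of silently returning
  zeros.
- Interval tails use strict inequalities against `(1 − mass)/2` exactly
  as defined above; no floating-point slack is added.
- Simulation sizes in the tests (up to 10,000 sites, a few hundred
  replicates) are chosen so Monte-Carlo noise sits well inside the
  asserted bounds while the whole suite runs in seconds.
- Degenerate inputs fail loudly: zero genotyped chromosomes, `s = 1` at a
  fixed site (no possible survivor), fewer than two polymorphic sites,
  zero-variance LD vectors (NaN, distinct from r² = 0).

## Known limitations

- Per-site independence in both the model and the simulator; linked
  selection and LD are not modeled (the haplotype block generator is a
  coarse stand-in).
- The pool size `n_H` is assumed known and shared across sites.
- The aSFS interval conditions on the point estimate `p̂_anc`; estimation
  error at extreme frequencies makes the test conservative rather than
  anti-conservative (coverage stays above nominal in simulation).
- Phasing and imputation are consumed, not performed; the error-rate
  metric quantifies an external imputation's quality.
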