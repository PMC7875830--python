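# Methods

This note documents the models behind each `introkit` stage, the parameters
that matter, the numerical choices, and the limits of what the synthetic-data
tests demonstrate.

## Synthetic data generator (`simdata`)

The generator reproduces the *structure* the analysis assumes, not any
particular organism's history.  Per locus *l*:

* an ancestral derived-allele frequency `p_l ~ Beta(a, b)` (default `a=b=1`,
  i.e. uniform);
* each species' frequency drifts independently under the Balding–Nichols
  model, `p_X,l ~ Beta(p_l(1−F_X)/F_X, (1−p_l)(1−F_X)/F_X)`, so
  `E[p_X] = p_l` and `Var = p_l(1−p_l) F_X`.  Defaults `F_A = F_B = 0.2`
  (exposed as parameters; the real three-/nine-spined divergence is much
  deeper, but no usable estimate exists for calibrating it, and 0.2 keeps
  the two-cluster recovery problem non-trivial);
* diploid dosages are `Binomial(2, p_X,l)` per individual; the outgroup is
  fixed for the ancestral allele everywhere, which makes every site
  polarizable and mirrors using a distant reference genome as the ancestor;
* the focal (recipient) individual draws its genotype from the *donor*
  species' frequency at a Bernoulli(`introgression_alpha`) subset of loci
  (or contiguous tracts of `tract_length` loci, for realistic jackknife
  correlation).  The realized mask is the truth record; `q_true` is its
  mean.

Default sample sizes (3 + 5 + 1) mirror the eight-library study design with
a single outgroup.  10,000 loci mirrors the ~10^4 SNPs the original
D-statistic analysis retained.  Loci are spread evenly over 21 chromosomes
(the stickleback karyotype) with increasing positions.

What it does **not** emulate: linkage disequilibrium within chromosomes
(loci are exchangeable), RAD locus dropout and depth-dependent genotyping
error, outgroup polymorphism, and coalescent variance in species divergence.
Passing tests therefore demonstrate the *statistics* are correct and
calibrated under the model's assumptions, not that real stickleback data
would give identical numbers.

SAM simulation copies reads from a random reference with i.i.d.
substitutions; a configurable fraction of reads comes from a contaminant
reference diverged by a given rate, so the expected mismatch rate is
`(1−c)e + c(e + d(1−e/3) − de)` ≈ `e + c·d` to first order.  NM and MD tags
are written from the actual substitutions; the CIGAR is all-match unless an
indel option is enabled.  TE simulation plants exact zero-coverage gaps in
an otherwise constant (or Poisson) coverage track.

## Locus filters (`genio`)

Three filters, applied in order: biallelic-only (exactly one ALT), QUAL
strictly greater than a threshold (default 500; records without QUAL drop),
and invariant-locus removal, where a locus is invariant if every
*non-missing* genotype (as an unordered allele pair) is identical — the only
rule that stays well-defined under missingness; an all-missing locus is
vacuously invariant and drops.  The biallelic and quality filters act on
independent record attributes and commute (property-tested).  Coordinates
are 1-based VCF throughout this module; interval outputs elsewhere (BED
gaps) are 0-based half-open.

## Distances and Neighbor-Joining (`distclust`)

Distances are plain Euclidean on raw 0/1/2 dosages — no standardization, as
is usual when clustering genotype matrices directly.  Missing data are
handled pairwise-complete with `L/L_complete` rescaling inside the squared
sum, which makes the squared distance unbiased for its complete-data value
under loci-exchangeability; `complete-only` mode restricts to universally
typed loci instead.

NJ is the textbook Saitou–Nei agglomeration on `Q(i,j) = (n−2)d(i,j) − r_i −
r_j`.  Numerical choices: ties in the Q minimum break on the lowest (i, j)
index pair (deterministic output); negative limb-length estimates are
clamped to zero with the deficit moved to the sibling branch so path lengths
are preserved where possible; the final three nodes resolve by the
three-point closed form with plain clamping.  NJ is consistent on additive
matrices — the test suite verifies exact recovery of random 8-taxon trees
and agreement with an independent NJ implementation.

## Admixture model (`admixmc`)

The Structure admixture model: allele copy *c* of individual *i* originates
from cluster `z ~ Categorical(Q_i)` and is derived with probability
`f_z,l`.  Priors: `Q_i ~ Dirichlet(alpha)`; uncorrelated model
`f_kl ~ Beta(lambda, lambda)` (conjugate); correlated model (default)
`f_kl ~ Beta(p_l(1−F_k)/F_k, (1−p_l)(1−F_k)/F_k)` with `p_l ~ Uniform(0,1)`
and `F_k ~ Gamma(2, 0.05)`.

One Gibbs sweep: (a) multinomial reassignment of every copy's origin
(vectorized as sequential binomial splits over clusters); (b) frequency
update — conjugate Beta in the uncorrelated model, element-wise
Metropolis–Hastings under the drift prior in the correlated model, plus MH
updates of each `F_k` and each `p_l`; (c) conjugate Dirichlet update of each
`Q_i`; (d) optionally an MH update of `alpha` with uniform prior on (0, 10].
MH step sizes adapt toward 20–50% acceptance during burn-in only, so the
collected chain satisfies detailed balance.  Missing genotypes contribute no
copies.

Numerical/design choices that were genuinely open:

* **Initialization.**  Cluster frequencies are seeded from K distinct
  randomly chosen samples' smoothed observed frequencies (a k-means++-style
  overdispersed start).  A prior-drawn start leaves short chains in a
  metastable symmetric state (all clusters near the pooled frequencies, Q
  diffuse) whose Q values are far from the exact single-sample posterior
  computed by grid integration; the seeded start reaches the separated mode
  within a few hundred sweeps.  `freq_init="prior"` restores the pure-prior
  start.
* **Ancestry prior.**  Default `alpha = 1` held fixed — the uniform
  distribution on each ancestry vector.  Inferring `alpha` (available via
  `alpha_mode="infer"`) drives it to ~0.1 when most individuals are pure,
  and the resulting Dirichlet boundary spike absorbs a single individual's
  small admixture fraction at desk-scale locus counts (simulation: mean
  recovery error −0.05 vs −0.01 with the uniform prior).  At the locus
  counts of a real RAD study the likelihood dominates either prior.
* **Label switching** is resolved by greedy permutation matching of the
  cluster frequency vectors to a running reference within each chain, and by
  matching frequency means across chains.  Multi-chain fits report the
  maximum cross-chain disagreement in posterior mean Q.
* **Intervals** are equal-tailed 5th–95th percentiles of the retained Q
  trace.
* The admixture stage of the pipeline fits the *ingroup* samples only: a
  distant monomorphic outgroup individual otherwise captures one of the K
  clusters.

Known limitation: with a single admixed individual among few conspecifics,
the joint posterior mildly attenuates the admixture fraction — the focal
individual's donor-like copies also inform the conspecific cluster's
frequency estimates.  The effect shrinks as reference panels grow; the
recovery tests quantify it at the scaled study conditions (mean |error|
≈ 0.04 at q_true = 0.10 with 1,000 loci).

## ABBA-BABA D (`abbababa`)

Sites are polarized by the outgroup: the allele the outgroup carries is
ancestral; sites with a heterozygous, polymorphic, or missing outgroup are
dropped, as are sites with missing data in any involved sample and sites
with no derived variation.  A reference-nucleotide column can replace a
genotyped outgroup.

For the quadruple (Outgroup; P1, P2, Test) with P2/Test the sister pair,
per-site weights are `abba = p1(1−p2)p3` and `baba = p1 p2 (1−p3)`, so

    D = Σ p1 (p3 − p2) / Σ p1 (p2 + p3 − 2 p2 p3)

— the frequency-weighted estimator of the classic four-population test with
the outgroup at derived frequency 0.  Under incomplete lineage sorting alone
the sister pair is exchangeable and E[D] = 0; excess derived-allele sharing
between Test and P1 drives D positive.  With haploid-coded single-individual
populations the weights reduce to integer pattern counts (the exact oracle
in the tests).  The standard error is a delete-one-block jackknife over
contiguous blocks (default 50 equal-count blocks; per-chromosome blocks
optional), skipping blocks with zero pattern weight; `Z = D/SE`, with SE = 0
reported as an infinite-Z degenerate flag.

Power note: with the generator's default drift (F = 0.2) and a single
diploid test individual, the per-site signal-to-noise of D at a 5%
introgressed fraction is ≈ 1 (E[D] ≈ 0.013, SD ≈ 0.013 at 10^4 sites), so
the one-sided sign test detects it in roughly 85% of replicates; detection
is essentially certain by a 10% fraction or with deeper divergence.

## Contamination statistic (`contamcheck`)

Per library: `error_rate = substitutions / aligned bases`, where aligned
bases sum CIGAR M/=/X over primary mapped reads and substitutions are NM
minus inserted/deleted bases (MD-derived when NM is absent) — the
samtools-stats definition of the mapping error rate.  Cross-sample
comparison reports robust z-scores `(rate − median)/MAD` and flags rates
above `median + 5·MAD` (configurable); with zero MAD, anything above twice
the median.  The statistic is additive over reads, hence invariant to read
order and file sharding.  The point of the comparison: a genuinely admixed
sample has an ordinary error rate, a cross-contaminated library an elevated
one.

## TE diagnostic primers (`temarkers`)

Gaps are maximal runs of coverage ≤ `max_depth` (default 0) of length ≥
`min_length` (default 250, leaving room for a 200–500 nt product plus
primer footprints).  Candidate primers are enumerated inside the gap and
filtered by: length 18–25 nt, GC 0.40–0.60, Tm 50–62 °C (nearest-neighbor
thermodynamics, unified parameter set at default salt/primer
concentrations; the Wallace 2(A+T)+4(G+C) rule is available), pair ΔTm ≤
3.5 °C, no homopolymer run of 5+, and an optional (off by default) 3′ G/C
clamp.  These windows were calibrated once against the 24-primer published
stickleback TE panel shipped with the package — all 24 pass, several end in
A/T (hence no default clamp) and the panel's Tm range (52.0–59.1 °C) sets
the window.  Pairs are ranked by
`|ΔTm| + 10·(|GC_f − 0.5| + |GC_r − 0.5|) + 0.01·|product − target|` with
coordinate tie-breaks, so output is deterministic.

The in-silico screen calls a product when the forward primer and the
reverse primer's complement match the template in the correct orientation
within the product-length window, allowing a configurable number of
substitutions but requiring the 3′-terminal bases (default 3) to match
exactly — mimicking polymerase extension sensitivity.  No dimer/hairpin
thermodynamics or multiplexing constraints are modeled.

## Pipeline (`pipeline`)

Stages run in dependency order from one config (YAML or in-code); every
stage writes its table next to a human-readable summary and a JSON report
carrying the config digest and seed.  All randomness derives from the
config seed, so reruns are byte-identical.  A stage failure aborts with the
stage's name; completed outputs stay on disk.

## Problem sizes in tests and the acceptance script

Statistical checks use deliberately scaled designs chosen to give stable
verdicts in minutes on one CPU: 200 replicates of 10^4 SNPs for null
calibration of D, 50 replicates per introgression level for power, 50
replicates of 1,000 loci with 750-sweep chains for admixture recovery, 100
random 8-taxon matrices for NJ, 2,000 simulated reads per library for the
contamination check.  The CLI defaults keep the original full-scale chain
lengths (10,000 burn-in + 20,000 collection sweeps).
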