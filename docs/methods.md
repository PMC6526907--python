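# Methods

`fasterx` re-implements, end to end on synthetic data, a comparative analysis
of X-chromosome and autosome evolution in spiders with X1X2/0 sex
determination: assigning genome scaffolds to the X chromosomes from
flow-sorted sperm-pool sequencing, contrasting coding substitution rates
(dN/dS) and nucleotide diversity (pi) between X and autosomes in a subsocial
outcrossing species and its social inbreeding sister species, the
McDonald-Kreitman test, closed-form sex-ratio/mutation-bias theory, and
coalescent simulations of recurrent founder events. This note records the
models, the defaults and why, and what the synthetic data do and do not
establish.

## Scaffold assignment from sorted sperm pools (`xassign`)

Sperm nuclei of X1X2/0 males either carry both X chromosomes or neither, so
flow sorting yields an X-depleted pool ("pool 0") and an X-enriched pool
("pool X1X2"). After down-sampling the larger pool so both have equal totals
(per-read hypergeometric subsampling across scaffolds, preserving each
scaffold's expected share), the per-scaffold statistic

    P0 = reads_pool0 / (reads_pool0 + reads_poolX)

is near 0 for X-linked scaffolds (only sorting impurity places X chromatin in
pool 0) and slightly above 0.5 for autosomal ones (pool X1X2's reads spread
over more sequence, so autosomes get proportionally fewer of them there).
Scaffolds with fewer than 100 pool-X1X2 reads are too noisy to call and stay
unassigned.

The bimodal P0 density is modelled as a two-component beta mixture fitted by
EM (`BetaMixtureEM`, a scikit-learn-style estimator with random restarts and
weighted method-of-moments M-steps; beta components handle the X mode's
proximity to 0). Scaffolds enter the likelihood unweighted — one point per
scaffold — with a read-count-weighted option exposed (`weighted=True`)
because the original analysis's density convention is not documented.
Posterior membership probabilities drive the thresholds: t_x is the largest
P0 cutoff at which the expected fraction of autosomal scaffolds among calls
below it (1 − posterior, averaged over calls) stays at or below the nominal
FDR (default 2.5%), and t_a symmetrically bounds expected X contamination
among autosomal calls. The FDR is model-based (from fitted posteriors, not
held-out truth); on synthetic data the realized FDR is checked against the
nominal level. Lowering the FDR can only shrink the X set (prefix
construction), and a non-converged fit refuses to assign unless forced.

## Substitution counting (`divergence`)

Three-species codon alignments — two ingroups and an outgroup on the fixed
topology ((ingroup1, ingroup2), outgroup) — are reduced per gene to
branch-polarized counts with an NG86-style estimator: fractional
synonymous/nonsynonymous site counts per codon (each position contributes one
site split by the fraction of its sense changes that are synonymous; changes
to stops excluded), averaged over the three sequences. A codon column whose
difference is carried by exactly one ingroup (outgroup matches the other) is
assigned to that ingroup's branch and decomposed by averaging over minimal
substitution paths that avoid stop codons. Columns where both ingroups share
a non-outgroup state put the change outside both ingroup branches; columns
where the outgroup matches neither differing ingroup cannot be polarized and
are excluded from numerators *and* denominators to avoid biasing branch
attribution. Codons containing N, IUPAC symbols or gaps in any species are
removed from all three before counting.

This counting estimator stands in for codon-model maximum likelihood, which
is adequate at the divergences involved here (dS below a few percent, where
counting and ML estimates agree closely); alignments can be exported as
per-gene FASTA for external ML estimation if desired. Pooled dN and dS divide
summed substitution counts by summed site counts — never averaged per-gene
ratios — so pooled dN/dS equals pooled dN over pooled dS by construction.
CIs bootstrap over genes (default 1,000 replicates, percentile bounds, via
multinomial gene weights). Hypothesis tests permute labels: chromosome class
within a species (statistics: pooled omega difference, log dS ratio, or the
between-species difference of X/A omega ratios) or species within a class
(gene-wise swap of the two ingroup branches). Two-tailed p-values use the
add-one correction (1 + #{|null| >= |obs|}) / (n_perm + 1); ratio statistics
are compared on the log scale.

## Diversity (`diversity`)

Nei pi is the average over sequence pairs of the per-site difference
proportion, excluding for each pair the sites where either member carries a
gap, N, or other non-ACGT symbol. Per population and chromosome class, RAD
locus alignments are concatenated in a fixed order (scaffold, then position;
missing individuals as gap rows — the order is a package convention, chosen
for reproducibility) and cut into equal blocks. The universal block length is
floor(min over populations of the X-class total length / 15), anchoring the
thinnest X set at 15 blocks; remainder sites are discarded so every block is
exactly equal-length. Mean pi per set gets a percentile bootstrap CI over
blocks (default 10,000 replicates).

piX/piA is built pairwise: autosomal blocks are shuffled into as many
near-equal groups as there are X blocks, each group contributes its *median*
pi (pi distributions are strongly right-skewed, with many zero-diversity
blocks in inbred populations), and groups are randomly paired with X blocks;
zero-median pairs are dropped with a logged count. Species differences in the
ratio are tested with a linear mixed model (species fixed, population random
intercept, ML fit) against the intercept-only model by likelihood ratio
(chi-square, 1 df); the response is the raw ratio by default with a log-ratio
option, and a singular fit falls back to a t-test on population means.
Population differences within a species use one-way ANOVA with Tukey HSD
letters. Scaffold-level dispersion uses CV = sample SD / mean over scaffolds
with at least 3 RAD loci, bootstrap CI over scaffolds; the CV is undefined
when mean pi is 0, which is exactly the zero-diversity saturation that
precludes this comparison in heavily inbred populations.

## RAD library construction (`radlib`)

Consensus calling is coverage-tiered: depth below 3 or in [3, 7] emits N
(masked but coordinate-preserving); depth >= 8 calls the majority base,
upgraded to a two-base IUPAC code when the minority base has >= 3 reads
and/or frequency > 10%. The "and/or" in that rule is implemented as inclusive
OR by default (the most permissive reading) with an AND switch. More than two
qualifying bases masks the position. Sequences with >= 2.5% IUPAC symbols are
discarded. Stacks are exact-identity read groups with >= 3 copies; reference
construction clusters stacks from all conspecific individuals greedily
(descending count, ties lexicographic) into centroids at > 98% identity
(matching columns / length over equal-length reads), then keeps one
representative per mapped (scaffold, position, strand) — highest count,
ties to the lexicographically smallest sequence. Diploid consensus splits
each two-base IUPAC position into two alleles with arbitrary phase;
per-site allele counts, which is all pi uses, are phase-invariant. Read
quality scores are not modelled anywhere in this module: synthetic reads
carry no quality dimension, so all rules operate on counts (raw-read quality
trimming thresholds such as per-base Phred < 10 / mean < 30 belong upstream
of this package's inputs).

## Theory (`theory`)

Wright's effective sizes, Ne_X = 9NmNf/(2(2Nm+Nf)) and Ne_A = 4NmNf/(Nm+Nf),
give Ne_X/Ne_A = 9(Nm+Nf)/(8(2Nm+Nf)): 0.75 at equal breeder numbers,
bounded in (9/16, 9/8). The X1X2/0 karyotype behaves as standard X linkage
(both X chromosomes hemizygous in males), so these formulas apply unchanged.
The expected piX/piA curve multiplies this ratio by a standardization factor
anchoring it to an observed reference (e.g. observed/0.75 in a species with
an equal sex ratio), absorbing sex-ratio-independent effects such as a lower
X mutation rate; the standardization is multiplicative by default with an
additive option, and the curve inverts numerically (Brent on log Nf/Nm) to
an operational sex ratio.

Male mutation bias: X chromosomes spend 1/3 of their history in males, so
with male-to-female substitution ratio alpha the expected X/A synonymous
divergence ratio is k = (2/3)(2+alpha)/(1+alpha), inverted as
alpha = (4−3k)/(3k−2), valid for k in (2/3, 4/3]. Before inversion, raw X/A
divergence ratios are divided by the expected X/A ratio of total divergence
time, (T + 2·0.75·N_A)/(T + 2·N_A), which accounts for the shorter ancestral
coalescence time of X chromosomes. With ancestral N_A = 300,000 and
T = 400,000 generations this factor is 0.85; T = 400,000 is the documented
default because it is the unique value consistent with that printed factor
under the stated assumptions (the original generation-time conversion is not
public). The operational-sex-ratio inversion reports what the multiplicative
standardization implies; it is not forced to agree with any particular
published figure.

## Coalescent engine and founder events (`coalescent`, `foundersim`)

Independent loci, no within-locus recombination, infinite-sites mutation.
The genealogy sampler handles piecewise-constant diploid Ne by precomputing
the cumulative coalescent intensity Lambda(t) = integral dt/(2N(t)) and
inverting it by binary search, so periodic crash/recovery histories with
hundreds of epochs cost O(log epochs) per coalescence. A mutation carried by
d of n samples adds d(n−d) pairwise differences; E[pi] = 4·Ne·mu at
equilibrium. The same engine backs the RAD generator (which also records
carrier sets to emit sequences). Cross-checks: an independent oracle
(msprime) agrees on constant-size mean pi within Monte Carlo error, and a
genotype-route/direct-route internal comparison guards the mutation placement.

Founder-event scenarios share one crash schedule between compartments sized
ne_a = 20,000 and ne_x = 15,000 with mu = 1.2e-8 (matching RAD-scale
diversity) and 20,000 independent 100-bp loci by default, sampling 20
chromosomes; crashes recur every 50 or 100 generations at 1% or 10% of
standing size, parameterizable alternatively as an absolute founder propagule
in chromosome copies. Recovery is instantaneous by default with an
exponential-ramp option (8 steps per cycle); the original growth handling is
not documented.

A structural finding worth recording: when crash sizes are proportional to
each compartment's Ne, the *periodic steady state* of the crash cycle leaves
the expected piX/piA essentially at 0.75 (the two compartments' coalescent
intensity functions are exact scalar multiples, and direct integration of the
pairwise survival function confirms deviations below 0.001). The depression
of piX/piA is the Pool-Nielsen *transient*: once recurrent founder events
begin, diversity relaxes over ~Ne generations toward a much lower dynamic
equilibrium, and throughout that relaxation the faster-equilibrating X sits
disproportionately low (analytically ~0.70 after 100 cycles of 1% crashes
every 50 generations, versus 0.744 after 10 cycles). Simulations that sample
only a few cycles after onset therefore see almost no effect; the package's
tests sample 100+ cycles in, which matches the biological picture of social
lineages with long-established extinction/recolonization dynamics.

## Synthetic data (`synth`) — what it emulates and what it does not

* Sorted-pool counts: Poisson reads per scaffold-pool cell, expectation
  proportional to scaffold length (gamma-distributed, mean 100 kb) times the
  pool's copy fraction; defaults 3,000 scaffolds, 12% X-linked, 10% impurity
  in pool 0, 2% in pool X1X2, one million reads per pool — a regime with the
  same bimodal geometry (modes near 0.10 and 0.53) as real sorted-pool data.
  Not modelled: mappability variation, GC bias, overdispersion beyond
  Poisson.
* Codon alignments: per-branch Gillespie simulation over sense codons; each
  specific synonymous change fires at rate mu = dS/3 and each nonsynonymous
  change at mu·omega, so branch length calibrates to expected synonymous
  divergence. No transition/transversion bias, no codon frequency bias, no
  rate heterogeneity — sufficient for the ratio and recovery properties the
  pipeline asserts, not for absolute divergence calibration (realized
  NG86-site dS runs a few percent below nominal because stop-adjacent
  positions shrink NG86 denominators; all recovery checks are ratio- or
  omega-based).
* RAD loci: neutral coalescent per locus (free recombination between loci,
  none within), theta_a per site for autosomes and theta_a·x_factor for X
  loci, loci packed 5 per synthetic scaffold. Not modelled: linked
  selection, missing-data structure, allele dropout.
* MK inputs: a synthetic CDS with one variant per codon (GGA->GGG synonymous,
  ATG->ATA nonsynonymous) whose classified counts equal the requested
  Pn/Ps/Dn/Ds exactly — a bookkeeping harness, not a population model.

Passing tests on these generators establish estimator correctness and
calibration under the stated models; they say nothing about robustness to
mapping artefacts, selection, or demographic misspecification in real data.

## McDonald-Kreitman (`mktest`)

Variants in CDS context are classified by translating reference and
alternate codons (stop gain/loss is "other" and excluded); polymorphisms
require coverage >= 10. Alpha = 1 − (Ds·Pn)/(Dn·Ps), reported per chromosome
class, with the neutrality index (Pn/Ps)/(Dn/Ds); no divergence correction
and no low-frequency-variant correction are applied, and sites both
polymorphic and divergent count in both categories. Internal substitution
counts (from `divergence`) serve as the divergence source by default.

## Numerical conventions

Coordinates are 0-based half-open throughout (VCF-style POS is converted on
input); P0 values are clipped to [1e-6, 1−1e-6] before beta likelihoods; EM
convergence is a relative log-likelihood change below 1e-8 within 500
iterations over 8 restarts; bisection/Brent tolerances are 1e-6 on the sex
ratio; percentile CIs are 2.5/97.5. Every stochastic stage takes an explicit
seed, and the pipeline fans per-stage seeds out of one master seed by a fixed
affine scheme (`pipeline.stage_seed`), so one integer reproduces every output
byte. Test and demonstration problem sizes (e.g. 1,500-20,000 loci, 2,000
genes per class, 10 seeds for simulation contrasts) were chosen so each
statistical check has several-fold more precision than the effect it asserts
while keeping a full run on one CPU in minutes.

## Known limitations

* The beta-mixture/EM assignment is a documented stand-in for the original
  (unpublished) Bayesian mixture specification; posteriors, not a posterior
  distribution over partitions, drive the FDR thresholds.
* Counting-based dN/dS ignores multiple-hit saturation beyond within-codon
  path averaging; do not use it at dS >> 0.1.
* The mixed model for the species contrast treats subalignment ratios as
  exchangeable within populations; block autocorrelation along scaffolds is
  not modelled.
* Absolute published quantities that depend on the real sequencing data
  (Table-scale dN/dS values, the empirical piX/piA of 0.57/0.72, the real
  mixture means and thresholds) are inputs or context here, not outputs; the
  package reproduces their arithmetic and the properties of the estimators,
  not the raw-data estimates themselves.
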