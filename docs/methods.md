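# Methods

This note records the models implemented in sitesieve, the defaults and
the reasoning behind the choices that were genuinely open.

## Likelihood engine

Substitution models are reversible: $Q_{ij} = s_{ij}\pi_j$ with symmetric
exchangeabilities $s$ and stationary frequencies $\pi$, scaled to one
expected substitution per site per unit branch length. Transition
probabilities come from the eigendecomposition of the $\pi$-symmetrized
generator, which vectorizes over sites and rate categories. Among-site
rate variation uses a discrete Gamma with $k=4$ categories by default,
each category set to the mean of its quantile bin (mean-one rates).
Nucleotide (4-state) and protein (20-state, equal-exchangeability or
loadable PAML-style table) alphabets are supported; IUPAC ambiguity codes
enter the likelihood as unions of compatible states, and `-`/`?`/`N`/`X`
as complete uncertainty.

Site patterns are compressed before pruning. Partial likelihoods are
rescaled per node (log-scale accumulators), so long trees do not
underflow. Per-site values always sum to the total within $10^{-8}$, and
the pruning result is tested against exhaustive enumeration over
internal-node states on trees of up to 5 taxa at $10^{-10}$.

**Fixed-topology fitting** is coordinate ascent: Brent optimization of
each branch length in $[10^{-8}, 10]$ against cached inside/outside
partial products (each one-branch profile is exact when optimized, so the
ascent is monotone), alternating with Nelder-Mead moves on log-transformed
exchangeabilities, frequency logits and the Gamma shape. Sweeps stop when
the log-likelihood improves by less than $10^{-6}$ (default) or after 100
sweeps; non-convergence returns the best point with a warning.

**Per-site rates** are ML rate multipliers $r_i \in [0, 50]$ scaling all
branch lengths, with the Gamma mixture disabled for this step (the
multiplier replaces it); the optimum is found on a geometric grid refined
by vectorized golden-section search, and verified against a dense-grid
oracle. Constant sites sit exactly at the lower bound 0. The final rate
is the arithmetic mean across the fitted hypotheses. The profile
$\ell_i(r)$ can be bimodal for saturated sites (a near-flat plateau at
high $r$); ties between plateau points are scientifically irrelevant and
resolved by whichever the grid sees first.

**Tree search** is exhaustive enumeration (only permitted up to 8 taxa;
$(2n-5)!!$ topologies) or NNI hill climbing from a neighbor-joining start
(JC-corrected distances), with substitution parameters fitted once on the
start tree and held fixed while candidate topologies are compared on
optimized branch lengths.

## Site table and discriminant analysis

Per-clade GC content is $(\#G + \#C)/(\#A+\#C+\#G+\#T)$ among the clade's
taxa at the site; ambiguity codes are excluded from both numerator and
denominator, and a site where no clade taxon has an unambiguous base is
imputed with the feature's mean over sites (discarding such sites would
silently shrink the matrix). Missingness counts `-`, `?`, `N`/`X`.
The preferred topology is the arg-max of the per-site scores; differences
below a tolerance (default $10^{-9}$, i.e. exact ties only) are labelled
*uninformative*. Uninformative sites stay in the alignment, are excluded
from discriminant training, and are never ranked for removal.

LDA uses the pooled covariance with denominator $n-K$; QDA per-class
covariances with $n_k - 1$. A ridge of $10^{-6}\times$ the mean feature
variance (computed once, from the full data) stabilizes near-constant
features such as clade missingness in block-missing matrices. Class
priors are the observed class proportions. Leave-one-out posteriors are
computed exactly by rank-one downdates of the left-out class's mean and
scatter with batched linear algebra — no refitting loop — and match a
naive per-leave oracle to $10^{-8}$.

Two confidence metrics are available for ranking sites:

* `observed_ratio` (default): the LOOCV posterior of the site's observed
  class divided by that class's prior;
* `predicted_posterior`: the maximum LOOCV posterior.

They answer slightly different questions. The ratio rewards sites whose
*own* class is locally enriched relative to its prior — with few classes
and few features this can rank a rare class's core sites highest even
when that class carries the genuine signal. The predicted-class posterior
ranks by sheer predictability of the decision, which in the two-class
validation study is what actually isolates the biased (fast, convergent)
sites; the study therefore uses it, and both remain available.

The permutation test shuffles the preferred-topology labels among sites
(default 1000 replicates; seeded) and recomputes the mean LOOCV
posterior/prior ratio; $p = (1 + \#\{\text{null} \ge \text{obs}\})/(B+1)$.
Its null distribution is verified to be uniform by a 200-dataset
Kolmogorov–Smirnov calibration study.

Filtering removes $\mathrm{round}(f \cdot n_{\text{eligible}})$ top-ranked
informative sites (ties broken by site index) and emits both the retained
and the discarded alignment; the random control removes the same number
of eligible sites uniformly at random under a fixed seed.

## AU test

RELL bootstrap: at each scale $r \in \{0.5, 0.6, \dots, 1.4\}$,
$B = 10{,}000$ replicates draw $\mathrm{round}(rn)$ sites with
replacement and record the winning hypothesis (ties uniformly at random,
seeded). Bootstrap proportions of 0/1 get a $0.5/B$ continuity
correction. $\Phi^{-1}(1-\mathrm{BP}(r)) = d\sqrt r + c/\sqrt r$ is
fitted by weighted least squares with delta-method weights
$B\,\phi(z)^2 / (\mathrm{BP}(1-\mathrm{BP}))$, and
$p_{AU} = 1 - \Phi(d - c)$. A hypothesis with fewer than two
non-degenerate scales is flagged and assigned $p = 0$ or $1$. Results
depend on the scores only through per-site differences; for i.i.d.
Gaussian differences the p-value matches the conditional normal
approximation $\Phi(-T/(\sqrt n\, s))$.

## Non-stationary simulator

Each branch evolves under the shared exchangeabilities paired with its
own equilibrium frequencies (generator renormalized per branch to one
expected substitution per unit length); the root state is drawn from the
root frequencies, and sites are i.i.d. within a partition, optionally
with Gamma-distributed per-site rate multipliers or a discrete rate
mixture.

### The 8-taxon validation design

Two partitions share a balanced topology of four two-taxon clades with a
short innermost branch; the A and D stems are long (0.3 in the 1000-bp
partition, 0.5 in the 500-bp partition) and those stems plus the tips
they subtend evolve toward GC 0.8, all other branches at GC 0.5 (root GC
0.5, AT and GC split evenly). Defaults for the terms the design leaves
free: a shared transition/transversion bias $\kappa = 4$ (a standard
value for vertebrate nuclear coding sequence) and strong among-site rate
variation, Gamma shape $\alpha = 0.3$.

These two defaults are load-bearing and were chosen deliberately. With
homogeneous site rates and equal exchangeabilities the design produces
*no* reconstruction artifact at all under a correctly optimized ML
search (verified against FastTree as an independent implementation):
parsimony-level support for the artifactual grouping exists, but
likelihood discounts it. The artifact this design is meant to exhibit
requires saturated, compositionally convergent sites *and* an analysis
model that does not absorb the rate variation. The validation study
therefore analyzes under a rate-homogeneous GTR with empirical base
frequencies — the filtering method estimates its own per-site rates, and
the unmixed search is precisely the regime the filter is meant to repair.

What a passing study does and does not show: the simulator emulates
compositional attraction with rate heterogeneity on a small balanced
tree; it does not emulate alignment error, heterotachy within sites,
model variation among genes, or the taxon-sampling effects of real
matrices. Success here demonstrates the method's mechanics, not its
field performance.

Measured behavior at these settings (20 seeds, also recomputed by
`scripts/acceptance.py`): the unfiltered NNI search is captured by the
artifactual grouping in roughly 85% of replicates; rate-only QDA
filtering recovers the generating topology increasingly often as the
threshold deepens (about 30% of replicates at the 10% threshold up to
about 85% at the 50% threshold), while random removal of the same number
of sites stays near 20–35% at every threshold. The residual failures at
shallow thresholds have a structural cause: the artifact's log-likelihood
margin is partly carried by a large mass of weakly biased, near-invariant
sites which are uninformative (hence never ranked or removed), so
removing the top tenth of ranked sites cannot always flip the search.

### Multi-gene study fixture

`synthetic_study_generator` emulates a reduced-scale multi-gene matrix:
default 12 taxa, 20 genes of roughly 450 bp (normal lengths, rounded to
codons, minimum 150), log-normal among-gene rate multipliers
($\sigma = 0.6$), one clade with GC elevated by 0.15, a fifth of genes
simulated on an NNI-perturbed alternative topology, and block-wise taxon
deletion to a 50% occupancy target. The per-taxon keep probability is
solved numerically so that the expected occupancy hits the target despite
the minimum-taxa-per-gene floor (a naive Bernoulli deletion with
rejection biases occupancy upward). The truth record stores every drawn
parameter for downstream checks.

## Numerical and interface choices

* Branch lengths live in $[10^{-8}, 10]$; Brent tolerance $10^{-5}$.
* Partial-likelihood products are clipped at zero before rescaling
  (eigendecomposition roundoff can produce tiny negative values).
* Codon-level transforms assume reading frame 1 per gene; degeneracy
  recoding is derived programmatically from the standard genetic code
  (per position, the IUPAC code covering all nucleotides among the
  synonymous codons of the encoded amino acids); codons containing
  missing characters pass through unchanged, stop codons recode over the
  stop family with a warning.
* Coordinates are 1-based inclusive throughout the file formats; PHYLIP
  I/O uses the relaxed sequential dialect.
* Filtering fractions apply to the informative (rankable) sites; this is
  configurable at the call site by passing a different eligibility set.
* The pipeline is a pure function of (inputs, configuration, seeds);
  reruns are byte-identical.

## Known limitations

* The likelihood engine targets desk-scale problems (tens of taxa); there
  is no SSE/threaded kernel and no SPR search.
* Partitioned fits (`fit_partitioned`: shared branch lengths, unlinked
  per-gene substitution parameters) optimize branches against the summed
  per-gene likelihoods; partitioning-strategy selection is up to the user.
* QDA assumes Gaussian class-conditional features; site-rate
  distributions are skewed, and no interaction terms are modeled.
* AU p-values inherit RELL's assumption that per-site scores are fixed
  (no refitting within replicates).
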