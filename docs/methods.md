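# Methods

## The transmission model

The package tracks amplicon sequence variants (ASVs) — exact 16S sequence
units used as strain-level tokens — across a pedigree design: several
maternal parental colonies crossed with a single shared paternal colony,
each cross yielding one pedigree of offspring colonies. Three sample tiers
exist per pedigree: parental-colony workers, founding reproductives
(alates, the transmission bottleneck), and offspring-colony workers. All
samples are pooled-gut communities (5–10 guts per extraction), so the
colony, not the individual insect, is the observational unit.

**Classification rule.** An ASV is *vertically transmitted* within a
pedigree and lineage when it is (i) present in ≥ 1 parental worker sample
of that lineage, (ii) present in *every* founding-reproductive sample of
that lineage × pedigree, and (iii) present in ≥ 1 offspring sample of the
pedigree. Requiring all founder samples makes the call robust to a single
founder carrying a taxon by chance; requiring only one offspring sample
reflects that offspring samples pool few, small colonies. The rule is
monotone in read counts: adding reads can only add calls.

Parental presence is evaluated on *worker* samples only by default
(workers house most of the colony microbiome; parental queens/kings carry
low microbial loads and would add noise); `parental_castes` widens this.
Maternal and paternal lineages are classified symmetrically and merged
into uniquely-maternal / uniquely-paternal / shared / none status. Note
that paternal inheritance estimated this way is sensitive to when the
paternal colony was sampled; the package classifies what the presence
patterns support and leaves that caveat to interpretation.

**Presence** means ≥ 1 read after the dataset-level filter (ASVs with
< 25 reads summed over all samples are removed; strictly "less than", so a
25-read ASV survives). There is no per-sample threshold by default;
`min_count` exists for sensitivity analysis. Zero-read samples are kept
and reported as undefined rather than dropped.

## Abundance-weighted null model

To ask whether founders simply take up whatever is abundant, the null
model draws, per pedigree, ASV sets of the observed inherited size from
the maternal-worker pool *without replacement*, with selection probability
proportional to mean relative abundance in those workers. Draws are sets
because inherited ASV collections contain no duplicates. Sampling uses
exponential-race keys (each ASV gets an Exp(weight) arrival time and the
earliest n are taken), which is distributionally identical to sequential
draws with renormalization; the test suite verifies this against exact
enumeration over all ordered draw sequences for small pools. Default 100
iterations, seed always recorded.

Each draw is summarized by genus richness (distinct genus labels, with
unresolved genera grouped as `unclassified_<lowest resolved rank>` so the
partition stays exhaustive) and compared to the observed richness with a
proportion-based permutation p-value: with `alternative="less"`, p is the
proportion of null values at or below the observed statistic — if 96 of
100 null values lie above it, p = 0.04. Ties count toward the tail
(conservative). The raw proportion can be exactly 0 with finite
iterations, so the add-one variant (count+1)/(n+1) is always reported
alongside; the raw convention stays the default.

## Within-genus abundance and transmission

Relative abundances are centered by subtracting the genus mean
(per context: maternal workers, founders, or offspring workers), isolating
within-genus rank from between-genus composition; centered values sum to
zero within each genus by construction. For display, centered values are
spread with the odd, monotone transform y(x) = sign(x)·ln(1 + |x|/1e-5)
(natural log; the constant 1e-5 sets the scale at which the transform
turns logarithmic).

Whether centered abundance predicts transmission is tested with a
permutation test stratified by (pedigree, genus): the statistic is the
mean centered abundance of transmitted minus non-transmitted ASVs, and the
null permutes labels *within* strata, holding per-stratum label counts
fixed — the permutation analogue of controlling pedigree and genus as
grouping factors in a mixed model, without a parametric error model.
Strata containing a single label class carry no information and are
dropped with a warning. The suite checks type-I error control under
label-independent values and exact recovery of a planted shift.

## Network assortativity

Signed ASV co-occurrence networks (positive = co-occurrence, negative =
co-exclusion) are consumed as edge lists from any inference tool; before
network construction ASVs with < 200 total reads are removed (again
strictly "less than"). Newman's categorical assortativity is computed on
the unweighted edge mixing matrix e (each undirected edge contributes
symmetrically): r = (Σᵢeᵢᵢ − Σᵢaᵢbᵢ)/(1 − Σᵢaᵢbᵢ). r = 1 iff no edge joins
the two classes; when every edge joins a single class the denominator
vanishes and r is reported as undefined (None) rather than a number.
Edge weights are ignored by design — inheritance is a categorical node
attribute; a weighted variant was deliberately not made the default.
Display-only filters (e.g. keeping nodes with ≥ 6 connections) are never
applied before computing the coefficient.

The null comparison recomputes r on the *fixed* topology under labelings
derived from the abundance-weighted null draws (drawn set → inherited),
with a one-sided (greater) permutation p-value for assortativity excess.
Null draws must be taken from the network's node pool; a draw naming an
absent node is an error rather than silently ignored.

## Synthetic data generator

The generator emulates the pedigree design so every stage has planted
ground truth: a global pool of ~300 core ASVs nested in 60 genera
(geometric genus sizes, mean 5), per-colony log-normal expected abundances
over a random 80% subset of the pool, a heritable fraction (default 0.25)
of each colony's ASVs, founder samples in which heritable ASVs are boosted
3× and non-heritable parental ASVs drop out with probability 0.8 per
sample, and offspring communities mixing the maternal + paternal heritable
sets (at mass fraction 0.5) with an environment-only pool of 200 ASVs that
never occurs in parents. Read counts are Dirichlet-multinomial at 50 000
reads per sample.

Parameter notes:

* **overdispersion (default 50)** is the per-taxon Dirichlet concentration
  at mean abundance: the concentration vector is
  `overdispersion · S · q` for a community of S taxa with proportions q.
  At the default, sampling is close to multinomial (little
  presence/absence dropout); values of order 1 produce the heavy dropout
  regime. `math.inf` disables compositional noise entirely (pure
  multinomial), which is the setting under which planted heritable ASVs
  satisfy the classification rule by construction.
* **lognormal_sigma (0.8)** gives a realistic but moderate rank-abundance
  spread; much larger values push rare heritable ASVs below the detection
  floor at the default depth.
* **offspring_inherited_mass (0.5)** sets the expected share of offspring
  community abundance contributed by inherited ASVs, in the range reported
  for real offspring-worker communities (~0.44 relative abundance).
* Pooled guts are simulated as a single community draw (pooling collapses
  to one multinomial); `guts_pooled` is metadata only.

What the generator does *not* emulate: contamination, sequencing-run
batch effects, chimeras, copy-number variation, phylogenetic signal in
abundances, within-colony caste differentiation, or compositional shifts
from delayed paternal sampling. Passing the recovery tests therefore shows
the pipeline is correct under its stated model, not that real datasets
reach any particular precision; in real data the classification is
additionally limited by sequencing depth and ASV resolution.

A planted-partition generator produces signed test networks: positive
edges denser within label blocks, independent negative edges on the
remaining pairs (a pair gets at most one edge).

## Numerical and design choices

* Permutation tails: "less"/"greater" name the side on which the observed
  value is held to be extreme; ties always count toward the tail.
* Two-sided p doubles the smaller tail and caps at 1.
* Genus overlap between pedigrees i, j is |G_i ∩ G_j| / mean(|G_i|,|G_j|);
  cells for pedigrees with no inherited genus are NaN (flagged), not 0.
* Retention = (# vertically transmitted)/(# founder-transmitted), NaN when
  the denominator is 0.
* Undefined quantities are surfaced (None/NaN plus flags), never coerced.
* All randomness flows through `numpy.random.default_rng(seed)`; a fixed
  seed reproduces byte-identical generator output and identical null
  draws.

## Problem sizes used in the checks

The behavioural checks run at sizes where exact oracles are feasible:
sequential-sampling enumeration for pools ≤ 6 and n_select ≤ 3 at 20 000
iterations (3 s.e. agreement), exhaustive assortativity oracle over all
graphs with ≤ 6 nodes and ≤ 8 edges (1e-12 agreement), permutation
calibration over 500 replicates of 100-iteration nulls, and planted-truth
recovery on the default generator settings with the shipped seed
(precision and recall ≥ 0.95). Reduced generator settings
(2 pedigrees, 20 genera, 20 000 reads) are used where full defaults add
nothing to the property under test.

## Known limitations

* The classifier cannot distinguish a maternally heritable ASV from a
  paternally heritable one that also rides through every maternal founder
  sample; with realistic founder dropout this is rare, and the no-dropout
  structural test documents it explicitly.
* Offspring presence is per sample, not per colony: offspring worker pools
  may span multiple small colonies, so colony-level establishment is not
  resolved.
* The stratified permutation test targets the same question as a linear
  mixed model with pedigree and genus random effects but estimates no
  variance components and assumes exchangeability within strata.
* Network inference itself is out of scope; the package consumes edge
  lists and makes no claim about how well any inference method recovers
  true ecological interactions.
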