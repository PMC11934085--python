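# Methods

## Problem setting

Environmental-DNA (eDNA) metabarcoding of water samples yields, per
primer set, a table of read counts over operational taxonomic units
(OTUs).  Read counts are compositional: each sample sums to its
sequencing depth, so only relative information is present, and naive
correlations between OTU abundances are biased negative by closure.
`ednanet` infers a signed co-occurrence network from such tables,
builds the matching consumer–resource food web from diet records, and
compares the two graph types topologically — the workflow used to ask
whether co-occurrence edges reflect trophic interactions in coastal
marine communities.

## The eDNA index

Counts are first closed to proportions per sample,
`p_ij = c_ij / Σ_i c_ij`, then each OTU row is rescaled by its maximum,

    index_ij = p_ij / max_j p_ij  ∈ [0, 1],

which makes within-OTU abundance comparable across samples under the
assumption of constant per-taxon amplification efficiency.  `0/0` is
defined as 0 so the transform is total (all-zero rows are removed by
the prevalence filter in any real analysis anyway).  When two primer
sets detect the same OTU, their indices are averaged per sample
(ensemble index); OTUs seen by one marker pass through unchanged.

Order of operations: samples are subset first (temporal or spatial
groups), the prevalence filter (default: present in ≥ 25% of the
subset's samples, presence = count > 0, no minimum-read cutoff) is
applied within the subset, and the index row-maximum is taken over the
subset's samples.  A `global` index scope is available for analyses
that want one shared scaling across subsets.

## Ensemble association and significance

Five pairwise measures are computed on index vectors: Pearson and
Spearman correlation, Bray–Curtis dissimilarity, symmetrized
(Jeffreys) Kullback–Leibler divergence, and plug-in mutual information.
Inference is two-phase:

1. **Screening.**  Per measure, the `top_k` highest and `bottom_k`
   lowest scoring pairs (default 500/500) become candidates.
   Correlations sign a candidate by the score's sign; dissimilarities
   map the bottom tail to co-presence and the top tail to exclusion;
   mutual information selects only its top tail and carries no sign.
   When the pool is smaller than `top_k + bottom_k` every pair is
   selected and the pool splits proportionally between the tails.  Ties
   at a tail boundary go to the lexicographically smaller pair.
   Candidates need support from ≥ 2 measures with unanimous sign
   (mutual information adds support but no sign; sign conflicts drop
   the pair).
2. **Pricing.**  Each surviving pair gets a permutation null per
   supporting measure: the two focal rows of the proportion-scale
   matrix are independently permuted across samples, each sample's
   compositional normalization is recomputed over the full community
   with the permuted rows in place (permuted values divided by the
   destination sample's new total), the index row-scaling constants are
   kept fixed, and the measure is rescored.  Dividing by the
   destination sample's total puts the shared-denominator dependence
   that closure induces between any two taxa into the null — a plain
   shuffle, or a re-closure on the index scale, would miss it, which is
   why the `IndexTable` retains its proportion matrix.  The same
   permutations are shared
   across measures for one pair, so the per-measure null statistics are
   dependence-aligned.  The p-value is the two-sided tail of a Gaussian
   fitted to the 100 null scores — at 100 permutations an empirical
   rank cannot resolve below 0.0099, too coarse for the subsequent FDR
   step, while the Gaussian fit interpolates the tail smoothly.
   Stability is gated by 100 bootstrap resamples of the samples: an
   edge passes only if the null mean lies outside the central 95%
   bootstrap interval of the observed score, on every supporting
   measure.

Per-measure p-values are merged with Brown's method.  The Fisher
statistic `X = −2 Σ ln p_i` has null mean `2k`; its null variance is
estimated empirically as the variance of `X` over the aligned null
replicates (each permutation yields one p-value per measure under its
own fitted Gaussian).  The merged p is the upper tail of the scaled
chi-square `c·χ²_f` with `c = Var/(2·2k)`, `f = 2(2k)²/Var`.
Independent measures (`Var = 4k`) recover Fisher's method exactly;
perfectly duplicated p-values collapse to the common value.  Merged
p-values are Benjamini–Hochberg adjusted within each subset's network,
and edges with `q ≤ 0.05` are reported.

Randomness is reproducible and order-independent: a master seed plus a
CRC-32 hash of the pair id seeds each pair's generator, so edge tables
are byte-identical across reruns and independent of iteration order.

### Defaults that matter

| parameter | default | why |
| --- | --- | --- |
| `min_prevalence` | 0.25 | removes rare OTUs whose zeros dominate scores |
| `top_k` / `bottom_k` | 500 / 500 | captures both co-presence and exclusion tails |
| `min_support` | 2 | an edge needs agreement of ≥ 2 measures |
| `n_perm` / `n_boot` | 100 / 100 | null and stability iteration counts |
| `q_threshold` | 0.05 | BH-adjusted significance cutoff |
| `mi_bins` | 4 | ≥ ~5 expected points per bin at 20–60 samples |
| `kld_pseudocount` | 1e-8 | keeps KL finite on vectors with zeros |

Mutual-information binning is equal-frequency with deterministic tie
handling: sorting is stable on sample order, and exactly equal values
always share the bin of the first member of their tied run.  A constant
vector therefore occupies a single bin and shares no information with
anything — without the tie rule, two constant vectors would receive
identical positional bins and spuriously attain maximal MI.

## Food webs and comparison

Diet records (consumer → resource, one row per documented interaction)
are restricted to the detected, filter-surviving community; all
community OTUs remain as nodes (isolated species are part of the web).
Records naming finer taxa than the OTU labels resolve through an
explicit synonym table — no fuzzy matching.  Trophic levels: algae and
fungi are level 1, invertebrates level 2, vertebrates take their
database-derived value; explicit metadata always wins.

A co-occurrence edge counts as trophic if the unordered pair appears in
the food web in either direction.  Across subsets, edge identity is the
unordered pair with sign ignored for matching (sign agreement is a
separate column); percentages are integer percents of the union,
rounded half-up.  The abundance–degree correlation uses the per-OTU
mean index over the subset's samples, not raw reads.

Topology conventions (they matter for directed graphs): average
neighbours counts distinct adjacent nodes ignoring direction, so
reciprocal consumer pairs count once; directed paths follow the
consumer → resource direction; eccentricities are taken over reachable
nodes only and the radius is the minimum positive eccentricity (a
consumer whose resources are all basal attains radius 1); the
characteristic path length averages over ordered reachable pairs; the
clustering coefficient averages local clustering on the undirected
projection over nodes with ≥ 2 neighbours.  Report display rounds
half-up to 2 decimals (3 for average neighbours); internal values keep
full precision.

## Synthetic communities

The generator reproduces the statistical structure the analysis
assumes, not sequencing mechanics.  Latent log-abundances follow a
log-linear factor model: per-OTU baseline `N(0, 1.2)`, optional shared
environmental gradients (loadings `N(0, 0.4)`), unit residual noise.  A
planted pair at strength `s` shares a unit-variance latent factor with
loadings `±3.3·s` (equal signs for co-presence, opposite for
exclusion), giving a latent log-scale correlation of ≈ ±0.85 at
`s = 0.9` — strong but noisy, the regime the engine should recover.  A
`rare_fraction` of non-planted OTUs is thinned below 25% occupancy so
the prevalence filter has real work.  Observation: per marker and
sample, reads are multinomial with shares proportional to abundance ×
per-OTU/per-marker amplification efficiency (lognormal, σ = 0.5),
restricted to the marker's OTU panel; two default panels (85 and 36 of
110 OTUs, overlapping on 11) emulate a two-marker vertebrate panel plus
a smaller eukaryote panel; sample depths are lognormal around 1e5
reads.

What it does not emulate — and hence what passing tests do not show
about field data: spatial autocorrelation of eDNA transport, age-class
mixing, sequence errors/chimeras/clustering artefacts, taxonomic
mis-assignment, or amplification efficiencies varying with community
composition.  Recovery results here bound what the method can do when
its own model holds.

## Validation design and problem sizes

* Null calibration: independent-OTU communities (no planted pairs, no
  gradients), 40 OTUs × 60 samples × 20 seeds; the false-edge rate
  (reported edges / consensus candidates) averages ≈ 0.02, bound 0.10.
  With gradients enabled, gradient-driven co-occurrences are genuine
  environmental associations and cannot enter a false-positive count,
  which is why the null uses zero gradients.
* Per-measure null p-values on 200 independent pairs are near-uniform
  (Kolmogorov–Smirnov distance ≤ 0.15 for all five measures).
* Recovery: 110 OTUs × 60 samples, 20 planted co-presences and 10
  exclusions at strength 0.9, pooled over 3 seeds; recall of eligible
  (filter-surviving) co-presence pairs ≥ 0.8 and sign accuracy ≥ 0.9
  (exclusions ≥ 0.7) are the acceptance bounds; observed values are
  ≈ 0.98 / 1.0 / 1.0.
* Oracles: every measure, BH, Brown's independence limit and all path
  statistics are tested against independent brute-force references
  (scipy, step-up recursion, Fisher closed form, Floyd–Warshall).

## Known limitations

* No pair-permutation null can remove the positive coupling a
  hyper-dominant third taxon induces among everything else: when one
  OTU takes a large, fluctuating share of the reads (above roughly 80%
  in some samples), all other proportions co-vary through the shared
  denominator, and that dependence is real in the observed data.  On
  such communities the raw per-measure p-values skew small (observed
  Kolmogorov–Smirnov distances up to ≈ 0.29 for Spearman on the most
  dominance-heavy synthetic seeds) even though the latent abundances
  are independent; the downstream consensus, stability and FDR layers
  still keep the reported false-edge rate near 2%.  Conditional
  approaches (SparCC- or SPIEC-EASI-style) target this regime and are
  out of scope here.
* The Gaussian-tail p-value assumes an approximately normal permutation
  null; mutual information's null is mildly right-skewed, the largest
  (still passing) KS distance among the measures.
* Tail screening before testing means very weak true associations
  outside both tails are never priced; this bounds compute but caps
  recall at low strengths.
* Brown's empirical variance uses the same 100 permutations as the
  p-values; at much smaller `n_perm` the variance estimate becomes
  noisy.
* The meta-web is only as complete as its diet records; absent records
  deflate trophic-match fractions (a property of the data, not the
  matcher).
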