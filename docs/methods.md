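# Methods

## Scope and data model

`bogwater` operates on an integer OTU count table (samples × OTUs),
per-sample metadata (lake, layer, date; mixing regime is a fixed function
of lake), representative sequences, two reference databases, and a rooted
phylogeny with branch lengths whose leaves are OTU identifiers. Sample
identifiers follow a compact grammar — two-letter lake code, layer letter
(E/H/U for epilimnion/hypolimnion/unsplit water column), `DDMMMYY` date,
optional `.R<digit>` replicate suffix — chosen because the field sheets of
such surveys are commonly encoded this way; an explicit metadata file can
always override parsing. Biological replicates are kept as distinct
samples and never averaged. On disk the table stores OTUs as rows (the
long axis); in memory it is samples × OTUs.

## Quality control

Screening removes sequences with a single-base run longer than 8, length
outside 148–152 bp (the V4 fragment with slack), or any non-ACGT
character. The homopolymer and length thresholds are this package's
declared defaults for V4 data — screening tools of the era used similar
values but the exact settings are configurable and should be adapted to
the primer set.

The abundance filter removes OTUs with fewer than 25 reads summed over
the *entire* data set (not per sample); it is idempotent. The blacklist
filter drops OTUs whose assignment carries a blacklisted label at any
rank (typically `Chloroplast`); fully unclassified OTUs are retained.

Rarefaction subsamples each sample to a fixed depth (default 2,500 reads)
*without replacement* via the multivariate hypergeometric distribution —
this models drawing physical reads, guarantees no count exceeds its
input, and makes retained sample totals exactly equal to the depth.
Samples with fewer reads than the depth are dropped and listed in the
`FilterReport`. The seed is mandatory and recorded.

## Identity routing and classification

Routing computes, for each query, the best percent identity against the
curated freshwater references under deterministic semi-global alignment:
match +1, mismatch −1, linear gap −2, end gaps free on the reference
(the ~150 bp query may sit anywhere inside a full-length reference) but
penalized on the query. Percent identity is identical columns divided by
alignment columns along the traceback. A best hit *strictly greater*
than 98% routes the query to the freshwater database; a hit of exactly
98.0 goes to the comprehensive database. Raising the cutoff can only
move queries toward the comprehensive database (monotonicity).

Classification is the k-mer naive-Bayes bootstrap method. With k = 8,
the prior of word *w* over *N* training sequences containing it *n(w)*
times (presence per sequence) is `(n(w)+0.5)/(N+1)`; the conditional for
taxon *t* with *M_t* sequences, *m_t(w)* containing *w*, is
`(m_t(w)+prior(w))/(M_t+1)`. A query is scored by the summed log
conditionals over its distinct k-mers; ties break to the
lexicographically first taxon path for reproducibility. Confidence at
each rank is the percentage of 100 bootstrap replicates — each drawing
⌊W/8⌋ of the W query k-mers with replacement — agreeing with the
full-query label at that rank. Ranks below the 70% cutoff are set to
`unclassified`, and unclassification propagates to all finer ranks.
Unclassified ranks are reported with confidence 100 by convention: the
failed bootstrap support is not a claim the assignment makes, and this
keeps every reported confidence at or above the cutoff in force.

Rank vocabularies: the freshwater database uses
phylum → lineage → clade → tribe (lineage ≈ family, clade ≈ genus,
tribe ≈ species); the comprehensive database kingdom → … → genus.

## Diversity

Observed richness counts OTUs with nonzero counts; rarefaction curves
average richness of hypergeometric subsamples over replicates.

Beta diversity: Bray-Curtis on counts (`Σ|x−y| / Σ(x+y)`), Jaccard on
presence/absence, and three UniFrac variants computed from the tree via
a branch-incidence matrix (per-sample proportion of reads descending
through each branch). Unweighted UniFrac is unique branch length over
branch length observed in the union; weighted raw is
`Σ_i b_i |p_i^A − p_i^B|`; weighted normalized divides the raw sum by
`Σ_j d_j (p_j^A + p_j^B)` over leaves at root distance `d_j`, bounding
it in [0, 1]. The *normalized* variant is the package default where one
must be picked, because its boundedness makes cross-study comparison
sane; the raw variant is available by flag. All UniFrac variants require
every OTU with nonzero counts to be a tree leaf and raise otherwise
(implementations that silently prune give irreproducible distances).

PCoA is classical scaling: eigendecomposition of the Gower-centered
`−D²/2`. Negative eigenvalues (non-Euclidean input) are discarded with
no Cailliez/Lingoes correction, and proportion explained is relative to
the positive-eigenvalue total — the convention most ordination users
expect; the retained eigenvalue tolerance is `max(1e−10, λ_max·1e−12)`.

PERMANOVA partitions `SS_total = (1/n)Σ_{i<j} d²` into within-group
(`Σ_g (1/n_g)Σ_{i<j∈g} d²`) and between-group components;
`F = (SS_B/(a−1))/(SS_W/(n−a))`, `r² = SS_B/SS_total`. Significance uses
unrestricted label permutations (no strata) with the positively biased
estimator `p = (count+1)/(n_perm+1)` and a mandatory seed; exhaustive
enumeration is available for small n. `SS_W = 0` yields an infinite F
with a warning rather than an error.

Pairwise group comparisons use exact two-sided rank tests: the
Mann-Whitney rank-sum for independent groups (exact enumeration when
samples are untied and ≤ 30 per group, normal approximation with
midranks otherwise) and the Wilcoxon signed-rank for paired groups.
The unpaired rank-sum is the default because group sizes in lake-level
comparisons are unequal, making a signed-rank test undefined; paired
mode is provided for genuinely aligned series. Bonferroni adjustment
multiplies by the number of pairs and caps at 1.

Per-year z-scores use the sample SD; a constant year maps to zeros by
convention and a single-observation year is an error.

## Core, indicators, lifestyles

Core taxa are OTUs present in at least the occupancy fraction of samples
(inclusive threshold, default 0.90), regardless of abundance.

Indicator analysis builds an augmented abundance matrix of raw OTUs plus
taxa aggregated at every rank, drops rows with data-set totals under 500
reads, and computes for each row a *group-equalized point-biserial
correlation*: sample s gets weight `(N/G)/n_{g(s)}` so each of the G
groups contributes equal mass, and the statistic is the weighted Pearson
correlation between abundance and 0/1 membership. Tested patterns are
each single group and its complement (sufficient for three mixing
regimes; arbitrary subsets would explode the permutation cost). The
permutation p-value compares the observed best-pattern statistic against
the best-pattern statistic of each relabeling, so the maximization over
patterns does not inflate significance. Constant rows report statistic 0
with p = 1. Raw p-values are primary; Benjamini-Hochberg adjusted values
are reported alongside because many taxa × ranks are tested.

Lifestyle profiles summarize each lineage within a sample group by
persistence (fraction of samples containing it), mean relative abundance
over the samples where present, and coefficient of variation of relative
abundance. The CV denominator includes absent samples (zeros) by
default — occupancy differences are part of a taxon's variability — with
a present-only flag since the alternative convention also appears in the
literature.

## The synthetic generator

The generator emulates the survey's statistical structure, not its
limnology. Default design: the eight study lakes (three polymictic,
three dimictic, two meromictic, in the published mapping), two layers,
weekly sampling for ten weeks each summer over four years, 5,000 reads
per sample. Regime-structured richness comes from OTU pool sizes
(defaults 500 / 800 / 1,200 for polymictic / dimictic / meromictic), a
shared background pool, and extra taxa unique to meromictic hypolimnia.
Background OTUs split disjointly between layers; the core set and
indicators occur in both.

Each OTU belongs to a lineage, and lineages are archetype-pure:

| archetype | log-mean | log-sd | occupancy |
|---|---|---|---|
| core-generalist | 3.0 | 0.3 | 1.00 |
| conditionally-rare | 0.5 | 1.2 | 0.35 |
| bloomer-like | 3.5 | 1.0 | 0.12 |

These lognormal base abundances and per-sample presence probabilities
produce the persistence / abundance-when-present / CV triangle that
lifestyle profiling should recover: generalists persistent and stable,
conditionally rare taxa sparse and variable, bloomers abundant but
rarely present. Planted regime indicators are abundant, high-occupancy
taxa (log-mean 2.5, occupancy 0.9) with *zero* abundance outside their
regime — modeled on the fact that useful indicator groups in freshwater
surveys are abundant, well-sampled clades; very rare indicators would
fall under the 500-read analysis threshold by design, not by failure.

A sample's expected composition is the product of base weight, lake/layer
membership, a per-(OTU, lake, year) lognormal multiplier with SD 0.6
(the interannual shift), and a per-sample Bernoulli presence draw; counts
are multinomial at the library size, so compositional sampling noise is
realistic. On a mixing-event date the two layers' expectations are
averaged (the column homogenizes) and only the top fraction of taxa by
expected abundance survives (default 0.2), crashing observed richness;
default events are a fall event in Trout Bog 2007 and a mid-summer event
in North Sparkling Bog 2008 when those years are simulated.

What the generator does *not* emulate: temperature/oxygen dynamics,
seasonal succession within a summer (time-decay has no repeating annual
signal by construction), sequencing error at the read level, chimeras,
taxon-taxon interactions, and recovery trajectories after mixing. Tests
passing on synthetic data therefore demonstrate that the *methods*
recover planted structure of realistic shape and size — not that any
particular biological conclusion about real lakes is reproduced.

## Problem sizes and determinism

Tests and the acceptance script use a scaled design (`small_config`:
two summers of six weekly samples, pools 120/190/280, library 3,000 →
192 samples × ~500 OTUs) so the whole suite runs in minutes on one core;
the default configuration mirrors the full survey scale. Every stochastic
step — simulation, rarefaction, permutation tests, bootstrap
classification — takes an explicit seed, and all sub-seeds derive from
it. PERMANOVA null calibration uses 199 permutations per replicate,
whose p-value grid contains the 0.05 level exactly.

## Known limitations

* The aligner is a full dynamic program; for production-scale routing of
  10⁴ queries against large databases a seeded heuristic aligner would be
  the practical choice. It is exact and deterministic, which the 98%
  routing contract needs.
* Exact rank tests fall back to the normal approximation in the presence
  of ties or large samples; p-values near thresholds should be read
  accordingly.
* The indicator statistic is the group-equalized correlation family as
  specified here; numeric parity with any particular legacy
  implementation's tie-breaking or pattern enumeration is not claimed.
* PERMANOVA supports a single factor, matching the analyses this
  pipeline reports; multi-factor designs need a different tool.
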