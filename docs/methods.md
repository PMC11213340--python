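# Methods

This note documents the models, conventions and numerical choices behind
`ltspevo`, and what the synthetic data generator does and does not emulate.

## Inputs and conventions

The pipeline consumes a per-clone mutation table (TSV; one row per mutation
call per clone, with clone id, population, sampling day, 1-based position,
ref/alt alleles and a mutation class), an optional clone manifest (so clones
with zero called mutations still count in frequency denominators), a genome
annotation (GenBank, or GFF3 + FASTA), and optionally a two-column table of
functionally associated locus pairs. Coordinates are 1-based inclusive
throughout. Duplicated (clone, position, alt) rows are collapsed with a
logged warning. A clone is flagged as a *mutator* when it carries a mutation
in any gene of a configurable list (default *mutS*, *mutL*, *mutH*, *dnaQ*);
mutator clones are excluded from selection and contingency statistics.

## Synonymous/non-synonymous sites and dN/dS

For every coding position, each of the three possible substitutions
contributes 1/3 of a site to the synonymous or non-synonymous total under a
uniform substitution model (no transition/transversion weighting); weights
are summed per gene and genome-wide. Terminal stop codons are excluded from
the totals; substitutions creating a stop count as non-synonymous; genes
with internal stops or lengths not divisible by three are skipped with a
warning. This fixes the conservation invariant
`n_sites + s_sites = coding positions (stop excluded)` exactly. dN/dS is
`(n_obs/n_sites)/(s_obs/s_sites)` over unique mutations of non-mutator
clones; `s_obs = 0` yields an infinity flag and `n_obs = s_obs = 0` an
undefined flag. Neutrality is tested with a 1-df χ² goodness-of-fit of
(n_obs, s_obs) against the site split. Only SNPs enter dN/dS; indels and
structural changes are excluded from both classes. Time-resolved
non-synonymous fractions date each mutation to the earliest sampling day at
which any clone carries it.

## Lineage reconstruction

Mutation frequencies are computed per population-day over all sequenced
clones (mutators included); only mutations reaching ≥ 30% at some day enter
the phylogeny. Each clone's filtered mutation set is mapped to a string of
symbols in canonical (position, alt allele) order, and distances between
clones are unit-cost Levenshtein edit distances on those strings (with
canonical order, the distance equals the symmetric-difference size whenever
one set contains the other). Each clone's parent is the distance-minimizing
clone among those strictly before it in (day, clone id) order — this
ordering keeps edges day-monotone and the graph a forest — with ties broken
by earlier day, then larger shared-mutation count, then lexicographic id.
The population root (the ancestral, mutation-free genotype at day 0) always
competes and therefore wins distance ties against sampled clones via the
earlier-day rule.

Walking down from the root, the first edge introducing a qualifying (≥ 30%)
mutation opens a lineage comprising the entire subtree below it; deeper
qualifying acquisitions do not spawn sub-lineages (otherwise every common
adaptive mutation would found one). When several qualifying mutations are
introduced on the same edge, the one with the highest peak frequency names
the lineage (ties: smallest position/allele) and the rest are co-founders.
Subtrees founded by the same mutation are merged into one lineage: an
apparent re-acquisition of an established founder is an artifact of
attaching a distant clone to the root, not an independent origin. A lineage
must span at least two distinct sampling days; all remaining clones form one
pseudo-lineage per population, so every clone belongs to exactly one
container. Muller tables report per-day lineage fractions of sampled clones
(rows sum to 1 including the pseudo-lineage).

## Convergence

Mutations inside a CDS belong to that gene's locus; intergenic mutations
belong to the promoter locus of the gene whose upstream intergenic region
contains them (strand-aware; a plus-strand gene claims the gap to its left,
a minus-strand gene the gap to its right; between divergent genes the nearer
gene wins, exact ties go to the lexicographically smaller gene id). A gene
and its promoter are distinct loci. Convergence counts, per locus, the
number of independent units — populations, or lineages + pseudo-lineages —
containing at least one mutated non-mutator clone; mutations shared by
ancestry within a unit count once. The "fraction of mutations in convergent
loci" counts distinct (population, mutation) events among non-mutator
clones, deduplicating inherited copies within a population.

## Contingency screen

Candidate pairs are unordered pairs of convergently mutated loci
(≥ 2 lineages or populations; *rpoB*/*rpoC*-style founding loci excluded)
that are co-mutated within single non-mutator clones in ≥ 2 units. For each
pair a 2×2 table is built over the units (mutator lineages dropped entirely,
mutator clones dropped from remaining units): a = units containing a clone
mutated in both loci, b = in the first only, c = in the second only,
d = units containing a clone mutated in neither; one unit may contribute to
several cells. Coefficients: Q = (ad−bc)/(ad+bc),
Y = (√ad−√bc)/(√ad+√bc), φ = (ad−bc)/√((a+b)(c+d)(a+c)(b+d)); zero
denominators yield flagged undefined values rather than exceptions.

Significance is a one-sided large-sample z-test for positive association:
z = coefficient/SE with SE_Q = ((1−Q²)/2)·√(1/a+1/b+1/c+1/d) and
SE_Y = ((1−Y²)/4)·√(…); for φ the null standard error 1/√n is used
(z = φ√n, the χ² = nφ² test), n being the cell total. Whenever any cell is
zero, 0.5 is added to every cell for the SE computation only — reported
coefficients stay on raw counts (so bc = 0 still gives Q = Y = 1).
Benjamini–Hochberg FDR control is applied per coefficient across all tested
pairs at α = 0.05. The consensus reliable set consists of pairs
φ-FDR-significant and above the Q (0.8) and Y (0.5) cutoffs; when a
functional-association table is supplied, the cutoffs are re-derived by
scanning each coefficient's distinct significant values and choosing the
cutoff maximizing the fraction of above-cutoff pairs with a known
functional link (ties → lowest cutoff). The test statistic is isolated in
one private function so the distributional choice can be swapped.

Functional enrichment of a pair set is assessed by randomization: each of
1000 replicates draws the same number of distinct pairs from the candidate
loci (pairs without replacement within a replicate; loci may repeat), and
p = (1 + #{replicate fraction ≥ observed}) / (1001).

Directionality: for each unit containing a double-mutant clone, the clone's
ancestor chain is walked towards the root; the first ancestor carrying
exactly one of the two loci fixes which was mutated first in that unit. If
no chain in any informative unit ever separates the two, the pair is
*always_together*; if all separating units agree the pair is directed; any
disagreement makes it *ambiguous*.

The association of loci with specific lineage-defining (RNA-polymerase-like)
founding mutations uses the same coefficients on unit-level 2×2 tables (a
unit either was or was not founded by the mutation), with mutator lineages
and clones retained, and a configurable gene-group merge (default:
mutS+mutL+mutH as one "mismatch_repair" entity) applied before counting.

## The synthetic generator

`simulate_ltsp` emulates the sampling design of a six-year LTSP experiment:
5 populations sampled at days 11, 22, 32, 42, 64, 127, 374, 730, 1095,
1460, 1816 and 2191 with 10 sequenced clones each. Per population, three
lineages are founded at day 0 by fixed nonsynonymous variants in two
designated founding genes (the same variants recur across populations,
mirroring convergent founding); founding frequencies default to
0.40/0.31/0.26, the 3% remainder being clones that never join a lineage.
Lineage frequencies follow a renormalized mean-reverting (log-OU) geometric
walk (σ = 0.25, reversion 0.5 per sampling step): established LTSP lineages
coexist for years, so weights fluctuate around the founding composition
rather than random-walking away — which also makes the ≥ 30% detection of
every founder near-certain at these sizes.

Each lineage carries one heritable trunk: a Poisson neutral background
(1.5×10⁻³ per genome per day; 10% of events emitted as 1-bp deletions),
gains at a 24-locus shared adaptive pool (3×10⁻⁴ per locus per day), and
eight planted contingent pairs among the pool loci. A pair's first locus
arrives at 6×10⁻⁴ per day; the second locus's full propensity is 10⁻² per
day on backgrounds already carrying the first (contingent mutations follow
quickly under strong selection) and is multiplied by (1 − strength),
strength 0.995, otherwise — rate suppression, not hard prohibition, so
mixed patterns occur. A sampled clone inherits the trunk up to a divergence
time (sampling day minus an exponential lag, mean 150 days) plus private
neutral mutations accrued since, making within-lineage diversity and
ancestor states observable. Mutator lineages (the first founding variant in
populations 2–4) carry a founding mutation in a designated mismatch-repair
stand-in gene and a 20-fold neutral rate. Clones outside lineages are
independent single-clone genotypes replaying the same gain process —
genotypes that flare and vanish, like the real pseudo-lineage clones. The
neutral background avoids the founding, pool and mutator genes so that
locus-level ground truth (e.g. "second locus never without the first" at
strength 1) is exact by construction. Adaptive and founding mutations are
forced nonsynonymous; positions are drawn independently per lineage, so
convergence is at locus level. The toy genome (default 100 genes × 120
codons, alternating strands, ≥ 20-bp spacers) is generated from the same
seed; everything is reproducible from one integer.

What the generator does **not** emulate: death-phase demography and
population sizes, within-population spatial structure, sequencing error or
coverage noise, realistic codon usage, operon structure, indel/structural
mutation spectra beyond token 1-bp deletions, and epistasis beyond planted
pairwise contingencies. Passing recovery tests therefore shows the
*inference machinery* is correct under the stated generative assumptions,
not that the method is robust to every property of real resequencing data.

## Problem sizes and numerical choices

Default test and acceptance runs use 600 clones (5 populations × 12 days ×
10 clones) per simulated experiment and five experiments per evaluation,
each completing in a few seconds. Final-day non-mutator clones carry ~20
mutations, the order observed after six years in the real system. Muller
row sums are asserted to 1e-9; the Yule identity Q = 2Y/(1+Y²) to 1e-9;
empirical randomization p-values use +1 smoothing. Tie-breaks (parent
choice, founder naming, promoter assignment, threshold scanning) are all
deterministic and documented above, so repeated runs are byte-identical
under a fixed seed.

## Known limitations

Direct and indirect contingencies are not distinguished (A→B→C chains can
produce an apparent A–C association). Shared temporal ordering of
adaptations can mimic contingency; the screen's false positives on
synthetic data are of exactly this kind, and the consensus thresholds (all
three coefficients) are what keeps them rare. The large-sample z-test is an
approximation at these unit counts (~17–20); the isolated test function is
the place to substitute an exact test. Pairs involving loci mutated only on
mutator backgrounds are invisible to the screen because mutator clones are
excluded.
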