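# Methods

This note documents the models and procedures implemented in `mdmcensus`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions in corner cases.

## Genome subgroup classification

Each catalog genome is assigned to exactly one provenance/quality subgroup
by the first matching rule, in order:

1. **ISOLATION** — `ncbi_genome_category` is `none` or empty
   (case-insensitive, trimmed): the genome came from a pure culture.
2. **COMPLETE** — environmental genome with `ncbi_assembly_level` containing
   `complete genome` (case-insensitive substring, since database dialects
   vary in capitalization).
3. **HQ / MQ / LQ** — MIMAG high/medium/low-quality flag set
   (`t`/`true`/`1` are truthy, anything else false, matching the `t`/`f`
   convention of GTDB dumps).
4. **UNASSIGNED** — no rule fired.

The precedence forces the partition to be disjoint and exhaustive, so
subgroup percentages sum to 100% per domain. Genomes lacking any SSU
sequence cannot be hit by a tag and are excluded from the index; their count
is logged. The FASTA/metadata join tries accessions verbatim and with the
`RS_`/`GB_` prefixes stripped on either side before declaring a mismatch.

## Tag-to-genome matching

"Has a sequenced genome at identity tier *t*" means: some catalog SSU
contains, on either strand, a gapless window of the full query length whose
Hamming distance to the query is within

    budget(L, t) = floor(L * (1 - t/100)),

i.e. 0/1/2 mismatches for 90-bp tags at 100/98.7/97%. The window covers the
whole query, so coverage is 100% by construction. Consequences of the
gapless design:

- At 100%/100% the search is mathematically equivalent to a perfect BLASTn
  hit; no approximation is involved.
- At the relaxed tiers, gapped alignments are ignored. A short tag with an
  indel cannot reach 100% coverage at these identities without inflating
  the alignment length, so the divergence from a gapped aligner is bounded
  by the (small) gapped-hit fraction. An E-value threshold has no meaning
  for exact substring search and is intentionally not reimplemented.
- `N` in a query disqualifies the exact tier; `N` on either side counts as
  a mismatch at relaxed tiers. This is the conservative reading of "100%
  identity".

The search runs on a concatenated reference string (exact tier: C-level
substring scans) with a pigeonhole seed filter for the Hamming tiers (split
the query into budget+1 chunks; any true hit must contain one exact chunk).
Queries containing `N` fall back to a vectorized full window scan. Tier
results are derived from one search at the loosest budget, making tier
nesting structural. Hit lists are sorted by accession; everything is
deterministic. When several genomes hit one tag, the reported category is
the best by subgroup precedence, and all hits are retained in the output so
any other convention can be recomputed.

## Census statistics

Per sample and tier, over the ASVs with nonzero count:
P_number = matched/present, P_abundance = Σ relative abundance of matched.
Relative abundances are computed on unrarefied counts; rarefaction
(multivariate hypergeometric, i.e. subsampling without replacement, explicit
seed, default depth 20,000 reads) feeds only the alpha-diversity indices,
and samples below depth are flagged `EXCLUDED_LOW_DEPTH` rather than
erroring. Shannon entropy uses the natural log by default (a base option is
exposed; log2 is the other common convention); Chao1 is the bias-corrected
form S_obs + F1(F1−1)/(2(F2+1)). Environment summaries report median and
quartiles with linear interpolation (type 7), the common default, plus a
pooled median over all samples regardless of environment. Pearson
correlations of the P statistics against each alpha index return NaN on
zero-variance inputs instead of raising.

Abundance classes use strict inequalities: abundant ⇔ p > 0.01, rare ⇔
p < 0.001; boundary values fall in the intermediate class. Within the
abundant class the abundance is split into matched/unmatched parts.

The ablation experiment removes a genome subset from the index, re-matches
and re-censuses. Removal can only lower P statistics. The report carries
per-sample paired deltas (and their median), the before/after environment
summaries, and the list of ASVs above 0.5% relative abundance somewhere
whose match status flipped.

## OTU clustering and the prevalence filter

vsearch-style greedy centroid clustering, re-specified precisely so results
are reproducible without the external tool: ASVs sorted by decreasing total
abundance (ties: sequence, then id, lexicographic), each ASV joins the
first centroid within the Hamming budget at 97% identity (2 mismatches for
90-mers) else founds a new OTU. Equal sequence lengths are required (one
trimmed region); mixed lengths are a fatal input error. This ignores
vsearch's internal heuristics and is documented as an approximation of
them. OTU counts are the sum of member ASV counts; the OTU taxonomy label
is the centroid's, consumed as given.

Core ("prevalence") OTUs: present in > 40% of samples AND mean relative
abundance > 0.1%, both strict; presets tight = 50% and loose = 30%. The
abundance criterion is ambiguous between mean-across-samples and
within-some-sample; the mean is the default and the per-sample-anywhere
variant is exposed as an option. Presence means count > 0, unrarefied.

## Co-occurrence network and node roles

The network estimates conditional dependence between OTUs from compositional
counts in the SPIEC-EASI "mb" style, re-specified with fixed defaults:

1. restrict to OTUs present in > 30% of samples (sparsity control);
2. add pseudocount 1 and apply the centered log-ratio transform per sample;
3. per-node lasso neighborhood selection over a log-spaced 20-value penalty
   path (from the empirical λ_max down to λ_max/100);
4. stability selection over 20 random subsamples of 80% of the samples;
   per penalty, edge instability is the mean of 2θ(1−θ) over edge
   appearance frequencies θ; the instability curve is monotonized from the
   sparse end and the densest penalty whose monotonized instability stays
   ≤ 0.05 is selected (StARS);
5. refit on all samples at the selected penalty, symmetrizing edges by the
   OR rule. Edge weights annotate the empirical CLR correlation.

All five numbers (20 penalties, 20 subsamples, 80% ratio, 0.05 instability,
path floor 0.01·λ_max) are package choices and configurable. Inference is
deterministic given the seed; fewer than 10 samples is fatal (stability
selection is meaningless); a single subsample with a single penalty
degenerates to one lasso fit per node. A warning is issued when nodes
outnumber samples.

Modules are found by greedy modularity maximization per connected component
(singleton components are their own modules); module ids are ordered by
each module's lowest node id, so the assignment is deterministic. Node
roles use the Zi–Pi plane: Zi is the within-module degree z-score (0 when
the module's degree spread is 0), Pi = 1 − Σ_m (k_im/k_i)² (0 for isolated
nodes). Thresholds: module hubs Zi > 2.5 & Pi < 0.62, connectors Zi < 2.5 &
Pi > 0.62, network hubs both >, peripherals both <. The inequalities are
strict; nodes exactly on a boundary fall on the peripheral/connector side.

## Wanted-list assembly

The list is the union of the prevalence cores and the network hubs (module
hubs + network hubs), deduplicated, each entry flagged by the criteria it
met. Knowledge status per OTU: ISOLATE if any member ASV hits an isolation
genome at the active tier, else GENOME_ONLY if any hit at all, else DARK.
Under-represented phyla: among the top 10 phyla by summed mean abundance,
those with matched-abundance fraction < 0.5 are flagged (both parameters
exposed — in practice such phyla are picked by inspection, so the defaults
only formalize that step). OTUs without a taxonomy label fall under
"Unclassified" and are never flagged. A cross-table lookup reports, for
each listed OTU, the highest relative abundance of its exact centroid
sequence (either strand) in an external survey table, with the sample and
environment attaining it — useful for finding ecosystems where a wanted
organism is easier to enrich. The functional-guild criterion is consumed as
an optional user-supplied OTU list, not computed.

## Synthetic worlds

The generator exists because a real census of this kind consumes thousands
of public amplicon runs and a multi-gigabyte genome catalog. It emulates
the features the method is sensitive to:

- **Rank abundance**: per-sample lognormal abundances (σ = 1.3 by default)
  with the bottom 80% of taxa squeezed under 0.1% relative abundance. With
  400 taxa this yields ~5% of taxa above 1% abundance carrying ~40–55% of
  total abundance and a long rare tail — the hyper-dominance pattern of
  activated-sludge-like communities.
- **Planted matches**: a chosen fraction *f* of total abundance comes from
  taxa whose 90-bp tag is copied from a catalog SSU, optionally mutated by
  a planted mismatch spectrum; remaining taxa get novel random tags.
  Subset selection is randomized but constrained to hit *f* within a
  tolerance (default 0.02; fatal if unattainable — e.g. too few taxa).
- **Structure knobs**: planted core taxa (high presence probability and a
  weight floor) against low-prevalence backgrounds; a planted dark phylum
  (its taxa unsequenced, all other unsequenced taxa left unclassified so
  the flag is unambiguous); dedicated hybrid-only accessions carrying an
  abundance share *h* for ablation experiments; correlated latent factors
  injected into chosen taxon pairs before multinomial resampling for
  network recovery.
- Catalog SSUs are uniform i.i.d. DNA (1,500 nt); adequate because matching
  is exact/Hamming rather than model-based, and accidental 90-mer
  collisions have negligible probability.

What it does **not** emulate: 16S molecular evolution (real near-matches are
phylogenetically structured, not uniform substitutions), chimeras,
sequencing error, copy-number variation, compositional batch effects across
studies, or taxonomy assignment error. Passing recovery tests therefore
demonstrates the correctness of the bookkeeping and the estimators under
the stated sampling models, not robustness to those real-data artifacts.

All randomness flows through one seeded generator per world; emitted files
embed the seed in a header comment and regenerating with the same seed is
byte-identical.

## Problem sizes and tolerances in tests and the acceptance script

The shipped checks use catalogs of 100–200 genomes, communities of 250–400
taxa over 25–60 samples (50 samples for fraction recovery, 200 samples for
network recovery over few taxa), chosen so each planted quantity is
estimable with a comfortable margin: planted fraction recovery asserts the
median P_abundance within ±0.03 of *f* ∈ {0.25, 0.5, 0.75}; the planted
core set must be recovered exactly; the planted dark phylum must be the
unique flag; ≥80% of planted dependent pairs must appear as edges pooled
over ten seeds; and the hybrid-ablation delta must match the planted share
within ±0.03. Structural properties (oracle agreement of the matcher,
tier nesting/monotonicity, ablation monotonicity, Zi/Pi closed forms vs
exhaustive edge counting, preset nesting, rarefaction conservation) are
asserted exactly.

## Known limitations

- Gapless matching under-counts relaxed-tier hits relative to a gapped
  aligner by the gapped-hit fraction (exact at the 100% tier).
- Greedy centroid clustering is order-dependent by design; the order is
  fixed (abundance, then lexicographic) so results are reproducible, but
  they are not identical to vsearch's.
- The neighborhood-selection network is a conditional-independence sparsity
  pattern, not effect-size estimates; edge weights are annotations only.
- Headline proportions from real surveys depend on the full reference
  catalog and thousands of samples; the package reproduces the method, and
  its shipped numbers are synthetic-world recoveries, not survey values.
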