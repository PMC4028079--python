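# Methods

## The convergence model

The package treats a complex-disease gene hunt as a rank-aggregation
problem over three independent genome-wide evidence types. Each modality is
reduced to a clean, scored, one-row-per-gene table; genes are ranked within
the *full* table (rank 1 = best: highest linkage score, lowest association
weighted p, lowest expression adjusted p); and only genes present in all
three tables are retained. Each convergent gene's cumulative rank score is
the unweighted sum of its three full-table ranks,

    S_R = Rank_GWL + Rank_GWA + Rank_GWE,

and final priority is ascending in S_R. The model's assumptions are worth
stating plainly:

- **Unweighted sum.** No modality is considered more reliable than another.
  No p-value combination (Fisher, Stouffer) is offered: the method operates
  on ranks precisely so that heterogeneous score scales (linkage scores,
  SNP weighted p, expression adjusted p) never need to be reconciled.
- **Full-table ranks.** Ranks are assigned before intersection, so a gene's
  S_R reflects its standing among *all* survivors of its modality's
  filters, not among the (much smaller) convergent set. Re-ranking within
  the intersection would compress the score range and discard information.
- **Ties.** Ordinal ranks must be a permutation of 1..n for the sum to be
  well defined, so score ties break by ascending lexicographic symbol, and
  equal-S_R ties in the final ranking break the same way. This makes every
  ranking deterministic and reproducible; it introduces no bias that a
  symmetric tie-break would avoid, because ties are resolved identically in
  every run.

## Modality prefilters

- **Gene types.** Only active protein-coding genes participate. Pseudogenes,
  non-coding RNA classes (ncRNA, antisense, microRNA), open reading frames,
  hypothetical/uncharacterized entries, withdrawn records and genes on
  chromosome-X bands (Xp*/Xq*) are removed, with a per-rule removal log.
  A gene is counted against the first rule that removes it.
- **Linkage.** A region is kept when LOD ≥ 2.0 *or* region p < 0.05 (the
  LOD bound is inclusive; the p bound strict). Gene/region overlap uses
  0-based half-open intervals with any-overlap (≥ 1 bp) semantics — the
  standard BED convention; abutting intervals do not overlap.
- **Association.** SNPs with weighted p ≥ 10⁻³ and SNPs without a mapped
  gene symbol are dropped; the gene score is the minimum weighted p over
  its surviving SNPs. SNP→gene mapping is consumed as an input column —
  the package never maps SNPs itself.
- **Expression.** Within one brain region, multiple probe sets per gene are
  collapsed: direction-concordant probes are represented by the
  highest-variance probe (variance ties break by probe id); genes with
  probes in both directions are removed entirely. Fold change exactly 1
  carries no direction, so a gene mixing FC = 1 with directional probes is
  treated as discordant (a conservative reading of "same direction"), while
  all-FC-1 genes are trivially concordant. Survivors need adjusted p < 0.05
  and FC ≥ 2.0 (up) or ≤ 0.5 (down), both FC bounds inclusive. Regions are
  then merged by union, each gene scored by its minimum adjusted p across
  the regions where it survived (the per-region adjusted p values are kept,
  not recomputed), with the contributing region set recorded.
- **Region-specific candidates** are the per-region triple intersections
  with the full linkage and association repertoires, computed independently
  per region before any cross-region deduplication.

## Random walk with restart

Candidate prioritization over a network uses p ← (1−r)·W·p + r·p₀ with W
the column-normalized unweighted adjacency and p₀ uniform over the seeds
present in the network. Defaults: restart probability r = 0.75 (the value
classically used for disease-gene prioritization walks), L1 tolerance 10⁻⁶,
10,000-iteration cap. Evidence counts are deliberately not used as edge
weights. Mass reaching a degree-zero node is reinjected through the restart
vector so probability is conserved; disconnected non-seed components score
exactly zero. Seeds are an explicit input — the package takes no position
on whether they should be known disease genes or all interval genes.

## Network construction and MCL

The interaction network is built from an evidence-counted edge table around
a seed set: seed-incident edges with ≥ 2 experimental validations form the
primary network; any seed left without such a partner contributes its
single-validation edges as a fallback; the union is deduplicated (keeping
the maximum evidence count per unordered pair), self loops dropped,
isolated nodes removed, and each edge tagged with the rule that admitted
it. Construction is invariant to edge-row order.

Each node gets one subcellular layer out of eight compartments (plasma
membrane, extracellular, ER, golgi, lysosome, mitochondria, cytoplasm,
nucleus) or "unknown". Multi-compartment proteins resolve by a fixed,
configurable priority (plasma membrane first, nucleus last) so layering is
deterministic; the order roughly walks the secretory pathway outside-in.

MCL is implemented from first principles on a dense matrix: unit self loops,
column normalization, then alternating expansion (matrix squaring) and
inflation (entrywise power, column renormalization) with entries below the
pruning threshold zeroed, until the maximum absolute entry change drops
below 10⁻⁸. Clusters are read off the limit matrix's attractor structure:
rows with positive diagonal mass are attractors, attractors sharing
supported nodes merge into attractor systems, and a node claimed by several
systems joins the one with the lexicographically smallest attractor.
Defaults: inflation 2.0 (the algorithm's canonical default), pruning
threshold 10⁻⁵. Dense linear algebra is appropriate at the package's
operating scale (hundreds to low thousands of nodes).

"Significant" clusters are those with ≥ 5 members (configurable); all
clusters remain in the full listing. Each cluster's hub is its
maximum-degree node in the cluster-induced subgraph, ties broken by
whole-network degree then lexicographically — degree centrality being the
minimal defensible notion of a "central" protein.

## Enrichment and annotation clustering

Per-term over-representation uses the one-sided hypergeometric upper tail.
The default method is EASE — the same tail computed with one hit gene
removed (p = 1 whenever k ≤ 1) — which is conservative by construction
(EASE p ≥ Fisher p for every input); exact Fisher is available by flag.
The universe defaults to all genes in the annotation table and can be
overridden with an explicit background list. Benjamini–Hochberg adjusted
values are reported per term but do not gate annotation clustering, which
operates on raw p-values (mirroring how annotation-clustering services
behave).

Terms with raw p below the significance cut are clustered by agreement of
their gene memberships: Cohen's kappa over the universe (defined as 0 when
chance agreement is 1), seed groups of terms with kappa ≥ 0.5, groups
sharing ≥ 50% of the smaller group's members merged to a fixpoint. The
kappa and linkage defaults are round, defensible midpoints; the exact
heuristics of the original annotation-clustering services are not public.
Each cluster's enrichment score is −log₁₀ of the geometric mean of member
raw p-values; 1.3 (mean p ≈ 0.05) is the significance boundary. A p of
exactly 0 is clamped to the smallest positive float with a warning.

## Biomarker overlap

The three-way overlap of prioritized genes with CSF and plasma proteome
lists reports all seven exclusive Venn region counts (which sum to the
union size and are symmetric under relabeling) plus the sorted triple
intersection — the fluid-accessible candidates.

## The synthetic-study generator

`synthgen` emulates the statistical shape of the pipeline's inputs, not
their biology: a gene universe with a realistic mixture of excluded locus
types (15% excluded classes, 2% withdrawn, 3% X-linked by default);
linkage regions laid out so that region selection plus gene-type filtering
yields exactly the intended linkage survivor set; a SNP table whose
survivors carry weighted p < 10⁻³; per-region probe tables honoring a probe
multiplicity distribution (60/25/10/5% for 1–4 probes) and a 10%
discordance rate among null multi-probe genes; an edge table with planted
dense modules (6 modules of 8 at density 0.8 over a sparse background) and
designated fallback seeds wired only with single-validation edges;
annotation tables with planted enriched terms; and fluid lists with a
planted Venn structure (clamped to the planted genes available, so sparse
configs remain generable).

Planting operates in rank space: with advantage *a*, a planted gene's score
quantile is Beta(1, *a*) toward the good end of its modality's scale, so
*a* = 1 means planted genes are exchangeable with null survivors and large
*a* pushes them to the top. Since the pipeline consumes only score order,
this is the minimal sufficient planting model; no attempt is made to match
real LOD or p-value distributions, genotypes, raw expression matrices or
mass spectra. Consequently, passing tests demonstrate the pipeline's
*mechanics* (filters, arithmetic, determinism, recovery under a known
effect) — not calibration against any real cohort.

Defaults describe a desk-scale study: 2,000 genes, 30 planted convergent
genes, modality survivor tables of 600/400/800, rank advantage 50. At these
sizes the triple intersection is ≈ 90 genes (30 planted + ≈ 60 chance
members), a realistic ratio of signal to chance convergence, and a full
pipeline run takes about a second. One integer seed drives every
sub-generator through a `numpy` SeedSequence spawned per stage, so bundles
are byte-identical per seed and the fast modality-table path reproduces
exactly the tables embedded in the full bundle.

## Numerical and design choices

- All tables are TSV with a mandatory header (order-insensitive columns);
  fold change is linear by default with an opt-in log2 conversion on load.
- Gene identity is the normalized (trimmed, uppercased) symbol everywhere;
  an alias→symbol mapping table can be applied before any join.
- Reports are written with fixed column order and deterministic row order;
  the run log records counts and parameters only (never timestamps), so
  end-to-end reruns are byte-identical.
- Thresholds are config keys with the protocol values as defaults
  (`lod_min` 2.0, `region_p_max` 0.05, `gwa_p_max` 1e-3, `adjp_max` 0.05,
  `fc_up` 2.0, `fc_down` 0.5, `mcl_inflation` 2.0, `min_cluster_size` 5,
  `kappa_min` 0.5, `linkage_fraction` 0.5).
- Degenerate inputs: an empty triple intersection is a valid result (with a
  warning); an empty modality table is an error; empty fluid lists warn but
  compute; a single isolated node clusters as a singleton.

## Known limitations

- Genome coordinates are treated as abstract and build-agnostic; no
  liftover or build checking is performed.
- No live database access: SNP→gene mapping, interaction evidence curation
  and protein-id mapping are all consumed as input tables.
- The annotation-clustering heuristic is a faithful kappa/linkage
  implementation but cannot reproduce the exact cluster compositions of
  proprietary term databases and services.
- Concordance between a main and a replication analysis is reported as
  |A∩B| divided by a chosen denominator (the smaller set by default); no
  standard definition exists, so the denominator is explicit in the API.
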