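# Methods

## Ontology model

The GO DAG is held as a term table with typed parent edges. Only `is_a` and
`relationship: part_of` edges are kept at parse time; `regulates`-type edges
are dropped, matching the standard true-path-rule practice of propagating
annotation over `is_a`/`part_of` only. The traversed relation set is a
parameter (`relations`) on every closure-dependent operation, defaulting to
`{is_a, part_of}`.

Obsolete terms are retained so their identifiers still resolve, but they are
edge-less and may neither receive nor propagate annotation (annotating an
obsolete term is treated like annotating a missing term: an error, or a
skip-with-warning under `on_missing="skip"`). Secondary identifiers
(`alt_id`) are folded into their primary term at parse time; all downstream
operations see primary ids only, and construction fails if an alt id maps to
more than one primary.

Validation enforces: identifier syntax `GO:` + 7 digits, acyclicity, one
root per namespace, namespace-homogeneous parent edges, and reachability of
the namespace root from every non-obsolete term. Ancestor closures are
memoised per relation set; `propagate` replaces each gene's term set with
its ancestor closure and is idempotent. Propagated ancestors inherit the
evidence code of the annotation that implied them.

Distinct-term counts of propagated tables include the three namespace roots
by default; `include_roots=False` excludes them, since published distinct
counts do not always state which convention they use.

`reduce_to_most_specific` returns the antichain of an input term set — the
terms that are not ancestors of any other input term. Slim counting uses the
"single occurrence" convention: for each input term, each slim term equal to
it or among its ancestors is credited once, however many paths lead there.

## Two-step clustering

Stage 1 (within genome, paralog families): hits are deduplicated per ordered
(query, subject) pair keeping the highest bitscore (ties broken by lower
E-value, then higher identity), then filtered to same-genome, non-self hits
with E-value ≤ `max_evalue` (default 1e-5, boundary kept) and identity ≥
`min_identity_percent` (default 80, boundary kept). Match sets are
symmetrised over hit direction and include the protein itself — this makes
the Jaccard coefficient well defined for proteins whose only evidence is
being a subject, and mirrors the near-universal self-hit in real BLAST
output. An edge is drawn when J strictly exceeds `jaccard_threshold`
(default 0.6); connected components are the Jaccard clusters and partition
each proteome (singletons allowed). Candidate pairs are generated from
co-occurrence inside match sets, which is provably exactly the set of pairs
with non-empty match-set intersection, so no J > 0 pair is missed.

Stage 2 (across genomes): hits are filtered to cross-genome pairs with
E-value ≤ `max_evalue` (no identity filter). For each protein and target
genome the maximal-bitscore subjects are computed, retaining *all* tied
subjects — ranking is by bitscore, not E-value, because E-values saturate at
the floor, and keeping ties makes results independent of input order. Two
clusters from different genomes are linked iff each contains a member whose
best hits in the other genome intersect the other cluster (any member pair,
not necessarily the same pair reciprocally — the cluster-level reading of
the reciprocal-best-match rule). Components with ≥ 2 Jaccard clusters are
the Jaccard orthologous clusters; they may contain several clusters from one
genome (close paralogs). Isolated clusters are reported as unclustered.

Summary percentages are rounded half-up to the nearest integer, the
convention that reproduces the published coverage figures (33, 89, 97, 32).

## Annotation transfer

Each orthologous cluster gets a single term set: the union of the direct
terms of its annotated reference-genome members. Union is the only loss-free
choice consistent with requiring identical term sets across a cluster when
several annotated reference genes land in one cluster. Every member
(reference members included, by default) receives exactly that set with
evidence code IEA and the contributing reference genes in the GAF With/From
column; `keep_reference_direct=True` lets reference genes keep their
original annotation instead. Annotated reference genes outside any cluster
are counted as unmapped. Transfer is deterministic and independent of
cluster iteration order.

Writers emit GAF 2.x (17 columns, `!`-prefixed header carrying the genome
label and provenance), GMT (term, description, member genes) and gene2terms
(gene, comma-separated terms); output is sorted and byte-deterministic, with
a fixed date stamp in GAF. GAF round-trips to an identical table; GMT and
gene2terms round-trip the gene→term structure (those formats carry no
evidence codes).

## Enrichment

For study count k of n against universe count K of N, the one-tailed
Fisher's exact test p-value is the hypergeometric upper tail
Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n), computed via `scipy.stats.hypergeom.sf`
(verified against exact rational enumeration to < 1e-12 relative error over
every configuration with N ≤ 12). Under-representation is not tested.

The universe defaults to the annotated genes (≥ 1 propagated term), since
Fisher's test over unannotated genes carries no information; an
`all_predicted` mode accepts an explicit roster when the background should
include unannotated genes. Study identifiers outside the universe are
tallied and reported, never silently dropped, so n stays well defined; a
study set with no mappable ids is a usage error.

Candidate terms are those with k ≥ `min_study_count` (default 1), so the BH
family excludes terms untouched by the study set. Correction is joint across
all three namespaces by default, with a per-namespace mode for analyses
restricted to one ontology. Significance is q ≤ alpha (default 0.05,
boundary inclusive; alpha may be 1.0 to inspect all candidates). Among the
significant terms the most-specific antichain is flagged to suppress
redundant high-level ancestors in reports.

`EnrichmentAnalysis` precomputes the propagated background and per-term
universe counts once and scores many study sets against them with vectorised
tail probabilities; `enrich()` is the one-shot wrapper.

Exports: a TSV of all candidate records, a plain-text summary, and one DOT
graph per namespace containing the significant terms plus all their
ancestors, significant nodes filled, `part_of` edges dashed — valid input
for standard DOT → SVG renderers. DOT is written directly; the format is a
few lines of quoting rules and needs no library.

## Synthetic data

The generators are pure functions of `(spec, seed)`; one integer seed drives
independent numpy SeedSequence streams (0 ontology, 1 hits, 2 annotation),
so outputs are identical across runs and platforms and writable as standard
formats (OBO, id lists, 12-column hits, GAF) for end-to-end CLI runs.

The ontology generator builds one rooted tree per namespace with given depth
and branching, optionally adding multi-parent "diamond" nodes; the tier
below each root is tagged `subset: goslim_synthetic` for slim tests. The hit
generator plants paralog families as intra-genome cliques (identity 95%,
bitscore 300; every family member's match set equals the family, so
within-family J = 1) and ortholog groups as one-protein-per-genome sets with
reciprocal cross-genome hits whose bitscores (≥ 400, strictly decreasing per
group) dominate noise hits (identity 40–75%, bitscore 50–200) by a fixed
margin — so at zero noise the planted structure is recovered exactly and no
accidental bitscore ties occur. The annotation generator assigns each leaf
term to each gene independently at the background rate and plants one
biological_process leaf on a chosen number of carrier genes.

What the generator does *not* emulate: sequence evolution, realistic E-value
or bitscore distributions, correlated annotation between paralogs, genome-
scale ontology topology, or annotation depth heterogeneity. Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under the stated model, not performance on real proteomes.

A separate printed fixture carries a published ten-strain mapping summary
(predicted/annotated transcript counts and distinct propagated term counts
per strain, plus the annotated-and-clustered intersection and namespace
partition of the reference term list) for arithmetic checks at realistic
magnitudes.

## Problem sizes and statistical checks

The statistical suites run at sizes chosen to give tight Monte-Carlo
envelopes while keeping the default test run fast: the null-control check
draws 1,000 uniform study sets of 50 genes from a 2,000-gene universe
(background term rate 5%) and requires the family-wise detection rate to
stay within 0.05 + 3·√(0.05/1000); the planted-signal check plants a leaf
term on 20 of 50 study genes under the same background and requires recovery
among the significant most-specific terms in ≥ 95 of 100 seeded runs; the
clustering pipeline is compared against a naive all-pairs oracle on 100
random instances of up to 4 genomes × 15 proteins; DAG properties are
checked on 200 random DAGs of ≤ 30 nodes against a DFS oracle.

## Known limitations

- The graph-based RBH approach targets closely related genomes; it degrades
  with many distant genomes or highly repetitive proteomes, and no synteny
  or tree-aware orthology is attempted.
- Transferred annotation is purely computational (IEA); its quality is
  bounded by the reference curation and the correctness of the clusters.
- BH q-values assume the usual positive-dependence conditions; Fisher's
  p-values are discrete and therefore conservative, which the null-control
  check reflects (observed family-wise rates well below alpha).
- The percentage convention is round-half-up; published tables occasionally
  floor a share so that a percentage column sums to 100, so a reproduced
  share can differ by one point from a printed one.
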