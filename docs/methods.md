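# Methods

## Problem setting

Protein relationship networks link proteins by any shared property — gene
co-expression (COE), co-occurrence of protein names in literature abstracts
(LIT), experimentally determined physical interaction (PPI) and sequence
similarity (SEQ) — and are routinely partitioned into modules by graph
clustering. `netcoherence` quantifies whether such modules are *functionally
coherent* with respect to Gene Ontology (GO) biological-process annotation,
and whether combining evidence layers yields more coherent modules than any
single layer.

Two complementary views are implemented. The representative-function view
asks: how specific a set of GO terms can describe a stated fraction of a
module (AIC-MICA)? The fragmentation view asks: how badly does the clustering
scatter the protein set of each GO term across modules (fragment count N_t
and fragmentation entropy H_t, with permutation nulls and cross-network
best-rank proportions BFRP/BERP)?

## Network construction

Each evidence layer is thresholded independently:

- COE: edge iff |Pearson r| > 0.6 (strict; the magnitude rule links strong
  negative correlation as well). Configurable via `coe_min_abs_r`.
- SEQ: edge iff any BLAST hit between the pair, in either direction, has
  E-value < 1e-3 (strict) and percent identity >= 25 (inclusive). One
  undirected edge per pair; self-hits ignored.
- LIT: edge iff the pair co-occurs in at least one abstract.
- PPI: de-duplicated undirected pairs; self-interactions discarded.

The combined (ALL) network is the union of the layers; each edge carries the
set of evidence types supporting it. When a PPI layer is present the node
universe defaults to the PPI protein set (`--restrict-to-ppi`), reflecting a
design in which interaction data defines the reference proteome subset.
Orphans (degree-0 nodes) are kept so orphan counts remain computable. Edges
are unweighted: evidence multiplicity never increases weight. Summaries
follow the standard definitions — transitivity is 3 x triangles / connected
triples, the diameter is taken over the largest connected component with
unit-length edges, and the evidence-combination table reports exclusive
counts (a partition of the edge set by exact evidence set) and inclusive
counts (inclusive(S) = sum of exclusive(T) over supersets T of S).

## Information content and MICA

One GO namespace is analysed at a time as a rooted DAG of `is_a`/`part_of`
edges (other relation types do not propagate annotation — the usual
true-path-rule reading). Annotations are closed under ancestors; the
information content of a term is IC(t) = -log(n_t / N), with n_t the number
of reference-corpus proteins annotated at-or-below t and N the annotated
corpus size. Natural log is the default (the Resnik convention); base 2 and
base 10 are available. The reference corpus may be larger than the protein
set under analysis; by default it is that protein set itself. Terms never
annotated in the corpus have undefined IC and are excluded from
most-informative-common-ancestor (MICA) candidacy. `ancestors()` is
reflexive, so a term is its own common ancestor; IC ties are broken by
lexicographic term id, which makes results reproducible but means a parent
with the same annotation count as its only annotated child can be returned
in its place.

## AIC-MICA

For a cluster and a coverage fraction f in the default grid 0.40–0.90 (10%
steps), the quota is ceil(f x n) with n the cluster's annotated-protein
count. The representative set is selected greedily: repeatedly add the term
maximising IC(t) x (newly covered annotated proteins), ties broken by larger
new coverage then lexicographic id, until the quota is met; the AIC is the
unweighted mean IC of the selected terms. The greedy score is a deliberate
design choice in territory where only the intent (a set of common ancestors
covering the quota) is fixed: scoring by IC alone degenerates to per-protein
singleton terms, scoring by coverage alone degenerates to the root; the
product reduces to the single MICA whenever one informative term covers the
quota. The root covers every annotated protein, so the quota is always
reachable. A restricted single-term variant (the maximal-IC term whose cover
alone meets the quota) is monotone non-increasing in coverage and is used as
an exactly assertable invariant.

Choices a user can flip: the coverage denominator (`annotated`, the default,
versus `all` cluster members — unannotated proteins cannot contribute to any
common ancestor, so the `all` denominator can make quotas unreachable, in
which case the cluster is reported as ineligible at that level); quota
rounding is always ceil ("at least" semantics); a coverage-weighted AIC and
a cluster-size-weighted cross-cluster mean are available but not default.
Profiles report the mean and 25th/75th percentiles of per-cluster AIC over
eligible clusters (size >= 2 and >= 1 annotated protein) plus the number and
fraction of proteins in eligible clusters.

## Fragmentation entropy

For a term t with annotated set A_t (restricted to clustered proteins),
p_k = |A_t intersect cluster k| / |A_t| over the clusters C_t that contain
at least one member, N_t = |C_t| and H_t = -sum p_k log10 p_k. Base-10
logarithms are the default, back-calculated from the worked example the
metric is anchored to: a 16/1/1/1/1 split of 20 proteins gives H = 0.338
only in base 10. H_t = 0 iff N_t = 1 and H_t = log10(N_t) iff fragments are
equal-sized; merging two fragments never increases H_t.

Corpus averages take the unweighted mean of H_t over terms annotating at
least `min_proteins` (default 10) clustered proteins, a guard against
small-sample noise. The permutation null shuffles the node-to-cluster
assignment (cluster sizes preserved, annotations fixed to nodes) — the
statistic is identical under the equivalent view of permuting annotation
labels. The qualifying-term set is permutation-invariant and computed once.
p-values use the (exceedances + 1) / (n_perm + 1) correction, so 10000
permutations with zero exceedances report p < 1e-4. When several clusterings
(one per evidence network) are compared, BFRP and BERP credit, per term,
every network attaining the minimal N_t resp. H_t; percentages may therefore
sum above 100 across networks. Terms must qualify in every compared network
(shared-corpus filtering); per-network filtering drops non-shared terms with
a warning.

The shortest-path-length (SPL) check measures the mean unweighted SPL over
pairs of a term's proteins that share a connected component, against a null
that reassigns the annotation to a uniformly random node subset of equal
size. Cross-component pairs are excluded rather than assigned infinite
distance; draws with no connected pair are skipped.

## MCL clustering

The Markov Cluster algorithm is implemented densely in numpy: add unit
self-loops, column-normalise, then alternate expansion (matrix squaring) and
inflation (entrywise power, default 2.8, then renormalise), pruning entries
below 1e-5 and stopping when the maximum entrywise change falls below 1e-6
or at 100 iterations (a warning is emitted and the last iterate is used if
the cap is hit). Clusters are read from the attractor structure of the limit
matrix; a node claimed by several attractor systems goes to the one holding
the larger share of its column mass, then to the lexicographically smallest
attractor, forcing the true partition the fragmentation metrics require.
The implementation is deterministic and intended for networks of a few
thousand nodes; equivalence with an independently coded dense reference is
asserted on planted-partition graphs up to 40 nodes. Externally produced MCL
cluster files (one cluster per line, tab-separated) are accepted, so the
original `mcl` binary can be substituted for large inputs.

## Synthetic fixtures

The generator plants a partition of proteins into modules; every evidence
layer is an independent thinning (per-layer evidence probability, default
0.5) of a planted-partition graph with within-module edge probability
p_in = 0.9 and between-module probability p_out = 0.05. The ontology is a
balanced tree (default depth 3, branching 3) plus one two-parent diamond
term to exercise DAG code paths. Each module is mapped to a distinct
mid-depth term; a protein is annotated to a uniformly random term of its
module's subtree with probability `annotation_coherence` (default 1.0),
otherwise to a uniformly random leaf. One integer seed drives a spawned
child generator per layer, so adding a layer does not perturb earlier
layers' draws. The ground-truth partition is emitted alongside so metric
tests do not depend on MCL behaviour.

For the coherence-signal checks the fixture uses 9 modules on 1000 proteins
so the modules tile the full depth-2 level of the default DAG: coherent
modules are then covered by their own specific term (IC = ln(1000/111) ~
2.2) while random protein mixtures are covered by the three shallow depth-1
ancestors (IC ~ 1.1), which is the qualitative situation the metric is
meant to detect. Null-calibration checks use `annotation_coherence = 0`, under
which annotations are independent of module membership and permutation
p-values must be uniform.

What the generator does not emulate: realistic degree distributions, hub
structure or correlation between evidence layers beyond the shared planted
partition, annotation depth heterogeneity, or multi-term annotation per
protein. Passing tests therefore demonstrate correctness of the metrics and
their calibration under controlled conditions, not performance claims about
any real proteome.

## Numerical and degenerate-input conventions

Entropy terms with zero counts are dropped (0 log 0 = 0). Empty networks,
empty clusters, clusters overlapping across lines of a cluster file,
annotation-free corpora and terms annotating nobody are hard errors;
unknown annotation terms are dropped with a warning; a cluster with no
annotated protein is ineligible rather than an error. All permutation
operations require a seed and are exactly reproducible given one.

## Known limitations

Published absolute values of this kind — evidence-combination edge counts,
orphan counts, transitivity/diameter tables, absolute IC-versus-coverage
curves, average-entropy tables, and SPL reductions for named GO terms such
as "response to hormone stimulus" — depend on specific database snapshots
(IntAct, ATTED-II, PubMed abstract sets, TAIR/UniProt annotation and
proteome subsets) and on the IC reference corpus they imply. They are not
reproducible from code alone and are deliberately not asserted anywhere;
the structural identities, closed forms, oracle equivalences and
calibration properties exercised by the test suite are what the package
guarantees. Edge weighting and confidence integration across evidence
types, alternative clusterers, and evidence-code filtering of GAF records
are out of scope.
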