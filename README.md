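# netcoherence

Functional-coherence analysis of modules in multi-evidence protein
relationship networks.

Networks that link proteins by co-expression (COE), literature co-occurrence
(LIT), experimental interaction (PPI) or sequence similarity (SEQ) — and
their union (ALL) — are routinely partitioned into modules with the Markov
Cluster algorithm (MCL). `netcoherence` is a library and command-line tool
for asking whether those modules mean anything biologically, using Gene
Ontology (GO) annotation. It is aimed at systems-biology practitioners who
integrate heterogeneous evidence into one network and want a quantitative,
null-calibrated answer to "are the clusters functionally coherent, and did
integrating another data source help?"

## The metrics

**AIC-MICA (coverage vs. specificity).** For a cluster and a coverage level
f ∈ {0.40, …, 0.90}, find a set of GO terms, each a common ancestor of part
of the cluster, that together cover at least ⌈f·n⌉ of the n annotated
members, and report the average Resnik information content
IC(t) = −log(n_t/N) of that set. Terms are picked greedily by
IC × newly-covered-proteins, which reduces to the single most informative
common ancestor (MICA) when one informative term covers the quota. Coherent
clusters stay specific (high AIC) even at 90% coverage; incoherent ones
collapse toward the root (IC = 0).

**Fragmentation entropy (scatter of a function across modules).** For a GO
term t annotating the protein set A_t, with p_k the fraction of A_t in
cluster k over the N_t clusters touched,

    H_t = − Σ_k p_k log₁₀ p_k ,

so H_t = 0 when the term sits in one module and log₁₀(N_t) when it is
spread evenly. Corpus averages of H_t are tested against a null that
permutes the node-to-cluster assignment; across several networks, BFRP and
BERP report the percentage of terms for which each network attains the
lowest N_t resp. H_t (ties credited to all). A worked anchor: 20 proteins
split 16/1/1/1/1 give H = 0.338.

The package also builds the evidence layers from standard formats (BLAST
outfmt 6, correlation/co-occurrence/pair TSVs) with the usual thresholds
(|r| > 0.6; E-value < 10⁻³ and identity ≥ 25%; ≥ 1 shared abstract),
summarises them (evidence-combination tables, transitivity, components,
diameter, orphans), includes a deterministic dense MCL (inflation 2.8 by
default), and ships a synthetic-fixture generator with planted modules and
ground truth so the whole pipeline is testable offline. See
`docs/methods.md` for the full model description and design choices.

## Worked example

Generate a 60-protein fixture with 4 planted modules, cluster its combined
network with MCL, and score the result:

```
netcoherence synth --n-proteins 60 --n-modules 4 --seed 7 --out demo/fixture
netcoherence cluster --network demo/fixture/all.tsv --out demo/mcl
netcoherence coherence --obo demo/fixture/ontology.obo \
    --annotations demo/fixture/annotations.tsv \
    --clusters demo/mcl/clusters.tsv --out demo/coherence
netcoherence fragmentation --obo demo/fixture/ontology.obo \
    --annotations demo/fixture/annotations.tsv \
    --clusters demo/mcl/clusters.tsv \
    --min-proteins 10 --n-perm 1000 --seed 7 --out demo/frag
```

which prints

```
fixture with 60 proteins, 4 modules -> demo/fixture
4 clusters -> demo/mcl
AIC-MICA profile over 4 clusters -> demo/coherence
average entropy 0.154 vs permuted 0.576 (p = 9.99e-04) -> demo/frag
```

MCL recovers the four planted 15-protein modules exactly
(`demo/mcl/summary.json`: 4 clusters, largest 15, no singletons). The
AIC-MICA profile holds mean AIC = 1.386 = ln(60/15) at every coverage level
from 40% to 90% — each module is fully covered by its own designated term,
so specificity does not degrade with coverage. The per-term fragmentation
report (`demo/frag/terms.tsv`) shows the DAG at work: module terms have
N_t = 1 and H = 0 (intact), their parent covering three modules has
H = 0.477 = log₁₀ 3, and the root, necessarily split over all four equal
clusters, has H = 0.602 = log₁₀ 4. The permutation null
(`demo/frag/entropy_null.json`) puts the observed average entropy 0.154 far
below the permuted 0.576 — a 73.2% relative decrease with p ≈ 0.001, the
smallest p-value 1000 permutations can report.

Every subcommand writes a `manifest.json` (configuration, versions, seed)
next to its outputs. Externally produced MCL cluster files are accepted via
`--clusters`, so the reference `mcl` binary can stand in for the built-in
clusterer on large networks.

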