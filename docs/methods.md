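# Methods

## Input model

The pipeline consumes four kinds of plain-text inputs: (i) disease–gene and
drug–target association tables (TSV: `entity_id`, `gene_id`, optional
`entity_name`), (ii) a known-indication table (`disease_id`, `drug_id`),
(iii) one GMT gene-set library per feature category (biological process,
pathway, phenotype), and (iv) optionally a PPI edge list and a drug-id
cross-mapping for augmenting targets from a second vocabulary. The format
interface is deliberately source-neutral: any annotation resource that can
be dumped to these dialects works. Parsing is lenient by default (malformed
rows are skipped and counted) because real annotation dumps are dirty; a
strict mode turns every defect into an error. Entities with zero genes and
indications referencing unloaded entities are dropped at load, with counts
logged. Drug-target augmentation from a secondary source is applied before
anything else, so the merged target sets feed both the enrichment profiles
and the gene similarity layer uniformly.

## Enrichment

Over-representation is the one-sided hypergeometric tail
`P(X >= k)` for an overlap of `k` genes between an `n`-gene query and a
`K`-gene feature in an `N`-gene universe, computed with
`scipy.stats.hypergeom.sf`. The background universe defaults to the union
of all genes seen in any entity annotation or any library, overridable.
Correction is Bonferroni within each library: the multiplier `M` is the
number of features with a non-empty universe intersection, identical for
every entity; features with zero query overlap are never called enriched
regardless of `M`. The significance level defaults to 0.05. Gene sets are
treated flat — no ontology-graph propagation or term-redundancy pruning.

## Similarity layers and the weighted network

Each layer computes Jaccard similarity over an entity→set map (gene sets
for the gene layer, per-category enriched-feature sets for the other
three) across *all* pairs — disease–disease, disease–drug, drug–drug — and
keeps pairs with `J >= cutoff` (default 0.5, boundary inclusive). The
implementation uses an inverted index so only pairs with a non-empty
intersection are scored; this is provably identical to the all-pairs double
loop, which the test suite checks directly. A pair of empty sets is defined
to have `J = 0` (such pairs can never share anything). The network is the
union of surviving pairs; an edge's integer weight 1–4 is exactly the
number of layers that passed the cutoff — category sharing *below* the
cutoff is never observed and never contributes. Entities left without any
edge are dropped (configurably retained).

## Louvain clustering

Implemented from the modularity objective: phase one sweeps nodes in a
seeded shuffled order and moves each to the neighbouring community with the
largest positive modularity gain (ties keep the current community); phase
two collapses communities into super-nodes with internal weight as
self-loops, and the two phases repeat until an aggregation pass improves Q
by less than 1e-10 (a float-safe reading of "until the maximum of
modularity is reached"). Resolution is fixed at 1. The reported Q is
recomputed from the flat partition by the standalone `modularity` function,
and the level history is retained so the monotonicity of Q across passes is
testable. Determinism is guaranteed under a fixed seed; the independent
`networkx` Louvain implementation serves as a cross-check in the tests,
never as the implementation.

## Cohesive overlapping clustering

Cohesiveness is `f(V) = W_in / (W_in + W_bound + P(V))` with
`P(V) = penalty_per_node * |V|`; the penalty form is our concretisation of
the cited algorithm's term for unobserved connectivity. Growth seeds at the
highest-weighted-degree node not yet covered, then repeatedly applies the
single boundary-node addition or member removal that most increases `f`
(strict improvement with a 1e-12 margin; tie-break by node id) until no
step improves, which makes every grown cluster one-step locally optimal by
construction. Clusters may overlap; pairs with match coefficient
`|A∩B|²/(|A||B|) >= 0.8` are merged iteratively. Defaults follow the
published algorithm: penalty 2, minimum size 3, minimum weighted internal
density 0.3 (a singleton's density is defined as 0). Each surviving cluster
gets a one-sided Mann–Whitney p-value comparing internal vs boundary edge
weights, and clusters with `p > 0.05` are discarded; a cluster with no
boundary edges is kept with `p := 0` by convention. Note the rank test is a
large-network device: with only a handful of edges it cannot reach 0.05 at
all (the closed-form two-triangle checks therefore disable it). The
procedure is fully deterministic — the `seed` parameter exists for
interface symmetry with Louvain.

## Candidates, consensus, robustness, distances

Candidates are the union over mixed clusters (≥1 disease and ≥1 drug) of
the within-cluster disease × drug cross-product, minus known indications;
recovered known indications are reported separately rather than silently
dropped. Provenance (algorithm, cluster id) is kept per pair, and the
consensus set is the plain pair intersection of the two algorithms'
outputs.

Robustness removes `floor(0.1 · |E|)` edges uniformly at random (weights do
not bias sampling — nothing in the protocol says they should), re-runs both
clusterers and the extraction, and scores recovery as
`|original ∩ perturbed| / |original|` — candidate-level recall with the
original candidate count as denominator, the natural reading of "recovery
rate of our predictions". Ten replicates by default; each replicate's RNG
is derived from `(master_seed, replicate)`, so reports are bit-identical
across runs.

The indication-distance analysis takes, per known pair, the minimum
unweighted shortest-path length over all (disease gene, drug target)
combinations in the PPI — the most permissive reading of a per-pair
distance, with 0 when the pair shares a gene. Pairs whose genes are absent
from the interactome or mutually unreachable are counted as uncomputable
and excluded from the mean and median.

## Synthetic corpus

The generator plants `n_modules` modules (default 10), each with a private
pool of 10 genes, 3 diseases, and 10 drugs; every member draws 8 distinct
genes from its pool, so any within-module pair shares at least
`2·8 − 10 = 6` genes and its gene Jaccard has floor 0.6 — safely above the
0.5 cutoff — before contamination. Each drawn gene is independently swapped
for a gene from another module's pool with probability 0.05, the kind of
annotation noise that blurs module boundaries in real resources. Feature
libraries carry one feature per module and category (the module's pool)
plus five background decoys, so the enrichment layers genuinely connect
module members beyond shared genes — mirroring how pathway-level links can
exist between entities sharing no gene. A small unstructured background (5
diseases, 10 drugs over a 200-gene pool) stays below the cutoff and drops
out of the network. Known indications are sampled from within-module
disease–drug pairs at rate 0.1; the remaining within-module pairs are the
ground-truth expected candidates. The PPI fixture wires each module pool as
a clique with a few random inter-module bridges and chains background
genes. Everything is a pure function of the design dataclass, whose seed
feeds `numpy.random.default_rng`; identical designs yield byte-identical
bundles. Sizes were chosen so the full pipeline, the robustness protocol,
and the whole test suite finish in seconds on one CPU.

What the generator does **not** emulate: the heavy-tailed degree and
annotation-size distributions of real disease/drug resources, overlapping
or hierarchical module structure, correlated feature libraries, and
realistic interactome topology. Consequently, passing the planted-recovery
and robustness checks demonstrates the pipeline's correctness and stability
on well-separated module structure, not its ranking power on real,
noisier data — on real corpora the clusters are larger, the consensus
filter matters more, and recovery rates will be lower. Because
within-module entities share genes by construction, the synthetic
indication distances are 0; the distance analysis is exercised for its
mechanics (reachability handling, minimum over combinations), not for the
magnitude seen in real interactomes.

## Numerical and degenerate-input choices

Greedy moves (both algorithms) require strict improvement beyond 1e-12 to
guard against float-noise oscillation; Louvain's pass-level termination
threshold is 1e-10 absolute on Q. The empty network is an error for
modularity and clustering; an empty candidate set is an error for the
robustness protocol (recovery is undefined); an empty enrichment universe
is an error. Jaccard of two empty sets is 0; a cluster with no boundary is
maximally cohesive (`f = 1` at zero penalty) and significant by convention.
Community and cluster ids are canonicalised (ordered by smallest member) so
outputs are stable under node-order permutations.

## Limitations

Only the consensus flag ranks candidates — no scoring or prioritisation
beyond it. Enrichment supports Bonferroni only (the correction named by the
workflow); alternative FDR control would change edge density and is left as
a config hook. The Louvain implementation returns the final hierarchy level
only. Literature and clinical-trials validation of candidates is outside
the package's scope.
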