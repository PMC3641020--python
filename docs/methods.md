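# Methods

## The model

The package analyses an undirected, unweighted, simple graph over
protein symbols. Interaction confidence scores (STRING-style, canonical
scale 0–1000) act purely as an *inclusion filter* — an edge exists iff
its score reaches `min_score` — and never as edge lengths; all path
computations are unit-length. The default `min_score` is 400, the
conventional "medium confidence" STRING cutoff, and is recorded in every
run manifest since the whole topology downstream depends on it.

**Extended network.** Given seeds S and a cleaned interaction table, the
node set is (S ∩ table) ∪ N(S) and the edge set is *induced*: every
table edge with both endpoints in the node set, including
neighbour–neighbour edges. Seeds absent from the filtered table are
dropped with a warning by default (`keep_missing_seeds` retains them as
isolated flagged nodes). Cleaning collapses duplicate and reversed rows
to one undirected edge keeping the maximum score and drops
self-interactions; cleaning is idempotent.

**Centralities.** Betweenness uses the normalization
2/((N−1)(N−2)) on unordered pairs with endpoints excluded, so the centre
of a star scores exactly 1 — the convention of the classical network
tools this field uses; raw and normalized BC differ only by that
constant, but ranked cutoffs depend on consistency, so the convention is
fixed package-wide. Closeness is (N−1)/Σd. Betweenness, closeness and
the global statistics refuse disconnected input rather than silently
switching to harmonic variants: analysis is defined on the giant
component, and the refusal surfaces pipeline mistakes early. The average
degree is computed as ⟨k⟩ = 2E/N. (The published hypertension study
prints N = 535, E = 2572 and ⟨k⟩ = 7.61 for its giant network, an
internally inconsistent triple since 2·2572/535 ≈ 9.61; this package
always reports 2E/N and makes no attempt to force agreement.)

**Backbone and key nodes.** The high-BC cutoff is m = ⌈fraction·N⌉ with
fraction defaulting to 0.05: 5% of a 535-node network gives m = 27.
Ties *at the boundary* are all included (the published degree list has
28 entries for the same nominal cutoff, consistent with tie inclusion);
membership can therefore exceed m, and the inflation is logged. Ranked
*order* ties break by symbol for deterministic reports. Hubs are the
top-fraction by degree, bottlenecks the top-fraction by BC; the four
Yu-style classes partition the node set. Note that integer degrees tie
heavily — on synthetic data with equal-size cliques the hub set can
inflate well beyond m; this is the documented tie rule at work, not a
defect.

**Seed subnetwork.** For every unordered seed pair, *all* distinct
shortest paths are enumerated via the BFS predecessor DAG
(`networkx.all_shortest_paths`), not one representative. The subnetwork
is the induced subgraph on the union of path vertices, so induced edges
among collected nodes are kept (the published subnetwork figure is dense,
which supports the induced reading; path-only edges would be the
alternative). Shortest-path counts can explode combinatorially, so a
per-pair cap (default 10⁵) aborts with an explicit error rather than
sampling silently. Within the subnetwork, seed-pair distances equal
their giant-network distances: the subnetwork contains a shortest path
for every pair and, being induced, cannot lengthen any.

**Robustness protocol.** Omission depths k = 1..k_max (default 7 ≈ 10%
of 69): k = 1 omits every seed once; k = 2 pairs the central gene with
every other seed; k ≥ 3 draws `draws_per_k` (default 30) sets of
{central} ∪ (k−1 uniform without replacement), independent across draws
with repeats permitted — duplicates are deliberately kept so the group
sizes stay fixed. The top-M set of each test network uses M frozen at
the reference backbone's cutoff (27 in the published configuration), not
recomputed per network. Accuracy is |top-M ∩ reference backbone| / M.
The overall accuracy is the **unweighted mean of the per-depth mean
accuracies** — this is the aggregation that reproduces the published
overall value 0.80344 exactly from the published per-depth values; the
network-weighted mean (≈ 0.821 there) is also computed and labelled.
Argmax-BC ties break by symbol (real-valued BC makes ties vanishingly
rare, but determinism matters for the frequency tables).

## The synthetic generator

The generator emulates the *shape* of a disease-gene interactome study
without claiming biological realism:

* **Background**: Barabási–Albert preferential attachment
  (`n_background` = 500, 2 edges per new node), giving the heavy-tailed
  degree distribution characteristic of human PPI networks.
* **Planted bridge**: `n_modules` = 4 cliques of `module_size` = 25,
  each member adjacent to the designated bridge node and to nothing else
  outside its module; the bridge additionally attaches to the
  `bridge_anchors` = 8 largest background hubs. The bridge is therefore
  the unique cut vertex between all module mass and the background — a
  verification pass asserts this at generation time — which guarantees it
  a betweenness of at least the module–background pair mass. Anchoring on
  hubs rather than random nodes matters twice over: hubs are almost
  surely adjacent to some seed, so the module block cannot be severed
  from the background by omitting one unlucky seed; and spreading the
  module traffic over eight anchors keeps any single anchor's betweenness
  well below the bridge's. Margin sweeps over generator seeds show the
  bridge needs module mass around a third of the realized giant to
  dominate reliably; at the defaults its lead is comfortable, and
  configurations much leaner than ~30% module share should not be
  expected to recover it every time.
* **Scores**: structural edges draw uniform scores on [400, 1000]; noise
  edges — random non-structural pairs, 0.25 per structural edge, i.e.
  20% of all rows — draw on [100, 400). Filtering at the default
  threshold exactly recovers the planted topology, so the ground truth
  is provable; below 400 the noise edges can break the cut property, and
  the bridge guarantee is stated only for the default threshold.
* **Satellites**: two detached 2-node components, each contributing one
  seed — the analogue of the two seed proteins whose only partners fall
  outside the giant network.
* **Seeds**: 69 by default, 67 from the giant region and one per
  satellite; every module carries at least 2 seeds (so single omissions
  never empty a module) and background seeds are sampled
  degree-weighted — disease genes skew well-connected, and peripheral
  seeds would shed small fragments from the extended network. The bridge
  itself is *not* a seed by default: it enters the network only as a
  neighbour, reproducing the signature phenomenon of a non-seed protein
  dominating the centrality ranking of every test network.

What the generator does **not** emulate: interaction evidence channels,
protein complexes, degree-correlated false positives, or any biological
module semantics. Passing tests on generated data therefore demonstrate
that the *pipeline arithmetic and ranking logic* recover planted
topology under realistic size and noise, not that any biological claim
holds on a real interactome.

## Reproducibility and numerics

Every randomized stage consumes a named sub-seed derived (FNV-style,
< 2³¹) from the run's `rng_seed`, so stages are independently
reproducible and a manifest-driven re-run is byte-identical, floats
being written at a fixed 5 decimals. Components sort by size then
lexicographically smallest member; all ranked outputs break ties by
symbol. Problem sizes used in the shipped tests and the acceptance
script — giant components around 120–420 nodes, omission protocols of 65
to 287 test networks — were chosen so the full pipeline runs in seconds
to about a minute on one CPU while keeping every structural feature of
the full-scale study (satellites, tie inflation, seed re-entry).

## Known limitations

* The published study's own network tables derive from a retired STRING
  v9.0 snapshot; its node-level numbers (535/2572, NOS3 BC 0.27867,
  KNG1 degree 43, the 93-node subnetwork) are shipped as reference
  inputs for protocol arithmetic, and are not recomputable from raw
  data here.
* Identifier mapping is by symbol only; an optional two-column alias
  file remaps table ids to seed symbols, but no ortholog or isoform
  resolution is attempted.
* Betweenness is exact (Brandes); no approximate variant is provided, so
  very large interactomes (≫10⁴ nodes) will be slow through the 287-fold
  protocol.
* The backbone may be disconnected; its global statistics are then
  omitted rather than computed per component.
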