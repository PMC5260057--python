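# Methods

This note records the model implemented by `modrob`, the conventions chosen
where the mathematics leaves room, and what the test suite's synthetic
networks do and do not establish.

## Model

A network is a directed graph G(V, A) with N nodes in a fixed order and
signed arcs (activating +1 / inhibiting −1). At most one arc joins an
ordered pair; self-loops are allowed (autoregulation). Node order is part
of the data: it defines the bit positions of dynamic states, so two reads
of the same file always produce bit-compatible objects.

### Boolean dynamics

Each node carries a binary state. A node with k ≥ 1 regulators updates by
either the conjunction or the disjunction of its k literals (the
regulator's value, negated iff the arc inhibits); the choice is drawn
uniformly and independently per node from a seeded generator, once per
network instance. All nodes update simultaneously: s(t+1) = F(s(t)).

*Input-free nodes.* Nodes with no regulators keep their value (identity
rule). They thus act as constants of a trajectory, and flipping one is a
permanent, observable perturbation. The alternative — clamping such nodes
to a constant — would make perturbations of them invisible and silently
shrink the effective perturbation space.

Because the map is deterministic on a finite space, every trajectory ends
in a fixed point or a limit cycle. Attractors are stored canonically:
the cycle is rotated so its lexicographically smallest state (bits read in
node order) comes first, making attractor equality a plain sequence
comparison. Trajectory detection uses a visited-state hash map and is
capped (default 2²⁰ steps, configurable); exceeding the cap raises an
error rather than truncating. Within a robustness sweep an
`AttractorCache` memoizes every visited state's attractor, since the
perturbation grid revisits basins constantly.

### Robustness

γ(G) counts the fraction of (initial state s, flipped node v) pairs for
which the perturbed trajectory reaches *exactly the same* attractor
(canonical sequence equality — not a similarity threshold). The initial
states are a uniform sample S̃ without replacement, |S̃| = 2N by default;
when the requested sample covers the whole space the value is exact. One
sample is shared by γ and the module decomposition so all reported numbers
describe the same experiment.

For a partition P, γ_in(Vᵢ) and γ_out(Vᵢ) average the similarity H between
the projections of ⟨s⟩ and ⟨s_v̄⟩ onto Vᵢ and V∖Vᵢ respectively, over
s ∈ S̃ and v ∈ Vᵢ, normalized by |Vᵢ|; network-level γ_in/γ_out are plain
means over modules.

Two conventions make H well defined on projections:

* **Denominator.** The Hamming distance is divided by the dimension of the
  *compared* vectors (|Vᵢ| or |V∖Vᵢ|), not the full N, so H stays in
  [0, 1] for every projection and equals 1 exactly for identical
  projected cycles. Dividing by N would merely rescale projected
  distances by a module-size-dependent factor and break the H = 1
  calibration.

* **Alignment.** The projection of a cycle is first reduced to its minimal
  period — a subset of nodes may cycle with a shorter period than the full
  state (e.g. sit at a fixed point while the rest oscillates), and that
  shorter cycle is the subset's own partial attractor. The two reduced
  cycles, lengths l ≤ l′, are then paired under their best relative
  rotation: H = max_r (1/l′) Σ_{j<l} (1 − h(aⱼ, b_{j+r mod l′})/d).
  Attractors are rotation-equivalence classes, so a phase-dependent
  pairing would be an artifact of where a trajectory happened to enter the
  cycle. This convention has two consequences that double as test anchors:
  identical attractors score 1 on every projection (hence a network with a
  single global attractor has γ = γ_in = γ_out = 1), and a perturbation
  that cannot reach a dynamically independent subsystem leaves that
  subsystem's score at exactly 1 (γ_out(Vᵢ) = 1 when Vᵢ is a disconnected
  component). A naive pairing of canonically rotated full cycles satisfies
  neither: the rotation is chosen on full states, so the untouched
  coordinates end up compared out of phase.

  The standalone `attractor_similarity(a, b, dim)` operation, which has no
  projection context, compares whole canonical attractors positionally;
  for it, a fixed point versus a 2-cycle sharing its canonical first state
  scores 1/2.

A module equal to all of V has no complement; its γ_out is reported as NaN
and excluded from the γ_out mean (a single-module partition therefore has
a missing network γ_out rather than raising).

### Modularity

M(P) = Σᵢ (ω_{VᵢVᵢ}/ω − ωᵢ^out ωᵢ^in/ω²) on the unsigned digraph. The
degree sums ωᵢ^out/ωᵢ^in include intra-module arcs — the standard directed
null term, under which a single-module partition scores exactly 0 and two
disconnected 3-cycles score 0.5 under the component partition. The
`exclusive_boundary` switch implements the alternative reading in which
internal arcs are excluded from the degree sums; it is provided for
comparison only (it assigns a single-module partition the value 1, which
makes it unusable as an optimization target).

The optimizer runs independent trials (default 30): greedy single-node
label moves in a random visiting order (ties broken toward the lowest
module index), alternated with a greedy agglomerative merge phase over
connected module pairs, until neither improves M(P). The first trial
starts from singletons; later trials start from random labelings to
diversify the search basins. A trial whose local optimum is negative falls
back to the trivial single-module partition (value 0), so every trial
value is ≥ 0. Module statistics are maintained incrementally (O(deg)
per move) and the final value always equals a from-scratch evaluation —
this consistency is asserted in the tests. The reported network modularity
is the mean over trials, with the best trial's partition and value also
exposed; the module decomposition of robustness uses the best partition.
On networks of ≤ 8 nodes the best trial matches exhaustive enumeration
over all set partitions in every tested instance.

## Random networks

The five generator models, concretely:

* `ba` — directed preferential attachment: nodes arrive one at a time and
  send m arcs to distinct existing nodes drawn ∝ (total degree + 1), new →
  old. The +1 smoothing bootstraps the initially degree-0 seed nodes.
* `er` — exactly m arcs uniform among ordered pairs, no duplicates or
  self-loops.
* `er-variant` — every ordered pair independently an arc with
  probability p.
* `shuffle-dp` — double-edge swaps (a→b, c→d) ⇒ (a→d, c→b) with rejection
  of self-loops and duplicates; the joint (in, out) degree sequence is
  preserved exactly. Default 10× the arc count of successful swaps (a
  common mixing heuristic); a bounded-attempt guard raises with
  diagnostics on over-constrained templates.
* `shuffle-st` — the target column permuted uniformly, rejecting
  permutations that create self-loops or duplicates; out-degrees preserved.

Shuffles rewire blind to signs, and each moved arc keeps the sign it
carried in its source slot. Generated arcs receive signs independently,
activating with probability 0.5 by default — an uncommitted coin flip, in
the absence of any biological prior on the activating fraction of a random
ensemble.

## Batch mode and the replication ensemble

`run_batch` generates one network per replicate, draws fresh rules,
optimizes modularity, and computes the robustness decomposition on the
best partition, writing one TSV row per network (failed replicates are
marked, not fatal). Per-replicate seeds are master_seed + index, so any
subset of a batch reproduces in isolation; structure, signs, rules, search
and sampling get separate sub-seeds derived from the replicate seed. Each
(state, perturbation) unit of work is pure and the sample is drawn once up
front, so results are bitwise independent of the worker count.

The scaled-down replication study (`replication_ensemble_specs`) asks
whether the negative modularity–robustness relationship seen in signaling
networks holds across random ensembles. Composition: n = 30, three
uniform-random densities (m = 30, 60, 90) and three preferential-attachment
intensities (m = 1, 2, 3), 17 networks each — 102 networks, |S̃| = 2N,
30 modularity trials. The heterogeneity is the point: modularity in random
networks varies chiefly with model class and density, and within a single
fixed-density ensemble its spread is so narrow that module-size artifacts
dominate any correlation; a mixed ensemble is what actually probes the
trend while staying small enough to simulate in seconds. With this design
modularity correlates strongly negatively with γ and γ_in (|r| ≈ 0.6,
p < 10⁻⁹ at n = 102) and shows no significant trend with γ_out, stably
across master seeds.

## Enrichment

The two-group term comparison uses the pooled two-proportion z statistic,
z = (p₁ − p₂)/√(p̂(1−p̂)(1/n₁ + 1/n₂)), with a two-sided normal p-value;
z² coincides with the 2×2 chi-square statistic without continuity
correction, which the tests assert to 10⁻⁹. A pooled proportion of exactly
0 or 1 has zero variance; that degenerate case returns (z, p) = (0, 1)
with a warning, since the groups then agree exactly. Percentages are
reported against the number of genes in each group carrying ≥ 1 annotation
(raw group sizes are carried alongside); p-values are unadjusted by
default, with an optional Benjamini–Hochberg column. Identifier mapping
across databases is out of scope — the annotation table is a local TSV.

## Module network

Modules collapse to single nodes; an arc i→j exists iff some network arc
runs from Vᵢ to Vⱼ (intra-module arcs are not represented), weighted by
the inter-module arc count (absolute) or by w/(nᵢnⱼ) (relative). The
appearance-ratio filter keeps the ⌈ratio·E⌉ heaviest arcs with a
deterministic (source, target) tie-break, making it idempotent and
monotone in the ratio. Path-based centralities use the unweighted directed
graph by default (weighted variants use distance = 1/weight): degree is
in+out, closeness is harmonic on outgoing shortest paths (finite under
disconnection), betweenness is the usual shortest-path fraction, stress
the raw shortest-path count. Eigenvector centrality is computed on the
symmetrized adjacency of the largest undirected component, where
Perron–Frobenius guarantees a unique nonnegative principal vector
(L2-normalized; modules outside the component get 0).

## What the synthetic tests do and do not show

The test networks are small random digraphs (≤ 10 nodes for exhaustive
dynamics, ≤ 8 for exhaustive partition enumeration, n = 30 for the batch)
with uniformly random AND/OR rules. They establish algorithmic
correctness — exact agreement with brute-force oracles, calibration of the
2N-state sampler, determinism under seeds and worker counts — and the
qualitative modularity–robustness trend in mixed random ensembles. They do
not establish anything about real signaling networks: biological degree
distributions, sign compositions, and rule classes (canalizing functions,
thresholds) differ from these nulls, and the 2N-state sample that is exact
at toy sizes is a coarse estimate at genome scale. Conclusions about a
specific network should be drawn by running the tool on that network with
several seeds and sample sizes.

## Known limitations

* Only pure conjunction/disjunction rules; no general Boolean functions,
  thresholds, or asynchronous/probabilistic updates.
* Perturbations are single-bit initial-state flips; knockouts and edge
  mutations are not modelled.
* The modularity search is a local heuristic; on large networks different
  seeds can return different partitions (the trial mean and best value
  quantify this spread).
* The exact composition of published random-ensemble studies is not
  recoverable; the replication ensemble here is a deliberately scaled-down
  stand-in that reproduces directions and significance, not magnitudes.
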