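# Methods

## Model

The input is an alignment instance: a target PPI network G_t with known
complexes, ξ ≥ 1 aligned networks G₁…G_ξ, and a symmetric set of
cross-network links (sequence-similar protein pairs, e.g. BLASTP hits at
e-value ≤ 1e-7). All graphs are treated as simple, undirected and
unweighted; protein identity is the pair (network id, protein id), so
identical strings in different networks are distinct proteins. For one
target complex M₀ the output is a matchset {M₁,…,M_ξ} with every
non-empty M_k inducing a connected subgraph of G_k.

### Vertex score

For a protein u ∈ M_k and a chosen third network G_h (h ≠ k) with
subnetwork M_h:

- b₁ — number of links from u into M₀;
- b₂ — number of links from u into M_h;
- b₃ — number of threads through u: pairs (v ∈ M₀, t ∈ M_h) with links
  (u,v), (u,t) and (v,t) all present;
- d — degree of u in the subgraph induced by M_k (induced, not in all of
  G_k: the component/degree values of the worked example are only
  consistent with the induced subgraph);
- c — size of the connected component of that induced subgraph
  containing u.

The biological and topological terms are b₁^{1/λ}+b₂^{1/λ}+b₃^{1/λ} and
d^{1/ω}+c^{1/ω}; the combined score is their α/(1−α) convex combination.
0^{1/λ} and 0^{1/ω} are defined as 0 (continuity at the origin). The
objective Φ sums combined scores over all selected proteins of all
networks.

### Aggregation over third networks

The per-vertex biological term depends on which third network G_h is
consulted, but the objective has no h index. We define the per-vertex
biological term as the **mean** over all h ≠ k with a non-empty M_h
(`h_mode="sum"` is available). The mean keeps Φ comparable across
different numbers of networks and symmetric in the aligned networks; a
sum would grow with ξ for otherwise identical alignments. With ξ = 1 no
third network exists and b₂ = b₃ = 0 by definition, which keeps pairwise
alignment usable. Networks whose candidate pool is empty are excluded
both as k and as h.

## Search

Candidate pools contain, per aligned network, every protein with at
least one link into M₀; the search never leaves the pools, which both
bounds the space and guarantees each returned protein has cross-species
evidence. Subnetwork size is fixed at min(|M₀|, |pool|) so coverage is
comparable across complexes and methods; `size_slack` > 0 enables
occasional pure insertions/deletions that let the size drift by ± that
amount.

Each proposal picks a network uniformly among those with an alternative
candidate, removes a zero-degree protein if one exists (connectivity is a
hard output constraint, so disconnected vertices are evicted first) or
else the protein with the lowest current combined score — ties broken
uniformly — and inserts a uniformly drawn pool protein not currently
selected. Φ is recomputed exactly over the full matchset for every
proposal (no sampled-h shortcut), and the move is accepted when ΔΦ > 0,
or with probability exp(ΔΦ/(sT)) otherwise; ΔΦ = 0 is always accepted.
The temperature follows a geometric schedule T_max, T_max/θ, T_max/θ², …
down to t_min, with N proposals per level and K independent restarts.
Moved-out proteins stay eligible (no tabu list).

Defaults: α = 0.5, λ = 4.5, ω = 3, θ = 1.1, T_max = 100, N = 100,
K = 20, s = 1, t_min = 0.1. The acceptance scale s is redundant with
T_max (any s > 0 can be absorbed into it) and defaults to 1. t_min = 0.1
gives 73 cooling levels at θ = 1.1; at that temperature a move costing
one combined-score unit is accepted with probability e^{−10}, i.e. the
chain is effectively greedy well before termination.

### Connectivity

Two mechanisms guarantee connected output. During the search the best
fully connected state ever visited is tracked alongside the overall best
state. At termination the overall best is repaired — each disconnected
M_k is cut to its component with the highest summed vertex score, then
greedily regrown with Φ-improving pool proteins adjacent to the kept
component, up to the original size — and the better (by Φ) of the
repaired state and the best connected state is returned. Tracking the
connected best in addition to repairing was adopted because repair alone
can land below the connected optimum when the unconstrained optimum
contains isolated high-link vertices.

### Determinism

All randomness flows from numpy `SeedSequence`s: one root seed, a
per-complex seed (root + complex index, so results are independent of
processing order), and per-restart spawned streams. Identical seeds give
bit-identical results; candidate lists are sorted before sampling so the
iteration order of sets never leaks into the output.

## Evaluation metrics

E(M) = −Σᵢ pᵢ ln pᵢ with pᵢ the fraction of annotated matchset proteins
(pooled across all networks, target complex included by default)
carrying GO term i, over the d distinct terms present. The pᵢ are
fractions of proteins, not a distribution — a multi-annotated protein
counts toward several terms — and the formula is applied literally, so
E(M) may exceed ln d; this matches how entropies of richly annotated
matchsets become large. NE(M) = E(M)/ln d for d ≥ 2 and is defined as 0
for d ≤ 1. Natural logarithms throughout (NE is base-invariant; the base
only rescales ME uniformly). Unannotated proteins carry no consistency
signal and are excluded from n but counted in the report; matchsets with
no annotated protein are excluded from the aggregates with a logged
count. ME is the plain mean of E(M); MNE is the size-weighted mean of
NE(M) (weight = total protein count of the matchset; an unweighted
variant is a flag). Coverage is the per-network mean |M_k|, with an
optional 100·ours/baseline ratio column; a baseline identical to the
evaluated run gives 100% everywhere, including the target network whose
complexes are shared by construction.

## Synthetic data

The generator plants disjoint ancestral complexes (default 5, sizes 4–6)
into every network of an instance (default 3 networks × 150 proteins).
Each member survives per species with probability 1 − dropout (default
dropout 0.1); survivors are wired with within-complex density 0.8 plus a
random spanning tree (so every planted complex is connected), over an
Erdős–Rényi background at 0.01 (a preferential-attachment variant exists
for robustness checks, but ER gives closed-form edge-count checks and
degree realism is not needed for correctness testing). Counterpart
members share their protein id across networks; they are linked with
probability 0.9 with log-uniform e-values in [1e-50, 1e-10], and any
random cross-network pair gains a spurious link with probability 0.005
(e-values in [1e-30, 1e-8], all below the 1e-7 cutoff). Complex members
share 3 GO terms, each replaced by a random decoy with probability 0.05;
background proteins carry 1–3 terms from a separate background
vocabulary so GAF files are realistically non-empty. Instances are
written through the package's own writers (edge lists, BLAST tabular,
complexes TSV, GAF), so the readers are exercised end to end.

What the generator does **not** emulate: realistic degree distributions
(unless the power-law flag is used), correlated/within-network paralogy,
many-to-many ortholog families, evidence-code structure in GAF files, or
incomplete annotation coverage. Passing tests therefore demonstrate
correctness of the algorithmic machinery under the stated noise model,
not performance on real interactomes.

Under the default noise rates the candidate pool itself bounds recall:
a planted member is selectable only if at least one of its links into
the surviving target complex exists, which happens with probability
≈ 0.9 (counterpart survival) × 0.9 (link) ≈ 0.81 plus a small spurious
rescue term. The measured pool ceiling is ≈ 0.82 and the annealer
recovers ≈ 0.81, i.e. the search is essentially exhausting the
information the links provide.

## Problem sizes used in the test suite

The exhaustive-optimum suite runs 20 random instances of 8 proteins per
network (two aligned networks, complexes of size 3) where all
combinations of connected candidate subnetworks can be enumerated, with
full default annealing parameters. The invariant suite checks
connectivity and pool membership over 100 annealing runs on 40-protein
instances with a shortened schedule (K = 2, N = 30, t_min = 1) — the
invariants are structural and hold for any schedule. The planted-recovery
suite uses the generator defaults over 20 seeds with K = 5, N = 50; the
landscape there (pools of ~8 candidates) is easy enough that additional
restarts do not change the recovered sets, as the pool-ceiling comparison
above shows.

## Known limitations

- Per-proposal Φ recomputation is exact but O(total selected proteins ×
  ξ); incremental scoring would be needed for interactome-scale
  networks with large complexes.
- One-to-one counterpart structure is assumed by the generator, not by
  the algorithm; evaluation on paralog-rich families is untested.
- The entropy metrics ignore the GO DAG: no term propagation or semantic
  similarity, so annotation granularity differences read as
  inconsistency.
- With `size_slack` = 0 the subnetwork size is tied to |M₀| even when a
  larger well-supported module exists in an aligned network.
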