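"""Vertex scores and the alignment objective Φ.

Each selected protein u in an aligned subnetwork M_k is scored by a convex
combination of a biological and a topological term,

    score(u) = α · δ_bio(u) + (1 − α) · δ_topo(u),

where, for a chosen third network G_h (h ≠ k) with subnetwork M_h,

    δ_bio(u)  = b1^(1/λ) + b2^(1/λ) + b3^(1/λ)
    δ_topo(u) = d^(1/ω)  + c^(1/ω)

with b1 the number of links from u into the target complex M_0, b2 the
number of links into M_h, b3 the number of threads (protein triples
pairwise connected by links) through u, M_0 and M_h, d the degree of u in
the subgraph induced by M_k, and c the size of the maximal connected
component of that subgraph containing u.  The concave 1/λ and 1/ω roots
damp any single count from dominating.  The objective Φ sums score(u) over
all selected proteins of all aligned networks; the third-network terms are
aggregated over the available choices of h (mean by default).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable

from .core import AlignmentInstance, LinkSet, MatchSet, ProteinKey

#: a subnetwork as (network_id, protein set)
Subnetwork = tuple[str, Collection[str]]


@dataclass(frozen=True)
class ScoreParams:
    """Tunables of the objective.

    alpha ∈ [0, 1] trades the biological against the topological term;
    lam > 1 and omega > 1 are the root transforms applied to the raw
    biological and topological counts.
    """

    alpha: float = 0.5
    lam: float = 4.5
    omega: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.lam <= 1.0:
            raise ValueError(f"lam must be > 1, got {self.lam}")
        if self.omega <= 1.0:
            raise ValueError(f"omega must be > 1, got {self.omega}")


@dataclass(frozen=True)
class VertexScoreBreakdown:
    """All score components of one selected protein."""

    bio1: int
    bio2: int
    bio3: int
    topo1: int
    topo2: int
    bio: float
    topo: float
    combined: float


def _root(x: float, exponent: float) -> float:
    # 0^(1/p) is defined as 0 (continuity of x^(1/p) at the origin)
    return 0.0 if x == 0 else float(x) ** exponent


def bio_score(bio1: int, bio2: int, bio3: int, lam: float) -> float:
    """δ_bio: sum of the three link/thread counts under the 1/λ root."""
    if lam <= 1.0:
        raise ValueError(f"lam must be > 1, got {lam}")
    if min(bio1, bio2, bio3) < 0:
        raise ValueError("biological counts must be non-negative")
    inv = 1.0 / lam
    return _root(bio1, inv) + _root(bio2, inv) + _root(bio3, inv)


def topo_score(topo1: int, topo2: int, omega: float) -> float:
    """δ_topo: degree and component size under the 1/ω root."""
    if omega <= 1.0:
        raise ValueError(f"omega must be > 1, got {omega}")
    if min(topo1, topo2) < 0:
        raise ValueError("topological counts must be non-negative")
    inv = 1.0 / omega
    return _root(topo1, inv) + _root(topo2, inv)


def count_links_to(
    links: LinkSet,
    u: ProteinKey,
    target_network: str,
    target_set: Collection[str],
) -> int:
    """Number of proteins in *target_set* (within *target_network*) linked to u."""
    if target_network == u[0]:
        raise ValueError(
            f"target set must lie in a different network than {u!r}"
        )
    return len(links.partners(u, target_network) & set(target_set))


def count_threads(
    links: LinkSet,
    u: ProteinKey,
    target_network: str,
    m0: Collection[str],
    third_network: str,
    mh: Collection[str],
) -> int:
    """Number of threads (u, v ∈ M_0, t ∈ M_h) with all three links present."""
    if len({u[0], target_network, third_network}) != 3:
        raise ValueError(
            "thread counting needs three pairwise distinct networks, got "
            f"{u[0]!r}, {target_network!r}, {third_network!r}"
        )
    linked_m0 = links.partners(u, target_network) & set(m0)
    linked_mh = links.partners(u, third_network) & set(mh)
    if not linked_m0 or not linked_mh:
        return 0
    total = 0
    for v in linked_m0:
        total += len(
            links.partners((target_network, v), third_network) & linked_mh
        )
    return total


def _induced_degree_and_component(
    instance: AlignmentInstance, net_id: str, members: set[str], u: str
) -> tuple[int, int]:
    """Degree of u and size of its component, both in the induced subgraph."""
    graph = instance.network(net_id).graph
    nbrs = {v: set(graph.neighbors(v)) & members for v in members}
    # BFS from u over the induced adjacency
    comp = {u}
    stack = [u]
    while stack:
        v = stack.pop()
        for w in nbrs[v]:
            if w not in comp:
                comp.add(w)
                stack.append(w)
    return len(nbrs[u]), len(comp)


def vertex_score(
    u: ProteinKey,
    m0: Collection[str],
    mk: Subnetwork,
    mh: Subnetwork | None,
    instance: AlignmentInstance,
    params: ScoreParams,
) -> VertexScoreBreakdown:
    """Full score breakdown of one protein for one choice of third network.

    ``mh=None`` covers the pairwise case (a single aligned network): no
    thread or third-network term exists, so b2 = b3 = 0.
    """
    k_id, mk_members = mk[0], set(mk[1])
    if u[0] != k_id:
        raise ValueError(f"protein {u!r} does not belong to network {k_id!r}")
    if u[1] not in mk_members:
        raise ValueError(f"protein {u!r} is not a member of the subnetwork")
    unknown = mk_members - instance.network(k_id).proteins
    if unknown:
        raise ValueError(
            f"unknown protein(s) {sorted(unknown)!r} in network {k_id!r}"
        )
    t_id = instance.target.network_id
    bio1 = count_links_to(instance.links, u, t_id, m0)
    if mh is None:
        bio2 = bio3 = 0
    else:
        h_id, mh_members = mh[0], set(mh[1])
        bio2 = count_links_to(instance.links, u, h_id, mh_members)
        bio3 = count_threads(instance.links, u, t_id, m0, h_id, mh_members)
    topo1, topo2 = _induced_degree_and_component(
        instance, k_id, mk_members, u[1]
    )
    bio = bio_score(bio1, bio2, bio3, params.lam)
    topo = topo_score(topo1, topo2, params.omega)
    combined = params.alpha * bio + (1.0 - params.alpha) * topo
    return VertexScoreBreakdown(
        bio1=bio1,
        bio2=bio2,
        bio3=bio3,
        topo1=topo1,
        topo2=topo2,
        bio=bio,
        topo=topo,
        combined=combined,
    )


def total_score(
    m0: Collection[str],
    matchset: MatchSet,
    instance: AlignmentInstance,
    params: ScoreParams,
    h_mode: str = "mean",
) -> float:
    """The alignment objective Φ for a complete matchset.

    For each aligned network k and each selected protein, the biological
    term is aggregated over every available third network h ≠ k with a
    non-empty subnetwork (``h_mode``: "mean", the default, keeps Φ
    comparable across numbers of networks; "sum" adds the contributions).
    The topological term does not depend on h.
    """
    if h_mode not in ("mean", "sum"):
        raise ValueError(f"h_mode must be 'mean' or 'sum', got {h_mode!r}")
    phi = 0.0
    subnets = matchset.subnetworks
    for k_id, members in subnets.items():
        if not members:
            continue
        others = [
            (h_id, hm)
            for h_id, hm in subnets.items()
            if h_id != k_id and hm
        ]
        for p in members:
            u = (k_id, p)
            if not others:
                bd = vertex_score(u, m0, (k_id, members), None, instance, params)
                phi += bd.combined
                continue
            combined = [
                vertex_score(
                    u, m0, (k_id, members), (h_id, hm), instance, params
                ).combined
                for h_id, hm in others
            ]
            if h_mode == "mean":
                phi += sum(combined) / len(combined)
            else:
                phi += sum(combined)
    return phi


def per_vertex_scores(
    m0: Collection[str],
    matchset: MatchSet,
    instance: AlignmentInstance,
    params: ScoreParams,
    h_mode: str = "mean",
) -> dict[ProteinKey, float]:
    """h-aggregated combined score of every selected protein."""
    out: dict[ProteinKey, float] = {}
    subnets = matchset.subnetworks
    for k_id, members in subnets.items():
        others = [
            (h_id, hm)
            for h_id, hm in subnets.items()
            if h_id != k_id and hm
        ]
        for p in members:
            u = (k_id, p)
            if not others:
                out[u] = vertex_score(
                    u, m0, (k_id, members), None, instance, params
                ).combined
                continue
            vals = [
                vertex_score(
                    u, m0, (k_id, members), (h_id, hm), instance, params
                ).combined
                for h_id, hm in others
            ]
            out[u] = sum(vals) / len(vals) if h_mode == "mean" else sum(vals)
    return out
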