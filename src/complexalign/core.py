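"""Graph and alignment-instance data model.

Proteins are identified by a ``(network_id, protein_id)`` pair: the same
string in two networks denotes two distinct proteins, since species-specific
identifier schemes may collide.  All graphs are simple (no self-loops, no
parallel edges), undirected and unweighted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

#: A protein is addressed by the network it lives in plus its local id.
ProteinKey = tuple[str, str]


class PPINetwork:
    """One species' protein-protein interaction network.

    Parameters
    ----------
    network_id:
        Label for the network (typically a species tag).
    edges:
        Iterable of ``(u, v)`` protein-id pairs.  Self-loops are dropped
        with a warning; duplicate and reversed duplicates are merged.
    proteins:
        Extra proteins to include even if they have no interactions.
    """

    def __init__(
        self,
        network_id: str,
        edges: Iterable[tuple[str, str]] = (),
        proteins: Iterable[str] = (),
    ) -> None:
        self.network_id = str(network_id)
        g = nx.Graph()
        g.add_nodes_from(proteins)
        n_loops = 0
        for u, v in edges:
            if u == v:
                n_loops += 1
                g.add_node(u)
                continue
            g.add_edge(u, v)
        if n_loops:
            logger.warning(
                "network %s: dropped %d self-loop(s)", self.network_id, n_loops
            )
        self._graph = g

    # -- basic accessors -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def proteins(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def interactions(self) -> set[tuple[str, str]]:
        """Edge set with each unordered pair reported once, sorted."""
        return {tuple(sorted((u, v))) for u, v in self._graph.edges}

    @property
    def n_proteins(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_interactions(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, protein: str) -> bool:
        return protein in self._graph

    def neighbors(self, protein: str) -> set[str]:
        if protein not in self._graph:
            raise ValueError(
                f"unknown protein {protein!r} in network {self.network_id!r}"
            )
        return set(self._graph.neighbors(protein))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PPINetwork({self.network_id!r}, |V|={self.n_proteins}, "
            f"|E|={self.n_interactions})"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return (
            self.network_id == other.network_id
            and self.proteins == other.proteins
            and self.interactions == other.interactions
        )


def induced_subgraph(net: PPINetwork, vertices: Iterable[str]) -> PPINetwork:
    """Subgraph of *net* on *vertices* with exactly the edges inside it."""
    vset = set(vertices)
    unknown = vset - net.proteins
    if unknown:
        raise ValueError(
            f"unknown protein(s) {sorted(unknown)!r} in network "
            f"{net.network_id!r}"
        )
    sub = net.graph.subgraph(vset)
    return PPINetwork(net.network_id, edges=sub.edges, proteins=vset)


def connected_components(net: PPINetwork) -> list[set[str]]:
    """Maximal connected vertex sets, sorted by their smallest member id."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: min(c))
    return comps


def degree_in(net: PPINetwork, u: str) -> int:
    """Number of interaction partners of *u* within *net*."""
    if u not in net.graph:
        raise ValueError(f"unknown protein {u!r} in network {net.network_id!r}")
    return net.graph.degree[u]


@dataclass(frozen=True)
class Link:
    """A cross-network sequence-similarity pair.

    Endpoints always belong to different networks; a link is symmetric,
    i.e. ``Link(a, b)`` equals ``Link(b, a)`` once normalized by
    :class:`LinkSet`.
    """

    a: ProteinKey
    b: ProteinKey
    evalue: float = 0.0


class LinkSet:
    """Collection of links with O(1)-amortized partner lookup.

    For each protein key the set keeps, per other network, the set of its
    link partners there.  Duplicate links (in either orientation) are merged
    keeping the smallest e-value.
    """

    def __init__(self, links: Iterable[Link | tuple] = ()) -> None:
        self._evalue: dict[tuple[ProteinKey, ProteinKey], float] = {}
        self._index: dict[ProteinKey, dict[str, set[str]]] = {}
        for lk in links:
            if isinstance(lk, Link):
                self.add(lk.a, lk.b, lk.evalue)
            else:
                self.add(*lk)

    @staticmethod
    def _norm(a: ProteinKey, b: ProteinKey) -> tuple[ProteinKey, ProteinKey]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: ProteinKey, b: ProteinKey, evalue: float = 0.0) -> None:
        a = (str(a[0]), str(a[1]))
        b = (str(b[0]), str(b[1]))
        if a[0] == b[0]:
            raise ValueError(
                f"link endpoints must lie in different networks, got {a} - {b}"
            )
        if evalue < 0:
            raise ValueError(f"negative e-value {evalue!r}")
        key = self._norm(a, b)
        prev = self._evalue.get(key)
        if prev is None or evalue < prev:
            self._evalue[key] = float(evalue)
        self._index.setdefault(a, {}).setdefault(b[0], set()).add(b[1])
        self._index.setdefault(b, {}).setdefault(a[0], set()).add(a[1])

    def partners(self, u: ProteinKey, other_network: str) -> set[str]:
        """All link partners of *u* inside *other_network*."""
        return set(self._index.get(u, {}).get(other_network, ()))

    def partner_index(self, u: ProteinKey) -> dict[str, set[str]]:
        """Partner sets of *u* keyed by network (live view, do not mutate)."""
        return self._index.get(u, {})

    def has_link(self, a: ProteinKey, b: ProteinKey) -> bool:
        return self._norm(a, b) in self._evalue

    def evalue(self, a: ProteinKey, b: ProteinKey) -> float:
        return self._evalue[self._norm(a, b)]

    def __len__(self) -> int:
        return len(self._evalue)

    def __iter__(self) -> Iterator[Link]:
        for (a, b), ev in sorted(self._evalue.items()):
            yield Link(a, b, ev)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinkSet):
            return NotImplemented
        return self._evalue == other._evalue

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LinkSet(n={len(self)})"


@dataclass
class AlignmentInstance:
    """The alignment problem input.

    ``target`` carries the known complexes; ``aligned`` is the ordered list
    of networks in which counterpart subnetworks are sought; ``links`` holds
    every cross-network similarity pair (between any two of the networks,
    target included); ``complexes`` is the ordered list of
    ``(complex_id, member set)`` seeds, each a subset of the target's
    proteins.
    """

    target: PPINetwork
    aligned: list[PPINetwork]
    links: LinkSet
    complexes: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.aligned) < 1:
            raise ValueError("at least one aligned network is required")
        ids = [self.target.network_id] + [n.network_id for n in self.aligned]
        if len(set(ids)) != len(ids):
            raise ValueError(f"network ids must be distinct, got {ids}")
        self.complexes = [
            (str(cid), frozenset(members)) for cid, members in self.complexes
        ]
        for cid, members in self.complexes:
            missing = members - self.target.proteins
            if missing:
                raise ValueError(
                    f"complex {cid!r} contains unknown target protein(s) "
                    f"{sorted(missing)!r}"
                )

    @property
    def xi(self) -> int:
        """Number of aligned networks."""
        return len(self.aligned)

    @property
    def aligned_ids(self) -> list[str]:
        return [n.network_id for n in self.aligned]

    def network(self, network_id: str) -> PPINetwork:
        if network_id == self.target.network_id:
            return self.target
        for net in self.aligned:
            if net.network_id == network_id:
                return net
        raise KeyError(f"unknown network {network_id!r}")


@dataclass
class MatchSet:
    """Alignment output for one target complex.

    ``subnetworks`` maps each aligned network id to the selected protein
    set there (possibly empty when no candidate existed).  On final output
    every non-empty set induces a connected subgraph in its network.
    """

    complex_id: str
    subnetworks: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.subnetworks = {
            str(k): frozenset(v) for k, v in self.subnetworks.items()
        }

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.subnetworks.items()}

    @property
    def total_size(self) -> int:
        return sum(len(v) for v in self.subnetworks.values())

    def validate(self, instance: AlignmentInstance) -> None:
        """Raise if any selected protein is unknown to its network."""
        for net_id, members in self.subnetworks.items():
            net = instance.network(net_id)
            missing = set(members) - net.proteins
            if missing:
                raise ValueError(
                    f"matchset {self.complex_id!r}: protein(s) "
                    f"{sorted(missing)!r} not in network {net_id!r}"
                )
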