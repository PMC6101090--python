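"""Synthetic multi-species PPI instances with planted conserved complexes.

The generator emulates the structure the alignment method assumes: a set
of networks sharing ancestral protein complexes whose members are densely
interacting and connected within each species, with cross-species
sequence-similarity links concentrated on orthologous counterparts, plus
Erdős–Rényi background interactions, spurious links, and shared GO labels
per complex.  Counterpart proteins carry the same protein id in every
network (the ortholog map is the shared-name identity).

All randomness flows from a single seed, so instances are reproducible
bit for bit.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .core import AlignmentInstance, LinkSet, MatchSet, PPINetwork
from .io_formats import (
    GOAnnotationMap,
    write_blast_links,
    write_complexes,
    write_edge_list,
    write_gaf,
    write_protein_list,
)

logger = logging.getLogger(__name__)


@dataclass
class SimParams:
    """Generator settings.

    ``n_networks`` counts the target plus the aligned networks.  Complex
    members survive in each species with probability 1 − dropout_prob;
    within-complex edges are drawn at complex_edge_prob (a random spanning
    tree guarantees connectivity) against an Erdős–Rényi background at
    background_edge_prob.  Ortholog counterparts are linked with
    probability link_true_rate; any random cross-network pair gains a
    spurious link with probability link_false_rate.  Members of a complex
    share go_terms_per_complex GO terms, each replaced by a random decoy
    with probability go_noise_rate.
    """

    n_networks: int = 3
    proteins_per_network: int = 150
    background_edge_prob: float = 0.01
    n_complexes: int = 5
    complex_size_range: tuple[int, int] = (4, 6)
    complex_edge_prob: float = 0.8
    dropout_prob: float = 0.1
    link_true_rate: float = 0.9
    link_false_rate: float = 0.005
    go_terms_per_complex: int = 3
    go_noise_rate: float = 0.05
    degree_model: str = "er"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 2:
            raise ValueError("need at least a target and one aligned network")
        lo, hi = self.complex_size_range
        if not 2 <= lo <= hi:
            raise ValueError(
                f"invalid complex size range {self.complex_size_range}"
            )
        if hi > self.proteins_per_network:
            raise ValueError(
                "complex size exceeds the number of proteins per network"
            )
        if hi * self.n_complexes > self.proteins_per_network:
            raise ValueError(
                "complexes (kept disjoint) do not fit in the network"
            )
        for name in (
            "background_edge_prob",
            "complex_edge_prob",
            "dropout_prob",
            "link_true_rate",
            "link_false_rate",
            "go_noise_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.complex_edge_prob <= self.background_edge_prob:
            raise ValueError(
                "complex_edge_prob must exceed background_edge_prob"
            )
        if self.degree_model not in ("er", "powerlaw"):
            raise ValueError(f"unknown degree model {self.degree_model!r}")


@dataclass
class GroundTruth:
    """Planted structure of a generated instance.

    ``complexes[cid][net_id]`` is the surviving member set of a complex in
    one network; ``ancestral[cid]`` the full ancestral member list;
    ``go_terms[cid]`` the terms shared by its members.  Orthologous
    counterparts share their protein id across networks.
    """

    complexes: dict[str, dict[str, frozenset[str]]]
    ancestral: dict[str, tuple[str, ...]]
    go_terms: dict[str, frozenset[str]] = field(default_factory=dict)

    def planted(self, complex_id: str, net_id: str) -> frozenset[str]:
        if complex_id not in self.complexes:
            raise KeyError(f"unknown complex {complex_id!r}")
        return self.complexes[complex_id].get(net_id, frozenset())


def _protein_name(i: int) -> str:
    return f"p{i:04d}"


def _random_tree_edges(
    members: list[str], rng: np.random.Generator
) -> list[tuple[str, str]]:
    order = [members[i] for i in rng.permutation(len(members))]
    return [
        (order[i], order[int(rng.integers(i))]) for i in range(1, len(order))
    ]


def generate_instance(
    params: SimParams,
) -> tuple[AlignmentInstance, GOAnnotationMap, GroundTruth]:
    """Build one instance with its annotations and ground truth."""
    rng = np.random.default_rng(params.seed)
    n = params.proteins_per_network
    net_ids = [f"net{i}" for i in range(params.n_networks)]
    target_id = net_ids[0]
    names = [_protein_name(i) for i in range(n)]

    # --- ancestral complexes: disjoint member index sets -----------------
    lo, hi = params.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=params.n_complexes)
    member_idx = rng.choice(n, size=int(sizes.sum()), replace=False)
    complexes_anc: dict[str, tuple[str, ...]] = {}
    owner: dict[int, str] = {}
    pos = 0
    for c, size in enumerate(sizes):
        cid = f"C{c}"
        idx = sorted(int(i) for i in member_idx[pos : pos + size])
        pos += size
        complexes_anc[cid] = tuple(names[i] for i in idx)
        for i in idx:
            owner[i] = cid

    # --- per-network survival (dropout) ----------------------------------
    surviving: dict[str, dict[str, list[str]]] = {}
    for net_id in net_ids:
        surviving[net_id] = {}
        for cid, members in complexes_anc.items():
            mask = rng.random(len(members)) >= params.dropout_prob
            surviving[net_id][cid] = [
                m for m, keep in zip(members, mask) if keep
            ]

    # --- edges ------------------------------------------------------------
    networks: dict[str, PPINetwork] = {}
    iu, ju = np.triu_indices(n, k=1)
    for net_id in net_ids:
        edges: set[tuple[str, str]] = set()
        for cid, members in surviving[net_id].items():
            if len(members) >= 2:
                for e in _random_tree_edges(members, rng):
                    edges.add(tuple(sorted(e)))
                for a in range(len(members)):
                    for b in range(a + 1, len(members)):
                        if rng.random() < params.complex_edge_prob:
                            edges.add(tuple(sorted((members[a], members[b]))))
        if params.degree_model == "er":
            mask = rng.random(len(iu)) < params.background_edge_prob
            for a, b in zip(iu[mask], ju[mask]):
                if owner.get(int(a)) is not None and owner.get(int(a)) == owner.get(int(b)):
                    continue  # within-complex pairs are governed above
                edges.add((names[int(a)], names[int(b)]))
        else:
            m = max(1, round(params.background_edge_prob * (n - 1) / 2))
            edges |= _preferential_edges(names, m, owner, rng)
        networks[net_id] = PPINetwork(net_id, edges=edges, proteins=names)

    # --- links ------------------------------------------------------------
    links = LinkSet()
    for ai in range(len(net_ids)):
        for bi in range(ai + 1, len(net_ids)):
            a_id, b_id = net_ids[ai], net_ids[bi]
            present_a = {
                m for ms in surviving[a_id].values() for m in ms
            }
            present_b = {
                m for ms in surviving[b_id].values() for m in ms
            }
            for cid, members in complexes_anc.items():
                for m in members:
                    if (
                        m in present_a
                        and m in present_b
                        and rng.random() < params.link_true_rate
                    ):
                        ev = 10.0 ** rng.uniform(-50.0, -10.0)
                        links.add((a_id, m), (b_id, m), ev)
            if params.link_false_rate > 0:
                mask = rng.random((n, n)) < params.link_false_rate
                for a, b in np.argwhere(mask):
                    ka, kb = (a_id, names[int(a)]), (b_id, names[int(b)])
                    if not links.has_link(ka, kb):
                        ev = 10.0 ** rng.uniform(-30.0, -8.0)
                        links.add(ka, kb, ev)

    # --- GO labels ---------------------------------------------------------
    annotations = GOAnnotationMap(aspect="all")
    go_terms: dict[str, frozenset[str]] = {}
    term_no = 1
    for cid in complexes_anc:
        terms = frozenset(
            f"GO:{term_no + j:07d}" for j in range(params.go_terms_per_complex)
        )
        term_no += params.go_terms_per_complex
        go_terms[cid] = terms
    background_pool = [f"GO:08{j:05d}" for j in range(30)]
    decoy_pool = [f"GO:09{j:05d}" for j in range(99999)]
    for net_id in net_ids:
        members_here = {
            m: cid for cid, ms in surviving[net_id].items() for m in ms
        }
        for name in names:
            key = (net_id, name)
            cid = members_here.get(name)
            if cid is not None:
                for term in sorted(go_terms[cid]):
                    if rng.random() < params.go_noise_rate:
                        term = decoy_pool[int(rng.integers(len(decoy_pool)))]
                    annotations.add(key, term)
            else:
                k = int(rng.integers(1, 4))
                for j in rng.choice(len(background_pool), size=k, replace=False):
                    annotations.add(key, background_pool[int(j)])

    # --- assemble ----------------------------------------------------------
    target_complexes = []
    truth_complexes: dict[str, dict[str, frozenset[str]]] = {}
    for cid in complexes_anc:
        truth_complexes[cid] = {
            net_id: frozenset(surviving[net_id][cid]) for net_id in net_ids
        }
        target_members = frozenset(surviving[target_id][cid])
        if len(target_members) >= 2:
            target_complexes.append((cid, target_members))
        else:
            logger.info(
                "complex %s dropped below 2 target members; not seeded", cid
            )
    instance = AlignmentInstance(
        target=networks[target_id],
        aligned=[networks[i] for i in net_ids[1:]],
        links=links,
        complexes=target_complexes,
    )
    truth = GroundTruth(
        complexes=truth_complexes,
        ancestral=complexes_anc,
        go_terms=go_terms,
    )
    return instance, annotations, truth


def _preferential_edges(
    names: list[str],
    m: int,
    owner: dict[int, str],
    rng: np.random.Generator,
) -> set[tuple[str, str]]:
    """Barabási–Albert-style background for the power-law variant."""
    import networkx as nx

    g = nx.barabasi_albert_graph(len(names), m, seed=int(rng.integers(2**31)))
    out = set()
    for a, b in g.edges:
        if owner.get(a) is not None and owner.get(a) == owner.get(b):
            continue
        out.add(tuple(sorted((names[a], names[b]))))
    return out


def recovery_metrics(
    result: MatchSet, truth: GroundTruth, complex_id: str
) -> dict[str, dict[str, float | None]]:
    """Per-network precision/recall of a matchset against the planted sets.

    Recall is ``None`` for a network where the planted set is empty (full
    dropout); precision is ``None`` for an empty returned subnetwork.
    """
    if complex_id not in truth.complexes:
        raise KeyError(f"unknown complex {complex_id!r}")
    out: dict[str, dict[str, float | None]] = {}
    for net_id, members in result.subnetworks.items():
        planted = truth.planted(complex_id, net_id)
        inter = len(set(members) & planted)
        out[net_id] = {
            "precision": inter / len(members) if members else None,
            "recall": inter / len(planted) if planted else None,
        }
    return out


def write_instance(
    out_dir: str | Path,
    instance: AlignmentInstance,
    annotations: GOAnnotationMap,
    truth: GroundTruth,
    params: SimParams | None = None,
) -> Path:
    """Write an instance directory (edge lists, BLAST links, complexes,
    GAF files, ground truth) plus an ``instance.yaml`` manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nets = [instance.target, *instance.aligned]
    manifest: dict = {
        "target": instance.target.network_id,
        "networks": {},
        "proteins": {},
        "links": [],
        "complexes": "complexes.tsv",
        "gaf": {},
    }
    for net in nets:
        fn = f"{net.network_id}.edges.tsv"
        write_edge_list(net, out_dir / fn)
        manifest["networks"][net.network_id] = fn
        pfn = f"{net.network_id}.proteins.tsv"
        write_protein_list(net, out_dir / pfn)
        manifest["proteins"][net.network_id] = pfn
        gfn = f"{net.network_id}.gaf"
        write_gaf(annotations, net.network_id, out_dir / gfn)
        manifest["gaf"][net.network_id] = gfn
    ids = [net.network_id for net in nets]
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            fn = f"links.{ids[ai]}-{ids[bi]}.blast.tsv"
            write_blast_links(instance.links, ids[ai], ids[bi], out_dir / fn)
            manifest["links"].append({"a": ids[ai], "b": ids[bi], "path": fn})
    write_complexes(instance.complexes, out_dir / "complexes.tsv")
    truth_doc = {
        "complexes": {
            cid: {nid: sorted(m) for nid, m in nets_.items()}
            for cid, nets_ in truth.complexes.items()
        },
        "ancestral": {cid: list(m) for cid, m in truth.ancestral.items()},
        "go_terms": {cid: sorted(t) for cid, t in truth.go_terms.items()},
        "ortholog_convention": "shared-name",
    }
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth_doc, indent=1, sort_keys=True) + "\n"
    )
    if params is not None:
        doc = asdict(params)
        doc["complex_size_range"] = list(params.complex_size_range)
        (out_dir / "simparams.yaml").write_text(yaml.safe_dump(doc))
    (out_dir / "instance.yaml").write_text(yaml.safe_dump(manifest))
    return out_dir


def read_ground_truth(path: str | Path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    return GroundTruth(
        complexes={
            cid: {nid: frozenset(m) for nid, m in nets.items()}
            for cid, nets in doc["complexes"].items()
        },
        ancestral={cid: tuple(m) for cid, m in doc["ancestral"].items()},
        go_terms={cid: frozenset(t) for cid, t in doc["go_terms"].items()},
    )
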