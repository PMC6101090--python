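"""Readers and writers for the plain-text formats the tool consumes.

Edge lists are 2+ column whitespace/TSV files; cross-network similarity
comes as 12-column BLAST tabular output (outfmt 6) or as a 5-column link
table; complexes are one-per-line TSV; GO annotations are GAF 2.x.
Alignment results are written as JSON plus a TSV summary.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .core import (
    AlignmentInstance,
    LinkSet,
    MatchSet,
    PPINetwork,
    ProteinKey,
    connected_components,
    induced_subgraph,
)

logger = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: conventional BLAST homology-screen cutoff used throughout
DEFAULT_EVALUE_CUTOFF = 1e-7

_ASPECT_CODE = {"BP": "P", "MF": "F", "CC": "C"}


@dataclass
class GOAnnotationMap:
    """GO term sets per ``(network_id, protein_id)``.

    ``aspect`` records which ontology aspect the map was restricted to at
    read time ("BP", "MF", "CC" or "all").
    """

    terms: dict[ProteinKey, set[str]] = field(default_factory=dict)
    aspect: str = "all"

    def get(self, key: ProteinKey) -> set[str]:
        return self.terms.get(key, set())

    def add(self, key: ProteinKey, term: str) -> None:
        self.terms.setdefault(key, set()).add(term)

    def update(self, other: "GOAnnotationMap") -> None:
        for key, terms in other.terms.items():
            self.terms.setdefault(key, set()).update(terms)

    @property
    def n_proteins(self) -> int:
        return len(self.terms)

    def __len__(self) -> int:
        return len(self.terms)


def read_edge_list(path: str | Path, network_id: str) -> PPINetwork:
    """Read an undirected PPI edge list.

    Lines hold at least two whitespace-separated protein ids; ``#`` starts
    a comment.  Duplicate edges (in either orientation) are merged and
    self-loops dropped with a warning.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    n_data = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 fields, got "
                    f"{len(fields)}"
                )
            n_data += 1
            edges.append((fields[0], fields[1]))
    if n_data == 0:
        raise ValueError(f"{path}: no interactions found")
    net = PPINetwork(network_id, edges=edges)
    logger.info(
        "read %s: %d proteins, %d interactions (network %s)",
        path,
        net.n_proteins,
        net.n_interactions,
        network_id,
    )
    return net


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# network {net.network_id}\n")
        for u, v in sorted(net.interactions):
            fh.write(f"{u}\t{v}\n")


def write_protein_list(net: PPINetwork, path: str | Path) -> None:
    """One protein id per line; preserves interaction-free proteins, which
    a bare edge list cannot carry."""
    with Path(path).open("w") as fh:
        for p in sorted(net.proteins):
            fh.write(p + "\n")


def read_protein_list(path: str | Path) -> list[str]:
    out = []
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_blast_links(
    path: str | Path,
    net_a_id: str,
    net_b_id: str,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> LinkSet:
    """Parse 12-column BLAST tabular output into a link set.

    Query ids belong to ``net_a_id``, subject ids to ``net_b_id``.  For a
    (query, subject) pair with several HSP rows the minimum e-value is
    kept; pairs above the cutoff are discarded.
    """
    path = Path(path)
    best: dict[tuple[str, str], float] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 BLAST tabular columns, "
                    f"got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            try:
                ev = float(fields[10])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unparseable e-value {fields[10]!r}"
                ) from exc
            key = (q, s)
            if key not in best or ev < best[key]:
                best[key] = ev
    links = LinkSet()
    kept = 0
    for (q, s), ev in best.items():
        if ev <= evalue_cutoff:
            links.add((net_a_id, q), (net_b_id, s), ev)
            kept += 1
    logger.info(
        "read %s: %d hit pairs, %d below cutoff %.3g (%s vs %s)",
        path,
        len(best),
        kept,
        evalue_cutoff,
        net_a_id,
        net_b_id,
    )
    return links


def write_blast_links(
    links: LinkSet,
    net_a_id: str,
    net_b_id: str,
    path: str | Path,
) -> None:
    """Write the links between two networks as 12-column BLAST tabular rows.

    Only the query/subject ids and the e-value are meaningful; the other
    columns carry plausible placeholder alignment statistics.
    """
    path = Path(path)
    rows = []
    for link in links:
        ends = {link.a[0]: link.a[1], link.b[0]: link.b[1]}
        if set(ends) != {net_a_id, net_b_id}:
            continue
        rows.append((ends[net_a_id], ends[net_b_id], link.evalue))
    rows.sort()
    with path.open("w") as fh:
        for q, s, ev in rows:
            fh.write(
                f"{q}\t{s}\t50.0\t100\t50\t0\t1\t100\t1\t100\t"
                f"{ev:.6e}\t100.0\n"
            )


def read_link_table(
    path: str | Path, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> LinkSet:
    """Read a precomputed multi-pair link table.

    Columns: net_a, protein_a, net_b, protein_b[, evalue].  A missing
    e-value column is taken as 0 (always kept).
    """
    path = Path(path)
    links = LinkSet()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 4 fields"
                )
            ev = 0.0
            if len(fields) >= 5:
                try:
                    ev = float(fields[4])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: unparseable e-value {fields[4]!r}"
                    ) from exc
            if ev <= evalue_cutoff:
                links.add((fields[0], fields[1]), (fields[2], fields[3]), ev)
    return links


def read_complexes(
    path: str | Path, target_id: str | None = None
) -> list[tuple[str, frozenset[str]]]:
    """Read target complexes: complex_id followed by its member proteins.

    Complexes with fewer than two distinct members are skipped with a
    warning — a single protein carries no connectivity content.
    """
    path = Path(path)
    out: list[tuple[str, frozenset[str]]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            cid, members = fields[0], frozenset(fields[1:])
            if len(members) < 2:
                logger.warning(
                    "%s:%d: complex %r has %d distinct protein(s); skipped",
                    path,
                    lineno,
                    cid,
                    len(members),
                )
                continue
            out.append((cid, members))
    return out


def write_complexes(
    complexes: Iterable[tuple[str, frozenset[str]]], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        for cid, members in complexes:
            fh.write("\t".join([cid, *sorted(members)]) + "\n")


def read_gaf(
    path: str | Path, network_id: str, aspect_filter: str = "all"
) -> GOAnnotationMap:
    """Read GAF 2.x annotations for one network.

    ``aspect_filter`` is "BP", "MF", "CC" or "all".  Rows whose qualifier
    contains NOT are excluded; rows with a malformed GO id are skipped with
    a warning.
    """
    if aspect_filter not in ("all", *_ASPECT_CODE):
        raise ValueError(f"unknown aspect filter {aspect_filter!r}")
    want = None if aspect_filter == "all" else _ASPECT_CODE[aspect_filter]
    path = Path(path)
    out = GOAnnotationMap(aspect=aspect_filter)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("!"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                logger.warning("%s:%d: fewer than 9 columns; skipped", path, lineno)
                continue
            obj_id, qualifier, go_id, aspect = (
                fields[1],
                fields[3],
                fields[4],
                fields[8],
            )
            if "NOT" in qualifier.split("|"):
                continue
            if not GO_ID_RE.match(go_id):
                logger.warning(
                    "%s:%d: malformed GO id %r; skipped", path, lineno, go_id
                )
                continue
            if want is not None and aspect != want:
                continue
            out.add((network_id, obj_id), go_id)
    return out


def write_gaf(
    annotations: GOAnnotationMap,
    network_id: str,
    path: str | Path,
    aspects: Mapping[str, str] | None = None,
) -> None:
    """Write one network's annotations as minimal GAF 2.2 rows.

    ``aspects`` optionally maps GO ids to their aspect code (P/F/C);
    unmapped terms default to P.
    """
    aspects = aspects or {}
    with Path(path).open("w") as fh:
        fh.write("!gaf-version: 2.2\n")
        rows = [
            (prot, term)
            for (net, prot), terms in annotations.terms.items()
            if net == network_id
            for term in terms
        ]
        for prot, term in sorted(rows):
            asp = aspects.get(term, "P")
            cols = [
                "SYNT", prot, prot, "involved_in", term, "SYNT:ref",
                "IEA", "", asp, "", "", "protein", "taxon:0", "20200101",
                "SYNT", "", "",
            ]
            fh.write("\t".join(cols) + "\n")


def load_instance(
    instance_dir: str | Path,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    aspect_filter: str = "all",
) -> tuple[AlignmentInstance, GOAnnotationMap]:
    """Load a full alignment instance from an ``instance.yaml`` directory.

    The manifest (as written by the synthetic generator or by hand) names
    the target network, the per-network edge lists and GAF files, the
    per-pair BLAST link files, and the complex list.
    """
    import yaml

    instance_dir = Path(instance_dir)
    manifest_path = instance_dir / "instance.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    target_id = manifest["target"]
    networks = {}
    for net_id, fn in manifest["networks"].items():
        net = read_edge_list(instance_dir / fn, net_id)
        pfn = manifest.get("proteins", {}).get(net_id)
        if pfn:
            extra = read_protein_list(instance_dir / pfn)
            net = PPINetwork(
                net_id, edges=net.interactions, proteins=extra
            )
        networks[net_id] = net
    links = LinkSet()
    for entry in manifest.get("links", []):
        pair = read_blast_links(
            instance_dir / entry["path"], entry["a"], entry["b"], evalue_cutoff
        )
        for link in pair:
            links.add(link.a, link.b, link.evalue)
    complexes = read_complexes(instance_dir / manifest["complexes"], target_id)
    aligned_ids = [nid for nid in manifest["networks"] if nid != target_id]
    instance = AlignmentInstance(
        target=networks[target_id],
        aligned=[networks[nid] for nid in aligned_ids],
        links=links,
        complexes=complexes,
    )
    annotations = GOAnnotationMap(aspect=aspect_filter)
    for net_id, fn in manifest.get("gaf", {}).items():
        annotations.update(read_gaf(instance_dir / fn, net_id, aspect_filter))
    return instance, annotations


@dataclass
class MatchSetRecord:
    """One alignment result as stored on disk."""

    matchset: MatchSet
    phi: float
    target_proteins: frozenset[str]
    connected: dict[str, bool]


def write_matchsets(
    matchsets: Iterable[MatchSet],
    scores: Iterable[float],
    json_path: str | Path,
    instance: AlignmentInstance | None = None,
    tsv_path: str | Path | None = None,
) -> None:
    """Write alignment results as JSON (and optionally a TSV summary).

    When *instance* is given, per-network connectivity flags and the target
    complex membership are recorded alongside each matchset.
    """
    complexes = dict(instance.complexes) if instance is not None else {}
    entries = []
    for ms, phi in zip(matchsets, scores, strict=True):
        subnets = {}
        for net_id, members in ms.subnetworks.items():
            conn = None
            if instance is not None:
                sub = induced_subgraph(instance.network(net_id), members)
                conn = len(connected_components(sub)) <= 1
            subnets[net_id] = {
                "proteins": sorted(members),
                "connected": conn,
            }
        entries.append(
            {
                "complex_id": ms.complex_id,
                "phi": phi,
                "target_proteins": sorted(complexes.get(ms.complex_id, ())),
                "subnetworks": subnets,
            }
        )
    doc = {
        "format": "complexalign-matchsets",
        "version": 1,
        "target_network": instance.target.network_id if instance else None,
        "matchsets": entries,
    }
    json_path = Path(json_path)
    json_path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    if tsv_path is not None:
        with Path(tsv_path).open("w") as fh:
            fh.write("complex_id\tnetwork_id\tsize\tproteins\n")
            for entry in entries:
                for net_id, sub in entry["subnetworks"].items():
                    fh.write(
                        f"{entry['complex_id']}\t{net_id}\t"
                        f"{len(sub['proteins'])}\t"
                        f"{','.join(sub['proteins'])}\n"
                    )


def read_matchsets(
    json_path: str | Path,
) -> tuple[str | None, list[MatchSetRecord]]:
    """Read results written by :func:`write_matchsets`.

    Returns the target network id (if recorded) and the list of records.
    """
    doc = json.loads(Path(json_path).read_text())
    if doc.get("format") != "complexalign-matchsets":
        raise ValueError(f"{json_path}: not a matchset file")
    records = []
    for entry in doc["matchsets"]:
        ms = MatchSet(
            entry["complex_id"],
            {
                net_id: frozenset(sub["proteins"])
                for net_id, sub in entry["subnetworks"].items()
            },
        )
        records.append(
            MatchSetRecord(
                matchset=ms,
                phi=float(entry["phi"]),
                target_proteins=frozenset(entry.get("target_proteins", ())),
                connected={
                    net_id: sub.get("connected")
                    for net_id, sub in entry["subnetworks"].items()
                },
            )
        )
    return doc.get("target_network"), records
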