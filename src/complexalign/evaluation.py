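"""Coverage and GO-entropy consistency of alignment results.

A matchset's entropy is computed over the GO terms of its (annotated)
proteins pooled across all participating networks:

    E(M)  = − Σ_i p_i · ln p_i,        p_i = (# proteins carrying term i) / n
    NE(M) = E(M) / ln d,

with n the number of annotated proteins and d the number of distinct terms.
The p_i are fractions of proteins, not a probability distribution: a
protein carrying several terms contributes to several p_i, so E(M) can
exceed ln d.  The formula is applied literally rather than renormalized.
ME averages E(M) over matchsets; MNE is the size-weighted average of
NE(M).  Lower values mean more functionally coherent alignments.
Coverage is the per-network mean subnetwork size, optionally expressed as
a percentage of a baseline method's mean.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import MatchSet, ProteinKey
from .io_formats import GOAnnotationMap


@dataclass
class MatchsetConsistency:
    complex_id: str
    n_annotated: int
    n_unannotated: int
    n_terms: int
    entropy: float
    normalized_entropy: float
    size: int


@dataclass
class ConsistencyReport:
    entries: list[MatchsetConsistency]
    me: float
    mne: float
    n_excluded: int


@dataclass
class CoverageReport:
    """Per-network mean aligned-subnetwork size (proteins)."""

    mean_sizes: dict[str, float]
    n_matchsets: int
    ratios: dict[str, float] | None = None


def _term_fractions(
    proteins: Iterable[ProteinKey], annotations: GOAnnotationMap
) -> tuple[int, int, Counter]:
    annotated = 0
    unannotated = 0
    counts: Counter = Counter()
    for key in proteins:
        terms = annotations.get(key)
        if terms:
            annotated += 1
            counts.update(terms)
        else:
            unannotated += 1
    return annotated, unannotated, counts


def matchset_entropy(
    proteins: Iterable[ProteinKey], annotations: GOAnnotationMap
) -> float:
    """E(M) of a protein collection; natural logarithm.

    Raises ``ValueError`` when no protein carries any annotation (the
    metric is undefined there; callers exclude such matchsets and report
    the count).
    """
    n, _, counts = _term_fractions(proteins, annotations)
    if n == 0:
        raise ValueError("entropy undefined: no annotated proteins")
    ent = 0.0
    for c in counts.values():
        p = c / n
        ent -= p * math.log(p)
    return ent


def matchset_normalized_entropy(
    proteins: Iterable[ProteinKey], annotations: GOAnnotationMap
) -> float:
    """NE(M) = E(M)/ln d; 0 when d ≤ 1 (a single shared term is perfectly
    consistent).  Base-invariant."""
    prots = list(proteins)
    n, _, counts = _term_fractions(prots, annotations)
    if n == 0:
        raise ValueError("entropy undefined: no annotated proteins")
    d = len(counts)
    if d <= 1:
        return 0.0
    return matchset_entropy(prots, annotations) / math.log(d)


def mean_entropy(entropies: Sequence[float]) -> float:
    """ME: plain arithmetic mean over matchsets with a defined entropy."""
    if not entropies:
        raise ValueError("no matchset has a defined entropy")
    return sum(entropies) / len(entropies)


def mean_normalized_entropy(
    sized_values: Sequence[tuple[int, float]], weighted: bool = True
) -> float:
    """MNE: size-weighted mean of NE(M) (unweighted variant by flag)."""
    if not sized_values:
        raise ValueError("no matchset has a defined entropy")
    if not weighted:
        return sum(ne for _, ne in sized_values) / len(sized_values)
    total = sum(size for size, _ in sized_values)
    if total == 0:
        raise ValueError("all matchsets are empty")
    return sum(size * ne for size, ne in sized_values) / total


def matchset_proteins(
    matchset: MatchSet,
    target_network: str | None = None,
    target_proteins: Iterable[str] = (),
    include_target: bool = True,
) -> list[ProteinKey]:
    """All proteins of a matchset, optionally with the target complex."""
    out: list[ProteinKey] = [
        (net_id, p)
        for net_id, members in matchset.subnetworks.items()
        for p in sorted(members)
    ]
    if include_target and target_network is not None:
        out.extend((target_network, p) for p in sorted(target_proteins))
    return out


def consistency_report(
    matchsets: Sequence[MatchSet],
    annotations: GOAnnotationMap,
    target_network: str | None = None,
    target_sets: Mapping[str, frozenset[str]] | None = None,
    include_target: bool = True,
    weighted_mne: bool = True,
) -> ConsistencyReport:
    """ME/MNE over a collection of matchsets.

    ``target_sets`` maps complex ids to their target-network members; by
    default those proteins take part in the entropy, since a matchset is
    the set of complexes aligned to one target complex across all
    participating networks.
    """
    target_sets = target_sets or {}
    entries: list[MatchsetConsistency] = []
    excluded = 0
    for ms in matchsets:
        prots = matchset_proteins(
            ms,
            target_network=target_network,
            target_proteins=target_sets.get(ms.complex_id, ()),
            include_target=include_target,
        )
        n, n_un, counts = _term_fractions(prots, annotations)
        if n == 0:
            excluded += 1
            continue
        ent = matchset_entropy(prots, annotations)
        ne = matchset_normalized_entropy(prots, annotations)
        entries.append(
            MatchsetConsistency(
                complex_id=ms.complex_id,
                n_annotated=n,
                n_unannotated=n_un,
                n_terms=len(counts),
                entropy=ent,
                normalized_entropy=ne,
                size=len(prots),
            )
        )
    if not entries:
        raise ValueError("no matchset has any annotated protein")
    me = mean_entropy([e.entropy for e in entries])
    mne = mean_normalized_entropy(
        [(e.size, e.normalized_entropy) for e in entries], weighted=weighted_mne
    )
    return ConsistencyReport(entries=entries, me=me, mne=mne, n_excluded=excluded)


def coverage(
    matchsets: Sequence[MatchSet],
    baseline: "CoverageReport | Mapping[str, float] | None" = None,
    target_network: str | None = None,
    target_sets: Mapping[str, frozenset[str]] | None = None,
) -> CoverageReport:
    """Mean aligned-subnetwork size per network, with optional baseline ratio.

    The ratio is 100 × (our mean size / baseline mean size); when the
    target complexes are supplied, the target network appears as its own
    column (its ratio against an identical baseline is 100%).
    """
    sizes: dict[str, list[int]] = {}
    for ms in matchsets:
        for net_id, members in ms.subnetworks.items():
            sizes.setdefault(net_id, []).append(len(members))
        if target_network is not None and target_sets is not None:
            sizes.setdefault(target_network, []).append(
                len(target_sets.get(ms.complex_id, ()))
            )
    mean_sizes = {
        net_id: (sum(vals) / len(vals) if vals else 0.0)
        for net_id, vals in sorted(sizes.items())
    }
    ratios = None
    if baseline is not None:
        base = (
            baseline.mean_sizes
            if isinstance(baseline, CoverageReport)
            else dict(baseline)
        )
        ratios = {}
        for net_id, ours in mean_sizes.items():
            if net_id in base and base[net_id] > 0:
                ratios[net_id] = 100.0 * ours / base[net_id]
    return CoverageReport(
        mean_sizes=mean_sizes, n_matchsets=len(matchsets), ratios=ratios
    )
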