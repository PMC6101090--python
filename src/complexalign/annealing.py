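"""Simulated-annealing search for connected aligned subnetworks.

For one target complex M_0 the search space is, per aligned network, the
set of proteins having at least one similarity link into M_0 (the
candidate pool).  Starting from a random pool sample of size
min(|M_0|, |pool|) per network, each proposal removes one protein from a
randomly chosen network — preferring zero-degree proteins, else the
lowest-scoring one — inserts a random pool protein, and accepts the move
if Φ improves, or with probability exp(ΔΦ / (s·T)) otherwise.  The
temperature follows a geometric schedule T, T/θ, T/θ², … down to t_min,
with N proposals per level and K independent restarts.  Because subnetwork
connectivity is a hard output constraint, the best connected solution seen
is tracked alongside the overall best, and a repair step (keep the
strongest component, greedily re-add adjacent pool proteins) guarantees
connected output.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import AlignmentInstance, MatchSet
from .scoring import ScoreParams

logger = logging.getLogger(__name__)


class InfeasibleAlignmentError(ValueError):
    """No aligned network has any candidate for the given complex."""


@dataclass
class AnnealParams:
    """All tunables of the annealing search.

    s scales the temperature in the acceptance exponent (dimensionless,
    default 1 — any other value can be absorbed into t_max); t_max and
    t_min bound the geometric schedule with cooling factor theta > 1
    (temperature is divided by theta per level); n_iters proposals are made
    per level and k_restarts independent restarts are run.  size_slack > 0
    additionally allows pure insertions/deletions that let |M_k| drift by
    up to that many proteins around min(|M_0|, |pool|).
    """

    score: ScoreParams = field(default_factory=ScoreParams)
    s: float = 1.0
    t_max: float = 100.0
    t_min: float = 0.1
    theta: float = 1.1
    n_iters: int = 100
    k_restarts: int = 20
    size_slack: int = 0
    h_mode: str = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"s must be positive, got {self.s}")
        if self.theta <= 1.0:
            raise ValueError(f"theta must be > 1, got {self.theta}")
        if self.t_min <= 0 or self.t_max <= 0:
            raise ValueError("temperatures must be positive")
        if self.t_min >= self.t_max:
            raise ValueError(
                f"t_min ({self.t_min}) must be below t_max ({self.t_max})"
            )
        if self.n_iters < 1 or self.k_restarts < 1:
            raise ValueError("n_iters and k_restarts must be >= 1")
        if self.size_slack < 0:
            raise ValueError("size_slack must be >= 0")
        if self.h_mode not in ("mean", "sum"):
            raise ValueError(f"h_mode must be 'mean' or 'sum', got {self.h_mode!r}")


@dataclass
class CandidatePools:
    """Per aligned network: proteins with at least one link into M_0."""

    pools: dict[str, frozenset[str]]
    empty_networks: tuple[str, ...]

    def __getitem__(self, net_id: str) -> frozenset[str]:
        return self.pools[net_id]


@dataclass
class AnnealResult:
    matchset: MatchSet
    phi: float
    trace: list[dict]


def build_candidate_pools(
    instance: AlignmentInstance, m0: frozenset[str] | set[str]
) -> CandidatePools:
    """Collect, per aligned network, every protein linked to M_0."""
    missing = set(m0) - instance.target.proteins
    if missing:
        raise ValueError(
            f"complex contains unknown target protein(s) {sorted(missing)!r}"
        )
    t_id = instance.target.network_id
    pools: dict[str, set[str]] = {nid: set() for nid in instance.aligned_ids}
    for x in m0:
        index = instance.links.partner_index((t_id, x))
        for net_id in instance.aligned_ids:
            pools[net_id] |= index.get(net_id, set())
    # pool members must actually exist in their network
    for net in instance.aligned:
        pools[net.network_id] &= net.proteins
    empty = tuple(nid for nid in instance.aligned_ids if not pools[nid])
    if len(empty) == len(instance.aligned):
        raise InfeasibleAlignmentError(
            "no aligned network has any protein linked to the complex"
        )
    for nid in empty:
        logger.warning("network %s: empty candidate pool", nid)
    return CandidatePools(
        pools={nid: frozenset(p) for nid, p in pools.items()},
        empty_networks=empty,
    )


def init_solution(
    instance: AlignmentInstance,
    pools: CandidatePools,
    m0: frozenset[str] | set[str],
    rng: np.random.Generator,
) -> dict[str, frozenset[str]]:
    """Uniform random sample of min(|M_0|, |pool|) proteins per network."""
    out: dict[str, frozenset[str]] = {}
    for net_id in instance.aligned_ids:
        pool = sorted(pools[net_id])
        if not pool:
            out[net_id] = frozenset()
            continue
        size = min(len(m0), len(pool))
        chosen = rng.choice(len(pool), size=size, replace=False)
        out[net_id] = frozenset(pool[i] for i in chosen)
    return out


def select_removal(
    scores: Mapping[str, float],
    degrees: Mapping[str, int],
    rng: np.random.Generator,
) -> str:
    """Protein to move out: a zero-degree one if any, else the lowest score.

    Zero-degree proteins violate the connectivity goal and are evicted
    first; ties in either rule are broken uniformly at random.
    """
    if not scores:
        raise ValueError("cannot select a removal from an empty subnetwork")
    zero = sorted(p for p, d in degrees.items() if d == 0)
    if zero:
        return zero[int(rng.integers(len(zero)))] if len(zero) > 1 else zero[0]
    lowest = min(scores.values())
    ties = sorted(p for p, sc in scores.items() if sc == lowest)
    return ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0]


def accept_move(
    delta_phi: float, t: float, s: float, rng: np.random.Generator
) -> bool:
    """Metropolis-style rule: uphill always, downhill with exp(ΔΦ/(sT))."""
    if t <= 0 or s <= 0:
        raise ValueError("temperature and scale must be positive")
    if delta_phi > 0:
        return True
    x = delta_phi / (s * t)
    if x < -700.0:  # exp underflow; acceptance probability is 0
        return False
    return rng.random() < math.exp(x)


class _Evaluator:
    """Fast Φ evaluation over plain dict/set structures.

    Mirrors :func:`complexalign.scoring.total_score` (a test asserts the
    two routes agree) but avoids per-call graph construction, which the
    inner annealing loop cannot afford.
    """

    def __init__(
        self, instance: AlignmentInstance, params: ScoreParams, h_mode: str
    ) -> None:
        self.t_id = instance.target.network_id
        self.adj: dict[str, dict[str, set[str]]] = {}
        for net in [instance.target, *instance.aligned]:
            self.adj[net.network_id] = {
                p: set(net.graph.neighbors(p)) for p in net.proteins
            }
        self.links = instance.links
        self.alpha = params.alpha
        self.inv_lam = 1.0 / params.lam
        self.inv_om = 1.0 / params.omega
        self.h_mean = h_mode == "mean"
        self._bio_pow: dict[int, float] = {0: 0.0}
        self._topo_pow: dict[int, float] = {0: 0.0}

    def _pb(self, x: int) -> float:
        v = self._bio_pow.get(x)
        if v is None:
            v = self._bio_pow[x] = x**self.inv_lam
        return v

    def _pt(self, x: int) -> float:
        v = self._topo_pow.get(x)
        if v is None:
            v = self._topo_pow[x] = x**self.inv_om
        return v

    def evaluate(
        self, m0: frozenset[str] | set[str], subnets: Mapping[str, frozenset[str]]
    ) -> tuple[float, dict[str, dict[str, float]], dict[str, dict[str, int]]]:
        """Return (Φ, per-network combined vertex scores, induced degrees)."""
        phi = 0.0
        all_scores: dict[str, dict[str, float]] = {}
        all_degrees: dict[str, dict[str, int]] = {}
        active = [(k, s) for k, s in subnets.items() if s]
        empty: set[str] = set()
        for k_id, members in active:
            adjk = self.adj[k_id]
            nbrs = {u: adjk.get(u, empty) & members for u in members}
            comp_size: dict[str, int] = {}
            for u in members:
                if u in comp_size:
                    continue
                comp = {u}
                stack = [u]
                while stack:
                    v = stack.pop()
                    for w in nbrs[v]:
                        if w not in comp:
                            comp.add(w)
                            stack.append(w)
                size = len(comp)
                for v in comp:
                    comp_size[v] = size
            others = [(h, hs) for h, hs in active if h != k_id]
            scores: dict[str, float] = {}
            degrees: dict[str, int] = {}
            for u in members:
                key = (k_id, u)
                lu = self.links.partner_index(key)
                lt = lu.get(self.t_id, empty)
                m0_linked = lt & m0 if lt else empty
                b1 = len(m0_linked)
                deg = len(nbrs[u])
                topo = self._pt(deg) + self._pt(comp_size[u])
                if others:
                    bio_sum = 0.0
                    pb1 = self._pb(b1)
                    for h_id, hm in others:
                        lh = lu.get(h_id)
                        if lh:
                            mh_linked = lh & hm
                            b2 = len(mh_linked)
                        else:
                            b2 = 0
                        b3 = 0
                        if b1 and b2:
                            for v in m0_linked:
                                lv = self.links.partner_index(
                                    (self.t_id, v)
                                ).get(h_id)
                                if lv:
                                    b3 += len(lv & mh_linked)
                        bio_sum += pb1 + self._pb(b2) + self._pb(b3)
                    bio = bio_sum / len(others) if self.h_mean else bio_sum
                else:
                    bio = self._pb(b1)
                c = self.alpha * bio + (1.0 - self.alpha) * topo
                scores[u] = c
                degrees[u] = deg
                phi += c
            all_scores[k_id] = scores
            all_degrees[k_id] = degrees
        return phi, all_scores, all_degrees

    def components(self, net_id: str, members: frozenset[str]) -> list[set[str]]:
        adjk = self.adj[net_id]
        seen: set[str] = set()
        comps: list[set[str]] = []
        for u in members:
            if u in seen:
                continue
            comp = {u}
            stack = [u]
            while stack:
                v = stack.pop()
                for w in adjk.get(v, ()):
                    if w in members and w not in comp:
                        comp.add(w)
                        stack.append(w)
            seen |= comp
            comps.append(comp)
        comps.sort(key=lambda c: min(c))
        return comps


def _is_connected(ev: _Evaluator, subnets: Mapping[str, frozenset[str]]) -> bool:
    return all(
        len(ev.components(k, s)) <= 1 for k, s in subnets.items() if s
    )


def _repair(
    ev: _Evaluator,
    pools: CandidatePools,
    m0: frozenset[str],
    subnets: dict[str, frozenset[str]],
) -> dict[str, frozenset[str]]:
    """Make every subnetwork connected.

    Disconnected subnetworks are cut down to their component with the
    highest summed vertex score, then rebuilt greedily with adjacent pool
    proteins as long as Φ improves, up to the original size.
    """
    subnets = dict(subnets)
    for k_id in sorted(subnets):
        members = subnets[k_id]
        if len(members) <= 1:
            continue
        comps = ev.components(k_id, members)
        if len(comps) <= 1:
            continue
        _, scores, _ = ev.evaluate(m0, subnets)
        sk = scores[k_id]
        best_comp = max(
            comps, key=lambda c: (sum(sk[p] for p in c), len(c), min(c))
        )
        target_size = len(members)
        current = set(best_comp)
        subnets[k_id] = frozenset(current)
        while len(current) < target_size:
            adjacent = sorted(
                p
                for p in pools[k_id] - current
                if ev.adj[k_id].get(p, set()) & current
            )
            if not adjacent:
                break
            base_phi = ev.evaluate(m0, subnets)[0]
            best: tuple[str, float] | None = None
            for p in adjacent:
                subnets[k_id] = frozenset(current | {p})
                phi = ev.evaluate(m0, subnets)[0]
                if phi > base_phi + 1e-12 and (best is None or phi > best[1]):
                    best = (p, phi)
            if best is None:
                subnets[k_id] = frozenset(current)
                break
            current.add(best[0])
            subnets[k_id] = frozenset(current)
    return subnets


def anneal_one(
    instance: AlignmentInstance,
    m0: frozenset[str] | set[str],
    params: AnnealParams,
    seed: int | None = None,
    complex_id: str = "",
) -> AnnealResult:
    """Run the full annealing search for one target complex.

    Fully deterministic given the seed (``params.seed`` unless *seed*
    overrides it).  Returns the best connected solution found: the better,
    by Φ, of the best all-connected state visited and the repaired overall
    best state.
    """
    m0 = frozenset(m0)
    base_seed = params.seed if seed is None else seed
    pools = build_candidate_pools(instance, m0)
    ev = _Evaluator(instance, params.score, params.h_mode)
    base_sizes = {
        nid: min(len(m0), len(pools[nid])) for nid in instance.aligned_ids
    }

    best_any: dict[str, frozenset[str]] | None = None
    best_any_phi = -math.inf
    best_conn: dict[str, frozenset[str]] | None = None
    best_conn_phi = -math.inf
    trace: list[dict] = []

    for restart in range(params.k_restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=base_seed, spawn_key=(restart,))
        )
        cur = init_solution(instance, pools, m0, rng)
        cur_phi, cur_scores, cur_degrees = ev.evaluate(m0, cur)
        restart_best = cur_phi

        def consider(state: dict[str, frozenset[str]], phi: float) -> None:
            nonlocal best_any, best_any_phi, best_conn, best_conn_phi
            if phi > best_any_phi:
                best_any, best_any_phi = dict(state), phi
            if phi > best_conn_phi and _is_connected(ev, state):
                best_conn, best_conn_phi = dict(state), phi

        consider(cur, cur_phi)
        t = params.t_max
        while t >= params.t_min:
            for _ in range(params.n_iters):
                eligible = _eligible_networks(cur, pools, base_sizes, params)
                if not eligible:
                    break
                k_id = eligible[int(rng.integers(len(eligible)))]
                cand_k = _propose(
                    cur[k_id],
                    pools[k_id],
                    base_sizes[k_id],
                    cur_scores.get(k_id, {}),
                    cur_degrees.get(k_id, {}),
                    params.size_slack,
                    rng,
                )
                if cand_k is None:
                    continue
                cand = dict(cur)
                cand[k_id] = cand_k
                cand_phi, cand_scores, cand_degrees = ev.evaluate(m0, cand)
                if accept_move(cand_phi - cur_phi, t, params.s, rng):
                    cur, cur_phi = cand, cand_phi
                    cur_scores, cur_degrees = cand_scores, cand_degrees
                    consider(cur, cur_phi)
                    if cur_phi > restart_best:
                        restart_best = cur_phi
            trace.append(
                {
                    "restart": restart,
                    "temperature": t,
                    "best_phi": best_any_phi,
                }
            )
            t /= params.theta

    assert best_any is not None
    repaired = _repair(ev, pools, m0, best_any)
    repaired_phi = ev.evaluate(m0, repaired)[0]
    if best_conn is not None and best_conn_phi > repaired_phi:
        final, final_phi = best_conn, best_conn_phi
    else:
        final, final_phi = repaired, repaired_phi
    if not _is_connected(ev, final):  # pragma: no cover - safety net
        raise RuntimeError("connectivity repair failed")
    matchset = MatchSet(
        complex_id,
        {nid: final.get(nid, frozenset()) for nid in instance.aligned_ids},
    )
    return AnnealResult(matchset=matchset, phi=final_phi, trace=trace)


def _eligible_networks(
    cur: Mapping[str, frozenset[str]],
    pools: CandidatePools,
    base_sizes: Mapping[str, int],
    params: AnnealParams,
) -> list[str]:
    """Networks where some move exists (an alternative pool protein)."""
    out = []
    for net_id in sorted(cur):
        members = cur[net_id]
        if not members:
            continue
        if len(pools[net_id]) > len(members):
            out.append(net_id)
        elif params.size_slack > 0 and len(members) > 1:
            out.append(net_id)
    return out


def _propose(
    members: frozenset[str],
    pool: frozenset[str],
    base_size: int,
    scores: Mapping[str, float],
    degrees: Mapping[str, int],
    size_slack: int,
    rng: np.random.Generator,
) -> frozenset[str] | None:
    """One move on a single network's subnetwork: swap, insert or delete."""
    outside = sorted(pool - members)
    can_grow = size_slack > 0 and outside and len(members) < base_size + size_slack
    can_shrink = (
        size_slack > 0
        and len(members) > max(1, base_size - size_slack)
    )
    if size_slack > 0 and (can_grow or can_shrink) and rng.random() < 0.2:
        grow_ok = can_grow and (not can_shrink or rng.random() < 0.5)
        if grow_ok:
            return members | {outside[int(rng.integers(len(outside)))]}
        removed = select_removal(scores, degrees, rng)
        return members - {removed}
    if not outside:
        return None
    removed = select_removal(scores, degrees, rng)
    inserted = outside[int(rng.integers(len(outside)))]
    return (members - {removed}) | {inserted}


def align_all(
    instance: AlignmentInstance, params: AnnealParams
) -> list[AnnealResult]:
    """Anneal every complex of the instance independently.

    Per-complex seeds are derived as ``params.seed + complex index`` so
    results do not depend on processing order.  Infeasible complexes (no
    candidates anywhere) are logged and skipped.
    """
    results = []
    for idx, (cid, members) in enumerate(instance.complexes):
        try:
            res = anneal_one(
                instance,
                members,
                params,
                seed=params.seed + idx,
                complex_id=cid,
            )
        except InfeasibleAlignmentError as exc:
            logger.warning("complex %s skipped: %s", cid, exc)
            continue
        logger.info(
            "complex %s: phi=%.4f sizes=%s", cid, res.phi, res.matchset.sizes()
        )
        results.append(res)
    return results
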