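"""Shared fixtures: the three-network worked example and random instances."""
from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from complexalign.core import (
    AlignmentInstance,
    LinkSet,
    MatchSet,
    PPINetwork,
)


@pytest.fixture
def toy3():
    """Three tiny networks with one conserved complex.

    Target Net x holds the complex {x1,x2,x3}; Net y holds the candidate
    subnetwork {y1,y2,y3} with internal edges y1-y2 and y1-y3; Net z holds
    {z2,z3,z4}.  Links: (y1,x1), (y1,z2), (x1,z2) — so y1 has one link to
    the complex, one link to the Net-z subnetwork, and sits on exactly one
    thread.
    """
    netx = PPINetwork(
        "netx", edges=[("x1", "x2"), ("x2", "x3")], proteins=["x1", "x2", "x3"]
    )
    nety = PPINetwork(
        "nety",
        edges=[("y1", "y2"), ("y1", "y3")],
        proteins=["y1", "y2", "y3", "y4"],
    )
    netz = PPINetwork(
        "netz", edges=[("z2", "z3"), ("z3", "z4")], proteins=["z2", "z3", "z4"]
    )
    links = LinkSet()
    links.add(("nety", "y1"), ("netx", "x1"), 1e-20)
    links.add(("nety", "y1"), ("netz", "z2"), 1e-15)
    links.add(("netx", "x1"), ("netz", "z2"), 1e-18)
    m0 = frozenset({"x1", "x2", "x3"})
    instance = AlignmentInstance(
        target=netx, aligned=[nety, netz], links=links, complexes=[("C1", m0)]
    )
    return {
        "instance": instance,
        "m0": m0,
        "mk": ("nety", frozenset({"y1", "y2", "y3"})),
        "mh": ("netz", frozenset({"z2", "z3", "z4"})),
        "matchset": MatchSet(
            "C1",
            {
                "nety": frozenset({"y1", "y2", "y3"}),
                "netz": frozenset({"z2", "z3", "z4"}),
            },
        ),
    }


def random_ppi(network_id: str, n: int, p: float, rng: np.random.Generator):
    names = [f"{network_id}_{i}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return PPINetwork(network_id, edges=edges, proteins=names)


def tiny_instance(seed: int, n: int = 8, edge_p: float = 0.35,
                  link_p: float = 0.3, complex_size: int = 3):
    """Small random 3-network instance with a connected target complex.

    Deterministic in *seed*; retries with derived sub-seeds until the
    target has a connected complex of the requested size and every aligned
    network has a non-empty candidate pool.
    """
    from complexalign.annealing import (
        InfeasibleAlignmentError,
        build_candidate_pools,
    )

    for attempt in range(50):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(attempt,))
        )
        nets = {
            nid: random_ppi(nid, n, edge_p, rng) for nid in ("t", "a", "b")
        }
        links = LinkSet()
        for x, y in itertools.combinations(("t", "a", "b"), 2):
            for px in sorted(nets[x].proteins):
                for py in sorted(nets[y].proteins):
                    if rng.random() < link_p:
                        links.add((x, px), (y, py), 1e-20)
        # a connected complex in the target, grown by BFS from a random seed
        order = sorted(nets["t"].proteins)
        start = order[int(rng.integers(len(order)))]
        seen, queue = {start}, [start]
        while queue and len(seen) < complex_size:
            v = queue.pop(0)
            for w in sorted(nets["t"].neighbors(v)):
                if w not in seen:
                    seen.add(w)
                    queue.append(w)
                    if len(seen) == complex_size:
                        break
        if len(seen) < complex_size:
            continue
        m0 = frozenset(seen)
        instance = AlignmentInstance(
            target=nets["t"],
            aligned=[nets["a"], nets["b"]],
            links=links,
            complexes=[("C", m0)],
        )
        try:
            pools = build_candidate_pools(instance, m0)
        except InfeasibleAlignmentError:
            continue
        if all(pools[nid] for nid in ("a", "b")):
            return instance, m0
    raise RuntimeError(f"no feasible tiny instance for seed {seed}")


# ---------------------------------------------------------------------------
# brute-force reference scoring, independent of the package internals
# ---------------------------------------------------------------------------

def brute_phi(instance, m0, matchset, alpha, lam, omega, h_mode="mean"):
    """Direct evaluation of the objective from raw edge and link sets."""
    link_pairs = set()
    for lk in instance.links:
        link_pairs.add(frozenset((lk.a, lk.b)))

    def linked(u, v):
        return frozenset((u, v)) in link_pairs

    t_id = instance.target.network_id
    phi = 0.0
    subnets = matchset.subnetworks
    for k_id, members in subnets.items():
        if not members:
            continue
        edges = {
            frozenset(e)
            for e in instance.network(k_id).interactions
            if e[0] in members and e[1] in members
        }
        others = [
            (h, hm) for h, hm in subnets.items() if h != k_id and hm
        ]
        for u in members:
            deg = sum(1 for e in edges if u in e)
            # component of u by brute closure
            comp = {u}
            grown = True
            while grown:
                grown = False
                for e in edges:
                    a, b = tuple(e)
                    if a in comp and b not in comp:
                        comp.add(b)
                        grown = True
                    elif b in comp and a not in comp:
                        comp.add(a)
                        grown = True
            topo = _r(deg, omega) + _r(len(comp), omega)
            b1 = sum(1 for v in m0 if linked((k_id, u), (t_id, v)))
            if not others:
                bio_vals = [_r(b1, lam)]
            else:
                bio_vals = []
                for h_id, hm in others:
                    b2 = sum(1 for w in hm if linked((k_id, u), (h_id, w)))
                    b3 = sum(
                        1
                        for v in m0
                        for w in hm
                        if linked((k_id, u), (t_id, v))
                        and linked((k_id, u), (h_id, w))
                        and linked((t_id, v), (h_id, w))
                    )
                    bio_vals.append(_r(b1, lam) + _r(b2, lam) + _r(b3, lam))
            if h_mode == "mean":
                bio = sum(bio_vals) / len(bio_vals)
            else:
                bio = sum(bio_vals)
            phi += alpha * bio + (1 - alpha) * topo
    return phi


def _r(x, p):
    return 0.0 if x == 0 else x ** (1.0 / p)


def connected_subsets(net: PPINetwork, pool, max_size):
    """All subsets of *pool* of size 1..max_size inducing a connected graph."""
    pool = sorted(pool)
    out = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(pool, size):
            members = set(combo)
            start = combo[0]
            comp, stack = {start}, [start]
            while stack:
                v = stack.pop()
                for w in net.neighbors(v):
                    if w in members and w not in comp:
                        comp.add(w)
                        stack.append(w)
            if comp == members:
                out.append(frozenset(members))
    return out
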