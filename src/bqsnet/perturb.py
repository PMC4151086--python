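"""Edge-addition destabilisation probes.

The buffering of a network is measured by inserting a single new TF->TF
regulatory link and asking whether it creates a long feedback loop
(>= 3 nodes; a new 2-node loop is not destabilising).  Inserting
``u -> v`` creates a long loop iff a simple directed path ``v ~> u``
with at least 2 and at most ``max_len - 1`` edges already exists in the
TF subnetwork.  The probe either tries every possible insertion
(exhaustive, as for real GRNs) or estimates the probability from
uniform random insertions with replacement (``NS / n_samples``, as for
large random ensembles).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .grn import GRN, GRNError
from .loops import DEFAULT_MAX_LEN

CANDIDATE_SCOPES = ("all-tfs", "tf-subnet-nonisolated")


@dataclass
class ProbeResult:
    """Outcome of a destabilisation probe."""

    n_candidates: int
    n_destabilizing: int
    probability: float
    method: str                   # "exhaustive" | "sampled(n=..., seed=...)"
    destabilizing_edges: Optional[list[tuple[str, str, int]]] = None

    def to_dict(self) -> dict:
        out = {
            "schema": "bqsnet/probe-v1",
            "n_candidates": self.n_candidates,
            "n_destabilizing": self.n_destabilizing,
            "probability": self.probability,
            "method": self.method,
        }
        if self.destabilizing_edges is not None:
            out["destabilizing_edges"] = [
                {"regulator": u, "target": v, "loops_created": c}
                for u, v, c in self.destabilizing_edges
            ]
        return out


def candidate_insertions(g: GRN, scope: str = "all-tfs") -> set[tuple[str, str]]:
    """All ordered TF pairs (u, v), u != v, with edge u->v absent.

    ``scope="tf-subnet-nonisolated"`` restricts both endpoints to TFs
    carrying at least one TF-TF edge, mirroring analyses that drop TFs
    isolated within the TF subnetwork.
    """
    if scope not in CANDIDATE_SCOPES:
        raise ValueError(f"scope must be one of {CANDIDATE_SCOPES}")
    tfs = g.tf_set
    if scope == "tf-subnet-nonisolated":
        touched = set()
        for u, v in g.edges:
            if u in tfs and v in tfs:
                touched.add(u)
                touched.add(v)
        tfs = frozenset(touched)
    if len(tfs) < 2:
        raise GRNError("candidate insertions require at least 2 TFs in scope")
    return {
        (u, v)
        for u in tfs
        for v in tfs
        if u != v and (u, v) not in g.edges
    }


def _bounded_dist(h: nx.DiGraph, src: str, dst: str, max_edges: int,
                  skip_direct: bool = False) -> Optional[int]:
    """BFS shortest-path length src -> dst, capped at ``max_edges``.

    With ``skip_direct``, the direct edge src->dst is ignored (paths of
    length >= 2 never reuse it, since they would revisit dst).
    """
    if max_edges < 1:
        return None
    seen = {src}
    frontier = deque([(src, 0)])
    while frontier:
        node, d = frontier.popleft()
        if d >= max_edges:
            continue
        for w in h.successors(node):
            if skip_direct and node == src and w == dst:
                continue
            if w == dst:
                return d + 1
            if w not in seen:
                seen.add(w)
                frontier.append((w, d + 1))
    return None


def _is_destabilizing(h: nx.DiGraph, u: str, v: str, max_len: int) -> bool:
    """Would inserting u->v create a cycle of 3..max_len nodes?"""
    # need a simple path v ~> u of 2..max_len-1 edges; drop the direct
    # edge v->u (if any) so the shortest remaining path has >= 2 edges
    d = _bounded_dist(h, v, u, max_len - 1, skip_direct=h.has_edge(v, u))
    return d is not None and d >= 2


def _count_created_loops(h: nx.DiGraph, u: str, v: str, max_len: int) -> int:
    """Number of simple paths v ~> u with 2..max_len-1 edges."""
    succ = {x: tuple(h.successors(x)) for x in h.nodes}
    count = 0

    def extend(node: str, depth: int, visited: set) -> None:
        nonlocal count
        for w in succ[node]:
            if w in visited:
                continue
            if w == u:
                if depth + 1 >= 2:
                    count += 1
                continue
            if depth + 1 < max_len - 1:
                visited.add(w)
                extend(w, depth + 1, visited)
                visited.remove(w)

    extend(v, 0, {v})
    return count


def probe_exhaustive(
    g: GRN,
    max_len: int = DEFAULT_MAX_LEN,
    scope: str = "all-tfs",
    with_loop_counts: bool = True,
) -> ProbeResult:
    """Try every candidate TF->TF insertion; exact destabilisation ratio."""
    candidates = candidate_insertions(g, scope)
    if not candidates:
        raise GRNError("no candidate insertions (TF subnetwork is complete)")
    h = g.to_networkx(tf_only=True)
    destab = []
    for u, v in sorted(candidates):
        if _is_destabilizing(h, u, v, max_len):
            created = (
                _count_created_loops(h, u, v, max_len) if with_loop_counts else -1
            )
            destab.append((u, v, created))
    return ProbeResult(
        n_candidates=len(candidates),
        n_destabilizing=len(destab),
        probability=len(destab) / len(candidates),
        method="exhaustive",
        destabilizing_edges=destab,
    )


def probe_sampled(
    g: GRN,
    n_samples: int = 100_000,
    seed: int = 0,
    max_len: int = DEFAULT_MAX_LEN,
    scope: str = "all-tfs",
) -> ProbeResult:
    """Estimate the destabilisation probability from random insertions.

    Draws ``n_samples`` candidates uniformly *with replacement* and
    reports the hit fraction NS / n_samples.  Deterministic under
    ``seed``; repeated pairs are decided once and cached.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    candidates = sorted(candidate_insertions(g, scope))
    if not candidates:
        raise GRNError("no candidate insertions (TF subnetwork is complete)")
    h = g.to_networkx(tf_only=True)
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(candidates), size=n_samples)
    cache: dict[int, bool] = {}
    ns = 0
    for k in picks.tolist():
        hit = cache.get(k)
        if hit is None:
            u, v = candidates[k]
            hit = _is_destabilizing(h, u, v, max_len)
            cache[k] = hit
        ns += hit
    return ProbeResult(
        n_candidates=len(candidates),
        n_destabilizing=ns,
        probability=ns / n_samples,
        method=f"sampled(n_samples={n_samples}, seed={seed})",
    )


def destabilization_potential(
    g: GRN, reference: Optional[str] = None
) -> pd.DataFrame:
    """Per-TF count of single links that would close a 3-gene loop.

    A new link can close a 3-node loop through TF A for every pair of a
    TF regulator and a TF target of A, so the potential is
    ``in_from_tfs * out_to_tfs``.  The ``relative`` column normalises to
    the potential of ``reference`` (default: unit potential), giving the
    isocline value used to map cross-regulation scatter plots.
    """
    cross = g.cross_regulation()
    potential = cross["in_from_tfs"] * cross["out_to_tfs"]
    if reference is None:
        ref_value = 1.0
    else:
        if reference not in potential.index:
            raise GRNError(f"reference TF {reference!r} not in TF set")
        ref_value = float(potential[reference])
        if ref_value == 0:
            raise GRNError("reference TF has zero destabilization potential")
    out = cross.copy()
    out["potential"] = potential
    out["relative"] = potential / ref_value
    return out


@dataclass
class EnrichmentResult:
    """Cross-network destabilisation enrichment."""

    n_destabilizing: int
    n_candidates: int
    n_destab_realized: int
    n_all_realized: int
    frac_destab_realized: float
    frac_all_realized: float
    ratio: Optional[float]
    undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "schema": "bqsnet/enrichment-v1",
            "n_destabilizing": self.n_destabilizing,
            "n_candidates": self.n_candidates,
            "n_destab_realized": self.n_destab_realized,
            "n_all_realized": self.n_all_realized,
            "frac_destab_realized": self.frac_destab_realized,
            "frac_all_realized": self.frac_all_realized,
            "ratio": self.ratio,
            "undefined": self.undefined,
        }


def destabilization_enrichment(
    g_ref: GRN,
    g_alt: GRN,
    max_len: int = DEFAULT_MAX_LEN,
    scope: str = "all-tfs",
) -> EnrichmentResult:
    """Are g_ref's destabilising candidate edges enriched among g_alt's edges?

    D = destabilising candidate insertions of ``g_ref``; P = all candidate
    insertions.  Compares |D ∩ edges(g_alt)| / |D| with
    |P ∩ edges(g_alt)| / |P|; a ratio well above 1 means the second
    network preferentially realised exactly the links that destabilise
    the first.
    """
    probe = probe_exhaustive(g_ref, max_len=max_len, scope=scope, with_loop_counts=False)
    candidates = candidate_insertions(g_ref, scope)
    destab = {(u, v) for u, v, _ in probe.destabilizing_edges}
    alt_edges = g_alt.edges
    n_destab_real = len(destab & alt_edges)
    n_all_real = len(candidates & alt_edges)
    frac_all = n_all_real / len(candidates)
    if not destab:
        return EnrichmentResult(
            0, len(candidates), 0, n_all_real, float("nan"), frac_all,
            None, undefined=True,
        )
    frac_destab = n_destab_real / len(destab)
    ratio = frac_destab / frac_all if frac_all > 0 else None
    return EnrichmentResult(
        n_destabilizing=len(destab),
        n_candidates=len(candidates),
        n_destab_realized=n_destab_real,
        n_all_realized=n_all_real,
        frac_destab_realized=frac_destab,
        frac_all_realized=frac_all,
        ratio=ratio,
        undefined=ratio is None,
    )
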