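"""Feedback-loop and incomplete-feedback-loop censuses.

A feedback loop of length L is a directed simple cycle on L distinct
nodes, counted once regardless of starting node (the directed-cycle
sub-isomorphism count divided by L to absorb the cyclic automorphisms).
An incomplete feedback loop of length L is a directed simple path with L
edges whose single closing edge (last node -> first node) is absent, so
one new link turns it into an (L+1)-loop.  "Long" means >= 3 nodes
throughout: 2-node loops are legitimate under qualitative stability
(given suitable signs) and are never counted as destabilising.

All censuses run on the TF-induced subnetwork: genes that regulate
nothing cannot sit on a cycle, and including them would artificially
inflate apparent stability.  The default enumeration horizon is
``max_len = 14``; exhaustive path enumeration beyond that is
combinatorially infeasible in dense random networks, and random-ensemble
counts at length 14 already dwarf anything seen in real GRNs.

The identity ``incomplete[L] = paths[L] - (L+1) * cycles[L+1]`` ties the
three censuses together (every (L+1)-cycle contains L+1 closed L-paths)
and is exercised as a cross-check in the test-suite oracles.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .grn import GRN, GRNError

DEFAULT_MAX_LEN = 14


@dataclass
class LoopCensus:
    """Per-length counts of feedback loops or incomplete feedback loops."""

    kind: str                    # "feedback" | "incomplete"
    counts: dict[int, int]
    max_len: int
    restricted_to_tfs: bool = True

    def __post_init__(self):
        if self.kind not in ("feedback", "incomplete"):
            raise ValueError(f"unknown census kind {self.kind!r}")
        full = {L: 0 for L in range(2, self.max_len + 1)}
        full.update({int(k): int(v) for k, v in self.counts.items()})
        self.counts = full

    def __getitem__(self, length: int) -> int:
        return self.counts.get(length, 0)

    def total(self, min_len: int = 2, max_len: Optional[int] = None) -> int:
        max_len = self.max_len if max_len is None else max_len
        return sum(c for L, c in self.counts.items() if min_len <= L <= max_len)

    def long_total(self) -> int:
        """Total count at lengths >= 3 (the qualitative-stability horizon)."""
        return self.total(min_len=3)

    def to_dict(self) -> dict:
        return {
            "schema": "bqsnet/census-v1",
            "kind": self.kind,
            "max_len": self.max_len,
            "restricted_to_tfs": self.restricted_to_tfs,
            "counts": {str(L): self.counts[L] for L in sorted(self.counts)},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LoopCensus":
        return cls(
            kind=payload["kind"],
            counts={int(k): v for k, v in payload["counts"].items()},
            max_len=payload["max_len"],
            restricted_to_tfs=payload.get("restricted_to_tfs", True),
        )


def _analysis_graph(g: GRN, restrict_to_tfs: bool) -> nx.DiGraph:
    return g.to_networkx(tf_only=restrict_to_tfs)


# ---------------------------------------------------------------------------
# feedback loops


def count_feedback_loops(
    g: GRN, max_len: int = DEFAULT_MAX_LEN, restrict_to_tfs: bool = True
) -> LoopCensus:
    """Count directed simple cycles of 2..max_len nodes, once per cycle."""
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    h = _analysis_graph(g, restrict_to_tfs)
    counts: dict[int, int] = defaultdict(int)
    for cyc in nx.simple_cycles(h, length_bound=max_len):
        counts[len(cyc)] += 1
    return LoopCensus("feedback", dict(counts), max_len, restrict_to_tfs)


def enumerate_long_loops(
    g: GRN, max_len: int = DEFAULT_MAX_LEN, restrict_to_tfs: bool = True
) -> list[tuple[str, ...]]:
    """List all cycles on 3..max_len nodes (each as a node tuple)."""
    h = _analysis_graph(g, restrict_to_tfs)
    return [
        tuple(cyc)
        for cyc in nx.simple_cycles(h, length_bound=max_len)
        if len(cyc) >= 3
    ]


def has_long_loop(
    g: GRN, max_len: int = DEFAULT_MAX_LEN, restrict_to_tfs: bool = True
) -> bool:
    """True iff the (TF sub)network contains a cycle of >= 3 nodes.

    A cycle of >= 3 nodes can only live inside a strongly connected
    component of >= 3 nodes, so enumeration is confined to those.
    """
    h = _analysis_graph(g, restrict_to_tfs)
    for comp in nx.strongly_connected_components(h):
        if len(comp) < 3:
            continue
        sub = h.subgraph(comp)
        for cyc in nx.simple_cycles(sub, length_bound=min(max_len, len(comp))):
            if len(cyc) >= 3:
                return True
    return False


# ---------------------------------------------------------------------------
# simple paths and incomplete loops


def _adjacency(h: nx.DiGraph) -> tuple[list, dict, dict]:
    nodes = list(h.nodes)
    succ = {v: tuple(h.successors(v)) for v in nodes}
    succ_set = {v: set(s) for v, s in succ.items()}
    return nodes, succ, succ_set


def _path_dfs(h: nx.DiGraph, max_len: int) -> tuple[dict[int, int], dict[int, int]]:
    """Count simple paths (by edge count) and those whose closure is absent."""
    nodes, succ, succ_set = _adjacency(h)
    paths: dict[int, int] = defaultdict(int)
    incomplete: dict[int, int] = defaultdict(int)

    def extend(v0: str, v: str, depth: int, visited: set) -> None:
        nxt = depth + 1
        deeper = nxt < max_len
        for w in succ[v]:
            if w in visited:
                continue
            paths[nxt] += 1
            if v0 not in succ_set[w]:
                incomplete[nxt] += 1
            if deeper:
                visited.add(w)
                extend(v0, w, nxt, visited)
                visited.remove(w)

    for v0 in nodes:
        extend(v0, v0, 0, {v0})
    return dict(paths), dict(incomplete)


def count_simple_paths(
    g: GRN, max_len: int, restrict_to_tfs: bool = True
) -> dict[int, int]:
    """Number of directed simple paths with L edges, for L = 1..max_len."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    h = _analysis_graph(g, restrict_to_tfs)
    paths, _ = _path_dfs(h, max_len)
    return {L: paths.get(L, 0) for L in range(1, max_len + 1)}


def count_incomplete_loops(
    g: GRN, max_len: int = DEFAULT_MAX_LEN, restrict_to_tfs: bool = True
) -> LoopCensus:
    """Count simple L-edge paths whose closing edge is absent, L = 2..max_len."""
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    h = _analysis_graph(g, restrict_to_tfs)
    _, incomplete = _path_dfs(h, max_len)
    counts = {L: incomplete.get(L, 0) for L in range(2, max_len + 1)}
    return LoopCensus("incomplete", counts, max_len, restrict_to_tfs)


def closure_additions(path_length: int) -> int:
    """Single-edge additions turning a bare k-edge path into a long loop.

    Adding (v_j -> v_i) with j - i >= 2 closes a cycle of j - i + 1 >= 3
    nodes; there are k(k-1)/2 such ordered pairs on a path with k edges.
    """
    if path_length < 2:
        raise ValueError("path_length must be >= 2")
    k = path_length
    return k * (k - 1) // 2


# ---------------------------------------------------------------------------
# loop-derived diagnostics


def loops_per_gene(
    g: GRN, max_len: int = DEFAULT_MAX_LEN, restrict_to_tfs: bool = True
) -> tuple[pd.DataFrame, int]:
    """Long-loop membership per TF.

    Returns ``(table, n_long_loops)`` where the table has one row per TF
    appearing in at least one long loop, with the number of distinct
    long loops through it and that number as a percentage of all long
    loops.  With zero long loops the table is empty (no division).
    """
    loops = enumerate_long_loops(g, max_len, restrict_to_tfs)
    total = len(loops)
    if total == 0:
        empty = pd.DataFrame(columns=["loop_count", "percent_of_loops"])
        empty.index.name = "gene"
        return empty, 0
    counts: dict[str, int] = defaultdict(int)
    for cyc in loops:
        for v in cyc:
            counts[v] += 1
    genes = sorted(counts, key=lambda v: (-counts[v], v))
    df = pd.DataFrame(
        {
            "loop_count": [counts[v] for v in genes],
            "percent_of_loops": [100.0 * counts[v] / total for v in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return df, total


def critical_edges(
    g: GRN, max_len: int = DEFAULT_MAX_LEN, restrict_to_tfs: bool = True
) -> set[tuple[str, str]]:
    """Edges present in *every* long loop; removing any one kills them all."""
    loops = enumerate_long_loops(g, max_len, restrict_to_tfs)
    if not loops:
        raise GRNError("no long feedback loops: critical edges undefined")
    edge_sets = [
        {(cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc))}
        for cyc in loops
    ]
    common = set.intersection(*edge_sets)
    for e in common:
        pruned = GRN(g.edges - {e}, nodes=g.nodes, tf_set=g.tf_set)
        assert not has_long_loop(pruned, max_len, restrict_to_tfs), (
            "critical edge removal left a long loop"
        )
    return common


def stabilizing_pairs(
    g: GRN,
    max_len: int = DEFAULT_MAX_LEN,
    restrict_to_tfs: bool = True,
    top: Optional[int] = None,
) -> pd.DataFrame:
    """Residual long-loop count after removing each unordered TF pair.

    Brute force over all TF pairs, ranked ascending by residual count
    (ties broken lexicographically on the gene-id pair).  Low residuals
    identify pairs whose removal "stabilises" the network.
    """
    tfs = sorted(g.tf_set)
    if len(tfs) < 2:
        raise GRNError("stabilizing_pairs requires at least 2 TFs")
    loops = enumerate_long_loops(g, max_len, restrict_to_tfs)
    total = len(loops)
    membership: dict[str, set[int]] = defaultdict(set)
    for i, cyc in enumerate(loops):
        for v in cyc:
            membership[v].add(i)
    rows = []
    for a, b in itertools.combinations(tfs, 2):
        hit = len(membership[a] | membership[b])
        rows.append((a, b, total - hit))
    rows.sort(key=lambda r: (r[2], r[0], r[1]))
    if top is not None:
        rows = rows[:top]
    return pd.DataFrame(rows, columns=["tf_a", "tf_b", "residual_long_loops"])


def find_chaotic_motifs(g: GRN, restrict_to_tfs: bool = True) -> list[tuple[str, str, str]]:
    """Pairs of 2-node loops sharing a node, closed into a 3-node loop.

    Matches triples (A, B, C) with A<->B, B<->C and at least one of C->A
    or A->C (non-induced: extra edges among the three are permitted).
    This is the recurring "illegal" structure seen in stress-response
    modules, previously linked to chaotic dynamics in chemical networks.
    Each unordered instance (A, B, C) ~ (C, B, A) is reported once.
    """
    h = _analysis_graph(g, restrict_to_tfs)
    mutual: dict[str, set[str]] = defaultdict(set)
    for u, v in h.edges:
        if h.has_edge(v, u):
            mutual[u].add(v)
    seen = set()
    out = []
    for b in sorted(mutual):
        partners = sorted(mutual[b])
        for a, c in itertools.permutations(partners, 2):
            if h.has_edge(c, a):
                key = (b, frozenset((a, c)))
                if key not in seen:
                    seen.add(key)
                    out.append((a, b, c))
    return out


# ---------------------------------------------------------------------------
# qualitative-stability condition report


CONDITION4_NOTE = (
    "Sign-matrix invertibility would require two TFs regulating each other "
    "and acting identically on identical gene sets; network-reconstruction "
    "pipelines collapse such biochemically indistinguishable genes into one "
    "node, so the condition is structurally trivial for GRN data."
)


@dataclass
class QSReport:
    """Structural check of the four qualitative-stability conditions.

    Condition 1: no positive self-regulation.  Condition 2: no
    double-positive or double-negative 2-node loops (mixed-sign 2-node
    loops are allowed; isolated double-negative loops act as switches).
    Condition 3: no feedback loops of more than two nodes.  Condition 4
    (sign-matrix invertibility) is structurally trivial for GRN data.
    """

    positive_self_loops: list = field(default_factory=list)
    indeterminate_self_loops: list = field(default_factory=list)
    two_node_loops: list = field(default_factory=list)
    long_loop_census: Optional[LoopCensus] = None
    condition1_verdict: str = "pass"
    condition2_verdict: str = "pass"
    condition3_verdict: str = "pass"
    condition4_note: str = CONDITION4_NOTE

    def to_dict(self) -> dict:
        return {
            "schema": "bqsnet/qs-report-v1",
            "positive_self_loops": sorted(self.positive_self_loops),
            "indeterminate_self_loops": sorted(self.indeterminate_self_loops),
            "two_node_loops": self.two_node_loops,
            "long_loop_census": self.long_loop_census.to_dict()
            if self.long_loop_census
            else None,
            "condition1_verdict": self.condition1_verdict,
            "condition2_verdict": self.condition2_verdict,
            "condition3_verdict": self.condition3_verdict,
            "condition4_note": self.condition4_note,
        }


def _two_loop_sign_class(s1: str, s2: str) -> str:
    if "?" in (s1, s2) or "±" in (s1, s2):
        return "unsigned"
    if s1 == s2 == "+":
        return "double-positive"
    if s1 == s2 == "-":
        return "double-negative"
    return "mixed"


def qs_condition_report(
    g: GRN, max_len: int = DEFAULT_MAX_LEN, restrict_to_tfs: bool = True
) -> QSReport:
    """Check the structural qualitative-stability conditions on a GRN."""
    report = QSReport()

    # condition 1: positive self-regulation
    for u, _ in sorted(g.self_loops):
        s = g.sign_of((u, u))
        if s == "+":
            report.positive_self_loops.append(u)
        elif s in ("?", "±"):
            report.indeterminate_self_loops.append(u)
    if report.positive_self_loops:
        report.condition1_verdict = "violated"
    elif report.indeterminate_self_loops:
        report.condition1_verdict = "indeterminate"

    # condition 2: same-sign 2-node loops, with isolation flags
    h = _analysis_graph(g, restrict_to_tfs)
    two_loops = sorted(
        {frozenset((u, v)) for u, v in h.edges if h.has_edge(v, u)},
        key=sorted,
    )
    long_loops = enumerate_long_loops(g, max_len, restrict_to_tfs)
    loop_nodes = [set(c) for c in long_loops] + [set(p) for p in two_loops]
    classes = []
    for pair in two_loops:
        a, b = sorted(pair)
        cls = _two_loop_sign_class(g.sign_of((a, b)), g.sign_of((b, a)))
        shared = any(
            (pair & other) and other != set(pair) for other in loop_nodes
        )
        classes.append(
            {"nodes": [a, b], "sign_class": cls, "isolated": not shared}
        )
    report.two_node_loops = classes
    if any(c["sign_class"] in ("double-positive", "double-negative") for c in classes):
        report.condition2_verdict = "violated"
    elif any(c["sign_class"] == "unsigned" for c in classes):
        report.condition2_verdict = "indeterminate"

    # condition 3: long loops
    report.long_loop_census = count_feedback_loops(g, max_len, restrict_to_tfs)
    if report.long_loop_census.long_total() > 0:
        report.condition3_verdict = "violated"

    return report
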