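"""3- and 4-node motif census with buffering classification.

A motif instance is a *connected induced* subgraph of the TF subnetwork
(the standard motif-census convention: each node subset is counted once,
under the isomorphism class of its induced subgraph).  Buffering is then
judged on the motif's concrete edge set: a single-edge addition inside
the motif is *destabilising* if it creates a directed cycle of >= 3
nodes.  Motifs admitting zero such additions (and containing no long
cycle already) are *buffered*; exactly one, *mono-unbuffered*; two or
more, *poly-unbuffered*.  A motif that already contains a long cycle is
*unstable* (real GRNs should contain essentially none).

Canonical forms are row-major 0/1 adjacency strings (full n x n, zero
diagonal) under the lexicographically smallest relabelling.  Classes
with the same node count, edge count and number of placements
(n!/|Aut|) are equi-probable in an edge-uniform random network with a
fixed TF set, which is what makes within-group count comparisons fair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd

from .grn import GRN

CATEGORIES = ("buffered", "mono-unbuffered", "poly-unbuffered", "unstable")


# ---------------------------------------------------------------------------
# bit-matrix helpers: a size-n digraph is an int with bit i*n+j for edge i->j


def _edges_to_code(n: int, edges) -> int:
    code = 0
    for i, j in edges:
        if i != j:
            code |= 1 << (i * n + j)
    return code


def _code_has_edge(code: int, n: int, i: int, j: int) -> bool:
    return bool(code >> (i * n + j) & 1)


def _code_to_string(code: int, n: int) -> str:
    return "".join(
        "1" if (i != j and _code_has_edge(code, n, i, j)) else "0"
        for i in range(n)
        for j in range(n)
    )


def _string_to_code(s: str) -> tuple[int, int]:
    n = int(round(len(s) ** 0.5))
    if n * n != len(s):
        raise ValueError(f"adjacency string length {len(s)} is not a square")
    code = 0
    for pos, ch in enumerate(s):
        if ch == "1":
            i, j = divmod(pos, n)
            if i == j:
                raise ValueError("self-loops are not part of motif forms")
            code |= 1 << (i * n + j)
    return code, n


def _permute_code(code: int, n: int, perm: tuple[int, ...]) -> int:
    out = 0
    for i in range(n):
        for j in range(n):
            if i != j and code >> (i * n + j) & 1:
                out |= 1 << (perm[i] * n + perm[j])
    return out


@lru_cache(maxsize=8)
def _perms(n: int) -> tuple[tuple[int, ...], ...]:
    return tuple(itertools.permutations(range(n)))


@lru_cache(maxsize=None)
def _canonical_code(code: int, n: int) -> int:
    return min(_permute_code(code, n, p) for p in _perms(n))


@lru_cache(maxsize=None)
def _automorphisms(code: int, n: int) -> int:
    return sum(1 for p in _perms(n) if _permute_code(code, n, p) == code)


def _is_connected(code: int, n: int) -> bool:
    # weak connectivity on the underlying undirected graph
    adj = [
        [
            j
            for j in range(n)
            if j != i and (code >> (i * n + j) & 1 or code >> (j * n + i) & 1)
        ]
        for i in range(n)
    ]
    seen = {0}
    stack = [0]
    while stack:
        for j in adj[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == n


def _has_long_cycle(code: int, n: int) -> bool:
    """Any directed simple cycle on >= 3 of the n (<= 4) nodes."""
    for k in range(3, n + 1):
        for subset in itertools.combinations(range(n), k):
            first = subset[0]
            for rest in itertools.permutations(subset[1:]):
                seq = (first, *rest, first)
                if all(
                    _code_has_edge(code, n, seq[i], seq[i + 1]) for i in range(k)
                ):
                    return True
    return False


def _has_path_ge2(code: int, n: int, src: int, dst: int) -> bool:
    """Simple path src -> dst with at least 2 edges inside the motif."""
    for k in range(1, n - 1):  # k intermediate nodes
        others = [x for x in range(n) if x not in (src, dst)]
        for mids in itertools.permutations(others, k):
            seq = (src, *mids, dst)
            if all(_code_has_edge(code, n, seq[i], seq[i + 1]) for i in range(len(seq) - 1)):
                return True
    return False


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class MotifClass:
    """One isomorphism class of 3- or 4-node motifs with its buffering."""

    n_nodes: int
    canonical_form: str
    n_edges: int
    placements: int              # n! / |Aut|: distinct labelled embeddings
    destabilizing_additions: int
    category: str

    @property
    def group_key(self) -> tuple[int, int, int]:
        """Classes sharing this key are equi-probable in TF-fixed ensembles."""
        return (self.n_nodes, self.n_edges, self.placements)


@lru_cache(maxsize=None)
def _classify_code(code: int, n: int) -> MotifClass:
    canon = _canonical_code(code, n)
    n_edges = bin(canon).count("1")
    placements = _factorial(n) // _automorphisms(canon, n)
    unstable = _has_long_cycle(canon, n)
    additions = 0
    for i in range(n):
        for j in range(n):
            if i == j or _code_has_edge(canon, n, i, j):
                continue
            # adding i->j closes a long loop iff a >= 2-edge path j ~> i exists
            if _has_path_ge2(canon, n, j, i):
                additions += 1
    if unstable:
        category = "unstable"
    elif additions == 0:
        category = "buffered"
    elif additions == 1:
        category = "mono-unbuffered"
    else:
        category = "poly-unbuffered"
    return MotifClass(
        n_nodes=n,
        canonical_form=_code_to_string(canon, n),
        n_edges=n_edges,
        placements=placements,
        destabilizing_additions=additions,
        category=category,
    )


def _factorial(n: int) -> int:
    out = 1
    for k in range(2, n + 1):
        out *= k
    return out


def canonical_form(edges, nodes=None) -> str:
    """Canonical adjacency string for a small motif given as edge pairs."""
    nodes = sorted(nodes if nodes is not None else {x for e in edges for x in e})
    n = len(nodes)
    if n not in (3, 4):
        raise ValueError("motifs must have 3 or 4 nodes")
    idx = {v: i for i, v in enumerate(nodes)}
    code = _edges_to_code(n, [(idx[u], idx[v]) for u, v in edges])
    return _code_to_string(_canonical_code(code, n), n)


def classify_buffering(motif) -> MotifClass:
    """Classify a 3- or 4-node motif by its buffering against edge addition.

    ``motif`` is either a canonical adjacency string (row-major 0/1, as
    produced by :func:`canonical_form`) or an iterable of edge pairs.
    """
    if isinstance(motif, str):
        code, n = _string_to_code(motif)
    else:
        edges = list(motif)
        nodes = sorted({x for e in edges for x in e})
        n = len(nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        code = _edges_to_code(n, [(idx[u], idx[v]) for u, v in edges])
    if n not in (3, 4):
        raise ValueError("motifs must have 3 or 4 nodes")
    return _classify_code(code, n)


def all_motif_classes(size: int, connected_only: bool = True) -> list[MotifClass]:
    """Every isomorphism class of ``size``-node digraphs (no self-loops)."""
    if size not in (3, 4):
        raise ValueError("size must be 3 or 4")
    seen: dict[int, MotifClass] = {}
    npairs = size * (size - 1)
    pairs = [(i, j) for i in range(size) for j in range(size) if i != j]
    for mask in range(1 << npairs):
        code = 0
        for b, (i, j) in enumerate(pairs):
            if mask >> b & 1:
                code |= 1 << (i * size + j)
        canon = _canonical_code(code, size)
        if canon in seen:
            continue
        if connected_only and not _is_connected(canon, size):
            continue
        seen[canon] = _classify_code(canon, size)
    return sorted(seen.values(), key=lambda m: (m.n_edges, m.canonical_form))


# ---------------------------------------------------------------------------
# census (ESU enumeration of connected induced subgraphs)


def _esu_subsets(adj: list[set[int]], k: int):
    """Wernicke's ESU: yield every connected k-subset exactly once."""
    n = len(adj)
    for v in range(n):
        ext = {u for u in adj[v] if u > v}
        yield from _esu_extend([v], ext, v, adj, k)


def _esu_extend(sub: list[int], ext: set[int], v: int, adj: list[set[int]], k: int):
    if len(sub) == k:
        yield tuple(sub)
        return
    ext = set(ext)
    while ext:
        w = ext.pop()
        # exclusive neighbourhood: neighbours of w not adjacent to current sub
        sub_nbrs = set().union(*(adj[u] for u in sub)) | set(sub)
        new_ext = ext | {u for u in adj[w] if u > v and u not in sub_nbrs}
        yield from _esu_extend(sub + [w], new_ext, v, adj, k)


@dataclass
class MotifTable:
    """Observed counts per motif isomorphism class."""

    size: int
    table: pd.DataFrame    # indexed by canonical_form

    def __len__(self) -> int:
        return len(self.table)

    @property
    def total(self) -> int:
        return int(self.table["observed_count"].sum())

    def category_totals(self) -> pd.Series:
        return self.table.groupby("category")["observed_count"].sum()

    def to_dict(self) -> dict:
        return {
            "schema": "bqsnet/motif-table-v1",
            "size": self.size,
            "classes": self.table.reset_index().to_dict(orient="records"),
        }


def enumerate_motifs(g: GRN, size: int, restrict_to_tfs: bool = True) -> MotifTable:
    """Census of connected induced ``size``-node subgraphs of the TF subnetwork."""
    if size not in (3, 4):
        raise ValueError("size must be 3 or 4")
    h = g.to_networkx(tf_only=restrict_to_tfs)
    nodes = sorted(h.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    und: list[set[int]] = [set() for _ in range(n)]
    succ: list[set[int]] = [set() for _ in range(n)]
    for u, v in h.edges:
        iu, iv = idx[u], idx[v]
        succ[iu].add(iv)
        und[iu].add(iv)
        und[iv].add(iu)

    counts: dict[int, int] = {}
    cache: dict[int, int] = {}  # induced code -> canonical code
    for subset in _esu_subsets(und, size):
        sub = sorted(subset)
        code = 0
        for a, i in enumerate(sub):
            si = succ[i]
            for b, j in enumerate(sub):
                if j in si:
                    code |= 1 << (a * size + b)
        canon = cache.get(code)
        if canon is None:
            canon = _canonical_code(code, size)
            cache[code] = canon
        counts[canon] = counts.get(canon, 0) + 1

    rows = []
    for canon, cnt in counts.items():
        mc = _classify_code(canon, size)
        rows.append(
            {
                "canonical_form": mc.canonical_form,
                "n_edges": mc.n_edges,
                "placements": mc.placements,
                "destabilizing_additions": mc.destabilizing_additions,
                "category": mc.category,
                "observed_count": cnt,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "canonical_form",
            "n_edges",
            "placements",
            "destabilizing_additions",
            "category",
            "observed_count",
        ],
    )
    if len(df):
        df = df.sort_values(["n_edges", "canonical_form"]).set_index("canonical_form")
    else:
        df = df.set_index("canonical_form")
    return MotifTable(size=size, table=df)


def equiprobability_groups(table: MotifTable) -> dict[tuple[int, int, int], list[str]]:
    """Partition observed classes by (n_nodes, n_edges, placements).

    Within a group, expected counts under the TF-fixed edge-uniform
    random model are equal, so observed within-group imbalances are
    informative about selection on motif structure.
    """
    groups: dict[tuple[int, int, int], list[str]] = {}
    for form, row in table.table.iterrows():
        key = (table.size, int(row["n_edges"]), int(row["placements"]))
        groups.setdefault(key, []).append(form)
    return {k: sorted(v) for k, v in sorted(groups.items())}
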