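"""Independent brute-force enumerators used as test oracles.

Everything here works by exhaustive iteration over vertex sequences
(itertools), deliberately sharing no code with the package's census
implementations.  Only feasible for small graphs (<= ~8 nodes).
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_cycle_census(nodes, edges, max_len):
    """Count directed simple cycles per node count, once per cycle.

    Fixes the minimum node first to avoid counting rotations.
    """
    nodes = sorted(nodes)
    edge_set = set(edges)
    counts = {L: 0 for L in range(2, max_len + 1)}
    for k in range(2, min(max_len, len(nodes)) + 1):
        for subset in itertools.combinations(nodes, k):
            first = subset[0]
            for rest in itertools.permutations(subset[1:]):
                seq = (first, *rest)
                if all(
                    (seq[i], seq[(i + 1) % k]) in edge_set for i in range(k)
                ):
                    counts[k] += 1
    return counts


def brute_path_census(nodes, edges, max_len):
    """Count directed simple paths per edge count (each orientation once)."""
    nodes = sorted(nodes)
    edge_set = set(edges)
    counts = {L: 0 for L in range(1, max_len + 1)}
    for k in range(1, min(max_len, len(nodes) - 1) + 1):
        for seq in itertools.permutations(nodes, k + 1):
            if all((seq[i], seq[i + 1]) in edge_set for i in range(k)):
                counts[k] += 1
    return counts


def brute_incomplete_census(nodes, edges, max_len):
    """Simple paths whose closing edge (last -> first) is absent."""
    nodes = sorted(nodes)
    edge_set = set(edges)
    counts = {L: 0 for L in range(2, max_len + 1)}
    for k in range(2, min(max_len, len(nodes) - 1) + 1):
        for seq in itertools.permutations(nodes, k + 1):
            if all((seq[i], seq[i + 1]) in edge_set for i in range(k)):
                if (seq[-1], seq[0]) not in edge_set:
                    counts[k] += 1
    return counts


def brute_is_destabilizing(nodes, edges, u, v, max_len):
    """Would inserting u->v create a 3..max_len-node cycle?

    Enumerates vertex sequences v .. u: the insertion closes them into
    cycles; destabilising iff some such path has >= 2 edges.
    """
    edge_set = set(edges)
    others = [x for x in nodes if x not in (u, v)]
    for k in range(1, min(max_len - 2, len(others)) + 1):
        for mids in itertools.permutations(others, k):
            seq = (v, *mids, u)
            if all((seq[i], seq[i + 1]) in edge_set for i in range(len(seq) - 1)):
                return True
    return False


def brute_motif_additions(n, edge_set):
    """Destabilising single-edge additions inside an n-node motif.

    For each absent ordered pair, insert it and ask the cycle oracle
    whether a >= 3-node cycle appeared.
    """
    base_long = sum(
        v for L, v in brute_cycle_census(range(n), edge_set, n).items() if L >= 3
    )
    additions = 0
    for i in range(n):
        for j in range(n):
            if i == j or (i, j) in edge_set:
                continue
            after = set(edge_set) | {(i, j)}
            long_after = sum(
                v
                for L, v in brute_cycle_census(range(n), after, n).items()
                if L >= 3
            )
            if long_after > base_long:
                additions += 1
    return additions, base_long > 0


def random_digraph(rng: np.random.Generator, n_nodes: int, p: float):
    """Erdős–Rényi digraph as (nodes, edges) with string labels, no self-loops."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(n_nodes)
        if i != j and rng.random() < p
    ]
    return nodes, edges
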