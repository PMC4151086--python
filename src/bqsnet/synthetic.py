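"""Synthetic networks with analytically known census values.

Two generators:

* :func:`planted_network` assembles node-disjoint directed cycles,
  paths and small motifs plus acyclic filler edges, so the feedback and
  incomplete-loop censuses are known exactly from the construction
  (each planted structure contributes independently because the
  structures share no nodes).  This is the primary cross-module oracle
  for the census code.

* :func:`bqs_compliant_grn` builds a network that satisfies the design
  rules of a buffered, qualitatively stable GRN by construction: TFs
  are arranged in a layered DAG (edges only run from lower to higher
  layer index, so there are no cycles of any length), a requested
  fraction of TFs receives no TF regulation at all (constitutive top
  layer), and the remaining edges point at non-TF targets.  Real-data
  features it does NOT emulate: scale-free degree tails, signed
  interactions, and self-regulation.

Both generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .grn import GRN, GRNError
from .loops import LoopCensus, DEFAULT_MAX_LEN


class PackingError(GRNError):
    """The requested planted structures do not fit in n_genes nodes."""


@dataclass
class PlantSpec:
    """Recipe of node-disjoint planted structures.

    ``planted_cycles`` and ``planted_paths`` map length (cycle nodes /
    path edges) to the number of copies; ``filler_edges`` adds acyclic
    TF -> non-TF edges that touch no planted structure.  ``tf_fraction``
    only scales the node budget check; planted nodes are all designated
    TFs so the censuses see every structure.
    """

    planted_cycles: Mapping[int, int] = field(default_factory=dict)
    planted_paths: Mapping[int, int] = field(default_factory=dict)
    filler_edges: int = 0
    n_genes: Optional[int] = None
    seed: int = 0

    def nodes_needed(self) -> int:
        cyc = sum(L * k for L, k in self.planted_cycles.items())
        pth = sum((L + 1) * k for L, k in self.planted_paths.items())
        filler = (1 + self.filler_edges) if self.filler_edges else 0
        return cyc + pth + filler

    def validate(self) -> None:
        for L, k in self.planted_cycles.items():
            if L < 2 or k < 0:
                raise PackingError(f"invalid cycle plant {L}:{k}")
        for L, k in self.planted_paths.items():
            if L < 1 or k < 0:
                raise PackingError(f"invalid path plant {L}:{k}")
        if self.filler_edges < 0:
            raise PackingError("filler_edges must be >= 0")
        if self.n_genes is not None and self.nodes_needed() > self.n_genes:
            raise PackingError(
                f"{self.nodes_needed()} nodes needed but only {self.n_genes} available"
            )


def expected_censuses(spec: PlantSpec, max_len: int = DEFAULT_MAX_LEN) -> dict:
    """Closed-form census ground truth for a planted network.

    Node-disjointness makes contributions additive:

    * an L-cycle holds exactly one feedback loop (length L) and L simple
      paths of every length j = 1..L-1; the j-path closes iff j = L-1,
      so it contributes L incomplete loops at each j = 2..L-2;
    * a k-edge path holds k+1-j simple paths of length j = 1..k, none of
      which closes, so it contributes k+1-j incomplete loops at each
      j = 2..k;
    * filler edges run from one extra TF to non-TF sinks, so the
      TF-restricted censuses (which all of these are) never see them.
    """
    loops = {L: 0 for L in range(2, max_len + 1)}
    inc = {L: 0 for L in range(2, max_len + 1)}
    paths = {L: 0 for L in range(1, max_len + 1)}
    for L, k in spec.planted_cycles.items():
        if k == 0:
            continue
        if L <= max_len:
            loops[L] += k
        for j in range(1, min(L - 1, max_len) + 1):
            paths[j] += k * L
        for j in range(2, min(L - 2, max_len) + 1):
            inc[j] += k * L
    for k_len, k in spec.planted_paths.items():
        if k == 0:
            continue
        for j in range(1, min(k_len, max_len) + 1):
            paths[j] += k * (k_len + 1 - j)
            if j >= 2:
                inc[j] += k * (k_len + 1 - j)
    return {
        "feedback": LoopCensus("feedback", loops, max_len),
        "incomplete": LoopCensus("incomplete", inc, max_len),
        "simple_paths": paths,
    }


def planted_network(
    spec: PlantSpec, max_len: int = DEFAULT_MAX_LEN
) -> tuple[GRN, dict]:
    """Build the planted network and return it with its ground truth.

    All planted nodes (including path end-points) are designated TFs so
    the TF-restricted censuses see the full structures; filler edges run
    from one extra TF to fresh non-TF sinks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    edges: list[tuple[str, str]] = []
    tf_nodes: list[str] = []
    counter = 0

    def fresh(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:04d}"

    for L in sorted(spec.planted_cycles):
        for _ in range(spec.planted_cycles[L]):
            ring = [fresh("c") for _ in range(L)]
            tf_nodes += ring
            edges += [(ring[i], ring[(i + 1) % L]) for i in range(L)]
    for L in sorted(spec.planted_paths):
        for _ in range(spec.planted_paths[L]):
            chain = [fresh("p") for _ in range(L + 1)]
            tf_nodes += chain
            edges += [(chain[i], chain[i + 1]) for i in range(L)]
    if spec.filler_edges:
        hub = fresh("f")
        tf_nodes.append(hub)
        for _ in range(spec.filler_edges):
            edges.append((hub, fresh("x")))

    extra: list[str] = []
    if spec.n_genes is not None:
        total = len({n for e in edges for n in e} | set(tf_nodes))
        extra = [fresh("z") for _ in range(spec.n_genes - total)]
    rng.shuffle(extra)  # placement of padding genes is immaterial but seeded

    grn = GRN(edges, nodes=extra, tf_set=tf_nodes, meta={"planted": True})
    return grn, expected_censuses(spec, max_len)


def bqs_compliant_grn(
    n_genes: int,
    tf_fraction: float = 0.10,
    n_edges: int = 0,
    unregulated_tf_fraction: float = 0.5,
    seed: int = 0,
    tf_edge_fraction: float = 0.10,
) -> GRN:
    """Layered-DAG network obeying the buffered-stability design rules.

    TFs occupy the first ``tf_fraction`` of genes in a fixed order; a
    top layer of ``unregulated_tf_fraction`` of them receives no TF
    regulation.  TF->TF edges only run from a lower-ordered TF to a
    higher-ordered *regulated* TF, so the feedback-loop census is
    identically zero; roughly ``tf_edge_fraction`` of the edges are
    TF->TF (mirroring the sparse TF subnetworks of real GRNs) and every
    regulated TF gets at least one TF regulator, making the unregulated
    count exact.  Remaining edges point at non-TF genes.
    """
    if not 0 < tf_fraction <= 1:
        raise GRNError("tf_fraction must lie in (0, 1]")
    if not 0 <= unregulated_tf_fraction <= 1:
        raise GRNError("unregulated_tf_fraction must lie in [0, 1]")
    n_tfs = max(2, round(n_genes * tf_fraction))
    if n_tfs > n_genes:
        raise GRNError("more TFs than genes")
    n_unreg = round(n_tfs * unregulated_tf_fraction)
    n_reg = n_tfs - n_unreg
    if n_edges < n_reg:
        raise GRNError(
            f"need at least {n_reg} edges to regulate {n_reg} TFs"
        )
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes - 1)))
    names = [f"g{str(i).zfill(width)}" for i in range(n_genes)]
    tfs = names[:n_tfs]                       # order = layer order
    regulated = tfs[n_unreg:]                 # only these may be TF targets
    non_tfs = names[n_tfs:]

    edges: set[tuple[str, str]] = set()
    # guarantee the exact unregulated count: one incoming TF edge each
    for j, tgt in enumerate(regulated, start=n_unreg):
        src = tfs[int(rng.integers(0, j))]    # any lower-ordered TF
        edges.add((src, tgt))
    n_tf_edges = min(
        max(n_reg, round(n_edges * tf_edge_fraction)),
        sum(j for j in range(n_unreg, n_tfs)),  # forward pairs available
        n_edges,
    )
    guard = 0
    while len(edges) < n_tf_edges:
        guard += 1
        if guard > 100 * n_tf_edges + 1000:
            break  # forward TF pairs exhausted; fall through to gene targets
        j = int(rng.integers(n_unreg, n_tfs))
        i = int(rng.integers(0, j))
        edges.add((tfs[i], tfs[j]))
    if not non_tfs and len(edges) < n_edges:
        raise GRNError("no non-TF genes available to absorb remaining edges")
    while len(edges) < n_edges:
        src = tfs[int(rng.integers(0, n_tfs))]
        tgt = non_tfs[int(rng.integers(0, len(non_tfs)))]
        edges.add((src, tgt))
        guard += 1
        if guard > 100 * n_edges + 10_000:
            raise GRNError("edge budget infeasible for the requested shape")
    return GRN(
        edges,
        nodes=names,
        tf_set=tfs,
        meta={
            "generator": "bqs_compliant_grn",
            "seed": seed,
            "unregulated_tfs": n_unreg,
        },
    )
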