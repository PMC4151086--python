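"""Core data model for directed gene regulatory networks (GRNs).

A GRN is a directed graph whose edges run from a transcription factor (TF)
to a gene it transcriptionally regulates.  TFs are, by definition, the
only nodes with outgoing edges; a designated TF set may also be supplied
explicitly (needed for random-network models where a designated TF may end
up with no realised out-edges).  Self-regulating interactions are parsed
and stored but excluded from every census.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

logger = logging.getLogger("bqsnet")

#: recognised interaction signs: activation, repression, dual, unknown
SIGNS = ("+", "-", "±", "?")

_SIGN_ALIASES = {
    "+": "+", "activator": "+", "activation": "+", "positive": "+",
    "-": "-", "repressor": "-", "repression": "-", "negative": "-",
    "+-": "±", "-+": "±", "±": "±", "dual": "±", "d": "±",
    "?": "?", "unknown": "?", "": "?",
}


class GRNError(Exception):
    """Base class for GRN construction and analysis errors."""


class FormatError(GRNError):
    """A dataset file or table does not match its declared dialect."""


class EmptyNetworkError(GRNError):
    """A loaded dataset produced a network with no edges."""


def normalize_sign(token: object) -> str:
    """Map a free-form sign token to one of ``+ - ± ?``."""
    key = str(token).strip().lower()
    try:
        return _SIGN_ALIASES[key]
    except KeyError:
        raise FormatError(f"unrecognised interaction sign {token!r}") from None


class GRN:
    """Directed regulator -> target network with a designated TF subset.

    Parameters
    ----------
    edges
        Iterable of ``(regulator, target)`` pairs.  Duplicates are
        collapsed (set semantics) and self-pairs ``(g, g)`` are diverted
        to :attr:`self_loops`.
    nodes
        Optional additional nodes (e.g. isolated genes).
    tf_set
        Explicit TF designation.  If omitted, the TF set is inferred as
        exactly the nodes with out-degree >= 1.  If supplied, every edge
        source must belong to it.
    signs
        Optional mapping ``(regulator, target) -> sign`` with signs in
        ``{"+", "-", "±", "?"}`` (aliases such as ``activator`` accepted).
        Unlisted edges default to ``"?"``.
    """

    __slots__ = ("nodes", "edges", "tf_set", "signs", "self_loops", "meta")

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        nodes: Optional[Iterable[str]] = None,
        tf_set: Optional[Iterable[str]] = None,
        signs: Optional[Mapping[tuple[str, str], str]] = None,
        meta: Optional[dict] = None,
    ) -> None:
        edge_set: set[tuple[str, str]] = set()
        self_loops: set[tuple[str, str]] = set()
        for u, v in edges:
            if u == v:
                self_loops.add((u, v))
            else:
                edge_set.add((u, v))
        node_set = {u for u, _ in edge_set} | {v for _, v in edge_set}
        node_set |= {u for u, _ in self_loops}
        if nodes is not None:
            node_set |= set(nodes)

        if tf_set is None:
            tfs = {u for u, _ in edge_set}
        else:
            tfs = set(tf_set)
            node_set |= tfs
            bad = {u for u, _ in edge_set} - tfs
            if bad:
                raise GRNError(
                    f"{len(bad)} edge source(s) outside the designated TF set, "
                    f"e.g. {sorted(bad)[:3]}"
                )

        sign_map: dict[tuple[str, str], str] = {}
        if signs:
            for e, s in signs.items():
                key = (e[0], e[1])
                if key in edge_set or key in self_loops:
                    sign_map[key] = normalize_sign(s)

        self.nodes: frozenset[str] = frozenset(node_set)
        self.edges: frozenset[tuple[str, str]] = frozenset(edge_set)
        self.tf_set: frozenset[str] = frozenset(tfs)
        self.signs: dict[tuple[str, str], str] = sign_map
        self.self_loops: frozenset[tuple[str, str]] = frozenset(self_loops)
        self.meta: dict = dict(meta or {})

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_set)

    def sign_of(self, edge: tuple[str, str]) -> str:
        return self.signs.get(edge, "?")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GRN):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.tf_set == other.tf_set
            and self.self_loops == other.self_loops
            and {e: s for e, s in self.signs.items() if s != "?"}
            == {e: s for e, s in other.signs.items() if s != "?"}
        )

    def __hash__(self) -> int:  # GRNs are value objects
        return hash((self.nodes, self.edges, self.tf_set, self.self_loops))

    def __repr__(self) -> str:
        return (
            f"GRN(n_nodes={self.n_nodes}, n_edges={self.n_edges}, "
            f"n_tfs={self.n_tfs}, self_loops={len(self.self_loops)})"
        )

    # -- conversions ------------------------------------------------------

    def to_networkx(self, tf_only: bool = False) -> nx.DiGraph:
        """Return a :class:`networkx.DiGraph` (self-loops excluded).

        With ``tf_only=True``, the induced subgraph on the TF set.
        """
        g = nx.DiGraph()
        if tf_only:
            g.add_nodes_from(self.tf_set)
            g.add_edges_from(
                (u, v) for u, v in self.edges if u in self.tf_set and v in self.tf_set
            )
        else:
            g.add_nodes_from(self.nodes)
            g.add_edges_from(self.edges)
        return g

    def tf_subnetwork(self, recompute_tfs: bool = False) -> "GRN":
        """Induced subgraph on the TF set (self-loops carried along).

        By default the TF designation is inherited, so TFs that lose all
        their TF-directed edges remain designated TFs.  With
        ``recompute_tfs=True`` the TF set is re-inferred from out-degree
        within the subnetwork.
        """
        sub_edges = {
            (u, v) for u, v in self.edges if u in self.tf_set and v in self.tf_set
        }
        sub_loops = {(u, v) for u, v in self.self_loops if u in self.tf_set}
        signs = {e: s for e, s in self.signs.items() if e in sub_edges or e in sub_loops}
        tfs = None if recompute_tfs else self.tf_set
        meta = dict(self.meta)
        meta["tf_set_policy"] = "recomputed" if recompute_tfs else "inherited"
        return GRN(
            sub_edges | sub_loops,
            nodes=self.tf_set,
            tf_set=tfs,
            signs=signs,
            meta=meta,
        )

    # -- degree statistics ------------------------------------------------

    def density(self) -> float:
        """Edge density ``m / (n * (n - 1))``; self-loops excluded."""
        if self.n_nodes < 2:
            raise GRNError("density undefined for networks with fewer than 2 nodes")
        return self.n_edges / (self.n_nodes * (self.n_nodes - 1))

    def count_unregulated_tfs(self) -> tuple[int, float]:
        """TFs with no incoming edge from another TF.

        Returns ``(count, fraction of the TF set)``.  Self-loops are
        ignored (a purely self-regulating TF counts as unregulated).
        """
        if not self.tf_set:
            raise GRNError("count_unregulated_tfs undefined for empty TF set")
        regulated = {
            v for u, v in self.edges if u in self.tf_set and v in self.tf_set
        }
        count = len(self.tf_set - regulated)
        return count, count / len(self.tf_set)

    def cross_regulation(self) -> pd.DataFrame:
        """Per-TF in/out degree within the TF subnetwork.

        Columns ``in_from_tfs`` (number of distinct TF regulators) and
        ``out_to_tfs`` (number of distinct TF targets); self-loops excluded.
        """
        tfs = sorted(self.tf_set)
        idx = {t: i for i, t in enumerate(tfs)}
        indeg = [0] * len(tfs)
        outdeg = [0] * len(tfs)
        for u, v in self.edges:
            if u in self.tf_set and v in self.tf_set:
                outdeg[idx[u]] += 1
                indeg[idx[v]] += 1
        return pd.DataFrame(
            {"in_from_tfs": indeg, "out_to_tfs": outdeg},
            index=pd.Index(tfs, name="tf"),
        )

    def second_order_cross_regulation(self) -> pd.DataFrame:
        """Per-TF second-order out-reach through regulated TFs.

        ``out_of_targets(A)`` sums, over the TF targets B of A, the number
        of TF targets of B - i.e. the number of two-step regulatory routes
        A -> B -> C within the TF subnetwork.
        """
        cross = self.cross_regulation()
        out_to = cross["out_to_tfs"]
        targets: dict[str, list[str]] = {t: [] for t in cross.index}
        for u, v in self.edges:
            if u in self.tf_set and v in self.tf_set:
                targets[u].append(v)
        second = [sum(int(out_to[b]) for b in targets[a]) for a in cross.index]
        return pd.DataFrame(
            {"in_from_tfs": cross["in_from_tfs"], "out_of_targets": second},
            index=cross.index,
        )

    def summary(self) -> dict:
        """JSON-serialisable structural summary."""
        out = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_tfs": self.n_tfs,
            "n_self_loops": len(self.self_loops),
        }
        if self.n_nodes >= 2:
            out["density"] = self.density()
        tf_sub = self.tf_subnetwork()
        out["n_tf_tf_edges"] = tf_sub.n_edges
        if tf_sub.n_nodes >= 2:
            out["tf_density"] = tf_sub.density()
        if self.tf_set:
            n_unreg, frac = self.count_unregulated_tfs()
            out["n_unregulated_tfs"] = n_unreg
            out["unregulated_tf_fraction"] = frac
        return out
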