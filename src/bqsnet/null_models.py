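"""Constrained random-network null models and census ensembles.

Six generation recipes are provided, matched to a real GRN's gene, TF
and edge counts:

========================  =======  =======  ========  ==============
model                     # genes  # edges  # TFs     isolated genes
========================  =======  =======  ========  ==============
``tf_var_ig_allowed``     fixed    fixed    variable  allowed
``tf_fixed_ig_allowed``   fixed    fixed    fixed     allowed
``tf_var_ig_not``         fixed    fixed    variable  not allowed
``tf_fixed_ig_not_v1``    fixed    fixed    fixed     not allowed
``tf_fixed_ig_not_v2``    fixed    fixed    fixed     not allowed
``rewire``                degree-preserving shuffle of a template
========================  =======  =======  ========  ==============

TF-fixed models draw each edge source uniformly from a designated TF
set and the target uniformly from the other genes; TF-variable models
draw sources uniformly from all genes, so the TF count emerges.  The
"not allowed" variants forbid nodes of total degree zero: V1 seeds
every gene with one incoming edge from a random eligible source and
tops up with uniform edges (less biased, needs n_edges >= n_genes); V2
adds uniform edges until no gene is isolated, then adds or removes
uniform edges (removals never isolating a gene) to hit the edge count
exactly.  Duplicate edges and self-targets are resolved by rejection
sampling, which leaves the edge-count distribution unchanged.

All draws come from numpy's seeded PCG64 generator; ensemble rep ``r``
of seed ``s`` uses ``SeedSequence((s, r))``, so ensembles are
reproducible and trivially parallelisable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .grn import GRN, GRNError
from . import loops as _loops
from . import perturb as _perturb

MODELS = (
    "tf_var_ig_allowed",
    "tf_fixed_ig_allowed",
    "tf_var_ig_not",
    "tf_fixed_ig_not_v1",
    "tf_fixed_ig_not_v2",
    "rewire",
)

DEFAULT_METRICS = ("loops", "incomplete", "unregulated", "tf_tf_edges")


class FeasibilityError(GRNError):
    """The requested null-model parameters cannot be satisfied."""


@dataclass
class NullModelSpec:
    """One random-network recipe with its size parameters and seed."""

    model: str
    n_genes: int
    n_tfs: int = 0          # ignored for tf_var models and rewire
    n_edges: int = 0
    seed: int = 0
    template: Optional[GRN] = None      # rewire only
    swap_attempts: Optional[int] = None  # rewire only; default 100 * n_edges

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.model == "rewire":
            if self.template is None:
                raise FeasibilityError("rewire requires a template network")
            self.n_genes = self.template.n_nodes
            self.n_tfs = self.template.n_tfs
            self.n_edges = self.template.n_edges
            return
        if self.n_genes < 2:
            raise FeasibilityError("need at least 2 genes")
        fixed_tfs = self.model.startswith("tf_fixed")
        if fixed_tfs and not 1 <= self.n_tfs <= self.n_genes:
            raise FeasibilityError("n_tfs must lie in [1, n_genes] for TF-fixed models")
        n_sources = self.n_tfs if fixed_tfs else self.n_genes
        max_edges = n_sources * (self.n_genes - 1)
        if not 1 <= self.n_edges <= max_edges:
            raise FeasibilityError(
                f"n_edges must lie in [1, {max_edges}] for this model"
            )
        if self.model == "tf_fixed_ig_not_v1" and self.n_edges < self.n_genes:
            raise FeasibilityError("V1 seeds one incoming edge per gene: needs n_edges >= n_genes")
        if self.model == "tf_var_ig_not" and self.n_edges < self.n_genes:
            raise FeasibilityError("V1 seeding needs n_edges >= n_genes")
        if self.model == "tf_fixed_ig_not_v2" and self.n_edges < max(
            self.n_genes - self.n_tfs, (self.n_genes + 1) // 2
        ):
            raise FeasibilityError("too few edges to cover every gene")

    def describe(self) -> dict:
        return {
            "model": self.model,
            "n_genes": self.n_genes,
            "n_tfs": self.n_tfs,
            "n_edges": self.n_edges,
            "seed": self.seed,
            "swap_attempts": self.swap_attempts,
        }


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{str(i).zfill(width)}" for i in range(n)]


def _fill_edges(
    rng: np.random.Generator,
    chosen: set[int],
    n_edges: int,
    n_sources: int,
    n_genes: int,
) -> None:
    """Top up ``chosen`` (edge codes src * n_genes + tgt) to n_edges edges.

    Sources uniform on [0, n_sources); targets uniform on genes minus the
    source; duplicates rejected.  Mutates ``chosen`` in place.
    """
    while len(chosen) < n_edges:
        k = 2 * (n_edges - len(chosen)) + 16
        src = rng.integers(0, n_sources, size=k)
        tgt = rng.integers(0, n_genes - 1, size=k)
        tgt = tgt + (tgt >= src)
        for s, t in zip(src.tolist(), tgt.tolist()):
            chosen.add(s * n_genes + t)
            if len(chosen) == n_edges:
                break


def _codes_to_grn(
    codes: Sequence[int], n_genes: int, n_tfs: Optional[int]
) -> GRN:
    names = _gene_names(n_genes)
    edges = [(names[c // n_genes], names[c % n_genes]) for c in codes]
    tf_set = names[:n_tfs] if n_tfs is not None else None
    return GRN(edges, nodes=names, tf_set=tf_set)


def _generate_ig_allowed(spec: NullModelSpec, rng: np.random.Generator) -> GRN:
    fixed = spec.model.startswith("tf_fixed")
    n_sources = spec.n_tfs if fixed else spec.n_genes
    chosen: set[int] = set()
    _fill_edges(rng, chosen, spec.n_edges, n_sources, spec.n_genes)
    return _codes_to_grn(sorted(chosen), spec.n_genes, spec.n_tfs if fixed else None)


def _generate_ig_not_v1(spec: NullModelSpec, rng: np.random.Generator) -> GRN:
    fixed = spec.model.startswith("tf_fixed")
    n, n_src = spec.n_genes, (spec.n_tfs if fixed else spec.n_genes)
    if n_src < 2:
        raise FeasibilityError("V1 needs at least 2 eligible sources")
    chosen: set[int] = set()
    # seed: every gene receives one incoming edge from a random source != itself
    for g in range(n):
        while True:
            s = int(rng.integers(0, n_src))
            if s != g:
                break
        chosen.add(s * n + g)
    _fill_edges(rng, chosen, spec.n_edges, n_src, n)
    return _codes_to_grn(sorted(chosen), n, spec.n_tfs if fixed else None)


def _generate_ig_not_v2(spec: NullModelSpec, rng: np.random.Generator) -> GRN:
    n, t = spec.n_genes, spec.n_tfs
    degree = np.zeros(n, dtype=np.int64)
    chosen: set[int] = set()
    n_isolated = n
    # phase 1: add uniform edges until no gene is isolated
    while n_isolated > 0:
        s = int(rng.integers(0, t))
        x = int(rng.integers(0, n - 1))
        x += x >= s
        code = s * n + x
        if code in chosen:
            continue
        chosen.add(code)
        for node in (s, x):
            if degree[node] == 0:
                n_isolated -= 1
            degree[node] += 1
    # phase 2: adjust to the exact edge count
    if len(chosen) < spec.n_edges:
        # additions cannot isolate anyone
        while len(chosen) < spec.n_edges:
            s = int(rng.integers(0, t))
            x = int(rng.integers(0, n - 1))
            x += x >= s
            code = s * n + x
            if code not in chosen:
                chosen.add(code)
                degree[s] += 1
                degree[x] += 1
    else:
        attempts = 0
        max_attempts = 200 * max(len(chosen), 1)
        order = list(chosen)
        while len(chosen) > spec.n_edges:
            attempts += 1
            if attempts > max_attempts:
                raise FeasibilityError(
                    "could not reach the requested edge count without isolating genes"
                )
            code = order[int(rng.integers(0, len(order)))]
            if code not in chosen:
                continue
            s, x = code // n, code % n
            if degree[s] > 1 and degree[x] > 1:
                chosen.remove(code)
                degree[s] -= 1
                degree[x] -= 1
    return _codes_to_grn(sorted(chosen), n, t)


def rewire(
    g: GRN,
    seed: int = 0,
    swap_attempts: Optional[int] = None,
) -> GRN:
    """Degree-preserving shuffle: repeated double-edge swaps.

    Each attempt picks two edges (a, b), (c, d) and replaces them with
    (a, d), (c, b) unless that would create a self-loop or duplicate.
    Every node keeps its exact in- and out-degree, so the TF set is
    preserved.  Default 100 * n_edges attempts; the number of attempts,
    not successful swaps, is fixed for reproducibility.
    """
    rng = np.random.default_rng(seed)
    edges = sorted(g.edges)
    m = len(edges)
    if m < 2:
        return GRN(edges, nodes=g.nodes, tf_set=g.tf_set)
    attempts = swap_attempts if swap_attempts is not None else 100 * m
    present = set(edges)
    for _ in range(attempts):
        i, j = rng.integers(0, m, size=2).tolist()
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b or b == d or a == c:
            continue
        if (a, d) in present or (c, b) in present:
            continue
        present.discard((a, b))
        present.discard((c, d))
        present.add((a, d))
        present.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
    return GRN(edges, nodes=g.nodes, tf_set=g.tf_set)


def generate(spec: NullModelSpec) -> GRN:
    """Draw one random network; identical spec => identical network."""
    if spec.model == "rewire":
        return rewire(spec.template, seed=spec.seed, swap_attempts=spec.swap_attempts)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.model in ("tf_var_ig_allowed", "tf_fixed_ig_allowed"):
        return _generate_ig_allowed(spec, rng)
    if spec.model in ("tf_var_ig_not", "tf_fixed_ig_not_v1"):
        return _generate_ig_not_v1(spec, rng)
    if spec.model == "tf_fixed_ig_not_v2":
        return _generate_ig_not_v2(spec, rng)
    raise ValueError(f"unknown model {spec.model!r}")  # pragma: no cover


def rep_spec(spec: NullModelSpec, rep: int) -> NullModelSpec:
    """Spec for ensemble replicate ``rep`` (documented counter scheme)."""
    out = NullModelSpec(
        model=spec.model,
        n_genes=spec.n_genes,
        n_tfs=spec.n_tfs,
        n_edges=spec.n_edges,
        seed=spec.seed,
        template=spec.template,
        swap_attempts=spec.swap_attempts,
    )
    out.seed = (spec.seed, rep)  # consumed by SeedSequence
    return out


def generate_ensemble(spec: NullModelSpec, n_reps: int) -> list[GRN]:
    return [generate(rep_spec(spec, r)) for r in range(n_reps)]


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class EnsembleSummary:
    """Per-replicate census metrics with means and standard deviations."""

    spec: NullModelSpec
    n_reps: int
    max_len: int
    lengths: list[int] = field(default_factory=list)
    loop_counts: Optional[np.ndarray] = None        # (n_reps, len(lengths))
    incomplete_counts: Optional[np.ndarray] = None
    unregulated_count: Optional[np.ndarray] = None
    unregulated_fraction: Optional[np.ndarray] = None
    tf_tf_edges: Optional[np.ndarray] = None
    probe_probability: Optional[np.ndarray] = None

    def _stats(self, arr: Optional[np.ndarray]):
        if arr is None:
            return None
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1) if self.n_reps > 1 else np.zeros_like(
            arr.mean(axis=0)
        )
        return mean, sd

    def loop_column(self, length: int) -> np.ndarray:
        return self.loop_counts[:, self.lengths.index(length)]

    def incomplete_column(self, length: int) -> np.ndarray:
        return self.incomplete_counts[:, self.lengths.index(length)]

    def to_dict(self) -> dict:
        out = {
            "schema": "bqsnet/ensemble-v1",
            "spec": self.spec.describe(),
            "n_reps": self.n_reps,
            "max_len": self.max_len,
            "lengths": self.lengths,
            "metrics": {},
        }
        for name, arr in (
            ("loop_counts", self.loop_counts),
            ("incomplete_counts", self.incomplete_counts),
            ("unregulated_count", self.unregulated_count),
            ("unregulated_fraction", self.unregulated_fraction),
            ("tf_tf_edges", self.tf_tf_edges),
            ("probe_probability", self.probe_probability),
        ):
            stats = self._stats(arr)
            if stats is None:
                continue
            mean, sd = stats
            out["metrics"][name] = {
                "mean": np.asarray(mean).tolist(),
                "sd": np.asarray(sd).tolist(),
                "values": np.asarray(arr).tolist(),
            }
        return out


def ensemble_census(
    spec: NullModelSpec,
    n_reps: int,
    max_len: int = _loops.DEFAULT_MAX_LEN,
    metrics: Sequence[str] = DEFAULT_METRICS,
    probe_samples: int = 10_000,
) -> EnsembleSummary:
    """Generate ``n_reps`` networks and summarise census metrics.

    ``metrics`` selects among ``loops``, ``incomplete``, ``unregulated``,
    ``tf_tf_edges`` and ``probe`` (sampled probe with ``probe_samples``
    insertions per replicate).  Raw per-replicate values are retained
    for downstream statistics.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    lengths = list(range(2, max_len + 1))
    want = set(metrics)
    unknown = want - {"loops", "incomplete", "unregulated", "tf_tf_edges", "probe"}
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}")
    loop_rows, inc_rows, unreg_n, unreg_f, tft, probe_p = [], [], [], [], [], []
    for r in range(n_reps):
        g = generate(rep_spec(spec, r))
        if "loops" in want:
            census = _loops.count_feedback_loops(g, max_len)
            loop_rows.append([census[L] for L in lengths])
        if "incomplete" in want:
            inc = _loops.count_incomplete_loops(g, max_len)
            inc_rows.append([inc[L] for L in lengths])
        if "unregulated" in want:
            cnt, frac = g.count_unregulated_tfs()
            unreg_n.append(cnt)
            unreg_f.append(frac)
        if "tf_tf_edges" in want:
            tft.append(g.tf_subnetwork().n_edges)
        if "probe" in want:
            res = _perturb.probe_sampled(
                g, n_samples=probe_samples, seed=r, max_len=max_len
            )
            probe_p.append(res.probability)
    return EnsembleSummary(
        spec=spec,
        n_reps=n_reps,
        max_len=max_len,
        lengths=lengths,
        loop_counts=np.array(loop_rows) if loop_rows else None,
        incomplete_counts=np.array(inc_rows) if inc_rows else None,
        unregulated_count=np.array(unreg_n) if unreg_n else None,
        unregulated_fraction=np.array(unreg_f) if unreg_f else None,
        tf_tf_edges=np.array(tft) if tft else None,
        probe_probability=np.array(probe_p) if probe_p else None,
    )
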