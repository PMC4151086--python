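"""Model/Results facade for a full buffered-stability analysis.

:class:`BQSStabilityModel` bundles a network with a null-model
specification; :meth:`~BQSStabilityModel.fit` runs the censuses, the
destabilisation probe, the random ensemble and the statistical
comparison, returning a :class:`BQSStabilityResults` whose
``summary()`` prints the whole analysis as a text table.

    >>> model = BQSStabilityModel(grn)           # doctest: +SKIP
    >>> res = model.fit(n_reps=100, seed=1)      # doctest: +SKIP
    >>> print(res.summary())                     # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import io as _io
from . import loops as _loops
from . import motifs as _motifs
from . import null_models as _null
from . import perturb as _perturb
from . import stats as _stats
from .grn import GRN
from .loops import DEFAULT_MAX_LEN


class BQSStabilityModel:
    """Buffered-stability analysis of one GRN against a random null model.

    Parameters
    ----------
    grn
        The network to analyse.
    null_spec
        Null-model recipe; defaults to the TF-fixed, isolated-genes-
        allowed model matched to the network's gene/TF/edge counts (the
        standard chance baseline).
    max_len
        Census horizon: cycles and paths are enumerated up to this many
        edges (default 14).
    """

    def __init__(
        self,
        grn: GRN,
        null_spec: Optional[_null.NullModelSpec] = None,
        max_len: int = DEFAULT_MAX_LEN,
    ) -> None:
        self.grn = grn
        self.max_len = max_len
        self.null_spec = null_spec  # seed applied at fit time

    @classmethod
    def from_edge_list(cls, path, dialect=None, tf_set=None, **kwargs):
        """Build the model straight from an edge-list file."""
        return cls(_io.load_edge_list(path, dialect=dialect, tf_set=tf_set), **kwargs)

    def _resolve_spec(self, seed: int) -> _null.NullModelSpec:
        if self.null_spec is not None:
            spec = self.null_spec
            spec.seed = seed
            return spec
        return _null.NullModelSpec(
            model="tf_fixed_ig_allowed",
            n_genes=self.grn.n_nodes,
            n_tfs=self.grn.n_tfs,
            n_edges=self.grn.n_edges,
            seed=seed,
        )

    def fit(
        self,
        n_reps: int = 100,
        seed: int = 0,
        probe: str = "auto",
        probe_samples: int = 10_000,
        metrics: Sequence[str] = _null.DEFAULT_METRICS,
        motif_sizes: Sequence[int] = (3, 4),
    ) -> "BQSStabilityResults":
        """Run the full analysis.

        ``probe`` selects the real-network probe mode: ``exhaustive``,
        ``sampled`` or ``auto`` (exhaustive up to 20k candidates).
        """
        g = self.grn
        feedback = _loops.count_feedback_loops(g, self.max_len)
        incomplete = _loops.count_incomplete_loops(g, self.max_len)
        n_unreg, frac_unreg = g.count_unregulated_tfs()

        candidates = _perturb.candidate_insertions(g)
        if probe == "auto":
            probe = "exhaustive" if len(candidates) <= 20_000 else "sampled"
        if probe == "exhaustive":
            probe_result = _perturb.probe_exhaustive(g, self.max_len)
        elif probe == "sampled":
            probe_result = _perturb.probe_sampled(
                g, n_samples=probe_samples, seed=seed, max_len=self.max_len
            )
        else:
            raise ValueError("probe must be 'auto', 'exhaustive' or 'sampled'")

        motif_tables = {
            size: _motifs.enumerate_motifs(g, size) for size in motif_sizes
        }

        spec = self._resolve_spec(seed)
        ensemble = _null.ensemble_census(
            spec, n_reps, max_len=self.max_len,
            metrics=metrics, probe_samples=probe_samples,
        )
        real = {
            "loops": {L: feedback[L] for L in range(2, self.max_len + 1)},
            "incomplete": {L: incomplete[L] for L in range(2, self.max_len + 1)},
            "unregulated_count": n_unreg,
            "probe_probability": probe_result.probability,
        }
        comparison = _stats.compare_real_vs_random(real, ensemble)
        return BQSStabilityResults(
            model=self,
            feedback_census=feedback,
            incomplete_census=incomplete,
            unregulated_count=n_unreg,
            unregulated_fraction=frac_unreg,
            probe=probe_result,
            motif_tables=motif_tables,
            ensemble=ensemble,
            comparison=comparison,
            qs_report=_loops.qs_condition_report(g, self.max_len),
        )


@dataclass
class BQSStabilityResults:
    """Fitted buffered-stability analysis."""

    model: BQSStabilityModel
    feedback_census: _loops.LoopCensus
    incomplete_census: _loops.LoopCensus
    unregulated_count: int
    unregulated_fraction: float
    probe: _perturb.ProbeResult
    motif_tables: dict
    ensemble: _null.EnsembleSummary
    comparison: dict
    qs_report: _loops.QSReport = field(repr=False, default=None)

    # -- convenience accessors -------------------------------------------

    @property
    def long_loop_total(self) -> int:
        return self.feedback_census.long_total()

    @property
    def is_qualitatively_stable(self) -> bool:
        """No long loops, no same-sign (or unsigned) 2-node loops, no
        positive self-regulation - the structural stability conditions."""
        r = self.qs_report
        return (
            r.condition1_verdict == "pass"
            and r.condition2_verdict == "pass"
            and r.condition3_verdict == "pass"
        )

    def loop_pvalue(self, length: int) -> Optional[float]:
        entry = self.comparison["metrics"].get("loops", {}).get(str(length))
        if entry is None or entry.get("degenerate"):
            return None
        return entry["p_value"]

    def summary(self) -> str:
        g = self.model.grn
        lines = []
        bar = "=" * 72
        lines.append(bar)
        lines.append("Buffered Qualitative Stability analysis".center(72))
        lines.append(bar)
        lines.append(
            f"Network: {g.n_nodes} genes, {g.n_edges} edges, {g.n_tfs} TFs, "
            f"{g.tf_subnetwork().n_edges} TF-TF edges"
        )
        spec = self.ensemble.spec
        lines.append(
            f"Null model: {spec.model} (n={spec.n_genes}, tfs={spec.n_tfs}, "
            f"m={spec.n_edges}), {self.ensemble.n_reps} replicates, "
            f"max loop length {self.ensemble.max_len}"
        )
        lines.append("-" * 72)
        lines.append(
            f"{'len':>4} {'loops':>8} {'rand mean':>10} {'rand sd':>9} "
            f"{'p':>10}   {'incompl.':>8} {'rand mean':>10}"
        )
        loops_m = self.ensemble._stats(self.ensemble.loop_counts)
        inc_m = self.ensemble._stats(self.ensemble.incomplete_counts)
        for i, L in enumerate(self.ensemble.lengths):
            p = self.loop_pvalue(L)
            p_str = f"{p:10.3g}" if p is not None else f"{'-':>10}"
            lm = f"{loops_m[0][i]:10.1f}" if loops_m else f"{'-':>10}"
            ls = f"{loops_m[1][i]:9.1f}" if loops_m else f"{'-':>9}"
            iv = self.incomplete_census[L]
            im = f"{inc_m[0][i]:10.1f}" if inc_m else f"{'-':>10}"
            lines.append(
                f"{L:>4} {self.feedback_census[L]:>8} {lm} {ls} {p_str}   "
                f"{iv:>8} {im}"
            )
        lines.append("-" * 72)
        lines.append(
            f"Long feedback loops (>=3 nodes): {self.long_loop_total}"
            f"   qualitatively stable: {self.is_qualitatively_stable}"
        )
        lines.append(
            f"Unregulated TFs: {self.unregulated_count}/{g.n_tfs} "
            f"({100 * self.unregulated_fraction:.1f}%)"
        )
        unreg = self.comparison["metrics"].get("unregulated_tfs")
        if unreg and not unreg.get("degenerate"):
            lines.append(
                f"  vs random: mean {unreg['mean']:.1f} sd {unreg['sd']:.1f}, "
                f"upper-tail p = {unreg['p_value']:.3g}"
            )
        lines.append(
            f"Destabilisation probe [{self.probe.method}]: "
            f"{self.probe.n_destabilizing} of "
            f"{self.probe.n_candidates if self.probe.method == 'exhaustive' else 'sampled'}"
            f" insertions create a long loop "
            f"(p = {self.probe.probability:.4f})"
        )
        for size, table in sorted(self.motif_tables.items()):
            cats = table.category_totals().to_dict()
            cat_str = ", ".join(f"{k}: {v}" for k, v in sorted(cats.items()))
            lines.append(f"{size}-node motifs ({table.total} instances): {cat_str}")
        lines.append(bar)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "schema": "bqsnet/results-v1",
            "network": self.model.grn.summary(),
            "feedback_census": self.feedback_census.to_dict(),
            "incomplete_census": self.incomplete_census.to_dict(),
            "unregulated_count": self.unregulated_count,
            "unregulated_fraction": self.unregulated_fraction,
            "probe": self.probe.to_dict(),
            "motifs": {
                str(size): t.to_dict() for size, t in self.motif_tables.items()
            },
            "comparison": self.comparison,
            "qs_report": self.qs_report.to_dict() if self.qs_report else None,
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text + "\n")
        return text
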