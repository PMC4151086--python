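"""Normal-tail statistics for comparing a real GRN to a null ensemble.

Loop counts in random ensembles are heavily skewed, but the transform
``y = log(n + 1)`` renders them approximately normal (checked with the
Shapiro-Wilk test, which here is diagnostic, not gating).  Tail
probabilities for an observed count are then read off the fitted normal
on the transformed scale; the result is invariant to the log base
because the z-score is affine-invariant.  Counts that are already
approximately normal (e.g. numbers of unregulated TFs) use the identity
transform.  Analyses are per loop length, never pooled across lengths:
counts at different lengths are strongly dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .grn import GRNError
from .null_models import EnsembleSummary


class DegenerateEnsembleError(GRNError):
    """The ensemble is constant: no spread to fit a normal to."""


@dataclass
class PValueEstimate:
    """One-sided normal-tail probability of an observed census value."""

    metric: str
    transform: str          # "log1p" | "identity"
    mean: float             # fitted on the transformed scale
    sd: float
    shapiro_p: float
    observed: float         # on the raw scale
    z: float
    p_value: float
    tail: str               # "lower" | "upper"

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "transform": self.transform,
            "mean": self.mean,
            "sd": self.sd,
            "shapiro_p": self.shapiro_p,
            "observed": self.observed,
            "z": self.z,
            "p_value": self.p_value,
            "tail": self.tail,
        }


def _fit(values: np.ndarray, metric: str) -> tuple[float, float, float]:
    if len(values) < 3:
        raise GRNError(f"{metric}: need at least 3 ensemble values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise DegenerateEnsembleError(
            f"{metric}: ensemble values are all equal ({values[0]!r}); "
            "tail probability undefined"
        )
    shapiro_p = float(sps.shapiro(values).pvalue)
    return mean, sd, shapiro_p


def loop_zero_probability(
    ensemble_counts,
    observed: int = 0,
    metric: str = "loops",
    tail: str = "lower",
) -> PValueEstimate:
    """Tail probability of an observed loop count under the fitted log-normal.

    Fits a normal to ``log(n + 1)`` of the ensemble counts at one loop
    length and returns the one-sided tail probability of the observed
    count (default: lower tail of observing zero loops).
    """
    values = np.log1p(np.asarray(ensemble_counts, dtype=float))
    mean, sd, shapiro_p = _fit(values, metric)
    y = math.log1p(float(observed))
    z = (y - mean) / sd
    p = float(sps.norm.cdf(z) if tail == "lower" else sps.norm.sf(z))
    return PValueEstimate(
        metric=metric, transform="log1p", mean=mean, sd=sd,
        shapiro_p=shapiro_p, observed=float(observed), z=z, p_value=p,
        tail=tail,
    )


def count_tail_probability(
    ensemble_counts,
    observed: float,
    tail: str = "upper",
    metric: str = "count",
) -> PValueEstimate:
    """One-sided normal tail probability on the raw (identity) scale."""
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    values = np.asarray(ensemble_counts, dtype=float)
    mean, sd, shapiro_p = _fit(values, metric)
    z = (float(observed) - mean) / sd
    p = float(sps.norm.cdf(z) if tail == "lower" else sps.norm.sf(z))
    return PValueEstimate(
        metric=metric, transform="identity", mean=mean, sd=sd,
        shapiro_p=shapiro_p, observed=float(observed), z=z, p_value=p,
        tail=tail,
    )


def compare_real_vs_random(
    real: dict,
    summary: EnsembleSummary,
    min_len: int = 2,
) -> dict:
    """Per-metric comparison report of a real network against an ensemble.

    ``real`` carries the observed census values::

        {"loops": {length: count}, "incomplete": {length: count},
         "unregulated_count": int}

    Loop and incomplete-loop counts are compared per length on the
    log1p scale in the lower tail (the stability prediction is *fewer*
    loops than chance); unregulated-TF counts on the identity scale in
    the upper tail (the prediction is *more* unregulated TFs).  Lengths
    whose ensemble is degenerate (constant counts) are reported as such
    rather than dropped silently.
    """
    report: dict = {
        "schema": "bqsnet/comparison-v1",
        "n_reps": summary.n_reps,
        "max_len": summary.max_len,
        "metrics": {},
    }

    def _per_length(name: str, observed_map: dict, column) -> None:
        if observed_map is None:
            return
        entries = {}
        for L in summary.lengths:
            if L < min_len:
                continue
            obs = int(observed_map.get(L, 0))
            counts = column(L)
            try:
                est = loop_zero_probability(
                    counts, observed=obs, metric=f"{name}[{L}]", tail="lower"
                )
                entries[str(L)] = est.to_dict()
            except DegenerateEnsembleError:
                entries[str(L)] = {
                    "metric": f"{name}[{L}]",
                    "observed": obs,
                    "ensemble_constant": float(counts[0]),
                    "degenerate": True,
                }
        report["metrics"][name] = entries

    if "loops" in real and summary.loop_counts is not None:
        _per_length("loops", real["loops"], summary.loop_column)
    if "incomplete" in real and summary.incomplete_counts is not None:
        _per_length("incomplete", real["incomplete"], summary.incomplete_column)
    if "unregulated_count" in real and summary.unregulated_count is not None:
        est = count_tail_probability(
            summary.unregulated_count,
            observed=real["unregulated_count"],
            tail="upper",
            metric="unregulated_tfs",
        )
        report["metrics"]["unregulated_tfs"] = est.to_dict()
    if "probe_probability" in real and summary.probe_probability is not None:
        est = count_tail_probability(
            summary.probe_probability,
            observed=real["probe_probability"],
            tail="lower",
            metric="probe_probability",
        )
        report["metrics"]["probe_probability"] = est.to_dict()
    return report
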