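"""Readers and writers for GRN edge-list dialects.

Supported input dialects:

* plain / ENCODE-style edge-list TSV (two or more columns, configurable
  column names, e.g. ``enets8.GM_proximal_filtered_network.txt``);
* RegulonDB-style tables with per-interaction evidence-code lists,
  filtered by a minimum number of (optionally "strong") evidence codes;
* binding p-value tables (Harbison/Lee style), either a target x regulator
  matrix or a long-form table, filtered at a strict p-value threshold;
* time-course binding-score tables with one score column per timepoint,
  filtered at a strict score threshold (default 26.9).

The canonical on-disk format is a 3-column TSV ``regulator  target  sign``
with a header row; unknown signs are written as ``?``.  Gene identifiers
are case-preserved and matched exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .grn import GRN, EmptyNetworkError, FormatError, normalize_sign

logger = logging.getLogger("bqsnet")

PathLike = Union[str, Path]

DEFAULT_DIALECT = {
    "sep": "\t",
    "regulator": "regulator",
    "target": "target",
    "sign": None,         # optional sign column
    "header": 0,          # pandas header row; None for headerless files
    "comment": "#",
}


@dataclass(frozen=True)
class EvidenceRecord:
    """One RegulonDB-style interaction with its supporting evidence codes."""

    regulator: str
    target: str
    sign: str = "?"
    evidence_codes: tuple[str, ...] = ()
    strong_flags: tuple[bool, ...] = ()

    def __post_init__(self):
        if not self.evidence_codes:
            raise FormatError(
                f"interaction {self.regulator}->{self.target} has no evidence codes"
            )
        if self.strong_flags and len(self.strong_flags) != len(self.evidence_codes):
            raise FormatError("strong_flags length must match evidence_codes")

    @property
    def n_codes(self) -> int:
        return len(self.evidence_codes)

    @property
    def n_strong(self) -> int:
        return sum(self.strong_flags)


@dataclass(frozen=True)
class TimecourseRecord:
    """One TF->TF binding interaction scored across timepoints."""

    regulator: str
    target: str
    combined_score: float
    score_at_time: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        import math

        vals = [self.combined_score, *self.score_at_time.values()]
        if any(not math.isfinite(float(v)) for v in vals):
            raise FormatError(
                f"non-finite score for {self.regulator}->{self.target}"
            )


# ---------------------------------------------------------------------------
# edge-list dialect


def load_dialect(path: PathLike) -> dict:
    """Read a YAML column-mapping config and merge it over the defaults."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"dialect config {path} must be a mapping")
    merged = dict(DEFAULT_DIALECT)
    merged.update(cfg)
    return merged


def load_edge_list(
    path: PathLike,
    dialect: Optional[Mapping] = None,
    tf_set: Optional[Iterable[str]] = None,
) -> GRN:
    """Load a GRN from a delimited regulator->target edge list.

    Duplicate rows are collapsed, self-pairs are diverted to the GRN's
    self-loop store, and a load report is emitted to the ``bqsnet`` log.
    """
    cfg = dict(DEFAULT_DIALECT)
    if dialect:
        cfg.update(dialect)
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep=cfg["sep"],
            header=cfg["header"],
            comment=cfg.get("comment"),
            dtype=str,
        )
    except pd.errors.EmptyDataError:
        raise EmptyNetworkError(f"{path} contains no data") from None
    if cfg["header"] is None:
        # positional columns: regulator, target[, sign]
        names = ["regulator", "target", "sign"][: df.shape[1]]
        df.columns = names + list(df.columns[len(names):])
        src_col, tgt_col = "regulator", "target"
        sign_col = "sign" if "sign" in df.columns and cfg.get("sign") is not False else None
    else:
        src_col, tgt_col = cfg["regulator"], cfg["target"]
        sign_col = cfg.get("sign")
    missing = [c for c in (src_col, tgt_col) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    if sign_col is not None and sign_col not in df.columns:
        raise FormatError(f"{path}: sign column {sign_col!r} not found")

    df = df.dropna(subset=[src_col, tgt_col])
    if df.empty:
        raise EmptyNetworkError(f"{path} contains no interactions")

    src = [str(x) for x in df[src_col]]
    tgt = [str(x) for x in df[tgt_col]]
    edges = list(zip(src, tgt))
    signs: dict[tuple[str, str], str] = {}
    if sign_col is not None:
        signs = {
            (u, v): normalize_sign(s) for u, v, s in zip(src, tgt, df[sign_col])
        }

    n_rows = len(edges)
    grn = GRN(edges, tf_set=tf_set, signs=signs or None, meta={"source": str(path)})
    n_dup = n_rows - len(set(edges))
    logger.info(
        "loaded %s: %d rows, %d duplicates collapsed, %d self-loops diverted, "
        "%d nodes / %d edges / %d TFs",
        path, n_rows, n_dup, len(grn.self_loops),
        grn.n_nodes, grn.n_edges, grn.n_tfs,
    )
    return grn


def write_canonical(grn: GRN, path: PathLike) -> None:
    """Write the canonical 3-column TSV (regulator, target, sign).

    Self-loops are included (they round-trip back into the self-loop
    store on load); rows are sorted for byte-stable output.
    """
    path = Path(path)
    rows = sorted(grn.edges | grn.self_loops)
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tsign\n")
        for u, v in rows:
            fh.write(f"{u}\t{v}\t{grn.sign_of((u, v))}\n")


def network_summary_json(grn: GRN, path: Optional[PathLike] = None) -> str:
    payload = {"schema": "bqsnet/network-summary-v1", **grn.summary()}
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# RegulonDB-style evidence filtering


def read_regulondb_table(
    path: PathLike,
    dialect: Optional[Mapping] = None,
    strong_codes: Optional[Iterable[str]] = None,
) -> list[EvidenceRecord]:
    """Parse a RegulonDB-style TSV into :class:`EvidenceRecord` rows.

    Expected columns (configurable): regulator, target, effect, evidence.
    The evidence cell is a delimited list of codes; a code is flagged
    strong if it appears in ``strong_codes`` or (fallback) if it carries a
    ``[W]``/``[S]`` confidence marker with ``S``.
    """
    cfg = {
        "sep": "\t",
        "regulator": "regulator",
        "target": "target",
        "sign": "effect",
        "evidence": "evidence",
        "evidence_sep": ",",
        "header": 0,
        "comment": "#",
    }
    if dialect:
        cfg.update(dialect)
    df = pd.read_csv(path, sep=cfg["sep"], header=cfg["header"], comment=cfg.get("comment"), dtype=str)
    for col in (cfg["regulator"], cfg["target"], cfg["evidence"]):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    strong = set(strong_codes or ())
    records = []
    for row in df.itertuples(index=False):
        codes = [
            c.strip()
            for c in str(row[df.columns.get_loc(cfg["evidence"])]).split(cfg["evidence_sep"])
            if c.strip()
        ]
        flags = tuple(
            (c in strong) or c.endswith("[S]") or c.startswith("S:") for c in codes
        )
        sign = "?"
        if cfg.get("sign") and cfg["sign"] in df.columns:
            sign = normalize_sign(row[df.columns.get_loc(cfg["sign"])])
        records.append(
            EvidenceRecord(
                regulator=str(row[df.columns.get_loc(cfg["regulator"])]),
                target=str(row[df.columns.get_loc(cfg["target"])]),
                sign=sign,
                evidence_codes=tuple(codes),
                strong_flags=flags,
            )
        )
    return records


def load_regulondb(
    records: Sequence[EvidenceRecord],
    min_codes: int = 2,
    strong_only: bool = False,
    tf_set: Optional[Iterable[str]] = None,
) -> GRN:
    """Build a GRN keeping interactions with enough evidence codes.

    A record is kept iff it is supported by at least ``min_codes``
    evidence codes (``strong_only=False``) or at least ``min_codes``
    strong-flagged codes (``strong_only=True``).  Edge signs are
    preserved.  The default ``min_codes=2`` is the standard confidence
    filter for RegulonDB-style data.
    """
    if min_codes < 1:
        raise ValueError("min_codes must be >= 1")
    kept = [
        r
        for r in records
        if (r.n_strong if strong_only else r.n_codes) >= min_codes
    ]
    logger.info(
        "evidence filter (min_codes=%d, strong_only=%s): kept %d of %d records",
        min_codes, strong_only, len(kept), len(records),
    )
    edges = [(r.regulator, r.target) for r in kept]
    signs = {(r.regulator, r.target): r.sign for r in kept}
    return GRN(edges, tf_set=tf_set, signs=signs)


# ---------------------------------------------------------------------------
# p-value binding tables


def load_pvalue_network(
    table: pd.DataFrame,
    threshold: float = 1e-3,
    long_form: Optional[bool] = None,
    columns: tuple[str, str, str] = ("regulator", "target", "p_value"),
) -> GRN:
    """Build a GRN from binding p-values, keeping edges with ``p < threshold``.

    ``table`` is either a matrix (rows = targets, columns = regulators)
    or a long-form frame with regulator/target/p-value columns.  The
    comparison is strict, so ``p == threshold`` is dropped.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    if long_form is None:
        long_form = all(c in table.columns for c in columns)
    if long_form:
        reg_c, tgt_c, p_c = columns
        missing = [c for c in columns if c not in table.columns]
        if missing:
            raise FormatError(f"long-form p-value table missing columns {missing}")
        sub = table[[reg_c, tgt_c, p_c]].dropna()
        pvals = sub[p_c].astype(float)
        if ((pvals < 0) | (pvals > 1)).any():
            raise FormatError("p-values outside [0, 1]")
        keep = sub[pvals < threshold]
        edges = [(str(u), str(v)) for u, v in zip(keep[reg_c], keep[tgt_c])]
    else:
        vals = table.astype(float)
        if ((vals < 0) | (vals > 1)).any().any():
            raise FormatError("p-values outside [0, 1]")
        edges = [
            (str(reg), str(tgt))
            for reg in vals.columns
            for tgt in vals.index
            if vals.at[tgt, reg] < threshold
        ]
    logger.info("p-value filter (p < %g): %d edges kept", threshold, len(edges))
    return GRN(edges)


# ---------------------------------------------------------------------------
# time-course binding-score tables


def read_timecourse_table(
    path: PathLike,
    score_columns: Mapping[str, str],
    dialect: Optional[Mapping] = None,
) -> list[TimecourseRecord]:
    """Parse a long-form time-course table.

    ``score_columns`` maps timepoint labels (e.g. ``"0hr"``) to the
    column holding the binding score at that timepoint; the combined
    score column is configured in the dialect (default ``combined``).
    """
    cfg = {"sep": "\t", "regulator": "regulator", "target": "target",
           "combined": "combined", "header": 0}
    if dialect:
        cfg.update(dialect)
    df = pd.read_csv(path, sep=cfg["sep"], header=cfg["header"])
    needed = [cfg["regulator"], cfg["target"], cfg["combined"], *score_columns.values()]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TimecourseRecord(
                regulator=str(row[df.columns.get_loc(cfg["regulator"])]),
                target=str(row[df.columns.get_loc(cfg["target"])]),
                combined_score=float(row[df.columns.get_loc(cfg["combined"])]),
                score_at_time={
                    label: float(row[df.columns.get_loc(col)])
                    for label, col in score_columns.items()
                },
            )
        )
    return records


def load_timecourse(
    records: Sequence[TimecourseRecord],
    timepoint: str,
    threshold: float = 26.9,
) -> GRN:
    """Build the GRN active at one timepoint of a binding time course.

    An edge is inserted iff both the combined binding score and the
    score at the requested timepoint exceed ``threshold`` (strictly).
    The records are expected to describe TF->TF interactions only.
    """
    for r in records:
        if timepoint not in r.score_at_time:
            raise FormatError(
                f"timepoint {timepoint!r} missing for {r.regulator}->{r.target}; "
                f"available: {sorted(r.score_at_time)}"
            )
    kept = [
        r
        for r in records
        if r.combined_score > threshold and r.score_at_time[timepoint] > threshold
    ]
    logger.info(
        "time-course filter (score > %g at %s): kept %d of %d records",
        threshold, timepoint, len(kept), len(records),
    )
    edges = [(r.regulator, r.target) for r in kept]
    return GRN(edges)
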