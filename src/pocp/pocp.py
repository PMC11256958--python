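"""Percentage of conserved proteins: filtering, counting, matrices, summaries.

A query protein is *conserved* in a partner proteome when at least one of
its alignment hits satisfies, simultaneously and strictly,

    e-value < 1e-5,  percent identity > 40,  query coverage > 50.

The existential reading ("has a hit") means any passing hit qualifies a
protein, which also makes the result independent of hit-table sort order.
For two proteomes with C1 conserved of T1 and C2 conserved of T2,

    POCP = 100 * (C1 + C2) / (T1 + T2)

symmetric by construction. A POCP above 50% has been proposed as a
genus-level boundary; note that unequal proteome sizes bias the value (a
small proteome paired with a large one caps the achievable POCP), which
this package reports but does not correct.
"""

from __future__ import annotations

import math
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Protocol

import pandas as pd

from . import __version__
from .aligner import KarlinAltschulParams, ScoringScheme, align_proteomes
from .errors import InputError
from .fasta_io import Proteome, validate_run_inputs
from .hits import AlignmentHit, parse_tabular_hits


class NonstandardCriteriaWarning(UserWarning):
    """Raised when filter criteria deviate from the original POCP definition."""


@dataclass(frozen=True)
class FilterCriteria:
    """The three conservation thresholds.

    Defaults reproduce the original POCP criteria. ``strict=True`` (the
    default, and the published convention) rejects hits that sit exactly on
    a threshold.
    """

    max_evalue: float = 1e-5
    min_identity_pct: float = 40.0
    min_coverage_pct: float = 50.0
    strict: bool = True

    def __post_init__(self):
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if not (0 <= self.min_identity_pct <= 100):
            raise ValueError("min_identity_pct must be in [0, 100]")
        if not (0 <= self.min_coverage_pct <= 100):
            raise ValueError("min_coverage_pct must be in [0, 100]")

    def is_default(self) -> bool:
        return self == FilterCriteria()

    def changed_fields(self) -> dict[str, object]:
        default = FilterCriteria()
        return {
            f.name: getattr(self, f.name)
            for f in dc_fields(self)
            if getattr(self, f.name) != getattr(default, f.name)
        }


def nonstandard_criteria_message(criteria: FilterCriteria, version: str = __version__) -> str | None:
    """Warning text when criteria differ from the original definition, else None."""
    changed = criteria.changed_fields()
    if not changed:
        return None
    detail = ", ".join(f"{k}={v}" for k, v in sorted(changed.items()))
    return (
        f"WARNING: nonstandard conservation criteria ({detail}); POCP values are "
        f"not comparable to the original definition. Report these settings and "
        f"the tool version (pocp {version}) alongside any shared results."
    )


def is_conserved(hit: AlignmentHit, criteria: FilterCriteria | None = None) -> bool:
    """Does one hit pass the three conservation filters?"""
    c = criteria or FilterCriteria()
    if c.strict:
        return (
            hit.evalue < c.max_evalue
            and hit.percent_identity > c.min_identity_pct
            and hit.query_coverage > c.min_coverage_pct
        )
    return (
        hit.evalue <= c.max_evalue
        and hit.percent_identity >= c.min_identity_pct
        and hit.query_coverage >= c.min_coverage_pct
    )


def count_conserved(hits: Iterable[AlignmentHit], criteria: FilterCriteria | None = None) -> int:
    """Number of distinct query proteins with at least one passing hit.

    All hits must come from one directed comparison (one query proteome
    against one subject proteome); a query with several passing hits counts
    once.
    """
    c = criteria or FilterCriteria()
    return len({h.query_id for h in hits if is_conserved(h, c)})


def pocp_from_counts(c1: int, c2: int, t1: int, t2: int) -> float:
    """100 * (C1 + C2) / (T1 + T2), with sanity checks on the counts."""
    if t1 < 1 or t2 < 1:
        raise ValueError("total protein counts must be >= 1")
    if not (0 <= c1 <= t1) or not (0 <= c2 <= t2):
        raise ValueError(
            f"conserved counts out of range: c1={c1} (t1={t1}), c2={c2} (t2={t2}); "
            "this indicates an upstream counting bug"
        )
    return 100.0 * (c1 + c2) / (t1 + t2)


@dataclass(frozen=True)
class PairwiseResult:
    """Bidirectional conserved counts and the POCP value for one pair."""

    label_a: str
    label_b: str
    c1: int
    c2: int
    t1: int
    t2: int
    pocp_pct: float


@dataclass(frozen=True)
class SummaryStats:
    n_pairs: int
    min_pocp: float | None
    max_pocp: float | None
    mean_pocp: float | None
    n_pairs_above_genus_threshold: int
    genus_threshold_pct: float = 50.0


@dataclass
class POCPMatrix:
    """Symmetric POCP matrix (diagonal fixed at 100 by convention).

    ``values`` is a label-indexed square DataFrame; cells not computed in
    one-vs-all mode are NaN (written as "NA"), never zero-filled.
    """

    labels: list[str]
    values: pd.DataFrame
    pairs: list[PairwiseResult]
    summary: SummaryStats


class HitBackend(Protocol):
    """Source of directed hits for a (query proteome, subject proteome) pair."""

    def directed_hits(self, query: Proteome, subject: Proteome) -> list[AlignmentHit]: ...


class AlignerBackend:
    """Built-in Smith-Waterman backend.

    *max_evalue* (usually the filter cutoff) lets the aligner drop hits that
    could never pass the e-value filter without tracing them back.
    """

    def __init__(
        self,
        scoring: ScoringScheme | None = None,
        params: KarlinAltschulParams | None = None,
        max_evalue: float | None = None,
    ):
        self.scoring = scoring or ScoringScheme()
        self.params = params or KarlinAltschulParams()
        self.max_evalue = max_evalue

    def directed_hits(self, query: Proteome, subject: Proteome) -> list[AlignmentHit]:
        return align_proteomes(
            query, subject, self.scoring, self.params, max_evalue=self.max_evalue
        )


class HitTableBackend:
    """Backend over precomputed directed hit tables, one file per ordered pair."""

    def __init__(self, tables: dict[tuple[str, str], str | Path]):
        self.tables = dict(tables)

    def directed_hits(self, query: Proteome, subject: Proteome) -> list[AlignmentHit]:
        key = (query.label, subject.label)
        if key not in self.tables:
            raise InputError(
                f"missing hit table for directed comparison "
                f"'{query.label}' (query) vs '{subject.label}' (subject)"
            )
        return parse_tabular_hits(self.tables[key], query_proteome=query)


def compare_pair(
    a: Proteome,
    b: Proteome,
    backend: HitBackend | None = None,
    criteria: FilterCriteria | None = None,
) -> PairwiseResult:
    """Bidirectional comparison of two proteomes.

    Runs (or loads) both directions, counts conserved proteins each way, and
    applies the POCP formula. The value is direction-independent:
    compare_pair(a, b) and compare_pair(b, a) agree on pocp_pct.
    """
    criteria = criteria or FilterCriteria()
    if backend is None:
        backend = AlignerBackend(max_evalue=criteria.max_evalue)
    if a.label == b.label:
        raise InputError(f"cannot compare a proteome with itself: '{a.label}'")
    c1 = count_conserved(backend.directed_hits(a, b), criteria)
    c2 = count_conserved(backend.directed_hits(b, a), criteria)
    t1, t2 = a.total_proteins, b.total_proteins
    return PairwiseResult(
        label_a=a.label,
        label_b=b.label,
        c1=c1,
        c2=c2,
        t1=t1,
        t2=t2,
        pocp_pct=pocp_from_counts(c1, c2, t1, t2),
    )


def summarize(
    pairs: list[PairwiseResult], genus_threshold_pct: float = 50.0
) -> SummaryStats:
    """Min/max/mean POCP and the count of pairs strictly above the genus
    threshold; empty input yields undefined (None) min/max/mean."""
    if not pairs:
        return SummaryStats(0, None, None, None, 0, genus_threshold_pct)
    vals = [p.pocp_pct for p in pairs]
    return SummaryStats(
        n_pairs=len(pairs),
        min_pocp=min(vals),
        max_pocp=max(vals),
        mean_pocp=sum(vals) / len(vals),
        n_pairs_above_genus_threshold=sum(1 for v in vals if v > genus_threshold_pct),
        genus_threshold_pct=genus_threshold_pct,
    )


def compute_matrix(
    proteomes: list[Proteome],
    backend: HitBackend | None = None,
    mode: str = "all-vs-all",
    target: str | None = None,
    criteria: FilterCriteria | None = None,
    genus_threshold_pct: float = 50.0,
    threads: int = 1,
) -> POCPMatrix:
    """POCP over all unordered pairs, or only pairs involving *target*.

    The diagonal is set to 100.00 by convention, without computation.
    Pairs may be computed concurrently (*threads* > 1); assembly order is
    deterministic regardless.
    """
    criteria = criteria or FilterCriteria()
    if backend is None:
        backend = AlignerBackend(max_evalue=criteria.max_evalue)
    validate_run_inputs(proteomes)
    labels = [p.label for p in proteomes]
    if mode not in ("all-vs-all", "one-vs-all"):
        raise InputError(f"unknown mode '{mode}'")
    if mode == "one-vs-all":
        if target is None:
            raise InputError("one-vs-all mode requires a target label")
        if target not in labels:
            raise InputError(
                f"target '{target}' is not among the inputs; available labels: "
                + ", ".join(labels)
            )
    msg = nonstandard_criteria_message(criteria)
    if msg:
        warnings.warn(msg, NonstandardCriteriaWarning, stacklevel=2)

    index = {p.label: p for p in proteomes}
    if mode == "all-vs-all":
        todo = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    else:
        todo = [(target, lbl) for lbl in labels if lbl != target]

    def work(pair: tuple[str, str]) -> PairwiseResult:
        return compare_pair(index[pair[0]], index[pair[1]], backend, criteria)

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            pairs = list(pool.map(work, todo))
    else:
        pairs = [work(p) for p in todo]

    values = pd.DataFrame(math.nan, index=labels, columns=labels, dtype=float)
    for lbl in labels:
        values.loc[lbl, lbl] = 100.0
    for pr in pairs:
        values.loc[pr.label_a, pr.label_b] = pr.pocp_pct
        values.loc[pr.label_b, pr.label_a] = pr.pocp_pct
    return POCPMatrix(
        labels=labels,
        values=values,
        pairs=pairs,
        summary=summarize(pairs, genus_threshold_pct),
    )


# ---------------------------------------------------------------------------
# Tab-separated output formats


def write_matrix_tsv(matrix: POCPMatrix, path: str | Path) -> None:
    """Square matrix; labels in the first row/column, 2 decimals, NA missing."""
    with open(path, "w") as handle:
        handle.write("\t".join([""] + matrix.labels) + "\n")
        for row_lbl in matrix.labels:
            cells = [row_lbl]
            for col_lbl in matrix.labels:
                v = matrix.values.loc[row_lbl, col_lbl]
                cells.append("NA" if pd.isna(v) else f"{v:.2f}")
            handle.write("\t".join(cells) + "\n")


def write_long_table_tsv(pairs: list[PairwiseResult], path: str | Path) -> None:
    """One row per computed pair: labels, directed counts, totals, POCP."""
    with open(path, "w") as handle:
        handle.write("label_a\tlabel_b\tc1\tc2\tt1\tt2\tpocp_pct\n")
        for p in pairs:
            handle.write(
                f"{p.label_a}\t{p.label_b}\t{p.c1}\t{p.c2}\t{p.t1}\t{p.t2}\t{p.pocp_pct:.2f}\n"
            )


def read_long_table_tsv(path: str | Path) -> list[PairwiseResult]:
    """Inverse of :func:`write_long_table_tsv` (POCP at printed precision)."""
    pairs = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("label_a\t"):
            raise InputError(f"{path}: not a POCP long-table file")
        for line in handle:
            la, lb, c1, c2, t1, t2, pp = line.rstrip("\n").split("\t")
            pairs.append(
                PairwiseResult(la, lb, int(c1), int(c2), int(t1), int(t2), float(pp))
            )
    return pairs


def write_summary_tsv(
    summary: SummaryStats,
    criteria: FilterCriteria,
    path: str | Path,
    version: str = __version__,
) -> None:
    """Key/value lines: the stats plus the criteria and tool version used."""

    def fmt(v) -> str:
        if v is None:
            return "NA"
        if isinstance(v, float):
            return f"{v:.2f}"
        return str(v)

    rows = [
        ("tool_version", version),
        ("max_evalue", repr(criteria.max_evalue)),
        ("min_identity_pct", repr(criteria.min_identity_pct)),
        ("min_coverage_pct", repr(criteria.min_coverage_pct)),
        ("strict_thresholds", str(criteria.strict)),
        ("n_pairs", summary.n_pairs),
        ("min_pocp", fmt(summary.min_pocp)),
        ("max_pocp", fmt(summary.max_pocp)),
        ("mean_pocp", fmt(summary.mean_pocp)),
        ("genus_threshold_pct", fmt(summary.genus_threshold_pct)),
        ("n_pairs_above_genus_threshold", summary.n_pairs_above_genus_threshold),
    ]
    with open(path, "w") as handle:
        for key, val in rows:
            handle.write(f"{key}\t{val}\n")
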