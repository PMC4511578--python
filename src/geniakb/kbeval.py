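"""Recall/precision/F1 scoring of system query results against gold results.

For each query, the result set from the system-derived knowledge base is
compared with the result set from the gold-derived one.  With ``GS`` the
gold count, ``P`` the system (positive) count and ``TP`` the size of the
intersection:

    recall    = 100 * TP / GS        (0 when GS = 0)
    precision = 100 * TP / P         (0 when P = 0)
    F1        = 2 * R * Pr / (R + Pr)  (0 when R + Pr = 0)

Percentages are reported rounded half-up to two decimals; F1 is computed
from the *unrounded* recall and precision.  Displayed values are zero-padded
to two integer digits (``04.20``, ``00.00``).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .kbquery import QUERY_IDS, ResultSet, run_query
from .rdfkb import DEFAULT_NAMESPACES, NamespaceConfig, TripleGraph

__all__ = [
    "EvalResult",
    "score",
    "score_sets",
    "evaluate_submission",
    "expected_pair_score",
    "format_table",
    "round2",
    "fmt_pct",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (banker's rounding would give 0.125 -> 0.12)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def fmt_pct(x: float) -> str:
    """Display convention: two decimals, zero-padded to two integer digits."""
    return f"{round2(x):05.2f}"


@dataclass(frozen=True)
class EvalResult:
    gold_count: int
    sys_count: int
    tp: int
    recall: float
    precision: float
    f1: float

    def __post_init__(self) -> None:
        if self.tp > min(self.gold_count, self.sys_count):
            raise ValueError(
                f"tp={self.tp} exceeds min(gold={self.gold_count}, "
                f"sys={self.sys_count})"
            )

    def formatted(self) -> str:
        return f"{fmt_pct(self.recall)} / {fmt_pct(self.precision)} / {fmt_pct(self.f1)}"


def score(gold_count: int, sys_count: int, tp: int) -> EvalResult:
    """Score from the three counts; percentages rounded half-up to 2 decimals."""
    if min(gold_count, sys_count, tp) < 0:
        raise ValueError("counts must be non-negative")
    recall = 100.0 * tp / gold_count if gold_count else 0.0
    precision = 100.0 * tp / sys_count if sys_count else 0.0
    f1 = (
        2.0 * recall * precision / (recall + precision)
        if recall + precision > 0
        else 0.0
    )
    return EvalResult(
        gold_count, sys_count, tp,
        recall=round2(recall), precision=round2(precision), f1=round2(f1),
    )


def score_sets(gold: ResultSet, system: ResultSet) -> EvalResult:
    """Score a system result set against gold (set intersection = TP)."""
    if gold.arity != system.arity:
        raise ValueError(
            f"arity mismatch: gold {gold.arity} vs system {system.arity}"
        )
    return score(len(gold.rows), len(system.rows), len(gold.rows & system.rows))


class SpanBaseMismatchError(ValueError):
    """Gold and system graphs cover disjoint documents; scores would be vacuous."""


def _span_doc_bases(g: TripleGraph, cfg: NamespaceConfig) -> set[str]:
    bases = set()
    for _, p, o in g.triples:
        if p == cfg.denoted_by:
            bases.add(o.rsplit("/spans/", 1)[0])
    return bases


def evaluate_submission(
    gold_graph: TripleGraph,
    sys_graph: TripleGraph,
    queries: tuple[str, ...] = QUERY_IDS,
    cfg: NamespaceConfig = DEFAULT_NAMESPACES,
) -> dict[str, EvalResult]:
    """Run each query on both graphs and score the system answers.

    Raises :class:`SpanBaseMismatchError` when the two graphs reference
    disjoint document span bases (nothing could ever match).
    """
    gb = _span_doc_bases(gold_graph, cfg)
    sb = _span_doc_bases(sys_graph, cfg)
    if gb and sb and not (gb & sb):
        raise SpanBaseMismatchError(
            "gold and system graphs share no document span base; "
            "check sourcedb/sourceid/divid and the span_base namespace"
        )
    out: dict[str, EvalResult] = {}
    for q in queries:
        out[q] = score_sets(
            run_query(gold_graph, q, cfg), run_query(sys_graph, q, cfg)
        )
    return out


def expected_pair_score(single_f: float) -> float:
    """Expected pair-retrieval score if pair errors were independent: P x P.

    Finding a pair requires finding both members, so with single-protein
    performance P the expected pair performance is P*P (as a percentage:
    ``100 * (P/100)**2``).  The observed pair scores fall well below this
    bound because collective-vs-distributive grouping adds its own errors.
    """
    if not 0.0 <= single_f <= 100.0:
        raise ValueError("single_f must be a percentage in [0, 100]")
    return round2(100.0 * (single_f / 100.0) ** 2)


def format_table(results: dict[str, EvalResult], fmt: str = "tsv") -> str:
    """Render per-query results with columns query, GS, P, TP, R, Pr, F."""
    header = ("query", "GS", "P", "TP", "R", "Pr", "F")
    rows = [
        (
            q, str(r.gold_count), str(r.sys_count), str(r.tp),
            fmt_pct(r.recall), fmt_pct(r.precision), fmt_pct(r.f1),
        )
        for q, r in results.items()
    ]
    if fmt == "tsv":
        return "\n".join("\t".join(row) for row in (header, *rows))
    if fmt == "markdown":
        lines = ["| " + " | ".join(header) + " |",
                 "|" + "---|" * len(header)]
        lines += ["| " + " | ".join(row) + " |" for row in rows]
        return "\n".join(lines)
    raise ValueError(f"unknown table format {fmt!r}")
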