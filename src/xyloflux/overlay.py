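"""Differential-expression overlay onto the central metabolic map.

The package does not fit differential expression itself; it consumes a
DESeq2-style result table (gene id, log2 fold change, BH-adjusted
p-value) and projects it onto model reactions through their
gene-reaction rules, the way transcript data are drawn onto central
carbon metabolism maps.  Two threshold presets recur in this kind of
analysis: fold change >= 2 with padj <= 0.05 for genome-wide calls, and
fold change >= 1.5 with padj <= 0.05 for the pathway-map overlay.  All
threshold boundaries are closed (>= / <=).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEGRecord",
    "ReactionExpression",
    "GeneRuleError",
    "SchemaError",
    "parse_gene_rule",
    "gene_rule_genes",
    "classify_record",
    "classify_genes",
    "aggregate_to_reactions",
    "rpkm",
    "read_de_table",
    "write_de_table",
    "read_overlay",
    "write_overlay",
    "DE_TABLE_COLUMNS",
]

DE_TABLE_COLUMNS = ["gene_id", "log2FoldChange", "padj", "baseMean"]


class GeneRuleError(ValueError):
    """A gene-reaction rule could not be parsed."""


class SchemaError(ValueError):
    """A table is missing required columns."""


@dataclass
class DEGRecord:
    """One gene-level differential-expression result (contrast vs reference)."""

    gene_id: str
    log2fc: float
    padj: float
    base_mean: float = 0.0


@dataclass
class ReactionExpression:
    """Reaction-level aggregation of gene-level fold changes.

    ``aggregated_log2fc`` is None when the gene rule references no
    measured gene (class ``no_data``).
    """

    reaction_id: str
    aggregated_log2fc: float | None
    padj: float | None
    klass: str  # up | down | unchanged | no_data
    contributing_genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Gene-reaction rules
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gene_rule(rule: str):
    """Parse a boolean AND/OR gene rule into a nested tuple AST.

    Returns ``None`` for an empty rule, ``("gene", id)`` for a single
    gene, ``("and", [...])`` / ``("or", [...])`` otherwise.  ``and``
    binds tighter than ``or``; parentheses group.
    """
    tokens = _TOKEN.findall(rule)
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_atom():
        tok = peek()
        if tok is None:
            raise GeneRuleError(f"unexpected end of rule {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GeneRuleError(f"unbalanced parentheses in rule {rule!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GeneRuleError(f"unexpected token {tok!r} in rule {rule!r}")
        return ("gene", take())

    def parse_and():
        items = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            items.append(parse_atom())
        return items[0] if len(items) == 1 else ("and", items)

    def parse_or():
        items = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            items.append(parse_and())
        return items[0] if len(items) == 1 else ("or", items)

    node = parse_or()
    if pos != len(tokens):
        raise GeneRuleError(f"trailing tokens in rule {rule!r}")
    return node


def gene_rule_genes(rule: str) -> set[str]:
    node = parse_gene_rule(rule)
    out: set[str] = set()

    def walk(n):
        if n is None:
            return
        if n[0] == "gene":
            out.add(n[1])
        else:
            for child in n[1]:
                walk(child)

    walk(node)
    return out


# ---------------------------------------------------------------------------
# Gene-level classification
# ---------------------------------------------------------------------------

def classify_record(log2fc: float, padj: float, fc_threshold: float, alpha: float) -> str:
    """Closed-boundary up/down/unchanged call for one gene."""
    if padj <= alpha:
        if 2.0 ** log2fc >= fc_threshold:
            return "up"
        if 2.0 ** log2fc <= 1.0 / fc_threshold:
            return "down"
    return "unchanged"


def _coerce_records(records) -> list[DEGRecord]:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in DE_TABLE_COLUMNS[:3] if c not in records.columns]
        if missing:
            raise SchemaError(f"DE table missing required columns: {missing}")
        base = (
            records["baseMean"]
            if "baseMean" in records.columns
            else pd.Series(0.0, index=records.index)
        )
        return [
            DEGRecord(str(g), float(fc), float(p) if pd.notna(p) else math.nan, float(b))
            for g, fc, p, b in zip(
                records["gene_id"], records["log2FoldChange"], records["padj"], base
            )
        ]
    return list(records)


def classify_genes(records, fc_threshold: float = 1.5, alpha: float = 0.05):
    """Classify genes as up / down / unchanged.

    ``records`` is a DataFrame with columns gene_id, log2FoldChange,
    padj (baseMean optional) or an iterable of :class:`DEGRecord`.
    Records with a missing (NaN) padj are skipped; the number skipped is
    logged as a warning.

    A gene is ``up`` iff 2**log2fc >= fc_threshold and padj <= alpha,
    ``down`` iff 2**log2fc <= 1/fc_threshold and padj <= alpha.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1 (fold-change scale)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    out: dict[str, str] = {}
    skipped = 0
    for rec in _coerce_records(records):
        if rec.padj is None or math.isnan(rec.padj):
            skipped += 1
            continue
        if not math.isfinite(rec.log2fc):
            skipped += 1
            continue
        out[rec.gene_id] = classify_record(rec.log2fc, rec.padj, fc_threshold, alpha)
    if skipped:
        logger.warning("classify_genes: skipped %d records with missing values", skipped)
    return out


# ---------------------------------------------------------------------------
# Reaction-level aggregation
# ---------------------------------------------------------------------------

def _evaluate_rule(node, table: dict[str, tuple[float, float]], alpha: float):
    """Aggregate a gene-rule AST to one (gene, log2fc, padj) or None.

    Isozymes (OR) follow the strongest significant signal: among the
    significant branches take the one of maximum |log2fc| (falling back
    to the overall maximum when none is significant).  Complexes (AND)
    follow the weakest member: the branch of minimum |log2fc|.  Ties are
    broken by rule order, unmeasured genes are dropped.
    """
    if node is None:
        return None
    if node[0] == "gene":
        val = table.get(node[1])
        if val is None or math.isnan(val[1]) or not math.isfinite(val[0]):
            return None
        return (node[1], val[0], val[1])
    children = [_evaluate_rule(c, table, alpha) for c in node[1]]
    children = [c for c in children if c is not None]
    if not children:
        return None
    if node[0] == "and":
        return min(children, key=lambda c: abs(c[1]))
    sig = [c for c in children if c[2] <= alpha]
    pool = sig if sig else children
    return max(pool, key=lambda c: abs(c[1]))


def aggregate_to_reactions(
    model, records, fc_threshold: float = 1.5, alpha: float = 0.05
) -> list[ReactionExpression]:
    """Project gene-level log2 fold changes onto model reactions.

    Each reaction's gene rule is aggregated (OR = isozymes, AND =
    complex members; see :func:`_evaluate_rule`), then classified with
    the same closed thresholds as :func:`classify_genes`.  Reactions
    whose rule references no measured gene get class ``no_data``.
    """
    recs = _coerce_records(records)
    table = {r.gene_id: (r.log2fc, r.padj) for r in recs}
    out = []
    for rxn in model.reactions.values():
        node = parse_gene_rule(rxn.gene_rule)
        agg = _evaluate_rule(node, table, alpha)
        if agg is None:
            out.append(ReactionExpression(rxn.id, None, None, "no_data", []))
            continue
        gene, fc, padj = agg
        klass = classify_record(fc, padj, fc_threshold, alpha)
        out.append(ReactionExpression(rxn.id, fc, padj, klass, [gene]))
    return out


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

def rpkm(counts, gene_lengths, library_sizes):
    """Reads Per Kilobase per Million mapped reads.

    ``rpkm[g, s] = counts[g, s] * 1e9 / (length[g] * library_size[s])``.

    Parameters
    ----------
    counts : DataFrame or array, genes x samples
    gene_lengths : per-gene transcript length in bp (> 0)
    library_sizes : per-sample mapped read totals (> 0)
    """
    values = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float).reshape(-1, 1)
    libs = np.asarray(library_sizes, dtype=float).reshape(1, -1)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")
    if lengths.shape[0] != values.shape[0] or libs.shape[1] != values.shape[1]:
        raise ValueError("shape mismatch between counts, lengths and library sizes")
    result = values * 1e9 / (lengths * libs)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(result, index=counts.index, columns=counts.columns)
    return result


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_de_table(path) -> pd.DataFrame:
    """Read a DE table TSV (gene_id, log2FoldChange, padj, baseMean).

    Extra columns are preserved; missing required columns raise
    :class:`SchemaError` listing them.
    """
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise SchemaError(
            f"DE table missing required columns: {DE_TABLE_COLUMNS}"
        ) from None
    missing = [c for c in DE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"DE table missing required columns: {missing}")
    return frame


def write_de_table(path, frame: pd.DataFrame) -> None:
    missing = [c for c in DE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"DE table missing required columns: {missing}")
    frame.to_csv(path, sep="\t", index=False)


OVERLAY_COLUMNS = ["reaction_id", "aggregated_log2fc", "class", "contributing_genes"]


def write_overlay(path, results: list[ReactionExpression]) -> None:
    rows = [
        {
            "reaction_id": r.reaction_id,
            "aggregated_log2fc": "" if r.aggregated_log2fc is None else r.aggregated_log2fc,
            "class": r.klass,
            "contributing_genes": ";".join(r.contributing_genes),
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=OVERLAY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_overlay(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in OVERLAY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"overlay table missing required columns: {missing}")
    return frame
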