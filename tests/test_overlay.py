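"""DE classification thresholds, gene-rule aggregation, RPKM, table I/O."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import xyloflux as xf
from xyloflux.overlay import (
    DEGRecord,
    GeneRuleError,
    SchemaError,
    classify_record,
    parse_gene_rule,
    gene_rule_genes,
    _evaluate_rule,
)


def frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2FoldChange", "padj", "baseMean"])


# ---------------------------------------------------------------------------
# gene-level classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "log2fc,padj,fc,alpha,expected",
    [
        (1.0, 0.01, 2.0, 0.05, "up"),          # genome-wide preset
        (1.0, 0.2, 2.0, 0.05, "unchanged"),     # fails alpha
        (math.log2(1.5), 0.05, 1.5, 0.05, "up"),  # both boundaries closed
        (-math.log2(1.5), 0.05, 1.5, 0.05, "down"),
        (0.5, 0.01, 2.0, 0.05, "unchanged"),    # below fold threshold
        (-3.0, 0.01, 2.0, 0.05, "down"),
    ],
)
def test_classification_thresholds(log2fc, padj, fc, alpha, expected):
    assert classify_record(log2fc, padj, fc, alpha) == expected


def test_classify_genes_skips_missing_padj(caplog):
    records = frame(
        [("gA", 2.0, 0.01, 10.0), ("gB", 2.0, float("nan"), 10.0)]
    )
    classes = xf.classify_genes(records, 2.0, 0.05)
    assert classes == {"gA": "up"}


def test_classify_genes_rejects_bad_thresholds():
    records = frame([("gA", 1.0, 0.01, 1.0)])
    with pytest.raises(ValueError):
        xf.classify_genes(records, fc_threshold=0.5)
    with pytest.raises(ValueError):
        xf.classify_genes(records, alpha=1.5)


@given(
    st.lists(
        st.tuples(
            st.floats(-8, 8, allow_nan=False),
            st.floats(0, 1, allow_nan=False),
        ),
        min_size=1,
        max_size=40,
    )
)
@settings(deadline=None, max_examples=60)
def test_negating_fold_changes_swaps_up_and_down(data):
    records = frame(
        [(f"g{i}", fc, p, 1.0) for i, (fc, p) in enumerate(data)]
    )
    neg = frame(
        [(f"g{i}", -fc, p, 1.0) for i, (fc, p) in enumerate(data)]
    )
    a = xf.classify_genes(records, 1.5, 0.05)
    b = xf.classify_genes(neg, 1.5, 0.05)
    counts = lambda d: (
        sum(v == "up" for v in d.values()),
        sum(v == "down" for v in d.values()),
    )
    assert counts(a) == counts(b)[::-1]


@given(
    st.lists(
        st.tuples(
            st.floats(-8, 8, allow_nan=False),
            st.floats(0, 1, allow_nan=False),
        ),
        min_size=1,
        max_size=40,
    ),
    st.floats(1.0, 4.0),
    st.floats(1.0, 4.0),
)
@settings(deadline=None, max_examples=60)
def test_raising_threshold_never_adds_calls(data, t1, t2):
    lo, hi = sorted((t1, t2))
    records = frame([(f"g{i}", fc, p, 1.0) for i, (fc, p) in enumerate(data)])
    called = lambda d: sum(v != "unchanged" for v in d.values())
    assert called(xf.classify_genes(records, hi, 0.05)) <= called(
        xf.classify_genes(records, lo, 0.05)
    )


# ---------------------------------------------------------------------------
# gene-rule parsing and aggregation
# ---------------------------------------------------------------------------

def test_rule_parser_precedence_and_parens():
    assert parse_gene_rule("a") == ("gene", "a")
    assert parse_gene_rule("a and b or c") == (
        "or",
        [("and", [("gene", "a"), ("gene", "b")]), ("gene", "c")],
    )
    assert parse_gene_rule("a and (b or c)") == (
        "and",
        [("gene", "a"), ("or", [("gene", "b"), ("gene", "c")])],
    )
    assert gene_rule_genes("a and (b or c)") == {"a", "b", "c"}
    assert parse_gene_rule("") is None


@pytest.mark.parametrize("rule", ["a and", "(a or b", "and a", "a b and c (", "a (b)"])
def test_rule_parser_rejects_malformed(rule):
    with pytest.raises(GeneRuleError):
        parse_gene_rule(rule)


def brute_force_rule_value(rule, table, alpha):
    """Independent recursive evaluation over explicit branch enumeration."""
    node = parse_gene_rule(rule)

    def ev(n):
        if n[0] == "gene":
            v = table.get(n[1])
            if v is None or math.isnan(v[1]):
                return None
            return (n[1], v[0], v[1])
        vals = [ev(c) for c in n[1]]
        vals = [v for v in vals if v is not None]
        if not vals:
            return None
        if n[0] == "and":
            best = vals[0]
            for v in vals[1:]:
                if abs(v[1]) < abs(best[1]):
                    best = v
            return best
        sig = [v for v in vals if v[2] <= alpha]
        pool = sig if sig else vals
        best = pool[0]
        for v in pool[1:]:
            if abs(v[1]) > abs(best[1]):
                best = v
        return best

    return ev(node)


def test_isozyme_or_takes_strongest_significant():
    table = {"gA": (2.0, 0.01), "gB": (-0.3, 0.01)}
    got = _evaluate_rule(parse_gene_rule("gA or gB"), table, 0.05)
    assert got == ("gA", 2.0, 0.01)


def test_complex_and_takes_weakest_member():
    table = {"gA": (2.0, 0.01), "gB": (-0.3, 0.01)}
    got = _evaluate_rule(parse_gene_rule("gA and gB"), table, 0.05)
    assert got == ("gB", -0.3, 0.01)


def test_aggregation_examples_on_model():
    tsv = (
        "id\tequation\tlb\tub\tgene_rule\tsubsystem\n"
        "iso\t1 a_c -> 1 b_c\t\t\t gA or gB\tEMP\n"
        "cplx\t1 b_c -> 1 a_c\t\t\tgA and gB\tEMP\n"
        "nodata\t1 a_c -> 1 a_e\t\t\tgZ\tTRANSPORT\n"
    )
    model = xf.parse_reaction_table(tsv)
    records = frame([("gA", 2.0, 0.01, 5.0), ("gB", -0.3, 0.01, 5.0)])
    results = {r.reaction_id: r for r in xf.aggregate_to_reactions(model, records, 1.5, 0.05)}
    assert results["iso"].aggregated_log2fc == 2.0
    assert results["iso"].klass == "up"
    assert results["cplx"].aggregated_log2fc == -0.3
    assert results["cplx"].klass == "unchanged"
    assert results["nodata"].klass == "no_data"
    assert results["nodata"].aggregated_log2fc is None


def test_empty_records_all_no_data(core_model):
    results = xf.aggregate_to_reactions(core_model, frame([]), 1.5, 0.05)
    measured = [r for r in results if r.klass != "no_data"]
    assert measured == []


@st.composite
def rules_and_tables(draw):
    genes = [f"g{i}" for i in range(draw(st.integers(2, 6)))]

    def rule(depth):
        if depth == 0 or draw(st.booleans()):
            return draw(st.sampled_from(genes))
        op = draw(st.sampled_from([" and ", " or "]))
        k = draw(st.integers(2, 3))
        return "(" + op.join(rule(depth - 1) for _ in range(k)) + ")"

    text = rule(2)
    table = {
        g: (
            draw(st.floats(-4, 4, allow_nan=False)),
            draw(st.floats(0, 1, allow_nan=False)),
        )
        for g in genes
        if draw(st.integers(0, 3)) > 0  # some genes unmeasured
    }
    return text, table


@given(rules_and_tables())
@settings(deadline=None, max_examples=80)
def test_aggregation_matches_brute_force(case):
    rule, table = case
    got = _evaluate_rule(parse_gene_rule(rule), table, 0.05)
    want = brute_force_rule_value(rule, table, 0.05)
    assert got == want


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

def test_rpkm_direct_arithmetic():
    counts = pd.DataFrame({"s1": [100, 0]}, index=["gA", "gB"])
    out = xf.rpkm(counts, gene_lengths=[1000, 500], library_sizes=[1e7])
    assert out.loc["gA", "s1"] == pytest.approx(10.0)  # 100*1e9/(1e3*1e7)
    assert out.loc["gB", "s1"] == 0.0


def test_rpkm_scaling_and_errors():
    counts = np.array([[100.0, 100.0]])
    a = xf.rpkm(counts, [1000], [1e7, 2e7])
    assert a[0, 1] == pytest.approx(a[0, 0] / 2.0)  # doubling library halves RPKM
    with pytest.raises(ValueError):
        xf.rpkm(counts, [0], [1e7, 1e7])
    with pytest.raises(ValueError):
        xf.rpkm(counts, [1000], [0.0, 1e7])


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def test_de_table_roundtrip_preserves_extras(tmp_path):
    table = frame([("gA", 1.5, 0.001, 200.0)])
    table["extra"] = ["kept"]
    path = tmp_path / "de.tsv"
    xf.write_de_table(path, table)
    again = xf.read_de_table(path)
    assert list(again.columns) == list(table.columns)
    assert again.loc[0, "extra"] == "kept"
    assert again.loc[0, "log2FoldChange"] == 1.5


def test_empty_de_file_is_schema_error(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    with pytest.raises(SchemaError):
        xf.read_de_table(path)


def test_missing_columns_listed(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("gene_id\tlog2FoldChange\ngA\t1.0\n")
    with pytest.raises(SchemaError, match="padj"):
        xf.read_de_table(path)


def test_overlay_write_read(tmp_path, core_model):
    records = frame([("Mtxyd1", 2.5, 0.001, 300.0), ("Mtxyl1", -2.0, 0.002, 300.0)])
    results = xf.aggregate_to_reactions(core_model, records, 1.5, 0.05)
    path = tmp_path / "overlay.tsv"
    xf.write_overlay(path, results)
    table = pd.read_csv(path, sep="\t")
    by_id = table.set_index("reaction_id")
    assert by_id.loc["XDH1", "class"] == "up"
    assert by_id.loc["XYLR", "class"] == "down"
    assert by_id.loc["XYLLACT", "class"] == "no_data"
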