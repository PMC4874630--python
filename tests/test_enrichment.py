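import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathbridge.convert import convert_pathway
from pathbridge.enrichment import (
    DataTable,
    parse_criterion,
    permuted_mean_z,
    qualification_by_identifier,
    run_enrichment,
    zscore,
)
from pathbridge.errors import CriterionError, DomainError
from pathbridge.source_model import SourceEntity, SourcePathway, Xref
from pathbridge.synth import (
    ExpressionSpec,
    FixtureSpec,
    gen_expression_table,
    gen_pathway_collection,
)


class TestCriterion:
    @pytest.mark.parametrize(
        "expr,row,expected",
        [
            ("[P.value] < 0.05", {"P.value": 0.01}, True),
            ("[P.value] < 0.05", {"P.value": 0.2}, False),
            ("abs([logFC]) > 1 AND [P.value] < 0.05", {"logFC": -1.5, "P.value": 0.2}, False),
            ("abs([logFC]) > 1 AND [P.value] < 0.05", {"logFC": -1.5, "P.value": 0.01}, True),
            ("NOT [x] > 0", {"x": -1.0}, True),
            ("[x] = 2 OR [x] = 3", {"x": 3.0}, True),
            ("([x] > 0 AND [y] > 0) OR [x] < -10", {"x": -20.0, "y": 0.0}, True),
            ("(abs([x])) >= 1", {"x": -1.0}, True),
        ],
    )
    def test_evaluation(self, expr, row, expected):
        assert parse_criterion(expr).evaluate(row) is expected

    def test_missing_value_never_qualifies(self):
        crit = parse_criterion("NOT [x] > 0")
        assert crit.evaluate({"x": float("nan")}) is False
        assert crit.evaluate({"x": None}) is False

    @pytest.mark.parametrize("bad", ["[x] <", "[x] 0.05", "frob([x]) > 1", "", "[x] > 1 extra"])
    def test_syntax_errors(self, bad):
        with pytest.raises(CriterionError):
            parse_criterion(bad)

    def test_referenced_columns_reported(self):
        crit = parse_criterion("abs([logFC]) > 1 AND [P.value] < 0.05")
        assert crit.columns == {"logFC", "P.value"}

    def test_differential_against_reference_evaluator(self):
        """Random criterion trees agree with a Python-eval reference on random rows."""
        rng = np.random.default_rng(20260923)
        cols = ["a", "b", "c"]

        def gen_value(depth):
            r = rng.random()
            if r < 0.4 or depth > 2:
                v = round(float(rng.uniform(-3, 3)), 2)
                return (str(v), str(v))
            if r < 0.8:
                col = cols[rng.integers(3)]
                return (f"[{col}]", f"row[{col!r}]")
            crit, ref = gen_value(depth + 1)
            return (f"abs({crit})", f"abs({ref})")

        def gen_bool(depth):
            r = rng.random()
            if r < 0.5 or depth > 2:
                op = ["<", "<=", ">", ">=", "="][rng.integers(5)]
                lc, lr = gen_value(depth)
                rc, rr = gen_value(depth)
                return (f"{lc} {op} {rc}", f"({lr}) {'==' if op == '=' else op} ({rr})")
            if r < 0.65:
                c, p = gen_bool(depth + 1)
                return (f"NOT ({c})", f"not ({p})")
            kw = "AND" if rng.random() < 0.5 else "OR"
            lc, lp = gen_bool(depth + 1)
            rc, rp = gen_bool(depth + 1)
            return (f"({lc}) {kw} ({rc})", f"({lp}) {kw.lower()} ({rp})")

        for _ in range(1000):
            crit_text, py_text = gen_bool(0)
            crit = parse_criterion(crit_text)
            row = {c: round(float(rng.uniform(-3, 3)), 2) for c in cols}
            expected = bool(eval(py_text, {"abs": abs}, {"row": row}))
            assert crit.evaluate(row) is expected, crit_text


class TestZscore:
    def test_zero_when_r_at_expectation(self):
        # r = n R / N exactly
        assert zscore(r=5, n=10, R=50, N=100) == 0.0

    def test_single_draw_matches_bernoulli_standardization(self):
        p = 30 / 100
        expected = (1 - p) / math.sqrt(p * (1 - p))
        assert zscore(r=1, n=1, R=30, N=100) == pytest.approx(expected)

    @pytest.mark.parametrize("r,n,R,N", [(0, 0, 5, 10), (0, 3, 0, 10), (3, 3, 10, 10)])
    def test_degenerate_settings_undefined(self, r, n, R, N):
        assert math.isnan(zscore(r, n, R, N))

    @pytest.mark.parametrize("r,n,R,N", [(5, 3, 6, 10), (1, 3, 0, 10), (0, 5, 4, 4)])
    def test_precondition_violations_raise(self, r, n, R, N):
        with pytest.raises(DomainError):
            zscore(r, n, R, N)

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_in_r(self, data):
        N = data.draw(st.integers(5, 200))
        R = data.draw(st.integers(1, N - 1))
        n = data.draw(st.integers(1, N - 1))
        rmax = min(n, R)
        zs = [zscore(r, n, R, N) for r in range(rmax + 1)]
        assert all(a < b for a, b in zip(zs, zs[1:]))

    def test_moments_match_hypergeometric_simulation(self):
        """The formula's center and scale match hypergeometric sampling."""
        rng = np.random.default_rng(99)
        for _ in range(5):
            N = int(rng.integers(50, 400))
            R = int(rng.integers(5, N - 5))
            n = int(rng.integers(2, N - 1))
            draws = rng.hypergeometric(R, N - R, n, size=20000)
            mean_se = draws.std(ddof=1) / math.sqrt(draws.size)
            assert abs(draws.mean() - n * R / N) < 3 * mean_se + 1e-12
            p = R / N
            var = n * p * (1 - p) * (1 - (n - 1) / (N - 1))
            var_se = draws.var(ddof=1) * math.sqrt(2 / (draws.size - 1))
            assert abs(draws.var(ddof=1) - var) < 4 * var_se + 1e-12


def _table(rows):
    return DataTable(frame=pd.DataFrame(rows), id_column="id")


class TestRunEnrichment:
    def test_probe_collapse_any_qualifies(self):
        table = _table(
            [
                {"id": "probe1", "P.value": 0.5},
                {"id": "probe2", "P.value": 0.01},
            ]
        )
        qual = qualification_by_identifier(
            table, parse_criterion("[P.value] < 0.05"), {"probe1": "G1", "probe2": "G1"}
        )
        assert qual == {"G1": True}

    def test_unknown_criterion_column_names_it(self):
        table = _table([{"id": "a", "P.value": 0.5}])
        with pytest.raises(CriterionError, match="logFC"):
            qualification_by_identifier(table, parse_criterion("[logFC] > 1"))

    def test_planted_pathway_ranks_first(self):
        spec = FixtureSpec()
        collection = gen_pathway_collection(spec, 20, seed=5)
        gpmls = [convert_pathway(p) for p, _ in collection]
        gene_sets = {p.name: t.gene_identifiers() for p, t in collection}
        planted = collection[7][0].name
        table, _ = gen_expression_table(spec.expression, gene_sets, planted, seed=6)
        results = run_enrichment(table, parse_criterion("abs([logFC]) > 1 AND [P.value] < 0.05"), gpmls)
        assert results[0].pathway == planted
        assert results[0].z > results[1].z

    def test_no_qualifying_rows_gives_undefined_z(self):
        table = _table([{"id": f"g{i}", "P.value": 0.9} for i in range(10)])
        nodes = [
            SourceEntity(f"e{i}", f"g{i}", "protein", (10.0 * i, 10.0, 80.0, 25.0),
                         xrefs=[Xref("UniProt", f"g{i}")])
            for i in range(5)
        ]
        p = convert_pathway(SourcePathway(name="pw", organism="h", entities=nodes))
        (res,) = run_enrichment(table, parse_criterion("[P.value] < 0.05"), [p])
        assert res.R == 0 and math.isnan(res.z)

    def test_pathway_containing_all_genes_undefined_and_ranked_last(self):
        table = _table(
            [{"id": "g1", "P.value": 0.01}, {"id": "g2", "P.value": 0.9}]
        )
        all_nodes = [
            SourceEntity("e1", "g1", "protein", (10, 10, 80, 25), xrefs=[Xref("UniProt", "g1")]),
            SourceEntity("e2", "g2", "protein", (90, 10, 80, 25), xrefs=[Xref("UniProt", "g2")]),
        ]
        full = convert_pathway(SourcePathway(name="all", organism="h", entities=all_nodes))
        half = convert_pathway(SourcePathway(name="half", organism="h", entities=all_nodes[:1]))
        results = run_enrichment(table, parse_criterion("[P.value] < 0.05"), [full, half])
        assert results[0].pathway == "half"
        assert math.isnan(results[1].z)  # n = N

    def test_flattened_components_count_toward_n(self):
        """A pathway with complexes scores identically to its complex-free twin."""
        proteins = [
            SourceEntity(f"p{i}", f"PR{i}", "protein", (50.0 * i, 30.0, 80.0, 25.0),
                         xrefs=[Xref("UniProt", f"U{i:04d}")])
            for i in range(1, 7)
        ]
        cx = SourceEntity(
            "cx", "cpx", "complex", (100.0, 120.0, 100.0, 40.0),
            xrefs=[Xref("Reactome", "R-HSA-7")],
            components=[("p5", 1), ("p6", 1)],
        )
        with_complex = SourcePathway(name="with", organism="h", entities=[*proteins, cx])
        without = SourcePathway(name="without", organism="h", entities=proteins)
        table = _table(
            [{"id": f"U{i:04d}", "P.value": 0.01 if i <= 3 else 0.5} for i in range(1, 7)]
            + [{"id": f"BG{i}", "P.value": 0.5} for i in range(30)]
        )
        results = run_enrichment(
            table, parse_criterion("[P.value] < 0.05"),
            [convert_pathway(with_complex), convert_pathway(without)],
        )
        a, b = results
        assert (a.r, a.n, a.z) == (b.r, b.n, b.z)

    def test_empty_table_rejected(self):
        table = DataTable(frame=pd.DataFrame({"id": [], "P.value": []}), id_column="id")
        with pytest.raises(DomainError):
            run_enrichment(table, parse_criterion("[P.value] < 0.05"), [])


def test_permutation_null_mean_z_near_zero():
    """Shuffling qualification labels should center z at zero."""
    rng = np.random.default_rng(17)
    ids = [f"g{i}" for i in range(200)]
    qual = {i: bool(rng.random() < 0.2) for i in ids}
    members = set(rng.choice(ids, size=30, replace=False))
    mean, se = permuted_mean_z(members, qual, 500, rng)
    assert abs(mean) < 3 * se
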