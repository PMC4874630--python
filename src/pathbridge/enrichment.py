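"""Criterion-based over-representation analysis with the standardized z score.

A *criterion* is a boolean expression over named numeric columns of a data
table, e.g. ``abs([logFC]) > 1 AND [P.value] < 0.05`` — the conventional
filter for differentially expressed genes in exploratory pathway analysis.
For each pathway the analysis counts ``n`` measured identifiers on the
pathway and ``r`` of them qualifying under the criterion, against dataset
totals ``N`` and ``R``, and ranks pathways by the standardized score

    z = (r - n R / N) / sqrt( n (R/N) (1 - R/N) (1 - (n-1)/(N-1)) )

i.e. the observed qualifying count centered and scaled by the mean and
variance of a hypergeometric draw of ``n`` from ``N`` with ``R`` successes.
Flattened complex components drawn at the bottom of converted pathways are
ordinary data nodes and therefore count toward ``n``; complex placeholder
nodes do not.

Grammar of criterion expressions (case-insensitive keywords)::

    expr        := and_expr ( OR  and_expr )*
    and_expr    := not_expr ( AND not_expr )*
    not_expr    := NOT not_expr | primary
    primary     := '(' expr ')' | comparison
    comparison  := value ( '<' | '<=' | '>' | '>=' | '=' ) value
    value       := NUMBER | '-' NUMBER | '[' column name ']'
                 | 'abs' '(' value ')' | '(' value ')'

A row with a missing value in any column the criterion references does not
qualify (but still counts as measured).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from pathbridge.errors import CriterionError, DomainError
from pathbridge.gpml import GpmlPathway

# ---------------------------------------------------------------------------
# Data table


@dataclass
class DataTable:
    """Measurement table: identifier column plus named numeric columns."""

    frame: pd.DataFrame
    id_column: str = "id"
    source_column: str | None = None

    def __post_init__(self) -> None:
        if self.id_column not in self.frame.columns:
            raise DomainError(f"identifier column {self.id_column!r} not in table")
        if self.frame.columns.duplicated().any():
            raise DomainError("table column names must be unique")

    @property
    def value_columns(self) -> list[str]:
        skip = {self.id_column, self.source_column}
        return [c for c in self.frame.columns if c not in skip]

    def rows(self) -> Iterable[tuple[str, dict[str, float]]]:
        cols = self.value_columns
        for _, row in self.frame.iterrows():
            yield str(row[self.id_column]), {c: row[c] for c in cols}


def read_data_table(path, sep: str = "\t", id_column: str | None = None) -> DataTable:
    """Read a delimited text table; first column is the identifier by default."""
    frame = pd.read_csv(path, sep=sep, comment="#")
    if frame.empty:
        raise DomainError(f"data table {path} has no rows")
    idc = id_column or frame.columns[0]
    return DataTable(frame=frame, id_column=idc)


# ---------------------------------------------------------------------------
# Criterion expressions

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lbracket>\[(?P<col>[^\]]+)\])
      | (?P<num>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
      | (?P<op><=|>=|<|>|=)
      | (?P<lparen>\()
      | (?P<rparen>\))
      | (?P<word>[A-Za-z_][A-Za-z_0-9.]*)
    )""",
    re.VERBOSE,
)

_KEYWORDS = {"and", "or", "not", "abs"}


def _tokenize(expr: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip() == "":
                break
            raise CriterionError(f"syntax error at position {pos}: {expr[pos:pos+10]!r}")
        if m.group("lbracket"):
            tokens.append(("col", m.group("col"), m.start()))
        elif m.group("num"):
            tokens.append(("num", m.group("num"), m.start()))
        elif m.group("op"):
            tokens.append(("op", m.group("op"), m.start()))
        elif m.group("lparen"):
            tokens.append(("(", "(", m.start()))
        elif m.group("rparen"):
            tokens.append((")", ")", m.start()))
        else:
            word = m.group("word")
            low = word.lower()
            if low in _KEYWORDS:
                tokens.append(("kw", low, m.start()))
            else:
                raise CriterionError(
                    f"unknown name {word!r} at position {m.start()} "
                    "(column names must be bracketed, e.g. [logFC])"
                )
        pos = m.end()
    return tokens


class _Missing(Exception):
    pass


# AST nodes -----------------------------------------------------------------


@dataclass(frozen=True)
class _Col:
    name: str

    def value(self, row: Mapping[str, float]) -> float:
        if self.name not in row:
            raise CriterionError(f"criterion references unknown column {self.name!r}")
        v = row[self.name]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise _Missing()
        return float(v)


@dataclass(frozen=True)
class _Num:
    v: float

    def value(self, row) -> float:
        return self.v


@dataclass(frozen=True)
class _Abs:
    inner: object

    def value(self, row) -> float:
        return abs(self.inner.value(row))


_CMP: dict[str, Callable[[float, float], bool]] = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "=": lambda a, b: a == b,
}


@dataclass(frozen=True)
class _Cmp:
    op: str
    left: object
    right: object

    def test(self, row) -> bool:
        return _CMP[self.op](self.left.value(row), self.right.value(row))


@dataclass(frozen=True)
class _Not:
    inner: object

    def test(self, row) -> bool:
        return not self.inner.test(row)


@dataclass(frozen=True)
class _Bool:
    op: str  # "and" | "or"
    parts: tuple

    def test(self, row) -> bool:
        if self.op == "and":
            return all(p.test(row) for p in self.parts)
        return any(p.test(row) for p in self.parts)


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]]):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, -1)

    def take(self, kind=None, value=None):
        tok = self.peek()
        if tok[0] is None:
            raise CriterionError("unexpected end of expression")
        if kind is not None and tok[0] != kind or value is not None and tok[1] != value:
            raise CriterionError(
                f"unexpected token {tok[1]!r} at position {tok[2]}"
            )
        self.i += 1
        return tok

    def expr(self):
        parts = [self.and_expr()]
        while self.peek()[:2] == ("kw", "or"):
            self.take()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else _Bool("or", tuple(parts))

    def and_expr(self):
        parts = [self.not_expr()]
        while self.peek()[:2] == ("kw", "and"):
            self.take()
            parts.append(self.not_expr())
        return parts[0] if len(parts) == 1 else _Bool("and", tuple(parts))

    def not_expr(self):
        if self.peek()[:2] == ("kw", "not"):
            self.take()
            return _Not(self.not_expr())
        return self.primary()

    def primary(self):
        tok = self.peek()
        if tok[0] == "(":
            # could be a parenthesized boolean or a parenthesized value
            mark = self.i
            try:
                self.take("(")
                inner = self.expr()
                self.take(")")
                return inner
            except CriterionError:
                self.i = mark
        return self.comparison()

    def comparison(self):
        left = self.value()
        tok = self.peek()
        if tok[0] != "op":
            raise CriterionError(
                f"expected a comparison operator at position {tok[2]}"
                if tok[0] is not None
                else "expected a comparison operator at end of expression"
            )
        op = self.take("op")[1]
        right = self.value()
        return _Cmp(op, left, right)

    def value(self):
        tok = self.peek()
        if tok[0] == "num":
            self.take()
            return _Num(float(tok[1]))
        if tok[0] == "col":
            self.take()
            return _Col(tok[1])
        if tok[:2] == ("kw", "abs"):
            self.take()
            self.take("(")
            inner = self.value()
            self.take(")")
            return _Abs(inner)
        if tok[0] == "(":
            self.take("(")
            inner = self.value()
            self.take(")")
            return inner
        raise CriterionError(
            f"expected a value at position {tok[2]}"
            if tok[0] is not None
            else "expected a value at end of expression"
        )


@dataclass(frozen=True)
class Criterion:
    """A parsed boolean filter over table columns."""

    expression: str
    tree: object = field(compare=False, repr=False, default=None)

    @property
    def columns(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node):
            if isinstance(node, _Col):
                out.add(node.name)
            elif isinstance(node, _Cmp):
                walk(node.left), walk(node.right)
            elif isinstance(node, _Abs):
                walk(node.inner)
            elif isinstance(node, _Not):
                walk(node.inner)
            elif isinstance(node, _Bool):
                for p in node.parts:
                    walk(p)

        walk(self.tree)
        return frozenset(out)

    def evaluate(self, row: Mapping[str, float]) -> bool:
        """True iff the row qualifies; missing referenced values → False."""
        try:
            return self.tree.test(row)
        except _Missing:
            return False


def parse_criterion(expr: str) -> Criterion:
    """Parse a criterion expression; raises CriterionError with position info."""
    tokens = _tokenize(expr)
    if not tokens:
        raise CriterionError("empty criterion expression")
    parser = _Parser(tokens)
    tree = parser.expr()
    if parser.i != len(tokens):
        tok = parser.peek()
        raise CriterionError(f"trailing input {tok[1]!r} at position {tok[2]}")
    return Criterion(expression=expr, tree=tree)


# ---------------------------------------------------------------------------
# Z score


def zscore(r: int, n: int, R: int, N: int) -> float:
    """Standardized over-representation score for counts (r, n, R, N).

    Centers r at its hypergeometric mean n·R/N and scales by the finite
    population variance n·(R/N)·(1−R/N)·(1−(n−1)/(N−1)).  Returns NaN when
    the variance is zero (n = 0, n = N, R = 0, or R = N).
    """
    if N < 2:
        raise DomainError(f"N must be at least 2, got {N}")
    if not (0 <= r <= n <= N):
        raise DomainError(f"need 0 <= r <= n <= N, got r={r}, n={n}, N={N}")
    if not (r <= R <= N):
        raise DomainError(f"need r <= R <= N, got r={r}, R={R}, N={N}")
    p = R / N
    var = n * p * (1.0 - p) * (1.0 - (n - 1) / (N - 1))
    if var <= 0.0:
        return math.nan
    return (r - n * p) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Over-representation analysis


@dataclass
class EnrichmentResult:
    pathway: str
    source: str
    r: int
    n: int
    R: int
    N: int
    z: float


def qualification_by_identifier(
    table: DataTable,
    crit: Criterion,
    id_mapper: Callable[[str], str] | Mapping[str, str] | None = None,
) -> dict[str, bool]:
    """Collapse probe rows to identifiers: qualifying if ANY probe qualifies."""
    missing = crit.columns - set(table.value_columns)
    if missing:
        raise CriterionError(
            f"criterion references column(s) not in the table: {sorted(missing)}"
        )
    if isinstance(id_mapper, Mapping):
        mapper = lambda i: id_mapper.get(i, i)  # noqa: E731
    else:
        mapper = id_mapper or (lambda i: i)
    qual: dict[str, bool] = {}
    for ident, row in table.rows():
        mapped = mapper(ident)
        qual[mapped] = qual.get(mapped, False) or crit.evaluate(row)
    return qual


def pathway_identifiers(p: GpmlPathway) -> set[str]:
    """Distinct xref identifiers on a pathway's measurable data nodes.

    Complex placeholder nodes are excluded; the flattened component nodes
    (which carry the genes) are ordinary nodes and are included.
    """
    out: set[str] = set()
    for n in p.data_nodes:
        if n.node_type == "Complex":
            continue
        if n.xref is not None:
            out.add(n.xref[1])
    return out


def run_enrichment(
    table: DataTable,
    crit: Criterion,
    pathways: list[GpmlPathway],
    id_mapper: Callable[[str], str] | Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Rank pathways by the over-representation z score.

    Ties are broken by pathway name; pathways with undefined z (no measured
    members, or degenerate totals) sort last.  The source collection tag is
    taken from each pathway's data-source attribute.
    """
    if table.frame.empty:
        raise DomainError("empty data table")
    qual = qualification_by_identifier(table, crit, id_mapper)
    N = len(qual)
    if N < 2:
        raise DomainError(f"need at least 2 measured identifiers, got {N}")
    R = sum(qual.values())

    results: list[EnrichmentResult] = []
    for p in pathways:
        ids = pathway_identifiers(p) & set(qual)
        n = len(ids)
        r = sum(1 for i in ids if qual[i])
        z = zscore(r, n, R, N)
        results.append(
            EnrichmentResult(
                pathway=p.name,
                source=p.data_source or "Unknown",
                r=r,
                n=n,
                R=R,
                N=N,
                z=z,
            )
        )
    results.sort(
        key=lambda e: (math.isnan(e.z), -e.z if not math.isnan(e.z) else 0.0, e.pathway)
    )
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate ranked results (pathway, source, r, n, R, N, z)."""
    return pd.DataFrame(
        [
            {
                "pathway": e.pathway,
                "source": e.source,
                "r": e.r,
                "n": e.n,
                "R": e.R,
                "N": e.N,
                "z": round(e.z, 6) if not math.isnan(e.z) else float("nan"),
            }
            for e in results
        ]
    )


def permuted_mean_z(
    pathway_ids: set[str],
    qual: dict[str, bool],
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Null check utility: mean and SE of z after shuffling qualification labels.

    Shuffling breaks any association between pathway membership and
    qualification, so the mean z should be near zero; returns
    (mean, standard error) over the permutations with defined z.
    """
    ids = sorted(qual)
    labels = np.array([qual[i] for i in ids])
    member_mask = np.array([i in pathway_ids for i in ids])
    N = len(ids)
    R = int(labels.sum())
    n = int(member_mask.sum())
    zs = []
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        r = int(perm[member_mask].sum())
        z = zscore(r, n, R, N)
        if not math.isnan(z):
            zs.append(z)
    arr = np.array(zs)
    if arr.size == 0:
        return math.nan, math.nan
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))
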