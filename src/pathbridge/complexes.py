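"""Per-complex percentage scoring under a user criterion, with color rules.

Re-implementation of the ComplexViz idea: every complex (or entity set) on a
converted pathway gets the percentage of its components that qualify a user
criterion, computed over the components for which measurements exist.  The
score can then be turned into a color per complex through ordered threshold
rules (first match wins) or a linear RGB gradient, and the complex ↔
component linkage can be queried in both directions.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Mapping

from pathbridge.convert import ComplexComponentMap
from pathbridge.enrichment import Criterion, DataTable, qualification_by_identifier
from pathbridge.errors import LookupError_, ValidationError
from pathbridge.gpml import GpmlPathway


@dataclass
class ComplexScore:
    complex_id: str
    n_components: int  # distinct components with measurement data
    n_qualifying: int
    percent: float  # 100 * n_qualifying / n_components; NaN when no data

    @property
    def defined(self) -> bool:
        return not math.isnan(self.percent)


def score_complexes(
    p: GpmlPathway,
    cmap: ComplexComponentMap,
    table: DataTable,
    crit: Criterion,
    id_mapper: Callable[[str], str] | Mapping[str, str] | None = None,
) -> list[ComplexScore]:
    """Score every container in the component map.

    Components without a table row are excluded from both numerator and
    denominator (mirroring the convention that unmeasured genes are shown
    gray, not counted as failing).  A container whose components all lack
    data gets an undefined (NaN) percent.
    """
    nodes = p.node_index()
    for container_id, member_ids in cmap.mapping.items():
        for gid in (container_id, *member_ids):
            if gid not in nodes:
                raise ValidationError(
                    f"component map id {gid!r} does not resolve in the pathway"
                )
    qual = qualification_by_identifier(table, crit, id_mapper)
    scores: list[ComplexScore] = []
    for container_id, member_ids in cmap.mapping.items():
        with_data = 0
        qualifying = 0
        for gid in member_ids:
            xref = nodes[gid].xref
            if xref is None or xref[1] not in qual:
                continue
            with_data += 1
            if qual[xref[1]]:
                qualifying += 1
        percent = 100.0 * qualifying / with_data if with_data else math.nan
        scores.append(
            ComplexScore(
                complex_id=container_id,
                n_components=with_data,
                n_qualifying=qualifying,
                percent=percent,
            )
        )
    return scores


# ---------------------------------------------------------------------------
# Color rules

_HEX_RE = re.compile(r"^#?([0-9A-Fa-f]{6})$")

_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "=": lambda a, b: a == b,
}


def _parse_hex(color: str) -> tuple[int, int, int]:
    m = _HEX_RE.match(color)
    if not m:
        raise ValidationError(f"bad hex color {color!r}")
    h = m.group(1)
    return int(h[0:2], 16), int(h[2:4], 16), int(h[4:6], 16)


def _format_hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*rgb)


@dataclass
class ColorRule:
    """Either a threshold rule (``percent > 25`` → color) or a gradient.

    Threshold form: ``op`` and ``threshold`` set, ``color`` is the target.
    Gradient form: two anchor (value, color) pairs; percents are clamped to
    the anchor interval and interpolated linearly per RGB channel.
    """

    op: str | None = None
    threshold: float | None = None
    color: str | None = None
    gradient: tuple[tuple[float, str], tuple[float, str]] | None = None

    def __post_init__(self) -> None:
        if self.gradient is not None:
            (v0, _), (v1, _) = self.gradient
            if v0 == v1:
                raise ValidationError("gradient anchor values must be distinct")
        elif self.op not in _OPS or self.threshold is None or self.color is None:
            raise ValidationError("threshold rule needs op, threshold and color")

    def apply(self, percent: float) -> str | None:
        """Return a color for a defined percent, or None when not matching."""
        if self.gradient is not None:
            (v0, c0), (v1, c1) = self.gradient
            t = (percent - v0) / (v1 - v0)
            t = min(max(t, 0.0), 1.0)
            rgb0, rgb1 = _parse_hex(c0), _parse_hex(c1)
            return _format_hex(
                tuple(round(a + t * (b - a)) for a, b in zip(rgb0, rgb1))
            )
        if _OPS[self.op](percent, self.threshold):
            return _format_hex(_parse_hex(self.color))
        return None


_RULE_RE = re.compile(r"^percent\s*(<=|>=|<|>|=)\s*(-?\d+(?:\.\d+)?)\s*:\s*(#[0-9A-Fa-f]{6})$")
_GRADIENT_RE = re.compile(
    r"^gradient\s*:\s*(-?\d+(?:\.\d+)?)\s*:\s*(#[0-9A-Fa-f]{6})"
    r"\s*:\s*(-?\d+(?:\.\d+)?)\s*:\s*(#[0-9A-Fa-f]{6})$"
)


def parse_color_rule(text: str) -> ColorRule:
    """Parse ``percent>25:#FFA500`` or ``gradient:0:#0000FF:100:#FFFF00``."""
    m = _RULE_RE.match(text.strip())
    if m:
        return ColorRule(op=m.group(1), threshold=float(m.group(2)), color=m.group(3))
    m = _GRADIENT_RE.match(text.strip())
    if m:
        return ColorRule(
            gradient=((float(m.group(1)), m.group(2)), (float(m.group(3)), m.group(4)))
        )
    raise ValidationError(f"cannot parse color rule {text!r}")


def apply_color_rules(
    scores: list[ComplexScore],
    rules: list[ColorRule],
    default_color: str,
) -> dict[str, str]:
    """Assign one color per complex: first matching rule wins.

    Undefined scores (no measured components) take the default color, as do
    scores no rule matches.
    """
    if not rules and not default_color:
        raise ValidationError("need at least one rule or a default color")
    default = _format_hex(_parse_hex(default_color))
    out: dict[str, str] = {}
    for s in scores:
        color = None
        if s.defined:
            for rule in rules:
                color = rule.apply(s.percent)
                if color is not None:
                    break
        out[s.complex_id] = color if color is not None else default
    return out


def lookup(p: GpmlPathway, cmap: ComplexComponentMap, graph_id: str) -> list[str]:
    """Two-way complex ↔ component lookup.

    A complex id returns its component node ids; a component id returns all
    containing complex ids (a shared, deduplicated component can belong to
    several).  Unknown ids raise.
    """
    if graph_id in cmap.mapping:
        return list(cmap.mapping[graph_id])
    containers = cmap.containers_of(graph_id)
    if containers:
        return containers
    raise LookupError_(
        f"{graph_id!r} is neither a complex nor a component in the map"
    )
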