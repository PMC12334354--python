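"""The mass-spectrometry query language: grammar, parser, AST and tooling.

A query selects scans from MS data by combining peak conditions
(MS1MZ, MS2PREC, MS2PROD, MS2NL), metadata conditions (CHARGE, POLARITY,
RTMIN/RTMAX, SCANMIN/SCANMAX, MOBILITY) and per-condition qualifiers
(tolerances, intensity thresholds, mass-defect windows, EXCLUDED) with
Boolean AND/OR.  m/z values may be written relative to a query variable X
(``MS1MZ=X-1.993``), which lets a single query express multi-peak isotope
and adduct patterns anchored at an unknown mass.

Surface syntax::

    QUERY scaninfo(MS2DATA) WHERE MS2PROD=98.9847:TOLERANCEPPM=50:INTENSITYPERCENT=50
    QUERY scaninfo(MS1DATA) WHERE MS1MZ=X AND MS1MZ=X-1.993:INTENSITYMATCH=Y*0.063:INTENSITYMATCHPERCENT=25

Keywords are case-insensitive.  AND binds tighter than OR; parentheses
override.  Negation is expressed through the EXCLUDED qualifier only.
Numeric literals are plain decimals (no scientific notation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from decimal import Decimal
from enum import Enum
from typing import Iterator, List, Optional, Sequence, Tuple, Union

__all__ = [
    "ConditionType",
    "NumericExpr",
    "Range",
    "QualifierSet",
    "Condition",
    "ConditionNode",
    "ParsedQuery",
    "Diagnostic",
    "QuerySyntaxError",
    "parse",
    "serialize",
    "validate",
    "describe",
]


class ConditionType(str, Enum):
    MS1MZ = "MS1MZ"
    MS2PREC = "MS2PREC"
    MS2PROD = "MS2PROD"
    MS2NL = "MS2NL"
    CHARGE = "CHARGE"
    POLARITY = "POLARITY"
    RTMIN = "RTMIN"
    RTMAX = "RTMAX"
    SCANMIN = "SCANMIN"
    SCANMAX = "SCANMAX"
    MOBILITY = "MOBILITY"


#: conditions whose value is an m/z (tolerance qualifiers apply)
MZ_CONDITIONS = frozenset(
    {ConditionType.MS1MZ, ConditionType.MS2PREC, ConditionType.MS2PROD, ConditionType.MS2NL}
)
#: conditions carrying per-peak intensity, where intensity qualifiers apply
INTENSITY_CONDITIONS = frozenset({ConditionType.MS1MZ, ConditionType.MS2PROD})
#: conditions where a mass-defect window applies
MASSDEFECT_CONDITIONS = frozenset(
    {ConditionType.MS1MZ, ConditionType.MS2PREC, ConditionType.MS2PROD}
)
#: conditions that only make sense against MS2 scans
MS2_ONLY_CONDITIONS = frozenset(
    {ConditionType.MS2PREC, ConditionType.MS2PROD, ConditionType.MS2NL, ConditionType.CHARGE}
)


@dataclass(frozen=True)
class NumericExpr:
    """A constant m/z, or the query variable X plus a constant offset."""

    variable: bool = False
    value: float = 0.0  # the constant, or the offset from X

    def resolve(self, x: Optional[float] = None) -> float:
        if not self.variable:
            return self.value
        if x is None:
            raise ValueError("variable expression requires a binding for X")
        return x + self.value

    @property
    def is_anchor(self) -> bool:
        return self.variable and self.value == 0.0


@dataclass(frozen=True)
class Range:
    min: float
    max: float


@dataclass(frozen=True)
class QualifierSet:
    tolerance_mz: Optional[float] = None
    tolerance_ppm: Optional[float] = None
    intensity_value: Optional[float] = None
    intensity_percent: Optional[float] = None
    intensity_tic_percent: Optional[float] = None
    intensity_match_ratio: Optional[float] = None
    intensity_match_percent: Optional[float] = None
    mass_defect: Optional[Range] = None
    excluded: bool = False


@dataclass(frozen=True)
class Condition:
    type: ConditionType
    value: Union[NumericExpr, str, Range, float]
    qualifiers: QualifierSet = field(default_factory=QualifierSet)


@dataclass(frozen=True)
class ConditionNode:
    """A node of the Boolean condition tree: LEAF, AND or OR."""

    kind: str  # "LEAF" | "AND" | "OR"
    children: Tuple["ConditionNode", ...] = ()
    leaf: Optional[Condition] = None

    def iter_leaves(self) -> Iterator[Condition]:
        if self.kind == "LEAF":
            assert self.leaf is not None
            yield self.leaf
        else:
            for child in self.children:
                yield from child.iter_leaves()


@dataclass(frozen=True)
class ParsedQuery:
    function: str  # scaninfo | scannum | scansum
    datatype: str  # MS1DATA | MS2DATA
    where: Optional[ConditionNode]  # None = match all
    # provenance only; excluded from structural equality
    source_text: str = field(default="", compare=False)

    @property
    def uses_variable(self) -> bool:
        if self.where is None:
            return False
        return any(
            isinstance(c.value, NumericExpr) and c.value.variable
            for c in self.where.iter_leaves()
        )


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "error" | "warning"
    position: int  # character offset in source (0 when AST-only)
    message: str


class QuerySyntaxError(ValueError):
    """Syntax error in a query string, carrying the earliest failing offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.message = message
        self.offset = offset


# ---------------------------------------------------------------------------
# Tokenizer

_TOKEN_RE = re.compile(
    r"""
    (?P<WS>\s+)
  | (?P<NUMBER>\d+\.\d*|\.\d+|\d+)
  | (?P<IDENT>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<LPAREN>\()
  | (?P<RPAREN>\))
  | (?P<COLON>:)
  | (?P<COMMA>,)
  | (?P<EQUALS>=)
  | (?P<PLUS>\+)
  | (?P<MINUS>-|−)
  | (?P<STAR>\*)
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class _Token:
    kind: str
    text: str
    pos: int


def _tokenize(text: str) -> List[_Token]:
    tokens: List[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise QuerySyntaxError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        if kind != "WS":
            tokens.append(_Token(kind, m.group(), pos))
        pos = m.end()
    tokens.append(_Token("EOF", "", len(text)))
    return tokens


# ---------------------------------------------------------------------------
# Parser

_FUNCTIONS = ("scaninfo", "scannum", "scansum")
_DATATYPES = ("MS1DATA", "MS2DATA")
_CONDITION_NAMES = {ct.value: ct for ct in ConditionType}
_QUALIFIER_NAMES = (
    "TOLERANCEMZ",
    "TOLERANCEPPM",
    "INTENSITYVALUE",
    "INTENSITYPERCENT",
    "INTENSITYTICPERCENT",
    "INTENSITYMATCH",
    "INTENSITYMATCHPERCENT",
    "MASSDEFECT",
    "EXCLUDED",
)


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.tokens[self.i]
        if tok.kind != "EOF":
            self.i += 1
        return tok

    def fail(self, message: str, tok: Optional[_Token] = None) -> None:
        tok = tok or self.cur
        raise QuerySyntaxError(message, tok.pos)

    def expect(self, kind: str, what: str) -> _Token:
        if self.cur.kind != kind:
            self.fail(f"expected {what}")
        return self.advance()

    def expect_keyword(self, word: str) -> _Token:
        if self.cur.kind != "IDENT" or self.cur.text.upper() != word.upper():
            self.fail(f"expected keyword {word!r}")
        return self.advance()

    def at_keyword(self, word: str) -> bool:
        return self.cur.kind == "IDENT" and self.cur.text.upper() == word.upper()

    def number(self, what: str = "a number") -> float:
        if self.cur.kind != "NUMBER":
            self.fail(f"expected {what}")
        return float(self.advance().text)

    # grammar: query := QUERY function "(" datatype ")" [WHERE expr] EOF
    def parse_query(self) -> ParsedQuery:
        self.expect_keyword("QUERY")
        if self.cur.kind != "IDENT" or self.cur.text.lower() not in _FUNCTIONS:
            self.fail("expected an output function (scaninfo, scannum or scansum)")
        function = self.advance().text.lower()
        self.expect("LPAREN", "'('")
        if self.cur.kind != "IDENT" or self.cur.text.upper() not in _DATATYPES:
            self.fail("expected a data type (MS1DATA or MS2DATA)")
        datatype = self.advance().text.upper()
        self.expect("RPAREN", "')'")
        where = None
        if self.at_keyword("WHERE"):
            self.advance()
            where = self.parse_or()
        if self.cur.kind != "EOF":
            self.fail("unexpected trailing input")
        return ParsedQuery(function, datatype, where, self.text)

    # expr := and_expr (OR and_expr)*  -- n-ary, flattened
    def parse_or(self) -> ConditionNode:
        children = [self.parse_and()]
        while self.at_keyword("OR"):
            self.advance()
            children.append(self.parse_and())
        if len(children) == 1:
            return children[0]
        return ConditionNode("OR", tuple(children))

    def parse_and(self) -> ConditionNode:
        children = [self.parse_primary()]
        while self.at_keyword("AND"):
            self.advance()
            children.append(self.parse_primary())
        if len(children) == 1:
            return children[0]
        return ConditionNode("AND", tuple(children))

    def parse_primary(self) -> ConditionNode:
        if self.cur.kind == "LPAREN":
            self.advance()
            node = self.parse_or()
            self.expect("RPAREN", "')'")
            return node
        return ConditionNode("LEAF", leaf=self.parse_condition())

    def parse_condition(self) -> Condition:
        if self.cur.kind != "IDENT":
            self.fail("expected a condition name")
        name = self.cur.text.upper()
        if name not in _CONDITION_NAMES:
            self.fail(f"unknown condition name {self.cur.text!r}")
        ctype = _CONDITION_NAMES[name]
        self.advance()
        self.expect("EQUALS", "'='")
        value = self.parse_value(ctype)
        qualifiers = self.parse_qualifiers()
        return Condition(ctype, value, qualifiers)

    def parse_value(self, ctype: ConditionType):
        if ctype in MZ_CONDITIONS:
            return self.parse_mz_expr()
        if ctype is ConditionType.POLARITY:
            if self.cur.kind != "IDENT" or self.cur.text.capitalize() not in (
                "Positive",
                "Negative",
            ):
                self.fail("expected Positive or Negative")
            return self.advance().text.capitalize()
        if ctype is ConditionType.MOBILITY:
            return self.parse_range("range")
        if ctype is ConditionType.CHARGE:
            value = self.number("a charge value")
            if value != int(value):
                self.fail("charge must be an integer", self.tokens[self.i - 1])
            return float(value)
        # RTMIN/RTMAX/SCANMIN/SCANMAX
        return self.number("a numeric value")

    def parse_mz_expr(self) -> NumericExpr:
        if self.cur.kind == "NUMBER":
            return NumericExpr(False, float(self.advance().text))
        if self.at_keyword("X"):
            self.advance()
            if self.cur.kind == "STAR":
                self.fail("multiplication of the variable X is not supported")
            if self.cur.kind in ("PLUS", "MINUS"):
                sign = 1.0 if self.cur.kind == "PLUS" else -1.0
                self.advance()
                return NumericExpr(True, sign * self.number("an m/z offset"))
            return NumericExpr(True, 0.0)
        self.fail("expected an m/z value")

    def parse_range(self, keyword: str) -> Range:
        self.expect_keyword(keyword)
        self.expect("LPAREN", "'('")
        self.expect_keyword("min")
        self.expect("EQUALS", "'='")
        lo = self.number("the range minimum")
        self.expect("COMMA", "','")
        self.expect_keyword("max")
        self.expect("EQUALS", "'='")
        hi = self.number("the range maximum")
        self.expect("RPAREN", "')'")
        return Range(lo, hi)

    def parse_qualifiers(self) -> QualifierSet:
        q = QualifierSet()
        seen = set()
        while self.cur.kind == "COLON":
            self.advance()
            if self.cur.kind != "IDENT":
                self.fail("expected a qualifier name")
            name = self.cur.text.upper()
            if name not in _QUALIFIER_NAMES:
                self.fail(f"unknown qualifier name {self.cur.text!r}")
            if name in seen:
                self.fail(f"duplicate qualifier {name}")
            seen.add(name)
            name_tok = self.advance()
            if name == "EXCLUDED":
                q = replace(q, excluded=True)
                continue
            self.expect("EQUALS", "'='")
            if name == "MASSDEFECT":
                q = replace(q, mass_defect=self.parse_range("massdefect"))
            elif name == "INTENSITYMATCH":
                # canonical form Y*<ratio>; a bare ratio is also accepted
                if self.at_keyword("Y"):
                    self.advance()
                    self.expect("STAR", "'*'")
                q = replace(q, intensity_match_ratio=self.number("an intensity ratio"))
            else:
                value = self.number("a qualifier value")
                attr = {
                    "TOLERANCEMZ": "tolerance_mz",
                    "TOLERANCEPPM": "tolerance_ppm",
                    "INTENSITYVALUE": "intensity_value",
                    "INTENSITYPERCENT": "intensity_percent",
                    "INTENSITYTICPERCENT": "intensity_tic_percent",
                    "INTENSITYMATCHPERCENT": "intensity_match_percent",
                }[name]
                q = replace(q, **{attr: value})
            if q.tolerance_mz is not None and q.tolerance_ppm is not None:
                self.fail("TOLERANCEMZ and TOLERANCEPPM are mutually exclusive", name_tok)
        return q


def parse(query_text: str) -> ParsedQuery:
    """Parse query text into a :class:`ParsedQuery` AST.

    Raises :class:`QuerySyntaxError` with the earliest failing character
    offset on any malformed input.
    """
    if not query_text or not query_text.strip():
        raise QuerySyntaxError("empty query", 0)
    return _Parser(query_text).parse_query()


# ---------------------------------------------------------------------------
# Serialization

def _fmt_number(v: float) -> str:
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    r = repr(float(v))
    if "e" in r or "E" in r:
        return format(Decimal(r), "f")
    return r


def _serialize_qualifiers(q: QualifierSet) -> str:
    parts = []
    if q.tolerance_mz is not None:
        parts.append(f"TOLERANCEMZ={_fmt_number(q.tolerance_mz)}")
    if q.tolerance_ppm is not None:
        parts.append(f"TOLERANCEPPM={_fmt_number(q.tolerance_ppm)}")
    if q.intensity_value is not None:
        parts.append(f"INTENSITYVALUE={_fmt_number(q.intensity_value)}")
    if q.intensity_percent is not None:
        parts.append(f"INTENSITYPERCENT={_fmt_number(q.intensity_percent)}")
    if q.intensity_tic_percent is not None:
        parts.append(f"INTENSITYTICPERCENT={_fmt_number(q.intensity_tic_percent)}")
    if q.intensity_match_ratio is not None:
        parts.append(f"INTENSITYMATCH=Y*{_fmt_number(q.intensity_match_ratio)}")
    if q.intensity_match_percent is not None:
        parts.append(f"INTENSITYMATCHPERCENT={_fmt_number(q.intensity_match_percent)}")
    if q.mass_defect is not None:
        parts.append(
            f"MASSDEFECT=massdefect(min={_fmt_number(q.mass_defect.min)}, "
            f"max={_fmt_number(q.mass_defect.max)})"
        )
    if q.excluded:
        parts.append("EXCLUDED")
    return "".join(":" + p for p in parts)


def _serialize_value(cond: Condition) -> str:
    v = cond.value
    if isinstance(v, NumericExpr):
        if not v.variable:
            return _fmt_number(v.value)
        if v.value == 0:
            return "X"
        sign = "+" if v.value > 0 else "-"
        return f"X{sign}{_fmt_number(abs(v.value))}"
    if isinstance(v, Range):
        return f"range(min={_fmt_number(v.min)}, max={_fmt_number(v.max)})"
    if isinstance(v, str):
        return v
    return _fmt_number(float(v))


def _serialize_node(node: ConditionNode, parent: Optional[str]) -> str:
    if node.kind == "LEAF":
        cond = node.leaf
        assert cond is not None
        return f"{cond.type.value}={_serialize_value(cond)}{_serialize_qualifiers(cond.qualifiers)}"
    sep = " AND " if node.kind == "AND" else " OR "
    body = sep.join(_serialize_node(c, node.kind) for c in node.children)
    # parentheses only where required to preserve grouping under
    # AND-binds-tighter precedence (or to keep hand-built nesting)
    needs_parens = (node.kind == "OR" and parent is not None) or (
        node.kind == "AND" and parent == "AND"
    )
    return f"({body})" if needs_parens else body


def serialize(query: ParsedQuery) -> str:
    """Render a query in canonical text form.

    Fixed keyword case, fixed qualifier order, minimal parentheses;
    ``parse(serialize(q))`` is structurally equal to ``q``.
    """
    head = f"QUERY {query.function}({query.datatype})"
    if query.where is None:
        return head
    return f"{head} WHERE {_serialize_node(query.where, None)}"


# ---------------------------------------------------------------------------
# Validation

def validate(query: ParsedQuery) -> List[Diagnostic]:
    """Static checks beyond syntax; an empty list means the query is executable."""
    diags: List[Diagnostic] = []

    def err(message: str) -> None:
        diags.append(Diagnostic("error", 0, message))

    leaves = list(query.where.iter_leaves()) if query.where is not None else []

    uses_x = any(
        isinstance(c.value, NumericExpr) and c.value.variable for c in leaves
    )
    has_anchor = any(
        isinstance(c.value, NumericExpr) and c.value.is_anchor for c in leaves
    )
    if uses_x and not has_anchor:
        err("a query using the variable X needs an anchor condition with value X")

    rtmins = [float(c.value) for c in leaves if c.type is ConditionType.RTMIN]
    rtmaxs = [float(c.value) for c in leaves if c.type is ConditionType.RTMAX]
    if rtmins and rtmaxs and min(rtmins) > max(rtmaxs):
        err("RTMIN exceeds RTMAX")

    for cond in leaves:
        q = cond.qualifiers
        name = cond.type.value
        if q.tolerance_mz is not None and q.tolerance_ppm is not None:
            err(f"{name}: TOLERANCEMZ and TOLERANCEPPM are mutually exclusive")
        if (q.tolerance_mz is not None or q.tolerance_ppm is not None) and (
            cond.type not in MZ_CONDITIONS
        ):
            err(f"{name}: tolerance qualifiers apply only to m/z conditions")
        if cond.type not in INTENSITY_CONDITIONS and any(
            v is not None
            for v in (
                q.intensity_value,
                q.intensity_percent,
                q.intensity_tic_percent,
                q.intensity_match_ratio,
                q.intensity_match_percent,
            )
        ):
            err(f"{name}: intensity qualifiers apply only to MS1MZ and MS2PROD")
        if q.mass_defect is not None and cond.type not in MASSDEFECT_CONDITIONS:
            err(f"{name}: MASSDEFECT applies only to MS1MZ, MS2PREC and MS2PROD")
        if q.excluded and cond.type not in MZ_CONDITIONS:
            err(f"{name}: EXCLUDED applies only to peak conditions")
        if q.intensity_match_ratio is not None:
            if not uses_x:
                err(f"{name}: INTENSITYMATCH requires a variable-anchored query")
            if q.intensity_match_percent is None:
                err(f"{name}: INTENSITYMATCH requires INTENSITYMATCHPERCENT")
        if q.intensity_match_percent is not None and q.intensity_match_ratio is None:
            err(f"{name}: INTENSITYMATCHPERCENT requires INTENSITYMATCH")
        for label, v in (
            ("TOLERANCEMZ", q.tolerance_mz),
            ("TOLERANCEPPM", q.tolerance_ppm),
            ("INTENSITYVALUE", q.intensity_value),
            ("INTENSITYPERCENT", q.intensity_percent),
            ("INTENSITYTICPERCENT", q.intensity_tic_percent),
            ("INTENSITYMATCH", q.intensity_match_ratio),
            ("INTENSITYMATCHPERCENT", q.intensity_match_percent),
        ):
            if v is not None and v < 0:
                err(f"{name}: {label} must be non-negative")
        if cond.type in MS2_ONLY_CONDITIONS and query.datatype != "MS2DATA":
            err(f"{name}: condition requires an MS2DATA query")
        if cond.type is ConditionType.MOBILITY and isinstance(cond.value, Range):
            if cond.value.min > cond.value.max:
                err("MOBILITY: range minimum exceeds maximum")
        if cond.type is ConditionType.POLARITY and cond.value not in (
            "Positive",
            "Negative",
        ):
            err("POLARITY: value must be Positive or Negative")

    for node in _iter_nodes(query.where):
        if node.kind in ("AND", "OR") and len(node.children) < 2:
            err(f"{node.kind} node must have at least two children")

    return diags


def _iter_nodes(node: Optional[ConditionNode]) -> Iterator[ConditionNode]:
    if node is None:
        return
    yield node
    for child in node.children:
        yield from _iter_nodes(child)


# ---------------------------------------------------------------------------
# English description

_LEVEL_NAMES = {"MS1DATA": "MS1", "MS2DATA": "MS2"}
_FUNCTION_PHRASES = {
    "scaninfo": "Return information for",
    "scannum": "Return scan numbers for",
    "scansum": "Return the summed matched intensity over",
}


def _describe_qualifiers(q: QualifierSet) -> List[str]:
    notes = []
    if q.tolerance_mz is not None:
        notes.append(f"within {_fmt_number(q.tolerance_mz)} Da")
    if q.tolerance_ppm is not None:
        notes.append(f"within {_fmt_number(q.tolerance_ppm)} ppm")
    if q.intensity_value is not None:
        notes.append(f"with intensity at least {_fmt_number(q.intensity_value)}")
    if q.intensity_percent is not None:
        notes.append(f"at least {_fmt_number(q.intensity_percent)}% of the base peak")
    if q.intensity_tic_percent is not None:
        notes.append(f"at least {_fmt_number(q.intensity_tic_percent)}% of the TIC")
    if q.intensity_match_ratio is not None:
        pct = q.intensity_match_percent
        band = f" (within {_fmt_number(pct)}%)" if pct is not None else ""
        notes.append(
            f"at {_fmt_number(q.intensity_match_ratio * 100)}% of the anchor peak intensity{band}"
        )
    if q.mass_defect is not None:
        notes.append(
            f"with mass defect between {_fmt_number(q.mass_defect.min)} and "
            f"{_fmt_number(q.mass_defect.max)}"
        )
    return notes


def _describe_condition(cond: Condition) -> str:
    q = cond.qualifiers
    notes = _describe_qualifiers(q)
    suffix = f" ({'; '.join(notes)})" if notes else ""
    value = _serialize_value(cond)
    verb = "does not contain" if q.excluded else "contains"
    t = cond.type
    if t is ConditionType.MS1MZ:
        return f"the MS1 scan {verb} a peak at m/z {value}{suffix}"
    if t is ConditionType.MS2PROD:
        return f"the scan {verb} a product ion at m/z {value}{suffix}"
    if t is ConditionType.MS2PREC:
        return f"the precursor m/z {'is not' if q.excluded else 'is'} {value}{suffix}"
    if t is ConditionType.MS2NL:
        return f"the scan {verb} a neutral loss of {value} Da{suffix}"
    if t is ConditionType.CHARGE:
        return f"the precursor charge is {value}"
    if t is ConditionType.POLARITY:
        return f"the ionization polarity is {value.lower()}"
    if t is ConditionType.RTMIN:
        return f"the retention time is at least {value} minutes"
    if t is ConditionType.RTMAX:
        return f"the retention time is at most {value} minutes"
    if t is ConditionType.SCANMIN:
        return f"the scan number is at least {value}"
    if t is ConditionType.SCANMAX:
        return f"the scan number is at most {value}"
    if t is ConditionType.MOBILITY:
        assert isinstance(cond.value, Range)
        return (
            f"the ion mobility is between {_fmt_number(cond.value.min)} and "
            f"{_fmt_number(cond.value.max)}"
        )
    raise AssertionError(f"unhandled condition type {t}")


def _describe_node(node: ConditionNode, parent: Optional[str]) -> str:
    if node.kind == "LEAF":
        assert node.leaf is not None
        return _describe_condition(node.leaf)
    joiner = " and " if node.kind == "AND" else " or "
    body = joiner.join(_describe_node(c, node.kind) for c in node.children)
    if parent is not None and node.kind != parent:
        return f"({body})"
    return body


def describe(query: ParsedQuery) -> str:
    """Deterministic English rendering of a query."""
    level = _LEVEL_NAMES[query.datatype]
    head = _FUNCTION_PHRASES[query.function]
    if query.where is None:
        return f"{head} all {level} scans."
    return f"{head} {level} scans where {_describe_node(query.where, None)}."
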