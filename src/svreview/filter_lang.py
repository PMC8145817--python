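"""Small boolean expression language for filtering SV VCF records.

The grammar (this package's own; frozen here):

.. code-block:: text

    expr      := or
    or        := and ( '||' and )*
    and       := unary ( '&&' unary )*
    unary     := '!' unary | '(' expr ')' | comparison | predicate
    comparison:= value ('==' | '!=' | '<' | '<=' | '>' | '>=') value
    value     := NUMBER | 'string' | "string" | field
    field     := SVTYPE | SVLEN | CHROM | POS | END | INFO.key
    predicate := het(who) | hom_ref(who) | hom_alt(who) | missing(who)
                 | exists(INFO.key)

``who`` is a VCF sample name or a pedigree role (offspring / mother /
father, resolved against affected trio members of a PED file).

Missing-value rule: any comparison whose operand is missing evaluates
false, and that falseness is *sticky* — negating it still yields false.
Presence must be asserted explicitly with ``exists(INFO.key)``.  This
keeps filtering predictable without introducing tri-valued logic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Any

_MISSING = object()

FIELD_NAMES = ("SVTYPE", "SVLEN", "CHROM", "POS", "END")
GT_PREDICATES = ("het", "hom_ref", "hom_alt", "missing")


class FilterSyntaxError(ValueError):
    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} at offset {offset}")
        self.offset = offset


@dataclass(frozen=True)
class Token:
    kind: str  # OP, NUMBER, STRING, IDENT, LPAREN, RPAREN, DOT, COMMA, END
    text: str
    offset: int


_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<op>==|!=|<=|>=|&&|\|\||<|>|!)"
    r"|(?P<number>-?\d+(?:\.\d+)?)"
    r"|(?P<string>'[^']*'|\"[^\"]*\")"
    r"|(?P<ident>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<lparen>\()|(?P<rparen>\))|(?P<dot>\.)|(?P<comma>,)"
    r")"
)


def tokenize(text: str) -> list[Token]:
    tokens: list[Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            off = len(text) - len(stripped)
            ch = text[off]
            hint = " (did you mean '==')" if ch == "=" else ""
            raise FilterSyntaxError(f"unexpected character {ch!r}{hint}", off)
        for kind in ("op", "number", "string", "ident", "lparen", "rparen", "dot", "comma"):
            val = m.group(kind)
            if val is not None:
                tokens.append(Token(kind.upper(), val, m.start(kind)))
                break
        pos = m.end()
    tokens.append(Token("END", "", len(text)))
    return tokens


# ---------------------------------------------------------------- AST nodes

@dataclass(frozen=True)
class Literal:
    value: Any


@dataclass(frozen=True)
class Field:
    name: str  # SVTYPE/SVLEN/CHROM/POS/END or INFO.<key>


@dataclass(frozen=True)
class Cmp:
    op: str
    lhs: Any
    rhs: Any


@dataclass(frozen=True)
class Not:
    operand: Any


@dataclass(frozen=True)
class BoolOp:
    op: str  # '&&' or '||'
    operands: tuple


@dataclass(frozen=True)
class Predicate:
    name: str
    arg: str


@dataclass(frozen=True)
class FilterExpression:
    ast: Any
    text: str


class _Parser:
    def __init__(self, tokens: list[Token], text: str):
        self.tokens = tokens
        self.text = text
        self.i = 0

    def peek(self) -> Token:
        return self.tokens[self.i]

    def take(self) -> Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str) -> Token:
        tok = self.peek()
        if tok.kind != kind:
            raise FilterSyntaxError(f"expected {kind}, found {tok.text or 'end of input'!r}", tok.offset)
        return self.take()

    def parse(self) -> Any:
        node = self.or_expr()
        tok = self.peek()
        if tok.kind != "END":
            raise FilterSyntaxError(f"unexpected trailing input {tok.text!r}", tok.offset)
        return node

    def or_expr(self) -> Any:
        operands = [self.and_expr()]
        while self.peek().kind == "OP" and self.peek().text == "||":
            self.take()
            operands.append(self.and_expr())
        return operands[0] if len(operands) == 1 else BoolOp("||", tuple(operands))

    def and_expr(self) -> Any:
        operands = [self.unary()]
        while self.peek().kind == "OP" and self.peek().text == "&&":
            self.take()
            operands.append(self.unary())
        return operands[0] if len(operands) == 1 else BoolOp("&&", tuple(operands))

    def unary(self) -> Any:
        tok = self.peek()
        if tok.kind == "OP" and tok.text == "!":
            self.take()
            return Not(self.unary())
        if tok.kind == "LPAREN":
            self.take()
            node = self.or_expr()
            self.expect("RPAREN")
            return node
        return self.comparison()

    def comparison(self) -> Any:
        lhs = self.value()
        tok = self.peek()
        if tok.kind == "OP" and tok.text in ("==", "!=", "<", "<=", ">", ">="):
            op = self.take().text
            rhs = self.value()
            return Cmp(op, lhs, rhs)
        if isinstance(lhs, Predicate):
            return lhs
        raise FilterSyntaxError(
            "expected a comparison operator or genotype predicate",
            tok.offset,
        )

    def value(self) -> Any:
        tok = self.take()
        if tok.kind == "NUMBER":
            num = float(tok.text)
            return Literal(int(num) if num.is_integer() else num)
        if tok.kind == "STRING":
            return Literal(tok.text[1:-1])
        if tok.kind == "IDENT":
            name = tok.text
            if name == "INFO":
                self.expect("DOT")
                key = self.expect("IDENT").text
                return Field(f"INFO.{key}")
            if name in FIELD_NAMES:
                return Field(name)
            if self.peek().kind == "LPAREN":
                self.take()
                arg_tok = self.take()
                if arg_tok.kind == "IDENT" and arg_tok.text == "INFO" and self.peek().kind == "DOT":
                    self.take()
                    arg = "INFO." + self.expect("IDENT").text
                elif arg_tok.kind in ("IDENT", "STRING", "NUMBER"):
                    arg = arg_tok.text.strip("'\"")
                else:
                    raise FilterSyntaxError("expected predicate argument", arg_tok.offset)
                self.expect("RPAREN")
                if name not in GT_PREDICATES + ("exists",):
                    raise FilterSyntaxError(f"unknown predicate {name!r}", tok.offset)
                return Predicate(name, arg)
            raise FilterSyntaxError(f"unknown identifier {name!r}", tok.offset)
        raise FilterSyntaxError(
            f"expected a value, found {tok.text or 'end of input'!r}", tok.offset
        )


def parse_filter(text: str) -> FilterExpression:
    """Parse an expression string; raises :class:`FilterSyntaxError` with a
    character offset on malformed input."""
    return FilterExpression(ast=_Parser(tokenize(text), text).parse(), text=text)


# ---------------------------------------------------------------- evaluation

@dataclass
class Pedigree:
    """Six-column PED (family, individual, father, mother, sex, phenotype);
    phenotype 2 marks affected individuals."""

    rows: list[tuple[str, str, str, str, str, str]]

    @classmethod
    def read(cls, path: str) -> "Pedigree":
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) >= 6 and not line.startswith("#"):
                    rows.append(tuple(parts[:6]))
        return cls(rows)

    def resolve_role(self, role: str) -> str | None:
        """offspring = first affected individual with both parents listed."""
        role = role.lower()
        for fam, iid, father, mother, sex, pheno in self.rows:
            if pheno == "2" and father != "0" and mother != "0":
                if role in ("offspring", "child", "proband", "kid"):
                    return iid
                if role == "father":
                    return father
                if role == "mother":
                    return mother
        return None


def _field_value(field: Field, record) -> Any:
    name = field.name
    if name == "SVTYPE":
        return record.svtype if record.svtype is not None else _MISSING
    if name == "SVLEN":
        v = record.svlen
        return v if v is not None else _MISSING
    if name == "CHROM":
        return record.chrom
    if name == "POS":
        return record.start
    if name == "END":
        return record.end
    if name.startswith("INFO."):
        key = name[5:]
        if key not in record.info:
            return _MISSING
        v = record.info[key]
        if isinstance(v, (tuple, list)):
            v = v[0] if v else _MISSING
        return True if v is None else v  # Flag INFO keys carry no value
    return _MISSING


def _as_number(v: Any) -> float | None:
    if isinstance(v, bool):
        return None
    if isinstance(v, (int, float)):
        return float(v)
    if isinstance(v, str):
        try:
            return float(v)
        except ValueError:
            return None
    return None


def _compare(op: str, a: Any, b: Any) -> bool:
    na, nb = _as_number(a), _as_number(b)
    if na is not None and nb is not None:
        a, b = na, nb
    elif isinstance(a, str) and isinstance(b, str):
        pass
    elif op == "==":
        return a == b
    elif op == "!=":
        return a != b
    else:
        return False
    return {
        "==": a == b,
        "!=": a != b,
        "<": a < b,
        "<=": a <= b,
        ">": a > b,
        ">=": a >= b,
    }[op]


def _resolve_sample(who: str, record, pedigree: Pedigree | None) -> str | None:
    if who in record.genotypes:
        return who
    if pedigree is not None:
        resolved = pedigree.resolve_role(who)
        if resolved in record.genotypes:
            return resolved
    return None


def _eval(node, record, pedigree) -> tuple[bool, bool]:
    """Returns (truth, tainted-by-missing)."""
    if isinstance(node, Cmp):
        vals = []
        for side in (node.lhs, node.rhs):
            v = side.value if isinstance(side, Literal) else _field_value(side, record)
            if v is _MISSING:
                return False, True
            vals.append(v)
        return _compare(node.op, vals[0], vals[1]), False
    if isinstance(node, Not):
        truth, tainted = _eval(node.operand, record, pedigree)
        if tainted:
            return False, True  # sticky missing: negation stays false
        return not truth, False
    if isinstance(node, BoolOp):
        results = [_eval(op, record, pedigree) for op in node.operands]
        taint = any(t for _, t in results)
        if node.op == "&&":
            return all(v for v, _ in results), taint
        return any(v for v, _ in results), taint
    if isinstance(node, Predicate):
        if node.name == "exists":
            key = node.arg if node.arg.startswith("INFO.") else f"INFO.{node.arg}"
            return _field_value(Field(key), record) is not _MISSING, False
        sample = _resolve_sample(node.arg, record, pedigree)
        if sample is None:
            return False, True
        return record.gt_class(sample) == node.name, False
    raise TypeError(f"cannot evaluate node {node!r}")


def evaluate_filter(expr: FilterExpression, record, pedigree: Pedigree | None = None) -> bool:
    """Pure predicate over one :class:`~svreview.variants.SVRecord`.

    Total over any record: missing INFO keys, absent samples and
    unresolvable pedigree roles make the enclosing comparison false rather
    than raising."""
    truth, _ = _eval(expr.ast, record, pedigree)
    return truth
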