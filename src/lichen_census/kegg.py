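"""KEGG module definitions: parsing and block-based completeness.

A KEGG module definition is a boolean expression over KEGG Orthology (KO)
identifiers describing a pathway as a sequence of *blocks* (reaction steps).
The grammar implemented here follows KEGG conventions:

* space separates sequential blocks (logical AND); only top-level spaces
  delimit the blocks counted for completeness,
* comma separates alternatives (logical OR) and binds tighter than space,
* ``+`` joins obligatory subunits of a complex (AND) and binds tighter than
  comma,
* ``-`` prefixes an optional component, which is excluded from requirements,
* parentheses group arbitrarily nested sub-expressions,
* ``--`` is KEGG's missing-step placeholder, treated as an always-absent
  leaf,
* ``M#####`` leaves reference other modules and are resolved through an
  optional expansion mapping; without one, evaluation raises.

Completeness of a module against a genome's KO set is the fraction of
top-level blocks whose expression is satisfied; a block made solely of
optional components does not enter the denominator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "ModuleDefinition",
    "CompletenessResult",
    "Node",
    "ParseError",
    "parse_definition",
    "block_present",
    "completeness",
    "partial_one_missing",
]

_KO_RE = re.compile(r"K\d{5}")
_MODULE_RE = re.compile(r"M\d{5}")

#: node kinds of the parsed expression tree
SEQUENCE = "sequence"
ALTERNATIVE = "alternative"
COMPLEX = "complex"
OPTIONAL = "optional"
KO_LEAF = "ko"
MODULE_REF = "module"
GAP = "gap"  # the '--' placeholder


class ParseError(ValueError):
    """Raised for malformed definitions; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Node:
    """One node of a parsed module-definition expression tree."""

    kind: str
    children: tuple["Node", ...] = ()
    value: str | None = None

    def leaves(self) -> Iterator["Node"]:
        if self.kind in (KO_LEAF, MODULE_REF, GAP):
            yield self
        for child in self.children:
            yield from child.leaves()


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    name: str
    definition_text: str
    root: Node = field(compare=False)

    @property
    def blocks(self) -> tuple[Node, ...]:
        if self.root.kind == SEQUENCE:
            return self.root.children
        return (self.root,)

    def kos(self) -> set[str]:
        return {n.value for n in self.root.leaves() if n.kind == KO_LEAF}

    def serialize(self) -> str:
        return _serialize(self.root, top=True)


@dataclass(frozen=True)
class CompletenessResult:
    module_id: str
    genome_id: str
    n_blocks: int
    n_present_blocks: int
    fraction: float
    complete: bool
    partial_one_missing: bool
    missing_kos: frozenset[str]


# ---------------------------------------------------------------------------
# tokenizer / recursive-descent parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"K\d{5}|M\d{5}|--|[(),+\- ]")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ParseError(f"unexpected character {text[pos]!r}", pos)
        tokens.append((m.group(), pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.text)

    def next(self) -> str:
        tok = self.tokens[self.i][0]
        self.i += 1
        return tok

    # definition := block (' ' block)*
    def parse_sequence(self) -> Node:
        blocks = [self.parse_alternative()]
        while self.peek() == " ":
            self.next()
            if self.peek() in (None, ")", " "):
                raise ParseError("dangling block separator", self.pos())
            blocks.append(self.parse_alternative())
        if len(blocks) == 1:
            return blocks[0]
        return Node(SEQUENCE, tuple(blocks))

    # block := complex (',' complex)*
    def parse_alternative(self) -> Node:
        alts = [self.parse_complex()]
        while self.peek() == ",":
            self.next()
            if self.peek() in (None, ")", ",", " "):
                raise ParseError("dangling alternative separator", self.pos())
            alts.append(self.parse_complex())
        if len(alts) == 1:
            return alts[0]
        return Node(ALTERNATIVE, tuple(alts))

    # complex := ['-'] unit (('+'|'-') unit)*
    def parse_complex(self) -> Node:
        parts: list[Node] = []
        if self.peek() == "-":  # leading optional component
            self.next()
            parts.append(Node(OPTIONAL, (self.parse_unit(),)))
        else:
            parts.append(self.parse_unit())
        while self.peek() in ("+", "-"):
            op = self.next()
            if self.peek() in (None, ")", ",", " ", "+", "-"):
                raise ParseError(f"dangling operator {op!r}", self.pos())
            unit = self.parse_unit()
            parts.append(Node(OPTIONAL, (unit,)) if op == "-" else unit)
        if len(parts) == 1:
            return parts[0]
        return Node(COMPLEX, tuple(parts))

    def parse_unit(self) -> Node:
        tok = self.peek()
        if tok == "(":
            self.next()
            inner = self.parse_sequence()
            if self.peek() != ")":
                raise ParseError("unbalanced parenthesis", self.pos())
            self.next()
            return inner
        if tok == "--":
            self.next()
            return Node(GAP, value="--")
        if tok is not None and _KO_RE.fullmatch(tok):
            self.next()
            return Node(KO_LEAF, value=tok)
        if tok is not None and _MODULE_RE.fullmatch(tok):
            self.next()
            return Node(MODULE_REF, value=tok)
        raise ParseError(f"expected KO, module id, '--' or '('; got {tok!r}", self.pos())


def parse_definition(text: str, module_id: str = "", name: str = "") -> ModuleDefinition:
    """Parse a module definition string into an expression tree.

    Raises :class:`ParseError` (with position) on unbalanced parentheses or
    dangling operators; parse → serialize → parse is a fixed point.
    """
    stripped = text.strip()
    if not stripped:
        raise ParseError("empty definition", 0)
    parser = _Parser(stripped)
    root = parser.parse_sequence()
    if parser.peek() is not None:
        raise ParseError(f"trailing token {parser.peek()!r}", parser.pos())
    return ModuleDefinition(module_id=module_id, name=name, definition_text=stripped, root=root)


def _serialize(node: Node, top: bool = False) -> str:
    if node.kind in (KO_LEAF, MODULE_REF, GAP):
        return node.value or ""
    if node.kind == OPTIONAL:
        return "-" + _wrap(node.children[0], COMPLEX)
    if node.kind == SEQUENCE:
        parts = [_wrap(c, SEQUENCE) for c in node.children]
        out = " ".join(parts)
        return out if top else f"({out})"
    if node.kind == ALTERNATIVE:
        return ",".join(_wrap(c, ALTERNATIVE) for c in node.children)
    if node.kind == COMPLEX:
        parts = []
        for c in node.children:
            if c.kind == OPTIONAL:
                parts.append("-" + _wrap(c.children[0], COMPLEX))
            else:
                parts.append(("+" if parts else "") + _wrap(c, COMPLEX))
        return "".join(parts)
    raise ValueError(f"unknown node kind {node.kind!r}")


def _wrap(node: Node, parent_kind: str) -> str:
    text = _serialize(node)
    needs_parens = (
        (parent_kind == ALTERNATIVE and node.kind in (SEQUENCE,))
        or (parent_kind == COMPLEX and node.kind in (SEQUENCE, ALTERNATIVE, COMPLEX))
    )
    # SEQUENCE children already self-parenthesize via _serialize(top=False)
    if needs_parens and not text.startswith("("):
        return f"({text})"
    return text


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


class UnresolvedModuleError(KeyError):
    """A nested M##### reference was hit without a resolution mapping."""


def _is_optional_only(node: Node) -> bool:
    if node.kind == OPTIONAL:
        return True
    if node.kind == GAP:
        return False
    if node.kind in (KO_LEAF, MODULE_REF):
        return False
    if not node.children:
        return False
    if node.kind == COMPLEX:
        return all(_is_optional_only(c) for c in node.children)
    return all(_is_optional_only(c) for c in node.children)


def block_present(
    node: Node,
    kos: set[str] | frozenset[str],
    module_expansion: Mapping[str, set[str]] | None = None,
) -> bool:
    """Recursively evaluate one block expression against a KO set.

    SEQUENCE and COMPLEX require all (non-optional) children, ALTERNATIVE
    any child; OPTIONAL is always satisfied; a KO leaf tests membership; a
    ``--`` gap is never satisfied. MODULE_REF leaves are satisfied when all
    KOs in ``module_expansion[module_id]`` are present; without a mapping,
    :class:`UnresolvedModuleError` is raised.
    """
    kind = node.kind
    if kind == KO_LEAF:
        return node.value in kos
    if kind == GAP:
        return False
    if kind == MODULE_REF:
        if module_expansion is None or node.value not in module_expansion:
            raise UnresolvedModuleError(
                f"nested module reference {node.value} has no expansion mapping"
            )
        required = module_expansion[node.value]
        return all(k in kos for k in required)
    if kind == OPTIONAL:
        return True
    if kind == ALTERNATIVE:
        return any(block_present(c, kos, module_expansion) for c in node.children)
    if kind in (SEQUENCE, COMPLEX):
        return all(
            block_present(c, kos, module_expansion)
            for c in node.children
            if c.kind != OPTIONAL
        )
    raise ValueError(f"unknown node kind {kind!r}")


def _required_kos(node: Node) -> set[str]:
    """KOs appearing in non-optional positions of a block."""
    if node.kind == KO_LEAF:
        return {node.value}
    if node.kind in (GAP, MODULE_REF, OPTIONAL):
        return set()
    out: set[str] = set()
    for child in node.children:
        if child.kind == OPTIONAL:
            continue
        out |= _required_kos(child)
    return out


def completeness(
    module: ModuleDefinition,
    kos: set[str] | frozenset[str],
    genome_id: str = "",
    module_expansion: Mapping[str, set[str]] | None = None,
) -> CompletenessResult:
    """Fraction of the module's blocks satisfied by a genome's KO set.

    Blocks consisting only of optional components are excluded from the
    denominator; a module with no countable blocks is an error.
    """
    counted = [b for b in module.blocks if not _is_optional_only(b)]
    if not counted:
        raise ValueError(f"module {module.module_id or '<anonymous>'} has no countable blocks")
    present = [block_present(b, kos, module_expansion) for b in counted]
    n_present = sum(present)
    fraction = n_present / len(counted)
    missing: set[str] = set()
    for blk, ok in zip(counted, present):
        if not ok:
            missing |= _required_kos(blk) - set(kos)
    complete = n_present == len(counted)
    rescued = (
        None
        if complete
        else partial_one_missing(module, kos, module_expansion=module_expansion)[1]
    )
    return CompletenessResult(
        module_id=module.module_id,
        genome_id=genome_id,
        n_blocks=len(counted),
        n_present_blocks=n_present,
        fraction=fraction,
        complete=complete,
        partial_one_missing=(not complete and rescued is not None),
        missing_kos=frozenset(missing),
    )


def partial_one_missing(
    module: ModuleDefinition,
    kos: set[str] | frozenset[str],
    module_expansion: Mapping[str, set[str]] | None = None,
) -> tuple[bool, str | None]:
    """Whether adding a single KO would complete an incomplete module.

    Interprets "allowing one missing gene" literally as one gene (KO), not
    one block. Returns ``(flag, rescuing_ko)``; a complete module returns
    ``(False, None)``.
    """
    counted = [b for b in module.blocks if not _is_optional_only(b)]
    if all(block_present(b, kos, module_expansion) for b in counted):
        return False, None
    kos = set(kos)
    for candidate in sorted(module.kos() - kos):
        augmented = kos | {candidate}
        if all(block_present(b, augmented, module_expansion) for b in counted):
            return True, candidate
    return False, None
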