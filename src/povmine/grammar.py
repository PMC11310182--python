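"""Tokenizer and recursive-descent parser for the textual tree grammar.

One grammar serves variants, rewrite patterns and process trees:

    node     := leaf | operator "(" node ("," node)* ")"
    leaf     := "'" label "'" | "tau" | "..."
    operator := "->" (sequence) | "+" (parallel) | "X" (choice) | "*" (loop)

Which leaves and operators are admissible is decided by the caller; this
module only produces a neutral s-expression made of ``(op, children)``
tuples, ``("leaf", label)``, ``("tau",)`` and ``("wildcard",)``.
"""

from __future__ import annotations

from typing import Iterator

SEQ_TOKEN = "->"
PAR_TOKEN = "+"
XOR_TOKEN = "X"
LOOP_TOKEN = "*"
TAU_TOKEN = "tau"
WILDCARD_TOKEN = "..."

_OPERATORS = (SEQ_TOKEN, PAR_TOKEN, XOR_TOKEN, LOOP_TOKEN)


class ParseError(ValueError):
    """Malformed tree text; carries the character position of the defect."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    """Yield (kind, value, position) tokens.

    Kinds: 'op', 'lparen', 'rparen', 'comma', 'label', 'tau', 'wildcard'.
    """
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c == "(":
            yield ("lparen", "(", i)
            i += 1
        elif c == ")":
            yield ("rparen", ")", i)
            i += 1
        elif c == ",":
            yield ("comma", ",", i)
            i += 1
        elif c == "'":
            j = text.find("'", i + 1)
            if j < 0:
                raise ParseError("unterminated label quote", i)
            label = text[i + 1 : j]
            if not label:
                raise ParseError("empty activity label", i)
            yield ("label", label, i)
            i = j + 1
        elif text.startswith(SEQ_TOKEN, i):
            yield ("op", SEQ_TOKEN, i)
            i += 2
        elif text.startswith(WILDCARD_TOKEN, i):
            yield ("wildcard", WILDCARD_TOKEN, i)
            i += 3
        elif c in (PAR_TOKEN, XOR_TOKEN, LOOP_TOKEN):
            yield ("op", c, i)
            i += 1
        elif text.startswith(TAU_TOKEN, i):
            yield ("tau", TAU_TOKEN, i)
            i += 3
        else:
            raise ParseError(f"unexpected character {c!r}", i)


def parse(text: str) -> tuple:
    """Parse ``text`` into a neutral s-expression tree."""
    tokens = list(_tokenize(text))
    pos = 0

    def peek() -> tuple[str, str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def expect(kind: str) -> tuple[str, str, int]:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ParseError(f"expected {kind}, found end of input", len(text))
        if tok[0] != kind:
            raise ParseError(f"expected {kind}, found {tok[1]!r}", tok[2])
        pos += 1
        return tok

    def node() -> tuple:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ParseError("expected a node, found end of input", len(text))
        kind, value, at = tok
        if kind == "label":
            pos += 1
            return ("leaf", value)
        if kind == "tau":
            pos += 1
            return ("tau",)
        if kind == "wildcard":
            pos += 1
            return ("wildcard",)
        if kind == "op":
            pos += 1
            expect("lparen")
            children = [node()]
            while peek() and peek()[0] == "comma":
                pos += 1
                children.append(node())
            expect("rparen")
            return (value, children)
        raise ParseError(f"unexpected token {value!r}", at)

    result = node()
    tok = peek()
    if tok is not None:
        raise ParseError(f"trailing input {tok[1]!r}", tok[2])
    return result


def quote_label(label: str) -> str:
    if "'" in label:
        raise ValueError(f"activity label may not contain a single quote: {label!r}")
    return f"'{label}'"
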