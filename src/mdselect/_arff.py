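"""Minimal ARFF reader/writer for the dense multi-label dialects.

Supports numeric and nominal attributes, ``?`` missing values, quoted
tokens, and ``%`` comments.  Sparse ``{...}`` data rows are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ParseError

_NUMERIC_TYPES = {"numeric", "real", "integer"}


@dataclass
class ArffAttribute:
    name: str
    type_decl: str  # "numeric" or "nominal"
    domain: list[str] | None = None  # nominal values in declaration order


@dataclass
class ArffFile:
    relation: str
    attributes: list[ArffAttribute]
    rows: list[list[str | None]] = field(default_factory=list)


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "'\"":
        return token[1:-1].replace("\\'", "'").replace('\\"', '"')
    return token


def _split_csv(line: str) -> list[str]:
    """Split a data/nominal line on commas, honouring quotes."""
    out, buf, quote = [], [], None
    for ch in line:
        if quote:
            buf.append(ch)
            if ch == quote and (len(buf) < 2 or buf[-2] != "\\"):
                quote = None
        elif ch in "'\"":
            quote = ch
            buf.append(ch)
        elif ch == ",":
            out.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    out.append("".join(buf))
    return [t.strip() for t in out]


_ATTR_RE = re.compile(r"@attribute\s+(.+)", re.IGNORECASE)


def _parse_attribute(decl: str, lineno: int) -> ArffAttribute:
    decl = decl.strip()
    if decl.startswith(("'", '"')):
        quote = decl[0]
        end = decl.find(quote, 1)
        while end != -1 and decl[end - 1] == "\\":
            end = decl.find(quote, end + 1)
        if end == -1:
            raise ParseError(f"line {lineno}: unterminated attribute name")
        name, rest = _unquote(decl[: end + 1]), decl[end + 1 :].strip()
    else:
        parts = decl.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: attribute declaration needs a type")
        name, rest = parts
    rest = rest.strip()
    if rest.lower() in _NUMERIC_TYPES:
        return ArffAttribute(name, "numeric")
    if rest.startswith("{") and rest.endswith("}"):
        values = [_unquote(v) for v in _split_csv(rest[1:-1])]
        if not values:
            raise ParseError(f"line {lineno}: empty nominal domain for {name!r}")
        return ArffAttribute(name, "nominal", values)
    raise ParseError(f"line {lineno}: unsupported attribute type {rest!r}")


def load_arff(path: str) -> ArffFile:
    relation = ""
    attributes: list[ArffAttribute] = []
    rows: list[list[str | None]] = []
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if not in_data:
                if low.startswith("@relation"):
                    relation = _unquote(line.split(None, 1)[1]) if " " in line else ""
                elif low.startswith("@attribute"):
                    m = _ATTR_RE.match(line)
                    if m is None:
                        raise ParseError(f"line {lineno}: malformed @attribute")
                    attributes.append(_parse_attribute(m.group(1), lineno))
                elif low.startswith("@data"):
                    if not attributes:
                        raise ParseError(f"line {lineno}: @data before any @attribute")
                    in_data = True
                else:
                    raise ParseError(f"line {lineno}: unexpected header line {line!r}")
                continue
            if line.startswith("{"):
                raise ParseError(f"line {lineno}: sparse ARFF rows are not supported")
            tokens = [_unquote(t) for t in _split_csv(line)]
            if len(tokens) != len(attributes):
                raise ParseError(
                    f"line {lineno}: expected {len(attributes)} values, got {len(tokens)}"
                )
            rows.append([None if t == "?" else t for t in tokens])
    if not in_data:
        raise ParseError("no @data section found")
    return ArffFile(relation, attributes, rows)


def _quote_if_needed(value: str) -> str:
    if value == "" or re.search(r"[\s,{}%'\"]", value):
        return "'" + value.replace("'", "\\'") + "'"
    return value


def dump_arff(arff: ArffFile, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"@relation {_quote_if_needed(arff.relation)}\n\n")
        for attr in arff.attributes:
            if attr.type_decl == "numeric":
                fh.write(f"@attribute {_quote_if_needed(attr.name)} numeric\n")
            else:
                domain = ",".join(_quote_if_needed(v) for v in attr.domain or [])
                fh.write(f"@attribute {_quote_if_needed(attr.name)} {{{domain}}}\n")
        fh.write("\n@data\n")
        for row in arff.rows:
            fh.write(
                ",".join("?" if v is None else _quote_if_needed(v) for v in row) + "\n"
            )
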