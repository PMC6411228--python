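"""Parsing of workflow files into a structured model.

A workflow file (extension ``.pfw``) is plain UTF-8 text divided into
sections by bracketed headers.  A section header names one or more
(workflow, step-index) entries — ``[lasso_1, ridge_1]`` declares a step
shared by the ``lasso`` and ``ridge`` workflows — and may carry options,
most importantly ``provides`` wildcard patterns for outcome-oriented
steps.  A section body holds directives (``input:``, ``output:``,
``depends:``, ``task:``, ``parameter:``), action calls with embedded
scripts, and plain statements.

Header grammar::

    header  = "[" entry ("," entry)* (":" option ("," option)*)? "]"
    entry   = name | name "_" index | index      # bare index -> "default"
    option  = key "=" expression

Code appearing before the first header is split between global scope
(parameter definitions and plain assignments) and an implicit ``default``
section (action calls and directives), so that a file that is nothing but
two bare script blocks is still a runnable one-step workflow.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Iterator

from .errors import ParseError, PolyflowError
from .interpolation import evaluate_expression

__all__ = [
    "Script", "Section", "StepHeader", "ParameterDef", "Statement",
    "WorkflowPlan", "parse_script", "parse_header", "resolve_workflow",
    "extract_help", "serialize",
]

DIRECTIVES = ("input", "output", "depends", "task", "parameter")

TYPE_TAGS = {
    "string": str,
    "integer": int,
    "float": float,
    "boolean": bool,
    "path": str,
    "list-of-string": list,
    "list-of-path": list,
}

_HEADER_RE = re.compile(r"^\[(?P<body>.*)\]\s*(#.*)?$")
_ACTION_RE = re.compile(r"^(?P<name>[A-Za-z_]\w*)\s*:\s*(?P<options>.*)$")
_IDENT_RE = re.compile(r"^[A-Za-z_]\w*$")
_NAME_INDEX_RE = re.compile(r"^(?P<name>[A-Za-z_]\w*?)_(?P<index>\d+)$")


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass
class StepHeader:
    """Parsed section header: entries plus options."""
    entries: list[tuple[str, int | None]]
    options: dict[str, Any] = field(default_factory=dict)
    lineno: int = field(default=0, compare=False)

    @property
    def provides(self) -> list[str]:
        pats = self.options.get("provides", [])
        if isinstance(pats, str):
            return [pats]
        return list(pats)

    def display_name(self) -> str:
        name, index = self.entries[0]
        return name if index is None else f"{name}_{index}"

    def render(self) -> str:
        parts = [n if i is None else f"{n}_{i}" for n, i in self.entries]
        text = ", ".join(parts)
        if self.options:
            opts = ", ".join(f"{k} = {v!r}" for k, v in self.options.items())
            text += f": {opts}"
        return f"[{text}]"


@dataclass
class ParameterDef:
    """A command-line parameter: typed, optionally defaulted, documented."""
    name: str
    type_tag: str
    default: Any = None
    has_default: bool = False
    comment: str = ""
    lineno: int = field(default=0, compare=False)

    def coerce(self, text: str | list[str]) -> Any:
        """Coerce a command-line string (or repeated strings) to the type."""
        if self.type_tag in ("list-of-string", "list-of-path"):
            if isinstance(text, str):
                return [text]
            return list(text)
        if isinstance(text, list):
            if len(text) != 1:
                raise PolyflowError(
                    f"parameter '{self.name}' accepts a single value")
            text = text[0]
        if self.type_tag == "integer":
            return int(text)
        if self.type_tag == "float":
            return float(text)
        if self.type_tag == "boolean":
            if text.lower() in ("1", "true", "yes", "on"):
                return True
            if text.lower() in ("0", "false", "no", "off"):
                return False
            raise PolyflowError(
                f"parameter '{self.name}': cannot interpret {text!r} as boolean")
        return text


@dataclass
class Statement:
    """One section-body statement.

    ``kind`` is one of ``input_spec``, ``output_spec``, ``depends_spec``,
    ``task_spec``, ``action_call``, ``plain``.  ``payload`` is
    kind-specific: specs hold an expression string and an option mapping;
    action calls hold the action name, verbatim (de-indented) script text,
    and options; plain statements hold the code block.
    """
    kind: str
    payload: dict[str, Any]
    lineno: int = field(default=0, compare=False)


@dataclass
class Section:
    """A header, its descriptive comment, parameters, and body statements."""
    header: StepHeader
    description: str = ""
    parameters: list[ParameterDef] = field(default_factory=list)
    body: list[Statement] = field(default_factory=list)

    def statements_of(self, kind: str) -> list[Statement]:
        return [s for s in self.body if s.kind == kind]

    def single(self, kind: str) -> Statement | None:
        found = self.statements_of(kind)
        return found[0] if found else None

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.header.entries]


@dataclass
class Script:
    """A parsed workflow file."""
    path: str | None = None
    global_statements: list[Statement] = field(default_factory=list)
    parameters: list[ParameterDef] = field(default_factory=list)
    sections: list[Section] = field(default_factory=list)
    source: str = field(default="", compare=False)

    def workflow_names(self) -> list[str]:
        seen: list[str] = []
        for sec in self.sections:
            for name, _index in sec.header.entries:
                if name not in seen:
                    seen.append(name)
        return seen

    def all_parameters(self) -> list[ParameterDef]:
        out = list(self.parameters)
        for sec in self.sections:
            out.extend(sec.parameters)
        return out

    def section_by_entry(self, name: str, index: int | None) -> Section | None:
        for sec in self.sections:
            if (name, index) in sec.header.entries:
                return sec
        return None


@dataclass
class WorkflowPlan:
    """An ordered step plan for one named workflow."""
    name: str
    steps: list[tuple[int, Section]]  # ascending bound indices

    @property
    def indices(self) -> list[int]:
        return [i for i, _ in self.steps]


# ---------------------------------------------------------------------------
# header parsing
# ---------------------------------------------------------------------------

def _split_top_level(text: str, sep: str = ",") -> list[str]:
    """Split on a separator, ignoring separators inside brackets/quotes."""
    parts, depth, quote, start = [], 0, None, 0
    i = 0
    while i < len(text):
        c = text[i]
        if quote:
            if c == "\\":
                i += 2
                continue
            if c == quote:
                quote = None
        elif c in "\"'":
            quote = c
        elif c in "([{":
            depth += 1
        elif c in ")]}":
            depth -= 1
        elif c == sep and depth == 0:
            parts.append(text[start:i])
            start = i + 1
        i += 1
    parts.append(text[start:])
    return parts


def _find_top_level(text: str, char: str) -> int:
    depth, quote = 0, None
    for i, c in enumerate(text):
        if quote:
            if c == quote and (i == 0 or text[i - 1] != "\\"):
                quote = None
        elif c in "\"'":
            quote = c
        elif c in "([{":
            depth += 1
        elif c in ")]}":
            depth -= 1
        elif c == char and depth == 0:
            return i
    return -1


def _parse_options(text: str, lineno: int) -> dict[str, Any]:
    options: dict[str, Any] = {}
    for item in _split_top_level(text):
        item = item.strip()
        if not item:
            continue
        eq = _find_top_level(item, "=")
        if eq < 0:
            raise ParseError(f"malformed option {item!r} (expected key = value)", lineno)
        key = item[:eq].strip()
        if not _IDENT_RE.match(key):
            raise ParseError(f"malformed option name {key!r}", lineno)
        try:
            options[key] = evaluate_expression(item[eq + 1:], {})
        except PolyflowError as exc:
            raise ParseError(f"option {key!r}: {exc}", lineno) from exc
    return options


def parse_header(line: str, lineno: int = 0) -> StepHeader:
    """Parse a bracketed section header line into a :class:`StepHeader`."""
    m = _HEADER_RE.match(line.strip())
    if not m:
        raise ParseError(f"malformed section header {line.strip()!r}", lineno)
    body = m.group("body").strip()
    if not body:
        raise ParseError("empty section header", lineno)
    colon = _find_top_level(body, ":")
    entry_text = body if colon < 0 else body[:colon]
    option_text = "" if colon < 0 else body[colon + 1:]
    entries: list[tuple[str, int | None]] = []
    for token in _split_top_level(entry_text):
        token = token.strip()
        if not token:
            raise ParseError("empty entry in section header", lineno)
        if token.isdigit():
            entries.append(("default", int(token)))
            continue
        m2 = _NAME_INDEX_RE.match(token)
        if m2:
            entries.append((m2.group("name"), int(m2.group("index"))))
        elif _IDENT_RE.match(token):
            entries.append((token, None))
        else:
            raise ParseError(
                f"malformed header entry {token!r} (expected name, name_index, "
                f"or bare index)", lineno)
    if not entries:
        raise ParseError("section header declares no entries", lineno)
    options = _parse_options(option_text, lineno) if option_text.strip() else {}
    return StepHeader(entries=entries, options=options, lineno=lineno)


# ---------------------------------------------------------------------------
# script parsing
# ---------------------------------------------------------------------------

def _infer_type(value: Any) -> str:
    if isinstance(value, bool):
        return "boolean"
    if isinstance(value, int):
        return "integer"
    if isinstance(value, float):
        return "float"
    if isinstance(value, (list, tuple)):
        return "list-of-string"
    return "string"


def _parse_parameter(payload: str, comment: str, lineno: int) -> ParameterDef:
    payload = payload.strip()
    eq = _find_top_level(payload, "=")
    if eq >= 0:
        name = payload[:eq].strip()
        if not _IDENT_RE.match(name):
            raise ParseError(f"malformed parameter name {name!r}", lineno)
        try:
            default = evaluate_expression(payload[eq + 1:], {})
        except PolyflowError as exc:
            raise ParseError(f"parameter '{name}': {exc}", lineno) from exc
        return ParameterDef(name=name, type_tag=_infer_type(default),
                            default=default, has_default=True,
                            comment=comment, lineno=lineno)
    colon = _find_top_level(payload, ":")
    if colon >= 0:
        name = payload[:colon].strip()
        tag = payload[colon + 1:].strip()
        if tag not in TYPE_TAGS:
            raise ParseError(
                f"unknown parameter type {tag!r} (expected one of "
                f"{', '.join(sorted(TYPE_TAGS))})", lineno)
    else:
        name, tag = payload, "string"
    if not _IDENT_RE.match(name):
        raise ParseError(f"malformed parameter name {name!r}", lineno)
    return ParameterDef(name=name, type_tag=tag, comment=comment, lineno=lineno)


def _parse_spec(kind: str, payload: str, lineno: int) -> Statement:
    """Parse an input/output/depends/task directive payload.

    Top-level ``key = value`` items whose key is a known option (or, for
    outputs, any identifier, which defines a named-output label) are
    options; the rest joins the expression.
    """
    known = {
        "input_spec": {"group_by", "paired_with"},
        "output_spec": set(),
        "depends_spec": set(),
        "task_spec": {"queue"},
    }[kind]
    exprs: list[str] = []
    options: dict[str, str] = {}
    label = None
    for item in _split_top_level(payload):
        stripped = item.strip()
        if not stripped:
            continue
        eq = _find_top_level(stripped, "=")
        if eq > 0 and stripped[eq - 1] not in "<>!=" and \
                (eq + 1 >= len(stripped) or stripped[eq + 1] != "="):
            key = stripped[:eq].strip()
            if _IDENT_RE.match(key):
                value = stripped[eq + 1:].strip()
                if key in known:
                    options[key] = value
                    continue
                if kind == "output_spec":
                    if label is not None:
                        raise ParseError(
                            "an output statement defines at most one label", lineno)
                    label = key
                    exprs.append(value)
                    continue
        exprs.append(stripped)
    payload_dict: dict[str, Any] = {"expr": ", ".join(exprs), "options": options}
    if kind == "output_spec":
        payload_dict["label"] = label
    return Statement(kind=kind, payload=payload_dict, lineno=lineno)


class _Lines:
    def __init__(self, text: str):
        self.lines = text.splitlines()
        self.pos = 0

    def peek(self) -> str | None:
        return self.lines[self.pos] if self.pos < len(self.lines) else None

    def next(self) -> str:
        line = self.lines[self.pos]
        self.pos += 1
        return line

    @property
    def lineno(self) -> int:
        return self.pos  # 1-based number of the line just consumed


def _dedent_block(lines: list[str]) -> str:
    while lines and not lines[-1].strip():
        lines.pop()
    non_blank = [l for l in lines if l.strip()]
    if not non_blank:
        return ""
    prefix = None
    for l in non_blank:
        indent = l[:len(l) - len(l.lstrip())]
        prefix = indent if prefix is None else _common_prefix(prefix, indent)
    n = len(prefix or "")
    return "\n".join(l[n:] if l.strip() else "" for l in lines)


def _common_prefix(a: str, b: str) -> str:
    out = []
    for x, y in zip(a, b):
        if x != y:
            break
        out.append(x)
    return "".join(out)


def _is_continuation_open(text: str) -> bool:
    """True when brackets or quotes are still open at end of text."""
    depth, quote = 0, None
    i = 0
    while i < len(text):
        c = text[i]
        if quote:
            if c == "\\":
                i += 2
                continue
            if c == quote:
                quote = None
        elif c in "\"'":
            quote = c
        elif c in "([{":
            depth += 1
        elif c in ")]}":
            depth -= 1
        elif c == "#" and depth == 0:
            break
        i += 1
    return depth > 0


def _strip_comment(text: str) -> str:
    depth, quote = 0, None
    i = 0
    while i < len(text):
        c = text[i]
        if quote:
            if c == "\\":
                i += 2
                continue
            if c == quote:
                quote = None
        elif c in "\"'":
            quote = c
        elif c == "#":
            return text[:i].rstrip()
        i += 1
    return text.rstrip()


def _read_logical_line(lines: _Lines) -> tuple[str, int]:
    """Read a directive line, joining bracket continuations."""
    text = lines.next()
    lineno = lines.lineno
    while _is_continuation_open(_strip_comment(text)) and lines.peek() is not None:
        text += "\n" + lines.next()
    return text, lineno


def _collect_block(lines: _Lines) -> list[str]:
    """Collect following indented or blank lines (an embedded script)."""
    block: list[str] = []
    while (nxt := lines.peek()) is not None:
        if nxt.strip() and not nxt[0].isspace():
            break
        block.append(lines.next())
    return block


def _collect_plain(first: str, lines: _Lines) -> str:
    """A plain statement plus its indented suite (if/for bodies)."""
    parts = [first]
    while _is_continuation_open(_strip_comment("\n".join(parts))) and lines.peek() is not None:
        parts.append(lines.next())
    if _strip_comment(parts[-1]).rstrip().endswith(":"):
        while (nxt := lines.peek()) is not None:
            if nxt.strip() and not nxt[0].isspace():
                break
            parts.append(lines.next())
    while parts and not parts[-1].strip():
        parts.pop()
    return "\n".join(parts)


def parse_script(text: str, path: str | None = None) -> Script:
    """Parse workflow source text into a :class:`Script`.

    Raises :class:`ParseError` (with a line number) on malformed headers,
    duplicate ``(name, index)`` pairs, or invalid directives.
    """
    script = Script(path=path, source=text)
    lines = _Lines(text)
    pending_comments: list[str] = []

    current: Section | None = None  # None while in the leading global region
    implicit: Section | None = None
    in_global = True

    def target_section() -> Section:
        nonlocal implicit, in_global
        if current is not None:
            return current
        if implicit is None:
            implicit = Section(header=StepHeader(entries=[("default", None)], lineno=0))
            script.sections.insert(0, implicit)
        in_global = False
        return implicit

    while (raw := lines.peek()) is not None:
        stripped = raw.strip()
        if not stripped:
            lines.next()
            pending_comments.clear()
            continue
        if stripped.startswith("#") and not raw[0].isspace():
            lines.next()
            pending_comments.append(stripped.lstrip("#").strip())
            continue
        if raw.startswith("["):
            line, lineno = lines.next(), lines.lineno
            header = parse_header(line, lineno)
            current = Section(header=header,
                              description="\n".join(pending_comments).strip())
            pending_comments.clear()
            script.sections.append(current)
            continue
        if raw[0].isspace():
            raise ParseError(f"unexpected indentation: {stripped!r}", lines.pos + 1)

        m = _ACTION_RE.match(raw)
        keyword = m.group("name") if m else None
        if keyword in DIRECTIVES:
            logical, lineno = _read_logical_line(lines)
            payload = _strip_comment(logical[logical.index(":") + 1:])
            if keyword == "parameter":
                param = _parse_parameter(payload, "\n".join(pending_comments).strip(),
                                         lineno)
                holder = current.parameters if current is not None else script.parameters
                if any(p.name == param.name for p in holder):
                    raise ParseError(
                        f"duplicate parameter '{param.name}'", lineno)
                holder.append(param)
            else:
                sec = target_section()
                kind = f"{keyword}_spec"
                if kind in ("input_spec", "output_spec", "task_spec") and \
                        sec.single(kind) is not None:
                    raise ParseError(
                        f"section allows at most one {keyword} statement", lineno)
                sec.body.append(_parse_spec(kind, payload, lineno))
            pending_comments.clear()
            continue
        if m and _looks_like_action(raw, m):
            line, lineno = lines.next(), lines.lineno
            opts_text = _strip_comment(m.group("options"))
            options = _parse_options(opts_text, lineno) if opts_text else {}
            block = _collect_block(lines)
            sec = target_section()
            sec.body.append(Statement(
                kind="action_call",
                payload={"name": m.group("name"),
                         "script": _dedent_block(block),
                         "options": options},
                lineno=lineno))
            pending_comments.clear()
            continue

        # plain statement (possibly with an indented suite)
        first, lineno = lines.next(), lines.lineno
        code = _collect_plain(first, lines)
        stmt = Statement(kind="plain", payload={"code": code}, lineno=lineno)
        if in_global and current is None and implicit is None and _is_assignment(code):
            script.global_statements.append(stmt)
        else:
            target_section().body.append(stmt)
        pending_comments.clear()

    _check_duplicates(script)
    return script


def _looks_like_action(raw: str, m: re.Match) -> bool:
    """Heuristic: ``name:`` (with only options after the colon) is an action."""
    rest = _strip_comment(m.group("options"))
    if not rest:
        return True
    # options must parse as comma-separated key = value items
    for item in _split_top_level(rest):
        item = item.strip()
        if not item:
            continue
        eq = _find_top_level(item, "=")
        if eq <= 0 or not _IDENT_RE.match(item[:eq].strip()):
            return False
    return True


def _is_assignment(code: str) -> bool:
    import ast as _ast
    try:
        tree = _ast.parse(code)
    except SyntaxError:
        return False
    return all(isinstance(n, (_ast.Assign, _ast.AugAssign)) for n in tree.body)


def _check_duplicates(script: Script) -> None:
    seen: dict[tuple[str, int | None], int] = {}
    for sec in script.sections:
        for entry in sec.header.entries:
            if entry in seen:
                name = entry[0] if entry[1] is None else f"{entry[0]}_{entry[1]}"
                raise ParseError(
                    f"duplicate step '{name}' (also declared at line "
                    f"{seen[entry]})", sec.header.lineno)
            seen[entry] = sec.header.lineno


# ---------------------------------------------------------------------------
# workflow resolution
# ---------------------------------------------------------------------------

def resolve_workflow(script: Script, name: str | None = None) -> WorkflowPlan:
    """Resolve a workflow name to its ordered step plan.

    Sections listing the name at any index are included, sorted by
    ascending index (an index-free entry binds at index 0).  Shared
    sections appear in the plans of all workflows they name.
    """
    if name is None:
        if script.section_by_entry("default", None) or any(
                n == "default" for s in script.sections
                for n, _ in s.header.entries):
            name = "default"
        else:
            names = script.workflow_names()
            if len(names) == 1:
                name = names[0]
            else:
                raise PolyflowError(
                    "no workflow specified and no 'default' entry exists; "
                    f"available workflows: {', '.join(names) or '(none)'}")
    steps: list[tuple[int, Section]] = []
    for sec in script.sections:
        for ename, index in sec.header.entries:
            if ename == name:
                steps.append((0 if index is None else index, sec))
    if not steps:
        names = script.workflow_names()
        raise PolyflowError(
            f"unknown workflow '{name}'; available workflows: "
            f"{', '.join(names) or '(none)'}")
    steps.sort(key=lambda t: t[0])
    return WorkflowPlan(name=name, steps=steps)


# ---------------------------------------------------------------------------
# help extraction and serialization
# ---------------------------------------------------------------------------

def extract_help(script: Script) -> str:
    """Build the ``-h`` help text: workflows with descriptions, parameters."""
    lines = [f"usage: polyflow run {script.path or '<script>'} "
             "[workflow] [options] [--parameter value ...]"]
    names = script.workflow_names()
    if names:
        lines.append("")
        lines.append("workflows:")
        for name in names:
            descs = [s.description for s in script.sections
                     if name in s.names and s.description]
            first = descs[0].splitlines()[0] if descs else ""
            lines.append(f"  {name:<20} {first}".rstrip())
    params = script.all_parameters()
    if params:
        lines.append("")
        lines.append("parameters:")
        for p in params:
            default = f" (default: {p.default!r})" if p.has_default else " (required)"
            comment = p.comment.splitlines()[0] if p.comment else ""
            lines.append(f"  --{p.name:<18} {p.type_tag}{default}"
                         + (f"  {comment}" if comment else ""))
    return "\n".join(lines) + "\n"


def _render_statement(stmt: Statement) -> str:
    if stmt.kind == "plain":
        return stmt.payload["code"]
    if stmt.kind == "action_call":
        name = stmt.payload["name"]
        opts = ", ".join(f"{k}={v!r}" for k, v in stmt.payload["options"].items())
        head = f"{name}:" + (f" {opts}" if opts else "")
        body = stmt.payload["script"]
        if not body:
            return head
        indented = "\n".join("    " + l if l.strip() else "" for l in body.splitlines())
        return head + "\n" + indented
    keyword = stmt.kind.removesuffix("_spec")
    parts = []
    if stmt.kind == "output_spec" and stmt.payload.get("label"):
        parts.append(f"{stmt.payload['label']} = {stmt.payload['expr']}")
    elif stmt.payload["expr"]:
        parts.append(stmt.payload["expr"])
    for k, v in stmt.payload["options"].items():
        parts.append(f"{k}={v}")
    return f"{keyword}: {', '.join(parts)}".rstrip(": ") if parts else f"{keyword}:"


def _render_parameter(p: ParameterDef) -> str:
    lines = [f"# {c}" for c in p.comment.splitlines()] if p.comment else []
    if p.has_default:
        lines.append(f"parameter: {p.name} = {p.default!r}")
    else:
        lines.append(f"parameter: {p.name}: {p.type_tag}")
    return "\n".join(lines)


def serialize(script: Script) -> str:
    """Render a parsed script back to workflow-file text.

    Re-parsing the result yields a structurally equal script; embedded
    script bodies survive byte-identically.
    """
    chunks: list[str] = []
    for p in script.parameters:
        chunks.append(_render_parameter(p))
    for stmt in script.global_statements:
        chunks.append(_render_statement(stmt))
    for sec in script.sections:
        block: list[str] = []
        if sec.description:
            block.extend(f"# {l}" for l in sec.description.splitlines())
        implicit = sec.header.entries == [("default", None)] and sec.header.lineno == 0
        if not implicit or sec.header.options:
            block.append(sec.header.render())
        for p in sec.parameters:
            block.append(_render_parameter(p))
        for stmt in sec.body:
            block.append(_render_statement(stmt))
        chunks.append("\n".join(block))
    return "\n\n".join(chunks) + ("\n" if chunks else "")
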