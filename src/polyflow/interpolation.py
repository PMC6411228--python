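"""Template expansion and value rendering for embedded scripts.

Workflow variables are substituted into embedded scripts with
``expand_text``, which evaluates delimiter-bounded expressions against a
:class:`VariableScope`.  Path values support single-letter format options
(``format_path``), e.g. ``{_input:n}`` strips the extension of every input
path.  Expression evaluation is deliberately restricted: only a sandboxed
subset of the host language (names, literals, arithmetic, comparisons,
subscripts, attribute access, comprehensions, and calls to registered
functions or harmless value methods) is permitted.

Rendering rules when a value is substituted into text
-----------------------------------------------------
==================  ==============================================------
value               rendered as
==================  ========================================------------
str / path          the text itself, unquoted
list of paths       elements space-separated, each shell-quoted on demand
int / float / bool  ``str(value)``
==================  ================================================----
"""

from __future__ import annotations

import ast
import os
import shlex
from typing import Any, Callable, Iterable, Mapping

from .errors import EvaluationError, InterpolationError

__all__ = [
    "VariableScope",
    "PathList",
    "expand_text",
    "format_path",
    "evaluate_expression",
    "render_value",
]

#: Names the engine itself maintains; user code must not rebind them.
RESERVED_NAMES = frozenset({"_input", "_output", "_index", "step_name"})

_FORMAT_LETTERS = "bdneaqr"

# Shell characters that force quoting under the `q` option.
_SHELL_UNSAFE = set(" \t\n'\"\\$&|;<>()*?[]{}~`!#")


class PathList(list):
    """An ordered list of path strings with workflow rendering semantics.

    Stringifies as space-separated, shell-quoted-on-demand paths so that
    ``{_input}`` can be dropped verbatim into a shell command line.
    """

    def __str__(self) -> str:  # pragma: no cover - exercised via render_value
        return " ".join(_quote_on_demand(str(p)) for p in self)

    def formatted(self, spec: str) -> "PathList":
        """Apply ``format_path`` elementwise, returning a new PathList."""
        return PathList(format_path(str(p), spec) for p in self)


class VariableScope:
    """A chainable namespace binding workflow identifiers to values.

    Engine-reserved names (``_input``, ``_output``, ``_index``,
    ``step_name``) may only be set through :meth:`set_reserved`.
    """

    def __init__(self, bindings: Mapping[str, Any] | None = None,
                 parent: "VariableScope | None" = None):
        self._bindings: dict[str, Any] = dict(bindings or {})
        self._parent = parent

    # -- mapping protocol ------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._bindings or (self._parent is not None and name in self._parent)

    def __getitem__(self, name: str) -> Any:
        if name in self._bindings:
            return self._bindings[name]
        if self._parent is not None:
            return self._parent[name]
        raise KeyError(name)

    def get(self, name: str, default: Any = None) -> Any:
        try:
            return self[name]
        except KeyError:
            return default

    def __setitem__(self, name: str, value: Any) -> None:
        if name in RESERVED_NAMES:
            raise EvaluationError(f"'{name}' is reserved and set only by the engine")
        self._bindings[name] = value

    def set_reserved(self, name: str, value: Any) -> None:
        self._bindings[name] = value

    def update(self, other: Mapping[str, Any]) -> None:
        for k, v in other.items():
            self[k] = v

    def child(self, bindings: Mapping[str, Any] | None = None) -> "VariableScope":
        return VariableScope(bindings, parent=self)

    def flatten(self) -> dict[str, Any]:
        """All visible bindings, innermost scope winning."""
        out = self._parent.flatten() if self._parent is not None else {}
        out.update(self._bindings)
        return out


def _quote_on_demand(text: str) -> str:
    if text and not (_SHELL_UNSAFE & set(text)):
        return text
    return shlex.quote(text)


def render_value(value: Any) -> str:
    """Render a scope value as text for substitution into a script."""
    if isinstance(value, str):
        return value
    if isinstance(value, (list, tuple)):
        return " ".join(_quote_on_demand(str(v)) for v in value)
    return str(value)


# ---------------------------------------------------------------------------
# path format options
# ---------------------------------------------------------------------------

def format_path(path: str, spec: str) -> str:
    """Apply single-letter path format options left to right.

    ======  =====================================================
    letter  effect
    ======  =====================================================
    ``b``   basename
    ``d``   parent directory (``.`` when there is none)
    ``n``   strip the last extension, directory preserved
    ``e``   the extension including its dot (empty when none)
    ``a``   lexically absolutized path
    ``q``   shell-quote when whitespace/metacharacters present
    ``r``   quoted literal suitable for embedding in code
    ======  =====================================================
    """
    text = str(path)
    for letter in spec:
        if letter == "b":
            text = os.path.basename(text)
        elif letter == "d":
            text = os.path.dirname(text) or "."
        elif letter == "n":
            root, _ext = os.path.splitext(text)
            text = root
        elif letter == "e":
            _root, ext = os.path.splitext(text)
            text = ext
        elif letter == "a":
            text = os.path.abspath(text)
        elif letter == "q":
            text = _quote_on_demand(text)
        elif letter == "r":
            text = repr(text)
        else:
            raise EvaluationError(f"unknown path format option {letter!r} in spec {spec!r}")
    return text


# ---------------------------------------------------------------------------
# restricted expression / statement evaluation
# ---------------------------------------------------------------------------

_SAFE_BUILTINS: dict[str, Any] = {
    "abs": abs, "all": all, "any": any, "bool": bool, "dict": dict,
    "enumerate": enumerate, "float": float, "int": int, "len": len,
    "list": list, "max": max, "min": min, "range": range, "repr": repr,
    "reversed": reversed, "round": round, "set": set, "sorted": sorted,
    "str": str, "sum": sum, "tuple": tuple, "zip": zip,
}

_ALLOWED_EXPR_NODES = (
    ast.Expression, ast.Constant, ast.Name, ast.Load, ast.Store,
    ast.Attribute, ast.Subscript, ast.Slice, ast.Tuple, ast.List,
    ast.Dict, ast.Set, ast.BinOp, ast.UnaryOp, ast.BoolOp, ast.Compare,
    ast.Call, ast.keyword, ast.IfExp, ast.ListComp, ast.SetComp,
    ast.DictComp, ast.GeneratorExp, ast.comprehension, ast.JoinedStr,
    ast.FormattedValue, ast.Starred,
)

_ALLOWED_STMT_NODES = _ALLOWED_EXPR_NODES + (
    ast.Module, ast.Expr, ast.Assign, ast.AugAssign, ast.If, ast.For,
    ast.While, ast.Break, ast.Continue, ast.Pass, ast.Del, ast.Delete,
)


def _check_tree(tree: ast.AST, allowed: tuple, source: str) -> None:
    for node in ast.walk(tree):
        if isinstance(node, (ast.operator, ast.unaryop, ast.cmpop, ast.boolop)):
            continue
        if not isinstance(node, allowed):
            raise EvaluationError(
                f"statement element {type(node).__name__!r} is outside the "
                f"supported workflow grammar: {source.strip()!r}")
        if isinstance(node, ast.Attribute) and node.attr.startswith("__"):
            raise EvaluationError(f"access to {node.attr!r} is not permitted")
        if isinstance(node, ast.Name) and node.id.startswith("__"):
            raise EvaluationError(f"access to {node.id!r} is not permitted")


def _namespace(scope: VariableScope | Mapping[str, Any],
               functions: Mapping[str, Callable] | None) -> dict[str, Any]:
    ns = dict(_SAFE_BUILTINS)
    if functions:
        ns.update(functions)
    if isinstance(scope, VariableScope):
        ns.update(scope.flatten())
    elif scope:
        ns.update(scope)
    ns["__builtins__"] = {}
    return ns


def _split_format_suffix(expr: str) -> tuple[str, str | None]:
    """Split a trailing ``:spec`` path-format suffix off an expression."""
    idx = expr.rfind(":")
    if idx <= 0:
        return expr, None
    spec = expr[idx + 1:].strip()
    body = expr[:idx]
    if spec and all(c in _FORMAT_LETTERS for c in spec):
        try:
            ast.parse(body, mode="eval")
        except SyntaxError:
            return expr, None
        return body, spec
    return expr, None


def evaluate_expression(expr: str, scope: VariableScope | Mapping[str, Any],
                        functions: Mapping[str, Callable] | None = None) -> Any:
    """Evaluate a restricted expression against a scope.

    Supports a trailing ``:spec`` suffix of path format options, applied
    elementwise to path lists (``_input:n``) or directly to a single path.
    """
    expr = expr.strip()
    if not expr:
        raise EvaluationError("empty expression")
    body, spec = _split_format_suffix(expr)
    try:
        tree = ast.parse(body, mode="eval")
    except SyntaxError as exc:
        if spec is not None:  # suffix split was wrong; try the raw text
            tree = None
        else:
            raise EvaluationError(f"invalid expression {expr!r}: {exc.msg}") from exc
    if tree is None:
        try:
            tree = ast.parse(expr, mode="eval")
            body, spec = expr, None
        except SyntaxError as exc:
            raise EvaluationError(f"invalid expression {expr!r}: {exc.msg}") from exc
    _check_tree(tree, _ALLOWED_EXPR_NODES, body)
    ns = _namespace(scope, functions)
    try:
        value = eval(compile(tree, "<expression>", "eval"), ns)  # noqa: S307
    except NameError as exc:
        raise EvaluationError(f"undefined variable in {expr!r}: {exc}") from exc
    except EvaluationError:
        raise
    except Exception as exc:
        raise EvaluationError(f"error evaluating {expr!r}: {exc}") from exc
    if spec:
        if isinstance(value, PathList):
            value = value.formatted(spec)
        elif isinstance(value, (list, tuple)):
            value = PathList(format_path(str(v), spec) for v in value)
        else:
            value = format_path(str(value), spec)
    return value


def execute_statements(code: str, scope: VariableScope,
                       functions: Mapping[str, Callable] | None = None) -> None:
    """Execute restricted plain statements, writing results back into scope.

    Only assignments, conditionals, loops, and expression (function-call)
    statements are admitted; imports, definitions, and dunder access are
    rejected.  The step's scope is the sole namespace.
    """
    try:
        tree = ast.parse(code, mode="exec")
    except SyntaxError as exc:
        raise EvaluationError(
            f"invalid statement (line {exc.lineno}): {exc.msg}") from exc
    _check_tree(tree, _ALLOWED_STMT_NODES, code)
    ns = _namespace(scope, functions)
    before = set(ns)
    try:
        exec(compile(tree, "<statements>", "exec"), ns)  # noqa: S102
    except NameError as exc:
        raise EvaluationError(f"undefined variable: {exc}") from exc
    except (EvaluationError, Exception) as exc:
        if isinstance(exc, EvaluationError):
            raise
        from .errors import PolyflowError
        if isinstance(exc, PolyflowError):
            raise
        raise EvaluationError(f"error executing statements: {exc}") from exc
    for name, value in ns.items():
        if name == "__builtins__" or callable(value) and name in before:
            continue
        if name in RESERVED_NAMES:
            continue
        if name not in before or scope.get(name, _SENTINEL) is not value:
            scope[name] = value


_SENTINEL = object()


# ---------------------------------------------------------------------------
# template expansion
# ---------------------------------------------------------------------------

def expand_text(template: str, scope: VariableScope | Mapping[str, Any],
                delimiters: tuple[str, str] = ("{", "}"),
                functions: Mapping[str, Callable] | None = None) -> str:
    """Expand delimiter-bounded expressions in a template.

    Doubled delimiters escape to literals (``{{`` renders ``{``); text
    outside expressions is copied byte-identically.  Undefined names raise
    :class:`InterpolationError` naming the variable and template line.
    """
    lo, lc = delimiters
    if not lo or not lc:
        raise InterpolationError("delimiters must be non-empty")
    if lo in lc or lc in lo:
        raise InterpolationError(f"delimiters {delimiters!r} overlap")
    out: list[str] = []
    i, n = 0, len(template)
    while i < n:
        if template.startswith(lo + lo, i):
            out.append(lo)
            i += 2 * len(lo)
            continue
        if template.startswith(lc + lc, i):
            out.append(lc)
            i += 2 * len(lc)
            continue
        if template.startswith(lo, i):
            line = template.count("\n", 0, i) + 1
            depth, j = 1, i + len(lo)
            while j < n and depth:
                if template.startswith(lo, j):
                    depth += 1
                    j += len(lo)
                elif template.startswith(lc, j):
                    depth -= 1
                    j += len(lc)
                else:
                    j += 1
            if depth:
                raise InterpolationError(
                    f"unbalanced delimiter {lo!r} at template line {line}")
            expr = template[i + len(lo):j - len(lc)]
            try:
                value = evaluate_expression(expr, scope, functions)
            except EvaluationError as exc:
                raise InterpolationError(f"template line {line}: {exc}") from exc
            out.append(render_value(value))
            i = j
            continue
        if template.startswith(lc, i):
            # A close delimiter with no open is an error for the default
            # brace pair; under a custom pair (chosen precisely because the
            # script is brace-heavy) it is literal text.
            if (lo, lc) == ("{", "}"):
                line = template.count("\n", 0, i) + 1
                raise InterpolationError(
                    f"unbalanced delimiter {lc!r} at template line {line}")
            out.append(lc)
            i += len(lc)
            continue
        out.append(template[i])
        i += 1
    return "".join(out)
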