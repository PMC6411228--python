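"""Execution-graph construction for the three workflow styles.

Process-oriented (forward) graphs follow step-index order by default; a
step that declares its own ``input:``/``depends:`` severs the implicit
chain and draws edges from the steps it actually consumes
(``output_from``, ``named_output``, ``sos_step``, or plain file-name
matching).  Outcome-oriented graphs are resolved backward from requested
targets through ``provides`` wildcard patterns.  Mixed graphs arise
naturally: a forward build pulls in auxiliary provider sections for input
files nobody in the plan produces.

The graph is kept acyclic at all times; edge insertions that would create
a cycle are rejected.  Graphs can be expanded dynamically while running
(nested workflows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import networkx as nx

from .errors import CycleError, DAGError
from .interpolation import PathList, VariableScope, evaluate_expression
from .errors import EvaluationError
from .script_model import Script, Section, WorkflowPlan
from .targets import (SignatureStore, Target, match_pattern,
                      substitute_pattern, target_satisfied)

__all__ = [
    "StepNode", "DAG", "DepRef", "build_forward_dag", "resolve_outcome_dag",
    "ready_steps", "insert_nested", "assert_acyclic", "to_dot",
]

PENDING, READY, RUNNING, DONE, SKIPPED, FAILED, ABORTED = (
    "pending", "ready", "running", "done", "skipped", "failed", "aborted")

_TRANSITIONS = {
    (PENDING, READY), (READY, RUNNING), (RUNNING, DONE), (RUNNING, FAILED),
    (PENDING, SKIPPED), (PENDING, ABORTED),
    # a ready node may still be skipped by signature or aborted by a failure
    (READY, SKIPPED), (READY, ABORTED), (READY, RUNNING),
}


@dataclass(frozen=True)
class DepRef:
    """A non-file dependency reference inside a spec expression."""
    kind: str  # output_from | named_output | step
    value: Any


def dep_functions():
    """Stub implementations used for static spec analysis."""
    return {
        "output_from": lambda x: DepRef("output_from", x),
        "named_output": lambda label: DepRef("named_output", label),
        "sos_step": lambda name: DepRef("step", name),
    }


class StepNode:
    """A section bound to a workflow (and optionally a pattern binding)."""

    def __init__(self, section: Section, bound_workflow: str,
                 bound_index: int | None = None,
                 pattern_binding: dict[str, str] | None = None):
        self.section = section
        self.bound_workflow = bound_workflow
        self.bound_index = bound_index
        self.pattern_binding = dict(pattern_binding or {})
        self.status = PENDING
        self.outputs: list[str] = []
        self.substep_statuses: list[str] = []
        self.error: str | None = None

    @property
    def key(self) -> tuple:
        return (self.section.header.display_name(), self.bound_workflow,
                self.bound_index, tuple(sorted(self.pattern_binding.items())))

    @property
    def name(self) -> str:
        """Display name: the workflow-bound step name plus any binding."""
        base_name = None
        for n, i in self.section.header.entries:
            if n == self.bound_workflow and (self.bound_index is None or
                                             i == self.bound_index or
                                             (i is None and self.bound_index == 0)):
                base_name = n if i is None else f"{n}_{i}"
                break
        if base_name is None:
            base_name = self.section.header.display_name()
        if self.pattern_binding:
            bound = ",".join(f"{k}={v}" for k, v in sorted(self.pattern_binding.items()))
            return f"{base_name}({bound})"
        return base_name

    def set_status(self, status: str) -> None:
        if status != self.status and (self.status, status) not in _TRANSITIONS:
            raise DAGError(
                f"invalid status transition {self.status} -> {status} "
                f"for step {self.name}")
        self.status = status

    def __hash__(self):
        return hash(self.key)

    def __eq__(self, other):
        return isinstance(other, StepNode) and self.key == other.key

    def __repr__(self):
        return f"<StepNode {self.name} [{self.status}]>"


class DAG:
    """A directed acyclic graph of :class:`StepNode`, cycle-checked on insert."""

    def __init__(self):
        self.graph = nx.DiGraph()
        self._by_key: dict[tuple, StepNode] = {}

    # -- construction ----------------------------------------------------
    def add_node(self, node: StepNode) -> StepNode:
        existing = self._by_key.get(node.key)
        if existing is not None:
            return existing
        self._by_key[node.key] = node
        self.graph.add_node(node)
        return node

    def add_edge(self, prerequisite: StepNode, dependent: StepNode) -> None:
        prerequisite = self.add_node(prerequisite)
        dependent = self.add_node(dependent)
        if prerequisite is dependent:
            raise CycleError(f"self-dependency on step {dependent.name}",
                             [dependent.name] * 2)
        if self.graph.has_edge(prerequisite, dependent):
            return
        if nx.has_path(self.graph, dependent, prerequisite):
            path = nx.shortest_path(self.graph, dependent, prerequisite)
            names = [n.name for n in path] + [dependent.name]
            raise CycleError(
                f"edge {prerequisite.name} -> {dependent.name} would create "
                f"a cycle: {' -> '.join(names)}", names)
        self.graph.add_edge(prerequisite, dependent)

    def merge(self, other: "DAG") -> list[StepNode]:
        """Add all nodes/edges of another graph; return its nodes (deduped)."""
        mapped = {}
        for node in other.nodes:
            mapped[node] = self.add_node(node)
        for a, b in other.graph.edges:
            self.add_edge(mapped[a], mapped[b])
        return [mapped[n] for n in other.nodes]

    # -- queries ---------------------------------------------------------
    @property
    def nodes(self) -> list[StepNode]:
        return list(self.graph.nodes)

    def get(self, key: tuple) -> StepNode | None:
        return self._by_key.get(key)

    def predecessors(self, node: StepNode) -> list[StepNode]:
        return list(self.graph.predecessors(node))

    def descendants(self, node: StepNode) -> set[StepNode]:
        return nx.descendants(self.graph, node)

    def sorted_nodes(self) -> list[StepNode]:
        return sorted(self.nodes, key=lambda n: _node_sort_key(n))

    def finished(self) -> bool:
        return all(n.status in (DONE, SKIPPED, FAILED, ABORTED) for n in self.nodes)


def _node_sort_key(node: StepNode) -> tuple:
    return (node.bound_workflow, node.bound_index
            if node.bound_index is not None else -1,
            node.section.header.display_name(),
            tuple(sorted(node.pattern_binding.items())))


# ---------------------------------------------------------------------------
# static spec analysis
# ---------------------------------------------------------------------------

def _flatten(value: Any, refs: list[DepRef], files: list[str]) -> None:
    if value is None:
        return
    if isinstance(value, DepRef):
        refs.append(value)
    elif isinstance(value, (list, tuple, PathList)):
        for item in value:
            _flatten(item, refs, files)
    elif isinstance(value, str):
        files.append(value)
    else:
        files.append(str(value))


def static_eval_spec(expr: str, scope: VariableScope
                     ) -> tuple[list[DepRef], list[str]] | None:
    """Evaluate a spec expression statically; None when it needs runtime
    context (e.g. references ``_input``)."""
    refs: list[DepRef] = []
    files: list[str] = []
    if not expr.strip():
        return refs, files
    try:
        value = evaluate_expression(expr, scope, functions=dep_functions())
    except EvaluationError:
        return None
    _flatten(value, refs, files)
    return refs, files


def section_static_outputs(section: Section, scope: VariableScope,
                           binding: dict[str, str] | None = None
                           ) -> list[str] | None:
    """Statically known output files of a section, or None when dynamic."""
    if binding is not None and section.header.provides:
        return [substitute_pattern(pat, binding) for pat in section.header.provides]
    stmt = section.single("output_spec")
    if stmt is None:
        return []
    local = scope.child(dict(binding or {}))
    result = static_eval_spec(stmt.payload["expr"], local)
    if result is None:
        return None
    refs, files = result
    if refs:
        return None
    return files


def section_static_inputs(section: Section, scope: VariableScope,
                          binding: dict[str, str] | None = None
                          ) -> tuple[list[DepRef], list[str]] | None:
    """Statically known (refs, files) consumed by a section's input and
    depends statements; None when any part is dynamic."""
    refs: list[DepRef] = []
    files: list[str] = []
    local = scope.child(dict(binding or {}))
    stmts = ([section.single("input_spec")] if section.single("input_spec") else []) \
        + section.statements_of("depends_spec")
    for stmt in stmts:
        result = static_eval_spec(stmt.payload["expr"], local)
        if result is None:
            return None
        r, f = result
        refs.extend(r)
        files.extend(f)
    return refs, files


# ---------------------------------------------------------------------------
# provider lookup (provides patterns, declared outputs, named labels)
# ---------------------------------------------------------------------------

class ProviderIndex:
    """Resolves a file target to the section able to create it."""

    def __init__(self, script: Script, scope: VariableScope):
        self.script = script
        self.scope = scope
        self._static_outputs: list[tuple[Section, list[str]]] = []
        self.labels: dict[str, Section] = {}
        for sec in script.sections:
            outs = section_static_outputs(sec, scope)
            if outs:
                self._static_outputs.append((sec, outs))
            stmt = sec.single("output_spec")
            if stmt is not None and stmt.payload.get("label"):
                label = stmt.payload["label"]
                if label in self.labels:
                    raise DAGError(
                        f"named output label '{label}' declared by both "
                        f"'{self.labels[label].header.display_name()}' and "
                        f"'{sec.header.display_name()}'; labels must be unique")
                self.labels[label] = sec

    def providers_for(self, path: str) -> list[tuple[Section, dict[str, str]]]:
        found: list[tuple[Section, dict[str, str]]] = []
        for sec in self.script.sections:
            for pat in sec.header.provides:
                binding = match_pattern(pat, path)
                if binding is not None:
                    found.append((sec, binding))
                    break
        for sec, outs in self._static_outputs:
            if path in outs and all(s is not sec for s, _b in found):
                found.append((sec, {}))
        return found

    def unique_provider(self, path: str) -> tuple[Section, dict[str, str]] | None:
        found = self.providers_for(path)
        if not found:
            return None
        if len(found) > 1:
            names = ", ".join(f"'{s.header.display_name()}'" for s, _b in found)
            raise DAGError(
                f"ambiguous providers for target '{path}': {names}")
        return found[0]

    def label_provider(self, label: str) -> Section:
        if label not in self.labels:
            raise DAGError(f"no step declares named output '{label}'")
        return self.labels[label]


# ---------------------------------------------------------------------------
# forward (process-oriented) construction
# ---------------------------------------------------------------------------

def build_forward_dag(plan: WorkflowPlan, script: Script,
                      scope: VariableScope | None = None,
                      store: SignatureStore | None = None) -> DAG:
    """Build the process-oriented graph for an ordered step plan.

    Steps chain sequentially by index unless they declare their own input;
    declared dependencies (``output_from``, ``named_output``, ``sos_step``,
    or file names another step produces) replace the implicit edge.  Input
    files no plan step produces are resolved through ``provides`` sections
    when unsatisfied (the mixed style).
    """
    if not plan.steps:
        raise DAGError(f"workflow '{plan.name}' has no steps")
    scope = scope or VariableScope()
    dag = DAG()
    index = ProviderIndex(script, scope)

    nodes: list[StepNode] = []
    for step_index, section in plan.steps:
        nodes.append(dag.add_node(StepNode(section, plan.name, step_index)))

    by_index = {n.bound_index: n for n in nodes}
    produced_by: dict[str, StepNode] = {}
    for node in nodes:
        outs = section_static_outputs(node.section, scope)
        for path in outs or []:
            produced_by[path] = node

    for pos, node in enumerate(nodes):
        section = node.section
        has_input_stmt = section.single("input_spec") is not None
        static = section_static_inputs(section, scope)
        explicit_edge = False
        if static is not None:
            refs, files = static
            for ref in refs:
                for target_node in _nodes_for_ref(ref, plan, by_index, dag,
                                                  script, scope, index):
                    dag.add_edge(target_node, node)
                    explicit_edge = True
            for path in files:
                if path in produced_by:
                    if produced_by[path] is not node:
                        dag.add_edge(produced_by[path], node)
                        explicit_edge = True
                elif store is None or not target_satisfied(Target.file(path), store):
                    provider = index.unique_provider(path)
                    if provider is not None:
                        sec, binding = provider
                        pnode = dag.add_node(StepNode(
                            sec, plan.name, None, pattern_binding=binding))
                        _resolve_backward(dag, pnode, script, scope, store, index,
                                          seen=set())
                        dag.add_edge(pnode, node)
                        explicit_edge = True
        if not has_input_stmt and not explicit_edge and pos > 0:
            dag.add_edge(nodes[pos - 1], node)
    return dag


def _nodes_for_ref(ref: DepRef, plan: WorkflowPlan,
                   by_index: dict[int | None, StepNode], dag: DAG,
                   script: Script, scope: VariableScope,
                   index: "ProviderIndex") -> list[StepNode]:
    if ref.kind == "output_from":
        raw = ref.value if isinstance(ref.value, (list, tuple)) else [ref.value]
        out = []
        for item in raw:
            if isinstance(item, int):
                if item not in by_index:
                    raise DAGError(
                        f"output_from({item}): workflow '{plan.name}' has no "
                        f"step with index {item}")
                out.append(by_index[item])
            else:
                out.append(_step_node_by_name(str(item), plan, dag, script))
        return out
    if ref.kind == "named_output":
        sec = index.label_provider(str(ref.value))
        bound = _bind_section(sec, plan)
        return [dag.add_node(StepNode(sec, bound[0], bound[1]))]
    if ref.kind == "step":
        return [_step_node_by_name(str(ref.value), plan, dag, script)]
    raise DAGError(f"unknown dependency reference {ref!r}")


def _bind_section(section: Section, plan: WorkflowPlan) -> tuple[str, int | None]:
    for name, idx in section.header.entries:
        if name == plan.name:
            return name, (0 if idx is None else idx)
    name, idx = section.header.entries[0]
    return name, idx


def _step_node_by_name(name: str, plan: WorkflowPlan, dag: DAG,
                       script: Script) -> StepNode:
    for sec in script.sections:
        for ename, idx in sec.header.entries:
            display = ename if idx is None else f"{ename}_{idx}"
            if display == name or (idx is None and ename == name):
                return dag.add_node(StepNode(sec, ename, idx))
    raise DAGError(f"reference to nonexistent step '{name}'")


# ---------------------------------------------------------------------------
# outcome-oriented (backward) construction
# ---------------------------------------------------------------------------

def resolve_outcome_dag(script: Script, requested: Iterable[Target | str],
                        store: SignatureStore,
                        scope: VariableScope | None = None,
                        workflow_name: str = "default") -> DAG:
    """Backward-chain from requested targets through providers.

    Satisfied targets (existing or zapped files, completed steps)
    terminate the recursion, so the graph contains only the nodes actually
    required.  Raises when no section provides an unsatisfied target, or
    when two provide the same one.
    """
    requested = list(requested)
    if not requested:
        raise DAGError("no targets requested")
    scope = scope or VariableScope()
    dag = DAG()
    index = ProviderIndex(script, scope)
    for item in requested:
        target = item if isinstance(item, Target) else Target.file(str(item))
        if target_satisfied(target, store):
            continue
        if target.kind == "file":
            provider = index.unique_provider(target.key)
            if provider is None:
                raise DAGError(f"no step provides target '{target.key}'")
            sec, binding = provider
            node = dag.add_node(StepNode(sec, workflow_name, None,
                                         pattern_binding=binding))
            _resolve_backward(dag, node, script, scope, store, index, seen=set())
        elif target.kind == "named_output":
            sec = index.label_provider(target.key)
            node = dag.add_node(StepNode(sec, workflow_name, None))
            _resolve_backward(dag, node, script, scope, store, index, seen=set())
        else:
            node = _step_node_by_name(target.key, WorkflowPlan(workflow_name, []),
                                      dag, script)
            _resolve_backward(dag, node, script, scope, store, index, seen=set())
    return dag


def _resolve_backward(dag: DAG, node: StepNode, script: Script,
                      scope: VariableScope, store: SignatureStore | None,
                      index: ProviderIndex, seen: set) -> None:
    if node.key in seen:
        return
    seen.add(node.key)
    static = section_static_inputs(node.section, scope, node.pattern_binding)
    if static is None:
        return
    refs, files = static
    for ref in refs:
        if ref.kind == "named_output":
            sec = index.label_provider(str(ref.value))
            sub = dag.add_node(StepNode(sec, node.bound_workflow, None))
        elif ref.kind == "step":
            sub = _step_node_by_name(str(ref.value),
                                     WorkflowPlan(node.bound_workflow, []),
                                     dag, script)
        else:
            raise DAGError(
                "output_from() requires a process-oriented plan and cannot "
                "be resolved from outcome-style recursion")
        dag.add_edge(sub, node)
        _resolve_backward(dag, sub, script, scope, store, index, seen)
    for path in files:
        if store is not None and target_satisfied(Target.file(path), store):
            continue
        provider = index.unique_provider(path)
        if provider is None:
            raise DAGError(f"no step provides target '{path}'")
        sec, binding = provider
        sub = dag.add_node(StepNode(sec, node.bound_workflow, None,
                                    pattern_binding=binding))
        dag.add_edge(sub, node)
        _resolve_backward(dag, sub, script, scope, store, index, seen)


# ---------------------------------------------------------------------------
# scheduling queries, nested insertion, acyclicity
# ---------------------------------------------------------------------------

def ready_steps(dag: DAG) -> list[StepNode]:
    """Pending nodes whose prerequisites are all done or skipped, in
    deterministic order."""
    out = []
    for node in dag.sorted_nodes():
        if node.status != PENDING:
            continue
        if all(p.status in (DONE, SKIPPED) for p in dag.predecessors(node)):
            out.append(node)
    return out


def abort_dependents(dag: DAG, failed: StepNode) -> list[StepNode]:
    """Abort every pending transitive dependent of a failed node."""
    aborted = []
    for node in dag.descendants(failed):
        if node.status == PENDING:
            node.set_status(ABORTED)
            aborted.append(node)
    return aborted


def insert_nested(dag: DAG, parent: StepNode, subdags: list[DAG], *,
                  keys: Iterable[tuple] = (),
                  active: Iterable[tuple] = ()) -> list[list[StepNode]]:
    """Insert nested sub-graphs under a running parent node.

    Each sub-graph's roots gain an edge from the parent; sub-graphs passed
    in one call stay mutually unordered (they may run in parallel).  A
    nested workflow whose (name, parameters) key is already on the active
    call stack is a cycle.
    """
    if parent.status != RUNNING:
        raise DAGError(
            f"nested insertion requires a running parent; {parent.name} is "
            f"{parent.status}")
    keys = list(keys)
    active = set(active)
    for i, key in enumerate(keys):
        if key in active:
            raise CycleError(
                f"nested workflow '{key[0]}' is already active with identical "
                f"parameters (recursive invocation)", [key[0], parent.name, key[0]])
    inserted: list[list[StepNode]] = []
    for sub in subdags:
        nodes = dag.merge(sub)
        for node in nodes:
            if node.status == PENDING and not any(
                    p is not parent for p in dag.predecessors(node)):
                dag.add_edge(parent, node)
        inserted.append(nodes)
    return inserted


def assert_acyclic(dag: DAG) -> None:
    """Raise :class:`CycleError` listing an ordered cycle path, if any."""
    try:
        cycle = nx.find_cycle(dag.graph)
    except nx.NetworkXNoCycle:
        return
    names = [edge[0].name for edge in cycle] + [cycle[0][0].name]
    raise CycleError(f"dependency cycle: {' -> '.join(names)}", names)


def to_dot(dag: DAG) -> str:
    """Render the graph in DOT format with stable, sorted node labels."""
    lines = ["digraph workflow {"]
    for node in dag.sorted_nodes():
        lines.append(f'  "{node.name}" [status="{node.status}"];')
    edges = sorted(((a.name, b.name) for a, b in dag.graph.edges))
    for a, b in edges:
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
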