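"""Workflow execution: substep grouping, signature skip, locks, cleanup.

The executor turns a DAG of step nodes into completed files.  Every step
is split into *substeps* — one execution of the body per input group — and
each substep independently checks the signature store, acquires a process
lock, runs its statements (plain statements through the sandboxed
evaluator, action calls through the action registry or the task queue),
verifies its declared outputs, and records a signature.  Failed substeps
remove the outputs they created; failed steps abort their transitive
dependents while independent branches continue.

Skip semantics (``sig_mode``):

* ``default`` — skip a substep when a matching signature exists and all
  inputs/outputs still check out (zap placeholders count as present);
* ``force``  — ignore existing records, re-run, re-record;
* ``ignore`` — re-run and do not record.

A consumer whose *input* file has been zapped needs actual bytes, so the
producing step is transparently re-run first (its outputs are then held
to the stricter content-required standard) and the placeholder is
retired.
"""

from __future__ import annotations

import json
import os
import re
import sys
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

from . import dag as dag_mod
from .actions import (BUILTIN_ACTIONS, action_command, default_registry,
                      run_builtin, run_interpreter)
from .dag import (ABORTED, DAG, DONE, FAILED, PENDING, READY, RUNNING, SKIPPED,
                  DepRef, ProviderIndex, StepNode, abort_dependents,
                  build_forward_dag, insert_nested, ready_steps,
                  resolve_outcome_dag, to_dot)
from .errors import (CycleError, EvaluationError, ExecutionError, PolyflowError,
                     TargetError)
from .interpolation import (PathList, VariableScope, evaluate_expression,
                            execute_statements, expand_text)
from .script_model import Script, Section, Statement, WorkflowPlan, resolve_workflow
from .targets import (ENGINE_VERSION, SignatureRecord, SignatureStore, Target,
                      ZapPlaceholder, check_skip, file_digest, text_digest,
                      target_satisfied)
from .taskqueue import Task, TaskQueue, load_host_config

__all__ = ["Executor", "RunResult", "SubstepContext", "run", "group_inputs",
           "action_execute"]

_NESTED_RE = re.compile(r"\b(?:sos_run|nested_run)\b")
_LOCK_TIMEOUT = 300.0


@dataclass
class SubstepContext:
    """Execution context of one substep (one input group)."""
    _input: PathList
    _output: PathList
    _index: int
    scope: VariableScope
    workdir: Path


@dataclass
class RunResult:
    """Aggregate outcome of a run."""
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    elapsed: float = 0.0
    dot: str | None = None
    rendered_scripts: list[tuple[str, str, str]] = field(default_factory=list)
    #: steps that only orchestrate nested workflows (no actions of their own)
    orchestration_steps: set[str] = field(default_factory=set)

    def bump(self, step: str, status: str, n: int = 1) -> None:
        row = self.counts.setdefault(
            step, {"executed": 0, "skipped": 0, "failed": 0, "aborted": 0})
        row[status] += n

    def total(self, status: str) -> int:
        return sum(row[status] for row in self.counts.values())

    @property
    def succeeded(self) -> bool:
        return self.total("failed") == 0 and self.total("aborted") == 0

    def executed_steps(self) -> set[str]:
        return {s for s, row in self.counts.items() if row["executed"]}

    def summary(self) -> dict:
        return {"steps": self.counts,
                "totals": {k: self.total(k) for k in
                           ("executed", "skipped", "failed", "aborted")},
                "outputs": self.outputs, "elapsed": self.elapsed}


def group_inputs(paths: list[str], group_by: int | str | None) -> list[list[str]]:
    """Order-preserving partition of input files into substep groups.

    ``group_by`` may be a positive integer (group size; the file count
    must divide evenly) or ``"all"``/None for a single group.
    """
    paths = list(paths)
    if group_by in (None, "all"):
        return [paths]
    if isinstance(group_by, bool) or not isinstance(group_by, int) or group_by <= 0:
        raise ExecutionError(
            f"group_by must be a positive integer or 'all', got {group_by!r}")
    if len(paths) % group_by:
        raise ExecutionError(
            f"cannot divide {len(paths)} input files into groups of "
            f"{group_by} (remainder {len(paths) % group_by})")
    return [paths[i:i + group_by] for i in range(0, len(paths), group_by)]


def action_execute(action_name: str, script_text: str, options: dict,
                   ctx: SubstepContext, registry: dict[str, str] | None = None,
                   tmpdir: Path | None = None) -> int:
    """Execute one action in a substep context; returns 0 on success.

    The script is expanded against the context scope when ``expand`` is
    set (True for ``{}`` delimiters, or a custom delimiter pair).
    """
    registry = registry if registry is not None else default_registry()
    expanded = _expand_script(script_text, options, ctx.scope)
    command = action_command(registry, action_name)
    if action_name in BUILTIN_ACTIONS:
        inputs = [ctx.workdir / p for p in ctx._input]
        outputs = [ctx.workdir / p for p in ctx._output]
        run_builtin(action_name, expanded, inputs, outputs)
        return 0
    tmpdir = tmpdir or (ctx.workdir / ".polyflow" / "tmp")
    tag = f"{action_name}_{os.getpid()}_{text_digest(expanded)[:8]}"
    run_interpreter(command, expanded, ctx.workdir, tmpdir, tag)
    return 0


def _expand_script(script_text: str, options: dict, scope: VariableScope) -> str:
    expand = options.get("expand", False)
    if not expand:
        return script_text
    delimiters = ("{", "}")
    if isinstance(expand, (tuple, list)) and len(expand) == 2:
        delimiters = (str(expand[0]), str(expand[1]))
    return expand_text(script_text, scope, delimiters)


# ---------------------------------------------------------------------------
# the executor
# ---------------------------------------------------------------------------

class Executor:
    """Executes workflows from one parsed script against one working root."""

    def __init__(self, script: Script, workdir: str | Path,
                 parameters: dict[str, Any] | None = None, *,
                 jobs: int = 1, sig_mode: str = "default",
                 dryrun: bool = False, queue: str | None = None,
                 config: dict | None = None):
        if sig_mode not in ("default", "force", "ignore"):
            raise PolyflowError(f"unknown sig_mode {sig_mode!r}")
        self.script = script
        self.workdir = Path(os.path.abspath(workdir))
        self.workdir.mkdir(parents=True, exist_ok=True)
        self.store = SignatureStore(self.workdir)
        self.jobs = max(1, int(jobs))
        self.sig_mode = sig_mode
        self.dryrun = dryrun
        self.default_queue = queue
        config = config or {}
        self.registry = default_registry()
        self.registry.update(config.get("actions") or {})
        hosts_yaml = {"hosts": config.get("hosts") or {}}
        import yaml as _yaml
        self.hosts = load_host_config(_yaml.safe_dump(hosts_yaml))
        self.taskqueue = TaskQueue(self.hosts, self.store)
        self.scope = self._build_scope(parameters or {})
        self.result = RunResult()
        self._step_outputs: dict[tuple[str, int | None], list[str]] = {}
        self._active: set[tuple] = set()
        self._pool: ThreadPoolExecutor | None = None

    # -- scope -----------------------------------------------------------
    def _build_scope(self, overrides: dict[str, Any]) -> VariableScope:
        scope = VariableScope()
        for p in self.script.all_parameters():
            if p.name in overrides:
                value = overrides[p.name]
                if isinstance(value, (str, list)) and not (
                        p.type_tag == "string" and isinstance(value, str)):
                    value = p.coerce(value)
                scope[p.name] = value
            elif p.has_default:
                scope[p.name] = p.default
            else:
                raise PolyflowError(
                    f"required parameter '--{p.name}' was not provided")
        for name, value in overrides.items():
            if name not in scope:
                scope[name] = value
        for stmt in self.script.global_statements:
            execute_statements(stmt.payload["code"], scope)
        return scope

    # -- public entry points ----------------------------------------------
    def run(self, workflow: str | None = None,
            targets: list[str] | None = None) -> RunResult:
        """Execute a named workflow (process style) or requested targets
        (outcome style)."""
        t0 = time.monotonic()
        if workflow is not None and targets:
            raise PolyflowError("give either a workflow name or targets, not both")
        if targets:
            graph = resolve_outcome_dag(self.script, targets, self.store,
                                        self.scope)
        else:
            plan = resolve_workflow(self.script, workflow)
            graph = build_forward_dag(plan, self.script, self.scope, self.store)
        dag_mod.assert_acyclic(graph)
        self.result.dot = to_dot(graph)
        if self.dryrun:
            self._render_dryrun(graph)
        else:
            try:
                self._execute_dag(graph)
            finally:
                self._shutdown_pool()
        self.result.elapsed = time.monotonic() - t0
        self._write_summary()
        return self.result

    # -- scheduling -------------------------------------------------------
    def _execute_dag(self, graph: DAG, scope: VariableScope | None = None) -> None:
        scope = scope or self.scope
        while True:
            ready = ready_steps(graph)
            if not ready:
                for node in graph.nodes:
                    if node.status == PENDING:
                        node.set_status(ABORTED)
                        self.result.bump(node.name, "aborted",
                                         max(1, len(node.substep_statuses)))
                break
            for node in ready:
                self._execute_node(graph, node, scope)

    def _execute_node(self, graph: DAG, node: StepNode,
                      scope: VariableScope) -> None:
        node.set_status(READY)
        t0 = time.monotonic()
        try:
            statuses = self._execute_step(graph, node, scope)
        except PolyflowError as exc:
            node.error = node.error or str(exc)
            if node.status != FAILED:
                if node.status in (READY, PENDING):
                    node.set_status(RUNNING)
                node.set_status(FAILED)
                self.result.bump(node.name, "failed")
            for dep in abort_dependents(graph, node):
                self.result.bump(dep.name, "aborted")
            self._log(node.name, "failed", t0, detail=str(exc))
            return
        if all(s == "skipped" for s in statuses) and statuses:
            if node.status == READY:
                node.set_status(SKIPPED)
            self._log(node.name, "skipped", t0)
        else:
            self._log(node.name, "done", t0)

    # -- step execution ---------------------------------------------------
    def _execute_step(self, graph: DAG, node: StepNode,
                      scope: VariableScope,
                      require_content: bool = False) -> list[str]:
        section = node.section
        step_scope = scope.child()
        step_scope.set_reserved("step_name", node.name.split("(")[0])
        for k, v in node.pattern_binding.items():
            step_scope[k] = v

        funcs = self._runtime_functions(node, step_scope)
        inputs, options = self._resolve_inputs(graph, node, step_scope, funcs)
        depends_files = self._resolve_depends(node, step_scope, funcs)

        group_by = options.get("group_by")
        if group_by is not None:
            group_by = evaluate_expression(group_by, step_scope)
        groups = group_inputs(list(inputs), group_by)
        paired = self._resolve_paired(options, step_scope, groups, inputs)

        contexts: list[SubstepContext] = []
        out_stmt = section.single("output_spec")
        for i, group in enumerate(groups):
            sub_scope = step_scope.child()
            sub_scope.set_reserved("_input", PathList(group))
            sub_scope.set_reserved("_index", i)
            for name, values in paired.items():
                sub_scope.set_reserved(f"_{name}", values[i])
            if out_stmt is not None and out_stmt.payload["expr"].strip():
                value = evaluate_expression(out_stmt.payload["expr"], sub_scope)
                out_paths = PathList()
                dag_mod._flatten(value, [], out_paths)
            elif node.pattern_binding and section.header.provides:
                from .targets import substitute_pattern
                out_paths = PathList(
                    substitute_pattern(pat, node.pattern_binding)
                    for pat in section.header.provides)
            else:
                out_paths = PathList()
            sub_scope.set_reserved("_output", out_paths)
            contexts.append(SubstepContext(
                _input=PathList(group), _output=out_paths, _index=i,
                scope=sub_scope, workdir=self.workdir))

        node.set_status(RUNNING)
        node.substep_statuses = ["pending"] * len(contexts)
        has_nested = self._has_nested(section)
        if has_nested and not section.statements_of("action_call"):
            self.result.orchestration_steps.add(node.name)
        task_queue_name = self._task_queue_name(section, step_scope)

        def run_one(i_ctx):
            i, ctx = i_ctx
            return self._run_substep(node, ctx, depends_files,
                                     has_nested=has_nested,
                                     queue_name=task_queue_name,
                                     require_content=require_content)

        if self.jobs > 1 and len(contexts) > 1 and not has_nested:
            pool = self._get_pool()
            statuses = list(pool.map(run_one, list(enumerate(contexts))))
        else:
            statuses = [run_one(ic) for ic in enumerate(contexts)]

        node.substep_statuses = statuses
        failed = [i for i, s in enumerate(statuses) if s == "failed"]
        executed = sum(1 for s in statuses if s == "executed")
        skipped = sum(1 for s in statuses if s == "skipped")
        if executed:
            self.result.bump(node.name, "executed", executed)
        if skipped:
            self.result.bump(node.name, "skipped", skipped)
        if failed:
            self.result.bump(node.name, "failed", len(failed))
            node.set_status(FAILED)
            for dep in abort_dependents(graph, node):
                self.result.bump(dep.name, "aborted")
            raise ExecutionError(
                f"step {node.name}: {len(failed)} of {len(statuses)} "
                f"substeps failed")

        outputs: list[str] = []
        for ctx in contexts:
            outputs.extend(ctx._output)
        node.outputs = outputs
        self.result.outputs.extend(p for p in outputs
                                   if p not in self.result.outputs)
        self._record_step_completion(node, outputs)
        if node.status == RUNNING:
            node.set_status(DONE)
        return statuses

    def _record_step_completion(self, node: StepNode, outputs: list[str]) -> None:
        digest = self._static_digest(node.section)
        self.store.mark_step_done(node.name.split("(")[0], digest, outputs)
        self._step_outputs[(node.bound_workflow, node.bound_index)] = outputs
        out_stmt = node.section.single("output_spec")
        if out_stmt is not None and out_stmt.payload.get("label"):
            self.store.save_named_output(out_stmt.payload["label"], outputs,
                                         node.name.split("(")[0])

    # -- substep ----------------------------------------------------------
    def _run_substep(self, node: StepNode, ctx: SubstepContext,
                     depends_files: list[str], *, has_nested: bool,
                     queue_name: str | None,
                     require_content: bool = False) -> str:
        section = node.section
        digest = self._content_digest(section, ctx)
        lock = self._acquire_lock(digest, ctx._index)
        try:
            if (self.sig_mode == "default" and not has_nested and
                    check_skip(self.store, digest, ctx._index,
                               inputs=[str(p) for p in ctx._input],
                               outputs=[str(p) for p in ctx._output],
                               depends=depends_files,
                               require_output_content=require_content)):
                return "skipped"
            executed_before = self.result.total("executed")
            try:
                # about to run: any zapped input must be materialized first
                for path in ctx._input:
                    self._ensure_content(str(path), ctx.scope)
                self._run_statements(node, ctx, queue_name)
                missing = [str(p) for p in ctx._output
                           if not self.store.resolve(str(p)).is_file()]
                if missing:
                    raise ExecutionError(
                        f"step {node.name} (substep {ctx._index}): output not "
                        f"created: {', '.join(missing)}")
            except PolyflowError as exc:
                self._remove_partial_outputs(ctx)
                node.error = str(exc)
                sys.stderr.write(f"polyflow: {exc}\n")
                return "failed"
            for p in ctx._output:
                ZapPlaceholder.sidecar_path(self.store.resolve(str(p))).unlink(
                    missing_ok=True)
            if self.sig_mode != "ignore" and not has_nested:
                self._write_signature(digest, ctx, depends_files)
            if (has_nested and not node.section.statements_of("action_call")
                    and not ctx._output
                    and self.result.total("executed") == executed_before):
                # pure orchestration whose nested work was all skipped:
                # nothing was actually computed here
                return "skipped"
            return "executed"
        finally:
            self._release_lock(lock)

    def _run_statements(self, node: StepNode, ctx: SubstepContext,
                        queue_name: str | None) -> None:
        funcs = self._runtime_functions(node, ctx.scope)
        task_ops: list[dict] = []
        for stmt in node.section.body:
            if stmt.kind in ("input_spec", "output_spec", "depends_spec",
                             "task_spec"):
                continue
            if stmt.kind == "plain":
                execute_statements(stmt.payload["code"], ctx.scope, funcs)
            elif stmt.kind == "action_call":
                name = stmt.payload["name"]
                expanded = _expand_script(stmt.payload["script"],
                                          stmt.payload["options"], ctx.scope)
                if queue_name is not None:
                    op = {"action": name, "script": expanded,
                          "script_translated": expanded}
                    if name not in BUILTIN_ACTIONS:
                        op["command"] = action_command(self.registry, name)
                    task_ops.append(op)
                else:
                    self._run_action_local(name, expanded, ctx)
        if task_ops:
            self._submit_task(node, ctx, task_ops, queue_name)

    def _run_action_local(self, name: str, expanded: str,
                          ctx: SubstepContext) -> None:
        command = action_command(self.registry, name)
        if name in BUILTIN_ACTIONS:
            inputs = [self.store.resolve(str(p)) for p in ctx._input]
            outputs = [self.store.resolve(str(p)) for p in ctx._output]
            run_builtin(name, expanded, inputs, outputs)
            return
        tag = f"{name}_{os.getpid()}_{ctx._index}_{text_digest(expanded)[:8]}"
        run_interpreter(command, expanded, self.workdir,
                        self.store.root / "tmp", tag)

    def _submit_task(self, node: StepNode, ctx: SubstepContext,
                     ops: list[dict], queue_name: str) -> None:
        host = self.taskqueue.host(queue_name)
        input_files = [str(self.store.resolve(str(p))) for p in ctx._input]
        output_files = [str(self.store.resolve(str(p))) for p in ctx._output]
        if host.kind == "mock_remote":
            # Re-target absolute local paths in the expanded payload; paths
            # relative to the working directory survive unchanged because the
            # remote side runs with the translated working directory as cwd.
            mapping = {p: t for p in input_files + output_files
                       if (t := self._try_translate(p, host)) is not None}
            for op in ops:
                translated = op["script"]
                for old in sorted(mapping, key=len, reverse=True):
                    translated = translated.replace(old, mapping[old])
                op["script_translated"] = translated
        task = Task(payload={
            "ops": ops, "workdir": str(self.workdir),
            "input_digests": [file_digest(p) for p in input_files
                              if Path(p).is_file()]},
            input_files=input_files, output_files=output_files)
        self.taskqueue.submit(task, queue_name)

    def _try_translate(self, path: str, host) -> str | None:
        from .taskqueue import translate_path
        try:
            return translate_path(path, host)
        except PolyflowError:
            return None

    # -- input/depends resolution -----------------------------------------
    def _runtime_functions(self, node: StepNode,
                           scope: VariableScope) -> dict[str, Callable]:
        def output_from(ref):
            refs = ref if isinstance(ref, (list, tuple)) else [ref]
            out = PathList()
            for r in refs:
                key = (node.bound_workflow, r) if isinstance(r, int) else None
                if key is not None and key in self._step_outputs:
                    out.extend(self._step_outputs[key])
                    continue
                name = r if isinstance(r, str) else f"{node.bound_workflow}_{r}"
                recorded = self.store.step_outputs(name)
                if recorded is None:
                    raise ExecutionError(
                        f"output_from({r!r}): step has not produced outputs")
                out.extend(recorded)
            return out

        def named_output(label):
            recorded = self.store.named_output(str(label))
            if recorded is None:
                raise ExecutionError(
                    f"named_output({label!r}): no outputs recorded")
            return PathList(recorded)

        def sos_step(name):
            return DepRef("step", str(name))

        def sos_run(names, **params):
            return self._nested_run(node, names, params)

        return {"output_from": output_from, "named_output": named_output,
                "sos_step": sos_step, "sos_run": sos_run,
                "nested_run": sos_run, "zap": self._zap_action}

    def _zap_action(self, paths):
        from .targets import zap_files
        paths = paths if isinstance(paths, (list, tuple)) else [paths]
        zap_files([str(self.store.resolve(str(p))) for p in paths], self.store)

    def _resolve_inputs(self, graph: DAG, node: StepNode,
                        step_scope: VariableScope,
                        funcs: dict) -> tuple[PathList, dict]:
        stmt = node.section.single("input_spec")
        if stmt is None:
            return self._implicit_input(graph, node), {}
        expr = stmt.payload["expr"]
        options = dict(stmt.payload["options"])
        if not expr.strip():
            return PathList(), options
        value = evaluate_expression(expr, step_scope, funcs)
        refs: list[DepRef] = []
        files = PathList()
        dag_mod._flatten(value, refs, files)
        for ref in refs:
            if ref.kind == "step":
                continue  # ordering dependency only; no file contribution
            raise ExecutionError(f"unsupported input reference {ref!r}")
        return files, options

    def _implicit_input(self, graph: DAG, node: StepNode) -> PathList:
        candidates = [p for p in graph.predecessors(node)
                      if p.bound_workflow == node.bound_workflow
                      and p.bound_index is not None
                      and (node.bound_index is None
                           or p.bound_index < node.bound_index)]
        if not candidates:
            return PathList()
        best = max(candidates, key=lambda p: p.bound_index)
        return PathList(best.outputs)

    def _resolve_depends(self, node: StepNode, step_scope: VariableScope,
                         funcs: dict) -> list[str]:
        files: list[str] = []
        for stmt in node.section.statements_of("depends_spec"):
            expr = stmt.payload["expr"]
            if not expr.strip():
                continue
            value = evaluate_expression(expr, step_scope, funcs)
            refs: list[DepRef] = []
            dag_mod._flatten(value, refs, files)
            for ref in refs:
                if ref.kind == "step":
                    if not self.store.step_done(str(ref.value)):
                        raise ExecutionError(
                            f"depends: step '{ref.value}' has not completed")
        return files

    def _resolve_paired(self, options: dict, scope: VariableScope,
                        groups: list[list[str]],
                        inputs: PathList) -> dict[str, list]:
        paired: dict[str, list] = {}
        raw = options.get("paired_with")
        if raw is None:
            return paired
        value = evaluate_expression(raw, scope)
        names = value if isinstance(value, (list, tuple)) and all(
            isinstance(v, str) and v in scope for v in value) else [value]
        if isinstance(value, str):
            names = [value]
        for name in names:
            seq = list(scope[name]) if isinstance(name, str) else list(name)
            label = name if isinstance(name, str) else "paired"
            if len(seq) != len(inputs):
                raise ExecutionError(
                    f"paired_with '{label}': {len(seq)} values for "
                    f"{len(inputs)} inputs")
            grouped, k = [], 0
            for g in groups:
                grouped.append(seq[k:k + len(g)])
                k += len(g)
            paired[label] = grouped
        return paired

    # -- zap regeneration --------------------------------------------------
    def _ensure_content(self, path: str, scope: VariableScope) -> None:
        resolved = self.store.resolve(path)
        if resolved.is_file():
            return
        zap = ZapPlaceholder.read(resolved)
        if zap is None:
            return  # missing entirely; the substep will fail with a clear error
        index = ProviderIndex(self.script, scope)
        provider = index.unique_provider(path)
        if provider is None:
            rec = self.store.record_producing(str(resolved))
            raise TargetError(
                f"input '{path}' was zapped and no step can regenerate it")
        section, binding = provider
        node = StepNode(section, "regenerate", None, pattern_binding=binding)
        mini = DAG()
        mini.add_node(node)
        node.set_status(READY)
        self._execute_step(mini, node, scope, require_content=True)
        if not resolved.is_file():
            raise TargetError(f"regeneration of zapped input '{path}' failed")
        new_digest = file_digest(resolved)
        if new_digest != zap.digest:
            sys.stderr.write(
                f"polyflow: warning: regenerated '{path}' differs from its "
                f"zapped digest\n")
        ZapPlaceholder.sidecar_path(resolved).unlink(missing_ok=True)

    # -- nested workflows --------------------------------------------------
    def _nested_run(self, parent: StepNode, names, params: dict) -> None:
        names = [names] if isinstance(names, str) else list(names)
        scope = self.scope.child(params) if params else self.scope
        keys = []
        for name in names:
            key = (name, text_digest(json.dumps(
                sorted((k, repr(v)) for k, v in params.items()))))
            if key in self._active:
                raise CycleError(
                    f"nested workflow '{name}' is already active with "
                    f"identical parameters (recursive invocation)",
                    [name, parent.name, name])
            keys.append(key)
        subdags = []
        for name in names:
            plan = resolve_workflow(self.script, name)
            subdags.append(build_forward_dag(plan, self.script, scope,
                                             self.store))
        combined = DAG()
        combined.add_node(parent)
        insert_nested(combined, parent, subdags, keys=keys,
                      active=self._active)
        # the parent is mid-execution (its prologue has run); the nested
        # scheduler works on the sub-graph only
        combined.graph.remove_node(parent)
        del combined._by_key[parent.key]
        self._active.update(keys)
        try:
            self._execute_dag(combined, scope)
        finally:
            self._active.difference_update(keys)
        failed = [n for n in combined.nodes
                  if n is not parent and n.status in (FAILED, ABORTED)]
        if failed:
            raise ExecutionError(
                f"nested workflow failed: "
                f"{', '.join(sorted(n.name for n in failed))}")

    # -- signatures --------------------------------------------------------
    def _has_nested(self, section: Section) -> bool:
        return any(stmt.kind == "plain" and
                   _NESTED_RE.search(stmt.payload["code"])
                   for stmt in section.body)

    def _static_digest(self, section: Section) -> str:
        parts = []
        for stmt in section.body:
            if stmt.kind == "action_call":
                parts.append(f"action {stmt.payload['name']} "
                             f"{sorted(stmt.payload['options'].items())!r}")
                parts.append(stmt.payload["script"])
            elif stmt.kind == "plain":
                parts.append(stmt.payload["code"])
            else:
                parts.append(f"{stmt.kind} {stmt.payload['expr']} "
                             f"{sorted(stmt.payload['options'].items())!r}")
        return text_digest("\n".join(parts))

    def _content_digest(self, section: Section, ctx: SubstepContext) -> str:
        parts = [f"engine {ENGINE_VERSION}"]
        param_names = {p.name for p in self.script.all_parameters()}
        used: set[str] = set()
        for stmt in section.body:
            if stmt.kind == "action_call":
                options = stmt.payload["options"]
                parts.append(f"action {stmt.payload['name']} "
                             f"{sorted(options.items())!r}")
                parts.append(f"interpreter "
                             f"{self.registry.get(stmt.payload['name'], 'builtin')}")
                try:
                    parts.append(_expand_script(stmt.payload["script"], options,
                                                ctx.scope))
                except PolyflowError:
                    parts.append(stmt.payload["script"])
                used |= _identifiers(stmt.payload["script"]) & param_names
            elif stmt.kind == "plain":
                parts.append(stmt.payload["code"])
                used |= _identifiers(stmt.payload["code"]) & param_names
            else:
                parts.append(f"{stmt.kind} {stmt.payload['expr']} "
                             f"{sorted(stmt.payload['options'].items())!r}")
                used |= _identifiers(stmt.payload["expr"]) & param_names
        for name in sorted(used):
            parts.append(f"param {name}={ctx.scope.get(name)!r}")
        return text_digest("\n".join(parts))

    def _write_signature(self, digest: str, ctx: SubstepContext,
                         depends_files: list[str]) -> None:
        def rows(paths):
            out = []
            for p in paths:
                resolved = self.store.resolve(str(p))
                if resolved.is_file():
                    out.append((str(p), file_digest(resolved),
                                resolved.stat().st_size))
                else:
                    zap = ZapPlaceholder.read(resolved)
                    if zap is not None:
                        out.append((str(p), zap.digest, zap.size))
            return out

        record = SignatureRecord(
            step_content_digest=digest, substep_index=ctx._index,
            input_digests=rows(ctx._input), output_digests=rows(ctx._output),
            depends_digests=rows(depends_files))
        self.store.save_record(record)

    # -- locks -------------------------------------------------------------
    def _acquire_lock(self, digest: str, substep: int) -> Path | None:
        """Take the content-keyed process lock for one substep.

        Re-entrant within a thread (a nested step whose content is
        byte-identical to an enclosing one must not deadlock on itself);
        returns None in that case so only the outermost holder releases.
        """
        import threading
        path = self.store.lock_path(f"{digest[:32]}.{substep}")
        owner = f"{os.getpid()}:{threading.get_ident()}"
        deadline = time.monotonic() + _LOCK_TIMEOUT
        while True:
            try:
                fd = os.open(path, os.O_CREAT | os.O_EXCL | os.O_WRONLY)
                os.write(fd, owner.encode())
                os.close(fd)
                return path
            except FileExistsError:
                try:
                    if path.read_text() == owner:
                        return None
                except OSError:
                    pass
                if time.monotonic() > deadline:
                    raise ExecutionError(
                        f"timed out waiting for process lock {path}")
                time.sleep(0.05)

    def _release_lock(self, path: Path | None) -> None:
        if path is not None:
            path.unlink(missing_ok=True)

    # -- misc ---------------------------------------------------------------
    def _task_queue_name(self, section: Section,
                         scope: VariableScope) -> str | None:
        stmt = section.single("task_spec")
        if stmt is None:
            return None
        raw = stmt.payload["options"].get("queue")
        if raw is not None:
            return str(evaluate_expression(raw, scope))
        return self.default_queue

    def _remove_partial_outputs(self, ctx: SubstepContext) -> None:
        for p in ctx._output:
            self.store.resolve(str(p)).unlink(missing_ok=True)

    def _get_pool(self) -> ThreadPoolExecutor:
        if self._pool is None:
            self._pool = ThreadPoolExecutor(max_workers=self.jobs)
        return self._pool

    def _shutdown_pool(self) -> None:
        if self._pool is not None:
            self._pool.shutdown(wait=True)
            self._pool = None

    def _log(self, step: str, status: str, t0: float, detail: str = "") -> None:
        elapsed = time.monotonic() - t0
        line = f"{step} {status} {elapsed:.2f}s"
        if detail:
            line += f"  ({detail.splitlines()[0][:120]})"
        sys.stderr.write(line + "\n")

    def _write_summary(self) -> None:
        path = self.store.root / "summary.json"
        path.write_text(json.dumps(self.result.summary(), indent=1,
                                   sort_keys=True))

    def _render_dryrun(self, graph: DAG) -> None:
        for node in graph.sorted_nodes():
            scope = self.scope.child()
            scope.set_reserved("step_name", node.name.split("(")[0])
            scope.set_reserved("_input", PathList())
            scope.set_reserved("_index", 0)
            outs = dag_mod.section_static_outputs(node.section, self.scope,
                                                  node.pattern_binding or None)
            scope.set_reserved("_output", PathList(outs or []))
            for k, v in node.pattern_binding.items():
                scope[k] = v
            for stmt in node.section.body:
                if stmt.kind != "action_call":
                    continue
                try:
                    text = _expand_script(stmt.payload["script"],
                                          stmt.payload["options"], scope)
                except PolyflowError:
                    text = stmt.payload["script"]
                self.result.rendered_scripts.append(
                    (node.name, stmt.payload["name"], text))


def _identifiers(code: str) -> set[str]:
    return set(re.findall(r"[A-Za-z_]\w*", code))


def run(script: Script, workflow: str | None = None,
        targets: list[str] | None = None,
        parameters: dict[str, Any] | None = None, *,
        workdir: str | Path = ".", jobs: int = 1, sig_mode: str = "default",
        dryrun: bool = False, queue: str | None = None,
        config: dict | None = None) -> RunResult:
    """Convenience wrapper: build an :class:`Executor` and run once."""
    return Executor(script, workdir, parameters, jobs=jobs, sig_mode=sig_mode,
                    dryrun=dryrun, queue=queue, config=config).run(
        workflow=workflow, targets=targets)
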