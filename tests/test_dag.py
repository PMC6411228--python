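"""Graph construction in all three styles, scheduling queries, acyclicity."""

import random

import networkx as nx
import pytest

from polyflow import (CycleError, DAGError, parse_script, resolve_workflow)
from polyflow.dag import (DAG, DONE, FAILED, PENDING, RUNNING, StepNode,
                          abort_dependents, assert_acyclic, build_forward_dag,
                          insert_nested, ready_steps, resolve_outcome_dag,
                          to_dot)
from polyflow.script_model import Section, StepHeader
from polyflow.targets import SignatureStore


def _forward(text, name, store=None):
    script = parse_script(text)
    plan = resolve_workflow(script, name)
    return build_forward_dag(plan, script, store=store), script


def _names(nodes):
    return sorted(n.name for n in nodes)


def _edge_names(dag):
    return sorted((a.name, b.name) for a, b in dag.graph.edges)


def _dummy_node(label):
    return StepNode(Section(header=StepHeader(entries=[(label, None)])), label)


# ---------------------------------------------------------------------------
# forward construction
# ---------------------------------------------------------------------------

def test_unspecified_io_chains_sequentially():
    dag, _ = _forward(
        "[w_1]\npython:\n    pass\n\n[w_2]\npython:\n    pass\n\n"
        "[w_3]\npython:\n    pass\n", "w")
    assert _edge_names(dag) == [("w_1", "w_2"), ("w_2", "w_3")]


def test_output_from_overrides_default_chain():
    dag, _ = _forward(
        "[w_1]\noutput: 'a.txt'\npython:\n    pass\n\n"
        "[w_2]\noutput: 'b.txt'\npython:\n    pass\n\n"
        "[w_3]\ninput: output_from(1), output_from(2)\npython:\n    pass\n",
        "w")
    assert ("w_1", "w_3") in _edge_names(dag)
    assert ("w_2", "w_3") in _edge_names(dag)


def test_disjoint_declared_io_runs_parallel():
    dag, _ = _forward(
        "[w_1]\ninput: 'x.in'\noutput: 'x.out'\n\n"
        "[w_2]\ninput: 'y.in'\noutput: 'y.out'\n", "w")
    assert _edge_names(dag) == []
    assert _names(ready_steps(dag)) == ["w_1", "w_2"]


def test_filename_flow_creates_edge():
    dag, _ = _forward(
        "[w_1]\noutput: 'mid.txt'\n\n"
        "[w_5]\ninput: 'unrelated.txt'\noutput: 'x'\n\n"
        "[w_9]\ninput: 'mid.txt'\noutput: 'final.txt'\n", "w")
    assert ("w_1", "w_9") in _edge_names(dag)
    assert ("w_5", "w_9") not in _edge_names(dag)


def test_forward_reference_to_missing_step_errors():
    with pytest.raises(DAGError, match="no step with index 7"):
        _forward("[w_1]\n\n[w_2]\ninput: output_from(7)\n", "w")


def test_mixed_style_pulls_provider_for_missing_input(tmp_path):
    store = SignatureStore(tmp_path)
    dag, _ = _forward(
        "[aux: provides = 'data_{id}.txt']\ntext_transform:\n    write x\n\n"
        "[w_1]\ninput: 'data_7.txt'\noutput: 'out.txt'\n", "w", store)
    assert _names(dag.nodes) == ["aux(id=7)", "w_1"]
    assert _edge_names(dag) == [("aux(id=7)", "w_1")]


# ---------------------------------------------------------------------------
# outcome construction
# ---------------------------------------------------------------------------

OUTCOME = """\
[simulation: provides = 'data_{id}.out']
text_transform:
    write simulated

[evaluation: provides = '{m}_{id}.mse']
input: f"data_{id}.out"
text_transform:
    suffix evaluated
"""


def test_outcome_backward_chain(tmp_path):
    store = SignatureStore(tmp_path)
    dag = resolve_outcome_dag(parse_script(OUTCOME), ["lasso_2.mse"], store)
    assert _names(dag.nodes) == ["evaluation(id=2,m=lasso)", "simulation(id=2)"]
    assert _edge_names(dag) == [("simulation(id=2)", "evaluation(id=2,m=lasso)")]


def test_outcome_satisfied_target_is_empty_graph(tmp_path):
    store = SignatureStore(tmp_path)
    (tmp_path / "lasso_2.mse").write_text("0.5")
    dag = resolve_outcome_dag(parse_script(OUTCOME), ["lasso_2.mse"], store)
    assert dag.nodes == []


def test_outcome_no_provider_errors(tmp_path):
    store = SignatureStore(tmp_path)
    with pytest.raises(DAGError, match="no step provides target 'nosuch.bin'"):
        resolve_outcome_dag(parse_script(OUTCOME), ["nosuch.bin"], store)


def test_outcome_ambiguous_providers_error(tmp_path):
    store = SignatureStore(tmp_path)
    text = ("[a: provides = 'x_{i}.txt']\n\n[b: provides = '{j}_1.txt']\n")
    with pytest.raises(DAGError, match="ambiguous"):
        resolve_outcome_dag(parse_script(text), ["x_1.txt"], store)


def test_outcome_minimality_by_reachability(tmp_path):
    """Every node lies on a path to a requested target."""
    store = SignatureStore(tmp_path)
    script = parse_script(OUTCOME)
    dag = resolve_outcome_dag(script, ["lasso_1.mse", "ridge_2.mse"], store)
    requested = {"evaluation(id=1,m=lasso)", "evaluation(id=2,m=ridge)"}
    for node in dag.nodes:
        reachable = {n.name for n in nx.descendants(dag.graph, node)} | {node.name}
        assert reachable & requested, node.name


# ---------------------------------------------------------------------------
# scheduling queries
# ---------------------------------------------------------------------------

DIAMOND = ("[d_1]\noutput: 'a'\n\n[d_2]\ninput: 'a'\noutput: 'b'\n\n"
           "[d_3]\ninput: 'a'\noutput: 'c'\n\n"
           "[d_4]\ninput: 'b', 'c'\noutput: 'd'\n")


def test_ready_steps_linear_and_diamond():
    dag, _ = _forward("[w_1]\n\n[w_2]\n\n[w_3]\n", "w")
    assert _names(ready_steps(dag)) == ["w_1"]

    dag, _ = _forward(DIAMOND, "d")
    head = ready_steps(dag)
    assert _names(head) == ["d_1"]
    head[0].set_status("ready")
    head[0].set_status("running")
    head[0].set_status("done")
    assert _names(ready_steps(dag)) == ["d_2", "d_3"]


def test_failure_aborts_reachable_dependents_only():
    dag, _ = _forward(DIAMOND, "d")
    nodes = {n.name: n for n in dag.nodes}
    for status in ("ready", "running", "done"):
        nodes["d_1"].set_status(status)
    for status in ("ready", "running", "failed"):
        nodes["d_2"].set_status(status)
    aborted = abort_dependents(dag, nodes["d_2"])
    # oracle: exactly the transitive dependents of the failed node
    expected = {n.name for n in nx.descendants(dag.graph, nodes["d_2"])}
    assert {n.name for n in aborted} == expected == {"d_4"}
    assert _names(ready_steps(dag)) == ["d_3"]  # independent branch continues


# ---------------------------------------------------------------------------
# nested insertion
# ---------------------------------------------------------------------------

def _two_subdags():
    text = ("[left_1]\noutput: 'l'\n\n[right_1]\noutput: 'r'\n")
    script = parse_script(text)
    return [build_forward_dag(resolve_workflow(script, n), script)
            for n in ("left", "right")]


def test_insert_nested_parallel_subworkflows():
    parent = _dummy_node("outer")
    parent.set_status("ready")
    parent.set_status("running")
    dag = DAG()
    dag.add_node(parent)
    inserted = insert_nested(dag, parent, _two_subdags())
    (left,), (right,) = inserted
    assert dag.predecessors(left) == [parent]
    assert dag.predecessors(right) == [parent]
    assert not nx.has_path(dag.graph, left, right)
    assert not nx.has_path(dag.graph, right, left)


def test_insert_nested_requires_running_parent():
    parent = _dummy_node("outer")
    dag = DAG()
    dag.add_node(parent)
    with pytest.raises(DAGError, match="running"):
        insert_nested(dag, parent, _two_subdags())


def test_insert_nested_recursion_is_cycle_error():
    parent = _dummy_node("outer")
    parent.set_status("ready")
    parent.set_status("running")
    dag = DAG()
    dag.add_node(parent)
    key = ("left", "params0")
    with pytest.raises(CycleError):
        insert_nested(dag, parent, _two_subdags(),
                      keys=[key, ("right", "params0")], active={key})


# ---------------------------------------------------------------------------
# acyclicity
# ---------------------------------------------------------------------------

def test_assert_acyclic_chain_ok():
    dag, _ = _forward("[w_1]\n\n[w_2]\n", "w")
    assert_acyclic(dag)


def test_cycle_reported_as_path():
    dag = DAG()
    a, b = _dummy_node("A"), _dummy_node("B")
    dag.add_edge(a, b)
    with pytest.raises(CycleError) as err:
        dag.add_edge(b, a)
    assert err.value.path[0] == err.value.path[-1]
    assert set(err.value.path) == {"A", "B"}


def test_random_dag_topological_order_oracle():
    rng = random.Random(7)
    nodes = [_dummy_node(f"n{i:02d}") for i in range(50)]
    dag = DAG()
    for n in nodes:
        dag.add_node(n)
    for i in range(50):
        for j in range(i + 1, 50):
            if rng.random() < 0.08:
                dag.add_edge(nodes[i], nodes[j])
    assert_acyclic(dag)
    order = list(nx.topological_sort(dag.graph))  # independent oracle
    position = {n: i for i, n in enumerate(order)}
    for a, b in dag.graph.edges:
        assert position[a] < position[b]


def test_dot_rendering_stable():
    dag, _ = _forward("[w_1]\n\n[w_2]\n", "w")
    dot = to_dot(dag)
    assert '"w_1" -> "w_2";' in dot
    assert dot == to_dot(dag)
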