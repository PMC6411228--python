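"""Step execution: grouping, actions, signatures, cleanup, nesting."""

import pytest

from polyflow import (CycleError, ExecutionError, PolyflowError, parse_script,
                      run)
from polyflow.executor import Executor, SubstepContext, action_execute, \
    group_inputs
from polyflow.fixtures import write_text_fixture
from polyflow.interpolation import PathList, VariableScope
from polyflow.targets import SignatureStore


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("paths,group_by,expected", [
    (["a", "b", "c", "d"], 1, [["a"], ["b"], ["c"], ["d"]]),
    (["a", "b", "c", "d"], 2, [["a", "b"], ["c", "d"]]),
    (["a", "b"], "all", [["a", "b"]]),
    (["a", "b"], None, [["a", "b"]]),
    ([], None, [[]]),
])
def test_group_inputs(paths, group_by, expected):
    assert group_inputs(paths, group_by) == expected


def test_group_inputs_divisibility_enforced():
    with pytest.raises(ExecutionError, match="3 input files into groups of 2"):
        group_inputs(["a", "b", "c"], 2)
    with pytest.raises(ExecutionError, match="positive integer"):
        group_inputs(["a"], 0)


# ---------------------------------------------------------------------------
# actions
# ---------------------------------------------------------------------------

def _ctx(workdir, inputs=(), outputs=(), extra=None):
    scope = VariableScope(dict(extra or {}))
    scope.set_reserved("_input", PathList(inputs))
    scope.set_reserved("_output", PathList(outputs))
    scope.set_reserved("_index", 0)
    return SubstepContext(_input=PathList(inputs), _output=PathList(outputs),
                          _index=0, scope=scope, workdir=workdir)


def test_builtin_concat(tmp_path):
    (tmp_path / "a").write_bytes(b"AA")
    (tmp_path / "b").write_bytes(b"BB")
    action_execute("concat", "", {}, _ctx(tmp_path, ["a", "b"], ["c"]))
    assert (tmp_path / "c").read_bytes() == b"AABB"


def test_shell_action_with_expansion(tmp_path):
    ctx = _ctx(tmp_path, outputs=["out.txt"])
    action_execute("sh", "echo hi > {_output}", {"expand": True}, ctx)
    assert (tmp_path / "out.txt").read_text().strip() == "hi"


def test_action_without_expansion_passes_braces_verbatim(tmp_path):
    ctx = _ctx(tmp_path, outputs=["out.txt"])
    action_execute("sh", "echo '{x}' > out.txt", {}, ctx)
    assert (tmp_path / "out.txt").read_text().strip() == "{x}"


def test_unregistered_action_lists_registry(tmp_path):
    with pytest.raises(ExecutionError, match="concat"):
        action_execute("fortran", "", {}, _ctx(tmp_path))


# ---------------------------------------------------------------------------
# whole-step execution semantics
# ---------------------------------------------------------------------------

def test_chain_execution_and_skip(run_wf, workdir):
    text = write_text_fixture("chain", workdir).read_text()
    first = run_wf(text, "chain")
    assert first.total("executed") == 3 and first.succeeded
    assert (workdir / "c3.txt").read_text() == "alpha\nbeta\ngamma\n"
    again = run_wf(text, "chain")
    assert again.total("executed") == 0 and again.total("skipped") == 3


def test_sig_mode_force_and_ignore(run_wf, workdir):
    text = write_text_fixture("chain", workdir).read_text()
    run_wf(text, "chain")
    forced = run_wf(text, "chain", sig_mode="force")
    assert forced.total("executed") == 3
    (workdir / ".polyflow").rename(workdir / ".polyflow.bak")
    ignored = run_wf(text, "chain", sig_mode="ignore")
    assert ignored.total("executed") == 3
    rerun = run_wf(text, "chain")  # nothing was recorded under "ignore"
    assert rerun.total("executed") == 3


def test_signatures_are_workflow_independent(run_wf, workdir):
    # the same shared section re-invoked under another workflow name skips
    text = ("[alpha_1, beta_1]\noutput: 'shared.txt'\n"
            "text_transform:\n    write shared\n")
    assert run_wf(text, "alpha").total("executed") == 1
    second = run_wf(text, "beta")
    assert second.total("executed") == 0 and second.total("skipped") == 1


def test_missing_declared_output_fails_step(run_wf, workdir):
    text = "[w_1]\noutput: 'never.txt'\nsh:\n    true\n"
    result = run_wf(text, "w")
    assert not result.succeeded and result.total("failed") == 1
    assert not (workdir / "never.txt").exists()


def test_failed_substep_removes_partial_outputs(run_wf, workdir):
    text = ("[w_1]\noutput: 'half.txt'\n"
            "sh:\n    echo partial > half.txt\n    exit 3\n")
    result = run_wf(text, "w")
    assert result.total("failed") == 1
    assert not (workdir / "half.txt").exists()


def test_failure_aborts_dependents_independent_branch_completes(run_wf, workdir):
    text = ("[f_1]\noutput: 'a.txt'\ntext_transform:\n    write root\n\n"
            "[f_2]\ninput: 'a.txt'\noutput: 'b.txt'\n"
            "text_transform:\n    fail on purpose\n\n"
            "[f_3]\ninput: 'a.txt'\noutput: 'c.txt'\n"
            "text_transform:\n    suffix ok\n\n"
            "[f_4]\ninput: 'b.txt'\noutput: 'd.txt'\nconcat:\n")
    result = run_wf(text, "f")
    assert result.counts["f_2"]["failed"] == 1
    assert result.counts["f_4"]["aborted"] == 1
    assert result.counts["f_3"]["executed"] == 1
    assert (workdir / "c.txt").exists() and not (workdir / "d.txt").exists()


def test_grouped_substeps_and_worker_parity(run_wf, workdir, tmp_path):
    text = write_text_fixture("grouped", workdir).read_text()
    res = run_wf(text, "group", jobs=1)
    assert res.counts["group_1"]["executed"] == 2
    pair0 = (workdir / "pair_0.txt").read_bytes()
    pair1 = (workdir / "pair_1.txt").read_bytes()
    assert pair0 == b"content-1\ncontent-2\n"
    assert pair1 == b"content-3\ncontent-4\n"
    other = tmp_path / "wd4"
    write_text_fixture("grouped", other)
    from polyflow import parse_script as ps
    res4 = run(ps(other.joinpath("grouped.pfw").read_text()), "group",
               workdir=other, jobs=4)
    assert res4.counts["group_1"]["executed"] == 2
    assert (other / "pair_0.txt").read_bytes() == pair0
    assert (other / "pair_1.txt").read_bytes() == pair1


def test_substep_accounting_invariant(run_wf, workdir):
    text = write_text_fixture("grouped", workdir).read_text()
    res = run_wf(text, "group")
    for step, row in res.counts.items():
        assert sum(row.values()) == 2  # group count per step


def test_paired_with_exposes_per_group_values(run_wf, workdir):
    for i in (1, 2):
        (workdir / f"s{i}.txt").write_text(f"sample {i}\n")
    text = ("labels = ['x', 'y']\n\n"
            "[w_1]\n"
            "input: 's1.txt', 's2.txt', group_by=1, paired_with='labels'\n"
            "output: f\"out_{_labels[0]}.txt\"\n"
            "concat:\n")
    res = run_wf(text, "w")
    assert res.counts["w_1"]["executed"] == 2
    assert (workdir / "out_x.txt").read_text() == "sample 1\n"
    assert (workdir / "out_y.txt").read_text() == "sample 2\n"


def test_dryrun_creates_nothing(run_wf, workdir):
    text = write_text_fixture("chain", workdir).read_text()
    res = run_wf(text, "chain", dryrun=True)
    assert res.dot and "chain_1" in res.dot
    assert res.rendered_scripts
    assert not (workdir / "c1.txt").exists()
    assert res.total("executed") == 0


def test_nested_run_parallel_workflows(run_wf, workdir):
    text = write_text_fixture("nested", workdir).read_text()
    res = run_wf(text)
    assert (workdir / "left.txt").exists() and (workdir / "right.txt").exists()
    assert res.counts["left_1"]["executed"] == 1
    assert res.counts["right_1"]["executed"] == 1
    assert "default" in res.orchestration_steps


def test_nested_run_unknown_name(run_wf):
    text = "[default]\nsos_run('nosuch')\n"
    res = run_wf(text)
    assert not res.succeeded


def test_nested_recursion_detected(run_wf):
    text = "[loop_1]\nsos_run('loop')\n\n[default]\nsos_run('loop')\n"
    res = run_wf(text)
    assert not res.succeeded  # cycle error surfaces as step failure


def test_required_parameter_enforced(workdir):
    script = parse_script("parameter: depth: integer\n[w_1]\noutput: 'x'\n"
                          "text_transform:\n    write ok\n")
    with pytest.raises(PolyflowError, match="--depth"):
        Executor(script, workdir)
    res = run(script, "w", parameters={"depth": "3"}, workdir=workdir)
    assert res.succeeded


def test_parameters_reach_scripts(run_wf, workdir):
    text = ("parameter: word = 'hello'\n\n"
            "[w_1]\noutput: 'msg.txt'\n"
            "text_transform: expand=True\n    write {word}\n")
    run_wf(text, "w", parameters={"word": "salve"})
    assert (workdir / "msg.txt").read_text() == "salve\n"
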