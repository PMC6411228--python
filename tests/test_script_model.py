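"""Workflow-file parsing, workflow resolution, help extraction."""

import pytest

from polyflow import (ParseError, PolyflowError, extract_help, parse_header,
                      parse_script, resolve_workflow, serialize)
from polyflow.fixtures import FixtureSpec, write_regression_fixture


@pytest.mark.parametrize("line,entries,options", [
    ("[lasso_1, ridge_1]", [("lasso", 1), ("ridge", 1)], {}),
    ("[default]", [("default", None)], {}),
    ("[simulate: provides = 'data_{id}.out']", [("simulate", None)],
     {"provides": "data_{id}.out"}),
    ("[10]", [("default", 10)], {}),
    ("[a_2, b_5]", [("a", 2), ("b", 5)], {}),
    ("[fit: provides = ['{m}_{i}.coef', '{m}_{i}.pred']]", [("fit", None)],
     {"provides": ["{m}_{i}.coef", "{m}_{i}.pred"]}),
])
def test_header_grammar(line, entries, options):
    header = parse_header(line)
    assert header.entries == entries
    assert header.options == options


@pytest.mark.parametrize("line", ["[]", "[  ]", "[a b]", "[a,,b]", "[x!]"])
def test_header_errors(line):
    with pytest.raises(ParseError):
        parse_header(line)


def test_bare_script_forms_implicit_section():
    # two bare action blocks with no headers: one implicit default step
    # executing the blocks in inclusion order
    script = parse_script(
        "python:\n    print('convert')\n\nrscript:\n    plot(1)\n")
    assert len(script.sections) == 1
    sec = script.sections[0]
    assert sec.header.entries == [("default", None)]
    actions = sec.statements_of("action_call")
    assert [a.payload["name"] for a in actions] == ["python", "rscript"]
    assert actions[0].payload["script"] == "print('convert')"


def test_empty_script():
    script = parse_script("")
    assert script.sections == [] and script.global_statements == []


def test_named_sections_are_separate_workflows():
    script = parse_script(
        "[convert]\npython:\n    pass\n\n[plot]\nrscript:\n    pass\n")
    assert script.workflow_names() == ["convert", "plot"]
    assert len(resolve_workflow(script, "convert").steps) == 1
    assert len(resolve_workflow(script, "plot").steps) == 1


def test_duplicate_step_entry_is_parse_error():
    with pytest.raises(ParseError, match="duplicate"):
        parse_script("[a_1]\n\n[b_1, a_1]\n")


def test_leading_assignments_are_global():
    script = parse_script('prefix = "out"\n\n[a_1]\noutput: f"{prefix}.txt"\n')
    assert len(script.global_statements) == 1
    assert len(script.sections) == 1


def test_parameter_typing_and_comments():
    script = parse_script(
        "# significance cutoff\nparameter: cutoff = 0.05\n"
        "parameter: tag: string\n"
        "parameter: n = 10\n"
        "parameter: verbose = False\n")
    by_name = {p.name: p for p in script.parameters}
    assert by_name["cutoff"].type_tag == "float"
    assert by_name["cutoff"].comment == "significance cutoff"
    assert by_name["tag"].type_tag == "string" and not by_name["tag"].has_default
    assert by_name["n"].type_tag == "integer"
    assert by_name["verbose"].type_tag == "boolean"
    assert by_name["n"].coerce("7") == 7
    assert by_name["verbose"].coerce("yes") is True


def test_duplicate_input_statement_rejected():
    with pytest.raises(ParseError, match="at most one input"):
        parse_script("[a_1]\ninput: 'x'\ninput: 'y'\n")


@pytest.mark.parametrize("name,indices", [
    ("lasso", [1, 2, 3]),
    ("sparse", [10, 20]),
])
def test_resolve_orders_steps_by_index(name, indices):
    text = "".join(f"[{name}_{i}]\npython:\n    pass\n\n" for i in reversed(indices))
    plan = resolve_workflow(parse_script(text), name)
    assert plan.indices == sorted(indices)


def test_shared_section_in_both_plans():
    text = ("[lasso_1, ridge_1]\npython:\n    pass\n\n"
            "[lasso_2]\npython:\n    pass\n\n"
            "[ridge_2]\npython:\n    pass\n")
    script = parse_script(text)
    shared = script.sections[0]
    assert shared in [s for _i, s in resolve_workflow(script, "lasso").steps]
    assert shared in [s for _i, s in resolve_workflow(script, "ridge").steps]


def test_resolve_unknown_workflow_lists_names():
    script = parse_script("[convert]\npython:\n    pass\n")
    with pytest.raises(PolyflowError, match="convert"):
        resolve_workflow(script, "nosuch")


def test_resolve_independent_of_section_order():
    sections = [f"[w_{i}]\noutput: 'f{i}.txt'\n" for i in (3, 1, 2)]
    a = resolve_workflow(parse_script("\n".join(sections)), "w")
    b = resolve_workflow(parse_script("\n".join(reversed(sections))), "w")
    assert a.indices == b.indices == [1, 2, 3]
    assert [s.single("output_spec").payload["expr"] for _i, s in a.steps] == \
           [s.single("output_spec").payload["expr"] for _i, s in b.steps]


def test_help_lists_workflows_and_parameters():
    text = ("# threshold used by the plot\nparameter: cutoff = 0.5\n\n"
            "# Convert the spreadsheet\n[convert]\npython:\n    pass\n\n"
            "# Plot the converted data\n[plot]\nrscript:\n    pass\n")
    help_text = extract_help(parse_script(text))
    assert "convert" in help_text and "plot" in help_text
    assert "Convert the spreadsheet" in help_text
    assert "--cutoff" in help_text and "threshold used by the plot" in help_text


def test_help_on_empty_script_is_usage_only():
    help_text = extract_help(parse_script(""))
    assert help_text.startswith("usage:")
    assert "workflows:" not in help_text


def test_help_parameter_without_comment():
    help_text = extract_help(parse_script("parameter: depth = 3\n"))
    assert "--depth" in help_text and "integer" in help_text


@pytest.mark.parametrize("style", ["process", "outcome", "mixed"])
def test_roundtrip_structural_equality(tmp_path, style):
    """parse -> serialize -> parse preserves structure and embedded scripts."""
    path = write_regression_fixture(FixtureSpec(style=style, outdir=tmp_path))
    first = parse_script(path.read_text())
    second = parse_script(serialize(first))
    assert first.parameters == second.parameters
    assert first.global_statements == second.global_statements
    assert first.sections == second.sections
    for a, b in zip(first.sections, second.sections):
        for sa, sb in zip(a.statements_of("action_call"),
                          b.statements_of("action_call")):
            assert sa.payload["script"] == sb.payload["script"]  # byte-exact


def test_embedded_script_deindent_preserves_relative_indent():
    script = parse_script(
        "[a_1]\npython:\n        if True:\n            x = 1\n\n        y = 2\n")
    body = script.sections[0].statements_of("action_call")[0].payload["script"]
    assert body == "if True:\n    x = 1\n\ny = 2"
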