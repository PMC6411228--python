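# The `.pfw` workflow file format

A workflow file is UTF-8 text made of an optional global region followed
by bracketed sections.

## Sections and headers

```
header  = "[" entry ("," entry)* (":" option ("," option)*)? "]"
entry   = name | name "_" index | index        # bare index binds "default"
option  = key "=" expression
```

* `[convert]` — a single step of workflow `convert`.
* `[lasso_1, ridge_1]` — one section shared as step 1 of two workflows.
* `[simulate: provides = ['data_{id}.train.txt', 'data_{id}.test.txt']]` —
  an auxiliary step that can create any file matching the patterns;
  matched `{name}` wildcards become variables in the step's scope.

Indices are nonnegative and need not be consecutive. Duplicate
`(name, index)` pairs across a file are an error. Contiguous `#` comment
lines directly above a header (or a `parameter:` line) become its help
text, shown by `polyflow run script.pfw -h`.

## The global region

Code before the first header is split by role: `parameter:` definitions
and plain assignments belong to the global scope; action calls and
directives form an implicit `[default]` section, so a file that is just
two bare script blocks is a runnable one-step workflow.

## Directives

| directive | cardinality | meaning |
|---|---|---|
| `parameter: name = default` | any | command-line parameter, type inferred from the default |
| `parameter: name: type` | any | required parameter; type ∈ string, integer, float, boolean, path, list-of-string, list-of-path |
| `input: exprs, group_by=N, paired_with=...` | ≤ 1 | step input files; omitting it chains from the previous step's output, `input:` with no expressions severs the chain |
| `output: exprs` / `output: label = exprs` | ≤ 1 | declared outputs, optionally as a named output group |
| `depends: exprs` | any | extra dependency targets (files or `sos_step('name')`) |
| `task: queue='host'` | ≤ 1 | run this step's actions through the task queue |

Spec expressions are a restricted language: names, literals, arithmetic,
comparisons, subscripts, attribute access, f-strings, comprehensions, and
calls to the dependency functions `output_from(index_or_list)`,
`named_output('label')`, `sos_step('name')`. A trailing `:spec` applies
path format options.

`group_by` is a positive integer (the input count must divide evenly —
a remainder is an error) or `'all'`. With `paired_with='var'`, the list
`var` is split alongside the groups and exposed per substep as `_var`.

## Plain statements and nested workflows

Any other non-indented line is a plain statement executed by a sandboxed
evaluator (assignments, conditionals, loops, calls; no imports,
definitions, or dunder access). `sos_run(['a', 'b'], param=value)` runs
nested workflows; several names in one call run mutually unordered.
`zap(paths)` replaces tracked intermediates with digest placeholders.

## Action calls

```
python: expand=True
    import numpy as np
    np.savetxt("{_output[0]}", np.zeros(3))
```

An identifier followed by `:` and an indented block runs the block
through the named action. Common leading whitespace is stripped; the text
is otherwise stored byte-exact. With `expand=True` the script is expanded
against the step scope using `{}` delimiters (doubled braces escape);
`expand=('${', '}')` selects a custom pair for brace-heavy scripts — under
a custom pair a bare close delimiter is literal.

Reserved scope names: `_input`, `_output` (ordered path lists, rendered
as space-separated shell-quoted-on-demand paths), `_index` (group
ordinal), `step_name`.

### Path format options (`{_input:bn}` etc.)

| letter | effect |
|---|---|
| `b` | basename |
| `d` | parent directory (`.` when none) |
| `n` | strip the last extension, directory preserved |
| `e` | the extension including its dot |
| `a` | lexically absolutized path |
| `q` | shell-quote when whitespace or metacharacters present |
| `r` | quoted literal for embedding in code |

Options apply left to right and elementwise over path lists.

### Built-in actions (no interpreter needed)

* `concat` — write the byte concatenation of `_input` to every `_output`;
* `copy` — pairwise copy `_input[i]` to `_output[i]`;
* `text_transform` — apply one directive per script line to the
  concatenated input text and write the result to every output:
  `upper`, `lower`, `reverse`, `replace OLD NEW`, `prefix TEXT`,
  `suffix TEXT`, `write TEXT`, `sleep SECONDS`, `fail [MESSAGE]`.

Interpreter actions are defined in the registry (defaults: `python`,
`sh`, `bash`, `rscript`) and extended through the engine configuration:

```yaml
actions:
  perl: "perl {script}"
hosts:
  cluster:
    kind: mock_remote
    root: /path/to/isolated/fs
    path_map:
      - /home/me/project = /scratch/me/project
    max_running: 4
    submit_template: "/bin/sh {script}"   # optional scheduler stand-in
```

## The signature store

`<workdir>/.polyflow/` holds one line-oriented text record per completed
substep (`signatures/*.sig`, keyed by content digest, substep index, and
input digests), step and named-output completion markers, lock files,
task records, and temporary scripts (kept on failure for debugging).
`<path>.zapped` sidecar files sit next to the original intermediates.
The store records its digest algorithm and refuses to mix algorithms.
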