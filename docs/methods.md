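# Methods

## What the engine computes

A workflow file is parsed into sections; a run binds sections to a DAG in
one of three ways. A *process* build takes the requested workflow's
sections in ascending index order, chains each step to its predecessor
unless the step declares its own `input:`, and adds edges for explicit
references (`output_from`, `named_output`, `sos_step`) and for file names
another step statically declares as output. An *outcome* build starts
from requested targets and recurses backward: a target that exists (or is
zapped) terminates recursion; otherwise exactly one section must provide
it, either by declared output or by a `provides` wildcard match, whose
binding becomes part of the node's identity and scope. A *mixed* build is
the forward build plus backward resolution for input files nobody in the
plan produces. Ambiguity (two providers for one target) is always an
error, never auto-resolved; likewise sibling subworkflows are only run
together when explicitly requested in one nested call, since their
relative order is otherwise undefined.

Scheduling executes ready nodes (all prerequisites done or skipped) in a
deterministic sorted order; substeps within a step are dispatched to a
thread pool of `jobs` workers. Determinism of final outputs across worker
counts follows because substeps write disjoint declared outputs.

## Runtime signatures

A substep is skipped when a stored record matches
`(content digest, substep index, input digests)` and its recorded outputs
are still present with their recorded digests. The content digest covers:
the canonical statement list of the section body (whitespace and comments
outside embedded scripts do not contribute), each embedded script *after*
interpolation, the interpreter command associated with each action, the
engine version, and the values of those parameters whose names occur in
the body. Workflow and step names are deliberately excluded, which makes
signatures workflow-independent: a shared or renamed workflow recognizes
work done under another name. The one deviation this engine makes from a
pure skip rule is steps that invoke nested workflows: their own signature
cannot vouch for the sub-steps' validity, so such steps always re-enter
the nested scheduler (cheap when everything below skips) and are counted
as skipped only when none of their nested work executed. They are also
reported separately (`RunResult.orchestration_steps`) so accounting can
distinguish orchestration from computation.

Signature granularity is per substep, so a partially completed grouped
step skips its finished groups. Records are one text file each, written
atomically (`os.replace`); the store refuses to open records written with
a different digest algorithm (SHA-256 here, recorded in store metadata).

## Zap

Zapping replaces a tracked intermediate (it must appear as an output in
some signature record) with a `<path>.zapped` sidecar holding its digest
and size. Placeholders satisfy existence checks and input-digest checks,
so producers and previously-signed consumers skip. When a substep is
actually about to run and one of its *input* files is zapped, the engine
regenerates it: the providing section is re-executed with output
satisfaction held to a content-required standard, after which the
placeholder is retired. `depends:` targets only need existence and do not
trigger regeneration. The alternative semantics — erroring when zapped
content is required — was considered and rejected in favor of keeping
workflows runnable end to end; a digest mismatch after regeneration is
reported as a warning rather than silently accepted.

## Locks and failure

Each substep takes an exclusive lock file keyed by its content digest and
substep index, covering the skip check, execution, and signature write;
a second engine instance therefore waits, then skips off the fresh
record. Locks are re-entrant within a thread (a nested step whose body is
byte-identical to an enclosing step's would otherwise deadlock on
itself). On substep failure, all of the substep's declared outputs are
deleted — partial results never survive — the step is marked failed, its
transitive dependents abort, and independent branches keep running; the
process exits 1. Stale locks from killed processes are not reclaimed
automatically; the wait times out after 300 s with an error naming the
lock file.

## Tasks and the mock-remote host

A step with a `task:` statement packages each substep's expanded action
scripts plus its input/output file lists into a task whose id is a digest
of that payload (resubmitting an identical completed task returns
immediately). For a `mock_remote` host the engine translates every
absolute path by longest matching `path_map` prefix, copies inputs into
the host root with digest verification, executes the payload with the
translated working directory and an environment denied the local store,
then copies outputs back (again digest-verified, via a temp file so a
failed sync leaves nothing partial). Signature records are written after
synchronization against local paths only. `max_running` is enforced with
a per-host bounded semaphore; `submit_template` wraps the command in a
generated shell script, standing in for a batch scheduler's submission
step. The mock backend intentionally models only the observable contract
(translation, sync, status, kill, concurrency limits) — no SSH, no real
queue, no polling latency.

## Interpolation and the sandboxed evaluator

Spec expressions and plain statements are evaluated over the step scope
by a restricted evaluator: the syntax tree is checked against a whitelist
(names, literals, arithmetic, comparisons, subscripts, attribute access,
comprehensions, f-strings, calls; statements add assignment, `if`,
`for`/`while`) with imports, definitions, and dunder access rejected, and
run with a curated builtin set. Template expansion substitutes
delimiter-bounded expressions; doubled delimiters escape. Under the
default `{}` pair a bare close brace is an unbalanced-delimiter error;
under a custom pair (chosen precisely for brace-heavy scripts) a bare
close delimiter is literal text. Path lists render as space-separated
paths, each shell-quoted only when it contains whitespace or
metacharacters; an empty list renders as the empty string.

Wildcard patterns match placeholders against nonempty, separator-free
substrings; among multiple consistent matches the leftmost placeholder
takes the shortest substring with ties resolved left to right — i.e. the
lexicographically minimal tuple of placeholder lengths, which is exactly
what a left-anchored non-greedy regular expression produces and what the
test suite verifies against brute-force enumeration of all splits.

## The demonstration study and its defaults

The regression fixture simulates y = Xβ + ε with X an n×p standard
normal matrix, β sparse (first k entries equal to `beta_scale`, rest
zero), ε standard normal, one train and one test set per dataset, RNG
seeded with `seed + dataset_id` so every style regenerates identical
bytes. Defaults: n_dataset = 2, n = 60, p = 100, k = 5, beta_scale = 3.0,
seed = 20201 — a p > n regime with strong sparse signal, sized to run the
whole three-style comparison in seconds on one CPU. The lasso penalty
λ = 0.2 (objective (1/2n)‖y−Xβ‖² + λ‖β‖₁, the parametrization used by
scikit-learn, against which the coordinate-descent solver is
cross-checked to ~1e-6) and ridge λ = 1.0 (closed form, checked to
~1e-9) were fixed once as round values giving a clearly sparse lasso fit;
under these conditions lasso's test MSE beats ridge's in essentially all
replicates, and the suite asserts the deliberately loose bound of ≥ 60%
over 20 seeded replicates. Files are tab-delimited text, response first
column, all floats printed with `%.10g` so cross-style byte comparison is
meaningful.

The numerical core is written once as plain functions whose source is
embedded verbatim into the generated workflow scripts — the same bytes
run in every style, and the same functions are importable for direct
testing. What the generator does *not* emulate: real data idiosyncrasies
(missingness, heteroscedasticity, correlated designs), long-running
steps, or large files; passing tests demonstrate engine semantics and
solver correctness at desk scale, not statistical performance claims
about real datasets.

## Design choices where the design was open

* **Header grammar** (`[entry(, entry)*(: option(, option)*)]`, entry =
  name, name_index, or bare integer assigned to `default`) covers every
  observed usage; a section may in principle join two workflows at
  different indices (`a_2, b_5`) — the grammar permits it, and binding is
  per workflow, but the combination is untested territory and not used by
  the fixtures.
* **Leading-region split**: assignments and parameters are global;
  actions/directives form the implicit default section. This keeps both
  "a file of bare script blocks is a workflow" and "global parameters
  above the first header" true simultaneously.
* **Parameter typing** is inferred from defaults; required parameters
  carry an annotation token. Command-line strings are coerced to the
  declared type; booleans accept 1/0, true/false, yes/no, on/off.
* **Skipped steps re-expose outputs** by re-evaluating their declared
  output expressions (not by trusting records), so downstream
  `output_from` behaves identically whether the producer ran or skipped.
* **Divisible `group_by` is enforced** — an uneven split would silently
  mis-pair grouped inputs (e.g. train/test pairs), so a remainder fails
  fast.
* **`sig_mode`**: `default` (skip on valid record), `force` (re-run and
  re-record), `ignore` (re-run, record nothing).
* **Engine "environment" in the signature** is the engine version plus
  the interpreter command of each action used — a bounded, reproducible
  proxy; capturing full interpreter/library versions is out of scope.
* **Non-synchronized remote modes** (inputs living permanently on the
  remote side) are excluded rather than given guessed signature
  semantics.

## Known limitations

* Static analysis evaluates spec expressions with the global scope; a
  step whose inputs are only computable at run time falls back to the
  sequential chain edge, which is safe but conservative.
* Outcome resolution treats an existing file as satisfied without
  re-validating the chain that produced it; `-s force` exists for when
  upstream definitions changed underneath an existing file.
* One engine process executes ready steps sequentially (substeps in
  parallel); step-level wall-clock parallelism across heavy steps is not
  attempted at desk scale, though the DAG exposes the parallel frontier.
* Stale lock files from hard-killed processes must be removed manually.
* The sandboxed evaluator is a safety rail against accidents, not a
  security boundary — workflow files are trusted input.
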