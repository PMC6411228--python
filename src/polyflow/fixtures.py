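"""Workflow generators: the regression demonstration and engine-test fixtures.

The headline fixture is a three-stage computational experiment — simulate
labeled datasets, fit lasso and ridge regression, evaluate test-set mean
squared prediction error — written in each of the three workflow styles:

* **process**: numbered steps per method (``lasso_1`` shared with
  ``ridge_1``), a ``default`` step launching both methods with one nested
  call;
* **outcome**: every stage declared through ``provides`` wildcard
  patterns, resolved backward from the requested result files;
* **mixed**: a ``provides``-pattern simulate step feeding process-oriented
  fit/evaluate steps.

Data are simulated from a sparse linear model y = Xβ + ε with X standard
normal (n × p), β having the first k entries equal to ``beta_scale`` and
the rest zero, and ε standard normal — a regime where the ℓ1 penalty
should usually beat the ℓ2 penalty on test error.  The numerical core
(coordinate-descent lasso, closed-form ridge) lives in this module as
plain functions whose source is embedded verbatim into the generated
workflow scripts, so every style runs byte-identical numerics; the same
functions are importable for direct cross-checking against independent
implementations.

All dataset files are tab-delimited text with the response in the first
column and predictors after it (``data_{id}.train.txt`` /
``data_{id}.test.txt``); results are single-value ``{method}_{id}.mse.txt``
files.
"""

from __future__ import annotations

import inspect
import textwrap
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import PolyflowError

__all__ = [
    "FixtureSpec", "write_regression_fixture", "write_text_fixture",
    "simulate_dataset", "load_dataset", "fit_lasso", "fit_ridge",
    "predict_mse", "eval_mse",
]


# ---------------------------------------------------------------------------
# numerical core (embedded verbatim into generated workflow scripts;
# keep these functions free of brace characters)
# ---------------------------------------------------------------------------

def simulate_dataset(seed, dataset_id, n, p, k, beta_scale,
                     train_path, test_path):
    """Simulate one train/test pair from a sparse linear model."""
    rng = np.random.default_rng(seed + dataset_id)
    beta = np.zeros(p)
    beta[:k] = beta_scale
    for path in (train_path, test_path):
        X = rng.standard_normal((n, p))
        y = X @ beta + rng.standard_normal(n)
        table = np.column_stack([y, X])
        np.savetxt(path, table, fmt="%.10g", delimiter="\t")


def load_dataset(path):
    table = np.loadtxt(path, delimiter="\t")
    return table[:, 1:], table[:, 0]


def fit_ridge(X, y, lam):
    """Closed-form penalized least squares: (X'X + lam I)^-1 X'y."""
    p = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)


def fit_lasso(X, y, lam, n_iter=1000, tol=1e-9):
    """Cyclic coordinate descent for (1/2n)||y - Xb||^2 + lam ||b||_1."""
    n, p = X.shape
    beta = np.zeros(p)
    col_sq = (X * X).sum(axis=0)
    resid = y.copy()
    gamma = lam * n
    for _ in range(n_iter):
        max_step = 0.0
        for j in range(p):
            if col_sq[j] == 0.0:
                continue
            rho = X[:, j] @ resid + col_sq[j] * beta[j]
            new = np.sign(rho) * max(abs(rho) - gamma, 0.0) / col_sq[j]
            step = new - beta[j]
            if step != 0.0:
                resid -= X[:, j] * step
                beta[j] = new
                if abs(step) > max_step:
                    max_step = abs(step)
        if max_step < tol:
            break
    return beta


def predict_mse(X, y, beta):
    err = y - X @ beta
    return float(err @ err / len(y))


def eval_mse(test_path, pred_path, out_path):
    """Mean squared prediction error of stored predictions on a test set."""
    table = np.loadtxt(test_path, delimiter="\t")
    y = table[:, 0]
    pred = np.loadtxt(pred_path)
    err = y - pred
    mse = float(err @ err / len(y))
    with open(out_path, "w") as fh:
        fh.write("%.10g\n" % mse)


def _source(*funcs) -> str:
    return "\n".join(textwrap.dedent(inspect.getsource(f)) for f in funcs)


# ---------------------------------------------------------------------------
# fixture specification
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Study conditions for the regression fixture.

    The same (n_dataset, n, p, seed) must yield byte-identical simulated
    data files in every style.
    """
    style: str = "process"
    n_dataset: int = 2
    n: int = 60
    p: int = 100
    seed: int = 20201
    outdir: str | Path = "."
    k: int = 5
    beta_scale: float = 3.0
    lasso_lam: float = 0.2
    ridge_lam: float = 1.0


_PARAMS = """\
# number of simulated datasets
parameter: n_dataset = {n_dataset}
# samples per dataset
parameter: n = {n}
# number of predictors
parameter: p = {p}
# base random seed (dataset id is added)
parameter: seed = {seed}
# nonzero true coefficients
parameter: k = {k}
# magnitude of nonzero coefficients
parameter: beta_scale = {beta_scale}
# lasso penalty (objective (1/2n)|y-Xb|^2 + lam |b|_1)
parameter: lasso_lam = {lasso_lam}
# ridge penalty (objective |y-Xb|^2 + lam |b|^2)
parameter: ridge_lam = {ridge_lam}
"""


def _indent(text: str) -> str:
    return "\n".join("    " + l if l.strip() else "" for l in text.splitlines())


def _simulate_all_script() -> str:
    body = ("import numpy as np\n\n"
            + _source(simulate_dataset)
            + "\nfor i in range(1, {n_dataset} + 1):\n"
              "    simulate_dataset({seed}, i, {n}, {p}, {k}, {beta_scale},\n"
              "                     \"data_%d.train.txt\" % i,"
              " \"data_%d.test.txt\" % i)\n")
    return _indent(body)


def _simulate_one_script() -> str:
    body = ("import numpy as np\n\n"
            + _source(simulate_dataset)
            + "\nsimulate_dataset({seed}, int(\"{id}\"), {n}, {p}, {k}, "
              "{beta_scale},\n"
              "                 \"data_{id}.train.txt\", \"data_{id}.test.txt\")\n")
    return _indent(body)


def _fit_script(method_expr: str) -> str:
    """Fit driver for sections whose method is only known at run time."""
    body = ("import numpy as np\n\n"
            + _source(load_dataset, fit_ridge, fit_lasso)
            + "\nmethod = " + method_expr + "\n"
            "X, y = load_dataset(\"{_input[0]}\")\n"
            "Xt, yt = load_dataset(\"{_input[1]}\")\n"
            "if method == \"lasso\":\n"
            "    beta = fit_lasso(X, y, {lasso_lam})\n"
            "else:\n"
            "    beta = fit_ridge(X, y, {ridge_lam})\n"
            "np.savetxt(\"{_output[0]}\", beta, fmt=\"%.10g\")\n"
            "np.savetxt(\"{_output[1]}\", Xt @ beta, fmt=\"%.10g\")\n")
    return _indent(body)


def _fit_script_fixed(method: str) -> str:
    """Fit driver for a single fixed method.

    Each method's section embeds only its own algorithm and penalty, so
    editing one method's settings leaves the other method's steps
    untouched on re-execution.
    """
    fit_fn = fit_lasso if method == "lasso" else fit_ridge
    lam = "{lasso_lam}" if method == "lasso" else "{ridge_lam}"
    body = ("import numpy as np\n\n"
            + _source(load_dataset, fit_fn)
            + "\nX, y = load_dataset(\"{_input[0]}\")\n"
            "Xt, yt = load_dataset(\"{_input[1]}\")\n"
            f"beta = {fit_fn.__name__}(X, y, {lam})\n"
            "np.savetxt(\"{_output[0]}\", beta, fmt=\"%.10g\")\n"
            "np.savetxt(\"{_output[1]}\", Xt @ beta, fmt=\"%.10g\")\n")
    return _indent(body)


def _eval_loop_script() -> str:
    body = ("import numpy as np\n\n"
            + _source(eval_mse)
            + "\nmethod = \"{step_name}\".split(\"_\")[0]\n"
            "for i in range(1, {n_dataset} + 1):\n"
            "    eval_mse(\"data_%d.test.txt\" % i,\n"
            "             \"%s_%d.pred.txt\" % (method, i),\n"
            "             \"%s_%d.mse.txt\" % (method, i))\n")
    return _indent(body)


def _eval_one_script() -> str:
    body = ("import numpy as np\n\n"
            + _source(eval_mse)
            + "\neval_mse(\"{_input[0]}\", \"{_input[1]}\", \"{_output[0]}\")\n")
    return _indent(body)


def _process_style(spec: FixtureSpec) -> str:
    parts = [_PARAMS.format(**vars(spec))]
    parts.append(
        "# Simulate train/test dataset pairs (shared by both methods)\n"
        "[lasso_1, ridge_1]\n"
        "output: sum([[f\"data_{i}.train.txt\", f\"data_{i}.test.txt\"]"
        " for i in range(1, n_dataset + 1)], [])\n"
        "python: expand=True\n" + _simulate_all_script())
    for method in ("lasso", "ridge"):
        parts.append(
            f"# Fit {method} regression on each train/test pair\n"
            f"[{method}_2]\n"
            "input: output_from(1), group_by=2\n"
            f"output: f\"{method}_{{_index + 1}}.coef.txt\","
            f" f\"{method}_{{_index + 1}}.pred.txt\"\n"
            "python: expand=True\n" + _fit_script_fixed(method))
    parts.append(
        "# Evaluate prediction error for every dataset (shared step)\n"
        "[lasso_3, ridge_3]\n"
        "input: output_from(1), output_from(2)\n"
        "output: [f\"{step_name.split('_')[0]}_{i}.mse.txt\""
        " for i in range(1, n_dataset + 1)]\n"
        "python: expand=True\n" + _eval_loop_script())
    parts.append(
        "# Run both regression pipelines\n"
        "[default]\n"
        "sos_run(['lasso', 'ridge'])\n")
    return "\n".join(parts)


def _outcome_style(spec: FixtureSpec) -> str:
    parts = [_PARAMS.format(**vars(spec))]
    parts.append(
        "# Simulate one train/test dataset pair on demand\n"
        "[simulation: provides = ['data_{id}.train.txt', 'data_{id}.test.txt']]\n"
        "python: expand=True\n" + _simulate_one_script())
    parts.append(
        "# Fit either regression method for one dataset\n"
        "[fit: provides = ['{method}_{id}.coef.txt', '{method}_{id}.pred.txt']]\n"
        "input: f\"data_{id}.train.txt\", f\"data_{id}.test.txt\"\n"
        "python: expand=True\n" + _fit_script('"{method}"'))
    parts.append(
        "# Evaluate prediction error for one method/dataset pair\n"
        "[evaluation: provides = '{method}_{id}.mse.txt']\n"
        "input: f\"data_{id}.test.txt\", f\"{method}_{id}.pred.txt\"\n"
        "python: expand=True\n" + _eval_one_script())
    parts.append(
        "# Expected results drive the whole computation backward\n"
        "[default]\n"
        "depends: [f\"{m}_{i}.mse.txt\" for m in ('lasso', 'ridge')"
        " for i in range(1, n_dataset + 1)]\n")
    return "\n".join(parts)


def _mixed_style(spec: FixtureSpec) -> str:
    parts = [_PARAMS.format(**vars(spec))]
    parts.append(
        "# Auxiliary simulate step, matched by wildcard pattern when needed\n"
        "[simulate: provides = ['data_{id}.train.txt', 'data_{id}.test.txt']]\n"
        "python: expand=True\n" + _simulate_one_script())
    parts.append(
        "# Fit each method on every train/test pair (process-oriented trunk)\n"
        "[lasso_1, ridge_1]\n"
        "input: sum([[f\"data_{i}.train.txt\", f\"data_{i}.test.txt\"]"
        " for i in range(1, n_dataset + 1)], []), group_by=2\n"
        "output: f\"{step_name.split('_')[0]}_{_index + 1}.coef.txt\","
        " f\"{step_name.split('_')[0]}_{_index + 1}.pred.txt\"\n"
        "python: expand=True\n"
        + _fit_script('"{step_name}".split("_")[0]'))
    parts.append(
        "# Evaluate prediction error for every dataset\n"
        "[lasso_2, ridge_2]\n"
        "input: output_from(1)\n"
        "output: [f\"{step_name.split('_')[0]}_{i}.mse.txt\""
        " for i in range(1, n_dataset + 1)]\n"
        "python: expand=True\n" + _eval_loop_script())
    parts.append(
        "# Run both regression pipelines\n"
        "[default]\n"
        "sos_run(['lasso', 'ridge'])\n")
    return "\n".join(parts)


def write_regression_fixture(spec: FixtureSpec) -> Path:
    """Emit the regression workflow in the requested style; returns its path."""
    writers = {"process": _process_style, "outcome": _outcome_style,
               "mixed": _mixed_style}
    if spec.style not in writers:
        raise PolyflowError(
            f"unsupported style {spec.style!r} (choose from "
            f"{', '.join(sorted(writers))})")
    outdir = Path(spec.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"regression_{spec.style}.pfw"
    path.write_text(writers[spec.style](spec))
    return path


# ---------------------------------------------------------------------------
# interpreter-free engine-test workflows
# ---------------------------------------------------------------------------

_TEXT_FIXTURES = {
    "chain": """\
# First stage writes the seed line
[chain_1]
output: 'c1.txt'
text_transform:
    write alpha

# Second stage extends it
[chain_2]
output: 'c2.txt'
text_transform:
    suffix beta

# Third stage extends it again
[chain_3]
output: 'c3.txt'
text_transform:
    suffix gamma
""",
    "diamond": """\
[d_1]
output: 'a.txt'
text_transform:
    write root

[d_2]
input: 'a.txt'
output: 'b.txt'
text_transform:
    suffix left

[d_3]
input: 'a.txt'
output: 'c.txt'
text_transform:
    suffix right

[d_4]
input: 'b.txt', 'c.txt'
output: 'd.txt'
concat:
""",
    "grouped": """\
[group_1]
input: 'in_1.txt', 'in_2.txt', 'in_3.txt', 'in_4.txt', group_by=2
output: f"pair_{_index}.txt"
concat:
""",
    "zap": """\
[z_1]
output: 'raw.txt'
text_transform:
    write payload

[z_2]
input: 'raw.txt'
output: 'mid.txt'
text_transform:
    suffix middle

[z_3]
input: 'mid.txt'
output: 'final.txt'
text_transform:
    suffix finished
""",
    "nested": """\
[left_1]
output: 'left.txt'
text_transform:
    write left

[right_1]
output: 'right.txt'
text_transform:
    write right

[default]
sos_run(['left', 'right'])
""",
}


def write_text_fixture(kind: str, outdir: str | Path) -> Path:
    """Emit an interpreter-free workflow exercising one engine feature.

    ``grouped`` also creates its four distinct input files so the pairing
    of substep groups is observable in the outputs.
    """
    if kind not in _TEXT_FIXTURES:
        raise PolyflowError(
            f"unknown fixture kind {kind!r} (choose from "
            f"{', '.join(sorted(_TEXT_FIXTURES))})")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{kind}.pfw"
    path.write_text(_TEXT_FIXTURES[kind])
    if kind == "grouped":
        for i in range(1, 5):
            (outdir / f"in_{i}.txt").write_text(f"content-{i}\n")
    return path
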