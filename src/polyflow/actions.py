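"""Action registry: how embedded scripts are executed.

An *action* names the interpreter for an embedded script (``python:``,
``sh:``, ...).  The registry maps action names to command templates with a
``{script}`` placeholder for the temp file holding the script text; a
configuration file can extend it (``actions: {name: "cmd {script}"}``).

Three interpreter-free built-in actions (``concat``, ``copy``,
``text_transform``) operate on text files directly, so engine behavior can
be exercised without any external interpreter.  ``text_transform`` applies
one directive per script line to the concatenation of the input files and
writes the result to every output file:

======================  ==============================================
directive               effect
======================  ==============================================
``upper`` / ``lower``   case-fold the text
``reverse``             reverse line order
``replace OLD NEW``     replace every occurrence of OLD with NEW
``prefix TEXT``         prepend a line
``suffix TEXT``         append a line
``write TEXT``          append a line (usable with no inputs)
``sleep SECONDS``       pause (for exercising concurrency)
======================  ==============================================
"""

from __future__ import annotations

import shlex
import shutil
import subprocess
import sys
import time
from pathlib import Path

from .errors import ExecutionError

__all__ = ["default_registry", "BUILTIN_ACTIONS", "action_command",
           "run_builtin", "run_interpreter"]

BUILTIN_ACTIONS = ("concat", "copy", "text_transform")


def default_registry() -> dict[str, str]:
    """Built-in interpreter command templates."""
    return {
        "python": f"{sys.executable} {{script}}",
        "sh": "/bin/sh {script}",
        "bash": "bash {script}",
        "rscript": "Rscript {script}",
    }


def action_command(registry: dict[str, str], name: str) -> str:
    if name in BUILTIN_ACTIONS:
        return f"builtin:{name}"
    if name not in registry:
        known = ", ".join(sorted(list(registry) + list(BUILTIN_ACTIONS)))
        raise ExecutionError(
            f"unregistered action '{name}' (registered actions: {known})")
    return registry[name]


def run_builtin(name: str, script_text: str, inputs: list[Path],
                outputs: list[Path]) -> None:
    """Execute an interpreter-free built-in action."""
    if name == "concat":
        data = b"".join(p.read_bytes() for p in inputs)
        if not outputs:
            raise ExecutionError("concat: no output files declared")
        for out in outputs:
            out.parent.mkdir(parents=True, exist_ok=True)
            out.write_bytes(data)
        return
    if name == "copy":
        if len(inputs) != len(outputs):
            raise ExecutionError(
                f"copy: {len(inputs)} inputs but {len(outputs)} outputs")
        for src, dst in zip(inputs, outputs):
            dst.parent.mkdir(parents=True, exist_ok=True)
            dst.write_bytes(src.read_bytes())
        return
    if name == "text_transform":
        text = "".join(p.read_text() for p in inputs)
        for raw in script_text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            op, *args = line.split(None, 1)
            arg = args[0] if args else ""
            if op == "upper":
                text = text.upper()
            elif op == "lower":
                text = text.lower()
            elif op == "reverse":
                text = "\n".join(reversed(text.splitlines())) + ("\n" if text.endswith("\n") else "")
            elif op == "replace":
                try:
                    old, new = arg.split(None, 1)
                except ValueError as exc:
                    raise ExecutionError(
                        f"text_transform: replace needs OLD NEW: {line!r}") from exc
                text = text.replace(old, new)
            elif op == "prefix":
                text = arg + "\n" + text
            elif op in ("suffix", "write"):
                text = text + arg + "\n"
            elif op == "sleep":
                time.sleep(float(arg))
            elif op == "fail":
                raise ExecutionError(f"text_transform: scripted failure: {arg or 'fail'}")
            else:
                raise ExecutionError(f"text_transform: unknown directive {op!r}")
        for out in outputs:
            out.parent.mkdir(parents=True, exist_ok=True)
            out.write_text(text)
        return
    raise ExecutionError(f"unknown built-in action {name!r}")


def run_interpreter(command_template: str, script_text: str, workdir: Path,
                    tmpdir: Path, tag: str, env: dict | None = None,
                    keep_on_failure: bool = True) -> None:
    """Write the script to a temp file and run it through its interpreter.

    The interpreter must resolve on PATH before anything is executed.  The
    temp script is kept under the store on failure for debugging and
    removed on success.
    """
    tmpdir = Path(tmpdir).absolute()
    tmpdir.mkdir(parents=True, exist_ok=True)
    script_path = tmpdir / f"{tag}.script"
    script_path.write_text(script_text)
    argv = shlex.split(command_template.format(script=shlex.quote(str(script_path))))
    exe = argv[0] if argv else ""
    if not shutil.which(exe) and not Path(exe).exists():
        raise ExecutionError(
            f"interpreter '{exe}' not found; action not executed")
    proc = subprocess.run(argv, cwd=str(workdir), capture_output=True,
                          text=True, env=env)
    if proc.returncode != 0:
        detail = (proc.stderr or proc.stdout or "").strip()
        where = f" (script kept at {script_path})" if keep_on_failure else ""
        if not keep_on_failure:
            script_path.unlink(missing_ok=True)
        raise ExecutionError(
            f"action exited with status {proc.returncode}{where}:\n{detail}")
    script_path.unlink(missing_ok=True)
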