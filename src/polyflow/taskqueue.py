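"""Cross-host task execution with path translation and file synchronization.

A *task* is an externalized unit of computation: the expanded scripts of
one substep plus its input and output files.  Hosts are declared in a
YAML configuration::

    hosts:
      cluster:
        kind: mock_remote            # or localhost
        root: /path/to/remote/fs     # the isolated "remote" filesystem
        path_map:
          - /home/me/project = /scratch/me/project
        max_running: 4
        submit_template: "/bin/sh {script}"   # optional scheduler stand-in

Submitting a task to a ``mock_remote`` host copies its inputs to the
prefix-translated locations under the host root (digests verified),
executes the payload with the translated working directory, and copies
the translated outputs back.  The local signature store never references
remote paths: records are written after synchronization, against local
files.  The mock backend stands in for batch schedulers at desk scale; it
preserves the observable contract (translation, sync, status, kill,
concurrency limits) without SSH or a real queue.
"""

from __future__ import annotations

import hashlib
import json
import os
import shlex
import signal
import subprocess
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .actions import BUILTIN_ACTIONS, run_builtin
from .errors import ConfigError, TaskError
from .targets import SignatureStore, file_digest

__all__ = ["HostConfig", "Task", "TaskQueue", "load_host_config", "translate_path"]

STATUSES = ("pending", "submitted", "running", "completed", "failed", "aborted")
_STATUS_ORDER = {s: i for i, s in enumerate(STATUSES)}


@dataclass
class HostConfig:
    """One execution host: localhost or an isolated mock-remote filesystem."""
    name: str
    kind: str = "localhost"
    root: str | None = None
    path_map: list[tuple[str, str]] = field(default_factory=list)
    max_running: int = 4
    submit_template: str | None = None

    def __post_init__(self):
        if self.kind not in ("localhost", "mock_remote"):
            raise ConfigError(f"host '{self.name}': unknown kind {self.kind!r}")
        if self.kind == "mock_remote" and not self.root:
            raise ConfigError(f"host '{self.name}': mock_remote requires a root")
        # longest prefix first so translation is unambiguous
        self.path_map = sorted(
            [(os.path.normpath(a), os.path.normpath(b)) for a, b in self.path_map],
            key=lambda ab: -len(ab[0]))


def load_host_config(yaml_text: str) -> dict[str, HostConfig]:
    """Parse and validate a YAML host-configuration document."""
    try:
        data = yaml.safe_load(yaml_text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid host configuration YAML: {exc}") from exc
    hosts: dict[str, HostConfig] = {}
    for name, raw in (data.get("hosts") or {}).items():
        raw = dict(raw or {})
        path_map: list[tuple[str, str]] = []
        for entry in raw.get("path_map") or []:
            if isinstance(entry, str):
                if "=" not in entry:
                    raise ConfigError(
                        f"host '{name}': path_map entry {entry!r} must be "
                        f"'local = remote'")
                local, remote = (s.strip() for s in entry.split("=", 1))
            elif isinstance(entry, dict) and len(entry) == 1:
                (local, remote), = entry.items()
            else:
                raise ConfigError(f"host '{name}': malformed path_map entry {entry!r}")
            path_map.append((local, remote))
        seen = {}
        for local, _remote in path_map:
            norm = os.path.normpath(local)
            if norm in seen:
                raise ConfigError(
                    f"host '{name}': duplicate path_map prefix {local!r}")
            seen[norm] = True
        hosts[name] = HostConfig(
            name=name, kind=raw.get("kind", "localhost"), root=raw.get("root"),
            path_map=path_map, max_running=int(raw.get("max_running", 4)),
            submit_template=raw.get("submit_template"))
    if "localhost" not in hosts:
        hosts["localhost"] = HostConfig(name="localhost")
    return hosts


def translate_path(path: str, host: HostConfig) -> str:
    """Map a local path to its host counterpart by longest matching prefix."""
    if host.kind == "localhost" and not host.path_map:
        return path
    norm = os.path.normpath(path)
    for local, remote in host.path_map:  # sorted longest-first
        if norm == local or norm.startswith(local + os.sep):
            return remote + norm[len(local):]
    raise TaskError(
        f"path '{path}' matches no path_map prefix of host '{host.name}'")


@dataclass
class Task:
    """An externalized substep: payload plus its file lists."""
    payload: dict  # {"ops": [{"action", "script", "command"}], "workdir": str}
    input_files: list[str] = field(default_factory=list)
    output_files: list[str] = field(default_factory=list)
    translated_inputs: list[str] = field(default_factory=list)
    translated_outputs: list[str] = field(default_factory=list)
    status: str = "pending"
    id: str = ""

    def __post_init__(self):
        if not self.id:
            body = json.dumps(
                {"ops": self.payload.get("ops", []),
                 "inputs": self.input_files, "outputs": self.output_files,
                 "input_digests": self.payload.get("input_digests", [])},
                sort_keys=True)
            self.id = hashlib.sha256(body.encode()).hexdigest()[:16]

    def advance(self, status: str) -> None:
        if _STATUS_ORDER[status] < _STATUS_ORDER[self.status]:
            raise TaskError(
                f"task {self.id}: status may not regress "
                f"({self.status} -> {status})")
        self.status = status


class TaskQueue:
    """Submits tasks to configured hosts and tracks persisted records."""

    def __init__(self, hosts: dict[str, HostConfig], store: SignatureStore):
        self.hosts = hosts
        self.store = store
        self._semaphores: dict[str, threading.BoundedSemaphore] = {}
        self._sem_lock = threading.Lock()

    # -- record persistence ----------------------------------------------
    def _record_path(self, task_id: str) -> Path:
        return self.store.root / "tasks" / f"{task_id}.task"

    def _write_record(self, task: Task, host: str, **extra) -> None:
        path = self._record_path(task.id)
        old = self.read_record(task.id) if path.exists() else {}
        rec = {"id": task.id, "host": host, "status": task.status,
               "inputs": task.input_files, "outputs": task.output_files,
               "created": old.get("created", time.time())}
        rec.update({k: v for k, v in old.items()
                    if k in ("started", "finished", "pid")})
        rec.update(extra)
        tmp = path.with_suffix(".tmp%d" % os.getpid())
        tmp.write_text(json.dumps(rec, indent=1, sort_keys=True))
        os.replace(tmp, path)

    def read_record(self, task_id: str) -> dict:
        path = self._record_path(task_id)
        if not path.exists():
            raise TaskError(f"unknown task id '{task_id}'")
        return json.loads(path.read_text())

    def all_records(self) -> list[dict]:
        out = []
        for path in sorted((self.store.root / "tasks").glob("*.task")):
            out.append(json.loads(path.read_text()))
        return out

    # -- host helpers ----------------------------------------------------
    def host(self, name: str) -> HostConfig:
        if name not in self.hosts:
            raise ConfigError(
                f"unknown host '{name}'; configured hosts: "
                f"{', '.join(sorted(self.hosts))}")
        return self.hosts[name]

    def _semaphore(self, host: HostConfig) -> threading.BoundedSemaphore:
        with self._sem_lock:
            if host.name not in self._semaphores:
                self._semaphores[host.name] = threading.BoundedSemaphore(
                    host.max_running)
            return self._semaphores[host.name]

    # -- the task lifecycle ----------------------------------------------
    def translate(self, task: Task, host: HostConfig) -> Task:
        """Fill in translated paths and re-target the payload workdir."""
        task.translated_inputs = [translate_path(p, host) for p in task.input_files]
        task.translated_outputs = [translate_path(p, host) for p in task.output_files]
        task.payload["remote_workdir"] = translate_path(
            task.payload["workdir"], host)
        return task

    def submit(self, task: Task, host_name: str) -> str:
        """Execute a task on a host; returns the task id.

        Identical completed payloads are recognized by id and returned
        without re-execution.  On failure no partial outputs reach the
        local side.
        """
        host = self.host(host_name)
        try:
            record = self.read_record(task.id)
        except TaskError:
            record = None
        if record is not None and record.get("status") == "completed":
            task.status = "completed"
            return task.id

        for path in task.input_files:
            if not Path(path).is_file():
                raise TaskError(f"task input missing locally: {path}")

        self.translate(task, host)
        task.advance("submitted")
        self._write_record(task, host.name)
        sem = self._semaphore(host)
        with sem:
            task.advance("running")
            self._write_record(task, host.name, started=time.time())
            try:
                if host.kind == "mock_remote":
                    self._run_mock_remote(task, host)
                else:
                    self._run_ops(task, Path(task.payload["workdir"]),
                                  translated=False, host=host)
            except BaseException as exc:
                record = self.read_record(task.id)
                if record.get("status") == "aborted":
                    task.status = "aborted"
                    raise TaskError(f"task {task.id} aborted") from exc
                task.advance("failed")
                self._write_record(task, host.name, finished=time.time(),
                                   error=str(exc))
                raise TaskError(f"task {task.id} failed on host "
                                f"'{host.name}': {exc}") from exc
        task.advance("completed")
        self._write_record(task, host.name, finished=time.time())
        return task.id

    def _run_mock_remote(self, task: Task, host: HostConfig) -> None:
        root = Path(host.root)
        local_root = Path(self.store.workdir).resolve()
        if root.resolve() == local_root or local_root in root.resolve().parents \
                or root.resolve() in (local_root, *local_root.parents):
            raise ConfigError(
                f"host '{host.name}': mock_remote root {root} overlaps the "
                f"local working root {local_root}")
        # 1-2) translate (done) and transfer inputs, digests verified
        for local, remote in zip(task.input_files, task.translated_inputs):
            dst = Path(remote)
            dst.parent.mkdir(parents=True, exist_ok=True)
            dst.write_bytes(Path(local).read_bytes())
            if file_digest(dst) != file_digest(local):
                raise TaskError(f"input transfer verification failed: {local}")
        # 3) execute in the remote root, blind to the local store
        workdir = Path(task.payload["remote_workdir"])
        workdir.mkdir(parents=True, exist_ok=True)
        self._run_ops(task, workdir, translated=True, host=host)
        # 4-5) transfer outputs back, digests verified
        for local, remote in zip(task.output_files, task.translated_outputs):
            src = Path(remote)
            if not src.is_file():
                raise TaskError(f"task did not create remote output: {remote}")
            dst = Path(local)
            dst.parent.mkdir(parents=True, exist_ok=True)
            tmp = dst.with_name(dst.name + ".sync")
            tmp.write_bytes(src.read_bytes())
            if file_digest(tmp) != file_digest(src):
                tmp.unlink(missing_ok=True)
                raise TaskError(f"output transfer verification failed: {remote}")
            os.replace(tmp, dst)

    def _run_ops(self, task: Task, workdir: Path, translated: bool,
                 host: HostConfig) -> None:
        env = {k: v for k, v in os.environ.items()}
        if host.kind == "mock_remote":
            env["POLYFLOW_STORE"] = ""  # remote side must not see the store
        for i, op in enumerate(task.payload.get("ops", [])):
            script = op.get("script_translated" if translated else "script", "")
            name = op["action"]
            if name in BUILTIN_ACTIONS:
                inputs = [Path(p) for p in (task.translated_inputs if translated
                                            else task.input_files)]
                outputs = [Path(p) for p in (task.translated_outputs if translated
                                             else task.output_files)]
                run_builtin(name, script, inputs, outputs)
                continue
            workdir.mkdir(parents=True, exist_ok=True)
            script_path = workdir / f".task_{task.id}_{i}.script"
            script_path.write_text(script)
            command = op["command"].format(script=shlex.quote(str(script_path)))
            if host.submit_template:
                wrapper = workdir / f".task_{task.id}_{i}.submit"
                wrapper.write_text("#!/bin/sh\n" + command + "\n")
                command = host.submit_template.format(
                    script=shlex.quote(str(wrapper)))
            proc = subprocess.Popen(
                shlex.split(command), cwd=str(workdir), env=env,
                stdout=subprocess.PIPE, stderr=subprocess.PIPE, text=True)
            self._write_record(task, host.name, pid=proc.pid)
            out, err = proc.communicate()
            script_path.unlink(missing_ok=True)
            if proc.returncode != 0:
                record = self.read_record(task.id)
                if record.get("status") == "aborted":
                    raise TaskError(f"task {task.id} aborted")
                raise TaskError(
                    f"op {i} ({name}) exited {proc.returncode}: "
                    f"{(err or out).strip()}")

    # -- management ------------------------------------------------------
    def task_status(self, task_id: str | None = None,
                    host: str | None = None) -> list[dict]:
        """Status listing for one task or all tasks (optionally per host)."""
        if task_id is not None:
            return [self.read_record(task_id)]
        records = self.all_records()
        if host is not None:
            records = [r for r in records if r.get("host") == host]
        return records

    def kill(self, task_id: str) -> dict:
        """Terminate a pending/running task; its status becomes aborted."""
        record = self.read_record(task_id)
        if record["status"] in ("completed", "failed", "aborted"):
            raise TaskError(
                f"task {task_id} is already {record['status']}")
        pid = record.get("pid")
        record["status"] = "aborted"
        record["finished"] = time.time()
        path = self._record_path(task_id)
        path.write_text(json.dumps(record, indent=1, sort_keys=True))
        if pid:
            try:
                os.kill(int(pid), signal.SIGTERM)
            except ProcessLookupError:
                pass
        return record
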