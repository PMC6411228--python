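"""Host configuration, path translation, mock-remote submission, management."""

import sys
import threading
import time

import pytest
import yaml

from polyflow import (ConfigError, TaskError, parse_script, run)
from polyflow.targets import SignatureStore
from polyflow.taskqueue import (HostConfig, Task, TaskQueue, load_host_config,
                                translate_path)


def _hosts(tmp_path, max_running=4):
    remote = tmp_path / "remote_fs"
    local = tmp_path / "wd"
    local.mkdir(exist_ok=True)
    text = yaml.safe_dump({"hosts": {
        "mock": {"kind": "mock_remote", "root": str(remote),
                 "path_map": [f"{local} = {remote}/wd"],
                 "max_running": max_running},
    }})
    return load_host_config(text), local, remote


# ---------------------------------------------------------------------------
# configuration and translation
# ---------------------------------------------------------------------------

def test_localhost_only_config_identity():
    hosts = load_host_config("hosts:\n  localhost:\n    kind: localhost\n")
    assert hosts["localhost"].kind == "localhost"
    assert translate_path("/any/where.txt", hosts["localhost"]) == "/any/where.txt"


def test_mock_host_map_parsed(tmp_path):
    hosts, local, remote = _hosts(tmp_path)
    assert hosts["mock"].kind == "mock_remote"
    assert hosts["mock"].path_map == [(str(local), f"{remote}/wd")]


def test_malformed_config_errors(tmp_path):
    with pytest.raises(ConfigError, match="local = remote"):
        load_host_config("hosts:\n  h:\n    path_map: ['noequals']\n")
    with pytest.raises(ConfigError, match="unknown kind"):
        load_host_config("hosts:\n  h:\n    kind: teleport\n")
    with pytest.raises(ConfigError, match="requires a root"):
        load_host_config("hosts:\n  h:\n    kind: mock_remote\n")
    with pytest.raises(ConfigError, match="duplicate"):
        load_host_config(
            "hosts:\n  h:\n    path_map: ['/a = /x', '/a = /y']\n")


@pytest.mark.parametrize("path,expected", [
    ("/home/u/proj/a.txt", "/remote/proj/a.txt"),  # longest prefix wins
    ("/home/u/proj/deep/b.txt", "/remote/proj/deep/b.txt"),  # longest prefix
    ("/home/u", "/scratch/u"),
])
def test_longest_prefix_translation(path, expected):
    host = HostConfig(name="h", kind="localhost", path_map=[
        ("/home/u", "/scratch/u"), ("/home/u/proj", "/remote/proj")])
    # oracle: plain string prefix substitution with the longest local prefix
    assert translate_path(path, host) == expected


def test_unmapped_path_errors():
    host = HostConfig(name="h", kind="localhost", path_map=[("/home/u", "/s")])
    with pytest.raises(TaskError, match="/tmp/x"):
        translate_path("/tmp/x", host)


# ---------------------------------------------------------------------------
# submission
# ---------------------------------------------------------------------------

def _python_op(code):
    return {"action": "python", "script": code, "script_translated": code,
            "command": f"{sys.executable} {{script}}"}


def _make_task(local, code, inputs=(), outputs=()):
    return Task(payload={"ops": [_python_op(code)], "workdir": str(local)},
                input_files=[str(local / p) for p in inputs],
                output_files=[str(local / p) for p in outputs])


def test_mock_submit_matches_local_execution(tmp_path):
    hosts, local, remote = _hosts(tmp_path)
    (local / "in.txt").write_text("payload\n")
    code = ("data = open('in.txt').read()\n"
            "open('out.txt', 'w').write(data.upper())\n")
    queue = TaskQueue(hosts, SignatureStore(local))
    task = _make_task(local, code, ["in.txt"], ["out.txt"])
    queue.submit(task, "mock")
    assert task.status == "completed"
    mock_result = (local / "out.txt").read_bytes()
    # oracle: run the identical payload purely locally
    other = tmp_path / "pure_local"
    other.mkdir()
    (other / "in.txt").write_text("payload\n")
    local_task = _make_task(other, code, ["in.txt"], ["out.txt"])
    TaskQueue(hosts, SignatureStore(other)).submit(local_task, "localhost")
    assert (other / "out.txt").read_bytes() == mock_result == b"PAYLOAD\n"
    # remote side holds translated copies; local records stay local
    assert (remote / "wd" / "out.txt").exists()


def test_resubmission_of_completed_task_skips(tmp_path):
    hosts, local, _ = _hosts(tmp_path)
    (local / "in.txt").write_text("x")
    code = ("import time\nopen('stamp.txt', 'w').write(str(time.time()))\n")
    queue = TaskQueue(hosts, SignatureStore(local))
    first = _make_task(local, code, ["in.txt"], ["stamp.txt"])
    queue.submit(first, "mock")
    stamp = (local / "stamp.txt").read_text()
    second = _make_task(local, code, ["in.txt"], ["stamp.txt"])
    assert second.id == first.id  # identical payload, stable id
    queue.submit(second, "mock")
    assert second.status == "completed"
    assert (local / "stamp.txt").read_text() == stamp  # not re-run


def test_two_hosts_simultaneously(tmp_path):
    hosts, local, remote = _hosts(tmp_path)
    hosts["mock2"] = HostConfig(
        name="mock2", kind="mock_remote", root=str(tmp_path / "remote2"),
        path_map=[(str(local), str(tmp_path / "remote2" / "wd"))])
    queue = TaskQueue(hosts, SignatureStore(local))
    tasks = [_make_task(local, f"open('h{i}.txt', 'w').write('{i}')\n",
                        outputs=[f"h{i}.txt"]) for i in (1, 2)]
    threads = [threading.Thread(target=queue.submit, args=(t, h))
               for t, h in zip(tasks, ("mock", "mock2"))]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    assert [t.status for t in tasks] == ["completed", "completed"]
    assert (local / "h1.txt").exists() and (local / "h2.txt").exists()


def test_failed_task_leaves_no_partial_local_outputs(tmp_path):
    hosts, local, _ = _hosts(tmp_path)
    code = "open('part.txt', 'w').write('partial')\nraise SystemExit(3)\n"
    queue = TaskQueue(hosts, SignatureStore(local))
    task = _make_task(local, code, outputs=["part.txt"])
    with pytest.raises(TaskError):
        queue.submit(task, "mock")
    assert task.status == "failed"
    assert not (local / "part.txt").exists()


# ---------------------------------------------------------------------------
# status / kill / concurrency limit
# ---------------------------------------------------------------------------

def test_status_and_unknown_id(tmp_path):
    hosts, local, _ = _hosts(tmp_path)
    queue = TaskQueue(hosts, SignatureStore(local))
    assert queue.task_status() == []
    with pytest.raises(TaskError, match="unknown task id"):
        queue.task_status("feedbead00000000")
    task = _make_task(local, "pass\n")
    queue.submit(task, "localhost")
    rows = queue.task_status()
    assert len(rows) == 1 and rows[0]["status"] == "completed"


def test_kill_long_running_task(tmp_path):
    hosts, local, _ = _hosts(tmp_path)
    queue = TaskQueue(hosts, SignatureStore(local))
    code = "import time\ntime.sleep(30)\nopen('late.txt', 'w').write('x')\n"
    task = _make_task(local, code, outputs=["late.txt"])
    worker = threading.Thread(target=lambda: _swallow(queue, task))
    worker.start()
    deadline = time.monotonic() + 10
    while time.monotonic() < deadline:
        try:
            if queue.read_record(task.id).get("pid"):
                break
        except TaskError:
            pass
        time.sleep(0.05)
    record = queue.kill(task.id)
    worker.join(timeout=10)
    assert record["status"] == "aborted"
    assert queue.read_record(task.id)["status"] == "aborted"
    assert not (local / "late.txt").exists()


def _swallow(queue, task):
    try:
        queue.submit(task, "mock")
    except TaskError:
        pass


def test_max_running_never_exceeded(tmp_path):
    hosts, local, remote = _hosts(tmp_path, max_running=2)
    queue = TaskQueue(hosts, SignatureStore(local))
    code = ("import time\n"
            "open('t_TAG.start', 'w').write(str(time.time()))\n"
            "time.sleep(0.25)\n"
            "open('t_TAG.end', 'w').write(str(time.time()))\n"
            "open('out_TAG.txt', 'w').write('done')\n")
    tasks = [_make_task(local, code.replace("TAG", str(i)),
                        outputs=[f"out_{i}.txt"]) for i in range(6)]
    threads = [threading.Thread(target=queue.submit, args=(t, "mock"))
               for t in tasks]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    intervals = []
    for i in range(6):
        # timing marks are written remote-side with relative paths
        start = float((remote / "wd" / f"t_{i}.start").read_text())
        end = float((remote / "wd" / f"t_{i}.end").read_text())
        intervals.append((start, end))
    for start, _end in intervals:
        overlap = sum(1 for s, e in intervals if s <= start < e)
        assert overlap <= 2
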