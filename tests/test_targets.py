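"""Checksums, signature records, zap placeholders, wildcard matching."""

import hashlib
import os
import random

import pytest

from polyflow import (SignatureRecord, Target, TargetError, ZapPlaceholder,
                      file_digest, match_pattern, substitute_pattern,
                      target_satisfied, zap_files)
from polyflow.targets import SignatureStore, check_skip, pattern_placeholders

from _oracles import brute_force_match, random_pattern_and_path


@pytest.fixture
def store(tmp_path):
    return SignatureStore(tmp_path)


# ---------------------------------------------------------------------------
# digests
# ---------------------------------------------------------------------------

def test_empty_file_digest_is_algorithm_constant(tmp_path):
    f = tmp_path / "empty"
    f.write_bytes(b"")
    assert file_digest(f) == hashlib.sha256(b"").hexdigest()


def test_digest_ignores_timestamps(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    a.write_bytes(b"same bytes")
    b.write_bytes(b"same bytes")
    os.utime(a, (1_000_000_000, 1_000_000_000))
    os.utime(b, (2_000_000_000, 2_000_000_000))
    assert file_digest(a) == file_digest(b)


def test_one_byte_difference_changes_digest(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    a.write_bytes(b"same bytes")
    b.write_bytes(b"same bytez")
    assert file_digest(a) != file_digest(b)


def test_digest_missing_file_errors(tmp_path):
    with pytest.raises(TargetError, match="missing"):
        file_digest(tmp_path / "nope")


# ---------------------------------------------------------------------------
# satisfaction and zap
# ---------------------------------------------------------------------------

def test_target_satisfaction_cases(store, tmp_path):
    f = tmp_path / "x.txt"
    assert not target_satisfied(Target.file("x.txt"), store)
    f.write_text("hello")
    assert target_satisfied(Target.file("x.txt"), store)
    # zapped file still satisfies after deletion
    ZapPlaceholder(str(f), file_digest(f), 5).write()
    f.unlink()
    assert target_satisfied(Target.file("x.txt"), store)
    assert not target_satisfied(Target.step("sim_1"), store)
    store.mark_step_done("sim_1", "abc", ["x.txt"])
    assert target_satisfied(Target.step("sim_1"), store)


def test_zap_untracked_or_missing_errors(store, tmp_path):
    (tmp_path / "loose.txt").write_text("data")
    with pytest.raises(TargetError, match="untracked"):
        zap_files(["loose.txt"], store)
    assert (tmp_path / "loose.txt").exists()  # nothing deleted
    with pytest.raises(TargetError, match="missing"):
        zap_files(["ghost.txt"], store)


def test_zap_conserves_digest_and_size(store, tmp_path):
    f = tmp_path / "big.txt"
    f.write_bytes(b"intermediate contents\n" * 10)
    digest, size = file_digest(f), f.stat().st_size
    record = SignatureRecord("stepdigest", 0,
                             output_digests=[("big.txt", digest, size)])
    store.save_record(record)
    placeholders = zap_files(["big.txt"], store)
    assert not f.exists()
    zap = ZapPlaceholder.read(f)
    assert zap.digest == digest and zap.size == size
    assert placeholders[0].digest == digest
    assert target_satisfied(Target.file("big.txt"), store)


# ---------------------------------------------------------------------------
# signature records and skip decisions
# ---------------------------------------------------------------------------

def test_record_roundtrip(store):
    rec = SignatureRecord(
        "d" * 64, 3,
        input_digests=[("in with space.txt", "aa", 10)],
        output_digests=[("out.txt", "bb", 20)],
        depends_digests=[("dep.txt", "cc", 30)])
    again = SignatureRecord.decode(rec.encode())
    assert again == rec
    store.save_record(rec)
    assert store.load_record("d" * 64, 3, rec.input_key) == rec


def test_record_refuses_other_algorithm():
    text = "polyflow-signature 1 md5\nstep x\nsubstep 0\n"
    with pytest.raises(TargetError, match="refuses to mix"):
        SignatureRecord.decode(text)


def test_check_skip_lifecycle(store, tmp_path):
    (tmp_path / "in.txt").write_text("input")
    (tmp_path / "out.txt").write_text("output")
    args = dict(inputs=["in.txt"], outputs=["out.txt"], depends=[])
    assert not check_skip(store, "digest1", 0, **args)  # empty store: run
    rec = SignatureRecord(
        "digest1", 0,
        input_digests=[("in.txt", file_digest(tmp_path / "in.txt"), 5)],
        output_digests=[("out.txt", file_digest(tmp_path / "out.txt"), 6)])
    store.save_record(rec)
    assert check_skip(store, "digest1", 0, **args)
    # changed input content invalidates
    (tmp_path / "in.txt").write_text("different")
    assert not check_skip(store, "digest1", 0, **args)
    (tmp_path / "in.txt").write_text("input")
    # missing output invalidates, zapped output still satisfies
    digest = file_digest(tmp_path / "out.txt")
    ZapPlaceholder(str(tmp_path / "out.txt"), digest, 6).write()
    (tmp_path / "out.txt").unlink()
    assert check_skip(store, "digest1", 0, **args)
    assert not check_skip(store, "digest1", 0, require_output_content=True, **args)


# ---------------------------------------------------------------------------
# wildcard patterns
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pattern,path,expected", [
    ("data_{id}.out", "data_3.out", {"id": "3"}),
    ("data_{id}.out", "other.txt", None),
    ("a_{x}_{y}.txt", "a_1_2_3.txt", {"x": "1", "y": "2_3"}),
    ("{m}_{i}.mse.txt", "lasso_2.mse.txt", {"m": "lasso", "i": "2"}),
    ("d/{name}.csv", "d/x.csv", {"name": "x"}),
    ("d/{name}.csv", "d/sub/x.csv", None),  # no separator inside a hole
    ("literal.txt", "literal.txt", {}),
])
def test_match_pattern(pattern, path, expected):
    assert match_pattern(pattern, path) == expected


def test_duplicate_placeholder_rejected():
    with pytest.raises(TargetError, match="duplicate"):
        pattern_placeholders("{x}_{x}.txt")
    with pytest.raises(TargetError, match="duplicate"):
        match_pattern("{x}_{x}.txt", "a_b.txt")


def test_match_agrees_with_enumeration_oracle():
    rng = random.Random(42)
    checked = 0
    for _ in range(300):
        pattern, path = random_pattern_and_path(rng)
        got = match_pattern(pattern, path)
        want = brute_force_match(pattern, path)
        assert got == want, (pattern, path)
        if got is not None:
            # substitution inverse: binding reproduces the matched path
            assert substitute_pattern(pattern, got) == path
            checked += 1
    assert checked > 50
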