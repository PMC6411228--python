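"""Dependency targets, checksums, runtime signatures, and zap placeholders.

The engine decides whether work can be skipped by comparing *runtime
signatures*: content checksums over a step's canonical source, its
interpolated scripts, the parameter values it uses, and the digests of its
input, output, and dependency files.  Signatures are keyed independently
of workflow names and file timestamps, so a step completed under one
workflow is recognized as complete by any other workflow with the same
content.

Large intermediate files can be *zapped*: the file content is deleted and
replaced by a sidecar ``<path>.zapped`` record carrying the digest and
size.  A zapped file still satisfies existence checks; a step that needs
its actual bytes triggers regeneration (see the executor).
"""

from __future__ import annotations

import hashlib
import os
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import TargetError

__all__ = [
    "Target", "SignatureRecord", "SignatureStore", "ZapPlaceholder",
    "PatternBinding", "file_digest", "text_digest", "target_satisfied",
    "zap_files", "match_pattern", "pattern_placeholders", "substitute_pattern",
]

HASH_ALGORITHM = "sha256"
STORE_DIRNAME = ".polyflow"
ENGINE_VERSION = "polyflow/0.1.0"

_PLACEHOLDER_RE = re.compile(r"\{([A-Za-z_]\w*)\}")


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

def _normalize_path(key: str) -> str:
    return os.path.normpath(str(key)).replace(os.sep, "/")


@dataclass(frozen=True)
class Target:
    """A dependency unit: a file path, a step reference, or a named output."""
    kind: str  # file | step_ref | named_output
    key: str

    def __post_init__(self):
        if self.kind not in ("file", "step_ref", "named_output"):
            raise TargetError(f"unknown target kind {self.kind!r}")
        if self.kind == "file":
            object.__setattr__(self, "key", _normalize_path(self.key))

    @classmethod
    def file(cls, path: str) -> "Target":
        return cls("file", path)

    @classmethod
    def step(cls, name: str) -> "Target":
        return cls("step_ref", name)

    @classmethod
    def named(cls, label: str) -> "Target":
        return cls("named_output", label)


# ---------------------------------------------------------------------------
# checksums
# ---------------------------------------------------------------------------

def file_digest(path: str | Path, algorithm: str = HASH_ALGORITHM) -> str:
    """Checksum of a file's byte content (timestamp-independent)."""
    p = Path(path)
    if not p.is_file():
        raise TargetError(f"cannot digest missing file: {p}")
    h = hashlib.new(algorithm)
    with open(p, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def text_digest(text: str, algorithm: str = HASH_ALGORITHM) -> str:
    return hashlib.new(algorithm, text.encode("utf-8")).hexdigest()


# ---------------------------------------------------------------------------
# zap placeholders
# ---------------------------------------------------------------------------

@dataclass
class ZapPlaceholder:
    """Sidecar record standing in for a deleted intermediate file."""
    original_path: str
    digest: str
    size: int

    @staticmethod
    def sidecar_path(path: str | Path) -> Path:
        return Path(str(path) + ".zapped")

    def write(self) -> Path:
        sidecar = self.sidecar_path(self.original_path)
        sidecar.write_text(
            f"polyflow-zap 1 {HASH_ALGORITHM}\n"
            f"digest {self.digest}\n"
            f"size {self.size}\n"
            f"path {self.original_path}\n")
        return sidecar

    @classmethod
    def read(cls, path: str | Path) -> "ZapPlaceholder | None":
        sidecar = cls.sidecar_path(path)
        if not sidecar.is_file():
            return None
        fields = {}
        lines = sidecar.read_text().splitlines()
        if not lines or not lines[0].startswith("polyflow-zap "):
            return None
        for line in lines[1:]:
            key, _, value = line.partition(" ")
            fields[key] = value
        return cls(original_path=fields.get("path", str(path)),
                   digest=fields.get("digest", ""),
                   size=int(fields.get("size", 0)))


# ---------------------------------------------------------------------------
# signature records and the on-disk store
# ---------------------------------------------------------------------------

@dataclass
class SignatureRecord:
    """One completed substep: content digest plus per-target digests.

    Keyed by ``(step_content_digest, substep_index, input-digest key)``;
    deliberately independent of workflow names and timestamps.
    """
    step_content_digest: str
    substep_index: int
    input_digests: list[tuple[str, str, int]] = field(default_factory=list)
    output_digests: list[tuple[str, str, int]] = field(default_factory=list)
    depends_digests: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def input_key(self) -> str:
        joined = ";".join(f"{p}={d}" for p, d, _s in sorted(self.input_digests))
        return text_digest(joined)

    def encode(self) -> str:
        lines = [f"polyflow-signature 1 {HASH_ALGORITHM}",
                 f"step {self.step_content_digest}",
                 f"substep {self.substep_index}",
                 f"inkey {self.input_key}"]
        for kind, rows in (("input", self.input_digests),
                           ("output", self.output_digests),
                           ("depends", self.depends_digests)):
            for path, digest, size in rows:
                lines.append(f"{kind} {digest} {size} {path}")
        return "\n".join(lines) + "\n"

    @classmethod
    def decode(cls, text: str) -> "SignatureRecord":
        lines = text.splitlines()
        if not lines or not lines[0].startswith("polyflow-signature 1 "):
            raise TargetError("unrecognized signature record format")
        algo = lines[0].split()[2]
        if algo != HASH_ALGORITHM:
            raise TargetError(
                f"signature store uses digest algorithm {algo!r}; this engine "
                f"is configured for {HASH_ALGORITHM!r} and refuses to mix them")
        rec = cls(step_content_digest="", substep_index=0)
        for line in lines[1:]:
            if not line.strip():
                continue
            key, _, rest = line.partition(" ")
            if key == "step":
                rec.step_content_digest = rest.strip()
            elif key == "substep":
                rec.substep_index = int(rest)
            elif key == "inkey":
                pass  # derived
            elif key in ("input", "output", "depends"):
                digest, size, path = rest.split(" ", 2)
                getattr(rec, f"{key}_digests").append((path, digest, int(size)))
            else:
                raise TargetError(f"unrecognized signature field {key!r}")
        if not rec.step_content_digest:
            raise TargetError("signature record missing step digest")
        return rec


class SignatureStore:
    """Content-addressed store under ``<workdir>/.polyflow/``.

    Holds signature records (one line-oriented text file per substep),
    step/named-output completion markers, locks, task records, and
    temporary script files.
    """

    def __init__(self, workdir: str | Path):
        self.workdir = Path(os.path.abspath(workdir))
        self.root = self.workdir / STORE_DIRNAME
        for sub in ("signatures", "steps", "named", "locks", "tasks", "tmp"):
            (self.root / sub).mkdir(parents=True, exist_ok=True)
        meta = self.root / "meta"
        if meta.exists():
            recorded = dict(
                line.split(" ", 1) for line in meta.read_text().splitlines() if " " in line)
            if recorded.get("algorithm") != HASH_ALGORITHM:
                raise TargetError(
                    f"store at {self.root} uses digest algorithm "
                    f"{recorded.get('algorithm')!r}; refusing to mix algorithms")
        else:
            meta.write_text(f"engine {ENGINE_VERSION}\nalgorithm {HASH_ALGORITHM}\n")

    # -- path helpers ----------------------------------------------------
    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.workdir / p

    def _sig_path(self, step_digest: str, substep: int, input_key: str) -> Path:
        return self.root / "signatures" / f"{step_digest}.{substep}.{input_key[:16]}.sig"

    # -- signature records ----------------------------------------------
    def save_record(self, record: SignatureRecord) -> Path:
        path = self._sig_path(record.step_content_digest, record.substep_index,
                              record.input_key)
        tmp = path.with_suffix(".tmp%d" % os.getpid())
        tmp.write_text(record.encode())
        os.replace(tmp, path)
        return path

    def load_record(self, step_digest: str, substep: int,
                    input_key: str) -> SignatureRecord | None:
        path = self._sig_path(step_digest, substep, input_key)
        if not path.is_file():
            return None
        return SignatureRecord.decode(path.read_text())

    def iter_records(self) -> Iterable[SignatureRecord]:
        for path in sorted((self.root / "signatures").glob("*.sig")):
            yield SignatureRecord.decode(path.read_text())

    def invalidate_records_for_output(self, path: str) -> int:
        """Drop records listing ``path`` among their outputs; return count."""
        norm = _normalize_path(path)
        dropped = 0
        for sig in sorted((self.root / "signatures").glob("*.sig")):
            rec = SignatureRecord.decode(sig.read_text())
            if any(_normalize_path(p) == norm for p, _d, _s in rec.output_digests):
                sig.unlink()
                dropped += 1
        return dropped

    def record_producing(self, path: str) -> SignatureRecord | None:
        norm = _normalize_path(path)
        for rec in self.iter_records():
            if any(_normalize_path(p) == norm for p, _d, _s in rec.output_digests):
                return rec
        return None

    # -- step / named-output completion markers --------------------------
    def mark_step_done(self, step_name: str, content_digest: str,
                       outputs: list[str]) -> None:
        path = self.root / "steps" / f"{step_name}.done"
        lines = [f"digest {content_digest}"] + [f"output {p}" for p in outputs]
        path.write_text("\n".join(lines) + "\n")

    def step_done(self, step_name: str) -> bool:
        return (self.root / "steps" / f"{step_name}.done").is_file()

    def step_outputs(self, step_name: str) -> list[str] | None:
        path = self.root / "steps" / f"{step_name}.done"
        if not path.is_file():
            return None
        return [l.split(" ", 1)[1] for l in path.read_text().splitlines()
                if l.startswith("output ")]

    def save_named_output(self, label: str, paths: list[str],
                          producer: str) -> None:
        path = self.root / "named" / f"{label}.out"
        lines = [f"producer {producer}"] + [f"output {p}" for p in paths]
        path.write_text("\n".join(lines) + "\n")

    def named_output(self, label: str) -> list[str] | None:
        path = self.root / "named" / f"{label}.out"
        if not path.is_file():
            return None
        return [l.split(" ", 1)[1] for l in path.read_text().splitlines()
                if l.startswith("output ")]

    def named_output_producer(self, label: str) -> str | None:
        path = self.root / "named" / f"{label}.out"
        if not path.is_file():
            return None
        for l in path.read_text().splitlines():
            if l.startswith("producer "):
                return l.split(" ", 1)[1]
        return None

    # -- locks -----------------------------------------------------------
    def lock_path(self, key: str) -> Path:
        return self.root / "locks" / f"{key}.lock"


# ---------------------------------------------------------------------------
# satisfaction and skip checks
# ---------------------------------------------------------------------------

def target_satisfied(target: Target, store: SignatureStore) -> bool:
    """Is a dependency target already met?

    A file target is met when the file exists *or* a zap placeholder
    stands in for it; a step reference or named output is met when the
    referenced step has completed (valid marker in the store).
    """
    if target.kind == "file":
        path = store.resolve(target.key)
        return path.exists() or ZapPlaceholder.read(path) is not None
    if target.kind == "step_ref":
        return store.step_done(target.key)
    return store.named_output(target.key) is not None


def _current_digest(store: SignatureStore, path: str,
                    require_content: bool = False) -> tuple[str, int] | None:
    """Digest/size of a file, honoring zap placeholders unless content is
    required.  None when neither file nor placeholder exists."""
    resolved = store.resolve(path)
    if resolved.is_file():
        return file_digest(resolved), resolved.stat().st_size
    if not require_content:
        zap = ZapPlaceholder.read(resolved)
        if zap is not None:
            return zap.digest, zap.size
    return None


def check_skip(store: SignatureStore, step_digest: str, substep_index: int,
               inputs: list[str], outputs: list[str], depends: list[str],
               require_output_content: bool = False) -> bool:
    """Skip iff a matching signature exists and every target still checks out.

    The record must match the step content digest, the substep index, and
    the digests of all current inputs; outputs must exist (or be zapped,
    unless ``require_output_content``) with their recorded digests; depends
    targets must still match.
    """
    current_inputs: list[tuple[str, str, int]] = []
    for path in inputs:
        got = _current_digest(store, path)
        if got is None:
            return False
        current_inputs.append((path, got[0], got[1]))
    probe = SignatureRecord(step_digest, substep_index, input_digests=current_inputs)
    record = store.load_record(step_digest, substep_index, probe.input_key)
    if record is None:
        return False
    recorded_in = {p: d for p, d, _s in record.input_digests}
    for path, digest, _size in current_inputs:
        if recorded_in.get(path) != digest:
            return False
    recorded_out = {p: (d, s) for p, d, s in record.output_digests}
    for path in outputs:
        if path not in recorded_out:
            return False
        got = _current_digest(store, path, require_content=require_output_content)
        if got is None or got[0] != recorded_out[path][0]:
            return False
    recorded_dep = {p: d for p, d, _s in record.depends_digests}
    for path in depends:
        got = _current_digest(store, path)
        if got is None:
            return False
        if path in recorded_dep and recorded_dep[path] != got[0]:
            return False
    return True


# ---------------------------------------------------------------------------
# zap
# ---------------------------------------------------------------------------

def zap_files(paths: Iterable[str], store: SignatureStore) -> list[ZapPlaceholder]:
    """Replace tracked intermediate files with digest placeholders.

    Every path must exist and be recorded as an output of some signature
    record; otherwise nothing is deleted and an error is raised.
    """
    paths = [str(p) for p in paths]
    planned: list[tuple[Path, ZapPlaceholder]] = []
    for path in paths:
        resolved = store.resolve(path)
        if not resolved.is_file():
            raise TargetError(f"cannot zap missing file: {path}")
        if store.record_producing(path) is None:
            raise TargetError(
                f"cannot zap untracked file (no signature record lists it as "
                f"an output): {path}")
        planned.append((resolved, ZapPlaceholder(
            original_path=str(resolved), digest=file_digest(resolved),
            size=resolved.stat().st_size)))
    placeholders = []
    for resolved, zap in planned:
        zap.write()
        resolved.unlink()
        placeholders.append(zap)
    return placeholders


# ---------------------------------------------------------------------------
# wildcard pattern matching
# ---------------------------------------------------------------------------

def pattern_placeholders(pattern: str) -> list[str]:
    names = _PLACEHOLDER_RE.findall(pattern)
    if len(names) != len(set(names)):
        raise TargetError(
            f"duplicate placeholder names in pattern {pattern!r}")
    return names


def match_pattern(pattern: str, path: str) -> dict[str, str] | None:
    """Match a ``{name}``-wildcard pattern against a path.

    Placeholders match nonempty substrings without the path separator.
    Among consistent matches the leftmost placeholder takes the shortest
    substring, ties resolved left to right (i.e. non-greedy from the
    left).  Returns the placeholder binding, or None.
    """
    names = pattern_placeholders(pattern)
    regex_parts: list[str] = []
    pos = 0
    for m in _PLACEHOLDER_RE.finditer(pattern):
        regex_parts.append(re.escape(pattern[pos:m.start()]))
        regex_parts.append(f"(?P<{m.group(1)}>[^/]+?)")
        pos = m.end()
    regex_parts.append(re.escape(pattern[pos:]))
    m = re.fullmatch("".join(regex_parts), path)
    if m is None:
        return None
    return {name: m.group(name) for name in names}


def substitute_pattern(pattern: str, binding: dict[str, str]) -> str:
    """Substitute a binding back into a pattern (inverse of match)."""
    def repl(m: re.Match) -> str:
        name = m.group(1)
        if name not in binding:
            raise TargetError(f"binding lacks placeholder {name!r}")
        return binding[name]
    return _PLACEHOLDER_RE.sub(repl, pattern)


@dataclass
class PatternBinding:
    """A matched wildcard pattern with its placeholder values."""
    pattern: str
    values: dict[str, str]

    def path(self) -> str:
        return substitute_pattern(self.pattern, self.values)
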