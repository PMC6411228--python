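"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check.
"""

from __future__ import annotations

import random
import re
import string


def brute_force_match(pattern: str, path: str) -> dict[str, str] | None:
    """Enumerate every placeholder split; pick the match in which the
    leftmost placeholder takes the shortest substring (ties left to right).

    Placeholders must match nonempty substrings without '/'.
    """
    parts = re.split(r"\{([A-Za-z_]\w*)\}", pattern)
    literals = parts[0::2]
    names = parts[1::2]
    solutions: list[tuple[tuple[int, ...], dict[str, str]]] = []

    def recurse(pos: int, i: int, binding: dict[str, str]):
        lit = literals[i]
        if not path.startswith(lit, pos):
            return
        pos += len(lit)
        if i == len(names):
            if pos == len(path):
                solutions.append(
                    (tuple(len(binding[n]) for n in names), dict(binding)))
            return
        for end in range(pos + 1, len(path) + 1):
            piece = path[pos:end]
            if "/" in piece:
                break
            binding[names[i]] = piece
            recurse(end, i + 1, binding)
        binding.pop(names[i], None)

    recurse(0, 0, {})
    if not solutions:
        return None
    return min(solutions)[1]


def random_pattern_and_path(rng: random.Random) -> tuple[str, str]:
    """A random wildcard pattern and a path that may or may not match it."""
    alphabet = string.ascii_lowercase + string.digits
    n_holes = rng.randint(1, 3)
    pieces = []
    for i in range(n_holes + 1):
        pieces.append("".join(rng.choice(alphabet + "_.")
                              for _ in range(rng.randint(0, 4))))
    names = [f"v{i}" for i in range(n_holes)]
    pattern = pieces[0]
    for name, lit in zip(names, pieces[1:]):
        pattern += "{" + name + "}" + lit
    if rng.random() < 0.6:
        # build a path by substituting random values (usually matches)
        path = pieces[0]
        for lit in pieces[1:]:
            value = "".join(rng.choice(alphabet + "_.")
                            for _ in range(rng.randint(1, 5)))
            path += value + lit
    else:
        path = "".join(rng.choice(alphabet + "_./")
                       for _ in range(rng.randint(0, 12)))
    return pattern, path
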