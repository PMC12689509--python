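"""Base-pair set utilities shared across modules.

A structure is a set of pairs ``(i, j)`` with ``i < j`` in 0-based
coordinates, each position in at most one pair.  Dot-bracket strings use
``(``/``)`` and ``.`` only; crossing (pseudoknotted) pair sets cannot be
written as dot-bracket and must be resolved first.
"""

from __future__ import annotations

from typing import Callable, Collection, Iterable


PairSet = frozenset


def base_pair_distance(pairs_a: Collection[tuple], pairs_b: Collection[tuple]) -> int:
    """Number of base pairs present in exactly one of the two structures."""
    return len(set(pairs_a) ^ set(pairs_b))


def pairs_cross(p: tuple, q: tuple) -> bool:
    (i, j), (k, l) = sorted((tuple(p), tuple(q)))
    return i < k < j < l


def find_crossings(pairs: Iterable[tuple]) -> list[tuple]:
    ps = sorted(tuple(p) for p in pairs)
    out = []
    for a in range(len(ps)):
        for b in range(a + 1, len(ps)):
            if pairs_cross(ps[a], ps[b]):
                out.append((ps[a], ps[b]))
    return out


def resolve_crossings(
    pairs: Collection[tuple],
    priority: Callable[[tuple], float],
) -> tuple[set, list]:
    """Greedily keep pairs in decreasing ``priority`` order, dropping any
    pair that crosses an already-kept one.  Returns (kept, dropped)."""
    kept: set = set()
    dropped: list = []
    for p in sorted(pairs, key=lambda q: (-priority(q), q)):
        p = tuple(p)
        if any(pairs_cross(p, q) for q in kept):
            dropped.append(p)
        else:
            kept.add(p)
    return kept, dropped


def validate_pairs(pairs: Collection[tuple], length: int | None = None) -> None:
    seen: set[int] = set()
    for i, j in pairs:
        if not i < j:
            raise ValueError(f"pair ({i}, {j}) must have i < j")
        if length is not None and not (0 <= i and j < length):
            raise ValueError(f"pair ({i}, {j}) outside sequence of length {length}")
        for x in (i, j):
            if x in seen:
                raise ValueError(f"position {x} participates in more than one pair")
            seen.add(x)


def pairs_to_dbn(pairs: Collection[tuple], length: int) -> str:
    """Dot-bracket for a nested pair set; raises on crossings."""
    validate_pairs(pairs, length)
    if find_crossings(pairs):
        raise ValueError("crossing pairs cannot be encoded in dot-bracket; resolve first")
    chars = ["."] * length
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def dbn_to_pairs(dbn: str) -> frozenset:
    stack: list[int] = []
    pairs = set()
    for pos, c in enumerate(dbn):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif c != ".":
            raise ValueError(f"unsupported dot-bracket character {c!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return frozenset(pairs)
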