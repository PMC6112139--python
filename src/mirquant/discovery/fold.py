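"""Secondary-structure folding and dot-bracket statistics.

The default engine maximizes base pairs (Watson-Crick + GU wobble, minimum
hairpin loop of 3 nt) with a dynamic program, reporting a pseudo-MFE of
-(pairs + 0.5 * stacked pairs). A thermodynamic folder can be substituted:
every structure-derived feature is computed purely from the dot-bracket
string, so both engines feed :func:`structure_stats` identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # optional JIT: pure-numpy fallback below is exact but slower
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

MIN_LOOP = 3
_PAIRABLE = {
    ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"),
}
STACK_BONUS = 0.5


class FoldError(ValueError):
    pass


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_PAIR_OK = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in _PAIRABLE:
    _PAIR_OK[_CODE[_a], _CODE[_b]] = True


def _dp_fill_numpy(codes: np.ndarray) -> np.ndarray:
    n = len(codes)
    can_pair = _PAIR_OK[codes[:, None], codes[None, :]]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        i = np.arange(0, n - span)
        j = i + span
        best = dp[i, j - 1].copy()
        pair_term = np.where(can_pair[i, j], dp[i + 1, j - 1] + 1, -1)
        np.maximum(best, pair_term, out=best)
        for t in range(0, span - 1):  # bifurcation at k = i + t
            np.maximum(best, dp[i, i + t] + dp[i + t + 1, j], out=best)
        dp[i, j] = best
    return dp


if _HAVE_NUMBA:

    @njit(cache=True)
    def _dp_fill_numba(codes, pair_ok):  # pragma: no cover - jitted
        n = len(codes)
        dp = np.zeros((n, n), dtype=np.int32)
        for span in range(MIN_LOOP + 1, n):
            for i in range(n - span):
                j = i + span
                best = dp[i, j - 1]
                if pair_ok[codes[i], codes[j]]:
                    v = dp[i + 1, j - 1] + 1
                    if v > best:
                        best = v
                for k in range(i, j - 1):
                    v = dp[i, k] + dp[k + 1, j]
                    if v > best:
                        best = v
                dp[i, j] = best
        return dp


def fold(sequence: str) -> tuple[str, float]:
    """Maximum-pairing fold; returns (dot-bracket, pseudo-MFE <= 0)."""
    sequence = sequence.upper()
    if set(sequence) - set("ACGTUN"):
        raise FoldError(f"non-nucleotide characters in {sequence!r}")
    seq = sequence.replace("U", "T")
    n = len(seq)
    if n == 0:
        return "", 0.0

    codes = np.array([_CODE[c] for c in seq], dtype=np.uint8)
    if _HAVE_NUMBA:
        dp = _dp_fill_numba(codes, _PAIR_OK)
    else:
        dp = _dp_fill_numpy(codes)
    can_pair = _PAIR_OK[codes[:, None], codes[None, :]]
    can_pair &= np.triu(np.ones((n, n), dtype=bool), k=MIN_LOOP + 1)

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP or dp[i, j] == 0:
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        if can_pair[i, j] and dp[i, j] == dp[i + 1, j - 1] + 1:
            structure[i] = "("
            structure[j] = ")"
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            if dp[i, j] == dp[i, k] + dp[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
        else:  # pragma: no cover - DP and traceback disagree
            raise FoldError("traceback failed")

    db = "".join(structure)
    return db, structure_energy(db)


def structure_energy(structure: str) -> float:
    """Pseudo-MFE of a dot-bracket: -(pairs + 0.5 * stacked pairs)."""
    pairs = dict(pair_list(structure))
    stacked = sum(1 for i, j in pairs.items() if pairs.get(i + 1) == j - 1)
    return -(len(pairs) + STACK_BONUS * stacked)


def pair_list(structure: str) -> list[tuple[int, int]]:
    """(i, j) pairs of a dot-bracket string; raises on imbalance."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise FoldError(f"unbalanced structure at position {i}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise FoldError(f"invalid character {c!r} in structure")
    if stack:
        raise FoldError("unbalanced structure: unclosed '('")
    pairs.sort()
    return pairs


@dataclass
class StructureStats:
    hairpin_count: int
    stem_length: int
    interior_loop_count: int
    binding_count: int
    count_bindings_in_mirna: int
    percentage_paired_in_mirna: float
    distance_to_loop: int
    arm_type: str  # "5p" | "3p" | "loop"
    terminal_loop: tuple[int, int]  # 0-based half-open span of the main hairpin loop


def _children_map(pairs: list[tuple[int, int]]) -> dict[tuple[int, int] | None, list[tuple[int, int]]]:
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for pair in pairs:  # sorted by opening position
        while stack and pair[0] > stack[-1][1]:
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(pair)
        children.setdefault(pair, [])
        stack.append(pair)
    return children


def structure_stats(
    structure: str, stable_start: int, stable_end: int
) -> StructureStats:
    """Loop/stem decomposition features for a window's dot-bracket.

    ``stable_start``/``stable_end`` give the stable range as a 0-based
    half-open span *within the folded window*.
    """
    pairs = pair_list(structure)
    children = _children_map(pairs)

    binding_count = len(pairs)
    in_range = sum(
        1
        for i, j in pairs
        if stable_start <= i < stable_end or stable_start <= j < stable_end
    )
    range_len = max(stable_end - stable_start, 1)

    hairpin_count = sum(1 for p in pairs if not children[p])

    interior_loop_count = 0
    for p in pairs:
        kids = children[p]
        if len(kids) == 1:
            (ci, cj) = kids[0]
            if ci - p[0] - 1 > 0 and p[1] - cj - 1 > 0:
                interior_loop_count += 1

    def depth(pair: tuple[int, int]) -> int:
        best = 0
        for kid in children[pair]:
            best = max(best, depth(kid))
        return 1 + best

    stem_length = max((depth(p) for p in children[None]), default=0)

    # main hairpin: walk the deepest path from the deepest root to its leaf
    loop_start = loop_end = 0
    if pairs:
        node = max(children[None], key=lambda p: (depth(p), -p[0]))
        while children[node]:
            node = max(children[node], key=lambda p: (depth(p), -p[0]))
        loop_start, loop_end = node[0] + 1, node[1]  # half-open unpaired span

    if not pairs:
        arm = "loop"
        distance = 0
    elif stable_end <= loop_start:
        arm = "5p"
        distance = loop_start - stable_end
    elif stable_start >= loop_end:
        arm = "3p"
        distance = stable_start - loop_end
    else:
        arm = "loop"
        distance = 0

    return StructureStats(
        hairpin_count=hairpin_count,
        stem_length=stem_length,
        interior_loop_count=interior_loop_count,
        binding_count=binding_count,
        count_bindings_in_mirna=in_range,
        percentage_paired_in_mirna=in_range / range_len,
        distance_to_loop=distance,
        arm_type=arm,
        terminal_loop=(loop_start, loop_end),
    )
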