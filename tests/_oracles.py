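"""Independent brute-force oracles used across the test suite.

Each oracle is deliberately written as the most direct, naive computation
of its quantity, sharing no code path with the package implementation.
"""

from __future__ import annotations

import math
import random

_PAIRABLE = {"AT", "TA", "GC", "CG", "GT", "TG"}


def max_pairs_exhaustive(seq: str, i: int = 0, j: int | None = None) -> int:
    """Maximum base-pair count by plain recursion over all structures.

    Watson-Crick + GU pairs, minimum hairpin loop of 3 unpaired bases.
    Exponential; only for short sequences (<= ~16 nt).
    """
    if j is None:
        j = len(seq) - 1
    if j - i <= 3:
        return 0
    best = max_pairs_exhaustive(seq, i + 1, j)  # i unpaired
    for k in range(i + 4, j + 1):
        if seq[i] + seq[k] in _PAIRABLE:
            inner = max_pairs_exhaustive(seq, i + 1, k - 1)
            outer = max_pairs_exhaustive(seq, k + 1, j)
            best = max(best, 1 + inner + outer)
    return best


def stable_range_brute(
    assembled_len: int,
    members: list[tuple[int, str, int]],  # (offset, sequence, count)
    threshold: float,
) -> tuple[int, int] | None:
    """Per-position tally: longest (leftmost) run of qualifying positions."""
    total = sum(c for _, _, c in members)
    good = []
    for pos in range(assembled_len):
        symbols: dict[str, int] = {}
        for offset, seq, count in members:
            idx = pos - offset
            if 0 <= idx < len(seq):
                symbols[seq[idx]] = symbols.get(seq[idx], 0) + count
            else:
                symbols["-absent-"] = symbols.get("-absent-", 0) + count
        major = max(symbols, key=lambda s: (symbols[s], s != "-absent-"))
        good.append(major != "-absent-" and symbols[major] / total >= threshold)
    best = None
    pos = 0
    while pos < assembled_len:
        if good[pos]:
            run_start = pos
            while pos < assembled_len and good[pos]:
                pos += 1
            if best is None or pos - run_start > best[1] - best[0]:
                best = (run_start, pos)
        else:
            pos += 1
    return best


def mcc_via_pearson(tp: int, fp: int, tn: int, fn: int) -> float:
    """MCC as the Pearson correlation of expanded binary label vectors."""
    truth = [1] * tp + [0] * fp + [1] * fn + [0] * tn
    pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
    n = len(truth)
    if n == 0:
        return 0.0
    mt = sum(truth) / n
    mp = sum(pred) / n
    cov = sum((t - mt) * (p - mp) for t, p in zip(truth, pred))
    vt = sum((t - mt) ** 2 for t in truth)
    vp = sum((p - mp) ** 2 for p in pred)
    if vt == 0 or vp == 0:
        return 0.0
    return cov / math.sqrt(vt * vp)


def mutual_information_brute(xs: list, ys: list) -> float:
    """Plug-in MI (nats) from the joint empirical distribution."""
    n = len(xs)
    joint: dict[tuple, int] = {}
    px: dict[object, int] = {}
    py: dict[object, int] = {}
    for x, y in zip(xs, ys):
        joint[(x, y)] = joint.get((x, y), 0) + 1
        px[x] = px.get(x, 0) + 1
        py[y] = py.get(y, 0) + 1
    mi = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        mi += pxy * math.log(pxy / (px[x] / n * py[y] / n))
    return mi


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    total = 0.0
    for x in range(k, n + 1):
        total += math.comb(n, x) * p**x * (1 - p) ** (n - x)
    return min(total, 1.0)


def find_adapter_brute(read: str, adapter: str, min_overlap: int, max_rate: float):
    """Leftmost suffix-anchored adapter-prefix match by full enumeration."""
    for start in range(len(read)):
        overlap = min(len(adapter), len(read) - start)
        if overlap < min_overlap:
            return None
        mism = sum(
            1 for a, b in zip(read[start : start + overlap], adapter[:overlap]) if a != b
        )
        if mism <= int(max_rate * overlap):
            return start
    return None


def isomir_scan_brute(
    read: str,
    matures: dict[str, str],
    max_mismatch: int = 1,
    max_tail: int = 3,
    offsets: range = range(-2, 3),
    max_trim: int = 5,
):
    """All tolerant matches of a read against a mature library.

    Returns a list of (target_id, offset, n_mismatch, tail, trim).
    """
    hits = []
    for target_id, mature in sorted(matures.items()):
        for start in offsets:
            mism = 0
            ok = True
            tail_start = len(read)
            for i, base in enumerate(read):
                mpos = start + i
                if mpos < 0:
                    continue
                if mpos >= len(mature):
                    tail_start = i
                    break
                if base != mature[mpos]:
                    mism += 1
            tail = read[tail_start:]
            trim = max(0, len(mature) - (start + len(read)))
            covered = min(len(read) + start, len(mature)) - max(start, 0)
            if (
                mism <= max_mismatch
                and len(tail) <= max_tail
                and trim <= max_trim
                and covered >= len(mature) - max_trim - max(0, start)
            ):
                hits.append((target_id, start, mism, tail, trim))
    return hits


def random_cluster(rng: random.Random, span: int = 40, n_members: int = 8):
    """A random member list for the stable-range oracle comparison."""
    members = []
    for _ in range(rng.randint(1, n_members)):
        length = rng.randint(5, span)
        offset = rng.randint(0, span - length)
        seq = "".join(rng.choice("ACGT") for _ in range(length))
        members.append((offset, seq, rng.randint(1, 5)))
    return members
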