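"""Independent reference implementations used only as test oracles.

These deliberately re-derive results from first principles (direct
window enumeration, exhaustive pathway enumeration, closed-form sums)
and share no code with the package internals they check.
"""

from __future__ import annotations

import itertools
from math import comb, log
from typing import Optional

import numpy as np
from Bio.Seq import Seq

UNITS = {"C-rich": "CCCCAA", "G-rich": "TTGGGG"}


def brute_force_scan(seq: str, end: str, params) -> Optional[tuple[int, int, str]]:
    """Best telomeric run at a read end by direct enumeration of every
    (class, phase, window) combination.

    A window qualifies if it is anchored within max_end_offset_bp of the
    terminus, its innermost base matches the periodic repeat, its length
    is >= min_run_bp and it contains <= max_mismatches mismatching bases
    (N mismatches everything).  Returns (run_length, mismatches, class)
    for the longest window (ties: fewer mismatches, then C-rich first),
    or None.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    best = None  # key: (-len, mism, class_idx)
    for ci, (cls, unit) in enumerate(UNITS.items()):
        u = np.frombuffer(unit.encode(), dtype=np.uint8)
        for q in range(6):
            expected = u[(np.arange(n) + q) % 6]
            mism = arr != expected
            cum = np.concatenate([[0], np.cumsum(mism)])
            if end == "left":
                for a in range(0, min(params.max_end_offset_bp, n - 1) + 1):
                    bs = np.arange(a + params.min_run_bp, n + 1)
                    if len(bs) == 0:
                        continue
                    ok = (~mism[bs - 1]) & (cum[bs] - cum[a] <= params.max_mismatches)
                    if not ok.any():
                        continue
                    lengths = bs[ok] - a
                    mm = cum[bs[ok]] - cum[a]
                    i = np.lexsort((mm, -lengths))[0]
                    key = (-int(lengths[i]), int(mm[i]), ci)
                    if best is None or key < best[0]:
                        best = (key, (int(lengths[i]), int(mm[i]), cls))
            else:
                for b in range(max(n - params.max_end_offset_bp, 1), n + 1):
                    as_ = np.arange(0, b - params.min_run_bp + 1)
                    if len(as_) == 0:
                        continue
                    ok = (~mism[as_]) & (cum[b] - cum[as_] <= params.max_mismatches)
                    if not ok.any():
                        continue
                    lengths = b - as_[ok]
                    mm = cum[b] - cum[as_[ok]]
                    i = np.lexsort((mm, -lengths))[0]
                    key = (-int(lengths[i]), int(mm[i]), ci)
                    if best is None or key < best[0]:
                        best = (key, (int(lengths[i]), int(mm[i]), cls))
    return None if best is None else best[1]


def brute_force_classify(seq: str, params) -> str:
    left = brute_force_scan(seq, "left", params)
    right = brute_force_scan(seq, "right", params)
    if left and right and left[2] != right[2]:
        return "both"
    if left and right:
        return "left" if (left[0], -left[1]) >= (right[0], -right[1]) else "right"
    if left:
        return "left"
    if right:
        return "right"
    return "none"


# ---------------------------------------------------------------------------
# NG86 reference
# ---------------------------------------------------------------------------


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def reference_site_counts(codon: str) -> float:
    """Synonymous sites of one codon by direct neighbour enumeration."""
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            nb = codon[:pos] + alt + codon[pos + 1 :]
            if _aa(nb) != "*" and _aa(nb) == _aa(codon):
                syn += 1 / 3
    return syn


def reference_diff_counts(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences, exhaustive."""
    pos = [i for i in range(3) if a[i] != b[i]]
    if not pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(pos):
        cur, steps, blocked = a, [], False
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            steps.append((cur, nxt))
            if _aa(nxt) == "*":
                blocked = True
            cur = nxt
        paths.append((blocked, steps))
    usable = [s for blk, s in paths if not blk] or [s for _, s in paths]
    sd = sum(1 for steps in usable for c, x in steps if _aa(c) == _aa(x)) / len(usable)
    nd = sum(1 for steps in usable for c, x in steps if _aa(c) != _aa(x)) / len(usable)
    return sd, nd


def reference_ng86(seq_a: str, seq_b: str) -> dict:
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if _aa(ca) == "*" or _aa(cb) == "*":
            continue
        sa, sb = reference_site_counts(ca), reference_site_counts(cb)
        S += (sa + sb) / 2
        N += 3 - (sa + sb) / 2
        sd, nd = reference_diff_counts(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")

    def jc(p):
        return float("nan") if p >= 0.75 else (-0.75 * log(1 - 4 * p / 3) if p else 0.0)

    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN, "ks": jc(pS), "ka": jc(pN)}


# ---------------------------------------------------------------------------
# Hypergeometric tail by direct summation
# ---------------------------------------------------------------------------


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for a hypergeometric draw, by explicit summation."""
    total = comb(N, n)
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return num / total
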