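"""Telomeric-repeat detection at read ends and minichromosome calling.

Ciliate macronuclear minichromosomes carry de novo telomeres built from
the 6-bp repeat (C4A2)n on one strand and its reverse complement (T2G4)n
on the other.  A sequencing read that begins and ends with such repeats
(of opposite repeat classes) spans a complete minichromosome.

The scanner finds, at each read end, the longest telomeric *run*: a
window anchored at (or within a configurable offset of) the terminus,
matched against the periodic repeat in every phase, tolerating a bounded
number of mismatches.  Platform presets follow common practice for short
accurate reads (>= 18 bp, <= 1 mismatch, anchored exactly at the end)
and long noisy reads (>= 30 bp, <= 5 mismatches, anchor within 100 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Optional

import numpy as np
import pandas as pd

# Repeat units written 5'->3' as they appear on the emitted strand:
# C-rich at the left read end, G-rich at the right read end.
TELOMERE_UNITS: dict[str, str] = {"C-rich": "CCCCAA", "G-rich": "TTGGGG"}
UNIT_LENGTH = 6

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanParams:
    """Thresholds for a qualifying telomeric run at a read end.

    min_run_bp
        Minimum run length in bp.
    max_mismatches
        Maximum number of mismatching bases tolerated inside the run
        (an ``N`` counts as a mismatch).
    max_end_offset_bp
        How far from the read terminus the outer edge of the run may be
        anchored; 0 forces the run to start at the terminus itself.
    platform
        Informational label ("short" or "long").
    """

    min_run_bp: int = 18
    max_mismatches: int = 1
    max_end_offset_bp: int = 0
    platform: str = "short"

    def __post_init__(self) -> None:
        if self.min_run_bp <= 0:
            raise ValueError("min_run_bp must be positive")
        if self.max_mismatches < 0 or self.max_end_offset_bp < 0:
            raise ValueError("max_mismatches and max_end_offset_bp must be >= 0")


#: Illumina-style preset: >= 18 bp of repeat, one mismatch, anchored at the end.
SHORT_READ_PARAMS = ScanParams(18, 1, 0, "short")
#: PacBio-style preset: >= 30 bp of repeat, five mismatches, anchor within 100 bp.
LONG_READ_PARAMS = ScanParams(30, 5, 100, "long")


@dataclass(frozen=True)
class TelomereHit:
    """A qualifying telomeric run at one read end."""

    end: Literal["left", "right"]
    run_length_bp: int
    mismatches: int
    phase: int
    repeat_class: str
    anchor_offset_bp: int = 0

    read_id: Optional[str] = None


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise ValueError(f"invalid character {ch!r} at position {i}")


def _scan_oriented(seq: str, params: ScanParams, unit: str) -> Optional[tuple[int, int, int, int]]:
    """Scan the *left* end of ``seq`` against the periodic ``unit``.

    Returns the best ``(run_length, mismatches, phase, anchor)`` over all
    global phases q (expected base at position i is ``unit[(i + q) % 6]``)
    and anchors ``a <= max_end_offset_bp``, or None.  A run is a window
    ``[a, b)`` whose innermost base matches the expected repeat base
    (trailing mismatches are never part of a run) and whose mismatch
    count is within budget.  Selection: longest run, then fewest
    mismatches, then lowest phase index at the run start, then smallest
    anchor.
    """
    n = len(seq)
    best: Optional[tuple[int, int, int, int]] = None
    best_key: Optional[tuple[int, int, int, int]] = None
    max_anchor = min(params.max_end_offset_bp, n - 1)
    for q in range(UNIT_LENGTH):
        for a in range(max_anchor + 1):
            mism = 0
            run_len = 0
            run_mism = 0
            i = a
            while i < n:
                if seq[i] == unit[(i + q) % UNIT_LENGTH]:
                    run_len = i - a + 1
                    run_mism = mism
                else:
                    if mism == params.max_mismatches:
                        break
                    mism += 1
                i += 1
            if run_len >= params.min_run_bp:
                start_phase = (a + q) % UNIT_LENGTH
                key = (-run_len, run_mism, start_phase, a)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (run_len, run_mism, start_phase, a)
    return best


def scan_read_end(
    seq: str,
    end: Literal["left", "right"],
    params: ScanParams,
    read_id: Optional[str] = None,
) -> Optional[TelomereHit]:
    """Detect a telomeric run at one end of a read.

    Both repeat classes are tried at each end; the best qualifying run
    wins (longest, then fewest mismatches, then the C-rich class, then
    lowest phase).  Returns None when no run meets the thresholds.
    """
    _check_sequence(seq)
    if end not in ("left", "right"):
        raise ValueError(f"end must be 'left' or 'right', got {end!r}")

    candidates: list[tuple[tuple[int, int, int, int, int], TelomereHit]] = []
    for class_idx, (repeat_class, unit) in enumerate(TELOMERE_UNITS.items()):
        if end == "left":
            res = _scan_oriented(seq, params, unit)
        else:
            # Scan the reversed sequence against the reversed unit; a run
            # ending at the right terminus becomes a left-anchored run.
            res = _scan_oriented(seq[::-1], params, unit[::-1])
        if res is not None:
            run_len, mism, phase, anchor = res
            key = (-run_len, mism, class_idx, phase, anchor)
            candidates.append(
                (key, TelomereHit(end, run_len, mism, phase, repeat_class, anchor, read_id))
            )
    if not candidates:
        return None
    return min(candidates, key=lambda c: c[0])[1]


def classify_read(
    seq: str, params: ScanParams, read_id: Optional[str] = None
) -> tuple[str, Optional[TelomereHit], Optional[TelomereHit]]:
    """Classify a read as 'left', 'right', 'both' or 'none'.

    'both' additionally requires the two ends to carry runs of opposite
    repeat classes (a C-rich and a G-rich telomere), the signature of a
    complete minichromosome.  The classification is invariant under
    reverse complement, with left and right exchanged.
    """
    left = scan_read_end(seq, "left", params, read_id)
    right = scan_read_end(seq, "right", params, read_id)
    if left and right and left.repeat_class != right.repeat_class:
        return "both", left, right
    if left and right:
        # Same class at both ends: report the stronger end only.
        if (left.run_length_bp, -left.mismatches) >= (right.run_length_bp, -right.mismatches):
            return "left", left, None
        return "right", None, right
    if left:
        return "left", left, None
    if right:
        return "right", None, right
    return "none", None, None


@dataclass(frozen=True)
class MinichromosomeCall:
    read_id: str
    total_length_bp: int
    trimmed_length_bp: int
    left_hit: TelomereHit
    right_hit: TelomereHit


def call_minichromosomes(
    reads: Iterable[tuple[str, str]],
    params: ScanParams = LONG_READ_PARAMS,
) -> pd.DataFrame:
    """Call full-length minichromosomes from long reads.

    One call per read classified 'both'; the trimmed length is the read
    length minus both telomeric runs (and any anchor offsets outside
    them).  Returns a table with columns read_id, total_length_bp,
    trimmed_length_bp, left_run_bp, right_run_bp, left_class,
    left_mismatches, right_mismatches.
    """
    rows = []
    for read_id, seq in reads:
        cls, left, right = classify_read(seq, params, read_id)
        if cls != "both":
            continue
        trimmed = (
            len(seq)
            - left.run_length_bp
            - left.anchor_offset_bp
            - right.run_length_bp
            - right.anchor_offset_bp
        )
        rows.append(
            {
                "read_id": read_id,
                "total_length_bp": len(seq),
                "trimmed_length_bp": max(trimmed, 0),
                "left_run_bp": left.run_length_bp,
                "right_run_bp": right.run_length_bp,
                "left_class": left.repeat_class,
                "left_mismatches": left.mismatches,
                "right_mismatches": right.mismatches,
            }
        )
    columns = [
        "read_id",
        "total_length_bp",
        "trimmed_length_bp",
        "left_run_bp",
        "right_run_bp",
        "left_class",
        "left_mismatches",
        "right_mismatches",
    ]
    return pd.DataFrame(rows, columns=columns)


def length_histogram(
    calls: pd.DataFrame, bin_bp: int = 500, column: str = "trimmed_length_bp"
) -> pd.DataFrame:
    """Histogram of called minichromosome lengths with configurable bins."""
    if calls.empty:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    lengths = calls[column].to_numpy()
    lo = int(lengths.min() // bin_bp * bin_bp)
    hi = int(lengths.max() // bin_bp * bin_bp + bin_bp)
    edges = np.arange(lo, hi + bin_bp, bin_bp)
    counts, _ = np.histogram(lengths, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )
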