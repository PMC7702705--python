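"""Chromosome-breakage profiling along reference contigs.

Maps telomere-addition evidence (reads whose ends carry telomeric
repeats) onto the reference in fixed windows, compares tracks between
datasets or strains by Spearman correlation, and extracts telomere-dense
regions as input for external motif discovery.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from minichrom.telomere import TELOMERE_UNITS, UNIT_LENGTH


def addition_positions(records: pd.DataFrame) -> pd.DataFrame:
    """Reference coordinate of the telomere-addition point of each read.

    Each telomere-classified read contributes one point: the reference
    coordinate of its first non-telomeric base.  C-rich (left-class)
    hits mark the left boundary of the aligned segment, G-rich
    (right-class) hits the right boundary.  Input needs columns contig,
    start, end, telomere_class.
    """
    if "telomere_class" not in records.columns:
        raise ValueError("records need a telomere_class column")
    sub = records[records.telomere_class.isin(("C-rich", "G-rich"))].copy()
    pos = np.where(sub.telomere_class == "C-rich", sub.start, sub.end - 1)
    sub["position"] = pos.astype(int)
    return sub


def window_counts(
    records: pd.DataFrame,
    contig_lengths: dict[str, int],
    window_bp: int = 2000,
) -> pd.DataFrame:
    """Telomere-addition read counts in fixed windows tiling each contig.

    Each read increments the single window containing its telomere-
    addition position; the final partial window is kept and its coverage
    normalized by its true length.  Returns columns contig,
    window_start, window_end, read_count, normalized_coverage.
    """
    pts = addition_positions(records) if "position" not in records.columns else records
    rows = []
    grouped = dict(iter(pts.groupby("contig", sort=False))) if len(pts) else {}
    for contig, L in contig_lengths.items():
        n_win = max(1, math.ceil(L / window_bp))
        counts = np.zeros(n_win, dtype=int)
        if contig in grouped:
            positions = grouped[contig].position.to_numpy()
            bad = (positions < 0) | (positions >= L)
            if bad.any():
                rid = grouped[contig].read_id.to_numpy()[bad][0] if "read_id" in grouped[contig] else "?"
                raise ValueError(f"record {rid} at position off contig {contig}")
            np.add.at(counts, positions // window_bp, 1)
        starts = np.arange(n_win) * window_bp
        ends = np.minimum(starts + window_bp, L)
        for s, e, c in zip(starts, ends, counts):
            rows.append(
                {
                    "contig": contig,
                    "window_start": int(s),
                    "window_end": int(e),
                    "read_count": int(c),
                    "normalized_coverage": c / (e - s),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for small n (< 10)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    if denom == 0:
        return 1.0
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    r_all = (ry[perms] - ry.mean()) @ rx_c / denom
    obs = abs(float(rx_c @ ry_c) / denom)
    return float(np.mean(np.abs(r_all) >= obs - 1e-12))


def correlate_tracks(track_a: pd.DataFrame, track_b: pd.DataFrame) -> CorrelationResult:
    """Spearman rank correlation between two windowed tracks.

    The tracks must share an identical window grid.  Ties get average
    ranks; the p-value uses the t approximation for n >= 10 and exact
    permutation enumeration below that.
    """
    key = ["contig", "window_start", "window_end"]
    a = track_a.sort_values(key).reset_index(drop=True)
    b = track_b.sort_values(key).reset_index(drop=True)
    if len(a) != len(b) or not (a[key].values == b[key].values).all():
        raise ValueError("window grids differ between tracks")
    x = a.normalized_coverage.to_numpy(dtype=float)
    y = b.normalized_coverage.to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 windows for a defined correlation")
    rho, p = stats.spearmanr(x, y)
    if n < 10:
        p = _exact_spearman_p(x, y)
    return CorrelationResult(float(rho), float(p), n)


def _mask_telomeric(seq: str, min_mask_bp: int = 12) -> str:
    """Remove telomeric repeat stretches (either class, any phase) of at
    least min_mask_bp from a sequence."""
    n = len(seq)
    keep = np.ones(n, dtype=bool)
    for unit in TELOMERE_UNITS.values():
        for q in range(UNIT_LENGTH):
            i = 0
            while i < n:
                if seq[i] == unit[(i + q) % UNIT_LENGTH]:
                    j = i
                    while j < n and seq[j] == unit[(j + q) % UNIT_LENGTH]:
                        j += 1
                    if j - i >= min_mask_bp:
                        keep[i:j] = False
                    i = j
                else:
                    i += 1
    return "".join(ch for ch, k in zip(seq, keep) if k)


def extract_motif_regions(
    records: pd.DataFrame,
    contigs: dict[str, str],
    interval_bp: int = 500,
    min_reads: int = 4,
) -> list[tuple[str, str]]:
    """Sequences of telomere-dense intervals, for external motif discovery.

    Left-class and right-class telomere reads are tracked separately
    (mirroring separate mapping of the two read sets); every interval of
    interval_bp with at least min_reads telomere-containing reads in
    either track is emitted, with telomeric repeat stretches removed.
    Returns (name, sequence) pairs.
    """
    for contig in records.contig.unique():
        if contig not in contigs:
            raise ValueError(f"missing reference sequence for contig {contig}")
    lengths = {c: len(s) for c, s in contigs.items()}
    out = []
    emitted = set()
    for klass in ("C-rich", "G-rich"):
        sub = records[records.telomere_class == klass]
        if sub.empty:
            continue
        track = window_counts(sub, lengths, window_bp=interval_bp)
        for row in track[track.read_count >= min_reads].itertuples():
            key = (row.contig, row.window_start)
            if key in emitted:
                continue
            emitted.add(key)
            seq = contigs[row.contig][row.window_start : row.window_end]
            out.append(
                (
                    f"{row.contig}:{row.window_start}-{row.window_end}",
                    _mask_telomeric(seq),
                )
            )
    out.sort()
    return out


def depth_profile(
    depth: np.ndarray, interval_bp: int = 1000, step_bp: int = 500
) -> pd.DataFrame:
    """Sliding-window mean depth (interval_bp windows every step_bp)."""
    if step_bp > interval_bp:
        raise ValueError("step must not exceed the interval")
    depth = np.asarray(depth, dtype=float)
    n = len(depth)
    cum = np.concatenate([[0.0], np.cumsum(depth)])
    starts = np.arange(0, max(n - interval_bp, 0) + 1, step_bp)
    if len(starts) == 0:
        starts = np.array([0])
    ends = np.minimum(starts + interval_bp, n)
    means = (cum[ends] - cum[starts]) / (ends - starts)
    return pd.DataFrame({"start": starts, "end": ends, "mean_depth": means})
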