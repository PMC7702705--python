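"""Functional-allele selection and upstream nucleotide diversity.

Alleles of one locus, collected across strains and haplotypes and placed
on a shared alignment, are partitioned into CDS subgroups by their
(start, stop) alignment columns.  The subgroup with the most alleles
(with a longer-CDS rule when the top two are within one) defines the
functional form of the locus, and the member allele with the highest
mean pairwise alignment bit score represents it.  Per-site nucleotide
diversity pi = 2pqn/(n-1) is profiled over the region upstream of the
translation start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import log
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

# Karlin-Altschul ungapped constants for BLOSUM62 (standard values used to
# convert raw scores to bit scores).
_BLOSUM62_LAMBDA = 0.3176
_BLOSUM62_K = 0.134
_LN2 = log(2.0)


@dataclass
class CDSSubgroup:
    """Alleles of one locus sharing identical start and stop columns."""

    start_col: int
    stop_col: int
    allele_ids: list[str]
    strains: list[str]

    @property
    def size(self) -> int:
        return len(self.allele_ids)

    @property
    def cds_length(self) -> int:
        return self.stop_col - self.start_col + 3  # stop codon included


@dataclass(frozen=True)
class FunctionalGene:
    locus: str
    start_col: int
    stop_col: int
    subgroup_size: int
    representative: str
    mean_bitscore: float


def group_alleles(locus_alleles: pd.DataFrame) -> list[CDSSubgroup]:
    """Partition a locus's alleles into CDS subgroups by (start, stop) column.

    Expects columns allele_id, strain, start_col, stop_col.  Subgroups
    are ordered by size (descending), then CDS length (descending), then
    coordinates, so the ordering is deterministic and input-order free.
    """
    if locus_alleles.empty:
        raise ValueError("locus has no alleles")
    if locus_alleles.start_col.isna().any() or locus_alleles.stop_col.isna().any():
        missing = locus_alleles[locus_alleles.start_col.isna() | locus_alleles.stop_col.isna()]
        raise ValueError(f"allele {missing.allele_id.iloc[0]} missing start/stop columns")
    groups = []
    for (start, stop), sub in locus_alleles.groupby(["start_col", "stop_col"], sort=True):
        sub = sub.sort_values("allele_id")
        groups.append(
            CDSSubgroup(int(start), int(stop), list(sub.allele_id), list(sub.strain))
        )
    groups.sort(key=lambda g: (-g.size, -g.cds_length, g.start_col, g.stop_col))
    return groups


def _choose_subgroup(groups: Sequence[CDSSubgroup]) -> CDSSubgroup:
    if len(groups) == 1:
        return groups[0]
    top, second = groups[0], groups[1]
    if top.size - second.size <= 1:
        # Within one allele of each other: prefer the longer coding region,
        # then the subgroup spanning more strains, then coordinates.
        pair = sorted(
            [top, second],
            key=lambda g: (-g.cds_length, -len(set(g.strains)), g.start_col, g.stop_col),
        )
        return pair[0]
    return top


def make_blast_like_scorer(
    matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0
) -> Callable[[str, str], float]:
    """Global protein aligner returning Karlin-Altschul bit scores.

    Uses the named substitution matrix with affine gaps; the raw optimal
    score S is converted to bits as (lambda*S - ln K)/ln 2 with the
    matrix's standard ungapped constants.  The scorer is symmetric.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend

    valid = set(str(aligner.substitution_matrix.alphabet))

    def score(a: str, b: str) -> float:
        if not a or not b:
            raise ValueError("empty protein sequence")
        for seq in (a, b):
            bad = set(seq) - valid
            if bad:
                raise ValueError(f"invalid residue {sorted(bad)[0]!r}")
        raw = aligner.score(a, b)
        return (_BLOSUM62_LAMBDA * raw - log(_BLOSUM62_K)) / _LN2

    return score


def pairwise_alignment_bitscore(a: str, b: str) -> float:
    """Bit score of the optimal global alignment of two proteins
    (BLOSUM62, affine gaps 11/1)."""
    return make_blast_like_scorer()(a, b)


def translate_cds(allele_row: pd.Series | dict) -> str:
    """Protein of the coding region between an allele's start and stop columns."""
    seq = allele_row["cds_seq"][allele_row["start_col"] : allele_row["stop_col"]]
    return str(Seq(seq.replace("-", "")).translate())


def select_functional_allele(
    locus: str,
    locus_alleles: pd.DataFrame,
    scorer: Optional[Callable[[str, str], float]] = None,
) -> FunctionalGene:
    """Pick the functional CDS subgroup and its representative allele.

    The subgroup with the most alleles wins; when the top two subgroup
    sizes differ by at most one, the one with the longer coding region
    wins.  The representative is the member with the highest mean
    pairwise bit score against the other members (singletons represent
    themselves; ties go to the lexicographically smallest allele id).
    """
    groups = group_alleles(locus_alleles)
    chosen = _choose_subgroup(groups)
    members = locus_alleles[locus_alleles.allele_id.isin(chosen.allele_ids)]
    members = members.sort_values("allele_id").reset_index(drop=True)
    if len(members) == 1:
        return FunctionalGene(
            locus, chosen.start_col, chosen.stop_col, 1, members.allele_id.iloc[0], float("nan")
        )
    if scorer is None:
        scorer = make_blast_like_scorer()
    proteins = [translate_cds(row) for _, row in members.iterrows()]
    n = len(proteins)
    score_mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s = scorer(proteins[i], proteins[j])
            except Exception as exc:
                raise RuntimeError(
                    f"scorer failed for pair ({members.allele_id[i]}, {members.allele_id[j]})"
                ) from exc
            score_mat[i, j] = score_mat[j, i] = s
    mean_scores = score_mat.sum(axis=1) / (n - 1)
    best = int(np.argmax(mean_scores))  # argmax takes the first (smallest id) on ties
    return FunctionalGene(
        locus,
        chosen.start_col,
        chosen.stop_col,
        chosen.size,
        members.allele_id.iloc[best],
        float(mean_scores[best]),
    )


def site_diversity(column: Sequence[str]) -> Optional[float]:
    """Per-site nucleotide diversity pi = 2pqn/(n-1).

    p is the major-allele frequency and q = 1 - p pools all non-major
    alleles (the formula is biallelic; pooling preserves it).  Gaps and
    N are excluded from n; returns None for columns with fewer than two
    informative alleles.
    """
    bases = [c for c in column if c in "ACGT"]
    n = len(bases)
    if n < 2:
        return None
    counts = pd.Series(bases).value_counts()
    p = counts.iloc[0] / n
    q = 1.0 - p
    return 2.0 * p * q * n / (n - 1)


def _column_diversity(seqs: list[str], limit: int) -> np.ndarray:
    """Vectorized per-column pi over the first `limit` columns of equal-role
    sequences; equals site_diversity column by column."""
    mat = np.frombuffer("".join(s[:limit] for s in seqs).encode(), dtype=np.uint8)
    mat = mat.reshape(len(seqs), limit)
    counts = np.stack([(mat == ord(b)).sum(axis=0) for b in "ACGT"])
    n = counts.sum(axis=0).astype(float)
    top = counts.max(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = top / n
        pi = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    pi[n < 2] = np.nan
    return pi


def upstream_diversity_profile(
    alleles: pd.DataFrame,
    min_alleles: int = 5,
    max_len: int = 500,
    subgroup_only: bool = True,
) -> pd.DataFrame:
    """Mean per-position nucleotide diversity upstream of the start codon.

    Position 1 is the first base upstream of the translation start.
    Only loci whose chosen CDS subgroup has at least min_alleles alleles
    contribute (a more-than-four-alleles filter at the default);
    each locus contributes positions up to its distance to the
    neighbouring gene, capped at max_len.  Returns columns position,
    mean_pi, n_loci.
    """
    sums = np.zeros(max_len)
    counts = np.zeros(max_len, dtype=int)
    for locus, sub in alleles.groupby("locus", sort=True):
        if subgroup_only:
            groups = group_alleles(sub)
            chosen = _choose_subgroup(groups)
            sub = sub[sub.allele_id.isin(chosen.allele_ids)]
        if len(sub) < min_alleles:
            continue
        seqs = sub.upstream_seq.to_list()
        limit = min(max_len, int(sub.upstream_len.min()), min(len(s) for s in seqs))
        if limit <= 0:
            continue
        pis = _column_diversity(seqs, limit)
        ok = ~np.isnan(pis)
        sums[:limit][ok] += pis[ok]
        counts[:limit][ok] += 1
    with np.errstate(invalid="ignore"):
        mean_pi = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"position": np.arange(1, max_len + 1), "mean_pi": mean_pi, "n_loci": counts}
    )


def estimate_profile_changepoint(profile: pd.DataFrame) -> int:
    """Least-squares single changepoint of a diversity profile.

    Fits a two-level step function to mean_pi and returns the position
    (1-based) at which the second regime starts.
    """
    y = profile.mean_pi.to_numpy(dtype=float)
    pos = profile.position.to_numpy()
    ok = ~np.isnan(y)
    y, pos = y[ok], pos[ok]
    if len(y) < 4:
        raise ValueError("profile too short for changepoint estimation")
    best_c, best_sse = 1, np.inf
    cum = np.concatenate([[0.0], np.cumsum(y)])
    cum2 = np.concatenate([[0.0], np.cumsum(y**2)])
    n = len(y)
    for c in range(1, n):
        s1, s2 = cum[c], cum[n] - cum[c]
        q1, q2 = cum2[c], cum2[n] - cum2[c]
        sse = (q1 - s1**2 / c) + (q2 - s2**2 / (n - c))
        if sse < best_sse - 1e-12:
            best_sse = sse
            best_c = c
    return int(pos[best_c])
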