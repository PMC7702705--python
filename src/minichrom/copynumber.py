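"""Depth-normalized relative copy number, cross-strain CV, conservation groups.

Relative copy number of a contig or gene is its mean per-base read depth
divided by the genome-wide mean per-base depth, so the length-weighted
genome mean is exactly 1.  The coefficient of variation of a gene's copy
number across strains separates dosage-conserved genes (bottom quantile)
from non-conserved ones (top quantile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def depth_from_alignments(
    records: pd.DataFrame, units: pd.DataFrame, contig_lengths: dict[str, int]
) -> pd.DataFrame:
    """Summed base depth per unit (gene or contig) from alignment intervals.

    records: columns contig, start, end (reference coordinates of the
    aligned genomic segment).  units: columns unit_id, contig, start, end.
    Returns unit_id, length_bp, summed_depth.
    """
    unknown = set(records.contig.unique()) - set(contig_lengths)
    if unknown:
        raise ValueError(f"alignment records reference unknown contig {sorted(unknown)[0]}")
    per_contig_depth: dict[str, np.ndarray] = {}
    for contig, L in contig_lengths.items():
        diff = np.zeros(L + 1, dtype=np.int64)
        sub = records[records.contig == contig]
        if len(sub):
            starts = np.clip(sub.start.to_numpy(), 0, L)
            ends = np.clip(sub.end.to_numpy(), 0, L)
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
        per_contig_depth[contig] = np.cumsum(diff[:-1])
    rows = []
    for u in units.itertuples():
        depth = per_contig_depth.get(u.contig)
        if depth is None:
            raise ValueError(f"unit {u.unit_id} on unknown contig {u.contig}")
        rows.append(
            {
                "unit_id": u.unit_id,
                "length_bp": int(u.end - u.start),
                "summed_depth": int(depth[u.start : u.end].sum()),
            }
        )
    return pd.DataFrame(rows)


def normalized_copy_number(depth_table: pd.DataFrame) -> pd.DataFrame:
    """Relative copy number per unit from a summed-depth table.

    relative_cn = (summed_depth / length) / (total depth / total length),
    i.e. mean unit depth over genome-wide mean depth.  Zero-depth
    fraction per unit (if a zero_frac column is present) is carried
    through so heavily uncovered units can be flagged downstream.
    """
    total_depth = depth_table.summed_depth.sum()
    total_len = depth_table.length_bp.sum()
    if total_depth <= 0:
        raise ValueError("zero genome coverage")
    genome_mean = total_depth / total_len
    out = depth_table.copy()
    out["mean_depth"] = out.summed_depth / out.length_bp
    out["relative_cn"] = out.mean_depth / genome_mean
    return out


@dataclass(frozen=True)
class DosageSummary:
    n_below: int
    n_above: int
    n_total: int

    @property
    def fraction_outside(self) -> float:
        return (self.n_below + self.n_above) / self.n_total


def dosage_distribution(
    cn_table: pd.DataFrame, low: float = 0.67, high: float = 1.5
) -> tuple[DosageSummary, pd.DataFrame]:
    """Count units whose relative copy number falls outside [low, high].

    Returns the summary and a histogram table (log2-spaced bins) for
    dosage-distribution plots.
    """
    if low >= high:
        raise ValueError("low bound must be below high bound")
    if cn_table.empty:
        raise ValueError("empty copy-number table")
    cn = cn_table.relative_cn.to_numpy(dtype=float)
    summary = DosageSummary(int((cn < low).sum()), int((cn > high).sum()), len(cn))
    positive = cn[cn > 0]
    edges = np.logspace(
        np.log2(max(positive.min(), 1e-3)), np.log2(positive.max() + 1e-9), 41, base=2.0
    )
    counts, _ = np.histogram(positive, bins=edges)
    hist = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})
    return summary, hist


def copy_number_cv(cn_by_strain: pd.DataFrame) -> pd.DataFrame:
    """Coefficient of variation of copy number across strains, per gene.

    Input: columns unit_id, strain, relative_cn, one row per gene per
    strain.  CV = sample standard deviation (n-1 denominator) / mean,
    computed only for genes covered in >= 2 strains; genes with zero
    mean are flagged undefined and excluded downstream.
    """
    rows = []
    for unit_id, sub in cn_by_strain.groupby("unit_id", sort=True):
        cn = sub.relative_cn.to_numpy(dtype=float)
        if len(cn) < 2:
            continue
        mean = cn.mean()
        row = {"unit_id": unit_id, "n_strains": len(cn), "mean_cn": mean}
        if mean <= 0:
            row.update(cv=np.nan, defined=False)
        else:
            row.update(cv=cn.std(ddof=1) / mean, defined=True)
        rows.append(row)
    return pd.DataFrame(rows)


def assign_conservation_groups(cv_table: pd.DataFrame, q: float = 0.25) -> pd.DataFrame:
    """Partition genes into conserved / non-conserved / middle CV groups.

    The bottom q fraction by CV (lowest cross-strain variability) is the
    conserved copy-number group, the top q fraction the non-conserved
    group.  Membership is by rank with ties broken by unit id, so group
    sizes are exactly floor(qN).
    """
    if not 0 < q < 0.5:
        raise ValueError("quantile must be in (0, 0.5)")
    defined = cv_table[cv_table.defined].copy() if "defined" in cv_table else cv_table.copy()
    if len(defined) < 4:
        raise ValueError("need at least 4 genes with defined CV")
    defined = defined.sort_values(["cv", "unit_id"], kind="mergesort").reset_index(drop=True)
    n = len(defined)
    k = int(np.floor(q * n))
    group = np.array(["middle"] * n, dtype=object)
    group[:k] = "conserved"
    if k > 0:
        group[n - k :] = "non_conserved"
    defined["group"] = group
    defined.attrs["quantile"] = q
    defined.attrs["group_size"] = k
    return defined


def cn_expression_correlation(
    cn_table: pd.DataFrame, expression: pd.DataFrame
) -> tuple[float, float, int]:
    """Spearman correlation between gene copy number and expression (TPM).

    Tables are joined on unit_id / gene_id; returns (rho, p, n).
    """
    expr = expression.rename(columns={"gene_id": "unit_id"})
    merged = cn_table.merge(expr, on="unit_id", how="inner")
    if len(merged) < 3:
        raise ValueError("fewer than 3 genes shared between tables")
    rho, p = stats.spearmanr(merged.relative_cn, merged.tpm)
    return float(rho), float(p), len(merged)
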