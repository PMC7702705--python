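"""Selection statistics: NG86 Ka/Ks, group tests, enrichment, clustering.

The evolutionary-rate estimator is the Nei-Gojobori (1986) method:
synonymous and nonsynonymous site counts by fractional enumeration of
each codon's nine single-step neighbours, difference counts averaged
over all minimal substitution pathways between differing codons
(pathways through stop codons excluded), and the Jukes-Cantor multiple-
hit correction d = -3/4 ln(1 - 4p/3).  Group contrasts use the
Mann-Whitney U test, term enrichment the upper-tail hypergeometric test
with Benjamini-Hochberg adjustment, and spatial clustering of a gene
set is assessed against an equal-size random-draw bootstrap null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, log
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from Bio.Data import CodonTable


def genetic_code(table_id: int = 1) -> dict[str, str]:
    """Codon -> amino acid map ('*' for stops) for an NCBI translation table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


def _codon_site_counts(codon: str, code: dict[str, str]) -> float:
    """Fractional number of synonymous sites in one codon.

    For each position, the fraction of the three possible changes that
    are synonymous; changes to stop codons count as nonsynonymous, so
    synonymous + nonsynonymous sites always total 3.
    """
    aa = code[codon]
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            neighbour = codon[:pos] + alt + codon[pos + 1 :]
            if code[neighbour] == aa and code[neighbour] != "*":
                syn += 1.0 / 3.0
    return syn


def _pathway_differences(
    a: str, b: str, code: dict[str, str]
) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons, averaged
    over all minimal substitution pathways; pathways passing through a
    stop codon are excluded (all pathways used if every one is blocked)."""
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    all_paths = []
    valid_paths = []
    for order in itertools.permutations(diff_pos):
        cur = a
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            if code[nxt] == "*":
                blocked = True
            cur = nxt
        all_paths.append(steps)
        if not blocked:
            valid_paths.append(steps)
    paths = valid_paths if valid_paths else all_paths
    sd = nd = 0.0
    for steps in paths:
        for cur, nxt in steps:
            if code[cur] == code[nxt]:
                sd += 1.0
            else:
                nd += 1.0
    return sd / len(paths), nd / len(paths)


_NG86_CACHE: dict[int, tuple[dict, dict]] = {}


def _ng86_tables(table_id: int) -> tuple[dict, dict]:
    """Precomputed per-codon site counts and pairwise pathway differences."""
    if table_id not in _NG86_CACHE:
        code = genetic_code(table_id)
        sense = [c for c, aa in code.items() if aa != "*"]
        sites = {c: _codon_site_counts(c, code) for c in sense}
        paths = {
            (ca, cb): _pathway_differences(ca, cb, code)
            for ca in sense
            for cb in sense
            if ca != cb
        }
        _NG86_CACHE[table_id] = (sites, paths)
    return _NG86_CACHE[table_id]


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -3/4 ln(1 - 4p/3); undefined (nan) for p >= 3/4."""
    if p >= 0.75:
        return float("nan")
    if p == 0.0:
        return 0.0
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ks: float
    ka: float

    @property
    def ratio(self) -> float:
        if np.isnan(self.ka) or np.isnan(self.ks) or self.ks == 0.0:
            return float("nan")
        return self.ka / self.ks


def _strip_gapped_codons(a: str, b: str) -> tuple[str, str]:
    out_a, out_b = [], []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        out_a.append(ca)
        out_b.append(cb)
    return "".join(out_a), "".join(out_b)


def ng86_pairwise(seq_a: str, seq_b: str, table_id: int = 1) -> KaKsResult:
    """Nei-Gojobori Ka/Ks for one codon-aligned CDS pair.

    Sequences must be aligned (equal length, divisible by 3); gapped
    codons are stripped as triplets; internal stop codons raise an error
    naming the codon index.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    if len(seq_a) % 3 != 0:
        raise ValueError("aligned length must be divisible by 3")
    code = genetic_code(table_id)
    sites, paths = _ng86_tables(table_id)
    a, b = _strip_gapped_codons(seq_a.upper(), seq_b.upper())
    n_codons = len(a) // 3
    S = N = Sd = Nd = 0.0
    for ci in range(n_codons):
        ca, cb = a[3 * ci : 3 * ci + 3], b[3 * ci : 3 * ci + 3]
        if ca not in code or cb not in code:
            raise ValueError(f"invalid codon at codon index {ci}: {ca!r}/{cb!r}")
        for name, codon in (("first", ca), ("second", cb)):
            if code[codon] == "*" and ci < n_codons - 1:
                raise ValueError(f"internal stop codon at codon index {ci} in {name} sequence")
        if code[ca] == "*" or code[cb] == "*":
            continue  # terminal stop codons carry no site information
        s_a = sites[ca]
        s_b = sites[cb]
        S += (s_a + s_b) / 2.0
        N += 3.0 - (s_a + s_b) / 2.0
        sd, nd = paths[ca, cb] if ca != cb else (0.0, 0.0)
        Sd += sd
        Nd += nd
    if S + N <= 0:
        raise ValueError("no scorable codons in alignment")
    # a codon set with no synonymous (or no nonsynonymous) sites leaves the
    # corresponding proportion, and hence Ks or Ka, undefined
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")
    return KaKsResult(S, N, Sd, Nd, pS, pN, jukes_cantor(pS), jukes_cantor(pN))


def gene_mean_kaks(
    subgroup_alleles: pd.DataFrame, min_alleles: int = 4, table_id: int = 1
) -> Optional[float]:
    """Mean pairwise Ka/Ks over all allele pairs of a CDS subgroup.

    Subgroups with fewer than min_alleles alleles are excluded (None);
    pairs with undefined ratios (Ks = 0 or saturated) are dropped, and
    None is returned when no pair has a defined ratio.  Each allele's
    coding region is taken between its start and stop columns.
    """
    if len(subgroup_alleles) < min_alleles:
        return None
    rows = subgroup_alleles.sort_values("allele_id").reset_index(drop=True)
    start = int(rows.start_col.iloc[0])
    stop = int(rows.stop_col.iloc[0])
    cds = [r.cds_seq[start:stop] for r in rows.itertuples()]
    ratios = []
    for i in range(len(cds)):
        for j in range(i + 1, len(cds)):
            res = ng86_pairwise(cds[i], cds[j], table_id)
            if not np.isnan(res.ratio):
                ratios.append(res.ratio)
    if not ratios:
        return None
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U test between two value groups.

    Uses exact enumeration when both groups have <= 20 values and no
    ties, the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (max(len(a), len(b)) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def go_enrichment(
    gene_set: Sequence[str],
    background: Sequence[str],
    annotation: pd.DataFrame,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a gene set against a background.

    annotation: columns gene_id, term (one row per assignment).  Terms
    annotated to fewer than min_genes background genes are excluded
    before testing.  The enrichment score is (k/n)/(K/N) and the
    p-value the upper tail P(X >= k); BH adjustment spans tested terms.
    """
    background = sorted(set(background))
    gene_set = sorted(set(gene_set))
    bg = set(background)
    missing = [g for g in gene_set if g not in bg]
    if missing:
        raise ValueError(f"gene {missing[0]} absent from background")
    ann = annotation[annotation.gene_id.isin(bg)]
    set_ann = ann[ann.gene_id.isin(set(gene_set))]
    N, n = len(background), len(gene_set)
    rows = []
    for term, sub in ann.groupby("term", sort=True):
        K = sub.gene_id.nunique()
        if K < min_genes:
            continue
        k = set_ann[set_ann.term == term].gene_id.nunique()
        score = (k / n) / (K / N) if n > 0 else float("nan")
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term": term, "k_set": k, "n_set": n, "K_background": K, "N_background": N,
             "score": score, "p_value": p}
        )
    result = pd.DataFrame(rows)
    if not result.empty:
        result["p_adjusted"] = multipletests(result.p_value, method="fdr_bh")[1]
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
    return result


# ---------------------------------------------------------------------------
# Family expansion
# ---------------------------------------------------------------------------


def family_expansion_test(
    counts: pd.DataFrame,
    genome_totals: dict[str, int],
    focal_species: str,
) -> pd.DataFrame:
    """Per-family z-scores and focal-vs-pooled two-proportion tests.

    counts: families x species gene-count table (index = family).  Each
    family's per-species proportions (count / genome total) are
    z-transformed with the population standard deviation; the focal
    species is tested against the other species pooled with a pooled-
    variance two-proportion z-test, BH-adjusted across families.
    Families present only in the focal species are flagged
    species_specific.
    """
    species = list(counts.columns)
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    for sp in species:
        if genome_totals.get(sp, 0) <= 0:
            raise ValueError(f"zero genome total for species {sp}")
    others = [sp for sp in species if sp != focal_species]
    totals = np.array([genome_totals[sp] for sp in species], dtype=float)
    rows = []
    for family, row in counts.iterrows():
        x = row.to_numpy(dtype=float)
        props = x / totals
        sigma = props.std(ddof=0)
        if sigma > 1e-9 * (np.abs(props).max() + 1e-300):
            z_scores = (props - props.mean()) / sigma
        else:
            z_scores = np.zeros_like(props)
        x1 = float(row[focal_species])
        n1 = float(genome_totals[focal_species])
        x2 = float(sum(row[sp] for sp in others))
        n2 = float(sum(genome_totals[sp] for sp in others))
        if x1 + x2 == 0 or x1 + x2 == n1 + n2:
            z_stat, p = 0.0, 1.0
        else:
            z_stat, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
        rec = {"family": family, "p_value": float(p), "z_stat": float(z_stat),
               "species_specific": bool(x1 > 0 and x2 == 0)}
        for sp, z in zip(species, z_scores):
            rec[f"z_{sp}"] = float(z)
        rows.append(rec)
    result = pd.DataFrame(rows).set_index("family")
    result["p_adjusted"] = multipletests(result.p_value, method="fdr_bh")[1]
    return result


# ---------------------------------------------------------------------------
# Gene clustering and bootstrap
# ---------------------------------------------------------------------------


def cluster_genes(
    gene_coords: pd.DataFrame, dist: int = 500
) -> tuple[list[list[str]], float]:
    """Group a gene set into genomic clusters by inter-gene gap.

    Within each contig, genes sorted by start join one cluster when the
    gap to the previous cluster member (next.start - running max end) is
    at most dist; overlapping genes (gap <= 0) always join.  Clusters
    need >= 2 genes.  Returns (clusters, clustered-gene fraction).
    """
    clusters: list[list[str]] = []
    total = len(gene_coords)
    for _, sub in gene_coords.groupby("contig", sort=True):
        sub = sub.sort_values(["start", "gene_id"], kind="mergesort")
        current: list[str] = []
        run_end = None
        for g in sub.itertuples():
            if run_end is not None and g.start - run_end <= dist:
                current.append(g.gene_id)
                run_end = max(run_end, g.end)
            else:
                if len(current) >= 2:
                    clusters.append(current)
                current = [g.gene_id]
                run_end = g.end
        if len(current) >= 2:
            clusters.append(current)
    clustered = sum(len(c) for c in clusters)
    fraction = clustered / total if total else 0.0
    return clusters, fraction


def _clustered_fraction(
    contig_codes: np.ndarray, starts: np.ndarray, ends: np.ndarray, dist: int
) -> float:
    """Array version of the cluster fraction (same gap semantics)."""
    order = np.lexsort((starts, contig_codes))
    c = contig_codes[order]
    s = starts[order]
    e = ends[order]
    n = len(s)
    if n == 0:
        return 0.0
    # running max end within each contig
    run_end = np.empty(n, dtype=np.int64)
    joined = np.zeros(n, dtype=bool)
    cur_end = e[0]
    for i in range(1, n):
        if c[i] == c[i - 1] and s[i] - cur_end <= dist:
            joined[i] = True
            cur_end = max(cur_end, e[i])
        else:
            cur_end = e[i]
    # a gene is clustered if it joined the previous one or the next joined it
    clustered = joined.copy()
    clustered[:-1] |= joined[1:]
    return float(clustered.sum()) / n


@dataclass(frozen=True)
class ClusterTestResult:
    observed_fraction: float
    null_mean: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int


def cluster_bootstrap_test(
    gene_set: Sequence[str],
    genome_genes: pd.DataFrame,
    n_boot: int = 1000,
    dist: int = 500,
    seed: int = 0,
) -> ClusterTestResult:
    """Is a gene set more clustered than equal-size random draws?

    The null distribution comes from n_boot draws of |set| genes without
    replacement from the genome gene table, each clustered with the same
    distance threshold.  The one-sided empirical p-value carries a +1
    correction, (1 + #{null >= observed}) / (n_boot + 1), so it is never
    zero; the 95% CI is the 2.5/97.5 null percentiles.
    """
    gene_set = list(dict.fromkeys(gene_set))
    if len(gene_set) < 2:
        raise ValueError("gene set must contain at least 2 genes")
    if len(gene_set) > len(genome_genes):
        raise ValueError("gene set larger than the genome gene table")
    coords = genome_genes.set_index("gene_id")
    missing = [g for g in gene_set if g not in coords.index]
    if missing:
        raise ValueError(f"gene {missing[0]} not in genome table")
    sub = coords.loc[gene_set].reset_index()
    _, observed = cluster_genes(sub, dist)
    rng = np.random.default_rng(seed)
    contig_codes = pd.factorize(genome_genes.contig)[0].astype(np.int64)
    starts = genome_genes.start.to_numpy(dtype=np.int64)
    ends = genome_genes.end.to_numpy(dtype=np.int64)
    n_genes = len(genome_genes)
    null = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.choice(n_genes, size=len(gene_set), replace=False)
        null[i] = _clustered_fraction(contig_codes[idx], starts[idx], ends[idx], dist)
    p = (1 + int((null >= observed - 1e-12).sum())) / (n_boot + 1)
    return ClusterTestResult(
        observed_fraction=float(observed),
        null_mean=float(null.mean()),
        ci_low=float(np.percentile(null, 2.5)),
        ci_high=float(np.percentile(null, 97.5)),
        p_value=float(p),
        n_boot=n_boot,
        seed=seed,
    )
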