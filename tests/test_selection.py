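"""Selection statistics: NG86, group tests, enrichment, clustering."""

import numpy as np
import pandas as pd
import pytest

from minichrom.selection import (
    _clustered_fraction,
    cluster_bootstrap_test,
    cluster_genes,
    compare_groups,
    family_expansion_test,
    gene_mean_kaks,
    genetic_code,
    go_enrichment,
    ng86_pairwise,
)
from oracles import hypergeom_tail, reference_ng86

SENSE = [c for c, aa in genetic_code(1).items() if aa != "*"]


def test_ng86_worked_example():
    res = ng86_pairwise("TTTGATGCC", "TTCGATGCC")
    assert res.S == pytest.approx(5 / 3)
    assert res.N == pytest.approx(22 / 3)
    assert (res.Sd, res.Nd) == (1.0, 0.0)
    assert res.pS == pytest.approx(0.6)
    assert res.ks == pytest.approx(-0.75 * np.log(0.2), abs=1e-9)
    assert res.ka == 0.0
    assert res.ratio == 0.0


def test_ng86_identical_sequences_undefined_ratio():
    res = ng86_pairwise("ATGAAA", "ATGAAA")
    assert res.ks == 0.0 and res.ka == 0.0
    assert np.isnan(res.ratio)


def test_ng86_site_counts_sum_to_three_per_codon(rng):
    for _ in range(30):
        codons = rng.choice(SENSE, size=int(rng.integers(2, 60)))
        a = "".join(codons)
        b = "".join(rng.choice(SENSE, size=len(codons)))
        res = ng86_pairwise(a, b)
        assert res.S + res.N == pytest.approx(3 * len(codons), abs=1e-9)


def test_ng86_matches_reference_on_random_pairs(rng):
    for _ in range(200):
        ca, cb = rng.choice(SENSE, size=2)
        res = ng86_pairwise(ca, cb)
        ref = reference_ng86(ca, cb)
        assert res.Sd == pytest.approx(ref["Sd"], abs=1e-12)
        assert res.Nd == pytest.approx(ref["Nd"], abs=1e-12)
        assert res.S == pytest.approx(ref["S"], abs=1e-12)


def test_ng86_input_contracts():
    with pytest.raises(ValueError, match="divisible"):
        ng86_pairwise("ATGA", "ATGA")
    with pytest.raises(ValueError, match="equal length"):
        ng86_pairwise("ATG", "ATGATG")
    with pytest.raises(ValueError, match="codon index 1"):
        ng86_pairwise("ATGTAAGGG", "ATGTAAGGG")


def test_ng86_gap_stripping():
    res_gapped = ng86_pairwise("ATG---AAA", "ATGCCCAAA")
    res_plain = ng86_pairwise("ATGAAA", "ATGAAA")
    assert res_gapped.S == res_plain.S


def _subgroup(seqs):
    return pd.DataFrame(
        {
            "locus": "L1",
            "allele_id": [f"a{i}" for i in range(len(seqs))],
            "strain": [f"S{i % 4}" for i in range(len(seqs))],
            "cds_seq": seqs,
            "start_col": 0,
            "stop_col": len(seqs[0]),
        }
    )


def test_gene_mean_kaks_filters():
    assert gene_mean_kaks(_subgroup(["ATGAAAGGG"] * 3)) is None  # too few alleles
    assert gene_mean_kaks(_subgroup(["ATGAAAGGG"] * 4)) is None  # no defined ratio


def test_gene_mean_kaks_equals_pair_average():
    seqs = ["ATGGATACCGGG", "ATGGATACAGGG", "ATGGACACCGGG", "ATGGATACCGGC"]
    mean = gene_mean_kaks(_subgroup(seqs))
    ratios = []
    for i in range(4):
        for j in range(i + 1, 4):
            r = ng86_pairwise(seqs[i], seqs[j]).ratio
            if not np.isnan(r):
                ratios.append(r)
    assert mean == pytest.approx(np.mean(ratios))


def test_mannwhitney_cases(rng):
    a = list(range(10))
    u, p = compare_groups(a, a)
    # identical distributions: U near n^2/2, p close to 1
    assert p > 0.9

    u, p = compare_groups([1, 2, 3], [10, 20, 30], alternative="less")
    assert p == pytest.approx(1 / 20)  # exact: 1 of C(6,3) arrangements

    x = rng.lognormal(0, 0.4, 500)
    y = rng.lognormal(0.6, 0.4, 500)
    _, p = compare_groups(x, y)
    assert p < 1e-4

    with pytest.raises(ValueError, match="non-empty"):
        compare_groups([], [1.0])


def test_enrichment_exact_tail_and_exclusions():
    genes = [f"g{i}" for i in range(20)]
    ann = pd.DataFrame(
        {"gene_id": genes[:5] + genes[5:7], "term": ["T1"] * 5 + ["T2"] * 2}
    )
    res = go_enrichment(genes[:4] + [genes[10]], genes, ann, min_genes=3)
    assert set(res.term) == {"T1"}  # T2 has K=2 < 3
    row = res.iloc[0]
    assert row.p_value == pytest.approx(76 / 15504)
    assert row.p_value == pytest.approx(hypergeom_tail(4, 20, 5, 5))
    assert row.score == pytest.approx((4 / 5) / (5 / 20))


def test_enrichment_full_set_is_null():
    genes = [f"g{i}" for i in range(10)]
    ann = pd.DataFrame({"gene_id": genes, "term": ["T1"] * 5 + ["T2"] * 5})
    res = go_enrichment(genes, genes, ann)
    assert np.allclose(res.score, 1.0)
    assert np.allclose(res.p_value, 1.0)


def test_enrichment_rejects_foreign_gene():
    with pytest.raises(ValueError, match="absent"):
        go_enrichment(["x"], ["a", "b"], pd.DataFrame({"gene_id": ["a"], "term": ["T"]}))


def test_bh_adjustment_preserves_order(rng):
    genes = [f"g{i}" for i in range(60)]
    ann = pd.DataFrame(
        {
            "gene_id": rng.choice(genes, 300),
            "term": rng.choice([f"T{i}" for i in range(12)], 300),
        }
    ).drop_duplicates()
    res = go_enrichment(genes[:15], genes, ann)
    ordered = res.sort_values("p_value")
    assert (ordered.p_adjusted.diff().dropna() >= -1e-12).all()
    assert (ordered.p_adjusted >= ordered.p_value - 1e-12).all()


def test_family_expansion_hand_value():
    counts = pd.DataFrame(
        {"focal": [10, 5], "other_a": [5, 5], "other_b": [5, 5]},
        index=["FAM1", "FAM2"],
    )
    totals = {"focal": 1000, "other_a": 1500, "other_b": 1500}
    res = family_expansion_test(counts, totals, "focal")
    # FAM1: 10/1000 vs pooled 10/3000 -> z ~ 2.588, p ~ 0.0097
    assert res.loc["FAM1", "z_stat"] == pytest.approx(2.5885, abs=1e-3)
    assert res.loc["FAM1", "p_value"] == pytest.approx(0.00965, abs=1e-4)
    assert not res.species_specific.any()


def test_family_expansion_degenerate_rows():
    counts = pd.DataFrame(
        {"focal": [3, 4], "other_a": [3, 0], "other_b": [3, 0]},
        index=["EQ", "ONLY"],
    )
    totals = {"focal": 1000, "other_a": 1000, "other_b": 1000}
    res = family_expansion_test(counts, totals, "focal")
    assert res.loc["EQ", "z_focal"] == 0.0
    assert res.loc["ONLY", "species_specific"]
    with pytest.raises(ValueError, match="zero genome total"):
        family_expansion_test(counts, {"focal": 0, "other_a": 1, "other_b": 1}, "focal")


def _coords(specs):
    return pd.DataFrame(
        [
            {"gene_id": gid, "contig": c, "start": s, "end": e}
            for gid, c, s, e in specs
        ]
    )


def test_cluster_gap_semantics():
    close = _coords([("a", "c1", 0, 1000), ("b", "c1", 1400, 2000)])  # gap 400
    clusters, frac = cluster_genes(close, dist=500)
    assert clusters == [["a", "b"]] and frac == 1.0

    far = _coords([("a", "c1", 0, 1000), ("b", "c1", 1600, 2000)])  # gap 600
    clusters, frac = cluster_genes(far, dist=500)
    assert clusters == [] and frac == 0.0

    single = _coords([("a", "c1", 0, 1000)])
    assert cluster_genes(single, dist=500) == ([], 0.0)

    overlapping = _coords([("a", "c1", 0, 1000), ("b", "c1", 500, 800)])
    clusters, frac = cluster_genes(overlapping, dist=500)
    assert clusters == [["a", "b"]]


def test_clustered_fraction_matches_dataframe_path(rng):
    n = 60
    table = _coords(
        [
            (f"g{i}", f"c{int(rng.integers(3))}", int(s := rng.integers(0, 50_000)), int(s + rng.integers(500, 2000)))
            for i in range(n)
        ]
    )
    _, frac = cluster_genes(table, dist=500)
    fast = _clustered_fraction(
        pd.factorize(table.contig)[0].astype(np.int64),
        table.start.to_numpy(np.int64),
        table.end.to_numpy(np.int64),
        500,
    )
    assert fast == pytest.approx(frac)


def test_bootstrap_full_set_and_floor():
    genes = _coords([(f"g{i}", "c1", i * 3000, i * 3000 + 1000) for i in range(10)])
    res = cluster_bootstrap_test(genes.gene_id.tolist(), genes, n_boot=50, seed=1)
    assert res.p_value == 1.0  # the set is the genome: every draw ties it
    assert res.p_value >= 1 / 51  # +1 correction keeps p off zero
    assert res.ci_low <= res.null_mean <= res.ci_high

    with pytest.raises(ValueError, match="at least 2"):
        cluster_bootstrap_test(["g0"], genes, n_boot=10, seed=0)


def test_bootstrap_detects_planted_tandem_cluster():
    specs = [(f"t{i}", "c1", i * 1200, i * 1200 + 1000) for i in range(10)]
    specs += [(f"g{i}", "c1", 40_000 + i * 9000, 40_000 + i * 9000 + 1000) for i in range(40)]
    genes = _coords(specs)
    res = cluster_bootstrap_test([f"t{i}" for i in range(10)], genes, n_boot=200, seed=5)
    assert res.observed_fraction == 1.0
    assert res.p_value <= 0.01
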