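"""CDS subgrouping, functional-allele selection, nucleotide diversity."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from minichrom.alleles import (
    _column_diversity,
    estimate_profile_changepoint,
    group_alleles,
    make_blast_like_scorer,
    pairwise_alignment_bitscore,
    select_functional_allele,
    site_diversity,
    upstream_diversity_profile,
)


def _alleles(specs, cds="ATGAAATAA"):
    """specs: list of (allele_id, strain, start_col, stop_col[, cds])."""
    rows = []
    for spec in specs:
        aid, strain, start, stop = spec[:4]
        rows.append(
            {
                "locus": "L1",
                "allele_id": aid,
                "strain": strain,
                "haplotype": 1,
                "cds_seq": spec[4] if len(spec) > 4 else cds,
                "start_col": start,
                "stop_col": stop,
                "upstream_seq": "ACGT" * 10,
                "upstream_len": 40,
            }
        )
    return pd.DataFrame(rows)


def test_grouping_partitions_by_start_stop():
    table = _alleles(
        [(f"a{i}", f"S{i % 4}", 101, 1300) for i in range(6)]
        + [("b0", "S0", 101, 1200), ("b1", "S1", 101, 1200)]
    )
    groups = group_alleles(table)
    assert [g.size for g in groups] == [6, 2]
    assert {a for g in groups for a in g.allele_ids} == set(table.allele_id)

    single = group_alleles(_alleles([("x", "S0", 0, 6)]))
    assert len(single) == 1 and single[0].size == 1

    same = group_alleles(_alleles([(f"a{i}", "S0", 0, 6) for i in range(5)]))
    assert len(same) == 1 and same[0].size == 5


def test_grouping_requires_columns():
    table = _alleles([("a", "S0", 0, 6)])
    table.loc[0, "start_col"] = np.nan
    with pytest.raises(ValueError, match="missing start/stop"):
        group_alleles(table)


def test_subgroup_selection_rules():
    cds = "ATG" + "AAA" * 40 + "TAA"
    # clear majority: 5 vs 3
    table = _alleles(
        [(f"a{i}", f"S{i}", 0, 120, cds) for i in range(5)]
        + [(f"b{i}", f"S{i}", 0, 60, cds) for i in range(3)]
    )
    fg = select_functional_allele("L1", table)
    assert fg.subgroup_size == 5 and fg.stop_col == 120

    # within one: 4 vs 3, the smaller subgroup has the longer CDS
    table = _alleles(
        [(f"a{i}", f"S{i}", 0, 60, cds) for i in range(4)]
        + [(f"b{i}", f"S{i}", 0, 120, cds) for i in range(3)]
    )
    fg = select_functional_allele("L1", table)
    assert fg.subgroup_size == 3 and fg.stop_col == 120


def test_representative_tie_break_is_lexicographic():
    cds = "ATG" + "GAT" * 30 + "TAA"
    table = _alleles([(aid, "S0", 0, 90, cds) for aid in ("z9", "m5", "a1")])
    fg = select_functional_allele("L1", table)
    assert fg.representative == "a1"


def test_selection_invariant_to_input_order(rng):
    cds = "ATG" + "GAT" * 30 + "TAA"
    specs = [(f"a{i}", f"S{i % 4}", 0, 90, cds) for i in range(6)] + [
        ("b0", "S0", 0, 30, cds),
        ("b1", "S1", 0, 30, cds),
    ]
    table = _alleles(specs)
    fg1 = select_functional_allele("L1", table)
    fg2 = select_functional_allele("L1", table.sample(frac=1, random_state=3))
    assert fg1 == fg2


def test_bitscore_symmetry_and_optimality():
    a, b = "MKVLLITHG", "MKVLLATHG"
    assert pairwise_alignment_bitscore(a, b) == pytest.approx(
        pairwise_alignment_bitscore(b, a)
    )
    assert pairwise_alignment_bitscore(a, a) >= pairwise_alignment_bitscore(a, b)


def test_bitscore_hand_formula():
    # raw score of MKV vs MKV = 5 + 5 + 4 = 14 under BLOSUM62;
    # bits = (0.3176 * 14 - ln 0.134) / ln 2
    expected = (0.3176 * 14 - math.log(0.134)) / math.log(2)
    assert pairwise_alignment_bitscore("MKV", "MKV") == pytest.approx(expected, abs=1e-6)


def test_bitscore_invalid_residue():
    with pytest.raises(ValueError, match="invalid residue"):
        pairwise_alignment_bitscore("MK1", "MKV")


@pytest.mark.parametrize(
    "column,expected",
    [
        (["A", "C"], 1.0),  # n=2 differing: 2*0.5*0.5*2/1
        (["A", "A", "A", "A"], 0.0),
        (["A", "A", "A", "C"], 0.5),  # n=4, p=0.75: 2*0.75*0.25*4/3
        (["A", "-", "-", "-"], None),
        (["-", "-"], None),
    ],
)
def test_site_diversity_direct_formula(column, expected):
    pi = site_diversity(column)
    if expected is None:
        assert pi is None
    else:
        assert pi == pytest.approx(expected)


def test_site_diversity_exhaustive_small_n():
    """pi matches direct evaluation of 2pqn/(n-1) for every base column
    with n <= 6 (non-major alleles pooled into q)."""
    for n in range(2, 7):
        for column in itertools.product("ACGT", repeat=n):
            counts = sorted((column.count(b) for b in "ACGT"), reverse=True)
            p = counts[0] / n
            expected = 2 * p * (1 - p) * n / (n - 1)
            assert site_diversity(column) == pytest.approx(expected), column


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 10), L=st.integers(1, 40))
def test_column_diversity_matches_scalar(seed, n, L):
    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list("ACGTN-"), size=L)) for _ in range(n)]
    vec = _column_diversity(seqs, L)
    for i in range(L):
        scalar = site_diversity([s[i] for s in seqs])
        if scalar is None:
            assert np.isnan(vec[i])
        else:
            assert vec[i] == pytest.approx(scalar)


def test_pi_maximized_at_half():
    values = [site_diversity(["A"] * k + ["C"] * (8 - k)) for k in range(1, 8)]
    assert max(values) == values[3]  # p = 0.5
    assert site_diversity(["A", "C"] * 500) == pytest.approx(0.5, abs=1e-3)


def _profile_table(upstreams, n_strains=6):
    rows = []
    for locus, seqs in upstreams.items():
        for i, s in enumerate(seqs):
            rows.append(
                {
                    "locus": locus,
                    "allele_id": f"{locus}|a{i}",
                    "strain": f"S{i % n_strains}",
                    "haplotype": 1,
                    "cds_seq": "ATGTAA",
                    "start_col": 0,
                    "stop_col": 3,
                    "upstream_seq": s,
                    "upstream_len": len(s),
                }
            )
    return pd.DataFrame(rows)


def test_profile_truncates_at_neighbouring_gene():
    table = _profile_table({"L1": ["A" * 60] * 5})
    prof = upstream_diversity_profile(table, min_alleles=5, max_len=500)
    assert (prof.n_loci.iloc[:60] == 1).all()
    assert (prof.n_loci.iloc[60:] == 0).all()
    assert (prof.mean_pi.iloc[:60] == 0).all()  # monomorphic: flat zero


def test_profile_excludes_small_loci():
    table = _profile_table({"L1": ["ACGT" * 10] * 4})
    prof = upstream_diversity_profile(table, min_alleles=5)
    assert (prof.n_loci == 0).all()


def test_changepoint_recovery_on_step_profile(rng):
    y = np.concatenate([np.zeros(50), np.full(150, 0.06)]) + rng.normal(0, 0.005, 200)
    prof = pd.DataFrame({"position": np.arange(1, 201), "mean_pi": y, "n_loci": 10})
    assert abs(estimate_profile_changepoint(prof) - 51) <= 3
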