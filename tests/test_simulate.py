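"""Synthetic MAC generator: determinism, composition and planted structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy.stats import spearmanr

from minichrom.simulate import (
    SimulationConfig,
    generate_genome,
    generate_minichromosome_pool,
    generate_strain_panel,
    simulate_all,
    simulate_long_reads,
    simulate_short_reads,
    true_gene_copy_numbers,
)
from minichrom.telomere import TELOMERE_UNITS, revcomp


def test_config_validation():
    with pytest.raises(ValueError, match="gc_target"):
        SimulationConfig(gc_target=1.5)
    with pytest.raises(ValueError, match="mini_len_range"):
        SimulationConfig(contig_length_bp=5000, mini_len_range_bp=(8000, 16000))
    with pytest.raises(ValueError, match="divergence"):
        SimulationConfig(strain_divergence=0.6)


def test_generation_is_deterministic(small_config, small_sim):
    again = simulate_all(small_config)
    assert again.genome.contigs == small_sim.genome.contigs
    assert_frame_equal(again.genome.genes, small_sim.genome.genes)
    assert_frame_equal(again.minis, small_sim.minis)
    assert_frame_equal(again.alleles, small_sim.alleles)
    assert_frame_equal(again.truth.expression, small_sim.truth.expression)


def test_realized_gc_near_target():
    cfg = SimulationConfig(seed=4, n_contigs=1, contig_length_bp=500_000, genes_per_contig=220)
    genome = generate_genome(cfg)
    seq = genome.contigs["contig_1"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert 0.278 <= gc <= 0.298


def test_infeasible_gene_layout_raises():
    cfg = SimulationConfig(
        seed=1, n_contigs=1, contig_length_bp=50_000, genes_per_contig=100,
        cds_length_bp=1500, mini_len_range_bp=(8000, 16000),
    )
    with pytest.raises(ValueError, match="cannot fit"):
        generate_genome(cfg)


def test_gene_models_well_formed(small_sim):
    genes = small_sim.genome.genes
    exons = small_sim.genome.exons
    for cname, sub in genes.groupby("contig"):
        sub = sub.sort_values("start")
        assert (sub.start.to_numpy()[1:] >= sub.end.to_numpy()[:-1]).all(), "genes overlap"
    # introns start GT and end AG on the coding strand
    for g in genes.itertuples():
        ex = exons[exons.gene_id == g.gene_id].sort_values("start")
        seq = small_sim.genome.contigs[g.contig]
        bounds = list(zip(ex.start, ex.end))
        for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
            intron = seq[e1:s2]
            if g.strand == "-":
                intron = revcomp(intron)
            assert intron[:2] == "GT" and intron[-2:] == "AG"
        spliced = "".join(seq[s:e] for s, e in bounds)
        if g.strand == "-":
            spliced = revcomp(spliced)
        assert spliced == g.cds


def test_minichromosome_lengths_in_range(small_sim, small_config):
    lo, hi = small_config.mini_len_range_bp
    lengths = small_sim.minis.end - small_sim.minis.start
    assert ((lengths >= lo) & (lengths <= hi)).mean() >= 0.95


def test_every_gene_on_a_minichromosome(small_sim):
    minis = small_sim.minis
    for g in small_sim.genome.genes.itertuples():
        sub = minis[minis.contig == g.contig]
        assert ((sub.start <= g.start) & (sub.end >= g.end)).any(), g.gene_id


def test_dosage_conservation_invariant(small_sim, small_config):
    """Per-gene true copy number equals the sum over containing minis."""
    recomputed = true_gene_copy_numbers(small_sim.genome, small_sim.minis)
    assert_frame_equal(recomputed, small_sim.truth.gene_cn)
    minis = small_sim.minis
    g = small_sim.genome.genes.iloc[3]
    containing = minis[(minis.contig == g.contig) & (minis.start <= g.start) & (minis.end >= g.end)]
    manual = containing["cn_S2"].sum()
    got = small_sim.truth.gene_cn.query("gene_id == @g.gene_id and strain == 'S2'").true_cn.iloc[0]
    assert got == pytest.approx(manual, rel=1e-12)


def test_degenerate_single_hotspot_no_jitter():
    cfg = SimulationConfig(
        seed=2, n_contigs=1, contig_length_bp=60_000, genes_per_contig=25,
        n_minichromosomes=40, n_hotspots_per_contig=1, hotspot_sd_bp=0.0,
        background_breakage_weight=0.0,
    )
    genome = generate_genome(cfg)
    minis = generate_minichromosome_pool(genome, cfg)
    main_pool = minis.iloc[:40]  # gene-coverage rescues excluded
    assert main_pool.start.nunique() == 1


def test_zero_conserved_sigma_gives_zero_cv():
    cfg = SimulationConfig(
        seed=6, n_contigs=1, contig_length_bp=80_000, genes_per_contig=35,
        n_minichromosomes=80, conserved_fraction=1.0, cn_lognormal_sigma_conserved=0.0,
    )
    sim = simulate_all(cfg)
    wide = sim.truth.gene_cn.pivot(index="gene_id", columns="strain", values="true_cn")
    cv = wide.std(axis=1, ddof=1) / wide.mean(axis=1)
    assert (cv == 0).all()


def test_long_reads_are_telomere_capped(small_sim, small_config, rng):
    reads, records = simulate_long_reads(
        small_sim.genome, small_sim.minis, small_config, "S1", rng, count=50
    )
    t = small_config.telomere_length_bp
    left = TELOMERE_UNITS["C-rich"] * (t // 6)
    right = TELOMERE_UNITS["G-rich"] * (t // 6)
    for (rid, seq), rec in zip(reads, records.itertuples()):
        assert seq.startswith(left) and seq.endswith(right)
        mini = small_sim.minis.set_index("mini_id").loc[rec.mini_id]
        assert len(seq) == (mini.end - mini.start) + 2 * t
        core = seq[t:-t]
        genomic = small_sim.genome.contigs[rec.contig][mini.start : mini.end]
        assert core == (genomic if rec.strand == "+" else revcomp(genomic))


def test_long_read_sampling_tracks_copy_number(rng):
    cfg = SimulationConfig(
        seed=8, n_contigs=1, contig_length_bp=60_000, genes_per_contig=25,
        n_minichromosomes=4, background_breakage_weight=1.0,
    )
    genome = generate_genome(cfg)
    minis = generate_minichromosome_pool(genome, cfg).iloc[:2].copy()
    for s in cfg.strains:
        minis[f"cn_{s}"] = [4.0, 1.0]
    _, records = simulate_long_reads(genome, minis, cfg, "S1", rng, count=4000)
    share = (records.mini_id == minis.mini_id.iloc[0]).mean()
    assert 0.77 <= share <= 0.83  # binomial band around 0.8


def test_short_read_coverage_definition(small_sim, small_config, rng):
    records, _ = simulate_short_reads(
        small_sim.genome, small_sim.minis, small_config, "S1", rng, coverage=3.0
    )
    pool_bp = (small_sim.minis.end - small_sim.minis.start).sum()
    emitted = len(records) * small_config.read_length_bp
    assert abs(emitted - 3.0 * pool_bp) / (3.0 * pool_bp) < 0.05


def test_short_read_errors_rejected():
    cfg = SimulationConfig(seed=1)
    with pytest.raises(ValueError, match="coverage"):
        simulate_short_reads(None, None, cfg, "S1", np.random.default_rng(0), coverage=0.0)


def test_strain_divergence_realized(small_sim):
    """Neutrally evolving (variable-class) alleles diverge at the configured
    rate against the reference CDS."""
    genes = small_sim.genome.genes.set_index("gene_id")
    variable = genes[genes.conservation_class == "variable"]
    al = small_sim.alleles[small_sim.alleles.locus.isin(variable.index)]
    diffs = total = 0
    for r in al.itertuples():
        ref = genes.loc[r.locus, "cds"]
        if r.start_col != 0 or r.stop_col != len(ref) - 3:
            continue  # skip start/stop-altered alleles
        diffs += sum(a != b for a, b in zip(ref, r.cds_seq))
        total += len(ref)
    assert total > 100_000
    assert 0.025 <= diffs / total <= 0.035


def test_no_startstop_variants_one_subgroup():
    cfg = SimulationConfig(
        seed=9, n_contigs=1, contig_length_bp=60_000, genes_per_contig=20,
        n_minichromosomes=40, startstop_variant_rate=0.0,
    )
    sim = simulate_all(cfg)
    per_locus = sim.alleles.groupby("locus")[["start_col", "stop_col"]].nunique()
    assert (per_locus == 1).all().all()


def test_expression_noise_degrades_cn_correlation():
    cfg = SimulationConfig(
        seed=12, n_contigs=1, contig_length_bp=80_000, genes_per_contig=35,
        n_minichromosomes=80,
    )
    genome = generate_genome(cfg)
    minis = generate_minichromosome_pool(genome, cfg)
    gene_cn = true_gene_copy_numbers(genome, minis)
    rhos = []
    for sigma in (0.1, 0.8, 2.5):
        c = dataclasses.replace(cfg, expression_noise_sigma=sigma)
        _, expr, _ = generate_strain_panel(genome, gene_cn, c, np.random.default_rng(77))
        sub = expr[expr.strain == "S1"]
        rhos.append(spearmanr(sub.true_cn, sub.tpm)[0])
    assert rhos[0] > rhos[1] > rhos[2]
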