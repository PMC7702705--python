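"""End-to-end pipeline: simulate -> telomeres -> breakage -> cnv -> alleles
-> diversity -> kaks -> groups -> enrich -> cluster-test.

Each stage reads persisted intermediates from the run directory and
writes its own outputs there, so any stage can be re-run in isolation.
Defaults reproduce the published analysis parameters (telomere-scan
thresholds 18 bp/1 mismatch and 30 bp/5 mismatches, 2-kb breakage
windows, 0.5-kb motif intervals with >= 4 telomere reads, the
0.67x/1.5x dosage band, 25% CV quantiles, 500-bp upstream cap, allele
minima of 5 for diversity and 4 for Ka/Ks, GO terms with >= 3 genes,
cluster distance 500 bp with 1000 bootstrap draws).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from minichrom import alleles as alleles_mod
from minichrom import breakage, copynumber, io, selection
from minichrom import telomere as telomere_mod
from minichrom.simulate import (
    SimulationConfig,
    generate_family_counts,
    generate_go_annotation,
    simulate_all,
    simulate_long_reads,
    simulate_short_reads,
)
from minichrom.telomere import ScanParams

STAGES = (
    "simulate",
    "telomeres",
    "breakage",
    "cnv",
    "alleles",
    "diversity",
    "kaks",
    "groups",
    "enrich",
    "cluster-test",
)


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (defaults = published values)."""

    seed: int = 0
    outdir: str = "minichrom_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    short_min_run_bp: int = 18
    short_max_mismatches: int = 1
    short_end_offset_bp: int = 0
    long_min_run_bp: int = 30
    long_max_mismatches: int = 5
    long_end_offset_bp: int = 100
    window_bp: int = 2000
    motif_interval_bp: int = 500
    motif_min_reads: int = 4
    dosage_low: float = 0.67
    dosage_high: float = 1.5
    cv_quantile: float = 0.25
    max_upstream_bp: int = 500
    min_alleles_pi: int = 5
    min_alleles_kaks: int = 4
    min_go_genes: int = 3
    cluster_dist_bp: int = 500
    n_boot: int = 1000

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        # the genome seed follows the run seed unless set explicitly
        if self.simulation.seed != self.seed:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @property
    def short_params(self) -> ScanParams:
        return ScanParams(
            self.short_min_run_bp, self.short_max_mismatches, self.short_end_offset_bp, "short"
        )

    @property
    def long_params(self) -> ScanParams:
        return ScanParams(
            self.long_min_run_bp, self.long_max_mismatches, self.long_end_offset_bp, "long"
        )

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("simulation", {})
        if isinstance(sim, dict):
            for key in ("telomere_units", "mini_len_range_bp"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
        return cls(simulation=SimulationConfig(**sim) if isinstance(sim, dict) else sim, **data)


def _out(config: RunConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


_FLIP = {"C-rich": "G-rich", "G-rich": "C-rich"}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig) -> dict:
    out = _out(config)
    sim = simulate_all(config.simulation)
    cfg = config.simulation
    io.write_fasta(sim.genome.contigs.items(), out / "reference.fasta")
    io.write_gff3(sim.genome.genes, sim.genome.exons, out / "genes.gff3")
    io.write_tsv(sim.truth.genes, out / "truth_genes.tsv")
    io.write_tsv(sim.minis, out / "truth_minis.tsv")
    io.write_tsv(sim.truth.gene_cn, out / "truth_gene_cn.tsv")
    io.write_tsv(sim.truth.expression, out / "expression.tsv")
    io.write_tsv(sim.truth.variants, out / "truth_variants.tsv")
    io.write_tsv(sim.alleles, out / "alleles.tsv")

    rng = np.random.default_rng(cfg.seed + 100)
    long_reads, long_records = simulate_long_reads(sim.genome, sim.minis, cfg, "S1", rng)
    io.write_fastq(long_reads, out / "long_reads.fastq")
    io.write_tsv(long_records, out / "long_records.tsv")
    n_short = {}
    for i, strain in enumerate(cfg.strains):
        srng = np.random.default_rng(cfg.seed + 200 + i)
        with_seqs = strain == "S1"
        records, seqs = simulate_short_reads(
            sim.genome, sim.minis, cfg, strain, srng, with_sequences=with_seqs
        )
        io.write_tsv(records, out / f"short_records_{strain}.tsv")
        if with_seqs:
            io.write_fastq(seqs, out / "short_reads_S1.fastq")
        n_short[strain] = len(records)

    arng = np.random.default_rng(cfg.seed + 300)
    annotation = generate_go_annotation(sim.genome.genes, arng)
    io.write_tsv(annotation, out / "go_annotation.tsv")
    fam_counts, totals = generate_family_counts(arng)
    fam_counts.rename_axis("family").reset_index().to_csv(
        out / "family_counts.tsv", sep="\t", index=False
    )
    with open(out / "family_totals.json", "w") as fh:
        json.dump(totals, fh, sort_keys=True)
    return {
        "n_contigs": len(sim.genome.contigs),
        "n_genes": len(sim.genome.genes),
        "n_minichromosomes": len(sim.minis),
        "n_long_reads": len(long_reads),
        "n_short_reads": n_short,
        "n_alleles": len(sim.alleles),
    }


def _reference(config: RunConfig) -> dict[str, str]:
    return dict(io.read_fasta(_out(config) / "reference.fasta"))


def stage_telomeres(config: RunConfig) -> dict:
    out = _out(config)
    long_reads = io.read_fastq(out / "long_reads.fastq")
    calls = telomere_mod.call_minichromosomes(long_reads, config.long_params)
    io.write_tsv(calls, out / "mini_calls.tsv")
    hist = telomere_mod.length_histogram(calls)
    io.write_tsv(hist, out / "mini_length_hist.tsv")

    # Telomere-run intervals in read coordinates (BED).
    runs = []
    for c in calls.itertuples():
        runs.append({"contig": c.read_id, "start": 0, "end": c.left_run_bp, "name": "left"})
        runs.append(
            {
                "contig": c.read_id,
                "start": c.total_length_bp - c.right_run_bp,
                "end": c.total_length_bp,
                "name": "right",
            }
        )
    io.write_bed(pd.DataFrame(runs, columns=["contig", "start", "end", "name"]), out / "telomere_runs.bed")

    # Reference-oriented telomere records from both-telomere long reads.
    long_records = io.read_tsv(out / "long_records.tsv").set_index("read_id")
    both_ids = set(calls.read_id)
    long_rows = []
    for rid in calls.read_id:
        rec = long_records.loc[rid]
        for klass, _end in (("C-rich", "start"), ("G-rich", "end")):
            long_rows.append(
                {
                    "read_id": rid,
                    "contig": rec.contig,
                    "start": int(rec.start),
                    "end": int(rec.end),
                    "strand": rec.strand,
                    "telomere_class": klass,
                }
            )
    io.write_tsv(pd.DataFrame(long_rows), out / "telomere_reads_long.tsv")

    # Classify short reads and map hit classes to reference orientation.
    short_reads = io.read_fastq(out / "short_reads_S1.fastq")
    short_records = io.read_tsv(out / "short_records_S1.tsv")
    short_records = short_records[short_records.mapped].set_index("read_id")
    short_rows = []
    n_class = {"left": 0, "right": 0, "both": 0, "none": 0}
    for rid, seq in short_reads:
        cls, left, right = telomere_mod.classify_read(seq, config.short_params, rid)
        n_class[cls] += 1
        if cls == "none" or rid not in short_records.index:
            continue
        rec = short_records.loc[rid]
        for hit in (left, right):
            if hit is None:
                continue
            ref_class = hit.repeat_class if rec.strand == "+" else _FLIP[hit.repeat_class]
            short_rows.append(
                {
                    "read_id": rid,
                    "contig": rec.contig,
                    "start": int(rec.start),
                    "end": int(rec.end),
                    "strand": rec.strand,
                    "telomere_class": ref_class,
                    "run_length_bp": hit.run_length_bp,
                    "mismatches": hit.mismatches,
                }
            )
    io.write_tsv(
        pd.DataFrame(
            short_rows,
            columns=[
                "read_id", "contig", "start", "end", "strand",
                "telomere_class", "run_length_bp", "mismatches",
            ],
        ),
        out / "telomere_reads_short.tsv",
    )
    return {
        "n_minichromosome_calls": len(calls),
        "n_short_telomere_reads": len(short_rows),
        "short_read_classes": n_class,
    }


def stage_breakage(config: RunConfig) -> dict:
    out = _out(config)
    ref = _reference(config)
    lengths = {c: len(s) for c, s in ref.items()}
    short = io.read_tsv(out / "telomere_reads_short.tsv")
    long_ = io.read_tsv(out / "telomere_reads_long.tsv")
    track_short = breakage.window_counts(short, lengths, config.window_bp)
    track_long = breakage.window_counts(long_, lengths, config.window_bp)
    io.write_tsv(track_short, out / "track_short.tsv")
    io.write_tsv(track_long, out / "track_long.tsv")
    corr = breakage.correlate_tracks(track_short, track_long)
    io.write_tsv(
        pd.DataFrame(
            [{"comparison": "short_vs_long", "rho": corr.rho, "p_value": corr.p_value, "n_windows": corr.n}]
        ),
        out / "track_correlations.tsv",
    )
    combined = pd.concat([short, long_], ignore_index=True)
    regions = breakage.extract_motif_regions(
        combined, ref, config.motif_interval_bp, config.motif_min_reads
    )
    io.write_fasta(regions, out / "motif_regions.fasta")
    return {
        "rho_short_vs_long": corr.rho,
        "p_short_vs_long": corr.p_value,
        "n_windows": corr.n,
        "n_motif_regions": len(regions),
    }


def stage_cnv(config: RunConfig) -> dict:
    out = _out(config)
    ref = _reference(config)
    lengths = {c: len(s) for c, s in ref.items()}
    genes, _ = io.read_gff3(out / "genes.gff3")
    units = genes.rename(columns={"gene_id": "unit_id"})[["unit_id", "contig", "start", "end"]]
    contig_units = pd.DataFrame(
        [{"unit_id": c, "contig": c, "start": 0, "end": L} for c, L in lengths.items()]
    )
    strains = SimulationConfig(**dataclasses.asdict(config.simulation)).strains
    cn_frames = []
    contig_frames = []
    for strain in strains:
        records = io.read_tsv(out / f"short_records_{strain}.tsv")
        records = records[records.mapped]
        depth = copynumber.depth_from_alignments(records, units, lengths)
        cn = copynumber.normalized_copy_number(depth)
        cn["strain"] = strain
        cn_frames.append(cn)
        cdepth = copynumber.depth_from_alignments(records, contig_units, lengths)
        ccn = copynumber.normalized_copy_number(cdepth)
        ccn["strain"] = strain
        contig_frames.append(ccn)
    cn_all = pd.concat(cn_frames, ignore_index=True)
    io.write_tsv(cn_all, out / "cn_genes.tsv")
    io.write_tsv(pd.concat(contig_frames, ignore_index=True), out / "cn_contigs.tsv")

    s1 = cn_all[cn_all.strain == "S1"]
    summary, hist = copynumber.dosage_distribution(s1, config.dosage_low, config.dosage_high)
    io.write_tsv(hist, out / "dosage_hist.tsv")
    cv = copynumber.copy_number_cv(cn_all)
    io.write_tsv(cv, out / "cn_cv.tsv")
    groups = copynumber.assign_conservation_groups(cv, config.cv_quantile)
    io.write_tsv(groups, out / "cn_groups.tsv")
    expression = io.read_tsv(out / "expression.tsv")
    rho, p, n = copynumber.cn_expression_correlation(
        s1, expression[expression.strain == "S1"]
    )
    return {
        "dosage_fraction_outside": summary.fraction_outside,
        "n_genes_cv": len(cv),
        "group_size": int(groups.attrs["group_size"]),
        "cn_expression_rho": rho,
        "cn_expression_p": p,
        "cn_expression_n": n,
    }


def stage_alleles(config: RunConfig) -> dict:
    out = _out(config)
    allele_table = io.read_tsv(out / "alleles.tsv")
    scorer = alleles_mod.make_blast_like_scorer()
    func_rows = []
    subgroup_rows = []
    for locus, sub in allele_table.groupby("locus", sort=True):
        groups = alleles_mod.group_alleles(sub)
        for gi, g in enumerate(groups):
            subgroup_rows.append(
                {
                    "locus": locus,
                    "subgroup": gi,
                    "start_col": g.start_col,
                    "stop_col": g.stop_col,
                    "n_alleles": g.size,
                    "allele_ids": ",".join(g.allele_ids),
                }
            )
        fg = alleles_mod.select_functional_allele(locus, sub, scorer)
        func_rows.append(dataclasses.asdict(fg))
    functional = pd.DataFrame(func_rows)
    io.write_tsv(functional, out / "functional_genes.tsv")
    io.write_tsv(pd.DataFrame(subgroup_rows), out / "cds_subgroups.tsv")
    reps = allele_table.set_index("allele_id").loc[functional.representative]
    io.write_fasta(
        [(aid, row.cds_seq) for aid, row in reps.iterrows()], out / "functional_genes.fasta"
    )
    return {
        "n_loci": len(functional),
        "n_subgroups": len(subgroup_rows),
        "mean_subgroup_size": float(functional.subgroup_size.mean()),
    }


def stage_diversity(config: RunConfig) -> dict:
    out = _out(config)
    allele_table = io.read_tsv(out / "alleles.tsv")
    profile = alleles_mod.upstream_diversity_profile(
        allele_table, config.min_alleles_pi, config.max_upstream_bp
    )
    io.write_tsv(profile, out / "diversity_profile.tsv")
    informative = profile[profile.n_loci > 0]
    changepoint = alleles_mod.estimate_profile_changepoint(informative)
    return {
        "n_positions": int((profile.n_loci > 0).sum()),
        "profile_changepoint_bp": changepoint,
        "mean_pi_proximal": float(informative.mean_pi.iloc[:changepoint].mean()),
        "mean_pi_distal": float(informative.mean_pi.iloc[changepoint:].mean()),
    }


def stage_kaks(config: RunConfig) -> dict:
    out = _out(config)
    allele_table = io.read_tsv(out / "alleles.tsv")
    functional = io.read_tsv(out / "functional_genes.tsv")
    rows = []
    for f in functional.itertuples():
        sub = allele_table[
            (allele_table.locus == f.locus)
            & (allele_table.start_col == f.start_col)
            & (allele_table.stop_col == f.stop_col)
        ]
        mean_ratio = selection.gene_mean_kaks(sub, config.min_alleles_kaks)
        if mean_ratio is None:
            continue
        rows.append({"gene_id": f.locus, "mean_kaks": mean_ratio, "n_alleles": len(sub)})
    kaks = pd.DataFrame(rows)
    io.write_tsv(kaks, out / "kaks.tsv")
    return {"n_genes_kaks": len(kaks), "median_kaks": float(kaks.mean_kaks.median())}


def stage_groups(config: RunConfig) -> dict:
    out = _out(config)
    groups = io.read_tsv(out / "cn_groups.tsv")
    kaks = io.read_tsv(out / "kaks.tsv")
    expression = io.read_tsv(out / "expression.tsv")
    expr1 = expression[expression.strain == "S1"][["gene_id", "tpm"]]
    merged = groups.rename(columns={"unit_id": "gene_id"}).merge(kaks, on="gene_id", how="left")
    merged = merged.merge(expr1, on="gene_id", how="left")
    results = []
    whole_k = merged.mean_kaks.dropna()
    whole_e = merged.tpm.dropna()
    for grp in ("conserved", "non_conserved"):
        sel_k = merged[merged.group == grp].mean_kaks.dropna()
        if len(sel_k) and len(whole_k):
            u, p = selection.compare_groups(sel_k, whole_k)
            results.append(
                {"test": f"kaks_{grp}_vs_genome", "n_a": len(sel_k), "n_b": len(whole_k), "U": u, "p_value": p}
            )
        sel_e = merged[merged.group == grp].tpm.dropna()
        if len(sel_e) and len(whole_e):
            u, p = selection.compare_groups(sel_e, whole_e)
            results.append(
                {"test": f"expression_{grp}_vs_genome", "n_a": len(sel_e), "n_b": len(whole_e), "U": u, "p_value": p}
            )
    res = pd.DataFrame(results)
    io.write_tsv(res, out / "group_tests.tsv")
    return {r["test"]: r["p_value"] for r in results}


def stage_enrich(config: RunConfig) -> dict:
    out = _out(config)
    groups = io.read_tsv(out / "cn_groups.tsv")
    annotation = io.read_tsv(out / "go_annotation.tsv")
    background = groups.unit_id.tolist()
    report = {}
    for grp in ("conserved", "non_conserved"):
        gene_set = groups[groups.group == grp].unit_id.tolist()
        table = selection.go_enrichment(gene_set, background, annotation, config.min_go_genes)
        io.write_tsv(table, out / f"enrichment_{grp}.tsv")
        report[f"n_terms_tested_{grp}"] = len(table)
        report[f"n_terms_significant_{grp}"] = int((table.p_adjusted <= 0.05).sum())
    fam = pd.read_csv(out / "family_counts.tsv", sep="\t").set_index("family")
    with open(out / "family_totals.json") as fh:
        totals = json.load(fh)
    fam_res = selection.family_expansion_test(fam, totals, fam.columns[0])
    io.write_tsv(fam_res.reset_index(), out / "family_expansion.tsv")
    report["n_families_significant"] = int((fam_res.p_adjusted <= 0.05).sum())
    return report


def stage_cluster_test(config: RunConfig) -> dict:
    out = _out(config)
    groups = io.read_tsv(out / "cn_groups.tsv")
    genes, _ = io.read_gff3(out / "genes.gff3")
    conserved = groups[groups.group == "conserved"].unit_id.tolist()
    result = selection.cluster_bootstrap_test(
        conserved, genes, config.n_boot, config.cluster_dist_bp, seed=config.seed + 400
    )
    io.write_tsv(pd.DataFrame([dataclasses.asdict(result)]), out / "cluster_test.tsv")
    return dataclasses.asdict(result)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "telomeres": stage_telomeres,
    "breakage": stage_breakage,
    "cnv": stage_cnv,
    "alleles": stage_alleles,
    "diversity": stage_diversity,
    "kaks": stage_kaks,
    "groups": stage_groups,
    "enrich": stage_enrich,
    "cluster-test": stage_cluster_test,
}


def run_pipeline(config: RunConfig, stages: Optional[list[str]] = None) -> dict:
    """Run the requested stages (all by default) in dependency order.

    Writes the resolved configuration and a machine-readable run report
    into the run directory and returns the report.
    """
    out = _out(config)
    config.to_yaml(out / "run_config.yaml")
    report: dict = {"seed": config.seed, "version": _package_version()}
    todo = STAGES if stages is None else [s for s in STAGES if s in stages]
    for stage in todo:
        report[stage] = _STAGE_FUNCS[stage](config)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _package_version() -> str:
    from minichrom import __version__

    return __version__
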