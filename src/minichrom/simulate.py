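"""Seeded synthetic MAC-genome simulator with ground truth.

Emulates the statistical structure of a ciliate macronuclear genome the
downstream analyses assume: a gene-dense, AT-rich genome (GC ~ 28.8%)
with short intergenic regions and small GT..AG introns; minichromosomes
of 8-16 kb produced by hotspot-plus-background chromosome breakage with
(C4A2)n / (T2G4)n telomeres; per-minichromosome copy numbers with
planted conserved / variable gene classes; a panel of diverged strains
(2-4% divergence, two haplotypes each) carrying start/stop-altering
alleles; expression correlated with copy number; and both long
telomere-capped reads and short fragment reads.

Every quantity is drawn from a single seeded generator, so one seed
fully determines all outputs, byte for byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _CodonTable
from scipy.optimize import brentq

from minichrom.telomere import TELOMERE_UNITS, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_AA = dict(_CodonTable.unambiguous_dna_by_id[1].forward_table)
_COMP = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic MAC genome, with literature-scale defaults."""

    seed: int = 0
    n_contigs: int = 4
    contig_length_bp: int = 150_000
    gc_target: float = 0.288
    genes_per_contig: int = 70
    cds_length_bp: int = 1_400
    introns_per_gene: float = 2.4
    intron_length_bp: int = 25
    mean_intergenic_bp: int = 180
    telomere_units: tuple[str, str] = (TELOMERE_UNITS["C-rich"], TELOMERE_UNITS["G-rich"])
    telomere_length_bp: int = 60
    mini_len_range_bp: tuple[int, int] = (8_000, 16_000)
    n_minichromosomes: int = 1_200
    n_hotspots_per_contig: Optional[int] = None
    hotspot_sd_bp: float = 200.0
    background_breakage_weight: float = 0.05
    cn_base_sigma: float = 0.3
    cn_segment_sigma: float = 0.4
    cn_lognormal_sigma_conserved: float = 0.05
    cn_lognormal_sigma_variable: float = 0.8
    conserved_fraction: float = 0.25
    n_strains: int = 4
    strain_divergence: float = 0.03
    startstop_variant_rate: float = 0.15
    conserved_dn_keep: float = 0.25
    upstream_conserved_bp: int = 50
    long_read_count: int = 2_000
    short_read_coverage: float = 2.0
    read_length_bp: int = 150
    error_rate_long: float = 0.0
    error_rate_short: float = 0.0
    expression_noise_sigma: float = 0.5

    def __post_init__(self) -> None:
        fractions = {
            "gc_target": self.gc_target,
            "background_breakage_weight": self.background_breakage_weight,
            "conserved_fraction": self.conserved_fraction,
            "startstop_variant_rate": self.startstop_variant_rate,
            "conserved_dn_keep": self.conserved_dn_keep,
            "error_rate_long": self.error_rate_long,
            "error_rate_short": self.error_rate_short,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.mini_len_range_bp
        if not 0 < lo <= hi <= self.contig_length_bp:
            raise ValueError(
                "mini_len_range_bp must lie within (0, contig_length_bp]"
            )
        if self.strain_divergence > 0.5:
            raise ValueError(
                "strain_divergence > 0.5 breaks the gap-free alignment assumption"
            )
        for unit in self.telomere_units:
            if len(unit) != 6:
                raise ValueError("telomere units must be 6-mers")
        if revcomp(self.telomere_units[0]) != self.telomere_units[1]:
            raise ValueError("telomere units must be reverse complements")
        if self.telomere_length_bp % 6 != 0:
            raise ValueError("telomere_length_bp must be a multiple of the 6-bp unit")

    @property
    def strains(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_strains)]


@dataclass
class Genome:
    contigs: dict[str, str]
    genes: pd.DataFrame  # gene_id, contig, start, end, strand, cds, conservation_class
    exons: pd.DataFrame  # gene_id, exon_index, start, end
    hotspots: dict[str, np.ndarray]
    config: SimulationConfig


@dataclass
class SimulationTruth:
    """Planted ground truth: gene classes, minichromosomes, copy numbers."""

    genes: pd.DataFrame
    minis: pd.DataFrame  # mini_id, contig, start, end, conservation_class, cn_<strain>...
    gene_cn: pd.DataFrame  # gene_id, strain, true_cn
    expression: pd.DataFrame  # gene_id, strain, tpm, true_cn
    variants: pd.DataFrame  # locus, allele_id, pos, ref, alt


# ---------------------------------------------------------------------------
# Sequence building blocks
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _sense_codons() -> list[str]:
    return [
        "".join(c)
        for c in itertools.product("ACGT", repeat=3)
        if "".join(c) not in _STOPS
    ]


def codon_weights(gc_target: float) -> tuple[list[str], np.ndarray]:
    """Uniform-usage codon distribution tuned so expected GC = gc_target.

    Codons are weighted by independent per-base probabilities with a GC
    parameter theta; stop codons are excluded and the distribution
    renormalized, so theta is solved numerically to hit the target.
    """
    codons = _sense_codons()
    gc_counts = np.array([sum(b in "GC" for b in c) for c in codons], dtype=float)

    def expected_gc(theta: float) -> float:
        pb = {"A": (1 - theta) / 2, "T": (1 - theta) / 2, "G": theta / 2, "C": theta / 2}
        w = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in codons])
        w /= w.sum()
        return float((w * gc_counts).sum() / 3.0)

    theta = brentq(lambda t: expected_gc(t) - gc_target, 1e-4, 1 - 1e-4)
    pb = {"A": (1 - theta) / 2, "T": (1 - theta) / 2, "G": theta / 2, "C": theta / 2}
    w = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in codons])
    return codons, w / w.sum()


def _build_gene(
    rng: np.random.Generator,
    config: SimulationConfig,
    codons: list[str],
    weights: np.ndarray,
) -> tuple[str, str, list[tuple[int, int]]]:
    """One gene: returns (genomic sequence on '+', spliced CDS, exon intervals)."""
    n_codons = max(60, int(round(rng.normal(config.cds_length_bp, config.cds_length_bp / 4))) // 3)
    body = rng.choice(len(codons), size=n_codons - 2, p=weights)
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    cds = "ATG" + "".join(codons[i] for i in body) + stop
    n_introns = min(int(rng.poisson(config.introns_per_gene)), len(cds) // 50)
    if n_introns > 0:
        cut_points = np.sort(
            rng.choice(np.arange(30, len(cds) - 30), size=n_introns, replace=False)
        )
    else:
        cut_points = np.array([], dtype=int)
    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    prev = 0
    pos = 0
    for cut in cut_points:
        exon = cds[prev:cut]
        intron_len = int(rng.integers(20, 32))
        intron = "GT" + _random_bases(rng, intron_len - 4, config.gc_target).tobytes().decode() + "AG"
        pieces.append(exon)
        exons.append((pos, pos + len(exon)))
        pos += len(exon)
        pieces.append(intron)
        pos += len(intron)
        prev = cut
    pieces.append(cds[prev:])
    exons.append((pos, pos + len(cds) - prev))
    return "".join(pieces), cds, exons


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def generate_genome(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> Genome:
    """Generate reference contigs with non-overlapping gene models.

    Raises ValueError when the requested genes cannot fit on a contig.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    codons, weights = codon_weights(config.gc_target)
    contigs: dict[str, str] = {}
    gene_rows = []
    exon_rows = []
    hotspot_map: dict[str, np.ndarray] = {}
    gene_counter = 0
    for ci in range(config.n_contigs):
        cname = f"contig_{ci + 1}"
        L = config.contig_length_bp
        seq = _random_bases(rng, L, config.gc_target)
        pos = 40 + int(rng.exponential(config.mean_intergenic_bp))
        contig_genes = []
        for gi in range(config.genes_per_contig):
            genomic, cds, exons = _build_gene(rng, config, codons, weights)
            strand = "+" if rng.random() < 0.5 else "-"
            glen = len(genomic)
            if pos + glen > L - 40:
                raise ValueError(
                    f"genes cannot fit: contig {cname} of {L} bp exhausted at "
                    f"{pos} bp after {gi} of {config.genes_per_contig} genes "
                    f"(next gene needs {glen} bp)"
                )
            if strand == "-":
                placed = revcomp(genomic)
                exon_abs = [(pos + glen - e, pos + glen - s) for s, e in exons][::-1]
            else:
                placed = genomic
                exon_abs = [(pos + s, pos + e) for s, e in exons]
            seq[pos : pos + glen] = np.frombuffer(placed.encode(), dtype=np.uint8)
            gene_id = f"g{gene_counter + 1:05d}"
            gene_counter += 1
            contig_genes.append((gene_id, pos, pos + glen, strand, cds))
            for k, (s, e) in enumerate(exon_abs):
                exon_rows.append({"gene_id": gene_id, "exon_index": k, "start": s, "end": e})
            pos += glen + max(40, int(rng.exponential(config.mean_intergenic_bp)))
        contigs[cname] = seq.tobytes().decode()

        hotspots = _place_hotspots(rng, config, contig_genes, L)
        hotspot_map[cname] = hotspots
        # Conservation classes are assigned to breakage segments (genes inherit
        # the class of the segment containing their midpoint); the outermost
        # hotspots are not class boundaries, so the short contig-edge segments
        # merge with their neighbours and genes share the class of the
        # minichromosomes that cover them.  Segments are filled in shuffled
        # order until the conserved gene fraction is met.
        boundaries = _class_boundaries(hotspots)
        n_seg = len(boundaries) + 1
        seg_genes = np.zeros(n_seg, dtype=int)
        for _, s, e, _, _ in contig_genes:
            seg_genes[int(np.searchsorted(boundaries, (s + e) // 2))] += 1
        seg_class = np.array(["variable"] * n_seg, dtype=object)
        target = config.conserved_fraction * len(contig_genes)
        acc = 0
        for si in rng.permutation(n_seg):
            if acc + seg_genes[si] <= target + 1:
                seg_class[si] = "conserved"
                acc += seg_genes[si]
        for gene_id, s, e, strand, cds in contig_genes:
            seg = int(np.searchsorted(boundaries, (s + e) // 2))
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "contig": cname,
                    "start": s,
                    "end": e,
                    "strand": strand,
                    "cds": cds,
                    "conservation_class": seg_class[seg],
                }
            )
    genes = pd.DataFrame(gene_rows)
    exons = pd.DataFrame(exon_rows)
    return Genome(contigs, genes, exons, hotspot_map, config)


def _place_hotspots(
    rng: np.random.Generator,
    config: SimulationConfig,
    contig_genes: list[tuple],
    L: int,
) -> np.ndarray:
    """Breakage hotspots, preferentially in intergenic gaps, spaced so that
    consecutive-hotspot spans fall inside the minichromosome length range."""
    lo, hi = config.mini_len_range_bp
    mids = []
    prev_end = 0
    for _, s, e, _, _ in contig_genes:
        if s - prev_end >= 30:
            mids.append((prev_end + s) // 2)
        prev_end = e
    if L - prev_end >= 30:
        mids.append((prev_end + L) // 2)
    mids_arr = np.array(sorted(mids))

    if config.n_hotspots_per_contig is not None:
        n = config.n_hotspots_per_contig
        targets = np.linspace(0, L, n + 2)[1:-1]
        out = []
        for t in targets:
            if len(mids_arr) and abs(mids_arr - t).min() < 1500:
                out.append(int(mids_arr[np.abs(mids_arr - t).argmin()]))
            else:
                out.append(int(t))
        return np.unique(np.array(out, dtype=int))

    out = []
    h = int(rng.uniform(1000, 3000))
    if len(mids_arr) and abs(mids_arr - h).min() < 1500:
        h = int(mids_arr[np.abs(mids_arr - h).argmin()])
    out.append(h)
    margin = int(3 * config.hotspot_sd_bp) + 600
    while True:
        target = h + rng.uniform(lo + margin + 500, hi - margin - 500)
        if target > L - lo / 2:
            break
        window = mids_arr[(mids_arr >= h + lo + margin) & (mids_arr <= h + hi - margin)]
        if len(window):
            h = int(window[np.abs(window - target).argmin()])
        else:
            h = int(target)
        out.append(h)
    return np.array(sorted(set(out)), dtype=int)


# ---------------------------------------------------------------------------
# Minichromosome pool
# ---------------------------------------------------------------------------


def _class_boundaries(hotspots: np.ndarray) -> np.ndarray:
    """Hotspots acting as conservation-class boundaries (outermost excluded)."""
    return hotspots[1:-1] if len(hotspots) >= 2 else hotspots[:0]


def _junction_clean_left(seq: str, pos: int, unit: str) -> bool:
    # The six genomic bases following a left telomere must all break the
    # repeat continuation, so the telomere-genome junction is unambiguous
    # even under a 5-mismatch scan budget.
    if pos < 0 or pos + 6 > len(seq):
        return False
    return all(seq[pos + j] != unit[j] for j in range(6))


def _junction_clean_right(seq: str, pos: int, unit: str) -> bool:
    if pos - 6 < 0 or pos > len(seq):
        return False
    return all(seq[pos - 6 + j] != unit[j] for j in range(6))


def _nudge(
    seq: str,
    pos: int,
    side: str,
    units: tuple[str, str],
    allowed: Optional[np.ndarray] = None,
) -> int:
    """Nearest breakpoint to ``pos`` with an unambiguous telomere junction.

    ``allowed`` optionally restricts breakpoints to permitted positions
    (used to keep breakage out of gene bodies so depth-based dosage
    matches containment-based truth exactly)."""
    check = _junction_clean_left if side == "left" else _junction_clean_right
    unit = units[0] if side == "left" else units[1]
    for delta in range(0, 30_000):
        for p in ((pos + delta, pos - delta) if delta else (pos,)):
            if allowed is not None and not (0 <= p < len(allowed) and allowed[p]):
                continue
            if check(seq, p, unit):
                return p
    raise RuntimeError(f"no clean junction near {pos}")  # pragma: no cover


def _intergenic_mask(genome: Genome, cname: str) -> np.ndarray:
    """True at positions where a breakpoint does not split a gene."""
    mask = np.ones(len(genome.contigs[cname]) + 1, dtype=bool)
    for g in genome.genes[genome.genes.contig == cname].itertuples():
        mask[g.start + 1 : g.end] = False
    return mask


def generate_minichromosome_pool(
    genome: Genome,
    config: Optional[SimulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Breakage-derived minichromosomes with per-strain copy numbers.

    Breakpoints come from a mixture of Gaussian jitter around hotspot
    pairs and a uniform background; lengths are rejection-sampled into
    the configured range.  Breakpoints are then nudged to the nearest
    position whose flanking bases break the telomeric repeat, keeping
    telomere-genome junctions unambiguous.  Every gene is guaranteed to
    be fully contained in at least one minichromosome.  Copy numbers are
    lognormal: a shared baseline per minichromosome times a per-strain
    factor whose sigma depends on the planted conservation class.
    """
    config = config or genome.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.mini_len_range_bp
    units = config.telomere_units
    contig_names = list(genome.contigs)
    lengths = np.array([len(genome.contigs[c]) for c in contig_names], dtype=float)
    alloc = np.floor(config.n_minichromosomes * lengths / lengths.sum()).astype(int)
    alloc[: config.n_minichromosomes - alloc.sum()] += 1

    rows = []
    for cname, n_here in zip(contig_names, alloc):
        seq = genome.contigs[cname]
        L = len(seq)
        hotspots = genome.hotspots[cname]
        for _ in range(n_here):
            if rng.random() < config.background_breakage_weight or len(hotspots) == 0:
                left = rng.uniform(0, max(L - lo, 1))
                right = left + rng.uniform(lo, min(hi, L - left))
            else:
                i = int(rng.integers(len(hotspots)))
                left = hotspots[i] + rng.normal(0, config.hotspot_sd_bp)
                right = None
                if i + 1 < len(hotspots):
                    for _attempt in range(20):
                        cand = hotspots[i + 1] + rng.normal(0, config.hotspot_sd_bp)
                        if lo <= cand - left <= hi:
                            right = cand
                            break
                if right is None:
                    right = left + rng.uniform(lo, hi)
            left = int(np.clip(left, 0, L - lo))
            right = int(np.clip(right, left + 100, L))
            rows.append((cname, left, right))

    masks = {c: _intergenic_mask(genome, c) for c in contig_names}
    nudged: list[tuple[str, int, int]] = []
    for cname, left, right in rows:
        seq = genome.contigs[cname]
        nudged.append(
            (
                cname,
                _nudge(seq, left, "left", units, masks[cname]),
                _nudge(seq, right, "right", units, masks[cname]),
            )
        )

    # Rescue minichromosomes so every gene lies on at least one (checked on
    # post-nudge coordinates; rescues are themselves nudged and re-verified).
    covered: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_names}
    for cname, left, right in nudged:
        covered[cname].append((left, right))
    for g in genome.genes.itertuples():
        if any(s <= g.start and e >= g.end for s, e in covered[g.contig]):
            continue
        seq = genome.contigs[g.contig]
        glen = g.end - g.start
        for margin in (100, 400, 1600):
            length = max(int(rng.uniform(lo, hi)), glen + 2 * margin)
            left = max(0, g.start - int(rng.integers(margin, max(margin + 1, length - glen - margin))))
            right = min(len(seq), left + length)
            left = _nudge(seq, left, "left", units, masks[g.contig])
            right = _nudge(seq, right, "right", units, masks[g.contig])
            if left <= g.start and right >= g.end:
                nudged.append((g.contig, left, right))
                covered[g.contig].append((left, right))
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not cover gene {g.gene_id}")

    mini_rows = []
    for k, (cname, left, right) in enumerate(nudged):
        boundaries = _class_boundaries(genome.hotspots[cname])
        seg = int(np.searchsorted(boundaries, (left + right) // 2))
        mini_rows.append(
            {
                "mini_id": f"m{k + 1:05d}",
                "contig": cname,
                "start": left,
                "end": right,
                "segment": seg,
            }
        )
    minis = pd.DataFrame(mini_rows)
    if minis.empty:
        raise ValueError("empty minichromosome pool")

    # Class per minichromosome from its midpoint segment.
    seg_class = {}
    genes = genome.genes
    for cname in contig_names:
        boundaries = _class_boundaries(genome.hotspots[cname])
        sub = genes[genes.contig == cname]
        classes = {}
        for g in sub.itertuples():
            classes.setdefault(
                int(np.searchsorted(boundaries, (g.start + g.end) // 2)), g.conservation_class
            )
        seg_class[cname] = classes
    minis["conservation_class"] = [
        seg_class[r.contig].get(r.segment, "variable") for r in minis.itertuples()
    ]

    n = len(minis)
    # Minichromosomes from the same breakage segment share a dosage factor
    # (they carry the same genes), on top of an independent per-mini term;
    # this gives gene-level dosage the broad right-skewed spread seen at
    # the whole-genome level.
    seg_keys = pd.factorize(minis.contig.astype(str) + ":" + minis.segment.astype(str))[0]
    n_segments = seg_keys.max() + 1
    seg_factor = rng.lognormal(0.0, config.cn_segment_sigma, n_segments)
    base = seg_factor[seg_keys] * rng.lognormal(0.0, config.cn_base_sigma, n)
    sigma = np.where(
        minis.conservation_class.to_numpy() == "conserved",
        config.cn_lognormal_sigma_conserved,
        config.cn_lognormal_sigma_variable,
    )
    # The class sigma acts at the segment level per strain (minis carrying
    # the same genes drift together under amitosis), with a small
    # proportional per-mini jitter on top; a gene's cross-strain CV then
    # reflects its planted class rather than shrinking with the number of
    # minichromosomes that cover it.
    seg_sigma = np.zeros(n_segments)
    seg_sigma[seg_keys] = sigma
    # Each strain's total pool dosage is pinned to genome mean 1 (constant
    # total MAC DNA content), as depth-based relative copy number assumes.
    # The variable-class minis absorb the strain-to-strain remainder, so
    # the cross-strain CV of dosage-conserved genes stays at its planted
    # level instead of tracking fluctuations of the strain total.
    glen = (minis.end - minis.start).to_numpy()
    genome_len = float(sum(len(genome.contigs[c]) for c in contig_names))
    is_var = minis.conservation_class.to_numpy() != "conserved"
    pool_len = float(glen.sum())
    if is_var.any() and (~is_var).any():
        # Conserved minis get a strain-independent scale matching their
        # genomic share, so their cross-strain CV stays at the planted
        # level; variable minis absorb each strain's remainder, pinning
        # the total pool dosage to genome mean 1 per strain.
        cons_share = float(glen[~is_var].sum()) / pool_len
        k_cons = cons_share * genome_len / float((base[~is_var] * glen[~is_var]).sum())
    else:
        cons_share, k_cons = 0.0, 1.0
    for strain in config.strains:
        z_seg = rng.normal(0.0, 1.0, n_segments)
        z_mini = rng.normal(0.0, 1.0, n)
        cn = base * np.exp(z_seg[seg_keys] * seg_sigma[seg_keys] + z_mini * 0.1 * sigma)
        if is_var.any() and (~is_var).any():
            cn[~is_var] *= k_cons
            cons_total = float((cn[~is_var] * glen[~is_var]).sum())
            var_total = float((cn[is_var] * glen[is_var]).sum())
            cn[is_var] *= (genome_len - cons_total) / var_total
        else:
            cn *= genome_len / float((cn * glen).sum())
        minis[f"cn_{strain}"] = cn
    return minis.drop(columns=["segment"])


def true_gene_copy_numbers(genome: Genome, minis: pd.DataFrame) -> pd.DataFrame:
    """Per-gene true copy number = sum over minichromosomes fully containing it."""
    config = genome.config
    records = []
    for cname, sub in minis.groupby("contig", sort=False):
        genes = genome.genes[genome.genes.contig == cname]
        starts = sub.start.to_numpy()
        ends = sub.end.to_numpy()
        cn = {s: sub[f"cn_{s}"].to_numpy() for s in config.strains}
        for g in genes.itertuples():
            mask = (starts <= g.start) & (ends >= g.end)
            for s in config.strains:
                records.append(
                    {"gene_id": g.gene_id, "strain": s, "true_cn": float(cn[s][mask].sum())}
                )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    shift = rng.integers(1, 4, size=len(hits))
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    arr[hits] = _BASES[(lut[arr[hits]] + shift) % 4]
    return arr.tobytes().decode()


def _molecule(genome: Genome, config: SimulationConfig, contig: str, start: int, end: int) -> str:
    tel = config.telomere_length_bp // 6
    return (
        config.telomere_units[0] * tel
        + genome.contigs[contig][start:end]
        + config.telomere_units[1] * tel
    )


def simulate_long_reads(
    genome: Genome,
    minis: pd.DataFrame,
    config: SimulationConfig,
    strain: str,
    rng: np.random.Generator,
    count: Optional[int] = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Full-length minichromosome reads with telomeres at both ends.

    Sampling probability is proportional to the minichromosome's copy
    number in the given strain; each read is reverse-complemented with
    probability 0.5 and optionally corrupted by uniform substitutions.
    """
    count = config.long_read_count if count is None else count
    if count <= 0:
        raise ValueError("long read count must be positive")
    cn = minis[f"cn_{strain}"].to_numpy()
    p = cn / cn.sum()
    draws = rng.multinomial(count, p)
    reads = []
    records = []
    ridx = 0
    for mi, k in enumerate(draws):
        if k == 0:
            continue
        row = minis.iloc[mi]
        mol = _molecule(genome, config, row.contig, row.start, row.end)
        for _ in range(k):
            seq = mol
            strand = "+"
            if rng.random() < 0.5:
                seq = revcomp(seq)
                strand = "-"
            seq = _apply_errors(seq, config.error_rate_long, rng)
            rid = f"long_{strain}_{ridx + 1:06d}"
            ridx += 1
            reads.append((rid, seq))
            records.append(
                {
                    "read_id": rid,
                    "contig": row.contig,
                    "start": int(row.start),
                    "end": int(row.end),
                    "strand": strand,
                    "mini_id": row.mini_id,
                }
            )
    return reads, pd.DataFrame(records)


def simulate_short_reads(
    genome: Genome,
    minis: pd.DataFrame,
    config: SimulationConfig,
    strain: str,
    rng: np.random.Generator,
    coverage: Optional[float] = None,
    with_sequences: bool = False,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Uniform short fragments from the minichromosome pool.

    Coverage is defined against the summed genomic length of the pool;
    fragments overlapping a molecule end retain the telomeric remnant.
    Returns alignment records with true reference coordinates (telomeric
    overhang lengths included as columns) and, optionally, sequences.
    """
    coverage = config.short_read_coverage if coverage is None else coverage
    if coverage <= 0:
        raise ValueError("short-read coverage must be positive")
    rl = config.read_length_bp
    tel = config.telomere_length_bp
    glens = (minis.end - minis.start).to_numpy()
    full = glens + 2 * tel
    cn = minis[f"cn_{strain}"].to_numpy()
    n_reads = int(round(coverage * glens.sum() / rl))
    w = cn * full
    idx = rng.choice(len(minis), size=n_reads, p=w / w.sum())
    off = np.floor(rng.random(n_reads) * (full[idx] - rl + 1)).astype(int)
    minus = rng.random(n_reads) < 0.5

    g_start = minis.start.to_numpy()[idx]
    gl = glens[idx]
    gs = np.maximum(off - tel, 0)
    ge = np.minimum(off + rl - tel, gl)
    mapped = ge > gs
    tel_left = np.maximum(tel - off, 0)
    tel_left = np.minimum(tel_left, rl)
    tel_right = np.maximum(off + rl - (tel + gl), 0)
    tel_right = np.minimum(tel_right, rl)

    records = pd.DataFrame(
        {
            "read_id": [f"short_{strain}_{i + 1:07d}" for i in range(n_reads)],
            "contig": minis.contig.to_numpy()[idx],
            "start": g_start + gs,
            "end": g_start + ge,
            "strand": np.where(minus, "-", "+"),
            "mini_id": minis.mini_id.to_numpy()[idx],
            "telomere_left_bp": tel_left,
            "telomere_right_bp": tel_right,
            "mapped": mapped,
        }
    )
    seqs: list[tuple[str, str]] = []
    if with_sequences:
        molecules: dict[int, str] = {}
        rows = minis[["contig", "start", "end"]].to_numpy(dtype=object)
        read_ids = records.read_id.to_numpy()
        for i in range(n_reads):
            mi = int(idx[i])
            if mi not in molecules:
                c, s, e = rows[mi]
                molecules[mi] = _molecule(genome, config, c, int(s), int(e))
            frag = molecules[mi][off[i] : off[i] + rl]
            if minus[i]:
                frag = revcomp(frag)
            frag = _apply_errors(frag, config.error_rate_short, rng)
            seqs.append((read_ids[i], frag))
    return records, seqs


# ---------------------------------------------------------------------------
# Strain panel: alleles and expression
# ---------------------------------------------------------------------------


def _mutate_cds(
    cds: str, rate: float, rng: np.random.Generator, dn_keep: float = 1.0
) -> tuple[str, list[tuple[int, str, str]]]:
    """Substitute bases at the given rate, avoiding new in-frame stops and
    leaving the start and stop codons untouched.

    dn_keep < 1 models purifying selection: a substitution that changes
    the encoded amino acid is retained only with that probability.
    """
    arr = list(cds)
    n = len(arr)
    positions = np.nonzero(rng.random(n) < rate)[0]
    muts = []
    for pos in positions:
        if pos < 3 or pos >= n - 3:
            continue
        old = arr[pos]
        choices = [b for b in "ACGT" if b != old]
        order = rng.permutation(3)
        for oi in order:
            new = choices[oi]
            c0 = 3 * (pos // 3)
            old_codon = "".join(arr[c0 : c0 + 3])
            codon = "".join(arr[c0:pos]) + new + "".join(arr[pos + 1 : c0 + 3])
            if codon in _STOPS:
                continue
            if _AA.get(codon) != _AA.get(old_codon) and rng.random() > dn_keep:
                break  # nonsynonymous change purged by selection
            arr[pos] = new
            muts.append((int(pos), old, new))
            break
    return "".join(arr), muts


def generate_strain_panel(
    genome: Genome,
    truth_cn: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-locus alleles for each strain (2 haplotypes), expression, variants.

    Each haplotype is independently diverged from the reference CDS at
    the configured rate (gap-free, so alleles share a trivial alignment).
    A configured fraction of alleles receive a start- or stop-altering
    variant, shifting their (start, stop) alignment columns.  Upstream
    sequences are mutated only beyond the conserved promoter zone.
    Expression is true copy number times lognormal noise, TPM-scaled.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    genes = genome.genes
    allele_rows = []
    variant_rows = []
    upstream_avail = _upstream_lengths(genome)
    for g in genes.itertuples():
        cds = g.cds
        n_cod = len(cds) // 3
        up_len = upstream_avail[g.gene_id]
        up_ref = _upstream_sequence(genome, g, up_len)
        for strain in config.strains:
            for hap in (1, 2):
                allele_id = f"{g.gene_id}|{strain}|h{hap}"
                dn_keep = (
                    config.conserved_dn_keep
                    if g.conservation_class == "conserved"
                    else 1.0
                )
                seq, muts = _mutate_cds(cds, config.strain_divergence, rng, dn_keep)
                start_col, stop_col = 0, len(cds) - 3
                if rng.random() < config.startstop_variant_rate:
                    if rng.random() < 0.5:  # premature stop
                        j = int(rng.integers(n_cod // 4, 3 * n_cod // 4))
                        seq = seq[: 3 * j] + "TAA" + seq[3 * j + 3 :]
                        stop_col = 3 * j
                    else:  # start shift to a downstream in-frame ATG
                        k = int(rng.integers(2, 9))
                        seq = "ATA" + seq[3 : 3 * k] + "ATG" + seq[3 * k + 3 :]
                        start_col = 3 * k
                up_seq = _mutate_upstream(up_ref, config, rng)
                for pos, old, new in muts:
                    variant_rows.append(
                        {"locus": g.gene_id, "allele_id": allele_id, "pos": pos, "ref": old, "alt": new}
                    )
                allele_rows.append(
                    {
                        "locus": g.gene_id,
                        "allele_id": allele_id,
                        "strain": strain,
                        "haplotype": hap,
                        "cds_seq": seq,
                        "start_col": start_col,
                        "stop_col": stop_col,
                        "upstream_seq": up_seq,
                        "upstream_len": up_len,
                    }
                )
    alleles = pd.DataFrame(allele_rows)
    variants = pd.DataFrame(variant_rows, columns=["locus", "allele_id", "pos", "ref", "alt"])

    cn_wide = truth_cn.pivot(index="gene_id", columns="strain", values="true_cn")
    expr_rows = []
    for strain in config.strains:
        cn = cn_wide[strain].reindex(genes.gene_id).to_numpy()
        noise = rng.lognormal(0.0, config.expression_noise_sigma, len(genes))
        raw = cn * noise
        tpm = raw / raw.sum() * 1e6
        for gid, t, c in zip(genes.gene_id, tpm, cn):
            expr_rows.append({"gene_id": gid, "strain": strain, "tpm": float(t), "true_cn": float(c)})
    expression = pd.DataFrame(expr_rows)
    return alleles, expression, variants


def _upstream_lengths(genome: Genome) -> dict[str, int]:
    out = {}
    for cname, sub in genome.genes.groupby("contig", sort=False):
        sub = sub.sort_values("start")
        starts = sub.start.to_numpy()
        ends = sub.end.to_numpy()
        L = len(genome.contigs[cname])
        for i, g in enumerate(sub.itertuples()):
            if g.strand == "+":
                prev_end = ends[i - 1] if i > 0 else 0
                avail = g.start - prev_end
            else:
                next_start = starts[i + 1] if i + 1 < len(sub) else L
                avail = next_start - g.end
            out[g.gene_id] = int(min(500, max(avail, 0)))
    return out


def _upstream_sequence(genome: Genome, gene, up_len: int) -> str:
    """Upstream sequence indexed so character 0 is position 1 (the first
    base upstream of the translation start)."""
    seq = genome.contigs[gene.contig]
    if gene.strand == "+":
        return seq[gene.start - up_len : gene.start][::-1]
    return seq[gene.end : gene.end + up_len].translate(_COMP)


def _mutate_upstream(ref: str, config: SimulationConfig, rng: np.random.Generator) -> str:
    arr = list(ref)
    hits = np.nonzero(rng.random(len(arr)) < config.strain_divergence)[0]
    for pos in hits:
        if pos < config.upstream_conserved_bp:
            continue  # promoter-proximal zone is conserved
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(3))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Annotation-style side tables
# ---------------------------------------------------------------------------


def generate_go_annotation(
    genes: pd.DataFrame, rng: np.random.Generator, n_terms: int = 20
) -> pd.DataFrame:
    """Synthetic GO-style annotation (gene_id, term), 1-3 terms per gene.

    Two designated terms are biased toward the conserved / variable
    dosage classes so enrichment of the conservation groups has planted
    signal; the rest are assigned uniformly.
    """
    terms = [f"GO:{7000000 + i}" for i in range(n_terms)]
    rows = []
    for g in genes.itertuples():
        k = int(rng.integers(1, 4))
        chosen = set(rng.choice(n_terms, size=k, replace=False).tolist())
        if g.conservation_class == "conserved" and rng.random() < 0.6:
            chosen.add(0)  # housekeeping-like term
        if g.conservation_class == "variable" and rng.random() < 0.6:
            chosen.add(1)  # environment-response-like term
        for t in sorted(chosen):
            rows.append({"gene_id": g.gene_id, "term": terms[t]})
    return pd.DataFrame(rows)


def generate_family_counts(
    rng: np.random.Generator,
    n_families: int = 60,
    species: tuple[str, ...] = ("focal", "relative_a", "relative_b"),
    n_expanded: int = 6,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Synthetic family x species gene-count table with planted expansions.

    Most families have similar per-species proportions; n_expanded
    families carry a 4-8x excess in the focal species.
    """
    totals = {sp: int(rng.integers(12_000, 18_000)) for sp in species}
    counts = {}
    for fi in range(n_families):
        base = int(rng.integers(2, 40))
        row = {}
        for sp in species:
            lam = base * totals[sp] / 15_000
            if sp == species[0] and fi < n_expanded:
                lam *= rng.uniform(4, 8)
            row[sp] = int(rng.poisson(lam))
        counts[f"FAM{fi + 1:04d}"] = row
    table = pd.DataFrame(counts).T[list(species)]
    return table, totals


# ---------------------------------------------------------------------------
# One-call orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    genome: Genome
    minis: pd.DataFrame
    truth: SimulationTruth
    alleles: pd.DataFrame


def simulate_all(config: SimulationConfig) -> SimulationResult:
    """Genome -> minichromosome pool -> strain panel, fully seeded."""
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    minis = generate_minichromosome_pool(genome, config, rng)
    gene_cn = true_gene_copy_numbers(genome, minis)
    alleles, expression, variants = generate_strain_panel(genome, gene_cn, config, rng)
    truth = SimulationTruth(
        genes=genome.genes.drop(columns=["cds"]),
        minis=minis,
        gene_cn=gene_cn,
        expression=expression,
        variants=variants,
    )
    return SimulationResult(genome, minis, truth, alleles)
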