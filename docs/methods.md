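# Methods

This note records the models and procedures `minichrom` implements, the
choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Telomere-run detection

A telomeric run at a read end is a window anchored at the terminus (or
within `max_end_offset_bp` of it; default 0 for short reads, 100 for
long reads) scored against the periodic 6-bp repeat — C-rich `CCCCAA`
or G-rich `TTGGGG` — in all six phases. A window qualifies if its
length is at least `min_run_bp`, it contains at most `max_mismatches`
mismatching bases (`N` always mismatches), and its innermost base
matches the repeat. Platform presets are 18 bp / 1 mismatch (short
accurate reads) and 30 bp / 5 mismatches (long noisy reads). Among
qualifying windows the scanner returns the longest, breaking ties by
fewer mismatches, then the C-rich class, then the lowest phase index —
a fully deterministic rule.

Two points deserve emphasis:

- *Inner-edge-match rule.* Without it, a maximal-window definition
  would extend a clean 18-bp run into flanking sequence through
  trailing mismatches whenever budget remains, inflating run lengths
  with non-telomeric bases. Requiring the innermost base to match makes
  the reported run end on repeat sequence while still counting internal
  mismatches.
- *Greedy equals exhaustive.* For a fixed anchor, greedy inward
  extension that stops when the next mismatch would exceed the budget
  finds exactly the longest qualifying window, so the implementation is
  checkable against a brute-force enumeration of every
  (class, phase, window) combination; the test suite enforces exact
  agreement on planted and adversarial reads.

A read is classified `both` (a full-length minichromosome) when its two
ends carry qualifying runs of *opposite* repeat classes; classification
is invariant under reverse complement with left/right exchanged. The
trimmed length (read length minus both runs and anchor offsets) is the
minichromosome's genomic span.

## Breakage profiling

Each telomere-classified read contributes one point position: the
reference coordinate of its first non-telomeric base (left boundary for
C-rich hits, right boundary for G-rich). Point semantics — rather than
full-overlap counting — keeps the count-conservation property exact
(window counts sum to the number of reads) and matches counting *reads*
per window. Windows tile each contig from coordinate 0 (2 kb by
default); the final partial window is kept and normalized by its true
length. Track comparisons use Spearman's ρ with average ranks for ties;
the p-value uses the t approximation for n ≥ 10 windows and exact
permutation enumeration below that. Motif-region extraction works at
0.5-kb intervals, emits intervals with ≥ 4 telomere-containing reads in
either the left-class or right-class track (tracked separately), and
removes telomeric repeat stretches of ≥ 12 bp (any phase, either class)
before output.

## Copy number and conservation groups

Relative copy number of a unit (gene or contig) is
`(summed depth / length) / (total depth / total length)`; the
length-weighted genome mean is therefore exactly 1, which the tests
assert to 1e-9. The dosage band summary counts units below 0.67× and
above 1.5×. The coefficient of variation per gene across strains uses
the sample (n−1) standard deviation — material with four strains — and
is recorded as such. Conservation groups are assigned by rank, not by
CV threshold: the bottom floor(qN) genes by CV (ties broken by gene id)
form the conserved group and the top floor(qN) the non-conserved group,
so group sizes are exact and assignment is deterministic. Genes with
zero mean CN are flagged undefined and excluded.

## Functional-allele selection and diversity

Alleles of a locus sharing identical start and stop alignment columns
form a CDS subgroup. The subgroup with the most alleles defines the
functional gene; when the top two counts differ by at most one, the
longer coding region wins, then (a tie-break the procedure leaves open)
the subgroup spanning more strains, then coordinates. The
representative allele maximizes the mean pairwise alignment bit score
against the other members: global protein alignment under BLOSUM62 with
affine gaps 11/1, raw score converted to bits via the Karlin–Altschul
formula (λ·S − ln K)/ln 2 with the matrix's standard ungapped constants
(λ = 0.3176, K = 0.134). The scorer is pluggable, so a local-alignment
bit score can be substituted. Global alignment is the default because
subgroup members are homologous full-length CDS translations.

Per-site nucleotide diversity is π = 2pqn/(n−1) with p the major-allele
frequency; columns with more than two bases pool all non-major alleles
into q, preserving the biallelic formula. Gaps and N are excluded from
n; columns with n < 2 are undefined. The upstream profile averages π
per position (position 1 = first base upstream of the start codon)
across loci whose chosen subgroup has ≥ 5 alleles, truncating each
locus at the neighbouring gene and at 500 bp. A two-level least-squares
step fit estimates the position where diversity rises — the edge of the
constrained promoter-proximal zone.

## Selection statistics

*Ka/Ks* uses the Nei–Gojobori (1986) counting estimator: fractional
synonymous-site counts from each codon's nine single-step neighbours
(mutations creating stop codons count as nonsynonymous, so S + N is
exactly 3 per codon), differences averaged over all minimal
substitution pathways with stop-containing pathways excluded (all
pathways are used in the rare case every one is blocked), and the
Jukes–Cantor correction d = −¾·ln(1 − 4p/3), undefined at p ≥ ¾.
Gapped codons are stripped as triplets; internal stops are errors. The
counting estimator was chosen over maximum-likelihood codon models
because it is transparent and verifiable against exhaustive
enumeration (the tests check all 61×61 sense-codon pairs); ML and
counting estimates are not numerically interchangeable, a compatibility
caveat for comparisons against ML-derived values. The standard nuclear
genetic code is the default; the ciliate code (table 6, TAA/TAG → Gln)
is available as a parameter. Per-gene values average the defined
pairwise ratios of subgroups with ≥ 4 alleles.

*Group contrasts* use the Mann–Whitney U test — exact enumeration when
both groups have ≤ 20 untied values, the tie-corrected normal
approximation otherwise. *Enrichment* is the upper-tail hypergeometric
P(X ≥ k) with terms annotated to fewer than 3 background genes removed
before testing, the score (k/n)/(K/N), and Benjamini–Hochberg step-up
adjustment. *Family expansions* z-transform per-species proportions
with the population (n-denominator) standard deviation and test the
focal species against the pooled others with a pooled-variance
two-proportion z-test — the pooling choice resolves an ambiguity in how
a "two-proportional test" applies to three species. *Clustering* joins
consecutive same-contig genes whose start-to-previous-end gap is ≤ 500
bp (overlaps always join; clusters need ≥ 2 genes); the bootstrap null
draws equal-size gene sets without replacement, and the one-sided
empirical p-value carries a +1 correction so it is never zero.

## The synthetic MAC generator

The generator's defaults are the study conditions: GC 28.8%, 2.4
introns per gene (GT..AG, ~20–30 bp), short intergenic regions (mean
180 bp), minichromosomes of 8–16 kb, four strains at 3% divergence
(within the observed 2.1–4.0% range) with two haplotypes each, a 15%
start/stop-variant rate, 60-bp telomeres, and lognormal dosage with
class sigmas 0.05 (conserved) and 0.8 (variable). One seed determines
every output byte-for-byte.

Design choices that shape what the simulation can and cannot show:

- *Codon model.* Uniform codon usage with independent per-base GC
  tuned numerically so the expected coding GC equals the target; stop
  codons only at CDS ends. Realized contig GC lands within ±0.01 of
  target for contigs ≥ 100 kb.
- *Breakage model.* Hotspots are placed in intergenic gaps at spacings
  compatible with the length range; a minichromosome spans a
  consecutive hotspot pair with Gaussian jitter (sd 200 bp), plus a 5%
  uniform background; lengths are rejection-sampled into range.
- *Unambiguous junctions.* Breakpoints are nudged (deterministically,
  to the nearest valid position) so the six genomic bases flanking each
  junction all break the telomeric repeat continuation. Without this, a
  mismatch-tolerant maximal-run scan would legitimately extend a few
  bases into genomic sequence wherever it happens to continue the
  repeat, and exact length recovery would be undefined rather than
  merely hard. Real junctions carry no such guarantee; recovery being
  *exact* on simulated data says the scanner finds precisely the
  planted run, not that real telomere boundaries are unambiguous.
- *Breakpoints avoid gene bodies.* Valid breakpoints are restricted to
  intergenic positions so every minichromosome either fully contains a
  gene or misses it, making depth-based dosage equal containment-based
  truth. Real breakage places an appreciable share of telomere-addition
  sites inside coding regions; this generator does not emulate that,
  so partial-gene dosage effects are untested.
- *Dosage structure.* Each breakage segment carries a shared lognormal
  factor (σ = 0.4, common to strains), and the class-specific strain
  factor acts at the segment level (minis carrying the same genes drift
  together under amitosis) with a small per-mini jitter. Each strain's
  total pool dosage is pinned to genome mean 1 — constant total MAC DNA
  content — by letting the variable class absorb the remainder;
  otherwise strain-total fluctuations would leak into every conserved
  gene's CV through depth normalization. Conservation classes are
  assigned to segments (edge segments merge with neighbours) in
  shuffled order until the planted conserved fraction (default 25%,
  matching the bottom-quartile grouping) is met. Because classes are
  spatially blocked, planted conserved genes are also physically
  clustered — which is what the cluster bootstrap is meant to detect.
- *Strain panel.* Haplotypes mutate independently at the divergence
  rate, never touching start/stop codons and resampling substitutions
  that would create in-frame stops. Conserved-class genes retain
  amino-acid-changing substitutions with probability 0.25 (purifying
  selection), giving the Ka/Ks group contrast planted signal. Upstream
  mutations are suppressed within 50 bp of the start codon, the
  constrained-promoter zone the diversity profile should recover.
  Expression is true copy number times lognormal noise (σ = 0.5),
  TPM-scaled.
- *Reads.* Long reads are complete minichromosome molecules (both
  telomeres), sampled proportionally to copy number,
  reverse-complemented with probability 0.5; short reads are uniform
  fragments of the telomere-capped molecule, so end fragments retain
  telomeric remnants. Coverage is defined against the summed genomic
  length of the pool. The error model is uniform substitutions only;
  indels are not simulated, which keeps telomere-run positions exact.
  Telomere length must be a multiple of the 6-bp unit (default 60 bp),
  keeping both junction phases fixed.

Not simulated: IES excision, haplotype phasing beyond independent
divergence, clonal aging, intra-gene breakage, indel errors, GC
heterogeneity along contigs, and any motif structure at breakage sites
(hotspot positions are sequence-independent, so motif-region extraction
is exercised only as a mechanical contract).

## Numerical and scale choices

Exact permutation tests switch to asymptotics at n = 10 (Spearman) and
group size 20 (Mann–Whitney). Quantile-group sizes use floor(qN) with
rank-based membership. The bootstrap uses 1,000 draws by default.
Default pipeline scale (4 contigs × 150 kb, 280 genes, 1,200
minichromosomes, 4 strains) is chosen so a full run completes in
minutes on one CPU; the test suite and the acceptance script use
2-contig (100 kb) genomes with 400 minichromosomes, 2,000-mini pools
for length-recovery checks, 50× coverage for copy-number recovery, and
a 2,000-locus panel for the diversity profile. Statistical conclusions
at these scales transfer qualitatively, not numerically, to real
26.8-Mb-scale genomes.

## Known limitations

The NG86 estimator and the BLOSUM62 global-alignment bit score stand in
for the ML Ka/Ks and local-alignment scores a full reanalysis would
use; both substitutions are documented above and behind pluggable
interfaces. The generator's lognormal dosage model is a stand-in — the
shape of the real minichromosome copy-number distribution is not
established. GO annotations are taken as given (no ontology-graph
propagation). Alignment of alleles is assumed (the generator emits
gap-free homologous alleles); no de novo multiple alignment is
performed.
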