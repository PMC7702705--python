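"""Format readers/writers: FASTA, FASTQ, GFF3, BED, TSV.

Internal coordinates are 0-based half-open everywhere; GFF3 is written
1-based inclusive and BED 0-based half-open, converting at the boundary.
All writers are deterministic (fixed ordering, no timestamps), so
identically seeded runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: truncated FASTQ ({len(lines)} lines)")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"{path}: malformed record at line {i + 1}")
        if len(seq) != len(qual):
            raise ValueError(
                f"{path}: sequence/quality length mismatch at line {i + 1}"
            )
        out.append((header[1:].split()[0], seq))
    return out


def write_gff3(genes: pd.DataFrame, exons: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as GFF3 (gene + mRNA + exon features, 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        exon_groups = dict(iter(exons.groupby("gene_id", sort=False)))
        for g in genes.itertuples():
            gid = g.gene_id
            fh.write(
                f"{g.contig}\tminichrom\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{g.contig}\tminichrom\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            ex = exon_groups.get(gid)
            if ex is not None:
                for e in ex.sort_values("start").itertuples():
                    fh.write(
                        f"{g.contig}\tminichrom\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t"
                        f"Parent={gid}.t1\n"
                    )


def read_gff3(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse GFF3 gene models back to 0-based half-open gene/exon tables."""
    gene_rows, exon_rows = [], []
    exon_counter: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 record at line {ln}")
            contig, _, ftype, start, end, _, strand, _, attrs = fields
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gene_rows.append(
                    {
                        "gene_id": attr["ID"],
                        "contig": contig,
                        "start": int(start) - 1,
                        "end": int(end),
                        "strand": strand,
                    }
                )
            elif ftype == "exon":
                gid = attr["Parent"].rsplit(".t1", 1)[0]
                idx = exon_counter.get(gid, 0)
                exon_counter[gid] = idx + 1
                exon_rows.append(
                    {
                        "gene_id": gid,
                        "exon_index": idx,
                        "start": int(start) - 1,
                        "end": int(end),
                    }
                )
    return pd.DataFrame(gene_rows), pd.DataFrame(exon_rows)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """BED (0-based half-open); expects columns contig, start, end and
    optionally name, score."""
    cols = ["contig", "start", "end"]
    for opt in ("name", "score"):
        if opt in intervals.columns:
            cols.append(opt)
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    names = ["contig", "start", "end", "name", "score"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
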