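"""Readers and writers for the standard text formats the pipeline consumes.

GTF (Gencode attribute dialect), BED3/BED6, TSV count tables with a sidecar
condition map, and FASTA (via Biopython).  GTF's 1-based inclusive
coordinates are converted to the package-internal 0-based half-open
convention on read and back on write.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CountTable, ExonModel, GenomeInterval, TranscriptModel

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class ParseError(ValueError):
    pass


def read_gtf(path, source: str = "reference") -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    Exons are grouped per transcript and ranked in transcription direction
    (reverse genomic order on the minus strand).
    """
    exons: dict[str, list[tuple[GenomeInterval, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            attr = dict(_ATTR_RE.findall(attrs))
            if "transcript_id" not in attr or "gene_id" not in attr:
                raise ParseError(
                    f"{path}: line {lineno}: exon lacks gene_id/transcript_id attributes"
                )
            iv = GenomeInterval(chrom, start_i - 1, end_i, strand)
            exons.setdefault(attr["transcript_id"], []).append((iv, attr["gene_id"]))
    out = []
    for tid in sorted(exons):
        ivs = exons[tid]
        gene_id = ivs[0][1]
        strand = ivs[0][0].strand
        ordered = sorted((iv for iv, _ in ivs), key=lambda iv: iv.start, reverse=strand == "-")
        models = [ExonModel(iv, rank=i + 1) for i, iv in enumerate(ordered)]
        out.append(TranscriptModel(tid, gene_id, models, source=source))
    return out


def write_gtf(transcripts: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for tx in sorted(transcripts, key=lambda t: (t.chrom, t.span.start, t.transcript_id)):
            for exon in tx.exons:
                iv = exon.interval
                fh.write(
                    f"{iv.chrom}\tafexon\texon\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";\n'
                )


def read_bed(path, scored: bool = False):
    """Read BED3/BED6 records as (GenomeInterval, score-or-None) pairs."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end")
            strand = fields[5] if len(fields) >= 6 else "."
            score = None
            if scored:
                if len(fields) < 5:
                    raise ParseError(f"{path}: line {lineno}: scored BED needs >= 5 fields")
                score = float(fields[4])
            out.append((GenomeInterval(chrom, start, end, strand), score))
    return out


def write_bed(records: Iterable, path) -> None:
    """Write (interval, name, score) triples (name/score optional) as BED6."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomeInterval):
                iv, name, score = rec, ".", 0
            else:
                iv = rec[0]
                name = rec[1] if len(rec) > 1 else "."
                score = rec[2] if len(rec) > 2 else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def read_counts(counts_path, conditions_path) -> CountTable:
    """Read a feature-by-sample TSV count table plus its sample->condition map."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    cond = pd.read_csv(conditions_path, sep="\t", header=None, names=["sample", "condition"])
    return CountTable(counts.astype(int), dict(zip(cond["sample"], cond["condition"])))


def write_counts(table: CountTable, counts_path, conditions_path) -> None:
    table.counts.to_csv(counts_path, sep="\t")
    with open(conditions_path, "w") as fh:
        for s in table.sample_ids:
            fh.write(f"{s}\t{table.condition_of[s]}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def package_data(name: str) -> Path:
    return Path(__file__).parent / "data" / name
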