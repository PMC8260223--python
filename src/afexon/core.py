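"""Shared genomic coordinate types, interval algebra and multiple-testing correction.

All coordinates are 0-based half-open (BED convention) throughout the
package; GTF input/output is converted at the boundary.  A single internal
convention keeps the event builder, window arithmetic and peak overlaps free
of off-by-one drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when an input record violates a documented invariant."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class ExonModel:
    """An exon with its 1-based order along the direction of transcription."""

    interval: GenomeInterval
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValidationError(f"exon rank must be >= 1, got {self.rank}")


@dataclass
class TranscriptModel:
    """A transcript as an ordered chain of exons.

    ``source`` distinguishes reference-annotation transcripts from isoform
    models assembled from long reads; the distinction drives event novelty
    and known/novel TSS classification downstream.
    """

    transcript_id: str
    gene_id: str
    exons: list[ExonModel]
    source: str = "reference"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.interval.chrom for e in self.exons}
        strands = {e.interval.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id} mixes chromosomes/strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.rank)
        ranks = [e.rank for e in self.exons]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError(
                f"transcript {self.transcript_id} exon ranks not 1..n: {ranks}"
            )
        ivs = sorted((e.interval.start, e.interval.end) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )
        if self.source not in ("reference", "longread"):
            raise ValidationError(f"unknown transcript source {self.source!r}")

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom,
            min(e.interval.start for e in self.exons),
            max(e.interval.end for e in self.exons),
            self.strand,
        )

    @property
    def first_exon(self) -> ExonModel:
        return self.exons[0]

    @property
    def last_exon(self) -> ExonModel:
        return self.exons[-1]

    def junctions(self) -> list["SpliceJunction"]:
        """Splice junctions in transcription order.

        Genomic orientation is preserved in the record (donor_end <
        acceptor_start regardless of strand).
        """
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            ia, ib = a.interval, b.interval
            if self.strand == "-":
                # transcription right-to-left: exon a is genomically right of b
                out.append(SpliceJunction(self.chrom, ib.end, ia.start, self.strand))
            else:
                out.append(SpliceJunction(self.chrom, ia.end, ib.start, self.strand))
        return out


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """An intron in genomic orientation: (end of left exon, start of right exon)."""

    chrom: str
    donor_end: int
    acceptor_start: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValidationError(
                f"junction {self.chrom}:{self.donor_end}-{self.acceptor_start} "
                "has intron length < 1"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def intron(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.donor_end, self.acceptor_start, self.strand)

    def up_site(self) -> int:
        """Splice site of the transcription-upstream exon (the 5' donor)."""
        return self.acceptor_start if self.strand == "-" else self.donor_end

    def down_site(self) -> int:
        """Splice site of the transcription-downstream exon (the 3' acceptor)."""
        return self.donor_end if self.strand == "-" else self.acceptor_start


@dataclass
class CountTable:
    """Non-negative integer counts per (feature, sample) plus a condition map."""

    counts: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate feature ids in count table")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        missing = [s for s in self.counts.columns if s not in self.condition_of]
        if missing:
            raise ValidationError(f"samples without a condition: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def row_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return seen


# ---------------------------------------------------------------------------
# interval algebra


def _trees(
    intervals: Sequence[GenomeInterval], stranded: bool
) -> dict[tuple, IntervalTree]:
    trees: dict[tuple, IntervalTree] = {}
    for iv in intervals:
        key = (iv.chrom, iv.strand) if stranded else (iv.chrom,)
        trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def intersect(
    a: Sequence[GenomeInterval],
    b: Sequence[GenomeInterval],
    mode: str = "overlap",
    stranded: bool = False,
) -> list:
    """Overlap query between two interval sets (half-open semantics).

    mode="overlap" returns ``(a_member, [overlapping b_members])`` for every
    a-member with at least one overlap; mode="no_overlap" returns the
    a-members with none (the ``intersectBed -v`` behaviour).
    """
    if mode not in ("overlap", "no_overlap"):
        raise ValidationError(f"unknown intersect mode {mode!r}")
    trees = _trees(b, stranded)
    hits, misses = [], []
    for iv in a:
        key = (iv.chrom, iv.strand) if stranded else (iv.chrom,)
        tree = trees.get(key)
        found = sorted((h.data for h in tree.overlap(iv.start, iv.end))) if tree else []
        if found:
            hits.append((iv, found))
        else:
            misses.append(iv)
    return hits if mode == "overlap" else misses


def merge_near(
    intervals: Iterable[GenomeInterval],
    max_gap: int = 0,
    closed: bool = False,
) -> list[GenomeInterval]:
    """Merge intervals whose gap is below ``max_gap``, transitively.

    The default is strict (gap < max_gap merges); ``closed=True`` switches to
    gap <= max_gap, the ``bedtools merge -d`` convention.  Strand is ignored
    (peaks are unstranded); output is sorted and disjoint.
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    merged: list[GenomeInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom:
            gap = iv.start - merged[-1].end
            if gap < max_gap or (closed and gap == max_gap) or gap < 0:
                prev = merged.pop()
                iv = GenomeInterval(iv.chrom, prev.start, max(prev.end, iv.end), ".")
                merged.append(iv)
                continue
        merged.append(GenomeInterval(iv.chrom, iv.start, iv.end, "."))
    return merged


def bh_adjust(pvalues: Sequence) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries stay NaN.

    Missing values are excluded from the number of tests m, matching
    standard practice when some features are untested.
    """
    p = np.asarray([np.nan if v is None else float(v) for v in pvalues], dtype=float)
    mask = ~np.isnan(p)
    if mask.any():
        vals = p[mask]
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError("p-values must lie in [0, 1]")
        adj = multipletests(vals, method="fdr_bh")[1]
        out = np.full(p.shape, np.nan)
        out[mask] = adj
        return out
    return p
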