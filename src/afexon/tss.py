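"""Transcript start sites: extraction, known/novel classification, CAGE support."""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .core import GenomeInterval, TranscriptModel, ValidationError, intersect


def extract_tss(transcripts: Sequence[TranscriptModel]) -> pd.DataFrame:
    """One single-base TSS record per transcript.

    The TSS is the genomic start of the rank-1 exon on +, and the last base
    (end - 1) of the rank-1 exon on -.  Unstranded transcripts are an error:
    a TSS is undefined without a direction of transcription.
    """
    rows = []
    for tx in transcripts:
        if tx.strand == ".":
            raise ValidationError(f"transcript {tx.transcript_id}: TSS undefined without strand")
        fe = tx.first_exon.interval
        pos = fe.end - 1 if tx.strand == "-" else fe.start
        rows.append(
            {
                "transcript_id": tx.transcript_id,
                "gene_id": tx.gene_id,
                "chrom": tx.chrom,
                "pos": pos,
                "strand": tx.strand,
                "source": tx.source,
            }
        )
    return pd.DataFrame(rows)


def reference_tss_set(transcripts: Sequence[TranscriptModel]) -> pd.DataFrame:
    """Distinct 1-bp starts of the reference-source transcripts."""
    tss = extract_tss([t for t in transcripts if t.source == "reference"])
    return tss[["chrom", "pos", "strand"]].drop_duplicates().reset_index(drop=True)


def _iv(row, slack: int = 0) -> GenomeInterval:
    return GenomeInterval(row["chrom"], max(0, row["pos"] - slack), row["pos"] + 1 + slack, row["strand"])


def classify_tss(
    tss: pd.DataFrame,
    reference_tss: pd.DataFrame,
    slack: int = 0,
    stranded: bool = True,
) -> pd.DataFrame:
    """Label each TSS known/novel by overlap with the reference start set.

    A TSS is known when its 1-bp interval, widened by +/- ``slack``, touches
    a reference start; comparison is strand-aware by default.
    """
    if slack < 0:
        raise ValidationError("slack must be >= 0")
    ref = [_iv(r) for _, r in reference_tss.iterrows()]
    out = tss.copy()
    queries = [_iv(r, slack) for _, r in tss.iterrows()]
    hit_ivs = {id(a) for a, _ in intersect(queries, ref, mode="overlap", stranded=stranded)}
    out["status"] = ["known" if id(q) in hit_ivs else "novel" for q in queries]
    return out


def cage_support(
    tss: pd.DataFrame,
    cage_peaks: Sequence[tuple[GenomeInterval, float]],
    truth_peaks: Optional[Sequence[GenomeInterval]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-TSS CAGE peak support and known/novel summary.

    Each TSS gets its matched peak count and best score; the summary holds
    the score distributions stratified by status and, when a
    classifier-true peak set is supplied, the fraction of known and novel
    TSSs overlapping it.  CAGE peaks are unstranded, so matching ignores
    strand.
    """
    peak_ivs = [iv for iv, _ in cage_peaks]
    score_of = {}
    for iv, score in cage_peaks:
        score_of.setdefault((iv.chrom, iv.start, iv.end), score)
    out = tss.copy()
    npeaks, best = [], []
    queries = [_iv(r) for _, r in tss.iterrows()]
    matched = {id(a): bs for a, bs in intersect(queries, peak_ivs, mode="overlap")}
    for q in queries:
        hits = matched.get(id(q), [])
        npeaks.append(len(hits))
        scores = [score_of[(h.chrom, h.start, h.end)] for h in hits]
        scores = [s for s in scores if s is not None]
        best.append(max(scores) if scores else 0.0)
    out["cage_peaks"] = npeaks
    out["best_cage_score"] = best

    summary: dict = {"score_distribution": {}, "true_overlap_fraction": {}}
    if "status" in out.columns:
        for status, sub in out.groupby("status"):
            supported = sub[sub["cage_peaks"] > 0]
            summary["score_distribution"][status] = sorted(supported["best_cage_score"])
        if truth_peaks is not None:
            tqueries = queries
            true_hit = {
                id(a) for a, _ in intersect(tqueries, list(truth_peaks), mode="overlap")
            }
            flags = [id(q) in true_hit for q in tqueries]
            out["classifier_true"] = flags
            for status, sub in out.groupby("status"):
                summary["true_overlap_fraction"][status] = (
                    float(sub["classifier_true"].mean()) if len(sub) else 0.0
                )
        else:
            summary["true_overlap_fraction"] = None
    return out, summary
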