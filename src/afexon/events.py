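"""Alternative-splicing event construction, classification and PSI quantification.

Events are built from transcript structures plus a splice-junction universe.
Each event carries >= 2 candidate isoforms; per-sample abundance is the raw
count divided by the candidate's effective length (exon lengths plus a fixed
per-junction sequence length), and PSI is the percent contribution of a
candidate to the event total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CountTable,
    GenomeInterval,
    SpliceJunction,
    TranscriptModel,
    ValidationError,
)

EVENT_TYPES = ("AFE", "ALE", "CASSETTE", "MXE", "A5SS", "A3SS", "IR")

#: junction "sequence length" used as the effective length of a junction part;
#: 88 for short-read-only runs, 238 for the merged long-read annotation run.
DEFAULT_JCN_SEQ_LEN = 88


@dataclass(frozen=True)
class IsoformCandidate:
    """One candidate isoform path of an event: exon parts + junction parts."""

    label: str
    exon_parts: tuple[GenomeInterval, ...] = ()
    junction_parts: tuple[SpliceJunction, ...] = ()

    def effective_length(self, jcn_seq_len: int = DEFAULT_JCN_SEQ_LEN) -> int:
        length = sum(len(iv) for iv in self.exon_parts)
        length += jcn_seq_len * len(self.junction_parts)
        if length <= 0:
            raise ValidationError(f"candidate {self.label} has effective length 0")
        return length


@dataclass
class ASEvent:
    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    candidates: list[IsoformCandidate]
    inclusion_index: int = 0
    novelty: str = "K"

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type}")
        if len(self.candidates) < 2:
            raise ValidationError(f"event {self.event_id} needs >= 2 candidates")
        if self.novelty not in ("K", "N"):
            raise ValidationError(f"novelty must be K or N, got {self.novelty}")

    def row_id(self, candidate: int) -> str:
        return f"{self.event_id}|{self.candidates[candidate].label}"


def isoform_abundance(count: float, effective_length: float) -> float:
    """Length-normalized abundance: read count / effective isoform length."""
    if effective_length <= 0:
        raise ValidationError("effective_length must be > 0")
    if count < 0:
        raise ValidationError("count must be >= 0")
    return count / effective_length


def compute_psi(inclusion_abundance: float, exclusion_abundance: float) -> Optional[float]:
    """PSI = 100 * inclusion / (inclusion + exclusion); None when undefined."""
    if inclusion_abundance < 0 or exclusion_abundance < 0:
        raise ValidationError("abundances must be >= 0")
    total = inclusion_abundance + exclusion_abundance
    if total == 0:
        return None
    return 100.0 * inclusion_abundance / total


# ---------------------------------------------------------------------------
# event construction


def _tx_junction_sites(tx: TranscriptModel) -> list[tuple[int, int]]:
    """Junctions of a transcript as (up_site, down_site) in transcription sense."""
    return [(j.up_site(), j.down_site()) for j in tx.junctions()]


def _first_exon_key(iv: GenomeInterval) -> tuple:
    return (iv.start, iv.end)


def _disjoint(ivs: Sequence[GenomeInterval]) -> bool:
    s = sorted(ivs, key=lambda iv: (iv.start, iv.end))
    return all(a.end <= b.start for a, b in zip(s, s[1:]))


def _mk_junction(chrom: str, strand: str, up: int, down: int) -> SpliceJunction:
    if strand == "-":
        return SpliceJunction(chrom, down, up, strand)
    return SpliceJunction(chrom, up, down, strand)


def build_events(
    transcripts: Sequence[TranscriptModel],
    junction_universe: Optional[Iterable[SpliceJunction]] = None,
) -> list[ASEvent]:
    """Classify AFE/ALE/cassette/MXE/A5SS/A3SS/IR events per gene.

    AFE: distinct, non-overlapping first exons whose first junctions share
    one downstream acceptor; overlapping alternatives at a shared acceptor
    are alternative 5' splice sites instead (symmetrically at last exons for
    ALE vs A3SS).  Novelty is "N" when any candidate part is absent from the
    reference-source transcripts.  Output is deterministic and sorted.
    """
    genes: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        genes.setdefault(tx.gene_id, []).append(tx)

    extra_juncs = set(junction_universe) if junction_universe else set()

    # known parts from reference transcripts, for novelty labelling
    known_exons: set[tuple] = set()
    known_juncs: set[SpliceJunction] = set()
    for tx in transcripts:
        if tx.source == "reference":
            for e in tx.exons:
                known_exons.add((e.interval.chrom, e.interval.start, e.interval.end, e.interval.strand))
            known_juncs.update(tx.junctions())

    events: list[ASEvent] = []
    for gene_id in sorted(genes):
        txs = sorted(genes[gene_id], key=lambda t: t.transcript_id)
        chrom, strand = txs[0].chrom, txs[0].strand
        gene_juncs = {j for tx in txs for j in tx.junctions()}
        gene_juncs |= {j for j in extra_juncs if j.chrom == chrom}
        junc_sites = {(j.up_site(), j.down_site()) for j in gene_juncs}
        raw: list[tuple[tuple, str, list[IsoformCandidate], int]] = []

        # --- AFE / A5SS: first junctions grouped by shared downstream acceptor
        fe_groups: dict[int, dict[tuple, tuple[GenomeInterval, SpliceJunction]]] = {}
        for tx in txs:
            jx = tx.junctions()
            if not jx:
                continue
            first_j = jx[0]
            fe = tx.first_exon.interval
            fe_groups.setdefault(first_j.down_site(), {})[_first_exon_key(fe)] = (fe, first_j)
        for anchor, members in fe_groups.items():
            if len(members) < 2:
                continue
            pairs = [members[k] for k in sorted(members)]
            etype = "AFE" if _disjoint([fe for fe, _ in pairs]) else "A5SS"
            cands = [
                IsoformCandidate(
                    label=f"{fe.start}-{fe.end}", exon_parts=(fe,), junction_parts=(j,)
                )
                for fe, j in pairs
            ]
            raw.append(((0, anchor), etype, cands, 0))

        # --- ALE / A3SS: last junctions grouped by shared upstream donor
        le_groups: dict[int, dict[tuple, tuple[GenomeInterval, SpliceJunction]]] = {}
        for tx in txs:
            jx = tx.junctions()
            if not jx:
                continue
            last_j = jx[-1]
            le = tx.last_exon.interval
            le_groups.setdefault(last_j.up_site(), {})[_first_exon_key(le)] = (le, last_j)
        for anchor, members in le_groups.items():
            if len(members) < 2:
                continue
            pairs = [members[k] for k in sorted(members)]
            etype = "ALE" if _disjoint([le for le, _ in pairs]) else "A3SS"
            cands = [
                IsoformCandidate(
                    label=f"{le.start}-{le.end}", exon_parts=(le,), junction_parts=(j,)
                )
                for le, j in pairs
            ]
            raw.append(((1, anchor), etype, cands, 0))

        # --- CASSETTE and MXE: internal exons keyed by flanking splice sites
        internal: dict[tuple[int, int], dict[tuple, tuple[GenomeInterval, SpliceJunction, SpliceJunction]]] = {}
        for tx in txs:
            jx = tx.junctions()
            for i, exon in enumerate(tx.exons[1:-1], start=1):
                up_j, down_j = jx[i - 1], jx[i]
                key = (up_j.up_site(), down_j.down_site())
                internal.setdefault(key, {})[_first_exon_key(exon.interval)] = (
                    exon.interval,
                    up_j,
                    down_j,
                )
        for (up, down), members in internal.items():
            skip = (up, down) in junc_sites
            exon_items = [members[k] for k in sorted(members)]
            if skip:
                skip_j = _mk_junction(chrom, strand, up, down)
                for iv, up_j, down_j in exon_items:
                    incl = IsoformCandidate(
                        label=f"incl_{iv.start}-{iv.end}",
                        exon_parts=(iv,),
                        junction_parts=(up_j, down_j),
                    )
                    excl = IsoformCandidate(label="skip", junction_parts=(skip_j,))
                    raw.append(((2, iv.start), "CASSETTE", [incl, excl], 0))
            elif len(exon_items) >= 2 and _disjoint([iv for iv, _, _ in exon_items]):
                cands = [
                    IsoformCandidate(
                        label=f"{iv.start}-{iv.end}",
                        exon_parts=(iv,),
                        junction_parts=(up_j, down_j),
                    )
                    for iv, up_j, down_j in exon_items
                ]
                raw.append(((3, up), "MXE", cands, 0))

        # --- IR: a junction whose intron is fully covered by an exon of a sibling
        all_exons = sorted(
            {(e.interval.start, e.interval.end) for tx in txs for e in tx.exons}
        )
        retained_src = {
            (e.interval.start, e.interval.end): tx.source
            for tx in txs
            for e in tx.exons
        }
        for j in sorted(gene_juncs):
            for es, ee in all_exons:
                if es < j.donor_end and ee > j.acceptor_start:
                    intron = GenomeInterval(chrom, j.donor_end, j.acceptor_start, strand)
                    incl = IsoformCandidate(
                        label=f"retained_{intron.start}-{intron.end}",
                        exon_parts=(intron,),
                    )
                    excl = IsoformCandidate(label="spliced", junction_parts=(j,))
                    novel_ir = retained_src[(es, ee)] == "longread" and (
                        (chrom, es, ee, strand) not in known_exons
                    )
                    raw.append(((4, j.donor_end), "IR", [incl, excl], 1 if novel_ir else 0))
                    break

        # materialise with deterministic ids and novelty labels
        counters: dict[str, int] = {}
        for _key, etype, cands, force_novel in sorted(raw, key=lambda r: (r[1], r[0])):
            counters[etype] = counters.get(etype, 0) + 1
            novelty = "K"
            for c in cands:
                for iv in c.exon_parts:
                    if etype != "IR" and (iv.chrom, iv.start, iv.end, iv.strand) not in known_exons:
                        novelty = "N"
                for jp in c.junction_parts:
                    if jp not in known_juncs:
                        novelty = "N"
            if force_novel:
                novelty = "N"
            events.append(
                ASEvent(
                    event_id=f"{gene_id}:{etype}:{counters[etype]}",
                    event_type=etype,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    candidates=list(cands),
                    inclusion_index=0,
                    novelty=novelty,
                )
            )
    events.sort(key=lambda e: e.event_id)
    return events


# ---------------------------------------------------------------------------
# PSI tables


@dataclass
class PsiTable:
    """Per-(event, candidate, sample) PSI plus supporting abundances.

    ``psi`` and ``abundance`` are indexed by event/candidate row ids
    ("<event_id>|<candidate label>"); ``totals`` holds the per-event raw
    count totals used for the missing-data threshold.  PSI is NaN wherever
    the event's total raw count in that sample fell below the threshold.
    """

    psi: pd.DataFrame
    abundance: pd.DataFrame
    totals: pd.DataFrame
    meta: pd.DataFrame  # row_id -> event_id, candidate label/index, type, novelty, gene
    condition_of: dict[str, str]

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.psi.columns if self.condition_of[s] == condition]


def psi_table(
    events: Sequence[ASEvent],
    counts: CountTable,
    count_threshold: int = 10,
    jcn_seq_len: int = DEFAULT_JCN_SEQ_LEN,
) -> PsiTable:
    """Quantify per-candidate PSI for every event and sample.

    Candidate PSI is 100 * abundance / sum of candidate abundances; a
    sample's PSIs for an event are missing when the event's total raw count
    in that sample is below ``count_threshold``.
    """
    rows = []
    meta_rows = []
    for ev in events:
        for idx, cand in enumerate(ev.candidates):
            rid = ev.row_id(idx)
            if rid not in counts.counts.index:
                raise KeyError(
                    f"no count row for event {ev.event_id} candidate {cand.label}"
                )
            rows.append(rid)
            meta_rows.append(
                {
                    "row_id": rid,
                    "event_id": ev.event_id,
                    "candidate": cand.label,
                    "candidate_index": idx,
                    "event_type": ev.event_type,
                    "novelty": ev.novelty,
                    "gene_id": ev.gene_id,
                    "effective_length": cand.effective_length(jcn_seq_len),
                }
            )
    meta = pd.DataFrame(meta_rows).set_index("row_id")
    raw = counts.counts.loc[rows].astype(float)
    abundance = raw.div(meta["effective_length"], axis=0)

    ab_sum = abundance.groupby(meta["event_id"]).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = 100.0 * abundance / ab_sum
    totals_by_event = raw.groupby(meta["event_id"]).sum()
    totals = totals_by_event.loc[meta["event_id"]].set_axis(meta.index)
    psi = psi.where(totals >= count_threshold)
    return PsiTable(
        psi=psi,
        abundance=abundance,
        totals=totals_by_event,
        meta=meta.drop(columns=["effective_length"]),
        condition_of=dict(counts.condition_of),
    )


def isoform_usage(
    assignments: CountTable,
    gene_of: Mapping[str, str],
    promoter_of: Optional[Mapping[str, str]] = None,
    predominance_threshold: float = 10.0,
) -> pd.DataFrame:
    """Per-transcript usage (% of gene total per sample) and predominance.

    A transcript is predominant in a sample when it carries at least
    ``predominance_threshold`` percent of its gene's expression there.  When
    ``promoter_of`` groups transcripts by promoter, per-group usage columns
    are the sums of member usages.
    """
    counts = assignments.counts.astype(float)
    genes = pd.Series({t: gene_of[t] for t in counts.index})
    gene_tot = counts.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = 100.0 * counts / gene_tot
    usage = usage.where(gene_tot > 0)
    out = usage.copy()
    out.columns = [f"usage_{c}" for c in usage.columns]
    out.insert(0, "gene_id", genes)
    for c in usage.columns:
        out[f"predominant_{c}"] = usage[c] >= predominance_threshold
    if promoter_of is not None:
        out["promoter"] = pd.Series({t: promoter_of.get(t) for t in counts.index})
    return out


def promoter_group_usage(usage: pd.DataFrame) -> pd.DataFrame:
    """Sum per-transcript usage within (gene, promoter) groups."""
    if "promoter" not in usage.columns:
        raise ValidationError("usage table lacks a promoter column")
    cols = [c for c in usage.columns if c.startswith("usage_")]
    return usage.groupby(["gene_id", "promoter"])[cols].sum()


def write_event_table(psi: PsiTable, counts: CountTable, path) -> None:
    """Event/candidate table with per-sample raw counts (TSV)."""
    tbl = psi.meta.copy()
    for s in counts.sample_ids:
        tbl[s] = counts.counts.loc[tbl.index, s]
    tbl.to_csv(path, sep="\t")
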