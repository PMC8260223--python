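"""Synthetic data with a complete ground-truth ledger.

The generator lays out a single toy chromosome with one gene per fixed-width
tile.  Each gene follows one archetype (alternative first exons splicing to
a shared acceptor, alternative last exons, cassette, mutually exclusive
exons, alternative 5'/3' splice sites, intron retention), written in
transcription-space coordinates and mirrored genomically on the minus
strand, so all strand logic downstream is exercised.  Junction counts are
drawn from the same Dirichlet-multinomial process the differential test
fits; CAGE peaks, peak count matrices and 5'UTR sequences carry planted
truth recorded in the ledger so every downstream discovery is scoreable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CountTable, ExonModel, GenomeInterval, TranscriptModel, ValidationError
from .events import build_events

CHROM = "chrS"
TILE = 100_000  # one gene per tile
GENE_SPAN = 20_000  # transcription-space length of every toy gene


@dataclass
class SyntheticTruth:
    """Ledger of everything the generators planted."""

    seed: int = 0
    event_census: dict = field(default_factory=dict)
    afe_genes: list = field(default_factory=list)
    novel_afe_genes: set = field(default_factory=set)
    true_tss: set = field(default_factory=set)  # (chrom, pos, strand)
    novel_tss: set = field(default_factory=set)
    event_effects: dict = field(default_factory=dict)
    planted_events: set = field(default_factory=set)
    cage_true_peaks: list = field(default_factory=list)
    cage_covered_tss: set = field(default_factory=set)
    diff_peaks: dict = field(default_factory=dict)  # assay -> set of peak ids
    diff_peak_genes: dict = field(default_factory=dict)  # assay -> set of gene ids
    planted_motifs: dict = field(default_factory=dict)  # seq id -> [(class, pos)]
    de_genes: set = field(default_factory=set)


_OTHER_TYPES = ("ALE", "CASSETTE", "MXE", "A5SS", "A3SS", "IR")


def _place(gene_start: int, strand: str, s: int, e: int) -> GenomeInterval:
    """Map a transcription-space block [s, e) into genome coordinates."""
    if strand == "-":
        return GenomeInterval(CHROM, gene_start + GENE_SPAN - e, gene_start + GENE_SPAN - s, strand)
    return GenomeInterval(CHROM, gene_start + s, gene_start + e, strand)


def _tx(tid: str, gid: str, blocks: list[GenomeInterval], source: str = "reference") -> TranscriptModel:
    return TranscriptModel(
        tid, gid, [ExonModel(iv, rank=i + 1) for i, iv in enumerate(blocks)], source=source
    )


def make_toy_annotation(
    n_genes: int = 60,
    afe_fraction: float = 0.5,
    n_first_exons: int = 2,
    novel_afe_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[TranscriptModel], SyntheticTruth]:
    """Build a toy annotation with a known per-type event census.

    ``afe_fraction`` of the genes carry ``n_first_exons`` distinct first
    exons splicing to a shared second-exon acceptor; the rest cycle through
    the other archetypes in equal shares.  ``novel_afe_fraction`` of AFE
    genes have their alternative first-exon transcript marked as a
    long-read isoform (novel first exon, novel TSS).  Strands alternate by
    gene index.  Deterministic under the seed.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if not (0 <= afe_fraction <= 1):
        raise ValidationError("afe_fraction must be in [0, 1]")
    n_afe = int(round(afe_fraction * n_genes))
    if n_afe and n_first_exons < 2:
        raise ValidationError("AFE genes need n_first_exons >= 2")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    transcripts: list[TranscriptModel] = []
    census: dict[str, int] = {}

    afe_idx = set(range(n_afe))
    novel = set(
        rng.choice(sorted(afe_idx), size=int(round(novel_afe_fraction * n_afe)), replace=False)
    ) if n_afe else set()

    other_cycle = 0
    for gi in range(n_genes):
        gid = f"g{gi:04d}"
        g0 = gi * TILE
        strand = "+" if gi % 2 == 0 else "-"
        if gi in afe_idx:
            truth.afe_genes.append(gid)
            e2 = _place(g0, strand, 5000, 5200)
            e3 = _place(g0, strand, 8000, 8200)
            for j in range(n_first_exons):
                fe = _place(g0, strand, j * 600, j * 600 + 200)
                source = "reference"
                if gi in novel and j == n_first_exons - 1:
                    source = "longread"
                    truth.novel_afe_genes.add(gid)
                tx = _tx(f"{gid}.t{j}", gid, [fe, e2, e3], source=source)
                transcripts.append(tx)
            census["AFE"] = census.get("AFE", 0) + 1
        else:
            etype = _OTHER_TYPES[other_cycle % len(_OTHER_TYPES)]
            other_cycle += 1
            census[etype] = census.get(etype, 0) + 1
            if etype == "ALE":
                e1 = _place(g0, strand, 0, 200)
                e2 = _place(g0, strand, 2000, 2200)
                transcripts.append(_tx(f"{gid}.t0", gid, [e1, e2, _place(g0, strand, 5000, 5200)]))
                transcripts.append(_tx(f"{gid}.t1", gid, [e1, e2, _place(g0, strand, 7000, 7200)]))
            elif etype == "CASSETTE":
                e1 = _place(g0, strand, 0, 200)
                e2 = _place(g0, strand, 3000, 3150)
                e3 = _place(g0, strand, 6000, 6200)
                transcripts.append(_tx(f"{gid}.t0", gid, [e1, e2, e3]))
                transcripts.append(_tx(f"{gid}.t1", gid, [e1, e3]))
            elif etype == "MXE":
                e1 = _place(g0, strand, 0, 200)
                a = _place(g0, strand, 3000, 3150)
                b = _place(g0, strand, 5000, 5150)
                e4 = _place(g0, strand, 8000, 8200)
                transcripts.append(_tx(f"{gid}.t0", gid, [e1, a, e4]))
                transcripts.append(_tx(f"{gid}.t1", gid, [e1, b, e4]))
            elif etype == "A5SS":
                e2 = _place(g0, strand, 5000, 5200)
                transcripts.append(_tx(f"{gid}.t0", gid, [_place(g0, strand, 0, 400), e2]))
                transcripts.append(_tx(f"{gid}.t1", gid, [_place(g0, strand, 0, 200), e2]))
            elif etype == "A3SS":
                e1 = _place(g0, strand, 0, 200)
                transcripts.append(_tx(f"{gid}.t0", gid, [e1, _place(g0, strand, 5000, 5400)]))
                transcripts.append(_tx(f"{gid}.t1", gid, [e1, _place(g0, strand, 5200, 5400)]))
            elif etype == "IR":
                e1 = _place(g0, strand, 0, 200)
                e2 = _place(g0, strand, 3000, 3200)
                transcripts.append(_tx(f"{gid}.t0", gid, [e1, e2]))
                transcripts.append(_tx(f"{gid}.t1", gid, [_place(g0, strand, 0, 3200)]))
    truth.event_census = census

    ref_tss = set()
    for tx in transcripts:
        fe = tx.first_exon.interval
        pos = fe.end - 1 if tx.strand == "-" else fe.start
        truth.true_tss.add((tx.chrom, pos, tx.strand))
        if tx.source == "reference":
            ref_tss.add((tx.chrom, pos, tx.strand))
    truth.novel_tss = truth.true_tss - ref_tss
    return transcripts, truth


def simulate_junction_counts(
    transcripts: Sequence[TranscriptModel],
    truth: SyntheticTruth,
    n_per_condition: int = 3,
    depth: float = 200.0,
    phi: float = 50.0,
    effect_fraction: float = 0.5,
    effect_delta: float = 30.0,
    conditions: tuple[str, str] = ("control", "LPS"),
    seed: int = 0,
) -> CountTable:
    """Draw per-event candidate counts under the Dirichlet-multinomial model.

    Per event and sample: total ~ Poisson(depth); the candidate split is a
    Dirichlet(phi * pi) draw followed by a multinomial draw.  A fraction of
    AFE events receives a planted inclusion shift of ``effect_delta`` PSI
    points in the treated condition; all other events are null.  True
    proportions and planted deltas are recorded in the ledger.
    """
    if depth <= 0 or phi <= 0:
        raise ValidationError("depth and phi must be > 0")
    rng = np.random.default_rng(seed)
    events = build_events(transcripts)
    afe_ids = [ev.event_id for ev in events if ev.event_type == "AFE"]
    n_plant = int(round(effect_fraction * len(afe_ids)))
    planted = set(rng.choice(afe_ids, size=n_plant, replace=False)) if n_plant else set()
    truth.planted_events = set(planted)

    control, treated = conditions
    samples = [f"{control}_{i + 1}" for i in range(n_per_condition)] + [
        f"{treated}_{i + 1}" for i in range(n_per_condition)
    ]
    condition_of = {s: (control if s.startswith(control) else treated) for s in samples}

    row_ids, data = [], []
    for ev in events:
        k = len(ev.candidates)
        if ev.event_id in planted:
            p0 = rng.uniform(0.20, 0.95 - effect_delta / 100.0)
            rest = rng.dirichlet(np.full(k - 1, 5.0)) * (1 - p0) if k > 2 else np.array([1 - p0])
            pi_c = np.concatenate([[p0], rest])
            shift = effect_delta / 100.0
            pi_t = pi_c.copy()
            pi_t[0] = p0 + shift
            pi_t[1:] *= (1 - pi_t[0]) / (1 - p0)
        else:
            if k == 2:
                p0 = rng.uniform(0.25, 0.75)
                pi_c = np.array([p0, 1 - p0])
            else:
                pi_c = rng.dirichlet(np.full(k, 5.0))
            pi_t = pi_c.copy()
        truth.event_effects[ev.event_id] = {
            "psi_control": (100.0 * pi_c).tolist(),
            "psi_treated": (100.0 * pi_t).tolist(),
            "delta_psi": float(100.0 * (pi_t[0] - pi_c[0])),
            "planted": ev.event_id in planted,
        }
        block = np.zeros((k, len(samples)), dtype=int)
        for si, s in enumerate(samples):
            pi = pi_t if condition_of[s] == treated else pi_c
            n = rng.poisson(depth)
            if n > 0:
                g = rng.dirichlet(phi * pi)
                block[:, si] = rng.multinomial(n, g)
        for idx in range(k):
            row_ids.append(ev.row_id(idx))
            data.append(block[idx])
    counts = pd.DataFrame(np.array(data, dtype=int), index=row_ids, columns=samples)
    return CountTable(counts, condition_of)


def simulate_cage_peaks(
    transcripts: Sequence[TranscriptModel],
    truth: SyntheticTruth,
    true_rate: float = 0.45,
    decoy_rate: float = 0.2,
    seed: int = 0,
) -> list[tuple[GenomeInterval, str, float]]:
    """CAGE-like scored peaks: high-scoring peaks on a fraction of true TSSs
    plus low-scoring decoys away from any TSS.

    Returns (interval, name, score) records; the ledger keeps the peaks that
    mark real TSSs ("classifier-true") and the set of covered TSS positions.
    """
    if not (0 <= true_rate <= 1 and 0 <= decoy_rate <= 1):
        raise ValidationError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tss = sorted(truth.true_tss)
    records = []
    truth.cage_true_peaks = []
    truth.cage_covered_tss = set()
    for i, (chrom, pos, strand) in enumerate(tss):
        if rng.random() < true_rate:
            w = int(rng.integers(20, 51))
            start = max(0, pos - w // 2)
            iv = GenomeInterval(chrom, start, start + w, ".")
            score = float(np.round(np.exp(rng.normal(3.0, 0.5)), 3))
            records.append((iv, f"cage_true_{i}", score))
            truth.cage_true_peaks.append(iv)
            truth.cage_covered_tss.add((chrom, pos, strand))
    n_decoy = int(round(decoy_rate * len(tss)))
    span = max((p for _, p, _ in tss), default=TILE) + TILE
    tss_pos = np.array(sorted(p for _, p, _ in tss)) if tss else np.array([0])
    made = 0
    while made < n_decoy:
        pos = int(rng.integers(0, span))
        if np.min(np.abs(tss_pos - pos)) < 1000:
            continue
        w = int(rng.integers(20, 51))
        iv = GenomeInterval(CHROM, pos, pos + w, ".")
        score = float(np.round(np.exp(rng.normal(1.0, 0.5)), 3))
        records.append((iv, f"cage_decoy_{made}", score))
        made += 1
    return records


def simulate_peak_counts(
    transcripts: Sequence[TranscriptModel],
    truth: SyntheticTruth,
    assays: Sequence[str] = ("ATAC", "p65", "IRF3"),
    diff_fraction: float = 0.25,
    effect_lfc: float = 3.0,
    n_per_condition: int = 3,
    base_mean: float = 200.0,
    nb_shape: float = 50.0,
    conditions: tuple[str, str] = ("control", "LPS"),
    seed: int = 0,
) -> dict[str, tuple[list[tuple[GenomeInterval, str]], CountTable]]:
    """Per-assay peak sets and negative-binomial count matrices.

    Every AFE gene gets one promoter peak per assay spanning its first-exon
    cluster; an independently drawn ``diff_fraction`` of those peaks per
    assay is shifted by ``effect_lfc`` log2 units in the treated condition.
    Non-AFE promoter peaks and the remaining AFE peaks stay flat.  Planted
    peak and gene ids are recorded per assay.
    """
    if effect_lfc < 0:
        raise ValidationError("effect_lfc must be >= 0")
    rng = np.random.default_rng(seed)
    control, treated = conditions
    samples = [f"{control}_{i + 1}" for i in range(n_per_condition)] + [
        f"{treated}_{i + 1}" for i in range(n_per_condition)
    ]
    condition_of = {s: (control if s.startswith(control) else treated) for s in samples}

    # promoter peak per gene: span of first exons padded by 100 bp
    first_exons: dict[str, list[GenomeInterval]] = {}
    for tx in transcripts:
        first_exons.setdefault(tx.gene_id, []).append(tx.first_exon.interval)
    gene_peaks = {}
    for gid in sorted(first_exons):
        ivs = first_exons[gid]
        start = max(0, min(iv.start for iv in ivs) - 100)
        end = max(iv.end for iv in ivs) + 100
        gene_peaks[gid] = GenomeInterval(ivs[0].chrom, start, end, ".")

    afe = [g for g in sorted(first_exons) if g in set(truth.afe_genes)]
    out = {}
    for ai, assay in enumerate(assays):
        arng = np.random.default_rng(seed + 7919 * (ai + 1))
        n_diff = int(round(diff_fraction * len(afe)))
        diff_genes = set(arng.choice(afe, size=n_diff, replace=False)) if n_diff else set()
        peaks, rows, data = [], [], []
        truth.diff_peaks.setdefault(assay, set())
        truth.diff_peak_genes[assay] = set(diff_genes)
        for gid in sorted(gene_peaks):
            pid = f"{assay}_peak_{gid}"
            peaks.append((gene_peaks[gid], pid))
            base = float(np.exp(arng.normal(np.log(base_mean), 0.4)))
            is_diff = gid in diff_genes
            if is_diff:
                truth.diff_peaks[assay].add(pid)
            row = []
            for s in samples:
                mean = base * (2.0 ** effect_lfc if is_diff and condition_of[s] == treated else 1.0)
                lam = arng.gamma(nb_shape, mean / nb_shape)
                row.append(int(arng.poisson(lam)))
            rows.append(pid)
            data.append(row)
        counts = pd.DataFrame(np.array(data, dtype=int), index=rows, columns=samples)
        out[assay] = (peaks, CountTable(counts, condition_of))
    return out


IRE_LOOP = "CAGTGC"  # canonical CAGUGH loop, DNA spelling
_COMP = str.maketrans("ACGT", "TGCA")


def plant_utr_motifs(
    n_seqs: int = 100,
    length: int = 200,
    ire_rate: float = 0.3,
    seed: int = 0,
    truth: Optional[SyntheticTruth] = None,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Random-uniform 5'UTR-like sequences with canonical IREs planted.

    An ``ire_rate`` fraction of sequences receives one embedded element: the
    unpaired C bulge, a random fully-paired 5-bp upper stem, and the
    canonical loop.  The ledger records each loop offset.
    """
    if length < 30:
        raise ValidationError("length must be >= 30 to host the motif")
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = SyntheticTruth(seed=seed)
    records = []
    n_plant = int(round(ire_rate * n_seqs))
    for i in range(n_seqs):
        sid = f"utr{i:04d}"
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if i < n_plant:
            arm5 = "".join(rng.choice(list("ACGT"), size=5))
            arm3 = arm5.translate(_COMP)[::-1]
            element = "C" + arm5 + IRE_LOOP + arm3
            pos = int(rng.integers(1, length - len(element)))
            seq = seq[:pos] + element + seq[pos + len(element):]
            truth.planted_motifs[sid] = [("IRE", pos + 6)]  # loop offset
        else:
            truth.planted_motifs[sid] = []
        records.append((sid, seq))
    return records, truth


def simulate_de_table(
    gene_ids: Sequence[str],
    truth: SyntheticTruth,
    de_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """A differential-expression gene table with a planted DE subset.

    Planted genes get |log2FC| >= 2 and small adjusted p; the rest sit well
    inside the null region.  Planted ids go to the ledger.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(set(gene_ids))
    n_de = int(round(de_fraction * len(genes)))
    de = set(rng.choice(genes, size=n_de, replace=False)) if n_de else set()
    truth.de_genes = set(de)
    rows = []
    for g in genes:
        if g in de:
            lfc = float(rng.uniform(2.0, 6.0) * rng.choice([-1, 1]))
            padj = float(rng.uniform(0.0, 0.04))
        else:
            lfc = float(np.clip(rng.normal(0, 0.5), -1.5, 1.5))
            padj = float(rng.uniform(0.1, 1.0))
        rows.append({"gene": g, "log2fc": lfc, "p_adj": padj})
    return pd.DataFrame(rows)
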