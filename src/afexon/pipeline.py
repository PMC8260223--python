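"""End-to-end orchestration: simulate -> events/PSI -> differential tests ->
TSS/CAGE -> promoter attribution -> motif scan, with a JSON run manifest.

Every stage writes its table under the output directory; reruns with the
same configuration and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import events as ev_mod
from . import io as io_mod
from .core import GenomeInterval
from .diffsplice import dm_lrt, significant_events, ttest_diff, union_genes
from .motifs import hits_table, scan_ire
from .promoters import (
    ACCESSIBILITY_THRESHOLDS,
    TF_THRESHOLDS,
    attribute_regulation,
    differential_peaks,
    promoter_windows,
    select_afe_coordinates,
)
from .simulate import (
    make_toy_annotation,
    plant_utr_motifs,
    simulate_cage_peaks,
    simulate_de_table,
    simulate_junction_counts,
    simulate_peak_counts,
)
from .tss import cage_support, classify_tss, extract_tss, reference_tss_set

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of a full synthetic run."""

    outdir: str = "results/pipeline"
    seed: int = 0
    # annotation
    n_genes: int = 60
    afe_fraction: float = 0.5
    n_first_exons: int = 2
    novel_afe_fraction: float = 0.3
    # counts
    n_per_condition: int = 3
    depth: float = 200.0
    phi: float = 50.0
    effect_fraction: float = 0.5
    effect_delta: float = 30.0
    conditions: tuple[str, str] = ("control", "LPS")
    # quantification / testing
    jcn_seq_len: int = 88
    count_threshold: int = 10
    delta_thresh: float = 5.0
    alpha: float = 0.25
    delta: float = 10.0
    selection_alpha: float = 0.05
    min_samps_gene_expr: int = 6
    min_samps_feature_expr: int = 3
    min_gene_expr: int = 10
    min_feature_expr: int = 0
    # promoters / peaks
    upstream: int = 10_000
    assays: tuple[str, ...] = ("ATAC", "p65", "IRF3")
    diff_fraction: float = 0.25
    effect_lfc: float = 3.0
    # CAGE
    cage_true_rate: float = 0.45
    cage_decoy_rate: float = 0.2
    # motifs
    n_utr_seqs: int = 100
    utr_length: int = 200
    ire_rate: float = 0.3
    # DE cross-reference
    de_fraction: float = 0.5
    de_lfc_min: float = 2.0
    de_alpha: float = 0.05


def crossref_de(
    afe_genes,
    de_table: pd.DataFrame,
    lfc_min: float = 2.0,
    alpha: float = 0.05,
) -> dict:
    """Partition AFE genes into differentially vs non-differentially expressed.

    A gene is DE when |log2FC| >= ``lfc_min`` and adjusted p <= ``alpha``;
    genes absent from the table count as non-DE.
    """
    de_set = set(
        de_table.loc[
            (de_table["log2fc"].abs() >= lfc_min) & (de_table["p_adj"] <= alpha), "gene"
        ]
    )
    genes = sorted(set(afe_genes))
    missing = [g for g in genes if g not in set(de_table["gene"])]
    if missing:
        log.info("crossref_de: %d AFE genes absent from DE table", len(missing))
    n_de = sum(g in de_set for g in genes)
    return {
        "n_afe_genes": len(genes),
        "n_de": n_de,
        "n_non_de": len(genes) - n_de,
        "frac_de": n_de / len(genes) if genes else float("nan"),
        "de_genes": sorted(g for g in genes if g in de_set),
    }


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages on synthetic data and write the output bundle.

    Returns the manifest (also written to ``manifest.json``): parameters,
    seed, per-output row counts, and the stage summaries.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start, seed=%d, outdir=%s", config.seed, out)
    manifest: dict = {"config": asdict(config), "outputs": {}, "summary": {}}

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format="%.6g")
        manifest["outputs"][name] = int(len(df))

    # stage 1: annotation + counts
    transcripts, truth = make_toy_annotation(
        n_genes=config.n_genes,
        afe_fraction=config.afe_fraction,
        n_first_exons=config.n_first_exons,
        novel_afe_fraction=config.novel_afe_fraction,
        seed=config.seed,
    )
    io_mod.write_gtf(transcripts, out / "annotation.gtf")
    counts = simulate_junction_counts(
        transcripts,
        truth,
        n_per_condition=config.n_per_condition,
        depth=config.depth,
        phi=config.phi,
        effect_fraction=config.effect_fraction,
        effect_delta=config.effect_delta,
        conditions=config.conditions,
        seed=config.seed + 1,
    )
    io_mod.write_counts(counts, out / "junction_counts.tsv", out / "conditions.tsv")
    manifest["outputs"]["junction_counts.tsv"] = int(len(counts.counts))

    # stage 2: events + PSI
    events = ev_mod.build_events(transcripts)
    psi = ev_mod.psi_table(
        events, counts, count_threshold=config.count_threshold, jcn_seq_len=config.jcn_seq_len
    )
    ev_mod.write_event_table(psi, counts, out / "event_table.tsv")
    manifest["summary"]["n_events"] = len(events)
    manifest["summary"]["event_census"] = (
        pd.Series([e.event_type for e in events]).value_counts().to_dict()
    )

    # stage 3: differential splicing, both routes
    control, treated = config.conditions
    res_t = ttest_diff(psi, control=control, treated=treated, delta_thresh=config.delta_thresh)
    res_dm = dm_lrt(
        events,
        counts,
        control=control,
        treated=treated,
        min_samps_gene_expr=config.min_samps_gene_expr,
        min_samps_feature_expr=config.min_samps_feature_expr,
        min_gene_expr=config.min_gene_expr,
        min_feature_expr=config.min_feature_expr,
    )
    save(res_t, "diff_ttest.tsv")
    save(res_dm, "diff_dmlrt.tsv")
    sig_t = significant_events(res_t, alpha=config.alpha, delta=config.delta)
    sig_dm = significant_events(res_dm, alpha=config.alpha, delta=config.delta)
    save(sig_t, "significant_ttest.tsv")
    save(sig_dm, "significant_dmlrt.tsv")
    genes_by_type = union_genes(sig_t, sig_dm)
    _write_json({k: sorted(v) for k, v in genes_by_type.items()}, out / "union_genes.json")
    manifest["summary"]["n_significant_union_genes"] = {
        k: len(v) for k, v in sorted(genes_by_type.items())
    }

    # stage 4: TSS extraction, classification, CAGE support
    tss = extract_tss(transcripts)
    ref = reference_tss_set(transcripts)
    tss = classify_tss(tss, ref)
    cage = simulate_cage_peaks(
        transcripts,
        truth,
        true_rate=config.cage_true_rate,
        decoy_rate=config.cage_decoy_rate,
        seed=config.seed + 2,
    )
    io_mod.write_bed([(iv, name, score) for iv, name, score in cage], out / "cage_peaks.bed")
    tss, cage_summary = cage_support(
        tss, [(iv, score) for iv, _, score in cage], truth_peaks=truth.cage_true_peaks
    )
    save(tss, "tss.tsv")
    manifest["summary"]["tss"] = {
        "n_known": int((tss["status"] == "known").sum()),
        "n_novel": int((tss["status"] == "novel").sum()),
        "true_overlap_fraction": cage_summary["true_overlap_fraction"],
    }

    # stage 5: promoter attribution
    sig_afe = pd.concat([sig_t, sig_dm], ignore_index=True)
    sig_afe = sig_afe[sig_afe["p_adj"] <= config.selection_alpha]
    events_by_id = {e.event_id: e for e in events}
    exons = select_afe_coordinates(sig_afe, events_by_id, delta_min=config.delta)
    windows = promoter_windows(exons, upstream=config.upstream, stranded=True)
    io_mod.write_bed([(w, f"win_{i}", 0) for i, w in enumerate(windows)], out / "afe_windows.bed")
    peak_data = simulate_peak_counts(
        transcripts,
        truth,
        assays=config.assays,
        diff_fraction=config.diff_fraction,
        effect_lfc=config.effect_lfc,
        conditions=config.conditions,
        seed=config.seed + 3,
    )
    diff_by_assay = {}
    for assay, (peaks, pcounts) in peak_data.items():
        thr = ACCESSIBILITY_THRESHOLDS if assay == "ATAC" else TF_THRESHOLDS
        dp = differential_peaks(peaks, pcounts, control=control, treated=treated, thresholds=thr)
        save(dp, f"peaks_{assay}.tsv")
        sig = dp[dp["differential"]]
        diff_by_assay[assay] = [
            GenomeInterval(r["chrom"], r["start"], r["end"], ".") for _, r in sig.iterrows()
        ]
    named_windows = list(zip([f"win_{i}" for i in range(len(windows))], windows))
    attribution, partition = attribute_regulation(named_windows, diff_by_assay)
    save(attribution, "afe_attribution.tsv")
    _write_json(partition, out / "upset_partition.json")
    manifest["summary"]["upset_partition"] = dict(sorted(partition.items()))

    # stage 6: 5'UTR motif scan
    utrs, truth = plant_utr_motifs(
        n_seqs=config.n_utr_seqs,
        length=config.utr_length,
        ire_rate=config.ire_rate,
        seed=config.seed + 4,
        truth=truth,
    )
    io_mod.write_fasta(utrs, out / "utrs.fa")
    hits = [h for sid, seq in utrs for h in scan_ire(seq, sid)]
    save(hits_table(hits), "ire_hits.tsv")
    manifest["summary"]["n_ire_hits"] = len(hits)

    # stage 7: DE cross-reference
    de_table = simulate_de_table(
        sorted(truth.afe_genes), truth, de_fraction=config.de_fraction, seed=config.seed + 5
    )
    save(de_table, "de_table.tsv")
    xref = crossref_de(truth.afe_genes, de_table, lfc_min=config.de_lfc_min, alpha=config.de_alpha)
    manifest["summary"]["crossref_de"] = {
        k: v for k, v in xref.items() if k != "de_genes"
    }

    # truth ledger + manifest
    _write_json(
        {
            "seed": truth.seed,
            "event_census": truth.event_census,
            "afe_genes": sorted(truth.afe_genes),
            "novel_afe_genes": sorted(truth.novel_afe_genes),
            "planted_events": sorted(truth.planted_events),
            "diff_peak_genes": {k: sorted(v) for k, v in truth.diff_peak_genes.items()},
            "de_genes": sorted(truth.de_genes),
            "n_true_tss": len(truth.true_tss),
            "n_novel_tss": len(truth.novel_tss),
        },
        out / "truth_ledger.json",
    )
    _write_json(manifest, out / "manifest.json")
    log.info("pipeline done: %s", manifest["summary"])
    return manifest
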