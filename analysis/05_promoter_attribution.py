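#!/usr/bin/env python
"""Attribute significant AFE events to promoter regulation.

Selects upregulated first-exon coordinates by the delta-PSI sign rule,
extends 10 kb upstream (strand-aware), calls differential
accessibility/TF-binding peaks from simulated count matrices under the
quoted thresholds (ATAC: log2FC > 0.8 & raw p < 0.15; TF: log2FC > 1 &
adjusted p < 0.25), and partitions the AFE windows by the exact set of
flagged assays (the UpSet decomposition).
"""

import json
from pathlib import Path

import pandas as pd

from afexon.core import GenomeInterval
from afexon.diffsplice import dm_lrt, significant_events, ttest_diff
from afexon.events import build_events, psi_table
from afexon.io import read_counts, read_gtf, write_bed
from afexon.promoters import (
    ACCESSIBILITY_THRESHOLDS,
    TF_THRESHOLDS,
    attribute_regulation,
    differential_peaks,
    promoter_windows,
    select_afe_coordinates,
)
from afexon.simulate import make_toy_annotation, simulate_peak_counts

IN = Path("results/cohort")
OUT = Path("results/promoters")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 2026

transcripts = read_gtf(IN / "annotation.gtf")
counts = read_counts(IN / "junction_counts.tsv", IN / "conditions.tsv")
events = build_events(transcripts)
table = psi_table(events, counts)

sig = pd.concat(
    [significant_events(ttest_diff(table)), significant_events(dm_lrt(events, counts))],
    ignore_index=True,
)
sig = sig[sig["p_adj"] <= 0.05]  # the selection step's stricter gate
events_by_id = {e.event_id: e for e in events}
exons = select_afe_coordinates(sig, events_by_id)
windows = promoter_windows(exons, upstream=10_000, stranded=True)
write_bed([(w, f"win_{i}", 0) for i, w in enumerate(windows)], OUT / "afe_windows.bed")

# peak matrices come from the same genome layout
anno_transcripts, truth = make_toy_annotation(
    n_genes=200, afe_fraction=0.5, n_first_exons=2, novel_afe_fraction=0.3, seed=SEED
)
peak_data = simulate_peak_counts(
    anno_transcripts, truth, assays=("ATAC", "p65", "IRF3"),
    diff_fraction=0.25, effect_lfc=3.0, seed=SEED + 3,
)
diff_by_assay = {}
for assay, (peaks, pcounts) in peak_data.items():
    thr = ACCESSIBILITY_THRESHOLDS if assay == "ATAC" else TF_THRESHOLDS
    dp = differential_peaks(peaks, pcounts, thresholds=thr)
    dp.to_csv(OUT / f"peaks_{assay}.tsv", sep="\t", index=False, float_format="%.6g")
    diff_by_assay[assay] = [
        GenomeInterval(r["chrom"], r["start"], r["end"], ".")
        for _, r in dp[dp["differential"]].iterrows()
    ]

named = list(zip([f"win_{i}" for i in range(len(windows))], windows))
attribution, partition = attribute_regulation(named, diff_by_assay)
attribution.to_csv(OUT / "attribution.tsv", sep="\t", index=False)
with open(OUT / "upset_partition.json", "w") as fh:
    json.dump(partition, fh, indent=2, sort_keys=True)

summary = attribution.attrs.get("summary", {})
print(f"{len(windows)} AFE promoter windows attributed")
print(f"UpSet partition: {dict(sorted(partition.items()))}")
print(
    f"fraction with differential accessibility: {summary.get('frac_accessibility', 0):.2f}; "
    f"with differential TF binding: {summary.get('frac_tf', 0):.2f} "
    "(planted at 25% per assay)"
)
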