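"""AFE promoter attribution: exon selection by the delta-PSI sign rule,
10-kb upstream windows, differential peak calling against thresholds, and
the exact-subset (UpSet) partition over assays."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountTable, GenomeInterval, ValidationError, bh_adjust, intersect
from .events import ASEvent

#: (lfc_min, p_min, use_adjusted) presets quoted for each assay family
ACCESSIBILITY_THRESHOLDS = (0.8, 0.15, False)
TF_THRESHOLDS = (1.0, 0.25, True)


def select_afe_coordinates(
    results: pd.DataFrame,
    events_by_id: Mapping[str, ASEvent],
    delta_min: float = 10.0,
) -> list[GenomeInterval]:
    """Pick the treated-upregulated first-exon coordinates of significant AFE events.

    Per candidate row: a delta PSI above ``delta_min`` emits the candidate's
    own exon; below ``-delta_min``, every sibling candidate of the event
    with delta PSI above ``delta_min`` is emitted instead.  Identical exon
    coordinates across the output are removed; order is deterministic.
    """
    afe = results[results["event_type"] == "AFE"]
    by_event = {eid: sub for eid, sub in afe.groupby("event_id")}
    chosen: list[GenomeInterval] = []
    for _, row in afe.iterrows():
        ev = events_by_id[row["event_id"]]
        d = row["delta_psi"]
        if pd.isna(d):
            continue
        if d > delta_min:
            cand = ev.candidates[int(row["candidate_index"])]
            chosen.extend(cand.exon_parts)
        elif d < -delta_min:
            sibs = by_event[row["event_id"]]
            for _, sib in sibs.iterrows():
                if sib["candidate_index"] != row["candidate_index"] and sib["delta_psi"] > delta_min:
                    cand = ev.candidates[int(sib["candidate_index"])]
                    chosen.extend(cand.exon_parts)
    seen, out = set(), []
    for iv in sorted(chosen):
        key = (iv.chrom, iv.start, iv.end, iv.strand)
        if key not in seen:
            seen.add(key)
            out.append(iv)
    return out


def promoter_windows(
    exons: Sequence[GenomeInterval],
    upstream: int = 10_000,
    stranded: bool = True,
) -> list[GenomeInterval]:
    """Extend each exon by ``upstream`` bases toward its promoter.

    Strand-aware by default (upstream is 5' of the exon); the unstranded
    mode extends on the genomic left only.  Coordinates clip at zero.
    """
    if upstream < 0:
        raise ValidationError("upstream must be >= 0")
    out = []
    for iv in exons:
        if stranded and iv.strand == "-":
            out.append(GenomeInterval(iv.chrom, iv.start, iv.end + upstream, iv.strand))
        else:
            out.append(GenomeInterval(iv.chrom, max(0, iv.start - upstream), iv.end, iv.strand))
    return out


def differential_peaks(
    peaks: Sequence[tuple[GenomeInterval, str]],
    counts: CountTable,
    control: str = "control",
    treated: str = "LPS",
    thresholds: tuple[float, float, bool] = ACCESSIBILITY_THRESHOLDS,
) -> pd.DataFrame:
    """Flag differential peaks from a peak count matrix.

    log2FC is the mean difference of log2 counts-per-million (0.5
    pseudocount) between conditions; the p-value is a two-sample t-test on
    the per-sample log-CPM, BH-adjusted across peaks.  A peak is
    differential when log2FC exceeds ``lfc_min`` and the (adjusted if
    ``use_adjusted`` else raw) p-value falls below ``p_min``.
    """
    lfc_min, p_min, use_adjusted = thresholds
    ctrl = counts.samples_of(control)
    trt = counts.samples_of(treated)
    if not ctrl or not trt:
        raise ValidationError("each condition needs >= 1 replicate")
    mat = counts.counts.astype(float)
    lib = mat.sum(axis=0)
    logcpm = np.log2((mat + 0.5).div(lib + 1.0, axis=1) * 1e6)
    rows = []
    for iv, pid in peaks:
        c = logcpm.loc[pid, ctrl].to_numpy()
        t = logcpm.loc[pid, trt].to_numpy()
        lfc = float(t.mean() - c.mean())
        if len(c) >= 2 and len(t) >= 2 and (np.ptp(c) > 0 or np.ptp(t) > 0):
            p = float(stats.ttest_ind(t, c, equal_var=True).pvalue)
        else:
            p = np.nan if lfc == 0 else 0.0
        rows.append(
            {"peak_id": pid, "chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "log2fc": lfc, "p_raw": p}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"])
    pcol = out["p_adj"] if use_adjusted else out["p_raw"]
    out["differential"] = (out["log2fc"] > lfc_min) & (pcol < p_min)
    out["differential"] = out["differential"].fillna(False)
    return out


def attribute_regulation(
    windows: Sequence[tuple[str, GenomeInterval]],
    diff_peaks_by_assay: Mapping[str, Sequence[GenomeInterval]],
    accessibility_assays: Sequence[str] = ("ATAC",),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag each promoter window per assay and partition by the flag set.

    A window is flagged for an assay when at least one differential peak of
    that assay overlaps it (>= 1 bp, strand-blind).  The partition label is
    the exact set of flagged assays, so labels partition the window set;
    subset counts feed the UpSet summary.
    """
    assays = sorted(diff_peaks_by_assay)
    rows = []
    flags_per_assay = {}
    ivs = [iv for _, iv in windows]
    for assay in assays:
        peaks = list(diff_peaks_by_assay[assay])
        hit = {id(a) for a, _ in intersect(ivs, peaks, mode="overlap")}
        flags_per_assay[assay] = [id(iv) in hit for iv in ivs]
    counts: dict[str, int] = {}
    for i, (name, iv) in enumerate(windows):
        flagged = tuple(a for a in assays if flags_per_assay[a][i])
        label = "+".join(flagged) if flagged else "none"
        counts[label] = counts.get(label, 0) + 1
        row = {"window_id": name, "chrom": iv.chrom, "start": iv.start,
               "end": iv.end, "strand": iv.strand, "partition": label}
        for a in assays:
            row[f"diff_{a}"] = flags_per_assay[a][i]
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        acc = [a for a in assays if a in set(accessibility_assays)]
        tf = [a for a in assays if a not in set(accessibility_assays)]
        summary = {
            "n_windows": len(df),
            "frac_accessibility": float(df[[f"diff_{a}" for a in acc]].any(axis=1).mean()) if acc else 0.0,
            "frac_tf": float(df[[f"diff_{a}" for a in tf]].any(axis=1).mean()) if tf else 0.0,
        }
        df.attrs["summary"] = summary
    return df, counts
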