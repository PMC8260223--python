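#!/usr/bin/env python
"""Build splicing events from the cohort annotation and quantify PSI.

Reads results/cohort/, classifies AFE/ALE/cassette/MXE/A5SS/A3SS/IR events,
and writes the per-candidate PSI table (length-normalized, count threshold
10) under results/events/.
"""

from pathlib import Path

import pandas as pd

from afexon.events import build_events, psi_table, write_event_table
from afexon.io import read_counts, read_gtf

IN = Path("results/cohort")
OUT = Path("results/events")
OUT.mkdir(parents=True, exist_ok=True)

transcripts = read_gtf(IN / "annotation.gtf")
counts = read_counts(IN / "junction_counts.tsv", IN / "conditions.tsv")
events = build_events(transcripts)
table = psi_table(events, counts, count_threshold=10, jcn_seq_len=88)

write_event_table(table, counts, OUT / "event_table.tsv")
table.meta.join(table.psi).to_csv(OUT / "psi.tsv", sep="\t", float_format="%.6g")

census = pd.Series([e.event_type for e in events]).value_counts()
n_missing = int(table.psi.isna().sum().sum())
print(f"{len(events)} events quantified over {len(counts.sample_ids)} samples")
print(census.to_string())
print(f"{n_missing} PSI cells masked by the count threshold")
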