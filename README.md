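# afexon

Inflammatory stimulation of macrophages changes not only how much genes are
expressed but *which isoform* is made — most prominently through alternative
first exon (AFE) usage, where transcripts of one gene start at different
first exons (hence different promoters and 5′UTRs) that splice into a shared
downstream acceptor. A switch of first exon can put a new regulatory element
in front of an unchanged coding sequence: the mouse dsDNA sensor *Aim2* is
the flagship case, where the inflammation-induced isoform carries a longer
5′UTR with an iron-responsive element (IRE) that represses translation.

`afexon` is a tested pipeline for this analysis, aimed at computational
biologists working with splice-junction count data from bulk or long-read
RNA-seq of stimulated vs resting cells:

- **Event construction and PSI** — classify AFE/ALE/cassette/MXE/A5SS/A3SS/
  intron-retention events from transcript models plus a junction universe,
  and quantify percent spliced in per candidate isoform:
  Ψ = 100 · (c_incl/ℓ_incl) / Σ_j (c_j/ℓ_j), with effective length ℓ = exon
  lengths + a fixed junction sequence length (88 nt by default).
- **Differential splicing, two routes** — a per-candidate two-sample t-test
  on Ψ (testing gated at |ΔΨ| ≥ 5, BH correction), and a per-event
  Dirichlet-multinomial likelihood-ratio test: y_s ~ DM(n_s; π, φ), LRT of
  condition-specific vs shared π at a common precision φ, χ² with
  (C−1)(K−1) df. φ is shared across events, estimated by Cox–Reid-adjusted
  profile likelihood (see `docs/methods.md`). Discovery threshold:
  adjusted p ≤ 0.25 and |ΔΨ| ≥ 10, novel intron-retention events removed.
- **TSS validation** — extract transcript start sites strand-correctly,
  classify known/novel against the reference-annotation start set, and
  score CAGE peak support per class.
- **Promoter attribution** — select the upregulated first-exon coordinates
  by the ΔΨ sign rule, extend 10 kb upstream, call differential
  accessibility (log2FC > 0.8, raw p < 0.15) and TF-binding peaks
  (log2FC > 1, adjusted p < 0.25), and partition AFE events by the exact
  combination of flagged assays (UpSet decomposition).
- **5′UTR motifs** — an IRE stem-loop detector (C-A-G-N-G-N apical loop,
  5-bp upper stem with Watson–Crick and G·U pairs, unpaired 5′ C bulge),
  Musashi-binding-element scanning ((G/A)U₁₋₃AGU), a motif census of
  inclusion vs exclusion first exons, and a base-pair-maximization hairpin
  support score.
- **Synthetic data with a truth ledger** — every input the pipeline
  consumes can be generated with planted effects (DM junction counts,
  CAGE-like peaks, peak count matrices, UTR sequences), so every discovery
  is scoreable as true/false positive.

## Worked example

The package ships the two *Aim2* 5′UTR isoform sequences (the
RefSeq-annotated one and the longer unannotated, inflammation-induced one):

```
$ afexon motifs src/afexon/data/aim2_5utr.fa
1 IRE hits, 2 MBE hits -> ire_hits.tsv

$ python analysis/06_utr_motif_scan.py
Aim2_5UTR_annotated: 0 IRE, 0 MBE
Aim2_5UTR_unannotated: 1 IRE, 2 MBE
  loop CAGAGC at 95, 5/5 stem pairs, hairpin support 6 bp
```

The unannotated 5′UTR contains exactly one IRE-like stem-loop — loop
`CAGAGC` at offset 95, all five stem positions paired (three Watson–Crick,
two G·U), C bulge present — while the annotated 5′UTR contains none. This
is the molecular basis for iron-dependent translational control of the
inflammatory *Aim2* isoform: with normal iron, iron-regulatory proteins
bind the IRE and block translation.

A full synthetic run (`afexon run-all --seed 7` or the numbered scripts
under `analysis/`) simulates a two-condition cohort, recovers the planted
AFE inclusion shifts by both tests, classifies novel TSSs, and attributes
promoter regulation:

```
$ python analysis/05_promoter_attribution.py
51 AFE promoter windows attributed
UpSet partition: {'ATAC': 5, 'ATAC+IRF3': 3, 'ATAC+p65': 4, 'IRF3': 7, 'IRF3+p65': 4, 'none': 22, 'p65': 6}
fraction with differential accessibility: 0.24; with differential TF binding: 0.47 (planted at 25% per assay)
```

## Layout

```
src/afexon/       library: core types, io, events, diffsplice, tss,
                  promoters, motifs, simulate, pipeline, cli
analysis/         numbered narrative drivers writing results/
tests/            pytest suite (unit, property, end-to-end)
scripts/          acceptance.py
docs/methods.md   models, parameters, numerical choices, limitations
```
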