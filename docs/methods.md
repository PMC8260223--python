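# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention). GTF's
1-based inclusive coordinates are converted on read and write; round trips
are bit-exact. Exons are ranked in the direction of transcription, so the
first exon of a minus-strand transcript is its rightmost genomic block and
its TSS is that block's last base (end − 1). Interval overlap means at
least one shared base under half-open semantics; abutting intervals do not
overlap. `merge_near` merges intervals whose gap is *strictly* less than
`max_gap` (the quoted merging rule is "less than 10 bp"); the closed
variant (`gap <= max_gap`, the `bedtools merge -d` convention) is available
by flag. Peak merging and CAGE matching are strand-blind (peaks are
unstranded); TSS known/novel classification is strand-aware, since a
minus-strand start should not be validated by a plus-strand one.

## Event model

Events are classified from transcript structures per gene, in
strand-normalized (transcription-sense) coordinates:

- **AFE** — distinct, pairwise non-overlapping first exons whose first
  junctions share one downstream acceptor. Overlapping alternatives at a
  shared acceptor are **A5SS** instead (same exon body, alternative donor).
  **ALE/A3SS** are the mirror cases at last exons sharing a donor.
- **Cassette** — an internal exon with flanking junctions whose direct
  skip junction exists in the junction universe; **MXE** — two or more
  disjoint internal exons sharing both flank sites with no skip junction;
  **IR** — a junction whose intron is fully covered by an exon of a
  sibling transcript.

An AFE event with J first exons is one event with J candidates; candidate
j's PSI treats exon j as inclusion against the sum of the others, which is
what makes the coordinate-selection sign rule (below) expressible. Events
are marked novel (`N`) when any candidate part (exon or junction) is
absent from the reference-source transcripts.

Candidate abundance is count / effective length; a junction part
contributes a fixed `jcn_seq_len` (default 88 nt; 238 nt is the value for
junction counts derived from a merged long-read annotation — it is a
config scalar, not inferred). PSI is 100 · abundance / event abundance
sum. A sample's PSIs for an event are missing when the event's total raw
count in that sample is below `count_threshold` (default 10) — the
threshold is applied per sample, the simplest reading of the wrapped
tool's `--thresh` flag.

## Differential splicing

**t-test route.** Per candidate, a pooled-variance two-sample t-test on
per-sample PSI (Welch by flag). Candidates with |ΔΨ| below `delta_thresh`
(default 5) are not assigned a p-value — the testing gate is distinct from
the reporting threshold — and BH runs over assigned p-values only. ΔΨ is
mean(treated) − mean(control), so stimulus-induced inclusion is positive.

**Dirichlet-multinomial route.** Each sample's candidate count vector is
modeled DM(n_s; π, φ): Dirichlet-distributed isoform proportions with mean
π and precision φ, then a multinomial draw; φ → ∞ recovers the
multinomial, small φ means strong biological overdispersion. The LRT
compares condition-specific π against shared π at a common φ; p-values are
upper χ² tails with (C−1)(K−1) df and BH runs across events. Proportions
at fixed φ are fitted by a Minka-type fixed point on α = φπ (renormalized
each sweep, initialized at pooled proportions); φ is profiled on a log
grid refined by golden-section search.

**Precision is shared across events.** With 3 replicates per condition a
per-event φ estimate is far too noisy for the χ² reference: its sampling
error is strongly coupled to the LRT numerator (an event whose groups
split apart by chance looks both "significant" and "precise"), which
simulation shows inflates type-I error to ~0.11–0.18 however the per-event
estimate is taken, while with the true φ the χ² reference is essentially
exact. The default test therefore estimates one φ across all tested
events by maximizing the summed Cox–Reid-adjusted profile likelihood under
the full (per-condition) design — the adjustment subtracts half the
log-determinant of the per-event proportion information, removing the
small-sample bias of plain profiling (unadjusted profiling overestimates φ
by ~70% at 3+3 replicates; adjusted estimates are unbiased within ~2% in
simulation). This is the moderation idea the established
Dirichlet-multinomial differential-usage tools apply, taken to its
simplest limit (a single common precision; no per-event shrinkage or
trend). The sum is evaluated on at most 500 evenly spaced events — the
estimator's Monte-Carlo error is already well below the calibration
tolerance there — and a fixed φ can be supplied instead.

**Filters and thresholds.** Events enter the DM test when ≥
`min_samps_gene_expr` samples carry an event total ≥ `min_gene_expr` and
each candidate reaches `min_feature_expr` in ≥ `min_samps_feature_expr`
samples; presets 6/3/10/0 (mouse-style designs) and 8/4/10/0 (human-style)
are provided. Discovery keeps adjusted p ≤ 0.25 and |ΔΨ| ≥ 10 (strict
preset α = 0.05) and drops novel intron-retention rows. Gene sets are the
per-type deduplicated union over both tests. The ranking composition
orders events by raw p (ties by event id), restricts to |ΔΨ| ≥ 10, and
tabulates event types among the top ⌈k%⌉ for k ∈ {5,10,15,20,25} — ceiling
so small sets stay non-empty. Cross-species conservation uses
case-insensitive symbol identity unless an explicit ortholog map is given.
BH is applied globally per test, not within event-type strata; stratified
adjustment would be the alternative reading.

## Promoter attribution

Significant AFE results (selection gate p ≤ 0.05, stricter than
discovery) yield exon coordinates by the sign rule: a candidate with
ΔΨ > 10 contributes its own first exon; one with ΔΨ < −10 contributes
every sibling candidate with ΔΨ > 10; identical coordinates are
deduplicated. Windows extend 10 kb upstream *strand-aware* (a minus-strand
exon extends genomically right) — the literal genomic-left reading is kept
as an option, but promoters lie 5′ of the exon and that is plainly the
intent. Differential peaks are called from peak count matrices by a
two-sample t-test on log2 CPM (pseudocount 0.5), BH-adjusted, then
thresholded exactly as quoted: accessibility log2FC > 0.8 and *raw*
p < 0.15; TF binding log2FC > 1 and *adjusted* p < 0.25 (the asymmetry is
preserved verbatim, not interpreted). The log-CPM t-test is this package's
own declared stand-in for the original count-model fits, which are out of
scope; only the thresholding logic is shared. A window is flagged per
assay on ≥ 1 bp overlap with ≥ 1 differential peak; the partition label is
the exact flagged-assay set, so labels partition the windows and subset
counts feed the UpSet summary.

## TSS and CAGE

TSSs are one record per transcript at the strand-correct 5′ base. The
reference TSS set is exactly the distinct 1-bp starts of reference-source
transcripts. Known ⇔ the TSS (widened by ± `slack`, default 0) overlaps a
reference start on the same strand. CAGE support reports matched peak
count and best BED score (taken as-is, no re-normalization) per TSS, score
distributions stratified by known/novel, and — when a classifier-true peak
set is supplied — the fraction of each class overlapping it.

## IRE and MBE detection

The IRE detector scans the sense strand (5′UTRs arrive in mRNA sense) for
the apical loop consensus **C-A-G-N-G-N**, pairs the five nucleotides on
either side antiparallel (arm5[i] with arm3[4−i]; Watson–Crick and G·U
count), and requires ≥ `min_pairs` of 5 paired (default 4) plus a C
immediately 5′ of the stem (the unpaired bulge). The loop is deliberately
more degenerate than the canonical CAGUGH: natural IRE-like elements —
including the one in the unannotated Aim2 5′UTR, whose loop is CAGAGC —
fail a canonical-only pattern; the strict mode restores CAGUGH. The
alternative UGC/C internal-loop IRE variant is not modeled. N never pairs
and never matches the loop. Overlapping hits are all reported. MBE
scanning matches (G/A)U₁₋₃AGU with overlapping matches allowed (the regex
reports one match per start position, the shortest U-run).

`hairpin_support` is a Nussinov-style maximum non-crossing base-pair count
(WC + G·U, minimum loop 3) — a structural support score, *not* a
thermodynamic folding; it ranks how much pairing a window can sustain and
nothing more.

## Synthetic data

The generator emulates the study conditions so the statistical machinery
is testable end to end: a single toy chromosome, one gene per 100-kb tile,
strands alternating, every gene following one archetype written in
transcription-space and mirrored genomically on minus strands. Defaults
(chosen once, as the conditions the analysis targets): 3 replicates per
condition, event depth Poisson(200), precision φ = 50 (moderate biological
overdispersion), planted AFE inclusion shifts of 30 PSI points in half of
AFE events; CAGE peaks 20–50 bp wide covering 45% of true TSSs (the
observed novel-TSS support level in FANTOM-scale data) with low-scoring
decoys at 20%; peak counts negative-binomial (Gamma–Poisson, shape 50,
base mean 200) with planted log2FC = 3 at 25% of AFE promoters per assay,
independently per assay; 5′UTRs 200 nt with canonical fully-paired IREs
planted at rate 0.3; DE tables with half the AFE genes planted beyond
|log2FC| ≥ 2, p_adj ≤ 0.05. Counts are drawn by the exact two-stage DM
construction (Dirichlet then multinomial), matching the fitted model's
data-generating process. All generators are bit-reproducible under
(parameters, seed), and the truth ledger records every planted effect.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic sequence composition (background is
uniform ACGT), overlapping genes and shared exons across genes, junction
mis-assignment and mapping artifacts, per-event precision heterogeneity
(one φ generates all events), library-size imbalance, batch effects, and
correlated replicates. Calibration and power results transfer to real data
only to the extent the DM noise model does.

## Numerical choices

- PSI cells are NaN (missing), never zero-filled; BH excludes missing
  p-values from the number of tests.
- Two-candidate groups with zero within-group variance and a real mean
  difference get p = 0 in the t-test rather than a NaN from a degenerate
  statistic.
- DM log-likelihoods use log-gamma throughout; π_j = 0 with positive
  counts returns −∞, not an exception. The fixed point stops at 1e-9
  sup-norm change or 100 sweeps; φ profiling covers [0.5, 5·10⁴] on an
  18-point log grid before refinement to ~0.1% in log φ.
- Sorting and tie-breaks are deterministic everywhere (event ids,
  coordinates), and all writers emit fixed float formats, so identical
  seeds give byte-identical output bundles.
- Problem sizes in the test suite and acceptance script (2,000 events for
  calibration, 400 for power, 80-gene end-to-end runs) hold Monte-Carlo
  error comfortably below the asserted tolerances while keeping a full run
  in minutes on one core.

## Known limitations

- The event classifier targets clean isoform structures; it does not
  resolve compound events (e.g. a cassette nested inside an AFE region) or
  junction-only alternative-donor/acceptor subtypes, which are explicitly
  out of scope.
- A single shared precision is a deliberate simplification; data with
  strong per-event dispersion heterogeneity would need per-event shrinkage
  estimates between the two extremes implemented here.
- The IRE detector is a pattern-plus-pairing rule, not a thermodynamic or
  covariance model; its specificity is characterized empirically on random
  background (roughly one hit per 10–15 kb at default settings) rather
  than guaranteed.
- χ² asymptotics for the LRT are validated by simulation at the default
  study conditions; far smaller depths or many-candidate events may drift.
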