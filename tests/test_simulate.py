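import collections

import numpy as np
import pytest

from afexon.core import ValidationError
from afexon.events import build_events
from afexon.simulate import (
    make_toy_annotation,
    plant_utr_motifs,
    simulate_cage_peaks,
    simulate_de_table,
    simulate_junction_counts,
    simulate_peak_counts,
)


class TestToyAnnotation:
    def test_single_afe_gene_shares_downstream_exons(self):
        transcripts, _ = make_toy_annotation(n_genes=1, afe_fraction=1.0, n_first_exons=2)
        assert len(transcripts) == 2
        a, b = transcripts
        assert a.first_exon.interval != b.first_exon.interval
        assert [e.interval for e in a.exons[1:]] == [e.interval for e in b.exons[1:]]

    def test_zero_afe_fraction_yields_no_afe_events(self):
        transcripts, truth = make_toy_annotation(n_genes=12, afe_fraction=0.0, seed=1)
        assert "AFE" not in truth.event_census
        assert all(e.event_type != "AFE" for e in build_events(transcripts))

    def test_event_census_matches_ledger_exactly(self):
        transcripts, truth = make_toy_annotation(n_genes=100, afe_fraction=0.4, seed=5)
        built = collections.Counter(e.event_type for e in build_events(transcripts))
        assert dict(built) == truth.event_census

    def test_invalid_first_exon_count_rejected(self):
        with pytest.raises(ValidationError):
            make_toy_annotation(n_genes=4, afe_fraction=1.0, n_first_exons=1)

    def test_novel_afe_genes_marked_longread(self):
        transcripts, truth = make_toy_annotation(
            n_genes=20, afe_fraction=1.0, novel_afe_fraction=0.5, seed=2
        )
        longread_genes = {t.gene_id for t in transcripts if t.source == "longread"}
        assert longread_genes == truth.novel_afe_genes
        assert len(longread_genes) == 10


class TestJunctionCounts:
    def test_bit_reproducible_under_seed(self, toy_annotation):
        transcripts, truth = toy_annotation
        a = simulate_junction_counts(transcripts, truth, seed=9)
        b = simulate_junction_counts(transcripts, truth, seed=9)
        assert a.counts.equals(b.counts)

    def test_high_precision_concentrates_psi(self):
        transcripts, truth = make_toy_annotation(n_genes=40, afe_fraction=1.0, seed=1)
        counts = simulate_junction_counts(
            transcripts, truth, depth=10_000, phi=1e7, effect_fraction=0.0, seed=2
        )
        evs = build_events(transcripts)
        spreads = []
        for ev in evs:
            y = counts.counts.loc[[ev.row_id(0), ev.row_id(1)]].to_numpy(float)
            props = y[0] / y.sum(axis=0)
            true_p = truth.event_effects[ev.event_id]["psi_control"][0] / 100
            spreads.append(np.abs(props - true_p).max())
        # multinomial limit at depth 1e4: sampling sd ~ 0.005
        assert np.median(spreads) < 0.02

    def test_null_generator_has_no_mean_shift(self):
        transcripts, truth = make_toy_annotation(n_genes=60, afe_fraction=1.0, seed=3)
        counts = simulate_junction_counts(transcripts, truth, effect_fraction=0.0, seed=4)
        evs = build_events(transcripts)
        ctrl = counts.samples_of("control")
        trt = counts.samples_of("LPS")
        deltas = []
        for ev in evs:
            y = counts.counts.loc[[ev.row_id(0), ev.row_id(1)]]
            pc = (y[ctrl].iloc[0] / y[ctrl].sum()).mean()
            pt = (y[trt].iloc[0] / y[trt].sum()).mean()
            deltas.append(pt - pc)
        assert abs(np.mean(deltas)) < 0.02

    def test_method_of_moments_recovers_precision(self):
        # rho = 1/(phi+1); per-sample proportion variance under DM is
        # p(1-p) * (1 + (n-1) rho) / n
        transcripts, truth = make_toy_annotation(n_genes=1000, afe_fraction=1.0, seed=6)
        phi_true = 30.0
        counts = simulate_junction_counts(
            transcripts, truth, phi=phi_true, depth=500, effect_fraction=0.0, seed=7
        )
        evs = build_events(transcripts)
        rhos = []
        for ev in evs:
            y = counts.counts.loc[[ev.row_id(0), ev.row_id(1)]].to_numpy(float)
            n = y.sum(axis=0)
            ok = n > 0
            p = y[0, ok] / n[ok]
            if ok.sum() < 4:
                continue
            pbar = p.mean()
            if pbar in (0, 1):
                continue
            v = p.var(ddof=1)
            nbar = n[ok].mean()
            rho = (v * nbar / (pbar * (1 - pbar)) - 1) / (nbar - 1)
            rhos.append(rho)
        phi_hat = 1 / np.mean(rhos) - 1
        assert phi_hat == pytest.approx(phi_true, rel=0.2)

    def test_counts_sum_to_drawn_totals_and_nonnegative(self, toy_counts):
        assert (toy_counts.counts.to_numpy() >= 0).all()

    def test_invalid_precision_rejected(self, toy_annotation):
        transcripts, truth = toy_annotation
        with pytest.raises(ValidationError):
            simulate_junction_counts(transcripts, truth, phi=0.0)


class TestCagePeaks:
    def test_rate_one_covers_every_tss(self):
        transcripts, truth = make_toy_annotation(n_genes=20, afe_fraction=1.0, seed=1)
        simulate_cage_peaks(transcripts, truth, true_rate=1.0, decoy_rate=0.0, seed=2)
        assert truth.cage_covered_tss == truth.true_tss

    def test_rate_zero_covers_none(self):
        transcripts, truth = make_toy_annotation(n_genes=20, afe_fraction=1.0, seed=1)
        records = simulate_cage_peaks(transcripts, truth, true_rate=0.0, decoy_rate=0.0, seed=2)
        assert records == [] and truth.cage_covered_tss == set()

    def test_mixed_rates_match_ledger(self):
        transcripts, truth = make_toy_annotation(n_genes=200, afe_fraction=1.0, seed=1)
        records = simulate_cage_peaks(transcripts, truth, true_rate=0.45, decoy_rate=0.3, seed=2)
        n_true = sum(1 for _, name, _ in records if name.startswith("cage_true"))
        assert n_true == len(truth.cage_covered_tss)
        frac = len(truth.cage_covered_tss) / len(truth.true_tss)
        se = np.sqrt(0.45 * 0.55 / len(truth.true_tss))
        assert abs(frac - 0.45) < 3 * se


class TestPeakCounts:
    def test_three_assays_get_independent_ledgers(self):
        transcripts, truth = make_toy_annotation(n_genes=40, afe_fraction=0.5, seed=1)
        out = simulate_peak_counts(transcripts, truth, seed=2)
        assert set(out) == {"ATAC", "p65", "IRF3"}
        ledgers = [truth.diff_peak_genes[a] for a in out]
        assert not (ledgers[0] == ledgers[1] == ledgers[2])
        for assay, genes in truth.diff_peak_genes.items():
            assert genes <= set(truth.afe_genes)

    def test_zero_effect_plants_nothing_detectable(self):
        transcripts, truth = make_toy_annotation(n_genes=40, afe_fraction=0.5, seed=1)
        out = simulate_peak_counts(transcripts, truth, effect_lfc=0.0, seed=2)
        peaks, counts = out["ATAC"]
        diff = truth.diff_peaks["ATAC"]
        mat = counts.counts
        ctrl = counts.samples_of("control")
        trt = counts.samples_of("LPS")
        lfc = np.log2(mat[trt].mean(axis=1) + 0.5) - np.log2(mat[ctrl].mean(axis=1) + 0.5)
        assert lfc.abs().max() < 0.8


class TestUtrMotifs:
    def test_rate_extremes(self):
        records, truth = plant_utr_motifs(n_seqs=10, ire_rate=0.0, seed=1)
        assert all(not v for v in truth.planted_motifs.values())
        records, truth = plant_utr_motifs(n_seqs=10, ire_rate=1.0, seed=1)
        assert all(len(v) == 1 for v in truth.planted_motifs.values())

    def test_short_sequence_rejected(self):
        with pytest.raises(ValidationError):
            plant_utr_motifs(n_seqs=2, length=20)

    def test_reproducible(self):
        a, _ = plant_utr_motifs(n_seqs=5, seed=3)
        b, _ = plant_utr_motifs(n_seqs=5, seed=3)
        assert a == b


class TestDeTable:
    def test_planted_genes_pass_thresholds(self):
        genes = [f"g{i}" for i in range(40)]
        from afexon.simulate import SyntheticTruth

        truth = SyntheticTruth()
        de = simulate_de_table(genes, truth, de_fraction=0.5, seed=1)
        called = set(de.loc[(de["log2fc"].abs() >= 2) & (de["p_adj"] <= 0.05), "gene"])
        assert called == truth.de_genes
        assert len(called) == 20
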