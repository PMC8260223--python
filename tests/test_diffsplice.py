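import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from afexon.core import CountTable, ValidationError
from afexon.diffsplice import (
    conserved_genes,
    dm_fit,
    dm_loglik,
    dm_lrt,
    ranking_composition,
    significant_events,
    ttest_diff,
    union_genes,
)
from afexon.events import build_events, psi_table
from afexon.simulate import make_toy_annotation, simulate_junction_counts
from conftest import tx


def _two_group_counts(c_counts, t_counts):
    """One 2-candidate AFE event with explicit per-sample candidate counts."""
    t1 = tx("t1", "g", [(0, 200), (5000, 5200)])
    t2 = tx("t2", "g", [(600, 800), (5000, 5200)])
    events = build_events([t1, t2])
    (ev,) = events
    samples = [f"control_{i}" for i in range(len(c_counts))] + [
        f"LPS_{i}" for i in range(len(t_counts))
    ]
    mat = np.array(c_counts + t_counts).T
    counts = CountTable(
        pd.DataFrame(mat, index=[ev.row_id(0), ev.row_id(1)], columns=samples),
        {s: ("control" if s.startswith("control") else "LPS") for s in samples},
    )
    return events, counts


class TestTtest:
    def test_no_difference_is_untested_at_default_gate(self):
        events, counts = _two_group_counts([[50, 50]] * 3, [[50, 50]] * 3)
        psi = psi_table(events, counts)
        res = ttest_diff(psi)
        assert res["delta_psi"].iloc[0] == pytest.approx(0.0)
        assert res["p_raw"].isna().all()

    def test_full_separation_gives_tiny_p(self):
        events, counts = _two_group_counts(
            [[10, 90], [11, 89], [10, 90]], [[90, 10], [89, 11], [91, 9]]
        )
        psi = psi_table(events, counts)
        res = ttest_diff(psi)
        row = res[res["candidate_index"] == 0].iloc[0]
        assert row["delta_psi"] == pytest.approx(80, abs=2)
        assert row["p_raw"] < 1e-6

    def test_group_entirely_missing_is_untested_not_fatal(self):
        events, counts = _two_group_counts([[2, 3]] * 3, [[60, 40]] * 3)
        psi = psi_table(events, counts, count_threshold=10)  # control all below
        res = ttest_diff(psi)
        assert res["p_raw"].isna().all()

    def test_sign_agreement_with_dm(self, toy_annotation):
        transcripts, truth = toy_annotation
        counts = simulate_junction_counts(transcripts, truth, effect_fraction=0.5, seed=6)
        events = build_events(transcripts)
        psi = psi_table(events, counts)
        rt = ttest_diff(psi, delta_thresh=0.0)
        rd = dm_lrt(events, counts, precision=50.0)
        merged = rt.merge(rd, on=["event_id", "candidate_index"], suffixes=("_t", "_d"))
        big = merged[merged["delta_psi_t"].abs() > 5]
        assert (np.sign(big["delta_psi_t"]) == np.sign(big["delta_psi_d"])).all()


class TestDmLoglik:
    def test_empty_sample_set_is_zero(self):
        assert dm_loglik(np.zeros((0, 2)), [0.5, 0.5], 10.0) == 0.0

    def test_single_draw_reduces_to_categorical(self):
        for phi in (0.5, 3.0, 800.0):
            assert dm_loglik([[1, 0]], [0.5, 0.5], phi) == pytest.approx(np.log(0.5))
            assert dm_loglik([[0, 1]], [0.2, 0.8], phi) == pytest.approx(np.log(0.8))

    def test_large_precision_approaches_multinomial(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 5))
            pi = rng.dirichlet(np.ones(k) * 2)
            y = rng.multinomial(50, pi, size=3)
            multi = sum(
                gammaln(r.sum() + 1) - gammaln(r + 1).sum() + (r * np.log(pi)).sum()
                for r in y
            )
            assert dm_loglik(y, pi, 1e8) == pytest.approx(multi, abs=1e-4)

    def test_zero_probability_with_counts_is_neg_inf(self):
        assert dm_loglik([[3, 1]], [0.0, 1.0], 5.0) == float("-inf")

    def test_matches_direct_loggamma_evaluation(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 5))
            s = int(rng.integers(1, 5))
            pi = rng.dirichlet(np.ones(k))
            phi = float(rng.uniform(0.5, 200))
            y = rng.integers(0, 40, size=(s, k)).astype(float)
            direct = 0.0
            for row in y:
                n = row.sum()
                direct += gammaln(n + 1) - sum(gammaln(v + 1) for v in row)
                direct += gammaln(phi) - gammaln(n + phi)
                direct += sum(
                    gammaln(v + phi * p) - gammaln(phi * p) for v, p in zip(row, pi)
                )
            assert dm_loglik(y, pi, phi) == pytest.approx(direct, abs=1e-8)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            dm_loglik([[1, 1]], [0.5, 0.5], 0.0)
        with pytest.raises(ValidationError):
            dm_loglik([[1, 1]], [0.7, 0.7], 1.0)


class TestDmFit:
    def test_identical_groups_give_null_statistic(self):
        y = np.array([[40, 60]] * 3)
        fit = dm_fit({"a": y, "b": y})
        assert fit.lrt_stat == pytest.approx(0.0, abs=1e-4)
        assert fit.df == 1

    def test_recovers_opposite_proportions(self, rng):
        def draw(pi, n=3, depth=500, phi=50):
            return np.array(
                [rng.multinomial(depth, rng.dirichlet(phi * np.asarray(pi))) for _ in range(n)]
            )

        fit = dm_fit({"c": draw([0.2, 0.8]), "t": draw([0.8, 0.2])})
        assert fit.pi_by_condition["c"][0] == pytest.approx(0.2, abs=0.05)
        assert fit.pi_by_condition["t"][0] == pytest.approx(0.8, abs=0.05)
        assert fit.lrt_stat > stats.chi2.ppf(0.95, 1)

    def test_large_phi_matches_observed_proportions(self):
        yc = np.array([[30, 70]])
        yt = np.array([[60, 40]])
        fit = dm_fit({"c": yc, "t": yt}, phi=1e7)
        assert fit.pi_by_condition["c"][0] == pytest.approx(0.3, abs=1e-3)
        assert fit.pi_by_condition["t"][0] == pytest.approx(0.6, abs=1e-3)

    def test_all_zero_counts_is_fit_error(self):
        with pytest.raises(ValidationError):
            dm_fit({"a": np.zeros((3, 2)), "b": np.ones((3, 2))})

    def test_invariant_to_sample_order_and_label_swap(self, rng):
        yc = rng.integers(1, 60, size=(3, 2)).astype(float)
        yt = rng.integers(1, 60, size=(3, 2)).astype(float)
        a = dm_fit({"c": yc, "t": yt}, phi=50.0)
        b = dm_fit({"c": yc[::-1], "t": yt[::-1]}, phi=50.0)
        c = dm_fit({"t": yt, "c": yc}, phi=50.0)
        assert a.lrt_stat == pytest.approx(b.lrt_stat, abs=1e-8)
        assert a.lrt_stat == pytest.approx(c.lrt_stat, abs=1e-8)


class TestDmLrt:
    def test_event_below_sample_filter_excluded(self):
        # expressed in only 5 of 6 samples at min_samps_gene_expr=6
        events, counts = _two_group_counts(
            [[50, 50], [50, 50], [0, 0]], [[50, 50], [50, 50], [50, 50]]
        )
        res = dm_lrt(events, counts, min_samps_gene_expr=6)
        assert res.empty
        assert res.attrs["excluded"] == {events[0].event_id: "min_samps_gene_expr"}

    def test_planted_effect_detected(self):
        events, counts = _two_group_counts(
            [[30, 170], [35, 165], [28, 172]], [[95, 105], [100, 100], [90, 110]]
        )
        res = dm_lrt(events, counts, precision=50.0)
        assert res["p_raw"].iloc[0] < 0.01
        assert res[res["candidate_index"] == 0]["delta_psi"].iloc[0] > 25


class TestSignificantEvents:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["event_id", "event_type", "novelty", "gene_id", "delta_psi", "p_adj"],
        )

    def test_discovery_thresholds(self):
        df = self._frame(
            [
                ("e1", "AFE", "K", "g1", 12.0, 0.20),  # kept
                ("e2", "AFE", "K", "g2", 9.0, 0.20),  # delta below 10
                ("e3", "AFE", "K", "g3", 15.0, 0.30),  # p above 0.25
            ]
        )
        kept = significant_events(df, alpha=0.25, delta=10)
        assert list(kept["event_id"]) == ["e1"]

    def test_novel_intron_retention_removed(self):
        df = self._frame([("e1", "IR", "N", "g1", 50.0, 0.01), ("e2", "IR", "K", "g2", 50.0, 0.01)])
        kept = significant_events(df)
        assert list(kept["event_id"]) == ["e2"]


class TestUnionAndConservation:
    def _res(self, pairs):
        return pd.DataFrame(pairs, columns=["event_type", "gene_id"])

    def test_union_deduplicates(self):
        u = union_genes(
            self._res([("AFE", "a"), ("AFE", "b")]), self._res([("AFE", "b"), ("IR", "c")])
        )
        assert u == {"AFE": {"a", "b"}, "IR": {"c"}}

    def test_union_idempotent(self):
        r = self._res([("AFE", "a")])
        assert union_genes(r, r) == {"AFE": {"a"}}

    def test_case_insensitive_symbol_match(self):
        out = conserved_genes(
            {"mouse": {"AFE": {"Aim2", "Irf7"}}, "human": {"AFE": {"AIM2", "STAT1"}}}
        )
        assert out["AFE"] == {"Aim2"}

    def test_disjoint_sets_empty(self):
        out = conserved_genes({"mouse": {"AFE": {"a"}}, "human": {"AFE": {"b"}}})
        assert out["AFE"] == set()

    def test_planted_shared_genes_recovered(self, rng):
        shared = {f"Shared{i}" for i in range(11)}
        mouse = shared | {f"M{i}" for i in range(30)}
        human = {g.upper() for g in shared} | {f"H{i}" for i in range(25)}
        out = conserved_genes({"mouse": {"AFE": mouse}, "human": {"AFE": human}})
        assert out["AFE"] == shared


class TestRankingComposition:
    def _results(self, types_and_p):
        rows = []
        for i, (etype, p) in enumerate(types_and_p):
            rows.append(
                {
                    "event_id": f"e{i:03d}",
                    "event_type": etype,
                    "gene_id": f"g{i}",
                    "delta_psi": 50.0,
                    "p_raw": p,
                }
            )
        return pd.DataFrame(rows)

    def test_single_type_everywhere(self):
        res = self._results([("AFE", p) for p in np.linspace(0.001, 0.5, 40)])
        comp = ranking_composition(res)
        assert set(comp.columns) == {"AFE"}

    def test_ceiling_top_five_percent_of_twenty(self):
        res = self._results([("AFE", 0.001)] + [("IR", p) for p in np.linspace(0.01, 0.5, 19)])
        comp = ranking_composition(res, percents=(5,))
        assert comp.loc[5].sum() == 1 and comp.loc[5, "AFE"] == 1

    def test_small_delta_events_excluded(self):
        res = self._results([("AFE", 0.001), ("IR", 0.002)])
        res.loc[res["event_type"] == "IR", "delta_psi"] = 5.0
        comp = ranking_composition(res, percents=(25,))
        assert "IR" not in comp.columns

    def test_afe_share_declines_when_afe_effects_lead(self):
        rows = [("AFE", p) for p in np.linspace(1e-6, 0.01, 30)]
        rows += [("CASSETTE", p) for p in np.linspace(0.02, 0.9, 70)]
        comp = ranking_composition(self._results(rows))
        share = comp["AFE"] / comp.sum(axis=1)
        assert (share.diff().dropna() <= 1e-12).all()
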