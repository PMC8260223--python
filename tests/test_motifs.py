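import numpy as np
import pytest

from afexon.core import ValidationError
from afexon.io import package_data, read_fasta
from afexon.motifs import (
    hairpin_support,
    motif_census,
    scan_ire,
    scan_mbe,
)
from afexon.simulate import plant_utr_motifs


@pytest.fixture(scope="module")
def aim2():
    return dict(read_fasta(package_data("aim2_5utr.fa")))


CANONICAL = "C" + "GGAGC" + "CAGTGT" + "GCTCC"  # bulge + arm + loop + paired arm


class TestScanIre:
    def test_unannotated_aim2_utr_has_single_element(self, aim2):
        hits = scan_ire(aim2["Aim2_5UTR_unannotated"], "unannotated")
        assert len(hits) == 1
        (h,) = hits
        assert h.loop_seq == "CAGAGC"
        assert h.stem_pairs == 5  # 3 Watson-Crick + 2 G.U

    def test_annotated_aim2_utr_has_none(self, aim2):
        assert scan_ire(aim2["Aim2_5UTR_annotated"], "annotated") == []

    def test_planted_canonical_element_found_exactly_once(self, rng):
        bg = "".join(rng.choice(list("ACGT"), size=60))
        # avoid accidental second hits by rejecting backgrounds that scan alone
        while scan_ire(bg):
            bg = "".join(rng.choice(list("ACGT"), size=60))
        seq = bg[:20] + CANONICAL + bg[20:]
        hits = scan_ire(seq)
        assert len(hits) == 1
        assert hits[0].stem_pairs == 5
        assert hits[0].span[0] == 20

    def test_case_and_tu_spelling_invariant(self):
        hits_dna = scan_ire(CANONICAL.lower())
        hits_rna = scan_ire(CANONICAL.replace("T", "U"))
        assert len(hits_dna) == len(hits_rna) == 1
        assert hits_dna[0].loop_start == hits_rna[0].loop_start

    def test_reverse_complement_does_not_preserve_hit(self):
        comp = str.maketrans("ACGT", "TGCA")
        rc = CANONICAL.translate(comp)[::-1]
        assert scan_ire(CANONICAL) and not scan_ire(rc)

    def test_strict_loop_mode_requires_canonical_consensus(self, aim2):
        # the Aim2 element's CAGAGC loop fails the canonical CAGUGH pattern
        assert scan_ire(aim2["Aim2_5UTR_unannotated"], strict_loop=True) == []
        assert len(scan_ire(CANONICAL, strict_loop=True)) == 1

    def test_short_sequence_yields_nothing(self):
        assert scan_ire("CAGTG") == []

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValidationError):
            scan_ire("ACGTXACGT" * 3)

    def test_min_pairs_five_requires_full_stem(self):
        broken = "C" + "GGAGC" + "CAGTGT" + "GCTGG"  # two terminal mismatches
        assert scan_ire(broken, min_pairs=5) == []
        assert len(scan_ire(CANONICAL, min_pairs=5)) == 1

    def test_background_hit_rate_stable_across_seeds(self):
        rates = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n, hits = 0, 0
            for _ in range(60):
                seq = "".join(rng.choice(list("ACGT"), size=500))
                hits += len(scan_ire(seq))
                n += len(seq)
            rates.append(hits / n)
        p = np.mean(rates)
        se = np.sqrt(p * (1 - p) / (60 * 500))
        assert max(abs(r - p) for r in rates) < 3 * se + 1e-9

    def test_planted_set_recovered_against_ledger(self):
        records, truth = plant_utr_motifs(n_seqs=500, length=200, ire_rate=0.5, seed=4)
        detected = {sid for sid, seq in records if scan_ire(seq, sid)}
        planted = {sid for sid, v in truth.planted_motifs.items() if v}
        missed = planted - detected
        assert not missed  # every planted canonical element has a full stem
        fp = detected - planted
        assert len(fp) / 500 < 0.10  # measured background rate stays low


class TestScanMbe:
    @pytest.mark.parametrize("seq,n", [("GUAGU", 1), ("AUUUAGU", 1), ("GGGGG", 0)])
    def test_basic_patterns(self, seq, n):
        assert len(scan_mbe(seq)) == n

    def test_matches_naive_sliding_window(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=10_000))
        naive = []
        for i in range(len(seq)):
            for run in (1, 2, 3):
                m = seq[i : i + 3 + run]
                if len(m) == 3 + run and m[0] in "GA" and m[1 : 1 + run] == "U" * run and m[1 + run :] == "AG":
                    naive.append(i)
        # naive pattern: [GA] U{run} A G — plus trailing U
        naive2 = []
        for i in range(len(seq)):
            for run in (1, 2, 3):
                m = seq[i : i + 4 + run]
                if (
                    len(m) == 4 + run
                    and m[0] in "GA"
                    and m[1 : 1 + run] == "U" * run
                    and m[1 + run :] == "AGU"
                ):
                    naive2.append(i)
                    break  # regex reports one (shortest) match per start
        got = [pos for pos, _ in scan_mbe(seq)]
        assert got == naive2


class TestHairpinSupport:
    def test_unpairable_sequence(self):
        assert hairpin_support("AAAA") == 0

    def test_perfect_stem(self):
        assert hairpin_support("GGGAAACCC") == 3

    def test_five_bp_hairpin_with_hexaloop(self):
        stem5 = "GCGCG"
        loop = "AAAAAA"
        stem3 = "CGCGC"
        assert hairpin_support(stem5 + loop + stem3) == 5

    def test_matches_exhaustive_enumeration(self, rng):
        from itertools import combinations

        def paired(a, b):
            return {a, b} in ({"A", "U"}, {"G", "C"}, {"G", "U"})

        def best(seq):
            n = len(seq)
            pairs = [
                (i, j)
                for i in range(n)
                for j in range(i + 4, n)
                if paired(seq[i], seq[j])
            ]

            def rec(chosen, remaining):
                if not remaining:
                    return len(chosen)
                (i, j), rest = remaining[0], remaining[1:]
                out = rec(chosen, rest)
                compatible = all(
                    (j < a) or (b < i) or (a < i and j < b) or (i < a and b < j)
                    for a, b in chosen
                ) and all(x not in (i, j) for p in chosen for x in p)
                if compatible:
                    out = max(out, rec(chosen + [(i, j)], rest))
                return out

            return rec([], pairs)

        for _ in range(12):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(5, 11))))
            assert hairpin_support(seq) == best(seq)


class TestMotifCensus:
    def test_identical_sets_give_unit_ratio(self):
        seqs = [("a", CANONICAL + "GUAGU")]
        out = motif_census(seqs, seqs)
        assert (out["ratio"] == 1.0).all()

    def test_exclusion_only_background_has_zero_ire(self, rng):
        inc, _ = plant_utr_motifs(n_seqs=20, ire_rate=1.0, seed=1)
        exc = [("b", "ACGT" * 50)]
        out = motif_census(inc, exc)
        assert out.loc["IRE", "exclusion_total"] == 0
        assert out.loc["IRE", "inclusion_total"] >= 20

    def test_planting_rate_ratio_recovered(self):
        inc, _ = plant_utr_motifs(n_seqs=300, ire_rate=0.3, seed=2)
        exc, _ = plant_utr_motifs(n_seqs=300, ire_rate=0.1, seed=3)
        out = motif_census(inc, exc)
        assert out.loc["IRE", "ratio"] == pytest.approx(3.0, rel=0.5)
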