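import numpy as np
import pytest

from reinforcescan import annotate
from reinforcescan.annotate import (BsiftRecord, bsift_score, classify_effect,
                                    flank_sequences, motif_matches,
                                    motif_uniqueness, unique_parapatric_sites)
from reinforcescan.io import (Gene, GeneAnnotationSet, MotifLibrary, Pwm,
                              SiftTable, Transcript)
from conftest import make_matrix, make_popmap
import oracles


# ---------------------------------------------------------------------------
# parapatric-unique sites

class TestUniqueSites:
    def _G(self, rows):
        popmap = make_popmap((2, 2, 2, 3))
        G = make_matrix(rows, sample_ids=list(popmap.mapping))
        return G, popmap

    def test_private_alt_selected(self):
        #                 am am pm pm af af pf pf pf
        G, popmap = self._G([[0, 0, 0, 0, 0, 0, 2, 1, 0]])
        assert list(unique_parapatric_sites(G, popmap)) == [0]

    def test_shared_alt_not_selected(self):
        G, popmap = self._G([[0, 0, 0, 0, 1, 0, 2, 1, 0]])
        assert list(unique_parapatric_sites(G, popmap)) == []

    def test_alt_absent_in_para_fas_not_selected(self):
        G, popmap = self._G([[1, 0, 2, 0, 1, 0, 0, 0, 0]])
        assert list(unique_parapatric_sites(G, popmap)) == []

    def test_missing_contributes_nothing(self):
        M = annotate.MISSING
        G, popmap = self._G([[M, M, 0, 0, 0, 0, 1, M, 0]])
        assert list(unique_parapatric_sites(G, popmap)) == [0]

    def test_region_restriction(self):
        popmap = make_popmap((2, 2, 2, 3))
        rows = [[0, 0, 0, 0, 0, 0, 1, 0, 0]] * 3
        G = make_matrix(rows, positions=[100, 200, 300],
                        sample_ids=list(popmap.mapping))
        got = unique_parapatric_sites(G, popmap, regions=[(150, 250)])
        assert list(got) == [1]

    def test_monotone_in_other_carriers(self, rng):
        """Removing a non-parapatric-fascicularis carrier can only grow
        the selected set."""
        popmap_full = make_popmap((3, 2, 2, 3))
        dosage = rng.integers(0, 3, size=(60, 10)).astype(np.int8)
        G_full = make_matrix(dosage, sample_ids=list(popmap_full.mapping))
        sel_full = set(unique_parapatric_sites(G_full, popmap_full))
        popmap_small = make_popmap((2, 2, 2, 3))
        G_small = make_matrix(np.delete(dosage, 2, axis=1),
                              sample_ids=list(popmap_small.mapping))
        sel_small = set(unique_parapatric_sites(G_small, popmap_small))
        assert sel_full <= sel_small


# ---------------------------------------------------------------------------
# effect classification on a hand-annotated toy locus

def toy_locus():
    """Two genes on a 7 kb contig of 'A's with patched codons.

    gene_plus  [100,400)+ : exons [100,180)+[240,400), CDS [130,180)+[240,340)
    gene_minus [450,570)- : exon  [450,570),           CDS [460,550)
    """
    seq = list("A" * 7000)
    seq[136:139] = list("TAC")        # codon for the stop_gained case
    seq[547:550] = list("TTT")        # minus-strand codon AAA (complemented)
    ref = {"chrT": "".join(seq)}
    tx1 = Transcript("tx1", 100, 400, [(100, 180), (240, 400)],
                     [(130, 180), (240, 340)])
    tx2 = Transcript("tx2", 450, 570, [(450, 570)], [(460, 550)])
    genes = GeneAnnotationSet([
        Gene("gene_plus", "chrT", 100, 400, "+", [tx1]),
        Gene("gene_minus", "chrT", 450, 570, "-", [tx2]),
    ])
    return genes, ref


# (1-based pos, ref, alt, transcript, expected class) — hand-derived
TOY_CASES = [
    (133, "A", "G", "tx1", "synonymous"),      # AAA->AAG, Lys
    (134, "A", "G", "tx1", "missense"),        # AAA->GAA, Lys->Glu
    (139, "C", "A", "tx1", "stop_gained"),     # TAC->TAA
    (241, "A", "C", "tx1", "missense"),        # junction codon AAA->AAC
    (182, "A", "C", "tx1", "splice_donor"),    # intron base 2 after exon 1
    (240, "A", "C", "tx1", "splice_acceptor"),  # intron base 1 before exon 2
    (186, "A", "C", "tx1", "splice_region"),   # intron base 6
    (111, "A", "C", "tx1", "5_prime_UTR"),
    (351, "A", "C", "tx1", "3_prime_UTR"),
    (201, "A", "C", "tx1", "intron"),
    (51, "A", "C", "tx1", "upstream_gene"),
    (6501, "A", "C", None, "intergenic"),
    (550, "T", "C", "tx2", "missense"),        # minus strand AAA->GAA
    (581, "A", "C", "tx2", "upstream_gene"),   # right of minus-strand tx
]


class TestClassifyEffect:
    @pytest.mark.parametrize("pos,ref,alt,tx,expected", TOY_CASES)
    def test_hand_annotated_toy_gene(self, pos, ref, alt, tx, expected):
        genes, fasta = toy_locus()
        anns = classify_effect(pos, ref, alt, genes, "chrT", fasta)
        if tx is None:
            assert [a.effect for a in anns] == [expected]
        else:
            got = {a.transcript_id: a.effect for a in anns}
            assert got[tx] == expected

    def test_frameshifted_cds_skipped(self):
        seq = {"chrT": "A" * 1000}
        tx = Transcript("bad", 100, 400, [(100, 400)], [(100, 200)])
        genes = GeneAnnotationSet([Gene("g", "chrT", 100, 400, "+", [tx])])
        anns = classify_effect(150, "A", "G", genes, "chrT", seq)
        assert [a.effect for a in anns] == ["intergenic"]   # no usable tx

    def test_reference_mismatch_raises(self):
        genes, fasta = toy_locus()
        with pytest.raises(ValueError, match="mismatch"):
            classify_effect(133, "C", "G", genes, "chrT", fasta)


# ---------------------------------------------------------------------------
# flank pairs

class TestFlankSequences:
    def _G(self, positions, ref, alt, n_samples=4):
        dosage = np.ones((len(positions), n_samples), dtype=np.int8)
        return make_matrix(dosage, positions=positions, ref=ref, alt=alt)

    def test_center_and_length(self):
        seq = {"chr1": "ACGTACGTACGTACGTACGT"}
        G = self._G([10], ["C"], ["T"])
        pairs = flank_sequences(G, [0], seq)
        assert len(pairs[0].ref_seq) == len(pairs[0].alt_seq) == 13
        assert pairs[0].ref_seq[6] == "C" and pairs[0].alt_seq[6] == "T"
        diff = [i for i in range(13)
                if pairs[0].ref_seq[i] != pairs[0].alt_seq[i]]
        assert diff == [6]

    def test_consensus_carries_nearby_variant(self):
        seq = {"chr1": "AAAAAAAAAAAAAAAAAAAA"}
        G = self._G([10, 12], ["A", "A"], ["G", "T"])
        pairs = flank_sequences(G, [0, 1], seq)
        # the alt flank of the first site also shows the second variant
        assert pairs[0].alt_seq[6] == "G" and pairs[0].alt_seq[8] == "T"
        assert pairs[0].ref_seq == "A" * 13

    def test_edge_site_skipped(self):
        seq = {"chr1": "A" * 30}
        G = self._G([4], ["A"], ["C"])
        assert flank_sequences(G, [0], seq) == []

    def test_reference_mismatch_named(self):
        seq = {"chr1": "A" * 30}
        G = self._G([10], ["G"], ["C"])
        with pytest.raises(ValueError, match="chr1:10"):
            flank_sequences(G, [0], seq)


# ---------------------------------------------------------------------------
# B-SIFT

class TestBsift:
    def _table(self):
        rows = {
            ("chr1", 1, "A"): (0.3, False), ("chr1", 1, "C"): (0.8, False),
            ("chr1", 2, "A"): (0.5, False), ("chr1", 2, "C"): (0.5, False),
            ("chr1", 3, "A"): (1.0, False), ("chr1", 3, "C"): (0.0, False),
            ("chr1", 4, "A"): (0.2, True), ("chr1", 4, "C"): (0.9, True),
            ("chr1", 5, "A"): (0.1, False),
        }
        return SiftTable(rows)

    def test_adaptive(self):
        r = bsift_score("chr1", 1, "A", "C", self._table())
        assert r.bsift == pytest.approx(0.5) and r.effect_class == "adaptive"

    def test_neutral(self):
        r = bsift_score("chr1", 2, "A", "C", self._table())
        assert r.bsift == 0 and r.effect_class == "neutral"

    def test_deleterious_extreme(self):
        r = bsift_score("chr1", 3, "A", "C", self._table())
        assert r.bsift == pytest.approx(-1.0)
        assert r.effect_class == "deleterious"

    def test_low_confidence_not_classified(self):
        r = bsift_score("chr1", 4, "A", "C", self._table())
        assert r.low_confidence and r.effect_class == "low_confidence"

    def test_missing_score(self):
        r = bsift_score("chr1", 5, "A", "C", self._table())
        assert r.effect_class == "no_score" and np.isnan(r.bsift)

    def test_toy_table_class_counts(self):
        """Hand counts on a 10-row toy table: 3 adaptive, 3 deleterious,
        2 neutral, 1 low-confidence, 1 missing."""
        scores = [(0.1, 0.9), (0.2, 0.5), (0.0, 0.1),     # adaptive
                  (0.9, 0.1), (0.5, 0.2), (1.0, 0.0),     # deleterious
                  (0.4, 0.4), (0.0, 0.0)]                 # neutral
        rows = {}
        for i, (r, a) in enumerate(scores, start=1):
            rows[("chr1", i, "A")] = (r, False)
            rows[("chr1", i, "C")] = (a, False)
        rows[("chr1", 9, "A")] = (0.3, True)
        rows[("chr1", 9, "C")] = (0.6, True)
        rows[("chr1", 10, "A")] = (0.3, False)             # alt score absent
        table = SiftTable(rows)
        recs = [bsift_score("chr1", i, "A", "C", table) for i in range(1, 11)]
        counts = {}
        for r in recs:
            counts[r.effect_class] = counts.get(r.effect_class, 0) + 1
        assert counts == {"adaptive": 3, "deleterious": 3, "neutral": 2,
                          "low_confidence": 1, "no_score": 1}


# ---------------------------------------------------------------------------
# motif scan

def one_hot_pwm(seq, motif_id="hot"):
    m = np.full((4, len(seq)), 0.0)
    for j, b in enumerate(seq):
        m["ACGT".index(b), j] = 1.0
    return Pwm(motif_id, m)


class TestMotifScan:
    def test_one_hot_exact_match_unique_to_alt(self):
        pair = annotate.FlankPair("chr1", 100, "G",
                                  ref_seq="ACGTACATACGTA",
                                  alt_seq="ACGTACGTACGTA")
        lib = MotifLibrary([one_hot_pwm(pair.alt_seq)])
        ms = motif_uniqueness(pair, lib, threshold_frac=1.0)
        assert ms.unique_to_alt == {"hot"}

    def test_motif_on_untouched_segment_in_both(self):
        pair = annotate.FlankPair("chr1", 100, "G",
                                  ref_seq="ACGTACATACGTA",
                                  alt_seq="ACGTACGTACGTA")
        lib = MotifLibrary([one_hot_pwm("ACGTA", "left")])
        ms = motif_uniqueness(pair, lib, threshold_frac=1.0)
        assert "left" in ms.motifs_ref and "left" in ms.motifs_alt
        assert ms.unique_to_alt == frozenset()

    def test_reverse_complement_invariance(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        lib = MotifLibrary([
            Pwm(f"m{k}", rng.dirichlet([1] * 4, size=8).T) for k in range(5)])
        seq = "".join(rng.choice(list("ACGT"), 13))
        rc = "".join(comp[b] for b in reversed(seq))
        assert motif_matches(seq, lib, 0.7) == motif_matches(rc, lib, 0.7)

    def test_matches_exhaustive_oracle(self, rng):
        """Best scores agree with a brute-force offset/strand scan for
        random 8-wide PWMs on random 13-mers."""
        for _ in range(10):
            pwm = Pwm("m", rng.dirichlet([0.8] * 4, size=8).T)
            seq = "".join(rng.choice(list("ACGT"), 13))
            got = annotate.best_pwm_score(seq, pwm)
            want = oracles.pwm_best_score_oracle(seq, pwm.matrix)
            assert got == pytest.approx(want, abs=1e-9)

    def test_wide_motif_skipped(self):
        lib = MotifLibrary([Pwm("wide", np.full((4, 20), 0.25))])
        assert motif_matches("A" * 13, lib, 0.5) == frozenset()
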