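import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lncsift import features as F
from lncsift.seqio import DataError, Transcript

from oracles import fickett_oracle, orf_oracle, peptide_charge_grid_pi

seq_strategy = st.text(alphabet="ACGT", min_size=3, max_size=120)


def T(seq):
    return Transcript(id="t", seq=seq)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 0.5), ("GGGG", 1.0), ("ANNT", 0.0), ("AANNCC", 0.5)]
    )
    def test_examples(self, seq, expected):
        assert F.gc_content(T(seq)) == pytest.approx(expected)

    def test_all_n_is_zero(self):
        assert F.gc_content(T("NNNN")) == 0.0


class TestStopCodonSd:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("TAATAATAA", math.sqrt(6 / 3)),
            ("AAAAAA", 0.0),
            ("TAGTAGTAGTAG", math.sqrt(32 / 9)),
        ],
    )
    def test_examples(self, seq, expected):
        assert F.stop_codon_sd(T(seq)) == pytest.approx(expected, abs=1e-12)

    def test_short_sequence_is_zero(self):
        assert F.stop_codon_sd(T("AT")) == 0.0

    @given(seq_strategy)
    def test_nonnegative_and_zero_iff_equal_counts(self, seq):
        sd = F.stop_codon_sd(T(seq))
        counts = F.stop_codon_counts(T(seq))
        assert sd >= 0
        assert (sd == 0) == (len(set(counts)) == 1)


class TestFindLongestOrf:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGAAATAG", (0, 9, 0, True, True)),
            ("ATGAAA", (0, 6, 0, True, False)),
            ("CCCCCC", (0, 6, 0, False, False)),
        ],
    )
    def test_examples(self, seq, expected):
        o = F.find_longest_orf(T(seq))
        assert (o.start, o.end, o.frame, o.has_start, o.has_stop) == expected

    def test_matches_bruteforce_on_random_short_sequences(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGTN"))
        for _ in range(300):
            L = int(rng.integers(3, 61))
            seq = "".join(bases[rng.integers(0, 5, size=L)])
            o = F.find_longest_orf(T(seq))
            assert (o.start, o.end, o.frame, o.has_start, o.has_stop) == orf_oracle(seq)

    def test_n_codon_never_matches_start_or_stop(self):
        o = F.find_longest_orf(T("ANGAAATNA"))
        assert not o.has_start and not o.has_stop


class TestCdsFeatures:
    def test_complete_orf(self):
        t = T("ATGAAATAG")
        out = F.cds_features(F.find_longest_orf(t), t)
        assert out == (1.0, 9, 109.0, 1.0)

    def test_degenerate(self):
        t = T("CCCCCC")
        assert F.cds_features(F.find_longest_orf(t), t) == (0.0, 6, 6.0, 1.0)

    def test_kozak_bonus(self):
        # A at -3 and G at +4 around the ATG
        t = T("AAAATGGCCTAA")
        orf = F.find_longest_orf(t)
        _, _, score, _ = F.cds_features(orf, t)
        assert score == orf.length_nt + 100 + 25

    def test_score_monotone_in_orf_length(self):
        t_long = T("ATGAAAAAAAAATAGCCC")
        t_short = T("ATGAAATAGCCCCCCCCC")
        s_long = F.cds_features(F.find_longest_orf(t_long), t_long)[2]
        s_short = F.cds_features(F.find_longest_orf(t_short), t_short)[2]
        assert s_long > s_short

    @given(seq_strategy)
    def test_percent_bounds(self, seq):
        t = T(seq)
        _, cds_len, _, pct = F.cds_features(F.find_longest_orf(t), t)
        assert 0 <= pct <= 1
        assert cds_len <= len(seq)


class TestPeptideFeatures:
    def test_translation(self):
        t = T("ATGAAATAG")
        pep_len, _ = F.peptide_features(F.find_longest_orf(t), t)
        assert pep_len == 2  # MK, stop excluded

    def test_charge_ordering(self):
        pi_k = F.isoelectric_point("K" * 10)
        pi_d = F.isoelectric_point("D" * 10)
        assert pi_k > pi_d

    @pytest.mark.parametrize("pep", ["MK", "MDEK", "ACDEFGHIKLMNPQRSTVWY"])
    def test_pi_matches_grid_oracle(self, pep):
        assert F.isoelectric_point(pep) == pytest.approx(
            peptide_charge_grid_pi(pep), abs=2e-3
        )

    def test_empty_peptide_convention(self):
        assert F.isoelectric_point("") == 7.0


class TestFickett:
    def test_position_parameter_balanced_counts(self):
        pos, _ = F.fickett_parts(T("AAAAAA"))
        assert pos["A"] == pytest.approx(2 / 3)

    def test_too_short_errors(self):
        with pytest.raises(DataError, match="Fickett"):
            F.fickett_score(T("AT"))

    def test_score_unchanged_by_appending_n(self):
        seq = "ATGACGTACGATCGTACG"
        assert F.fickett_score(T(seq)) == F.fickett_score(T(seq + "NNN"))

    def test_matches_independent_table_lookup(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            seq = "".join(bases[rng.integers(0, 4, size=int(rng.integers(3, 400)))])
            assert F.fickett_score(T(seq)) == pytest.approx(fickett_oracle(seq), abs=1e-12)

    def test_score_within_table_range(self):
        # max possible: all 8 probabilities at their table maximum
        hi = sum(
            max(F._fickett.POSITION_PROB[b]) * F._fickett.POSITION_WEIGHT[b]
            + max(F._fickett.CONTENT_PROB[b]) * F._fickett.CONTENT_WEIGHT[b]
            for b in "ACGT"
        )
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(500):
            seq = "".join(bases[rng.integers(0, 4, size=300)])
            assert 0 < F.fickett_score(T(seq)) <= hi


class TestTrinucFrequencies:
    def test_homopolymer(self):
        f = F.trinuc_frequencies(T("AAAA"))
        assert f[F.TRINUCLEOTIDES.index("AAA")] == 1.0
        assert f.sum() == 1.0

    def test_two_windows(self):
        f = F.trinuc_frequencies(T("ACGT"))
        assert f[F.TRINUCLEOTIDES.index("ACG")] == 0.5
        assert f[F.TRINUCLEOTIDES.index("CGT")] == 0.5

    def test_n_windows_skipped(self):
        f = F.trinuc_frequencies(T("AAANAAA"))
        assert f[F.TRINUCLEOTIDES.index("AAA")] == 1.0

    @given(seq_strategy)
    def test_sums_to_one(self, seq):
        assert F.trinuc_frequencies(T(seq)).sum() == pytest.approx(1.0, abs=1e-12)


class TestExtractFeatures:
    def test_animal_preset_columns(self):
        ts = [Transcript("a", "ATGACGTACGATCGTACGATTAG" * 10)]
        m = F.extract_features(ts, feature_list=F.SCALAR_FEATURES[:3] + F.ANIMAL_TRINUCS)
        assert m.names == F.SCALAR_FEATURES[:3] + F.ANIMAL_TRINUCS

    def test_unknown_feature_errors(self):
        with pytest.raises(DataError, match="XYZ"):
            F.extract_features([Transcript("a", "ACGTACGT")], feature_list=["XYZ"])

    def test_hexamer_requires_table(self):
        with pytest.raises(DataError, match="[Hh]examer"):
            F.extract_features([Transcript("a", "ACGTACGT")], feature_list=["Hexamer"])

    def test_labels_carried(self):
        ts = [Transcript("a", "ACGTACGTACGT", label="lncRNA")]
        m = F.extract_features(ts, feature_list=["Length", "GC_content"])
        assert list(m.labels) == ["lncRNA"]
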