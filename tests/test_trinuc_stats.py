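import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from lncsift import trinuc_stats as TS
from lncsift.features import TRINUCLEOTIDES
from lncsift.seqio import DataError

from oracles import bh_oracle


def freq_frame(rows: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=TRINUCLEOTIDES)


def column_with_moments(mean: float, sd: float, n: int, rng) -> np.ndarray:
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestTrinucZtest:
    def test_identical_groups_give_zero_z(self):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.ones(64), size=10)
        out = TS.trinuc_ztest(freq_frame(rows), freq_frame(rows.copy()))
        assert np.allclose(out["z"], 0.0)
        assert np.allclose(out["p"], 1.0)

    def test_engineered_moments_match_closed_form(self):
        # means 0.5 vs 0.3, both sds 0.1, n=25 each -> Z = 0.2/sqrt(0.0008)
        rng = np.random.default_rng(1)
        pos = np.tile(column_with_moments(0.5, 0.1, 25, rng)[:, None], (1, 64))
        neg = np.tile(column_with_moments(0.3, 0.1, 25, rng)[:, None], (1, 64))
        out = TS.trinuc_ztest(freq_frame(pos), freq_frame(neg))
        assert out["z"].to_numpy() == pytest.approx(np.full(64, 7.0710678), abs=1e-6)

    def test_small_sample_matches_hand_arithmetic(self):
        import statistics

        rng = np.random.default_rng(2)
        pos = rng.dirichlet(np.ones(64), size=5)
        neg = rng.dirichlet(np.ones(64), size=5)
        out = TS.trinuc_ztest(freq_frame(pos), freq_frame(neg))
        j = 17
        x1, x2 = pos[:, j].tolist(), neg[:, j].tolist()
        z_hand = (statistics.mean(x1) - statistics.mean(x2)) / (
            (statistics.stdev(x1) ** 2 / 5 + statistics.stdev(x2) ** 2 / 5) ** 0.5
        )
        assert out["z"][j] == pytest.approx(z_hand, abs=1e-12)

    def test_degenerate_zero_variance(self):
        pos = np.full((3, 64), 0.5 / 64)
        neg = np.full((3, 64), 0.3 / 64)
        out = TS.trinuc_ztest(freq_frame(pos), freq_frame(neg))
        assert out["degenerate"].all()
        assert (out["p"] == 0.0).all()

    def test_small_groups_rejected(self):
        pos = np.full((1, 64), 1 / 64)
        with pytest.raises(DataError):
            TS.trinuc_ztest(freq_frame(pos), freq_frame(np.full((5, 64), 1 / 64)))


class TestPFromZ:
    @pytest.mark.parametrize("z,expected", [(0.0, 1.0), (1.959964, 0.05)])
    def test_reference_points(self, z, expected):
        assert TS.p_from_z(z) == pytest.approx(expected, abs=1e-6)

    @given(st.floats(-8, 8))
    def test_symmetry(self, z):
        assert TS.p_from_z(z) == TS.p_from_z(-z)


class TestFdrAdjust:
    def test_equal_after_adjustment(self):
        assert TS.fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_value(self):
        assert TS.fdr_adjust([0.04]) == pytest.approx([0.04])

    def test_stepup_example(self):
        assert TS.fdr_adjust([0.005, 0.009, 0.05]) == pytest.approx([0.0135, 0.0135, 0.05])

    def test_matches_bruteforce_and_statsmodels(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            ours = TS.fdr_adjust(p)
            assert ours == pytest.approx(bh_oracle(list(p)), abs=1e-12)
            _, sm, _, _ = multipletests(p, method="fdr_bh")
            assert ours == pytest.approx(sm, abs=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        assert TS.fdr_adjust(p)[perm] == pytest.approx(TS.fdr_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            TS.fdr_adjust([0.5, 1.2])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=30)
        assert (TS.fdr_adjust(p) >= p - 1e-15).all()


class TestSelectTrinucs:
    def _stats(self, z_values, p_adj):
        return pd.DataFrame(
            {"trinuc": TRINUCLEOTIDES, "z": z_values, "p_adj": p_adj}
        )

    def test_nothing_significant(self):
        stats = self._stats(np.ones(64), np.full(64, 0.5))
        selected, report = TS.select_trinucs([stats], alpha=0.01)
        assert selected == []
        assert not report["selected"].any()

    def test_single_significant(self):
        p = np.full(64, 0.5)
        p[10] = 0.001
        selected, _ = TS.select_trinucs([self._stats(np.ones(64), p)], alpha=0.01)
        assert selected == [TRINUCLEOTIDES[10]]

    def test_three_species_ordering_matches_explicit_sort(self):
        rng = np.random.default_rng(6)
        stats = []
        for _ in range(3):
            z = rng.normal(scale=5, size=64)
            p = np.where(np.abs(z) > 1.5, 0.001, 0.5)
            stats.append(self._stats(z, p))
        selected, report = TS.select_trinucs(stats, alpha=0.01)
        sig = np.ones(64, dtype=bool)
        total = np.zeros(64)
        for df in stats:
            sig &= df["p_adj"].to_numpy() < 0.01
            total += np.abs(df["z"].to_numpy())
        expected = sorted(
            (TRINUCLEOTIDES[i] for i in np.flatnonzero(sig)),
            key=lambda t: (-total[TRINUCLEOTIDES.index(t)], t),
        )
        assert selected == expected

    def test_top_k_truncation(self):
        p = np.full(64, 0.001)
        selected, _ = TS.select_trinucs(
            [self._stats(np.arange(64, dtype=float), p)], alpha=0.01, top_k=5
        )
        assert len(selected) == 5
        assert selected[0] == TRINUCLEOTIDES[63]

    def test_empty_input_errors(self):
        with pytest.raises(DataError):
            TS.select_trinucs([])
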