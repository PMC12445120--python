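"""Rank statistics: oracles, identities, and the stratified comparison."""

import warnings
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from ecomenu.stats import (
    assign_letters,
    compare_sources,
    kruskal_wallis,
    mann_whitney_u,
    spearman_rho,
)


def brute_force_u(a, b):
    """Independent oracle: count wins with half credit for ties."""
    return sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
    )


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)  # only the two extreme assignments

    def test_identical_samples_give_half_max(self):
        u, _ = mann_whitney_u([5, 7, 9], [5, 7, 9])
        assert u == 9 / 2

    def test_u_matches_brute_force_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_a = int(rng.integers(1, 8))
            n_b = int(rng.integers(1, 8))
            a = rng.integers(0, 6, n_a).astype(float)
            b = rng.integers(0, 6, n_b).astype(float)
            u, _ = mann_whitney_u(a, b)
            assert u == pytest.approx(brute_force_u(a, b))

    def test_u_symmetry_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.normal(size=int(rng.integers(2, 15)))
            b = rng.normal(size=int(rng.integers(2, 15)))
            u_ab, _ = mann_whitney_u(a, b)
            u_ba, _ = mann_whitney_u(b, a)
            assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_large_sample_p_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.8, 1, 20)
        u, p = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=10)
        b = rng.normal(size=12)
        u1, p1 = mann_whitney_u(a, b)
        u2, p2 = mann_whitney_u(np.exp(a), np.exp(b))
        assert (u1, p1) == (u2, p2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0)

    def test_all_observations_tied_degenerate(self):
        h, p = kruskal_wallis([[4, 4], [4, 4, 4]])
        assert (h, p) == (0.0, 1.0)

    def test_three_constant_groups_hand_ranked(self):
        # groups {1}x5, {2}x5, {3}x5: rank means 3, 8, 13; H = 12.5
        h, _ = kruskal_wallis([[1] * 5, [2] * 5, [3] * 5])
        n, rank_means, grand = 15, [3.0, 8.0, 13.0], 8.0
        expected = 12.0 / (n * (n + 1)) * sum(5 * (r - grand) ** 2 for r in rank_means)
        tie = 1 - (3 * (5**3 - 5)) / (15**3 - 15)
        assert h == pytest.approx(expected / tie)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            groups = [
                rng.integers(0, 8, int(rng.integers(3, 12))).astype(float)
                for _ in range(3)
            ]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            h, p = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert h == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_group_rejection_consistent_with_mwu(self):
        """On two groups, KW and MWU agree on rejection at alpha=0.05."""
        rng = np.random.default_rng(5)
        agree = 0
        n = 200
        for _ in range(n):
            shift = rng.uniform(0, 1.5)
            a = rng.normal(0, 1, 18)
            b = rng.normal(shift, 1, 18)
            kw_reject = kruskal_wallis([a, b]).pvalue < 0.05
            mwu_reject = mann_whitney_u(a, b).pvalue < 0.05
            agree += kw_reject == mwu_reject
        assert agree >= 0.97 * n  # chi2(H) vs normal(U): same test up to approximation


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_rho(x, x).statistic == pytest.approx(1.0)
        assert spearman_rho(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_tie_heavy_matches_rank_then_pearson(self):
        x = [1, 1, 2, 2, 3, 3, 4]
        y = [2, 2, 2, 5, 5, 7, 7]
        rho, p = spearman_rho(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_flagged_not_raised(self):
        with pytest.warns(UserWarning, match="constant"):
            res = spearman_rho([1, 1, 1], [1, 2, 3])
        assert np.isnan(res.statistic)


class TestLetters:
    def test_no_significant_pairs_share_one_letter(self):
        letters = assign_letters(["A", "B", "C"], set())
        assert letters == {"A": "a", "B": "a", "C": "a"}

    def test_one_source_split_off(self):
        letters = assign_letters(["A", "B", "C"], {("A", "C"), ("B", "C")})
        assert letters["A"] == letters["B"]
        assert set(letters["C"]) & set(letters["A"]) == set()

    def test_chain_without_transitivity_shares_middle(self):
        # A!=C significant, but A~B and B~C: B shares a letter with both
        letters = assign_letters(["A", "B", "C"], {("A", "C")})
        assert set(letters["A"]) & set(letters["B"])
        assert set(letters["B"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["C"])


class TestCompareSources:
    def _long(self, rng, shift_c=0.0, n=30):
        import pandas as pd

        rows = []
        for source, shift in (("DPM", 0.0), ("NMPG", 0.0), ("IAM", shift_c)):
            for day, v in enumerate(rng.normal(shift, 1, n)):
                rows.append(
                    dict(
                        source=source, target_group="prison", meal_type="I",
                        metric="carbon_kgco2e", day=day + 1, value=v,
                    )
                )
        return pd.DataFrame(rows)

    def test_shifted_source_gets_distinct_letter(self):
        rng = np.random.default_rng(6)
        table = compare_sources(self._long(rng, shift_c=3.0)).table
        row = table.iloc[0]
        assert row["kw_p"] < 0.05
        assert row["letter_IAM"]
        assert not set(row["letter_IAM"]) & set(row["letter_DPM"] + row["letter_NMPG"])

    def test_null_data_usually_unlettered(self):
        rng = np.random.default_rng(7)
        unlettered = 0
        for _ in range(40):
            table = compare_sources(self._long(rng)).table
            row = table.iloc[0]
            unlettered += row["kw_p"] >= 0.05
        assert unlettered >= 30  # ~95% expected

    def test_letters_only_when_kw_significant(self):
        rng = np.random.default_rng(8)
        table = compare_sources(self._long(rng)).table
        row = table.iloc[0]
        if row["kw_p"] >= 0.05:
            assert row["letter_DPM"] == row["letter_NMPG"] == row["letter_IAM"] == ""

    def test_single_source_warns_and_empties(self):
        import pandas as pd

        df = pd.DataFrame(
            dict(source=["DPM"] * 3, target_group="prison", meal_type="I",
                 metric="m", day=[1, 2, 3], value=[1.0, 2.0, 3.0])
        )
        with pytest.warns(UserWarning):
            result = compare_sources(df)
        assert len(result.table) == 0


def test_exact_mwu_p_matches_full_enumeration():
    """Exact branch equals an independently coded permutation enumeration."""
    rng = np.random.default_rng(9)
    for _ in range(20):
        n_a = int(rng.integers(2, 6))
        n_b = int(rng.integers(2, 6))
        a = rng.integers(0, 4, n_a).astype(float)
        b = rng.integers(0, 4, n_b).astype(float)
        u_obs, p = mann_whitney_u(a, b)
        pooled = np.concatenate([a, b])
        mu = n_a * n_b / 2
        hits = total = 0
        for idx in combinations(range(n_a + n_b), n_a):
            mask = np.zeros(n_a + n_b, bool)
            mask[list(idx)] = True
            u_perm = brute_force_u(pooled[mask], pooled[~mask])
            hits += abs(u_perm - mu) >= abs(u_obs - mu) - 1e-9
            total += 1
        assert p == pytest.approx(hits / total)
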