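from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from rscukit.stats import (
    bonferroni,
    cohens_d,
    compare_groups,
    effect_bin,
    mann_whitney_exact,
)


def oracle_u(x, y):
    """Pair-counting U: #{x_i > y_j} + 0.5 #{x_i = y_j}."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def oracle_p(x, y):
    """Two-sided exact p by full enumeration of all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = oracle_u(x, y)
    extreme = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(oracle_u(xs, ys) - mu) >= abs(u_obs - mu) - 1e-9:
            extreme += 1
        total += 1
    return extreme / total


class TestMannWhitney:
    def test_fully_separated_groups(self):
        u, p, _ = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / comb(6, 3))  # = 0.1

    def test_all_tied_values(self):
        u, p, _ = mann_whitney_exact([1, 1, 1], [1, 1, 1])
        assert u == pytest.approx(4.5)
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])

    def test_u_range_and_symmetry(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=5)
        ux, px, _ = mann_whitney_exact(x, y)
        uy, py, _ = mann_whitney_exact(y, x)
        assert 0 <= ux <= 30 and ux + uy == pytest.approx(30)
        assert px == pytest.approx(py)

    def test_matches_enumeration_oracle_with_ties(self, rng):
        """U and p agree with full enumeration for n1, n2 <= 7, ties included."""
        for trial in range(20):
            n1, n2 = rng.integers(1, 8), rng.integers(1, 8)
            # draw from few distinct values so ties are common
            x = rng.choice([0.0, 1.0, 2.0, 3.5], size=n1)
            y = rng.choice([0.0, 1.0, 2.0, 3.5], size=n2)
            u, p, _ = mann_whitney_exact(x, y)
            assert u == pytest.approx(oracle_u(x, y))
            assert p == pytest.approx(oracle_p(x, y), abs=1e-12)

    def test_large_no_ties_uses_shift_distribution(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        _, p, method = mann_whitney_exact(x, y)
        assert method == "shift" and 0 < p <= 1

    def test_monte_carlo_for_large_tied_samples(self, rng):
        x = rng.choice([0.0, 1.0, 2.0], size=15)
        y = rng.choice([0.0, 1.0, 2.0], size=16) + 0.5
        _, p, method = mann_whitney_exact(x, y, seed=3)
        assert method == "monte_carlo" and 0 < p <= 1


class TestBonferroni:
    def test_closed_form(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.04]), [0.02, 0.08])
        np.testing.assert_allclose(bonferroni([0.9, 0.3]), [1.0, 0.6])
        assert bonferroni([0.001], 59)[0] == pytest.approx(0.059)

    def test_order_preserving_and_dominating(self, rng):
        p = np.sort(rng.random(30))
        adj = bonferroni(p, 40)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(adj >= p)

    def test_undersized_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        _, adj, _, _ = multipletests(p, method="bonferroni")
        np.testing.assert_allclose(bonferroni(p), adj)


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_unit_effect(self, rng):
        x = rng.normal(2.0, 1.0, 20000)
        y = rng.normal(1.0, 1.0, 20000)
        assert cohens_d(x, y) == pytest.approx(1.0, abs=0.05)

    def test_antisymmetric(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=12)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_shift_and_scale_invariance(self, rng):
        x, y = rng.normal(size=10), rng.normal(1.0, 2.0, 12)
        d = cohens_d(x, y)
        assert cohens_d(x + 5, y + 5) == pytest.approx(d)
        assert cohens_d(3 * x, 3 * y) == pytest.approx(d)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    def test_pooled_variant_differs_when_unbalanced(self, rng):
        x, y = rng.normal(0, 1, 5), rng.normal(1, 3, 40)
        assert cohens_d(x, y) != pytest.approx(cohens_d(x, y, pooled=True))


class TestEffectBins:
    @pytest.mark.parametrize(
        "d,label",
        [
            (0.05, "very small"),
            (0.21, "small"),
            (0.38, "medium"),
            (0.70, "large"),
            (-0.70, "large"),
            (1.0, "large"),
            (9.01, "very large"),
            (48.88, "very large"),
        ],
    )
    def test_binning(self, d, label):
        assert effect_bin(d) == label

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            effect_bin(float("nan"))


def _rscu_frames(rng, n=8, shift=0.0, codons=("AAC", "AAT", "GCC", "GCT")):
    a = pd.DataFrame(
        rng.normal(1.0, 0.1, (n, len(codons))),
        columns=list(codons),
        index=[f"a{i}" for i in range(n)],
    )
    b = pd.DataFrame(
        rng.normal(1.0, 0.1, (n, len(codons))),
        columns=list(codons),
        index=[f"b{i}" for i in range(n)],
    )
    b["AAC"] += shift
    return a, b


class TestCompareGroups:
    def test_identical_groups_nothing_significant(self, rng):
        a, _ = _rscu_frames(rng)
        summary = compare_groups(a, a.copy())
        assert summary.fraction_significant == 0.0
        assert all(r.p_raw == 1.0 for r in summary.results)

    def test_planted_shift_detected(self, rng):
        a, b = _rscu_frames(rng, n=15, shift=1.0)
        summary = compare_groups(a, b)
        sig = {r.codon for r in summary.results if r.significant}
        assert sig == {"AAC"}

    def test_bookkeeping_identity(self, rng):
        a, b = _rscu_frames(rng, n=10, shift=0.5)
        summary = compare_groups(a, b)
        frame = summary.to_frame()
        pooled = frame[frame["stratum"] == "all"]
        assert summary.fraction_significant == pytest.approx(
            pooled["significant"].sum() / len(pooled)
        )
        assert summary.n_comparisons == len(frame)

    def test_undefined_codons_skipped(self, rng):
        a, b = _rscu_frames(rng, n=6)
        a.loc[:, "GCC"] = np.nan
        summary = compare_groups(a, b)
        assert ("GCC", "all") in summary.skipped
        assert "GCC" not in {r.codon for r in summary.results}

    def test_strata_and_contributions(self, rng):
        a, b = _rscu_frames(rng, n=16, shift=1.5)
        strata = pd.Series(
            {i: ("early" if int(i[1:]) < 8 else "late") for i in list(a.index) + list(b.index)}
        )
        summary = compare_groups(a, b, strata=strata)
        strata_seen = {r.stratum for r in summary.results}
        assert strata_seen == {"all", "early", "late"}
        contrib = summary.stratum_contributions()
        assert "all" not in contrib
        assert sum(contrib.values()) == pytest.approx(1.0)

    def test_insufficient_samples_rejected(self, rng):
        a, b = _rscu_frames(rng, n=1)
        with pytest.raises(ValueError):
            compare_groups(a, b)
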