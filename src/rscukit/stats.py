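"""Codon-wise two-group statistics: exact Mann-Whitney U, Bonferroni
adjustment, unequal-variance Cohen's d, and effect-size binning.

The U statistic counts pairs where an x-value exceeds a y-value (ties count
one half).  The exact two-sided p-value is the null probability, over all
C(n1+n2, n1) equally likely group assignments of the pooled data, of a U at
least as far from its mean n1*n2/2 as observed.  Small problems are fully
enumerated; without ties larger problems use the exact shift-algorithm
distribution; with ties they fall back to a seeded Monte-Carlo permutation
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

ENUMERATION_LIMIT = 2_000_000
MC_PERMUTATIONS = 100_000

#: Contiguous |d| bins honoring every printed boundary of the study's scheme.
EFFECT_BINS = (
    (0.20, "very small"),
    (0.36, "small"),
    (0.66, "medium"),
    (1.0 + 1e-12, "large"),  # 1.0 itself still counts as large
    (np.inf, "very large"),
)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{x_i > y_j} + 0.5 * #{x_i = y_j}, via pooled mid-ranks."""
    n1 = len(x)
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_exact(
    x, y, seed: int = 0
) -> tuple[float, float, str]:
    """Exact two-sided Mann-Whitney U test.

    Returns ``(U, p, method)`` where method records how the null
    distribution was obtained: ``enumeration``, ``shift`` (exact, no ties)
    or ``monte_carlo`` (ties, C(n1+n2,n1) too large to enumerate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    if abs(u_obs - mu) <= 1e-9:
        # every assignment is at least this extreme: p = P(|U - mu| >= 0) = 1
        return u_obs, 1.0, "degenerate"
    has_ties = len(np.unique(pooled)) < len(pooled)

    n_assign = comb(n1 + n2, n1)
    if n_assign <= ENUMERATION_LIMIT:
        ranks = sps.rankdata(pooled)
        const = n1 * (n1 + 1) / 2.0
        extreme = 0
        target = abs(u_obs - mu) - 1e-9
        chunk: list[tuple] = []
        for idx in combinations(range(n1 + n2), n1):
            chunk.append(idx)
            if len(chunk) == 50_000:
                u_all = ranks[np.array(chunk)].sum(axis=1) - const
                extreme += int(np.count_nonzero(np.abs(u_all - mu) >= target))
                chunk = []
        if chunk:
            u_all = ranks[np.array(chunk)].sum(axis=1) - const
            extreme += int(np.count_nonzero(np.abs(u_all - mu) >= target))
        return u_obs, extreme / n_assign, "enumeration"

    if not has_ties:
        # Null U distribution is symmetric about mu, so the distance-based
        # two-sided p equals the standard doubled one-sided exact p.
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return u_obs, float(res.pvalue), "shift"

    rng = np.random.default_rng(seed)
    count = 0
    target = abs(u_obs - mu) - 1e-9
    ranks = sps.rankdata(pooled)
    const = n1 * (n1 + 1) / 2.0
    for start in range(0, MC_PERMUTATIONS, 10_000):
        m = min(10_000, MC_PERMUTATIONS - start)
        perm = np.argsort(rng.random((m, n1 + n2)), axis=1)[:, :n1]
        u_all = ranks[perm].sum(axis=1) - const
        count += int(np.count_nonzero(np.abs(u_all - mu) >= target))
    # add-one correction keeps the Monte-Carlo p strictly positive
    return u_obs, (count + 1) / (MC_PERMUTATIONS + 1), "monte_carlo"


def bonferroni(p_values, n_comparisons: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, N * p).

    N defaults to the number of p-values; a larger N (a wider comparison
    family) may be supplied, a smaller one is an error.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p) if n_comparisons is None else int(n_comparisons)
    if n < len(p):
        raise ValueError(f"N={n} smaller than the {len(p)} tests performed")
    return np.minimum(1.0, n * p)


def cohens_d(x, y, pooled: bool = False) -> float:
    """Standardized mean difference between two groups.

    Default denominator is the quadratic mean of the two group SDs,
    sqrt((s1^2 + s2^2)/2) with (n-1) variances — the standard
    unequal-variance form; ``pooled=True`` uses the n-weighted pooled SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("Cohen's d requires at least 2 values per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if pooled:
        denom = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    else:
        denom = np.sqrt((v1 + v2) / 2.0)
    if denom == 0:
        raise ValueError("zero variance in both groups; effect size undefined")
    return float((x.mean() - y.mean()) / denom)


def effect_bin(d: float) -> str:
    """Bin |d| as very small / small / medium / large / very large."""
    if not np.isfinite(d):
        raise ValueError(f"effect size must be finite, got {d}")
    a = abs(d)
    for upper, label in EFFECT_BINS:
        if a < upper:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class CodonTestResult:
    """One codon's two-group comparison within one stratum."""

    codon: str
    stratum: str
    n1: int
    n2: int
    u: float
    p_raw: float
    p_adjusted: float
    d: float
    effect: str
    significant: bool
    method: str


@dataclass(frozen=True)
class ComparisonSummary:
    """All codon tests of one comparison plus bookkeeping fractions."""

    results: list[CodonTestResult]
    skipped: list[tuple[str, str]]
    alpha: float
    n_comparisons: int

    @property
    def n_tested(self) -> int:
        return len(self.results)

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.results)

    def _pooled(self) -> list[CodonTestResult]:
        pooled = [r for r in self.results if r.stratum == "all"]
        return pooled if pooled else self.results

    @property
    def fraction_significant(self) -> float:
        """Fraction of codons significant in the pooled (all-sample) tests."""
        pooled = self._pooled()
        return sum(r.significant for r in pooled) / len(pooled) if pooled else 0.0

    def stratum_contributions(self) -> dict[str, float]:
        """Share of significant per-stratum (codon, stage) results per stratum."""
        sig = [r for r in self.results if r.significant and r.stratum != "all"]
        if not sig:
            return {}
        counts = pd.Series([r.stratum for r in sig]).value_counts()
        return (counts / len(sig)).to_dict()

    def top_decile_effects(self) -> list[CodonTestResult]:
        """Results in the top 10 % of |d| (at least one)."""
        if not self.results:
            return []
        ordered = sorted(self.results, key=lambda r: -abs(r.d))
        k = max(1, int(np.ceil(0.10 * len(ordered))))
        return ordered[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "codon": r.codon,
                    "stratum": r.stratum,
                    "n1": r.n1,
                    "n2": r.n2,
                    "U": r.u,
                    "p_raw": r.p_raw,
                    "p_adj": r.p_adjusted,
                    "d": r.d,
                    "effect": r.effect,
                    "significant": r.significant,
                    "method": r.method,
                }
                for r in self.results
            ]
        )


def compare_groups(
    rscu_a: pd.DataFrame,
    rscu_b: pd.DataFrame,
    strata: pd.Series | None = None,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
    seed: int = 0,
) -> ComparisonSummary:
    """Codon-wise comparison of two RSCU sample groups.

    Parameters
    ----------
    rscu_a, rscu_b
        Samples x codons RSCU matrices for the two groups (e.g.
        healthy-weighted vs disease-weighted profiles).
    strata
        Optional stage label per sample (covering both groups); tests run
        per codon within each stratum.  Without strata a single pooled
        stratum ``"all"`` is used.
    n_comparisons
        Bonferroni family size; defaults to the number of tests actually
        run within this comparison.

    Codons with undefined RSCU (or fewer than two defined values) in either
    group of a stratum are skipped and reported.
    """
    groups_a: dict[str, pd.DataFrame] = {"all": rscu_a}
    groups_b: dict[str, pd.DataFrame] = {"all": rscu_b}
    if strata is not None:
        strata = pd.Series(strata)
        for s in sorted(strata.unique(), key=str):
            groups_a[str(s)] = rscu_a.loc[
                [i for i in rscu_a.index if str(strata.get(i)) == str(s)]
            ]
            groups_b[str(s)] = rscu_b.loc[
                [i for i in rscu_b.index if str(strata.get(i)) == str(s)]
            ]

    raw: list[dict] = []
    skipped: list[tuple[str, str]] = []
    tested_any = False
    for stratum in groups_a:
        sub_a, sub_b = groups_a[stratum], groups_b[stratum]
        if len(sub_a) < 2 or len(sub_b) < 2:
            skipped.extend((c, stratum) for c in rscu_a.columns)
            continue
        tested_any = True
        for codon in rscu_a.columns:
            xa = sub_a[codon].dropna().to_numpy()
            xb = sub_b[codon].dropna().to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                skipped.append((codon, stratum))
                continue
            u, p, method = mann_whitney_exact(xa, xb, seed=seed)
            try:
                d = cohens_d(xa, xb)
            except ValueError:
                skipped.append((codon, stratum))
                continue
            raw.append(
                dict(codon=codon, stratum=stratum, n1=len(xa), n2=len(xb),
                     u=u, p=p, d=d, method=method)
            )
    if not tested_any:
        raise ValueError("no stratum has >= 2 samples in both groups")

    n_family = len(raw) if n_comparisons is None else n_comparisons
    p_adj = bonferroni([r["p"] for r in raw], n_family) if raw else np.array([])
    results = [
        CodonTestResult(
            codon=r["codon"],
            stratum=r["stratum"],
            n1=r["n1"],
            n2=r["n2"],
            u=r["u"],
            p_raw=r["p"],
            p_adjusted=float(pa),
            d=r["d"],
            effect=effect_bin(r["d"]),
            significant=bool(pa <= alpha),
            method=r["method"],
        )
        for r, pa in zip(raw, p_adj)
    ]
    return ComparisonSummary(
        results=results, skipped=skipped, alpha=alpha, n_comparisons=n_family
    )
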