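"""Relative synonymous codon usage (RSCU) and representation classes.

RSCU of codon *c* in a family of degeneracy *k* is its observed usage
divided by the family mean: ``rscu(c) = usage(c) * k / sum(family usage)``.
A value of 1 means no bias; values at or above 1.5 are called
overrepresented and at or below 0.5 underrepresented.  Families with zero
total usage yield *undefined* (NaN) rather than zero, so sparse data never
produce spurious "under" calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codons import AA_THREE, GeneticCode
from .weighting import WeightedUsageProfile

OVER, UNDER, NEUTRAL, UNDEFINED = "over", "under", "neutral", "undefined"

DEFAULT_HI = 1.5
DEFAULT_LO = 0.5


@dataclass(frozen=True)
class RSCUProfile:
    """Per-sample RSCU over the 61 sense codons plus representation classes."""

    sample_id: str
    rscu: pd.Series
    classes: pd.Series


def rscu_values(usage: pd.Series, code: GeneticCode) -> pd.Series:
    """RSCU per sense codon from a (64- or 61-codon) usage vector.

    Stop codons are excluded.  Zero-total families give NaN.  The result is
    invariant to positive rescaling of ``usage``.
    """
    if (usage.dropna() < 0).any():
        raise ValueError("codon usage must be nonnegative")
    out = pd.Series(np.nan, index=list(code.sense_codons), dtype=float)
    for aa, family in code.families.items():
        vals = usage.reindex(list(family)).fillna(0.0)
        total = float(vals.sum())
        if total > 0:
            out[list(family)] = vals.to_numpy() * len(family) / total
    return out


def classify_representation(
    rscu: pd.Series, hi: float = DEFAULT_HI, lo: float = DEFAULT_LO
) -> pd.Series:
    """Classify codons as over (>= hi), under (<= lo), neutral, or undefined.

    Both thresholds are inclusive.
    """
    if not hi > lo > 0:
        raise ValueError(f"need hi > lo > 0, got hi={hi}, lo={lo}")
    classes = pd.Series(NEUTRAL, index=rscu.index, dtype=object)
    classes[rscu >= hi] = OVER
    classes[rscu <= lo] = UNDER
    classes[rscu.isna()] = UNDEFINED
    return classes


def rscu_profile(
    profile: WeightedUsageProfile,
    code: GeneticCode,
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
) -> RSCUProfile:
    """Compute an :class:`RSCUProfile` from a weighted usage profile."""
    vals = rscu_values(profile.usage, code)
    return RSCUProfile(
        sample_id=profile.sample_id,
        rscu=vals,
        classes=classify_representation(vals, hi=hi, lo=lo),
    )


def rscu_matrix(profiles: list[RSCUProfile]) -> pd.DataFrame:
    """Stack RSCU profiles into a samples x 61 matrix."""
    return pd.DataFrame(
        {p.sample_id: p.rscu for p in profiles}
    ).T.rename_axis("sample_id")


@dataclass(frozen=True)
class GroupSummary:
    """Per-codon mean and SD of RSCU across a sample group."""

    label: str
    n: int
    mean: pd.Series
    sd: pd.Series
    single_sample: bool


def summarize_group(profiles: list[RSCUProfile], label: str) -> GroupSummary:
    """Mean and (n-1)-denominator SD of RSCU per codon over a group.

    Undefined (NaN) values are excluded per codon.  With a single profile
    the SD is reported as 0 and flagged.
    """
    if not profiles:
        raise ValueError("summarize_group requires at least one profile")
    mat = rscu_matrix(profiles)
    n = len(profiles)
    sd = mat.std(ddof=1).fillna(0.0) if n > 1 else pd.Series(0.0, index=mat.columns)
    return GroupSummary(
        label=label, n=n, mean=mat.mean(), sd=sd, single_sample=(n == 1)
    )


def classify_external_usage(
    usage_table: pd.Series | dict,
    code: GeneticCode,
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
) -> pd.Series:
    """Classify an external (e.g. genomic) codon-usage table via RSCU.

    Accepts a 64- or 61-codon table of nonnegative values; uses the same
    RSCU and threshold code path as internal sample profiles.
    """
    usage = pd.Series(usage_table, dtype=float)
    missing = set(code.sense_codons) - set(usage.index)
    if missing:
        raise KeyError(f"usage table missing codons: {sorted(missing)[:5]}")
    return classify_representation(rscu_values(usage, code), hi=hi, lo=lo)


def class_table(classes: pd.Series, code: GeneticCode) -> pd.DataFrame:
    """Tidy over/under table keyed ``Aa-CODON`` (e.g. ``Ala-GCC``)."""
    rows = [
        {
            "codon": codon,
            "aa": AA_THREE[code.codon_to_aa[codon]],
            "name": f"{AA_THREE[code.codon_to_aa[codon]]}-{codon}",
            "class": cls,
        }
        for codon, cls in classes.items()
    ]
    return pd.DataFrame(rows)
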