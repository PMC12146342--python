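"""Dimensionality reduction of RSCU matrices and loading interpretation.

The 61 sense codons minus the two single-codon families (ATG/Met, TGG/Trp)
leave 59 informative features.  These are standardized and reduced by PCA
to the smallest number of components explaining 80 % of the variance,
capped at 5.  Interpretation follows two reporting rules: loadings beyond
|0.2| grouped by amino acid (an amino acid is highlighted only when at
least two of its synonymous codons pass), and samples with a component
score above 5 described by those codon sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .codons import AA_THREE, GeneticCode, standard_genetic_code

#: Codons removed before PCA: the three stops plus the single-codon families.
EXCLUDED_FEATURES: tuple[str, ...] = ("TGA", "TAG", "TAA", "ATG", "TGG")

N_FEATURES = 59


def select_codon_features(rscu: pd.DataFrame) -> pd.DataFrame:
    """Drop stop codons and single-codon families, leaving 59 feature columns.

    Accepts a 61- or 64-codon matrix; idempotent. Raises if any expected
    sense-codon column is missing.
    """
    code = standard_genetic_code()
    expected = [c for c in code.sense_codons if c not in EXCLUDED_FEATURES]
    missing = [c for c in expected if c not in rscu.columns]
    if missing:
        raise KeyError(f"missing codon feature columns: {missing[:5]}")
    return rscu[expected]


def standardize(fm: pd.DataFrame) -> tuple[pd.DataFrame, StandardScaler, list[str]]:
    """Column-wise z-scoring (population denominator, ML-scaler convention).

    Returns the scaled matrix, the fitted scaler, and the names of
    zero-variance columns (left as all-zero and flagged).
    """
    if fm.shape[0] < 2:
        raise ValueError("standardization requires at least 2 samples")
    scaler = StandardScaler()
    scaled = scaler.fit_transform(fm.to_numpy(dtype=float))
    constant = [c for c, v in zip(fm.columns, scaler.var_) if v == 0]
    return pd.DataFrame(scaled, index=fm.index, columns=fm.columns), scaler, constant


@dataclass
class PCAModel:
    """Fitted PCA on the 59-codon feature space.

    loadings: features x K, columns orthonormal, sign-fixed so each
    component's largest-|loading| entry is positive.  scores: samples x K.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    feature_means: np.ndarray
    feature_scales: np.ndarray
    n_components: int = field(init=False)

    def __post_init__(self):
        self.n_components = self.loadings.shape[1]


def fit_pca(
    fm: pd.DataFrame, var_threshold: float = 0.80, cap: int = 5
) -> PCAModel:
    """PCA keeping K = min(cap, smallest k reaching the variance threshold).

    ``fm`` should already be standardized; it is re-centered defensively.
    """
    if not 0 < var_threshold <= 1:
        raise ValueError(f"var_threshold must be in (0, 1], got {var_threshold}")
    X = fm.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    full = PCA()
    full_scores = full.fit_transform(X)
    cum = np.cumsum(full.explained_variance_ratio_)
    k80 = int(np.searchsorted(cum, var_threshold) + 1)
    k = min(cap, k80, len(cum))

    loadings = full.components_[:k].T.copy()  # features x k
    scores = full_scores[:, :k].copy()
    # PCA signs are arbitrary; fix each component so its largest-|loading|
    # entry is positive, for reproducible +corr/-corr codon sets.
    for j in range(k):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    pcs = [f"PC{i + 1}" for i in range(k)]
    return PCAModel(
        loadings=pd.DataFrame(loadings, index=fm.columns, columns=pcs),
        scores=pd.DataFrame(scores, index=fm.index, columns=pcs),
        explained_variance_ratio=full.explained_variance_ratio_[:k],
        feature_means=full.mean_,
        feature_scales=np.ones(X.shape[1]),
    )


@dataclass(frozen=True)
class LoadingReport:
    """Per-component high-loading codons grouped by amino acid.

    ``highlighted``: PC -> {aa: {"positive": [...], "negative": [...]}},
    restricted to amino acids with >= 2 passing codons on that component.
    ``raw`` keeps every passing codon regardless of the two-codon rule.
    """

    cutoff: float
    highlighted: dict
    raw: dict


def loading_report(
    model: PCAModel,
    cutoff: float = 0.2,
    code: GeneticCode | None = None,
    per_sign: bool = False,
) -> LoadingReport:
    """Group codons with |loading| >= cutoff by amino acid, per component.

    By default the >= 2-synonymous-codon rule pools both signs on a
    component; ``per_sign=True`` counts each sign separately.
    """
    code = code or standard_genetic_code()
    highlighted: dict = {}
    raw: dict = {}
    for pc in model.loadings.columns:
        col = model.loadings[pc]
        pos = sorted(col.index[col >= cutoff])
        neg = sorted(col.index[col <= -cutoff])
        raw[pc] = {"positive": pos, "negative": neg}
        by_aa: dict = {}
        for codon in pos + neg:
            by_aa.setdefault(code.codon_to_aa[codon], {"positive": [], "negative": []})
        for codon in pos:
            by_aa[code.codon_to_aa[codon]]["positive"].append(codon)
        for codon in neg:
            by_aa[code.codon_to_aa[codon]]["negative"].append(codon)
        kept = {}
        for aa, sets in by_aa.items():
            if per_sign:
                ok = len(sets["positive"]) >= 2 or len(sets["negative"]) >= 2
            else:
                ok = len(sets["positive"]) + len(sets["negative"]) >= 2
            if ok:
                kept[AA_THREE[aa]] = sets
        highlighted[pc] = kept
    return LoadingReport(cutoff=cutoff, highlighted=highlighted, raw=raw)


@dataclass(frozen=True)
class SampleDescriptor:
    """A sample singled out by a high component score."""

    sample_id: str
    pc: str
    score: float
    positive_codons: tuple[str, ...]
    negative_codons: tuple[str, ...]


def describe_samples(
    model: PCAModel,
    score_threshold: float = 5.0,
    absolute: bool = False,
    report: LoadingReport | None = None,
) -> list[SampleDescriptor]:
    """Samples whose score exceeds the threshold (strictly) on any component.

    Scores are signed by default; ``absolute=True`` also picks up samples in
    the negative quadrants.  Each descriptor carries the component's
    positively and negatively loaded codon sets.
    """
    report = report or loading_report(model)
    out = []
    for pc in model.scores.columns:
        col = model.scores[pc]
        vals = col.abs() if absolute else col
        for sample_id in col.index[vals > score_threshold]:
            out.append(
                SampleDescriptor(
                    sample_id=str(sample_id),
                    pc=pc,
                    score=float(col[sample_id]),
                    positive_codons=tuple(report.raw[pc]["positive"]),
                    negative_codons=tuple(report.raw[pc]["negative"]),
                )
            )
    return out


def nucleotide_preference(codon_set, position: int = 2) -> str:
    """Rank nucleotide usage at a codon position (default: third/wobble).

    Emits e.g. ``"C>G>T>A"``; ``=`` joins tied counts, ties displayed
    alphabetically.  All four nucleotides always appear.
    """
    codons = list(codon_set)
    if not codons:
        raise ValueError("empty codon set")
    counts = {nt: 0 for nt in "ACGT"}
    for codon in codons:
        counts[codon[position]] += 1
    ranked = sorted(counts, key=lambda nt: (-counts[nt], nt))
    parts = [ranked[0]]
    for prev, nt in zip(ranked, ranked[1:]):
        parts.append(("=" if counts[nt] == counts[prev] else ">") + nt)
    return "".join(parts)
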