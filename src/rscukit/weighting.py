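"""Gene-set-restricted expression and transcriptome-weighted codon usage.

A sample's codon demand is the expression-weighted sum of the codon counts
of the genes it expresses: ``W(c) = sum_g TPM(g) * counts_g(c)``, optionally
normalized to codons per 1,000 weighted codons (codon-usage-table
convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import CODONS


class EmptySelectionError(ValueError):
    """A sample or gene filter matched nothing."""


class DegenerateSampleError(ValueError):
    """Total weighted codon count is zero; the profile is undefined."""


@dataclass(frozen=True)
class GeneSet:
    """A labelled gene set (e.g. healthy- or disease-associated genes)."""

    label: str
    gene_ids: frozenset[str]


@dataclass(frozen=True)
class WeightedUsageProfile:
    """Per-sample transcriptome-weighted codon usage (64 codons).

    ``usage`` is indexed by :data:`rscukit.codons.CODONS`; when
    ``normalized`` it sums to 1,000.
    """

    sample_id: str
    usage: pd.Series
    normalized: bool


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TPM matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicate gene or sample ids in {path}")
    if (df.values < 0).any():
        raise ValueError(f"negative TPM values in {path}")
    return df


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, strain, tissue, stage, library_id)."""
    meta = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    required = {"sample_id", "strain", "tissue", "stage", "library_id"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns: {sorted(missing)}")
    return meta


def filter_samples(
    metadata: pd.DataFrame,
    tissue: str,
    strains: list[str] | None = None,
) -> list[str]:
    """Select sample ids by tissue and (optionally) strain, order preserved."""
    mask = metadata["tissue"] == tissue
    if strains is not None:
        mask &= metadata["strain"].isin(strains)
    selected = metadata.loc[mask, "sample_id"].tolist()
    if not selected:
        raise EmptySelectionError(
            f"no samples match tissue={tissue!r}, strains={strains!r}"
        )
    return selected


def restrict_to_gene_set(
    expr: pd.DataFrame, gene_set: GeneSet, cds_gene_ids: set[str]
) -> pd.DataFrame:
    """Restrict the expression matrix to genes in the set with a known CDS.

    The retained gene axis is the three-way intersection of expression
    genes, the gene set, and the CDS collection, in expression-matrix order.
    """
    keep = [
        g for g in expr.index if g in gene_set.gene_ids and g in cds_gene_ids
    ]
    if not keep:
        raise EmptySelectionError(
            "empty intersection: "
            f"{len(expr.index)} expression genes, "
            f"{len(gene_set.gene_ids)} gene-set genes, "
            f"{len(cds_gene_ids)} CDS genes"
        )
    return expr.loc[keep]


def weighted_codon_usage(
    tpm_column: pd.Series,
    codon_counts: dict[str, np.ndarray],
    normalize: bool = True,
    sample_id: str | None = None,
) -> WeightedUsageProfile:
    """Weight per-gene codon counts by a sample's TPM values.

    Parameters
    ----------
    tpm_column
        TPM per gene for one sample; its index must be a subset of
        ``codon_counts`` keys.
    codon_counts
        Gene -> 64-vector of codon counts.
    normalize
        If true, scale to 1,000 total weighted codons.
    """
    missing = [g for g in tpm_column.index if g not in codon_counts]
    if missing:
        raise KeyError(f"genes without codon counts: {missing[:5]}")
    count_matrix = np.vstack([codon_counts[g] for g in tpm_column.index])
    raw = tpm_column.to_numpy(dtype=float) @ count_matrix
    total = raw.sum()
    if total <= 0:
        raise DegenerateSampleError(
            f"sample {tpm_column.name!r}: total weighted codon count is zero"
        )
    usage = 1000.0 * raw / total if normalize else raw
    return WeightedUsageProfile(
        sample_id=str(sample_id if sample_id is not None else tpm_column.name),
        usage=pd.Series(usage, index=list(CODONS)),
        normalized=normalize,
    )


def usage_matrix(profiles: list[WeightedUsageProfile]) -> pd.DataFrame:
    """Stack profiles into a samples x 64 usage table (CoCoPUTs-like)."""
    return pd.DataFrame(
        {p.sample_id: p.usage for p in profiles}
    ).T.rename_axis("sample_id")
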