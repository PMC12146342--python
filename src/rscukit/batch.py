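"""Library-of-origin batch correction for RSCU feature matrices.

Implements the parametric empirical-Bayes location/scale ("ComBat") model
with no biological covariates: features are standardized against the grand
mean and pooled variance, per-batch additive and multiplicative effects are
estimated, shrunk toward their across-feature priors (normal prior for
locations, inverse-gamma for scales), removed, and the grand location/scale
restored.  Batches default to the sequence-archive accession prefix of each
sample's library id (SRR = NCBI SRA, ERR = EGA/ENA, DRR = DDBJ).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KNOWN_PREFIXES = ("SRR", "ERR", "DRR")


class UnknownBatchError(ValueError):
    """A library id does not start with a recognized archive prefix."""


class SingletonBatchError(ValueError):
    """A batch contains a single sample; EB variance is undefined."""


def infer_batches(metadata: pd.DataFrame) -> pd.Series:
    """Batch label per sample from an explicit ``batch`` column if present,
    otherwise from the library-id accession prefix (SRR/ERR/DRR).

    Returns a Series indexed by sample_id.
    """
    if "batch" in metadata.columns:
        return pd.Series(
            metadata["batch"].astype(str).values,
            index=metadata["sample_id"].values,
            name="batch",
        )
    labels = {}
    for _, row in metadata.iterrows():
        lib = str(row["library_id"])
        prefix = lib[:3].upper()
        if prefix not in KNOWN_PREFIXES:
            raise UnknownBatchError(
                f"library id {lib!r} (sample {row['sample_id']!r}) has no "
                f"recognized archive prefix {KNOWN_PREFIXES}; add an explicit "
                "'batch' metadata column to override"
            )
        labels[row["sample_id"]] = prefix
    return pd.Series(labels, name="batch")


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2 if s2 > 0 else 2.0


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2 if s2 > 0 else m


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative EB solution for one batch's shrunk location/scale."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).clip(1e-12).max(),
            np.abs(d_new - d_old).max() / np.abs(d_old).clip(1e-12).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def adjust_batch_effects(
    matrix: pd.DataFrame,
    batches: pd.Series,
    merge_singletons: bool = False,
    parametric_shrinkage: bool = True,
) -> pd.DataFrame:
    """Remove per-batch location/scale effects from a samples x features matrix.

    Features with zero pooled variance are passed through unchanged, as is
    the whole matrix when only one batch is present.  Sample order, shape,
    and index/columns are preserved.

    Parameters
    ----------
    matrix
        Samples (rows) x features (columns), e.g. an RSCU matrix.
    batches
        Batch label per sample, indexed by (or aligned with) matrix rows.
    merge_singletons
        Pool single-sample batches into the largest batch instead of
        raising :class:`SingletonBatchError`.
    parametric_shrinkage
        Apply the parametric empirical-Bayes shrinkage (default); if off,
        the raw per-batch location/scale estimates are used.
    """
    batches = pd.Series(batches)
    if len(batches) != matrix.shape[0]:
        raise ValueError("one batch label per sample is required")
    labels = np.asarray(batches.values, dtype=object)

    sizes = pd.Series(labels).value_counts()
    if (sizes == 1).any() and len(sizes) > 1:
        singles = sizes.index[sizes == 1].tolist()
        if not merge_singletons:
            raise SingletonBatchError(
                f"batches {singles} have a single sample; merge them into a "
                "larger batch (merge_singletons=True) or drop the samples"
            )
        largest = sizes.idxmax()
        labels = np.where(np.isin(labels, singles), largest, labels)
        logger.warning("merged singleton batches %s into %r", singles, largest)

    unique = pd.unique(labels)
    if len(unique) == 1:
        return matrix.copy()

    # ComBat operates features x samples.
    X = matrix.to_numpy(dtype=float).T
    n_feat, n_samp = X.shape
    groups = [np.flatnonzero(labels == b) for b in unique]
    n_per = np.array([len(g) for g in groups], dtype=float)

    batch_means = np.stack([X[:, g].mean(axis=1) for g in groups], axis=1)
    grand_mean = batch_means @ (n_per / n_samp)
    fitted = np.zeros_like(X)
    for j, g in enumerate(groups):
        fitted[:, g] = batch_means[:, [j]]
    var_pooled = ((X - fitted) ** 2).mean(axis=1)

    active = var_pooled > 0  # zero-variance features pass through
    Xa = X[active]
    sd = np.sqrt(var_pooled[active])
    Z = (Xa - grand_mean[active, None]) / sd[:, None]

    adjusted = Z.copy()
    for j, g in enumerate(groups):
        zb = Z[:, g]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        d_hat = np.clip(d_hat, 1e-12, None)
        if parametric_shrinkage and len(g_hat) > 1:
            g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
            if t2 <= 0:
                g_star, d_star = g_hat, d_hat
            else:
                a, b = _aprior(d_hat), _bprior(d_hat)
                g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, b)
        else:
            g_star, d_star = g_hat, d_hat
        adjusted[:, g] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = X.copy()
    out[active] = adjusted * sd[:, None] + grand_mean[active, None]
    return pd.DataFrame(out.T, index=matrix.index, columns=matrix.columns)
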