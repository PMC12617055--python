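"""Count filtering, size factors, TPM and log transforms.

Low-count filtering keeps a gene when at least ``min_count`` reads are seen
in strictly more than ``min_samples_exclusive`` samples. Size factors use the
median-of-ratios estimator: per sample, the median over all-positive genes of
the ratio of that sample's count to the gene's geometric mean across samples.
TPM divides counts by gene length in kb and rescales each sample to 1e6.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import CountMatrix


def filter_low_counts(
    cm: CountMatrix, min_count: int = 5, min_samples_exclusive: int = 3
) -> CountMatrix:
    """Keep genes detected at >= min_count reads in > min_samples_exclusive samples."""
    if min_count < 0 or min_samples_exclusive < 0:
        raise ValueError("thresholds must be >= 0")
    n_detected = (cm.counts >= min_count).sum(axis=1)
    keep = n_detected > min_samples_exclusive
    if not keep.any():
        warnings.warn("low-count filter removed every gene", stacklevel=2)
    return cm.subset_genes(keep)


def size_factors_median_of_ratios(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    Reference genes are those with positive counts in every sample; their
    per-sample count / geometric-mean ratios are medianned per sample.
    """
    counts = cm.counts.astype(float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; filter low-count "
            "genes or check the matrix"
        )
    ref = counts[all_positive]
    log_geo_mean = np.log(ref).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(ref) - log_geo_mean, axis=0))
    return factors


def normalized_counts(cm: CountMatrix, size_factors: np.ndarray | None = None) -> pd.DataFrame:
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(cm)
    return pd.DataFrame(
        cm.counts / np.asarray(size_factors)[None, :],
        index=cm.gene_ids,
        columns=cm.sample_ids,
    )


def tpm(cm: CountMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Transcripts per kilobase million; every sample column sums to 1e6."""
    lengths = annotation.set_index("gene_id")["length"].reindex(cm.gene_ids.astype(str))
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise KeyError(f"annotation missing lengths for genes: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = cm.counts / (lengths.to_numpy()[:, None] / 1e3)
    col_sums = rate.sum(axis=0)
    if (col_sums == 0).any():
        bad = cm.sample_ids[col_sums == 0].tolist()
        raise ValueError(f"TPM undefined for all-zero samples: {bad}")
    return pd.DataFrame(rate / col_sums * 1e6, index=cm.gene_ids, columns=cm.sample_ids)


def log2_with_pseudocount(values, pseudocount: float = 1.0):
    """Elementwise log2(value + pseudocount); input must be non-negative."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    out = np.log2(arr + pseudocount)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def pca_qc(
    log_expression: pd.DataFrame, n_components: int = 2, top_genes: int = 500
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA on the top-variance genes, for QC of tissue/sex structure.

    Parameters
    ----------
    log_expression
        genes x samples matrix of log-scale expression.
    n_components
        number of principal components to return.
    top_genes
        number of highest-variance genes used (all genes if fewer).

    Returns (coordinates: samples x PCs, variance_explained ratios).
    """
    n_samples = log_expression.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > min(n_samples, log_expression.shape[0]):
        raise ValueError("n_components exceeds matrix rank bound")
    variances = log_expression.var(axis=1)
    top = variances.sort_values(ascending=False).index[: min(top_genes, len(variances))]
    X = log_expression.loc[top].to_numpy().T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=log_expression.columns, columns=cols),
        pca.explained_variance_ratio_,
    )
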