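"""Library-size normalization, expression filtering, log transform, outlier flagging.

The normalization is the median-of-ratios estimator: a per-gene
pseudo-reference (geometric mean across samples, over genes with no zero
count) and a per-sample size factor equal to the median count/reference
ratio.  The log transform is a size-factor-aware pseudocount log2 — a
deliberately simple variance-moderating transform whose name is recorded
on the output so provenance is explicit.  Outlier samples are flagged
from their terminal merge height in an average-linkage dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import median_abs_deviation


class NormalizationImpossibleError(ValueError):
    """No gene has strictly positive counts in every sample."""


class InsufficientSamplesError(ValueError):
    """Hierarchical outlier flagging needs at least three samples."""


@dataclass
class NormalizationResult:
    size_factors: pd.Series        # per-sample, positive
    reference_genes_used: int


@dataclass
class LogMatrix:
    values: pd.DataFrame           # genes x samples
    pseudocount: float
    transform_name: str = "log2_sf_pseudocount"


def compute_size_factors(counts: pd.DataFrame) -> NormalizationResult:
    """Median-of-ratios size factors (genes x samples input)."""
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise NormalizationImpossibleError(
            "no gene with all-positive counts; cannot form the pseudo-reference")
    ref = np.exp(np.log(x[allpos]).mean(axis=1))       # per-gene geometric mean
    ratios = x[allpos] / ref[:, None]
    s = np.median(ratios, axis=0)
    return NormalizationResult(
        size_factors=pd.Series(s, index=counts.columns, name="size_factor"),
        reference_genes_used=int(allpos.sum()),
    )


def filter_low_expression(counts: pd.DataFrame, min_count: int = 5,
                          max_low_samples: int = 80) -> pd.DataFrame:
    """Drop gene g iff count < min_count in MORE THAN max_low_samples samples.

    The boundary is strict: a gene low in exactly max_low_samples samples
    is retained.
    """
    if min_count < 0 or max_low_samples < 0:
        raise ValueError("thresholds must be >= 0")
    if max_low_samples > counts.shape[1]:
        raise ValueError("max_low_samples exceeds the number of samples")
    n_low = (counts.to_numpy() < min_count).sum(axis=1)
    return counts.loc[n_low <= max_low_samples]


def moderated_log(counts: pd.DataFrame, sf: NormalizationResult,
                  pseudocount: float = 1.0) -> LogMatrix:
    """log2(count/size_factor + pseudocount), monotone in counts per cell."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    s = sf.size_factors.reindex(counts.columns).to_numpy(dtype=float)
    vals = np.log2(counts.to_numpy(dtype=float) / s[None, :] + pseudocount)
    return LogMatrix(values=pd.DataFrame(vals, index=counts.index, columns=counts.columns),
                     pseudocount=float(pseudocount))


def terminal_merge_heights(logm: LogMatrix) -> pd.Series:
    """Height at which each sample (as a singleton) first merges."""
    n = logm.values.shape[1]
    d = pdist(logm.values.to_numpy().T, metric="euclidean")
    Z = linkage(d, method="average")
    h = np.full(n, np.nan)
    for a, b, height in zip(Z[:, 0].astype(int), Z[:, 1].astype(int), Z[:, 2]):
        if a < n:
            h[a] = height
        if b < n:
            h[b] = height
    return pd.Series(h, index=logm.values.columns, name="terminal_merge_height")


def flag_outlier_samples(logm: LogMatrix, height_mads: float = 3.0) -> list:
    """Samples whose terminal merge height exceeds median + k * MAD.

    MAD is normal-consistent (scaled by 1.4826) so k behaves like a
    robust z-score threshold.
    """
    if logm.values.shape[1] < 3:
        raise InsufficientSamplesError("need at least 3 samples to flag outliers")
    h = terminal_merge_heights(logm)
    mad = median_abs_deviation(h.to_numpy(), scale="normal")
    cut = np.median(h.to_numpy()) + height_mads * mad
    return list(h.index[h.to_numpy() > cut])
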