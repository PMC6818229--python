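"""Normalization, expression filtering and sample QC.

Between-sample normalization is the trimmed mean of M-values (TMM): a
weighted trimmed mean of per-gene log expression ratios against a reference
sample, which corrects library composition bias that raw library-size
scaling misses.  Expression is reported as counts per million (CPM) on the
TMM-adjusted effective library size.  Sample QC follows the usual RNA-seq
idiom: classical multidimensional scaling of pairwise expression distances,
with a nearest-centroid rule to flag samples that sit closer to another
biological group than to their own.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "tmm_factors",
    "compute_cpm",
    "filter_expressed",
    "working_set",
    "mds_embedding",
    "flag_outlier_samples",
]


def tmm_factors(counts: pd.DataFrame,
                log_ratio_trim: float = 0.3,
                abs_expr_trim: float = 0.05) -> pd.Series:
    """TMM normalization factor per sample.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile.  For each sample, genes expressed
    in both the sample and the reference contribute an M-value (log2 ratio
    of library-size-scaled counts) and an A-value (average log abundance);
    the most extreme 30% of M on each side and 5% of A are trimmed, and
    the factor is 2 to the inverse-variance-weighted mean of the remaining
    M-values.  Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(
            f"all-zero sample(s): {list(counts.columns[zero])}")

    q75 = np.array([np.quantile(y[:, j], 0.75) for j in range(y.shape[1])])
    f75 = q75 / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yk, nk = y[:, j], lib[j]
        keep = (yk > 0) & (yr > 0)
        if not keep.any():
            continue
        m = np.log2((yk[keep] / nk) / (yr[keep] / nr))
        a = 0.5 * np.log2((yk[keep] / nk) * (yr[keep] / nr))
        # inverse of the delta-method variance of each M-value
        w = 1.0 / ((nk - yk[keep]) / (nk * yk[keep])
                   + (nr - yr[keep]) / (nr * yr[keep]))
        finite = np.isfinite(m) & np.isfinite(a)
        m, a, w = m[finite], a[finite], w[finite]
        if m.size == 0 or np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_m = np.floor(n * log_ratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_expr_trim) + 1
        hi_a = n + 1 - lo_a
        rm, ra = rankdata(m, method="average"), rankdata(a, method="average")
        keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep2.any() or w[keep2].sum() == 0:
            continue
        factors[j] = 2.0 ** (np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2]))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def compute_cpm(counts: pd.DataFrame,
                factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on the TMM-effective library size.

    cpm[g, s] = counts[g, s] / (library_size[s] * factor[s]) * 1e6.
    """
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        raise ValueError("normalization factors do not align with samples")
    if (factors <= 0).any():
        raise ValueError("normalization factors must be positive")
    eff = lib * factors
    return counts.div(eff, axis=1) * 1e6


def filter_expressed(cpm: pd.DataFrame, min_cpm: float = 1.0,
                     min_libraries: int = 3) -> pd.Index:
    """Genes with CPM strictly above ``min_cpm`` in >= ``min_libraries``."""
    if min_libraries > cpm.shape[1]:
        raise ValueError(
            f"min_libraries={min_libraries} exceeds sample count {cpm.shape[1]}")
    keep = (cpm > min_cpm).sum(axis=1) >= min_libraries
    return cpm.index[keep]


def working_set(cpm: pd.DataFrame, condition_of_sample: pd.Series,
                min_cpm: float = 1.0) -> pd.Index:
    """Genes whose mean CPM exceeds ``min_cpm`` in at least one condition."""
    cond = condition_of_sample.reindex(cpm.columns)
    if cond.isna().any():
        raise ValueError("every sample needs a condition assignment")
    means = cpm.T.groupby(cond.to_numpy()).mean().T
    if means.shape[1] == 0:
        raise ValueError("no conditions defined")
    return cpm.index[(means > min_cpm).any(axis=1)]


def _pairwise_distance(logcpm: np.ndarray, n_top: int) -> np.ndarray:
    """Root-mean-square log-expression difference over the genes that differ
    most between each specific pair ('leading log fold change' idiom)."""
    n = logcpm.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (logcpm[:, i] - logcpm[:, j]) ** 2
            k = min(n_top, diff2.size)
            top = np.sort(diff2)[-k:]
            d[i, j] = d[j, i] = np.sqrt(top.mean())
    return d


def mds_embedding(cpm: pd.DataFrame, n_top: int = 500,
                  prior: float = 0.5) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples in 2 dimensions.

    Distances are the RMS of log2(CPM + prior) differences over the
    ``n_top`` most divergent genes of each sample pair.  Axis signs are
    fixed so the embedding is fully deterministic.
    """
    if cpm.shape[1] < 3:
        raise ValueError("MDS needs at least three samples")
    logcpm = np.log2(cpm.to_numpy(dtype=float) + prior)
    d = _pairwise_distance(logcpm, n_top)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    for k in range(coords.shape[1]):  # deterministic sign
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    return pd.DataFrame(coords, index=cpm.columns, columns=["dim1", "dim2"])


def flag_outlier_samples(embedding: pd.DataFrame,
                         group_of_sample: pd.Series) -> list[str]:
    """Samples closer to another group's centroid than to their own.

    Own-group centroids are computed leaving the candidate sample out, so a
    far outlier cannot drag its own centroid after itself.  Ties resolve as
    not-flagged; singleton groups are never flagged.
    """
    groups = group_of_sample.reindex(embedding.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    coords = embedding.to_numpy(dtype=float)
    labels = groups.to_numpy()
    flagged = []
    for i, sid in enumerate(embedding.index):
        own = labels == labels[i]
        own_others = own.copy()
        own_others[i] = False
        if not own_others.any():
            continue
        d_own = np.linalg.norm(coords[i] - coords[own_others].mean(axis=0))
        for other in np.unique(labels[~own]):
            cent = coords[labels == other].mean(axis=0)
            if np.linalg.norm(coords[i] - cent) < d_own - 1e-12:
                flagged.append(sid)
                break
    return flagged
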