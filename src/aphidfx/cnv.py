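"""Pool-seq coverage-ratio copy-number analysis.

Gene-level depth in each biotype pool is the length-weighted mean of its
per-exon mean depths; pool depths are made comparable by dividing by the
pool-wide mean gene coverage, and the per-gene ratio of normalized
coverages (pea / alfalfa by convention) tracks relative copy number:
about 1 for equal copy number, near 0.5 for a hemizygous deletion in the
numerator pool, below 0.1 suggesting the gene is absent from the
numerator biotype.  Biotype-specific absence calls additionally require
the expression pattern to agree (CPM below threshold in every line of the
depleted biotype, above it in every line of the other).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "gene_coverage",
    "normalize_coverage",
    "coverage_ratio",
    "compare_subset_ratios",
    "call_biotype_specific",
    "cnv_table",
]


def gene_coverage(exon_depth: pd.DataFrame) -> pd.Series:
    """Length-weighted mean exon depth per gene.

    Input columns: chrom, start, end, gene_id, mean_depth (BED half-open,
    the shape of coverageBed mean output).  Coverage = sum(depth * exon
    length) / sum(exon length).
    """
    length = (exon_depth["end"] - exon_depth["start"]).to_numpy(dtype=float)
    if (length < 1).any():
        raise ValueError("exon lengths must be >= 1")
    df = pd.DataFrame({
        "gene_id": exon_depth["gene_id"].to_numpy(),
        "weighted": exon_depth["mean_depth"].to_numpy(dtype=float) * length,
        "length": length,
    })
    agg = df.groupby("gene_id", sort=True).sum()
    if (agg["length"] <= 0).any():
        raise ValueError("gene with zero total exon length")
    return (agg["weighted"] / agg["length"]).rename("gene_coverage")


def normalize_coverage(coverage: pd.Series) -> pd.Series:
    """Divide by the pool-wide mean gene coverage (normalized mean = 1)."""
    mean = coverage.mean()
    if not mean > 0:
        raise ValueError("pool has no coverage")
    return (coverage / mean).rename("normalized_coverage")


def coverage_ratio(normalized_a: pd.Series,
                   normalized_b: pd.Series) -> pd.Series:
    """Per-gene ratio a/b of normalized coverages.

    0/0 is undefined (NaN); positive/0 is +inf.  Gene universes must match.
    """
    if not normalized_a.index.sort_values().equals(
            normalized_b.index.sort_values()):
        raise ValueError("gene universes differ between pools")
    b = normalized_b.reindex(normalized_a.index)
    a = normalized_a
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a.to_numpy() / b.to_numpy()
    r = np.where((a.to_numpy() == 0) & (b.to_numpy() == 0), np.nan, r)
    return pd.Series(r, index=a.index, name="ratio")


def compare_subset_ratios(ratios: pd.Series,
                          classes: pd.Series,
                          pairs: list[tuple[str, str]] = (
                              ("alfalfa_up", "non_de"),
                              ("pea_up", "non_de"))) -> pd.DataFrame:
    """Two-sided Mann-Whitney U between effector-class ratio distributions.

    Normal approximation with tie correction; reports U, p and medians.
    Subsets with fewer than two finite ratios yield NA with a warning.
    """
    cls = classes.reindex(ratios.index)
    rows = []
    for a, b in pairs:
        xa = ratios[(cls == a) & np.isfinite(ratios)].to_numpy()
        xb = ratios[(cls == b) & np.isfinite(ratios)].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(f"subset too small for {a} vs {b}", stacklevel=2)
            rows.append((a, b, np.nan, np.nan, np.nan, np.nan))
            continue
        if (len(np.unique(np.concatenate([xa, xb]))) == 1):
            u = len(xa) * len(xb) / 2.0
            p = 1.0
        else:
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                     method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
        rows.append((a, b, u, p, float(np.median(xa)), float(np.median(xb))))
    return pd.DataFrame(rows, columns=["subset_a", "subset_b", "U", "p_value",
                                       "median_a", "median_b"])


def call_biotype_specific(ratios: pd.Series,
                          line_mean_cpm: pd.DataFrame,
                          biotype_of_line: dict[str, str],
                          numerator_biotype: str = "pea",
                          ratio_threshold: float = 0.1,
                          cpm_threshold: float = 1.0) -> pd.Series:
    """Genes likely absent from one biotype's genome.

    With ratio = numerator/denominator pool coverage, a gene is called
    absent in the numerator biotype when ratio < ratio_threshold, its mean
    CPM is below cpm_threshold in every line of the numerator biotype, and
    above it in every line of the other biotype; symmetrically (ratio >
    1/ratio_threshold) for absence in the denominator biotype.  Returns a
    per-gene label: absent_in_<biotype> or none.
    """
    lines = list(line_mean_cpm.columns)
    num_lines = [l for l in lines if biotype_of_line[l] == numerator_biotype]
    den_lines = [l for l in lines if biotype_of_line[l] != numerator_biotype]
    den_biotype = biotype_of_line[den_lines[0]] if den_lines else "other"
    cpm = line_mean_cpm.reindex(ratios.index)
    low_num = (cpm[num_lines] < cpm_threshold).all(axis=1)
    high_num = (cpm[num_lines] > cpm_threshold).all(axis=1)
    low_den = (cpm[den_lines] < cpm_threshold).all(axis=1)
    high_den = (cpm[den_lines] > cpm_threshold).all(axis=1)
    r = ratios.to_numpy(dtype=float)
    absent_num = (r < ratio_threshold) & low_num & high_den
    with np.errstate(over="ignore"):
        absent_den = (r > 1.0 / ratio_threshold) & low_den & high_num
    out = np.select([absent_num, absent_den],
                    [f"absent_in_{numerator_biotype}",
                     f"absent_in_{den_biotype}"], default="none")
    return pd.Series(out, index=ratios.index, name="cnv_call")


def cnv_table(pool_a_exons: pd.DataFrame, pool_b_exons: pd.DataFrame,
              name_a: str = "pea", name_b: str = "alfalfa") -> pd.DataFrame:
    """Assembled per-gene CNV table: coverages, normalized values, ratio."""
    cov_a = gene_coverage(pool_a_exons)
    cov_b = gene_coverage(pool_b_exons)
    norm_a = normalize_coverage(cov_a)
    norm_b = normalize_coverage(cov_b)
    ratio = coverage_ratio(norm_a, norm_b)
    return pd.DataFrame({
        f"cov_{name_a}": cov_a, f"cov_{name_b}": cov_b,
        f"norm_{name_a}": norm_a, f"norm_{name_b}": norm_b,
        "ratio": ratio,
    })
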