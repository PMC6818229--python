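"""Orthology proportion tests, the duplicated-gene resampling CI, and the
fecundity Kruskal-Wallis test.

The duplication enrichment test treats the effector catalogue as a finite
population: each effector subset's expected duplicated-gene count is the
empirical distribution of draws of the subset's size, without replacement,
from the full effector list (10,000 draws by default).  A subset is
enriched when its observed duplicated count lies above the 95% CI of that
distribution, depleted when below.  Because sampling is without
replacement the exact reference distribution is hypergeometric, which the
test suite uses as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "proportion_test",
    "orthology_proportion_tests",
    "ResamplingResult",
    "duplication_resampling_ci",
    "kruskal_wallis",
    "fecundity_tests",
]


def proportion_test(count_a: int, total_a: int, count_b: int,
                    total_b: int) -> float:
    """Two-sided two-proportion chi-square test with continuity correction.

    Matches R's two-sample prop.test (Yates-corrected 2x2 chi-square).
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("counts must lie within totals")
    if count_a * total_b == count_b * total_a:
        return 1.0
    table = np.array([[count_a, total_a - count_a],
                      [count_b, total_b - count_b]], dtype=float)
    res = stats.chi2_contingency(table, correction=True)
    return float(res.pvalue)


def orthology_proportion_tests(annotations: pd.DataFrame,
                               subsets: dict[str, pd.Index],
                               background: pd.Index) -> pd.DataFrame:
    """Per-category proportion tests: each subset vs the background genes.

    Background is typically the expressed genes not in the effector
    catalogue.  Emits raw and BH-adjusted p-values (adjusted across
    categories within each subset).
    """
    from .diffexp import bh_fdr
    cats = annotations["orthology_category"].unique()
    rows = []
    bg = annotations.loc[background, "orthology_category"]
    for name, idx in subsets.items():
        sub = annotations.loc[idx, "orthology_category"]
        ps = []
        for cat in cats:
            p = proportion_test(int((sub == cat).sum()), len(sub),
                                int((bg == cat).sum()), len(bg))
            ps.append(p)
        q = bh_fdr(np.array(ps))
        for cat, p, qv in zip(cats, ps, q):
            rows.append((name, cat,
                         float((sub == cat).mean()),
                         float((bg == cat).mean()), p, qv))
    return pd.DataFrame(rows, columns=[
        "subset", "category", "subset_fraction", "background_fraction",
        "p_value", "fdr"])


@dataclass(frozen=True)
class ResamplingResult:
    subset_name: str
    subset_size: int
    observed_duplicated: int
    ci_low: int
    ci_high: int
    n_reps: int
    verdict: str  # above | within | below


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    n = len(sorted_vals)
    k = max(int(np.ceil(q * n)), 1)
    return sorted_vals[k - 1]


def duplication_resampling_ci(effector_ids: pd.Index,
                              duplicated: pd.Series,
                              subset_sizes: dict[str, int],
                              observed: dict[str, int],
                              n_reps: int = 10_000,
                              alpha: float = 0.05,
                              seed: int = 0) -> dict[str, ResamplingResult]:
    """Resampling 95% CI for duplicated-gene counts in effector subsets.

    For each subset, draws ``subset_size`` genes without replacement from
    the full effector list, counts the duplicated ones, repeats ``n_reps``
    times and takes the empirical [alpha/2, 1-alpha/2] percentiles
    (nearest-rank).  Verdict compares the observed count with strict
    inequalities: above ci_high = enrichment, below ci_low = depletion.
    """
    if n_reps < 100:
        warnings.warn("n_reps < 100 gives unstable CI bounds", stacklevel=2)
    flags = duplicated.reindex(effector_ids)
    if flags.isna().any():
        raise ValueError("duplication flags missing for some effectors")
    flags = flags.to_numpy(dtype=bool)
    n = len(flags)
    rng = np.random.default_rng(seed)
    out = {}
    for name, k in subset_sizes.items():
        if k > n:
            raise ValueError(f"subset {name!r} larger than the effector list")
        if k == n:
            d = int(flags.sum())
            counts = np.full(n_reps, d)
        else:
            counts = np.empty(n_reps, dtype=int)
            for i in range(n_reps):
                counts[i] = flags[rng.choice(n, size=k, replace=False)].sum()
        counts.sort()
        lo = int(_nearest_rank(counts, alpha / 2))
        hi = int(_nearest_rank(counts, 1 - alpha / 2))
        obs = int(observed[name])
        verdict = "above" if obs > hi else ("below" if obs < lo else "within")
        out[name] = ResamplingResult(name, int(k), obs, lo, hi,
                                     int(n_reps), verdict)
    return out


def kruskal_wallis(groups: list) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test: (H with tie correction, df, p).

    Degenerate all-identical data returns H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 nonempty groups")
    df = len(groups) - 1
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, df, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), df, float(res.pvalue)


def fecundity_tests(fecundity: pd.DataFrame) -> pd.DataFrame:
    """Per-line Kruskal-Wallis across the three test plants."""
    rows = []
    for line, sub in fecundity.groupby("line", sort=False):
        groups = [g["nymph_count"].to_numpy()
                  for _, g in sub.groupby("plant", sort=False)]
        h, df, p = kruskal_wallis(groups)
        rows.append((line, h, df, p))
    return pd.DataFrame(rows, columns=["line", "H", "df", "p_value"])
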