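"""Classification cascade from expression and secretion to the effector
catalogue.

A gene is a candidate salivary effector when it is predicted to be
secreted and expressed (mean CPM above threshold) in the salivary glands
of at least one of the two reference lines.  Candidates are then
partitioned by which line expresses them, flagged as SG-upregulated per
line from the SG-vs-AT organ contrasts, and assigned a biotype expression
class (alfalfa-up / pea-up / non-DE) from the filtered biotype contrast.
Every step is a deterministic set operation given its inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_candidates",
    "partition_line_specific",
    "sg_upregulated_union",
    "assign_biotype_class",
    "catalog_summary",
    "head_sg_concordance",
    "round_percent",
]


def round_percent(x: float) -> int:
    """Integer percent, rounding halves away from zero."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x))


def classify_candidates(sg_mean_cpm: pd.DataFrame, annotations: pd.DataFrame,
                        cpm_threshold: float = 1.0) -> pd.DataFrame:
    """Candidate effector table from per-line SG mean CPM + secretion flags.

    ``sg_mean_cpm``: genes x reference lines (mean CPM over SG replicates).
    Returns one row per gene with is_candidate, per-line expression flags
    and the line-specificity class.
    """
    missing = sg_mean_cpm.index.difference(annotations.index)
    if len(missing):
        raise ValueError(f"genes missing annotation: {list(missing[:10])}")
    lines = list(sg_mean_cpm.columns)
    if len(lines) != 2:
        raise ValueError("expected SG expression for exactly two lines")
    la, lb = lines
    cat = pd.DataFrame(index=sg_mean_cpm.index)
    secreted = annotations.loc[cat.index, "is_secreted"].astype(bool)
    cat[f"sg_expressed_{la}"] = sg_mean_cpm[la] > cpm_threshold
    cat[f"sg_expressed_{lb}"] = sg_mean_cpm[lb] > cpm_threshold
    cat["is_secreted"] = secreted
    expressed_any = cat[f"sg_expressed_{la}"] | cat[f"sg_expressed_{lb}"]
    cat["is_candidate"] = secreted & expressed_any
    both = cat[f"sg_expressed_{la}"] & cat[f"sg_expressed_{lb}"]
    spec = np.select(
        [~cat["is_candidate"], both,
         cat[f"sg_expressed_{la}"], cat[f"sg_expressed_{lb}"]],
        ["none", "shared", f"{la}_only", f"{lb}_only"], default="none")
    cat["line_specificity"] = spec
    cat.attrs["lines"] = (la, lb)
    return cat


def partition_line_specific(catalog: pd.DataFrame) -> dict[str, int]:
    """Counts of shared / line-A-only / line-B-only candidates."""
    la, lb = catalog.attrs["lines"]
    cand = catalog[catalog["is_candidate"]]
    counts = cand["line_specificity"].value_counts()
    return {
        "shared": int(counts.get("shared", 0)),
        f"{la}_only": int(counts.get(f"{la}_only", 0)),
        f"{lb}_only": int(counts.get(f"{lb}_only", 0)),
    }


def sg_upregulated_union(catalog: pd.DataFrame,
                         organ_results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-line SG-up flags from the organ contrasts, plus the union.

    ``organ_results[line]`` is a DE table from the SG-vs-AT contrast of
    that reference line with SG as group a, so fc > 1 means SG-up.  Adds
    sg_up_<line> columns and sg_up_any to the catalogue.
    """
    la, lb = catalog.attrs["lines"]
    for line in (la, lb):
        if line not in organ_results:
            raise ValueError(f"missing organ contrast for line {line!r}")
        res = organ_results[line].reindex(catalog.index)
        up = res["is_de"].fillna(False).astype(bool) & (res["fc"] > 1.0)
        catalog[f"sg_up_{line}"] = up & catalog["is_candidate"]
    catalog["sg_up_any"] = catalog[f"sg_up_{la}"] | catalog[f"sg_up_{lb}"]
    return catalog


def assign_biotype_class(catalog: pd.DataFrame,
                         biotype_result: pd.DataFrame) -> pd.DataFrame:
    """alfalfa_up / pea_up / non_de classes for candidates.

    ``biotype_result`` comes from the filtered biotype contrast with
    alfalfa as group a (``is_de_final`` when the t-filter ran, else
    ``is_de``); direction from fc.  Non-candidates get not_applicable.
    """
    res = biotype_result.reindex(catalog.index)
    de_col = "is_de_final" if "is_de_final" in res.columns else "is_de"
    de = res[de_col].fillna(False).astype(bool)
    fc = res["fc"]
    cls = np.select(
        [~catalog["is_candidate"], de & (fc > 1.0), de & (fc < 1.0)],
        ["not_applicable", "alfalfa_up", "pea_up"], default="non_de")
    catalog["biotype_class"] = cls
    return catalog


def catalog_summary(catalog: pd.DataFrame) -> dict:
    """The catalogue's full set accounting.

    Totals, the line-specificity partition, per-cell SG-up counts with the
    five disjoint cells (shared up in both lines, shared up in one line
    only, and each line-specific class up in its own line), the SG-up
    union, biotype class sizes and per-class SG-up percentages.
    """
    la, lb = catalog.attrs["lines"]
    cand = catalog[catalog["is_candidate"]]
    part = partition_line_specific(catalog)
    out = {
        "candidate_total": int(len(cand)),
        "partition": part,
    }
    if f"sg_up_{la}" in cand.columns:
        shared = cand[cand["line_specificity"] == "shared"]
        a_only = cand[cand["line_specificity"] == f"{la}_only"]
        b_only = cand[cand["line_specificity"] == f"{lb}_only"]
        cells = {
            "shared_up_both": int((shared[f"sg_up_{la}"]
                                   & shared[f"sg_up_{lb}"]).sum()),
            f"shared_up_{la}_only": int((shared[f"sg_up_{la}"]
                                         & ~shared[f"sg_up_{lb}"]).sum()),
            f"shared_up_{lb}_only": int((~shared[f"sg_up_{la}"]
                                         & shared[f"sg_up_{lb}"]).sum()),
            f"{la}_only_up": int(a_only[f"sg_up_{la}"].sum()),
            f"{lb}_only_up": int(b_only[f"sg_up_{lb}"].sum()),
        }
        out["sg_up_cells"] = cells
        out["sg_up_union"] = int(cand["sg_up_any"].sum())
        pct = {}
        if len(shared):
            pct["shared_up_both"] = round_percent(
                100.0 * cells["shared_up_both"] / len(shared))
            pct[f"shared_up_{la}_only"] = round_percent(
                100.0 * cells[f"shared_up_{la}_only"] / len(shared))
            pct[f"shared_up_{lb}_only"] = round_percent(
                100.0 * cells[f"shared_up_{lb}_only"] / len(shared))
        if len(a_only):
            pct[f"{la}_only_up"] = round_percent(
                100.0 * cells[f"{la}_only_up"] / len(a_only))
        if len(b_only):
            pct[f"{lb}_only_up"] = round_percent(
                100.0 * cells[f"{lb}_only_up"] / len(b_only))
        out["sg_up_percent"] = pct
    if "biotype_class" in cand.columns:
        vc = cand["biotype_class"].value_counts()
        classes = {k: int(vc.get(k, 0))
                   for k in ("alfalfa_up", "pea_up", "non_de")}
        out["biotype_classes"] = classes
        if "sg_up_any" in cand.columns:
            up_pct = {}
            up_counts = {}
            for k in classes:
                sub = cand[cand["biotype_class"] == k]
                up_counts[k] = int(sub["sg_up_any"].sum())
                if len(sub):
                    up_pct[k] = round_percent(100.0 * up_counts[k] / len(sub))
            out["biotype_class_sg_up"] = up_counts
            out["biotype_class_sg_up_percent"] = up_pct
    return out


def head_sg_concordance(sg_mean_cpm: pd.Series, head_mean_cpm: pd.Series,
                        candidates: pd.Index,
                        cpm_threshold: float = 1.0) -> tuple[float, float]:
    """(Spearman rho on log2(CPM+0.5), candidate detection fraction).

    Correlation is over the shared gene universe; detection is the
    fraction of the line's candidates with head mean CPM above threshold.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate set")
    sg = np.log2(sg_mean_cpm.to_numpy(dtype=float) + 0.5)
    head = np.log2(head_mean_cpm.reindex(sg_mean_cpm.index)
                   .to_numpy(dtype=float) + 0.5)
    rho = stats.spearmanr(sg, head).statistic
    detected = (head_mean_cpm.reindex(candidates) > cpm_threshold).mean()
    return float(rho), float(detected)
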