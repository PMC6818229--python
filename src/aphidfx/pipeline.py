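"""End-to-end orchestration and reporting.

``run_pipeline`` drives the full chain on an on-disk dataset: TMM/CPM
normalization, MDS-based sample QC with outlier removal, the organ, plant,
biotype and line differential-expression contrasts, the effector
classification cascade, orthology/duplication enrichment, the pool-seq
copy-number analysis, and the summary tables (the contrast accounting
table and the clustered expression-matrix export).  Every output is a
plain-text table or JSON document and the run manifest records input and
output checksums so identical inputs and seed reproduce identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import linkage, to_tree

from . import catalog as cat
from . import cnv as cnvmod
from . import enrichment as enr
from .diffexp import DEOptions, two_group_de, biotype_de, line_effect
from .expression import (compute_cpm, filter_expressed, flag_outlier_samples,
                         mds_embedding, tmm_factors, working_set)
from .simulate import REFERENCE_LINES

log = logging.getLogger("aphidfx")

__all__ = ["PipelineConfig", "run_pipeline", "build_table1",
           "export_expression_heatmap_matrix", "load_dataset_dir"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and the contrast roster for a pipeline run."""

    input_dir: str
    out_dir: str
    min_cpm: float = 1.0
    min_libraries: int = 3
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    t_alpha: float = 0.05
    ratio_threshold: float = 0.1
    ql_prior_weight: float = 10.0
    n_resample_reps: int = 10_000
    mds_top_genes: int = 500
    numerator_pool: str = "pea"
    denominator_pool: str = "alfalfa"
    seed: int = 0

    def de_options(self) -> DEOptions:
        return DEOptions(fc_threshold=self.fc_threshold,
                         fdr_threshold=self.fdr_threshold,
                         cpm_gate=self.min_cpm,
                         ql_prior_weight=self.ql_prior_weight,
                         t_alpha=self.t_alpha)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_dataset_dir(input_dir) -> dict:
    """Read the standard flat-file dataset layout into DataFrames."""
    d = Path(input_dir)
    needed = ["counts.tsv", "samples.tsv", "annotations.tsv", "exons.bed"]
    for name in needed:
        if not (d / name).exists():
            raise FileNotFoundError(f"missing input file: {d / name}")
    data = {
        "counts": pd.read_csv(d / "counts.tsv", sep="\t", index_col=0),
        "design": pd.read_csv(d / "samples.tsv", sep="\t"),
        "annotations": pd.read_csv(d / "annotations.tsv", sep="\t",
                                   index_col=0),
        "exons": pd.read_csv(d / "exons.bed", sep="\t", header=None,
                             names=["chrom", "start", "end", "gene_id"]),
    }
    data["pools"] = {}
    for p in sorted(d.glob("pool_*_exon_depth.tsv")):
        pool = p.name[len("pool_"):-len("_exon_depth.tsv")]
        data["pools"][pool] = pd.read_csv(p, sep="\t")
    fec = d / "fecundity.tsv"
    if fec.exists():
        data["fecundity"] = pd.read_csv(fec, sep="\t")
    return data


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def build_table1(de_tables: dict[str, pd.DataFrame],
                 candidate_ids: pd.Index) -> pd.DataFrame:
    """Contrast accounting: DE genes and DE candidate effectors per row.

    ``de_tables`` maps contrast name -> DE table carrying an ``is_de``
    (or ``is_de_final``) column.  'Total' rows for the plant and line
    effects are set unions over the two per-biotype sets, not sums.
    """
    cand = set(candidate_ids)

    def de_set(tbl: pd.DataFrame) -> set:
        col = "is_de_final" if "is_de_final" in tbl.columns else "is_de"
        return set(tbl.index[tbl[col].fillna(False).astype(bool)])

    rows = []
    unions: dict[str, set] = {}
    for name, tbl in de_tables.items():
        s = de_set(tbl)
        rows.append((name, len(s), len(s & cand)))
        prefix = name.split("_")[0]
        unions.setdefault(prefix, set()).update(s)
    for prefix in ("plant", "line"):
        if prefix in unions and sum(n.startswith(prefix)
                                    for n in de_tables) > 1:
            s = unions[prefix]
            rows.append((f"{prefix}_total", len(s), len(s & cand)))
    return pd.DataFrame(rows, columns=["contrast", "n_de", "n_de_effector"])


def _newick(node, leaf_names: list[str]) -> str:
    if node.is_leaf():
        return leaf_names[node.id]
    left = _newick(node.get_left(), leaf_names)
    right = _newick(node.get_right(), leaf_names)
    bl = node.dist - node.get_left().dist
    br = node.dist - node.get_right().dist
    return f"({left}:{bl:.6g},{right}:{br:.6g})"


def export_expression_heatmap_matrix(
        cpm: pd.DataFrame, genes: pd.Index,
        catalog_df: pd.DataFrame | None = None,
        cnv_df: pd.DataFrame | None = None,
        prior: float = 0.5) -> tuple[pd.DataFrame, str | None]:
    """Clustered log-expression matrix for a gene-family heatmap.

    Average-linkage hierarchical clustering on Euclidean distances of the
    log2(CPM + prior) rows; rows are emitted in leaf order with DE class
    and coverage-ratio columns appended when available.  Returns (matrix,
    newick) — newick is None for a singleton input.
    """
    genes = pd.Index([g for g in genes if g in cpm.index])
    if len(genes) == 0:
        raise ValueError("no genes to export")
    mat = np.log2(cpm.loc[genes] + prior)
    newick = None
    order = np.arange(len(genes))
    if len(genes) >= 2:
        z = linkage(mat.to_numpy(), method="average", metric="euclidean")
        tree = to_tree(z)
        order = tree.pre_order(lambda n: n.id)
        newick = _newick(tree, list(genes)) + ";"
    out = mat.iloc[order].copy()
    if catalog_df is not None and "biotype_class" in catalog_df.columns:
        out["biotype_class"] = catalog_df["biotype_class"].reindex(out.index)
    if cnv_df is not None and "ratio" in cnv_df.columns:
        out["coverage_ratio"] = cnv_df["ratio"].reindex(out.index)
    return out, newick


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest."""
    inp = Path(config.input_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    opts = config.de_options()
    written: list[Path] = []

    def emit_tsv(name: str, df: pd.DataFrame, index: bool = True) -> None:
        p = out / name
        _write_tsv(df, p, index=index)
        written.append(p)

    def emit_json(name: str, obj) -> None:
        p = out / name
        _write_json(obj, p)
        written.append(p)

    log.info("loading dataset from %s", inp)
    data = load_dataset_dir(inp)
    counts, design = data["counts"], data["design"]
    annotations = data["annotations"]

    # --- normalize -------------------------------------------------------
    factors = tmm_factors(counts)
    cpm = compute_cpm(counts, factors)
    emit_tsv("factors.tsv", factors.to_frame())
    emit_tsv("cpm.tsv", cpm)

    # --- QC: MDS on head samples, nearest-centroid outlier flags ---------
    heads = design[design["organ"] == "head"]
    head_ids = heads["sample_id"].tolist()
    head_cpm_all = compute_cpm(counts[head_ids], tmm_factors(counts[head_ids]))
    expressed_heads = filter_expressed(head_cpm_all, config.min_cpm,
                                       min(config.min_libraries,
                                           len(head_ids)))
    emb = mds_embedding(head_cpm_all.loc[expressed_heads],
                        n_top=config.mds_top_genes)
    flags = flag_outlier_samples(emb, heads.set_index("sample_id")["biotype"])
    emit_tsv("mds.tsv", emb)
    emit_tsv("qc_flags.tsv",
             pd.DataFrame({"sample_id": flags, "flag": "outlier"}),
             index=False)
    if flags:
        log.warning("removing %d outlier head sample(s): %s",
                    len(flags), flags)
    keep_heads = [s for s in head_ids if s not in set(flags)]
    design_used = design[(design["organ"] != "head")
                         | design["sample_id"].isin(keep_heads)]

    # --- working set over all conditions ---------------------------------
    cond = design_used.set_index("sample_id").apply(
        lambda r: f"{r['line']}|{r['organ']}|{r['plant']}", axis=1)
    used_cols = [s for s in counts.columns if s in set(design_used["sample_id"])]
    ws = working_set(cpm[used_cols], cond.reindex(used_cols), config.min_cpm)
    emit_tsv("working_set.tsv", pd.DataFrame(index=ws), index=True)

    # --- organ contrasts (SG vs AT per reference line) -------------------
    ref_lines = [l for l in REFERENCE_LINES
                 if (design_used["line"] == l).any()]
    organ_results: dict[str, pd.DataFrame] = {}
    organ_samples = design_used[design_used["organ"].isin(["SG", "AT"])]
    organ_cols = organ_samples["sample_id"].tolist()
    organ_cpm = compute_cpm(counts[organ_cols], tmm_factors(counts[organ_cols]))
    organ_universe = filter_expressed(
        organ_cpm, config.min_cpm, min(config.min_libraries, len(organ_cols)))
    for line in ref_lines:
        sg = organ_samples[(organ_samples["line"] == line)
                           & (organ_samples["organ"] == "SG")]["sample_id"]
        at = organ_samples[(organ_samples["line"] == line)
                           & (organ_samples["organ"] == "AT")]["sample_id"]
        res = two_group_de(counts.loc[organ_universe], sg.tolist(),
                           at.tolist(), options=opts)
        organ_results[line] = res
        emit_tsv(f"de_organ_{line}.tsv", res)

    # --- plant contrasts within biotype ----------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    head_universe = filter_expressed(
        head_cpm_all[keep_heads], config.min_cpm,
        min(config.min_libraries, len(keep_heads)))
    head_counts = counts.loc[head_universe]
    heads_used = design_used[design_used["organ"] == "head"]
    for biotype in ("alfalfa", "pea"):
        sub = heads_used[heads_used["biotype"] == biotype]
        ga = sub[sub["plant"] == "universal"]["sample_id"].tolist()
        gb = sub[sub["plant"] == "specific"]["sample_id"].tolist()
        disp_groups = sub.set_index("sample_id").apply(
            lambda r: f"{r['line']}|{r['plant']}", axis=1)
        res = two_group_de(head_counts, ga, gb, options=opts,
                           dispersion_groups=disp_groups)
        de_tables[f"plant_{biotype}"] = res
        emit_tsv(f"de_plant_{biotype}.tsv", res)

    # --- biotype contrast with t-filter ----------------------------------
    bio = biotype_de(head_counts, design_used, options=opts)
    de_tables["biotype"] = bio
    emit_tsv("de_biotype.tsv", bio)

    # --- line contrasts within biotype ------------------------------------
    for biotype in ("alfalfa", "pea"):
        res = line_effect(head_counts, design_used, biotype, options=opts)
        de_tables[f"line_{biotype}"] = res
        emit_tsv(f"de_line_{biotype}.tsv", res)

    # --- effector catalogue ------------------------------------------------
    sg_means = pd.DataFrame({
        line: organ_cpm.loc[:, organ_samples[
            (organ_samples["line"] == line)
            & (organ_samples["organ"] == "SG")]["sample_id"]].mean(axis=1)
        for line in ref_lines})
    catalog_df = cat.classify_candidates(sg_means, annotations,
                                         config.min_cpm)
    catalog_df = cat.sg_upregulated_union(catalog_df, organ_results)
    catalog_df = cat.assign_biotype_class(catalog_df, bio)
    summary = cat.catalog_summary(catalog_df)
    emit_tsv("catalog.tsv", catalog_df)
    emit_json("summary.json", summary)

    cand_ids = catalog_df.index[catalog_df["is_candidate"]]

    # --- head/SG concordance per reference line ---------------------------
    concordance = {}
    for line in ref_lines:
        head_cols = heads_used[(heads_used["line"] == line)
                               & (heads_used["plant"] == "universal")][
                                   "sample_id"].tolist() or \
            heads_used[heads_used["line"] == line]["sample_id"].tolist()
        line_cands = catalog_df.index[
            catalog_df["is_candidate"]
            & catalog_df[f"sg_expressed_{line}"]]
        if len(line_cands) == 0:
            continue
        rho, det = cat.head_sg_concordance(
            sg_means[line], head_cpm_all[head_cols].mean(axis=1), line_cands,
            config.min_cpm)
        concordance[line] = {"spearman_rho": rho, "detection_fraction": det}
    emit_json("concordance.json", concordance)

    # --- enrichment --------------------------------------------------------
    subsets = {k: catalog_df.index[catalog_df["biotype_class"] == k]
               for k in ("alfalfa_up", "pea_up", "non_de")}
    background = ws.difference(cand_ids)
    enrich_tbl = enr.orthology_proportion_tests(
        annotations, {k: v for k, v in subsets.items() if len(v)}, background)
    emit_tsv("enrichment.tsv", enrich_tbl, index=False)

    dup = annotations["is_duplicated"].astype(bool)
    observed = {k: int(dup.reindex(v).sum()) for k, v in subsets.items()}
    res_ci = enr.duplication_resampling_ci(
        cand_ids, dup, {k: len(v) for k, v in subsets.items()}, observed,
        n_reps=config.n_resample_reps, seed=config.seed)
    emit_json("resampling.json",
              {k: dataclasses.asdict(v) for k, v in res_ci.items()})

    if "fecundity" in data:
        fec = enr.fecundity_tests(data["fecundity"])
        emit_tsv("fecundity_tests.tsv", fec, index=False)

    # --- CNV ---------------------------------------------------------------
    pools = data["pools"]
    num, den = config.numerator_pool, config.denominator_pool
    if num in pools and den in pools:
        cnv_df = cnvmod.cnv_table(pools[num], pools[den], num, den)
        line_means = pd.DataFrame({
            line: head_cpm_all.loc[:, heads_used[
                heads_used["line"] == line]["sample_id"]].mean(axis=1)
            for line in heads_used["line"].unique()})
        biotype_of_line = dict(zip(design["line"], design["biotype"]))
        cnv_df["call"] = cnvmod.call_biotype_specific(
            cnv_df["ratio"], line_means, biotype_of_line, num,
            config.ratio_threshold, config.min_cpm)
        emit_tsv("cnv.tsv", cnv_df)
        tests = cnvmod.compare_subset_ratios(
            cnv_df["ratio"], catalog_df["biotype_class"])
        emit_json("cnv_tests.json",
                  json.loads(tests.to_json(orient="records")))
    else:
        cnv_df = None

    # --- contrast accounting table ----------------------------------------
    table1 = build_table1(de_tables, cand_ids)
    emit_tsv("table1.tsv", table1, index=False)

    # --- manifest ----------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {p.name: _sha256(p) for p in sorted(inp.glob("*"))
                   if p.is_file()},
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
        "n_working_set": int(len(ws)),
        "n_candidates": int(len(cand_ids)),
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
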