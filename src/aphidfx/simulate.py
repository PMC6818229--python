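"""Synthetic data generator for the effector-expression pipeline.

Emulates the post-mapping artefacts of a two-biotype pea aphid RNA-seq /
pool-seq study: gene x sample count matrices for a factorial head design
(2 biotypes x 3 lines x 2 host plants x replicates) plus salivary gland (SG)
and alimentary tract (AT) libraries for the two reference lines, per-gene
secretion / orthology / duplication annotations, exon models, pool-seq
per-exon depth tracks for the two biotype pools, and fecundity assays.

Counts are negative binomial with variance mu + phi * mu^2 (the edgeR
mean/dispersion convention), with planted organ, biotype, plant, line and
copy-number effects recorded in a ground-truth table for parameter-recovery
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "PlantedSet",
    "SimulationConfig",
    "Dataset",
    "ALFALFA_LINES",
    "PEA_LINES",
    "REFERENCE_LINES",
    "simulate_design",
    "simulate_counts",
    "simulate_annotations",
    "simulate_pool_coverage",
    "simulate_fecundity",
    "simulate_all",
    "write_dataset",
]

ALFALFA_LINES = ("LSR1", "LL01", "L84")
PEA_LINES = ("P123", "ArPo58", "S1PS02")
#: reference lines with dissected-organ (SG/AT) libraries: one per biotype
REFERENCE_LINES = ("LSR1", "P123")

BIOTYPE_OF_LINE = {**{l: "alfalfa" for l in ALFALFA_LINES},
                   **{l: "pea" for l in PEA_LINES}}


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass(frozen=True)
class PlantedSet:
    """A planted effect: how many genes carry it and its size.

    ``effect`` is a log2 fold change for expression effects and a copy
    ratio (pea relative to alfalfa) for the CNV effects.
    """

    n_genes: int
    effect: float


def _default_planted_sets() -> dict[str, PlantedSet]:
    # Scaled to a 2,000-gene desk genome, mirroring the study's ratios:
    # roughly a quarter of genes secreted, ~4% of effectors biotype-DE,
    # organ effects common, plant effects rare, a handful of CNVs.
    return {
        "organ_up_per_line": PlantedSet(150, 2.0),
        "biotype_alfalfa_up": PlantedSet(25, 2.0),
        "biotype_pea_up": PlantedSet(18, 2.0),
        "plant_effect": PlantedSet(8, 1.5),
        "line_effect": PlantedSet(40, 2.0),
        "cnv_deletion": PlantedSet(10, 0.5),
        "cnv_duplication": PlantedSet(10, 2.0),
    }


_EXPRESSION_SETS = ("organ_up_per_line", "biotype_alfalfa_up",
                    "biotype_pea_up", "plant_effect", "line_effect")
_CNV_SETS = ("cnv_deletion", "cnv_duplication")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the study design as defaults.

    Parameters
    ----------
    n_genes : total genes in the synthetic genome.
    n_reps_per_condition : biological replicates per condition (study: 3).
    baseline_log_mean_range : range (log2 scale) of per-gene baseline
        relative-abundance weights; spans lowly to highly expressed genes.
    dispersion : NB dispersion phi, variance = mu + phi mu^2.
    frac_secreted : marginal fraction of genes predicted secreted.
    frac_duplicated : marginal fraction of genes with >=1 paralogue.
    orthology_category_labels : ordered category labels; the last one is
        treated as the aphid lineage-specific level.
    planted_sets : effect name -> (gene count, effect size).
    duplication_enrichment : multiplier on the duplication frequency inside
        the planted biotype-DE sets (1 = no enrichment).
    lineage_enrichment : same for the lineage-specific orthology category.
    planted_secreted : force planted organ/biotype/CNV genes to be secreted
        so they enter the candidate catalogue.
    library_size_range : per-sample library sizes, drawn log-uniform.
    base_depth : pool-seq mean exon depth at copy ratio 1 (study: >110X).
    coverage_noise_cv : coefficient of variation of multiplicative gamma
        noise on exon depths (0 = noiseless).
    fecundity_* : NB means for matched / mismatched host-plant assays and
        their dispersion; 12 test plants per condition as in the assays.
    """

    n_genes: int = 2000
    n_reps_per_condition: int = 3
    baseline_log_mean_range: tuple[float, float] = (-4.0, 4.0)
    dispersion: float = 0.1
    frac_secreted: float = 0.27
    frac_duplicated: float = 0.30
    orthology_category_labels: tuple[str, ...] = (
        "conserved_metazoa", "conserved_insecta", "aphid_lineage_specific")
    planted_sets: dict[str, PlantedSet] = field(
        default_factory=_default_planted_sets)
    duplication_enrichment: float = 2.0
    lineage_enrichment: float = 2.0
    planted_secreted: bool = True
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    base_depth: float = 110.0
    coverage_noise_cv: float = 0.1
    fecundity_matched_mean: float = 80.0
    fecundity_mismatched_mean: float = 2.0
    fecundity_dispersion: float = 0.2
    n_fecundity_reps: int = 12
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_reps_per_condition < 1:
            raise ConfigError("n_reps_per_condition must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be nonnegative")
        for name, frac in (("frac_secreted", self.frac_secreted),
                           ("frac_duplicated", self.frac_duplicated)):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must be positive and ordered")
        unknown = set(self.planted_sets) - set(_EXPRESSION_SETS + _CNV_SETS)
        if unknown:
            raise ConfigError(f"unknown planted sets: {sorted(unknown)}")
        total = sum(ps.n_genes for ps in self.planted_sets.values())
        total += self.planted_sets.get(
            "organ_up_per_line", PlantedSet(0, 0)).n_genes  # one set per line
        if total > self.n_genes:
            raise ConfigError("planted sets exceed n_genes")
        for name in _CNV_SETS:
            if name in self.planted_sets and self.planted_sets[name].effect < 0:
                raise ConfigError("copy ratios must be >= 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

def simulate_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet for the factorial design.

    Head samples for the 6 lines x 2 host plants x replicates, plus SG and
    AT libraries (universal host) for the two reference lines.
    """
    config.validate()
    rows = []
    for line in ALFALFA_LINES + PEA_LINES:
        for plant in ("universal", "specific"):
            for rep in range(1, config.n_reps_per_condition + 1):
                rows.append((f"{line}_head_{plant}_r{rep}", line,
                             BIOTYPE_OF_LINE[line], "head", plant, rep))
    for line in REFERENCE_LINES:
        for organ in ("SG", "AT"):
            for rep in range(1, config.n_reps_per_condition + 1):
                rows.append((f"{line}_{organ}_r{rep}", line,
                             BIOTYPE_OF_LINE[line], organ, "universal", rep))
    design = pd.DataFrame(
        rows, columns=["sample_id", "line", "biotype", "organ", "plant",
                       "replicate"])
    if design["sample_id"].duplicated().any():  # pragma: no cover
        raise AssertionError("sample ids must be unique")
    return design


# ---------------------------------------------------------------------------
# counts + planted truth
# ---------------------------------------------------------------------------

def _assign_planted_genes(config: SimulationConfig,
                          rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Disjoint gene index sets for every planted effect."""
    sizes: list[tuple[str, int]] = []
    for name in _EXPRESSION_SETS + _CNV_SETS:
        ps = config.planted_sets.get(name)
        if ps is None or ps.n_genes == 0:
            continue
        if name == "organ_up_per_line":
            for line in REFERENCE_LINES:
                sizes.append((f"organ_up_{line}", ps.n_genes))
        else:
            sizes.append((name, ps.n_genes))
    total = sum(k for _, k in sizes)
    pool = rng.choice(config.n_genes, size=total, replace=False)
    out, cursor = {}, 0
    for name, k in sizes:
        out[name] = np.sort(pool[cursor:cursor + k])
        cursor += k
    return out


def simulate_counts(config: SimulationConfig,
                    design: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB counts with planted effects; returns (counts, truth).

    Counts: genes x samples DataFrame indexed by gene_id. Truth: one row
    per gene recording every planted membership and effect size, plus the
    true copy ratio per pool (CNV effects are planted in the pea pool, so
    the pea/alfalfa ratio equals the planted copy ratio; expression of CNV
    genes in pea-biotype samples is scaled by the same ratio).
    """
    config.validate()
    rng = _rng(config, 1)
    n, samples = config.n_genes, design["sample_id"].to_numpy()

    lo, hi = config.baseline_log_mean_range
    base_weight = 2.0 ** rng.uniform(lo, hi, size=n)
    rel_abundance = base_weight / base_weight.sum()

    lo_l, hi_l = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lo_l), np.log(hi_l), size=len(samples)))

    planted = _assign_planted_genes(config, rng)
    mult = np.ones((n, len(samples)))
    truth = pd.DataFrame({"gene_id": _gene_ids(n)})
    truth["organ_up_line"] = ""
    truth["organ_up_lfc"] = 0.0
    truth["biotype_up"] = ""
    truth["biotype_lfc"] = 0.0
    truth["plant_lfc"] = 0.0
    truth["line_effect_line"] = ""
    truth["line_lfc"] = 0.0
    truth["copy_ratio_pea"] = 1.0
    truth["copy_ratio_alfalfa"] = 1.0
    truth["baseline_weight"] = base_weight

    organ = design["organ"].to_numpy()
    line = design["line"].to_numpy()
    biotype = design["biotype"].to_numpy()
    plant = design["plant"].to_numpy()

    for ref_line in REFERENCE_LINES:
        key = f"organ_up_{ref_line}"
        if key not in planted:
            continue
        lfc = config.planted_sets["organ_up_per_line"].effect
        cols = (organ == "SG") & (line == ref_line)
        mult[np.ix_(planted[key], np.flatnonzero(cols))] *= 2.0 ** lfc
        truth.loc[planted[key], "organ_up_line"] = ref_line
        truth.loc[planted[key], "organ_up_lfc"] = lfc

    for name, bt in (("biotype_alfalfa_up", "alfalfa"),
                     ("biotype_pea_up", "pea")):
        if name not in planted:
            continue
        lfc = config.planted_sets[name].effect
        cols = np.flatnonzero(biotype == bt)
        mult[np.ix_(planted[name], cols)] *= 2.0 ** lfc
        truth.loc[planted[name], "biotype_up"] = bt
        truth.loc[planted[name], "biotype_lfc"] = lfc

    if "plant_effect" in planted:
        lfc = config.planted_sets["plant_effect"].effect
        cols = np.flatnonzero((plant == "universal") & (organ == "head"))
        mult[np.ix_(planted["plant_effect"], cols)] *= 2.0 ** lfc
        truth.loc[planted["plant_effect"], "plant_lfc"] = lfc

    if "line_effect" in planted:
        lfc = config.planted_sets["line_effect"].effect
        all_lines = ALFALFA_LINES + PEA_LINES
        for j, g in enumerate(planted["line_effect"]):
            target = all_lines[j % len(all_lines)]
            cols = np.flatnonzero(line == target)
            mult[g, cols] *= 2.0 ** lfc
            truth.loc[g, "line_effect_line"] = target
            truth.loc[g, "line_lfc"] = lfc

    for name in _CNV_SETS:
        if name not in planted:
            continue
        ratio = config.planted_sets[name].effect
        cols = np.flatnonzero(biotype == "pea")
        mult[np.ix_(planted[name], cols)] *= ratio
        truth.loc[planted[name], "copy_ratio_pea"] = ratio

    mean = rel_abundance[:, None] * mult * lib[None, :]
    if config.dispersion == 0:
        counts = rng.poisson(mean)
    else:
        size = 1.0 / config.dispersion
        p = size / (size + mean)
        counts = np.where(mean > 0, rng.negative_binomial(size, np.clip(p, 1e-12, 1.0)), 0)
    counts_df = pd.DataFrame(counts, index=pd.Index(_gene_ids(n), name="gene_id"),
                             columns=samples)
    return counts_df, truth.set_index("gene_id")


# ---------------------------------------------------------------------------
# annotations + exon models
# ---------------------------------------------------------------------------

def simulate_annotations(
        config: SimulationConfig,
        truth: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene annotation flags and exon models.

    Returns ``(annotations, exons)``. Secretion, orthology and duplication
    flags emulate the outputs of secretome prediction and ortholog-group
    analysis that the real pipeline consumes; planted DE sets can be
    enriched for duplicated and lineage-specific genes.
    """
    config.validate()
    rng = _rng(config, 2)
    n = config.n_genes
    ids = _gene_ids(n)

    forced = np.zeros(n, dtype=bool)
    if config.planted_secreted:
        forced = ((truth["organ_up_line"] != "")
                  | (truth["biotype_up"] != "")
                  | (truth["copy_ratio_pea"] != 1.0)).to_numpy()
    n_forced = int(forced.sum())
    target = config.frac_secreted * n
    p_rest = 0.0 if n == n_forced else np.clip(
        (target - n_forced) / (n - n_forced), 0.0, 1.0)
    secreted = forced | (rng.random(n) < p_rest)
    if config.frac_secreted >= 1.0:
        secreted[:] = True

    de_planted = (truth["biotype_up"] != "").to_numpy()
    p_dup = np.full(n, config.frac_duplicated)
    p_dup[de_planted] = np.clip(
        config.frac_duplicated * config.duplication_enrichment, 0.0, 1.0)
    duplicated = rng.random(n) < p_dup

    cats = list(config.orthology_category_labels)
    base_p = np.full(len(cats), 1.0 / len(cats))
    enr_p = base_p.copy()
    enr_p[-1] = min(1.0, base_p[-1] * config.lineage_enrichment)
    if enr_p[:-1].sum() > 0:
        enr_p[:-1] *= (1.0 - enr_p[-1]) / enr_p[:-1].sum()
    u = rng.random(n)
    cat_idx = np.empty(n, dtype=int)
    for mask, probs in ((~de_planted, base_p), (de_planted, enr_p)):
        cum = np.cumsum(probs)
        cat_idx[mask] = np.searchsorted(cum, u[mask], side="right").clip(
            0, len(cats) - 1)

    annotations = pd.DataFrame({
        "gene_id": ids,
        "is_secreted": secreted,
        "orthology_category": [cats[i] for i in cat_idx],
        "is_duplicated": duplicated,
    }).set_index("gene_id")

    # exon models: genes laid head-to-tail on 4 chromosomes, BED half-open
    rows = []
    cursors = {f"chr{c}": 0 for c in range(1, 5)}
    for i, gid in enumerate(ids):
        chrom = f"chr{(i % 4) + 1}"
        pos = cursors[chrom] + int(rng.integers(200, 2000))
        for _ in range(int(rng.integers(1, 11))):
            length = int(rng.integers(100, 1001))
            rows.append((chrom, pos, pos + length, gid))
            pos += length + int(rng.integers(50, 501))
        cursors[chrom] = pos
    exons = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    return annotations, exons


# ---------------------------------------------------------------------------
# pool-seq exon depth tracks
# ---------------------------------------------------------------------------

def simulate_pool_coverage(config: SimulationConfig, exons: pd.DataFrame,
                           truth: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-exon mean depth for the pea and alfalfa pools.

    Depth = base_depth x the gene's true copy ratio in that pool x
    multiplicative gamma noise with the configured CV (mean 1), the shape
    coverageBed's mean output takes after pool-seq mapping.
    """
    config.validate()
    rng = _rng(config, 3)
    out = {}
    for pool in ("pea", "alfalfa"):
        ratio = truth.loc[exons["gene_id"], f"copy_ratio_{pool}"].to_numpy()
        depth = config.base_depth * ratio
        cv = config.coverage_noise_cv
        if cv > 0:
            shape = 1.0 / cv**2
            depth = depth * rng.gamma(shape, 1.0 / shape, size=len(depth))
        table = exons.copy()
        table["mean_depth"] = depth
        out[pool] = table
    return out


# ---------------------------------------------------------------------------
# fecundity assays
# ---------------------------------------------------------------------------

def simulate_fecundity(config: SimulationConfig) -> pd.DataFrame:
    """Offspring counts per (line, test plant, replicate).

    High NB mean on the universal host and on the biotype's own host plant,
    low mean on the mismatched host; 12 test plants per condition.
    """
    config.validate()
    rng = _rng(config, 4)
    own_host = {"alfalfa": "Ms", "pea": "Ps"}
    rows = []
    for line in ALFALFA_LINES + PEA_LINES:
        bt = BIOTYPE_OF_LINE[line]
        for plant in ("Vf", "Ms", "Ps"):
            matched = plant == "Vf" or plant == own_host[bt]
            mean = (config.fecundity_matched_mean if matched
                    else config.fecundity_mismatched_mean)
            size = 1.0 / max(config.fecundity_dispersion, 1e-9)
            counts = rng.negative_binomial(
                size, size / (size + mean), size=config.n_fecundity_reps)
            for rep, c in enumerate(counts, start=1):
                rows.append((line, plant, rep, int(c)))
    return pd.DataFrame(rows, columns=["line", "plant", "replicate",
                                       "nymph_count"])


# ---------------------------------------------------------------------------
# bundle + on-disk dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    config: SimulationConfig
    design: pd.DataFrame
    counts: pd.DataFrame
    truth: pd.DataFrame
    annotations: pd.DataFrame
    exons: pd.DataFrame
    pool_depths: dict[str, pd.DataFrame]
    fecundity: pd.DataFrame


def simulate_all(config: SimulationConfig) -> Dataset:
    """Run every generator stage under one config/seed."""
    design = simulate_design(config)
    counts, truth = simulate_counts(config, design)
    annotations, exons = simulate_annotations(config, truth)
    pools = simulate_pool_coverage(config, exons, truth)
    fecundity = simulate_fecundity(config)
    return Dataset(config, design, counts, truth, annotations, exons, pools,
                   fecundity)


def write_dataset(ds: Dataset, out_dir) -> dict[str, str]:
    """Write the standard flat-file layout; returns name -> path."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _tsv(name: str, df: pd.DataFrame, index: bool) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=index, float_format="%.6g")
        paths[name] = str(p)

    _tsv("counts.tsv", ds.counts, index=True)
    _tsv("samples.tsv", ds.design, index=False)
    _tsv("annotations.tsv", ds.annotations, index=True)
    _tsv("truth.tsv", ds.truth, index=True)
    _tsv("fecundity.tsv", ds.fecundity, index=False)
    bed = out / "exons.bed"
    ds.exons.to_csv(bed, sep="\t", index=False, header=False)
    paths["exons.bed"] = str(bed)
    for pool, table in ds.pool_depths.items():
        _tsv(f"pool_{pool}_exon_depth.tsv", table, index=False)
    return paths
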