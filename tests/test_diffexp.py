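import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from aphidfx import (DEOptions, SimulationConfig, bh_fdr, biotype_de,
                     biotype_de_filter, call_de, estimate_common_dispersion,
                     fold_change, line_effect, nb_test, simulate_all,
                     two_group_de)
from aphidfx.simulate import PlantedSet
from conftest import nb_counts


def brute_force_bh(p):
    """Independent step-up: sort, scale by m/rank, cummin from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


class TestDispersion:
    def test_poisson_data_gives_near_zero(self, rng):
        counts = nb_counts(rng, 2000, [9e5] * 6, phi=0.0)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
        assert estimate_common_dispersion(counts, groups) <= 0.05

    def test_recovers_planted_dispersion(self, rng):
        counts = nb_counts(rng, 2000, rng.uniform(8e5, 1.2e6, 6), phi=0.2)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
        est = estimate_common_dispersion(counts, groups)
        assert 0.15 <= est <= 0.25

    def test_stable_under_duplication(self, rng):
        counts = nb_counts(rng, 800, [1e6] * 6, phi=0.15)
        dup = pd.concat([counts, counts.add_suffix("_dup")], axis=1)
        g1 = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
        g2 = pd.Series((["a"] * 3 + ["b"] * 3) * 2, index=dup.columns)
        e1 = estimate_common_dispersion(counts, g1)
        e2 = estimate_common_dispersion(dup, g2)
        assert abs(e2 - e1) / e1 < 0.2

    def test_no_replication_rejected(self, rng):
        counts = nb_counts(rng, 50, [1e6, 1e6], phi=0.1)
        groups = pd.Series(["a", "b"], index=counts.columns)
        with pytest.raises(ValueError, match="dispersion"):
            estimate_common_dispersion(counts, groups)


class TestNBTest:
    def test_identical_groups_not_significant(self):
        counts = pd.DataFrame([[10, 12, 9, 10, 12, 9]] * 3,
                              columns=[f"s{i}" for i in range(6)],
                              index=list("abc"))
        eff = pd.Series(1e6, index=counts.columns)
        res = nb_test(counts, eff, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
                      0.1)
        assert (res["p_value"] >= 0.9).all()

    def test_planted_fourfold_gene_detected(self, rng):
        mult = np.ones((500, 6))
        mult[:20, :3] = 4.0
        counts = nb_counts(rng, 500, [1e6] * 6, phi=0.05, multipliers=mult,
                           log2_weight_range=(1.0, 6.0))
        eff = counts.sum(axis=0).astype(float)
        res = nb_test(counts, eff, list(counts.columns[:3]),
                      list(counts.columns[3:]), 0.05)
        assert (res["p_value"].iloc[:20] < 0.01).mean() >= 0.9

    def test_type_i_error_calibration(self, rng):
        # 5,000 null genes, phi = 0.1, 3 vs 3, nominal 0.05
        counts = nb_counts(rng, 5000, rng.uniform(8e5, 1.2e6, 6), phi=0.1)
        eff = counts.sum(axis=0).astype(float)
        res = nb_test(counts, eff, list(counts.columns[:3]),
                      list(counts.columns[3:]), 0.1)
        expressed = counts.sum(axis=1) > 0
        rate = (res.loc[expressed, "p_value"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_group_swap_preserves_p_values(self, rng):
        counts = nb_counts(rng, 300, [1e6] * 6, phi=0.1)
        eff = counts.sum(axis=0).astype(float)
        a, b = list(counts.columns[:3]), list(counts.columns[3:])
        r1 = nb_test(counts, eff, a, b, 0.1)
        r2 = nb_test(counts, eff, b, a, 0.1)
        assert np.allclose(r1["p_value"], r2["p_value"], atol=1e-8)


class TestFoldChange:
    def test_threshold_boundary_case(self):
        assert fold_change(30.0, 20.0, prior=0.0) == pytest.approx(1.5)

    def test_equal_means_give_one(self):
        assert fold_change(7.0, 7.0, prior=0.5) == pytest.approx(1.0)
        assert fold_change(0.0, 0.0, prior=0.5) == pytest.approx(1.0)

    def test_direction(self):
        assert fold_change(2.0, 8.0, prior=0.0) == pytest.approx(0.25)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1.0, 2.0)


class TestBH:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], brute_force_bh([0.01, 0.5]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force(self, ps):
        assert np.allclose(bh_fdr(ps), brute_force_bh(ps), atol=1e-12)


class TestCallDE:
    def _row(self, **kw):
        base = dict(mean_cpm_a=5.0, mean_cpm_b=2.0, fc=1.6, fdr=0.04)
        base.update(kw)
        return pd.DataFrame([base])

    def test_default_threshold_rules(self):
        assert call_de(self._row()).iloc[0]
        assert not call_de(self._row(fdr=0.2)).iloc[0]
        assert not call_de(self._row(fc=1.4)).iloc[0]

    def test_downregulated_direction_counts(self):
        assert call_de(self._row(fc=0.5)).iloc[0]

    def test_expression_gate_overrides_significance(self):
        row = self._row(mean_cpm_a=0.5, mean_cpm_b=0.8, fdr=1e-30, fc=10.0)
        assert not call_de(row).iloc[0]

    def test_monotone_in_thresholds(self, rng):
        tbl = pd.DataFrame({
            "mean_cpm_a": rng.uniform(0, 10, 200),
            "mean_cpm_b": rng.uniform(0, 10, 200),
            "fc": rng.uniform(0.2, 5, 200),
            "fdr": rng.uniform(0, 1, 200)})
        loose = call_de(tbl, fdr_threshold=0.2)
        tight = call_de(tbl, fdr_threshold=0.01)
        assert (tight <= loose).all()
        wide_fc = call_de(tbl, fc_threshold=1.2)
        narrow_fc = call_de(tbl, fc_threshold=2.0)
        assert (narrow_fc <= wide_fc).all()


class TestBiotypeFilter:
    def test_hand_computed_separated_triples(self):
        a = pd.DataFrame([[10.0, 11.0, 9.0]])
        b = pd.DataFrame([[2.0, 2.5, 1.5]])
        res = biotype_de_filter(a, b)
        # pooled t by hand: sp2 = (2 + 0.5)/4, se = sqrt(sp2 * 2/3)
        assert res["t_stat"].iloc[0] == pytest.approx(8.0 / np.sqrt(2.5 / 4 * 2 / 3))
        assert res["t_p"].iloc[0] < 0.001
        assert res["t_pass"].iloc[0]

    def test_high_intra_biotype_variability_excluded(self):
        a = pd.DataFrame([[1.0, 20.0, 2.0]])
        b = pd.DataFrame([[3.0, 4.0, 5.0]])
        res = biotype_de_filter(a, b)
        assert res["t_p"].iloc[0] > 0.05
        assert not res["t_pass"].iloc[0]

    def test_identical_triples_excluded(self):
        a = pd.DataFrame([[3.0, 3.0, 3.0]])
        res = biotype_de_filter(a, a.copy())
        assert res["t_p"].iloc[0] == 1.0

    def test_zero_variance_unequal_means(self):
        a = pd.DataFrame([[3.0, 3.0, 3.0]])
        b = pd.DataFrame([[5.0, 5.0, 5.0]])
        assert biotype_de_filter(a, b)["t_p"].iloc[0] == 0.0


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(
        n_genes=2000, dispersion=0.1, seed=7,
        planted_sets={"biotype_alfalfa_up": PlantedSet(50, 2.0),
                      "biotype_pea_up": PlantedSet(50, 2.0),
                      "line_effect": PlantedSet(40, 3.0)})
    return simulate_all(cfg)


class TestAssembledContrasts:

    def test_biotype_procedure_recovers_planted_genes(self, planted):
        ds = planted
        heads = ds.design[(ds.design["organ"] == "head")
                          & (ds.design["plant"] == "universal")]
        res = biotype_de(ds.counts[heads["sample_id"].tolist()], heads)
        truth_de = ds.truth["biotype_up"] != ""
        called = res["is_de_final"]
        sens = (called & truth_de).sum() / truth_de.sum()
        fdr = (called & ~truth_de).sum() / max(int(called.sum()), 1)
        assert sens >= 0.8
        assert fdr <= 0.1

    def test_direction_of_fc(self, planted):
        ds = planted
        heads = ds.design[(ds.design["organ"] == "head")
                          & (ds.design["plant"] == "universal")]
        res = biotype_de(ds.counts[heads["sample_id"].tolist()], heads)
        alf = ds.truth.index[ds.truth["biotype_up"] == "alfalfa"]
        pea = ds.truth.index[ds.truth["biotype_up"] == "pea"]
        assert (res.loc[alf, "fc"] > 1).mean() > 0.95
        assert (res.loc[pea, "fc"] < 1).mean() > 0.95

    def test_t_filter_removes_single_line_artifacts(self, planted):
        ds = planted
        heads = ds.design[(ds.design["organ"] == "head")
                          & (ds.design["plant"] == "universal")]
        res = biotype_de(ds.counts[heads["sample_id"].tolist()], heads)
        var_genes = ds.truth["line_effect_line"] != ""
        nb_called = res["is_de"] & var_genes
        if nb_called.sum() > 0:
            excluded = (nb_called & ~res["t_pass"]).sum() / nb_called.sum()
            assert excluded >= 0.8

    def test_line_effect_flags_planted_line_genes(self, planted):
        ds = planted
        # planted single-line 8-fold genes should be caught by at least one
        # pairwise within-biotype contrast
        res_a = line_effect(ds.counts, ds.design, "alfalfa")
        res_p = line_effect(ds.counts, ds.design, "pea")
        flagged = res_a["is_de"] | res_p["is_de"]
        var_genes = ds.truth.index[ds.truth["line_effect_line"] != ""]
        assert flagged.loc[var_genes].mean() >= 0.9

    def test_two_group_symmetry(self, planted):
        ds = planted
        heads = ds.design[(ds.design["organ"] == "head")
                          & (ds.design["plant"] == "universal")]
        ga = heads[heads["biotype"] == "alfalfa"]["sample_id"].tolist()
        gb = heads[heads["biotype"] == "pea"]["sample_id"].tolist()
        counts = ds.counts[ga + gb]
        r1 = two_group_de(counts, ga, gb, dispersion=0.1)
        r2 = two_group_de(counts, gb, ga, dispersion=0.1)
        assert np.allclose(r1["fc"], 1.0 / r2["fc"], rtol=1e-9)
        assert np.allclose(r1["p_value"], r2["p_value"], atol=1e-9)

    def test_null_data_type_i_control_through_gates(self, rng):
        counts = nb_counts(rng, 3000, rng.uniform(8e5, 1.2e6, 6), phi=0.1)
        a, b = list(counts.columns[:3]), list(counts.columns[3:])
        res = two_group_de(counts, a, b)
        frac = res["is_de"].mean()
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert frac <= 0.05 + 3 * se
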