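"""Z-score essentiality: gene aggregation, null construction, scoring."""

import numpy as np
import pandas as pd
import pytest

from nutriscreen.core import (
    CountMatrix,
    DataValidationError,
    LibraryMap,
    normalize_log2_rpm,
)
from nutriscreen.crispr import (
    NullModel,
    build_null,
    differential_essentiality,
    filter_expressed,
    gene_level_lfc,
    score_crispr_screen,
    zscore_genes,
)
from nutriscreen.synth import simulate_crispr_screen


def _screen_from_arrays(ref, smp, genes, classes=None):
    elements = [f"e{i}" for i in range(len(ref))]
    counts = pd.DataFrame(
        {"ref": ref, "smp": smp}, index=pd.Index(elements, name="element_id")
    )
    meta = pd.DataFrame(
        {
            "condition": ["pre_swap", "uridine"],
            "replicate": [1, 1],
            "day": [0.0, 21.0],
            "role": ["pre_swap_reference", "screen"],
        },
        index=pd.Index(["ref", "smp"], name="sample_id"),
    )
    table = pd.DataFrame(
        {
            "gene": genes,
            "element_class": classes or ["targeting"] * len(genes),
        },
        index=pd.Index(elements, name="element_id"),
    )
    return CountMatrix(counts=counts, sample_meta=meta), LibraryMap(table=table)


class TestGeneLevelLfc:
    def test_mean_of_equal_sgrnas(self):
        # 4 sgRNAs halve in abundance (approximately, pseudocount aside)
        m, lib = _screen_from_arrays(
            [4000, 4000, 4000, 4000, 984000],
            [2000, 2000, 2000, 2000, 992000],
            ["A", "A", "A", "A", "FILL"],
        )
        norm = normalize_log2_rpm(m)
        out = gene_level_lfc(norm, lib, reference="ref", sample="smp")
        expected = np.log2(2000 / 1e6 * 1e6 + 1) - np.log2(4000 + 1)
        assert out["A"] == pytest.approx(expected, abs=1e-12)

    def test_mean_of_mixed_sgrnas(self):
        m, lib = _screen_from_arrays(
            [1000, 1000, 4000, 4000, 990000],
            [1000, 1000, 1000, 1000, 996000],
            ["B", "B", "B", "B", "FILL"],
        )
        norm = normalize_log2_rpm(m)
        out = gene_level_lfc(norm, lib, reference="ref", sample="smp")
        per_sg = [
            np.log2(1001) - np.log2(1001),
            np.log2(1001) - np.log2(1001),
            np.log2(1001) - np.log2(4001),
            np.log2(1001) - np.log2(4001),
        ]
        assert out["B"] == pytest.approx(np.mean(per_sg), abs=1e-12)

    def test_controls_aggregate_under_pseudo_gene(self):
        m, lib = _screen_from_arrays(
            [100, 100, 800],
            [100, 100, 800],
            ["A", "ctrlA", "ctrlA"],
            classes=["targeting", "control_noncutting", "control_noncutting"],
        )
        norm = normalize_log2_rpm(m)
        out = gene_level_lfc(norm, lib, reference="ref", sample="smp")
        assert set(out.index) == {"A", "control:ctrlA"}

    def test_unmapped_element_is_an_error(self):
        m, lib = _screen_from_arrays([10, 10], [10, 10], ["A", "A"])
        lib2 = LibraryMap(table=lib.table.iloc[:1])
        with pytest.raises(DataValidationError, match="missing from library"):
            gene_level_lfc(normalize_log2_rpm(m), lib2, reference="ref", sample="smp")


class TestFilterExpressed:
    expr = pd.Series({"low": -0.1, "edge": 0.0, "high": 3.0})

    def test_below_threshold_removed(self):
        assert "low" not in filter_expressed({"low", "high"}, self.expr)

    def test_exactly_zero_retained(self):
        assert "edge" in filter_expressed({"edge"}, self.expr)

    def test_absent_gene_removed(self):
        assert filter_expressed({"ghost"}, self.expr) == set()


class TestBuildNull:
    def test_hand_computed_statistics(self):
        lfcs = pd.Series({"a": 1.0, "b": 1.0, "c": 2.0})
        expr = pd.Series({"a": -3.0, "b": -2.0, "c": -1.0})
        null = build_null(lfcs, expr, k=3)
        vals = np.array([1.0, 1.0, 2.0])
        assert null.mu == pytest.approx(vals.mean())
        assert null.sigma == pytest.approx(vals.std(ddof=1))

    def test_expression_tie_breaks_lexicographically(self):
        lfcs = pd.Series({"zzz": 0.0, "aaa": 1.0, "mid": 2.0})
        expr = pd.Series({"zzz": -1.0, "aaa": -1.0, "mid": 5.0})
        null = build_null(lfcs, expr, k=2)
        assert null.member_genes == frozenset({"aaa", "zzz"})

    def test_degenerate_null_rejected(self):
        lfcs = pd.Series({"a": 1.0, "b": 1.0})
        expr = pd.Series({"a": -1.0, "b": -2.0})
        with pytest.raises(DataValidationError, match="degenerate"):
            build_null(lfcs, expr, k=2)

    def test_k_larger_than_pool_rejected(self):
        lfcs = pd.Series({"a": 1.0, "b": 2.0})
        expr = pd.Series({"a": -1.0, "b": -2.0})
        with pytest.raises(DataValidationError):
            build_null(lfcs, expr, k=3)


class TestZscore:
    def test_gene_at_null_mean_scores_zero(self):
        null = NullModel(member_genes=frozenset({"x"}), mu=0.5, sigma=2.0)
        z = zscore_genes(pd.Series({"g": 0.5}), null)
        assert z["g"] == 0.0

    def test_simple_null_arithmetic(self):
        # null members {-1, 0, 1}: mu 0, sample sd 1; gene at 2 scores z = 2
        lfcs = pd.Series({"n1": -1.0, "n2": 0.0, "n3": 1.0, "g": 2.0})
        expr = pd.Series({"n1": -3.0, "n2": -2.0, "n3": -1.0, "g": 4.0})
        null = build_null(lfcs, expr, k=3)
        z = zscore_genes(lfcs, null)
        assert z["g"] == pytest.approx(2.0)

    def test_null_members_self_normalize(self):
        rng = np.random.default_rng(7)
        lfcs = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        expr = pd.Series(rng.normal(size=50), index=lfcs.index)
        null = build_null(lfcs, expr, k=50)
        z = zscore_genes(lfcs, null)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12


class TestDifferentialEssentiality:
    def _table(self, z_glu, z_u):
        za = pd.Series({"g": z_glu})
        zb = pd.Series({"g": z_u})
        return differential_essentiality(za, zb).iloc[0]

    def test_neutral_gene(self):
        assert self._table(0.0, 0.0)["class"] == "neutral"

    def test_uridine_specific_essential(self):
        # dispensable in glucose, strongly depleted in uridine
        assert self._table(-0.2, -6.0)["class"] == "u_specific_essential"

    def test_glucose_specific_essential(self):
        assert self._table(-6.0, -0.2)["class"] == "glu_specific_essential"

    def test_shared_essential(self):
        assert self._table(-5.0, -4.0)["class"] == "shared_essential"

    def test_inner_join_on_differing_gene_sets(self):
        za = pd.Series({"a": 0.0, "b": -1.0})
        zb = pd.Series({"b": -2.0, "c": 1.0})
        out = differential_essentiality(za, zb)
        assert list(out["gene"]) == ["b"]


def _spreadsheet_pipeline(counts, meta, lib_table, expr, k):
    """Plain-arithmetic re-derivation of the whole scoring chain.

    Deliberately uses nothing from the package: normalization, per-gene
    means, replicate averaging, null statistics and z-scores are spelled
    out the way one would lay them out in a spreadsheet.
    """
    log2norm = {}
    for col in counts.columns:
        total = counts[col].sum()
        log2norm[col] = {
            e: np.log2(counts.loc[e, col] / total * 1e6 + 1) for e in counts.index
        }
    refs = {meta.loc[s, "replicate"]: s for s in meta.index
            if meta.loc[s, "role"] == "pre_swap_reference"}
    by_cond = {}
    for cond in ("glucose", "uridine"):
        screens = [s for s in meta.index
                   if meta.loc[s, "role"] == "screen" and meta.loc[s, "condition"] == cond]
        gene_lfcs = {}
        for s in screens:
            ref = refs[meta.loc[s, "replicate"]] if len(refs) > 1 else next(iter(refs.values()))
            per_gene = {}
            for e in counts.index:
                g = lib_table.loc[e, "gene"]
                if lib_table.loc[e, "element_class"] == "control_noncutting":
                    g = "control:" + g
                per_gene.setdefault(g, []).append(log2norm[s][e] - log2norm[ref][e])
            for g, vals in per_gene.items():
                gene_lfcs.setdefault(g, []).append(np.mean(vals))
        mean_lfc = {g: np.mean(v) for g, v in gene_lfcs.items()}
        with_expr = sorted(
            (g for g in mean_lfc if g in expr.index), key=lambda g: (expr[g], g)
        )
        members = with_expr[:k]
        vals = np.array([mean_lfc[g] for g in members])
        mu, sigma = vals.mean(), vals.std(ddof=1)
        by_cond[cond] = {g: (mean_lfc[g] - mu) / sigma for g in mean_lfc}
    return by_cond


def test_end_to_end_matches_spreadsheet_oracle():
    sim = simulate_crispr_screen(
        n_genes=30, n_noncutting=8, n_planted=4, depth=200.0,
        low_expr_fraction=0.3, seed=42,
    )
    k = 6
    result = score_crispr_screen(sim.counts, sim.library, sim.expression, null_k=k)
    oracle = _spreadsheet_pipeline(
        sim.counts.counts, sim.counts.sample_meta, sim.library.table, sim.expression, k
    )
    table = result.table.set_index("gene")
    for gene in table.index:
        assert table.loc[gene, "z_glucose"] == pytest.approx(oracle["glucose"][gene], abs=1e-10)
        assert table.loc[gene, "z_uridine"] == pytest.approx(oracle["uridine"][gene], abs=1e-10)
        dz = oracle["uridine"][gene] - oracle["glucose"][gene]
        assert table.loc[gene, "dz"] == pytest.approx(dz, abs=1e-10)


def test_null_self_consistency_both_modes(crispr_sim_small):
    sim = crispr_sim_small
    for mode in ("expression", "noncutting"):
        result = score_crispr_screen(sim.counts, sim.library, sim.expression, null_mode=mode)
        for cond, null in result.nulls.items():
            z = zscore_genes(result.mean_lfcs[cond].loc[sorted(null.member_genes)], null)
            assert abs(z.mean()) < 1e-12
            assert abs(z.std(ddof=1) - 1.0) < 1e-12


def test_shift_and_scale_equivariance(crispr_sim_small):
    sim = crispr_sim_small
    result = score_crispr_screen(sim.counts, sim.library, sim.expression)
    lfcs = result.mean_lfcs["uridine"]
    null = result.nulls["uridine"]
    z = zscore_genes(lfcs, null)

    from nutriscreen.crispr import build_null as _bn

    # adding a constant to every LFC leaves sigma alone and shifts no z
    # relative to another: all z move together by constant/sigma
    shifted = _bn(lfcs + 3.0, sim.expression, null.k)
    assert shifted.sigma == pytest.approx(null.sigma)
    z_shift = zscore_genes(lfcs + 3.0, shifted)
    assert np.allclose(z_shift - z, (z_shift - z).iloc[0])

    scaled = _bn(lfcs * 2.5, sim.expression, null.k)
    assert scaled.sigma == pytest.approx(2.5 * null.sigma)
    z_scaled = zscore_genes((lfcs * 2.5).loc[sorted(scaled.member_genes)], scaled)
    z_members = z.loc[sorted(null.member_genes)]
    assert np.allclose(z_scaled, z_members)


def test_planted_genes_dominate_negative_dz_tail():
    sim = simulate_crispr_screen(n_genes=400, n_planted=20, seed=2)
    result = score_crispr_screen(sim.counts, sim.library, sim.expression)
    table = result.table.set_index("gene")
    planted = set(sim.truth.loc[sim.truth["planted"], "gene"])
    tail = set(table["dz"].nsmallest(int(0.05 * 400)).index)
    assert len(tail & planted) / len(planted) >= 0.95
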