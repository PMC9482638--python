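"""CSS pipeline: normalization, LFC, blocklist, mode/RMSD scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmras import crispr
from mmras.utils import auroc


def _table(counts: dict, genes=None):
    n = len(next(iter(counts.values())))
    return pd.DataFrame(
        {
            "guide_id": [f"sg{i}" for i in range(n)],
            "gene": genes or [f"G{i}" for i in range(n)],
            **counts,
        }
    )


class TestSizeFactors:
    def test_identical_samples_equal_factors(self):
        t = _table({"a": [10, 100, 1000], "b": [10, 100, 1000]})
        f = crispr.size_factors(t)
        assert f["a"] == pytest.approx(f["b"])

    def test_doubled_sample_factor_ratio_two(self):
        t = _table({"a": [10, 100, 1000], "b": [20, 200, 2000]})
        f = crispr.size_factors(t)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_hand_computed_median_of_ratios(self):
        # guides (10,20),(100,200),(1000,2000): geomeans sqrt(200), sqrt(2e4),
        # sqrt(2e6); ratios a/geo = 1/sqrt(2) for all, b/geo = sqrt(2)
        t = _table({"a": [10, 100, 1000], "b": [20, 200, 2000]})
        f = crispr.size_factors(t)
        assert f["a"] == pytest.approx(1 / np.sqrt(2))
        assert f["b"] == pytest.approx(np.sqrt(2))

    def test_no_common_nonzero_guide_errors(self):
        t = _table({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(crispr.NormalizationError):
            crispr.size_factors(t)


class TestGuideLog2fc:
    def test_identity_gives_zero(self):
        t = _table({"n1": [10, 50], "d1": [10, 50]})
        lfc = crispr.guide_log2fc(t, ["n1"], ["d1"], pseudocount=0.0)
        np.testing.assert_allclose(lfc["lfc"], 0.0)

    def test_exact_log_ratio(self):
        # equal size factors (symmetric construction), pseudocount 0
        t = _table({"n1": [100, 25], "d1": [25, 100]})
        lfc = crispr.guide_log2fc(t, ["n1"], ["d1"], pseudocount=0.0)
        np.testing.assert_allclose(lfc["lfc"], [2.0, -2.0])

    def test_zero_counts_with_pseudocount(self):
        t = _table({"n1": [0, 100], "d1": [0, 100]})
        lfc = crispr.guide_log2fc(t, ["n1"], ["d1"], pseudocount=0.5)
        assert lfc["lfc"].iloc[0] == pytest.approx(0.0)

    def test_missing_group_errors(self):
        t = _table({"n1": [1, 2], "d1": [1, 2]})
        with pytest.raises(ValueError):
            crispr.guide_log2fc(t, ["n1"], ["nope"])


class TestBlocklist:
    def test_empty_blocklist_identity(self):
        g = pd.DataFrame({"guide_id": ["a", "b"], "gene": ["G1", "G1"], "lfc": [0.0, 1.0]})
        out, rep = crispr.apply_blocklist(g, set())
        pd.testing.assert_frame_equal(out, g)
        assert rep["n_removed"] == 0

    def test_whole_gene_removed_downstream(self):
        g = pd.DataFrame(
            {"guide_id": ["a", "b", "c"], "gene": ["G1", "G1", "G2"], "lfc": [0.0, 1.0, 2.0]}
        )
        out, _ = crispr.apply_blocklist(g, {"a", "b"})
        genes = crispr.gene_level_lfc(out)
        assert list(genes["gene"]) == ["G2"]

    def test_reported_fraction_matches_printed_counts(self):
        # a library of 77,441 guides with 9,919 blocklisted reports 13%
        g = pd.DataFrame(
            {"guide_id": [f"sg{i}" for i in range(77441)],
             "gene": "G", "lfc": 0.0}
        )
        bl = {f"sg{i}" for i in range(9919)}
        _, rep = crispr.apply_blocklist(g, bl)
        assert rep["n_removed"] == 9919
        assert round(100 * rep["fraction_removed"]) == 13

    def test_unknown_ids_reported_not_fatal(self):
        g = pd.DataFrame({"guide_id": ["a"], "gene": ["G1"], "lfc": [0.0]})
        out, rep = crispr.apply_blocklist(g, {"zzz"})
        assert rep["unknown_ids"] == ["zzz"]
        assert len(out) == 1

    def test_blocklisted_guides_never_influence_results(self, screen_data):
        counts, _ = screen_data
        bl = set(counts["guide_id"].iloc[::7])  # arbitrary subset
        num, den = ["day21_rep1", "day21_rep2"], ["day0_rep1", "day0_rep2"]
        via_blocklist = crispr.score_screen(counts, num, den, bl).genes
        prefiltered = counts[~counts["guide_id"].isin(bl)].reset_index(drop=True)
        direct = crispr.score_screen(prefiltered, num, den).genes
        pd.testing.assert_frame_equal(via_blocklist, direct)


class TestGeneLevelLfc:
    def test_plain_mean(self):
        g = pd.DataFrame({"guide_id": ["a", "b"], "gene": ["G1", "G1"], "lfc": [-1.0, -3.0]})
        out = crispr.gene_level_lfc(g)
        assert out["raw_lfc"].iloc[0] == pytest.approx(-2.0)
        assert out["n_guides_used"].iloc[0] == 2

    def test_single_guide_gene(self):
        g = pd.DataFrame({"guide_id": ["a"], "gene": ["G1"], "lfc": [0.7]})
        assert crispr.gene_level_lfc(g)["raw_lfc"].iloc[0] == pytest.approx(0.7)

    def test_order_invariance(self):
        g = pd.DataFrame(
            {"guide_id": ["a", "b", "c"], "gene": ["G2", "G1", "G2"], "lfc": [1.0, 2.0, 3.0]}
        )
        out1 = crispr.gene_level_lfc(g)
        out2 = crispr.gene_level_lfc(g.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(out1, out2)


class TestCssNormalize:
    def _gene_table(self, values):
        return pd.DataFrame(
            {"gene": [f"G{i}" for i in range(len(values))],
             "raw_lfc": values, "n_guides_used": 4}
        )

    def test_standard_normal_mode_near_zero(self):
        # argmax of a Silverman-bandwidth KDE on n=20,000 standard normals
        # has sampling sd ~ sd(f')/|f''(0)| ~ 0.075 near the flat density
        # peak; 3 sd bounds the recovered mode
        rng = np.random.default_rng(0)
        raw = rng.normal(0, 1, 20000)
        out = crispr.css_normalize(self._gene_table(raw))
        assert abs(out.attrs["mode"]) < 0.225
        # css ~ raw elementwise once mode ~ 0 and RMSD ~ 1
        np.testing.assert_allclose(out["css"], raw, atol=0.35)

    def test_normalized_scores_have_mode_zero_rmsd_one(self):
        rng = np.random.default_rng(1)
        raw = np.concatenate([rng.normal(0, 0.5, 950), rng.normal(-2, 0.5, 50)])
        out = crispr.css_normalize(self._gene_table(raw))
        css = out["css"].to_numpy()
        mode_css, grid_dx = crispr.kde_mode(css)
        assert abs(mode_css) <= 2 * grid_dx
        rmsd_css = np.sqrt(np.mean((css - 0.0) ** 2))
        assert rmsd_css == pytest.approx(1.0, abs=1e-6)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(0, 1, 500)
        a = crispr.css_normalize(self._gene_table(raw))["css"]
        b = crispr.css_normalize(self._gene_table(raw + 5.0))["css"]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        raw = rng.normal(0, 1, 500)
        a = crispr.css_normalize(self._gene_table(raw))["css"]
        b = crispr.css_normalize(self._gene_table(raw * 3.5))["css"]
        np.testing.assert_allclose(a, b, atol=1e-9)

    @settings(deadline=None, max_examples=20)
    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_affine_invariance_property(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        raw = rng.normal(0, 1, 200)
        a = crispr.css_normalize(self._gene_table(raw))["css"]
        b = crispr.css_normalize(self._gene_table(raw * scale + shift))["css"]
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_too_few_genes_rejected(self):
        with pytest.raises(crispr.ScoringError):
            crispr.css_normalize(self._gene_table(np.arange(10.0)))


class TestEndToEnd:
    def test_essential_gene_ranking_auroc(self, screen_data):
        counts, truth = screen_data
        res = crispr.score_screen(
            counts, ["day21_rep1", "day21_rep2"], ["day0_rep1", "day0_rep2"]
        )
        merged = res.genes.merge(truth, on="gene")
        score = auroc(-merged["css"].to_numpy(), merged["is_essential"].to_numpy())
        assert score >= 0.95

    def test_deterministic_rescoring(self, screen_data):
        counts, _ = screen_data
        args = (counts, ["day21_rep1"], ["day0_rep1"])
        pd.testing.assert_frame_equal(
            crispr.score_screen(*args).genes, crispr.score_screen(*args).genes
        )

    def test_auroc_matches_sklearn(self, screen_data):
        from sklearn.metrics import roc_auc_score

        counts, truth = screen_data
        res = crispr.score_screen(
            counts, ["day21_rep1", "day21_rep2"], ["day0_rep1", "day0_rep2"]
        )
        merged = res.genes.merge(truth, on="gene")
        ours = auroc(-merged["css"].to_numpy(), merged["is_essential"].to_numpy())
        ref = roc_auc_score(merged["is_essential"], -merged["css"])
        assert ours == pytest.approx(ref, abs=1e-12)


class TestSortedAndModifierScreens:
    def _sorted_screen(self, seed=21, flip=False):
        """Counts for a sort screen with one gene 8-fold enriched in 'low'."""
        rng = np.random.default_rng(seed)
        n_genes, gpg = 300, 4
        genes = np.repeat([f"G{i}" for i in range(n_genes)], gpg)
        base = rng.poisson(500, size=n_genes * gpg)
        low = rng.poisson(base).astype(float)
        high = rng.poisson(base).astype(float)
        low[:gpg] *= 8  # gene G0 enriched in the low sort
        t = pd.DataFrame(
            {"guide_id": [f"sg{i}" for i in range(n_genes * gpg)], "gene": genes,
             "low_rep1": low.astype(int), "high_rep1": high.astype(int)}
        )
        return t

    def test_planted_gene_ranks_top(self):
        t = self._sorted_screen()
        res = crispr.sorted_screen_score(t, ["low_rep1"], ["high_rep1"])
        ranked = res.genes.sort_values("css", ascending=False)
        assert ranked["gene"].iloc[0] == "G0"
        assert res.genes.set_index("gene").loc["G0", "css"] >= np.quantile(
            res.genes["css"], 0.99
        )

    def test_label_swap_flips_sign(self):
        t = self._sorted_screen()
        a = crispr.sorted_screen_score(t, ["low_rep1"], ["high_rep1"]).genes
        b = crispr.sorted_screen_score(t, ["high_rep1"], ["low_rep1"]).genes
        merged = a.merge(b, on="gene", suffixes=("_a", "_b"))
        # antisymmetric up to the re-estimated mode/RMSD of each direction
        corr = np.corrcoef(merged["css_a"], -merged["css_b"])[0, 1]
        assert corr > 0.99

    def test_modifier_delta_identity_and_antisymmetry(self, screen_data):
        counts, _ = screen_data
        res = crispr.score_screen(
            counts, ["day21_rep1"], ["day0_rep1"]
        ).genes
        same = crispr.modifier_delta(res, res)
        np.testing.assert_allclose(same["delta_css"], 0.0)
        res2 = crispr.score_screen(counts, ["day21_rep2"], ["day0_rep2"]).genes
        ab = crispr.modifier_delta(res, res2)
        ba = crispr.modifier_delta(res2, res)
        np.testing.assert_allclose(
            ab["delta_css"].to_numpy(), -ba["delta_css"].to_numpy(), atol=1e-12
        )

    def test_modifier_delta_planted_condition_specific_gene(self):
        rng = np.random.default_rng(33)
        genes = [f"G{i}" for i in range(300)]
        base = pd.DataFrame(
            {"gene": genes, "raw_lfc": rng.normal(0, 0.3, 300), "n_guides_used": 4}
        )
        cond = base.copy()
        cond.loc[0, "raw_lfc"] -= 3.0  # essential only under the condition
        d = crispr.modifier_delta(
            crispr.css_normalize(cond), crispr.css_normalize(base)
        )
        top = d.reindex(d["delta_css"].abs().sort_values(ascending=False).index)
        assert top["gene"].iloc[0] == "G0"
        assert top["delta_css"].iloc[0] < 0

    def test_empty_intersection_errors(self):
        a = pd.DataFrame({"gene": ["G1"], "css": [0.0]})
        b = pd.DataFrame({"gene": ["G2"], "css": [0.0]})
        with pytest.raises(ValueError):
            crispr.modifier_delta(a, b)
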