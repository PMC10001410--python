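"""Differential-expression stage: normalization, dispersions, Wald test, BH."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mirnet as mn
from mirnet.de import (
    ContrastError,
    adjust_bh,
    estimate_dispersions,
    estimate_size_factors,
    wald_contrast,
)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[5], [50], [500]], (1, 4)))
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_gets_double_factor(self, tiny_counts):
        doubled = tiny_counts.counts.copy()
        doubled["s4"] = doubled["s4"] * 2
        sf = estimate_size_factors(doubled)
        ratio = sf["s4"] / sf["s1"]
        base = estimate_size_factors(tiny_counts.counts)
        assert ratio == pytest.approx(2 * base["s4"] / base["s1"])

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.poisson(80, size=(50, 6)) + 1)
        sf = estimate_size_factors(counts)
        # independent re-computation, feature by feature
        logs = np.log(counts.to_numpy(dtype=float))
        geo = logs.mean(axis=1)
        expected = [
            np.exp(np.median([logs[i, j] - geo[i] for i in range(50)]))
            for j in range(6)
        ]
        assert np.allclose(sf.to_numpy(), expected)

    def test_errors_when_no_feature_expressed_everywhere(self):
        counts = pd.DataFrame([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            estimate_size_factors(counts)


# ---------------------------------------------------------------------------
# dispersions
# ---------------------------------------------------------------------------


class TestDispersions:
    @pytest.mark.parametrize(
        "true_alpha, lo, hi",
        [(0.0, 0.0, 0.01), (0.2, 0.1, 0.4)],
        ids=["poisson", "overdispersed"],
    )
    def test_recovers_known_dispersion(self, true_alpha, lo, hi):
        cfg = mn.SimConfig(
            n_genes=2000, n_mirnas=10, n_per_group=6, frac_de=0.0,
            dispersion=true_alpha, seed=13,
        )
        cm, _ = mn.simulate_counts(cfg, "mRNA")
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        med = float(np.median(disp.final))
        assert lo <= med <= hi

    def test_constant_counts_give_zero_genewise(self):
        counts = pd.DataFrame(
            np.tile([[20], [40]], (1, 4)), columns=["a", "b", "c", "d"]
        )
        meta = pd.DataFrame(
            {"genotype": ["WT", "WT", "KO", "KO"], "assay": "mRNA", "batch": "b1"},
            index=counts.columns,
        )
        cm = mn.CountMatrix(counts, meta)
        disp = estimate_dispersions(cm, estimate_size_factors(counts))
        assert (disp.genewise == 0).all()

    def test_requires_two_replicates_per_group(self, tiny_counts):
        lonely = tiny_counts.subset_samples(
            tiny_counts.sample_meta.index.isin(["s1", "s3", "s4"])
        )
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersions(lonely, estimate_size_factors(tiny_counts.counts[["s1", "s3", "s4"]]))


# ---------------------------------------------------------------------------
# Wald contrast
# ---------------------------------------------------------------------------


def _run(cm, spec):
    return mn.run_contrast(cm, spec)


class TestWald:
    def test_null_feature_has_unit_pvalue(self, tiny_counts):
        spec = mn.ContrastSpec("KO", lfc_threshold=0.0)
        res = _run(tiny_counts, spec)
        # f3 is all-zero: untested
        assert np.isnan(res.table.loc["f3", "pvalue"])
        assert not res.table.loc["f3", "is_de"]

    def test_interior_of_composite_null_is_exactly_one(self, small_cfg):
        cm, _ = mn.simulate_counts(replace(small_cfg, frac_de=0.0), "mRNA")
        res = _run(cm, mn.ContrastSpec.mrna("KO"))
        inside = res.table["lfc"].abs() <= 1.0
        assert inside.any()
        assert (res.table.loc[inside, "pvalue"] == 1.0).all()

    def test_pvalues_monotone_in_threshold(self, small_cfg):
        cm, _ = mn.simulate_counts(small_cfg, "mRNA")
        p0 = _run(cm, mn.ContrastSpec("KO", lfc_threshold=0.0)).table["pvalue"]
        p1 = _run(cm, mn.ContrastSpec("KO", lfc_threshold=1.0)).table["pvalue"]
        both = ~(p0.isna() | p1.isna())
        assert (p1[both] >= p0[both] - 1e-15).all()

    def test_swapping_groups_negates_lfc_and_keeps_pvalues(self, small_cfg):
        cm, _ = mn.simulate_counts(small_cfg, "mRNA")
        fwd = _run(cm, mn.ContrastSpec("KO", "WT", lfc_threshold=1.0)).table
        rev = _run(cm, mn.ContrastSpec("WT", "KO", lfc_threshold=1.0)).table
        assert np.allclose(fwd["lfc"], -rev["lfc"], atol=1e-12)
        ok = ~fwd["pvalue"].isna()
        assert np.allclose(fwd.loc[ok, "pvalue"], rev.loc[ok, "pvalue"], atol=1e-12)

    def test_sample_rescaling_leaves_lfc_invariant(self, small_cfg):
        cm, _ = mn.simulate_counts(replace(small_cfg, n_genes=200), "mRNA")
        scaled_counts = cm.counts.copy()
        scaled_counts.iloc[:, 0] = scaled_counts.iloc[:, 0] * 3
        scaled = mn.CountMatrix(scaled_counts, cm.sample_meta)
        sf_a = estimate_size_factors(cm)
        sf_b = estimate_size_factors(scaled)
        assert sf_b.iloc[0] / sf_a.iloc[0] == pytest.approx(
            3 * sf_b.iloc[1] / sf_a.iloc[1], rel=1e-9
        )
        lfc_a = _run(cm, mn.ContrastSpec.mrna("KO")).table["lfc"]
        lfc_b = _run(scaled, mn.ContrastSpec.mrna("KO")).table["lfc"]
        assert np.allclose(lfc_a, lfc_b, atol=1e-9)

    def test_power_on_strongly_planted_features(self):
        cfg = mn.SimConfig(
            n_genes=2000, n_mirnas=10, n_per_group=6, frac_de=0.05,
            lfc_magnitude=3.0, dispersion=0.05, mean_log_mu=np.log(500.0),
            seed=21,
        )
        cm, truth = mn.simulate_counts(cfg, "mRNA")
        res = _run(cm, mn.ContrastSpec.mrna("KO"))
        planted = [f for f, v in truth.de_features.items() if "KO" in v]
        called = set(res.de_features)
        recall = np.mean([f in called for f in planted])
        assert recall >= 0.9

    def test_confounded_contrast_refused(self, small_cfg):
        cm, _ = mn.simulate_counts(small_cfg, "miRNA")
        with pytest.raises(ContrastError, match="confounded"):
            mn.run_contrast(cm, mn.ContrastSpec.mirna("KO", ref_genotype="KI"))

    def test_missing_genotype_in_batch_refused(self, small_cfg):
        cm, _ = mn.simulate_counts(small_cfg, "miRNA")
        with pytest.raises(ContrastError, match="no samples"):
            mn.run_contrast(cm, mn.ContrastSpec.mirna("KO", batch_restrict="batch1"))

    def test_default_thresholds_by_assay(self):
        assert mn.ContrastSpec.mrna("KO").lfc_threshold == 1.0
        assert mn.ContrastSpec.mirna("KO").lfc_threshold == 0.0
        assert mn.ContrastSpec.mrna("KO").alpha == 0.1


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_unchanged(self):
        assert adjust_bh([0.37])[0] == pytest.approx(0.37)

    def test_nan_passthrough_excluded_from_m(self):
        padj = adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(padj[1])
        # m = 2, not 3
        assert padj[0] == pytest.approx(0.02)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_dominance_bounds(self, pvals):
        padj = adjust_bh(pvals)
        assert (padj >= np.asarray(pvals) - 1e-12).all()
        assert (padj <= 1.0 + 1e-12).all()


# ---------------------------------------------------------------------------
# cross-check against an independent DESeq2 implementation
# ---------------------------------------------------------------------------


def test_size_factors_match_pydeseq2(small_cfg):
    """Median-of-ratios normalization agrees with pydeseq2 on the same data."""
    import warnings

    cm, _ = mn.simulate_counts(replace(small_cfg, n_genes=300), "mRNA")
    ours = estimate_size_factors(cm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from pydeseq2.dds import DeseqDataSet

        dds = DeseqDataSet(
            counts=cm.counts.T,
            metadata=cm.sample_meta.rename(columns={"genotype": "condition"}),
            design="~condition",
            quiet=True,
        )
        dds.fit_size_factors()
        theirs = dds.obs["size_factors"]
    assert np.allclose(ours.to_numpy(), theirs.to_numpy(), rtol=1e-6)


def test_yaml_contrast_config(tmp_path):
    path = tmp_path / "contrasts.yaml"
    path.write_text(
        "contrasts:\n"
        "  - test_genotype: KO\n"
        "  - test_genotype: KI\n"
        "    assay: miRNA\n"
        "    batch_restrict: batch1\n"
    )
    specs = mn.contrasts_from_yaml(path)
    assert specs[0].lfc_threshold == 1.0 and specs[0].ref_genotype == "WT"
    assert specs[1].lfc_threshold == 0.0 and specs[1].batch_restrict == "batch1"
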