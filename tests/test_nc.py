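"""Centering strategies and nearest-centroid classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import subtypekit as sk
from subtypekit.nc import (
    CenteringSpec,
    REFERENCE_ER_POS_PROPORTION,
    apply_centering,
    classify_nc,
)
from subtypekit.types import CentroidModel, QuantileTable, ValidationError

from conftest import make_clinical, make_expression
from _oracles import pearson, spearman


def toy_centroids(n_genes=6, seed=0, kind="spearman"):
    rng = np.random.default_rng(seed)
    mat = rng.normal(size=(n_genes, 5))
    return CentroidModel(
        centroids=pd.DataFrame(
            mat, index=[f"g{i}" for i in range(n_genes)],
            columns=list(sk.SUBTYPES),
        ),
        correlation_kind=kind,
    )


class TestCentering:
    def test_median_noop_when_medians_zero(self):
        values = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0]])
        expr = make_expression(values)
        out, _ = apply_centering(expr, None, CenteringSpec(strategy="median"))
        assert np.allclose(out.data.to_numpy(), values, atol=1e-15)

    def test_median_subtracts_per_gene_median(self):
        expr = make_expression([[1.0, 2.0, 6.0]])
        out, _ = apply_centering(expr, None, CenteringSpec(strategy="median"))
        assert list(out.data.iloc[0]) == [-1.0, 0.0, 4.0]

    def test_robust_scale_formula(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(3, 30))
        expr = make_expression(values)
        out, _ = apply_centering(expr, None,
                                 CenteringSpec(strategy="robust_scale"))
        for i in range(3):
            row = values[i]
            q05, q95 = np.quantile(row, [0.05, 0.95])
            expected = (row - q05) / (q95 - q05) - 0.5
            assert np.allclose(out.data.iloc[i].to_numpy(), expected,
                               atol=1e-12)

    def test_ssbc_quantile_p_half_equals_median(self):
        rng = np.random.default_rng(8)
        expr = make_expression(rng.normal(size=(4, 9)))
        qt = QuantileTable(pd.DataFrame({
            "gene_id": expr.gene_ids,
            "subgroup": ["ER+"] * 4,
            "quantile_prob": [0.5] * 4,
        }))
        spec = CenteringSpec(strategy="ssbc_quantile", quantiles=qt,
                             subgroup="ER+")
        out, _ = apply_centering(expr, None, spec)
        ref, _ = apply_centering(expr, None, CenteringSpec(strategy="median"))
        assert np.array_equal(out.data.to_numpy(), ref.data.to_numpy())

    def test_ssbc_missing_subgroup_errors(self):
        expr = make_expression(np.ones((2, 3)))
        qt = QuantileTable(pd.DataFrame({
            "gene_id": ["g0"], "subgroup": ["ER+"], "quantile_prob": [0.4],
        }))
        spec = CenteringSpec(strategy="ssbc_quantile", quantiles=qt,
                             subgroup="TN")
        with pytest.raises(ValidationError, match="TN"):
            apply_centering(expr, None, spec)

    def test_cihc_hits_target_fraction(self):
        # 60% ER+ cohort of 60: the selected subcohort's ER+ fraction must
        # land within 1/n_subcohort of 54/118 = 45.8%
        n = 60
        er = ["pos"] * 36 + ["neg"] * 24
        clin = make_clinical(er, sample_ids=[f"s{j}" for j in range(n)])
        expr = make_expression(np.random.default_rng(0).normal(size=(5, n)),
                               sample_ids=[f"s{j}" for j in range(n)])
        spec = CenteringSpec(strategy="cihc", seed=3)
        out, flags = apply_centering(expr, clin, spec)
        size = flags["subcohort_size"]
        # recompute the draw to inspect composition
        from subtypekit.nc import _balanced_subcohort
        sub = _balanced_subcohort(clin.er_status(), REFERENCE_ER_POS_PROPORTION,
                                  np.random.default_rng(3))
        frac = np.mean([clin.table.loc[s, "er"] == "pos" for s in sub])
        assert abs(frac - REFERENCE_ER_POS_PROPORTION) <= 1.0 / len(sub)
        assert size == len(sub)

    def test_cihc_deterministic_under_seed(self):
        n = 40
        er = ["pos"] * 30 + ["neg"] * 10
        clin = make_clinical(er, sample_ids=[f"s{j}" for j in range(n)])
        expr = make_expression(np.random.default_rng(1).normal(size=(4, n)),
                               sample_ids=[f"s{j}" for j in range(n)])
        spec = CenteringSpec(strategy="cihc", seed=11)
        out1, _ = apply_centering(expr, clin, spec)
        out2, _ = apply_centering(expr, clin, spec)
        assert np.array_equal(out1.data.to_numpy(), out2.data.to_numpy())

    def test_cihc_unattainable_errors(self):
        clin = make_clinical(["pos"] * 5)
        expr = make_expression(np.ones((2, 5)))
        with pytest.raises(ValidationError, match="unattainable"):
            apply_centering(expr, clin, CenteringSpec(strategy="cihc"))

    def test_cihc_iterative_converges_and_flags(self, toy_models):
        spec_sim = sk.SimSpec(seed=4, noise_sd=0.2, n=80)
        expr, clin, _ = sk.simulate_cohort(spec_sim, toy_models.centroid)
        spec = CenteringSpec(strategy="cihc_iterative", seed=2)
        out, flags = apply_centering(expr, clin, spec,
                                     model=toy_models.centroid)
        assert 1 <= flags["iterations"] <= spec.max_iterations

    def test_pca_guided_recovers_er_split(self, toy_models):
        # with strong ER/subtype coupling, PC1 should produce a usable split
        spec_sim = sk.SimSpec(seed=6, noise_sd=0.2, n=100)
        expr, clin, _ = sk.simulate_cohort(spec_sim, toy_models.centroid)
        spec = CenteringSpec(strategy="pca_guided", seed=2)
        out, flags = apply_centering(expr, clin, spec)
        assert out.data.shape == expr.data.shape

    def test_requires_log2_scale(self):
        expr = make_expression([[1.0]], platform="rnaseq_counts")
        with pytest.raises(ValidationError, match="log2"):
            apply_centering(expr, None, CenteringSpec(strategy="median"))


class TestClassifyNC:
    def test_self_correlation_is_one(self):
        model = toy_centroids()
        values = model.centroids[["Basal"]].to_numpy()
        expr = make_expression(values, gene_ids=model.gene_ids,
                               sample_ids=["s0"])
        calls = classify_nc(expr, model)
        assert calls[0].label == "Basal"
        assert calls[0].scores["Basal"] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("kind", ["spearman", "pearson"])
    def test_matches_bruteforce_oracle(self, kind):
        rng = np.random.default_rng(17)
        for _ in range(100):
            model = toy_centroids(n_genes=20, seed=rng.integers(1 << 30),
                                  kind=kind)
            x = rng.normal(size=20)
            expr = make_expression(x[:, None], gene_ids=model.gene_ids,
                                   sample_ids=["s0"])
            call = classify_nc(expr, model)[0]
            oracle_fn = spearman if kind == "spearman" else pearson
            oracle_scores = {
                k: oracle_fn(list(x), list(model.centroids[k]))
                for k in model.subtype_order
            }
            for k in model.subtype_order:
                assert call.scores[k] == pytest.approx(oracle_scores[k],
                                                       abs=1e-12)
            best = max(oracle_scores.values())
            oracle_label = [k for k in model.subtype_order
                            if oracle_scores[k] == best][0]
            assert call.label == oracle_label

    def test_tie_breaks_by_subtype_order_with_flag(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=6)
        mat = np.column_stack([base] * 2 + [rng.normal(size=6)
                                            for _ in range(3)])
        model = CentroidModel(
            centroids=pd.DataFrame(mat, index=[f"g{i}" for i in range(6)],
                                   columns=list(sk.SUBTYPES)),
        )
        expr = make_expression(base[:, None], gene_ids=model.gene_ids,
                               sample_ids=["s0"])
        call = classify_nc(expr, model)[0]
        assert call.label == "LumA"  # first of the two tied columns
        assert call.flags.get("tie_broken")

    def test_low_overlap_errors_listing_missing(self):
        model = toy_centroids(n_genes=10)
        expr = make_expression(np.ones((5, 1)),
                               gene_ids=[f"g{i}" for i in range(5)])
        with pytest.raises(ValidationError, match="overlap"):
            classify_nc(expr, model)

    def test_partial_overlap_sets_coverage_flag(self):
        model = toy_centroids(n_genes=10)
        genes = model.gene_ids[:9]
        expr = make_expression(
            model.centroids.loc[genes, ["Her2"]].to_numpy(),
            gene_ids=genes, sample_ids=["s0"],
        )
        call = classify_nc(expr, model)[0]
        assert call.flags.get("low_gene_coverage")

    @given(st.integers(0, 2**32 - 1), st.sampled_from(["exp", "cube", "arctan"]))
    @settings(max_examples=30, deadline=None)
    def test_spearman_invariant_to_monotone_transforms(self, seed, fname):
        rng = np.random.default_rng(seed)
        model = toy_centroids(n_genes=12, seed=7, kind="spearman")
        x = rng.normal(size=12)
        fn = {"exp": np.exp, "cube": lambda v: v ** 3,
              "arctan": np.arctan}[fname]
        e1 = make_expression(x[:, None], gene_ids=model.gene_ids,
                             sample_ids=["s0"])
        e2 = make_expression(fn(x)[:, None], gene_ids=model.gene_ids,
                             sample_ids=["s0"])
        c1 = classify_nc(e1, model)[0]
        c2 = classify_nc(e2, model)[0]
        assert c1.label == c2.label
        for k in model.subtype_order:
            assert c1.scores[k] == pytest.approx(c2.scores[k], abs=1e-12)


class TestParameterRecovery:
    def test_median_nc_recovers_labels_at_low_noise(self, toy_models,
                                                    balanced_cohort):
        expr, clin, truth = balanced_cohort  # sigma = 0.2
        centered, _ = apply_centering(expr, clin,
                                      CenteringSpec(strategy="median"))
        calls = classify_nc(centered, toy_models.centroid)
        labels = pd.Series({c.sample_id: c.label for c in calls})
        assert (labels == truth).mean() >= 0.99

    def test_zero_noise_recovery_is_exact(self, toy_models):
        spec = sk.SimSpec(seed=3, noise_sd=0.0, n=60)
        expr, clin, truth = sk.simulate_cohort(spec, toy_models.centroid)
        centered, _ = apply_centering(expr, clin,
                                      CenteringSpec(strategy="median"))
        calls = classify_nc(centered, toy_models.centroid)
        labels = pd.Series({c.sample_id: c.label for c in calls})
        assert (labels == truth).all()
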