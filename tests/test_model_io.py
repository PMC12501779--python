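"""Domain types, file readers/writers, round trips, audit replay."""

import numpy as np
import pandas as pd
import pytest

import subtypekit as sk
from subtypekit import io
from subtypekit.types import ValidationError

from conftest import make_clinical, make_expression


# ---------------------------------------------------------------------------
# expression parsing
# ---------------------------------------------------------------------------

def _write_tsv(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestReadExpression:
    def test_counts_platform_tags(self, tmp_path):
        p = _write_tsv(
            tmp_path / "e.tsv",
            "gene_id\ts1\ts2\ng1\t1\t2\ng2\t3\t4\ng3\t0\t5\n",
        )
        expr = io.read_expression(p, "rnaseq_counts")
        assert expr.scale == "linear"
        assert expr.units == "counts"
        assert expr.gene_ids == ["g1", "g2", "g3"]
        assert expr.data.loc["g2", "s2"] == 4

    def test_na_cell_names_location(self, tmp_path):
        p = _write_tsv(
            tmp_path / "e.tsv", "gene_id\ts1\ts2\ng1\t1\tNA\ng2\t3\t4\n"
        )
        with pytest.raises(ValidationError, match="g1.*s2"):
            io.read_expression(p, "rnaseq_counts")

    def test_log2fpkm_tags(self, tmp_path):
        p = _write_tsv(tmp_path / "e.tsv", "gene_id\ts1\ng1\t1.5\ng2\t-0.25\n")
        expr = io.read_expression(p, "rnaseq_log2fpkm")
        assert expr.scale == "log2"
        assert expr.units == "fpkm"

    def test_negative_counts_rejected(self, tmp_path):
        p = _write_tsv(tmp_path / "e.tsv", "gene_id\ts1\ng1\t-3\n")
        with pytest.raises(ValidationError, match="egative"):
            io.read_expression(p, "rnaseq_counts")

    def test_duplicate_gene_rejected(self, tmp_path):
        p = _write_tsv(tmp_path / "e.tsv", "gene_id\ts1\ng1\t1\ng1\t2\n")
        with pytest.raises(ValidationError, match="duplicate gene"):
            io.read_expression(p, "rnaseq_counts")

    def test_transpose(self, tmp_path):
        p = _write_tsv(
            tmp_path / "e.tsv", "sample\tg1\tg2\ns1\t1\t2\ns2\t3\t4\n"
        )
        expr = io.read_expression(p, "microarray", transpose=True)
        assert expr.gene_ids == ["g1", "g2"]
        assert expr.sample_ids == ["s1", "s2"]

    def test_roundtrip(self, tmp_path):
        expr = make_expression(np.random.default_rng(0).normal(size=(4, 3)))
        io.write_expression(expr, tmp_path / "e.tsv")
        back = io.read_expression(tmp_path / "e.tsv", "microarray")
        assert np.allclose(back.data.to_numpy(), expr.data.to_numpy(),
                           atol=1e-12)


# ---------------------------------------------------------------------------
# clinical parsing
# ---------------------------------------------------------------------------

class TestReadClinical:
    def test_synonyms(self, tmp_path):
        p = _write_tsv(
            tmp_path / "c.tsv",
            "sample_id\ter\tpr\ther2\ttn\n"
            "s1\tpositive\tnegative\tnegative\tfalse\n"
            "s2\t0\t0\t0\ttrue\n"
            "s3\t+\t-\tweird\tfalse\n",
        )
        clin = io.read_clinical(p)
        assert clin.table.loc["s1", "er"] == "pos"
        assert clin.table.loc["s1", "pr"] == "neg"
        assert not clin.table.loc["s1", "tn"]
        assert clin.table.loc["s2", "tn"]
        assert clin.table.loc["s3", "her2"] == "unknown"

    def test_tn_consistency_error(self, tmp_path):
        p = _write_tsv(
            tmp_path / "c.tsv",
            "sample_id\ter\tpr\ther2\ttn\ns3\t1\t0\t0\ttrue\n",
        )
        with pytest.raises(ValidationError, match="TN"):
            io.read_clinical(p)

    def test_unknown_column_warned_and_ignored(self, tmp_path):
        p = _write_tsv(
            tmp_path / "c.tsv",
            "sample_id\ter\tpr\ther2\tage\ns1\t1\t1\t0\t62\n",
        )
        with pytest.warns(UserWarning, match="age"):
            clin = io.read_clinical(p)
        assert "age" not in clin.table.columns

    def test_roundtrip(self, tmp_path):
        clin = make_clinical(
            ["pos", "neg", "neg"],
            pr=["pos", "neg", "neg"],
            her2=["neg", "neg", "neg"],
            tn=[False, True, True],
        )
        io.write_clinical(clin, tmp_path / "c.tsv")
        back = io.read_clinical(tmp_path / "c.tsv")
        pd.testing.assert_frame_equal(back.table, clin.table)


# ---------------------------------------------------------------------------
# model files
# ---------------------------------------------------------------------------

class TestModelFiles:
    def test_centroid_roundtrip(self, toy_models, tmp_path):
        io.write_centroids(toy_models.centroid, tmp_path / "m.tsv")
        back = io.read_model(tmp_path / "m.tsv", "centroid")
        pd.testing.assert_frame_equal(back.centroids, toy_models.centroid.centroids,
                                      atol=1e-12, rtol=0, check_names=False)
        assert back.correlation_kind == toy_models.centroid.correlation_kind
        assert back.min_gene_fraction == toy_models.centroid.min_gene_fraction

    def test_centroid_long_names_normalized(self, tmp_path):
        text = (
            "gene_id\tLuminal A\tLuminal B\tHER2-enriched\tBasal-like\tNormal-like\n"
            + "\n".join(f"g{i}\t1\t2\t3\t4\t5" for i in range(3))
            + "\n"
        )
        (tmp_path / "m.tsv").write_text(text)
        model = io.read_centroids(tmp_path / "m.tsv")
        assert model.subtype_order == ("LumA", "LumB", "Her2", "Basal", "Normal")

    def test_centroid_unknown_label_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene_id\tLumA\tClaudinLow\ng1\t1\t2\n")
        with pytest.raises(ValidationError, match="unknown subtype"):
            io.read_centroids(tmp_path / "m.tsv")

    def test_quantile_roundtrip(self, toy_models, tmp_path):
        io.write_quantiles(toy_models.quantile, tmp_path / "q.tsv")
        back = io.read_model(tmp_path / "q.tsv", "quantile")
        pd.testing.assert_frame_equal(
            back.table.reset_index(drop=True),
            toy_models.quantile.table.reset_index(drop=True),
            atol=1e-12, rtol=0,
        )

    def test_quantile_prob_out_of_range(self, tmp_path):
        (tmp_path / "q.tsv").write_text(
            "gene_id\tsubgroup\tquantile_prob\ng1\tER+\t1.5\n"
        )
        with pytest.raises(ValidationError, match="quantile_prob"):
            io.read_quantiles(tmp_path / "q.tsv")

    def test_quantile_duplicate_pair(self, tmp_path):
        (tmp_path / "q.tsv").write_text(
            "gene_id\tsubgroup\tquantile_prob\ng1\tER+\t0.5\ng1\tER+\t0.6\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            io.read_quantiles(tmp_path / "q.tsv")

    def test_ruleset_roundtrip(self, toy_models, tmp_path):
        rules = toy_models.rulesets["AIMS"]
        io.write_ruleset(rules, tmp_path / "r.tsv")
        back = io.read_model(tmp_path / "r.tsv", "ruleset")
        assert back.rules == rules.rules
        assert np.allclose(back.probs.to_numpy(), rules.probs.to_numpy(),
                           atol=1e-12)
        assert np.allclose(back.priors.to_numpy(), rules.priors.to_numpy(),
                           atol=1e-12)

    def test_ruleset_probability_clipped(self, tmp_path):
        (tmp_path / "r.tsv").write_text(
            "gene_a\tgene_b\tLumA\tBasal\ng1\tg2\t1.0\t0.4\n"
        )
        with pytest.warns(UserWarning, match="clipped"):
            rules = io.read_ruleset(tmp_path / "r.tsv")
        assert rules.probs.iloc[0, 0] == pytest.approx(1 - 1e-6)

    def test_ruleset_probability_out_of_range(self, tmp_path):
        (tmp_path / "r.tsv").write_text(
            "gene_a\tgene_b\tLumA\tBasal\ng1\tg2\t1.4\t0.4\n"
        )
        with pytest.raises(ValidationError):
            io.read_ruleset(tmp_path / "r.tsv")

    def test_ruleset_same_gene_rejected(self, tmp_path):
        (tmp_path / "r.tsv").write_text(
            "gene_a\tgene_b\tLumA\tBasal\ng1\tg1\t0.5\t0.4\n"
        )
        with pytest.raises(ValidationError, match="identical genes"):
            io.read_ruleset(tmp_path / "r.tsv")


# ---------------------------------------------------------------------------
# decisions and call matrices
# ---------------------------------------------------------------------------

class TestDecisionAudit:
    def test_decision_roundtrip_replays_partition(self, registry, tmp_path):
        clin = make_clinical(["pos"] * 10 + ["neg"] * 40)
        diag = sk.cohort_diagnostics(clin)
        decision = sk.select_methods(diag, "unselected", registry)
        io.write_decision(decision, tmp_path / "d.json")
        back = io.read_decision(tmp_path / "d.json")
        assert back.partition() == decision.partition()
        assert back.branch == decision.branch
        assert back.thresholds == decision.thresholds

    def test_call_matrix_roundtrip(self, tmp_path):
        labels = pd.DataFrame(
            {"m1": ["LumA", "Basal", np.nan], "m2": ["LumA", np.nan, "Her2"]},
            index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        )
        calls = sk.CallMatrix(labels)
        io.write_call_matrix(calls, tmp_path / "cm.tsv")
        back = io.read_call_matrix(tmp_path / "cm.tsv")
        pd.testing.assert_frame_equal(back.labels, calls.labels)

    def test_call_matrix_rejects_noncanon_label(self):
        labels = pd.DataFrame({"m1": ["LuminalX"]},
                              index=pd.Index(["s1"], name="sample_id"))
        with pytest.raises(ValidationError, match="canon"):
            sk.CallMatrix(labels)


class TestClinicalTable:
    def test_tn_flag_requires_triple_negative(self):
        with pytest.raises(ValidationError, match="TN"):
            make_clinical(["pos"], pr=["neg"], her2=["neg"], tn=[True])

    def test_subset_missing_sample(self):
        clin = make_clinical(["pos", "neg"])
        with pytest.raises(ValidationError, match="absent"):
            clin.subset(["s0", "s9"])
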