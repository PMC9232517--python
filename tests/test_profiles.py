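"""Summary surfaces: count table consistency, positional bias arithmetic,
feature/strand attribution conservation, and sample PCA determinism."""
import json

import numpy as np
import pandas as pd
import pytest

from mitopirna import ingest, profiles
from mitopirna.annotate import FeatureOverlap


class TestPositionalBias:
    def test_sequence_weighted_frequencies(self):
        df, modal = profiles.positional_bias(["ACG", "AGG", "GTT"])
        assert df.loc[1, "A"] == pytest.approx(2 / 3)
        assert modal == "A"

    def test_read_weighted_frequencies(self):
        df, modal = profiles.positional_bias(["ACG", "AGG", "GTT"], [10, 10, 80])
        assert df.loc[1, "G"] == pytest.approx(0.8)
        assert modal == "G"

    def test_unit_weights_equal_unweighted(self):
        seqs = ["ACGTACGT", "TTGCAAGT", "ACG"]
        a, _ = profiles.positional_bias(seqs)
        b, _ = profiles.positional_bias(seqs, [1, 1, 1])
        pd.testing.assert_frame_equal(a, b)

    def test_rows_sum_to_one_over_covering_sequences(self):
        seqs = ["ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"]  # 40 nt > lmax
        df, _ = profiles.positional_bias(seqs)
        assert df.shape[0] == profiles.BIAS_LMAX
        assert np.allclose(df.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            profiles.positional_bias([])


def _ov(name, ftype, ori, nt):
    return FeatureOverlap(name, ftype, ori, nt)


class TestAttribution:
    def test_feature_distribution_conserves_reads(self):
        overlaps = {
            "S1": [[_ov("tRNA-X", "tRNA", "forward", 20), _ov("mt-Nd1", "CDS", "forward", 10)]],
            "S2": [[_ov("D-loop", "D-loop", "reverse", 25)], [_ov("intergenic", "intergenic", "forward", 25)]],
        }
        lengths = {"S1": 30, "S2": 25}
        gclass = {"S1": "MT", "S2": "NUMT"}
        totals = {"S1": 90, "S2": 40}
        fdist = profiles.feature_distribution(overlaps, lengths, gclass, totals)
        assert fdist["reads"].sum() == pytest.approx(130)
        trna = fdist[fdist["feature_type"] == "tRNA"]["reads"].iloc[0]
        assert trna == pytest.approx(90 * 20 / 30)

    def test_strand_matrix_columns_conserve_cpm(self):
        overlaps = {
            "S1": [[_ov("tRNA-X", "tRNA", "forward", 30)]],
            "S2": [[_ov("D-loop", "D-loop", "reverse", 10), _ov("intergenic", "intergenic", "forward", 15)]],
        }
        lengths = {"S1": 30, "S2": 25}
        cpm = pd.DataFrame({"a": [100.0, 60.0], "b": [0.0, 30.0]}, index=["S1", "S2"])
        cpm.index.name = "sequence"
        smat = profiles.strand_matrix(overlaps, lengths, cpm)
        assert np.allclose(smat.sum(axis=0), cpm.sum(axis=0))
        assert "D-loop:Rvr" in smat.index

    def test_per_kb_enrichment(self):
        fdist = pd.DataFrame(
            [{"feature_type": "tRNA", "genome_class": "MT", "sequences": 1.0, "reads": 500.0}]
        )
        features = pd.DataFrame(
            [{"contig": "chrM", "name": "t1", "type": "tRNA", "start": 1, "end": 500, "strand": "+"}]
        )
        out = profiles.per_kb_enrichment(fdist, features)
        assert out["reads_per_kb"].iloc[0] == pytest.approx(1000.0)


class TestSummarize:
    def test_category_class_cells_sum_to_mito_totals(self, small_run):
        table = pd.read_csv(
            small_run.outputs["profile"]["sample_table.tsv"], sep="\t", index_col="sample_id"
        )
        body = table.drop(index="Average")
        cells = body[["mirna_NUMT_reads", "mirna_MT_reads", "pirna_NUMT_reads", "pirna_MT_reads"]]
        assert (body["mito_reads"] >= cells.sum(axis=1)).all()  # remainder = 'other'
        assert (body["total_reads"] >= body["mito_reads"]).all()

    def test_dual_sequences_count_in_pirna_columns(self):
        counts = pd.DataFrame({"s": [10, 5]}, index=["AAA", "CCC"])
        flags = pd.DataFrame({"s": [True, True]}, index=["AAA", "CCC"])
        table, props = profiles.summarize_counts(
            {"AAA": "dual", "CCC": "other"}, {"AAA": "NUMT", "CCC": "MT"}, counts, flags
        )
        assert table.loc["s", "pirna_NUMT_reads"] == 10
        assert table.loc["s", "mirna_NUMT_reads"] == 0
        assert table.loc["s", "mito_reads"] == 15


class TestPCA:
    def test_identical_columns_are_degenerate(self):
        m = pd.DataFrame(np.ones((5, 4)) * 3.0, columns=list("abcd"))
        coords, evr = profiles.pca_samples(m)
        assert np.allclose(coords.to_numpy(), 0)
        assert np.allclose(evr, 0)

    def test_variance_fractions_sum_below_one(self, small_run):
        smat = pd.read_csv(
            small_run.outputs["profile"]["strand_matrix.tsv"], sep="\t", index_col="feature_orientation"
        )
        _, evr = profiles.pca_samples(smat)
        assert evr.sum() <= 1.0 + 1e-9

    def test_planted_group_effect_separates_cell_types(self, tmp_path):
        from sklearn.metrics import silhouette_score

        from mitopirna import pipeline, simdata
        from conftest import SMALL

        cfg = simdata.SimConfig(seed=21, pgc_family_fold=8.0, **SMALL)
        res = pipeline.run_all(cfg, tmp_path / "grp")
        coords = pd.read_csv(res.outputs["profile"]["pca.tsv"], sep="\t", index_col=0)
        labels = [sid.startswith("PGC") for sid in coords.index]
        score = silhouette_score(coords[["PC1"]].to_numpy(), labels)
        assert score > 0

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            profiles.pca_samples(pd.DataFrame(np.ones((4, 2))))


def test_matrices_round_trip_tsv(small_run, tmp_path):
    smat = pd.read_csv(
        small_run.outputs["profile"]["strand_matrix.tsv"], sep="\t", index_col="feature_orientation"
    )
    p = tmp_path / "roundtrip.tsv"
    smat.to_csv(p, sep="\t")
    back = pd.read_csv(p, sep="\t", index_col="feature_orientation")
    assert np.allclose(smat.to_numpy(), back.to_numpy(), atol=1e-9)


def test_metrics_bundle_has_pos1_adenine_hallmark(small_run):
    metrics = json.loads(small_run.outputs["profile"]["metrics.json"].read_text())
    # planted mito-piRNA families start with adenine: the 1A hallmark must show
    assert metrics["pos1_modal_sequences"] == "A"
    assert metrics["pos1_modal_reads"] == "A"
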