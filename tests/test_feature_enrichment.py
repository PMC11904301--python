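import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import targetrank as tr
from targetrank.feature_enrichment import apply_overrides, load_schema


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestLoadSnapshot:
    def test_gtex_like_table(self, tmp_path):
        header = "gene\t" + "\t".join(f"tissue_{i}" for i in range(5))
        rows = [f"G{i}\t1\t2\t3\t4\t5" for i in range(3)]
        path = write(tmp_path, "g.tsv", header + "\n" + "\n".join(rows) + "\n")
        snap = tr.load_snapshot(path, "gtex_like")
        assert snap.table.shape == (3, 5)
        assert snap.table.index.tolist() == ["G0", "G1", "G2"]

    def test_drugdb_preserves_records(self, tmp_path):
        path = write(tmp_path, "d.tsv",
                     "gene\tphenotype\tmodality\tstatus\n"
                     "A\tNBL\tADC\tclinical\nA\tNBL\tCAR-T\tdiscontinued\n")
        snap = tr.load_snapshot(path, "drugdb")
        assert len(snap.table) == 2
        assert set(snap.table.columns) == {"gene", "phenotype", "modality", "status"}

    def test_duplicate_rows_collapse_by_max(self, tmp_path):
        path = write(tmp_path, "s.tsv",
                     "gene\tevidence_score\nMYC\t2\nMYC\t5\n")
        snap = tr.load_snapshot(path, "surface_evidence")
        assert snap.table.loc["MYC", "evidence_score"] == 5

    def test_missing_required_column(self, tmp_path):
        path = write(tmp_path, "s.tsv", "gene\tother\nA\t1\n")
        with pytest.raises(tr.ValidationError, match="required"):
            tr.load_snapshot(path, "surface_evidence")

    def test_empty_table(self, tmp_path):
        path = write(tmp_path, "s.tsv", "gene\tevidence_score\n")
        with pytest.raises(tr.ValidationError, match="empty"):
            tr.load_snapshot(path, "surface_evidence")

    def test_unknown_schema(self, tmp_path):
        path = write(tmp_path, "s.tsv", "gene\tx\nA\t1\n")
        with pytest.raises(tr.ValidationError, match="schema"):
            tr.load_snapshot(path, "bogus_schema")

    def test_all_schemas_load(self):
        for name in ("gtex_like", "surface_evidence", "depmap_like",
                     "pmtl_like", "drugdb"):
            schema = load_schema(name)
            assert schema["key_column"] == "gene"


class TestEnrich:
    @pytest.fixture()
    def bundle(self, small_projects):
        return small_projects[0][0]

    def test_rows_match_dataset_genes_exactly(self, bundle):
        matrix = tr.build_feature_matrix(bundle.dataset, bundle.snapshots)
        assert matrix.gene_ids == bundle.dataset.gene_ids

    def test_absent_gene_gets_missing_not_zero(self, bundle):
        # surface snapshot drops ~5% of background genes
        surf = bundle.snapshots["surface_evidence"].table
        absent = [g for g in bundle.dataset.gene_ids if g not in surf.index]
        assert absent, "fixture should leave some genes unassayed"
        matrix = tr.build_feature_matrix(bundle.dataset, bundle.snapshots)
        assert matrix.values.loc[absent, "surface_evidence"].isna().all()

    def test_normal_expr_max_is_row_max(self, bundle):
        matrix = tr.build_feature_matrix(bundle.dataset, bundle.snapshots)
        gtex = bundle.snapshots["gtex_like"].table
        g = bundle.dataset.gene_ids[0]
        assert matrix.values.loc[g, "normal_expr_max"] == gtex.loc[g].max()

    def test_invariant_to_snapshot_order(self, bundle):
        matrix1 = tr.build_feature_matrix(bundle.dataset, bundle.snapshots)
        reordered = dict(reversed(list(bundle.snapshots.items())))
        matrix2 = tr.build_feature_matrix(bundle.dataset, reordered)
        pd.testing.assert_frame_equal(matrix1.values, matrix2.values)

    def test_missing_snapshot_for_enabled_feature(self, bundle):
        snapshots = {k: v for k, v in bundle.snapshots.items()
                     if k != "surface_evidence"}
        with pytest.raises(tr.ValidationError, match="surface_evidence"):
            tr.build_feature_matrix(bundle.dataset, snapshots)

    def test_overrides(self):
        catalog = apply_overrides(tr.default_catalog(),
                                  {"surface_evidence": {"weight": 3.0,
                                                        "enabled": False}})
        spec = [s for s in catalog if s.name == "surface_evidence"][0]
        assert spec.weight == 3.0 and not spec.enabled
        with pytest.raises(tr.ValidationError):
            apply_overrides(tr.default_catalog(), {"nope": {"weight": 1}})


def drug_snapshot(records):
    table = pd.DataFrame(records, columns=["gene", "phenotype", "modality",
                                           "status"])
    return tr.FeatureSnapshot("drugdb", table, schema="drugdb")


class TestDeriveLabels:
    def test_status_rules(self):
        snap = drug_snapshot([
            ("A", "NBL", "ADC", "clinical"),
            ("B", "NBL", "ADC", "discontinued"),
            ("C", "NBL", "CAR-T", "discontinued"),
            ("C", "NBL", "ADC", "approved"),
            ("D", "EWS", "ADC", "approved"),  # other phenotype: ignored
        ])
        labels = tr.derive_labels("NBL", snap)
        assert labels.positives == {"A", "C"}
        assert labels.negatives == {"B"}

    def test_modality_filter(self):
        snap = drug_snapshot([("A", "NBL", "CAR-T", "clinical"),
                              ("B", "NBL", "ADC", "clinical")])
        labels = tr.derive_labels("NBL", snap, modalities=["ADC"])
        assert labels.positives == {"B"}

    def test_phenotype_matching_casefolds(self):
        snap = drug_snapshot([("A", "nbl", "ADC", "approved")])
        assert tr.derive_labels("NBL", snap).positives == {"A"}

    def test_unknown_status_rejected(self):
        snap = drug_snapshot([("A", "NBL", "ADC", "withdrawn")])
        with pytest.raises(tr.ValidationError):
            tr.derive_labels("NBL", snap)

    @given(st.lists(st.tuples(st.sampled_from("ABCDEF"),
                              st.sampled_from(["NBL", "EWS"]),
                              st.sampled_from(["ADC", "CAR-T", "mAb"]),
                              st.sampled_from(["approved", "clinical",
                                               "discontinued"])),
                    min_size=1, max_size=25))
    def test_label_sets_always_disjoint(self, records):
        labels = tr.derive_labels("NBL", drug_snapshot(records))
        assert not (labels.positives & labels.negatives)


class TestRestrictedNormalFilter:
    def make(self, values):
        genes = list(values)
        catalog = [tr.FeatureSpec("normal_expr_max", "normal_expression",
                                  "derived:normal_expr_max",
                                  direction="lower_better")]
        matrix = tr.FeatureMatrix(
            values=pd.DataFrame({"normal_expr_max": list(values.values())},
                                index=genes),
            catalog=catalog)
        table = pd.DataFrame({
            "score": np.linspace(1, 0, len(genes)),
            "rank": np.arange(1, len(genes) + 1),
            "percentile": np.linspace(100, 0, len(genes)),
        }, index=genes)
        return tr.ScoreReport(table=table), matrix

    def test_printed_toy_column(self):
        # 20th percentile of {1,2,3,4,100} by linear interpolation is 1.8
        report, matrix = self.make({"g1": 1, "g2": 2, "g3": 3, "g4": 4,
                                    "g5": 100})
        assert tr.restricted_normal_filter(report, matrix, pct=20) == ["g1"]

    def test_pct_100_keeps_everything_below_max(self):
        report, matrix = self.make({"g1": 1, "g2": 2, "g3": 3})
        out = tr.restricted_normal_filter(report, matrix, pct=100)
        assert out == ["g1", "g2"]

    def test_missing_gene_never_returned(self):
        report, matrix = self.make({"g1": 1, "g2": np.nan, "g3": 3, "g4": 4})
        out = tr.restricted_normal_filter(report, matrix, pct=90)
        assert "g2" not in out

    def test_report_order_preserved(self):
        report, matrix = self.make({"g1": 4, "g2": 1, "g3": 2, "g4": 100})
        out = tr.restricted_normal_filter(report, matrix, pct=80)
        assert out == [g for g in report.ranking() if g in set(out)]

    def test_all_missing_rejected(self):
        report, matrix = self.make({"g1": np.nan, "g2": np.nan})
        with pytest.raises(tr.ValidationError):
            tr.restricted_normal_filter(report, matrix, pct=20)
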