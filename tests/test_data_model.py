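import numpy as np
import pandas as pd
import pytest

from sigrank.data_model import (
    AnalysisConfig,
    CompoundRecord,
    IndicationRecord,
    InteractionMatrix,
    ValidationError,
    display_percent,
    load_compounds,
    load_indications,
    load_matrix,
    load_metadata,
    save_compounds,
    save_indications,
    save_matrix,
)


def _write(path, text):
    path.write_text(text)
    return path


class TestInteractionMatrix:
    def test_tsv_round_trip_of_hand_written_fixture(self, tmp_path):
        path = _write(
            tmp_path / "m.tsv",
            "compound_id\tP1\tP2\nC1\t0.5\t1.5\nC2\t-1\t2\nC3\t0\t0\n",
        )
        m = load_matrix(path, "tsv")
        assert m.compound_ids == ("c1", "c2", "c3")
        assert m.protein_ids == ("p1", "p2")
        assert m.scores.shape == (3, 2)
        assert m.scores[0, 1] == 1.5

    def test_duplicate_compound_id_is_named_in_error(self, tmp_path):
        path = _write(
            tmp_path / "m.tsv", "compound_id\tP1\nC1\t0.5\nC1\t1.0\n"
        )
        with pytest.raises(ValidationError, match="c1"):
            load_matrix(path, "tsv")

    def test_nan_cell_reports_coordinates(self, tmp_path):
        path = _write(tmp_path / "m.tsv", "compound_id\tP1\tP2\nC1\t0.5\t\n")
        with pytest.raises(ValidationError, match="c1.*p2"):
            load_matrix(path, "tsv")

    @pytest.mark.parametrize("dialect", ["tsv", "matrix-market"])
    def test_save_load_round_trip_is_identity(self, tmp_path, dialect):
        rng = np.random.default_rng(42)
        m = InteractionMatrix(
            tuple(f"c{i}" for i in range(10)),
            tuple(f"p{j}" for j in range(8)),
            rng.normal(size=(10, 8)),
        )
        ext = "tsv" if dialect == "tsv" else "mtx"
        path = tmp_path / f"m.{ext}"
        save_matrix(m, path, dialect)
        back = load_matrix(path, dialect)
        assert back.compound_ids == m.compound_ids
        assert back.protein_ids == m.protein_ids
        np.testing.assert_allclose(back.scores, m.scores, rtol=0, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            InteractionMatrix(("a", "b"), ("p",), np.zeros((3, 1)))

    def test_ids_are_normalized_on_ingest(self):
        m = InteractionMatrix((" A ", "b"), ("P1", "p2"), np.zeros((2, 2)))
        assert m.compound_ids == ("a", "b")
        assert "A" in m and "a " in m


class TestMetadata:
    def _tables(self, tmp_path):
        compounds = _write(
            tmp_path / "c.tsv",
            "compound_id\tname\tsmiles\tis_psychoactive\tchem_class\n"
            "d1\tdrug one\t\tfalse\tnone\n"
            "d2\tdrug two\t\tfalse\tnone\n"
            "d3\tdrug three\t\tfalse\tnone\n"
            "psy1\tstimulant\tCC(N)Cc1ccccc1\ttrue\tamphetamine\n"
            "psy2\thallucinogen\tNCCc1c[nH]c2ccccc12\ttrue\ttryptamine\n",
        )
        indications = _write(
            tmp_path / "i.tsv",
            "mesh_id\tname\tis_mental_health\tapproved_compound_ids\n"
            "ind1\tfirst\ttrue\td1;d2\n"
            "ind2\tsecond\tfalse\td3\n",
        )
        return compounds, indications

    def _matrix(self, ids):
        return InteractionMatrix(
            tuple(ids), ("p1",), np.zeros((len(ids), 1))
        )

    def test_parse_fidelity(self, tmp_path):
        cpath, ipath = self._tables(tmp_path)
        matrix = self._matrix(["d1", "d2", "d3", "psy1", "psy2"])
        compounds, indications = load_metadata(cpath, ipath, matrix)
        assert len(compounds) == 5 and len(indications) == 2
        assert {c.compound_id for c in compounds if c.is_psychoactive} == {
            "psy1",
            "psy2",
        }
        ind1 = next(i for i in indications if i.mesh_id == "ind1")
        assert ind1.is_mental_health
        assert ind1.approved_compound_ids == {"d1", "d2"}

    def test_psychoactive_in_approved_list_is_an_error(self, tmp_path):
        cpath, _ = self._tables(tmp_path)
        ipath = _write(
            tmp_path / "bad.tsv",
            "mesh_id\tname\tis_mental_health\tapproved_compound_ids\n"
            "ind1\tfirst\ttrue\td1;psy1\n",
        )
        matrix = self._matrix(["d1", "d2", "d3", "psy1", "psy2"])
        with pytest.raises(ValidationError, match="psy1.*ind1"):
            load_metadata(cpath, ipath, matrix)

    def test_approved_compound_absent_from_matrix_is_an_error(self, tmp_path):
        cpath, ipath = self._tables(tmp_path)
        matrix = self._matrix(["d1", "d2", "psy1", "psy2"])  # d3 missing
        with pytest.raises(ValidationError, match="d3"):
            load_metadata(cpath, ipath, matrix)

    def test_empty_approved_list_is_accepted_but_unusable(self, tmp_path):
        ipath = _write(
            tmp_path / "i.tsv",
            "mesh_id\tname\tis_mental_health\tapproved_compound_ids\n"
            "ind1\tfirst\ttrue\t\n",
        )
        records = load_indications(ipath)
        assert len(records) == 1 and not records[0].usable

    def test_validation_is_order_independent(self, tmp_path):
        cpath, ipath = self._tables(tmp_path)
        cframe = pd.read_csv(cpath, sep="\t", keep_default_na=False)
        iframe = pd.read_csv(ipath, sep="\t", keep_default_na=False)
        cframe.iloc[::-1].to_csv(tmp_path / "c2.tsv", sep="\t", index=False)
        iframe.iloc[::-1].to_csv(tmp_path / "i2.tsv", sep="\t", index=False)
        matrix = self._matrix(["d1", "d2", "d3", "psy1", "psy2"])
        a = load_metadata(cpath, ipath, matrix)
        b = load_metadata(tmp_path / "c2.tsv", tmp_path / "i2.tsv", matrix)
        assert a == b

    def test_metadata_round_trip(self, tmp_path):
        compounds = [
            CompoundRecord("x1", "one", "CCO", True, "other"),
            CompoundRecord("x2", "two", None, False, "none"),
        ]
        indications = [
            IndicationRecord("m1", "ind", True, frozenset({"x2"})),
        ]
        save_compounds(compounds, tmp_path / "c.tsv")
        save_indications(indications, tmp_path / "i.tsv")
        assert load_compounds(tmp_path / "c.tsv") == sorted(
            compounds, key=lambda r: r.compound_id
        )
        assert load_indications(tmp_path / "i.tsv") == indications

    def test_chem_class_requires_psychoactive_flag(self):
        with pytest.raises(ValidationError, match="is_psychoactive"):
            CompoundRecord("x", is_psychoactive=False, chem_class="tryptamine")


class TestAnalysisConfig:
    def test_defaults_match_study_setup(self):
        config = AnalysisConfig()
        assert config.topx_values == (10, 25, 40, 100)
        assert config.association_thresholds == {10: 2, 25: 3, 40: 4, 100: 6}
        assert config.n_randomizations == 1000

    def test_threshold_for_unknown_topx_rejected(self):
        with pytest.raises(ValidationError, match="Top50"):
            AnalysisConfig(topx_values=(10,), association_thresholds={50: 2})

    def test_yaml_round_trip(self, tmp_path):
        config = AnalysisConfig(topx_values=(10, 25),
                                association_thresholds={10: 2}, seed=5)
        config.to_yaml(tmp_path / "cfg.yaml")
        assert AnalysisConfig.from_yaml(tmp_path / "cfg.yaml") == config


@pytest.mark.parametrize(
    "value,expected", [(63.6363, 64), (33.3333, 33), (0.5, 1), (70.0, 70)]
)
def test_display_percent_rounds_half_up(value, expected):
    assert display_percent(value) == expected
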