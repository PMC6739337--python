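import logging

import numpy as np
import pytest

from sigrank import AnalysisConfig
from sigrank.consensus import (
    ConsensusTable,
    PredictionEntry,
    build_consensus_table,
    predict_indication,
)
from sigrank.data_model import (
    IndicationRecord,
    InteractionMatrix,
    ValidationError,
)
from sigrank.similarity import rank_neighbors


def brute_force_consensus(indication, matrix, topx):
    """Independent recount from individual neighbour lists."""
    counts = {}
    for drug in sorted(indication.approved_compound_ids):
        for cid in rank_neighbors(drug, matrix).ids(topx):
            counts[cid] = counts.get(cid, 0) + 1
    return counts


def random_matrix(rng, n, p):
    return InteractionMatrix(
        tuple(f"c{i:02d}" for i in range(n)),
        tuple(f"p{j}" for j in range(p)),
        rng.normal(size=(n, p)),
    )


class TestPredictIndication:
    def test_membership_counting_on_six_compound_fixture(self):
        # Signatures laid out on a line: d1=0, d2=10, d3=20, cand=1, far=40,
        # mid=9.  With Top2 lists: d1 -> {cand, mid}, d2 -> {mid, cand}? no:
        # distances from d2: mid=1, cand=9, d1=10 -> {mid, cand};
        # d3 -> {mid(11), far(20)}.  cand appears for d1 and d2 only.
        m = InteractionMatrix(
            ("d1", "d2", "d3", "cand", "far", "mid"),
            ("p",),
            np.array([[0.0], [10.0], [20.0], [1.0], [40.0], [9.0]]),
        )
        ind = IndicationRecord(
            "ind1", approved_compound_ids=frozenset({"d1", "d2", "d3"})
        )
        entries = {
            e.compound_id: e for e in predict_indication(ind, m, topx=2)
        }
        assert entries["cand"].consensus_count == 2
        assert entries["cand"].percent_occurrence == pytest.approx(66.66667, abs=1e-3)
        assert not entries["cand"].already_approved

    def test_consensus_bounded_by_approved_count(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 70, 4)
        approved = frozenset(m.compound_ids[:65])
        ind = IndicationRecord("big", approved_compound_ids=approved)
        entries = predict_indication(ind, m, topx=25)
        assert max(e.consensus_count for e in entries) <= 65

    def test_saturation_when_topx_covers_all_compounds(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 12, 3)
        approved = frozenset(m.compound_ids[:4])
        ind = IndicationRecord("sat", approved_compound_ids=approved)
        entries = predict_indication(ind, m, topx=11)
        # Every non-query compound is in every list: the four approved
        # drugs are each missing only from their own list.
        for e in entries:
            expected = 3 if e.already_approved else 4
            assert e.consensus_count == expected
        assert sum(e.percent_occurrence == 100.0 for e in entries) == 8

    def test_consensus_mass_conservation(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 15, 5)
        approved = frozenset(m.compound_ids[:5])
        ind = IndicationRecord("cons", approved_compound_ids=approved)
        for topx in (3, 7, 14):
            entries = predict_indication(ind, m, topx=topx)
            assert sum(e.consensus_count for e in entries) == 5 * topx

    def test_empty_approved_list_is_an_error(self, tiny_matrix):
        with pytest.raises(ValidationError, match="unusable"):
            predict_indication(IndicationRecord("empty"), tiny_matrix, 2)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(5, 21))
            m = random_matrix(rng, n, int(rng.integers(2, 11)))
            k = int(rng.integers(1, min(6, n)))
            approved = frozenset(
                rng.choice(m.compound_ids, size=k, replace=False)
            )
            ind = IndicationRecord("x", approved_compound_ids=approved)
            topx = int(rng.integers(1, n))
            got = {
                e.compound_id: e.consensus_count
                for e in predict_indication(ind, m, topx)
            }
            assert got == brute_force_consensus(ind, m, topx)


class TestBuildConsensusTable:
    def test_full_coverage_of_indications_and_topx(self, default_consensus):
        table = default_consensus
        assert table.topx_levels == (10, 25)
        for topx in (10, 25):
            sub = table.at_topx(topx)
            assert sub["indication_id"].nunique() == 480

    def test_topx_nesting_monotonicity(self, default_consensus):
        t10 = default_consensus.at_topx(10)
        t25 = default_consensus.at_topx(25)
        m10 = t10.set_index(["indication_id", "compound_id"])["consensus_count"]
        m25 = t25.set_index(["indication_id", "compound_id"])["consensus_count"]
        assert set(m10.index) <= set(m25.index)
        aligned = m25.reindex(m10.index)
        assert (m10 <= aligned).all()

    def test_iteration_order_of_indications_is_irrelevant(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 20, 5)
        inds = [
            IndicationRecord(
                f"i{k}",
                approved_compound_ids=frozenset(
                    rng.choice(m.compound_ids, size=3, replace=False)
                ),
            )
            for k in range(4)
        ]
        config = AnalysisConfig(topx_values=(5,), association_thresholds={5: 2})
        a = build_consensus_table(inds, m, config)
        b = build_consensus_table(inds[::-1], m, config)
        assert a.entries.equals(b.entries)

    def test_unusable_indications_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 10, 3)
        inds = [
            IndicationRecord(
                "good", approved_compound_ids=frozenset(m.compound_ids[:2])
            ),
            IndicationRecord("empty"),
            IndicationRecord(
                "orphan", approved_compound_ids=frozenset({"nonexistent"})
            ),
        ]
        config = AnalysisConfig(topx_values=(3,), association_thresholds={3: 2})
        with caplog.at_level(logging.WARNING):
            table = build_consensus_table(inds, m, config)
        assert set(table.entries["indication_id"]) == {"good"}
        assert "empty" in caplog.text and "orphan" in caplog.text

    def test_duplicate_entries_rejected(self):
        e = PredictionEntry("i", "c", 10, 1, 50.0, False)
        with pytest.raises(ValidationError, match="duplicate"):
            ConsensusTable.from_entries([e, e])

    def test_save_load_round_trip(self, tmp_path, default_consensus):
        path = tmp_path / "consensus.tsv"
        default_consensus.save(path)
        back = ConsensusTable.load(path)
        assert back.entries.shape == default_consensus.entries.shape
        a = default_consensus.entries.sort_values(
            ["topx", "indication_id", "compound_id"]
        ).reset_index(drop=True)
        b = back.entries.sort_values(
            ["topx", "indication_id", "compound_id"]
        ).reset_index(drop=True)
        assert a[["consensus_count"]].equals(b[["consensus_count"]])
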