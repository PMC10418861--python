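"""Hub selection, per-hub simulations, back-/cross-evaluation and the final
candidate ranking, including regression against the shipped hub-score
fixture (reference scores with synthetic placeholder CUIs in the C9xxxxxx
range)."""

import pytest

from hetepath import (
    SimulationSpec,
    back_evaluate,
    cross_evaluate,
    final_ranking,
    run_hub_layer,
    select_hubs,
)
from hetepath.hubs import load_hub_scores
from hetepath.simulation import RankedResult

from .conftest import DISEASE, build_g1

EBASTINE = "C9200005"
SLC33A1, ANTIHISTAMINE, DRD2, EEF1A2, GRM1 = (
    "C9100011", "C9100001", "C9100003", "C9100004", "C9100005",
)


def _result(cui, score, rank=1, semtype="DSYN", name=None):
    return RankedResult(
        source_cui=cui,
        source_name=name or cui,
        source_semtype=semtype,
        raw_score=score,
        normalized_score=score,
        rank=rank,
        n_metapaths=1,
    )


@pytest.fixture
def fixture_hub_results(hub_scores_path):
    return load_hub_scores(hub_scores_path)


class TestSelectHubs:
    def test_all_above_threshold_kept_in_order(self):
        results = [
            _result("C9100007", 0.927, 1, name="granuloma"),
            _result("C9100009", 0.499, 2, name="liver injury"),
            _result("C9100010", 0.341, 3, name="renal"),
        ]
        sel = select_hubs(results, threshold=0.2, max_hubs=14)
        assert [h.source_name for h in sel.hubs] == ["granuloma", "liver injury", "renal"]

    def test_below_threshold_yields_empty_selection(self):
        sel = select_hubs([_result("C9100001", 0.19)], threshold=0.2, max_hubs=5)
        assert sel.hubs == ()

    def test_max_hubs_truncates(self):
        results = [_result(f"C910000{i}", 0.9 - 0.1 * i, i + 1) for i in range(3)]
        sel = select_hubs(results, threshold=0.2, max_hubs=2)
        assert len(sel.hubs) == 2
        assert sel.cuis == (results[0].source_cui, results[1].source_cui)

    def test_semtype_restriction(self):
        results = [_result("C9100001", 0.9, semtype="GNGM"), _result("C9100002", 0.8)]
        sel = select_hubs(results, allowed_semtypes={"GNGM"})
        assert sel.cuis == ("C9100001",)


class TestRunHubLayer:
    def template(self):
        return SimulationSpec(
            name="hub",
            target_cuis=("C0000000",),
            source_semtypes=frozenset({"PHSU"}),
            max_metapath_length=2,
        )

    def test_one_simulation_per_hub(self, g1):
        hubs = select_hubs(
            [_result("C9000011", 0.9, semtype="GNGM"), _result("C9000012", 0.8, semtype="GNGM")]
        )
        out = run_hub_layer(g1, hubs, self.template())
        assert sorted(out) == ["C9000011", "C9000012"]

    def test_hub_excluded_from_its_own_candidates(self, g1):
        hubs = select_hubs([_result("C9000001", 0.9, semtype="PHSU")])
        out = run_hub_layer(g1, hubs, self.template())
        assert "C9000001" not in {r.source_cui for r in out["C9000001"]}

    def test_missing_hub_recorded_others_proceed(self, g1, caplog):
        import logging

        hubs = select_hubs(
            [_result("C9000011", 0.9, semtype="GNGM"), _result("C0123456", 0.8)]
        )
        with caplog.at_level(logging.ERROR):
            out = run_hub_layer(g1, hubs, self.template())
        assert sorted(out) == ["C9000011"]
        assert any("C0123456" in r.message for r in caplog.records)


class TestBackEvaluate:
    def test_fixture_candidate_passes_in_five_hubs_descending(self, fixture_hub_results):
        count, passed = back_evaluate(EBASTINE, fixture_hub_results, threshold=0.2)
        assert count == 5
        assert passed == [
            (SLC33A1, 0.585),
            (ANTIHISTAMINE, 0.446),
            (DRD2, 0.399),
            (EEF1A2, 0.398),
            (GRM1, 0.369),
        ]

    def test_absent_candidate_yields_zero(self, fixture_hub_results):
        assert back_evaluate("C9999998", fixture_hub_results) == (0, [])

    def test_zero_threshold_returns_every_containing_hub(self, fixture_hub_results):
        count, _ = back_evaluate(EBASTINE, fixture_hub_results, threshold=0.0)
        assert count == 5  # fixture only stores passing cells

    def test_empty_hub_results_is_error(self):
        with pytest.raises(ValueError):
            back_evaluate(EBASTINE, {})


class TestCrossEvaluate:
    def test_fixture_recurrences(self, fixture_hub_results):
        table = cross_evaluate(fixture_hub_results, threshold=0.2)
        assert table.recurrence["C9200001"] == 8  # vancomycin
        assert table.recurrence["C9200002"] == 8  # captopril
        assert table.recurrence["C9200003"] == 6  # neramexane
        assert table.recurrence["C9200004"] == 4  # levocetirizine
        assert table.recurrence[EBASTINE] == 5

    def test_fixture_row_rendering_descending(self, fixture_hub_results):
        table = cross_evaluate(fixture_hub_results, threshold=0.2)
        assert table.row_rendering(EBASTINE) == [
            (SLC33A1, 0.585),
            (ANTIHISTAMINE, 0.446),
            (DRD2, 0.399),
            (EEF1A2, 0.398),
            (GRM1, 0.369),
        ]

    def test_fixture_mean_score(self, fixture_hub_results):
        table = cross_evaluate(fixture_hub_results, threshold=0.2)
        assert table.mean_score[EBASTINE] == pytest.approx(0.4394, abs=1e-12)

    def test_columns_render_descending(self, fixture_hub_results):
        table = cross_evaluate(fixture_hub_results, threshold=0.2)
        for hub in table.scores.columns:
            col = [v for _, v in table.column_rendering(hub)]
            assert col == sorted(col, reverse=True)

    def test_disjoint_hubs_all_recurrence_one(self):
        hub_results = {
            "C9100001": [_result("C9200001", 0.5, semtype="PHSU")],
            "C9100002": [_result("C9200002", 0.6, semtype="PHSU")],
        }
        table = cross_evaluate(hub_results)
        assert set(table.recurrence.index) == {"C9200001", "C9200002"}
        assert all(table.recurrence == 1)

    def test_fewer_than_two_simulations_is_error(self):
        with pytest.raises(ValueError):
            cross_evaluate({"C9100001": []})

    def test_recurrence_matches_back_evaluation(self, fixture_hub_results):
        table = cross_evaluate(fixture_hub_results, threshold=0.2)
        for cand in table.scores.index:
            count, _ = back_evaluate(cand, fixture_hub_results, threshold=0.2)
            assert count == table.recurrence[cand]

    def test_raising_threshold_never_increases_recurrence(self, fixture_hub_results):
        low = cross_evaluate(fixture_hub_results, threshold=0.2)
        high = cross_evaluate(fixture_hub_results, threshold=0.4)
        for cand in high.scores.index:
            assert high.recurrence[cand] <= low.recurrence[cand]


class TestFinalRanking:
    def test_mean_breaks_recurrence_tie(self, fixture_hub_results):
        table = cross_evaluate(fixture_hub_results, threshold=0.2)
        names = {c: (c, "PHSU") for c in table.scores.index}
        final = final_ranking([], table, names=names)
        by_cui = {f.cui: f for f in final}
        a = by_cui["C9200001"]  # vancomycin, recurrence 8
        b = by_cui["C9200002"]  # captopril, recurrence 8
        assert a.recurrence == b.recurrence == 8
        winner = a if a.mean_score > b.mean_score else b
        assert winner.rank < (b if winner is a else a).rank

    def test_recurrence_dominates_mean_score(self):
        hub_results = {
            f"C91000{i:02d}": [
                _result("C9200010", 0.4, semtype="PHSU"),
            ]
            for i in range(3)
        }
        hub_results["C9100099"] = [_result("C9200011", 1.0, semtype="PHSU")]
        table = cross_evaluate(hub_results)
        names = {"C9200010": ("thrice", "PHSU"), "C9200011": ("once", "PHSU")}
        final = final_ranking([], table, names=names)
        assert [f.name for f in final] == ["thrice", "once"]

    def test_candidate_semtype_restriction(self, fixture_hub_results):
        table = cross_evaluate(fixture_hub_results, threshold=0.2)
        names = {c: (c, "PHSU") for c in table.scores.index}
        names["C9200001"] = ("vancomycin", "DSYN")  # pretend it's not a drug
        final = final_ranking([], table, candidate_semtypes=("PHSU",), names=names)
        assert "C9200001" not in {f.cui for f in final}
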