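"""Ranking, hit statistics, summary means and report rendering."""

import pandas as pd
import pytest

from aisid import (
    PairScore,
    ScreenResult,
    hit_statistics,
    rank_candidates,
    read_annotations,
    render_heatmap,
    summary_means,
)
from conftest import planted_result


def pair(bait, lig, score):
    return PairScore(bait_id=bait, ligand_id=lig, aisidscore=score,
                     best_model_id="m1", n_models=25)


class TestScreenResult:
    def test_duplicate_ligand_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ScreenResult("b", [pair("b", "x", 0.1), pair("b", "x", 0.2)])

    def test_unknown_annotation_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            ScreenResult("b", [pair("b", "x", 0.1)], annotations={"y"})


class TestRankCandidates:
    def test_descending_with_ranks(self):
        res = ScreenResult("b", [pair("b", "x", 0.2), pair("b", "y", 0.9)],
                           annotations={"y"})
        table = rank_candidates(res)
        assert table["rank"].tolist() == [1, 2]
        assert table["ligand_id"].tolist() == ["y", "x"]
        assert table["is_known_pair"].tolist() == [True, False]

    def test_single_candidate(self):
        table = rank_candidates(ScreenResult("b", [pair("b", "x", 0.5)]))
        assert table["rank"].tolist() == [1]

    def test_tie_broken_by_ligand_id(self):
        res = ScreenResult("bait", [pair("bait", "b", 0.5), pair("bait", "a", 0.5)])
        assert rank_candidates(res)["ligand_id"].tolist() == ["a", "b"]

    def test_empty_scores_raise(self):
        with pytest.raises(ValueError):
            rank_candidates(ScreenResult("b", []))

    def test_output_is_permutation_of_panel(self):
        res = planted_result("b", {3, 7})
        table = rank_candidates(res)
        assert sorted(table["ligand_id"]) == sorted(res.ligand_ids)


class TestHitStatistics:
    def test_small_exhaustive_case(self):
        # one bait, 3 candidates, the true pair ranked second
        res = planted_result("b", {2}, n_ligands=3)
        stats = hit_statistics([res], k_values=(1, 3))
        assert stats["top_k"] == {1: 0, 3: 1}
        assert stats["top1_baits"] == 0
        assert stats["total_annotated_pairs"] == 1

    def test_no_annotations_yields_zero_counts(self):
        res = planted_result("b", set())
        stats = hit_statistics([res])
        assert stats["total_annotated_pairs"] == 0
        assert stats["top_k"] == {1: 0, 3: 0, 5: 0}
        assert stats["n_annotated_baits"] == 0

    def test_planted_ranks_hand_count(self):
        # planted annotated ranks over five baits: 1, 1, 2, 4, 6
        results = [planted_result(f"b{i}", {r}) for i, r in enumerate([1, 1, 2, 4, 6])]
        stats = hit_statistics(results, k_values=(1, 3, 5))
        assert stats["top_k"] == {1: 2, 3: 3, 5: 4}
        assert stats["top1_baits"] == 2
        assert stats["total_annotated_pairs"] == 5

    def test_multi_ligand_bait_counts_each_pair(self):
        res = planted_result("b", {1, 2, 9})
        stats = hit_statistics([res], k_values=(1, 3, 5))
        assert stats["top_k"] == {1: 1, 3: 2, 5: 2}
        best_only = hit_statistics([res], k_values=(1, 3, 5), best_pair_only=True)
        assert best_only["top_k"] == {1: 1, 3: 1, 5: 1}
        assert best_only["total_annotated_pairs"] == 1

    def test_monotone_in_k(self):
        results = [planted_result(f"b{i}", {r}) for i, r in enumerate([1, 2, 5, 8, 18])]
        stats = hit_statistics(results, k_values=(1, 3, 5))
        assert (
            stats["top_k"][1] <= stats["top_k"][3] <= stats["top_k"][5]
            <= stats["total_annotated_pairs"]
        )

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            hit_statistics([planted_result("b", {1})], k_values=(0,))


class TestSummaryMeans:
    def test_no_annotations_mean_undefined(self):
        res = ScreenResult("b", [pair("b", "x", 0.2), pair("b", "y", 0.4)])
        means = summary_means([res])
        assert means.mean_all == pytest.approx(0.3)
        assert means.mean_annotated is None
        assert means.mean_control is None

    def test_annotated_subset(self):
        res = ScreenResult("b", [pair("b", "x", 0.9), pair("b", "y", 0.1)],
                           annotations={"x"})
        means = summary_means([res])
        assert means.mean_annotated == pytest.approx(0.9)
        assert (means.min_all, means.max_all) == (0.1, 0.9)

    def test_control_bait_mean(self):
        good = ScreenResult("b", [pair("b", "x", 0.8)], annotations={"x"})
        ctrl = ScreenResult("neg", [pair("neg", "x", 0.1)])
        means = summary_means([good, ctrl], control_bait_ids=["neg"])
        assert means.mean_control == pytest.approx(0.1)
        assert means.mean_all == pytest.approx(0.45)

    def test_matches_bruteforce_on_mixed_screen(self):
        results = [planted_result(f"b{i}", {i + 1}) for i in range(4)]
        means = summary_means(results)
        flat = [s.aisidscore for r in results for s in r.scores]
        assert means.mean_all == pytest.approx(sum(flat) / len(flat))


class TestRenderHeatmap:
    def make_results(self):
        r1 = ScreenResult("b1", [pair("b1", "x", 0.9), pair("b1", "y", 0.2),
                                 pair("b1", "z", 0.1)], annotations={"x"})
        r2 = ScreenResult("b2", [pair("b2", "x", 0.3), pair("b2", "y", 0.5),
                                 pair("b2", "z", 0.4)])
        return [r1, r2]

    def test_matrix_and_image_written(self, tmp_path):
        tsv, img = render_heatmap(self.make_results(), tmp_path / "heat",
                                  control_bait_ids=["b2"])
        assert img.exists() and img.stat().st_size > 0
        df = pd.read_csv(tsv, sep="\t", index_col="bait_id")
        assert df.shape == (2, 4)  # 3 ligands + best_known_rank
        assert df.at["b1", "x"] == pytest.approx(0.9)
        assert df.at["b1", "best_known_rank"] == "1"
        assert df.at["b2", "best_known_rank"] == "none"

    def test_unknown_rank_label(self, tmp_path):
        tsv, _ = render_heatmap(self.make_results(), tmp_path / "heat")
        df = pd.read_csv(tsv, sep="\t", index_col="bait_id")
        assert df.at["b2", "best_known_rank"] == "unknown"

    def test_cellwise_oracle(self, tmp_path):
        results = self.make_results()
        tsv, _ = render_heatmap(results, tmp_path / "heat")
        df = pd.read_csv(tsv, sep="\t", index_col="bait_id")
        for r in results:
            for s in r.scores:
                assert df.at[r.bait_id, s.ligand_id] == pytest.approx(
                    round(s.aisidscore, 3)
                )

    def test_inconsistent_panels_error_lists_difference(self, tmp_path):
        r1 = ScreenResult("b1", [pair("b1", "x", 0.1)])
        r2 = ScreenResult("b2", [pair("b2", "y", 0.1)])
        with pytest.raises(ValueError, match="symmetric difference"):
            render_heatmap([r1, r2], tmp_path / "heat")


def test_read_annotations(tmp_path):
    p = tmp_path / "ann.tsv"
    p.write_text("bait_id\tligand_id\nb1\tx\nb1\ty\nb2\tz\n")
    assert read_annotations(p) == {"b1": {"x", "y"}, "b2": {"z"}}
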