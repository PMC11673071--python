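import numpy as np
import pandas as pd
import pytest

from npvuln import (
    AHNPCriteria,
    ClusterAnnotationRecord,
    GeneList,
    ValidationError,
    classify_ahnp,
    dissection_membership_breakdown,
    estimate_regional_counts,
    rank_top_regions,
    split_np_tags,
)
from npvuln.regional import read_cluster_annotation, round_half_up, write_cluster_annotation

ADNP = GeneList("adnp", [f"A{i}" for i in range(1, 7)])
NP = GeneList("np", [f"A{i}" for i in range(1, 7)] + ["X1", "X2", "X3"])


def _record(tags, cells=1000, pcts=None, cid="C1", **attrs):
    return ClusterAnnotationRecord(cid, set(tags), cells, pcts or {"D1": 100.0}, **attrs)


class TestTagSplitting:
    def test_set_arithmetic(self):
        record = _record([f"A{i}" for i in range(1, 7)] + ["X1", "X2"])
        assert split_np_tags(record, ADNP, NP) == (6, 2)

    def test_empty_tags(self):
        assert split_np_tags(_record([]), ADNP, NP) == (0, 0)

    def test_unknown_tag_excluded_from_both_counts(self):
        record = _record(["A1", "UNKNOWN-TAG"])
        assert split_np_tags(record, ADNP, NP) == (1, 0)


class TestClassification:
    @pytest.mark.parametrize("n_adnp,n_non,expected", [
        (6, 2, True),   # inclusive on the ADNP bound
        (6, 3, False),  # strictly fewer than 3 non-ADNPs
        (5, 0, False),  # 6+ ADNPs required
        (6, 0, True),
    ])
    def test_boundaries(self, n_adnp, n_non, expected):
        tags = [f"A{i}" for i in range(1, n_adnp + 1)] + [f"X{i}" for i in range(1, n_non + 1)]
        assert classify_ahnp(_record(tags), AHNPCriteria(), ADNP, NP) is expected

    def test_monotone_in_adnp_tags(self):
        # adding an ADNP tag never flips true -> false
        for n_non in range(3):
            previous = False
            for n_adnp in range(0, 7):
                tags = [f"A{i}" for i in range(1, n_adnp + 1)] + [f"X{i}" for i in range(1, n_non + 1)]
                current = classify_ahnp(_record(tags), AHNPCriteria(), ADNP, NP)
                assert current or not previous
                previous = current


class TestRegionalEstimates:
    def test_proportional_attribution(self):
        record = _record([f"A{i}" for i in range(1, 7)], cells=1000,
                         pcts={"A": 40.0, "B": 60.0})
        table = estimate_regional_counts([record], ADNP, NP, level="dissection")
        by = table.set_index("region_or_dissection")["ahnp_cell_estimate"]
        assert by["A"] == pytest.approx(400)
        assert by["B"] == pytest.approx(600)

    def test_shortfall_not_renormalized(self):
        record = _record([f"A{i}" for i in range(1, 7)], cells=1000,
                         pcts={"A": 50.0, "B": 40.0})
        table = estimate_regional_counts([record], ADNP, NP, level="dissection")
        assert table["ahnp_cell_estimate"].sum() == pytest.approx(900)

    def test_overfull_percentages_name_cluster(self):
        record = _record([f"A{i}" for i in range(1, 7)], pcts={"A": 70.0, "B": 40.0}, cid="BAD")
        with pytest.raises(ValidationError, match="BAD"):
            estimate_regional_counts([record], ADNP, NP, level="dissection")

    def test_region_level_sums_dissections(self):
        records = [
            _record([f"A{i}" for i in range(1, 7)], cells=100, pcts={"D1": 100.0}, cid="C1"),
            _record([f"A{i}" for i in range(1, 7)], cells=200, pcts={"D2": 100.0}, cid="C2"),
        ]
        region_map = {"D1": "R", "D2": "R"}
        regions = estimate_regional_counts(records, ADNP, NP, region_map=region_map, level="region")
        dissections = estimate_regional_counts(records, ADNP, NP, level="dissection")
        assert regions["ahnp_cell_estimate"].iloc[0] == pytest.approx(
            dissections["ahnp_cell_estimate"].sum())

    def test_non_ahnp_clusters_excluded(self):
        records = [
            _record([f"A{i}" for i in range(1, 7)], cells=100, cid="yes"),
            _record(["A1", "A2"], cells=9999, cid="no"),
        ]
        table = estimate_regional_counts(records, ADNP, NP, level="dissection")
        assert table["ahnp_cell_estimate"].iloc[0] == pytest.approx(100)

    def test_generator_ground_truth_recovered_exactly(self):
        from npvuln import AnnotationGeneratorParams, generate_cluster_annotation
        params = AnnotationGeneratorParams(seed=11)
        records, region_map, truth = generate_cluster_annotation(params)
        table = estimate_regional_counts(records, params.adnp_list, params.np_panel,
                                         region_map=region_map, level="region")
        estimated = {row["region_or_dissection"]: round_half_up(row["ahnp_cell_estimate"])
                     for _, row in table.iterrows()}
        assert estimated == truth["per_region"]
        ranking = list(table["region_or_dissection"])
        assert ranking == truth["ranking"]


class TestRanking:
    def _table(self, estimates, names=None):
        names = names or [f"R{i}" for i in range(len(estimates))]
        return pd.DataFrame({"region_or_dissection": names,
                             "ahnp_cell_estimate": estimates,
                             "n_contributing_clusters": [1] * len(estimates)})

    def test_top_k(self):
        top = rank_top_regions(self._table([10, 30, 20]), k=2)
        assert list(top["region_or_dissection"]) == ["R1", "R2"]

    def test_alphabetical_tie_break(self):
        top = rank_top_regions(self._table([5, 5], names=["zeta", "alpha"]), k=2)
        assert list(top["region_or_dissection"]) == ["alpha", "zeta"]

    def test_k_exceeding_rows(self):
        assert len(rank_top_regions(self._table([1, 2]), k=5)) == 2


class TestBreakdown:
    def _records(self):
        ahnp_tags = [f"A{i}" for i in range(1, 7)]
        return [
            _record(ahnp_tags, cells=800, pcts={"MEC": 50.0, "X": 30.0, "Y": 20.0},
                    cid="C1", neurotransmitter="GABA"),
            _record(ahnp_tags, cells=500, pcts={"MEC": 20.0, "X": 30.0, "Y": 25.0, "Z": 25.0},
                    cid="C2", neurotransmitter="GABA"),  # MEC ranks 4th -> excluded
            _record(ahnp_tags, cells=1000, pcts={"MEC": 10.0, "X": 90.0},
                    cid="C3", neurotransmitter=None),
        ]

    def test_top_rank_inclusion_and_grouping(self):
        grouped = dissection_membership_breakdown(self._records(), "MEC", ADNP, NP)
        by = grouped.set_index("group")["cells"]
        assert by["GABA"] == pytest.approx(400)  # only C1: 800 * 50%
        assert by["unannotated"] == pytest.approx(100)  # C3: MEC rank 2 of 2

    def test_unknown_dissection_lists_known(self):
        with pytest.raises(ValidationError, match="MEC"):
            dissection_membership_breakdown(self._records(), "NOPE", ADNP, NP)

    def test_grouped_sum_across_clusters(self):
        ahnp_tags = [f"A{i}" for i in range(1, 7)]
        records = [
            _record(ahnp_tags, cells=800, pcts={"MEC": 50.0}, cid="C1", neurotransmitter="GABA"),
            _record(ahnp_tags, cells=200, pcts={"MEC": 50.0}, cid="C2", neurotransmitter="GABA"),
        ]
        grouped = dissection_membership_breakdown(records, "MEC", ADNP, NP)
        assert grouped.set_index("group")["cells"]["GABA"] == pytest.approx(500)


class TestAnnotationIO:
    def test_round_trip(self, tmp_path):
        records = [
            _record(["A1", "X1"], cells=123, pcts={"D1": 60.0, "D2": 40.0}, cid="C1",
                    neurotransmitter="GABA", subtype="SST", mtg_label="Inh L1-2"),
            _record([], cells=7, pcts={"D1": 100.0}, cid="C2"),
        ]
        path = tmp_path / "ann.csv"
        write_cluster_annotation(records, path)
        again = read_cluster_annotation(path)
        assert [r.cluster_id for r in again] == ["C1", "C2"]
        assert again[0].np_tags == {"A1", "X1"}
        assert again[0].dissection_percentages == {"D1": 60.0, "D2": 40.0}
        assert again[0].subtype == "SST"
        assert again[1].np_tags == set()


class TestRounding:
    @pytest.mark.parametrize("value,expected", [(0.5, 1), (1.5, 2), (2.4, 2), (2.5, 3), (-0.0, 0)])
    def test_half_up(self, value, expected):
        assert round_half_up(value) == expected
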