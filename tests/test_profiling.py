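from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npvuln import (
    GeneExpressionMatrix,
    QCThresholds,
    StratumScheme,
    ValidationError,
    compare_stratum_proportions,
    count_np_coexpression,
    cpm_normalize,
    log_transform,
    np_count_abundance_correlation,
    qc_filter,
    stratify,
    stratum_proportions,
    subsample_donors,
)


def _matrix(values, genes=None, cells=None, layer="raw_counts"):
    values = np.asarray(values)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return GeneExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells), layer)


class TestQCFilter:
    def _cohort(self):
        # cell expressed-gene counts: 150, 300, 300; mito 1%, 6%, 1%
        rng = np.random.default_rng(0)
        values = np.zeros((400, 3), dtype=int)
        values[:150, 0] = 1
        values[:300, 1] = 1
        values[:300, 2] = 1
        matrix = _matrix(values)
        meta = pd.DataFrame({"donor_id": ["d"] * 3, "condition": ["CT"] * 3,
                             "pct_mito": [0.01, 0.06, 0.01]}, index=matrix.obs_ids)
        return matrix, meta

    def test_bounds_applied_per_criterion(self):
        matrix, meta = self._cohort()
        kept, tally = qc_filter(matrix, meta, QCThresholds(200, 2500, 0.05))
        assert kept.obs_ids == ["c2"]  # c0 too few genes, c1 too much mito
        assert tally["removed_min_genes"] == 1
        assert tally["removed_mito"] == 1
        assert tally["retained"] == 1

    def test_mito_computed_from_gene_prefix_when_meta_absent(self):
        values = np.array([[90, 100], [10, 2]])
        matrix = _matrix(values, genes=["G1", "MT-ND1"])
        kept, _ = qc_filter(matrix, None, QCThresholds(1, 10, 0.05))
        assert kept.obs_ids == ["c1"]  # c0 has 10% mito

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            QCThresholds(min_genes=10, max_genes=5)


class TestNormalization:
    def test_cpm_columns_sum_to_one_million(self, rng):
        matrix = _matrix(rng.integers(0, 20, (100, 50)))
        cpm = cpm_normalize(matrix)
        totals = cpm.data.to_numpy().sum(axis=0)
        nonzero = totals > 0
        assert np.allclose(totals[nonzero], 1e6, rtol=1e-6)

    def test_cpm_simple_values(self):
        cpm = cpm_normalize(_matrix([[1], [1]]))
        assert np.allclose(cpm.data.to_numpy().ravel(), [5e5, 5e5])

    def test_zero_column_flagged_not_scaled(self):
        cpm = cpm_normalize(_matrix([[1, 0], [1, 0]]))
        assert cpm.zero_obs == ("c1",)
        assert (cpm.data["c1"] == 0).all()

    def test_log_transform_values_and_inverse(self, rng):
        matrix = _matrix([[0.0, 3.0]], layer="tpm")
        logged = log_transform(matrix)
        assert logged.layer == "log_tpm"
        assert logged.data.iloc[0, 0] == 0.0
        assert logged.data.iloc[0, 1] == 2.0
        values = rng.random((10, 5)) * 100
        roundtrip = np.exp2(log_transform(_matrix(values, layer="tpm")).data.to_numpy()) - 1
        assert np.allclose(roundtrip, values, atol=1e-9)

    def test_zero_pseudocount_with_zeros_rejected(self):
        with pytest.raises(ValidationError):
            log_transform(_matrix([[0.0]], layer="tpm"), pseudocount=0)


class TestCoexpressionCounting:
    def test_count_and_sum(self, small_counts, np_list):
        profiles = count_np_coexpression(small_counts, np_list)
        assert profiles.loc["c1", "np_count"] == 3
        assert profiles.loc["c1", "np_transcript_sum"] == 6
        assert profiles.loc["c2", "np_count"] == 0
        assert profiles.loc["c2", "np_transcript_sum"] == 0

    def test_full_panel_cell(self):
        genes = [f"NP{i}" for i in range(10)]
        matrix = _matrix(np.ones((10, 1)), genes=genes)
        from npvuln import GeneList
        profiles = count_np_coexpression(matrix, GeneList("np", genes))
        assert profiles.iloc[0]["np_count"] == 10
        assert profiles.iloc[0]["np_transcript_sum"] == 10

    def test_empty_intersection_is_error(self, small_counts):
        from npvuln import GeneList
        with pytest.raises(ValidationError):
            count_np_coexpression(small_counts, GeneList("other", ["XYZ"]))

    def test_count_invariant_under_positive_rescaling(self, small_counts, np_list):
        base = count_np_coexpression(small_counts, np_list)["np_count"]
        scaled = GeneExpressionMatrix(small_counts.data * 37.5, "raw_counts")
        assert (count_np_coexpression(scaled, np_list)["np_count"] == base).all()


class TestStratification:
    @pytest.mark.parametrize("count,expected", [
        (0, "low"), (1, "low"), (2, "mid"), (5, "mid"), (6, "high"), (40, "high"),
    ])
    def test_default_boundaries(self, count, expected):
        profiles = pd.DataFrame({"np_count": [count]}, index=["c"])
        assert stratify(profiles)["stratum"].iloc[0] == expected

    def test_partition_is_exhaustive(self, rng):
        counts = rng.integers(0, 30, 500)
        profiles = stratify(pd.DataFrame({"np_count": counts}))
        sizes = profiles["stratum"].value_counts()
        assert sizes.sum() == 500

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValidationError):
            StratumScheme(low_max=5, mid_max=5)


class TestCorrelation:
    def test_perfect_monotone(self):
        profiles = pd.DataFrame({"np_count": [1, 2, 3], "np_transcript_sum": [10, 20, 30]})
        assert np_count_abundance_correlation(profiles).estimate == pytest.approx(1.0)

    def test_derived_rho_half(self):
        profiles = pd.DataFrame({"np_count": [1, 2, 3], "np_transcript_sum": [2, 1, 3]})
        assert np_count_abundance_correlation(profiles).estimate == pytest.approx(0.5)

    def test_perfect_antimonotone(self):
        profiles = pd.DataFrame({"np_count": [1, 2, 3], "np_transcript_sum": [30, 20, 10]})
        assert np_count_abundance_correlation(profiles).estimate == pytest.approx(-1.0)

    def test_zero_variance_is_error(self):
        profiles = pd.DataFrame({"np_count": [1, 1, 1], "np_transcript_sum": [1, 2, 3]})
        with pytest.raises(ValueError):
            np_count_abundance_correlation(profiles)

    def test_invariant_under_monotone_transform(self, rng):
        counts = rng.integers(0, 10, 50)
        sums = counts * 2.0 + rng.random(50)
        base = np_count_abundance_correlation(
            pd.DataFrame({"np_count": counts, "np_transcript_sum": sums}))
        transformed = np_count_abundance_correlation(
            pd.DataFrame({"np_count": counts, "np_transcript_sum": np.exp(sums / 10)}))
        assert transformed.estimate == pytest.approx(base.estimate, abs=1e-12)


def _props(counts_by_donor, conditions):
    rows = []
    profiles = []
    meta_rows = []
    for donor, counts in counts_by_donor.items():
        for i, c in enumerate(counts):
            obs = f"{donor}_{i}"
            profiles.append({"obs_id": obs, "np_count": c, "np_transcript_sum": float(c)})
            meta_rows.append({"obs_id": obs, "donor_id": donor, "condition": conditions[donor]})
    prof = stratify(pd.DataFrame(profiles).set_index("obs_id"))
    meta = pd.DataFrame(meta_rows).set_index("obs_id")
    return stratum_proportions(prof, meta)


class TestStratumProportions:
    def test_direct_division(self):
        props = _props({"d1": [0] * 7 + [3] * 2 + [8]}, {"d1": "CT"})
        by_stratum = props.set_index("stratum")["proportion"]
        assert by_stratum["low"] == pytest.approx(0.7)
        assert by_stratum["mid"] == pytest.approx(0.2)
        assert by_stratum["high"] == pytest.approx(0.1)

    def test_all_low_donor_reports_zero_strata(self):
        props = _props({"d1": [0, 1, 0]}, {"d1": "CT"})
        by_stratum = props.set_index("stratum")
        assert by_stratum.loc["low", "proportion"] == 1.0
        assert by_stratum.loc["high", "n_cells"] == 0

    def test_proportions_sum_to_one_per_donor(self, rng):
        donors = {f"d{i}": rng.integers(0, 12, 30).tolist() for i in range(6)}
        conditions = {d: ("CT" if i < 3 else "AD") for i, d in enumerate(donors)}
        props = _props(donors, conditions)
        sums = props.groupby("donor_id")["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestCompareStratumProportions:
    def test_exact_p_for_full_separation(self):
        records = pd.DataFrame({
            "donor_id": [f"d{i}" for i in range(6)],
            "condition": ["CT"] * 3 + ["AD"] * 3,
            "stratum": ["high"] * 6,
            "n_cells": [1] * 6,
            "proportion": [0.30, 0.40, 0.35, 0.10, 0.05, 0.12],
        })
        res = compare_stratum_proportions(records, "CT", "AD", "high", "greater")
        assert res.p_value == pytest.approx(1 / comb(6, 3))

    def test_identical_groups_two_sided_p_one(self):
        records = pd.DataFrame({
            "donor_id": [f"d{i}" for i in range(6)],
            "condition": ["CT"] * 3 + ["AD"] * 3,
            "stratum": ["high"] * 6,
            "n_cells": [1] * 6,
            "proportion": [0.1, 0.2, 0.3, 0.1, 0.2, 0.3],
        })
        res = compare_stratum_proportions(records, "CT", "AD", "high", "two_sided")
        assert res.p_value == 1.0

    def test_label_swap_symmetry(self, rng):
        prop_a = rng.random(5).round(3)
        prop_b = rng.random(4).round(3)
        records = pd.DataFrame({
            "donor_id": [f"d{i}" for i in range(9)],
            "condition": ["CT"] * 5 + ["AD"] * 4,
            "stratum": ["high"] * 9,
            "n_cells": [1] * 9,
            "proportion": np.concatenate([prop_a, prop_b]),
        })
        p_greater = compare_stratum_proportions(records, "CT", "AD", "high", "greater").p_value
        p_less = compare_stratum_proportions(records, "AD", "CT", "high", "less").p_value
        assert p_greater == pytest.approx(p_less)

    def test_missing_condition_is_error(self):
        records = pd.DataFrame({"donor_id": ["d1"], "condition": ["CT"], "stratum": ["high"],
                                "n_cells": [1], "proportion": [0.5]})
        with pytest.raises(ValidationError, match="MCI"):
            compare_stratum_proportions(records, "CT", "MCI", "high")

    @given(st.lists(st.integers(0, 4), min_size=3, max_size=5),
           st.lists(st.integers(0, 4), min_size=3, max_size=5))
    @settings(max_examples=30, deadline=None)
    def test_exact_path_matches_brute_force_enumeration(self, a_raw, b_raw):
        """Exact p agrees with direct enumeration over all rank splits (U-statistic oracle)."""
        from npvuln._stats import rank_sum_test
        a = np.array(a_raw, dtype=float) / 4.0
        b = np.array(b_raw, dtype=float) / 4.0
        res = rank_sum_test(a, b, "greater")
        # independent oracle: count pairwise wins over every group assignment
        pooled = np.concatenate([a, b])
        n = len(pooled)

        def u_stat(ix_a):
            ix_a = set(ix_a)
            av = [pooled[i] for i in ix_a]
            bv = [pooled[i] for i in range(n) if i not in ix_a]
            return sum((x > y) + 0.5 * (x == y) for x in av for y in bv)

        observed = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        splits = list(combinations(range(n), len(a)))
        p_oracle = sum(u_stat(s) >= observed - 1e-9 for s in splits) / len(splits)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)


class TestSubsampleDonors:
    def _meta(self, n_ct=20, n_ad=8):
        rows = []
        for i in range(n_ct):
            rows.append({"obs_id": f"ct{i}", "donor_id": f"CTd{i}", "condition": "CT"})
        for i in range(n_ad):
            rows.append({"obs_id": f"ad{i}", "donor_id": f"ADd{i}", "condition": "AD"})
        return pd.DataFrame(rows).set_index("obs_id")

    def test_exact_availability_keeps_input_order(self):
        meta = self._meta(n_ct=8, n_ad=8)
        picked = subsample_donors(meta, 8, seed=123)
        assert picked == [f"CTd{i}" for i in range(8)] + [f"ADd{i}" for i in range(8)]

    def test_same_seed_same_selection(self):
        meta = self._meta()
        assert subsample_donors(meta, 5, seed=7) == subsample_donors(meta, 5, seed=7)

    def test_different_seeds_usually_differ(self):
        meta = self._meta(n_ct=20, n_ad=20)
        differing = sum(
            subsample_donors(meta, 5, seed=s) != subsample_donors(meta, 5, seed=s + 1000)
            for s in range(100)
        )
        assert differing >= 95

    def test_insufficient_donors_names_condition(self):
        with pytest.raises(ValidationError, match="AD"):
            subsample_donors(self._meta(n_ad=3), 8, seed=1)
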