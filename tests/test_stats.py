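"""Merging, CpM, detection threshold and Mann-Whitney differential expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import mann_whitney_enumeration
from srnakit import fixtures, stats


def count_table(molecules, counts):
    return pd.DataFrame({
        "DB": ["db"] * len(molecules),
        "Name": molecules,
        "ID": [f"id_{m}" for m in molecules],
        "Count": counts,
    })


class TestMergeSamples:
    def test_single_sample_identity(self):
        table = count_table(["m1", "m2"], [3, 7])
        merged = stats.merge_samples([("s1", table)])
        assert list(merged["s1"]) == [3, 7]

    def test_missing_molecule_filled_with_zero(self):
        merged = stats.merge_samples([
            ("A", count_table(["m1"], [5])),
            ("B", count_table(["m2"], [2])),
        ])
        assert merged.loc[("db", "m1", "id_m1"), "B"] == 0
        assert merged.loc[("db", "m2", "id_m2"), "A"] == 0

    def test_three_sample_union_has_four_zeros(self):
        merged = stats.merge_samples([
            ("s1", count_table(["m1", "m2"], [1, 2])),
            ("s2", count_table(["m2", "m3"], [3, 4])),
            ("s3", count_table(["m3"], [5])),
        ])
        assert merged.shape == (3, 3)
        assert int((merged == 0).sum().sum()) == 4

    def test_duplicate_sample_names_rejected(self):
        table = count_table(["m1"], [1])
        with pytest.raises(ValueError, match="duplicate sample"):
            stats.merge_samples([("s1", table), ("s1", table)])

    def test_merge_from_files(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        count_table(["m1"], [4]).to_csv(p1, sep="\t", index=False)
        count_table(["m1", "m2"], [1, 9]).to_csv(p2, sep="\t", index=False)
        merged = stats.merge_samples([("a", str(p1)), ("b", str(p2))])
        assert merged.loc[("db", "m2", "id_m2"), "a"] == 0
        assert merged.loc[("db", "m1", "id_m1"), "b"] == 1


class TestCpm:
    def test_symmetric_column(self):
        table = pd.DataFrame({"s": [2, 2]})
        assert list(stats.cpm_normalize(table)["s"]) == [500_000.0, 500_000.0]

    def test_single_molecule_takes_whole_library(self):
        assert stats.cpm_normalize(pd.DataFrame({"s": [7]}))["s"].iloc[0] == 1e6

    def test_direct_formula(self):
        out = stats.cpm_normalize(pd.DataFrame({"s": [1, 3]}))
        assert list(out["s"]) == [250_000.0, 750_000.0]

    def test_all_columns_sum_to_one_million(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.integers(0, 500, size=(40, 6)).astype(float),
                             columns=list("abcdef"))
        table += 1  # keep library sizes positive
        sums = stats.cpm_normalize(table).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_zero_library_names_sample(self):
        table = pd.DataFrame({"good": [1], "empty": [0]})
        with pytest.raises(ValueError, match="empty"):
            stats.cpm_normalize(table)


class TestDetection:
    @pytest.mark.parametrize("count,detected", [(5, True), (4, False), (0, False)])
    def test_threshold_boundary_inclusive(self, count, detected):
        table = pd.DataFrame({"s": [count]})
        assert bool(stats.detection_filter(table)["s"].iloc[0]) is detected

    def test_threshold_zero_detects_everything(self):
        table = pd.DataFrame({"s": [0, 1, 100]})
        assert stats.detection_filter(table, 0).all().all()

    def test_detected_sets(self):
        table = pd.DataFrame({"s1": [5, 4], "s2": [0, 9]}, index=["m1", "m2"])
        sets = stats.detected_sets(table)
        assert sets == {"s1": {"m1"}, "s2": {"m2"}}


class TestMannWhitney:
    def test_complete_separation_of_three_vs_three(self):
        u, p = stats.mann_whitney_row(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        u, p = stats.mann_whitney_row(np.array([5.0, 5, 5]), np.array([5.0, 5, 5]))
        assert p == 1.0

    def test_symmetric_groups_give_p_one(self):
        _, p = stats.mann_whitney_row(np.array([10.0, 20]), np.array([10.0, 20]))
        assert p == 1.0

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_exact_path_matches_full_enumeration(self, data):
        n1 = data.draw(st.integers(3, 5))
        n2 = data.draw(st.integers(3, 5))
        pool = data.draw(
            st.lists(st.integers(0, 10_000), min_size=n1 + n2, max_size=n1 + n2,
                     unique=True)
        )
        x, y = [float(v) for v in pool[:n1]], [float(v) for v in pool[n1:]]
        u_oracle, p_oracle = mann_whitney_enumeration(x, y)
        u, p = stats.mann_whitney_row(np.array(x), np.array(y))
        assert u == u_oracle
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_label_swap_flips_direction_keeps_p(self, spec):
        table, case, control, _ = fixtures.make_de_fixture(spec, n_null=20, n_shifted=5)
        forward = stats.mann_whitney_de(table, case, control, normalize=None)
        backward = stats.mann_whitney_de(table, control, case, normalize=None)
        assert np.allclose(forward["p_value"], backward["p_value"])
        nonzero = forward["direction"] != 0
        assert (forward.loc[nonzero, "direction"]
                == -backward.loc[nonzero, "direction"]).all()

    def test_type_one_error_calibration_on_null_rows(self, spec):
        """Exact 6v6 test on 1000 tie-free null rows: rejection at 0.05 stays
        near the conservative exact level (~0.041)."""
        table, case, control, truth = fixtures.make_de_fixture(
            spec, n_null=1000, n_shifted=0
        )
        de = stats.mann_whitney_de(table, case, control, normalize=None)
        frac = float((de["p_value"] <= 0.05).mean())
        assert 0.02 <= frac <= 0.09

    def test_shifted_rows_reach_complete_separation_p(self, spec):
        table, case, control, truth = fixtures.make_de_fixture(
            spec, n_null=10, n_shifted=20
        )
        de = stats.mann_whitney_de(table, case, control, normalize=None)
        shifted = de[truth["shifted"].to_numpy()]
        assert np.allclose(shifted["p_value"], 2 / 924)
        assert (shifted["direction"] == 1).all()

    def test_de_validates_labels(self):
        table = pd.DataFrame({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError, match="unknown sample"):
            stats.mann_whitney_de(table, ["a"], ["zzz"], normalize=None)
        with pytest.raises(ValueError, match="at least one case"):
            stats.mann_whitney_de(table, ["a"], [], normalize=None)

    def test_cpm_normalization_changes_the_tested_values(self):
        # library-size artifact: raw counts differ, CpM proportions identical
        table = pd.DataFrame(
            {"c1": [10, 90], "c2": [20, 180], "k1": [1, 9], "k2": [2, 18]},
            index=["m1", "m2"],
        )
        de_cpm = stats.mann_whitney_de(table, ["c1", "c2"], ["k1", "k2"],
                                       normalize="cpm")
        assert (de_cpm["p_value"] == 1.0).all()
        de_raw = stats.mann_whitney_de(table, ["c1", "c2"], ["k1", "k2"],
                                       normalize=None)
        assert (de_raw["median_case"] > de_raw["median_control"]).all()


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert stats.adjust_pvalues([0.05])[0] == pytest.approx(0.05)

    def test_hand_computed_step_up(self):
        assert np.allclose(stats.adjust_pvalues([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert np.allclose(stats.adjust_pvalues([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(4)
        p = np.sort(rng.uniform(0, 1, 50))
        q = stats.adjust_pvalues(p)
        assert (q >= p - 1e-12).all()
        assert (np.diff(q) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            stats.adjust_pvalues([1.5])
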