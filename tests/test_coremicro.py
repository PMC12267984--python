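import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from _oracles import oracle_interpolated_quantile, oracle_top_share
from asmram.coremicro import (
    default_threshold_grid,
    filter_samples_by_coverage,
    global_core,
    plot_ubiquity_curves,
    regional_core,
    top_abundance_share,
    ubiquity_abundance_curves,
)


def meta_frame(coverages, ids=None):
    ids = ids or [f"s{i}" for i in range(len(coverages))]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "country": ["x"] * len(ids),
            "region": ["r"] * len(ids),
            "nonpareil_coverage_pct": coverages,
        }
    )


class TestCoverageFilter:
    def test_equal_coverages_remove_nothing(self):
        meta = meta_frame([80.0] * 6)
        retained, cutoff = filter_samples_by_coverage(meta)
        assert retained == meta["sample_id"].tolist()
        assert cutoff == 80.0  # IQR = 0; strict inequality keeps everything

    def test_worked_example(self):
        meta = meta_frame([20, 60, 70, 75, 80, 85, 90, 95])
        retained, cutoff = filter_samples_by_coverage(meta)
        assert cutoff == pytest.approx(39.375)
        assert retained == meta["sample_id"].tolist()[1:]

    def test_matches_interpolated_quantile_oracle(self):
        rng = np.random.default_rng(0)
        coverages = rng.uniform(10, 100, 37).tolist()
        meta = meta_frame(coverages)
        _, cutoff = filter_samples_by_coverage(meta, multiplier=1.5)
        q1 = oracle_interpolated_quantile(coverages, 0.25)
        q3 = oracle_interpolated_quantile(coverages, 0.75)
        assert cutoff == pytest.approx(q1 - 1.5 * (q3 - q1))

    def test_multiplier_zero_removes_below_q1(self):
        coverages = [10.0, 20.0, 30.0, 40.0, 50.0]
        meta = meta_frame(coverages)
        retained, cutoff = filter_samples_by_coverage(meta, multiplier=0.0)
        assert cutoff == pytest.approx(20.0)
        assert retained == ["s1", "s2", "s3", "s4"]

    def test_too_few_values_warns_and_keeps_all(self):
        meta = meta_frame([50.0, 60.0, 70.0])
        with pytest.warns(UserWarning, match="< 4"):
            retained, cutoff = filter_samples_by_coverage(meta)
        assert retained == meta["sample_id"].tolist()
        assert cutoff is None

    def test_missing_column_warns_and_keeps_all(self):
        meta = meta_frame([50.0] * 5).drop(columns=["nonpareil_coverage_pct"])
        with pytest.warns(UserWarning, match="lacks"):
            retained, cutoff = filter_samples_by_coverage(meta)
        assert retained == meta["sample_id"].tolist()
        assert cutoff is None


def toy_table():
    return pd.DataFrame(
        {
            "s1": [5.0, 0.0, 2.0],
            "s2": [5.0, 1.0, 0.0],
            "s3": [5.0, 3.0, 0.0],
            "s4": [5.0, 0.0, 9.0],
        },
        index=["everywhere", "sometimes", "rare"],
    )


class TestUbiquityCurves:
    def test_everywhere_species_100pct(self):
        curves = ubiquity_abundance_curves(toy_table(), [1.0])
        assert curves.loc["everywhere", 1.0] == 100.0

    def test_threshold_above_global_max_zero(self):
        curves = ubiquity_abundance_curves(toy_table(), [100.0])
        assert (curves[100.0] == 0.0).all()

    def test_toy_hand_enumeration(self):
        curves = ubiquity_abundance_curves(toy_table(), [1.0, 3.0, 6.0])
        # sometimes: abundances (0,1,3,0) -> >=1 in 2/4, >=3 in 1/4, >=6 in 0
        assert curves.loc["sometimes"].tolist() == [50.0, 25.0, 0.0]
        # rare: (2,0,0,9) -> 50, 25, 25
        assert curves.loc["rare"].tolist() == [50.0, 25.0, 25.0]

    def test_unsorted_thresholds_error(self):
        with pytest.raises(ValueError, match="ascending"):
            ubiquity_abundance_curves(toy_table(), [3.0, 1.0])

    @given(
        arrays(
            float,
            (4, 6),
            elements=st.floats(min_value=0, max_value=100, allow_nan=False),
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_non_increasing(self, values):
        table = pd.DataFrame(values, index=[f"sp{i}" for i in range(4)])
        thresholds = np.linspace(0.1, 120, 12)
        curves = ubiquity_abundance_curves(table, thresholds)
        diffs = np.diff(curves.to_numpy(), axis=1)
        assert (diffs <= 1e-12).all()

    def test_default_grid_ascending_and_spans_range(self):
        grid = default_threshold_grid(toy_table())
        assert (np.diff(grid) > 0).all()
        assert grid[0] == pytest.approx(1.0)
        assert grid[-1] == pytest.approx(9.0)

    def test_plot_smoke(self, tmp_path):
        curves = ubiquity_abundance_curves(toy_table(), [0.5, 1.0, 3.0])
        out = tmp_path / "curves.svg"
        plot_ubiquity_curves(curves, out)
        assert out.stat().st_size > 0


class TestGlobalCore:
    def test_strict_inequality_boundary(self):
        table = pd.DataFrame(
            {
                "s1": [1.0, 1.0],
                "s2": [1.0, 1.0],
                "s3": [0.0, 1.0],
                "s4": [0.0, 0.0],
                "s5": [0.0, 0.0],
            },
            index=["three_of_five", "two_of_three_like"],
        )
        # 3/5 = exactly 60% -> excluded under strict >
        assert "three_of_five" not in global_core(table, 0.60)
        # 2 of 3 samples = 66.7% -> included
        small = table[["s1", "s2", "s3"]]
        assert "three_of_five" in global_core(small, 0.60)

    def test_all_zero_species_never_included(self):
        table = toy_table()
        table.loc["ghost"] = 0.0
        assert "ghost" not in global_core(table, min_ubiquity=0.0)

    def test_limits(self):
        table = toy_table()
        at_zero = global_core(table, min_ubiquity=0.0)
        assert set(at_zero) == {"everywhere", "sometimes", "rare"}
        assert global_core(table, min_ubiquity=1.0) == []

    def test_planted_recovery(self, abundance_fixture):
        table, _, truth = abundance_fixture
        assert global_core(table) == truth.global_species

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            global_core(pd.DataFrame())


class TestRegionalCore:
    def _fixture(self):
        # region with 5 countries, 4 samples each
        countries = [f"c{i}" for i in range(5)]
        samples, rows = [], []
        for c in countries:
            for s in range(4):
                sid = f"{c}_{s}"
                samples.append(sid)
                rows.append({"sample_id": sid, "country": c, "region": "R"})
        meta = pd.DataFrame(rows)
        # species passes in countries c0..c3 (present in all samples), absent in c4
        values = [1.0 if not sid.startswith("c4") else 0.0 for sid in samples]
        table = pd.DataFrame([values], index=["four_of_five"], columns=samples)
        return table, meta

    def test_four_of_five_countries_is_member(self):
        table, meta = self._fixture()
        report = regional_core(table, meta)
        row = report.frame.iloc[0]
        assert row["pct_countries"] == pytest.approx(80.0)
        assert bool(row["member"])  # 80% boundary is inclusive

    def test_species_passing_nowhere_absent_from_report(self):
        table, meta = self._fixture()
        table.loc["nowhere"] = 0.0
        report = regional_core(table, meta)
        assert "nowhere" not in set(report.frame["species"])

    def test_planted_recovery(self, abundance_fixture):
        table, meta, truth = abundance_fixture
        report = regional_core(table, meta)
        for region, planted in truth.regional_species.items():
            expected = sorted(truth.global_species + planted)
            assert sorted(report.members(region)) == expected

    def test_invariant_to_sample_and_country_order(self, abundance_fixture):
        table, meta, _ = abundance_fixture
        rng = np.random.default_rng(0)
        shuffled_cols = list(rng.permutation(table.columns))
        shuffled_meta = meta.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = regional_core(table, meta)
        b = regional_core(table[shuffled_cols], shuffled_meta)
        key = ["region", "species"]
        pd.testing.assert_frame_equal(
            a.frame.sort_values(key).reset_index(drop=True),
            b.frame.sort_values(key).reset_index(drop=True),
        )

    def test_unmapped_sample_errors(self):
        table, meta = self._fixture()
        with pytest.raises(ValueError, match="missing from metadata"):
            regional_core(table, meta.iloc[:-1])

    def test_country_without_samples_warns_and_is_excluded(self):
        table, meta = self._fixture()
        # country c9 appears in metadata but none of its samples are in the table
        meta_extra = pd.concat(
            [meta, pd.DataFrame([{"sample_id": "ghost", "country": "c9", "region": "R"}])],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="c9"):
            report = regional_core(table, meta_extra)
        # denominator still 5 countries: 4/5 pass -> 80%
        assert report.frame.iloc[0]["pct_countries"] == pytest.approx(80.0)

    def test_country_in_two_regions_errors(self):
        table, meta = self._fixture()
        meta.loc[0, "region"] = "OTHER"
        with pytest.raises(ValueError, match="multiple regions"):
            regional_core(table, meta)


class TestTopAbundanceShare:
    def test_single_species(self):
        table = pd.DataFrame({"s1": [3.0], "s2": [1.0]}, index=["only"])
        shares = top_abundance_share(table)
        assert shares["only"] == 100.0

    def test_ties_credit_nobody(self):
        table = pd.DataFrame(
            {"s1": [2.0, 2.0], "s2": [1.0, 1.0]}, index=["a", "b"]
        )
        with pytest.warns(UserWarning, match="tied"):
            shares = top_abundance_share(table)
        assert shares["a"] == 0.0 and shares["b"] == 0.0

    def test_matches_argmax_oracle(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            rng.uniform(0, 10, size=(4, 6)),
            index=[f"sp{i}" for i in range(4)],
            columns=[f"s{j}" for j in range(6)],
        )
        shares = top_abundance_share(table)
        oracle = oracle_top_share(
            {sp: table.loc[sp].to_dict() for sp in table.index}, list(table.columns)
        )
        for sp in table.index:
            assert shares[sp] == pytest.approx(oracle[sp])
        assert shares.sum() <= 100.0 + 1e-9

    def test_subgroup(self):
        table = toy_table()
        shares = top_abundance_share(table, group=["s4"])
        assert shares["rare"] == 100.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            top_abundance_share(toy_table(), group=[])

    def test_unknown_sample_errors(self):
        with pytest.raises(KeyError):
            top_abundance_share(toy_table(), group=["nope"])
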