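import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ratknee.reference import (
    PRINTED_AREA_INCREASE_MEDIAL,
    PRINTED_PEAK_PRESSURE,
    printed_pressure_records,
)
from ratknee.stats import test_normality as shapiro_wilk
from ratknee.stats import (
    DegenerateDataError,
    anova_oneway,
    compare_model_types,
    make_summary_tables,
    max_area_increase,
    tukey_hsd,
)


class TestShapiroWilk:
    def test_constant_sample_raises(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([2.0] * 10)

    def test_too_small_sample_raises(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([1.0, 2.0])

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([np.zeros(25), np.full(25, 10.0)]) + rng.normal(0, 0.05, 50)
        _, p = shapiro_wilk(x)
        assert p < 0.01

    def test_null_p_values_uniform(self):
        """Under normal data the p-value is uniform (KS check over 200 seeds)."""
        ps = []
        for seed in range(200):
            x = np.random.default_rng(seed).normal(size=50)
            ps.append(shapiro_wilk(x)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestOneWayAnova:
    def test_hand_computed_example(self):
        # SSB = 6, SSW = 6 -> F = (6/2)/(6/6) = 3 with df (2, 6)
        res = anova_oneway([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.F == pytest.approx(3.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.p == pytest.approx(1 - sps.f.cdf(3.0, 2, 6), abs=1e-12)

    def test_identical_groups_with_internal_variance(self):
        res = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_location_invariance(self):
        groups = [[1.0, 2.5], [2.0, 4.0], [0.5, 1.5]]
        shifted = [[v + 17.3 for v in g] for g in groups]
        assert anova_oneway(groups).F == pytest.approx(anova_oneway(shifted).F, rel=1e-10)

    def test_degenerate_constant_data_raises(self):
        with pytest.raises(DegenerateDataError):
            anova_oneway([[1.0, 1.0], [1.0, 1.0]])

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=30)
    def test_matches_brute_force_sums_of_squares(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        groups = [rng.normal(size=rng.integers(2, 11)) for _ in range(k)]
        res = anova_oneway(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F = (ssb / (k - 1)) / (ssw / (len(allv) - k))
        assert res.F == pytest.approx(F, abs=1e-10)


class TestTukeyHSD:
    def test_two_groups_reduce_to_pooled_t_test(self):
        a, b = [1.1, 2.0, 2.9, 1.5], [2.2, 3.1, 2.8, 3.9]
        table = tukey_hsd([a, b])
        t_p = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert table["p_adjusted"].iloc[0] == pytest.approx(t_p, abs=1e-6)

    def test_identical_groups_not_significant(self):
        table = tukey_hsd([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert np.all(table["p_adjusted"] > 0.999)

    def test_matches_reference_studentized_range_implementation(self):
        groups = [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
        table = tukey_hsd(groups)
        ref = sps.tukey_hsd(*[np.asarray(g, dtype=float) for g in groups])
        for _, row in table.iterrows():
            i = int(row["group_a"][1:])
            j = int(row["group_b"][1:])
            assert row["p_adjusted"] == pytest.approx(ref.pvalue[i, j], abs=1e-4)

    def test_adjusted_p_not_below_pairwise_t(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(loc=m, size=6) for m in (0.0, 0.4, 1.0)]
        table = tukey_hsd(groups)
        for _, row in table.iterrows():
            i = int(row["group_a"][1:])
            j = int(row["group_b"][1:])
            t_p = sps.ttest_ind(groups[i], groups[j], equal_var=True).pvalue
            assert row["p_adjusted"] >= t_p - 1e-9


class TestSummaryTables:
    def test_printed_group_means_reproduced_verbatim(self):
        tables = make_summary_tables(printed_pressure_records())
        for _, row in PRINTED_PEAK_PRESSURE.iterrows():
            got = tables.peak_pressure.loc[(row["model_type"], row["varus_level"])]
            assert got["medial"] == pytest.approx(row["medial"], abs=1e-12)
            assert got["lateral"] == pytest.approx(row["lateral"], abs=1e-12)

    def test_printed_delta_aggregates(self):
        tables = make_summary_tables(printed_pressure_records())
        # max(2.30-1.77, 2.35-1.80) and max(1.66-1.25, 1.64-1.21) over FEA rows
        assert tables.aggregates["max_medial_pressure_increase"] == pytest.approx(0.55, abs=1e-12)
        assert tables.aggregates["max_lateral_pressure_decrease"] == pytest.approx(0.43, abs=1e-12)

    def test_experimental_increase_flagged_beyond_fea_aggregate(self):
        tables = make_summary_tables(printed_pressure_records())
        assert any("exceeds the FEA-only aggregate" in f for f in tables.flags)

    def test_printed_area_increments_aggregate(self):
        assert max_area_increase(PRINTED_AREA_INCREASE_MEDIAL) == pytest.approx(1.28, abs=1e-12)

    def test_permutation_invariance(self):
        rec = printed_pressure_records()
        shuffled = rec.sample(frac=1.0, random_state=3).reset_index(drop=True)
        t1 = make_summary_tables(rec)
        t2 = make_summary_tables(shuffled)
        pd.testing.assert_frame_equal(t1.peak_pressure, t2.peak_pressure)
        for key, v1 in t1.aggregates.items():
            v2 = t2.aggregates[key]
            assert (np.isnan(v1) and np.isnan(v2)) or v1 == v2

    def test_deltas_consistent_with_rounded_means(self):
        tables = make_summary_tables(printed_pressure_records())
        for _, row in tables.deltas.iterrows():
            block = tables.peak_pressure.loc[row["model_type"]]
            expected = block.loc[row["varus_level"], row["compartment"]] - block.loc[0, row["compartment"]]
            assert row["delta"] == pytest.approx(expected, abs=1e-12)

    def test_missing_cell_raises_completeness_error(self):
        rec = printed_pressure_records()
        rec = rec[~((rec["model_type"] == "ssam_fea") & (rec["varus_level"] == 50))]
        with pytest.raises(ValueError, match="missing cells"):
            make_summary_tables(rec)


class TestModelTypeComparison:
    def test_degenerate_cells_get_nan_p(self):
        rows = []
        for mt in ("sample_fea", "ssam_fea"):
            for knee in range(4):
                for side in ("medial", "lateral"):
                    val = 0.0 if side == "lateral" else 1.0 + 0.1 * knee + (0.01 if mt == "ssam_fea" else 0)
                    rows.append({"knee_id": knee, "model_type": mt, "varus_level": 100,
                                 "compartment": side, "peak_pressure": val, "contact_area": val})
        out = compare_model_types(pd.DataFrame(rows))
        med = out[out["compartment"] == "medial"]["p"].iloc[0]
        lat = out[out["compartment"] == "lateral"]["p"].iloc[0]
        assert np.isfinite(med)
        assert np.isnan(lat)
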