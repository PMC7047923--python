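"""End-to-end checks on schedules, mean vectors, missingness and communities."""

import numpy as np
import pandas as pd
import pytest

from ldasim import (
    NA,
    CovarianceSpec,
    TrendSpec,
    TruncationSpec,
    build_mean_vector,
    make_timepoints,
    simulate_community,
    simulate_feature,
    simulate_from_design,
)


class TestMakeTimepoints:
    def test_equidistant_five_points(self, make_design):
        d = make_design(num_timepoints=5, t_interval=(0, 10))
        times = make_timepoints(d)
        np.testing.assert_allclose(times[0], [0, 2.5, 5, 7.5, 10])
        assert all(t is times[0] for t in times)  # shared grid

    def test_equidistant_unit_steps(self, make_design):
        d = make_design(num_timepoints=7, t_interval=(0, 6))
        np.testing.assert_allclose(make_timepoints(d)[0], np.arange(7.0))

    def test_asynchronous_contract(self, make_design, rng):
        d = make_design(asynch_time=True, num_timepoints=6, t_interval=(0, 10))
        times = make_timepoints(d, rng)
        assert len(times) == d.n_subjects
        for t in times:
            assert t[0] == 0.0  # baseline always at t1
            assert np.all(np.diff(t) >= 0)
            assert t[-1] <= 10.0 and len(t) == 6
        # subjects draw distinct schedules
        assert not np.allclose(times[0][1:], times[1][1:])


class TestBuildMeanVector:
    def test_null_trend_gives_constant_mean(self, make_design):
        d = make_design(trend=TrendSpec("none"), control_mean=2.0)
        times = make_timepoints(d)
        mu = build_mean_vector(d, times)
        np.testing.assert_array_equal(mu, 2.0)
        assert mu.size == d.n_total

    def test_quadratic_treatment_baseline_equals_control(self, make_design):
        d = make_design()  # quadratic beta=(0,3,-0.5), control_mean=2
        mu = build_mean_vector(d, make_timepoints(d))
        # treatment subject at t=0: f(0)=0 so mean is mu_0
        treat_first = d.n_control * d.num_timepoints
        assert mu[treat_first] == pytest.approx(2.0)

    def test_hockey_stick_treatment_mean(self, make_design):
        d = make_design(
            trend=TrendSpec("L_up", (0.5,), (5,)),
            num_timepoints=10,
            t_interval=(0, 9),
        )
        mu = build_mean_vector(d, make_timepoints(d))
        treat = mu[d.n_control * 10:]
        # at t=9: 2 + 0.5*(9-5) = 4
        assert treat[9] == pytest.approx(4.0)
        np.testing.assert_array_equal(mu[: d.n_control * 10], 2.0)

    def test_asynch_uses_subject_own_times(self, make_design, rng):
        d = make_design(
            trend=TrendSpec("linear", (0.0, 1.0)), asynch_time=True,
            t_interval=(0, 6),
        )
        times = make_timepoints(d, rng)
        mu = build_mean_vector(d, times)
        treat_times = np.concatenate(times[d.n_control:])
        np.testing.assert_allclose(mu[d.n_control * 7:], 2.0 + treat_times)


class TestSimulateFeature:
    def test_record_count_and_groups(self, make_design):
        ds = simulate_feature(make_design())
        assert ds.n_total == 280 and len(ds.records) == 280
        counts = ds.records["group"].value_counts()
        assert counts["Control"] == 140 and counts["Treatment"] == 140
        # control IDs 1..n0, treatment n0+1..n
        ctrl_ids = ds.records.loc[ds.records["group"] == "Control", "ID"].unique()
        assert ctrl_ids.min() == 1 and ctrl_ids.max() == 20

    def test_no_missingness_leaves_y_obs_equal(self, make_design):
        ds = simulate_feature(make_design(missing_pct=0.0, missing_per_subject=0))
        assert len(ds.miss_data) == 0
        np.testing.assert_array_equal(ds.y, ds.y_obs)

    def test_same_seed_identical_datasets(self, make_design):
        d = make_design(missing_pct=0.2, missing_per_subject=2, seed=99)
        ds1, ds2 = simulate_feature(d), simulate_feature(d)
        pd.testing.assert_frame_equal(ds1.records, ds2.records)
        pd.testing.assert_frame_equal(ds1.miss_data, ds2.miss_data)

    def test_records_sorted_by_id_then_time(self, make_design):
        ds = simulate_feature(make_design(asynch_time=True))
        rec = ds.records
        assert (rec["ID"].diff().fillna(0) >= 0).all()
        within = rec.groupby("ID")["time"].apply(lambda s: (s.diff().dropna() >= 0).all())
        assert within.all()

    def test_invalid_design_raises_with_context(self, make_design):
        bad = make_design(missing_per_subject=10)  # q-1 = 6
        with pytest.raises(ValueError, match="non-baseline"):
            simulate_feature(bad)


class TestMissingness:
    def test_exact_accounting(self, make_design):
        """20% of 40 subjects, 2 cells each: 8 subjects, 16 cells."""
        d = make_design(missing_pct=0.2, missing_per_subject=2, miss_val=0.0)
        ds = simulate_feature(d)
        assert ds.miss_data["miss_id"].nunique() == 8
        assert len(ds.miss_data) == 16
        assert (ds.miss_data["miss_id"].value_counts() == 2).all()

    def test_baseline_never_missing(self, make_design):
        d = make_design(missing_pct=1.0, missing_per_subject=2)
        ds = simulate_feature(d)
        assert (ds.miss_data["miss_time"] > 0).all()

    def test_y_obs_differs_exactly_on_missing_cells(self, make_design):
        d = make_design(missing_pct=0.2, missing_per_subject=2, miss_val=0.0)
        ds = simulate_feature(d)
        differs = ds.records[ds.records["Y"] != ds.records["Y_obs"]]
        assert len(differs) == len(ds.miss_data)
        got = set(zip(differs["ID"], differs["time"]))
        listed = set(zip(ds.miss_data["miss_id"], ds.miss_data["miss_time"]))
        assert got == listed
        assert (differs["Y_obs"] == 0.0).all()

    def test_na_marker_missingness(self, make_design):
        d = make_design(missing_pct=0.2, missing_per_subject=2, miss_val=NA)
        ds = simulate_feature(d)
        assert ds.records["Y_obs"].isna().sum() == 16
        assert ds.records["Y"].notna().all()


class TestSimulateCommunity:
    @pytest.fixture
    def community_design(self, make_design):
        return make_design(
            trend=TrendSpec("L_down", (2.0, -0.5)),
            num_timepoints=5,
            t_interval=(0, 10),
            missing_pct=0.2,
            missing_per_subject=2,
            seed=3,
        )

    def test_shape_and_row_names(self, community_design):
        c = simulate_community(10, 4, community_design)
        assert c.abundance.shape == (10, 200)
        assert list(c.abundance.index[:4]) == [f"Diff_Bug{i}" for i in range(1, 5)]
        assert list(c.abundance.index[4:]) == [f"NoDiffBug_{i}" for i in range(1, 7)]
        assert list(c.sample_meta.columns) == ["ID", "time", "group", "Sample_ID"]
        assert list(c.sample_meta["Sample_ID"][:2]) == ["Sample_1", "Sample_2"]
        assert len(c.sample_meta) == 200

    def test_all_null_features(self, community_design):
        c = simulate_community(5, 0, community_design)
        assert all(name.startswith("NoDiffBug") for name in c.abundance.index)

    def test_diff_features_show_early_group_gap(self, make_design):
        """Under L_down beta=(2,-0.5), diff rows separate the arms at early
        times while null rows do not."""
        d = make_design(
            n_control=40, n_treat=40,
            trend=TrendSpec("L_down", (2.0, -0.5)),
            num_timepoints=5, t_interval=(0, 10),
            covariance=CovarianceSpec("independent", sigma=0.5),
            control_mean=5.0, seed=11,
        )
        c = simulate_community(6, 3, d)
        meta = c.sample_meta
        at_t0 = meta["time"] == 0.0
        treat = meta["group"] == "Treatment"
        for name in c.abundance.index:
            row = c.abundance.loc[name]
            gap = row[at_t0 & treat].mean() - row[at_t0 & ~treat].mean()
            if name.startswith("Diff_Bug"):
                assert gap > 1.0  # f(0) = 2
            else:
                assert abs(gap) < 0.7

    def test_reseeding_changes_noise_not_structure(self, community_design):
        from dataclasses import replace

        c1 = simulate_community(4, 2, community_design)
        c2 = simulate_community(4, 2, replace(community_design, seed=4))
        assert list(c1.abundance.index) == list(c2.abundance.index)
        assert not np.allclose(c1.abundance.to_numpy(), c2.abundance.to_numpy())
        c3 = simulate_community(4, 2, community_design)
        pd.testing.assert_frame_equal(c1.abundance, c3.abundance)


class TestSimulateFromDesign:
    @pytest.fixture
    def mouse_like_table(self):
        """12 subjects, 6 per arm, irregular per-subject schedules."""
        rows = []
        rng = np.random.default_rng(0)
        for sid in range(1, 13):
            grp = "Control" if sid <= 6 else "Treatment"
            times = np.sort(rng.uniform(0, 80, size=rng.integers(8, 13)))
            times[0] = 0.0
            for t in times:
                rows.append({"ID": sid, "time": float(t), "group": grp})
        return pd.DataFrame(rows)

    def test_five_fold_replication(self, mouse_like_table):
        ds = simulate_from_design(
            mouse_like_table,
            replication_factor=5,
            control_mean=2.0,
            covariance=CovarianceSpec("ar1", sigma=1.0, rho=0.7),
            trend=TrendSpec("L_up", (0.05,), (21.0,)),
            rng=1,
        )
        assert ds.records["ID"].nunique() == 60
        assert (ds.records.groupby("ID")["group"].nunique() == 1).all()
        assert ds.records.loc[ds.records["group"] == "Control", "ID"].nunique() == 30

    def test_factor_one_preserves_schedules(self, mouse_like_table):
        ds = simulate_from_design(
            mouse_like_table, 1, 2.0,
            CovarianceSpec("ar1", sigma=1.0, rho=0.7),
            TrendSpec("none"), rng=1,
        )
        assert ds.records["ID"].nunique() == 12
        orig_q = mouse_like_table.groupby("ID").size().sort_values().to_list()
        new_q = ds.records.groupby("ID").size().sort_values().to_list()
        assert orig_q == new_q

    def test_unequal_q_total_matches(self, mouse_like_table):
        ds = simulate_from_design(
            mouse_like_table, 2, 2.0,
            CovarianceSpec("compound", sigma=1.0, rho=0.5),
            TrendSpec("none"), rng=1,
        )
        assert ds.n_total == 2 * len(mouse_like_table) == len(ds.records)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_from_design(
                pd.DataFrame(columns=["ID", "time", "group"]), 1, 2.0,
                CovarianceSpec("ar1", sigma=1.0, rho=0.5), TrendSpec("none"),
            )


def test_moment_recovery_inactive_truncation(make_design):
    """With mu_0 >> 0 truncation is inert: treatment-minus-control means
    recover f(t) and the pooled SD recovers sigma."""
    d = make_design(
        n_control=500, n_treat=500, control_mean=10.0,
        covariance=CovarianceSpec("ar1", sigma=1.0, rho=0.5),
        trend=TrendSpec("linear", (0.0, 0.5)),
        num_timepoints=6, t_interval=(0, 5), seed=21,
    )
    ds = simulate_feature(d)
    rec = ds.records
    f_t = 0.5 * np.arange(6.0)
    se_diff = np.sqrt(2 * 1.0**2 / 500)
    for j, t in enumerate(np.arange(6.0)):
        at_t = rec[rec["time"] == t]
        diff = (
            at_t.loc[at_t["group"] == "Treatment", "Y"].mean()
            - at_t.loc[at_t["group"] == "Control", "Y"].mean()
        )
        assert abs(diff - f_t[j]) < 3 * se_diff
    resid = rec["Y"] - ds.mu
    sd = resid.std()
    assert abs(sd - 1.0) < 3 * 1.0 / np.sqrt(2 * len(rec))
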