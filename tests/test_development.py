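import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import make_quant_table
from proxirank.development import (
    change_filter,
    cluster_fraction_summary,
    cluster_profiles,
    cross_stage_intersection,
    nfasc_stage_values,
    pcca_normalize,
    run_development_analysis,
    stage_negative_filter,
    volcano_stats,
    zscore_profiles,
)
from proxirank.quant_io import Channel, ChannelDesign
from proxirank.synthetic import (
    DEFAULT_TRENDS,
    PCCA_ACCESSION,
    SyntheticSpec,
    generate_stage_series,
    make_stage_designs,
)


@pytest.fixture
def div7_design():
    return ChannelDesign(
        (
            Channel("f1", "NFASC", "positive", "DIV7", 1),
            Channel("f2", "NFASC", "positive", "DIV7", 2),
            Channel("neg", "no_1Ab", "negative", "DIV7"),
            Channel("neun", "NeuN", "reference", "DIV7"),
            Channel("map2", "MAP2", "reference", "DIV7"),
        )
    )


class TestStageNegativeFilter:
    def test_mean_log2_difference_above_cutoff_kept(self, div7_design):
        t = make_quant_table(
            {"P1": {"f1": 1600.0, "f2": 1600.0, "neg": 100.0, "neun": 1, "map2": 1}}
        )
        assert stage_negative_filter(t, div7_design, "DIV7", 3.5) == {"P1"}

    def test_mean_log2_difference_below_cutoff_dropped(self, div7_design):
        # mean of (log2 3, 0) ~= 0.79 < 1 -> dropped at the DIV14 cutoff
        t = make_quant_table(
            {"P1": {"f1": 300.0, "f2": 100.0, "neg": 100.0, "neun": 1, "map2": 1}}
        )
        assert stage_negative_filter(t, div7_design, "DIV7", 1.0) == set()

    def test_detected_without_negative_is_retained(self, div7_design):
        t = make_quant_table(
            {"P1": {"f1": 10.0, "f2": 10.0, "neun": 1, "map2": 1}},
            ["f1", "f2", "neg", "neun", "map2"],
        )
        assert stage_negative_filter(t, div7_design, "DIV7", 3.5) == {"P1"}

    def test_undetected_in_nfasc_dropped(self, div7_design):
        t = make_quant_table(
            {"P1": {"neg": 10.0, "neun": 1, "map2": 1}},
            ["f1", "f2", "neg", "neun", "map2"],
        )
        assert stage_negative_filter(t, div7_design, "DIV7", 3.5) == set()


class TestCrossStageIntersection:
    def test_nested_sets_give_smallest(self):
        assert cross_stage_intersection(
            {"A", "B", "C", "D"}, {"A", "B", "C"}, {"A", "B"}, {"A"}
        ) == {"A"}

    def test_any_empty_input_gives_empty(self):
        assert cross_stage_intersection({"A"}, set(), {"A"}) == set()


class TestPccaNormalize:
    def test_anchor_scales_to_one_and_ratios_preserved(self, div7_design):
        t = make_quant_table(
            {
                PCCA_ACCESSION: {"f1": 500.0, "f2": 50.0, "neg": 1, "neun": 1, "map2": 1},
                "X": {"f1": 1000.0, "f2": 100.0, "neg": 1, "neun": 1, "map2": 1},
            }
        )
        out = pcca_normalize(t, div7_design)
        vals = out.data.set_index(out.leading_ids)
        assert vals.loc["X", "f1"] == 2.0
        assert vals.loc["X", "f2"] == 2.0  # 10x scale difference removed
        assert vals.loc[PCCA_ACCESSION, "f1"] == 1.0

    def test_idempotent(self, div7_design):
        t = make_quant_table(
            {
                PCCA_ACCESSION: {"f1": 500.0, "f2": 50.0, "neg": 1, "neun": 1, "map2": 1},
                "X": {"f1": 1000.0, "f2": 100.0, "neg": 1, "neun": 1, "map2": 1},
            }
        )
        once = pcca_normalize(t, div7_design)
        twice = pcca_normalize(once, div7_design)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_missing_anchor_channel_named_in_error(self, div7_design):
        t = make_quant_table(
            {
                PCCA_ACCESSION: {"f1": 500.0, "neg": 1, "neun": 1, "map2": 1},
                "X": {"f1": 1000.0, "f2": 100.0, "neg": 1, "neun": 1, "map2": 1},
            },
            ["f1", "f2", "neg", "neun", "map2"],
        )
        with pytest.raises(ValueError, match="f2"):
            pcca_normalize(t, div7_design)

    def test_absent_anchor_errors(self, div7_design):
        t = make_quant_table(
            {"X": {"f1": 1.0, "f2": 1.0, "neg": 1, "neun": 1, "map2": 1}}
        )
        with pytest.raises(ValueError, match="not found"):
            pcca_normalize(t, div7_design)


class TestChangeFilter:
    @pytest.mark.parametrize(
        "profile,kept",
        [
            ((100.0, 110.0, 119.0), False),  # max ratio 1.19 <= 1.2
            ((100.0, 125.0, 110.0), True),  # ratio 1.25 > 1.2
            ((50.0, 50.0, 50.0), False),  # constant
            ((100.0, 121.0, 100.0), True),  # just above the strict bound
            ((100.0, 120.0, 100.0), False),  # exactly 1.2 excluded
        ],
    )
    def test_pairwise_ratio_threshold(self, profile, kept):
        df = pd.DataFrame([profile], columns=["DIV7", "DIV14", "DIV21"], index=["P1"])
        assert (change_filter(df) == {"P1"}) is kept

    def test_symmetric_in_stage_order_and_scale_invariant(self):
        df = pd.DataFrame(
            {"DIV7": [100.0], "DIV14": [125.0], "DIV21": [110.0]}, index=["P1"]
        )
        permuted = df[["DIV21", "DIV7", "DIV14"]]
        scaled = df * 1e3
        assert change_filter(df) == change_filter(permuted) == change_filter(scaled)

    def test_non_positive_mean_excluded_with_warning(self):
        df = pd.DataFrame(
            {"DIV7": [0.0, 100.0], "DIV14": [1.0, 200.0], "DIV21": [1.0, 300.0]},
            index=["bad", "good"],
        )
        with pytest.warns(UserWarning, match="non-positive"):
            assert change_filter(df) == {"good"}


class TestZscoreProfiles:
    def test_closed_form_population_sd(self):
        df = pd.DataFrame(
            {"DIV7": [1.0], "DIV14": [2.0], "DIV21": [3.0]}, index=["P1"]
        )
        z = zscore_profiles(df)
        np.testing.assert_allclose(
            z.loc["P1"].to_numpy(), [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_constant_profile_maps_to_zero(self):
        df = pd.DataFrame(
            {"DIV7": [5.0], "DIV14": [5.0], "DIV21": [5.0]}, index=["P1"]
        )
        assert zscore_profiles(df).loc["P1"].tolist() == [0.0, 0.0, 0.0]

    def test_permuting_stages_permutes_z(self):
        df = pd.DataFrame(
            {"DIV7": [1.0], "DIV14": [4.0], "DIV21": [2.0]}, index=["P1"]
        )
        z = zscore_profiles(df)
        z_perm = zscore_profiles(df[["DIV14", "DIV21", "DIV7"]])
        assert z.loc["P1", "DIV14"] == z_perm.loc["P1", "DIV14"]
        assert z.loc["P1", "DIV7"] == z_perm.loc["P1", "DIV7"]


class TestClustering:
    def _planted_profiles(self, sigma=0.05, n_per=10, seed=0):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for k, (name, mult) in enumerate(DEFAULT_TRENDS.items()):
            z = zscore_profiles(
                pd.DataFrame([mult], columns=["DIV7", "DIV14", "DIV21"])
            ).iloc[0]
            for i in range(n_per):
                rows.append(z.to_numpy() + rng.normal(0, sigma, 3))
                labels.append(k)
        df = pd.DataFrame(
            rows,
            columns=["DIV7", "DIV14", "DIV21"],
            index=[f"P{i:03d}" for i in range(len(rows))],
        )
        return df, np.asarray(labels)

    def test_recovers_planted_partition(self):
        profiles, labels = self._planted_profiles()
        assignments = cluster_profiles(profiles, k=6)
        # perfect agreement: each planted class maps to exactly one cluster
        ct = pd.crosstab(labels, assignments)
        assert (ct.gt(0).sum(axis=1) == 1).all()
        assert (ct.gt(0).sum(axis=0) == 1).all()

    def test_agreement_with_sklearn_ari(self):
        from sklearn.metrics import adjusted_rand_score

        profiles, labels = self._planted_profiles()
        assignments = cluster_profiles(profiles, k=6)
        assert adjusted_rand_score(labels, assignments.to_numpy()) == pytest.approx(1.0)

    def test_k_one_gives_single_cluster(self):
        profiles, _ = self._planted_profiles(n_per=3)
        assert set(cluster_profiles(profiles, k=1)) == {1}

    def test_duplicate_profiles_share_cluster(self):
        profiles, _ = self._planted_profiles(sigma=0.0, n_per=2)
        assignments = cluster_profiles(profiles, k=6)
        for k in range(6):
            a, b = f"P{2 * k:03d}", f"P{2 * k + 1:03d}"
            assert assignments[a] == assignments[b]

    def test_k_exceeding_n_errors(self):
        profiles, _ = self._planted_profiles(n_per=1)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_profiles(profiles, k=7)

    def test_cluster_ids_ordered_by_descending_size(self):
        rng = np.random.default_rng(3)
        big = rng.normal(0, 0.05, (30, 3)) + np.array([-1.0, 0.0, 1.0])
        small = rng.normal(0, 0.05, (5, 3)) + np.array([1.0, 0.0, -1.0])
        profiles = pd.DataFrame(
            np.vstack([small, big]), columns=["DIV7", "DIV14", "DIV21"]
        )
        assignments = cluster_profiles(profiles, k=2)
        sizes = assignments.value_counts()
        assert sizes[1] == 30 and sizes[2] == 5


class TestClusterSummary:
    def test_fractions_and_trends(self):
        z = pd.DataFrame(
            [[-1, 0, 1]] * 5 + [[1, 0, -1]] * 3 + [[-1, 1, -1]] * 2,
            columns=["DIV7", "DIV14", "DIV21"],
            index=[f"P{i}" for i in range(10)],
            dtype=float,
        )
        assignments = pd.Series([1] * 5 + [2] * 3 + [3] * 2, index=z.index)
        out = cluster_fraction_summary(assignments, z)
        assert out["percent"].tolist() == [50.0, 30.0, 20.0]
        assert out["trend"].tolist() == ["monotone-up", "monotone-down", "peaked"]
        assert out["percent"].sum() == pytest.approx(100.0)


class TestVolcanoStats:
    def _frame(self, rows: dict) -> pd.DataFrame:
        return pd.DataFrame.from_dict(rows, orient="index")

    def test_identical_groups_are_ns_with_p_one(self):
        a = self._frame({"P1": [1.0, 1.0]})
        b = self._frame({"P1": [1.0, 1.0]})
        out = volcano_stats(a, b)
        assert out.loc["P1", "log2_fc"] == 0.0
        assert out.loc["P1", "p_value"] == 1.0
        assert out.loc["P1", "call"] == "ns"

    def test_fold_change_definition(self):
        a = self._frame({"P1": [1.0, 1.0]})
        b = self._frame({"P1": [4.0, 4.0]})
        with pytest.warns(UserWarning, match="zero within-group variance"):
            out = volcano_stats(a, b)
        assert out.loc["P1", "log2_fc"] == 2.0
        assert out.loc["P1", "p_value"] > 0.0
        assert out.loc["P1", "call"] == "up"

    def test_swap_negates_fc_and_preserves_p(self):
        rng = np.random.default_rng(9)
        a = pd.DataFrame(rng.lognormal(0, 0.3, (20, 3)),
                         index=[f"P{i}" for i in range(20)])
        b = pd.DataFrame(rng.lognormal(0.5, 0.3, (20, 3)),
                         index=[f"P{i}" for i in range(20)])
        ab = volcano_stats(a, b)
        ba = volcano_stats(b, a)
        np.testing.assert_allclose(ab["log2_fc"], -ba["log2_fc"])
        np.testing.assert_allclose(ab["p_value"], ba["p_value"])

    def test_insufficient_replicates_dropped(self):
        a = self._frame({"P1": [1.0, np.nan]})
        b = self._frame({"P1": [2.0, 2.0]})
        assert volcano_stats(a, b).empty


class TestEndToEnd:
    def test_planted_trends_recovered_through_full_pipeline(self):
        spec = SyntheticSpec(
            seed=3, n_ais=60, n_background=300, log2_noise_sd=0.05, missing_rate=0.0
        )
        t1, d1, t2, d2, truth = generate_stage_series(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = run_development_analysis(t1, d1, t2, d2)
        planted = truth.set_index("protein_id")["trend"]
        planted = planted[planted != ""]
        # all planted dynamic proteins survive to clustering
        assert set(planted.index) <= set(result["assignments"].index)
        ct = pd.crosstab(
            planted.loc[result["assignments"].index.intersection(planted.index)],
            result["assignments"].loc[
                result["assignments"].index.intersection(planted.index)
            ],
        )
        assert (ct.gt(0).sum(axis=1) == 1).all()

    def test_planted_up_trend_called_up_in_volcano(self):
        spec = SyntheticSpec(
            seed=4, n_ais=30, n_background=200, log2_noise_sd=0.1, missing_rate=0.0
        )
        t1, d1, t2, d2, truth = generate_stage_series(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = run_development_analysis(t1, d1, t2, d2)
        up_ids = truth.loc[truth.trend == "up", "protein_id"]
        calls = result["volcano"]["DIV7_vs_DIV21"]
        calls = calls.loc[calls.index.intersection(up_ids), "call"]
        assert len(calls) > 0
        assert (calls == "up").all()

    def test_constant_protein_excluded_by_change_filter(self):
        spec = SyntheticSpec(
            seed=5, n_ais=12, n_background=100, log2_noise_sd=0.0, missing_rate=0.0
        )
        flat = {"flat": (1.0, 1.0, 1.0), "up": (1.0, 2.0, 4.0)}
        t1, d1, t2, d2, truth = generate_stage_series(spec, trends=flat)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = run_development_analysis(t1, d1, t2, d2)
        flat_ids = set(truth.loc[truth.trend == "flat", "protein_id"])
        assert flat_ids <= result["common"]
        assert flat_ids & set(result["assignments"].index) == set()
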