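import numpy as np
import pandas as pd
import pytest

from songtypicality import data_io
from songtypicality.predictors import (
    assemble_predictors,
    great_circle_km,
    neighbour_counts,
    patristic_matrix,
    phylo_nn_distance,
    society_mean_loo,
    standardize,
)

from conftest import law_of_cosines_km


def society_table(rows):
    return pd.DataFrame(rows, columns=["society_id", "region_id", "latitude", "longitude"])


class TestGreatCircle:
    def test_identical_points_are_zero(self):
        assert great_circle_km(12.3, -45.6, 12.3, -45.6) == 0.0

    def test_quarter_great_circle(self):
        # equator to 90 degrees of longitude: pi * R / 2
        assert great_circle_km(0, 0, 0, 90) == pytest.approx(
            np.pi * 6371.0088 / 2, rel=1e-9
        )
        assert great_circle_km(0, 0, 0, 90) == pytest.approx(10007.56, abs=0.01)

    def test_matches_law_of_cosines_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            lat1, lat2 = rng.uniform(-85, 85, 2)
            lon1, lon2 = rng.uniform(-180, 180, 2)
            ours = great_circle_km(lat1, lon1, lat2, lon2)
            theirs = law_of_cosines_km(lat1, lon1, lat2, lon2)
            assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-6)

    def test_symmetric(self):
        a, b = (10.0, 20.0), (-30.0, 140.0)
        assert great_circle_km(*a, *b) == pytest.approx(great_circle_km(*b, *a))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="latitude"):
            great_circle_km(91, 0, 0, 0)
        with pytest.raises(ValueError, match="longitude"):
            great_circle_km(0, 181, 0, 0)


class TestNeighbourCounts:
    def test_single_society_counts_zero(self):
        soc = society_table([("A", "r", 0.0, 0.0)])
        assert neighbour_counts(soc, 500).tolist() == [0]

    def test_radius_threshold_behaviour(self):
        # two societies ~300 km apart along the equator
        lon = 300 / (6371.0088 * np.pi / 180)
        soc = society_table([("A", "r", 0.0, 0.0), ("B", "r", 0.0, lon)])
        assert neighbour_counts(soc, 500).tolist() == [1, 1]
        assert neighbour_counts(soc, 250).tolist() == [0, 0]

    def test_boundary_is_inclusive(self):
        lon = 90.0
        d = great_circle_km(0, 0, 0, lon)
        soc = society_table([("A", "r", 0.0, 0.0), ("B", "r", 0.0, lon)])
        assert neighbour_counts(soc, d).tolist() == [1, 1]

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(7)
        soc = society_table(
            [(f"S{i}", "r", rng.uniform(-10, 10), rng.uniform(-10, 10)) for i in range(15)]
        )
        counts = neighbour_counts(soc, 600)
        for i in range(15):
            expected = sum(
                1
                for j in range(15)
                if j != i
                and law_of_cosines_km(
                    soc.latitude[i], soc.longitude[i], soc.latitude[j], soc.longitude[j]
                )
                <= 600
            )
            assert counts.iloc[i] == expected

    def test_contribution_is_symmetric(self):
        rng = np.random.default_rng(8)
        soc = society_table(
            [(f"S{i}", "r", rng.uniform(-5, 5), rng.uniform(-5, 5)) for i in range(10)]
        )
        lat, lon = soc.latitude.to_numpy(), soc.longitude.to_numpy()
        d = great_circle_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        within = d <= 400
        np.fill_diagonal(within, False)
        assert (within == within.T).all()

    def test_missing_coordinates_give_missing_count(self):
        soc = society_table([("A", "r", 0.0, 0.0), ("B", "r", np.nan, np.nan)])
        counts = neighbour_counts(soc, 500)
        assert counts["A"] == 0
        assert np.isnan(counts["B"])


class TestPhyloNN:
    def _tree(self, newick, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text(newick)
        return data_io.read_tree(path)

    def test_hand_readable_tree(self, tmp_path):
        tree = self._tree("((A:1,B:1):1,C:3);", tmp_path)
        soc = society_table([("sA", "r", 0, 0), ("sB", "r", 0, 0), ("sC", "r", 0, 0)])
        soc["language_id"] = ["A", "B", "C"]
        nn = phylo_nn_distance(tree, soc)
        assert nn["sA"] == pytest.approx(2.0)
        assert nn["sB"] == pytest.approx(2.0)
        assert nn["sC"] == pytest.approx(5.0)

    def test_shared_tip_distance_zero(self, tmp_path):
        tree = self._tree("((A:1,B:1):1,C:3);", tmp_path)
        soc = society_table([("s1", "r", 0, 0), ("s2", "r", 0, 0)])
        soc["language_id"] = ["A", "A"]
        nn = phylo_nn_distance(tree, soc)
        assert nn["s1"] == 0.0 and nn["s2"] == 0.0

    def test_unmapped_society_missing(self, tmp_path):
        tree = self._tree("((A:1,B:1):1,C:3);", tmp_path)
        soc = society_table([("s1", "r", 0, 0), ("s2", "r", 0, 0), ("s3", "r", 0, 0)])
        soc["language_id"] = ["A", "B", None]
        nn = phylo_nn_distance(tree, soc)
        assert np.isnan(nn["s3"])

    def test_matches_full_matrix_minimum(self, small_world):
        tree, societies = small_world["tree"], small_world["societies"]
        nn = phylo_nn_distance(tree, societies)
        full = patristic_matrix(tree)
        diameter = full.to_numpy().max()
        for _, row in societies.iterrows():
            d = full.loc[row["language_id"]].drop(row["language_id"])
            assert nn[row["society_id"]] == pytest.approx(d.min(), rel=1e-9)
            assert nn[row["society_id"]] <= diameter


class TestSocietyMeanLoo:
    @staticmethod
    def _scores(values, societies):
        return pd.DataFrame(
            {"unit_id": [f"s{i}" for i in range(len(values))],
             "society_id": societies, "region_id": "r",
             "unusualness": values, "n_items_scored": 3}
        )

    def test_pairwise_swap(self):
        loo = society_mean_loo(self._scores([-1.0, -3.0], ["A", "A"]))
        assert loo.tolist() == [-3.0, -1.0]

    def test_three_song_society(self):
        loo = society_mean_loo(self._scores([-1.0, -2.0, -3.0], ["A", "A", "A"]))
        assert loo.tolist() == pytest.approx([-2.5, -2.0, -1.5])

    def test_singleton_society_missing(self):
        loo = society_mean_loo(self._scores([-1.0, -2.0], ["A", "B"]))
        assert loo.isna().all()

    def test_shares_society_total_with_scores(self):
        # (score - loo_mean) * (n-1)/n sums to zero within each society
        scores = self._scores([-1.0, -2.0, -4.0, -3.0, -5.0], ["A", "A", "A", "B", "B"])
        loo = society_mean_loo(scores)
        df = scores.assign(loo=loo.to_numpy())
        for _, g in df.groupby("society_id"):
            n = len(g)
            assert ((g["unusualness"] - g["loo"]) * (n - 1) / n).sum() == pytest.approx(0.0)


class TestStandardize:
    def test_three_point_column(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        assert standardize(df, ["x"])["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent(self):
        df = pd.DataFrame({"x": np.random.default_rng(1).normal(3, 2, 50)})
        once = standardize(df, ["x"])
        twice = standardize(once, ["x"])
        assert np.allclose(once["x"], twice["x"], atol=1e-12)

    def test_missing_preserved_and_moments_exact(self):
        df = pd.DataFrame({"x": [1.0, np.nan, 2.0, 5.0, np.nan]})
        out = standardize(df, ["x"])["x"]
        assert out.isna().tolist() == [False, True, False, False, True]
        assert out.mean(skipna=True) == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1, skipna=True) == pytest.approx(1.0)

    def test_constant_column_is_fatal(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), ["x"])


class TestAssemblePredictors:
    def test_columns_match_componentwise_recomputation(self, strong_style_world):
        from songtypicality.unusualness import all_song_unusualness, society_trait_unusualness

        w = strong_style_world
        scores = all_song_unusualness(w["codings"], w["scheme"])
        kin = society_trait_unusualness(w["traits"], w["societies"], "kinship")
        eco = society_trait_unusualness(w["traits"], w["societies"], "economic")
        table = assemble_predictors(
            scores, kin, eco, w["societies"], w["tree"], 500.0, do_standardize=False
        )
        assert len(table) == len(scores)
        nbrs = neighbour_counts(w["societies"], 500.0)
        nn = phylo_nn_distance(w["tree"], w["societies"])
        loo = society_mean_loo(scores)
        for _, row in table.sample(40, random_state=0).iterrows():
            assert row["neighbours"] == nbrs[row["society_id"]]
            assert row["phylo_nn"] == pytest.approx(nn[row["society_id"]])
            assert row["society_mean_loo"] == pytest.approx(loo[row["unit_id"]])
            assert row["kinship_u"] == pytest.approx(
                kin.set_index("society_id")["unusualness"][row["society_id"]]
            )

    def test_standardized_columns_have_unit_moments(self, strong_style_world):
        from songtypicality.unusualness import all_song_unusualness, society_trait_unusualness

        w = strong_style_world
        scores = all_song_unusualness(w["codings"], w["scheme"])
        kin = society_trait_unusualness(w["traits"], w["societies"], "kinship")
        eco = society_trait_unusualness(w["traits"], w["societies"], "economic")
        table = assemble_predictors(scores, kin, eco, w["societies"], w["tree"], 500.0)
        ok = table[table["complete"]]
        for col in ["response", "neighbours", "phylo_nn", "kinship_u", "society_mean_loo"]:
            assert abs(ok[col].mean()) < 1e-9
            assert ok[col].std(ddof=1) == pytest.approx(1.0)

    def test_society_missing_traits_flagged_incomplete(self, toy_codings, tiny_scheme):
        from songtypicality.unusualness import all_song_unusualness

        scores = all_song_unusualness(toy_codings, tiny_scheme)
        societies = pd.DataFrame(
            {"society_id": list("ABCDE"),
             "region_id": ["north"] * 3 + ["south"] * 2,
             "latitude": [0.0, 1.0, 2.0, 40.0, 41.0],
             "longitude": [0.0, 1.0, 2.0, 40.0, 41.0],
             "language_id": pd.NA}
        )
        trait_scores = pd.DataFrame(
            {"unit_id": list("ABCDE"), "society_id": list("ABCDE"),
             "region_id": societies["region_id"],
             "unusualness": [-0.5, -0.2, np.nan, -0.1, -0.4],
             "n_items_scored": 1}
        )
        table = assemble_predictors(
            scores, trait_scores, trait_scores, societies, None, 500.0, do_standardize=False
        )
        c_rows = table[table["society_id"] == "C"]
        assert (~c_rows["complete"]).all()
        assert table.attrs["n_listwise_dropped"] >= len(c_rows)

    def test_unknown_society_is_fatal(self, toy_codings, tiny_scheme):
        from songtypicality.unusualness import all_song_unusualness

        scores = all_song_unusualness(toy_codings, tiny_scheme)
        societies = society_table([("A", "north", 0.0, 0.0)])
        societies["language_id"] = pd.NA
        with pytest.raises(ValueError, match="absent from society table"):
            assemble_predictors(scores, scores, scores, societies, None)
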