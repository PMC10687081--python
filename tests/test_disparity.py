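import numpy as np
import pandas as pd
import pytest

from trilokit.disparity import (
    DEVONIAN_STAGES,
    Stage,
    StageTable,
    assign_bins,
    disparity_through_time,
    nnd,
    richness_range_through,
    sor,
    sov,
)
from trilokit.morphospace import pca
from trilokit.procrustes import gpa

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


class TestMetrics:
    def test_sov_unit_square(self):
        assert sov(UNIT_SQUARE) == pytest.approx(2.0 / 3.0)

    def test_sov_identical_rows(self):
        assert sov(np.ones((5, 3))) == 0.0

    def test_sov_centroid_identity(self, rng):
        X = rng.normal(size=(17, 4))
        n = len(X)
        msd = ((X - X.mean(axis=0)) ** 2).sum(axis=1).mean()
        assert sov(X) == pytest.approx(msd * n / (n - 1))

    def test_sor_unit_square(self):
        assert sor(UNIT_SQUARE) == pytest.approx(2.0)

    def test_sor_monotone(self, rng):
        X = rng.normal(size=(10, 3))
        X2 = np.vstack([X, X.max(axis=0) + 1.0])
        assert sor(X2) >= sor(X)

    def test_sor_degenerate(self):
        assert sor(np.tile([1.0, 2.0], (4, 1))) == 0.0

    def test_nnd_two_points(self):
        assert nnd(np.array([[0.0, 0.0], [3.0, 4.0]])) == pytest.approx(5.0)

    def test_nnd_collinear_unit_spacing(self):
        pts = np.arange(6.0)[:, None] * [1.0, 0.0]
        assert nnd(pts) == pytest.approx(1.0)

    def test_nnd_brute_force_oracle(self, rng):
        X = rng.normal(size=(20, 3))
        expected = np.mean(
            [
                min(np.linalg.norm(X[i] - X[j]) for j in range(20) if j != i)
                for i in range(20)
            ]
        )
        assert nnd(X) == pytest.approx(expected)

    @pytest.mark.parametrize("fn", [sov, sor, nnd])
    def test_single_point_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(np.array([[1.0, 2.0]]))

    def test_rotation_invariance_sov_nnd(self, rng):
        X = rng.normal(size=(15, 4))
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        assert sov(X @ Q) == pytest.approx(sov(X), rel=1e-10)
        assert nnd(X @ Q) == pytest.approx(nnd(X), rel=1e-10)

    def test_sor_axis_permutation_invariance(self, rng):
        X = rng.normal(size=(15, 4))
        assert sor(X[:, [2, 0, 3, 1]]) == pytest.approx(sor(X), rel=1e-12)


class TestStageTable:
    def test_devonian_has_seven_stages(self):
        assert len(DEVONIAN_STAGES) == 7
        assert DEVONIAN_STAGES.names[0] == "Lochkovian"
        assert DEVONIAN_STAGES.names[-1] == "Famennian"

    def test_contiguity_enforced(self):
        with pytest.raises(ValueError, match="not contiguous"):
            StageTable([Stage("A", 10.0, 8.0), Stage("B", 7.0, 5.0)])

    def test_base_above_top(self):
        with pytest.raises(ValueError, match="base_age"):
            Stage("A", 5.0, 8.0)

    def test_unknown_name(self):
        with pytest.raises(KeyError, match="Wenlock"):
            DEVONIAN_STAGES.index("Wenlock")

    def test_csv_round_trip(self, tmp_path):
        f = tmp_path / "stages.csv"
        DEVONIAN_STAGES.to_frame().to_csv(f, index=False)
        back = StageTable.from_csv(f)
        assert back.names == DEVONIAN_STAGES.names


class TestAssignBins:
    def test_point_occurrence(self):
        out = assign_bins({"s1": ("Eifelian", "Eifelian")}, DEVONIAN_STAGES)
        assert out == {"s1": ["Eifelian"]}

    def test_interval_cover(self):
        out = assign_bins({"s1": ("Lochkovian", "Emsian")}, DEVONIAN_STAGES)
        assert out["s1"] == ["Lochkovian", "Pragian", "Emsian"]

    def test_order_insensitive(self):
        a = assign_bins({"s": ("Emsian", "Lochkovian")}, DEVONIAN_STAGES)
        b = assign_bins({"s": ("Lochkovian", "Emsian")}, DEVONIAN_STAGES)
        assert a == b

    def test_range_through_by_genus(self):
        from trilokit.shapeio import SpecimenRecord, Stratigraphy, Taxonomy

        recs = [
            SpecimenRecord(id="a", taxonomy=Taxonomy(genus="G"),
                           stratigraphy=Stratigraphy(min_age="Lochkovian", max_age="Lochkovian")),
            SpecimenRecord(id="b", taxonomy=Taxonomy(genus="G"),
                           stratigraphy=Stratigraphy(min_age="Famennian", max_age="Famennian")),
        ]
        out = assign_bins(recs, DEVONIAN_STAGES, mode="range_through")
        assert out == {"G": DEVONIAN_STAGES.names}

    def test_unresolvable_stage_errors(self):
        with pytest.raises(KeyError, match="Ludlow"):
            assign_bins({"s": ("Ludlow", "Emsian")}, DEVONIAN_STAGES)


class TestRichness:
    def test_spanning_taxon(self):
        occ = pd.DataFrame(
            {"taxon": ["T"], "stage_first": ["Lochkovian"], "stage_last": ["Famennian"]}
        )
        counts = richness_range_through(occ, DEVONIAN_STAGES)
        assert (counts == 1).all()

    def test_disjoint_taxa(self):
        occ = pd.DataFrame(
            {
                "taxon": ["A", "B"],
                "stage_first": ["Pragian", "Frasnian"],
                "stage_last": ["Pragian", "Frasnian"],
            }
        )
        counts = richness_range_through(occ, DEVONIAN_STAGES)
        assert counts["Pragian"] == 1
        assert counts["Frasnian"] == 1
        assert counts.sum() == 2

    def test_brute_force_oracle(self, rng):
        names = DEVONIAN_STAGES.names
        taxa, first, last = [], [], []
        for t in range(50):
            i, j = sorted(rng.integers(0, 7, size=2))
            taxa.append(f"tax{t}")
            first.append(names[i])
            last.append(names[j])
        occ = pd.DataFrame({"taxon": taxa, "stage_first": first, "stage_last": last})
        counts = richness_range_through(occ, DEVONIAN_STAGES)
        for k, stage in enumerate(names):
            expected = sum(
                1
                for f, l in zip(first, last)
                if names.index(f) <= k <= names.index(l)
            )
            assert counts[stage] == expected

    def test_multiple_occurrences_range_through(self):
        # one taxon recorded in two disjoint stages ranges through the gap
        occ = pd.DataFrame(
            {
                "taxon": ["T", "T"],
                "stage_first": ["Lochkovian", "Givetian"],
                "stage_last": ["Lochkovian", "Givetian"],
            }
        )
        counts = richness_range_through(occ, DEVONIAN_STAGES)
        assert counts["Emsian"] == 1
        assert counts["Frasnian"] == 0


@pytest.fixture
def small_space(rng):
    coords = rng.normal(size=(8, 2, 15)) * 0.1 + 3
    return pca(gpa(coords))


class TestDisparityThroughTime:
    def test_single_bin_matches_direct_sov(self, small_space):
        bin_map = {sid: "all" for sid in small_space.specimen_ids}
        df = disparity_through_time(small_space, bin_map, n_boot=50, seed=1)
        assert len(df) == 1
        assert df.loc[0, "SoV"] == pytest.approx(sov(small_space.scores))
        assert df.loc[0, "SoR"] == pytest.approx(sor(small_space.scores))
        assert df.loc[0, "n"] == 15

    def test_singleton_bin_absent_metrics(self, small_space):
        ids = small_space.specimen_ids
        bin_map = {ids[0]: "lonely"}
        bin_map.update({sid: "rest" for sid in ids[1:]})
        df = disparity_through_time(small_space, bin_map, n_boot=20, seed=1).set_index("bin")
        assert df.loc["lonely", "n"] == 1
        assert np.isnan(df.loc["lonely", "SoV"])
        assert not np.isnan(df.loc["rest", "SoV"])

    def test_deterministic_for_seed(self, small_space):
        bin_map = {sid: "all" for sid in small_space.specimen_ids}
        df1 = disparity_through_time(small_space, bin_map, n_boot=100, seed=7)
        df2 = disparity_through_time(small_space, bin_map, n_boot=100, seed=7)
        pd.testing.assert_frame_equal(df1, df2)

    def test_bootstrap_interval_brackets_point(self, small_space):
        bin_map = {sid: "all" for sid in small_space.specimen_ids}
        hits = 0
        runs = 40
        for seed in range(runs):
            df = disparity_through_time(small_space, bin_map, n_boot=300, seed=seed)
            if df.loc[0, "SoV_lower"] <= df.loc[0, "SoV"] <= df.loc[0, "SoV_upper"]:
                hits += 1
        assert hits >= int(0.9 * runs)

    def test_n_axes_restriction(self, small_space):
        bin_map = {sid: "all" for sid in small_space.specimen_ids}
        df = disparity_through_time(small_space, bin_map, n_boot=10, seed=1, n_axes=2)
        assert df.loc[0, "SoV"] == pytest.approx(sov(small_space.scores[:, :2]))

    def test_unknown_specimen_rejected(self, small_space):
        with pytest.raises(KeyError, match="ghost"):
            disparity_through_time(small_space, {"ghost": "x"}, n_boot=10, seed=1)
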