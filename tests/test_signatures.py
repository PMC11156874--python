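import math

import numpy as np
import pandas as pd
import pytest

from woundnet import signatures as sig
from woundnet.io import GeneSetCollection


def _counts_design(medians_uw, medians_w, timepoints):
    """Build a 1-replicate-pair dataset whose medians are exactly given."""
    rows, cols = [], {}
    for cond, med in (("UW", medians_uw), ("W", medians_w)):
        for ti, t in enumerate(timepoints):
            for rep in (1, 2, 3):
                sid = f"{cond}_t{t:g}_r{rep}"
                rows.append({"sample_id": sid, "condition": cond,
                             "timepoint_h": t, "replicate": rep})
                cols[sid] = [med[g][ti] for g in med]
    genes = list(medians_uw)
    counts = pd.DataFrame(cols, index=genes)
    return counts, pd.DataFrame(rows)


class TestSelectHidegs:
    def test_hand_worked_toy(self):
        # four iDEGs; g_low is in the bottom 25% by overall expression and
        # must be dropped despite a large fold change; g_flat fails the
        # fold-change filter; g_edge sits exactly at FC 2 (strict).
        tps = [1.0, 2.0]
        uw = {"g_hi": [100, 100], "g_mid": [80, 80], "g_edge": [60, 60],
              "g_low": [1, 1]}
        w = {"g_hi": [400, 100], "g_mid": [80, 80], "g_edge": [121, 60],
             "g_low": [50, 1]}
        counts, design = _counts_design(uw, w, tps)
        sf = pd.Series(1.0, index=counts.columns)
        got = sig.select_hidegs(["g_hi", "g_mid", "g_edge", "g_low"],
                                counts, design, sf)
        # top 75% of 4 = ceil(3) = 3 genes: g_hi, g_mid, g_edge
        # FC>2 in >=1 tp: g_hi (401/101), g_edge ((121+1)/(60+1)=2 exactly -> out)
        assert got == ["g_hi"]

    def test_exact_fc_two_excluded(self):
        tps = [1.0]
        uw = {"a": [99], "b": [9]}
        w = {"a": [199], "b": [39]}   # a: (199+1)/(99+1)=2.0; b: 4.0
        counts, design = _counts_design(uw, w, tps)
        sf = pd.Series(1.0, index=counts.columns)
        got = sig.select_hidegs(["a", "b"], counts, design, sf)
        assert got == ["b"]

    def test_tie_broken_lexicographically(self):
        tps = [1.0]
        uw = {"b": [10], "a": [10], "c": [10], "d": [10]}
        w = {"b": [100], "a": [100], "c": [100], "d": [100]}
        counts, design = _counts_design(uw, w, tps)
        sf = pd.Series(1.0, index=counts.columns)
        got = sig.select_hidegs(["b", "a", "c", "d"], counts, design, sf)
        assert got == ["a", "b", "c"]  # ceil(0.75*4)=3, ties by gene id

    def test_empty_ideg_set_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="empty"):
            sig.select_hidegs([], small_bundle.counts, small_bundle.design,
                              pd.Series(1.0, index=small_bundle.counts.columns))


class TestWoundInduced:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "timepoint_h",
                                           "log2fc", "q"])

    def test_hand_enumeration(self):
        t = self._table([
            ("up_sig", 1.0, 1.2, 0.01),       # in
            ("up_weak", 1.0, 0.9, 0.01),      # log2fc <= 1 -> out
            ("up_notsig", 1.0, 2.0, 0.20),    # q >= 0.05 -> out
            ("down_sig", 1.0, -2.0, 0.001),   # down only -> out
            ("late_up", 4.0, 1.5, 0.04),      # in
            ("not_hideg", 1.0, 3.0, 0.001),   # not in hiDEG set -> out
        ])
        hidegs = ["up_sig", "up_weak", "up_notsig", "down_sig", "late_up"]
        assert sig.define_wound_induced(hidegs, t) == ["late_up", "up_sig"]

    def test_boundaries_strict(self):
        t = self._table([("edge_q", 1.0, 1.5, 0.05), ("edge_fc", 1.0, 1.0,
                                                      0.01)])
        assert sig.define_wound_induced(["edge_q", "edge_fc"], t) == []


class TestTrajectoryMatrix:
    def test_pseudo_zero_and_values(self, small_bundle, small_norm):
        traj = small_norm["traj"]
        assert traj.columns[0] == 0.0
        assert (traj[0.0] == 0).all()
        assert np.isfinite(traj.to_numpy()).all()

    def test_known_ratio(self):
        counts, design = _counts_design({"g": [9]}, {"g": [19]}, [1.0])
        sf = pd.Series(1.0, index=counts.columns)
        traj = sig.trajectory_matrix(counts, design, sf)
        assert traj.loc["g", 1.0] == pytest.approx(1.0)  # log2(20/10)


def _planted_matrix(rng, onsets, n_per=40, amp=3.0):
    tps = [0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 10.0, 24.0]
    rows, labels = [], []
    for onset in onsets:
        for _ in range(n_per):
            rows.append([amp if t >= onset and t > 0 else 0.0 for t in tps]
                        + rng.normal(0, 0.1, len(tps)))
            labels.append(onset)
    mat = pd.DataFrame(rows, columns=tps,
                       index=[f"g{i}" for i in range(len(rows))])
    return mat, labels


class TestClustering:
    def test_elbow_recovers_three_groups(self, rng):
        # three equidistant groups with disjoint responsive timepoints, so
        # the within-SS curve has its kink exactly at k = 3
        tps = list(np.arange(9, dtype=float) + 1)
        rows, block = [], 3
        for g in range(3):
            for _ in range(40):
                rows.append([4.0 if g * block <= i < (g + 1) * block else 0.0
                             for i in range(9)] + rng.normal(0, 0.05, 9))
        mat = pd.DataFrame(rows, columns=tps)
        k, ss = sig.choose_k_elbow(mat, seed=0)
        assert k == 3
        assert sig.choose_k_elbow(mat, seed=0)[0] == k  # same seed, same k

    def test_all_equal_rows_k1(self):
        mat = pd.DataFrame(np.ones((20, 5)))
        assert sig.choose_k_elbow(mat)[0] == 1

    def test_two_groups_ari_one_and_label_stability(self, rng):
        mat, labels = _planted_matrix(rng, onsets=[0.25, 6.0])
        lab, comp = sig.cluster_trajectories(mat, k=2, seed=0)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels, list(lab)) == 1.0
        # C1 must be the earlier-peaking cluster
        assert comp.loc["C1"].idxmax() <= comp.loc["C2"].idxmax()
        # row permutation leaves canonical labels unchanged
        perm = mat.sample(frac=1.0, random_state=1)
        lab2, _ = sig.cluster_trajectories(perm, k=2, seed=0)
        pd.testing.assert_series_equal(lab2.sort_index(), lab.sort_index())

    def test_k1_composite_is_column_mean(self, rng):
        mat, _ = _planted_matrix(rng, onsets=[1.0], n_per=10)
        _, comp = sig.cluster_trajectories(mat, k=1, seed=0)
        np.testing.assert_allclose(comp.loc["C1"], mat.mean(axis=0))

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            sig.cluster_trajectories(pd.DataFrame(np.ones((3, 4))), k=5)


class TestTimepointCorrelation:
    def test_block_structure_recovers_stages(self, rng):
        tps = [0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 10.0, 12.0, 14.0, 16.0,
               18.0, 24.0]
        stage_of = {t: sig.stage_of_timepoint(t) for t in tps}
        rows = []
        for _ in range(300):
            which = rng.choice(["S1", "S2", "S3"])
            rows.append([3.0 + rng.normal(0, 0.3) if stage_of[t] == which
                         else rng.normal(0, 0.3) for t in tps])
        mat = pd.DataFrame(rows, columns=tps)
        corr, groups = sig.timepoint_correlation_stages(mat)
        got = {frozenset(tps) for tps in groups.values()}
        expected = {frozenset(v) for v in sig.STAGE_TIMEPOINTS.values()}
        assert got == expected

    def test_identical_columns_warn(self, rng):
        col = rng.normal(size=50)
        mat = pd.DataFrame({0.25: col, 0.5: col, 1.0: col})
        with pytest.warns(UserWarning):
            corr, _ = sig.timepoint_correlation_stages(mat)
        np.testing.assert_allclose(corr, 1.0)

    def test_zero_variance_column_rejected(self, rng):
        mat = pd.DataFrame({0.25: rng.normal(size=10), 0.5: np.zeros(10)})
        with pytest.raises(ValueError, match="0.5"):
            sig.timepoint_correlation_stages(mat)

    def test_too_few_timepoints(self, rng):
        mat = pd.DataFrame({0.25: rng.normal(size=10),
                            0.5: rng.normal(size=10)})
        with pytest.raises(ValueError, match="groups"):
            sig.timepoint_correlation_stages(mat, n_groups=3)


class TestAssignStages:
    def test_planted_onsets_recovered(self, rng):
        mat, labels = _planted_matrix(rng, onsets=[0.25, 1.0, 10.0])
        assign, comp = sig.assign_stages(mat, seed=0)
        expected = {0.25: "S1", 1.0: "S2", 10.0: "S3"}
        got = assign["stage"]
        assert all(got[f"g{i}"] == expected[labels[i]]
                   for i in range(len(labels)))
        assert set(assign["stage_label"]) == {"Response", "Repair",
                                              "Remodeling"}

    def test_degenerate_all_early_warns(self, rng):
        mat, _ = _planted_matrix(rng, onsets=[0.25], n_per=60)
        with pytest.warns(UserWarning, match="same stage"):
            assign, _ = sig.assign_stages(mat, seed=0)
        assert set(assign["stage"]) == {"S1"}

    def test_k_not_three_rejected(self, rng):
        mat, _ = _planted_matrix(rng, onsets=[0.25], n_per=10)
        with pytest.raises(ValueError):
            sig.assign_stages(mat, k=4)


class TestGeneSetEnrichment:
    def _collection(self, sets):
        return GeneSetCollection({k: ("", frozenset(v))
                                  for k, v in sets.items()})

    def test_exact_combinatorial_value(self):
        universe = {f"g{i}" for i in range(20)}
        members = {"g0", "g1", "g2", "g3", "g4"}
        res = sig.gene_set_enrichment(members, self._collection(
            {"s": members}), universe)
        assert res["p"].iloc[0] == pytest.approx(1 / math.comb(20, 5),
                                                 rel=1e-9)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        res = sig.gene_set_enrichment({"g0"}, self._collection(
            {"s": {"g5", "g6"}}), universe)
        row = res.iloc[0]
        assert row["overlap"] == 0 and row["p"] <= 1.0
        res0 = sig.gene_set_enrichment(set(), self._collection(
            {"s": {"g5"}}), universe)
        assert res0["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        # all C(8,3) draws from an 8-gene universe, set of size 4
        import itertools
        universe = [f"g{i}" for i in range(8)]
        members = set(universe[:4])
        for query in itertools.combinations(universe, 3):
            k = len(members & set(query))
            res = sig.gene_set_enrichment(set(query), self._collection(
                {"s": members}), set(universe))
            count = sum(1 for draw in itertools.combinations(universe, 3)
                        if len(members & set(draw)) >= k)
            expected = count / math.comb(8, 3)
            assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_requirements(self):
        with pytest.raises(ValueError, match="universe"):
            sig.gene_set_enrichment({"a"}, self._collection({}), set())
        with pytest.raises(ValueError, match="subset"):
            sig.gene_set_enrichment({"a"}, self._collection({}), {"b"})
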