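import numpy as np
import pandas as pd
import pytest

from woundnet import pointwise as pw

from conftest import nb_counts


def _design(n_reps=3, timepoints=(0.25,), conditions=("UW", "W")):
    rows = []
    for c in conditions:
        for t in timepoints:
            for r in range(1, n_reps + 1):
                rows.append({"sample_id": f"{c}_t{t:g}_r{r}", "condition": c,
                             "timepoint_h": float(t), "replicate": r})
    return pd.DataFrame(rows)


class TestSizeFactors:
    def test_doubled_sample(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]},
                              index=["g1", "g2", "g3"])
        s = pw.estimate_size_factors(counts)
        np.testing.assert_allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [5, 7], "b": [5, 7], "c": [5, 7]})
        np.testing.assert_allclose(pw.estimate_size_factors(counts), 1.0)

    def test_matches_brute_force_median_of_ratios(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(30, 3)),
                              columns=["a", "b", "c"])
        counts += 1  # ensure all-nonzero reference genes
        s = pw.estimate_size_factors(counts)
        # brute force: median over genes of count/geomean, then rescale
        arr = counts.to_numpy(dtype=float)
        geo = np.exp(np.mean(np.log(arr), axis=1))
        raw = np.median(arr / geo[:, None], axis=0)
        expected = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(s, expected, rtol=1e-12)
        assert np.exp(np.log(s).mean()) == pytest.approx(1.0)

    def test_all_zero_reference_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="pseudocount"):
            pw.estimate_size_factors(counts)


class TestFpkm:
    def _ann(self, lengths):
        return pd.DataFrame({"length_nt": lengths},
                            index=[f"g{i}" for i in range(len(lengths))])

    def test_reference_value(self):
        counts = pd.DataFrame({"s": [10, 0]}, index=["g0", "g1"])
        counts.loc["g1"] = 1e6 - 10  # library size 1e6
        ann = self._ann([1000, 1000])
        sf = pd.Series({"s": 1.0})
        f = pw.compute_fpkm(counts, sf, ann)
        assert f.loc["g0", "s"] == pytest.approx(10.0)

    def test_zero_counts_and_length_scaling(self):
        counts = pd.DataFrame({"s": [0, 100, 100]}, index=["g0", "g1", "g2"])
        ann = self._ann([500, 1000, 2000])
        f = pw.compute_fpkm(counts, pd.Series({"s": 1.0}), ann)
        assert f.loc["g0", "s"] == 0
        assert f.loc["g1", "s"] == pytest.approx(2 * f.loc["g2", "s"])


class TestDispersion:
    def test_poisson_data_near_floor(self, rng):
        design = _design(n_reps=3, timepoints=np.linspace(1, 24, 12))
        mu = rng.uniform(100, 1000, size=400)
        counts = pd.DataFrame(rng.poisson(mu[:, None],
                                          size=(400, len(design))),
                              columns=design["sample_id"])
        sf = pd.Series(1.0, index=design["sample_id"])
        alpha = pw.estimate_dispersion(counts, sf, design)
        assert np.mean(alpha <= 0.02) >= 0.95

    def test_nb_dispersion_recovered(self, rng):
        # 50 replicate groups pooled, alpha = 0.3, means >= 100
        design = _design(n_reps=3, timepoints=np.arange(1, 26),
                         conditions=("UW", "W"))
        mu = rng.uniform(100, 500, size=300)
        counts = pd.DataFrame(
            nb_counts(rng, np.tile(mu[:, None], (1, len(design))), 0.3),
            columns=design["sample_id"])
        sf = pd.Series(1.0, index=design["sample_id"])
        alpha = pw.estimate_dispersion(counts, sf, design)
        assert 0.2 <= np.median(alpha) <= 0.4

    def test_constant_replicates_at_floor(self):
        design = _design(n_reps=3)
        counts = pd.DataFrame(50, index=["g1"], columns=design["sample_id"])
        sf = pd.Series(1.0, index=design["sample_id"])
        alpha = pw.estimate_dispersion(counts, sf, design)
        assert alpha.iloc[0] == pw.ALPHA_FLOOR

    def test_single_replicate_rejected(self):
        design = _design(n_reps=1)
        counts = pd.DataFrame(5, index=["g1"], columns=design["sample_id"])
        sf = pd.Series(1.0, index=design["sample_id"])
        with pytest.raises(ValueError, match="replicate"):
            pw.estimate_dispersion(counts, sf, design)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(pw.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert pw.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_brute_force_definition(self, rng):
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            q = pw.bh_adjust(p)
            m = len(p)
            order = np.argsort(p, kind="stable")
            expected = np.empty(m)
            for rank_pos, idx in enumerate(order):
                # q_i = min over j >= rank of m * p_(j) / (j+1)
                vals = [m * p[order[j]] / (j + 1)
                        for j in range(rank_pos, m)]
                expected[idx] = min(1.0, min(vals))
            np.testing.assert_allclose(q, expected, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pw.bh_adjust([0.5, 1.5])


class TestWaldTest:
    def test_identical_conditions_null(self, rng):
        design = _design(n_reps=3)
        base = rng.poisson(200, size=50)
        counts = pd.DataFrame(np.tile(base[:, None], (1, 6)),
                              columns=design["sample_id"])
        disp = pd.Series(0.1, index=counts.index)
        res = pw.wald_test_timepoint(counts, design, 0.25, disp,
                                     pd.Series(1.0, index=design["sample_id"]))
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-9)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-9)

    def test_planted_fourfold_recovered(self, rng):
        design = _design(n_reps=3)
        mu = np.full(200, 100.0)
        uw = nb_counts(rng, np.tile(mu[:, None], (1, 3)), 0.2)
        w = nb_counts(rng, np.tile(4 * mu[:, None], (1, 3)), 0.2)
        counts = pd.DataFrame(np.hstack([uw, w]),
                              columns=design["sample_id"])
        disp = pd.Series(0.2, index=counts.index)
        res = pw.wald_test_timepoint(counts, design, 0.25, disp,
                                     pd.Series(1.0, index=design["sample_id"]))
        assert abs(np.median(res["log2fc"]) - 2.0) <= 0.3

    def test_all_zero_gene_is_ns(self):
        design = _design(n_reps=2)
        counts = pd.DataFrame([[0, 0, 0, 0], [5, 6, 7, 8]],
                              index=["gz", "g"],
                              columns=design["sample_id"])
        disp = pd.Series(0.1, index=counts.index)
        res = pw.wald_test_timepoint(counts, design, 0.25, disp)
        row = res.set_index("gene_id").loc["gz"]
        assert row["p"] == 1.0 and row["log2fc"] == 0.0


class TestCallDegs:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "timepoint_h",
                                           "log2fc", "q"]).assign(
            se=0.1, wald_z=0.0, p=lambda d: d["q"])

    def test_strict_boundaries(self):
        t = self._table([("up", 1.0, np.log2(1.6), 0.04),
                         ("edge_fc", 1.0, np.log2(1.5), 0.04),
                         ("edge_q", 1.0, np.log2(1.6), 0.05)])
        res = pw.call_degs(t)
        assert res["per_timepoint"][1.0]["up"] == {"up"}
        assert res["union"] == {"up"}

    def test_bidirectional_flagged(self):
        t = self._table([("flip", 1.0, 2.0, 0.01), ("flip", 2.0, -2.0, 0.01),
                         ("mono", 1.0, 2.0, 0.01), ("mono", 2.0, 2.0, 0.01),
                         ("ns", 1.0, 0.1, 0.9), ("ns", 2.0, 0.0, 0.9),
                         ("dn", 1.0, -2.0, 0.01), ("dn", 2.0, -0.1, 0.5),
                         ("late", 2.0, 1.2, 0.02), ("late", 1.0, 0.0, 1.0)])
        res = pw.call_degs(t)
        assert res["bidirectional"] == {"flip"}
        assert res["union"] == {"flip", "mono", "dn", "late"}
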