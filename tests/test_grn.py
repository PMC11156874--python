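import itertools

import numpy as np
import pandas as pd
import pytest

from woundnet import grn
from woundnet.io import PWM


def _ann(rows):
    return pd.DataFrame(rows, columns=["chrom", "strand", "tss", "length_nt",
                                       "is_tf", "is_chromatin_factor"],
                        index=pd.Index([r[-1] for r in []] or
                                       [f"g{i}" for i in range(len(rows))],
                                       name="gene_id"))


class TestPromoterWindows:
    def _annotation(self, strand, tss):
        return pd.DataFrame({"chrom": ["chrI"], "strand": [strand],
                             "tss": [tss], "length_nt": [1000],
                             "is_tf": [False], "is_chromatin_factor": [False]},
                            index=pd.Index(["g1"], name="gene_id"))

    def test_plus_strand(self):
        w = grn.promoter_windows(self._annotation("+", 5000))
        assert (w.iloc[0]["start"], w.iloc[0]["end"]) == (3000, 6000)

    def test_minus_strand_mirror(self):
        w = grn.promoter_windows(self._annotation("-", 5000))
        assert (w.iloc[0]["start"], w.iloc[0]["end"]) == (4000, 7000)

    def test_clipping(self):
        w = grn.promoter_windows(self._annotation("+", 500),
                                 chrom_lengths={"chrI": 1200})
        assert (w.iloc[0]["start"], w.iloc[0]["end"]) == (0, 1200)

    def test_unknown_chrom_warns(self):
        with pytest.warns(UserWarning, match="length"):
            grn.promoter_windows(self._annotation("+", 5000),
                                 chrom_lengths={"chrII": 100})


def _pwm(consensus, p_major=0.85):
    probs = np.full((len(consensus), 4), (1 - p_major) / 3)
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = p_major
    return PWM("m", "tfA", probs)


class TestScanPwm:
    def test_uniform_pwm_no_hits(self):
        pwm = PWM("u", "tfA", np.full((5, 4), 0.25))
        hits = grn.scan_pwm("ACGTACGTACGT", pwm, p_cut=0.5)
        assert len(hits) == 0

    def test_consensus_score_arithmetic(self):
        pwm = _pwm("AAA" + "A")  # length-4 to satisfy min length
        hits = grn.scan_pwm("AAAA", pwm, p_cut=1.0 - 1e-12)
        fwd = hits[(hits["strand"] == "+") & (hits["offset"] == 0)]
        expected = 4 * np.log2(0.85 / 0.25)
        assert fwd["score_bits"].iloc[0] == pytest.approx(expected, abs=5e-3)

    def test_pvalues_match_enumeration_for_l4(self, rng):
        pwm = _pwm("ACGT")
        scanner = grn.PWMScanner([pwm], p_cut=1.0 - 1e-12)
        # brute-force null: all 256 windows, uniform background
        ints = grn._int_logodds(pwm.probs, pwm.background)[:, :4]
        all_scores = sorted(
            sum(ints[i, b] for i, b in enumerate(word))
            for word in itertools.product(range(4), repeat=4))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        hits = scanner.scan("g", seq)
        fwd = hits[hits["strand"] == "+"]
        # oracle: per-window integer score and enumeration p-value
        code = grn.encode_sequence(seq)
        oracle = {}
        for off in range(len(seq) - 3):
            s_int = sum(ints[i, code[off + i]] for i in range(4))
            oracle[off] = sum(1 for s in all_scores if s >= s_int) / 256.0
        cut = 1.0 - 1e-12
        assert set(fwd["offset"]) == {o for o, p in oracle.items() if p < cut}
        for row in fwd.itertuples(index=False):
            assert row.p == pytest.approx(oracle[row.offset], rel=1e-12)

    def test_n_windows_skipped(self):
        pwm = _pwm("AAAA")
        hits = grn.scan_pwm("AANAAAAA", pwm, p_cut=1e-2)
        assert all(off >= 3 for off in hits["offset"])

    def test_short_sequence_empty(self):
        assert len(grn.scan_pwm("ACG", _pwm("AAAA"))) == 0

    def test_minus_strand_hit(self):
        pwm = _pwm("AAAACCCC")
        hits = grn.scan_pwm("GGGGTTTT", pwm, p_cut=1e-4)
        assert set(hits["strand"]) == {"-"}


class TestPeakOverlap:
    def _windows(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start",
                                           "end", "strand"])

    def test_one_bp_overlap_counts(self):
        peaks = pd.DataFrame([("chrI", 5900, 6100, "tfA", 1.0)],
                             columns=["chrom", "start", "end", "tf_id",
                                      "score"])
        w = self._windows([("g1", "chrI", 3000, 6000, "+")])
        ev = grn.map_peaks_to_promoters(peaks, w)
        assert len(ev) == 1

    def test_half_open_no_overlap(self):
        peaks = pd.DataFrame([("chrI", 6000, 6100, "tfA", 1.0)],
                             columns=["chrom", "start", "end", "tf_id",
                                      "score"])
        w = self._windows([("g1", "chrI", 3000, 6000, "+")])
        assert len(grn.map_peaks_to_promoters(peaks, w)) == 0

    def test_random_intervals_match_brute_force(self, rng):
        peaks = pd.DataFrame(
            [("chrI", s, s + rng.integers(1, 50), f"tf{i % 3}", 1.0)
             for i, s in enumerate(rng.integers(0, 500, 40))],
            columns=["chrom", "start", "end", "tf_id", "score"])
        w = self._windows([(f"g{i}", "chrI", s, s + rng.integers(1, 80), "+")
                           for i, s in enumerate(rng.integers(0, 500, 25))])
        ev = grn.map_peaks_to_promoters(peaks, w)
        got = set(zip(ev["tf_id"], ev["gene_id"]))
        expected = set()
        for p in peaks.itertuples(index=False):
            for win in w.itertuples(index=False):
                if p.start < win.end and p.end > win.start:
                    expected.add((p.tf_id, win.gene_id))
        assert got == expected


class TestTfTargetMatrix:
    def test_evidence_combination(self):
        peak_ev = pd.DataFrame({"tf_id": ["A", "A"], "gene_id": ["g1", "g2"]})
        motif = pd.DataFrame({"tf_id": ["A", "B"], "gene_id": ["g2", "g3"],
                              "motif_id": "m", "offset": 0, "strand": "+",
                              "score_bits": 1.0, "p": 1e-5})
        matrix, ev = grn.build_tf_target_matrix(peak_ev, motif)
        e = ev.set_index(["tf_id", "gene_id"])["evidence"]
        assert e[("A", "g1")] == "peak"
        assert e[("A", "g2")] == "both"
        assert e[("B", "g3")] == "motif"
        assert matrix.loc["g2", "A"] and not matrix.loc["g1", "B"]

    def test_unknown_tf_rejected(self):
        motif = pd.DataFrame({"tf_id": [""], "gene_id": ["g1"]})
        with pytest.raises(ValueError, match="unknown TF"):
            grn.build_tf_target_matrix(pd.DataFrame(columns=["tf_id",
                                                             "gene_id"]),
                                       motif)


def _split_fixture(rng, n=60, sep=2.0):
    """Half the genes jump by `sep` log2FC at 0.5 h, half stay flat."""
    tps = [0.0, 0.25, 0.5, 1.0, 2.0]
    rows = []
    for i in range(n):
        up = i < n // 2
        rows.append([0, 0, sep if up else 0, sep if up else 0,
                     sep if up else 0] + rng.normal(0, 0.05, 5))
    traj = pd.DataFrame(rows, columns=tps,
                        index=[f"g{i}" for i in range(n)])
    tf_targets = pd.DataFrame(
        {"tfU": [i < n // 2 for i in range(n)],
         "tfF": [i >= n // 2 for i in range(n)]}, index=traj.index)
    fpkm_tp = pd.DataFrame(5.0, index=["tfU", "tfF"],
                           columns=[t for t in tps if t > 0])
    return traj, tf_targets, fpkm_tp


class TestSplits:
    def test_planted_divergence_single_split(self, rng):
        traj, tf_targets, fpkm_tp = _split_fixture(rng)
        res = grn.detect_paths_and_splits(traj, tf_targets, fpkm_tp, seed=0)
        assert len(res["splits"]) == 1
        split = res["splits"][0]
        assert split["timepoint_h"] == 0.5
        up_branch = split["branches"][0]
        assert set(up_branch["genes"]) == {f"g{i}" for i in range(30)}
        assert split["used_for_clustering"]
        # the up-branch TF is enriched in the up branch
        assigned = {(r["tf_id"], r["branch"]) for r in split["tf_assignments"]}
        assert ("tfU", up_branch["path_id"]) in assigned

    def test_homogeneous_trajectories_no_split(self, rng):
        traj, tf_targets, fpkm_tp = _split_fixture(rng, sep=0.0)
        res = grn.detect_paths_and_splits(traj, tf_targets, fpkm_tp, seed=0)
        assert res["splits"] == []

    def test_min_sd_monotonicity(self, rng):
        traj, tf_targets, fpkm_tp = _split_fixture(rng, sep=2.0)
        found = []
        for min_sd in (0.25, 0.5, 1.0, 1.5):
            res = grn.detect_paths_and_splits(traj, tf_targets, fpkm_tp,
                                              min_sd=min_sd, seed=0)
            found.append(any(s["timepoint_h"] == 0.5 for s in res["splits"]))
        assert all(found)  # lowering min_sd below 2.0 never loses the split

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grn.detect_paths_and_splits(pd.DataFrame(), pd.DataFrame(),
                                        pd.DataFrame())


def _edges(rows):
    return pd.DataFrame(rows, columns=["tf_id", "target_id", "evidence",
                                       "active_timepoints", "stages",
                                       "edge_class"])


class TestEdgeClassesAndDegrees:
    def _annotation(self, tfs, genes):
        ids = tfs + genes
        return pd.DataFrame({"chrom": "chrI", "strand": "+", "tss": 0,
                             "length_nt": 100,
                             "is_tf": [g in tfs for g in ids],
                             "is_chromatin_factor": False},
                            index=pd.Index(ids, name="gene_id"))

    def test_classification_and_autoregulators(self):
        ann = self._annotation(["A", "B"], ["g1"])
        evidence = pd.DataFrame({"tf_id": ["A", "A", "A"],
                                 "gene_id": ["A", "B", "g1"],
                                 "evidence": ["motif", "peak", "peak"]})
        traj = pd.DataFrame(2.0, index=["A", "B", "g1"],
                            columns=[0.0, 0.25, 6.0])
        fpkm_tp = pd.DataFrame(5.0, index=["A", "B"], columns=[0.25, 6.0])
        edges = grn.annotate_edges(evidence, traj, fpkm_tp, ann)
        by_target = edges.set_index("target_id")["edge_class"]
        assert by_target["A"] == "TF-(self-TF)"
        assert by_target["B"] == "TF-(other-TF)"
        assert by_target["g1"] == "TF-(non-TF)"
        _, autoregs = grn.classify_edges(edges, ann)
        assert autoregs == {"A"}

    def test_star_hub_degree(self):
        rows = [("H", f"T{i}", "peak", (0.25,), ("S1",), "TF-(other-TF)")
                for i in range(5)]
        table = grn.stage_subnetwork_degrees(_edges(rows), "S1")
        assert table.iloc[0]["tf_id"] == "H" and table.iloc[0]["degree"] == 5

    def test_reciprocal_edges_deduplicated(self):
        rows = [("A", "B", "peak", (0.25,), ("S1",), "TF-(other-TF)"),
                ("B", "A", "peak", (0.25,), ("S1",), "TF-(other-TF)")]
        table = grn.stage_subnetwork_degrees(_edges(rows), "S1")
        assert set(table["degree"]) == {1}

    def test_toy_network_hand_count(self):
        rows = [("A", "B", "p", (0.25,), ("S1",), "TF-(other-TF)"),
                ("A", "C", "p", (0.25,), ("S1",), "TF-(other-TF)"),
                ("B", "C", "p", (0.25,), ("S1",), "TF-(other-TF)"),
                ("C", "D", "p", (6.0,), ("S3",), "TF-(other-TF)"),
                ("A", "g", "p", (0.25,), ("S1",), "TF-(non-TF)"),
                ("A", "A", "p", (0.25,), ("S1",), "TF-(self-TF)")]
        table = grn.stage_subnetwork_degrees(_edges(rows), "S1")
        degrees = dict(zip(table["tf_id"], table["degree"]))
        assert degrees == {"A": 2, "B": 2, "C": 2}

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            grn.stage_subnetwork_degrees(_edges([]), "S9")


class TestInferMode:
    def _setup(self, sign):
        tps = [0.0, 0.25, 1.0, 6.0]
        tf_traj = [0.0, 2.0, 2.0, 1.0]
        target = [sign * v for v in tf_traj]
        traj = pd.DataFrame([tf_traj] + [target] * 4,
                            index=["TF", "u1", "u2", "u3", "u4"],
                            columns=tps)
        rows = [("TF", f"u{i}", "motif", (0.25,), ("S1",), "TF-(non-TF)")
                for i in range(1, 5)]
        return _edges(rows), traj

    def test_activator_and_repressor(self):
        for sign, mode in ((1, "activator"), (-1, "repressor")):
            edges, traj = self._setup(sign)
            res = grn.infer_tf_mode("TF", edges, traj)
            assert res["mode"] == mode
            assert res["r"] == pytest.approx(sign, abs=1e-9)

    def test_too_few_unique_targets_indeterminate(self):
        edges, traj = self._setup(1)
        res = grn.infer_tf_mode("TF", edges.iloc[:2], traj)
        assert res["mode"] == "indeterminate"
        assert "unique targets" in res["reason"]

    def test_shared_targets_not_unique(self):
        edges, traj = self._setup(1)
        # add three co-regulators of u1: it now has 4 regulators > 2
        extra = _edges([(f"X{j}", "u1", "peak", (0.25,), ("S1",),
                         "TF-(non-TF)") for j in range(3)])
        res = grn.infer_tf_mode("TF", pd.concat([edges, extra]), traj)
        assert "u1" not in res["unique_targets"]
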