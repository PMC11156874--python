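"""End-to-end orchestration: synthetic or user inputs through every stage.

A single config (YAML-able dict) drives the run; every source of
randomness derives from one master seed; outputs are plain TSV/JSON files
hashed into a manifest so reruns can be verified bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import grn, impulse, io, perturb, pointwise, ppi_idr, signatures, topics
from .simulate import (SimulationConfig, simulate_experiment,
                       simulate_knockdown, simulate_ppi_idr)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},               # SimulationConfig overrides; None => load inputs
    "inputs": None,               # dict of paths when not simulating
    "stages": {"pointwise": True, "impulse": True, "signatures": True,
               "grn": True, "topics": True, "ppi_idr": True,
               "perturb": True, "report": True},
    "thresholds": {
        "fc_cut": 1.5, "q_deg": 0.05, "q_ideg": 0.01,
        "hideg_top_fraction": 0.75, "hideg_fc": 2.0,
        "promoter_up": 2000, "promoter_down": 1000, "motif_p_cut": 1e-4,
        "min_sd": 1.0, "min_branch": 10, "fpkm_cut": 1.0,
        "topics_k": 8, "tf_z_cut": 2.0, "gene_z_cut": 1.0, "n_perm": 1000,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _load_inputs(paths: dict) -> dict:
    counts, design = io.read_counts_design(paths["counts"], paths["design"])
    data = {
        "counts": counts, "design": design,
        "annotation": io.read_annotation(paths["annotation"]),
        "promoters": io.read_promoters(paths["promoters"])
        if paths.get("promoters") else None,
        "pwms": io.read_meme_pwms(paths["motifs"])
        if paths.get("motifs") else [],
        "truth": None,
    }
    peaks = []
    for tf, ppath in (paths.get("peaks") or {}).items():
        peaks.append(io.read_narrowpeak(ppath, tf))
    data["peaks"] = pd.concat(peaks, ignore_index=True) if peaks \
        else pd.DataFrame(columns=["chrom", "start", "end", "tf_id", "score"])
    data["ppi"] = io.read_ppi(paths["ppi"]) if paths.get("ppi") else None
    data["idr"] = io.read_idr(paths["idr"]) if paths.get("idr") else None
    return data


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run every enabled stage in dependency order into ``out_dir``.

    Returns a results dict; writes stage outputs plus a manifest with a
    sha256 per file. Missing inputs fail before any stage runs.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    th = cfg["thresholds"]
    seed = int(cfg["seed"])
    out = Path(out_dir or "woundnet_run")
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    results: dict = {"config": cfg}
    skipped: list[str] = []

    # --- inputs
    if cfg["simulate"] is not None:
        sim_cfg = SimulationConfig(**{**cfg["simulate"], "seed": seed})
        bundle = simulate_experiment(sim_cfg)
        data = {"counts": bundle.counts, "design": bundle.design,
                "annotation": bundle.annotation,
                "promoters": bundle.promoters, "peaks": bundle.peaks,
                "pwms": bundle.pwms, "truth": bundle.truth}
        ppi, idr = simulate_ppi_idr(bundle.truth, seed=seed + 1)
        data["ppi"], data["idr"] = ppi, idr
        results["bundle"] = bundle
        _write_truth(bundle, out / "truth.json")
    else:
        if not cfg["inputs"]:
            raise ValueError("either simulate or inputs must be configured")
        missing = [k for k, p in cfg["inputs"].items()
                   if isinstance(p, str) and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        data = _load_inputs(cfg["inputs"])
    counts, design = data["counts"], data["design"]
    annotation = data["annotation"]

    # --- normalization shared by everything
    sf = pointwise.estimate_size_factors(counts)
    disp = pointwise.estimate_dispersion(counts, sf, design)
    fpkm = pointwise.compute_fpkm(counts, sf, annotation)
    traj = signatures.trajectory_matrix(counts, design, sf)
    _write_tsv(sf.to_frame(), out / "size_factors.tsv", index=True)
    _write_tsv(traj, out / "trajectories.tsv", index=True)
    results.update(size_factors=sf, dispersion=disp, trajectories=traj)

    # --- pointwise DE
    if stages.get("pointwise"):
        pw_res = pointwise.run_pointwise(counts, design, sf, disp)
        degs = pointwise.call_degs(pw_res, fc_cut=th["fc_cut"],
                                   q_cut=th["q_deg"])
        _write_tsv(degs["table"], out / "pointwise.tsv")
        results["pointwise"] = degs
    else:
        skipped.append("pointwise")

    # --- impulse screen
    if stages.get("impulse"):
        screen = impulse.run_impulse_screen(
            counts, design, sf, disp, q_cut=th["q_ideg"], seed=seed + 2)
        _write_tsv(screen, out / "idegs.tsv")
        results["impulse"] = screen
    else:
        skipped.append("impulse")

    # --- signatures
    if stages.get("signatures") and stages.get("impulse") \
            and stages.get("pointwise"):
        idegs = sorted(results["impulse"].loc[results["impulse"]["is_ideg"],
                                              "gene_id"])
        results["idegs"] = idegs
        if idegs:
            hidegs = signatures.select_hidegs(
                idegs, counts, design, sf,
                top_fraction=th["hideg_top_fraction"], fc_cut=th["hideg_fc"])
            wound = signatures.define_wound_induced(
                hidegs, results["pointwise"]["table"], q_cut=th["q_deg"])
        else:
            hidegs, wound = [], []
        pd.Series(hidegs, name="gene_id").to_csv(out / "hidegs.tsv",
                                                 sep="\t", index=False)
        pd.Series(wound, name="gene_id").to_csv(out / "wound_induced.tsv",
                                                sep="\t", index=False)
        results["hidegs"], results["wound_induced"] = hidegs, wound
        if len(wound) >= 6:
            assign, composite = signatures.assign_stages(traj.loc[wound],
                                                         seed=seed + 3)
            _write_tsv(assign, out / "stages.tsv", index=True)
            _write_tsv(composite, out / "composites.tsv", index=True)
            results["stages"] = assign
    else:
        skipped.append("signatures")

    # --- regulatory network
    if stages.get("grn") and data.get("promoters"):
        windows = grn.promoter_windows(annotation, up=th["promoter_up"],
                                       down=th["promoter_down"])
        hits = grn.scan_promoters(data["promoters"], data["pwms"],
                                  p_cut=th["motif_p_cut"])
        peak_ev = grn.map_peaks_to_promoters(data["peaks"], windows)
        matrix, evidence = grn.build_tf_target_matrix(peak_ev, hits)
        fpkm_tp = grn.tf_fpkm_by_timepoint(fpkm, design)
        edges = grn.annotate_edges(evidence, traj, fpkm_tp, annotation,
                                   fpkm_cut=th["fpkm_cut"])
        class_table, autoregs = grn.classify_edges(edges, annotation)
        edges_out = edges.copy()
        edges_out["active_timepoints"] = edges_out["active_timepoints"].map(
            lambda ts: ",".join(f"{t:g}" for t in ts))
        edges_out["stages"] = edges_out["stages"].map(",".join)
        _write_tsv(edges_out, out / "edges.tsv")
        _write_tsv(class_table, out / "edge_classes.tsv")
        modes = pd.DataFrame([
            {k: v for k, v in grn.infer_tf_mode(tf, edges, traj).items()
             if k != "unique_targets"}
            for tf in sorted(set(edges["tf_id"]))])
        _write_tsv(modes, out / "tf_modes.tsv")
        degree_tables = []
        for stage in signatures.STAGE_TIMEPOINTS:
            dt = grn.stage_subnetwork_degrees(edges, stage)
            dt.insert(0, "stage", stage)
            degree_tables.append(dt)
        _write_tsv(pd.concat(degree_tables, ignore_index=True),
                   out / "degrees.tsv")
        results.update(edges=edges, tf_target_matrix=matrix,
                       autoregulators=autoregs, tf_modes=modes,
                       edge_classes=class_table)
        if "hidegs" in results and len(results["hidegs"]) >= 4 * th["min_branch"]:
            split_genes = [g for g in results["hidegs"] if g in traj.index]
            splits = grn.detect_paths_and_splits(
                traj.loc[split_genes], matrix, fpkm_tp,
                min_sd=th["min_sd"], min_branch=th["min_branch"],
                fpkm_cut=th["fpkm_cut"], seed=seed + 4)
            (out / "splits.json").write_text(json.dumps(
                _splits_jsonable(splits), indent=1, sort_keys=True))
            results["splits"] = splits
    else:
        skipped.append("grn")

    # --- topics
    if stages.get("topics") and "edges" in results:
        try:
            ttm = topics.build_time_tagged_matrix(results["edges"])
        except ValueError:
            ttm = None
        if ttm is not None:
            k_cfg = th["topics_k"]
            if k_cfg == "auto":
                k, table = topics.select_topic_number(ttm, seed=seed + 5)
                _write_tsv(table, out / "topic_selection.tsv")
            else:
                k = int(k_cfg)
            model = topics.fit_lda_gibbs(ttm, K=max(k, 2), seed=seed + 6)
            _write_tsv(model.phi, out / "topics_phi.tsv", index=True)
            _write_tsv(model.theta, out / "topics_theta.tsv", index=True)
            results["topic_model"], results["ttm"] = model, ttm
            if model.K >= 3:
                mem = topics.topic_membership_zscores(
                    model, ttm, tf_z_cut=th["tf_z_cut"],
                    gene_z_cut=th["gene_z_cut"])
                occ = topics.tf_topic_occurrence(mem["tf"])
                _write_tsv(mem["tf"], out / "topic_membership_tf.tsv")
                _write_tsv(mem["gene"], out / "topic_membership_gene.tsv")
                _write_tsv(occ, out / "topic_occurrence.tsv")
                results["membership"] = mem
    elif not stages.get("topics"):
        skipped.append("topics")
        if stages.get("ppi_idr"):
            skipped.append("ppi_idr (requires topics)")
            stages = {**stages, "ppi_idr": False}

    # --- PPI / IDR statistics
    if stages.get("ppi_idr") and results.get("membership") is not None \
            and data.get("ppi") is not None:
        mem_tf = results["membership"]["tf"]
        topic_sets = {t: set(g["tf_id"]) for t, g in mem_tf.groupby("topic")}
        universe = sorted(set(results["edges"]["tf_id"]))
        enr = ppi_idr.topic_ppi_enrichment(
            topic_sets, data["ppi"], universe, n_perm=th["n_perm"],
            seed=seed + 7)
        _write_tsv(enr, out / "ppi_enrichment.tsv")
        results["ppi_enrichment"] = enr
        idr_stats = {}
        if data.get("idr") is not None:
            fracs = io.idr_fractions(data["idr"])
            tf_set = set(universe)
            others = sorted(set(fracs.index) - tf_set)
            if others and len(tf_set) >= 3 and len(others) >= 3:
                idr_stats["presence"] = ppi_idr.idr_presence_test(
                    tf_set, set(others), data["idr"])
                idr_stats["presence"].pop("table")
                idr_stats["fraction"] = ppi_idr.idr_fraction_test(
                    fracs.reindex(sorted(tf_set & set(fracs.index))).dropna(),
                    fracs.reindex(others).dropna())
            degs_ppi = ppi_idr.ppi_degrees(data["ppi"], universe)
            tf_fracs = fracs.reindex(universe).dropna()
            if len(tf_fracs) >= 4:
                idr_stats["idr_ppi_correlation"] = ppi_idr.idr_ppi_correlation(
                    tf_fracs, degs_ppi)
            cfs = set(annotation.index[annotation["is_chromatin_factor"]])
            if cfs:
                all_tfs = set(annotation.index[annotation["is_tf"]])
                idr_stats["chromatin_overlap"] = \
                    ppi_idr.chromatin_factor_overlap(set(universe), cfs,
                                                     all_tfs)
            (out / "idr_tests.json").write_text(
                json.dumps(idr_stats, indent=1, sort_keys=True, default=float))
            results["idr_tests"] = idr_stats
    elif not stages.get("ppi_idr"):
        if "ppi_idr (requires topics)" not in skipped:
            skipped.append("ppi_idr")

    # --- perturbation (synthetic runs only: needs planted truth)
    if stages.get("perturb") and data.get("truth") is not None \
            and "edges" in results:
        results["perturbation"] = _run_perturbation(
            data["truth"], results["edges"], cfg, out, seed)
    elif not stages.get("perturb"):
        skipped.append("perturb")

    results["skipped"] = skipped
    manifest = {
        "config": _jsonable(cfg),
        "skipped_stages": skipped,
        "files": {p.name: _sha256(p) for p in sorted(out.iterdir())
                  if p.is_file() and p.name not in ("manifest.json",
                                                    "report.txt")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    if stages.get("report"):
        write_report(out)
    return results


def _run_perturbation(truth, edges, cfg, out: Path, seed: int) -> dict:
    """Knock down the best-covered planted activator (and a partner from
    the same module) and compute the validation statistics."""
    sim_cfg = SimulationConfig(**{**cfg["simulate"], "seed": seed})
    eff = truth.knockdown_effects
    activators = [tf for tf, s in truth.tf_signs.items() if s > 0]
    per_tf = eff[eff["tf_id"].isin(activators)].groupby("tf_id").size()
    if per_tf.empty:
        return {}
    tf_a = per_tf.idxmax()
    targets_a = set(eff.loc[eff["tf_id"] == tf_a, "target_id"])
    # partner: the TF sharing the most targets with tf_a
    overlap = {t: len(targets_a
                      & set(eff.loc[eff["tf_id"] == t, "target_id"]))
               for t in per_tf.index if t != tf_a}
    partners = pd.Series(overlap).sort_index() if overlap else pd.Series(
        dtype=int)
    result: dict = {"tf_a": tf_a}
    t_kd = 2.0
    kd_counts, kd_design = simulate_knockdown(truth, {tf_a}, t_kd, sim_cfg,
                                              seed=seed + 8)
    kd_a = perturb.knockdown_de(kd_counts, kd_design,
                                dispersion=sim_cfg.nb_dispersion)
    try:
        result["target_shift"] = {
            k: v for k, v in perturb.target_vs_nontarget_test(
                kd_a, edges, tf_a, direction="down").items()
            if not k.startswith("ecdf")}
    except ValueError as exc:
        result["target_shift"] = {"error": str(exc)}
    if len(partners) and partners.max() >= 5:
        tf_b = partners.idxmax()
        result["tf_b"] = tf_b
        kd_b = perturb.knockdown_de(*simulate_knockdown(
            truth, {tf_b}, t_kd, sim_cfg, seed=seed + 9),
            dispersion=sim_cfg.nb_dispersion)
        kd_ab = perturb.knockdown_de(*simulate_knockdown(
            truth, {tf_a, tf_b}, t_kd, sim_cfg, seed=seed + 10),
            dispersion=sim_cfg.nb_dispersion)
        sets = perturb.common_target_sets(edges, tf_a, tf_b,
                                          kd_a["gene_id"])
        result["n_common"] = len(sets["common"])
        if len(sets["common"]) >= 5:
            result["additive"] = perturb.additive_effect_test(
                sets["common"], kd_a, kd_b, kd_ab)
    (out / "perturbation.json").write_text(
        json.dumps(result, indent=1, sort_keys=True, default=float))
    return result


def _splits_jsonable(splits: dict) -> dict:
    return {
        "splits": [{**s, "branches": s["branches"]} for s in splits["splits"]],
        "paths": [{k: v for k, v in p.items()} for p in splits["paths"]],
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_truth(bundle, path: Path) -> None:
    truth = bundle.truth
    payload = {
        "config": _jsonable(asdict(bundle.config)),
        "planted_edges": truth.planted_edges.to_dict("records"),
        "stage_label": truth.stage_label,
        "tf_modules": truth.tf_modules,
        "tf_signs": truth.tf_signs,
        "module_stage": {str(k): v for k, v in truth.module_stage.items()},
        "autoregulators": sorted(truth.autoregulators),
        "motif_consensus": truth.motif_consensus,
        "knockdown_effects": truth.knockdown_effects.to_dict("records"),
    }
    path.write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True))


def write_report(run_dir) -> str:
    """Summarize a completed run directory into report.txt."""
    run = Path(run_dir)
    lines = ["woundnet run summary", "====================", ""]

    def count_rows(name):
        p = run / name
        if not p.exists():
            return None
        with open(p) as fh:
            return max(sum(1 for _ in fh) - 1, 0)

    manifest_p = run / "manifest.json"
    if manifest_p.exists():
        manifest = json.loads(manifest_p.read_text())
        if manifest.get("skipped_stages"):
            lines.append("skipped stages: "
                         + ", ".join(manifest["skipped_stages"]))
    for label, fname in [
            ("pointwise test rows", "pointwise.tsv"),
            ("impulse-screen rows", "idegs.tsv"),
            ("hiDEGs", "hidegs.tsv"),
            ("wound-induced genes", "wound_induced.tsv"),
            ("network edges", "edges.tsv"),
            ("TF topic memberships", "topic_membership_tf.tsv")]:
        n = count_rows(fname)
        lines.append(f"{label}: {'absent' if n is None else n}")
    idegs_p = run / "idegs.tsv"
    if idegs_p.exists():
        t = pd.read_csv(idegs_p, sep="\t")
        lines.append(f"iDEGs (q<cut): {int(t['is_ideg'].sum())} of "
                     f"{int((t['status'] == 'tested').sum())} tested")
    stages_p = run / "stages.tsv"
    if stages_p.exists():
        t = pd.read_csv(stages_p, sep="\t")
        vc = t["stage"].value_counts().sort_index()
        lines.append("stage sizes: "
                     + ", ".join(f"{k}={v}" for k, v in vc.items()))
    edges_p = run / "edges.tsv"
    if edges_p.exists():
        t = pd.read_csv(edges_p, sep="\t")
        auto = t[t["tf_id"] == t["target_id"]]["tf_id"].nunique()
        lines.append(f"autoregulators: {auto}")
    degrees_p = run / "degrees.tsv"
    if degrees_p.exists():
        t = pd.read_csv(degrees_p, sep="\t")
        if len(t):
            top = t.sort_values("degree", ascending=False).iloc[0]
            lines.append(f"top hub: {top['tf_id']} "
                         f"(degree {top['degree']}, {top['stage']})")
    splits_p = run / "splits.json"
    if splits_p.exists():
        s = json.loads(splits_p.read_text())
        tps = [sp["timepoint_h"] for sp in s["splits"]]
        lines.append(f"path splits at: {tps}")
    else:
        lines.append("path splits: absent")
    for name in ("perturbation.json", "idr_tests.json"):
        p = run / name
        if p.exists():
            lines.append(f"{name}: {p.read_text().count(chr(10))} lines "
                         "(see file)")
    text = "\n".join(lines) + "\n"
    (run / "report.txt").write_text(text)
    return text
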