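"""End-to-end orchestration: simulate -> diff -> integrate -> validate.

A single global seed yields deterministic per-stage seeds (stable hash of the
stage name), so each stage is reproducible independent of execution order.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import congenic as cg
from . import dominance as dom
from . import normdiff as nd
from . import qtl as qt
from . import rad as rd
from . import signature as sig
from .core_io import GenomicInterval
from .simulate import (
    ASSAYS,
    SimulationConfig,
    simulate,
    write_outputs,
)

_KNOWN_TOP_KEYS = {"seed", "outdir", "simulation", "stages", "thresholds"}
_KNOWN_STAGES = {"diff", "qtl", "signature", "rad", "dominance", "congenic"}
_KNOWN_THRESHOLDS = {
    "di_fdr", "min_span_bp", "min_count", "min_samples",
    "discordance_q", "min_lod", "epsilon", "n_perm",
}


class ConfigError(ValueError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def validate_config(config: dict) -> dict:
    unknown = set(config) - _KNOWN_TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages", {})
    unknown = set(stages) - _KNOWN_STAGES
    if unknown:
        raise ConfigError(f"unknown stage toggles: {sorted(unknown)}")
    thresholds = config.get("thresholds", {})
    unknown = set(thresholds) - _KNOWN_THRESHOLDS
    if unknown:
        raise ConfigError(f"unknown thresholds: {sorted(unknown)}")
    sim = config.get("simulation", {})
    known_sim = set(SimulationConfig.__dataclass_fields__)
    unknown = set(sim) - known_sim
    if unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
    return config


def run_pipeline(config: dict) -> dict:
    """Execute the synthetic end-to-end run; returns the machine-readable report."""
    validate_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "transchrom_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages_on = {s: bool(config.get("stages", {}).get(s, True)) for s in _KNOWN_STAGES}
    thr = config.get("thresholds", {})
    di_fdr = float(thr.get("di_fdr", 0.2))
    discordance_q = float(thr.get("discordance_q", 0.05))
    min_lod = float(thr.get("min_lod", 8.0))
    epsilon = float(thr.get("epsilon", 0.05))
    n_perm = int(thr.get("n_perm", 200))

    report: dict = {"seed": seed, "stages": {}, "parameters": {
        "di_fdr": di_fdr, "discordance_q": discordance_q,
        "min_lod": min_lod, "epsilon": epsilon, "n_perm": n_perm,
    }}

    def record(stage: str, outputs: dict[str, str], **extra) -> None:
        report["stages"][stage] = {
            "outputs": {k: {"path": v, "sha256_16": _file_hash(v)} for k, v in outputs.items()},
            **extra,
        }

    # --- simulate -----------------------------------------------------------
    t0 = time.time()
    sim_kwargs = dict(config.get("simulation", {}))
    sim_kwargs["seed"] = stage_seed(seed, "simulate")
    cfg = SimulationConfig(**sim_kwargs)
    result = simulate(cfg)
    sim_paths = write_outputs(result, outdir / "simulate")
    record("simulate", sim_paths, seconds=round(time.time() - t0, 2),
           config=asdict(cfg))

    layout = result.layout
    sheet = result.sample_sheet
    spec = nd.FilterSpec(
        min_span_bp=int(thr.get("min_span_bp", 5000)),
        min_count=int(thr.get("min_count", 4)),
        min_samples=int(thr.get("min_samples", 2)),
        di_fdr=di_fdr,
    )

    # --- differential tests (B6 vs D2 per assay) ----------------------------
    diff_results: dict[str, pd.DataFrame] = {}
    if stages_on["diff"]:
        t0 = time.time()
        diff_dir = outdir / "diff"
        diff_dir.mkdir(exist_ok=True)
        outputs = {}
        filter_reports = {}
        for assay in ASSAYS:
            counts = result.counts[assay]
            if assay == "PET":
                retained, freport = nd.filter_interactions(layout.interactions, counts, spec)
                counts = nd.CountMatrix(counts.df.loc[[i.id for i in retained]].copy())
                filter_reports["PET"] = freport.as_dict()
            samples = (sheet.samples_for(strain="B6", assay=assay)
                       + sheet.samples_for(strain="D2", assay=assay))
            sub = counts.subset_samples(samples)
            groups = ["B6" if s in sheet.samples_for(strain="B6", assay=assay) else "D2"
                      for s in samples]
            res = nd.differential_pipeline(sub, groups, group_order=("B6", "D2"))
            diff_results[assay] = res
            path = diff_dir / f"diff_{assay}.tsv"
            res.to_csv(path, sep="\t", index_label="feature_id")
            outputs[f"diff_{assay}"] = str(path)
        if filter_reports:
            frpath = diff_dir / "filter_report.json"
            frpath.write_text(json.dumps(filter_reports, indent=2))
            outputs["filter_report"] = str(frpath)
        n_sig = {a: int((r["qvalue"] <= di_fdr).sum()) for a, r in diff_results.items()}
        record("diff", outputs, seconds=round(time.time() - t0, 2), n_significant=n_sig)
    else:
        report["stages"]["diff"] = {"skipped": True}

    qtl_table = layout.qtl_targets
    peak_targets = qtl_table[qtl_table["feature_type"] == "peak"]

    # --- qtl integration ----------------------------------------------------
    if stages_on["qtl"] and stages_on["diff"]:
        t0 = time.time()
        qdir = outdir / "qtl"
        qdir.mkdir(exist_ok=True)
        pet = diff_results["PET"]
        dis_called = nd.call_differential(pet, di_fdr)
        di_ids = set(dis_called.index)
        dis = [i for i in layout.interactions if i.id in di_ids]
        target_ivs = [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.target_id)
            for r in peak_targets.itertuples(index=False)
        ]
        classification = qt.classify_anchor_overlap(dis, target_ivs)
        enr = qt.permutation_enrichment(
            dis, target_ivs, layout.peaks, n_perm=n_perm, seed=stage_seed(seed, "qtl")
        )
        targets = [
            qt.QtlTarget(r.target_id,
                         GenomicInterval(r.chrom, int(r.start), int(r.end), r.target_id),
                         r.mode, r.high_allele, r.lod, r.effect_size, r.qtl_locus)
            for r in peak_targets.itertuples(index=False)
        ]
        fc_map = dis_called["log2fc"].to_dict()
        pairs = qt.pair_di_targets(dis, fc_map, targets)
        corr = {}
        for mode in ("cis", "trans"):
            sel = pairs[pairs["mode"] == mode]
            if len(sel) >= 3 and sel["di_log2fc"].std() > 0 and sel["effect_size"].std() > 0:
                corr[mode] = qt.correlate_strength_effect(
                    sel["di_log2fc"], sel["effect_size"], mode)
        directions = np.where(pairs["di_log2fc"] > 0, "higher_in_a",
                              np.where(pairs["di_log2fc"] < 0, "higher_in_b", "none"))
        keep = directions != "none"
        conc = qt.allele_concordance(list(directions[keep]), list(pairs["high_allele"][keep]))
        cpath = qdir / "classification.tsv"
        classification.to_csv(cpath, sep="\t", index=False)
        jpath = qdir / "qtl_integration.json"
        jpath.write_text(json.dumps({
            "proportions": classification.attrs["proportions"],
            "enrichment": {c: {"observed": e.observed, "pvalue": e.pvalue, "n_perm": e.n_perm}
                           for c, e in enr.items()},
            "correlation": corr,
            "concordance": {k: v for k, v in conc.items() if k != "table"},
        }, indent=2, default=float))
        record("qtl", {"classification": str(cpath), "summary": str(jpath)},
               seconds=round(time.time() - t0, 2))
    else:
        report["stages"]["qtl"] = {"skipped": True}

    # --- chromatin signature ------------------------------------------------
    if stages_on["signature"] and stages_on["diff"]:
        t0 = time.time()
        sdir = outdir / "signature"
        sdir.mkdir(exist_ok=True)
        fc_frames = []
        for assay in ("ATAC", "H3K27ac", "H3K9me3"):
            res = diff_results[assay]
            fc_frames.append(pd.DataFrame(dict(
                feature_id=res.index, assay=assay,
                log2fc=res["log2fc"].to_numpy(), qvalue=res["qvalue"].to_numpy())))
        fc_table = pd.concat(fc_frames, ignore_index=True)
        calls = sig.call_discordance(fc_table, q_threshold=discordance_q)
        class_map = {r.target_id: r.mode for r in peak_targets.itertuples(index=False)}
        contrast = sig.discordance_odds_ratio(calls, class_map)
        corr = {}
        for mode in ("cis", "trans"):
            ids = [t for t, m in class_map.items() if m == mode]
            corr[mode] = sig.correlate_assays(fc_table, "ATAC", "H3K9me3", ids)
        fpath = sdir / "foldchanges.tsv"
        fc_table.to_csv(fpath, sep="\t", index=False)
        dpath = sdir / "discordance.tsv"
        calls.to_csv(dpath, sep="\t", index=False)
        jpath = sdir / "contrast.json"
        jpath.write_text(json.dumps({
            "odds_ratio": contrast["odds_ratio"], "beta": contrast["beta"],
            "pvalue": contrast["pvalue"], "ci95": list(contrast["ci95"]),
            "table": contrast["table"],
            "correlation_atac_k9": corr,
        }, indent=2, default=float))
        record("signature", {"foldchanges": str(fpath), "discordance": str(dpath),
                             "contrast": str(jpath)},
               seconds=round(time.time() - t0, 2))
    else:
        report["stages"]["signature"] = {"skipped": True}

    # --- RAD spatial enrichment ---------------------------------------------
    if stages_on["rad"]:
        t0 = time.time()
        rdir = outdir / "rad"
        rdir.mkdir(exist_ok=True)
        rcfg = rd.RadConfig(window_bp=cfg.rad_window_bp)
        eff = layout.effects
        focal_peaks = eff[(eff["feature_type"] == "peak") & (eff["class"] == "trans_target")].index
        linked = eff[(eff["feature_type"] == "gene") & (eff["class"] == "trans_target")].index
        conns = rd.build_connections(layout.genes, layout.peaks, linked, focal_peaks, rcfg)
        enrichment = rd.rad_enrichment(conns, rcfg)
        conns_ctrl = rd.build_connections(
            layout.genes, layout.peaks, layout.control_egenes, focal_peaks, rcfg)
        control = rd.rad_enrichment(conns_ctrl, rcfg)
        epath = rdir / "rad_linked.tsv"
        enrichment.to_csv(epath, sep="\t", index=False)
        cpath = rdir / "rad_control.tsv"
        control.to_csv(cpath, sep="\t", index=False)
        record("rad", {"linked": str(epath), "control": str(cpath)},
               seconds=round(time.time() - t0, 2))
    else:
        report["stages"]["rad"] = {"skipped": True}

    # --- dominance ----------------------------------------------------------
    if stages_on["dominance"]:
        t0 = time.time()
        ddir = outdir / "dominance"
        ddir.mkdir(exist_ok=True)
        counts = result.counts["ATAC"]
        norm = nd.cpm(counts, nd.tmm_factors(counts))
        log2cpm = np.log2(norm + 0.5)
        means = pd.DataFrame({
            s: log2cpm[sheet.samples_for(strain=s, assay="ATAC")].mean(axis=1)
            for s in ("B6", "D2", "F1")
        })
        hi_lod = peak_targets[peak_targets["lod"] > min_lod]
        table = dom.dominance_table(means.loc[means.index.intersection(hi_lod["target_id"])],
                                    epsilon=epsilon)
        mode_map = hi_lod.set_index("target_id")["mode"]
        table["mode"] = mode_map.reindex(table.index)
        comp = dom.compare_dominance(
            table.loc[table["mode"] == "trans", "d"],
            table.loc[table["mode"] == "cis", "d"],
        )
        alleles = dom.classify_repressive_alleles(peak_targets[peak_targets["mode"] == "trans"])
        frac_d2 = float((alleles["repressive_allele"] == "D2").mean())
        tpath = ddir / "dominance.tsv"
        table.to_csv(tpath, sep="\t", index_label="feature_id")
        jpath = ddir / "comparison.json"
        jpath.write_text(json.dumps({**comp, "frac_d2_repressive": frac_d2},
                                    indent=2, default=float))
        record("dominance", {"table": str(tpath), "comparison": str(jpath)},
               seconds=round(time.time() - t0, 2))
    else:
        report["stages"]["dominance"] = {"skipped": True}

    # --- congenic validation ------------------------------------------------
    if stages_on["congenic"]:
        t0 = time.time()
        vdir = outdir / "congenic"
        vdir.mkdir(exist_ok=True)
        calls = dom.classify_repressive_alleles(
            peak_targets[peak_targets["mode"] == "trans"])
        preds = cg.predict_directions(calls, assays=("H3K9me3", "ATAC", "H3K27ac"))
        target_ivs = {
            r.target_id: GenomicInterval(r.chrom, int(r.start), int(r.end), r.target_id)
            for r in calls.itertuples(index=False)
        }
        pet_preds = cg.predict_interaction_directions(layout.interactions, calls, target_ivs)
        preds = pd.concat([preds, pet_preds], ignore_index=True)
        obs_frames = []
        for comparison in cg.COMPARISONS:
            for assay in ("H3K9me3", "ATAC", "H3K27ac", "PET"):
                obs_frames.append(
                    cg.observe_direction(result.counts[assay], sheet, comparison, assay))
        observations = pd.concat(obs_frames, ignore_index=True)
        per_feature, summary = cg.validate(preds, observations)
        effect = cg.effectsize_validated_vs_not(per_feature)
        ppath = vdir / "per_feature.tsv"
        per_feature.to_csv(ppath, sep="\t", index=False)
        spath = vdir / "summary.tsv"
        summary.to_csv(spath, sep="\t", index=False)
        jpath = vdir / "effect_size.json"
        jpath.write_text(json.dumps(effect, indent=2, default=float))
        record("congenic", {"per_feature": str(ppath), "summary": str(spath),
                            "effect_size": str(jpath)},
               seconds=round(time.time() - t0, 2))
    else:
        report["stages"]["congenic"] = {"skipped": True}

    rpath = outdir / "report.json"
    rpath.write_text(json.dumps(report, indent=2, default=float))
    return report
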