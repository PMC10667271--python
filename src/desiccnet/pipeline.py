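"""Pipeline orchestration: simulate (or load) inputs, then run
physiology, differential expression, network inference, metabolomics
and phytohormone stages, writing every table plus a JSON manifest.

The manifest records the config hash, seed and per-stage row/edge
counts; identical config + seed yields a byte-identical manifest (no
timestamps in the manifest — timings go to the log).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import coexnet, diffexpr, hormones, io, metabolomics, physiology
from .config import PipelineConfig
from .simulate import (HORMONES, generate_expression, generate_hormones,
                       generate_metabolites, generate_physiology)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to
    ``<outdir>/manifest.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    timings = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            counts = fn()
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            manifest["stages"][name] = {"status": "failed"}
            _write_manifest(manifest, outdir)
            raise StageError(name, exc) from exc
        timings[name] = time.perf_counter() - t0
        manifest["stages"][name] = {"status": "ok", **counts}
        logger.info("stage %s done in %.2fs", name, timings[name])

    data = {}

    def stage_inputs():
        if config.simulate is not None:
            sim = config.simulate
            expr, samples, truth = generate_expression(sim)
            met, _, met_truth = generate_metabolites(sim)
            horm, horm_truth = generate_hormones(sim)
            weights, viability, survival = generate_physiology(sim)
            truth.metabolite_truth = met_truth.metabolite_truth
            truth.hormone_profile_truth = horm_truth.hormone_profile_truth
            data.update(expression=expr, samples=samples, metabolites=met,
                        hormones=horm, weights=weights, viability=viability,
                        survival=survival)
            io.write_inputs(outdir / "inputs", expr=expr, samples=samples,
                            metabolites=met, hormones=horm, weights=weights,
                            viability=viability, survival=survival,
                            truth=truth)
        else:
            data.update(io.read_inputs(config.input_dir))
            if "expression" not in data or "samples" not in data:
                raise FileNotFoundError(
                    f"expression.tsv / samples.csv not found in "
                    f"{config.input_dir}")
        return {"n_genes": int(len(data["expression"])),
                "n_samples": int(len(data["samples"]))}

    def stage_physiology():
        counts = {}
        if "weights" in data:
            rwc = physiology.compute_rwc_table(data["weights"])
            io.write_table(rwc, outdir / "rwc.csv")
            counts["n_weight_records"] = int(len(rwc))
        if "survival" in data:
            band = physiology.survival_threshold(data["survival"])
            counts["survival_threshold_band"] = band
        if "viability" in data:
            cdi = physiology.cell_death_index(data["viability"])
            io.write_table(
                pd.DataFrame(sorted(cdi.items()),
                             columns=["treatment", "cell_death_index"]),
                outdir / "cell_death_index.csv")
            counts["n_viability_treatments"] = len(cdi)
        return counts

    deg_by_tissue = {}

    def stage_diffexpr():
        expr, samples = data["expression"], data["samples"]
        counts = {}
        frames = []
        for tissue in samples["tissue"].unique():
            tables = diffexpr.deg_tables_for_tissue(
                expr, samples, tissue,
                fc_threshold=config.fc_threshold, alpha=config.alpha)
            deg_by_tissue[tissue] = tables
            for state, t in tables.items():
                frames.append(t)
                counts[f"n_degs_{tissue}_{state}"] = int(t["passes"].sum())
        io.write_table(pd.concat(frames, ignore_index=True),
                       outdir / "degs.tsv")
        return counts

    def stage_coexnet():
        expr, samples = data["expression"], data["samples"]
        counts = {}
        for tissue in samples["tissue"].unique():
            ranking = coexnet.rank_by_cv(expr, samples, tissue)
            top = coexnet.select_top_k(ranking, k=min(config.top_k,
                                                      len(ranking)))
            cols = samples.loc[samples["tissue"] == tissue,
                               "sample_id"].tolist()
            corr = coexnet.pearson_all_pairs(expr.loc[top, cols])
            net = coexnet.build_network(corr, threshold=config.corr_threshold,
                                        tissue=tissue)
            overlay = coexnet.overlay_deg_states(
                net, deg_by_tissue.get(tissue, {}))
            summary = coexnet.summarize_states(net, overlay) if overlay else None
            coexnet.export_network(net, overlay,
                                   outdir / f"network_{tissue}.edges.tsv",
                                   outdir / f"network_{tissue}.graphml")
            if summary is not None:
                io.write_table(summary["per_state"],
                               outdir / f"network_{tissue}_state_summary.csv")
                summary["jaccard"].to_csv(
                    outdir / f"network_{tissue}_jaccard.csv",
                    float_format="%.17g")
            counts[f"n_nodes_{tissue}"] = int(net.number_of_nodes())
            counts[f"n_edges_{tissue}"] = int(net.number_of_edges())
        return counts

    def stage_metabolomics():
        if "metabolites" not in data:
            return {"skipped": True}
        met, samples = data["metabolites"], data["samples"]
        fc = metabolomics.metabolite_fold_changes(met, samples,
                                                  alpha=config.alpha)
        io.write_table(fc, outdir / "metabolite_fold_changes.csv")
        row_order, col_order = metabolomics.heatmap_order(met)
        pca = metabolomics.run_pca(met)
        io.write_table(pca.scores.reset_index(names="sample_id"),
                       outdir / "metabolite_pca_scores.csv")
        with open(outdir / "metabolite_heatmap_order.json", "w") as fh:
            json.dump({"rows": list(row_order), "columns": list(col_order)},
                      fh, indent=1)
        return {"n_fold_change_rows": int(len(fc)),
                "n_significant_up": int(fc["significant_up"].sum())}

    def stage_hormones():
        if "hormones" not in data:
            return {"skipped": True}
        meas = data["hormones"]
        rows = []
        for hormone in meas["hormone"].unique():
            f, p = hormones.anova_oneway(meas, hormone)
            letters = hormones.compact_letters(meas, hormone,
                                               alpha=config.alpha)
            for state, letter in letters.items():
                rows.append({"hormone": hormone, "state": state,
                             "anova_F": f, "anova_p": p, "letters": letter})
        table = pd.DataFrame(rows)
        io.write_table(table, outdir / "hormone_letters.csv")
        return {"n_hormones": int(meas["hormone"].nunique())}

    run_stage("inputs", stage_inputs)
    run_stage("physiology", stage_physiology)
    run_stage("diffexpr", stage_diffexpr)
    run_stage("coexnet", stage_coexnet)
    run_stage("metabolomics", stage_metabolomics)
    run_stage("phytohormones", stage_hormones)

    _write_manifest(manifest, outdir)
    with open(outdir / "pipeline.log", "w") as fh:
        for name, dt in timings.items():
            fh.write(f"{name}\t{dt:.3f}s\n")
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
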