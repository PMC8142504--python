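"""Config-driven orchestration of the full subtype-discovery flow.

The pipeline runs, in order: the prognostic immune-gene screen on the
training cohort, consensus-NMF subtyping (validation cohorts re-clustered
with the training gene list), immune scoring with group tests and
correlation screening per cohort, the DEG/GSEA contrast on the training
cohort, per-cohort mutation summaries, the random-forest classifier with
cross-cohort prediction, subclass mapping against the immunotherapy
cohort, and co-expression modules with hub-gene intersection. Every stage
writes plain TSV tables; a manifest records the config hash, the derived
per-stage seeds and the package version, and suffices to re-run any
single stage in isolation (the ``stage`` CLI verb reads the cached
upstream tables).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, scoring
from .classifier import predict_subtypes, roc_auc, select_classifier_genes, train_and_cv
from .dge import call_degs, preranked_gsea, rank_by_logfc
from .mutations import driver_compare, summarize_maf
from .network import CoexpressionNetwork, NetworkConfig, hub_and_intersect
from .nmf import assign_subtypes
from .submap import submap_correspondence
from .survival import km_logrank, screen_irgs

logger = logging.getLogger(__name__)

STAGES = ["screen", "subtype", "scores", "dge", "mutations", "classifier",
          "submap", "network"]

_CSV_KW = dict(sep="\t", float_format="%.10g")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config, base=Path(path).parent)
    return config


def validate_config(config: dict, base: Path | None = None) -> None:
    cohorts = config.get("cohorts", [])
    if not cohorts:
        raise ValueError("config must list at least one cohort")
    training = [c for c in cohorts if c.get("training")]
    if len(training) != 1:
        raise ValueError("exactly one cohort must be flagged training: true")
    names = [c["name"] for c in cohorts]
    if len(set(names)) != len(names):
        raise ValueError("cohort names must be unique")
    base = base or Path(".")
    for c in cohorts:
        for key in ("expression", "clinical"):
            if key not in c:
                raise ValueError(f"cohort {c['name']}: missing {key} path")
            p = _resolve(c[key], base)
            if not p.exists():
                raise ValueError(f"cohort {c['name']}: {key} path {p} does not exist")
    if "seed" not in config:
        raise ValueError("config must set a master seed")


def stage_seed(master: int, stage: str) -> int:
    return (int(master) * 1009 + STAGES.index(stage) * 97 + 11) % (2**31 - 1)


def _resolve(path, base: Path) -> Path:
    p = Path(path)
    return p if p.is_absolute() else base / p


def build_context(config: dict, base_path=".") -> dict:
    """Load all configured inputs into a stage context."""
    base = Path(base_path)
    validate_config(config, base=base)
    cohorts = []
    for spec in config["cohorts"]:
        c = {
            "name": spec["name"],
            "expression": io.read_expression(_resolve(spec["expression"], base),
                                             spec.get("unit", "raw_counts")),
            "clinical": io.read_clinical(_resolve(spec["clinical"], base)),
            "training": bool(spec.get("training", False)),
        }
        if spec.get("maf"):
            c["maf"] = io.read_maf(_resolve(spec["maf"], base))
        cohorts.append(c)
    gs = config.get("gene_sets", {})
    training = next(c for c in cohorts if c["training"])
    ctx = {
        "config": config,
        "params": config.get("params", {}),
        "master_seed": int(config["seed"]),
        "cohorts": cohorts,
        "training": training,
        "irg_list": io.read_gene_list(_resolve(gs["irg_list"], base))
        if "irg_list" in gs else list(training["expression"].values.index),
        "cell_types": io.read_gmt(_resolve(gs["cell_types"], base))
        if "cell_types" in gs else None,
        "stromal_immune": io.read_gmt(_resolve(gs["stromal_immune"], base))
        if "stromal_immune" in gs else None,
        "pathways": io.read_gmt(_resolve(gs["pathways"], base))
        if "pathways" in gs else None,
        "drivers": io.read_gene_list(_resolve(gs["drivers"], base))
        if "drivers" in gs else [],
    }
    if config.get("immunotherapy"):
        it = config["immunotherapy"]
        ctx["immunotherapy"] = {
            "expression": io.read_expression(_resolve(it["expression"], base),
                                             it.get("unit", "raw_counts")),
            "response": pd.read_csv(_resolve(it["response"], base), sep="\t",
                                    index_col=0).iloc[:, 0],
        }
    return ctx


def load_cached(ctx: dict, outdir) -> None:
    """Populate the context from tables a previous run wrote."""
    outdir = Path(outdir)
    p = outdir / "screen_retained.tsv"
    if p.exists():
        ctx["nmf_genes"] = pd.read_csv(p, sep="\t")["gene"].tolist()
    assignments = {}
    for c in ctx["cohorts"]:
        p = outdir / f"subtypes_{c['name']}.tsv"
        if p.exists():
            assignments[c["name"]] = io.read_assignment(p, cohort=c["name"])
    if assignments:
        ctx["assignments"] = assignments
    p = outdir / "degs.tsv"
    if p.exists():
        deg = pd.read_csv(p, sep="\t", index_col=0)
        deg["is_deg"] = deg["is_deg"].astype(bool)
        ctx["deg"] = deg


# --------------------------------------------------------------------------
# stages


def _stage_screen(ctx, outdir, seed):
    params = ctx["params"]
    training = ctx["training"]
    screen = screen_irgs(
        training["expression"], training["clinical"], ctx["irg_list"],
        p_threshold=params.get("screen_p", 0.05),
        mad_threshold=params.get("mad_threshold", 0.5),
    )
    screen.table.to_csv(outdir / "screen.tsv", index_label="gene", **_CSV_KW)
    ctx["nmf_genes"] = screen.mad_retained_genes
    pd.Series(screen.mad_retained_genes, name="gene").to_csv(
        outdir / "screen_retained.tsv", sep="\t", index=False)
    return {"n_retained": len(screen.retained_genes),
            "n_nmf_genes": len(screen.mad_retained_genes)}


def _stage_subtype(ctx, outdir, seed):
    params = ctx["params"]
    assignments = {}
    rank_range = range(params.get("rank_min", 2), params.get("rank_max", 6) + 1)
    for c in ctx["cohorts"]:
        A = io.log2cpm(c["expression"], genes=ctx["nmf_genes"])
        k, assignment, summary = assign_subtypes(
            A, rank_range=rank_range, n_restarts=params.get("n_restarts", 30),
            seed=seed, max_iter=params.get("nmf_max_iter", 2000),
            cohort=c["name"],
        )
        assignments[c["name"]] = assignment
        io.write_assignment(assignment, outdir / f"subtypes_{c['name']}.tsv")
        summary.metrics_frame().to_csv(outdir / f"rank_metrics_{c['name']}.tsv",
                                       **_CSV_KW)
        np.savetxt(outdir / f"consensus_{c['name']}.tsv", summary.consensus[k],
                   delimiter="\t", fmt="%.10g")
        surv = c["clinical"].survival("os")
        common = [s for s in assignment.sample_ids if s in surv.index]
        lr = km_logrank(assignment.labels.loc[common],
                        surv.loc[common, "time"], surv.loc[common, "event"])
        pd.DataFrame({"chi2": [lr["chi2"]], "p": [lr["p"]]}).to_csv(
            outdir / f"logrank_{c['name']}.tsv", index=False, **_CSV_KW)
    ctx["assignments"] = assignments
    return {"k": {n: a.k for n, a in assignments.items()}}


def _stage_scores(ctx, outdir, seed):
    params = ctx["params"]
    for c in ctx["cohorts"]:
        expr = c["expression"]
        assignment = ctx["assignments"][c["name"]]
        table = pd.DataFrame(index=expr.sample_ids)
        if ctx["stromal_immune"] is not None:
            table = table.join(scoring.estimate_scores(
                expr, ctx["stromal_immune"]["stromal"],
                ctx["stromal_immune"]["immune"]))
        if ctx["cell_types"] is not None:
            enr = scoring.ssgsea_enrichment(io.log2cpm(expr), ctx["cell_types"])
            adaptive = [n for n in scoring.ADAPTIVE_CELL_TYPES
                        if n in enr["nes"].index]
            innate = [n for n in scoring.INNATE_CELL_TYPES if n in enr["nes"].index]
            enr["nes"].T.to_csv(outdir / f"cell_type_nes_{c['name']}.tsv",
                                index_label="sample_id", **_CSV_KW)
            table = table.join(scoring.iis_tis(enr, adaptive, innate))
        try:
            table = table.join(scoring.apm_score(io.log2cpm(expr)))
        except (ValueError, KeyError):
            logger.warning("APM score unavailable in cohort %s", c["name"])
        table = table.join(scoring.cyt_score(expr))
        table["checkpoint_sig"] = scoring.signature_mean(
            expr, scoring.checkpoint_genes(params.get("checkpoint_literal", False)))
        table["infg_sig"] = scoring.signature_mean(expr, scoring.INFG_GENES)
        table["cd8_sig"] = scoring.signature_mean(expr, scoring.CD8_GENES)
        if "maf" in c:
            table = table.join(scoring.compute_tmb(
                c["maf"], footprint_mb=params.get("footprint_mb", 35.0),
                cohort_samples=expr.sample_ids))
        table.to_csv(outdir / f"scores_{c['name']}.tsv",
                     index_label="sample_id", **_CSV_KW)
        if assignment.k == 2:
            labels = assignment.labels.loc[table.index]
            tests = []
            for col in table.columns:
                if table[col].isna().any():
                    continue
                res = scoring.wilcoxon_test(table[col].to_numpy(), labels.to_numpy())
                tests.append((col, res["U"], res["p"]))
            pd.DataFrame(tests, columns=["score", "U", "p"]).to_csv(
                outdir / f"score_tests_{c['name']}.tsv", index=False, **_CSV_KW)
        numeric = table.dropna(axis=1)
        if numeric.shape[1] >= 2:
            scoring.pearson_strong(numeric).to_csv(
                outdir / f"score_correlations_{c['name']}.tsv", index=False,
                **_CSV_KW)
    return {}


def _stage_dge(ctx, outdir, seed):
    params = ctx["params"]
    training = ctx["training"]
    deg = call_degs(training["expression"],
                    ctx["assignments"][training["name"]].labels,
                    p_thresh=params.get("deg_p", 0.01),
                    fdr_thresh=params.get("deg_fdr", 0.05),
                    lfc_thresh=params.get("deg_lfc", 1.0))
    deg.to_csv(outdir / "degs.tsv", index_label="gene", **_CSV_KW)
    ctx["deg"] = deg
    if ctx["pathways"] is not None:
        gsea = preranked_gsea(rank_by_logfc(deg), ctx["pathways"],
                              n_perm=params.get("gsea_n_perm", 1000), seed=seed)
        gsea.table.to_csv(outdir / "gsea.tsv", **_CSV_KW)
    return {"n_degs": int(deg["is_deg"].sum())}


def _stage_mutations(ctx, outdir, seed):
    params = ctx["params"]
    for c in ctx["cohorts"]:
        if "maf" not in c:
            continue
        land = summarize_maf(c["maf"], ctx["assignments"][c["name"]],
                             top_n=params.get("top_mutated_genes", 20))
        land.gene_frequency.to_csv(outdir / f"mutation_frequency_{c['name']}.tsv",
                                   index_label="gene", **_CSV_KW)
        land.classification_counts.to_csv(
            outdir / f"mutation_classes_{c['name']}.tsv",
            index_label="classification", **_CSV_KW)
        land.spectrum.to_csv(outdir / f"snv_spectrum_{c['name']}.tsv",
                             index_label="substitution", **_CSV_KW)
        if ctx["drivers"] and ctx["assignments"][c["name"]].k == 2:
            driver_compare(c["maf"], ctx["assignments"][c["name"]],
                           ctx["drivers"]).to_csv(
                outdir / f"driver_compare_{c['name']}.tsv", **_CSV_KW)
    return {}


def _stage_classifier(ctx, outdir, seed):
    params = ctx["params"]
    training = ctx["training"]
    genes = select_classifier_genes(ctx["deg"], training["expression"],
                                    training["clinical"],
                                    p=params.get("classifier_cox_p", 0.05))
    spec = train_and_cv(
        training["expression"], ctx["assignments"][training["name"]], genes,
        mtry=params.get("mtry", 2), ntree=params.get("ntree", 500),
        folds=params.get("cv_folds", 10), repeats=params.get("cv_repeats", 10),
        seed=seed, subset_sizes=params.get("subset_sizes"),
    )
    spec.cv_error_curve.rename_axis("n_variables").to_csv(
        outdir / "cv_error_curve.tsv", **_CSV_KW)
    pd.Series(spec.selected_genes, name="gene").to_csv(
        outdir / "classifier_genes.tsv", sep="\t", index=False)
    aucs = {}
    for c in ctx["cohorts"]:
        assignment = ctx["assignments"][c["name"]]
        pred = predict_subtypes(spec, c["expression"], reference=assignment)
        pred["labels"].to_csv(outdir / f"predicted_{c['name']}.tsv",
                              sep="\t", index_label="sample_id")
        score = pred["votes"]["sub1"].loc[assignment.sample_ids]
        truth = (assignment.labels == "sub1").astype(int)
        roc = roc_auc(score.to_numpy(), truth.to_numpy())
        aucs[c["name"]] = {"auc": roc["auc"], "concordance": pred["concordance"]}
    pd.DataFrame(aucs).T.to_csv(outdir / "classifier_performance.tsv",
                                index_label="cohort", **_CSV_KW)
    return {"n_genes": len(spec.selected_genes), "performance": aucs}


def _stage_submap(ctx, outdir, seed):
    params = ctx["params"]
    if "immunotherapy" not in ctx:
        return {"skipped": "no immunotherapy cohort configured"}
    it = ctx["immunotherapy"]
    for c in ctx["cohorts"]:
        res = submap_correspondence(
            c["expression"], ctx["assignments"][c["name"]].labels,
            it["expression"], it["response"],
            n_markers=params.get("submap_markers", 100),
            n_perm=params.get("submap_n_perm", 200), seed=seed,
        )
        res.p_matrix.to_csv(outdir / f"submap_p_{c['name']}.tsv",
                            index_label="subtype", **_CSV_KW)
        res.bonferroni_matrix.to_csv(outdir / f"submap_bonferroni_{c['name']}.tsv",
                                     index_label="subtype", **_CSV_KW)
    return {}


def _stage_network(ctx, outdir, seed):
    params = ctx["params"]
    deg_genes = ctx["deg"].index[ctx["deg"]["is_deg"]].tolist()
    net_cfg = NetworkConfig(
        min_module_size=params.get("min_module_size", 10),
        scale_free_r2_target=params.get("scale_free_r2", 0.8),
    )
    stats_per, modules_per = {}, {}
    for c in ctx["cohorts"]:
        genes_present = [g for g in deg_genes if g in c["expression"].values.index]
        if len(genes_present) < 2 * net_cfg.min_module_size:
            logger.warning("cohort %s: too few DEGs for a network", c["name"])
            continue
        X = io.log2cpm(c["expression"], genes=genes_present).T
        indicator = (ctx["assignments"][c["name"]].labels == "sub1").astype(float)
        try:
            net = CoexpressionNetwork(config=net_cfg).fit(X, indicator.loc[X.index])
        except ValueError as e:
            logger.warning("cohort %s: %s; skipped in hub intersection",
                           c["name"], e)
            continue
        stats_per[c["name"]] = net.stats_
        modules_per[c["name"]] = net.modules_
        net.modules_.labels.to_csv(outdir / f"modules_{c['name']}.tsv",
                                   sep="\t", index_label="gene")
        net.stats_["eigengenes"].to_csv(outdir / f"eigengenes_{c['name']}.tsv",
                                        index_label="sample_id", **_CSV_KW)
        net.stats_["module_trait"].to_csv(outdir / f"module_trait_{c['name']}.tsv",
                                          **_CSV_KW)
    if not stats_per:
        return {"skipped": "no cohort had enough DEGs"}
    hubs = hub_and_intersect(stats_per, modules_per,
                             mm_min=params.get("hub_mm_min", 0.8),
                             gs_min=params.get("hub_gs_min", 0.5))
    rows = [(cohort, g) for cohort, gl in hubs["hubs"].items() for g in gl]
    rows += [("intersection", g) for g in hubs["intersection"]]
    pd.DataFrame(rows, columns=["cohort", "gene"]).to_csv(
        outdir / "hub_genes.tsv", sep="\t", index=False)
    return {"n_intersection": len(hubs["intersection"])}


_STAGE_FUNCS = {
    "screen": _stage_screen,
    "subtype": _stage_subtype,
    "scores": _stage_scores,
    "dge": _stage_dge,
    "mutations": _stage_mutations,
    "classifier": _stage_classifier,
    "submap": _stage_submap,
    "network": _stage_network,
}


def run_pipeline(config: dict, outdir, base_path=".") -> Path:
    """Execute the full flow; returns the output directory."""
    t_start = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = build_context(config, base_path)
    manifest = {
        "config_hash": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()).hexdigest(),
        "version": __version__,
        "seeds": {s: stage_seed(ctx["master_seed"], s) for s in STAGES},
        "stages": {},
    }
    for stage in STAGES:
        t0 = time.time()
        try:
            info = _STAGE_FUNCS[stage](ctx, outdir, stage_seed(ctx["master_seed"],
                                                               stage))
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2),
                                     **(info or {})}
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)
    manifest["total_seconds"] = round(time.time() - t_start, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def run_stage(config: dict, outdir, stage: str, base_path=".") -> dict:
    """Re-run one stage, reading upstream inputs from cached tables."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = build_context(config, base_path)
    load_cached(ctx, outdir)
    try:
        return _STAGE_FUNCS[stage](ctx, outdir,
                                   stage_seed(ctx["master_seed"], stage)) or {}
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e
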