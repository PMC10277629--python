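"""End-to-end driver: simulate -> preprocess -> deconvolve -> screen x2 ->
classify -> co-expression -> module enrichment, with a reproducible manifest.

Every stage writes its table(s) into the output directory as TSV; a
``manifest.json`` records seeds, thresholds, package versions and stage
timings so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, coexpr, deconv, effects, gee, io, preprocess, synth
from .config import PipelineConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclasses.dataclass
class PipelineResult:
    outdir: Path
    manifest: dict


def simulate_cohort(config: PipelineConfig, seed: int | None = None):
    """Generate signature, compositions, plan, counts, metadata and truth."""
    c = config.cohort
    seed = config.seed if seed is None else seed
    signature = synth.generate_signature(
        c.n_genes, c.n_cell_types, c.markers_per_type, c.marker_fold, seed=seed
    )
    shifts = {tp: {c.shifted_type: delta} for tp, delta in c.shift_schedule}
    compositions = synth.generate_compositions(
        c.n_subjects,
        c.timepoints,
        dict(zip(signature.cell_types, c.baseline_alpha)),
        logit_shifts=shifts,
        seed=seed + 1,
    )
    plan = synth.default_regulation_plan(
        signature,
        compositions,
        regulated_fraction=c.regulated_fraction,
        effect_size=c.regulation_effect,
        mixed_markers=c.mixed_markers,
        tau=c.tau,
        phi_range=(c.phi_min, c.phi_max),
        lib_size_mean=c.lib_size_mean,
        lib_size_cv=c.lib_size_cv,
        revert_postpartum=c.revert_postpartum,
        seed=seed + 2,
    )
    counts, metadata, truth = synth.generate_counts(
        signature, compositions, plan, seed=seed + 3
    )
    return signature, compositions, plan, counts, metadata, truth


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    t = config.thresholds
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    _write_manifest(outdir, manifest, timings)
                    raise StageError(name, exc) from exc
                logger.info("stage %s finished in %.2fs", name, timings[name])
                return False

        return _Timer()

    with stage("simulate"):
        signature, compositions, plan, counts, metadata, truth = simulate_cohort(config)
        io.write_table(signature.values, outdir / "signature.tsv")
        io.write_counts(counts, outdir / "counts.tsv")
        io.write_metadata(metadata, outdir / "metadata.tsv")
        io.write_table(truth.table, outdir / "truth.tsv")
        io.write_table(truth.proportions, outdir / "true_proportions.tsv")

    with stage("preprocess"):
        filtered = preprocess.filter_low_expression(
            counts, cpm_numerator=t.cpm_numerator, min_samples=t.min_samples
        )
        factors = preprocess.tmm_factors(filtered)
        cpm = preprocess.cpm_normalized(filtered, factors)
        log_cpm = preprocess.cpm_normalized(filtered, factors, log=True)
        io.write_table(
            pd.DataFrame(
                {"tmm_factor": factors.factors, "lib_size": factors.lib_sizes}
            ),
            outdir / "norm_factors.tsv",
        )
        manifest["stages"]["preprocess"] = {
            "n_genes_in": int(counts.shape[0]),
            "n_genes_kept": int(filtered.shape[0]),
            "reference_sample": factors.reference,
        }

    with stage("deconvolve"):
        est = deconv.estimate_proportions(cpm, signature.values)
        pcs = deconv.proportion_pcs(est)
        selected = deconv.select_pcs(
            pcs, log_cpm, fdr=t.pc_fdr, min_genes_fraction=t.pc_min_genes_fraction
        )
        pc_scores = pcs.scores.iloc[:, list(selected)]
        io.write_table(est.proportions, outdir / "proportions.tsv")
        io.write_table(pcs.scores, outdir / "pc_scores.tsv")
        manifest["stages"]["deconvolve"] = {
            "selected_pcs": [pcs.scores.columns[i] for i in selected],
            "variance_explained": [round(float(v), 6) for v in pcs.variance_explained],
        }

    with stage("screen"):
        screen_unadj = gee.run_screen(
            filtered, factors, metadata,
            corstr=config.model.corstr, covariates=config.model.covariates,
            timepoint_order=config.cohort.timepoints,
        )
        screen_adj = gee.run_screen(
            filtered, factors, metadata, pcs=pc_scores if len(selected) else None,
            corstr=config.model.corstr, covariates=config.model.covariates,
            timepoint_order=config.cohort.timepoints,
        )
        io.write_table(screen_unadj, outdir / "screen_unadjusted.tsv")
        io.write_table(screen_adj, outdir / "screen_adjusted.tsv")

    with stage("classify"):
        calls_u = effects.call_pregnancy_associated(screen_unadj, fdr=t.fdr, fc=t.fc)
        calls_a = effects.call_pregnancy_associated(screen_adj, fdr=t.fdr, fc=t.fc)
        mech = effects.classify_mechanism(calls_u, calls_a)
        io.write_table(mech, outdir / "mechanism.tsv")
        io.write_table(effects.venn_counts(calls_u), outdir / "venn_unadjusted.tsv")
        io.write_table(effects.venn_counts(calls_a), outdir / "venn_adjusted.tsv")
        manifest["stages"]["classify"] = {
            "class_counts": mech["class"].value_counts().to_dict()
        }

    reversion = None
    if "PP3" in config.cohort.timepoints:
        with stage("reversion"):
            screen_t3 = gee.run_screen(
                filtered, factors, metadata, baseline="T3",
                corstr=config.model.corstr, covariates=config.model.covariates,
                timepoint_order=config.cohort.timepoints,
            )
            io.write_table(screen_t3, outdir / "screen_t3_baseline.tsv")
            r, n_rev = effects.reversion_correlation(
                screen_unadj, screen_t3, fdr=t.fdr, fc=t.fc
            )
            reversion = {"pearson_r": None if np.isnan(r) else round(float(r), 6), "n_genes": n_rev}
            manifest["stages"]["reversion"] = reversion

    with stage("coexpress"):
        if config.model.coexpr_universe == "significant":
            genes = mech.index[mech["class"] != "none"]
            expr = log_cpm.loc[genes] if len(genes) >= 2 else log_cpm
        else:
            expr = log_cpm
        cor = coexpr.bicor_matrix(expr, max_p_outliers=t.max_p_outliers)
        adj = coexpr.adjacency_signed_hybrid(cor, beta=t.power_beta)
        tom = coexpr.tom_similarity(adj)
        labels = coexpr.detect_modules(
            tom, min_module_size=t.min_module_size, cut_height=t.cut_height
        )
        assignment = coexpr.merge_modules(expr, labels, merge_cut=t.merge_cut)
        io.write_table(assignment.labels.to_frame("module"), outdir / "modules.tsv")
        io.write_table(assignment.eigengenes, outdir / "module_eigengenes.tsv")
        manifest["stages"]["coexpress"] = {
            "n_modules": int((assignment.labels != coexpr.UNASSIGNED).sum() and
                             assignment.labels[assignment.labels != coexpr.UNASSIGNED].nunique()),
            "n_unassigned": int((assignment.labels == coexpr.UNASSIGNED).sum()),
        }

    with stage("enrich"):
        stage_lists = {}
        for tp in effects.TRIMESTERS:
            col = f"adjusted_flag_{tp}"
            if col in mech.columns:
                stage_lists[tp] = list(mech.index[mech[col]])
        enr = coexpr.module_set_enrichment(assignment, stage_lists)
        io.write_table(enr.set_index("stage") if not enr.empty else enr, outdir / "module_enrichment.tsv")

    _write_manifest(outdir, manifest, timings)
    return PipelineResult(outdir=outdir, manifest=manifest)


def _write_manifest(outdir: Path, manifest: dict, timings: dict) -> None:
    manifest["timings_s"] = timings
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
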