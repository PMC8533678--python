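"""Pipeline orchestration: dge → func annotation → gx-FBA → classification.

Each stage reads the outputs of the previous one in memory, writes its TSVs
under the configured output directory, and records its wall time in the run
report. Reruns with an identical configuration reproduce byte-identical
TSVs (the report's timing fields naturally differ).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .annotation import AnnotationTable, summarize_by_category
from .classify import (
    ReactionClassification,
    category_counts,
    classify_reactions,
    export_pathway_colors,
    generic_response,
    overlap_table,
)
from .config import RunConfig
from .dge import (
    CountMatrix,
    DETable,
    estimate_common_dispersion,
    exact_test,
    summarize_de,
    tmm_factors,
)
from .errors import StressFluxError
from .gxfba import build_gxfba, solve_gxfba
from .metnet import read_model

__all__ = ["run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("dge", "annot", "gxfba", "classify", "compare")


def _versions() -> dict[str, str]:
    import cobra
    import numpy
    import pandas
    import scipy

    return {
        "stressflux": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "cobra": cobra.__version__,
    }


def run_pipeline(config: RunConfig, stages: Iterable[str] = ALL_STAGES) -> dict:
    """Execute the requested stages; returns the machine-readable run report."""
    stages = list(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise StressFluxError(f"unknown pipeline stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "versions": _versions(),
        "seed": config.seed,
        "alpha": config.alpha,
        "epsilon": config.epsilon,
        "stages": {},
    }

    def _stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                logger.info("stage %s started", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                report["stages"].setdefault(name, {})["wall_time_s"] = round(dt, 3)
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                else:
                    logger.info("stage %s finished in %.3f s", name, dt)
                return False

        return _Timer()

    # ---- differential expression -------------------------------------
    de_table: DETable | None = None
    with _stage("dge"):
        try:
            counts = CountMatrix.from_tsv(config.counts, config.design)
            counts = counts.drop_all_zero_genes()
            norm = tmm_factors(counts, trim_m=config.trim_m, trim_a=config.trim_a)
            phi = (
                config.dispersion
                if config.dispersion is not None
                else estimate_common_dispersion(counts, norm)
            )
            de_table = exact_test(
                counts, norm, phi, alpha=config.alpha, fdr=config.fdr
            )
            summary = summarize_de(de_table, n_mapped=config.n_mapped)
            de_table.to_tsv(outdir / "de_table.tsv")
            summary.to_frame().to_csv(outdir / "de_summary.tsv", sep="\t", index=False)
            norm.factors.rename_axis("sample").to_csv(
                outdir / "norm_factors.tsv", sep="\t"
            )
            report["stages"]["dge"] = {
                "dispersion": float(phi),
                "dispersion_fixed": config.dispersion is not None,
                "n_genes": len(de_table.frame),
                "n_de": summary.n_de,
                "n_up": summary.n_up,
                "n_down": summary.n_down,
                "pct_de": summary.pct_de,
            }
        except StressFluxError as exc:
            raise StressFluxError(f"stage dge: {exc}") from exc

    # ---- functional categories ---------------------------------------
    if "annot" in stages and config.annotation is not None:
        with _stage("annot"):
            try:
                annot = AnnotationTable.from_tsv(config.annotation)
                cats = summarize_by_category(
                    de_table, annot, multi_count=config.multi_count_categories
                )
                cats.to_tsv(outdir / "category_counts.tsv")
                report["stages"]["annot"] = {
                    "n_categories_hit": int(
                        (cats.frame[["n_up", "n_down"]].sum(axis=1) > 0).sum()
                    )
                }
            except StressFluxError as exc:
                raise StressFluxError(f"stage annot: {exc}") from exc

    # ---- gx-FBA + classification -------------------------------------
    classification: ReactionClassification | None = None
    need_model = {"gxfba", "classify", "compare"} & set(stages)
    if need_model and config.model is not None:
        with _stage("gxfba"):
            try:
                model = read_model(config.model, config.model_format)
                ref_env = config.reference_env.to_spec()
                stress_env = config.stress_env.to_spec()
                problem = build_gxfba(
                    model,
                    ref_env,
                    stress_env,
                    de_table,
                    and_rule=config.gpr_and,
                    or_rule=config.gpr_or,
                    epsilon=config.epsilon,
                    cap_relaxation=config.cap_relaxation,
                )
                result = solve_gxfba(problem)
                result.to_frame(problem).rename_axis("reaction").to_csv(
                    outdir / "gxfba_result.tsv", sep="\t"
                )
                (outdir / "gxfba_diagnostics.json").write_text(
                    json.dumps(result.diagnostics, indent=2, sort_keys=True) + "\n"
                )
                report["stages"]["gxfba"] = dict(result.diagnostics)
            except StressFluxError as exc:
                raise StressFluxError(f"stage gxfba: {exc}") from exc

        with _stage("classify"):
            try:
                classification = classify_reactions(
                    problem.v_ref, result.stress_range, epsilon=config.epsilon
                )
                classification.to_tsv(outdir / "classification.tsv")
                summary_rows = {"treated": category_counts(classification)}
                report["stages"]["classify"] = {
                    k: int(v) for k, v in category_counts(classification).items()
                }
            except StressFluxError as exc:
                raise StressFluxError(f"stage classify: {exc}") from exc

        if config.pathway_map is not None:
            pmap = pd.read_csv(config.pathway_map, sep="\t", index_col=0)
            export_pathway_colors(
                classification,
                pmap.iloc[:, 0].to_dict(),
                outdir / "pathway_colors.tsv",
            )

        # ---- cross-condition comparison ------------------------------
        if "compare" in stages and config.conditions:
            with _stage("compare"):
                try:
                    per_condition = []
                    for cond in config.conditions:
                        de_c = DETable.from_tsv(cond.de_table, alpha=config.alpha)
                        prob_c = build_gxfba(
                            model,
                            ref_env,
                            stress_env,
                            de_c,
                            and_rule=config.gpr_and,
                            or_rule=config.gpr_or,
                            epsilon=config.epsilon,
                            cap_relaxation=config.cap_relaxation,
                        )
                        res_c = solve_gxfba(prob_c)
                        cls_c = classify_reactions(
                            prob_c.v_ref, res_c.stress_range, epsilon=config.epsilon
                        )
                        summary_rows[cond.label] = category_counts(cls_c)
                        per_condition.append((prob_c.v_ref, res_c.stress_range))
                    generic = generic_response(per_condition, epsilon=config.epsilon)
                    summary_rows["generic"] = category_counts(generic.classification)
                    overlap = overlap_table(classification, generic.classification)
                    overlap.to_csv(outdir / "overlap_table.tsv", sep="\t")
                    report["stages"]["compare"] = {
                        "n_conditions": len(config.conditions),
                        "overlap_down_down": int(overlap.loc["down", "down"]),
                    }
                except StressFluxError as exc:
                    raise StressFluxError(f"stage compare: {exc}") from exc

        pd.DataFrame(summary_rows).T.rename_axis("condition").to_csv(
            outdir / "flux_category_summary.tsv", sep="\t"
        )

    (outdir / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
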