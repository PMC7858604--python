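"""End-to-end pipeline driver: simulate -> ewas -> pathways -> recovery -> embed.

A single :class:`PipelineConfig` (loadable from YAML) describes either a
synthetic cohort to simulate or paths to existing inputs, plus the analysis
parameters.  :func:`run_pipeline` writes every stage output under the
configured directory and assembles a JSON report whose numbers are
recomputable from the stage files.  Identical config + seed yields
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from . import recovery as rec
from .errors import ConfigurationError, PipelineError
from .ewas import HYPOTHESES, qq_points, run_ewas, summarize_ewas
from .pathways import (
    background_genes,
    enrich_terms,
    pathway_cpg_universe,
    pathway_score_table,
    rank_top_genes,
    volcano_points,
)
from .synthetic import CohortConfig, EffectConfig, LibraryConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    # either a simulation block ...
    cohort: CohortConfig | None = None
    effects: EffectConfig | None = None
    library: LibraryConfig | None = None
    # ... or paths to existing inputs
    matrix_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    covariates: tuple = ("age", "sex", "plate", "alcohol", "smoking")
    alpha: float = 0.05
    n_top_genes: int = 30
    p_cut: float = 1e-5
    recovery_thresholds: tuple | None = None
    embed_perplexity: float = 10.0
    embed_iterations: int = 10000
    run_embedding: bool = True

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        simulated = self.cohort is not None and self.effects is not None
        loaded = self.matrix_path is not None and self.samples_path is not None
        if not simulated and not loaded:
            raise ConfigurationError(
                "config needs either a cohort+effects simulation block "
                "or matrix_path+samples_path")
        if loaded:
            for attr in ("matrix_path", "samples_path", "annotation_path", "gmt_path"):
                value = getattr(self, attr)
                if value is not None and not Path(value).exists():
                    raise ConfigurationError(f"{attr} does not exist: {value}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        for key, klass in (("cohort", CohortConfig), ("effects", EffectConfig),
                           ("library", LibraryConfig)):
            if isinstance(raw.get(key), dict):
                block = dict(raw[key])
                for tuple_field in ("recovery_probe_ids", "affected_probes_swd",
                                    "affected_probes_ctrl"):
                    if tuple_field in block and block[tuple_field] is not None:
                        block[tuple_field] = tuple(block[tuple_field])
                raw[key] = klass(**block)
        if raw.get("covariates") is not None:
            raw["covariates"] = tuple(raw["covariates"])
        if raw.get("recovery_thresholds") is not None:
            raw["recovery_thresholds"] = tuple(raw["recovery_thresholds"])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analysis-relevant config (outdir excluded, so reruns
        into different directories remain byte-comparable)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _stage(name: str):
    def decorator(func):
        def wrapper(*args, **kwargs):
            try:
                return func(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return decorator


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report (also written as report.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config_sha256": config.digest(), "stages": {}}

    matrix, sheet, annotation, library = _stage("data")(_data_stage)(config, outdir)
    report["stages"]["data"] = {
        "n_probes": int(matrix.shape[0]),
        "n_samples": int(matrix.shape[1]),
        "n_subjects": int(sheet["subject"].nunique()),
        "simulated": config.cohort is not None,
    }

    table = _stage("ewas")(_ewas_stage)(config, outdir, matrix, sheet)
    summary = summarize_ewas(table, alpha=config.alpha)
    sio.write_json(summary, outdir / "ewas_summary.json")
    report["stages"]["ewas"] = {"n_probes_tested": int(table.shape[0]), "summary": summary}

    pathway_section = None
    if annotation is not None and library is not None:
        pathway_section = _stage("pathways")(_pathway_stage)(
            config, outdir, table, annotation, library)
        report["stages"]["pathways"] = pathway_section

    recovery_section = _stage("recovery")(_recovery_stage)(
        config, outdir, matrix, sheet, table, annotation, library, pathway_section)
    report["stages"]["recovery"] = recovery_section

    if config.run_embedding:
        embedding = _stage("embed")(rec.embed_global_profiles)(
            matrix, sheet, perplexity=config.embed_perplexity,
            iterations=config.embed_iterations, seed=config.seed)
        embedding.to_csv(outdir / "embedding.tsv", sep="\t", index=False)
        report["stages"]["embed"] = {"n_samples": int(embedding.shape[0])}

    sio.write_json(report, outdir / "report.json")
    return report


def _data_stage(config: PipelineConfig, outdir: Path):
    if config.cohort is not None:
        bundle = simulate_dataset(
            config.cohort, config.effects, config.library, seed=config.seed)
        sheet, matrix = bundle["sheet"], bundle["matrix"]
        annotation = bundle.get("annotation")
        library = bundle.get("library")
        sio.write_matrix(matrix, outdir / "matrix.tsv")
        sio.write_samples(sheet, outdir / "samples.csv")
        sio.write_json(bundle["truth"].to_dict(), outdir / "truth.json")
        if annotation is not None:
            sio.write_annotation(annotation, outdir / "annotation.tsv")
            sio.write_gmt(library, outdir / "library.gmt")
        return matrix, sheet, annotation, library
    matrix = sio.read_matrix(config.matrix_path)
    sheet = sio.read_samples(config.samples_path)
    annotation = sio.read_annotation(config.annotation_path) if config.annotation_path else None
    library = sio.read_gmt(config.gmt_path) if config.gmt_path else None
    return matrix, sheet, annotation, library


def _ewas_stage(config: PipelineConfig, outdir: Path, matrix, sheet):
    covariates = [c for c in config.covariates if c in sheet.columns]
    table = run_ewas(matrix, sheet, covariates=covariates, alpha=config.alpha)
    table.to_csv(outdir / "ewas.tsv", sep="\t")
    for hyp in HYPOTHESES:
        expected, observed = qq_points(table[f"p_{hyp}"].to_numpy())
        pd.DataFrame({"expected_neglog10": expected, "observed_neglog10": observed}).to_csv(
            outdir / f"qq_{hyp}.tsv", sep="\t", index=False)
    return table


def _pathway_stage(config: PipelineConfig, outdir: Path, table, annotation, library) -> dict:
    genes = rank_top_genes(table, annotation, group="swd",
                           n_top=config.n_top_genes, p_cut=config.p_cut)
    background = background_genes(table, annotation)
    section: dict = {"n_top_genes": len(genes), "top_genes": genes}
    if genes:
        enrichment = enrich_terms(genes, library, background)
        enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        section["top_terms"] = enrichment.head(10).to_dict(orient="records")
    scores = pathway_score_table(library, annotation, table, alpha=config.alpha)
    scores.to_csv(outdir / "pathway_scores.tsv", sep="\t", index=False)
    swd_scores = scores[scores["group"] == "swd"]
    best = swd_scores.sort_values(
        ["enrichment_pct", "term"], ascending=[False, True], kind="mergesort").iloc[0]
    section["top_pathway"] = {
        "term": str(best["term"]),
        "enrichment_pct": None if pd.isna(best["enrichment_pct"]) else float(best["enrichment_pct"]),
        "hypo_pct": None if pd.isna(best["hypo_pct"]) else float(best["hypo_pct"]),
        "n_dmps": int(best["n_dmps"]),
        "n_cpgs": int(best["n_cpgs"]),
    }
    return section


def _recovery_stage(config, outdir: Path, matrix, sheet, table, annotation,
                    library, pathway_section) -> dict:
    scores = rec.subject_symptom_scores(sheet)
    swd_scores = scores.loc[scores["group"] == "swd", "change_symptoms"]
    section: dict = {"n_scored_subjects": int(scores.shape[0])}
    labels = rec.assign_recovery_groups(swd_scores, thresholds=config.recovery_thresholds)
    labels.rename("recovery_group").to_csv(outdir / "recovery_groups.tsv", sep="\t")
    section["recovery_group_sizes"] = labels.value_counts().to_dict()

    # probe set: the top SWD pathway's DMPs when available, else all SWD DMPs
    if pathway_section is not None and annotation is not None and library is not None:
        term = pathway_section["top_pathway"]["term"]
        universe = sorted(pathway_cpg_universe(term, library, annotation))
        dmps = [p for p in universe if p in table.index and bool(table.loc[p, "dmp_swd"])]
        section["probe_set"] = {"source": term, "n_dmps": len(dmps)}
        vol = volcano_points(table, [p for p in universe if p in table.index], group="swd")
        vol.to_csv(outdir / "volcano.tsv", sep="\t", index=False)
    else:
        dmps = list(table.index[table["dmp_swd"]])
        section["probe_set"] = {"source": "all_swd_dmps", "n_dmps": len(dmps)}

    changes = rec.methylation_change(matrix, sheet)
    swd_subjects = [s for s in changes.columns if s in swd_scores.index]
    results = rec.correlate_recovery(
        changes[swd_subjects], swd_scores, probes=dmps or None, annotation=annotation)
    results.to_csv(outdir / "recovery.tsv", sep="\t", index=False)
    section["correlation_summary"] = rec.summarize_recovery(results, alpha=config.alpha)

    anova = rec.work_period_anova(matrix, sheet, probes=dmps or None)
    anova.to_csv(outdir / "anova.tsv", sep="\t", index=False)
    section["anova_n_p_below"] = int((anova["p"] < config.alpha).sum())
    return section
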