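"""End-to-end orchestration: generate → curate → annotate → evaluate →
classify → saturate, with a manifest and per-stage reports.

Every stage writes its intermediate artifact (raw TSV, curated TSVs,
annotated TSV, ROC points, report JSONs) into the run directory so any
reported number can be recomputed by calling the owning module on the
stage's input file.  A single seed in :class:`RunConfig` drives all stages;
two runs with the same config produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotate, classify, curate, evaluate, io, saturate, synth
from .synth import PREDICTORS, GeneratorConfig

__all__ = ["RunConfig", "run", "load_run_config"]

ALL_STAGES = ("synth", "curate", "annotate", "evaluate", "classify", "saturate")

#: score sets evaluated by default: each single predictor, the two pairwise
#: ensembles sharing predictor 1, the all-predictor ensemble, and RSA.
DEFAULT_SCORE_SETS: tuple[tuple[str, ...], ...] = (
    ("ddg_p1",),
    ("ddg_p2",),
    ("ddg_p3",),
    ("ddg_p1", "ddg_p2"),
    ("ddg_p1", "ddg_p3"),
    ("ddg_p1", "ddg_p2", "ddg_p3"),
)


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    generator: GeneratorConfig | None = None
    #: path to a pre-annotated TSV; overrides the generator for evaluation
    annotated_path: str | None = None
    raw_path: str | None = None
    n_benign: int = 2000
    n_pathogenic: int = 2000
    #: "optimize" or a mapping from score-set name to a fixed cutoff
    cutoffs: str | dict[str, float] = "optimize"
    resampling_repeats: int = 100
    stratify_by: tuple[str, ...] = ("cat_hydropathy", "cat_size", "functional_class")
    min_group_count: int = 100
    classifier_protocol: classify.SplitProtocol | None = None
    classifier_features: tuple[classify.FeatureSpec, ...] = (
        classify.FeatureSpec(("ddg_p1",), True),
        classify.FeatureSpec(("ddg_p1", "ddg_p3"), True),
    )
    saturation_n_proteins: int = 5
    saturation_min_len: int = 100
    saturation_max_len: int = 300
    saturation_cutoff: float = saturate.DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML or JSON file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return run_config_from_dict(data or {})


def run_config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    if "generator" in data and data["generator"] is not None:
        gen = dict(data["generator"])
        for key, cls in (
            ("ddg_pathogenic", synth.GaussianParams),
            ("ddg_benign", synth.GaussianParams),
        ):
            if key in gen:
                g = dict(gen[key])
                g["means"] = tuple(g["means"])
                g["sds"] = tuple(g["sds"])
                gen[key] = cls(**g)
        for key in ("rsa_pathogenic", "rsa_benign"):
            if key in gen:
                gen[key] = synth.BetaParams(**gen[key])
        for key in ("af_benign", "af_pathogenic"):
            if key in gen:
                gen[key] = synth.LogUniformRange(**gen[key])
        if "variants_per_gene" in gen:
            gen["variants_per_gene"] = tuple(gen["variants_per_gene"])
        data["generator"] = GeneratorConfig(**gen)
    if "classifier_protocol" in data and data["classifier_protocol"] is not None:
        proto = dict(data["classifier_protocol"])
        if "c_grid" in proto:
            proto["c_grid"] = tuple(proto["c_grid"])
        data["classifier_protocol"] = classify.SplitProtocol(**proto)
    if "classifier_features" in data:
        data["classifier_features"] = tuple(
            classify.FeatureSpec(tuple(fs["ddg_predictors"]), fs.get("include_rsa", True))
            for fs in data["classifier_features"]
        )
    for key in ("stages", "stratify_by"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def _score_set_name(predictors: tuple[str, ...]) -> str:
    return "+".join(predictors)


def _evaluate_score(
    scores: np.ndarray,
    labels: np.ndarray,
    name: str,
    cutoffs,
    n_repeats: int,
    rng: np.random.Generator,
) -> dict:
    auc = evaluate.auc_concordance(scores, labels)
    if cutoffs == "optimize":
        threshold, best_mcc = evaluate.optimal_threshold(scores, labels)
    else:
        threshold = float(cutoffs[name])
        best_mcc = evaluate.mcc(evaluate.confusion(scores, labels, threshold))
    summary = evaluate.balanced_resample_evaluate(
        labels, scores=scores, threshold=threshold, n_repeats=n_repeats, seed=rng
    )
    return {
        "auc": auc,
        "cutoff": threshold,
        "mcc_at_cutoff": best_mcc,
        "resampling": summary.to_dict(),
    }


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen_config = config.generator or GeneratorConfig(seed=config.seed)

    if "synth" in config.stages:
        raw = synth.generate_raw_table(gen_config)
        io.write_variant_table(raw, out / "raw_variants.tsv")
        annotated = synth.generate_annotated(
            gen_config, config.n_benign, config.n_pathogenic
        )
        io.write_variant_table(annotated, out / "annotated_variants.tsv")

    if "curate" in config.stages:
        raw_path = config.raw_path or out / "raw_variants.tsv"
        raw = io.read_variant_table(raw_path)
        ds1, ds2, report = curate.build_datasets(raw)
        io.write_variant_table(ds1, out / "dataset1.tsv")
        io.write_variant_table(ds2, out / "dataset2.tsv")
        io.write_json(report.to_dict(), out / "curation_report.json")

    annotated_path = config.annotated_path or out / "annotated_variants.tsv"
    df = None
    if "annotate" in config.stages:
        df = annotate.annotate_variants(io.read_variant_table(annotated_path))
        io.write_variant_table(df, out / "annotated_categorized.tsv")

    if "evaluate" in config.stages:
        if df is None:
            df = annotate.annotate_variants(io.read_variant_table(annotated_path))
        labels = df["label"].to_numpy()
        rng = np.random.default_rng([101, config.seed])
        eval_report: dict = {"scores": {}, "stratified": {}}
        for predictors in DEFAULT_SCORE_SETS:
            name = _score_set_name(predictors)
            scores = np.asarray(annotate.ensemble_ddg(df, predictors))
            eval_report["scores"][name] = _evaluate_score(
                scores, labels, name, config.cutoffs,
                config.resampling_repeats, rng,
            )
            roc = evaluate.roc_curve(scores, labels)
            roc.to_frame().to_csv(out / f"roc_{name}.tsv", sep="\t", index=False)
        eval_report["scores"]["rsa"] = _evaluate_score(
            df["rsa"].to_numpy(), labels, "rsa", config.cutoffs,
            config.resampling_repeats, rng,
        )
        eval_report["scores"]["rsa"]["note"] = "lower RSA (buried) scored as pathogenic"
        best_pair = annotate.ensemble_ddg(df, ("ddg_p1", "ddg_p3"))
        for grouping in config.stratify_by:
            if grouping not in df.columns:
                continue
            table = evaluate.stratified_auc(
                df, grouping, "ddg_p1", min_count=config.min_group_count
            )
            table_pair = evaluate.stratified_auc(
                df.assign(_ens=np.asarray(best_pair)), grouping, "_ens",
                min_count=config.min_group_count,
            )
            eval_report["stratified"][grouping] = {
                "ddg_p1": table.to_dict(orient="records"),
                "ddg_p1+ddg_p3": table_pair.to_dict(orient="records"),
            }
        eval_report["fraction_destabilizing_pathogenic"] = {
            p: annotate.fraction_destabilizing(df[df["label"] == 1], p)
            for p in PREDICTORS
        }
        io.write_json(eval_report, out / "evaluation_report.json")

    if "classify" in config.stages:
        if df is None:
            df = annotate.annotate_variants(io.read_variant_table(annotated_path))
        protocol = config.classifier_protocol or classify.SplitProtocol(
            seed=config.seed
        )
        rows = []
        for spec in config.classifier_features:
            rep = classify.train_eval(df, spec, protocol)
            model = rep.pop("model")
            rep.pop("cv_mean_auc")
            rep["features"] = list(model.feature_names)
            rep["model"] = model.to_dict()
            rows.append(rep)
        io.write_json({"models": rows}, out / "classifier_report.json")

    if "saturate" in config.stages:
        records = synth.generate_sequences(
            gen_config,
            config.saturation_n_proteins,
            config.saturation_min_len,
            config.saturation_max_len,
        )
        io.write_fasta(records, out / "saturation_input.fasta")
        scorer = saturate.SyntheticScorer(seed=config.seed)
        summary = saturate.scan_to_tsv(
            records, lambda pid: scorer, out / "saturation_scan.tsv",
            cutoff=config.saturation_cutoff,
        )
        io.write_json(summary, out / "saturation_summary.json")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "config": _jsonable(config),
    }
    io.write_json(manifest, out / "manifest.json")
    return out


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj
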