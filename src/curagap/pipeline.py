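"""End-to-end pipeline: harmonize -> classify -> overlap -> predictor eval.

`run_pipeline` executes the stages in curation order — consolidation of raw
mentions onto genomic keys, pathogenicity classification from evidence,
variant-class labeling, database presence/overlap analysis, predictor
benchmarking, chaperone-rescue calls and protein-feature overlap — writing
every stage's outputs under the configured directory and logging counts as
it goes.  `demo` generates a fully synthetic input set first, so the whole
pipeline is exercisable with zero external files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .classify import (
    RuleConfig,
    assign_pathogenicity,
    classify_rescue,
    classify_variant_class,
    load_feature_map,
    map_protein_features,
    super_class,
)
from .gap import inclusion_rank_test, load_db_export, mark_presence, overlap_report
from .gene_model import read_gene_model, write_gene_model
from .harmonize import consolidate_mentions
from .predict import (
    aggregate_accuracy,
    cadd_band_report,
    prediction_accuracy,
    prediction_coverage,
    round_half_up_pct,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "write_report", "demo"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: Path
    mentions_path: Path | None = None
    gene_model_path: Path | None = None
    gene_model_fasta: Path | None = None
    alt_gene_model_paths: list = field(default_factory=list)
    db_exports: dict = field(default_factory=dict)  # name -> (path, dialect)
    scores_path: Path | None = None
    feature_map_path: Path | None = None
    rules: RuleConfig = field(default_factory=RuleConfig)
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(path.read_text())
        else:
            raw = json.loads(path.read_text())
        rules = RuleConfig(**raw.pop("rules", {}))
        db = {k: (Path(p), d) for k, (p, d) in raw.pop("db_exports", {}).items()}
        return cls(
            out_dir=Path(raw.pop("out_dir")),
            rules=rules,
            db_exports=db,
            **{k: (Path(v) if k.endswith("_path") or k.endswith("_fasta") else v)
               for k, v in raw.items()},
        )


@dataclass
class ReportBundle:
    consolidation: dict
    tier_counts: dict
    class_counts: dict
    overlap: dict | None = None
    inclusion_test: dict | None = None
    predictor: dict | None = None
    rescue: list = field(default_factory=list)
    features: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)


def _count_stage(calls, classes) -> tuple[dict, dict]:
    tier_counts = {"pathogenic_star": 0, "benign": 0, "vus": 0}
    class_counts = {"exonic": 0, "intronic": 0, "utr": 0, "large_deletion": 0,
                    "SNV": 0, "MNV": 0}
    for uid, call in calls.items():
        cls = classes[uid]
        class_counts[cls.region] += 1
        class_counts[cls.width] += 1
        if cls.region == "large_deletion":
            continue
        sc = super_class(call.tier)
        if sc == "pathogenic":
            tier_counts["pathogenic_star"] += 1
        elif sc == "benign":
            tier_counts["benign"] += 1
        else:
            tier_counts["vus"] += 1
    return tier_counts, class_counts


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis from a config; returns the report bundle.

    Stage failures abort with the stage name; a missing optional input
    (scores, exports, feature map) skips only that stage with a warning.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.gene_model_path is None or config.mentions_path is None:
        raise ValueError("gene_model_path and mentions_path are required")

    logger.info("stage 1/5: harmonization")
    model = read_gene_model(config.gene_model_path, config.gene_model_fasta)
    alt_models = [read_gene_model(p, config.gene_model_fasta)
                  for p in config.alt_gene_model_paths]
    mentions = cio.read_mentions_tsv(config.mentions_path)
    variants, report = consolidate_mentions(mentions, model, alt_models)
    logger.info("  %d mentions -> %d unique variants, %d duplicates, %d unresolved",
                report.n_raw, report.n_unique, report.n_duplicates,
                len(report.unresolved))
    for mid, reason in report.unresolved:
        logger.warning("  unresolved mention %s: %s", mid, reason)

    logger.info("stage 2/5: classification")
    calls = {v.uid: assign_pathogenicity(v.evidence, config.rules) for v in variants}
    classes = {v.uid: classify_variant_class(v, model) for v in variants}
    tier_counts, class_counts = _count_stage(calls, classes)
    cio.write_variants_tsv(variants, calls, classes, out / "variants.tsv")
    cio.write_vcf_like(variants, model, out / "variants_vcf_like.tsv")

    bundle = ReportBundle(
        consolidation={
            "n_raw": report.n_raw,
            "n_unique": report.n_unique,
            "n_duplicates": report.n_duplicates,
            "n_unresolved": len(report.unresolved),
            "duplicate_fraction": report.duplicate_pct,
        },
        tier_counts=tier_counts,
        class_counts=class_counts,
    )

    logger.info("stage 3/5: database overlap")
    if config.db_exports:
        catalogs = [
            load_db_export(p, dialect, model, db_name=name)
            for name, (p, dialect) in config.db_exports.items()
        ]
        for cat in catalogs:
            logger.info("  %s: %d entries (%d skipped)", cat.db_name,
                        len(cat), cat.n_skipped)
        matrix = mark_presence(variants, calls, catalogs)
        bundle.overlap = overlap_report(matrix, calls, classes, variants)
        try:
            mwu = inclusion_rank_test(matrix, classes)
            bundle.inclusion_test = dataclasses.asdict(mwu)
        except ValueError as exc:
            logger.warning("  inclusion test skipped: %s", exc)
        matrix.presence.to_csv(out / "presence_matrix.tsv", sep="\t")
    else:
        logger.warning("no database exports configured; overlap stage skipped")

    logger.info("stage 4/5: predictor evaluation")
    if config.scores_path is not None:
        scores = cio.read_scores_tsv(config.scores_path)
        uids = [v.uid for v in variants]
        cov = prediction_coverage(scores, uids)
        acc = prediction_accuracy(scores, calls, config.rules, uids)
        bands = cadd_band_report(scores, calls, config.rules.cadd_cutoffs, uids)
        agg = aggregate_accuracy(scores, calls, config.rules, uids)
        bundle.predictor = {
            "coverage": cov.to_dict(),
            "per_algorithm": acc.reset_index().to_dict(orient="records"),
            "cadd_bands": bands.reset_index().to_dict(orient="records"),
            "aggregate": agg,
        }
    else:
        logger.warning("no predictor scores configured; predictor stage skipped")

    logger.info("stage 5/5: rescue calls and protein features")
    rescue_rows = []
    for v in variants:
        for ev in v.evidence:
            if ev.pba_uptake_before is not None:
                rescue_rows.append({
                    "uid": v.uid,
                    "uptake_before": ev.pba_uptake_before,
                    "uptake_after": ev.pba_uptake_after,
                    "call": classify_rescue(ev.pba_uptake_before,
                                            ev.pba_uptake_after, config.rules),
                })
                break
    bundle.rescue = rescue_rows
    if config.feature_map_path is not None:
        fmap = load_feature_map(config.feature_map_path)
        tags = map_protein_features(variants, fmap)
        bundle.features = {u: sorted(t) for u, t in tags.items() if t}

    write_report(bundle, out)
    return bundle


# ------------------------------------------------------------------ output
def _pct(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{round_half_up_pct(x)}%"


def write_report(bundle: ReportBundle, out_dir, formats=("json", "tsv")) -> None:
    """JSON at full precision; TSV with integer percentages (reporting style)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "json" in formats:
        with open(out / "report.json", "w") as fh:
            json.dump(bundle.to_json_dict(), fh, indent=2, default=_json_default)
    if "tsv" not in formats:
        return
    lines = ["section\tname\tvalue"]
    c = bundle.consolidation
    lines.append(f"consolidation\tn_raw\t{c.get('n_raw', 0)}")
    lines.append(f"consolidation\tn_unique\t{c.get('n_unique', 0)}")
    lines.append(f"consolidation\tn_duplicates\t{c.get('n_duplicates', 0)}")
    lines.append(f"consolidation\tduplicate_pct\t{_pct(c.get('duplicate_fraction'))}")
    for k, v in bundle.tier_counts.items():
        lines.append(f"tiers\t{k}\t{v}")
    for k, v in bundle.class_counts.items():
        lines.append(f"classes\t{k}\t{v}")
    if bundle.overlap:
        for db, rows in bundle.overlap["per_database"].items():
            for stratum, r in rows.items():
                lines.append(f"overlap\t{db}.{stratum}\t{_pct(r['fraction'])}")
            conc = bundle.overlap["concordance"][db]
            lines.append(f"overlap\t{db}.concordance\t{_pct(conc['fraction'])}")
        for stratum, r in bundle.overlap["uncaptured"].items():
            lines.append(f"uncaptured\t{stratum}\t{_pct(r['fraction'])}")
    if bundle.inclusion_test:
        lines.append(f"inclusion\tmann_whitney_p\t{bundle.inclusion_test['p_value']:.4g}")
        lines.append(f"inclusion\tt_test_p\t{bundle.inclusion_test['t_test_p']:.4g}")
    if bundle.predictor:
        for alg, v in bundle.predictor["coverage"].items():
            lines.append(f"predictor\t{alg}.coverage\t{_pct(v)}")
        for row in bundle.predictor["per_algorithm"]:
            alg = row["algorithm"]
            lines.append(f"predictor\t{alg}.accuracy_pathogenic\t{_pct(row['accuracy_pathogenic'])}")
            lines.append(f"predictor\t{alg}.accuracy_benign\t{_pct(row['accuracy_benign'])}")
        agg = bundle.predictor["aggregate"]
        lines.append(f"predictor\tany_accurate\t{_pct(agg['any_accurate'])}")
        lines.append(f"predictor\tsolely_cadd\t{_pct(agg['solely_cadd_among_accurate'])}")
    n_rescued = sum(1 for r in bundle.rescue if r["call"] == "rescued")
    n_not = sum(1 for r in bundle.rescue if r["call"] == "not_rescued")
    lines.append(f"rescue\trescued\t{n_rescued}")
    lines.append(f"rescue\tnot_rescued\t{n_not}")
    with open(out / "report.tsv", "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# -------------------------------------------------------------------- demo
def demo(out_dir, seed: int = 0, corpus_spec=None) -> ReportBundle:
    """Generate a complete synthetic input set and run the pipeline on it.

    The generated corpus uses the default study-shaped parameters unless a
    :class:`curagap.synth.CorpusSpec` is supplied.
    """
    from importlib import resources

    from .synth import (
        CorpusSpec,
        synth_corpus,
        synth_db_exports,
        synth_gene_model,
        synth_predictor_scores,
    )

    out = Path(out_dir)
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]

    model = synth_gene_model(sub[0])
    spec = corpus_spec or CorpusSpec(seed=sub[1])
    mentions, truth = synth_corpus(model, spec)
    write_gene_model(model, inputs / "gene_model.tsv", inputs / "gene_model.fa")
    alt_paths = []
    for i, am in enumerate(truth.alt_models):
        p = inputs / f"gene_model_alt{i}.tsv"
        write_gene_model(am, p)
        alt_paths.append(p)
    cio.write_mentions_tsv(mentions, inputs / "mentions.tsv")
    db_paths, _ = synth_db_exports(truth, model, inputs / "db", seed=sub[2])
    scores, _ = synth_predictor_scores(truth, seed=sub[3])
    cio.write_scores_tsv(scores, inputs / "scores.tsv")
    fmap_ref = resources.files("curagap").joinpath("data/protein_features.tsv")
    with resources.as_file(fmap_ref) as fp:
        feature_path = inputs / "feature_map.tsv"
        feature_path.write_text(Path(fp).read_text())

    config = PipelineConfig(
        out_dir=out,
        mentions_path=inputs / "mentions.tsv",
        gene_model_path=inputs / "gene_model.tsv",
        gene_model_fasta=inputs / "gene_model.fa",
        alt_gene_model_paths=alt_paths,
        db_exports={name: (p, d) for name, (p, d) in db_paths.items()},
        scores_path=inputs / "scores.tsv",
        feature_map_path=feature_path,
        seed=seed,
    )
    return run_pipeline(config)
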