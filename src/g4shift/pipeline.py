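"""End-to-end orchestration: scan/load tracks, window statistics, shuffled
controls, pooled contingency, distance profiles, annotation, and confounder
stratification, all from one config with logged seeds.

Every numeric output is reproducible from the config plus seeds alone; each
feature track is analysed independently (no cross-track multiple-testing
adjustment is applied).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import GeneAnnotation, assign_features, stratified_exclusion_analysis
from .intervals import (
    GenomeDef,
    IntervalSet,
    ValidationError,
    read_bed,
    read_chrom_sizes,
)
from .stats import (
    build_contingency,
    distance_profile,
    fold_change_pseudocount,
    pearson_chi_square,
    percent_within,
    shuffled_control_percent,
    window_overlap,
)

logger = logging.getLogger("g4shift")

__all__ = ["RunConfig", "RunReport", "validate_config", "run_analysis"]


@dataclass
class RunConfig:
    """Analysis parameters; paths are resolved relative to the config file."""

    chrom_sizes: str
    event_paths: dict[str, str]  # sample label -> BED path
    conditions: dict[str, str]  # sample label -> condition label
    feature_tracks: dict[str, str]  # track id -> BED path
    out_dir: str
    exclude_path: str | None = None
    confounder_paths: dict[str, str] = field(default_factory=dict)
    gene_models: str | None = None
    w: int = 5
    profile_edges_coarse: tuple[int, ...] = tuple(range(0, 51, 5))
    profile_edges_fine: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    seed: int = 0
    n_shuffles: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            return p if p is None or os.path.isabs(p) else os.path.join(base, p)

        return cls(
            chrom_sizes=resolve(raw["chrom_sizes"]),
            event_paths={k: resolve(v) for k, v in raw["events"].items()},
            conditions=dict(raw["conditions"]),
            feature_tracks={k: resolve(v) for k, v in raw["features"].items()},
            out_dir=resolve(raw.get("out_dir", "g4shift_out")),
            exclude_path=resolve(raw.get("exclude")),
            confounder_paths={
                k: resolve(v) for k, v in raw.get("confounders", {}).items()
            },
            gene_models=resolve(raw.get("gene_models")),
            w=int(raw.get("w", 5)),
            seed=int(raw.get("seed", 0)),
            n_shuffles=int(raw.get("n_shuffles", 1)),
        )


@dataclass
class RunReport:
    """Machine-readable results of one run; also written to out_dir as TSV/JSON."""

    config_hash: str
    version: str
    seed: int
    per_sample: pd.DataFrame
    contingency: dict[str, dict]
    profiles_coarse: dict[str, pd.DataFrame]
    profiles_fine: dict[str, pd.DataFrame]
    feature_distributions: dict[str, pd.Series]
    stratified: dict[str, dict]


def validate_config(config: RunConfig) -> list[str]:
    """Report-only validation: missing files, label collisions, name mismatches."""
    issues: list[str] = []
    paths = {"chrom_sizes": config.chrom_sizes}
    paths.update({f"events[{k}]": v for k, v in config.event_paths.items()})
    paths.update({f"features[{k}]": v for k, v in config.feature_tracks.items()})
    paths.update({f"confounders[{k}]": v for k, v in config.confounder_paths.items()})
    if config.exclude_path:
        paths["exclude"] = config.exclude_path
    if config.gene_models:
        paths["gene_models"] = config.gene_models
    for label, p in paths.items():
        if not os.path.exists(p):
            issues.append(f"missing file: {label} -> {p}")
    missing_cond = set(config.event_paths) - set(config.conditions)
    if missing_cond:
        issues.append(f"samples without condition label: {sorted(missing_cond)}")
    if config.w < 0:
        issues.append(f"window w must be >= 0, got {config.w}")
    if not issues:
        genome = read_chrom_sizes(config.chrom_sizes)
        for label, p in config.event_paths.items():
            _, skipped = read_bed(p, genome, strict=False)
            if skipped:
                issues.append(
                    f"events[{label}]: {skipped} records on chromosomes absent "
                    "from the genome (name mismatch?)"
                )
    return issues


def run_analysis(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write outputs under ``config.out_dir``."""
    issues = validate_config(config)
    if issues:
        raise ValidationError("config invalid: " + "; ".join(issues))
    os.makedirs(config.out_dir, exist_ok=True)
    genome = read_chrom_sizes(config.chrom_sizes)
    exclude = None
    if config.exclude_path:
        exclude, _ = read_bed(config.exclude_path, genome, role="exclusion")
    events: dict[str, IntervalSet] = {}
    for label, path in config.event_paths.items():
        events[label], _ = read_bed(path, genome, role="events")
        logger.info("loaded %d events for sample %s", len(events[label]), label)
    confounders = []
    for label, path in config.confounder_paths.items():
        track, _ = read_bed(path, genome, role="features")
        confounders.append(track)
        logger.info("loaded confounder %s: %d intervals", label, len(track))
    annotation = None
    if config.gene_models:
        if config.gene_models.endswith((".gff", ".gff3")):
            annotation = GeneAnnotation.from_gff3(config.gene_models)
        else:
            annotation = GeneAnnotation.from_bed12(config.gene_models)

    cfg_hash = hashlib.sha256(
        json.dumps(
            {k: str(v) for k, v in vars(config).items()}, sort_keys=True
        ).encode()
    ).hexdigest()[:16]

    rows = []
    contingency: dict[str, dict] = {}
    profiles_coarse: dict[str, pd.DataFrame] = {}
    profiles_fine: dict[str, pd.DataFrame] = {}
    stratified: dict[str, dict] = {}
    for track_id, path in config.feature_tracks.items():
        features, _ = read_bed(path, genome, role="features")
        logger.info("track %s: %d features", track_id, len(features))
        for i, (label, ev) in enumerate(events.items()):
            n = len(ev)
            k = len(window_overlap(ev, features, config.w))
            pct = 100.0 * k / n
            seed = config.seed + 1000 * i
            ctrl = shuffled_control_percent(
                ev, features, genome, exclude, config.w,
                n_shuffles=config.n_shuffles, seed=seed,
            )
            ctrl_pct = float(np.mean(ctrl))
            ctrl_count = int(round(ctrl_pct / 100.0 * n))
            rows.append(
                {
                    "track": track_id,
                    "sample": label,
                    "condition": config.conditions[label],
                    "n_events": n,
                    "n_associated": k,
                    "percent": pct,
                    "shuffled_percent": ctrl_pct,
                    "fold_change": fold_change_pseudocount(k, ctrl_count),
                    "seed": seed,
                }
            )
        pooled: dict[str, IntervalSet] = {}
        for label, ev in events.items():
            cond = config.conditions[label]
            pooled.setdefault(cond, [])
            pooled[cond] = pooled[cond] + list(ev) if pooled[cond] else list(ev)
        pooled_sets = {
            c: IntervalSet(ivs, genome, "events") for c, ivs in pooled.items()
        }
        if len(pooled_sets) == 2:
            res = pearson_chi_square(
                build_contingency(pooled_sets, features, config.w)
            )
            contingency[track_id] = {
                "observed": res.table.observed,
                "row_labels": res.table.row_labels,
                "expected": res.expected,
                "residuals": res.residuals,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
            if confounders:
                strat_res, retained = stratified_exclusion_analysis(
                    pooled_sets, features, confounders, config.w
                )
                stratified[track_id] = {
                    "observed": strat_res.table.observed,
                    "residuals": strat_res.residuals,
                    "statistic": strat_res.statistic,
                    "p_value": strat_res.p_value,
                    "retained_counts": retained,
                }
        prof_c = distance_profile(events, features, list(config.profile_edges_coarse))
        prof_f = distance_profile(events, features, list(config.profile_edges_fine))
        profiles_coarse[track_id] = pd.DataFrame(
            prof_c.percents, index=prof_c.samples,
            columns=[str(e) for e in prof_c.edges],
        )
        profiles_fine[track_id] = pd.DataFrame(
            prof_f.percents, index=prof_f.samples,
            columns=[str(e) for e in prof_f.edges],
        )

    feature_distributions: dict[str, pd.Series] = {}
    if annotation is not None:
        for label, ev in events.items():
            feature_distributions[label] = assign_features(ev, annotation).distribution()

    per_sample = pd.DataFrame(rows)
    report = RunReport(
        config_hash=cfg_hash,
        version=__version__,
        seed=config.seed,
        per_sample=per_sample,
        contingency=contingency,
        profiles_coarse=profiles_coarse,
        profiles_fine=profiles_fine,
        feature_distributions=feature_distributions,
        stratified=stratified,
    )
    _write_report(report, config)
    return report


def _write_report(report: RunReport, config: RunConfig) -> None:
    out = config.out_dir
    report.per_sample.to_csv(os.path.join(out, "per_sample_enrichment.tsv"),
                             sep="\t", index=False, float_format="%.10g")
    payload = {
        "version": report.version,
        "config_hash": report.config_hash,
        "seed": report.seed,
        "w": config.w,
        "contingency": report.contingency,
        "stratified": report.stratified,
    }
    with open(os.path.join(out, "contingency.json"), "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
    for track_id, df in report.profiles_coarse.items():
        df.to_csv(os.path.join(out, f"profile_coarse_{track_id}.tsv"),
                  sep="\t", float_format="%.10g")
    for track_id, df in report.profiles_fine.items():
        df.to_csv(os.path.join(out, f"profile_fine_{track_id}.tsv"),
                  sep="\t", float_format="%.10g")
    if report.feature_distributions:
        pd.DataFrame(report.feature_distributions).to_csv(
            os.path.join(out, "feature_distribution.tsv"), sep="\t",
            float_format="%.10g",
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
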