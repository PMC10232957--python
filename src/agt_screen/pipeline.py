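"""End-to-end pipeline: means table in, full report bundle out.

The pipeline reruns the whole screening analysis from a genotype-mean
table: index scoring and classification, group comparisons, correlation,
PCA, Gower/Ward.D2 clustering with cluster profiles, and (optionally)
marker diversity plus single-marker association and replicated-trial
variance components. Every output is deterministic given the configuration
and seed, and every table carries the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import AgtScreenError, ValidationError
from .group_compare import group_summary
from .indices import score_panel, tolerance_counts
from .marker_diversity import allele_stats, genetic_distance, single_marker_analysis, stats_frame
from .multivariate import (
    AG_TRAITS, cluster_profile, correlation_matrix, gower_distance, pca,
    ward_d2_cluster,
)
from .traits import TRAIT_ORDER
from .trial_io import (
    load_reference_panel, read_genotype_means, read_marker_scores,
    read_trial_table, records_to_frame,
)
from .varcomp import anova_pooled, anova_rcbd
from .variability import variability_parameters

log = logging.getLogger("agt_screen")

TRAIT_PRESETS = {"all": list(TRAIT_ORDER), "ag_traits": list(AG_TRAITS)}


@dataclass
class PipelineConfig:
    """Plain-data pipeline configuration (YAML-serializable)."""

    means_path: str | None = None       # None -> packaged reference panel
    trial_path: str | None = None
    markers_path: str | None = None
    traits: str | list[str] = "all"     # preset name or explicit list
    cluster_traits: str | list[str] = "all"
    k_phenotype: int = 6
    k_markers: int = 4
    alpha: float = 0.05
    ga_basis: str = "genotypic"
    marker_metric: str = "nei_li"
    out_dir: str = "agt_report"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0,1)")

    def resolve_traits(self, which: str | list[str]) -> list[str]:
        if isinstance(which, str):
            if which not in TRAIT_PRESETS:
                raise ValidationError(f"unknown trait preset {which!r}")
            return TRAIT_PRESETS[which]
        return list(which)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ReportBundle:
    config: PipelineConfig
    outputs: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path | None = None) -> Path:
        out = Path(out_dir or self.config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        h = self.config.config_hash()
        for name, obj in self.outputs.items():
            path = out / name
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(path)
            elif isinstance(obj, pd.Series):
                obj.to_frame().to_csv(path)
            elif isinstance(obj, str):
                path.write_text(obj)
            else:
                path.write_text(json.dumps(obj, indent=2, default=str))
        meta = {
            "version": __version__,
            "config_hash": h,
            "config": self.config.to_dict(),
        }
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str))
        return out


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except AgtScreenError as exc:
                raise AgtScreenError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every configured stage; abort with the stage name on failure."""
    bundle = ReportBundle(config)
    outputs = bundle.outputs
    h = config.config_hash()

    @_stage("load_means")
    def load_means():
        if config.means_path is None:
            return load_reference_panel()
        return records_to_frame(read_genotype_means(config.means_path))

    frame = load_means()
    traits = [t for t in config.resolve_traits(config.traits) if t in frame.columns]

    scored = _stage("score_panel")(score_panel)(frame)
    scored.attrs["config_hash"] = h
    outputs["scored.csv"] = scored
    outputs["tolerance_counts.json"] = tolerance_counts(scored)

    for by in ("tolerance_class", "grain_type", "grain_type_rule"):
        if by in scored.columns:
            tab = _stage(f"groups_{by}")(group_summary)(
                scored, by, traits, alpha=config.alpha
            )
            outputs[f"groups_by_{by}.csv"] = tab

    corr = _stage("correlation")(correlation_matrix)(frame, traits)
    outputs["correlation_r.csv"] = corr.r
    outputs["correlation_p.csv"] = corr.p

    pca_res = _stage("pca")(pca)(frame, traits)
    outputs["pca_eigenvalues.csv"] = pd.DataFrame(
        {
            "eigenvalue": pca_res.eigenvalues,
            "percent": pca_res.percent_variance,
            "cumulative": pca_res.cumulative_percent,
        },
        index=pca_res.cos2.columns,
    )
    outputs["pca_cos2.csv"] = pca_res.cos2
    outputs["pca_scores.csv"] = pca_res.scores

    cluster_traits = [
        t for t in config.resolve_traits(config.cluster_traits)
        if t in frame.columns
    ]
    dist = _stage("gower")(gower_distance)(frame, cluster_traits)
    tree, assign = _stage("ward")(ward_d2_cluster)(dist, k=config.k_phenotype)
    outputs["dendrogram.newick"] = tree.to_newick()
    outputs["clusters.csv"] = assign
    profile = _stage("cluster_profile")(cluster_profile)(
        assign, scored, traits=traits, distances=dist, alpha=config.alpha
    )
    outputs["cluster_summary.csv"] = profile["summary"]
    outputs["cluster_within_distance.csv"] = profile["within"]
    outputs["cluster_between_distance.csv"] = profile["between"]

    if config.markers_path is not None:
        if not Path(config.markers_path).exists():
            raise AgtScreenError(
                f"stage 'markers' failed: marker file not found: "
                f"{config.markers_path}"
            )
        markers = _stage("markers_read")(read_marker_scores)(config.markers_path)
        outputs["marker_stats.csv"] = stats_frame(allele_stats(markers))
        mdist = _stage("markers_distance")(genetic_distance)(
            markers, config.marker_metric
        )
        mtree, massign = ward_d2_cluster(mdist, k=config.k_markers)
        outputs["marker_dendrogram.newick"] = mtree.to_newick()
        outputs["marker_clusters.csv"] = massign
        outputs["marker_associations.csv"] = _stage("markers_assoc")(
            single_marker_analysis
        )(markers, frame, traits, alpha=config.alpha)

    if config.trial_path is not None:
        trial = _stage("trial_read")(read_trial_table)(config.trial_path)
        rows = []
        for trait in trial.traits:
            if len(trial.seasons) > 1:
                _, comps = anova_pooled(trial, trait)
            else:
                _, comps = anova_rcbd(trial, trait, trial.seasons[0])
            mean = float(
                trial.observations.query("trait == @trait")["value"].mean()
            )
            row = {"trait": trait, **comps.as_dict()}
            if mean > 0:
                vp = variability_parameters(
                    comps, mean=mean, ga_basis=config.ga_basis
                )
                row.update(vp.as_dict())
            rows.append(row)
        outputs["variance_components.csv"] = pd.DataFrame(rows).set_index("trait")

    return bundle
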