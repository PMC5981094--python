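"""Orchestration of the four analyses: derivation, reliability across
visits, pattern generalization (TPR), and multivariate-vs-univariate T-map
comparison.  Each stage returns plain tables (pandas) plus the artefacts the
next stage needs; `run_report` chains all of them for a whole cohort.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from .imageio import BrainMask, CohortManifest, VolumeImage
from .ssm import (
    DataMatrix,
    SsmModel,
    build_difference_matrix,
    derive_ssm,
    project_tpr,
    ztransform_pattern,
)


@dataclasses.dataclass
class DeriveResult:
    model: SsmModel
    table: pd.DataFrame  # component, vaf, t, p, d (retained components only)
    identified: int | None  # lowest-index component with p < alpha, or None


def run_derive(
    manifest: CohortManifest,
    visit: str,
    mask: BrainMask,
    volumes: Mapping[str, VolumeImage] | None = None,
    alpha: float = 0.05,
) -> DeriveResult:
    """Derive the SSM model for one visit and identify the condition
    difference-related pattern (lowest-index component whose expression
    separates the groups at p < alpha; rank-deficient components are
    excluded from testing)."""
    data = build_difference_matrix(manifest, visit, mask, volumes=volumes)
    model = derive_ssm(data)
    rows = []
    identified = None
    for k in model.retained_components():
        test = stats.two_sample_t(model.ssf[:, k], model.group_labels)
        rows.append(
            {
                "component": k + 1,
                "vaf": model.vaf[k],
                "t": test.t,
                "p": test.p,
                "d": test.d,
            }
        )
        if identified is None and test.p < alpha:
            identified = int(k)
    return DeriveResult(model=model, table=pd.DataFrame(rows), identified=identified)


def run_reliability(
    models: Mapping[str, SsmModel], component: int = 0
) -> pd.DataFrame:
    """Pairwise pattern similarity and expression reliability across visits.

    For each visit pair: Pearson r of the two independently derived patterns
    (after sign alignment) and ICC + Pearson r of their expressions.  All
    models must share mask and subject set.
    """
    visits = list(models)
    if len(visits) < 2:
        raise ValueError("need at least 2 models")
    ref = models[visits[0]]
    for v in visits[1:]:
        m = models[v]
        if not ref.mask.same_space(m.mask):
            raise ValueError(f"model {v!r} is on a different mask")
        if m.subject_ids != ref.subject_ids:
            raise ValueError(f"model {v!r} has a different subject set")
    rows = []
    for i in range(len(visits)):
        for j in range(i + 1, len(visits)):
            a, b = models[visits[i]], models[visits[j]]
            sim = stats.pattern_similarity(a.gis[:, component], b.gis[:, component])
            rel = stats.icc(a.ssf[:, component], b.ssf[:, component])
            rows.append(
                {
                    "visit_a": visits[i],
                    "visit_b": visits[j],
                    "pattern_r": sim.r,
                    "pattern_flipped": sim.flipped,
                    "ssf_icc": rel.icc,
                    "ssf_r": rel.r,
                }
            )
    return pd.DataFrame(rows)


def run_generalize(
    model: SsmModel,
    manifest: CohortManifest,
    target_visits: Sequence[str],
    mask: BrainMask,
    component: int = 0,
    volumes: Mapping[str, VolumeImage] | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Project a derived pattern onto other visits (TPR) and test it there.

    Returns the per-visit table (t, p, d of the projected expressions) and,
    when exactly two target visits are given, the ICC between the two
    projected expression vectors.
    """
    rows = []
    projections = {}
    for visit in target_visits:
        data = build_difference_matrix(manifest, visit, mask, volumes=volumes)
        if data.subject_ids != model.subject_ids:
            raise ValueError(f"visit {visit!r} has a different subject set")
        ssf = project_tpr(model, component, data)
        projections[visit] = ssf
        test = stats.two_sample_t(ssf, data.group_labels)
        rows.append(
            {"visit": visit, "t": test.t, "p": test.p, "d": test.d}
        )
    icc_value = None
    if len(target_visits) == 2:
        a, b = (projections[v] for v in target_visits)
        icc_value = stats.icc(a, b).icc
    return pd.DataFrame(rows), icc_value


@dataclasses.dataclass
class CompareResult:
    t_threshold: float
    cluster_min: int
    tmap_voxels: int
    z_threshold: float
    pattern_voxels: int
    dsc: float
    tmap: stats.ThresholdedMap
    pattern_map: stats.ThresholdedMap


def run_compare_tmap(
    model: SsmModel,
    data: DataMatrix,
    cluster_min: int,
    connectivity: int = 26,
    alpha: float = 0.05,
    component: int = 0,
) -> CompareResult:
    """Dice overlap between the thresholded univariate T map and the
    z-transformed pattern.

    The T map is cut at the two-tailed critical t for the data's df, then
    cluster-filtered; the |z| threshold for the pattern is chosen so its
    surviving voxel count matches the T map's as closely as possible (never
    exceeding it) under the same cluster-extent filter.
    """
    t, df = stats.voxelwise_ttest(data)
    tcrit = stats.critical_t(df, alpha)
    tmap = stats.cluster_filter(
        np.abs(t) > tcrit, data.mask, cluster_min, connectivity, threshold=tcrit
    )
    z = ztransform_pattern(model, component)
    pattern_map = stats.threshold_match(
        z, cluster_min, tmap.survivor_count, connectivity
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # both-empty Dice
        dsc = stats.dice(pattern_map, tmap)
    return CompareResult(
        t_threshold=tcrit,
        cluster_min=cluster_min,
        tmap_voxels=tmap.survivor_count,
        z_threshold=pattern_map.threshold,
        pattern_voxels=pattern_map.survivor_count,
        dsc=dsc,
        tmap=tmap,
        pattern_map=pattern_map,
    )


def run_report(
    manifest: CohortManifest,
    mask: BrainMask,
    cluster_min: int = 5,
    connectivity: int = 26,
    alpha: float = 0.05,
    component: int = 0,
    volumes: Mapping[str, VolumeImage] | None = None,
) -> dict:
    """Run all four analyses on a cohort; returns a JSON-serializable report."""
    visits = manifest.visits
    derive_results = {
        v: run_derive(manifest, v, mask, volumes=volumes, alpha=alpha) for v in visits
    }
    models = {v: r.model for v, r in derive_results.items()}
    report: dict = {
        "derivation": {
            v: {
                "components": r.table.to_dict(orient="records"),
                "identified_component": None
                if r.identified is None
                else r.identified + 1,
            }
            for v, r in derive_results.items()
        }
    }
    if len(visits) >= 2:
        report["reliability"] = run_reliability(models, component).to_dict(
            orient="records"
        )
        generalization = {}
        for v in visits:
            others = [w for w in visits if w != v]
            table, icc_value = run_generalize(
                models[v], manifest, others, mask, component, volumes=volumes
            )
            generalization[v] = {
                "tests": table.to_dict(orient="records"),
                "projected_icc": icc_value,
            }
        report["generalization"] = generalization
    comparison = {}
    for v in visits:
        data = build_difference_matrix(manifest, v, mask, volumes=volumes)
        cmp = run_compare_tmap(
            models[v], data, cluster_min, connectivity, alpha, component
        )
        comparison[v] = {
            "t_threshold": cmp.t_threshold,
            "cluster_min": cmp.cluster_min,
            "tmap_voxels": cmp.tmap_voxels,
            "z_threshold": cmp.z_threshold,
            "pattern_voxels": cmp.pattern_voxels,
            "dsc": cmp.dsc,
        }
    report["comparison"] = comparison
    return report
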