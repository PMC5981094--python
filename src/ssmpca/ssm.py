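"""Scaled Subprofile Model PCA: difference matrices, derivation, projection.

The derivation chain, for an M-voxel × N-subject matrix of condition
difference maps:

1. centre each subject column to zero mean;
2. the Group Mean Profile (GMP) is the row (voxel) mean of the centred
   matrix; subtracting it row-wise yields the Subject Residual Profile (SRP);
3. a reduced SVD, SRP = U Σ Vᵀ, gives the spatial covariance patterns
   (Group Invariant Subprofiles, GIS = columns of U), the Subject Scaling
   Factors (SSF_jk = Σ_i SRP_ij · GIS_ik, the expression of pattern k in
   subject j) and the variance accounted for, VAF_k = σ_k² / Σ σ².

Because SRP is centred both ways its rank is at most N−1, so the last
singular value is always ≈ 0 and the last component carries no variance.

Projection of a previously derived pattern onto new subjects (Topographic
Profile Rating, TPR) mirrors the derivation: centre the new subject's
column, subtract the *derivation* GMP, and take the inner product with the
pattern.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imageio import (
    GROUPS,
    BrainMask,
    CohortManifest,
    VolumeImage,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)

#: singular values below RANK_TOL × σ₁ are flagged rank-deficient and
#: excluded from group statistics downstream
RANK_TOL = 1e-12


@dataclasses.dataclass
class DataMatrix:
    """M×N voxel-by-subject matrix in the mask's canonical voxel order."""

    values: np.ndarray
    mask: BrainMask
    subject_ids: list[str]
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D voxel × subject matrix")
        m, n = self.values.shape
        if m != self.mask.n_voxels:
            raise ValueError(
                f"row count {m} does not match mask voxel count {self.mask.n_voxels}"
            )
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match column count")
        if self.group_labels is not None and len(self.group_labels) != n:
            raise ValueError("group_labels length does not match column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("data matrix contains non-finite entries")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class SsmModel:
    """Everything the SSM-PCA derivation produced, enough to re-project.

    ``gis`` columns are unit-norm and mutually orthogonal; ``ssf[j, k]`` is
    the expression of pattern k in derivation subject j; ``vaf`` sums to 1
    (all-zero residuals set it to zero and flag ``degenerate``).
    """

    gmp: np.ndarray
    gis: np.ndarray
    singular_values: np.ndarray
    vaf: np.ndarray
    ssf: np.ndarray
    right_vectors: np.ndarray  # V (N×K), sign-aligned with gis
    column_means: np.ndarray
    mask: BrainMask
    subject_ids: list[str]
    group_labels: list[str] | None
    rank_deficient: np.ndarray  # boolean per component
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return self.gis.shape[1]

    def retained_components(self) -> np.ndarray:
        """Indices of components kept for statistics (not rank-deficient)."""
        return np.flatnonzero(~self.rank_deficient)


@dataclasses.dataclass
class ZPattern:
    """A GIS standardized over in-mask voxels (mean 0, sd 1, M−1 denominator)."""

    z: np.ndarray
    source_component: int
    mask: BrainMask


def build_difference_matrix(
    manifest: CohortManifest,
    visit: str,
    mask: BrainMask,
    volumes: Mapping[str, VolumeImage] | None = None,
    signed: bool = True,
) -> DataMatrix:
    """Condition-difference maps for one visit, one column per subject.

    With ``signed=True`` (the derivation convention) the column is EC−EO for
    EC-EO-group subjects and EO−EC for EO-EC-group subjects; with
    ``signed=False`` every column is EC−EO regardless of group (useful when
    group membership is reassigned afterwards, e.g. in the random-division
    bootstrap).

    ``volumes`` optionally maps manifest path strings to in-memory images;
    paths not present (or when ``volumes`` is None) are read from disk.
    """

    sub = manifest.for_visit(visit)

    def fetch(path: str) -> VolumeImage:
        if volumes is not None and path in volumes:
            return volumes[path]
        return read_volume(path)

    columns = []
    subjects = sub.subjects
    groups = [sub.group_of(s) for s in subjects]
    for subject, group in zip(subjects, groups):
        ec = mask.flatten(fetch(sub.path_for(subject, visit, "EC")))
        eo = mask.flatten(fetch(sub.path_for(subject, visit, "EO")))
        diff = ec - eo
        if signed and group == "EO-EC":
            diff = -diff
        columns.append(diff)
    return DataMatrix(
        values=np.column_stack(columns),
        mask=mask,
        subject_ids=subjects,
        group_labels=groups,
    )


def _component_signs(
    gis: np.ndarray, ssf: np.ndarray, group_labels: Sequence[str] | None
) -> np.ndarray:
    """Deterministic sign per component.

    With group labels: the mean SSF of the EC-EO group minus the mean SSF of
    the EO-EC group is made non-negative.  Otherwise (or on an exact tie) the
    largest-|weight| voxel of the pattern is made positive.
    """
    n_comp = gis.shape[1]
    signs = np.ones(n_comp)
    labels = np.asarray(group_labels) if group_labels is not None else None
    for k in range(n_comp):
        s = 0.0
        if labels is not None and set(GROUPS) <= set(labels):
            s = ssf[labels == GROUPS[0], k].mean() - ssf[labels == GROUPS[1], k].mean()
        if s == 0.0:
            w = gis[:, k]
            s = w[np.argmax(np.abs(w))]
        if s < 0:
            signs[k] = -1.0
    return signs


def derive_ssm(data: DataMatrix) -> SsmModel:
    """Run the SSM-PCA derivation on a voxel × subject difference matrix."""
    m, n = data.values.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if m < n:
        raise ValueError(f"need at least as many voxels as subjects (M={m}, N={n})")

    column_means = data.values.mean(axis=0)
    centered = data.values - column_means  # subject columns centred to zero
    gmp = centered.mean(axis=1)
    srp = centered - gmp[:, None]

    u, s, vt = np.linalg.svd(srp, full_matrices=False)  # K = N components
    total = float(np.sum(s**2))
    degenerate = total <= 0.0
    if degenerate:
        warnings.warn(
            "all-zero residual profile: every SSF is 0 and VAF is reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        vaf = np.zeros(n)
    else:
        vaf = s**2 / total

    # Eq-3 route: expression = inner products of residuals with the patterns.
    ssf = srp.T @ u
    signs = _component_signs(u, ssf, data.group_labels)
    u = u * signs
    ssf = ssf * signs
    v = vt.T * signs

    rank_deficient = s < RANK_TOL * (s[0] if s.size and s[0] > 0 else 1.0)

    return SsmModel(
        gmp=gmp,
        gis=u,
        singular_values=s,
        vaf=vaf,
        ssf=ssf,
        right_vectors=v,
        column_means=column_means,
        mask=data.mask,
        subject_ids=list(data.subject_ids),
        group_labels=list(data.group_labels) if data.group_labels else None,
        rank_deficient=rank_deficient,
        degenerate=degenerate,
    )


def ssf_oracle_check(model: SsmModel) -> float:
    """Max |SSF − σ·V| over subjects and components.

    The expressions are computed during derivation as voxel-space inner
    products (SRPᵀ·GIS); algebraically they must equal σ_k·V_jk from the SVD
    factor.  Returns the maximum absolute deviation between the two routes.
    """
    expected = model.right_vectors * model.singular_values
    return float(np.max(np.abs(model.ssf - expected)))


def project_tpr(
    model: SsmModel,
    component: int,
    new_data: DataMatrix,
    center_columns: bool = True,
) -> np.ndarray:
    """Expression of a derived pattern in new subjects (Topographic Profile
    Rating): centre each new subject's column, subtract the derivation GMP,
    inner product with the pattern.  Returns a length-N′ vector."""
    if not model.mask.same_space(new_data.mask):
        raise ValueError("new data are not on the model's mask/voxel order")
    if not 0 <= component < model.n_components:
        raise ValueError(
            f"component {component} out of range 0..{model.n_components - 1}"
        )
    x = new_data.values
    if center_columns:
        x = x - x.mean(axis=0)
    srp_new = x - model.gmp[:, None]
    return srp_new.T @ model.gis[:, component]


def ztransform_pattern(model: SsmModel, component: int) -> ZPattern:
    """Standardize a pattern over in-mask voxels to mean 0, sd 1."""
    if not 0 <= component < model.n_components:
        raise ValueError(
            f"component {component} out of range 0..{model.n_components - 1}"
        )
    w = model.gis[:, component]
    sd = float(w.std(ddof=1))
    if sd == 0.0:
        raise ValueError("pattern is constant over in-mask voxels (sd = 0)")
    return ZPattern(z=(w - w.mean()) / sd, source_component=component, mask=model.mask)


# ---------------------------------------------------------------------------
# model serialization: a directory of NIfTI volumes + TSV tables + meta.json


def save_model(model: SsmModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mask(model.mask, directory / "mask.nii.gz")
    write_volume(model.mask.unflatten(model.gmp), directory / "gmp.nii.gz")
    gis4d = np.stack(
        [model.mask.unflatten(model.gis[:, k]).data for k in range(model.n_components)],
        axis=3,
    )
    write_volume(VolumeImage(gis4d, model.mask.affine), directory / "gis.nii.gz")
    comp = [f"c{k + 1}" for k in range(model.n_components)]
    pd.DataFrame(model.ssf, index=model.subject_ids, columns=comp).to_csv(
        directory / "ssf.tsv", sep="\t", index_label="subject_id"
    )
    pd.DataFrame(
        {
            "component": comp,
            "singular_value": model.singular_values,
            "vaf": model.vaf,
            "rank_deficient": model.rank_deficient.astype(int),
        }
    ).to_csv(directory / "vaf.tsv", sep="\t", index=False)
    pd.DataFrame(model.right_vectors, index=model.subject_ids, columns=comp).to_csv(
        directory / "right_vectors.tsv", sep="\t", index_label="subject_id"
    )
    meta = {
        "subject_ids": model.subject_ids,
        "group_labels": model.group_labels,
        "column_means": list(map(float, model.column_means)),
        "degenerate": model.degenerate,
        "sign_convention": "EC-EO group mean SSF >= EO-EC group mean SSF",
        "voxel_order": "first-axis-fastest ascending over in-mask positions",
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(directory: str | Path) -> SsmModel:
    directory = Path(directory)
    mask = read_mask(directory / "mask.nii.gz")
    gmp = mask.flatten(read_volume(directory / "gmp.nii.gz"))
    gis4d = read_volume(directory / "gis.nii.gz").data
    gis = np.column_stack(
        [
            mask.flatten(VolumeImage(gis4d[..., k], mask.affine))
            for k in range(gis4d.shape[3])
        ]
    )
    ssf = pd.read_csv(directory / "ssf.tsv", sep="\t", index_col="subject_id")
    vaf_table = pd.read_csv(directory / "vaf.tsv", sep="\t")
    v = pd.read_csv(directory / "right_vectors.tsv", sep="\t", index_col="subject_id")
    meta = json.loads((directory / "meta.json").read_text())
    return SsmModel(
        gmp=gmp,
        gis=gis,
        singular_values=vaf_table["singular_value"].to_numpy(),
        vaf=vaf_table["vaf"].to_numpy(),
        ssf=ssf.to_numpy(),
        right_vectors=v.to_numpy(),
        column_means=np.asarray(meta["column_means"], dtype=float),
        mask=mask,
        subject_ids=[str(s) for s in ssf.index],
        group_labels=meta["group_labels"],
        rank_deficient=vaf_table["rank_deficient"].to_numpy().astype(bool),
        degenerate=bool(meta["degenerate"]),
    )
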