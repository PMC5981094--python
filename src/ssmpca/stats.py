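"""Scalar and voxelwise statistics: group tests, ICC, bootstrap, Dice.

The reliability coefficient used throughout is the one-way intraclass
correlation ICC = (BMS − WMS) / (BMS + WMS), with subjects as targets and
the two visits as ratings (equivalent to Shrout–Fleiss ICC(1,1) at k = 2).
Group comparisons are pooled-variance two-sample Student t tests with
Cohen's d = (mean difference)/pooled sd.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import scipy.ndimage
import scipy.stats

from .imageio import GROUPS, BrainMask
from .ssm import DataMatrix, ZPattern, derive_ssm


@dataclasses.dataclass
class GroupTestResult:
    """Pooled-variance two-sample t test with effect size."""

    t: float
    df: int
    p: float
    d: float
    group_means: tuple[float, float]
    groups: tuple[str, str]


@dataclasses.dataclass
class ReliabilityResult:
    icc: float
    bms: float
    wms: float
    r: float  # Pearson correlation of the paired values


@dataclasses.dataclass
class PatternSimilarity:
    r: float
    flipped: bool


@dataclasses.dataclass
class BootstrapSummary:
    values: np.ndarray
    mean: float
    sd: float
    ci95: tuple[float, float]
    seed: int


@dataclasses.dataclass
class ThresholdedMap:
    """Binary in-mask map surviving a height + cluster-extent threshold."""

    binary: np.ndarray
    mask: BrainMask
    threshold: float
    cluster_min: int
    connectivity: int = 26

    @property
    def survivor_count(self) -> int:
        return int(np.count_nonzero(self.binary))


def _split_groups(
    values: np.ndarray, labels: Sequence[str]
) -> tuple[tuple[str, str], np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    # canonical EC-EO / EO-EC ordering when those are the labels
    order = tuple(GROUPS) if set(uniq) == set(GROUPS) else tuple(uniq)
    a = values[labels == order[0]]
    b = values[labels == order[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 members")
    return order, a, b


def two_sample_t(values: np.ndarray, labels: Sequence[str]) -> GroupTestResult:
    """Pooled-variance Student t between the two label groups.

    The sign of t follows mean(group 1) − mean(group 2), with EC-EO taken as
    group 1 when the labels are the condition-order groups.
    """
    values = np.asarray(values, dtype=float)
    order, a, b = _split_groups(values, labels)
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if pooled_var <= 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = scipy.stats.ttest_ind(a, b, equal_var=True)
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var)
    return GroupTestResult(
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        d=float(d),
        group_means=(float(a.mean()), float(b.mean())),
        groups=order,
    )


def critical_t(df: int, alpha: float = 0.05) -> float:
    """Two-tailed critical value of the t distribution."""
    return float(scipy.stats.t.ppf(1 - alpha / 2, df))


def icc(first: np.ndarray, second: np.ndarray) -> ReliabilityResult:
    """One-way ICC = (BMS − WMS)/(BMS + WMS) for paired ratings.

    ``first`` and ``second`` are the two ratings (e.g. two visits) of the
    same N ≥ 3 targets; also returns the plain Pearson r of the pairs.
    """
    x = np.asarray(first, dtype=float)
    y = np.asarray(second, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ratings must be two equal-length 1D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 targets")
    k = 2
    pairs = np.column_stack([x, y])
    target_means = pairs.mean(axis=1)
    grand = pairs.mean()
    bms = k * np.sum((target_means - grand) ** 2) / (n - 1)
    wms = np.sum((pairs - target_means[:, None]) ** 2) / (n * (k - 1))
    if bms + wms <= 0:
        raise ValueError("all ratings identical: ICC undefined (BMS + WMS = 0)")
    r = float(scipy.stats.pearsonr(x, y).statistic)
    return ReliabilityResult(
        icc=float((bms - wms) / (bms + wms)), bms=float(bms), wms=float(wms), r=r
    )


def pattern_similarity(p1: np.ndarray, p2: np.ndarray) -> PatternSimilarity:
    """Pearson similarity of two patterns after sign alignment.

    Patterns from separate SVDs carry an arbitrary sign; if the raw
    correlation is negative the second pattern is flipped (reported via
    ``flipped``) and the aligned, non-negative r is returned.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1 or len(p1) < 3:
        raise ValueError("patterns must be equal-length 1D vectors of length >= 3")
    if p1.std() == 0 or p2.std() == 0:
        raise ValueError("constant pattern: correlation undefined")
    r = float(scipy.stats.pearsonr(p1, p2).statistic)
    flipped = r < 0
    return PatternSimilarity(r=-r if flipped else r, flipped=flipped)


def voxelwise_ttest(
    data: DataMatrix, labels: Sequence[str] | None = None
) -> tuple[np.ndarray, int]:
    """Per-voxel pooled-variance t map; returns (t vector, df).

    Voxels with zero pooled variance get t = 0 (with a warning) rather than
    propagating NaNs into thresholding.
    """
    if labels is None:
        labels = data.group_labels
    if labels is None:
        raise ValueError("group labels are required")
    order, _, _ = _split_groups(data.values[0], labels)
    labels = np.asarray(labels)
    a = data.values[:, labels == order[0]]
    b = data.values[:, labels == order[1]]
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    pooled_var = (
        (n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)
    ) / df
    zero = pooled_var <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-variance voxels set to t = 0",
            RuntimeWarning,
            stacklevel=2,
        )
    denom = np.sqrt(np.where(zero, 1.0, pooled_var) * (1.0 / n1 + 1.0 / n2))
    t = np.where(zero, 0.0, (a.mean(axis=1) - b.mean(axis=1)) / denom)
    return t, df


_STRUCTURES = {6: 1, 18: 2, 26: 3}


def cluster_filter(
    binary: np.ndarray,
    mask: BrainMask,
    cluster_min: int,
    connectivity: int = 26,
    threshold: float = float("nan"),
) -> ThresholdedMap:
    """Drop connected components smaller than ``cluster_min`` voxels.

    Components are found on the 3D grid with 6/18/26-neighbour connectivity
    (faces / faces+edges / faces+edges+corners).
    """
    if cluster_min < 1:
        raise ValueError("cluster_min must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    grid = mask.unflatten_indicator(np.asarray(binary, dtype=bool))
    structure = scipy.ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    labelled, n_comp = scipy.ndimage.label(grid, structure=structure)
    if n_comp:
        sizes = np.bincount(labelled.ravel())
        sizes[0] = 0
        keep = sizes >= cluster_min
        grid = keep[labelled]
    flat = grid.ravel(order="F")[mask._flat]
    return ThresholdedMap(
        binary=flat,
        mask=mask,
        threshold=threshold,
        cluster_min=cluster_min,
        connectivity=connectivity,
    )


def threshold_match(
    z: ZPattern,
    cluster_min: int,
    target_count: int,
    connectivity: int = 26,
) -> ThresholdedMap:
    """Choose the |z| cut whose surviving voxel count best matches a target.

    Candidate thresholds are the distinct observed |z| values (inclusive cut
    |z| ≥ θ).  Among thresholds whose post-cluster-filter survivor count does
    not exceed ``target_count``, the one with the maximal count is chosen;
    ties go to the largest threshold.  The survivor count is monotone
    non-increasing in θ (growing a set can only grow its connected
    components), so a binary search over the sorted candidates suffices.
    """
    mask = z.mask
    absz = np.abs(z.z)
    if not 0 <= target_count <= mask.n_voxels:
        raise ValueError("target_count must be between 0 and the mask size")
    candidates = np.unique(absz)[::-1]  # descending

    def survivors(theta: float) -> ThresholdedMap:
        return cluster_filter(
            absz >= theta, mask, cluster_min, connectivity, threshold=theta
        )

    if survivors(candidates[0]).survivor_count > target_count:
        # even the strictest cut overshoots: return the empty map
        return ThresholdedMap(
            binary=np.zeros(mask.n_voxels, dtype=bool),
            mask=mask,
            threshold=float("inf"),
            cluster_min=cluster_min,
            connectivity=connectivity,
        )
    # binary search for the last candidate (smallest θ) with count <= target
    lo, hi = 0, len(candidates) - 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if survivors(candidates[mid]).survivor_count <= target_count:
            lo = mid
        else:
            hi = mid - 1
    best_count = survivors(candidates[lo]).survivor_count
    # largest θ achieving best_count (ties broken towards the stricter cut)
    lo2, hi2 = 0, lo
    while lo2 < hi2:
        mid = (lo2 + hi2) // 2
        if survivors(candidates[mid]).survivor_count >= best_count:
            hi2 = mid
        else:
            lo2 = mid + 1
    return survivors(candidates[lo2])


def dice(a: ThresholdedMap, b: ThresholdedMap) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|); two empty sets give 0."""
    if not a.mask.same_space(b.mask):
        raise ValueError("maps are not on the same mask")
    na, nb = a.survivor_count, b.survivor_count
    if na + nb == 0:
        warnings.warn("both maps empty: Dice defined as 0", RuntimeWarning, stacklevel=2)
        return 0.0
    overlap = int(np.count_nonzero(a.binary & b.binary))
    return 2.0 * overlap / (na + nb)


def bootstrap_division_icc(
    diff_by_visit: Mapping[str, DataMatrix],
    group_sizes: tuple[int, int],
    n_iter: int,
    seed: int,
    component: int = 0,
) -> dict[tuple[str, str], BootstrapSummary]:
    """Reliability of pattern expression under random re-division of subjects.

    ``diff_by_visit`` holds, per visit, the *unsigned* (EC−EO for every
    subject) difference matrix on a common subject set.  Each iteration
    re-partitions the subjects uniformly at random into groups of sizes
    (n₁, n₂), flips the columns of the second group to rebuild the signed
    matrices, re-derives the SSM model per visit, and computes the ICC of the
    chosen component's expressions for every visit pair.  Identical seeds and
    inputs give identical output.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    visits = list(diff_by_visit)
    if len(visits) < 2:
        raise ValueError("need at least 2 visits")
    ref = diff_by_visit[visits[0]]
    for v in visits[1:]:
        if diff_by_visit[v].subject_ids != ref.subject_ids:
            raise ValueError(f"visit {v!r} has a different subject set")
    n1, n2 = group_sizes
    n = ref.n_subjects
    if n1 + n2 != n:
        raise ValueError("group sizes must sum to the number of subjects")

    rng = np.random.default_rng(seed)
    pairs = [(visits[i], visits[j]) for i in range(len(visits)) for j in range(i + 1, len(visits))]
    values: dict[tuple[str, str], list[float]] = {p: [] for p in pairs}
    for _ in range(n_iter):
        perm = rng.permutation(n)
        labels = np.empty(n, dtype=object)
        labels[perm[:n1]] = GROUPS[0]
        labels[perm[n1:]] = GROUPS[1]
        sign = np.where(labels == GROUPS[0], 1.0, -1.0)
        ssf1: dict[str, np.ndarray] = {}
        for v in visits:
            base = diff_by_visit[v]
            signed = DataMatrix(
                values=base.values * sign,
                mask=base.mask,
                subject_ids=base.subject_ids,
                group_labels=list(labels),
            )
            model = derive_ssm(signed)
            ssf1[v] = model.ssf[:, component]
        for va, vb in pairs:
            values[(va, vb)].append(icc(ssf1[va], ssf1[vb]).icc)

    out = {}
    for p in pairs:
        vals = np.asarray(values[p])
        out[p] = BootstrapSummary(
            values=vals,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if n_iter > 1 else 0.0,
            ci95=(
                float(np.percentile(vals, 2.5)),
                float(np.percentile(vals, 97.5)),
            ),
            seed=seed,
        )
    return out
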