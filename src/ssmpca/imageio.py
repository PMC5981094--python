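"""Volumetric I/O, brain masks and cohort manifests.

All volumes in one analysis live on a single voxel grid; a :class:`BrainMask`
defines the canonical bijection between in-mask grid positions and positions
in a flat voxel vector (first grid axis fastest, ascending — i.e. Fortran
raveling of the grid).  Every voxel×subject matrix downstream uses this
ordering, so serialized models remain portable across runs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
import nibabel as nib
import numpy as np
import pandas as pd

GROUPS = ("EC-EO", "EO-EC")
CONDITIONS = ("EC", "EO")

MANIFEST_COLUMNS = ("subject_id", "group", "visit", "condition", "path")


class ManifestError(ValueError):
    """A cohort manifest violates its invariants."""


@dataclasses.dataclass
class VolumeImage:
    """A 3D (or 4D) scalar image on a voxel grid with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"expected a 3D or 4D volume, got {self.data.ndim} dimensions"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI volume; only 3D and 4D images are accepted."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim not in (3, 4):
        raise ValueError(
            f"{path}: unsupported dimensionality {data.ndim} (need 3 or 4)"
        )
    return VolumeImage(data=data, affine=np.asarray(img.affine))


def write_volume(image: VolumeImage, path: str | Path) -> None:
    nib.Nifti1Image(np.asarray(image.data, dtype=np.float64), image.affine).to_filename(
        str(path)
    )


class BrainMask:
    """Binary 3D mask plus the canonical enumeration of its in-mask voxels.

    The enumeration orders in-mask positions by Fortran ravel index of the
    grid (first axis fastest, ascending) and is deterministic: two masks
    built from equal indicator arrays produce identical orderings.
    """

    def __init__(self, indicator: np.ndarray, affine: np.ndarray | None = None):
        indicator = np.asarray(indicator)
        if indicator.ndim != 3:
            raise ValueError("mask indicator must be 3D")
        self.indicator = indicator != 0
        self.affine = np.eye(4) if affine is None else np.asarray(affine, float)
        # positions in Fortran (first-axis-fastest) ravel order
        self._flat = np.flatnonzero(self.indicator.ravel(order="F"))
        if self._flat.size < 2:
            raise ValueError("mask must contain at least 2 in-mask voxels")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.indicator.shape)

    @property
    def n_voxels(self) -> int:
        """M, the number of in-mask voxels."""
        return int(self._flat.size)

    @property
    def voxel_order(self) -> np.ndarray:
        """(M, 3) integer grid coordinates of in-mask voxels, canonical order."""
        return np.column_stack(
            np.unravel_index(self._flat, self.grid_shape, order="F")
        )

    def flatten(self, image: VolumeImage) -> np.ndarray:
        """Extract in-mask values as a length-M vector (or M×T for 4D)."""
        if image.grid_shape != self.grid_shape:
            raise ValueError(
                f"grid mismatch: image {image.grid_shape} vs mask {self.grid_shape}"
            )
        if image.data.ndim == 3:
            return image.data.ravel(order="F")[self._flat]
        flat = image.data.reshape(-1, image.data.shape[3], order="F")
        return flat[self._flat]

    def unflatten(
        self, vector: np.ndarray, affine: np.ndarray | None = None, fill: float = 0.0
    ) -> VolumeImage:
        """Place a length-M vector back on the grid; out-of-mask voxels get *fill*."""
        vector = np.asarray(vector)
        if vector.shape != (self.n_voxels,):
            raise ValueError(
                f"vector length {vector.shape} does not match mask ({self.n_voxels},)"
            )
        flat = np.full(int(np.prod(self.grid_shape)), fill, dtype=vector.dtype)
        flat[self._flat] = vector
        data = flat.reshape(self.grid_shape, order="F")
        return VolumeImage(data=data, affine=self.affine if affine is None else affine)

    def unflatten_indicator(self, binary: np.ndarray) -> np.ndarray:
        """Boolean grid from an in-mask boolean vector."""
        binary = np.asarray(binary, dtype=bool)
        if binary.shape != (self.n_voxels,):
            raise ValueError("binary vector length does not match mask")
        flat = np.zeros(int(np.prod(self.grid_shape)), dtype=bool)
        flat[self._flat] = binary
        return flat.reshape(self.grid_shape, order="F")

    def same_space(self, other: "BrainMask") -> bool:
        return self.grid_shape == other.grid_shape and np.array_equal(
            self._flat, other._flat
        )


def read_mask(path: str | Path) -> BrainMask:
    vol = read_volume(path)
    if vol.data.ndim != 3:
        raise ValueError("mask must be a 3D volume")
    return BrainMask(vol.data != 0, affine=vol.affine)


def write_mask(mask: BrainMask, path: str | Path) -> None:
    write_volume(
        VolumeImage(mask.indicator.astype(np.float64), mask.affine), path
    )


def flatten(image: VolumeImage, mask: BrainMask) -> np.ndarray:
    """In-mask voxel vector of *image* in the mask's canonical order."""
    return mask.flatten(image)


def unflatten(vector: np.ndarray, mask: BrainMask) -> VolumeImage:
    return mask.unflatten(vector)


class CohortManifest:
    """Table of (subject, group, visit, condition, path) rows.

    Invariants: every (subject, visit) pair has exactly one EC and one EO row;
    each subject belongs to exactly one group; each group has ≥ 2 subjects.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = self._validate(table)

    @staticmethod
    def _validate(table: pd.DataFrame) -> pd.DataFrame:
        if table.empty:
            raise ManifestError("manifest is empty")
        missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
        if missing:
            raise ManifestError(f"manifest is missing columns: {missing}")
        table = table.loc[:, list(MANIFEST_COLUMNS)].copy()
        table["subject_id"] = table["subject_id"].astype(str)
        table["visit"] = table["visit"].astype(str)

        bad_cond = sorted(set(table["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ManifestError(f"unknown condition labels: {bad_cond}")
        bad_group = sorted(set(table["group"]) - set(GROUPS))
        if bad_group:
            raise ManifestError(f"unknown group labels: {bad_group}")

        groups_per_subject = table.groupby("subject_id")["group"].nunique()
        multi = groups_per_subject[groups_per_subject > 1]
        if not multi.empty:
            raise ManifestError(
                f"subjects assigned to more than one group: {list(multi.index)}"
            )

        for (subj, visit), rows in table.groupby(["subject_id", "visit"]):
            conds = sorted(rows["condition"])
            if conds != ["EC", "EO"]:
                raise ManifestError(
                    f"subject {subj!r} visit {visit!r} must have exactly one EC "
                    f"and one EO row, found conditions {conds}"
                )

        sizes = table.drop_duplicates("subject_id")["group"].value_counts()
        small = {g: int(n) for g, n in sizes.items() if n < 2}
        if small:
            raise ManifestError(f"groups with fewer than 2 subjects: {small}")
        return table.reset_index(drop=True)

    @property
    def subjects(self) -> list[str]:
        """Subject ids in first-appearance order."""
        return list(dict.fromkeys(self.table["subject_id"]))

    @property
    def visits(self) -> list[str]:
        return list(dict.fromkeys(self.table["visit"]))

    def group_of(self, subject: str) -> str:
        rows = self.table[self.table["subject_id"] == subject]
        if rows.empty:
            raise KeyError(subject)
        return str(rows["group"].iloc[0])

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes = self.table.drop_duplicates("subject_id")["group"].value_counts()
        return {g: int(sizes.get(g, 0)) for g in GROUPS}

    def path_for(self, subject: str, visit: str, condition: str) -> str:
        rows = self.table[
            (self.table["subject_id"] == subject)
            & (self.table["visit"] == visit)
            & (self.table["condition"] == condition)
        ]
        if rows.empty:
            raise KeyError(
                f"no row for subject {subject!r} visit {visit!r} condition {condition!r}"
            )
        return str(rows["path"].iloc[0])

    def for_visit(self, visit: str) -> "CohortManifest":
        sub = self.table[self.table["visit"] == visit]
        if sub.empty:
            raise ManifestError(f"no rows for visit {visit!r}")
        return CohortManifest(sub)

    def __len__(self) -> int:
        return len(self.table)

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def load_manifest(path: str | Path) -> CohortManifest:
    """Load and validate a tab-separated cohort manifest (header required)."""
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ManifestError(f"{path}: manifest file is empty") from exc
    return CohortManifest(table)
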