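"""Synthetic EC/EO cohorts with a planted spatial covariance pattern.

The generator emulates the statistical structure the SSM-PCA reliability
analysis assumes, on a small grid:

* an ellipsoidal "brain" mask and a unit-norm pattern P built from signed
  Gaussian blobs (posterior/"visual" and superior/"sensorimotor" positive,
  two frontal negative);
* per subject j and visit v a pattern loading s_jv = s_j + e_jv with a
  stable subject part s_j ~ N(μ_s, σ_b²) and session noise
  e_jv ~ N(0, σ_w²), so the loading's between/within structure — and hence
  the test-retest reliability of the pattern expression — is controlled
  analytically;
* condition maps EC = baseline + anatomy_j + ½·s_jv·P + noise and
  EO = baseline + anatomy_j − ½·s_jv·P + noise, so the condition difference
  carries s_jv·P; the signed difference used in derivation (EC−EO for the
  EC-EO group, EO−EC for the EO-EC group) therefore expresses the pattern
  with group-dependent sign g_j·s_jv;
* a per-visit scanner gain multiplying the final maps (visit 3 emulates the
  scanner switch);
* optionally, 4D band-limited BOLD series with exactly known in-band
  amplitudes for testing the ALFF operations.

Because the signed expression g_j·s_jv is what the pipeline estimates, the
planted reliability accounts for the group-mean separation and for the
voxel-noise projection:

    true_icc = σ_t² / (σ_t² + σ_w² + 2σ_v²),   σ_t² = σ_b² + 4p₁p₂μ_s²,

where p₁, p₂ are the group proportions, and the planted effect size is
d = 2μ_s / sqrt(σ_b² + σ_w² + 2σ_v²) (pooled within-group sd units).
:meth:`SimulationConfig.from_targets` inverts these relations so cohorts can
be requested directly by (true ICC, effect size).

All randomness flows from one seed through per-(subject, visit) seed
substreams, so adding visits or subjects does not perturb earlier draws.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
import numpy as np
import pandas as pd
import scipy.ndimage

from .alff import BoldSeries
from .imageio import GROUPS, BrainMask, CohortManifest, VolumeImage, write_mask, write_volume


@dataclasses.dataclass(frozen=True)
class Blob:
    """An isotropic Gaussian bump: centre (voxel coords), sd (voxels), weight."""

    center: tuple[float, float, float]
    radius: float
    weight: float


DEFAULT_GRID = (20, 24, 20)

#: signed blobs for the default 20×24×20 grid: positive posterior ("visual")
#: and superior ("sensorimotor") foci, negative bilateral frontal foci
DEFAULT_PATTERN = (
    Blob(center=(10.0, 4.0, 8.0), radius=3.0, weight=1.0),
    Blob(center=(10.0, 14.0, 16.0), radius=2.5, weight=0.8),
    Blob(center=(6.0, 19.0, 10.0), radius=2.0, weight=-0.7),
    Blob(center=(13.0, 19.0, 10.0), radius=2.0, weight=-0.7),
)


def default_pattern_for(grid_shape: tuple[int, int, int]) -> tuple[Blob, ...]:
    """The default blob layout rescaled to an arbitrary grid."""
    scale = np.asarray(grid_shape) / np.asarray(DEFAULT_GRID)
    radius_scale = float(np.prod(scale) ** (1 / 3))
    return tuple(
        Blob(
            center=tuple(np.asarray(b.center) * scale),
            radius=b.radius * radius_scale,
            weight=b.weight,
        )
        for b in DEFAULT_PATTERN
    )


@dataclasses.dataclass
class SimulationConfig:
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    mask_kind: str = "ellipsoid"  # or "box"
    n_subjects: int = 21
    group_sizes: tuple[int, int] = (11, 10)
    n_visits: int = 3
    pattern_spec: tuple[Blob, ...] = DEFAULT_PATTERN
    loading_mean: float = 0.8142  # μ_s (plants effect size 1.2 with the sds below)
    loading_sd: float = 0.9167  # σ_b, subject-level (plants true ICC 0.6)
    session_noise_sd: float = 1.0  # σ_w, loading-level
    voxel_noise_sd: float = 0.025  # σ_v, per condition map
    anatomy_sd: float = 0.05  # smooth per-subject background variation
    baseline: float = 1.0  # mean of a global-mean-normalized ALFF map
    scanner_gain: tuple[float, ...] = (1.0, 1.0, 1.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern_spec is DEFAULT_PATTERN and tuple(self.grid_shape) != DEFAULT_GRID:
            self.pattern_spec = default_pattern_for(self.grid_shape)
        if sum(self.group_sizes) != self.n_subjects:
            raise ValueError("group sizes must sum to n_subjects")
        if min(self.group_sizes) < 2:
            raise ValueError("each group needs at least 2 subjects")
        for name in ("loading_sd", "session_noise_sd", "voxel_noise_sd", "anatomy_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.scanner_gain) < self.n_visits:
            raise ValueError("scanner_gain must cover every visit")

    # -- planted quantities ------------------------------------------------

    @property
    def group_proportion_product(self) -> float:
        n1, n2 = self.group_sizes
        n = self.n_subjects
        return (n1 / n) * (n2 / n)

    @property
    def within_variance(self) -> float:
        """Visit-level noise on the signed expression: σ_w² + 2σ_v²."""
        return self.session_noise_sd**2 + 2 * self.voxel_noise_sd**2

    @property
    def true_icc(self) -> float:
        """Population ICC of the signed pattern expression across visits."""
        sigma_t2 = (
            self.loading_sd**2
            + 4 * self.group_proportion_product * self.loading_mean**2
        )
        return sigma_t2 / (sigma_t2 + self.within_variance)

    @property
    def true_effect(self) -> float:
        """Expected standardized (pooled-sd) group difference of expressions."""
        return 2 * self.loading_mean / np.sqrt(self.loading_sd**2 + self.within_variance)

    @classmethod
    def from_targets(
        cls, true_icc: float = 0.6, effect_size: float = 1.2, **kwargs
    ) -> "SimulationConfig":
        """Solve (μ_s, σ_b) so the cohort plants the requested reliability
        and effect size, keeping the other noise parameters at their
        defaults (or the supplied overrides)."""
        if not 0 < true_icc < 1:
            raise ValueError("true_icc must be in (0, 1)")
        probe = cls(**kwargs)
        w = probe.within_variance
        pp = probe.group_proportion_product
        ratio = true_icc / (1 - true_icc)
        sigma_b2 = w * (ratio - pp * effect_size**2) / (1 + pp * effect_size**2)
        if sigma_b2 <= 0:
            raise ValueError(
                "requested effect size is too large for the requested ICC: "
                "the group separation alone would exceed the between-subject variance"
            )
        mu = 0.5 * effect_size * np.sqrt(sigma_b2 + w)
        return cls(loading_mean=float(mu), loading_sd=float(np.sqrt(sigma_b2)), **kwargs)


@dataclasses.dataclass
class SimTruth:
    """Ground truth planted by the generator."""

    pattern: np.ndarray  # unit-norm in-mask voxel vector
    loadings: np.ndarray  # subjects × visits, s_jv (unsigned)
    group_labels: list[str]
    true_icc: float
    true_effect: float


@dataclasses.dataclass
class SyntheticCohort:
    """In-memory cohort: maps keyed by manifest path, plus mask and truth."""

    maps: dict[str, VolumeImage]
    manifest: CohortManifest
    mask: BrainMask
    truth: SimTruth
    config: SimulationConfig

    def write(self, directory: str | Path) -> None:
        """Write NIfTI maps, manifest.tsv, mask and truth files to disk."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        table = self.manifest.table.copy()
        for i, rel in enumerate(table["path"]):
            out = directory / rel
            write_volume(self.maps[rel], out)
            table.loc[i, "path"] = str(out)
        table.to_csv(directory / "manifest.tsv", sep="\t", index=False)
        write_mask(self.mask, directory / "mask.nii.gz")
        write_volume(
            self.mask.unflatten(self.truth.pattern), directory / "true_pattern.nii.gz"
        )
        pd.DataFrame(
            self.truth.loadings,
            index=self.manifest.subjects,
            columns=[f"V{v + 1}" for v in range(self.truth.loadings.shape[1])],
        ).to_csv(directory / "true_loadings.tsv", sep="\t", index_label="subject_id")
        (directory / "truth.json").write_text(
            json.dumps(
                {
                    "true_icc": self.truth.true_icc,
                    "true_effect": self.truth.true_effect,
                    "group_labels": self.truth.group_labels,
                },
                indent=2,
            )
        )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def make_phantom(config: SimulationConfig) -> tuple[BrainMask, np.ndarray]:
    """Build the mask and the unit-norm planted pattern (in-mask vector)."""
    shape = np.asarray(config.grid_shape)
    if config.mask_kind == "box":
        indicator = np.ones(config.grid_shape, dtype=bool)
    elif config.mask_kind == "ellipsoid":
        center = (shape - 1) / 2.0
        semi = shape * 0.45
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        dist2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
        indicator = dist2 <= 1.0
    else:
        raise ValueError(f"unknown mask_kind {config.mask_kind!r}")
    if not indicator.any():
        raise ValueError("empty mask")
    mask = BrainMask(indicator)

    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    field = np.zeros(config.grid_shape)
    for blob in config.pattern_spec:
        c = tuple(int(round(x)) for x in blob.center)
        if not all(0 <= ci < si for ci, si in zip(c, shape)) or not indicator[c]:
            raise ValueError(f"blob centre {blob.center} lies outside the mask")
        d2 = sum((g - x) ** 2 for g, x in zip(grids, blob.center))
        field += blob.weight * np.exp(-d2 / (2.0 * blob.radius**2))
    pattern = mask.flatten(VolumeImage(field))
    norm = np.linalg.norm(pattern)
    if norm == 0:
        raise ValueError("pattern is identically zero inside the mask")
    return mask, pattern / norm


def _anatomy(config: SimulationConfig, subject: int) -> np.ndarray:
    """Smooth per-subject background map (same across visits and conditions)."""
    if config.anatomy_sd == 0:
        return np.zeros(config.grid_shape)
    rng = _rng(config.seed, 3, subject)
    field = scipy.ndimage.gaussian_filter(
        rng.standard_normal(config.grid_shape), sigma=2.0
    )
    sd = field.std()
    return config.anatomy_sd * field / (sd if sd > 0 else 1.0)


def simulate_loadings(config: SimulationConfig) -> np.ndarray:
    """The subjects × visits loading matrix s_jv the cohort generator plants.

    Reproduces exactly the loadings :func:`simulate_cohort` would draw for
    the same config (the per-(subject, visit) seed substreams are shared), so
    loading-level properties can be studied at large N without building maps.
    """
    loadings = np.empty((config.n_subjects, config.n_visits))
    for j in range(config.n_subjects):
        s_j = config.loading_mean + config.loading_sd * _rng(
            config.seed, 1, j
        ).standard_normal()
        for v in range(config.n_visits):
            e = config.session_noise_sd * _rng(config.seed, 2, j, v).standard_normal()
            loadings[j, v] = s_j + e
    return loadings


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate per-subject per-visit EC and EO maps, manifest and truth."""
    mask, pattern = make_phantom(config)
    pattern_vol = mask.unflatten(pattern).data
    n1, _ = config.group_sizes
    groups = [GROUPS[0]] * n1 + [GROUPS[1]] * (config.n_subjects - n1)
    subjects = [f"sub-{j + 1:02d}" for j in range(config.n_subjects)]

    loadings = np.empty((config.n_subjects, config.n_visits))
    maps: dict[str, VolumeImage] = {}
    rows = []
    for j, subject in enumerate(subjects):
        s_j = config.loading_mean + config.loading_sd * _rng(
            config.seed, 1, j
        ).standard_normal()
        anatomy = _anatomy(config, j)
        for v in range(config.n_visits):
            visit = f"V{v + 1}"
            rng = _rng(config.seed, 2, j, v)
            s_jv = s_j + config.session_noise_sd * rng.standard_normal()
            loadings[j, v] = s_jv
            gain = config.scanner_gain[v]
            base = config.baseline + anatomy
            for condition, half in (("EC", +0.5), ("EO", -0.5)):
                noise = config.voxel_noise_sd * rng.standard_normal(config.grid_shape)
                data = gain * (base + half * s_jv * pattern_vol + noise)
                path = f"{subject}_{visit}_{condition}.nii.gz"
                maps[path] = VolumeImage(data)
                rows.append(
                    {
                        "subject_id": subject,
                        "group": groups[j],
                        "visit": visit,
                        "condition": condition,
                        "path": path,
                    }
                )

    manifest = CohortManifest(pd.DataFrame(rows))
    truth = SimTruth(
        pattern=pattern,
        loadings=loadings,
        group_labels=groups,
        true_icc=config.true_icc,
        true_effect=config.true_effect,
    )
    return SyntheticCohort(
        maps=maps, manifest=manifest, mask=mask, truth=truth, config=config
    )


def simulate_bold(
    grid_shape: tuple[int, int, int],
    tr: float,
    n_timepoints: int,
    in_band_freq: float,
    out_band_freq: float,
    in_band_amplitude: tuple[float, float] = (0.5, 1.5),
    out_band_amplitude: float = 1.0,
    trend_slope: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BoldSeries, np.ndarray]:
    """Band-limited 4D series with exactly known per-voxel in-band amplitude.

    Each voxel's series is a linear trend + an in-band sinusoid (amplitude
    drawn uniformly from ``in_band_amplitude``) + an out-of-band sinusoid +
    white noise.  Both frequencies must sit exactly on DFT bins so the truth
    map is exact; off-bin frequencies are rejected.
    Returns the series and the per-voxel in-band amplitude map.
    """
    T = n_timepoints
    for f in (in_band_freq, out_band_freq):
        cycles = f * T * tr
        if abs(cycles - round(cycles)) > 1e-9:
            raise ValueError(
                f"frequency {f} Hz is not on a DFT bin for T={T}, tr={tr}"
            )
        if round(cycles) <= 0 or round(cycles) > T // 2:
            raise ValueError(f"frequency {f} Hz outside (0, Nyquist]")
    rng = np.random.default_rng(seed)
    t = np.arange(T) * tr
    amp = rng.uniform(*in_band_amplitude, size=grid_shape)
    phase_in = rng.uniform(0, 2 * np.pi, size=grid_shape)
    phase_out = rng.uniform(0, 2 * np.pi, size=grid_shape)
    data = (
        amp[..., None] * np.sin(2 * np.pi * in_band_freq * t + phase_in[..., None])
        + out_band_amplitude
        * np.sin(2 * np.pi * out_band_freq * t + phase_out[..., None])
        + trend_slope * t
    )
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return BoldSeries(data, tr=tr), amp
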