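"""Synthetic aligned cohorts for exercising the whole pipeline.

Generates, for each subject on one shared grid: a gray-matter density
volume built from a fixed template of smooth positive blobs, a stack of K
component spatial maps (each with a positive and a negative Gaussian
lobe, so that the max- and |min|-projections carry distinct information),
and optionally a band-limited 4D time series for the spectral baselines.

Class structure mimics a dementia cohort without any anatomical claim:

* AD subjects have their designated "atrophy" blobs scaled by
  (1 - gm_effect); disease also loses network amplitude, so the
  designated components' lobes are scaled by (1 + icn_effect) in CN and
  left at baseline in AD, with MCI halfway on both axes.  This matches
  the empirical observation that the cognitively normal maps carry the
  higher in-mask maxima.  The designated component lobes sit on the
  atrophy blobs, so the product channel sMRI*iVIP carries the class
  signal too; one non-designated component is pinned onto a non-atrophy
  gray-matter blob so per-subject min-max renormalization has a stable,
  class-independent anchor.
* Voxel noise is independent Gaussian with standard deviation noise_sd.

Everything is deterministic given the cohort seed; subject sub-seeds
follow the counter scheme seed * 1_000_003 + subject_index (mod 2^31).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .spectral import FrequencyBand, TimeSeriesVolume, DEFAULT_BAND
from .volumes import ComponentStack, Volume, VolumeGrid, write_volume

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "generate_cohort",
    "generate_timeseries",
    "write_cohort",
    "load_subject_table",
    "designated_blob_mask",
    "ATROPHY_CENTERS",
    "GM_BLOB_CENTERS",
]

CLASSES = ("AD", "MCI", "CN")

#: fixed fractional centers of the gray-matter template blobs;
#: the first two are the designated "atrophy" blobs
GM_BLOB_CENTERS = (
    (0.32, 0.38, 0.42),
    (0.68, 0.38, 0.42),
    (0.50, 0.62, 0.52),
    (0.35, 0.68, 0.66),
    (0.65, 0.68, 0.66),
    (0.50, 0.42, 0.70),
)
ATROPHY_CENTERS = GM_BLOB_CENTERS[:2]
GM_BLOB_SIGMA = 0.10
HEAD_SIGMA = 0.34  # broad background blob so the brain mask is contiguous
COMPONENT_SIGMA = 0.13
N_DESIGNATED_COMPONENTS = 2


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_per_class: dict = field(default_factory=lambda: {"AD": 10, "MCI": 0, "CN": 10})
    grid: VolumeGrid = field(default_factory=lambda: VolumeGrid.isotropic((24, 24, 24)))
    k_components: int = 8
    gm_effect: float = 0.4
    icn_effect: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_per_class) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class label(s) {sorted(unknown)}")
        counts = {c: int(self.n_per_class.get(c, 0)) for c in CLASSES}
        if any(v < 0 for v in counts.values()) or sum(counts.values()) < 2:
            raise ValueError("class counts must be >= 0 and total >= 2")
        object.__setattr__(self, "n_per_class", counts)
        if min(self.grid.dims) < 8:
            raise ValueError(f"grid {self.grid.dims} too small for blob templates (< 8 per axis)")
        if self.k_components < 1:
            raise ValueError("need at least one component")
        if self.gm_effect < 0 or self.icn_effect < 0 or not np.isfinite(self.gm_effect + self.icn_effect):
            raise ValueError("effects must be finite and >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_class.values())


@dataclass
class SyntheticSubject:
    subject_id: str
    label: str
    smri: Volume
    icn_stack: ComponentStack
    ts: Optional[TimeSeriesVolume] = None
    ground_truth: dict = field(default_factory=dict)


def _frac_coords(grid: VolumeGrid) -> list[np.ndarray]:
    """Per-axis voxel-center coordinates in [0, 1]."""
    return [
        (np.arange(d) + 0.5) / d for d in grid.dims
    ]


def _blob(grid: VolumeGrid, center: tuple, sigma: float) -> np.ndarray:
    cx, cy, cz = _frac_coords(grid)
    dx = ((cx - center[0]) ** 2)[:, None, None]
    dy = ((cy - center[1]) ** 2)[None, :, None]
    dz = ((cz - center[2]) ** 2)[None, None, :]
    return np.exp(-(dx + dy + dz) / (2.0 * sigma ** 2))


def _gm_template(grid: VolumeGrid) -> tuple[np.ndarray, list[np.ndarray]]:
    """Background head blob plus the fixed gray-matter blobs."""
    head = 0.25 * _blob(grid, (0.5, 0.5, 0.5), HEAD_SIGMA)
    blobs = [_blob(grid, c, GM_BLOB_SIGMA) for c in GM_BLOB_CENTERS]
    return head, blobs


def _component_templates(grid: VolumeGrid, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """(positive lobe, negative lobe) template pair per component.

    Designated components pin their class-sensitive lobe onto an atrophy
    blob so gray-matter and network effects spatially coincide; the
    remaining lobes come from a fixed (cohort-independent) layout.
    """
    layout_rng = np.random.default_rng(7)  # fixed template layout, not cohort noise
    templates = []
    for i in range(k):
        pos_c = tuple(layout_rng.uniform(0.25, 0.75, size=3))
        neg_c = tuple(layout_rng.uniform(0.25, 0.75, size=3))
        if i == 0:
            pos_c = ATROPHY_CENTERS[0]
        elif i == 1:
            neg_c = ATROPHY_CENTERS[1]
        elif i == 2:
            pos_c = GM_BLOB_CENTERS[2]  # class-independent anchor lobe
        templates.append(
            (_blob(grid, pos_c, COMPONENT_SIGMA), _blob(grid, neg_c, COMPONENT_SIGMA))
        )
    return templates


def _class_factors(label: str, spec: CohortSpec) -> tuple[float, float]:
    """(gray-matter retention, designated component amplitude) for a class.

    Atrophy removes gray matter in AD; network amplitude in the
    designated components is likewise lost with disease (CN carries the
    full 1 + icn_effect amplitude, AD the baseline, MCI halfway).
    """
    if label == "AD":
        return 1.0 - spec.gm_effect, 1.0
    if label == "MCI":
        return 1.0 - spec.gm_effect / 2.0, 1.0 + spec.icn_effect / 2.0
    return 1.0, 1.0 + spec.icn_effect


def subject_seed(cohort_seed: int, index: int) -> int:
    """Documented counter scheme for per-subject sub-seeds."""
    return (cohort_seed * 1_000_003 + index) % (2 ** 31)


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Deterministically generate the cohort described by ``spec``."""
    grid = spec.grid
    head, gm_blobs = _gm_template(grid)
    comp_templates = _component_templates(grid, spec.k_components)
    subjects: list[SyntheticSubject] = []
    index = 0
    for label in CLASSES:
        for j in range(spec.n_per_class[label]):
            seed = subject_seed(spec.seed, index)
            rng = np.random.default_rng(seed)
            gm_keep, icn_amp = _class_factors(label, spec)

            gm = head.copy()
            for b, blob in enumerate(gm_blobs):
                scale = gm_keep if b < len(ATROPHY_CENTERS) else 1.0
                gm += scale * blob
            gm = gm + rng.normal(0.0, spec.noise_sd, size=grid.dims)

            maps = []
            for i, (pos, neg) in enumerate(comp_templates):
                amp = icn_amp if i < min(N_DESIGNATED_COMPONENTS, spec.k_components) else 1.0
                signal = amp * pos - amp * neg if i < N_DESIGNATED_COMPONENTS else pos - neg
                maps.append(Volume(grid, signal + rng.normal(0.0, spec.noise_sd, size=grid.dims)))

            subjects.append(
                SyntheticSubject(
                    subject_id=f"{label}_{j:03d}",
                    label=label,
                    smri=Volume(grid, gm),
                    icn_stack=ComponentStack(grid, maps),
                    ground_truth={
                        "seed": seed,
                        "gm_retention": gm_keep,
                        "icn_amplitude": icn_amp,
                        "atrophy_centers": ATROPHY_CENTERS,
                        "designated_components": tuple(
                            range(min(N_DESIGNATED_COMPONENTS, spec.k_components))
                        ),
                    },
                )
            )
            index += 1
    return subjects


def generate_timeseries(
    subject: SyntheticSubject,
    t: int = 128,
    tr_seconds: float = 2.0,
    band: FrequencyBand = DEFAULT_BAND,
    amplitude_scale: float = 1.0,
    noise_sd: float = 0.05,
) -> TimeSeriesVolume:
    """Band-limited sinusoid per voxel, amplitude tied to the component signal.

    The sinusoid sits on an exact FFT bin inside the band (nearest bin to
    the band center), its per-voxel amplitude scales with the subject's
    max-absolute component projection, and independent white noise is
    added.  Reproducible from the subject's recorded sub-seed.
    """
    if t < 32:
        raise ValueError(f"need at least 32 time points, got {t}")
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    in_band = (freqs >= band.lo_hz) & (freqs <= band.hi_hz) & (freqs > 0)
    if not in_band.any():
        raise ValueError(f"band [{band.lo_hz}, {band.hi_hz}] Hz infeasible for T={t}, TR={tr_seconds}")
    center = 0.5 * (band.lo_hz + band.hi_hz)
    f0 = freqs[in_band][np.argmin(np.abs(freqs[in_band] - center))]

    rng = np.random.default_rng(subject.ground_truth.get("seed", 0) + 2 ** 20)
    amp = amplitude_scale * np.abs(subject.icn_stack.as_array()).max(axis=0)
    phase = rng.uniform(0, 2 * np.pi, size=subject.smri.grid.dims)
    times = np.arange(t) * tr_seconds
    series = amp[..., None] * np.sin(
        2 * np.pi * f0 * times[None, None, None, :] + phase[..., None]
    )
    if noise_sd > 0:
        series = series + rng.normal(0.0, noise_sd, size=series.shape)
    subject.ts = TimeSeriesVolume(subject.smri.grid, series, tr_seconds)
    return subject.ts


def designated_blob_mask(grid: VolumeGrid, radius_sigmas: float = 1.0) -> np.ndarray:
    """Boolean map of voxels within the designated atrophy blobs."""
    mask = np.zeros(grid.dims, dtype=bool)
    for c in ATROPHY_CENTERS:
        mask |= _blob(grid, c, GM_BLOB_SIGMA) > np.exp(-0.5 * radius_sigmas ** 2)
    return mask


def write_cohort(subjects: list[SyntheticSubject], out_dir: Union[str, Path],
                 write_timeseries: bool = False) -> Path:
    """Write the NIfTI + CSV layout the pipeline consumes; return the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        smri_path = out_dir / f"{s.subject_id}_gm.nii.gz"
        stack_path = out_dir / f"{s.subject_id}_icn.nii.gz"
        write_volume(s.smri, smri_path)
        write_volume(s.icn_stack, stack_path)
        row = {
            "subject_id": s.subject_id,
            "label": s.label,
            "smri_path": smri_path.name,
            "icn_stack_path": stack_path.name,
            "ts_path": "",
        }
        if write_timeseries and s.ts is not None:
            import nibabel as nib

            ts_path = out_dir / f"{s.subject_id}_rest.nii.gz"
            img = nib.Nifti1Image(np.asarray(s.ts.values, dtype=np.float32), s.smri.grid.affine)
            img.header.set_zooms(s.smri.grid.voxel_size_mm + (s.ts.tr_seconds,))
            nib.save(img, str(ts_path))
            row["ts_path"] = ts_path.name
        rows.append(row)
    csv_path = out_dir / "subjects.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path


def load_subject_table(csv_path: Union[str, Path]) -> pd.DataFrame:
    """Read a subject table and validate its label bookkeeping.

    Returns the table with a ``label`` column restricted to AD/MCI/CN;
    per-class counts therefore always sum to the table length.
    """
    df = pd.read_csv(csv_path)
    required = {"subject_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing column(s) {sorted(missing)}")
    bad = set(df["label"].unique()) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown label(s) in subject table: {sorted(bad)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in table")
    return df
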