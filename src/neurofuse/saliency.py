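"""Guided-backpropagation saliency with cohort-level aggregation.

Guided backprop computes the gradient of a chosen class logit with
respect to each input channel, but at every ReLU the backward signal is
zeroed wherever the forward activation was non-positive OR the incoming
backward signal is negative.  For a network with no ReLU it reduces
exactly to the plain input gradient — the analytic oracle used in the
test suite.

Cohort summaries follow the usual recipe: mask each per-subject map,
smooth it (FWHM 10 by default), then average voxel-wise across subjects.
Because smoothing is linear, smoothing-then-averaging equals
averaging-then-smoothing; thresholding is applied only at visualization
time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fusion import ModelInput
from .model import ClassifierModel
from .volumes import BinaryMask, Volume, VolumeGrid, gaussian_smooth, write_volume

__all__ = [
    "SaliencyVolume",
    "SaliencySummary",
    "guided_backprop",
    "aggregate_saliency",
    "render_montage",
]


@dataclass
class SaliencyVolume:
    """Signed per-voxel attribution for one input channel of one subject."""

    grid: VolumeGrid
    values: np.ndarray
    channel_index: int
    subject_id: str = ""
    target_class: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"saliency shape {self.values.shape} != grid dims {self.grid.dims}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("saliency map contains non-finite values")


@dataclass
class SaliencySummary:
    """Cohort mean saliency for one channel, with the recipe recorded."""

    grid: VolumeGrid
    mean_map: np.ndarray
    channel_index: int
    n_subjects: int
    fwhm_used: float
    mask: Optional[BinaryMask] = None
    signed: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("summary needs at least one subject")
        self.mean_map = np.asarray(self.mean_map, dtype=np.float64)
        if self.mean_map.shape != self.grid.dims:
            raise ValueError("mean map shape does not match grid")


def guided_backprop(
    model: ClassifierModel,
    model_input: Union[ModelInput, np.ndarray],
    target_class: int,
    grid: Optional[VolumeGrid] = None,
    guided: bool = True,
) -> list[SaliencyVolume]:
    """One saliency map per input channel for a single subject.

    ``guided=False`` gives the plain input gradient (useful as a
    reference).  The model is evaluated in eval mode, so the result is
    deterministic for fixed parameters.
    """
    if isinstance(model_input, ModelInput):
        x = model_input.as_array()[None]
        grid = model_input.channels[0].grid
        subject_id = model_input.subject_id
    else:
        x = np.asarray(model_input, dtype=np.float64)
        if x.ndim == 4:
            x = x[None]
        if grid is None:
            grid = VolumeGrid.isotropic(x.shape[2:5])
        subject_id = ""
    model.eval_mode()
    logits = model.forward(x)
    n_classes = logits.shape[1]
    if not 0 <= target_class < n_classes:
        raise ValueError(f"target_class {target_class} out of range for {n_classes} classes")
    dout = np.zeros_like(logits)
    dout[0, target_class] = 1.0
    dx = model.net.backward(dout, guided=guided)[0]  # (C, D, H, W)
    return [
        SaliencyVolume(grid, dx[c], channel_index=c, subject_id=subject_id,
                       target_class=target_class)
        for c in range(dx.shape[0])
    ]


def aggregate_saliency(
    maps: Sequence[SaliencyVolume],
    fwhm: float = 10.0,
    mask: Optional[BinaryMask] = None,
    units: str = "mm",
    signed: bool = False,
) -> SaliencySummary:
    """Mask, smooth (FWHM default 10), then average across subjects.

    By default maps are reduced to magnitudes (absolute value) before
    averaging so that positive and negative attributions do not cancel;
    ``signed=True`` averages the raw signed maps instead.
    """
    if not maps:
        raise ValueError("no saliency maps to aggregate")
    channel = maps[0].channel_index
    grid = maps[0].grid
    for m in maps:
        if m.channel_index != channel:
            raise ValueError(
                f"mixed channels in aggregation: {channel} vs {m.channel_index}"
            )
        grid.require_match(m.grid)
    if mask is not None:
        grid.require_match(mask.grid)
    acc = np.zeros(grid.dims)
    for m in maps:
        v = m.values if signed else np.abs(m.values)
        if mask is not None:
            v = np.where(mask.included, v, 0.0)
        acc += gaussian_smooth(Volume(grid, v), fwhm, units=units).values
    return SaliencySummary(
        grid=grid,
        mean_map=acc / len(maps),
        channel_index=channel,
        n_subjects=len(maps),
        fwhm_used=float(fwhm),
        mask=mask,
        signed=signed,
    )


def _slice_indices(n: int, count: int = 6) -> np.ndarray:
    return np.unique(np.linspace(n * 0.2, n * 0.8, count).astype(int))


def render_montage(
    summary: SaliencySummary,
    out_path: Union[str, Path],
    threshold_quantile: float = 0.9,
    n_slices: int = 6,
) -> Path:
    """Write a 3-row (axial/coronal/sagittal) slice montage PNG.

    Values below the in-mask quantile are suppressed (quantile 0 keeps
    everything).  The thresholded map is also written as NIfTI next to
    the PNG.  A constant map degenerates the threshold; the montage is
    still rendered, with a warning.
    """
    if not 0 <= threshold_quantile < 1:
        raise ValueError(f"threshold_quantile must be in [0, 1), got {threshold_quantile}")
    values = summary.mean_map
    in_mask = values[summary.mask.included] if summary.mask is not None else values.ravel()
    if in_mask.size == 0:
        raise ValueError("no in-mask values to threshold")
    if np.ptp(in_mask) == 0:
        warnings.warn("constant saliency map: threshold is degenerate", RuntimeWarning,
                      stacklevel=2)
        thr = -np.inf if threshold_quantile == 0 else np.inf
    else:
        thr = -np.inf if threshold_quantile == 0 else float(
            np.quantile(in_mask, threshold_quantile)
        )
    shown = np.where(values >= thr, values, 0.0)
    if summary.mask is not None:
        shown = np.where(summary.mask.included, shown, 0.0)

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    write_volume(Volume(summary.grid, shown), out_path.with_suffix(".nii.gz"))

    axes_labels = ("sagittal", "coronal", "axial")
    fig, axes = plt.subplots(3, n_slices, figsize=(2.0 * n_slices, 6.0))
    vmax = float(np.abs(shown).max()) or 1.0
    for row, axis_name in enumerate(axes_labels):
        dim = summary.grid.dims[row]
        for col, s in enumerate(_slice_indices(dim, n_slices)):
            ax = np.atleast_2d(axes)[row, col]
            sl = np.take(shown, s, axis=row)
            ax.imshow(sl.T, origin="lower", cmap="hot", vmin=0, vmax=vmax)
            ax.set_xticks([])
            ax.set_yticks([])
            if col == 0:
                ax.set_ylabel(axis_name)
    fig.suptitle(
        f"channel {summary.channel_index}: mean saliency over {summary.n_subjects} "
        f"subject(s), FWHM {summary.fwhm_used:g}, q={threshold_quantile:g}"
    )
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
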