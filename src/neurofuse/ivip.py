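"""Voxel-wise intensity projections (iVIP) over a stack of ICN maps.

A subject's resting-state decomposition yields K component spatial maps
(intrinsic connectivity networks).  Each projection collapses the stack to
one 3D map per voxel:

* ``max_icn``      — the most activating network: max_k x_k
* ``abs_min_icn``  — the most de-activating network: |min_k x_k|
* ``max_abs_icn``  — the most extreme network regardless of sign: max_k |x_k|

Projections are computed on the raw component values; masking and min-max
normalization happen downstream (see :mod:`neurofuse.fusion`).  The exact
identity ``max_abs = max(max_icn, abs_min_icn)`` holds voxel-wise and is
used as a self-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import ComponentStack, VolumeGrid

__all__ = [
    "FeatureVolume",
    "FEATURE_KINDS",
    "project_max",
    "project_abs_min",
    "project_max_abs",
    "project",
    "argmax_component",
]

FEATURE_KINDS = (
    "smri",
    "max_icn",
    "abs_min_icn",
    "max_abs_icn",
    "alff",
    "falff",
    "fused_channel",
)


@dataclass
class FeatureVolume:
    """One 3D feature map with a record of what it is and where it came from."""

    grid: VolumeGrid
    values: np.ndarray
    feature_kind: str
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"feature shape {self.values.shape} != grid dims {self.grid.dims}"
            )
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(
                f"unknown feature_kind {self.feature_kind!r}; expected one of {FEATURE_KINDS}"
            )


def project_max(stack: ComponentStack) -> FeatureVolume:
    """Per voxel, the maximum value across the K component maps."""
    values = stack.as_array().max(axis=0)
    return FeatureVolume(stack.grid, values, "max_icn", f"max over {stack.k} ICNs")


def project_abs_min(stack: ComponentStack) -> FeatureVolume:
    """Per voxel, the absolute value of the minimum across components."""
    values = np.abs(stack.as_array().min(axis=0))
    return FeatureVolume(stack.grid, values, "abs_min_icn", f"|min| over {stack.k} ICNs")


def project_max_abs(stack: ComponentStack) -> FeatureVolume:
    """Per voxel, the maximum absolute value across components."""
    values = np.abs(stack.as_array()).max(axis=0)
    return FeatureVolume(stack.grid, values, "max_abs_icn", f"max|.| over {stack.k} ICNs")


_PROJECTIONS = {
    "max_icn": project_max,
    "abs_min_icn": project_abs_min,
    "max_abs_icn": project_max_abs,
}


def project(stack: ComponentStack, kind: str) -> FeatureVolume:
    """Dispatch a projection by feature kind name."""
    try:
        fn = _PROJECTIONS[kind]
    except KeyError:
        raise ValueError(
            f"unknown projection {kind!r}; expected one of {sorted(_PROJECTIONS)}"
        ) from None
    return fn(stack)


def argmax_component(stack: ComponentStack, kind: str = "max_abs_icn") -> np.ndarray:
    """Which component wins the projection at each voxel (diagnostic).

    Ties break toward the lowest component index (np.argmax convention).
    """
    arr = stack.as_array()
    if kind == "max_icn":
        return arr.argmax(axis=0)
    if kind == "abs_min_icn":
        return arr.argmin(axis=0)
    if kind == "max_abs_icn":
        return np.abs(arr).argmax(axis=0)
    raise ValueError(f"unknown projection {kind!r}")
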