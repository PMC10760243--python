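"""Assemble per-subject multi-channel model inputs.

Three constructions, mirroring the study's three experiments:

1. unimodal    — one channel: masked, min-max normalized feature map
2. two_channel — [sMRI, iVIP], each masked and normalized
3. fused       — [s*s, s*v, v*v] where s and v are the masked, normalized
                 sMRI and iVIP maps; each product/square is re-normalized
                 after computation so every channel spans [0, 1]

One mask per subject, derived from that subject's gray-matter map, is
applied to every channel.  Channel order is fixed and semantic: the
sMRI-derived channel always comes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ivip import FeatureVolume
from .volumes import BinaryMask, Volume, minmax_normalize

__all__ = ["FusionSpec", "ModelInput", "build_unimodal", "build_two_channel", "build_fused", "build_model_input"]

EXPERIMENT_CHANNELS = {"unimodal": 1, "two_channel": 2, "fused": 3}


@dataclass(frozen=True)
class FusionSpec:
    """Which experiment to build, and which iVIP (or spectral) feature feeds it."""

    experiment: str
    ivip_kind: str = "max_abs_icn"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_CHANNELS:
            raise ValueError(
                f"experiment must be one of {sorted(EXPERIMENT_CHANNELS)}, got {self.experiment!r}"
            )

    @property
    def n_channels(self) -> int:
        return EXPERIMENT_CHANNELS[self.experiment]


@dataclass
class ModelInput:
    """Ordered [0,1] channels for one subject, plus its label."""

    subject_id: str
    channels: list[FeatureVolume]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a model input needs at least one channel")
        grid = self.channels[0].grid
        for i, ch in enumerate(self.channels):
            grid.require_match(ch.grid)
            if ch.values.min() < 0 or ch.values.max() > 1:
                raise ValueError(f"channel {i} has values outside [0, 1]")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def as_array(self) -> np.ndarray:
        """(n_channels, x, y, z) array for the classifier."""
        return np.stack([ch.values for ch in self.channels], axis=0)


def _mask_and_normalize(vol: FeatureVolume, mask: BinaryMask) -> FeatureVolume:
    vol.grid.require_match(mask.grid)
    masked = np.where(mask.included, vol.values, 0.0)
    normed = minmax_normalize(Volume(vol.grid, masked), mask)
    return FeatureVolume(vol.grid, normed.values, vol.feature_kind, vol.provenance)


def build_unimodal(vol: FeatureVolume, mask: BinaryMask, subject_id: str = "", label: str = "") -> ModelInput:
    """Single-channel input: minmax_normalize(mask(vol))."""
    return ModelInput(subject_id, [_mask_and_normalize(vol, mask)], label)


def build_two_channel(
    smri: FeatureVolume, ivip: FeatureVolume, mask: BinaryMask, subject_id: str = "", label: str = ""
) -> ModelInput:
    """Two channels: sMRI first, the iVIP second, each masked and normalized."""
    return ModelInput(
        subject_id,
        [_mask_and_normalize(smri, mask), _mask_and_normalize(ivip, mask)],
        label,
    )


def build_fused(
    smri: FeatureVolume, ivip: FeatureVolume, mask: BinaryMask, subject_id: str = "", label: str = ""
) -> ModelInput:
    """Three fused channels [s*s, s*v, v*v], each re-normalized.

    Normalization happens after each modality is masked/normalized AND
    again after each product or square, which keeps the three channels on
    an equal footing.
    """
    s = _mask_and_normalize(smri, mask)
    v = _mask_and_normalize(ivip, mask)

    def renorm(prod: np.ndarray, prov: str) -> FeatureVolume:
        normed = minmax_normalize(Volume(smri.grid, prod), mask)
        return FeatureVolume(smri.grid, normed.values, "fused_channel", prov)

    return ModelInput(
        subject_id,
        [
            renorm(s.values * s.values, "sMRI*sMRI"),
            renorm(s.values * v.values, f"sMRI*{ivip.feature_kind}"),
            renorm(v.values * v.values, f"{ivip.feature_kind}*{ivip.feature_kind}"),
        ],
        label,
    )


def build_model_input(
    spec: FusionSpec,
    smri: FeatureVolume,
    ivip: FeatureVolume | None,
    mask: BinaryMask,
    subject_id: str = "",
    label: str = "",
    unimodal_feature: str = "smri",
) -> ModelInput:
    """Dispatch to the experiment's construction.

    For unimodal inputs, ``unimodal_feature`` picks which map is used
    ("smri" or anything else meaning the iVIP/spectral map).
    """
    if spec.experiment == "unimodal":
        vol = smri if unimodal_feature == "smri" else ivip
        if vol is None:
            raise ValueError("unimodal non-sMRI input requires an ivip volume")
        return build_unimodal(vol, mask, subject_id, label)
    if ivip is None:
        raise ValueError(f"experiment {spec.experiment!r} requires an ivip volume")
    if spec.experiment == "two_channel":
        return build_two_channel(smri, ivip, mask, subject_id, label)
    return build_fused(smri, ivip, mask, subject_id, label)
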