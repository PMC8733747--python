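"""Shared domain types: spectral channels, plaque component classes, colors.

The imaging geometry follows an intravascular rotational pullback: each
frame is one full rotation of the probe, sampled at ``ALINES_PER_FRAME``
depth scans (A-lines). Fluorescence readouts are produced on a coarser
angular grid of ``ALINES_PER_GROUP`` consecutive A-lines per location,
giving ``N_LOCATIONS`` locations per frame. Angle 0 degrees is at
12 o'clock and increases clockwise; A-line spans are half-open and 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

ALINES_PER_FRAME = 2048
ALINES_PER_GROUP = 4
N_LOCATIONS = ALINES_PER_FRAME // ALINES_PER_GROUP  # 512
N_FEATURES_PER_LOCATION = 6  # 3 channel lifetimes + 3 intensity ratios


@dataclass(frozen=True)
class SpectralChannelSpec:
    """One detection band of the multispectral fluorescence system."""

    index: int  # 1-based
    center_wavelength_nm: float
    bandwidth_nm: float

    def __post_init__(self) -> None:
        if self.index not in (1, 2, 3):
            raise ValueError("channel index must be 1, 2 or 3")


#: The three detection bands (center/bandwidth in nm).
DEFAULT_CHANNELS: tuple[SpectralChannelSpec, ...] = (
    SpectralChannelSpec(1, 390.0, 40.0),
    SpectralChannelSpec(2, 452.0, 45.0),
    SpectralChannelSpec(3, 542.0, 50.0),
)

N_CHANNELS = len(DEFAULT_CHANNELS)


class ComponentClass(str, Enum):
    """The five biochemical plaque component classes."""

    NORMAL = "normal"
    FIBROTIC = "fibrotic"
    LIPID = "lipid"
    MACROPHAGE = "macrophage"
    LIPID_MACROPHAGE = "lipid_macrophage"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed class order used everywhere (confusion matrices, burden indices, ...).
CLASS_ORDER: tuple[ComponentClass, ...] = (
    ComponentClass.NORMAL,
    ComponentClass.FIBROTIC,
    ComponentClass.LIPID,
    ComponentClass.MACROPHAGE,
    ComponentClass.LIPID_MACROPHAGE,
)

CLASS_LABELS: tuple[str, ...] = tuple(c.value for c in CLASS_ORDER)

#: Display colors (RGB in 0..1): normal bright blue, fibrotic green,
#: lipid yellow, macrophage bright red, lipids+macrophage dark red.
CLASS_COLORS: dict[ComponentClass, tuple[float, float, float]] = {
    ComponentClass.NORMAL: (0.1, 0.5, 1.0),
    ComponentClass.FIBROTIC: (0.1, 0.8, 0.2),
    ComponentClass.LIPID: (1.0, 0.9, 0.1),
    ComponentClass.MACROPHAGE: (1.0, 0.1, 0.1),
    ComponentClass.LIPID_MACROPHAGE: (0.55, 0.0, 0.0),
}

#: Color for locations that could not be classified (invalid signal).
UNCLASSIFIED_COLOR: tuple[float, float, float] = (0.5, 0.5, 0.5)

#: The classification feature set: ch.1 and ch.2 lifetimes plus the
#: ch.1/ch.2 intensity ratio (ch.3 is excluded due to weak signal).
CLASSIFIER_FEATURES: tuple[str, ...] = ("FL_ch1", "FL_ch2", "IR1")

#: All six per-location readout features.
FEATURE_NAMES: tuple[str, ...] = ("FL_ch1", "FL_ch2", "FL_ch3", "IR1", "IR2", "IR3")


def class_index(label: ComponentClass | str) -> int:
    """Position of a class in the fixed class order."""
    return CLASS_ORDER.index(ComponentClass(label))


def aline_span(location: int, alines_per_group: int = ALINES_PER_GROUP) -> tuple[int, int]:
    """Half-open span of OCT A-lines covered by one readout location."""
    if location < 0:
        raise ValueError("location index must be non-negative")
    return (location * alines_per_group, (location + 1) * alines_per_group)
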