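"""Run configuration: the quantification constants and their validation.

Defaults reproduce the published analysis settings: nuclei kept at
150-600 px equivalent diameter (~7-29 um at the default pixel size) and
form factor 0.70-1.00; pDNA puncta 4-40 px diameter; Gal9 puncta
0.5-2 um diameter; colocalization called at >=30 % overlap of the Gal9
punctum area.  Everything is overridable from a YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Default pixel size, um per pixel.  Chosen so the published pixel and
#: micron windows agree (600 px ~ 29 um); override per dataset.
DEFAULT_PIXEL_SIZE_UM = 0.048


@dataclass
class ChannelParams:
    """Punctum-detection settings for one fluorescence channel.

    `diameter_min`/`diameter_max` bound the equivalent diameter of a
    detected object (inclusive), in `units` ("px" or "um").  The intensity
    threshold is ``mean + k * sd`` of negative-control non-nuclear pixels
    unless `fixed_threshold` is set.
    """

    diameter_min: float
    diameter_max: float
    units: str = "px"
    k: float = 3.0
    fixed_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.diameter_min > self.diameter_max:
            raise ValueError(
                f"diameter window min {self.diameter_min} > max "
                f"{self.diameter_max}"
            )
        if self.diameter_min < 0:
            raise ValueError("diameters must be non-negative")
        if self.units not in ("px", "um"):
            raise ValueError(f"units must be 'px' or 'um', got {self.units!r}")

    def diameter_window_px(self, pixel_size_um: float) -> tuple[float, float]:
        """The diameter window converted to pixels."""
        if self.units == "px":
            return (self.diameter_min, self.diameter_max)
        return (self.diameter_min / pixel_size_um,
                self.diameter_max / pixel_size_um)


@dataclass
class SegmentationParams:
    """Nucleus segmentation and filtering settings."""

    size_min: float = 150.0
    size_max: float = 600.0
    #: Whether the size window refers to equivalent diameter ("diameter")
    #: or object area ("area"), both in pixel units.
    size_interpretation: str = "diameter"
    form_factor_min: float = 0.7
    form_factor_max: float = 1.0
    smoothing_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.size_min > self.size_max:
            raise ValueError("size window min > max")
        if self.form_factor_min > self.form_factor_max:
            raise ValueError("form-factor window min > max")
        if self.size_interpretation not in ("diameter", "area"):
            raise ValueError(
                "size_interpretation must be 'diameter' or 'area'"
            )
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


@dataclass
class RunConfig:
    """Complete configuration for one quantification run."""

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    channels: dict[str, ChannelParams] = field(default_factory=lambda: {
        "pdna": ChannelParams(4.0, 40.0, units="px"),
        "gal9": ChannelParams(0.5, 2.0, units="um"),
        "sc35": ChannelParams(0.5, 3.0, units="um"),
    })
    #: Edge band thickness as a fraction of the maximum interior
    #: boundary distance; the remainder is the inner region.
    edge_fraction: float = 0.2
    #: Minimum overlap fraction of the Gal9 punctum area for a
    #: colocalization call (inclusive).
    coloc_threshold: float = 0.30
    #: Apply the 2-SD outlier rule before group comparisons.
    exclude_outliers: bool = True
    #: Nucleus labels to drop per source image (stands in for the
    #: manual out-of-focus exclusions of the original workflow).
    exclusion_list: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not 0 <= self.edge_fraction < 1:
            raise ValueError("edge_fraction must be in [0, 1)")
        if not 0 <= self.coloc_threshold <= 1:
            raise ValueError("coloc_threshold must be in [0, 1]")


def _build(cls, data: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML, filling unset fields with the
    published defaults.  Unknown keys raise, so typos fail loudly.

    `path` may be ``None`` for an all-defaults configuration.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw)}")
    data = dict(raw)
    if "segmentation" in data:
        data["segmentation"] = _build(
            SegmentationParams, data["segmentation"], "segmentation")
    if "channels" in data:
        channels = RunConfig().channels  # start from the printed defaults
        for role, params in data["channels"].items():
            channels[role] = _build(ChannelParams, params, f"channels.{role}")
        data["channels"] = channels
    return _build(RunConfig, data, "config")
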