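"""Punctum detection with negative-control-calibrated thresholds.

The original workflow set intensity thresholds manually from
untransfected control samples.  Here that step is made reproducible:
the background model is the mean and population SD of non-nuclear
pixels pooled over negative-control stacks, and the detection threshold
is ``mean + k * sd`` (k = 3 by default; a fixed manual threshold can be
configured instead).  Detection thresholds the raw plane at the model
threshold, labels 8-connected components, and keeps components whose
equivalent diameter falls in the channel's (inclusive) size window and
whose mean raw intensity exceeds the threshold.  Each punctum is
assigned to a nucleus region (edge / inner / cytoplasm) by its
centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from nucleopunct.config import ChannelParams, RunConfig
from nucleopunct.segmentation import NucleusRecord
from nucleopunct.stack import ChannelStack


@dataclass
class BackgroundModel:
    """Background statistics for one channel, from negative controls."""

    channel: str
    mean: float
    sd: float
    k: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def threshold(self) -> float:
        return self.mean + self.k * self.sd


@dataclass
class Punctum:
    """One detected punctum."""

    id: int
    channel: str
    bbox: tuple[int, int, int, int]
    mask: np.ndarray                  # bool, local to bbox
    centroid: tuple[float, float]     # global (row, col)
    area_px: int
    equiv_diameter_px: float
    equiv_diameter_um: float
    mean_intensity: float
    nucleus_label: int | None = None
    region: str = "cytoplasm"

    def full_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Global (rows, cols) of the punctum's pixels."""
        rr, cc = np.nonzero(self.mask)
        return rr + self.bbox[0], cc + self.bbox[1]


def _nuclear_mask(stack: ChannelStack) -> np.ndarray:
    """Rough nuclear mask from the Hoechst plane (Otsu), used only to
    exclude nuclear pixels from background pooling."""
    plane = np.asarray(stack.plane("hoechst"), float)
    if np.ptp(plane) == 0:
        return np.zeros(plane.shape, bool)
    return plane > threshold_otsu(plane)


def estimate_background(
    controls: list[ChannelStack], channel: str, k: float = 3.0
) -> BackgroundModel:
    """Pool non-nuclear pixels of `channel` over negative-control stacks
    and return mean, population SD and the ``mean + k*sd`` threshold."""
    if not controls:
        raise ValueError("need at least one negative-control stack")
    values = []
    for stack in controls:
        if not stack.has_role(channel):
            raise KeyError(f"control stack lacks channel {channel!r}")
        plane = np.asarray(stack.plane(channel), float)
        keep = ~_nuclear_mask(stack) if stack.has_role("hoechst") \
            else np.ones(plane.shape, bool)
        values.append(plane[keep])
    pooled = np.concatenate(values)
    return BackgroundModel(
        channel=channel,
        mean=float(pooled.mean()),
        sd=float(pooled.std()),   # population SD: calibration, not inference
        k=float(k),
    )


def subtract_background(plane: np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Pixelwise ``max(plane - model.mean, 0)``."""
    return np.maximum(np.asarray(plane, float) - model.mean, 0.0)


def detect_puncta(
    plane: np.ndarray,
    channel: str,
    params: ChannelParams,
    model: BackgroundModel,
    nuclei: list[NucleusRecord] | None = None,
    pixel_size_um: float = 1.0,
) -> list[Punctum]:
    """Detect puncta on a raw channel plane.

    Pixels strictly above the model threshold (fixed threshold when the
    channel config sets one) form candidate components; components are
    kept when their equivalent diameter lies inside the channel window
    (inclusive, after unit conversion) and their mean raw intensity
    exceeds the threshold.  When `nuclei` are given, each punctum is
    assigned to a nucleus and region by its centroid.
    """
    plane = np.asarray(plane, float)
    thr = params.fixed_threshold if params.fixed_threshold is not None \
        else model.threshold
    binary = plane > thr
    if not binary.any():
        return []
    labels, _ = ndimage.label(binary, structure=np.ones((3, 3), int))
    d_min, d_max = params.diameter_window_px(pixel_size_um)
    out: list[Punctum] = []
    next_id = 1
    for rp in measure.regionprops(labels, intensity_image=plane):
        d = float(rp.equivalent_diameter_area)
        if not d_min <= d <= d_max:
            continue
        if not rp.intensity_mean > thr:
            continue
        p = Punctum(
            id=next_id,
            channel=channel,
            bbox=tuple(rp.bbox),
            mask=rp.image,
            centroid=tuple(rp.centroid),
            area_px=int(rp.area),
            equiv_diameter_px=d,
            equiv_diameter_um=d * pixel_size_um,
            mean_intensity=float(rp.intensity_mean),
        )
        if nuclei is not None:
            assign_region(p, nuclei)
        out.append(p)
        next_id += 1
    return out


def assign_region(punctum: Punctum, nuclei: list[NucleusRecord]) -> str:
    """Assign a punctum to edge / inner / cytoplasm by its centroid.

    The edge and inner sets of each nucleus are disjoint, so the
    assignment is unambiguous.  Centroids outside every retained nucleus
    are cytoplasmic with no nucleus label.
    """
    row, col = punctum.centroid
    for nuc in nuclei:
        if not nuc.retained:
            continue
        p = nuc.local_point(row, col)
        if p is None or not nuc.mask[p]:
            continue
        punctum.nucleus_label = nuc.label
        if nuc.inner_mask is not None and nuc.inner_mask[p]:
            punctum.region = "inner"
        else:
            punctum.region = "edge"
        return punctum.region
    punctum.nucleus_label = None
    punctum.region = "cytoplasm"
    return punctum.region


def puncta_table(puncta: list[Punctum], source_id: str = "") -> list[dict]:
    """Flatten puncta into rows for the per-punctum CSV."""
    return [{
        "source_id": source_id,
        "punctum_id": p.id,
        "channel": p.channel,
        "centroid_row": p.centroid[0],
        "centroid_col": p.centroid[1],
        "area_px": p.area_px,
        "equiv_diameter_px": p.equiv_diameter_px,
        "equiv_diameter_um": p.equiv_diameter_um,
        "mean_intensity": p.mean_intensity,
        "nucleus_label": p.nucleus_label,
        "region": p.region,
    } for p in puncta]
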