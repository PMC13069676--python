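"""Synthetic fluorescence scenes and flow tables with exact ground truth.

Scenes emulate the structure of the real experiments: elliptical nuclei
(Hoechst channel) containing punctate Gal9, pDNA and SC35 signals with
controlled sizes, edge/inner placement, and controlled pairwise
Gal9-pDNA and Gal9-SC35 colocalization fractions.  Objects are rendered
as hard disks / filled ellipses, blurred by a Gaussian PSF, and offset
by a constant background plus zero-mean Gaussian read noise.  Geometry
stays analytic, so every downstream measurement can be checked against
the planted truth.

Flow tables emulate a transfected sample: a log-normal negative
(autofluorescence) population and a log-normal positive population
mixed at a known positive fraction, with scatter channels and a
viability flag.

All randomness flows through one `numpy` Generator seeded from the
mandatory `seed` parameter, so identical parameters give bit-identical
output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.optimize import brentq

from nucleopunct.stack import CHANNEL_ROLES, ChannelStack

#: Attempts per object before placement is declared infeasible.
MAX_PLACEMENT_ATTEMPTS = 10_000


class ScenePlacementError(RuntimeError):
    """Requested objects cannot be placed without overlap — the scene is
    over-crowded for rejection sampling."""


@dataclass
class SceneParams:
    """Parameters of one synthetic scene.

    Defaults describe the reference imaging conditions: a 2048 x 2048
    field at 0.048 um/px holding 10 well-separated nuclei of 8-14 um
    diameter, ~12 Gal9 and pDNA puncta and ~8 SC35 puncta per nucleus
    (Poisson counts), punctum peak signal 20x the noise SD above
    background, and a 1.5 px Gaussian PSF.
    """

    image_shape: tuple[int, int] = (2048, 2048)
    pixel_size_um: float = 0.048
    n_nuclei: int = 10
    nucleus_diameter_um_range: tuple[float, float] = (10.0, 16.0)
    nucleus_axis_ratio_range: tuple[float, float] = (1.0, 1.5)
    puncta_per_nucleus: dict[str, float] = field(default_factory=lambda: {
        "gal9": 12.0, "pdna": 12.0, "sc35": 6.0})
    punctum_diameter_um: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "gal9": (0.6, 1.2), "pdna": (0.3, 0.9), "sc35": (0.8, 1.6)})
    coloc_fraction_gal9_pdna: float = 0.3
    coloc_fraction_gal9_sc35: float = 0.3
    edge_placement_fraction: float = 0.3
    ring_edge_fraction: float = 0.2
    nucleus_intensity: float = 300.0
    punctum_intensity: float = 200.0
    background_level: float = 100.0
    noise_sd: float = 10.0
    psf_sigma_px: float = 1.5
    spot_profile: str = "disk"      # "disk" or "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coloc_fraction_gal9_pdna", "coloc_fraction_gal9_sc35",
                     "edge_placement_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.ring_edge_fraction < 1:
            raise ValueError("ring_edge_fraction must be in [0, 1)")
        for name in ("nucleus_diameter_um_range",):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"invalid range {name}: ({lo}, {hi})")
        lo, hi = self.nucleus_axis_ratio_range
        if lo < 1 or lo > hi:
            raise ValueError("axis ratio range must satisfy 1 <= min <= max")
        for ch, (lo, hi) in self.punctum_diameter_um.items():
            if lo > hi or lo <= 0:
                raise ValueError(f"invalid diameter range for {ch}")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.noise_sd < 0 or self.psf_sigma_px < 0:
            raise ValueError("noise_sd and psf_sigma_px must be >= 0")
        if self.spot_profile not in ("disk", "gaussian"):
            raise ValueError("spot_profile must be 'disk' or 'gaussian'")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TrueNucleus:
    label: int
    center: tuple[float, float]           # (row, col)
    axes: tuple[float, float]             # semi-axes (a, b) px, a >= b
    orientation: float                    # radians
    form_factor: float                    # analytic 4*pi*A/P^2 (Ramanujan P)


@dataclass
class TruePunctum:
    index: int
    channel: str
    center: tuple[float, float]
    diameter_px: float
    nucleus_label: int | None
    region: str                           # edge | inner | cytoplasm


@dataclass
class ColocPair:
    gal9_index: int
    partner_channel: str
    partner_index: int
    planted_overlap: float


@dataclass
class SceneTruth:
    """Exact ground truth of one synthetic scene."""

    nuclei: list[TrueNucleus]
    puncta: list[TruePunctum]
    coloc_pairs: list[ColocPair]
    pixel_size_um: float
    image_shape: tuple[int, int]

    def puncta_of(self, channel: str) -> list[TruePunctum]:
        return [p for p in self.puncta if p.channel == channel]

    def to_json(self, path: str | Path) -> None:
        data = {
            "pixel_size_um": self.pixel_size_um,
            "image_shape": list(self.image_shape),
            "nuclei": [asdict(n) for n in self.nuclei],
            "puncta": [asdict(p) for p in self.puncta],
            "coloc_pairs": [asdict(c) for c in self.coloc_pairs],
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            nuclei=[TrueNucleus(**{**n,
                                   "center": tuple(n["center"]),
                                   "axes": tuple(n["axes"])})
                    for n in data["nuclei"]],
            puncta=[TruePunctum(**{**p, "center": tuple(p["center"])})
                    for p in data["puncta"]],
            coloc_pairs=[ColocPair(**c) for c in data["coloc_pairs"]],
            pixel_size_um=data["pixel_size_um"],
            image_shape=tuple(data["image_shape"]),
        )


# ---------------------------------------------------------------------------
# analytic disk geometry

def lens_area(r1: float, r2: float, d: float) -> float:
    """Area of intersection of two disks of radii r1, r2 with centre
    distance d (the circle-circle 'lens')."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    a1 = r1 * r1 * math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    k = 0.5 * math.sqrt(max(0.0, (-d + r1 + r2) * (d + r1 - r2)
                            * (d - r1 + r2) * (d + r1 + r2)))
    return a1 + a2 - k


def disk_overlap_fraction(r1: float, r2: float, d: float) -> float:
    """Analytic overlap of disk 2 with disk 1, as a fraction of disk 1's
    area."""
    return lens_area(r1, r2, d) / (math.pi * r1 * r1)


def offset_for_overlap(r1: float, r2: float, target: float) -> float:
    """Centre distance d at which disk 2 covers `target` of disk 1's
    area.  Requires target <= min(1, (r2/r1)^2)."""
    if not 0 < target <= 1:
        raise ValueError("target overlap must be in (0, 1]")
    if disk_overlap_fraction(r1, r2, 0.0) < target:
        raise ValueError("target overlap unreachable for these radii")
    f = lambda d: disk_overlap_fraction(r1, r2, d) - target
    if f(abs(r1 - r2)) >= 0 and abs(r1 - r2) > 0:
        lo = abs(r1 - r2)
    else:
        lo = 0.0
    if f(lo) <= 0:
        return lo
    return brentq(f, lo, r1 + r2)


def ellipse_form_factor(a: float, b: float) -> float:
    """Analytic 4*pi*A/P^2 of an ellipse with semi-axes a, b, using
    Ramanujan's perimeter approximation."""
    h = ((a - b) / (a + b)) ** 2 if a + b > 0 else 0.0
    p = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
    return 4 * math.pi * (math.pi * a * b) / p**2


def ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                 axes: tuple[float, float], orientation: float) -> np.ndarray:
    """Rasterize a filled rotated ellipse (pixel-centre inclusion test)."""
    a, b = axes
    cr, cc = center
    reach = max(a, b) + 1
    r0 = max(0, int(cr - reach)); r1 = min(shape[0], int(cr + reach) + 2)
    c0 = max(0, int(cc - reach)); c1 = min(shape[1], int(cc + reach) + 2)
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    dr = rr - cr
    dc = cc_grid - cc
    cos, sin = math.cos(orientation), math.sin(orientation)
    u = dr * cos + dc * sin
    v = -dr * sin + dc * cos
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    out = np.zeros(shape, bool)
    out[r0:r1, c0:c1] = inside
    return out


def disk_mask(shape: tuple[int, int], center: tuple[float, float],
              radius: float) -> np.ndarray:
    """Rasterize a filled disk (pixel-centre inclusion test)."""
    return ellipse_mask(shape, center, (radius, radius), 0.0)


# ---------------------------------------------------------------------------
# placement

def _place_nuclei(params: SceneParams, rng: np.random.Generator
                  ) -> list[TrueNucleus]:
    shape = params.image_shape
    d_lo, d_hi = params.nucleus_diameter_um_range
    q_lo, q_hi = params.nucleus_axis_ratio_range
    placed: list[tuple[float, float, float]] = []   # (row, col, bounding r)
    nuclei = []
    for label in range(1, params.n_nuclei + 1):
        d_px = rng.uniform(d_lo, d_hi) / params.pixel_size_um
        q = rng.uniform(q_lo, q_hi)
        # semi-axes chosen so the equivalent diameter equals d_px
        a = 0.5 * d_px * math.sqrt(q)
        b = 0.5 * d_px / math.sqrt(q)
        theta = rng.uniform(0, math.pi)
        reach = a + 2.0                     # keep off the border
        ok = False
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            cr = rng.uniform(reach, shape[0] - reach)
            cc = rng.uniform(reach, shape[1] - reach)
            if all(math.hypot(cr - pr, cc - pc) > reach + pr_reach + 4
                   for pr, pc, pr_reach in placed):
                ok = True
                break
        if not ok:
            raise ScenePlacementError(
                f"could not place nucleus {label} of {params.n_nuclei} "
                f"after {MAX_PLACEMENT_ATTEMPTS} attempts"
            )
        placed.append((cr, cc, reach))
        nuclei.append(TrueNucleus(
            label=label, center=(cr, cc), axes=(a, b), orientation=theta,
            form_factor=ellipse_form_factor(a, b)))
    return nuclei


def _region_pixel_lists(mask: np.ndarray, bbox_offset: tuple[int, int],
                        edge_fraction: float
                        ) -> dict[str, np.ndarray]:
    """(row, col) arrays of the edge and inner pixels of a nucleus mask,
    in global coordinates, using the same distance-to-boundary rule as
    the measurement pipeline."""
    padded = np.pad(mask, 1)
    dist = distance_transform_edt(padded)[1:-1, 1:-1]
    inner = mask & (dist > edge_fraction * dist.max())
    edge = mask & ~inner
    out = {}
    for name, m in (("edge", edge), ("inner", inner)):
        rr, cc = np.nonzero(m)
        out[name] = np.stack(
            [rr + bbox_offset[0], cc + bbox_offset[1]], axis=1)
    return out


def _pixel_overlap(c1: tuple[float, float], r1: float,
                   c2: tuple[float, float], r2: float) -> float:
    """Pixelwise overlap of disk 2 with disk 1 on a local grid."""
    reach = int(math.ceil(max(r1, r2) + abs(c1[0] - c2[0])
                          + abs(c1[1] - c2[1]))) + 2
    # grid aligned to integer pixel centres, as in full-frame rasterization
    f1 = (c1[0] - math.floor(c1[0]), c1[1] - math.floor(c1[1]))
    f2 = (c2[0] - math.floor(c1[0]), c2[1] - math.floor(c1[1]))
    rr, cc = np.mgrid[-reach:reach + 1, -reach:reach + 1]
    m1 = (rr - f1[0]) ** 2 + (cc - f1[1]) ** 2 <= r1 * r1
    m2 = (rr - f2[0]) ** 2 + (cc - f2[1]) ** 2 <= r2 * r2
    n1 = int(m1.sum())
    return float((m1 & m2).sum()) / n1 if n1 else 0.0


def _separated(center: tuple[float, float], radius: float,
               others: list[tuple[float, float, float]], gap: float) -> bool:
    return all(math.hypot(center[0] - r, center[1] - c) > radius + rad + gap
               for r, c, rad in others)


def _place_puncta(params: SceneParams, nuclei: list[TrueNucleus],
                  rng: np.random.Generator
                  ) -> tuple[list[TruePunctum], list[ColocPair]]:
    shape = params.image_shape
    px = params.pixel_size_um
    # gap keeping blurred masks of distinct objects apart: the blurred
    # edge of a disk crosses a 3-sigma noise threshold ~1 PSF sigma
    # outside the disk, so 2 sigma + 3 px of clearance separates masks
    gap = 2.0 * params.psf_sigma_px + 3.0
    # punctum counts scale with nucleus area, normalized to the
    # configured per-nucleus means at the mid-range diameter
    mean_d_px = 0.5 * sum(params.nucleus_diameter_um_range) / px
    puncta: list[TruePunctum] = []
    pairs: list[ColocPair] = []

    region_lists = {}
    for nuc in nuclei:
        mask = ellipse_mask(shape, nuc.center, nuc.axes, nuc.orientation)
        rr, cc = np.nonzero(mask)
        r0, c0 = rr.min(), cc.min()
        local = mask[r0:rr.max() + 1, c0:cc.max() + 1]
        region_lists[nuc.label] = _region_pixel_lists(
            local, (r0, c0), params.ring_edge_fraction)

    def sample_center(nucleus: TrueNucleus, radius: float,
                      blocked: list[tuple[float, float, float]],
                      ) -> tuple[tuple[float, float], str]:
        lists = region_lists[nucleus.label]
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            region = "edge" if rng.random() < params.edge_placement_fraction \
                else "inner"
            pool = lists[region]
            if len(pool) == 0:
                region = "inner" if region == "edge" else "edge"
                pool = lists[region]
                if len(pool) == 0:
                    break
            row, col = pool[rng.integers(len(pool))]
            center = (float(row), float(col))
            if not (radius + 1 <= row < shape[0] - radius - 1
                    and radius + 1 <= col < shape[1] - radius - 1):
                continue
            if _separated(center, radius, blocked, gap):
                return center, region
        raise ScenePlacementError(
            f"could not place punctum in nucleus {nucleus.label} after "
            f"{MAX_PLACEMENT_ATTEMPTS} attempts"
        )

    for nuc in nuclei:
        area_factor = 4.0 * nuc.axes[0] * nuc.axes[1] / mean_d_px**2
        # --- Gal9 reference puncta
        n_gal9 = int(rng.poisson(
            area_factor * params.puncta_per_nucleus.get("gal9", 0.0)))
        gal9_here: list[TruePunctum] = []
        gal9_blocked: list[tuple[float, float, float]] = []
        d_lo, d_hi = params.punctum_diameter_um["gal9"]
        for _ in range(n_gal9):
            radius = 0.5 * rng.uniform(d_lo, d_hi) / px
            center, region = sample_center(nuc, radius, gal9_blocked)
            p = TruePunctum(index=len(puncta), channel="gal9", center=center,
                            diameter_px=2 * radius,
                            nucleus_label=nuc.label, region=region)
            puncta.append(p)
            gal9_here.append(p)
            gal9_blocked.append((center[0], center[1], radius))

        # --- partner channels: planted colocalization + independent puncta
        for channel, coloc_fraction in (
                ("pdna", params.coloc_fraction_gal9_pdna),
                ("sc35", params.coloc_fraction_gal9_sc35)):
            mean = params.puncta_per_nucleus.get(channel, 0.0)
            if mean == 0 and coloc_fraction == 0:
                continue
            n_total = int(rng.poisson(area_factor * mean))
            n_pairs = int(round(coloc_fraction * len(gal9_here)))
            chosen = rng.choice(len(gal9_here), size=n_pairs, replace=False) \
                if n_pairs else np.array([], int)
            d_lo, d_hi = params.punctum_diameter_um[channel]
            partner_blocked: list[tuple[float, float, float]] = []
            for gi in chosen:
                g = gal9_here[int(gi)]
                r_g = g.diameter_px / 2
                r_p = 0.5 * rng.uniform(d_lo, d_hi) / px
                target = rng.uniform(0.6, 0.9)
                if disk_overlap_fraction(r_g, r_p, 0.0) < target:
                    r_p = r_g      # guarantee the target is reachable
                dist = offset_for_overlap(r_g, r_p, target)
                # pick an offset direction that keeps the partner clear
                # of previously placed same-channel puncta if possible
                angle = rng.uniform(0, 2 * math.pi)
                for _ in range(32):
                    cand = (g.center[0] + dist * math.sin(angle),
                            g.center[1] + dist * math.cos(angle))
                    if _separated(cand, r_p, partner_blocked, gap):
                        break
                    angle = rng.uniform(0, 2 * math.pi)
                # back off the analytic offset until the rasterized
                # overlap also meets the planted fraction
                while dist > 0 and _pixel_overlap(
                        g.center, r_g,
                        (g.center[0] + dist * math.sin(angle),
                         g.center[1] + dist * math.cos(angle)),
                        r_p) < target:
                    dist = max(0.0, dist - 0.5)
                center = (g.center[0] + dist * math.sin(angle),
                          g.center[1] + dist * math.cos(angle))
                region = _locate_region(center, nuc, region_lists)
                p = TruePunctum(index=len(puncta), channel=channel,
                                center=center, diameter_px=2 * r_p,
                                nucleus_label=nuc.label, region=region)
                puncta.append(p)
                partner_blocked.append((center[0], center[1], r_p))
                pairs.append(ColocPair(
                    gal9_index=g.index, partner_channel=channel,
                    partner_index=p.index, planted_overlap=target))
            for _ in range(max(0, n_total - n_pairs)):
                radius = 0.5 * rng.uniform(d_lo, d_hi) / px
                center, region = sample_center(
                    nuc, radius, gal9_blocked + partner_blocked)
                p = TruePunctum(index=len(puncta), channel=channel,
                                center=center, diameter_px=2 * radius,
                                nucleus_label=nuc.label, region=region)
                puncta.append(p)
                partner_blocked.append((center[0], center[1], radius))
    return puncta, pairs


def _locate_region(center: tuple[float, float], nucleus: TrueNucleus,
                   region_lists: dict[int, dict[str, np.ndarray]]) -> str:
    row, col = int(round(center[0])), int(round(center[1]))
    for name in ("inner", "edge"):
        pool = region_lists[nucleus.label][name]
        if len(pool) and np.any((pool[:, 0] == row) & (pool[:, 1] == col)):
            return name
    return "cytoplasm"


# ---------------------------------------------------------------------------
# rendering

def _render(params: SceneParams, nuclei: list[TrueNucleus],
            puncta: list[TruePunctum], rng: np.random.Generator,
            source_id: str) -> ChannelStack:
    shape = params.image_shape
    planes = {role: np.zeros(shape, float) for role in CHANNEL_ROLES}
    for nuc in nuclei:
        mask = ellipse_mask(shape, nuc.center, nuc.axes, nuc.orientation)
        planes["hoechst"][mask] += params.nucleus_intensity
    for p in puncta:
        r = p.diameter_px / 2
        if params.spot_profile == "disk":
            planes[p.channel][disk_mask(shape, p.center, r)] += \
                params.punctum_intensity
        else:
            sigma = r / 2
            reach = int(math.ceil(3 * sigma)) + 1
            r0 = max(0, int(p.center[0]) - reach)
            r1 = min(shape[0], int(p.center[0]) + reach + 1)
            c0 = max(0, int(p.center[1]) - reach)
            c1 = min(shape[1], int(p.center[1]) + reach + 1)
            rr, cc = np.mgrid[r0:r1, c0:c1]
            planes[p.channel][r0:r1, c0:c1] += params.punctum_intensity * \
                np.exp(-((rr - p.center[0]) ** 2 + (cc - p.center[1]) ** 2)
                       / (2 * sigma ** 2))
    out = []
    for role in CHANNEL_ROLES:
        plane = planes[role]
        if params.psf_sigma_px > 0:
            plane = gaussian_filter(plane, params.psf_sigma_px)
        plane = plane + params.background_level
        if params.noise_sd > 0:
            plane = plane + rng.normal(0.0, params.noise_sd, size=shape)
        out.append(plane)
    return ChannelStack(
        planes=out,
        roles={role: i for i, role in enumerate(CHANNEL_ROLES)},
        pixel_size_um=params.pixel_size_um,
        source_id=source_id,
    )


def generate_scene(params: SceneParams
                   ) -> tuple[ChannelStack, SceneTruth]:
    """Generate one synthetic 4-channel scene and its exact truth.

    Channel order is (hoechst, gal9, sc35, pdna); roles are also in the
    stack metadata.  Every planted colocalization pair overlaps its Gal9
    punctum by at least the recorded planted fraction on the pre-blur
    disk masks.  Deterministic given `params.seed`.
    """
    rng = np.random.default_rng(params.seed)
    nuclei = _place_nuclei(params, rng)
    puncta, pairs = _place_puncta(params, nuclei, rng)
    stack = _render(params, nuclei, puncta, rng,
                    source_id=f"scene-seed{params.seed}")
    truth = SceneTruth(nuclei=nuclei, puncta=puncta, coloc_pairs=pairs,
                       pixel_size_um=params.pixel_size_um,
                       image_shape=params.image_shape)
    return stack, truth


def generate_negative_control(params: SceneParams) -> ChannelStack:
    """A matched negative control: nuclei only, with the same background
    and noise model but no puncta in the gal9/sc35/pdna channels."""
    rng = np.random.default_rng(params.seed)
    nuclei = _place_nuclei(params, rng)
    return _render(params, nuclei, [], rng,
                   source_id=f"control-seed{params.seed}")


# ---------------------------------------------------------------------------
# flow cytometry

@dataclass
class FlowSimParams:
    """Parameters of a simulated flow-cytometry event table.

    Green fluorescence is a two-component log-normal mixture: an
    autofluorescent negative population and a reporter-positive
    population mixed at `positive_fraction`.  Defaults put the
    populations ~two decades apart, as for a bright EGFP reporter.
    """

    n_events: int = 10_000
    positive_fraction: float = 0.4
    neg_logmean: float = math.log(100.0)
    neg_logsd: float = 0.5
    pos_logmean: float = math.log(10_000.0)
    pos_logsd: float = 0.8
    viability: float = 0.9
    fsc_mean: float = 50_000.0
    fsc_sd: float = 8_000.0
    ssc_mean: float = 30_000.0
    ssc_sd: float = 6_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must be in [0, 1]")
        if not 0 <= self.viability <= 1:
            raise ValueError("viability must be in [0, 1]")
        if self.neg_logsd <= 0 or self.pos_logsd <= 0:
            raise ValueError("log-SDs must be > 0")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")


def generate_flow_table(params: FlowSimParams) -> pd.DataFrame:
    """One row per event: fsc, ssc, green, live (0/1), is_positive
    (ground-truth component label).  Deterministic given `params.seed`."""
    rng = np.random.default_rng(params.seed)
    n = params.n_events
    positive = rng.random(n) < params.positive_fraction
    log_green = np.where(
        positive,
        rng.normal(params.pos_logmean, params.pos_logsd, n),
        rng.normal(params.neg_logmean, params.neg_logsd, n),
    )
    return pd.DataFrame({
        "fsc": rng.normal(params.fsc_mean, params.fsc_sd, n),
        "ssc": rng.normal(params.ssc_mean, params.ssc_sd, n),
        "green": np.exp(log_green),
        "live": (rng.random(n) < params.viability).astype(int),
        "is_positive": positive.astype(int),
    })
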