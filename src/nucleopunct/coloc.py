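"""Object-based colocalization of Gal9 puncta with partner signals.

A Gal9 punctum is called colocalized with a partner channel (pDNA or
SC35) when the overlap between the punctum and the partner signal mask
covers at least 30 % of the punctum's own area (inclusive threshold,
configurable).  Gal9 is always the reference object — the denominator
is the Gal9 punctum area — so the score is deliberately asymmetric.

The partner signal is, by default, the thresholded mask of the partner
channel (every pixel above that channel's background threshold); a
stricter punctum-vs-punctum mode that uses only the partner's detected
in-window puncta is available via :func:`puncta_union_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nucleopunct.puncta import BackgroundModel, Punctum
from nucleopunct.segmentation import NucleusRecord


@dataclass
class ColocRecord:
    """Overlap fractions and boolean calls for one Gal9 punctum."""

    gal9_id: int
    nucleus_label: int | None
    overlap_fraction_pdna: float
    overlap_fraction_sc35: float
    coloc_pdna: bool
    coloc_sc35: bool

    @property
    def triple(self) -> bool:
        return self.coloc_pdna and self.coloc_sc35


@dataclass
class NucleusCounts:
    """Per-nucleus punctum and colocalization counts."""

    nucleus_label: int
    counts: dict[str, dict[str, int]]       # channel -> {edge, inner, total}
    n_gal9_coloc_pdna: int = 0
    n_gal9_coloc_sc35: int = 0
    n_triple: int = 0


def overlap_fraction(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|A ∩ B| / |A| for two same-shape boolean masks; A must be
    non-empty."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    n_a = int(a.sum())
    if n_a == 0:
        raise ValueError("reference mask is empty")
    return float(np.count_nonzero(a & b)) / n_a


def punctum_overlap(punctum: Punctum, signal_mask: np.ndarray) -> float:
    """Overlap fraction of a punctum against a full-frame signal mask."""
    r0, c0, r1, c1 = punctum.bbox
    window = signal_mask[r0:r1, c0:c1]
    n_a = int(punctum.mask.sum())
    return float(np.count_nonzero(punctum.mask & window)) / n_a


def threshold_mask(plane: np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Partner 'signal' mask: raw pixels strictly above the channel's
    background threshold."""
    return np.asarray(plane, float) > model.threshold


def puncta_union_mask(
    puncta: list[Punctum], shape: tuple[int, int]
) -> np.ndarray:
    """Union of detected punctum masks — the stricter partner mask for
    punctum-vs-punctum colocalization."""
    out = np.zeros(shape, bool)
    for p in puncta:
        rr, cc = p.full_coords()
        out[rr, cc] = True
    return out


def score_colocalization(
    gal9_puncta: list[Punctum],
    partner_mask: np.ndarray,
    threshold: float = 0.30,
) -> list[tuple[int, float, bool]]:
    """Score each Gal9 punctum against a partner signal mask.

    Returns (punctum id, overlap fraction, fraction >= threshold) per
    punctum.  The threshold is inclusive: exactly 30 % overlap is a
    positive call.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    out = []
    for p in gal9_puncta:
        f = punctum_overlap(p, partner_mask)
        out.append((p.id, f, f >= threshold))
    return out


def build_coloc_records(
    gal9_puncta: list[Punctum],
    pdna_mask: np.ndarray | None,
    sc35_mask: np.ndarray | None,
    threshold: float = 0.30,
) -> list[ColocRecord]:
    """One :class:`ColocRecord` per Gal9 punctum; channels whose partner
    mask is absent score 0 overlap."""
    records = []
    for p in gal9_puncta:
        f_pdna = punctum_overlap(p, pdna_mask) if pdna_mask is not None else 0.0
        f_sc35 = punctum_overlap(p, sc35_mask) if sc35_mask is not None else 0.0
        records.append(ColocRecord(
            gal9_id=p.id,
            nucleus_label=p.nucleus_label,
            overlap_fraction_pdna=f_pdna,
            overlap_fraction_sc35=f_sc35,
            coloc_pdna=f_pdna >= threshold,
            coloc_sc35=f_sc35 >= threshold,
        ))
    return records


def per_nucleus_counts(
    nuclei: list[NucleusRecord],
    puncta_by_channel: dict[str, list[Punctum]],
    coloc_records: list[ColocRecord],
) -> list[NucleusCounts]:
    """Per-nucleus edge/inner/total punctum counts and colocalization
    counts, over retained nuclei only."""
    coloc_by_nucleus: dict[int, list[ColocRecord]] = {}
    for rec in coloc_records:
        if rec.nucleus_label is not None:
            coloc_by_nucleus.setdefault(rec.nucleus_label, []).append(rec)
    out = []
    for nuc in nuclei:
        if not nuc.retained:
            continue
        counts: dict[str, dict[str, int]] = {}
        for channel, puncta in puncta_by_channel.items():
            edge = sum(1 for p in puncta
                       if p.nucleus_label == nuc.label and p.region == "edge")
            inner = sum(1 for p in puncta
                        if p.nucleus_label == nuc.label and p.region == "inner")
            counts[channel] = {"edge": edge, "inner": inner,
                               "total": edge + inner}
        recs = coloc_by_nucleus.get(nuc.label, [])
        out.append(NucleusCounts(
            nucleus_label=nuc.label,
            counts=counts,
            n_gal9_coloc_pdna=sum(r.coloc_pdna for r in recs),
            n_gal9_coloc_sc35=sum(r.coloc_sc35 for r in recs),
            n_triple=sum(r.triple for r in recs),
        ))
    return out


def per_cell_coloc_fractions(
    counts: list[NucleusCounts], partner: str = "pdna"
) -> tuple[list[float], int]:
    """Per-cell colocalized-punctum fractions (n coloc Gal9 / n Gal9).

    Cells with zero Gal9 puncta cannot contribute a fraction; they are
    skipped and returned as a QC count alongside the fractions.
    """
    attr = {"pdna": "n_gal9_coloc_pdna", "sc35": "n_gal9_coloc_sc35"}[partner]
    fractions, skipped = [], 0
    for nc in counts:
        n_gal9 = nc.counts.get("gal9", {}).get("total", 0)
        if n_gal9 == 0:
            skipped += 1
            continue
        fractions.append(getattr(nc, attr) / n_gal9)
    return fractions, skipped


def coloc_fraction_summary(
    groups: dict[str, list[float]]
) -> pd.DataFrame:
    """Mean ± SEM of the per-cell colocalized fraction per group.

    Input maps group label (condition or time point) to the per-cell
    fractions from :func:`per_cell_coloc_fractions`.  Groups with no
    eligible cells report n = 0 and blank mean/SEM.  Secondary metric:
    the fraction of cells with at least one colocalized punctum.
    """
    rows = []
    for label, values in groups.items():
        n = len(values)
        if n == 0:
            rows.append({"group": label, "mean_fraction": np.nan,
                         "sem": np.nan, "n": 0, "any_coloc_fraction": np.nan})
            continue
        arr = np.asarray(values, float)
        sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({
            "group": label,
            "mean_fraction": float(arr.mean()),
            "sem": sem,
            "n": n,
            "any_coloc_fraction": float((arr > 0).mean()),
        })
    return pd.DataFrame(rows)


def counts_table(counts: list[NucleusCounts], source_id: str = "") -> list[dict]:
    """Flatten per-nucleus counts into CSV rows."""
    rows = []
    for nc in counts:
        row = {"source_id": source_id, "nucleus_label": nc.nucleus_label}
        for channel, c in nc.counts.items():
            for region in ("edge", "inner", "total"):
                row[f"{channel}_{region}"] = c[region]
        row["n_gal9_coloc_pdna"] = nc.n_gal9_coloc_pdna
        row["n_gal9_coloc_sc35"] = nc.n_gal9_coloc_sc35
        row["n_triple"] = nc.n_triple
        rows.append(row)
    return rows
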