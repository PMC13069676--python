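"""Flow-cytometry outcome metrics for transfection experiments.

Implements the event-table side of the analysis: rectangular
forward/side-scatter gating, electrotransfection efficiency (eTE, the
percentage of reporter-positive cells within the gated population),
expression level (geometric mean of reporter fluorescence among
positives), apparent expression level (the product of eTE, expression
level and viability), and EdU-histogram cell-cycle fractions.

The positive/negative cut is taken from an untransfected control
sample — by default the 99.5th percentile of its green intensities — or
supplied as a fixed value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def gate_events(table: pd.DataFrame,
                fsc_window: tuple[float, float],
                ssc_window: tuple[float, float]) -> pd.DataFrame:
    """Keep events inside the (inclusive) rectangular scatter windows."""
    for name, (lo, hi) in (("fsc", fsc_window), ("ssc", ssc_window)):
        if lo > hi:
            raise ValueError(f"{name} window min {lo} > max {hi}")
    keep = (
        table["fsc"].between(*fsc_window)
        & table["ssc"].between(*ssc_window)
    )
    return table.loc[keep]


def positive_threshold(control: pd.DataFrame,
                       percentile: float = 99.5) -> float:
    """Positive cut from an untransfected control: the given percentile
    of its green intensities."""
    if control.empty:
        raise ValueError("control table is empty")
    return float(np.percentile(control["green"].to_numpy(), percentile))


def compute_eTE(gated: pd.DataFrame, threshold: float) -> float:
    """Transfection efficiency: percentage of gated events with green
    intensity strictly above the positive threshold."""
    n = len(gated)
    if n == 0:
        raise ValueError("gated table is empty")
    return 100.0 * float((gated["green"] > threshold).sum()) / n


def expression_level(gated: pd.DataFrame, threshold: float) -> float:
    """Geometric mean of green intensity among positive events."""
    pos = gated.loc[gated["green"] > threshold, "green"].to_numpy(float)
    if pos.size == 0:
        raise ValueError("no positive events above the threshold")
    if np.any(pos <= 0):
        raise ValueError("geometric mean undefined for non-positive "
                         "intensities")
    return float(np.exp(np.mean(np.log(pos))))


def viability_fraction(table: pd.DataFrame) -> float:
    """Fraction of live events, from the `live` flag column."""
    if "live" not in table.columns:
        raise KeyError("table has no 'live' column")
    if len(table) == 0:
        raise ValueError("table is empty")
    return float(table["live"].mean())


def apparent_expression(eTE_percent: float, expression: float,
                        viability: float) -> float:
    """Composite outcome ``(eTE/100) * expression_level * viability``.

    eTE enters as a fraction so the result is scale-consistent for fold
    comparisons across samples; report it alongside its three factors.
    """
    if not 0 <= eTE_percent <= 100:
        raise ValueError("eTE must be a percentage in [0, 100]")
    if not 0 <= viability <= 1:
        raise ValueError("viability must be a fraction in [0, 1]")
    return (eTE_percent / 100.0) * expression * viability


def classify_cell_cycle(edu: np.ndarray, low: float, high: float
                        ) -> tuple[float, float, float]:
    """Cell-cycle fractions from an EdU intensity histogram.

    G0/G1: signal <= `low`; early S: (`low`, `high`]; late S: > `high`.
    Returns fractions that sum to 1.
    """
    if low >= high:
        raise ValueError("low threshold must be below high threshold")
    edu = np.asarray(edu, float)
    n = edu.size
    if n == 0:
        raise ValueError("no EdU intensities given")
    g1 = float((edu <= low).sum()) / n
    early_s = float(((edu > low) & (edu <= high)).sum()) / n
    late_s = float((edu > high).sum()) / n
    return g1, early_s, late_s


def sample_metrics(table: pd.DataFrame,
                   fsc_window: tuple[float, float],
                   ssc_window: tuple[float, float],
                   threshold: float,
                   viability: float | None = None) -> dict[str, float]:
    """All outcome metrics for one sample.

    `viability` defaults to the fraction of live-flagged events within
    the gate; pass a scalar when viability was measured separately.
    """
    gated = gate_events(table, fsc_window, ssc_window)
    ete = compute_eTE(gated, threshold)
    expr = expression_level(gated, threshold) if ete > 0 else float("nan")
    if viability is None:
        viability = viability_fraction(gated)
    return {
        "n_gated": float(len(gated)),
        "eTE_percent": ete,
        "expression_level": expr,
        "viability": viability,
        "apparent_expression":
            apparent_expression(ete, expr, viability) if ete > 0 else 0.0,
    }
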