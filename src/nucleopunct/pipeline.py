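"""End-to-end orchestration: images + controls + config -> tables.

`quantify_stack` runs the full measurement chain on one stack:
segment nuclei -> size/shape filter -> edge/inner partition ->
detect puncta per channel against control-calibrated thresholds ->
score Gal9 colocalization -> per-nucleus counts.  `run_quantification`
applies it to a manifest of condition-grouped stacks and writes the
CSV outputs; `run_benchmark` closes the loop on synthetic scenes,
scoring recovery against the planted truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nucleopunct import io as npio
from nucleopunct.coloc import (
    ColocRecord,
    NucleusCounts,
    build_coloc_records,
    counts_table,
    coloc_fraction_summary,
    per_cell_coloc_fractions,
    per_nucleus_counts,
    threshold_mask,
)
from nucleopunct.config import RunConfig, load_config
from nucleopunct.puncta import (
    BackgroundModel,
    Punctum,
    estimate_background,
    puncta_table,
)
from nucleopunct.puncta import detect_puncta
from nucleopunct.segmentation import (
    NucleusRecord,
    filter_nuclei,
    nuclei_table,
    partition_rings,
    segment_nuclei,
)
from nucleopunct.stack import ChannelStack
from nucleopunct.stats import compare_groups, comparisons_table
from nucleopunct.synthetic import (
    SceneParams,
    SceneTruth,
    generate_negative_control,
    generate_scene,
)

log = logging.getLogger("nucleopunct")

PUNCTA_CHANNELS = ("gal9", "pdna", "sc35")


@dataclass
class RunManifest:
    """Inputs of one quantification run."""

    conditions: dict[str, list[Path]]      # condition label -> stack paths
    controls: list[Path]
    config_path: Path | None = None
    output_dir: Path = Path("nucleopunct-out")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("manifest needs at least one condition")
        for label, paths in self.conditions.items():
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(
                        f"condition {label!r}: missing input {p}")
        for p in self.controls:
            if not Path(p).exists():
                raise FileNotFoundError(f"missing control {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        import yaml
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        return cls(
            conditions={k: [base / p for p in v]
                        for k, v in raw["conditions"].items()},
            controls=[base / p for p in raw.get("controls", [])],
            config_path=(base / raw["config"]) if raw.get("config") else None,
            output_dir=base / raw.get("output_dir", "nucleopunct-out"),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class StackResult:
    """Everything measured on one stack."""

    stack: ChannelStack
    nuclei: list[NucleusRecord]
    retained: list[NucleusRecord]
    puncta: dict[str, list[Punctum]]
    coloc_records: list[ColocRecord]
    counts: list[NucleusCounts]

    @property
    def qc(self) -> dict:
        row = {
            "source_id": self.stack.source_id,
            "nuclei_found": len(self.nuclei),
            "nuclei_retained": len(self.retained),
        }
        for ch, ps in self.puncta.items():
            row[f"n_{ch}"] = len(ps)
        row["n_coloc_pdna"] = sum(r.coloc_pdna for r in self.coloc_records)
        row["n_coloc_sc35"] = sum(r.coloc_sc35 for r in self.coloc_records)
        row["n_triple"] = sum(r.triple for r in self.coloc_records)
        return row


def calibrate_backgrounds(
    controls: list[ChannelStack], config: RunConfig
) -> dict[str, BackgroundModel]:
    """Background model per puncta channel present in the controls."""
    models = {}
    for channel in PUNCTA_CHANNELS:
        if all(c.has_role(channel) for c in controls):
            k = config.channels[channel].k if channel in config.channels \
                else 3.0
            models[channel] = estimate_background(controls, channel, k=k)
    return models


def quantify_stack(
    stack: ChannelStack,
    config: RunConfig,
    backgrounds: dict[str, BackgroundModel],
) -> StackResult:
    """Run the full measurement chain on one stack."""
    _, nuclei = segment_nuclei(stack.plane("hoechst"), config)
    excluded = set(config.exclusion_list.get(stack.source_id, []))
    if excluded:
        nuclei = [n for n in nuclei if n.label not in excluded]
    retained = filter_nuclei(nuclei, config)
    for nuc in retained:
        partition_rings(nuc, config.edge_fraction)
    if not retained:
        log.warning("stack %s: zero retained nuclei", stack.source_id)

    puncta: dict[str, list[Punctum]] = {}
    for channel in PUNCTA_CHANNELS:
        if not stack.has_role(channel) or channel not in backgrounds:
            continue
        puncta[channel] = detect_puncta(
            stack.plane(channel), channel, config.channels[channel],
            backgrounds[channel], nuclei=retained,
            pixel_size_um=stack.pixel_size_um)

    gal9 = puncta.get("gal9", [])
    pdna_mask = threshold_mask(stack.plane("pdna"), backgrounds["pdna"]) \
        if stack.has_role("pdna") and "pdna" in backgrounds else None
    sc35_mask = threshold_mask(stack.plane("sc35"), backgrounds["sc35"]) \
        if stack.has_role("sc35") and "sc35" in backgrounds else None
    coloc_records = build_coloc_records(
        gal9, pdna_mask, sc35_mask, threshold=config.coloc_threshold)
    counts = per_nucleus_counts(retained, puncta, coloc_records)
    return StackResult(stack=stack, nuclei=nuclei, retained=retained,
                       puncta=puncta, coloc_records=coloc_records,
                       counts=counts)


def coloc_table(records: list[ColocRecord], source_id: str = "") -> list[dict]:
    return [{
        "source_id": source_id,
        "punctum_id": r.gal9_id,
        "nucleus_label": r.nucleus_label,
        "overlap_fraction_pdna": r.overlap_fraction_pdna,
        "overlap_fraction_sc35": r.overlap_fraction_sc35,
        "coloc_pdna": r.coloc_pdna,
        "coloc_sc35": r.coloc_sc35,
        "triple": r.triple,
    } for r in records]


def run_quantification(manifest: RunManifest) -> dict:
    """Run the whole manifest and write all output tables.

    Layout: one directory per condition holding per-stack nucleus,
    punctum, colocalization and count tables; top-level `report.csv`
    (per-stack QC), `coloc_summary.csv` (per-condition mean ± SEM of
    the per-cell colocalized fraction) and `stats.csv` (group
    comparisons on the per-cell fractions).
    """
    config = load_config(manifest.config_path)
    out_dir = Path(manifest.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    controls = [npio.read_stack(p) for p in manifest.controls]
    backgrounds = calibrate_backgrounds(controls, config)

    qc_rows = []
    fractions_by_condition: dict[str, list[float]] = {}
    skipped_by_condition: dict[str, int] = {}
    for condition, paths in manifest.conditions.items():
        cond_dir = out_dir / condition
        cond_dir.mkdir(parents=True, exist_ok=True)
        fractions_by_condition[condition] = []
        skipped_by_condition[condition] = 0
        for path in paths:
            stack = npio.read_stack(path)
            result = quantify_stack(stack, config, backgrounds)
            sid = stack.source_id
            stem = Path(path).stem
            npio.write_results(pd.DataFrame(
                nuclei_table(result.nuclei, sid)),
                cond_dir / f"{stem}_nuclei.csv")
            all_puncta = [row for ch in sorted(result.puncta)
                          for row in puncta_table(result.puncta[ch], sid)]
            npio.write_results(pd.DataFrame(all_puncta),
                               cond_dir / f"{stem}_puncta.csv")
            npio.write_results(pd.DataFrame(
                coloc_table(result.coloc_records, sid)),
                cond_dir / f"{stem}_coloc.csv")
            npio.write_results(pd.DataFrame(counts_table(result.counts, sid)),
                               cond_dir / f"{stem}_counts.csv")
            fr, skipped = per_cell_coloc_fractions(result.counts, "pdna")
            fractions_by_condition[condition].extend(fr)
            skipped_by_condition[condition] += skipped
            qc = result.qc
            qc["condition"] = condition
            qc_rows.append(qc)
            log.info("stack %s: %d/%d nuclei retained, %s puncta", sid,
                     len(result.retained), len(result.nuclei),
                     {c: len(p) for c, p in result.puncta.items()})

    report = pd.DataFrame(qc_rows)
    npio.write_results(report, out_dir / "report.csv")
    summary = coloc_fraction_summary(fractions_by_condition)
    summary["cells_without_gal9"] = summary["group"].map(skipped_by_condition)
    npio.write_results(summary, out_dir / "coloc_summary.csv", sort_by=["group"])

    stats_result = None
    eligible = {k: v for k, v in fractions_by_condition.items() if len(v) >= 2}
    if len(eligible) >= 2:
        stats_result = compare_groups(eligible,
                                      exclude_outliers=config.exclude_outliers)
        npio.write_results(
            pd.DataFrame(comparisons_table(stats_result["comparisons"])),
            out_dir / "stats.csv", sort_by=["test", "groups"])
    return {
        "report": report,
        "coloc_summary": summary,
        "stats": stats_result,
        "fractions": fractions_by_condition,
    }


# ---------------------------------------------------------------------------
# synthetic benchmark

def match_nuclei(
    truth: SceneTruth, detected: list[NucleusRecord], max_dist: float = 25.0
) -> tuple[int, int, int]:
    """Greedy one-to-one centroid matching of planted vs detected nuclei.

    Returns (n_matched, n_planted, n_detected)."""
    unmatched = list(detected)
    matched = 0
    for nuc in truth.nuclei:
        best, best_d = None, max_dist
        for rec in unmatched:
            d = math.hypot(rec.centroid[0] - nuc.center[0],
                           rec.centroid[1] - nuc.center[1])
            if d < best_d:
                best, best_d = rec, d
        if best is not None:
            matched += 1
            unmatched.remove(best)
    return matched, len(truth.nuclei), len(detected)


def evaluate_scene(
    params: SceneParams, config: RunConfig | None = None
) -> dict:
    """Generate a scene plus matched control, quantify it, and score
    recovery against the planted truth."""
    if config is None:
        config = RunConfig(pixel_size_um=params.pixel_size_um)
    stack, truth = generate_scene(params)
    control = generate_negative_control(params)
    backgrounds = calibrate_backgrounds([control], config)
    result = quantify_stack(stack, config, backgrounds)
    n_match, n_planted, n_detected = match_nuclei(truth, result.retained)
    row: dict = {
        "seed": params.seed,
        "planted_coloc_fraction": params.coloc_fraction_gal9_pdna,
        "nuclei_planted": n_planted,
        "nuclei_detected": n_detected,
        "nucleus_recall": n_match / n_planted if n_planted else float("nan"),
        "nucleus_precision": n_match / n_detected if n_detected else float("nan"),
    }
    for channel in PUNCTA_CHANNELS:
        planted = len(truth.puncta_of(channel))
        found = len(result.puncta.get(channel, []))
        row[f"{channel}_planted"] = planted
        row[f"{channel}_detected"] = found
        row[f"{channel}_count_error"] = (
            abs(found - planted) / planted if planted else float("nan"))
    fractions, skipped = per_cell_coloc_fractions(result.counts, "pdna")
    est = float(np.mean(fractions)) if fractions else float("nan")
    row["estimated_coloc_fraction"] = est
    row["coloc_abs_error"] = abs(est - params.coloc_fraction_gal9_pdna) \
        if fractions else float("nan")
    row["cells_without_gal9"] = skipped
    return row


def run_benchmark(
    coloc_fractions: list[float],
    seeds: list[int],
    base_params: SceneParams | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Parameter-recovery benchmark over a grid of planted
    colocalization fractions and seeds; one row per (fraction, seed)."""
    if not coloc_fractions or not seeds:
        raise ValueError("grid must be non-empty")
    import dataclasses
    rows = []
    for f in coloc_fractions:
        for seed in seeds:
            params = dataclasses.replace(
                base_params or SceneParams(),
                coloc_fraction_gal9_pdna=f, seed=seed)
            rows.append(evaluate_scene(params, config))
    return pd.DataFrame(rows)
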