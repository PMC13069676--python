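# nucleopunct

Quantification of nuclear puncta and object-based colocalization in
multi-channel fluorescence microscopy, with the matching flow-cytometry
outcome metrics, for non-viral gene delivery experiments.

After electrotransfection or lipofection of plasmid DNA (pDNA), nuclei
show punctate signals from the delivered pDNA, from Galectin-9 (Gal9),
and from SC35-marked nuclear speckles. This package implements the
complete desk-side analysis for such experiments:

- **Nucleus segmentation** from the Hoechst channel with a size window
  (150–600 px equivalent diameter by default) and a **form-factor gate**
  (4πA/P² in 0.70–1.00) that removes out-of-focus, jagged and merged
  objects;
- **concentric edge/inner partitioning** of each nucleus by boundary
  distance;
- **punctum detection** per channel against thresholds calibrated on
  negative controls (mean + k·SD of non-nuclear pixels), with inclusive
  diameter windows (pDNA 4–40 px, Gal9 0.5–2 μm);
- **object-based colocalization**: a Gal9 punctum counts as colocalized
  when the partner signal (pDNA or SC35) covers ≥ 30 % of the Gal9
  punctum area — Gal9 is always the reference object;
- **flow-cytometry metrics**: transfection efficiency (eTE, % of gated
  cells above the positive cut), expression level (geometric mean
  fluorescence among positives), viability, apparent expression
  (their product), and EdU cell-cycle fractions;
- **group statistics** as used in this field: Mann–Whitney U (exact p
  for small tie-free samples), one-way ANOVA + Tukey HSD, single-pass
  2-SD outlier exclusion, mean ± SEM summaries with star codes;
- a **synthetic-scene generator** with exact ground truth (elliptical
  nuclei, planted puncta, planted pairwise overlap fractions, Gaussian
  PSF + noise), so the whole chain is validated by parameter recovery
  without any raw data.

## Worked example

Generate a synthetic scene with a planted 30 % Gal9–pDNA
colocalization fraction, run the full pipeline against a matched
negative control, and compare with the ground truth:

```python
from nucleopunct.synthetic import SceneParams
from nucleopunct.pipeline import evaluate_scene

row = evaluate_scene(SceneParams(seed=1))
for key in ("nuclei_planted", "nuclei_detected", "gal9_planted",
            "gal9_detected", "estimated_coloc_fraction", "coloc_abs_error"):
    print(key, row[key])
```

prints

```
nuclei_planted 10
nuclei_detected 10
gal9_planted 158
gal9_detected 158
estimated_coloc_fraction 0.3054096829096829
coloc_abs_error 0.005409682909682911
```

All 10 planted nuclei are segmented, retained by the size and
form-factor gates and matched to the truth; all 158 planted Gal9
puncta are detected; and the per-cell mean colocalized fraction
(0.305) recovers the planted 0.3 within 0.006.

The same loop is available from the shell:

```sh
nucleopunct simulate scene --seed 3 --out scene_dir/   # TIFF + truth JSON
nucleopunct benchmark --fractions 0,0.3,0.6 --seeds 1,2,3 --out bench.csv
nucleopunct run --manifest manifest.yaml               # real or synthetic stacks
```

Flow metrics on a simulated event table (40 % true positives, 90 %
viability), with the positive cut taken from an untransfected control:

```sh
nucleopunct simulate flow --seed 4 --out flow.csv
nucleopunct simulate flow --seed 5 --config ctrl.yaml --out ctrl.csv
nucleopunct flow-metrics --events flow.csv --control ctrl.csv
```

```
{
 "n_gated": 10000.0,
 "eTE_percent": 40.1,
 "expression_level": 9725.259291878156,
 "viability": 0.9018,
 "apparent_expression": 3516.8657705957044,
 "positive_threshold": 361.58064114006197
}
```

where `ctrl.yaml` contains `positive_fraction: 0.0`.

## Layout

| module | contents |
| --- | --- |
| `nucleopunct.synthetic` | scene / flow-table generators with ground truth |
| `nucleopunct.io` | TIFF stack and CSV table reading/writing |
| `nucleopunct.config` | run configuration, published defaults, validation |
| `nucleopunct.segmentation` | nucleus segmentation, form factor, ring partition |
| `nucleopunct.puncta` | background calibration and punctum detection |
| `nucleopunct.coloc` | overlap rule, per-nucleus counts, group summaries |
| `nucleopunct.flow` | gating, eTE, expression, apparent expression, EdU |
| `nucleopunct.stats` | outlier rule, Mann–Whitney, ANOVA + Tukey, stars |
| `nucleopunct.pipeline` | manifests, end-to-end runs, synthetic benchmark |

See `docs/methods.md` for the measurement model, parameter choices and
known limitations.
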