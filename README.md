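# g2screen

Analysis pipeline for arrayed RNAi screens of the **Topo2a-dependent G2
arrest** — the cell-cycle arrest triggered by catalytic inhibition of
topoisomerase IIα (e.g. by ICRF193), which is genetically distinct from the
DNA-damage checkpoint.

In such a screen, cells depleted of a candidate gene are treated with
ICRF193 plus the microtubule antagonist nocodazole: cells that *bypass* the
G2 arrest enter mitosis and are trapped there, so the **mitotic index**

```
MI = 100 × (MPM2-positive cells) / (total cells)
```

read out per well reports arrest abrogation. `g2screen` implements the full
desk-side analysis of this assay for people running or re-analysing
high-content screens:

- **Plate normalization** — MI, robust z-scores
  `z = (well − plate median) / plate MAD`, and percent-of-control
  `POC = 100 × well / mean(Risc-free wells)` per plate, instrument and
  condition, with triplicate-median aggregation and plate QC.
- **Hit-selection cascade** — primary screen (`z_MI > 2.5` on both
  instruments, cell-number `z > −1.5` toxicity exclusion), validation by POC
  (ICRF > 350/200 per instrument; drug-independent mitotic accumulators
  excluded on the no-drug arm), an extended counter-screen (ICRF POC > 350
  and > 2× the bleomycin, etoposide, irradiation and no-drug arms), and
  siRNA-pool deconvolution (on-target iff ≥ 2 of 4 duplexes exceed POC 150).
- **Network enrichment** — induced-subgraph edge-count enrichment of hit
  sets against a supplied STRING-style edge list, with a permutation null
  over random equal-size gene sets, `p = (1 + #{null ≥ obs})/(1 + R)`, an
  analytic normal-tail mode for very small p, and ranked candidate expansion
  in groups of ten under an enrichment-threshold stopping rule.
- **Foci imaging** — DAPI nucleus segmentation, per-nucleus
  percentile-filter foci detection, area-normalized foci densities, and
  directional cross-channel colocalization for PLA and PML/Topo2a foci.
- **Validation statistics** — 2^−ΔΔCT relative expression (GAPDH
  reference), sister-chromatid-catenation scoring, segregation-defect rates.
- **Synthetic data** — a generator for complete screening campaigns
  (384-well triplicate plates, 900 cells/well, two instruments, six
  treatment arms) and fluorescence images with planted ground truth, so
  every stage is testable without external data.

## Worked example

Simulate a 352-gene campaign with eight planted ICRF-selective arrest
abrogators, five toxic pools and three mitotic accumulators, then run the
cascade:

```python
from g2screen import synthetic_data as sd, plate_normalization as pn, hit_selection as hs

lib = sd.generate_library(
    352,
    {"icrf_selective_abrogator": 8, "toxic": 5, "mitotic_accumulator": 3},
    seed=11,
)
campaign = sd.simulate_campaign(lib, seed=11)        # 11520 wells
normalized, qc = pn.normalize_wells(campaign)
table = hs.analyze_campaign(normalized)
print(table["classification"].value_counts())
```

```
classification
not_hit                 333
icrf_selective            8
excluded_toxic            5
excluded_accumulator      3
primary_hit               3
```

All eight planted abrogators are recovered as ICRF-selective, the toxic and
accumulator pools are excluded with their reasons, and three neutral genes
that passed the primary z cutoffs by chance are removed at validation
(their POC never reaches 350). `hs.cascade_funnel(table)` turns this into a
stage-by-stage funnel report with yields as percentages of the previous
stage — e.g. `"primary": 14 (4.0% of 352)` → `"repeated": 8 (57.1%)` here.

The same operations are available from the shell:

```
g2screen simulate --genes 352 --seed 11 --out campaign.csv
g2screen normalize campaign.csv --out normalized.csv --qc-out qc.json
g2screen call-hits normalized.csv --out hits.csv --funnel-out funnel.json
g2screen network --edges string_export.tsv --core hits.txt \
    --candidates ranked.txt --seed 1 --out final_set.txt
g2screen foci field.tif --percentile 97.5 --out per_nucleus.csv
```

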