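# Methods

This note documents the models and procedures implemented in `g2screen`,
the parameters that matter, the design choices made where the published
analysis leaves the design open, and what the synthetic benchmarks do and
do not demonstrate.

## The assay and its measures

The screen measures bypass of the Topo2a-dependent G2 arrest. Cells are
transfected with arrayed siRNA pools in 384-well plates (900 cells seeded
per well, three technical replicates), treated for 18 h with an
arrest-inducing agent plus 1 µM nocodazole, and scored by immunofluorescence
on two instruments (an ArrayScan-type imager and an Acumen-type laser
cytometer). Cells that escape G2 are trapped in mitosis and counted as
MPM2-positive, giving the per-well mitotic index
`MI = 100 × mpm2 / cells`.

Three normalizations are used, each per plate, replicate, instrument and
condition:

- **Robust z**: `(well − plate median) / plate MAD`, with the plate
  statistics computed over library wells only — plate normalization assumes
  most wells are phenotypically null, and control wells are
  non-representative by design. The MAD is **unscaled** by default (no
  1.4826 consistency factor), matching the formula as printed; a
  `mad_scaled` switch applies the factor. A zero MAD is a plate QC failure:
  the plate is flagged and no z-scores are emitted.
- **Percent of control**: `100 × well / mean(Risc-free wells)` of the same
  plate and condition. Same-condition matching is used because it is the
  only reading under which the validation cutoffs for different treatment
  arms are mutually comparable; it also makes the control average exactly
  100 on every plate, a property the tests assert.
- **Nocodazole normalization**: MI as a percentage of the nocodazole-only
  trapped fraction, used for arrest assays outside the screen proper.

Replicates are aggregated as the median of available values; missing wells
propagate as missing, never as zero. z-scores are computed per instrument
throughout (the two instruments carry separate cutoffs, so their streams
are never pooled before thresholding).

## The selection cascade

The cutoff table (all comparisons strict; ties fail):

| Stage | Rule |
|---|---|
| Primary | `z_MI(ICRF) > 2.5` on **both** instruments (AND; OR configurable) |
| Toxicity | cell-number `z > −1.5` (Acumen stream) |
| Validation | ICRF POC > 350 (ArrayScan) and > 200 (Acumen); no-drug POC ≥ 150/200 excludes as accumulator; bleomycin POC < 200 is an annotation |
| Counter-screen | ICRF POC > 350 and ICRF > 2× each of bleomycin, etoposide, IR, no-drug (ArrayScan) |
| Deconvolution | on-target iff ≥ 2 of 4 duplexes with ICRF POC > 150 (ArrayScan) |

Design choices where the published rules leave room:

- **Toxicity pooling.** Toxicity is a property of the reagent, not of the
  treatment, so the default toxicity measure (`toxicity_zscores`) is the
  median cell-count z over *every* well of a gene across all conditions and
  replicates. With only the three primary-screen wells, a strict −1.5
  unscaled-MAD rule on a median of three false-flags ≈ 6% of null genes —
  enough to erode cascade sensitivity and to misroute genuine accumulators
  into the toxic bin; pooling the full campaign (15 wells per instrument in
  the default design) drops the false-flag rate below 10⁻⁴ while leaving
  genuinely toxic pools (viability far below 1 in every arm) unambiguous.
  The per-stage `primary_hits` function accepts any toxicity series, so the
  primary-screen-only variant remains available.
- **Bleomycin rule as annotation.** Repeated-but-non-selective genes are a
  reported category of their own, so the validation bleomycin cutoff
  annotates selectivity rather than excluding; the extended counter-screen
  fold rules are the hard requirement for the final selective set.
- **Unevaluable ≠ failed.** Genes with missing required measures are
  reported in a separate category, never silently dropped or failed.
- Funnel yields are reported both to one decimal and as integers, since
  published funnels mix the two formats (e.g. 47.6% vs 35%).

## Network enrichment

Hit sets are placed on a supplied gene–gene edge list (a STRING-style
3-column TSV; the database itself is never fetched). The enrichment
statistic is the package's own definition — no claim of equivalence to any
database's score: the observed statistic is the induced-subgraph edge
count; the null is R uniform draws of equal-size gene sets from the
background universe (default: the screened library); and
`p = (1 + #{null ≥ obs}) / (1 + R)`, so p can never fall below `1/(R+1)`.
Because the expansion threshold (default 10⁻⁸) lies far below any
attainable permutation p, an **analytic mode** fits a continuity-corrected
normal tail to the same null sample; it is floored at 10⁻³⁰⁰ and labelled
in the result. Permutation and analytic modes agree within Monte-Carlo
error for p ≥ 10⁻³, which the tests verify against brute-force enumeration
on universes of ≤ 12 genes.

Ranked expansion appends candidate genes in groups (default ten, by ranked
z-score) and stops before the first group whose inclusion pushes the
cumulative p past the threshold. The cumulative scope is the default; a
marginal scope (testing each group's edge gain) is a configuration switch.
The null does not condition on degree by default; a degree-preserving
rewiring null is available and flagged in the output. The permutation seed
is a required configuration field.

## Foci quantification

Nuclei are segmented from the DAPI channel by global Otsu threshold, binary
hole filling and a minimum-area filter (default 100 px); watershed
splitting of touching nuclei is out of scope, so fields should have
separated nuclei. Foci are detected **per nucleus**: pixels strictly above
that nucleus's intensity percentile (default 97.5) form candidate regions,
and connected regions of at least the minimum area (default 4 px) become
foci. Computing the percentile per nucleus rather than per image keeps
nucleus-to-nucleus brightness variation from biasing counts, consistent
with the per-nucleus normalization of the downstream statistics. Counts
are reported per unit nuclear area (default per 1000 px) because drug
treatments alter nuclear size.

Colocalization is directional — the percentage of channel-A foci
satisfying the criterion against any channel-B focus of the same nucleus —
with three criteria: mask overlap ≥ 1 pixel (default), centroid-in-mask
(the test point is the centroid, snapped to the focus's nearest own pixel
when a non-convex region does not contain its centroid, so
self-colocalization is always 100%), and centroid distance ≤ d (default
3 px, suited to PLA-style point signals). An empty A-channel yields a
missing value, never 0.

Both detection and colocalization are invariant under positive affine
intensity rescaling, since all thresholds are percentiles of the data.

**Operating regime.** A percentile filter at percentile q assumes foci
occupy less than (100 − q)% of the nuclear area; when planted spots exceed
that budget the threshold lands inside the spot intensity itself and
recall degrades. The synthetic fixtures therefore plant 1–4 foci of radius
1.8–2.5 px per 20–28 px-radius nucleus (≈ 1–2% of nuclear area), the
regime typical of PML bodies and PLA puncta.

## Synthetic data model

The generator's mechanism: per well, the cell count is Poisson with mean
`seeded × growth × viability` (negative binomial optional via a dispersion
parameter), and the MPM2-positive count is binomial with
`p = baseline(condition) × bypass(gene, condition)`, clipped to [0, 1].
Both instruments read the same underlying well; the second applies a
binomial detection-efficiency thinning (default 0.85) to the mitotic
count — POC and z are scale-invariant, so this adds realism without
changing separations.

Default condition baselines (configurable; the nocodazole-only trapped
fraction after 18 h is not published, so these are explicit choices, not
reconstructions): nocodazole-only 0.40; arrest-competent
ICRF/bleomycin/etoposide/IR 0.02; no drug 0.03. Effect classes: the
ICRF-selective abrogator multiplies the ICRF mitotic probability ×10
(0.02 → 0.20, half the trapping baseline, expected ICRF POC ≈ 1000 — well
clear of every cutoff, so the benchmark is insensitive to the exact
baselines); the pan-checkpoint abrogator does the same under every
arrest-inducing arm; the accumulator multiplies all arms ×5; toxic pools
have viability 0.3. Control wells occupy two reserved columns per plate:
Risc-free (16 wells), siATM+siATR (4), nocodazole-only (8) and untreated
(4); control and library wells never overlap, and replicate plates share
the layout. Random streams are keyed per (condition, plate, replicate), so
extending the condition panel never perturbs earlier draws; everything is
bit-reproducible for a fixed seed.

Images are rendered as hard discs (nuclei on the DAPI channel, foci on
signal channels) over a flat background with additive Gaussian noise, with
a faint nuclear counterstain on signal channels so percentiles are taken
over a realistic intranuclear background. In the noise-free limit the
image equals the analytic profile exactly.

**What the generator does not emulate:** spatial plate effects (edge
evaporation, dispenser gradients — the analysis performs no spatial
correction either), siRNA efficacy variation within on-target duplexes,
cell-cycle kinetics, optics (PSF blur, uneven illumination), or touching
nuclei. Passing benchmarks therefore demonstrate the correctness of the
statistics and rule logic under the stated noise model, not robustness to
these real-data artifacts.

## Benchmark problem sizes

The cascade benchmark simulates ten campaigns of 500 genes (three
replicates, five treatment arms, two instruments; ≈ 23 000 wells each,
plus an ICRF-only duplex deconvolution campaign) with 20 on-target
ICRF-selective abrogators, 5 off-target pools (one active duplex), 10
toxic, 10 accumulator and 10 pan-checkpoint pools planted per campaign.
Foci benchmarks use twenty 256×256 fields of ~5 nuclei with spot amplitude
80× the noise σ. Enrichment checks use 10⁵ permutations against exact
enumeration on ≤ 12-gene universes and a planted 5-clique in a 100-gene
universe. These sizes keep the full suite under a minute while leaving the
planted separations large relative to sampling error.

## Known limitations

- The enrichment statistic is a permutation test of edge counts; it is not
  STRING's proprietary score, and the analytic tail is a normal
  approximation whose extreme-tail values (≪ 1/R) should be read as
  ordering information, not calibrated probabilities.
- Percentile foci detection saturates when foci occupy more than
  (100 − percentile)% of a nucleus (see operating regime above).
- No spatial plate-effect correction, no watershed nucleus splitting, no
  3-D stacks, no amplification-efficiency modelling in 2^−ΔΔCT, and no
  inferential statistics beyond the reported standard errors.
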