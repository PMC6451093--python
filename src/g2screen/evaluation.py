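"""End-to-end benchmarking of the selection cascade on simulated campaigns.

The planted ground truth of the synthetic generator makes the cascade's
operating characteristics measurable: sensitivity (planted on-target
ICRF-selective abrogators recovered in the final set), false-discovery
proportion (final-set genes that were not planted as such), and whether
toxic and drug-independent accumulator pools were excluded with the correct
stated reason.
"""

from __future__ import annotations

from dataclasses import dataclass

from g2screen import hit_selection as hs
from g2screen import plate_normalization as pn
from g2screen import synthetic_data as sd

#: Planted composition of the benchmark campaign: a 500-gene library with
#: 20 on-target ICRF-selective abrogators, 5 off-target pools (a single
#: active duplex), 10 toxic pools, 10 drug-independent mitotic accumulators
#: and 10 pan-checkpoint abrogators; the remainder neutral.
BENCHMARK_ASSIGNMENTS = (
    sd.EffectAssignment("icrf_selective_abrogator", count=20),
    sd.EffectAssignment("icrf_selective_abrogator", count=5, n_on_target=1),
    sd.EffectAssignment("toxic", count=10),
    sd.EffectAssignment("mitotic_accumulator", count=10),
    sd.EffectAssignment("pan_checkpoint_abrogator", count=10),
)


@dataclass(frozen=True)
class CascadeScore:
    sensitivity: float
    false_discovery_proportion: float
    toxic_excluded_with_reason: bool
    accumulators_excluded_with_reason: bool
    n_true_hits: int
    n_final: int


def run_benchmark_campaign(seed: int, n_genes: int = 500) -> CascadeScore:
    """Simulate one full campaign (pools + duplex deconvolution) and score it."""
    library = sd.generate_library(n_genes, list(BENCHMARK_ASSIGNMENTS), seed=seed)
    campaign = sd.simulate_campaign(library, seed=seed)
    normalized, _ = pn.normalize_wells(campaign)
    duplex_design = sd.PlateDesign(conditions=(sd.ICRF,), instruments=(sd.ARRAYSCAN,))
    duplex_campaign = sd.simulate_campaign(
        library, duplex_design, seed=seed + 100_000, reagents="duplexes"
    )
    duplex_normalized, _ = pn.normalize_wells(duplex_campaign)
    table = hs.analyze_campaign(normalized, duplex_normalized)

    effects = library.effects
    true_hits = set(effects.genes_of_class("icrf_selective_abrogator", min_on_target=2))
    final = set(table.index[table["classification"] == hs.ON_TARGET])
    toxic_ok = set(effects.genes_of_class("toxic")) <= set(
        table.index[table["classification"] == hs.EXCLUDED_TOXIC]
    )
    accum_ok = set(effects.genes_of_class("mitotic_accumulator")) <= set(
        table.index[table["classification"] == hs.EXCLUDED_ACCUMULATOR]
    )
    return CascadeScore(
        sensitivity=len(final & true_hits) / len(true_hits),
        false_discovery_proportion=len(final - true_hits) / max(1, len(final)),
        toxic_excluded_with_reason=toxic_ok,
        accumulators_excluded_with_reason=accum_ok,
        n_true_hits=len(true_hits),
        n_final=len(final),
    )
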