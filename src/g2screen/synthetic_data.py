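"""Synthetic screening campaigns and fluorescence images with known ground truth.

The generator emulates an arrayed siRNA screen for bypass of the
Topo2a-dependent G2 arrest: 384-well plates seeded at 900 cells/well in
triplicate, read on two instruments, under a panel of arrest conditions
(catalytic Topo2 inhibition by ICRF193, the DNA-damaging agents bleomycin and
etoposide, ionizing radiation — each combined with a nocodazole mitotic trap —
plus no-drug and nocodazole-only references).  Genes carry planted effect
classes (arrest abrogators selective for ICRF193, pan-checkpoint abrogators,
toxic siRNAs, drug-independent mitotic accumulators) whose annotations are
retained as ground truth, so the sensitivity and specificity of every
downstream selection stage can be measured.

Counts are generated mechanistically: the number of cells in a well is
Poisson with mean ``seeded cells x growth x viability``, and the number of
MPM2-positive (mitotic) cells is binomial with success probability
``baseline(condition) x arrest-bypass factor``, clipped to [0, 1].  Both
instruments measure the same underlying well; the second instrument applies a
binomial detection-efficiency thinning to the mitotic count.

A small image renderer plants circular nuclei and intranuclear foci on a flat
background with additive Gaussian noise, for testing the foci quantifier
against known positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# condition / instrument / reagent vocabulary
# --------------------------------------------------------------------------

ICRF = "icrf_noc"
BLEO = "bleo_noc"
ETOP = "etop_noc"
IR = "ir_noc"
NO_DRUG = "no_drug"
NOC_ONLY = "noc_only"

SCREEN_CONDITIONS = (ICRF, BLEO, ETOP, IR, NO_DRUG)
ALL_CONDITIONS = SCREEN_CONDITIONS + (NOC_ONLY,)

ARRAYSCAN = "arrayscan"
ACUMEN = "acumen"

RISC_FREE = "risc_free"
SI_ATM_ATR = "si_atm_atr"
UNTREATED = "untreated"
CONTROL_REAGENTS = (RISC_FREE, SI_ATM_ATR, UNTREATED)

EFFECT_CLASSES = (
    "neutral",
    "icrf_selective_abrogator",
    "pan_checkpoint_abrogator",
    "toxic",
    "mitotic_accumulator",
)

WELL_COLUMNS = [
    "plate_id",
    "replicate",
    "row",
    "col",
    "reagent_id",
    "gene",
    "condition",
    "instrument",
    "cell_count",
    "mpm2_count",
]


# --------------------------------------------------------------------------
# effect model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneEffect:
    """Ground-truth phenotype of one gene's siRNA pool.

    ``bypass`` multiplies the baseline mitotic probability of each condition
    (a value of 1 means no effect); ``viability`` multiplies the expected
    cell count; ``on_target`` flags which of the pool's four duplexes carry
    the effect (off-target pools reproduce it with fewer than two duplexes).
    """

    effect_class: str = "neutral"
    bypass: Mapping[str, float] = field(default_factory=dict)
    viability: float = 1.0
    on_target: tuple[bool, bool, bool, bool] = (True, True, True, True)

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        if not 0.0 < self.viability <= 1.0:
            raise ValueError("viability factor must be in (0, 1]")
        if any(m < 0 for m in self.bypass.values()):
            raise ValueError("arrest-bypass factors must be >= 0")
        if len(self.on_target) != 4:
            raise ValueError("every pool has exactly 4 duplexes")
        if self.effect_class == "neutral" and (
            self.viability != 1.0 or any(m != 1.0 for m in self.bypass.values())
        ):
            raise ValueError("neutral genes must have all multipliers equal to 1")
        if self.effect_class == "toxic" and self.viability >= 1.0:
            raise ValueError("toxic class requires viability factor < 1")

    def bypass_factor(self, condition: str) -> float:
        return float(self.bypass.get(condition, 1.0))


#: Default multipliers per effect class.  The ICRF-selective abrogator raises
#: the mitotic probability under ICRF193 tenfold (0.02 -> 0.20, i.e. half the
#: nocodazole trapping baseline); the pan-checkpoint abrogator does so under
#: every arrest-inducing treatment; the accumulator elevates the mitotic
#: fraction fivefold regardless of drug; toxic pools lose 70% of cells.
CLASS_DEFAULTS: dict[str, GeneEffect] = {
    "neutral": GeneEffect("neutral"),
    "icrf_selective_abrogator": GeneEffect(
        "icrf_selective_abrogator", bypass={ICRF: 10.0}
    ),
    "pan_checkpoint_abrogator": GeneEffect(
        "pan_checkpoint_abrogator",
        bypass={ICRF: 10.0, BLEO: 10.0, ETOP: 10.0, IR: 10.0},
    ),
    "toxic": GeneEffect("toxic", viability=0.3),
    "mitotic_accumulator": GeneEffect(
        "mitotic_accumulator",
        bypass={c: 5.0 for c in SCREEN_CONDITIONS},
    ),
}

#: Phenotypes of the plate control reagents.  The non-targeting (Risc-free)
#: control is neutral; the siATM+siATR positive control abrogates every
#: checkpoint arrest.
CONTROL_EFFECTS: dict[str, GeneEffect] = {
    RISC_FREE: GeneEffect("neutral"),
    UNTREATED: GeneEffect("neutral"),
    SI_ATM_ATR: CLASS_DEFAULTS["pan_checkpoint_abrogator"],
}


@dataclass(frozen=True)
class EffectAssignment:
    """Assign an effect class to named genes or to ``count`` random genes."""

    effect_class: str
    genes: tuple[str, ...] | None = None
    count: int | None = None
    n_on_target: int = 4
    effect: GeneEffect | None = None  # override the class default multipliers

    def resolved_effect(self) -> GeneEffect:
        base = self.effect if self.effect is not None else CLASS_DEFAULTS[self.effect_class]
        flags = tuple(i < self.n_on_target for i in range(4))
        return replace(base, on_target=flags)


class EffectModel:
    """Per-gene ground-truth effects; unlisted genes are neutral."""

    def __init__(self, effects: Mapping[str, GeneEffect] | None = None):
        self._effects = dict(effects or {})

    def __getitem__(self, gene: str) -> GeneEffect:
        return self._effects.get(gene, CLASS_DEFAULTS["neutral"])

    def __contains__(self, gene: str) -> bool:
        return gene in self._effects

    def items(self):
        return self._effects.items()

    def genes_of_class(self, effect_class: str, min_on_target: int = 0) -> list[str]:
        return sorted(
            g
            for g, e in self._effects.items()
            if e.effect_class == effect_class and sum(e.on_target) >= min_on_target
        )

    def to_dict(self) -> dict:
        return {
            g: {
                "effect_class": e.effect_class,
                "bypass": dict(e.bypass),
                "viability": e.viability,
                "on_target": list(e.on_target),
            }
            for g, e in sorted(self._effects.items())
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EffectModel":
        return cls(
            {
                g: GeneEffect(
                    effect_class=v["effect_class"],
                    bypass=v.get("bypass", {}),
                    viability=v.get("viability", 1.0),
                    on_target=tuple(v.get("on_target", (True,) * 4)),
                )
                for g, v in d.items()
            }
        )


# --------------------------------------------------------------------------
# reagent library
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReagentLibrary:
    """Genes, their siRNA pools and the four duplexes per pool.

    ``effects`` carries the planted ground truth used to score downstream
    selection stages.
    """

    genes: tuple[str, ...]
    pool_ids: Mapping[str, str]  # gene -> pool reagent id
    duplex_ids: Mapping[str, tuple[str, str, str, str]]  # gene -> 4 duplex ids
    effects: EffectModel

    def duplex_gene(self, duplex_id: str) -> str:
        gene, _ = duplex_id.rsplit("_d", 1)
        return gene

    def duplex_on_target(self, gene: str, index: int) -> bool:
        return self.effects[gene].on_target[index]


def generate_library(
    n_genes: int,
    effect_assignments: Sequence[EffectAssignment] | Mapping[str, int] | None = None,
    seed: int = 0,
) -> ReagentLibrary:
    """Build a reagent library of ``n_genes`` pools with planted effects.

    ``effect_assignments`` may be a mapping ``{effect_class: count}`` (genes
    drawn at random with ``seed``) or a sequence of :class:`EffectAssignment`
    for explicit gene lists, duplex on-target counts, or custom multipliers.
    Assignments naming a gene outside the library raise ``KeyError``.
    Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    genes = tuple(f"GENE{i + 1:05d}" for i in range(n_genes))
    gene_set = set(genes)
    rng = np.random.default_rng([seed, 0x11B])

    if effect_assignments is None:
        assignments: list[EffectAssignment] = []
    elif isinstance(effect_assignments, Mapping):
        assignments = [
            EffectAssignment(cls, count=cnt) for cls, cnt in effect_assignments.items()
        ]
    else:
        assignments = list(effect_assignments)

    effects: dict[str, GeneEffect] = {}
    unassigned = list(genes)
    for a in assignments:
        if a.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {a.effect_class!r}")
        if a.genes is not None:
            chosen = list(a.genes)
            for g in chosen:
                if g not in gene_set:
                    raise KeyError(f"effect assignment names unknown gene {g!r}")
        else:
            if a.count is None:
                raise ValueError("assignment needs explicit genes or a count")
            pool = [g for g in unassigned if g not in effects]
            if a.count > len(pool):
                raise ValueError("more effect genes requested than genes available")
            chosen = sorted(rng.choice(pool, size=a.count, replace=False))
        eff = a.resolved_effect()
        for g in chosen:
            effects[g] = eff

    pool_ids = {g: f"{g}_pool" for g in genes}
    duplex_ids = {g: tuple(f"{g}_d{i + 1}" for i in range(4)) for g in genes}
    return ReagentLibrary(genes, pool_ids, duplex_ids, EffectModel(effects))


# --------------------------------------------------------------------------
# plate design and campaign simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateDesign:
    """Geometry, seeding, conditions and controls of the screening plates.

    Defaults reflect the screen's configuration: 384-well plates, 900 cells
    seeded per well, three technical replicates, two read-out instruments.
    ``baselines`` is the per-condition mitotic probability of an
    arrest-competent (neutral) well: the nocodazole-only trap accumulates
    ~40% mitotic cells over the treatment window, intact arrests keep the
    mitotic fraction at ~2%, and untreated cycling cells sit at ~3%.
    """

    n_rows: int = 16
    n_cols: int = 24
    cells_per_well: int = 900
    growth_factor: float = 2.0
    replicates: int = 3
    conditions: tuple[str, ...] = SCREEN_CONDITIONS
    instruments: tuple[str, ...] = (ARRAYSCAN, ACUMEN)
    detection_efficiency: Mapping[str, float] = field(
        default_factory=lambda: {ARRAYSCAN: 1.0, ACUMEN: 0.85}
    )
    baselines: Mapping[str, float] = field(
        default_factory=lambda: {
            ICRF: 0.02,
            BLEO: 0.02,
            ETOP: 0.02,
            IR: 0.02,
            NO_DRUG: 0.03,
            NOC_ONLY: 0.40,
        }
    )
    control_columns: tuple[int, ...] = (0, 1)
    nb_dispersion: float | None = None  # Poisson cell counts unless set

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("condition panel must be nonempty")
        missing = [c for c in self.conditions if c not in self.baselines]
        if missing:
            raise ValueError(f"missing condition baselines: {missing}")
        if len(self.control_columns) != len(set(self.control_columns)):
            raise ValueError("duplicate control columns")

    @property
    def library_wells_per_plate(self) -> int:
        return self.n_rows * (self.n_cols - len(self.control_columns))

    def control_map(self) -> list[tuple[int, int, str, str | None]]:
        """(row, col, reagent, condition-override) for every control well.

        Control wells live in the reserved columns and never overlap library
        wells.  Nocodazole-only and untreated wells override the plate
        condition; Risc-free and siATM+siATR wells share it.
        """
        wells: list[tuple[int, int, str, str | None]] = []
        half = self.n_rows // 2
        three_q = (3 * self.n_rows) // 4
        for j, col in enumerate(self.control_columns):
            for row in range(self.n_rows):
                if row < half:
                    wells.append((row, col, RISC_FREE, None))
                elif row < three_q:
                    reagent = SI_ATM_ATR if j % 2 == 0 else UNTREATED
                    override = None if j % 2 == 0 else NO_DRUG
                    wells.append((row, col, reagent, override))
                else:
                    wells.append((row, col, RISC_FREE, NOC_ONLY))
        return wells

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cells_per_well": self.cells_per_well,
            "growth_factor": self.growth_factor,
            "replicates": self.replicates,
            "conditions": list(self.conditions),
            "instruments": list(self.instruments),
            "detection_efficiency": dict(self.detection_efficiency),
            "baselines": dict(self.baselines),
            "control_columns": list(self.control_columns),
            "nb_dispersion": self.nb_dispersion,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlateDesign":
        d = dict(d)
        for key in ("conditions", "instruments", "control_columns"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _library_layout(
    library: ReagentLibrary, design: PlateDesign, reagents: str
) -> list[list[tuple[str, str]]]:
    """Tile reagents (pools or individual duplexes) across plates.

    Returns, per plate, the list of (reagent_id, gene) in row-major well
    order.  Replicate plates share this layout.
    """
    if reagents == "pools":
        entries = [(library.pool_ids[g], g) for g in library.genes]
    elif reagents == "duplexes":
        entries = [
            (d, g) for g in library.genes for d in library.duplex_ids[g]
        ]
    else:
        raise ValueError("reagents must be 'pools' or 'duplexes'")
    per_plate = design.library_wells_per_plate
    return [entries[i : i + per_plate] for i in range(0, len(entries), per_plate)]


def simulate_campaign(
    library: ReagentLibrary,
    design: PlateDesign | None = None,
    model: EffectModel | None = None,
    seed: int = 0,
    reagents: str = "pools",
) -> pd.DataFrame:
    """Simulate a full screening campaign as a well-level table.

    One physical plate exists per (condition, plate index, replicate); each
    instrument contributes an independent read of it.  Cell counts are
    Poisson (negative binomial if the design sets a dispersion) with mean
    ``seeded x growth x viability``; MPM2-positive counts are binomial with
    ``p = baseline(condition) x bypass(gene, condition)`` clipped to [0, 1].
    Random streams are keyed per (condition, plate, replicate) so extending
    the condition panel does not perturb earlier draws.  Deterministic for a
    fixed seed.
    """
    design = design or PlateDesign()
    model = model or library.effects
    for g in library.genes:
        # EffectModel defaults unlisted genes to neutral, so coverage always
        # holds; keep the access to fail fast on malformed models.
        model[g]

    layouts = _library_layout(library, design, reagents)
    control_wells = design.control_map()
    lib_cols = [c for c in range(design.n_cols) if c not in design.control_columns]

    records: list[pd.DataFrame] = []
    for cond_idx, condition in enumerate(design.conditions):
        for plate_idx, layout in enumerate(layouts):
            plate_id = f"{condition}-P{plate_idx + 1:02d}"
            for rep in range(1, design.replicates + 1):
                rng = np.random.default_rng(
                    [seed & 0x7FFFFFFF, cond_idx, plate_idx, rep]
                )
                rows: list[int] = []
                cols: list[int] = []
                reagent_ids: list[str] = []
                gene_names: list[str | None] = []
                conds: list[str] = []
                p_list: list[float] = []
                viab: list[float] = []

                # library wells, row-major over the non-control columns
                positions = [(r, c) for r in range(design.n_rows) for c in lib_cols]
                for (r, c), (reagent_id, gene) in zip(positions, layout):
                    eff = model[gene]
                    if reagents == "duplexes":
                        d_index = int(reagent_id.rsplit("_d", 1)[1]) - 1
                        if not eff.on_target[d_index]:
                            eff = CLASS_DEFAULTS["neutral"]
                    rows.append(r)
                    cols.append(c)
                    reagent_ids.append(reagent_id)
                    gene_names.append(gene)
                    conds.append(condition)
                    p_list.append(
                        design.baselines[condition] * eff.bypass_factor(condition)
                    )
                    viab.append(eff.viability)

                for r, c, reagent, override in control_wells:
                    eff = CONTROL_EFFECTS[reagent]
                    well_cond = override or condition
                    rows.append(r)
                    cols.append(c)
                    reagent_ids.append(reagent)
                    gene_names.append(None)
                    conds.append(well_cond)
                    p_list.append(
                        design.baselines[well_cond] * eff.bypass_factor(well_cond)
                    )
                    viab.append(eff.viability)

                n = len(rows)
                p = np.clip(np.asarray(p_list), 0.0, 1.0)
                mean_cells = (
                    design.cells_per_well * design.growth_factor * np.asarray(viab)
                )
                if design.nb_dispersion is None:
                    cell_count = rng.poisson(mean_cells)
                else:
                    k = design.nb_dispersion
                    cell_count = rng.negative_binomial(k, k / (k + mean_cells))
                true_mitotic = rng.binomial(cell_count, p)

                for instrument in design.instruments:
                    eff_det = design.detection_efficiency.get(instrument, 1.0)
                    mpm2 = (
                        true_mitotic
                        if eff_det >= 1.0
                        else rng.binomial(true_mitotic, eff_det)
                    )
                    records.append(
                        pd.DataFrame(
                            {
                                "plate_id": plate_id,
                                "replicate": rep,
                                "row": rows,
                                "col": cols,
                                "reagent_id": reagent_ids,
                                "gene": gene_names,
                                "condition": conds,
                                "instrument": instrument,
                                "cell_count": cell_count,
                                "mpm2_count": mpm2,
                            }
                        )
                    )

    df = pd.concat(records, ignore_index=True)[WELL_COLUMNS]
    df["gene"] = df["gene"].astype(object)
    return df


def write_campaign(
    df: pd.DataFrame, path, library: ReagentLibrary | None = None
) -> None:
    """Write the well-level CSV; with a library, a ground-truth JSON sidecar."""
    df.to_csv(path, index=False)
    if library is not None:
        sidecar = str(path).rsplit(".", 1)[0] + ".truth.json"
        with open(sidecar, "w") as fh:
            json.dump(
                {"genes": list(library.genes), "effects": library.effects.to_dict()},
                fh,
                indent=1,
            )


def read_campaign(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"campaign table missing columns: {missing}")
    return df


# --------------------------------------------------------------------------
# image rendering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedNucleus:
    center: tuple[float, float]  # (row, col), 0-based
    radius: float
    amplitude: float = 600.0


@dataclass(frozen=True)
class PlantedFocus:
    center: tuple[float, float]
    radius: float
    amplitude: float
    channel: int  # >= 1; channel 0 is DAPI


@dataclass(frozen=True)
class ImageSpec:
    """Layout of a rendered multi-channel field; coordinates 0-based, row-major."""

    shape: tuple[int, int] = (256, 256)
    nuclei: tuple[PlantedNucleus, ...] = ()
    foci: tuple[PlantedFocus, ...] = ()
    n_channels: int = 2
    background: float = 100.0
    noise_sigma: float = 5.0

    def __post_init__(self) -> None:
        for f in self.foci:
            if not 1 <= f.channel < self.n_channels:
                raise ValueError(f"focus channel {f.channel} out of range")
            if f.amplitude <= 0:
                raise ValueError("focus amplitude must exceed background")
            if self._parent_nucleus(f) is None:
                raise ValueError(f"focus at {f.center} lies outside every nucleus")

    def _parent_nucleus(self, focus: PlantedFocus) -> int | None:
        for i, nuc in enumerate(self.nuclei):
            dr = focus.center[0] - nuc.center[0]
            dc = focus.center[1] - nuc.center[1]
            if np.hypot(dr, dc) + focus.radius <= nuc.radius:
                return i
        return None


def _disc(shape: tuple[int, int], center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def render_nucleus_image(
    spec: ImageSpec, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Render the field and return (image, ground-truth foci, nucleus labels).

    The image is ``(n_channels, H, W)`` float64: a flat background plus hard
    discs for nuclei (DAPI channel) and foci, with additive Gaussian noise.
    The ground-truth table lists every planted focus with its channel and
    parent nucleus label; the label image numbers nuclei from 1 in the order
    given by the spec.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x1F0C1])
    h, w = spec.shape
    img = np.full((spec.n_channels, h, w), spec.background, dtype=float)
    labels = np.zeros((h, w), dtype=np.int32)

    for i, nuc in enumerate(spec.nuclei):
        mask = _disc(spec.shape, nuc.center, nuc.radius)
        img[0][mask] += nuc.amplitude
        labels[mask] = i + 1
        # faint nuclear counterstain in the foci channels so percentiles are
        # taken over a realistic intranuclear background
        for ch in range(1, spec.n_channels):
            img[ch][mask] += 0.1 * nuc.amplitude

    truth_rows = []
    for f in spec.foci:
        mask = _disc(spec.shape, f.center, f.radius)
        img[f.channel][mask] += f.amplitude
        parent = spec._parent_nucleus(f)
        truth_rows.append(
            {
                "channel": f.channel,
                "row": f.center[0],
                "col": f.center[1],
                "radius": f.radius,
                "amplitude": f.amplitude,
                "nucleus": parent + 1,
            }
        )

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)

    truth = pd.DataFrame(
        truth_rows, columns=["channel", "row", "col", "radius", "amplitude", "nucleus"]
    )
    return img, truth, labels


def random_image_spec(
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    n_nuclei: int = 5,
    foci_per_nucleus: tuple[int, int] = (1, 4),
    nucleus_radius: tuple[float, float] = (20.0, 28.0),
    focus_radius: tuple[float, float] = (1.8, 2.5),
    focus_amplitude: float = 400.0,
    n_channels: int = 2,
    background: float = 100.0,
    noise_sigma: float = 5.0,
) -> ImageSpec:
    """Draw a non-overlapping random field of nuclei with planted foci."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x5EED])
    h, w = shape
    nuclei: list[PlantedNucleus] = []
    attempts = 0
    while len(nuclei) < n_nuclei and attempts < 1000:
        attempts += 1
        radius = rng.uniform(*nucleus_radius)
        center = (
            rng.uniform(radius + 2, h - radius - 2),
            rng.uniform(radius + 2, w - radius - 2),
        )
        if all(
            np.hypot(center[0] - n.center[0], center[1] - n.center[1])
            > radius + n.radius + 4
            for n in nuclei
        ):
            nuclei.append(PlantedNucleus(center, radius))
    foci: list[PlantedFocus] = []
    for nuc in nuclei:
        for ch in range(1, n_channels):
            n_foci = rng.integers(foci_per_nucleus[0], foci_per_nucleus[1] + 1)
            placed: list[tuple[float, float]] = []
            tries = 0
            while len(placed) < n_foci and tries < 200:
                tries += 1
                fr = rng.uniform(*focus_radius)
                ang = rng.uniform(0, 2 * np.pi)
                dist = rng.uniform(0, nuc.radius - fr - 2)
                center = (
                    nuc.center[0] + dist * np.sin(ang),
                    nuc.center[1] + dist * np.cos(ang),
                )
                if all(
                    np.hypot(center[0] - p[0], center[1] - p[1]) > 2 * fr + 3
                    for p in placed
                ):
                    placed.append(center)
                    foci.append(PlantedFocus(center, fr, focus_amplitude, ch))
    return ImageSpec(
        shape=shape,
        nuclei=tuple(nuclei),
        foci=tuple(foci),
        n_channels=n_channels,
        background=background,
        noise_sigma=noise_sigma,
    )


def write_image(path, image: np.ndarray, truth: pd.DataFrame | None = None) -> None:
    """Write a multi-page TIFF (one page per channel) with a JSON sidecar."""
    import tifffile

    tifffile.imwrite(path, image.astype(np.float32))
    if truth is not None:
        sidecar = str(path).rsplit(".", 1)[0] + ".truth.json"
        truth.to_json(sidecar, orient="records", indent=1)
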