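"""The hit-selection cascade of the arrest-bypass screen.

The screen proceeds through fixed-cutoff stages, each fed by the replicate
medians from plate normalization:

1. **Primary screen** — robust z of the ICRF193 mitotic index must exceed
   2.5 on both instruments; pools depressing the cell-count z below -1.5 are
   excluded as toxic.
2. **Validation screen** — percent-of-control under ICRF193 must exceed the
   per-instrument cutoff (350 ArrayScan / 200 Acumen); pools elevating the
   no-drug mitotic fraction past its cutoff are excluded as drug-independent
   mitotic accumulators; the bleomycin cutoff annotates selectivity.
3. **Extended counter-screen** — ICRF193 POC above 350 and more than twice
   the POC of each comparator treatment (bleomycin, etoposide, ionizing
   radiation, no drug).
4. **Pool deconvolution** — an effect is on-target when at least two of the
   four individual duplexes exceed ICRF193 POC 150.

All comparisons are strict, exactly as the criteria are printed; ties fail.
Genes with missing measures are flagged unevaluable, never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from g2screen.synthetic_data import (
    ACUMEN,
    ARRAYSCAN,
    BLEO,
    ETOP,
    ICRF,
    IR,
    NO_DRUG,
)

EXCLUDED_TOXIC = "excluded_toxic"
EXCLUDED_ACCUMULATOR = "excluded_accumulator"
NOT_HIT = "not_hit"
PRIMARY_HIT = "primary_hit"
REPEATED = "repeated"
ICRF_SELECTIVE = "icrf_selective"
ON_TARGET = "on_target"
UNEVALUABLE = "unevaluable"


@dataclass(frozen=True)
class SelectionCriteria:
    """The cutoff table parameterizing every selection round."""

    primary_z: Mapping[str, float] = field(
        default_factory=lambda: {ARRAYSCAN: 2.5, ACUMEN: 2.5}
    )
    primary_logic: str = "and"  # both instruments must pass ("or" configurable)
    toxicity_z: float = -1.5
    toxicity_instrument: str = ACUMEN
    validation_icrf_poc: Mapping[str, float] = field(
        default_factory=lambda: {ARRAYSCAN: 350.0, ACUMEN: 200.0}
    )
    validation_bleo_poc: Mapping[str, float] = field(
        default_factory=lambda: {ARRAYSCAN: 200.0, ACUMEN: 200.0}
    )
    validation_nodrug_poc: Mapping[str, float] = field(
        default_factory=lambda: {ARRAYSCAN: 150.0, ACUMEN: 200.0}
    )
    counter_icrf_poc: float = 350.0
    counter_fold: float = 2.0
    counter_instrument: str = ARRAYSCAN
    counter_conditions: tuple[str, ...] = (BLEO, ETOP, IR, NO_DRUG)
    deconvolution_poc: float = 150.0
    deconvolution_instrument: str = ARRAYSCAN
    deconvolution_min_duplexes: int = 2

    def __post_init__(self) -> None:
        if self.primary_logic not in ("and", "or"):
            raise ValueError("primary_logic must be 'and' or 'or'")
        if self.counter_fold <= 1:
            raise ValueError("counter-screen fold factor must exceed 1")
        for m in (self.primary_z, self.validation_icrf_poc):
            if not all(np.isfinite(list(m.values()))):
                raise ValueError("all cutoffs must be finite")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SelectionCriteria":
        with open(path) as fh:
            d = json.load(fh)
        if "counter_conditions" in d:
            d["counter_conditions"] = tuple(d["counter_conditions"])
        return cls(**d)


# --------------------------------------------------------------------------
# stage rules
# --------------------------------------------------------------------------


def primary_hits(
    z_mi: pd.DataFrame,
    z_cell: pd.Series,
    criteria: SelectionCriteria | None = None,
) -> pd.DataFrame:
    """Primary-screen call per gene.

    ``z_mi`` is a genes x instruments frame of aggregated ICRF193
    mitotic-index z-scores; ``z_cell`` the aggregated cell-count z on the
    toxicity instrument.  Returns a frame with boolean columns ``pass_mi``
    (cutoff exceeded per the dual-instrument logic), ``toxic`` (cell-count
    rule failed), ``hit`` (both), ``toxic_excluded`` (passed the mitotic
    rules but excluded for toxicity) and ``unevaluable``.
    """
    criteria = criteria or SelectionCriteria()
    genes = z_mi.index
    per_inst = pd.DataFrame(index=genes)
    for inst, cutoff in criteria.primary_z.items():
        if inst not in z_mi.columns:
            raise KeyError(f"missing instrument stream {inst!r} in z-score table")
        per_inst[inst] = z_mi[inst] > cutoff
    missing = z_mi[list(criteria.primary_z)].isna().any(axis=1) | z_cell.reindex(
        genes
    ).isna()
    if criteria.primary_logic == "and":
        pass_mi = per_inst.all(axis=1)
    else:
        pass_mi = per_inst.any(axis=1)
    toxic = ~(z_cell.reindex(genes) > criteria.toxicity_z)
    res = pd.DataFrame(
        {
            "pass_mi": pass_mi & ~missing,
            "toxic": toxic & ~z_cell.reindex(genes).isna(),
            "unevaluable": missing,
        }
    )
    res["hit"] = res["pass_mi"] & ~res["toxic"] & ~res["unevaluable"]
    res["toxic_excluded"] = res["pass_mi"] & res["toxic"]
    return res


def validation_screen(
    poc: Mapping[str, pd.DataFrame],
    criteria: SelectionCriteria | None = None,
) -> pd.DataFrame:
    """Validation-round call per gene.

    ``poc`` maps condition -> genes x instruments POC frame and must cover
    the ICRF193, bleomycin and no-drug conditions.  A gene *repeats* when
    its ICRF POC exceeds the cutoff on every instrument listed in the
    criteria; genes whose no-drug POC reaches its cutoff on any instrument
    are excluded as drug-independent mitotic accumulators regardless of
    their ICRF score.  The bleomycin rule yields the ``bleo_selective``
    annotation, not an exclusion.
    """
    criteria = criteria or SelectionCriteria()
    for cond in (ICRF, BLEO, NO_DRUG):
        if cond not in poc:
            raise KeyError(f"validation requires POC for condition {cond!r}")
    icrf = poc[ICRF]
    genes = icrf.index

    def _per_instrument(frame: pd.DataFrame, cutoffs: Mapping[str, float], op):
        cols = {}
        for inst, cut in cutoffs.items():
            series = frame[inst] if inst in frame.columns else pd.Series(
                np.nan, index=genes
            )
            cols[inst] = op(series.reindex(genes), cut)
        return pd.DataFrame(cols, index=genes)

    repeats = _per_instrument(icrf, criteria.validation_icrf_poc, lambda s, c: s > c)
    missing_icrf = icrf.reindex(genes)[list(criteria.validation_icrf_poc)].isna().any(
        axis=1
    )
    nodrug = poc[NO_DRUG]
    accumulator = _per_instrument(
        nodrug, criteria.validation_nodrug_poc, lambda s, c: ~(s < c) & s.notna()
    ).any(axis=1)
    bleo = poc[BLEO]
    bleo_ok = _per_instrument(
        bleo, criteria.validation_bleo_poc, lambda s, c: s < c
    ).all(axis=1)

    res = pd.DataFrame(index=genes)
    res["unevaluable"] = missing_icrf
    res["accumulator"] = accumulator
    res["repeated"] = repeats.all(axis=1) & ~missing_icrf & ~accumulator
    res["bleo_selective"] = bleo_ok
    return res


def counter_screen(
    poc: Mapping[str, pd.Series] | pd.DataFrame,
    criteria: SelectionCriteria | None = None,
) -> pd.DataFrame:
    """Extended counter-screen: ICRF selectivity against four comparators.

    ``poc`` maps condition -> per-gene POC on the counter-screen instrument
    (or a frame with conditions as columns).  A gene is ICRF-selective iff
    its ICRF POC strictly exceeds the absolute cutoff and ``fold`` times the
    POC of every comparator condition.
    """
    criteria = criteria or SelectionCriteria()
    if isinstance(poc, pd.DataFrame):
        poc = {c: poc[c] for c in poc.columns}
    needed = (ICRF,) + tuple(criteria.counter_conditions)
    for cond in needed:
        if cond not in poc:
            raise KeyError(f"counter-screen requires POC for condition {cond!r}")
    icrf = poc[ICRF]
    genes = icrf.index
    res = pd.DataFrame(index=genes)
    res["pass_absolute"] = icrf > criteria.counter_icrf_poc
    missing = icrf.isna()
    fold_ok = pd.Series(True, index=genes)
    for cond in criteria.counter_conditions:
        comp = poc[cond].reindex(genes)
        fold_ok &= icrf > criteria.counter_fold * comp
        missing |= comp.isna()
    res["pass_fold"] = fold_ok
    res["unevaluable"] = missing
    res["selective"] = res["pass_absolute"] & res["pass_fold"] & ~missing
    return res


def deconvolute(
    duplex_poc: Sequence[float],
    criteria: SelectionCriteria | None = None,
) -> tuple[bool, int]:
    """On-target call for one pool from its four individual duplexes.

    Missing duplex measurements count as failures.  Returns the on-target
    boolean and the number of passing duplexes.
    """
    criteria = criteria or SelectionCriteria()
    values = list(duplex_poc)
    if len(values) > 4:
        raise ValueError("a pool has exactly 4 duplexes")
    arr = np.asarray(values, dtype=float)
    n_pass = int(np.sum(arr > criteria.deconvolution_poc))
    return n_pass >= criteria.deconvolution_min_duplexes, n_pass


def deconvolute_table(
    duplex_poc: pd.DataFrame, criteria: SelectionCriteria | None = None
) -> pd.DataFrame:
    """Vectorized deconvolution: a genes x (up to 4) duplex-POC frame."""
    criteria = criteria or SelectionCriteria()
    if duplex_poc.shape[1] > 4:
        raise ValueError("a pool has exactly 4 duplexes")
    n_pass = (duplex_poc > criteria.deconvolution_poc).sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "n_duplexes_pass": n_pass,
            "on_target": n_pass >= criteria.deconvolution_min_duplexes,
        },
        index=duplex_poc.index,
    )


# --------------------------------------------------------------------------
# funnel reporting
# --------------------------------------------------------------------------


def stage_percentage(count: int, parent: int) -> float:
    """Stage yield as a percentage of the previous stage."""
    if parent <= 0:
        raise ValueError("parent stage count must be positive")
    return 100.0 * count / parent


def stage_summary(
    stages: Sequence[tuple[str, int]],
    branches: Sequence[tuple[str, int, str]] = (),
) -> dict:
    """Screening-funnel report.

    ``stages`` is the ordered main funnel as (name, count) pairs; each entry
    reports its yield against the previous stage both to one decimal
    (``pct``) and rounded to an integer (``pct_int``).  ``branches`` are
    side counts (name, count, parent-stage name), e.g. exclusions, reported
    against their named parent.
    """
    counts = dict(stages)
    report: dict = {"stages": [], "branches": []}
    prev: int | None = None
    for name, count in stages:
        entry = {"stage": name, "count": int(count)}
        if prev is not None:
            entry["of"] = prev
            if prev > 0:
                pct = stage_percentage(count, prev)
                entry["pct"] = round(pct, 1)
                entry["pct_int"] = int(round(pct))
            else:  # an empty upstream stage carries no yield percentage
                entry["pct"] = None
                entry["pct_int"] = None
        report["stages"].append(entry)
        prev = count
    for name, count, parent in branches:
        if parent not in counts:
            raise KeyError(f"branch parent stage {parent!r} not in funnel")
        parent_count = counts[parent]
        pct = stage_percentage(count, parent_count) if parent_count > 0 else None
        report["branches"].append(
            {
                "stage": name,
                "count": int(count),
                "of": parent_count,
                "pct": round(pct, 1) if pct is not None else None,
                "pct_int": int(round(pct)) if pct is not None else None,
            }
        )
    return report


# --------------------------------------------------------------------------
# full cascade
# --------------------------------------------------------------------------


def duplex_poc_matrix(
    duplex_agg: pd.DataFrame, criteria: SelectionCriteria | None = None
) -> pd.DataFrame:
    """Genes x 4 matrix of duplex ICRF POC from an aggregated duplex campaign."""
    criteria = criteria or SelectionCriteria()
    dsub = duplex_agg[
        (duplex_agg["condition"] == ICRF)
        & (duplex_agg["instrument"] == criteria.deconvolution_instrument)
    ].sort_values(["gene", "reagent_id"])
    dsub = dsub.assign(position=dsub.groupby("gene").cumcount())
    if (dsub["position"] > 3).any():
        raise ValueError("a pool has exactly 4 duplexes")
    return dsub.pivot_table(
        index="gene", columns="position", values="POC_MI", aggfunc="first"
    )


def toxicity_zscores(
    normalized: pd.DataFrame, instrument: str = ACUMEN
) -> pd.Series:
    """Per-gene toxicity measure: median cell-count z over the whole campaign.

    Toxicity is a property of the reagent, not of the treatment, so the
    median is taken over every library well of the gene (all conditions and
    replicates) on the chosen instrument — far more reliable than the three
    primary-screen wells alone.
    """
    lib = normalized[
        normalized["gene"].notna() & (normalized["instrument"] == instrument)
    ]
    return lib.groupby("gene")["z_cellcount"].median()


def run_cascade(
    pool_agg: pd.DataFrame,
    duplex_agg: pd.DataFrame | None = None,
    criteria: SelectionCriteria | None = None,
    z_cell: pd.Series | None = None,
) -> pd.DataFrame:
    """Run every selection stage on aggregated campaign tables.

    ``pool_agg`` / ``duplex_agg`` are the tidy outputs of
    :func:`g2screen.plate_normalization.aggregate_genes` for the pool and
    deconvolution campaigns.  ``z_cell`` is the per-gene toxicity measure
    (preferably :func:`toxicity_zscores` over the full campaign); when
    omitted it falls back to the ICRF-condition aggregated cell-count z.
    Returns the per-gene hit table: stage-by-stage booleans, the measures
    each rule compared, and a final ``classification`` (the furthest stage
    reached, or an exclusion reason).
    """
    from g2screen.plate_normalization import measure_matrix

    criteria = criteria or SelectionCriteria()

    z_mi = measure_matrix(pool_agg, "z_MI", ICRF)
    if z_cell is None:
        z_cell_mat = measure_matrix(pool_agg, "z_cellcount", ICRF)
        if criteria.toxicity_instrument not in z_cell_mat.columns:
            raise KeyError(
                f"missing toxicity instrument {criteria.toxicity_instrument!r}"
            )
        z_cell = z_cell_mat[criteria.toxicity_instrument]
    genes = z_mi.index

    table = pd.DataFrame(index=genes)
    for inst in z_mi.columns:
        table[f"z_icrf_{inst}"] = z_mi[inst]
    table["z_cellcount"] = z_cell

    prim = primary_hits(z_mi, z_cell, criteria)
    table["primary_pass_mi"] = prim["pass_mi"]
    table["toxic"] = prim["toxic"]
    table["primary_hit"] = prim["hit"]
    table["unevaluable_primary"] = prim["unevaluable"]

    poc = {c: measure_matrix(pool_agg, "POC_MI", c) for c in pool_agg["condition"].unique()}
    for cond, frame in poc.items():
        for inst in frame.columns:
            table[f"poc_{cond}_{inst}"] = frame[inst].reindex(genes)

    val = validation_screen(poc, criteria)
    table["accumulator"] = val["accumulator"].reindex(genes).fillna(False)
    table["repeated"] = (
        table["primary_hit"] & val["repeated"].reindex(genes).fillna(False)
    )
    table["bleo_selective"] = val["bleo_selective"].reindex(genes).fillna(False)

    inst = criteria.counter_instrument
    counter_poc = {
        cond: frame[inst].reindex(genes)
        if inst in frame.columns
        else pd.Series(np.nan, index=genes)
        for cond, frame in poc.items()
    }
    ctr = counter_screen(counter_poc, criteria)
    table["selective"] = table["repeated"] & ctr["selective"].reindex(genes).fillna(
        False
    )

    if duplex_agg is not None:
        dvals = duplex_poc_matrix(duplex_agg, criteria)
        dec = deconvolute_table(dvals.reindex(genes), criteria)
        table["n_duplexes_pass"] = dec["n_duplexes_pass"].reindex(genes).fillna(0).astype(int)
        table["on_target"] = table["selective"] & dec["on_target"].reindex(genes).fillna(False)
    else:
        table["n_duplexes_pass"] = pd.NA
        table["on_target"] = False

    def _classify(row) -> str:
        if row["unevaluable_primary"]:
            return UNEVALUABLE
        if row["toxic"]:
            return EXCLUDED_TOXIC
        if not row["primary_hit"]:
            return NOT_HIT
        if row["accumulator"]:
            return EXCLUDED_ACCUMULATOR
        if row["on_target"]:
            return ON_TARGET
        if row["selective"]:
            return ICRF_SELECTIVE
        if row["repeated"]:
            return REPEATED
        return PRIMARY_HIT

    table["classification"] = table.apply(_classify, axis=1)
    return table


def cascade_funnel(table: pd.DataFrame) -> dict:
    """Funnel report of a hit table produced by :func:`run_cascade`."""
    n_primary = int(table["primary_hit"].sum())
    stages = [
        ("library", int(len(table))),
        ("primary", n_primary),
        ("repeated", int(table["repeated"].sum())),
        ("icrf_selective", int(table["selective"].sum())),
        ("on_target", int(table["on_target"].sum())),
    ]
    branches = [
        ("excluded_toxic", int((table["classification"] == EXCLUDED_TOXIC).sum()), "library"),
        (
            "excluded_accumulator",
            int((table["classification"] == EXCLUDED_ACCUMULATOR).sum()),
            "primary",
        ),
    ]
    return stage_summary(stages, branches)


def analyze_campaign(
    normalized: pd.DataFrame,
    duplex_normalized: pd.DataFrame | None = None,
    criteria: SelectionCriteria | None = None,
) -> pd.DataFrame:
    """Aggregate normalized well tables and run the full selection cascade.

    The toxicity measure is the campaign-wide per-gene cell-count z median
    (see :func:`toxicity_zscores`).
    """
    from g2screen.plate_normalization import aggregate_genes

    criteria = criteria or SelectionCriteria()
    pool_agg = aggregate_genes(normalized)
    z_cell = toxicity_zscores(normalized, criteria.toxicity_instrument)
    duplex_agg = (
        aggregate_genes(duplex_normalized) if duplex_normalized is not None else None
    )
    return run_cascade(pool_agg, duplex_agg, criteria, z_cell=z_cell)
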