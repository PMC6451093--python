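"""Plate-level normalization of well counts.

Three measures are derived from the raw counts of each well:

* mitotic index, ``MI = 100 x MPM2-positive / total cells``;
* a robust z-score, ``(well - plate median) / plate MAD``, computed per
  plate, instrument and condition over the library wells (controls are
  non-representative by design and excluded from the plate statistics);
* percent of control, ``POC = 100 x well / mean(Risc-free wells)`` of the
  same plate, replicate, instrument and condition.

The MAD is unscaled by default (no 1.4826 consistency factor), matching the
screen's plate-normalization formula; ``mad_scaled=True`` applies the factor.
Replicates are aggregated as the median of the available values.  Missing
wells propagate as missing, never as zero.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from g2screen.synthetic_data import (
    CONTROL_REAGENTS,
    NOC_ONLY,
    RISC_FREE,
    WELL_COLUMNS,
)

MAD_CONSISTENCY = 1.4826

FLAG_CONTROL = "control"
FLAG_QC_FAIL = "qc_fail"
FLAG_UNDEFINED = "undefined_well"
FLAG_NO_CONTROL = "missing_control"


class QCError(ValueError):
    """A plate failed quality control (degenerate MAD or missing controls)."""


class UndefinedWellError(ValueError):
    """A well's measure is undefined (zero cell count)."""


# --------------------------------------------------------------------------
# scalar / vector primitives
# --------------------------------------------------------------------------


def mitotic_index(mpm2_count: int, cell_count: int) -> float:
    """Percentage of MPM2-positive cells among all cells of a well."""
    if cell_count <= 0:
        raise UndefinedWellError("mitotic index undefined for zero cell count")
    if not 0 <= mpm2_count <= cell_count:
        raise ValueError("mpm2_count must lie in [0, cell_count]")
    return 100.0 * mpm2_count / cell_count


def robust_zscore(
    values: Sequence[float], scaled: bool = False, min_wells: int = 8
) -> np.ndarray:
    """Median/MAD z-scores of one plate's values.

    Raises :class:`QCError` when the MAD is zero (the plate carries no
    usable spread) or fewer than ``min_wells`` finite values are present.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < min_wells:
        raise QCError(f"need >= {min_wells} wells to normalize a plate")
    med = np.median(finite)
    mad = np.median(np.abs(finite - med))
    if mad == 0:
        raise QCError("plate MAD is zero; no z-scores emitted")
    if scaled:
        mad *= MAD_CONSISTENCY
    return (arr - med) / mad


def percent_of_control(
    value: float | Sequence[float], control_values: Sequence[float]
) -> float | np.ndarray:
    """100 x value / mean of the same-plate, same-condition Risc-free wells."""
    controls = np.asarray(control_values, dtype=float)
    controls = controls[np.isfinite(controls)]
    if controls.size == 0:
        raise QCError("no control wells available for POC")
    mean = controls.mean()
    if mean <= 0:
        raise QCError("control mean must be positive for POC")
    return 100.0 * np.asarray(value, dtype=float) / mean if np.ndim(value) else (
        100.0 * float(value) / mean
    )


def aggregate_replicates(values: Iterable[float]) -> float:
    """Median of the available technical replicates; NaN if all are missing."""
    arr = np.asarray(list(values), dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        return float("nan")
    return float(np.median(finite))


def normalize_to_nocodazole(mi: float, noc_only_mean: float) -> float:
    """Mitotic index as a percentage of the nocodazole-only trapped fraction."""
    if noc_only_mean <= 0:
        raise QCError("nocodazole-only mean must be positive")
    return 100.0 * mi / noc_only_mean


# --------------------------------------------------------------------------
# campaign-level pipeline
# --------------------------------------------------------------------------


def _plate_groups(df: pd.DataFrame):
    return df.groupby(["plate_id", "replicate", "instrument", "condition"], sort=False)


def normalize_wells(
    df: pd.DataFrame,
    control_reagent: str = RISC_FREE,
    mad_scaled: bool = False,
    min_wells: int = 8,
) -> tuple[pd.DataFrame, dict]:
    """Add MI, z_MI, z_cellcount, POC_MI and flags to a well-level table.

    Returns the annotated table and a plate-QC report.  Library wells alone
    define each plate's median and MAD; POC controls are the
    ``control_reagent`` wells of the same plate, replicate, instrument and
    condition.  Plates with zero MAD are flagged and emit no z-scores;
    wells with zero cells are flagged and carry missing measures.
    """
    out = df.copy()
    is_control = out["reagent_id"].isin(CONTROL_REAGENTS)
    undefined = out["cell_count"] <= 0
    bad = (out["mpm2_count"] > out["cell_count"]) & ~undefined
    if bad.any():
        raise ValueError("mpm2_count exceeds cell_count in input wells")

    out["MI"] = np.where(
        undefined, np.nan, 100.0 * out["mpm2_count"] / out["cell_count"].replace(0, 1)
    )
    out["z_MI"] = np.nan
    out["z_cellcount"] = np.nan
    out["POC_MI"] = np.nan
    flags = np.where(is_control, FLAG_CONTROL, "")
    flags = np.where(
        undefined, np.char.add(np.char.add(flags.astype("<U64"), ";"), FLAG_UNDEFINED), flags
    )
    out["flags"] = flags

    qc: dict[str, dict] = {}
    for keys, idx in _plate_groups(out).groups.items():
        plate_id, rep, instrument, condition = keys
        sub = out.loc[idx]
        lib = sub[~sub["reagent_id"].isin(CONTROL_REAGENTS)]
        entry: dict = {
            "plate_id": plate_id,
            "replicate": int(rep),
            "instrument": instrument,
            "condition": condition,
            "n_wells": int(len(sub)),
            "n_library_wells": int(len(lib)),
            "qc_pass": True,
            "reasons": [],
        }
        control_only = len(lib) == 0
        entry["control_only"] = control_only
        # z-scores from library wells only; control-only groups (e.g. the
        # nocodazole-only reference wells) carry no plate statistics of
        # their own and are not a QC failure
        for measure, col in () if control_only else (
            ("MI", "z_MI"),
            ("cell_count", "z_cellcount"),
        ):
            lib_vals = lib[measure].to_numpy(dtype=float)
            finite = lib_vals[np.isfinite(lib_vals)]
            if finite.size < min_wells:
                entry["qc_pass"] = False
                entry["reasons"].append(f"too few library wells for {measure}")
                continue
            med = float(np.median(finite))
            mad = float(np.median(np.abs(finite - med)))
            entry[f"{measure}_median"] = med
            entry[f"{measure}_mad"] = mad
            if mad == 0:
                entry["qc_pass"] = False
                entry["reasons"].append(f"zero MAD for {measure}")
                continue
            if mad_scaled:
                mad *= MAD_CONSISTENCY
            out.loc[idx, col] = (sub[measure].to_numpy(dtype=float) - med) / mad

        # POC against same-condition controls of the same plate read
        ctrl = sub[(sub["reagent_id"] == control_reagent)]
        ctrl_mi = ctrl["MI"].to_numpy(dtype=float)
        ctrl_mi = ctrl_mi[np.isfinite(ctrl_mi)]
        if ctrl_mi.size == 0 or ctrl_mi.mean() <= 0:
            if not control_only:
                entry["qc_pass"] = False
                entry["reasons"].append("no usable POC control wells")
            out.loc[idx, "flags"] = out.loc[idx, "flags"].astype(str) + ";" + FLAG_NO_CONTROL
        else:
            entry["control_mean_MI"] = float(ctrl_mi.mean())
            out.loc[idx, "POC_MI"] = 100.0 * sub["MI"].to_numpy(dtype=float) / ctrl_mi.mean()

        if not entry["qc_pass"]:
            out.loc[idx, "flags"] = out.loc[idx, "flags"].astype(str) + ";" + FLAG_QC_FAIL
        qc[f"{plate_id}|r{rep}|{instrument}|{condition}"] = entry

    out["flags"] = out["flags"].str.strip(";")
    return out, qc


def aggregate_genes(normalized: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicates: per (gene, condition, instrument) medians.

    Uses library wells only.  Each row carries the replicate medians of MI,
    z_MI, z_cellcount and POC_MI plus the number of replicates observed and
    missing.  Wells on QC-failed plates contribute missing values.
    """
    lib = normalized[~normalized["reagent_id"].isin(CONTROL_REAGENTS)].copy()
    lib = lib.dropna(subset=["gene"])

    keys = ["gene", "reagent_id", "condition", "instrument"]
    grouped = lib.groupby(keys, sort=True)
    agg = grouped[["MI", "z_MI", "z_cellcount", "POC_MI"]].median()
    agg["n_replicates"] = grouped["replicate"].nunique()
    agg["n_missing"] = grouped["MI"].apply(lambda s: int(s.isna().sum()))
    return agg.reset_index()


def measure_matrix(
    agg: pd.DataFrame, measure: str, condition: str
) -> pd.DataFrame:
    """Pivot an aggregated table to genes x instruments for one measure."""
    sub = agg[agg["condition"] == condition]
    return sub.pivot_table(
        index="gene", columns="instrument", values=measure, aggfunc="first"
    )


def nocodazole_reference(normalized: pd.DataFrame) -> float:
    """Mean MI of the nocodazole-only trapped control wells of a campaign."""
    noc = normalized[normalized["condition"] == NOC_ONLY]
    vals = noc["MI"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise QCError("campaign has no nocodazole-only wells")
    return float(vals.mean())
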