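"""Closed-form quantifications used in the validation experiments.

* relative qPCR expression by the 2^-ddCT method with a reference gene
  (GAPDH) and a calibrator sample;
* sister-chromatid-intertwine (catenation) scoring on chromosome spreads,
  as the percentage of catenated sister-chromatid pairs per cell;
* segregation-defect rates (chromatin bridges, lagging chromosomes,
  PICH-positive ultrafine bridges) as percentages of scored cells, each
  class reported independently.

Dispersion is reported as the standard error over cells or experiments, as
in the figure legends; no inferential tests are computed here.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

REFERENCE_GENE = "GAPDH"

CT_COLUMNS = ("sample", "gene", "ct")


def _mean_ct(ct: pd.DataFrame, sample: str, gene: str) -> float:
    """Mean of a sample's replicate CTs for one gene; NaN when absent."""
    vals = ct.loc[(ct["sample"] == sample) & (ct["gene"] == gene), "ct"]
    vals = pd.to_numeric(vals, errors="coerce").dropna()
    if vals.empty:
        return float("nan")
    if (vals <= 0).any() or not np.isfinite(vals).all():
        raise ValueError("CT values must be finite and positive")
    return float(vals.mean())


def ddct_expression(
    ct: pd.DataFrame,
    target: str,
    sample: str,
    calibrator: str,
    reference: str = REFERENCE_GENE,
) -> float:
    """Relative expression of ``target`` in ``sample`` vs ``calibrator``.

    Replicate CTs are averaged on the CT scale; then
    ``dCT = CT_target - CT_reference`` per sample,
    ``ddCT = dCT_sample - dCT_calibrator``, and the fold change is
    ``2**-ddCT``.  Missing CTs yield NaN, never a silent zero.
    """
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"CT table missing columns: {missing}")
    dct_sample = _mean_ct(ct, sample, target) - _mean_ct(ct, sample, reference)
    dct_cal = _mean_ct(ct, calibrator, target) - _mean_ct(ct, calibrator, reference)
    ddct = dct_sample - dct_cal
    if np.isnan(ddct):
        return float("nan")
    return float(2.0 ** (-ddct))


def ddct_table(
    ct: pd.DataFrame, calibrator: str, reference: str = REFERENCE_GENE
) -> pd.DataFrame:
    """Fold change of every (sample, gene) pair against the calibrator."""
    genes = [g for g in ct["gene"].unique() if g != reference]
    samples = ct["sample"].unique()
    rows = [
        {
            "sample": s,
            "gene": g,
            "fold_change": ddct_expression(ct, g, s, calibrator, reference),
        }
        for s in samples
        for g in genes
    ]
    return pd.DataFrame(rows)


def sci_score(spreads: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Catenation scores from chromosome spreads.

    ``spreads`` needs columns ``condition``, ``cell``, ``total`` (scored
    sister-chromatid pairs) and ``catenated``.  Returns the per-cell
    percentages and the per-condition mean with its standard error over
    cells.  Cells with zero scored pairs are excluded and logged in the
    per-cell table's ``excluded`` column.
    """
    for col in ("condition", "cell", "total", "catenated"):
        if col not in spreads.columns:
            raise ValueError(f"spread table missing column {col!r}")
    if (spreads["catenated"] > spreads["total"]).any():
        raise ValueError("catenated pairs cannot exceed total pairs")
    per_cell = spreads.copy()
    per_cell["excluded"] = per_cell["total"] <= 0
    per_cell["pct_catenated"] = np.where(
        per_cell["excluded"],
        np.nan,
        100.0 * per_cell["catenated"] / per_cell["total"].replace(0, 1),
    )
    usable = per_cell[~per_cell["excluded"]]
    summary = (
        usable.groupby("condition")["pct_catenated"]
        .agg(
            mean="mean",
            se=lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
            n_cells="count",
        )
        .reset_index()
    )
    return per_cell, summary


def segregation_defect_rate(
    scores: pd.DataFrame, classes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Percentage of cells positive for each defect class.

    ``scores`` holds one row per cell with boolean columns per class
    (e.g. ``bridge``, ``lagging``, ``ultrafine``); a cell may count in
    several classes.  Optionally grouped by a ``condition`` column.
    """
    if len(scores) == 0:
        raise ValueError("no cells scored")
    classes = list(
        classes
        if classes is not None
        else [c for c in scores.columns if c not in ("condition", "cell")]
    )
    group_cols = ["condition"] if "condition" in scores.columns else []

    def _rates(df: pd.DataFrame) -> pd.Series:
        n = len(df)
        out = {f"pct_{c}": 100.0 * df[c].astype(bool).sum() / n for c in classes}
        out["n_cells"] = n
        return pd.Series(out)

    if group_cols:
        return scores.groupby(group_cols).apply(_rates, include_groups=False).reset_index()
    return _rates(scores).to_frame().T
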