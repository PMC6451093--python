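"""Nuclear-foci quantification for immunofluorescence and PLA images.

Nuclei are segmented from the DAPI channel (global Otsu threshold, hole
filling, minimum-area filter); foci in each signal channel are the connected
pixel regions above a per-nucleus intensity percentile (default 97.5) with
at least a minimum area (default 4 px).  Foci counts are normalized to
nuclear area — drug treatments alter nuclear size, and counts per unit area
remove that bias.  Colocalization is directional: the percentage of
channel-A foci that satisfy the chosen criterion (mask overlap, centroid in
mask, or centroid distance) against any channel-B focus of the same nucleus.

Both detection and colocalization are invariant under positive affine
rescaling of any channel's intensities, since thresholds are percentiles of
the data themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

COLOC_MODES = ("overlap", "centroid_in_mask", "centroid_distance")


@dataclass(frozen=True)
class FociConfig:
    """Tunable parameters of segmentation, detection and colocalization."""

    percentile: float = 97.5  # per-nucleus intensity percentile
    min_focus_area: int = 4  # pixels
    coloc_mode: str = "overlap"
    coloc_distance: float = 3.0  # pixels, for centroid_distance mode
    min_nucleus_area: int = 100  # pixels
    threshold_method: str = "otsu"

    def __post_init__(self) -> None:
        if not 50 < self.percentile < 100:
            raise ValueError("percentile must lie in (50, 100)")
        if self.coloc_mode not in COLOC_MODES:
            raise ValueError(f"coloc_mode must be one of {COLOC_MODES}")
        if self.coloc_distance < 0:
            raise ValueError("coloc_distance must be >= 0")


@dataclass
class Nuclei:
    """Labeled nucleus masks of one image (labels start at 1)."""

    labels: np.ndarray  # int32 label image, 0 = background
    table: pd.DataFrame  # label, area, centroid, bbox

    def __len__(self) -> int:
        return len(self.table)

    def mask(self, label_id: int) -> np.ndarray:
        return self.labels == label_id


@dataclass
class FociSet:
    """Detected foci of one channel, tied to their parent nuclei."""

    labels: np.ndarray  # focus label image (0 = none)
    table: pd.DataFrame  # focus, nucleus, area, centroid, peak/mean intensity
    channel: int | None = None
    nuclear_areas: pd.Series | None = None  # per-nucleus areas for density

    def __len__(self) -> int:
        return len(self.table)


def segment_nuclei(dapi: np.ndarray, config: FociConfig | None = None) -> Nuclei:
    """Segment nuclei from the DAPI channel.

    Global Otsu threshold, binary hole filling, connected-component
    labeling, and removal of objects below the minimum area.  An all-flat
    image yields an empty set.
    """
    config = config or FociConfig()
    img = np.asarray(dapi, dtype=float)
    if img.ndim != 2:
        raise ValueError("DAPI channel must be a 2-D image")
    if np.ptp(img) == 0:
        return Nuclei(np.zeros(img.shape, dtype=np.int32), _empty_nucleus_table())
    thr = threshold_otsu(img)
    binary = ndimage.binary_fill_holes(img > thr)
    labels, _ = ndimage.label(binary)
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    next_id = 0
    for prop in regionprops(labels):
        if prop.area < config.min_nucleus_area:
            continue
        next_id += 1
        keep[prop.label] = next_id
        rows.append(
            {
                "label": next_id,
                "area": int(prop.area),
                "centroid_row": prop.centroid[0],
                "centroid_col": prop.centroid[1],
                "bbox_min_row": prop.bbox[0],
                "bbox_min_col": prop.bbox[1],
                "bbox_max_row": prop.bbox[2],
                "bbox_max_col": prop.bbox[3],
            }
        )
    relabeled = keep[labels]
    table = pd.DataFrame(rows) if rows else _empty_nucleus_table()
    return Nuclei(relabeled.astype(np.int32), table)


def _empty_nucleus_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "label",
            "area",
            "centroid_row",
            "centroid_col",
            "bbox_min_row",
            "bbox_min_col",
            "bbox_max_row",
            "bbox_max_col",
        ]
    )


def detect_foci(
    image: np.ndarray,
    nuclei: Nuclei,
    config: FociConfig | None = None,
    channel: int | None = None,
) -> FociSet:
    """Detect intranuclear foci with a per-nucleus percentile filter.

    Within each nucleus, pixels strictly above that nucleus's intensity
    percentile form candidate regions; connected regions of at least the
    minimum area become foci.  Pixels outside every nucleus are never
    considered, so foci cannot fall outside nuclei.  A uniform-intensity
    nucleus yields no foci (no pixel strictly exceeds the percentile of a
    constant sample).
    """
    config = config or FociConfig()
    img = np.asarray(image, dtype=float)
    if img.shape != nuclei.labels.shape:
        raise ValueError("image and nucleus masks must share geometry")
    foci_labels = np.zeros(img.shape, dtype=np.int32)
    rows = []
    next_id = 0
    for nucleus_id in nuclei.table["label"].astype(int):
        mask = nuclei.labels == nucleus_id
        vals = img[mask]
        thr = np.percentile(vals, config.percentile)
        cand = mask & (img > thr)
        if not cand.any():
            continue
        lab, n = ndimage.label(cand)
        for prop in regionprops(lab, intensity_image=img):
            if prop.area < config.min_focus_area:
                continue
            next_id += 1
            region = lab == prop.label
            foci_labels[region] = next_id
            rows.append(
                {
                    "focus": next_id,
                    "nucleus": nucleus_id,
                    "channel": channel,
                    "area": int(prop.area),
                    "centroid_row": prop.centroid[0],
                    "centroid_col": prop.centroid[1],
                    "peak_intensity": float(prop.intensity_max),
                    "mean_intensity": float(prop.intensity_mean),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "focus",
            "nucleus",
            "channel",
            "area",
            "centroid_row",
            "centroid_col",
            "peak_intensity",
            "mean_intensity",
        ],
    )
    areas = nuclei.table.set_index("label")["area"] if len(nuclei) else pd.Series(dtype=float)
    return FociSet(foci_labels, table, channel=channel, nuclear_areas=areas)


def foci_density(
    foci: FociSet, nuclei: Nuclei, per_pixels: float = 1000.0
) -> tuple[pd.DataFrame, float]:
    """Foci per unit nuclear area (default per 1000 px), per nucleus and image.

    The image summary is the mean over nuclei, so fields dominated by a few
    large nuclei are not biased by absolute counts.
    """
    counts = foci.table.groupby("nucleus").size() if len(foci) else pd.Series(dtype=int)
    rows = []
    for nucleus_id, area in nuclei.table.set_index("label")["area"].items():
        n = int(counts.get(nucleus_id, 0))
        rows.append(
            {
                "nucleus": int(nucleus_id),
                "area": int(area),
                "n_foci": n,
                "density": per_pixels * n / area,
            }
        )
    per_nucleus = pd.DataFrame(rows, columns=["nucleus", "area", "n_foci", "density"])
    image_mean = float(per_nucleus["density"].mean()) if len(per_nucleus) else float("nan")
    return per_nucleus, image_mean


def colocalization_fraction(
    foci_a: FociSet,
    foci_b: FociSet,
    mode: str | None = None,
    distance: float | None = None,
    config: FociConfig | None = None,
) -> float:
    """Percentage of A-foci colocalized with any B-focus of the same nucleus.

    Directional (fraction of A in B, not symmetric).  With no A-foci the
    fraction is undefined and returned as NaN, never as 0.
    """
    config = config or FociConfig()
    mode = mode or config.coloc_mode
    distance = config.coloc_distance if distance is None else distance
    if mode not in COLOC_MODES:
        raise ValueError(f"unknown colocalization mode {mode!r}")
    if len(foci_a) == 0:
        return float("nan")
    n_coloc = 0
    b_by_nucleus = (
        dict(tuple(foci_b.table.groupby("nucleus"))) if len(foci_b) else {}
    )
    for _, a in foci_a.table.iterrows():
        b_in_nucleus = b_by_nucleus.get(a["nucleus"])
        if b_in_nucleus is None or len(b_in_nucleus) == 0:
            continue
        if mode == "overlap":
            a_mask = foci_a.labels == a["focus"]
            if (foci_b.labels[a_mask] > 0).any():
                n_coloc += 1
        elif mode == "centroid_in_mask":
            # test point: the centroid, snapped to the focus's nearest own
            # pixel when a non-convex region does not contain its centroid
            r = int(round(a["centroid_row"]))
            c = int(round(a["centroid_col"]))
            r = min(max(r, 0), foci_b.labels.shape[0] - 1)
            c = min(max(c, 0), foci_b.labels.shape[1] - 1)
            if foci_a.labels[r, c] != a["focus"]:
                rr, cc = np.nonzero(foci_a.labels == a["focus"])
                i = np.argmin(
                    (rr - a["centroid_row"]) ** 2 + (cc - a["centroid_col"]) ** 2
                )
                r, c = int(rr[i]), int(cc[i])
            if foci_b.labels[r, c] > 0:
                n_coloc += 1
        else:  # centroid_distance
            d = np.hypot(
                b_in_nucleus["centroid_row"] - a["centroid_row"],
                b_in_nucleus["centroid_col"] - a["centroid_col"],
            )
            if (d <= distance).any():
                n_coloc += 1
    return 100.0 * n_coloc / len(foci_a)


def analyze_image(
    image: np.ndarray,
    config: FociConfig | None = None,
    coloc_pairs: Sequence[tuple[int, int]] = (),
) -> dict:
    """Full quantification of a multi-channel image (channel 0 = DAPI).

    Returns nuclei, per-channel foci sets, the per-nucleus summary table
    (areas, counts, densities per channel) and directional colocalization
    percentages for the requested (A, B) channel pairs.
    """
    config = config or FociConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 3:
        raise ValueError("expected a (channels, H, W) image")
    nuclei = segment_nuclei(img[0], config)
    foci = {
        ch: detect_foci(img[ch], nuclei, config, channel=ch)
        for ch in range(1, img.shape[0])
    }
    summary = nuclei.table[["label", "area"]].rename(columns={"label": "nucleus"})
    for ch, fs in foci.items():
        per_nucleus, _ = foci_density(fs, nuclei)
        summary = summary.merge(
            per_nucleus[["nucleus", "n_foci", "density"]].rename(
                columns={"n_foci": f"n_foci_ch{ch}", "density": f"density_ch{ch}"}
            ),
            on="nucleus",
            how="left",
        )
    coloc = {
        (a, b): colocalization_fraction(foci[a], foci[b], config=config)
        for a, b in coloc_pairs
    }
    return {
        "nuclei": nuclei,
        "foci": foci,
        "per_nucleus": summary,
        "colocalization": coloc,
    }


def match_foci(
    detected: pd.DataFrame, truth: pd.DataFrame, max_distance: float = 2.0
) -> tuple[int, int, int]:
    """Greedy centroid matching of detected vs planted foci.

    Returns (true positives, false positives, false negatives); each planted
    focus matches at most one detection within ``max_distance`` pixels.
    """
    if len(truth) == 0:
        return 0, len(detected), 0
    if len(detected) == 0:
        return 0, 0, len(truth)
    det = detected[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    tru = truth[["row", "col"]].to_numpy(dtype=float)
    dmat = np.hypot(
        det[:, None, 0] - tru[None, :, 0], det[:, None, 1] - tru[None, :, 1]
    )
    matched_det: set[int] = set()
    matched_tru: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(dmat, axis=None), dmat.shape))[0]
    for i, j in order:
        if dmat[i, j] > max_distance:
            break
        if i in matched_det or j in matched_tru:
            continue
        matched_det.add(int(i))
        matched_tru.add(int(j))
    tp = len(matched_tru)
    return tp, len(detected) - tp, len(truth) - tp
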