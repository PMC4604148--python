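"""Whole-cell-normalized compartment intensity time-courses.

Each probe frame is divided by its whole-cell ROI mean (renormalized every
frame, so photobleaching and focal drift cancel), and the mean normalized
intensity over the marker-derived compartment mask is reported per frame.
A value above 1 means the probe is enriched at the compartment relative to
the cell average; dissociation of a membrane probe drives the value toward 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .image import CellImage
from .wavelet import CompartmentMask, MaskParams, mask_timelapse

__all__ = [
    "normalized_intensity_image",
    "compartment_mean",
    "timecourse",
    "aggregate_cohort",
    "percent_change",
    "select_representative",
    "guess_roi",
]

logger = logging.getLogger(__name__)


def normalized_intensity_image(raw: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Divide every ROI pixel by the ROI mean; zero outside the ROI.

    The output's ROI mean is exactly 1 by construction, making values
    directly interpretable as fold-enrichment over the whole cell.
    """
    raw = np.asarray(raw, dtype=np.float64)
    roi = np.asarray(roi, dtype=bool)
    if raw.shape != roi.shape:
        raise ValueError("image and ROI shapes differ")
    if not roi.any():
        raise ValueError("ROI is empty")
    m = raw[roi].mean()
    if m <= 0:
        raise ValueError("ROI mean must be > 0 for normalization")
    out = np.zeros_like(raw)
    out[roi] = raw[roi] / m
    return out


def compartment_mean(norm: np.ndarray, mask: CompartmentMask | np.ndarray,
                     roi: np.ndarray | None = None) -> float:
    """Mean normalized intensity over the compartment mask (within the ROI).

    Returns NaN with a logged warning if the mask is empty within the ROI —
    a frame with no detected compartments becomes a missing value rather
    than aborting the run.
    """
    m = mask.mask if isinstance(mask, CompartmentMask) else np.asarray(mask, bool)
    if roi is not None:
        m = m & np.asarray(roi, bool)
    if not m.any():
        logger.warning("empty compartment mask within ROI; reporting NaN")
        return float("nan")
    return float(norm[m].mean())


def timecourse(
    stack: CellImage,
    probe_channels: list[str] | tuple[str, ...],
    marker_channel: str,
    mask_params: MaskParams = MaskParams(),
    cell_id: str = "cell",
) -> pd.DataFrame:
    """Per-frame normalized compartment intensity for each probe channel.

    At every frame the compartment mask is rebuilt from that frame's marker
    image, each probe frame is renormalized to its whole-cell ROI mean, and
    the masked mean is recorded. Returns a tidy table with one row per
    (frame, probe): cell_id, frame, time (minutes), probe_channel,
    compartment, normalized_intensity, n_mask_pixels.
    """
    if stack.roi is None:
        raise ValueError("stack has no whole-cell ROI")
    for ch in list(probe_channels) + [marker_channel]:
        stack.channel_index(ch)  # raises KeyError on unknown labels
    masks = mask_timelapse(stack, marker_channel, params=mask_params)
    rows = []
    for t, cmask in enumerate(masks):
        eff = cmask.mask & stack.roi
        for probe in probe_channels:
            norm = normalized_intensity_image(stack.frame(t, probe), stack.roi)
            value = compartment_mean(norm, eff) if eff.any() else float("nan")
            if not eff.any():
                logger.warning("frame %d: empty mask; missing row", t)
            rows.append(
                {
                    "cell_id": cell_id,
                    "frame": t,
                    "time": t * stack.frame_interval,
                    "probe_channel": probe,
                    "compartment": marker_channel,
                    "normalized_intensity": value,
                    "n_mask_pixels": int(eff.sum()),
                }
            )
    return pd.DataFrame(rows)


def aggregate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean ± s.e.m. per (frame, probe) across cells.

    Missing per-cell values (NaN) are dropped; ``n_cells`` counts the cells
    actually contributing at each point. s.e.m. = sample s.d. / sqrt(n).
    """
    valid = table.dropna(subset=["normalized_intensity"])
    grouped = valid.groupby(["frame", "probe_channel"], as_index=False).agg(
        time=("time", "first"),
        mean=("normalized_intensity", "mean"),
        sd=("normalized_intensity", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        n_cells=("cell_id", "nunique"),
    )
    grouped["sem"] = grouped["sd"] / np.sqrt(grouped["n_cells"])
    return grouped.drop(columns="sd")


def percent_change(
    table: pd.DataFrame, event_frame: int, plateau_frames: int = 3
) -> pd.DataFrame:
    """Per-cell percent change of compartment intensity after the event.

    Baseline is the mean of all pre-event frames; the plateau is the mean of
    the last ``plateau_frames`` frames. Change is reported in percent of the
    baseline (negative = dissociation). A convenience summary; the per-frame
    traces remain the primary output.
    """
    out = []
    for (cell, probe), sub in table.groupby(["cell_id", "probe_channel"]):
        sub = sub.sort_values("frame")
        base = sub.loc[sub["frame"] < event_frame, "normalized_intensity"].mean()
        plateau = sub["normalized_intensity"].tail(plateau_frames).mean()
        out.append(
            {
                "cell_id": cell,
                "probe_channel": probe,
                "baseline": base,
                "plateau": plateau,
                "percent_change": 100.0 * (plateau - base) / base,
            }
        )
    return pd.DataFrame(out)


def guess_roi(image: np.ndarray, smooth_sigma: float = 4.0) -> np.ndarray:
    """Convenience whole-cell ROI guess: Otsu threshold on a smoothed frame,
    keep the largest connected component, fill holes.

    Drawing the whole-cell ROI is an analyst decision; this guesser exists
    for quick looks only and is never used by the pipeline defaults.
    """
    from scipy.ndimage import binary_fill_holes, gaussian_filter
    from skimage.filters import threshold_otsu
    from skimage.measure import label

    smooth = gaussian_filter(np.asarray(image, dtype=np.float64), smooth_sigma)
    fg = smooth > threshold_otsu(smooth)
    lab = label(fg)
    if lab.max() == 0:
        return np.zeros(image.shape, dtype=bool)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return binary_fill_holes(lab == largest)


def select_representative(cells: list[tuple[str, float]]) -> str:
    """Cell whose score is nearest the cohort median (tie -> smallest id).

    Used to pick example images for figures; the returned cell's score
    always falls within the 25th-75th percentile of the cohort, which is
    asserted.
    """
    if not cells:
        raise ValueError("no cells to select from")
    ids = [c[0] for c in cells]
    scores = np.asarray([c[1] for c in cells], dtype=float)
    med = np.median(scores)
    dist = np.abs(scores - med)
    best = np.flatnonzero(dist == dist.min())
    winner = min(best, key=lambda i: ids[i])
    p25, p75 = np.percentile(scores, [25, 75])
    assert p25 <= scores[winner] <= p75, "nearest-to-median fell outside IQR"
    return ids[winner]
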