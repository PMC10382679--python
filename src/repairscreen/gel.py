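"""Pseudo-gel rendering: per-site lesion counts as band intensities.

Mimics an autoradiograph panel: one lane per sample (unirradiated control
first, then timepoints in order), one band row per site in ascending
TSS-relative coordinate, band darkness a monotone (gamma-compressed)
transform of the count normalized to the image maximum.  Rendering is a pure
function of (table, spec).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .lesionmap import LesionCountTable


@dataclass(frozen=True)
class PseudoGelSpec:
    band_height: int = 3        # px per band row
    gap: int = 1                # px between band rows
    lane_width: int = 36        # px per lane
    lane_gap: int = 6           # px between lanes
    gamma: float = 0.7          # film-response mimic; cosmetic
    background: int = 255       # 8-bit gray of empty gel

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def render_pseudo_gel(
    table: LesionCountTable,
    spec: PseudoGelSpec = PseudoGelSpec(),
    path: str | None = None,
    lane_order: list[str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a grayscale pseudo-gel; returns (uint8 image, row legend).

    Intensity is ``(count / max count) ** gamma`` scaled to full darkness at
    the image maximum, so doubling every count leaves the image unchanged.
    An all-zero table renders as uniform background with a warning.  When
    ``path`` is given the image is also written as 8-bit grayscale PNG.
    """
    if table.counts.empty:
        raise ValueError("empty lesion count table")
    lanes = lane_order or list(table.counts.columns)
    counts = table.counts[lanes].sort_index()
    sites = counts.index.to_numpy()
    mat = counts.to_numpy(dtype=float)
    cmax = mat.max()
    if cmax <= 0:
        warnings.warn(f"{table.gene}/{table.strand}: all counts zero; "
                      "uniform background image")
        rel = np.zeros_like(mat)
    else:
        rel = (mat / cmax) ** spec.gamma
    darkness = np.round(rel * spec.background).astype(np.uint8)

    n_sites, n_lanes = mat.shape
    H = n_sites * (spec.band_height + spec.gap) + spec.gap
    W = n_lanes * (spec.lane_width + spec.lane_gap) + spec.lane_gap
    img = np.full((H, W), spec.background, dtype=np.uint8)
    for i in range(n_sites):
        y0 = spec.gap + i * (spec.band_height + spec.gap)
        for j in range(n_lanes):
            x0 = spec.lane_gap + j * (spec.lane_width + spec.lane_gap)
            img[y0:y0 + spec.band_height, x0:x0 + spec.lane_width] = (
                spec.background - darkness[i, j])
    legend = pd.DataFrame({
        "row": np.arange(n_sites),
        "site": sites,
        "y_top": spec.gap + np.arange(n_sites) * (spec.band_height + spec.gap),
    })
    if path is not None:
        Image.fromarray(img, mode="L").save(path)
    return img, legend
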