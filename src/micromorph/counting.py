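"""Automated nuclei-channel cell counting and multinucleation flagging.

Counting follows the canonical chain for nuclear-stain rasters: Gaussian
smoothing, global Otsu threshold, hole filling, optional watershed
separation of touching nuclei (markers at distance-transform peaks), and an
area filter. All parameters live in :class:`CountConfig`; the chain is
deterministic given raster + config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sklabel
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = ["CountConfig", "CountResult", "count_nuclei", "nuclei_per_cell"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountConfig:
    smooth_sigma_um: float = 2.0
    min_area_um2: float = 12.0
    max_area_um2: float = 600.0
    use_watershed: bool = True
    peak_min_distance_um: float = 5.0


@dataclass
class CountResult:
    roi_id: str
    n_cells: int
    centroids: list[tuple[float, float]]  # (x, y) in um
    density_per_mm2: float

    def __post_init__(self):
        assert self.n_cells == len(self.centroids)


def count_nuclei(
    nuclei: np.ndarray,
    pixel_size_um: float = 1.0,
    config: CountConfig | None = None,
    roi_id: str = "roi",
) -> CountResult:
    """Count nuclei in a single-channel raster.

    A blank (constant) raster yields a count of 0 rather than an error.
    """
    cfg = config or CountConfig()
    img = np.asarray(nuclei, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclei raster must be 2-D")
    px = float(pixel_size_um)
    area_mm2 = img.size * px * px / 1e6

    if np.ptp(img) == 0:
        return CountResult(roi_id, 0, [], 0.0)
    smoothed = gaussian(img, sigma=cfg.smooth_sigma_um / px, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return CountResult(roi_id, 0, [], 0.0)
    bw = smoothed > threshold_otsu(smoothed)
    bw = ndi.binary_fill_holes(bw)
    if not bw.any():
        return CountResult(roi_id, 0, [], 0.0)

    if cfg.use_watershed:
        dist = ndi.distance_transform_edt(bw)
        min_dist = max(1, int(round(cfg.peak_min_distance_um / px)))
        peaks = peak_local_max(dist, min_distance=min_dist, labels=bw,
                               exclude_border=False)
        markers = np.zeros_like(bw, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            labeled = sklabel(bw)
        else:
            labeled = watershed(-dist, markers, mask=bw)
    else:
        labeled = sklabel(bw)

    centroids = []
    for prop in regionprops(labeled):
        area_um2 = prop.area * px * px
        if cfg.min_area_um2 <= area_um2 <= cfg.max_area_um2:
            cy, cx = prop.centroid
            centroids.append((cx * px, cy * px))
    n = len(centroids)
    return CountResult(roi_id, n, centroids, n / area_mm2 if area_mm2 > 0 else 0.0)


def nuclei_per_cell(
    labels: np.ndarray,
    centroids: Sequence[tuple[float, float]],
    pixel_size_um: float = 1.0,
) -> tuple[pd.DataFrame, bool]:
    """Assign nucleus centroids to cells; flag ROI-level multinucleation.

    Each centroid (x, y in um) is assigned to the label under it; centroids
    over background are logged and dropped. Returns the per-cell nucleus
    count table and True if any cell holds >= 2 nuclei.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("labels raster must be 2-D")
    px = float(pixel_size_um)
    counts: dict[int, int] = {int(c): 0 for c in np.unique(labels) if c != 0}
    for x, y in centroids:
        r, c = int(round(y / px)), int(round(x / px))
        if not (0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]):
            logger.warning("centroid (%.1f, %.1f) um outside raster; skipped", x, y)
            continue
        lab = int(labels[r, c])
        if lab == 0:
            logger.warning("centroid (%.1f, %.1f) um over background; unassigned", x, y)
            continue
        counts[lab] = counts.get(lab, 0) + 1
    table = pd.DataFrame(
        {"cell_id": list(counts.keys()), "n_nuclei": list(counts.values())}
    ).sort_values("cell_id", ignore_index=True)
    multinucleated = bool((table["n_nuclei"] >= 2).any()) if len(table) else False
    return table, multinucleated
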