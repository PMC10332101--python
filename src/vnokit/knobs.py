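"""Knob detection in still images and density-based total-knob estimation.

Responder percentages are expressed relative to the *estimated total knob
number* of a recording site: a mean knob density (knobs per 100 um^2,
measured by counting knob-like structures in randomly placed 40 x 40 um
squares) times the recorded area.  The pooled density constant 8.32
knobs/100 um^2 — the simple mean of the two genotype means 8.42 and 8.21 —
is the default normalizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.feature import blob_log

from ._util import round_half_away, sem

SQUARE_SIDE_UM = 40.0
SQUARE_AREA_100UM2 = (SQUARE_SIDE_UM**2) / 100.0  # 16 sampling units of 100 um^2

#: Pooled mean knob density (knobs per 100 um^2) across both genotypes,
#: used by default to convert recorded area into total knob number.
POOLED_KNOB_DENSITY = 8.32


@dataclass
class DensityEstimate:
    """Knob density from per-square counts of 40 x 40 um sampling squares."""

    counts_per_square: list[int]
    density_per_100um2: float
    sem_per_100um2: Optional[float]

    @property
    def n_squares(self) -> int:
        return len(self.counts_per_square)


@dataclass
class SiteGeometry:
    """Recorded area of one site and its estimated total knob count."""

    site_id: str
    recorded_area_um2: float
    density_per_100um2: float = POOLED_KNOB_DENSITY

    def __post_init__(self) -> None:
        if self.recorded_area_um2 < 0:
            raise ValueError("recorded area must be non-negative")

    @property
    def estimated_total_knobs(self) -> int:
        return estimate_total_knobs(self.recorded_area_um2, self.density_per_100um2)


def detect_knobs(
    image: np.ndarray,
    pixel_um: float,
    min_sigma_um: float = 0.4,
    max_sigma_um: float = 1.2,
    threshold_rel: float = 0.15,
    min_spacing_um: float = 2.0,
) -> np.ndarray:
    """Detect knob-like spots; returns an (n, 2) array of (x, y) in um.

    Multiscale Laplacian-of-Gaussian blob detection: local maxima of the
    band-pass response above ``threshold_rel`` times the global response
    maximum, non-maximum suppressed so no two detections are closer than
    ``min_spacing_um``.  Deterministic for a fixed image.
    """
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.size == 0 or img.max() <= img.min():
        return np.empty((0, 2))
    img = (img - img.min()) / (img.max() - img.min())
    blobs = blob_log(
        img,
        min_sigma=min_sigma_um / pixel_um,
        max_sigma=max_sigma_um / pixel_um,
        num_sigma=5,
        threshold=None,
        threshold_rel=threshold_rel,
    )
    if blobs.size == 0:
        return np.empty((0, 2))
    # blob_log rows are (row, col, sigma); convert to (x, y) in um
    xy = blobs[:, [1, 0]] * pixel_um
    # greedy non-maximum suppression at min_spacing_um, brightest first
    rows = np.clip(blobs[:, 0].astype(int), 0, img.shape[0] - 1)
    cols = np.clip(blobs[:, 1].astype(int), 0, img.shape[1] - 1)
    order = np.argsort(-img[rows, cols])
    kept: list[int] = []
    for i in order:
        if all(np.hypot(*(xy[i] - xy[j])) >= min_spacing_um for j in kept):
            kept.append(i)
    return xy[sorted(kept)]


def estimate_density(counts_per_square: Sequence[int]) -> DensityEstimate:
    """Mean +/- SEM knob density (per 100 um^2) across sampling squares."""
    counts = list(int(c) for c in counts_per_square)
    if len(counts) < 1:
        raise ValueError("at least one sampling square is required")
    per_100 = np.asarray(counts, dtype=float) / SQUARE_AREA_100UM2
    return DensityEstimate(counts, float(per_100.mean()), sem(per_100))


def pool_group_densities(group_means: Sequence[float], ndigits: int = 2) -> float:
    """Simple (unweighted) mean of per-group densities, rounded half away
    from zero to ``ndigits`` — the convention behind the pooled 8.32."""
    return round_half_away(float(np.mean(np.asarray(group_means, dtype=float))), ndigits)


def estimate_total_knobs(area_um2: float, density_per_100um2: float) -> int:
    """Total knob number of a recorded area: round(density x area / 100)."""
    if area_um2 < 0:
        raise ValueError("area must be non-negative")
    return int(round_half_away(density_per_100um2 * area_um2 / 100.0, 0))


def match_detections(
    truth_xy: np.ndarray, detected_xy: np.ndarray, radius_um: float = 1.0
) -> tuple[int, float, float]:
    """Greedy one-to-one matching of detections to ground-truth positions.

    Returns (n_matched, recall, precision) at the given match radius.
    """
    truth = np.asarray(truth_xy, dtype=float).reshape(-1, 2)
    det = np.asarray(detected_xy, dtype=float).reshape(-1, 2)
    if truth.shape[0] == 0 or det.shape[0] == 0:
        return 0, 0.0 if truth.shape[0] else 1.0, 0.0 if det.shape[0] else 1.0
    d = np.linalg.norm(truth[:, None, :] - det[None, :, :], axis=2)
    pairs = np.argwhere(d <= radius_um)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]])
    used_t: set[int] = set()
    used_d: set[int] = set()
    matched = 0
    for ti, di in pairs[order]:
        if ti not in used_t and di not in used_d:
            used_t.add(ti)
            used_d.add(di)
            matched += 1
    return matched, matched / truth.shape[0], matched / det.shape[0]
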