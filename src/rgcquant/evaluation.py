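"""Counting-engine acceptance protocol.

A counting model is accepted the way trained counters are accepted against
human annotators: fixed-size frames (177 x 177 um) are sampled equally from
the central, mid and peripheral retina; per-frame counts from the model are
regressed against reference counts; the model passes if its slope is close
to 1, its R^2 is high, and its R^2 is not materially below the agreement
between two independent reference counters. Point-level quality
(precision/recall/F1) comes from one-to-one centroid matching within a
radius of one soma radius.

Two synthetic "human counters" are emulated from ground truth by applying
independent miss and spurious-addition rates, so the whole protocol can be
exercised without manual annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .imgio import CentroidSet
from .segmentation import RetinaMask

__all__ = [
    "Frame",
    "AgreementStats",
    "MatchResult",
    "sample_frames",
    "frame_counts",
    "agreement_regression",
    "match_detections",
    "accept_detector",
    "run_acceptance_protocol",
    "emulate_counter",
    "FramePlacementError",
]

FRAME_SIDE_UM = 177.0
STRATA = ("central", "mid", "peripheral")


class FramePlacementError(RuntimeError):
    """Could not place the requested number of non-overlapping frames."""


@dataclass(frozen=True)
class Frame:
    """One counting frame: origin = top-left corner in um, side fixed."""

    origin: Tuple[float, float]
    stratum: str
    side: float = FRAME_SIDE_UM

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x0, y0 = self.origin
        return (x >= x0) & (x < x0 + self.side) & (y >= y0) & (y < y0 + self.side)


@dataclass(frozen=True)
class AgreementStats:
    """OLS agreement between two per-frame count vectors."""

    slope: float
    intercept: float
    r_squared: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("agreement needs at least 2 frames")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("r_squared out of [0, 1]")


@dataclass(frozen=True)
class MatchResult:
    """One-to-one centroid matching outcome."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool = False  # an empty denominator was encountered


def _rim_distance_map(mask: RetinaMask, onh_center):
    """Normalized radial position of mask pixels: 0 at ONH, 1 at local rim.

    For each foreground pixel, the ONH-to-rim distance along its direction is
    approximated by the pixel's distance to ONH plus its distance to the
    nearest background pixel (exact for a star-shaped footprint).
    """
    from scipy import ndimage as ndi

    px = mask.pixel_size
    dist_to_edge = ndi.distance_transform_edt(mask.mask) * px
    h, w = mask.mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r_onh = np.hypot(xx * px - onh_center[0], yy * px - onh_center[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = r_onh / (r_onh + dist_to_edge)
    norm[~mask.mask] = np.nan
    return norm, dist_to_edge


def sample_frames(
    mask: RetinaMask,
    onh_center,
    n_total: int,
    seed: int,
    max_tries: int = 20_000,
) -> List[Frame]:
    """Sample counting frames equally from three radial strata.

    Strata are equal thirds of the normalized ONH-to-rim distance
    (central < 1/3 <= mid < 2/3 <= peripheral), assigned by frame centre.
    Frames lie wholly inside the retina mask. Placement is seeded and
    deterministic, and prefers pairwise non-overlapping frames; when a
    stratum is geometrically too small to host its share of disjoint
    frames (published frame tallies pool several retinas, but this samples
    one mount), the minimum centre spacing is progressively relaxed so the
    requested count is still delivered with maximal dispersion.
    """
    if n_total % 3 != 0:
        raise ValueError("n_total must be divisible by 3 (equal strata)")
    per_stratum = n_total // 3
    rng = np.random.default_rng(seed)
    norm, dist_to_edge = _rim_distance_map(mask, onh_center)
    px = mask.pixel_size
    half_diag = FRAME_SIDE_UM / math.sqrt(2.0)

    frames: List[Frame] = []
    bounds = {"central": (0.0, 1 / 3), "mid": (1 / 3, 2 / 3), "peripheral": (2 / 3, 1.0)}
    for stratum in STRATA:
        lo, hi = bounds[stratum]
        ok = (norm >= lo) & (norm < hi) & (dist_to_edge >= half_diag)
        rows, cols = np.nonzero(ok)
        if rows.size == 0:
            raise FramePlacementError(f"no admissible centres in {stratum} stratum")
        placed_centers: List[Tuple[float, float]] = []
        spacing = FRAME_SIDE_UM
        tries = 0
        while len(placed_centers) < per_stratum:
            if tries >= max_tries:
                # stratum cannot host this many disjoint frames: relax
                spacing *= 0.7
                tries = 0
                if spacing < px:
                    raise FramePlacementError(
                        f"could not place {per_stratum} frames in the "
                        f"{stratum} stratum even with overlap allowed"
                    )
                continue
            tries += 1
            i = int(rng.integers(rows.size))
            cx, cy = cols[i] * px, rows[i] * px
            if any(
                abs(cx - ox) < spacing and abs(cy - oy) < spacing
                for ox, oy in placed_centers
            ):
                continue
            # frame must sit wholly inside the mask: check its corners too
            x0, y0 = cx - FRAME_SIDE_UM / 2, cy - FRAME_SIDE_UM / 2
            corners_x = np.array([x0, x0 + FRAME_SIDE_UM, x0, x0 + FRAME_SIDE_UM])
            corners_y = np.array([y0, y0, y0 + FRAME_SIDE_UM, y0 + FRAME_SIDE_UM])
            if not mask.contains(corners_x, corners_y).all():
                continue
            placed_centers.append((cx, cy))
            frames.append(Frame(origin=(x0, y0), stratum=stratum))
    return frames


def frame_counts(centroids: CentroidSet, frames: Sequence[Frame]) -> np.ndarray:
    """Number of centroids falling in each frame."""
    return np.array(
        [int(f.contains(centroids.x, centroids.y).sum()) for f in frames], dtype=int
    )


def agreement_regression(counts_x, counts_y) -> AgreementStats:
    """OLS of y on x plus squared Pearson correlation."""
    x = np.asarray(counts_x, dtype=float).ravel()
    y = np.asarray(counts_y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("count vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least two frames")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: zero variance in x counts")
    slope, intercept = np.polyfit(x, y, 1)
    if np.ptp(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return AgreementStats(
        slope=float(slope), intercept=float(intercept), r_squared=r2, n_frames=x.size
    )


def match_detections(
    predicted: CentroidSet,
    truth: CentroidSet,
    radius: float,
    method: str = "auto",
) -> MatchResult:
    """One-to-one matching of predicted vs truth centroids within ``radius``.

    ``hungarian`` maximizes the number of matched pairs by optimal
    assignment (minimum total distance among maximum matchings);
    ``greedy`` matches nearest pairs first, which coincides with the optimum
    for well-separated point sets and scales to full retinas. ``auto`` uses
    hungarian up to ~2000x2000 pairs.
    """
    if not (radius > 0):
        raise ValueError("matching radius must be > 0")
    np_, nt = len(predicted), len(truth)
    if np_ == 0 or nt == 0:
        tp = 0
        fp, fn = np_, nt
        return MatchResult(
            tp=tp,
            fp=fp,
            fn=fn,
            precision=0.0 if np_ else 0.0,
            recall=0.0 if nt else 0.0,
            f1=0.0,
            degenerate=(np_ == 0 or nt == 0),
        )
    if method == "auto":
        method = "hungarian" if np_ * nt <= 4_000_000 else "greedy"

    if method == "hungarian":
        from scipy.spatial.distance import cdist

        d = cdist(predicted.points, truth.points)
        big = 1e9
        cost = np.where(d <= radius, d, big)
        ri, ci = linear_sum_assignment(cost)
        tp = int(np.sum(d[ri, ci] <= radius))
    elif method == "greedy":
        tree = cKDTree(truth.points)
        pairs = tree.query_ball_point(predicted.points, r=radius)
        cand = [
            (float(np.hypot(*(predicted.points[i] - truth.points[j]))), i, j)
            for i, js in enumerate(pairs)
            for j in js
        ]
        cand.sort()
        used_p = np.zeros(np_, bool)
        used_t = np.zeros(nt, bool)
        tp = 0
        for _, i, j in cand:
            if not used_p[i] and not used_t[j]:
                used_p[i] = used_t[j] = True
                tp += 1
    else:
        raise ValueError(f"unknown method {method!r}")

    fp = np_ - tp
    fn = nt - tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return MatchResult(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)


def emulate_counter(
    truth: CentroidSet,
    mask: RetinaMask,
    seed: int,
    miss_rate: float = 0.02,
    spurious_rate: float = 0.01,
    label: str = "counter_A",
) -> CentroidSet:
    """Synthetic human annotator: truth corrupted by misses and spurious marks.

    Each true centroid is independently dropped with ``miss_rate``; spurious
    marks (``spurious_rate`` x n) are added uniformly inside the mask.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    keep = rng.random(n) >= miss_rate
    x, y = truth.x[keep], truth.y[keep]
    n_spur = int(rng.poisson(spurious_rate * n))
    if n_spur:
        rows, cols = np.nonzero(mask.mask)
        idx = rng.integers(rows.size, size=n_spur)
        px = mask.pixel_size
        x = np.concatenate([x, cols[idx] * px])
        y = np.concatenate([y, rows[idx] * px])
    return CentroidSet(x=x, y=y, label=label, source_id=f"emulated-{label}")


def run_acceptance_protocol(
    preset,
    seed: int = 0,
    pixel_size: float = 1.0,
    n_frames: int = 36,
    injured_dpi: Optional[float] = None,
    detection_params=None,
):
    """Full counting-engine acceptance run for one species preset.

    Mirrors how counting models are established against human annotators:
    the testing set pools frames from more than one whole-mount and more
    than one condition — here half the frames come from an uninjured
    retina and half from an injured one (by default the time-point of
    maximal RGC loss in the preset's course), so the per-frame counts span
    the range the counter must track. Returns a dict with the accept/reject
    decision, both agreement regressions and point-level match metrics.
    """
    from .detection import detect_cells, params_for_preset
    from .pipeline import analyze_image
    from .synth import generate_retina

    if n_frames % 6 != 0:
        raise ValueError("n_frames must be divisible by 6 (two retinas x 3 strata)")
    if injured_dpi is None:
        injured_dpi = min(preset.injury_course.anchors, key=lambda a: (a[1], a[0]))[0]
    params = detection_params or params_for_preset(preset)

    model_counts, truth_counts, ca_counts, cb_counts = [], [], [], []
    match = None
    for i, dpi in enumerate((0.0, float(injured_dpi))):
        retina = generate_retina(
            preset, dpi=dpi, pixel_size=pixel_size, seed=seed + 100 * i
        )
        meas = analyze_image(retina.image, params=params, preset=preset)
        frames = sample_frames(
            retina.truth_mask, retina.onh_center, n_frames // 2, seed=seed + 11 + i
        )
        truth_counts.append(frame_counts(retina.truth_centroids, frames))
        model_counts.append(frame_counts(meas.centroids, frames))
        ca = emulate_counter(retina.truth_centroids, retina.truth_mask, seed + 21 + i)
        cb = emulate_counter(
            retina.truth_centroids, retina.truth_mask, seed + 42 + i, label="counter_B"
        )
        ca_counts.append(frame_counts(ca, frames))
        cb_counts.append(frame_counts(cb, frames))
        if dpi == 0.0:
            match = match_detections(
                meas.centroids,
                retina.truth_centroids,
                radius=preset.soma_diameter_mean / 2,
                method="greedy",
            )
    ok, model, inter = accept_detector(
        np.concatenate(model_counts),
        np.concatenate(truth_counts),
        np.concatenate(ca_counts),
        np.concatenate(cb_counts),
    )
    return {
        "accepted": ok,
        "model": model,
        "inter_counter": inter,
        "match": match,
        "injured_dpi": float(injured_dpi),
        "n_frames": n_frames,
    }


def accept_detector(
    model_counts,
    truth_counts,
    counter_a_counts,
    counter_b_counts,
    slope_window: Tuple[float, float] = (0.9, 1.1),
    min_r2: float = 0.9,
    max_r2_deficit: float = 0.05,
):
    """Accept/reject the counting engine by the agreement protocol.

    Accept iff the model-vs-reference slope lies in ``slope_window``, its
    R^2 is at least ``min_r2``, and its R^2 is no more than
    ``max_r2_deficit`` below the inter-counter R^2. Returns
    ``(accepted, model_stats, inter_counter_stats)``.
    """
    model = agreement_regression(truth_counts, model_counts)
    inter = agreement_regression(counter_a_counts, counter_b_counts)
    ok = (
        slope_window[0] <= model.slope <= slope_window[1]
        and model.r_squared >= min_r2
        and model.r_squared >= inter.r_squared - max_r2_deficit
    )
    return bool(ok), model, inter
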