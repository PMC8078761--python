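"""Post-prediction: score predictions against the image, discard outliers,
resolve head-tail orientation over time, interpolate gaps and smooth.

The network predicts unoriented poses frame by frame. This module (a) turns
each prediction back into a synthetic image and scores it against the input
frame with normalized cross-correlation (the *image error*, 1 - |c|_max),
(b) builds temporal segments of mutually consistent orientations, aligns
them to the sparse head-tail labels from classical tracking, and (c)
optionally fills small gaps with cubic splines and smooths the angle time
series with a Savitzky-Golay filter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import interpolate, signal
from skimage.feature import match_template

from .geometry import flip_centerline, mean_abs_angle_distance, wrap_angle
from .network import PredictionPair
from .preprocess import ProcessedFrame
from .synth import ReferenceFrame, SynthParams, interpolate_widths, render_synthetic, worm_outline_mask

__all__ = [
    "ScoredPrediction",
    "Segment",
    "OrientedSegment",
    "image_error",
    "score_prediction",
    "choose_threshold",
    "build_segments",
    "orient_segments",
    "interpolate_gaps",
    "smooth_angles",
    "make_results_table",
    "to_wcon",
]

#: default image-error threshold above which a frame is discarded
DEFAULT_ERROR_THRESHOLD = 0.3

#: adjacent-frame mean-absolute angle distance allowed inside a segment
SEGMENT_ANGLE_THRESHOLD = np.deg2rad(30.0)

#: look-ahead horizon and minimum segment duration, in seconds
SEGMENT_LOOKAHEAD_S = 0.2
SEGMENT_MIN_DURATION_S = 0.2

#: padding around the rendered worm bounding box before template matching
TEMPLATE_PADDING = 2


def image_error(
    original: ProcessedFrame,
    candidate: np.ndarray,
    ref: ReferenceFrame,
    params: SynthParams | None = None,
) -> tuple[float, tuple[int, int]]:
    """Reconstruction error of a candidate centerline against the frame.

    The candidate is rendered synthetically from the (nearest labeled)
    reference frame, cropped to the worm bounding box plus 2 px padding,
    and slid over the original as a template computing the normalized
    correlation coefficient at every placement. Returns
    ``(1 - |c|_max, argmax location)``; |c| is used so that a
    reversed-intensity copy still scores as a perfect match.
    """
    params = params or SynthParams(augment=False)
    if params.augment:
        params = SynthParams(step=params.step, w_multiplier=params.w_multiplier, augment=False)
    sample = render_synthetic(ref, np.asarray(candidate, float), params, np.random.default_rng(0))
    n_s = sample.target_skeleton.n_points
    outline = worm_outline_mask(
        sample.target_skeleton, interpolate_widths(ref.widths3, n_s), sample.image.shape
    )
    rows = np.any(outline, axis=1).nonzero()[0]
    cols = np.any(outline, axis=0).nonzero()[0]
    pad = TEMPLATE_PADDING
    r0 = max(rows[0] - pad, 0)
    r1 = min(rows[-1] + 1 + pad, sample.image.shape[0])
    c0 = max(cols[0] - pad, 0)
    c1 = min(cols[-1] + 1 + pad, sample.image.shape[1])
    template = sample.image[r0:r1, c0:c1].astype(float)
    source = original.image.astype(float)
    if template.shape[0] > source.shape[0] or template.shape[1] > source.shape[1]:
        raise ValueError("template larger than the source image")
    corr = match_template(source, template, pad_input=False)
    best = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
    c_max = float(np.abs(corr[best]))
    return 1.0 - c_max, (int(best[1]), int(best[0]))


@dataclass
class ScoredPrediction:
    """A prediction pair with its per-orientation image errors."""

    pair: PredictionPair
    errors: tuple[float, float]  # (theta_hat, theta_hat_flipped)
    offsets: tuple[tuple[int, int], tuple[int, int]]

    @property
    def best_error(self) -> float:
        return min(self.errors)

    @property
    def best_orientation_by_image(self) -> int:
        return int(np.argmin(self.errors))

    @property
    def skeleton_offset(self) -> tuple[int, int]:
        return self.offsets[self.best_orientation_by_image]


def score_prediction(
    original: ProcessedFrame,
    pair: PredictionPair,
    ref: ReferenceFrame,
    params: SynthParams | None = None,
) -> ScoredPrediction:
    """Image error for both head-tail orientations of a prediction."""
    e0, off0 = image_error(original, pair.theta_hat, ref, params)
    e1, off1 = image_error(original, pair.theta_hat_flipped, ref, params)
    return ScoredPrediction(pair=pair, errors=(e0, e1), offsets=(off0, off1))


def choose_threshold(
    errors_on_labeled,
    default: float = DEFAULT_ERROR_THRESHOLD,
    plot_path=None,
) -> tuple[float, pd.DataFrame]:
    """Image-error threshold selection aid.

    Returns the default threshold together with a table of the error
    distribution on trusted labeled frames (quantiles and the fraction
    retained at a grid of thresholds), and optionally writes a histogram
    plot. The default is kept unless the user overrides it after
    inspection.
    """
    errors = np.asarray(list(errors_on_labeled), dtype=float)
    if errors.size == 0:
        warnings.warn("no labeled-frame errors supplied; using the default threshold", stacklevel=2)
        return default, pd.DataFrame(columns=["threshold", "retained_fraction"])
    grid = np.round(np.arange(0.05, 1.0001, 0.05), 2)
    table = pd.DataFrame(
        {"threshold": grid, "retained_fraction": [(errors <= t).mean() for t in grid]}
    )
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.hist(errors, bins=40, color="steelblue")
        ax.axvline(default, color="crimson", ls="--", label=f"default {default}")
        ax.set_xlabel("image error (1 - |c|max)")
        ax.set_ylabel("labeled frames")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return default, table


# ---------------------------------------------------------------------------
# head-tail resolution


@dataclass
class Segment:
    """A run of frames with mutually consistent (still unoriented) poses."""

    frame_indices: np.ndarray  # aligned frames only; gaps are absent
    choices: np.ndarray  # 0 = theta_hat, 1 = theta_hat_flipped
    orientation_source: str = "random-start"

    @property
    def start(self) -> int:
        return int(self.frame_indices[0])

    @property
    def end(self) -> int:
        return int(self.frame_indices[-1])


@dataclass
class OrientedSegment:
    """A segment whose head-tail orientation has been resolved."""

    frame_indices: np.ndarray
    angles: np.ndarray  # (n_frames, N) chosen centerlines
    orientation_source: str  # labels | neighbor | unresolved


def build_segments(
    pairs: list[PredictionPair],
    fps: float,
    valid: np.ndarray | None = None,
    threshold: float = SEGMENT_ANGLE_THRESHOLD,
    seed: int = 0,
) -> list[Segment]:
    """Greedy temporal segmentation into near-continuous pose runs.

    Starting from a random orientation, each subsequent frame takes the
    orientation minimizing the mean absolute angle distance to the last
    aligned frame; frames failing the threshold (30 degrees) become gaps,
    and if no frame within 0.2 s rejoins the segment a new one is started.
    Segments spanning less than 0.2 s are discarded. Exact orientation ties
    (a symmetric pose) keep the incumbent orientation.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    rng = np.random.default_rng(seed)
    n = len(pairs)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    lookahead = max(1, int(round(SEGMENT_LOOKAHEAD_S * fps)))
    min_span = max(1, int(round(SEGMENT_MIN_DURATION_S * fps)))
    segments: list[Segment] = []
    cur_frames: list[int] = []
    cur_choices: list[int] = []
    last_theta = None
    last_index = -1

    def close() -> None:
        nonlocal cur_frames, cur_choices, last_theta
        if cur_frames and (cur_frames[-1] - cur_frames[0] + 1) >= min_span:
            segments.append(
                Segment(
                    frame_indices=np.asarray(cur_frames),
                    choices=np.asarray(cur_choices),
                )
            )
        cur_frames, cur_choices, last_theta = [], [], None

    for u in range(n):
        if last_theta is None:
            if valid[u]:
                choice = int(rng.integers(0, 2))
                cur_frames, cur_choices = [u], [choice]
                last_theta = pairs[u].theta_hat if choice == 0 else pairs[u].theta_hat_flipped
                last_index = u
            continue
        if valid[u]:
            d0 = mean_abs_angle_distance(pairs[u].theta_hat, last_theta)
            d1 = mean_abs_angle_distance(pairs[u].theta_hat_flipped, last_theta)
            if min(d0, d1) <= threshold:
                if d0 == d1:
                    choice = cur_choices[-1]
                else:
                    choice = 0 if d0 < d1 else 1
                cur_frames.append(u)
                cur_choices.append(choice)
                last_theta = pairs[u].theta_hat if choice == 0 else pairs[u].theta_hat_flipped
                last_index = u
                continue
        if u - last_index >= lookahead:
            close()
            if valid[u]:
                choice = int(rng.integers(0, 2))
                cur_frames, cur_choices = [u], [choice]
                last_theta = pairs[u].theta_hat if choice == 0 else pairs[u].theta_hat_flipped
                last_index = u
    close()
    return segments


def _head_tail_vector(theta: np.ndarray) -> np.ndarray:
    """Head-to-tail displacement of the unit-segment skeleton implied by the
    angles (first to last skeleton point; translation-free)."""
    return np.array([np.cos(theta).sum(), np.sin(theta).sum()])


def orient_segments(
    segments: list[Segment],
    pairs: list[PredictionPair],
    labeled_vectors: dict[int, np.ndarray],
) -> list[OrientedSegment]:
    """Resolve each segment's global head-tail orientation.

    Segments overlapping labeled frames are flipped (as a whole) to
    maximize the summed cosine similarity between predicted and labeled
    head-to-tail vectors. Label-less segments inherit the orientation of
    the nearest already-aligned neighbor via their two closest frames;
    anything left is flagged unresolved.
    """
    n_seg = len(segments)
    chosen = []
    for seg in segments:
        angles = np.stack(
            [
                pairs[f].theta_hat if c == 0 else pairs[f].theta_hat_flipped
                for f, c in zip(seg.frame_indices, seg.choices)
            ]
        )
        chosen.append(angles)

    flip_state = [None] * n_seg  # None = undecided; False/True = keep/flip
    source = ["unresolved"] * n_seg
    for i, seg in enumerate(segments):
        score = 0.0
        hits = 0
        for row, f in enumerate(seg.frame_indices):
            lab = labeled_vectors.get(int(f))
            if lab is None:
                continue
            vec = _head_tail_vector(chosen[i][row])
            denom = np.linalg.norm(vec) * np.linalg.norm(lab)
            if denom == 0:
                continue
            score += float(vec @ lab) / denom
            hits += 1
        if hits:
            flip_state[i] = score < 0
            source[i] = "labels"

    # propagate to unlabeled segments from the nearest aligned neighbor
    changed = True
    while changed:
        changed = False
        for i, seg in enumerate(segments):
            if flip_state[i] is not None:
                continue
            best_j, best_gap = None, None
            for j in range(n_seg):
                if flip_state[j] is None or j == i:
                    continue
                gap = min(
                    abs(seg.start - segments[j].end), abs(segments[j].start - seg.end)
                )
                if best_gap is None or gap < best_gap:
                    best_j, best_gap = j, gap
            if best_j is None:
                continue
            other = segments[best_j]
            if other.end <= seg.start:
                v_other = _head_tail_vector(chosen[best_j][-1])
                v_self = _head_tail_vector(chosen[i][0])
            else:
                v_other = _head_tail_vector(chosen[best_j][0])
                v_self = _head_tail_vector(chosen[i][-1])
            if flip_state[best_j]:
                v_other = -v_other
            sim = float(v_self @ v_other)
            if sim != 0:
                flip_state[i] = sim < 0
                source[i] = "neighbor"
                changed = True

    if all(s == "unresolved" for s in source) and n_seg:
        warnings.warn("no labels or aligned neighbors; all segments unresolved", stacklevel=2)

    out = []
    for i, seg in enumerate(segments):
        angles = chosen[i]
        if flip_state[i]:
            angles = np.stack([flip_centerline(a) for a in angles])
        out.append(
            OrientedSegment(
                frame_indices=seg.frame_indices.copy(),
                angles=angles,
                orientation_source=source[i],
            )
        )
    return out


# ---------------------------------------------------------------------------
# interpolation and smoothing


def interpolate_gaps(
    series: np.ndarray, max_gap: int = 4
) -> np.ndarray:
    """Fill small gaps (NaN rows) in an angle time series.

    Gaps of at most ``max_gap`` frames with valid frames on both sides are
    filled per angle index by third-order spline interpolation over the
    neighboring valid frames (angles are unwrapped in time first). Longer
    gaps are left untouched.
    """
    series = np.asarray(series, dtype=float)
    out = series.copy()
    valid = ~np.isnan(series).any(axis=1)
    t = np.arange(series.shape[0])
    if valid.all() or (~valid).all():
        return out
    # locate gap runs
    starts = np.where(~valid & np.roll(valid, 1))[0]
    for s in starts:
        e = s
        while e < series.shape[0] and not valid[e]:
            e += 1
        if s == 0 or e == series.shape[0]:
            continue  # boundary gap: no support on both sides
        if e - s > max_gap:
            continue
        left = np.where(valid[:s])[0][-4:]
        right = np.where(valid[e:])[0][:4] + e
        support = np.concatenate([left, right])
        kind = "cubic" if support.size >= 4 else "linear"
        block = np.unwrap(series[support], axis=0)
        f = interpolate.interp1d(t[support], block, kind=kind, axis=0)
        out[s:e] = wrap_angle(f(t[s:e]))
    return out


def smooth_angles(series: np.ndarray, window: int = 9, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing of the angle time series (third-order
    polynomials, nominally 8-frame windows; an odd window of 9 centered
    frames is used since the filter requires symmetric support).

    Series shorter than the window are returned unchanged with a warning.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < window:
        warnings.warn("series shorter than the smoothing window; returning unchanged", stacklevel=2)
        return series.copy()
    unwrapped = np.unwrap(series, axis=0)
    smoothed = signal.savgol_filter(unwrapped, window_length=window, polyorder=polyorder, axis=0)
    return wrap_angle(smoothed)


# ---------------------------------------------------------------------------
# results


def make_results_table(
    n_frames: int,
    fps: float,
    oriented: list[OrientedSegment],
    errors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame results: timestamp, orientation source, image error and a
    discard flag (frames belonging to no oriented segment are discarded)."""
    table = pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "time_s": np.arange(n_frames) / fps,
            "orientation_source": "none",
            "discarded": True,
            "image_error": np.nan if errors is None else np.asarray(errors, float),
        }
    )
    for seg in oriented:
        table.loc[seg.frame_indices, "orientation_source"] = seg.orientation_source
        table.loc[seg.frame_indices, "discarded"] = seg.orientation_source == "unresolved"
    return table


def to_wcon(
    skeletons: dict[int, np.ndarray],
    fps: float,
    path,
    worm_id: str = "1",
    units_xy: str = "px",
) -> None:
    """Export per-frame skeleton coordinates to Worm tracker Commons Object
    Notation (a JSON interchange format): t, x, y per skeleton point, with
    the first point marking the head."""
    frames = sorted(skeletons)
    data = {
        "id": worm_id,
        "t": [f / fps for f in frames],
        "x": [np.asarray(skeletons[f])[:, 0].tolist() for f in frames],
        "y": [np.asarray(skeletons[f])[:, 1].tolist() for f in frames],
        "head": "first-point",
    }
    doc = {
        "units": {"t": "s", "x": units_xy, "y": units_xy},
        "metadata": {"software": {"name": "coilpose"}},
        "data": [data],
    }
    Path(path).write_text(json.dumps(doc))
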