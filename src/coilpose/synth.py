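"""Synthetic worm image generation by reverse skeletonization.

Given a labeled reference frame (image + skeleton + widths at head, midbody
and tail) and an arbitrary target posture, small rectangular texture patches
are taken along the reference body and affine-warped onto the corresponding
rectangles along the target skeleton. Overlaps are alpha-blended, protruding
pixels are masked away with a drawn body outline, and the result is cleaned
with a median filter — producing a realistic image of the reference worm in
a posture it never actually assumed. This is what lets a network be trained
on poses (including deep coils) for which no classical tracker label exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import disk, polygon

from .geometry import (
    Skeleton,
    angles_to_skeleton,
    flip_centerline,
    resample_skeleton,
    wrap_angle,
)
from .preprocess import ProcessedFrame
from .shape_model import ShapeModel, sample_shapes

__all__ = [
    "ReferenceFrame",
    "SynthParams",
    "SyntheticSample",
    "interpolate_widths",
    "worm_outline_mask",
    "render_synthetic",
    "sample_training_poses",
    "generate_training_set",
]

#: arc-length fractions of the head / midbody / tail width landmarks
WIDTH_LANDMARKS = (0.15, 0.5, 0.85)

#: advisable range for the number of skeleton points; outside it the
#: synthetic images become either too simplistic or needlessly slow
N_S_ADVISED = (20, 200)

#: maximum number of reference frames kept per rendering process
MAX_REFERENCE_POOL = 1000


@dataclass
class ReferenceFrame:
    """A processed real frame with its labeled skeleton and widths,
    used as the texture template for rendering."""

    frame: ProcessedFrame
    skeleton: Skeleton  # N_S points, head -> tail, inside the image
    widths3: tuple[float, float, float]  # head, midbody, tail width in px
    frame_index: int = -1

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.widths3):
            raise ValueError("worm widths must be positive")
        n_s = self.skeleton.n_points
        if not (N_S_ADVISED[0] <= n_s <= N_S_ADVISED[1]):
            import warnings

            warnings.warn(
                f"N_S = {n_s} skeleton points is outside the advised range "
                f"{N_S_ADVISED}; rendering quality may suffer",
                stacklevel=2,
            )
        pts = self.skeleton.points
        size = self.frame.size
        if pts.min() < 0 or pts.max() > size - 1:
            raise ValueError("reference skeleton must lie inside the image")


@dataclass
class SynthParams:
    """Rendering and augmentation parameters.

    ``step`` is the patch length in skeleton indices (``None`` means
    N_S / 16); a patch starts at every index, so larger ``step`` means more
    overlap. ``w_multiplier`` widens patches beyond the body so each
    carries a border of background pixels.
    """

    step: int | None = None
    w_multiplier: float = 1.2
    augment: bool = True
    translate_frac: float = 0.05  # of the image side, per axis
    length_range: tuple[float, float] = (0.9, 1.1)
    thickness_range: tuple[float, float] = (1.1, 1.3)
    order_flip_prob: float = 0.5
    blur_prob: float = 0.25
    blur_kernel_frac: tuple[float, float] = (0.03, 0.10)
    blur_kernel_max: int = 13

    def __post_init__(self) -> None:
        if self.step is not None and self.step < 1:
            raise ValueError("step must be >= 1")
        if self.w_multiplier <= 1.0:
            raise ValueError("w_multiplier must exceed 1")

    def resolve_step(self, n_s: int) -> int:
        return self.step if self.step is not None else max(1, n_s // 16)


@dataclass
class SyntheticSample:
    """A rendered image with its two equivalent centerline labels."""

    image: np.ndarray  # (L, L) uint8
    target: np.ndarray  # (N,) angles; flip_centerline(target) is equivalent
    target_skeleton: Skeleton
    provenance: dict = field(default_factory=dict)

    @property
    def target_flipped(self) -> np.ndarray:
        return flip_centerline(self.target)


def interpolate_widths(
    widths3: Sequence[float],
    n_points: int,
    landmarks: Sequence[float] = WIDTH_LANDMARKS,
) -> np.ndarray:
    """Per-point body width from the three labeled widths.

    Constant ``head_width`` before the head landmark, linear head->midbody
    and midbody->tail between landmarks, constant ``tail_width`` after.
    """
    head_w, mid_w, tail_w = widths3
    if head_w <= 0 or mid_w <= 0 or tail_w <= 0:
        raise ValueError("widths must be positive")
    f_head, f_mid, f_tail = landmarks
    if not (0.0 < f_head < f_mid < f_tail < 1.0):
        raise ValueError("landmark fractions must increase within (0, 1)")
    frac = np.linspace(0.0, 1.0, n_points)
    return np.interp(
        frac,
        [0.0, f_head, f_mid, f_tail, 1.0],
        [head_w, head_w, mid_w, tail_w, tail_w],
    )


def worm_outline_mask(
    skeleton: Skeleton | np.ndarray,
    widths: np.ndarray,
    shape: tuple[int, int],
) -> np.ndarray:
    """Expected worm body mask: the union of per-segment quadrilaterals of
    the local width around the centerline, with filled circles at the two
    extremities. Skeleton parts outside the canvas are clipped."""
    points = skeleton.points if isinstance(skeleton, Skeleton) else np.asarray(skeleton, float)
    widths = np.asarray(widths, dtype=float)
    if points.shape[0] != widths.shape[0]:
        raise ValueError("one width per skeleton point required")
    if skeleton_degenerate(points):
        raise ValueError("degenerate (zero-length) skeleton")
    if points.min() < -0.5 or points[:, 0].max() > shape[1] - 0.5 or points[:, 1].max() > shape[0] - 0.5:
        import warnings

        warnings.warn("skeleton exits the canvas; outline clipped", stacklevel=2)
    # per-point unit normals from central-difference tangents
    tangents = np.gradient(points, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangents /= norms
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    left = points + normals * (widths[:, None] / 2.0)
    right = points - normals * (widths[:, None] / 2.0)
    mask = np.zeros(shape, dtype=bool)
    for i in range(points.shape[0] - 1):
        quad_x = [left[i, 0], left[i + 1, 0], right[i + 1, 0], right[i, 0]]
        quad_y = [left[i, 1], left[i + 1, 1], right[i + 1, 1], right[i, 1]]
        rr, cc = polygon(quad_y, quad_x, shape=shape)
        mask[rr, cc] = True
    for end, w in ((0, widths[0]), (-1, widths[-1])):
        rr, cc = disk((points[end, 1], points[end, 0]), max(w / 2.0, 1.0), shape=shape)
        mask[rr, cc] = True
    return mask


def skeleton_degenerate(points: np.ndarray) -> bool:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum()) <= 0.0


def _patch_index_pairs(n_s: int, step: int) -> list[tuple[int, int]]:
    """Start/end skeleton indices of the texture patches.

    A rectangle of length ``step`` segments starts at every index, so
    consecutive patches overlap by ``step - 1`` segments and blend
    seamlessly (with ``step = 1`` patches merely touch, which leaves
    visible seams — hence the larger default)."""
    step = min(step, n_s - 1)
    return [(i, i + step) for i in range(0, n_s - step)]


def _rect_frame(p_a: np.ndarray, p_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    center = (p_a + p_b) / 2.0
    axis = p_b - p_a
    half_len = float(np.linalg.norm(axis)) / 2.0
    u = axis / (2.0 * half_len) if half_len > 0 else np.array([1.0, 0.0])
    n = np.array([-u[1], u[0]])
    return center, u, n, half_len


def _warp_patches(
    ref_image: np.ndarray,
    ref_points: np.ndarray,
    tgt_points: np.ndarray,
    patch_widths: np.ndarray,
    pairs: list[tuple[int, int]],
    canvas_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Warp reference texture rectangles onto the target skeleton.

    Each source/target rectangle pair is related by the affine map fixed by
    three corresponding corners (the fourth is implied); because both are
    rectangles this map is evaluated in closed form through the rectangles'
    local coordinates. Patches are alpha-blended: a newly drawn patch
    replaces uncovered pixels and averages (weight 0.5) with already-covered
    ones, so later patches sit on top.
    """
    canvas = np.zeros(canvas_shape, dtype=float)
    covered = np.zeros(canvas_shape, dtype=bool)
    h, w = canvas_shape
    ref_f = ref_image.astype(float)
    for (i, j), width in zip(pairs, patch_widths):
        sc, su, sn, s_half = _rect_frame(ref_points[i], ref_points[j])
        tc, tu, tn, t_half = _rect_frame(tgt_points[i], tgt_points[j])
        if t_half <= 0 or s_half <= 0:
            continue
        half_w = width / 2.0
        corners = (
            tc[None, :]
            + np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]])
            @ np.stack([tu * t_half, tn * half_w])
        )
        x0 = max(int(np.floor(corners[:, 0].min())), 0)
        x1 = min(int(np.ceil(corners[:, 0].max())) + 1, w)
        y0 = max(int(np.floor(corners[:, 1].min())), 0)
        y1 = min(int(np.ceil(corners[:, 1].max())) + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        dx = xs - tc[0]
        dy = ys - tc[1]
        a = (dx * tu[0] + dy * tu[1]) / t_half  # [-1, 1] along the axis
        b = (dx * tn[0] + dy * tn[1]) / half_w  # [-1, 1] across
        inside = (np.abs(a) <= 1.0) & (np.abs(b) <= 1.0)
        if not inside.any():
            continue
        a_in = a[inside]
        b_in = b[inside]
        src_x = sc[0] + a_in * s_half * su[0] + b_in * half_w * sn[0]
        src_y = sc[1] + a_in * s_half * su[1] + b_in * half_w * sn[1]
        values = ndimage.map_coordinates(
            ref_f, [src_y, src_x], order=1, mode="nearest"
        )
        yy = ys[inside]
        xx = xs[inside]
        old_cov = covered[yy, xx]
        old_val = canvas[yy, xx]
        canvas[yy, xx] = np.where(old_cov, (old_val + values) * 0.5, values)
        covered[yy, xx] = True
    return canvas, covered


def _gaussian_sigma_for_kernel(kernel: int) -> float:
    return 0.3 * ((kernel - 1) * 0.5 - 1) + 0.8


def render_synthetic(
    ref: ReferenceFrame,
    target: np.ndarray,
    params: SynthParams | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticSample:
    """Render the reference worm's texture in the ``target`` posture.

    The target skeleton is built by integrating the target angles with
    segment length ``reference worm length / (N_S - 1)``, centered in the
    canvas (plus the optional translation augmentation), then texture
    patches spaced ``step`` skeleton indices apart are warped from the
    reference onto it, blended, masked by the expected body outline,
    median-filtered (window 3) and composited over the reference
    background. Deterministic given ``rng`` state.
    """
    params = params or SynthParams()
    rng = rng or np.random.default_rng(0)
    target = np.asarray(target, dtype=float)
    size = ref.frame.size
    n_s = ref.skeleton.n_points
    step = params.resolve_step(n_s)

    length_scale = 1.0
    thickness = params.w_multiplier
    head_first_draw = False  # default: draw from the tail so head lands on top
    blur_kernel = 0
    if params.augment:
        length_scale = rng.uniform(*params.length_range)
        thickness = rng.uniform(*params.thickness_range)
        head_first_draw = rng.random() < params.order_flip_prob
        if rng.random() < params.blur_prob:
            lo, hi = params.blur_kernel_frac
            blur_kernel = min(int(round(rng.uniform(lo, hi) * size)), params.blur_kernel_max)

    worm_length = ref.skeleton.length * length_scale
    native = angles_to_skeleton(target, ds=worm_length / target.size)
    tgt_points = resample_skeleton(native.points, n_s)

    center = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    tgt_points = tgt_points - tgt_points.mean(axis=0) + center
    if params.augment:
        # translation augmentation; resampled if it pushes the worm outside
        margin = max(ref.widths3) / 2.0 + 1.0
        for _ in range(10):
            shift = rng.uniform(-1.0, 1.0, size=2) * params.translate_frac * size
            moved = tgt_points + shift
            if (
                moved.min() >= margin
                and moved[:, 0].max() <= size - 1 - margin
                and moved[:, 1].max() <= size - 1 - margin
            ):
                tgt_points = moved
                break

    ww = interpolate_widths(ref.widths3, n_s)
    pairs = _patch_index_pairs(n_s, step)
    if head_first_draw is False:
        pairs = pairs[::-1]
    patch_widths = np.array([thickness * ww[(i + j) // 2] for i, j in pairs])

    canvas, covered = _warp_patches(
        ref.frame.image, ref.skeleton.points, tgt_points, patch_widths, pairs, (size, size)
    )

    outline = worm_outline_mask(tgt_points, ww, (size, size))
    background = ref.frame.background_value
    image = np.where(outline & covered, canvas, background)
    image = ndimage.median_filter(image, size=3)
    image[~outline] = background
    if blur_kernel >= 3:
        image = ndimage.gaussian_filter(image, sigma=_gaussian_sigma_for_kernel(blur_kernel))
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    ds = worm_length / (n_s - 1)
    return SyntheticSample(
        image=image,
        target=wrap_angle(target),
        target_skeleton=Skeleton(points=tgt_points, ds=ds),
        provenance={
            "reference_index": ref.frame_index,
            "step": step,
            "w_multiplier": thickness,
            "length_scale": length_scale,
            "blur_kernel": blur_kernel,
            "head_first_draw": bool(head_first_draw),
            "patch_anchor": "centered on the midpoint of indices (i, i+step)",
        },
    )


def sample_training_poses(
    model: ShapeModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` training poses: a GMM shape plus a global orientation
    uniform on (0, 2pi], with the head end assigned to either extremity
    with probability 1/2.

    Returns ``(angles, rotations, flipped)``.
    """
    seed = int(rng.integers(0, 2**31 - 1))
    base = sample_shapes(model, n, seed=seed)
    rotations = rng.uniform(0.0, 2.0 * np.pi, size=n)
    flipped = rng.random(n) < 0.5
    angles = wrap_angle(base + rotations[:, None])
    angles[flipped] = np.array([flip_centerline(a) for a in angles[flipped]])
    return angles, rotations, flipped


def generate_training_set(
    refs: Sequence[ReferenceFrame],
    model: ShapeModel,
    n: int,
    params: SynthParams | None = None,
    seed: int = 0,
) -> Iterator[SyntheticSample]:
    """Stream ``n`` synthetic training samples.

    Each sample draws a pose from the shape model (plus global rotation and
    random head assignment), picks a random reference from a bounded pool
    (at most 1000), and renders it. Render failures are skipped with a log
    message. Deterministic given ``seed``.
    """
    if len(refs) == 0:
        raise ValueError("at least one reference frame is required")
    params = params or SynthParams()
    rng = np.random.default_rng(seed)
    if len(refs) > MAX_REFERENCE_POOL:
        pool_idx = rng.choice(len(refs), size=MAX_REFERENCE_POOL, replace=False)
        refs = [refs[i] for i in pool_idx]
    if n <= 0:
        return
    poses, _, _ = sample_training_poses(model, n, rng)
    ref_choices = rng.integers(0, len(refs), size=n)
    for k in range(n):
        try:
            yield render_synthetic(refs[ref_choices[k]], poses[k], params, rng)
        except Exception as exc:  # noqa: BLE001 - a bad draw is not fatal
            import logging

            logging.getLogger(__name__).warning("skipping failed render: %s", exc)


def replace_params(params: SynthParams, **kwargs) -> SynthParams:
    """Return a copy of ``params`` with fields replaced."""
    return replace(params, **kwargs)
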