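"""Procedural worm-video fixtures and the dataset-adapter API.

The fixture generator renders a smoothly undulating synthetic worm —
sinusoidal eigen-mode dynamics with scheduled deep-turn (coiling) bouts —
as a filled body outline with a brightness profile, noise and blur, and
emits per-frame ground-truth centerlines. Only non-coiled frames (turning
mode below a threshold) are marked "labeled", mimicking the partial
coverage of classical tracker output. Every pipeline stage can therefore
be exercised end to end without any external recording.

The adapter API is the only path by which the pipeline touches data; the
fixture adapter and user-written adapters are interchangeable and can be
registered programmatically or through ``coilpose.adapters`` entry points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import EigenBasis, angles_to_skeleton, wrap_angle
from .preprocess import segment_worm
from .synth import interpolate_widths, worm_outline_mask

__all__ = [
    "FixtureWorld",
    "FixtureVideo",
    "fixture_basis",
    "fixture_shape_corpus",
    "generate_fixture_video",
    "DatasetAdapter",
    "FixtureAdapter",
    "ImageFolderAdapter",
    "register_adapter",
    "get_adapter",
    "available_adapters",
]

#: turning-mode magnitude above which a pose counts as coiled (classical
#: skeletonization fails and no label is available)
COIL_LABEL_THRESHOLD = 10.0


@dataclass
class FixtureWorld:
    """Physical and imaging parameters of the procedural worm.

    Defaults emulate a small crawling worm filmed at 30 Hz: body wave of
    about 1.5 wavelengths at 0.5 Hz with tangent-angle amplitude around
    0.8 rad, periodic deep-turn bouts reaching the coiled regime, dark worm
    on a light, mildly noisy background.
    """

    worm_length_px: float = 40.0
    widths3: tuple[float, float, float] = (4.0, 8.0, 4.0)
    undulation_amplitude: float = 5.5  # first two mode coefficients, eigen units
    waves_per_body: float = 1.5
    frequency_hz: float = 0.5
    coil_interval_s: float = 8.0
    coil_duration_s: float = 2.5
    coil_peak_a3: float = 24.0
    orientation_walk_std: float = 0.02  # rad per frame
    background_level: int = 200
    worm_level: int = 80
    noise_sigma: float = 3.0
    blur_sigma: float = 0.5
    fps: float = 30.0
    duration_s: float = 30.0
    frame_size: int = 80
    n_angles: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = [
            self.worm_length_px,
            *self.widths3,
            self.undulation_amplitude,
            self.waves_per_body,
            self.frequency_hz,
            self.coil_interval_s,
            self.coil_duration_s,
            self.fps,
            self.duration_s,
        ]
        if any(v <= 0 for v in numeric):
            raise ValueError("fixture physical parameters must be positive")
        # a fully coiled worm spans roughly length/pi; keep a safety margin
        if self.worm_length_px * 0.75 > self.frame_size:
            raise ValueError("worm too large for the canvas")


def fixture_basis(world: FixtureWorld | None = None, n_extra: int = 2) -> EigenBasis:
    """The fixture's constructed eigen-style basis.

    Two quadrature sinusoids (the traveling-wave pair), a centered ramp
    (the turning mode) and small higher-harmonic modes, orthonormalized and
    orthogonal to the constant vector so projections are invariant to
    global rotation.
    """
    world = world or FixtureWorld()
    n = world.n_angles
    s = (np.arange(n) + 0.5) / n
    k = world.waves_per_body
    raw = [
        np.cos(2 * np.pi * k * s),
        np.sin(2 * np.pi * k * s),
        s - 0.5,
        np.cos(2 * np.pi * (2 * k) * s),
        np.sin(2 * np.pi * (2 * k) * s),
    ][: 3 + n_extra]
    # Gram-Schmidt, including the constant direction first (discarded) so
    # every mode has zero mean
    basis = [np.ones(n) / np.sqrt(n)]
    for v in raw:
        u = v.astype(float)
        for b in basis:
            u = u - (u @ b) * b
        u /= np.linalg.norm(u)
        basis.append(u)
    comps = np.stack(basis[1:])
    d = comps.shape[0]
    return EigenBasis(
        mean_angles=np.zeros(n),
        components=comps,
        explained_variance_ratio=np.full(d, 1.0 / d),
        source="fixture-constructed",
    )


def _coil_schedule(world: FixtureWorld, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Turning-mode trajectory: smooth raised-cosine bouts of alternating
    sign on a quiet baseline."""
    a3 = np.zeros_like(t)
    bout_start = world.coil_interval_s * 0.5
    sign = 1.0
    while bout_start + world.coil_duration_s < t[-1]:
        peak = world.coil_peak_a3 * rng.uniform(0.7, 1.0) * sign
        inside = (t >= bout_start) & (t < bout_start + world.coil_duration_s)
        phase = (t[inside] - bout_start) / world.coil_duration_s
        a3[inside] += peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        sign = -sign
        bout_start += world.coil_interval_s * rng.uniform(0.8, 1.2)
    a3 += rng.normal(0.0, 0.5, size=t.shape)
    return ndimage.gaussian_filter1d(a3, sigma=max(world.fps / 15.0, 1.0))


def fixture_mode_trajectories(
    world: FixtureWorld, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Mode coefficient time series (T, d) plus global orientation (T,)."""
    n_frames = int(round(world.duration_s * world.fps))
    t = np.arange(n_frames) / world.fps
    chi = 2.0 * np.pi * world.frequency_hz * t + np.cumsum(
        rng.normal(0.0, 0.03, size=n_frames)
    )
    amp = world.undulation_amplitude * (1.0 + 0.1 * np.sin(2 * np.pi * 0.05 * t))
    a1 = amp * np.cos(chi)
    a2 = amp * np.sin(chi)
    a3 = _coil_schedule(world, t, rng)
    extras = ndimage.gaussian_filter1d(
        rng.normal(0.0, 0.6, size=(2, n_frames)), sigma=world.fps / 6.0, axis=1
    )
    modes = np.column_stack([a1, a2, a3, extras[0], extras[1]])
    orientation = np.cumsum(rng.normal(0.0, world.orientation_walk_std, size=n_frames))
    orientation += rng.uniform(0.0, 2.0 * np.pi)
    return modes, orientation


def render_fixture_frame(
    points: np.ndarray,
    widths: np.ndarray,
    world: FixtureWorld,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one frame: filled outline with a center-dark depth profile,
    Gaussian blur and pixel noise. Returns ``(image, true_body_mask)``."""
    shape = (world.frame_size, world.frame_size)
    mask = worm_outline_mask(points, widths, shape)
    img = np.full(shape, float(world.background_level))
    if mask.any():
        # interior depth profile: full contrast over most of the body with a
        # soft shoulder at the boundary (so segmentation sees a crisp blob)
        dist = ndimage.distance_transform_edt(mask)
        profile = np.sqrt(np.clip(dist / max(0.35 * dist.max(), 1.0), 0.0, 1.0))
        img -= (world.background_level - world.worm_level) * profile
    img = ndimage.gaussian_filter(img, sigma=world.blur_sigma)
    # photometric ground truth: the half-contrast contour of the noiseless
    # image (what an ideal segmentation of this recording would recover)
    half = world.background_level - 0.5 * (world.background_level - world.worm_level)
    body_mask = img <= half
    img = img + rng.normal(0.0, world.noise_sigma, size=shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), body_mask


@dataclass
class FixtureVideo:
    """A rendered fixture recording with full ground truth."""

    frames: np.ndarray  # (T, H, W) uint8
    body_masks: np.ndarray  # (T, H, W) bool: photometric ground-truth body
    angles: np.ndarray  # (T, N) ground-truth tangent angles (oriented)
    skeletons: np.ndarray  # (T, N+1, 2) ground-truth points, head first
    modes: np.ndarray  # (T, d) ground-truth mode coefficients
    labeled: np.ndarray  # (T,) bool: classical-tracker coverage
    basis: EigenBasis
    world: FixtureWorld

    @property
    def fps(self) -> float:
        return self.world.fps

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def generate_fixture_video(
    world: FixtureWorld | None = None,
    label_threshold: float = COIL_LABEL_THRESHOLD,
) -> FixtureVideo:
    """Render a full fixture video with ground truth for every frame.

    Frames whose |a_3| exceeds ``label_threshold`` are marked unlabeled
    (coiled postures that a classical tracker would fail on). Deterministic
    given ``world.seed``.
    """
    world = world or FixtureWorld()
    rng = np.random.default_rng(world.seed)
    basis = fixture_basis(world)
    modes, orientation = fixture_mode_trajectories(world, rng)
    n_frames = modes.shape[0]
    n = world.n_angles
    ds = world.worm_length_px / n
    widths = interpolate_widths(world.widths3, n + 1)
    center = (world.frame_size - 1) / 2.0

    frames = np.empty((n_frames, world.frame_size, world.frame_size), dtype=np.uint8)
    body_masks = np.empty((n_frames, world.frame_size, world.frame_size), dtype=bool)
    angles_all = np.empty((n_frames, n))
    skeletons = np.empty((n_frames, n + 1, 2))
    for i in range(n_frames):
        theta = wrap_angle(orientation[i] + modes[i] @ basis.components)
        skel = angles_to_skeleton(theta, ds=ds)
        pts = skel.points - skel.points.mean(axis=0)
        jitter = rng.uniform(-2.0, 2.0, size=2)
        pts = pts + center + jitter
        frames[i], body_masks[i] = render_fixture_frame(pts, widths, world, rng)
        angles_all[i] = theta
        skeletons[i] = pts
    labeled = np.abs(modes[:, 2]) < label_threshold
    return FixtureVideo(
        frames=frames,
        body_masks=body_masks,
        angles=angles_all,
        skeletons=skeletons,
        modes=modes,
        labeled=labeled,
        basis=basis,
        world=world,
    )


def fixture_shape_corpus(
    world: FixtureWorld | None = None,
    n: int = 5000,
    seed: int = 0,
    coiled_fraction: float = 0.5,
) -> tuple[np.ndarray, EigenBasis]:
    """A posture library for shape-model fitting, in the body frame
    (zero-mean angles; global rotation is added at training-sample time).

    An equal population of uncoiled and coiled postures: the wave pair at
    a uniformly random phase, with a_3 near zero for the uncoiled half and
    uniform up to the deep-coil regime (both signs) for the coiled half —
    approximating a library sampled uniformly in body curvature.
    """
    world = world or FixtureWorld()
    rng = np.random.default_rng(seed)
    basis = fixture_basis(world)
    chi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    amp = world.undulation_amplitude * rng.uniform(0.75, 1.15, size=n)
    n_coiled = int(round(n * coiled_fraction))
    a3 = np.concatenate(
        [
            rng.normal(0.0, 3.0, size=n - n_coiled),
            rng.uniform(COIL_LABEL_THRESHOLD, world.coil_peak_a3, size=n_coiled)
            * rng.choice([-1.0, 1.0], size=n_coiled),
        ]
    )
    rng.shuffle(a3)
    modes = np.column_stack(
        [
            amp * np.cos(chi),
            amp * np.sin(chi),
            a3,
            rng.normal(0.0, 0.6, size=n),
            rng.normal(0.0, 0.6, size=n),
        ]
    )
    # returned un-wrapped (smooth along the body): deep coils exceed +/-pi
    # and wrapping would put artificial discontinuities into the library
    shapes = modes @ basis.components
    return shapes, basis


# ---------------------------------------------------------------------------
# dataset adapters


class DatasetAdapter:
    """Base dataset adapter: indexed frame access, per-labeled-frame worm
    features, and the frame segmentation hook.

    Subclasses implement :meth:`get_frame`, :meth:`labeled_indices` and
    :meth:`features`; the default segmentation hook can be overridden for
    unusual imaging conditions.
    """

    fps: float = 30.0

    def __len__(self) -> int:  # pragma: no cover - abstract
        raise NotImplementedError

    def get_frame(self, index: int) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def labeled_indices(self) -> np.ndarray:
        return np.array([], dtype=int)

    def features(self, index: int) -> dict:
        """Labeled-frame features: ``skeleton`` (points head->tail in raw
        frame coordinates) and ``widths3``."""
        raise KeyError(f"frame {index} has no labels")

    def segment(self, frame: np.ndarray):
        """Segmentation hook returning ``(worm_mask, background_value)``."""
        return segment_worm(frame)


class FixtureAdapter(DatasetAdapter):
    """Adapter over a :class:`FixtureVideo` (the stand-in for tracker
    output such as Tierpsy's)."""

    def __init__(self, video: FixtureVideo):
        self.video = video
        self.fps = video.fps

    def __len__(self) -> int:
        return self.video.n_frames

    def get_frame(self, index: int) -> np.ndarray:
        return self.video.frames[index]

    def labeled_indices(self) -> np.ndarray:
        return np.nonzero(self.video.labeled)[0]

    def features(self, index: int) -> dict:
        if not self.video.labeled[index]:
            raise KeyError(f"frame {index} has no labels")
        return {
            "skeleton": self.video.skeletons[index],
            "widths3": self.video.world.widths3,
        }


class ImageFolderAdapter(DatasetAdapter):
    """Frames from a folder of image files (sorted by name); no labels.

    A features-bearing tracker-output adapter (e.g. for the Tierpsy HDF5
    schema: per-frame ``skeleton`` coordinates, ``width_head`` /
    ``width_midbody`` / ``width_tail``, frame rate and head-tail marks) can
    subclass this and implement :meth:`features`.
    """

    def __init__(self, folder, fps: float = 30.0):
        import imageio.v3 as iio
        from pathlib import Path

        self._paths = sorted(p for p in Path(folder).iterdir() if p.is_file())
        self._iio = iio
        self.fps = fps

    def __len__(self) -> int:
        return len(self._paths)

    def get_frame(self, index: int) -> np.ndarray:
        return np.asarray(self._iio.imread(self._paths[index]))


_ADAPTERS: dict[str, type] = {
    "fixture": FixtureAdapter,
    "image-folder": ImageFolderAdapter,
}


def register_adapter(name: str, factory: type) -> None:
    """Register a dataset adapter under a name (plugin registry)."""
    _ADAPTERS[name] = factory


def _load_entry_point_adapters() -> None:
    from importlib.metadata import entry_points

    try:
        for ep in entry_points(group="coilpose.adapters"):
            _ADAPTERS.setdefault(ep.name, ep.load())
    except Exception:  # pragma: no cover - defensive against broken plugins
        pass


def get_adapter(name: str) -> type:
    if name not in _ADAPTERS:
        _load_entry_point_adapters()
    return _ADAPTERS[name]


def available_adapters() -> list[str]:
    _load_entry_point_adapters()
    return sorted(_ADAPTERS)
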