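"""Posture-scale roaming/dwelling analysis.

On food, worms alternate between long-lived *roaming* (fast, straight
paths) and *dwelling* (slow, frequent reorientation) states. The classical
segmentation fits a two-state Gaussian HMM to centroid speed and angular
speed averaged in 10 s windows. With full postures available the analysis
goes further: the first two eigenworm coefficients define a body-wave phase
phi = atan2(a2, a1) whose derivative omega (the phase velocity) signs
forward vs backward waves, complete body waves are counted from recurrences
of cos(phi), and the turning mode a_3 separates Omega-turns
(10 <= |a_3| < 20) from deeper delta-turns (|a_3| >= 20).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy import signal
from scipy.interpolate import CubicSpline

from .geometry import wrap_angle_diff

__all__ = [
    "KinematicsSeries",
    "HmmResult",
    "centroid_kinematics",
    "fit_roam_dwell",
    "direction_angle",
    "phase_velocity",
    "count_body_waves",
    "turn_distribution",
]

#: analysis sampling rate after downsampling, Hz
ANALYSIS_RATE_HZ = 3.0

#: window for state-classification averages, seconds (non-overlapping)
STATE_WINDOW_S = 10.0

#: body-wave peak detection: prominence of cos(phi) peaks and minimum
#: separation in (original-rate) frames
WAVE_PROMINENCE = 1.95
WAVE_MIN_SEPARATION_FRAMES = 8

#: turning-mode bands: Omega-like turns and deeper delta-turns
OMEGA_TURN_BAND = (10.0, 20.0)
DELTA_TURN_MIN = 20.0

ROAM, DWELL = 1, 0


@dataclass
class KinematicsSeries:
    """Centroid kinematics at 3 Hz plus 10 s windowed means."""

    time: np.ndarray  # (T,) seconds
    centroid: np.ndarray  # (T, 2)
    speed: np.ndarray  # (T-1,) px/s (or physical units if calibrated)
    angular_speed: np.ndarray  # (T-2,) rad/s
    window_time: np.ndarray  # (W,) window centers, s
    window_speed: np.ndarray  # (W,)
    window_angular_speed: np.ndarray  # (W,)
    frame_of_sample: np.ndarray  # (T,) original frame index per sample


def centroid_kinematics(
    centroids: np.ndarray,
    fps: float,
    calibration: float = 1.0,
) -> KinematicsSeries:
    """Centroid speed and angular speed, downsampled to 3 Hz.

    The velocity is the finite difference between subsequent downsampled
    points (dt = 1/3 s); the angular speed is the angle between the two
    displacement vectors of three subsequent points divided by dt. 10 s
    non-overlapping boxcar means are appended for state classification.

    ``calibration`` converts pixels to physical units (um/px) if supplied.
    """
    if fps < ANALYSIS_RATE_HZ:
        raise ValueError(f"fps must be at least {ANALYSIS_RATE_HZ}")
    centroids = np.asarray(centroids, dtype=float) * calibration
    stride = max(1, int(round(fps / ANALYSIS_RATE_HZ)))
    frames = np.arange(0, centroids.shape[0], stride)
    c = centroids[frames]
    dt = stride / fps
    if c.shape[0] < int(np.ceil(STATE_WINDOW_S / dt)):
        raise ValueError("series shorter than one state window")
    v = np.diff(c, axis=0) / dt
    speed = np.linalg.norm(v, axis=1)
    headings = np.arctan2(v[:, 1], v[:, 0])
    turn = np.abs(wrap_angle_diff(headings[1:], headings[:-1]))
    angular_speed = turn / dt
    per_window = int(round(STATE_WINDOW_S / dt))
    n_windows = speed.shape[0] // per_window
    w_speed = speed[: n_windows * per_window].reshape(n_windows, per_window).mean(axis=1)
    # angular speed is one sample shorter; use the same window boundaries
    a_padded = np.concatenate([angular_speed, [np.nan]])
    w_ang = np.nanmean(
        a_padded[: n_windows * per_window].reshape(n_windows, per_window), axis=1
    )
    t = frames / fps
    return KinematicsSeries(
        time=t,
        centroid=c,
        speed=speed,
        angular_speed=angular_speed,
        window_time=(np.arange(n_windows) + 0.5) * STATE_WINDOW_S,
        window_speed=w_speed,
        window_angular_speed=w_ang,
        frame_of_sample=frames,
    )


@dataclass
class HmmResult:
    """Two-state roaming/dwelling segmentation.

    State 1 is canonically *roaming* (the larger-mean-speed state) and
    state 0 *dwelling*, regardless of the order EM happened to find them.
    """

    states: np.ndarray  # (W,) per-window label, ROAM=1 / DWELL=0
    transition_matrix: np.ndarray  # (2, 2) row-stochastic
    stationary: np.ndarray  # (2,)
    means: np.ndarray  # (2, 2) per-state emission means (speed, ang. speed)
    variances: np.ndarray  # (2, 2) diagonal emission variances
    log_likelihood: float


def fit_roam_dwell(kin: KinematicsSeries, seed: int = 0) -> HmmResult:
    """Fit the two-state Gaussian HMM (diagonal covariance, Baum-Welch) to
    the windowed (speed, angular speed) features and decode by Viterbi."""
    features = np.column_stack([kin.window_speed, kin.window_angular_speed])
    features = features[~np.isnan(features).any(axis=1)]
    if features.shape[0] < 4 or np.allclose(features.std(axis=0), 0.0):
        raise ValueError("degenerate kinematics: cannot separate two states")
    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        n_iter=200,
        tol=1e-4,
        random_state=seed,
        init_params="stmc",
    )
    model.fit(features)
    states = model.predict(features)  # Viterbi
    means = model.means_.copy()
    variances = np.array([np.diag(c) for c in model.covars_])
    transmat = model.transmat_.copy()
    # canonical labeling: roaming has the larger mean speed
    roam_raw = int(np.argmax(means[:, 0]))
    if roam_raw != ROAM:
        states = 1 - states
        perm = np.array([1 - roam_raw, roam_raw])  # new index -> old index
        means = means[perm]
        variances = variances[perm]
        transmat = transmat[np.ix_(perm, perm)]
    evals, evecs = np.linalg.eig(transmat.T)
    stat = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    stat = stat / stat.sum()
    return HmmResult(
        states=states,
        transition_matrix=transmat,
        stationary=stat,
        means=means,
        variances=variances,
        log_likelihood=float(model.score(features)),
    )


def direction_angle(
    velocities: np.ndarray,
    mean_body_angles: np.ndarray,
    min_speed: float = 1e-9,
) -> np.ndarray:
    """Movement direction relative to the body axis.

    ``delta_psi = psi - Psi`` where psi = atan2(v_y, v_x) is the centroid
    velocity direction and Psi the mean centerline angle, normalized into
    [-pi/2, 3pi/2). Forward locomotion has delta_psi < pi/2. Samples with
    (near-)zero velocity are masked NaN.
    """
    velocities = np.asarray(velocities, dtype=float)
    mean_body_angles = np.asarray(mean_body_angles, dtype=float)
    if velocities.shape[0] != mean_body_angles.shape[0]:
        raise ValueError("velocity and body-angle series must align")
    psi = np.arctan2(velocities[:, 1], velocities[:, 0])
    delta = psi - mean_body_angles
    delta = np.mod(delta + np.pi / 2.0, 2.0 * np.pi) - np.pi / 2.0
    speed = np.linalg.norm(velocities, axis=1)
    delta[speed < min_speed] = np.nan
    return delta


def phase_velocity(
    a1: np.ndarray,
    a2: np.ndarray,
    fps: float,
    sign_convention: str = "methods",
    min_amplitude: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Body-wave phase and phase velocity from the first two eigenmodes.

    phi is the (quadrant-correct) angle between a2 and a1, unwrapped in
    time; omega is the derivative of a cubic-spline fit of phi. With the
    default ``methods`` convention phi = atan2(a2, a1); ``results`` negates
    it, which only flips the forward/backward labeling of omega. Samples
    where both modes vanish are masked NaN.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if sign_convention not in ("methods", "results"):
        raise ValueError("sign_convention must be 'methods' or 'results'")
    phi = np.arctan2(a2, a1)
    if sign_convention == "results":
        phi = -phi
    phi = np.unwrap(phi)
    t = np.arange(phi.shape[0]) / fps
    spline = CubicSpline(t, phi)
    omega = spline.derivative()(t)
    weak = np.hypot(a1, a2) < min_amplitude
    phi = phi.copy()
    phi[weak] = np.nan
    omega[weak] = np.nan
    return phi, omega


def count_body_waves(
    phi: np.ndarray,
    omega: np.ndarray,
    fps: float,
    prominence: float = WAVE_PROMINENCE,
    min_separation: int = WAVE_MIN_SEPARATION_FRAMES,
) -> dict:
    """Count complete body waves.

    Within maximal runs where the phase velocity does not change sign,
    peaks of cos(phi) with the given prominence and minimum separation are
    counted as full-body-wave events, split by direction (sign of omega).
    Returns event frames, counts per direction and rates per second.
    """
    phi = np.asarray(phi, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if phi.shape != omega.shape:
        raise ValueError("phi and omega must align")
    sign = np.sign(omega)
    sign[np.isnan(omega)] = 0
    events: list[int] = []
    directions: list[int] = []
    start = 0
    for end in range(1, phi.shape[0] + 1):
        if end == phi.shape[0] or sign[end] != sign[start]:
            if sign[start] != 0 and end - start >= 2:
                seg = np.cos(phi[start:end])
                peaks, _ = signal.find_peaks(
                    seg, prominence=prominence, distance=min_separation
                )
                events.extend((peaks + start).tolist())
                directions.extend([int(sign[start])] * peaks.size)
            start = end
    duration = phi.shape[0] / fps
    events_arr = np.asarray(events, dtype=int)
    directions_arr = np.asarray(directions, dtype=int)
    return {
        "event_frames": events_arr,
        "event_directions": directions_arr,
        "n_forward": int((directions_arr > 0).sum()),
        "n_backward": int((directions_arr < 0).sum()),
        "rate_per_s": events_arr.size / duration if duration > 0 else 0.0,
    }


def turn_distribution(
    a3: np.ndarray,
    states: np.ndarray,
    bins: int = 60,
) -> dict:
    """Per-state distribution of the turning mode a_3 with the fractions in
    the Omega-turn band (10 <= |a_3| < 20) and delta-turn band
    (|a_3| >= 20)."""
    a3 = np.asarray(a3, dtype=float)
    states = np.asarray(states)
    if a3.shape[0] != states.shape[0]:
        raise ValueError("a3 must align with state labels")
    lo, hi = OMEGA_TURN_BAND
    out: dict = {}
    edges = np.histogram_bin_edges(a3[~np.isnan(a3)], bins=bins)
    for label, name in ((ROAM, "roam"), (DWELL, "dwell")):
        vals = a3[(states == label) & ~np.isnan(a3)]
        if vals.size:
            pdf, _ = np.histogram(vals, bins=edges, density=True)
            omega_frac = float(((np.abs(vals) >= lo) & (np.abs(vals) < hi)).mean())
            delta_frac = float((np.abs(vals) >= DELTA_TURN_MIN).mean())
        else:
            pdf = np.zeros(edges.size - 1)
            omega_frac = delta_frac = 0.0
        out[name] = {
            "pdf": pdf,
            "bin_edges": edges,
            "omega_turn_fraction": omega_frac,
            "delta_turn_fraction": delta_frac,
            "n": int(vals.size),
        }
    return out
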