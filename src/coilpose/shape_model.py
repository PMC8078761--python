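"""Gaussian-mixture generative model of worm posture.

A GMM with full covariances over tangent-angle vectors serves as a simple
generative model of body shape: fitted by expectation-maximization to a
library of resolved postures, selected by AIC, then sampled to produce an
arbitrarily large stream of training poses that respect the correlations
between body parts while generalizing beyond the library.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .geometry import wrap_angle

__all__ = [
    "ShapeModel",
    "fit_shape_model",
    "select_components_aic",
    "sample_shapes",
    "balance_by_curvature",
    "save_shape_model",
    "load_shape_model",
]

#: default number of mixture components (appropriate for a ~15000-shape
#: library; tune to the desired variability of generated shapes)
DEFAULT_N_COMPONENTS = 270

#: diagonal jitter added to covariances during EM; keeps full covariances on
#: 100-dim data with few points per component non-singular
COVARIANCE_REGULARIZATION = 1e-6

_SCHEMA_VERSION = 1


@dataclass
class ShapeModel:
    """A fitted Gaussian mixture over centerline angle vectors."""

    weights: np.ndarray  # (k,) simplex
    means: np.ndarray  # (k, N)
    covariances: np.ndarray  # (k, N, N) full, symmetric PSD
    train_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if not np.allclose(self.covariances, np.swapaxes(self.covariances, 1, 2), atol=1e-8):
            raise ValueError("covariances must be symmetric")

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]


def _make_gmm(n_components: int, seed: int, max_iter: int = 100) -> GaussianMixture:
    return GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        reg_covar=COVARIANCE_REGULARIZATION,
        max_iter=max_iter,
        tol=1e-3,
        n_init=1,
        init_params="kmeans",
        random_state=seed,
    )


def fit_shape_model(
    shapes: np.ndarray,
    n_components: int = DEFAULT_N_COMPONENTS,
    seed: int = 0,
    max_iter: int = 100,
) -> ShapeModel:
    """Fit the posture GMM by expectation-maximization.

    Deterministic given ``seed``; raises if there are fewer shapes than
    components.
    """
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim != 2:
        raise ValueError("shapes must be (n_shapes, N)")
    if shapes.shape[0] < n_components:
        raise ValueError(
            f"{shapes.shape[0]} shapes cannot support {n_components} components"
        )
    gmm = _make_gmm(n_components, seed, max_iter=max_iter)
    gmm.fit(shapes)
    loglik = float(gmm.score(shapes) * shapes.shape[0])
    return ShapeModel(
        weights=gmm.weights_,
        means=gmm.means_,
        covariances=gmm.covariances_,
        train_meta={
            "seed": int(seed),
            "n_shapes": int(shapes.shape[0]),
            "aic": float(gmm.aic(shapes)),
            "log_likelihood": loglik,
            "converged": bool(gmm.converged_),
        },
    )


def select_components_aic(
    shapes: np.ndarray, candidates: list[int], seed: int = 0
) -> tuple[int, dict[int, float]]:
    """Akaike-information-criterion model selection over component counts.

    Returns ``(best_count, {count: aic})``; the best count is the argmin of
    AIC = 2k - 2 log L. Individual fit failures are recorded as ``inf``
    rather than raised.
    """
    shapes = np.asarray(shapes, dtype=float)
    if len(candidates) == 0:
        raise ValueError("candidates must be non-empty")
    curve: dict[int, float] = {}
    for k in candidates:
        try:
            gmm = _make_gmm(int(k), seed)
            gmm.fit(shapes)
            curve[int(k)] = float(gmm.aic(shapes))
        except Exception:  # noqa: BLE001 - a failed fit is data, not fatal
            curve[int(k)] = float("inf")
    best = min(curve, key=curve.get)
    return best, curve


def sample_shapes(model: ShapeModel, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` i.i.d. centerlines from the mixture, wrapped to (-pi, pi].

    Deterministic given ``seed``; sampling is done directly from the stored
    parameters so a model loaded from disk samples identically.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, model.weights)
    out = np.empty((n, model.n_dims))
    pos = 0
    for k, c in enumerate(counts):
        if c == 0:
            continue
        out[pos : pos + c] = rng.multivariate_normal(
            model.means[k], model.covariances[k], size=c, method="cholesky"
        )
        pos += c
    rng.shuffle(out)
    return wrap_angle(out)


def balance_by_curvature(
    shapes: np.ndarray,
    a3: np.ndarray,
    n: int,
    n_bins: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Subsample ``n`` shape indices approximately uniform in the turning
    mode a_3 over its occupied range.

    Implements inverse-frequency weighting over an ``n_bins`` histogram of
    a_3, so over-represented gently-curved postures are down-weighted and
    coils are kept. Sampling is with replacement (each occupied bin carries
    equal total probability, so sparse deep-coil bins are re-used rather
    than exhausted). Returns indices into ``shapes``.
    """
    a3 = np.asarray(a3, dtype=float)
    if a3.shape[0] != np.asarray(shapes).shape[0]:
        raise ValueError("a3 must align with shapes")
    rng = np.random.default_rng(seed)
    counts, edges = np.histogram(a3, bins=n_bins)
    which = np.clip(np.digitize(a3, edges[1:-1]), 0, n_bins - 1)
    weights = 1.0 / np.maximum(counts[which], 1)
    weights /= weights.sum()
    return rng.choice(a3.shape[0], size=n, replace=True, p=weights)


def save_shape_model(model: ShapeModel, path) -> None:
    """Serialize to a single ``.npz`` archive with a versioned schema."""
    np.savez_compressed(
        path,
        schema_version=_SCHEMA_VERSION,
        weights=model.weights,
        means=model.means,
        covariances=model.covariances,
        train_meta=json.dumps(model.train_meta),
    )


def load_shape_model(path) -> ShapeModel:
    with np.load(path, allow_pickle=False) as archive:
        version = int(archive["schema_version"])
        if version != _SCHEMA_VERSION:
            raise ValueError(f"unsupported shape-model schema version {version}")
        return ShapeModel(
            weights=archive["weights"],
            means=archive["means"],
            covariances=archive["covariances"],
            train_meta=json.loads(str(archive["train_meta"])),
        )
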