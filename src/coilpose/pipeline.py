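"""End-to-end pipeline: preprocess -> shape model -> synthetic training set
-> network training -> prediction -> post-processing -> optional behavior.

Every stage writes its artifact under a run directory and is skipped on
re-run if the artifact exists (resumable, reproducible: all randomness
derives from the config seed). The pipeline touches data only through the
:class:`~coilpose.fixtures.DatasetAdapter` API.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import network as net
from . import postprocess as post
from . import preprocess as prep
from . import shape_model as sm
from .fixtures import DatasetAdapter
from .geometry import (
    Skeleton,
    compute_eigenbasis,
    project_modes,
    resample_skeleton,
    skeleton_to_angles,
)
from .synth import ReferenceFrame, SynthParams, generate_training_set

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for one analysis run (defaults are desk-scale)."""

    image_size: int | None = None  # None: derived from labeled worm lengths
    n_skeleton_points: int = 33
    n_components: int = 40
    n_train: int = 4000
    n_eval_max: int = 500
    epochs: int = 5
    batch_size: int = 128
    learning_rate: float = 1e-3
    error_threshold: float = post.DEFAULT_ERROR_THRESHOLD
    augment: bool = True
    interpolate: bool = True
    smooth: bool = True
    run_behavior: bool = False
    max_references: int = 200
    seed: int = 0


def _round_to_divisor(size: int, divisor: int = 16) -> int:
    return max(int(np.ceil(size / divisor)) * divisor, 32)


def _stage(run_dir: Path, name: str):
    return run_dir / f"{name}.npz"


def run_pipeline(
    adapter: DatasetAdapter,
    config: PipelineConfig,
    run_dir,
    shape_corpus: np.ndarray | None = None,
    model_dir=None,
    resume: bool = True,
    verbose: bool = False,
) -> pd.DataFrame:
    """Run the full pipeline and return the per-frame results table.

    ``shape_corpus`` supplies the posture library for the generative model
    (body-frame angle vectors); if omitted, the labeled frames' own angles
    are used (which contain no coils — supplying a richer library is
    recommended). ``model_dir`` skips training and predicts with an
    existing checkpoint.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    rng_seed = int(config.seed)

    # ---- stage 1: preprocess ------------------------------------------------
    t0 = time.perf_counter()
    labeled_idx = np.asarray(adapter.labeled_indices(), dtype=int)
    if labeled_idx.size == 0:
        raise RuntimeError("preprocess stage failed: adapter provides no labeled frames")
    lengths = []
    for i in labeled_idx[: min(200, labeled_idx.size)]:
        skel = np.asarray(adapter.features(int(i))["skeleton"], float)
        lengths.append(float(np.linalg.norm(np.diff(skel, axis=0), axis=1).sum()))
    size = config.image_size or prep.default_image_size(lengths)
    size = _round_to_divisor(size)

    proc_file = _stage(run_dir, "processed")
    if resume and proc_file.exists():
        with np.load(proc_file) as a:
            images, bgs, offsets, usable = a["images"], a["bgs"], a["offsets"], a["usable"]
    else:
        n = len(adapter)
        images = np.zeros((n, size, size), dtype=np.uint8)
        bgs = np.zeros(n)
        offsets = np.zeros((n, 2), dtype=int)
        usable = np.zeros(n, dtype=bool)
        for i in range(n):
            try:
                mask, bg = adapter.segment(adapter.get_frame(i))
                frame = prep.standardize_frame(adapter.get_frame(i), mask, bg, size)
            except (prep.FrameUnusableError, ValueError):
                continue
            images[i] = frame.image
            bgs[i] = frame.background_value
            offsets[i] = frame.offset
            usable[i] = True
        np.savez_compressed(proc_file, images=images, bgs=bgs, offsets=offsets, usable=usable)
    timings["preprocess"] = time.perf_counter() - t0

    def processed_frame(i: int) -> prep.ProcessedFrame:
        mask = images[i] != np.uint8(np.clip(round(bgs[i]), 0, 255))
        return prep.ProcessedFrame(
            image=images[i], worm_mask=mask, background_value=bgs[i], offset=tuple(offsets[i])
        )

    # ---- stage 2: references and eval labels --------------------------------
    t0 = time.perf_counter()
    refs: list[ReferenceFrame] = []
    eval_images, eval_targets, eval_bgs = [], [], []
    ref_rng = np.random.default_rng(rng_seed + 1)
    chosen = labeled_idx[usable[labeled_idx]]
    angles_gt: dict[int, np.ndarray] = {}
    label_vectors: dict[int, np.ndarray] = {}
    for i in chosen:
        feats = adapter.features(int(i))
        raw_skel = np.asarray(feats["skeleton"], float)
        proc_skel = raw_skel - offsets[i][None, :]
        label_vectors[int(i)] = raw_skel[-1] - raw_skel[0]
        angles_gt[int(i)] = skeleton_to_angles(resample_skeleton(raw_skel, 101))
        if proc_skel.min() < 0 or proc_skel.max() > size - 1:
            continue
        pts = resample_skeleton(proc_skel, config.n_skeleton_points)
        seg_len = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).mean())
        refs.append(
            ReferenceFrame(
                frame=processed_frame(int(i)),
                skeleton=Skeleton(points=pts, ds=seg_len),
                widths3=tuple(feats["widths3"]),
                frame_index=int(i),
            )
        )
        eval_images.append(images[i])
        eval_targets.append(angles_gt[int(i)])
        eval_bgs.append(bgs[i])
    if not refs:
        raise RuntimeError("reference stage failed: no usable labeled frames")
    if len(refs) > config.max_references:
        keep = ref_rng.choice(len(refs), size=config.max_references, replace=False)
        refs = [refs[k] for k in sorted(keep)]
    if len(eval_images) > config.n_eval_max:
        keep = ref_rng.choice(len(eval_images), size=config.n_eval_max, replace=False)
        eval_images = [eval_images[k] for k in sorted(keep)]
        eval_targets = [eval_targets[k] for k in sorted(keep)]
        eval_bgs = [eval_bgs[k] for k in sorted(keep)]
    timings["references"] = time.perf_counter() - t0

    # ---- stage 3: shape model -----------------------------------------------
    t0 = time.perf_counter()
    model_file = run_dir / "shape_model.npz"
    if resume and model_file.exists():
        shape_model = sm.load_shape_model(model_file)
    else:
        if shape_corpus is None:
            shapes = np.stack([angles_gt[int(i)] for i in chosen])
            shapes = shapes - shapes.mean(axis=1, keepdims=True)
        else:
            shapes = np.asarray(shape_corpus, float)
        n_comp = min(config.n_components, shapes.shape[0] // 4)
        shape_model = sm.fit_shape_model(shapes, n_components=n_comp, seed=rng_seed + 2)
        sm.save_shape_model(shape_model, model_file)
    timings["shape_model"] = time.perf_counter() - t0

    # ---- stage 4 and 5: synthetic training set + training -------------------
    model_path = Path(model_dir) if model_dir else run_dir / "model"
    t0 = time.perf_counter()
    if not (resume and (model_path / "weights.npz").exists()):
        params = SynthParams(augment=config.augment)
        train_images = np.empty((config.n_train, size, size), dtype=np.uint8)
        train_targets = np.empty((config.n_train, 100), dtype=np.float32)
        train_bgs = np.empty(config.n_train, dtype=np.float32)
        k = 0
        for sample in generate_training_set(
            refs, shape_model, config.n_train, params, seed=rng_seed + 3
        ):
            train_images[k] = sample.image
            train_targets[k] = sample.target
            # corners are guaranteed background after outline masking
            train_bgs[k] = float(sample.image[0, 0])
            k += 1
        train_images, train_targets, train_bgs = (
            train_images[:k],
            train_targets[:k],
            train_bgs[:k],
        )
        spec = net.reduced_spec(size)
        model = net.build_model(spec, seed=rng_seed + 4)
        history = net.train(
            model,
            train_images,
            train_targets,
            train_bgs,
            np.stack(eval_images),
            np.stack(eval_targets),
            np.asarray(eval_bgs),
            net.TrainConfig(
                batch_size=config.batch_size,
                epochs=config.epochs,
                learning_rate=config.learning_rate,
                seed=rng_seed + 5,
            ),
            verbose=verbose,
        )
        net.save_model(model, model_path)
        (run_dir / "history.json").write_text(json.dumps(history))
    model = net.load_model(model_path)
    timings["train"] = time.perf_counter() - t0

    # ---- stage 6: predict ---------------------------------------------------
    t0 = time.perf_counter()
    pred_file = _stage(run_dir, "predictions")
    frame_ids = np.nonzero(usable)[0]
    if resume and pred_file.exists():
        with np.load(pred_file) as a:
            thetas = a["thetas"]
    else:
        pairs = net.predict(model, images[frame_ids], bgs[frame_ids], frame_indices=frame_ids)
        thetas = np.stack([p.theta_hat for p in pairs])
        np.savez_compressed(pred_file, thetas=thetas, frame_ids=frame_ids)
    pairs = [
        net.PredictionPair(
            theta_hat=thetas[k],
            theta_hat_flipped=post.flip_centerline(thetas[k]),
            frame_index=int(frame_ids[k]),
        )
        for k in range(len(frame_ids))
    ]
    timings["predict"] = time.perf_counter() - t0

    # ---- stage 7: postprocess -----------------------------------------------
    t0 = time.perf_counter()
    ref_frames = np.array([r.frame_index for r in refs])
    errors = np.full(len(adapter), np.nan)
    for k, fid in enumerate(frame_ids):
        ref = refs[int(np.argmin(np.abs(ref_frames - fid)))]
        err, _ = post.image_error(processed_frame(int(fid)), pairs[k].theta_hat, ref)
        errors[fid] = err
    valid = np.array([errors[fid] <= config.error_threshold for fid in frame_ids])
    segments = post.build_segments(pairs, adapter.fps, valid=valid, seed=rng_seed + 6)
    oriented = post.orient_segments(
        segments,
        pairs,
        {int(np.searchsorted(frame_ids, f)): v for f, v in label_vectors.items()
         if f in set(frame_ids.tolist())},
    )
    # oriented segments index into `pairs`; map back to dataset frames
    series = np.full((len(adapter), 100), np.nan)
    source = np.full(len(adapter), "none", dtype=object)
    for seg in oriented:
        fids = frame_ids[seg.frame_indices]
        series[fids] = seg.angles
        source[fids] = seg.orientation_source
    if config.interpolate:
        series = post.interpolate_gaps(series)
    if config.smooth:
        series = _smooth_runs(series)
    np.savez_compressed(_stage(run_dir, "angles"), angles=series)
    table = pd.DataFrame(
        {
            "frame": np.arange(len(adapter)),
            "time_s": np.arange(len(adapter)) / adapter.fps,
            "image_error": errors,
            "orientation_source": source,
            "discarded": np.isnan(series).any(axis=1),
        }
    )
    table.to_csv(run_dir / "results.csv", index=False)
    timings["postprocess"] = time.perf_counter() - t0

    # ---- stage 8: behavior (optional) ---------------------------------------
    if config.run_behavior:
        t0 = time.perf_counter()
        corpus = (
            np.asarray(shape_corpus, float)
            if shape_corpus is not None
            else np.stack([angles_gt[int(i)] for i in chosen])
        )
        basis = compute_eigenbasis(corpus - corpus.mean(axis=1, keepdims=True), n_modes=5)
        ok = ~np.isnan(series).any(axis=1)
        modes = np.full((len(adapter), 5), np.nan)
        modes[ok] = project_modes(series[ok], basis)
        centroids = _mask_centroids(images, bgs, offsets)
        kin = behavior_mod.centroid_kinematics(centroids, adapter.fps)
        hmm = behavior_mod.fit_roam_dwell(kin, seed=rng_seed + 7)
        np.savez_compressed(
            _stage(run_dir, "behavior"),
            modes=modes,
            window_states=hmm.states,
            transition_matrix=hmm.transition_matrix,
        )
        timings["behavior"] = time.perf_counter() - t0

    manifest = {
        "config": asdict(config),
        "image_size": int(size),
        "n_references": len(refs),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table


def _smooth_runs(series: np.ndarray, window: int = 9) -> np.ndarray:
    """Savitzky-Golay smoothing applied per contiguous valid run."""
    out = series.copy()
    valid = ~np.isnan(series).any(axis=1)
    start = None
    for i in range(series.shape[0] + 1):
        if i < series.shape[0] and valid[i]:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= window:
                out[start:i] = post.smooth_angles(series[start:i], window=window)
            start = None
    return out


def _mask_centroids(images: np.ndarray, bgs: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Worm centroid per frame in raw-frame coordinates, from the uniform-
    background processed images."""
    n = images.shape[0]
    out = np.zeros((n, 2))
    for i in range(n):
        mask = images[i] != np.uint8(np.clip(round(bgs[i]), 0, 255))
        if not mask.any():
            out[i] = np.nan
            continue
        ys, xs = np.nonzero(mask)
        out[i] = (xs.mean() + offsets[i, 0], ys.mean() + offsets[i, 1])
    return out
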