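"""End-to-end orchestration: simulate/load -> preprocess -> segment ->
CNN features -> IGWO-trained MLP -> metrics.

Every stage writes plain-file artifacts (PNG masks, CSV features, JSON
model and report) into the run directory so stages are independently
inspectable. One global seed fans out to per-stage child seeds, so a rerun
with the same configuration reproduces the final confusion matrix exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import features as feat
from . import igwo
from . import metrics as met
from . import preprocess as pre
from . import segmentation as seg
from . import synthetic as syn

__all__ = ["PipelineConfig", "RunReport", "ConfigurationError",
           "split_dataset", "run_pipeline", "load_manifest_images"]


class ConfigurationError(ValueError):
    """A pipeline input or option is missing or inconsistent."""


@dataclass
class PipelineConfig:
    """Run settings; ``reduced=True`` selects the CPU-scale CNN profile and
    small optimizer budgets, ``False`` the full-scale defaults."""

    out_dir: str = "melanopt_run"
    data_dir: str | None = None  # None -> simulate n_images synthetic samples
    n_images: int = 100
    melanoma_fraction: float = 0.5
    train_fraction: float = 0.7
    seed: int = 0
    reduced: bool = True
    segmentation: bool = True  # False -> use supplied ground-truth masks
    cnn_epochs: int | None = None
    igwo_population: int = 30
    igwo_iterations: int = 60
    igwo_stagnation: int = 30
    image: syn.ImageGenConfig = field(default_factory=syn.ImageGenConfig)


@dataclass
class RunReport:
    config: dict
    timings: dict
    dice_per_image: list
    cnn_history: list
    igwo_best_fitness: float
    igwo_iterations: int
    igwo_history: list
    confusion: dict
    test_metrics: dict
    roc_auc: float

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def split_dataset(manifest: pd.DataFrame, train_fraction: float, seed: int):
    """Deterministic stratified split of a (filename,label) manifest."""
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for _, group in manifest.groupby("label", sort=True):
        idx = rng.permutation(len(group))
        n_train = int(round(train_fraction * len(group)))
        train_parts.append(group.iloc[idx[:n_train]])
        test_parts.append(group.iloc[idx[n_train:]])
    train = pd.concat(train_parts).sort_index()
    test = pd.concat(test_parts).sort_index()
    return train, test


def load_manifest_images(data_dir):
    """Read manifest.csv plus images and any ``*_mask.png`` ground truth.

    Returns (manifest, images, masks) with images as float arrays in [0, 1]
    and masks as boolean arrays or None.
    """
    import imageio.v3 as iio

    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    images, masks = [], []
    for fname in manifest["filename"]:
        img = iio.imread(data_dir / fname).astype(float) / 255.0
        images.append(img)
        mask_path = data_dir / (Path(fname).stem + "_mask.png")
        masks.append(iio.imread(mask_path) > 127 if mask_path.exists() else None)
    return manifest, images, masks


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full diagnosis pipeline; returns the run report.

    Stage order: (simulate or load) -> preprocess -> SOM + greedy-refined
    segmentation -> ROI crop -> CNN feature training/extraction -> feature
    z-scoring -> IGWO-trained MLP -> held-out metrics.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_seed, split_seed, som_seed, cnn_seed, igwo_seed = _child_seeds(config.seed, 5)
    timings = {}

    t0 = time.perf_counter()
    if config.data_dir is None:
        data_dir = out / "data"
        syn.generate_dataset(replace(config.image, seed=sim_seed),
                             config.n_images, config.melanoma_fraction, data_dir)
    else:
        data_dir = Path(config.data_dir)
    manifest, images, masks = load_manifest_images(data_dir)
    timings["data"] = time.perf_counter() - t0

    if not config.segmentation:
        missing = [f for f, m in zip(manifest["filename"], masks) if m is None]
        if missing:
            raise ConfigurationError(
                "segmentation disabled but ground-truth masks are missing for: "
                + ", ".join(missing[:5])
            )

    cnn_config = (feat.CNNConfig.reduced(seed=cnn_seed) if config.reduced
                  else feat.CNNConfig(seed=cnn_seed))
    if config.cnn_epochs is not None:
        cnn_config = replace(cnn_config, epochs=config.cnn_epochs)

    t0 = time.perf_counter()
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    rois, dice_log = [], []
    import imageio.v3 as iio

    for i, (img, gt_mask) in enumerate(zip(images, masks)):
        processed = pre.preprocess(img)
        gray = pre.to_grayscale(processed)
        if config.segmentation:
            try:
                mask, _ = seg.segment_image(
                    gray, seg.SOMConfig(seed=som_seed + i))
            except (seg.DegenerateSegmentationError, seg.DegenerateRegionError):
                mask = np.ones_like(gray, dtype=bool)  # fall back to full frame
        else:
            mask = gt_mask
        if gt_mask is not None:
            dice_log.append(float(seg.dice(mask, gt_mask)))
        iio.imwrite(mask_dir / f"mask_{i:04d}.png",
                    np.where(mask, 255, 0).astype(np.uint8))
        rois.append(seg.extract_roi(processed, mask, out_side=cnn_config.input_side))
    rois = np.stack(rois).astype(np.float32)
    timings["preprocess_segment"] = time.perf_counter() - t0

    labels = (manifest["label"] == syn.MELANOMA).astype(int).to_numpy()
    train_df, test_df = split_dataset(manifest, config.train_fraction, split_seed)
    train_idx = train_df.index.to_numpy()
    test_idx = test_df.index.to_numpy()

    t0 = time.perf_counter()
    model = feat.build_feature_extractor(cnn_config)
    model, cnn_history = feat.train_feature_extractor(
        model, rois[train_idx], labels[train_idx])
    all_feats = feat.extract_features(model, rois)
    timings["cnn"] = time.perf_counter() - t0

    # z-score with training statistics so the box-bounded tanh MLP sees
    # well-scaled inputs
    mu = all_feats[train_idx].mean(axis=0)
    sd = all_feats[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    all_feats = (all_feats - mu) / sd
    feat_df = pd.DataFrame(all_feats,
                           columns=[f"f{j:03d}" for j in range(all_feats.shape[1])])
    feat_df.insert(0, "filename", manifest["filename"])
    feat_df.insert(1, "label", manifest["label"])
    feat_df.to_csv(out / "features.csv", index=False)

    t0 = time.perf_counter()
    igwo_config = igwo.IGWOConfig(
        population_size=config.igwo_population,
        max_iterations=config.igwo_iterations,
        stagnation_limit=config.igwo_stagnation,
        seed=igwo_seed,
    ) if config.reduced else igwo.IGWOConfig(seed=igwo_seed)
    mlp, opt_result = clf.train_classifier(
        all_feats[train_idx], labels[train_idx], igwo_config)
    mlp.to_json(out / "classifier.json")
    timings["igwo"] = time.perf_counter() - t0

    pred = mlp.predict(all_feats[test_idx])
    scores = mlp.scores(all_feats[test_idx])
    cm = met.confusion(labels[test_idx], pred)
    test_metrics = {"accuracy": (cm.tp + cm.tn) / cm.total}
    for fn in (met.binary_metrics, met.macro_metrics):
        try:
            test_metrics |= fn(cm)
        except met.UndefinedMetricError as err:  # degenerate tiny test sets
            test_metrics[err.metric] = None
    for name, fn in (("mcc", met.mcc), ("csi", met.csi)):
        try:
            test_metrics[name] = fn(cm)
        except met.UndefinedMetricError:
            test_metrics[name] = None
    try:
        _, _, auc = met.roc_curve(scores, labels[test_idx])
    except met.UndefinedMetricError:
        auc = float("nan")

    report = RunReport(
        config={k: v for k, v in asdict(config).items() if k != "image"},
        timings=timings,
        dice_per_image=dice_log,
        cnn_history=cnn_history,
        igwo_best_fitness=float(opt_result.best_fitness),
        igwo_iterations=int(opt_result.n_iterations),
        igwo_history=[float(v) for v in opt_result.history],
        confusion={"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
        test_metrics=test_metrics,
        roc_auc=float(auc),
    )
    report.save(out / "report.json")
    return report
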