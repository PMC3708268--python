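"""End-to-end orchestration of the CAD pipeline.

Stage order: restoration (Wiener) → optional wavelet diagnostics → lung
segmentation → left/right separation → candidate extraction + feature
discretization → maximum-likelihood HMM classification.  4-D input is
first sorted retrospectively into breathing-phase bins, then each bin is
processed with the 4-D threshold default.

Everything is driven by a :class:`PipelineConfig` that is validated in
full before any computation starts, and all randomness flows from a
single seed, so a run is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as lio
from .features import Codebook, build_codebook, discretize, extract_candidates
from .hmm import HMMParams, baum_welch, classify, init_params
from .lobes import LungSeparationError, conditional_dilate, separate_lungs
from .phantom import Frame, PhantomConfig, apply_degradation, generate_4d, \
    generate_slice, sort_by_phase
from .preprocess import BlurSpec, motion_blur, wiener_restore
from .segment import THRESHOLD_2D, THRESHOLD_4D, lung_mask
from .wavelet import dwt2, noise_map

__all__ = ["PipelineConfig", "run_pipeline", "run_4d",
           "nodule_classification_experiment"]

log = logging.getLogger("lungcad")


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed.

    ``threshold=None`` selects the stock default for the input kind
    (0.05555 for 2-D slices, 0.0678 for 4-D frames).
    """

    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(
        n_nodules=2, noise_sigma=0.01, blur_length=5))
    wiener_k: float = 0.05
    wavelet_levels: int = 0          # 0 disables the diagnostic branch
    threshold: float | None = None
    min_area: int = 4
    intensity_quantile: float = 0.95
    lobe_min_fraction: float = 0.1
    lobe_half_width: int = 10
    dilate_iterations: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.wiener_k < 0:
            raise ValueError("wiener_k must be >= 0")
        if self.threshold is not None and not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if not 0.0 < self.intensity_quantile < 1.0:
            raise ValueError("intensity_quantile must lie in (0, 1)")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.wavelet_levels < 0:
            raise ValueError("wavelet_levels must be >= 0")
        if self.dilate_iterations < 0:
            raise ValueError("dilate_iterations must be >= 0")
        if not 0.0 <= self.lobe_min_fraction <= 1.0:
            raise ValueError("lobe_min_fraction must lie in [0, 1]")
        # PhantomConfig validates itself on construction

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True)


def _process_slice(image: np.ndarray, config: PipelineConfig, threshold: float,
                   models: dict[str, HMMParams] | None,
                   codebook: Codebook | None, prev_path=None) -> dict:
    """Run restoration → segmentation → separation → features on one slice."""
    blur = motion_blur(image.shape, config.phantom.blur_length,
                       config.phantom.blur_angle, K=config.wiener_k)
    restored = wiener_restore(image, blur) if config.phantom.blur_length > 1 \
        else image
    artifacts = {"restored": restored}

    if config.wavelet_levels > 0:
        artifacts["noise_map"] = noise_map(dwt2(restored, config.wavelet_levels))

    lungs_bin = lung_mask(restored, threshold)
    summary: dict = {"n_lung_pixels": int((lungs_bin > 0).sum())}
    if not lungs_bin.any():
        log.warning("no lung component survived cleanup")
        summary.update({"candidates": [], "symbols": [], "call": None})
        artifacts["lungs"] = lungs_bin
        return {"summary": summary, "artifacts": artifacts, "path": None}

    sep = separate_lungs(lungs_bin, restored, prev_path=prev_path,
                         min_fraction=config.lobe_min_fraction,
                         half_width=config.lobe_half_width)
    lungs = conditional_dilate(sep.labels, lungs_bin, config.dilate_iterations)
    artifacts["lungs"] = lungs

    cands = extract_candidates(restored, lungs, config.min_area,
                               config.intensity_quantile)
    summary["candidates"] = [
        {"centroid": [round(float(x), 3) for x in c.centroid],
         "features": [round(float(f), 6) for f in c.features]} for c in cands]

    symbols: list[int] = []
    if codebook is not None and cands:
        symbols = [int(s) for s in discretize(cands, codebook)]
    summary["symbols"] = symbols

    call = None
    if models is not None and symbols:
        label, logliks = classify(models, np.array(symbols))
        call = {"label": label,
                "logliks": {k: round(float(v), 6) for k, v in logliks.items()}}
    summary["call"] = call
    return {"summary": summary, "artifacts": artifacts, "path": sep.path if lungs_bin.any() else None}


def run_pipeline(config: PipelineConfig, input: str | Path = "simulate",
                 models: dict[str, HMMParams] | None = None,
                 codebook: Codebook | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run the full 2-D pipeline on a file or a simulated phantom.

    Returns the machine-readable summary; with ``out_dir`` every
    intermediate (restored slice, lung labels, noise map, summary JSON)
    is also written to disk.  Deterministic given config + seed.
    """
    config.validate()
    threshold = config.threshold if config.threshold is not None else THRESHOLD_2D

    if str(input) == "simulate":
        clean, gt = generate_slice(dataclasses.replace(config.phantom,
                                                       seed=config.seed))
        blur = motion_blur(clean.shape, config.phantom.blur_length,
                           config.phantom.blur_angle)
        degraded = apply_degradation(clean, blur, config.phantom.noise_sigma,
                                     seed=config.seed + 1)
        truth = {"n_nodules": len(gt.nodule_centers),
                 "nodule_centers": [[int(r), int(c)] for r, c, _rad, _m
                                    in gt.nodule_centers]}
    else:
        degraded = lio.read_image(input)
        truth = None

    result = _process_slice(degraded, config, threshold, models, codebook)
    summary = {"input": str(input), "threshold": threshold,
               "seed": config.seed, **result["summary"]}
    if truth is not None:
        summary["ground_truth"] = truth

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lio.write_image(out / "restored.png", result["artifacts"]["restored"])
        lio.write_mask(out / "lungs.png", result["artifacts"]["lungs"])
        if "noise_map" in result["artifacts"]:
            nm = result["artifacts"]["noise_map"]
            lio.write_image(out / "noise_map.png", nm / max(nm.max(), 1e-12))
        (out / "summary.json").write_text(json.dumps(summary, sort_keys=True,
                                                     indent=2) + "\n")
    return summary


def run_4d(config: PipelineConfig, frames: list[Frame] | None = None,
           models: dict[str, HMMParams] | None = None,
           codebook: Codebook | None = None,
           out_dir: str | Path | None = None) -> dict:
    """Per-phase-bin pipeline over a tagged frame sequence.

    Frames are sorted retrospectively into ``config.phantom.n_phases``
    bins; each bin's frames run through the slice pipeline with the 4-D
    threshold default, the junction path propagating frame to frame.
    """
    config.validate()
    threshold = config.threshold if config.threshold is not None else THRESHOLD_4D
    if frames is None:
        frames, _gt = generate_4d(dataclasses.replace(config.phantom,
                                                      seed=config.seed))
    bins = sort_by_phase(frames, config.phantom.n_phases)
    out: dict = {"threshold": threshold, "n_frames": len(frames), "bins": {}}
    for b in sorted(bins):
        prev_path = None
        frame_summaries = []
        for fr in bins[b]:
            res = _process_slice(fr.image, config, threshold, models, codebook,
                                 prev_path=prev_path)
            prev_path = res["path"] or prev_path
            frame_summaries.append(res["summary"])
        out["bins"][str(b)] = {"n_frames": len(bins[b]),
                               "frames": frame_summaries}
    if out_dir is not None:
        outp = Path(out_dir)
        outp.mkdir(parents=True, exist_ok=True)
        (outp / "summary4d.json").write_text(json.dumps(out, sort_keys=True,
                                                        indent=2) + "\n")
    return out


def _scan_features(seed: int, malignant: bool, image_size: int = 128) -> list[np.ndarray]:
    """Simulate one scan and return its candidate feature vectors in order."""
    phantom = PhantomConfig(
        image_size=image_size,
        n_nodules=1 if malignant else 2,
        nodule_radius_range=(4.5, 6.5) if malignant else (2.0, 3.5),
        malignant=malignant,
        noise_sigma=0.01, blur_length=5, seed=seed)
    cfg = PipelineConfig(phantom=phantom, intensity_quantile=0.90,
                         min_area=8, seed=seed)
    summary = run_pipeline(cfg)
    return [np.array(c["features"]) for c in summary["candidates"]]


def nodule_classification_experiment(n_scans: int = 200, seed: int = 0,
                                     n_states: int = 2, n_symbols: int = 8,
                                     train_fraction: float = 0.5,
                                     image_size: int = 128) -> dict:
    """Two-model HMM benign/malignant study on simulated scans.

    Half the scans carry small round ("benign") nodules, half larger
    irregular ("malignant-like") ones.  Every scan runs through the full
    pipeline; train-split candidates fit the shared codebook and one HMM
    per class, and held-out scans are called by maximum likelihood.
    A scan yielding no candidates counts as a miss.

    Returns accuracy (percent), per-class counts and the split sizes.
    """
    rng = np.random.default_rng(seed)
    scan_seeds = rng.integers(0, 2 ** 31 - 1, size=n_scans)
    labels = np.array(["malignant" if i % 2 else "benign" for i in range(n_scans)])
    feats = [_scan_features(int(s), lab == "malignant", image_size)
             for s, lab in zip(scan_seeds, labels)]

    n_train = int(round(train_fraction * n_scans))
    train_idx = np.arange(n_train)
    test_idx = np.arange(n_train, n_scans)

    train_vectors = np.vstack([f for i in train_idx for f in feats[i]])
    codebook = build_codebook(train_vectors, n_symbols, seed=seed)

    models: dict[str, HMMParams] = {}
    for lab in ("benign", "malignant"):
        seqs = [discretize(np.vstack(feats[i]), codebook)
                for i in train_idx if labels[i] == lab and feats[i]]
        init = init_params(n_states, n_symbols, seed=seed)
        models[lab] = baum_welch(init, seqs, max_iter=100).params

    n_correct = 0
    n_detected = 0
    for i in test_idx:
        if not feats[i]:
            continue
        n_detected += 1
        call, _ = classify(models, discretize(np.vstack(feats[i]), codebook))
        n_correct += int(call == labels[i])

    n_test = len(test_idx)
    return {"accuracy_percent": 100.0 * n_correct / n_test,
            "n_scans": n_scans, "n_train": n_train, "n_test": n_test,
            "n_test_detected": n_detected}
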