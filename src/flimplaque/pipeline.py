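"""End-to-end convenience pipelines over the default study conditions.

These functions wire the generator, processing, classification and
reproducibility stages together exactly as the package's tests and
reproduction scripts run them: a labeled 297-ROI training pullback for
cross-validation, and a twice-simulated atheroma pullback for the
repeatability statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import CvReport, RfcConfig, classify_pullback, cross_validate, train_rfc
from .processing import ProcessingConfig, PullbackReadouts, process_pullback
from .repro import FramePairSet, class_proportion_agreement, feature_agreement
from .roi import extract_roi_features, rois_from_phantom
from .synthetic import (
    OpticsConfig,
    VesselPhantom,
    atheroma_config,
    build_vessel_phantom,
    roi_dataset_config,
    simulate_decays,
    simulate_replicate,
)

__all__ = [
    "build_labeled_dataset",
    "default_crossval",
    "replicate_agreement",
]


def build_labeled_dataset(
    seed: int = 42,
    optics: OpticsConfig | None = None,
    processing: ProcessingConfig | None = None,
) -> tuple[pd.DataFrame, VesselPhantom, PullbackReadouts]:
    """Simulate and process the default labeled training pullback.

    Builds the 297-ROI phantom (79 fibrotic / 66 lipid / 41 macrophage /
    38 lipids+macrophage / 73 normal), simulates its decay cube and
    returns the location-level feature table together with the phantom and
    the processed readouts.
    """
    rng = np.random.default_rng(seed)
    phantom = build_vessel_phantom(roi_dataset_config(), seed=int(rng.integers(2**31 - 1)))
    cube = simulate_decays(phantom, optics=optics, seed=int(rng.integers(2**31 - 1)))
    readouts = process_pullback(cube, processing)
    table = extract_roi_features(readouts, rois_from_phantom(phantom.rois))
    return table, phantom, readouts


def default_crossval(seed: int = 42, k: int = 5, n_trees: int = 100) -> CvReport:
    """ROI-grouped k-fold cross-validation on the default labeled dataset."""
    table, _, _ = build_labeled_dataset(seed)
    return cross_validate(table, k=k, config=RfcConfig(n_trees=n_trees, seed=seed))


def replicate_agreement(
    seed: int = 1,
    n_frames: int = 49,
    train_seed: int = 42,
    with_classification: bool = True,
) -> dict:
    """Repeatability statistics for two simulated pullbacks of one artery.

    Simulates an atheroma phantom twice under the replicate-noise model
    (new Poisson noise, distance factors redrawn within +/-10%), pairs the
    frames by index, and reports per-feature frame-mean agreement
    (ICC(2,1) + Bland-Altman). With ``with_classification`` a forest
    trained on the default labeled dataset also classifies both pullbacks
    and the per-class proportion ICCs are included.
    """
    rng = np.random.default_rng(seed)
    phantom = build_vessel_phantom(atheroma_config(n_frames), seed=int(rng.integers(2**31 - 1)))
    cube_a = simulate_replicate(phantom, seed=int(rng.integers(2**31 - 1)))
    cube_b = simulate_replicate(phantom, seed=int(rng.integers(2**31 - 1)))
    ra, rb = process_pullback(cube_a), process_pullback(cube_b)
    pairs = FramePairSet(tuple((f, f) for f in range(n_frames)), provenance="index pairing")
    report: dict = {"features": feature_agreement(ra, rb, pairs), "n_pairs": len(pairs)}
    if with_classification:
        table, _, _ = build_labeled_dataset(train_seed)
        model = train_rfc(table, RfcConfig(seed=train_seed))
        map_a, map_b = classify_pullback(model, ra), classify_pullback(model, rb)
        report["class_proportions"] = class_proportion_agreement(map_a, map_b, pairs)
    return report
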