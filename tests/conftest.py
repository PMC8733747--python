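"""Shared fixtures: expensive simulated datasets are built once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import flimplaque as fp
from flimplaque.roi import aggregate_features, extract_roi_features
from flimplaque.synthetic import build_vessel_phantom, roi_dataset_config, simulate_decays

warnings.filterwarnings("ignore", category=RuntimeWarning, module="pingouin")


@pytest.fixture(scope="session")
def default_dataset():
    """The default labeled 297-ROI training pullback (seed 42)."""
    table, phantom, readouts = fp.build_labeled_dataset(seed=42)
    return table, phantom, readouts


@pytest.fixture(scope="session")
def default_cv(default_dataset):
    """ROI-grouped 5-fold cross-validation report on the default dataset."""
    table, _, _ = default_dataset
    return fp.cross_validate(table, k=5, config=fp.RfcConfig(seed=42))


@pytest.fixture(scope="session")
def balanced_roi_tables():
    """A 30-ROI-per-class pullback for the signature similarity statistics.

    Returns (location_table, roi_table): the location-level feature table
    and its per-ROI aggregation.
    """
    cfg = roi_dataset_config({c: 30 for c in fp.CLASS_ORDER})
    phantom = build_vessel_phantom(cfg, seed=5)
    cube = simulate_decays(phantom, seed=6)
    table = extract_roi_features(fp.process_pullback(cube), fp.rois_from_phantom(phantom.rois))
    return table, aggregate_features(table, "roi")


@pytest.fixture(scope="session")
def tiny_pullback():
    """A small mixed pullback with its decay cube and readouts (fast)."""
    cfg = fp.PhantomConfig(
        n_frames=6, n_locations=64, layout="rois",
        roi_counts={c: 5 for c in fp.CLASS_ORDER}, roi_frames=1, roi_locations=8,
    )
    phantom = build_vessel_phantom(cfg, seed=3)
    cube = simulate_decays(phantom, seed=4)
    readouts = fp.process_pullback(cube)
    return phantom, cube, readouts
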