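"""Readers and writers tying the pipeline stages together.

One HDF5 container per pullback holds the decay cube, the phantom ground
truth and all acquisition metadata; feature tables travel as CSV with a
stable column order; trained models as a single joblib file with a schema
version tag; reports as JSON. All numeric payloads round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import h5py
import joblib
import numpy as np
import pandas as pd
import yaml

from .classify import CvReport, RfcModel
from .core import CLASS_ORDER, ComponentClass
from .processing import EnFaceMap
from .roi import FEATURE_COLUMNS, LabeledRoi
from .synthetic import DecayCube, OpticsConfig, PhantomConfig, PhantomRoi, VesselPhantom

__all__ = [
    "SCHEMA_VERSION",
    "write_pullback_container",
    "read_pullback_container",
    "write_feature_table",
    "read_feature_table",
    "write_model",
    "read_model",
    "write_report",
    "read_roi_table",
    "write_roi_table",
    "save_en_face_png",
    "load_config",
]

SCHEMA_VERSION = "1"

FEATURE_TABLE_COLUMNS = ["roi_id", "frame", "location", *FEATURE_COLUMNS, "label"]


class FormatError(ValueError):
    """A file does not conform to the expected container/table layout."""


# ---------------------------------------------------------------------------
# Pullback container (HDF5)
# ---------------------------------------------------------------------------

def write_pullback_container(
    path: str | Path, cube: DecayCube, phantom: VesselPhantom | None = None
) -> None:
    """Write one pullback (decay cube + optional phantom truth) to HDF5.

    Layout: ``/traces`` (frame x location x channel x bin, float32),
    ``/phantom/{labels,depth,distance}``, ``/phantom/rois`` (id, f0, f1,
    l0, l1, class index), optics parameters and seeds as root attributes.
    """
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.create_dataset("traces", data=cube.traces, compression="gzip", compression_opts=1)
        for k, v in dataclasses.asdict(cube.optics).items():
            h5.attrs[f"optics_{k}"] = v
        h5.attrs["seed"] = -1 if cube.seed is None else cube.seed
        if phantom is not None:
            g = h5.create_group("phantom")
            g.create_dataset("labels", data=phantom.labels)
            g.create_dataset("depth", data=phantom.depth)
            g.create_dataset("distance", data=phantom.distance)
            g.attrs["seed"] = phantom.seed
            rois = np.array(
                [
                    (r.roi_id, *r.frame_range, *r.loc_range, CLASS_ORDER.index(r.label))
                    for r in phantom.rois
                ],
                dtype=np.int64,
            ).reshape(-1, 6)
            g.create_dataset("rois", data=rois)


def read_pullback_container(path: str | Path) -> tuple[DecayCube, VesselPhantom | None]:
    path = Path(path)
    try:
        h5 = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"{path} is not a readable pullback container: {exc}") from exc
    with h5:
        if "traces" not in h5:
            raise FormatError(f"{path} lacks the /traces dataset")
        opt_keys = {f.name for f in dataclasses.fields(OpticsConfig)}
        kwargs: dict[str, Any] = {}
        for k, v in h5.attrs.items():
            if k.startswith("optics_") and k[7:] in opt_keys:
                if k[7:] == "background_window":
                    v = tuple(np.asarray(v).tolist())
                elif hasattr(v, "item"):
                    v = v.item()
                kwargs[k[7:]] = v
        kwargs["poisson_noise"] = bool(kwargs.get("poisson_noise", True))
        seed = int(h5.attrs.get("seed", -1))
        cube = DecayCube(h5["traces"][...], OpticsConfig(**kwargs), None if seed < 0 else seed)
        phantom = None
        if "phantom" in h5:
            g = h5["phantom"]
            rois = [
                PhantomRoi(int(r[0]), (int(r[1]), int(r[2])), (int(r[3]), int(r[4])),
                           CLASS_ORDER[int(r[5])])
                for r in g["rois"][...]
            ]
            labels = g["labels"][...]
            phantom = VesselPhantom(
                labels, g["depth"][...], g["distance"][...], rois,
                int(g.attrs["seed"]), PhantomConfig(n_frames=labels.shape[0],
                                                    n_locations=labels.shape[1]),
            )
    return cube, phantom


# ---------------------------------------------------------------------------
# Tables, models, reports
# ---------------------------------------------------------------------------

def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write a location-level feature table as CSV in the stable column order."""
    cols = [c for c in FEATURE_TABLE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("FL_ch1", "FL_ch2", "IR1", "label") if c not in df.columns]
    if missing:
        raise FormatError(f"feature table {path} lacks columns {missing}")
    df.attrs["level"] = "location"
    return df


def write_roi_table(path: str | Path, rois: list[LabeledRoi]) -> None:
    pd.DataFrame(
        [
            {
                "roi_id": r.roi_id, "pullback": r.pullback_id,
                "frame_start": r.frame_range[0], "frame_end": r.frame_range[1],
                "loc_start": r.loc_range[0], "loc_end": r.loc_range[1],
                "class": r.label.value, "note": r.note,
            }
            for r in rois
        ]
    ).to_csv(path, index=False)


def read_roi_table(path: str | Path) -> list[LabeledRoi]:
    df = pd.read_csv(path)
    need = {"roi_id", "frame_start", "frame_end", "loc_start", "loc_end", "class"}
    if not need.issubset(df.columns):
        raise FormatError(f"ROI table {path} lacks columns {sorted(need - set(df.columns))}")
    return [
        LabeledRoi(
            int(r.roi_id), (int(r.frame_start), int(r.frame_end)),
            (int(r.loc_start), int(r.loc_end)), ComponentClass(r["class"]),
            str(r.get("pullback", "")), str(r.get("note", "")),
        )
        for _, r in df.iterrows()
    ]


def write_model(path: str | Path, model: RfcModel) -> None:
    joblib.dump({"schema_version": SCHEMA_VERSION, "kind": "flimplaque-rfc", "model": model}, path)


def read_model(path: str | Path) -> RfcModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # joblib raises assorted errors on truncation
        raise FormatError(f"{path} is not a readable model file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("kind") != "flimplaque-rfc":
        raise FormatError(f"{path} is not a flimplaque model file")
    return payload["model"]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    return obj


def write_report(path: str | Path, report: Any) -> None:
    """Serialize a report object (dataclass / dict / DataFrame mix) to JSON."""
    payload = {"schema_version": SCHEMA_VERSION, "report": _jsonable(report)}
    if isinstance(report, CvReport):
        payload["kind"] = "cv-report"
        payload["report"].pop("roc_curves", None)  # curves are large; keep AUCs
    Path(path).write_text(json.dumps(payload, indent=2))


def save_en_face_png(path: str | Path, en_face: EnFaceMap) -> None:
    """Render an en face map to PNG with a JSON sidecar of the color scale."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    im = ax.imshow(en_face.values.T, aspect="auto", origin="lower", cmap=en_face.cmap)
    ax.set_xlabel("frame (pullback axis)")
    ax.set_ylabel("location (angle)")
    fig.colorbar(im, ax=ax, label=en_face.feature)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "feature": en_face.feature,
                "cmap": en_face.cmap,
                "vmin": float(en_face.values.min()),
                "vmax": float(en_face.values.max()),
                "shape": list(en_face.shape),
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS = {"phantom", "optics", "forest", "processing", "seeds", "paths"}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML/JSON pipeline config; unknown top-level keys are rejected."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config root must be a mapping")
    unknown = set(cfg) - _CONFIG_SECTIONS
    if unknown:
        raise FormatError(f"unknown config section(s): {sorted(unknown)}")
    return cfg
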