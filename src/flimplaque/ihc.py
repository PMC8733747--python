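"""Quantitative immunohistochemistry: stain unmixing and angular morphometry.

Stained-section RGB images are unmixed in Beer-Lambert optical-density
space (per-pixel 3x3 linear solve against the stain reference OD vectors,
negative solutions clipped), overlaid into a multiplexed pseudo-color
image, and quantified inside 200-um-deep quadrangular ROIs drawn at every
1-degree angle interval along the luminal contour. The component with the
highest relative density is the representative component of each ROI; a
ROI whose lipid and macrophage densities both exceed threshold without
either dominating by more than 2:1 is called lipids+macrophage, since no
joint stain exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .core import CLASS_LABELS, ComponentClass

__all__ = [
    "StainSpec",
    "DEFAULT_STAINS",
    "MultiplexedIHC",
    "QuadRoi",
    "color_deconvolve",
    "multiplex_overlay",
    "generate_quad_rois",
    "roi_component_densities",
    "compare_rfc_vs_ihc",
]

_EPS = 1e-6


@dataclass(frozen=True)
class StainSpec:
    """One stain: its target component, reference OD vector and display color.

    The OD vectors are synthetic reference absorptions chosen to be well
    conditioned, not calibrated chromogen spectra. ``positivity_threshold``
    is the mean in-ROI density above which a component counts as present.
    """

    name: str
    target: str  # component the stain marks: lipid / macrophage / smc
    od_vector: tuple[float, float, float]
    display_color: tuple[float, float, float]
    positivity_threshold: float = 0.1


#: ORO marks lipid (displayed yellow), PM-2K macrophages (red),
#: SMA smooth muscle cells (bright blue).
DEFAULT_STAINS: tuple[StainSpec, ...] = (
    StainSpec("ORO", "lipid", (0.10, 0.75, 0.65), (1.0, 0.9, 0.1)),
    StainSpec("PM-2K", "macrophage", (0.27, 0.57, 0.78), (1.0, 0.1, 0.1)),
    StainSpec("SMA", "smc", (0.65, 0.70, 0.29), (0.1, 0.5, 1.0)),
)


def _od_matrix(stains: tuple[StainSpec, ...]) -> np.ndarray:
    m = np.asarray([s.od_vector for s in stains], dtype=float)
    if len(stains) > 3:
        raise ValueError("at most 3 stains can be unmixed from an RGB image")
    if np.linalg.matrix_rank(m) < len(stains) or (
        len(stains) == 3 and np.linalg.cond(m) > 1e6
    ):
        raise ValueError("stain OD vectors are collinear; cannot unmix")
    return m


def color_deconvolve(
    rgb: np.ndarray, stains: tuple[StainSpec, ...] = DEFAULT_STAINS
) -> dict[str, np.ndarray]:
    """Unmix an RGB image into per-stain density maps.

    ``rgb`` is float in [0, 1] (or uint8, rescaled). Per pixel the optical
    density ``-ln(rgb)`` is solved against the stain OD matrix in the
    least-squares sense (exact for 3 independent stains); negative
    densities are clipped to 0. A pure white pixel has zero density in
    every stain.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.dtype.kind != "f" or rgb.max() > 1.5:
        rgb = rgb / 255.0
    m = _od_matrix(stains)
    od = -np.log(np.clip(rgb, _EPS, 1.0))
    sol, *_ = np.linalg.lstsq(m.T, od.reshape(-1, 3).T, rcond=None)
    dens = np.clip(sol.T.reshape(*rgb.shape[:2], len(stains)), 0.0, None)
    return {s.name: dens[..., i] for i, s in enumerate(stains)}


@dataclass
class MultiplexedIHC:
    """Co-registered per-stain density maps plus their pseudo-color overlay."""

    densities: dict[str, np.ndarray]
    overlay: np.ndarray  # (H, W, 3) float in [0, 1]
    stains: tuple[StainSpec, ...]
    pixel_size_um: float


def multiplex_overlay(
    densities: dict[str, np.ndarray],
    stains: tuple[StainSpec, ...] = DEFAULT_STAINS,
    pixel_size_um: float = 4.0,
    display_threshold: float = 0.05,
) -> MultiplexedIHC:
    """Blend per-stain density maps into one multiplexed overlay.

    Additive blend on black: each stain contributes its display color
    weighted by its density where the density exceeds the display
    threshold. The overlay is fully determined by the stored maps, so
    regenerating it is pixel-identical.
    """
    by_name = {s.name: s for s in stains}
    unknown = set(densities) - set(by_name)
    if unknown:
        raise ValueError(f"unknown stain name(s): {sorted(unknown)}")
    shape = next(iter(densities.values())).shape
    overlay = np.zeros((*shape, 3))
    for name, dmap in densities.items():
        s = by_name[name]
        w = np.where(dmap >= display_threshold, np.clip(dmap, 0.0, 1.0), 0.0)
        overlay += w[..., None] * np.asarray(s.display_color)
    overlay = np.clip(overlay, 0.0, 1.0)
    used = tuple(by_name[n] for n in densities)
    return MultiplexedIHC(dict(densities), overlay, used, pixel_size_um)


@dataclass(frozen=True)
class QuadRoi:
    """One angular quadrangular ROI anchored on the luminal contour.

    Vertices in um, ordered (inner at angle a, inner at a+step, outer at
    a+step, outer at a); ``angle_deg`` is the starting angle.
    """

    angle_deg: int
    vertices_um: tuple[tuple[float, float], ...]


def _contour_radius(contour: np.ndarray, center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Angles (deg, 12 o'clock = 0, clockwise) and radii of contour vertices."""
    rel = contour - center
    ang = np.degrees(np.arctan2(rel[:, 0], -rel[:, 1])) % 360.0
    rad = np.hypot(rel[:, 0], rel[:, 1])
    order = np.argsort(ang)
    return ang[order], rad[order]


def generate_quad_rois(
    contour_um: np.ndarray,
    center_um: tuple[float, float] = (0.0, 0.0),
    depth_um: float = 200.0,
    step_deg: int = 1,
) -> list[QuadRoi]:
    """Quadrangular ROIs along the luminal surface, one per angular step.

    ``contour_um`` is a closed polygon (first vertex repeated last) of
    (x, y) points in um around ``center_um``. Each ROI spans ``step_deg``
    degrees angularly and extends ``depth_um`` radially outward from the
    interpolated luminal radius. 360 ROIs at the default 1-degree step.
    """
    contour_um = np.asarray(contour_um, dtype=float)
    if contour_um.ndim != 2 or contour_um.shape[1] != 2 or len(contour_um) < 4:
        raise ValueError("contour must be an (N, 2) array of at least 4 points")
    if not np.allclose(contour_um[0], contour_um[-1]):
        raise ValueError("contour is open: first and last vertices must coincide")
    if depth_um <= 0:
        raise ValueError("ROI depth must be positive")
    if 360 % step_deg:
        raise ValueError("step_deg must divide 360")
    center = np.asarray(center_um, dtype=float)
    ang, rad = _contour_radius(contour_um[:-1], center)
    # periodic interpolation of r(theta)
    ang_ext = np.r_[ang - 360.0, ang, ang + 360.0]
    rad_ext = np.r_[rad, rad, rad]

    def r_of(theta: np.ndarray) -> np.ndarray:
        return np.interp(theta, ang_ext, rad_ext)

    def xy(theta_deg: float, r: float) -> tuple[float, float]:
        th = np.radians(theta_deg)
        return (center[0] + r * np.sin(th), center[1] - r * np.cos(th))

    rois = []
    for a in range(0, 360, step_deg):
        a1 = a + step_deg
        r0 = float(r_of(np.array([float(a)]))[0])
        r1 = float(r_of(np.array([float(a1)]))[0])
        verts = (
            xy(a, r0),
            xy(a1, r1),
            xy(a1, r1 + depth_um),
            xy(a, r0 + depth_um),
        )
        rois.append(QuadRoi(a, verts))
    return rois


def roi_component_densities(
    multiplexed: MultiplexedIHC,
    rois: list[QuadRoi],
    origin_um: tuple[float, float] | None = None,
    tie_priority: tuple[str, ...] = ("macrophage", "lipid", "smc"),
    dominance_ratio: float = 2.0,
) -> pd.DataFrame:
    """Mean per-component densities and representative component per ROI.

    ROI vertices (um, centered coordinates by default) are rasterized onto
    the density-map pixel grid. The representative component is the argmax
    of the mean densities (ties broken by ``tie_priority``, macrophage
    first as the inflammation-sensitive choice); 'none' if all components
    are below their positivity thresholds; 'lipid_macrophage' if both the
    lipid and macrophage densities exceed threshold and neither dominates
    the other by more than ``dominance_ratio``.
    """
    shape = multiplexed.overlay.shape[:2]
    px = multiplexed.pixel_size_um
    if origin_um is None:
        origin = np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0]) * px
    else:
        origin = np.asarray(origin_um, dtype=float)
    by_target = {s.target: s for s in multiplexed.stains}

    records = []
    for roi in rois:
        v = np.asarray(roi.vertices_um)
        cols = (v[:, 0] + origin[0]) / px
        rows = (v[:, 1] + origin[1]) / px
        rr, cc = draw_polygon(rows, cols, shape=shape)
        dens: dict[str, float] = {}
        for target, stain in by_target.items():
            dmap = multiplexed.densities[stain.name]
            dens[target] = float(dmap[rr, cc].mean()) if len(rr) else 0.0

        positive = {t: dens[t] > by_target[t].positivity_threshold for t in dens}
        lip, mph = dens.get("lipid", 0.0), dens.get("macrophage", 0.0)
        if (
            positive.get("lipid")
            and positive.get("macrophage")
            and max(lip, mph) <= dominance_ratio * min(lip, mph)
        ):
            rep = "lipid_macrophage"
        elif not any(positive.values()):
            rep = "none"
        else:
            candidates = [t for t in dens if positive[t]]
            best = max(dens[t] for t in candidates)
            tied = [t for t in candidates if dens[t] == best]
            rep = min(tied, key=tie_priority.index) if len(tied) > 1 else tied[0]
        records.append(
            {"angle_deg": roi.angle_deg, **{f"density_{t}": d for t, d in dens.items()},
             "representative": rep, "n_pixels": len(rr)}
        )
    return pd.DataFrame(records)


#: How an IHC representative may match an in vivo class. The in vivo
#: lipids+macrophage class maps to co-presence of lipid and macrophage
#: staining; SMA-positive tissue matches either fibrotic tissue or normal
#: wall; unstained ROIs match normal wall.
_MATCH: dict[str, set[str]] = {
    "lipid": {"lipid", "lipid_macrophage"},
    "macrophage": {"macrophage", "lipid_macrophage"},
    "lipid_macrophage": {"lipid_macrophage", "lipid", "macrophage"},
    "smc": {"fibrotic", "normal"},
    "none": {"normal"},
}


def compare_rfc_vs_ihc(
    frame_classes: np.ndarray,
    representatives: pd.DataFrame,
    angular_offset_deg: int = 0,
) -> dict:
    """Per-degree agreement between in vivo classification and IHC morphometry.

    ``frame_classes`` is one frame's per-location class-index row (-1 for
    unclassified); ``representatives`` the output of
    :func:`roi_component_densities`. ``angular_offset_deg`` is the manual
    rotational registration between section and frame (in vivo angle =
    IHC angle + offset). Returns percent agreement over classified degrees
    plus a confusion table of (in vivo class x IHC representative) counts.
    """
    frame_classes = np.asarray(frame_classes)
    L = len(frame_classes)
    reps = representatives.sort_values("angle_deg")
    angles = reps["angle_deg"].to_numpy()
    rep_vals = reps["representative"].to_numpy()

    matched = 0
    total = 0
    pairs = []
    for ang, rep in zip(angles, rep_vals):
        vivo_deg = (ang + angular_offset_deg) % 360
        loc = int(round(vivo_deg / 360.0 * L)) % L
        ci = frame_classes[loc]
        if ci < 0:
            continue
        vivo = CLASS_LABELS[ci]
        total += 1
        hit = vivo in _MATCH.get(rep, set())
        matched += hit
        pairs.append((vivo, rep, hit))

    confusion = (
        pd.DataFrame(pairs, columns=["in_vivo", "ihc", "match"])
        .groupby(["in_vivo", "ihc"])
        .size()
        .unstack(fill_value=0)
        if pairs
        else pd.DataFrame()
    )
    return {
        "percent_agreement": 100.0 * matched / total if total else float("nan"),
        "n_compared": total,
        "confusion": confusion,
    }
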