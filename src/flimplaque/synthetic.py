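"""Synthetic pullback and histology generator.

This module replaces the imaging hardware and animal experiments with a
seeded forward model. It produces

* vessel *phantoms*: per-frame, per-location component label maps with a
  catheter-to-wall distance factor per location,
* *decay cubes*: time-resolved multispectral fluorescence traces simulated
  as an instrument-response-blurred mono-exponential decay with Poisson
  counting noise, and
* *stained-section fixtures*: RGB immunohistochemistry-like images mixed in
  Beer-Lambert optical-density space with known ground-truth densities.

The default component signature table is synthetic: per-class lifetime and
relative-intensity values are free parameters chosen so that the generated
data reproduce the qualitative similarity structure of the five plaque
classes (lipid vs. lipids+macrophage indistinguishable on ch.1/ch.2
lifetimes but well separated on the ch.1/ch.2 intensity ratio; fibrotic
vs. normal alike on ch.1; macrophage vs. fibrotic alike on ch.2; macrophage
ch.2 lifetimes bimodal over two depth sub-populations). They are not
measured tissue values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .core import (
    CLASS_ORDER,
    N_CHANNELS,
    N_LOCATIONS,
    ComponentClass,
)

__all__ = [
    "ComponentSignature",
    "SimilarityPattern",
    "OpticsConfig",
    "PhantomConfig",
    "VesselPhantom",
    "DecayCube",
    "default_signatures",
    "default_similarity_pattern",
    "build_vessel_phantom",
    "simulate_decays",
    "simulate_replicate",
    "roi_dataset_config",
    "atheroma_config",
    "make_ihc_fixture",
    "section_from_labels",
    "IhcImageConfig",
]

# depth tags for macrophage locations
DEPTH_NONE, DEPTH_SUPERFICIAL, DEPTH_DEEP = 0, 1, 2


# ---------------------------------------------------------------------------
# Component signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentSignature:
    """Spectroscopic signature of one component class.

    Lifetimes are in ns; ``rel_intensity`` is the dimensionless expected
    integrated intensity of each channel relative to ch.2. ``intensity_sd``
    is the log-normal sigma of the per-location, per-channel intensity
    jitter. For the macrophage class, ``ch2_mode_lifetimes`` holds the two
    depth sub-population means (superficial, deep) of the ch.2 lifetime and
    ``mixing_weight`` the superficial fraction.
    """

    lifetime_mean: tuple[float, float, float]
    lifetime_sd: tuple[float, float, float] = (0.3, 0.3, 0.3)
    rel_intensity: tuple[float, float, float] = (1.0, 1.0, 0.1)
    intensity_sd: float = 0.15
    ch2_mode_lifetimes: tuple[float, float] | None = None
    mixing_weight: float | None = None

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.lifetime_mean):
            raise ValueError("lifetime means must be positive")
        if self.mixing_weight is not None and not 0 < self.mixing_weight < 1:
            raise ValueError("mixing weight must be in (0, 1)")


def default_signatures() -> dict[ComponentClass, ComponentSignature]:
    """Default synthetic signature table (see module docstring).

    IR1 = I_ch1 / I_ch2 expectations per class: normal 1.2, fibrotic 2.0,
    lipid 0.8, macrophage 0.4, lipids+macrophage 2.8. ch.3 intensity is
    ~10% of ch.2 in every class to emulate its weak signal-to-noise ratio.
    """
    C = ComponentClass
    return {
        C.NORMAL: ComponentSignature((4.0, 2.0, 1.5), rel_intensity=(1.2, 1.0, 0.1)),
        C.FIBROTIC: ComponentSignature((4.0, 4.5, 2.0), rel_intensity=(2.0, 1.0, 0.1)),
        C.LIPID: ComponentSignature((6.5, 6.0, 3.0), rel_intensity=(0.8, 1.0, 0.1)),
        C.MACROPHAGE: ComponentSignature(
            (2.5, 4.5, 2.5),
            rel_intensity=(0.4, 1.0, 0.1),
            ch2_mode_lifetimes=(3.5, 5.5),
            mixing_weight=0.5,
        ),
        C.LIPID_MACROPHAGE: ComponentSignature((6.5, 6.0, 3.5), rel_intensity=(2.8, 1.0, 0.1)),
    }


@dataclass(frozen=True)
class SimilarityPattern:
    """Expected pairwise relations of class signatures per feature.

    ``entries`` maps (feature, class_a, class_b) -> "similar" | "distinct";
    unordered pairs are stored sorted by class order. Pairs not listed for
    a feature carry no expectation on that feature, but every class pair
    must be distinct on at least one feature.
    """

    entries: dict[tuple[str, ComponentClass, ComponentClass], str]

    def relation(self, feature: str, a: ComponentClass, b: ComponentClass) -> str | None:
        key = (feature, *sorted((a, b), key=CLASS_ORDER.index))
        return self.entries.get(key)


def default_similarity_pattern() -> SimilarityPattern:
    C = ComponentClass
    e: dict[tuple[str, ComponentClass, ComponentClass], str] = {}

    def put(feat: str, a: ComponentClass, b: ComponentClass, rel: str) -> None:
        e[(feat, *sorted((a, b), key=CLASS_ORDER.index))] = rel

    put("FL_ch1", C.LIPID, C.LIPID_MACROPHAGE, "similar")
    put("FL_ch1", C.FIBROTIC, C.NORMAL, "similar")
    put("FL_ch2", C.LIPID, C.LIPID_MACROPHAGE, "similar")
    put("FL_ch2", C.MACROPHAGE, C.FIBROTIC, "similar")
    put("IR1", C.LIPID, C.LIPID_MACROPHAGE, "distinct")
    return SimilarityPattern(e)


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomConfig:
    """Layout of a synthetic vessel pullback.

    ``layout`` selects how component labels are placed:

    * ``"uniform"``: every location gets ``background_class``.
    * ``"fractions"``: ``class_fractions`` allocated exactly (largest
      remainder) over all locations, then spread in contiguous angular
      runs per frame.
    * ``"rois"``: ``roi_counts`` rectangular ROIs (``roi_frames`` frames x
      ``roi_locations`` locations each) tiled over the pullback on a
      ``background_class`` background; used to build labeled training sets.
    * ``"random_arcs"``: per frame, a random number of diseased arcs over a
      normal background; used for atheroma-like pullbacks.
    """

    n_frames: int
    n_locations: int = N_LOCATIONS
    layout: str = "uniform"
    background_class: ComponentClass = ComponentClass.NORMAL
    class_fractions: dict[ComponentClass, float] | None = None
    roi_counts: dict[ComponentClass, int] | None = None
    roi_frames: int = 2
    roi_locations: int = 16
    arcs_per_frame: tuple[int, int] = (3, 8)
    arc_width: tuple[int, int] = (20, 80)
    distance_range: tuple[float, float] = (0.3, 1.0)

    def __post_init__(self) -> None:
        if self.n_frames <= 0 or self.n_locations <= 0:
            raise ValueError("phantom needs at least one frame and one location")
        if self.layout not in ("uniform", "fractions", "rois", "random_arcs"):
            raise ValueError(f"unknown layout {self.layout!r}")


@dataclass(frozen=True)
class PhantomRoi:
    """A labeled rectangular region of a phantom (half-open ranges)."""

    roi_id: int
    frame_range: tuple[int, int]
    loc_range: tuple[int, int]
    label: ComponentClass


@dataclass
class VesselPhantom:
    """Ground-truth component map of a synthetic pullback.

    ``labels`` holds class indices into :data:`~flimplaque.core.CLASS_ORDER`
    (frame x location), ``depth`` the macrophage depth tag (0 none,
    1 superficial, 2 deep), ``distance`` the per-location catheter-to-wall
    distance factor shared by all spectral channels.
    """

    labels: np.ndarray  # (F, L) int8
    depth: np.ndarray  # (F, L) int8
    distance: np.ndarray  # (F, L) float64
    rois: list[PhantomRoi]
    seed: int
    config: PhantomConfig

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_locations(self) -> int:
        return self.labels.shape[1]

    def class_of(self, frame: int, location: int) -> ComponentClass:
        return CLASS_ORDER[self.labels[frame, location]]


def _exact_allocation(fractions: dict[ComponentClass, float], n: int) -> dict[ComponentClass, int]:
    """Largest-remainder allocation of n items to the requested fractions."""
    total = sum(fractions.values())
    quotas = {c: f / total * n for c, f in fractions.items()}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = n - sum(counts.values())
    by_rem = sorted(fractions, key=lambda c: quotas[c] - counts[c], reverse=True)
    for c in by_rem[:short]:
        counts[c] += 1
    return counts


def build_vessel_phantom(config: PhantomConfig, seed: int) -> VesselPhantom:
    """Generate a labeled vessel phantom. Deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    F, L = config.n_frames, config.n_locations
    bg = CLASS_ORDER.index(config.background_class)
    labels = np.full((F, L), bg, dtype=np.int8)
    rois: list[PhantomRoi] = []

    if config.layout == "fractions":
        if not config.class_fractions:
            raise ValueError("fractions layout requires class_fractions")
        counts = _exact_allocation(config.class_fractions, F * L)
        flat = np.concatenate(
            [np.full(k, CLASS_ORDER.index(c), dtype=np.int8) for c, k in counts.items()]
        )
        rng.shuffle(flat)
        labels = flat.reshape(F, L)
    elif config.layout == "rois":
        if not config.roi_counts:
            raise ValueError("rois layout requires roi_counts")
        per_band = L // config.roi_locations
        n_rois = sum(config.roi_counts.values())
        n_bands = -(-n_rois // per_band)
        if F < n_bands * config.roi_frames:
            raise ValueError(
                f"{n_rois} ROIs need at least {n_bands * config.roi_frames} frames, got {F}"
            )
        cls_seq = np.concatenate(
            [np.full(k, CLASS_ORDER.index(c), dtype=np.int8) for c, k in config.roi_counts.items()]
        )
        rng.shuffle(cls_seq)
        for i, ci in enumerate(cls_seq):
            band, slot = divmod(i, per_band)
            f0 = band * config.roi_frames
            l0 = slot * config.roi_locations
            fr = (f0, f0 + config.roi_frames)
            lr = (l0, l0 + config.roi_locations)
            labels[fr[0]:fr[1], lr[0]:lr[1]] = ci
            rois.append(PhantomRoi(i, fr, lr, CLASS_ORDER[ci]))
    elif config.layout == "random_arcs":
        diseased = [c for c in CLASS_ORDER if c != config.background_class]
        for f in range(F):
            n_arcs = rng.integers(config.arcs_per_frame[0], config.arcs_per_frame[1] + 1)
            for _ in range(n_arcs):
                c = diseased[rng.integers(len(diseased))]
                start = int(rng.integers(L))
                width = int(rng.integers(config.arc_width[0], config.arc_width[1] + 1))
                idx = (np.arange(start, start + width)) % L
                labels[f, idx] = CLASS_ORDER.index(c)

    # macrophage depth sub-populations: inside labeled ROIs the split is
    # exact (every macrophage region holds both populations at the mixing
    # weight); elsewhere it is Bernoulli per location
    depth = np.zeros((F, L), dtype=np.int8)
    mph_idx = CLASS_ORDER.index(ComponentClass.MACROPHAGE)
    w = default_signatures()[ComponentClass.MACROPHAGE].mixing_weight or 0.5
    in_roi = np.zeros((F, L), dtype=bool)
    for roi in rois:
        if roi.label is not ComponentClass.MACROPHAGE:
            continue
        block = np.s_[roi.frame_range[0]:roi.frame_range[1], roi.loc_range[0]:roi.loc_range[1]]
        in_roi[block] = True
        n = labels[block].size
        tags = np.full(n, DEPTH_DEEP, dtype=np.int8)
        tags[: int(round(w * n))] = DEPTH_SUPERFICIAL
        rng.shuffle(tags)
        depth[block] = tags.reshape(labels[block].shape)
    loose = (labels == mph_idx) & ~in_roi
    draw = rng.random(loose.sum())
    depth[loose] = np.where(draw < w, DEPTH_SUPERFICIAL, DEPTH_DEEP)

    lo, hi = config.distance_range
    distance = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(F, L)))
    return VesselPhantom(labels, depth, distance, rois, seed, config)


def roi_dataset_config(
    roi_counts: dict[ComponentClass, int] | None = None,
    roi_frames: int = 2,
    roi_locations: int = 16,
) -> PhantomConfig:
    """Config for the default labeled training pullback.

    The default per-class ROI counts are fibrotic 79, lipid 66,
    macrophage 41, lipids+macrophage 38 and normal 73 (297 ROIs total).
    """
    if roi_counts is None:
        C = ComponentClass
        roi_counts = {C.FIBROTIC: 79, C.LIPID: 66, C.MACROPHAGE: 41,
                      C.LIPID_MACROPHAGE: 38, C.NORMAL: 73}
    per_band = N_LOCATIONS // roi_locations
    n_rois = sum(roi_counts.values())
    n_frames = -(-n_rois // per_band) * roi_frames
    return PhantomConfig(
        n_frames=n_frames,
        layout="rois",
        roi_counts=roi_counts,
        roi_frames=roi_frames,
        roi_locations=roi_locations,
    )


def atheroma_config(n_frames: int = 49) -> PhantomConfig:
    """Config for an atheroma-like pullback with varied per-frame plaque arcs."""
    return PhantomConfig(n_frames=n_frames, layout="random_arcs")


# ---------------------------------------------------------------------------
# Decay simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticsConfig:
    """Time grid, excitation and detection model of the simulated system.

    The excitation pulse sits at ``pulse_time`` ns on a grid of ``n_bins``
    bins of ``time_step`` ns; the instrument response is a Gaussian of
    ``irf_fwhm`` ns FWHM. ``amplitude_scale`` sets the peak photon count of
    a unit-intensity, unit-distance trace; ``background_level`` is the dark
    count per bin. The pre-pulse ``background_window`` (ns, half-open) is
    used downstream for background estimation.
    """

    time_step: float = 0.2
    n_bins: int = 300
    pulse_time: float = 4.0
    irf_fwhm: float = 0.5
    background_level: float = 1.0
    amplitude_scale: float = 2000.0
    poisson_noise: bool = True
    background_window: tuple[float, float] = (0.0, 2.5)

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.n_bins <= 1:
            raise ValueError("need at least two time bins")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.time_step

    def irf_kernel(self) -> np.ndarray:
        """Unit-sum Gaussian IRF sampled on the time grid, centered at the pulse."""
        sigma = self.irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        k = np.exp(-0.5 * ((self.time - self.pulse_time) / sigma) ** 2)
        return k / k.sum()


@dataclass
class DecayCube:
    """Time-resolved traces of a whole pullback (frame x location x channel x bin)."""

    traces: np.ndarray  # (F, L, C, T) float32 photon counts
    optics: OpticsConfig
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]

    @property
    def n_locations(self) -> int:
        return self.traces.shape[1]

    @property
    def time(self) -> np.ndarray:
        return self.optics.time


def _signature_arrays(
    signatures: dict[ComponentClass, ComponentSignature],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack the signature table into class-indexed arrays."""
    K = len(CLASS_ORDER)
    mean = np.zeros((K, N_CHANNELS))
    sd = np.zeros((K, N_CHANNELS))
    rel = np.zeros((K, N_CHANNELS))
    isd = np.zeros(K)
    modes = np.zeros((K, 2))
    for i, c in enumerate(CLASS_ORDER):
        s = signatures[c]
        mean[i] = s.lifetime_mean
        sd[i] = s.lifetime_sd
        rel[i] = s.rel_intensity
        isd[i] = s.intensity_sd
        modes[i] = s.ch2_mode_lifetimes if s.ch2_mode_lifetimes else (s.lifetime_mean[1],) * 2
    return mean, sd, rel, isd, modes


def simulate_decays(
    phantom: VesselPhantom,
    signatures: dict[ComponentClass, ComponentSignature] | None = None,
    optics: OpticsConfig | None = None,
    seed: int = 0,
) -> DecayCube:
    """Simulate the time-resolved multispectral decay traces of a phantom.

    Each trace is ``background + Poisson(amplitude * distance *
    exp(-t/tau) (x) IRF)`` where the per-location lifetime ``tau`` and the
    per-channel intensity jitter are drawn from the class signature, and
    the distance factor multiplies all channels equally so that intensity
    ratios stay distance-insensitive by construction.

    The biological variation (per-location lifetimes and intensity
    jitter) is a tissue property: it is drawn from a stream derived from
    the *phantom's* seed, so re-simulating the same phantom with a new
    ``seed`` redraws only the photon counting noise, as a repeated
    pullback of the same artery would.
    """
    signatures = signatures if signatures is not None else default_signatures()
    optics = optics if optics is not None else OpticsConfig()
    mean, sd, rel, isd, modes = _signature_arrays(signatures)
    if np.any(mean <= 0):
        raise ValueError("all signature lifetimes must be positive")

    rng = np.random.default_rng(seed)
    rng_bio = np.random.default_rng(np.random.SeedSequence([phantom.seed, 0xB10]))
    F, L = phantom.labels.shape
    T = optics.n_bins
    t = optics.time
    kernel = optics.irf_kernel()
    traces = np.empty((F, L, N_CHANNELS, T), dtype=np.float32)

    for f in range(F):
        lab = phantom.labels[f]
        tau = rng_bio.normal(mean[lab], sd[lab])  # (L, C)
        # macrophage ch.2: replace by depth sub-population mode
        dtag = phantom.depth[f]
        sup, deep = dtag == DEPTH_SUPERFICIAL, dtag == DEPTH_DEEP
        if sup.any():
            tau[sup, 1] = rng_bio.normal(modes[lab[sup], 0], sd[lab[sup], 1])
        if deep.any():
            tau[deep, 1] = rng_bio.normal(modes[lab[deep], 1], sd[lab[deep], 1])
        tau = np.clip(tau, 0.05, None)

        jitter = np.exp(rng_bio.normal(0.0, isd[lab][:, None], size=(L, N_CHANNELS)))
        amp = optics.amplitude_scale * rel[lab] * jitter * phantom.distance[f][:, None]

        decay = np.exp(-t[None, :] / tau.reshape(-1, 1))
        conv = fftconvolve(decay, kernel[None, :], mode="full", axes=-1)[:, :T]
        model = optics.background_level + amp.reshape(-1, 1) * conv
        model = np.clip(model, 0.0, None)
        frame = rng.poisson(model) if optics.poisson_noise else model
        traces[f] = frame.reshape(L, N_CHANNELS, T)

    return DecayCube(traces, optics, seed)


def simulate_replicate(
    phantom: VesselPhantom,
    signatures: dict[ComponentClass, ComponentSignature] | None = None,
    optics: OpticsConfig | None = None,
    seed: int = 0,
    distance_jitter: float = 0.1,
) -> DecayCube:
    """Re-simulate a pullback of the same artery (repeatability model).

    Keeps the phantom's component map, redraws the Poisson noise and the
    per-location biological variation, and perturbs each distance factor
    uniformly within ``+/- distance_jitter`` to mimic a repeated catheter
    pullback with slightly different wire position.
    """
    rng = np.random.default_rng(seed)
    factor = rng.uniform(1.0 - distance_jitter, 1.0 + distance_jitter, phantom.distance.shape)
    rep = VesselPhantom(
        phantom.labels, phantom.depth, phantom.distance * factor,
        phantom.rois, phantom.seed, phantom.config,
    )
    return simulate_decays(rep, signatures, optics, seed=int(rng.integers(2**31 - 1)))


# ---------------------------------------------------------------------------
# IHC fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IhcImageConfig:
    """Geometry of a rendered stained-section image."""

    size_px: int = 440
    pixel_size_um: float = 4.0
    lumen_radius_um: float = 600.0
    band_depth_um: float = 200.0


#: Per-degree stain-target densities emulating how each component class
#: would stain on the three sections (lipid / macrophage / smooth muscle).
_CLASS_STAIN_DENSITY: dict[ComponentClass, tuple[float, float, float]] = {
    ComponentClass.NORMAL: (0.0, 0.0, 0.25),
    ComponentClass.FIBROTIC: (0.0, 0.0, 0.9),
    ComponentClass.LIPID: (0.8, 0.0, 0.05),
    ComponentClass.MACROPHAGE: (0.0, 0.8, 0.05),
    ComponentClass.LIPID_MACROPHAGE: (0.5, 0.45, 0.05),
}


def section_from_labels(labels_row: np.ndarray) -> dict[str, np.ndarray]:
    """Per-degree (360) stain-target densities from one frame's label row."""
    L = labels_row.shape[0]
    deg = np.arange(360)
    loc = np.round(deg / 360.0 * L).astype(int) % L
    dens = np.array([_CLASS_STAIN_DENSITY[CLASS_ORDER[i]] for i in labels_row[loc]])
    return {"lipid": dens[:, 0], "macrophage": dens[:, 1], "smc": dens[:, 2]}


def make_ihc_fixture(
    section: dict[str, np.ndarray],
    stains=None,
    config: IhcImageConfig | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """Render single-stain RGB section images from a per-degree density map.

    ``section`` maps component name (lipid / macrophage / smc) to a
    360-element density array in [0, 1]. Returns ``(images, truth)`` where
    ``images`` maps stain name to an RGB float image in [0, 1] (white
    background, Beer-Lambert attenuation by the stain's optical-density
    vector), and ``truth`` records the geometry and per-degree densities.
    """
    from .ihc import DEFAULT_STAINS  # local import to avoid cycle at import time

    stains = stains if stains is not None else DEFAULT_STAINS
    config = config if config is not None else IhcImageConfig()
    by_target = {s.target: s for s in stains}
    for comp in section:
        if comp not in by_target:
            raise ValueError(f"no stain registered for component {comp!r}")

    n = config.size_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r_um = np.hypot(xx - c, yy - c) * config.pixel_size_um
    # angle 0 at 12 o'clock, increasing clockwise
    ang = np.degrees(np.arctan2(xx - c, c - yy)) % 360.0
    deg = np.floor(ang).astype(int) % 360
    in_band = (r_um >= config.lumen_radius_um) & (
        r_um < config.lumen_radius_um + config.band_depth_um
    )

    images: dict[str, np.ndarray] = {}
    for comp, dens in section.items():
        stain = by_target[comp]
        dmap = np.where(in_band, np.asarray(dens, dtype=float)[deg], 0.0)
        od = dmap[:, :, None] * np.asarray(stain.od_vector)[None, None, :]
        images[stain.name] = np.exp(-od)

    truth = {
        "densities": {k: np.asarray(v, dtype=float) for k, v in section.items()},
        "geometry": {
            "size_px": config.size_px,
            "pixel_size_um": config.pixel_size_um,
            "lumen_radius_um": config.lumen_radius_um,
            "band_depth_um": config.band_depth_um,
        },
    }
    return images, truth
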