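"""Decay-to-feature processing.

Turns time-resolved fluorescence traces into the per-location multispectral
readout of the imaging system: three channel fluorescence lifetimes (FL,
ns) and three inter-channel intensity ratios (IR, dimensionless), laid out
on the A-line group grid (default 512 locations per frame, i.e. 3,072
readout values per frame), plus en face maps of any single feature.

Lifetimes are estimated by default with an IRF-centroid-corrected average
delay: the count-weighted mean arrival time over a noise-thresholded
support window, minus the excitation/IRF centroid, with an analytic
correction for the truncation of the exponential tail at the support edge.
A mono-exponential least-squares fit is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve

from .core import ALINES_PER_GROUP, FEATURE_NAMES, N_CHANNELS
from .synthetic import DecayCube, OpticsConfig

__all__ = [
    "ProcessingConfig",
    "FlimFrameReadout",
    "PullbackReadouts",
    "EnFaceMap",
    "subtract_background",
    "estimate_intensity",
    "estimate_lifetime",
    "compute_intensity_ratios",
    "assemble_frame_readouts",
    "process_pullback",
    "build_en_face_map",
]


@dataclass(frozen=True)
class ProcessingConfig:
    """Feature-extraction parameters.

    ``min_counts`` is the integrated-count validity threshold below which a
    location's lifetime is flagged invalid (the average-delay variance is
    unusable there); it doubles as the noise floor under which an intensity
    ratio's denominator renders the ratio undefined. ``tail_frac`` sets the
    support cut-off as a fraction of the smoothed peak.
    """

    method: str = "average_delay"  # or "monoexp_fit"
    min_counts: float = 100.0
    tail_frac: float = 0.002
    smooth_bins: int = 5

    def __post_init__(self) -> None:
        if self.method not in ("average_delay", "monoexp_fit"):
            raise ValueError(f"unknown lifetime method {self.method!r}")


# ---------------------------------------------------------------------------
# Per-trace primitives
# ---------------------------------------------------------------------------

def subtract_background(
    trace: np.ndarray, background_window: tuple[float, float], time_step: float
) -> np.ndarray:
    """Subtract the mean of the pre-pulse background window from a trace.

    ``background_window`` is a half-open interval in ns that must precede
    the excitation pulse and lie on the time axis. Works on any array whose
    last axis is time. Negative bins are *not* clipped here; clipping is
    applied inside lifetime estimation only.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[-1]
    lo, hi = background_window
    i0, i1 = int(np.ceil(lo / time_step)), int(np.floor(hi / time_step))
    if lo < 0 or i0 >= n or i1 > n:
        raise ValueError("background window outside the time axis")
    if i1 <= i0:
        raise ValueError("background window is empty")
    bg = trace[..., i0:i1].mean(axis=-1, keepdims=True)
    return trace - bg


def estimate_intensity(trace: np.ndarray) -> np.ndarray | float:
    """Time-integrated counts of a background-subtracted trace (>= 0).

    The sum runs over the raw (unclipped) trace so that zero-mean noise
    does not bias the integral; only the total is clipped at zero.
    """
    trace = np.asarray(trace, dtype=float)
    out = np.clip(trace.sum(axis=-1), 0.0, None)
    return float(out) if out.ndim == 0 else out


def _truncation_corrected(m: np.ndarray, span: np.ndarray) -> np.ndarray:
    """Invert the truncated-exponential mean.

    For a mono-exponential decay observed only on [0, T], the count-weighted
    mean delay is m(tau) = tau - T e^{-T/tau} / (1 - e^{-T/tau}). Given the
    observed mean ``m`` and the support span ``T``, recover tau by fixed-point
    iteration. Falls back to ``m`` where the correction is not meaningful.
    """
    m = np.asarray(m, dtype=float)
    span = np.asarray(span, dtype=float)
    tau = np.clip(m, 1e-6, None)
    ok = (m > 0) & (span > 0)
    for _ in range(8):
        with np.errstate(over="ignore", invalid="ignore"):
            x = np.clip(span / np.clip(tau, 1e-6, None), 1e-9, 700.0)
            corr = span * np.exp(-x) / (1.0 - np.exp(-x))
        tau = np.where(ok, m + corr, tau)
    return np.where(ok, tau, np.clip(m, 0.0, None))


def _average_delay(
    traces: np.ndarray,
    time_step: float,
    t0: float,
    tail_frac: float = 0.002,
    smooth_bins: int = 5,
) -> np.ndarray:
    """Vectorized average-delay lifetime for (N, T) background-subtracted traces."""
    raw = np.asarray(traces, dtype=float)
    w = np.clip(raw, 0.0, None)
    n_bins = w.shape[-1]
    sm = uniform_filter1d(w, smooth_bins, axis=-1, mode="nearest")
    peak = sm.max(axis=-1)
    # noise-aware threshold floor keeps late noise bumps out of the support
    sigma = 1.4826 * np.median(np.abs(raw - np.median(raw, axis=-1, keepdims=True)), axis=-1)
    thr = np.maximum(tail_frac * peak, 2.5 * sigma / np.sqrt(smooth_bins))
    above = sm > thr[..., None]
    idx = np.arange(n_bins)
    # support: the contiguous above-threshold run containing the peak
    p = np.argmax(sm, axis=-1)
    below = ~above
    after = np.where(below & (idx > p[..., None]), idx, n_bins)
    last = after.min(axis=-1) - 1
    before = np.where(below & (idx < p[..., None]), idx, -1)
    first = before.max(axis=-1) + 1
    mask = (idx >= first[..., None]) & (idx <= last[..., None])
    wm = np.where(mask, w, 0.0)
    tot = wm.sum(axis=-1)
    # mid-bin convention: bin k collects photons arriving around (k + 1/2) dt
    tmid = (idx + 0.5) * time_step
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = (wm @ tmid) / tot
    m = mu - t0
    span = (last + 1.0) * time_step - t0  # truncated-tail span measured from the pulse
    tau = _truncation_corrected(m, span)
    tau = np.where(tot > 0, np.clip(tau, 0.0, None), np.nan)
    return tau


def _irf_kernel(n_bins: int, time_step: float, t0: float, irf_fwhm: float | None) -> np.ndarray:
    t = np.arange(n_bins) * time_step
    if not irf_fwhm:  # delta excitation
        k = np.zeros(n_bins)
        k[int(round(t0 / time_step))] = 1.0
        return k
    sigma = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    k = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    return k / k.sum()


def _monoexp_fit(
    trace: np.ndarray, time_step: float, t0: float, irf_fwhm: float | None
) -> float:
    """Least-squares fit of A exp(-t/tau) convolved with the IRF, single trace."""
    trace = np.asarray(trace, dtype=float)
    n_bins = trace.shape[-1]
    t = np.arange(n_bins) * time_step
    kernel = _irf_kernel(n_bins, time_step, t0, irf_fwhm)

    def model(tt: np.ndarray, amp: float, tau: float) -> np.ndarray:
        d = np.exp(-tt / max(tau, 1e-6))
        return amp * np.convolve(d, kernel)[:n_bins]

    tau0 = _average_delay(trace[None, :], time_step, t0)[0]
    if not np.isfinite(tau0) or tau0 <= 0:
        tau0 = 1.0
    amp0 = max(float(trace.max()), 1e-6)
    try:
        popt, _ = curve_fit(
            model, t, np.clip(trace, 0.0, None), p0=(amp0, tau0),
            bounds=((0.0, 1e-3), (np.inf, 1e3)), maxfev=200,
        )
        return float(popt[1])
    except RuntimeError:  # no convergence: fall back to the moment estimate
        return float(tau0)


def estimate_lifetime(
    trace: np.ndarray,
    time_step: float,
    t0: float,
    method: str = "average_delay",
    irf_fwhm: float | None = None,
    min_counts: float = 100.0,
    tail_frac: float = 0.002,
) -> float:
    """Fluorescence lifetime (ns) of one background-subtracted trace.

    ``t0`` is the centroid of the excitation pulse / IRF on the time axis.
    Returns NaN (invalid flag, not an exception) when integrated counts
    fall below ``min_counts``.
    """
    trace = np.asarray(trace, dtype=float)
    if estimate_intensity(trace) < min_counts:
        return float("nan")
    if method == "average_delay":
        return float(_average_delay(trace[None, :], time_step, t0, tail_frac)[0])
    if method == "monoexp_fit":
        return _monoexp_fit(trace, time_step, t0, irf_fwhm)
    raise ValueError(f"unknown lifetime method {method!r}")


def compute_intensity_ratios(
    i_ch1: np.ndarray | float,
    i_ch2: np.ndarray | float,
    i_ch3: np.ndarray | float,
    noise_floor: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inter-channel intensity ratios IR1 = I1/I2, IR2 = I2/I3, IR3 = I3/I1.

    A ratio is NaN (undefined) where its denominator is below ``noise_floor``.
    Because a catheter-to-wall distance change scales all channels equally,
    these ratios are distance-insensitive.
    """
    i1, i2, i3 = (np.asarray(x, dtype=float) for x in (i_ch1, i_ch2, i_ch3))
    with np.errstate(divide="ignore", invalid="ignore"):
        ir1 = np.where(i2 >= noise_floor, i1 / i2, np.nan)
        ir2 = np.where(i3 >= noise_floor, i2 / i3, np.nan)
        ir3 = np.where(i1 >= noise_floor, i3 / i1, np.nan)
    return ir1, ir2, ir3


# ---------------------------------------------------------------------------
# Frame / pullback assembly
# ---------------------------------------------------------------------------

@dataclass
class FlimFrameReadout:
    """Per-location features of one frame: 3 FLs + 3 IRs per location.

    At the default 512 locations this is 3,072 readout values per frame;
    location ``k`` covers OCT A-lines ``[4k, 4k+4)``.
    """

    frame_index: int
    fl: np.ndarray  # (L, 3) ns
    ir: np.ndarray  # (L, 3) dimensionless
    valid: np.ndarray  # (L,) bool
    alines_per_group: int = ALINES_PER_GROUP

    @property
    def n_locations(self) -> int:
        return self.fl.shape[0]

    @property
    def n_readouts(self) -> int:
        """Total feature values carried by the frame (FLs + IRs)."""
        return self.fl.size + self.ir.size

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def aline_span(self, location: int) -> tuple[int, int]:
        return (location * self.alines_per_group, (location + 1) * self.alines_per_group)


@dataclass
class PullbackReadouts:
    """Stacked readouts of a whole pullback (frames x locations)."""

    fl: np.ndarray  # (F, L, 3)
    ir: np.ndarray  # (F, L, 3)
    valid: np.ndarray  # (F, L) bool

    @property
    def n_frames(self) -> int:
        return self.fl.shape[0]

    @property
    def n_locations(self) -> int:
        return self.fl.shape[1]

    def frame(self, index: int) -> FlimFrameReadout:
        return FlimFrameReadout(index, self.fl[index], self.ir[index], self.valid[index])

    def feature(self, name: str) -> np.ndarray:
        """(F, L) array of one named feature (NaN where undefined)."""
        if name not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {name!r}; expected one of {FEATURE_NAMES}")
        block, col = ("fl", int(name[-1]) - 1) if name.startswith("FL") else ("ir", int(name[-1]) - 1)
        return getattr(self, block)[:, :, col]


def assemble_frame_readouts(
    cube: DecayCube, frame_index: int, config: ProcessingConfig | None = None
) -> FlimFrameReadout:
    """Extract the 6-feature readout of one frame from a decay cube."""
    config = config if config is not None else ProcessingConfig()
    optics = cube.optics
    traces = np.asarray(cube.traces[frame_index], dtype=float)  # (L, C, T)
    L = traces.shape[0]

    # The dark-count offset is a detector property: estimate it per channel,
    # pooled over all locations of the frame. A per-trace estimate from the
    # short pre-pulse window alone is noisy enough to leak through the
    # integrated-count validity threshold on signal-free traces.
    lo, hi = optics.background_window
    i0 = int(np.ceil(lo / optics.time_step))
    i1 = int(np.floor(hi / optics.time_step))
    if i1 <= i0 or i1 > traces.shape[-1]:
        raise ValueError("background window outside the time axis")
    bg = traces[:, :, i0:i1].mean(axis=(0, 2))  # (C,)
    corrected = traces - bg[None, :, None]
    intensity = np.clip(corrected.sum(axis=-1), 0.0, None)  # (L, C)

    flat = corrected.reshape(L * N_CHANNELS, -1)
    if config.method == "average_delay":
        tau = _average_delay(
            flat, optics.time_step, optics.pulse_time, config.tail_frac, config.smooth_bins
        ).reshape(L, N_CHANNELS)
    else:
        tau = np.array([
            _monoexp_fit(tr, optics.time_step, optics.pulse_time, optics.irf_fwhm)
            for tr in flat
        ]).reshape(L, N_CHANNELS)

    fl = np.where(intensity >= config.min_counts, tau, np.nan)
    ir = np.stack(
        compute_intensity_ratios(
            intensity[:, 0], intensity[:, 1], intensity[:, 2], noise_floor=config.min_counts
        ),
        axis=-1,
    )
    valid = (intensity[:, 0] >= config.min_counts) & (intensity[:, 1] >= config.min_counts)
    return FlimFrameReadout(frame_index, fl, ir, valid)


def process_pullback(cube: DecayCube, config: ProcessingConfig | None = None) -> PullbackReadouts:
    """Extract readouts for every frame of a pullback."""
    frames = [assemble_frame_readouts(cube, f, config) for f in range(cube.n_frames)]
    return PullbackReadouts(
        fl=np.stack([fr.fl for fr in frames]),
        ir=np.stack([fr.ir for fr in frames]),
        valid=np.stack([fr.valid for fr in frames]),
    )


@dataclass
class EnFaceMap:
    """Unrolled pullback map (frames x angular locations) of one feature."""

    values: np.ma.MaskedArray  # (F, L), invalid cells masked
    feature: str
    cmap: str = "viridis"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_en_face_map(readouts: PullbackReadouts, feature: str) -> EnFaceMap:
    """En face map of one feature; invalid or undefined cells are masked."""
    vals = readouts.feature(feature)
    mask = ~readouts.valid | ~np.isfinite(vals)
    return EnFaceMap(np.ma.masked_array(vals, mask=mask), feature)
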