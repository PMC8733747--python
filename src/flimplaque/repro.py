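"""Reliability and reproducibility statistics for repeated pullbacks.

Two pullbacks of the same artery are compared on expert-paired frames.
Agreement of per-frame feature means uses the intraclass correlation
coefficient — two-way random effects, absolute agreement, single measures,
i.e. ICC(2,1) with both frames and pullbacks as random effects — and
Bland-Altman analysis with limits of agreement at the mean difference
+/- 1.96 SD of the paired differences. Per-class classified-area
proportions are compared the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import UNCLASSIFIED, ClassificationMap
from .core import CLASS_LABELS, CLASS_ORDER
from .processing import PullbackReadouts

__all__ = [
    "FramePairSet",
    "AgreementStats",
    "load_frame_pairs",
    "icc",
    "bland_altman",
    "feature_agreement",
    "class_proportion_agreement",
]


@dataclass(frozen=True)
class FramePairSet:
    """Expert frame pairing between two pullbacks of the same artery."""

    pairs: tuple[tuple[int, int], ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def frames_a(self) -> np.ndarray:
        return np.array([a for a, _ in self.pairs], dtype=int)

    @property
    def frames_b(self) -> np.ndarray:
        return np.array([b for _, b in self.pairs], dtype=int)


def load_frame_pairs(path: str | Path) -> FramePairSet:
    """Read a CSV pairing file with columns frameA, frameB.

    Each frame may appear in at most one pair; duplicates are an error.
    An empty file yields an empty set.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        import warnings

        warnings.warn(f"pair file {path} contains no pairs", stacklevel=2)
        return FramePairSet((), provenance=str(path))
    cols = {c.lower(): c for c in df.columns}
    try:
        a = df[cols["framea"]].astype(int)
        b = df[cols["frameb"]].astype(int)
    except KeyError as exc:
        raise ValueError(f"pair file {path} must have columns frameA, frameB") from exc
    for name, col in (("A", a), ("B", b)):
        dup = col[col.duplicated()]
        if not dup.empty:
            raise ValueError(
                f"frame(s) {sorted(dup.unique())} of pullback {name} appear in more than one pair"
            )
    return FramePairSet(tuple(zip(a.tolist(), b.tolist())), provenance=str(path))


def icc(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``x`` and ``y`` are the two repeated measurements of the same targets
    (equal lengths, n >= 5). Returns ``(icc, p)`` with the F-based P value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("the two measurement vectors must have equal length")
    if x.ndim != 1 or len(x) < 5:
        raise ValueError("need at least 5 paired measurements")
    import pingouin as pg

    n = len(x)
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "rating": np.concatenate([x, y]),
        }
    )
    res = pg.intraclass_corr(df, targets="target", raters="rater", ratings="rating")
    row = res.loc[res["Type"] == "ICC2"].iloc[0] if "ICC2" in set(res["Type"]) else \
        res.loc[res["Type"] == "ICC(A,1)"].iloc[0]
    return float(row["ICC"]), float(row["pval"])


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement summary of paired measurements."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    pct_within_loa: float
    n: int


def bland_altman(x: np.ndarray, y: np.ndarray) -> AgreementStats:
    """Bland-Altman statistics of paired measurements (differences x - y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("the two measurement vectors must have equal length")
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need at least 3 paired measurements")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi)) * 100.0)
    return AgreementStats(mean, sd, lo, hi, within, len(d))


def _frame_means(readouts: PullbackReadouts, frames: np.ndarray) -> pd.DataFrame:
    out = {}
    for feat in ("FL_ch1", "FL_ch2", "IR1"):
        vals = readouts.feature(feat)[frames]
        ok = readouts.valid[frames] & np.isfinite(vals)
        with np.errstate(invalid="ignore"):
            out[feat] = np.where(
                ok.any(axis=1), np.nanmean(np.where(ok, vals, np.nan), axis=1), np.nan
            )
    return pd.DataFrame(out)


def feature_agreement(
    readouts_a: PullbackReadouts,
    readouts_b: PullbackReadouts,
    pairs: FramePairSet,
) -> dict[str, dict]:
    """Per-feature agreement of frame means across paired frames.

    For each of ch.1 FL, ch.2 FL and IR1, the per-frame mean over valid
    locations is compared across the pairing with ICC(2,1) and
    Bland-Altman statistics.
    """
    ma = _frame_means(readouts_a, pairs.frames_a)
    mb = _frame_means(readouts_b, pairs.frames_b)
    report = {}
    for feat in ma.columns:
        a, b = ma[feat].to_numpy(), mb[feat].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        val, p = icc(a[ok], b[ok])
        report[feat] = {
            "icc": val,
            "icc_p": p,
            "bland_altman": bland_altman(a[ok], b[ok]),
            "n_pairs": int(ok.sum()),
        }
    return report


def _frame_proportions(cmap: ClassificationMap, frames: np.ndarray) -> np.ndarray:
    """(n_frames, 5) per-frame class proportions over classified locations."""
    props = np.full((len(frames), len(CLASS_ORDER)), np.nan)
    for i, f in enumerate(frames):
        row = cmap.classes[f]
        valid = row != UNCLASSIFIED
        if valid.any():
            props[i] = np.bincount(row[valid], minlength=len(CLASS_ORDER)) / valid.sum()
    return props


def class_proportion_agreement(
    map_a: ClassificationMap,
    map_b: ClassificationMap,
    pairs: FramePairSet,
) -> dict[str, dict]:
    """Per-class ICC of per-frame component proportions across the pairing.

    A class whose proportions show no between-frame variance in either
    pullback makes the ICC degenerate; such classes are flagged.
    """
    pa = _frame_proportions(map_a, pairs.frames_a)
    pb = _frame_proportions(map_b, pairs.frames_b)
    report = {}
    for i, name in enumerate(CLASS_LABELS):
        a, b = pa[:, i], pb[:, i]
        ok = np.isfinite(a) & np.isfinite(b)
        degenerate = bool(np.std(a[ok]) == 0.0 or np.std(b[ok]) == 0.0)
        if degenerate:
            report[name] = {"icc": float("nan"), "icc_p": float("nan"),
                            "degenerate": True, "n_pairs": int(ok.sum())}
            continue
        val, p = icc(a[ok], b[ok])
        report[name] = {"icc": val, "icc_p": p, "degenerate": False, "n_pairs": int(ok.sum())}
    return report
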