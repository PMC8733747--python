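"""Histology-labeled ROI feature extraction and component-comparison statistics.

ROIs are rectangular frame-range x angular-range regions of a pullback
labeled with one of the five component classes. Features at every valid
location inside a ROI form a location-level table; per-ROI or per-frame
means feed the group comparisons (one-way ANOVA with Tukey's post hoc when
every group passes a Shapiro-Wilk normality check, otherwise
Kruskal-Wallis with Dunn's post hoc, Holm-adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .core import CLASS_ORDER, ComponentClass
from .processing import PullbackReadouts
from .synthetic import PhantomRoi

__all__ = [
    "LabeledRoi",
    "rois_from_phantom",
    "extract_roi_features",
    "aggregate_features",
    "ComparisonReport",
    "compare_components",
    "histogram_by_class",
]

FEATURE_COLUMNS = ["FL_ch1", "FL_ch2", "FL_ch3", "IR1", "IR2", "IR3"]


@dataclass(frozen=True)
class LabeledRoi:
    """A labeled region of a pullback (half-open frame and location ranges)."""

    roi_id: int
    frame_range: tuple[int, int]
    loc_range: tuple[int, int]
    label: ComponentClass
    pullback_id: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.frame_range[1] <= self.frame_range[0] or self.loc_range[1] <= self.loc_range[0]:
            raise ValueError("ROI ranges must be non-empty half-open intervals")


def rois_from_phantom(rois: list[PhantomRoi], pullback_id: str = "phantom") -> list[LabeledRoi]:
    """Adopt a phantom's ground-truth ROI layout as a labeled ROI set."""
    return [
        LabeledRoi(r.roi_id, r.frame_range, r.loc_range, r.label, pullback_id, "generator truth")
        for r in rois
    ]


def extract_roi_features(readouts: PullbackReadouts, rois: list[LabeledRoi]) -> pd.DataFrame:
    """Location-level feature table of every valid location inside each ROI.

    One row per (ROI, frame, location); invalid locations are dropped but
    counted in the per-ROI coverage table stored in ``df.attrs["coverage"]``.
    Overlapping ROIs contribute one row per ROI membership.
    """
    rows = []
    coverage = []
    for roi in rois:
        f0, f1 = roi.frame_range
        l0, l1 = roi.loc_range
        if f0 < 0 or f1 > readouts.n_frames or l0 < 0 or l1 > readouts.n_locations:
            raise ValueError(f"ROI {roi.roi_id} outside pullback bounds")
        valid = readouts.valid[f0:f1, l0:l1]
        ff, ll = np.nonzero(valid)
        n_total, n_valid = valid.size, len(ff)
        coverage.append((roi.roi_id, n_total, n_valid))
        if n_valid == 0:
            continue
        fl = readouts.fl[f0:f1, l0:l1][ff, ll]
        ir = readouts.ir[f0:f1, l0:l1][ff, ll]
        part = pd.DataFrame(
            np.column_stack([fl, ir]),
            columns=["FL_ch1", "FL_ch2", "FL_ch3", "IR1", "IR2", "IR3"],
        )
        part.insert(0, "roi_id", roi.roi_id)
        part.insert(1, "frame", ff + f0)
        part.insert(2, "location", ll + l0)
        part["label"] = roi.label.value
        rows.append(part)

    cols = ["roi_id", "frame", "location", *FEATURE_COLUMNS, "label"]
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)
    table.attrs["level"] = "location"
    table.attrs["coverage"] = [
        {"roi_id": r, "n_total": t, "n_valid": v} for r, t, v in coverage
    ]
    return table


def aggregate_features(table: pd.DataFrame, level: str) -> pd.DataFrame:
    """Mean features per ROI or per frame; group size recorded in ``n``."""
    if level not in ("roi", "frame"):
        raise ValueError("aggregation level must be 'roi' or 'frame'")
    key = "roi_id" if level == "roi" else "frame"
    feats = [c for c in FEATURE_COLUMNS if c in table.columns]
    grouped = table.groupby(key, as_index=False).agg(
        {**{c: "mean" for c in feats}, "label": "first"}
    )
    grouped["n"] = table.groupby(key).size().values
    grouped.attrs["level"] = level
    return grouped


# ---------------------------------------------------------------------------
# Component comparison statistics
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Outcome of a multi-group feature comparison.

    ``test`` records which branch ran ("anova+tukey" or "kruskal+dunn");
    ``pairwise_p`` is a symmetric class x class matrix of adjusted post hoc
    P values (diagonal 1).
    """

    feature: str
    test: str
    global_p: float
    pairwise_p: pd.DataFrame
    group_normality_p: dict[str, float]
    group_sizes: dict[str, int]


def _dunn_holm(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based post hoc z tests with Holm adjustment.

    Standard large-sample Dunn statistics on the pooled ranks with tie
    correction; two-sided P values are Holm-adjusted over the family of all
    pairwise comparisons.
    """
    names = list(groups)
    values = np.concatenate([groups[g] for g in names])
    sizes = np.array([len(groups[g]) for g in names])
    ranks = stats.rankdata(values)
    n = len(values)
    # tie correction term
    _, counts = np.unique(values, return_counts=True)
    tie = (counts**3 - counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie
    bounds = np.r_[0, np.cumsum(sizes)]
    mean_ranks = {
        g: ranks[bounds[i]:bounds[i + 1]].mean() for i, g in enumerate(names)
    }
    raw = {}
    for a, b in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw[(a, b)] = 2.0 * stats.norm.sf(abs(z))
    # Holm step-down
    items = sorted(raw.items(), key=lambda kv: kv[1])
    m = len(items)
    adj = {}
    running = 0.0
    for i, (pair, p) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        adj[pair] = running
    mat = pd.DataFrame(1.0, index=names, columns=names)
    for (a, b), p in adj.items():
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def _tukey_matrix(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    res = stats.tukey_hsd(*[groups[g] for g in names])
    mat = pd.DataFrame(1.0, index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                mat.loc[a, b] = mat.loc[b, a] = float(res.pvalue[i, j])
    return mat


def compare_components(
    table: pd.DataFrame, feature: str, alpha_normality: float = 0.05
) -> ComparisonReport:
    """Compare one feature across component classes at the table's level.

    Every group must pass Shapiro-Wilk at ``alpha_normality`` for the
    parametric branch (one-way ANOVA + Tukey HSD); otherwise the rank-based
    branch (Kruskal-Wallis + Dunn/Holm) runs.
    """
    groups = {
        lab: sub[feature].dropna().to_numpy()
        for lab, sub in table.groupby("label", sort=False)
    }
    groups = {lab: v for lab, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        raise ValueError("need at least two component groups to compare")
    for lab, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 observations")

    normality = {lab: float(stats.shapiro(v).pvalue) for lab, v in groups.items()}
    parametric = all(p > alpha_normality for p in normality.values())
    arrays = list(groups.values())
    if parametric:
        global_p = float(stats.f_oneway(*arrays).pvalue)
        pairwise = _tukey_matrix(groups)
        test = "anova+tukey"
    else:
        global_p = float(stats.kruskal(*arrays).pvalue)
        pairwise = _dunn_holm(groups)
        test = "kruskal+dunn"
    return ComparisonReport(
        feature=feature,
        test=test,
        global_p=global_p,
        pairwise_p=pairwise,
        group_normality_p=normality,
        group_sizes={lab: len(v) for lab, v in groups.items()},
    )


# ---------------------------------------------------------------------------
# Class histograms / bimodality
# ---------------------------------------------------------------------------

def histogram_by_class(
    table: pd.DataFrame,
    feature: str,
    component: ComponentClass | str,
    bins: int = 30,
    seed: int = 0,
) -> dict:
    """Fixed-width histogram of one feature for one class, with a bimodality flag.

    The flag compares 1- vs 2-component Gaussian-mixture fits by BIC and
    additionally requires the fitted modes to be well separated
    (Ashman's D > 2), so that a heavy-tailed unimodal sample does not flag.
    """
    component = ComponentClass(component)
    values = table.loc[table["label"] == component.value, feature].dropna().to_numpy()
    if len(values) < 10:
        raise ValueError("need at least 10 observations for a histogram")
    counts, edges = np.histogram(values, bins=bins)

    x = values.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=seed).fit(x)
    gm2 = GaussianMixture(2, random_state=seed, n_init=3).fit(x)
    mu = gm2.means_.ravel()
    var = gm2.covariances_.ravel()
    ashman_d = abs(mu[0] - mu[1]) * np.sqrt(2.0 / (var[0] + var[1]))
    bimodal = bool(gm2.bic(x) < gm1.bic(x) and ashman_d > 2.0)
    return {
        "counts": counts,
        "edges": edges,
        "bimodal": bimodal,
        "ashman_d": float(ashman_d),
        "modes": np.sort(mu),
        "n": len(values),
    }
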