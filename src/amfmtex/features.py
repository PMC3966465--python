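"""AM-FM texture features and group statistics.

Per image and scale we form 32-bin normalized histograms of the
instantaneous amplitude (IA) and of the IF magnitude ``||grad phi||`` in
cycles/mm, plus scalar summaries over the region of interest.  The
per-image scalar feature is the ROI median, yielding six features per
image: LIA/MIA/HIA (amplitude at the low/medium/high scale) and
LIF/MIF/HIF (frequency magnitude).  Groups of images are screened for
differences feature-by-feature with the two-sided Mann-Whitney rank-sum
test at P < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .amfm import DEFAULT_PIXEL_DENSITY, SCALES, AMFMResult

__all__ = [
    "FEATURE_NAMES",
    "FeatureTable",
    "GroupComparison",
    "compute_features",
    "summarize_group",
    "compare_groups",
]

FEATURE_NAMES = ("LIA", "MIA", "HIA", "LIF", "MIF", "HIF")
_PERCENTILES = (5, 10, 25, 75, 90, 95)
N_BINS = 32


def _feature_key(scale: str, kind: str) -> str:
    return scale[0].upper() + kind.upper()  # low+ia -> LIA


@dataclass
class FeatureTable:
    """Histograms and scalar summaries for one image."""

    histograms: dict[str, np.ndarray] = field(default_factory=dict)
    bin_edges: dict[str, np.ndarray] = field(default_factory=dict)
    summaries: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def medians(self) -> dict[str, float]:
        return {k: v["median"] for k, v in self.summaries.items()}


def _summary(values: np.ndarray) -> dict[str, float]:
    out = {
        "mean": float(np.mean(values)),
        "std": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        "median": float(np.median(values)),
    }
    for p in _PERCENTILES:
        out[f"p{p}"] = float(np.percentile(values, p))  # linear interpolation
    return out


def compute_features(
    amfm: dict[str, AMFMResult] | AMFMResult,
    roi: np.ndarray | None = None,
    pixel_density: float = DEFAULT_PIXEL_DENSITY,
    ia_max: float | None = None,
    n_bins: int = N_BINS,
) -> FeatureTable:
    """Extract histogram and scalar features from demodulation results.

    Statistics are computed over ``roi & valid`` pixels.  IA histograms span
    ``[0, ia_max]`` (per-image maximum when ``ia_max`` is not given; pass a
    cohort-wide maximum to make histograms comparable across images); IF
    histograms span each scale's passband in cycles/mm so the 32 bins line
    up across images by construction.
    """
    if isinstance(amfm, AMFMResult):
        amfm = {amfm.scale or "low": amfm}
    table = FeatureTable()
    for scale, res in amfm.items():
        band = SCALES[scale]
        sel = res.valid if roi is None else (res.valid & np.asarray(roi, dtype=bool))
        if not sel.any():
            raise ValueError(f"no valid ROI pixels at the {scale} scale")
        ia = res.ia[sel]
        ifm = res.if_magnitude(pixel_density)[sel]

        hi = float(ia_max if ia_max is not None else ia.max())
        hist_ia, edges_ia = np.histogram(ia, bins=n_bins, range=(0.0, hi or 1.0))
        hist_if, edges_if = np.histogram(ifm, bins=n_bins, range=(band.f_min, band.f_max))

        k_ia, k_if = _feature_key(scale, "ia"), _feature_key(scale, "if")
        table.histograms[k_ia] = hist_ia / max(hist_ia.sum(), 1)
        table.histograms[k_if] = hist_if / max(hist_if.sum(), 1)
        table.bin_edges[k_ia] = edges_ia
        table.bin_edges[k_if] = edges_if
        table.summaries[k_ia] = _summary(ia)
        table.summaries[k_if] = _summary(ifm)
    return table


def summarize_group(
    tables: list[FeatureTable],
    features: tuple[str, ...] | None = None,
    scale_by_100: bool = True,
) -> pd.DataFrame:
    """Group-level distribution of the per-image median features.

    One row per feature with mean/STD/median and the 5/10/25/75/90/95
    percentiles of the per-image medians, pre-multiplied by 100 for display
    (IA as a percentage of full scale, IF in hundredths of cycles/mm).
    """
    if not tables:
        raise ValueError("empty group")
    if features is None:
        features = tuple(tables[0].summaries.keys())
    factor = 100.0 if scale_by_100 else 1.0
    rows = {}
    for feat in features:
        vals = np.array([t.summaries[feat]["median"] for t in tables]) * factor
        rows[feat] = _summary(vals)
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class GroupComparison:
    """Pairwise Mann-Whitney screen over the six AM-FM features."""

    table: pd.DataFrame  # index: feature; columns: U, p, significant
    alpha: float
    low_power: bool = False

    @property
    def score(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def significant_features(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def compare_groups(
    group_a: list[FeatureTable],
    group_b: list[FeatureTable],
    features: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    correction: str | None = None,
) -> GroupComparison:
    """Two-sided Mann-Whitney U on per-image median features of two groups.

    No multiple-testing correction is applied by default (each feature is
    screened at the raw ``alpha``); ``correction='bonferroni'`` divides
    alpha by the number of features.
    """
    if features is None:
        features = tuple(group_a[0].summaries.keys())
    low_power = min(len(group_a), len(group_b)) < 3
    if low_power:
        warnings.warn(
            "groups with fewer than 3 images: Mann-Whitney p-values have very low power",
            stacklevel=2,
        )
    thr = alpha / len(features) if correction == "bonferroni" else alpha
    rows = []
    for feat in features:
        x = [t.summaries[feat]["median"] for t in group_a]
        y = [t.summaries[feat]["median"] for t in group_b]
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        rows.append(
            {"feature": feat, "U": float(res.statistic), "p": float(res.pvalue),
             "significant": bool(res.pvalue < thr)}
        )
    table = pd.DataFrame(rows).set_index("feature")
    return GroupComparison(table=table, alpha=alpha, low_power=low_power)
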