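"""Outlier trimming, control normalization and composite Z scoring.

The immunophenotyping summary works on per-animal n-fold values (treatment
over pooled untreated control-well mean). Raw values are first trimmed per
analysis group with quartile fences Q1 - m*IQR / Q3 + m*IQR (m = 1.7 by
default; quartiles by linear interpolation between order statistics). For
each metric and condition, knockout (KO) animals are scored against the
control-genotype (CTRL) reference::

    z = (X - mu) / sigma        X: KO value; mu, sigma: CTRL mean and SD

Per-animal cytokine z values are averaged into pro- and anti-inflammatory
cluster scores ("all" and "core" memberships), and each core cluster is
combined with a directionally matched shape-descriptor z:

    ProIF  = (z{IL-1b, IL-6, TNFa} + z_roundness) / 2
    AntiIF = (z{IL-4, IL-10}       + z_aspect_ratio) / 2

Missing members propagate: cluster scores average the non-missing members,
combined scores are missing if either component is missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin, TransformerMixin

__all__ = [
    "TrimRule",
    "ClusterConfig",
    "trim_outliers",
    "QuartileFenceTrimmer",
    "normalize_to_controls",
    "z_test",
    "ReferenceZScorer",
    "cluster_z",
    "combined_z",
    "build_zscore_panel",
]

logger = logging.getLogger(__name__)

PRO_CORE = ("IL-1b", "IL-6", "TNFa")
ANTI_CORE = ("IL-4", "IL-10")
PRO_ALL = ("TNFa", "IFNg", "IL-1b", "IL-2", "IL-6", "IL-12", "IL-17")
ANTI_ALL = ("IL-4", "IL-10", "IL-27")


@dataclass(frozen=True)
class TrimRule:
    """Quartile-fence outlier rule.

    ``multiplier`` scales the IQR (default 1.7, wider than Tukey's 1.5);
    ``quantile_method`` names the quartile convention (numpy's
    ``linear`` = interpolation between order statistics).
    """

    multiplier: float = 1.7
    quantile_method: str = "linear"

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("multiplier must be > 0")

    def fences(self, values: np.ndarray) -> tuple[float, float]:
        q1, q3 = np.percentile(values, [25, 75], method=self.quantile_method)
        iqr = q3 - q1
        return q1 - self.multiplier * iqr, q3 + self.multiplier * iqr


def trim_outliers(values, rule: TrimRule | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(kept_values, keep_mask)`` under the quartile-fence rule.

    With fewer than 4 values the rule cannot be applied; everything is kept
    and a warning is emitted.
    """
    rule = rule or TrimRule()
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be 1-D")
    if v.size < 4:
        warnings.warn("fewer than 4 values; outlier rule skipped", stacklevel=2)
        return v.copy(), np.ones(v.size, dtype=bool)
    lo, hi = rule.fences(v)
    mask = (v >= lo) & (v <= hi)
    return v[mask], mask


class QuartileFenceTrimmer(BaseEstimator, OutlierMixin):
    """Quartile-fence outlier detector with a scikit-learn interface.

    ``fit`` learns the fences from a 1-D sample; ``predict`` returns +1 for
    inliers and -1 for outliers (the sklearn outlier convention).
    """

    def __init__(self, multiplier: float = 1.7, quantile_method: str = "linear"):
        self.multiplier = multiplier
        self.quantile_method = quantile_method

    def fit(self, X, y=None):
        v = np.asarray(X, dtype=float).ravel()
        if v.size < 4:
            raise ValueError("need at least 4 values to fit fences")
        rule = TrimRule(self.multiplier, self.quantile_method)
        self.lower_fence_, self.upper_fence_ = rule.fences(v)
        return self

    def predict(self, X) -> np.ndarray:
        v = np.asarray(X, dtype=float).ravel()
        inlier = (v >= self.lower_fence_) & (v <= self.upper_fence_)
        return np.where(inlier, 1, -1)


def normalize_to_controls(values, control_mean: float, mode: str = "n_fold"):
    """Ratio (``n_fold``) or difference (``delta``) to the control mean.

    n-fold with a zero control mean is undefined; NaN plus a reason code is
    returned instead of inventing a divisor.
    """
    v = np.asarray(values, dtype=float)
    if mode == "n_fold":
        if control_mean == 0:
            out = np.full(v.shape, np.nan)
            reason = "zero_control_mean"
        else:
            out = v / control_mean
            reason = "ok"
    elif mode == "delta":
        out = v - control_mean
        reason = "ok"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if out.ndim == 0:
        return float(out), reason
    return out, reason


def z_test(X, mu: float, sigma: float):
    """z = (X - mu) / sigma; sigma = 0 yields NaN with a reason code."""
    x = np.asarray(X, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        out = np.full(x.shape, np.nan)
        reason = "zero_sigma"
    else:
        out = (x - mu) / sigma
        reason = "ok"
    if out.ndim == 0:
        return float(out), reason
    return out, reason


class ReferenceZScorer(BaseEstimator, TransformerMixin):
    """Score samples against a reference population (sklearn interface).

    ``fit`` stores the reference mean and SD per column; ``transform``
    returns z scores of new data against that reference. ``ddof`` defaults
    to 1 (sample SD), matching scoring small per-condition animal groups.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.mu_ = np.nanmean(X, axis=0)
        self.sigma_ = np.nanstd(X, axis=0, ddof=self.ddof)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (X - self.mu_) / self.sigma_
        z = np.where(self.sigma_ == 0, np.nan, z)
        return z.ravel() if squeeze else z


def cluster_z(z_values) -> float:
    """Arithmetic mean of member z values, ignoring missing members.

    Returns NaN when every member is missing.
    """
    z = np.asarray(z_values, dtype=float)
    if np.all(np.isnan(z)):
        return float("nan")
    return float(np.nanmean(z))


def combined_z(cytokine_cluster_z: float, shape_z: float) -> float:
    """Mean of a cytokine-cluster z and a shape-descriptor z.

    Missing either component makes the combined score missing (no silent
    imputation).
    """
    if np.isnan(cytokine_cluster_z) or np.isnan(shape_z):
        return float("nan")
    return 0.5 * (float(cytokine_cluster_z) + float(shape_z))


@dataclass(frozen=True)
class ClusterConfig:
    """Cytokine cluster membership and the paired shape descriptors."""

    pro_all: tuple[str, ...] = PRO_ALL
    anti_all: tuple[str, ...] = ANTI_ALL
    pro_core: tuple[str, ...] = PRO_CORE
    anti_core: tuple[str, ...] = ANTI_CORE
    pro_shape: str = "roundness"
    anti_shape: str = "aspect_ratio"


def _trimmed_group(df: pd.DataFrame, value_col: str, rule: TrimRule) -> pd.DataFrame:
    """Drop fence outliers within each (genotype, treatment) group."""
    kept = []
    for _, grp in df.groupby(["genotype", "treatment"], sort=False):
        v = grp[value_col].to_numpy(dtype=float)
        finite = np.isfinite(v)
        if finite.sum() < 4:
            kept.append(grp)
            continue
        lo, hi = rule.fences(v[finite])
        mask = ~finite | ((v >= lo) & (v <= hi))
        kept.append(grp[mask])
    return pd.concat(kept) if kept else df


def build_zscore_panel(
    cytokine_nfold: pd.DataFrame,
    shape_nfold: pd.DataFrame,
    clusters: ClusterConfig | None = None,
    rule: TrimRule | None = None,
    reference_genotype: str = "CTRL",
    scored_genotype: str = "KO",
) -> pd.DataFrame:
    """Build the per-animal x condition Z-score panel.

    ``cytokine_nfold``: per-animal columns [animal, genotype, treatment,
    analyte, n_fold]. ``shape_nfold``: per-animal columns [animal,
    genotype, treatment, metric, n_fold] with metrics including the paired
    shape descriptors. Raw n-fold values are trimmed per (genotype,
    treatment, metric) group before the reference statistics are taken.

    Returns one row per scored (KO) animal x treatment with per-cytokine z,
    cluster z (pro/anti, all/core), shape z, and the ProIF / AntiIF
    combined scores.
    """
    clusters = clusters or ClusterConfig()
    rule = rule or TrimRule()

    cyto = []
    for analyte, grp in cytokine_nfold.groupby("analyte", sort=False):
        g = _trimmed_group(grp, "n_fold", rule).copy()
        g["metric"] = analyte
        cyto.append(g[["animal", "genotype", "treatment", "metric", "n_fold"]])
    shp = []
    for metric, grp in shape_nfold.groupby("metric", sort=False):
        g = _trimmed_group(grp, "n_fold", rule).copy()
        shp.append(g[["animal", "genotype", "treatment", "metric", "n_fold"]])
    tidy = pd.concat(cyto + shp, ignore_index=True)

    # reference mean/SD per (treatment, metric) from CTRL animals
    ref = (
        tidy[tidy["genotype"] == reference_genotype]
        .groupby(["treatment", "metric"])["n_fold"]
        .agg(mu="mean", sigma=lambda v: v.std(ddof=1))
        .reset_index()
    )
    ko = tidy[tidy["genotype"] == scored_genotype].merge(
        ref, on=["treatment", "metric"], how="left"
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ko["z"] = (ko["n_fold"] - ko["mu"]) / ko["sigma"]
    ko.loc[~(ko["sigma"] > 0), "z"] = np.nan

    rows = []
    for (animal, treatment), grp in ko.groupby(["animal", "treatment"], sort=False):
        zmap = dict(zip(grp["metric"], grp["z"]))
        def zs(names):
            return [zmap.get(n, float("nan")) for n in names]
        pro_all_z = cluster_z(zs(clusters.pro_all))
        anti_all_z = cluster_z(zs(clusters.anti_all))
        pro_core_z = cluster_z(zs(clusters.pro_core))
        anti_core_z = cluster_z(zs(clusters.anti_core))
        round_z = zmap.get(clusters.pro_shape, float("nan"))
        ar_z = zmap.get(clusters.anti_shape, float("nan"))
        row = {
            "animal": animal,
            "treatment": treatment,
            "pro_all_z": pro_all_z,
            "anti_all_z": anti_all_z,
            "pro_core_z": pro_core_z,
            "anti_core_z": anti_core_z,
            "roundness_z": round_z,
            "aspect_ratio_z": ar_z,
            "proif_z": combined_z(pro_core_z, round_z),
            "antiif_z": combined_z(anti_core_z, ar_z),
        }
        for name, val in zmap.items():
            row[f"z_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
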