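"""Poverty-exposure disparity analysis.

Uses gridded infant mortality rate (IMR, deaths per 1,000 live births) as
a subnational poverty proxy and asks whether poorer populations are
disproportionately exposed to fire-derived PM2.5: exposure distributions
binned by IMR with anomalies relative to the across-bin mean, a
99%-confidence comparison of mean exposure between the extreme poverty
groups (IMR <= 20 vs >= 60 by default), fire-vs-nonfire source fractions
per poverty class, and a 3x3 bivariate poverty x exposure classification
map.

Interval convention throughout: left-closed right-open [a, b), with the
final bin right-closed.  Statistics are cell-level by default (the
gridded-value convention); population weighting is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .exceptions import ConfigurationError, UndefinedValueError
from .grids import check_aligned, make_field

__all__ = [
    "PovertyClassScheme",
    "BinnedExposureSummary",
    "bin_exposure_by_imr",
    "compare_extreme_groups",
    "exposure_source_fraction_by_class",
    "bivariate_classification",
]


@dataclass
class PovertyClassScheme:
    """Ordered IMR cutpoints and labels (De Sherbinin-style classes).

    Defaults: IMR < 15 not poor; 15-32 moderately poor; 32-65 poor;
    65-100 very poor.  The [a, b) convention resolves boundary overlap.
    """

    cutpoints: tuple[float, ...] = (15.0, 32.0, 65.0, 100.0)
    labels: tuple[str, ...] = ("not poor", "moderately poor", "poor", "very poor")

    def __post_init__(self):
        self.cutpoints = tuple(self.cutpoints)
        self.labels = tuple(self.labels)
        if list(self.cutpoints) != sorted(set(self.cutpoints)):
            raise ConfigurationError("cutpoints must be strictly increasing")
        if len(self.labels) != len(self.cutpoints):
            raise ConfigurationError("need one label per class")

    def classify(self, imr_values: np.ndarray) -> np.ndarray:
        """Class label per value; values above the last cutpoint get the
        last label, NaNs get ''. """
        v = np.asarray(imr_values, dtype=float)
        edges = (0.0,) + self.cutpoints
        idx = np.clip(np.digitize(v, edges[1:-1], right=False), 0, len(self.labels) - 1)
        out = np.asarray(self.labels, dtype=object)[idx]
        out[~np.isfinite(v)] = ""
        return out


@dataclass
class BinnedExposureSummary:
    """Per-IMR-bin exposure distributions and anomalies.

    ``table`` has one row per occupied bin: n cells, mean, median,
    quartiles, whisker bounds (1.5 IQR beyond quartiles) and the anomaly
    (bin mean minus the mean of bin means); ``outliers`` lists values
    beyond the whiskers per bin.
    """

    table: pd.DataFrame
    outliers: dict = field(default_factory=dict)
    grand_mean: float = float("nan")  # mean of bin means

    @property
    def anomalies(self) -> np.ndarray:
        return self.table["anomaly"].values


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """[a, b) bins, last bin right-closed; -1 for out-of-range/NaN."""
    v = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    idx = np.digitize(v, edges, right=False) - 1
    idx[np.isclose(v, edges[-1])] = len(edges) - 2
    bad = ~np.isfinite(v) | (idx < 0) | (idx > len(edges) - 2)
    idx[bad] = -1
    return idx


def bin_exposure_by_imr(
    pm_field: xr.DataArray,
    imr: xr.DataArray,
    bin_edges=None,
    bin_width: float = 10.0,
    pop: xr.DataArray | None = None,
) -> BinnedExposureSummary:
    """Distribution of cell PM values within each IMR bin.

    Anomaly = bin mean - mean(bin means), so anomalies average exactly to
    zero across occupied bins.  With ``pop`` supplied, bin means are
    population-weighted (distribution statistics stay cell-level).
    """
    check_aligned(pm_field, imr)
    pm = pm_field.values.ravel()
    iv = imr.values.ravel()
    ok = np.isfinite(pm) & np.isfinite(iv)
    if not ok.any():
        raise UndefinedValueError("no cells with both PM and IMR values")
    if bin_edges is None:
        top = np.ceil(np.nanmax(iv[ok]) / bin_width) * bin_width
        bin_edges = np.arange(0.0, max(top, bin_width) + bin_width / 2, bin_width)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ConfigurationError("bin edges must be strictly increasing")
    idx = _bin_index(iv, bin_edges)
    weights = pop.values.ravel() if pop is not None else None
    rows, outliers = [], {}
    for b in range(len(bin_edges) - 1):
        sel = ok & (idx == b)
        if not sel.any():
            continue
        x = pm[sel]
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo_w, hi_w = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        if weights is not None and weights[sel].sum() > 0:
            mean = float(np.average(x, weights=weights[sel]))
        else:
            mean = float(x.mean())
        label = f"[{bin_edges[b]:g}, {bin_edges[b + 1]:g})"
        rows.append(
            {
                "bin": label,
                "bin_left": bin_edges[b],
                "bin_right": bin_edges[b + 1],
                "n_cells": int(sel.sum()),
                "mean": mean,
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_lo": float(max(lo_w, x.min())),
                "whisker_hi": float(min(hi_w, x.max())),
            }
        )
        outliers[label] = x[(x < lo_w) | (x > hi_w)]
    table = pd.DataFrame(rows)
    grand = float(table["mean"].mean())
    table["anomaly"] = table["mean"] - grand
    return BinnedExposureSummary(table=table, outliers=outliers, grand_mean=grand)


def compare_extreme_groups(
    pm_field: xr.DataArray,
    imr: xr.DataArray,
    low_cut: float = 20.0,
    high_cut: float = 60.0,
    confidence: float = 0.99,
    method: str = "t",
    n_permutations: int = 9999,
    seed: int = 0,
) -> dict:
    """Compare mean exposure between high-poverty (IMR >= high_cut) and
    low-poverty (IMR <= low_cut) cells.

    Default test: Welch's unequal-variance two-sample t-test (two-sided);
    a seeded permutation test on the mean difference is available with
    ``method="permutation"``.  Returns group means, difference
    (high - low), statistic, p-value and the significance decision at the
    requested confidence level.
    """
    check_aligned(pm_field, imr)
    pm = pm_field.values.ravel()
    iv = imr.values.ravel()
    ok = np.isfinite(pm) & np.isfinite(iv)
    low = pm[ok & (iv <= low_cut)]
    high = pm[ok & (iv >= high_cut)]
    if low.size == 0 or high.size == 0:
        raise UndefinedValueError("an extreme-IMR group is empty")
    result = {
        "mean_low": float(low.mean()),
        "mean_high": float(high.mean()),
        "difference": float(high.mean() - low.mean()),
        "n_low": int(low.size),
        "n_high": int(high.size),
        "confidence": confidence,
    }
    if low.size < 2 or high.size < 2:
        result.update({"statistic": float("nan"), "p_value": float("nan"), "significant": None})
        return result
    if method == "t":
        test = stats.ttest_ind(high, low, equal_var=False)
        stat, p = float(test.statistic), float(test.pvalue)
    elif method == "permutation":
        res = stats.permutation_test(
            (high, low),
            lambda a, b, axis=-1: a.mean(axis=axis) - b.mean(axis=axis),
            n_resamples=n_permutations,
            vectorized=True,
            rng=np.random.default_rng(seed),
        )
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ConfigurationError(f"unknown test method '{method}'")
    result.update({"statistic": stat, "p_value": p, "significant": bool(p < 1 - confidence)})
    return result


def exposure_source_fraction_by_class(
    fire_pm: xr.DataArray,
    nonfire_pm: xr.DataArray,
    imr: xr.DataArray,
    scheme: PovertyClassScheme | None = None,
) -> pd.DataFrame:
    """Fire vs nonfire share of mean PM2.5 exposure per poverty class.

    Per class: fire fraction = mean(fire) / (mean(fire) + mean(nonfire));
    complements sum exactly to 1.  Empty classes are omitted.
    """
    scheme = scheme or PovertyClassScheme()
    check_aligned(fire_pm, nonfire_pm, imr)
    f = fire_pm.values.ravel()
    nf = nonfire_pm.values.ravel()
    iv = imr.values.ravel()
    ok = np.isfinite(f) & np.isfinite(nf) & np.isfinite(iv)
    labels = scheme.classify(iv)
    rows = []
    for lab in scheme.labels:
        sel = ok & (labels == lab)
        if not sel.any():
            continue
        mf, mn = float(f[sel].mean()), float(nf[sel].mean())
        tot = mf + mn
        if tot <= 0:
            continue
        rows.append(
            {
                "class": lab,
                "n_cells": int(sel.sum()),
                "mean_fire": mf,
                "mean_nonfire": mn,
                "fire_fraction": mf / tot,
                "nonfire_fraction": mn / tot,
            }
        )
    return pd.DataFrame(rows)


_BIVARIATE_LEVELS = ("low", "med", "high")


def bivariate_classification(
    pm_field: xr.DataArray,
    imr: xr.DataArray,
    pm_edges=(0.0, 5.0, 15.0, 30.0),
    imr_edges=(0.0, 20.0, 60.0, 100.0),
    pop: xr.DataArray | None = None,
) -> dict:
    """3x3 poverty x exposure categorical map.

    Each cell gets one of nine (IMR class x PM class) categories coded
    0..8 = 3*imr_class + pm_class; cells outside either top edge (or
    missing) are flagged -1.  Returns the coded map, a legend, and
    category counts (with population totals when ``pop`` is given).
    """
    check_aligned(pm_field, imr)
    pm_edges = np.asarray(pm_edges, dtype=float)
    imr_edges = np.asarray(imr_edges, dtype=float)
    for e, nm in ((pm_edges, "pm_edges"), (imr_edges, "imr_edges")):
        if np.any(np.diff(e) <= 0):
            raise ConfigurationError(f"{nm} must be strictly increasing")
    pm_idx = _bin_index(pm_field.values.ravel(), pm_edges)
    imr_idx = _bin_index(imr.values.ravel(), imr_edges)
    code = np.where((pm_idx >= 0) & (imr_idx >= 0), 3 * imr_idx + pm_idx, -1)
    code2d = code.reshape(pm_field.shape)
    legend = {
        3 * i + j: f"IMR {_BIVARIATE_LEVELS[i]} / PM {_BIVARIATE_LEVELS[j]}"
        for i in range(3)
        for j in range(3)
    }
    legend[-1] = "out of range"
    rows = []
    popv = pop.values.ravel() if pop is not None else None
    for c in sorted(legend):
        sel = code == c
        row = {"code": c, "label": legend[c], "n_cells": int(sel.sum())}
        if popv is not None:
            row["population"] = float(popv[sel].sum())
        rows.append(row)
    coded = make_field(
        code2d.astype(float), pm_field.coords["lat"].values, pm_field.coords["lon"].values,
        name="bivariate_class",
    )
    coded.attrs["legend"] = str(legend)
    return {"map": coded, "legend": legend, "counts": pd.DataFrame(rows)}
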