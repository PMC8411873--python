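"""Health-burden attribution for PM2.5 and ozone exposure.

The PM2.5 exposure-response uses the GEMM (Global Exposure Mortality
Model) relative-risk curve

    RR(z) = exp( theta * log(1 + z/alpha) / (1 + exp(-(z - mu)/nu)) ),
    z = max(0, C - cf),

with cause- (and age-) specific coefficients and a low-concentration
counterfactual cf (default 2.4 ug m-3).  Long-term ozone mortality uses a
log-linear response, RR = rr10 ** (max(0, ADM8h - TMREL) / 10).

Attributable burden per cell, cause and age group is

    burden = AF(RR(C)) * baseline_rate * age_fraction * population,

with AF = (RR - 1)/RR, aggregated over region masks.  Fire-attributable
burden follows the subtraction method: M_FIRE = M_ALL - M_FIRE_OFF,
computed per stratum (negative ozone differences are retained, not
clipped).  95% uncertainty intervals are propagated by Monte Carlo:
theta ~ Normal(theta, se), baseline rates lognormal and age fractions
logit-normal matched to their 95UIs, with draws shared across scenarios
and regions so that differences and group totals aggregate per draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import (
    ConfigurationError,
    MissingBaselineError,
    UndefinedValueError,
)
from .grids import RegionMask, check_aligned

__all__ = [
    "gemm_parameters",
    "OzoneERFParameters",
    "gemm_relative_risk",
    "ozone_relative_risk",
    "attributable_fraction",
    "ParameterDraws",
    "sample_parameter_draws",
    "scenario_burden",
    "fire_attributable_burden",
    "per_capita_rate",
    "BurdenResult",
]

_Z975 = 1.959963984540054

# Packaged default GEMM coefficients (configuration inputs, editable /
# replaceable via CSV).  "ncd_lri" is the all-age nonaccidental
# (NCD + LRI) aggregate; "five_cause" the cause-specific shape.
_GEMM_TABLES = {
    "ncd_lri": [
        # cause, age_group, theta, theta_se, alpha, mu, nu
        ("ncd_lri", "25+", 0.1430, 0.01807, 1.6, 15.5, 36.8),
    ],
    "five_cause": [
        ("ihd", "25+", 0.2969, 0.01787, 1.9, 12.0, 40.2),
        ("stroke", "25+", 0.2720, 0.07697, 6.2, 16.7, 23.7),
        ("copd", "25+", 0.2510, 0.06762, 6.5, 2.5, 32.0),
        ("lung_cancer", "25+", 0.2942, 0.06147, 9.3, 29.8, 84.6),
        ("lri", "all", 0.4468, 0.11735, 6.4, 5.7, 8.4),
    ],
}


def gemm_parameters(variant: str = "ncd_lri", counterfactual: float = 2.4) -> pd.DataFrame:
    """Default GEMM coefficient table for a variant, with counterfactual."""
    if variant not in _GEMM_TABLES:
        raise ConfigurationError(f"unknown GEMM variant '{variant}'")
    df = pd.DataFrame(
        _GEMM_TABLES[variant],
        columns=["cause", "age_group", "theta", "theta_se", "alpha", "mu", "nu"],
    )
    df["cf"] = counterfactual
    return df


@dataclass
class OzoneERFParameters:
    """Log-linear long-term ozone mortality response."""

    rr_per_10ppb: float = 1.12
    rr_ci: tuple[float, float] = (1.08, 1.16)
    tmrel: float = 26.7  # ppbv
    cause: str = "resp"
    age_group: str = "25+"

    def __post_init__(self):
        if self.rr_per_10ppb <= 0:
            raise ConfigurationError("rr_per_10ppb must be > 0")
        if self.tmrel < 0:
            raise ConfigurationError("tmrel must be >= 0")

    @property
    def beta(self) -> float:
        """log-RR per 10 ppbv."""
        return float(np.log(self.rr_per_10ppb))

    @property
    def beta_se(self) -> float:
        lo, hi = self.rr_ci
        return float((np.log(hi) - np.log(lo)) / (2 * _Z975))


def _gemm_g(c, alpha: float, mu: float, nu: float, cf: float):
    """theta-free part of the GEMM log-relative-risk."""
    c = np.asarray(c, dtype=float)
    if np.any(c[np.isfinite(c)] < 0):
        raise ValueError("concentrations must be nonnegative")
    z = np.maximum(0.0, c - cf)
    return np.log1p(z / alpha) / (1.0 + np.exp(-(z - mu) / nu))


def gemm_relative_risk(c, params_row) -> np.ndarray | float:
    """GEMM relative risk at PM2.5 concentration(s) c for one cause/age.

    ``params_row`` is a mapping or table row with theta, alpha, mu, nu, cf.
    """
    g = _gemm_g(c, params_row["alpha"], params_row["mu"], params_row["nu"], params_row["cf"])
    rr = np.exp(params_row["theta"] * g)
    return float(rr) if np.isscalar(c) or np.ndim(c) == 0 else rr


def ozone_relative_risk(adm8h_value, p: OzoneERFParameters):
    """Relative risk at an ADM8h ozone exposure (ppbv)."""
    z10 = np.maximum(0.0, np.asarray(adm8h_value, dtype=float) - p.tmrel) / 10.0
    rr = np.power(p.rr_per_10ppb, z10)
    return float(rr) if np.ndim(adm8h_value) == 0 else rr


def attributable_fraction(rr):
    """Population attributable fraction AF = (RR - 1)/RR."""
    arr = np.asarray(rr, dtype=float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise ValueError("relative risk must be positive")
    if np.any(arr[np.isfinite(arr)] < 1):
        warnings.warn("RR < 1 yields a negative attributable fraction", stacklevel=2)
    af = (arr - 1.0) / arr
    return float(af) if np.ndim(rr) == 0 else af


# --- Monte Carlo parameter draws -----------------------------------------


@dataclass
class ParameterDraws:
    """Pre-sampled uncertain inputs, shared across scenarios.

    theta: (cause, age_group) -> (n_draws,) log-RR slope draws (for ozone,
    log-RR per 10 ppbv).  rates: (region, cause, age_group, metric) ->
    baseline-rate draws; fracs: (region, cause, age_group) -> age-fraction
    draws.
    """

    n_draws: int
    theta: dict = field(default_factory=dict)
    rates: dict = field(default_factory=dict)
    fracs: dict = field(default_factory=dict)


def _lognormal_draws(rng, central, lo, hi, n):
    if central <= 0 or hi <= lo:
        return np.full(n, central)
    sigma = (np.log(hi) - np.log(lo)) / (2 * _Z975)
    if sigma <= 0:
        return np.full(n, central)
    return np.exp(rng.normal(np.log(central), sigma, size=n))


def _logitnormal_draws(rng, central, lo, hi, n):
    if central <= 0 or central >= 1 or hi <= lo or lo <= 0 or hi >= 1:
        return np.full(n, central)

    def logit(x):
        return np.log(x / (1 - x))

    sigma = (logit(hi) - logit(lo)) / (2 * _Z975)
    if sigma <= 0:
        return np.full(n, central)
    draws = rng.normal(logit(central), sigma, size=n)
    return 1.0 / (1.0 + np.exp(-draws))


def sample_parameter_draws(
    baseline: pd.DataFrame,
    gemm_params: pd.DataFrame | None = None,
    ozone_params: OzoneERFParameters | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> ParameterDraws:
    """Sample all uncertain inputs once, for reuse in every scenario.

    Sharing one set of draws between the all-sources and fires-off burden
    computations makes the subtraction-method uncertainty interval a
    per-draw difference, and group 95UIs per-draw sums.
    """
    if n_draws <= 0:
        raise ConfigurationError("n_draws must be positive")
    rng = np.random.default_rng(seed)
    d = ParameterDraws(n_draws=n_draws)
    if gemm_params is not None:
        for _, row in gemm_params.iterrows():
            d.theta[(row["cause"], row["age_group"])] = rng.normal(
                row["theta"], row["theta_se"], size=n_draws
            ) if row["theta_se"] > 0 else np.full(n_draws, row["theta"])
    if ozone_params is not None:
        se = ozone_params.beta_se
        d.theta[(ozone_params.cause, ozone_params.age_group)] = (
            rng.normal(ozone_params.beta, se, size=n_draws)
            if se > 0
            else np.full(n_draws, ozone_params.beta)
        )
    for _, row in baseline.iterrows():
        key = (row["region"], row["cause"], row["age_group"])
        d.rates[key + ("mortality",)] = _lognormal_draws(
            rng, row["mort_rate"], row["mort_lo"], row["mort_hi"], n_draws
        )
        d.rates[key + ("daly",)] = _lognormal_draws(
            rng, row["daly_rate"], row["daly_lo"], row["daly_hi"], n_draws
        )
        d.fracs[key] = _logitnormal_draws(
            rng, row["age_fraction"], row["frac_lo"], row["frac_hi"], n_draws
        )
    return d


# --- burden results -------------------------------------------------------


@dataclass
class BurdenResult:
    """Attributable burden per (region, cause, age_group) stratum.

    ``table`` holds central estimates (columns ``mortality`` in deaths/yr
    and ``daly`` in DALYs/yr); ``draws`` holds the matching Monte-Carlo
    samples, metric -> array of shape (n_draws, n_strata), row-aligned
    with ``table``.  Uncertainty intervals for any roll-up are percentile
    summaries of per-draw sums.
    """

    table: pd.DataFrame
    draws: dict | None = None
    scenario: str = ""
    kind: str = "PM2.5"

    def _select(self, region=None, cause=None):
        sel = np.ones(len(self.table), dtype=bool)
        if region is not None:
            regions = [region] if isinstance(region, str) else list(region)
            sel &= self.table["region"].isin(regions).values
        if cause is not None:
            sel &= (self.table["cause"] == cause).values
        return sel

    def central(self, metric: str = "mortality", region=None, cause=None) -> float:
        sel = self._select(region, cause)
        return float(self.table.loc[sel, metric].sum())

    def draw_sums(self, metric: str = "mortality", region=None, cause=None) -> np.ndarray:
        if self.draws is None:
            raise UndefinedValueError("no Monte-Carlo draws attached")
        sel = self._select(region, cause)
        return self.draws[metric][:, sel].sum(axis=1)

    def ui(self, metric: str = "mortality", region=None, cause=None) -> tuple[float, float]:
        s = self.draw_sums(metric, region, cause)
        return (float(np.percentile(s, 2.5)), float(np.percentile(s, 97.5)))

    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.table["region"]))

    def __sub__(self, other: "BurdenResult") -> "BurdenResult":
        return fire_attributable_burden(self, other)


def _check_same_strata(a: BurdenResult, b: BurdenResult) -> None:
    cols = ["region", "cause", "age_group"]
    if len(a.table) != len(b.table) or not (
        a.table[cols].reset_index(drop=True).equals(b.table[cols].reset_index(drop=True))
    ):
        raise UndefinedValueError("burden results have mismatched stratification")


def scenario_burden(
    field: xr.DataArray,
    pop: xr.DataArray,
    baseline: pd.DataFrame,
    params,
    kind: str = "PM2.5",
    masks: list[RegionMask] | None = None,
    draws: ParameterDraws | None = None,
    scenario: str = "",
) -> BurdenResult:
    """Attributable burden of one scenario field, by region/cause/age.

    ``params`` is a GEMM coefficient table (kind "PM2.5") or
    :class:`OzoneERFParameters` (kind "O3").  Baseline rates are joined to
    cells through the region masks; a region without baseline rows raises
    an explicit error naming it.
    """
    check_aligned(field, pop)
    if masks is None:
        masks = [RegionMask("domain", xr.ones_like(pop, dtype=bool))]
    if kind == "PM2.5":
        rows = [dict(r) for _, r in params.iterrows()]
    elif kind == "O3":
        rows = [
            {
                "cause": params.cause,
                "age_group": params.age_group,
                "theta": params.beta,
                "theta_se": params.beta_se,
            }
        ]
    else:
        raise ConfigurationError(f"unknown burden kind '{kind}'")

    missing = []
    for m in masks:
        for r in rows:
            hit = baseline[
                (baseline["region"] == m.name)
                & (baseline["cause"] == r["cause"])
                & (baseline["age_group"] == r["age_group"])
            ]
            if hit.empty:
                missing.append((m.name, r["cause"]))
    if missing:
        raise MissingBaselineError(f"baseline rates missing for: {sorted(set(missing))}")

    out_rows = []
    out_draws = {"mortality": [], "daly": []} if draws is not None else None
    for m in masks:
        check_aligned(field, m.mask)
        cells = m.mask.values & np.isfinite(field.values)
        c_cells = field.values[cells]
        p_cells = pop.values[cells]
        for r in rows:
            if kind == "PM2.5":
                g = _gemm_g(c_cells, r["alpha"], r["mu"], r["nu"], r["cf"])
            else:
                g = np.maximum(0.0, c_cells - params.tmrel) / 10.0
            af = 1.0 - np.exp(-r["theta"] * g)
            exposed = float(np.dot(p_cells, af))
            base = baseline[
                (baseline["region"] == m.name)
                & (baseline["cause"] == r["cause"])
                & (baseline["age_group"] == r["age_group"])
            ].iloc[0]
            mort = exposed * base["mort_rate"] * base["age_fraction"]
            daly = exposed * base["daly_rate"] * base["age_fraction"]
            out_rows.append(
                {
                    "region": m.name,
                    "cause": r["cause"],
                    "age_group": r["age_group"],
                    "mortality": mort,
                    "daly": daly,
                }
            )
            if draws is not None:
                th = draws.theta[(r["cause"], r["age_group"])]
                # (n_draws, n_cells) attributable fractions -> exposed persons
                af_d = 1.0 - np.exp(-np.outer(th, g))
                exposed_d = af_d @ p_cells
                key = (m.name, r["cause"], r["age_group"])
                fr_d = draws.fracs[key]
                out_draws["mortality"].append(exposed_d * draws.rates[key + ("mortality",)] * fr_d)
                out_draws["daly"].append(exposed_d * draws.rates[key + ("daly",)] * fr_d)

    table = pd.DataFrame(out_rows)
    draws_out = None
    if draws is not None:
        draws_out = {k: np.column_stack(v) for k, v in out_draws.items()}
    return BurdenResult(table=table, draws=draws_out, scenario=scenario, kind=kind)


def fire_attributable_burden(all_result: BurdenResult, nofire_result: BurdenResult) -> BurdenResult:
    """Subtraction method: fire burden = all-sources minus fires-off,
    per stratum.  Negative differences (possible for ozone where fires
    suppress production) are retained."""
    _check_same_strata(all_result, nofire_result)
    table = all_result.table.copy()
    for metric in ("mortality", "daly"):
        table[metric] = all_result.table[metric].values - nofire_result.table[metric].values
    draws = None
    if all_result.draws is not None and nofire_result.draws is not None:
        draws = {
            k: all_result.draws[k] - nofire_result.draws[k] for k in all_result.draws
        }
    return BurdenResult(table=table, draws=draws, scenario="fire", kind=all_result.kind)


def burden_percent_reduction(
    all_result: BurdenResult, fire_result: BurdenResult, metric="mortality", region=None
) -> float:
    """Percentage of the all-sources burden attributable to fires."""
    total = all_result.central(metric, region)
    if total == 0:
        return float("nan")
    return 100.0 * fire_result.central(metric, region) / total


def per_capita_rate(burden: float, population: float) -> float:
    """Deaths (or DALYs) per 100,000 persons per year."""
    if population <= 0:
        raise UndefinedValueError("population must be positive")
    return 1.0e5 * burden / population
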