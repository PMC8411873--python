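"""Regional aggregation, rounding conventions and pipeline orchestration.

Emits a summary table in the shape used for fire health-impact
assessments: one row per region plus group-total rows (e.g. a mainland
group and a whole-domain total), with exposure reductions, burden
reductions, averted mortality and DALYs with 95% uncertainty intervals,
and per-capita rates.

Rounding is presentation-only and applied last: PM2.5 mortality and DALY
values to the nearest 100, ozone mortality to the nearest 10,
half-away-from-zero.  Machine-readable outputs always carry the
unrounded values alongside.  Group 95UIs are computed by summing
Monte-Carlo samples per draw, never by summing interval endpoints.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import equity as eq
from . import evaluation as ev
from . import exposure as ex
from . import health as hb
from . import synthetic as syn
from .config import PipelineConfig
from .exceptions import ConfigurationError, StageError
from .grids import RegionMask, write_netcdf

__all__ = ["apply_rounding", "aggregate_regions", "SummaryTable", "run_pipeline", "Pipeline"]


def apply_rounding(value: float, species_kind: str) -> float:
    """Presentation rounding: PM2.5 mortality/DALYs to the nearest 100,
    O3 mortality to the nearest 10; half rounds away from zero."""
    if not np.isfinite(value):
        return value
    q = 100.0 if species_kind.upper().startswith("PM") else 10.0
    return float(np.sign(value) * np.floor(abs(value) / q + 0.5) * q)


@dataclass
class SummaryTable:
    """Per-region summary with group-total rows.

    ``table`` columns include central estimates, 95UI bounds, and rounded
    presentation values; ``draws_by_region`` retains per-draw samples so
    group intervals aggregate per draw.
    """

    table: pd.DataFrame

    def validate_group_sums(self, groupings: dict) -> None:
        """Group-total central estimates must equal member sums exactly
        (pre-rounding)."""
        t = self.table.set_index("region")
        for group, members in groupings.items():
            for col in ("pm25_mortality", "o3_mortality", "pm25_daly"):
                if col not in t.columns:
                    continue
                member_sum = t.loc[members, col].sum()
                if not np.isclose(t.loc[group, col], member_sum, rtol=1e-12, atol=1e-9):
                    raise ConfigurationError(
                        f"group '{group}' {col} differs from member sum"
                    )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def aggregate_regions(
    burden: hb.BurdenResult, groupings: dict, metric: str = "mortality"
) -> pd.DataFrame:
    """Group totals from per-region burdens.

    Central group value = sum of member central estimates; 95UIs (when
    draws are attached) are percentiles of per-draw member sums.
    Referencing a region absent from the burden result raises.
    """
    known = set(burden.regions())
    rows = []
    for group, members in groupings.items():
        if not members:
            raise ConfigurationError(f"grouping '{group}' is empty")
        unknown = [m for m in members if m not in known]
        if unknown:
            raise ConfigurationError(f"grouping '{group}' references unknown regions {unknown}")
        row = {"group": group, "central": burden.central(metric, region=members)}
        if burden.draws is not None:
            lo, hi = burden.ui(metric, region=members)
            row["ui_lower"], row["ui_upper"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


class Pipeline:
    """Lazily-computed pipeline products for one configuration.

    Every product is deterministic in (config, seed); stages are exposed
    individually so CLI subcommands can run them in isolation.
    """

    def __init__(self, config: PipelineConfig):
        self.config = config
        self._cache: dict = {}

    def _get(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    # --- products ---------------------------------------------------------
    @property
    def pair(self):
        return self._get("pair", lambda: syn.generate_scenario_pair(self.config.synthetic))

    @property
    def population(self):
        return self._get("pop", lambda: syn.generate_population(self.config.synthetic))

    @property
    def fire_pm25_annual(self):
        return self._get("fire_pm", lambda: self.pair.fire_pm25_annual())

    @property
    def imr(self):
        return self._get(
            "imr", lambda: syn.generate_imr_grid(self.config.synthetic, self.fire_pm25_annual)
        )

    @property
    def stations(self):
        return self._get(
            "stations",
            lambda: syn.generate_station_series(
                self.config.synthetic, self.pair, self.config.evaluation.n_stations
            ),
        )

    @property
    def masks(self) -> list[RegionMask]:
        def build():
            s = self.config.synthetic
            return [
                RegionMask.from_box(
                    r.name, s.lat, s.lon, r.lat_min, r.lat_max, r.lon_min, r.lon_max
                )
                for r in self.config.regions
            ]

        return self._get("masks", build)

    @property
    def baseline(self):
        return self._get(
            "baseline",
            lambda: syn.generate_baseline_health(
                [m.name for m in self.masks], self.config.health.gemm_variant
            ),
        )

    @property
    def adm8h_fields(self):
        def build():
            return {
                scen: ex.adm8h(self.pair.o3(scen)) for scen in ("all", "nofire")
            }

        return self._get("adm8h", build)

    def _group_mask(self, members: list[str]) -> RegionMask:
        by_name = {m.name: m for m in self.masks}
        combined = by_name[members[0]].mask.copy()
        for m in members[1:]:
            combined = combined | by_name[m].mask
        return RegionMask("+".join(members), combined)

    # --- stages -----------------------------------------------------------
    def exposure_table(self) -> pd.DataFrame:
        """Population-weighted exposure metrics and WHO exceedances per
        region and per group."""
        cfg = self.config
        pm_all = self.pair.annual("PM2.5", "all")
        pm_no = self.pair.annual("PM2.5", "nofire")
        o3 = self.adm8h_fields
        units = []
        for m in self.masks:
            units.append((m.name, m))
        for group, members in cfg.reporting.groupings.items():
            units.append((group, self._group_mask(members)))
        rows = []
        for name, mask in units:
            pwm_all = ex.population_weighted_mean(pm_all, self.population, mask)
            pwm_no = ex.population_weighted_mean(pm_no, self.population, mask)
            o3_all = ex.population_weighted_mean(o3["all"], self.population, mask)
            o3_no = ex.population_weighted_mean(o3["nofire"], self.population, mask)
            it2 = cfg.reporting.who_interim_target2
            exc_all = ex.population_above_threshold(pm_all, self.population, it2, mask)
            exc_no = ex.population_above_threshold(pm_no, self.population, it2, mask)
            rows.append(
                {
                    "region": name,
                    "pm25_pw_all": pwm_all,
                    "pm25_pw_nofire": pwm_no,
                    "pm25_exposure_reduction_pct": ex.percent_change(pwm_all, pwm_no),
                    "o3_adm8h_pw_all": o3_all,
                    "o3_adm8h_pw_nofire": o3_no,
                    "o3_exposure_reduction_pct": ex.percent_change(o3_all, o3_no),
                    "pop_above_it2_all": exc_all,
                    "pop_above_it2_nofire": exc_no,
                    "pop_above_it2_reduction_pct": ex.percent_change(exc_all, exc_no)
                    if exc_all > 0
                    else 0.0,
                }
            )
        return pd.DataFrame(rows)

    def burden_results(self) -> dict:
        """Central + Monte-Carlo burdens for both species and scenarios."""
        if "burden" in self._cache:
            return self._cache["burden"]
        cfg = self.config
        gemm = hb.gemm_parameters(cfg.health.gemm_variant, cfg.health.counterfactual)
        o3p = hb.OzoneERFParameters(
            rr_per_10ppb=cfg.health.ozone_rr_per_10ppb,
            rr_ci=cfg.health.ozone_rr_ci,
            tmrel=cfg.health.ozone_tmrel,
        )
        draws = hb.sample_parameter_draws(
            self.baseline, gemm, o3p, n_draws=cfg.health.n_draws, seed=cfg.seed
        )
        out = {}
        for kind, params, fields in (
            ("PM2.5", gemm, {s: self.pair.annual("PM2.5", s) for s in ("all", "nofire")}),
            ("O3", o3p, self.adm8h_fields),
        ):
            res = {
                scen: hb.scenario_burden(
                    fields[scen],
                    self.population,
                    self.baseline,
                    params,
                    kind=kind,
                    masks=self.masks,
                    draws=draws,
                    scenario=scen,
                )
                for scen in ("all", "nofire")
            }
            res["fire"] = hb.fire_attributable_burden(res["all"], res["nofire"])
            out[kind] = res
        self._cache["burden"] = out
        return out

    def evaluation_table(self) -> pd.DataFrame:
        cfg = self.config
        selected = ev.select_fire_influenced(
            self.pair.annual("PM10", "all"),
            self.pair.annual("PM10", "nofire"),
            self.stations,
            cfg.evaluation.fire_influence_threshold,
            cfg.evaluation.sampling,
        )
        use = selected if selected else self.stations
        table = ev.evaluate_stations(use, scenario="all", fire_derived=True)
        table.insert(1, "fire_influenced", True if selected else False)
        return table

    def equity_results(self) -> dict:
        cfg = self.config.equity
        fire = self.fire_pm25_annual
        nonfire = self.pair.annual("PM2.5", "nofire")
        binned = eq.bin_exposure_by_imr(fire, self.imr, bin_width=cfg.imr_bin_width)
        extreme_fire = eq.compare_extreme_groups(
            fire, self.imr, cfg.low_cut, cfg.high_cut, cfg.confidence
        )
        extreme_nonfire = eq.compare_extreme_groups(
            nonfire, self.imr, cfg.low_cut, cfg.high_cut, cfg.confidence
        )
        fractions = eq.exposure_source_fraction_by_class(
            fire, nonfire, self.imr,
            eq.PovertyClassScheme(cfg.poverty_cutpoints, cfg.poverty_labels),
        )
        bivar = eq.bivariate_classification(
            fire, self.imr, cfg.pm_class_edges, cfg.imr_class_edges, pop=self.population
        )
        return {
            "binned": binned,
            "extreme_fire": extreme_fire,
            "extreme_nonfire": extreme_nonfire,
            "fractions": fractions,
            "bivariate": bivar,
        }

    def summary_table(self) -> SummaryTable:
        """Table-2-shaped summary: regions then group totals."""
        cfg = self.config
        exposure = self.exposure_table().set_index("region")
        burdens = self.burden_results()
        pm, o3 = burdens["PM2.5"], burdens["O3"]
        units: list[tuple[str, list[str]]] = [(m.name, [m.name]) for m in self.masks]
        units += [(g, members) for g, members in cfg.reporting.groupings.items()]
        rows = []
        for name, members in units:
            pm_fire = pm["fire"].central("mortality", region=members)
            pm_all = pm["all"].central("mortality", region=members)
            daly_fire = pm["fire"].central("daly", region=members)
            o3_fire = o3["fire"].central("mortality", region=members)
            o3_all = o3["all"].central("mortality", region=members)
            pm_lo, pm_hi = pm["fire"].ui("mortality", region=members)
            dl_lo, dl_hi = pm["fire"].ui("daly", region=members)
            o3_lo, o3_hi = o3["fire"].ui("mortality", region=members)
            mask = self._group_mask(members)
            pop_total = float(self.population.values[mask.mask.values].sum())
            rows.append(
                {
                    "region": name,
                    "pm25_exposure_reduction_pct": exposure.loc[
                        name, "pm25_exposure_reduction_pct"
                    ],
                    "pm25_burden_reduction_pct": 100.0 * pm_fire / pm_all if pm_all else np.nan,
                    "pm25_mortality": pm_fire,
                    "pm25_mortality_lo": pm_lo,
                    "pm25_mortality_hi": pm_hi,
                    "pm25_daly": daly_fire,
                    "pm25_daly_lo": dl_lo,
                    "pm25_daly_hi": dl_hi,
                    "o3_exposure_reduction_pct": exposure.loc[name, "o3_exposure_reduction_pct"],
                    "o3_burden_reduction_pct": 100.0 * o3_fire / o3_all if o3_all else np.nan,
                    "o3_mortality": o3_fire,
                    "o3_mortality_lo": o3_lo,
                    "o3_mortality_hi": o3_hi,
                    "mortality_per_100k": hb.per_capita_rate(pm_fire, pop_total),
                    "pm25_mortality_rounded": apply_rounding(pm_fire, "PM2.5"),
                    "pm25_daly_rounded": apply_rounding(daly_fire, "PM2.5"),
                    "o3_mortality_rounded": apply_rounding(o3_fire, "O3"),
                }
            )
        return SummaryTable(table=pd.DataFrame(rows))


def _config_hash(config: PipelineConfig) -> str:
    from .config import _plain

    blob = json.dumps(_plain(config.to_dict()), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Execute generate -> exposure -> burden -> evaluation -> equity ->
    report, writing all outputs plus a provenance record.

    Idempotent under a fixed seed: rerunning writes byte-identical summary
    CSVs.  A stage failure raises :class:`StageError` naming the stage and
    listing the outputs already written.
    """
    if seed is not None:
        config = config.with_seed(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pipe = Pipeline(config)
    written: list[str] = []

    def _write(name, fn):
        try:
            result = fn()
        except Exception as err:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, str(err), written) from err
        return result

    artifacts: dict = {}

    def emit_csv(df: pd.DataFrame, fname: str):
        path = outdir / fname
        df.to_csv(path, index=False)
        written.append(fname)
        return path

    # simulate
    def _simulate():
        write_netcdf(pipe.pair.to_dataset(), outdir / "scenario_pair.nc")
        write_netcdf(pipe.population.to_dataset(name="population"), outdir / "population.nc")
        write_netcdf(pipe.imr.to_dataset(name="imr"), outdir / "imr.nc")
        written.extend(["scenario_pair.nc", "population.nc", "imr.nc"])
        rows = []
        for s in pipe.stations:
            for t, o, ma, mn in zip(
                s.time, s.observed, s.model["all"], s.model["nofire"]
            ):
                rows.append(
                    {
                        "station_id": s.station_id,
                        "lat": s.lat,
                        "lon": s.lon,
                        "date": t.strftime("%Y-%m-%d"),
                        "observed": o,
                        "model_all": ma,
                        "model_nofire": mn,
                    }
                )
        emit_csv(pd.DataFrame(rows), "stations.csv")
        return True

    _write("simulate", _simulate)
    artifacts["exposure"] = _write("exposure", pipe.exposure_table)
    emit_csv(artifacts["exposure"], "exposure.csv")
    artifacts["burden"] = _write("burden", pipe.burden_results)
    artifacts["evaluation"] = _write("evaluate", pipe.evaluation_table)
    emit_csv(artifacts["evaluation"], "evaluation.csv")
    artifacts["equity"] = _write("equity", pipe.equity_results)
    emit_csv(artifacts["equity"]["binned"].table, "equity_binned.csv")
    emit_csv(artifacts["equity"]["fractions"], "equity_fractions.csv")
    emit_csv(artifacts["equity"]["bivariate"]["counts"], "equity_bivariate_counts.csv")
    with open(outdir / "equity_tests.json", "w") as fh:
        json.dump(
            {
                "fire": artifacts["equity"]["extreme_fire"],
                "nonfire": artifacts["equity"]["extreme_nonfire"],
            },
            fh,
            indent=2,
            default=float,
        )
    written.append("equity_tests.json")
    summary = _write("report", pipe.summary_table)
    summary.validate_group_sums(config.reporting.groupings)
    emit_csv(summary.table, "summary.csv")
    artifacts["summary"] = summary

    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": written,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    artifacts["provenance"] = provenance
    artifacts["pipeline"] = pipe
    return artifacts
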