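"""Configuration-driven orchestration of the analysis matrix.

One run executes, for every requested cell of the matrix

    causes × {base, SES-adjusted [, ozone-adjusted]}
           × {total PM2.5, non-traffic residual}
           × {linear, spline}  (+ subgroup and low-exposure restriction runs)

the same steps a direct library call would: person-month expansion →
sufficient-statistic aggregation → stratified Cox fit → RR per 10 µg/m³ (or
RR curve). Orchestration adds nothing numeric: every cell's estimate equals
the corresponding direct :mod:`pmcox.engine` call on the same inputs. A
stage failure aborts only its matrix cell and is recorded in the summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import exposure as expo
from .causes import CauseOfDeathMap
from .cohort import (
    classify_ses_tertiles,
    impute_missing_income_years,
    read_cohort_csv,
    validate_cohort,
)
from .effects import attach_zip_attribute, age_group_column, subgroup_rrs
from .engine import aggregate_cells, expand_person_months, fit_cox, rr_per_10
from .splines import SplineBasis, place_knots, rr_curve

DEFAULT_CAUSES = ["all_cause", "non_accidental", "all_cvd", "all_respiratory", "all_cancer"]


@dataclass
class RunConfig:
    """Everything one analysis run needs; loadable from YAML."""

    input_dir: str
    output_dir: str
    causes: list = field(default_factory=lambda: list(DEFAULT_CAUSES))
    variants: list = field(default_factory=lambda: ["base", "ses"])  # + "ozone"
    exposures: list = field(default_factory=lambda: ["total"])  # + "nontraffic"
    spline_causes: list = field(default_factory=list)
    spline_knots: int = 3
    knot_override: list | None = None
    restriction_thresholds: list = field(default_factory=list)  # e.g. [8, 10, 12]
    modifiers: list = field(default_factory=list)  # sex, race, urban, ses, age_group
    ses_mode: str = "strata"  # "strata" (extra stratum dim) or "covariate"
    monitor_radius_miles: float = 6.0
    tol: float = 1e-8
    max_iter: int = 50
    seed: int = 0
    make_figures: bool = False
    cause_ranges: dict | None = None  # override the default cause map

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_inputs(input_dir) -> dict:
    """Read the delimited-text input bundle the generator (or a user) provides."""
    d = pathlib.Path(input_dir)
    cohort, residence = read_cohort_csv(d / "cohort.csv", d / "residence.csv")
    exposure_long = pd.read_csv(d / "exposure.csv")
    surfaces = {
        p: expo.ZipMonthSurface.from_long(exposure_long, p)
        for p in exposure_long["pollutant"].unique()
    }
    data = {
        "cohort": cohort,
        "residence": residence,
        "surfaces": surfaces,
        "zip_attrs": pd.read_csv(d / "zip_attributes.csv"),
        "income": pd.read_csv(d / "zip_income.csv"),
    }
    for opt in ("tracers", "monitors"):
        p = d / f"{opt}.csv"
        if p.exists():
            data[opt] = pd.read_csv(p)
    return data


def validate_inputs(input_dir) -> dict:
    """Schema/coverage/invariant checks; analysis refuses to run on errors."""
    errors: list[str] = []
    warnings: list[str] = []
    try:
        data = load_inputs(input_dir)
    except (OSError, KeyError, ValueError) as exc:
        return {"errors": [f"unreadable inputs: {exc}"], "warnings": [], "n_errors": 1}

    errors += validate_cohort(data["cohort"], data["residence"])

    if "PM25" not in data["surfaces"]:
        errors.append("no PM25 exposure surface")
    else:
        surf = data["surfaces"]["PM25"]
        if np.nanmin(surf.values) < 0:
            errors.append("negative PM25 concentrations")
        n_missing = int(np.isnan(surf.values).sum())
        if n_missing:
            warnings.append(f"PM25 surface has {n_missing} missing ZIP-months")
        res_zips = set(data["residence"]["zip"].unique())
        missing_zips = res_zips - set(surf.zips.tolist())
        if missing_zips:
            errors.append(f"{len(missing_zips)} residence ZIPs lack exposure series")

    known_zips = set(data["zip_attrs"]["zip"])
    extra = set(data["residence"]["zip"].unique()) - known_zips
    if extra:
        errors.append(f"{len(extra)} residence ZIPs missing from zip_attributes")
    return {"errors": errors, "warnings": warnings, "n_errors": len(errors)}


# ---------------------------------------------------------------------------


def ses_levels_by_year(income: pd.DataFrame, years) -> pd.DataFrame:
    """Per-ZIP-year income tertile labels with the carry-forward imputation."""
    wide = income.pivot_table(index="zip", columns="year", values="income")
    completed = {}
    for z, row in wide.iterrows():
        completed[z] = impute_missing_income_years(
            {int(y): v for y, v in row.dropna().items()}
        )
    rows = []
    for yr in years:
        series = pd.Series({z: d.get(yr, np.nan) for z, d in completed.items()})
        labels = classify_ses_tertiles(series)
        rows.append(pd.DataFrame({"zip": labels.index, "year": yr, "ses": labels.to_numpy()}))
    return pd.concat(rows, ignore_index=True)


class AnalysisRun:
    """Prepared inputs and cached exposure covariates for one run."""

    def __init__(self, config: RunConfig, data: dict | None = None):
        self.config = config
        self.data = data or load_inputs(config.input_dir)
        self.cause_map = (
            CauseOfDeathMap.from_ranges(config.cause_ranges)
            if config.cause_ranges
            else CauseOfDeathMap.default()
        )
        self.cohort = self.data["cohort"]
        self.residence = self.data["residence"]
        self.surfaces = self.data["surfaces"]
        years = sorted(
            set(
                (self.cohort["follow_up_start"].min() // 12,
                 self.cohort["follow_up_end"].max() // 12)
            )
        )
        years = range(years[0], years[-1] + 1)
        self.ses = ses_levels_by_year(self.data["income"], years)
        self._cov_cache: dict = {}

    # -- exposure covariates -------------------------------------------------

    def pm12(self):
        if "pm12" not in self._cov_cache:
            self._cov_cache["pm12"] = expo.person_month_exposure(
                self.cohort, self.residence, self.surfaces["PM25"]
            )
        return self._cov_cache["pm12"]

    def no2_12(self):
        if "no2" not in self._cov_cache:
            self._cov_cache["no2"] = expo.person_month_exposure(
                self.cohort, self.residence, self.surfaces["NO2"]
            )
        return self._cov_cache["no2"]

    def nontraffic(self):
        """Stage-1 fit on ZIP-month 12-mo averages; residual applied per person-month."""
        if "nt" not in self._cov_cache:
            pm_surf, no2_surf = self.surfaces["PM25"], self.surfaces["NO2"]
            zm_pm = expo.moving_average_12(pm_surf.values)
            zm_no2 = expo.moving_average_12(no2_surf.values)
            model = expo.fit_residual_model(zm_pm.ravel(), zm_no2.ravel())
            pm_mat, start = self.pm12()
            no2_mat, _ = self.no2_12()
            self._cov_cache["nt"] = (
                model,
                (model.predict_residual(pm_mat, no2_mat), start),
            )
        return self._cov_cache["nt"]

    def ozone_covariate(self):
        """Warm-season average (by calendar year) as a ZIP-month-constant covariate."""
        if "o3" not in self._cov_cache:
            surf = self.surfaces["O3"]
            t0 = int(self.cohort["follow_up_start"].min())
            t1 = int(self.cohort["follow_up_end"].max())
            mat = np.full((len(surf.zips), t1 - t0 + 1), np.nan)
            for yr in range(t0 // 12, t1 // 12 + 1):
                try:
                    w = expo.warm_season_from_monthly(surf, yr).to_numpy()
                except expo.ExposureError:
                    continue
                cols = [m - t0 for m in range(yr * 12, yr * 12 + 12) if t0 <= m <= t1]
                mat[:, cols] = w[:, None]
            o3_surface = expo.ZipMonthSurface("O3_warm", surf.zips, t0, mat)
            self._cov_cache["o3"] = expo.person_month_exposure(
                self.cohort, self.residence, o3_surface, window=1
            )
        return self._cov_cache["o3"]

    # -- model building ------------------------------------------------------

    def _strata_and_ses(self, variant: str):
        if variant == "base":
            return ("age", "sex", "race", "zip"), None, []
        if variant in ("ses", "ozone"):
            if self.config.ses_mode == "strata":
                return ("age", "sex", "race", "zip", "ses"), self.ses, []
            return ("age", "sex", "race", "zip"), self.ses, ["ses_rank"]
        raise ValueError(f"unknown model variant {variant!r}")

    def _restrict(self, cohort, residence, zips_keep):
        keep_ids = (
            residence.groupby("id")["zip"]
            .apply(lambda z: np.isin(z, zips_keep).all())
        )
        ids = keep_ids[keep_ids].index
        return (
            cohort[cohort["id"].isin(ids)].reset_index(drop=True),
            residence[residence["id"].isin(ids)].reset_index(drop=True),
        )

    def monitor_zips(self):
        monitors = self.data.get("monitors")
        if monitors is None:
            raise expo.ExposureError("ozone-adjusted models need a monitors.csv input")
        return expo.monitor_subset(
            self.data["zip_attrs"], monitors, self.config.monitor_radius_miles
        )

    def expand(self, cause, variant="ses", exposure_kind="total",
               cohort=None, residence=None):
        """Person-month table for one matrix cell (shared by linear and spline fits)."""
        strata, ses, extra = self._strata_and_ses(variant)
        if exposure_kind == "total":
            mat, start = self.pm12()
            covs = {"pm25_12mo": mat}
        elif exposure_kind == "nontraffic":
            _, (mat, start) = self.nontraffic()
            covs = {"nontraffic_pm25_12mo": mat}
        else:
            raise ValueError(f"unknown exposure kind {exposure_kind!r}")
        if variant == "ozone":
            o3_mat, o3_start = self.ozone_covariate()
            lead = o3_start - start  # o3 matrix starts later than the exposure axis
            if lead > 0:
                o3_mat = np.pad(o3_mat, ((0, 0), (lead, 0)), constant_values=np.nan)
            elif lead < 0:
                o3_mat = o3_mat[:, -lead:]
            covs["o3_warm"] = o3_mat

        sub_cohort = cohort if cohort is not None else self.cohort
        sub_res = residence if residence is not None else self.residence
        if variant == "ozone":
            keep = self.monitor_zips()
            sub_cohort, sub_res = self._restrict(sub_cohort, sub_res, keep)

        if cohort is not None or variant == "ozone":
            # covariate matrices are aligned to the full cohort's rows
            rows = pd.Index(self.cohort["id"]).get_indexer(sub_cohort["id"])
            covs = {k: v[rows] for k, v in covs.items()}

        pm = expand_person_months(
            sub_cohort, sub_res, covs, start, cause,
            cause_map=self.cause_map, ses_levels=ses,
        )
        if "ses_rank" in extra:  # SES as ordinal adjustment covariate
            codes = pm.df["ses"].cat.codes.to_numpy(float)
            pm.df["ses_rank"] = codes
            pm.covariate_names.append("ses_rank")
        return pm, strata

    def fit_cell(self, cause, variant="ses", exposure_kind="total", **kw):
        pm, strata = self.expand(cause, variant, exposure_kind, **kw)
        cells = aggregate_cells(pm, strata=strata)
        fit = fit_cox(cells, tol=self.config.tol, max_iter=self.config.max_iter)
        return pm, fit


def _fit_record(cause, variant, exposure_kind, fit, extra=None):
    rr, (lo, hi) = rr_per_10(fit, 0)
    rec = {
        "cause": cause,
        "variant": variant,
        "exposure": exposure_kind,
        "rr_per_10": rr,
        "rr_lo95": lo,
        "rr_hi95": hi,
        "coef": float(fit.beta[0]),
        "se": float(fit.se[0]),
        "loglik": fit.loglik,
        "iterations": fit.iterations,
        "converged": bool(fit.converged),
        "n_events": fit.n_events,
        "n_person_months": fit.n_person_months,
        "n_cells": fit.n_cells,
        "n_risk_sets": fit.n_risk_sets,
    }
    if extra:
        rec.update(extra)
    return rec


def run_analysis(config: RunConfig, data: dict | None = None) -> dict:
    """Execute the requested matrix; write tables and a machine-readable summary."""
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = AnalysisRun(config, data)
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "fits": [],
        "failures": [],
        "outputs": [],
    }

    records = []
    for cause in config.causes:
        for variant in config.variants:
            for exposure_kind in config.exposures:
                try:
                    _, fit = run.fit_cell(cause, variant, exposure_kind)
                    records.append(_fit_record(cause, variant, exposure_kind, fit))
                except Exception as exc:  # cell-local failure
                    summary["failures"].append(
                        {"cell": [cause, variant, exposure_kind], "error": str(exc)}
                    )
    if records:
        rr_table = pd.DataFrame(records)
        rr_table.to_csv(out / "rr_table.csv", index=False)
        summary["outputs"].append("rr_table.csv")
        summary["fits"] = records

    # restriction analyses (SES-adjusted, total exposure)
    restr_records = []
    if config.restriction_thresholds:
        pm_surf = run.surfaces["PM25"]
        t0 = int(run.cohort["follow_up_start"].min())
        zip_means = pd.Series(
            pm_surf.values[:, t0 - pm_surf.start_month:].mean(axis=1),
            index=pm_surf.zips,
        )
        for thr in sorted(config.restriction_thresholds):
            keep = expo.restrict_low_pm(zip_means, thr)
            sub_c, sub_r = run._restrict(run.cohort, run.residence, keep)
            for cause in config.causes:
                try:
                    _, fit = run.fit_cell(
                        cause, "ses", "total", cohort=sub_c, residence=sub_r
                    )
                    restr_records.append(
                        _fit_record(cause, "ses", "total", fit,
                                    {"threshold": thr, "n_zips_kept": len(keep)})
                    )
                except Exception as exc:
                    summary["failures"].append(
                        {"cell": [cause, "restrict", thr], "error": str(exc)}
                    )
        if restr_records:
            pd.DataFrame(restr_records).to_csv(out / "restriction_table.csv", index=False)
            summary["outputs"].append("restriction_table.csv")
            summary["restrictions"] = restr_records

    # spline exposure-response curves
    curves = []
    for cause in config.spline_causes:
        try:
            pm, strata = run.expand(cause, "ses", "total")
            x = pm.df["pm25_12mo"].to_numpy()
            knots = (
                np.asarray(config.knot_override, float)
                if config.knot_override
                else place_knots(x, config.spline_knots)
            )
            basis = SplineBasis(knots)
            names = basis.names("pm25_12mo")
            b = basis(x)
            for j, nm in enumerate(names[1:], start=1):
                pm.df[nm] = b[:, j]
            cells = aggregate_cells(pm, strata=strata, covariates=names)
            fit = fit_cox(cells, tol=config.tol, max_iter=config.max_iter)
            grid = np.linspace(0, np.quantile(x, 0.995), 60)
            curve = rr_curve(fit, basis, grid).to_frame()
            curve.insert(0, "cause", cause)
            curves.append(curve)
            if config.make_figures:
                _plot_curve(curve, cause, out / f"curve_{cause}.png")
                summary["outputs"].append(f"curve_{cause}.png")
        except Exception as exc:
            summary["failures"].append({"cell": [cause, "spline"], "error": str(exc)})
    if curves:
        pd.concat(curves).to_csv(out / "rr_curves.csv", index=False)
        summary["outputs"].append("rr_curves.csv")

    # effect modification (first cause, SES-adjusted)
    if config.modifiers and config.causes:
        cause = config.causes[0]
        pm, strata = run.expand(cause, "ses", "total")
        urban_map = pd.Series(
            np.where(run.data["zip_attrs"]["urban"], "urban", "non-urban"),
            index=run.data["zip_attrs"]["zip"],
        )
        sub_tables = []
        for modifier in config.modifiers:
            try:
                if modifier == "urban":
                    attach_zip_attribute(pm, urban_map, "urban")
                if modifier == "age_group":
                    age_group_column(pm)
                eff = subgroup_rrs(
                    pm, "pm25_12mo", modifier, strata=strata,
                    tol=config.tol, max_iter=config.max_iter,
                )
                tab = eff.table.copy()
                tab.insert(0, "modifier", modifier)
                tab.insert(0, "cause", cause)
                sub_tables.append(tab)
            except Exception as exc:
                summary["failures"].append(
                    {"cell": [cause, "modification", modifier], "error": str(exc)}
                )
        if sub_tables:
            pd.concat(sub_tables).to_csv(out / "subgroup_table.csv", index=False)
            summary["outputs"].append("subgroup_table.csv")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _plot_curve(curve: pd.DataFrame, cause: str, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve["exposure"], curve["rr"], color="C0")
    ax.fill_between(
        curve["exposure"], curve["rr_lo95"], curve["rr_hi95"], alpha=0.25, color="C0"
    )
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xlabel("12-month average PM$_{2.5}$ (µg/m³)")
    ax.set_ylabel("RR vs 0 µg/m³")
    ax.set_title(cause)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
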