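"""Synthetic Medicare-like study generator.

Generates an open cohort of elderly beneficiaries (entry at the study start
or staggered later entry, exit at death or administrative censoring) living
in synthetic ZIP codes with correlated pollutant surfaces, and cause-specific
deaths from known stratified proportional hazards — so the whole analysis
pipeline is testable, with ground truth, without restricted data.

Exposure world
    Per-ZIP monthly PM2.5 is the sum of a *traffic* and a *non-traffic*
    component, each with an urbanicity-dependent ZIP mean plus AR(1)
    month-to-month noise; the non-traffic (secondary) component also carries
    the seasonal cycle. NO2 is an affine function of the traffic component
    plus autocorrelated noise whose scale is calibrated, from the realized
    component moments, so that corr(12-mo PM2.5, 12-mo NO2) hits its target
    (0.59 by default). Ozone couples to the secondary component the same way
    (target 0.24). Annual EC-like and sulfate-like tracers are proportional
    to the traffic and secondary components respectively.

Mortality world
    Death is simulated monthly: cause-specific hazards
    λ_c = share_c · h0(age, sex) · exp((β_c + δ_subgroup) · x) with x the
    beneficiary's trailing 12-month PM2.5 and β_c = ln(RR_c)/10. Monthly
    death probabilities are ≪ 1, so the discrete-time Bernoulli scheme
    agrees with the continuous-time proportional-hazards model to first
    order. The planted RRs default to the magnitudes reported for elderly
    US cohorts (e.g. 1.126 for IHD, 1.025 for all cancer per 10 µg/m³).

Every draw comes from one seeded generator: a seed fully determines the
study. Ground truth (all planted parameters) is emitted as a sidecar dict /
JSON file; recovery tests read truth only from the sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .causes import CauseOfDeathMap
from .cohort import write_cohort_csv
from .exposure import ZipMonthSurface, person_month_exposure
from .months import month_index, month_str

# disjoint generating ("leaf") causes: ICD ranges, share of total mortality,
# default planted RR per 10 µg/m³
LEAF_CAUSES: dict[str, dict] = {
    "ihd": {"ranges": ["I20-I25"], "share": 0.2000, "rr": 1.126},
    "cbv": {"ranges": ["I60-I69"], "share": 0.0720, "rr": 1.126},
    "chf": {"ranges": ["I50"], "share": 0.0296, "rr": 0.986},
    "cvd_other": {"ranges": ["I00-I19", "I26-I49", "I51-I59", "I70-I99"],
                  "share": 0.0984, "rr": 1.019},
    "copd": {"ranges": ["J40-J44"], "share": 0.05625, "rr": 1.023},
    "pneumonia": {"ranges": ["J12-J18"], "share": 0.02925, "rr": 1.078},
    "resp_other": {"ranges": ["J00-J11", "J19-J39", "J45-J99"],
                   "share": 0.0270, "rr": 1.056},
    "lung_cancer": {"ranges": ["C34"], "share": 0.0630, "rr": 0.995},
    "cancer_other": {"ranges": ["C00-C33", "C35-C97", "D00-D48"],
                     "share": 0.1620, "rr": 1.025},
    "other_nonacc": {"ranges": ["A00-B99", "D50-H95", "K00-R99"],
                     "share": 0.2000, "rr": 1.017},
    "accidental": {"ranges": ["V01-Y98"], "share": 0.0625, "rr": 0.998},
}


class CalibrationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Planted parameters of the synthetic study (the study conditions)."""

    n_beneficiaries: int = 50_000
    n_zips: int = 500
    study_start: str = "2000-01"
    n_months: int = 108

    # geography / urbanicity
    urban_fraction_zips: float = 0.45
    urban_fraction_beneficiaries: float = 0.74

    # exposure surfaces (12-mo PM2.5 pooled mean ~10.3 µg/m³, sd ~3.2).
    # The urban excess is traffic-driven; the secondary (non-traffic)
    # component has the same mean everywhere, as regional pollutants do.
    pm_mean_urban: float = 11.2
    pm_mean_nonurban: float = 8.0
    traffic_mean_urban: float = 4.5
    traffic_mean_nonurban: float = 1.2
    traffic_zip_sd: float = 1.6
    nontraffic_zip_sd: float = 1.4
    season_amplitude: float = 1.5
    # high persistence gives the slow multi-year drifts real surfaces show,
    # which is what survives 12-month averaging
    ar_rho: float = 0.97
    ar_sd_nontraffic: float = 1.30
    ar_sd_traffic: float = 0.40
    no2_base: float = 8.0
    no2_per_traffic: float = 2.2    # ppb per µg/m³ of traffic PM2.5
    no2_noise_rho: float = 0.95
    target_corr_pm_no2: float = 0.59
    o3_base: float = 40.0
    o3_per_secondary: float = 0.5   # ppb per µg/m³ of secondary PM2.5
    o3_season_amplitude: float = 8.0
    o3_noise_rho: float = 0.95
    target_corr_pm_o3: float = 0.24

    # annual tracers (arbitrary speciation-like units)
    ec_per_traffic: float = 0.9
    sulfate_per_secondary: float = 0.45
    tracer_noise_sd: float = 0.15

    # ZIP income (SES); the 2000 and 2003 survey years are withheld,
    # mimicking the gap the carry-forward rule exists for
    income_mean_urban: float = 52_000.0
    income_mean_nonurban: float = 38_000.0
    income_zip_sd: float = 9_000.0
    income_year_drift: float = 800.0
    income_missing_years: tuple = (2000, 2003)

    # cohort
    female_fraction: float = 0.56
    race_probs: dict = field(
        default_factory=lambda: {
            "White": 0.85, "Black": 0.08, "Hispanic": 0.04, "Asian": 0.02, "Other": 0.01
        }
    )
    prevalent_fraction: float = 0.60     # enrolled at the window start; the
    # rest age in or migrate in during follow-up, as Medicare turnover does
    entry_age_scale_years: float = 8.0   # truncated-exponential age-above-65 at entry
    entry_age_max: float = 105.0
    incident_age_scale_months: float = 24.0
    monthly_move_prob: float = 0.004  # ~5%/yr, typical elderly mobility

    # hazards
    base_monthly_hazard_65: float = 0.0011
    age_log_slope_per_year: float = 0.09
    male_hazard_mult: float = 1.35
    cause_shares: dict = field(
        default_factory=lambda: {c: v["share"] for c, v in LEAF_CAUSES.items()}
    )
    rr_per_10: dict = field(
        default_factory=lambda: {c: v["rr"] for c, v in LEAF_CAUSES.items()}
    )
    # additive log-RR (per 10 µg/m³) for members of a subgroup, "col:level"
    subgroup_modifiers: dict = field(default_factory=lambda: {"race:Black": 0.056})
    # optional non-linear truth: the log-hazard slope in exposure changes by
    # ``slope_change_ratio`` above ``slope_change_threshold`` µg/m³
    slope_change_threshold: float | None = None
    slope_change_ratio: float = 1.0
    # optional component-specific truth: the traffic share of PM2.5 carries
    # ``traffic_effect_multiplier`` times the per-µg effect of the secondary
    # share (1.0 = the effect acts on total PM2.5)
    traffic_effect_multiplier: float = 1.0

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @property
    def start_index(self) -> int:
        return month_index(self.study_start)

    def validate(self):
        if abs(sum(self.cause_shares.values()) - 1.0) > 1e-9:
            raise CalibrationError("cause shares must sum to 1")
        if not 0 < self.urban_fraction_zips < 1:
            raise CalibrationError("urban_fraction_zips must be in (0,1)")
        # p = 1 - exp(-h) < 1 always; still reject worlds where a typical
        # 90-year-old would face an implausible monthly hazard
        typical = (
            self.base_monthly_hazard_65
            * np.exp(self.age_log_slope_per_year * 25)
            * self.male_hazard_mult
            * max(np.exp(np.log(max(self.rr_per_10.values())) / 10 * 20), 1)
        )
        if typical >= 0.5:
            raise CalibrationError("hazard settings imply implausible monthly hazards")


@dataclass
class SyntheticStudy:
    """A complete generated study plus its ground-truth sidecar."""

    cohort: pd.DataFrame
    residence: pd.DataFrame
    surfaces: dict  # pollutant -> ZipMonthSurface (PM25, NO2, O3)
    components: dict  # "traffic"/"secondary" ZipMonthSurface (latent, for tests)
    zip_attrs: pd.DataFrame  # zip, urban, lat, lon
    income: pd.DataFrame  # zip, year, income (missing years absent)
    tracers: pd.DataFrame  # zip, year, species, value
    monitors: pd.DataFrame  # monitor, lat, lon
    truth: dict

    def write(self, outdir):
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(
            self.cohort, self.residence, out / "cohort.csv", out / "residence.csv"
        )
        pd.concat([s.to_long() for s in self.surfaces.values()]).to_csv(
            out / "exposure.csv", index=False
        )
        self.zip_attrs.to_csv(out / "zip_attributes.csv", index=False)
        self.income.to_csv(out / "zip_income.csv", index=False)
        self.tracers.to_csv(out / "tracers.csv", index=False)
        self.monitors.to_csv(out / "monitors.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# exposure surfaces


def _ar1(rng, shape, rho, sd):
    """Stationary AR(1) noise along the last axis with stationary sd ``sd``."""
    n_t = shape[-1]
    innov_sd = sd * np.sqrt(1 - rho**2)
    out = np.empty(shape)
    out[..., 0] = rng.normal(0, sd, shape[:-1])
    eps = rng.normal(0, innov_sd, shape[:-1] + (n_t - 1,))
    for t in range(1, n_t):
        out[..., t] = rho * out[..., t - 1] + eps[..., t - 1]
    return out


def _trailing12(values):
    from .exposure import moving_average_12

    return moving_average_12(values)


def _calibrated_noise(u, PM, comp, pm12, comp12, u12, gain, target_r):
    """Noise series λ·u' such that corr(pm12, base + gain·comp12 + noise12) = target.

    The raw noise u is first orthogonalized (in sample, via its 12-month
    averages) against PM and the component — trailing averaging is linear,
    so subtracting the fitted monthly combination orthogonalizes the
    averaged series exactly. The scale λ then follows in closed form from
    the realized second moments. Unattainable targets (the component
    explains less of PM2.5 than the target correlation requires) raise.
    """
    mask = np.isfinite(pm12) & np.isfinite(u12) & np.isfinite(comp12)
    P, T, U = pm12[mask], comp12[mask], u12[mask]
    Z = np.column_stack([np.ones_like(P), P, T])
    coef, *_ = np.linalg.lstsq(Z, U, rcond=None)
    u_perp = u - coef[0] - coef[1] * PM - coef[2] * comp
    U_perp = U - Z @ coef
    vP, vT, vU = np.var(P), np.var(T), np.var(U_perp)
    cPT = np.cov(P, T)[0, 1]
    num = cPT**2 / (target_r**2 * vP) - vT
    if num <= 0:
        raise CalibrationError(
            f"correlation target {target_r} unattainable: the component "
            f"explains too little of PM2.5 (max corr "
            f"{abs(cPT) / np.sqrt(vP * vT):.2f})"
        )
    lam = gain * np.sqrt(num / vU)
    return lam * u_perp, float(lam)


def simulate_exposures(config: SimulationConfig, rng) -> tuple[dict, dict, pd.DataFrame]:
    """Generate PM2.5/NO2/O3 surfaces, latent components and annual tracers.

    Surfaces start 11 months before the study window so that trailing
    12-month averages exist from the first study month.
    """
    n_z = config.n_zips
    ext = 11
    n_t = config.n_months + ext
    start = config.start_index - ext
    months = start + np.arange(n_t)

    zips = np.arange(10001, 10001 + n_z)
    n_urban = int(round(n_z * config.urban_fraction_zips))
    urban = np.zeros(n_z, bool)
    urban[rng.permutation(n_z)[:n_urban]] = True

    class_mean = np.where(urban, config.pm_mean_urban, config.pm_mean_nonurban)
    class_mean_T = np.where(
        urban, config.traffic_mean_urban, config.traffic_mean_nonurban
    )

    # a finite-ZIP draw can leave the traffic component with too little
    # variance for the correlation target: reject and redraw (deterministic
    # given the seed), erroring only when the target is structurally out of
    # reach for this configuration
    last_err = None
    for _attempt in range(10):
        try:
            mean_T = np.maximum(rng.normal(class_mean_T, config.traffic_zip_sd), 0.2)
            mean_N = np.maximum(
                rng.normal(class_mean - class_mean_T, config.nontraffic_zip_sd), 1.0
            )

            phase = rng.normal(0, 1.0, n_z)
            season = config.season_amplitude * np.cos(
                2 * np.pi * (months[None, :] - phase[:, None]) / 12.0
            )
            N = mean_N[:, None] + season + _ar1(
                rng, (n_z, n_t), config.ar_rho, config.ar_sd_nontraffic
            )
            T = mean_T[:, None] + _ar1(
                rng, (n_z, n_t), config.ar_rho, config.ar_sd_traffic
            )
            N, T = np.maximum(N, 0.0), np.maximum(T, 0.0)
            PM = T + N

            study_cols = slice(ext, None)
            pm12 = _trailing12(PM)[:, study_cols]
            t12 = _trailing12(T)[:, study_cols]
            n12 = _trailing12(N)[:, study_cols]

            u = _ar1(rng, (n_z, n_t), config.no2_noise_rho, 1.0)
            u12 = _trailing12(u)[:, study_cols]
            noise, lam = _calibrated_noise(
                u, PM, T, pm12, t12, u12,
                config.no2_per_traffic, config.target_corr_pm_no2,
            )

            uo = _ar1(rng, (n_z, n_t), config.o3_noise_rho, 1.0)
            uo12 = _trailing12(uo)[:, study_cols]
            noise_o, lam_o = _calibrated_noise(
                uo, PM, N, pm12, n12, uo12,
                config.o3_per_secondary, config.target_corr_pm_o3,
            )
            break
        except CalibrationError as err:
            last_err = err
    else:
        raise last_err
    NO2 = np.maximum(config.no2_base + config.no2_per_traffic * T + noise, 0.0)
    o3_season = config.o3_season_amplitude * np.cos(
        2 * np.pi * (months[None, :] % 12 - 6.5) / 12.0
    )
    O3 = np.maximum(
        config.o3_base + o3_season + config.o3_per_secondary * N + noise_o, 0.0
    )

    surfaces = {
        "PM25": ZipMonthSurface("PM25", zips, start, PM),
        "NO2": ZipMonthSurface("NO2", zips, start, NO2),
        "O3": ZipMonthSurface("O3", zips, start, O3),
    }
    components = {
        "traffic": ZipMonthSurface("traffic", zips, start, T),
        "secondary": ZipMonthSurface("secondary", zips, start, N),
    }

    # annual tracers from the latent components (study years only)
    years = np.unique(months[ext:] // 12)
    rows = []
    for yr in years:
        cols = np.isin(months, np.arange(yr * 12, yr * 12 + 12))
        ec = config.ec_per_traffic * T[:, cols].mean(axis=1) + rng.normal(
            0, config.tracer_noise_sd, n_z
        )
        so4 = config.sulfate_per_secondary * N[:, cols].mean(axis=1) + rng.normal(
            0, config.tracer_noise_sd, n_z
        )
        rows.append(pd.DataFrame({"zip": zips, "year": yr, "species": "ec", "value": ec}))
        rows.append(
            pd.DataFrame({"zip": zips, "year": yr, "species": "sulfate", "value": so4})
        )
    tracers = pd.concat(rows, ignore_index=True)

    lat = rng.uniform(25.0, 48.0, n_z)
    lon = rng.uniform(-124.0, -67.0, n_z)
    zip_attrs = pd.DataFrame(
        {"zip": zips, "urban": urban, "lat": lat, "lon": lon}
    )

    # ozone monitors near ~30% of ZIP centroids (within the 6-mile subset rule)
    n_mon = max(int(0.3 * n_z), 1)
    mon_idx = rng.permutation(n_z)[:n_mon]
    monitors = pd.DataFrame(
        {
            "monitor": np.arange(n_mon),
            "lat": lat[mon_idx] + rng.normal(0, 0.02, n_mon),
            "lon": lon[mon_idx] + rng.normal(0, 0.02, n_mon),
        }
    )

    meta = {"noise_scale_no2": lam, "noise_scale_o3": lam_o}
    return surfaces | {"_meta": meta}, components, (zip_attrs, tracers, monitors)


def simulate_income(config: SimulationConfig, zip_attrs: pd.DataFrame, rng) -> pd.DataFrame:
    years = np.arange(
        config.start_index // 12, (config.start_index + config.n_months - 1) // 12 + 1
    )
    urban = zip_attrs["urban"].to_numpy()
    base = rng.normal(
        np.where(urban, config.income_mean_urban, config.income_mean_nonurban),
        config.income_zip_sd,
    ).clip(12_000)
    # a survey year is withheld only when its carry-forward donor exists
    donors = {2000: 2001, 2003: 2004}
    withheld = {
        y for y in config.income_missing_years if donors.get(y, y + 1) in years
    }
    rows = []
    for i, yr in enumerate(years):
        if int(yr) in withheld:
            continue
        noise = rng.normal(0, 500.0, len(base))
        rows.append(
            pd.DataFrame(
                {
                    "zip": zip_attrs["zip"],
                    "year": int(yr),
                    "income": base + config.income_year_drift * i + noise,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(
    config: SimulationConfig, surfaces: dict, zip_attrs: pd.DataFrame, rng,
    components: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate beneficiaries, residence paths and cause-specific deaths."""
    n = config.n_beneficiaries
    t0, n_t = config.start_index, config.n_months
    window_end = t0 + n_t - 1

    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    races = list(config.race_probs)
    race = rng.choice(races, n, p=np.array(list(config.race_probs.values())))

    prevalent = rng.random(n) < config.prevalent_fraction
    entry = np.where(
        prevalent, t0, t0 + rng.integers(1, max(n_t - 12, 2), n)
    ).astype(int)
    extra_years = np.minimum(
        rng.exponential(config.entry_age_scale_years, n), config.entry_age_max - 65
    )
    age_at_entry_months = np.where(
        prevalent,
        (65 + extra_years) * 12,
        65 * 12 + np.minimum(rng.exponential(config.incident_age_scale_months, n), 240),
    ).astype(int)
    birth = entry - age_at_entry_months

    urban_zips = zip_attrs.loc[zip_attrs["urban"], "zip"].to_numpy()
    rural_zips = zip_attrs.loc[~zip_attrs["urban"], "zip"].to_numpy()
    in_urban = rng.random(n) < config.urban_fraction_beneficiaries
    zip0 = np.where(
        in_urban,
        rng.choice(urban_zips, n),
        rng.choice(rural_zips, n),
    )

    # residential moves
    move_mask = rng.random((n, n_t)) < config.monthly_move_prob
    move_mask[:, 0] = False
    movers, move_cols = np.nonzero(move_mask)
    all_zips = zip_attrs["zip"].to_numpy()
    new_zips = rng.choice(all_zips, len(movers))
    seg = pd.DataFrame(
        {
            "id": np.r_[np.arange(n), movers],
            "start_month": np.r_[entry, t0 + move_cols],
            "zip": np.r_[zip0, new_zips],
        }
    )
    seg = seg[(seg["start_month"] >= np.r_[entry, entry[movers]])]
    residence = (
        seg.drop_duplicates(["id", "start_month"], keep="last")
        .sort_values(["id", "start_month"])
        .reset_index(drop=True)
    )

    draft = pd.DataFrame(
        {
            "id": np.arange(n),
            "birth_month": birth,
            "sex": sex,
            "race": race,
            "follow_up_start": entry,
            "follow_up_end": window_end,
            "death_month": np.nan,
            "icd10_cause": pd.array([None] * n, dtype="string"),
        }
    )

    x_mat, x_start = person_month_exposure(draft, residence, surfaces["PM25"])
    cols = slice(t0 - x_start, t0 - x_start + n_t)
    x = x_mat[:, cols]  # (n, n_t) trailing 12-mo PM2.5 in study months

    # effective exposure driving the hazard
    x_eff = x
    if config.traffic_effect_multiplier != 1.0:
        if components is None:
            raise CalibrationError(
                "traffic_effect_multiplier needs the latent component surfaces"
            )
        t_mat, _ = person_month_exposure(draft, residence, components["traffic"])
        x_t = t_mat[:, cols]
        x_eff = (x - x_t) + config.traffic_effect_multiplier * x_t
    if config.slope_change_threshold is not None:
        thr = config.slope_change_threshold
        x_eff = np.minimum(x_eff, thr) + config.slope_change_ratio * np.maximum(
            x_eff - thr, 0.0
        )

    months = t0 + np.arange(n_t)
    age_years = (months[None, :] - birth[:, None]) // 12
    h0 = (
        config.base_monthly_hazard_65
        * np.exp(config.age_log_slope_per_year * (age_years - 65))
        * np.where(sex == "M", config.male_hazard_mult, 1.0)[:, None]
    )

    delta = np.zeros(n)
    for key, add in config.subgroup_modifiers.items():
        col, level = key.split(":")
        vals = {"sex": sex, "race": race}.get(col)
        if vals is None:
            member = np.isin(zip0, zip_attrs.loc[zip_attrs[col], "zip"].to_numpy())
        else:
            member = vals == level
        delta = delta + np.where(member, add / 10.0, 0.0)

    causes = list(config.cause_shares)
    shares = np.array([config.cause_shares[c] for c in causes])
    betas = np.array([np.log(config.rr_per_10[c]) / 10.0 for c in causes])

    mix = np.zeros((n, n_t))
    for s_c, b_c in zip(shares, betas):
        mix += s_c * np.exp(b_c * x_eff)
    total_hazard = h0 * np.exp(delta[:, None] * x_eff) * mix
    p_death = 1.0 - np.exp(-total_hazard)

    at_risk = months[None, :] >= entry[:, None]
    dies = (rng.random((n, n_t)) < p_death) & at_risk
    any_death = dies.any(axis=1)
    first = np.argmax(dies, axis=1)

    death_month = np.where(any_death, t0 + first, -1)
    cohort = draft.copy()
    cohort.loc[any_death, "death_month"] = death_month[any_death].astype(float)
    cohort["follow_up_end"] = np.where(any_death, death_month, window_end)

    # sample the cause for each death, proportional to its hazard that month
    cmap = CauseOfDeathMap.from_ranges({c: LEAF_CAUSES[c]["ranges"] for c in causes})
    roots = {c: cmap.roots_in(c) for c in causes}
    idx = np.flatnonzero(any_death)
    xd = x_eff[idx, first[idx]]
    weights = shares[None, :] * np.exp(betas[None, :] * xd[:, None])
    weights /= weights.sum(axis=1, keepdims=True)
    cum = np.cumsum(weights, axis=1)
    pick = (rng.random(len(idx))[:, None] > cum).sum(axis=1)
    codes = [
        roots[causes[k]][rng.integers(len(roots[causes[k]]))] for k in pick
    ]
    cohort.loc[idx, "icd10_cause"] = codes

    # trim residence segments past follow-up end
    end_by_id = cohort.set_index("id")["follow_up_end"]
    residence = residence[
        residence["start_month"].to_numpy()
        <= end_by_id[residence["id"]].to_numpy()
    ].reset_index(drop=True)

    truth = {
        "rr_per_10": dict(config.rr_per_10),
        "cause_shares": dict(config.cause_shares),
        "subgroup_modifiers": dict(config.subgroup_modifiers),
        "leaf_ranges": {c: LEAF_CAUSES[c]["ranges"] for c in causes},
        "slope_change_threshold": config.slope_change_threshold,
        "slope_change_ratio": config.slope_change_ratio,
        "traffic_effect_multiplier": config.traffic_effect_multiplier,
        "n_deaths": int(any_death.sum()),
    }
    return cohort, residence, truth


def homogeneous_group_rr(config: SimulationConfig, cause: str,
                         cause_map: CauseOfDeathMap | None = None) -> float | None:
    """Planted RR for a cause *group*, defined only when every leaf cause the
    group contains carries the same planted RR (and no modifiers apply)."""
    cause_map = cause_map or CauseOfDeathMap.default()
    member_rrs = {
        config.rr_per_10[leaf]
        for leaf, spec in LEAF_CAUSES.items()
        if any(cause_map.contains(cause, root) for root in [spec["ranges"][0].split("-")[0]])
    }
    return member_rrs.pop() if len(member_rrs) == 1 else None


def simulate_study(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate the full study: surfaces, cohort, attributes, truth sidecar."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    surfaces, components, (zip_attrs, tracers, monitors) = simulate_exposures(config, rng)
    meta = surfaces.pop("_meta")
    income = simulate_income(config, zip_attrs, rng)
    cohort, residence, truth = simulate_cohort(
        config, surfaces, zip_attrs, rng, components=components
    )
    truth.update(
        {
            "seed": int(seed),
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "calibration": meta,
        }
    )
    return SyntheticStudy(
        cohort=cohort,
        residence=residence,
        surfaces=surfaces,
        components=components,
        zip_attrs=zip_attrs,
        income=income,
        tracers=tracers,
        monitors=monitors,
        truth=truth,
    )
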