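"""Effect modification via exposure × subgroup interaction terms.

Subgroup exposure effects are estimated in a single joint fit: the design
contains the exposure plus one interaction column x·1[level] per non-reference
level of the modifier. Because every candidate modifier (age group, sex,
race, urbanicity, SES tertile) is already part of — or constant within — the
baseline-hazard strata, no main-effect terms are needed: they are absorbed
by stratification. The level-specific slope is β_main + γ_level, and its
per-10 µg/m³ RR confidence interval propagates the joint covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import (
    CoxFit,
    EngineError,
    PersonMonthTable,
    aggregate_cells,
    fit_cox,
    DEFAULT_STRATA,
)


@dataclass
class SubgroupEffects:
    """Per-level RRs per 10 µg/m³ from one joint interaction fit."""

    modifier: str
    reference: str
    table: pd.DataFrame  # level, rr, lo95, hi95, n_events, gamma, gamma_se
    fit: CoxFit


def attach_zip_attribute(pm: PersonMonthTable, values: pd.Series, name: str) -> None:
    """Join a per-ZIP attribute (e.g. urbanicity) onto the person-month table."""
    pm.df[name] = pd.Categorical(values.reindex(pm.df["zip"]).to_numpy())


def age_group_column(pm: PersonMonthTable, breaks=(75, 85), name: str = "age_group") -> None:
    """Coarse attained-age groups (e.g. 65-74 / 75-84 / 85+) for modification."""
    edges = [64] + list(breaks) + [200]
    labels = [
        f"{lo + 1}-{hi}" if hi < 200 else f"{lo + 1}+" for lo, hi in zip(edges, edges[1:])
    ]
    pm.df[name] = pd.cut(pm.df["age"], bins=edges, labels=labels)


def subgroup_rrs(
    pm: PersonMonthTable,
    exposure: str,
    modifier: str,
    strata: tuple[str, ...] = DEFAULT_STRATA,
    reference: str | None = None,
    extra_covariates: list[str] | None = None,
    **fit_kwargs,
) -> SubgroupEffects:
    """Joint interaction fit; one RR (with CI) per level of ``modifier``.

    The reference level (default: most person-months) carries γ ≡ 0, so its
    RR is exp(10·β_main). Levels with zero events are flagged and reported
    without an RR.
    """
    df = pm.df
    if modifier not in df.columns:
        raise EngineError(f"modifier column {modifier!r} not in person-month table")
    counts = df[modifier].value_counts()
    levels = [lv for lv in counts.index.tolist() if counts[lv] > 0]
    if reference is None:
        reference = levels[0]  # value_counts sorts by frequency
    ordered = [reference] + sorted(str(l) for l in levels if str(l) != str(reference))

    events_per_level = df.groupby(modifier, observed=True)["event"].sum()
    x = df[exposure].to_numpy(float)
    inter_names = []
    for lv in ordered[1:]:
        if events_per_level.get(lv, 0) == 0:
            continue
        col = f"{exposure}:{modifier}={lv}"
        df[col] = x * (df[modifier].astype(str) == lv)
        inter_names.append(col)

    from .engine import RankDeficiencyError

    created = list(inter_names)
    inestimable: list[str] = []
    while True:
        covs = [exposure] + inter_names + list(extra_covariates or [])
        cells = aggregate_cells(pm, strata=strata, covariates=covs)
        try:
            fit = fit_cox(cells, **fit_kwargs)
            break
        except RankDeficiencyError as exc:
            # a level whose events all sit in no-contrast risk sets is
            # inestimable: drop its interaction term and report it as such
            drop = [c for c in exc.aliased if c in inter_names]
            if not drop:
                raise
            inter_names = [c for c in inter_names if c not in drop]
            inestimable += [c.split("=", 1)[1] for c in drop]
    if not fit.converged:
        raise EngineError("joint interaction fit did not converge")

    rows = []
    b_main = fit.beta[0]
    v_main = fit.cov[0, 0]
    for lv in ordered:
        n_ev = int(events_per_level.get(lv, 0))
        if lv != reference and (n_ev == 0 or str(lv) in inestimable):
            rows.append(
                {"level": lv, "rr": np.nan, "lo95": np.nan, "hi95": np.nan,
                 "n_events": n_ev, "gamma": np.nan, "gamma_se": np.nan,
                 "note": "no events" if n_ev == 0 else "no informative events"}
            )
            continue
        if lv == reference:
            slope, var, gamma, g_se = b_main, v_main, 0.0, 0.0
        else:
            j = fit.covariate_names.index(f"{exposure}:{modifier}={lv}")
            slope = b_main + fit.beta[j]
            var = v_main + fit.cov[j, j] + 2 * fit.cov[0, j]
            gamma, g_se = fit.beta[j], np.sqrt(fit.cov[j, j])
        se = np.sqrt(var)
        rows.append(
            {
                "level": lv,
                "rr": np.exp(10 * slope),
                "lo95": np.exp(10 * (slope - 1.96 * se)),
                "hi95": np.exp(10 * (slope + 1.96 * se)),
                "n_events": n_ev,
                "gamma": gamma,
                "gamma_se": g_se,
                "note": "reference" if lv == reference else "",
            }
        )
    # clean interaction columns off the shared frame
    df.drop(columns=created, inplace=True)
    return SubgroupEffects(modifier, str(reference), pd.DataFrame(rows), fit)
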