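"""Restricted-cubic-spline exposure-response curve with a 0 µg/m³ reference.

Fits a 3-knot RCS to the PM2.5-mortality association, compares it with 4-
and 5-knot candidates by AIC, and prints the RR curve against a zero
reference — the shape analysis used to ask whether low exposures still
carry risk and whether there is any threshold.
"""

import numpy as np

from pmcox import SimulationConfig, simulate_study
from pmcox.engine import aggregate_cells, expand_person_months, fit_cox
from pmcox.exposure import person_month_exposure
from pmcox.splines import SplineBasis, compare_knot_counts, place_knots, rr_curve

config = SimulationConfig(n_beneficiaries=15_000, n_zips=60, subgroup_modifiers={})
# a strong linear truth (RR 1.5 per 10 µg/m³ for every non-accidental cause)
# so the fitted shape is visible at desk scale
config = config.replace(
    rr_per_10={c: (1.5 if c != "accidental" else 1.0) for c in config.rr_per_10}
)
study = simulate_study(config, seed=3)
mat, start = person_month_exposure(study.cohort, study.residence, study.surfaces["PM25"])
pm = expand_person_months(study.cohort, study.residence, {"x": mat}, start, "non_accidental")
x = pm.df["x"].to_numpy()


def fit_with(basis: SplineBasis):
    names = basis.names("x")
    b = basis(x)
    for j, nm in enumerate(names[1:], start=1):
        pm.df[nm] = b[:, j]
    fit = fit_cox(aggregate_cells(pm, covariates=names))
    pm.df.drop(columns=names[1:], inplace=True)
    return fit


report = compare_knot_counts(fit_with, x, m_list=(3, 4, 5))
for m, cand in report["candidates"].items():
    print(f"m={m} knots at {np.round(cand['knots'], 1)}: AIC {cand['aic']:.1f}")
print(f"selected: {report['best_m']} knots (ties go to fewer)")

basis = SplineBasis(place_knots(x, report["best_m"]))
fit = fit_with(basis)
curve = rr_curve(fit, basis, grid=np.array([0.0, 5.0, 8.0, 10.0, 12.0, 15.0]))
print("\nRR vs 0 ug/m3 (pointwise 95% CI):")
for xi, rr, lo, hi in zip(curve.exposure, curve.rr, curve.lo95, curve.hi95):
    print(f"  {xi:5.1f} ug/m3  RR {rr:5.2f}  ({lo:.2f}, {hi:.2f})")
print("the curve is anchored at RR(0)=1; under the linear planted truth the"
      "\nlog-RR should rise roughly in proportion to exposure, with the linear"
      "\ntail extrapolating below the lowest observed exposures")
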