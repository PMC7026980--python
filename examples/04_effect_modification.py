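"""Effect modification: subgroup RRs from a single joint interaction fit.

Plants a larger PM2.5 effect for Black beneficiaries (RR 1.10 vs 1.04 per
10 µg/m³) and recovers per-race RRs from one stratified Cox fit with
exposure x race interaction terms; race main effects are absorbed by the
baseline-hazard strata.
"""

import numpy as np

from pmcox import SimulationConfig, simulate_study
from pmcox.effects import subgroup_rrs
from pmcox.engine import expand_person_months
from pmcox.exposure import person_month_exposure

delta = np.log(1.10) - np.log(1.04)
config = SimulationConfig(n_beneficiaries=25_000, n_zips=60)
rr = {c: (1.04 if c != "accidental" else 1.0) for c in config.rr_per_10}
config = config.replace(rr_per_10=rr, subgroup_modifiers={"race:Black": delta})

study = simulate_study(config, seed=88)
mat, start = person_month_exposure(study.cohort, study.residence, study.surfaces["PM25"])
pm = expand_person_months(
    study.cohort, study.residence, {"pm25_12mo": mat}, start, "non_accidental"
)
eff = subgroup_rrs(pm, "pm25_12mo", "race", reference="White")
print(f"modifier: {eff.modifier} (reference {eff.reference})")
cols = ["level", "rr", "lo95", "hi95", "n_events", "note"]
print(eff.table[cols].round(3).to_string(index=False))
print(
    "\nplanted: White RR 1.04, Black RR 1.10; each level's CI should cover its"
    "\ntruth — at this cohort size the subgroup CIs are wide, as they are in"
    "\nany desk-scale replication of an administrative-data analysis"
)
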