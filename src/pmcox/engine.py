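"""Stratified Cox proportional-hazards engine on grouped person-months.

The analysis unit is the person-month: one row per beneficiary per month at
risk, on a follow-up time axis (months since cohort entry). Baseline
hazards are stratified (age bin × sex × race × ZIP [× SES]), events are
cause-specific (death from any other cause censors that month), and ties —
which are massive at monthly resolution — are handled with the Breslow
approximation.

Breslow's partial likelihood depends on the data only through sufficient
statistics of each (stratum, follow-up time) risk set: the number of
person-months sharing each distinct covariate vector, and how many of those
are events. Compressing person-months into these *cells* is exact (not an
approximation) and is what makes billions of person-months tractable; here
it reduces a cohort by whatever factor the covariate resolution allows.

For cells c in risk set (s, t), with weight w_c (at-risk count), event
count e_c, d_st = Σ e_c, the contribution to the log partial likelihood is

    Σ_c e_c · βᵀx_c  −  d_st · log Σ_c w_c · exp(βᵀx_c)

with gradient and observed information accumulated analytically from the
weighted moments of x within the risk set. Risk sets with no events
contribute exactly zero and are dropped up front.

All reductions use fixed sequential/pairwise summation over a
deterministically sorted cell order, so results are bit-identical across
runs and degrees of parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import age_bin_code
from .causes import CauseOfDeathMap

DEFAULT_STRATA = ("age", "sex", "race", "zip")


class EngineError(ValueError):
    pass


class RankDeficiencyError(EngineError):
    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"singular information matrix; aliased covariates: {aliased}")


# ---------------------------------------------------------------------------
# person-month expansion


@dataclass
class PersonMonthTable:
    """Expanded person-month rows for one cause-specific model."""

    df: pd.DataFrame
    covariate_names: list[str]
    cause: str
    n_dropped_missing: int = 0

    @property
    def n_person_months(self) -> int:
        return len(self.df)

    @property
    def n_events(self) -> int:
        return int(self.df["event"].sum())


def expand_person_months(
    cohort: pd.DataFrame,
    residence: pd.DataFrame,
    covariates: dict[str, np.ndarray],
    cov_start_month: int,
    cause: str,
    cause_map: CauseOfDeathMap | None = None,
    ses_levels: pd.DataFrame | None = None,
    keep_ids: bool = False,
) -> PersonMonthTable:
    """Expand a cohort into one row per at-risk month.

    ``covariates`` maps covariate name -> (n_beneficiaries, n_months) matrix
    aligned to ``cov_start_month`` (see
    :func:`pmcox.exposure.person_month_exposure`); NaN entries mark missing
    exposure and drop the person-month from the risk set (counted in
    ``n_dropped_missing``). Events are evaluated cause-specifically: a death
    whose ICD-10 code falls outside ``cause`` censors at the death month.
    ``ses_levels`` (columns zip, year, ses) attaches a per-ZIP-year income
    tertile for SES-stratified or SES-adjusted models.
    """
    cause_map = cause_map or CauseOfDeathMap.default()
    start = cohort["follow_up_start"].to_numpy(int)
    end = cohort["follow_up_end"].to_numpy(int)
    if np.any(end < start):
        bad = cohort.loc[end < start, "id"].iloc[0]
        raise EngineError(f"beneficiary {bad!r}: follow-up end before start")

    lengths = end - start + 1
    n_rows = int(lengths.sum())
    rows = np.repeat(np.arange(len(cohort)), lengths)
    t = np.arange(n_rows) - np.repeat(np.cumsum(lengths) - lengths, lengths)
    cal = start[rows] + t

    died = cohort["death_month"].notna().to_numpy()
    codes = cohort["icd10_cause"].fillna("").to_numpy()
    is_cause = np.array(
        [bool(d) and cause_map.contains(cause, c) for d, c in zip(died, codes)]
    )
    event = (is_cause[rows] & (cal == end[rows])).astype(np.int8)

    # residence zip per person-month
    from .exposure import residence_zip_matrix

    zips_universe = np.sort(residence["zip"].unique())
    m0, m1 = int(cal.min()), int(cal.max())
    zmat = residence_zip_matrix(cohort, residence, zips_universe, m0, m1 - m0 + 1)
    zip_pm = zips_universe[zmat[rows, cal - m0]]

    birth = cohort["birth_month"].to_numpy(int)
    age_bin = age_bin_code(birth[rows], cal).astype(np.int16)

    df = pd.DataFrame(
        {
            "t": t.astype(np.int32),
            "calendar_month": cal.astype(np.int32),
            "age": age_bin,
            "sex": pd.Categorical(cohort["sex"].to_numpy()[rows]),
            "race": pd.Categorical(cohort["race"].to_numpy()[rows]),
            "zip": zip_pm,
            "event": event,
        }
    )
    if keep_ids:
        df.insert(0, "id", cohort["id"].to_numpy()[rows])

    names = list(covariates)
    for name, mat in covariates.items():
        df[name] = mat[rows, cal - cov_start_month]

    if ses_levels is not None:
        key = df["zip"].astype(np.int64) * 10000 + (df["calendar_month"] // 12)
        lut = pd.Series(
            ses_levels["ses"].to_numpy(),
            index=ses_levels["zip"].astype(np.int64) * 10000 + ses_levels["year"],
        )
        df["ses"] = pd.Categorical(lut.reindex(key).to_numpy())

    ok = np.ones(len(df), bool)
    for name in names:
        ok &= np.isfinite(df[name].to_numpy())
    dropped = int((~ok).sum())
    if dropped:
        df = df[ok].reset_index(drop=True)
    return PersonMonthTable(df, names, cause, dropped)


# ---------------------------------------------------------------------------
# aggregation into sufficient-statistic cells


def _combine_codes(arrays) -> np.ndarray:
    """Dense group codes for the tuple key formed by several arrays."""
    codes = None
    for arr in arrays:
        f, uniques = pd.factorize(arr, use_na_sentinel=False)
        if codes is None:
            codes = f.astype(np.int64)
        else:
            codes = codes * np.int64(len(uniques)) + f
            codes = pd.factorize(codes)[0].astype(np.int64)
    return codes


@dataclass
class CellData:
    """Aggregated sufficient statistics, sorted by (stratum, time) risk set.

    Only risk sets containing at least one event are stored: event-free
    risk sets contribute identically zero to the Breslow partial
    likelihood, its gradient and its information.
    """

    X: np.ndarray                 # (n_cells, p) covariate vectors
    w: np.ndarray                 # at-risk count per cell
    e: np.ndarray                 # event count per cell
    starts: np.ndarray            # first cell index of each risk set
    d: np.ndarray                 # events per risk set
    covariate_names: list[str]
    n_person_months: int = 0
    n_events_total: int = 0
    n_cells_total: int = 0
    n_strata: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.w)

    @property
    def n_risk_sets(self) -> int:
        return len(self.starts)

    def scale(self) -> np.ndarray:
        """Covariate half-range, used for divergence detection."""
        if self.X.shape[1] == 0:
            return np.empty(0)
        return np.maximum(0.5 * (self.X.max(axis=0) - self.X.min(axis=0)), 1e-300)


def aggregate_cells(
    pm: PersonMonthTable,
    strata: tuple[str, ...] = DEFAULT_STRATA,
    covariates: list[str] | None = None,
    rounding: int | None = None,
) -> CellData:
    """Compress person-months into (stratum, time, covariate-vector) cells.

    The compression is lossless for the Breslow partial likelihood.
    ``rounding`` optionally rounds covariates to a fixed number of decimals
    before keying (coarser cells, smaller table); the default keys on exact
    values, which is already maximally shared when covariates are ZIP-month
    quantities.
    """
    names = covariates if covariates is not None else pm.covariate_names
    df = pm.df
    X = df[names].to_numpy(float) if names else np.empty((len(df), 0))
    if rounding is not None:
        X = np.round(X, rounding)
    strat_codes = _combine_codes([df[c].to_numpy() for c in strata])
    t = df["t"].to_numpy()
    event = df["event"].to_numpy()
    return _build_cells(
        strat_codes, t, X, event, names, n_strata=int(strat_codes.max()) + 1
    )


def _build_cells(strat_codes, t, X, event, names, n_strata) -> CellData:
    n = len(t)
    cell_codes = _combine_codes([strat_codes, t] + [X[:, j] for j in range(X.shape[1])])
    order = np.argsort(cell_codes, kind="stable")
    sc = cell_codes[order]
    starts = np.flatnonzero(np.r_[True, sc[1:] != sc[:-1]])
    w = np.diff(np.r_[starts, n]).astype(float)
    e = np.add.reduceat(event[order].astype(float), starts)
    rep = order[starts]
    Xc, strat_c, t_c = X[rep], strat_codes[rep], t[rep]

    # sort cells into (stratum, time) risk sets
    g_order = np.lexsort((t_c, strat_c))
    Xc, w, e, strat_c, t_c = (a[g_order] for a in (Xc, w, e, strat_c, t_c))
    gkey = _combine_codes([strat_c, t_c])
    g_starts = np.flatnonzero(np.r_[True, gkey[1:] != gkey[:-1]])
    d = np.add.reduceat(e, g_starts)

    # drop event-free risk sets (exactly zero contribution)
    keep_group = d > 0
    cell_group = np.repeat(np.arange(len(g_starts)), np.diff(np.r_[g_starts, len(w)]))
    keep = keep_group[cell_group]
    Xk, wk, ek, gk = Xc[keep], w[keep], e[keep], cell_group[keep]
    new_starts = np.flatnonzero(np.r_[True, gk[1:] != gk[:-1]])

    return CellData(
        X=np.ascontiguousarray(Xk),
        w=wk,
        e=ek,
        starts=new_starts,
        d=d[keep_group],
        covariate_names=list(names),
        n_person_months=n,
        n_events_total=int(event.sum()),
        n_cells_total=len(w),
        n_strata=n_strata,
    )


def cells_from_raw(pm: PersonMonthTable, strata=DEFAULT_STRATA, covariates=None) -> CellData:
    """One cell per person-month (no compression) — the aggregation oracle."""
    names = covariates if covariates is not None else pm.covariate_names
    df = pm.df
    X = df[names].to_numpy(float) if names else np.empty((len(df), 0))
    strat_codes = _combine_codes([df[c].to_numpy() for c in strata])
    t = df["t"].to_numpy()
    event = df["event"].to_numpy()
    # unique row ids defeat cell sharing
    fake = np.arange(len(df), dtype=float)
    Xf = np.column_stack([X, fake])
    cells = _build_cells(
        strat_codes, t, Xf, event, list(names) + ["_row"], int(strat_codes.max()) + 1
    )
    return CellData(
        X=np.ascontiguousarray(cells.X[:, :-1]),
        w=cells.w,
        e=cells.e,
        starts=cells.starts,
        d=cells.d,
        covariate_names=list(names),
        n_person_months=cells.n_person_months,
        n_events_total=cells.n_events_total,
        n_cells_total=cells.n_cells_total,
        n_strata=cells.n_strata,
    )


# ---------------------------------------------------------------------------
# partial likelihood


def partial_loglik(cells: CellData, beta: np.ndarray):
    """Breslow log partial likelihood, gradient and observed information.

    Exponentials are guarded by a per-risk-set log-sum-exp shift, so the
    value is finite for any finite β.
    """
    beta = np.asarray(beta, float)
    if not np.all(np.isfinite(beta)):
        raise EngineError("non-finite beta")
    X, w, e, starts, d = cells.X, cells.w, cells.e, cells.starts, cells.d
    p = X.shape[1]
    if len(beta) != p:
        raise EngineError(f"beta has length {len(beta)}, expected {p}")

    # fixed column-wise accumulation: thread-count independent
    eta = np.zeros(len(w))
    for j in range(p):
        eta += X[:, j] * beta[j]

    m = np.maximum.reduceat(eta, starts)
    m_row = np.repeat(m, np.diff(np.r_[starts, len(w)]))
    z = w * np.exp(eta - m_row)
    s0 = np.add.reduceat(z, starts)

    value = float(np.sum(e * eta) - np.sum(d * (np.log(s0) + m)))

    s1 = np.empty((len(starts), p))
    for j in range(p):
        s1[:, j] = np.add.reduceat(z * X[:, j], starts)
    xbar = s1 / s0[:, None]
    grad = np.zeros(p)
    for j in range(p):
        grad[j] = np.sum(e * X[:, j]) - np.sum(d * xbar[:, j])

    info = np.empty((p, p))
    for j in range(p):
        for k in range(j, p):
            s2 = np.add.reduceat(z * X[:, j] * X[:, k], starts)
            info[j, k] = info[k, j] = np.sum(d * (s2 / s0 - xbar[:, j] * xbar[:, k]))

    if not np.isfinite(value):
        bad = int(np.flatnonzero(~np.isfinite(np.log(s0)))[0]) if np.any(s0 <= 0) else -1
        raise EngineError(f"non-finite partial likelihood (risk set {bad})")
    return value, grad, info


# ---------------------------------------------------------------------------
# Newton-Raphson fit


@dataclass
class CoxFit:
    """A fitted stratified Cox model."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    covariate_names: list[str]
    n_events: int
    n_person_months: int
    n_cells: int
    n_risk_sets: int
    n_strata: int
    monotone: bool = False
    loglik_null: float = float("nan")

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> pd.DataFrame:
        rr, lo, hi = np.exp(10 * self.beta), *_rr_bounds(self.beta, self.se)
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "rr_per_10": rr,
                "rr_lo95": lo,
                "rr_hi95": hi,
            },
            index=self.covariate_names,
        )


def _rr_bounds(beta, se):
    return np.exp(10 * (beta - 1.96 * se)), np.exp(10 * (beta + 1.96 * se))


MONOTONE_LINPRED_BOUND = 20.0  # |beta| * covariate half-range beyond which we call divergence


def fit_cox(
    cells: CellData,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    max_halvings: int = 10,
) -> CoxFit:
    """Newton–Raphson with step-halving on the grouped partial likelihood.

    Convergence: relative log-likelihood change below ``tol``. A monotone
    (divergent) likelihood — e.g. a covariate perfectly separating events —
    is detected by the linear predictor running away and is flagged rather
    than silently returned.
    """
    p = cells.X.shape[1]
    if cells.n_cells == 0 or len(cells.d) == 0:
        raise EngineError("no informative risk sets (no events)")
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    scale = cells.scale()

    ll, grad, info = partial_loglik(cells, beta)
    ll_null = ll if beta0 is None else partial_loglik(cells, np.zeros(p))[0]
    converged = False
    monotone = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = _solve_info(info, grad, cells.covariate_names)
        except RankDeficiencyError:
            if it > 1:
                # information collapsed along the divergence direction
                monotone = True
                break
            raise
        new_beta = beta + step
        new_ll, new_grad, new_info = partial_loglik(cells, new_beta)
        h = 0
        while new_ll < ll and h < max_halvings:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = partial_loglik(cells, new_beta)
            h += 1
        delta = new_ll - ll
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.max(np.abs(beta) * scale) > MONOTONE_LINPRED_BOUND:
            monotone = True
            break
        if abs(delta) <= tol * (abs(ll) + 1.0):
            converged = True
            break

    cov = np.linalg.inv(info) if converged else np.full((p, p), np.nan)
    return CoxFit(
        beta=beta,
        cov=cov,
        loglik=ll,
        iterations=it,
        converged=converged,
        covariate_names=list(cells.covariate_names),
        n_events=cells.n_events_total,
        n_person_months=cells.n_person_months,
        n_cells=cells.n_cells_total,
        n_risk_sets=cells.n_risk_sets,
        n_strata=cells.n_strata,
        monotone=monotone,
        loglik_null=ll_null,
    )


def _solve_info(info, grad, names):
    vals, vecs = np.linalg.eigh(info)
    if not np.all(np.isfinite(vals)) or vals.min() <= vals.max() * 1e-9 or vals.max() <= 0:
        null = vecs[:, vals <= max(vals.max(), 0.0) * 1e-9]
        aliased = [names[j] for j in np.flatnonzero((np.abs(null) > 1e-6).any(axis=1))]
        raise RankDeficiencyError(aliased or list(names))
    return vecs @ ((vecs.T @ grad) / vals)


def rr_per_10(fit: CoxFit, term: int | str = 0) -> tuple[float, tuple[float, float]]:
    """Risk ratio per 10 µg/m³ for one coefficient, with 95% CI."""
    if not fit.converged:
        raise EngineError("refusing to compute RRs from an unconverged fit")
    j = fit.covariate_names.index(term) if isinstance(term, str) else term
    b, s = fit.beta[j], fit.se[j]
    return float(np.exp(10 * b)), (
        float(np.exp(10 * (b - 1.96 * s))),
        float(np.exp(10 * (b + 1.96 * s))),
    )
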