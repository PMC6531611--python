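"""Two-level linear mixed models with AR(1) within-person errors.

The estimator is written for daily-diary panels: observations are days
nested in persons, the model is

    y_it = x_it' beta + u_i + e_it,
    u_i ~ N(0, sigma2_u),
    cov(e_it, e_is) = sigma2_e * rho^|d_it - d_is|,

where d is the scored day index, so a missing day widens the AR(1) gap.
The focal daily predictor enters twice, decomposed into a between-person
component (person mean centered at the sample mean of person means) and a
within-person component (daily deviation from the person mean).

Estimation maximizes the (restricted) Gaussian log-likelihood over the
three variance parameters with beta profiled out by GLS; persons sharing a
day-spacing pattern share one covariance factorization, so cohorts of
hundreds of persons with a week of days fit in milliseconds.  Standard
errors come from the GLS information matrix and p-values are Wald z
(no denominator-degrees-of-freedom correction is attempted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

SLEEP_OUTCOMES = ("onset_mc_h", "offset_h", "duration_min", "sme_pct")
PA_OUTCOMES = ("mvpa_min", "sedentary_min")

#: scale of each variable as a model term: hours, minutes or percent
VARIABLE_UNITS = {
    "onset_mc_h": "hours", "offset_h": "hours",
    "duration_min": "minutes", "sme_pct": "percent",
    "mvpa_min": "minutes", "sedentary_min": "minutes",
}

#: categorical covariates with the reference level listed first
CATEGORICAL_REFS = {
    "sex": "Female",
    "race": "White, non-Hispanic",
    "mother_education": "Less than High School",
    "family_structure": "Biomother + Biofather",
    "income_band": ">=300%",
}
NUMERIC_COVARIATES = ("age", "bmi_pct")


@dataclass(frozen=True)
class ModelSpec:
    """One model of the bidirectional suite."""

    outcome: str
    predictor: str
    direction: str                      # pa_to_sleep | sleep_to_pa
    covariates: tuple = ()              # covariate-table column names
    estimation: str = "ML"              # ML | REML

    def __post_init__(self):
        if self.direction not in ("pa_to_sleep", "sleep_to_pa"):
            raise ValueError("direction must be 'pa_to_sleep' or 'sleep_to_pa'")
        if self.estimation not in ("ML", "REML"):
            raise ValueError("estimation must be 'ML' or 'REML'")


@dataclass
class ModelFit:
    """Estimated fixed effects and variance components."""

    coef: pd.DataFrame                  # term, B, SE, p
    sigma2_u: float
    sigma2_e: float
    rho: float
    loglik: float
    n_obs: int
    n_participants: int
    estimation: str = "ML"
    converged: bool = True
    warnings: list = field(default_factory=list)

    def __getitem__(self, term: str) -> pd.Series:
        row = self.coef[self.coef["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]


# --- centering and panel construction -------------------------------------


def center(panel: pd.DataFrame, variable: str,
           person_col: str = "participant_id") -> tuple[pd.Series, pd.Series]:
    """Within/between decomposition of a daily variable.

    within = value - person mean (over that person's rows);
    between = person mean - sample mean of the person means.
    A person with a single day has within identically zero (kept).
    """
    pmean = panel.groupby(person_col)[variable].transform("mean")
    grand = panel.groupby(person_col)[variable].mean().mean()
    return pmean - grand, panel[variable] - pmean


def build_lagged_panel(table: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Model table for one temporal direction.

    ``sleep_to_pa`` keeps each person-day record as-is: the night's sleep
    predicts the following day's activity.  ``pa_to_sleep`` lags activity:
    a day's activity is paired with the *next* record's night sleep, so the
    first night of every person drops (no prior day) and non-consecutive
    records break pairs.  Rows with missing members are dropped.
    """
    if direction not in ("pa_to_sleep", "sleep_to_pa"):
        raise ValueError("direction must be 'pa_to_sleep' or 'sleep_to_pa'")
    df = table.copy()
    if "day_index" not in df.columns:
        if "cut_day" not in df.columns:
            raise ValueError("table needs a day_index or cut_day column")
        origin = df.groupby("participant_id")["cut_day"].transform("min")
        df["day_index"] = (
            (df["cut_day"].to_numpy("datetime64[D]") - origin.to_numpy("datetime64[D]"))
            .astype("timedelta64[D]").astype(int)
        )
    has_valid = "valid_pa" in df.columns
    df = df.sort_values(["participant_id", "day_index"]).reset_index(drop=True)
    sleep_ok = df[list(SLEEP_OUTCOMES)].notna().all(axis=1)
    act_ok = df[list(PA_OUTCOMES)].notna().all(axis=1)
    if has_valid:
        act_ok &= df["valid_pa"].astype(bool)

    cols = ["participant_id", "day_index", "weekend"] + list(SLEEP_OUTCOMES) + list(PA_OUTCOMES)
    if direction == "sleep_to_pa":
        df["weekend"] = df["weekend_day"] if "weekend_day" in df.columns else df["weekend"]
        out = df[sleep_ok & act_ok]
        return out[cols].reset_index(drop=True)

    g = df.groupby("participant_id")
    nxt = g[["day_index", "weekend_night" if "weekend_night" in df.columns else "weekend",
             *SLEEP_OUTCOMES]].shift(-1)
    nxt.columns = ["next_day_index", "next_weekend", *SLEEP_OUTCOMES]
    pair_ok = (
        act_ok
        & (nxt["next_day_index"] - df["day_index"] == 1)
        & nxt[list(SLEEP_OUTCOMES)].notna().all(axis=1)
    )
    out = pd.concat(
        [df[["participant_id"] + list(PA_OUTCOMES)], nxt], axis=1
    )[pair_ok]
    out = out.rename(columns={"next_day_index": "day_index", "next_weekend": "weekend"})
    out["day_index"] = out["day_index"].astype(int)
    return out[cols].reset_index(drop=True)


def build_design(panel: pd.DataFrame, spec: ModelSpec,
                 covariates: pd.DataFrame | None = None):
    """Design matrix with intercept, covariate dummies, weekend, and the
    between/within components of the focal predictor."""
    df = panel.copy()
    if covariates is not None and len(spec.covariates) > 0:
        df = df.merge(covariates, on="participant_id", how="left", validate="m:1")
    between, within = center(df, spec.predictor)
    terms, columns = ["Intercept"], [np.ones(len(df))]
    for cov in spec.covariates:
        if cov in CATEGORICAL_REFS:
            ref = CATEGORICAL_REFS[cov]
            for level in sorted(df[cov].dropna().unique()):
                if level == ref:
                    continue
                terms.append(f"{cov}[{level}]")
                columns.append((df[cov] == level).to_numpy(float))
        else:
            terms.append(cov)
            columns.append(df[cov].to_numpy(float))
    terms.append("weekend")
    columns.append(df["weekend"].to_numpy(float))
    terms.append(f"{spec.predictor} (between)")
    columns.append(between.to_numpy(float))
    terms.append(f"{spec.predictor} (within)")
    columns.append(within.to_numpy(float))
    X = np.column_stack(columns)
    y = df[spec.outcome].to_numpy(float)
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    return (X[keep], y[keep], df.loc[keep, "participant_id"].to_numpy(),
            df.loc[keep, "day_index"].to_numpy(int), terms)


# --- likelihood -----------------------------------------------------------


def _group_by_pattern(X, y, person, day):
    """Group persons by their relative day-spacing pattern.

    Returns a list of (D, Xg, Yg) where D is the |d_i - d_j| matrix shared
    by the group, Xg stacks the members' design blocks (m, d, p) and Yg
    their outcomes (m, d)."""
    order = np.lexsort((day, person))
    X, y, person, day = X[order], y[order], person[order], day[order]
    groups: dict[tuple, list] = {}
    _, starts = np.unique(person, return_index=True)
    starts = np.sort(starts)
    bounds = np.r_[starts, len(person)]
    for a, b in zip(bounds[:-1], bounds[1:]):
        key = tuple(day[a:b] - day[a])
        groups.setdefault(key, []).append((X[a:b], y[a:b]))
    out = []
    for key, members in groups.items():
        d = np.asarray(key)
        D = np.abs(d[:, None] - d[None, :])
        Xg = np.stack([m[0] for m in members])
        Yg = np.stack([m[1] for m in members])
        out.append((D, Xg, Yg))
    return out


def _nll_profiled(sigma2_u, sigma2_e, rho, groups, n_obs, reml):
    """Negative profiled log-likelihood; also returns (beta, A = X'V^-1 X)."""
    p = groups[0][1].shape[2]
    A = np.zeros((p, p))
    b = np.zeros(p)
    quad = 0.0
    logdet = 0.0
    for D, Xg, Yg in groups:
        V = sigma2_u + sigma2_e * rho ** D
        try:
            L = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        Vinv = cho_solve(L, np.eye(V.shape[0]))
        logdet += Xg.shape[0] * 2.0 * np.sum(np.log(np.diag(L[0])))
        XtVi = np.einsum("mdp,de->mep", Xg, Vinv)
        A += np.einsum("mep,meq->pq", XtVi, Xg)
        b += np.einsum("mep,me->p", XtVi, Yg)
        quad += np.einsum("md,de,me->", Yg, Vinv, Yg)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    nll = 0.5 * (logdet + quad - b @ beta + n_obs * np.log(2.0 * np.pi))
    if reml:
        sign, ld = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, None, None
        nll += 0.5 * ld - 0.5 * p * np.log(2.0 * np.pi)
    return nll, beta, A


def _unpack(theta):
    return np.exp(theta[0]), np.exp(theta[1]), np.tanh(theta[2])


def fit_lmm_ar1(panel: pd.DataFrame, spec: ModelSpec,
                covariates: pd.DataFrame | None = None,
                fix: dict | None = None,
                rho_starts=(-0.5, 0.0, 0.5)) -> ModelFit:
    """Fit one two-level AR(1) model by (restricted) maximum likelihood.

    ``fix`` pins variance parameters (keys among ``sigma2_u``, ``sigma2_e``,
    ``rho``) instead of estimating them — e.g. ``{"sigma2_u": 0, "rho": 0}``
    reduces the fit to ordinary least squares weights.  The variance
    parameters are profiled over the GLS solution for beta and optimized by
    Nelder-Mead with multiple starting values of rho to avoid local optima
    near the boundaries.
    """
    X, y, person, day, terms = build_design(panel, spec, covariates)
    return _fit_arrays(X, y, person, day, terms, spec.estimation, fix, rho_starts)


def _fit_arrays(X, y, person, day, terms, estimation="ML", fix=None,
                rho_starts=(-0.5, 0.0, 0.5)) -> ModelFit:
    n_obs = len(y)
    uniq = np.unique(person)
    if n_obs < X.shape[1] + 2 or uniq.size < 2:
        raise ValueError("need at least 2 participants and more observations than terms")
    groups = _group_by_pattern(X, y, person, day)
    reml = estimation == "REML"
    fix = dict(fix or {})

    var_y = max(float(np.var(y)), 1e-12)
    su0 = fix.get("sigma2_u", 0.3 * var_y)
    se0 = fix.get("sigma2_e", 0.7 * var_y)
    free = [k for k in ("sigma2_u", "sigma2_e", "rho") if k not in fix]

    def full_theta(x):
        vals = dict(fix)
        for name, v in zip(free, x):
            vals[name] = (
                np.exp(np.clip(v, -30.0, 30.0)) if name != "rho" else np.tanh(v)
            )
        return vals

    def objective(x):
        v = full_theta(x)
        nll, _, _ = _nll_profiled(
            v["sigma2_u"], v["sigma2_e"], v["rho"], groups, n_obs, reml
        )
        return nll

    if free:
        best = None
        inits = {
            "sigma2_u": np.log(max(su0, 1e-10)),
            "sigma2_e": np.log(max(se0, 1e-10)),
        }
        for r0 in (rho_starts if "rho" in free else [0.0]):
            x0 = []
            for name in free:
                x0.append(np.arctanh(r0) if name == "rho" else inits[name])
            res = optimize.minimize(
                objective, np.asarray(x0), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        vals = full_theta(best.x)
        converged = bool(best.success) and np.isfinite(best.fun)
    else:
        vals = dict(fix)
        converged = True
    nll, beta, A = _nll_profiled(
        vals["sigma2_u"], vals["sigma2_e"], vals["rho"], groups, n_obs, reml
    )
    if not np.isfinite(nll) or beta is None:
        raise RuntimeError(
            f"mixed-model fit did not converge (nll={nll}); "
            f"variance parameters: {vals}"
        )
    warnings = []
    if abs(vals["rho"]) > 0.99:
        warnings.append("rho estimate at boundary")
    if vals["sigma2_u"] < 1e-8 * var_y:
        warnings.append("sigma2_u estimate near zero")
    try:
        cov_beta = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("singular design matrix (collinear terms; "
                           "too few participants for the covariate set?)") from exc
    d = np.diag(cov_beta)
    if not np.all(np.isfinite(d)) or np.any(d <= 0):
        raise RuntimeError("singular design matrix (collinear terms; "
                           "too few participants for the covariate set?)")
    se = np.sqrt(d)
    z = beta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    coef = pd.DataFrame({"term": terms, "B": beta, "SE": se, "p": pvals})
    return ModelFit(
        coef=coef, sigma2_u=float(vals["sigma2_u"]),
        sigma2_e=float(vals["sigma2_e"]), rho=float(vals["rho"]),
        loglik=-float(nll), n_obs=int(n_obs), n_participants=int(uniq.size),
        estimation=estimation, converged=converged, warnings=warnings,
    )


def loglik_ar1(panel: pd.DataFrame, spec: ModelSpec, beta, sigma2_u, sigma2_e,
               rho, covariates: pd.DataFrame | None = None) -> float:
    """Structured log-likelihood at given parameters (for cross-checks)."""
    X, y, person, day, _ = build_design(panel, spec, covariates)
    groups = _group_by_pattern(X - 0.0, y, person, day)
    # evaluate at fixed beta: reuse machinery by shifting y
    total = 0.0
    n = 0
    for D, Xg, Yg in groups:
        V = sigma2_u + sigma2_e * rho ** D
        L = cho_factor(V, lower=True)
        Vinv = cho_solve(L, np.eye(V.shape[0]))
        R = Yg - Xg @ np.asarray(beta)
        total += -0.5 * (
            Xg.shape[0] * 2.0 * np.sum(np.log(np.diag(L[0])))
            + np.einsum("md,de,me->", R, Vinv, R)
            + R.size * np.log(2.0 * np.pi)
        )
        n += R.size
    return float(total)


# --- effect scaling and the model suite -----------------------------------


def scale_coefficient(B: float, outcome_unit: str, round_digits: int | None = None):
    """Re-express a per-minute within-person coefficient as the effect of a
    one-hour change in the predictor, in minutes (or percent).

    ``B`` is in outcome-units per predictor-minute.  Multiplying by 60 gives
    the effect per predictor-hour; an outcome measured in hours is then
    converted to minutes (x60 again).  Percent and minute outcomes keep
    their unit.
    """
    if outcome_unit not in ("hours", "minutes", "percent"):
        raise ValueError(f"unknown outcome unit: {outcome_unit!r}")
    eff = B * 60.0
    if outcome_unit == "hours":
        eff *= 60.0
    if round_digits is not None:
        eff = round(eff, round_digits)
        if round_digits <= 0:
            eff = int(eff)
    return eff


DEFAULT_COVARIATES = (
    "sex", "age", "race", "mother_education", "family_structure",
    "income_band", "bmi_pct",
)


def run_model_suite(person_days: pd.DataFrame,
                    covariates: pd.DataFrame | None = None,
                    covariate_names=DEFAULT_COVARIATES,
                    estimation: str = "ML") -> dict:
    """The full bidirectional suite: sixteen models.

    Eight models predict the four nightly sleep outcomes from the two
    (lagged) daytime activity predictors; eight predict the two daily
    activity outcomes from the four previous-night sleep predictors.  Every
    model adjusts for the covariate set plus weekend.  Failures are
    recorded per model and the suite continues.

    Returns ``{name: ModelFit | Exception}`` keyed ``predictor->outcome``.
    """
    covs = tuple(covariate_names) if covariates is not None else ()
    panels = {
        d: build_lagged_panel(person_days, d) for d in ("pa_to_sleep", "sleep_to_pa")
    }
    results = {}
    for direction, outs, preds in (
        ("pa_to_sleep", SLEEP_OUTCOMES, PA_OUTCOMES),
        ("sleep_to_pa", PA_OUTCOMES, SLEEP_OUTCOMES),
    ):
        for outcome in outs:
            for pred in preds:
                spec = ModelSpec(outcome=outcome, predictor=pred,
                                 direction=direction, covariates=covs,
                                 estimation=estimation)
                name = f"{pred}->{outcome}"
                try:
                    results[name] = fit_lmm_ar1(panels[direction], spec, covariates)
                except Exception as exc:   # noqa: BLE001 - suite continues
                    results[name] = exc
    return results


def suite_tables(results: dict) -> dict[str, pd.DataFrame]:
    """Per-model coefficient tables (term, B, SE, p) for delimited output."""
    return {
        name: fit.coef.copy()
        for name, fit in results.items()
        if isinstance(fit, ModelFit)
    }
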