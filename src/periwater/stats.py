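"""Statistical layer for normalized lesion/shell diffusion measures.

Implements the study's analysis plan on a ROI-measure table joined with
subject covariates: per-ROI one-sample t-tests of the normalized measures
against zero, longitudinal linear mixed-effects models with crossed subject
and location random intercepts (timepoint dummy-coded against the first
visit, days-since-stroke z-scored within timepoint, Tukey-adjusted pairwise
timepoint contrasts), per-timepoint cross-sectional mixed models contrasting
shells against the lesion, Spearman correlations with clinical scores and
lesion evolution (exact permutation p for small n), covariate-adjusted OLS
regressions, and one-sample t-test power from the noncentral t.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """Raised when data cannot support the requested test (e.g. zero variance)."""


class RankDeficiencyError(ValueError):
    """Raised when a regression design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear design columns: {', '.join(self.columns)}")


# ---------------------------------------------------------------------------
# one-sample t-tests


@dataclass(frozen=True)
class TTestResult:
    """One-sample t-test of normalized measures against zero.

    ``mean_pct`` and ``ci95`` are on the percent scale (0.406 -> 40.6).
    """

    location: str
    timepoint: str
    measure: str
    n: int
    mean_pct: float
    ci95: tuple
    t_stat: float
    dof: int
    p_value: float
    cohens_d: float


def one_sample_t(
    values,
    location: str = "",
    timepoint: str = "",
    measure: str = "",
    alpha: float = 0.05,
) -> TTestResult:
    """Two-sided one-sample t-test of ``values`` against zero.

    Cohen's d is mean / sample SD (n-1 denominator). Zero-variance input is
    degenerate and raises rather than emitting an unfounded p-value.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise DegenerateDataError(f"need >= 2 finite values, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance: t-test undefined")
    mean = x.mean()
    se = sd / np.sqrt(n)
    t_stat = mean / se
    dof = n - 1
    p = 2.0 * sps.t.sf(abs(t_stat), dof)
    half = sps.t.ppf(1.0 - alpha / 2.0, dof) * se
    return TTestResult(
        location=location,
        timepoint=timepoint,
        measure=measure,
        n=n,
        mean_pct=100.0 * mean,
        ci95=(100.0 * (mean - half), 100.0 * (mean + half)),
        t_stat=t_stat,
        dof=dof,
        p_value=p,
        cohens_d=mean / sd,
    )


def ttest_table(measures: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-sample t-tests for every (timepoint, location, measure) cell."""
    rows = []
    for (tp, loc, m), grp in measures.groupby(
        ["timepoint", "location", "measure"], sort=False
    ):
        vals = grp["normalized"].dropna()
        if len(vals) < 2 or vals.std(ddof=1) == 0:
            log.warning("degenerate cell %s/%s/%s skipped", tp, loc, m)
            continue
        r = one_sample_t(vals, location=loc, timepoint=tp, measure=m, alpha=alpha)
        rows.append(
            {
                "timepoint": tp,
                "location": loc,
                "measure": m,
                "n": r.n,
                "mean_pct": r.mean_pct,
                "ci95_low": r.ci95[0],
                "ci95_high": r.ci95[1],
                "t": r.t_stat,
                "dof": r.dof,
                "p": r.p_value,
                "cohens_d": r.cohens_d,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariate preparation


def zscore_within_group(x, group) -> np.ndarray:
    """Z-score ``x`` within each level of ``group``.

    Groups with fewer than two members or zero variance map to 0, keeping
    the covariate defined for sparse visits.
    """
    s = pd.Series(np.asarray(x, dtype=float))
    g = pd.Series(np.asarray(group))
    out = np.zeros(len(s))
    for _, idx in g.groupby(g).groups.items():
        vals = s.loc[idx]
        sd = vals.std(ddof=1)
        if len(vals) >= 2 and sd > 0:
            out[np.asarray(idx)] = (vals - vals.mean()) / sd
    return out


def _prepare_model_frame(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    required = {
        "subject_id", "timepoint", "location", "measure", "normalized",
        "lesion_volume_ml", "age", "sex", "days_since_stroke",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"model table lacks columns: {sorted(missing)}")
    df = table[table["measure"] == measure].copy()
    n0 = len(df)
    df = df.dropna(subset=["normalized", "lesion_volume_ml", "age", "sex",
                           "days_since_stroke"])
    if len(df) < n0:
        log.info("dropped %d rows with missing components (never imputed)", n0 - len(df))
    df["sex_male"] = (df["sex"].astype(str).str.upper().str.startswith("M")).astype(float)
    df["days_z"] = zscore_within_group(
        df["days_since_stroke"].to_numpy(), df["timepoint"].to_numpy()
    )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# mixed models


@dataclass
class LmmResult:
    """Mixed-model summary: fixed effects, omnibus test, post-hocs, R^2."""

    fixed: pd.DataFrame  # index term; columns estimate, se, p
    omnibus_chi2: float
    omnibus_dof: int
    omnibus_p: float
    contrasts: pd.DataFrame  # pairwise Tukey-adjusted contrasts
    r2_marginal: float
    r2_conditional: float
    vc: dict
    resid_var: float
    n_obs: int
    resid_dof: float
    converged: bool
    measure: str = ""


def _tukey_contrasts(
    levels: list[str],
    coef: np.ndarray,
    cov: np.ndarray,
    level_cols: dict[str, int | None],
    dof: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-step (Tukey) adjusted pairwise contrasts between levels.

    The joint distribution of the pairwise t-statistics is multivariate t
    with the correlation induced by the fixed-effect covariance; each
    adjusted p is ``1 - P(max_j |T_j| <= |t_i|)`` under that distribution.
    """
    pairs = list(itertools.combinations(levels, 2))
    C = np.zeros((len(pairs), coef.shape[0]))
    for i, (a, b) in enumerate(pairs):
        if level_cols[b] is not None:
            C[i, level_cols[b]] += 1.0
        if level_cols[a] is not None:
            C[i, level_cols[a]] -= 1.0
    est = C @ coef
    V = C @ cov @ C.T
    se = np.sqrt(np.diag(V))
    tvals = est / se
    # joint null distribution of the contrast t-statistics: multivariate t
    # with the (rank-deficient: 6 contrasts span 3 dimensions) correlation
    # induced by the coefficient covariance; the equicoordinate probability
    # is estimated by seeded Monte Carlo on a factor of that covariance
    dof_t = max(dof, 3.0)
    evals, evecs = np.linalg.eigh((V + V.T) / 2.0)
    keep = evals > max(evals.max(), 1e-300) * 1e-12
    F = evecs[:, keep] * np.sqrt(evals[keep])  # V ~= F F'
    rng = np.random.default_rng(seed)
    n_mc = 200_000
    z = rng.standard_normal((n_mc, F.shape[1]))
    w = rng.chisquare(dof_t, size=n_mc)
    t_mc = (z @ F.T) / se[None, :] / np.sqrt(w / dof_t)[:, None]
    max_abs = np.abs(t_mc).max(axis=1)
    p_adj = np.array([np.mean(max_abs >= abs(t)) for t in tvals])
    p_unadj = 2.0 * sps.t.sf(np.abs(tvals), dof)
    return pd.DataFrame(
        {
            "contrast": [f"{b} - {a}" for a, b in pairs],
            "estimate": est,
            "se": se,
            "t": tvals,
            "p_unadjusted": p_unadj,
            "p_tukey": p_adj,
        }
    )


def _fit_mixedlm(model):
    """REML fit with a fallback chain for fragile optimizer paths.

    statsmodels' gradient-based path can hit a singular working covariance
    at intermediate iterates; the derivative-free retry usually survives.
    """
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (["lbfgs", "powell"], "powell", "nm"):
            try:
                return model.fit(reml=True, method=method, maxiter=500)
            except np.linalg.LinAlgError:
                continue
    raise DegenerateDataError("mixed model fit failed on every optimizer")


def _nakagawa_r2(fitted_fixed: np.ndarray, vc_vars: dict, resid_var: float):
    var_f = float(np.var(fitted_fixed))
    var_re = float(sum(vc_vars.values()))
    total = var_f + var_re + resid_var
    return var_f / total, (var_f + var_re) / total


def fit_longitudinal_lmm(
    table: pd.DataFrame,
    measure: str = "fw",
    omnibus: str = "wald",
    tukey_seed: int = 0,
) -> LmmResult:
    """Longitudinal mixed model of a normalized measure across timepoints.

    Random intercepts for subject and location of measurement (crossed),
    REML estimation; fixed effects are dummy-coded timepoint (first visit
    as reference), lesion volume, age, sex (male indicator) and
    days-since-stroke z-scored within timepoint. The omnibus timepoint test
    is a Wald chi-square by default (``omnibus="lrt"`` refits by ML for a
    likelihood-ratio test); pairwise timepoint contrasts carry Tukey
    (single-step multivariate-t) adjusted p-values. R^2 follows the
    variance-partition (marginal/conditional) convention.
    """
    df = _prepare_model_frame(table, measure)
    tps = sorted(df["timepoint"].unique())
    if len(tps) < 2:
        raise DegenerateDataError("need >= 2 timepoints")
    if df["location"].nunique() < 2:
        raise DegenerateDataError("need >= 2 locations")
    if df["subject_id"].nunique() < 3:
        raise DegenerateDataError("need >= 3 subjects")
    ref = tps[0]
    formula = (
        f"normalized ~ C(timepoint, Treatment('{ref}')) + lesion_volume_ml"
        " + age + sex_male + days_z"
    )
    vc = {"subject": "0 + C(subject_id)", "location": "0 + C(location)"}
    model = smf.mixedlm(
        formula, df, groups=np.ones(len(df)), vc_formula=vc, re_formula="0"
    )
    res = _fit_mixedlm(model)
    converged = bool(res.converged)
    if not converged:
        log.warning("longitudinal mixed model did not fully converge; "
                    "estimates reported with converged=False")

    fe_names = list(res.fe_params.index)
    coef = res.fe_params.to_numpy()
    cov = np.asarray(res.cov_params())[: len(fe_names), : len(fe_names)]
    tp_cols = {ref: None}
    for t in tps[1:]:
        name = f"C(timepoint, Treatment('{ref}'))[T.{t}]"
        tp_cols[t] = fe_names.index(name)
    tp_idx = [tp_cols[t] for t in tps[1:]]

    # omnibus timepoint test
    if omnibus == "lrt":
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full_ml = smf.mixedlm(formula, df, groups=np.ones(len(df)),
                                  vc_formula=vc, re_formula="0").fit(reml=False)
            red_ml = smf.mixedlm(
                "normalized ~ lesion_volume_ml + age + sex_male + days_z",
                df, groups=np.ones(len(df)), vc_formula=vc, re_formula="0",
            ).fit(reml=False)
        chi2 = 2.0 * (full_ml.llf - red_ml.llf)
        dof = len(tps) - 1
    else:
        est = coef[tp_idx]
        V = cov[np.ix_(tp_idx, tp_idx)]
        chi2 = float(est @ np.linalg.solve(V, est))
        dof = len(tp_idx)
    omnibus_p = float(sps.chi2.sf(chi2, dof))

    n_obs = len(df)
    resid_dof = n_obs - len(fe_names)
    contrasts = _tukey_contrasts(tps, coef, cov, tp_cols, resid_dof, seed=tukey_seed)

    X = model.exog
    vc_vars = {name: float(v) for name, v in res.vcomp_to_dict().items()} if hasattr(
        res, "vcomp_to_dict") else dict(zip(model.exog_vc.names, res.vcomp))
    resid_var = float(res.scale)
    r2m, r2c = _nakagawa_r2(X @ coef, vc_vars, resid_var)

    fixed = pd.DataFrame(
        {"estimate": res.fe_params, "se": res.bse_fe, "p": res.pvalues[fe_names]}
    )
    return LmmResult(
        fixed=fixed,
        omnibus_chi2=float(chi2),
        omnibus_dof=int(dof),
        omnibus_p=omnibus_p,
        contrasts=contrasts,
        r2_marginal=r2m,
        r2_conditional=r2c,
        vc=vc_vars,
        resid_var=resid_var,
        n_obs=n_obs,
        resid_dof=resid_dof,
        converged=converged,
        measure=measure,
    )


def fit_cross_sectional_lmm(
    table: pd.DataFrame,
    timepoint: str,
    measure: str = "fw",
    tukey_seed: int = 0,
) -> LmmResult:
    """Per-timepoint mixed model contrasting locations against the lesion.

    Subject random intercept; location fixed with the lesion as reference;
    same covariates as the longitudinal model (days z-scoring degenerates
    to zero within a single timepoint).
    """
    df = _prepare_model_frame(table, measure)
    df = df[df["timepoint"] == timepoint].reset_index(drop=True)
    if df.empty:
        raise DegenerateDataError(f"no rows at timepoint {timepoint!r}")
    locs = list(dict.fromkeys(df["location"]))  # preserve lesion-first order
    if len(locs) < 2:
        raise DegenerateDataError("need >= 2 locations for location contrasts")
    ref = "lesion" if "lesion" in locs else locs[0]
    formula = (
        f"normalized ~ C(location, Treatment('{ref}')) + lesion_volume_ml"
        " + age + sex_male"
    )
    model = smf.mixedlm(formula, df, groups=df["subject_id"])
    res = _fit_mixedlm(model)
    fe_names = list(res.fe_params.index)
    coef = res.fe_params.to_numpy()
    cov = np.asarray(res.cov_params())[: len(fe_names), : len(fe_names)]
    loc_cols = {ref: None}
    others = [l for l in locs if l != ref]
    for l in others:
        loc_cols[l] = fe_names.index(f"C(location, Treatment('{ref}'))[T.{l}]")
    loc_idx = [loc_cols[l] for l in others]
    est_loc = coef[loc_idx]
    V_loc = cov[np.ix_(loc_idx, loc_idx)]
    chi2 = float(est_loc @ np.linalg.solve(V_loc, est_loc))
    dof = len(others)
    n_obs = len(df)
    resid_dof = n_obs - len(fe_names)

    rows = []
    for l in others:
        j = loc_cols[l]
        est = coef[j]
        se = np.sqrt(cov[j, j])
        t = est / se
        rows.append(
            {"contrast": f"{l} - {ref}", "estimate": est, "se": se, "t": t,
             "p_unadjusted": 2.0 * sps.t.sf(abs(t), resid_dof), "p_tukey": np.nan}
        )
    contrasts = pd.DataFrame(rows)

    re_var = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
    resid_var = float(res.scale)
    r2m, r2c = _nakagawa_r2(model.exog @ coef, {"subject": re_var}, resid_var)
    fixed = pd.DataFrame(
        {"estimate": res.fe_params, "se": res.bse_fe, "p": res.pvalues[fe_names]}
    )
    return LmmResult(
        fixed=fixed,
        omnibus_chi2=chi2,
        omnibus_dof=dof,
        omnibus_p=float(sps.chi2.sf(chi2, dof)),
        contrasts=contrasts,
        r2_marginal=r2m,
        r2_conditional=r2c,
        vc={"subject": re_var},
        resid_var=resid_var,
        n_obs=n_obs,
        resid_dof=resid_dof,
        converged=bool(res.converged),
        measure=measure,
    )


# ---------------------------------------------------------------------------
# correlations, regressions, power


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    For n <= ``exact_max_n`` the two-sided p-value is computed by full
    permutation enumeration of the rank pairing; otherwise by the usual
    t-approximation. Constant input yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise DegenerateDataError(f"need >= 3 paired values, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant vector: Spearman correlation undefined")
        return np.nan, np.nan
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    rho = float((rxc * ryc).sum() / denom)
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rho, p


def lesion_volume_change(volumes: dict, baseline: str = "TP1") -> dict:
    """Relative change (V_t - V_baseline) / V_baseline per timepoint.

    Missing timepoints yield NaN; a missing or nonpositive baseline is an
    error.
    """
    if baseline not in volumes or not np.isfinite(volumes[baseline]):
        raise ValueError(f"baseline volume ({baseline}) missing")
    v0 = float(volumes[baseline])
    if v0 <= 0:
        raise ValueError("baseline volume must be positive")
    out = {}
    for tp, v in volumes.items():
        if tp == baseline:
            continue
        out[tp] = (float(v) - v0) / v0 if v is not None and np.isfinite(v) else np.nan
    return out


def adjusted_regression(
    df: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple = ("age", "sex_male", "baseline_volume_ml", "days_since_stroke"),
) -> pd.DataFrame:
    """OLS of ``outcome`` on ``predictor`` adjusting for ``covariates``.

    Returns coefficient table (estimate, se, t, p). Rank-deficient designs
    raise :class:`RankDeficiencyError` naming the collinear columns.
    """
    cols = [predictor, *covariates]
    work = df[[outcome, *cols]].dropna()
    X = work[cols].to_numpy(dtype=float)
    y = work[outcome].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise DegenerateDataError(f"need n > p + 2 (n={n}, p={p})")
    Xc = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        bad = []
        rank = 1
        base = np.ones((n, 1))
        for name, col in zip(cols, X.T):
            cand = np.column_stack([base, col])
            r = np.linalg.matrix_rank(cand)
            if r == rank:
                bad.append(name)
            else:
                base, rank = cand, r
        raise RankDeficiencyError(bad or cols)
    res = sm.OLS(y, sm.add_constant(work[cols].astype(float))).fit()
    return pd.DataFrame(
        {"estimate": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues}
    )


def power_one_sample_t(d: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided one-sample t-test at effect size d = mean/sd.

    Uses the noncentral t distribution with ncp = d * sqrt(n), matching the
    standard power-calculator convention.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    dof = n - 1
    ncp = d * np.sqrt(n)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, dof)
    return float(sps.nct.sf(tcrit, dof, ncp) + sps.nct.cdf(-tcrit, dof, ncp))


# ---------------------------------------------------------------------------
# ROI summaries used by the correlation analyses


def average_measures(
    measures: pd.DataFrame, rois: str = "shells", measure: str = "fw"
) -> pd.DataFrame:
    """Per subject x timepoint average of normalized values.

    ``rois="shells"`` takes the unweighted mean of the shell means (the
    perilesional summary); ``rois="lesion"`` the lesion ROI itself.
    """
    df = measures[measures["measure"] == measure]
    if rois == "shells":
        df = df[df["location"] != "lesion"]
    elif rois == "lesion":
        df = df[df["location"] == "lesion"]
    else:
        raise ValueError("rois must be 'shells' or 'lesion'")
    out = (
        df.groupby(["subject_id", "timepoint"])["normalized"]
        .mean()
        .reset_index()
        .rename(columns={"normalized": f"{measure}_{rois}"})
    )
    return out
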