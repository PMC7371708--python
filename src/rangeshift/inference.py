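"""Staged mixed-model inference on space-use, movement and resource use.

All models share one protocol: the sampling unit is the animal-year,
entering as a random intercept (``ind``); fixed effects are built
progressively (Phase, then preference h_FS, their interaction, Sex, and
the Sex interactions), fitted by maximum likelihood; term p-values come
from likelihood-ratio tests of each term against the model without it
(respecting marginality); non-significant terms are dropped iteratively
from the full model. Variance explained is summarized with the
variance-partition (marginal / conditional) coefficients of
determination, using the logit-link distribution-specific residual
variance pi^2 / 3 for binomial models.

Linear mixed models delegate to statsmodels' MixedLM. The binomial
random-intercept model is fitted here directly by Laplace-approximated
maximum likelihood (scalar random effect per group, Newton inner loop),
which matches the standard frequentist GLMM fit for this model family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "ModelFit",
    "fit_lmm",
    "fit_resource_glmm",
    "build_model_sequence",
    "drop_nonsignificant",
    "r_squared",
    "random_effect_sensitivity",
    "LOGIT_RESIDUAL_VAR",
]

LOGIT_RESIDUAL_VAR = np.pi**2 / 3


@dataclass
class ModelFit:
    """One fitted mixed model and its reporting surface."""

    response: str
    terms: list[str]
    family: str  # "gaussian" | "binomial"
    params: pd.Series
    bse: pd.Series
    term_pvalues: dict[str, float]
    llf: float
    re_var: float
    resid_var: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    drop_log: list[str] = field(default_factory=list)

    def summary_dict(self) -> dict:
        return {
            "response": self.response,
            "family": self.family,
            "terms": list(self.terms),
            "coefficients": {
                k: {"estimate": float(self.params[k]), "se": float(self.bse[k])}
                for k in self.params.index
            },
            "term_pvalues": {k: float(v) for k, v in self.term_pvalues.items()},
            "loglik": float(self.llf),
            "random_intercept_var": float(self.re_var),
            "residual_var": float(self.resid_var),
            "r2_marginal": float(self.r2_marginal),
            "r2_conditional": float(self.r2_conditional),
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "flags": list(self.flags),
            "drop_log": list(self.drop_log),
        }


def _formula(response: str, terms: Sequence[str]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def _term_sets(terms: Sequence[str]) -> dict[str, frozenset]:
    return {t: frozenset(t.split(":")) for t in terms}


def droppable_terms(terms: Sequence[str]) -> list[str]:
    """Terms whose removal respects marginality.

    A term is droppable unless a retained higher-order interaction strictly
    contains it (a main effect under a kept interaction stays in).
    """
    sets = _term_sets(terms)
    out = []
    for t, s in sets.items():
        if not any(s < other for other in sets.values()):
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# Linear mixed models (statsmodels MixedLM, ML)
# ---------------------------------------------------------------------------

class _OLSBoundaryFit:
    """Shim for the random-variance-zero boundary, where MixedLM's Hessian
    is singular: the ML solution then coincides with ordinary least squares."""

    def __init__(self, res_ols, nobs: int):
        self.fe_params = res_ols.params
        self.bse_fe = res_ols.bse
        self.llf = float(res_ols.llf)
        self.cov_re = pd.DataFrame([[0.0]])
        self.scale = float(res_ols.ssr / nobs)
        self.converged = True
        self.nobs = nobs


def _fit_mixedlm_raw(table: pd.DataFrame, response: str,
                     terms: Sequence[str], group: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(_formula(response, terms), table,
                            groups=table[group])
        try:
            res = model.fit(reml=False)
        except np.linalg.LinAlgError:
            try:
                res = model.fit(reml=False, method="powell")
            except np.linalg.LinAlgError:
                # boundary solution with zero random variance: exact OLS limit
                ols = smf.ols(_formula(response, terms), table).fit()
                res = _OLSBoundaryFit(ols, nobs=len(table))
    return res


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    group: str = "ind",
    pvalues: bool = True,
) -> ModelFit:
    """ML fit of a Gaussian random-intercept model.

    The response is assumed already transformed (log area, logit VI, log
    step length, logit |turn|/pi). Term p-values are LRTs against the
    model without the term; main effects shielded by a retained
    interaction get no p-value (NaN). A singular random-effect variance is
    retained at ~0 with a flag rather than failing.
    """
    res = _fit_mixedlm_raw(table, response, terms, group)
    flags = []
    if not res.converged:
        flags.append("nonconvergence")
    re_var = float(np.squeeze(res.cov_re.to_numpy()))
    if re_var < 1e-10:
        flags.append("singular random-effect variance")
    llf = float(res.llf)
    pvals: dict[str, float] = {t: np.nan for t in terms}
    if pvalues:
        for t in droppable_terms(terms):
            reduced_terms = [u for u in terms if u != t]
            red = _fit_mixedlm_raw(table, response, reduced_terms, group)
            df = len(res.fe_params) - len(red.fe_params)
            lr = 2 * (llf - float(red.llf))
            pvals[t] = float(stats.chi2.sf(max(lr, 0.0), max(df, 1)))
    fixed = res.fe_params
    X = patsy.dmatrix(_formula(response, terms).split("~")[1], table,
                      return_type="dataframe")
    var_f = float(np.var(X.to_numpy() @ fixed.to_numpy(), ddof=0))
    resid = float(res.scale)
    denom = var_f + re_var + resid
    return ModelFit(
        response=response,
        terms=list(terms),
        family="gaussian",
        params=fixed,
        bse=res.bse_fe,
        term_pvalues=pvals,
        llf=llf,
        re_var=re_var,
        resid_var=resid,
        r2_marginal=var_f / denom,
        r2_conditional=(var_f + re_var) / denom,
        n_obs=int(res.nobs),
        n_groups=table[group].nunique(),
        converged=bool(res.converged),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Binomial random-intercept GLMM (Laplace ML)
# ---------------------------------------------------------------------------

def _glmm_loglik(beta: np.ndarray, log_sigma: float, X: np.ndarray,
                 y: np.ndarray, gidx: np.ndarray, n_groups: int,
                 newton_iter: int = 30) -> float:
    """Laplace-approximated marginal log-likelihood.

    For each group the scalar random intercept's conditional mode is found
    by Newton's method (the inner objective is strictly concave), and the
    Gaussian integral is replaced by its Laplace approximation.
    """
    sigma2 = np.exp(2 * log_sigma)
    eta0 = X @ beta
    u = np.zeros(n_groups)
    for _ in range(newton_iter):
        eta = eta0 + u[gidx]
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = np.bincount(gidx, y - mu, minlength=n_groups) - u / sigma2
        w = np.bincount(gidx, mu * (1 - mu), minlength=n_groups) + 1 / sigma2
        step = grad / w
        # damped Newton keeps the inner loop stable for extreme eta
        step = np.clip(step, -5.0, 5.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + u[gidx]
    # log p(y | u) summed within groups, numerically stable logistic loglik
    ll_obs = y * eta - np.logaddexp(0.0, eta)
    ll_g = np.bincount(gidx, ll_obs, minlength=n_groups)
    w = np.bincount(gidx, (1 / (1 + np.exp(-eta))) * (1 - 1 / (1 + np.exp(-eta))),
                    minlength=n_groups) + 1 / sigma2
    ll = ll_g - u**2 / (2 * sigma2) - 0.5 * np.log(sigma2) - 0.5 * np.log(w)
    return float(ll.sum())


def _fit_glmm_raw(X: np.ndarray, y: np.ndarray, gidx: np.ndarray,
                  n_groups: int, start: np.ndarray | None = None,
                  ridge: float = 0.0):
    p = X.shape[1]
    if start is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=sm.families.Binomial())
            try:
                beta0 = glm.fit(maxiter=50).params
            except Exception:
                beta0 = np.zeros(p)
        beta0 = np.clip(np.nan_to_num(beta0), -10, 10)
        start = np.concatenate([beta0, [np.log(0.5)]])

    def nll(theta: np.ndarray) -> float:
        val = _glmm_loglik(theta[:p], theta[p], X, y, gidx, n_groups)
        if ridge > 0:
            val -= ridge * float(theta[:p] @ theta[:p])
        return -val

    res = optimize.minimize(nll, start, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-11})
    return res, p


def fit_resource_glmm(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    group: str = "ind",
    pvalues: bool = True,
) -> ModelFit:
    """Binomial (logit) mixed model with an animal-year random intercept.

    ``response`` is a 0/1 presence series for one resource state. Fitting
    is Laplace-approximated ML. Complete separation (or non-convergence)
    triggers a lightly ridge-penalized refit, flagged on the result. An
    all-constant response is refused as degenerate.
    """
    y = table[response].to_numpy(float)
    if y.min() == y.max():
        raise ValueError(f"{response}: response is constant; model undefined")
    X_df = patsy.dmatrix(_formula(response, terms).split("~")[1], table,
                         return_type="dataframe")
    X = X_df.to_numpy(float)
    groups, gidx = np.unique(table[group].to_numpy(), return_inverse=True)
    n_groups = len(groups)

    res, p = _fit_glmm_raw(X, y, gidx, n_groups)
    flags: list[str] = []
    if (not res.success) or np.max(np.abs(res.x[:p])) > 30:
        res, p = _fit_glmm_raw(X, y, gidx, n_groups, ridge=1e-4)
        flags.append("penalized refit (separation or non-convergence)")
    theta = res.x
    llf = -float(res.fun)

    # SEs from the numerical Hessian of the Laplace log-likelihood
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        H = approx_hess1(theta, lambda th: -_glmm_loglik(
            th[:p], th[p], X, y, gidx, n_groups))
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.clip(np.diag(cov)[:p], 0, np.inf))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
        flags.append("singular Hessian")

    pvals: dict[str, float] = {t: np.nan for t in terms}
    if pvalues:
        for t in droppable_terms(terms):
            reduced = [u for u in terms if u != t]
            Xr = patsy.dmatrix(_formula(response, reduced).split("~")[1], table,
                               return_type="dataframe").to_numpy(float)
            r_res, pr = _fit_glmm_raw(Xr, y, gidx, n_groups)
            lr = 2 * (llf - (-float(r_res.fun)))
            df = p - pr
            pvals[t] = float(stats.chi2.sf(max(lr, 0.0), max(df, 1)))

    beta = pd.Series(theta[:p], index=X_df.columns)
    sigma2 = float(np.exp(2 * theta[p]))
    var_f = float(np.var(X @ theta[:p], ddof=0))
    denom = var_f + sigma2 + LOGIT_RESIDUAL_VAR
    return ModelFit(
        response=response,
        terms=list(terms),
        family="binomial",
        params=beta,
        bse=pd.Series(bse, index=X_df.columns),
        term_pvalues=pvals,
        llf=llf,
        re_var=sigma2,
        resid_var=LOGIT_RESIDUAL_VAR,
        r2_marginal=var_f / denom,
        r2_conditional=(var_f + sigma2) / denom,
        n_obs=len(y),
        n_groups=n_groups,
        converged=bool(res.success),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Protocol: progressive construction, dropping, sensitivity
# ---------------------------------------------------------------------------

DEFAULT_TERM_ORDER = ("phase", "h_fs", "phase:h_fs", "sex", "phase:sex")


def build_model_sequence(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str] = DEFAULT_TERM_ORDER,
    fitter: Callable[..., ModelFit] = fit_lmm,
    group: str = "ind",
) -> pd.DataFrame:
    """Fit the nested fixed-effect sequence and track coefficient stability.

    Models grow one term at a time in the given order (an empty term list
    yields the intercept-only fit). Returns one row per (stage,
    coefficient) with the estimate, plus a ``sign_stable`` flag saying
    whether that coefficient kept one sign across every stage containing
    it — the check that the data support the richer formulations.
    """
    rows = []
    fits: list[ModelFit] = []
    for k in range(len(terms) + 1):
        stage_terms = list(terms[:k])
        fit = fitter(table, response, stage_terms, group=group)
        fits.append(fit)
        for name, est in fit.params.items():
            rows.append({"stage": k, "terms": " + ".join(stage_terms) or "1",
                         "coef": name, "estimate": float(est),
                         "llf": fit.llf})
    df = pd.DataFrame(rows)
    stable = (
        df[df["coef"] != "Intercept"]
        .groupby("coef")["estimate"]
        .agg(lambda v: bool((v > 0).all() or (v < 0).all()))
    )
    df["sign_stable"] = df["coef"].map(stable).astype("boolean").fillna(True).astype(bool)
    return df


def drop_nonsignificant(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    alpha: float = 0.05,
    fitter: Callable[..., ModelFit] = fit_lmm,
    group: str = "ind",
) -> ModelFit:
    """Backward elimination of non-significant fixed effects.

    Starting from the full model, repeatedly removes the least significant
    droppable term with p > alpha and refits; a main effect never leaves
    while one of its interactions stays (marginality). The drop sequence
    is recorded on the returned fit.
    """
    current = list(terms)
    log: list[str] = []
    fit = fitter(table, response, current, group=group)
    while True:
        cand = {t: p for t, p in fit.term_pvalues.items()
                if t in droppable_terms(current) and np.isfinite(p) and p > alpha}
        if not cand:
            break
        worst = max(cand, key=cand.get)
        log.append(f"dropped {worst} (p={cand[worst]:.3g})")
        current.remove(worst)
        fit = fitter(table, response, current, group=group)
    fit.drop_log = log
    return fit


def r_squared(fit: ModelFit) -> tuple[float, float]:
    """(marginal, conditional) variance-partition coefficients.

    marginal = var(fixed) / (var(fixed) + var(random) + var(residual));
    conditional adds the random-intercept variance to the numerator. For
    binomial-logit fits the residual variance is pi^2/3.
    """
    return fit.r2_marginal, fit.r2_conditional


def random_effect_sensitivity(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    fitter: Callable[..., ModelFit] = fit_lmm,
    unit_group: str = "ind",
    animal_group: str = "animal_id",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare animal-year vs animal random-intercept fits, per term.

    Refits the same fixed-effect structure with the coarser animal-level
    grouping and reports sign and significance agreement for every
    coefficient — the robustness check that the grouping choice does not
    qualitatively change the conclusions. When every animal contributes a
    single year the two fits coincide.
    """
    if animal_group not in table.columns:
        raise ValueError(f"column {animal_group!r} required for the "
                         "animal-level sensitivity refit")
    fit_ay = fitter(table, response, terms, group=unit_group)
    fit_an = fitter(table, response, terms, group=animal_group)
    rows = []
    for name in fit_ay.params.index:
        e1, e2 = float(fit_ay.params[name]), float(fit_an.params[name])
        rows.append({
            "coef": name,
            "estimate_animal_year": e1,
            "estimate_animal": e2,
            "sign_agrees": np.sign(e1) == np.sign(e2),
        })
    per_term = pd.DataFrame(rows)
    sig = []
    for t in set(fit_ay.term_pvalues) | set(fit_an.term_pvalues):
        p1 = fit_ay.term_pvalues.get(t, np.nan)
        p2 = fit_an.term_pvalues.get(t, np.nan)
        agree = (not np.isfinite(p1) and not np.isfinite(p2)) or \
            (np.isfinite(p1) and np.isfinite(p2) and (p1 <= alpha) == (p2 <= alpha))
        sig.append({"coef": t, "significance_agrees": bool(agree)})
    return per_term.merge(pd.DataFrame(sig), on="coef", how="left")
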