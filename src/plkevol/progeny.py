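"""Brood-level fertility and sex-ratio statistics.

One record per mated male: transgene, strain, batch, and counts of female
and male progeny in his vial.  Three analyses mirror the experimental
design:

* progeny-count model — linear mixed model of a count response (total,
  female or male progeny) with transgene as fixed effect and random
  intercepts for batch and strain (REML);
* siring model — mixed logistic regression of whether a male sired any
  progeny, same fixed/random structure (variational-Bayes fit);
* sex-ratio model — per transgene, a linear mixed model of the number of
  progeny with progeny sex and vial as fixed effects and batch/strain
  random intercepts; the progeny-sex F statistic (containment denominator
  degrees of freedom, n_vials - 1) is the headline output.

A per-male exact binomial test of the brood sex ratio against 1:1 serves as
a model-free cross-check.

Fixed effects use treatment (reference-level) coding; the estimation
criterion and any degradation of the random-effects structure are recorded
in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest, f as f_dist, norm

import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.tools import numdiff

__all__ = [
    "REQUIRED_COLUMNS",
    "ModelResult",
    "validate_records",
    "fit_count_model",
    "fit_sired_model",
    "sex_ratio_model",
    "binomial_sex_ratio",
]

REQUIRED_COLUMNS = ("male_id", "transgene", "strain", "batch",
                    "n_female", "n_male")


@dataclass
class ModelResult:
    """Tidy fixed-effect table plus fitting metadata.

    ``terms`` has columns term, estimate, se, stat, stat_name, df_num,
    df_den, p_value.
    """

    method: str
    formula: str
    coding: str
    terms: pd.DataFrame
    criterion: str
    warnings: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def term(self, name_fragment: str) -> pd.Series:
        hits = self.terms[self.terms.term.str.contains(name_fragment,
                                                       regex=False)]
        if hits.empty:
            raise KeyError(name_fragment)
        return hits.iloc[0]

    def summary(self) -> str:
        lines = [
            f"{self.method}",
            f"  formula: {self.formula}",
            f"  fixed-effect coding: {self.coding}",
            f"  criterion: {self.criterion}",
            self.terms.to_string(index=False,
                                 float_format=lambda v: f"{v:.4g}"),
        ]
        for w in self.warnings:
            lines.append(f"  WARNING: {w}")
        return "\n".join(lines)


def validate_records(records) -> pd.DataFrame:
    df = pd.DataFrame(records).copy()
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    for col in ("n_female", "n_male"):
        if (df[col] < 0).any():
            raise ValueError(f"{col} must be nonnegative")
    df["total"] = df["n_female"] + df["n_male"]
    df["sired"] = (df["total"] > 0).astype(int)
    return df


def _vc_formulas(df: pd.DataFrame, factors=("batch", "strain")):
    """Variance-component formulas for the grouping factors that vary.

    Crossed random intercepts are expressed as variance components on a
    single trivial group.  Factors with one level are dropped with a
    warning (graceful degradation).
    """
    vc = {}
    notes = []
    for factor in factors:
        if df[factor].nunique() >= 2:
            vc[factor] = f"0 + C({factor})"
        else:
            notes.append(
                f"random effect for {factor!r} dropped (single level)"
            )
    return vc, notes


def _mixedlm_terms(fit, df_den=None) -> pd.DataFrame:
    fe = fit.fe_params
    se = fit.bse_fe
    rows = []
    for name in fe.index:
        est, s = float(fe[name]), float(se[name])
        z = est / s if s > 0 else np.nan
        if df_den is None:
            p = 2.0 * norm.sf(abs(z))
            rows.append({"term": name, "estimate": est, "se": s, "stat": z,
                         "stat_name": "z", "df_num": np.nan,
                         "df_den": np.nan, "p_value": p})
        else:
            fstat = z ** 2
            p = float(f_dist.sf(fstat, 1, df_den))
            rows.append({"term": name, "estimate": est, "se": s,
                         "stat": fstat, "stat_name": "F", "df_num": 1,
                         "df_den": df_den, "p_value": p})
    return pd.DataFrame(rows)


def _containment_df(df: pd.DataFrame, effect: str, groupings,
                    n_fixed: int) -> int:
    """Containment denominator df for a between-group fixed effect.

    If the effect is constant within the levels of some random grouping
    (e.g. strain nested in transgene), the denominator df comes from that
    grouping: n_levels - n_effect_levels.  Otherwise the effect varies
    within every grouping and the residual df applies.
    """
    candidates = []
    for factor in groupings:
        nested = (df.groupby(factor, observed=True)[effect]
                  .nunique().max() == 1)
        if nested:
            candidates.append(df[factor].nunique())
    if candidates:
        return max(min(candidates) - df[effect].nunique(), 1)
    return max(len(df) - n_fixed, 1)


def fit_count_model(records, response: str = "total") -> ModelResult:
    """Linear mixed model of progeny counts.

    response in {"total", "female", "male"}; transgene fixed, batch and
    strain random intercepts, REML.
    """
    df = validate_records(records)
    colmap = {"total": "total", "female": "n_female", "male": "n_male"}
    if response not in colmap:
        raise ValueError(f"response must be one of {sorted(colmap)}")
    ycol = colmap[response]
    levels = df["transgene"].nunique()
    if levels < 2:
        raise ValueError("need at least two transgene levels")
    if df.groupby("transgene").size().min() < 2:
        raise ValueError(
            "need at least two records per transgene level for a mixed fit"
        )
    vc, notes = _vc_formulas(df)
    formula = f"{ycol} ~ C(transgene)"
    df = df.assign(_one=1)
    if vc:
        model = smf.mixedlm(formula, df, groups="_one", vc_formula=vc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
        # containment denominator df for the transgene contrasts: strain
        # (or batch) levels nested within transgene contain the effect
        df_den = _containment_df(df, "transgene", list(vc),
                                 n_fixed=levels)
        terms = _mixedlm_terms(fit, df_den=df_den)
        criterion = ("REML (linear mixed model); F on containment "
                     f"df (1, {df_den})")
        extra = {"vc": dict(zip(vc, map(float, np.atleast_1d(fit.vcomp))))}
    else:
        fit = smf.ols(formula, df).fit()
        terms = pd.DataFrame(
            {
                "term": fit.params.index,
                "estimate": fit.params.values,
                "se": fit.bse.values,
                "stat": fit.tvalues.values,
                "stat_name": "t",
                "df_num": np.nan,
                "df_den": fit.df_resid,
                "p_value": fit.pvalues.values,
            }
        )
        criterion = "OLS (no random terms retained)"
        notes.append("all random terms dropped; ordinary least squares used")
        extra = {}
    return ModelResult(
        method=f"progeny count model (response: {response})",
        formula=formula + " + (1|batch) + (1|strain)",
        coding="treatment (first level is reference)",
        terms=terms,
        criterion=criterion,
        warnings=notes,
        extra=extra,
    )


def _laplace_logistic_mixed(y, X, z_factors):
    """Laplace-approximation logistic mixed model with crossed random
    intercepts (the glmer criterion).

    y : (n,) 0/1 outcomes; X : (n, p) fixed design; z_factors : ordered
    mapping factor name -> (n,) integer level codes.  Returns (beta, se,
    sigmas) with one random-intercept sd per factor.

    The marginal likelihood integrates the random intercepts u ~ N(0, D)
    out by Laplace: maximize the joint over u (penalized Newton/IRLS),
    then correct with -0.5 log det of the joint Hessian.  (beta, log sigma)
    are optimized jointly; Wald standard errors condition on the estimated
    variance parameters, as in glmer.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    blocks = []  # (slice in u, n_levels) per factor
    Z_cols = []
    q = 0
    for codes in z_factors.values():
        codes = np.asarray(codes)
        n_lev = codes.max() + 1
        Zf = np.zeros((n, n_lev))
        Zf[np.arange(n), codes] = 1.0
        Z_cols.append(Zf)
        blocks.append((slice(q, q + n_lev), n_lev))
        q += n_lev
    Z = np.hstack(Z_cols)

    def d_inv(log_sig):
        out = np.empty(q)
        for (sl, n_lev), ls in zip(blocks, log_sig):
            out[sl] = np.exp(-2.0 * ls)
        return out  # diagonal of D^{-1}

    def inner(beta, log_sig, u0=None):
        """Penalized Newton for u-hat; returns (u, H) with H the joint
        Hessian Z'WZ + D^{-1}."""
        di = d_inv(log_sig)
        u = np.zeros(q) if u0 is None else u0.copy()
        for _ in range(50):
            eta = X @ beta + Z @ u
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            grad = Z.T @ (y - mu) - di * u
            H = (Z.T * w) @ Z + np.diag(di)
            step = np.linalg.solve(H, grad)
            u = u + step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = X @ beta + Z @ u
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (Z.T * w) @ Z + np.diag(d_inv(log_sig))
        return u, H

    state = {"u": None}

    def neg_laplace(theta):
        beta, log_sig = theta[:p], theta[p:]
        di = d_inv(log_sig)
        u, H = inner(beta, log_sig, state["u"])
        state["u"] = u
        eta = X @ beta + Z @ u
        l_cond = float(y @ eta - np.logaddexp(0.0, eta).sum())
        log_det_d = 2.0 * sum(
            ls * n_lev for (_, n_lev), ls in zip(blocks, log_sig)
        )
        sign, log_det_h = np.linalg.slogdet(H)
        ll = (l_cond - 0.5 * float(di @ u ** 2)
              - 0.5 * log_det_d - 0.5 * log_det_h)
        return -ll

    beta0 = np.zeros(p)
    beta0[0] = np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
    theta0 = np.concatenate([beta0, np.full(len(blocks), -1.0)])
    bounds = [(None, None)] * p + [(-5.0, 3.0)] * len(blocks)
    res = minimize(neg_laplace, theta0, method="L-BFGS-B", bounds=bounds)
    beta_hat = res.x[:p]
    log_sig_hat = res.x[p:]

    def neg_ll_beta(beta):
        return neg_laplace(np.concatenate([beta, log_sig_hat]))

    hess = numdiff.approx_hess(beta_hat, neg_ll_beta)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return beta_hat, se, np.exp(log_sig_hat), res.success


def fit_sired_model(records) -> ModelResult:
    """Mixed logistic regression of siring (brood > 0) on transgene.

    Fitted by Laplace approximation with crossed random intercepts for
    batch and strain; per-contrast Wald z statistics condition on the
    estimated variance parameters.  Complete separation within a transgene
    level is flagged (estimates then sit near the parameter-space boundary
    with large standard errors).
    """
    df = validate_records(records)
    if df["sired"].nunique() < 2:
        raise ValueError(
            "siring outcome has no variation (all males "
            + ("sired" if df["sired"].iloc[0] else "failed to sire")
            + " progeny)"
        )
    if df["transgene"].nunique() < 2:
        raise ValueError("need at least two transgene levels")
    vc, notes = _vc_formulas(df)
    by_level = df.groupby("transgene")["sired"].agg(["mean"])
    separated = by_level[(by_level["mean"] == 0) | (by_level["mean"] == 1)]
    if len(separated):
        notes.append(
            "complete separation in transgene level(s) "
            f"{list(separated.index)}; estimates lie near the boundary "
            "and standard errors are unreliable"
        )
    formula = "sired ~ C(transgene)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if vc:
            import patsy

            X = patsy.dmatrix("C(transgene)", df, return_type="dataframe")
            names = list(X.columns)
            factors = {
                f: pd.Categorical(df[f]).codes for f in vc
            }
            est, sd, sigmas, ok = _laplace_logistic_mixed(
                df["sired"].to_numpy(), X.to_numpy(), factors
            )
            criterion = "Laplace approximation (mixed logistic)"
            if not ok:
                notes.append("optimizer did not report convergence")
            notes_extra = {"random_intercept_sd": dict(zip(vc, map(float, sigmas)))}
        else:
            glm = smf.glm(formula, df, family=sm.families.Binomial()).fit()
            est, sd, names = glm.params.values, glm.bse.values, list(glm.params.index)
            criterion = "ML logistic (no random terms retained)"
            notes.append("all random terms dropped; plain logistic used")
            notes_extra = {}
    z = np.asarray(est) / np.asarray(sd)
    terms = pd.DataFrame(
        {
            "term": names,
            "estimate": np.asarray(est, dtype=float),
            "se": np.asarray(sd, dtype=float),
            "stat": z,
            "stat_name": "z",
            "df_num": np.nan,
            "df_den": np.nan,
            "p_value": 2.0 * norm.sf(np.abs(z)),
        }
    )
    return ModelResult(
        method="siring model (sired vs not)",
        formula=formula + " + (1|batch) + (1|strain)",
        coding="treatment (first level is reference)",
        terms=terms,
        criterion=criterion,
        warnings=notes,
        extra=notes_extra,
    )


def sex_ratio_model(records, transgene: str | None = None) -> ModelResult:
    """Sex-ratio mixed model for the broods of one transgene.

    The table is reshaped to two rows per vial (one per progeny sex); the
    model is count ~ progeny_sex + vial with batch and strain random
    intercepts.  All-zero broods are excluded (their sex ratio is
    undefined).  The progeny-sex F statistic uses containment denominator
    degrees of freedom, n_vials - 1.
    """
    df = validate_records(records)
    if transgene is not None:
        df = df[df["transgene"] == transgene]
        if df.empty:
            raise ValueError(f"no records for transgene {transgene!r}")
    n_zero = int((df["total"] == 0).sum())
    df = df[df["total"] > 0].copy()
    notes = [f"{n_zero} all-zero brood(s) excluded"] if n_zero else []
    if len(df) < 3:
        raise ValueError("too few nonzero broods for a sex-ratio model")
    long = pd.concat(
        [
            df.assign(progeny_sex="female", count=df["n_female"]),
            df.assign(progeny_sex="male", count=df["n_male"]),
        ],
        ignore_index=True,
    )
    long["vial"] = long["male_id"].astype(str)
    n_vials = long["vial"].nunique()
    df_den = n_vials - 1
    vc, vc_notes = _vc_formulas(long)
    notes.extend(vc_notes)
    formula = "count ~ C(progeny_sex) + C(vial)"
    long = long.assign(_one=1)
    terms = None
    criterion = ""
    if vc:
        # vial fixed effects absorb batch/strain, so the variance components
        # are usually degenerate; fall back to OLS if the fit fails
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(formula, long, groups="_one",
                                  vc_formula=vc).fit(reml=True)
            if np.all(np.isfinite(fit.bse_fe)):
                terms = _mixedlm_terms(fit, df_den=df_den)
                criterion = "REML (linear mixed model); F on containment df"
        except (np.linalg.LinAlgError, ValueError):
            terms = None
    if terms is None:
        fit = smf.ols(formula, long).fit()
        tvals = fit.tvalues
        terms = pd.DataFrame(
            {
                "term": fit.params.index,
                "estimate": fit.params.values,
                "se": fit.bse.values,
                "stat": tvals.values ** 2,
                "stat_name": "F",
                "df_num": 1,
                "df_den": df_den,
                "p_value": [float(f_dist.sf(t ** 2, 1, df_den))
                            for t in tvals.values],
            }
        )
        criterion = "OLS (vial fixed effects absorb grouping factors)"
        notes.append("random-effect fit degenerate; OLS estimates reported")
    # headline row: the progeny-sex effect
    sex_rows = terms[terms.term.str.contains("progeny_sex", regex=False)]
    headline = sex_rows.iloc[0]
    return ModelResult(
        method="sex-ratio model"
        + (f" (transgene: {transgene})" if transgene else ""),
        formula=formula + " + (1|batch) + (1|strain)",
        coding="treatment (female is reference: positive male term = "
               "male-biased broods)",
        terms=terms,
        criterion=criterion,
        warnings=notes,
        extra={
            "n_vials": int(n_vials),
            "sex_F": float(headline["stat"]),
            "sex_p": float(headline["p_value"]),
            "sex_estimate": float(headline["estimate"]),
        },
    )


def binomial_sex_ratio(n_female: int, n_male: int):
    """Exact two-sided binomial test of a brood's sex ratio against 1:1.

    Returns (p_value, estimate) with estimate = n_female / total.
    """
    if n_female < 0 or n_male < 0:
        raise ValueError("counts must be nonnegative")
    total = n_female + n_male
    if total == 0:
        raise ValueError("empty brood: sex ratio undefined")
    res = binomtest(int(n_female), int(total), p=0.5, alternative="two-sided")
    return float(res.pvalue), n_female / total
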