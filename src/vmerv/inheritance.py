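"""Transgenerational inheritance analysis of locus methylation.

Offspring methylation (logit scale) is modelled with maternal
methylation, paternal methylation and sex as fixed effects and random
intercepts for breeding pair and for litter nested within pair,
controlling for the non-independence of siblings and littermates:

    logit(m_offspring) = b0 + b_mat * logit(m_dam) + b_pat * logit(m_sire)
                         + b_sex * I(male) + u_pair + u_litter + e

The model is fitted by REML; fixed-effect t statistics use Satterthwaite
denominator degrees of freedom, p values are adjusted with the
Benjamini-Hochberg step-up across loci, and per-effect effect sizes are
semi-partial R^2 values.  The reference intercept is the female level
(sexes coded alphabetically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_EPS = 0.005
FIXED_EFFECTS = ("intercept", "maternal", "paternal", "sex_male")
_BOUNDARY_TOL = 1e-8


def logit_transform(m, eps: float = DEFAULT_EPS):
    """logit of a methylation fraction with boundary clamping.

    Values are clamped to [eps, 1-eps] before ln(m/(1-m)) so fully
    methylated or unmethylated observations stay finite.
    """
    if not 0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    arr = np.asarray(m, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("methylation fractions must lie in [0, 1]")
    clamped = np.clip(arr, eps, 1.0 - eps)
    out = np.log(clamped / (1.0 - clamped))
    return float(out) if out.ndim == 0 else out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def semi_partial_r2(f_stat: float, df1: float, df2: float) -> float:
    """Semi-partial R^2 of a fixed effect from its F statistic:
    (df1/df2 * F) / (1 + df1/df2 * F)."""
    if f_stat < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("F must be >= 0 and dfs > 0")
    ratio = df1 / df2 * f_stat
    return ratio / (1.0 + ratio)


@dataclass
class HeritabilityResult:
    """REML fit of the inheritance model for one locus."""

    effects: pd.DataFrame  # index: fixed effect; estimate, se, t, df, p, (q), r2
    varcomp: dict[str, float]  # pair, litter, residual variances
    n_obs: int
    n_pairs: int
    n_litters: int
    boundary: bool  # a variance component estimated at zero
    locus: str = ""
    reml_loglik: float = float("nan")
    extra: dict = field(default_factory=dict)


def _indicator(labels: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(labels)
    z = np.zeros((len(codes), codes.max() + 1))
    z[np.arange(len(codes)), codes] = 1.0
    return z


def _design(records: pd.DataFrame, eps: float):
    y = logit_transform(records["methylation"].to_numpy(), eps)
    x = np.column_stack(
        [
            np.ones(len(records)),
            logit_transform(records["maternal_methylation"].to_numpy(), eps),
            logit_transform(records["paternal_methylation"].to_numpy(), eps),
            (records["sex"].to_numpy() == "M").astype(float),
        ]
    )
    z_pair = _indicator(records["pair_id"])
    litter_key = records["pair_id"].astype(str) + "//" + records["litter_id"].astype(str)
    z_litter = _indicator(litter_key)
    return y, x, z_pair, z_litter


def _reml_pieces(theta: np.ndarray, y, x, zz_pair, zz_litter):
    """Cholesky-based REML quantities at variances theta=(pair, litter, residual)."""
    s2p, s2l, s2e = theta
    n, p = x.shape
    v = s2e * np.eye(n) + s2p * zz_pair + s2l * zz_litter
    c, low = linalg.cho_factor(v, lower=True)
    vi_y = linalg.cho_solve((c, low), y)
    vi_x = linalg.cho_solve((c, low), x)
    xtvix = x.T @ vi_x
    beta = linalg.solve(xtvix, x.T @ vi_y, assume_a="pos")
    resid = y - x @ beta
    quad = float(resid @ linalg.cho_solve((c, low), resid))
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    sign, logdet_xtvix = np.linalg.slogdet(xtvix)
    loglik = -0.5 * (logdet_v + logdet_xtvix + quad + (n - p) * np.log(2.0 * np.pi))
    return loglik, beta, xtvix


def _reml_loglik(theta, y, x, zz_pair, zz_litter) -> float:
    return _reml_pieces(np.asarray(theta, dtype=float), y, x, zz_pair, zz_litter)[0]


def _profiled_criterion(gammas, y, x, zz_pair, zz_litter) -> float:
    """-2 REML log-likelihood profiled over the residual variance,
    parameterised by variance ratios gamma = (s2_pair, s2_litter)/s2_residual."""
    g1, g2 = gammas
    n, p = x.shape
    v0 = np.eye(n) + g1 * zz_pair + g2 * zz_litter
    try:
        c, low = linalg.cho_factor(v0, lower=True)
    except linalg.LinAlgError:
        return np.inf
    vi_y = linalg.cho_solve((c, low), y)
    vi_x = linalg.cho_solve((c, low), x)
    xtvix = x.T @ vi_x
    beta = linalg.solve(xtvix, x.T @ vi_y, assume_a="pos")
    resid = y - x @ beta
    quad = float(resid @ linalg.cho_solve((c, low), resid))
    if quad <= 0:
        return np.inf
    logdet_v0 = 2.0 * float(np.sum(np.log(np.diag(c))))
    _sign, logdet_xtvix = np.linalg.slogdet(xtvix)
    return (n - p) * np.log(quad) + logdet_v0 + logdet_xtvix


def _fit_variances(y, x, zz_pair, zz_litter) -> np.ndarray:
    n, p = x.shape
    best = None
    for x0 in ([0.5, 0.5], [0.05, 0.05], [2.0, 0.2]):
        res = optimize.minimize(
            _profiled_criterion,
            x0=np.asarray(x0),
            args=(y, x, zz_pair, zz_litter),
            method="L-BFGS-B",
            bounds=[(0.0, 1e6), (0.0, 1e6)],
        )
        if best is None or res.fun < best.fun:
            best = res
    g1, g2 = best.x
    v0 = np.eye(n) + g1 * zz_pair + g2 * zz_litter
    c, low = linalg.cho_factor(v0, lower=True)
    vi_y = linalg.cho_solve((c, low), y)
    vi_x = linalg.cho_solve((c, low), x)
    beta = linalg.solve(x.T @ vi_x, x.T @ vi_y, assume_a="pos")
    resid = y - x @ beta
    s2e = float(resid @ linalg.cho_solve((c, low), resid)) / (n - p)
    return np.array([g1 * s2e, g2 * s2e, s2e])


def _satterthwaite(theta, y, x, zz_pair, zz_litter) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-effect Satterthwaite denominator df.

    df_j = 2 f_j^2 / (g_j' A g_j) with f_j the sampling variance of the
    j-th fixed effect as a function of the variance components, g_j its
    gradient (central differences) and A the asymptotic covariance of
    the variance-component estimates (inverse observed REML
    information).
    """
    n, p = x.shape
    theta = np.asarray(theta, dtype=float)
    # variance components estimated at the zero boundary are held fixed
    # (one-sided curvature there is meaningless); with both random effects at
    # zero this reduces df to the residual n - p, matching the OLS limit
    active = [k for k in range(2) if theta[k] > _BOUNDARY_TOL * theta[2]] + [2]

    def cov_beta_diag(th):
        _ll, _beta, xtvix = _reml_pieces(th, y, x, zz_pair, zz_litter)
        return np.diag(np.linalg.inv(xtvix))

    f0 = cov_beta_diag(theta)
    steps = np.maximum(1e-4 * np.maximum(theta, theta[2]), 1e-8)

    grads = np.zeros((p, len(active)))
    for i, k in enumerate(active):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += steps[k]
        tm[k] -= steps[k]
        try:
            fp = cov_beta_diag(tp)
            fm = cov_beta_diag(tm)
        except linalg.LinAlgError:
            tm[k] = theta[k]
            fp = cov_beta_diag(tp)
            fm = f0
        grads[:, i] = (fp - fm) / (tp[k] - tm[k])

    def ll(th):
        return _reml_loglik(th, y, x, zz_pair, zz_litter)

    m = len(active)
    hess = np.zeros((m, m))
    try:
        for i, a in enumerate(active):
            for j_, b in enumerate(active[i:], start=i):
                ha, hb = steps[a], steps[b]
                if a == b:
                    hess[i, i] = (
                        ll(theta + 2 * _e(a, ha)) - 2 * ll(theta) + ll(theta - 2 * _e(a, ha))
                    ) / (4 * ha * ha)
                else:
                    hess[i, j_] = hess[j_, i] = (
                        ll(theta + _e(a, ha) + _e(b, hb))
                        - ll(theta + _e(a, ha) - _e(b, hb))
                        - ll(theta - _e(a, ha) + _e(b, hb))
                        + ll(theta - _e(a, ha) - _e(b, hb))
                    ) / (4 * ha * hb)
        acov = np.linalg.inv(-hess)
    except (np.linalg.LinAlgError, linalg.LinAlgError):
        acov = np.linalg.pinv(-hess)

    dfs = np.empty(p)
    for j in range(p):
        denom = float(grads[j] @ acov @ grads[j])
        if denom <= 0 or not np.isfinite(denom):
            dfs[j] = n - p
        else:
            dfs[j] = min(max(2.0 * f0[j] ** 2 / denom, 1.0), float(n - p))
    return dfs, f0, ll(theta)


def _e(k: int, h: float) -> np.ndarray:
    v = np.zeros(3)
    v[k] = h
    return v


def fit_inheritance_model(
    records: pd.DataFrame, eps: float = DEFAULT_EPS, locus: str = ""
) -> HeritabilityResult:
    """REML fit of the inheritance mixed model for one locus.

    ``records`` needs columns animal_id, sex (F/M), methylation,
    maternal_methylation, paternal_methylation, pair_id, litter_id.
    Offspring and parental levels are logit-transformed with the same
    clamping.  Returns fixed-effect estimates with Satterthwaite-df t
    tests and semi-partial R^2, plus the pair/litter/residual variance
    components; a variance component estimated at zero is flagged as a
    boundary fit.
    """
    required = {
        "sex", "methylation", "maternal_methylation", "paternal_methylation",
        "pair_id", "litter_id",
    }
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"pedigree records lack columns: {sorted(missing)}")
    n_pairs = records["pair_id"].nunique()
    litter_key = records["pair_id"].astype(str) + "//" + records["litter_id"].astype(str)
    n_litters = litter_key.nunique()
    if n_pairs < 2 or n_litters < 2:
        raise ValueError("need at least 2 breeding pairs and 2 litters")

    y, x, z_pair, z_litter = _design(records, eps)
    zz_pair = z_pair @ z_pair.T
    zz_litter = z_litter @ z_litter.T

    theta = _fit_variances(y, x, zz_pair, zz_litter)
    boundary = bool(np.any(theta[:2] <= _BOUNDARY_TOL * theta[2]))
    if boundary:
        logger.info("locus %s: variance component estimated at zero (boundary fit)", locus)

    _ll, beta, _xtvix = _reml_pieces(theta, y, x, zz_pair, zz_litter)
    dfs, var_beta, loglik = _satterthwaite(theta, y, x, zz_pair, zz_litter)
    se = np.sqrt(var_beta)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=dfs)
    r2 = np.array([semi_partial_r2(tt * tt, 1.0, df) for tt, df in zip(t, dfs)])

    effects = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "t": t,
            "df": dfs,
            "p": p,
            "r2": r2,
        },
        index=list(FIXED_EFFECTS),
    )
    return HeritabilityResult(
        effects=effects,
        varcomp={"pair": float(theta[0]), "litter": float(theta[1]), "residual": float(theta[2])},
        n_obs=len(records),
        n_pairs=int(n_pairs),
        n_litters=int(n_litters),
        boundary=boundary,
        locus=locus,
        reml_loglik=float(loglik),
    )


def analyze_loci(
    panels: dict[str, pd.DataFrame], eps: float = DEFAULT_EPS, bh_family: str = "global"
) -> pd.DataFrame:
    """Fit the inheritance model per locus and BH-adjust the fixed-effect p values.

    ``bh_family="global"`` adjusts all fixed-effect p values across loci
    jointly (the default, matching a joint q table over loci);
    ``"per_locus"`` adjusts within each locus.  The intercept is not a
    hypothesis of interest and is excluded from the adjustment family.
    """
    if bh_family not in ("global", "per_locus"):
        raise ValueError("bh_family must be 'global' or 'per_locus'")
    rows = []
    for locus, records in panels.items():
        res = fit_inheritance_model(records, eps=eps, locus=locus)
        for effect, row in res.effects.iterrows():
            rows.append(
                {
                    "locus": locus,
                    "effect": effect,
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "t": row["t"],
                    "df": row["df"],
                    "p": row["p"],
                    "r2": row["r2"],
                    "var_pair": res.varcomp["pair"],
                    "var_litter": res.varcomp["litter"],
                    "var_residual": res.varcomp["residual"],
                    "boundary": res.boundary,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    testable = out["effect"] != "intercept"
    if bh_family == "global":
        out.loc[testable, "q"] = bh_adjust(out.loc[testable, "p"].to_numpy())
    else:
        for locus in out["locus"].unique():
            sel = testable & (out["locus"] == locus)
            out.loc[sel, "q"] = bh_adjust(out.loc[sel, "p"].to_numpy())
    return out


@dataclass
class LitterMeanTest:
    statistic: float
    pvalue: float
    n_high: int
    n_low: int
    flagged: bool = False


def litter_mean_test(high_group, low_group, equal_var: bool = False) -> LitterMeanTest:
    """One-sided unpaired t test that litters of highly methylated mothers
    have higher mean methylation than litters of lowly methylated mothers.

    Welch's test by default (``equal_var=True`` for the pooled-variance
    version).  Two zero-variance groups with equal means return p = 0.5
    by convention, flagged.
    """
    hi = np.asarray(high_group, dtype=float)
    lo = np.asarray(low_group, dtype=float)
    if hi.size < 2 or lo.size < 2:
        raise ValueError("need at least 2 litter means per group")
    if np.ptp(hi) == 0 and np.ptp(lo) == 0:
        if hi.mean() == lo.mean():
            return LitterMeanTest(0.0, 0.5, hi.size, lo.size, flagged=True)
        p = 0.0 if hi.mean() > lo.mean() else 1.0
        return LitterMeanTest(np.inf if p == 0 else -np.inf, p, hi.size, lo.size, flagged=True)
    res = stats.ttest_ind(hi, lo, equal_var=equal_var, alternative="greater")
    return LitterMeanTest(float(res.statistic), float(res.pvalue), hi.size, lo.size)
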