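"""Pre-registered statistics: normality gating, Spearman correlations
with confidence intervals, mixed-effects moderation with simple slopes,
and correlation / regression power solvers.

The moderation model is a linear mixed model with a subject random
intercept over the balanced two-condition (low/high image intensity)
design:

    outcome_ij = b0 + b1 * intensity_ij + b2 * moderator_i
                 + b3 * moderator_i * intensity_ij + u_i + e_ij

With exactly two observations per subject the design decomposes into
orthogonal between-subject (subject means) and within-subject
(high - low differences) strata, so the REML solution is available in
closed form: the within stratum is an ordinary regression of the
difference scores on the moderator, the between stratum a regression of
the subject means. Fixed effects, their standard errors, and the REML
variance components from this decomposition are algebraically identical
to the iterative mixed-model fit, and the between-within denominator
degrees of freedom (n_subjects - 2 for every term) are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class NormalityResult:
    W: float
    p: float


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p: float
    ci: tuple[float, float]


@dataclass
class TermEstimate:
    estimate: float
    se: float
    t: float
    df: int
    p: float
    ci: tuple[float, float]


@dataclass
class ModerationResult:
    terms: dict[str, TermEstimate]
    random_intercept_var: float
    residual_var: float
    n_subjects: int
    n_obs: int
    moderator_sd: float
    #: covariance of (intensity, interaction) estimates, needed for slopes
    within_cov: np.ndarray


@dataclass
class SimpleSlope:
    at_sd: float
    estimate: float
    se: float
    t: float
    df: int
    p: float
    ci: tuple[float, float]


@dataclass
class PowerResult:
    kind: str
    alpha: float
    power: float
    inputs: dict
    answer: float


def shapiro_wilk(x) -> NormalityResult:
    """Shapiro-Wilk normality test (Royston approximation via scipy)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample; normality test undefined")
    W, p = stats.shapiro(x)
    return NormalityResult(W=float(W), p=float(p))


def spearman_ci(x, y, ci_level: float = 0.95) -> CorrelationResult:
    """Spearman rank correlation with t-approximation p-value and a
    Bonett-Wright Fisher-transform confidence interval.

    rho is the Pearson correlation of mid-ranks (average ranks on ties);
    the CI uses SE = sqrt((1 + rho^2 / 2) / (n - 3)) on the atanh scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
        ci = (rho, rho) if n <= 3 else (np.sign(rho) * 1.0,) * 2
        return CorrelationResult(rho=rho, n=n, p=p, ci=(float(ci[0]), float(ci[1])))
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    se = np.sqrt((1.0 + rho**2 / 2.0) / (n - 3))
    zcrit = stats.norm.ppf(1.0 - (1.0 - ci_level) / 2.0)
    lo, hi = np.tanh(np.arctanh(rho) + np.array([-1, 1]) * zcrit * se)
    return CorrelationResult(rho=rho, n=n, p=float(p), ci=(float(lo), float(hi)))


def prepare_moderation_table(
    acc_low, acc_high, moderator, subjects=None
) -> pd.DataFrame:
    """Long-format moderation table: two rows per subject.

    Image intensity is dummy-coded (0 = low, 1 = high); the moderator is
    grand-mean-centered across subjects.
    """
    acc_low = np.asarray(acc_low, dtype=float)
    acc_high = np.asarray(acc_high, dtype=float)
    moderator = np.asarray(moderator, dtype=float)
    n = acc_low.size
    if not (acc_high.size == n and moderator.size == n):
        raise ValueError("per-subject vectors must align")
    if subjects is None:
        subjects = [f"sub-{i + 1:03d}" for i in range(n)]
    elif len(subjects) != n:
        raise ValueError("subject ids do not align with scores")
    centered = moderator - moderator.mean()
    rows = []
    for s, lo, hi, m in zip(subjects, acc_low, acc_high, centered):
        rows.append({"subject": s, "intensity": 0, "moderator": m, "outcome": lo})
        rows.append({"subject": s, "intensity": 1, "moderator": m, "outcome": hi})
    return pd.DataFrame(rows)


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS of y on [1, x]: coefficients, coefficient covariance, residual
    variance (ddof = 2)."""
    n = y.size
    X = np.column_stack([np.ones(n), x])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - 2)
    return beta, sigma2 * xtx_inv, sigma2


def fit_moderation(table: pd.DataFrame, df_method: str = "between-within") -> ModerationResult:
    """Fit the random-intercept moderation model by exact closed-form REML.

    Requires the balanced design: exactly one low- and one high-intensity
    row per subject. Denominator df are between-within (n_subjects - 2
    for all four terms).
    """
    if df_method != "between-within":
        raise ValueError("only the between-within df method is supported")
    required = {"subject", "intensity", "moderator", "outcome"}
    if not required <= set(table.columns):
        raise ValueError(f"table missing columns: {sorted(required - set(table.columns))}")
    wide = table.pivot_table(
        index="subject", columns="intensity", values=["outcome", "moderator"], aggfunc="first"
    )
    counts = table.groupby("subject").size()
    if (counts != 2).any() or wide["outcome"].isna().any().any():
        raise ValueError(
            "unbalanced table: every subject needs exactly one low- and one "
            "high-intensity row; complete the data listwise first"
        )
    n = len(wide)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    y0 = wide["outcome"][0].to_numpy(dtype=float)
    y1 = wide["outcome"][1].to_numpy(dtype=float)
    x = wide["moderator"][0].to_numpy(dtype=float)

    # within stratum: difference scores estimate b1 (intensity) and b3
    d = y1 - y0
    beta_w, cov_w, sigma2_d = _ols(d, x)
    # between stratum: subject means estimate b0 + b1/2 and b2 + b3/2
    m = (y0 + y1) / 2.0
    beta_b, cov_b, sigma2_m = _ols(m, x)

    sigma2_e = sigma2_d / 2.0
    sigma2_u = max(sigma2_m - sigma2_e / 2.0, 0.0)

    b1, b3 = beta_w
    b0 = beta_b[0] - b1 / 2.0
    b2 = beta_b[1] - b3 / 2.0
    var = {
        "intensity": cov_w[0, 0],
        "interaction": cov_w[1, 1],
        "intercept": cov_b[0, 0] + cov_w[0, 0] / 4.0,
        "moderator": cov_b[1, 1] + cov_w[1, 1] / 4.0,
    }
    est = {"intercept": b0, "intensity": b1, "moderator": b2, "interaction": b3}
    df = n - 2
    tcrit = stats.t.ppf(0.975, df)
    terms = {}
    for name in ("intercept", "intensity", "moderator", "interaction"):
        se = float(np.sqrt(var[name]))
        t = est[name] / se
        terms[name] = TermEstimate(
            estimate=float(est[name]),
            se=se,
            t=float(t),
            df=df,
            p=float(2.0 * stats.t.sf(abs(t), df)),
            ci=(float(est[name] - tcrit * se), float(est[name] + tcrit * se)),
        )
    return ModerationResult(
        terms=terms,
        random_intercept_var=float(sigma2_u),
        residual_var=float(sigma2_e),
        n_subjects=n,
        n_obs=2 * n,
        moderator_sd=float(np.std(x, ddof=1)),
        within_cov=cov_w,
    )


def simple_slopes(result: ModerationResult, sd_offsets=(-1.0, 1.0)) -> list[SimpleSlope]:
    """Conditional effect of intensity at moderator = mean + k * SD.

    slope(k) = b_intensity + k * SD * b_interaction, with variance from
    the within-stratum coefficient covariance.
    """
    b1 = result.terms["intensity"].estimate
    b3 = result.terms["interaction"].estimate
    df = result.terms["intensity"].df
    tcrit = stats.t.ppf(0.975, df)
    slopes = []
    for k in sd_offsets:
        offset = k * result.moderator_sd
        est = b1 + offset * b3
        var = (
            result.within_cov[0, 0]
            + offset**2 * result.within_cov[1, 1]
            + 2.0 * offset * result.within_cov[0, 1]
        )
        se = float(np.sqrt(var))
        t = est / se
        slopes.append(
            SimpleSlope(
                at_sd=float(k),
                estimate=float(est),
                se=se,
                t=float(t),
                df=df,
                p=float(2.0 * stats.t.sf(abs(t), df)),
                ci=(float(est - tcrit * se), float(est + tcrit * se)),
            )
        )
    return slopes


# ---------------------------------------------------------------------------
# power / sensitivity solvers


def correlation_power(n: int, r: float, alpha: float = 0.05) -> float:
    """Two-sided power of the correlation test of H0: rho = 0.

    Fisher-z approximation with the r/(2(n-1)) bias correction and a
    t-derived critical correlation (the convention of the standard R
    power calculators), so printed sample sizes reproduce exactly.
    """
    if not 0 < r < 1:
        raise ValueError("r must be in (0, 1)")
    if n < 4:
        raise ValueError("n must be at least 4")
    ttt = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    rc = np.sqrt(ttt**2 / (ttt**2 + n - 2))
    zr = np.arctanh(r) + r / (2.0 * (n - 1))
    zrc = np.arctanh(rc)
    root = np.sqrt(n - 3)
    return float(stats.norm.cdf((zr - zrc) * root) + stats.norm.cdf((-zr - zrc) * root))


def power_n_for_r(r: float, alpha: float = 0.05, power: float = 0.80) -> PowerResult:
    """Smallest integer n whose two-sided correlation power reaches target."""
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    n = 4
    # the small slack keeps the search stable when the target power is hit
    # exactly up to floating-point error (e.g. r from min_detectable_r)
    while correlation_power(n, r, alpha) < power - 1e-9:
        n += 1
        if n > 10**7:
            raise RuntimeError("sample-size search failed to converge")
    return PowerResult(
        kind="n_for_r", alpha=alpha, power=power, inputs={"r": r}, answer=float(n)
    )


def min_detectable_r(n: int, alpha: float = 0.05, power: float = 0.80) -> PowerResult:
    """Smallest correlation detectable with the given n, alpha, power."""
    if n < 4:
        raise ValueError("n must be at least 4")
    r = optimize.brentq(
        lambda rr: correlation_power(n, rr, alpha) - power, 1e-9, 1 - 1e-12, xtol=1e-12
    )
    return PowerResult(
        kind="r_for_n", alpha=alpha, power=power, inputs={"n": n}, answer=float(r)
    )


def regression_f_power(
    f: float, n: int, n_predictors: int, test_df: int = 1, alpha: float = 0.05
) -> float:
    """Power of the F test of `test_df` coefficients in a regression with
    n_predictors predictors, at Cohen's effect size f (lambda = f^2 *
    (test_df + denominator df + 1))."""
    v = n - n_predictors - 1
    if v <= 0:
        raise ValueError("n must exceed n_predictors + 1")
    lam = f**2 * (test_df + v + 1)
    crit = stats.f.ppf(1.0 - alpha, test_df, v)
    return float(stats.ncf.sf(crit, test_df, v, lam))


def min_detectable_f(
    n: int, n_predictors: int, test_df: int = 1, alpha: float = 0.05, power: float = 0.80
) -> PowerResult:
    """Smallest Cohen's f detectable by the noncentral-F test.

    Solves for the noncentrality giving the target power, then converts
    via f^2 = lambda / (test_df + denominator_df + 1).
    """
    v = n - n_predictors - 1
    if v <= 0:
        raise ValueError("n must exceed n_predictors + 1")
    crit = stats.f.ppf(1.0 - alpha, test_df, v)

    def gap(lam: float) -> float:
        return stats.ncf.sf(crit, test_df, v, lam) - power

    if gap(1e-9) > 0:
        raise ValueError("requested power is below the test's size; no solution")
    lam = optimize.brentq(gap, 1e-9, 1e4, xtol=1e-12)
    f = float(np.sqrt(lam / (test_df + v + 1)))
    return PowerResult(
        kind="f_for_n",
        alpha=alpha,
        power=power,
        inputs={"n": n, "n_predictors": n_predictors, "test_df": test_df},
        answer=f,
    )


def correlation_battery(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    gate_alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlations for each (x, y) column pair, gated by
    Shapiro-Wilk normality checks.

    Pairwise-complete deletion per cell; the rank method is used
    regardless of the gate (and would be mandated whenever either
    variable fails normality at ``gate_alpha``).
    """
    rows = []
    for xcol, ycol in pairs:
        sub = table.loc[:, [xcol, ycol]].dropna()
        n = len(sub)
        if n < 4:
            raise ValueError(f"fewer than 4 complete pairs for ({xcol}, {ycol})")
        x = sub[xcol].to_numpy(dtype=float)
        y = sub[ycol].to_numpy(dtype=float)
        wx = shapiro_wilk(x)
        wy = shapiro_wilk(y)
        res = spearman_ci(x, y)
        rows.append(
            {
                "x": xcol,
                "y": ycol,
                "n": n,
                "rho": res.rho,
                "p": res.p,
                "ci_low": res.ci[0],
                "ci_high": res.ci[1],
                "x_shapiro_p": wx.p,
                "y_shapiro_p": wy.p,
                "nonnormal": bool(wx.p < gate_alpha or wy.p < gate_alpha),
                "method": "spearman",
            }
        )
    return pd.DataFrame(rows)
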