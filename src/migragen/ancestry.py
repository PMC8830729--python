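"""Does migratory behaviour depend on genetic ancestry?

Regressions of individual migratory behaviour on the admixture
proportion Q of one cluster at a time (Q columns are compositional; one
predictor per model): ordinary least squares for the continuous range
overlap index, maximum-likelihood logistic regression for the binary
migrant/resident classification, and random-intercept variants that
statistically control for ecotype (linear: ML mixed model; logistic:
adaptive Gauss-Hermite quadrature, 15 nodes).  Ecotype-level group
comparisons use Kruskal-Wallis and pairwise two-sided Wilcoxon rank-sum
tests with no multiplicity correction (raw pairwise p-values).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "regress_io_on_q",
    "regress_migrant_on_q",
    "regress_with_ecotype",
    "ecotype_group_tests",
]


@dataclass
class RegressionResult:
    """One behaviour-on-ancestry regression fit."""

    response: str
    predictor: str
    family: str                  # 'linear' | 'logistic'
    beta: float
    se: float
    stat: float                  # t (linear) or z (logistic)
    p: float
    r2: float                    # R^2 or McFadden pseudo-R^2
    aic: float
    n: int
    random_effect_var: float | None = None
    flags: list = field(default_factory=list)

    def summary(self):
        kind = {"linear": "t", "logistic": "z"}[self.family]
        lines = [
            f"{self.family} regression: {self.response} ~ {self.predictor}"
            + (" + (1|ecotype)" if self.random_effect_var is not None else ""),
            f"n = {self.n}",
            f"beta = {self.beta:.4f}  se = {self.se:.4f}  "
            f"{kind} = {self.stat:.3f}  p = {self.p:.4g}",
            f"R2 = {self.r2:.4f}  AIC = {self.aic:.2f}",
        ]
        if self.random_effect_var is not None:
            lines.append(f"ecotype intercept variance = {self.random_effect_var:.5f}")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def _check_xy(y, q, min_n=3):
    y = np.asarray(y, dtype=float)
    q = np.asarray(q, dtype=float)
    if y.shape[0] != q.shape[0]:
        raise ValueError("response and predictor lengths differ")
    if np.isnan(y).any() or np.isnan(q).any():
        raise ValueError("inputs must be complete (mask upstream)")
    if y.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if np.ptp(q) == 0:
        raise ValueError("constant predictor")
    return y, q


def regress_io_on_q(io, q, response="IO", predictor="Q"):
    """OLS of the overlap index on an admixture proportion."""
    y, x = _check_xy(io, q)
    model = sm.OLS(y, sm.add_constant(x))
    res = model.fit()
    return RegressionResult(
        response=response, predictor=predictor, family="linear",
        beta=float(res.params[1]), se=float(res.bse[1]),
        stat=float(res.tvalues[1]), p=float(res.pvalues[1]),
        r2=float(res.rsquared), aic=float(res.aic), n=len(y),
    )


def regress_migrant_on_q(status, q, response="nsd_class", predictor="Q"):
    """ML logistic regression of migrant status (0/1) on ancestry.

    Perfect separation is reported via a flag on the result rather than
    silently diverging estimates.
    """
    y, x = _check_xy(status, q)
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ValueError("status must be 0/1")
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    flags = []
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = sm.Logit(y, sm.add_constant(x)).fit(disp=False, maxiter=200)
        except Exception:
            flags.append("perfect separation suspected; penalized refit")
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(x)).fit_regularized(
                alpha=1e-4, disp=False
            )
    if not getattr(res, "mle_retvals", {"converged": True}).get("converged", True):
        flags.append("non-convergence")
    llf = float(res.llf)
    llnull = float(sm.Logit(y, np.ones((len(y), 1))).fit(disp=False).llf)
    mcfadden = 1.0 - llf / llnull if llnull != 0 else np.nan
    beta = float(np.asarray(res.params)[1])
    se = float(np.asarray(res.bse)[1]) if hasattr(res, "bse") else np.nan
    z = beta / se if se and np.isfinite(se) else np.nan
    return RegressionResult(
        response=response, predictor=predictor, family="logistic",
        beta=beta, se=se, stat=float(z),
        p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        r2=float(mcfadden), aic=float(-2 * llf + 2 * 2), n=len(y), flags=flags,
    )


# ---------------------------------------------------------------------------
# Random-intercept (ecotype) variants

def _linear_mixed(y, x, groups):
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "q": x, "eco": groups})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.mixedlm("y ~ q", df, groups=df["eco"]).fit(reml=False)
    var_re = float(res.cov_re.iloc[0, 0])
    k = 4  # intercept, slope, residual var, random-intercept var
    aic = float(-2 * res.llf + 2 * k)
    flags = []
    if var_re < 1e-3 * np.var(y):
        # at the boundary the mixed model IS the fixed model; report it exactly
        flags.append("random-intercept variance at zero boundary")
        fixed = sm.OLS(y, sm.add_constant(x)).fit()
        return RegressionResult(
            response="", predictor="", family="linear",
            beta=float(fixed.params[1]), se=float(fixed.bse[1]),
            stat=float(fixed.tvalues[1]), p=float(fixed.pvalues[1]),
            r2=float(fixed.rsquared), aic=float(fixed.aic), n=len(y),
            random_effect_var=0.0, flags=flags,
        )
    # marginal R2: fixed-effect variance over total
    fixed = res.params["q"] * x
    denom = np.var(fixed) + var_re + float(res.scale)
    r2 = float(np.var(fixed) / denom) if denom > 0 else np.nan
    return RegressionResult(
        response="", predictor="", family="linear",
        beta=float(res.params["q"]), se=float(res.bse["q"]),
        stat=float(res.tvalues["q"]), p=float(res.pvalues["q"]),
        r2=r2, aic=aic, n=len(y),
        random_effect_var=max(var_re, 0.0), flags=flags,
    )


def _logistic_gh_loglik(params, x_design, y, group_idx, nodes, weights):
    """Marginal log-likelihood via adaptive Gauss-Hermite quadrature."""
    beta = params[:-1]
    sigma = np.exp(params[-1])
    eta = x_design @ beta
    total = 0.0
    for idx in group_idx:
        e, yy = eta[idx], y[idx]

        def h(u):
            lin = e + u
            # log Bernoulli likelihood + log prior
            return (yy * lin - np.logaddexp(0.0, lin)).sum() \
                - 0.5 * u**2 / sigma**2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)

        # Newton mode-finding for the adaptive shift
        u_hat = 0.0
        for _ in range(50):
            p = 1.0 / (1.0 + np.exp(-(e + u_hat)))
            grad = (yy - p).sum() - u_hat / sigma**2
            hess = -(p * (1 - p)).sum() - 1.0 / sigma**2
            step = grad / hess
            u_hat -= step
            if abs(step) < 1e-10:
                break
        p = 1.0 / (1.0 + np.exp(-(e + u_hat)))
        curv = (p * (1 - p)).sum() + 1.0 / sigma**2
        scale = np.sqrt(2.0 / curv)
        u_q = u_hat + scale * nodes
        h_q = np.array([h(u) for u in u_q])
        total += np.log(scale) + np.log((weights * np.exp(h_q + nodes**2)).sum()
                                        + 1e-300)
    return total


def _logistic_mixed(y, x, groups, n_nodes=15):
    nodes, weights = hermgauss(n_nodes)
    x_design = np.column_stack([np.ones_like(x), x])
    codes, _ = pd.factorize(groups)
    group_idx = [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]

    start_logit = sm.Logit(y, x_design).fit(disp=False)
    x0 = np.r_[np.asarray(start_logit.params), np.log(0.5)]

    def nll(params):
        return -_logistic_gh_loglik(params, x_design, y, group_idx, nodes, weights)

    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            bounds=[(None, None)] * 2 + [(-10.0, 5.0)])
    from statsmodels.tools.numdiff import approx_hess

    hess = approx_hess(res.x, nll)
    try:
        cov = np.linalg.inv(hess)
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se = np.nan
    sigma2 = float(np.exp(res.x[-1]) ** 2)
    flags = []
    if sigma2 < 1e-3:
        # boundary: the marginal model is plain logistic regression
        flags.append("random-intercept variance at zero boundary")
        fixed = regress_migrant_on_q(y, x)
        fixed.random_effect_var = 0.0
        fixed.flags = flags + fixed.flags
        return fixed
    beta = float(res.x[1])
    z = beta / se if se and np.isfinite(se) else np.nan
    llf = -float(res.fun)
    llnull = float(sm.Logit(y, np.ones((len(y), 1))).fit(disp=False).llf)
    return RegressionResult(
        response="", predictor="", family="logistic",
        beta=beta, se=se, stat=float(z),
        p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        r2=float(1.0 - llf / llnull) if llnull != 0 else np.nan,
        aic=float(2 * res.fun + 2 * 3), n=len(y),
        random_effect_var=sigma2, flags=flags,
    )


def regress_with_ecotype(response_values, q, ecotype, family="linear",
                         response="IO", predictor="Q"):
    """Behaviour ~ Q + (1 | ecotype), fit by maximum likelihood.

    Linear responses use a Gaussian random-intercept model (profile ML);
    binary responses a logistic random-intercept model integrated by
    adaptive Gauss-Hermite quadrature with 15 nodes.  A variance
    estimate at the zero boundary is reported as 0 with a flag.
    """
    y, x = _check_xy(response_values, q)
    ecotype = np.asarray(ecotype)
    if len(np.unique(ecotype)) < 2:
        raise ValueError("need >= 2 ecotypes for a random intercept")
    if family == "linear":
        result = _linear_mixed(y, x, ecotype)
    elif family == "logistic":
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("both classes must be present")
        result = _logistic_mixed(y, x, ecotype)
    else:
        raise ValueError(f"unknown family {family!r}")
    result.response = response
    result.predictor = predictor
    return result


def ecotype_group_tests(values, labels, exact_threshold=20):
    """Kruskal-Wallis across ecotypes plus pairwise Wilcoxon rank-sum.

    Pairwise tests are two-sided, exact when both groups are smaller
    than ``exact_threshold``, and otherwise use the normal approximation
    with tie correction (no continuity correction, matching the
    chi-square/z-square equivalence with Kruskal-Wallis at two groups).
    No multiplicity correction is applied.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [g for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[labels == g] for g in groups]
    for g, s in zip(groups, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has < 2 values")
    kw_p = float(stats.kruskal(*samples).pvalue)
    pw = pd.DataFrame(np.ones((len(groups), len(groups))),
                      index=groups, columns=groups)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            vi, vj = samples[i], samples[j]
            if (len(vi) < exact_threshold and len(vj) < exact_threshold
                    and len(np.unique(np.r_[vi, vj])) == len(vi) + len(vj)):
                p = float(stats.mannwhitneyu(vi, vj, alternative="two-sided",
                                             method="exact").pvalue)
            else:
                p = float(stats.mannwhitneyu(
                    vi, vj, alternative="two-sided", method="asymptotic",
                    use_continuity=False).pvalue)
            pw.iloc[i, j] = pw.iloc[j, i] = p
    return kw_p, pw
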