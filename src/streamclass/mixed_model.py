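"""Random-intercept mixed-effects test for per-trial correlations.

Per-trial correlation coefficients cluster within subjects, so testing
whether their mean differs from zero uses the one-way random-intercept
model

    rho_ij = mu + b_j + e_ij,   b_j ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2)

fitted by restricted maximum likelihood.  The fixed intercept is tested
with a t statistic whose degrees of freedom come from the Satterthwaite
approximation (second-order expansion of Var(mu_hat) in the variance
components, with the component covariance taken from the curvature of the
restricted log-likelihood).  The random effect is tested by a restricted
likelihood ratio against the no-random-effect model, referred to the
50:50 mixture of a point mass at zero and chi-square(1) appropriate for a
variance component on the boundary.

The model is fitted in closed form up to a one-dimensional search over the
variance ratio, which makes large calibration simulations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["MixedModelResult", "fit_random_intercept", "mixed_model_test"]


@dataclass(frozen=True)
class MixedModelResult:
    mu_hat: float
    se: float
    t_stat: float
    df: float
    p_fixed: float
    subject_variance: float
    residual_variance: float
    lrt_stat: float
    p_random: float
    n_obs: int
    n_groups: int
    singular: bool


def _suff_stats(y: np.ndarray, groups: np.ndarray):
    uniq, inv = np.unique(groups, return_inverse=True)
    n_j = np.bincount(inv).astype(float)
    sum_j = np.bincount(inv, weights=y)
    mean_j = sum_j / n_j
    ss_within = float(np.sum(y ** 2) - np.sum(n_j * mean_j ** 2))
    return n_j, mean_j, ss_within


def _reml_loglik(sb2: float, se2: float, n_j, mean_j, ss_within) -> float:
    """Restricted log-likelihood (up to an additive constant)."""
    if se2 <= 0 or sb2 < 0:
        return -np.inf
    d_j = se2 + n_j * sb2
    w_j = n_j / d_j
    mu = float(np.sum(w_j * mean_j) / np.sum(w_j))
    logdet = float(np.sum((n_j - 1) * np.log(se2) + np.log(d_j)))
    quad = ss_within / se2 + float(np.sum(n_j * (mean_j - mu) ** 2 / d_j))
    return -0.5 * (logdet + np.log(np.sum(w_j)) + quad)


def _profile_se2(lam: float, n_j, mean_j, ss_within) -> float:
    """REML estimate of sigma_e^2 at fixed ratio lam = sigma_b^2/sigma_e^2."""
    d_j = 1.0 + n_j * lam
    w_j = n_j / d_j
    mu = float(np.sum(w_j * mean_j) / np.sum(w_j))
    quad = ss_within + float(np.sum(n_j * (mean_j - mu) ** 2 / d_j))
    return quad / (np.sum(n_j) - 1.0)


def fit_random_intercept(y, groups) -> MixedModelResult:
    """Fit the one-way random-intercept model by REML and test both effects.

    Parameters
    ----------
    y:
        Observations (e.g. per-trial correlation coefficients).
    groups:
        Group (subject) label per observation.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 1 or len(y) != len(groups):
        raise ValueError("y and groups must be 1-d and equally long")
    n_j, mean_j, ss_within = _suff_stats(y, groups)
    J, N = len(n_j), int(n_j.sum())
    if J < 2 or N < 3:
        raise ValueError("need at least 2 groups and 3 observations")

    def neg_profiled(log_lam):
        lam = np.exp(log_lam)
        se2 = _profile_se2(lam, n_j, mean_j, ss_within)
        return -_reml_loglik(lam * se2, se2, n_j, mean_j, ss_within)

    opt = optimize.minimize_scalar(neg_profiled, bounds=(-30.0, 10.0), method="bounded")
    lam = float(np.exp(opt.x))
    se2 = _profile_se2(lam, n_j, mean_j, ss_within)
    sb2 = lam * se2
    ll_full = _reml_loglik(sb2, se2, n_j, mean_j, ss_within)

    # null model: no random effect
    se2_null = _profile_se2(0.0, n_j, mean_j, ss_within)
    ll_null = _reml_loglik(0.0, se2_null, n_j, mean_j, ss_within)
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    singular = lrt < 1e-8 or sb2 < 1e-12 * se2
    if singular:
        sb2, se2, ll_full, lrt = 0.0, se2_null, ll_null, 0.0
    # boundary-corrected reference distribution
    p_random = 0.5 * stats.chi2.sf(lrt, 1) if lrt > 0 else 1.0

    d_j = se2 + n_j * sb2
    w_j = n_j / d_j
    mu = float(np.sum(w_j * mean_j) / np.sum(w_j))
    var_mu = 1.0 / float(np.sum(w_j))
    se_mu = np.sqrt(var_mu)
    t_stat = mu / se_mu

    if singular:
        df = float(N - 1)
    else:
        df = _satterthwaite_df(sb2, se2, n_j, mean_j, ss_within)
    p_fixed = 2.0 * stats.t.sf(abs(t_stat), df)

    return MixedModelResult(
        mu_hat=mu, se=se_mu, t_stat=t_stat, df=df, p_fixed=float(p_fixed),
        subject_variance=sb2, residual_variance=se2,
        lrt_stat=lrt, p_random=float(p_random),
        n_obs=N, n_groups=J, singular=singular,
    )


def _satterthwaite_df(sb2, se2, n_j, mean_j, ss_within) -> float:
    """df = 2 f^2 / (g' A g) with f = Var(mu_hat), g its gradient in the
    variance components and A the inverse curvature of the restricted
    log-likelihood at the REML estimate."""
    d_j = se2 + n_j * sb2
    w_sum = float(np.sum(n_j / d_j))
    f = 1.0 / w_sum
    # analytic gradient of f wrt (sb2, se2)
    d_wsum_db = float(np.sum(-n_j ** 2 / d_j ** 2))
    d_wsum_de = float(np.sum(-n_j / d_j ** 2))
    g = np.array([-d_wsum_db, -d_wsum_de]) / w_sum ** 2

    # numeric Hessian of the restricted log-likelihood
    h_b = max(1e-8, 1e-4 * max(sb2, se2))
    h_e = max(1e-8, 1e-4 * se2)
    def ll(b, e):
        return _reml_loglik(max(b, 0.0), e, n_j, mean_j, ss_within)
    H = np.empty((2, 2))
    H[0, 0] = (ll(sb2 + h_b, se2) - 2 * ll(sb2, se2) + ll(max(sb2 - h_b, 0.0), se2)) / h_b ** 2
    H[1, 1] = (ll(sb2, se2 + h_e) - 2 * ll(sb2, se2) + ll(sb2, se2 - h_e)) / h_e ** 2
    H[0, 1] = H[1, 0] = (
        ll(sb2 + h_b, se2 + h_e) - ll(sb2 + h_b, se2 - h_e)
        - ll(max(sb2 - h_b, 0.0), se2 + h_e) + ll(max(sb2 - h_b, 0.0), se2 - h_e)
    ) / (4 * h_b * h_e)
    try:
        A = np.linalg.inv(-H)
        denom = float(g @ A @ g)
    except np.linalg.LinAlgError:
        denom = np.nan
    if not np.isfinite(denom) or denom <= 0:
        return float(len(n_j) - 1)
    df = 2.0 * f ** 2 / denom
    return float(np.clip(df, 1.0, n_j.sum() - 1.0))


def mixed_model_test(per_trial, value_index: int = 2) -> MixedModelResult:
    """Convenience wrapper over :func:`fit_random_intercept` for the output
    of ``per_trial_correlations`` ((subject, trial, rho) tuples)."""
    subjects = [t[0] for t in per_trial]
    values = [t[value_index] for t in per_trial]
    return fit_random_intercept(values, subjects)
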