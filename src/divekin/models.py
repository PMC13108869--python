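"""Binomial mixed-effects feeding classifier and AIC model comparison.

The response is per-dive behavior (Feeding = 1, Travel/non-feeding = 0) with
kinematic predictors as fixed effects and a per-deployment random intercept
absorbing individual, tag-placement and year differences.  The random-
intercept logistic model is fit by maximum likelihood with Gauss-Hermite
quadrature over the random effect (the same marginal likelihood lme4's
``glmer`` maximizes), so log-likelihoods and AICs are comparable across
candidate models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

__all__ = [
    "ModelSpec",
    "FitResult",
    "SeparationError",
    "fit_logistic_glmm",
    "fit_feeding_glmm",
    "compare_models",
    "predict_feeding",
    "table4_candidate_specs",
]

RESPONSE_MAP = {"Feeding": 1, "Travel": 0}


class SeparationError(RuntimeError):
    """The response admits no finite maximum-likelihood estimate."""


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: fixed effects + per-group random intercept."""

    name: str
    fixed_effects: tuple = ()
    random_intercept: str = "deployment_id"
    response: str = "label"

    def __post_init__(self):
        object.__setattr__(self, "fixed_effects", tuple(self.fixed_effects))


@dataclass
class FitResult:
    """ML fit of a random-intercept logistic model (input-scale estimates)."""

    params: pd.Series           # coefficients incl. "Intercept"
    bse: pd.Series              # standard errors
    zvalues: pd.Series
    pvalues: pd.Series
    re_sd: float                # random-intercept SD
    log_likelihood: float
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    warnings: list = field(default_factory=list)
    spec: ModelSpec | None = None
    _profile_data: dict | None = field(default=None, repr=False)

    @property
    def k_params(self) -> int:
        """Estimated parameters: fixed effects + the random-effect variance."""
        return len(self.params) + 1

    def profile_confint(self, level: float = 0.95, names=None) -> pd.DataFrame:
        """Profile-likelihood confidence intervals for the fixed effects.

        For each coefficient the marginal log-likelihood is re-maximized
        over all other parameters (including the random-effect variance)
        along a grid of fixed values, and the interval endpoints are where
        the profile deviance crosses the chi-square(1) quantile.  Better
        calibrated than Wald intervals when the group count is small or the
        random-effect variance sits near its boundary.
        """
        if self._profile_data is None:
            raise RuntimeError("fit carries no data to profile")
        from scipy.optimize import brentq
        from scipy.stats import chi2

        d = self._profile_data
        y, Xm, group_idx, n_groups = d["y"], d["Xm"], d["group_idx"], d["n_groups"]
        nodes, weights = d["nodes"], d["weights"]
        theta_hat = d["theta_raw"]
        nll_min = -self.log_likelihood
        target = nll_min + chi2.ppf(level, 1) / 2.0
        all_names = list(self.params.index)
        names = list(names) if names is not None else all_names

        def nll(theta):
            return -_gh_loglik(theta[:-1], theta[-1], y, Xm, group_idx,
                               n_groups, nodes, weights)

        rows = []
        for name in names:
            j = all_names.index(name)
            free = [i for i in range(len(theta_hat)) if i != j]

            def profile_nll(b, start):
                th = theta_hat.copy()
                th[j] = b
                th[free] = start

                def f(sub):
                    full = th.copy()
                    full[free] = sub
                    return nll(full)

                res = minimize(f, th[free], method="L-BFGS-B",
                               options={"ftol": 1e-10, "maxiter": 200})
                return res.fun, res.x

            se = self.bse.iloc[j]
            step = se if np.isfinite(se) and se > 0 else 0.5
            bounds = {}
            for side, sign in (("lower", -1.0), ("upper", 1.0)):
                b_hat = theta_hat[j]
                start = theta_hat[free].copy()
                b_out, val_out = b_hat, nll_min
                for m in range(1, 40):
                    b_try = b_hat + sign * step * m * 0.75
                    val, start = profile_nll(b_try, start)
                    if val > target:
                        b_out, val_out = b_try, val
                        break
                else:
                    bounds[side] = sign * np.inf
                    continue

                def g(b, _s=[start]):
                    val, _s[0] = profile_nll(b, _s[0])
                    return val - target

                inner = b_hat + sign * step * (m - 1) * 0.75
                lo, hi = sorted((inner, b_out))
                bounds[side] = brentq(g, lo, hi, xtol=1e-4 * max(step, 1e-3))
            rows.append({"name": name, "lower": bounds["lower"],
                         "upper": bounds["upper"]})
        return pd.DataFrame(rows).set_index("name")


def _gh_loglik(beta, log_sigma, y, X, group_idx, n_groups, nodes, weights):
    """Marginal log-likelihood by Gauss-Hermite quadrature.

    For each group the random intercept is integrated out:
    log integral prod_j p(y_ij | eta_ij + u) N(u; 0, sigma^2) du,
    evaluated at u = sqrt(2)*sigma*z_k with weights w_k / sqrt(pi).
    """
    sigma = np.exp(log_sigma)
    eta = X @ beta
    # log p(y | eta + offset) summed per group, for every node
    offsets = np.sqrt(2.0) * sigma * nodes  # (K,)
    # (n, K): log Bernoulli likelihoods
    lin = eta[:, None] + offsets[None, :]
    # log invlogit(s*lin) with s = +/-1 = -log1p(exp(-s*lin))
    s = np.where(y > 0.5, 1.0, -1.0)[:, None]
    ll_obs = -np.logaddexp(0.0, -s * lin)
    per_group = np.zeros((n_groups, len(nodes)))
    np.add.at(per_group, group_idx, ll_obs)
    log_w = np.log(weights / np.sqrt(np.pi))
    return float(np.sum(logsumexp(per_group + log_w[None, :], axis=1)))


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_logistic_glmm(
    y,
    X: pd.DataFrame,
    groups,
    n_quad: int = 25,
    tol: float = 1e-8,
    maxiter: int = 500,
    spec: ModelSpec | None = None,
) -> FitResult:
    """ML fit of y ~ X + (1 | groups), binomial logit.

    Continuous columns of ``X`` are standardized internally for a
    well-conditioned optimization; reported coefficients and standard errors
    are back-transformed to the input scale.  AIC counts the random-effect
    variance as one parameter: AIC = 2k - 2*logLik, k = p + 1.

    Raises
    ------
    SeparationError
        Response is all 0 or all 1.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise SeparationError("response takes a single value; no finite MLE")
    groups = np.asarray(groups)
    uniq, group_idx = np.unique(groups, return_inverse=True)
    n_groups = len(uniq)

    names = ["Intercept"] + list(X.columns)
    Xm = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])
    # standardize non-constant columns
    mu = Xm.mean(axis=0)
    sd = Xm.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    center = np.where(sd > 0, mu, 0.0)
    Xs = (Xm - center) / scale

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    def nll(theta):
        return -_gh_loglik(
            theta[:-1], theta[-1], y, Xs, group_idx, n_groups, nodes, weights
        )

    # start from the no-random-effect logistic fit
    from statsmodels.api import GLM, families

    warns: list[str] = []
    try:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # start values only; separation re-checked below
            glm = GLM(y, Xs, family=families.Binomial()).fit(maxiter=100)
        beta0 = np.asarray(glm.params)
        if not np.all(np.isfinite(beta0)) or np.max(np.abs(beta0)) > 20:
            warns.append("possible complete separation in the fixed effects")
            beta0 = np.clip(np.nan_to_num(beta0), -5, 5)
    except Exception:
        beta0 = np.zeros(Xs.shape[1])
    theta0 = np.concatenate([beta0, [np.log(0.5)]])

    res = minimize(
        nll, theta0, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
    )
    theta = res.x
    beta_s, log_sigma = theta[:-1], theta[-1]
    if np.max(np.abs(beta_s)) > 15:
        warns.append("possible complete separation (extreme coefficient)")
    if np.exp(log_sigma) < 1e-4:
        warns.append("singular random-effect variance (near zero)")
    ll = -res.fun

    H = _numeric_hessian(nll, theta)
    try:
        cov = np.linalg.inv(H)
        cov_beta_s = cov[:-1, :-1]
        if np.any(np.diag(cov_beta_s) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov_beta_s = np.full((len(beta_s), len(beta_s)), np.nan)
        warns.append("Hessian not positive definite; standard errors unavailable")

    # back-transform: eta = beta_s . (x - c)/s  =>  raw slopes beta_s/s,
    # raw intercept beta0_s - sum(beta_s * c / s)
    p = len(beta_s)
    A = np.zeros((p, p))
    A[0, 0] = 1.0
    for j in range(1, p):
        A[j, j] = 1.0 / scale[j]
        A[0, j] = -center[j] / scale[j]
    beta_raw = A @ beta_s
    cov_raw = A @ cov_beta_s @ A.T
    se_raw = np.sqrt(np.diag(cov_raw))

    params = pd.Series(beta_raw, index=names)
    bse = pd.Series(se_raw, index=names)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / bse
    from scipy.stats import norm

    pvals = pd.Series(2 * norm.sf(np.abs(z)), index=names)
    k = p + 1
    profile_data = dict(
        y=y, Xm=Xm, group_idx=group_idx, n_groups=n_groups,
        nodes=nodes, weights=weights,
        theta_raw=np.concatenate([beta_raw, [log_sigma]]),
    )
    return FitResult(
        params=params,
        bse=bse,
        zvalues=z,
        pvalues=pvals,
        re_sd=float(np.exp(log_sigma)),
        log_likelihood=ll,
        aic=2 * k - 2 * ll,
        n_obs=len(y),
        n_groups=n_groups,
        converged=bool(res.success),
        warnings=warns,
        spec=spec,
        _profile_data=profile_data,
    )


def _model_frame(features: pd.DataFrame, spec: ModelSpec,
                 extra_cols=()) -> pd.DataFrame:
    """Rows usable for fitting: Feeding/Travel response, listwise-complete."""
    cols = set(spec.fixed_effects) | set(extra_cols)
    df = features[features[spec.response].isin(RESPONSE_MAP)].copy()
    df["_y"] = df[spec.response].map(RESPONSE_MAP)
    keep = list(cols) + ["_y", spec.random_intercept]
    df = df[keep].dropna()
    return df


def fit_feeding_glmm(features: pd.DataFrame, spec: ModelSpec, **kwargs) -> FitResult:
    """Fit a candidate feeding model on the dive feature table.

    Rows labeled PotentialForaging or NoVideo are excluded (ambiguous
    response); rows with any missing fixed effect are dropped listwise.
    """
    df = _model_frame(features, spec)
    if df[spec.random_intercept].nunique() < 2:
        import warnings

        warnings.warn("fewer than 2 groups; random intercept weakly identified",
                      UserWarning)
    X = df[list(spec.fixed_effects)] if spec.fixed_effects else df[[]]
    return fit_logistic_glmm(
        df["_y"].to_numpy(), X, df[spec.random_intercept].to_numpy(),
        spec=spec, **kwargs,
    )


def compare_models(features: pd.DataFrame, specs: list[ModelSpec],
                   **kwargs) -> pd.DataFrame:
    """AIC/logLik comparison of candidate models on a common observation set.

    Rows with a missing value in *any* candidate's fixed effects are dropped
    before every fit, so likelihoods are computed on identical data.  dAIC
    is relative to the null (intercept + random intercept) model, positive
    when a candidate improves on it; the selected model minimizes AIC.
    """
    all_feats = sorted({f for s in specs for f in s.fixed_effects})
    base = specs[0]
    null_spec = ModelSpec("NULL", (), base.random_intercept, base.response)
    frame = _model_frame(features, null_spec, extra_cols=all_feats)

    def fit_on_frame(spec):
        X = frame[list(spec.fixed_effects)] if spec.fixed_effects else frame[[]]
        return fit_logistic_glmm(
            frame["_y"].to_numpy(), X, frame[spec.random_intercept].to_numpy(),
            spec=spec, **kwargs,
        )

    fits = {}
    has_null = any(len(s.fixed_effects) == 0 for s in specs)
    if not has_null:
        fits["NULL"] = fit_on_frame(null_spec)
    for s in specs:
        fits[s.name] = fit_on_frame(s)

    null_name = next(n for n, f in fits.items() if not f.spec.fixed_effects)
    aic_null = fits[null_name].aic
    rows = [
        {
            "model": name,
            "fixed_effects": " + ".join(f.spec.fixed_effects) or "-",
            "AIC": f.aic,
            "logLik": f.log_likelihood,
            "dAIC": aic_null - f.aic if name != null_name else np.nan,
            "converged": f.converged,
        }
        for name, f in fits.items()
    ]
    table = pd.DataFrame(rows)
    table.attrs["selected"] = table.loc[table["AIC"].idxmin(), "model"]
    table.attrs["fits"] = fits
    return table


def predict_feeding(fit: FitResult, features: pd.DataFrame) -> pd.Series:
    """Per-dive feeding probability; new groups get the population intercept.

    Rows missing any required feature yield NaN.
    """
    names = [n for n in fit.params.index if n != "Intercept"]
    eta = np.full(len(features), fit.params["Intercept"], dtype=float)
    for n in names:
        eta = eta + fit.params[n] * features[n].to_numpy(dtype=float)
    return pd.Series(expit(eta), index=features.index, name="p_feeding")


def table4_candidate_specs() -> list[ModelSpec]:
    """The shipped candidate set for the feeding-classifier comparison.

    Null; bottom-speed only; bottom-fluke-rate only; a five-term model with
    linear time of day; and the full model with the circular time-of-day
    encoding.
    """
    return [
        ModelSpec("NULL", ()),
        ModelSpec("1", ("bottom_mean_speed",)),
        ModelSpec("2", ("bottom_fluke_rate_mean",)),
        ModelSpec(
            "3",
            ("bottom_mean_speed", "bottom_peak_jerk", "bottom_mean_pitch",
             "bottom_mean_roll", "tod_linear"),
        ),
        ModelSpec(
            "4",
            ("bottom_mean_speed", "bottom_peak_jerk", "speed_change",
             "bottom_mean_roll", "bottom_mean_pitch", "tod"),
        ),
    ]
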