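"""Random-intercept linear models for biennial trends and TMN associations.

Health regions are the observational unit, observed once per biennium
(a 22 x 6 panel under the default study conditions).  Trend models are

.. math:: y_{jt} = \\beta_0 + \\beta_1 t + u_j + \\varepsilon_{jt},
          \\quad u_j \\sim N(0, \\tau^2),
          \\quad \\varepsilon_{jt} \\sim N(0, \\sigma^2),

with the biennium coded as consecutive integers t = 1..6 and estimation
by restricted maximum likelihood (REML).  The multivariable neonatal
mortality (TMN) models add the flow-weighted distance and the regional
indicators as fixed covariates:

* Model 1 - biennium only;
* Model 2 - biennium + flow-weighted distance;
* Model 3 - biennium + distance + % displaced + NICU beds/1,000 + the
  four birth indicators.

Fixed effects are reported with Wald 95% CIs.  Variance components are
reported as standard deviations with either log-scale Wald intervals
(random intercept, from the REML information matrix; residual from a
scaled chi-square approximation) or seeded parametric-bootstrap
percentile intervals, selectable per call.  A simulation harness draws
panels from the same model for parameter-recovery studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from neonet.errors import ParameterError

#: Covariate sets of the multivariable TMN models.
TMN_MODEL_COVARIATES = {
    1: (),
    2: ("m_j",),
    3: ("m_j", "pct_displaced", "nicu_beds_per_1000", "pct_low_weight",
        "pct_ga_lt28", "pct_apgar5_le7", "pct_maternal_35plus"),
}

CONDITION_NUMBER_THRESHOLD = 1e8


@dataclass
class ModelFit:
    """Fitted random-intercept model: estimates with 95% CIs."""

    fixed_effects: dict[str, tuple[float, float, float]]  # term -> (est, lo, hi)
    random_intercept_sd: tuple[float, float, float]
    residual_sd: tuple[float, float, float]
    n_obs: int
    n_units: int
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-term table (term, estimate, ci_low, ci_high, group)."""
        rows = [(t, e, lo, hi, "fixed")
                for t, (e, lo, hi) in self.fixed_effects.items()]
        rows.append(("random_intercept_sd", *self.random_intercept_sd, "random"))
        rows.append(("residual_sd", *self.residual_sd, "random"))
        return pd.DataFrame(rows, columns=["term", "estimate", "ci_low",
                                           "ci_high", "group"])


def _sigma_ci_chi2(sigma2: float, df: float) -> tuple[float, float]:
    # Scaled chi-square interval for the residual variance; approximate for
    # a mixed model but cheap and anti-conservative only mildly at 22x6.
    df = max(df, 1.0)
    lo = df * sigma2 / scipy.stats.chi2.ppf(0.975, df)
    hi = df * sigma2 / scipy.stats.chi2.ppf(0.025, df)
    return float(np.sqrt(lo)), float(np.sqrt(hi))


def fit_trend(panel: pd.DataFrame, response: str,
              covariates: Sequence[str] = (),
              time_col: str = "biennium_index", group_col: str = "region_id",
              vc_ci: str = "wald", n_boot: int = 200,
              seed: int = 0) -> ModelFit:
    """Fit ``response = b0 + b1*time (+ covariates) + u_group + e`` by REML.

    Rows with missing values in any used column are dropped listwise.
    ``vc_ci`` selects the variance-component CI method: ``"wald"``
    (default, log-scale Wald / chi-square) or ``"bootstrap"`` (parametric,
    seeded, ``n_boot`` refits).  Non-convergence is reported through the
    ``converged`` flag, never silently.
    """
    cols = [group_col, time_col, response, *covariates]
    data = panel[cols].dropna()
    if data[group_col].nunique() < 2 or data[time_col].nunique() < 2:
        raise ParameterError("need >= 2 units and >= 2 time points")

    terms = ["intercept", "biennium", *covariates]
    exog = np.column_stack([np.ones(len(data)), data[time_col].to_numpy(dtype=float),
                            *[data[c].to_numpy(dtype=float) for c in covariates]])
    endog = data[response].to_numpy(dtype=float)
    groups = data[group_col].to_numpy()

    msgs: list[str] = []
    cond = np.linalg.cond(exog)
    if cond > CONDITION_NUMBER_THRESHOLD:
        msgs.append(f"design matrix ill-conditioned (cond={cond:.3g})")

    # Noise-free data make the REML problem degenerate (the random
    # intercepts can absorb the fixed intercept); the fixed effects are
    # then simply the exact least-squares solution.
    beta, sse, *_ = np.linalg.lstsq(exog, endog, rcond=None)
    resid_ms = float(np.sum((endog - exog @ beta) ** 2) / len(endog))
    if resid_ms <= 1e-12 * max(1.0, float(np.var(endog))):
        fixed = {term: (float(beta[i]), float(beta[i]), float(beta[i]))
                 for i, term in enumerate(terms)}
        return ModelFit(fixed_effects=fixed,
                        random_intercept_sd=(0.0, 0.0, 0.0),
                        residual_sd=(0.0, 0.0, 0.0),
                        n_obs=int(len(data)),
                        n_units=int(data[group_col].nunique()),
                        converged=True,
                        warnings=msgs + ["response fits exactly; variance "
                                         "components degenerate at zero"])

    model = sm.MixedLM(endog, exog, groups=groups)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = model.fit(reml=True)
            fe = np.asarray(result.fe_params)
            fe_se = np.asarray(result.bse_fe)
            tau2 = float(np.asarray(result.cov_re)[0, 0])
            sigma2 = float(result.scale)
            bse_re = float(np.asarray(result.bse_re)[0])
        for w in caught:
            msgs.append(str(w.message))
        converged = bool(getattr(result, "converged", True))
    except np.linalg.LinAlgError as err:
        # Singular design (e.g. exactly collinear covariates): report the
        # minimum-norm least-squares solution, flagged as non-converged.
        msgs.append(f"estimation failed ({err}); minimum-norm LS fallback")
        fe = beta
        fe_se = np.full(exog.shape[1], np.nan)
        tau2, sigma2, bse_re = 0.0, resid_ms, np.nan
        converged = False

    z = scipy.stats.norm.ppf(0.975)
    fixed = {term: (float(fe[i]), float(fe[i] - z * fe_se[i]),
                    float(fe[i] + z * fe_se[i]))
             for i, term in enumerate(terms)}

    tau, sigma = float(np.sqrt(tau2)), float(np.sqrt(sigma2))

    if vc_ci == "bootstrap":
        tau_ci, sigma_ci = _bootstrap_vc_ci(
            exog, groups, fe, tau, sigma, n_boot=n_boot, seed=seed)
    elif vc_ci == "wald":
        if tau2 > 0 and np.isfinite(bse_re) and bse_re > 0:
            # Cap the log-scale SE: near the tau=0 boundary the Wald SE
            # explodes and the upper limit is not meaningful anyway.
            se_log = min(bse_re / tau2, 10.0)
            tau_ci = (float(np.sqrt(tau2 * np.exp(-z * se_log))),
                      float(np.sqrt(tau2 * np.exp(z * se_log))))
        else:
            tau_ci = (0.0, tau)
        n_units = data[group_col].nunique()
        sigma_ci = _sigma_ci_chi2(sigma2, len(data) - exog.shape[1] - n_units)
    else:
        raise ParameterError(f"unknown vc_ci method: {vc_ci!r}")

    tau_ci = (min(tau_ci[0], tau), max(tau_ci[1], tau))
    sigma_ci = (min(sigma_ci[0], sigma), max(sigma_ci[1], sigma))
    return ModelFit(
        fixed_effects=fixed,
        random_intercept_sd=(tau, *tau_ci),
        residual_sd=(sigma, *sigma_ci),
        n_obs=int(len(data)),
        n_units=int(data[group_col].nunique()),
        converged=converged,
        warnings=msgs,
    )


def _bootstrap_vc_ci(exog, groups, fe_params, tau, sigma, n_boot, seed):
    """Parametric bootstrap percentile CIs for (tau, sigma)."""
    rng = np.random.default_rng(seed)
    unique_groups = np.unique(groups)
    taus = np.empty(n_boot)
    sigmas = np.empty(n_boot)
    mean = exog @ np.asarray(fe_params)
    for b in range(n_boot):
        u = dict(zip(unique_groups, rng.normal(0.0, tau, unique_groups.size)))
        y = mean + np.array([u[g] for g in groups]) + rng.normal(0.0, sigma, len(groups))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, exog, groups=groups).fit(reml=True)
        taus[b] = np.sqrt(float(np.asarray(res.cov_re)[0, 0]))
        sigmas[b] = np.sqrt(float(res.scale))
    return (tuple(np.quantile(taus, [0.025, 0.975])),
            tuple(np.quantile(sigmas, [0.025, 0.975])))


def fit_tmn_model(panel: pd.DataFrame, model: int = 3,
                  response: str = "tmn", **kwargs) -> ModelFit:
    """Fit one of the multivariable TMN random-intercept models (1, 2 or 3)."""
    try:
        covariates = TMN_MODEL_COVARIATES[model]
    except KeyError:
        raise ParameterError(f"model must be 1, 2 or 3, got {model}") from None
    return fit_trend(panel, response, covariates=covariates, **kwargs)


def simulate_panel(fixed: Mapping[str, float], tau: float, sigma: float,
                   n_units: int = 22, n_times: int = 6, seed: int = 0,
                   covariate_dists: Mapping[str, tuple[float, float]] | None = None,
                   response: str = "response") -> pd.DataFrame:
    """Draw a balanced panel from the random-intercept model.

    ``fixed`` maps ``"intercept"``, ``"biennium"`` and any covariate names
    to their coefficients; covariate values are drawn i.i.d. normal with
    the (mean, sd) given in ``covariate_dists``.  Reproducible per seed.
    """
    if tau < 0 or sigma < 0:
        raise ParameterError("tau and sigma must be non-negative")
    covariate_dists = dict(covariate_dists or {})
    extra = set(fixed) - {"intercept", "biennium"} - set(covariate_dists)
    if extra:
        raise ParameterError(f"no distribution given for covariates: {sorted(extra)}")
    rng = np.random.default_rng(seed)
    units = np.repeat(np.arange(1, n_units + 1), n_times)
    times = np.tile(np.arange(1, n_times + 1), n_units)
    u = rng.normal(0.0, tau, n_units)
    y = (fixed.get("intercept", 0.0) + fixed.get("biennium", 0.0) * times
         + u[units - 1] + rng.normal(0.0, sigma, units.size))
    panel = pd.DataFrame({"region_id": units, "biennium_index": times})
    for name, (mu, sd) in covariate_dists.items():
        x = rng.normal(mu, sd, units.size)
        panel[name] = x
        y = y + fixed.get(name, 0.0) * x
    panel[response] = y
    return panel
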