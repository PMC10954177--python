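"""Maximum-likelihood estimation of the yields Y_ac, Y_bu, Y_pr.

Each yield is the proportionality constant between proxy-catalysed
reaction extent and mol of VFA produced.  For a candidate Y the observer
is run over the proxy record, and residuals between measured and
estimated concentrations enter a Gaussian constant-variance likelihood
(whose argmin equals least squares).  Minimization is Nelder–Mead on
log Y (positivity by construction), with seeded multistarts to guard
against simplex stagnation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .evaluation import cvrmse, summarize
from .observer import integrate_observer, transform_state
from .types import VFA_NAMES, FitConfig, FitResult, ObserverParams, ProxyTimeSeries, VFATimeSeries

__all__ = ["negative_log_likelihood", "fit_yield", "fit_all"]


def _paired_residual_setup(observations: VFATimeSeries, vfa: str, m: ProxyTimeSeries):
    """Observation times usable for the loss: inside the proxy span, first
    observation reserved for initializing the transformed state."""
    s = observations.concentration(vfa)
    lo, hi = m.span
    usable = (observations.times >= lo - 1e-12) & (observations.times <= hi + 1e-12)
    times = observations.times[usable]
    s = s[usable]
    if times.size < 3:
        raise ValueError(
            "need at least two paired observations beyond the initialization point"
        )
    return times[0], s[0], times[1:], s[1:]


def _predict(yield_, t0, s0, t_obs, m, alpha, dilution_rate, interpolation):
    params = ObserverParams(alpha=alpha, dilution_rate=dilution_rate, yield_=yield_)
    m0 = float(m.interpolate(t0, mode="linear" if interpolation == "linear" else "zoh")[0])
    z0 = float(transform_state(s0, yield_, m0))
    est = integrate_observer(
        params, m, z0, output_times=t_obs, interpolation=interpolation, method="exact"
    )
    return est.s_hat


def negative_log_likelihood(
    yield_: float,
    observations: VFATimeSeries,
    vfa: str,
    m: ProxyTimeSeries,
    alpha: float = 0.85,
    dilution_rate: float = 0.0335,
    interpolation: str = "linear",
) -> float:
    """Profiled Gaussian NLL of the observer run with candidate yield.

    sigma^2 is profiled out (sigma_hat^2 = RSS/n), so the returned value
    is (n/2) * (log(2*pi*RSS/n) + 1); its argmin over Y coincides with the
    least-squares solution.
    """
    if yield_ <= 0:
        return np.inf
    t0, s0, t_obs, s_obs = _paired_residual_setup(observations, vfa, m)
    s_hat = _predict(yield_, t0, s0, t_obs, m, alpha, dilution_rate, interpolation)
    rss = float(np.sum((s_obs - s_hat) ** 2))
    n = s_obs.size
    if rss == 0.0:
        return -np.inf
    return 0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def fit_yield(
    observations: VFATimeSeries,
    vfa: str,
    m: ProxyTimeSeries,
    alpha: float = 0.85,
    dilution_rate: float = 0.0335,
    config: FitConfig | None = None,
    unit: str = "",
) -> FitResult:
    """Nelder–Mead ML fit of one scalar yield for one VFA and one unit."""
    config = config or FitConfig()
    t0, s0, t_obs, s_obs = _paired_residual_setup(observations, vfa, m)
    n = s_obs.size

    def rss_of(yield_):
        s_hat = _predict(yield_, t0, s0, t_obs, m, alpha, dilution_rate, config.interpolation)
        return float(np.sum((s_obs - s_hat) ** 2))

    guess = config.initial_guess
    if guess is None:
        mean_m = float(np.mean(m.values))
        guess = float(np.mean(np.abs(s_obs))) / mean_m if mean_m > 0 else 1.0
        if guess <= 0:
            guess = 1.0

    rng = np.random.default_rng(config.seed)
    starts = [guess] + list(
        guess * np.exp(rng.normal(0.0, 1.0, size=max(0, config.multistarts - 1)))
    )

    if config.log_parameterization:
        objective = lambda th: rss_of(float(np.exp(th[0])))  # noqa: E731
        to_param = np.log
        from_param = np.exp
    else:
        objective = lambda th: rss_of(th[0]) if th[0] > 0 else np.inf  # noqa: E731
        to_param = lambda y: y  # noqa: E731
        from_param = lambda th: th  # noqa: E731

    best = None
    iterations = 0
    converged = False
    for start in starts:
        res = minimize(
            objective,
            x0=[to_param(start)],
            method="Nelder-Mead",
            options={
                "xatol": config.xatol,
                "fatol": config.fatol,
                "maxiter": config.max_iterations,
            },
        )
        iterations += res.nit
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    y_hat = float(from_param(best.x[0]))
    rss = float(best.fun)
    # never report a loss above the initial guess's: the simplex starts there
    rss = min(rss, rss_of(guess))
    sigma2 = rss / n
    nll = -np.inf if rss == 0 else 0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    s_hat = _predict(y_hat, t0, s0, t_obs, m, alpha, dilution_rate, config.interpolation)
    return FitResult(
        vfa=vfa,
        yield_hat=y_hat,
        nll=nll,
        sigma2=sigma2,
        iterations=iterations,
        converged=converged,
        cvrmse=cvrmse(s_obs, s_hat),
        n_obs=n,
        unit=unit,
    )


def fit_all(
    datasets: dict[str, tuple[VFATimeSeries, dict[str, ProxyTimeSeries]]],
    alpha: float = 0.85,
    dilution_rate: float = 0.0335,
    config: FitConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Independent per-VFA, per-unit fits plus a mean ± s.d. summary.

    ``datasets`` maps an experimental unit (vessel, cow) to its VFA record
    and per-VFA proxy series.  Failures in one unit are reported in the
    result table (NaN yield) without aborting the others.
    """
    rows = []
    for unit, (obs, proxies) in datasets.items():
        for vfa in VFA_NAMES:
            if vfa not in proxies:
                continue
            try:
                fit = fit_yield(
                    obs, vfa, proxies[vfa], alpha=alpha,
                    dilution_rate=dilution_rate, config=config, unit=unit,
                )
                rows.append(fit.to_dict())
            except Exception as exc:  # propagate as data, not as abort
                rows.append(
                    {
                        "unit": unit, "vfa": vfa, "Y_hat": np.nan, "loss": np.nan,
                        "sigma2": np.nan, "iterations": 0, "converged": False,
                        "cvrmse": np.nan, "n_obs": 0, "error": str(exc),
                    }
                )
    results = pd.DataFrame(rows)
    summary_rows = []
    for vfa in VFA_NAMES:
        vals = results.loc[(results["vfa"] == vfa) & results["Y_hat"].notna(), "Y_hat"]
        if len(vals) == 0:
            continue
        s = summarize(vals.values, decimals=12)
        summary_rows.append(
            {"vfa": vfa, "mean": s["mean"], "sd": s["sd"], "n_units": len(vals)}
        )
    return results, pd.DataFrame(summary_rows)
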