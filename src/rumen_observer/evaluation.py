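"""Model-performance metrics: CVRMSE, molar proportions, summary rows."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .types import VFA_NAMES

__all__ = ["cvrmse", "molar_proportions", "round_half_up", "summarize", "metric_table"]


def cvrmse(observed, predicted) -> float:
    """Coefficient of variation of the RMSE, in percent.

    100 * sqrt(mean((obs - pred)^2)) / mean(obs), with the conventional
    1/n inside the mean.  Scale-invariant: common rescaling of both series
    leaves it unchanged.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted series differ in length")
    if observed.size == 0:
        raise ValueError("need at least one observation")
    mean_obs = observed.mean()
    if mean_obs == 0:
        raise ZeroDivisionError("mean of observations is zero; CVRMSE undefined")
    rmse = np.sqrt(np.mean((observed - predicted) ** 2))
    return float(100.0 * rmse / mean_obs)


def molar_proportions(acetate, butyrate, propionate) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-time molar fraction of each VFA among the three; fractions sum to 1."""
    a = np.asarray(acetate, dtype=float)
    b = np.asarray(butyrate, dtype=float)
    p = np.asarray(propionate, dtype=float)
    total = a + b + p
    if np.any(total <= 0):
        raise ZeroDivisionError("total VFA concentration is zero at some time")
    return a / total, b / total, p / total


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (2.25 -> 2.3), as used in the report tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize(values, decimals: int = 1) -> dict:
    """Mean and sample (n-1) standard deviation of per-unit metric rows.

    Returns raw and half-up-rounded values plus a "mean ± s.d." string.
    With fewer than two rows the s.d. is undefined and reported empty.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to summarize")
    mean = float(values.mean())
    mean_r = round_half_up(mean, decimals)
    if values.size < 2:
        return {
            "mean": mean,
            "sd": None,
            "mean_rounded": mean_r,
            "sd_rounded": None,
            "text": f"{mean_r:g} ±",
        }
    sd = float(values.std(ddof=1))
    sd_r = round_half_up(sd, decimals)
    return {
        "mean": mean,
        "sd": sd,
        "mean_rounded": mean_r,
        "sd_rounded": sd_r,
        "text": f"{mean_r:g} ± {sd_r:g}",
    }


def metric_table(rows: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Append a "Mean ± s.d." row to a units x VFA metric table."""
    cols = [c for c in rows.columns if c in VFA_NAMES] or list(rows.columns)
    summary = {c: summarize(rows[c].values, decimals)["text"] for c in cols}
    out = rows.copy().astype(object)
    out.loc["Mean ± s.d."] = pd.Series(summary)
    return out
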