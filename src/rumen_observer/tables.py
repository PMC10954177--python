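"""Packaged reference data from the two case studies.

The package ships, as plain CSV resources, the per-unit results of the
two experiments the method was developed on: a RUSITEC run (four
vessel/diet combinations, proxies summed over liquid and solid phases,
samples at 2/4/8/24 h) and a four-cow trial (liquid phase, 16 samples
every 3 h).  These serve demonstrations, regression tests and the report
layouts; the raw sequence data they derive from are not needed.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .types import ProxyTimeSeries

_PROXY_COLS = {"m_ac": "acetate", "m_bu": "butyrate", "m_pr": "propionate"}


def _read(name: str, **kw) -> pd.DataFrame:
    ref = resources.files("rumen_observer.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, **kw)


def invitro_proxy_table() -> pd.DataFrame:
    """Tidy per-unit, per-time proxy abundances of the RUSITEC study."""
    return _read("invitro_proxies.csv")


def invivo_proxy_table() -> pd.DataFrame:
    """Tidy per-cow, per-time proxy abundances of the in-vivo study."""
    return _read("invivo_proxies.csv")


def _proxies_for(table: pd.DataFrame, unit: str) -> dict[str, ProxyTimeSeries]:
    sub = table[table["unit"] == unit].sort_values("time_h")
    if sub.empty:
        raise KeyError(f"unknown unit {unit!r}; available: {sorted(table['unit'].unique())}")
    times = sub["time_h"].to_numpy(dtype=float)
    return {
        vfa: ProxyTimeSeries(times, sub[col].to_numpy(dtype=float), name=col)
        for col, vfa in _PROXY_COLS.items()
    }


def invitro_proxies(unit: str) -> dict[str, ProxyTimeSeries]:
    return _proxies_for(invitro_proxy_table(), unit)


def invivo_proxies(cow: str) -> dict[str, ProxyTimeSeries]:
    return _proxies_for(invivo_proxy_table(), cow)


def invitro_cvrmse() -> pd.DataFrame:
    """Per-unit CVRMSE (%) of the observer on in-vitro concentrations."""
    return _read("invitro_cvrmse.csv", index_col="unit")


def invivo_cvrmse() -> pd.DataFrame:
    """Per-cow CVRMSE (%) of the observer on in-vivo concentrations."""
    return _read("invivo_cvrmse.csv", index_col="unit")


def invivo_proportion_cvrmse() -> pd.DataFrame:
    """Per-cow CVRMSE (%) on in-vivo VFA molar proportions."""
    return _read("invivo_proportion_cvrmse.csv", index_col="unit")


def invitro_yields() -> pd.DataFrame:
    """Per-unit fitted yields (mol VFA per proxy unit), in vitro."""
    return _read("invitro_yields.csv", index_col="unit")


def invivo_yields() -> pd.DataFrame:
    """Per-cow fitted yields (mol VFA per proxy unit), in vivo."""
    return _read("invivo_yields.csv", index_col="unit")
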