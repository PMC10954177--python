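"""From OTU counts to scaled functional-proxy time series.

The chain is: median-of-ratios size factors (the scaling used by
differential-abundance tools for count libraries) -> per-sample scaling ->
aggregation of KO copy numbers into KEGG-style module abundances ->
selection of the three VFA proxy modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_PROXY_MODULES,
    GeneContentProfile,
    ModuleCatalog,
    OTUTable,
    ProxyTimeSeries,
)


class ScalingError(ValueError):
    """No OTU usable as a scaling reference."""


def compute_size_factors(table: OTUTable) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Only OTUs with strictly positive counts in every sample enter the
    reference: for each such OTU the geometric mean across samples is
    taken, and the factor of a sample is the median over reference OTUs
    of count / geometric mean.
    """
    counts = table.counts.astype(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ScalingError(
            "no OTU has positive counts in every sample; "
            "median-of-ratios scaling is impossible"
        )
    ref = counts.loc[positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.exp(np.log(ref).sub(log_geo_mean, axis=0))
    factors = ratios.median(axis=0)
    factors.name = "size_factor"
    return factors


def scale_counts(table: OTUTable, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    missing = [s for s in table.sample_ids if s not in factors.index]
    if missing:
        raise ValueError(f"no size factor for samples: {missing}")
    factors = factors.loc[table.sample_ids]
    if (factors <= 0).any():
        raise ValueError("size factors must be strictly positive")
    return table.counts.astype(float).div(factors, axis=1)


@dataclass(frozen=True)
class ModuleAbundances:
    """Module x sample abundance matrix plus the unmapped-OTU report."""

    abundances: pd.DataFrame          # rows = module ids, columns = sample ids
    sample_times: pd.Series
    unmapped_otus: tuple[str, ...]
    unmapped_fraction: float          # share of total scaled abundance unmapped


def aggregate_modules(
    scaled: pd.DataFrame,
    genes: GeneContentProfile,
    catalog: ModuleCatalog,
    sample_times: pd.Series,
) -> ModuleAbundances:
    """Aggregate scaled OTU abundances into module abundances.

    abundance(M, sample) = sum_otu scaled(otu, sample) * sum_{ko in M}
    copy_number(otu, ko).  OTUs missing from the gene-content profile
    contribute nothing and are reported in the unmapped fraction.
    """
    mapped = [o for o in scaled.index if o in genes.copy_numbers.index]
    if not mapped:
        raise ValueError("no overlap between OTU table and gene-content profile")
    unmapped = tuple(o for o in scaled.index if o not in genes.copy_numbers.index)
    total = float(scaled.values.sum())
    unmapped_fraction = (
        float(scaled.loc[list(unmapped)].values.sum()) / total if total > 0 else 0.0
    )
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} OTU(s) absent from the gene-content profile "
            f"({100 * unmapped_fraction:.1f}% of scaled abundance) contribute 0",
            stacklevel=2,
        )

    copy = genes.copy_numbers.loc[mapped]
    rows = {}
    for module_id in catalog.module_ids:
        kos = [k for k in catalog[module_id] if k in copy.columns]
        weights = copy[kos].sum(axis=1) if kos else pd.Series(0.0, index=copy.index)
        rows[module_id] = weights.values @ scaled.loc[mapped].values
    abundances = pd.DataFrame(rows, index=scaled.columns).T
    return ModuleAbundances(
        abundances=abundances,
        sample_times=sample_times.loc[scaled.columns],
        unmapped_otus=unmapped,
        unmapped_fraction=unmapped_fraction,
    )


def sum_phases(liquid: ModuleAbundances, solid: ModuleAbundances) -> ModuleAbundances:
    """Element-wise sum of liquid- and solid-phase module abundances.

    Both phases must have been sampled on the same time grid and carry the
    same module set; no implicit alignment is attempted.
    """
    if list(liquid.abundances.index) != list(solid.abundances.index):
        raise ValueError("module sets differ between phases")
    lt = np.asarray(liquid.sample_times.values, dtype=float)
    st = np.asarray(solid.sample_times.values, dtype=float)
    if lt.shape != st.shape or not np.allclose(lt, st):
        raise ValueError("sampling time grids differ between phases")
    combined = liquid.abundances.values + solid.abundances.values
    abundances = pd.DataFrame(
        combined, index=liquid.abundances.index, columns=liquid.abundances.columns
    )
    tot_l = liquid.abundances.values.sum()
    tot_s = solid.abundances.values.sum()
    tot = tot_l + tot_s
    frac = (
        (liquid.unmapped_fraction * tot_l + solid.unmapped_fraction * tot_s) / tot
        if tot > 0
        else 0.0
    )
    return ModuleAbundances(
        abundances=abundances,
        sample_times=liquid.sample_times,
        unmapped_otus=tuple(sorted(set(liquid.unmapped_otus) | set(solid.unmapped_otus))),
        unmapped_fraction=float(frac),
    )


def select_vfa_proxies(
    modules: ModuleAbundances,
    mapping: dict[str, str] | None = None,
) -> dict[str, ProxyTimeSeries]:
    """Pick the three proxy modules and return them as time series keyed by VFA."""
    mapping = dict(DEFAULT_PROXY_MODULES) if mapping is None else mapping
    out: dict[str, ProxyTimeSeries] = {}
    times = np.asarray(modules.sample_times.values, dtype=float)
    order = np.argsort(times)
    for module_id, vfa in mapping.items():
        if module_id not in modules.abundances.index:
            raise KeyError(f"proxy module {module_id} not present in module table")
        values = modules.abundances.loc[module_id].values[order]
        out[vfa] = ProxyTimeSeries(times=times[order], values=values, name=f"m_{vfa}")
    return out


def infer_proxies(
    table: OTUTable,
    genes: GeneContentProfile,
    catalog: ModuleCatalog,
    mapping: dict[str, str] | None = None,
) -> dict[str, ProxyTimeSeries]:
    """Full chain: size factors -> scaling -> modules -> VFA proxies."""
    factors = compute_size_factors(table)
    scaled = scale_counts(table, factors)
    modules = aggregate_modules(scaled, genes, catalog, table.sample_times)
    return select_vfa_proxies(modules, mapping)
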