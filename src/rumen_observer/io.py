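"""File dialects: OTU tables, gene content, module catalogs, proxy and
VFA CSVs, YAML run configuration, and provenance records.

Concentrations are converted to the internal mol/L on read; the input
unit is declared in the configuration (default mmol/L).
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .observer import ObserverEstimate
from .types import VFA_NAMES, GeneContentProfile, ModuleCatalog, OTUTable, ProxyTimeSeries, VFATimeSeries

PROXY_COLUMNS = {"acetate": "m_ac", "butyrate": "m_bu", "propionate": "m_pr"}
_UNIT_FACTORS = {"mol/L": 1.0, "mmol/L": 1e-3}


class FormatError(ValueError):
    """Malformed input file; the message carries the offending lines."""


def _require_columns(df: pd.DataFrame, needed, path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _numeric(df: pd.DataFrame, cols, path, header_lines: int = 1) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        vals = pd.to_numeric(out[c], errors="coerce")
        bad = out.index[vals.isna() & out[c].notna()]
        if len(bad):
            lines = [int(i) + header_lines + 1 for i in bad[:5]]
            raise FormatError(f"{path}: non-numeric values in column {c!r} at line(s) {lines}")
        out[c] = vals
    return out


def _read_table(path, sep) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return df


def read_otu_tsv(counts_path, metadata_path) -> OTUTable:
    """OTU count TSV (first column ``#OTU ID``) plus sample-metadata TSV
    with columns ``sample_id``, ``time_h`` and optional ``phase``."""
    counts = _read_table(counts_path, "\t")
    id_col = counts.columns[0]
    if id_col != "#OTU ID":
        raise FormatError(f"{counts_path}: first column must be '#OTU ID', got {id_col!r}")
    counts = _numeric(counts, counts.columns[1:], counts_path).set_index(id_col)

    meta = _read_table(metadata_path, "\t")
    _require_columns(meta, ["sample_id", "time_h"], metadata_path)
    meta = _numeric(meta, ["time_h"], metadata_path).set_index("sample_id")
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise FormatError(f"{metadata_path}: samples without metadata: {missing}")
    phases = meta["phase"] if "phase" in meta.columns else None
    return OTUTable(counts=counts, sample_times=meta["time_h"], phase_labels=phases)


def read_gene_content(path) -> GeneContentProfile:
    """TSV with OTU ids in the first column and KO ids as headers."""
    df = _read_table(path, "\t")
    df = _numeric(df, df.columns[1:], path).set_index(df.columns[0])
    return GeneContentProfile(copy_numbers=df)


def read_module_catalog(path) -> ModuleCatalog:
    """TSV with one (module_id, ko_id) pair per row."""
    df = _read_table(path, "\t")
    _require_columns(df, ["module_id", "ko_id"], path)
    modules = {
        mid: frozenset(sub["ko_id"].astype(str))
        for mid, sub in df.groupby("module_id")
    }
    return ModuleCatalog(modules=modules)


def read_proxy_csv(path) -> dict[str, ProxyTimeSeries]:
    df = _read_table(path, ",")
    _require_columns(df, ["time_h", *PROXY_COLUMNS.values()], path)
    df = _numeric(df, ["time_h", *PROXY_COLUMNS.values()], path).sort_values("time_h")
    times = df["time_h"].to_numpy()
    return {
        vfa: ProxyTimeSeries(times, df[col].to_numpy(), name=col)
        for vfa, col in PROXY_COLUMNS.items()
    }


def write_proxy_csv(proxies: dict[str, ProxyTimeSeries], path) -> None:
    first = next(iter(proxies.values()))
    df = pd.DataFrame({"time_h": first.times})
    for vfa, col in PROXY_COLUMNS.items():
        series = proxies[vfa]
        if not np.array_equal(series.times, first.times):
            raise ValueError("proxy series must share one time grid to be written together")
        df[col] = series.values
    df.to_csv(path, index=False)


def read_vfa_csv(path, unit: str = "mmol/L") -> VFATimeSeries:
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown concentration unit {unit!r}; use one of {list(_UNIT_FACTORS)}")
    f = _UNIT_FACTORS[unit]
    df = _read_table(path, ",")
    _require_columns(df, ["time_h", *VFA_NAMES], path)
    df = _numeric(df, ["time_h", *VFA_NAMES], path).sort_values("time_h")
    return VFATimeSeries(
        df["time_h"].to_numpy(),
        *(df[v].to_numpy() * f for v in VFA_NAMES),
    )


def write_vfa_csv(series: VFATimeSeries, path, unit: str = "mmol/L") -> None:
    f = _UNIT_FACTORS[unit]
    df = series.to_frame()
    for v in VFA_NAMES:
        df[v] = df[v] / f
    df.to_csv(path, index=False)


def write_estimate_csv(estimates: dict[str, ObserverEstimate], path, unit: str = "mmol/L") -> None:
    """Long-form observer output: time_h, vfa, m, z_hat, s_hat, flag."""
    f = _UNIT_FACTORS[unit]
    frames = []
    for vfa, est in estimates.items():
        frames.append(
            pd.DataFrame(
                {
                    "time_h": est.times,
                    "vfa": vfa,
                    "m": est.m,
                    "z_hat": est.z_hat / f,
                    "s_hat": est.s_hat / f,
                    "flag": np.where(est.negative, "negative", ""),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_estimate_csv(path, unit: str = "mmol/L") -> pd.DataFrame:
    f = _UNIT_FACTORS[unit]
    df = _read_table(path, ",")
    _require_columns(df, ["time_h", "vfa", "s_hat"], path)
    df = _numeric(df, ["time_h", "s_hat"], path)
    df["s_hat"] = df["s_hat"] * f
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a YAML mapping")
    return cfg


def write_provenance(outdir, config: dict, seed=None, extra=None) -> Path:
    """Machine-readable record of what produced the artifacts in outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "package": "rumen-observer",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "seed": seed,
        "config": config,
        "dialect_versions": {"proxy_csv": 1, "vfa_csv": 1, "estimate_csv": 1, "otu_tsv": 1},
    }
    if extra:
        record.update(extra)
    path = outdir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
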