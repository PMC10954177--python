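"""Core domain containers shared across the pipeline.

All concentrations are held internally in mol/L and all times in hours
(0 = start of feeding/incubation).  Proxy abundances are dimensionless
scaled counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VFA_NAMES = ("acetate", "butyrate", "propionate")

#: default mapping KEGG module -> VFA produced.  M00579 is the
#: phosphate acetyltransferase–acetate kinase module, M00013 the
#: (methyl)malonyl-CoA route to propionate, and M99999 a custom butyrate
#: module (KEGG has none for butyrate production).
DEFAULT_PROXY_MODULES = {
    "M00579": "acetate",
    "M99999": "butyrate",
    "M00013": "propionate",
}


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class ProxyTimeSeries:
    """Sampled abundance of one microbial functional proxy m_j."""

    times: np.ndarray
    values: np.ndarray
    name: str = "proxy"

    def __post_init__(self):
        object.__setattr__(self, "times", _as_float_array(self.times, "times"))
        object.__setattr__(self, "values", _as_float_array(self.values, "values"))
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("proxy abundances must be non-negative")

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def interpolate(self, t, mode: str = "linear") -> np.ndarray:
        """Evaluate the proxy at arbitrary times inside the sampled span.

        ``linear`` joins samples by straight lines; ``zoh`` holds the most
        recent sample (zero-order hold).
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.span
        if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
            raise ValueError(
                f"requested times outside measured span [{lo}, {hi}]; "
                "no extrapolation is performed"
            )
        if mode == "linear":
            return np.interp(t, self.times, self.values)
        if mode == "zoh":
            idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, len(self) - 1)
            return self.values[idx]
        raise ValueError(f"unknown interpolation mode {mode!r}")


@dataclass(frozen=True)
class VFATimeSeries:
    """Measured concentrations (mol/L) of the three major VFA."""

    times: np.ndarray
    acetate: np.ndarray
    butyrate: np.ndarray
    propionate: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", _as_float_array(self.times, "times"))
        for name in VFA_NAMES:
            object.__setattr__(self, name, _as_float_array(getattr(self, name), name))
            if getattr(self, name).size != self.times.size:
                raise ValueError(f"{name} length does not match times")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def concentration(self, vfa: str) -> np.ndarray:
        if vfa not in VFA_NAMES:
            raise KeyError(f"unknown VFA {vfa!r}")
        return getattr(self, vfa)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.times, **{v: getattr(self, v) for v in VFA_NAMES}}
        )


@dataclass(frozen=True)
class ObserverParams:
    """Operating parameters of the asymptotic observer.

    alpha
        Microbial retention factor, 0 < alpha <= 1.  Attached/aggregated
        microbes wash out at alpha*D instead of D.
    dilution_rate
        D, fraction of the liquid volume renewed per hour (1/h).
    yield_
        Y_j, mol VFA produced per unit of proxy abundance.
    """

    alpha: float = 0.85
    dilution_rate: float = 0.0335
    yield_: float = 1.0

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must satisfy 0 < alpha <= 1")
        if self.dilution_rate <= 0:
            raise ValueError("dilution rate must be positive")
        if self.yield_ <= 0:
            raise ValueError("yield must be positive")


@dataclass(frozen=True)
class OTUTable:
    """OTU counts per sample with the sampling metadata attached.

    ``counts`` is indexed by OTU id with one column per sample id;
    ``sample_times`` gives hours since the start for each sample and
    ``phase_labels`` optionally tags each sample liquid/solid/mixed.
    """

    counts: pd.DataFrame
    sample_times: pd.Series
    phase_labels: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.sample_times.index]
        if missing:
            raise ValueError(f"samples without a time: {missing}")
        times = self.sample_times.loc[self.counts.columns]
        if self.phase_labels is None:
            groups = [times]
        else:
            groups = [g for _, g in times.groupby(self.phase_labels.loc[self.counts.columns])]
        for g in groups:
            if np.any(np.diff(g.values.astype(float)) <= 0):
                raise ValueError("sample times must be strictly increasing within a phase")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class GeneContentProfile:
    """KO copy numbers per OTU (rows = OTU ids, columns = KO ids)."""

    copy_numbers: pd.DataFrame

    def __post_init__(self):
        if (self.copy_numbers.values < 0).any():
            raise ValueError("copy numbers must be non-negative")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.copy_numbers.index)

    @property
    def ko_ids(self) -> list[str]:
        return list(self.copy_numbers.columns)


@dataclass(frozen=True)
class ModuleCatalog:
    """KEGG-style module definitions: module id -> set of KO ids."""

    modules: dict[str, frozenset[str]]

    def __post_init__(self):
        for mid, kos in self.modules.items():
            if not kos:
                raise ValueError(f"module {mid} has an empty KO set")

    def __contains__(self, module_id: str) -> bool:
        return module_id in self.modules

    def __getitem__(self, module_id: str) -> frozenset[str]:
        return self.modules[module_id]

    @property
    def module_ids(self) -> list[str]:
        return list(self.modules)


@dataclass
class FitConfig:
    """Settings for maximum-likelihood yield estimation."""

    initial_guess: float | None = None  # default: mean(s)/mean(m)
    xatol: float = 1e-10
    fatol: float = 1e-10
    max_iterations: int = 2000
    log_parameterization: bool = True
    multistarts: int = 5
    seed: int = 0
    interpolation: str = "linear"

    def __post_init__(self):
        if self.initial_guess is not None and self.initial_guess <= 0:
            raise ValueError("initial guess must be positive")
        if self.xatol <= 0 or self.fatol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class FitResult:
    """Outcome of one per-VFA maximum-likelihood yield fit."""

    vfa: str
    yield_hat: float
    nll: float
    sigma2: float
    iterations: int
    converged: bool
    cvrmse: float
    n_obs: int
    unit: str = ""

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "vfa": self.vfa,
            "Y_hat": self.yield_hat,
            "loss": self.nll,
            "sigma2": self.sigma2,
            "iterations": self.iterations,
            "converged": self.converged,
            "cvrmse": self.cvrmse,
            "n_obs": self.n_obs,
        }
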