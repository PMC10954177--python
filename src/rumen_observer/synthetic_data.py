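"""Mechanistic simulator of a continuous rumen fermenter.

Ground truth for testing the whole pipeline: n microbial species x_i grow
on a pulse-fed substrate with Monod (optionally Haldane) kinetics inside
a continuously diluted vessel, with differential retention of microbes
(washout alpha*D < D):

    dx_i/dt = r_i - alpha*D*x_i,      r_i = mu_max_i * x_i * S/(Ks_i + S)
    dS/dt   = -sum_i r_i / Yx_i - D*S   (+ instantaneous feed pulses)
    ds_j/dt = sum_i Y_{j,i} * r_i - D*s_j

Functional proxies are linear read-outs of the community,
m_j = sum_i w_{j,i} * x_i.  When each species' VFA yields are
proportional to its proxy weights (Y_{j,i} = Y_j * w_{j,i}) the pair
(m_j, s_j) satisfies the observer's two-equation model exactly with
effective yield Y_j — the regime in which the observer is provably
exact.  Setting the yields non-proportionally probes its robustness.

Default parameters emulate a RUSITEC vessel: dilution 3.35 %/h,
alpha = 0.85, one feed-bag exchange per day idealized as an instantaneous
substrate jump, VFA in the tens of mmol/L, proxy abundances of order 1e4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .types import VFA_NAMES, GeneContentProfile, ModuleCatalog, OTUTable, ProxyTimeSeries, VFATimeSeries

__all__ = [
    "SpeciesKinetics",
    "SimulationConfig",
    "SyntheticDataset",
    "species_from_effective_yields",
    "simulate_ground_truth",
    "sample_measurements",
    "default_gene_content",
    "default_module_catalog",
    "emit_otu_table",
    "rusitec_preset",
    "invivo_preset",
    "perturbed_config",
]

#: sampling offsets of one RUSITEC monitoring day (hours after feeding)
RUSITEC_DAY_OFFSETS = (2.0, 4.0, 8.0, 24.0)


@dataclass(frozen=True)
class SpeciesKinetics:
    """Growth and product-formation parameters of one microbial group."""

    name: str
    mu_max: float                    # 1/h
    ks: float                        # g/L substrate half-saturation
    substrate_yield: float           # g biomass per g substrate
    vfa_yields: dict                 # VFA -> mol per g biomass growth
    proxy_weights: dict              # VFA -> proxy abundance units per g/L biomass
    x0: float                        # g/L initial biomass
    ki: float = np.inf               # g/L Haldane inhibition constant (inf = Monod)

    def rate(self, x: float, substrate: float) -> float:
        s = max(substrate, 0.0)
        denom = self.ks + s
        if np.isfinite(self.ki):
            denom = denom + s * s / self.ki
        return self.mu_max * x * s / denom


@dataclass(frozen=True)
class SimulationConfig:
    species: tuple
    dilution_rate: float = 0.0335            # 1/h
    alpha: float = 0.85
    feeding_interval_h: float = 24.0
    substrate_dose: float = 10.0             # g/L instantaneous jump per feeding
    substrate0: float = 10.0                 # g/L at t=0 (feed already supplied)
    vfa0: dict = field(
        default_factory=lambda: {"acetate": 0.05, "butyrate": 0.015, "propionate": 0.012}
    )
    duration_h: float = 72.0
    sampling_times: tuple = tuple(
        off + 24.0 * day for day in range(3) for off in RUSITEC_DAY_OFFSETS
    )
    noise_sd_proxy: float = 0.05
    noise_sd_vfa: float = 0.05
    seed: int = 0
    dense_dt: float = 0.02                   # h, ground-truth output grid

    def __post_init__(self):
        if self.duration_h < max(self.sampling_times, default=0.0):
            raise ValueError("duration must cover all sampling times")
        if not any(sp.mu_max > 0 for sp in self.species):
            raise ValueError("at least one species must be able to grow")


@dataclass(frozen=True)
class SyntheticDataset:
    """Dense ground-truth trajectories plus the generating parameters."""

    config: SimulationConfig
    times: np.ndarray                        # dense grid, h
    biomass: pd.DataFrame                    # columns = species names
    substrate: np.ndarray                    # g/L
    vfa: dict                                # VFA -> mol/L trajectory
    proxies: dict                            # VFA -> proxy trajectory
    effective_yields: dict                   # VFA -> Y_j (nan if not reducible)

    def at(self, series: np.ndarray, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, series)


def species_from_effective_yields(
    name, mu_max, ks, substrate_yield, x0, proxy_weights, effective_yields, ki=np.inf
) -> SpeciesKinetics:
    """Build a species whose VFA yields are proportional to its proxy
    weights — the exact-reduction regime of the observer model."""
    vfa_yields = {j: effective_yields[j] * proxy_weights[j] for j in proxy_weights}
    return SpeciesKinetics(
        name=name, mu_max=mu_max, ks=ks, substrate_yield=substrate_yield,
        vfa_yields=vfa_yields, proxy_weights=proxy_weights, x0=x0, ki=ki,
    )


_DEFAULT_EFFECTIVE_YIELDS = {"acetate": 1.4e-6, "butyrate": 1.6e-7, "propionate": 2.4e-6}


def _default_species() -> tuple:
    table = [
        # name, mu_max, ks, Yx, x0, weights (ac, bu, pr)
        ("fibrolytic", 0.25, 0.6, 0.15, 0.40, (60000.0, 100000.0, 8000.0)),
        ("saccharolytic", 0.20, 0.9, 0.12, 0.25, (30000.0, 60000.0, 12000.0)),
        ("propionogenic", 0.30, 1.2, 0.10, 0.10, (20000.0, 30000.0, 6000.0)),
    ]
    out = []
    for name, mu, ks, yx, x0, w in table:
        weights = dict(zip(VFA_NAMES, w))
        out.append(
            species_from_effective_yields(
                name, mu, ks, yx, x0, weights, _DEFAULT_EFFECTIVE_YIELDS
            )
        )
    return tuple(out)


def rusitec_preset(**overrides) -> SimulationConfig:
    """RUSITEC monitoring: D = 3.35 %/h, alpha = 0.85, daily feeding,
    samples at 2, 4, 8 and 24 h after feeding on 3 consecutive days."""
    cfg = SimulationConfig(species=_default_species())
    return replace(cfg, **overrides) if overrides else cfg


def invivo_preset(dilution_rate: float, **overrides) -> SimulationConfig:
    """In-vivo style monitoring: 16 samples every 3 h over 48 h.

    The ruminal fractional passage rate has no universal default and must
    be supplied.  Times run 7..52 h, matching a record that starts before
    the monitoring window.
    """
    times = tuple(7.0 + 3.0 * k for k in range(16))
    cfg = SimulationConfig(
        species=_default_species(),
        dilution_rate=dilution_rate,
        feeding_interval_h=12.0,
        substrate_dose=6.0,
        substrate0=6.0,
        duration_h=52.0,
        sampling_times=times,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _effective_yields(species) -> dict:
    out = {}
    for j in VFA_NAMES:
        ratios = [
            sp.vfa_yields.get(j, 0.0) / sp.proxy_weights[j]
            for sp in species
            if sp.proxy_weights.get(j, 0.0) > 0
        ]
        if ratios and np.allclose(ratios, ratios[0], rtol=1e-9):
            out[j] = float(ratios[0])
        else:
            out[j] = float("nan")
    return out


def simulate_ground_truth(config: SimulationConfig) -> SyntheticDataset:
    """Integrate the fermenter ODEs through the feed pulses.

    Integration is LSODA with rtol 1e-10; a state dipping below -1e-9
    raises rather than silently clipping.
    """
    species = config.species
    n = len(species)
    D, alpha = config.dilution_rate, config.alpha

    def rhs(t, y):
        x = y[:n]
        S = y[n]
        s = y[n + 1:]
        r = np.array([sp.rate(xi, S) for sp, xi in zip(species, x)])
        dx = r - alpha * D * x
        dS = -np.sum(r / np.array([sp.substrate_yield for sp in species])) - D * S
        ds = np.array(
            [sum(sp.vfa_yields.get(j, 0.0) * ri for sp, ri in zip(species, r))
             for j in VFA_NAMES]
        ) - D * s
        return np.concatenate([dx, [dS], ds])

    pulses = np.arange(config.feeding_interval_h, config.duration_h, config.feeding_interval_h)
    grid = np.unique(
        np.concatenate([
            np.arange(0.0, config.duration_h, config.dense_dt),
            [config.duration_h],
            pulses,
            np.asarray(config.sampling_times, dtype=float),
        ])
    )

    y = np.concatenate([
        [sp.x0 for sp in species],
        [config.substrate0],
        [config.vfa0[j] for j in VFA_NAMES],
    ]).astype(float)

    segments = np.concatenate([[0.0], pulses, [config.duration_h]])
    times_out, states_out = [0.0], [y.copy()]
    for t0, t1 in zip(segments[:-1], segments[1:]):
        t_eval = grid[(grid > t0) & (grid <= t1)]
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA", rtol=1e-10, atol=1e-12, t_eval=t_eval
        )
        if not sol.success:
            raise RuntimeError(f"simulation failed on [{t0}, {t1}]: {sol.message}")
        times_out.extend(sol.t.tolist())
        states_out.extend(sol.y.T)
        y = sol.y[:, -1].copy()
        if t1 in pulses:
            y[n] += config.substrate_dose
    times = np.asarray(times_out)
    states = np.asarray(states_out)
    if states.min() < -1e-9:
        raise RuntimeError("negative state encountered; integration tolerances too loose")

    x = states[:, :n]
    substrate = states[:, n]
    vfa = {j: states[:, n + 1 + k] for k, j in enumerate(VFA_NAMES)}
    proxies = {
        j: x @ np.array([sp.proxy_weights.get(j, 0.0) for sp in species])
        for j in VFA_NAMES
    }
    return SyntheticDataset(
        config=config,
        times=times,
        biomass=pd.DataFrame(x, columns=[sp.name for sp in species]),
        substrate=substrate,
        vfa=vfa,
        proxies=proxies,
        effective_yields=_effective_yields(species),
    )


def sample_measurements(
    dataset: SyntheticDataset,
    schedule=None,
    noise_sd_proxy: float | None = None,
    noise_sd_vfa: float | None = None,
    seed: int | None = None,
) -> tuple[dict, VFATimeSeries]:
    """Noisy sampling of proxies and VFA on a schedule.

    Each value is multiplied by (1 + eps), eps ~ N(0, sd), with one seeded
    stream; negative draws are truncated at zero with a warning.  sd = 0
    returns the exact trajectory values.
    """
    cfg = dataset.config
    schedule = np.asarray(cfg.sampling_times if schedule is None else schedule, dtype=float)
    if schedule.min() < dataset.times[0] or schedule.max() > dataset.times[-1]:
        raise ValueError("sampling schedule outside simulated span")
    sd_m = cfg.noise_sd_proxy if noise_sd_proxy is None else noise_sd_proxy
    sd_s = cfg.noise_sd_vfa if noise_sd_vfa is None else noise_sd_vfa
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    def noisy(values, sd):
        if sd == 0:
            return values.copy()
        out = values * (1.0 + rng.normal(0.0, sd, size=values.shape))
        if (out < 0).any():
            warnings.warn(f"{int((out < 0).sum())} negative draw(s) truncated at 0", stacklevel=2)
            out = np.clip(out, 0.0, None)
        return out

    proxies = {
        j: ProxyTimeSeries(schedule, noisy(dataset.at(dataset.proxies[j], schedule), sd_m), f"m_{j}")
        for j in VFA_NAMES
    }
    vfa_vals = {j: noisy(dataset.at(dataset.vfa[j], schedule), sd_s) for j in VFA_NAMES}
    return proxies, VFATimeSeries(schedule, vfa_vals["acetate"], vfa_vals["butyrate"], vfa_vals["propionate"])


# --- OTU-level emission: round-trip fixture for proxy inference ---------

_MODULE_KOS = {
    "M00579": ("K00625", "K00925"),            # pta / ackA
    "M99999": ("K00634", "K00929", "K01034"),  # ptb / buk / but CoA-transferase
    "M00013": ("K01847", "K11264"),            # mcm / mmd
}
_VFA_MODULE = {"acetate": "M00579", "butyrate": "M99999", "propionate": "M00013"}


def default_module_catalog() -> ModuleCatalog:
    return ModuleCatalog({m: frozenset(kos) for m, kos in _MODULE_KOS.items()})


def default_gene_content(
    config: SimulationConfig, n_background: int = 20, copy_scale: float = 1e-4
) -> GeneContentProfile:
    """KO copy numbers consistent with the species' proxy weights.

    Each species' copies over module j's KOs sum to w_{j,i} * copy_scale,
    so module aggregation of (absolute) abundances is proportional to the
    true proxies.  Background OTUs carry none of the proxy KOs.
    """
    kos = [k for kos in _MODULE_KOS.values() for k in kos]
    rows = {}
    for sp in config.species:
        row = {}
        for j, module in _VFA_MODULE.items():
            members = _MODULE_KOS[module]
            per_ko = sp.proxy_weights.get(j, 0.0) * copy_scale / len(members)
            for k in members:
                row[k] = per_ko
        rows[f"OTU_{sp.name}"] = row
    for b in range(n_background):
        rows[f"OTU_bg{b:02d}"] = {k: 0.0 for k in kos}
    return GeneContentProfile(pd.DataFrame(rows).T.fillna(0.0)[kos])


def emit_otu_table(
    dataset: SyntheticDataset,
    depth: int = 100_000,
    seed: int = 0,
    schedule=None,
    n_background: int = 20,
    background_total: float = 1.0,
) -> OTUTable:
    """Multinomial OTU counts at a fixed sequencing depth per sample.

    One OTU per simulated species plus a constant-abundance background
    community (a stable core, spanning two orders of magnitude).  The
    background anchors median-of-ratios scaling, which assumes most taxa
    do not change.
    """
    cfg = dataset.config
    schedule = np.asarray(cfg.sampling_times if schedule is None else schedule, dtype=float)
    rng = np.random.default_rng(seed)
    focal = np.vstack([dataset.at(dataset.biomass[sp.name].values, schedule) for sp in cfg.species])
    bg = np.geomspace(0.01, 1.0, n_background) if n_background else np.empty(0)
    if n_background:
        bg = bg * (background_total / bg.sum())
    abundance = np.vstack([focal, np.tile(bg[:, None], (1, len(schedule)))])
    totals = abundance.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("zero total abundance at some sample")
    counts = np.column_stack(
        [rng.multinomial(depth, abundance[:, k] / totals[k]) for k in range(len(schedule))]
    )
    otu_ids = [f"OTU_{sp.name}" for sp in cfg.species] + [f"OTU_bg{b:02d}" for b in range(n_background)]
    sample_ids = [f"S{k:02d}" for k in range(len(schedule))]
    return OTUTable(
        counts=pd.DataFrame(counts, index=otu_ids, columns=sample_ids),
        sample_times=pd.Series(schedule, index=sample_ids, name="time_h"),
    )


def perturbed_config(base: SimulationConfig, seed: int, rel: float = 0.3) -> SimulationConfig:
    """Random scenario around a base configuration (seeded).

    Kinetic parameters, initial states, dose and effective yields are
    jittered by lognormal factors of spread ``rel`` while preserving the
    exact-reduction regime (yields stay proportional to proxy weights).
    """
    rng = np.random.default_rng(seed)
    jit = lambda v: float(v * np.exp(rng.normal(0.0, rel)))  # noqa: E731
    eff = {j: jit(_DEFAULT_EFFECTIVE_YIELDS[j]) for j in VFA_NAMES}
    species = tuple(
        species_from_effective_yields(
            sp.name, jit(sp.mu_max), jit(sp.ks), jit(sp.substrate_yield), jit(sp.x0),
            {j: jit(sp.proxy_weights[j]) for j in VFA_NAMES}, eff, ki=sp.ki,
        )
        for sp in base.species
    )
    return replace(
        base,
        species=species,
        substrate_dose=jit(base.substrate_dose),
        substrate0=jit(base.substrate0),
        vfa0={j: jit(base.vfa0[j]) for j in VFA_NAMES},
        seed=int(rng.integers(0, 2**31 - 1)),
    )
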