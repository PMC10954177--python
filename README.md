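# rumen-observer

Estimate the dynamics of rumen volatile fatty acids (VFA) — acetate,
butyrate and propionate — from 16S rRNA amplicon time series, using an
asymptotic state observer driven by microbial functional proxies.

Rumen fermentation models usually need explicit kinetic rate functions
with many parameters that are hard to identify.  This package takes a
different route: for each VFA *j* it builds a **functional proxy**
*m<sub>j</sub>* — the scaled, community-wide abundance of the KEGG-module
gene subunit responsible for producing that VFA — and treats the pair
(*m<sub>j</sub>*, *s<sub>j</sub>*) as a two-state continuous-fermenter
model with dilution rate *D* and microbial retention factor *α*:

```
dm_j/dt = ρ_j − α·D·m_j
ds_j/dt = Y_j·ρ_j − D·s_j
```

The reaction rate *ρ<sub>j</sub>* is unknown, but the transformation
*z<sub>j</sub> = s<sub>j</sub> − Y<sub>j</sub>·m<sub>j</sub>* cancels it:

```
dẑ_j/dt = −D·ẑ_j − (1−α)·D·Y_j·m_j(t)
ŝ_j     = ẑ_j + Y_j·m_j
```

so the VFA concentration estimate ŝ<sub>j</sub> can be simulated from
proxy measurements alone, given *α* (default 0.85), *D* (3.35 %/h for
RUSITEC in-vitro fermenters) and the yield *Y<sub>j</sub>* (mol VFA per
proxy abundance unit), which is estimated by maximum likelihood
(Nelder–Mead on log *Y*).  Any error in the initialization is forgotten
exponentially at the fixed rate *D* — the defining property (and the
known limitation) of asymptotic observers.

The package is aimed at rumen microbiologists and modellers who have an
OTU table with sampling times, a gene-content profile (e.g. CowPI-style
KO copy numbers), and VFA concentration measurements, and want a
kinetics-free estimate of fermentation dynamics — plus a mechanistic
fermenter simulator to validate the whole chain without any external
data.

## What is in the box

| module | contents |
| --- | --- |
| `proxy_inference` | median-of-ratios size factors, count scaling, KO→module aggregation, liquid+solid phase summing, VFA proxy selection (M00579 → acetate, M99999 → butyrate, M00013 → propionate) |
| `observer` | state transformation, exact and LSODA integration of the observer ODE, analytic zero-order-hold oracle, concentration reconstruction |
| `yield_estimation` | Gaussian maximum-likelihood yield fits (Nelder–Mead, seeded multistarts), per-unit/per-VFA batch fitting with mean ± s.d. summaries |
| `evaluation` | CVRMSE (% of the observation mean), VFA molar proportions, half-up-rounded report tables |
| `synthetic_data` | Monod/Haldane multi-species fermenter with pulse feeding and microbial retention, RUSITEC and in-vivo sampling presets, noisy sampling, OTU-table emission |
| `io` / `cli` | CSV/TSV dialects, YAML configuration, provenance records, and the `rumen-observer` command line |
| `tables` | packaged per-unit reference results of the two case studies (RUSITEC vessels; four fistulated cows) |

## Worked example

Simulate a RUSITEC-style experiment (3 species, daily feeding, samples
at 2/4/8/24 h on 3 days, 5 % multiplicative measurement noise), then
estimate the yields back from the noisy samples:

```python
from rumen_observer import rusitec_preset, simulate_ground_truth, sample_measurements
from rumen_observer.yield_estimation import fit_all

cfg = rusitec_preset(seed=42)
truth = simulate_ground_truth(cfg)
proxies, vfa = sample_measurements(truth, seed=42)   # 5% multiplicative noise
results, summary = fit_all({"vessel_1": (vfa, proxies)},
                           alpha=cfg.alpha, dilution_rate=cfg.dilution_rate)
print(results[["unit", "vfa", "Y_hat", "cvrmse", "converged"]].to_string(index=False))
```

```
    unit        vfa        Y_hat   cvrmse  converged
vessel_1    acetate 1.447974e-06 6.288715       True
vessel_1   butyrate 1.565036e-07 7.355449       True
vessel_1 propionate 2.372751e-06 7.036642       True
```

The generating yields were 1.4·10⁻⁶, 1.6·10⁻⁷ and 2.4·10⁻⁶ mol per proxy
unit: each is recovered within a few percent, and the observer tracks
the noisy concentrations with a CVRMSE of 6–7 % — the same order as
reported for real fermenter data (see below).  The same steps are
available from the shell (`rumen-observer simulate | fit | observe |
evaluate`), reading and writing plain CSV.

Rendering a packaged case-study table with its summary row:

```
$ rumen-observer report --packaged invitro-cvrmse
                   acetate  butyrate   propionate
unit
inoculum1_grass        7.1      11.8         13.2
inoculum2_grass        4.6       7.8          1.3
inoculum1_hay         16.9      20.0         25.6
inoculum2_hay         10.5      16.4         18.0
Mean ± s.d.      9.8 ± 5.3  14 ± 5.3  14.5 ± 10.2
```

i.e. across the four vessel/diet combinations the observer reproduced
measured acetate with a mean CVRMSE of 9.8 %, butyrate 14 %, propionate
14.5 %.

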