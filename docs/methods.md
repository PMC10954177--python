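# Methods

## The observer model

A continuous fermenter (a RUSITEC vessel, or the rumen liquid phase)
with dilution rate *D* (1/h) hosts *n* microbial species *x_i* growing
at rates *r_i* and producing VFA.  Microbes attach to particles and form
aggregates, so they wash out more slowly than solutes; this is modelled
by a retention factor *α* ∈ (0, 1] multiplying *D* in the biomass
balance.  Rather than assigning one reaction to one species — untenable
for rumen microbes, which run many pathways at once — each VFA *j* gets
a community-level functional proxy *m_j*: the scaled abundance of the
gene subunit (a KEGG-style module) that catalyses the last steps of its
production, summed over all community members.  The working model per
VFA is then

    dm_j/dt = ρ_j(t) − α·D·m_j
    ds_j/dt = Y_j·ρ_j(t) − D·s_j

with a single unknown rate ρ_j and a yield Y_j (mol VFA per proxy
abundance unit).  Differentiating z_j = s_j − Y_j·m_j removes ρ_j:

    dz_j/dt = −D·z_j − (1−α)·D·Y_j·m_j(t)

This is the form the package integrates.  (A variant of the observer
equation sometimes written as dẑ/dt = −D·ẑ + (1−α)·Y·m is dimensionally
inconsistent — the forcing lacks a rate constant — and fails the
steady-state check below; it is available behind `literal_printed_ode`
for comparison, but never used by default.)  Two structural facts drive
everything else:

* **Steady state.** For constant m, z → −(1−α)·Y·m and hence
  ŝ → α·Y·m: with full retention (α = 1) the observer reduces to a
  static proportionality, and the forcing term vanishes entirely.
* **Fixed-rate forgetting.** The ODE is linear with eigenvalue −D, so
  two estimates started from different z(0) converge to each other
  exactly as Δz₀·e^(−Dt).  The convergence rate is an operating
  condition, not a tuning knob; at the RUSITEC D = 0.0335/h the memory
  of the initialization has an e-folding time of ~30 h.  The package
  initializes ẑ(t₀) = s(t₀) − Y·m(t₀) whenever a concentration
  measurement exists at the first proxy time, so this transient is
  absorbed by data; otherwise ẑ(t₀) = 0 with a warning.

## Proxy construction

OTU counts are scaled per sample with median-of-ratios size factors
(the estimator used by count-based differential-abundance tools): OTUs
with a zero anywhere are excluded from the geometric-mean reference —
the method's standard zero-handling — and the factor of a sample is the
median ratio of its counts to the per-OTU geometric means.  Scaled
abundances are multiplied by KO copy numbers and summed over each
module's KO set; the three proxies are M00579 (acetate;
phosphotransacetylase–acetate kinase), a custom module M99999 (butyrate;
KEGG defines none, so a placeholder KO set with the butyrate kinase /
phosphate butyryltransferase / CoA-transferase families is shipped and
meant to be overridden), and M00013 (propionate).  Gene content and
module catalogs are user-supplied inputs; only a small demonstration
catalog is packaged.  When liquid and solid phases are sequenced
separately, each phase is scaled on its own (they are separate
libraries) and the module abundances are summed afterwards on a shared
time grid; no alignment is ever implied.  OTUs missing from the gene
content contribute nothing and are reported as an unmapped fraction.

Proxies are relative measurements.  The model treats them as
proportional to absolute catalytic capacity, which makes ŝ affine in Y
and the fitted Y exactly inversely proportional to any common rescaling
of m (tested as scale equivariance); the absolute magnitude of m is
therefore meaningless on its own and only the product Y·m carries units.

## Yield estimation

Y_j is fitted per VFA and per experimental unit by maximum likelihood
under additive Gaussian error with constant variance — the argmin
coincides with least squares; σ² is profiled out.  The first usable
observation initializes ẑ and is excluded from the loss (it would
contribute an identically zero residual).  Optimization is Nelder–Mead
on log Y (positivity by construction), tolerances 1e−10, at most 2000
iterations, default 5 seeded multistarts around the moment heuristic
Y₀ = mean(s)/mean(m).  α and D are fixed by configuration, never
co-estimated.  Units are fitted independently and summarized as
mean ± sample (n−1) s.d.

## Evaluation

CVRMSE = 100·√(mean((obs−pred)²))/mean(obs), with 1/n inside the mean —
the conventional definition; it is invariant to common rescaling.
Molar proportions divide each VFA by the per-time sum of the three;
observed proportions come from observed concentrations, predicted ones
from ŝ, and CVRMSE is then applied per VFA.  Report tables round
half-up to the displayed precision; machine outputs keep full precision.
The half-up convention and the sample-s.d. convention were chosen
because together they reproduce the packaged per-unit reference tables'
own summary rows, with known exceptions: a handful of published yield
summary cells (and one CVRMSE mean that falls exactly on a rounding
half) are not arithmetically consistent with their printed per-unit
entries — they evidently summarize unrounded fits — and the tests
assert only the consistent cells.

## The synthetic fermenter

The simulator is the testbed for everything: *n* species with Monod
kinetics r_i = μ_max,i·x_i·S/(K_S,i + S) (Haldane inhibition optional
via K_I), a substrate balance dS/dt = −Σ r_i/Y_x,i − D·S, VFA balances
ds_j/dt = Σ_i Y_{j,i}·r_i − D·s_j, and differential retention α on the
biomass only.  Feeding is idealized as instantaneous substrate jumps —
the simplest mechanism that keeps the system off steady state, mimicking
daily feed-bag exchange.  Proxies are linear read-outs
m_j = Σ_i w_{j,i}·x_i.

When every species' VFA yields are proportional to its proxy weights
(Y_{j,i} = Y_j·w_{j,i}), the pair (m_j, s_j) satisfies the observer's
two-equation model *exactly*, with ρ_j = Σ_i w_{j,i}·r_i emerging
implicitly — the observer never evaluates it.  The default community is
built in this regime, so observer exactness is a provable property the
tests check to 1e−6 relative; breaking the proportionality probes
robustness.  Defaults emulate a RUSITEC vessel: D = 0.0335/h, α = 0.85,
three species (fibrolytic/saccharolytic/propionogenic caricatures,
μ_max 0.20–0.30/h, K_S 0.6–1.2 g/L), ~10 g/L substrate dosed daily,
initial VFA 50/15/12 mmol/L, proxy weights of order 10⁴–10⁵ per g/L
biomass and effective yields 1.4·10⁻⁶ / 1.6·10⁻⁷ / 2.4·10⁻⁶ mol per
proxy unit — chosen once so that concentrations (tens of mmol/L), proxy
magnitudes (10⁴–10⁵) and yields all sit in the ranges reported for real
rumen systems.  Sampling presets: RUSITEC (2, 4, 8, 24 h after feeding
on 3 consecutive days, 12 samples) and in-vivo (16 samples every 3 h,
7–52 h; the ruminal passage rate D has no defensible default and must
be supplied).  Measurement noise is multiplicative Gaussian (default
sd 5 %), seeded, truncated at zero with a flag.

For OTU-level round trips the emitter draws multinomial counts at fixed
depth from the community composition, one OTU per species plus a
constant background community (20 taxa spanning two orders of
magnitude).  The background is what makes median-of-ratios scaling
identifiable — the estimator assumes most taxa are stable — and stands
in for the large unmodelled fraction of a real rumen community.  KO
copy numbers are constructed so each species' copies over module j sum
to w_{j,i}·10⁻⁴, making module aggregation proportional to the true
proxies.

What the simulator does **not** emulate: pH and its feedback on rates,
gas phase and methane, protozoa, substrate fractionation, species
interactions, compositional artefacts beyond fixed-depth multinomial
sampling, sequencing error, and copy-number uncertainty.  Passing tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not that those assumptions hold in any given
rumen.

## Numerical choices

* Observer integration: exact piecewise closed form of the linear ODE
  under linear (default) or zero-order-hold interpolation of m between
  samples — the interpolation choice is a modelling decision the data
  cannot resolve.  An independent LSODA route (rtol 1e−10) exists and is
  cross-checked against the analytic zero-order-hold step to ~1e−10.
* Simulator: LSODA, rtol 1e−10, atol 1e−12, integrated piecewise
  between feed pulses with the dose added as a state jump; any state
  below −1e−9 aborts.  Ground truth is emitted on a 0.02 h grid
  (0.05 h where many scenarios are run).
* Fits used in tests and the acceptance script: noiseless recovery uses
  an hourly sampling grid over 72 h (separating optimizer accuracy from
  proxy-interpolation bias, which dominates at 12 samples); the noisy
  benchmark uses the realistic 12-sample RUSITEC grid, 20 scenarios,
  5 % noise.
* Negative ŝ values are flagged, never clipped — they are the visible
  symptom of a mis-specified yield or retention factor.
* Degenerate inputs fail loudly: no proxy extrapolation outside the
  measured span, no implicit time-grid alignment, scaling refuses tables
  without an all-positive OTU, fits refuse fewer than two residual
  observations.

## Known limitations

* The butyrate module's KO membership is a placeholder; real analyses
  must supply their own catalog entry.
* One scalar yield per VFA per unit assumes the community's per-proxy
  stoichiometry is time-invariant within a monitoring window.
* The observer propagates proxy measurement noise into ŝ with no
  smoothing, and its accuracy hinges on α and D being known — neither is
  identifiable from (m, s) jointly with Y in this structure.
* In-vivo use requires an externally estimated liquid passage rate.
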