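# Methods

## The model

A promoter is described by a two-state (telegraph) process: it switches
between an OFF state `D_off` and an ON state `D_on` with rates `k_on` and
`k_off`, and expression occurs from the ON state.  With first-order protein
turnover (lifetime `τ`), the stationary mean and noise (squared coefficient
of variation, `η² = σ²/μ²`) of the reporter are

```
mean = C · k_on / (k_on + k_off)
η²   = 1/mean + (k_off/k_on) · 1 / (τ·(k_on + k_off) + 1)
```

`C` is an expression-scale constant absorbing transcription, translation and
mRNA turnover; it equals the mean of an always-ON promoter.  The noise is a
Poisson-like floor `1/mean` plus a promoter-switching term: fluctuations of
the promoter state with correlation time `1/(k_on+k_off)` are low-pass
filtered by the protein lifetime, giving the factor `1/(τ(k_on+k_off)+1)`.
At a fixed mean (fixed `k_off/k_on` ratio) the noise ordering is carried by
this factor alone: slower total switching means noisier expression.

A repressing dCas9 module sterically blocks RNA-polymerase assembly and
reduces only `k_on`; an activating dCas9-ω module stabilises assembled
polymerase and reduces only `k_off`:

```
k_on  = k_on,wt  · (1 − k_r · [R]/(K_r+[R]) · int₁)
k_off = k_off,wt · (1 − k_a · [A]/(K_a+[A]) · int₂)
```

`[A]` and `[R]` are the relative guide concentrations; the guide pool of a
cell has capacity 1, split between the two guides in proportion to their
promoter strengths.  When the two guides target the **same strand** they
compete for overlapping sites, modeled as competitive Michaelis–Menten
inhibition: `K_r = K_ro(1+[A]/K_i)`, `K_a = K_ao(1+[R]/K_i)`,
`int₁ = int₂ = 1`.  When they target **opposite strands** each complex
attenuates the other: `int₁ = 1/(1+K_int1·[A])`, `int₂ = 1/(1+K_int2·[R])`
with unperturbed half-saturation constants.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `k_on,wt`, `k_off,wt` | wild-type switching rates | 1, 1 | 1/time |
| `τ` | protein lifetime | 1 | time |
| `C` | always-ON expression scale | 200 | a.u. / molecules |
| `k_r`, `k_a` | maximal fractional repression / activation | estimated | – |
| `K_ro`, `K_ao` | repressor / activator half-saturation | 0.01, 0.02 | conc. |
| `K_i` | competitive-inhibition constant | 10 | conc. |
| `K_int1`, `K_int2` | cross-strand interaction constants | 0.5, 2 | 1/conc. |
| promoter strengths | pStr : pMed : pWeak | 12 : 2.4 : 1 | relative |

`τ` is implemented as a lifetime (inverse decay rate) so that
`τ·(k_on+k_off)` is dimensionless; the formulas are only dimensionally
consistent under this reading.  `k_r` and `k_a` are clamped to [0, 1]
because larger values would drive a rate negative.  The promoter-strength
ratios encode the measured ~5-fold (strong/medium) and ~12-fold
(strong/weak) intensity ratios of the three constitutive guide promoters.
`C = 200` places the control mean at 100 fluorescence-equivalent units, so
the Poisson floor (`1/mean ≈ 0.01`) is small but not negligible against
switching noise — the regime of a moderately expressed bacterial reporter.

## Strength estimation

At guide saturation a lone repressor gives the fold change
`f = [(1−k_r)/(2−k_r)] / (1/2)` (unit wild-type rates), inverted in closed
form as `k_r = (2−2f)/(2−f)`; a lone activator gives `f = 2/(2−k_a)`,
inverted as `k_a = 2 − 2/f`.  The activation map saturates at `f = 2`
(complete loss of `k_off`); larger measured fold changes are clamped to
`k_a = 1` with a warning, since the two-state model cannot express them.
Fold changes are ratios of control-normalized means, replicate-averaged
after normalization.

## Construct classification and selection

Each paired construct receives three deterministic labels: (1) activator
targets the non-coding vs coding strand, (2) the two guides target the same
vs opposite strands, (3) the two guide concentrations are equal vs unequal
(equal means identical promoter strength; the tolerance is configurable and
defaults to exact identity).

Two three-layer decision trees select construct panels:

* **same mean, different noise** — restrict to the low-expression region
  (`1/normalized mean > 1`, i.e. below the no-guide control), then walk
  strand relation (opposite → same) and concentration (equal → unequal).
* **same noise, different mean** — restrict to the low-noise region
  (at or below the library's median noise by default), then walk activator
  strand (coding → non-coding) and strand relation (opposite → same).

The selector scans windows of mean- (or noise-) compatible constructs
(maximum pairwise relative difference within tolerance), prefers the window
covering the most tree leaves, picks one representative per leaf (the
construct closest to the window median; with a single covered leaf the whole
window is returned), and orders the result by the free axis.  Ties retain
input order.  The matching tolerances are the maximum pairwise relative
difference (5% for means, 10% for noises by default); the boundary between
high- and low-expression regions is a configurable threshold defaulting to
the control mean, and the low-noise region defaults to the median split —
both are analysis knobs, not model quantities.

When constructs are compared across categories at matched expression, points
are paired greedily (closest first) under a tolerance of ±0.03 in
1/(normalized mean), each point used at most once, and the matched subset is
tested with a two-way ANOVA (factors: category and pair).

The deviation from the constitutive linear law (`η²` vs `1/normalized
mean`) is quantified by `d_ave`: the mean vertical |residual| of the paired
constructs from the line fitted to the single-guide library, reported per
expression region.  Vertical residuals in linear coordinates are used — the
statistically standard choice; perpendicular distance or log-scaled
abscissae would change the numbers but not the regional ordering.

## Stochastic-simulation oracle

The analytic formulas are validated against an exact direct-method
Gillespie simulation of the full scheme (promoter switching, transcription
from `D_on` at `k_m`, mRNA decay `γ_m`, translation `k_p` per mRNA, protein
decay `γ_p = 1/τ`).  Auxiliary rates default to `γ_m = 10`, `k_p = 0.5`,
with `k_m = C·γ_m/(k_p·τ)` so the protein scale matches `C`.  These sit in
the formulas' validity regime: the translational burst size `k_p/γ_m =
0.05` inflates the Poisson floor by under ~5% even at the least favorable
grid corner, and with `γ_m = 10` the mRNA tier attenuates the transmitted
promoter noise by only 1–2% for total switching rates up to 2.  Validation
draws 10,000 independent cells per rate combination and requires the
empirical mean within 3 standard errors and the empirical CV² within 10%
relative of the analytic values.

Each cell starts cold at `(D_off, 0 mRNA, 0 protein)`.  The default burn-in
is ten times the *slowest* relaxation scale, `max(τ, 1/(k_on+k_off))`,
rather than a flat `10τ`: with slow promoter mixing (e.g. total switching
0.2) a flat `10τ` leaves the ON-occupancy measurably short of stationarity
from a cold start and would bias the sampled mean by several percent.
Steady-state samples are end points of independent trajectories (no
thinning), so the standard error of the mean is the plain `s/√n`.  The
multi-cell sampler advances all cells in lockstep with vectorized draws;
this is exact per cell (cells are independent) and deterministic given the
seed.

## Synthetic data generator

The generator emulates the study's measurement campaign: 48 paired
constructs (36 unique activator×repressor pairings over
{pStr,pMed,pWeak}×{A1,A2} and ×{R2,R3}, plus transcription-order swaps of
the first 12 pairings in enumeration order), nine single-guide variants
(R1–R3, A1–A6), a no-sgRNA control, and a blank — six replicates of 20,000
events each.

* **Paired constructs** are two-state: event intensities are gamma
  distributed with the analytic mean and CV² (the standard steady-state
  protein-distribution approximation, cross-checked against the SSA mode).
* **Single-guide variants** are generated as a constitutive family: the
  modulated rates set the mean, and the noise is exactly `1/mean`
  (equivalently, `k_off = 0` with a per-variant effective scale).  This
  mirrors the experimental observation that single-guide regulation keeps
  the promoter on the constitutive noise line, and it is what makes the
  single-guide library a valid reference line for `d_ave`.
* **Control** is the wild-type two-state promoter (mean `C/2`,
  `η² = 2/C + 1/3` at the defaults).
* **Blank** is a low gamma noise floor at 1% of the control mean, used only
  to exercise gating.

Each replicate carries a lognormal scale jitter (CV 5%) and each event an
independent lognormal measurement factor (CV 5%), so the pooled squared CV
obeys `(1+cv_rep²)(1+cv_meas²)(1+η²) − 1`.  The 5% replicate jitter is a
plausible placeholder for day-to-day variation (recorded in the manifest);
real replicate variability for this system is unknown.  One global seed
expands to per-(group, replicate) generators as
`default_rng([seed, group_index, replicate])`, so any subset regenerates
identically in isolation.

The ground-truth regulation strengths of the four paired-library guides
default to `A1 = 0.80, A2 = 0.70, R2 = 0.85, R3 = 0.75`.  They are not
measurable from first principles; they were fixed once, by a coarse screen
over plausible dCas9ω strengths, at the combination whose paired library
reproduces the study system's qualitative behaviour — panels of constructs
with matched mean but graded noise (and matched noise but graded mean)
spanning all decision-tree leaves exist, and mean-matched same-strand
constructs are noisier than opposite-strand ones.  The remaining
single-guide strengths (A3–A6, R1) shape only the spread of the
constitutive line and encode the position dependence of activation (optimum
near 80 bp upstream, decaying beyond).

**What passing tests on these data do and do not show.**  The generator
draws from the same moment structure the analysis assumes (gamma shapes,
lognormal noise factors, exact label bookkeeping).  Passing therefore
demonstrates internal consistency of the estimators, selectors and
statistics at realistic sample sizes — not robustness to instrument effects
absent from the generator: scatter-based gating, autofluorescence spectra,
saturation, spillover, cell-size extrinsic noise, or growth-coupled
artifacts.

## Numerical choices and degenerate inputs

* Sample (n−1) standard deviations throughout; at ≥20,000 events the
  distinction from the population estimator is negligible.
* Gating replaces scatter gates (impossible for single-channel synthetic
  data) by an intensity threshold at the blank's 0.99 quantile; the
  threshold depends only on the blank, so gating is idempotent.  A warning
  fires if any group loses more than half its events.
* Normalization uses the pooled control mean by default; a replicate-wise
  mode exists.
* Constructs whose predicted mean falls below 1% of the control mean are
  flagged degenerate (their summary statistics are noise-floor dominated).
* Mean-matched noise comparison requires `k_off/k_on` ratios equal within a
  configurable relative tolerance and errors out otherwise.
* OLS fits require ≥3 points and positive regressor variance; `R² = 1` is
  reported only for exactly collinear inputs.
* Contour grids must be strictly ascending and positive; ranges default to
  [0.01, 1] per axis (the modulated-rate domain under unit wild-type
  rates), 50×50 points.

## Problem sizes

Default analyses run the full study scale: 59 measured groups × 6
replicates × 20,000 events (~7·10⁶ events) for pipeline statistics, 10,000
simulated cells per grid point for the SSA validation, and 20 independent
synthetic studies for the recovery summary.  Unit tests use reduced sizes
(hundreds to thousands of events) chosen so each statistical assertion
retains a comfortable margin at its tolerance.

## Known limitations

* Transcription order of the two guides is metadata only; the model has no
  order term, so order-swapped constructs predict identically.
* No extrinsic-noise decomposition, cell growth, division or partitioning
  noise; the model and generator are purely intrinsic.
* Guide position enters only through each variant's catalogued role and
  strength; there is no sequence-level model of dCas9 binding.
* The activation estimator cannot represent fold changes above the model
  ceiling (2 at unit wild-type rates); such inputs are clamped with a
  warning.
* Uncertainty on estimated strengths is limited to replicate-level spread;
  no error propagation into predicted construct rates.
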