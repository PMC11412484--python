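# Methods

## Record model

Annual bests of one event are treated as iid draws x_t ~ N(μ, σ²) around a
stationary level — the null hypothesis of "no systematic progression".
All arithmetic runs on an internal maximize scale (times negated once on
entry, predictions mapped back once on exit), so the record after N years
is the maximum of N iid Gaussians. Its expectation is approximated by

    E[max] ≈ μ + σ·(a₀ + a₁L + a₂L²),  L = ln ln N,  a = (0.818, 0.574, 0.349)

and the band halfwidth by σ_E = σ·(b₀ + b₁L + b₂L²) with
b = (0.8023, −0.2751, 0.0020), clamped at zero. Published statements of
these formulas are typographically inconsistent (a₂ is quoted but absent
from the displayed equation); the full quadratic is the only reading under
which the quoted coefficients achieve the quoted 0.06 accuracy, which we
verify directly: against the exact expectation (quadrature of
N·φ(x)·Φ(x)^(N−1) over [−12, 12], absolute tolerance ≤ 1e−6, cross-checked
by seeded Monte Carlo at 10⁶ draws) the maximum absolute error over
N ∈ [3, 1000] is 0.0288. The calibration interval [3, 1000] is our choice:
the bound fails at N = 2, and practical horizons never exceed N = 27.

σ_E is used verbatim as the halfwidth of a ±1·σ_E band centered on the
prediction. We deliberately do not claim σ_E equals the standard deviation
of the N-year maximum: the quadrature oracle shows the b-polynomial
differs from sd(max) by several percent, and only the qualitative property
(positive, strictly decreasing in N) is asserted.

## Fitting and deviation classification

(μ, σ) are the sample mean and n−1 standard deviation of the annual bests
in the fit window (default 1992–2001; ≥ 2 observations required; σ = 0 is
allowed and yields a degenerate band). Horizons use N = year − first fit
year + 1, so 2018 against a 1992 window is N = 27. The observed
comparator is the running record (cumulative best since the fit-window
start), because the model predicts the best of N years; a projection year
is *inside* iff |observed − predicted| ≤ σ_E on the internal scale, else
above/below by sign. An event shows *systematic deviation* when its final
K consecutive projection years are outside on the same side; K = 5 by
default. K is an artifact decision — no formal rule exists in the
literature this implements, which reports the judgment narratively.

Operating characteristics, estimated by simulation with the packaged
generator: under the stationary null the flag fires for roughly 30% of
events (the ±1·σ_E band is narrow relative to the sampling noise of the
running record plus the estimation noise of μ̂ and σ̂ from ten
observations, and year-to-year statuses are strongly dependent); under the
default improvement regime (≈ 0.25% of the event level per year, i.e.
3–5 σ per decade, injected after the fit window) detection on the "above"
side is essentially certain. Detection power at the margins: ≈ 57% at
1 σ per decade, ≈ 90% at 2 σ per decade. The flag is therefore a
sensitive screen, not a calibrated test; treat "no flag" as consistency
with the null, and a flag as grounds to inspect the per-year table.

## Evolution statistics

Percent change between years is signed so that positive always means
improvement, with the earlier (baseline) mark as denominator:
100·(base − target)/base for times, 100·(target − base)/base for
distances. Span comparison pairs the k-th years of two equal-length spans
(default 1992–2005 vs 2005–2018, a fixed 13-year offset); a span given in
descending order pairs backwards, supporting comparisons such as 1992–2002
against 2018–2008. Ranking by mean change is dense (ties share a rank)
with ties broken by catalog order.

## TSRF and network

TSRF_j = x_j / x_i for minimize events and x_i / x_j for maximize events
(baseline i = 1992 by default, excluded from the series). The reciprocal
form for maximize events was chosen over negation because it preserves
positivity and scale-freeness and makes an event and its
reciprocal-marked mirror identical. Pearson correlations are computed
pairwise over the shared year axis (≥ 3 years; zero-variance rows are an
error) with two-sided p-values from the t-transform with n−2 df. Edges
require R > 0.7 AND p < 0.05, both strict; whether published figures also
applied the significance condition is not documented, so
`require_significance=False` exposes the R-only rule. No multiple-testing
correction is applied by default — raw p at 0.05 across the 276 pairs is
the convention this reproduces — but a Benjamini–Hochberg switch
(`fdr_correction=True`) is provided. Components are plain connected
components; no centrality or modularity statistics are computed. Strength
bands: |R| > 0.7 high, 0.4 ≤ |R| ≤ 0.7 moderate, else weak, signed.

## Synthetic panels

The generator draws, on a "performance" scale where larger is better,
perf_e(t) = δ_e·max(0, t − t₀_drift) + σ_e·z_{e,t}, then maps to native
marks (level − perf for times, level + perf for jumps). The z rows are
standard Gaussians with a user-supplied cross-event correlation (PSD with
unit diagonal; identity by default) and are independent across years — the
null being emulated is a smooth stochastic process with no memory, and no
autocorrelation evidence exists to calibrate one (an AR(1) knob exists,
default off). Drift enters the mean linearly, the minimal form that makes
band deviation detectable; `drift_start_year` lets the improvement regime
begin after a clean baseline. Positivity of every generated mark is
enforced. Identical spec + seed gives bit-identical panels.

The packaged default spec mimics the shape of the real 1992–2018 panel:
24 events with early-1990s world-class levels, year-to-year sigmas of a
few tenths of a percent of the level, a correlated block (all 13 swimming
events, both sprints, the marathon) at within-block correlation 0.8 with
improvement drift 0.25% of the level per year (the scale of the observed
swimming progression), and an uncorrelated track-and-field remainder with
slight negative drift (−0.02%/yr), mirroring the observed stagnation.

What passing tests on these panels show — and what they do not: they
validate the estimator arithmetic, the band's operating characteristics
under a known data-generating process, and structure recovery (planted
two-block panels with within/between correlation 0.9/0.0 are recovered as
exactly the two components in ≥ 99% of replicates). Real annual-best
panels have features the generator omits — rule and equipment changes
(e.g. the 2008–2009 swimsuit era), participation trends, doping-era
artifacts, serial dependence through standing records — so agreement on
synthetic data does not certify conclusions about real records, only that
the machinery computes what it claims.

## Numerical and design choices

- Quadrature: `scipy.integrate.quad` on [−12, 12] (the integrand is below
  1e−30 outside), epsabs/epsrel 1e−10, moments cached per N.
- CSV floats are written with repr-level precision, so write→read is the
  identity and pipeline reruns are byte-identical.
- Mark strings accept `8.95`, `M:SS.ff` and `H:MM:SS` dialects; parsing is
  strict (no negative components, positive totals, row-numbered errors).
- The reported problem sizes in the statistical tests (150–200 panels,
  100-replicate recovery runs, 2·10³ coverage replicates, 10⁶-draw Monte
  Carlo) were sized to keep each run's sampling error well below the
  margins being asserted while completing in seconds to a couple of
  minutes.

## Known limitations

- The σ_E band is used as published; it is not a calibrated confidence
  band, and the systematic-deviation flag's null rate (~30%) reflects
  that. A user needing a calibrated test should widen the band by a
  multiplier or use the exact oracle's sd(max).
- Annual bests are assumed Gaussian; heavy-tailed mark distributions would
  bias both μ̂/σ̂ and the band.
- No refitting of the a/b coefficients is shipped; the oracle exists to
  support it if someone needs another calibration interval.
- Event-level panel only: no athlete-level covariates, no wind/altitude/
  equipment adjustments, no female-record roster in the packaged catalog
  (user-supplied catalogs work anywhere a catalog is accepted).
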