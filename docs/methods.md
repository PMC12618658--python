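# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limitations of `pncmap`. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Station harmonization

Size-distribution records report `dN/dlog₁₀D` (cm⁻³) on a discrete diameter
grid `D₀ < … < D_{N−1}` (nm). Bin borders are placed at geometric midpoints,

    bᵢ = √(Dᵢ₋₁ · Dᵢ),          1 ≤ i ≤ N−1,

with the outer borders extrapolating the same log spacing outward,
`b₀ = 10^(1.5·log₁₀D₀ − 0.5·log₁₀D₁)` and symmetrically at the top. The
logarithmic width of bin j is `Δⱼ = log₁₀(bⱼ₊₁/bⱼ)`, and the total number
concentration is `Σⱼ (dN/dlog₁₀D)ⱼ · Δⱼ`. This treats `dN/dlog₁₀D` as
piecewise constant within bins — the representation the border construction
itself implies; trapezoidal integration over bin midpoints would be the
alternative, and differs only at the few-percent level for smooth spectra.
The same piecewise-constant reading drives the sub-100 nm fraction: a bin
straddling the cutoff contributes `log₁₀(100/bⱼ)/Δⱼ` of its number
(log-uniform apportionment).

Quality control keeps records flagged valid (0.000) or
checked-by-originator (0.100) in the NetCDF dialect, and `numflag = 0` in
the flat-text dialect. Aggregation is strictly two-stage — sub-daily records
to daily means (UTC day bucketing; leap days are ordinary days), daily means
to the annual mean — because the unweighted mean of daily means is not the
pooled record mean under uneven sampling. A station-year needs at least 150
unique days, the threshold long-term aerosol climatologies use to balance
representativeness against data yield; 149 days rejects, 150 accepts.
Negative concentrations surviving QC raise an error rather than being
clipped: flags should have removed them, so a survivor indicates a reader
bug.

## Covariate fusion

The master grid is plate-carrée with 0.01° half-open cells
`[edge, edge+size)`; points on the outer maximum boundary belong to the last
cell. One convention everywhere prevents double counting in rasterization,
regridding, and station-to-cell joins. The supported latitude extent is
55°S–68°N, the overlap of the covariate products; observations outside it,
or on sea-masked cells, are dropped with a logged reason.

Emission species arrive as per-coarse-cell totals (the emission grid is an
integer multiple of the master cell). Downscaling weights each fine cell by
the average of its population share and built-up-volume share of the coarse
block:

    Em_fine = Em_coarse · (Pop_fine/Pop_block + BV_fine/BV_block) / 2.

Both share vectors sum to one per block, so block totals are conserved
exactly. A block whose population (or built-up) sum is zero uses the uniform
share 1/k for that term — the minimal choice that preserves conservation.

Roads are counted per cell as the number of *distinct* segments whose
geometry intersects the half-open cell; a segment lying exactly on a shared
edge is counted only in the cell whose half-open box contains the edge.
Candidate cells are generated by walking the segment column-by-column, then
confirmed with exact geometric predicates.

Regridding uses nearest-neighbour for categorical layers (degree of
urbanisation) and block means of native cell centers for continuous layers;
identical grids pass through unchanged. Static layers (roads, built-up,
urbanisation) are reused across years.

## Exposure model and validation

The regressor is XGBoost with the tuned configuration (250 estimators, one
parallel tree, depth 10, learning rate 0.03, subsample and column subsample
0.75); the boosting algorithm itself is the library's. The split protocol is
nested 90/10: a test decile first, then a validation decile of the
remainder; grid search is exhaustive over a configurable discrete grid and
selects by validation RMSE (ties: fewer estimators, then shallower trees).
The evaluation schemes are 10-fold CV, spatial LOOCV (whole stations held
out) and temporal LOOCV (whole years held out), each pooling exclusively
held-out predictions, with an in-loop audit that no (station, year) key
appears on both sides of a fold. Metrics are MAE, RMSE, R², and the mean
relative error in percent. The squared-error column is reported as RMSE,
which is the quantity on the concentration scale. LOOCV folds reuse the
tuned configuration rather than re-tuning per fold; with O(100) rows per
synthetic table, per-fold tuning would mostly fit fold noise.

Population stratification uses rural < 250, suburban 250–800 (boundary
values inclusive), urban > 800 people per km², summarized as mean ±
standard error of per-row interval widths and percentage errors.

## Conformal intervals

Jackknife+ after bootstrap, written against a bare `fit`/`predict` learner
contract. B bootstrap samples of size n (with replacement, seeded) each fit
one learner; training point i's out-of-bag (OOB) prediction aggregates —
by the mean — the models whose sample excludes i, giving nonconformity
scores `Rᵢ = |yᵢ − μ̂₋ᵢ(xᵢ)|`. At a query x the lower endpoint is the
`⌊α(n+1)⌋`-th smallest of `{μ̂₋ᵢ(x) − Rᵢ}` and the upper the
`⌈(1−α)(n+1)⌉`-th smallest of `{μ̂₋ᵢ(x) + Rᵢ}`, clamped to achievable order
statistics. Points contained in every bootstrap sample have no OOB models
and are dropped from the score set (probability ≈ 0.368^B ≈ 10⁻⁹ per point
at B = 20; the count is logged). The point prediction is the full-ensemble
mean, so released point estimates and intervals come from one ensemble; a
separately trained point model would be marginally sharper but
self-inconsistent with the intervals. The coverage guarantee is ≥ 1 − 2α
under exchangeability; empirically the intervals sit near 1 − α, which the
acceptance suite measures over 50 replications (defaults α = 0.05, B = 20).

## UFP fraction model

The sub-100 nm number fractions of valid PSD records (daily means) are
fitted by maximum likelihood to a two-parameter Beta on the fixed support
[0, 1]; values are clipped into [10⁻⁶, 1−10⁻⁶] first (clip count logged),
and fits require ≥ 30 non-degenerate values. With shapes (18.75, 1.89) the
analytic mean α/(α+β) ≈ 0.9084 — a ~91% UFP share — and
sd = √(αβ/((α+β)²(α+β+1))) ≈ 0.062. The reported band is mean ± 1.96·sd
≈ [0.787, 1.030]; its upper end exceeding 1 identifies it as a normal
approximation, *not* a Beta quantile pair, so true Beta quantiles are
exposed alongside. Both the analytic mean and the sample mean are kept,
since they differ at the fourth decimal on real-sized samples. UFP maps are
`mean_fraction × PNC`; the fraction band is metadata and is deliberately not
propagated into the CI map, which reflects conformal PNC uncertainty only.
A single global fraction is used — industrial/coastal regimes with coarser
aerosol would need a localized fraction, which is out of scope.

## Explanation

Shapley attributions are exact: all 2^|F| coalition values are evaluated in
one batched predict call, with features outside the coalition masked to a
single reference point (the feature means), and combined with the weights
`|S|!(|F|−|S|−1)!/|F|!`. Enumeration is refused above 16 features; for the
14-feature model the CLI explains the top-variance 8 by default (the rest
held at their means inside the value function). Single-reference masking is
exact and cheap; background-set averaging would estimate an observational
rather than a point-reference contrast and can be layered on top by
averaging attributions over references. Tree-path ("TreeSHAP") attributions
would differ numerically; only the axiomatic properties (efficiency,
symmetry, dummy) are asserted. Attributions on a 0–1-scaled target convert
to cm⁻³ by the scaler span. Partial dependence holds non-focal features at
their means and sweeps the focal feature over its central 95% observed
range.

## Synthetic world

The generator is the package's study design, not a convenience fixture. Its
defaults define the conditions under which every end-to-end claim is tested:

* **Grid** 80×80 cells of 0.01° (tests mostly use 60×60), sea mask a fixed
  2-cell border band — deterministic and easy to assert, at the cost of no
  interior coastlines.
* **Population** — a sum of 5 Gaussian clusters (amplitudes lognormal
  around 4,000 people/cell, widths 3–7 cells) plus a uniform floor; the
  world always contains cells on both sides of the 250 and 800 people/km²
  class limits. Built-up volume is `500·pop^0.9` with 25% lognormal noise;
  settlement is smoothed population; urbanisation is the three-level class
  indicator.
* **Emissions** — block-constant on a 10× coarser grid, scaling as
  (block population)^0.9 with 20% lognormal noise, one scale per species.
  NO₂ and PM₂.₅ are smoothed transforms of population and emissions plus
  noise; temperature (288 ± 5 K), boundary-layer height (600 ± 250 m,
  floored at 100 m) and precipitation (800 ± 400 mm) are smooth Gaussian
  random fields.
* **Latent truth** — `pnc_true = exp(4.6 + 0.33·log1p(BV) + 0.30·z(NO₂) +
  0.20·z(BC) − 0.15·z(BLH) + 0.05·z(T))`, standardized over land. These
  coefficients were chosen once so that dense urban cells sit above
  10⁴ cm⁻³ and rural cells in the low thousands — the qualitative contrast
  real monitoring shows — without targeting any published number.
* **Stations** — placed without replacement with probability ∝ population
  plus a 10%-of-mean uniform floor: an urban-biased network that still
  guarantees rural coverage. 30% of stations report totals only (flat-text
  dialect); the rest report full size distributions (NetCDF dialect).
* **Size distributions** — two lognormal modes (geometric means 20 and
  150 nm, geometric SD 1.7), the simplest family with heavy sub-100 nm mass
  and a mode-weight → UFP-fraction mapping that is monotone. Each
  station-day draws its fraction from Beta(18.75, 1.89) and solves for the
  mode weight; the default diameter grid (25 log-uniform diameters,
  10^(0.55+0.1k) nm) puts a bin border exactly at 100 nm, so the
  discretized fraction equals the drawn one and parameter recovery through
  the harmonizer is unbiased. Daily totals are the local truth times
  mean-corrected lognormal day factors (σ = 0.3) and station-year factors
  (σ = 0.1) — the former keeps annual means recoverable from 150+ days, the
  latter creates irreducible between-year variability so model skill is not
  trivially perfect. Flags are invalid with probability 0.05; whole days
  drop out with probability 0.10.

What the generator does **not** emulate: realistic spatial autocorrelation
scales, instrument diversity (CPC vs SMPS cut-offs), seasonal cycles,
regional aerosol regimes (dust, marine), or the covariate measurement error
of the real products. Passing tests therefore demonstrate that the
*pipeline* is correct and well calibrated under its stated assumptions —
not that the real-data accuracy figures transfer.

The conformal coverage study uses a separate, deliberately standard
benchmark: a Friedman-style nonlinear response over five uniform features
with homoscedastic unit-variance Gaussian noise, 300 training and 300 test
points per replication.

## Numerical choices and problem sizes

* Fill value −9999 in map files; masks must agree across PNC/CI/UFP on
  read. NetCDF I/O uses xarray's scipy backend (NetCDF3 classic), readable
  by any NetCDF tool.
* Interval order statistics are clamped into [1, n]; lower is capped at
  upper to guard pathological score sets.
* Grid-search ties break toward fewer estimators, then shallower depth —
  the cheaper, more regular model.
* Default test worlds are 60×60 with 30 stations over 3 years (~90
  station-years, ~30,000 sub-daily records), sized so the full suite and
  the end-to-end checks run in well under a minute each on one CPU while
  leaving enough rows for stable CV estimates. The coverage study runs 50
  replications.

## Known limitations

* Plate-carrée cells are treated as equal-area; no projection handling.
* The spatial join is cell-containment only; no bilinear extraction at
  station coordinates.
* Real-data adapters (GeoTIFF covariates, live database retrieval) are
  extension points, not implemented.
* The conformal model serializes via joblib (pickle); exchange it within a
  matching software environment only.
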