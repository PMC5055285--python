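# Methods

This note records the models, the synthetic study conditions, and the
numerical and design choices behind `musselskill`, at the level of detail a
maintainer needs to change them safely.

## Analysis substrate

All scoring operates on **paired daily maxima**: for each site-local
calendar day (local standard time = UTC + `utc_offset`; no daylight saving),
the highest hourly value among *emersed* hours, computed independently for
the forecast and the observed series. The hour at which each side peaks need
not coincide — the quantity of physiological interest is the temperature
reached, not its timing. Days on which either side has no emersed,
non-missing hour are dropped rather than padded.

Emersion is decided by a threshold rule: a logger is emersed iff
`tide + run-up < logger_elevation`, with ties counting as submerged. Wave
run-up is the linear proxy `runup_coefficient × shore_slope × Hs` (default
coefficient 1.0). This is deliberately the simplest defensible swash model;
empirical run-up formulas vary by an O(1) factor that the exposed
coefficient absorbs.

`hourly_average` collapses sub-hourly records to in-hour arithmetic means.
Two contracts exist for already-hourly input and they conflict: hourly
*means* must pass through unchanged (idempotence), while on-the-hour *point*
measurements of slowly varying quantities are averaged with the following
observation. The caller states which applies via `point_values` (default
False = pass-through); no cadence heuristic can distinguish the two cases.

`fill_solar` completes an hourly solar record that is only observed inside
the 09:00–16:00 local window (the situation with gridded shortwave
products): hours with non-positive solar elevation are zeroed, and the
sunrise→09:00 and 16:00→sunset gaps are filled linearly between the window
boundary value and zero at the adjacent dark hour. Days with an incomplete
window are flagged and left unfilled.

## Body-temperature models

**Air proxy.** Identity copy of air temperature. Its failure mode — missing
all solar heating — is the package's reference point.

**Fixed empirical regression.** T_mussel = T_air + 5.03·L with L in
Langleys min⁻¹, or T_mussel = T_air + 7.21×10⁻³·S with S in W m⁻². The SI
coefficient is adopted verbatim as conventionally printed; re-deriving it
from first principles (1 Langley = 1 cal cm⁻², 1 cal = 4.184 J gives
1 W m⁻² = 1.434×10⁻³ Langleys min⁻¹, hence 5.03 × 1.434×10⁻³ =
7.21×10⁻³ °C per W m⁻²) agrees to the printed precision, so no conflict
arises. Negative irradiance is rejected.

**Site-fitted regression.** OLS of observed hourly logger temperature on
(1, T_air, S) over emersed hours only, via `statsmodels`. The intercept is
included by default (`include_intercept=False` available); rank-deficient
designs raise an error naming the collinear column. In the pipeline the fit
pools all loggers at a site, is trained on the chronologically first half of
the record and scored on the second half (out-of-sample) unless
`in_sample_regression` / `--in-sample` is set; in-sample fitting inflates
apparent skill, so the honest split is the default.

**Steady-state heat budget.** The emersed body is assumed to equilibrate
within the hour (the thermal time constant of a mid-size mussel is
~20–30 min), so each hour solves the algebraic balance

    α·A_p·S + εσ(T_sky⁴ − T_b⁴) + εσ(T_ground⁴ − T_b⁴)
      + h(u)·(T_air − T_b) + k_g·(T_ground − T_b) = 0

with T_ground = T_air (stated simplification), T_sky = T_air −
`sky_temp_depression` (constant-cloud longwave), evaporation neglected, and
h(u) = `convective_coeff_scale` · (max(u, 0.1 m/s) / L_c)^`convective_exponent`
— a forced-convection scaling over the shell length with a free-convection
floor at 0.1 m/s. Radiative terms use kelvins.

Default parameters (absorptivity 0.75, emissivity 0.96, projection 0.5,
L_c = 0.075 m, scale 4.0, exponent 0.5, sky depression 15 K, ground contact
conductance 10 W m⁻² K⁻¹) are documented package defaults chosen to give
realistic behaviour for a dark-shelled mussel in a horizontal bed — midday
elevations of ~5–8 °C above air at S ≈ 900 W m⁻², clear-night dips of
~2–3 °C below air. They are calibration choices, not measured constants, and
all sit in `HeatBudgetParams`.

The residual is strictly decreasing in T_b, so the root is unique. It is
bracketed a priori in [T_air − 40, T_air + 60] °C (the gain term is bounded
by 0.375·S while losses at the bracket edges exceed it for any terrestrial
irradiance) and solved by Newton steps clipped to a shrinking
bisection bracket, to |residual| < 10⁻⁶ W m⁻², vectorised over the series;
non-convergence raises with the worst residual rather than returning junk.

## Verification statistics

Daily-max pairs are binned lower-inclusive/upper-exclusive into the
seven-category scheme (bounds 0, 10, 17, 22, 32, 38 °C) and tallied into a
k×k table, rows = forecast. Bias (forecast − observed), MAE and RMSE are
computed on the raw pairs.

Per category: hit rate = n(F_iO_i)/n(O_i), false-alarm ratio =
[n(F_i) − n(F_iO_i)]/n(F_i). Both are *undefined* — carried as NaN and
rendered "NA" — when their denominator is zero; rare extreme categories make
this a routine occurrence, and silently reporting 0 would fabricate skill
information.

The Heidke and Peirce scores share the numerator PC − E (proportion correct
minus the marginal chance expectation); Heidke normalises by 1 − E, Peirce
by 1 − Σp(O_i)². They coincide whenever the forecast and observed marginals
match (an identity exercised as a property test).

The Gerrity scoring matrix is built from the observed marginal only:
p_i = n(O_i)/N, odds ratios a_i = (1 − D_i)/D_i for the leading cumulative
sums D_i (i = 1..k−1), diagonal s_ii = [Σ_{r<i} a_r⁻¹ + Σ_{r≥i} a_r]/(k−1),
off-diagonal s_ij (i<j) = [Σ_{r<i} a_r⁻¹ − (j−i) + Σ_{r≥j} a_r]/(k−1),
symmetric. This is the standard equitable construction; published renderings
of these sums are frequently garbled typographically, so the implementation
is validated structurally instead: every row satisfies Σ_j p_j·s_ij = 0
(any constant forecast scores exactly 0), s is symmetric, a perfect forecast
scores 1, and a brute-force per-event oracle agrees to 10⁻¹² on 10⁴ random
tables.

When a leading cumulative D_i is 0 or 1 before the last category (empty
leading or trailing observed categories), some a_i is 0 or infinite and the
score is undefined. The direct `gerrity()` call raises with advice to
collapse categories; `skill_report()` maps it to NaN, because a summer-only
record never observes the freezing category and an error there would be
unusable. This matches how such entries appear as NA in site-level summary
tables.

Cross-site summaries report the unweighted mean and the **sample** (n−1)
standard deviation of per-site values, NaN-skipped. Note one arithmetic
caveat: summary cells recomputed from per-site values that were themselves
rounded to two decimals can differ from independently computed cells by up
to ~0.01 — an input-rounding effect, not a formula difference.

## Synthetic study conditions

The generator emulates one heat-stress summer (default 2007-06-01 to
2007-09-01, 10-min cadence) at a temperate eastern-Pacific shore. It is the
package's study condition, fixed once; it is not tuned per experiment.

- **Air temperature**: annual-mean 14 °C + seasonal cosine (amplitude 6 °C,
  peak late July) + diurnal cosine (amplitude 5 °C, peak 15:00 local) +
  AR(1) noise (sd 1.5 °C, 6 h persistence).
- **Solar**: clear-sky geometric curve (declination/hour-angle formulas,
  1000 W m⁻² zenith peak, longitude-based solar time) × AR(1) cloud
  transmission clipped to [0.05, 1]; identically zero whenever the solar
  elevation is non-positive.
- **Tide**: mean level 0.9 m above MLLW plus harmonic constituents, default
  M2/K1/S2 at 0.8/0.4/0.25 m — a mixed semidiurnal regime that exposes a
  +1.5 m MLLW logger for roughly half of all hours.
- **Wind / wave height**: positive AR(1) processes (means 3 m s⁻¹ and
  1.0 m), clipped at zero.
- **SST**: 12 °C mean + small seasonal cycle + slow AR(1) noise — well
  below daytime air temperature, so submersion and splash cool.
- **Truth loggers**: steady-state heat budget during emersion (SST during
  submersion), plus a per-logger N(0, 2.0 °C) microsite offset, plus splash
  events that instantaneously reset an emersed logger to SST (probability
  `splash_rate` = 0.05 per emersed hour at the water line, decaying
  exponentially with the height gap, e-fold 0.5 m), plus i.i.d. N(0, 2 °C)
  instrument noise. A `truth_model="air_proxy"` mode supports exact
  self-forecast tests.

The offset scale 2.0 °C was set from E|N₁ − N₂| = 2σ/√π ≈ 1.13σ so that,
with the noise and max-selection contributions, the mean absolute
inter-logger difference of daily maxima sits in the 2–3 °C range reported
for real robomussel arrays; simulated summers average ≈2.5 °C, and splash
asymmetry produces instantaneous inter-logger differences above 10 °C
(observed arrays report maxima of 12–23 °C). Individual 3-logger summers
scatter around the band, so the regression test averages five seeds.

Determinism: every stream derives from `SeedSequence([seed, crc32(site_id),
…])`, with a fixed documented draw order (air, cloud, wind, wave, SST; per
logger: offset, splash uniforms, noise), so runs are bit-reproducible per
(seed, site, logger) and adding loggers never perturbs existing ones.

What the generator does **not** emulate: real harmonic-constituent phases,
weather fronts and coastal fog, within-bed conduction, logger loss and data
gaps, acclimatization, and any correlation between cloudiness and air
temperature. Passing tests therefore demonstrate the correctness of the
machinery and qualitative orderings (e.g. the air proxy runs cold and misses
high-stress categories), not quantitative agreement with any field record.

## Pipeline conventions

- Hourly masks and forecasts share one grid; truth generated at 10-min
  cadence is hourly-averaged, so hours straddling an emersion transition mix
  body and water temperature — as real loggers do. Exact self-forecast
  identities hold at hourly generation cadence, where the two resolutions
  coincide.
- The inter-logger baseline scores every ordered pair; bias antisymmetry
  means pair-mean bias is ~0 by construction, so its information is in the
  error magnitudes and category scores.
- Per-(site, model) failures are recorded and skipped, not fatal; the run
  fails only if nothing succeeds. A run log records hours, emersed hours and
  paired days per stage so filter attrition is auditable.
- Outputs are CSV with "NA" for missing; `provenance.json` stores the config
  hash, seed and package version.
- Default problem sizes (one 92-day summer, 3 loggers, ≤ 5 sites) keep a
  full experiment under a second; multi-year runs scale linearly and remain
  practical.

## Known limitations

- The heat-budget constants are plausible defaults, not fitted to any
  mussel data set; absolute temperatures from it should not be interpreted
  ecologically without calibration.
- The linear run-up proxy ignores wave period, beach state and infragravity
  swash; the emersion threshold is binary with no splash wetting short of
  full submersion (splash is modelled only in the synthetic truth).
- The Gerrity score is simply undefined when extreme categories are
  unobserved; no category-collapsing is performed automatically.
- No probabilistic verification (ROC, Brier), no bootstrap intervals on
  scores, and no duration-weighted (degree-heating) stress metrics.
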