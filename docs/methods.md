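# Methods

This note documents the models, conversions and design decisions behind
`kelpflux`, and what the synthetic-data generator does and does not
emulate.

## Chamber flux estimation

A sealed 20 L chamber encloses one attached kelp blade; an optode logs
dissolved O₂ (mg·L⁻¹) and temperature every minute. The protocol is 40 min
dark (respiration), a 10 min light-acclimation interval, then 40 min light
(net photosynthesis). Phase windows are cut by protocol arithmetic with a
one-minute trim at each transition to drop handling transients from
removing the dark bag; the trim length is configurable
(`IncubationProtocol.transition_trim_minutes`).

NPP and R are ordinary-least-squares slopes of O₂ against time over the
light and dark windows, converted to per-hour units, then standardised:

    flux [μmol O₂·g⁻¹ DW·h⁻¹] = slope [mg·L⁻¹·h⁻¹] × V [L] / DW [g] × 1000 / 31.998

with the O₂ molar mass fixed at 31.998 g·mol⁻¹ and V = 20 L by default (an
optional correction for the ≤ 2 % blade volume is off by default). GPP is
defined as NPP + |R|, using the dark-phase respiration as the light-phase
respiration — a standard but imperfect assumption of the chamber method,
retained deliberately and noted here. A positive dark slope (O₂ production
in the dark) is physically unexpected but possible with sensor drift; it
produces a warning flag, not an error.

**Linearity fallback.** If a phase fit falls below r² = 0.95, the estimator
searches all contiguous sub-windows of at least 10 samples and keeps the
longest one meeting the threshold (ties broken by r²), flagging the result.
This automates the salvage needed when a sensor fails partway through a
phase. If no sub-window qualifies, the full-window fit is kept flagged. A
perfectly flat trace has undefined r²; it is reported as a degenerate fit
with slope 0 rather than an error.

No blank (kelp-free) chamber correction is applied: the water-column
metabolism inside the 20 L chamber is assumed negligible relative to the
blade signal. No photosynthesis–irradiance curve is fitted; only
linear-phase fluxes are produced.

## Growth, erosion and biomass production

Holes are punched at 10 and 15 cm above the stipe–blade junction; because
the meristem sits at the blade base, the holes ride outward with newly
produced tissue. The per-hole growth rate over an interval is
(measured distance − punch position) / days, and G averages the matched
holes (a single surviving hole is acceptable; both lost yields a missing
interval with a reason code). Negative per-hole displacements are treated
as measurement anomalies — meristematic growth cannot be negative — and are
flagged and excluded unless every hole is negative.

**Repunch bookkeeping.** In the field, holes are renewed at every visit
because erosion and grazing destroy them. An observation therefore carries
the distances *measured at arrival* for the previous visit's holes, plus a
`holes_repunched` flag; the hole state carried into the next interval is
the punch positions, not the measured distances. This convention is what
makes consecutive rows of a long cohort table pairable.

Erosion is the bookkeeping residual `erosion = G − ΔBL/Δt` (apical tissue
loss offsets basal production), and the identity
`elongation + erosion = G` holds exactly for every interval by
construction. Biomass production converts linear growth to dry mass:

    BP [mg DW·d⁻¹] = G [cm·d⁻¹] × B_base [g WW·cm⁻¹] / (WW:DW) × 1000

where B_base is the mean wet weight per cm of mid-blade segments and WW:DW
their mean wet-to-dry ratio. The division by WW:DW is deliberate: the
ratio as defined (≈ 7–11) converts wet mass *down* to dry mass, and the
magnitudes only cohere this way (G ≈ 1.38 cm·d⁻¹ with B_base ≈ 0.88 g·cm⁻¹
and WW:DW 7.3 gives BP ≈ 167 mg DW·d⁻¹). Segment coefficients come from
three destructive sampling events (late May, early August, mid September);
each event's coefficients apply to the growth periods it brackets: late
May → June; early August → July and early August; September → late August
(and September, for the carbon coefficients). Intervals are assigned to
periods by their midpoint date.

## Carbon budget

Oxygen fluxes convert to carbon through the photosynthetic quotient
(PQ = 1.13 for *S. latissima* in shallow turbid water):

    mg C·d⁻¹ = (μmol O₂·h⁻¹ / PQ) × 12.01 / 1000 × photoperiod [h]

Dividing by PQ is the stoichiometric convention (PQ = moles O₂ evolved per
mole CO₂ fixed, and PQ > 1, so carbon < oxygen); a `multiply` mode is kept
behind a switch for comparison with analyses written the other way round
(the two modes differ exactly by a factor PQ²). Per-individual oxygen
rates are the per-gram fluxes times the individual's dry weight.
Photoperiods default to June/July 15.5 h, August 14.5 h, September 12.5 h.
The respiratory carbon loss is scaled by the photoperiod like the other
rates — a methodological choice recorded in the run metadata, not a claim
that respiration stops at night.

Carbon assimilation is C_assim = BP × C_avg with C_avg the mean tissue
carbon fraction (default 0.295 mg C·mg⁻¹ DW); the molar C:N ratio is
(C/12.011)/(N/14.007). Budget fractions express BP and |R| as percentages
of GPP at full precision, with nearest-integer display rounding; their
residual (100 − BP% − |R|%) is a bookkeeping upper bound on dissolved
organic release, not a DOC measurement. Missing period/quantity
combinations (e.g. no growth data in September) are reported as NA with a
reason, never dropped.

## Driver attribution

Fluxes are regressed on daily mean temperature, daily mean salinity (day
of incubation, local calendar day) and the incubation-window mean light
(PAR directly, or lux × calibration coefficient). Collinearity is screened
by iteratively removing the highest VIF above 5, where
VIF_j = 1/(1 − R²_j) from regressing predictor j on the others. The
predictor subset is chosen by exhaustive AIC over all subsets using the
convention AIC = n·ln(RSS/n) + 2k with k = predictors + intercept + error
variance; additive constants cancel in comparisons, and ties break toward
fewer predictors then lexicographically, so selection is invariant to
predictor ordering.

Dominance analysis computes, for each predictor, the incremental R² of
adding it to every subset not containing it, averaged first within subset
sizes and then across sizes (general dominance weights). The weights sum
exactly to the full-model R²; rank-deficient subsets fall back to a
pseudo-inverse fit and flag the result. The exhaustive 2^p enumeration is
capped at p = 12. "Significant" predictors reported for dominance are
those in the AIC-best model with coefficient p < 0.05. OLS fitting and
p-values are delegated to statsmodels; VIF and dominance are computed from
first principles (statsmodels' VIF serves as an independent cross-check in
the tests).

## Salinity and light conversions

Practical salinity uses the PSS-78 algorithm (UNESCO 1983 polynomials)
with reference conductivity C(35, 15, 0) = 42.914 mS·cm⁻¹, evaluated at
0 dbar by default (the loggers sit at 1–5 m; the pressure correction is
negligible there, and the pressure term is implemented for completeness).
Validity is 2–42 on the scale: values outside raise a warning, not an
error, because estuarine surface water can brush the lower bound.
Temperature input is restricted to −2…35 °C. The inverse (conductivity for
a target salinity) is solved with Brent's method to 1e-12 on the
conductivity ratio.

The lux → PAR calibration is a through-origin least-squares slope
k = Σ(lux·par)/Σ(lux²) — zero light must map to zero PAR, and a single
multiplicative coefficient is what the two-sensor deployment supports —
with the uncentred r² reported. Planar pendant loggers are known to
overestimate irradiance near low tide and solar zenith; no correction is
applied for this.

Aggregation windows are closed on both ends (boundary samples included
once); a daily summary with a single sample reports SD 0 with a degenerate
flag.

## Synthetic-data generator

The generator's defaults are the study conditions: four incubation
campaigns (8, 6, 6, 6 chambers in June, late July, late August,
September), true NPP drawn from [50, 350] and R from [−75, −15]
μmol O₂·g⁻¹ DW·h⁻¹, optode noise σ = 0.02 mg·L⁻¹, blade dry weights
4–15 g; a 40-individual cohort with growth mean 1.38 ± 0.55 cm·d⁻¹,
erosion mean 1.0 cm·d⁻¹, 15 % tag loss per interval with replacement, and
hole loss when a hole's true position passes the eroding apex; segment
events with WW:DW 10.5 / 7.3 / 9.0, B_base mean 0.88 g·cm⁻¹, C fraction
0.295, N fraction 0.0155; monthly environment targets (temperature,
irradiance, salinity means and SDs) for June through September. Dry
weights follow from realistic blade sizes (40–140 cm at B_base ≈ 0.88 and
WW:DW 7–11); the noise scales are one-significant-figure magnitudes of
instrument precision for optodes, rulers on moving blades, and field
balances.

Chamber traces are exactly linear in the dark and light phases (so the
noiseless estimator round trip is exact) with an exponential slope
relaxation (τ = 3 min) across the acclimation interval. Environment series
use a half-sine diel light curve scaled per month so the deterministic
sample mean hits the monthly target, multiplied by unit-mean lognormal
cloud noise (σ = 0.8, giving the heavy-tailed irradiance distributions
seen in moored records) and a mild 12.42 h tidal attenuation; nights are
exactly zero. Conductivity is generated by numerically inverting PSS-78
from a target salinity series, so the derived salinity round-trips.
Regression scenarios draw correlated standardised predictors and calibrate
the noise variance to a requested population R².

Randomness uses a single root seed with named, order-independent
substreams (`SeedSequence([seed, crc32(name)])`). Ground truth is returned
as sidecar structures and written to `truth.json`, never into the files
the pipeline reads.

**What passing tests do and do not show.** The generator reproduces the
*structure* of the field data — protocol timing, tag/hole loss, diel and
tidal variation, magnitudes and dispersions — but its dynamics are
idealised: phases are truly linear (no P–I saturation or photoinhibition
within the light phase), growth is stationary within intervals, erosion is
independent of grazer dynamics, and environment noise is uncorrelated in
time. Recovery tests therefore validate the estimators under the method's
own assumptions; they do not show that those assumptions hold in any real
kelp bed, and field means (growth rates, monthly environment, C:N) enter
only as emulation targets checked within sampling error (3 SE), not as
reproducible outputs.

## Numerical and reporting choices

- O₂ molar mass 31.998 g·mol⁻¹; carbon 12.01 g·mol⁻¹ in the daily-rate
  conversion; 12.011/14.007 for the molar C:N ratio.
- Problem sizes in the test and acceptance runs (200 simulated
  incubations for flux recovery, 18–40 individuals per cohort, hourly
  month-long environment series) are chosen to give tight Monte-Carlo
  checks at second-scale runtimes.
- Display rounding: one decimal for mg C·d⁻¹, nearest integer for
  percentages. Identities (GPP = NPP + |R|, erosion bookkeeping, dominance
  weight sums) are asserted before rounding, at 1e-9…1e-12.
- Stage outputs are plain CSV/JSON; a run manifest records the seed,
  config hash and per-stage row counts, and reruns with the same config
  are byte-identical.

## Known limitations

- Dark respiration stands in for light respiration in GPP; no
  photorespiration model.
- No water-column (blank chamber) correction; no DOC measurement model —
  the "implied DOC" fraction is a residual.
- The WW:DW conversion direction is a documented interpretation of an
  ambiguous published equation (division, see above); users can supply
  their own coefficient tables.
- Dominance analysis is exhaustive and so limited to ≤ 12 predictors;
  with the three field predictors this is 8 model fits.
- PSS-78, not TEOS-10: practical salinity suffices for a driver
  covariate; no absolute-salinity conversion is attempted.
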