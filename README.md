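# kelpflux

Summer primary productivity and carbon budgets for subarctic kelp
(*Saccharina latissima*), from raw field measurements to a per-period
carbon-partition table.

Kelp forests fix large amounts of carbon, but only part of what
photosynthesis captures ends up bound in tissue — the rest is respired or
released as dissolved organic carbon. Quantifying that partition requires
combining three very different field measurements: **in situ
photorespirometry** (sealed chamber incubations logging dissolved O₂ every
minute through a dark → acclimation → light protocol), **tagged-individual
growth** (holes punched above the stipe–blade junction migrate outward with
the growing blade), and **moored environmental loggers** (temperature,
conductivity, lux/PAR irradiance). `kelpflux` implements this whole chain
as a tested Python library with a synthetic-data generator that emulates
every input with known ground truth.

## What it computes

- **Oxygen fluxes.** For each incubation, NPP and R are the OLS slopes of
  O₂ (mg·L⁻¹) against time over the light and dark phases, standardised as
  `flux = slope × V / DW × 1000 / 31.998` (μmol O₂·g⁻¹ DW·h⁻¹, chamber
  volume V = 20 L), with GPP = NPP + |R|. A linearity threshold
  (r² ≥ 0.95) with a longest-linear-sub-window fallback salvages partial
  records.
- **Growth and biomass production.** G (cm·d⁻¹) from hole displacement
  between visits; apical erosion = G − ΔBL/Δt; biomass production
  BP = G × B_base / (WW:DW) × 1000 (mg DW·d⁻¹), with B_base (g WW·cm⁻¹)
  and WW:DW estimated from mid-blade segments per sampling event.
- **Carbon budget.** Oxygen → carbon with the photosynthetic quotient
  (PQ = 1.13, carbon = O₂/PQ by default), scaled to daily rates by the
  period photoperiod; carbon assimilation C_assim = BP × C_avg; budget
  fractions BP/GPP and |R|/GPP, whose residual bounds the dissolved
  organic release.
- **Driver attribution.** Flux ~ temperature + salinity + light multiple
  regression with VIF > 5 screening, exhaustive-AIC subset selection, and
  general-dominance variance decomposition (weights sum exactly to R²).
- **Conversions.** PSS-78 practical salinity from conductivity (with a
  numerical inverse), and a through-origin lux → PAR calibration.

## Worked example

```bash
python examples/flux_from_chamber_trace.py
```

```
NPP =  200.59 umol O2 / g DW / h   (true 200)
R   =  -41.88 umol O2 / g DW / h   (true -40)
GPP =  242.47 umol O2 / g DW / h   (true 240)
dark-phase fit r2 = 0.9725, light-phase fit r2 = 0.9992
```

A synthetic chamber trace generated with true NPP = 200 and
R = −40 μmol O₂·g⁻¹ DW·h⁻¹ and realistic optode noise (σ = 0.02 mg·L⁻¹)
is recovered within a few percent; with the noise switched off the round
trip is exact. The other example scripts walk through growth → biomass
(`growth_to_biomass.py`), the full budget table and GPP partition
(`carbon_budget_table.py`), dominance-based driver attribution
(`driver_attribution.py`) and the logger-stream conversions
(`environment_conversions.py`). The full pipeline is also available from
the shell:

```bash
kelpflux run-all --seed 1 --out runs/demo    # simulate -> report.md
```

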