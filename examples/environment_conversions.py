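"""Logger-stream conversions: conductivity -> salinity, lux -> PAR.

Shows the PSS-78 practical-salinity conversion at its defining point and on
estuarine values, and calibrates the lux -> PAR coefficient from paired
sensor readings.
"""

from kelpflux import (
    SimulationConfig,
    calibrate_lux_to_par,
    conductivity_from_salinity,
    salinity_from_conductivity,
)
from kelpflux.environment import C_35_15_0
from kelpflux.simulate import simulate_calibration_pairs

print(f"S(C = {C_35_15_0} mS/cm, 15 degC, 0 dbar) = "
      f"{salinity_from_conductivity(C_35_15_0, 15.0):.3f}  "
      "(defining point of the scale)")

c = conductivity_from_salinity(22.0, 9.7)
print(f"conductivity for S=22.0 at 9.7 degC: {c:.3f} mS/cm; "
      f"round trip -> {salinity_from_conductivity(c, 9.7):.6f}")

lux, par = simulate_calibration_pairs(SimulationConfig(seed=3), n=500)
cal = calibrate_lux_to_par(lux, par)
print(f"lux->PAR coefficient k = {cal.coefficient:.4f} "
      f"umol photons m^-2 s^-1 per lux (r2 = {cal.fit_r2:.4f}, "
      f"n = {cal.n_pairs})")
# k converts planar pendant-logger readings (lux) to quantum PAR units so
# both light sensors can feed the same driver regression.
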