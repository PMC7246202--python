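"""Convert a pH-reported CO2 treatment into μatm pCO2.

Many perturbation experiments report the achieved pH (with temperature,
salinity and total alkalinity) rather than pCO2.  The carbonate module
solves the seawater CO2 system for the equivalent partial pressure so
treatments can be binned into common pCO2 categories.
"""

from oameta import CarbonateState, solve_pco2, solve_ph_from_pco2

# Cold Antarctic surface water, pH on the total scale, TA in μmol/kg.
control = CarbonateState(
    temperature=1.0, salinity=34.0, ph=8.05, ph_scale="total", alkalinity=2300.0
)
acidified = control.model_copy(update={"ph": 7.70})

p_control = solve_pco2(control)
p_acidified = solve_pco2(acidified)
print(f"pH 8.05 -> pCO2 = {p_control:7.1f} μatm   (near-ambient control)")
print(f"pH 7.70 -> pCO2 = {p_acidified:7.1f} μatm   (acidified treatment)")

# The inverse: what pH does a 1,000 μatm target correspond to?
ph_1000 = solve_ph_from_pco2(1000.0, alkalinity=2300.0, temperature=1.0, salinity=34.0)
print(f"1000 μatm at the same T/S/TA corresponds to pH(total) = {ph_1000:.3f}")

# Lower pH always means more dissolved CO2: pH 8.05 is near-ambient
# (~386 μatm) while pH 7.70 lands in the 801-1,000 μatm treatment
# category used in pooling.
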