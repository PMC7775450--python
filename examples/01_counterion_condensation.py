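"""Line charge density of heparan sulphate and its condensation state.

Heparan sulphate carries up to four charged groups per nanometre of chain.
Compare its inter-charge spacing with the Bjerrum length of water at 25 degC
to decide whether counterions condense onto the chain.
"""

from glycobind import (PolyelectrolyteChain, SolventConditions,
                       bjerrum_length, charge_spacing, line_charge_density)

chain = PolyelectrolyteChain(contour_length_nm=1.0, n_charges=4,
                             label="heparan sulphate")
water = SolventConditions.from_celsius(25.0, dielectric_constant=78.5)

b = charge_spacing(chain)
state = line_charge_density(b, water)

print(f"charge spacing b        : {b:.2f} nm")
print(f"Bjerrum length (water)  : {bjerrum_length(water):.3f} nm")
print(f"line charge density xi  : {state.xi:.2f}")
print(f"condensed               : {state.is_condensed}")
print(f"condensed charge frac.  : {state.condensed_fraction:.2f}")
# xi > 1 means counterions condense onto the chain and screen
# 1 - 1/xi of its charge; only the remaining fraction is felt by an
# approaching cationic nanocapsule.
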