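"""Convert DES mole-ratio notation to weight percent water and back.

Hydrated deep eutectic solvents are labelled 1:2:n (salt : hydrogen-bond
donor : water); n is the hydration parameter every observable is plotted
against after conversion to wt % water.
"""

from desfold import glycerol_des, urea_des, water_mole_ratio, wt_percent_water

for n in (0.4, 1.0, 2.0, 5.0, 10.0, 20.0):
    wt_g = wt_percent_water(glycerol_des(n))
    wt_u = wt_percent_water(urea_des(n))
    print(f"n = {n:5.1f}   ChCl:Glyc {wt_g:5.1f} wt %   ChCl:Urea {wt_u:5.1f} wt %")

# the inverse: which n gives a half-water solvent?
n_half = water_mole_ratio(50.0, glycerol_des(0.0))
print(f"\n50 wt % water in ChCl:Glyc requires n = {n_half:.2f}")
print("(each wt % is the water mass fraction of the whole solvent mixture)")
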