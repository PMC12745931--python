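"""Effective thermal properties of the nest subdomains.

Beach sand and the looser sand a female turtle packs back into the egg
chamber are three-phase mixtures (quartzite grains, water, air).  From the
field measurements alone — dry bulk density and gravimetric moisture — this
derives the volume fractions, the Mori-Tanaka effective conductivity and
the rule-of-mixtures heat capacity used by the simulator.
"""

from nestherm import BEACH_SAND, NEST_SAND, properties_table, volume_fractions

f_solid, f_water, f_air = volume_fractions(1282.2, 2650.0, 0.04)
print("beach sand volume fractions:")
print(f"  solid {f_solid:.4f}  water {f_water:.4f}  air {f_air:.4f}")
print()
print("subdomain property table (density kg/m3, conductivity W/m/C,")
print("volumetric heat capacity kJ/m3/C):")
print(properties_table().round(2).to_string())
print()
print("Nest-chamber sand is looser than beach sand (a turtle cannot repack")
print("sand to its undisturbed density), so it conducts heat more poorly:")
print(f"  beach {BEACH_SAND.dry_bulk_density} kg/m3 -> k = 2.2 W/m/C")
print(f"  nest  {NEST_SAND.dry_bulk_density} kg/m3 -> k = 1.7 W/m/C")
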