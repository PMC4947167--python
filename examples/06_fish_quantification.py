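"""Count single RNA molecules in a 3D smFISH stack.

Simulates a stack with 68 diffraction-limited spots, 94% cytoplasmic
(the published per-cell scale for NORAD in U2OS cells), and runs the full
quantification: 3D LoG filtering, stability-based threshold selection,
background removal and nuclear/cytoplasmic assignment.
"""

from decoyscan.fish import (assign_compartment, detect_spots,
                            remove_background)
from decoyscan.simulate import gen_fish_stack

signal, dapi, truth = gen_fish_stack(n_spots=68, cyto_fraction=0.94,
                                     snr=10, seed=1)
spots = detect_spots(signal)
[spots], removed = remove_background([spots])
spots = assign_compartment(spots, dapi)
fractions = spots.compartment_fractions()

print(f"planted spots          : {len(truth)}")
print(f"detected spots         : {len(spots)}")
print(f"selected threshold     : {spots.selected_threshold:.2f}")
print(f"background removed     : {removed:.1%}")
print(f"cytoplasmic fraction   : {fractions['cytoplasmic']:.1%}")
print(f"nuclear fraction       : {fractions['nuclear']:.1%}")
print("\nEach detected component is one RNA molecule; the DAPI mask "
      "splits the counts\ninto nuclear vs cytoplasmic, the localization "
      "signature of a cytoplasmic decoy.")
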