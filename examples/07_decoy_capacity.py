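"""Decoy stoichiometry: can the RNA's sites soak up the protein pool?

Multiplies transcript copies per cell by binding sites per copy and
compares the result with the proteins' cellular copy numbers (the
published NORAD/Pumilio numbers: ~70 copies x 17 PREs vs ~200 PUM1 and
~550 PUM2 proteins).
"""

from decoyscan.stoichiometry import binding_capacity

model = binding_capacity(70, 17, {"PUM1": 200, "PUM2": 550}, round_to=100)

print(f"site capacity          : {model.site_capacity:.0f} "
      f"(~{model.site_capacity_rounded:.0f})")
print(f"protein pool           : {sum(model.protein_copies.values()):.0f} "
      f"copies/cell")
print(f"site : protein ratio   : {model.site_to_protein_ratio:.2f}")
print("\nThe decoy offers more simultaneous binding sites than there are "
      "Pumilio\nproteins in the cell - enough to buffer their repressive "
      "activity.")
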