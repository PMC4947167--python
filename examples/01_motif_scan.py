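"""Scan published NORAD repeat-9 oligos for Pumilio recognition elements.

The wild-type oligo carries two PREs; the mutant (TGTG->ACA) destroys the
first one. The 3x luciferase reporter element carries three strong PREs;
its mutated version none.
"""

from decoyscan.motifs import PRE_DENSITY, PRE_TARGET, scan_motif
from decoyscan.sequences import (PRE_ELEMENT_MUT, PRE_ELEMENT_WT,
                                 REPEAT9_MUT, REPEAT9_WT)

for name, seq, pattern in [
    ("repeat-9 wild type", REPEAT9_WT, PRE_DENSITY),
    ("repeat-9 PRE mutant", REPEAT9_MUT, PRE_DENSITY),
    ("3x PRE reporter", PRE_ELEMENT_WT * 3, PRE_TARGET),
    ("3x mutPRE reporter", PRE_ELEMENT_MUT * 3, PRE_TARGET),
]:
    hits = scan_motif(seq, pattern, mode="nonoverlapping")
    offsets = ", ".join(f"{h.start}:{h.match}" for h in hits) or "none"
    print(f"{name:22s} ({pattern.consensus}): {len(hits)} hits [{offsets}]")

print("\nEach hit is a non-overlapping occurrence of the degenerate PRE "
      "consensus;\nthe wild-type/mutant difference is what the pulldown "
      "and reporter assays exploit.")
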