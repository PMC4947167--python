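"""Motif-density statistic against the dinucleotide-preserving null.

Builds a 5.3-kb transcript-scale sequence with 17 planted PREs (the scale
of the NORAD decoy) and compares the observed non-overlapping count with
the expectation over 1,000 dinucleotide-preserving shuffles.
"""

from decoyscan.motifs import PRE_DENSITY, count_nonoverlapping
from decoyscan.shuffle import motif_enrichment
from decoyscan.simulate import gen_background_seq, plant_motifs

bg = gen_background_seq(5339, seed=301)
transcript, positions = plant_motifs(bg, PRE_DENSITY, 17, seed=17,
                                     min_gap=100)
null = motif_enrichment(transcript, PRE_DENSITY, n_shuffles=1000, seed=1)

print(f"observed non-overlapping PREs : {null.observed}")
print(f"expected under shuffle null   : {null.expected:.3f}")
print(f"empirical p (add-one)         : {null.p_empirical:.4g}")
print("\nThe observed count dwarfs what the sequence's own dinucleotide "
      "composition\nwould produce by chance - the signature of a "
      "multi-site protein decoy.")
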