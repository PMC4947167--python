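"""Published NORAD-derived sequences used throughout the package.

These are the in vitro transcription / reporter sequences for the ninth
NORAD repeat unit and for the strong-PRE luciferase reporter element, given
here DNA-style.  The wild-type repeat-9 oligo carries two PREs; the mutant
oligo carries a TGTG->ACA substitution that destroys the first of them.
The 28-nt reporter element carries one strong PRE (TGTACATA); the mutant
element carries the ACAACATA substitution that inactivates it.
"""

#: 161-nt wild-type oligo spanning NORAD repeat unit 9 (two PREs).
REPEAT9_WT = (
    "GTCTGCATTTTCATTTACTGTGCTGTGTATATAGTGTATATAAGCGGACATAGGAGTCCTAATTTACG"
    "TCTAGTCGATGTTAAAAAGGTTGCCAGTATATGACAAAAGTAGAATTAGTAAACTACTACATTGAGTA"
    "CACTTTGTGTTAAAATTCATAGGGA"
)

#: Repeat-9 oligo with the first PRE mutated (TGTG -> ACA).
REPEAT9_MUT = (
    "GTCTGCATTTTCATTTACTGTGCTACATATATAGTGTATATAAGCGGACATAGGAGTCCTAATTTACG"
    "TCTAGTCGATGTTAAAAAGGTTGCCAGTATATGACAAAAGTAGAATTAGTAAACTACTACATTGAGTA"
    "CACTTTGTGTTAAAATTCATAGGGA"
)

#: 28-nt reporter element with one strong wild-type PRE (TGTACATA).
PRE_ELEMENT_WT = "TTGTTGTCGAAAATTGTACATAAGCCAA"

#: The same element with the PRE mutated (TGTACATA -> ACAACATA).
PRE_ELEMENT_MUT = "TTGTTGTCGAAAATACAACATAAGCCAA"
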