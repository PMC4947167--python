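"""Degenerate (IUPAC) motif patterns and scanning.

The motifs of interest here are the Pumilio recognition elements:
``UGURUAUA`` (R = A/G), the consensus used for motif-density statistics on
NORAD itself, and ``UGUANAUA`` (N = any base), the looser consensus used for
genome-wide 3'-UTR target calling.  Scanning supports overlapping counting
(all match offsets) and greedy left-to-right non-overlapping counting, the
natural reading of "non-overlapping instances" of a motif.

Coordinates are 0-based, half-open throughout (BED-compatible).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .seqio import SequenceRecord, as_record

#: IUPAC nucleotide codes, with U accepted as a synonym for T.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif as per-position allowed-base sets."""

    name: str
    consensus: str
    sets: tuple[frozenset[str], ...]

    @property
    def length(self) -> int:
        return len(self.sets)

    def matches(self, word: str) -> bool:
        return len(word) == self.length and all(
            c in s for c, s in zip(word, self.sets)
        )


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``end - start`` equals the pattern length."""

    seq_id: str
    start: int
    end: int
    match: str
    strand: str = "+"


def parse_iupac(consensus: str, name: str | None = None) -> MotifPattern:
    """Compile an IUPAC consensus into per-position allowed-base sets.

    Raises ``ValueError`` naming the (1-based) position of any character
    that is not an IUPAC nucleotide code.
    """
    if not consensus:
        raise ValueError("empty consensus")
    sets = []
    for i, c in enumerate(consensus.upper()):
        try:
            sets.append(frozenset(IUPAC_CODES[c]))
        except KeyError:
            raise ValueError(
                f"non-IUPAC character {c!r} at position {i + 1} of "
                f"{consensus!r}"
            ) from None
    return MotifPattern(name=name or consensus, consensus=consensus,
                        sets=tuple(sets))


#: PRE consensus for motif-density statistics (R = A/G).
PRE_DENSITY = parse_iupac("UGURUAUA", name="PRE/UGURUAUA")
#: PRE consensus for 3'-UTR target calling (N = any).
PRE_TARGET = parse_iupac("UGUANAUA", name="PRE/UGUANAUA")


def _match_positions(seq: str, pattern: MotifPattern) -> np.ndarray:
    """All 0-based offsets where the pattern matches (vectorised)."""
    L, m = len(seq), pattern.length
    n = L - m + 1
    if n <= 0:
        return np.empty(0, dtype=np.intp)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ok = np.ones(n, dtype=bool)
    for p, allowed in enumerate(pattern.sets):
        table = np.zeros(256, dtype=bool)
        for b in allowed:  # 'N' in the subject is never in a set: no match
            table[ord(b)] = True
        ok &= table[codes[p:p + n]]
    return np.flatnonzero(ok)


def scan_motif(
    seq: "str | SequenceRecord",
    pattern: MotifPattern,
    mode: Literal["overlapping", "nonoverlapping"] = "nonoverlapping",
    scan_reverse: bool = False,
) -> list[MotifHit]:
    """Scan a sequence for a degenerate motif.

    ``overlapping`` returns every match offset; ``nonoverlapping`` returns
    the greedy left-to-right maximal set (after accepting a hit at *i*, the
    scan restarts at ``i + pattern.length``).  Only the given (sense) strand
    is scanned unless ``scan_reverse`` is set, in which case hits on the
    reverse complement are reported too, with ``strand='-'`` and coordinates
    on the forward sequence.
    """
    rec = as_record(seq)
    if mode not in ("overlapping", "nonoverlapping"):
        raise ValueError(f"unknown mode {mode!r}")
    m = pattern.length

    def _hits(s: str, strand: str) -> list[MotifHit]:
        pos = _match_positions(s, pattern)
        if mode == "nonoverlapping":
            kept, nxt = [], 0
            for i in pos:
                if i >= nxt:
                    kept.append(i)
                    nxt = i + m
            pos = kept
        L = len(s)
        out = []
        for i in pos:
            if strand == "+":
                out.append(MotifHit(rec.id, int(i), int(i) + m,
                                    s[i:i + m], "+"))
            else:  # map back onto forward coordinates
                out.append(MotifHit(rec.id, L - int(i) - m, L - int(i),
                                    s[i:i + m], "-"))
        return out

    hits = _hits(rec.seq, "+")
    if scan_reverse:
        rc = rec.seq.translate(_COMPLEMENT)[::-1]
        hits += _hits(rc, "-")
        hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def count_nonoverlapping(seq: "str | SequenceRecord",
                         pattern: MotifPattern) -> int:
    """Number of greedy non-overlapping motif instances."""
    return len(scan_motif(seq, pattern, mode="nonoverlapping"))


def hits_to_bed(hits: Iterable[MotifHit], path: str | Path) -> None:
    """Write hits as BED6 (name = matched word, score = 0)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.start}\t{h.end}\t{h.match}\t0\t"
                     f"{h.strand}\n")
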