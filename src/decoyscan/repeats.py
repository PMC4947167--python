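"""Tandem-repeat architecture of a transcript by self-comparison.

A word-match self-dotplot (exact k-mer matches between distinct positions)
exposes tandem repeats as off-diagonal lines; the repeat period is read off
as the smallest offset whose match density peaks, and the repeat region is
segmented into units of that period.  Repeat units are then annotated for
the element classes that recur in NORAD's ~300-nt units: one or two PREs, a
short 4-bp-stem hairpin, a U-rich run of 2-5 nt, and a long 8-9-bp-stem
hairpin.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .motifs import MotifHit, MotifPattern, PRE_DENSITY, scan_motif
from .seqio import as_record

_PAIRS_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_PAIRS_GU = _PAIRS_WC | {("G", "T"), ("T", "G")}


@dataclass
class DotMatrix:
    """Exact k-word self-matches of a sequence, stored for i < j."""

    length: int
    k: int
    pairs: np.ndarray  # (n, 2) array of (i, j) with i < j
    offset_density: np.ndarray  # density per offset d = j - i

    @property
    def n_matches(self) -> int:
        return len(self.pairs)


@dataclass
class RepeatUnitSet:
    period: int | None
    span: tuple[int, int] | None
    boundaries: list[tuple[int, int]]

    @property
    def n_units(self) -> int:
        return len(self.boundaries)


@dataclass
class Hairpin:
    """A contiguous stem of ``stem_len`` pairs enclosing a loop."""

    start: int  # 5' end of the stem (0-based)
    end: int  # half-open end of the 3' arm
    stem_len: int
    loop_start: int
    loop_end: int

    @property
    def loop_len(self) -> int:
        return self.loop_end - self.loop_start


@dataclass
class UnitAnnotation:
    pre_hits: list[MotifHit]
    short_hairpins: list[Hairpin]
    u_rich_runs: list[tuple[int, int]]
    long_hairpins: list[Hairpin]

    @property
    def element_presence(self) -> dict[str, bool]:
        return {
            "pre": bool(self.pre_hits),
            "short_hairpin": bool(self.short_hairpins),
            "u_rich": bool(self.u_rich_runs),
            "long_hairpin": bool(self.long_hairpins),
        }


def self_dotplot(seq, k: int = 8) -> DotMatrix:
    """All exact k-word matches between distinct positions of a sequence.

    Per-offset density is the number of matching position pairs at offset
    ``d`` divided by the number of comparable pairs, ``L - d - k + 1``.
    """
    s = as_record(seq).seq
    L = len(s)
    if L < k:
        raise ValueError(f"sequence length {L} shorter than word size {k}")
    where: dict[str, list[int]] = defaultdict(list)
    for i in range(L - k + 1):
        where[s[i:i + k]].append(i)
    pairs = []
    for positions in where.values():
        for ai in range(len(positions) - 1):
            for bi in range(ai + 1, len(positions)):
                pairs.append((positions[ai], positions[bi]))
    pairs_arr = (np.array(sorted(pairs), dtype=np.intp)
                 if pairs else np.empty((0, 2), dtype=np.intp))

    density = np.zeros(L, dtype=float)
    if len(pairs_arr):
        offs = pairs_arr[:, 1] - pairs_arr[:, 0]
        counts = np.bincount(offs, minlength=L)
        for d in np.flatnonzero(counts):
            denom = L - d - k + 1
            if denom > 0:
                density[d] = counts[d] / denom
    return DotMatrix(length=L, k=k, pairs=pairs_arr, offset_density=density)


def estimate_period_and_segment(
    dm: DotMatrix,
    min_density: float = 0.2,
    min_period: int = 30,
) -> RepeatUnitSet:
    """Estimate the tandem period and cut the repeat region into units.

    The period is the smallest offset >= ``min_period`` whose match density
    is a local maximum above ``min_density``.  The repeat-region span is
    the union of coordinates matching at (near-)multiples of the period,
    and unit boundaries are cut at period intervals from the span start.
    An empty RepeatUnitSet (no offset passes) is a result, not an error.
    """
    dens = dm.offset_density
    candidates = [
        d for d in range(min_period, len(dens))
        if dens[d] >= min_density
        and dens[d] >= (dens[d - 1] if d >= 1 else 0.0)
        and dens[d] >= (dens[d + 1] if d + 1 < len(dens) else 0.0)
    ]
    if not candidates:
        return RepeatUnitSet(period=None, span=None, boundaries=[])
    period = int(candidates[0])

    offs = dm.pairs[:, 1] - dm.pairs[:, 0]
    tol = max(2, period // 100)
    mult = np.abs(((offs + period // 2) % period) - period // 2) <= tol
    sel = dm.pairs[mult]
    if not len(sel):
        return RepeatUnitSet(period=period, span=None, boundaries=[])
    start = int(sel[:, 0].min())
    end = int(sel[:, 1].max()) + dm.k
    n_units = max(1, round((end - start) / period))
    boundaries = [
        (start + u * period, min(start + (u + 1) * period, dm.length))
        for u in range(n_units)
    ]
    return RepeatUnitSet(period=period, span=(start, end),
                         boundaries=boundaries)


def find_hairpins(
    seq,
    stem_min: int,
    stem_max: int,
    loop_min: int = 3,
    loop_max: int = 30,
    allow_gu: bool = False,
) -> list[Hairpin]:
    """All maximal contiguous-stem hairpins with stem length in range.

    A hairpin is a run of ``s`` contiguous Watson-Crick pairs (G-U wobble
    optional) enclosing a loop of ``loop_min..loop_max`` unpaired-by-
    construction bases.  Each stem is reported once, at its maximal
    extension: stems that could be extended outward, or inward without the
    loop dropping below ``loop_min``, are not reported separately.
    """
    if stem_min < 2:
        raise ValueError("stem_min must be >= 2")
    s = as_record(seq).seq
    L = len(s)
    pairs = _PAIRS_GU if allow_gu else _PAIRS_WC

    def paired(i: int, j: int) -> bool:
        return 0 <= i and j < L and (s[i], s[j]) in pairs

    out = []
    for a in range(L):
        for loop_len in range(loop_min, loop_max + 1):
            b = a + loop_len  # loop is s[a:b]
            if b >= L:
                break
            # stem grows outward from (a-1, b)
            st = 0
            while paired(a - 1 - st, b + st):
                st += 1
            if not (stem_min <= st <= stem_max):
                continue
            # inward-maximality: the innermost loop bases must not pair,
            # unless pairing them would shrink the loop below loop_min
            if loop_len - 2 >= loop_min and paired(a, b - 1):
                continue
            out.append(Hairpin(start=a - st, end=b + st, stem_len=st,
                               loop_start=a, loop_end=b))
    return out


def find_u_rich(seq, min_run: int = 2, max_run: int = 5) -> list[tuple[int, int]]:
    """Maximal U (T) runs whose length lies in [min_run, max_run]."""
    s = as_record(seq).seq
    return [
        (m.start(), m.end())
        for m in re.finditer(r"T+", s)
        if min_run <= m.end() - m.start() <= max_run
    ]


def annotate_unit(
    unit_seq,
    pattern: MotifPattern = PRE_DENSITY,
    allow_gu: bool = False,
) -> UnitAnnotation:
    """Annotate one repeat unit for its recurring element classes."""
    rec = as_record(unit_seq)
    return UnitAnnotation(
        pre_hits=scan_motif(rec, pattern, mode="nonoverlapping"),
        short_hairpins=find_hairpins(rec, 4, 4, allow_gu=allow_gu),
        u_rich_runs=find_u_rich(rec),
        long_hairpins=find_hairpins(rec, 8, 9, allow_gu=allow_gu),
    )


def plot_dotplot(dm: DotMatrix, path=None, ax=None):
    """Render the self-dotplot (both triangles) as a scatter of matches."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    if len(dm.pairs):
        ax.plot(dm.pairs[:, 0], dm.pairs[:, 1], ".", ms=1, color="k")
        ax.plot(dm.pairs[:, 1], dm.pairs[:, 0], ".", ms=1, color="k")
    ax.plot([0, dm.length], [0, dm.length], lw=0.5, color="0.7")
    ax.set(xlim=(0, dm.length), ylim=(dm.length, 0),
           xlabel="position (nt)", ylabel="position (nt)",
           title=f"self-dotplot, k={dm.k}")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
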