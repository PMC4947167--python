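"""Genome-wide Pumilio target calling from 3'-UTR site excess.

A gene is called a *target* when its 3'-UTR carries at least two more
non-overlapping UGUANAUA sites than expected given the UTR's length and
composition; a *control* when it carries no more sites than expected; and
*intermediate* otherwise (intermediates are excluded from both analysis
groups downstream).  Expected counts come either from per-UTR
dinucleotide-preserving shuffles (default, consistent with the transcript
density statistic) or from a fast closed-form mononucleotide model whose
frequencies are estimated from the whole supplied UTR set.

Length-matched control sampling divides all genes into 10 bins by 3'-UTR
length (deciles over targets and pool together) and samples, per bin and
without replacement, as many controls as there are targets.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .motifs import MotifPattern, PRE_TARGET, count_nonoverlapping
from .seqio import SequenceRecord, as_record
from .shuffle import dinucleotide_shuffle, expected_analytic


@dataclass(frozen=True)
class UTRRecord:
    gene_id: str
    utr_seq: SequenceRecord

    @property
    def utr_length(self) -> int:
        return len(self.utr_seq)


def make_utr(gene_id: str, seq: "str | SequenceRecord") -> UTRRecord:
    return UTRRecord(gene_id=gene_id, utr_seq=as_record(seq, id=gene_id))


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    observed: int
    expected: float
    klass: str  # "target" | "control" | "intermediate"

    @property
    def excess(self) -> float:
        return self.observed - self.expected


@dataclass
class ControlSample:
    bin_edges: np.ndarray
    targets_per_bin: list[int]
    sampled_controls: list[str]
    seed: int | None


def mono_freqs_from_utrs(utrs: Iterable[UTRRecord]) -> dict[str, float]:
    """Mononucleotide frequencies pooled over a UTR set (N excluded)."""
    counts = Counter()
    for u in utrs:
        counts.update(u.utr_seq.seq)
    counts.pop("N", None)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no sequence content in UTR set")
    return {b: counts.get(b, 0) / total for b in "ACGT"}


def expected_sites(
    utr: UTRRecord,
    pattern: MotifPattern = PRE_TARGET,
    method: Literal["shuffle", "analytic"] = "shuffle",
    n_shuffles: int = 200,
    rng: np.random.Generator | None = None,
    mono_freqs: dict[str, float] | None = None,
) -> float:
    """Expected non-overlapping site count for one UTR.

    ``shuffle``: mean count over dinucleotide-preserving permutations of
    this UTR.  ``analytic``: closed form under an i.i.d. model with the
    supplied mononucleotide frequencies (an occurrence expectation).
    Empty UTRs have expectation 0.
    """
    L = utr.utr_length
    if L == 0:
        return 0.0
    if method == "analytic":
        if mono_freqs is None:
            raise ValueError("analytic method needs mono_freqs")
        return expected_analytic(L, pattern, mono_freqs)
    if method != "shuffle":
        raise ValueError(f"unknown method {method!r}")
    if L < 2:
        return 0.0
    if rng is None:
        rng = np.random.default_rng()
    s = utr.utr_seq.seq
    counts = [
        count_nonoverlapping(dinucleotide_shuffle(s, rng), pattern)
        for _ in range(n_shuffles)
    ]
    return float(np.mean(counts))


def classify_genes(
    utrs: Sequence[UTRRecord],
    pattern: MotifPattern = PRE_TARGET,
    method: Literal["shuffle", "analytic"] = "shuffle",
    n_shuffles: int = 200,
    seed: int | None = None,
    min_excess: float = 2.0,
) -> list[TargetCall]:
    """Classify every gene as target / control / intermediate.

    target: excess >= ``min_excess`` (default 2 extra sites);
    control: observed <= expected; intermediate: everything else.
    Genes with absent/empty UTRs are excluded with a warning.  Duplicate
    gene ids are rejected.
    """
    ids = [u.gene_id for u in utrs]
    dupes = [g for g, c in Counter(ids).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")

    empty = [u.gene_id for u in utrs if u.utr_length == 0]
    if empty:
        warnings.warn(
            f"excluding {len(empty)} gene(s) with empty 3'-UTRs "
            f"(e.g. {empty[:3]})"
        )
    kept = [u for u in utrs if u.utr_length > 0]

    mono = mono_freqs_from_utrs(kept) if method == "analytic" else None
    rng = np.random.default_rng(seed)
    calls = []
    for u in kept:
        obs = count_nonoverlapping(u.utr_seq, pattern)
        exp = expected_sites(u, pattern, method=method, n_shuffles=n_shuffles,
                             rng=rng, mono_freqs=mono)
        if obs - exp >= min_excess:
            klass = "target"
        elif obs <= exp:
            klass = "control"
        else:
            klass = "intermediate"
        calls.append(TargetCall(u.gene_id, obs, exp, klass))
    return calls


def calls_to_frame(calls: Iterable[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.observed, c.expected, c.excess, c.klass)
         for c in calls],
        columns=["gene_id", "observed", "expected", "excess", "klass"],
    )


def sample_length_matched_controls(
    calls: Sequence[TargetCall],
    utrs: Sequence[UTRRecord],
    n_bins: int = 10,
    seed: int | None = None,
) -> ControlSample:
    """Sample length-matched controls, one per target, within length bins.

    Bin edges are deciles of all supplied genes' UTR lengths (targets and
    pool together).  Within each bin, as many controls as targets are drawn
    without replacement; a bin with too few controls is an error naming the
    bin.
    """
    lengths = {u.gene_id: u.utr_length for u in utrs}
    call_by_id = {c.gene_id: c for c in calls}
    missing = [g for g in call_by_id if g not in lengths]
    if missing:
        raise ValueError(f"no UTR length for genes: {missing[:5]}")

    all_len = np.array([lengths[c.gene_id] for c in calls], dtype=float)
    edges = np.quantile(all_len, np.linspace(0, 1, n_bins + 1))

    def bin_of(length: float) -> int:
        # right-closed upper bins; clamp into [0, n_bins-1]
        i = int(np.searchsorted(edges[1:-1], length, side="left"))
        return min(i, n_bins - 1)

    targets_in = [[] for _ in range(n_bins)]
    controls_in = [[] for _ in range(n_bins)]
    for c in calls:
        b = bin_of(lengths[c.gene_id])
        if c.klass == "target":
            targets_in[b].append(c.gene_id)
        elif c.klass == "control":
            controls_in[b].append(c.gene_id)

    rng = np.random.default_rng(seed)
    sampled: list[str] = []
    for b in range(n_bins):
        need = len(targets_in[b])
        pool = controls_in[b]
        if need == 0:
            continue
        if len(pool) < need:
            raise ValueError(
                f"bin {b} (UTR length {edges[b]:.0f}-{edges[b + 1]:.0f}): "
                f"{need} targets but only {len(pool)} controls"
            )
        sampled.extend(rng.choice(pool, size=need, replace=False))
    return ControlSample(
        bin_edges=edges,
        targets_per_bin=[len(t) for t in targets_in],
        sampled_controls=sampled,
        seed=seed,
    )


def targets_from_clip(
    utr_intervals: pd.DataFrame,
    clip_clusters: pd.DataFrame,
) -> set[str]:
    """Alternative target definition: genes with CLIP clusters in the UTR.

    Both frames need ``chrom``, ``start``, ``end`` columns (0-based
    half-open); ``utr_intervals`` additionally needs ``gene_id``.  Returns
    the genes whose 3'-UTR interval overlaps at least one cluster.
    """
    out: set[str] = set()
    by_chrom = {c: g[["start", "end"]].to_numpy()
                for c, g in clip_clusters.groupby("chrom")}
    for row in utr_intervals.itertuples(index=False):
        clusters = by_chrom.get(row.chrom)
        if clusters is None:
            continue
        if np.any((clusters[:, 0] < row.end) & (clusters[:, 1] > row.start)):
            out.add(row.gene_id)
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """Minimal BED reader (first 3-6 columns)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df
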