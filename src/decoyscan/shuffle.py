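"""Dinucleotide-preserving sequence permutation and motif-density nulls.

A dinucleotide-preserving shuffle keeps all 16 adjacent-pair counts (and
hence the first and last characters) of the input, which controls the motif
null for local composition.  Sampling is uniform over such permutations via
random Eulerian trails on the dinucleotide multigraph: each character is a
vertex, each adjacent pair an edge, and a permutation is exactly an
Eulerian trail from the first to the last character.  A trail is drawn by
choosing a uniform random last-exit-edge arborescence into the terminal
vertex (rejection-sampled over uniform last-edge assignments) and then a
uniform random ordering of the remaining out-edges of every vertex
(Altschul-Erickson construction).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .motifs import MotifPattern, count_nonoverlapping, scan_motif
from .seqio import SequenceRecord, as_record


def dinucleotide_counts(seq: "str | SequenceRecord") -> Counter:
    """All 16 adjacent-pair counts of a sequence."""
    s = as_record(seq).seq
    return Counter(s[i:i + 2] for i in range(len(s) - 1))


def _reaches_root(last_edge: dict[str, str], root: str) -> bool:
    """Do the chosen last edges form an arborescence into *root*?"""
    for v in last_edge:
        seen = {v}
        cur = v
        while cur != root:
            cur = last_edge.get(cur)
            if cur is None or cur in seen:
                return False
            seen.add(cur)
    return True


def dinucleotide_shuffle(
    seq: "str | SequenceRecord",
    rng: np.random.Generator,
) -> "str | SequenceRecord":
    """Uniform dinucleotide-preserving permutation of a sequence.

    Returns the same type as the input (string in, string out).  Sequences
    shorter than 2 are rejected: they have no dinucleotides to preserve.
    """
    rec = as_record(seq)
    s = rec.seq
    if len(s) < 2:
        raise ValueError("dinucleotide shuffle requires length >= 2")

    first, last = s[0], s[-1]
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(s, s[1:]):
        edges[a].append(b)

    # Rejection-sample a uniform last-edge assignment that forms an
    # arborescence into the terminal vertex.  A valid assignment always
    # exists (the last-exit edges of the original walk), and the alphabet
    # has at most 4 vertices, so acceptance is fast.
    verts = [v for v in edges if v != last]
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in verts}
        if _reaches_root(last_edge, last):
            break

    order: dict[str, list[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        order[v] = pool

    out = [first]
    ptr = {v: 0 for v in order}
    cur = first
    for _ in range(len(s) - 1):
        nxt = order[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    shuffled = "".join(out)

    if isinstance(seq, str):
        return shuffled
    return SequenceRecord(id=rec.id, seq=shuffled,
                          alphabet_note=rec.alphabet_note)


@dataclass
class ShuffleNull:
    """Observed motif count against its dinucleotide-shuffle distribution."""

    observed: int
    shuffle_counts: np.ndarray
    n_shuffles: int
    seed: int | None
    mode: str = "nonoverlapping"
    rng_name: str = "numpy.random.PCG64"

    @property
    def expected(self) -> float:
        return float(np.mean(self.shuffle_counts))

    @property
    def p_empirical(self) -> float:
        """Add-one empirical p-value; never exactly 0."""
        ge = int(np.sum(self.shuffle_counts >= self.observed))
        return (1 + ge) / (1 + self.n_shuffles)

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "expected": self.expected,
            "p_empirical": self.p_empirical,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
            "mode": self.mode,
            "rng": self.rng_name,
            "shuffle_counts": [int(c) for c in self.shuffle_counts],
        }


def motif_enrichment(
    seq: "str | SequenceRecord",
    pattern: MotifPattern,
    n_shuffles: int = 1000,
    seed: int | None = None,
    mode: str = "nonoverlapping",
) -> ShuffleNull:
    """Motif-density statistic against the dinucleotide-preserving null.

    The observed count and every shuffle count use the same counting mode,
    so observed and expected are commensurable.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rec = as_record(seq)

    def _count(s: "str | SequenceRecord") -> int:
        return len(scan_motif(s, pattern, mode=mode))

    observed = _count(rec)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_shuffles, dtype=np.int64)
    for i in range(n_shuffles):
        counts[i] = _count(dinucleotide_shuffle(rec.seq, rng))
    return ShuffleNull(observed=observed, shuffle_counts=counts,
                       n_shuffles=n_shuffles, seed=seed, mode=mode)


def expected_analytic(
    length: int,
    pattern: MotifPattern,
    mono_freqs: dict[str, float],
) -> float:
    """Closed-form expected number of motif *occurrences*.

    ``E = (L - m + 1) * prod_i sum_{b in set_i} p(b)`` under an i.i.d.
    mononucleotide model.  This is an occurrence (overlapping) expectation,
    not a non-overlap expectation; for sparse motifs the two are close.
    """
    total = sum(mono_freqs.get(b, 0.0) for b in "ACGT")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mononucleotide frequencies sum to {total}, not 1")
    n = length - pattern.length + 1
    if n <= 0:
        return 0.0
    p = 1.0
    for allowed in pattern.sets:
        p *= sum(mono_freqs.get(b, 0.0) for b in allowed)
    return n * p
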