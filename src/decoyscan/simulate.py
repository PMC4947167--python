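"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure its consuming stage
assumes — first-order Markov background sequence for the shuffle null,
UTR sets with planted site excess for target calling, negative-binomial
count matrices with planted fold-change shifts for the response analysis,
diverged tandem arrays for repeat discovery, and 3D stacks with planted
diffraction-limited spots at a set nuclear/cytoplasmic split for the FISH
pipeline — and returns a machine-readable truth table alongside the data.
All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .fish import ImageStack
from .motifs import MotifPattern, PRE_TARGET, count_nonoverlapping
from .seqio import SequenceRecord
from .shuffle import expected_analytic
from .targets import UTRRecord, make_utr

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
UNIFORM_DINUC = {a + b: 1 / 16 for a in "ACGT" for b in "ACGT"}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed))


def gen_background_seq(
    length: int,
    dinucleotide_freqs: dict[str, float] | None = None,
    seed=None,
    id: str = "background",
) -> SequenceRecord:
    """First-order Markov sequence with the given dinucleotide frequencies.

    The chain starts from the dinucleotide marginal and steps with
    transition probabilities p(b | a) = f(ab) / sum_b f(ab).
    """
    freqs = dinucleotide_freqs or UNIFORM_DINUC
    F = np.zeros((4, 4))
    for i, a in enumerate("ACGT"):
        for j, b in enumerate("ACGT"):
            F[i, j] = freqs.get(a + b, 0.0)
    if F.sum() <= 0 or (F < 0).any():
        raise ValueError("invalid dinucleotide frequency table")
    F /= F.sum()
    row = F.sum(axis=1)
    if length == 0:
        return SequenceRecord(id=id, seq="")
    start_p = row if row.sum() > 0 else np.full(4, 0.25)
    start_p = start_p / start_p.sum()
    trans_cum = np.cumsum(
        np.where(row[:, None] > 0, F / np.where(row[:, None] > 0,
                                                row[:, None], 1), 0.25),
        axis=1,
    )
    rng = _rng(seed)
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    cur = int(np.searchsorted(np.cumsum(start_p), u[0], side="right"))
    cur = min(cur, 3)
    out[0] = _BASES[cur]
    for i in range(1, length):
        cur = min(int(np.searchsorted(trans_cum[cur], u[i], side="right")), 3)
        out[i] = _BASES[cur]
    return SequenceRecord(id=id, seq=out.tobytes().decode("ascii"))


def plant_motifs(
    seq: SequenceRecord,
    pattern: MotifPattern,
    n: int,
    seed=None,
    min_gap: int = 0,
) -> tuple[SequenceRecord, list[int]]:
    """Overwrite *n* non-overlapping concrete motif instances at random.

    Planted starts are pairwise separated by at least ``pattern.length +
    min_gap``; their positions are returned as ground truth.  Raises when
    the sequence cannot accommodate the request.
    """
    rng = _rng(seed)
    m = pattern.length
    L = len(seq)
    if n == 0:
        return seq, []
    if n * m + (n - 1) * min_gap > L:
        raise ValueError(f"cannot place {n} motifs of length {m} with gap "
                         f">= {min_gap} in {L} nt")
    for _ in range(1000):
        starts = np.sort(rng.integers(0, L - m + 1, size=n))
        if n == 1 or np.all(np.diff(starts) >= m + min_gap):
            break
    else:
        raise ValueError("could not place motifs; sequence too crowded")
    chars = list(seq.seq)
    for s in starts:
        for p, allowed in enumerate(pattern.sets):
            chars[s + p] = sorted(allowed)[rng.integers(len(allowed))]
    rec = SequenceRecord(id=seq.id, seq="".join(chars),
                         alphabet_note=seq.alphabet_note)
    return rec, [int(s) for s in starts]


def gen_tandem_repeat_seq(
    unit_length: int = 300,
    n_units: int = 12,
    per_base_mutation_rate: float = 0.0,
    seed=None,
    flank: int = 200,
    id: str = "tandem",
) -> tuple[SequenceRecord, list[tuple[int, int]]]:
    """A tandem array of mutated copies of one random ancestral unit.

    Each copy is independently point-substituted at the given per-base
    rate; random flanks are appended on both sides.  Returns the sequence
    and the true unit boundaries.
    """
    rng = _rng(seed)
    ancestor = rng.integers(0, 4, size=unit_length)
    parts = [rng.integers(0, 4, size=flank)]
    boundaries = []
    pos = flank
    for _ in range(n_units):
        copy = ancestor.copy()
        mut = rng.random(unit_length) < per_base_mutation_rate
        # substitute to one of the three other bases
        copy[mut] = (copy[mut] + rng.integers(1, 4, size=mut.sum())) % 4
        parts.append(copy)
        boundaries.append((pos, pos + unit_length))
        pos += unit_length
    parts.append(rng.integers(0, 4, size=flank))
    codes = np.concatenate(parts)
    seq = _BASES[codes].tobytes().decode("ascii")
    return SequenceRecord(id=id, seq=seq), boundaries


def gen_utr_universe(
    n_genes: int,
    target_fraction: float = 0.1,
    planted_excess: float = 3.0,
    median_length: float = 1000.0,
    sigma_log: float = 0.6,
    seed=None,
    pattern: MotifPattern = PRE_TARGET,
    min_length: int = 60,
) -> tuple[list[UTRRecord], pd.DataFrame]:
    """A synthetic 3'-UTR universe with planted Pumilio-site excess.

    UTR lengths are log-normal (median ~1 kb, making 10-bin length
    matching nontrivial); backgrounds are dinucleotide-uniform; designated
    target genes receive ``ceil(expected + planted_excess)`` planted
    UGUANAUA sites.  Returns the records plus a truth table.
    """
    rng = _rng(seed)
    if n_genes == 0:
        return [], pd.DataFrame(
            columns=["gene_id", "utr_length", "is_target", "n_planted"])
    lengths = np.maximum(
        min_length,
        rng.lognormal(math.log(median_length), sigma_log, n_genes),
    ).astype(int)
    n_targets = int(round(target_fraction * n_genes))
    is_target = np.zeros(n_genes, dtype=bool)
    is_target[rng.choice(n_genes, size=n_targets, replace=False)] = True

    uniform_mono = {b: 0.25 for b in "ACGT"}
    utrs, rows = [], []
    for g in range(n_genes):
        gid = f"gene{g:05d}"
        rec = gen_background_seq(int(lengths[g]), seed=rng, id=gid)
        n_planted = 0
        if is_target[g]:
            expected = expected_analytic(len(rec), pattern, uniform_mono)
            n_planted = math.ceil(expected + planted_excess)
            rec, _ = plant_motifs(rec, pattern, n_planted, seed=rng,
                                  min_gap=4)
        utrs.append(make_utr(gid, rec))
        rows.append((gid, int(lengths[g]), bool(is_target[g]), n_planted))
    truth = pd.DataFrame(
        rows, columns=["gene_id", "utr_length", "is_target", "n_planted"])
    return utrs, truth


def gen_count_matrix(
    n_genes: int,
    n_targets: int,
    planted_log2fc: float,
    n_reps: int = 2,
    dispersion: float = 0.05,
    median_rpm: float = 200.0,
    sigma_log_rpm: float = 1.0,
    lib_size: float = 5e6,
    seed=None,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Control/treated count-matrix pair with a planted target shift.

    Baseline expression levels are log-normal on the RPM scale; counts are
    negative-binomial around the condition means (variance mu + phi*mu^2),
    Poisson in the phi -> 0 limit.  The first ``n_targets`` genes have
    their treated-condition mean shifted by ``planted_log2fc``.
    """
    rng = _rng(seed)
    if n_targets > n_genes:
        raise ValueError("more targets than genes")
    gene_ids = [f"gene{g:05d}" for g in range(n_genes)]
    base_rpm = rng.lognormal(math.log(median_rpm), sigma_log_rpm, n_genes)
    is_target = np.zeros(n_genes, dtype=bool)
    is_target[:n_targets] = True
    mu_ctrl = base_rpm / 1e6 * lib_size
    mu_treat = mu_ctrl * np.where(is_target, 2.0 ** planted_log2fc, 1.0)

    def _draw(mu: np.ndarray) -> np.ndarray:
        mu_rep = np.repeat(mu[:, None], n_reps, axis=1)
        if dispersion < 1e-8:
            return rng.poisson(mu_rep)
        r = 1.0 / dispersion
        p = r / (r + mu_rep)
        return rng.negative_binomial(r, p)

    cols_c = [f"ctrl_{i + 1}" for i in range(n_reps)]
    cols_t = [f"treat_{i + 1}" for i in range(n_reps)]
    ctrl = CountMatrix(pd.DataFrame(_draw(mu_ctrl), index=gene_ids,
                                    columns=cols_c))
    treat = CountMatrix(pd.DataFrame(_draw(mu_treat), index=gene_ids,
                                     columns=cols_t))
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "baseline_rpm": base_rpm,
        "is_target": is_target,
        "planted_log2fc": np.where(is_target, planted_log2fc, 0.0),
    })
    return ctrl, treat, truth


def _render_gaussian_spots(
    shape: tuple[int, int, int],
    positions: np.ndarray,
    amplitude: float,
    sigma: float,
) -> np.ndarray:
    img = np.zeros(shape)
    r = int(math.ceil(4 * sigma))
    for z0, y0, x0 in positions:
        zlo, zhi = max(0, int(z0) - r), min(shape[0], int(z0) + r + 1)
        ylo, yhi = max(0, int(y0) - r), min(shape[1], int(y0) + r + 1)
        xlo, xhi = max(0, int(x0) - r), min(shape[2], int(x0) + r + 1)
        zz, yy, xx = np.mgrid[zlo:zhi, ylo:yhi, xlo:xhi]
        d2 = (zz - z0) ** 2 + (yy - y0) ** 2 + (xx - x0) ** 2
        img[zlo:zhi, ylo:yhi, xlo:xhi] += amplitude * np.exp(
            -d2 / (2 * sigma ** 2))
    return img


def gen_fish_stack(
    dims: tuple[int, int, int] = (8, 128, 128),
    n_spots: int = 68,
    cyto_fraction: float = 0.94,
    nucleus_radius_xy: float = 28.0,
    psf_sigma_px: float = 1.5,
    snr: float = 10.0,
    background: float = 10.0,
    read_noise: float = 1.0,
    min_separation: float = 6.0,
    seed=None,
) -> tuple[ImageStack, ImageStack, pd.DataFrame]:
    """Signal + DAPI stacks with planted spots at a set nuclear split.

    An ellipsoidal nucleus is rendered into the DAPI channel; spots are
    isotropic 3D Gaussians of the given PSF sigma, placed inside or
    outside the nucleus's (y, x) footprint according to ``cyto_fraction``
    and separated pairwise by at least ``min_separation`` voxels.  Spot
    amplitude is ``snr`` times the background noise scale
    sqrt(background + read_noise^2); voxel noise is Poisson shot noise
    plus Gaussian read noise.  Returns (signal, dapi, truth).
    """
    rng = _rng(seed)
    nz, ny, nx = dims
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2

    yy, xx = np.mgrid[0:ny, 0:nx]
    nuc2d = (((yy - cy) / nucleus_radius_xy) ** 2
             + ((xx - cx) / nucleus_radius_xy) ** 2) <= 1.0

    n_nuc = int(round(n_spots * (1 - cyto_fraction)))
    n_cyto = n_spots - n_nuc
    margin = max(3.0, 3 * psf_sigma_px)

    positions: list[tuple[float, float, float]] = []
    comps: list[str] = []

    def _try_place(want_nuclear: bool) -> bool:
        for _ in range(5000):
            z = rng.uniform(1.0, nz - 2.0)
            y = rng.uniform(margin, ny - 1 - margin)
            x = rng.uniform(margin, nx - 1 - margin)
            inside = bool(nuc2d[int(round(y)), int(round(x))])
            if inside != want_nuclear:
                continue
            # keep clear of the mask boundary so compartments are unambiguous
            rr = math.hypot(y - cy, x - cx)
            if abs(rr - nucleus_radius_xy) < 2.5:
                continue
            if any((z - pz) ** 2 + (y - py) ** 2 + (x - px) ** 2
                   < min_separation ** 2 for pz, py, px in positions):
                continue
            positions.append((z, y, x))
            comps.append("nuclear" if want_nuclear else "cytoplasmic")
            return True
        return False

    for _ in range(n_nuc):
        if not _try_place(True):
            raise ValueError("could not place nuclear spots; nucleus too "
                             "small or stack too crowded")
    for _ in range(n_cyto):
        if not _try_place(False):
            raise ValueError("could not place cytoplasmic spots; stack too "
                             "crowded")

    noise_scale = math.sqrt(background + read_noise ** 2)
    amplitude = snr * noise_scale
    signal_clean = background + _render_gaussian_spots(
        dims, np.array(positions).reshape(-1, 3), amplitude, psf_sigma_px)
    signal = rng.poisson(signal_clean) + rng.normal(0, read_noise, dims)
    signal = np.clip(signal, 0, None)

    zz3 = np.abs(np.arange(nz) - cz)[:, None, None]
    nuc3d = nuc2d[None] & (zz3 <= max(1.0, 0.45 * nz))
    dapi_clean = background + 50.0 * nuc3d
    dapi = rng.poisson(dapi_clean) + rng.normal(0, read_noise, dims)
    dapi = np.clip(dapi, 0, None)

    truth = pd.DataFrame(positions, columns=["z", "y", "x"])
    truth["compartment"] = comps
    return (
        ImageStack(voxels=signal, channel="signal"),
        ImageStack(voxels=dapi, channel="dapi"),
        truth,
    )
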