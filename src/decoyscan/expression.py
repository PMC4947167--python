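"""Expression response of predicted targets to RNA perturbations.

Gene-level read counts are normalised to reads per million aligned reads
(RPM), genes with an average RPM below 50 across the experimental
conditions are dropped, and per-contrast fold changes are computed after
adding a pseudocount of 0.1 RPM to each condition.  Predicted targets are
compared with controls by a two-sided Wilcoxon rank-sum test (exact
enumeration for small groups, tie-corrected normal approximation
otherwise), perturbation pairs are compared by Spearman correlation, and
ribosome-footprint data are folded in as translation efficiency (footprint
RPM over mRNA RPM).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Above this total sample count the rank-sum test switches from exact
#: enumeration to the tie-corrected normal approximation.
EXACT_RANKSUM_MAX_N = 10


@dataclass
class CountMatrix:
    """Gene x sample matrix of raw non-negative read counts."""

    counts: pd.DataFrame  # genes in rows, samples in columns
    layer: str = "exon"  # "exon" | "whole_locus" | "ribosome_footprint"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class GroupComparison:
    contrast: str
    n_target: int
    n_control: int
    median_target: float
    median_control: float
    statistic: float
    p: float
    method: str

    @property
    def direction(self) -> str:
        d = self.median_target - self.median_control
        return "up" if d > 0 else ("down" if d < 0 else "none")


def normalize_rpm(cm: "CountMatrix | pd.DataFrame") -> pd.DataFrame:
    """Reads per million aligned reads, per sample (column)."""
    df = cm.counts if isinstance(cm, CountMatrix) else cm
    totals = df.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)[:5]}")
    return df * 1e6 / totals


def filter_expressed(rpm: pd.DataFrame, min_avg: float = 50.0) -> pd.Index:
    """Genes whose mean RPM across the supplied samples is >= min_avg."""
    return rpm.index[rpm.mean(axis=1) >= min_avg]


def fold_change(
    rpm_treat: pd.DataFrame | pd.Series,
    rpm_ctrl: pd.DataFrame | pd.Series,
    pseudocount: float = 0.1,
) -> pd.Series:
    """Per-gene log2 fold change between two conditions.

    Replicate columns are averaged per condition before the pseudocount
    ratio, so each condition contributes one RPM value per gene.
    """
    def _avg(x):
        x = x if isinstance(x, pd.Series) else x.mean(axis=1)
        if (x < 0).any():
            raise ValueError("negative RPM values")
        return x

    t, c = _avg(rpm_treat), _avg(rpm_ctrl)
    t, c = t.align(c, join="inner")
    return np.log2((t + pseudocount) / (c + pseudocount))


def intronic_counts(
    whole_locus: CountMatrix, exon: CountMatrix
) -> tuple[CountMatrix, int]:
    """Intron-mapping counts as whole-locus minus exon-mapping reads.

    Differences below zero (multi-mapping artifacts) are clipped to 0; the
    number of clipped cells is returned and warned about.
    """
    w, e = whole_locus.counts, exon.counts
    if not (w.index.equals(e.index) and w.columns.equals(e.columns)):
        raise ValueError("whole-locus and exon matrices must share the same "
                         "genes and samples")
    diff = w - e
    n_clipped = int((diff.to_numpy() < 0).sum())
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} negative intron count(s) to 0")
    return CountMatrix(diff.clip(lower=0), layer="intron"), n_clipped


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by enumeration of all labelings.

    The statistic is the rank sum W of the first group; the p-value is the
    fraction of labelings at least as far from the (tie-invariant) mean
    n1(N+1)/2 as the observed W.  Ties are handled through midranks.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= dev - 1e-9:
            hits += 1
    return float(w_obs), hits / total


def compare_groups(
    fc: pd.Series,
    targets,
    controls,
    contrast: str = "",
) -> GroupComparison:
    """Two-sided rank-sum comparison of target vs control fold changes.

    Uses exact enumeration when the total group size is at most 10 and the
    tie- and continuity-corrected normal approximation otherwise.
    """
    x = fc.reindex(pd.Index(targets)).dropna().to_numpy(dtype=float)
    y = fc.reindex(pd.Index(controls)).dropna().to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty after filtering")
    if len(x) + len(y) <= EXACT_RANKSUM_MAX_N:
        statistic, p = _exact_ranksum_p(x, y)
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        statistic, p = float(res.statistic), float(res.pvalue)
        method = "normal"
    return GroupComparison(
        contrast=contrast,
        n_target=len(x),
        n_control=len(y),
        median_target=float(np.median(x)),
        median_control=float(np.median(y)),
        statistic=statistic,
        p=min(p, 1.0),
        method=method,
    )


def correlate_perturbations(
    fc_a: pd.Series, fc_b: pd.Series
) -> tuple[float, float]:
    """Spearman correlation of two fold-change tables on shared genes."""
    a, b = fc_a.align(fc_b, join="inner")
    mask = a.notna() & b.notna()
    if mask.sum() < 3:
        raise ValueError("fewer than 3 shared genes")
    rho, p = stats.spearmanr(a[mask], b[mask])
    return float(rho), float(p)


def translation_efficiency(
    footprint_rpm: pd.DataFrame | pd.Series,
    mrna_rpm: pd.DataFrame | pd.Series,
    pseudocount: float = 0.1,
) -> pd.Series:
    """Per-gene translation efficiency (footprint + pc) / (mRNA + pc)."""
    def _avg(x):
        x = x if isinstance(x, pd.Series) else x.mean(axis=1)
        if (x < 0).any():
            raise ValueError("negative RPM values")
        return x

    f, m = _avg(footprint_rpm), _avg(mrna_rpm)
    f, m = f.align(m, join="inner")
    return (f + pseudocount) / (m + pseudocount)


def delta_te(te_treat: pd.Series, te_ctrl: pd.Series) -> pd.Series:
    """log2 change in translation efficiency between two conditions."""
    t, c = te_treat.align(te_ctrl, join="inner")
    return np.log2(t / c)


def consistent_regulation(
    fold_changes: list[pd.Series],
    min_change: float = 0.2,
) -> tuple[pd.Index, pd.Index]:
    """Genes consistently up-/down-regulated across several contrasts.

    A gene is consistently downregulated when its expression drops by at
    least ``min_change`` (fractional, e.g. 0.2 = 20%) in *all* supplied
    contrasts, and consistently upregulated when it rises by at least that
    fraction in all of them.  Returns (up_genes, down_genes).
    """
    if not fold_changes:
        raise ValueError("no fold-change tables supplied")
    up_thr = np.log2(1 + min_change)
    dn_thr = np.log2(1 - min_change)
    df = pd.concat(fold_changes, axis=1, join="inner")
    up = df.index[(df >= up_thr).all(axis=1)]
    down = df.index[(df <= dn_thr).all(axis=1)]
    return up, down
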