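"""Decoy-capacity arithmetic and standard-curve protein quantification.

The decoy capacity of a multi-site RNA is purely multiplicative:
transcript copies per cell times binding sites per copy, optionally set
against the cellular copy numbers of the proteins being sequestered (for
NORAD: ~70 copies x 17 PREs ~ 1,200 sites vs ~200 PUM1 and ~550 PUM2
proteins per cell).  Protein copy numbers come from a linear standard
curve calibrated on known amounts of purified protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class CapacityModel:
    transcript_copies_per_cell: float
    sites_per_copy: int
    protein_copies: dict[str, float] = field(default_factory=dict)
    round_to: int | None = None

    @property
    def site_capacity(self) -> float:
        return self.transcript_copies_per_cell * self.sites_per_copy

    @property
    def site_capacity_rounded(self) -> float:
        if self.round_to is None:
            return self.site_capacity
        return round(self.site_capacity / self.round_to) * self.round_to

    @property
    def site_to_protein_ratio(self) -> float | None:
        total = sum(self.protein_copies.values())
        return None if total == 0 else self.site_capacity / total

    def to_dict(self) -> dict:
        return {
            "transcript_copies_per_cell": self.transcript_copies_per_cell,
            "sites_per_copy": self.sites_per_copy,
            "site_capacity": self.site_capacity,
            "site_capacity_rounded": self.site_capacity_rounded,
            "protein_copies": dict(self.protein_copies),
            "site_to_protein_ratio": self.site_to_protein_ratio,
        }


@dataclass
class StandardCurve:
    known_amounts: np.ndarray
    signals: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def binding_capacity(
    copies: float,
    sites: int,
    protein_copies: dict[str, float] | None = None,
    round_to: int | None = None,
) -> CapacityModel:
    """Simultaneous binding capacity of a decoy RNA, copies x sites."""
    if copies < 0 or sites < 0:
        raise ValueError("copies and sites must be non-negative")
    return CapacityModel(
        transcript_copies_per_cell=float(copies),
        sites_per_copy=int(sites),
        protein_copies=dict(protein_copies or {}),
        round_to=round_to,
    )


def fit_standard_curve(known_amounts, signals) -> StandardCurve:
    """Ordinary least-squares line: signal = slope * amount + intercept."""
    amounts = np.asarray(known_amounts, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if len(amounts) < 2 or len(np.unique(amounts)) < 2:
        raise ValueError("need at least 2 distinct known amounts")
    res = stats.linregress(amounts, sig)
    return StandardCurve(
        known_amounts=amounts,
        signals=sig,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
    )


def copies_per_cell(
    curve: StandardCurve,
    lysate_signal: float,
    amount_to_molecules: float = 1.0,
    n_cells: float = 1.0,
) -> float:
    """Invert the standard curve to protein copies per cell.

    A lysate signal below the curve intercept inverts to a negative
    amount; it is reported as 0 with a warning.
    """
    if curve.slope == 0:
        raise ValueError("standard curve has zero slope")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    amount = (lysate_signal - curve.intercept) / curve.slope
    if amount < 0:
        warnings.warn("lysate signal below curve intercept; reporting 0")
        return 0.0
    return amount * amount_to_molecules / n_cells
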