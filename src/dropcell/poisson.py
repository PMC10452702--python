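"""Poisson statistics of cell encapsulation in microfluidic droplets.

When a dilute cell suspension is dispersed into monodisperse droplets, the
number of cells landing in any one droplet is Poisson distributed with mean
``lam`` (the "cells per droplet", CPD).  This module provides the forward
model (per-count probabilities and the derived encapsulation rates), the
inverse estimator of CPD from droplet detections, and the physical CPD
predicted from cell density and droplet size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PoissonModel",
    "EncapsulationRates",
    "EncapsulationSummary",
    "pmf",
    "rates",
    "estimate_cpd",
    "cpd_from_physical",
    "summarize_counts",
]


@dataclass(frozen=True)
class PoissonModel:
    """Poisson cell-loading model with mean cells per droplet ``lam``."""

    lam: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"CPD lambda must be >= 0, got {self.lam}")


@dataclass(frozen=True)
class EncapsulationRates:
    """Theoretical encapsulation rates at a given CPD.

    ``single_cell_rate`` is the conditional probability of exactly one cell
    given at least one cell, rho_1 / (1 - rho_0).  It is undefined at
    lambda = 0 and reported as ``None`` there.
    """

    empty: float
    single: float
    multicell: float
    single_cell_rate: float | None


@dataclass
class EncapsulationSummary:
    """Observed encapsulation statistics of a set of detected droplets."""

    n_droplets: int
    m_positive: int
    counts_by_k: dict[int, int]
    empty_rate: float
    single_rate: float
    multicell_rate: float
    single_cell_rate: float | None
    lambda_hat: float

    def to_dict(self) -> dict:
        return {
            "n_droplets": self.n_droplets,
            "m_positive": self.m_positive,
            "counts_by_k": {str(k): v for k, v in sorted(self.counts_by_k.items())},
            "empty_rate": self.empty_rate,
            "single_rate": self.single_rate,
            "multicell_rate": self.multicell_rate,
            "single_cell_rate": self.single_cell_rate,
            "lambda_hat": self.lambda_hat,
        }


def pmf(model: PoissonModel, k) -> np.ndarray | float:
    """Probability of ``k`` cells in one droplet, rho_k = lam^k e^-lam / k!."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or not np.issubdtype(k_arr.dtype, np.integer):
        if np.any(np.mod(k_arr, 1) != 0) or np.any(k_arr < 0):
            raise ValueError("k must be a nonnegative integer")
    out = stats.poisson.pmf(k_arr, model.lam)
    return float(out) if np.isscalar(k) else out


def rates(model: PoissonModel) -> EncapsulationRates:
    """Empty / single / multicell fractions and conditional single-cell rate."""
    rho0 = math.exp(-model.lam)
    rho1 = model.lam * rho0
    multi = 1.0 - rho0 - rho1
    if model.lam > 0:
        scr = rho1 / (1.0 - rho0)
    else:
        scr = None
    return EncapsulationRates(empty=rho0, single=rho1, multicell=multi, single_cell_rate=scr)


def estimate_cpd(n_droplets: int, m_positive: int) -> float:
    """Estimate CPD from detections: lambda_hat = -ln(1 - M/N).

    ``n_droplets`` is the number of detected droplets and ``m_positive`` the
    number containing at least one cell.  ``m_positive == n_droplets`` gives
    an infinite estimate and raises.
    """
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    if m_positive < 0 or m_positive > n_droplets:
        raise ValueError("m_positive must lie in [0, n_droplets]")
    if m_positive == n_droplets:
        raise ValueError(
            "all droplets positive: CPD estimate is infinite (saturated sample)"
        )
    return -math.log1p(-m_positive / n_droplets)


#: microns^3 per millilitre (1 mL = 1 cm^3 = 1e12 um^3)
_UM3_PER_ML = 1e12


def cpd_from_physical(cell_density_per_ml: float, droplet_radius_um: float) -> float:
    """CPD predicted from cell density and droplet size: lam = D_cell * V.

    Units are explicit in the argument names: density in cells/mL, radius in
    micrometres; the droplet volume (4/3) pi R^3 is converted to mL so the
    product is dimensionless.
    """
    if cell_density_per_ml < 0:
        raise ValueError("cell density must be >= 0")
    if droplet_radius_um <= 0:
        raise ValueError("droplet radius must be > 0")
    volume_ml = (4.0 / 3.0) * math.pi * droplet_radius_um**3 / _UM3_PER_ML
    return cell_density_per_ml * volume_ml


def summarize_counts(counts) -> EncapsulationSummary:
    """Summarize per-droplet cell counts into encapsulation statistics.

    ``lambda_hat`` uses the positive-fraction estimator; if every droplet is
    positive the estimate is reported as ``inf``.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("counts must be a nonempty 1-D sequence")
    if np.any(counts < 0):
        raise ValueError("cell counts must be >= 0")
    n = int(counts.size)
    m = int(np.count_nonzero(counts))
    ks, freqs = np.unique(counts, return_counts=True)
    empty = float(np.mean(counts == 0))
    single = float(np.mean(counts == 1))
    multi = float(np.mean(counts >= 2))
    scr = single / (1.0 - empty) if empty < 1.0 else None
    lam_hat = math.inf if m == n else estimate_cpd(n, m)
    return EncapsulationSummary(
        n_droplets=n,
        m_positive=m,
        counts_by_k={int(k): int(f) for k, f in zip(ks, freqs)},
        empty_rate=empty,
        single_rate=single,
        multicell_rate=multi,
        single_cell_rate=scr,
        lambda_hat=lam_hat,
    )
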