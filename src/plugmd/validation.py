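"""Correctness instruments: NVE conservation statistics and the canonical
ensemble-consistency check.

The ensemble check exploits the identity for canonical potential-energy
distributions at two inverse temperatures beta_1 > beta_2:

    ln[ P(E | beta_2) / P(E | beta_1) ] = (beta_1 - beta_2) E + const,

so a linear fit of the log bin-probability ratio against bin-centre energy
must recover the slope beta_1 - beta_2 if the sampler generates the
correct ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import KB, KCAL_TO_KJ
from .integrators import EnergyRecord

__all__ = [
    "ConservationReport", "EnsembleCheckResult", "InsufficientDataError",
    "DegenerateFitError", "conservation_report", "theoretical_slope",
    "ensemble_consistency_check",
]


class InsufficientDataError(ValueError):
    pass


class DegenerateFitError(RuntimeError):
    pass


@dataclass
class ConservationReport:
    """Total-energy stability statistics of an NVE run (kcal/mol units)."""
    fluctuation_per_dof_kcal: float   # SD(total energy) / n_dof
    total_sd_kcal: float
    drift_kcal_per_ns: float          # least-squares slope of total energy
    drift_se_kcal_per_ns: float
    n_dof: int
    n_records: int


def _extract(records, attr):
    if records and isinstance(records[0], EnergyRecord):
        return np.array([getattr(r, attr) for r in records])
    raise TypeError("expected a list of EnergyRecord")


def conservation_report(records: Sequence[EnergyRecord] | tuple,
                        n_dof: int) -> ConservationReport:
    """Fluctuation and drift statistics of the total energy.

    Accepts either a list of :class:`EnergyRecord` or a
    ``(times_ps, total_energies_kjmol)`` pair.  Values are reported in
    kcal/mol (and kcal/mol/ns for the drift).
    """
    if isinstance(records, tuple) and len(records) == 2:
        t = np.asarray(records[0], dtype=float)
        e = np.asarray(records[1], dtype=float)
    else:
        t = _extract(records, "time_ps")
        e = _extract(records, "total")
    if len(e) < 100:
        raise InsufficientDataError(
            f"need >= 100 energy records, got {len(e)}")
    e_kcal = e / KCAL_TO_KJ
    sd = float(np.std(e_kcal))
    # least-squares drift in kcal/mol/ns (t is in ps)
    t_ns = t / 1000.0
    A = np.vstack([np.ones_like(t_ns), t_ns]).T
    coef, *_ = np.linalg.lstsq(A, e_kcal, rcond=None)
    # Drift SE from block-mean increments.  The total energy of a
    # truncated-potential NVE run behaves like fast thermal oscillation on
    # top of a slow random walk (cutoff noise); both make the plain OLS
    # slope SE far too small, and a fitted "trend" cannot be separated
    # from the walk within one trajectory.  Increments of block means are
    # serially uncorrelated (or anticorrelated), so the SE of their mean
    # is an honest -- conservative -- drift uncertainty.
    n_blocks = min(25, len(e) // 4)
    bt = np.array([b.mean() for b in np.array_split(t_ns, n_blocks)])
    be = np.array([b.mean() for b in np.array_split(e_kcal, n_blocks)])
    inc = np.diff(be) / np.diff(bt)
    se = (float(np.std(inc, ddof=1) / np.sqrt(len(inc)))
          if len(inc) > 1 else float("nan"))
    return ConservationReport(
        fluctuation_per_dof_kcal=sd / n_dof,
        total_sd_kcal=sd,
        drift_kcal_per_ns=float(coef[1]),
        drift_se_kcal_per_ns=se,
        n_dof=int(n_dof),
        n_records=len(e),
    )


def theoretical_slope(T1: float, T2: float) -> float:
    """Predicted slope 1/(k_B T1) - 1/(k_B T2) of the log-ratio fit, mol/kJ."""
    if T1 <= 0 or T2 <= 0:
        raise ValueError("temperatures must be positive")
    return 1.0 / (KB * T1) - 1.0 / (KB * T2)


@dataclass
class EnsembleCheckResult:
    """Outcome of the two-temperature ensemble-consistency fit."""
    slope: float                  # mol/kJ
    slope_se: float
    intercept: float              # absorbs beta2*A2 - beta1*A1, not separable
    theoretical: float            # beta1 - beta2, mol/kJ
    relative_deviation_pct: float
    bins_used: int
    bins_excluded: int
    bin_centers: np.ndarray
    log_ratio: np.ndarray


def ensemble_consistency_check(E1: np.ndarray, E2: np.ndarray,
                               T1: float, T2: float, n_bins: int = 30,
                               p_min: float = 0.001, trim: int = 3
                               ) -> EnsembleCheckResult:
    """Fit ln(P(E|T2)/P(E|T1)) vs E and compare with beta1 - beta2.

    Recipe: the combined min/max range of both sample sets is divided into
    ``n_bins`` equal bins; per-trajectory bin probabilities are computed
    independently; bins with probability below ``p_min`` in either
    trajectory are excluded; of the surviving bins the first and last
    ``trim`` are dropped; ordinary least squares on the remaining
    log-ratios gives slope and intercept.
    """
    E1 = np.asarray(E1, dtype=float)
    E2 = np.asarray(E2, dtype=float)
    if len(E1) == 0 or len(E2) == 0:
        raise InsufficientDataError("both sample sets must be non-empty")
    if T1 > T2:
        raise ValueError("requires T1 <= T2")
    lo = min(E1.min(), E2.min())
    hi = max(E1.max(), E2.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p1 = np.histogram(E1, bins=edges)[0] / len(E1)
    p2 = np.histogram(E2, bins=edges)[0] / len(E2)

    keep = (p1 >= p_min) & (p2 >= p_min)
    surviving = np.flatnonzero(keep)
    if trim > 0:
        surviving = surviving[trim:len(surviving) - trim]
    if len(surviving) < 2:
        raise DegenerateFitError(
            f"only {len(surviving)} usable bins after exclusions")

    x = centers[surviving]
    y = np.log(p2[surviving] / p1[surviving])
    A = np.vstack([np.ones_like(x), x]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    # SE of the unweighted-OLS slope by propagating the multinomial
    # variance of each log bin-probability ratio: residual-based SEs
    # undercover here because deviations from the line are smooth
    # (binning curvature), not independent noise.
    var_y = ((1.0 - p1[surviving]) / (len(E1) * p1[surviving])
             + (1.0 - p2[surviving]) / (len(E2) * p2[surviving]))
    xb = x.mean()
    sxx = float(np.sum((x - xb) ** 2))
    slope_var = float(np.sum(((x - xb) / sxx) ** 2 * var_y))
    theo = theoretical_slope(T1, T2)
    rel = abs(coef[1] - theo) / abs(theo) * 100.0 if theo != 0 else float("nan")
    return EnsembleCheckResult(
        slope=float(coef[1]), slope_se=float(np.sqrt(slope_var)),
        intercept=float(coef[0]), theoretical=theo,
        relative_deviation_pct=float(rel),
        bins_used=len(surviving), bins_excluded=n_bins - len(surviving),
        bin_centers=x, log_ratio=y,
    )
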