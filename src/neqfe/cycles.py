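"""Thermodynamic-cycle assembly and convergence diagnostics.

Solvation free energies at the cheap level come from the difference of
the gas-phase and aqueous annihilation legs; the endstate correction to
the expensive level combines the gas- and aqueous-phase level-change
legs as ΔG_corr = −ΔG_gas + ΔG_aq; the corrected solvation free energy
is the cheap-level value plus the correction.  Diagnostics cover the
forward/reverse work-distribution overlap, the deviation between
unidirectional and bidirectional estimates (with 1 kT and 2 kcal/mol
flags), the deviation of multistate results from the bidirectional
ones, and the discard/stride subsampling rule for multistate
equilibrium samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import DEFAULT_TEMPERATURE, kt
from .worksets import FreeEnergyEstimate, ValidationError, WorkSet

__all__ = [
    "CycleLeg",
    "CorrectionRecord",
    "SubsampleResult",
    "solvation_from_legs",
    "endstate_correction",
    "corrected_asfe",
    "work_overlap",
    "crooks_deviation",
    "mfes_deviation",
    "mfes_subsample",
]


@dataclass
class CycleLeg:
    """One leg of the solvation thermodynamic cycle."""

    phase: str  # {"gas", "aqueous"}
    levels: str  # {"MM->NNP", "annihilation"}
    estimate: FreeEnergyEstimate

    def __post_init__(self) -> None:
        if self.phase not in ("gas", "aqueous"):
            raise ValidationError(f"phase must be gas/aqueous, got {self.phase!r}")
        if self.estimate is None or not np.isfinite(self.estimate.value):
            raise ValidationError("cycle leg requires a finite estimate")


@dataclass
class CorrectionRecord:
    """Per-molecule correction bookkeeping (all energies kcal/mol)."""

    dG_mm_solv: float
    dG_corr: float
    dG_corr_err: float = 0.0
    dG_crooks: float | None = None
    dG_mfes: float | None = None
    overlap: float | None = None

    @property
    def dG_corrected_solv(self) -> float:
        return corrected_asfe(self.dG_mm_solv, self.dG_corr)[0]


def _check_finite(*values: float) -> None:
    for v in values:
        if not np.isfinite(v):
            raise ValidationError(f"non-finite input {v!r}")


def solvation_from_legs(dG_gas: float, dG_aq: float,
                        err_gas: float = 0.0, err_aq: float = 0.0
                        ) -> tuple[float, float]:
    """Solvation free energy from the two annihilation legs.

    ΔG_solv = ΔG_gas − ΔG_aq (annihilating in the gas phase minus
    annihilating in solution); uncertainties combine in quadrature.
    """
    _check_finite(dG_gas, dG_aq)
    return dG_gas - dG_aq, math.hypot(err_gas, err_aq)


def endstate_correction(dG_gas_corr: float, dG_aq_corr: float,
                        err_gas: float = 0.0, err_aq: float = 0.0
                        ) -> tuple[float, float]:
    """Level-of-theory correction ΔG_corr = −ΔG_gas + ΔG_aq."""
    _check_finite(dG_gas_corr, dG_aq_corr)
    return -dG_gas_corr + dG_aq_corr, math.hypot(err_gas, err_aq)


def corrected_asfe(dG_mm_solv: float, dG_corr: float,
                   err_mm: float = 0.0, err_corr: float = 0.0
                   ) -> tuple[float, float]:
    """Corrected solvation free energy ΔG_solv(high) = ΔG_solv(low) + ΔG_corr."""
    _check_finite(dG_mm_solv, dG_corr)
    return dG_mm_solv + dG_corr, math.hypot(err_mm, err_corr)


def work_overlap(works: WorkSet, bins: str | int = "fd") -> float:
    """Histogram overlap of forward and negated-reverse work distributions.

    Both samples are binned on a shared grid (Freedman–Diaconis width on
    the pooled sample by default) and the overlap coefficient
    Σ min(p_f, p_r)·Δw of the two density histograms is returned:
    1 for identical distributions, 0 for disjoint supports.
    """
    if works.n_forward == 0 or works.n_reverse == 0:
        raise ValidationError("overlap requires work values in both directions")
    f = works.forward
    r = -works.reverse
    pooled = np.concatenate([f, r])
    if np.ptp(pooled) == 0.0:
        return 1.0  # all mass in one point for both samples
    edges = np.histogram_bin_edges(pooled, bins=bins)
    if edges.size < 3:  # degenerate FD width (zero IQR): fall back
        edges = np.histogram_bin_edges(pooled, bins="sturges")
    hf, _ = np.histogram(f, bins=edges, density=True)
    hr, _ = np.histogram(r, bins=edges, density=True)
    widths = np.diff(edges)
    return float(np.sum(np.minimum(hf, hr) * widths))


def crooks_deviation(dG_jar: float, dG_crooks: float,
                     kT: float = kt(DEFAULT_TEMPERATURE)) -> tuple[float, str]:
    """|Crooks − Jarzynski| deviation with its significance flag.

    Flags: ``gt_2kcal`` above 2 kcal/mol, ``gt_1kT`` above one thermal
    energy, ``none`` otherwise.
    """
    _check_finite(dG_jar, dG_crooks)
    if kT <= 0:
        raise ValidationError("kT must be positive")
    delta = abs(dG_crooks - dG_jar)
    if delta > 2.0:
        flag = "gt_2kcal"
    elif delta > kT:
        flag = "gt_1kT"
    else:
        flag = "none"
    return delta, flag


def mfes_deviation(dG_mfes: float, dG_crooks: float) -> float:
    """Signed deviation of the multistate result from the Crooks result."""
    _check_finite(dG_mfes, dG_crooks)
    return dG_mfes - dG_crooks


@dataclass
class SubsampleResult:
    """Outcome of the discard/stride equilibration pruning rule."""

    n_input: int
    n_after_discard: int
    n_retained: int
    indices: np.ndarray


def mfes_subsample(n_samples: int, discard_fraction: float = 0.2,
                   stride: int = 5) -> SubsampleResult:
    """Discard the initial burn-in fraction, then decimate by ``stride``.

    The first floor(discard_fraction·n_samples) indices are dropped and
    every ``stride``-th index of the remainder is kept, starting with
    the first retained one.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValidationError("discard_fraction must lie in [0, 1)")
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    if n_samples < 0:
        raise ValidationError("n_samples must be >= 0")
    n_discard = math.floor(discard_fraction * n_samples)
    indices = np.arange(n_discard, n_samples, stride)
    return SubsampleResult(n_samples, n_samples - n_discard,
                           int(indices.size), indices)
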