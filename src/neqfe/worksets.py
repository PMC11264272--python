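"""Containers for nonequilibrium work ensembles and free-energy estimates.

A :class:`WorkSet` holds the work values accumulated along switching
trajectories between a low-level (state 0) and a high-level (state 1)
potential.  Forward works are measured along 0→1 switches started from
equilibrium at state 0; reverse works along 1→0 switches started from
equilibrium at state 1.  A :class:`MultistateSamples` holds the reduced
potential-energy matrix of equilibrium samples drawn at several
intermediate λ states, as consumed by the multistate (MBAR) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import beta_from_temperature

__all__ = [
    "WorkSet",
    "FreeEnergyEstimate",
    "MultistateSamples",
    "ValidationError",
    "EstimationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a container or operation precondition."""


class EstimationError(RuntimeError):
    """Raised when a free-energy estimate cannot be produced at all."""


def _as_work_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite work values")
    return arr


@dataclass
class WorkSet:
    """Work values from one or both switching directions.

    Parameters
    ----------
    forward : array-like
        Work values W(0→1) in kcal/mol.
    reverse : array-like, optional
        Work values W(1→0) in kcal/mol; may be empty for unidirectional
        protocols.
    beta : float
        Inverse temperature 1/(kT) in mol/kcal.
    label : str
        Free-text provenance label.
    """

    forward: np.ndarray
    reverse: np.ndarray = field(default_factory=lambda: np.empty(0))
    beta: float = beta_from_temperature()
    label: str = ""

    def __post_init__(self) -> None:
        self.forward = _as_work_array(self.forward, "forward works")
        self.reverse = _as_work_array(self.reverse, "reverse works")
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ValidationError(f"beta must be positive and finite, got {self.beta}")

    @property
    def n_forward(self) -> int:
        return int(self.forward.size)

    @property
    def n_reverse(self) -> int:
        return int(self.reverse.size)

    @property
    def bidirectional(self) -> bool:
        return self.n_forward > 0 and self.n_reverse > 0

    def swapped(self) -> "WorkSet":
        """The work set with the roles of the two states exchanged."""
        return WorkSet(self.reverse.copy(), self.forward.copy(), self.beta,
                       label=f"{self.label} (swapped)" if self.label else "swapped")


@dataclass
class FreeEnergyEstimate:
    """A free-energy difference ΔG(0→1) with its bootstrap uncertainty."""

    value: float
    stderr: float
    estimator: str  # one of {"EXP", "BAR", "MBAR"}
    n_forward: int = 0
    n_reverse: int = 0
    converged: bool = True
    diagnostic: str | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.stderr) and self.stderr < 0:
            raise ValidationError("stderr must be non-negative")
        if not self.converged and not self.diagnostic:
            raise ValidationError("unconverged estimates must carry a diagnostic message")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        flag = "" if self.converged else " [NOT CONVERGED]"
        return f"{self.estimator}: {self.value:+.4f} ± {self.stderr:.4f} kcal/mol{flag}"


@dataclass
class MultistateSamples:
    """Reduced energies u[k, n] of every sample evaluated at every state.

    ``reduced_energies`` is dimensionless (already multiplied by beta);
    ``counts[k]`` is the number of samples drawn from state k, and the
    sample columns are ordered by state of origin.  ``beta`` is kept so
    that dimensionless free energies can be converted back to kcal/mol.
    """

    reduced_energies: np.ndarray
    counts: np.ndarray
    beta: float = beta_from_temperature()

    def __post_init__(self) -> None:
        self.reduced_energies = np.asarray(self.reduced_energies, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int).ravel()
        if self.reduced_energies.ndim != 2:
            raise ValidationError("reduced_energies must be a 2-D matrix u[k, n]")
        k, n = self.reduced_energies.shape
        if self.counts.size != k:
            raise ValidationError(
                f"counts has {self.counts.size} entries for {k} states")
        if int(self.counts.sum()) != n:
            raise ValidationError(
                f"sum(counts)={int(self.counts.sum())} does not match {n} sample columns")
        if np.any(self.counts < 1):
            raise ValidationError("every state must contribute at least one sample")
        if not np.all(np.isfinite(self.reduced_energies)):
            raise ValidationError("reduced_energies contains non-finite entries")
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ValidationError(f"beta must be positive and finite, got {self.beta}")

    @property
    def n_states(self) -> int:
        return int(self.reduced_energies.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.reduced_energies.shape[1])
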