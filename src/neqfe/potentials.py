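"""Analytic toy potentials standing in for the two levels of theory.

A :class:`PotentialPair` bundles a cheap ("low", state 0) and an
expensive ("high", state 1) potential-energy function on the same
coordinates, mirroring an alchemical MM → high-level change of the
energy description.  Potentials expose energies and gradients so that
Langevin dynamics can be propagated on any λ-interpolated mixture
U(λ) = (1−λ)·U_low + λ·U_high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .worksets import ValidationError

__all__ = ["Potential", "Harmonic", "QuarticDoubleWell", "PotentialPair",
           "interpolated_energy", "interpolated_gradient"]


class Potential:
    """Interface: scalar energy and gradient of a dim-D configuration.

    ``energy``/``gradient`` accept either a single configuration of
    shape (dim,) or a batch of shape (n, dim); batches return arrays.
    """

    dim: int = 1

    def energy(self, x: np.ndarray):  # pragma: no cover - interface
        raise NotImplementedError

    def gradient(self, x: np.ndarray):  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class Harmonic(Potential):
    """U(x) = ½ k |x − c|²  (kcal/mol, isotropic spring)."""

    k: float = 1.0
    center: float = 0.0
    dim: int = 1

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * self.k * np.sum((x - self.center) ** 2, axis=-1)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        return self.k * (x - self.center)


@dataclass
class QuarticDoubleWell(Potential):
    """U(x) = b (x² − 1)² + t·x in 1-D.

    ``barrier`` b sets the well-to-barrier height at zero tilt; the tilt
    t breaks the symmetry: t > 0 favors the left well (x ≈ −1), t < 0
    the right one.
    """

    barrier: float = 5.0
    tilt: float = 0.0
    dim: int = 1

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        x0 = x[..., 0]
        return self.barrier * (x0 ** 2 - 1.0) ** 2 + self.tilt * x0

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        x0 = x[..., 0]
        g[..., 0] = 4.0 * self.barrier * x0 * (x0 ** 2 - 1.0) + self.tilt
        return g


@dataclass
class PotentialPair:
    """Low- and high-level potentials with the exact ΔG when known.

    ``analytic_dG`` is the classical free-energy difference low→high in
    kcal/mol at the pair's reference β, or None when no closed form or
    quadrature value is attached.
    """

    low: Potential
    high: Potential
    dim: int = 1
    analytic_dG: float | None = None

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValidationError("dim must be >= 1")

    def energy(self, x, lam: float):
        return interpolated_energy(self, x, lam)

    def gradient(self, x, lam: float):
        return interpolated_gradient(self, x, lam)


def _check_lambda(lam: float) -> float:
    if not 0.0 <= lam <= 1.0:
        raise ValidationError(f"coupling parameter must lie in [0, 1], got {lam}")
    return float(lam)


def interpolated_energy(pair: PotentialPair, x, lam: float):
    """Linear alchemical mixture U = (1−λ)·u_low(x) + λ·u_high(x)."""
    lam = _check_lambda(lam)
    if lam == 0.0:
        return pair.low.energy(x)
    if lam == 1.0:
        return pair.high.energy(x)
    return (1.0 - lam) * pair.low.energy(x) + lam * pair.high.energy(x)


def interpolated_gradient(pair: PotentialPair, x, lam: float):
    lam = _check_lambda(lam)
    if lam == 0.0:
        return pair.low.gradient(x)
    if lam == 1.0:
        return pair.high.gradient(x)
    return (1.0 - lam) * pair.low.gradient(x) + lam * pair.high.gradient(x)
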