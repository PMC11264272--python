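"""Equilibrium sampling and nonequilibrium switching on toy potentials.

The switching protocol mirrors the alternating perturbation/propagation
scheme used in endstate-correction work: the coupling parameter follows
the linear schedule λ_t = t/τ; each perturbation step switches the
potential at fixed coordinates and the work increment is the energy
change U_{λ_{t+1}}(x) − U_{λ_t}(x) under that switch; propagation is a
single BAOAB-discretized Langevin step at the freshly-updated λ.  With
n_steps = 1 the protocol degenerates to an instantaneous jump and the
work is exactly u_high(start) − u_low(start).

Everything runs in reduced toy units: unit particle mass, energies in
kcal/mol, kT set by the protocol temperature, dt and friction chosen for
stability on stiffnesses up to k ≈ 100.

Seeding: one master seed; each switch draws from its own stream derived
from (seed, switch index, direction), so a work ensemble is independent
of execution order and of whether switches run singly or batched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .potentials import PotentialPair
from .units import kt as thermal_energy
from .worksets import ValidationError, WorkSet

__all__ = [
    "SwitchingProtocol",
    "SwitchResult",
    "PropagationError",
    "SwitchError",
    "langevin_step",
    "sample_equilibrium",
    "run_switch",
    "run_protocol",
    "run_bidirectional",
]

_DIRECTIONS = ("low_to_high", "high_to_low")


class PropagationError(RuntimeError):
    """Raised when Langevin propagation encounters a non-finite force."""


class SwitchError(RuntimeError):
    """Raised when a switching trajectory produces a non-finite work value."""


@dataclass
class SwitchingProtocol:
    """Schedule parameters of one nonequilibrium switch.

    ``n_steps`` is the number of perturbation steps τ; ``dt`` and
    ``friction`` are in reduced toy units (unit mass).
    """

    n_steps: int = 100
    dt: float = 0.001
    temperature: float = 300.0
    friction: float = 1.0
    direction: str = "low_to_high"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.friction < 0:
            raise ValidationError("friction must be non-negative")
        if self.direction not in _DIRECTIONS:
            raise ValidationError(
                f"direction must be one of {_DIRECTIONS}, got {self.direction!r}")

    @property
    def kt(self) -> float:
        return thermal_energy(self.temperature)

    def reversed(self) -> "SwitchingProtocol":
        other = _DIRECTIONS[1 - _DIRECTIONS.index(self.direction)]
        return replace(self, direction=other)

    def lambda_schedule(self) -> np.ndarray:
        lams = np.linspace(0.0, 1.0, self.n_steps + 1)
        return lams if self.direction == "low_to_high" else lams[::-1]


@dataclass
class SwitchResult:
    """Outcome of one switching trajectory."""

    total_work: float
    work_trace: np.ndarray
    final_coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.work_trace = np.asarray(self.work_trace, dtype=float)
        if abs(self.total_work - float(self.work_trace.sum())) > 1e-10:
            raise ValidationError("total_work inconsistent with work_trace")


def _ou_coefficients(protocol: SwitchingProtocol) -> tuple[float, float]:
    c1 = math.exp(-protocol.friction * protocol.dt)
    c2 = math.sqrt(protocol.kt * (1.0 - c1 * c1))
    return c1, c2


def langevin_step(
    x: np.ndarray,
    v: np.ndarray,
    force: Callable[[np.ndarray], np.ndarray],
    protocol: SwitchingProtocol,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One BAOAB Langevin update at unit mass.

    B: half-kick, A: half-drift, O: Ornstein–Uhlenbeck velocity
    randomization at the protocol's temperature and friction, then A and
    B again.  ``noise`` (standard normal, shape of ``x``) may be supplied
    instead of ``rng`` for pre-drawn batched streams; the update is
    deterministic given the noise.
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if noise is None:
        if rng is None:
            rng = np.random.default_rng(protocol.seed)
        noise = rng.standard_normal(x.shape)
    dt = protocol.dt
    c1, c2 = _ou_coefficients(protocol)
    f = np.asarray(force(x), dtype=float)
    if not np.all(np.isfinite(f)):
        bad = np.argwhere(~np.isfinite(f))
        raise PropagationError(f"non-finite force at coordinates {bad[:5].tolist()}")
    v = v + 0.5 * dt * f
    x = x + 0.5 * dt * v
    v = c1 * v + c2 * noise
    x = x + 0.5 * dt * v
    f = np.asarray(force(x), dtype=float)
    if not np.all(np.isfinite(f)):
        bad = np.argwhere(~np.isfinite(f))
        raise PropagationError(f"non-finite force at coordinates {bad[:5].tolist()}")
    v = v + 0.5 * dt * f
    return x, v


def sample_equilibrium(
    pair: PotentialPair,
    level: str,
    n_samples: int,
    n_equil_steps: int = 2000,
    stride: int = 10,
    protocol: SwitchingProtocol | None = None,
    x0: np.ndarray | None = None,
    n_chains: int = 1,
) -> np.ndarray:
    """Equilibrium configurations of one endpoint potential.

    Runs Langevin dynamics on ``level`` ∈ {"low", "high"}, discards
    ``n_equil_steps`` burn-in steps, then records every ``stride``-th
    frame until ``n_samples`` configurations are pooled.  ``n_chains``
    independent chains may be propagated in parallel (each contributing
    an equal share of frames), which decorrelates the pool; ``x0`` sets
    the common starting point (defaults to the origin).
    Returns an array of shape (n_samples, dim).
    """
    if level not in ("low", "high"):
        raise ValidationError(f"level must be 'low' or 'high', got {level!r}")
    if n_samples < 0 or n_chains < 1 or stride < 1:
        raise ValidationError("n_samples >= 0, n_chains >= 1, stride >= 1 required")
    protocol = protocol or SwitchingProtocol()
    if n_samples == 0:
        return np.empty((0, pair.dim))
    lam = 0.0 if level == "low" else 1.0
    force = lambda x: -pair.gradient(x, lam)  # noqa: E731
    rng = np.random.default_rng(np.random.SeedSequence([protocol.seed, 97, int(lam)]))
    x = np.zeros((n_chains, pair.dim)) if x0 is None else \
        np.broadcast_to(np.asarray(x0, dtype=float), (n_chains, pair.dim)).copy()
    v = math.sqrt(protocol.kt) * rng.standard_normal(x.shape)
    for _ in range(n_equil_steps):
        x, v = langevin_step(x, v, force, protocol, rng=rng)
    per_chain = -(-n_samples // n_chains)  # ceil
    frames = np.empty((per_chain, n_chains, pair.dim))
    for i in range(per_chain):
        for _ in range(stride):
            x, v = langevin_step(x, v, force, protocol, rng=rng)
        frames[i] = x
    pooled = frames.reshape(-1, pair.dim)
    if not np.all(np.isfinite(pooled)):
        raise PropagationError("equilibrium trajectory diverged")
    return pooled[:n_samples]


def _switch_rng(seed: int, index: int, direction: str) -> np.random.Generator:
    ss = np.random.SeedSequence([seed, index, _DIRECTIONS.index(direction)])
    return np.random.default_rng(ss)


def run_switch(
    pair: PotentialPair,
    start: np.ndarray,
    protocol: SwitchingProtocol,
    rng: np.random.Generator | None = None,
) -> SwitchResult:
    """One switching trajectory: alternating perturbation and propagation.

    Work accumulates as the potential-switch energy change at fixed
    coordinates, W_t = U_{λ_{t+1}}(x) − U_{λ_t}(x), summed over all
    n_steps perturbation steps; a Langevin step at the new λ follows
    each perturbation.
    """
    x = np.asarray(start, dtype=float).reshape(pair.dim)
    if not np.all(np.isfinite(x)):
        raise ValidationError("start coordinates must be finite")
    if rng is None:
        rng = _switch_rng(protocol.seed, 0, protocol.direction)
    lams = protocol.lambda_schedule()
    v = math.sqrt(protocol.kt) * rng.standard_normal(x.shape)
    trace = np.empty(protocol.n_steps)
    for t in range(protocol.n_steps):
        w = float(pair.energy(x, lams[t + 1]) - pair.energy(x, lams[t]))
        if not np.isfinite(w):
            raise SwitchError(f"non-finite work increment at step {t}")
        trace[t] = w
        force = lambda y, lam=lams[t + 1]: -pair.gradient(y, lam)  # noqa: E731
        x, v = langevin_step(x, v, force, protocol, rng=rng)
    return SwitchResult(float(trace.sum()), trace, x)


def _run_switch_batch(
    pair: PotentialPair,
    starts: np.ndarray,
    protocol: SwitchingProtocol,
    rngs: list[np.random.Generator],
) -> np.ndarray:
    """Vectorized propagation of many switches; per-switch noise streams
    are pre-drawn so results match the sequential path exactly."""
    n = starts.shape[0]
    x = starts.astype(float).copy()
    kt_sqrt = math.sqrt(protocol.kt)
    v = np.stack([kt_sqrt * r.standard_normal(pair.dim) for r in rngs])
    noise = np.stack([r.standard_normal((protocol.n_steps, pair.dim)) for r in rngs])
    lams = protocol.lambda_schedule()
    work = np.zeros(n)
    for t in range(protocol.n_steps):
        work += pair.energy(x, lams[t + 1]) - pair.energy(x, lams[t])
        force = lambda y, lam=lams[t + 1]: -pair.gradient(y, lam)  # noqa: E731
        x, v = langevin_step(x, v, force, protocol, noise=noise[:, t, :])
    if not np.all(np.isfinite(work)):
        bad = int(np.argwhere(~np.isfinite(work))[0, 0])
        raise SwitchError(f"non-finite total work in switch {bad}")
    return work


def run_protocol(
    pair: PotentialPair,
    protocol: SwitchingProtocol,
    n_switches: int = 300,
    equilibrium_pool: np.ndarray | None = None,
) -> WorkSet:
    """A work ensemble from ``n_switches`` switching trajectories.

    Start configurations are drawn with replacement from the
    equilibrium pool of the protocol's initial endpoint; each switch
    uses its own seed stream derived from (protocol.seed, index,
    direction).  Returns the :class:`WorkSet` for the protocol's
    direction (forward for low→high, reverse for high→low).
    """
    beta = 1.0 / protocol.kt
    if n_switches < 0:
        raise ValidationError("n_switches must be >= 0")
    if n_switches == 0:
        return WorkSet(np.empty(0), np.empty(0), beta)
    pool = np.asarray(equilibrium_pool, dtype=float) if equilibrium_pool is not None \
        else None
    if pool is None or pool.size == 0:
        raise ValidationError("equilibrium_pool must be non-empty")
    pool = pool.reshape(-1, pair.dim)
    rngs = [_switch_rng(protocol.seed, i, protocol.direction)
            for i in range(n_switches)]
    idx = np.array([int(r.integers(pool.shape[0])) for r in rngs])
    works = _run_switch_batch(pair, pool[idx], protocol, rngs)
    if protocol.direction == "low_to_high":
        return WorkSet(works, np.empty(0), beta)
    return WorkSet(np.empty(0), works, beta)


def run_bidirectional(
    pair: PotentialPair,
    protocol: SwitchingProtocol,
    pool_low: np.ndarray,
    pool_high: np.ndarray,
    n_switches: int = 300,
) -> WorkSet:
    """Forward and reverse work ensembles from the two endpoint pools."""
    fwd = replace(protocol, direction="low_to_high")
    rev = replace(protocol, direction="high_to_low")
    ws_f = run_protocol(pair, fwd, n_switches, pool_low)
    ws_r = run_protocol(pair, rev, n_switches, pool_high)
    return WorkSet(ws_f.forward, ws_r.reverse, ws_f.beta)
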