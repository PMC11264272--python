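"""Free-energy estimators for nonequilibrium work and multistate samples.

Three estimators are provided:

``exp_estimate``
    Exponential averaging of unidirectional work (Jarzynski):
    ΔG = −β⁻¹ ln ⟨exp(−βW)⟩, evaluated with log-sum-exp so that large
    |βW| never overflows.

``bar_estimate``
    The Bennett acceptance ratio, i.e. the maximum-likelihood estimator
    implied by the Crooks fluctuation theorem.  ΔG is the root of the
    self-consistency condition

        Σ_i f(M + βW_f,i − βΔG) = Σ_j f(−M + βW_r,j + βΔG),

    with the Fermi function f(x) = 1/(1+eˣ) and the sample-count offset
    M = ln(N_f/N_r), so unequal numbers of forward and reverse switches
    are handled.

``mbar_estimate``
    The multistate generalization over K λ-states, solved by
    self-consistent iteration with a damped-Newton fallback on the
    convex MBAR objective; state 0 is the anchor (ΔF₀ = 0).

Uncertainties come from :func:`bootstrap_stderr`: resampling with
replacement at the original sample size, re-running the estimator, and
taking the standard deviation over the resamples.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import expit, logsumexp

from .worksets import (
    EstimationError,
    FreeEnergyEstimate,
    MultistateSamples,
    ValidationError,
    WorkSet,
)

__all__ = [
    "exp_estimate",
    "bar_estimate",
    "mbar_estimate",
    "bootstrap_stderr",
    "workset_to_multistate",
]

DEFAULT_N_BOOT = 1000


def _exp_value(works: np.ndarray, beta: float) -> float:
    # ΔG = −β⁻¹ [logsumexp(−βW) − ln N]; safe for |βW| up to ~1e308's log range
    return float(-(logsumexp(-beta * works) - np.log(works.size)) / beta)


def exp_estimate(
    works: WorkSet,
    direction: str = "forward",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = 0,
) -> FreeEnergyEstimate:
    """Jarzynski (exponential-averaging) estimate of ΔG(0→1).

    For ``direction="reverse"`` the exponential average runs over the
    1→0 work values and the result is negated, so that the returned
    value is always the 0→1 free-energy difference.
    """
    if direction not in ("forward", "reverse"):
        raise ValidationError(f"unknown direction {direction!r}")
    w = works.forward if direction == "forward" else works.reverse
    if w.size == 0:
        raise EstimationError(f"empty {direction} work list")
    sign = 1.0 if direction == "forward" else -1.0
    value = sign * _exp_value(w, works.beta)
    stderr = 0.0
    if n_boot and n_boot >= 2:
        one_dir = WorkSet(w, beta=works.beta)
        stderr = bootstrap_stderr(
            one_dir, lambda ws: sign * _exp_value(ws.forward, ws.beta),
            n_boot=n_boot, seed=seed)
    return FreeEnergyEstimate(value, stderr, "EXP",
                              n_forward=works.n_forward, n_reverse=works.n_reverse)


def _bar_residual(x: float, wf: np.ndarray, wr: np.ndarray, m: float) -> float:
    # x = βΔG; Fermi f(t) = 1/(1+e^t) = expit(−t); residual is increasing in x
    lhs = expit(-(m + wf - x)).sum()
    rhs = expit(-(-m + wr + x)).sum()
    return lhs - rhs


def _bar_value(forward: np.ndarray, reverse: np.ndarray, beta: float,
               tol: float, max_iter: int) -> tuple[float, bool, str | None]:
    wf = beta * forward
    wr = beta * reverse
    m = np.log(forward.size / reverse.size)
    # bracket from the pooled work values (in reduced units), expanded
    # geometrically until the monotone residual changes sign
    pooled = np.concatenate([wf, -wr])
    lo = float(pooled.min()) - 1.0
    hi = float(pooled.max()) + 1.0
    width = max(hi - lo, 1.0)
    for _ in range(200):
        if _bar_residual(lo, wf, wr, m) < 0 < _bar_residual(hi, wf, wr, m):
            break
        lo -= width
        hi += width
        width *= 2.0
    else:
        return float(np.mean(forward)), False, "could not bracket the BAR fixed point"
    try:
        x = brentq(_bar_residual, lo, hi, args=(wf, wr, m),
                   xtol=beta * tol, maxiter=max_iter)
    except RuntimeError as err:  # pragma: no cover - brentq rarely fails on a bracket
        return float(0.5 * (lo + hi) / beta), False, f"BAR root finding failed: {err}"
    return float(x / beta), True, None


def bar_estimate(
    works: WorkSet,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = 0,
) -> FreeEnergyEstimate:
    """Bennett acceptance ratio estimate of ΔG(0→1) from bidirectional work."""
    if works.n_forward == 0 or works.n_reverse == 0:
        raise EstimationError("BAR requires work values in both directions")
    value, converged, diag = _bar_value(works.forward, works.reverse,
                                        works.beta, tol, max_iter)
    stderr = 0.0
    if n_boot and n_boot >= 2:
        stderr = bootstrap_stderr(
            works,
            lambda ws: _bar_value(ws.forward, ws.reverse, ws.beta, tol, max_iter)[0],
            n_boot=n_boot, seed=seed)
    return FreeEnergyEstimate(value, stderr, "BAR",
                              n_forward=works.n_forward, n_reverse=works.n_reverse,
                              converged=converged, diagnostic=diag)


def _mbar_objective(f_rest: np.ndarray, u: np.ndarray, counts: np.ndarray):
    """Convex MBAR objective and gradient over the non-anchored free energies."""
    f = np.concatenate([[0.0], f_rest])
    log_n = np.log(counts)
    # log D_n = logsumexp_k [ ln N_k + f_k − u_kn ]
    log_d = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
    obj = log_d.sum() - float(counts @ f)
    w = np.exp(log_n[:, None] + f[:, None] - u - log_d[None, :])  # (K, N)
    grad = w.sum(axis=1) - counts
    return obj, grad[1:]


def _mbar_values(u: np.ndarray, counts: np.ndarray, tol: float,
                 max_iter: int) -> tuple[np.ndarray, bool, str | None]:
    k, _ = u.shape
    log_n = np.log(counts.astype(float))
    f = np.zeros(k)
    converged = False
    n_scf = min(50, max_iter)
    for _ in range(n_scf):
        log_d = logsumexp((log_n + f)[:, None] - u, axis=0)
        f_new = -logsumexp(-u - log_d[None, :], axis=1)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        # damped Newton via quasi-Newton minimization of the convex objective
        res = minimize(_mbar_objective, f[1:], args=(u, counts),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-12})
        f = np.concatenate([[0.0], res.x])
        # final polish + convergence check with the self-consistency residual
        log_d = logsumexp((log_n + f)[:, None] - u, axis=0)
        f_new = -logsumexp(-u - log_d[None, :], axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        converged = residual < max(tol, 1e-8)
    diag = None if converged else "MBAR self-consistency iteration did not converge"
    return f, converged, diag


def mbar_estimate(
    samples: MultistateSamples,
    tol: float = 1e-10,
    max_iter: int = 2000,
    n_boot: int = 0,
    seed: int | None = 0,
) -> list[FreeEnergyEstimate]:
    """Multistate (MBAR) free energies of every state relative to state 0.

    Returns one estimate per state, in kcal/mol, anchored at state 0.
    Bootstrap uncertainties (resampling columns within each state of
    origin) are computed when ``n_boot >= 2``; otherwise stderr is 0.
    """
    u = samples.reduced_energies
    counts = samples.counts
    f, converged, diag = _mbar_values(u, counts, tol, max_iter)
    stderrs = np.zeros(samples.n_states)
    if n_boot and n_boot >= 2:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, samples.n_states))
        starts = np.concatenate([[0], np.cumsum(counts)])
        for b in range(n_boot):
            cols = np.concatenate([
                rng.integers(starts[i], starts[i + 1], size=counts[i])
                for i in range(samples.n_states)])
            fb, _, _ = _mbar_values(u[:, cols], counts, tol, max_iter)
            boots[b] = fb
        stderrs = boots.std(axis=0, ddof=1) / samples.beta
    return [
        FreeEnergyEstimate(float(f[i] / samples.beta), float(stderrs[i]), "MBAR",
                           n_forward=int(counts[i]), n_reverse=0,
                           converged=converged, diagnostic=diag)
        for i in range(samples.n_states)
    ]


def mbar_weights(samples: MultistateSamples, tol: float = 1e-10,
                 max_iter: int = 2000) -> np.ndarray:
    """Normalized MBAR weight matrix W[k, n]; each row sums to 1 at convergence."""
    u = samples.reduced_energies
    counts = samples.counts
    f, _, _ = _mbar_values(u, counts, tol, max_iter)
    log_n = np.log(counts.astype(float))
    log_d = logsumexp((log_n + f)[:, None] - u, axis=0)
    log_norm = logsumexp(-u - log_d[None, :], axis=1)
    return np.exp(-u - log_d[None, :] - log_norm[:, None])


def workset_to_multistate(works: WorkSet) -> MultistateSamples:
    """Recast bidirectional work values as an equivalent two-state sample set.

    A forward sample contributes the column (u₀, u₁) = (0, βW_f); a
    reverse sample the column (βW_r, 0).  Per-column constants cancel in
    the multistate equations, so two-state MBAR on this matrix equals BAR
    on the original work set.
    """
    if not works.bidirectional:
        raise ValidationError("two-state recasting needs both directions")
    beta = works.beta
    nf, nr = works.n_forward, works.n_reverse
    u = np.zeros((2, nf + nr))
    u[1, :nf] = beta * works.forward
    u[0, nf:] = beta * works.reverse
    return MultistateSamples(u, np.array([nf, nr]), beta=beta)


def bootstrap_stderr(
    works_or_inputs,
    estimator: Callable,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = 0,
) -> float:
    """Bootstrap standard deviation of a scalar estimator.

    Resamples the input with replacement at its original size, applies
    ``estimator`` to each resample, and returns the standard deviation
    of the resulting estimates.  Accepts a :class:`WorkSet` (each
    direction resampled independently), a :class:`MultistateSamples`
    (columns resampled within each state of origin), or a plain array.
    The same seed always yields the identical result.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    values = []
    failures = 0
    for _ in range(n_boot):
        resampled = _resample(works_or_inputs, rng)
        try:
            est = estimator(resampled)
        except Exception:
            failures += 1
            continue
        values.append(float(est.value if hasattr(est, "value") else est))
    if failures > 0.1 * n_boot:
        raise EstimationError(
            f"estimator failed on {failures}/{n_boot} bootstrap resamples")
    return float(np.std(values, ddof=1))


def _resample(inputs, rng: np.random.Generator):
    if isinstance(inputs, WorkSet):
        if inputs.n_forward == 0 and inputs.n_reverse == 0:
            raise ValidationError("cannot bootstrap an empty work set")
        fwd = rng.choice(inputs.forward, size=inputs.n_forward, replace=True) \
            if inputs.n_forward else inputs.forward
        rev = rng.choice(inputs.reverse, size=inputs.n_reverse, replace=True) \
            if inputs.n_reverse else inputs.reverse
        return WorkSet(fwd, rev, inputs.beta, label=inputs.label)
    if isinstance(inputs, MultistateSamples):
        starts = np.concatenate([[0], np.cumsum(inputs.counts)])
        cols = np.concatenate([
            rng.integers(starts[i], starts[i + 1], size=inputs.counts[i])
            for i in range(inputs.n_states)])
        return MultistateSamples(inputs.reduced_energies[:, cols],
                                 inputs.counts, beta=inputs.beta)
    arr = np.asarray(inputs, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError("cannot bootstrap an empty sample")
    return rng.choice(arr, size=arr.size, replace=True)
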