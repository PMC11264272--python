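# Methods

This note records the models implemented in `neqfe`, the conventions
and defaults they use, what the synthetic generators do and do not
emulate, and the numerical choices that were genuinely open.

## Estimators

**Conventions.** State 0 is the low (cheap) level of theory, state 1
the high level.  Forward work W₀→₁ is accumulated along switches
started from equilibrium at state 0; reverse work W₁→₀ from state 1.
All energies are kcal/mol; β = 1/(kT) in mol/kcal.  The default
temperature is 300 K (kT = 0.5962 kcal/mol, β = 1.677 mol/kcal);
every threshold quoted "in kT" is evaluated at the configured
temperature, which is always explicit in the `WorkSet`/protocol
objects.

**EXP (exponential averaging).** ΔG = −β⁻¹ ln⟨e^(−βW)⟩ over the chosen
direction, computed as −β⁻¹(logsumexp(−βW) − ln N) so that reduced
works of hundreds of kT cannot overflow.  A reverse-direction estimate
is negated before being reported, so the returned value is always the
0→1 free-energy difference.  By Jensen's inequality the estimate never
exceeds the mean work; the gap is the dissipation.

**BAR.** The maximum-likelihood estimator implied by the Crooks
fluctuation theorem: ΔG solves

    Σᵢ f(M + βW_f,i − βΔG) = Σⱼ f(−M + βW_r,j + βΔG),

with the Fermi function f(x) = 1/(1+eˣ) (evaluated as a logistic
sigmoid for stability) and M = ln(N_f/N_r), which handles unequal
numbers of forward and reverse switches.  The left side is increasing
in ΔG and the right side decreasing, so the root is unique; it is
bracketed from the pooled work values with geometric expansion and
refined by Brent's method to 10⁻⁸ kcal/mol.  Failure to bracket or
converge returns an estimate flagged `converged=False` with a
diagnostic, never an exception.  Antisymmetry (swapping the direction
lists negates the estimate) and shift covariance (adding c to forward
works and −c to reverse works shifts the estimate by c) hold to the
root tolerance; a data set whose reverse list equals its forward list
is its own swap, which pins the estimate at exactly zero.

**MBAR.** For K states with reduced energies u_k(x_n) the dimensionless
free energies satisfy f_k = −ln Σₙ e^(−u_kn)/Σₗ N_l e^(f_l − u_ln),
anchored at f₀ = 0.  The solver runs self-consistent iteration (50
sweeps) and, if the residual has not fallen below tolerance, minimizes
the equivalent convex objective Σₙ ln Σₖ N_k e^(f_k − u_kn) − Σₖ N_k f_k
with L-BFGS and an analytic gradient, then polishes with one more
self-consistent sweep.  At convergence the implied weight matrix rows
each sum to one (checked to 10⁻¹⁰ in the tests).  With K = 2 the
equations reduce exactly to BAR, which the suite verifies on identical
input to 10⁻⁶ kcal/mol — a deliberate dual-route consistency check,
since the two code paths share nothing but the work values.

**Uncertainties.** One bootstrap convention everywhere: resample the
input with replacement at its original size (each work direction, or
the sample columns within each λ state, independently), re-run the
estimator, and report the standard deviation over resamples.  The
default is 1000 resamples from a single seeded generator per call;
identical seeds give bit-identical results.  Percentile intervals are
reserved for the benchmark statistics (below).  If more than 10% of
resamples fail, the bootstrap aborts with a diagnostic rather than
silently reporting a truncated spread.

## Switching engine

The engine works in reduced toy units: unit particle mass, energies in
kcal/mol, kT from the protocol temperature.  The defaults dt = 0.001
and friction γ = 1 are stable for stiffnesses up to k ≈ 100; the
equilibrium sampler is usually run at dt = 0.01, where the BAOAB
discretization error in configurational moments is O(dt²) and
negligible at the stiffnesses used.

A switch alternates perturbation and propagation over the linear
schedule λ_t = t/τ (reversed for high→low switches):

1. perturbation: λ advances one increment and the work increment
   U_{λ+}(x) − U_λ(x) is recorded **at the current coordinates** —
   switching the potential at fixed configuration;
2. propagation: one BAOAB Langevin step at the freshly updated λ.

Whether the very first increment is taken before or after the first
propagation step is a genuinely open convention; perturbation-first
was chosen because it makes the τ = 1 limit reduce exactly to
single-configuration instantaneous perturbation,
W = u_high(start) − u_low(start), while every later increment is
evaluated at post-propagation coordinates.  Total work equals the sum
of the per-step trace to 10⁻¹⁰ by construction, and mean dissipated
work decreases with protocol length (verified statistically over
τ ∈ {10, 100, 1000, 5000}).

**Seeding.** One master seed; the stream for switch i in direction d
derives from `SeedSequence([seed, i, d])`.  Work ensembles are
therefore independent of execution order, and the vectorized batch
path (all switches propagated together on pre-drawn noise blocks)
reproduces the sequential path bit for bit — a property the suite
asserts directly.  Start configurations are drawn from the equilibrium
pool *with replacement*, accepting slightly higher variance than
without-replacement draws for the sake of matching the standard
protocol.

**Equilibrium pools.** `sample_equilibrium` can run many chains in
parallel.  For quantitative recovery runs the pools are generated with
one chain per sample (e.g. 1000 chains, one frame each, after a
burn-in of ~15 position-relaxation times at dt = 0.01), so the pool is
a set of independent equilibrium draws.  Pools built from a few long
correlated chains have an effective sample size far below their
nominal size; the resulting start-distribution error propagates into
the work ensemble but is invisible to the work bootstrap, which is why
the independent-chain construction is the default in the acceptance
runs.

## Cycle bookkeeping and diagnostics

Solvation from annihilation legs: ΔG_solv = ΔG_gas − ΔG_aq.  Endstate
correction: ΔG_corr = −ΔG_gas(corr) + ΔG_aq(corr).  Corrected ASFE:
ΔG_solv(low) + ΔG_corr.  Uncertainties combine as independent-Gaussian
quadrature; correlations between legs are ignored because legs come
from independent simulations.  The four-leg cycle closes identically
(checked to 10⁻¹²).

**Overlap.** No canonical overlap statistic exists for work
distributions; the histogram overlap coefficient
Σ min(p_f, p_r)Δw between the forward and negated-reverse samples was
chosen for interpretability (1 identical, 0 disjoint), with a shared
Freedman–Diaconis binning on the pooled sample for determinism (falling
back to Sturges when the IQR degenerates).  For two unit-variance
Gaussians Δ apart the statistic approaches 2Φ(−Δ/2), which the tests
use as the oracle.  Binning resolution limits its accuracy to a few
hundredths; it is a screening diagnostic, not a precision measurement.

**Deviation flags.** Δ_Crooks = |ΔG_Crooks − ΔG_Jarzynski| is flagged
above 1 kT and, more severely, above 2 kcal/mol; Δ_MFES is the signed
deviation of the multistate result from the Crooks result.  The
subsampling rule for multistate equilibrium data discards the first
floor(fraction·N) samples (default 20%) and keeps every stride-th
(default 5th) of the remainder starting with the first retained index:
5000 samples → 4000 → 800.

## Benchmark statistics

Deviations use δΔG = ΔG_exp − ΔG_calc, so predictions that are too
positive (too hydrophobic) give negative δΔG.  RMSE, MAE, Pearson and
Spearman (average ranks on ties) come with 95% percentile-bootstrap
confidence intervals from a **joint** row resample — the same resample
feeds all four statistics, preserving their correlations; per-statistic
resampling was the alternative and was rejected as statistically
incoherent.  Constant columns make correlations undefined; they are
reported as missing with a diagnostic, never as zero.  KDEs use a
Gaussian kernel with Scott's rule by default (overridable), a grid
spanning the data ± 3 bandwidths, and integrate to 1 within 10⁻³.

"Improvement" means a strict decrease of |δΔG| after adding the
correction; ties count as non-improvement (the conservative reading).
Report percentages are rounded half away from zero; exact fractions
are retained internally and the rounded numbers are checked for
coherence with the underlying counts.  Worst-performer selection ranks
by |δΔG| descending with molecule-id tie-breaks after removing rows
whose element sets leave {H, C, N, O, F, S, Cl}; box statistics per
rotatable-bond count use the Tukey 1.5×IQR whisker rule with outliers
ranked by |correction|.  Rotatable-bond counts are consumed as a
column; no cheminformatics is performed.

## Synthetic data

`gaussian_work_pairs` draws forward works from N(ΔG + βσ²/2, σ²) and
reverse works from N(−ΔG + βσ²/2, σ²); this pair satisfies the Crooks
relation with free energy ΔG identically at the density level, so ΔG
is exact ground truth.  `harmonic_pair` has the closed form
ΔG = ln(k_h/k_l)/(2β) (center shifts change work values but not ΔG).
`double_well_pair` uses quartic wells b(x²−1)² + t·x with opposite
tilts at the two levels, the trapping scenario; its ΔG comes from
adaptive quadrature of both partition functions on a domain where the
integrand is far below 10⁻¹⁶ of its peak, with a relative tolerance of
10⁻¹⁰.  Exact Boltzmann draws for multistate tests use inverse-CDF
sampling on a dense grid.

`benchmark_table` emulates the *statistical shape* of a hydration
free-energy benchmark of ~600 drug-like molecules: experimental values
from a two-component Gaussian mixture spanning roughly [−25, +5]
kcal/mol; force-field predictions biased +1 kcal/mol (too positive)
with Gaussian noise of total sd 0.9 kcal/mol, so the δΔG density peaks
near −1 and the RMSE lands near 1.3 kcal/mol; two force-field columns
share 60% of their error variance, so their worst-100 lists overlap
partially; half the corrections fall strictly inside ±0.5 kcal/mol
with a heavy exponential tail beyond (capped at 6 kcal/mol); each
correction points toward experiment with probability 0.62 and is
capped below twice the deviation so that pointing toward experiment
actually improves the row; an optional mode couples correction
magnitude to a synthetic rotatable-bond count (Poisson(3), capped at
12); about 8% of rows carry elements outside the allowed set so the
element filter has work to do.  Molecule ids, element strings and
rotatable-bond counts are labels, not chemistry: the generator
reproduces none of the quantum-chemical or conformational physics that
drives real corrections, so passing benchmarks here validates the
*statistics machinery*, not any force field.

All generators are bit-reproducible from their seed.

## Problem sizes

The standard analysis sizes used throughout the tests and the
acceptance script: 300 work values per direction with 1000 bootstrap
resamples; switching protocols up to 5000 steps; equilibrium pools of
600–1000 independent chains; 11 λ windows × 800 samples for the
multistate runs (with 25 bootstrap resamples for their uncertainty);
benchmark tables of 589–642 rows.  These sizes were chosen so every
statistical tolerance in the suite is comfortably resolved.

## Known limitations

- One-dimensional toy potentials only; no solvent, periodic boundaries
  or pressure coupling — conclusions about estimator behaviour
  transfer, absolute magnitudes do not.
- The work bootstrap does not see start-pool quality; biased pools
  bias the estimate without inflating its error bar (this is a real
  failure mode the package reproduces, not a defect of the bootstrap).
- The overlap coefficient depends on binning at the few-percent level.
- MBAR uncertainties come from the bootstrap, not the asymptotic
  covariance estimator.
- The benchmark generator produces plausible *numbers*, not molecules;
  element sets and flexibility labels are synthetic.
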