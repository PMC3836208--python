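# Methods

## Model

The state is a vector `c(t)` of continuous abundances for `m = 2q` T-cell
species: healthy species `1..q` and preleukemic species `q+1..2q`, species
`i` and `q+i` together forming clone `i`. `n` niches supply resources at
constant rates `p_j ≥ 0`. Affinities enter through an `m × n` matrix
`A = [a_ij] ≥ 0` with the structure "unspecific affinity `u` everywhere plus
specific affinity `s` on the preferred niche", preferred niches pairing
clone `i` with niche `i` (the construction therefore requires `n = q`).

The dynamics compose three maps evaluated at every instant:

1. `r_ij = a_ij c_i / (Σ_k a_kj c_k) · p_j` when the denominator is
   positive, else 0. Column sums of `R` equal `p_j` for every contested
   niche (resource conservation); rates depend on *relative* affinities
   only, which is why one affinity parameter (`u_h = 1/n`) can be fixed as
   the reference without loss of generality.
2. `k_i = v_i Σ_j r_ij` — the carrying capacity is the acquired resource
   rate scaled by the resource utilization efficiency `v_i`.
3. `dc_i/dt = (c_i/τ)(1 − c_i/k_i)` for `k_i > 0`, else 0. Because
   `r_ij ∝ c_i`, capacity is proportional to abundance and the per-capita
   growth rate depends on the state only through the niche denominators;
   `c_i = 0` is absorbing and the non-negative orthant is forward-invariant.

Interpretation of the parameters (defaults in brackets): `τ` [8 h] is the
minimum cell cycle time, bounding per-capita growth by `1/τ`; `p_j` [100
resource units/h] sizes a niche at 100 sustainable cells for `v = 1`;
`s_h` [1] and `u_h` [0.01] set how strongly a healthy clone is bound to its
own niche versus the rest (their ratio measures the strictness of niche
regulation); `v_h` [1] normalizes the physiological total to
`v_h Σ_j p_j = 10^4` cells. The preleukemic triple `(s_p, u_p, v_p)` is the
object of the screen and is expressed as fold-changes of the healthy values.

## In-silico transplantation

All simulations start from 500 cells placed in an empty system, matching the
transplantation assay the model addresses (5×10⁶ transplanted cells against
a repertoire of order 10⁶ clones, i.e. ~5 cells per clone, rescaled to the
`q = 100` system). Scenarios P1/P10/P100 make 1/10/100 of the 500 cells
preleukemic. Monoclonal grafts put all healthy cells in clone 1 and all
preleukemic cells in species `q+1`; polyclonal grafts seed preleukemic cells
one per clone into clones `1..P` and spread the healthy remainder over all
`q` healthy species. Healthy allocation is even by default (as equal as
possible, remainder to the lowest indices) — fully deterministic and
reproducible; a multinomial mode with a mandatory seed reproduces a
uniform-random allocation. Steady states are insensitive to this choice as
long as every clone starts non-empty, which the test suite checks rather
than assumes.

The generator emulates the *cell-number and clonality structure* of the
assay only. It does not represent oncogene heterogeneity, multi-step
lesion acquisition, TCR sequence identity, cross-reactivity structure, or
stochastic birth–death noise at small cell numbers — a single preleukemic
"cell" here is a deterministic continuum variable. Passing screens
therefore show consistency of the competition mechanism with the observed
outcome pattern, not a fit to any measured clone-size data.

## Integration and steady-state detection

The steady-state criterion is defined on a fixed checkpoint grid, making it
integrator-independent: the state is sampled every `check_interval` [1 h]
and the run is converged at the first checkpoint where
`max_i |c_i(t) − c_i(t−Δ)| / max(c_i(t−Δ), floor) < 10⁻⁶`. Abundances below
`floor` [10⁻⁹ cells] are clamped to exactly 0 when sampled, so extinction
actually terminates (the continuous logistic only reaches 0 asymptotically)
and the relative-change denominator stays defined. Runs that have not met
the criterion by `t_max` are flagged, never treated as errors; screen runs
use `t_max = 10⁷ h` so that even near-neutral competitive exclusion (rates
of order 10⁻⁶/h) resolves, and in practice every grid point converges.

Two independent integration paths exist:

* **Full system** (`tniche.simulate.integrate`): scipy's adaptive RK45
  (Dormand–Prince) at `rtol 10⁻⁸ / atol 10⁻¹⁰`, called over geometrically
  growing multi-checkpoint chunks (32 → 4096 checkpoints) with dense output
  at the checkpoint grid. The live state is floor-clamped at chunk
  boundaries, sampled states at every checkpoint. Trajectory storage is
  optional so that long runs stay cheap in memory.
* **Reduced system** (`tniche._reduced`): clones with identical parameters
  and identical initial conditions remain identical under the dynamics, so
  grouping clones into classes `g` of size `N_g` collapses the system to
  `2G ≤ 6` equations with niche denominators
  `D_g = s_h h_g + s_p z_g + u_h H + u_p Z` and capacity ratios
  `φ = v p (s/D_g + u S)`, `S = Σ_g N_g/D_g`. A numba-compiled
  Dormand–Prince 5(4) stepper with the same tolerances integrates one such
  system per parameter set; checkpoints are evaluated by cubic Hermite
  interpolation inside accepted steps (step size capped at 64 check
  intervals, keeping the interpolation error ~10⁻⁸ relative — two orders
  below the convergence criterion), and the same floor/criterion logic is
  applied.

The reduction is exact, not approximate; agreement of the two paths (~10⁻⁶
relative on steady-state totals over random screen points) is enforced by
tests and serves as the correctness oracle for both. The reduced path is
what makes the ≈2×10⁵-run screen take minutes on a single core.

## Screen and classification

Fold-changes are exact powers of 1.2 centered on 1 (41 values per
parameter, `1.2^±20 ≈ 1/38.3 … 38.3`); 20% spacing with 41 values fixes the
grid up to an anchor, and 1.0 is the only natural anchor. Classification
compares the converged state against the physiological reference total
`v_h Σ_j p_j`: monoclonal *premalignant* means total ≥ 300% of reference
and preleukemic fraction ≥ 80%; polyclonal *controlled* means total ≤ 120%
and fraction ≤ 50%. "At least/at most" are read as inclusive bounds. An
empty final state has preleukemic fraction 0 by convention (trivially
controlled, never premalignant). *Consistent* = premalignant (mono) AND
controlled (poly).

## Analysis conventions

"Decreased"/"increased" for fold-changes use strict comparison against 1
(the grid contains exactly 1.0, which counts as neither). Octant membership
is the sign pattern of `(log s_fold, log u_fold, log v_fold)`. The relation
between `u_fold` and `v_fold` over consistent sets is summarized as a
minimal enclosing parallel band in log–log space: the common slope is a
least-squares fit through the midpoint of the `log u` range at each distinct
`v_fold`, and the two intercepts are pushed out to cover every point. The
band is descriptive, not inferential — no fitting procedure is implied by
the underlying observation that the points lie between two parallel lines.

## Design choices where the design was open

* The length of a "time step" is not physically defined; the checkpoint
  interval is fixed at 1 h and the physiological perturbation experiment is
  read as 400 h with the kill at 200 h. Steady-state classifications are
  invariant to this unit choice.
* Polyclonal P1 distributes the 499 healthy cells over *all* 100 healthy
  species, including the sibling of the preleukemic clone.
* `run_screen` parallelizes through the compiled kernel's thread pool
  (`--workers`); per-record failure isolation applies to the single-run
  API, while the batched kernel reports numerical trouble through the
  non-convergence flag (it has no failure mode that aborts the sweep).
* Screen part files are written per (s_h, scenario) block; `--resume`
  reloads finished blocks.

## Problem sizes used by the shipped tests

The test suite runs the complete default screen (3 scenarios × 41³ fold
triples, s_h = 1), the two full variant screens at s_h = 0.2 and 5, a
200-point random reduced-vs-full cross-check at the full 200-species size,
and the physiological perturbation runs — all at the model's native scale;
nothing is scaled down. Toy grids (3³) appear only in interface tests.

## Known limitations

* The niche-per-clone pairing (`n = q`) is built into the affinity
  construction; heterogeneous niche supplies are accepted by the model core
  but unexplored, and the reduced fast path requires a constant `p`.
* Deterministic ODE dynamics cannot capture extinction/fixation noise at
  1–10 cells, exactly where scenarios P1 and P10 start; results describe
  mean-field behavior.
* Only proportional cell-kill perturbations are implemented; niche
  addition/removal events are out of scope.
* The classification thresholds are part of the question being asked, not
  fitted quantities; conclusions inherit their arbitrariness.
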