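# Methods

## Model and assumptions

The model tracks one locus with two alleles, a driving haplotype (Ab10) and
the wild type (N10), in an infinite, monoecious, randomly mating population
with discrete non-overlapping generations. The state is the pair of driver
frequencies in the two gamete pools, `p_f` (ovules) and `p_m` (pollen);
census is taken in the gametes, so heterozygote frequency after random union
is `p_f q_m + p_m q_f` rather than the one-sex Hardy–Weinberg `2pq`.

Fitness acts multiplicatively through four components, each with its own
homozygous cost and dominance:

| symbol | acts on | carrier |
|---|---|---|
| `f`, `h_f` | ovule number (female fecundity) | maternal genotype |
| `s`, `h_s` | seed viability via seed size | maternal genotype |
| `m`, `h_m` | pollen viability/competitiveness | paternal genotype |
| `v`, `h` | seed-to-flowering survival | offspring genotype |

Drive `d` biases transmission only through ovules of heterozygotes, which
pass the driver at rate `(1+d)/2`. Pollen transmission is Mendelian. The
one-generation recursion normalizes each pool by its mean fitness `W_f`,
`W_m`; the map is undefined (raises `DegenerateNormalizerError`) only when a
normalizer vanishes, which requires a boundary state combined with a
complete cost.

Deliberate simplifications: no drift, mutation, migration, inbreeding,
sex-specific populations, or linked modifiers; all nine parameters constant
in time; `d` treated as a free parameter up to the mechanistic ceiling.

## Boundary analysis

Linearizing the two-dimensional map at each fixation gives closed-form
leading eigenvalues `lambda0` (driver rare) and `lambda1` (wild type rare);
see the README for the expressions. `lambda1` is reported as `inf` when the
resident Ab10 population is inviable or sterile (`v`, `f`, `s`, or `m`
equal to 1), since a rare wild-type allele then invades trivially.

The four-way classification (`N10_FIXATION`, `AB10_FIXATION`, `BISTABLE`,
`PROTECTED_POLYMORPHISM`) comes from the sign pattern of
`(lambda0 − 1, lambda1 − 1)` with a tie tolerance of `1e-12`; values within
tolerance of 1 are treated as ≤ 1, so exact neutrality classifies as loss of
the driver rather than polymorphism.

The closed forms are validated against a numerical Jacobian built by
**complex-step differentiation** (`eps = 1e-100`) of the un-clamped
recursion. Complex-step has no subtractive cancellation, so the oracle is
accurate to machine precision even at the Ab10 fixation, where central
differences lose up to ~1e-3 of relative accuracy when the resident weights
are small. The test suite requires agreement to `1e-8` over 1000 random
parameter draws.

`boundary_curve` inverts `lambda = 1` for the fecundity cost `f` at fixed
drive by bracketed bisection (`scipy.optimize.brentq`, tolerance `1e-10`),
returning `NaN` where the eigenvalue does not cross 1 on `f ∈ [0, 1]`.

## Interior equilibria

Fixed points satisfy two polynomial residuals (mean fitnesses are strictly
positive in the open unit square, so clearing denominators is safe): one
quadratic in `p_f` and linear in `p_m`, the other linear in `p_f` and
quadratic in `p_m`. Two independent solvers are provided:

- **Multi-start damped Newton** (`method="newton"`, the default): a 21×21
  interior grid of starts (`np.linspace(0, 1, 23)[1:-1]`), analytic
  Jacobian, step-halving damping, up to 60 iterations. Roots are accepted
  if the map residual is below `1e-11`, kept if at least `1e-6` from the
  boundary, and deduplicated at radius `1e-6`. Batched, vectorized over
  draws × starts for Monte-Carlo use.
- **Quintic elimination** (`method="elimination"`): solving the linear
  residual for `p_f` and substituting into the other yields a degree-5
  polynomial in `p_m` whose real roots in (0, 1) are found with `np.roots`
  and polished by Newton. This is exhaustive by construction (all interior
  fixed points are among the five roots) and ~300× faster per draw, so it
  backs the coverage statistics; a sympy resultant serves as an independent
  symbolic oracle in the tests. Degenerate parameter corners where the
  elimination collapses raise `DegenerateParametersError`.

The two methods agree on every non-degenerate draw tested (150 random
draws, plus 20 000 draws confirming at most 3 interior equilibria).
Equilibrium stability is classified from the spectral radius of the exact
Jacobian with a margin of `1e-9` (stable / unstable / saddle /
indeterminate).

`global_outcome` iterates the map from a five-point start battery to tol
`1e-12`, detects period-2 cycles (one-step delta above tolerance while the
two-step delta stays below it for 100 consecutive generations), classifies
attractors with a corner tolerance of `1e-5`, and flags agreement with the
eigenvalue prediction.

## Monte-Carlo sweeps

Seven sampling scenarios share a fixed draw order (drive first, then the
four costs, then dominances) so results are reproducible from a single
seed: `general` (all nine parameters uniform on [0, 1]), `weak_selection`
(costs uniform on [0, 0.1]), `constant_dominance` (one shared random
dominance), `recessive` / `additive` / `dominant` (shared dominance fixed
at 0, 0.5, 1), and `actual_drive` (`d` uniform on [0.2, 0.6]). Outcome
percentages use the closed-form eigenvalues, vectorized; equilibrium counts
use the batch solvers above, chunked at 2000 draws to bound memory.

Sample sizes in `scripts/acceptance.py` are the package's own accuracy
choices: 1e5 draws put the three-standard-error band at roughly ±0.2
percentage points for mid-range fractions; the dominant scenario uses 5e5
because its invasion fraction is ~0.1% and needs the extra resolution; the
Newton enumeration uses 2e4 draws (~20 ms/draw) to stay within a modest
CPU budget.

## Applied analyses

Three presets encode published empirical cost estimates: `maize_solid`
(maize, no offspring-survival cost), `maize_dashed` (adds `v = 0.3`,
`h = 0.238`), and `mimulus` (the *Mimulus guttatus* D driver, `d = 0.16`).

`equilibrium_curve` iterates to the attractor along a drive grid and reports
the equilibrium gamete frequencies plus the **adult census**: genotype
frequencies among flowering plants, i.e. zygote frequencies reweighted by
the survival-relevant components `(1−s)(1−v)` / `(1−h_s s)(1−h v)` / 1 and
renormalized. Fecundity components (`f`, `m`) act after flowering and are
excluded; this is the quantity comparable to field surveys of adult plants.

`drive_window` finds the drive interval on which the driver persists
polymorphically, by two deliberately different routes reported side by
side: root-finding on `lambda0 = 1` and `lambda1 = 1` (`brentq`,
`xtol = 1e-6`), and a global scan that iterates the full dynamics on a grid
(default step 0.002 up to the mechanistic cap 2/3) with boolean bisection
refinement of the edges. For the maize presets the two agree to well under
0.01 in `d`. Any previously published threshold values are not used as
targets; the window is recomputed from the model, and the tests only demand
that the two independent methods agree with each other.

The mechanistic ceiling on drive comes from meiosis geometry:
`max_transmission(p_mii, e) = p_mii·e + (1 − p_mii)/2`, and with the
observed 2/3 of segregation patterns susceptible to neocentromere activity
and complete preferential segregation this gives 5/6 transmission, i.e.
`d = 2/3`.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds stay below 2^31.
- Iteration tolerance `1e-12` on the max-norm one-step delta; generation
  cap 1e6.
- CSV output uses `%.12g` so round-tripped files are byte-stable; every CLI
  artifact gets a JSON manifest with the exact configuration and seed.

## Limitations

- The eigenvalue classification is local; with multiple interior equilibria
  (< 0.7% of draws in the worst scenario) the global outcome can differ
  from the boundary prediction, which is why `global_outcome` carries an
  explicit agreement flag.
- Degenerate corners (complete costs at fixation) are surfaced as
  exceptions rather than silently regularized.
- Near-transcritical parameters (`|lambda − 1|` within roundoff) make the
  discrete outcome label sensitive to the `1e-12` tie rule; quantitative
  conclusions should use the eigenvalues themselves there.
- Period-2 cycle detection covers the only non-convergent behavior observed;
  longer cycles or chaos, if present elsewhere in parameter space, would
  exhaust the generation cap and be reported as non-converged rather than
  misclassified.
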