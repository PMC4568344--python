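# Methods

## The model

`gradewalk` implements a per-step potential-energy model of human gradient
walking. Walking alternates between double support (both feet down, centre
of mass at its lowest) and single support (one straight leg, centre of mass
at its highest). For a leg of length *l* and a step length *l*/*k* (the
dimensionless step parameter *k* is leg length over step length), the joint
height in double support follows from a right triangle with the leg as
hypotenuse and the half step *l*/2*k* as base:

    y' = l √(1 − 1/(4k²)),    Δy = l − y' = l (1 − √(1 − 1/(4k²)))

Raising the centre of mass by Δy every step costs

    ΔU_osc = m g Δy

On a gradient *i* (rise over run, negative downhill) a step additionally
changes height by dy = i·dx with horizontal projection
dx = (*l*/*k*)/√(1+i²), so

    ΔU_grad = m g i (l/k) / √(1+i²)

The balance U_tot = ΔU_osc + ΔU_grad is converted to a positive energy
requirement by a piecewise braking-efficiency rule: positive balances are
paid in full by positive muscular work, while a negative balance (surplus
energy gained on a descent) must be absorbed by braking (negative) work,
which is about five times cheaper per joule:

    ε = U_tot            if U_tot > 0
    ε = −U_tot / 5       if U_tot < 0

Both branches vanish at U_tot = 0, so ε is continuous, non-negative, and
V-shaped in *i* with a zero minimum at the gradient where the descent
exactly pays for the lift.

### Assumptions

- **Kinetic energy is ignored.** At ~1.25 m/s the centre of mass fluctuates
  by only ~0.1 m/s per step, so the kinetic energy actually re-supplied
  (~0.12 J·kg⁻¹ per step) is several times smaller than the potential
  oscillation (0.78–0.98 J·kg⁻¹ for an 8–10 cm excursion). The
  `magnitudes` module recomputes this comparison; across the observed
  fluctuation range the PE/KE ratio spans roughly 3.5–9, i.e. potential
  energy dominates, though the extreme corner (largest fluctuation,
  smallest oscillation) dips just below the often-quoted 5×.
- **Step-phase timing on gradients is ignored.** Whether the centre-of-mass
  rise happens earlier or later in the step does not change the per-step
  height budget.
- **No physiology.** ε is a mechanical potential-energy requirement per
  step, not a metabolic rate; the zero minimum at the optimum is the
  model's idealization (real walkers still pay basal and swing costs).

## The optimal gradient

Setting U_tot = 0 gives (i/k)/√(1+i²) + (1 − √(1 − 1/(4k²))) = 0. Since
|i| ≲ 0.13 at the optimum, √(1+i²) ≈ 1 and the closed form follows:

    i(k) = k √(1 − 1/(4k²)) − k = √(k² − ¼) − k

which is negative for every k ≥ ½ and strictly increasing in k: long steps
(k ≈ 1.1) are optimal near −12%, short steps (k ≈ 1.5) near −8.6%, and the
comfortable midpoint k = 1.35 gives −9.6% ≈ −10%, the classic experimental
optimum. Three solvers are provided and cross-checked:

1. **closed form** — the expression above;
2. **exact root** — Brent root-finding of the un-approximated balance on
   the bracket (−0.5+10⁻⁹, −10⁻¹²). The un-approximated root also has the
   analytic form i = −c/√(1−c²) with c = k − √(k²−¼), which the tests use
   as an independent oracle. For k within ~0.003 of the geometric limit
   0.5 that root falls below −0.5, outside the bracket; the solver raises
   a clear error there rather than returning a wrong sign-change;
3. **numeric argmin** — a brute-force grid scan of the ε curve (default
   10 001 points) refined by bounded scalar minimization (xatol 10⁻⁷),
   fully independent of the analytic route. An argmin on the grid boundary
   is returned with a warning rather than refined.

Over the comfortable band k ∈ [1.0, 1.6] the closed form and exact root
differ by at most 0.003 (fraction units; ~0.12 percentage points at k = 1),
quantifying how little the dropped √(1+i²) costs. The numeric argmin lands
on the exact root to ~10⁻⁵.

### Step-length strategy

Squaring √(k²−¼) = k + i inverts the closed form exactly:

    k(i) = −(¼ + i²)/(2i),   i ∈ (−0.5, 0)

This inverse is an implementation derivation (the forward closed form is
the model's contribution; its algebraic inverse follows from it) and
round-trips with the forward map to 10⁻¹⁰. `recommend_step_length` maps a
route gradient to the step length that zeroes ε, flags it against the
comfortable range k = 1.35 ± 0.20 (i.e. [1.15, 1.55]; the alternative
bounds [1.10, 1.50] quoted for the strategy discussion are exposed as
`COMFORT_K_RANGE_ALT`), and clamps to the nearest comfortable k when
outside. Beyond about −13% the optimal step exceeds the leg length (k < 1)
and the advice says so. Uphill/level gradients have no
oscillation-cancelling optimum; the function returns a structured
no-optimum result instead of raising, so route sweeps degrade gracefully.

## Parameters, units, defaults

| parameter | unit | default | why |
|---|---|---|---|
| mass m | kg | 1 | per-unit-mass energies; ε scales linearly in m |
| leg length l | m | 0.9 | typical adult; the worked step-length range 60–80 cm assumes it |
| step parameter k | — | 1.35 | midpoint of the comfortable range 1.35 ± 0.20 |
| gradient i | fraction | — | CLI reads/prints percent by default (`--fraction` overrides) |
| efficiency factor | — | 5 | braking ≈ 4–5× cheaper than positive work; configurable |
| g | m·s⁻² | 9.81 | standard gravity; configurable for what-ifs |

k ≥ 0.5 is enforced as a hard domain bound (below it the step triangle
cannot close); values outside [1.15, 1.55] only warn
(`ComfortRangeWarning`), since the mathematics is still valid.

## Numerical choices

- U_tot = 0 maps to ε = 0; both branches agree there, so no tie-break is
  needed, but the contract states it.
- Δy is computed as l − y′, never (y0+l) − (y0+y′), so it is bit-identical
  across trunk offsets and gradients.
- Root bracket (−0.5+10⁻⁹, −10⁻¹²): the closed-form optimum lies in
  (−0.5, 0) for all k > 0.5, and the exact root does too for all
  k > 0.5032.
- Sweep CSV bodies carry 12 significant digits so that write→read
  round-trips to 10⁻¹⁰; every table echoes m, l, g, the efficiency factor
  and the grid in its metadata, because the curves' absolute scale is
  meaningless without them.
- The ε-vs-gradient table emits joules per step for the configured mass
  (per-unit-mass when m = 1, the default).

## Synthetic cohorts

`generate_cohort` draws leg lengths uniformly from 0.75–1.00 m (adult
range) and k uniformly from the comfortable range [1.15, 1.55], from a
single named `numpy` generator seeded by the caller. It emulates
between-subject anthropometric spread only — no within-subject step
variability, no speed, no fatigue — so passing cohort tests demonstrates
that the solvers are well-behaved across realistic parameter ranges, not
that the model predicts any individual's metabolic data.

## Known limitations

- The geometric oscillation Δy at l = 0.9 m, k = 1.35 is 6.4 cm, while
  direct observations put the centre-of-mass excursion at 8–10 cm. The
  model follows its own geometry; the magnitude module accepts the
  observed amplitudes directly. The discrepancy means absolute ε values
  at default parameters are conservative.
- The ε curve's absolute scale depends on m and l, which the characteristic
  plots do not pin down; sweep tables are therefore validated on shape
  (V-form, zero minimum, minimum location) rather than absolute axis
  values.
- Only mechanical potential energy is modelled: no metabolic baseline, no
  kinetic term, no speed dependence, no age effects, no timing
  adaptations.

## Problem sizes

Grid sizes default to 601 points for cost-vs-gradient tables and 10 001
points for the numeric argmin; the property suite scans 10⁴-point grids.
These resolve the optimum to ~10⁻⁴ before refinement and keep the full
test suite and the acceptance script each well under a minute on one CPU.
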