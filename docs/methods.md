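# Methods

## The model

`crowdcell` asks a physiological question: what cytosolic volume occupancy
`rho` — the fraction of cytosol volume filled by dry mass — lets a
bacterial cell grow fastest?  Packing more catalysts and substrates into
the cytosol raises encounter rates and enzyme saturation, but the
resulting macromolecular crowding slows diffusion and perturbs binding
equilibria.  The package implements this tradeoff in three layers.

### Crowding-adjusted kinetics

Each catalytic reaction is split into a diffusive encounter step and a
reversible binding/conversion step.  Crowding enters the effective
Michaelis parameter

    KM* = KM0 * (Gamma + theta * exp(-g rho)) /
                ((1 + theta) * Gamma * exp(-g rho)),

the convex time-additivity combination of the two sub-step rate laws:
weight `theta/(1+theta)` on the transition-state-limited Michaelis
parameter `KM0 / Gamma` and `1/(1+theta)` on the diffusion-limited one
`KM0 * exp(g rho)`.  It satisfies all limiting behaviours at once:
`KM* = KM0` at `rho = 0`, `KM0 * exp(g rho)` at `theta = 0`, and
`KM0 / Gamma` as `theta -> infinity`.  `kcat` is assumed crowding-
independent (irreversible kinetics, no structural perturbation of the
active site).

**Diffusion slowdown.**  `g(r_S)` comes from the empirical size-dependent
slowdown law for the bacterial cytosol,
`ln(D0/Dcyto) = (xi^2/R^2 + xi^2/r_h^2)^(-a/2)` with `xi = 0.51 nm`
(mean crowder surface separation), `R = 42 nm` (largest common crowders),
`a = 0.53`, and hydrodynamic radius `r_h = 1.3 (r + 0.14 nm)`.  Dividing
by the reference occupancy 0.22 at which the law was calibrated converts
it into the exponent of `exp(-g rho)`.  Only the substrate's size enters:
the substrate is the faster-diffusing partner, and its diffusion
coefficient dominates the encounter rate.  The exponential form is an
extrapolation; it degrades near `rho -> 1`, which is why scans stop at
0.8.

**Gibbs perturbation.**  `Gamma = gamma_S * gamma_E / gamma_ES` with
scaled-particle-theory (SPT) activity coefficients of hard spheres in the
current mixture,

    ln gamma_i = -ln(1-<<V>>)
               + (r_i <<S>> + S_i <<r>> + V_i <<1>>) / (1-<<V>>)
               + (r_i^2 <<S>>^2 + 2 V_i <<r>> <<S>>) / (2 (1-<<V>>)^2)
               + V_i <<r>>_2 <<S>>^2 / (3 (1-<<V>>)^3),

where `<<X>> = sum_j w_j X_j` are number-density-weighted moments over
all crowding species.  This is the hard-sphere-mixture excess chemical
potential of SPT (equivalently, the Percus-Yevick compressibility route),
re-derived here from the insertion-work form to fix the term grouping;
the Widom-insertion Monte-Carlo test in `tests/test_acceptance.py` is the
independent check (SPT is exact to within ~1% of simulation at the
occupancies used).  Complexes are volume-additive spheres,
`r_ES = (r_E^3 + r_S^3)^(1/3)`, and crowd as single particles — which is
why `Gamma > 1`: two separate spheres exclude more volume than their
fused complex, so crowding favours binding.

**Self-consistency.**  `KM*` depends on the free/bound composition and
vice versa.  The solver iterates: given `KM*`, the complex concentration
is the exact root of the binding quadratic
`ES = E_tot * S_free / (S_free + KM*)`, `S_free = S_tot - ES` (mass
conservation holds exactly at every step); given the composition, the
mixture moments give `Gamma` and hence a new `KM*`.  Iteration stops when
every `KM*` changes by less than 1e-5 relative (0.001%), with a 0.5
damping step if the complex update oscillates.  Using the quadratic root
instead of plain substitution for the inner update leaves the fixed point
unchanged but converges unconditionally when catalyst is abundant.

### Pathway models

A linear chain of N identical reactions at steady state (a coarse-grained
metabolic pathway) collapses to one reaction with rescaled parameters:
per-reaction concentrations `[s]/N`, `[E]/N`, pathway flux
`v = (kcat/N) [s][E] / (N KM* + [s])`, and growth proxy `mu = v / rho`.
A parallel N-reaction system (one ribosome per anticodon) has the same
mathematics with `mu` multiplied by N.  Two size presets:

| preset     | substrate r (nm) | catalyst r (nm) | interpretation        |
|------------|------------------|-----------------|-----------------------|
| metabolic  | 0.34             | 2.4             | metabolite + enzyme   |
| ribosomal  | 2.4              | 13              | ternary complex + ribosome |

Defaults `kcat = 1/s` (pure scale factor), `KM0 = 130 uM` (median for
metabolic enzymes, close to the ribosome's 120 uM), `theta = 2.3` (the
only available experimental estimate, from a MAP-kinase phosphorylation
reaction; a 4.6 variant probes the sensitivity).

Scans tabulate `mu` (or total flux) over occupancies 0.01..0.80 in steps
of 0.01, refined to 0.001 on 0.100..0.360, and over the substrate share
of occupied volume from 0.1% to 97.7% in geometric steps of 1.0023.  The
reported curve is the per-rho envelope (objective maximized over the
share); ties break toward smaller rho.  A grid point maps to
concentrations via `n_s = f rho / V_s`, `n_E = (1-f) rho / V_E` — the
share is read as a fraction of *occupied* volume.

### Whole-cell model

Five concentrations span the solution space: metabolic intermediates
`[s]`, precursor `[p]` (charged-tRNA-like, r = 2.4 nm), transporter `[T]`
(membrane-bound: excluded from crowding and from rho), metabolic enzymes
`[M]` (r = 2.4 nm, N lumped reactions, kcat = 13.7/s, KM0 = 130 uM), and
ribosomes `[R]` (r = 13 nm, kcat = 22/s, KM0 = 120 uM).  Protein costs:
300 precursors per transporter or enzyme, 7459 per ribosome.  Balanced
growth at rate `mu = v_R / (l_T [T] + l_M [M] + l_R [R])` requires
production to offset consumption plus dilution for s and p.  Both
crowding-adjusted reactions see one shared mixture (free s, free M, Ms
complexes, free p, free R, Rp complex), and `exp(-g rho)` uses the total
occupied fraction of that mixture.

At each occupancy the growth rate is maximized subject to the two balance
equations and `rho(state) = rho_target` (equality) by multi-start SLSQP
in log-concentration space: a crowding-unaware warm start (deterministic
sector-split composition plus random log-uniform points in 1e-6..1e5 uM),
then >= 20 SLSQP runs of the crowding-adjusted model from log-normal
perturbations (sigma = 0.4) of the warm start.  Hard variable bounds are
deliberately wide (1e-6..1e9 uM): optimal states hold molar-range
metabolite pools whose volume cost is tiny, and a tight upper bound would
cap metabolic saturation independently of rho and destroy the density
tradeoff.  Every candidate is polished by a Newton projection (root-solve
of the three constraints over T, M, R at fixed s, p) so reported
residuals are at machine precision, well inside the 1e-9 relative
feasibility gate.  Occupancy scans warm-start each grid point from its
neighbour (continuation) in addition to the random restarts; ties break
toward smaller rho.

### Density conversion

Dry mass is treated as a protein/RNA two-component mixture: specific
density `D(r) = 1.35/(1+r) + rho_RNA * r/(1+r)` g/mL with the RNA density
1.81 g/mL derived from the ribosome (1.637 g/mL, 61.87% RNA by linear
mass-fraction mixing), and occupancy `rho = rho_DM / D(r)`.  The
RNA/protein ratio comes from the linear growth law
`r = 0.087 + mu/4.5 h^-1` or from a user-supplied interpolation table.

## Problem sizes

The pathway scans run the full grids above (~10^6 grid points,
vectorized; seconds).  The whole-cell occupancy scans use a 0.01 grid on
[0.05, 0.45] refined to 0.002 within +-0.015 of the coarse optimum, 20
restarts per point; the (N, s_ext) map behind the qualitative trend and
correlation checks uses a 0.02 grid refined to 0.005 with 4 restarts per
point — at these resolutions the located optima are stable to well below
the quoted differences.  The Widom oracle uses 512 spheres, ~1.2e5
insertions per case, with batch-level standard errors.

## What the tests do and do not show

All inputs are the printed parameter sets; there is no external data.
The Monte-Carlo gate validates the SPT formula, not the hard-sphere
idealization itself; real macromolecules are neither spherical nor inert,
`theta` is a single-reaction estimate applied to all reactions, and the
diffusion law is an extrapolation fitted to simulations of one cytosol
model.  Passing tests therefore show internal consistency with the
published model, not quantitative truth about any real cell.

## Known limitations

* The five printed pathway quantities (optima 0.30 / 0.12 / 0.21 and
  half-occupancy losses 21% / 1.3%) are reproduced to within the grid
  resolution.  The whole-cell layer reproduces every qualitative
  contract — the interior optimum exists only with crowding, rho_opt
  rises with N and falls with nutrient, mu(rho) is flat (~1.6% / ~3.5%
  loss at half / double occupancy vs the printed 1.1% / 3%), and the
  ribosomal KM* tracks rho_opt (Spearman ~0.99) while the metabolic KM*
  does not — but its absolute optima sit a uniform ~20% below the
  printed values (0.20 / 0.19 / 0.17 vs 0.250 / 0.234 / 0.204).
  Structural variants (macromolecule-only diffusion occupancy,
  per-sector crowding backgrounds, the alternative parenthesization of
  the combined rate law, tight concentration bounds) were each tested
  and make the agreement worse or destroy qualitative contracts; and any
  rescaling of the shared kinetics that lifted the whole-cell optima
  would shift the pathway optima off their matched values by the same
  factor.  The gap is therefore specific to the whole-cell optimization
  layer and is documented rather than tuned away.
* The growth-rate surface is extremely flat near its optimum (<0.1%
  variation over +-0.05 in rho), so argmax locations are intrinsically
  ill-conditioned; ratio quantities evaluated at the optimum inherit
  that width.  This is a property of the model, not of the solver.
* Intermediate metabolite dilution is treated through the lumped total
  only; free tRNA is not modelled; all reactions within a sector share
  identical kinetics and sizes.
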