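# Methods

This note records the models implemented in `fluxdesign`, the defaults
and their rationale, the numerical choices, and what the bundled toy
systems do and do not demonstrate.

## Network model and flux parametrization

A network is metabolites (name, carbon count, balanced flag) plus
reactions with per-carbon atom transitions in letter notation
(`A#ab + B#c -> C#abc`); the atom map must be a bijection between educt
and product carbons. Balanced pools contribute mass-balance rows to the
stoichiometric system; measured extracellular rates are appended as
equality rows, treated as exact (the weighting of uncertain rate
measurements is deliberately out of scope — they would otherwise have to
enter the information matrix as data, not constraints).

The steady-state flux space is parametrized by free net fluxes: the
kernel of the combined equality system, with coordinates chosen greedily
— caller-preferred reactions first, then declaration order, keeping a
reaction whenever it enlarges the rank of the selected kernel rows. The
choice is non-unique in principle; the greedy pivoted rule makes runs
reproducible. Singular values below 1e-10 of the largest count as zero.
Each reversible reaction adds one nonnegative exchange flux;
unidirectional rates are `fwd = xch + max(net, 0)`,
`bwd = xch + max(−net, 0)`. A reversible reaction with zero exchange
behaves exactly like an irreversible one at the design point.

## Labeling simulation

The cumomer framework is used rather than EMU: measurement groups are
arbitrary nonnegative linear functionals over isotopomer space (tandem-MS
joint precursor/fragment indicators, NMR positional rows, IRMS total
enrichment), which cumomer states support exactly; EMU would be an
optimization, not a generalization, here. The level-`w` cumomer balance
of every balanced pool is linear given levels `< w` and the input
patterns; each level is solved directly (LAPACK `solve`) with a residual
check at 1e-10. Isotopomer fractions are recovered by Moebius inversion
over the subset lattice.

Tracer species are described by a 0/1 labeling pattern and a purity `q`:
designed-labeled positions carry the heavy isotope independently with
probability `q`, other positions with probability 0. Natural ¹³C
abundance is not modelled (it affects real spectra correction, not the
design-stage information comparison). Mixtures are simplex-constrained
and enter linearly, which the test suite exploits as an invariant.

Sensitivities `∂η/∂v_free` are central finite differences with step
`1e-6 · max(1, |v_i|)`, falling back to one-sided differences with a
warning at constraint boundaries. An analytic implicit-function Jacobian
would be faster but adds nothing at desk scale; the finite-difference
route doubles as the reference any analytic path would have to match.

## Measurements and error models

A measurement group is the jointly acquired, jointly normalized block of
one analyte on one device. Normalized groups are scaled to unit sum
*before* anything downstream sees them — sensitivities and error models
operate on the normalized (percentage-scale) prediction. Standard
deviations follow the linear device model `σ = a(n)·(b1·η + b2)` with
`b1 ≥ 0, b2 > 0` consumed as configuration (fitting them to literature
data is out of scope). The replicate factor defaults to the jackknife-style
`a(n) = sqrt(n/(n−1))` for `n ≥ 2`, capped at `a(1) = 2`: it is ≥ 1,
non-increasing, tends to 1 for many repeats, and expresses that a
single-replicate error estimate is unreliable. The exact published form
of `a` is not available; the scheme is configurable (`"none"` disables
it, a callable replaces it), and the toy fixtures use `"none"` so their
hand-derived standard deviations are exact.

The covariance of the measurement vector is `diag(σ²)`. The Fisher
information uses the *inverse* covariance, `FIM = Jᵀ diag(σ⁻²) J` —
the printed form without the inverse would make noisier measurements more
informative, which is dimensionally untenable.

## Identifiability and criteria

The FIM passes if `λ_min > τ1 · max(λ_max, 1)` and
`cond(FIM) < τ2`, with defaults `τ1 = 1e-9`, `τ2 = 1e12`. The `max(·, 1)`
floor matters: a FIM built from pure finite-difference noise can be 1×1
with `λ_min = λ_max`, which a purely relative threshold would accept.
On failure the worst-determined free flux is frozen at its nominal value
and the test repeats. "Worst determined" is variance-based: fluxes
participating in the near-null eigenspace of the FIM (effectively
infinite variance) rank first; otherwise the largest diagonal entry of
the inverse decides. `p = 0` is a valid outcome, scored with zero
information and the design's actual cost so dominance disposes of it.

`Φ_D` is reported as `det(Cov)^(1/2p)` — the geometric mean of the flux
standard deviations, so it lives on flux-sd scale regardless of `p`.
Objective vectors are all-maximize: `(p, 1/Φ_D, −cost)` or
`(p, 1/Φ_D, 1/Φ_A, 1/Φ_E, −cost)`. Criteria are only comparable across
designs at equal `p`; the archive stores `p` explicitly and the analysis
layer filters on it. No affine rescaling is applied to reported criterion
values; any presentation scaling is left to the caller.

## Cost model

Per experiment: `substrate_mass · (x_inpᵀ·prices) + C_exp +
t_work_exp·C_work` on the experimental side and `n_samples·C_sample +
(Σ n_rep·n_peaks)·t_work_ana·C_work` on the analytical side. The
substrate term scales with fed substrate mass (default 5 g: a 250 mL
culture at 20 g/L); instrument depreciation is folded into `C_sample`;
`n_samples` is a per-experiment constant that also bounds replicate
counts (default 10). Default glucose prices carry the two documented
bounds — 0.30 EUR/g unlabeled, 1293.00 EUR/g [5-¹³C] — with intermediate
species set once to market-plausible values; all prices are plain
configuration. Modelling/analysis labor beyond peak evaluation is not
costed.

## Design space and search

A design is, per parallel experiment, the mixture fractions plus
per-group replicate counts. The swarm works on the continuous relaxation;
repair divides fraction blocks by their sum (preserving proportions — an
all-zero block becomes uniform) and rounds replicates half-up, and the
*rounded* design is what gets evaluated and archived, so every archive
entry is an executable protocol. Group inclusion is simply `n_rep ≥ 1`.

The SMPSO implementation uses the standard constriction coefficient with
acceleration constants drawn in U(1.5, 2.5), velocity clamped to half the
variable range and damped by 0.001 at bound hits, polynomial mutation
(distribution index 20, per-variable rate 1/d) on 15% of particles,
personal bests replaced unless strictly dominated, leaders drawn from the
bounded archive by binary crowding-distance tournament, and boundary
archive members protected from truncation (infinite crowding distance).
Defaults: swarm 100, 250 iterations, archive capacity 100. All
randomness flows from a single seeded generator; a fixed seed reproduces
archives bitwise. An exhaustive-grid evaluator (guarded at 1e6 points)
provides the exact front on discretized toy problems for validation.

## Analysis layer

Mixture clustering: feature vector = composition fractions, information
value, total cost, each min-max scaled to [0, 1]; Euclidean distance with
average linkage; cut by cluster count or distance threshold. Components
below 1% of a mixture are suppressed in displays. Robustness sampling
draws flux vectors uniformly in the axis-aligned bounding box of the
confidence ellipsoid (half-widths `z·sqrt(diag Cov)`, default `z = 1.96`
as no confidence level is prescribed), rejects infeasible draws, and
re-evaluates `Φ_D` on the *fixed* retained flux set so the criterion
dimension stays comparable. Exports are flat CSV tables; chord and
ternary diagrams themselves are drawn by external tools (e.g. Circos)
from the link tables, with objective coordinates min-max scaled to
0–100% and mixture-proportion histograms in 5%-wide bins.

## Toy systems and what they show

`chain` (labeling flux-independent), `branch` (order-preserving vs
carbon-swapping routes: positional data read the split ratio, the MID is
blind) and `cycle` (a reversible scrambling step whose exchange is
visible only to asymmetric tracers) are deterministic constructions with
hand-derivable oracles, built so the classic positional-vs-mass
information contrast is a built-in sanity check. Their tracer purities
are exactly 1 so closed-form expectations hold to machine precision.
They are desk-scale: passing tests demonstrate correctness of the
machinery, not performance or identifiability structure on genome-scale
networks, where measurement redundancy, compartmentation and larger
cascades dominate. The problem sizes used throughout the suite (networks
of 3–5 pools, swarms of 40–60 particles, 40–60 iterations, robustness
n = 1000 vs 10000) were chosen as the smallest at which each property is
non-trivially exercised.

## Known limitations

Isotopically non-stationary labeling, natural-abundance correction, flux
estimation from real data, FBA/thermodynamic feasibility and the
optimization of the number of parallel experiments are out of scope. The
information measures are local (design-point) quantities; the robustness
sampler quantifies, but does not remove, that locality.
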