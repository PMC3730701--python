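# Methods

`ergosoup` simulates a "primordial soup" of coupled stochastic subsystems
and analyses its self-organization: the emergence of a Markov blanket, the
apparent inference of external events by internal states, and the loss of
structural integrity when parts of the blanket are functionally silenced.
This note records the model, the numerical choices, and what the shipped
defaults do and do not demonstrate.

## The ensemble model

Each of `n` subsystems carries structural states — position `x` and
velocity `v` in a 2-D Euclidean space — and three electrochemical states
`(x1, x2, x3)`. All coupling is short-range: subsystem `j` influences `i`
only when their distance is at most the coupling radius (1 length unit),
and only when `j` is functionally *open*. The binary adjacency matrix `A`
(column `j` = influences *from* `j`) is therefore a function of the
instantaneous geometry. A random third of the subsystems are *closed* at
initialization: their adjacency column is permanently zero, so they sense
and move but cannot influence anyone's functional states.

### Electrochemical flow

Each subsystem's electrochemical states follow a Lorenz system, with rate
constant `kappa_i` in (0, 1], in which the first state's *local average*
`xb1` (the mean of `x1` over the subsystem and its in-neighbours) replaces
`x1` wherever it drives the flow:

    dx1/dt = kappa_i * sigma * (x2 - x1)
    dx2/dt = kappa_i * (rho * xb1 - x2 - xb1 * x3)
    dx3/dt = kappa_i * (xb1 * x2 - beta * x3)

with `(sigma, rho, beta) = (10, 32, 8/3)`. The average enters linearly
(the Rayleigh drive `rho * xb1`) and nonlinearly (the products), which is
the classic input-substitution scheme that supports generalized
synchronization between chaotic oscillators; relative to an uncoupled
subsystem the Rayleigh parameter is effectively rescaled by `xb1/x1`,
i.e. state-dependent. Substituting only the *input* (never the own-state
damping terms) preserves the Lorenz trapping region: the quadratic terms
cancel in the energy balance exactly as in the textbook system, so the
coupled flow remains dissipative and bounded. An isolated subsystem
recovers the textbook Lorenz system.

Rate constants are `kappa_i = U^(1/4)` with `U ~ Uniform(0,1)`: the
majority of subsystems are fast (`kappa` near one) with a thin tail of
slow ones. The quarter-power is a modelling choice matching that
qualitative description; the analyses do not depend on its exact form.

### Newtonian motion

Acceleration is the sum of pair forces, viscous drag `-nu * v`, and a
quadratic potential well `-k_well * x` that keeps the soup together.
Each pair contributes, along the line between the two subsystems,

    c_rep / d^2                             (repulsion, all pairs)
    - c_att * g * [reciprocally coupled] / d  (attraction)

where `g = exp(-(x3_i - x3_j)^2 / 8)` is a coherence gate on the third
electrochemical state and "reciprocally coupled" means both subsystems are
within the coupling radius *and both are open*. Attraction is thus an
electrochemical influence carried by the coupling: subsystems bind only
when they are synchronized *and* can exchange influence in both
directions. The predicate is symmetric, so every pair force is exactly
antisymmetric (Newton's third law) and total momentum is conserved when
the well, drag and noise are off.

The reciprocity condition is the load-bearing design choice. A purely
pairwise coherence gate cannot spatially sort closed subsystems, because a
closed subsystem synchronizes perfectly well by listening one-way (we
measured coherence gates of 0.88 for closed-open contact pairs vs 0.91
for open-open in a bound cluster). Requiring reciprocal coupling makes a
closed subsystem constitutionally unable to bind — it is a purely
repulsive body — which produces the two observed phenomena this package
must reproduce: closed subsystems are rusticated to the periphery of the
soup, and lesioning (closing) any part of a blanket destroys the binding
that holds its spatial organization together.

Pairwise distances are clamped at 1e-6 length units inside the force law;
a near-collision below ten times the clamp is logged (such pairs are blown
apart by the inverse-square law, which is physical behaviour here, not an
error).

### Integration

Forward Euler–Maruyama with `dt = 1/512 s`. Unit-variance Gaussian
increments scaled by `noise_sd * sqrt(dt)` enter the velocity and
electrochemical equations (not the position equation, which is slaved to
velocity). The adjacency matrix is recomputed every step from the current
geometry. States are saved every 1 s. Identical config and seed give
bit-identical trajectories. A compiled (numba) kernel and a pure-numpy
step implement the same update; they agree to machine precision and the
numpy path is the fallback.

### Default force constants

The shipped defaults place the ensemble in the "restless soup" regime — a
cohesive jostling cluster of open subsystems, a diffuse repulsive gas of
closed (and some open) subsystems around it, no blow-ups over thousands
of seconds. They were calibrated once, by scanning the
repulsion/attraction/viscosity/well space at the reduced scale (n=64,
512 s) until the cluster bootstraps from normal initial conditions within
the run and the closed/open spatial sorting is reproducible across seeds,
and then frozen: repulsion 1.0, attraction 2.0, viscosity 4.0, well
stiffness 0.15. High viscosity is what lets the cluster nucleate in place
from the compact initial conditions instead of dispersing in an initial
"big bang"; the attraction/repulsion ratio of 2 sets the bond length near
0.7, keeping the windowed contact graph sparse enough that a majority of
subsystems remain external. At the reduced scale the closed/open radial
sorting and the sensory-lesion contrast pass with thin margins — they are
slow phenomena and 512 s of organization plus 256 s of continuation sit
near the minimum needed to establish them.

## Markov blanket recovery

The contact graph is aggregated over a trailing window (default 256 s) by
element-wise OR: a pair that touched once in the window counts as coupled,
because the adjacency process is itself ergodic under the motion noise.
The blanket matrix `B = A + A' + A'A` collects children, parents and
parents of children in its row supports (verified exhaustively against a
set-based construction for all digraphs on up to 5 nodes and on random
digraphs up to 12 nodes). Internal states are the k = 8 largest entries
of the principal eigenvector of `B` (Perron–Frobenius: nonnegative on the
dominant component; ties at rank k go to the lowest index and are
logged). `B` is symmetric as defined — `A + A'` and `A'A` both are — and
the implementation still symmetrizes `(B + B')/2` before the
eigendecomposition as a recorded no-op guard. The blanket is the support
of `B·chi` outside the internal set; blanket members with an incoming
windowed edge from an external subsystem are sensory, the rest active.
`verify_blanket` certifies the partition by listing internal-external
edges; the construction guarantees there are none whenever the partition
was produced without error, so a non-empty list indicates a corrupted
partition rather than a sampling accident.

## The dependency test (apparent inference)

Internal electrochemical series over the trailing analysis window (512 s
at full scale) are lag-embedded at plus/minus 16 s on the 1 s save grid
(33 lags per channel, valid-region rows only), summarized by the first 32
eigenvariates (SVD left vectors scaled by singular values; sign fixed by
the largest-magnitude loading), and regressed on each external
subsystem's 2-D position series by canonical variates analysis. Wilks'
lambda is transformed with Bartlett's factor,
`chi2 = -(T - 1 - (p+q+1)/2) ln(Lambda)` on `p*q` degrees of freedom; the
CVA covariance blocks carry a ridge of `1e-8 * trace/dim` because the
embedded series are strongly collinear. Positions are used as-is (no
detrending). The null flips the external series in time, preserving
within-set autocorrelation while destroying cross-coupling; the count of
true statistics exceeding the *largest* null statistic is referred to a
Binomial(n_ext, 1/n_ext) and reported as the *strict* upper tail
P(K > count). With count 5 over 82 external subsystems this gives
p = 0.00052, matching the printed headline of the analysis this package
reproduces; the strict (rather than >=) convention is deliberate and
checked against a brute-force binomial sum in the tests.

## Lesions and integrity

A lesion closes every subsystem with a given blanket role; nothing else
changes at lesion time (positions, velocities, chemistry bit-identical).
The continuation runs the lesioned and an unlesioned control arm from the
same state with the same seeded noise stream, so differences are caused
by the lesion alone. Integrity is the mean distance of the
internal-and-blanket members from their centroid; the report carries the
full time series, the final/initial ratio, and the count of internal
members extruded beyond the median blanket radius. These metrics are this
package's own quantification of a qualitative phenomenon (the source
figures show decay and dispersion but print no number).

## Free-energy verification

The variational machinery is verified constructively where exact answers
exist:

- Standard-form flows `f = -(Gamma + R) grad G` with `R` antisymmetric
  (enforced to 1e-12): the stationarity residual of `p = exp(-G)` under
  the Fokker–Planck operator, discretized with central differences,
  converges at second order in the grid step for quadratic `G` with and
  without a solenoidal component, and a corrupted (non-antisymmetric) `R`
  leaves a residual orders of magnitude larger.
- An Euler–Maruyama simulation of the flow with fluctuation covariance
  `2 Gamma` reproduces `exp(-G)` as its long-run histogram (chi-square
  goodness of fit on 1e5 pooled draws from 1000 parallel chains, sampled
  every 2 time units after burn-in so the draws are effectively
  independent; `dt = 0.005` keeps the Euler stationary-variance bias below
  sampling noise).
- On linear-Gaussian joint models over (external, sensory, active,
  internal) coordinates, the free energy `F = E_q[G] - H[q]` has closed
  form; gradient-based minimization over Gaussian `q` (Cholesky
  parametrization, analytic gradients, L-BFGS-B) recovers the exact
  conditional posterior and attains the negative log evidence to 1e-6
  across 100 random well-conditioned models, and the gap
  `F - (-ln evidence)` equals the closed-form KL divergence to the
  posterior (Gibbs inequality: nonnegative, zero only at the optimum).
  Verification is restricted to the linear-Gaussian family on purpose:
  it is the largest family in which "variational optimum = posterior" is
  an assertable identity rather than an approximation.

## Reduced-scale study conditions

The full-scale reference conditions are 128 subsystems for 2048 s. Tests
and the acceptance script run a reduced battery — 64 subsystems, 512 s,
five seeds, 256 s adjacency window, k = 8, 256 s lesion continuations —
chosen so the whole suite completes in minutes while preserving the
phenomena: the bound cluster bootstraps within the run, the closed/open
sorting is established, and the lesion contrast is measurable. Reduced
scale weakens two things relative to the full conditions: the external
population is smaller (tens rather than 82), so exceedance counts are
coarser; and organization time eats a larger fraction of the run, so
partitions are noisier. Stochastic claims are therefore asserted as
seed-majorities or medians, mirroring how single stochastic realizations
are reported in the source analyses.

## What the synthetic data does not show

The simulator *is* the study system here — there is no external data —
but conclusions from the defaults still have limits. The phenomena are
demonstrated for one force law and one coupling topology class; the
"gas-like" and "crystalline" corners of parameter space are reachable
through the config but are not exercised by the tests. The dependency
test demonstrates statistical coupling between internal dynamics and
external motion, not a decoding of hidden states; and no claim is made
that the soup's internal states track exact posteriors — that
correspondence is verified only on the tractable linear-Gaussian systems
above.
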