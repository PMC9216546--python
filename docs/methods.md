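# Methods

## The inference problem

`ratesnap` addresses a recurring situation in systems biology: two molecular
components X2 and X3 of a large, mostly uncharacterized reaction network can
be measured jointly in single cells (flow cytometry, smFISH, single-cell
sequencing), the qualitative interaction "X2 modulates the production of X3"
is known, and the quantitative rate law f(x2) is not.  Snapshots carry no
temporal ordering, the rest of the network is unobserved, and perturbation
data are unavailable.

The package reconstructs f(x2) as a non-parametric table of values over the
observed X2 states from nothing but the empirical stationary joint
distribution P(x2, x3), using the fact that at stationarity the probability
flux crossing any abundance threshold of X3 upward must equal the flux
crossing it downward.  For production in single-molecule steps at rate
f(x2) and degradation removing d molecules per event at rate g(x3), the cut
at level m gives an exact balance relation for every m:

    sum_j f(j) P(x2 = j, x3 = m)  =  sum_{s=1..d} g(m+s) P(x3 = m+s).

For first-order degradation (d = 1, g = x3/tau3) the right side is
(m+1) P(x3 = m+1)/tau3; for the dimeric channel (d = 2, g = gamma x3 (x3-1))
it is gamma (m+1) m P(m+1) + gamma (m+2)(m+1) P(m+2).  These relations hold
for *any* dynamics of the unobserved remainder of the network — they follow
from marginalizing the chemical master equation, not from any model of the
upstream components.  Note the cut form is weaker than detailed balance:
the dimeric system breaks pairwise detailed balance (there is no single-step
downward flux at all) yet satisfies the cut relations exactly; the package's
oracle tests verify both facts.

## The solver

Stacking the cut relations over m gives G f = h with G_mj = P(x2=j, x3=m).
Empirical distributions carry sampling error, and the system is formally
underdetermined when each f(j) is free, so the package solves

    min_f  || G f - h ||^2  +  eps || Gamma f ||^2     s.t.  f >= 0,

with Gamma the discrete second-difference operator.  The smoothness penalty
encodes the one substantive assumption: biochemical rate laws do not jump
between adjacent abundance states.  The program is a convex quadratic with
non-negativity bounds; it is solved *exactly* (active-set NNLS on the
stacked matrix), so the global optimum is guaranteed and KKT optimality of
every returned estimate is checkable (`inference.kkt_violation`, verified
to ~1e-12 in the test suite).  Optional monotonicity constraints are folded
into the same NNLS form by a cumulative-sum change of variables.

Boundary handling: the top `d` balance rows reference states above the
observed support and provably cannot balance in finite samples; they are
dropped.  X2 columns inside the hull that were never observed are retained
(the penalty interpolates them) but carry `reliability = 0` in the returned
estimate; downstream error weighting ignores them automatically.

Scale: multiplying the degradation rate by any c > 0 multiplies the
recovered f by exactly c (verified to machine precision).  If tau3 (or
gamma) is unknown the method therefore returns the correct *shape*
tau3*f(x2), flagged by `scale_known=False`.

### Regularization strength

The shipped default is eps = 1/sqrt(N).  The appropriate strength is a
heuristic, not a derived quantity; measured on the built-in systems at
N = 1e5 the inference error has a broad optimum for eps in ~1e-3..1e-1 and
is an order of magnitude worse at eps = 1/N, which under-smooths once the
per-cell counts of the joint histogram are O(10).  The faster-decaying
1/N policy remains available (`default_epsilon(..., policy="one_over_n")`),
and every entry point accepts an explicit eps.  With exact (oracle)
distributions the solver is run at a floor of 1e-12, which only breaks the
degeneracy of the noiseless problem; recovery is then exact to <0.1% on all
non-negligible states.

### Constant-rate cross-validation

When f barely varies over the observed X2 range the free fit can only
overfit sampling noise.  `infer_rate_cv` splits the ensemble in half,
fits both the free table and the best single constant on the training half,
scores each by its summed squared violation of the *validation* half's own
balance system, and declares the rate constant when the constant model's
validation error is smaller than or within 5% of the free model's (ties go
to the simpler model).  The winning model is refit on the full data.  The
free candidate is evaluated on validation columns outside its fitted range
by constant extension of the edge values — consistent with the package's
general policy that extrapolation beyond observed states requires a priori
information it refuses to invent.

## Quality metrics

* Error heuristic `E = sum_x2 |f_inf - f_true| P(x2) / <f_true>`:
  probability-weighted so that errors at states the system never visits do
  not count, and normalized by the mean true rate so E is a relative error.
* Importance `I = |eta_x3f| / eta_x3x3`, where eta_x3x3 is the squared
  coefficient of variation of x3 and eta_x3f = Cov(x3, f(x2))/(<x3><f>).
  For any linear-degradation system in the supported class the stationary
  moments obey eta_x3x3 = 1/<x3> + eta_x3f exactly; `importance` reports
  the residual of that identity as a self-consistency diagnostic (it
  vanishes at the oracle distribution and decays ~1/sqrt(N) on samples).
  Small I means X2 fluctuations barely move X3, and inference quality
  degrades accordingly — the two are rank-correlated across parameter
  sweeps.

## Data generation

### Exact SSA and the snapshot protocol

Trajectories are exact Doob–Gillespie realizations (compiled kernel,
incremental propensity updates, seeded Mersenne–Twister; bit-reproducible
per seed).  Stationary snapshots come from one long trajectory: burn-in of
50 slowest lifetimes, then one record of the observed pair every 10 slowest
lifetimes (both multipliers configurable).  Spacing by lifetimes is a
heuristic: lifetimes do not bound the mixing time when the dynamics are
metastable (the bistable motif decorrelates over ~500 lifetimes) or
oscillatory, so `lag1_autocorrelation` is exposed as the independence
diagnostic.  For inference accuracy what matters is the fidelity of the
empirical joint, which is governed by total simulated time; correlated
oversampling biases nothing, it only reduces the effective sample count.

### Built-in motifs

Four three-component feedback architectures share the identical conserved
X3 part (Hill production f(x2) with lam=80, n=2, K=40, tau3=1; unit-step
decay, or gamma=2 dimeric decay removing two molecules) while the X1, X2
dynamics produce bistability, relaxation oscillations, noise control, and
noise enhancement.  Changing a lifetime tau_i rescales that component's
birth law by 1/tau_i so the stationary means stay put while the fluctuation
time-scale moves — this is what "changing lifetimes does not change the
dynamics" requires, and it is how the fast-upstream regime (tau2 << tau3)
is constructed.

One caveat discovered during implementation: the noise-controlling
parameter set as printed (birth f1 = 50 x3 with lifetime tau1 = 50, x2
production 3000*K^10/(K^10 + x1^10) with K = 10) admits no deterministic
fixed point and settles into a slow bursty regime in which x2 stays below
~20 with P(x2 = 0) ~ 0.9, far from the Hill half-point K = 40 of the
conserved part.  In that regime the regulator carries little information
about the rate (importance I ~ 0.27) and the probability-weighted error is
normalized by a tiny mean rate (<f_true> ~ 0.02), so inference quality is
intrinsically poor: measured E at N = 1e5 is ~0.5 under the default
regularization and never falls below ~0.1 at any regularization strength.
Its reliably-observed X2 states also barely overlap those of the other
three motifs, so cross-system shape comparisons involving it cover almost
no probability mass; the comparison helper returns the overlap mass
alongside the distance so this degeneracy is visible rather than silently
averaged away.  The corresponding acceptance test is intentionally left
failing for this motif rather than adjusting the printed parameters.

### Reduced-mean variant

Oracle-based tests use a scaled-down noise-enhancing system
(lam3=32, K3=16, f1=2, upstream Hill lam=12, K=12, c=4; means ~18 instead
of ~50) whose full three-species state space fits in a truncated box of
~4e4 states.  It preserves every qualitative feature that matters
(feedback topology, Hill nonlinearity, count discreteness) at tractable
exact-solve cost; what it does not emulate is the paper-scale abundances,
so absolute-noise magnitudes (e.g. sigma_abs = 8 molecules) are only
meaningful on the full-scale systems and are tested there.

### CME oracle

The truncated-generator stationary solve anchors the null space at the
deterministic fixed point (clipped into the box), drops that row/column,
and solves the remaining sparse system directly — anchoring near the mode
keeps the relative probabilities within floating-point range.  Reactions
that would exit the box are reflected (propensity zeroed), keeping the
generator a proper rate matrix; the total probability on the upper boundary
faces is reported as `leaked_mass` and every oracle-based test states its
leakage budget explicitly.  The oracle is deliberately capped at 2e6 states:
it exists to provide ground truth on small instances, not to compete with
scalable CME methods.

## Measurement noise

Additive Gaussian (sd sigma_abs molecules), relative Gaussian
(multiplicative, sd sigma_rel), and binomial undercounting (detection
probability p) corrupt ensembles per coordinate independently; noisy values
are rounded to the nearest integer because the balance equations live on
discrete states, and additive/relative draws that go negative are discarded
with the discard count recorded.  Undercounting admits an exact correction
for linearly degraded species: detected molecules form a birth-death
process of their own (births thinned to p*f, per-molecule death rate
unchanged), so the measured x3 axis already satisfies unit-step balance;
the correction rescales the x2 axis by 1/p and evaluates the degradation
rate at the reconstructed true abundance m/p.  With known p this recovers
f at the correct scale; with unknown p the shape survives but the x2 axis
and rate scale carry the unknown factor.  No de-convolution of the additive
or relative channels is attempted.

## What a green test establishes

Synthetic data here are exact simulations of the stated stochastic models,
so passing tests establish that the inversion recovers the generating rate
law under the paper-scale sampling budgets, time-scale separations, and
noise magnitudes tested — including regimes where the naive conditional
mean <x3|x2> is badly biased.  They do not establish robustness to features
real single-cell data add on top: non-stationarity, cell-cycle and growth
dilution structure, continuous washed-out intensities, or correlated
measurement noise, all of which are explicit non-goals of this package.

## Numerical conventions

* Hill law at n = 0 is lam/2 (shared limit of both branches) so sweeps
  across zero cooperativity are continuous; repressive Hill at x = 0 is lam.
* Dimeric degradation propensity gamma x(x-1) vanishes at x < 2, so the
  two-molecule removal never drives counts negative.
* NNLS tolerances are scipy defaults (~1e-12 relative); estimates are
  stable to 10x tolerance changes on the test fixtures.
* Sweeps derive per-cell seeds from the master seed via
  `SeedSequence.spawn`, keeping cells independent and order-insensitive;
  all internal seeds stay below 2^31.
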