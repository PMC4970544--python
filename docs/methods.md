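# Methods

`vwforce` models how the blood protein von Willebrand factor (VWF) senses
hydrodynamic force. It has two halves that meet in the Bell lifetime law:
a single-molecule force spectroscopy (SMFS) half that estimates the
kinetics of the A1/A2 domain interaction from rupture-force data, and a
Brownian-dynamics (BD) half that estimates the tension this interaction
experiences when a surface-anchored multimer sits in shear flow.

Throughout, forces are in pN, lengths in nm, times in s, and energies in
kBT with kB = 0.0138 pN nm/K, so kBT = 4.1124 pN nm at the default
temperature of 298 K ("room temperature" is not otherwise pinned down;
the choice changes diffusive time scales by about 2% relative to 293 K
and is configurable everywhere).

## Rupture kinetics

### Single-barrier (Bell–Evans / Evans–Ritchie) model

A bond whose off-rate grows exponentially with force,
k(F) = koff exp(x_beta F / kBT), pulled at constant loading rate r,
ruptures at a force with density

    p(F|r) = (koff/r) e^{x_beta F/kBT}
             exp[-(koff kBT/(r x_beta)) (e^{x_beta F/kBT} - 1)].

The CDF and quantile function are analytic; the synthetic generator
samples by inverse CDF and the test suite cross-checks it against
rejection sampling. `fit_bell_evans` maximizes the summed log density
with each event's own loading rate r_i = keff_i * v_i (the slope at
rupture times the pulling velocity), optimizing over (ln koff,
ln x_beta) with a simplex start and quasi-Newton polish; standard errors
come from the finite-difference observed information. Identifiability
requires at least two distinct loading rates; degenerate inputs (a single
rate, all forces equal) are rejected with errors.

The lifetime law tau(F) = tau0 exp(-x_beta F / kBT) with tau0 = 1/koff
converts any estimated tension into a bond lifetime.

### Cusp-landscape (BSK-type) model for fast loading

For loading rates reaching the force-probe-MD regime (~1e10 pN/s) the
Bell picture fails; the model used here parameterizes the free-energy
landscape as a harmonic well truncated by a sharp barrier (cusp):
U(x) = E (x/x_b)^2 - F x. The escape rate is the exact overdamped
mean-first-passage-time rate of this tilted landscape, which reduces to
a universal one-dimensional integral

    k(F) = 2 D E* / (x_b^2 sqrt(pi) H(u_b)),
    H(u) = ∫_0^u e^{t^2} (1 + erf t) dt,
    u_b = sqrt(E*) (1 - F/F_c),  E* = E/kBT,  F_c = 2E/x_b,

evaluated from a tabulated H. Its zero-force, high-barrier limit is
exactly the Kramers activation rate

    k0 = (2 D E / (x_b^2 kBT)) sqrt(E/(pi kBT)) e^{-E/kBT},

exposed as `kramers_k0` and attached to every fitted parameter set (the
finite-barrier correction is a few per cent at E >= 15 kBT). Because the
exact rate diverges as F -> F_c, the rupture-force density
P(F) = (k/LR) exp(-(1/LR)∫k) carries all its mass below the critical
force; no discrete atom is needed. An independent double-quadrature MFPT
oracle in the test suite agrees with this route to better than 1% in
density sup-norm.

### Fitting across AFM and MD loading rates

The default AFM input is one Gaussian (mu, sigma) per pulling velocity —
the Gaussian fitted to the first peak of that velocity's force
distribution — with loading rate LR = V <ke> (cycle-averaged slope).
Each summary contributes the Gauss–Hermite (32-node) expectation of
log P under its Gaussian; MD rupture forces enter as point log-densities
at their own loading rate. Optimization runs over (ln E, ln x_b, ln D)
with eight heuristic starts spread over the E–D ridge.

Two properties of this summarized likelihood are worth knowing:

* It is deliberately faithful to the summarized-input convention, but a
  Gaussian cannot match the skewed rupture density, so the estimator
  carries an irreducible bias (about +15-20% in E and x_b, up to an
  order of magnitude in D along the ridge, for typical AFM windows) even
  with exact population summaries. The mean-force-vs-LR curve it implies
  is nevertheless accurate to a few pN inside the AFM window.
* For unbiased parameter recovery the same function accepts raw
  (force, loading-rate) events (`afm_raw=...`); that exact likelihood is
  the consistent maximum-likelihood estimator and is what the recovery
  and coverage test suites exercise.

The 95% confidence band of the mean-force-vs-LR curve is a parametric
bootstrap (default 1000 replicates, seeded): simulate rupture forces from
the fitted model at every input loading rate, re-summarize (or keep raw),
refit warm-started, and form the basic (reflected-percentile) interval of
the curve values. The reflection cancels the first-order finite-sample
bias that a plain percentile band would apply twice; with it, the band
covers the generating curve at essentially all evaluated loading rates in
simulation.

When AFM data are combined with MD data for a bridged construct, the
largest MD force can be excluded (`exclude_max_md`): it stems from a
simulated pathway (A2 unfolding) that the bridged construct forbids.

## FDC analysis

Retraction traces follow the AFM convention: zero-force baseline, tether
load pulling the force negative, rupture as a discontinuous jump back to
baseline. `detect_rupture` estimates the baseline from the final 20% of
the trace (median) and the per-sample noise from the median absolute
successive difference of the whole trace; candidate ruptures are
single-sample jumps exceeding `snr_threshold` (default 4) noise units of
a difference and an absolute floor of 5 pN. A second-order polynomial
fitted over the 20 nm before the jump (the "characteristic parabolic"
linker signature) supplies both the rupture force (baseline minus fitted
force at onset, robust to single-sample noise) and keff (fitted slope
magnitude). Events within 15 nm of contact are discarded as nonspecific
adhesion — the automated stand-in for the manual parabola-vs-spike
discrimination an analyst performs; its parameters are configurable and
it is validated only against the synthetic generator. Detection limits
follow from the thresholds: ruptures below ~5 pN, or stretches whose
per-sample rise exceeds the jump floor, are invisible by construction.

The binding probability is the fraction of cycles with at least one
detected event; with multiple events per cycle the last (farthest)
rupture feeds the kinetics, the standard SMFS convention.

`fit_first_peak` fits a Gaussian to the lowest-force peak of the force
distribution. The density is a Gaussian KDE (Scott bandwidth) rather
than a raw histogram, because histogram noise generates spurious local
maxima; the fitted sigma is deconvolved from the KDE bandwidth. Forces
inside the closed interval mu +/- sigma feed further analysis. Note a
consequence verified in the tests: applied to *unimodal* synthetic data
this selection truncates genuine tails, and a plain single-barrier MLE
on the truncated cloud is biased (koff low, x_beta high). In the
experimental setting the selection removes other populations, which is
its purpose; the pipeline therefore exposes `select_for_lrd` to disable
it when the data are known to be single-population.

## The coarse-grained VWF model

One bead per protomer: N = 20 beads of radius a = 30 nm (the protomer's
radius of gyration), so 19 bonds of rest length 2a give a contour of
1.14 um. The energy is a full attractive 12-6 Lennard-Jones over all
pairs with minimum -eps at contact distance 2a (eps = 2 kBT, which
collapses the untethered multimer into a globule, as in circulating
VWF), harmonic bonds kappa/2 (r - 2a)^2, and a truncated-shifted
repulsive 10-4 wall of range sigma_R = 45 nm active below the cutoff
(zero above, continuous force at sigma_R). The wall prefactor is the
dimensionless ratio 2 pi sigma_R / a times a configurable multiplier;
every reported observable is insensitive to this prefactor because the
wall only keeps beads off the boundary.

The spring constant defaults to kappa = 203 kBT/a^2 (0.2256 kBT/nm^2,
i.e. 0.93 pN/nm at 298 K). In these units the explicit propagator is
comfortably stable at the standard time step (mu0 kappa dt ≈ 0.10 at
dt = 55 ns); reading the same digits in kBT/nm^2 would make that product
≈ 91 and the scheme unconditionally explosive, which is why the per-a^2
reading is adopted. kappa is configurable in kBT/nm^2 for users who want
stiffer bonds with a correspondingly smaller dt.

A numerical regularization: below a soft-core radius of 0.75 x 2a the
LJ pair force is frozen at its boundary value (energy continued
linearly). This bounds the force of the rare noise-driven deep overlap
so that it relaxes smoothly instead of triggering an explicit-Euler
runaway; at equilibrium distances the potential is untouched.

## Brownian dynamics with wall hydrodynamics

The propagator is first-order (Ermak–McCammon type):

    dr_i = [v_shear(z_i)(mu_ii/mu0) x̂ + Σ_j mu_ij F_j + v_corr(z_i) ẑ] dt
           + dr_random,

with v_shear(z) = shear_rate * z, the advection scaled by the normalized
self-mobility as a wall-slowdown factor (a literal unscaled variant sits
behind `shear_mobility_scaling=False` for sensitivity checks; at the
heights the chain samples the two differ by <~25%). The noise is
Gaussian with covariance 2 kBT dt mu (fluctuation–dissipation), realized
through a Cholesky factor of the mobility.

The mobility is Rotne–Prager–Yamakawa between beads (overlap form below
contact, which keeps the free-space matrix positive definite), plus
Blake's full stokeslet image system for the wall, plus self-mobility
wall corrections including the O((a/z)^3) finite-size terms

    mu_par/mu0 = 1 - (9/16)(a/z) + (1/8)(a/z)^3,
    mu_perp/mu0 = 1 - (9/8)(a/z) + (1/2)(a/z)^3,

so the grafted-height self-mobility stays positive. The spurious-drift
correction v_corr = kBT d(mu_zz)/dz is analytic and is checked against
finite differences to 1e-5. Known truncation limits: the far-field
series is non-monotone below z ≈ 1.15a (the drift correction then points
weakly toward the wall), and in tight wall-near configurations the
assembled matrix can lose strict positive definiteness. The engine
therefore verifies positive definiteness every step (a Cholesky attempt,
whose factor doubles as the noise square root) and clips negative modes
by eigendecomposition when needed — without the clip, a repulsive force
along a negative-mobility mode would *attract* beads and destabilize the
run. The wall potential keeps beads above ~1.3a in practice, where none
of these caveats bite.

Constraints and boundaries: bead 0 is grafted at (0, 0, a) and held by
constraint projection — the tether reaction force that exactly cancels
its deterministic velocity is computed from the self-mobility block and
coupled back to all beads through the mobility (simply discarding the
displacement would let the large static wall force on the grafted bead
advect the whole chain through hydrodynamic coupling). Its thermal noise
is discarded. Beads crossing z = 0 are reflected. A uniform rescale caps
the largest per-bead displacement at 0.15a per step (rescaling the whole
field preserves relative motion, so colliding beads still separate); the
cap engages only in rare force spikes. A bond exceeding ten contour
lengths aborts the run as a time-step diagnostic.

Internally the engine works in reduced units (length a, energy kBT,
mobility mu0 = 1/(6 pi eta a), time tau_a = a^2/(mu0 kBT) ≈ 1.1e-4 s for
eta = 0.89 mPa s), converting at the API boundary; dt = 55 ns is
5e-4 tau_a. The inner loop has a numba-compiled kernel (~50 us/step for
N = 20, mobility and Cholesky rebuilt every step) and a pure-numpy
reference implementation; a zero-noise test requires the two trajectories
to coincide to 1e-10.

## Observables, errors and problem sizes

Production runs record block averages (100 steps) of every bond length;
the profile is the mean of block means and the tension
f_i = kappa (<r_{i,i+1}> - 2a) in pN. Standard errors multiply the naive
block-mean error by the square root of the integrated autocorrelation
time of each bond's block series (initial-positive-sequence estimator) —
bond vibrations decorrelate within a few blocks, but the globule's
packing rearranges on 1e5-step scales and would otherwise be badly
underestimated. The lifetime estimate plugs the grafted-end tension f_0
into the Bell equation; compressive (negative) mean tension is clamped
to zero with a warning, since compression does not accelerate rupture in
this regime.

Published-scale runs are 1e8 steps (5.5 s of flow) with at least 1e5
equilibration steps. The package defaults target desk scale — 1e5
equilibration plus 1e5-1e6 production steps per shear rate, a few
minutes for the eight-rate sweep — with the autocorrelation-corrected SE
making the statistical resolution explicit. At this scale the four
lowest shear rates (5.5-182 /s) are statistically indistinguishable
(per-bond z-scores consistent with pure noise at one million steps),
grafted-end tension rises monotonically with shear rate to a few pN at
18175 /s, and tension decays from the grafted end toward the free end.
What desk scale does *not* show: tension differences below ~0.05 pN, and
slow packing modes beyond the run length; the quoted SEs carry that
information.

The synthetic SMFS generator emulates the study conditions — nine
velocities (50-3000 nm/s), ~1000 cycles per velocity for reliable
statistics, a 30 pN/nm cantilever, a blocking condition with the specific
fraction collapsed from 0.40 to 0.05 — with placeholder noise (5 pN sd)
and nonspecific-adhesion rate (10%), since the real instrument's values
are not on record. Passing round-trip tests therefore demonstrates the
analysis chain's correctness on data obeying its own assumptions
(parabolic linker signature, Gaussian baseline noise, single-barrier
kinetics), not robustness to instrument drift, multiple tethers, or
non-exponential unbinding, all of which are out of scope.
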