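# Methods

`ionfes` re-creates, at desk scale and in reduced units, the free-energy
workflow used to study how multidentate hydroxamate chelators (hexadentate
DFO-like, octadentate 4HMS-like) coordinate a highly charged metal cation
such as Zr4+ in solution: biased sampling along a coordination-number
collective variable, WHAM reconstruction of 1D and 2D free-energy surfaces
with Monte Carlo bootstrap errors, inherent-structure quenching of sampled
configurations, and descriptive geometric analyses.  The package does not
attempt the production-scale solvated simulations themselves; every method
is instead exercised on toy ion-chelator systems with exactly computable
answers, so that each stage of the workflow is validated against an
independent oracle.

## Units and interaction model

All energies are in kBT (temperature enters only as the unit), lengths in
Angstrom-like reduced units, masses 1.  The nonbonded pair energy is the
12-6-4 form

    U(r) = C12/r^12 - C6/r^6 - C4/r^4 + q/r,

a Lennard-Jones potential with an extra attractive C4 term representing the
charge-induced-dipole interaction that dominates the binding of highly
charged cations, plus point-charge Coulomb.  The potential is plainly
truncated at the cutoff (default 11): no switching, shifting, or Ewald
summation.  This is a deliberate simplification -- the toy systems are
non-periodic and small, and an isotropic harmonic tether per particle
replaces the periodic box as the confinement mechanism.  Bonds are harmonic,
`k/2 (r - r_eq)^2`.  Separations below `r_min_guard = 1e-3` raise an
explicit overlap error rather than returning a silently enormous energy
(the minimizers disable this guard and rely on large finite energies to
reject bad steps).

The mapped physical defaults are: time step 0.002 (2 fs), friction gamma =
2 (2 ps^-1), cutoff 11 (11 A), bias spring k = 20 kBT, switching cutoffs
r0 = 5 (ligand oxygens) and 2.5 (water oxygens).

## Collective variables

The coordination number of the ion with a member set (ligand oxygens, or
solvent oxygens) is the smooth count `CN = sum_i s(d_i)` with the rational
switching function

    s(d) = [1 - (d/r0)^n] / [1 - (d/r0)^m],   (n, m) = (6, 12) by default,

whose removable singularity at `d = r0` is evaluated by a first-order
expansion around its analytic limit `n/m`.  For m = 2n the function reduces
globally to `1/(1 + (d/r0)^n)`.  Gradients are analytic; they sum to zero
over particles and are validated against central finite differences at
1e-5.  The sharp (step-function) partial coordination number n(r) used for
radial-shell analyses is a separate observable and never conflated with the
smooth CV.  Chelate angles are measured at the oxygen vertex (vectors
O->ion and O->X), in degrees.

## Dynamics

Langevin NVT dynamics uses the B-A-O-A-B splitting with the exact
Ornstein-Uhlenbeck update in the O step; with gamma = 0 and T = 0 it is
velocity Verlet, and the suite verifies O(dt^2) energy conservation there.
BAOAB was chosen for its accurate configurational sampling at practical
time steps.  One explicitly seeded generator drives each trajectory
(window i of an umbrella set uses `base_seed + i`), so every output is
bitwise reproducible.  Umbrella windows apply `k/2 (CN - s0)^2`; ladders
start each window from the final frame of its predecessor and the first
10% of each window is discarded as equilibration (the production
equilibration protocol is out of scope, so the discard fraction is a plain
configurable default).

## WHAM

Binned WHAM iterates the standard self-consistency equations on window
histograms (default 100 bins spanning the data range padded by 0.25 CV
units; tolerance 1e-8 on the maximum window-offset change, at most 1e5
iterations), reports the profile in kBT with its minimum at zero over
sampled bins, and marks empty bins as unsampled rather than interpolating.
Windows that share no sampled bin are detected as disconnected components
and flagged.  2D surfaces over (ligand CN, water CN) are built by
reweighting individual frames with `w_j = 1 / sum_i N_i exp(f_i - U_i(s_j))`
using the converged offsets, with the bias evaluated at the exact frame
value; the marginal `-ln sum_w exp(-F)` over the secondary axis must
reproduce the 1D profile, and the suite enforces this within 0.2 kBT on
well-sampled bins.

Errors are Monte Carlo bootstrap: contiguous blocks (default 1/20 of each
series, to respect autocorrelation in dynamical data) are resampled with
replacement per window, the whole estimate is re-run warm-started from the
full-data offsets, and per-bin standard deviations over replicates are
reported.  Two gauge conventions are available, because a free-energy
profile is defined only modulo an additive constant: the default anchors
every replicate at its own minimum (matching the plotted min-zero
profiles), while `align="lsq"` aligns each replicate to the full-data
profile by its mean offset over a caller-supplied bin mask.  The second is
the right gauge for quantitative profile comparisons -- anchoring at a
minimum pins the error to zero at one bin and, for landscapes with
degenerate minima, lets the anchor hop between wells.

Two findings from validating the estimator are worth recording.  First,
binned WHAM carries an O(width^2) discretization bias arising from the
within-bin covariance of the density and the bias factor (approximately
F' U' w^2 / 12); evaluating bin-averaged bias factors does not remove the
cross term, so the validation studies simply use enough bins (200 for the
double-well study) that the bias sits far below the statistical error.
Second, the bootstrap is well calibrated when (and only when) the replicate
gauge, the comparison gauge, and the comparison target are consistent: the
ground truth must be binned the same way the estimator bins
(`-ln` of the bin-averaged Boltzmann weight, not the center value), and all
offsets must be taken over the same bin mask.  With that discipline the
per-bin bootstrap errors match the across-dataset spread of independent
replications and the mean squared standardized deviation is 1.0.

## Inherent structures

Sampled frames are quenched by steepest descent (backtracking Armijo line
search, energy non-increasing at every accepted step) followed by
Polak-Ribiere(+) conjugate gradient with secant line searches (exact on
quadratics, hence finite termination there) and automatic restarts.
Convergence is declared on the maximum force component at 1e-4 reduced
force units, matching the production force threshold; the Euclidean norm
is reported alongside since the threshold could be read either way.
Solvent particles are removed before quenching by default, mirroring the
practice of optimizing the bare complex, and the coordination number is
recomputed on each quenched geometry to support the U-vs-CN scatter that
maps the potential-energy landscape.  Quenching is idempotent to 1e-8 in U,
and basin assignments agree with dense gradient-flow integration on >= 95%
of random double-well starts (disagreements cluster at the separatrix).

## Synthetic ground truths and oracles

The estimation layer is validated on data whose answer is known exactly:

* `DoubleWell1D` -- `F0(s) = 8 (s^2 - 1)^2`, two basins at s = +-1
  separated by an 8 kBT barrier, standing in for the open/closed two-basin
  phenomenology of chelation profiles without claiming any real system's
  energetics.  `SeparableHarmonic2D` adds an uncoupled `2 (w - 4)^2`
  solvent coordinate.  Biased samples are drawn i.i.d. by inverse-CDF on a
  dense grid (conditional grid sampling for the 2D case), so estimator
  errors are purely statistical.
* `build_single_ligand_system` -- one mobile ligand oxygen around a frozen
  ion (12-6-4 well at r = 2, depth 4, harmonic tether k = 0.5): three
  unconstrained coordinates, so the free energy along the coordination
  number is computable by dense 3D grid quadrature
  (`reference_fes_quadrature`).  The quadrature evaluates plane by plane
  (bounded memory), and its grid must resolve the narrowest CN bins: the
  end-to-end study uses n_grid = 401, at which doubling the grid changes
  no compared bin by more than 0.02 kBT.  The oracle refuses systems with
  more than one free particle.
* `build_toy_chelator` -- the n-group bidentate analog (3 groups / 6
  oxygens, or 4 groups / 8 oxygens) with a chained backbone, soft tethers
  and optional solvent-oxygen shell, used by the pipeline and the
  geometric analyses.  Its angle analysis uses ion-O-backbone and
  ion-O-sibling-oxygen triplets as the reduced-model analogs of the
  ion-O-N / ion-O-C angle pairs of a real hydroxamate group.

## Validation studies and their problem sizes

`ionfes.studies` holds the canned experiments asserted by the test suite
and reported by `scripts/acceptance.py`.  Problem sizes were chosen so the
whole set runs in minutes on one CPU: 9 windows x 5e4 exact samples for
the 1D and 2D recovery studies (bootstrap n = 48 and 100); 9 windows x
2e5 Langevin steps (dt 0.003, stride 20, bias k = 100, bootstrap blocks of
1/10 of each series because the softest window's correlation time reaches
a few reduced time units) for the end-to-end study; 2e5 steps at dt 0.01
for the equilibrium-variance check, where the three Cartesian coordinates
of the tethered bead are pooled as three independent oscillators; 200
random starts for the minimizer-vs-gradient-flow comparison.

Profile comparisons fix the additive gauge by the mean offset over the
compared bins and use gauge-consistent bootstrap errors (above).  Each
study reports both the maximum absolute deviation relative to 3x the
bootstrap error at the bin where it occurs (the agreement check) and the
family-wise maximum of per-bin deviation/3sigma (a diagnostic: even for a
perfectly calibrated estimator its expectation is the extreme of ~10^2-10^3
standard normals divided by 3, i.e. near or above 1, so it is reported but
not thresholded).

## What passing does and does not show

The synthetic generators produce exact i.i.d. samples and low-dimensional
toy systems; they emulate the statistical structure of umbrella-sampled
coordination data (overlapping biased windows, two-basin landscapes, a
thermally fluctuating solvent coordinate) but not explicit-water physics,
real chelator chemistry, force-field accuracy, or the microsecond
time scales of production simulations.  Passing therefore certifies the
estimators, integrators and minimizers -- not any statement about real
Zr4+ chelation energetics, whose headline numbers are out of scope here.

## Known limitations

* Plain cutoff truncation makes the pair force discontinuous at the
  cutoff; at the toy scale the affected configurations carry negligible
  weight, but energy-conservation tests use bonded systems well inside it.
* Binned WHAM's O(width^2) bias (above) means very coarse grids on steep
  landscapes are systematically off; choose bins so that F' U' w^2 / 12 is
  small against the target accuracy.
* The quadrature oracle is limited to one free particle and a rectangular
  box; its histogram quadrature aliases if bins are much narrower than the
  CN change across one grid cell.
* `cn_transition_summary` uses running-mean smoothing plus +-0.25 hysteresis
  bands; transitions faster than the smoothing window are reported at the
  resolution of that window.
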