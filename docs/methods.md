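# Methods

## The reaction coordinate

The flipping coordinate ξ is a pseudo-dihedral over four pseudo centers,
each the mass-weighted center of a heavy-atom group (duplex anchor residues
opposite the lesion, anchor residues flanking it, the backbone of the
flipping nucleotides, and the flipping bases themselves).  Distributing the
coordinate over group centers spreads biasing forces over many atoms, which
is why this construction is preferred over single-atom torsions for base
flipping.  The dihedral sign follows the IUPAC convention (clockwise
positive looking from center 2 to center 3); group membership is user
configuration, never hard-coded, because residue numbering differs between
systems.  Note that a dihedral is *invariant* under reversing the center
order; the sign flips only under mirror reflection.

Angles live on a 360° circle but windows span more than half a period
(−320°…38°), so all statistics are done on an unwrapped branch: every
window series is shifted by whole periods onto the branch nearest its window
center before anything else.  Signed arcs between states are reported in a
chosen rotation sense (positive ≡ major groove, negative ≡ minor groove);
`angular_path` returns the arithmetic value and never special-cases any
printed number.

## Units

Degrees at every interface; radians internally wherever an energy couples
to the angle.  Force constants are kcal mol⁻¹ rad⁻² (default
400), diffusivities rad² ps⁻¹, energies kcal/mol, times ps internally and
seconds in the final report.  kB = 1.987204259×10⁻³ kcal mol⁻¹ K⁻¹;
default temperature 300 K (kT ≈ 0.596 kcal/mol).

## Periodic WHAM

Window histograms on a uniform periodic grid (default one 2° bin per
window) are combined by the standard self-consistent equations, iterated
entirely in log space so windows thousands of kT away from a bin cause no
underflow.  The harmonic bias is always evaluated with the periodic angular
distance.  Convergence is declared when the window constants move by less
than 10⁻⁷ kcal/mol (max-norm; cap 10⁵ iterations, non-convergence raises
with the last residual).  Unoccupied bins are NaN, never ±∞, so downstream
integrals restrict themselves to the occupied range; the profile minimum is
referenced to zero.  Optional per-window statistical inefficiencies
g = 2τ_int/dt + 1 divide the sample counts when weighting histograms;
per-window constant energy offsets are accepted and are exactly absorbed by
the window constants (gauge freedom), which the tests exploit.

Feature extraction (minima, saddles, basins) operates on the largest
contiguous occupied arc in circular order: stray samples that wrap to the
far side of the period form noisy islands that must not contaminate the
minimum reference or the basin split.  Plateaus count once, at their
center.  The two deepest minima define the intra- (higher angle) and
extra-helical states; the basins are split at the barrier maximum between
them and, when coverage closes the period, at the complementary maximum,
using cyclic-interval arithmetic so a basin may wrap the branch edge.
State free-energy differences are Boltzmann integrals over basin bins
(ΔF = F_extra − F_intra), not minimum-to-minimum differences.

Convergence across the campaign is quantified as the pairwise RMSD between
profiles of contiguous equal-length data segments, after re-referencing
each profile to zero mean on the mutually occupied bins (a constant offset
between segments is gauge, not disagreement).

## Restraint perturbation

Auxiliary flat-bottom restraints (zero inside [lower, upper], half-harmonic
walls outside; the stacking restraint of a flipping setup keeps the two
bases within 2.5–6.5 Å) are removed per window by exponential averaging,
evaluated with log-sum-exp.  The standard error comes from a block
bootstrap; the default block length is 2τ_int of the ΔU series, but a
conservative explicit block length is recommended whenever the generating
dynamics are slower than the ΔU fluctuations.  ΔF ≤ ⟨ΔU⟩ holds for every
sample set (Jensen); forward/backward estimates and their hysteresis are
reported as a finite-sampling diagnostic.  Corrected profiles are
re-referenced to zero after adding the per-window corrections.  The
restraint force constant has no default: it must be supplied.

## Diffusivity and passage times

Per window, D(ξ_i) = var(ξ)/τ_int with the variance of the unwrapped series
in rad² and τ_int from a least-squares double-exponential fit of the
normalized autocorrelation (computed by FFT with 1/N normalization).  The
fit window ends at the first zero crossing or the first drop below 0.05 —
beyond that an empirical autocorrelation is statistical noise — and both
time constants are bounded by the fit-window span: a slower component with
amplitude above the cutoff would itself keep C(t) above the cutoff and
extend the window, so anything beyond the bound is unidentifiable and, left
unbounded, noise tails inflate τ_int by factors of two.  The two-component
fit is kept only when it at least halves the single-exponential residual;
otherwise A = 1.  If fitting fails outright, τ_int falls back to the direct
integral of C(t), flagged.  The block-averaging standard-error curve is
attached as a consistency diagnostic (its plateau reproduces the
statistical inefficiency).

This variance/autocorrelation estimator assumes the window confines the
walker to a locally smooth stretch of landscape (window stiffness dominates
local curvature: k_U = 400 vs |F″| ≲ 10 kcal mol⁻¹ rad⁻²), which also makes
the bias-curvature correction to the variance negligible.

Passage times are cumulative-trapezoid double integrals on a resampled
uniform grid (default 1000 points) between a reflecting and an absorbing
boundary, by default the intra- and extra-helical minima.  Either boundary
ordering is accepted (the integral is mirrored internally); D is
interpolated log-linearly between window centers and clamped at the ends —
D is positive and fluctuates by up to an order of magnitude, so
interpolating ln D is the balanced choice.  The backward time exchanges the
boundary roles.  The constant-D variant replaces D(ξ) by the arithmetic
mean of the window values; with a rough D landscape it yields shorter
times (roughness slows diffusion, the harmonic-vs-arithmetic-mean effect),
by less than a factor of five at one order of magnitude of D fluctuation.
Reported times are converted to seconds in the Table-shaped record, always
alongside the detailed-balance consistency pair K_kin = τ₋/τ₊ and
K_thermo = e^{−ΔF/kT}.

## Synthetic data

The generator emulates exactly the statistical structure the analysis
assumes: overdamped Langevin dynamics ξ ← ξ + [−βD(F′+U′) + D′]Δt +
√(2DΔt)·η on a truncated-Fourier periodic landscape, with the Itô
spurious-drift term so the discrete stationary law is Boltzmann for
position-dependent D.  The flipping preset places the intra minimum at
+30°, the extra minimum at −135°, a 3 kcal/mol barrier above the intra
state on the direct segment and a −2 kcal/mol state offset — the geometry
of the damaged-base landscapes this analysis targets, with the barrier kept
in the low single digits so that first-passage statistics are measurable at
desk scale.  Presets are calibrated by fixed-point iteration of a
two-component periodic well mixture and verified to reproduce their
declared minima within 0.5° and barrier/offset within 0.05 kcal/mol;
construction fails loudly otherwise.  D is constant (0.15 rad²/ps) by
default or log-sinusoidal (amplitude ln(10)/2 ≈ 1.15 for one order of
magnitude peak-to-trough).

Integration uses Δt = 2.5×10⁻⁴ ps, stride 5, 10⁵ stored samples and
10⁴ equilibration steps per window by default.  The timestep is set by the
stiffest mode: a 400 kcal mol⁻¹ rad⁻² window with D = 0.15 rad²/ps relaxes
in τ = (βDk)⁻¹ ≈ 0.01 ps, so βDkΔt ≈ 0.025 keeps both the Euler stationary
variance bias and the diffusivity bias at the percent level.  A stability
check rejects settings whose per-step drift bound exceeds 0.2 rad.  The
campaign advances one walker per window and attempts neighbor configuration
swaps of alternating parity every 2000 steps with Metropolis acceptance on
the bias energies (the landscape term cancels for a swap); at the 2°/400
ladder the realized acceptance is ≈0.5, and the move provably preserves
each window's stationary law (KS-tested against no-exchange runs).
Independent trajectories draw per-walker substreams from a counter-based
seed sequence; the campaign and every kernel are bit-reproducible for a
given seed.

The first-passage oracle runs independent walkers from the reflecting
boundary (mirror reflection) to the absorbing one at Δt = 0.01 ps; walkers
hitting the step cap are censored and more than 1% censoring raises.  At
this timestep the oracle agrees with quadrature on the true landscape to
~1%, dominated by absorbing-boundary discretization.

What the generator does *not* emulate: memory effects (generalized Langevin
kernels), anisotropic or multidimensional flipping pathways, force-field
specifics, and the slow conformational couplings of real DNA–protein
systems.  Passing recovery tests therefore demonstrates the correctness of
the estimators under their own assumptions — not that 10 ns of all-atom
sampling per window suffices for a converged experimental prediction.

## Problem sizes

The headline recovery suite uses the full study geometry — 180 windows,
2° spacing, −320°…38° — with 10⁵ stored samples per window and a
10⁴-walker oracle (≈1 min on one CPU); unit fixtures use 92 windows ×
10⁴ samples.  Convergence tables use 2–5 segments.  These sizes are the
package's defaults and are deliberately desk-scale; all tolerances
(0.3 kcal/mol PMF RMS, 10% diffusivity, 15% passage time, |ln K ratio| <
0.2) are met with factor-of-several margin at these sizes.

## Known limitations

* WHAM evaluates the bias at bin centers; with very stiff biases the far
  tails of a window (≳3σ) carry a visible discretization bias, which is why
  flatness checks restrict to well-populated bins.  Finer bins remove it.
* The state ΔF of a *partial-coverage* campaign is truncated at the window
  range: K_thermo is then only directionally comparable with K_kin.
* MBAR is not implemented (WHAM histograms only); error bars on the profile
  are limited to segment RMSD, not bootstrap.
* The FEP module estimates a one-directional exponential average; poor
  reference/target overlap shows up as hysteresis but is not repaired
  (no multistate reweighting).
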