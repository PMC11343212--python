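# Methods

## The coarse-grained filament model

F-actin is represented as one spherical particle per subunit, placed on the
genetic (short-pitch) helix of the canonical filament: subunit *i* at
cylindrical coordinates (r = 25 Å, φ = i·(−166.67°), z = i·27.8 Å).  The
centroid radius is not fixed by the helical symmetry; 25 Å approximates the
centroid radius of an actin protomer and is configurable.  Consecutive
subunits lie on opposite long-pitch strands, so (i, i+1) bonds are
"lateral" (inter-strand) and (i, i+2) bonds are "axial" (intra-strand).

The potential is

    V = Σ ½ k_l (l − l₀)²  +  Σ ½ k_θ (θ − θ₀)²  +  Σ k_φ [1 − cos(n φ − φ₀)] ,

with harmonic bonds over the (i, i+1) and (i, i+2) pairs, harmonic angles
over all six vertex-centered triplets formed by each particle's four bonded
neighbors, and n = 1 dihedrals over one quadruplet per particle along each
helical path — the genetic helix (i, i+1, i+2, i+3) and the long-pitch
strand (i, i+2, i+4, i+6).  All rest values (l₀, θ₀, φ₀) are measured on
the generating lattice, which is therefore the exact zero-energy state.
Protomer deformations and nucleotide-state transitions are not modeled.

Internal units: nm, pN, pN·nm, ns, K (k_B T ≈ 4.11 pN·nm at 298 K).
Masses are nominal and equal; only configurational statistics are
interpreted, so the time axis is internal simulation time, not a
hydrodynamic mapping.

### The bending-tapered torsion potential

The plain cosine dihedral is ill-defined where three consecutive beads of a
quadruplet become collinear: the dihedral angle jumps by π there, so the
energy is discontinuous and the force diverges like 1/|b₁×b₂|.  For this
lattice that region is *always nearby*: the long-pitch strand quadruplets
have arm angles only ≈ 5.4° from collinear at rest, and thermal bending
crosses the singularity constantly.  Each crossing injects O(k_φ) of
energy, which heats and eventually destroys a run at any affordable time
step.

Production dynamics therefore use a bending-tapered torsion, in the spirit
of the combined bending–torsion potentials used for coarse-grained
polymers:

    V_φ = k_φ · W · [1 − cos(n φ − φ₀)],
    W   = Π_arm [ s² / (s² + ε) ] / W₀ ,   s = sin(arm angle),  ε = (s_rest/2)² ,

normalized so W = 1 at the rest geometry.  W vanishes smoothly (∝ s²)
through collinearity — exactly where φ itself is discontinuous — and is
bounded above by 1.5625, so bending can never amplify torsional rigidity.
At equilibrium the tapered and plain forms have identical energy, gradient
and curvature, so static calibration is unaffected; away from equilibrium
they differ (e.g. the measured stretch stiffness shifts by a few percent),
and all calibrated constants reported here are for the tapered model.  The
plain cosine form remains available (`dihedral_mode="cosine"`) and is
cross-checked against a literal term-by-term transcription oracle in the
tests.

### Integration

Langevin dynamics use BAOAB splitting; with the thermostat off the
integrator reduces to velocity Verlet (vacuum).  The default time step is
1/20 of the fastest harmonic period obtained by power iteration on the
Hessian at the start configuration; because the taper still steepens under
large deformations, the production defaults hold extra margin below the
*empirical* stability edge: dt = 0.002 ns for thermal and protocol runs
(stable across the calibration grids; verified by kinetic-energy audits
against equipartition), 0.0005 ns head-room settings are used in the
stability tests.  Divergence (any coordinate beyond 10⁵ nm) raises an
error naming the step.

## Calibration

Stretch stiffness: the 39-subunit filament is loaded with total axial
tensions of 5–25 pN (first five subunits fixed, last five loaded), each
relaxed to mechanical equilibrium by L-BFGS with analytic gradients (the
deterministic, overdamped zero-temperature limit; warm-started along the
tension ramp), and the least-squares slope of force versus extension
(loaded-group centroid minus fixed-group centroid, projected on the
initial axis) is the stiffness.  A (k_l, k_θ) grid scan selects the point
nearest the reference values 37 pN/nm (ATP state) and 31 pN/nm (ADP
state).  The default grid (k_l = 290–400 pN/nm in steps of 10, k_θ ∈
{100, 200} pN·nm/rad²) brackets both targets to well under 2%.

Twist variance: the 100-subunit filament is thermalized at 298 K
(friction 0.5 pN·ns/nm) and the per-interface twist measured on every
saved frame with the midpoint-projection algorithm (below).  The deviation
from −166.67° is squared and averaged per subunit — the zero-mean normal
fit — with the first and last 20 subunits excluded, and the cumulative sum
taken along the subunit index.  A (k_φ, k_θ) scan minimizes the
least-squares distance between simulated and reference cumulative-variance
curves.  The packaged reference is generated by the simulator itself (the
experimental reference curve is not available in numeric form); a real
curve can be supplied as CSV.  Self-consistency recovery of the generating
(k_φ, k_θ) from an independently seeded reference succeeds at grid
resolution with a ≈ 4× cost margin at 240 k steps per grid point.

Calibrated production parameters (repo-derived): ATP state k_l = 370,
k_θ = 100, k_φ = 150 (37.2 pN/nm, thermal twist SD ≈ 3.4°/interface);
ADP state k_l = 290 (30.8 pN/nm).  The ATP set drives the force-protocol
runs; which nucleotide state parameterized the original production runs is
not stated, and the ATP choice is the package's own.

### Twist measurement (midpoint projection)

Centroids of consecutive subunit pairs are joined into segments; midpoints
of neighboring segments, joined again, form the axis polyline.  Each
consecutive-subunit pair is projected onto its nearest axis segment and
the twist is the signed angle between the two projection vectors about
that segment.  Only interfaces with a covering axis segment are reported
(pairs 1 … n−3): the two terminal interfaces have systematically biased
projection geometry (≈ 0.7°) and are dropped, mirroring the terminal-
subunit exclusion of the variance analysis.  On the canonical lattice the
estimator is exact to < 0.01°.

The estimator low-passes the axis, so twist fluctuations at the interface
Nyquist frequency are attenuated (white per-interface noise is recovered
at ≈ 38% of its variance; noise correlated over ≳ 4 interfaces — the
realistic thermal case — is recovered within 2%).  The synthetic
twist-noise trajectories used for validation are band-limited accordingly.

## Force protocols

The study conditions: first five subunits fixed, 5 pN per particle on the
terminal five subunits (25 pN, one-myosin scale), tension pulling away
from the fixed end along the initial axis and compression pushing toward
it, direction held fixed.  The production filament is scaled down from 400
to 120 subunits (~330 nm); per-phase durations (100 ns apply / 150 ns
release internal time; 150 ns for constant loads) were chosen once, on the
compression protocol, as long enough for the buckling instability to
develop and settle.  Constant-load runs use friction 0.5 pN·ns/nm;
transient runs use 0.05 so that elastic recoil after release is
underdamped — the regime in which transient tension produces spiraling
during recoil.  Compression runs keep the thermostat on (at 298 K) so
buckling can nucleate from thermal fluctuations.

Spiral scoring: the central axis (midpoint construction) is decomposed by
PCA; the amplitude is the maximum |PC2| projection and a filament is
spiralling when the steady-state median amplitude exceeds the 15 nm
significance cutoff.  Wavelengths are read from the first autocorrelation
peak (Gaussian blur σ = 2 nm) of the PC2-versus-PC1 signal, with a
least-squares cosine fallback when less than about one period fits in the
filament; the per-phase wavelength is the median over the first
significant frames, i.e. the wavelength of the *emerging* superhelix —
on a 330 nm filament post-buckling coarsening otherwise grows the
wavelength toward the filament length within tens of ns.

Observed phenomenology at these conditions (recomputed by the tests):
constant compression buckles into a superhelix (median amplitude ≈ 20–25
nm); constant tension stays at thermal amplitude (≈ 4 nm); transient
tension spirals only during release; transient compression spirals remain
above the cutoff after force removal; emerging compression wavelengths
(~60–150 nm) are shorter than tension-release wavelengths (~120–310 nm);
spiral cross-sections are elliptical (PC2 > PC3 amplitude).

## Trace analytics

Marker traces are fitted with a smoothing spline (scipy `s` convention on
nm coordinates; default budget 150 nm², absorbing roughly 0.5–1 nm of
manual-picking jitter over a few hundred markers) and resampled evenly at
9.6 Å.  Curvature and torsion come from derivatives of the resampled
curve; for closed-form oracle checks the smoothing is set to zero, since
any nonzero budget attenuates genuine curvature of noiseless input.

Oscillatory segments (350–500 nm, ≥ 2 sign changes of curvature above
1.5 μm⁻¹) are PCA-decomposed and aligned: the PC2 sign is fixed so the
maximum-amplitude extremum is a trough (positive second derivative),
inverted decompositions are flipped by reversing traversal, and a common
350 nm window is imposed, sliding inside the trace when the extremum sits
near an end.  Wavelength: first autocorrelation peak of the PC2 signal
resampled on a uniform PC1 grid (arc length over-counts by the local
transverse slope), overlap-normalized to avoid the triangular-taper bias
and refined by a local cosine fit (the raw peak is biased by a few percent
at two observed periods).  Amplitudes are half the peak-to-peak range
(insensitive to the non-integer-period mean offset); the phase offset is
the parabolic-refined cross-correlation lag between PC2 and PC3 divided by
the wavelength, folded into [0, 0.5] — exactly ¼ for an ideal superhelix.
Polarity is never assigned; all statistics are invariant under rigid
motion and traversal reversal.

The ice-plane angle projects the plane normal (PC3 of marker points in
surrounding amorphous density) out of the segment's PC1 and measures the
angle between the segment's PC2 and the plane (0° in-plane, 90° along the
normal).  The KS test against a normal reference supports both fitted and
standard parameterizations, since the reference is not further specified.

## Curvature model

The thermal curvature distribution of an unloaded segment follows the
worm-like-chain Boltzmann weight P(κ) ∝ exp(−α L_p L κ²/2) over κ ≥ 0 —
a half-Gaussian with scale 1/√(α L_p L); the exponent is negative as the
bending energy E = ½ k_B T L_p L κ² requires (the distribution is
strictly decreasing with its mode at zero).  α is a dimensionless
adjustment acting as a proxy for an effective persistence length; its MLE
is the closed form α = 1/(L_p L ⟨κ²⟩), cross-checked against a scalar
numeric optimizer.  The default grid discretization is 0–20 μm⁻¹ at 0.05,
with an analytic continuous mode for cross-checks.

## Segmentation picker

Pipeline order (fixed): binarize at 0.3 → skeletonize → dilate 8 px (link
broken ends) → re-skeletonize → prune branches < 8 px → remove 16 px
disks at junctions → join fragments across removed junctions (pairs
minimizing the tangent discontinuity among facing endpoints) → per-track
spline.  Track centerlines are refined to sub-pixel accuracy before
curvature estimation: each point moves along its local normal to the
vertex of a parabola fitted to the log-intensity profile (exact for a
Gaussian cross-section), with a quadratic Savitzky–Golay smoothing pass
per iteration — without it, independent per-point normal shifts grow a
zigzag instability.  Signed curvature (positive = left turn from the
lower-index endpoint) is sampled every 3 px, terminal 50 px omitted, by a
local quadratic fit over a 24 px window: at 4.32 Å/px the ±1.5 μm⁻¹
criterion corresponds to sub-pixel sagitta over a 200 Å run, far below
what spline second derivatives at skeleton precision can resolve.  A
filament is superhelical iff it sustains ≥ 200 Å runs of curvature ≥ +1.5
and ≤ −1.5 μm⁻¹; picks are sampled every 100 Å (the pre-suppression
spacing is not otherwise constrained) and thinned per filament by greedy
non-maximum suppression scanning in along-filament order with an 830 Å
minimum separation.  Output is a RELION-style STAR coordinate loop plus a
CSV mirror.  Input maps are TIFF or in-memory arrays.

## Subdomain displacements

Protomer C-alpha models are superposed by Kabsch least squares with the
reflection branch rejected (a mirrored model reports a large residual
instead of silently inverting chirality); by default all shared residues
align, with a subset option.  Displacement vectors (model − reference) are
averaged within the standard subdomain residue ranges 7–35, 35–72, 72–147,
340–377, 147–183, 272–340, 183–272, kept exactly as stated, so boundary
residues contribute to two ranges.  The 15× display scaling seen in
figures is a plotting convention and is never applied to data.

## Synthetic data

Generators are pure functions of parameters and a mandatory seed, each
attaching its ground truth: superhelix/planar-arc/straight traces (default
marker jitter σ = 1 nm, the tracing-jitter scale); modulated lattices with
per-interface rise/twist programs and optional curved axis paths (subunits
placed in parallel-transported frames); 2D segmentation maps rasterized
with Gaussian cross-sections of 18 px FWHM (≈ 80 Å filament diameter at
4.32 Å/px) so the 0.3 threshold and the centerline refinement are
meaningful; half-Gaussian curvature samples; band-limited twist-noise
trajectories; synthetic protomer C-alpha blobs with programmed subdomain
shifts (labelled synthetic — they are not an actin fold).

What passing on synthetic data does not show: the generators contain no
missing-wedge anisotropy, no CTF or detector noise, no segmentation-
network artifacts, and filament crossings are sparse; real maps and traces
will degrade the picker and the trace statistics before they degrade the
geometry code.

## Problem sizes and limitations

Simulations are desk-scale: 39 subunits (calibration), 100 (thermal twist),
120 (force protocols, down from 400), with 5 seeds per protocol condition.
Bending rigidity is emergent, not calibrated — only stretch and twist are
matched — so absolute wavelengths and amplitudes are not expected to match
the experimental values quantitatively; only orderings and qualitative
phenomenology are asserted.  There is no excluded volume or filament
self-contact, no hydrodynamic coupling, and no explicit myosin; forces act
along a fixed initial axis.
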