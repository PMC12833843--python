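# Methods

## Scope and units

The package analyzes solution trajectories of carbohydrate-like solutes:
ordered frames of coordinates with an orthorhombic periodic cell and time
stamps. Internal units are Å, ps, amu and K. Diffusion coefficients cross
every API boundary in 10⁻⁹ m²/s (1 Å²/ps = 10 × 10⁻⁹ m²/s, exactly);
k_B = 1.380649 × 10⁻²³ J/K and N_A = 6.02214076 × 10²³ /mol are the SI
exact values. Only orthorhombic cells are supported — the target systems
are cubic — and triclinic input is rejected explicitly. Atom indices are
0-based everywhere, including grouping files.

The reference study conditions baked into defaults are: 20 solute copies
in a 664,424 Å³ cubic cell (≈87.35 Å edge, 50 mM), frames every 10 ps,
298 K, and three solvent viscosities — experimental water
0.00089 kg m⁻¹ s⁻¹, TIP5P 0.0007, OPC 0.00079.

## Diffusion estimation

Per-solute center-of-mass paths are extracted from an *unwrapped*
trajectory (atoms unwrapped independently by minimum-image frame-to-frame
increments; an apparent jump of half a box or more aborts with the frame
and solute named, since it cannot be resolved). `compute_msd` refuses
trajectories that still look wrapped (a center-of-mass jump above half a
box).

MSD defaults to averaging over all time origins, computed per solute with
the FFT autocorrelation identity (O(F log F)), then averaged over solutes
and, when replicates are supplied, over replicate curves before fitting —
per-replicate fits are retained for dispersion estimates. A
single-origin mode computes the plain ⟨|r(t) − r(0)|²⟩ definition
literally. D is the ordinary least-squares slope over a lag window
divided by 6 (three dimensions). Choices made where the protocol was
genuinely open:

- **Fit window.** Default [10%, 50%] of the maximum lag, configurable:
  the short-lag region is not yet diffusive and the long-lag tail of a
  windowed MSD has few independent origins. In the validation and
  acceptance runs the MSD is truncated at 25% of the trajectory length
  before fitting, which keeps the whole window in the well-averaged
  regime; with 20 solutes × 10 replicates × 2000 frames this recovers a
  known D within ~3% (the test bound is 5%).
- **Regression.** Unweighted with a free intercept by default; a
  through-origin option exists. A negative fitted slope is flagged on the
  estimate, never silently corrected.
- **Drift removal.** Subtracting the ensemble center-of-mass motion is
  off by default and flag-enabled; for well-behaved NVE-style input the
  drift is negligible and removing it silently would hide problems.
- The squared-displacement ensemble average is the standard second
  moment; the slope relation D = MSD/(6t) and the Stokes–Einstein
  conversion fix all units.

`finite_box_correction` adds the cubic-lattice hydrodynamic self-term
k_B T ξ / (6 π η L) with ξ = 2.837297 as an explicit, optional step —
never applied implicitly. `welch_t` (two-tailed, Welch–Satterthwaite
degrees of freedom) compares replicate estimates; it delegates to
scipy and is oracle-tested against the textbook formula.

## Solvation analysis

`compute_rdf` histograms minimum-image distances from a solute's
geometric center (unweighted mean; a mass-weighted option exists) to all
water oxygens, normalized by ρ · shell volume with ρ = n_waters/V
averaged over frames. Default bin width 0.05 Å; r_max may not exceed half
the smallest box length.

First-shell statistics are located on a Savitzky–Golay smoothed copy of
g(r) (window 11 bins, polyorder 3) with a prominence threshold (default
0.05 in g units), so single-bin noise and smoothing overshoots cannot
pose as extrema; peak height and minimum value are read off the raw
curve. N1 integrates 4πρ g(r) r² to r_min *exactly bin by bin* (the
histogram makes g piecewise constant, so each bin contributes
ρ g_i × its shell volume, with a partial shell for the bin containing
r_min). This makes a constructed shell of k waters integrate to exactly
k, and the ideal-gas null model match (4/3)πρr³ to well under 1% at
realistic sample sizes.

Occupancy maps deposit one normalized isotropic Gaussian (σ = 1.0 Å by
default, of the order of a water oxygen van der Waals radius; truncated
at 4σ) per water oxygen per frame on a cubic grid (default 25 Å edge,
0.25 Å spacing) centered on the solute, then average over frames; the
grid integral therefore equals the mean water count inside it. Frames
are first superposed on the solute (translation + Kabsch rotation;
degenerate solutes fall back to translation only), since the map is a
solute-frame density; alignment is switchable off. Visualization
cutoffs (3.6/3.8/4.0% of maximum) are exported as isovalue metadata
only — rendering is out of scope.

## Aggregation

Two solutes are in contact when any atom of one is within 2.85 Å of any
atom of the other (minimum image; the cutoff comes from the
nearest-approach distance of methanol oxygens in liquid methanol).
Hydrogens count by default ("any atom"); a heavy-only flag exists.
Contacts are found with a periodic KD-tree and verified in tests against
a brute-force all-pairs scan. Aggregates are connected components
(scipy csgraph; BFS oracle in tests).

Persistence semantics were genuinely open and are a declared choice:
an *event* is a maximal run of consecutive frames in which an identical
membership set is a component; any gain or loss of a member terminates
the event and starts a new one; events shorter than 2 frames (20 ps at
the default spacing) are discarded as transient encounters. An
alternative reading — filtering individual edges by persistence before
clustering — is noted but not the default, because membership-run
semantics make lifetimes well defined. Free monomers are counted per
frame from singletons, without subtracting members of discarded events
(also a declared choice; the source protocol is silent). Mean aggregate
size S is frame-weighted over surviving events. Solute conservation
(singletons + aggregate members = total) is asserted every frame.

## The hydration model

The empirical layer treats the hydrodynamic sphere as the bare-solute
sphere of radius R_g plus entrained waters of 30 Å³ each:

- N_W = (4/3)π(R_H³ − R_g³)/V_w, and its exact algebraic inverse
  R_H = cbrt(3 V_w N/(4π) + R_g³) (round-trip property-tested to 1e-12);
- N defaults to 1.1 × N_PA, with N_PA the polar-atom count: hydroxyl,
  ring, glycosidic and ether oxygens weigh 1; carboxylate, amide and
  ester groups weigh 2;
- D follows by Stokes–Einstein in experimental water (0.00089 kg m⁻¹ s⁻¹,
  298 K) — the prediction is compared against NMR, so the real solvent's
  viscosity is the right one — overridable per solvent model.

Negative N_W (R_g > R_H, extended polymers) is reported with a warning,
never clamped: it flags that the spherical-envelope picture has broken
down, as it does for chains like dextran or hyaluronic acid. The model is
not meant for large, non-globular polysaccharides, where R_g³ dominates
and the prediction collapses to R_H ≈ R_g.

The packaged reference tables (18-row radii and diffusion tables, 10-row
hydration table, and the polar-atom bookkeeping) are shipped as
checksummed CSVs; analyses recompute derived quantities from them rather
than editing them in place. Polar-atom counts absent from the source
hydration table are derived rows applying the group rules, marked as such
with provenance notes. The tabulated disaccharide counts are internally
inconsistent about the glycosidic oxygen (trehalose/sucrose count it,
lactose/maltose/cellobiose do not); the package stores the tabulated
convention and documents both. Mean waters-per-polar-atom ratios are
computed from unrounded per-row ratios before final rounding. Two cells
of the reconstructed tables (maltotriose, cellotriose) differ by 0.01
from the tabulated empirical values because those were evidently computed
from unrounded inputs; reconstruction reports flag rather than force
those cells. Predictions default to the TIP5P R_g column; the OPC column
differs by ≤0.01 Å and is available.

## Synthetic data: what it does and does not show

The generators stand in for the all-atom MD the estimators were designed
for, at desk scale and with exact ground truth:

- **Brownian walks** (20 single-pseudo-atom solutes, box 87.35 Å,
  Δt = 10 ps, per-dimension step variance 2 D Δt) validate the entire
  MSD → D chain including unwrap and unit conversion. They contain no
  hydrodynamic interactions, no solvent, no aggregation and no
  subdiffusive short-time regime, so passing recovery tests shows
  estimator correctness, not force-field realism.
- **Ideal solvent** (uniform i.i.d. water oxygens) is the exact g ≡ 1
  null: RDF flatness and the N1 closed form are sharp tests of
  normalization and quadrature, but say nothing about real water
  structure.
- **Constructed aggregates** place dumbbell solutes with nearest-atom
  gaps exactly at the requested contact distance and a controllable
  per-frame presence pattern, so size distributions, lifetimes and the
  persistence filter are checked against construction arithmetic,
  exactly.
- **Rigid bodies** carry an analytically evaluated R_g.

All generators are pure functions of their integer seed. Absolute
solvation-shell and aggregation numbers for real carbohydrates (e.g.
first-peak heights or free-monomer concentrations in specific water
models) require the original MD ensembles and are deliberately not
reproduction targets here.

## Numerical choices and limitations

- FFT MSD and the direct estimator agree to 1e-9 Å² on test paths.
- Trajectory round-trips through extended-XYZ preserve coordinates to
  1e-3 Å (6-decimal output); grids round-trip through cube/DX to 1e-6.
- Unwrapping assumes no atom legitimately travels ≥ L/2 between frames;
  the Brownian generator refuses specs whose step σ ≥ L/4 for the same
  reason.
- Minimum-image displacements use the floor convention, giving the
  half-open interval [−L/2, L/2).
- The contact KD-tree wraps coordinates into [0, L) and maps boundary
  hits to 0 to satisfy the periodic tree's domain requirements.
- Validation problem sizes (2000-frame, 10-replicate ensembles; 10²–10³
  waters for solvation tests) were chosen so the statistical bounds in
  the test suite are comfortably sharp at interactive runtimes.
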