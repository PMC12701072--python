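# Methods

This note documents the models, conventions, and numerical choices behind
`wrapkit`, and what the synthetic fixtures do and do not establish.

## Scientific setting

A face-to-face (FtF) histone tetramer presents four DNA-binding regions
around its perimeter: two **A-sites**, each formed by the β-bridge loop
residues of two monomers that meet across a tetramerization interface
(T27/G29 in loop l1, T56/T57 in loop l2, flanked by K54 and R59), and two
**B-sites**, each centered on the paired-end-of-helices motif at the α1
N-termini of a dimer (A13/S14/K15, flanked by K17 and K21).  DNA can either
**bridge** the tetramer — two separate duplexes resting on the two B-sites —
or **wrap** it, a single duplex engaging all four sites on a closed path.
The package quantifies which regime a structure or trajectory is in, and
what it costs to leave it.

## Conventions and definitions

**Binding contact.** Any protein/DNA heavy-atom pair within 4.0 Å,
*inclusive* at the boundary (an exactly-4.000-Å pair counts).  Heavy means
element ≠ H and ≠ D.  Contacts are atom pairs, not residue pairs; a
residue-level mean is reported separately.  Distances are plain Euclidean;
periodic images are a caller concern (fixture trajectories carry no box).

**Binding fluctuation.** δ_t = c_t − c̄ where c̄ is the mean contact count
over all frames; Σδ_t = 0 by construction.  Smoothing is a centered moving
average with truncated edge windows (default window 100 frames; even
windows are widened by one to stay centered).

**Hydrogen bonds and salt bridges.** Donor–acceptor distance ≤ 3.5 Å with a
D–H···A angle ≥ 120° when hydrogens are available, distance-only otherwise;
salt bridges use a charged-group N/O distance ≤ 4.0 Å with no angle term.
A pair is *persistent* at ≥ 50% frame occupancy.  All three thresholds are
parameters of `HBondCriteria`; the defaults follow common MD practice.

**DNA backbone.** Phosphate (P, OP1, OP2, O5', O3') plus sugar
(C1'–C5', O4') heavy atoms; bases are excluded from backbone RMSD because
wrapping-mode binding is dominated by backbone contacts.  The three classes
partition DNA heavy atoms exactly, which the tests enforce.

**DNA-backbone RMSD series.** Each frame is first superposed on the
reference over the protein heavy atoms (Kabsch), then RMSD is evaluated
over the DNA backbone — DNA motion relative to the protein, not tumbling.

**Tetramer planarity.** The dihedral over the four heavy-atom monomer
centroids ordered (dimer1.monA, dimer1.monB, dimer2.monA, dimer2.monB),
with dimer2.monA the monomer facing dimer1.monA across a tetramerization
interface.  A planar tetramer reads ±180°; collinear centroids give NaN.

**Helix crossing angle.** Each helix axis is estimated from the ordered Cα
trace via the cross products of successive radial bisector vectors
u_i = p_i − 2p_{i+1} + p_{i+2}, which are exactly perpendicular to the axis
of an ideal helix, making the recovery exact for noiseless constructions at
any sampling phase (a PCA axis carries an O(0.1°) phase bias on short
helices).  The angle is folded to [0°, 90°]; antiparallelism is reported
separately.

**Wrap coverage.** A base pair is wrapped when ≥ 1 of its heavy atoms lies
within the contact cutoff of a protein heavy atom.  Besides the count, the
longest contiguous run and the angular coverage are reported; the latter
sums occupied 10° sectors of wrapped-bp centers around the protein's
smallest principal axis (the tetramer's symmetry axis when DNA wraps in the
tetramer plane).

**Free-energy landscape.** F(x, y) = −kT ln(P/P_max) over a 2-D histogram
of two collective variables; empty bins are NaN, never ∞, so arithmetic
comparisons stay defined.  kT defaults to 2.577 kJ/mol (310 K), with the
temperature configurable.  The minimum basin is described by the location
of P_max, its area at F < 1 kT (configurable threshold), and a depth taken
as the median of defined F outside the basin.  F is invariant under global
rescaling of counts (longer sampling of the same density); the default CV
pair used in examples is (DNA-backbone RMSD, total contact count), a choice
the caller can replace freely.

**Work and barriers.** W(ξ) is the trapezoidal integral of the applied
force over the pulling coordinate.  dW/dξ is smoothed (shared
`SmoothingParams`), stretches where it exceeds 5% of its maximum (default)
are single candidate barriers, and each barrier's height is measured
plateau-to-plateau — from the midpoint of the preceding quiet gap to the
midpoint of the following one — so truncated force tails are not lost; this
is exact for staircase work profiles.  A barrier is attributed to the site
whose contact count drops most across that interval.  The reported
landscape is raw cumulative work from a single trajectory, not a PMF
estimate; Jarzynski/Crooks averaging over work ensembles is out of scope.

**Release order.** A site is released at the first ξ where its (optionally
smoothed) contact count falls below threshold × (its mean over the first 10
samples) and stays below for a dwell window (default 5 samples); sites that
never engage are excluded.  The threshold default is 0.25; a threshold of
1.0 degenerates to "first downward fluctuation", which the tests document.

**Residue energy decomposition.** E_i is the frame-mean of Coulomb
(k_e = 1389.35 kJ mol⁻¹ Å e⁻², relative dielectric configurable, default 1)
plus Lennard-Jones (Lorentz–Berthelot combination) over residue-i/DNA atom
pairs within a 12 Å cutoff.  Per-atom charges and LJ parameters are caller
inputs — typically parsed from a simulation topology; the package never
invents force-field parameters.  Fractions are reported on |E_i| of the
attractive residues, and Σ E_i is verified against a single-pass total.
Because any such decomposition is method-sensitive (cutoff, dielectric,
missing reciprocal-space terms), published percentage shares should be
compared qualitatively, not digit by digit.

**Masses.** Average (not monoisotopic) masses.  Peptides: Σ residue masses
+ 18.0153 Da.  DNA: Σ nucleotide-monophosphate residues + water, minus one
HPO₃ (79.98 Da) per strand under the default 5'-OH convention appropriate
for synthesized oligos; the 5'-phosphate convention is a switch (it shifts
a 30-bp duplex by ≈ 160 Da).  Complex masses are stoichiometric sums and
are reported beside measured masses as percent deviation.

**Shine–Dalgarno scan.** The SD motif (default AGGAGG, the anti-SD
complement) is slid over spacings of 4–14 nt upstream of each candidate
start; the score is the longest contiguous positional match, and scores ≥ 5
are flagged strong.  Starts other than ATG/GTG/TTG are scored with a
warning.  Motif, window, and threshold are parameters.

**Ladder densitometry.** Peaks are local maxima above median + 3×1.4826·MAD
with a 5%-of-maximum prominence guard, refined to sub-pixel positions by a
three-point parabola.  Calibration is a linear fit of log₁₀(size) against
marker migration, required to be monotone; sample sizes are interpolated
with uncertainties propagated from calibration residuals, and peaks outside
the marker range are flagged as extrapolated.

**TPM fit.** RMS(c) = RMS_min + (RMS₀ − RMS_min)/(1 + (c/c_½)^k), a
4-parameter logistic; saturation is reported at 95% of the total drop,
c_sat = c_½ · 19^{1/k}.  Flat data return a flagged degenerate fit rather
than raising.

**Isotherm fit.** A ligand-depletion-aware 1:1 quadratic (with the probe
concentration as input; a trace-probe limit when omitted) and a Hill
variant are both fit; AIC selects the model.  Titrations spanning < 2
decades only bound K_d and are flagged.

## Idealized B-DNA builder

Nucleotides are rigid heavy-atom templates (full backbone and ring
topology with approximate internal geometry) placed per base pair by a
rigid transform: along a straight axis with per-step rise and twist, or
along a circular arc (curvature κ) with arc-length spacing *h* and the
twist applied about the local tangent.  Strand 2 is the exact reverse
complement, generated by the pseudo-dyad (x, −y, −z).  5'-termini carry no
phosphate.  Defaults are fibre-B (h = 3.4 Å, Ω = 36°/bp); a 10.5 bp/turn
dialect (Ω ≈ 34.3°) is a parameter choice.  Because every downstream metric
uses heavy-atom positions and atom-name classes only, simplified internal
geometry is sufficient; the builder makes no claim of force-field accuracy
and no energy minimization or sequence-dependent base-step parameters are
applied.

Rise and twist are *recovered* from a built duplex by superposing the sugar
template onto each base pair (exact rigid-frame recovery), refitting the
axis curve (line, or plane + algebraic circle fit — exact for exact data),
and reading the rise as inter-frame spacing along the curve and the twist
as the residual rotation about the local helix axis after parallel
transport.  This inverts the construction exactly, and the tests hold it to
1e-6.

**Model assembly.** Interface templates are superposed onto the target
tetramer through atoms shared by (chain, residue, atom name); their
transformed DNA centroids become anchors.  Wrapping mode fits a circle
through the anchors in the tetramer plane, grows it to the closure radius
n·h/2π if the anchors sit tighter than a single turn can wrap, lays one
continuous curved duplex along it, and steps the radius outward (0.5 Å)
until the protein–DNA heavy-atom minimum distance clears 2.0 Å.  Anchors
whose radial spread exceeds half the fitted radius are rejected — the
reconnection would require an implausible kink.  Bridging mode gives each
of exactly two templates its own straight duplex along the template DNA
axis, pushed outward until clash-free and mutually separated by > 4 Å.
Tetramer coordinates pass through bit-exact.

## Crystallographic symmetry expansion

Requires cell and space-group metadata (an explicit error suggests using a
pre-expanded assembly otherwise).  All space-group operators combined with
a lattice-translation search wide enough for the radius plus the structure
extent are applied in fractional coordinates; a copy is kept when ≥ 1 atom
lies within the radius of the seed selection (atom-to-atom, not
center-of-mass), with a 20 Å default radius matching the usual
"symmetry mates within 20 Å" display convention.  Copies receive fresh
chain identifiers; the identity copy is always retained.  Alternate
locations collapse to the highest-occupancy conformer (ties: first in
file); residue and sequence numbering follow the deposited files verbatim.

## Synthetic fixtures: what they emulate, and what they do not

`gen_toy_complex` builds a coarse tetramer — four chains of pseudo-residues
carrying the real site-residue names and numbers, plus an Arg/Asp pair
planted 3.2 Å apart per monomer — around builder-made DNA: a closed 67-bp
arc (wrapping) or two straight 32-bp duplexes at ±25 Å (bridging).
Engaged-site atoms are placed 3.0–3.9 Å from the nearest DNA atom,
disengaged sites at ≥ 6 Å (≈ 8 Å target), and Gaussian jitter (default
σ = 0.3 Å per atom per frame; ensembles default to 200 frames) supplies
frame-to-frame variation.  Requesting all four sites engaged by two
straight segments is rejected as geometrically impossible.  Default SMD
barriers are (15 Å, 500 kJ/mol) at B-site 2 followed by (40 Å, 400 kJ/mol)
at A-site 2 — the two-step unwrapping scenario — realized as Gaussian force
bumps (σ_ξ = 2 Å) whose integrals equal the heights, with co-generated
sigmoidal site-contact drops.  Gel lanes use migration = 900 − 320·log₁₀
(size) pixels with 8-pixel Gaussian bands and the 10–300 bp ultra-low-range
marker ladder; TPM defaults are RMS₀ = 140 nm, RMS_min = 80 nm,
c_½ = 1500 nM, k = 2 (saturating near 6000 nM), and isotherm defaults
K_d = 2 µM.  Every generator is bitwise-deterministic under a fixed seed,
records the seed in its ground truth, and round-trips that ground truth
through JSON.

These fixtures emulate the *statistical structure* the analysis assumes —
planted contacts, known engagement labels, exact integrals, known fit
parameters.  They are not physics: jitter is isotropic and uncorrelated
(real ensembles have collective modes), pseudo-monomers are rigid point
clusters, no thermodynamic consistency links the contact counts to the work
profiles, and gel/TPM noise is Gaussian.  Passing tests therefore
demonstrate that the estimators recover what was planted under realistic
magnitudes — not that any particular biological system wraps DNA.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` run entirely from generated
inputs, in minutes on one CPU: toy ensembles of 20–60 frames (~2800 atoms),
1000-frame brute-force contact cross-checks on 220-atom random frames,
20-seed wrapping-vs-bridging classification at σ = 0.5 Å, 2000-sample
pulling series, and 10-replicate ladder fixtures.  The acceptance script
threads its `--seed` through every generator, so its JSON output is
bit-reproducible for a given seed.

## Known limitations

* The bundled 63-residue histone-like sequence is a synthetic stand-in (see
  `wrapkit.refdata`): residues with experimentally assigned positions are
  pinned, filler composition is histone-like, and its theoretical mass is
  7.1 kDa — adequate for mass arithmetic and plumbing, meaningless for
  sequence-level biology.
* Structure-derived checks (crossing angle, salt-bridge distance, symmetry
  expansion to a tetramer) run against synthetic constructions with planted
  values; re-running them against deposited crystal structures requires
  only `read_structure` plus the same calls.
* No enhanced-sampling reweighting (WHAM/MBAR), no crystallographic
  refinement, no gel-image processing from raw images (lane profiles are
  the input), and no force-field system preparation: the package analyzes
  structures and trajectories, it does not generate physics.
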