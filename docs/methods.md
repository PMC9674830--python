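# Methods

This note documents the models implemented in `qhelix`, their assumptions,
the tunable parameters, and the design choices taken where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Helix–coil model with side-chain H-bond terms

Each residue is two-state (helix h / coil c).  A configuration's weight is

* exp(−ΔG_i/RT) for every helical residue i (ΔG_i from an intrinsic
  propensity scale; default the Pace–Scholtz consensus values in kcal/mol,
  costs relative to Ala),
* exp(−ΔG_nuc/RT) once per contiguous helical segment (nucleation penalty,
  default 2.0 kcal/mol),
* exp(−ΔG_side/RT) for every declared Gln_{i+4} → X_i interaction whose
  window i…i+4 is entirely helical — the side-chain-to-main-chain H-bond
  requires the intervening helical turn to be formed.

Per-residue helical probabilities are marginals of a transfer matrix whose
state is the last four residues (16 states), which is exact for span-5
window terms; `enumerate_profile` (the 2^N Boltzmann sum, capped at N = 15)
is the independent oracle, and the two agree to < 1e-10 on random models.
This is deliberately *Agadir-like*, not Agadir: capping, helix-dipole, pH
and ionic-strength terms are out of scope, so absolute helicities are not
comparable with Agadir outputs; profile *differences* and fitted
interaction energies are the quantities of interest.  Temperature defaults
to 278 K (the usual NMR condition for these peptides).

ΔG_side fitting minimizes RMSD_Hel — the root-mean-square difference
between predicted and observed per-residue helicity — by bounded scalar
minimization on [−2, 0] kcal/mol, tolerance 1e-4.  The supplementary
definition of RMSD_Hel used with real NMR data is not public in the main
text; per-residue RMS is the documented convention here.

Cooperativity enters the synthetic study conditions in two ways.  (i) At
fixed composition, two interactions arranged so the donor of the first and
the acceptor of the second are sequence-adjacent share the shortest joint
helical window, so the concatenated topology always yields the highest mean
helicity — asserted as a property.  (ii) Effective-energy growth with polyQ
tract length is emulated by generating profiles from a model that adds
Gln_{i+4} → Gln_i windows on the tract (−0.15 kcal/mol each) to the four
fixed LQ interactions (−0.4 kcal/mol); refitting with an LQ-only template
then gives an effective |ΔG_side| that grows with tract length.  The
per-bond energies are generator constants, not fitted quantities.

## Scaffold design and motif scanning

The scanned pattern family is Ω-X-X-(Ω-Q-X)^{n−1}-Q-X-X-Q-X-X with
Ω = {L, F, Y, W, I, M} (3n + 6 positions), matching the published n = 4
ScanProsite query character for character.  `design_scaffold` realizes the
pattern with Leu acceptors, Gln donors and Ala at the free (X) positions
(optionally an N-terminal PGAS cap); a control mode replaces acceptors by
Ala, which abolishes both the stabilizing interactions and the motif match.
Guests (binding motifs) may only occupy free positions; collisions are
rejected with the offending index.  Scanning is case-insensitive over the
20 standard letters, counts overlapping matches at distinct 1-based starts
(records-with-≥1-match is the headline statistic, as in per-protein
database reporting), and skips records with non-amino-acid characters with
a warning.  Database querying is deliberately not performed: hit counts are
database-version-dependent and unreproducible; the scanner runs on user
FASTA and is property-tested against a plain regular-expression oracle.

Acceptor ranking is ordinary least squares on z-scored variables: observed
mean helicity against intrinsic helicity (x1) and mean donor Hε21 SASA
(x2).  Standardization makes the betas comparable; the reported ratio
|β_sasa|/|β_helicity| is the "relative weight" statistic.  Note that
z-scoring the response rescales both betas by 1/σ_y, so synthetic-truth
recovery is asserted up to that common factor.  Collinear predictors
(condition number > 1e6) are rejected; out-of-range predictions are clipped
to [0, 1] with a warning.

## Peptide construction and geometry

Backbones are grown by natural-extension-reference-frame placement with
idealized internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
C=O 1.231 Å, N–H 1.01 Å; N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°,
ω = 180°).  Side chains (and HA) are grafted from the ideal CCD residues
bundled with biotite by superimposing N/CA/C, then rotated about their chi
bonds to realize requested angles exactly; amide hydrogens are placed
in-plane on the C(prev)–N–CA bisector.  A rotamer library is deliberately
not used: only dihedrals and coarse geometry are consumed downstream.
The default backbone is (−60°, −40°); geometry fixtures use (−57°, −47°),
where the ideal-geometry i,i+4 H-bond (H···O ≈ 2.1 Å) clears the 2.4 Å
cutoff.

Hydrogen bonds use the distance/angle rule H···O < 2.4 Å and donor-H-
acceptor angle > 120°.  The angle is measured at the hydrogen — the
convention chosen here and used consistently (the alternative, at the donor
heavy atom, is not implemented).  A Gln_{i+4} → X_i contact is flagged
bifurcated when the main-chain N-H and a side-chain Nε2-H of residue i+4
both bond the same O(i).

Rotamer classes use centers m = −60°, p = +60°, t = 180° with half-open
windows [center − 60°, center + 60°); the boundary −120° therefore opens
the m window.  Classification is wrap-invariant.

SASA is Shrake–Rupley on a deterministic Fibonacci sphere lattice (default
960 points, probe 1.4 Å) with Bondi radii (C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20 Å) and amide hydrogens at 1.10 Å so that Hε21 exposure is
meaningful.  Oracles: the closed form 4π(r + 1.4)² for an isolated sphere
(within 1%) and a dense-grid evaluation for two-sphere cases (within 2%).

## Periodic Gaussian mixtures of (χ1, χ2)

EM is modified for periodicity by re-centering every point to the image
nearest the current cluster mean in each iteration — an approximation to a
wrapped-normal likelihood that is excellent for cluster SDs of order 10°
and degrades only for clusters approaching the 360° period (documented
limitation).  Initialization seeds cluster means at rotamer-form centers in
a fixed order (mt, tt, mm, tp, pt, tm, mp, pp, pm — a typical frequency
ordering for helical Gln/Leu side chains; user-overridable).  Convergence:
Δlog-likelihood < 1e-8 or 500 iterations; covariance eigenvalues floored at
1 deg²; clusters with prior < 1e-6 pruned with a warning.  Model selection
fits K = 1…9 and minimizes BIC = p·ln n − 2·ln L with p = 6K − 1.
Side-chain sampling draws χ1/χ2 from clusters with prior ≥ 0.05
(≤ 30 combinations, cluster choice proportional to renormalized priors) and
jitters χ3 around per-cluster centers (5 trials, SD 8°).

## NOESY strip decomposition

Strips are 1D ¹³C sub-spectra of NOE contacts from one ¹⁵N-bound proton.
Back-calculation uses the isolated-spin-pair approximation in the linear
mixing regime: every carbon-bound proton within 6 Å of the owner (in any
pool frame) contributes ⟨r⁻⁶⟩ ensemble-averaged intensity, rendered as a
Lorentzian (FWHM = halfwidth/spectrometer frequency; defaults 14 Hz at
201.2 MHz ¹³C, i.e. 0.070 ppm) at its attached carbon's shift.  Mixing time
(0.4 s) and overall correlation time (2.0 ns) enter as a uniform scale that
R-factor scaling absorbs; a full relaxation-matrix treatment is out of
scope.  The grid is the union of ±0.35 ppm windows around assigned shifts
at 0.005 ppm resolution — regions far from any resonance carry no
information.

The R-factor is Σ|I_obs − s·I_calc| / Σ|I_obs| with s the least-absolute-
deviation optimal scale (weighted median of per-point ratios); it is
scale-invariant and zero iff the strips are proportional.  The original
reference formulation is not public in this form; this definition is the
package's documented choice.

Per-strip decomposition follows the stochastic protocol: the starting
conformer is drawn from the 20 lowest-R conformers; all conformers are
tested in random order and added when they improve R by more than 0.0005;
convergence when a full pass adds nothing or the ensemble reaches 20
members; 100 trials; trials with R above mean + 1.645·SD (the upper tail of
a 90% band) are discarded and the retained trials' members pooled.
Witness strips for a residue are those whose owner proton approaches any
side-chain proton of that residue within 6 Å in at least one pool frame.
The greedy global optimizer alternates (i) adding the conformer giving the
greatest global-R reduction with (ii) per-residue side-chain resampling
from the fitted GMM, accepting a candidate only if it is sterically
acceptable (no non-bonded heavy-atom pair closer than 0.4 Å below the sum
of Bondi radii) and strictly lowers global R; the loop repeats until
neither phase changes the ensemble, the whole protocol runs 20 repeats
(independent RNG streams), and the best repeat is returned.  The R trace is
strictly decreasing at accepted steps by construction.

Identifiability caveat: with the generator's 10° within-class jitter, the
average of several same-class pool frames approximates any single frame to
within ~1% of strip intensity, so recovering *the* generating conformer is
well-posed only when observation noise is below that separation; the
planted-conformer fixtures use 0.2% noise (the mixture-fraction fixtures
are insensitive to this and use up to 2%).

## NMR observables

Decay fits are nonlinear least squares of I(t) = I₀·e^{−t/T} with SDs from
the fit covariance.  R₂/R₁ = T₁/T₂ and the heteronuclear NOE I_sat/I_ref
carry first-order propagated SDs (cross-checked against Monte Carlo).
Rigid-rotor rates use the standard ¹⁵N dipolar + CSA expressions with
J(ω) = (2/5)·τc/(1 + ω²τc²), r_NH = 1.02 Å, Δσ = −160 ppm (the source data
state no values; ratio-type outputs are insensitive to r_NH).  τc is
estimated from plateau ratios by weighted least squares on [0.1, 50] ns.
Reduced spectral density mapping lumps the high-frequency terms at
0.87·ωH (standard convention) and solves the three-point system for J(0),
J(ωN), J(0.87 ωH); errors are propagated by seeded Monte Carlo.

CSPs combine as √(Δδ_H² + (Δδ_N/5)²).  K_D fitting selects the top 10% of
peaks by final-point CSP (at least one), then fits one global K_D with one
Δδ_max per peak to the exact 1:1 quadratic isotherm; the inner Δδ_max solve
is linear, so the fit is a 1-D profile over log K_D (bounded, tolerance
1e-6 decades).  Monte-Carlo intervals refit with protein and peptide
concentrations perturbed by uniform ±20% factors (a Gaussian mode is a
one-line change; uniform is the documented reading of "within 20%
errors").  Fits pinned at the K_D bounds or with a flat profile are flagged
unidentifiable with an interval unbounded above.  Coverage calibration uses
titrations with 30 peaks so the top-10% rule keeps a realistic handful.
RDC agreement scales predicted couplings by least squares and reports
Q = rms(D_obs − s·D_pred)/rms(D_obs).

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their arguments and a seed (bitwise
reproducible), zero-noise outputs satisfy the generating equations to
machine precision, and every planted truth is returned in a machine-
readable record.  Noise is everywhere additive Gaussian with SD a fraction
of the maximum clean signal, matching the least-squares error models used
downstream.  Rotamer-planted ensembles jitter χ angles with a wrapped
Gaussian of SD 10° about class centers, keeping classes separable; decoy
motif sequences are rejected by explicit scanning, never assumed clean by
construction.

What passing these tests shows: the estimators recover known truths under
their own generating assumptions at realistic sizes.  What it does not
show: robustness to force-field error, spin diffusion, peak overlap,
chemical-exchange line broadening, anisotropic tumbling, or real
conformational heterogeneity — none of which the generators emulate.
Ensembles here are idealized helices with rotameric side-chain variation
only; real MD pools also vary the backbone.

## Problem sizes

Fixture sizes were chosen as the smallest that leave clear statistical
margin: helix-coil oracle checks on 100 random models (N ≤ 12); mixture
recovery on 400-frame pools with 60–100 trials; planted-conformer recovery
on 40-frame four-class pools, 10 planted frames x 50 trials; GMM selection
over 50 seeds at n = 500; K_D coverage over 300–500 titrations with
100–150 MC refits each.  The acceptance script prints each quantity with
the problem size it used.
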