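# Methods

This note documents the models, conventions and numerical choices
behind `sclipid`, and what its synthetic test surface does and does not
establish about real membrane data.

## Coordinate model and units

Internal units are fixed: nm, ps, atomic-mass units, kJ/mol, K.
Converters live only at format boundaries (GRO is native nm; PDB
ångströms are divided by 10 on input). Atom ids are 0-based in memory
and 1-based in files, per the GRO/PDB conventions. Only orthorhombic
boxes are supported — every system this package targets is rectangular —
and triclinic box records raise an explicit unsupported-format error
rather than being silently mangled. The z-axis is always the bilayer
normal.

## Density profiles

Profiles use 50 slices by default. Slices partition the *instantaneous*
box height each frame (not a fixed lab frame), because boxes fluctuate
under pressure coupling; atoms are wrapped into the primary box before
binning and assigned by point position (no smearing). Each frame's
slice masses are divided by the instantaneous slice volume and the
per-frame densities are averaged. This makes mass conservation exact:
the summed bin mass equals the selected mass on every frame, a property
the tests assert to machine precision.

By default the frame is recentered each frame so the lipid-species
centre of mass sits at z = 0, removing bilayer drift; whether the
original analysis recentred its profiles is not documented, so the
midplane-centred default is this package's choice and `centering="none"`
is provided for solvent-only boxes.

## Area per lipid, thickness, order parameters

APL is L_x·L_y divided by the lipids per leaflet, per frame, then block
averaged. Thickness is the distance between the maximum-density bins on
either side of the midplane of the ceramide-headgroup profile — argmax
per side, no interpolation or peak fitting, so the resolution is one
bin width (reported alongside the value). A profile with density on
only one side raises rather than returning a half-thickness.

For S_z, cos²θ is averaged over all chain instances and frames *before*
the (3x−1)/2 transform (the ensemble average of the second-Legendre
form); the per-atom formula leaves the averaging order open and this is
the standard reading. Carbon index 1 is the chain carbon nearest the
headgroup (amide/carboxyl end); terminal carbons have no
C_{n−1}→C_{n+1} vector and are excluded. Difference vectors are taken
with the minimum-image convention so wrapped chains are handled.
Because cos² is invariant under z → −z, leaflets pool without sign
bookkeeping. Reported uncertainties are standard errors of per-frame
means — an explicit choice, since "error bars" alone does not fix the
estimator; the same choice (SEM of block means) applies to every ±
value in the package.

## Hydrogen bonds

A donor–acceptor pair is bonded when the minimum-image distance is
**strictly** below 0.35 nm and the angle is **strictly** below 30°
(both thresholds read as "less than"). The angle convention is the
H–D···A reading: vertex at the donor, between the donor→hydrogen and
donor→acceptor directions. The phrase "hydrogen-donor···acceptor angle"
could also denote the angle at the hydrogen; the donor-vertex
convention is adopted here (it matches the GROMACS `hbond` tool whose
counts these analyses mirror) and is the single place the two readings
diverge. Intra-residue pairs are excluded; one donor-hydrogen may bond
several acceptors. Donor/acceptor roles come from a per-atom roles
table (sidecar TSV), not from hard-coded force-field rules.

Neighbour search uses a periodic k-d tree (scipy's `cKDTree` with
`boxsize`, a grid-binned structure with cells ≥ the cutoff) over wrapped
coordinates; the tree query is inclusive at the radius, so the strict
inequalities are enforced by post-filtering. The test suite proves the
detector identical, bond for bond, to an all-pairs brute force with
explicit 27-image enumeration on 100 dense random frames containing
planted boundary-wrapped bonds.

## Free energies

**BAR.** For one λ-window with forward samples ΔU_f (sampled in state
i) and reverse samples ΔU_r (sampled in state i+1), ΔG solves the
Bennett self-consistent equation — equal sums of Fermi functions
f(M + βΔU_f − βΔG) and f(−M + βΔU_r + βΔG), M = ln(n_f/n_r). The left
side is monotone increasing and the right side decreasing in ΔG, so the
root is unique; it is bracketed and solved with Brent's method to
1e-8 kT, working in reduced units internally with kJ/mol at the
boundary. The standard error is Bennett's asymptotic variance
(⟨f²⟩/⟨f⟩² − 1)/n summed over both sample sets. When the two work
distributions share no support the equation is numerically degenerate
(both Fermi sums vanish); this is detected and raised as an
`OverlapError` with the support gap in the message rather than
returning an arbitrary root. Window totals add; variances add across
windows (independent simulations); mixed temperatures across a chain
are an error. Samples are used as given — no statistical-inefficiency
subsampling is applied by default, matching the protocol the package
mirrors; callers can stride their input if their samples are strongly
correlated.

**log P.** The rendered partition-coefficient equation is reconstructed
from its prose definitions: with ΔG_hydration the free energy of
removing the solute *from water* and ΔG_solvation of removing it *from
octanol*, the stated sign semantics (more negative = more hydrophilic,
0 = 1:1 partitioning) force

    log P = (ΔG_solvation − ΔG_hydration) / (RT ln 10).

A solute costlier to remove from water than from octanol then gets
log P < 0, as required. RT ln 10 = 5.708 kJ/mol at 298.15 K.

**PMF.** PMF(z) = −kT ln(ρ_w(z)/ρ_bulk) per profile bin, in kJ/mol
(molar k). ρ_bulk is the mean over a caller-chosen bulk region (the
pipeline uses 1 nm slabs at the box edges). Bins with ρ = 0 are
reported with an explicit `defined = False` flag and NaN, never ±inf —
the convention of drawing the curve only where water actually visits.

## Statistics

Block averaging: contiguous equal blocks (ten by default, emulating ten
40 ns blocks over a 400 ns window), SEM = sd(block means)/√n_blocks; a
trailing remainder is dropped with a warning. The pipeline analyses the
final 80% of frames by default (mirroring a 400-of-500 ns analysis
window); the fraction is configurable. ANOVA is scipy's `f_oneway`;
Tukey HSD is scipy's studentized-range implementation with the
Tukey–Kramer correction for unequal group sizes, cross-checked in the
tests against statsmodels to 1e-3. Which observables are grouped and
compared is left to the caller — the grouping is an input, not a baked-in
scheme.

## Synthetic data: what it is and is not

The generator produces *geometric* stand-ins with exact answers, not
physical membranes:

- `build_bilayer`: headgroup reference atoms exactly on planes ±d/2
  around the midplane; chains are straight segments whose direction
  carries the tilt, so every C_{n−1}→C_{n+1} vector is collinear with
  the chain and S_z equals (3cos²θ0 − 1)/2 *exactly* at zero jitter —
  closed-form ground truth rather than an approximation. Defaults
  emulate the study conditions of the gel-phase SC systems this package
  targets: d = 4.89 nm, target APL = 0.325 nm², equimolar CER/FFA/CHOL.
  The carbon z-rise is 0.127 nm (all-trans chain).
- `add_solvent`: single-site water uniform outside a water-excluded
  core (default halfwidth 1.5 nm), single-site enhancer drawn from a
  bulk-uniform + Gaussian-interface-peak mixture at ±d/2; the amplitude
  parameter is the peak/bulk density ratio minus 1. Water is 18.015
  g/mol, PG 76.09 g/mol.
- `plant_hbond_fixture`: triplets on a ≥1.6 nm grid (so cross-triplet
  pairs can never bond), bonded ones inside both cutoffs, near-misses
  violating exactly one criterion with a safety margin
  (d ∈ [0.36, 0.50] nm or angle ∈ [35°, 60°]), and the first bonded
  pair deliberately wrapped across the periodic boundary.
- `sample_fep_work`: forward ~ N(ΔG + σ²/2, σ²), reverse ~
  N(−ΔG + σ²/2, σ²) in kT — the unique Gaussian pair satisfying the
  Crooks fluctuation relation, so BAR's target is known exactly.
- `solvent_composition` solves the two-component mass balance
  x·M_e/(x·M_e + (N−x)·M_w) = w exactly and rounds to the nearest
  molecule. Published composition tables for these systems deviate from
  any single rounding rule by 1–2 molecules (and one row by a whole
  molecule budget), so printed tables are treated as documentation, not
  as an oracle for this function.

No packing, excluded volume, energetics or dynamics are modelled.
Passing tests therefore establish the *analysis* code — binning,
geometry, estimators, statistics — not the realism of any simulation;
observables that depend on genuine MD ensembles (experimental-scale
APL, thickness, H-bond counts, log P of a real solute) are out of reach
of the synthetic surface by construction, and the test problem sizes
(tens of lipids, 10³–10⁵ solvent particles or work samples, ≤100
frames) are chosen as the smallest at which each property is sharp.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- Single-frame coordinate formats (GRO/PDB) plus in-memory
  trajectories; no compressed-trajectory reader.
- Thickness has one-bin resolution by design (no peak fitting).
- H-bond lifetimes, bifurcation statistics and energetic H-bond
  definitions are out of scope, as are MBAR/TI estimators and
  umbrella-sampling PMFs.
- The minimum-image H-bond search assumes box edges > 2 × cutoff.
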