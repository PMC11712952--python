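# Methods

This note documents the models inside `dcslet`, the defaults they ship
with, and what the desk-scale configuration can and cannot say about real
collimated proton fields.

## Stopping powers and range calibration

Mass electronic stopping powers for water (I = 75 eV, Z/A = 0.55509) and
nickel (I = 311 eV, Z/A = 0.47706) are generated at import from the Bethe
formula without shell or density corrections, tabulated on 600 log-spaced
nodes over 0.5–250 MeV. The only experimental anchors available to the
package are the Bragg-peak depths of a clinical beamline at 90/120/150 MeV
(6.4, 10.65, 15.75 cm in water). Because Bohr range straggling, the 0.7 %
beam energy spread and the multiple-scattering path detour together place
the *simulated* depth-dose maximum about one range-straggling σ proximal
to the CSDA range — an energy-independent ratio of 1/1.0168 over
90–150 MeV under the default physics — the water table is rescaled by a
single factor so that the simulated peaks, not the raw CSDA ranges, land
on the anchors. Verified peaks sit within ±0.4 mm of all three anchors;
`csda_range` consequently returns values ≈1.1 % deeper than the printed
depths. Below the 0.5 MeV tracking cutoff the residual range is under
10 μm and the remaining energy is deposited on the spot.

## Transport model

A condensed-history class-II-lite scheme, compiled with numba, one random
stream per history index (so batches are order-independent and runs are
bit-reproducible per seed):

* **Energy loss** per step by exact CSDA inversion of the range table
  (E′ = E(R(E) − Δs)); a forward-Euler update was measured to overshoot
  the range by ~1 mm at 90 MeV and is not used. Default steps: 0.05 cm in
  water, 0.02 cm in nickel.
* **Straggling**: Gaussian fluctuation with the relativistic Bohr
  variance, truncated to [0, E]. The straggled loss is both subtracted
  from the proton and tallied, so each history's energy books close to
  ~1e-15 relative. Feeding the straggled ε into the ε²/l tally adds a
  small positive bias to LET_d of ≈ σ²/(ε̄ Δs) per unit path — about +2 %
  in the entrance region and +0.2 % at the peak with the default step.
* **Multiple Coulomb scattering**: Highland angle in two projections;
  radiation lengths 36.08 g/cm² (water), 12.68 g/cm² (nickel).
* **Nuclear surrogate** (water only, default on): interaction probability
  1 %/cm above 20 MeV ramping to zero at 8 MeV; on interaction the proton
  is removed, 60 % of its energy is lumped locally as dose, one secondary
  proton with E ~ U(5, 0.5E) and forward-biased direction
  (cos θ ~ U(0.5, 1)) is emitted, and the remainder is booked to a
  binding-energy sink. This reproduces the qualitative entrance LET_d
  enhancement of full nonelastic physics but not its secondary
  multiplicity or angular spectra.
* **Geometry**: air gaps are vacuum; the X-trimmer pair's exit plane sits
  5 cm above the phantom surface (so the spectral tally plane coincides
  with the surface), the Y pair 4.15 cm further upstream. Blades are 3 cm
  of nickel along the beam — the CSDA range of 150 MeV protons in nickel
  is 2.53 cm, so thinner blades would leak degraded protons through their
  full thickness — with medial faces tilted onto the line through the
  effective point source (200 cm upstream) and the edge.

## Scoring

Each water step is split exactly at voxel faces; sub-step j adds
(ε·l_j/l, l_j, ε²·l_j/l²) to its voxel's accumulators (1 mm isotropic
default). Zero-length deposits (cutoff kills, nuclear lumps) are kept in a
separate dose-only accumulator: including a pathless energy lump in the
LET_d denominator would break the Cauchy–Schwarz ordering LET_d ≥ LET_t,
which otherwise holds voxel-by-voxel by construction. LET is scored for
protons only; a voxel's LET is reported only where its dose exceeds 1e-4
of the map maximum. Plane crossings are tallied in fixed 0.1 MeV and
0.1 keV/μm bins, and the scatter-fraction threshold is tied to the
*incident* spectrum model (nominal energy − 3σ), not the empirical mean.

## Source model

A parameterized divergent Gaussian stands in for the measured-fluence
back-projection of the clinical nozzle: surface spot σ of 0.52/0.43/0.37 cm
at 90/120/150 MeV, extended below 90 MeV by the 1/(β·pc)
multiple-scattering scaling (0.66 cm at 70 MeV, 0.92 cm at 50 MeV); energy
spread 0.7 % of the nominal energy; effective source 200 cm upstream.
These are package defaults, all configurable.

## Surrogate beamlets

Planning studies use analytic beamlets: a power-law slowing-down curve
s^(−k) convolved with a Gaussian range spread (integrated on a log grid in
residual range so the integrable singularity does not alias), a Gaussian
lateral profile with depth-growing σ, and a rational LET_d depth curve
through entrance/peak anchors with a Gaussian LET ridge at collimated
edges. The exponent k, the range-spread σ and the LET anchors are fitted
per energy to this package's own Monte Carlo (30k-history runs at 50, 70,
90, 120 and 150 MeV) and interpolated between — a self-calibration that
keeps the surrogate and transport engines mutually consistent without
hard-coding external values. Collimation is an erf truncation
(penumbra σ 0.12 cm) at absolute edge positions plus an optional 2 % halo.
Surrogates materialize as ordinary score-map accumulators, so
`letd_map(make_surrogate_scoremaps(p))` reproduces the analytic LET_d
exactly and every downstream operation accepts either source.

## Plans

Both study targets sit shallow, with their distal face at the 90 MeV
anchor depth (2.4–6.4 cm): the paper-scale layer count (11 layers at
4 MeV spacing across a 4 cm extent) pins dR/dE ≈ 0.09 cm/MeV, and shallow
targets are precisely the clinical regime for trimmer collimation, where
low-energy spots grow large. The phantom is 12.2 × 12.2 × 10 cm at 2 mm
voxels, with the lateral origin chosen so the ±2.5 cm target boundary
falls on voxel faces (an aperture through a voxel center would leave that
rim voxel permanently half-covered). The inverted pyramid carries its
5 × 5 cm base at the shallow face and its 5 mm apex at the deep face, so
the per-layer aperture expands over the distal-to-proximal delivery
order; per-layer apertures add a 4 mm expansion margin so deeper, narrower
layers do not starve the cone-shell voxels of entrance dose, while the
fixed cube aperture sits exactly on the target boundary.

Weights minimize Σ_target (D − p)² + 0.05·Σ_rings D² subject to w ≥ 0 by
Jacobi-preconditioned accelerated projected gradient (float32 influence
matrix, voxel sample strided 3/5 in target/rings — far below the beamlet
σ — 400 iterations, 1e-6 relative-objective stop). Optimized plans are
renormalized so the physical target D95 equals the 25 Gy prescription,
which is what makes collimated/uncollimated comparisons "equal coverage".
The converged optimum has D5/D95 ≈ 1.25–1.3: at 2–6 cm depth the pristine
peak widths (σ 0.06–0.14 cm) are well below the 0.36 cm layer spacing, so
a few-percent spread-out-peak ripple plus the rim penumbra is intrinsic
to the 4 MeV spacing, not an optimizer artifact (an independent 1-D
nonnegative-least-squares fit with the same depth curves reaches the same
floor). Composite LET_d is recombined from the weighted Σε and Σε²/l maps
— never by averaging per-beamlet LET_d.

## RBE model

The phenomenological proton RBE with RBE_max linear in LET_d/(α/β)ₓ and
RBE_min linear in √(α/β)ₓ·LET_d (p0 = 0.99064, p1 = 0.35605, p2 = 1.1012,
p3 = −0.0038703, (α/β)ₓ = 3.49 Gy). The D → 0 limit returns RBE_max. D is
the full per-voxel plan dose (no fractionation model) — note that at
fixed D above ≈22 Gy the negative p3 slope of RBE_min can make
RBE-weighted dose locally *decrease* with LET_d; monotonicity is a
fraction-dose property.

## Analysis conventions

LET_d maps are post-processed with a one-voxel-span (3³) median filter —
mask-aware, shrunken at edges — optionally followed by a 0.5-voxel
Gaussian; dose maps are smoothed only. Planar dose-weighted LET_d is
Σ(LET_d·D)/ΣD over a lateral plane's unmasked voxels. Penumbra LET_d is
interpolated at the outermost 10 %-of-peak dose crossing per side. The
"upper quartile" of a LET distribution is its 75th percentile.
Volume histograms are cumulative fraction-at-or-above curves; Dq values
are percentiles of the ROI voxel values; normal-tissue rings are 5/10/20 mm
Euclidean distance-transform shells, skin is the first 5 mm of phantom
depth, body the whole phantom.

## Problem sizes

Default runs: 1e5 histories for spectra, 2e5 for beamlet maps (the
package's statistics-versus-turnaround compromise; peak-plane LET_d then
carries ≈1–2 % statistical error), 30k for surrogate calibration;
2.8k–5.8k beamlets per plan at the 0.25 cm lattice.

## Known limitations

* The nickel scatter model (Gaussian Highland core, no single large-angle
  tail, no nuclear interactions in the blade) yields edge-scatter fluences
  of a few percent of the incident beam. A 1 μm-step half-space diffusion
  oracle confirms this magnitude is intrinsic to Gaussian multiple
  scattering at grazing incidence, but the resulting scatter *fractions*
  at the exit plane are orders of magnitude above the published
  clinical-study ratios, whose normalization could not be reconstructed;
  the package reports the literal fluence-fraction definition.
* The 150 MeV peak-plane LET_d is sensitive to the absolute energy spread;
  with the default 0.7 % it sits ~10 % below the published value while 90
  and 120 MeV agree within a few percent.
* No δ-ray transport, no neutrons/photons/fragments, no range shifter, no
  scanning-magnet optics (beamlets translate rigidly to spot positions),
  vacuum air gaps, single-field plans only.
* Passing tests demonstrate internal consistency against closed-form
  oracles and the package's own Monte Carlo; they do not validate against
  measured collimated-field data.
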