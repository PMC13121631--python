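# Methods

## Model and units

All energies are kJ/mol, distances Å, charges in elementary charge units,
temperatures K. The pairwise potential is 12-6 Lennard-Jones plus point-charge
Coulomb with Lorentz–Berthelot mixing (arithmetic-mean σ, geometric-mean ε);
the Coulomb prefactor is k_e = 1389.35457644 kJ·Å/(mol·e²) (CODATA-derived).
Gas-side calculations use kPa/L/mol/K with R = 8.314 L·kPa/(mol·K), the unit
system in which the embedded Beattie–Bridgeman CO₂ constants
(A₀ = 507.2836, a = 0.07132, B₀ = 0.10476, b = 0.07235, c = 6.60×10⁵) cohere.

Molecules are rigid bodies: each species is a template of sites with fixed
local geometry, and a configuration stores translated/rotated copies in a
periodic cubic box. Intramolecular flexibility, polarisation and empirical
potential refinement are out of scope — the analyses here consume refined or
synthetic configurations; they do not produce refined ones.

Electrostatics are plain (non-Ewald) Coulomb under the minimum image
convention. The molecule-pair energy used by all analyses is an explicit sum
over every intermolecular site pair with no cutoff beyond minimum image,
because the quantity of interest is the interaction energy of an identified
molecule pair, not a lattice-summed total. The Monte Carlo sampler truncates
at a cutoff (default half the box length) applied to **whole molecule pairs**,
keyed on the distance between the molecules' first sites: truncating
individual site pairs would cut neutral charge groups at the cutoff sphere
and leave large monopole artifacts (we observed ~20× over-binding of water
when site-wise truncation was used).

## Default force field

The embedded parameter set is SPC/E water (σ_O = 3.166 Å, ε_O = 0.650 kJ/mol,
q_O = −0.8476, q_H = +0.4238), literature-style Na⁺/K⁺ Lennard-Jones values,
OPLS-AA-style charge sets for glycinate, glycine zwitterion and glycine
carbamate, and TraPPE-style CO₂. Net charges are −1 (glycinate), 0
(zwitterion), and −2 (carbamate, ⁻OOC–NH–CH₂–COO⁻): the −2 is required for
electroneutrality of a loaded box (217 M⁺ against 65 anions + 76 carbamates)
and corresponds to deprotonated carbamic acid on the glycinate skeleton.
Glycine-derived geometries are built from standard bond lengths (C–N 1.47,
C–C 1.52, C–O 1.25, N–H 1.01, C–H 1.09 Å) with tetrahedral/planar angles;
they are chemically plausible rigid stand-ins, not refined structures. Every
value is overridable from a YAML parameter file (`load_forcefield`), since
published per-site parameter tables for these systems are not reproduced here.

## Synthetic-data stage

`build_box` inserts molecules at random positions and orientations, rejecting
any placement that puts two sites closer than 0.8·σ_ij or a hard floor of
0.8 Å (the floor protects zero-σ charged hydrogens). Box size comes from an
explicit edge length or from a target mass density; the default density for
glycinate solutions is 1.10 g/cm³, a realistic value for ~2 mol/kg aqueous
glycinate salts. Unloaded solution boxes follow the study composition ratio
(5767 waters : 217 ions : 217 glycinates, scaled to the box size in use).

`run_mc` performs single-molecule rigid-body Metropolis moves: a uniform
translation (default ±0.15 Å) combined, for multi-site molecules, with a
rotation about the centroid (default ±0.2 rad); these defaults give ~30%
acceptance for liquid water, the usual efficiency band. Whole molecules are
wrapped by their first site so rigid bodies stay spatially contiguous across
periodic boundaries. Frames are recorded every `frame_interval` production
moves (default 100 moves per molecule, mirroring the decorrelation stride of
the downstream analysis); at every recorded frame the bookkept running energy
is checked against a full recompute and a relative drift above 1e-6 raises.
Long-range (tail) corrections are omitted: the target is solvation-shell
structure and pair energetics, not absolute thermodynamics.

What the generator emulates: first-shell packing, hydrogen-bond geometry, ion
pairing, realistic densities — enough structure for every analysis stage to
detect and quantify. What it does not emulate: experiment-refined structure
(no empirical potential), long-range dielectric screening (no Ewald), proton
transfer, or intramolecular relaxation. Passing tests therefore demonstrate
the correctness of the analysis operations and the sanity of the sampler, not
quantitative agreement with refined solution structure; study-printed shell
statistics are used as documented reference inputs (e.g. for dominance
weighting), never as targets the sampler is tuned to.

## Analysis conventions

- **RDFs**: minimum-image distances, 0.03 Å bins by default, intramolecular
  pairs excluded, normalised per centre per frame by the ideal shell count
  4πρ_β r² dr with ρ_β = N_β/V. Tail flatness (mean of the last 10% of bins
  within [0.9, 1.1]) is the adequacy check for homogeneous systems.
- **Coordination numbers**: midpoint-rule integration of 4πρ_β r² g(r) with
  fractional coverage of the edge bins, so windows not aligned to bin edges
  do not overshoot by half a bin. The ±0.06 Å sensitivity probe equals two
  default bins.
- **Frame subsampling**: indices 0, s, 2s, … strictly below n (stride s =
  100 by default). The source material's own stride arithmetic is ambiguous
  (one stated count implies an inclusive endpoint, another an exclusive one);
  the half-open rule here is the one consistent with both worked examples
  used in testing.
- **Spatial density functions**: the local frame of a central molecule is
  built by Gram–Schmidt from three named sites — origin at the first, x-axis
  toward the second, xy-plane through the third; repeated labels resolve to
  successive occurrences within the molecule. Densities are per central
  molecule per frame, so the map's integral is the mean partner count within
  the cube, and spherical-shell integrals are comparable to coordination
  numbers (agreement to ≤5% at 0.25 Å voxels). The isosurface level for a
  probability fraction f is the largest density whose superlevel set holds
  ≥ f of the total mass (descending sort, cumulative sum).
- **Pair energetics**: a molecule pair qualifying through several site
  contacts is counted once per frame. Energy histograms default to 1 kJ/mol
  bins (hydration-scale interactions; ~5 kJ/mol is appropriate for ion
  pairs). A Gaussian (amplitude, location, width) is fitted to the binned
  counts by nonlinear least squares; the quoted uncertainty is the fit
  covariance SE of the location. Fewer than 10 pairs, fewer than 4 occupied
  bins, or a non-converging fit flag the result unreliable and the sample
  mean stands in.
- **Cutoff sensitivity** re-fits at cutoff×(1 ± 10%) and reports the mean
  absolute relative change of the fitted mean per 10% variation. The
  g(r)-difference metric (for force-field robustness sweeps) and the neutron
  R factor share one form: mean squared residual normalised by the mean
  squared reference magnitude. The exact published normalisation is not
  printed in the source material's main text; this documented choice is used
  consistently on both sides of every comparison.
- **Bulk water**: oxygens beyond per-atom-type exclusion cutoffs from every
  solute atom. The published cutoff table is unavailable, so defaults should
  be taken from the first minima of the corresponding solute–O_w RDFs of the
  trajectory under analysis. H-bond criteria are O–O ≤ 3.29 Å and O–H ≤
  2.44 Å.

## Neutron forward model

Partials are transformed as S_αβ(Q) − 1 = (4πρ/Q) ∫ r (g−1) sin(Qr) M(r) dr
with a Lorch window M(r) = sinc(r/r_max) damping finite-range truncation,
trapezoid-integrated on the RDF bin centres; an unconverged g(r) tail warns
and tapers. Totals use Faber–Ziman weighting,
F(Q) = Σ_{α≤β} (2−δ_αβ) c_α c_β ⟨b_α⟩⟨b_β⟩ (S_αβ−1), with coherent scattering
lengths from the standard Sears tabulation (H −3.739, D 6.671, C 6.646,
N 9.36, O 5.803, Na 3.63, K 3.67 fm) and fm² converted to barns. Exchangeable
hydrogens (water, N-bound) conventionally share the solvent H/D fraction
while C-bound hydrogens are set independently; the interface accepts
arbitrary per-type mean scattering lengths, so any isotopomer is expressible.
F(Q) is the distinct interference term only — self-scattering and
inelasticity corrections belong to data reduction.

## Gas-side model

The burette inventory uses the Beattie–Bridgeman equation
P = RT/ν² (1 − c/(νT³))(ν + B) − A/ν², A = A₀(1 − a/ν), B = B₀(1 − b/ν);
molar volume is recovered by bracketed root finding (Brent) on
[0.1·RT/P, 10·RT/P] from the ideal-gas start, round-tripping pressure to
better than 1e-10 relative at 30 bar. The vessel headspace (≈5 bar) is ideal
gas. Absorbed moles are n_abs(t) = n_burette(0) − n_burette(t) −
n_headspace(t); the headspace is evacuated at t = 0. Vessel and burette
volumes are required configuration inputs — they are apparatus properties not
derivable from anything else. Speciation rounds the CO₂ count to the nearest
whole molecule, clamped at the 0.5-equivalent ceiling (beyond which the
deliberately excluded bicarbonate channel would open).

## Problem sizes and numerical checks

The test suite runs its Monte Carlo fixtures at 64 waters (30k+30k moves) and
its end-to-end check at 600 molecules (550 water, 25 K⁺, 25 glycinate;
200k moves, 10 frames), sizes chosen so the whole suite completes in a few
minutes while every stage still has detectable structure to measure. Brute
force O(N²) re-implementations back every pair search; closed forms back the
coordination integral and the equation of state; independent quadrature backs
the Fourier transforms; generate-then-recover backs the uptake bookkeeping.
Statistical assertions on binned quantities control the family error across
bins (per-bin 3σ bands with the chance-expected excursion allowance and a
hard 5σ cap) rather than demanding every one of ~170 bins sit inside 3σ,
which a perfectly uniform gas would fail a third of the time.

## Known limitations

- Truncated, non-Ewald electrostatics bias absolute energies of highly
  charged pairs (ion–carbamate); trends and analysis mechanics are the
  target, not absolute thermodynamics.
- The default force field is a literature-style stand-in; per-site charges
  for the carbamate in particular are plausible rather than published.
- NPT sampling, intramolecular moves and parallel tempering are not
  implemented; very dense recipes can legitimately fail to pack.
- Cubic boxes only; orientational and triplet correlations out of scope.
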