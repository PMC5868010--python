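# Methods

This note records the models implemented in `dihedralir`, the parameter
choices that matter, and what the synthetic data do and do not emulate.

## Backbone geometry and transition dipoles

Backbones are built residue-by-residue by internal-coordinate (NeRF)
placement from per-residue (φ, ψ), with the peptide bond planar (ω = 180°)
and ideal bond parameters: N–Cα 1.46 Å, Cα–C 1.52 Å, C–N 1.33 Å,
C=O 1.23 Å, angles N–Cα–C 111.0°, Cα–C–N 116.2°, C–N–Cα 121.7°,
Cα–C–O 120.8°. The carbonyl O is placed in the peptide plane anti to the
next amide N; for the chain terminus a virtual next N defined by the last
ψ fixes the O, so every input dihedral is realized and measurable
(φ of residue 1 has no geometric consequence). φ/ψ round-trip to < 10⁻³°.

Each carbonyl carries one amide I transition dipole: origin at the C=O
bond midpoint (configurable fraction), direction the C→O axis rotated by a
20° tilt within the sp2 (O=C–N) plane toward the next amide nitrogen (for
the last residue, away from Cα, which lies on the opposite side of the same
plane — one fixed convention). Magnitudes are dimensionless multiples of a
reference amide I dipole.

PDB import (Bio.PDB) keeps author residue numbering, uses the first model
of multi-model files, and requires all four backbone atoms per residue.

## Couplings

**Nearest neighbours (through-bond).** The coupling between carbonyls i and
i+1 is looked up at the (φ, ψ) of residue i+1, the residue whose
N–Cα–C backbone links the two amide units. The packaged surface is a sum of
three periodic Gaussian kernels (concentration chosen for ~60° FWHM basins,
comparable to published nearest-neighbour maps) whose amplitudes are solved
exactly through three anchor couplings: +8.3 cm⁻¹ at the α-helix preset
(−57°, −47°), +2.5 cm⁻¹ at the parallel β-strand preset (−119°, +113°), and
+3.1 cm⁻¹ at (−80°, −30°). It is tabulated on a 1° grid — the anchors are
integer angles, hence grid nodes — and queried by periodic bilinear
interpolation, so the anchors are reproduced exactly. The surface is a
documented stand-in for a full ab-initio dihedral map: correct at the three
anchors and qualitatively smooth/periodic elsewhere, but not quantitative
away from the anchors.

**All other pairs (through-space).** Point transition-dipole coupling
β = C μ₁μ₂ (d̂₁·d̂₂ − 3(d̂₁·n̂)(d̂₂·n̂))/r³ with C = 5034 cm⁻¹·Å³·D⁻² (vacuum
point-dipole energy for Debye/Ångström units) and an effective transition
dipole of 0.37 D per unit magnitude. The 0.37 D default places nearest
in-register inter-strand sheet couplings in the literature-typical −5…−10
cm⁻¹ range; the printed amide I dipole *derivative* (3.7 D Å⁻¹ amu^½) is
carried as metadata, not used directly in the energy formula. Origins
closer than 0.5 Å are rejected (point-dipole breakdown). Pairs across chain
boundaries always use TDC, even at |i−j| = 1.

## Exciton model

H1 holds site frequencies (default 1650 cm⁻¹ unlabelled; ¹³C¹⁸O labels
−65 cm⁻¹, both configurable) on the diagonal and couplings off-diagonal.
H2, in the basis {|ii⟩ ascending, then |ij⟩ (i<j) lexicographic}, holds
2ωᵢ − Δ for overtones (Δ = 16 cm⁻¹ by default), ωᵢ + ωⱼ for combinations,
and the standard weakly-anharmonic harmonic completion off-diagonal:
⟨ii|H|ij⟩ = √2 βᵢⱼ, ⟨ij|H|ik⟩ = βⱼₖ, ⟨ii|H|jj⟩ = 0. Manifold dipoles follow
the harmonic ladder (⟨0|μ|i⟩ = μᵢ, ⟨i|μ|ii⟩ = √2 μᵢ, ⟨i|μ|ij⟩ = μⱼ), rotated
into the eigenbases. Eigenvector signs are fixed (first nonzero component
positive) for reproducible serialization. Trace conservation, the Δ = 0
harmonic limit, and the oscillator-strength sum rule are enforced by tests.

## Spectra

FTIR: |μ₀ₖ|² sticks convolved with a Lorentzian or Gaussian of configurable
FWHM (default Lorentzian, 12 cm⁻¹). Absorptive 2D: positive diagonal sticks
at (ωₖ, ωₖ) with weight **2**|μ₀ₖ|⁴ — the factor 2 counts the ground-state
bleach and stimulated-emission pathways, and makes the negative band the
equal-amplitude mirror of the fundamental for a lone site, since
harmonically |μ₁₂|² = 2|μ₀₁|² — and negative sticks at (ωₖ, ωₘ − ωₖ) with
weight |μ₀ₖ|²|μ₁₂,ₖₘ|². The 2D lineshape is the product of pump and probe
1D profiles (no spectral-diffusion tilt). Default grids are 1540–1700 cm⁻¹
at 0.5 cm⁻¹. Sticks below 10⁻¹⁰ of the strongest are culled (speed only).

Diagonal slices follow probe = pump (fundamental) or probe = pump − Δ
(sequence) with the *configured* Δ, not per-state anharmonic shifts. Note
that a strongly coupled pair's dominant 1–2 transition sits at a smaller
effective anharmonic offset (≈6 cm⁻¹ for the degenerate +8.3 cm⁻¹ dimer),
so the fixed-offset sequence track undercounts coupled-pair intensity;
analyses of simulated label pairs in this package therefore use the
fundamental cut.

Diagonal disorder: spectra are averaged over realizations with independent
zero-mean Gaussian site-frequency perturbations; seeded and bit-reproducible.

## NNMF and rank selection

The kinetics matrix I (time × frequency; sequence-band slices negated, and
the flip recorded) is factored as Iᵀ ≈ W H by Frobenius multiplicative
updates: 16 independently seeded uniform(0,1) initializations scaled to the
data mean, best replicate (smallest ‖I − WH‖_F) kept; iteration stops at
5000 iterations or a relative objective change below 10⁻⁸. Per-replicate
seeds spawn deterministically from one master seed.

A component is a **null vector** — it carries no unique kinetic state — in
either of two ways: its energy ‖W_k‖‖H_k‖ falls below 2% of the dominant
component's, or it *duplicates* another component. The duplicate test uses
the joint cosine cos(W_k, W_j)·cos(H_k, H_j) with threshold 0.35: on
planted data the best-of-replicates fit fills an excess rank by splitting
one state into two near-identical copies (joint cosine ≥ 0.54 in all
configurations measured) rather than letting a component die, while
distinct states at the true rank stay below 0.15 — the 0.35 threshold sits
between the two regimes with a wide margin on both sides. The lower-energy
member of a duplicated pair is flagged. The effective rank is the largest
scanned rank with no flagged component. Recovered factors are compared to
ground truth only after optimal column matching (Hungarian assignment on
cosine similarity), as NNMF is identified only up to permutation and scale.

## Dihedral indexing

Peak statistics within an analysis window: maximum by parabolic refinement
of the discrete argmax (window-edge maxima are flagged), area by trapezoid,
FWHM by linear interpolation at half maximum (window edge used where the
half level is not reached). Sequence-band slices are analyzed on negated
values.

Decision rule, with thresholds exposed in `IndexThresholds`
(defaults T_shift = 3 cm⁻¹, T_enh = 1.4, T_width = 1.3):

* **helix** if shift ≥ +T_shift and per-label enhancement ≥ T_enh;
* **sheet** if shift ≤ −T_shift;
* **disordered** if |shift| < T_shift and the pair band is ≥ T_width times
  broader than the single band;
* **ambiguous** otherwise.

Shift = peak(double) − peak(single); enhancement = area(double) /
(n_labels · area(single)), invariant to global rescaling.

**Helix population.** The coupled-band content of a slice is measured as
the asymmetry about the single-label maximum — integral above minus
integral below, normalized by the total window integral. This is exactly
zero for the symmetric uncoupled band (a plain above-threshold integral is
contaminated by the uncoupled band's tail) and maximal for the fully
helical reference. With ρ the ratio of the two normalized asymmetries, the
returned bracket spans the two limiting intensity-scaling assumptions:
signal ∝ population (p = ρ) and the |μ|⁴ two-state dilution limit, in which
coupled molecules carry a two-fold per-label 2D enhancement
(p = ρ/(2 − ρ)). On planted mixtures the bracket contains the true fraction
with the dilution-corrected end tight. This interval construction is this
package's own operationalization of an intensity-ratio population estimate,
not a unique definition.

## Synthetic data

`make_kinetics` builds I = Σ_k course_k ⊗ spectrum_k + clipped Gaussian
noise (default 1% of max) from Gaussian pseudo-bands and parametrized
courses (sigmoid rise/decay, exponential decay, rise-and-fall). Presets use
the experimentally observed label frequencies: two-state = monomer
(1595 + 1650 cm⁻¹ bands, 22/30 cm⁻¹ wide, sigmoidal decay t₅₀ = 150 min)
plus fiber (1578 + 1620 cm⁻¹, sigmoidal rise); three-state = monomer
(1605 + 1650 cm⁻¹, decay t₅₀ = 120 min), intermediate (broad 1571 cm⁻¹,
rising during the lag phase and decaying as the fiber forms) and fiber
(1560 + 1620 cm⁻¹, rise t₅₀ = 250 min). Time axis 0–600 min every 2 min;
grid 1540–1680 cm⁻¹. Lag times in real experiments vary run-to-run, so t₅₀
values are free parameters, not calibrated quantities.

Label-pair fixtures simulate the *labelled-site subsystem* (sites at
1595 cm⁻¹) through the full chain: unlabelled residues sit 55 cm⁻¹ away
and are omitted because at that detuning the +8.3 cm⁻¹ coupling with
near-parallel dipoles causes appreciable intensity borrowing that has no
counterpart in the isolated-pair comparison the rule formalizes. The helix
fixture is a 2-residue pair vs a lone site; the sheet fixture stacks 6
in-register strand segments along the hydrogen-bond direction (4.8 Å
spacing) so intra-strand (+2.5 cm⁻¹, anti-parallel carbonyls) and
inter-strand (negative TDC) couplings both push the pair band down — the
single-label column lands at ~1579 cm⁻¹ and the pair ~4 cm⁻¹ lower,
matching the sign and order of fiber observations. The disordered fixture
averages 160 realizations drawn from a coil ensemble (β/PPII : α_R : α_L =
60 : 30 : 10, 25° basin widths) with 2 cm⁻¹ site-frequency disorder:
the pair band broadens because coupling and carbonyl geometry vary across
the ensemble while the lone label only feels the frequency disorder.
Structured fixtures use Gaussian 6 cm⁻¹ lineshapes; the disordered fixture
10 cm⁻¹ (solvent-exposed sites are inhomogeneously broadened).

What the synthetic data do **not** emulate: detector/scatter noise
statistics, buffer backgrounds, spectral diffusion, finite-pulse and
polarization effects, and run-to-run lag-time variability. Passing tests
demonstrate internal consistency of the method chain on data with the
paper-like spectral structure, not instrument-grade realism.

## Numerical choices

* Diagonalization via LAPACK `eigh`; orthonormality asserted to 10⁻⁸;
  degenerate eigenvector gauge fixed by sign convention.
* Coupling-map serialization at %.17g for bit-identical round-trips;
  spectra at fixed precision (%.8e) for diffable outputs.
* NNMF epsilon guard 10⁻¹² in the update denominators.
* All randomness (disorder draws, noise, NNMF restarts) flows from
  explicit integer seeds through `numpy.random.default_rng` /
  `SeedSequence.spawn`; identical seeds give byte-identical outputs.

## Known limitations

* The coupling surface is constrained only at three conformations;
  couplings elsewhere on the Ramachandran map are smooth interpolations,
  not ab-initio values.
* The point-dipole TDC overestimates couplings below ~4 Å separation.
* The two-exciton model omits population transfer and lifetime effects;
  2D lineshapes carry no spectral-diffusion tilt.
* The fixed-offset sequence-band track misrepresents strongly coupled
  systems (see above); use fundamental cuts for simulated label pairs.
* Helix-population brackets assume the reference slice is fully helical
  and the mixture is two-state (helical + uncoupled).
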