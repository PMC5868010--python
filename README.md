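# dihedralir

Site-specific secondary-structure assignment from isotope-labelled amide I
2D IR spectra — "dihedral indexing" — together with the exciton-model
simulator and kinetics decomposition it rests on.

## The problem

The amide I band (backbone C=O stretch, ~1600–1700 cm⁻¹) reports on protein
secondary structure through vibrational couplings between carbonyl
oscillators. Labelling one residue with ¹³C¹⁸O drops its frequency ~65 cm⁻¹
below the main band, isolating a single site; labelling **two adjacent**
residues additionally switches on the nearest-neighbour coupling
β(φ, ψ), which depends on the backbone dihedral angles. Relative to the
single-label control:

* α-helix (β ≈ +8.3 cm⁻¹, near-parallel carbonyls) → the label pair's band
  shifts **up** in frequency and gains intensity;
* β-sheet (β ≈ +2.5 cm⁻¹ intra-strand with anti-parallel carbonyls, plus
  negative in-register inter-strand transition-dipole coupling) → the band
  shifts **down**;
* disordered sites → little net shift, but a broadened band.

Because 2D IR diagonal peaks scale as |μ|⁴ (FTIR only |μ|²), the coupled
pair's intensity enhancement — exactly 2× per label for a degenerate
parallel dimer — is a sensitive second observable. Applied during amyloid
aggregation (e.g. of human islet amyloid polypeptide, hIAPP), time series
of diagonal slices decompose by non-negative matrix factorization
(**I** = **WH** + **U**) into kinetic states: monomer, transient oligomeric
intermediate, and fiber.

## What the package computes

| module | contents |
| --- | --- |
| `geometry` | idealized backbones from (φ, ψ) by internal-coordinate (NeRF) placement; transition dipoles on each carbonyl (tilt 20°, configurable); PDB import/export |
| `coupling` | periodic Ramachandran coupling surface β(φ, ψ) anchored at +8.3 / +2.5 / +3.1 cm⁻¹; transition dipole coupling C·μ₁μ₂·κ/r³; full coupling matrices |
| `exciton` | one-/two-exciton Hamiltonians (anharmonicity Δ = 16 cm⁻¹), eigenstates, harmonic manifold dipoles |
| `spectra` | FTIR and absorptive 2D IR spectra (sum-over-states, Lorentzian/Gaussian lineshapes), diagonal slices, diagonal-disorder averaging |
| `nnmf` | seeded multiplicative-update NNMF (best of 16 replicates), null-vector rank selection, band restriction |
| `indexing` | peak statistics, the shift/enhancement/width classification rule, helix-population bracketing |
| `synthdata` | synthetic aggregation kinetics (two-/three-state presets) and closed-loop helix/sheet/disordered label-pair fixtures |
| `cli` | `dihedralir` command: `simulate-ftir`, `simulate-2d`, `slice`, `couple`, `nnmf`, `select-rank`, `index`, `synth` |

## Worked example

Simulate a doubly-labelled α-helical site and its single-label control
through the full geometry → coupling → exciton → spectra chain, then apply
the dihedral-indexing rule:

```python
import dihedralir as d

double, single = d.make_label_pair_fixture("helix")
res = d.dihedral_index(double, single, window=(1560.0, 1640.0))
print(f"shift       : {res.shift:+.2f} cm^-1")
print(f"enhancement : {res.enhancement:.2f} per label")
print(f"call        : {res.call}")
```

```
shift       : +8.45 cm^-1
enhancement : 1.51 per label
call        : helix
```

The +8 cm⁻¹ shift is the bright (symmetric) exciton state of the coupled
pair at ω₀ + β; the per-label enhancement approaches 2 as the bands resolve
(the stick-level value is exactly 2). Swapping `"helix"` for `"sheet"` or
`"disordered"` produces a negative shift or a broadened unshifted band and
the corresponding call.

Decomposing a synthetic three-state aggregation run (monomer decay,
transient intermediate, sigmoidal fiber rise):

```python
data = d.make_kinetics(d.preset_scheme("three-state", seed=7))
eff, diags = d.select_rank(data, (1, 4), seed=1)
print(f"effective rank: {eff}")
for dg in diags:
    print(f"  rank {dg.rank}: residual {dg.objective:.3f}, "
          f"null components {dg.null_components}")
```

```
effective rank: 3
  rank 1: residual 65.709, null components []
  rank 2: residual 34.492, null components []
  rank 3: residual 3.678, null components []
  rank 4: residual 3.647, null components [3]
```

Three states fit the data; requesting a fourth produces a null component
(a state carrying no unique spectrum/time course), so the effective rank
is 3.

The same flows are available from the shell, e.g.

```sh
dihedralir synth --preset three-state --seed 7 --outdir run/
dihedralir select-rank run/kinetics.tsv --outdir run/
```

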