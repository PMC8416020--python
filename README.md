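# aquaprobe

Local-hydration analysis for membrane receptors, built around three
coordinated computations:

1. **Emission-spectrum deconvolution and the hydration parameter H.**
   A 7-hydroxycoumarin fluorophore incorporated at a chosen residue of a
   receptor (e.g. the ghrelin receptor GHSR, a class-A GPCR) reports on the
   water content of its microenvironment: excited at 320 nm, it emits from
   a neutral band and from anionic/tautomer bands whose weight grows with
   local hydration.  aquaprobe fits the normalized emission spectrum
   I(λ), recorded over 340–600 nm, as a sum of three peak functions
   (Gaussian in wavelength by default, lognormal optionally)

       I(λ) = Σ_s A_s · exp(−(λ − c_s)² / 2w_s²) + b,   s ∈ {neutral, anionic, tautomer}

   by bounded nonlinear least squares, computes per-species fractional band
   areas f_s (analytically, Σ f_s = 1), and reports

       H = f_anionic + f_tautomer ∈ [0, 1]

   together with R² as goodness of fit.  Replicate H values per condition
   (apo receptor, ligands, lipid compositions) are compared by one-way
   ANOVA followed by Dunnett's many-to-one test against a reference
   condition, with multiplicity-adjusted p-values.

2. **Water-occupancy volumetric maps.** From a trajectory ensemble
   (PDB/DCD/XTC via MDAnalysis), frames are superposed on the receptor
   Cα atoms and space is discretised into cubic voxels (1 Å default).
   Each voxel stores the fraction of frames in which at least one water
   oxygen center lies inside it — a water-presence probability whose
   0.3-isosurface visualises hydrated regions.  Difference grids between
   conformational states, and per-probe contact fractions (waters within
   3.5 Å of the probe residue's side-chain heavy atoms), localise
   activation-coupled hydration changes: on activation a site behind
   position 5.58 gains water while 6.44 loses it.  Grids are written as
   OpenDX files readable by VMD/PyMOL.

3. **Curated Cα-ensemble PCA.** Structures of a receptor family mapped
   onto a multiple sequence alignment are curated by two missing-residue
   rules — drop a structure if it is the only one missing a residue at
   some alignment column; drop a column missing in ≥ 2 structures — then
   superposed (iterative mean fitting) and decomposed by covariance PCA of
   the flattened Cα coordinates.  Leading components capture collective
   motions such as intracellular TM6 spreading; external (e.g. simulation)
   conformers are projected onto the same modes.  For the reference
   class-A GPCR set, curation of the 268 retrieved structures removes six
   entries, leaving 262 structures over 164 conserved positions.

A seeded synthetic-data module generates inputs with known truth for every
stage (three-band spectra, two-state toy trajectories with site-wise water
presence probabilities, two-cluster hinge ensembles, replicate H tables),
so every estimator is tested against ground truth and against independent
brute-force oracles.

## Worked example

```python
from aquaprobe.synthetic import SpectrumTruth, gen_spectrum, gen_h_replicates
from aquaprobe.spectra import fit_band_model, compare_hydration_groups

truth = SpectrumTruth(
    fractional_areas={"neutral": 0.40, "anionic": 0.27, "tautomer": 0.33},
    noise_sd=0.01, seed=1,
)
spectrum, truth = gen_spectrum(truth)
result = fit_band_model(spectrum)
print(f"H = {result.H:.3f} (truth {truth.H_true:.2f}), R^2 = {result.r_squared:.4f}")

table = gen_h_replicates({"apo": 0.40, "ghrelin": 0.60, "SPA": 0.30},
                         n_reps=3, noise_sd=0.02, seed=2)
comparison = compare_hydration_groups(table, reference="apo")
for label in comparison.group_labels:
    p = comparison.dunnett_adjusted_p.get(label)
    tail = f"p_adj = {p:.4f}" if p is not None else "(reference)"
    print(f"{label}: H = {comparison.group_means[label]:.3f} "
          f"+/- {comparison.group_sds[label]:.3f} {tail}")
```

prints

```
H = 0.597 (truth 0.60), R^2 = 0.9991
apo: H = 0.395 +/- 0.008 (reference)
ghrelin: H = 0.603 +/- 0.046 p_adj = 0.0001
SPA: H = 0.305 +/- 0.011 p_adj = 0.0126
```

The fit recovers the injected hydration parameter to 0.003 under 1% noise;
the agonist-like condition is called significantly wetter than apo and the
inverse-agonist-like condition significantly drier, mirroring how such
ligand series are read.  The same pattern at the trajectory level:

```python
from aquaprobe.synthetic import default_sites, gen_two_state_trajectory, site_residue_indices
from aquaprobe.hydration import probe_hydration, classify_hydration_change

sites = default_sites()
inactive = gen_two_state_trajectory(sites, "inactive", n_frames=400, seed=3)
active = gen_two_state_trajectory(sites, "active", n_frames=400, seed=4)
for label, resid in site_residue_indices(sites).items():
    change = classify_hydration_change(
        probe_hydration(inactive, resid), probe_hydration(active, resid))
    print(f"site {label}: {change.fraction_inactive:.3f} -> "
          f"{change.fraction_active:.3f}  {change.call}")
```

```
site 5.58: 0.083 -> 0.915  increase
site 6.44: 0.885 -> 0.122  decrease
site control: 0.490 -> 0.487  none
```

A command-line interface mirrors the library
(`aquaprobe spectra fit`, `aquaprobe hydration map|probes|compare`,
`aquaprobe ensemble pca`, `aquaprobe synth ...`, `aquaprobe run --config
run.yaml` for config-driven multi-stage runs with a full parameter echo in
the report).

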