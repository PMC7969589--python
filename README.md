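# meshmorph

Landmark-free and landmark-based 3-D morphometrics for bone shape
phenotyping, in pure scientific Python.

Quantitative comparison of skeletal shape — e.g. between a mutant mouse line
and wild types, or across an outbred population — classically relies on
sparse anatomical landmarks placed by hand on each µCT scan.  `meshmorph`
implements the landmark-free alternative alongside the classical route, so
the two can be compared on the same data:

- **Volumes → surfaces**: thresholding, morphological clean-up, connected
  components, marker-based watershed parcellation, marching-cubes surface
  extraction; mesh cleaning, Laplacian smoothing, quadric edge-collapse
  decimation (PLY/OBJ/STL, NRRD/NIfTI/MHD).
- **Landmark route**: landmark file dialects (MPS, TAG, CSV/TXT,
  landmarkAscii), similarity/rigid alignment, Generalised Procrustes
  Analysis, Procrustes-distance permutation tests, centroid size,
  thin-plate-spline warps.
- **Landmark-free core**: a population shape atlas under the control-point
  LDDMM model.  A Gaussian kernel of width σ_V turns momenta α_k at control
  points c_k into a velocity field v(x) = Σ_k exp(−‖x−c_k‖²/σ_V²) α_k, flowed
  through the Hamiltonian geodesic equations; surfaces are compared without
  correspondence by a varifold (or currents) kernel metric of width σ_W on
  face centres and area-weighted normals.  Estimation minimises

      J = Σ_i [ d_W²(φ_{α_i}(T), S_i) / 2σ_ε² + ½ α_iᵀ K_V α_i ]

  over template T, control points and per-subject momenta, by gradient
  descent with hand-derived adjoint gradients.
- **Statistics & maps**: kernel PCA of the momenta, stratified k-fold
  permutation classification, scrambled-group overfitting diagnostic,
  allometry (common allometric component, size-explained variance),
  Bland-Altman agreement; displacement, signed-distance and local-stretch
  heatmaps, morph sequences.
- **Synthetic populations** with known group, size, sex and noise effects,
  so the full pipeline is testable end to end without any scan data.

## Worked example

Generate a two-group study (group B carries a localized shape "bump" of
0.25 mm against 0.01 mm vertex noise), run the whole pipeline, and read the
group statistics:

```python
from meshmorph import PopulationSpec, StudyConfig, generate_population, run_pipeline, write_study

pop = generate_population(PopulationSpec(
    n_per_group=(6, 6), subdivisions=1,
    bump_amplitude=0.25, noise_sd=0.01, size_sd=0.0, seed=7))
write_study(pop, "study")

manifest = run_pipeline(StudyConfig(
    out_dir="out", mesh_dir="study/meshes", labels_csv="study/truth.csv",
    alignment="centroid", sigma_w=0.5, sigma_v=1.0,
    max_iter=60, n_perm=200, seed=0))
print(manifest["results"])
```

prints:

```
{'cv_accuracy': 1.0, 'permutation_p': 0.004975124378109453,
 'scramble_z': 4.4571438851483025, 'scramble_shapiro_p': 1.1227518253712744e-26,
 'explained_variance_ratio': [0.7686, 0.0590, 0.0393, 0.0305, 0.0286],
 'max_displacement': 0.20057478600695658}
```

(explained-variance ratios abbreviated).  Reading: the linear-discriminant
classifier separates the groups perfectly in the 5-dimensional kernel-PCA
shape space (accuracy 1.0); the label permutation test puts that at
p ≈ 0.005, the 1/(n_perm+1) floor for 200 permutations; the first shape
component alone carries 77% of the variance (the injected group bump); and
the group difference vector sits 4.5 scramble standard deviations from
random group splits (z > 3.5 ⇒ the separation is not an overfitting
artefact).  The tiny Shapiro-Wilk p is itself informative here: with an
effect this strong the scramble magnitudes are a bimodal mixture rather
than normal, which is expected when the signal dwarfs the noise.  The
displacement heatmap between group mean meshes peaks at ≈0.20 mm against a
true bump amplitude of 0.25 mm resolved at kernel width σ_W = 0.5.
Heatmaps and group means are written under `out/maps/`.

The same stages are exposed on the command line:

```bash
meshmorph synth --out study --n-per-group 6 --subdivisions 1
meshmorph atlas --meshes study/meshes --sigma-w 0.5 --out out/atlas
meshmorph stats permtest --atlas out/atlas --labels study/truth.csv
meshmorph map stretch out/maps/mean_A.ply out/maps/mean_B.ply --out stretch.ply
```

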