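# caudalmorph

Ecomorphology of the avian tail skeleton: does the shape of the pygostyle
— the fused terminal element that anchors the tail fan — track how a bird
flies and forages, once shared ancestry is accounted for?

`caudalmorph` implements the full analysis chain for that question, for
researchers doing outline-based geometric morphometrics with phylogenetic
comparative statistics:

- **Outline shape.** Elliptic Fourier analysis (Kuhl–Giardina) of closed
  silhouettes: per harmonic n the four coefficients (a_n, b_n; c_n, d_n),
  harmonic count chosen where cumulative Fourier power
  P_n = (a_n²+b_n²+c_n²+d_n²)/2 reaches 99%, normalization on the first
  harmonic to 4N−3 size/position/rotation/start-invariant NEF descriptors,
  and species averaging. Inputs: binary PNG/TIFF masks (Moore boundary
  tracing), Freeman chain-code files, or vertex CSVs.
- **Linear morphometrics.** Eleven vertebral metrics at three serial
  positions, a geometric-mean body-size proxy from five skeletal
  measurements, and phylogenetic (GLS, λ = 1) size correction.
- **Phylogenetic statistics.** Pagel's λ by ML under the covariance
  C(λ) (off-diagonals scaled by λ ∈ [0,1]); a permutation test on the
  weighted squared-change parsimony tree length; phylogenetic PCA of the
  evolutionary covariance R = (X−1a)'C⁻¹(X−1a)/(n−1) with the ≥5%
  retention rule; phylogenetic MANOVA (Pillai–Bartlett trace, ahistorical
  F-based p and a Brownian-simulation p); and phylogenetic flexible
  discriminant analysis (pFDA) — optimal-scoring LDA after whitening by
  the inverse Cholesky factor of C(λ) — with resubstitution
  misclassification rates and 2-D ordinations.
- **Synthetic study generator.** Yule trees, ecological classes with
  convergent (multi-origin) structure, λ-scaled Brownian trait matrices
  with group mean shifts, and a parametric pygostyle shape family
  (elongation / taper / dorsal deflection / mid-constriction), so the
  entire pipeline is testable end to end without museum data.

See `docs/methods.md` for the models, their assumptions, and design
decisions.

## Worked example

The numbered scripts under `analysis/` run the study design on synthetic
data. With the default seed:

```sh
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_outline_fourier.py
python analysis/03_phylogenetic_signal.py
python analysis/04_pca_manova.py
python analysis/05_discriminant.py
```

prints (abridged):

```
simulated 51 species, 152 specimens, seed=1
decomposed 152 outlines; 3 harmonics reach 99% cumulative power -> 9 NEF descriptors (4N-3)
Pygostyle Shape: lambda = 0.9878 (logLik 1179.65), permutation p = 0.001, index = 0.957
First Vertebra:  lambda = 0.5797 (logLik 1028.60), permutation p = 0.001, index = 0.734
phylogenetic PCA: kept 3 components >= 5% (PC1 66.2%, PC2 14.7%, PC3 9.0%, ...)
Foraging Style: Pillai = 2.6035, ahistorical p = 1.84e-54, phylogenetic p = 0.001
Diving Type:    Pillai = 1.8676, ahistorical p = 8.18e-26, phylogenetic p = 0.001
pFDA at lambda = 0.459: misclassification 5.88% (3 of 51)
shuffled-label control: misclassification 74.51% (chance-level expected)
```

Reading the output: pygostyle shape carries strong phylogenetic signal
(λ near 1 here because the synthetic classes are partly cladewise), the
foraging classes differ significantly in shape even against the
tree-aware simulation null, and the discriminant assigns 48 of 51 species
to the correct foraging class from outline descriptors alone — while the
same analysis on shuffled labels collapses to chance, confirming the
classifier reads shape rather than noise. The three misclassifications are
plunge divers placed among wing-propelled divers: the two classes share
elongate, straight pygostyles and differ mainly in taper. The
shape-predicts-foraging result survives the convergent design: the
wing-propelled divers arise in four separate clades, so no clade-based
rule could match this accuracy.

The same machinery is available as a CLI (`caudalmorph synth / efa /
signal / ppca / manova / pfda / pipeline`) for running on real trees,
masks and measurement tables; `caudalmorph pipeline --config cfg.yaml`
executes the whole graph and writes every table with the config hash and
seed in the run log.

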