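# lssnd

Machine-learning analysis of light-scattering spectra (LSS) of cardiac
tissue for nuclear-density (ND) characterization.

Backscattered broad-spectrum light carries information about the density and
size of sub-cellular scatterers — above all cell nuclei. In maturing
ventricular myocardium the ND (nuclei/mm²) falls steeply with gestational
age as myocytes grow, which makes age-graded tissue a natural test bed for
optical ND estimation. This package implements the full analysis chain that
links fiber-probe spectra to histologically measured ND:

* **`lssnd.spectra`** — spectrum I/O and the fixed preprocessing chain:
  per-spectrum mean normalization, 1D Gaussian filtering (SD 20 samples,
  kernel 80), optional wavelength windowing, concatenation of the paired
  collection fibers (R1 at 210 µm, R2 at 345 µm from the illumination
  fiber), and factor-K resolution reduction by linear interpolation.
* **`lssnd.histology`** — automated nucleus segmentation of two-channel
  confocal images (DAPI nucleus channel, WGA matrix channel): histogram
  thresholding at mode + 2 SD, blur + erosion/dilation cleanup, watershed
  separation of touching nuclei, ND = count / tissue area, and the three ND
  classes used as classifier labels (low < 2000, medium 2000–3800,
  high ≥ 3800 nuclei/mm²); plus the exponential ND–age fit
  ND(a) = floor + amplitude·exp(−a/τ).
* **`lssnd.clustering`** — PCA, graph spectral clustering with a locally
  scaled Gaussian affinity, eigengap selection of the cluster count, and
  one-way ANOVA with Tukey–Kramer post-hoc comparisons of cluster NDs.
* **`lssnd.cnn`** — a ~150-parameter 1D convolutional network
  (conv(3,5,2)-conv(3,5,2)-pool-conv(3,5,2)-pool-dense-softmax) written in
  NumPy with Adam, loss-checkpointing and min-delta early stopping; a
  Numba-vectorized engine trains whole hyperparameter populations in
  lockstep.
* **`lssnd.loocv`** — leave-one-out cross-validation with a per-fold random
  validation sample, the 10 × 4 learning-rate/min-delta grid search,
  accuracy = n_correct/n_total over the aggregated confusion matrix, and
  wavelength-window / resolution-reduction sensitivity sweeps with ANOVA +
  Fisher's LSD.
* **`lssnd.synthetic`** — a synthetic study cohort (no public data exist for
  the original tissue measurements): 22 samples aged 4.3–56 months with an
  ND–age decline calibrated to 72.5 % (4.3→10 mo) and 78.2 % (4.3→56 mo),
  20 two-fiber acquisitions per sample (440 spectra) whose shape depends on
  ND, and confocal-like image pairs with known nucleus counts at
  0.2 µm/pixel.

## Worked example

```python
import numpy as np
from lssnd import synthetic as syn, spectra as sp, clustering as cl
from lssnd import histology as h, loocv as lv

cohort = syn.generate_cohort(syn.CohortConfig(seed=1))
records = syn.generate_study_spectra(cohort, seed=1)      # 880 fiber traces
X, sids = sp.preprocess_dataset(records)                  # (440, 7296)

pca = cl.pca_project(X)
print(f"PC1+PC2 variance: {100 * pca.top_k_fraction(2):.1f}%")

probe = cl.spectral_cluster(X, k=2, seed=1)
k = cl.estimate_cluster_count(probe.laplacian_eigenvalues)
assignment = cl.spectral_cluster(X, k=k, seed=1)
print(f"eigengap k = {k}, "
      f"miscategorized = {cl.count_miscategorized(assignment, sids)}/440")

classes = {m.sample_id: h.assign_nd_class(m.true_nd) for m in cohort}
report = lv.run_loocv(lv.SpectraDataset(X, sids, classes),
                      downsample_K=50.0, seed=1)
print(f"LOOCV accuracy: {100 * report.aggregate_accuracy:.2f}%")
```

Output:

```
PC1+PC2 variance: 98.8%
eigengap k = 5, miscategorized = 0/440
LOOCV accuracy: 100.00%
```

The first line says two principal modes (an ND-dependent spectral tilt and a
gentle oscillation) dominate the normalized spectra. The second line shows
the eigengap recovering the five planted ND groups with every spectrum in
its sample's majority cluster. The last line is the aggregate accuracy of
the nested leave-one-out evaluation: 22 folds, each training 40 networks
(10 learning rates × 4 minimum deltas) on 20 samples' spectra downsampled
by a factor of 50, selecting by validation accuracy, and classifying the
held-out sample's 20 spectra.

A command-line interface mirrors the same stages:

```bash
lssnd simulate --seed 1 --out-dir study/ --images
lssnd preprocess --in study/spectra.csv --out study/pre.csv --downsample 50
lssnd cluster --in study/pre.csv --manifest study/manifest.csv --out study/clusters.csv
lssnd train-loocv --in study/pre.csv --manifest study/manifest.csv --out study/report.json
lssnd nd --images study/ --out study/nd.csv
lssnd sensitivity --mode resolution --in study/pre.csv --manifest study/manifest.csv --out study/k_sweep.csv
```

## Notes

See `docs/methods.md` for the generator's statistical design, the
numerical choices (affinity scaling, early-stopping semantics, watershed
seeding) and the known limitations of synthetic-data validation.
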