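# overlapnet

Decomposition of a 36-region social brain atlas into partially overlapping
structural subnetworks using a family of penalized autoencoders, plus
prediction of social-lifestyle markers from participant-wise subnetwork
expressions.

The package has two arms:

1. **Unsupervised decomposition.** Per-participant grey-matter volumes at the
   36 atlas regions (extracted from NIfTI images, or simulated) are z-scored
   and compressed through a 15-unit bottleneck by one of seven autoencoder
   configurations (identity/ReLU activations; none/l1/l2/cross-covariance
   penalties; tied or untied weights; 1, 3, or 5 latent layers). Each latent
   unit defines one signed "subnetwork" over the regions; units are ranked by
   how well they alone reconstruct the data, relevance maps are read off the
   decoder, and solutions are compared across runs by optimal-assignment
   |Pearson| matching.
2. **Supervised trait prediction.** Traits are median-split into more/less
   social, crossed with sex into four classes, and classified one-vs-rest
   from the 15 latent embeddings plus age under nested cross-validation
   (l2 logistic regression or random forest), with per-subnetwork weight
   profiles and chance calibration.

Because the original population imaging data are access-restricted, a
first-class synthetic-data module plants known overlapping subnetworks
(hub regions loading on three or more factors) so that every stage is
verifiable by parameter recovery.

## CLI

```bash
overlapnet simulate --n 2000 --seed 0 --out sim/            # synthetic volumes + covariates
overlapnet extract --manifest scans.csv --atlas default     # NIfTI -> volume matrix
overlapnet train --volumes sim/volumes_raw.csv --arch baseline --out model.json
overlapnet subnetworks --model model.json --volumes sim/volumes_raw.csv --out reports/
overlapnet predict --model model.json --volumes sim/volumes_raw.csv \
    --covariates sim/covariates.csv --estimator logistic
overlapnet run --config config.yaml       # full pipeline, writes a hashed run manifest
overlapnet replicate --config config.yaml --splits 4   # row-disjoint stability analysis
```

`config.yaml` fields mirror `overlapnet.pipeline.RunConfig`; every run is
reproducible from the config plus the master seed (per-stage seeds are
derived by fixed offsets).

The default atlas fixture (36 regions, four clusters, alphabetical within
cluster) ships with the package; pass any CSV with columns
`name,hemisphere,x,y,z,cluster` to substitute coordinates. Region order
defines the column order of all matrices downstream.

## Notes on conventions

* "Explained variance" is defined as 1 − mean absolute error on z-scored
  data (so perfect reconstruction scores 1); raw MAE is reported alongside.
* A purely linear bottleneck is only identified up to an invertible latent
  transform, so trained single-layer identity models are canonicalized to
  the principal axes of their own reconstruction before any unit-wise
  cross-run comparison (`canonicalize_latents`); this leaves the
  input-to-output map untouched.
* Sphere membership uses voxel-center distance with the sphere center at
  the voxel nearest the region's mm coordinate; smoothing uses reflect
  padding; z-scoring uses population SD and can be fit globally, on
  training rows only, or disabled down to centering (`zscore_scope`).
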