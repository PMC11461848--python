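# volfuse

Volumetric deep feature extraction, canonical-correlation feature fusion and
metaheuristic wrapper feature selection for 3-class brain-MRI-style
classification — a config-driven pipeline that is fully exercisable on
synthetic volumetric data.

The pipeline has four variants:

| model  | stages |
|--------|--------|
| model1 | 3D CNN (ablation-selected variant, conv blocks 2+3+2) → FC3 features (element-wise max of the two 1000-wide FC taps) → classical classifier |
| model2 | 15-layer 3D residual network → FC4 features (1000-wide) → classifier |
| model3 | CCA fusion of FC3 and FC4 into canonical discriminant features (Z1 concat / Z2 sum) → classifier |
| model4 | model3 + whale-optimization wrapper feature selection (KNN-error + subset-size fitness) → classifier |

PSO, GA, GSA and ACO baselines run under the identical fitness and budget
for comparison, with convergence-curve export.

Everything is NumPy/SciPy/scikit-learn based (the 3D networks are a small
self-contained NumPy framework with hand-written backprop — no GPU or deep
learning runtime required). Volumes are read from NIfTI (nibabel) or
uncompressed explicit-VR little-endian DICOM slice series (built-in minimal
reader); real MRI should be skull-stripped/bias-corrected upstream.

## CLI

```bash
# generate labeled synthetic phantoms (NIfTI + labels.json)
volfuse synth --n 12 --shape 28,28,28 --seed 1 --out scratch/vols

# full pipeline from a YAML config
volfuse run --config examples/model4.yaml --seed 1 --out scratch/run

# stage-by-stage
volfuse extract --volumes scratch/vols --labels scratch/vols/labels.json \
    --kind cnn_variant3 --tap FC3 --shape 28,28,28 --width-scale 0.25 \
    --out scratch/fc3.csv
volfuse fuse --view-a scratch/fc3.csv --view-b scratch/fc4.csv --out scratch/z1.csv
volfuse select --features scratch/z1.csv --algorithm woa --out scratch/sel.json
volfuse evaluate --features scratch/z1.csv --classifier gb --k 5 --out scratch/eval.json
```

A YAML config mirrors `volfuse.pipeline.PipelineConfig` (flat keys:
`model`, `phantom` / `volume_dir` / `feature_csvs`, `input_shape`,
`width_scale`, `cnn_train`, `resnet_train`, `fusion_lam`, `fusion_d`,
`fusion_mode`, `optimizer`, `fitness`, `classifier`, `k_folds`, `seed`).
A single master seed fans out deterministically to per-stage seeds; every
intermediate artifact (feature CSVs, CCA archive, selection JSON,
evaluation JSON, manifest) is persisted in the output directory.

## Package layout

```
src/volfuse/
  synthetic.py     phantom volumes, dual-view features, planted selection problems
  volume_io.py     NIfTI/DICOM reading, resample+z-score preprocessing
  _dicom.py        minimal explicit-VR-LE DICOM subset
  nn.py            NumPy 3D conv framework (Conv3D/BN/pool/dense, Adam/SGD)
  extractors.py    CNN + ResNet architectures, training, FC tap extraction
  fusion.py        regularized CCA, Z1/Z2 fusion
  selection/       wrapper fitness, WOA, PSO/GA/GSA/ACO, comparison
  evaluation.py    stratified k-fold metrics (accuracy/precision/recall/F1)
  pipeline.py      model1-model4 orchestration + artifacts
  cli.py           click CLI (volfuse ...)
```
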