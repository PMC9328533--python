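# svimon

Semantic vegetation cover monitoring from repeat ground-level photographs.

The pipeline aligns repeat photographs of a site with an affine registration
step, segments every pixel into vegetation / sky / other with a compact
encoder-decoder network (U-Net), computes a per-image Semantic Vegetation
Index — the percentage of pixels classified as vegetation — and aggregates
quarterly per-site SVI time series. Because no public corpus of repeat
photographs exists, the package ships a synthetic scene generator that
produces landscape-like images with exact ground-truth masks, seasonal
vegetation dynamics and viewpoint jitter, so the whole pipeline is testable
offline.

The segmentation network, its backpropagation and the SGD training loop are
implemented directly on NumPy arrays (no deep-learning framework needed);
registration uses ORB keypoints with a RANSAC affine fit.

## Modules

| Module | Purpose |
| --- | --- |
| `svimon.scenegen` | Synthetic repeat-photography albums with exact masks, seasonal dynamics, viewpoint jitter |
| `svimon.registration` | ORB + RANSAC affine alignment, checkerboard QA mosaics |
| `svimon.datakit` | Colour-mask codec (vegetation = RGB 107,142,35), resizing, 80/15/5 split, paired augmentation |
| `svimon.segnet` | NumPy U-Net (and skip-free FCN baseline), SGD training with early stopping |
| `svimon.evalkit` | Confusion counts, precision/recall/F1/overall accuracy, IoU/mIoU |
| `svimon.sviseries` | Per-image SVI, quarterly per-site series, CSV/plot export |
| `svimon.platform` | End-to-end orchestration from a single YAML config, run manifest with checksums |

## CLI

Every stage is a subcommand of `svi`:

```bash
svi generate --sites 2 --years 2015:2020 --per-quarter 1 --out data --seed 1
svi register --reference data/site001/2015Q1_0000.png \
             --sensed data/site001/2016Q3_0006.png --out reg --checkerboard
svi prepare  --manifest data/album_manifest.csv --out prep --resize 64 --seed 1
svi train    --manifest prep/prepared_manifest.csv --config cfg.yaml --out model
svi evaluate --model model/model.npz --manifest prep/prepared_manifest.csv --out eval
svi series   --manifest data/album_manifest.csv --model model/model.npz --out series
svi run      --config cfg.yaml     # all of the above from one config
```

Exit codes: 0 success, 2 configuration error, 3 stage failure.

An example `cfg.yaml` (all keys optional; see `svimon.platform.RunConfig`):

```yaml
out_dir: runs/demo
n_sites: 2
years: [2015, 2020]
per_quarter: 1
image_side: 64
unet: {depth: 3, base_filters: 16, dropout_rate: 0.5}
train: {batch_size: 8, learning_rate: 0.01, max_epochs: 10, early_stop_patience: 9}
seed: 1
```

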