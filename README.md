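# gaitrec

Skeleton-based pathological gait recognition toolkit.  It combines three
views of a 3-D skeleton walking sequence — the raw joint-position tensor, a
25-column joint-angle sequence, and a 26-entry gait-parameter vector — in a
hybrid neural classifier: a spatial-temporal graph-convolution encoder for
the skeleton, a stacked LSTM for the angle sequences, a dense encoder for
the parameters, and a fused softmax head.  Because clinical gait recordings
are rarely shareable, the package ships a parametric kinematic simulator
that generates labeled walks for six gait classes (normal, antalgic,
steppage, lurching, stiff-legged, Trendelenburg) plus an irregular
vestibular-like class, with exact ground-truth events and commanded
parameters for testing.

Everything, including the neural network layers (graph convolution,
temporal convolution, LSTM, batch normalization, Adam), is implemented in
NumPy with hand-written, finite-difference-verified backward passes, so the
package has no deep-learning framework dependency.

## Layout

| module                | contents |
|-----------------------|----------|
| `gaitrec.skeleton`    | joint sets, skeleton sequences, CSV/JSON I/O, rigid calibration, left/right mirroring, windowing, minimum-length filtering, dataset manifests |
| `gaitrec.angles`      | joint bending angles, link angles, the default 25-angle extraction |
| `gaitrec.gait`        | heel-strike / toe-off detection, basic / phase-based / angle-based gait parameters, the normalized 26-entry parameter vector |
| `gaitrec.graph`       | skeleton joint graph with 3-subset spatial-configuration partitioning |
| `gaitrec.nn`          | NumPy layer library and Adam optimizer |
| `gaitrec.model`       | the three-branch hybrid model, training loop, checkpoints |
| `gaitrec.synth`       | forward-kinematic gait simulator and dataset generators |
| `gaitrec.features`    | per-example input-view assembly |
| `gaitrec.evaluate`    | LOSO / k-fold subject-disjoint cross-validation, confusion matrices, binary metrics, the input-combination ablation harness |
| `gaitrec.cli`         | `gaitrec` command-line interface |

## CLI

```bash
# simulate a labeled dataset (writes per-walk CSVs + manifest.csv)
gaitrec simulate --out data/sim --subjects 12 --walks 20 --seed 0 --mirror

# extract features from one skeleton file
gaitrec extract data/sim/example_00000.csv --angles-out angles.csv --params-out params.csv

# train / cross-validate / ablate on a manifest
gaitrec train data/sim/manifest.csv --out model.npz --window 100 --tail-drop 10
gaitrec evaluate data/sim/manifest.csv --out metrics.csv --protocol loso
gaitrec ablate data/sim/manifest.csv --out ablation.csv

# binary metric report from confusion counts
gaitrec metrics --tp 231 --fp 11 --tn 53 --fn 17
```

Model and training options can be supplied with `--config config.yaml`
(keys `model:` and `train:` mapping onto `HybridModelConfig` and
`TrainOptions` fields).

## Conventions

Coordinates are meters in a right-handed frame: `x` lateral, `y` up,
`z` the walking direction.  Frames are 0-indexed; windows are half-open.
Angles are degrees in [0, 180].  Skeleton files are long-form CSV
(`frame,joint,x,y,z`, optional `# fps=...` first line) or JSON with
`fps`/`joints`/`frames`; dataset manifests are CSV with
`path,subject_id,gait_label,walk_index,mirrored`.
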